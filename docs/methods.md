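# Methods

## The ensemble allosteric model

A construct is a network of *n* two-state domains. Each domain *i* is either
folded (for the DNA-binding domain: in its high-affinity conformation) or
unfolded, giving microstates `S* ∈ {0,1}^n`. Relative to the all-unfolded
reference state, a microstate's free energy is

    G(s) = − Σ_{i: S*_i = 1} ΔG_i − Σ_{(i,j): S*_i = S*_j = 1} Δg_ij

with `ΔG_i` the intrinsic folding stability of domain *i* (kcal/mol,
positive = folded favored in isolation) and `Δg_ij` the pairwise coupling
free energy (positive = mutually stabilizing), contributing only when both
partners are folded. Boltzmann weights `exp(−G/RT)` over all 2^n states
yield probabilities, and two observables are probability masses:

* **affinity** — `P(DBD high-affinity)`, a proxy for relative DNA-binding
  affinity (DNA is not an explicit species; the high-affinity conformation
  stands in for the bound-competent state);
* **activity** — `P(F folded ∧ DBD high-affinity)`, a proxy for relative
  transcriptional activity. Its state set is a subset of the affinity set,
  so activity ≤ affinity always.

The equivalent spin form of the pair energy is `E_int = J_ij S*_i S*_j`
with `J_ij = −Δg_ij`: favorable coupling = negative interaction energy, the
sign of `E_int` fixed by the sign of `J`, and `S* ∈ {1, 0}` (not ±1), so a
coupling contributes only when both domains are folded.

**Energy convention.** The all-unfolded state is the zero of energy; its
weight is exactly 1. This sign convention makes "positive Δg" literally mean
"stabilizing one domain stabilizes the other" and matches the sign structure
inferred for the receptor (direct F–DBD and R–DBD couplings positive, R–F
negative). The globally sign-flipped convention is isomorphic.

**Thermal energy.** `RT = 0.593 kcal/mol` (298.15 K) by default,
configurable per model. The natural grid unit used throughout is
`RT·ln 2 ≈ 0.411 kcal/mol`, one factor of two in a Boltzmann weight.

**Numerics.** Probabilities are computed from max-shifted exponentials
(log-domain partition function), so arbitrarily large |G| cannot produce
non-finite probabilities; raw per-state weights are reported as
`exp(−G/RT)` and may overflow to `inf` in pathological inputs without
affecting probabilities. Normalization holds to 1e−12; agreement with an
independently coded brute-force enumeration is asserted to 1e−10.

## The reference frustrated parameter set

All exact tests use a three-domain (R, F, DBD) parameter set in which every
weight is a power of two: `ΔG_R = RT·ln4`, `ΔG_F = ΔG_D = 0`,
`Δg_FD = RT·ln2`, `Δg_RF = −RT·ln32`, `Δg_RD = RT·ln4`. The eight weights in
(R, F, DBD) binary-counting order are 1, 1, 1, 2, 4, 16, 1/8, 1, so
`Q = 209/8 = 26.125`, activity `= 24/209`, affinity `= 160/209`. Ablating
`Δg_RD` to zero gives weights 1, 1, 1, 2, 4, 4, 1/8, 1/4, hence
`Q = 107/8 = 13.375`, activity `= 18/107` (up), affinity `= 58/107` (down) —
the counter-intuitive frustration signature, checkable by hand.

## Frustration taxonomy

For three couplings {F–D, R–F, R–D} there are 8 sign configurations. A
configuration is *frustrated* iff the product of the three signs is −1,
equivalently iff the direct F–D sign disagrees with the indirect sign
`sign(R–F)·sign(R–D)` routed through R, equivalently iff the number of
negative couplings is odd (the number of positive couplings even). Exactly
4 of 8 are frustrated. Classification demands strictly nonzero couplings; a
zero coupling raises a degenerate-configuration error rather than silently
choosing a side. Configurations are enumerated lexicographically over
(F–D, R–F, R–D) with + before −, and the roman-numeral labels attached to
that order are presentation metadata only — they are not meant to match any
particular published figure layout.

## Isoform family and fitting

The five-isoform family shares `ΔG_F`, `ΔG_D`, `Δg_RF`, `Δg_RD`, `Δg_FD`
and gives each R-bearing isoform (A, B, C1, C2) its own R stability
(`dG_R_A` … `dG_R_C2`); C3 lacks the R-domain entirely. An optional switch
zeroes the R couplings of chosen isoforms (emulating R segments too short
to contact the DBD); it is off by default. Observables are normalized to C3
(most active, present in all experiments); the reference is configurable.

The objective is the Gaussian negative log-likelihood
`Σ ((pred_rel − obs_rel)/err)² / 2` over constructs and both observables —
weighted least squares. It is minimized by exhaustive evaluation over a
Cartesian grid (no starting-point dependence), with deterministic
tie-breaking toward the lexicographically lowest parameter vector in axis
order. The search exploits separability: a parameter read by exactly one
construct is minimized conditionally on the shared ones, so the exact
argmin of the nominal grid (default budget 10^7 points) is found from a few
thousand vectorized closed-form evaluations. The closed-form per-construct
predictors are cross-checked against the generic ensemble machinery and
against a per-point brute-force search in the test suite. Profile
likelihoods (best objective at each fixed value of one parameter) come from
the same cached arrays.

**Default reduced grid.** Axes are multiples of `RT·ln2`: R stabilities in
[−2, +3]·RT·ln2 (6 points), `ΔG_F`, `ΔG_D`, `Δg_FD` in [−2, +2]·RT·ln2 (5),
`Δg_RD` in [−1, +3]·RT·ln2 (5), `Δg_RF` in [−5, +1]·RT·ln2 (7): the
marginal-stability regime of disordered domains, with the R–F axis floored
at −5·RT·ln2 because a co-folded R–F pair already contributes <1% of the
ensemble there and more negative values are observationally
indistinguishable. Nominal size 5,670,000 points.

**Uncertainty propagation.** Measurement error is propagated by resampling
the observed values from Gaussian(observed, err), refitting each draw on
the full grid, and reporting the mean and standard deviation of the
refitted predictions. Full-grid refits (rather than re-evaluation on
reduced profile grids) are used because the cached vectorized predictions
make one refit a few milliseconds; the propagation is seeded and exactly
reproducible.

## Identifiability of the ratio-normalized family

With both observables normalized to C3, the reference rows carry no
information (they are noise around 1.0), leaving 8 informative observations
for 9 parameters. The likelihood therefore has an exactly flat direction:
fixing `Δg_FD` at an arbitrary value — including the wrong sign — and
re-optimizing the remaining parameters reproduces all ratio observables to
machine precision (the compensation drives `Δg_RF` strongly negative and
shifts `Δg_RD` and the R stabilities). Consequences, quantified by the
recovery study (`analysis/06_parameter_recovery.py`, 200 datasets at 5%
noise): `Δg_RF` sign and all R stabilities are recovered essentially always,
`Δg_RD`'s sign in ≈92% of runs, but `Δg_FD` is unidentified — its sign is
recovered in a minority of runs and its fitted value wanders along the flat
direction. Any apparent recovery of `Δg_FD` on a coarse grid is a
discretization artifact, not information in the data. Resolving the
degeneracy requires observations on an absolute scale or additional
construct types (e.g. the linker–DBD pair, whose affinities constrain
`ΔG_D` and `Δg_RD` directly); this is the main caveat on what the
synthetic-data fits demonstrate about real, ratio-only datasets.

## Perturbations

`stability_shift` adds a ΔΔG to one domain; `coupling_scale` multiplies one
coupling by a retained fraction in [0, 1]. Both are pure functions (the
input model is never mutated). The mutation-signature classifier compares
the DNA-binding affinity of the linker–DBD construct (modeled as the DBD
alone — the flexible linker is functionally inert, consistent with its
length-insensitivity) and the R–linker–DBD construct before and after a
perturbation, at tolerance 1e−9: a shift in both is *stability-type*, in
only the R-bearing construct *coupling-type*, in neither *silent*. The
engineered chimera that swaps in a heterologous DBD is modeled as the host
with its R couplings zeroed, not as a new domain type. The triple-mutant
analogue is `coupling_scale` on Δg_RD (default fraction 0), optionally
combined with a DBD stability shift; its activity-up/affinity-down
signature holds in the frustrated case-ii regime and is deliberately *not*
asserted globally — outside that regime the direction flips with the
parameters, so a non-case-ii input triggers a warning, not an error.

## Trans-effector titration

An in-trans R-domain at concentration *c* binds the host with single-site
occupancy `f = c/(c + Kd)`. Each host microstate splits into an unbound
branch (factor `1 − f`) and a bound branch (factor `f`) whose internal
effector-fold partition is renormalized by its zero-coupling value,
`χ(s) = (1 + e^{(ΔG_eff + Δg·S_D)/RT}) / (1 + e^{ΔG_eff/RT})`; the coupling
Δg enters only when the effector is folded *and* the host partner domain is
high-affinity — binding to the low-affinity conformation carries no
coupling. This is the minimal mass-action-consistent expansion: with Δg = 0
the factor is identically 1 and the curve is exactly flat. Activity is
reported relative to c = 0, so every curve starts at exactly 1.0.

## Synthetic data

The generator emulates (a) the five-isoform table of relative activities
and affinities — observed = predicted·(1 + ε), ε ~ N(0, sd), with reported
error sd·predicted (error bars scaling with the values), default sd 5% —
and (b) single-site titration curves, `base + span·c/(c + Kd)` plus
additive noise expressed as a fraction of the span. The default ground
truth is the reference frustrated set with per-isoform R stabilities
stepping down by RT·ln2 (A = 2, B = 1, C1 = 0, C2 = −1 in RT·ln2 units),
keeping every truth value on the default grid. All randomness flows from a
single integer seed.

What the generator does **not** emulate: plate effects, transfection
normalization, luminescence count statistics, correlated errors between
activity and affinity, or inter-replicate batch structure. Passing recovery
tests therefore demonstrate correctness of the inference machinery under
the stated noise model, not robustness to real-assay systematics; and per
the identifiability section, ratio-normalized synthetic data cannot
demonstrate recovery of `Δg_FD` at all.

## Problem sizes and determinism

Default study sizes: 200 synthetic datasets for recovery, 200 titration
curves for Kd recovery, 200 random networks for the brute-force
cross-check, 1000 draws for the noise-model mean check, 200 Monte-Carlo
draws for error propagation. One recovery study completes in ~1 s because
the grid predictions are computed once and shared. Every stochastic step
takes an explicit seed; derived seeds stay below 2^31.

## Known limitations

* Domains are strictly two-state; no partial folding, no intra-domain
  coupling gradients.
* DNA is implicit: affinity is a conformational probability, so absolute
  Kd's and titration-curve shapes of the full receptor are out of scope
  (the single-site module handles isolated binding curves only).
* The frustration taxonomy is specific to three couplings; n > 3 networks
  (cycle-space frustration) are not classified.
* Grid search scales exponentially in the number of *shared* parameters;
  the separable trick only removes construct-private axes.
* The fitted parameters of ratio-only data are set-identified, not
  point-identified (see identifiability above).
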