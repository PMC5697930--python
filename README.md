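# gr-eam — ensemble allosteric model of glucocorticoid receptor isoforms

Allostery in intrinsically disordered proteins cannot be explained by
propagated structural change, because there is no fixed structure to
propagate through. The human glucocorticoid receptor (GR) makes the puzzle
concrete: its translational isoforms (A, B, C1, C2, C3) share identical
DNA-binding domains yet differ in both DNA-binding affinity and
transcriptional activity — and the two do not co-vary. This package
implements the statistical-thermodynamic treatment of that behavior: an
**ensemble allosteric model (EAM)** over coupled folding domains, in which
*energetic frustration* between domain couplings tunes activation and
repression simultaneously.

It is aimed at quantitative biophysicists and computational biologists who
want to build, fit, and perturb small coupled-folding domain networks with
testable, exactly reproducible numerics.

## The model

A construct is a set of two-state domains — here R (regulatory segment of
the disordered N-terminal domain), F (functional segment carrying the
activation core), and DBD (DNA-binding domain, high- vs low-affinity
conformation). A microstate is an indicator vector `S* ∈ {0,1}^n`; its free
energy relative to the all-unfolded state is

    G(s) = − Σ_{folded i} ΔG_i − Σ_{co-folded (i,j)} Δg_ij

and state probabilities follow from Boltzmann weights `e^{−G/RT}`.
Transcriptional activity is the probability that F is folded *and* the DBD
is high-affinity; DNA-binding affinity is the probability that the DBD is
high-affinity. The pair energy in spin form is `E_int = J_ij S*_i S*_j`
with `J_ij = −Δg_ij`: a coupling contributes only when both domains fold.

With three couplings there are 8 sign topologies; the 4 with an odd number
of negative couplings are *frustrated* — the direct F–DBD route and the
R-mediated route pull F in opposite directions. GR's topology
(Δg_FD > 0, Δg_RD > 0, Δg_RF < 0) is frustrated, which yields the model's
signature prediction: weakening the R–DBD coupling **raises** activity
while **lowering** DNA-binding affinity.

On top of the core ensemble the package provides: maximum-likelihood
grid-search fitting of the shared-parameter isoform family with profile
likelihoods and Monte-Carlo error propagation; perturbation predictions
(stability vs coupling mutations, 25–100% coupling-ablation scans,
in-trans effector titration); a fully seeded synthetic-data generator; YAML
model files; and a `gr-eam` command line.

## Worked example

```sh
python analysis/02_frustration_taxonomy.py
```

prints the sign taxonomy and the ablation signature of the frustrated
reference parameter set (all weights powers of two, hand-checkable):

```
8 sign configurations, 4 frustrated:
...
R-DBD coupling 0.822 -> 0 kcal/mol: activity 0.1148 -> 0.1682 (up),
affinity 0.7656 -> 0.5421 (down) - the frustration signature
```

Here 0.1148 = 24/209 and 0.7656 = 160/209 are exact state-probability sums
over the 8-state A-isoform ensemble (partition function 26.125); ablating
the R–DBD coupling moves them to 18/107 and 58/107 (partition function
13.375). Activity rises while affinity falls — only a frustrated topology
does that.

The full pipeline, end to end:

```sh
python analysis/01_enumerate_ensembles.py      # state tables of all shipped models
python analysis/02_frustration_taxonomy.py     # 8 topologies; ablation scan
python analysis/03_simulate_isoforms.py        # synthetic 5-isoform dataset (5% noise)
python analysis/04_fit_isoforms.py             # exhaustive grid fit + profiles + error propagation
python analysis/05_perturbation_predictions.py # mutation signatures, ablation, trans-titration
python analysis/06_parameter_recovery.py       # recovery rates over 200 simulated datasets
```

The fit in step 04 searches 5,670,000 grid points exhaustively (a few
seconds, via the family's separable structure) and reports, for the seed-1
dataset, maximum-likelihood couplings `dg_FD = +0.41`, `dg_RD = +0.41`,
`dg_RF = −1.64` kcal/mol — the frustrated case-ii sign pattern. Step 06
also quantifies what ratio-normalized data *cannot* determine (one exactly
flat likelihood direction; see `docs/methods.md`).

Or from the command line:

```sh
gr-eam frustration --signs "+,-,+"     # -> frustrated
gr-eam enumerate configs/isoform_C3.yaml
gr-eam simulate --seed 1 -o data.csv && gr-eam fit --data data.csv -o fit.txt
```

Shipped model files under `configs/` encode the reference frustrated
parameter set (a synthetic, hand-checkable stand-in parameterization; see
`docs/methods.md`).

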