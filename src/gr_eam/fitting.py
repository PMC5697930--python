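"""Grid-search maximum-likelihood fitting of shared-parameter isoform families.

Observed data are per-construct relative transcriptional activities and
relative DNA-binding affinities (normalized to a reference construct) with
Gaussian uncertainties.  The objective is the Gaussian negative
log-likelihood

    nll(theta) = sum_{constructs, observables} ((pred_rel - obs_rel) / err)^2 / 2,

minimized by exhaustive evaluation over a Cartesian parameter grid — an
unbiased search with no starting-point dependence.  Per-parameter profile
likelihoods (the best objective attainable with that parameter fixed at each
grid value) summarize identifiability.

The search exploits the family's separability: a parameter read by exactly
one construct (e.g. an isoform-specific R-domain stability) can be minimized
conditionally on the shared parameters, so the exact argmin of the full grid
is found without materializing it.  Predictions are vectorized over the grid
and cached, which also makes Monte-Carlo error propagation (resample the
data, refit, collect the spread of the predictions) essentially free.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble_core import relative_observables
from .errors import (
    BudgetExceededError,
    GrEamError,
    InconsistentFamilyError,
    InfeasibleSpaceError,
    ModelError,
)
from .family import IsoformFamily

__all__ = [
    "DEFAULT_BUDGET",
    "IsoformDataset",
    "ParameterAxis",
    "ParameterSpace",
    "FitResult",
    "objective",
    "grid_search",
    "profile_likelihood",
    "propagate_uncertainty",
    "recovery_parameter_space",
]

#: Default cap on the nominal grid size of one search.
DEFAULT_BUDGET = 10_000_000

_COLUMNS = ("activity_rel", "activity_err", "affinity_rel", "affinity_err")


@dataclass(frozen=True)
class IsoformDataset:
    """Observed relative observables, one row per construct.

    ``frame`` is indexed by construct name with columns ``activity_rel``,
    ``activity_err``, ``affinity_rel``, ``affinity_err``; ``reference`` names
    the construct the values are normalized to.
    """

    frame: pd.DataFrame
    reference: str

    def __post_init__(self) -> None:
        f = self.frame.copy()
        f.index = f.index.astype(str)
        f.index.name = "construct"
        object.__setattr__(self, "frame", f)
        missing = [c for c in _COLUMNS if c not in f.columns]
        if missing:
            raise ModelError(f"dataset missing columns {missing}")
        if self.reference not in f.index:
            raise ModelError(f"reference construct {self.reference!r} has no data row")
        vals = f[list(_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ModelError("dataset contains non-finite values")
        if (vals < 0).any():
            raise ModelError("dataset values must be >= 0")
        if (f[["activity_err", "affinity_err"]].to_numpy(dtype=float) <= 0).any():
            raise ModelError("dataset errors must be > 0")

    @property
    def constructs(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# reference: {self.reference}\n")
            self.frame.to_csv(fh, float_format="%.17g", lineterminator="\n")

    @classmethod
    def from_csv(cls, path, reference: str | None = None) -> "IsoformDataset":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("# reference:"):
                file_ref = first.split(":", 1)[1].strip()
                body = fh.read()
            else:
                file_ref = None
                body = first + fh.read()
        frame = pd.read_csv(io.StringIO(body)).set_index("construct")
        ref = reference or file_ref
        if ref is None:
            raise ModelError("no reference construct given (argument or '# reference:' header)")
        return cls(frame=frame, reference=ref)


@dataclass(frozen=True)
class ParameterAxis:
    """One grid axis: explicit values, optionally sign-constrained."""

    name: str
    values: tuple[float, ...]
    sign: str | None = None  # "+" or "-" keeps only that sign

    def __post_init__(self) -> None:
        if not self.values:
            raise ModelError(f"axis {self.name!r}: empty value list")
        vals = tuple(float(v) for v in self.values)
        if self.sign == "+":
            vals = tuple(v for v in vals if v > 0)
        elif self.sign == "-":
            vals = tuple(v for v in vals if v < 0)
        elif self.sign is not None:
            raise ModelError(f"axis {self.name!r}: sign must be '+', '-' or None")
        if not vals:
            raise InfeasibleSpaceError(
                f"axis {self.name!r}: sign constraint {self.sign!r} leaves no values"
            )
        object.__setattr__(self, "values", vals)

    @classmethod
    def linspace(
        cls, name: str, lo: float, hi: float, num: int, sign: str | None = None
    ) -> "ParameterAxis":
        if not lo < hi:
            raise ModelError(f"axis {name!r}: need lo < hi")
        if num < 2:
            raise ModelError(f"axis {name!r}: need at least 2 steps for a range")
        return cls(name, tuple(np.linspace(lo, hi, num)), sign)

    @classmethod
    def fixed(cls, name: str, value: float) -> "ParameterAxis":
        return cls(name, (float(value),))

    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def step(self) -> float:
        """Representative grid step (median spacing); 0 for a fixed axis."""
        if len(self.values) < 2:
            return 0.0
        return float(np.median(np.diff(sorted(self.values))))


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered set of grid axes; the search grid is their Cartesian product."""

    axes: tuple[ParameterAxis, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "axes", tuple(self.axes))
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ModelError("duplicate axis names in parameter space")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    @property
    def size(self) -> int:
        return int(np.prod([len(a.values) for a in self.axes], dtype=object))

    def axis(self, name: str) -> ParameterAxis:
        for a in self.axes:
            if a.name == name:
                return a
        raise ModelError(f"no axis named {name!r}")

    def replace_axis(self, axis: ParameterAxis) -> "ParameterSpace":
        return ParameterSpace(tuple(axis if a.name == axis.name else a for a in self.axes))


def recovery_parameter_space(rt: float | None = None) -> ParameterSpace:
    """Default reduced grid for the five-isoform family.

    Axes are multiples of RT ln 2 (one factor of two in a Boltzmann weight),
    spanning the marginal-stability regime of disordered domains: stabilities
    and the F-DBD coupling within +-2 RT ln 2, the R-DBD coupling up to
    +3 RT ln 2, and the R-F coupling down to -5 RT ln 2, below which a
    co-folded R-F pair contributes under 1% of the ensemble and further
    decreases are unresolvable.
    """
    from .family import RT_LN2

    a = RT_LN2 if rt is None else rt * math.log(2.0)
    return ParameterSpace(
        (
            ParameterAxis.linspace("dG_R_A", -2 * a, 3 * a, 6),
            ParameterAxis.linspace("dG_R_B", -2 * a, 3 * a, 6),
            ParameterAxis.linspace("dG_R_C1", -2 * a, 3 * a, 6),
            ParameterAxis.linspace("dG_R_C2", -2 * a, 3 * a, 6),
            ParameterAxis.linspace("dG_F", -2 * a, 2 * a, 5),
            ParameterAxis.linspace("dG_D", -2 * a, 2 * a, 5),
            ParameterAxis.linspace("dg_RF", -5 * a, 1 * a, 7),
            ParameterAxis.linspace("dg_RD", -1 * a, 3 * a, 5),
            ParameterAxis.linspace("dg_FD", -2 * a, 2 * a, 5),
        )
    )


def objective(
    params: Mapping[str, float], data: IsoformDataset, family: IsoformFamily
) -> float:
    """Gaussian negative log-likelihood of the data given one parameter vector.

    This is the reference (non-vectorized) path: it builds every construct's
    ensemble through the generic machinery and normalizes to the family's
    reference construct.
    """
    needed = set(data.constructs) | {family.reference}
    models = [family.construct(name).build(params) for name in sorted(needed)]
    try:
        rel = relative_observables(models, family.reference)
    except GrEamError as exc:
        raise InconsistentFamilyError(str(exc)) from exc
    total = 0.0
    for name in data.constructs:
        row = data.frame.loc[name]
        for obs in ("activity", "affinity"):
            pred = 1.0 if name == family.reference else float(rel.loc[name, f"{obs}_rel"])
            if not math.isfinite(pred):
                raise InconsistentFamilyError(
                    f"construct {name!r} does not define the {obs} observable "
                    "present in the dataset"
                )
            resid = (pred - float(row[f"{obs}_rel"])) / float(row[f"{obs}_err"])
            total += 0.5 * resid * resid
    return total


class _GridEvaluator:
    """Cached vectorized predictions over the grid, reusable across datasets.

    Splits parameters into *shared* (read by two or more data constructs,
    counting the reference's parameters as read by everyone) and *private*
    (read by exactly one).  Predictions are evaluated once; objectives for
    any dataset over the same constructs follow by cheap reductions.
    """

    def __init__(self, space: ParameterSpace, constructs: Sequence[str], family: IsoformFamily):
        self.space = space
        self.family = family
        self.constructs = tuple(constructs)

        for p in family.parameter_names:
            space.axis(p)  # every family parameter needs an axis

        ref = family.reference
        used = {
            c: set(family.params_used(c)) | set(family.params_used(ref))
            for c in self.constructs
        }
        counts: dict[str, int] = {}
        for c in self.constructs:
            for p in used[c]:
                counts[p] = counts.get(p, 0) + 1
        self.shared = tuple(n for n in space.names if counts.get(n, 0) >= 2)
        self.private = {
            c: tuple(n for n in space.names if counts.get(n, 0) == 1 and n in used[c])
            for c in self.constructs
        }
        self.unused = tuple(n for n in space.names if counts.get(n, 0) == 0)

        shared_axes = [space.axis(n).array() for n in self.shared]
        if shared_axes:
            mesh = np.meshgrid(*shared_axes, indexing="ij")
            self.shared_shape = mesh[0].shape
            shared_flat = {n: m.reshape(-1) for n, m in zip(self.shared, mesh)}
        else:
            self.shared_shape = ()
            shared_flat = {}
        self.n_shared = int(np.prod(self.shared_shape)) if self.shared_shape else 1

        # per-construct predictions, shape (n_shared, n_private_c)
        self.priv_shape: dict[str, tuple[int, ...]] = {}
        self.pred: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.ref_pred: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in self.constructs:
            priv = self.private[c]
            priv_axes = [space.axis(n).array() for n in priv]
            if priv_axes:
                pmesh = np.meshgrid(*priv_axes, indexing="ij")
                self.priv_shape[c] = pmesh[0].shape
                priv_flat = {n: m.reshape(-1) for n, m in zip(priv, pmesh)}
            else:
                self.priv_shape[c] = ()
                priv_flat = {}
            n_priv = int(np.prod(self.priv_shape[c])) if self.priv_shape[c] else 1

            def arrays_for(spec_params: tuple[str, ...]) -> dict[str, np.ndarray]:
                out = {}
                for p in spec_params:
                    if p in shared_flat:
                        out[p] = shared_flat[p][:, None]
                    elif p in priv_flat:
                        out[p] = priv_flat[p][None, :]
                    else:  # pragma: no cover - guarded by used-set construction
                        raise ModelError(f"parameter {p!r} not located in grid")
                return out

            spec = family.construct(c)
            act, aff = spec.predict(arrays_for(spec.params))
            self.pred[c] = (
                np.broadcast_to(act, (self.n_shared, n_priv)),
                np.broadcast_to(aff, (self.n_shared, n_priv)),
            )
            ref_spec = family.construct(ref)
            r_act, r_aff = ref_spec.predict(arrays_for(ref_spec.params))
            self.ref_pred[c] = (
                np.broadcast_to(r_act, (self.n_shared, n_priv)),
                np.broadcast_to(r_aff, (self.n_shared, n_priv)),
            )

    def terms(self, data: IsoformDataset) -> dict[str, np.ndarray]:
        """Per-construct objective contributions, shape (n_shared, n_private_c)."""
        out = {}
        ref = self.family.reference
        for c in self.constructs:
            row = data.frame.loc[c]
            act, aff = self.pred[c]
            r_act, r_aff = self.ref_pred[c]
            if c == ref:
                pa = np.ones_like(act)
                pf = np.ones_like(aff)
            else:
                pa = act / r_act
                pf = aff / r_aff
            t = 0.5 * ((pa - float(row["activity_rel"])) / float(row["activity_err"])) ** 2
            t = t + 0.5 * ((pf - float(row["affinity_rel"])) / float(row["affinity_err"])) ** 2
            out[c] = t
        return out

    def minimize(self, data: IsoformDataset, profiles: bool = False):
        """Exact grid argmin (+ optional profile curves) for one dataset."""
        space = self.space
        terms = self.terms(data)
        mins = {c: terms[c].min(axis=1) for c in self.constructs}
        totals = np.zeros(self.n_shared)
        for c in self.constructs:
            totals = totals + mins[c]
        best = float(totals.min())

        # assemble candidate full vectors at the exact minimum, then apply
        # the lexicographic (axis-order) tie-break
        cand_shared = np.flatnonzero(totals == best)
        vectors = []
        for si in cand_shared:
            vec: dict[str, float] = {}
            if self.shared:
                coords = np.unravel_index(si, self.shared_shape)
                for n, k in zip(self.shared, coords):
                    vec[n] = space.axis(n).values[k]
            for c in self.constructs:
                row = terms[c][si]
                pi = int(np.argmin(row))
                if self.private[c]:
                    pcoords = np.unravel_index(pi, self.priv_shape[c])
                    for n, k in zip(self.private[c], pcoords):
                        vec[n] = space.axis(n).values[k]
            for n in self.unused:
                vec[n] = space.axis(n).values[0]
            vectors.append(tuple(vec[n] for n in space.names))
        best_vec = min(vectors)
        best_params = dict(zip(space.names, best_vec))

        profile_curves: dict[str, pd.DataFrame] = {}
        if profiles:
            shaped = totals.reshape(self.shared_shape) if self.shared else totals
            for ax_i, name in enumerate(space.names):
                vals = space.axis(name).array()
                if name in self.shared:
                    k = self.shared.index(name)
                    other = tuple(i for i in range(len(self.shared)) if i != k)
                    curve = shaped.min(axis=other) if other else shaped.copy()
                else:
                    owner = next(
                        (c for c in self.constructs if name in self.private[c]), None
                    )
                    if owner is None:  # unused parameter: flat profile
                        curve = np.full(len(vals), best)
                        profile_curves[name] = pd.DataFrame(
                            {"value": vals, "objective": curve}
                        )
                        continue
                    rest = totals - mins[owner]
                    t = terms[owner].reshape((self.n_shared,) + self.priv_shape[owner])
                    k = self.private[owner].index(name)
                    other = tuple(
                        1 + i for i in range(len(self.private[owner])) if i != k
                    )
                    t_min = t.min(axis=other) if other else t
                    # t_min shape (n_shared, len(vals))
                    curve = (rest[:, None] + t_min).min(axis=0)
                profile_curves[name] = pd.DataFrame({"value": vals, "objective": curve})
        return best_params, best, profile_curves


@dataclass
class FitResult:
    """Outcome of a grid search."""

    best_params: dict[str, float]
    objective: float
    profiles: dict[str, pd.DataFrame]
    predicted: pd.DataFrame
    grid_size: int
    uncertainty: pd.DataFrame | None = None
    evaluator: _GridEvaluator | None = field(default=None, repr=False, compare=False)

    def to_text(self, path) -> None:
        """Structured-text serialization with embedded profile CSV blocks."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("[best_params]\n")
            for k, v in self.best_params.items():
                fh.write(f"{k} = {v:.17g}\n")
            fh.write(f"\n[objective]\n{self.objective:.17g}\n")
            fh.write(f"\n[grid_size]\n{self.grid_size}\n")
            fh.write("\n[predicted]\n")
            fh.write(self.predicted.to_csv(float_format="%.17g", lineterminator="\n"))
            for name, curve in self.profiles.items():
                fh.write(f"\n[profile {name}]\n")
                fh.write(curve.to_csv(index=False, float_format="%.17g", lineterminator="\n"))
            if self.uncertainty is not None:
                fh.write("\n[uncertainty]\n")
                fh.write(self.uncertainty.to_csv(float_format="%.17g", lineterminator="\n"))


def grid_search(
    space: ParameterSpace,
    data: IsoformDataset,
    family: IsoformFamily,
    budget: int = DEFAULT_BUDGET,
    profiles: bool = True,
) -> FitResult:
    """Exhaustive maximum-likelihood search over the Cartesian grid.

    Evaluates (exactly, via the separable decomposition) every grid point
    and returns the argmin, breaking ties toward the lexicographically
    lowest parameter vector in axis order.  Refuses grids whose nominal size
    exceeds ``budget``.
    """
    if space.size > budget:
        raise BudgetExceededError(required=space.size, budget=budget)
    evaluator = _GridEvaluator(space, data.constructs, family)
    best_params, best, curves = evaluator.minimize(data, profiles=profiles)
    models = family.build_models(best_params)
    predicted = relative_observables(models, family.reference)
    return FitResult(
        best_params=best_params,
        objective=best,
        profiles=curves,
        predicted=predicted,
        grid_size=space.size,
        evaluator=evaluator,
    )


def profile_likelihood(
    space: ParameterSpace,
    data: IsoformDataset,
    family: IsoformFamily,
    param: str,
    budget: int = DEFAULT_BUDGET,
) -> pd.DataFrame:
    """Profile-likelihood curve for one parameter.

    For each grid value of ``param``, the minimum objective over all other
    parameters; its minimum equals the global grid-search objective.
    """
    space.axis(param)
    fit = grid_search(space, data, family, budget=budget, profiles=True)
    return fit.profiles[param]


def propagate_uncertainty(
    fit: FitResult,
    data: IsoformDataset,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo propagation of measurement error through the model.

    Resamples the observed relative values from Gaussian(observed, err),
    refits on the cached grid, and reports the mean and standard deviation
    of the refitted model's predicted observables per construct.  Fully
    seeded and reproducible.
    """
    if n_draws < 2:
        raise ModelError("n_draws must be >= 2")
    if fit.evaluator is None:
        raise ModelError("fit carries no grid cache; rerun grid_search first")
    rng = np.random.default_rng(seed)
    ev = fit.evaluator
    family = ev.family
    samples: dict[str, list[np.ndarray]] = {c: [] for c in data.constructs}
    base = data.frame.copy()
    for _ in range(n_draws):
        drawn = base.copy()
        for obs in ("activity", "affinity"):
            drawn[f"{obs}_rel"] = base[f"{obs}_rel"] + rng.normal(
                0.0, base[f"{obs}_err"].to_numpy(dtype=float)
            )
        drawn[["activity_rel", "affinity_rel"]] = drawn[
            ["activity_rel", "affinity_rel"]
        ].clip(lower=0.0)
        resampled = IsoformDataset(frame=drawn, reference=data.reference)
        best_params, _, _ = ev.minimize(resampled, profiles=False)
        models = family.build_models(best_params)
        rel = relative_observables(models, family.reference)
        for c in data.constructs:
            samples[c].append(rel.loc[c, ["activity_rel", "affinity_rel"]].to_numpy(dtype=float))
    rows = {}
    for c, draws in samples.items():
        arr = np.asarray(draws)
        rows[c] = {
            "activity_rel_mean": arr[:, 0].mean(),
            "activity_rel_sd": arr[:, 0].std(ddof=1),
            "affinity_rel_mean": arr[:, 1].mean(),
            "affinity_rel_sd": arr[:, 1].std(ddof=1),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
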