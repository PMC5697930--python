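"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the two measurement types the fitting
stage consumes: (a) per-isoform relative transcriptional activities and
relative DNA-binding affinities with error bars that scale with the values
(multiplicative Gaussian noise), and (b) raw single-site binding titration
curves of the fluorescence-anisotropy kind (hyperbolic saturation plus
additive noise).  All randomness flows from a single integer seed through
``numpy.random.default_rng``; no unseeded entropy anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .ensemble_core import relative_observables
from .errors import FitConvergenceError, ModelError
from .family import IsoformFamily, default_truth_params, gr_isoform_family
from .fitting import IsoformDataset

__all__ = [
    "GroundTruth",
    "TitrationCurve",
    "default_ground_truth",
    "generate_isoform_dataset",
    "generate_titration",
    "fit_single_site",
    "parameter_recovery_study",
]


@dataclass(frozen=True)
class GroundTruth:
    """Known family parameters plus a noise model, for parameter recovery."""

    family: IsoformFamily
    params: Mapping[str, float]
    noise_sd: float = 0.05  # relative (multiplicative) Gaussian sd
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ModelError("noise_sd must be > 0")
        missing = [p for p in self.family.parameter_names if p not in self.params]
        if missing:
            raise ModelError(f"ground truth missing parameters {missing}")
        # every construct must resolve to a valid model
        self.family.build_models(self.params)


def default_ground_truth(noise_sd: float = 0.05, seed: int = 0) -> GroundTruth:
    """Five-isoform truth at the reference frustrated parameter set."""
    family = gr_isoform_family()
    return GroundTruth(
        family=family, params=default_truth_params(family.thermal_energy),
        noise_sd=noise_sd, seed=seed,
    )


def generate_isoform_dataset(truth: GroundTruth) -> IsoformDataset:
    """Noisy observed relative observables for every construct in the family.

    observed = predicted * (1 + eps) with eps ~ N(0, sd) drawn independently
    per construct and observable; the reported error is sd * predicted.
    """
    rng = np.random.default_rng(truth.seed)
    models = truth.family.build_models(truth.params)
    rel = relative_observables(models, truth.family.reference)
    rows = {}
    for name in truth.family.construct_names:
        pred_act = float(rel.loc[name, "activity_rel"])
        pred_aff = float(rel.loc[name, "affinity_rel"])
        eps_act, eps_aff = rng.normal(0.0, truth.noise_sd, size=2)
        rows[name] = {
            "activity_rel": max(pred_act * (1.0 + eps_act), 0.0),
            "activity_err": truth.noise_sd * pred_act,
            "affinity_rel": max(pred_aff * (1.0 + eps_aff), 0.0),
            "affinity_err": truth.noise_sd * pred_aff,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return IsoformDataset(frame=frame, reference=truth.family.reference)


def parameter_recovery_study(
    n_datasets: int = 200,
    noise_sd: float = 0.05,
    seed: int = 0,
    space=None,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """End-to-end parameter recovery: simulate, fit, score, repeat.

    Generates ``n_datasets`` noisy datasets from the ground truth (default:
    the reference frustrated set), grid-searches each on ``space`` (default:
    the reduced recovery grid), and reports per parameter the fraction of
    runs recovering the true coupling sign and the fraction landing within
    two grid steps of the truth.  The grid's cached predictions are shared
    across datasets, so the study runs in seconds.

    Returns a DataFrame indexed by parameter with columns ``truth``,
    ``sign_rate`` (NaN for parameters whose true value is 0, where a sign is
    meaningless) and ``within_2_steps_rate``.
    """
    from .fitting import _GridEvaluator, recovery_parameter_space

    if truth is None:
        truth = default_ground_truth(noise_sd=noise_sd, seed=seed)
    family = truth.family
    if space is None:
        space = recovery_parameter_space(family.thermal_energy)
    evaluator = _GridEvaluator(space, family.construct_names, family)
    rng = np.random.default_rng(seed)
    dataset_seeds = rng.integers(0, 2**31 - 1, size=n_datasets)

    names = space.names
    hits_sign = {n: 0 for n in names}
    hits_step = {n: 0 for n in names}
    for s in dataset_seeds:
        data = generate_isoform_dataset(
            GroundTruth(family=family, params=truth.params,
                        noise_sd=truth.noise_sd, seed=int(s))
        )
        best, _, _ = evaluator.minimize(data, profiles=False)
        for n in names:
            true_val = float(truth.params[n])
            if np.sign(best[n]) == np.sign(true_val) and true_val != 0.0:
                hits_sign[n] += 1
            step = space.axis(n).step
            if abs(best[n] - true_val) <= 2 * step + 1e-9:
                hits_step[n] += 1
    rows = {}
    for n in names:
        true_val = float(truth.params[n])
        rows[n] = {
            "truth": true_val,
            "sign_rate": hits_sign[n] / n_datasets if true_val != 0.0 else math.nan,
            "within_2_steps_rate": hits_step[n] / n_datasets,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class TitrationCurve:
    """A single-site binding titration: response vs ligand concentration."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    true_kd: float | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", tuple(float(r) for r in self.responses))
        if len(conc) != len(self.responses):
            raise ModelError("concentrations and responses differ in length")
        if any(c < 0 for c in conc):
            raise ModelError("concentrations must be >= 0")
        if any(b >= a for a, b in zip(conc[1:], conc[:-1])):
            raise ModelError("concentrations must be strictly increasing")


def _isotherm(c: np.ndarray, kd: float, base: float, span: float) -> np.ndarray:
    return base + span * c / (c + kd)


def generate_titration(
    kd: float,
    concentrations,
    base: float = 0.05,
    span: float = 0.15,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Anisotropy-style saturation curve: base + span * c/(c+Kd) + noise.

    ``noise_sd`` is additive Gaussian noise expressed as a fraction of the
    span (so 0.02 is "2% noise").
    """
    if not kd > 0:
        raise ModelError("Kd must be > 0")
    conc = np.asarray(sorted(concentrations), dtype=float)
    rng = np.random.default_rng(seed)
    resp = _isotherm(conc, kd, base, span)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd * span, size=conc.size)
    return TitrationCurve(
        concentrations=tuple(conc), responses=tuple(resp), true_kd=kd, noise_sd=noise_sd
    )


def fit_single_site(curve: TitrationCurve) -> dict[str, float]:
    """Least-squares fit of the single-site isotherm to a titration curve.

    Returns ``{"kd", "base", "span", "residual_norm"}``.  Raises
    :class:`FitConvergenceError` for degenerate (e.g. flat) or
    non-convergent inputs.
    """
    c = np.asarray(curve.concentrations, dtype=float)
    y = np.asarray(curve.responses, dtype=float)
    if c.size < 4:
        raise ModelError("need at least 4 titration points")
    if np.ptp(y) <= 0 or not np.isfinite(y).all():
        raise FitConvergenceError("responses carry no transition; Kd unidentifiable")
    p0 = (float(np.median(c[c > 0])) if (c > 0).any() else 1.0, float(y.min()), float(np.ptp(y)))
    try:
        popt, _ = optimize.curve_fit(
            _isotherm, c, y, p0=p0,
            bounds=([1e-12, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(f"single-site fit failed: {exc}") from exc
    kd, base, span = map(float, popt)
    resid = float(np.linalg.norm(y - _isotherm(c, kd, base, span)))
    return {"kd": kd, "base": base, "span": span, "residual_norm": resid}
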