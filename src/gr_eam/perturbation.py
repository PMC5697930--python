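"""Perturbed and engineered constructs: mutations, coupling ablation,
trans-effector titration.

Two mutation classes are distinguishable by their experimental signature on a
pair of constructs (DBD behind an inert linker, with and without the
R-domain): a *stability* mutation of the DBD shifts the DNA-binding affinity
of both constructs, whereas a *coupling* mutation (weakening the R-DBD
interaction) shifts only the R-containing construct.

For a frustrated (case-ii) isoform, weakening the R-DBD coupling removes the
R-mediated repression of the functional domain faster than it removes the
direct stabilization of the DBD, so activity *rises* while DNA-binding
affinity *falls* — the counter-intuitive signature of energetic frustration.

The trans-effector model treats a separately expressed R-domain as a ligand
of the host: at concentration *c* each host microstate splits into an
unbound branch (weight factor 1 - f) and a bound branch (weight factor f)
with single-site occupancy f = c / (c + Kd).  Within the bound branch the
effector has its own fold equilibrium, and its coupling free energy
contributes only when the effector is folded and the host partner domain is
in its high-affinity form; binding to the low-affinity form carries no
coupling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ensemble_core import (
    CouplingSpec,
    DomainSpec,
    ProteinModel,
    ensemble,
    enumerate_states,
    observable_activity,
    observable_affinity,
    state_free_energy,
)
from .errors import ModelError

__all__ = [
    "Perturbation",
    "TransEffector",
    "apply_perturbation",
    "mutation_signature",
    "frustration_prediction",
    "trans_titration",
]

_SIGNATURE_TOL = 1e-9


@dataclass(frozen=True)
class Perturbation:
    """A stability shift of one domain or a scaling of one coupling.

    ``magnitude`` is a ddG in kcal/mol for ``stability_shift`` and the
    retained fraction in [0, 1] for ``coupling_scale`` (0 = full ablation,
    1 = unperturbed).
    """

    kind: str
    target: str | tuple[str, str]
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ("stability_shift", "coupling_scale"):
            raise ModelError(f"unknown perturbation kind {self.kind!r}")
        if not math.isfinite(self.magnitude):
            raise ModelError("perturbation magnitude must be finite")
        if self.kind == "coupling_scale" and not 0.0 <= self.magnitude <= 1.0:
            raise ModelError(
                f"coupling_scale fraction must be in [0, 1], got {self.magnitude}"
            )
        if self.kind == "coupling_scale":
            object.__setattr__(self, "target", tuple(self.target))


@dataclass(frozen=True)
class TransEffector:
    """An in-trans effector domain titrated against a host construct."""

    effector: DomainSpec
    dissociation_constant: float
    concentrations: tuple[float, ...]
    coupling_to: CouplingSpec

    def __post_init__(self) -> None:
        if not self.dissociation_constant > 0:
            raise ModelError("dissociation constant must be > 0")
        object.__setattr__(self, "concentrations", tuple(self.concentrations))
        if len(self.concentrations) < 1:
            raise ModelError("need at least one concentration")
        if any(c < 0 for c in self.concentrations):
            raise ModelError("concentrations must be >= 0")
        if self.effector.name not in self.coupling_to.pair:
            raise ModelError("coupling_to must involve the effector domain")


def apply_perturbation(model: ProteinModel, p: Perturbation) -> ProteinModel:
    """Return a perturbed copy of the model; the input is never mutated."""
    if p.kind == "stability_shift":
        old = model.domains[model.domain_index(p.target)].stability
        return model.with_stability(p.target, old + p.magnitude)
    coupling = model.coupling_for(p.target)  # coupling_scale
    if coupling is None:
        raise ModelError(f"model {model.name!r}: no coupling for pair {p.target!r}")
    return model.with_coupling(p.target, coupling.delta_g * p.magnitude)


def _affinity_of(model: ProteinModel) -> float:
    return observable_affinity(ensemble(model), model)


def _applies(model: ProteinModel, p: Perturbation) -> bool:
    if p.kind == "stability_shift":
        return p.target in model.domain_names
    return model.coupling_for(p.target) is not None


def mutation_signature(
    base_pair_models: tuple[ProteinModel, ProteinModel], p: Perturbation
) -> str:
    """Classify a mutation by which construct's DNA-binding affinity it moves.

    ``base_pair_models`` is (linker-DBD, R-linker-DBD).  Returns
    ``"stability-type"`` (both affinities move), ``"coupling-type"`` (only
    the R-containing construct moves) or ``"silent"`` (neither moves); a
    perturbation whose target is absent from a construct leaves that
    construct unchanged.
    """
    without_r, with_r = base_pair_models
    changes = []
    for model in (without_r, with_r):
        if _applies(model, p):
            delta = abs(_affinity_of(apply_perturbation(model, p)) - _affinity_of(model))
        else:
            delta = 0.0
        changes.append(delta > _SIGNATURE_TOL)
    if changes[0] and changes[1]:
        return "stability-type"
    if changes[1] and not changes[0]:
        return "coupling-type"
    if not changes[0] and not changes[1]:
        return "silent"
    raise ModelError(
        "perturbation moved only the construct lacking the R-domain; the "
        "construct pair is not nested as required"
    )


def frustration_prediction(
    model_a: ProteinModel,
    fractions: Iterable[float],
    pair: tuple[str, str] = ("R", "DBD"),
) -> pd.DataFrame:
    """Observable changes when the R-DBD coupling is scaled down.

    Returns one row per retained fraction with activity and affinity deltas
    relative to the unperturbed (fraction 1.0) model.  For a frustrated
    case-ii parameter set the prediction is d_activity > 0 and
    d_affinity < 0 at reduced coupling; outside that regime the direction is
    parameter-dependent, so a non-case-ii model triggers a warning rather
    than an error.
    """
    fractions = sorted(set(float(f) for f in fractions))
    if not fractions:
        raise ModelError("empty fraction list")
    if 1.0 not in fractions:
        raise ModelError("fractions must include 1.0 as the unperturbed baseline")
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ModelError("fractions must lie in [0, 1]")

    def dg(pair_):
        c = model_a.coupling_for(pair_)
        return None if c is None else c.delta_g

    fd, rd, rf = dg(("F", "DBD")), dg(pair), dg(("R", "F"))
    if None in (fd, rd, rf) or not (fd > 0 and rd > 0 and rf < 0):
        warnings.warn(
            "model is not in the frustrated case-ii sign regime "
            "(dg_FD > 0, dg_RD > 0, dg_RF < 0); the direction of the "
            "predicted changes is regime-dependent",
            stacklevel=2,
        )

    base = ensemble(model_a)
    act0 = observable_activity(base, model_a)
    aff0 = observable_affinity(base, model_a)
    rows = []
    for f in fractions:
        m = apply_perturbation(model_a, Perturbation("coupling_scale", pair, f))
        res = ensemble(m)
        rows.append(
            {
                "fraction": f,
                "d_activity": observable_activity(res, m) - act0,
                "d_affinity": observable_affinity(res, m) - aff0,
            }
        )
    return pd.DataFrame(rows)


def trans_titration(host: ProteinModel, eff: TransEffector) -> pd.DataFrame:
    """Activity of the host titrated with an in-trans effector domain.

    Each host microstate is split into an unbound branch (weight factor
    1 - f(c)) and a bound branch (weight factor f(c) times the effector's
    internal fold partition, renormalized so that a couplingless effector
    leaves the host ensemble untouched).  Activity is reported relative to
    the zero-concentration point, so every curve starts at exactly 1.0.
    """
    partner = [n for n in eff.coupling_to.pair if n != eff.effector.name]
    if not partner or partner[0] not in host.domain_names:
        raise ModelError(
            f"host {host.name!r} lacks the coupling partner domain of the effector"
        )
    if any(c < 0 for c in eff.concentrations):
        raise ModelError("concentrations must be >= 0")
    partner_idx = host.domain_index(partner[0])
    if host.functional_domain is None or host.binding_domain is None:
        raise ModelError("trans_titration host needs activity and affinity readouts")
    func_idx = host.domain_index(host.functional_domain.name)
    bind_idx = host.domain_index(host.binding_domain.name)

    rt = host.thermal_energy
    states = enumerate_states(host)
    log_w = np.array([-state_free_energy(host, s) / rt for s in states])
    w = np.exp(log_w - log_w.max())
    partner_on = np.array([bool(s[partner_idx]) for s in states])
    active = np.array([bool(s[func_idx] and s[bind_idx]) for s in states])

    e_fold = math.exp(eff.effector.stability / rt)
    e_coupled = math.exp((eff.effector.stability + eff.coupling_to.delta_g) / rt)
    # bound-branch internal partition, normalized by its zero-coupling value
    chi = np.where(partner_on, (1.0 + e_coupled) / (1.0 + e_fold), 1.0)

    def activity_at(c: float) -> float:
        f = c / (c + eff.dissociation_constant)
        total = w * ((1.0 - f) + f * chi)
        return float(total[active].sum() / total.sum())

    act0 = activity_at(0.0)
    rows = [
        {"concentration": c, "activity_rel": activity_at(c) / act0}
        for c in eff.concentrations
    ]
    return pd.DataFrame(rows)
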