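"""Microstate ensembles for networks of two-state protein domains.

A protein is modeled as *n* domains, each of which is either folded (for the
DNA-binding domain: in its high-affinity conformation) or unfolded
(low-affinity).  A microstate is an indicator vector ``S* in {0,1}^n``.  Its
free energy, relative to the all-unfolded reference state, is

    G(s) = - sum_{i folded} dG_i  -  sum_{(i,j) co-folded} dg_ij

where ``dG_i`` is the intrinsic stability of domain *i* (positive favors the
folded form) and ``dg_ij`` is the pairwise coupling free energy (positive
means mutually stabilizing; it contributes only when *both* partners are
folded).  Boltzmann weights ``exp(-G/RT)`` over all 2^n states give the state
probabilities, and the two experimental observables are probability masses:

* *affinity* — total probability of states whose binding domain (DBD) is in
  the high-affinity conformation; a proxy for relative DNA-binding affinity.
* *activity* — total probability of states where the functional domain (F)
  is folded *and* the DBD is high-affinity; a proxy for relative
  transcriptional activity.

The equivalent spin formalism writes the pair interaction as
``E_int = J_ij * S*_i * S*_j`` with ``J_ij = -dg_ij``, so a favorable
coupling is a negative interaction energy, as in magnetic frustration models.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ModelError, ObservableUndefinedError

#: Default thermal energy RT in kcal/mol (298.15 K).
DEFAULT_RT = 0.593

__all__ = [
    "DEFAULT_RT",
    "DomainSpec",
    "CouplingSpec",
    "ProteinModel",
    "MicroState",
    "EnsembleResult",
    "enumerate_states",
    "interaction_energy",
    "state_free_energy",
    "ensemble",
    "observable_affinity",
    "observable_activity",
    "relative_observables",
]


@dataclass(frozen=True)
class DomainSpec:
    """One two-state unit: folded/high-affinity vs unfolded/low-affinity.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"R"``, ``"F"``, ``"DBD"``.
    stability:
        Intrinsic folding free energy dG in kcal/mol.  Positive means the
        folded (high-affinity) form is favored in isolation.
    is_functional:
        Marks the transcription-readout domain (F).
    is_binding:
        Marks the DNA-binding readout domain (DBD).
    """

    name: str
    stability: float
    is_functional: bool = False
    is_binding: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("domain name must be non-empty")
        if not math.isfinite(self.stability):
            raise ModelError(f"domain {self.name!r}: stability must be finite")


@dataclass(frozen=True)
class CouplingSpec:
    """Pairwise coupling free energy between two domains.

    ``delta_g > 0`` is a favorable coupling: stabilizing one domain
    stabilizes the other.  The spin-model interaction constant is
    ``j_energy = -delta_g``.
    """

    pair: tuple[str, str]
    delta_g: float

    def __post_init__(self) -> None:
        if len(self.pair) != 2 or self.pair[0] == self.pair[1]:
            raise ModelError(f"coupling pair must be two distinct names, got {self.pair!r}")
        if not math.isfinite(self.delta_g):
            raise ModelError(f"coupling {self.pair!r}: delta_g must be finite")
        object.__setattr__(self, "pair", (str(self.pair[0]), str(self.pair[1])))

    @property
    def j_energy(self) -> float:
        """Spin-model interaction constant J = -delta_g (kcal/mol)."""
        return -self.delta_g

    def key(self) -> frozenset[str]:
        return frozenset(self.pair)


@dataclass(frozen=True)
class ProteinModel:
    """A named domain network: one isoform or engineered construct."""

    name: str
    domains: tuple[DomainSpec, ...]
    couplings: tuple[CouplingSpec, ...] = ()
    thermal_energy: float = DEFAULT_RT

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        object.__setattr__(self, "couplings", tuple(self.couplings))
        if len(self.domains) < 1:
            raise ModelError(f"model {self.name!r}: needs at least one domain")
        names = [d.name for d in self.domains]
        if len(set(names)) != len(names):
            raise ModelError(f"model {self.name!r}: duplicate domain names")
        if sum(d.is_functional for d in self.domains) > 1:
            raise ModelError(f"model {self.name!r}: more than one functional domain")
        if sum(d.is_binding for d in self.domains) > 1:
            raise ModelError(f"model {self.name!r}: more than one binding domain")
        if not (self.thermal_energy > 0 and math.isfinite(self.thermal_energy)):
            raise ModelError(f"model {self.name!r}: thermal_energy must be positive")
        seen: set[frozenset[str]] = set()
        for c in self.couplings:
            for member in c.pair:
                if member not in names:
                    raise ModelError(
                        f"model {self.name!r}: coupling {c.pair!r} references "
                        f"unknown domain {member!r}"
                    )
            if c.key() in seen:
                raise ModelError(f"model {self.name!r}: duplicate coupling {c.pair!r}")
            seen.add(c.key())

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def domain_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.domains)

    def domain_index(self, name: str) -> int:
        try:
            return self.domain_names.index(name)
        except ValueError:
            raise ModelError(f"model {self.name!r}: no domain named {name!r}") from None

    def coupling_for(self, pair: tuple[str, str]) -> CouplingSpec | None:
        key = frozenset(pair)
        for c in self.couplings:
            if c.key() == key:
                return c
        return None

    @property
    def functional_domain(self) -> DomainSpec | None:
        return next((d for d in self.domains if d.is_functional), None)

    @property
    def binding_domain(self) -> DomainSpec | None:
        return next((d for d in self.domains if d.is_binding), None)

    def with_coupling(self, pair: tuple[str, str], delta_g: float) -> "ProteinModel":
        """Return a copy with the coupling for ``pair`` set to ``delta_g``."""
        key = frozenset(pair)
        if self.coupling_for(pair) is None:
            raise ModelError(f"model {self.name!r}: no coupling for pair {pair!r}")
        new = tuple(
            replace(c, delta_g=delta_g) if c.key() == key else c for c in self.couplings
        )
        return replace(self, couplings=new)

    def with_stability(self, domain: str, stability: float) -> "ProteinModel":
        """Return a copy with the named domain's stability replaced."""
        self.domain_index(domain)
        new = tuple(
            replace(d, stability=stability) if d.name == domain else d
            for d in self.domains
        )
        return replace(self, domains=new)


@dataclass(frozen=True)
class MicroState:
    """One microstate: indicator vector with energy, weight and probability."""

    indicators: tuple[int, ...]
    free_energy: float
    weight: float
    probability: float


@dataclass(frozen=True)
class EnsembleResult:
    """The full 2^n ensemble of a model plus its two observables.

    ``activity`` / ``affinity`` are ``None`` when the model lacks the
    corresponding readout domain (use the ``observable_*`` functions to get
    an explicit error instead).
    """

    model: ProteinModel
    states: tuple[MicroState, ...]
    partition_function: float
    activity: float | None = None
    affinity: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """State table: one row per microstate, one indicator column per domain."""
        names = self.model.domain_names
        rows = []
        for i, s in enumerate(self.states):
            row: dict[str, object] = {"state_id": i}
            row.update({n: s.indicators[k] for k, n in enumerate(names)})
            row["free_energy_kcal_mol"] = s.free_energy
            row["weight"] = s.weight
            row["probability"] = s.probability
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_states(model: ProteinModel) -> list[tuple[int, ...]]:
    """All 2^n indicator vectors in binary-counting order.

    The first-listed domain is the most significant bit, so the all-unfolded
    reference state comes first and the fully folded state last.
    """
    return [tuple(bits) for bits in itertools.product((0, 1), repeat=model.n_domains)]


def interaction_energy(j_energy: float, s_i: int, s_j: int) -> float:
    """Spin-model pair energy ``E_int = J * S*_i * S*_j`` in kcal/mol.

    Nonzero only when both domains are folded (``S* = 1``); an unfolded
    domain (``S* = 0``) switches its couplings off entirely.
    """
    if s_i not in (0, 1) or s_j not in (0, 1):
        raise ModelError(f"indicators must be 0 or 1, got ({s_i!r}, {s_j!r})")
    return j_energy * s_i * s_j


def state_free_energy(model: ProteinModel, indicators: tuple[int, ...]) -> float:
    """Free energy G(s) of one microstate relative to the all-unfolded state.

    G(s) = -sum_{folded} dG_i - sum_{co-folded pairs} dg_ij.  The all-zero
    state returns exactly 0.0.
    """
    if len(indicators) != model.n_domains:
        raise ModelError(
            f"indicator vector has length {len(indicators)}, model has "
            f"{model.n_domains} domains"
        )
    for s in indicators:
        if s not in (0, 1):
            raise ModelError(f"indicators must be 0 or 1, got {s!r}")
    g = 0.0
    for d, s in zip(model.domains, indicators):
        if s:
            g -= d.stability
    index = {name: i for i, name in enumerate(model.domain_names)}
    for c in model.couplings:
        i, j = index[c.pair[0]], index[c.pair[1]]
        if indicators[i] and indicators[j]:
            g -= c.delta_g
    return g


def ensemble(model: ProteinModel) -> EnsembleResult:
    """Enumerate all microstates and compute Boltzmann probabilities.

    Probabilities are computed from max-shifted exponentials so that models
    with very large |G| still yield finite, normalized probabilities.
    """
    rt = model.thermal_energy
    states = enumerate_states(model)
    energies = np.array([state_free_energy(model, s) for s in states])
    log_w = -energies / rt
    shift = log_w.max()
    shifted = np.exp(log_w - shift)
    probs = shifted / shifted.sum()
    # raw weights may overflow to inf for extreme energies; probabilities stay finite
    with np.errstate(over="ignore"):
        weights = np.exp(log_w)
    log_q = shift + math.log(shifted.sum())
    with np.errstate(over="ignore"):
        q = float(np.exp(log_q))

    micro = tuple(
        MicroState(
            indicators=s,
            free_energy=float(e),
            weight=float(w),
            probability=float(p),
        )
        for s, e, w, p in zip(states, energies, weights, probs)
    )

    activity = affinity = None
    bind = model.binding_domain
    func = model.functional_domain
    if bind is not None:
        bi = model.domain_index(bind.name)
        affinity = float(sum(p for s, p in zip(states, probs) if s[bi]))
        if func is not None:
            fi = model.domain_index(func.name)
            activity = float(sum(p for s, p in zip(states, probs) if s[bi] and s[fi]))
    return EnsembleResult(
        model=model,
        states=micro,
        partition_function=q,
        activity=activity,
        affinity=affinity,
    )


def observable_affinity(result: EnsembleResult, model: ProteinModel) -> float:
    """Relative DNA-binding affinity: P(binding domain in high-affinity form)."""
    if model.binding_domain is None:
        raise ObservableUndefinedError(
            f"model {model.name!r} has no is_binding domain; affinity undefined"
        )
    bi = model.domain_index(model.binding_domain.name)
    return float(sum(s.probability for s in result.states if s.indicators[bi]))


def observable_activity(result: EnsembleResult, model: ProteinModel) -> float:
    """Relative transcriptional activity: P(F folded and DBD high-affinity).

    The contributing state set is a subset of the affinity set, so
    activity <= affinity always holds.
    """
    if model.binding_domain is None or model.functional_domain is None:
        raise ObservableUndefinedError(
            f"model {model.name!r} needs both is_functional and is_binding "
            "domains for activity"
        )
    bi = model.domain_index(model.binding_domain.name)
    fi = model.domain_index(model.functional_domain.name)
    return float(
        sum(s.probability for s in result.states if s.indicators[bi] and s.indicators[fi])
    )


def relative_observables(models: list[ProteinModel], reference: str) -> pd.DataFrame:
    """Observables of each model normalized to a reference construct.

    Returns a DataFrame indexed by construct name with columns
    ``activity_rel`` / ``affinity_rel``.  A model lacking the functional
    domain gets ``NaN`` activity (affinity-only construct); the reference
    must define every observable it is asked to normalize and have nonzero
    values for them.
    """
    by_name = {m.name: m for m in models}
    if reference not in by_name:
        raise ModelError(f"reference {reference!r} not among models")
    results = {m.name: ensemble(m) for m in models}
    ref = results[reference]
    ref_model = by_name[reference]
    ref_aff = observable_affinity(ref, ref_model)
    ref_act = observable_activity(ref, ref_model)
    if ref_aff == 0.0 or ref_act == 0.0:
        raise ModelError(f"reference {reference!r} has a zero observable; cannot normalize")
    rows = {}
    for m in models:
        res = results[m.name]
        aff = observable_affinity(res, m) if m.binding_domain else math.nan
        if m.binding_domain and m.functional_domain:
            act = observable_activity(res, m)
        else:
            act = math.nan
        rows[m.name] = {"activity_rel": act / ref_act, "affinity_rel": aff / ref_aff}
    return pd.DataFrame.from_dict(rows, orient="index")
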