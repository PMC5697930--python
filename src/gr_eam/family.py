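"""The glucocorticoid-receptor isoform family as a shared-parameter model set.

The five constitutively active translational isoforms (A, B, C1, C2, C3)
share the functional domain F and the DNA-binding domain DBD and differ only
in their N-terminal regulatory segment R: A carries the full R-domain, B,
C1 and C2 progressively shorter versions (modeled as per-isoform R
stabilities), and C3 none at all.  The family therefore exposes nine free
parameters: four per-isoform R stabilities (``dG_R_A`` ... ``dG_R_C2``) and
five shared ones (``dG_F``, ``dG_D``, ``dg_RF``, ``dg_RD``, ``dg_FD``), all
in kcal/mol.

Besides building :class:`~gr_eam.ensemble_core.ProteinModel` objects, each
construct exposes a vectorized closed-form predictor of its two observables
over numpy parameter arrays.  The closed forms are plain Boltzmann sums over
the 8 (or 4) microstates and are cross-checked against the generic ensemble
machinery in the test suite; they exist so that exhaustive grid searches
stay desk-scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .ensemble_core import (
    DEFAULT_RT,
    CouplingSpec,
    DomainSpec,
    ProteinModel,
)
from .errors import ModelError

__all__ = [
    "RT_LN2",
    "ConstructSpec",
    "IsoformFamily",
    "gr_isoform_family",
    "reference_frustrated_params",
    "default_truth_params",
    "isoform_model",
    "two_domain_model",
    "linker_dbd_model",
    "r_linker_dbd_model",
]

#: One "factor of two" of stability at the default temperature, kcal/mol.
RT_LN2 = DEFAULT_RT * math.log(2.0)


def reference_frustrated_params(rt: float = DEFAULT_RT) -> dict[str, float]:
    """The reference frustrated (case-ii) parameter set.

    Every Boltzmann weight it produces is a power of two, so ensemble sums
    are exactly representable and hand-checkable: the three-domain ensemble
    has partition function 26.125, activity 3/26.125 and affinity 20/26.125.
    Signs follow the experimentally inferred topology: dg_FD > 0, dg_RD > 0,
    dg_RF < 0.
    """
    ln2 = rt * math.log(2.0)
    return {
        "dG_R": 2 * ln2,   # RT ln 4
        "dG_F": 0.0,
        "dG_D": 0.0,
        "dg_FD": ln2,      # RT ln 2
        "dg_RF": -5 * ln2,  # -RT ln 32
        "dg_RD": 2 * ln2,  # RT ln 4
    }


def default_truth_params(rt: float = DEFAULT_RT) -> dict[str, float]:
    """Default ground-truth family parameters for synthetic datasets.

    Shared parameters come from the reference frustrated set; per-isoform R
    stabilities step down by RT ln 2 with R-domain length (A most stable),
    keeping every value on the natural RT ln 2 grid.
    """
    ref = reference_frustrated_params(rt)
    ln2 = rt * math.log(2.0)
    return {
        "dG_R_A": ref["dG_R"],
        "dG_R_B": 1 * ln2,
        "dG_R_C1": 0.0,
        "dG_R_C2": -1 * ln2,
        "dG_F": ref["dG_F"],
        "dG_D": ref["dG_D"],
        "dg_RF": ref["dg_RF"],
        "dg_RD": ref["dg_RD"],
        "dg_FD": ref["dg_FD"],
    }


def isoform_model(
    name: str,
    dg_r: float,
    dg_f: float,
    dg_d: float,
    dg_rf: float,
    dg_rd: float,
    dg_fd: float,
    rt: float = DEFAULT_RT,
) -> ProteinModel:
    """Three-domain (R, F, DBD) isoform model."""
    return ProteinModel(
        name=name,
        domains=(
            DomainSpec("R", dg_r),
            DomainSpec("F", dg_f, is_functional=True),
            DomainSpec("DBD", dg_d, is_binding=True),
        ),
        couplings=(
            CouplingSpec(("R", "F"), dg_rf),
            CouplingSpec(("R", "DBD"), dg_rd),
            CouplingSpec(("F", "DBD"), dg_fd),
        ),
        thermal_energy=rt,
    )


def two_domain_model(
    name: str, dg_f: float, dg_d: float, dg_fd: float, rt: float = DEFAULT_RT
) -> ProteinModel:
    """Two-domain (F, DBD) model, e.g. the C3 isoform."""
    return ProteinModel(
        name=name,
        domains=(
            DomainSpec("F", dg_f, is_functional=True),
            DomainSpec("DBD", dg_d, is_binding=True),
        ),
        couplings=(CouplingSpec(("F", "DBD"), dg_fd),),
        thermal_energy=rt,
    )


def linker_dbd_model(dg_d: float, rt: float = DEFAULT_RT, name: str = "linker-DBD") -> ProteinModel:
    """DBD behind a flexible linker: the linker is functionally inert, so the
    construct is modeled as the DBD alone (affinity-only readout)."""
    return ProteinModel(
        name=name,
        domains=(DomainSpec("DBD", dg_d, is_binding=True),),
        thermal_energy=rt,
    )


def r_linker_dbd_model(
    dg_r: float,
    dg_d: float,
    dg_rd: float,
    rt: float = DEFAULT_RT,
    name: str = "R_A-linker-DBD",
) -> ProteinModel:
    """R-domain tethered to the DBD through an inert linker (no F-domain):
    isolates the R-DBD coupling; reports affinity only."""
    return ProteinModel(
        name=name,
        domains=(
            DomainSpec("R", dg_r),
            DomainSpec("DBD", dg_d, is_binding=True),
        ),
        couplings=(CouplingSpec(("R", "DBD"), dg_rd),),
        thermal_energy=rt,
    )


def _observables_three_domain(gr, gf, gd, grf, grd, gfd, rt):
    """Vectorized (activity, affinity) for an R/F/DBD model.

    Boltzmann factors: a = e^{dG_R/RT} etc.; every co-folded pair multiplies
    in e^{dg/RT}.  States in (R, F, D) indicator order.
    """
    a = np.exp(np.asarray(gr, dtype=float) / rt)
    b = np.exp(np.asarray(gf, dtype=float) / rt)
    d = np.exp(np.asarray(gd, dtype=float) / rt)
    u = np.exp(np.asarray(grf, dtype=float) / rt)
    v = np.exp(np.asarray(grd, dtype=float) / rt)
    w = np.exp(np.asarray(gfd, dtype=float) / rt)
    w_011 = b * d * w
    w_101 = a * d * v
    w_111 = a * b * d * u * v * w
    q = 1.0 + d + b + a + w_011 + w_101 + a * b * u + w_111
    activity = (w_011 + w_111) / q
    affinity = (d + w_011 + w_101 + w_111) / q
    return activity, affinity


def _observables_two_domain(gf, gd, gfd, rt):
    """Vectorized (activity, affinity) for an F/DBD model."""
    b = np.exp(np.asarray(gf, dtype=float) / rt)
    d = np.exp(np.asarray(gd, dtype=float) / rt)
    w = np.exp(np.asarray(gfd, dtype=float) / rt)
    w_11 = b * d * w
    q = 1.0 + b + d + w_11
    return w_11 / q, (d + w_11) / q


@dataclass(frozen=True)
class ConstructSpec:
    """One construct of a shared-parameter family.

    ``params`` names the family parameters this construct's model reads, in
    the order the builder and predictor expect them.
    """

    name: str
    params: tuple[str, ...]
    builder: Callable[..., ProteinModel]
    predictor: Callable[..., tuple[np.ndarray, np.ndarray]]

    def build(self, values: Mapping[str, float]) -> ProteinModel:
        return self.builder(*(values[p] for p in self.params))

    def predict(self, arrays: Mapping[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        return self.predictor(*(arrays[p] for p in self.params))


@dataclass(frozen=True)
class IsoformFamily:
    """A named set of constructs sharing a common parameter vector."""

    parameter_names: tuple[str, ...]
    constructs: tuple[ConstructSpec, ...]
    reference: str
    thermal_energy: float = DEFAULT_RT

    def __post_init__(self) -> None:
        names = [c.name for c in self.constructs]
        if len(set(names)) != len(names):
            raise ModelError("duplicate construct names in family")
        if self.reference not in names:
            raise ModelError(f"reference construct {self.reference!r} not in family")
        for c in self.constructs:
            for p in c.params:
                if p not in self.parameter_names:
                    raise ModelError(
                        f"construct {c.name!r} uses unknown parameter {p!r}"
                    )

    @property
    def construct_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.constructs)

    def construct(self, name: str) -> ConstructSpec:
        for c in self.constructs:
            if c.name == name:
                return c
        raise ModelError(f"no construct named {name!r} in family")

    def build_models(self, values: Mapping[str, float]) -> list[ProteinModel]:
        return [c.build(values) for c in self.constructs]

    def params_used(self, name: str) -> frozenset[str]:
        return frozenset(self.construct(name).params)


def gr_isoform_family(
    rt: float = DEFAULT_RT,
    zero_r_couplings_for: Sequence[str] = (),
    reference: str = "C3",
) -> IsoformFamily:
    """The five-isoform GR family (A, B, C1, C2 three-domain; C3 two-domain).

    ``zero_r_couplings_for`` optionally lists isoforms whose R-domain loses
    both couplings (emulating R-domains too short to contact the DBD); off by
    default.
    """
    zeroed = set(zero_r_couplings_for)

    def three(name: str, r_param: str) -> ConstructSpec:
        if name in zeroed:
            def builder(gr_, gf, gd, gfd, _n=name):
                return isoform_model(_n, gr_, gf, gd, 0.0, 0.0, gfd, rt=rt)

            def predictor(gr_, gf, gd, gfd):
                zero = np.zeros_like(np.asarray(gr_, dtype=float))
                return _observables_three_domain(gr_, gf, gd, zero, zero, gfd, rt)

            return ConstructSpec(name, (r_param, "dG_F", "dG_D", "dg_FD"), builder, predictor)

        def builder(gr_, gf, gd, grf, grd, gfd, _n=name):
            return isoform_model(_n, gr_, gf, gd, grf, grd, gfd, rt=rt)

        def predictor(gr_, gf, gd, grf, grd, gfd):
            return _observables_three_domain(gr_, gf, gd, grf, grd, gfd, rt)

        return ConstructSpec(
            name, (r_param, "dG_F", "dG_D", "dg_RF", "dg_RD", "dg_FD"), builder, predictor
        )

    def c3() -> ConstructSpec:
        def builder(gf, gd, gfd):
            return two_domain_model("C3", gf, gd, gfd, rt=rt)

        def predictor(gf, gd, gfd):
            return _observables_two_domain(gf, gd, gfd, rt)

        return ConstructSpec("C3", ("dG_F", "dG_D", "dg_FD"), builder, predictor)

    return IsoformFamily(
        parameter_names=(
            "dG_R_A", "dG_R_B", "dG_R_C1", "dG_R_C2",
            "dG_F", "dG_D", "dg_RF", "dg_RD", "dg_FD",
        ),
        constructs=(
            three("A", "dG_R_A"),
            three("B", "dG_R_B"),
            three("C1", "dG_R_C1"),
            three("C2", "dG_R_C2"),
            c3(),
        ),
        reference=reference,
        thermal_energy=rt,
    )
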