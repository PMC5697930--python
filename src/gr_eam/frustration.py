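"""Classification of coupling-sign topologies in a three-domain network.

With three pairwise couplings (F-D, R-F, R-D) there are 2^3 = 8 sign
configurations.  A configuration is *energetically frustrated* when the
direct F-D coupling disagrees in sign with the indirect coupling mediated
through R (the product sign(R-F) * sign(R-D)): the two routes then pull the
functional domain in opposite directions and no single microstate can
dominate.  Equivalently, a configuration is frustrated iff the product of
the three signs is -1, i.e. it has an odd number of negative (an even
number of positive) couplings.  Exactly 4 of the 8 configurations are
frustrated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .ensemble_core import ProteinModel, ensemble, observable_activity, observable_affinity
from .errors import DegenerateConfigurationError, ModelError

#: Canonical pair order used throughout: direct pair first, then the
#: R-mediated legs.
PAIRS = ("F-D", "R-F", "R-D")

#: Roman-numeral case labels for the 8 configurations (presentation metadata
#: only; the lexicographic enumeration order below is the load-bearing one).
CASE_LABELS = ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii")


class Frustration(str, Enum):
    FRUSTRATED = "frustrated"
    UNFRUSTRATED = "unfrustrated"


@dataclass(frozen=True)
class CouplingConfiguration:
    """Signs of the three couplings of an R/F/DBD-type network."""

    signs: Mapping[str, int]
    label: str | None = None

    def __post_init__(self) -> None:
        signs = dict(self.signs)
        if set(signs) != set(PAIRS):
            raise DegenerateConfigurationError(
                f"configuration must assign signs to exactly {PAIRS}, got {sorted(signs)}"
            )
        for pair, s in signs.items():
            if s not in (+1, -1):
                raise DegenerateConfigurationError(
                    f"coupling {pair} has sign {s!r}; signs must be +1 or -1 "
                    "(zero couplings have no sign)"
                )
        object.__setattr__(self, "signs", signs)

    def sign(self, pair: str) -> int:
        return self.signs[pair]


def sign_of(delta_g: float) -> int:
    """Strict sign of a coupling free energy; zero is degenerate."""
    if delta_g > 0:
        return +1
    if delta_g < 0:
        return -1
    raise DegenerateConfigurationError("zero coupling has no sign; classification undefined")


def classify(config: CouplingConfiguration) -> Frustration:
    """Frustrated iff the product of the three coupling signs is -1."""
    product = config.sign("F-D") * config.sign("R-F") * config.sign("R-D")
    return Frustration.FRUSTRATED if product == -1 else Frustration.UNFRUSTRATED


def net_indirect_sign(config: CouplingConfiguration) -> int:
    """Sign of the R-mediated route from the DBD to the F-domain.

    A positive R-D coupling combined with a negative R-F coupling (or vice
    versa) makes the indirect route repressive: stabilizing the DBD then
    destabilizes F through R.  Frustration is exactly a mismatch between
    this indirect sign and the direct F-D sign.
    """
    return config.sign("R-D") * config.sign("R-F")


def enumerate_configurations() -> list[tuple[CouplingConfiguration, Frustration]]:
    """All 8 sign configurations with their classification.

    Deterministic lexicographic order over (F-D, R-F, R-D) with + before -.
    """
    out = []
    for k, combo in enumerate(itertools.product((+1, -1), repeat=3)):
        config = CouplingConfiguration(
            signs=dict(zip(PAIRS, combo)), label=CASE_LABELS[k]
        )
        out.append((config, classify(config)))
    return out


def configuration_of(model: ProteinModel, pair_map: Mapping[str, tuple[str, str]] | None = None,
                     ) -> CouplingConfiguration:
    """Read a model's sign configuration off its three couplings.

    ``pair_map`` maps the canonical pair names to the model's domain-name
    pairs; defaults to R/F/DBD naming.
    """
    if pair_map is None:
        pair_map = {"F-D": ("F", "DBD"), "R-F": ("R", "F"), "R-D": ("R", "DBD")}
    signs = {}
    for canonical, pair in pair_map.items():
        c = model.coupling_for(pair)
        if c is None:
            raise ModelError(f"model {model.name!r} has no coupling for {pair!r}")
        signs[canonical] = sign_of(c.delta_g)
    return CouplingConfiguration(signs=signs)


def frustration_scan(
    model_template: ProteinModel,
    pair: tuple[str, str],
    grid: Iterable[float],
) -> pd.DataFrame:
    """Sweep one coupling free energy over a grid, recording both observables.

    Returns a DataFrame with columns ``delta_g``, ``activity``, ``affinity``,
    one row per grid point, in grid order.
    """
    grid = list(grid)
    if not grid:
        raise ModelError("frustration_scan: empty grid")
    rows = []
    for value in grid:
        m = model_template.with_coupling(pair, value)
        res = ensemble(m)
        rows.append(
            {
                "delta_g": value,
                "activity": observable_activity(res, m),
                "affinity": observable_affinity(res, m),
            }
        )
    return pd.DataFrame(rows)
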