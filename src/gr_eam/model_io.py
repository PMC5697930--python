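"""Reading and writing protein models as YAML configuration files.

Dialect (one model per file)::

    name: A
    thermal_energy: 0.593
    domains:
    - name: R
      stability: 0.8219...
    - name: F
      stability: 0.0
      is_functional: true
    - name: DBD
      stability: 0.0
      is_binding: true
    couplings:
    - pair: [R, F]
      delta_g: -2.05...

``stability`` and ``delta_g`` are kcal/mol; ``is_functional`` / ``is_binding``
default to false.  Parsing is strict by default: unknown keys are an error
(pass ``strict=False`` to ignore them).  Writing uses a canonical key order
and repr-exact floats, so write -> read -> write is byte-stable.
"""

from __future__ import annotations

from typing import Any, Mapping

import yaml

from .ensemble_core import DEFAULT_RT, CouplingSpec, DomainSpec, ProteinModel
from .errors import ModelError, ModelParseError

__all__ = ["read_model", "write_model", "model_to_dict", "model_from_dict"]

_MODEL_KEYS = {"name", "thermal_energy", "domains", "couplings"}
_DOMAIN_KEYS = {"name", "stability", "is_functional", "is_binding"}
_COUPLING_KEYS = {"pair", "delta_g"}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], where: str, strict: bool) -> None:
    unknown = set(mapping) - allowed
    if unknown and strict:
        raise ModelParseError(f"{where}: unknown keys {sorted(unknown)}")


def model_from_dict(raw: Mapping[str, Any], strict: bool = True) -> ProteinModel:
    if not isinstance(raw, Mapping):
        raise ModelParseError("model file must contain a mapping at top level")
    _check_keys(raw, _MODEL_KEYS, "model", strict)
    for key in ("name", "domains"):
        if key not in raw:
            raise ModelParseError(f"model: missing required key {key!r}")
    domains = []
    for i, d in enumerate(raw["domains"]):
        where = f"domains[{i}]"
        if not isinstance(d, Mapping):
            raise ModelParseError(f"{where}: expected a mapping")
        _check_keys(d, _DOMAIN_KEYS, where, strict)
        try:
            domains.append(
                DomainSpec(
                    name=str(d["name"]),
                    stability=float(d["stability"]),
                    is_functional=bool(d.get("is_functional", False)),
                    is_binding=bool(d.get("is_binding", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelParseError(f"{where}: {exc}") from exc
    couplings = []
    for i, c in enumerate(raw.get("couplings") or []):
        where = f"couplings[{i}]"
        if not isinstance(c, Mapping):
            raise ModelParseError(f"{where}: expected a mapping")
        _check_keys(c, _COUPLING_KEYS, where, strict)
        try:
            pair = tuple(str(p) for p in c["pair"])
            couplings.append(CouplingSpec(pair=pair, delta_g=float(c["delta_g"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelParseError(f"{where}: {exc}") from exc
    try:
        return ProteinModel(
            name=str(raw["name"]),
            domains=tuple(domains),
            couplings=tuple(couplings),
            thermal_energy=float(raw.get("thermal_energy", DEFAULT_RT)),
        )
    except ModelError as exc:
        raise ModelParseError(str(exc)) from exc


def read_model(path, strict: bool = True) -> ProteinModel:
    """Read one model from a YAML file; strict mode rejects unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ModelParseError(f"{path}: invalid YAML: {exc}") from exc
    return model_from_dict(raw, strict=strict)


def model_to_dict(model: ProteinModel) -> dict[str, Any]:
    out: dict[str, Any] = {
        "name": model.name,
        "thermal_energy": float(model.thermal_energy),
        "domains": [],
    }
    for d in model.domains:
        entry: dict[str, Any] = {"name": d.name, "stability": float(d.stability)}
        if d.is_functional:
            entry["is_functional"] = True
        if d.is_binding:
            entry["is_binding"] = True
        out["domains"].append(entry)
    if model.couplings:
        out["couplings"] = [
            {"pair": list(c.pair), "delta_g": float(c.delta_g)} for c in model.couplings
        ]
    return out


def write_model(model: ProteinModel, path) -> None:
    """Write a model in canonical key order with repr-exact floats."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(
            model_to_dict(model), fh, sort_keys=False, default_flow_style=None
        )
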