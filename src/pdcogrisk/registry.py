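"""Machine-readable risk-factor registries.

A registry declares, per scale, the ordered list of risk factors with their
input fields, comparison operators, cutoffs and point weights, plus the
scale's high-risk cutoff. The packaged default reproduces the published
threshold table for LIBRA (9 factors as used with PPMI data), MoPaRDS
(8 one-point factors) and pPREDICT (14 one-point factors); users may load a
modified registry for other cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Optional

import yaml

SCALES = ("libra", "mopards", "ppredict")

_SIMPLE_OPS = ("ge", "gt", "le", "lt", "eq", "flag")
_OPS = _SIMPLE_OPS + ("any_of", "count_ge", "age_sex_band", "band")


class RegistryError(ValueError):
    """Malformed registry configuration."""


@dataclass(frozen=True)
class FactorDef:
    """One risk-factor definition: which inputs it reads and how it scores."""

    name: str
    op: str
    points: float
    field: Optional[str] = None
    cutoff: Any = None
    sex_field: Optional[str] = None
    bands: tuple = ()
    terms: tuple = ()
    fields: tuple = ()

    def input_fields(self) -> tuple[str, ...]:
        """Names of every ParticipantRecord field this factor reads."""
        if self.op == "age_sex_band":
            return (self.field, self.sex_field)
        if self.op == "any_of":
            return tuple(t["field"] for t in self.terms)
        if self.op == "count_ge":
            return self.fields
        return (self.field,)

    def max_points(self) -> float:
        if self.op in ("age_sex_band",):
            return max(max(b["male"], b["female"]) for b in self.bands)
        if self.op == "band":
            return max(b["points"] for b in self.bands)
        return self.points


@dataclass(frozen=True)
class ScaleRegistry:
    """Ordered factor registry plus the high-risk cutoff for one scale."""

    scale: str
    high_risk_cutoff: float
    factors: tuple[FactorDef, ...] = ()

    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def __getitem__(self, name: str) -> FactorDef:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def max_total(self) -> float:
        return sum(f.max_points() for f in self.factors)


def _parse_factor(raw: dict, scale: str) -> FactorDef:
    op = raw.get("op")
    if op not in _OPS:
        raise RegistryError(f"{scale}: unknown operator {op!r} in factor {raw.get('name')!r}")
    name = raw.get("name")
    if not name:
        raise RegistryError(f"{scale}: factor without a name")
    points = float(raw.get("points", 0.0)) if op not in ("age_sex_band", "band") else 0.0
    kwargs: dict[str, Any] = dict(name=name, op=op, points=points)
    if op in _SIMPLE_OPS:
        if "field" not in raw:
            raise RegistryError(f"{scale}:{name}: operator {op} needs a field")
        kwargs["field"] = raw["field"]
        if op != "flag":
            kwargs["cutoff"] = raw.get("cutoff")
    elif op == "any_of":
        terms = tuple(dict(t) for t in raw.get("terms", ()))
        if not terms:
            raise RegistryError(f"{scale}:{name}: any_of needs terms")
        for t in terms:
            if t.get("op") not in ("ge", "gt", "le", "lt", "eq", "flag"):
                raise RegistryError(f"{scale}:{name}: bad term operator {t.get('op')!r}")
        kwargs["terms"] = terms
    elif op == "count_ge":
        flds = tuple(raw.get("fields", ()))
        if not flds:
            raise RegistryError(f"{scale}:{name}: count_ge needs fields")
        kwargs["fields"] = flds
        kwargs["cutoff"] = int(raw["cutoff"])
    elif op in ("age_sex_band", "band"):
        bands = tuple(dict(b) for b in raw.get("bands", ()))
        if not bands:
            raise RegistryError(f"{scale}:{name}: banded factor needs bands")
        _check_bands(bands, scale, name, sexed=(op == "age_sex_band"))
        kwargs["bands"] = bands
        kwargs["field"] = raw["field"]
        if op == "age_sex_band":
            kwargs["sex_field"] = raw.get("sex_field", "sex")
    return FactorDef(**kwargs)


def _check_bands(bands, scale: str, name: str, sexed: bool) -> None:
    keys = ("male", "female") if sexed else ("points",)
    for b in bands:
        if b["min"] >= b["max"]:
            raise RegistryError(f"{scale}:{name}: empty band {b}")
        for k in keys:
            if k not in b:
                raise RegistryError(f"{scale}:{name}: band missing {k!r}")
    # bands must tile their range without overlap
    ordered = sorted(bands, key=lambda b: b["min"])
    for lo, hi in zip(ordered, ordered[1:]):
        if not math.isclose(lo["max"], hi["min"]):
            raise RegistryError(f"{scale}:{name}: bands must be contiguous, gap at {lo['max']}")


def parse_registry(config: dict) -> dict[str, ScaleRegistry]:
    """Parse a registry mapping ``{scale: {high_risk_cutoff, factors}}``."""
    registries = {}
    for scale, raw in config.items():
        if scale not in SCALES:
            raise RegistryError(f"unknown scale {scale!r}; expected one of {SCALES}")
        factors = tuple(_parse_factor(f, scale) for f in raw.get("factors", ()))
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise RegistryError(f"{scale}: duplicate factor names")
        registries[scale] = ScaleRegistry(
            scale=scale,
            high_risk_cutoff=float(raw["high_risk_cutoff"]),
            factors=factors,
        )
    return registries


def load_registry(path: Optional[str] = None) -> dict[str, ScaleRegistry]:
    """Load a registry YAML; with no path, load the packaged default."""
    if path is None:
        text = resources.files("pdcogrisk.data").joinpath("registry.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return parse_registry(yaml.safe_load(text))


_default_cache: Optional[dict[str, ScaleRegistry]] = None


def default_registry() -> dict[str, ScaleRegistry]:
    """The packaged default registries (cached)."""
    global _default_cache
    if _default_cache is None:
        _default_cache = load_registry(None)
    return _default_cache
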