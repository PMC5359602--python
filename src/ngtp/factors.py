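"""Parameter tables of the accounting model.

Two parameter sets drive the pipeline:

* :class:`FactorSet` — Tier-1 style emission/uptake factors converting
  applied nitrogen into gas fluxes (kg gas-element per kg N applied).
* :class:`GTPCoefficientSet` — Global Temperature change Potential
  coefficients (kg CO2e per kg of each pathway's mass basis) given as
  literature low/high intervals for 20- and 100-year horizons.

Published GTP coefficients are intervals, so every downstream
computation takes a :class:`RangePolicy` deciding how to collapse an
interval to a scalar; the default (``mid``) uses the interval midpoint.

Mass bases are mixed by pathway: N2O, NH3, CH4 and CO2 coefficients act
on the molecular gas mass while both NOx pathways act on NOx-N (element
nitrogen) mass. This is the only convention under which the factor
table and coefficient table jointly reproduce the benchmark 1961/2010
results, and it is asserted throughout the test suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Union

import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "FactorSet",
    "GTPCoefficientSet",
    "RangePolicy",
    "PATHWAYS",
    "WARMING_PATHWAYS",
    "COOLING_PATHWAYS",
    "MASS_BASIS",
    "HORIZONS",
    "load_factor_config",
    "read_factor_config",
    "resolve_coefficient",
    "to_config",
    "write_factor_config",
]

#: GTP pathway identifiers, in reporting order.
PATHWAYS = (
    "n2o",
    "nox_o3_ch4",
    "nox_aerosol",
    "nh3_aerosol",
    "ch4_flux",
    "co2_flux",
)

#: Pathways whose coefficient is positive (warming direction).
WARMING_PATHWAYS = frozenset({"n2o", "ch4_flux", "co2_flux"})

#: Pathways whose coefficient is negative or zero (cooling direction).
COOLING_PATHWAYS = frozenset({"nox_o3_ch4", "nox_aerosol", "nh3_aerosol"})

#: Mass basis each pathway's coefficient multiplies (documentation aid).
MASS_BASIS = {
    "n2o": "Tg N2O (molecular)",
    "nox_o3_ch4": "Tg NOx-N (element)",
    "nox_aerosol": "Tg NOx-N (element)",
    "nh3_aerosol": "Tg NH3 (molecular)",
    "ch4_flux": "Tg CH4 (molecular)",
    "co2_flux": "Tg CO2 (molecular)",
}

#: Supported time horizons (years).
HORIZONS = (20, 100)

#: Default low/high coefficient intervals, kg CO2e per kg of mass basis.
_DEFAULT_INTERVALS: dict[tuple[str, int], tuple[float, float]] = {
    ("n2o", 20): (260.0, 290.0),
    ("n2o", 100): (290.0, 320.0),
    ("nox_o3_ch4", 20): (-55.0, -37.0),
    ("nox_o3_ch4", 100): (-2.9, -0.024),
    ("nox_aerosol", 20): (-31.0, -7.0),
    ("nox_aerosol", 100): (-0.0024, 0.0),
    ("nh3_aerosol", 20): (-9.5, -2.2),
    ("nh3_aerosol", 100): (-0.022, 0.0),
    ("ch4_flux", 20): (37.0, 77.0),
    ("ch4_flux", 100): (2.9, 4.9),
    ("co2_flux", 20): (1.0, 1.0),
    ("co2_flux", 100): (1.0, 1.0),
}


class RangePolicy(str, enum.Enum):
    """How to collapse a (low, high) coefficient interval to a scalar."""

    LOW = "low"
    MID = "mid"
    HIGH = "high"

    @classmethod
    def coerce(cls, value: Union["RangePolicy", str]) -> "RangePolicy":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValidationError(
                f"unknown range policy {value!r}; expected one of "
                f"{[p.value for p in cls]}"
            ) from None

    def resolve(self, interval: tuple[float, float]) -> float:
        low, high = interval
        if self is RangePolicy.LOW:
            return low
        if self is RangePolicy.HIGH:
            return high
        return (low + high) / 2.0


@dataclass(frozen=True)
class FactorSet:
    """Emission/uptake factors, stored as non-negative magnitudes.

    Signs (emission vs uptake) are applied by the flux engine, so the
    upland CH4 and CO2 sequestration factors are stored positive even
    though they describe uptake.

    Units: all per kg N applied — kg N2O-N, kg NO3-N, kg NH3-N,
    kg NOx-N, kg CH4-C, kg CO2-C respectively; ``frac_leach`` and
    ``f_lowland`` are dimensionless fractions.
    """

    ef_n2o_direct: float = 0.01
    ef_n2o_leach: float = 0.0075
    frac_leach: float = 0.3
    ef_nh3: float = 0.1
    ef_nox: float = 0.005
    ef_ch4_lowland: float = 0.008
    ef_ch4_upland: float = 0.012
    ef_co2_seq: float = 0.053
    f_lowland: float = 0.15

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ConfigurationError(f"factor {f.name} must be numeric, got {v!r}")
            if v < 0:
                raise ValidationError(f"factor {f.name} must be >= 0, got {v}")
        for name in ("frac_leach", "f_lowland"):
            v = getattr(self, name)
            if v > 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class GTPCoefficientSet:
    """GTP coefficient intervals per (pathway, horizon)."""

    intervals: Mapping[tuple[str, int], tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_INTERVALS)
    )

    def __post_init__(self) -> None:
        for key in _DEFAULT_INTERVALS:
            if key not in self.intervals:
                raise ValidationError(f"missing GTP interval for {key}")
        for (pathway, horizon), (low, high) in self.intervals.items():
            if pathway not in PATHWAYS or horizon not in HORIZONS:
                raise ValidationError(f"unknown pathway/horizon {(pathway, horizon)}")
            if low > high:
                raise ValidationError(
                    f"interval for {pathway}@{horizon} has low {low} > high {high}"
                )
            if pathway in WARMING_PATHWAYS and low <= 0:
                raise ValidationError(
                    f"warming pathway {pathway}@{horizon} requires low > 0, got {low}"
                )
            if pathway in COOLING_PATHWAYS and high > 0:
                raise ValidationError(
                    f"cooling pathway {pathway}@{horizon} requires high <= 0, got {high}"
                )

    def interval(self, pathway: str, horizon: int) -> tuple[float, float]:
        try:
            return self.intervals[(pathway, int(horizon))]
        except KeyError:
            raise LookupError(
                f"no GTP coefficient for pathway {pathway!r} at horizon {horizon}"
            ) from None


def resolve_coefficient(
    coeffs: GTPCoefficientSet,
    pathway: str,
    horizon: int,
    policy: Union[RangePolicy, str] = RangePolicy.MID,
) -> float:
    """Collapse the (pathway, horizon) interval to a signed scalar.

    Returns kg CO2e per kg of the pathway's mass basis; negative for
    cooling pathways.
    """
    return RangePolicy.coerce(policy).resolve(coeffs.interval(pathway, horizon))


_FACTOR_KEYS = tuple(f.name for f in fields(FactorSet))
_INTERVAL_KEYS = {
    f"{pathway}_gtp{horizon}": (pathway, horizon)
    for pathway in PATHWAYS
    for horizon in HORIZONS
}


def load_factor_config(
    doc: Mapping[str, object] | None,
) -> tuple[FactorSet, GTPCoefficientSet]:
    """Build parameter sets from a flat config mapping.

    Missing keys take the package defaults. Factor keys are the
    :class:`FactorSet` field names; interval keys are
    ``<pathway>_gtp20`` / ``<pathway>_gtp100`` with two-element
    ``[low, high]`` values.
    """
    doc = dict(doc or {})
    factor_overrides: dict[str, float] = {}
    intervals = dict(_DEFAULT_INTERVALS)
    for key, value in doc.items():
        if key in _FACTOR_KEYS:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigurationError(f"config key {key!r} must be numeric, got {value!r}")
            factor_overrides[key] = float(value)
        elif key in _INTERVAL_KEYS:
            try:
                low, high = (float(v) for v in value)  # type: ignore[union-attr]
            except (TypeError, ValueError):
                raise ConfigurationError(
                    f"config key {key!r} must be a two-element [low, high] array, got {value!r}"
                ) from None
            intervals[_INTERVAL_KEYS[key]] = (low, high)
        else:
            raise ConfigurationError(f"unknown config key {key!r}")
    return FactorSet(**factor_overrides), GTPCoefficientSet(intervals=intervals)


def to_config(factors: FactorSet, coeffs: GTPCoefficientSet) -> dict[str, object]:
    """Serialize both parameter sets to the flat config mapping."""
    doc: dict[str, object] = {name: getattr(factors, name) for name in _FACTOR_KEYS}
    for key, pair in _INTERVAL_KEYS.items():
        doc[key] = list(coeffs.intervals[pair])
    return doc


def read_factor_config(path: Union[str, Path]) -> tuple[FactorSet, GTPCoefficientSet]:
    """Load a YAML config file (flat key: value document)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"config file {path} is not a flat mapping")
    return load_factor_config(doc)


def write_factor_config(
    factors: FactorSet, coeffs: GTPCoefficientSet, path: Union[str, Path]
) -> None:
    """Write the parameter sets as YAML; reloading reproduces them exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_config(factors, coeffs), fh, sort_keys=True)


def with_overrides(factors: FactorSet, **overrides: float) -> FactorSet:
    """Return a copy of ``factors`` with the given fields replaced."""
    return replace(factors, **overrides)
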