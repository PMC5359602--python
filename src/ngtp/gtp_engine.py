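"""CO2-equivalent warming/cooling decomposition of gas fluxes.

Each flux is mapped to Tg CO2e at a 20- or 100-year horizon by the
Global Temperature change Potential (GTP) coefficient of its pathway.
Six pathways are tracked:

warming — N2O emission; net CH4 increase (lowland emission plus upland
sink suppression);

cooling — NH3-driven aerosol formation; NOx-driven ozone/CH4
perturbation; NOx-driven aerosol formation; CO2 sequestered by
N-stimulated productivity (the coefficient is +1 per kg CO2 but the
flux direction is uptake, so it cools).

All warming and cooling components are stored as positive magnitudes;
signs enter only in ``net = warming_total - cooling_total``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence, Union

import pandas as pd

from .errors import UndefinedSharesError, ValidationError
from .factors import (
    HORIZONS,
    GTPCoefficientSet,
    RangePolicy,
    resolve_coefficient,
)
from .flux_engine import FluxRecord

__all__ = [
    "GTPRecord",
    "PeriodSummary",
    "SpeciesGTP",
    "GTP_COMPONENT_FIELDS",
    "species_gtp",
    "annual_gtp",
    "cooling_shares",
    "warming_shares",
    "period_summary",
    "range_envelope",
    "gtp_frame",
    "write_gtp_csv",
]

#: GTPRecord component fields in canonical column order.
GTP_COMPONENT_FIELDS = (
    "warming_n2o",
    "warming_ch4",
    "cooling_nh3_aerosol",
    "cooling_nox_o3_ch4",
    "cooling_nox_aerosol",
    "cooling_co2_seq",
)

_WARMING_FIELDS = ("warming_n2o", "warming_ch4")
_COOLING_FIELDS = (
    "cooling_nh3_aerosol",
    "cooling_nox_o3_ch4",
    "cooling_nox_aerosol",
    "cooling_co2_seq",
)

#: Which flux field feeds each pathway, and the GTPRecord field it lands in.
_PATHWAY_WIRING = (
    # (pathway, flux field, record field)
    ("n2o", "n2o_total", "warming_n2o"),
    ("ch4_flux", "ch4", "warming_ch4"),
    ("nh3_aerosol", "nh3", "cooling_nh3_aerosol"),
    ("nox_o3_ch4", "nox_n", "cooling_nox_o3_ch4"),
    ("nox_aerosol", "nox_n", "cooling_nox_aerosol"),
    ("co2_flux", "co2_uptake", "cooling_co2_seq"),
)


@dataclass(frozen=True)
class GTPRecord:
    """One year × horizon decomposition into CO2e contributions (Tg CO2e)."""

    year: int
    horizon: int
    warming_n2o: float
    warming_ch4: float
    cooling_nh3_aerosol: float
    cooling_nox_o3_ch4: float
    cooling_nox_aerosol: float
    cooling_co2_seq: float
    warming_total: float
    cooling_total: float
    net: float

    def __post_init__(self) -> None:
        if self.horizon not in HORIZONS:
            raise ValidationError(f"horizon must be one of {HORIZONS}, got {self.horizon}")
        for name in GTP_COMPONENT_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{name} must be a non-negative magnitude, got {getattr(self, name)}"
                )
        if self.warming_total != self.warming_n2o + self.warming_ch4:
            raise ValidationError("warming_total must equal the sum of warming components")
        if self.cooling_total != sum(getattr(self, n) for n in _COOLING_FIELDS):
            raise ValidationError("cooling_total must equal the sum of cooling components")
        if self.net != self.warming_total - self.cooling_total:
            raise ValidationError("net must equal warming_total - cooling_total")


@dataclass(frozen=True)
class PeriodSummary:
    """Cumulative CO2e totals over a multi-year series at one horizon."""

    horizon: int
    n_years: int
    warming_total: float
    cooling_total: float
    net: float
    warming_shares: dict[str, float]
    cooling_shares: dict[str, float]


class SpeciesGTP(NamedTuple):
    """Magnitude of one pathway's CO2e contribution and its direction."""

    value: float
    direction: str  # "warming" or "cooling"


def species_gtp(
    flux: float,
    pathway: str,
    horizon: int,
    coeffs: GTPCoefficientSet,
    policy: Union[RangePolicy, str] = RangePolicy.MID,
) -> SpeciesGTP:
    """CO2e contribution of one flux (Tg of the pathway's mass basis).

    Returns the magnitude ``flux × |coefficient|`` tagged warming or
    cooling by the coefficient's sign (zero coefficients count as
    cooling-direction, which only arises at the null end of cooling
    intervals).
    """
    if flux < 0:
        raise ValidationError(f"flux must be >= 0, got {flux}")
    coef = resolve_coefficient(coeffs, pathway, horizon, policy)
    direction = "warming" if coef > 0 else "cooling"
    return SpeciesGTP(flux * abs(coef), direction)


def annual_gtp(
    flux: FluxRecord,
    horizon: int,
    coeffs: GTPCoefficientSet,
    policy: Union[RangePolicy, str] = RangePolicy.MID,
) -> GTPRecord:
    """Full warming/cooling decomposition of one year's fluxes."""
    components: dict[str, float] = {}
    for pathway, flux_field, record_field in _PATHWAY_WIRING:
        components[record_field] = species_gtp(
            getattr(flux, flux_field), pathway, horizon, coeffs, policy
        ).value
    warming_total = sum(components[n] for n in _WARMING_FIELDS)
    cooling_total = sum(components[n] for n in _COOLING_FIELDS)
    return GTPRecord(
        year=flux.year,
        horizon=horizon,
        warming_total=warming_total,
        cooling_total=cooling_total,
        net=warming_total - cooling_total,
        **components,
    )


def cooling_shares(record: GTPRecord, include_co2_seq: bool = True) -> dict[str, float]:
    """Each cooling pathway's fraction of total cooling.

    With ``include_co2_seq=False`` the shares are over the short-lived
    NH3/NOx pathways only (the aerosol and ozone/CH4 terms), the subset
    conventionally reported for reactive-N cooling.
    """
    names = _COOLING_FIELDS if include_co2_seq else _COOLING_FIELDS[:3]
    denom = sum(getattr(record, n) for n in names)
    if denom <= 0:
        raise UndefinedSharesError(
            f"cooling shares undefined: zero cooling in year {record.year}"
        )
    return {n: getattr(record, n) / denom for n in names}


def warming_shares(record: GTPRecord) -> dict[str, float]:
    """Each warming pathway's fraction of total warming."""
    if record.warming_total <= 0:
        raise UndefinedSharesError(
            f"warming shares undefined: zero warming in year {record.year}"
        )
    return {n: getattr(record, n) / record.warming_total for n in _WARMING_FIELDS}


def period_summary(records: Sequence[GTPRecord]) -> PeriodSummary:
    """Cumulative totals and pathway shares over a series of years.

    All records must share one horizon and have distinct years. Because
    every stage is linear in N input, the sum of per-year nets equals
    the net of the summed components exactly.
    """
    records = list(records)
    if not records:
        raise ValidationError("period_summary requires at least one record")
    horizons = {r.horizon for r in records}
    if len(horizons) != 1:
        raise ValidationError(f"mixed horizons in period_summary: {sorted(horizons)}")
    years = [r.year for r in records]
    if len(set(years)) != len(years):
        raise ValidationError("duplicate years in period_summary")
    sums = {
        name: sum(getattr(r, name) for r in records) for name in GTP_COMPONENT_FIELDS
    }
    warming_total = sum(sums[n] for n in _WARMING_FIELDS)
    cooling_total = sum(sums[n] for n in _COOLING_FIELDS)
    return PeriodSummary(
        horizon=horizons.pop(),
        n_years=len(records),
        warming_total=warming_total,
        cooling_total=cooling_total,
        net=warming_total - cooling_total,
        warming_shares={n: sums[n] / warming_total for n in _WARMING_FIELDS}
        if warming_total > 0
        else {n: 0.0 for n in _WARMING_FIELDS},
        cooling_shares={n: sums[n] / cooling_total for n in _COOLING_FIELDS}
        if cooling_total > 0
        else {n: 0.0 for n in _COOLING_FIELDS},
    )


def range_envelope(
    flux: FluxRecord, horizon: int, coeffs: GTPCoefficientSet
) -> tuple[GTPRecord, GTPRecord, GTPRecord]:
    """(low, mid, high) GTP records under the three range policies.

    Warming components are ordered low ≤ mid ≤ high. Cooling components
    follow the signed interval the same way, so their magnitudes are
    ordered the other way round: the ``low`` policy picks the most
    negative coefficient, i.e. the strongest cooling.
    """
    return tuple(
        annual_gtp(flux, horizon, coeffs, policy)
        for policy in (RangePolicy.LOW, RangePolicy.MID, RangePolicy.HIGH)
    )


def gtp_frame(records: Iterable[GTPRecord]) -> pd.DataFrame:
    columns = [
        "year",
        "horizon",
        *GTP_COMPONENT_FIELDS,
        "warming_total",
        "cooling_total",
        "net",
    ]
    rows = [{c: getattr(r, c) for c in columns} for r in records]
    return pd.DataFrame(rows, columns=columns)


def write_gtp_csv(records: Sequence[GTPRecord], path: Union[str, Path]) -> None:
    """Write GTP records as CSV (all values Tg CO2e, unrounded)."""
    gtp_frame(records).to_csv(path, index=False, float_format="%.17g")
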