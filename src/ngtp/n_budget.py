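"""Annual nitrogen budgets for global agriculture.

The total N input in a year, N_T (Tg N yr^-1), is the sum of five
sources: synthetic fertilizer, animal manure, crop residue return,
atmospheric deposition and biological N fixation (BNF). Deposition and
BNF can alternatively be estimated from agricultural/pulse-crop areas
and per-area rates; the direct Tg values are the primary entry path.

No rounding happens anywhere in this module — report rendering rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .errors import UndefinedSharesError, ValidationError
from .units import TG_PER_MHA_KG_HA

__all__ = [
    "NSourceRecord",
    "BudgetRates",
    "N_SOURCE_FIELDS",
    "total_n_input",
    "deposition_n",
    "bnf_n",
    "source_shares",
    "read_budget_csv",
    "write_budget_csv",
    "budget_frame",
]

#: The five N-source fields, in canonical column order.
N_SOURCE_FIELDS = (
    "fertilizer_n",
    "manure_n",
    "crop_residue_n",
    "deposition_n",
    "bnf_n",
)


@dataclass(frozen=True)
class NSourceRecord:
    """One year's N inputs by source (Tg N yr^-1), with optional areas (Mha)."""

    year: int
    fertilizer_n: float
    manure_n: float
    crop_residue_n: float
    deposition_n: float
    bnf_n: float
    area_agri: float | None = None
    area_pulse: float | None = None

    def __post_init__(self) -> None:
        for name in N_SOURCE_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0 in year {self.year}, got {v}")
        for name in ("area_agri", "area_pulse"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0 in year {self.year}, got {v}")
        if (
            self.area_agri is not None
            and self.area_pulse is not None
            and self.area_pulse > self.area_agri
        ):
            raise ValidationError(
                f"area_pulse ({self.area_pulse}) exceeds area_agri "
                f"({self.area_agri}) in year {self.year}"
            )

    def sources(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in N_SOURCE_FIELDS}


@dataclass(frozen=True)
class BudgetRates:
    """Per-area rates (kg N ha^-1 yr^-1) for the deposition and BNF estimators."""

    deposition_rate: float
    bnf_rate_pulse: float
    bnf_rate_nonpulse: float

    def __post_init__(self) -> None:
        for name in ("deposition_rate", "bnf_rate_pulse", "bnf_rate_nonpulse"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")


def total_n_input(record: NSourceRecord) -> float:
    """Total N input N_T (Tg N yr^-1): exact sum of the five sources."""
    return (
        record.fertilizer_n
        + record.manure_n
        + record.crop_residue_n
        + record.deposition_n
        + record.bnf_n
    )


def deposition_n(area_agri: float, rates: BudgetRates) -> float:
    """Atmospheric deposition onto agricultural land, Tg N yr^-1.

    ``area_agri`` in Mha times the deposition rate in kg N ha^-1 yr^-1;
    Mha × kg ha^-1 = 1e6 kg, i.e. ×1e-3 Tg.
    """
    if area_agri < 0:
        raise ValidationError(f"area_agri must be >= 0, got {area_agri}")
    return area_agri * rates.deposition_rate * TG_PER_MHA_KG_HA


def bnf_n(area_agri: float, area_pulse: float, rates: BudgetRates) -> float:
    """Biological N fixation, Tg N yr^-1.

    Pulse-crop area fixes at ``bnf_rate_pulse``; the remaining
    agricultural area at ``bnf_rate_nonpulse``.
    """
    if area_agri < 0 or area_pulse < 0:
        raise ValidationError("areas must be >= 0")
    if area_pulse > area_agri:
        raise ValidationError(
            f"area_pulse ({area_pulse}) exceeds area_agri ({area_agri})"
        )
    kg_per_ha_terms = (
        area_pulse * rates.bnf_rate_pulse
        + (area_agri - area_pulse) * rates.bnf_rate_nonpulse
    )
    return kg_per_ha_terms * TG_PER_MHA_KG_HA


def source_shares(record: NSourceRecord) -> dict[str, float]:
    """Fraction of total N contributed by each source; sums to 1."""
    total = total_n_input(record)
    if total <= 0:
        raise UndefinedSharesError(
            f"source shares undefined for zero total N in year {record.year}"
        )
    return {name: value / total for name, value in record.sources().items()}


_CSV_COLUMNS = ("year", *N_SOURCE_FIELDS, "area_agri", "area_pulse")


def read_budget_csv(path: Union[str, Path]) -> list[NSourceRecord]:
    """Read annual N-source records from CSV.

    Expected header: ``year,fertilizer_n,manure_n,crop_residue_n,
    deposition_n,bnf_n[,area_agri,area_pulse]``; N in Tg, areas in Mha.
    Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("year", *N_SOURCE_FIELDS) if c not in df.columns]
    if missing:
        raise ValidationError(f"input CSV {path} lacks required columns {missing}")
    if df.empty:
        raise ValidationError(f"input CSV {path} contains no records")
    records = []
    for row in df.itertuples(index=False):
        kwargs = {name: float(getattr(row, name)) for name in N_SOURCE_FIELDS}
        for opt in ("area_agri", "area_pulse"):
            if opt in df.columns and pd.notna(getattr(row, opt)):
                kwargs[opt] = float(getattr(row, opt))
        records.append(NSourceRecord(year=int(row.year), **kwargs))
    return records


def budget_frame(records: Iterable[NSourceRecord]) -> pd.DataFrame:
    """Records as a DataFrame with a ``total_n`` column appended."""
    rows = []
    for r in records:
        row = {"year": r.year, **r.sources()}
        row["area_agri"] = r.area_agri
        row["area_pulse"] = r.area_pulse
        row["total_n"] = total_n_input(r)
        rows.append(row)
    return pd.DataFrame(rows, columns=[*_CSV_COLUMNS, "total_n"])


def write_budget_csv(records: Sequence[NSourceRecord], path: Union[str, Path]) -> None:
    """Write records in the same schema :func:`read_budget_csv` accepts."""
    df = budget_frame(records).drop(columns=["total_n"])
    if df["area_agri"].isna().all() and df["area_pulse"].isna().all():
        df = df.drop(columns=["area_agri", "area_pulse"])
    df.to_csv(path, index=False, float_format="%.17g")
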