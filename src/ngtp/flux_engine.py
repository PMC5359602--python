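"""Gas fluxes from annual nitrogen input via emission/uptake factors.

Every flux is a fixed proportion (Tier-1 style emission factor) of the
total N input N_T, with an explicit element→molecule mass conversion
where the reporting basis is molecular:

* N2O: direct (EF 0.01 kg N2O-N per kg N) plus indirect from the
  leached fraction (0.3 of applied N leached as NO3-N, of which 0.0075
  kg N2O-N per kg N leached), reported as Tg N2O (×44/28).
* NO3 leaching: element-N basis, Tg NO3-N.
* NH3: EF 0.1, reported as Tg NH3 (×17/14).
* NOx: EF 0.005, reported on the element basis, Tg NOx-N.
* CH4: lowland (flooded) soils emit 0.008 kg CH4-C per kg N; upland
  soils lose 0.012 kg CH4-C per kg N of oxidation capacity (suppressed
  sink). Both act in the warming direction, mixed by the lowland
  fraction of applied N, reported as Tg CH4 (×16/12).
* CO2: N application sequesters 0.053 kg CO2-C per kg N, reported as a
  positive uptake magnitude in Tg CO2 (×44/12).

All fluxes are exactly linear in N_T; nothing is rounded here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .errors import ValidationError
from .factors import FactorSet
from .n_budget import NSourceRecord, total_n_input
from .units import CH4_PER_CH4_C, CO2_PER_CO2_C, N2O_PER_N2O_N, NH3_PER_NH3_N

__all__ = [
    "FluxRecord",
    "FLUX_FIELDS",
    "n2o_flux",
    "no3_leach_flux",
    "nh3_flux",
    "nox_flux",
    "ch4_flux",
    "co2_uptake_flux",
    "annual_fluxes",
    "fluxes_for_n_total",
    "flux_frame",
    "write_flux_csv",
    "read_flux_csv",
]

#: FluxRecord value fields in canonical column order.
FLUX_FIELDS = (
    "n2o_direct",
    "n2o_indirect_leach",
    "n2o_total",
    "no3_leach_n",
    "nh3",
    "nox_n",
    "ch4",
    "co2_uptake",
)

_UNITS_COMMENT = (
    "# units: n2o_* Tg N2O; no3_leach_n Tg NO3-N; nh3 Tg NH3; "
    "nox_n Tg NOx-N; ch4 Tg CH4; co2_uptake Tg CO2 (sequestration magnitude)"
)


@dataclass(frozen=True)
class FluxRecord:
    """One year's gas fluxes on their stated mass bases (Tg yr^-1)."""

    year: int
    n2o_direct: float
    n2o_indirect_leach: float
    n2o_total: float
    no3_leach_n: float
    nh3: float
    nox_n: float
    ch4: float
    co2_uptake: float

    def __post_init__(self) -> None:
        if self.n2o_total != self.n2o_direct + self.n2o_indirect_leach:
            raise ValidationError(
                f"n2o_total must equal n2o_direct + n2o_indirect_leach exactly "
                f"in year {self.year}"
            )
        for name in FLUX_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{name} must be >= 0 in year {self.year}, got {getattr(self, name)}"
                )


def _check_n_total(n_total: float) -> None:
    if n_total < 0:
        raise ValidationError(f"total N input must be >= 0, got {n_total}")


def n2o_flux(n_total: float, f: FactorSet) -> tuple[float, float, float]:
    """(direct, indirect-from-leaching, total) N2O emission, Tg N2O.

    Deposition-driven N2O is included implicitly because atmospheric
    deposition is a component of N_T.
    """
    _check_n_total(n_total)
    direct = n_total * f.ef_n2o_direct * N2O_PER_N2O_N
    indirect = n_total * f.frac_leach * f.ef_n2o_leach * N2O_PER_N2O_N
    return direct, indirect, direct + indirect


def no3_leach_flux(n_total: float, f: FactorSet) -> float:
    """Nitrate leached to water, Tg NO3-N (element basis)."""
    _check_n_total(n_total)
    return n_total * f.frac_leach


def nh3_flux(n_total: float, f: FactorSet) -> float:
    """Ammonia volatilization, Tg NH3 (molecular basis)."""
    _check_n_total(n_total)
    return n_total * f.ef_nh3 * NH3_PER_NH3_N


def nox_flux(n_total: float, f: FactorSet) -> float:
    """NOx emission, Tg NOx-N (element basis; no molecular conversion)."""
    _check_n_total(n_total)
    return n_total * f.ef_nox


def ch4_flux(n_total: float, f: FactorSet) -> float:
    """Net CH4 increase attributable to N use, Tg CH4.

    Lowland emission and upland uptake suppression both increase
    atmospheric CH4, so the two terms add with the same sign, weighted
    by the fraction of N applied to flooded soils.
    """
    _check_n_total(n_total)
    ef_c = f.f_lowland * f.ef_ch4_lowland + (1.0 - f.f_lowland) * f.ef_ch4_upland
    return n_total * ef_c * CH4_PER_CH4_C


def co2_uptake_flux(n_total: float, f: FactorSet) -> float:
    """CO2 sequestered due to N application, Tg CO2 (positive magnitude)."""
    _check_n_total(n_total)
    return n_total * f.ef_co2_seq * CO2_PER_CO2_C


def fluxes_for_n_total(year: int, n_total: float, f: FactorSet) -> FluxRecord:
    """All fluxes for one year's total N input."""
    direct, indirect, total = n2o_flux(n_total, f)
    return FluxRecord(
        year=year,
        n2o_direct=direct,
        n2o_indirect_leach=indirect,
        n2o_total=total,
        no3_leach_n=no3_leach_flux(n_total, f),
        nh3=nh3_flux(n_total, f),
        nox_n=nox_flux(n_total, f),
        ch4=ch4_flux(n_total, f),
        co2_uptake=co2_uptake_flux(n_total, f),
    )


def annual_fluxes(record: NSourceRecord, f: FactorSet) -> FluxRecord:
    """FluxRecord for one N-source record (fluxes of its summed N_T)."""
    return fluxes_for_n_total(record.year, total_n_input(record), f)


def flux_frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    rows = [
        {"year": r.year, **{name: getattr(r, name) for name in FLUX_FIELDS}}
        for r in records
    ]
    return pd.DataFrame(rows, columns=["year", *FLUX_FIELDS])


def write_flux_csv(records: Sequence[FluxRecord], path: Union[str, Path]) -> None:
    """Write fluxes as CSV with a leading units comment line."""
    with open(path, "w") as fh:
        fh.write(_UNITS_COMMENT + "\n")
        flux_frame(records).to_csv(fh, index=False, float_format="%.17g")


def read_flux_csv(path: Union[str, Path]) -> list[FluxRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return [
        FluxRecord(
            year=int(row.year),
            **{name: float(getattr(row, name)) for name in FLUX_FIELDS},
        )
        for row in df.itertuples(index=False)
    ]
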