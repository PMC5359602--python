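"""Synthetic FAOSTAT-like annual N-source series.

The historical 1961–2010 N-input series behind the 50-year aggregates
is not redistributable, so this module generates stand-in series
anchored at the two published benchmark years: per-source trajectories
interpolate between the 1961 and 2010 records, optionally perturbed by
multiplicative lognormal noise. Defaults mirror the qualitative shape
of the historical record — roughly tenfold exponential growth of
fertilizer N, gentler near-linear growth of the other four sources —
without claiming statistical fidelity to FAOSTAT interannual structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .n_budget import N_SOURCE_FIELDS, NSourceRecord

__all__ = [
    "SeriesSpec",
    "TRAJECTORIES",
    "DEFAULT_TRAJECTORIES",
    "anchor_records",
    "generate_series",
]

logger = logging.getLogger(__name__)

#: Supported per-source trajectory shapes.
TRAJECTORIES = ("linear", "exponential", "logistic")

#: Default per-source trajectory: exponential for fertilizer (≈10x growth
#: over the period), linear for the slower-moving sources.
DEFAULT_TRAJECTORIES: dict[str, str] = {
    "fertilizer_n": "exponential",
    "manure_n": "linear",
    "crop_residue_n": "linear",
    "deposition_n": "linear",
    "bnf_n": "linear",
}

#: Logistic steepness (curve is normalized to hit both anchors exactly).
_LOGISTIC_K = 10.0


def anchor_records() -> tuple[NSourceRecord, NSourceRecord]:
    """The 1961 and 2010 benchmark N-source records (Tg N yr^-1).

    These are the two published anchor years of the model: fertilizer,
    manure, crop residue, atmospheric deposition and BNF inputs to
    global agriculture.
    """
    rec_1961 = NSourceRecord(
        year=1961,
        fertilizer_n=11.59,
        manure_n=24.20,
        crop_residue_n=14.05,
        deposition_n=3.12,
        bnf_n=21.98,
    )
    rec_2010 = NSourceRecord(
        year=2010,
        fertilizer_n=113.40,
        manure_n=34.02,
        crop_residue_n=31.79,
        deposition_n=14.33,
        bnf_n=27.16,
    )
    return rec_1961, rec_2010


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for one synthetic annual series.

    ``trajectory`` may be a single shape name applied to every source or
    a per-source mapping; missing sources fall back to the defaults.
    ``noise_cv`` is the coefficient of variation of multiplicative
    lognormal noise (0 disables noise and makes endpoints exact).
    """

    start_year: int = 1961
    end_year: int = 2010
    anchor_start: NSourceRecord = field(default_factory=lambda: anchor_records()[0])
    anchor_end: NSourceRecord = field(default_factory=lambda: anchor_records()[1])
    trajectory: str | Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValidationError(
                f"start_year ({self.start_year}) must precede end_year ({self.end_year})"
            )
        if not 0 <= self.noise_cv < 0.5:
            raise ValidationError(f"noise_cv must lie in [0, 0.5), got {self.noise_cv}")
        for name, shape in self.trajectories().items():
            if shape not in TRAJECTORIES:
                raise ValidationError(
                    f"unknown trajectory {shape!r} for {name}; expected one of {TRAJECTORIES}"
                )
        if self.anchor_start.year != self.start_year or self.anchor_end.year != self.end_year:
            raise ValidationError("anchor record years must match start_year/end_year")

    def trajectories(self) -> dict[str, str]:
        if isinstance(self.trajectory, str):
            return {name: self.trajectory for name in N_SOURCE_FIELDS}
        merged = dict(DEFAULT_TRAJECTORIES)
        merged.update(self.trajectory)
        return merged


def _interpolate(v0: float, v1: float, t: float, shape: str) -> float:
    """Value at normalized time t in [0, 1] on the chosen trajectory."""
    if t == 0.0:
        return v0
    if t == 1.0:
        return v1
    if shape == "linear":
        return v0 + (v1 - v0) * t
    if shape == "exponential":
        # geometric interpolation; falls back to linear at a zero endpoint
        if v0 <= 0 or v1 <= 0:
            return v0 + (v1 - v0) * t
        return v0 * (v1 / v0) ** t
    # logistic: sigmoid in t, rescaled so s(0)=0 and s(1)=1 exactly
    s0 = 1.0 / (1.0 + math.exp(_LOGISTIC_K * 0.5))
    s1 = 1.0 / (1.0 + math.exp(-_LOGISTIC_K * 0.5))
    s = 1.0 / (1.0 + math.exp(-_LOGISTIC_K * (t - 0.5)))
    return v0 + (v1 - v0) * (s - s0) / (s1 - s0)


def generate_series(spec: SeriesSpec) -> list[NSourceRecord]:
    """One NSourceRecord per year from start to end inclusive.

    With ``noise_cv == 0`` the first and last records equal the anchors
    exactly and each source follows its trajectory deterministically.
    With noise, each value is multiplied by an independent lognormal
    draw with mean 1 and the stated CV; any negative result (impossible
    for lognormal noise, possible only for pathological anchors) is
    clipped to 0 and logged. Identical seeds give identical series.
    """
    rng = np.random.default_rng(spec.seed)
    shapes = spec.trajectories()
    n_years = spec.end_year - spec.start_year
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
        # lognormal with mean exactly 1
        noise = rng.lognormal(
            mean=-(sigma**2) / 2.0, sigma=sigma, size=(n_years + 1, len(N_SOURCE_FIELDS))
        )
    else:
        noise = np.ones((n_years + 1, len(N_SOURCE_FIELDS)))

    records: list[NSourceRecord] = []
    for i, year in enumerate(range(spec.start_year, spec.end_year + 1)):
        t = i / n_years
        values: dict[str, float] = {}
        for j, name in enumerate(N_SOURCE_FIELDS):
            v = _interpolate(
                getattr(spec.anchor_start, name),
                getattr(spec.anchor_end, name),
                t,
                shapes[name],
            ) * float(noise[i, j])
            if v < 0:
                logger.warning("clipped negative %s to 0 in year %d", name, year)
                v = 0.0
            values[name] = v
        records.append(NSourceRecord(year=year, **values))
    return records
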