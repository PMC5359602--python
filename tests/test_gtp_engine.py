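"""GTP engine: benchmark CO2e values, decomposition identities, envelopes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngtp.errors import UndefinedSharesError, ValidationError
from ngtp.factors import RangePolicy
from ngtp.flux_engine import fluxes_for_n_total
from ngtp.gtp_engine import (
    GTP_COMPONENT_FIELDS,
    annual_gtp,
    cooling_shares,
    gtp_frame,
    period_summary,
    range_envelope,
    species_gtp,
    warming_shares,
)

n_totals = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


def test_species_gtp_n2o_20(default_coeffs):
    got = species_gtp(1.4424, "n2o", 20, default_coeffs)
    assert got.direction == "warming"
    assert got.value == pytest.approx(1.4424 * 275, rel=1e-12)  # ≈ 396.66


def test_species_gtp_unit_co2_coefficient(default_coeffs):
    got = species_gtp(42.89, "co2_flux", 100, default_coeffs)
    assert got.value == pytest.approx(42.89, abs=1e-12)
    assert got.direction == "warming"  # coefficient sign; flux direction cools


def test_species_gtp_nh3_cooling(default_coeffs):
    got = species_gtp(26.7993, "nh3_aerosol", 20, default_coeffs)
    assert got.direction == "cooling"
    assert got.value == pytest.approx(26.7993 * 5.85, rel=1e-12)  # ≈ 156.78


def test_species_gtp_rejects_negative_flux(default_coeffs):
    with pytest.raises(ValidationError):
        species_gtp(-1.0, "n2o", 20, default_coeffs)


@pytest.mark.parametrize(
    "year,horizon,field,expected,tol",
    [
        # printed benchmark values; tolerance absorbs the 74.94-vs-74.93
        # column-sum rounding of the 1961 anchor
        (1961, 20, "warming_n2o", 396.67, 0.5),
        (2010, 20, "warming_n2o", 1168.32, 0.5),
        (1961, 100, "warming_n2o", 439.94, 0.5),
        (2010, 100, "warming_n2o", 1295.78, 0.5),
        (1961, 20, "cooling_total", 92.14, 0.5),
        (2010, 20, "cooling_total", 271.39, 0.5),
        (1961, 100, "cooling_total", 15.21, 0.5),
        (2010, 100, "cooling_total", 44.80, 0.5),
        (1961, 20, "net", 369.44, 0.5),
        (2010, 20, "net", 1088.15, 0.5),
        (1961, 100, "net", 429.17, 0.5),
        (2010, 100, "net", 1264.06, 0.5),
    ],
)
def test_annual_gtp_reproduces_benchmark(
    anchor_fluxes, default_coeffs, year, horizon, field, expected, tol
):
    rec = annual_gtp(anchor_fluxes[year], horizon, default_coeffs)
    assert getattr(rec, field) == pytest.approx(expected, abs=tol)


def test_short_lived_cooling_from_nh3_nox(anchor_fluxes, default_coeffs):
    """Cooling from the NH3/NOx pathways alone matches the printed pairs."""
    for year, horizon, expected in [
        (1961, 20, 77.58),
        (2010, 20, 228.50),
        (1961, 100, 0.65),
        (2010, 100, 1.91),
    ]:
        rec = annual_gtp(anchor_fluxes[year], horizon, default_coeffs)
        got = rec.cooling_nh3_aerosol + rec.cooling_nox_o3_ch4 + rec.cooling_nox_aerosol
        assert got == pytest.approx(expected, abs=max(0.005 * expected, 0.02))


def test_zero_flux_gives_zero_record(default_factors, default_coeffs):
    fx = fluxes_for_n_total(2000, 0.0, default_factors)
    rec = annual_gtp(fx, 20, default_coeffs)
    assert rec.warming_total == rec.cooling_total == rec.net == 0.0


def test_net_identity_holds_exactly(anchor_fluxes, default_coeffs):
    for fx in anchor_fluxes.values():
        for horizon in (20, 100):
            rec = annual_gtp(fx, horizon, default_coeffs)
            assert rec.net - (rec.warming_total - rec.cooling_total) == 0.0


def test_cooling_shares_match_published_split(anchor_fluxes, default_coeffs):
    rec = annual_gtp(anchor_fluxes[2010], 20, default_coeffs)
    shares = cooling_shares(rec, include_co2_seq=False)
    assert round(shares["cooling_nh3_aerosol"] * 100) == 69
    assert round(shares["cooling_nox_o3_ch4"] * 100) == 22
    assert round(shares["cooling_nox_aerosol"] * 100) == 9
    # 1961 pre-rounding split on the same subset
    rec61 = annual_gtp(anchor_fluxes[1961], 20, default_coeffs)
    shares61 = cooling_shares(rec61, include_co2_seq=False)
    assert shares61["cooling_nh3_aerosol"] == pytest.approx(0.686, abs=2e-3)
    assert shares61["cooling_nox_o3_ch4"] == pytest.approx(0.222, abs=2e-3)
    assert shares61["cooling_nox_aerosol"] == pytest.approx(0.092, abs=2e-3)
    assert sum(cooling_shares(rec).values()) == pytest.approx(1.0, abs=1e-12)


def test_shares_of_zero_record_error(default_factors, default_coeffs):
    fx = fluxes_for_n_total(2000, 0.0, default_factors)
    rec = annual_gtp(fx, 20, default_coeffs)
    with pytest.raises(UndefinedSharesError):
        cooling_shares(rec)
    with pytest.raises(UndefinedSharesError):
        warming_shares(rec)


def test_relative_reduction_vs_n2o_alone(anchor_fluxes, default_coeffs):
    """Net GTP sits below the N2O-only GTP by 6.9% (20 yr) and 2.4% (100 yr) in 2010."""
    fx = anchor_fluxes[2010]
    for horizon, expected in [(20, 6.9), (100, 2.4)]:
        rec = annual_gtp(fx, horizon, default_coeffs)
        reduction = (1 - rec.net / rec.warming_n2o) * 100
        assert round(reduction, 1) == expected


def test_horizon_decay_of_short_lived_cooling(anchor_fluxes, default_coeffs):
    """At 100 years the aerosol/ozone cooling of identical fluxes shrinks."""
    for fx in anchor_fluxes.values():
        r20 = annual_gtp(fx, 20, default_coeffs)
        r100 = annual_gtp(fx, 100, default_coeffs)
        assert r100.cooling_nh3_aerosol < r20.cooling_nh3_aerosol
        assert r100.cooling_nox_o3_ch4 < r20.cooling_nox_o3_ch4
        assert r100.cooling_nox_aerosol < r20.cooling_nox_aerosol


def test_period_summary_additivity(anchor_fluxes, default_coeffs):
    recs = [annual_gtp(anchor_fluxes[y], 20, default_coeffs) for y in (1961, 2010)]
    summary = period_summary(recs)
    assert summary.n_years == 2
    assert summary.warming_total == pytest.approx(
        recs[0].warming_total + recs[1].warming_total, rel=1e-15
    )
    assert summary.net == pytest.approx(recs[0].net + recs[1].net, rel=1e-15)
    assert sum(summary.warming_shares.values()) == pytest.approx(1.0, abs=1e-12)
    assert sum(summary.cooling_shares.values()) == pytest.approx(1.0, abs=1e-12)


def test_period_summary_two_identical_years_doubles(anchor_fluxes, default_coeffs):
    fx = anchor_fluxes[2010]
    one = annual_gtp(fx, 20, default_coeffs)
    import dataclasses

    other = dataclasses.replace(one, year=2011)
    summary = period_summary([one, other])
    assert summary.warming_total == 2 * one.warming_total
    assert summary.cooling_total == 2 * one.cooling_total
    assert summary.net == 2 * one.net


def test_period_summary_rejects_bad_sequences(anchor_fluxes, default_coeffs):
    fx = anchor_fluxes[2010]
    with pytest.raises(ValidationError):
        period_summary([])
    r20 = annual_gtp(fx, 20, default_coeffs)
    r100 = annual_gtp(fx, 100, default_coeffs)
    with pytest.raises(ValidationError):
        period_summary([r20, r100])
    with pytest.raises(ValidationError):
        period_summary([r20, r20])  # duplicate year


def test_range_envelope_ordering(anchor_fluxes, default_coeffs):
    fx = anchor_fluxes[1961]
    low, mid, high = range_envelope(fx, 20, default_coeffs)
    assert mid == annual_gtp(fx, 20, default_coeffs)
    # warming components ordered with the policy
    assert low.warming_n2o <= mid.warming_n2o <= high.warming_n2o
    assert low.warming_n2o == pytest.approx(fx.n2o_total * 260, rel=1e-12)
    assert high.warming_n2o == pytest.approx(fx.n2o_total * 290, rel=1e-12)
    # cooling magnitudes ordered the other way: low policy = strongest cooling
    assert low.cooling_nh3_aerosol >= mid.cooling_nh3_aerosol >= high.cooling_nh3_aerosol
    # degenerate CO2 interval gives identical bounds
    assert low.cooling_co2_seq == mid.cooling_co2_seq == high.cooling_co2_seq


@settings(derandomize=True, max_examples=50)
@given(nt=n_totals, k=st.floats(min_value=0, max_value=50, allow_nan=False))
def test_gtp_linear_in_n_input(nt, k, default_factors, default_coeffs):
    base = annual_gtp(fluxes_for_n_total(2000, nt, default_factors), 20, default_coeffs)
    scaled = annual_gtp(
        fluxes_for_n_total(2000, k * nt, default_factors), 20, default_coeffs
    )
    for name in (*GTP_COMPONENT_FIELDS, "warming_total", "cooling_total", "net"):
        assert getattr(scaled, name) == pytest.approx(
            k * getattr(base, name), rel=1e-12, abs=1e-9
        )


def test_gtp_frame_columns(anchor_fluxes, default_coeffs):
    df = gtp_frame([annual_gtp(anchor_fluxes[1961], 20, default_coeffs)])
    assert list(df.columns) == [
        "year",
        "horizon",
        *GTP_COMPONENT_FIELDS,
        "warming_total",
        "cooling_total",
        "net",
    ]
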