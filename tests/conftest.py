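import pytest

from ngtp import FactorSet, GTPCoefficientSet, anchor_records, annual_fluxes


@pytest.fixture(scope="session")
def default_factors() -> FactorSet:
    return FactorSet()


@pytest.fixture(scope="session")
def default_coeffs() -> GTPCoefficientSet:
    return GTPCoefficientSet()


@pytest.fixture(scope="session")
def anchors():
    """The 1961 and 2010 benchmark N-source records."""
    return anchor_records()


@pytest.fixture(scope="session")
def anchor_fluxes(anchors, default_factors):
    """Flux records for the two benchmark years, keyed by year."""
    return {r.year: annual_fluxes(r, default_factors) for r in anchors}
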