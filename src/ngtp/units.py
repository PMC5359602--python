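"""Mass-basis conversion constants and unit helpers.

All element↔molecule conversions in the pipeline use integer atomic
weights (N=14, C=12, O=16, H=1). These ratios are fixed, not
configurable: the accounting convention throughout the package is that
emission factors act on the element (N or C) mass and reported fluxes
are on the stated molecular basis.
"""

from __future__ import annotations

#: Tg N2O per Tg N2O-N (44/28)
N2O_PER_N2O_N = 44.0 / 28.0

#: Tg NH3 per Tg NH3-N (17/14)
NH3_PER_NH3_N = 17.0 / 14.0

#: Tg CH4 per Tg CH4-C (16/12)
CH4_PER_CH4_C = 16.0 / 12.0

#: Tg CO2 per Tg CO2-C (44/12)
CO2_PER_CO2_C = 44.0 / 12.0

#: Tg per (Mha × kg ha^-1): 1e6 ha × kg ha^-1 = 1e6 kg = 1e-3 Tg
TG_PER_MHA_KG_HA = 1e-3
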