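# Methods

## Scope and model structure

`ngtp` implements a linear, annual-resolution accounting model of the
climate impact of nitrogen use in global agriculture. Three stages:

1. **N budget** (`ngtp.n_budget`). Total N input `N_T` (Tg N yr⁻¹) is the
   exact sum of five sources: synthetic fertilizer, animal manure, crop
   residue return, atmospheric deposition and biological N fixation (BNF).
   Deposition and BNF can be estimated from agricultural and pulse-crop
   areas (Mha) times per-area rates (kg N ha⁻¹ yr⁻¹; Mha × kg ha⁻¹ → Tg is
   ×10⁻³ exactly), but directly supplied Tg values are the primary entry
   path: downstream results depend only on the five Tg amounts, and the
   two entry paths are verified to be interchangeable.
2. **Flux engine** (`ngtp.flux_engine`). Every gas flux is a Tier-1-style
   emission/uptake factor times `N_T`. Factors are stored as non-negative
   magnitudes; the engine owns all signs and all element↔molecule
   conversions (44/28 for N₂O/N₂O-N, 17/14 for NH₃/NH₃-N, 16/12 for
   CH₄/CH₄-C, 44/12 for CO₂/CO₂-C, at integer atomic weights — fixed, not
   configurable). NOₓ is deliberately reported on the element-N basis, with
   no molecular conversion, because NOₓ is a mixture without a single molar
   mass and its GTP coefficients are defined per kg NOₓ-N.
3. **GTP engine** (`ngtp.gtp_engine`). Each flux is multiplied by its
   pathway's Global Temperature change Potential coefficient at a 20- or
   100-year horizon. Warming pathways: N₂O; net CH₄ increase. Cooling
   pathways: NH₃→aerosol, NOₓ→ozone/CH₄ perturbation, NOₓ→aerosol, and CO₂
   sequestration (coefficient +1 per kg CO₂, cooling because the flux is an
   uptake). Components are stored as positive magnitudes; signs enter only
   in `net = warming_total − cooling_total`.

## Assumptions

- **Linearity.** All fluxes and CO₂e contributions scale proportionally
  with `N_T`; there are no saturation, lag or interaction terms. This makes
  multi-year aggregation exact component-wise addition
  (`period_summary`) and is asserted as a property test.
- **Pulse-metric accounting.** GTP coefficients are taken as published
  inputs; no radiative-forcing or impulse-response modelling is done, and
  only the 20- and 100-year horizons are supported.
- **Static factors.** One factor set applies to all years; temporal or
  spatial variation in emission factors is out of scope.

## Parameters

Emission/uptake factors (per kg N applied), defaults in `FactorSet`:

| parameter | default | unit | meaning |
|---|---|---|---|
| `ef_n2o_direct` | 0.01 | kg N₂O-N/kg N | direct soil N₂O emission |
| `ef_n2o_leach` | 0.0075 | kg N₂O-N/kg N leached | indirect N₂O from leached NO₃⁻ |
| `frac_leach` | 0.3 | – | fraction of applied N leached as NO₃-N |
| `ef_nh3` | 0.1 | kg NH₃-N/kg N | ammonia volatilization |
| `ef_nox` | 0.005 | kg NOₓ-N/kg N | NOₓ emission |
| `ef_ch4_lowland` | 0.008 | kg CH₄-C/kg N | emission from flooded soils |
| `ef_ch4_upland` | 0.012 | kg CH₄-C/kg N | suppressed oxidation in aerated soils |
| `ef_co2_seq` | 0.053 | kg CO₂-C/kg N | productivity-driven C sequestration |
| `f_lowland` | 0.15 | – | fraction of N applied to flooded soils |

Upland CH₄ "uptake" enters with warming sign: a suppressed sink raises
atmospheric CH₄ exactly as an emission does. `f_lowland = 0.15` is a
calibration: it is the lowland/upland mix under which the effective CH₄-C
factor (0.15×0.008 + 0.85×0.012 = 0.0114 kg CH₄-C per kg N) reproduces the
benchmark CH₄ series (1.14 Tg in 1961, 3.35 Tg in 2010); no independent
estimate of the split is built in.

GTP coefficients (`GTPCoefficientSet`) are low/high intervals per pathway
and horizon (e.g. N₂O: 260–290 at 20 yr, 290–320 at 100 yr; CO₂: the unit
coefficient by definition). A `RangePolicy` collapses intervals to scalars;
the default is the **midpoint**, the only choice consistent with the
benchmark CO₂e values (e.g. 1.4424 Tg N₂O × 275 ≈ 396.7 Tg CO₂e). The
`low`/`high` policies expose the interval as an uncertainty envelope
(`range_envelope`); note that for cooling pathways the `low` policy picks
the most negative coefficient, i.e. the strongest cooling.

**Mass bases are mixed by design.** The coefficient table is applied per kg
N₂O, NH₃, CH₄ and CO₂ (molecular) but per kg NOₓ-N (element). This is the
only convention under which the factor and coefficient tables jointly
reproduce the benchmark warming and cooling numbers, and the test suite
pins it.

## Numerical choices

- No rounding anywhere in the computation; display tables and the
  benchmark report round to 2 decimals at the rendering layer only.
- CSV round-trips are bit-exact: writers use `%.17g` and readers parse
  with round-trip float precision.
- The 1961 benchmark column sums to 74.94 Tg N while its published total
  was rounded to 74.93; the pipeline always uses the exact sum. All derived
  1961 quantities therefore sit within one rounding unit of their published
  counterparts (e.g. 396.71 vs 396.67 Tg CO₂e), which the benchmark
  tolerance of ±0.5 % / ±0.5 Tg CO₂e absorbs.
- Degenerate inputs: zero `N_T` yields all-zero fluxes and GTP records;
  shares of a zero total raise `UndefinedSharesError` rather than returning
  NaNs; mixed horizons or duplicate years in `period_summary` are rejected.

## Synthetic series generator

The historical 1961–2010 annual N-source series is not redistributable, so
`ngtp.synthetic_data` generates stand-ins anchored at the two built-in
benchmark records. Per-source trajectories interpolate between the anchors
— exponential for fertilizer (matching its roughly tenfold growth), linear
for the other four sources; a logistic shape is also available. Optional
multiplicative lognormal noise with a stated coefficient of variation
(mean exactly 1, independent across years and sources) is driven by a
single seeded generator; identical seeds give bit-identical series, and
noise-free series hit the anchors exactly.

What the generator does **not** emulate: FAOSTAT's interannual structure
(wars, policy shocks, autocorrelated growth), country composition, or any
correlation between sources. Passing tests on synthetic series therefore
demonstrate the correctness and stability of the accounting pipeline — its
linearity, aggregation and determinism — not fidelity of any particular
cumulative 50-year total to history. For that reason the published 50-year
aggregates are covered by structural property tests, not by value targets.

## Problem sizes

Everything is desk-scale: the benchmark surface is two years × two
horizons, and the synthetic pipeline runs use 50-year series (50 records),
which complete in well under a second.

## Known limitations

- Tier-1 factors ignore crop, soil, climate and management heterogeneity;
  results are global aggregates only.
- GTP interval endpoints are treated as hard bounds; no distributional
  uncertainty propagation is attempted beyond the low/mid/high envelope.
- The CH₄ lowland/upland split is a single calibrated constant.
- N cascade feedbacks (re-deposition of volatilized NH₃, indirect N₂O from
  deposition on non-agricultural land) are not modelled separately;
  deposition enters once as a budget source.
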