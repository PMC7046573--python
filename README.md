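# fraxepi

Registry-based fracture epidemiology for settings where a catchment-area
survey must carry a national fracture-risk model: stratified incidence
estimation with exact Poisson intervals, adjustment for cases that never
reach hospital sources, reference-ratio imputation of non-hip fracture
incidence, demographic projection of fracture counts, and 10-year /
lifetime fracture probabilities under competing mortality.

It is written for epidemiologists and biostatisticians running two-phase
(retrospective hospital-register + prospective primary-care) fracture
surveys of the kind used to build country-specific FRAX-style risk tools,
where the raw material is a case registry, census denominators and a
national life table.

## What it computes

**Incidence.** For events `D` over person-years `PY` in a (sex, age band)
stratum, the rate is `D / PY x 100,000` with the exact (Garwood) Poisson
interval from gamma quantiles — lower shape `D`, upper shape `D + 1` — so
fractional event counts after adjustment are handled naturally.

**Capture adjustment.** When a prospective phase with extra ascertainment
sources finds `a` additional cases beyond the `r` found per retrospective
year, hospital-only counts are uplifted by `(r + a) / r`. With `r = 65`
and `a = 19` this is a 29% uplift.

**Imputation.** Non-hip major osteoporotic fracture incidence is imputed
from local hip incidence via reference (Malmö) ratios:
`OMF_local = HF_local x OMF_ref / HF_ref` per sex and age band, with an
audit comparing predictions against observed rates (flagged when the
prediction falls outside the observed exact 95% interval).

**Probability.** With piecewise-constant first-fracture hazard `h_f` and
death hazard `h_d`, the probability of fracture before death within
horizon `T` from age `a` is

```
P = ∫₀ᵀ rr·h_f(t) · exp(−∫₀ᵗ (rr·h_f + h_d) du) dt
```

evaluated in closed form on each constant-hazard segment (`rr` is an
optional hazard-ratio multiplier for a clinical risk profile). Lifetime
risk integrates to a terminal age (default 110).

**Projection.** Expected national counts are `Σ rate/100,000 x population`
over strata, under stable age/sex-specific incidence, with percent change
against a base year.

A synthetic-data generator (`fraxepi.simulate`) draws whole registries
with known ground truth — stratum-level Poisson events, sex-specific
hospital capture, refusals, duplicate admissions, pathological
contaminants, Gompertz mortality — so the entire pipeline is testable
without access to confidential registry data. `fraxepi.study_data` ships
the published catchment tables of the Kazakh model-development study as
machine-readable fixtures.

## Worked example

```python
import fraxepi as fx

# Two retrospective years found 65 hip fractures each in women; the
# prospective year found 84. Estimate and apply the capture uplift:
adj = fx.capture_adjustment_factor(65, 19, applies_to_years=[2015, 2016])
print(adj.factor, adj.percent_uplift)      # 1.2923  29

counts = fx.apply_adjustment({2015: 65, 2016: 65, 2017: 84}, adj)
print(counts)                               # {2015: 84.0, 2016: 84.0, 2017: 84.0}

# Adjusted incidence for women 40+ over 106,880 person-years:
rate = fx.crude_rate(sum(counts.values()), 106_880)
lo, hi = fx.exact_poisson_ci(sum(counts.values()), 106_880)
print(f"{rate:.1f} ({lo:.1f}-{hi:.1f})")    # 235.8 (207.6-266.8)
```

The 29% uplift says that roughly a quarter of hip fractures never reached
hospital sources; 235.8 per 100,000/year (printed as 236, 95% CI 208–267)
is the capture-corrected hip fracture incidence in women aged 40+.

The command line mirrors the pipeline stages:

```sh
fraxepi simulate --seed 7 --outdir sim/
fraxepi incidence --registry sim/registry.csv --population sim/population.csv --site hip
fraxepi probability --incidence rates.csv --lifetable sim/life_table.csv \
    --age 70 --sex female --horizon 10 --rr 2
```

## Layout

- `fraxepi.bands` — age-band schemes (5-year hip, 10-year non-hip)
- `fraxepi.registry` — ingest, eligibility filtering, deduplication,
  person-year denominators
- `fraxepi.incidence` — rates, exact intervals, capture uplift, ratios,
  band aggregation, care-pathway summaries
- `fraxepi.imputation` — reference-ratio imputation and its audit
- `fraxepi.probability` — competing-risk 10-year / lifetime probabilities
- `fraxepi.projection` — expected national counts under population
  projections
- `fraxepi.simulate`, `fraxepi.study_data` — synthetic registries with
  ground truth; published-table fixtures
- `fraxepi.cli` — `fraxepi` command with one subcommand per stage

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
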