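# Methods

## Setting and data model

The package implements the computation chain of a two-phase catchment-area
fracture survey. Cases are ascertained from hospital registers and a
trauma centre (retrospective phase) and additionally from primary-care and
home-visit sources (prospective phase, hip only). One registry row is one
ascertained fracture event; denominators are census populations by sex and
age band per calendar year; a national life table supplies age-specific
mortality.

Site definitions are the ICD-10 sets standard in osteoporotic fracture
surveillance: hip S72.0–S72.2, distal forearm S52.5–S52.6, proximal
humerus S42.2. Eligibility: age ≥ 40 in completed years, permanent
resident, non-pathological (metastatic cancer and myeloma excluded),
radiographically confirmed, event year inside the study window. Trauma
energy is deliberately *not* an exclusion: osteoporotic patients fracture
at high trauma too, and bone density is similar in hip-fracture patients
regardless of trauma level. Hip cases verified clinically only (found at
home visits, radiography impossible) can be retained via a config flag;
this is the default in prospective mode, since excluding them would
reintroduce the ascertainment bias the prospective phase exists to
measure. Re-admissions for the same person and site group within the
window collapse to the earliest event (ties keep the first-seen row);
laterality is not recorded, so bilateral same-site fractures also
collapse — a conservative convention.

## Age bands and person-years

Bands are closed-open `[lower, upper)` intervals matching "40–44" style
labels: 5-year bands with a 95+ terminal band for hip, 10-year bands with
a 90+ terminal band for forearm/humerus. Person-years for a stratum over
a period are the annual populations summed; a table printed "for
2015–2017 combined" therefore holds period person-years, and the bundled
fixtures split such numbers evenly across the years so that any sub-period
is recoverable. A population table queried on a coarser band transparently
aggregates finer cells when they tile the requested band exactly; missing
cells are hard errors unless a nearest-year fallback is enabled.

## Incidence and intervals

Rates are events / person-years × 100,000. Intervals are exact (Garwood)
Poisson limits from gamma quantiles (lower shape k, upper shape k + 1),
chosen over normal or score approximations because many strata have very
few events (0–5) where approximate intervals under-cover. The gamma
formulation extends to fractional counts, which the capture adjustment
produces. Reported tables round half away from zero to integers; ratios
are reported to one decimal. Exactness is audited in the tests against an
independent numerical inversion of the Poisson tail probabilities, and
coverage on simulated data sits in the 94–97% band expected of exact
(conservative) intervals.

The capture uplift is estimated and applied at the sex-total level, not
per age band: the prospective excess is a handful of cases, far too few to
estimate band-specific capture. Uplifted counts are carried as fractions;
rounding happens only at report time.

## Imputation and its audit

The reference-ratio imputation assumes the local non-hip-to-hip incidence
ratio equals the reference population's, per sex and band. The audit rule
flags a stratum when the predicted rate falls outside the observed exact
95% interval — an interval-exclusion criterion, not a formal two-sample
test; it matches how such comparisons are flagged in the source tables and
is reproduced cell-for-cell in the tests. No reference (Malmö) incidence
data are bundled: the reference table is user-supplied CSV, and tests use
synthetic references.

## Probability engine

Both hazards are piecewise constant in age: band rates divided by 100,000
become annual first-fracture hazards on the band intervals (no
interpolation between band midpoints — the simplest convention consistent
with tabulated rates, isolated behind `HazardCurve` so alternatives are
pluggable); life-table death probabilities q convert to hazards via
h = −ln(1 − q). The cause-specific cumulative incidence is summed in
closed form over segments split at every knot, so results are exact to
floating point — verified against a knot-aligned fine-grid quadrature
oracle to 1e-8. Beyond the last band the final hazard is held constant to
a terminal age (default 110); with any realistic old-age death hazard the
survival term makes the tail contribution < 1e-4 (tested), so the
truncation choice is immaterial.

Rates are treated as hazards of *first* fracture (the registry counts
persons with at least one index fracture), so no multiple-event correction
applies. Clinical risk factors are reduced to a single user-supplied
hazard-ratio multiplier `rr` on the fracture hazard (e.g. a
prior-fracture profile); cohort-calibrated risk-factor coefficients and
bone-density integration are out of scope. Post-fracture excess mortality
is not modelled: death competes identically before and after the
assessment — a simplification that slightly overstates the survival of
fracture cases but leaves first-fracture probability itself unaffected.

## Projection

Expected counts apply stratum rates to projected populations assuming
stable age/sex-specific incidence — the conventional, likely conservative
assumption. The default age scope is 50+ (burden projections are usually
quoted for 50+ even when incidence tables start at 40); configurable.
Counts stay unrounded internally; percent changes are computed from
unrounded totals to avoid compounding rounding.

## Synthetic data generator

The generator emulates the catchment study's data-generating process at
stratum level: per (sex, band, site, year), events ~ Poisson(rate × PY)
on the bundled catchment denominators (~61,600 persons aged 40+ per
year, within a catchment of ~165,000 residents); each event reaches hospital sources with a sex-specific capture
probability (defaults 65/84 ≈ 0.774 for women and 1/1.08 ≈ 0.926 for men,
the values implied by the study's 29%/8% uplifts); captured cases draw
refusal (p = 82/348) and, among admitted, surgery (p = 200/266) flags;
3% of written rows gain a duplicate re-admission and a 1% contaminant
stream of pathological fractures is injected. Retrospective ascertainment
writes captured events only; prospective ascertainment also writes missed
events, flagged as not presenting and (hip) verified clinically.

True incidence is exponential in age, `rate(a) = r50·exp(slope·(a−50))`,
with defaults log-linear-fitted to the study's own printed band rates
(women hip: r50 = 38/100k, slope 0.108/y, a ~6.4-year doubling time; men
hip: 84.6/100k, 0.072/y; analogous fits for forearm and humerus), so
expected synthetic event counts sit near the study marginals (~350 hip
fractures over three years). Mortality is Gompertz, h(a) = α·e^{0.1a},
with α = 3.7574e-5 (women) and 6.8628e-5 (men) solved once so that life
expectancy at 50 is ≈ 25 and 20 years respectively — plausible for the
setting and clearly synthetic.

What the generator does *not* emulate: calendar-time trends and
seasonality, ethnic stratification, age-dependent refusal, person-level
life histories (stratum counts suffice for every downstream computation
and keep a full replicate in milliseconds), and any correlation between
capture and severity. Passing recovery tests therefore demonstrate that
the estimators are consistent under the assumed ascertainment model, not
that real registries satisfy it.

Alongside the generator, `study_data.study_marginal_registry()` expands
the published marginal counts into a deterministic synthetic registry
(1058 rows) whose cross-tabulations reproduce the printed totals exactly;
sub-marginal detail (which case refused admission, ages within bands,
year assignment) is allocated deterministically and carries no
information.

## Numerical choices and problem sizes

- Rounding for reports: half away from zero to integers; ratios to one
  decimal (banker's rounding would disagree with printed tables at .5).
- Interval level defaults to 95%; invalid levels, non-positive
  person-years, zero reference rates and uncovered hazard windows are
  hard errors rather than silent NaNs.
- Tests run Monte-Carlo checks at 2,000 replicates (interval coverage),
  300 paired replicates (capture-ratio recovery) and 200 registry
  replicates (end-to-end rate recovery, judged against three standard
  errors of the replicate mean); the full suite completes in a few
  seconds on one core.
- The numerical oracle for the probability engine uses knot-aligned
  midpoint quadrature at step 1e-4 years, agreeing with the closed form
  to 1e-8.

## Known limitations

- The capture adjustment assumes the prospective phase achieves complete
  ascertainment; if home-visit sources also miss cases, rates remain
  underestimates.
- Applying one catchment's incidence nationally assumes regional
  representativeness; urban/rural and ethnic gradients of up to two-fold
  are documented elsewhere and are not modelled.
- Imputation inherits the reference-pattern assumption; the packaged
  audit shows exactly where it fails (notably in women).
- The probability engine's single `rr` multiplier is a deliberate
  reduction of multi-factor risk models; it cannot reproduce
  risk-factor-specific, age-varying hazard ratios.
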