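# Methods

This note documents the models and procedures implemented in `shalehealth`,
the defaults and conventions chosen where the underlying methods leave
choices open, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Exposure measures

All distances are great-circle (haversine) on a sphere with the IUGG mean
Earth radius 6371.0088 km.  At the 5 km scale this differs from projected
GIS distances by well under 0.1%, which is negligible relative to the
coordinate precision of well inventories.

**Cumulative well density (CWD)** counts wells within a buffer of radius
*r* (default 5 km) around the home and divides by the buffer area π r²
(wells/km²).  The buffer is inclusive at the boundary (d ≤ r), a convention
fixed for determinism.  Wells are matched to the respondent's assessment
year through the inventory's `year` column; no within-year activity dating
is attempted.

**Inverse distance weighting (IDW)** sums 1/dᵢ (km⁻¹) over the wells in the
buffer.  Wells nearer than 100 m contribute 1/0.1 = 10 km⁻¹ each: inventory
coordinates cannot resolve distances below that scale and an unfloored
score is unbounded for co-located coordinates.

**Buffer clipping.**  When a buffer crosses a state line, the fraction of
its area beyond a straight boundary at perpendicular distance *x* is the
circular-segment formula `(r² acos(x/r) − x √(r²−x²)) / (π r²)`.  The
pipeline itself uses every well supplied; the clip fraction is provided to
audit how much of a buffer an inventory restricted to one state cannot see.

## Annual emission concentration (AEC)

The AEC chain estimates an annual screening concentration (µg/m³) at each
home from an annual emissions inventory and one hourly weather year.

1. **Unit conversion.**  Annual rates in US short tons/year (907 184.74 g;
   a metric switch is available) are converted to g/h by dividing by 8760.
   Each well's CO, NOx, PM2.5 and VOC rates are summed into one total;
   methane and CO₂ columns, if present, are excluded (no expected health
   effects at ambient exposure levels).

2. **Stability classification.**  Every hour maps to exactly one
   Pasquill–Gifford class A–F from three inputs.  Daytime is local hour
   7–18 (a fixed proxy for positive solar elevation); insolation is strong
   / moderate / slight for cloud cover < 1/3, [1/3, 2/3), ≥ 2/3; night
   splits at cloud cover 4/8.  Wind bins are < 2, 2–3, 3–5, 5–6, ≥ 6 m/s.
   The full decision table (in `dispersion.py`) follows the standard
   screening table, with the two-class entries resolved to a single class
   and winds ≥ 6 m/s always neutral (D), so the classification is a total,
   deterministic function.

3. **Box-model kernel.**  The hourly concentration at downwind distance *d*
   from a source of strength Q′ (µg/s) is `C = Q′ / (u_eff · 2 σy(d) σz(d))`
   — emissions diluted in a box advected at the wind speed whose
   cross-section grows with the Briggs open-country dispersion lengths
   `σ = a·x·(1 + b·x)^p` (x in metres; per-class constants tabulated in
   `BRIGGS_OPEN_COUNTRY`).  A wind floor `u_eff = max(u, 0.5 m/s)` handles
   calm hours, standard screening practice.  These kernel constants are an
   explicit, documented stand-in for "a" screening box model: the package's
   guarantees about the kernel are oracle-equivalence and monotonicity
   (C strictly decreasing in distance and wind), not agreement with any
   particular proprietary parameterisation.

4. **Reference percentiles.**  For a hypothetical reference well emitting
   300 g/h, the 8760-hour concentration series is computed at the five
   receptor distances 0.5, 1, 2, 3, 5 km and summarised by its 90th
   percentile (linear interpolation between order statistics — percentile
   dialects differ, so the definition is fixed and tested).  Plume
   direction is not modelled: every hour's plume is assumed to impact the
   receptor (screening worst case), so the four directional quadrants
   currently carry identical values.  The quadrant axis is retained in the
   table so a wind-rose weighting can be added without changing the schema.

5. **Per-well scaling and aggregation.**  Each well within 5 km is assigned
   the nearest distance bin (wells closer than 0.5 km use 0.5 km; nearest-bin
   was chosen over interpolation for determinism), its quadrant from the
   initial bearing home→well (half-open bins [0°,90°)→NE etc.), and
   contributes `rate_g_per_h × P90[bin, quadrant] / 300`.  Contributions sum
   across wells, making the AEC exactly linear in emissions.

## Cohort construction

Records arrive pre-coded (one row per respondent, binary `sym_*` columns).
Exclusions run in two audited stages — review-stage flags (minors,
oil-and-gas industry workers, out-of-state residents, incomplete
assessments), then missing residence coordinates — each reporting
input/removed/retained counts that must conserve.  Both stages are
idempotent.  The clinician plausibility review that strikes individual
symptoms cannot be algorithmised; it is represented as explicit per-symptom
override flags (`apply_symptom_overrides`) supplied with the data.

Frequency tables report per-symptom counts and integer percentages (half-up
rounding, matching how such tables are usually displayed).  Category
summaries map symptoms into nine groups (general; lung and heart; skin;
EENT; GI; nerves and muscle; reproductive; blood system; psychological)
through an editable YAML dictionary shipped with the package; its
memberships are sensible defaults, not clinical claims.

## Poisson GLM and model selection

Total symptom count is modelled as Poisson with log link, fitted by IRLS
(statsmodels) with Wald standard errors; `AIC = −2ℓ + 2k` and
`AICc = AIC + 2k(k+1)/(n−k−1)`.  The exposure term is forced into every
model; demographic candidates (age, sex, smoker, water source) enter as
main effects only, categoricals dummy-coded with configurable reference
levels (defaults: male, never-smoker, municipal water).  Exhaustive
selection fits all 2^m demographic subsets, each on the complete cases for
its own covariates, and ranks by AICc ascending with deterministic
tie-breaks (fewer terms, then lexicographic term names).  The single
lowest-AICc model is reported as best; the full ranked table is returned so
looser rules (e.g. "lowest or second lowest") can be applied by the user.
A spatial-scale comparison recomputes CWD at several radii (default 1, 2,
5 km), fits the same model form, and selects the radius with the lowest AIC.

Degenerate inputs fail loudly: constant-zero design columns and singular
designs raise before fitting, non-convergence raises with iteration
diagnostics, and AICc is undefined (error) for n ≤ k + 1.

## TITAN for binary symptoms

For a binary occurrence vector and an exposure gradient, every admissible
split between consecutive distinct sorted gradient values (≥ `min_split`,
default 5, samples per side) partitions respondents into low/high groups.
Each group's Dufrêne–Legendre indicator value is `IndVal_g = 100·A_g·B_g`
with specificity `A_g = m_g/(m_lo+m_up)` and fidelity `B_g` = occurrence
proportion in the group; for 0/1 data `B_g = m_g`, so
`IndVal_g = 100·m_g²/(m_lo+m_up)`.  The change point is the midpoint of the
gradient values flanking the split maximising the larger group IndVal, ties
resolved toward the lower exposure; the direction is *positive* when the
high-exposure group is the indicated one (exact group ties resolve to
positive).  Abundance weighting is deliberately out of scope for 0/1
symptoms.

**Significance.**  The gradient is permuted `n_perm` times (default 250)
and the maximised IndVal recomputed; the z-score standardises the observed
maximum against the permutation distribution.  The p-value is the add-one
**mid-p** estimator: exact ties between observed and permuted maxima —
common with binary data, roughly 4% of permutations at n ≈ 100 — receive
half weight.  Counting ties fully would push the realised type-I error to
~0.027 at a nominal 0.05; the mid-p version is calibrated (measured
0.042–0.049 under a simulated null) while the add-one term keeps p > 0.

**Stability.**  Respondents are resampled with replacement `n_boot` times
(default 500): *purity* is the share of replicates reproducing the observed
direction, *reliability* the share with permutation p ≤ 0.05.  Replicates
in which the indicator is undefined (no reporters drawn, or no admissible
split) count as neither.

**Filters.**  Symptoms reported fewer than 5 times are excluded from the
analysis; the reporting filter keeps significant symptoms with frequency
strictly greater than 10 and z ≥ 1 (the inclusive/strict boundaries are
encoded exactly and tested).

## Synthetic-data generator

The generator emulates the three inputs the pipeline consumes, with the
statistical structure the analyses assume; all randomness flows from one
seed through a splittable `SeedSequence`.

* **Wells**: uniform locations in a ~1°×1° bounding box over southwest
  Pennsylvania; per-pollutant tons/year log-normal (log-sd 1.0) with
  pollutant shares CO 40%, NOx 30%, PM2.5 5%, VOC 25% of a mean total of
  50 tons/year per well.  No spatial clustering into pads — uniform
  placement suffices for testing the metrics.
* **Weather**: a complete hourly year; cloud cover a logistic-mapped AR(1)
  (smooth, in [0,1]); wind a diurnal base (mean ≈ 3 m/s, afternoon peak)
  modulated by a log-scale AR(1), strictly positive.
* **Respondents** (default 104, mirroring a convenience-sample design):
  ages 18–90; 59% female; 40% ever-smokers with the smoker column masked
  "missing" for 25%; one-third municipal water.  The expected symptom count
  is log-linear: `λ = baseline · exp(β z + 0.49·female + 0.52·smoker) / c`,
  with baseline 7 symptoms, β (default 0.5) acting on the cohort-standardised
  IDW exposure, and `c` the analytic correction `E[exp(effects)]` so the
  cohort mean at β = 0 equals the baseline exactly in expectation.  The
  dose `z` is winsorised at ±3 SD: inverse-distance exposures are heavy
  tailed (a home on top of a well pad sits 10–15 SD out) and an unsaturated
  log-linear response would imply expected counts in the tens of thousands,
  which a finite symptom dictionary cannot express.  The Poisson draw is
  capped at `n_symptoms` (binary coding cannot exceed the dictionary) and
  allocated to symptom columns by weighted sampling without replacement
  over heterogeneous popularity weights.
* **Gradient-responsive symptoms** (the planted TITAN signal): a random
  subset (default 10) whose sampling weight is multiplied by the affinity
  (default 25) above the 75th-percentile exposure threshold and divided by
  it below, producing a crisp occurrence step.  The affinity default comes
  from a power analysis: with ~7 symptoms spread over 60 columns at
  n ≈ 100, upper-group occurrence rates below ~0.5 are not reliably
  detectable by the max-IndVal permutation test, so weaker affinities would
  not serve the generator's purpose of planting recoverable signal.  The
  threshold sits in the upper quartile so that the mass reallocated away
  from non-responsive symptoms is confined to a small group and they remain
  effectively null.  A flagged-record wrapper (`generate_assessment_records`)
  prepends review-stage and missing-coordinate exclusions so the audited
  cohort flow can be exercised end to end.

What passing tests on this generator do **not** show: the generator has no
spatial clustering of wells, no real meteorology, no recall bias, no
symptom-onset timing, and its demographic joint distribution is a stand-in
— so recovery results demonstrate the *machinery* is correct and calibrated,
not that any particular real-world cohort would yield the same findings.

## Problem sizes and numerical conventions

Simulation-based checks use cohorts of 104–2000 respondents, 100–400 wells,
20–200 replicates, 250 permutations and 100–500 bootstrap replicates —
sizes at which every statistical property under test (coverage,
calibration, recovery) has comfortable Monte-Carlo resolution on one CPU.
Percentiles use linear interpolation; percentages display half-up; all
tie-breaks (model ranking, change points, quadrant and distance bins) are
deterministic and documented at the definition site.  Reruns with the same
seed are byte-identical across the whole pipeline.

## Limitations

* The dispersion kernel is a screening model: no terrain, chemistry,
  deposition, mixing-height caps, plume direction, or multi-station weather
  blending; emissions are assumed constant over the year.
* Annual inventories cannot isolate development phases (drilling, fracking,
  flowback) with different emission profiles.
* The quadrant axis of the reference table currently duplicates one
  percentile series; it exists to host wind-rose weighting later.
* GLMs are Poisson only — no zero-inflated or negative-binomial variants
  (symptom totals with ~15% zeros do not require them).
* TITAN here is the per-response analysis; community-level sum(z)
  change-point curves are not implemented.
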