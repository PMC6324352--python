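# Methods

## Scope and model

The package evaluates a linear HCC risk-adjustment model against a
dual-payer (VA + Medicare A/B/D) patient-year population. The unit of
analysis is the patient-year: diagnoses from the year before the cost year
determine the risk score; the regressand is total annual cost across both
payers. Costs are carried as integer cents internally so the payer
additivity invariant (total = VA + Medicare) is exact.

The risk score is linear and additive on the dollar scale of the shipped
fixture specification:

r_i = d(sex_i, age_i; v_i) + Σ_{h ∈ HCC(i)} β_h(v_i)

where v_i is the coefficient variant — institutional if the patient spent
*strictly more than* 90 days in skilled nursing or long-term care during the
cost year, community otherwise (exactly 90 days is community). Demographic
cells are half-open age bands (lo, hi] per sex; an age on a band's upper edge
belongs to that band.

**Hierarchy semantics.** A hierarchy rule (dominant, suppressed set) fires if
and only if its dominant category is present in the *original* pre-hierarchy
category set; all suppressed categories of firing rules are removed in one
pass. This makes imposition order-independent and idempotent, and the output
is always a subset of the input. With chained rules A⊳B and B⊳C, the input
{A, B, C} yields {A}: B's rule fires because B was in the original set, even
though B is itself suppressed. (Real published hierarchy tables are
transitively closed, so the distinction never matters for them; the
convention is pinned here and cross-checked against a brute-force applier
over all subsets in the test suite.)

Unmapped diagnosis codes are counted and reported, never errors — real
claims always contain codes outside a model's map, and failing hard would
make the engine unusable on dirty data.

## Cost regressions

The primary model is OLS of total cost on the scalar risk score, because
capitated payment formulas are linear and additive. The augmented design
*supplements* the score with 47 psychiatric category indicators (it does not
remove the four MH/SA categories already priced inside the score), so the
two OLS designs are nested and the augmented R² can never be smaller on the
same sample.

Sensitivity families address cost skewness:

* **Gamma GLM, log link** — fitted by iteratively reweighted least squares
  (relative tolerance 1e-8, at most 100 iterations; non-convergence is an
  explicit error). Zero costs are floored at $1 with a logged count, since
  the gamma density requires positive outcomes. Predictions exp(Xβ) estimate
  the conditional mean directly, so no retransformation is needed
  (retransform_factor = 1).
* **Square-root OLS** — fitted on √cost. Back-transformation uses the Duan
  smearing estimator, which for a square-root transform is *additive*:
  E[y|x] = (Xβ)² + mean(e²). The fitted model stores the correction in
  `retransform_factor`; on noiseless data the correction is zero and the
  back-transform is exact. R² is reported both on the fitting (√) scale and
  on the dollar scale.

Healthcare costs are strongly heteroscedastic (the generator's noise is
multiplicative), so coefficient standard errors and 95% confidence intervals
use the HC1 sandwich estimator; classical OLS intervals would undercover.
Negative linear predictions are retained, not clipped — clipping would
distort decile membership — and a diagnostics counter reports how many occur.

## Decile calibration

Patients are sorted by (predicted cost, patient id) — the id tie-break makes
assignment deterministic — and split into ten contiguous groups with sizes as
equal as possible (the first n mod 10 groups take the extra patient). Per
decile the table reports the unweighted mean predicted ("expected") and
observed cost, the gap Δ_d = expected − actual (negative = underestimate),
and the percent gap 100·Δ_d/expected rounded to the nearest integer, half
away from zero. Half-away-from-zero rounding is used for all published-style
percentages because it reproduces every verifiable printed percentage in the
reference tables. Gaps and means are kept unrounded internally; rounding is a
display rule, so the conservation identity Σ_d n_d·Δ_d = Σ(ŷ − y) holds to
floating-point precision on every cohort.

Subgroup tables (diabetes, mental health, dementia) restrict the cohort
*first* and re-decile within the subgroup — subgroup tables therefore have
their own expected-cost ranges, which is what the published subgroup tables
show. Diabetes is measured by the risk model (raw diabetes categories before
hierarchy); mental health and dementia are measured by the psychiatric
grouper. The improvement series computes each model's gaps on its own deciles
and aligns them by decile index; the reduction summary is
mean|Δ_d|(base) − mean|Δ_d|(augmented).

## Synthetic population

The generator emulates a veteran-like population and is the package's test
bed; its defaults are the study conditions everything else is evaluated
under:

* demography: 93.5% male; age ~ N(63.0, 16.1²) truncated to [22, 100];
* condition prevalences: diabetes 22.1% (32% of it complicated), PTSD 10.4%,
  dementia 0.8%, any psychiatric category ≈ 36%, any MH/SA HCC ≈ 13%,
  serious mental illness ≈ 4.8%; mood-disorder (≈17.8% vs the 18.5% target)
  and substance-abuse (≈16.9% vs 17.9%) unions land about one percentage
  point low — the cost of matching the any-MH/SA union simultaneously;
* psychiatric comorbidity clusters through a Gaussian copula with one shared
  latent propensity per patient (latent correlation 0.45; a smaller value
  cannot reconcile the itemized prevalences with the any-MH/SA union);
* true expected clinical cost equals the fixture risk score (dollar scale),
  optionally plus psychiatric increments; observed clinical cost multiplies
  it by mean-one lognormal noise, cost = μ·exp(ε), ε ~ N(−σ²/2, σ²);
* payer split: Medicare share is zero below age 65 and ramps with age above
  it (≈ 4.5%/year, capped at 70%), concentrating Medicare cost in the ≥65
  stratum; splits are computed in integer cents so additivity is exact.

**Noise scale.** σ defaults to 0.65. Two requirements pull in opposite
directions: a heavy right tail (median cost below half the mean, as in real
annual cost data) wants large σ, while decile-level calibration noise at the
reference evaluation size (n = 100,000; decile means over 10,000 patients)
wants small σ — at σ ≈ 1.1 the per-decile sampling noise alone is ≈1.5% of
the decile mean, overwhelming a ±2% calibration band even for a perfectly
specified model. The package resolves this by putting most of the skewness
into the *condition mix* (a low demographic base of $1,500–$3,700 per year
plus rare expensive conditions up to $60,000) and keeping σ at 0.65, which
leaves per-decile noise ≈0.7% and a cost distribution with mean ≈ $12,200,
median ≈ $5,700 and SD ≈ $19,700.

**Mispricing channels** (`inject_mispricing`) change one thing at a time:

* `NONE` — expected cost equals the score exactly for every patient; a
  correctly specified model calibrates to within the display band in every
  decile.
* `MH_UNPRICED` — psychiatric categories that map to no condition category
  (PTSD $3,600, depression NOS $2,400, anxiety $1,500, nicotine $900, ...)
  carry real cost the score cannot see. After refitting, the mental-health
  subgroup is underestimated in every decile, ≈ $2,100 per mental-health
  patient-year at the defaults, and the 47-indicator augmented model
  recovers most of it.
* `DEMENTIA_CUSTODIAL` — dementia patients accrue custodial LTC days that
  grow with their clinical risk score (days ≈ 20 + score/90 + noise, capped
  at 365), billed at $250/day but absent from the coefficient tables. The
  custodial component is added *after* the multiplicative noise: per-diem
  custodial spending is mechanically determined by length of stay, not by
  episodic utilization, and this is what produces the published-style
  monotone growth of the dementia calibration gap across deciles at a
  realistic 0.8% dementia prevalence. In the other two modes the per-diem is
  zero and the pure multiplicative form holds exactly.

What the generator does **not** emulate: coding intensity differences between
payers, longitudinal multi-year trajectories, within-category severity
tiers, facility structure, and the real coefficient magnitudes — the shipped
risk-model spec (15 categories, 4 hierarchies) and 47-category code list are
synthetic fixtures with fabricated code ranges. Passing tests therefore
demonstrate that the *machinery* (mapping, hierarchies, scoring, grouping,
regression, calibration) behaves correctly and that the qualitative
mispricing mechanisms reproduce; they do not reproduce real-data cohort
estimates, which depend on restricted claims.

## Evaluation conventions

* **Parameter recovery** regresses cost on the generator's true score under
  exact pricing (population slope 1, intercept 0): 50 replicates at
  n = 20,000; the replicate-mean slope recovers truth within 1% and the HC1
  95% CI covers the true slope at close to nominal rate.
* **Exact-pricing calibration** is checked with predictions equal to the
  true conditional mean (the oracle). A refit OLS line adds slope sampling
  noise (SD ≈ 0.9% at n = 100,000 under these heavy-tailed costs) that the
  lowest decile amplifies several-fold in percent terms; the oracle
  convention isolates the calibration property itself from that estimator
  noise. The mispricing signatures, whose effects are an order of magnitude
  larger, use refit predictions.
* Decile assignment, rounding and tie-breaks are all deterministic, and the
  pipeline writes byte-identical artifacts for identical configurations.

## Known limitations

* The fixture specification treats coefficients as dollars; relative-factor
  tables load via the manifest `scale` flag but the generator only produces
  dollar-scale truth.
* The gamma GLM's $1 cost floor is a pragmatic choice for a cohort defined
  by healthcare use (near-zero totals are rare); it is logged, not silent.
* The missed-diagnosis denominator is defined exactly as
  {any psychiatric category} ∧ {no MH/SA HCC}. Published counts derived from
  real data need not nest this cleanly (the reference table's denominator
  differs slightly from the difference of its own marginal counts); the
  package documents rather than reproduces that discrepancy.
* Exclusion flags (medication-only use, no VA use) are taken as input
  columns; deriving them from raw utilization files is out of scope.
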