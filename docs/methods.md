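# Methods

This note records the models implemented by the package, the parameters
that matter, the design choices that were genuinely open, and what the
synthetic-data validation does and does not establish.

## Casemix weights

Medical weights are cost-relative: for each (stay stratum, ICD-10 code)
cell with at least `low_volume_threshold` (default 20) cases in the
weight-setting window, W_g is the cell's mean total charge divided by the
medical reference cost.  Stay strata are short (<2 days), medium (2–15)
and long (>15), on integer length of stay; weight-setting is performed
separately within each stratum, so the same diagnosis can carry different
weights in different strata.

Open choices, and how they were resolved:

* **Medical reference cost.**  Only the surgical reference (1,000,000 LBP)
  is an externally fixed constant.  The medical normalizer is taken as the
  grand mean charge over *all* medical cases in the window, which gives the
  natural calibration W = 1 for a code billing at the average and
  reproduces the expected ordering short-stay CMI < 1 < long-stay CMI.  It
  is overridable (`reference_cost=`).
* **Low-volume fallback scope.**  Codes under the 20-case threshold take
  the case-weighted average weight of the *stratum's* high-volume codes
  (falling back to the all-medical average only if a stratum has none),
  because weight-setting is stratum-separated; `fallback_scope="medical"`
  switches to the all-medical average.
* **No inflation adjustment.**  Charges enter as recorded; multi-year code
  averages are used without deflation.  Weights are frozen for the entire
  analysis period, so CMI movements reflect case composition, not price
  drift.

Surgical weights are flat fees divided by the 1M LBP reference, capped at
10.00 (`capped` flagged in the table) to bound outlier leverage.  Rejected
non-positive charges are counted and reported, never silently dropped.

## Case classification and CMI

A record with a diagnosis and no procedure is medical; procedures only,
surgical; both, mixed.  The medical case weight is the single discharge
diagnosis weight (comorbidities are not recorded); the surgical case
weight sums over all listed procedures, secondary included.  Mixed-case
series come in three components: medical (diagnosis weight), surgical
(summed procedures), and "all", which pools the two contributions of each
case as separate entries — the only pooling consistent with the ordering
medical component < all < surgical component; this is an interpretation
and is flagged as such.

Records are bucketed by **discharge** month.  The all-stay medical CMI
equals the case-weighted combination of the stratum CMIs exactly (asserted
in tests).  Months with no included case are carried as missing (`NaN`,
`n_cases = 0`), logged, and dropped listwise at regression time.

Chemotherapy sessions (Z51.1, Z51.2) are excluded before CMI computation:
they are low-cost short stays whose coding *improves* around such reforms
(general cancer codes corrected to Z51.1), so retaining them would
artificially depress the index precisely when coding gets better.  The
exclusion also applies to the medical component of mixed cases (the
surgical component of a chemotherapy-coded mixed case is kept); both
behaviours are configurable for sensitivity runs.  ICD codes are
uppercased with the dot preserved — three-digit (J18) and four-digit
(J18.0) codes are distinct, because the shift between them is itself an
analytic signal.

## Interrupted time series

Segmented regression on the monthly series with the month index starting
at 1, an interruption at intervention month + behavioural lag (default
August 2014 + 2 months = October 2014, lag configurable 0–4 for
sensitivity), and 11 calendar-month indicators with January as the
(arbitrary, estimate-irrelevant) reference.  The post-slope term is
centred at the first post-lag month, so the level coefficient is the level
change *at* that month.  Estimation requires ≥24 usable points with ≥6 on
each side of the interruption, and all 12 calendar months when seasonal
dummies are on.

Inference: Newey–West HAC covariance with Bartlett weights
w_j = 1 − j/(L+1).  `newey_covariance` itself is the plain sandwich (with
L = 0 it equals HC0 exactly, asserted against a brute-force double sum and
against statsmodels); at the fit level the covariance is scaled by
n/(n−k) and intervals use t(n−k) critical values, the usual small-sample
behaviour of Newey OLS implementations — in 1,000-replicate simulations at
n = 72 this lifts empirical 95% CI coverage from ≈0.90 to ≈0.92–0.94.
It can be disabled (`df_correction=False`).

**Bandwidth.**  The HAC lag is not an externally given constant.  Default:
L = 1, escalated to the largest order ≤6 at which the residual
autocorrelation test rejects at α = 0.05 — autocorrelation that the
behavioural lag does not absorb widens the standard errors instead of
being ignored.  A fixed `hac_lag` overrides this.

**Autocorrelation test.**  The Cumby–Huizinga general test, specialized to
a deterministic (hence strictly exogenous) design, reduces to its score
form: regress the residuals on the original design plus q lagged
residuals (zero-padded) and refer n·R² to χ²(q).  That asymptotic form is
measurably oversized at n = 72 (empirical size 0.07–0.09 at α = 0.05), so
the package defaults to the standard small-sample F version of the same
statistic (q, n−k−q degrees of freedom; empirical size ≈0.06, power
against AR(1) φ = 0.8 ≈ 1.0); `form="chi2"` restores the asymptotic
version, which is also the form cross-checked against the
Breusch–Godfrey implementation in statsmodels.  Numerically perfect fits
(residual variance at machine zero) report a zero statistic rather than
testing noise.

Relative changes divide by the starting level β₀: level %, pre-trend %,
post-trend % (β₁+β₃), trend-change %.  Two-sided p-values at α = 0.05; no
multiple-testing correction across strata — each stratum is reported on
its own, as is conventional for this design.

## Code-level attribution

Windows are discharge-year based (pre 2013–14, post 2015–16, disjoint by
construction).  Because weights are frozen, WN0 = W_g·N_pre and
WN1 = W_g·N_post.  The Code Count Effect squares the product of the WN
change and the weight's distance from the reference CMI, making it a
magnitude: codes are ranked by how much they moved the index in *either*
direction, with the direction reported separately as sign(ΔN).  Two
consequences are asserted as invariants: a zero-change code contributes
zero, and a code whose weight equals the reference contributes zero no
matter how its counts move.

* **CMI_ref** is not externally defined; the stratum's pre-window CMI is
  used (case-weighted mean code weight over the pre window), overridable
  for sensitivity comparison against a pooled-window reference.
* **Share change** (WN1−WN0)/WN0 reduces identically to the relative case
  change under frozen weights (asserted); the table additionally carries
  `share_point_change`, the change in the code's percentage share of total
  weighted volume, which is the more informative share quantity.  Relative
  change is blank (NaN) for codes absent from the pre window.
* **Ranking** defaults to attributable percent, descending, ties broken by
  |ΔN| then code; the key is configurable since a ranking by the share
  column is equally defensible.
* Surgical attribution counts procedure occurrences (secondary included),
  mirroring how procedures enter the surgical CMI.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
a configurable scale.  The study-like preset uses 2,000 cases/month
(≈144,000 records over 72 months, roughly one-tenth of the reference
population of ~1.35M) — large enough for stable monthly CMI points, small
enough that the full pipeline runs in seconds; tests use 120–500/month.

Conditions fixed by the preset: 2011-01–2016-12; case mix 55.4/42.5/2.1
medical/surgical/mixed; 32% public; medical stays 19.8/78.1/2.1
short/medium/long; calendar seasonality with a March minor peak,
July–August trough and November–December major peak (the same factor
scales expected volume and tilts severity); intervention August 2014 with
a 2-month lag.  The intervention block injects the mechanisms, not the
coefficients: chemotherapy recoding C50→Z51.1 (p = 0.41) and
C91.0→Z51.1 (p = 0.57), matching the published two-year declines of those
codes; admission declines of 0.5–1.3%/month for the low-severity
diagnoses A09, R10, I10 and R50; and monthly medium→short stay shifting of
1–1.5% for A09, R10 and I10.  The `level_effect`/`trend_effect` knobs
(exponential tilting of code propensities toward costlier codes,
approximately calibrated in CMI units) stay neutral in the preset and
exist for controlled experiments.

Per-code charge dispersion is not published anywhere; charges are
log-normal (strictly positive, right-skewed, like billing data) with
coefficients of variation of 0.15–0.40 chosen as free parameters.  Mean
charges are calibrated so that stratum CMIs land near 0.35 / 1.08 / 3.3 /
1.28 (short/medium/long/surgical) on a medical reference cost close to
1M LBP.  Mixed cases attach 1–3 procedures (mean ≈1.5) to a medical
record; surgical cases carry ≈1.1 procedures.  Recoding relabels a record
without changing its billed amount (the service delivered is unchanged);
stay shifting relabels the stratum and redraws the stay length.

Randomness: one root seed, split into per-month substreams, so output is
byte-identical for a fixed (config, seed) and an edit to one month's
parameters leaves other months' draws untouched.

**What passing tests show — and do not.**  The generator reproduces the
marginal structure the estimators consume (composition fractions, seasonal
volumes, per-code charge laws, abrupt/gradual injected effects).  It does
not model hospital-level heterogeneity beyond ownership, patient-level
case correlation, demand shocks (e.g. refugee-driven shifts in
deliveries), epidemic dynamics, or coding-quality drift outside the
injected mechanisms.  Estimator validation on these data therefore
establishes correctness of the arithmetic and calibration of the
inference under the stated model, not robustness to every real-world
departure from it.  At the scaled-down volume, mechanism-induced level
changes (≈+0.01 on the medical CMI) are of the same order as the monthly
sampling noise, so single-seed point estimates of the level change can
fall on either side of zero; exact coefficient-recovery checks instead
inject effects directly at series level, where truth is controlled.

## Pipeline

Stages (simulate/load → weights → CMI → ITS + lag sensitivity →
attribution) communicate only through files; a JSON manifest records the
config hash, seed, per-stage timings and row counts, including audit
counts for filter effects such as the chemotherapy exclusion.  Reruns with
the same config and seed are byte-identical; on a stage failure the run's
partial outputs are removed and the error names the stage.  Record
validation checks column presence, date parsing, LOS/date consistency,
code syntax (ICD-10 `letter+2 digits[.1-2 digits]`, alphanumeric CPT),
ownership vocabulary and record-id uniqueness, reporting one reason per
rejected row (first failing check wins).

## Known limitations

* Age and comorbidity adjustment are absent by design — single discharge
  diagnosis per medical case.
* The CMI excludes the denominator-correction component some casemix
  systems apply; league-table (per-hospital) CMI is out of scope.
* The ITS is single-group: causal reading rests on the historical control
  and seasonality adjustment, not on a contemporaneous comparison group.
* Attribution uses annual windows and frozen weights; it decomposes the
  change arithmetic, it does not test significance per code.
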