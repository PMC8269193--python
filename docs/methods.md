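# Methods

## The screening model

A pregnancy is screened at a 34+0–36+6 week ultrasound. Biometry (BPD, HC,
AC, FL, in mm at the API) yields an estimated fetal weight (EFW) through a
registered regression formula; the bundled formulas are the two Hadlock 1985
log10-linear models (four-parameter BPD/HC/AC/FL and three-parameter
HC/AC/FL) and the Stirnemann 2017 HC+AC natural-log model, each transcribed
from its source publication into a versioned JSON file with its citation.
Each growth standard declares which formula it was built on and converts the
EFW at the scan GA into an estimated percentile weight (EPW) on the 0–100
scale, clamped to [0.01, 99.99] so probit transforms stay finite.

Three parameterization families cover the six bundled standards:

* **z-score curve** (`msuh_nc`, `intergrowth21`, `fmf`): a tabulated median
  weight `m(GA)` (daily grid over 238–258 days, interpolated linearly in
  days) and a dispersion `sigma` under a declared transform of the ratio
  `u = w/m(GA)` — `normal` (`z=(u-1)/cv`), `log` (`z=ln(u)/s`), or the
  skew-capable `shifted_log` (`z=(ln(u+a)-ln(1+a))/s`). The shifted-log
  transform is the family's skewness slot: as `a -> 0` it is lognormal, as
  `a -> inf` it tends to a plain normal scale, and intermediate values fit
  distributions whose P10/P50/P90 are not log-symmetric.
* **customized** (`msuh_cust`, `figueras`): Gardosi-style individualization.
  Expected weight = `(base term weight + additive covariate effects in grams
  at the 280-day reference) * proportionality(GA)` with an exponential
  proportionality curve; the percentile comes from the same transform/z
  machinery around that individualized center. Covariate effects are
  per-unit (heights, BMI, age, with declared reference values) or
  categorical (parity, ethnicity, fetal sex). A record missing a required
  covariate is excluded from that standard only, with per-standard
  analyzed/excluded tallies that always sum to the cohort size.
* **quantile grid** (`who`): weights at the 5/10/25/50/75/90/95th
  percentiles on a weekly GA grid, validated at load for strict monotonicity
  across levels and nondecreasing weights in GA. Percentile lookup
  interpolates the grid linearly in GA, then linearly in weight against the
  probit of the level; outside P5–P95 the outer segment is extended on the
  probit scale and the result clamped.

Every family exposes the inverse map `weight_at_percentile`; forward and
inverse agree to 0.1 percentile points (tested for all six standards).

## The synthetic cohort

No patient-level data ship with the package; the generator emulates the
statistical structure the analysis needs, with defaults matched to a
published single-centre Spanish screening cohort (n = 9585; scan EFW median
2495 g by the four-parameter Hadlock formula and 2421 g by Stirnemann;
birthweight median 3310 g, IQR 3030–3590; SGA rate 9.4%; per-component APO
rates 0.2–2.8%).

* **Covariates** are sampled from independent marginals (normal for ages and
  heights, lognormal for BMI, categorical for parity/ethnicity/sex/smoking)
  matched to the published medians and IQRs. No covariate correlation is
  modeled — the source table reports only marginals.
* **Gestational ages** are integer days internally. The scan GA follows a
  discretized Laplace law centred on 246 days (median 35.1 weeks, IQR about
  ±1 day, range 238–258) reflecting how concentrated routine 35-week scans
  are; delivery GA is a truncated normal on 259–294 days (median 40.0
  weeks).
* **Latent percentiles.** A scan probit `z_s ~ N(0,1)` drives the scan-day
  weight `w = m_u(GA) * exp(sex_offset + 0.109 * z_s)` with
  `m_u(246) = 2495 g` growing at 1.0%/day, and a multiplicative fetal-sex
  effect of ±1.8%. The birth probit is `z_b = rho_d * z_s +
  sqrt(1 - rho_d^2) * eps` — a Gaussian copula whose correlation decays with
  the scan-to-delivery interval `d` days as
  `rho_d = rho * exp(-drift * d / 7)`; defaults `rho = 0.96`,
  `drift = 0.08`/week were chosen once so the interval-stratified AUC spans
  roughly 0.94 (1-week interval) down to 0.80 (6 weeks), the published
  range for this design. Birthweight is
  `m_b(GA) * exp(sex_offset + 0.117 * z_b)` with a quadratic median curve
  through 3310 g at 280 days.
* **Biometry synthesis** inverts the EFW formula: a reference quadruple at
  the scan GA receives seed-reproducible 2% lognormal jitter on the
  measurement ratios, then a common scale factor is solved (closed-form
  quadratic for the Hadlock log10 forms, bracketed root otherwise) so the
  four-parameter Hadlock EFW reproduces the latent scan weight exactly. The
  same quadruple fed to the other formulas yields realistically discordant
  EFWs (Stirnemann ≈ 3% lower at the median, ~2.6% extra log-SD from jitter
  propagation), which is how formula choice enters the standard comparison.
* **Outcomes.** APO component flags are Bernoulli draws whose base rates
  (defaults derived from the published marginals) are multiplied by a
  per-component relative risk (defaults 2.1–3.9, matching the published
  SGA-vs-rest contingency) when the latent birth percentile is below 10.
  The any-APO flag is the union of the five components; SGA itself is never
  an APO. A config switch controls whether any-APO *reporting* additionally
  drops SGA deliveries from the denominator (default: it does not — the
  exclusion is in the event definition only, which is the more natural
  reading of the source table's footnote).

What the generator does **not** emulate: covariate–weight correlations
(maternal height etc. are independent of the latent percentile, so
customization acts as pure noise and the customized standards' AUC penalty
is smaller here than in real cohorts), correlated APO components (the
printed any-APO total implies component overlap beyond independence, so the
simulated any-APO rate is ~7.5–8% against the published 6.7%), ultrasound
operator/machine effects beyond the single jitter term, and pathology
(Doppler, early FGR, preterm delivery). Passing tests therefore demonstrate
the pipeline's correctness and calibration machinery, not clinical
performance on real populations.

## Calibration of the bundled standards

The six standard parameter files are *synthetic calibrated stand-ins* (their
`provenance` field says so): the original publications' coefficient tables
are not reproduced; instead each file is fit so that the tuned synthetic
cohort reproduces the published P10/P50/P90 of that standard's percentile
distribution (e.g. 2.7/37.6/89.9 for the FMF standard — strongly
left-shifted — against 11.9/52.6/93.3 for the local non-customized
standard). The fit is semi-empirical and deterministic:

1. a 200 000-draw sample of log-EFW offsets around the population median is
   generated (latent spread, sex effect, jitter propagated through the
   standard's own formula, and — for customized standards — the covariate
   adjustment noise);
2. its P10/P50/P90 and the three target percentiles pin down the three
   shifted-log parameters in closed form (a bracketed root for the shift,
   then dispersion and scale explicitly);
3. for the quantile grid, the three probit anchor heights are adjusted by a
   root solve so that the *interpolated* percentile — not merely the grid
   construction — hits the targets.

`scripts/build_parameter_files.py` regenerates the shipped files
byte-for-byte. The customized standards' fetal-sex effect is completed at
build time as ± the sex fraction of the fitted base term weight, so the
additive adjustment cancels the generator's multiplicative sex effect to
first order.

The SGA gold standard uses a bundled *synthetic* birthweight reference grid
(sex-specific P10 weights on a weekly 259–294-day grid, linearly
interpolated): the P10 row is placed so that the fraction of the reference
population strictly below it is 9.4%, emulating an external national
reference whose 10th percentile cuts slightly under 10% of this cohort.
Classification is strictly "below" — a birthweight exactly at the
interpolated P10 is not SGA, and the same strict-< rule is used for EPW<10
screening positivity.

## Statistics

* **AUC**: midrank (tie-aware) Mann–Whitney statistic, scores negated so
  that low percentile = SGA-like gives AUC > 0.5; variance by the DeLong
  structural-components estimator, 95% Wald CI clamped to [0, 1]. The paired
  DeLong test uses the covariance of the per-record structural components; a
  standard compared with itself returns p = 1 exactly.
* **Sensitivity at fixed FPR**: the threshold is the largest candidate EPW
  cut whose realized FPR does not exceed the target (conservative tie
  policy; the realized FPR is reported alongside), with a sentinel above all
  observations so a 100% target returns 100% sensitivity. CIs are Wilson
  score intervals by default (Wald available); the choice is a convention —
  the original analysis does not name its method.
* **Two-proportion test**: pooled-variance two-sided z, continuity
  correction off by default. **Logistic OR**: Newton ML fit (tolerance 1e-8,
  ≤100 iterations) of outcome on EPW percentile; OR per +1 percentile with
  Wald CI; complete separation raises a named error rather than returning a
  divergent estimate.
* **Interval strata**: closed integer-day buckets 8–14, 15–21, 22–28, 29–35,
  36–42, 43–49; intervals of 1–7 or ≥50 days have no bucket and are excluded
  from the stratified analysis. A stratum with one outcome class is reported
  not-evaluable instead of raising. No multiple-testing correction is
  applied to the pairwise matrices, matching the raw-p convention of the
  design being reproduced.
* Table percentages are rounded half-up to one decimal.

## Problem sizes and seeds

The default cohort is n = 9585 (the published cohort size); the test suite
uses 800–9585-record cohorts, five seeds for the AUC-band and
interval-trend checks, 500 null replicates of n = 2000 for the DeLong
type-I-error calibration, and B = 20000 stratified bootstrap replicates for
the small-sample paired-test cross-check. All randomness flows from
`numpy.random.default_rng`; the pipeline derives a named substream per stage
from the single run seed, so partial re-runs are stage-reproducible.

## Known limitations

* Calibration anchors are summary percentiles, so the bundled standards
  reproduce location/spread/skew of each percentile scale but not any
  GA-interaction the original coefficient tables may encode beyond the
  shared growth-rate shape.
* The customized-standard AUC penalty is attenuated (see above); direction,
  not magnitude, is the reproducible claim here.
* The published hospital cohort's exact AUC/sensitivity values are not
  reproducible from summaries alone; the pipeline targets the documented
  qualitative bands (all-standard AUC within [0.78, 0.92]; AUC decreasing
  with interval) and the exactly recomputable contingency arithmetic.
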