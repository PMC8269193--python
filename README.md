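# epwscreen

Screening for late-onset small-for-gestational-age (SGA) birth from a
35-week ultrasound: a reusable pipeline that compares six fetal growth
standards on their ability to predict SGA and adverse perinatal outcomes
(APOs), together with a synthetic perinatal cohort generator that stands in
for hospital data.

## The problem

A third-trimester growth scan produces an estimated fetal weight (EFW) from
biometry — biparietal diameter (BPD), head circumference (HC), abdominal
circumference (AC), femur length (FL) — via regression formulas such as
Hadlock's log10-linear models or the Stirnemann HC+AC model. A *growth
standard* converts that EFW at the scan gestational age (GA) into an
estimated percentile weight (EPW), optionally customized to maternal
characteristics and fetal sex (Gardosi methodology). Screening performance is
then a question of how well a low EPW at ~35 weeks predicts a birthweight
below the 10th percentile at term delivery, and how that ability decays with
the ultrasound-to-delivery interval.

The package implements three standard parameterization families —

* **z-score curve**: `z = T(w / m(GA)) / sigma` for a median curve `m` and a
  declared transform `T` (identity, log, or a skew-capable shifted log),
  percentile = `100 * Phi(z)`;
* **customized**: expected weight `(base + sum of covariate effects) *
  proportionality(GA)` as the individualized center of the same z-score map;
* **quantile grid**: weights tabulated at the 5/10/25/50/75/90/95th
  percentiles on a weekly GA grid, interpolated linearly in GA and on the
  probit scale in weight

— and the full statistical battery: tie-aware AUC with DeLong variance and
the paired DeLong test, sensitivity (detection rate) at 5/10/15/20% false
positive rates with the realized threshold percentile, pooled two-proportion
z-tests, logistic odds ratios per 1% of EPW, APO detection by EPW < 10, and
the week-by-week interval-stratified subanalysis.

Six standards are bundled: a local hospital standard in non-customized and
customized forms, a Barcelona-style customized standard, INTERGROWTH-21st
(on the Stirnemann EFW), the WHO quantile grid, and the Fetal Medicine
Foundation model (on the three-parameter Hadlock EFW). Their parameter files
are synthetic calibrated stand-ins — fit so the tuned synthetic cohort
reproduces each standard's published P10/P50/P90 percentile row — not
transcriptions of the original coefficient tables; see `docs/methods.md`.

## Worked example

```python
from epwscreen import (
    CohortConfig, generate_frame, load_default_standards, load_reference,
    epw_table, screen_eval,
)
from epwscreen.outcomes import outcome_frame

frame = generate_frame(CohortConfig(seed=1))          # 9585 pregnancies
epw = epw_table(frame, load_default_standards())      # EFW + percentile per standard
sga = outcome_frame(frame, load_reference())["sga"]   # SGA at birth (<P10)

ev = screen_eval(epw["pct_fmf"], sga, standard_id="fmf")
print(f"SGA rate {100 * sga.mean():.1f}%  AUC {ev.auc:.2f} "
      f"({ev.auc_ci[0]:.2f}-{ev.auc_ci[1]:.2f})")
fpr10 = ev.by_fpr[1]
print(f"detection at 10% FPR: {fpr10.sensitivity:.1f}% "
      f"(threshold percentile {fpr10.threshold_percentile:.1f})")
```

prints

```
SGA rate 9.7%  AUC 0.84 (0.83-0.85)
detection at 10% FPR: 53.7% (threshold percentile 4.9)
```

i.e. on this simulated cohort 9.7% of newborns are SGA; ranking pregnancies
by the FMF percentile separates SGA from non-SGA deliveries with AUC 0.84,
and flagging every fetus below the 4.9th FMF percentile detects 54% of the
SGA births while screen-flagging 10% of the non-SGA ones.

The same pipeline runs from the shell:

```bash
epwscreen simulate --seed 17 --n 9585 --out cohort.csv
epwscreen evaluate --cohort cohort.csv --fprs 5,10,15,20 --out results/
epwscreen run-all --seed 17 --out results/     # simulate + evaluate in one go
```

`results/` then holds the cohort snapshot, per-standard EPW table, a results
JSON, CSV analogues of the five report tables, and a manifest with seed and
artifact hashes; a rerun with the same seed reproduces every artifact
byte-for-byte.

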