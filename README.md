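# ctdna-monitor

Tools for monitoring metastatic breast cancer with longitudinal circulating
tumour DNA (ctDNA). Shallow whole-genome sequencing of plasma cell-free DNA
yields a **tumour fraction** estimate per blood draw; tracked over time,
these fractions carry real-time information about treatment response that a
3-monthly CT scan only reveals later. This package implements, as a tested
and reusable pipeline, the full analytic chain around such data:

1. **Cohort model** — long-format tables of patients (ER/Her2 status),
   treatment intervals, plasma samples (tumour fraction, optional CA15-3 and
   targeted-panel max-VAF) and CT scans with RECIST progression flags, all on
   a per-patient day axis with day zero at the first CT scan.
2. **Tumour-burden metrics** from 1-Mb binned copy-number profiles:
   panel-of-normals normalization, read-count/noise QC, the genome-wide
   z-score, t-MAD, the multi-solution selection rule for tumour-fraction HMM
   output, and the arcsine transform `arcsin(sqrt(tf))`.
3. **Threshold discovery** — time-dependent Cox models of progression-free
   and overall survival in counting-process form with the percent score
   carried forward between draws; the score enters through a restricted
   cubic spline, a two-slope segmented regression of the fitted log-hazard
   locates the changepoint, and repeating this over random 70-patient
   subsamples yields a working risk threshold (rounded up to a whole
   percent) that is validated on the held-out patients.
4. **Stopping rule** — a deterministic rule predicting the next CT result
   from the latest tumour fraction: below the threshold (or above it but
   falling) predicts response; at/above it and not falling predicts
   progression. Scored against RECIST with sensitivity/specificity and
   lead times.
5. **BAY-ML** — a two-stage Bayesian model: a linear random-slopes-and-
   intercepts model of the arcsine-scale ctDNA trajectory
   (`y_i(s) = X1 b1 + b_i0 + b_i1 s + e`), whose per-patient posterior-mean
   random effects feed a random-intercept logistic model of progressive
   disease, `logit P(PD) = X2 b2 + u_i + gamma' bhat_i`. Temporal validation
   holds out each patient's last scan; the ROC is compared with a
   covariates-only ablation.
6. **Concordance** — interpolation-based per-patient correlations and
   threshold-concordance rates across tumour fraction, CA15-3 and max-VAF,
   plus a discordance audit that checks whether high ctDNA with a stable
   scan anticipated progression on the *next* scan (early detection, with
   lead time in months).

A synthetic-cohort generator reproduces the statistical structure the
analyses assume (random-effects trajectories, logistic PD outcomes linked
through the true random effects, class-dependent sampling cadences, hazard
models with a known threshold), so every stage is testable without any
external data.

## Worked example

```python
from ctdna_monitor import (SimConfig, simulate_cohort, simulate_threshold_cohort,
                           discover_threshold, select_decision_points,
                           evaluate_stopping_rule)
from ctdna_monitor.bayml import SamplerConfig, temporal_validation

cohort, truth = simulate_cohort(SimConfig(n_patients=143, seed=7))
thr_cohort = simulate_threshold_cohort(n_patients=150, break_tf=0.10, seed=7)
disc = discover_threshold(thr_cohort, n_train=70, reps=50, seed=7)
points = select_decision_points(cohort)
tm = evaluate_stopping_rule(points, threshold=0.07)
val = temporal_validation(cohort, SamplerConfig(seed=7))
```

prints (via the obvious f-strings):

```
cohort: 143 patients, 1335 plasma samples, 1042 CT scans
mean changepoint: 8.97% -> threshold 9%
held-out: mean HR 13.48, median c-index 0.74
stopping rule: 513 decision points, sensitivity 0.37, specificity 0.71
BAY-ML temporal validation: AUROC 0.62 with ctDNA vs 0.64 without; sensitivity 0.49 at 66% specificity
```

Reading the numbers: the discovery cohort was simulated with a hazard-slope
break at a 10% tumour fraction, and the resampled spline-Cox/segmented
procedure recovers a mean changepoint of 8.97% (the segmented fit of a
smooth spline places the break slightly early), rounding up to a 9% working
threshold; patients above it progress markedly faster on held-out data. On
the monitoring cohort the simple stopping rule trades sensitivity for
specificity, and the Bayesian model's gain from ctDNA depends on how
strongly the simulated progression outcomes load on the trajectory random
effects (moderate under the default generator, hence the overlapping AUROCs
at this seed).

## Command line

```sh
ctdna-monitor simulate --n-patients 143 --seed 17 --out cohort/
ctdna-monitor read --clinical clin.csv --scans ct.csv --samples ichor.csv \
                   --treatments trt.csv --config dialect.cfg --out cohort/
ctdna-monitor metrics --sample s.bed --panel p.bed --metric zscore --mode absolute
ctdna-monitor threshold --cohort cohort/ --reps 50 --ntrain 70 --seed 7 --out thr.json
ctdna-monitor stopping-rule --cohort cohort/ --threshold 0.07 --out tm.json
ctdna-monitor bayml validate --cohort cohort/ --chains 6 --steps 3000 --seed 11 --out bay/
ctdna-monitor concordance --cohort cohort/ --out conc.json
```

Input tables are plain CSV/TSV; a `key = value` column-mapping config adapts
foreign column names, and times may be integer day offsets or calendar dates.

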