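# ernlab

Analysis pipeline for EEG performance monitoring in the speeded arrow
flanker task: single-trial (rERP) robust regression of error-related brain
activity, post-error behavioural statistics, and multivariate gender
decoding from error-weight scalp maps — driven by a calibrated synthetic
cohort generator.

## Who this is for

Cognitive-neurophysiology researchers who study error processing (the
error-related negativity, ERN, and error positivity, Pe) and post-error
behavioural adjustment, and who want a tested, seedable reference
implementation of the full two-level analysis chain. Because large flanker
EEG cohorts are rarely shareable, the package ships a generator that
emulates one: 1080-trial counterbalanced sessions, ~14.3% errors, a 16 ms
male RT advantage, a 62 ms congruency cost (5 ms larger in women), 20 ms
higher female post-error slowing (PES), ERN/Pe components at Cz (64 ms /
226 ms) with a male ERN-amplitude advantage of Cohen's d ≈ 0.60, 10.5 ms
single-trial latency jitter, and negative within-subject coupling between
single-trial ERN amplitude and the next trial's RT.

## The models at the core

**Behaviour.** Per subject: standard PES = mean RT(correct post-error) −
mean RT(correct flanked by correct); pre-error and RT-normalized variants;
post-error accuracy change (PIA); congruency effect = RT(incongruent) −
RT(congruent) on correct trials. Group inference uses OLS on z-scored
variables with 99.9% CIs and Bonferroni correction (family m = 14), Grubbs
screening of subjects, and Bartlett tests on log-RT variances.

**First level (within subject).** At every electrode × timepoint t of the
response-locked, baselined (−250..−150 ms), 10 ms-smoothed epochs:

    y_i(e,t) = Xβ(e,t) + ε,   X = [1, error, congruency, distance,
                                   z(log RT), hand, RSI, next RSI]

fitted by iteratively reweighted least squares with the Tukey bisquare
weight (c = 4.685, MAD scale). The output is the SE-scaled weight
b/SE(b) — a t-like statistic comparable across subjects. Epochs are first
screened by a probability criterion (z > 4 of the mean per-channel Gaussian
log-likelihood) with an adaptive threshold capping rejections at 5% per
condition.

**Second level (across subjects).** Robust regression of first-level
error weights on z-scored sex, age, and error count (optionally mean RT),
with peak tests at locations fixed by the independent grand error-weight
map, pooled-SD Cohen's d, and a p ≤ 3.3 × 10⁻⁵ display mask.

**Decoding.** Linear SVM (C = 1) on subject × electrode error-weight maps:
classes balanced by subsampling, features min–max scaled to [−1, 1],
Monte-Carlo stratified 90/10 cross-validation (500 splits), permutation
inference (p = max(count, 1)/n_perm), and a three-variant electrode
searchlight (singleton / contralateral pair / 7-nearest-neighbour cluster).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from ernlab.config import CohortConfig
from ernlab.cohort import simulate_cohort_behavior
from ernlab import behavior as beh

cfg = CohortConfig(n_female=60, n_male=60, seed=7)
trials = simulate_cohort_behavior(cfg)          # 129,600 trials
summaries = beh.summarize_subjects(trials)      # filter + per-subject stats
print(summaries.groupby("sex")[["mean_rt_correct", "pes_standard",
                                "congruency_effect"]].mean().round(1))
report = beh.behavioral_regression(summaries, "mean_rt_correct",
                                   ["sex", "age", "n_errors"],
                                   family_size=14)
print(report.table.round(4).to_string(index=False))
```

prints

```
        mean_rt_correct  pes_standard  congruency_effect
sex
female            411.8          67.7               64.1
male              396.9          46.8               59.9
predictor       b  ci_low  ci_high  p_raw  p_bonferroni
intercept -0.0000 -0.2914   0.2914 1.0000        1.0000
      sex  0.3818  0.0637   0.6999 0.0001        0.0013
      age  0.1177 -0.2015   0.4368 0.2158        1.0000
 n_errors  0.0549 -0.2393   0.3491 0.5299        1.0000
```

Women respond ~15 ms slower on correct trials and slow down ~21 ms more
after errors; the standardized sex coefficient (b = 0.38, 99.9% CI shown,
Bonferroni-corrected p) confirms the RT difference beyond age and error
count even in this 120-subject cohort.

The same stages run from the shell:

```bash
ernlab simulate --n-female 10 --n-male 10 --seed 5 --out run/
ernlab behavior --trials run/trials.tsv --out run/
# full chain incl. EEG simulation, first/second level, decoding
ernlab run-all --seed 5 --n-female 12 --n-male 12 --out run-all/
```

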