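# Methods

`ernlab` implements a complete analysis chain for performance-monitoring EEG
in a speeded arrow flanker task — behavioural post-error statistics,
two-level single-trial robust regression of response-locked EEG, and
multivariate gender decoding — together with a synthetic cohort generator
calibrated to the group-level descriptives of a large (874-subject) flanker
study. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## The synthetic cohort

### Task structure

Each simulated session holds `n_trials` (default 1080) trials crossing
congruency (congruent/incongruent), flanker–target distance (close/far) and
response–stimulus interval (short/long). The 2×2×2 cells are exactly
balanced (`n_trials/8` each, hence every pairwise margin `n_trials/4`) and
shuffled pseudorandomly under the subject seed; `n_trials` must be divisible
by 8.

### Behaviour

Reaction times follow a shifted lognormal: the per-trial location is

    mu = baseline + (congruency ± cost/2) + PES·[post-error] + shift_err·[error]

and `rt = 200 + (mu − 200)·exp(σz − σ²/2)` with `z ~ N(0,1)`, so the noise
is multiplicative (reproducing the strong mean–SD correlation of real RT
data) while `E[rt] = mu`. σ is set per sex so the within-subject SD equals
`rt_within_sd` (60 ms) at the group-mean RT.

Key calibration choices:

* `rt_mean_male`/`rt_mean_female` (400/416 ms) are **marginal** means over
  correct, non-error-adjacent trials; the congruency cost is split ±cost/2
  around them, and the 5 ms female surplus likewise ±2.5 ms. This keeps the
  16 ms sex difference, the 62 ms grand-mean congruency cost and the 5 ms
  cost difference simultaneously exact in expectation.
* `rt_between_sd` = 20 ms. No between-subject SD is printed anywhere, but a
  standardized sex coefficient of b ≈ 0.42 for a 16 ms raw difference with a
  balanced binary predictor implies SD ≈ 16·0.5/0.42 ≈ 19 ms.
* Subject baselines are drawn by **stratified quantile sampling**
  (Latin-hypercube style) within each sex group: the cohort-level mean of
  the baselines then matches the configured value to O(1/n) instead of
  O(sd/√n), while each subject's marginal distribution is the same normal.
  A calibrated cohort generator should reproduce its configured group
  contrasts at realistic cohort sizes; iid baseline noise would only blur
  them with variance no analysis stage can remove.
* Errors are Bernoulli with a logistic model in congruency (+2.0 log-odds)
  and distance (+0.3 log-odds, far = more conflict); the intercept is solved
  by 1-D root finding so the marginal over the four cells equals
  `error_rate_target` (0.143). Post-error slowing (47.6/67.6 ms male/female)
  is added to every trial following an error; errors themselves are 80 ms
  fast (premature responses).
* 2% of trials are flagged multi-response and 1% given out-of-band RTs
  (<100 or >1000 ms) to exercise the filters; both are bookkept in an extra
  column so tests can verify the filter removes exactly the injected trials.
* Ages are sex-specific normals (male 25.5 ± 3.6, female 22.9 ± 3.7,
  clipped to 18–40) so age can serve as a second-level covariate.

### EEG epochs

Epochs are generated directly response-locked over −300..+600 ms at 500 Hz
(all in-scope analyses are response-locked; simulating a long
stimulus-locked record and re-epoching would only cost memory). Each epoch
is a sum of temporal Gaussian components times scalp topographies plus
noise:

* **ERN**: negative Gaussian bump, peak 64 ms, SD 22 ms, topography a
  spatial Gaussian centred at Cz (width 0.45 on the unit sphere). Its
  amplitude on error trials is `uV_per_weight · (s + d_i)` where `s` is the
  subject's error-effect level drawn from the sex-specific normal
  (female −6.9 ± 3.6, male −9.3 ± 4.4, in SE-scaled-weight units) and `d_i`
  is single-trial variability (SD 2).
* **Pe**: positive bump at 226 ms, SD 45 ms, broader Cz-centred topography
  (width 0.7), error-modulated, no sex effect.
* **Conflict**: a separate early bump at 34 ms (SD 18 ms) scaled by the
  far-distance indicator — kept distinct from the ERN kernel because the
  conflict modulation has its own, earlier peak.
* All three kernels share a per-trial latency jitter, N(0, 10.5 ms).
* Noise: spatially correlated AR(1) (lag-1 coefficient 0.95, stationary SD
  6 µV, spatial correlation `exp(−d²/2·0.6²)` on the unit sphere) plus 2 µV
  white noise. Epochs are stored float32; all fitting is float64.

Topographies are radially symmetric about the vertex; the
fronto-central/centro-parietal distinction of real ERN/Pe maps is
approximated only through kernel width. This is adequate for peak-finding
and decoding tests but not for fine topographic comparisons.

**ERN→behaviour coupling.** On each error trial the next trial's RT
*location* receives `coupling_coeff · uV_per_weight · d_i` (default −3 ms/µV
times the trial's amplitude deviation from the subject mean) before the
multiplicative RT noise is re-applied — the generator stores the location
and noise factor separately, so the increment genuinely enters ahead of the
noise. More-negative single-trial ERNs thus produce slower next-trial
responses within subjects, while between-subject ERN level and PES remain
uncoupled.

**Weight-map shortcut.** `simulate_subject_weight_maps` emits per-subject
electrode vectors (sex-scalar × Cz topography + electrode noise, SD 0.8)
for fast large-n decoding tests without any EEG simulation. With the
default parameters the pooled-SD effect size at Cz is
2.4/√((3.6²+0.8² + 4.4²+0.8²)/2) ≈ 0.59. An optional `distributed_signal_sd`
knob adds a non-topographic multivariate sex signal; it defaults to 0
because the printed univariate summaries do not constrain it, and no test
asserts a multivariate accuracy above the univariate bound.

## Behavioural analyses

* **Filtering**: keep 100 ≤ RT ≤ 1000 ms (inclusive) and single-response
  trials. Post-/pre-error adjacency is always evaluated on the *original*
  sequence; filtering removes trials from averages but never re-links
  neighbours. Session-boundary trials are excluded from baseline and
  post-error sets (their adjacency is undefined).
* **PES**: standard = mean correct post-error RT − mean RT of correct trials
  flanked by correct trials; pre-error variant = mean of RT(e+1) − RT(e−1)
  over errors with both neighbours correct and retained; normalized =
  standard / flanked-correct baseline. Subjects without a qualifying error
  get a missing PES and drop out of PES models only (counted in the logs).
* **Mean correct RT** is the flanked-correct mean (neither following nor
  preceding an error), which keeps the sex contrast clean of post-error
  effects.
* **Group regressions**: OLS on z-scored variables (binary sex coded
  female = 1 before z-scoring, so a positive RT coefficient means slower
  females), 99.9% CIs from the t distribution, Bonferroni correction with
  family size m = 14 by default. Both outcome-z-scored and raw-outcome
  variants exist; z-all is the default (the reported coefficient magnitudes
  are compatible with either at the tolerances used).
* **Grubbs screening** (subject exclusion): iterative, one-sided *upper* by
  default — the screen targets too-high proportions of missed/multi-response
  trials — with critical value ((n−1)/√n)·√(t²/(n−2+t²)), t = t(1−α/n, n−2).
  The one-sided test holds the per-dataset false-alarm rate at α (verified
  by null simulation); a two-sided variant (α/2 per tail) is available.
* **Variance analyses**: per-subject SD of log RT (RTs are log-transformed
  before variance comparisons), group regression of those SDs, and
  Bartlett's χ² for across-group variance equality.

## First-level EEG regression

Per subject, in order: align epochs to retained trials → adaptive rejection
→ baseline correction (−250..−150 ms) → 10 ms running average → bisquare
IRLS at every electrode × timepoint.

* **Rejection**: each epoch is scored by its mean Gaussian negative
  log-likelihood under per-channel amplitude distributions pooled over all
  epochs; scores are z-scored and epochs above 4 SD rejected. If either
  condition (error/correct) would lose more than 5%, the threshold is
  raised by binary search until the cap holds; the used threshold and
  counts are logged. At least 20 epochs per condition are required.
* **Design**: intercept, error (0/1), congruency, distance, z-scored log RT
  (z after log), response hand, current RSI, next-trial RSI. The final
  trial of a session (undefined next-RSI) is dropped. Error is coded 0/1
  with an explicit intercept so the error weight is negative at ERN
  latency.
* **Robust fit**: Tukey bisquare, c = 4.685, working scale = normalized MAD
  of the residuals, max 50 iterations, convergence when the largest
  coefficient change is < 1e−6 relative. The fit is vectorized across all
  electrode × timepoint cells (normal equations assembled with one GEMM per
  iteration; converged cells leave the active set). Non-converged cells
  become NaN and are counted, not fatal.
* **Scaled weights**: coefficient / SE with SE = biweight-midvariance scale
  of the final residuals × √diag((X'X)⁻¹). The psi-based sandwich SE is
  asymptotically ≈ 2.6% larger than the OLS SE on clean Gaussian data
  (bisquare's 95% efficiency), which would break the intended
  robust-equals-OLS-on-clean-data property; the biweight-midvariance scale
  is an unbiased, outlier-resistant estimate of σ, so scaled weights match
  OLS t-statistics on clean data (mean discrepancy under 1% in simulation)
  and still resist contaminated trials.
* **Coupling model**: on error trials with a retained following response,
  z-scored next-trial RT is robustly regressed on the z-scored EEG
  amplitude at each cell plus next-trial congruency, RSI and distance
  (Frisch–Waugh-style per-cell designs, fitted with the same batched IRLS);
  the standardized amplitude coefficient is returned. At least 10 usable
  error trials are required. Note the generator ties the coupling to the
  ERN component, so the simulated coupling peak sits at the ERN latency.
* **Peaks**: global signed extrema with ties broken by earliest latency,
  then electrode-label order. Single-trial latencies are argmin positions
  in a ±30 ms window around a component peak at one electrode; their
  per-subject SD feeds the latency-variance comparison.

Smoothing is applied before the first-level fit only; second-level analyses
use the first-level maps as-is.

## Second level and decoding

* **Group model**: bisquare IRLS of the stacked first-level scaled weights
  on z-scored sex, age, error count (optionally mean RT) at every cell;
  t = b/SE with df = n − p − 1, two-sided p.
* **Peak tests** follow the two-stage logic: the tested location comes from
  an independent localizing contrast (the grand error-regressor map), never
  from the tested predictor's own map. Reports include group means/SDs and
  Cohen's d with equal-weight pooled SD, d = (m₁−m₂)/√((s₁²+s₂²)/2).
* **Mask**: p ≤ 3.3e−5 per point, kept as an opaque constant (its
  multiple-comparison family is not derivable from the printed material).
* **Decoding**: subsample to equal classes (seeded), one global min–max map
  to [−1, 1], linear SVM with C = 1, Monte-Carlo stratified 90/10 CV
  (500 splits), permutation test with max(count,1)/n_perm convention
  (15000 permutations reproduce p = 6.67e−5 when never exceeded;
  permutations reuse a reduced split count, logged). Searchlight: per
  electrode the average of three 50-fold CV accuracies — singleton,
  electrode + contralateral partner (midline electrodes self-pair), and
  electrode + 7 nearest neighbours, equal weights. Eye channels are not
  part of the montage.
* Class re-subsampling happens once per decoding run (not per fold),
  seeded.

## Montage

Built at run time from the MNE standard 10-20 template: a 60-channel
extended 10-20 scalp set (default) and a 32-channel subset for desk-scale
EEG runs, both normalized to the unit sphere and writable as TSV.
Contralateral pairing parses the 10-20 label convention (odd ↔ even trailing
digit; 'z' labels self-pair).

## Problem sizes and tolerances

The packaged checks run at desk scale by design: behavioural recovery uses
the full 874-subject cohort (behaviour only, seconds); EEG recovery uses 24
subjects × 32 electrodes × 450 timepoints at 500 Hz through the complete
first level (minutes); decoding calibration uses the weight-map shortcut
with ~100–200 permutations of a reduced-split CV. Monte-Carlo assertions
use ±15% bands or ±2 SE; exact assertions (counterbalancing, PES toys,
worked examples from printed group summaries) are exact.

## Known limitations

* Radially symmetric topographies and a single dipole-free spatial model;
  no ocular or muscle artifact classes (the rejection stage is exercised
  with synthetic amplitude contamination instead).
* The generator's decoding ceiling is essentially the univariate bound
  implied by the configured d at one topography — distributed multivariate
  structure beyond that exists only via the optional knob, which is off by
  default. Passing decoding tests therefore demonstrate calibration and
  inference correctness, not real-data accuracy levels.
* Error generation is independent across trials (no streaks/fatigue), and
  the speed–accuracy coupling across subjects is not modelled.
* Epoch rejection scores epochs under an independent-Gaussian amplitude
  model; real joint-probability criteria weight channel covariance
  differently.
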