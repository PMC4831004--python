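"""Configuration objects for the synthetic cohort and the analysis pipeline.

All tunable quantities of the generator and of the analysis stages live here,
with units in the field names or docstrings.  Configs round-trip through YAML
and carry the master seed so every run is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class CohortConfig:
    """Parameters of the simulated flanker-task cohort.

    Behavioural defaults reproduce the group-level descriptives of a large
    (874-subject) flanker study: a 16 ms male RT advantage, a 62 ms congruency
    cost that is 5 ms larger in women, post-error slowing of 47.6 ms (men) /
    67.6 ms (women), and a ~14.3% marginal error rate.  EEG defaults place a
    negative error-related component (ERN) at Cz 64 ms and a positive one (Pe)
    at Cz 226 ms, with a male amplitude advantage of Cohen's d ~ 0.60 in
    scaled-weight units.
    """

    n_female: int = 438
    n_male: int = 436
    n_trials: int = 1080
    sampling_rate: float = 500.0  # Hz
    epoch_window: tuple = (-300.0, 600.0)  # ms, response-locked
    montage: str = "standard-60"  # builtin name or path to a montage TSV

    # --- reaction times (ms). rt_mean_* are MARGINAL means over correct
    # trials that are not adjacent to errors; the congruency cost is applied
    # symmetrically (+-cost/2) around them so the marginal is preserved.
    rt_mean_male: float = 400.0
    rt_mean_female: float = 416.0
    rt_between_sd: float = 20.0  # between-subject SD of the baseline
    rt_within_sd: float = 60.0   # within-subject SD at the group-mean RT
    rt_shift: float = 200.0      # shift of the shifted-lognormal RT model
    congruency_cost: float = 62.0
    congruency_cost_female_extra: float = 5.0
    pes_male: float = 47.6
    pes_female: float = 67.6
    error_rt_shift: float = -80.0  # errors are fast (premature) responses

    # --- error generation (logistic in congruency and distance)
    error_rate_target: float = 0.143
    error_congruency_logodds: float = 2.0  # incongruent vs congruent
    error_distance_logodds: float = 0.3    # far vs close (more conflict)

    # --- contamination injected to exercise the trial filters
    multi_response_fraction: float = 0.02
    rt_out_of_range_fraction: float = 0.01

    # --- EEG components (amplitudes in scaled-weight units unless noted)
    ern_peak_ms: float = 64.0
    ern_width_ms: float = 22.0  # Gaussian SD of the temporal kernel
    pe_peak_ms: float = 226.0
    pe_width_ms: float = 45.0
    ern_error_effect_female_mean: float = -6.9
    ern_error_effect_female_sd: float = 3.6
    ern_error_effect_male_mean: float = -9.3
    ern_error_effect_male_sd: float = 4.4
    ern_trial_amp_sd: float = 2.0   # single-trial amplitude variability (errors)
    ern_uv_per_weight: float = 1.0  # uV per scaled-weight unit (calibration)
    pe_error_effect_mean: float = 8.0
    pe_error_effect_sd: float = 3.0
    conflict_peak_ms: float = 34.0
    conflict_width_ms: float = 18.0
    conflict_effect: float = -2.5   # far-distance modulation, uV
    ern_topo_width: float = 0.45    # spatial Gaussian width on the unit sphere
    pe_topo_width: float = 0.70
    latency_jitter_sd: float = 10.5  # ms, single-trial component jitter

    # --- ERN -> next-trial RT coupling (ms per uV amplitude deviation)
    coupling_coeff: float = -3.0

    # --- noise model
    noise_white_sd: float = 2.0   # uV
    noise_ar_sd: float = 6.0      # uV, stationary SD of the AR(1) part
    noise_ar_coeff: float = 0.95
    noise_spatial_scale: float = 0.6  # correlation length on the unit sphere

    # --- subject-level covariates
    age_mean_male: float = 25.5
    age_sd_male: float = 3.6
    age_mean_female: float = 22.9
    age_sd_female: float = 3.7

    # --- shortcut weight-map generator
    weight_map_noise_sd: float = 0.8
    distributed_signal_sd: float = 0.0  # optional extra multivariate signal

    seed: int = 0

    def __post_init__(self):
        if isinstance(self.epoch_window, list):
            self.epoch_window = tuple(self.epoch_window)
        for name in ("n_female", "n_male", "n_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.error_rate_target < 1:
            raise ValueError("error_rate_target must lie in (0, 1)")
        lo, hi = self.epoch_window
        if not (lo < self.ern_peak_ms < hi and lo < self.pe_peak_ms < hi):
            raise ValueError("epoch_window must span both component peaks")
        for f in dataclasses.fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def sigma_log(self, sex: str) -> float:
        """Lognormal sigma reproducing rt_within_sd at the sex-mean RT."""
        import numpy as np

        mu = self.rt_mean_male if sex == "male" else self.rt_mean_female
        rel = self.rt_within_sd / (mu - self.rt_shift)
        return float(np.sqrt(np.log1p(rel**2)))


@dataclass
class AnalysisConfig:
    """Parameters of the analysis stages (EEG preprocessing, stats, decoding)."""

    reject_z_threshold: float = 4.0
    reject_max_fraction: float = 0.05
    baseline_window: tuple = (-250.0, -150.0)  # ms
    smooth_halfwidth_ms: float = 5.0  # running average spans 2*halfwidth
    family_size: int = 14             # Bonferroni family for behavioural tests
    mask_alpha: float = 3.3e-5        # per-point significance mask threshold
    cv_splits: int = 500
    test_fraction: float = 0.1
    n_permutations: int = 15000
    permutation_cv_splits: int = 100  # reduced split count inside permutations
    searchlight_splits: int = 50
    svm_c: float = 1.0

    def __post_init__(self):
        if isinstance(self.baseline_window, list):
            self.baseline_window = tuple(self.baseline_window)


@dataclass
class RunConfig:
    """Top-level pipeline configuration: cohort block, analysis block, seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "ernlab-run"
    seed: int = 0


def _asdict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def conv(x):
        if isinstance(x, tuple):
            return list(x)
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        return x

    return conv(d)


def config_to_yaml(cfg, path) -> None:
    Path(path).write_text(yaml.safe_dump(_asdict(cfg), sort_keys=False))


def cohort_config_from_yaml(path) -> CohortConfig:
    return CohortConfig(**yaml.safe_load(Path(path).read_text()))


def run_config_from_yaml(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig(
        cohort=CohortConfig(**raw.get("cohort", {})),
        analysis=AnalysisConfig(**raw.get("analysis", {})),
        out_dir=raw.get("out_dir", "ernlab-run"),
        seed=raw.get("seed", 0),
    )


def config_hash(cfg) -> str:
    """Stable short hash of a config, recorded in output metadata."""
    blob = json.dumps(_asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
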