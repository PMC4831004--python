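"""Synthetic flanker-task cohort: behaviour and single-trial EEG epochs.

The generator emulates the statistical structure the downstream analyses
assume: a counterbalanced 2 (congruency) x 2 (flanker distance) x 2 (RSI)
session; shifted-lognormal RTs with sex-dependent baseline, congruency cost
and post-error slowing; a logistic error model calibrated to a target
marginal error rate; and response-locked epochs containing an error-related
negativity (ERN), an error positivity (Pe), a distance-driven conflict
component, single-trial latency jitter, spatially correlated AR(1) noise,
and a within-subject coupling between single-trial ERN amplitude and the
next trial's RT.

Everything is driven by explicit seeds; identical (config, seed) pairs give
bit-identical outputs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import expit

from .config import CohortConfig
from .containers import EpochSet, TRIAL_COLUMNS
from .montage import Montage, MontageError, load_montage

REQUIRED_MIDLINE = ("FCz", "Cz", "CPz")


class BalanceError(ValueError):
    """Raised when the requested trial count cannot be counterbalanced."""


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trial sequence

def generate_trial_sequence(config: CohortConfig, subject_seed) -> pd.DataFrame:
    """Counterbalanced pseudorandom trial sequence for one session.

    Every congruency x distance x RSI cell holds exactly n_trials/8 trials,
    so each pairwise condition margin holds n_trials/4.
    """
    n = config.n_trials
    if n % 8 != 0:
        raise BalanceError(
            f"n_trials={n} not divisible by 8; condition cells cannot be "
            "counterbalanced"
        )
    rng = as_rng(subject_seed)
    cells = list(itertools.product(("congruent", "incongruent"),
                                   ("close", "far"), ("short", "long")))
    cong, dist, rsi = map(np.array, zip(*(c for c in cells for _ in range(n // 8))))
    order = rng.permutation(n)
    df = pd.DataFrame({
        "trial_index": np.arange(1, n + 1),
        "congruency": cong[order],
        "distance": dist[order],
        "rsi": rsi[order],
    })
    df["next_rsi"] = df["rsi"].shift(-1)
    return df


# ---------------------------------------------------------------------------
# behaviour

def error_intercept(config: CohortConfig) -> float:
    """Logistic intercept such that the marginal error rate over the four
    equally frequent congruency x distance cells equals error_rate_target."""
    bc, bd = config.error_congruency_logodds, config.error_distance_logodds

    def marginal(b0):
        cells = [b0, b0 + bc, b0 + bd, b0 + bc + bd]
        return float(np.mean(expit(cells))) - config.error_rate_target

    return brentq(marginal, -20.0, 10.0)


def error_probabilities(config: CohortConfig, congruency, distance) -> np.ndarray:
    b0 = error_intercept(config)
    eta = (b0
           + config.error_congruency_logodds * (np.asarray(congruency) == "incongruent")
           + config.error_distance_logodds * (np.asarray(distance) == "far"))
    return expit(eta)


def _sex_params(config: CohortConfig, sex: str):
    if sex == "female":
        return dict(
            rt_mean=config.rt_mean_female,
            cost=config.congruency_cost + config.congruency_cost_female_extra / 2.0,
            pes=config.pes_female,
            age_mean=config.age_mean_female, age_sd=config.age_sd_female,
            ern_mean=config.ern_error_effect_female_mean,
            ern_sd=config.ern_error_effect_female_sd,
        )
    if sex == "male":
        return dict(
            rt_mean=config.rt_mean_male,
            cost=config.congruency_cost - config.congruency_cost_female_extra / 2.0,
            pes=config.pes_male,
            age_mean=config.age_mean_male, age_sd=config.age_sd_male,
            ern_mean=config.ern_error_effect_male_mean,
            ern_sd=config.ern_error_effect_male_sd,
        )
    raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")


def simulate_behavior(sequence: pd.DataFrame, config: CohortConfig, sex: str,
                      subject_seed, subject_id: str = "s001",
                      baseline_quantile: float | None = None) -> pd.DataFrame:
    """Simulate accuracy, RTs and response hands for a trial sequence.

    RTs follow a shifted-lognormal model: a deterministic per-trial location
    (subject baseline + congruency term +- cost/2 + post-error increment +
    error shift) times a mean-one lognormal factor.  The location (rt_mu) and
    the noise factor (rt_noise) are kept as columns so later stages can
    modify the location without redrawing the noise.  A small fraction of
    trials is flagged multi_response or given an out-of-range RT to exercise
    the trial filters (bookkept in the rt_contaminated column).
    """
    p = _sex_params(config, sex)
    rng = as_rng(subject_seed)
    n = len(sequence)
    df = sequence.copy()

    if baseline_quantile is None:
        baseline = rng.normal(p["rt_mean"], config.rt_between_sd)
    else:
        # stratified cohort sampling: the caller supplies the quantile
        from scipy.stats import norm
        baseline = p["rt_mean"] + config.rt_between_sd * norm.ppf(
            float(baseline_quantile))
    age = float(np.clip(rng.normal(p["age_mean"], p["age_sd"]), 18, 40))

    probs = error_probabilities(config, df["congruency"], df["distance"])
    is_error = rng.random(n) < probs
    post_error = np.concatenate([[False], is_error[:-1]])

    cong_term = np.where(df["congruency"] == "incongruent",
                         p["cost"] / 2.0, -p["cost"] / 2.0)
    mu = (baseline + cong_term + p["pes"] * post_error
          + config.error_rt_shift * is_error)
    sigma = config.sigma_log(sex)
    noise = np.exp(sigma * rng.standard_normal(n) - sigma**2 / 2.0)
    rt = config.rt_shift + (mu - config.rt_shift) * noise

    target = np.where(rng.random(n) < 0.5, "left", "right")
    flip = {"left": "right", "right": "left"}
    hand = np.where(is_error, [flip[t] for t in target], target)

    u = rng.random(n)
    multi = u < config.multi_response_fraction
    oor = (~multi) & (u < config.multi_response_fraction
                      + config.rt_out_of_range_fraction)
    if oor.any():
        k = int(oor.sum())
        low = rng.uniform(20.0, 95.0, k)
        high = rng.uniform(1005.0, 1400.0, k)
        rt[oor] = np.where(rng.random(k) < 0.5, low, high)

    df["subject_id"] = subject_id
    df["sex"] = sex
    df["age"] = age
    df["response_hand"] = hand
    df["accuracy"] = np.where(is_error, "error", "correct")
    df["rt"] = rt
    df["multi_response"] = multi
    df["rt_mu"] = mu
    df["rt_noise"] = noise
    df["rt_contaminated"] = oor
    return df[TRIAL_COLUMNS + ["rt_mu", "rt_noise", "rt_contaminated"]]


# ---------------------------------------------------------------------------
# EEG epochs

def _check_midline(montage: Montage):
    missing = [l for l in REQUIRED_MIDLINE if l not in montage.labels]
    if missing:
        raise MontageError(
            f"montage missing required midline electrodes: {missing}"
        )


def _gauss_kernel(times: np.ndarray, peaks: np.ndarray, width: float) -> np.ndarray:
    """(n_trials, n_times) Gaussian bumps, one jittered peak per trial."""
    return np.exp(-0.5 * ((times[None, :] - peaks[:, None]) / width) ** 2)


def simulate_epochs(trials: pd.DataFrame, config: CohortConfig, sex: str,
                    subject_seed, montage: Montage | None = None):
    """Simulate response-locked epochs for a behavioural trial table.

    Returns (EpochSet, updated TrialTable): on error trials the next trial's
    RT location receives coupling_coeff times the trial's ERN-amplitude
    deviation from the subject mean, before the (already drawn) multiplicative
    RT noise is re-applied.
    """
    p = _sex_params(config, sex)
    rng = as_rng(subject_seed)
    if montage is None:
        montage = load_montage(config.montage)
    _check_midline(montage)

    n = len(trials)
    dt = 1000.0 / config.sampling_rate
    times = np.arange(config.epoch_window[0], config.epoch_window[1], dt)
    n_t, n_e = len(times), len(montage)

    is_error = (trials["accuracy"] == "error").to_numpy()
    far = (trials["distance"] == "far").to_numpy()

    subj_ern = rng.normal(p["ern_mean"], p["ern_sd"])
    subj_pe = rng.normal(config.pe_error_effect_mean, config.pe_error_effect_sd)
    dev = rng.normal(0.0, config.ern_trial_amp_sd, n)
    jitter = rng.normal(0.0, config.latency_jitter_sd, n)

    uvw = config.ern_uv_per_weight
    amp_ern = uvw * (subj_ern + dev) * is_error
    amp_pe = uvw * subj_pe * is_error
    amp_conf = config.conflict_effect * far

    topo_ern = montage.spatial_profile("Cz", config.ern_topo_width)
    topo_pe = montage.spatial_profile("Cz", config.pe_topo_width)

    signal = np.zeros((n, n_e, n_t))
    k_ern = _gauss_kernel(times, config.ern_peak_ms + jitter, config.ern_width_ms)
    k_pe = _gauss_kernel(times, config.pe_peak_ms + jitter, config.pe_width_ms)
    k_conf = _gauss_kernel(times, config.conflict_peak_ms + jitter,
                           config.conflict_width_ms)
    signal += amp_ern[:, None, None] * topo_ern[None, :, None] * k_ern[:, None, :]
    signal += amp_pe[:, None, None] * topo_pe[None, :, None] * k_pe[:, None, :]
    signal += amp_conf[:, None, None] * topo_ern[None, :, None] * k_conf[:, None, :]

    data = signal.astype(np.float32)
    del signal
    if config.noise_ar_sd > 0:
        z = rng.standard_normal((n, n_e, n_t), dtype=np.float32)
        z *= np.sqrt(1.0 - config.noise_ar_coeff**2)
        ar = lfilter([1.0], [1.0, -config.noise_ar_coeff], z, axis=-1)
        del z
        d2 = np.sum((montage.positions[:, None, :]
                     - montage.positions[None, :, :]) ** 2, axis=-1)
        K = np.exp(-0.5 * d2 / config.noise_spatial_scale**2)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n_e))
        L /= np.linalg.norm(L, axis=1, keepdims=True)  # unit marginal variance
        data += config.noise_ar_sd * np.einsum(
            "es,nst->net", L, ar).astype(np.float32)
        del ar
    if config.noise_white_sd > 0:
        w = rng.standard_normal((n, n_e, n_t), dtype=np.float32)
        data += np.float32(config.noise_white_sd) * w
        del w

    epochs = EpochSet(data=data, times=times,
                      electrode_labels=list(montage.labels),
                      subject_id=str(trials["subject_id"].iloc[0]),
                      trial_link=np.arange(n),
                      sampling_rate=config.sampling_rate)

    # ERN -> next-trial RT coupling, injected ahead of the RT noise factor
    out = trials.copy()
    delta = np.zeros(n)
    src = np.flatnonzero(is_error[:-1])
    delta[src + 1] = config.coupling_coeff * uvw * dev[src]
    if {"rt_mu", "rt_noise", "rt_contaminated"}.issubset(out.columns):
        touch = (delta != 0) & (~out["rt_contaminated"].to_numpy())
        mu = out["rt_mu"].to_numpy(float).copy()
        mu[touch] += delta[touch]
        rt = out["rt"].to_numpy(float).copy()
        rt[touch] = (config.rt_shift
                     + (mu[touch] - config.rt_shift)
                     * out["rt_noise"].to_numpy(float)[touch])
        out["rt_mu"] = mu
        out["rt"] = rt
    return epochs, out


def simulate_subject(config: CohortConfig, sex: str, subject_id: str, seed,
                     montage: Montage | None = None,
                     baseline_quantile: float | None = None):
    """Full single-subject simulation: sequence -> behaviour -> epochs."""
    rng = as_rng(seed)
    seq = generate_trial_sequence(config, rng)
    beh = simulate_behavior(seq, config, sex, rng, subject_id=subject_id,
                            baseline_quantile=baseline_quantile)
    epochs, beh = simulate_epochs(beh, config, sex, rng, montage=montage)
    return beh, epochs


def cohort_seeds(config: CohortConfig, seed=None):
    """Deterministic per-subject plan: (sex, subject_id, seed, baseline_q).

    Per-subject seeds come from a spawned SeedSequence.  Baseline-RT
    quantiles are stratified (Latin-hypercube style) within each sex group,
    so a finite cohort reproduces the configured group-level RT contrast
    without O(sd/sqrt(n)) cohort-level noise; the per-subject marginal
    distribution is unchanged.
    """
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(config.n_female + config.n_male + 1)
    qrng = np.random.default_rng(children[-1])
    plan = []
    offset = 0
    for sex, n in (("female", config.n_female), ("male", config.n_male)):
        q = (qrng.permutation(n) + qrng.random(n)) / n
        for i in range(n):
            plan.append((sex, f"{sex[0]}{i + 1:04d}",
                         children[offset + i], float(q[i])))
        offset += n
    return plan


def simulate_cohort_behavior(config: CohortConfig, seed=None) -> pd.DataFrame:
    """Behaviour-only simulation of the whole cohort (no EEG), one table."""
    frames = []
    for sex, sid, child, q in cohort_seeds(config, seed):
        rng = np.random.default_rng(child)
        seq = generate_trial_sequence(config, rng)
        frames.append(simulate_behavior(seq, config, sex, rng, subject_id=sid,
                                        baseline_quantile=q))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# shortcut: subject-level weight maps for decoding tests

def simulate_subject_weight_maps(config: CohortConfig, n_female: int,
                                 n_male: int, seed,
                                 montage: Montage | None = None):
    """Per-subject electrode vectors of SE-scaled error weights.

    Each subject's map is a sex-specific scalar (drawn from the configured
    normal) times the fronto-central ERN topography, plus electrode noise and
    an optional distributed (non-topographic) sex signal.  Bypasses the full
    EEG simulation for fast large-n decoding tests.

    Returns (features (n_subjects, n_electrodes), electrode labels, sexes).
    """
    rng = as_rng(seed)
    if montage is None:
        montage = load_montage(config.montage)
    topo = montage.spatial_profile("Cz", config.ern_topo_width)
    n_e = len(montage)
    sexes = np.array(["female"] * n_female + ["male"] * n_male)
    means = np.where(sexes == "female", config.ern_error_effect_female_mean,
                     config.ern_error_effect_male_mean)
    sds = np.where(sexes == "female", config.ern_error_effect_female_sd,
                   config.ern_error_effect_male_sd)
    scalars = rng.normal(means, sds)
    features = scalars[:, None] * topo[None, :]
    if config.weight_map_noise_sd > 0:
        features = features + rng.normal(
            0.0, config.weight_map_noise_sd, (len(sexes), n_e))
    if config.distributed_signal_sd > 0:
        pattern = rng.standard_normal(n_e)
        pattern /= np.linalg.norm(pattern)
        features = features + (config.distributed_signal_sd
                               * (sexes == "male")[:, None] * pattern[None, :])
    return features, list(montage.labels), sexes
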