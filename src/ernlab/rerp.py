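"""First-level (within-subject) mass-univariate robust EEG regression.

Pipeline order for one subject: align epochs to the behaviourally filtered
trials, adaptive epoch rejection, baseline correction, 10 ms running-average
smoothing, then bisquare-IRLS regression of every electrode x timepoint
amplitude onto the single-trial design matrix.  Outputs are SE-scaled
regression weights (t-like statistics comparable across subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CouplingMap, EpochSet, FirstLevelMap
from .robust import irls_bisquare

#: first-level regressor names, in design-matrix column order
DESIGN_COLUMNS = ["intercept", "error", "congruency", "distance",
                  "log_rt", "response_hand", "rsi", "next_rsi"]


class DesignError(ValueError):
    pass


@dataclass
class RejectionLog:
    threshold: float
    n_rejected: dict
    fractions: dict
    raised: bool


# ---------------------------------------------------------------------------
# epoch bookkeeping

def select_epochs_for_trials(epochs: EpochSet, trials: pd.DataFrame):
    """Keep epochs whose linked trial survives behavioural filtering.

    `trials` is a filtered table still holding original 1-based trial_index
    values; epochs.trial_link holds 0-based original row positions.
    Returns (EpochSet, aligned trial rows in epoch order).
    """
    wanted = set(trials["trial_index"].to_numpy() - 1)
    mask = np.array([t in wanted for t in epochs.trial_link])
    sub = epochs.select(mask)
    aligned = (trials.set_index(trials["trial_index"] - 1)
               .loc[sub.trial_link].reset_index(drop=True))
    return sub, aligned


# ---------------------------------------------------------------------------
# preprocessing

def reject_epochs_adaptive(epochs: EpochSet, accuracy,
                           z_threshold: float = 4.0,
                           max_fraction: float = 0.05):
    """Probability-based epoch rejection with a per-condition cap.

    Each epoch is scored by its mean Gaussian negative log-likelihood under
    per-channel amplitude distributions estimated from all epochs; scores are
    z-scored across epochs and epochs above `z_threshold` are rejected.  If
    more than `max_fraction` of either condition (error/correct) would be
    rejected, the threshold is raised by binary search until the cap holds.
    """
    acc = np.asarray(accuracy)
    is_err = acc == "error" if acc.dtype.kind in "OUS" else acc.astype(bool)
    n_err, n_cor = int(is_err.sum()), int((~is_err).sum())
    if min(n_err, n_cor) < 20:
        raise ValueError(
            f"need >=20 epochs per condition (got error={n_err}, "
            f"correct={n_cor})")
    x = epochs.data.astype(np.float64)
    mu = x.mean(axis=(0, 2), keepdims=True)
    sd = x.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    nll = (0.5 * ((x - mu) / sd) ** 2 + np.log(sd)).mean(axis=(1, 2))
    z = (nll - nll.mean()) / (nll.std() if nll.std() > 0 else 1.0)

    def caps_ok(thr):
        rej = z > thr
        return (rej[is_err].mean() <= max_fraction
                and rej[~is_err].mean() <= max_fraction)

    thr = z_threshold
    raised = not caps_ok(thr)
    if raised:
        lo, hi = thr, float(z.max()) + 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if caps_ok(mid):
                hi = mid
            else:
                lo = mid
        thr = hi
    rej = z > thr
    log = RejectionLog(
        threshold=float(thr),
        n_rejected={"error": int(rej[is_err].sum()),
                    "correct": int(rej[~is_err].sum())},
        fractions={"error": float(rej[is_err].mean()),
                   "correct": float(rej[~is_err].mean())},
        raised=raised)
    return epochs.select(~rej), log


def baseline_correct(epochs: EpochSet, window=(-250.0, -150.0)) -> EpochSet:
    """Subtract the per-epoch, per-channel mean amplitude in `window` (ms)."""
    lo, hi = window
    if lo < epochs.times[0] or hi > epochs.times[-1]:
        raise ValueError(f"baseline window {window} outside epoch times")
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(epochs.data - base)


def _moving_average(x: np.ndarray, k: int) -> np.ndarray:
    n = x.shape[-1]
    c = np.cumsum(x, axis=-1, dtype=np.float64)
    c = np.concatenate([np.zeros(x.shape[:-1] + (1,)), c], axis=-1)
    hi = np.minimum(np.arange(n) + k + 1, n)
    lo = np.maximum(np.arange(n) - k, 0)
    return ((c[..., hi] - c[..., lo]) / (hi - lo)).astype(x.dtype)


def smooth_running_average(epochs: EpochSet,
                           halfwidth_ms: float = 5.0) -> EpochSet:
    """Centred running average spanning `halfwidth_ms` on each side.

    Windows are truncated at the epoch edges; constant signals pass through
    unchanged.  With the 500 Hz default this is a 5-sample (10 ms) window.
    """
    dt = 1000.0 / epochs.sampling_rate
    if dt > 2 * halfwidth_ms and halfwidth_ms > 0:
        raise ValueError("sampling interval exceeds the smoothing window")
    k = int(round(halfwidth_ms / dt))
    if k == 0:
        return epochs.copy_with(epochs.data.copy())
    return epochs.copy_with(_moving_average(epochs.data, k))


# ---------------------------------------------------------------------------
# design matrix

def build_design_matrix(trials: pd.DataFrame):
    """Single-trial design matrix for the first-level model.

    Columns: intercept, error (correct 0 / error 1), congruency
    (incongruent 1), distance (far 1), z-scored log RT, response hand
    (right 1), RSI (long 1), next-trial RSI (long 1).  Rows with an undefined
    next-trial RSI (session end) are dropped; returns (X, valid_mask) where
    valid_mask aligns with the input rows.
    """
    valid = trials["next_rsi"].notna() & (trials["rt"] > 0)
    t = trials[valid]
    log_rt = np.log(t["rt"].to_numpy(float))
    sd = log_rt.std(ddof=1)
    if sd == 0:
        raise DesignError("log RT has zero variance")
    X = np.column_stack([
        np.ones(len(t)),
        (t["accuracy"] == "error").astype(float),
        (t["congruency"] == "incongruent").astype(float),
        (t["distance"] == "far").astype(float),
        (log_rt - log_rt.mean()) / sd,
        (t["response_hand"] == "right").astype(float),
        (t["rsi"] == "long").astype(float),
        (t["next_rsi"] == "long").astype(float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    return X, valid.to_numpy()


# ---------------------------------------------------------------------------
# fitting

def robust_fit_mass_univariate(epochs: EpochSet, X: np.ndarray,
                               regressor_names=DESIGN_COLUMNS) -> FirstLevelMap:
    """Bisquare-IRLS fit at every electrode x timepoint.

    Returns SE-scaled weights (coefficient / robust SE) for every regressor.
    Cells where the fit did not converge are set to NaN and counted.
    """
    n, n_e, n_t = epochs.data.shape
    if X.shape[0] != n:
        raise DesignError("design rows do not match epoch count")
    Y = epochs.data.reshape(n, n_e * n_t).astype(np.float64)
    res = irls_bisquare(X, Y)
    scaled = res.tvalues
    scaled[~res.converged] = np.nan
    weights = scaled.T.reshape(X.shape[1], n_e, n_t)
    return FirstLevelMap(weights=weights,
                         regressor_names=list(regressor_names),
                         times=epochs.times,
                         electrode_labels=list(epochs.electrode_labels),
                         subject_id=epochs.subject_id,
                         n_trials=n,
                         n_nonconverged=int((~res.converged).sum()))


def fit_coupling(epochs: EpochSet, original_trials: pd.DataFrame,
                 min_errors: int = 10) -> CouplingMap:
    """Standardized EEG -> next-trial-RT coupling on error trials.

    For every electrode x timepoint, z-scored next-trial RT is robustly
    regressed on the z-scored single-trial EEG amplitude plus the next
    trial's congruency, RSI and flanker distance.  Only error trials whose
    following trial has a retained, in-band RT contribute.
    """
    df = original_trials.sort_values("trial_index").reset_index(drop=True)
    nxt = df.shift(-1)
    multi_or_missing = nxt["multi_response"].isna() | nxt["multi_response"].eq(True)
    next_ok = (nxt["rt"].between(100.0, 1000.0)
               & ~multi_or_missing & nxt["rt"].notna())
    eligible = (df["accuracy"] == "error") & next_ok

    pos = {t: i for i, t in enumerate(epochs.trial_link)}
    rows = [i for i in range(len(df)) if eligible.iloc[i] and i in pos]
    if len(rows) < min_errors:
        raise ValueError(
            f"only {len(rows)} usable error trials (< {min_errors})")
    epoch_rows = [pos[i] for i in rows]

    y = nxt["rt"].to_numpy(float)[rows]
    y = (y - y.mean()) / y.std(ddof=1)
    Z = np.column_stack([
        (nxt["congruency"].to_numpy() == "incongruent")[rows].astype(float),
        (nxt["rsi"].to_numpy() == "long")[rows].astype(float),
        (nxt["distance"].to_numpy() == "far")[rows].astype(float),
    ])

    n_err = len(rows)
    n_e, n_t = epochs.data.shape[1:]
    amps = epochs.data[epoch_rows].astype(np.float64)  # (n_err, e, t)
    A = amps.reshape(n_err, n_e * n_t)
    sd = A.std(axis=0, ddof=1)
    ok = sd > 0
    Az = np.zeros_like(A)
    Az[:, ok] = (A[:, ok] - A[:, ok].mean(axis=0)) / sd[ok]

    m = n_e * n_t
    Xs = np.empty((m, n_err, 2 + Z.shape[1]))
    Xs[:, :, 0] = 1.0
    Xs[:, :, 1] = Az.T
    Xs[:, :, 2:] = Z[None, :, :]
    res = irls_bisquare(Xs[ok], y[:, None].repeat(int(ok.sum()), axis=1))
    fitted = res.coef[:, 1].copy()
    fitted[~res.converged] = np.nan
    coef = np.full(m, np.nan)
    coef[ok] = fitted
    return CouplingMap(coef=coef.reshape(n_e, n_t), times=epochs.times,
                       electrode_labels=list(epochs.electrode_labels),
                       subject_id=epochs.subject_id, n_error_trials=n_err)


# ---------------------------------------------------------------------------
# peak utilities

def find_global_extremum(values: np.ndarray, times: np.ndarray,
                         electrode_labels, polarity: str = "min",
                         time_window=None):
    """Signed global extremum of an (electrode x time) map.

    Ties are broken by earliest latency, then electrode-label order.
    Returns (electrode, latency_ms, value).
    """
    v = np.asarray(values, dtype=float)
    mask = np.ones(v.shape[1], dtype=bool)
    if time_window is not None:
        mask = (times >= time_window[0]) & (times <= time_window[1])
    sub = v[:, mask]
    if np.all(np.isnan(sub)):
        raise ValueError("map is all-missing in the search window")
    target = (np.nanmin(sub) if polarity == "min" else np.nanmax(sub))
    e_idx, t_idx = np.where(sub == target)
    t_sub = times[mask]
    order = sorted(zip(t_sub[t_idx],
                       [electrode_labels[e] for e in e_idx],
                       e_idx, t_idx))
    lat, label, _, _ = order[0]
    return label, float(lat), float(target)


def single_trial_latencies(epochs: EpochSet, is_error, electrode: str,
                           center: float, halfwidth: float = 30.0):
    """Latency of the per-trial amplitude minimum around a component peak.

    Searches `center` +- `halfwidth` ms at `electrode` on error trials;
    returns (latencies array, SD of latencies).
    """
    mask = (epochs.times >= center - halfwidth) & (epochs.times <= center + halfwidth)
    if not mask.any():
        raise ValueError("empty latency search window")
    e = epochs.electrode_labels.index(electrode)
    is_error = np.asarray(is_error, dtype=bool)
    seg = epochs.data[is_error, e][:, mask]
    lats = epochs.times[mask][np.argmin(seg, axis=1)]
    sd = float(np.std(lats, ddof=1)) if len(lats) > 1 else float("nan")
    return lats, sd
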