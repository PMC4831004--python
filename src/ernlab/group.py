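"""Second-level (across-subject) statistics on first-level weight maps.

Subjects' SE-scaled first-level weights are stacked and robustly regressed on
z-scored subject covariates (sex, age, error count, optionally mean RT) at
every electrode x timepoint.  Peak tests follow the two-stage approach: the
test location is fixed from an INDEPENDENT localizing contrast (the grand
error-regressor map), never from the predictor being tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .behavior import bartlett_test, behavioral_regression
from .containers import FirstLevelMap, GroupResult
from .robust import irls_bisquare


def stack_maps(maps, regressor: str) -> np.ndarray:
    """(n_subjects, n_electrodes, n_timepoints) stack of one regressor."""
    ref = maps[0]
    for m in maps[1:]:
        if (m.electrode_labels != ref.electrode_labels
                or len(m.times) != len(ref.times)):
            raise ValueError("first-level maps are not aligned")
    return np.stack([m.get(regressor) for m in maps])


def _covariate_matrix(covariates: pd.DataFrame, include_rt: bool):
    names = ["sex", "age", "n_errors"] + (["mean_rt"] if include_rt else [])
    cols = []
    for name in names:
        x = covariates[name]
        if x.dtype == object:
            x = (x == "female").astype(float)  # female=1 / male=0
        x = x.to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"covariate {name!r} is constant")
        cols.append((x - x.mean()) / sd)
    X = np.column_stack([np.ones(len(covariates))] + cols)
    return X, ["intercept"] + names


def second_level_regression(maps, covariates: pd.DataFrame,
                            include_rt: bool = False) -> GroupResult:
    """Robust IRLS regression of subject weight maps on group covariates.

    `maps` is either a list of FirstLevelMap (the 'error' regressor is used)
    or a pre-stacked (n_subjects, e, t) array.  `covariates` must contain
    sex, age, n_errors and (if include_rt) mean_rt, indexed like the maps.
    Subjects with missing covariates are dropped.
    """
    if isinstance(maps, (list, tuple)) and isinstance(maps[0], FirstLevelMap):
        stack = stack_maps(maps, "error")
        times = maps[0].times
        labels = maps[0].electrode_labels
    else:
        stack = np.asarray(maps, dtype=float)
        times = np.arange(stack.shape[2], dtype=float)
        labels = [f"e{i}" for i in range(stack.shape[1])]
    need = ["sex", "age", "n_errors"] + (["mean_rt"] if include_rt else [])
    keep = covariates[need].notna().all(axis=1).to_numpy()
    stack, cov = stack[keep], covariates.loc[keep]
    n, n_e, n_t = stack.shape
    X, names = _covariate_matrix(cov, include_rt)
    p = X.shape[1] - 1
    if n < p + 3:
        raise ValueError("too few subjects for the second-level model")
    res = irls_bisquare(X, stack.reshape(n, n_e * n_t))
    df_resid = n - p - 1
    t = res.tvalues
    t[~res.converged] = np.nan
    pvals = 2.0 * st.t.sf(np.abs(t), df_resid)
    shape = (X.shape[1], n_e, n_t)
    return GroupResult(coef=res.coef.T.reshape(shape),
                       t=t.T.reshape(shape),
                       p=pvals.T.reshape(shape),
                       predictor_names=names, times=times,
                       electrode_labels=list(labels),
                       df_resid=df_resid, n_subjects=n)


def cohens_d_pooled(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d with equal-weight pooled SD: (m1-m2)/sqrt((s1^2+s2^2)/2)."""
    return (mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def peak_test(result: GroupResult, predictor: str, at,
              stack: np.ndarray | None = None,
              groups: np.ndarray | None = None) -> dict:
    """Group test at a pre-specified (electrode, latency) location.

    The location must come from an independent localizing contrast; passing
    a location derived from the tested predictor's own map defeats the
    two-stage logic.  When the subject stack and group labels are supplied,
    group means/SDs and the pooled-SD Cohen's d are included.
    """
    electrode, latency = at
    if electrode not in result.electrode_labels:
        raise ValueError(f"electrode {electrode!r} outside map")
    e = result.electrode_labels.index(electrode)
    dt = np.abs(result.times - latency)
    step = (result.times[1] - result.times[0]) if len(result.times) > 1 \
        else np.inf
    if dt.min() > step:
        raise ValueError(f"latency {latency} ms outside map times")
    ti = int(np.argmin(dt))
    out = {
        "electrode": electrode,
        "latency_ms": float(result.times[ti]),
        "t": float(result.get(predictor, "t")[e, ti]),
        "p": float(result.get(predictor, "p")[e, ti]),
        "df": result.df_resid,
    }
    if stack is not None and groups is not None:
        groups = np.asarray(groups)
        vals = np.asarray(stack, dtype=float)[:, e, ti]
        descr = {}
        for gname in pd.unique(groups):
            gv = vals[groups == gname]
            descr[str(gname)] = {"mean": float(gv.mean()),
                                 "sd": float(gv.std(ddof=1)),
                                 "n": int(gv.size)}
        out["groups"] = descr
        if len(descr) == 2:
            (g1, d1), (g2, d2) = descr.items()
            out["cohens_d"] = float(abs(
                cohens_d_pooled(d1["mean"], d1["sd"], d2["mean"], d2["sd"])))
    return out


def bonferroni_mask(result: GroupResult, predictor: str,
                    alpha_per_point: float = 3.3e-5) -> np.ndarray:
    """Boolean map of points with p <= alpha_per_point."""
    p = result.get(predictor, "p")
    return np.where(np.isfinite(p), p <= alpha_per_point, False)


def latency_variance_compare(latencies_by_group: dict,
                             within_sd_table: pd.DataFrame | None = None) -> dict:
    """Across-group variance comparison of component latencies.

    Bartlett's test on the per-subject latency minima across groups, plus
    (optionally) a standardized regression of within-subject latency SDs on
    sex/age/error count.
    """
    groups = {k: np.asarray(v, dtype=float)
              for k, v in latencies_by_group.items()}
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 latencies")
    stat, p = bartlett_test(*groups.values())
    out = {
        "bartlett_stat": stat,
        "bartlett_p": p,
        "group_means": {k: float(v.mean()) for k, v in groups.items()},
        "group_sds": {k: float(v.std(ddof=1)) for k, v in groups.items()},
    }
    if within_sd_table is not None:
        preds = [c for c in ("sex", "age", "n_errors")
                 if c in within_sd_table.columns]
        out["within_report"] = behavioral_regression(
            within_sd_table, "latency_sd", preds)
    return out
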