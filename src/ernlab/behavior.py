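"""Behavioural analyses: trial filtering, post-error metrics, group stats.

Conventions
-----------
* Trial filtering keeps RTs in the inclusive 100-1000 ms band and drops
  multi-response trials; post-error / pre-error status is always determined
  on the ORIGINAL trial sequence (filtering removes trials from averages but
  does not re-link neighbours).
* Session-boundary trials (no previous or next trial) are excluded from the
  baseline and post-error sets, since their adjacency is undefined.
* "Standard" RT is the mean over correct trials that neither follow nor
  precede an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm


class SingularDesignError(ValueError):
    pass


class ZeroVarianceError(ValueError):
    pass


class EmptySubjectWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# filtering

RT_MIN, RT_MAX = 100.0, 1000.0


def _annotate_adjacency(trials: pd.DataFrame) -> pd.DataFrame:
    """Add neighbour columns computed on the full original sequence."""
    df = trials.sort_values(["subject_id", "trial_index"]).copy()
    kept = (df["rt"].between(RT_MIN, RT_MAX)
            & ~df["multi_response"].astype(bool)
            & df["rt"].notna())
    df["_kept"] = kept
    g = df.groupby("subject_id", sort=False)
    for col, shifted in (("prev", 1), ("next", -1)):
        df[f"{col}_accuracy"] = g["accuracy"].shift(shifted)
        df[f"{col}_rt"] = g["rt"].shift(shifted)
        df[f"{col}_kept"] = g["_kept"].shift(shifted)
    return df


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Apply the RT-band and multi-response filters.

    The input must be the complete original sequence(s); neighbour status
    (prev/next accuracy, RT, kept flag) is annotated before filtering so that
    post-error adjacency refers to the original trial order.
    """
    df = _annotate_adjacency(trials)
    out = df[df["_kept"]].drop(columns=["_kept"]).reset_index(drop=True)
    if out.empty:
        warnings.warn("all trials removed by filters; subject flagged",
                      EmptySubjectWarning)
    return out


# ---------------------------------------------------------------------------
# post-error metrics (single-subject filtered tables)

def _base_mask(df: pd.DataFrame) -> pd.Series:
    return ((df["accuracy"] == "correct")
            & (df["prev_accuracy"] == "correct")
            & (df["next_accuracy"] == "correct"))


def compute_pes(trials: pd.DataFrame, variant: str = "standard") -> float:
    """Post-error slowing in ms (or as a fraction for variant='normalized').

    standard   : mean correct post-error RT minus mean RT of correct trials
                 flanked by correct trials on both sides;
    preerror   : mean over errors of RT(e+1) - RT(e-1), using only errors
                 whose neighbours are both correct and both retained;
    normalized : standard PES divided by the flanked-correct baseline RT.
    Returns NaN when no qualifying trials exist.
    """
    base = trials.loc[_base_mask(trials), "rt"]
    if variant in ("standard", "normalized"):
        post = trials.loc[(trials["accuracy"] == "correct")
                          & (trials["prev_accuracy"] == "error"), "rt"]
        if post.empty or base.empty:
            return float("nan")
        pes = post.mean() - base.mean()
        return float(pes / base.mean()) if variant == "normalized" else float(pes)
    if variant == "preerror":
        err = trials[(trials["accuracy"] == "error")
                     & (trials["prev_accuracy"] == "correct")
                     & (trials["next_accuracy"] == "correct")
                     & (trials["prev_kept"] == True)  # noqa: E712
                     & (trials["next_kept"] == True)]  # noqa: E712
        if err.empty:
            return float("nan")
        return float((err["next_rt"] - err["prev_rt"]).mean())
    raise ValueError(f"unknown PES variant {variant!r}")


def compute_pia(trials: pd.DataFrame) -> float:
    """Post-error increase in accuracy: post-error minus post-correct."""
    post_err = trials[trials["prev_accuracy"] == "error"]
    post_cor = trials[trials["prev_accuracy"] == "correct"]
    if post_err.empty or post_cor.empty:
        return float("nan")
    return float((post_err["accuracy"] == "correct").mean()
                 - (post_cor["accuracy"] == "correct").mean())


def congruency_effect(trials: pd.DataFrame) -> float:
    """Mean incongruent minus congruent RT on correct trials, ms."""
    correct = trials[trials["accuracy"] == "correct"]
    inc = correct.loc[correct["congruency"] == "incongruent", "rt"]
    con = correct.loc[correct["congruency"] == "congruent", "rt"]
    if inc.empty or con.empty:
        return float("nan")
    return float(inc.mean() - con.mean())


def summarize_subject(filtered: pd.DataFrame) -> dict:
    """Per-subject behavioural summary from a filtered single-subject table."""
    correct = filtered[filtered["accuracy"] == "correct"]
    errors = filtered[filtered["accuracy"] == "error"]
    base = filtered.loc[_base_mask(filtered), "rt"]
    post_cor = filtered[(filtered["accuracy"] == "correct")
                        & (filtered["prev_accuracy"] == "error")]
    log_rt = np.log(correct["rt"])
    return {
        "subject_id": filtered["subject_id"].iloc[0],
        "sex": filtered["sex"].iloc[0],
        "age": float(filtered["age"].iloc[0]),
        "n_trials": int(len(filtered)),
        "n_errors": int(len(errors)),
        "mean_rt_correct": float(base.mean()) if len(base) else float("nan"),
        "mean_rt_error": float(errors["rt"].mean()) if len(errors) else float("nan"),
        "pes_standard": compute_pes(filtered, "standard"),
        "pes_preerror": compute_pes(filtered, "preerror"),
        "pes_normalized": compute_pes(filtered, "normalized"),
        "pia": compute_pia(filtered),
        "congruency_effect": congruency_effect(filtered),
        "log_rt_sd": float(log_rt.std(ddof=1)) if len(log_rt) > 1 else float("nan"),
        "post_error_log_rt_sd": (float(np.log(post_cor["rt"]).std(ddof=1))
                                 if len(post_cor) > 1 else float("nan")),
    }


def summarize_subjects(trials: pd.DataFrame) -> pd.DataFrame:
    """Filter and summarize every subject in a (multi-subject) trial table."""
    filtered = filter_trials(trials)
    rows = [summarize_subject(d)
            for _, d in filtered.groupby("subject_id", sort=True)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outlier screening

def grubbs_critical(n: int, alpha: float) -> float:
    """One-sided Grubbs critical value from the t-distribution."""
    t = st.t.ppf(1.0 - alpha / n, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_screen(values, alpha: float = 0.01,
                  side: str = "upper") -> np.ndarray:
    """Iterative Grubbs outlier test; True marks excluded values.

    At each step the most extreme value in the tested direction is removed
    while its G = deviation/sd statistic exceeds the critical value.  The
    default is the one-sided upper test (used to screen subjects with too
    HIGH a proportion of missed or multi-response trials), which holds the
    per-dataset false-alarm rate at `alpha`; side='both' runs the two-sided
    variant at the same overall alpha.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    if np.std(x, ddof=1) == 0:
        raise ZeroVarianceError("Grubbs test undefined for zero variance")
    if side not in ("upper", "lower", "both"):
        raise ValueError(f"unknown side {side!r}")
    alpha_eff = alpha / 2 if side == "both" else alpha
    mask = np.zeros(x.size, dtype=bool)
    idx = np.arange(x.size)
    while idx.size >= 3:
        sub = x[idx]
        sd = np.std(sub, ddof=1)
        if sd == 0:
            break
        if side == "upper":
            dev = sub - sub.mean()
        elif side == "lower":
            dev = sub.mean() - sub
        else:
            dev = np.abs(sub - sub.mean())
        g = dev.max() / sd
        if g > grubbs_critical(idx.size, alpha_eff):
            worst = idx[np.argmax(dev)]
            mask[worst] = True
            idx = idx[idx != worst]
        else:
            break
    return mask


# ---------------------------------------------------------------------------
# group regressions

@dataclass
class RegressionReport:
    """Standardized multiple-regression summary with Bonferroni correction."""

    table: pd.DataFrame  # predictor, b, ci_low, ci_high, p_raw, p_bonferroni
    df_resid: int
    n: int
    family_size: int
    n_dropped: int = 0
    extras: dict = field(default_factory=dict)

    def row(self, predictor: str) -> pd.Series:
        return self.table.set_index("predictor").loc[predictor]


def _encode(series: pd.Series) -> np.ndarray:
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        levels = sorted(series.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"cannot encode non-binary column: {levels}")
        # female=1/male=0 so a positive RT coefficient means slower females
        if set(levels) == {"female", "male"}:
            return (series == "female").astype(float).to_numpy()
        return (series == levels[1]).astype(float).to_numpy()
    return series.astype(float).to_numpy()


def zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ZeroVarianceError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def behavioral_regression(table: pd.DataFrame, outcome: str, predictors,
                          family_size: int = 14,
                          zscore_outcome: bool = True) -> RegressionReport:
    """OLS of a subject-level outcome on z-scored predictors.

    Binary columns (e.g. sex) are coded 0/1 before z-scoring.  Reports
    standardized coefficients with 99.9% confidence intervals, raw p-values
    and Bonferroni-corrected p-values for a family of `family_size` tests.
    Subjects with missing values in any used column are dropped (counted in
    n_dropped).
    """
    cols = [outcome] + list(predictors)
    used = table[cols].copy()
    n_before = len(used)
    used = used.dropna()
    n = len(used)
    if n <= len(predictors) + 1:
        raise ValueError("too few subjects for the requested model")
    y = _encode(used[outcome])
    y = zscore(y) if zscore_outcome else y
    Xcols = [zscore(_encode(used[p])) for p in predictors]
    X = sm.add_constant(np.column_stack(Xcols))
    if np.linalg.cond(X) > 1e10:
        raise SingularDesignError("predictors are collinear")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.001)
    rows = []
    for i, name in enumerate(["intercept"] + list(predictors)):
        rows.append({
            "predictor": name,
            "b": fit.params[i],
            "ci_low": ci[i, 0],
            "ci_high": ci[i, 1],
            "p_raw": fit.pvalues[i],
            "p_bonferroni": min(1.0, family_size * fit.pvalues[i]),
        })
    return RegressionReport(table=pd.DataFrame(rows),
                            df_resid=int(fit.df_resid), n=n,
                            family_size=family_size,
                            n_dropped=n_before - n)


def bartlett_test(*groups):
    """Bartlett's chi-square test for equality of variances."""
    for g in groups:
        if len(g) < 2:
            raise ValueError("Bartlett's test needs >=2 values per group")
    stat, p = st.bartlett(*groups)
    return float(stat), float(p)


def variance_analysis(summaries: pd.DataFrame,
                      value_col: str = "log_rt_sd",
                      predictors=("sex", "age", "n_errors"),
                      family_size: int = 14) -> dict:
    """Compare RT variability across subjects and sexes.

    Regresses the per-subject SD of log RT on sex/age/error count and runs
    Bartlett's test on the SDs across the two sex groups.
    """
    report = behavioral_regression(summaries, value_col, list(predictors),
                                   family_size=family_size)
    groups = [g[value_col].dropna().to_numpy()
              for _, g in summaries.groupby("sex")]
    stat, p = bartlett_test(*groups)
    return {"report": report, "bartlett_stat": stat, "bartlett_p": p}
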