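import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import make_epochs, make_trials
from ernlab import rerp
from ernlab.robust import irls_bisquare


# ---------------------------------------------------------------------------
# baseline correction

def test_baseline_constant_epoch_becomes_zero(rng):
    data = np.full((3, 2, 100), 5.0)
    ep = make_epochs(data, times=np.arange(-300, -100, 2))
    out = rerp.baseline_correct(ep, (-250, -150))
    assert np.allclose(out.data, 0.0)


def test_baseline_shift_invariance(rng):
    data = rng.standard_normal((4, 3, 200))
    times = np.arange(-300, 100, 2)
    a = rerp.baseline_correct(make_epochs(data, times=times), (-250, -150))
    b = rerp.baseline_correct(make_epochs(data + 3.0, times=times),
                              (-250, -150))
    assert np.allclose(a.data, b.data, atol=1e-10)
    # postcondition: window mean is zero
    mask = (times >= -250) & (times <= -150)
    assert np.allclose(a.data[:, :, mask].mean(axis=2), 0.0, atol=1e-12)


def test_baseline_window_outside_epoch_raises(rng):
    ep = make_epochs(rng.standard_normal((2, 2, 50)),
                     times=np.arange(0, 100, 2))
    with pytest.raises(ValueError):
        rerp.baseline_correct(ep, (-250, -150))


# ---------------------------------------------------------------------------
# smoothing

def test_smoothing_preserves_constants(rng):
    ep = make_epochs(np.full((2, 2, 80), 3.25))
    out = rerp.smooth_running_average(ep, 5.0)
    assert np.allclose(out.data, 3.25)


def test_smoothing_impulse_spreads_over_five_samples():
    data = np.zeros((1, 1, 21))
    data[0, 0, 10] = 1.0
    out = rerp.smooth_running_average(make_epochs(data), 5.0)
    sig = out.data[0, 0]
    assert np.allclose(sig[8:13], 0.2)
    assert np.allclose(sig[:8], 0.0) and np.allclose(sig[13:], 0.0)


def test_smoothing_reduces_noise_variance(rng):
    ep = make_epochs(rng.standard_normal((10, 2, 500)))
    out = rerp.smooth_running_average(ep, 5.0)
    assert out.data.var() < 0.5 * ep.data.var()


def test_smoothing_edge_truncation_keeps_means(rng):
    # truncated edge windows average fewer samples but stay unbiased
    ep = make_epochs(np.ones((1, 1, 10)))
    out = rerp.smooth_running_average(ep, 5.0)
    assert np.allclose(out.data, 1.0)


# ---------------------------------------------------------------------------
# epoch rejection

def _epochs_with_accuracy(rng, n_cor=60, n_err=30, n_e=4, n_t=50, sd=1.0):
    data = rng.standard_normal((n_cor + n_err, n_e, n_t)) * sd
    acc = np.array(["correct"] * n_cor + ["error"] * n_err)
    return make_epochs(data), acc


def test_rejection_flags_gross_outlier(rng):
    ep, acc = _epochs_with_accuracy(rng)
    data = ep.data.copy()
    data[7] *= 10.0
    ep = make_epochs(data)
    kept, log = rerp.reject_epochs_adaptive(ep, acc)
    assert 7 not in kept.trial_link
    assert log.n_rejected["correct"] >= 1
    assert log.fractions["correct"] <= 0.05


def test_rejection_never_exceeds_cap_on_clean_data(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        ep, acc = _epochs_with_accuracy(r, n_cor=200, n_err=60)
        _, log = rerp.reject_epochs_adaptive(ep, acc)
        assert log.fractions["correct"] <= 0.05
        assert log.fractions["error"] <= 0.05


def test_rejection_cap_binds_under_heavy_contamination(rng):
    n_err = 100
    ep, acc = _epochs_with_accuracy(rng, n_cor=300, n_err=n_err)
    data = ep.data.copy()
    bad = np.arange(300, 320)  # 20% of the error condition
    data[bad] *= 8.0
    kept, log = rerp.reject_epochs_adaptive(make_epochs(data), acc)
    assert log.n_rejected["error"] == int(0.05 * n_err)
    assert log.threshold > 4.0 and log.raised


def test_rejection_requires_minimum_epochs(rng):
    ep, acc = _epochs_with_accuracy(rng, n_cor=30, n_err=10)
    with pytest.raises(ValueError, match="20"):
        rerp.reject_epochs_adaptive(ep, acc)


# ---------------------------------------------------------------------------
# design matrix

def test_design_matrix_columns_and_validity():
    r = np.random.default_rng(12)
    n = 40
    t = make_trials(r.uniform(300, 600, n),
                    list(r.choice(["correct", "error"], n, p=[0.7, 0.3])))
    X, valid = rerp.build_design_matrix(t)
    assert valid.sum() == n - 1  # last trial has no next RSI
    assert X.shape == (n - 1, 8)
    assert np.allclose(X[:, 0], 1.0)
    assert set(np.unique(X[:, 1])) <= {0.0, 1.0}
    assert abs(X[:, 4].mean()) < 1e-12  # z-scored log RT
    assert np.linalg.matrix_rank(X) == 8


def test_design_matrix_rank_deficiency_raises():
    t = make_trials([400] * 6, ["correct"] * 6)
    with pytest.raises(rerp.DesignError):
        rerp.build_design_matrix(t)


# ---------------------------------------------------------------------------
# robust mass-univariate fit

def _simulated_cells(rng, n=3000, n_e=2, n_t=40, effect=1.5, noise=1.0):
    """Epochs whose amplitude depends on the error regressor only."""
    rts = rng.uniform(300, 600, n)
    accs = np.where(rng.random(n) < 0.3, "error", "correct")
    trials = make_trials(rts, accs)
    X, valid = rerp.build_design_matrix(trials)
    err = X[:, 1]
    data = (effect * err[:, None, None]
            + noise * rng.standard_normal((valid.sum(), n_e, n_t)))
    return make_epochs(data), X


def test_robust_fit_matches_ols_on_clean_data(rng):
    ep, X = _simulated_cells(rng)
    fl = rerp.robust_fit_mass_univariate(ep, X)
    t_rob = fl.get("error").ravel()
    t_ols = np.empty_like(t_rob)
    Y = ep.data.reshape(ep.data.shape[0], -1)
    for j in range(Y.shape[1]):
        t_ols[j] = sm.OLS(Y[:, j], X).fit().tvalues[1]
    rel = np.abs(t_rob / t_ols - 1)
    assert np.mean(rel) < 0.02
    assert np.median(rel) < 0.02


def test_robust_fit_resists_outlier_trials(rng):
    ep, X = _simulated_cells(rng, n=1200, n_e=1, n_t=10)
    Yc = ep.data.reshape(ep.data.shape[0], -1).copy()
    b_clean = np.array([sm.OLS(Yc[:, j], X).fit().params[1]
                        for j in range(Yc.shape[1])])
    Yd = Yc.copy()
    n_bad = int(0.05 * len(Yd))
    Yd[:n_bad] += 25.0
    res = irls_bisquare(X, Yd)
    b_rob = res.coef[:, 1]
    b_ols_bad = np.array([sm.OLS(Yd[:, j], X).fit().params[1]
                          for j in range(Yd.shape[1])])
    assert np.all(np.abs(b_rob - b_clean) < np.abs(b_ols_bad - b_clean))


def test_scaled_weights_standard_normal_under_null(rng):
    ep, X = _simulated_cells(rng, n=800, n_e=4, n_t=60, effect=0.0)
    fl = rerp.robust_fit_mass_univariate(ep, X)
    t = fl.get("error").ravel()
    from scipy.stats import kstest
    assert kstest(t, "norm").pvalue > 0.005


def test_nonconverged_cells_are_flagged_missing(rng):
    ep, X = _simulated_cells(rng, n=400, n_e=1, n_t=5)
    fl = rerp.robust_fit_mass_univariate(ep, X)
    n_nan = int(np.isnan(fl.weights).sum())
    assert n_nan == fl.n_nonconverged * len(fl.regressor_names) or n_nan == 0


# ---------------------------------------------------------------------------
# coupling

def test_coupling_noiseless_linear_map_gives_minus_one():
    n = 40
    rng = np.random.default_rng(3)
    amp = rng.standard_normal(n) * 2.0
    # trials: every odd trial is an error followed by a correct trial
    rts, accs = [], []
    for i in range(n):
        rts += [400.0, 400.0]
        accs += ["error", "correct"]
    trials = make_trials(rts, accs)
    # next-trial RT = -0.5 * amplitude on error trials
    rt = trials["rt"].to_numpy().copy()
    rt[1::2] = 500.0 - 0.5 * amp
    trials["rt"] = rt
    data = np.zeros((2 * n, 1, 3), dtype=float)
    data[0::2, 0, 1] = amp  # informative timepoint on error trials
    ep = make_epochs(data)
    cm = rerp.fit_coupling(ep, trials)
    assert cm.coef[0, 1] == pytest.approx(-1.0, abs=1e-6)
    assert np.isnan(cm.coef[0, 0])  # zero-variance amplitude -> undefined


def test_coupling_map_from_generator_peaks_at_ern():
    """Group-mean coupling is negative at (Cz, ERN latency) with the default
    negative coupling, and within noise of zero when the coupling is off."""
    from ernlab.cohort import generate_trial_sequence, simulate_behavior, \
        simulate_epochs
    from ernlab.config import CohortConfig
    from ernlab.montage import load_montage

    montage = load_montage("standard-32")
    for coeff in (-3.0, 0.0):
        cfg = CohortConfig(
            n_trials=400, montage="standard-32",
            epoch_window=(-280.0, 320.0), coupling_coeff=coeff,
            rt_within_sd=5.0, congruency_cost=0.0,
            congruency_cost_female_extra=0.0, error_rt_shift=0.0,
            pes_male=0.0, multi_response_fraction=0.0,
            rt_out_of_range_fraction=0.0, latency_jitter_sd=0.0,
            noise_ar_sd=1.5, noise_white_sd=1.0)
        coefs = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            seq = generate_trial_sequence(cfg, rng)
            tbl = simulate_behavior(seq, cfg, "male", rng)
            epochs, tbl = simulate_epochs(tbl, cfg, "male", rng,
                                          montage=montage)
            cm = rerp.fit_coupling(epochs, tbl)
            cz = cm.electrode_labels.index("Cz")
            ti = int(np.argmin(np.abs(cm.times - 64.0)))
            coefs.append(cm.coef[cz, ti])
        mean = np.mean(coefs)
        se = np.std(coefs, ddof=1) / np.sqrt(len(coefs))
        if coeff < 0:
            assert mean < -0.3
        else:
            assert abs(mean) <= 2 * se + 0.05


def test_coupling_requires_enough_error_trials():
    trials = make_trials([400.0] * 8, ["error", "correct"] * 4)
    ep = make_epochs(np.zeros((8, 1, 3)))
    with pytest.raises(ValueError, match="error trials"):
        rerp.fit_coupling(ep, trials)


# ---------------------------------------------------------------------------
# extrema and latencies

def test_global_extremum_with_injected_peak():
    v = np.zeros((3, 50))
    v[1, 20] = -7.0
    times = np.arange(50) * 2.0
    labels = ["Fz", "Cz", "Pz"]
    assert (rerp.find_global_extremum(v, times, labels, "min")
            == ("Cz", 40.0, -7.0))


def test_global_extremum_tie_broken_by_earliest_latency():
    v = np.zeros((2, 60))
    times = np.arange(60) * 2.0
    v[0, 30] = -5.0  # 60 ms
    v[1, 40] = -5.0  # 80 ms
    label, lat, val = rerp.find_global_extremum(v, times, ["A", "B"], "min")
    assert (label, lat) == ("A", 60.0)


def test_global_extremum_all_nan_raises():
    v = np.full((2, 10), np.nan)
    with pytest.raises(ValueError):
        rerp.find_global_extremum(v, np.arange(10.0), ["A", "B"], "min")


def test_single_trial_latency_sd_uniform_jitter_closed_form():
    rng = np.random.default_rng(4)
    J = 20.0
    n = 2000
    times = np.arange(-100, 200, 2.0)
    jit = rng.uniform(-J, J, n)
    data = np.zeros((n, 1, len(times)))
    for i in range(n):
        data[i, 0] = -np.exp(-0.5 * ((times - 60 - jit[i]) / 15.0) ** 2)
    ep = make_epochs(data, times=times)
    lats, sd = rerp.single_trial_latencies(ep, np.ones(n, bool), "ch0",
                                           center=60.0, halfwidth=40.0)
    # uniform jitter of half-width J has SD J/sqrt(3)
    assert sd == pytest.approx(J / np.sqrt(3), rel=0.05)


def test_single_trial_latency_empty_window_raises(rng):
    ep = make_epochs(rng.standard_normal((5, 1, 20)))
    with pytest.raises(ValueError):
        rerp.single_trial_latencies(ep, np.ones(5, bool), "ch0",
                                    center=1e4, halfwidth=1.0)
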