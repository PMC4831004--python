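import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from ernlab.config import CohortConfig
from ernlab.cohort import (BalanceError, error_intercept, error_probabilities,
                           generate_trial_sequence, simulate_behavior,
                           simulate_cohort_behavior, simulate_epochs,
                           simulate_subject, simulate_subject_weight_maps)
from ernlab.montage import MontageError


def quiet_eeg_config(**kw):
    """EEG config with all stochastic components switched off."""
    base = dict(noise_white_sd=0.0, noise_ar_sd=0.0, latency_jitter_sd=0.0,
                ern_trial_amp_sd=0.0, montage="standard-32")
    base.update(kw)
    return CohortConfig(**base)


# ---------------------------------------------------------------------------
# trial sequence

def test_sequence_counterbalancing_default():
    cfg = CohortConfig(n_trials=1080)
    seq = generate_trial_sequence(cfg, 0)
    assert (seq["congruency"] == "congruent").sum() == 540
    assert (seq["congruency"] == "incongruent").sum() == 540
    for a, b in (("congruency", "rsi"), ("distance", "rsi")):
        cells = seq.groupby([a, b]).size()
        assert (cells == 270).all()


@settings(max_examples=20, deadline=None)
@given(k=st_h.integers(1, 30), seed=st_h.integers(0, 2**31 - 1))
def test_sequence_cells_exactly_equal_property(k, seed):
    cfg = CohortConfig(n_trials=8 * k)
    seq = generate_trial_sequence(cfg, seed)
    cells = seq.groupby(["congruency", "distance", "rsi"]).size()
    assert len(cells) == 8 and (cells == k).all()


def test_sequence_minimal_and_balance_error():
    seq = generate_trial_sequence(CohortConfig(n_trials=8), 5)
    assert (seq.groupby(["congruency", "rsi"]).size() == 2).all()
    with pytest.raises(BalanceError):
        generate_trial_sequence(CohortConfig(n_trials=9), 5)


def test_sequence_deterministic_under_seed():
    cfg = CohortConfig(n_trials=80)
    a = generate_trial_sequence(cfg, 42)
    b = generate_trial_sequence(cfg, 42)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# behaviour

def test_degenerate_rt_model_returns_baseline():
    cfg = CohortConfig(rt_between_sd=0.0, rt_within_sd=0.0,
                       congruency_cost=0.0, congruency_cost_female_extra=0.0,
                       pes_male=0.0, pes_female=0.0, error_rt_shift=0.0,
                       multi_response_fraction=0.0,
                       rt_out_of_range_fraction=0.0, n_trials=80)
    seq = generate_trial_sequence(cfg, 3)
    beh = simulate_behavior(seq, cfg, "male", 3)
    assert np.allclose(beh["rt"], cfg.rt_mean_male)


def test_error_intercept_matches_target_marginal():
    cfg = CohortConfig()
    b0 = error_intercept(cfg)
    from scipy.special import expit
    cells = [b0, b0 + cfg.error_congruency_logodds,
             b0 + cfg.error_distance_logodds,
             b0 + cfg.error_congruency_logodds + cfg.error_distance_logodds]
    assert np.mean(expit(cells)) == pytest.approx(cfg.error_rate_target,
                                                  abs=1e-10)


def test_error_rate_and_congruency_calibration():
    cfg = CohortConfig(n_female=30, n_male=30)
    df = simulate_cohort_behavior(cfg, seed=11)
    # marginal error rate close to the calibrated target
    assert (df["accuracy"] == "error").mean() == pytest.approx(0.143, abs=0.01)
    # incongruent correct trials are slower by ~ the configured cost
    correct = df[(df["accuracy"] == "correct") & ~df["rt_contaminated"]
                 & ~df["multi_response"]]
    cost = (correct.loc[correct["congruency"] == "incongruent", "rt"].mean()
            - correct.loc[correct["congruency"] == "congruent", "rt"].mean())
    assert cost == pytest.approx(62.0, abs=3.0)


def test_contamination_bookkeeping_matches_filters():
    from ernlab.behavior import filter_trials

    cfg = CohortConfig(n_trials=1080)
    seq = generate_trial_sequence(cfg, 9)
    beh = simulate_behavior(seq, cfg, "female", 9)
    injected = (beh["multi_response"] | beh["rt_contaminated"]).sum()
    kept = filter_trials(beh)
    assert len(beh) - len(kept) == injected


def test_behavior_deterministic_under_seed():
    cfg = CohortConfig(n_trials=80)
    seq = generate_trial_sequence(cfg, 1)
    a = simulate_behavior(seq, cfg, "female", 7)
    b = simulate_behavior(seq, cfg, "female", 7)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# epochs

def test_noiseless_epoch_is_sum_of_kernels(montage32):
    cfg = quiet_eeg_config(n_trials=16, multi_response_fraction=0.0,
                           rt_out_of_range_fraction=0.0, conflict_effect=-2.5)
    seq = generate_trial_sequence(cfg, 21)
    beh = simulate_behavior(seq, cfg, "male", 21)
    epochs, beh2 = simulate_epochs(beh, cfg, "male", 99, montage=montage32)
    times = epochs.times
    cz = epochs.electrode_labels.index("Cz")
    topo_e = montage32.spatial_profile("Cz", cfg.ern_topo_width)
    topo_p = montage32.spatial_profile("Cz", cfg.pe_topo_width)

    # reconstruct one error epoch analytically (subject amplitudes are the
    # only random draws; recover them from the peak samples)
    rng = np.random.default_rng(99)
    subj_ern = rng.normal(cfg.ern_error_effect_male_mean,
                          cfg.ern_error_effect_male_sd)
    subj_pe = rng.normal(cfg.pe_error_effect_mean, cfg.pe_error_effect_sd)
    is_err = (beh2["accuracy"] == "error").to_numpy()
    far = (beh2["distance"] == "far").to_numpy()
    for i in range(len(beh2)):
        k_e = np.exp(-0.5 * ((times - cfg.ern_peak_ms) / cfg.ern_width_ms) ** 2)
        k_p = np.exp(-0.5 * ((times - cfg.pe_peak_ms) / cfg.pe_width_ms) ** 2)
        k_c = np.exp(-0.5 * ((times - cfg.conflict_peak_ms)
                             / cfg.conflict_width_ms) ** 2)
        expect = (subj_ern * is_err[i] * topo_e[:, None] * k_e[None, :]
                  + subj_pe * is_err[i] * topo_p[:, None] * k_p[None, :]
                  + cfg.conflict_effect * far[i] * topo_e[:, None] * k_c[None, :])
        assert np.allclose(epochs.data[i], expect, atol=1e-4)
    assert cz == np.argmax(topo_e)


def test_error_minus_correct_shows_ern_then_pe(montage32):
    cfg = CohortConfig(n_trials=400, montage="standard-32")
    tbl, epochs = simulate_subject(cfg, "male", "m01", 5, montage=montage32)
    cz = epochs.electrode_labels.index("Cz")
    err = (tbl["accuracy"] == "error").to_numpy()
    diff = (epochs.data[err, cz].mean(axis=0)
            - epochs.data[~err, cz].mean(axis=0))
    t = epochs.times
    near = lambda ms: (t >= ms - 20) & (t <= ms + 20)
    assert diff[near(64)].mean() < -2.0
    assert diff[near(226)].mean() > 2.0


def test_epochs_deterministic_and_missing_midline_raises(montage32):
    cfg = quiet_eeg_config(n_trials=16, noise_white_sd=1.0)
    seq = generate_trial_sequence(cfg, 2)
    beh = simulate_behavior(seq, cfg, "female", 2)
    e1, _ = simulate_epochs(beh, cfg, "female", 4, montage=montage32)
    e2, _ = simulate_epochs(beh, cfg, "female", 4, montage=montage32)
    assert np.array_equal(e1.data, e2.data)
    lateral = montage32.subset([l for l in montage32.labels
                                if not l.endswith("z")])
    with pytest.raises(MontageError, match="midline"):
        simulate_epochs(beh, cfg, "female", 4, montage=lateral)


def test_coupling_links_ern_amplitude_to_next_rt(montage32):
    # amplitude deviations must be visible: no jitter/noise, low RT noise
    common = dict(n_trials=400, rt_within_sd=5.0, multi_response_fraction=0.0,
                  rt_out_of_range_fraction=0.0, pes_male=0.0,
                  congruency_cost=0.0, congruency_cost_female_extra=0.0,
                  error_rt_shift=0.0)
    for coeff, check in ((-3.0, "neg"), (0.0, "null")):
        cfg = quiet_eeg_config(coupling_coeff=coeff, ern_trial_amp_sd=2.0,
                               **common)
        seq = generate_trial_sequence(cfg, 31)
        beh = simulate_behavior(seq, cfg, "male", 31)
        epochs, beh2 = simulate_epochs(beh, cfg, "male", 31, montage=montage32)
        cz = epochs.electrode_labels.index("Cz")
        ti = np.argmin(np.abs(epochs.times - cfg.ern_peak_ms))
        err = np.flatnonzero((beh2["accuracy"] == "error").to_numpy()[:-1])
        amp = epochs.data[err, cz, ti]
        next_rt = beh2["rt"].to_numpy()[err + 1]
        r = np.corrcoef(amp, next_rt)[0, 1]
        if check == "neg":
            assert r < -0.3  # more negative ERN -> slower next response
        else:
            assert abs(r) < 0.25


# ---------------------------------------------------------------------------
# weight maps

def test_weight_maps_noiseless_group_means():
    cfg = CohortConfig(weight_map_noise_sd=0.0, montage="standard-32")
    feats, labels, sexes = simulate_subject_weight_maps(cfg, 4000, 4000, 17)
    cz = labels.index("Cz")
    f = feats[sexes == "female", cz].mean()
    m = feats[sexes == "male", cz].mean()
    assert f == pytest.approx(-6.9, abs=0.2)
    assert m == pytest.approx(-9.3, abs=0.25)


def test_weight_maps_effect_size_matches_closed_form():
    cfg = CohortConfig(montage="standard-32")
    feats, labels, sexes = simulate_subject_weight_maps(cfg, 10000, 10000, 23)
    cz = labels.index("Cz")
    f, m = feats[sexes == "female", cz], feats[sexes == "male", cz]
    d = (f.mean() - m.mean()) / np.sqrt((f.var(ddof=1) + m.var(ddof=1)) / 2)
    sd_f = np.hypot(cfg.ern_error_effect_female_sd, cfg.weight_map_noise_sd)
    sd_m = np.hypot(cfg.ern_error_effect_male_sd, cfg.weight_map_noise_sd)
    d_expected = (cfg.ern_error_effect_female_mean
                  - cfg.ern_error_effect_male_mean) / np.sqrt(
                      (sd_f**2 + sd_m**2) / 2)
    assert d == pytest.approx(d_expected, abs=0.04)
    assert d_expected == pytest.approx(0.60, abs=0.05)


def test_weight_maps_no_signal_when_groups_equal():
    cfg = CohortConfig(ern_error_effect_female_mean=-8.0,
                       ern_error_effect_male_mean=-8.0,
                       ern_error_effect_female_sd=4.0,
                       ern_error_effect_male_sd=4.0,
                       montage="standard-32")
    feats, labels, sexes = simulate_subject_weight_maps(cfg, 2000, 2000, 29)
    cz = labels.index("Cz")
    diff = (feats[sexes == "female", cz].mean()
            - feats[sexes == "male", cz].mean())
    se = np.sqrt(feats[:, cz].var(ddof=1) * 2 / 2000)
    assert abs(diff) < 2 * se + 1e-12
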