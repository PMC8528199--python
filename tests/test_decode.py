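import numpy as np
import pytest

from seegbench.decode import (BAND_DEFS, SDA_BANDS, FeatureTensor, WindowDef,
                              baseline_zscore, burg_batch, burg_psd_batch,
                              decode_DA, decode_SDA, extract_features,
                              forward_select_channels, make_trial_folds,
                              window_starts)
from seegbench.io_montage import ChannelInfo, EpochSet


# ---------------------------------------------------------------------------
# window bookkeeping


def test_task_and_baseline_window_counts():
    w = WindowDef(0.5, 0.25)
    assert len(window_starts((0.0, 4.0), w)) == 15
    assert len(window_starts((-4.0, -2.0), w)) == 7


def test_trial_folds_partition_and_stratify():
    labels = np.repeat(["a", "b", "c"], 20)
    folds = make_trial_folds(labels, n_folds=10, seed=3)
    assert sorted(np.unique(folds)) == list(range(10))
    for f in range(10):
        test = folds == f
        assert test.sum() == 6           # 54 train / 6 test
        _, counts = np.unique(labels[test], return_counts=True)
        assert all(counts == 2)          # stratified: 2 trials per gesture


# ---------------------------------------------------------------------------
# Burg AR spectra


def test_burg_matches_statsmodels_reference():
    from statsmodels.regression.linear_model import burg as sm_burg

    rng = np.random.default_rng(0)
    # AR(2) process so the estimate is well conditioned
    x = np.zeros((3, 600))
    e = rng.standard_normal((3, 600))
    for t in range(2, 600):
        x[:, t] = 0.6 * x[:, t - 1] - 0.3 * x[:, t - 2] + e[:, t]
    a, _ = burg_batch(x[:, 100:], order=12, dtype=np.float64)
    for i in range(3):
        rho, _ = sm_burg(x[i, 100:], order=12, demean=False)
        np.testing.assert_allclose(-a[i], rho, atol=1e-10)


def test_burg_psd_integrates_to_signal_variance():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((4, 500))
    freqs, psd = burg_psd_batch(x, fs=1000.0, order=40)
    var = np.trapezoid(psd, freqs, axis=1)
    np.testing.assert_allclose(var, x.var(axis=1), rtol=0.15)


def _epochs_from(data, fs):
    n_ch = data.shape[1]
    montage = [ChannelInfo(f"S0C{i+1}", "S0", i + 1) for i in range(n_ch)]
    labels = np.tile(["a", "b", "c"], data.shape[0] // 3 + 1)[: data.shape[0]]
    return EpochSet(data=data, fs=fs, montage=montage, labels=labels)


def test_white_noise_band_power_scales_with_bandwidth():
    # 500-sample windows (1 kHz): at much shorter windows an AR(40) fit
    # overfits and inflates the lowest bands
    rng = np.random.default_rng(2)
    fs = 1000.0
    ep = _epochs_from(rng.standard_normal((12, 1, int(8 * fs))), fs)
    ft = extract_features(ep)
    bp = ft.task.mean(axis=(0, 1, 2))  # mean PSD density per band
    # flat spectrum: equal density in every band, i.e. integrated band power
    # proportional to bandwidth
    assert np.all(np.abs(bp / bp.mean() - 1) < 0.2)
    widths = np.array([hi - lo for lo, hi in BAND_DEFS])
    integrated = bp * widths
    rel = (integrated / integrated.sum()) / (widths / widths.sum())
    assert np.all(np.abs(rel - 1) < 0.2)


def test_pure_alpha_tone_dominates_alpha_band():
    fs = 500.0
    t = np.arange(int(8 * fs)) / fs
    tone = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
    ep = _epochs_from(np.tile(tone, (3, 1, 1)) + 1e-6, fs)
    ft = extract_features(ep)
    bp = ft.task.mean(axis=(0, 1, 2))
    assert np.argmax(bp) == 2  # 8-13 Hz


# ---------------------------------------------------------------------------
# baseline z-score


def _manual_features(task, baseline):
    n_tr, n_w, n_ch, n_b = task.shape
    return FeatureTensor(
        task=task, baseline=baseline, band_defs=BAND_DEFS[:n_b],
        window_def=WindowDef(), channel_ids=[f"C{i}" for i in range(n_ch)],
        fs=1000.0)


def test_baseline_zscore_reference_cases():
    rng = np.random.default_rng(3)
    base = rng.standard_normal((10, 7, 1, 1)) * 2.0 + 5.0
    mu, sd = base.mean(), base.std()
    task = np.full((10, 15, 1, 1), mu)
    z = baseline_zscore(_manual_features(task, base))
    np.testing.assert_allclose(z.task, 0.0, atol=1e-12)
    z2 = baseline_zscore(_manual_features(task + sd, base))
    np.testing.assert_allclose(z2.task, 1.0, atol=1e-12)


def test_baseline_zscore_zero_variance_feature_is_dropped():
    base = np.ones((5, 7, 1, 2))
    base[..., 1] += np.random.default_rng(4).standard_normal((5, 7, 1))
    task = np.random.default_rng(5).standard_normal((5, 15, 1, 2))
    with pytest.warns(UserWarning, match="zero baseline"):
        z = baseline_zscore(_manual_features(task, base))
    assert np.all(z.task[..., 0] == 0.0)
    assert not np.all(z.task[..., 1] == 0.0)


def test_stationary_noise_gives_centred_task_zscores(white_epochs):
    ft = baseline_zscore(extract_features(white_epochs))
    assert abs(ft.task.mean()) < 0.1


# ---------------------------------------------------------------------------
# forward selection


def _planted_features(n_ch=10, informative=3, n_trials=60, n_w=15, n_bands=2,
                      effect=1.5, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.tile(["a", "b", "c"], n_trials // 3)
    task = rng.standard_normal((n_trials, n_w, n_ch, n_bands))
    shift = {"a": -effect, "b": 0.0, "c": effect}
    for i, lab in enumerate(labels):
        task[i, :, informative, :] += shift[lab]
    base = rng.standard_normal((n_trials, 7, n_ch, n_bands))
    ft = _manual_features(task, base)
    ft.normalized = True
    return ft, labels


def test_forward_selection_finds_planted_channel_first():
    ft, labels = _planted_features(seed=11)
    selected, trace = forward_select_channels(ft, labels, seed=1)
    assert trace[0][0] == "C3"
    assert "C3" in selected


def test_forward_selection_stops_after_three_flat_steps():
    rng = np.random.default_rng(6)
    task = np.tile(rng.standard_normal((60, 15, 1, 2)), (1, 1, 8, 1))
    base = np.tile(rng.standard_normal((60, 7, 1, 2)), (1, 1, 8, 1))
    ft = _manual_features(task, base)
    ft.normalized = True
    labels = np.tile(["a", "b", "c"], 20)
    selected, trace = forward_select_channels(ft, labels, seed=2)
    # identical channels: peak at the first, then three non-improving adds
    assert len(trace) <= 4
    assert len(selected) >= 1


def test_selection_trace_peak_matches_returned_set():
    ft, labels = _planted_features(seed=12)
    selected, trace = forward_select_channels(ft, labels, seed=3)
    accs = [a for _, a in trace]
    assert len(selected) == int(np.argmax(accs)) + 1


# ---------------------------------------------------------------------------
# decoding


def test_perfectly_separable_features_decode_at_ceiling():
    ft, labels = _planted_features(effect=8.0, seed=13)
    res = decode_DA(ft, labels, ["C3"], seed=4)
    assert res.mean_da == 1.0
    assert len(res.fold_accuracies) == 10


def test_shuffled_labels_decode_at_chance():
    ft, labels = _planted_features(effect=8.0, seed=14)
    rng = np.random.default_rng(15)
    shuffled = rng.permutation(labels)
    res = decode_DA(ft, shuffled, ["C3", "C5"], seed=5)
    ci = 1.96 * np.sqrt((1 / 3) * (2 / 3) / 60)
    assert abs(res.mean_da - 1 / 3) < ci


def test_decode_requires_normalized_features():
    ft, labels = _planted_features()
    ft.normalized = False
    with pytest.raises(ValueError, match="normalize"):
        decode_DA(ft, labels, ["C0"], seed=0)


def test_sda_uses_band_subsets():
    """An effect planted only in the delta feature yields high delta SDA and
    chance-level beta SDA; the high-gamma set spans five sub-bins."""
    rng = np.random.default_rng(16)
    n_trials, n_ch = 60, 4
    labels = np.tile(["a", "b", "c"], 20)
    task = rng.standard_normal((n_trials, 15, n_ch, 9))
    shift = {"a": -4.0, "b": 0.0, "c": 4.0}
    for i, lab in enumerate(labels):
        task[i, :, 1, 0] += shift[lab]  # delta band of channel 1 only
    base = rng.standard_normal((n_trials, 7, n_ch, 9))
    ft = _manual_features(task, base)
    ft.normalized = True
    sda = decode_SDA(ft, labels, ["C1"], seed=6)
    assert set(sda) == set(SDA_BANDS)
    assert sda["delta"].mean_da > 0.9
    assert sda["beta"].mean_da < 0.55
    assert len(SDA_BANDS["high_gamma"]) == 5


def test_trial_vote_decoding_runs():
    ft, labels = _planted_features(effect=8.0, seed=17)
    res = decode_DA(ft, labels, ["C3"], seed=7, trial_vote=True)
    assert res.mean_da == 1.0


def test_nested_decoding_is_leakage_free_and_recovers_planted_channel():
    """With channel selection repeated inside each training fold, shuffled
    labels decode at chance (the no-leakage guarantee) while planted
    features still decode well and the informative channel appears in every
    fold's selection union."""
    from seegbench.decode import decode_DA_nested

    ft, labels = _planted_features(effect=2.0, seed=21)
    res = decode_DA_nested(ft, labels, seed=8)
    assert res.mean_da > 0.8
    assert "C3" in res.selected_channels
    assert len(res.fold_accuracies) == 10

    shuffled = np.random.default_rng(22).permutation(labels)
    null = decode_DA_nested(ft, shuffled, seed=9)
    ci = 1.96 * np.sqrt((1 / 3) * (2 / 3) / 60)
    assert abs(null.mean_da - 1 / 3) < 2 * ci
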