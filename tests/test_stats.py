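import numpy as np
import pytest
from scipy import signal, stats as sps

from seegbench.io_montage import ChannelInfo, EpochSet
from seegbench.stats import (SIGNIFICANCE_LEVEL, band_significance,
                             compute_TFD, fit_relevance_relation,
                             group_compare, task_relevance,
                             timefreq_decompose, TFDMap)


def _epochs(data, fs=500.0, labels=None):
    n_ch = data.shape[1]
    montage = [ChannelInfo(f"S0C{i+1}", "S0", i + 1) for i in range(n_ch)]
    if labels is None:
        labels = ["g"] * data.shape[0]
    return EpochSet(data=data, fs=fs, montage=montage, labels=labels)


# ---------------------------------------------------------------------------
# time-frequency decomposition


def test_tone_produces_ridge_at_its_frequency():
    fs = 500.0
    t = np.arange(int(8 * fs)) / fs
    tone = np.sin(2 * np.pi * 20.0 * t)
    ep = _epochs(np.tile(tone, (2, 1, 1)), fs)
    power, times, freqs = timefreq_decompose(ep, 0)
    ridge = freqs[np.argmax(power.mean(axis=(0, 1)))]
    assert abs(ridge - 20.0) < 1.0
    assert times[0] >= -4.0 and times[-1] <= 4.0


def test_zero_signal_gives_zero_power():
    ep = _epochs(np.zeros((1, 1, 4000)))
    power, _, _ = timefreq_decompose(ep, 0)
    assert np.all(power == 0.0)


def test_spectrogram_satisfies_parseval_per_frame():
    """Summed two-sided spectral power of each frame equals nfft times the
    windowed time-domain energy (DFT Parseval), within 5%."""
    rng = np.random.default_rng(0)
    fs = 500.0
    x = rng.standard_normal((1, 1, int(8 * fs)))
    ep = _epochs(x, fs)
    nfft = int(2 * fs)
    power, times, freqs = timefreq_decompose(ep, 0, fmax=fs / 2, nfft=nfft)
    # reconstruct the windowed frames
    wlen, hop = int(0.5 * fs), int(0.05 * fs)
    win = signal.windows.hann(wlen, sym=False)
    n_frames = power.shape[1]
    for k in range(0, n_frames, 30):
        frame = x[0, 0, k * hop:k * hop + wlen] * win
        expected = nfft * np.sum(frame ** 2)
        # one-sided -> double interior bins
        spec = power[0, k]
        total = spec[0] + 2 * spec[1:-1].sum() + spec[-1]
        assert total == pytest.approx(expected, rel=0.05)


# ---------------------------------------------------------------------------
# TFD


def test_identical_methods_give_zero_tfd_map():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((6, 1, 4000))
    ep = _epochs(data)
    tfd = compute_TFD(ep, _epochs(data.copy()), ["S0C1"])
    assert np.all(tfd.grid == 0.0)


def _paired_epochs_with_delta_difference(n_trials=40, fs=500.0, boost=2.5,
                                         seed=2):
    """Two epoch sets sharing identical noise; method B additionally carries
    a delta-band component during the task period only."""
    rng = np.random.default_rng(seed)
    n = int(8 * fs)
    base = rng.standard_normal((n_trials, 1, n))
    sos = signal.butter(4, (1.0, 4.0), btype="bandpass", fs=fs, output="sos")
    extra = signal.sosfiltfilt(sos, rng.standard_normal((n_trials, n)), axis=-1)
    gate = np.zeros(n)
    gate[int(4 * fs):] = 1.0  # task period [0, 4) s
    b = base.copy()
    b[:, 0, :] += boost * extra * gate
    return _epochs(base, fs), _epochs(b, fs)


def test_planted_delta_task_difference_localizes_in_tfd():
    ep_a, ep_b = _paired_epochs_with_delta_difference()
    tfd = compute_TFD(ep_a, ep_b, ["S0C1"])
    delta_task = band_significance(tfd, (1.0, 4.0), (0.5, 3.5))
    delta_base = band_significance(tfd, (1.0, 4.0), (-4.0, -2.0))
    beta_task = band_significance(tfd, (13.0, 30.0), (0.5, 3.5))
    assert delta_task > SIGNIFICANCE_LEVEL
    assert delta_base < SIGNIFICANCE_LEVEL
    assert beta_task < SIGNIFICANCE_LEVEL


def test_tfd_is_symmetric_in_its_arguments():
    ep_a, ep_b = _paired_epochs_with_delta_difference(n_trials=12)
    g1 = compute_TFD(ep_a, ep_b, ["S0C1"]).grid
    g2 = compute_TFD(ep_b, ep_a, ["S0C1"]).grid
    np.testing.assert_allclose(g1, g2, atol=1e-10)


def test_tfd_null_false_positive_rate_is_controlled():
    rng = np.random.default_rng(3)
    a = _epochs(rng.standard_normal((20, 2, 4000)))
    b = _epochs(rng.standard_normal((20, 2, 4000)))
    tfd = compute_TFD(a, b, ["S0C1", "S0C2"])
    frac = np.mean(tfd.grid > SIGNIFICANCE_LEVEL)
    assert frac <= 0.05


# ---------------------------------------------------------------------------
# task relevance


def _epochs_with_band_modulation(factor, band=(8.0, 13.0), n_trials=20,
                                 fs=500.0, seed=4):
    rng = np.random.default_rng(seed)
    n = int(8 * fs)
    data = rng.standard_normal((n_trials, 1, n))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.standard_normal((n_trials, n)),
                                 axis=-1)
    gate = np.zeros(n)
    gate[int(4 * fs):] = 1.0
    data[:, 0, :] += factor * carrier * gate
    return _epochs(data, fs)


def test_planted_power_increase_is_task_relevant():
    ep = _epochs_with_band_modulation(3.0)
    tr = task_relevance(ep, 0, (8.0, 13.0), n_perm=500, seed=5,
                        n_comparisons=10)
    assert tr.significant
    assert tr.r > 0.5


def test_equal_task_and_baseline_power_gives_zero_correlation():
    """When per-trial task power ties the baseline power exactly, the
    label correlation is exactly zero; with statistically identical (but
    not sample-identical) windows it stays near zero."""
    from seegbench.stats import _spearman_binary

    rng = np.random.default_rng(6)
    per_trial = rng.random(10)
    values = np.concatenate([per_trial, per_trial])
    labels = np.concatenate([np.zeros(10), np.ones(10)])
    assert _spearman_binary(values, labels) == pytest.approx(0.0, abs=1e-12)

    ep = _epochs(rng.standard_normal((30, 1, 4000)))
    tr = task_relevance(ep, 0, (8.0, 13.0), n_perm=200, seed=7)
    assert abs(tr.r) < 0.3 and not tr.significant


def test_constant_power_is_flagged_non_significant():
    ep = _epochs(np.zeros((8, 1, 4000)))
    tr = task_relevance(ep, 0, (8.0, 13.0), n_perm=100, seed=8)
    assert not tr.significant
    assert tr.p == 1.0


def test_empirical_permutation_mode_matches_gaussian_roughly():
    ep = _epochs_with_band_modulation(0.0, seed=9)
    g = task_relevance(ep, 0, (8.0, 13.0), n_perm=500, seed=10, mode="gaussian")
    e = task_relevance(ep, 0, (8.0, 13.0), n_perm=500, seed=10, mode="empirical")
    assert not g.significant and not e.significant


# ---------------------------------------------------------------------------
# band significance


def test_band_significance_reference_cases():
    times = np.linspace(-4, 4, 81)
    freqs = np.linspace(0, 195, 40)
    uniform = TFDMap(grid=np.full((81, 40), 1.7), times=times, freqs=freqs,
                     n_channels=1)
    assert band_significance(uniform, (0, 50)) == pytest.approx(1.7)

    baseline_only = TFDMap(grid=np.zeros((81, 40)), times=times, freqs=freqs,
                           n_channels=1)
    baseline_only.grid[times < -2.0, :] = 3.0
    assert band_significance(baseline_only, (0, 50), (0.0, 4.0)) == 0.0

    checker = TFDMap(grid=np.indices((81, 40)).sum(axis=0) % 2.0, times=times,
                     freqs=freqs, n_channels=1)
    val = band_significance(checker, (0, 195), (-4.0, 4.0))
    assert val == pytest.approx(0.5, abs=0.01)

    with pytest.raises(ValueError):
        band_significance(uniform, (300.0, 400.0))


# ---------------------------------------------------------------------------
# linear fit + F-test


def test_exact_line_fits_perfectly():
    x = np.arange(10.0)
    fit = fit_relevance_relation(x, 2.0 * x)
    assert fit.slope == pytest.approx(2.0)
    assert fit.r_square == pytest.approx(1.0)
    assert fit.p_value == pytest.approx(0.0, abs=1e-12)


def test_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(11)
    for _ in range(25):
        n = rng.integers(3, 21)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        fit = fit_relevance_relation(x, y)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)
        resid = y - X @ beta
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1 - np.sum(resid ** 2) / sst
        assert fit.r_square == pytest.approx(r2, abs=1e-8)


def test_fit_null_p_values_are_uniform():
    rng = np.random.default_rng(12)
    ps = [fit_relevance_relation(rng.standard_normal(40),
                                 rng.standard_normal(40)).p_value
          for _ in range(200)]
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_fit_zero_x_variance_is_flagged():
    fit = fit_relevance_relation(np.ones(5), np.arange(5.0))
    assert not fit.valid
    assert np.isnan(fit.slope)


# ---------------------------------------------------------------------------
# group comparisons


def test_group_compare_reference_cases():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert group_compare(a, a) == 1.0

    rng = np.random.default_rng(13)
    base = 0.8 + 0.01 * rng.standard_normal(8)
    p = group_compare(base * 1.1, base)
    # closed form: t = mean(d)/(sd(d)/sqrt(n))
    d = base * 0.1
    t = d.mean() / (d.std(ddof=1) / np.sqrt(8))
    expected = 2 * sps.t.sf(abs(t), 7)
    assert p == pytest.approx(expected, rel=1e-9)
    assert p < 0.05


def test_group_compare_bonferroni_arithmetic():
    rng = np.random.default_rng(14)
    a = rng.standard_normal(10)
    b = a + 0.5 + 0.5 * rng.standard_normal(10)
    p_raw = group_compare(b, a)
    p_corr = group_compare(b, a, bonferroni=5)
    assert p_corr == pytest.approx(min(1.0, 5 * p_raw))
    with pytest.raises(ValueError):
        group_compare([1.0], [2.0])
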