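"""Comparison statistics between re-referencing methods.

Three indices quantify how two cleaning methods differ and where:

* TFD (time-frequency difference): per time-frequency cell, a trial-wise
  paired t-test between the log spectrograms of the two methods, Bonferroni
  corrected and expressed as -log10(p), averaged over the union of the two
  methods' selected channels.  Significance threshold -log10(0.05) ~ 1.301.
* task relevance: per channel and band, the Spearman correlation between
  trial-wise Hilbert band power and the baseline/task label, with a
  label-permutation test (Gaussian fit to 1000 surrogate r values,
  one-sided parametric p).
* relation between the two: ordinary least-squares line of band-averaged
  TFD against task relevance across channels, with an F-test for the
  regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats as sps

from .io_montage import EpochSet

__all__ = [
    "TFDMap",
    "TaskRelevance",
    "FitResult",
    "RELEVANCE_BANDS",
    "timefreq_decompose",
    "compute_TFD",
    "task_relevance",
    "band_significance",
    "fit_relevance_relation",
    "group_compare",
]

SIGNIFICANCE_LEVEL = -np.log10(0.05)

#: analysis bands for task relevance and band-averaged TFD
RELEVANCE_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "high_gamma": (60.0, 195.0),
}


@dataclass
class TFDMap:
    grid: np.ndarray  # time x frequency, -log10(corrected p)
    times: np.ndarray
    freqs: np.ndarray
    n_channels: int
    pair: tuple[str, str] = ("A", "B")

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        return (self.freqs >= band[0]) & (self.freqs < band[1])

    def time_mask(self, period: tuple[float, float]) -> np.ndarray:
        return (self.times >= period[0]) & (self.times < period[1])


@dataclass
class TaskRelevance:
    channel_id: str
    band: str
    r: float
    p: float
    neg_log10_p: float
    significant: bool


@dataclass
class FitResult:
    slope: float
    intercept: float
    r_square: float
    f_stat: float
    p_value: float
    n: int
    valid: bool = True


# ---------------------------------------------------------------------------
# Time-frequency decomposition


def timefreq_decompose(epochs: EpochSet, channel: int,
                       window_s: float = 0.5, hop_s: float = 0.05,
                       fmax: float = 195.0, nfft: int | None = None):
    """Hanning-tapered short-time FFT power of one channel, per trial.

    Returns ``(power, times, freqs)`` with ``power`` of shape
    trials x times x freqs, frequencies limited to [0, fmax], and times the
    window centers in epoch time.  ``nfft`` defaults to a 0.5-Hz zero-padded
    grid (2 * fs).
    """
    fs = epochs.fs
    wlen = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if wlen > epochs.n_times:
        raise ValueError("window longer than epoch")
    nfft = nfft or int(2 * fs)
    win = signal.windows.hann(wlen, sym=False)
    x = epochs.data[:, channel, :]
    n_frames = (epochs.n_times - wlen) // hop + 1
    starts = np.arange(n_frames) * hop
    frames = np.lib.stride_tricks.sliding_window_view(x, wlen, axis=-1)[:, starts]
    spec = np.fft.rfft(frames * win, n=nfft, axis=-1)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    keep = freqs <= fmax
    power = np.abs(spec[..., keep]) ** 2
    times = epochs.tmin + (starts + wlen / 2) / fs
    return power, times, freqs[keep]


def compute_TFD(epochs_a: EpochSet, epochs_b: EpochSet, channel_union,
                bonferroni: int | None = None, log_floor: float = 1e-30,
                baseline_correct: bool = True, **tf_kwargs) -> TFDMap:
    """Time-frequency difference map between two cleaning methods.

    For each channel in ``channel_union`` (channel ids present in both
    epoch sets) a trial-wise paired t-test is run per (time, frequency) cell
    on log power; p-values are Bonferroni corrected (by the union size
    unless ``bonferroni`` overrides it, capped at 1) and mapped to
    -log10(p); the TFD map is the mean over channels.  Cells with
    zero-variance differences are assigned p = 1.

    With ``baseline_correct`` (default) each trial's log spectrogram is
    referenced to its own baseline-period mean per frequency before the
    test, so the map reflects task-related differences between the methods
    rather than the static power offset any re-referencing introduces.
    """
    channel_union = list(channel_union)
    if not channel_union:
        raise ValueError("channel union is empty")
    if epochs_a.n_trials != epochs_b.n_trials:
        raise ValueError("paired epochs need the same trials")
    factor = bonferroni if bonferroni is not None else len(channel_union)
    idx_a = {c: i for i, c in enumerate(epochs_a.channel_ids)}
    idx_b = {c: i for i, c in enumerate(epochs_b.channel_ids)}
    acc = None
    n = epochs_a.n_trials
    for cid in channel_union:
        if cid not in idx_a or cid not in idx_b:
            raise ValueError(f"channel {cid!r} missing from one method's epochs")
        pa, times, freqs = timefreq_decompose(epochs_a, idx_a[cid], **tf_kwargs)
        pb, _, _ = timefreq_decompose(epochs_b, idx_b[cid], **tf_kwargs)
        la = np.log(np.maximum(pa, log_floor))
        lb = np.log(np.maximum(pb, log_floor))
        if baseline_correct:
            b0, b1 = epochs_a.baseline_window
            bmask = (times >= b0) & (times < b1)
            if bmask.any():
                la = la - la[:, bmask].mean(axis=1, keepdims=True)
                lb = lb - lb[:, bmask].mean(axis=1, keepdims=True)
        d = la - lb
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
        p[~np.isfinite(t)] = 1.0  # zero-variance cells
        p_corr = np.minimum(p * factor, 1.0)
        neglog = -np.log10(np.maximum(p_corr, 1e-300))
        acc = neglog if acc is None else acc + neglog
    grid = acc / len(channel_union)
    return TFDMap(grid=grid, times=times, freqs=freqs,
                  n_channels=len(channel_union))


# ---------------------------------------------------------------------------
# Task relevance (Hilbert band power + label permutation)


def _spearman_binary(values: np.ndarray, labels: np.ndarray) -> float:
    ranks = sps.rankdata(values)
    if np.all(ranks == ranks[0]):
        return np.nan
    return float(np.corrcoef(ranks, labels)[0, 1])


def task_relevance(epochs: EpochSet, channel: int, band: tuple[float, float],
                   band_name: str = "", n_perm: int = 1000, seed: int = 0,
                   n_comparisons: int = 1, alpha: float = 0.05,
                   mode: str = "gaussian", edge_guard_s: float = 0.25) -> TaskRelevance:
    """Permutation-based task relevance of one channel in one band.

    The channel is band-passed (sixth-order Butterworth), band power is the
    squared magnitude of the Hilbert transform, averaged per trial over the
    baseline and task windows separately.  The observed Spearman r between
    the 2 x n_trials power values and their 0/1 (baseline/task) labels is
    compared to ``n_perm`` label permutations; the default ``gaussian`` mode
    fits a normal distribution to the surrogate r values and reports the
    one-sided parametric p (avoiding the 1/(n_perm+1) floor); ``empirical``
    uses the surrogate percentile directly.  Bonferroni correction divides
    alpha by ``n_comparisons`` (number of channels tested).
    """
    if not 0 < band[0] < band[1] < epochs.fs / 2:
        raise ValueError("band must lie inside (0, fs/2)")
    if mode not in ("gaussian", "empirical"):
        raise ValueError("mode must be 'gaussian' or 'empirical'")
    sos = signal.butter(6, band, btype="bandpass", fs=epochs.fs, output="sos")
    x = signal.sosfiltfilt(sos, epochs.data[:, channel, :], axis=-1)
    power = np.abs(signal.hilbert(x, axis=-1)) ** 2

    # windows touching the epoch edges are trimmed by a guard interval:
    # filtfilt/Hilbert edge transients otherwise bias the window means
    t_lo, t_hi = epochs.times[0], epochs.times[0] + epochs.n_times / epochs.fs

    def window_mean(window):
        lo = max(window[0], t_lo + edge_guard_s)
        hi = min(window[1], t_hi - edge_guard_s)
        return power[:, epochs.sample_slice((lo, hi))].mean(axis=-1)

    base = window_mean(epochs.baseline_window)
    task = window_mean(epochs.task_window)
    values = np.concatenate([base, task])
    labels = np.concatenate([np.zeros(len(base)), np.ones(len(task))])

    r_obs = _spearman_binary(values, labels)
    cid = epochs.channel_ids[channel]
    if not np.isfinite(r_obs):
        return TaskRelevance(cid, band_name, np.nan, 1.0, 0.0, False)

    rng = np.random.default_rng(seed)
    ranks = sps.rankdata(values)
    zr = (ranks - ranks.mean()) / ranks.std()
    r_perm = np.empty(n_perm)
    lab = labels.copy()
    for i in range(n_perm):
        rng.shuffle(lab)
        zl = (lab - lab.mean()) / lab.std()
        r_perm[i] = np.mean(zr * zl)
    if mode == "gaussian":
        mu, sd = r_perm.mean(), r_perm.std(ddof=1)
        p = float(sps.norm.sf((r_obs - mu) / sd)) if sd > 0 else 1.0
    else:
        p = float((1 + np.sum(r_perm >= r_obs)) / (n_perm + 1))
    p = min(max(p, 1e-300), 1.0)
    significant = p < alpha / max(n_comparisons, 1)
    return TaskRelevance(cid, band_name, r_obs, p, float(-np.log10(p)),
                         bool(significant))


def band_significance(tfd: TFDMap, band: tuple[float, float],
                      period: tuple[float, float] = (0.0, 4.0)) -> float:
    """Mean TFD value inside ``band`` during ``period`` (the task stage)."""
    fm = tfd.band_mask(band)
    tm = tfd.time_mask(period)
    if not fm.any() or not tm.any():
        raise ValueError("empty band or period slice")
    return float(tfd.grid[np.ix_(tm, fm)].mean())


# ---------------------------------------------------------------------------
# Regression of band significance on task relevance


def fit_relevance_relation(x, y) -> FitResult:
    """First-order least-squares fit of y on x with an F-test.

    F = MSR/MSE with (1, n-2) degrees of freedom; R^2 = SSR/SST.  A zero
    x-variance makes the fit undefined (flagged, not raised).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        return FitResult(np.nan, np.nan, np.nan, np.nan, np.nan, n, valid=False)
    res = sps.linregress(x, y)
    r2 = res.rvalue ** 2
    if r2 >= 1.0:
        return FitResult(res.slope, res.intercept, 1.0, np.inf, 0.0, n)
    f_stat = r2 * (n - 2) / (1.0 - r2)
    p = float(sps.f.sf(f_stat, 1, n - 2))
    return FitResult(float(res.slope), float(res.intercept), float(r2),
                     float(f_stat), p, n)


def group_compare(a, b, bonferroni: int = 1) -> float:
    """Two-sided paired t-test between per-subject metrics of two methods.

    Identical vectors (zero-variance differences) return p = 1 by
    convention.  ``bonferroni`` multiplies p (capped at 1) for families of
    band comparisons.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired vectors of length >= 2")
    d = a - b
    if np.all(d == d[0]) and d.std() == 0:
        if d[0] == 0:
            return 1.0
        # constant nonzero difference: t is infinite, p -> 0
        return min(1.0, 0.0 * bonferroni)
    t, p = sps.ttest_rel(a, b)
    return float(min(p * bonferroni, 1.0))
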