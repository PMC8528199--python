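"""Preprocessing: resampling, line-noise channel rejection, comb-notch and
band-pass filtering, EMG movement-onset detection, and epoch alignment.

All IIR filters are applied forward-backward (zero phase) so that detected
onset times are not shifted by filter group delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .io_montage import EpochSet, EventTable, Recording

logger = logging.getLogger("seegbench")

__all__ = [
    "PreprocConfig",
    "resample",
    "detect_line_noise_channels",
    "notch_and_bandpass",
    "detect_movement_onset",
    "epoch",
    "preprocess_subject",
]


@dataclass
class PreprocConfig:
    """Parameters of the preprocessing chain.

    ``mad_multiplier`` scales the mean absolute deviation in the line-noise
    channel-rejection threshold (median + k * MAD).  ``peak_bandwidth_hz``
    is the -3 dB bandwidth of the 50-Hz peak filter used to isolate the line
    component.  ``mad_mode`` selects whether the threshold statistics pool
    the absolute filtered samples of all channels (``pooled``) or the
    per-channel summary metrics (``per_channel``).
    """

    target_fs: float = 1000.0
    notch_base: float = 50.0
    peak_filter_order: int = 2
    peak_bandwidth_hz: float = 2.0
    mad_multiplier: float = 10.0
    mad_mode: str = "pooled"
    notch_q: float = 70.0
    bandpass: tuple = (0.5, 400.0)
    bandpass_order: int = 4
    emg_band: tuple = (55.0, 145.0)
    emg_order: int = 6
    task_multiplier: float = 1.5
    envelope_smooth_s: float = 0.1
    envelope_k: float = 3.0
    envelope_hold_s: float = 0.05  # envelope must stay above threshold this
    # long; rejects isolated noise excursions that would fire the onset early
    rest_window: tuple = (-4.0, -1.0)  # relative to cue, for the EMG baseline
    epoch_window: tuple = (-4.0, 4.0)
    task_s: float = 5.0

    def validate(self) -> None:
        if self.bandpass[1] >= self.target_fs / 2:
            raise ValueError("bandpass upper edge must be below Nyquist")
        if self.mad_multiplier <= 0 or self.task_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if self.mad_mode not in ("pooled", "per_channel"):
            raise ValueError("mad_mode must be 'pooled' or 'per_channel'")


def resample(recording: Recording, target_fs: float) -> Recording:
    """Polyphase (anti-aliased) resampling to ``target_fs``.

    Only downsampling (or identity) is supported; event times are in seconds
    and therefore unchanged.
    """
    if target_fs > recording.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == recording.fs:
        return recording
    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(recording.data, up, down, axis=-1)
    emg = None
    if recording.emg is not None:
        emg = signal.resample_poly(recording.emg, up, down, axis=-1)
    return Recording(data=data, fs=float(target_fs), montage=list(recording.montage),
                     emg=emg, line_freq=recording.line_freq)


def _peak_filter_sos(fs: float, config: PreprocConfig) -> np.ndarray:
    q = config.notch_base / config.peak_bandwidth_hz
    b, a = signal.iirpeak(config.notch_base, Q=q, fs=fs)
    return signal.tf2sos(b, a)


def detect_line_noise_channels(recording: Recording,
                               config: PreprocConfig | None = None):
    """Flag channels with excessive 50-Hz line noise.

    Each channel is passed through a second-order peak filter at the line
    frequency; the per-channel metric is the mean absolute value of the
    filtered signal.  The rejection threshold is
    ``median + mad_multiplier * MAD`` (MAD = mean absolute deviation)
    computed, in the default ``pooled`` mode, over the concatenated absolute
    filtered samples of all channels.  Channels whose metric strictly
    exceeds the threshold are flagged.

    Returns ``(bad_ids, metrics, threshold)`` where ``metrics`` aligns with
    the montage.
    """
    config = config or PreprocConfig()
    config.validate()
    if recording.n_channels < 2:
        raise ValueError("need at least 2 channels for line-noise screening")
    sos = _peak_filter_sos(recording.fs, config)
    filtered = signal.sosfiltfilt(sos, recording.data, axis=-1)
    abs_filtered = np.abs(filtered)
    metrics = abs_filtered.mean(axis=-1)
    if config.mad_mode == "pooled":
        pooled = abs_filtered.ravel()
    else:
        pooled = metrics
    med = np.median(pooled)
    mad = np.mean(np.abs(pooled - np.mean(pooled)))
    threshold = med + config.mad_multiplier * mad
    flagged = metrics > threshold
    if flagged.all():
        raise ValueError("all channels flagged as line-noise contaminated")
    bad_ids = [recording.montage[i].channel_id for i in np.flatnonzero(flagged)]
    return bad_ids, metrics, float(threshold)


def comb_notch(recording: Recording,
               config: PreprocConfig | None = None) -> Recording:
    """Zero-phase comb notch at the line frequency and its harmonics (up to
    the band-pass edge).  Idempotent in the stop-band sense: notching an
    already-notched signal barely changes its RMS."""
    config = config or PreprocConfig()
    fs = recording.fs
    data = recording.data
    k = 1
    while config.notch_base * k <= min(config.bandpass[1], 0.95 * fs / 2):
        # Q scaled by harmonic -> constant absolute notch bandwidth
        # (notch_base/notch_q Hz at every harmonic)
        b, a = signal.iirnotch(config.notch_base * k, Q=config.notch_q * k,
                               fs=fs)
        data = signal.filtfilt(b, a, data, axis=-1)
        k += 1
    return Recording(data=data, fs=fs, montage=list(recording.montage),
                     emg=recording.emg, line_freq=recording.line_freq)


def notch_and_bandpass(recording: Recording,
                       config: PreprocConfig | None = None) -> Recording:
    """50-Hz comb notch (harmonics up to the band-pass edge) then 0.5-400 Hz
    fourth-order Butterworth band-pass, both zero-phase."""
    config = config or PreprocConfig()
    rec = comb_notch(recording, config)
    sos = signal.butter(config.bandpass_order, config.bandpass,
                        btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return Recording(data=data, fs=rec.fs, montage=list(rec.montage),
                     emg=rec.emg, line_freq=rec.line_freq)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Trailing (causal) moving average, so a step edge starts rising at the
    edge rather than half a window early — keeps onset estimates unbiased."""
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="full")[: len(x)]


def detect_movement_onset(emg: np.ndarray, events: EventTable, fs: float,
                          config: PreprocConfig | None = None) -> EventTable:
    """Detect per-trial movement onsets from the surface-EMG pair.

    The two EMG channels are band-passed (55-145 Hz, sixth-order
    Butterworth) and subtracted.  Two candidate onsets are found per trial:

    * point A — first post-cue sample where the smoothed envelope (magnitude
      of the analytic signal, 100-ms moving average) exceeds an adaptive
      threshold (rest-period mean + k * sd of the envelope);
    * point B — first post-cue sample where the absolute EMG exceeds
      1.5x its mean absolute value over the task stage.

    The earlier of the two is the movement onset.  Trials with no crossing
    keep ``onset_time_s = NaN`` and are logged as flagged.
    """
    config = config or PreprocConfig()
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    if emg.shape[0] != 2:
        raise ValueError("expected exactly 2 EMG channels")
    sos = signal.butter(config.emg_order, config.emg_band, btype="bandpass",
                        fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, emg, axis=-1)
    diff = filt[0] - filt[1]
    envelope = np.abs(signal.hilbert(diff))
    envelope = _moving_average(envelope, int(round(config.envelope_smooth_s * fs)))
    n = len(diff)

    onsets = np.full(len(events), np.nan)
    for i in range(len(events)):
        cue = events.cue_time_s[i]
        c = int(round(cue * fs))
        r0 = max(int(round((cue + config.rest_window[0]) * fs)), 0)
        r1 = max(int(round((cue + config.rest_window[1]) * fs)), r0 + 1)
        t1 = min(int(round((cue + config.task_s) * fs)), n)
        if c >= n or t1 <= c:
            logger.warning("trial %d: cue outside recording, flagged", i)
            continue
        rest_env = envelope[r0:r1]
        thresh_a = rest_env.mean() + config.envelope_k * rest_env.std()
        seg_env = envelope[c:t1]
        above = seg_env > thresh_a
        hold = max(int(round(config.envelope_hold_s * fs)), 1)
        if hold > 1 and above.any():
            # sustained crossing: above-threshold for `hold` consecutive samples
            run = np.convolve(above.astype(int), np.ones(hold, dtype=int),
                              mode="valid")
            cross_a = np.flatnonzero(run == hold)
        else:
            cross_a = np.flatnonzero(above)
        seg_abs = np.abs(diff[c:t1])
        thresh_b = config.task_multiplier * seg_abs.mean()
        cross_b = np.flatnonzero(seg_abs > thresh_b)
        candidates = []
        if cross_a.size:
            candidates.append(cross_a[0])
        if cross_b.size:
            candidates.append(cross_b[0])
        if not candidates:
            logger.warning("trial %d: no EMG onset crossing, flagged", i)
            continue
        onsets[i] = (c + min(candidates)) / fs
    return EventTable(
        trial_id=events.trial_id,
        label=events.label,
        cue_time_s=events.cue_time_s,
        onset_time_s=onsets,
    )


def epoch(recording: Recording, events: EventTable,
          window: tuple[float, float] = (-4.0, 4.0),
          exclude_channels: list[str] | set | None = None) -> EpochSet:
    """Slice [-4, 4) s epochs around the detected movement onsets.

    Trials with no detected onset, or whose window crosses the recording
    edges, are dropped (and logged), never padded.  Channels listed in
    ``exclude_channels`` (bad channels) are removed.
    """
    if events.onset_time_s is None or np.all(np.isnan(events.onset_time_s)):
        raise ValueError("onsets must be detected before epoching")
    exclude = set(exclude_channels or ())
    keep_ch = [i for i, c in enumerate(recording.montage)
               if c.channel_id not in exclude]
    montage = [recording.montage[i] for i in keep_ch]
    n_len = int(round((window[1] - window[0]) * recording.fs))
    sub = recording.data[keep_ch]
    trials, labels, trial_ids = [], [], []
    for i in range(len(events)):
        onset = events.onset_time_s[i]
        if not np.isfinite(onset):
            logger.info("trial %d dropped: no onset", i)
            continue
        i0 = int(round((onset + window[0]) * recording.fs))
        i1 = i0 + n_len
        if i0 < 0 or i1 > recording.n_samples:
            logger.info("trial %d dropped: window outside recording", i)
            continue
        trials.append(sub[:, i0:i1])
        labels.append(events.label[i])
        trial_ids.append(events.trial_id[i])
    if not trials:
        raise ValueError("no valid trials to epoch")
    return EpochSet(
        data=np.stack(trials),
        fs=recording.fs,
        montage=montage,
        labels=np.array(labels),
        tmin=window[0],
        trial_id=np.array(trial_ids),
    )


def preprocess_subject(recording: Recording, events: EventTable,
                       config: PreprocConfig | None = None):
    """Full preprocessing chain for one subject.

    resample -> line-noise channel rejection -> comb notch + band-pass ->
    EMG onset detection -> epoching around onsets.  Returns
    ``(EpochSet, events_with_onsets, bad_channel_ids)``.
    """
    config = config or PreprocConfig()
    config.validate()
    rec = resample(recording, min(config.target_fs, recording.fs))
    bad_ids, _, _ = detect_line_noise_channels(rec, config)
    rec = notch_and_bandpass(rec, config)
    if rec.emg is None:
        raise ValueError("recording has no EMG channels for onset detection")
    events = detect_movement_onset(rec.emg, events, rec.fs, config)
    epochs = epoch(rec, events, config.epoch_window, exclude_channels=bad_ids)
    return epochs, events, bad_ids
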