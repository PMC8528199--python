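"""Synthetic SEEG + EMG generator for the cued three-gesture experiment.

Emulates the statistical structure the downstream analysis assumes: a
continuous recording made of concatenated 10-s trials (4 s rest, 1 s cue,
5 s task), depth-electrode montage geometry, layered noise (global
common-mode, per-shaft shared, per-channel pink), 50-Hz line noise with
harmonics and occasional extreme channels, class-specific band-limited power
modulation on a sparse set of informative channels, and a surface-EMG pair
whose burst starts at the true movement onset (Gaussian jitter after the
gesture cue).

The generator returns the ground truth (true onsets, informative channels,
planted bad channels) so every downstream stage can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_montage import ChannelInfo, EventTable, Recording

__all__ = ["SimConfig", "GroundTruth", "simulate_subject", "simulate_cohort",
           "make_montage"]


def _default_effect_sizes() -> dict:
    # multiplicative power gain of the channel-private in-band component
    # during the task stage, per gesture class; free parameters of the
    # simulation (see docs/methods.md)
    return {
        "delta": {"scissor": 1.6, "fist": 2.5, "thumb": 4.0},
        "high_gamma": {"scissor": 2.0, "fist": 3.2, "thumb": 5.0},
    }


EFFECT_BANDS = {"delta": (1.0, 4.0), "high_gamma": (70.0, 150.0)}


@dataclass
class SimConfig:
    """Configuration of one simulated subject.

    Trial structure and onset statistics follow the cued-gesture protocol
    (4 s rest, 1 s cue, 5 s task; movement onset 0.72 +/- 0.38 s after the
    gesture picture).  Noise variances are standard deviations in microvolts
    of the three layered components.  ``line_noise_bad_channels`` channels
    get their 50-Hz amplitude multiplied by ``line_noise_bad_multiplier``.
    """

    n_shafts: int = 10
    contacts_per_shaft: int = 12
    fs: float = 1000.0
    n_trials_per_class: int = 20
    class_labels: tuple = ("scissor", "fist", "thumb")
    rest_s: float = 4.0
    cue_s: float = 1.0
    task_s: float = 5.0
    onset_jitter_mean: float = 0.72
    onset_jitter_sd: float = 0.38
    onset_jitter_clip: tuple = (0.1, 2.0)
    n_informative: int = 3
    informative_channels: list | None = None
    effect_sizes: dict = field(default_factory=_default_effect_sizes)
    sd_common: float = 50.0
    sd_shaft: float = 15.0
    sd_channel: float = 5.0
    # per-channel coupling of the shared noise components: a smooth static
    # spatial profile (shaft offset + gradient along the shaft + small
    # channel jitter) plus a slow temporal drift, emulating heterogeneous
    # electrode coupling / impedance drift.  All zero -> shared noise is
    # identical on every channel.
    couple_shaft_sd: float = 0.2
    couple_grad: float = 0.3
    couple_channel_sd: float = 0.03
    couple_shaft_drift_sd: float = 0.15
    couple_channel_drift_sd: float = 0.05
    couple_drift_knot_s: float = 2.5
    # correlation between neighboring contacts of the within-shaft noise
    # (AR(1) along the shaft); 1.0 -> identical on the whole shaft
    shaft_spatial_rho: float = 0.95
    line_amp: float = 4.0
    line_harmonics: int = 3
    line_noise_bad_channels: int | list = 1
    line_noise_bad_multiplier: float = 30.0
    gray_fraction: float = 0.5
    emg_noise_sd: float = 1.0
    emg_burst_amp: float = 8.0
    pink_band: tuple = (0.5, 400.0)
    tail_s: float = 2.0  # extra recording after the last trial so that the
    # [-4, 4) s window around a late movement onset always fits
    seed: int = 0

    @property
    def trial_s(self) -> float:
        return self.rest_s + self.cue_s + self.task_s

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_class * len(self.class_labels)

    def validate(self) -> None:
        if self.n_shafts < 1 or self.contacts_per_shaft < 1:
            raise ValueError("montage must have at least one shaft and contact")
        for sd in (self.sd_common, self.sd_shaft, self.sd_channel):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        if self.onset_jitter_mean + 3 * self.onset_jitter_sd >= self.task_s:
            raise ValueError("onset jitter extends beyond the task stage")
        if self.fs < 2 * self.pink_band[1]:
            raise ValueError("fs must be at least twice the highest synthesized frequency")
        n_ch = self.n_shafts * self.contacts_per_shaft
        if self.informative_channels is not None:
            if any(i < 0 or i >= n_ch for i in self.informative_channels):
                raise ValueError("informative channel index outside montage")
        elif self.n_informative > n_ch:
            raise ValueError("more informative channels than contacts")
        for band in self.effect_sizes:
            if band not in EFFECT_BANDS:
                raise ValueError(f"unknown effect band {band!r}")
            missing = set(self.class_labels) - set(self.effect_sizes[band])
            if missing:
                raise ValueError(f"effect sizes missing for classes {sorted(missing)}")


@dataclass
class GroundTruth:
    """What was planted: per-trial onsets, informative channels, bad channels."""

    true_onsets_s: np.ndarray
    informative_channel_ids: list
    effect_table: dict
    bad_channel_ids: list


def make_montage(config: SimConfig, rng: np.random.Generator) -> list[ChannelInfo]:
    """Shaft/contact montage with randomized gray/white tissue labels."""
    montage = []
    for s in range(config.n_shafts):
        shaft = f"S{s}"
        for c in range(1, config.contacts_per_shaft + 1):
            tissue = "gray" if rng.random() < config.gray_fraction else "white"
            montage.append(
                ChannelInfo(
                    channel_id=f"{shaft}C{c}",
                    shaft=shaft,
                    contact_index=c,
                    tissue=tissue,
                    coords=(float(s) * 10.0, 0.0, float(c) * 3.5),
                )
            )
    return montage


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, band: tuple[float, float]) -> np.ndarray:
    """Band-limited 1/f-amplitude noise, unit variance per channel."""
    n_fft = n_samples
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    shape = np.zeros_like(freqs)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    shape[inside] = 1.0 / np.sqrt(np.maximum(freqs[inside], band[0]))
    spec = (rng.standard_normal((n_channels, len(freqs)))
            + 1j * rng.standard_normal((n_channels, len(freqs)))) * shape
    x = np.fft.irfft(spec, n=n_fft, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
              order: int = 4) -> np.ndarray:
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _ramp_window(n: int, fs: float, ramp_s: float = 0.05) -> np.ndarray:
    """Unit window with raised-cosine on/off ramps to avoid spectral clicks."""
    w = np.ones(n)
    r = min(int(ramp_s * fs), n // 2)
    if r > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        w[:r] = edge
        w[-r:] = edge[::-1]
    return w


def simulate_subject(config: SimConfig):
    """Generate one subject: (Recording, EventTable, GroundTruth).

    The continuous recording is the concatenation of the trials in a
    randomized class order.  Informative channels receive a multiplicative
    power gain on their private in-band component (delta 1-4 Hz and high
    gamma 70-150 Hz carriers) during [onset, onset + task) of each trial,
    with the gain depending on the gesture class.  Deterministic under a
    fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_ch = config.n_shafts * config.contacts_per_shaft
    montage = make_montage(config, rng)
    ids = [c.channel_id for c in montage]
    shaft_of = np.array([s for s in range(config.n_shafts)
                         for _ in range(config.contacts_per_shaft)])

    # trial order: randomized permutation of 20 repetitions per gesture
    labels = np.repeat(np.array(config.class_labels, dtype=object),
                       config.n_trials_per_class)
    labels = labels[rng.permutation(len(labels))]
    n_trials = len(labels)
    trial_len = int(round(config.trial_s * fs))
    n_samples = n_trials * trial_len + int(round(config.tail_s * fs))

    # planted bad (extreme line-noise) channels, drawn first so that planted
    # effects never land on channels the screening will discard
    if isinstance(config.line_noise_bad_channels, int):
        k = config.line_noise_bad_channels
        bad = sorted(rng.choice(n_ch, size=k, replace=False).tolist()) if k else []
    else:
        bad = sorted(config.line_noise_bad_channels)

    if config.informative_channels is not None:
        informative = list(config.informative_channels)
    else:
        # informative sites are sparse: avoid adjacent contacts so that each
        # carries its own modulation (falls back to plain sampling when the
        # montage is too small to allow it)
        good = list(np.setdiff1d(np.arange(n_ch), bad))
        informative: list[int] = []
        order = rng.permutation(good)
        for c in order:
            if len(informative) == config.n_informative:
                break
            if any(shaft_of[c] == shaft_of[i]
                   and abs(montage[c].contact_index
                           - montage[i].contact_index) <= 1
                   for i in informative):
                continue
            informative.append(int(c))
        for c in order:
            if len(informative) == config.n_informative:
                break
            if c not in informative:
                informative.append(int(c))
        informative = sorted(informative)

    # events and true onsets
    cue_times = (np.arange(n_trials) * config.trial_s
                 + config.rest_s + config.cue_s)
    jitter = rng.normal(config.onset_jitter_mean, config.onset_jitter_sd,
                        size=n_trials)
    jitter = np.clip(jitter, *config.onset_jitter_clip)
    onsets = cue_times + jitter

    # channel-private background activity (local population signal)
    data = config.sd_channel * _pink_noise(rng, n_ch, n_samples, fs, config.pink_band)

    # class-specific band-power modulation on informative channels: during
    # [onset, end of task stage) the private in-band component is scaled so
    # that its in-band power is multiplied by the configured effect size.
    # The carrier is the channel-private activity only: task modulation is a
    # local population effect, not a modulation of shared noise.
    effect_table = {band: dict(config.effect_sizes[band])
                    for band in config.effect_sizes}
    if informative and config.sd_channel > 0:
        for band_name, band in EFFECT_BANDS.items():
            if band_name not in config.effect_sizes:
                continue
            carrier = _bandpass(data[informative], band, fs)
            gain_extra = np.zeros(n_samples)
            for tr in range(n_trials):
                g = config.effect_sizes[band_name][labels[tr]]
                i0 = int(round(onsets[tr] * fs))
                i1 = min(int(round((cue_times[tr] + config.task_s) * fs)), n_samples)
                if i1 <= i0:
                    continue
                gain_extra[i0:i1] = (np.sqrt(g) - 1.0) * _ramp_window(i1 - i0, fs)
            data[informative] += carrier * gain_extra[None, :]

    # layered shared noise; shared components are multiplied by a
    # per-channel coupling alpha_c(t) = 1 + static_c + drift_c(t)
    pos = np.array([(c.contact_index - 1) / max(config.contacts_per_shaft - 1, 1)
                    - 0.5 for c in montage])
    static = (config.couple_shaft_sd * rng.standard_normal(config.n_shafts)[shaft_of]
              + config.couple_grad * pos
              + config.couple_channel_sd * rng.standard_normal(n_ch))
    n_knots = max(int(np.ceil(config.trial_s * n_trials
                              / config.couple_drift_knot_s)) + 1, 2)
    knot_t = np.linspace(0, n_samples - 1, n_knots)
    # drift is mostly shaft-level (electrode-wise impedance change) with a
    # small independent per-channel component
    shaft_knots = config.couple_shaft_drift_sd * rng.standard_normal(
        (config.n_shafts, n_knots))
    chan_knots = config.couple_channel_drift_sd * rng.standard_normal(
        (n_ch, n_knots))
    drift_knots = shaft_knots[shaft_of] + chan_knots
    common = (config.sd_common
              * _pink_noise(rng, 1, n_samples, fs, config.pink_band)[0]
              if config.sd_common > 0 else None)
    samp = np.arange(n_samples)
    rho = config.shaft_spatial_rho
    for s in range(config.n_shafts):
        idx = np.flatnonzero(shaft_of == s)  # ordered deep -> superficial
        if config.sd_shaft > 0:
            # within-shaft noise: pink in time, AR(1) along the contacts so
            # that neighboring contacts see nearly the same field
            g = _pink_noise(rng, len(idx), n_samples, fs, config.pink_band)
            shaft_noise = np.empty_like(g)
            shaft_noise[0] = g[0]
            for j in range(1, len(idx)):
                shaft_noise[j] = (rho * shaft_noise[j - 1]
                                  + np.sqrt(1.0 - rho**2) * g[j])
            shaft_noise *= config.sd_shaft
        else:
            shaft_noise = None
        for j, c in enumerate(idx):
            shared = 0.0
            if common is not None:
                shared = shared + common
            if shaft_noise is not None:
                shared = shared + shaft_noise[j]
            if isinstance(shared, np.ndarray):
                alpha = 1.0 + static[c] + np.interp(samp, knot_t, drift_knots[c])
                data[c] += alpha * shared

    # 50-Hz line noise with harmonics; clean channels get amplitudes jittered
    # in [0.9, 1], bad channels exactly the multiplier, so a planted bad
    # channel's 50-Hz RMS is always >= multiplier x the median channel's
    t = np.arange(n_samples) / fs
    line_gain = rng.uniform(0.8, 0.95, n_ch)
    line_gain[bad] = config.line_noise_bad_multiplier
    for h in range(1, config.line_harmonics + 1):
        phase = rng.uniform(0, 2 * np.pi)
        amp = config.line_amp / h
        data += (line_gain * amp)[:, None] * np.sin(
            2 * np.pi * 50.0 * h * t + phase)[None, :]

    # EMG pair: rest-level Gaussian noise plus a 55-145 Hz burst from onset
    emg = config.emg_noise_sd * rng.standard_normal((2, n_samples))
    burst_carrier = _bandpass(rng.standard_normal(n_samples), (55.0, 145.0), fs)
    sd = burst_carrier.std()
    if sd > 0:
        burst_carrier /= sd
    burst_env = np.zeros(n_samples)
    for tr in range(n_trials):
        i0 = int(round(onsets[tr] * fs))
        i1 = min(int(round((cue_times[tr] + config.task_s) * fs)), n_samples)
        if i1 > i0:
            burst_env[i0:i1] = _ramp_window(i1 - i0, fs, ramp_s=0.02)
    burst = config.emg_burst_amp * burst_carrier * burst_env
    emg[0] += burst
    emg[1] -= 0.3 * burst  # differential electrodes see the burst unequally

    recording = Recording(data=data, fs=fs, montage=montage, emg=emg)
    events = EventTable(
        trial_id=np.arange(n_trials),
        label=labels,
        cue_time_s=cue_times,
    )
    truth = GroundTruth(
        true_onsets_s=onsets,
        informative_channel_ids=[ids[i] for i in informative],
        effect_table=effect_table,
        bad_channel_ids=[ids[i] for i in bad],
    )
    return recording, events, truth


def simulate_cohort(configs: list[SimConfig]):
    """Simulate independent subjects (mixed sampling rates allowed)."""
    if not configs:
        raise ValueError("cohort needs at least one SimConfig")
    return [simulate_subject(cfg) for cfg in configs]
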