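"""Data model and I/O for SEEG recordings, montage metadata and trial events.

Conventions used throughout the package:

* time is stored in seconds; sample indices are 0-based;
* all windows are half-open intervals ``[a, b)``;
* ``contact_index`` counts contacts along an electrode shaft starting at 1
  for the deepest contact and increasing toward the most superficial one.
  This fixes the direction of bipolar derivations (deep minus superficial).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "Recording",
    "EventTable",
    "EpochSet",
    "validate_montage",
    "read_recording",
    "write_recording",
    "read_montage_tsv",
    "write_montage_tsv",
    "read_events_tsv",
    "write_events_tsv",
    "read_epochs",
    "write_epochs",
    "write_edf",
    "read_edf",
]

TISSUE_CLASSES = ("gray", "white", "unknown")

MONTAGE_COLUMNS = ["channel_id", "shaft", "contact_index", "tissue", "x", "y", "z"]
EVENT_COLUMNS = ["trial", "label", "cue_time_s"]


@dataclass(frozen=True)
class ChannelInfo:
    """Identity of one SEEG contact.

    ``contact_index`` is 1 for the deepest contact of a shaft and increases
    toward the skull.  ``tissue`` is the tissue class of the contact
    (``gray``, ``white`` or ``unknown``), used by the gray/white-matter
    reference.  ``is_bad`` marks channels rejected by line-noise screening.
    """

    channel_id: str
    shaft: str
    contact_index: int
    tissue: str = "unknown"
    coords: tuple[float, float, float] | None = None
    is_bad: bool = False

    def __post_init__(self) -> None:
        if self.contact_index < 1:
            raise ValueError(f"contact_index must be >= 1, got {self.contact_index}")
        if self.tissue not in TISSUE_CLASSES:
            raise ValueError(
                f"tissue must be one of {TISSUE_CLASSES}, got {self.tissue!r}"
            )


@dataclass
class Recording:
    """Continuous multi-channel recording (channels x samples, microvolts).

    ``emg`` holds the optional pair of surface EMG channels recorded at the
    same sampling rate, used for movement-onset detection.
    """

    data: np.ndarray
    fs: float
    montage: list[ChannelInfo]
    emg: np.ndarray | None = None
    line_freq: float = 50.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{len(self.montage)} channels"
            )
        if self.emg is not None:
            self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
            if self.emg.shape[1] != self.data.shape[1]:
                raise ValueError("emg and data must have the same length")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.montage]


@dataclass
class EventTable:
    """Per-trial events: gesture label, cue time, and detected movement onset.

    ``cue_time_s`` is the onset of the gesture picture (start of the task
    stage); ``onset_time_s`` is NaN until EMG onset detection has run, and
    stays NaN for trials in which no onset was found (such trials are
    excluded downstream).
    """

    trial_id: np.ndarray
    label: np.ndarray
    cue_time_s: np.ndarray
    onset_time_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        self.label = np.asarray(self.label)
        self.cue_time_s = np.asarray(self.cue_time_s, dtype=float)
        n = len(self.trial_id)
        if not (len(self.label) == len(self.cue_time_s) == n):
            raise ValueError("event columns must have equal length")
        if self.onset_time_s is None:
            self.onset_time_s = np.full(n, np.nan)
        else:
            self.onset_time_s = np.asarray(self.onset_time_s, dtype=float)
            if len(self.onset_time_s) != n:
                raise ValueError("onset_time_s length mismatch")

    def __len__(self) -> int:
        return len(self.trial_id)

    @property
    def labels(self) -> list:
        return list(self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial_id,
                "label": self.label,
                "cue_time_s": self.cue_time_s,
                "onset_time_s": self.onset_time_s,
            }
        )


@dataclass
class EpochSet:
    """Trials x channels x time array aligned to movement onset (time 0).

    The time axis spans ``[tmin, tmin + n_times/fs)``; with the default
    alignment window of [-4, 4) s, sample ``4 * fs`` sits exactly at 0 s.
    ``baseline_window`` and ``task_window`` are the half-open analysis
    windows in seconds relative to onset.
    """

    data: np.ndarray
    fs: float
    montage: list[ChannelInfo]
    labels: np.ndarray
    tmin: float = -4.0
    baseline_window: tuple[float, float] = (-4.0, -2.0)
    task_window: tuple[float, float] = (0.0, 4.0)
    trial_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("channel dimension does not match montage")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.trial_id is None:
            self.trial_id = np.arange(self.data.shape[0])
        else:
            self.trial_id = np.asarray(self.trial_id, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.fs

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.montage]

    def sample_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice for the half-open time window ``[lo, hi)`` seconds."""
        lo, hi = window
        i0 = int(round((lo - self.tmin) * self.fs))
        i1 = int(round((hi - self.tmin) * self.fs))
        if i0 < 0 or i1 > self.n_times:
            raise ValueError(f"window {window} outside epoch span")
        return slice(i0, i1)

    def with_data(self, data: np.ndarray, montage: list[ChannelInfo]) -> "EpochSet":
        """Copy of this EpochSet with new data/montage (e.g. re-referenced)."""
        return EpochSet(
            data=data,
            fs=self.fs,
            montage=montage,
            labels=self.labels,
            tmin=self.tmin,
            baseline_window=self.baseline_window,
            task_window=self.task_window,
            trial_id=self.trial_id,
        )


# ---------------------------------------------------------------------------
# Montage validation


def validate_montage(montage: Sequence[ChannelInfo]) -> list[dict]:
    """Report structural problems in a montage (report-only, never raises).

    Flags duplicate (shaft, contact_index) pairs, gaps in the contact
    numbering of a shaft, and shafts with fewer than two contacts (for which
    bipolar and Laplacian derivations are infeasible).
    """
    report: list[dict] = []
    by_shaft: dict[str, list[ChannelInfo]] = {}
    seen: set[tuple[str, int]] = set()
    for ch in montage:
        key = (ch.shaft, ch.contact_index)
        if key in seen:
            report.append(
                {"issue": "duplicate_contact", "shaft": ch.shaft,
                 "contact_index": ch.contact_index, "channel_id": ch.channel_id}
            )
        seen.add(key)
        by_shaft.setdefault(ch.shaft, []).append(ch)
    for shaft, chans in by_shaft.items():
        idx = sorted({c.contact_index for c in chans})
        missing = sorted(set(range(idx[0], idx[-1] + 1)) - set(idx))
        if missing:
            report.append(
                {"issue": "index_gap", "shaft": shaft, "missing": missing}
            )
        if len(chans) < 2:
            report.append(
                {"issue": "too_few_contacts", "shaft": shaft,
                 "detail": "bipolar/Laplacian infeasible"}
            )
    return report


# ---------------------------------------------------------------------------
# Montage / events TSV


def write_montage_tsv(montage: Sequence[ChannelInfo], path) -> None:
    rows = []
    for ch in montage:
        x, y, z = ch.coords if ch.coords is not None else (np.nan, np.nan, np.nan)
        rows.append(
            {"channel_id": ch.channel_id, "shaft": ch.shaft,
             "contact_index": ch.contact_index, "tissue": ch.tissue,
             "x": x, "y": y, "z": z}
        )
    pd.DataFrame(rows, columns=MONTAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_montage_tsv(path) -> list[ChannelInfo]:
    df = pd.read_csv(path, sep="\t")
    missing = set(MONTAGE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"montage TSV missing columns: {sorted(missing)}")
    montage = []
    for _, row in df.iterrows():
        coords = None
        if {"x", "y", "z"} <= set(df.columns) and np.isfinite(row.get("x", np.nan)):
            coords = (float(row["x"]), float(row["y"]), float(row["z"]))
        montage.append(
            ChannelInfo(
                channel_id=str(row["channel_id"]),
                shaft=str(row["shaft"]),
                contact_index=int(row["contact_index"]),
                tissue=str(row["tissue"]),
                coords=coords,
            )
        )
    return montage


def write_events_tsv(events: EventTable, path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events TSV missing columns: {sorted(missing)}")
    onset = df["onset_time_s"].to_numpy() if "onset_time_s" in df.columns else None
    return EventTable(
        trial_id=df["trial"].to_numpy(),
        label=df["label"].to_numpy(),
        cue_time_s=df["cue_time_s"].to_numpy(),
        onset_time_s=onset,
    )


# ---------------------------------------------------------------------------
# Native NPZ containers

_TISSUE_CODE = {t: i for i, t in enumerate(TISSUE_CLASSES)}


def _montage_arrays(montage: Sequence[ChannelInfo]) -> dict:
    coords = np.array(
        [c.coords if c.coords is not None else (np.nan,) * 3 for c in montage],
        dtype=float,
    )
    return {
        "mont_channel_id": np.array([c.channel_id for c in montage]),
        "mont_shaft": np.array([c.shaft for c in montage]),
        "mont_contact_index": np.array([c.contact_index for c in montage]),
        "mont_tissue": np.array([c.tissue for c in montage]),
        "mont_coords": coords,
        "mont_is_bad": np.array([c.is_bad for c in montage]),
    }


def _montage_from_arrays(z) -> list[ChannelInfo]:
    n = len(z["mont_channel_id"])
    montage = []
    for i in range(n):
        coords = z["mont_coords"][i]
        montage.append(
            ChannelInfo(
                channel_id=str(z["mont_channel_id"][i]),
                shaft=str(z["mont_shaft"][i]),
                contact_index=int(z["mont_contact_index"][i]),
                tissue=str(z["mont_tissue"][i]),
                coords=None if not np.all(np.isfinite(coords)) else tuple(coords),
                is_bad=bool(z["mont_is_bad"][i]),
            )
        )
    return montage


def write_recording(recording: Recording, path) -> None:
    """Write a Recording to the native NPZ container (lossless round trip)."""
    payload = {
        "data": recording.data,
        "fs": np.array(recording.fs),
        "line_freq": np.array(recording.line_freq),
        **_montage_arrays(recording.montage),
    }
    if recording.emg is not None:
        payload["emg"] = recording.emg
    np.savez(path, **payload)


def read_recording(path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        return Recording(
            data=z["data"],
            fs=float(z["fs"]),
            montage=_montage_from_arrays(z),
            emg=z["emg"] if "emg" in z else None,
            line_freq=float(z["line_freq"]),
        )


def write_epochs(epochs: EpochSet, path) -> None:
    np.savez(
        path,
        data=epochs.data,
        fs=np.array(epochs.fs),
        labels=epochs.labels.astype(str),
        tmin=np.array(epochs.tmin),
        baseline_window=np.array(epochs.baseline_window),
        task_window=np.array(epochs.task_window),
        trial_id=epochs.trial_id,
        **_montage_arrays(epochs.montage),
    )


def read_epochs(path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        return EpochSet(
            data=z["data"],
            fs=float(z["fs"]),
            montage=_montage_from_arrays(z),
            labels=z["labels"],
            tmin=float(z["tmin"]),
            baseline_window=tuple(z["baseline_window"]),
            task_window=tuple(z["task_window"]),
            trial_id=z["trial_id"],
        )


# ---------------------------------------------------------------------------
# EDF export / import
#
# EDF stores each channel as 16-bit integers mapped linearly between a
# physical and a digital range, so a round trip is exact only up to the
# quantization step (physical range / 65535).  The writer below emits plain
# EDF (continuous, 1-s data records); reading goes through MNE.


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> None:
    """Export the SEEG channels to a minimal 16-bit EDF file.

    Uses 1-second data records; the signal is zero-padded to a whole number
    of records.  Physical min/max per channel are taken from the data.
    """
    if recording.fs != int(recording.fs):
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(recording.fs)
    data = recording.data
    n_sig = data.shape[0]
    n_rec = int(np.ceil(data.shape[1] / fs))
    padded = np.zeros((n_sig, n_rec * fs))
    padded[:, : data.shape[1]] = data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax <= pmin
    pmax[flat] = pmin[flat] + 1.0
    # the header stores the physical range as 8-char ASCII; digitize against
    # the stored (rounded) values so the read-back mapping matches exactly
    pmin = np.array([float(f"{v:.5g}") for v in pmin])
    pmax = np.array([float(f"{v:.5g}") for v in pmax])
    pmax = np.maximum(pmax, pmin + 1e-6)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((padded - pmin[:, None]) / scale[:, None]) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("synthetic SEEG export", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + n_sig), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(1, 8),
            _edf_field(n_sig, 4),
        ]
    )

    def sig_block(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    labels = [c.channel_id[:16] for c in recording.montage]
    header += sig_block(labels, 16)
    header += sig_block(["SEEG"] * n_sig, 80)
    header += sig_block(["uV"] * n_sig, 8)
    header += sig_block([f"{v:.5g}" for v in pmin], 8)
    header += sig_block([f"{v:.5g}" for v in pmax], 8)
    header += sig_block([dmin] * n_sig, 8)
    header += sig_block([dmax] * n_sig, 8)
    header += sig_block([""] * n_sig, 80)
    header += sig_block([fs] * n_sig, 8)
    header += sig_block([""] * n_sig, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path, montage: list[ChannelInfo] | None = None) -> Recording:
    """Read an EDF file into a Recording (requires mne).

    If no montage is given, a flat one is built from the channel labels
    (shaft = label with trailing digits stripped, contact index from the
    trailing digits, tissue unknown).
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # volts
    data_uv = data * 1e6
    if montage is None:
        montage = []
        for name in raw.ch_names:
            stem = name.rstrip("0123456789")
            digits = name[len(stem):]
            montage.append(
                ChannelInfo(
                    channel_id=name,
                    shaft=stem or name,
                    contact_index=int(digits) if digits else 1,
                )
            )
    return Recording(data=data_uv, fs=float(raw.info["sfreq"]), montage=montage)
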