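"""Domain types and file I/O for sleep-EEG recordings, stimulus events and sleep stages.

Conventions
-----------
* Time is in seconds with the recording start at 0; epoch windows are
  half-open ``[t_min, t_max)``.
* EEG data are microvolts, shaped ``(n_channels, n_samples)``.
* Event and stage tables are UTF-8 tab-separated files with a header row;
  onsets carry at least millisecond precision.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS_19, normalize_channel_label

__all__ = [
    "Recording",
    "EventSet",
    "StageAnnotation",
    "EpochSet",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_stages",
    "write_stages",
    "mask_by_stage",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One 10-10 label per channel.
    reference
        Reference description (free text).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        self.channel_labels = [str(c) for c in self.channel_labels]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        norm = normalize_channel_label(label)
        labels = [normalize_channel_label(c) for c in self.channel_labels]
        try:
            return labels.index(norm)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.channel_labels), self.reference)


_EVENT_COLUMNS = ("onset", "condition", "word_id", "presentation")


@dataclass
class EventSet:
    """Stimulus events: onset (s from recording start), condition, word id, presentation index."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = pd.DataFrame(self.table).reset_index(drop=True)
        if "onset" not in tab.columns:
            raise ValueError("event table requires an 'onset' column")
        for col in _EVENT_COLUMNS[1:]:
            if col not in tab.columns:
                tab[col] = pd.NA
        onsets = tab["onset"].to_numpy(dtype=float)
        if len(onsets) and not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        self.table = tab

    @classmethod
    def from_onsets(cls, onsets, condition=None, word_id=None, presentation=None) -> "EventSet":
        onsets = np.asarray(onsets, dtype=float)
        tab = pd.DataFrame({"onset": onsets})
        tab["condition"] = condition if condition is not None else pd.NA
        tab["word_id"] = word_id if word_id is not None else pd.NA
        tab["presentation"] = presentation if presentation is not None else pd.NA
        return cls(tab)

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class StageAnnotation:
    """AASM sleep-stage labels over contiguous fixed-length epochs starting at t=0."""

    labels: list[str]
    epoch_s: float = 30.0

    VALID = ("W", "N1", "N2", "N3", "REM")

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("epoch duration must be positive")
        self.labels = [str(l) for l in self.labels]
        bad = sorted({l for l in self.labels} - set(self.VALID))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_s

    def stage_at(self, t: float) -> str | None:
        """Stage label of the 30-s epoch containing time ``t``; None outside the staged range."""
        if t < 0:
            return None
        idx = int(t // self.epoch_s)
        if idx >= len(self.labels):
            return None
        return self.labels[idx]


@dataclass
class EpochSet:
    """Event-locked EEG segments: ``(n_epochs, n_channels, n_samples)`` plus per-epoch metadata."""

    data: np.ndarray
    window: tuple[float, float]
    fs: float
    channel_labels: list[str]
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        t_min, t_max = self.window
        expected = int(round((t_max - t_min) * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window} at fs={self.fs} implies {expected} samples, "
                f"got {self.data.shape[2]}"
            )
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel label count mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time axis relative to event onset; includes t=0 when the window spans it."""
        t_min, _ = self.window
        return t_min + np.arange(self.data.shape[2]) / self.fs

    def channel_index(self, label: str) -> int:
        labels = [normalize_channel_label(c) for c in self.channel_labels]
        return labels.index(normalize_channel_label(label))


# ---------------------------------------------------------------------------
# Recording I/O (EDF / BrainVision)
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".vhdr":
        return "brainvision"
    raise ValueError(f"cannot infer recording format from {path.name!r}; pass format=")


def read_recording(path, format: str | None = None) -> Recording:
    """Read an EDF(+) or BrainVision recording into microvolts.

    Channel labels are normalized case-insensitively against the 19-channel
    montage; unknown labels are kept verbatim with a warning.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    try:
        if fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        elif fmt == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise IOError(f"unreadable recording {path}: {exc}") from exc

    data = raw.get_data(units="uV")
    labels = []
    known = {c.lower() for c in CHANNELS_19}
    for ch in raw.ch_names:
        norm = normalize_channel_label(ch)
        if norm.lower() not in known:
            warnings.warn(f"unknown channel label {ch!r} kept verbatim", stacklevel=2)
        labels.append(norm)
    return Recording(data, float(raw.info["sfreq"]), labels, reference="as-recorded")


def write_recording(recording: Recording, path, format: str | None = None) -> Path:
    """Write a recording as EDF (16-bit) or BrainVision (float32).

    EDF stores whole 1-s data records; recordings whose length is not a whole
    number of seconds are zero-padded to the next record boundary.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        _write_edf(recording, path)
    elif fmt == "brainvision":
        _write_brainvision(recording, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    spr = fs  # one-second data records
    n_rec = int(np.ceil(rec.n_samples / spr)) if rec.n_samples else 0
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data

    # symmetric physical range per file, digital range +/-32767
    pmax = float(np.max(np.abs(padded))) if padded.size else 1.0
    pmax = max(pmax, 1.0) * 1.0001
    dig = 32767
    scaled = np.clip(np.round(padded / pmax * dig), -dig, dig).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate 01-JAN-2000 X X X", 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(256 * (n_ch + 1), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field("1", 8),
            _edf_field(n_ch, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
            b"".join(_edf_field(f"{-pmax:.6g}"[:8], 8) for _ in range(n_ch)),
            b"".join(_edf_field(f"{pmax:.6g}"[:8], 8) for _ in range(n_ch)),
            b"".join(_edf_field(-dig, 8) for _ in range(n_ch)),
            b"".join(_edf_field(dig, 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field(spr, 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = scaled[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-by-channel within each record


def _write_brainvision(rec: Recording, path: Path) -> None:
    base = path.with_suffix("")
    eeg_path = base.with_suffix(".eeg")
    vmrk_path = base.with_suffix(".vmrk")
    n_ch = rec.n_channels
    vhdr = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / rec.fs:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels, start=1):
        vhdr.append(f"Ch{i}={lab},,1,µV")
    path.write_text("\n".join(vhdr) + "\n", encoding="utf-8")
    vmrk = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    vmrk_path.write_text("\n".join(vmrk) + "\n", encoding="utf-8")
    rec.data.T.astype("<f4").tofile(eeg_path)  # multiplexed: sample-major


# ---------------------------------------------------------------------------
# Event / stage tables
# ---------------------------------------------------------------------------

def read_events(path) -> EventSet:
    """Read a tab-separated event table (columns: onset, condition, word_id, presentation)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    tab = pd.read_csv(path, sep="\t")
    if "onset" not in tab.columns:
        raise ValueError(f"{path.name}: missing required 'onset' column")
    return EventSet(tab)


def write_events(events: EventSet, path) -> Path:
    path = Path(path)
    tab = events.table.copy()
    tab["onset"] = tab["onset"].map(lambda v: f"{v:.6f}")
    tab.to_csv(path, sep="\t", index=False)
    return path


def read_stages(path) -> StageAnnotation:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    tab = pd.read_csv(path, sep="\t")
    if not {"epoch_index", "label"} <= set(tab.columns):
        raise ValueError(f"{path.name}: stage table needs epoch_index and label columns")
    tab = tab.sort_values("epoch_index")
    idx = tab["epoch_index"].to_numpy()
    if len(idx) and not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError("stage epochs must be contiguous from 0")
    return StageAnnotation(list(tab["label"]))


def write_stages(stages: StageAnnotation, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"epoch_index": np.arange(len(stages.labels)), "label": stages.labels}
    ).to_csv(path, sep="\t", index=False)
    return path


def mask_by_stage(events: EventSet, stages: StageAnnotation, allowed) -> EventSet:
    """Retain events whose onset falls inside a 30-s epoch with an allowed stage label.

    Events beyond the staged range are excluded with a warning.
    """
    allowed = set(allowed)
    keep = []
    n_beyond = 0
    for i, onset in enumerate(events.onsets):
        stage = stages.stage_at(onset)
        if stage is None:
            n_beyond += 1
            continue
        if stage in allowed:
            keep.append(i)
    if n_beyond:
        warnings.warn(f"{n_beyond} events beyond the staged range were excluded", stacklevel=2)
    return EventSet(events.table.iloc[keep].reset_index(drop=True))
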