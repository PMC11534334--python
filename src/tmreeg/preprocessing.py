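"""Referencing, filtering, epoching and automatic artifact rejection.

Filters are zero-phase (forward-backward) Butterworth band-passes of order 4
per pass; band edges for the wake and sleep pipelines are (0.5, 45) and
(0.5, 35) Hz respectively. Artifact rejection replaces visual inspection with
a deterministic any-channel peak-to-peak threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import butter, detrend, sosfiltfilt

from .io_core import EpochSet, EventSet, Recording

__all__ = [
    "rereference_mastoids",
    "bandpass",
    "bandpass_array",
    "epoch",
    "reject_artifacts",
    "WAKE_BAND",
    "SLEEP_BAND",
    "WAKE_WINDOW",
    "SLEEP_WINDOW",
]

WAKE_BAND = (0.5, 45.0)
SLEEP_BAND = (0.5, 35.0)
WAKE_WINDOW = (-2.0, 4.0)
SLEEP_WINDOW = (-2.0, 8.0)


def rereference_mastoids(recording: Recording, mastoid_labels=("M1", "M2")) -> Recording:
    """Subtract the mean of the two mastoid channels from every channel."""
    if len(mastoid_labels) != 2:
        raise ValueError("exactly two mastoid labels required")
    try:
        idx = [recording.channel_index(m) for m in mastoid_labels]
    except KeyError as exc:
        raise ValueError(f"mastoid channel missing: {exc}") from exc
    ref = recording.data[idx].mean(axis=0)
    out = recording.copy()
    out.data = out.data - ref[None, :]
    out.reference = f"average of {mastoid_labels[0]}/{mastoid_labels[1]}"
    return out


def _band_sos(low_hz: float, high_hz: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) Hz at fs={fs}")
    return butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")


def bandpass_array(data: np.ndarray, low_hz: float, high_hz: float, fs: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = _band_sos(low_hz, high_hz, fs, order)
    return sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def bandpass(recording: Recording, low_hz: float, high_hz: float, order: int = 4) -> Recording:
    out = recording.copy()
    out.data = bandpass_array(recording.data, low_hz, high_hz, recording.fs, order)
    return out


def epoch(recording: Recording, events: EventSet, window: tuple[float, float],
          detrend_epochs: bool = True) -> EpochSet:
    """Cut one ``[t_min, t_max)`` segment per event, demeaned and linearly detrended.

    Events whose window does not fit inside the recording are dropped with a
    warning; zero retained events is an error.
    """
    t_min, t_max = window
    if t_max <= t_min:
        raise ValueError("window must satisfy t_min < t_max")
    n_samp = int(round((t_max - t_min) * recording.fs))
    segments, kept = [], []
    for i, onset in enumerate(events.onsets):
        start = int(round((onset + t_min) * recording.fs))
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            continue
        segments.append(recording.data[:, start:stop])
        kept.append(i)
    n_dropped = len(events) - len(kept)
    if n_dropped:
        warnings.warn(f"{n_dropped} events dropped: window outside recording", stacklevel=2)
    if not segments:
        raise ValueError("no events with a full epoch window inside the recording")
    data = np.stack(segments)
    if detrend_epochs:
        data = detrend(data, axis=-1, type="linear")
    meta = events.table.iloc[kept].reset_index(drop=True)
    return EpochSet(data, (t_min, t_max), recording.fs, list(recording.channel_labels), meta)


def reject_artifacts(epochs: EpochSet, ptp_threshold_uv: float) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs whose any-channel peak-to-peak amplitude exceeds the threshold.

    Returns the retained epochs and a rejection log (one row per input epoch
    with its max peak-to-peak value and whether it was kept).
    """
    if ptp_threshold_uv <= 0:
        raise ValueError("peak-to-peak threshold must be positive")
    ptp = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)  # (epochs, channels)
    worst = ptp.max(axis=1)
    keep = worst <= ptp_threshold_uv
    log = pd.DataFrame(
        {
            "epoch": np.arange(epochs.n_epochs),
            "max_ptp_uv": worst,
            "kept": keep,
        }
    )
    if not keep.any():
        raise ValueError("all epochs rejected; threshold too strict or data corrupt")
    kept_events = (
        epochs.events.loc[keep].reset_index(drop=True)
        if len(epochs.events) == epochs.n_epochs
        else epochs.events
    )
    out = EpochSet(epochs.data[keep], epochs.window, epochs.fs,
                   list(epochs.channel_labels), kept_events)
    return out, log
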