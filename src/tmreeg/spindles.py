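"""Fast sleep-spindle detection with per-subject amplitude thresholds.

Spindles are detected on one channel (default Pz) after 12-16 Hz band-pass
filtering. "Amplitude" for thresholding is the magnitude of the analytic
signal (Hilbert envelope) of the filtered trace. Detection statistics (mean
and SD of the envelope) are computed per subject over the concatenated
cue windows (default -2 to 8 s around each cue) when cue events are given,
otherwise over the whole trace. A candidate starts where the envelope
exceeds mean + 1.25 SD; its boundaries extend to where the envelope falls
below mean + 0.75 SD before and after; candidates closer than 0.1 s are
merged; only events lasting 0.5-3 s survive.

Spindle amplitude is the mean absolute value of all positive and negative
local extrema of the band-passed signal between the event boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .io_core import EpochSet, EventSet, Recording
from .preprocessing import bandpass_array
from .sw import event_histogram, local_extrema

__all__ = [
    "SpindleEvent",
    "detect_spindles",
    "spindle_amplitude",
    "spindle_density",
]

_DURATION = (0.5, 3.0)


@dataclass
class SpindleEvent:
    """One detected sleep spindle on one channel."""

    start_time: float
    end_time: float
    peak_time: float  # time of the envelope maximum
    amplitude: float  # mean |extrema| of the band-passed trace, µV
    channel: str = "Pz"
    trial_index: int | None = None
    latency: float | None = None  # peak time relative to the assigned cue onset

    def __post_init__(self) -> None:
        if not self.start_time < self.peak_time < self.end_time:
            raise ValueError("spindle boundaries must bracket the peak")
        if not _DURATION[0] - 1e-9 <= self.duration <= _DURATION[1] + 1e-9:
            raise ValueError(f"duration {self.duration:.3f} s outside {_DURATION}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def spindle_amplitude(start: float, end: float, bandpassed: np.ndarray, fs: float,
                      t_offset: float = 0.0) -> float:
    """Mean absolute value of all local extrema of the filtered trace in [start, end]."""
    i0 = max(0, int(round((start - t_offset) * fs)))
    i1 = min(len(bandpassed), int(round((end - t_offset) * fs)) + 1)
    seg = bandpassed[i0:i1]
    minima, maxima = local_extrema(seg)
    idx = np.concatenate([minima, maxima])
    if idx.size == 0:
        raise ValueError("no extrema inside the spindle interval")
    return float(np.mean(np.abs(seg[idx])))


def _cue_window_mask(n: int, fs: float, onsets: np.ndarray,
                     window: tuple[float, float]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for onset in onsets:
        a = max(0, int(round((onset + window[0]) * fs)))
        b = min(n, int(round((onset + window[1]) * fs)))
        mask[a:b] = True
    return mask


def _detect_on_trace(trace: np.ndarray, fs: float, band, thr_sd: float, edge_sd: float,
                     channel: str, stats_mask: np.ndarray | None,
                     merge_gap: float = 0.1, t_offset: float = 0.0,
                     stats: tuple[float, float] | None = None) -> list[SpindleEvent]:
    if len(trace) == 0:
        return []
    filt = bandpass_array(trace, band[0], band[1], fs)
    env = np.abs(hilbert(filt))
    if stats is not None:
        mu, sd = stats
    else:
        ref = env if stats_mask is None else env[stats_mask]
        if ref.size == 0:
            return []
        mu, sd = float(ref.mean()), float(ref.std())
    if sd == 0:
        return []
    thr_hi = mu + thr_sd * sd
    thr_lo = mu + edge_sd * sd

    above = env > thr_hi
    if not above.any():
        return []
    # candidate cores: contiguous runs above the detection threshold
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(env))

    below = env < thr_lo
    intervals = []
    for s, e in zip(starts, ends):
        # extend to the edge threshold on both sides
        left = s
        while left > 0 and not below[left - 1]:
            left -= 1
        right = e
        while right < len(env) and not below[right]:
            right += 1
        intervals.append((left, right))

    # merge candidates separated by < merge_gap (envelope dips)
    merged = []
    gap = int(round(merge_gap * fs))
    for iv in sorted(set(intervals)):
        if merged and iv[0] - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(iv)

    events = []
    for left, right in merged:
        duration = (right - left) / fs
        if not _DURATION[0] <= duration <= _DURATION[1]:
            continue
        peak = left + int(np.argmax(env[left:right]))
        if peak == left or peak == right:
            continue
        start_t = t_offset + left / fs
        end_t = t_offset + right / fs
        amp = spindle_amplitude(start_t, end_t, filt, fs, t_offset=t_offset)
        events.append(
            SpindleEvent(
                start_time=start_t,
                end_time=end_t,
                peak_time=t_offset + peak / fs,
                amplitude=amp,
                channel=channel,
            )
        )
    return events


def detect_spindles(recording_or_epochs, channel: str = "Pz",
                    band: tuple[float, float] = (12.0, 16.0),
                    thr_sd: float = 1.25, edge_sd: float = 0.75,
                    events: EventSet | None = None,
                    window: tuple[float, float] = (-2.0, 8.0),
                    merge_gap: float = 0.1) -> list[SpindleEvent]:
    """Detect fast spindles on one channel of a Recording or EpochSet.

    With a Recording plus cue ``events``, envelope statistics come from the
    concatenated cue windows and each spindle is assigned (by its envelope
    peak) to the most recent cue whose window contains it; spindles outside
    every cue window are dropped. Without events the whole trace is used and
    no trial assignment happens.
    """
    if isinstance(recording_or_epochs, Recording):
        rec = recording_or_epochs
        trace = rec.get_channel(channel)
        stats_mask = None
        if events is not None:
            stats_mask = _cue_window_mask(len(trace), rec.fs, events.onsets, window)
        found = _detect_on_trace(trace, rec.fs, band, thr_sd, edge_sd, channel,
                                 stats_mask, merge_gap)
        if events is None:
            return found
        onsets = np.asarray(events.onsets)
        kept = []
        for ev in found:
            k = int(np.searchsorted(onsets, ev.peak_time - window[0], side="right")) - 1
            if k < 0:
                continue
            latency = ev.peak_time - onsets[k]
            if window[0] <= latency <= window[1]:
                ev.trial_index = k
                ev.latency = float(latency)
                kept.append(ev)
        return kept

    if isinstance(recording_or_epochs, EpochSet):
        ep = recording_or_epochs
        ci = ep.channel_index(channel)
        t0 = float(ep.times[0])
        # per-subject statistics over all cue windows: concatenate the epochs
        concat = ep.data[:, ci, :].reshape(-1)
        filt = bandpass_array(concat, band[0], band[1], ep.fs)
        env = np.abs(hilbert(filt))
        mu, sd = float(env.mean()), float(env.std())
        out: list[SpindleEvent] = []
        for i in range(ep.n_epochs):
            evs = _detect_on_trace(ep.data[i, ci], ep.fs, band, thr_sd, edge_sd,
                                   channel, None, merge_gap, t_offset=t0,
                                   stats=(mu, sd))
            for ev in evs:
                ev.trial_index = i
                ev.latency = ev.peak_time
            out.extend(evs)
        return out

    raise TypeError("expected a Recording or an EpochSet")


def spindle_density(events: list[SpindleEvent], n_trials: int, bin_s: float = 0.5,
                    time_range: tuple[float, float] = (-0.5, 6.0)) -> pd.DataFrame:
    """Cue-locked spindle histogram keyed on the envelope-peak latency."""
    lats = [e.latency for e in events if e.latency is not None]
    return event_histogram(lats, n_trials, bin_s, time_range)
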