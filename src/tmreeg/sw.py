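"""Slow-wave detection and cue-locked slow-wave density.

Slow waves (SW, 0.5-3 Hz) are located on the band-pass filtered trace of a
single channel (default Cz): every negative local extremum flanked by
positive local extrema whose spacing lies in 0.3-2 s becomes a candidate
event. Because a single SW cycle is a broadband transient, the band-pass
attenuates its trough-to-peak excursion; amplitudes are therefore read from
the detector's *input* trace at the extrema located on the filtered trace.

For cue-locked analyses, detection runs on the continuous signal and each
trough is assigned to the most recent cue whose search window (default 0-6 s
post-onset) contains it, so overlapping cue windows never double-count a
trough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import EpochSet, EventSet, Recording
from .preprocessing import bandpass_array

__all__ = [
    "SWEvent",
    "detect_slow_waves",
    "select_top_amplitude",
    "sw_density",
    "sw_histogram",
    "local_extrema",
    "event_histogram",
]

_SPACING = (0.3, 2.0)  # allowed prior-to-posterior positive-peak distance, s


@dataclass
class SWEvent:
    """One detected slow wave on one channel."""

    trough_time: float
    prior_peak_time: float
    posterior_peak_time: float
    amplitude: float  # trough to posterior positive peak, µV
    channel: str = "Cz"
    trial_index: int | None = None
    latency: float | None = None  # trough time relative to the assigned cue onset

    def __post_init__(self) -> None:
        if not self.prior_peak_time < self.trough_time < self.posterior_peak_time:
            raise ValueError("peak/trough ordering violated")
        spacing = self.posterior_peak_time - self.prior_peak_time
        if not _SPACING[0] - 1e-9 <= spacing <= _SPACING[1] + 1e-9:
            raise ValueError(f"positive-peak spacing {spacing:.3f} s outside {_SPACING}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local minima and maxima; plateaus resolve to their midpoint."""
    x = np.asarray(x, dtype=float)
    s = np.sign(np.diff(x))
    nz = np.flatnonzero(s)
    minima, maxima = [], []
    for a, b in zip(nz[:-1], nz[1:]):
        if s[a] > 0 > s[b]:
            maxima.append((a + 1 + b) // 2)
        elif s[a] < 0 < s[b]:
            minima.append((a + 1 + b) // 2)
    return np.asarray(minima, dtype=int), np.asarray(maxima, dtype=int)


def _refine_trough(trace: np.ndarray, m: int, fs: float, halfwidth_s: float = 0.2) -> float:
    """Noise-robust trough localization: vertex of a least-squares parabola
    fitted to ``trace`` around the sample minimum detected on the filtered
    signal (falls back to the sample minimum). Fitting on the unfiltered
    input avoids the band-pass's waveform-asymmetry bias while the fit
    averages out broadband noise."""
    half = int(round(halfwidth_s * fs))
    a, b = max(0, m - half), min(len(trace), m + half + 1)
    if b - a < 5:
        return float(m)
    x = np.arange(a, b) - m
    c2, c1, _ = np.polyfit(x, trace[a:b], 2)
    if c2 <= 0:
        return float(m)
    v = -c1 / (2 * c2)
    if abs(v) > half:
        return float(m)
    return m + float(v)


def _detect_on_trace(trace: np.ndarray, fs: float, band, channel: str,
                     amplitude_from: str, t_offset: float = 0.0) -> list[SWEvent]:
    if len(trace) == 0:
        return []
    filt = bandpass_array(trace, band[0], band[1], fs)
    minima, maxima = local_extrema(filt)
    neg = minima[filt[minima] < 0]
    pos = maxima[filt[maxima] > 0]
    if len(neg) == 0 or len(pos) < 2:
        return []
    amp_trace = trace if amplitude_from == "input" else filt
    events = []
    for m in neg:
        j = np.searchsorted(pos, m)
        if j == 0 or j == len(pos):
            continue
        prior, post = pos[j - 1], pos[j]
        spacing = (post - prior) / fs
        if not _SPACING[0] <= spacing <= _SPACING[1]:
            continue
        amplitude = float(amp_trace[post] - amp_trace[m])
        if amplitude <= 0:
            continue
        trough = _refine_trough(amp_trace, m, fs)
        trough = min(max(trough, prior + 1.0), post - 1.0)  # keep ordering
        events.append(
            SWEvent(
                trough_time=t_offset + trough / fs,
                prior_peak_time=t_offset + prior / fs,
                posterior_peak_time=t_offset + post / fs,
                amplitude=amplitude,
                channel=channel,
            )
        )
    return events


def detect_slow_waves(recording_or_epochs, channel: str = "Cz",
                      band: tuple[float, float] = (0.5, 3.0),
                      events: EventSet | None = None,
                      search_window: tuple[float, float] = (0.0, 6.0),
                      amplitude_from: str = "input") -> list[SWEvent]:
    """Detect slow waves on one channel of a Recording or EpochSet.

    With a Recording plus ``events``, detection runs on the continuous trace
    and each trough is assigned to the most recent cue whose
    ``search_window`` contains it (troughs outside every window are dropped).
    With an EpochSet, detection runs per epoch on the epoch's own time axis
    and only troughs with latency inside ``search_window`` are kept.
    """
    if amplitude_from not in ("input", "filtered"):
        raise ValueError("amplitude_from must be 'input' or 'filtered'")

    if isinstance(recording_or_epochs, Recording):
        rec = recording_or_epochs
        trace = rec.get_channel(channel)
        found = _detect_on_trace(trace, rec.fs, band, channel, amplitude_from)
        if events is None:
            return found
        onsets = np.asarray(events.onsets)
        w0, w1 = search_window
        kept: list[SWEvent] = []
        for ev in found:
            k = int(np.searchsorted(onsets, ev.trough_time - w0, side="right")) - 1
            if k < 0:
                continue
            latency = ev.trough_time - onsets[k]
            if w0 <= latency <= w1:
                ev.trial_index = k
                ev.latency = float(latency)
                kept.append(ev)
        return kept

    if isinstance(recording_or_epochs, EpochSet):
        ep = recording_or_epochs
        ci = ep.channel_index(channel)
        t0 = float(ep.times[0])
        out: list[SWEvent] = []
        for i in range(ep.n_epochs):
            for ev in _detect_on_trace(ep.data[i, ci], ep.fs, band, channel,
                                       amplitude_from, t_offset=t0):
                if search_window[0] <= ev.trough_time <= search_window[1]:
                    ev.trial_index = i
                    ev.latency = ev.trough_time
                    out.append(ev)
        return out

    raise TypeError("expected a Recording or an EpochSet")


def select_top_amplitude(events: list[SWEvent], fraction: float = 0.30) -> list[SWEvent]:
    """Keep the ceil(fraction * N) largest-amplitude events; ties favour earlier troughs.

    Apply per subject: pass one subject's events at a time.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not events:
        return []
    k = max(1, math.ceil(fraction * len(events)))
    ranked = sorted(events, key=lambda e: (-e.amplitude, e.trough_time))
    return ranked[:k]


def event_histogram(latencies, n_trials: int, bin_s: float,
                    time_range: tuple[float, float]) -> pd.DataFrame:
    """Counts of event latencies per fixed-width bin, plus per-trial density."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    lo, hi = time_range
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.asarray(list(latencies), dtype=float), bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "per_trial": counts / n_trials,
        }
    )


def sw_density(events: list[SWEvent], n_trials: int, bin_s: float = 0.5,
               time_range: tuple[float, float] = (-1.5, 3.0),
               baseline: tuple[float, float] = (-1.5, 0.0)) -> pd.DataFrame:
    """Cue-locked SW density per bin with percent change relative to the baseline bins.

    Density is trough count per trial per bin; percent change is
    ``(density / mean(baseline densities) - 1) * 100``. If the baseline is
    empty the ``pct_change`` column is all-NaN and ``raw only`` is flagged.
    """
    lats = [e.latency for e in events if e.latency is not None]
    hist = event_histogram(lats, n_trials, bin_s, time_range)
    base_mask = (hist["bin_left"] >= baseline[0] - 1e-9) & (hist["bin_right"] <= baseline[1] + 1e-9)
    if not base_mask.any():
        raise ValueError("baseline bins must lie inside the histogram range")
    base_mean = float(hist.loc[base_mask, "per_trial"].mean())
    hist["baseline_bin"] = base_mask
    if base_mean == 0.0:
        hist["pct_change"] = np.nan
        hist.attrs["baseline_undefined"] = True
    else:
        hist["pct_change"] = (hist["per_trial"] / base_mean - 1.0) * 100.0
        hist.attrs["baseline_undefined"] = False
    return hist


def sw_histogram(events: list[SWEvent], n_trials: int, bin_s: float = 0.5,
                 time_range: tuple[float, float] = (-0.5, 6.0)) -> pd.DataFrame:
    """Cue-locked SW trough histogram (count and per-trial density, no baseline)."""
    lats = [e.latency for e in events if e.latency is not None]
    return event_histogram(lats, n_trials, bin_s, time_range)
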