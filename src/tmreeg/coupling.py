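"""Slow-wave / spindle coupling and SW-trough-locked time-frequency power.

A spindle counts as coupled when its envelope peak falls inside the SW
up-state window, i.e. 0.3 to 0.8 s (closed interval) after some SW trough.
A spindle qualifying for several slow waves is counted once, attached to the
SW whose lag is closest to the window midpoint (0.55 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import EpochSet, Recording
from .spindles import SpindleEvent
from .sw import SWEvent
from .timefrequency import TFR, band_window_power, baseline_subtract, morlet_tfr

__all__ = [
    "CoupledSpindle",
    "classify_coupling",
    "sw_locked_tfr",
    "upstate_band_power",
    "coupled_amplitude_contrast",
]

UPSTATE_WINDOW = (0.3, 0.8)


@dataclass
class CoupledSpindle:
    """A spindle with its coupling label and, if coupled, the matched SW and lag."""

    spindle: SpindleEvent
    sw: SWEvent | None
    lag: float | None  # spindle peak minus SW trough, s
    coupled: bool


def classify_coupling(spindles: list[SpindleEvent], sw_events: list[SWEvent],
                      window: tuple[float, float] = UPSTATE_WINDOW) -> list[CoupledSpindle]:
    """Label each spindle coupled/uncoupled against the SW troughs.

    Both event lists must share a time base (e.g. seconds from recording
    start). Boundary lags count as coupled; the recorded SW is the nearest
    qualifying one by |lag - window midpoint|.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("coupling window must have positive width")
    mid = 0.5 * (lo + hi)
    troughs = np.asarray([sw.trough_time for sw in sw_events], dtype=float)
    order = np.argsort(troughs)
    troughs_sorted = troughs[order]
    out = []
    for sp in spindles:
        peak = sp.peak_time
        # qualifying troughs lie in [peak - hi, peak - lo]
        a = np.searchsorted(troughs_sorted, peak - hi - 1e-12, side="left")
        b = np.searchsorted(troughs_sorted, peak - lo + 1e-12, side="right")
        if b > a:
            cand = np.arange(a, b)
            lags = peak - troughs_sorted[cand]
            best = cand[np.argmin(np.abs(lags - mid))]
            sw = sw_events[int(order[best])]
            out.append(CoupledSpindle(sp, sw, float(peak - sw.trough_time), True))
        else:
            out.append(CoupledSpindle(sp, None, None, False))
    return out


def sw_locked_tfr(recording: Recording, sw_troughs, halfwidth: float = 2.0,
                  freqs=None, baseline: tuple[float, float] = (-2.0, -1.5),
                  n_cycles: float = 7.0, t_step: float = 0.010,
                  pad: float = 0.5) -> TFR:
    """Morlet power around SW troughs, trough at t=0, baseline-subtracted.

    Segments span ±(halfwidth + pad) so that the returned ±halfwidth window
    has reduced edge contamination; troughs too close to the recording edges
    are dropped. ``freqs`` defaults to 1-30 Hz in 0.2 Hz steps.
    """
    from .timefrequency import default_freq_grid

    if freqs is None:
        freqs = default_freq_grid(1.0, 30.0, 0.2)
    freqs = np.asarray(freqs, dtype=float)
    troughs = np.asarray(
        [t.trough_time if isinstance(t, SWEvent) else float(t) for t in sw_troughs]
    )
    half = halfwidth + pad
    n_half = int(round(half * recording.fs))
    segs = []
    for t in troughs:
        c = int(round(t * recording.fs))
        if c - n_half < 0 or c + n_half > recording.n_samples:
            continue
        segs.append(recording.data[:, c - n_half : c + n_half])
    if not segs:
        raise ValueError("no SW troughs far enough from the recording edges")
    epochs = EpochSet(np.stack(segs), (-half, half), recording.fs,
                      list(recording.channel_labels))
    tfr = morlet_tfr(epochs, freqs, n_cycles=n_cycles, t_step=t_step)
    tfr = baseline_subtract(tfr, baseline)
    # crop back to the requested ±halfwidth
    keep = (tfr.times >= -halfwidth - 1e-9) & (tfr.times <= halfwidth + 1e-9)
    tfr.power = tfr.power[:, :, keep]
    if tfr.valid is not None:
        tfr.valid = tfr.valid[:, keep]
    tfr.times = tfr.times[keep]
    return tfr


def upstate_band_power(tfr: TFR, band: tuple[float, float] = (11.0, 14.0),
                       window: tuple[float, float] = UPSTATE_WINDOW,
                       channels=("Pz", "P3", "P4")) -> float:
    """Mean power in the up-state spindle-band box (per subject)."""
    if not channels:
        raise ValueError("empty channel selection")
    return band_window_power(tfr, band=band, window=window, channels=channels)


def coupled_amplitude_contrast(coupled: list[CoupledSpindle]) -> pd.Series:
    """Mean spindle amplitude per coupling class for one subject.

    Returns a Series indexed by 'coupled' / 'uncoupled'; a class with no
    events is absent from the index (missing cell, not zero).
    """
    rows = [("coupled" if c.coupled else "uncoupled", c.spindle.amplitude) for c in coupled]
    if not rows:
        return pd.Series(dtype=float, name="mean_amplitude")
    df = pd.DataFrame(rows, columns=["class", "amplitude"])
    out = df.groupby("class")["amplitude"].mean()
    out.name = "mean_amplitude"
    return out
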