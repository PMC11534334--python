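#!/usr/bin/env python
"""Classify SW-spindle coupling and compute SW-trough-locked spectral power.

Regenerates the simulated session, labels each detected spindle as coupled
(envelope peak 0.3-0.8 s after an SW trough) or uncoupled, computes the
Morlet TFR time-locked to the top-30% SW troughs (baseline -2 to -1.5 s) and
the mean 11-14 Hz power in the up-state window, and writes the coupling
table under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tmreeg import SleepSimParams, simulate_sleep_session
from tmreeg.coupling import classify_coupling, coupled_amplitude_contrast, sw_locked_tfr, upstate_band_power
from tmreeg.spindles import detect_spindles
from tmreeg.sw import detect_slow_waves, select_top_amplitude

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    rec, events, _ = simulate_sleep_session(SleepSimParams(), seed=seed)
    sw_top = select_top_amplitude(detect_slow_waves(rec, channel="Cz", events=events), 0.30)
    spindles = detect_spindles(rec, channel="Pz", events=events)

    coupled = classify_coupling(spindles, sw_top)
    table = pd.DataFrame([{
        "spindle_peak": c.spindle.peak_time,
        "sw_trough": c.sw.trough_time if c.sw else None,
        "lag": c.lag,
        "coupled": c.coupled,
        "amplitude": c.spindle.amplitude,
    } for c in coupled])
    table.to_csv(ROOT / "results" / "coupling.tsv", sep="\t", index=False)

    n_coupled = int(table["coupled"].sum()) if len(table) else 0
    print(f"{n_coupled}/{len(table)} spindles coupled to an SW up-state")
    means = coupled_amplitude_contrast(coupled)
    for cls, val in means.items():
        print(f"mean spindle amplitude ({cls}): {val:.1f} µV")

    tfr = sw_locked_tfr(rec, sw_top, freqs=np.arange(10.0, 16.5, 0.5))
    power = upstate_band_power(tfr, channels=("Pz", "P3", "P4"))
    print(f"up-state 11-14 Hz power (0.3-0.8 s post-trough, Pz/P3/P4, "
          f"baseline-corrected): {power:.2f} µV²")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    main(p.parse_args().seed)
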