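#!/usr/bin/env python
"""Detect cue-locked slow waves and fast spindles in the simulated session.

Regenerates the session EEG from the same seed as 01_simulate_session.py,
runs the SW detector (0.5-3 Hz, Cz, top-30% amplitude selection) and the
spindle detector (12-16 Hz, Pz, 1.25/0.75 SD thresholds), and writes the
event tables and cue-locked density histograms under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from tmreeg import SleepSimParams, simulate_sleep_session
from tmreeg.spindles import detect_spindles, spindle_density
from tmreeg.sw import detect_slow_waves, select_top_amplitude, sw_density

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    rec, events, gt = simulate_sleep_session(SleepSimParams(), seed=seed)

    # density bins reach back to -1.5 s, so detect over the full range
    sw_all = detect_slow_waves(rec, channel="Cz", events=events,
                               search_window=(-1.5, 6.0))
    sw_top = select_top_amplitude(sw_all, 0.30)
    density = sw_density(sw_top, n_trials=len(events))
    density.to_csv(ROOT / "results" / "sw_density.tsv", sep="\t", index=False)

    spindles = detect_spindles(rec, channel="Pz", events=events)
    sp_density = spindle_density(spindles, n_trials=len(events))
    sp_density.to_csv(ROOT / "results" / "spindle_density.tsv", sep="\t", index=False)

    pd.DataFrame([{
        "trial": e.trial_index, "trough_time": e.trough_time, "latency": e.latency,
        "amplitude": e.amplitude,
    } for e in sw_top]).to_csv(ROOT / "results" / "sw_events.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "trial": e.trial_index, "start": e.start_time, "end": e.end_time,
        "peak": e.peak_time, "duration": e.duration, "amplitude": e.amplitude,
    } for e in spindles]).to_csv(ROOT / "results" / "spindle_events.tsv", sep="\t",
                                 index=False)

    print(f"injected slow waves: {len(gt.sw_trough_times)}; detected candidates: "
          f"{len(sw_all)}; kept after top-30% selection: {len(sw_top)}")
    modal = density.loc[density["per_trial"].idxmax()]
    change = (f"({modal['pct_change']:+.0f}% vs baseline)"
              if not density.attrs.get("baseline_undefined") else "(no baseline events)")
    print(f"SW density peaks in bin [{modal['bin_left']:.1f}, {modal['bin_right']:.1f}) s "
          f"post-cue: {modal['per_trial']:.2f}/trial {change}")
    print(f"spindles detected: {len(spindles)} "
          f"(injected bursts: {len(gt.spindle_onsets)})")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    main(p.parse_args().seed)
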