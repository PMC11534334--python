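#!/usr/bin/env python
"""Simulate one TMR cueing session and the matching behavioral sessions.

Generates a 19-channel sleep recording with cue-locked slow waves and
SW-coupled spindle bursts (known ground truth), plus encoding / pre-sleep /
post-sleep trial tables for one subject whose easy (high-PP) words are cued.
Writes the text artifacts under results/session/; the EEG itself is
regenerated deterministically from the seed by the later steps.
"""

import argparse
import json
from pathlib import Path

from tmreeg import BehaviorSimParams, SleepSimParams, generate_behavior, simulate_sleep_session
from tmreeg.io_core import write_events

OUT = Path(__file__).resolve().parents[1] / "results" / "session"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rec, events, gt = simulate_sleep_session(SleepSimParams(), seed=seed)
    write_events(events, OUT / "events.tsv")
    (OUT / "ground_truth.json").write_text(json.dumps(gt.to_dict(), indent=2))

    tables = generate_behavior(BehaviorSimParams(cued_condition="high_pp", seed=seed))
    for name, tab in tables.items():
        tab.to_csv(OUT / f"behavior_{name}.tsv", sep="\t", index=False)

    print(f"recording: {rec.n_channels} channels, {rec.duration:.0f} s at {rec.fs:.0f} Hz")
    print(f"cues: {len(events)} (ISI 8±2 s)")
    print(f"injected: {len(gt.sw_trough_times)} slow waves, "
          f"{len(gt.spindle_onsets)} spindles "
          f"({sum(l is not None for l in gt.coupling_lags)} coupled)")
    print(f"behavior: {len(tables['encoding'])} encoding trials, "
          f"{len(tables['pre_sleep'])} memory trials per session")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    main(p.parse_args().seed)
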