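#!/usr/bin/env python
"""Score the simulated behavior with signal detection theory.

Reads the trial tables written by 01_simulate_session.py, computes per-
condition learning curves (d' over the three encoding presentations) and the
overnight change in d' and c-criterion, and writes both tables under
results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from tmreeg.behavior import score_session

ROOT = Path(__file__).resolve().parents[1]
SESSION = ROOT / "results" / "session"


def main() -> None:
    encoding = pd.read_csv(SESSION / "behavior_encoding.tsv", sep="\t")
    pre = pd.read_csv(SESSION / "behavior_pre_sleep.tsv", sep="\t")
    post = pd.read_csv(SESSION / "behavior_post_sleep.tsv", sep="\t")

    curves = score_session(encoding, by=("condition", "presentation"))
    curves.to_csv(ROOT / "results" / "learning_curves.tsv", sep="\t", index=False)
    print("encoding d' by condition and presentation:")
    print(curves[["condition", "presentation", "dprime"]].to_string(index=False))

    pre_s = score_session(pre).set_index("condition")
    post_s = score_session(post).set_index("condition")
    overnight = pd.DataFrame({
        "dprime_pre": pre_s["dprime"],
        "dprime_post": post_s["dprime"],
        "d_dprime": post_s["dprime"] - pre_s["dprime"],
        "d_criterion": post_s["criterion"] - pre_s["criterion"],
        "cued": [c == "high_pp" for c in pre_s.index],
    })
    overnight.to_csv(ROOT / "results" / "overnight_changes.tsv", sep="\t")
    print("\novernight changes (cued condition: high_pp):")
    print(overnight.round(3).to_string())


if __name__ == "__main__":
    argparse.ArgumentParser().parse_args()
    main()
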