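"""End-to-end orchestration: simulate -> detect -> couple -> TFR -> stats -> behavior.

A single YAML-serializable config drives every stage; unknown keys are
errors. Stage outputs are pure functions of (inputs, config, seed), and a
manifest records the parameter hash, seeds and per-stage counts needed to
reproduce each output file.
"""

from __future__ import annotations

import hashlib
import json
from copy import deepcopy

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import score_session
from .cluster_stats import Neighborhood, cluster_permutation_test, ttest_effsize
from .coupling import classify_coupling, coupled_amplitude_contrast, sw_locked_tfr, upstate_band_power
from .io_core import EventSet, Recording
from .spindles import detect_spindles, spindle_density
from .sw import detect_slow_waves, select_top_amplitude, sw_density
from .synthetic import BehaviorSimParams, SleepSimParams, generate_behavior, simulate_sleep_session

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "analyze_subject"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_per_group": 8,
        "n_cues": 30,
        "fs": 500.0,
        "n_channels": 19,
        "background_sd": 20.0,
        "sw_amplitude": 150.0,
        "spindle_amplitude": {"high_pp": 14.0, "low_pp": 8.0},
        "spindle_duration": 1.0,
        "spindle_freq": 13.0,
        "p_sw_per_cue": 0.6,
        "p_coupled": 0.8,
    },
    "detection": {
        "sw_channel": "Cz",
        "sw_band": [0.5, 3.0],
        "sw_search_window": [0.0, 6.0],
        "top_fraction": 0.30,
        "spindle_channel": "Pz",
        "spindle_band": [12.0, 16.0],
        "thr_sd": 1.25,
        "edge_sd": 0.75,
        "spindle_window": [-2.0, 8.0],
    },
    "tfr": {
        "freq_lo": 10.0,
        "freq_hi": 16.0,
        "freq_step": 1.0,
        "t_step": 0.02,
        "halfwidth": 2.0,
        "baseline": [-2.0, -1.5],
        "n_cycles": 7.0,
    },
    "stats": {
        "n_perm": 500,
        "cluster_alpha": 0.05,
        "min_chan": 2,
        "upstate_band": [11.0, 14.0],
        "upstate_window": [0.3, 0.8],
        "upstate_channels": ["Pz", "P3", "P4"],
    },
    "behavior": {
        "enabled": True,
        "n_words_per_set": 40,
    },
    "density": {
        "bin_s": 0.5,
        "range": [-1.5, 3.0],
        "baseline": [-1.5, 0.0],
    },
}


def _merge_validate(defaults: dict, override: dict, path: str = "") -> dict:
    out = deepcopy(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and not path + key == "simulate.spindle_amplitude":
            if not isinstance(value, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_validate(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(source=None) -> dict:
    """Build a validated config from a YAML path, a dict of overrides, or nothing."""
    import yaml

    if source is None:
        override = {}
    elif isinstance(source, dict):
        override = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
    return _merge_validate(DEFAULT_CONFIG, override)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def analyze_subject(recording: Recording, events: EventSet, config: dict) -> dict:
    """Run the per-subject sleep analysis: SW + spindle detection, coupling,
    SW-locked TFR and cue-locked density tables."""
    det, tf, dens = config["detection"], config["tfr"], config["density"]
    # the density analysis bins from before cue onset, so detection covers the
    # full peristimulus range; the coupling/TFR analyses use the post-onset
    # search window only
    w0, w1 = det["sw_search_window"]
    density_window = (min(w0, dens["range"][0]), w1)
    sw_all = detect_slow_waves(
        recording, channel=det["sw_channel"], band=tuple(det["sw_band"]),
        events=events, search_window=density_window,
    )
    sw_top = select_top_amplitude(sw_all, det["top_fraction"])
    sw_top_post = [e for e in sw_top if e.latency is not None and w0 <= e.latency <= w1]
    spindles = detect_spindles(
        recording, channel=det["spindle_channel"], band=tuple(det["spindle_band"]),
        thr_sd=det["thr_sd"], edge_sd=det["edge_sd"], events=events,
        window=tuple(det["spindle_window"]),
    )
    coupled = classify_coupling(spindles, sw_top_post)
    freqs = np.arange(tf["freq_lo"], tf["freq_hi"] + tf["freq_step"] / 2, tf["freq_step"])
    tfr = None
    if sw_top_post:
        try:
            tfr = sw_locked_tfr(
                recording, sw_top_post, halfwidth=tf["halfwidth"], freqs=freqs,
                baseline=tuple(tf["baseline"]), n_cycles=tf["n_cycles"],
                t_step=tf["t_step"],
            )
        except ValueError:
            tfr = None
    st = config["stats"]
    upstate = (
        upstate_band_power(tfr, band=tuple(st["upstate_band"]),
                           window=tuple(st["upstate_window"]),
                           channels=st["upstate_channels"])
        if tfr is not None else np.nan
    )
    return {
        "sw_events": sw_all,
        "sw_top": sw_top,
        "sw_top_post": sw_top_post,
        "spindles": spindles,
        "coupling": coupled,
        "amplitude_by_class": coupled_amplitude_contrast(coupled),
        "tfr": tfr,
        "upstate_power": upstate,
        "sw_density": sw_density(sw_top, len(events), bin_s=dens["bin_s"],
                                 time_range=tuple(dens["range"]),
                                 baseline=tuple(dens["baseline"])),
        "spindle_density": spindle_density(spindles, len(events)),
    }


def _upstate_box(tfr, config: dict) -> np.ndarray:
    st = config["stats"]
    band, window = st["upstate_band"], st["upstate_window"]
    fmask = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tmask = (tfr.times >= window[0]) & (tfr.times <= window[1])
    return tfr.power[:, fmask][:, :, tmask]


def run_pipeline(config: dict | None = None, out_dir=None, seed: int | None = None) -> dict:
    """Simulate a two-group cueing study and run the full analysis.

    Group 'high_pp' gets the larger coupled-spindle amplitude. Returns a
    result bundle (per-subject tables, cluster result on the up-state box,
    behavior scores) and, when ``out_dir`` is given, writes TSV/JSON outputs
    plus a manifest.
    """
    config = load_config(config)
    if seed is not None:
        config = dict(config, seed=int(seed))
    master = np.random.default_rng(config["seed"])
    sim = config["simulate"]

    groups = {"high_pp": [], "low_pp": []}
    subject_rows = []
    tfr_stack: dict[str, list] = {"high_pp": [], "low_pp": []}
    behavior_rows = []
    counts = {"sw": 0, "spindles": 0, "coupled": 0}
    channel_labels = None
    for cond in ("high_pp", "low_pp"):
        for s in range(sim["n_per_group"]):
            sub_seed = int(master.integers(2**31))
            params = SleepSimParams(
                n_cues=sim["n_cues"], fs=sim["fs"], n_channels=sim["n_channels"],
                background_sd=sim["background_sd"], sw_amplitude=sim["sw_amplitude"],
                spindle_amplitude=sim["spindle_amplitude"][cond],
                spindle_duration=sim["spindle_duration"],
                spindle_freq=sim["spindle_freq"], p_sw_per_cue=sim["p_sw_per_cue"],
                p_coupled=sim["p_coupled"], condition=cond,
            )
            rec, events, _gt = simulate_sleep_session(params, seed=sub_seed)
            channel_labels = list(rec.channel_labels)
            res = analyze_subject(rec, events, config)
            groups[cond].append(res)
            if res["tfr"] is not None:
                tfr_stack[cond].append((res["tfr"], _upstate_box(res["tfr"], config)))
            counts["sw"] += len(res["sw_events"])
            counts["spindles"] += len(res["spindles"])
            counts["coupled"] += sum(c.coupled for c in res["coupling"])
            amp = res["amplitude_by_class"]
            subject_rows.append({
                "group": cond, "subject": s, "seed": sub_seed,
                "n_sw": len(res["sw_events"]), "n_sw_top": len(res["sw_top"]),
                "n_spindles": len(res["spindles"]),
                "n_coupled": sum(c.coupled for c in res["coupling"]),
                "upstate_power": res["upstate_power"],
                "amp_coupled": amp.get("coupled", np.nan),
                "amp_uncoupled": amp.get("uncoupled", np.nan),
            })
            if config["behavior"]["enabled"]:
                bh = generate_behavior(BehaviorSimParams(
                    n_words_per_set=config["behavior"]["n_words_per_set"],
                    cued_condition=cond, seed=int(master.integers(2**31)),
                ))
                pre = score_session(bh["pre_sleep"], by=("condition",))
                post = score_session(bh["post_sleep"], by=("condition",))
                merged = pre.merge(post, on="condition", suffixes=("_pre", "_post"))
                for _, row in merged.iterrows():
                    behavior_rows.append({
                        "group": cond, "subject": s, "condition": row["condition"],
                        "cued": row["condition"] == cond,
                        "dprime_pre": row["dprime_pre"], "dprime_post": row["dprime_post"],
                        "d_dprime": row["dprime_post"] - row["dprime_pre"],
                        "d_criterion": row["criterion_post"] - row["criterion_pre"],
                    })

    subjects = pd.DataFrame(subject_rows)
    behavior = pd.DataFrame(behavior_rows)

    # group statistics on the up-state spindle-band box
    cluster = None
    if tfr_stack["high_pp"] and tfr_stack["low_pp"]:
        data_a = np.stack([box for _, box in tfr_stack["high_pp"]])
        data_b = np.stack([box for _, box in tfr_stack["low_pp"]])
        nbh = Neighborhood.from_montage(channel_labels)
        cluster = cluster_permutation_test(
            data_a, data_b, paired=False, neighborhood=nbh,
            n_perm=config["stats"]["n_perm"],
            cluster_alpha=config["stats"]["cluster_alpha"],
            min_chan=config["stats"]["min_chan"],
            seed=config["seed"],
        )

    upstate_t = None
    ha = subjects.loc[subjects["group"] == "high_pp", "upstate_power"].dropna()
    lo = subjects.loc[subjects["group"] == "low_pp", "upstate_power"].dropna()
    if len(ha) >= 2 and len(lo) >= 2:
        t, df, p, d = ttest_effsize(ha, lo, paired=False)
        upstate_t = {"t": t, "df": df, "p": p, "cohen_d": d}

    bundle = {
        "config": config,
        "subjects": subjects,
        "behavior": behavior,
        "cluster": cluster,
        "upstate_ttest": upstate_t,
        "counts": counts,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        subjects.to_csv(out_dir / "subjects.tsv", sep="\t", index=False)
        if len(behavior):
            behavior.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)
        cluster_json = None
        if cluster is not None:
            cluster_json = [
                {
                    "stat": c.stat,
                    "p": c.p,
                    "polarity": c.polarity,
                    "channels": sorted(c.channels),
                    "n_points": int(len(c.points)),
                }
                for c in cluster.clusters
            ]
            (out_dir / "clusters.json").write_text(json.dumps(cluster_json, indent=2))
        manifest = {
            "package_version": __version__,
            "config": config,
            "config_hash": _config_hash(config),
            "seed": config["seed"],
            "counts": counts,
            "n_subjects": int(len(subjects)),
            "outputs": sorted(p.name for p in out_dir.iterdir()),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = manifest
    return bundle
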