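"""Ground-truth recovery and calibration checks for the detection and
statistics stages.

These routines quantify, on synthetic data with known injected events, how
well the analysis recovers what was put in:

* slow-wave detection: sensitivity and trough-localization error at a given
  amplitude SNR (peak deviation of the injected wave over the broadband
  background SD);
* spindle detection: recall, false-discovery rate and boundary error at a
  given envelope SNR (injected envelope peak over the broadband background
  SD), with boundaries referenced to the closed-form threshold-crossing
  times of the noiseless injected envelope;
* cluster permutation test: empirical type-I error under the null and
  recovery of a localized multi-channel effect;
* SDT scoring: recovery of the generating accuracy from simulated sessions.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .behavior import score_session
from .cluster_stats import Neighborhood, cluster_permutation_test
from .montage import CHANNELS_19
from .preprocessing import bandpass_array
from .spindles import detect_spindles
from .sw import detect_slow_waves
from .synthetic import (
    BehaviorSimParams,
    generate_background,
    generate_behavior,
    generate_cue_events,
    inject_slow_waves,
    inject_spindles,
)

__all__ = [
    "sw_recovery",
    "spindle_recovery",
    "cluster_type1_error",
    "cluster_effect_recovery",
    "sdt_parameter_recovery",
    "pipeline_upstate_contrast",
]

_MATCH_WINDOW = 0.25  # s; a third of the 0.75 Hz slow-wave period


def sw_recovery(seed: int, snr: float = 3.0, n_sessions: int = 3, n_cues: int = 30,
                background_sd: float = 20.0, fs: float = 500.0) -> dict:
    """Inject cue-locked slow waves at the given SNR and measure recovery.

    SNR is the injected peak deviation (half the trough-to-peak amplitude)
    over the broadband background SD. Sensitivity counts injected troughs
    matched by a detection within ±0.25 s; the localization error is the
    median |Δt| of the matches.
    """
    rng = np.random.default_rng(seed)
    amplitude = 2.0 * snr * background_sd
    errors, n_matched, n_injected = [], 0, 0
    for _ in range(n_sessions):
        events = generate_cue_events(n_cues, seed=int(rng.integers(2**31)))
        duration = float(events.onsets[-1]) + 12.0
        bg = generate_background(duration, fs, 1, amplitude_scale=background_sd,
                                 seed=int(rng.integers(2**31)))
        troughs = events.onsets + rng.uniform(0.5, 1.5, size=n_cues)
        rec, _ = inject_slow_waves(bg, troughs, amplitude)
        det = detect_slow_waves(rec, channel=rec.channel_labels[0], events=events)
        dt = np.asarray([d.trough_time for d in det])
        n_injected += n_cues
        for t in troughs:
            if len(dt) == 0:
                continue
            err = float(np.min(np.abs(dt - t)))
            if err <= _MATCH_WINDOW:
                n_matched += 1
                errors.append(err)
    return {
        "sensitivity": n_matched / n_injected,
        "median_trough_error_ms": float(np.median(errors) * 1000.0) if errors else np.nan,
        "n_injected": n_injected,
    }


def spindle_recovery(seed: int, env_snr: float = 5.0, n_bursts: int = 20,
                     burst_duration: float = 1.0, background_sd: float = 20.0,
                     fs: float = 500.0) -> dict:
    """Inject cue-locked spindle bursts and measure recall / FDR / boundary error.

    The envelope SNR is the injected Hann-envelope peak over the broadband
    background SD. A detection matches an injected burst when their intervals
    overlap. Boundary errors are measured against the times where the
    noiseless injected envelope crosses the detector's edge threshold
    (mean + 0.75 SD of the cue-window envelope) — the ground truth an ideal
    edge-threshold detector would produce.
    """
    from scipy.signal import hilbert

    from .spindles import _cue_window_mask

    rng = np.random.default_rng(seed)
    amplitude = env_snr * background_sd
    events = generate_cue_events(n_bursts, seed=int(rng.integers(2**31)))
    duration = float(events.onsets[-1]) + 12.0
    bg = generate_background(duration, fs, 1, amplitude_scale=background_sd,
                             seed=int(rng.integers(2**31)))
    onsets = events.onsets + 1.0 - burst_duration / 2.0
    rec, _ = inject_spindles(bg, onsets=onsets, durations=burst_duration,
                             amplitudes=amplitude)
    det = detect_spindles(rec, channel=rec.channel_labels[0], events=events)

    env = np.abs(hilbert(bandpass_array(rec.data[0], 12.0, 16.0, fs)))
    mask = _cue_window_mask(len(env), fs, events.onsets, (-2.0, 8.0))
    thr_lo = float(env[mask].mean() + 0.75 * env[mask].std())
    frac = min(0.999, thr_lo / amplitude)
    tau = burst_duration * np.arccos(1.0 - 2.0 * frac) / (2.0 * np.pi)

    matched = np.zeros(n_bursts, dtype=bool)
    n_false = 0
    boundary_errors = []
    for d in det:
        hit = False
        for i, o in enumerate(onsets):
            if d.start_time < o + burst_duration and d.end_time > o:
                matched[i] = True
                hit = True
                boundary_errors.append(abs(d.start_time - (o + tau)))
                boundary_errors.append(abs(d.end_time - (o + burst_duration - tau)))
        if not hit:
            n_false += 1
    return {
        "recall": float(matched.mean()),
        "fdr": n_false / max(1, len(det)),
        "max_boundary_error_ms": float(np.max(boundary_errors) * 1000.0) if boundary_errors else np.nan,
        "n_injected": n_bursts,
        "n_detected": len(det),
    }


def _null_dataset(rng, n_subjects, shape):
    return rng.standard_normal((n_subjects, *shape))


def cluster_type1_error(seed: int, paired: bool, n_datasets: int = 200,
                        n_subjects: int = 15, n_freqs: int = 3, n_times: int = 10,
                        n_perm: int = 250, alpha: float = 0.05) -> dict:
    """Fraction of null datasets yielding any significant cluster (two-tailed)."""
    rng = np.random.default_rng(seed)
    nbh = Neighborhood.from_montage(CHANNELS_19)
    shape = (len(CHANNELS_19), n_freqs, n_times)
    n_fp = 0
    for i in range(n_datasets):
        a = _null_dataset(rng, n_subjects, shape)
        b = _null_dataset(rng, n_subjects, shape)
        res = cluster_permutation_test(a, b, paired=paired, neighborhood=nbh,
                                       n_perm=n_perm, seed=int(rng.integers(2**31)))
        if res.significant(alpha):
            n_fp += 1
    return {"rate": n_fp / n_datasets, "n_datasets": n_datasets}


def cluster_effect_recovery(seed: int, effect_channels=("P3", "Pz", "P4"),
                            effect_size: float = 1.5, n_subjects: int = 15,
                            n_freqs: int = 5, n_times: int = 10,
                            n_perm: int = 500) -> dict:
    """Inject a localized effect in adjacent channels and test its recovery.

    The effect (a mean shift of ``effect_size`` SD units) occupies the middle
    frequency rows of the named channels; the unpaired test should return a
    significant positive cluster containing at least two of them.
    """
    rng = np.random.default_rng(seed)
    nbh = Neighborhood.from_montage(CHANNELS_19)
    shape = (len(CHANNELS_19), n_freqs, n_times)
    a = _null_dataset(rng, n_subjects, shape)
    b = _null_dataset(rng, n_subjects, shape)
    idx = [CHANNELS_19.index(c) for c in effect_channels]
    fsel = slice(n_freqs // 2 - 1, n_freqs // 2 + 2)
    for c in idx:
        a[:, c, fsel, :] += effect_size
    res = cluster_permutation_test(a, b, paired=False, neighborhood=nbh,
                                   n_perm=n_perm, seed=seed)
    sig = res.significant(0.05)
    hit_channels = set()
    for cl in sig:
        if cl.polarity > 0:
            hit_channels |= cl.channels & set(effect_channels)
    return {
        "n_significant": len(sig),
        "effect_channels_recovered": len(hit_channels),
        "min_p": min((c.p for c in res.clusters), default=1.0),
    }


def sdt_parameter_recovery(seed: int, accuracy: float = 0.80,
                           n_sessions: int = 200) -> dict:
    """Recover the generating accuracy's analytic d' from simulated sessions.

    With symmetric response accuracy p the analytic d' is 2·z(p); the mean
    estimated d' over sessions should sit within ±0.1 of it.
    """
    rng = np.random.default_rng(seed)
    analytic = 2.0 * float(norm.ppf(accuracy))
    estimates = []
    for _ in range(n_sessions):
        params = BehaviorSimParams(
            memory_accuracy_pre={"high_pp": accuracy, "low_pp": accuracy},
            seed=int(rng.integers(2**31)),
        )
        tables = generate_behavior(params)
        scores = score_session(tables["pre_sleep"], by=("condition",))
        estimates.extend(scores["dprime"].tolist())
    return {
        "mean_dprime": float(np.mean(estimates)),
        "analytic_dprime": analytic,
        "abs_error": abs(float(np.mean(estimates)) - analytic),
        "n_sessions": n_sessions,
    }


def pipeline_upstate_contrast(seed: int, effect: bool, n_per_group: int = 6,
                              n_cues: int = 20, n_perm: int = 200) -> dict:
    """Full-pipeline check of the up-state spindle-band contrast.

    Simulates two cueing groups end to end (background + cue-locked SWs +
    coupled spindles), runs detection, coupling, SW-locked TFR and the
    unpaired cluster test on the 11-14 Hz / 0.3-0.8 s box. With ``effect``
    the groups differ in coupled-spindle amplitude; without it they share
    the same amplitude (the null).
    """
    from .pipeline import run_pipeline

    amplitudes = {"high_pp": 14.0, "low_pp": 8.0} if effect else \
        {"high_pp": 10.0, "low_pp": 10.0}
    config = {
        "seed": seed,
        "simulate": {
            "n_per_group": n_per_group,
            "n_cues": n_cues,
            "spindle_amplitude": amplitudes,
        },
        "stats": {"n_perm": n_perm},
        "behavior": {"enabled": False},
    }
    bundle = run_pipeline(config)
    cluster = bundle["cluster"]
    sig = cluster.significant(0.05) if cluster is not None else []
    return {
        "significant": bool(sig),
        "min_p": min((c.p for c in cluster.clusters), default=1.0) if cluster else 1.0,
        "n_subjects": int(len(bundle["subjects"])),
        "upstate_t": bundle["upstate_ttest"],
    }
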