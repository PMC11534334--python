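"""Synthetic sleep-EEG and behavior with known ground truth.

The generators emulate the structure the analysis assumes: NREM-like 1/f
background EEG, auditory cue trains with 8±2 s inter-stimulus intervals,
cue-locked slow waves (one biphasic sine cycle, trough then posterior
positive peak), 12-16 Hz Hann-windowed spindle bursts whose envelope peaks
nest 0.3-0.8 s after SW troughs, and two-condition reward-categorization
behavior with condition-specific learning curves. All generators are pure
functions of their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import EventSet, Recording
from .montage import CHANNELS_19

__all__ = [
    "GroundTruth",
    "BehaviorSimParams",
    "SleepSimParams",
    "generate_background",
    "generate_cue_events",
    "inject_slow_waves",
    "inject_spindles",
    "generate_behavior",
    "simulate_sleep_session",
]


@dataclass
class GroundTruth:
    """Injected-event bookkeeping: what a perfect detector should recover."""

    sw_trough_times: list[float] = field(default_factory=list)
    sw_amplitudes: list[float] = field(default_factory=list)
    spindle_onsets: list[float] = field(default_factory=list)
    spindle_durations: list[float] = field(default_factory=list)
    spindle_center_times: list[float] = field(default_factory=list)
    spindle_amplitudes: list[float] = field(default_factory=list)
    spindle_center_freqs: list[float] = field(default_factory=list)
    coupling_lags: list[float | None] = field(default_factory=list)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth()
        for name in self.__dataclass_fields__:
            setattr(out, name, getattr(self, name) + getattr(other, name))
        return out

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# EEG generators
# ---------------------------------------------------------------------------

def generate_background(duration_s: float, fs: float = 500.0, n_channels: int = 19,
                        spectral_exponent: float = 1.0, amplitude_scale: float = 20.0,
                        seed: int | None = None) -> Recording:
    """1/f^beta-shaped Gaussian noise, ``amplitude_scale`` µV SD per channel."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * fs))
    labels = list(CHANNELS_19[:n_channels]) if n_channels <= len(CHANNELS_19) else (
        list(CHANNELS_19) + [f"EXT{i}" for i in range(n_channels - len(CHANNELS_19))]
    )
    if amplitude_scale == 0:
        return Recording(np.zeros((n_channels, n)), fs, labels, reference="synthetic")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-spectral_exponent / 2.0)
    data = np.fft.irfft(spec * shaping[None, :], n=n, axis=1)
    sd = data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    data = data / sd * amplitude_scale
    return Recording(data, fs, labels, reference="synthetic")


def generate_cue_events(n_cues: int, isi_mean: float = 8.0, isi_jitter: float = 2.0,
                        seed: int | None = None, first_onset: float = 10.0,
                        condition=None) -> EventSet:
    """Cue train with ISIs uniform on [isi_mean - jitter, isi_mean + jitter]."""
    if n_cues < 1:
        raise ValueError("need at least one cue")
    if isi_jitter >= isi_mean:
        raise ValueError("jitter must be smaller than the mean ISI")
    rng = np.random.default_rng(seed)
    isis = rng.uniform(isi_mean - isi_jitter, isi_mean + isi_jitter, size=n_cues - 1)
    onsets = first_onset + np.concatenate([[0.0], np.cumsum(isis)])
    return EventSet.from_onsets(onsets, condition=condition)


def _sw_waveform(fs: float, freq_hz: float, amplitude: float) -> tuple[np.ndarray, int]:
    """One biphasic sine cycle (negative then positive half-wave).

    Returns (waveform, trough index); trough-to-posterior-peak equals
    ``amplitude``.
    """
    period = 1.0 / freq_hz
    n = int(round(period * fs))
    t = np.arange(n) / fs
    w = -(amplitude / 2.0) * np.sin(2.0 * np.pi * freq_hz * t)
    return w, int(round(period / 4.0 * fs))


def inject_slow_waves(recording: Recording, trough_times, amplitudes,
                      freq_hz: float = 0.75,
                      channel_weights=None) -> tuple[Recording, GroundTruth]:
    """Add one biphasic SW cycle per trough time; additive and reproducible.

    ``channel_weights`` scales the waveform per channel (default: all 1,
    i.e. a global slow wave). Overlapping injections sum with a warning.
    """
    trough_times = np.asarray(trough_times, dtype=float)
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), trough_times.shape)
    out = recording.copy()
    weights = (np.ones(recording.n_channels) if channel_weights is None
               else np.asarray(channel_weights, dtype=float))
    gt = GroundTruth()
    spans = []
    for t_trough, amp in zip(trough_times, amplitudes):
        w, trough_idx = _sw_waveform(recording.fs, freq_hz, amp)
        start = int(round(t_trough * recording.fs)) - trough_idx
        stop = start + len(w)
        if start < 0 or stop > recording.n_samples:
            raise ValueError(f"slow wave at {t_trough:.2f} s does not fit in the recording")
        if any(not (stop <= a or start >= b) for a, b in spans):
            warnings.warn("overlapping slow-wave injections are summed", stacklevel=2)
        spans.append((start, stop))
        out.data[:, start:stop] += weights[:, None] * w[None, :]
        gt.sw_trough_times.append(float(t_trough))
        gt.sw_amplitudes.append(float(amp))
    return out, gt


def inject_spindles(recording: Recording, onsets=None, durations=1.0,
                    center_freqs=13.0, amplitudes=10.0, coupled_to=None,
                    lags=None, channel_weights=None) -> tuple[Recording, GroundTruth]:
    """Add Hann-windowed sinusoidal bursts; envelope peak at the burst centre.

    Give either ``onsets`` (burst start times) or ``coupled_to`` (SW trough
    times) with ``lags``, in which case the envelope peak is placed at
    trough + lag. Centre frequencies outside 12-16 Hz are injected with a
    warning. Amplitude is the envelope peak (sinusoid amplitude at the
    centre), µV.
    """
    if (onsets is None) == (coupled_to is None):
        raise ValueError("give exactly one of onsets or coupled_to")
    if coupled_to is not None:
        coupled_to = np.asarray(coupled_to, dtype=float)
        if lags is None:
            raise ValueError("coupled injection needs lags")
        lags = np.broadcast_to(np.asarray(lags, dtype=float), coupled_to.shape)
        durations_arr = np.broadcast_to(np.asarray(durations, dtype=float), coupled_to.shape)
        centers = coupled_to + lags
        onsets_arr = centers - durations_arr / 2.0
        lag_list: list[float | None] = [float(l) for l in lags]
    else:
        onsets_arr = np.asarray(onsets, dtype=float)
        durations_arr = np.broadcast_to(np.asarray(durations, dtype=float), onsets_arr.shape)
        centers = onsets_arr + durations_arr / 2.0
        lag_list = [None] * len(onsets_arr)
    freqs_arr = np.broadcast_to(np.asarray(center_freqs, dtype=float), onsets_arr.shape)
    amps_arr = np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets_arr.shape)

    out = recording.copy()
    weights = (np.ones(recording.n_channels) if channel_weights is None
               else np.asarray(channel_weights, dtype=float))
    gt = GroundTruth()
    for onset, dur, f0, amp, lag, center in zip(
        onsets_arr, durations_arr, freqs_arr, amps_arr, lag_list, centers
    ):
        if dur <= 0 or dur >= recording.duration:
            raise ValueError("spindle duration must lie in (0, recording length)")
        if not 12.0 <= f0 <= 16.0:
            warnings.warn(f"spindle centre frequency {f0} Hz outside 12-16 Hz", stacklevel=2)
        n = int(round(dur * recording.fs))
        start = int(round(onset * recording.fs))
        if start < 0 or start + n > recording.n_samples:
            raise ValueError(f"spindle at {onset:.2f} s does not fit in the recording")
        t = np.arange(n) / recording.fs
        burst = amp * np.hanning(n) * np.sin(2.0 * np.pi * f0 * t)
        out.data[:, start : start + n] += weights[:, None] * burst[None, :]
        gt.spindle_onsets.append(float(onset))
        gt.spindle_durations.append(float(dur))
        gt.spindle_center_times.append(float(center))
        gt.spindle_amplitudes.append(float(amp))
        gt.spindle_center_freqs.append(float(f0))
        gt.coupling_lags.append(lag)
    return out, gt


# ---------------------------------------------------------------------------
# Behavior generator
# ---------------------------------------------------------------------------

_LETTER_GROUPS = {
    "C1": "bcdfghjklm",
    "C2": "npqrstvwxz",
    "V1": "aei",
    "V2": "ouy",
}
# letter-group sequences per word set; G1/G2 form the high-PP (easy)
# condition, G3/G4 the low-PP (difficult) condition
_SET_RULES = {
    "G1": ("C1", "V1", "V2", "C2"),
    "G2": ("C1", "V1", "C2", "V2"),
    "G3": ("V1", "C1", "C2", "V2"),
    "G4": ("V1", "C1", "V2", "C2"),
}
_SET_CONDITION = {"G1": "high_pp", "G2": "high_pp", "G3": "low_pp", "G4": "low_pp"}


@dataclass
class BehaviorSimParams:
    """Study conditions of the simulated reward-categorization experiment.

    Defaults: 4 word sets x 40 words (two sets per phonotactic-probability
    condition, half rewarded), three presentations during encoding, and
    per-presentation response accuracies that let the easy (high-PP)
    condition pull ahead of the difficult one from presentation 2 on. The
    pre-sleep accuracies sit near 80% (well above the 70%-accuracy inclusion
    threshold) and cueing the easy condition adds 3 accuracy points
    overnight, which corresponds to a d' gain of roughly 0.2-0.25.
    """

    n_words_per_set: int = 40
    presentations: int = 3
    encoding_accuracy: dict = field(default_factory=lambda: {
        "high_pp": (0.50, 0.68, 0.78),
        "low_pp": (0.50, 0.60, 0.70),
    })
    memory_accuracy_pre: dict = field(default_factory=lambda: {
        "high_pp": 0.80,
        "low_pp": 0.75,
    })
    overnight_accuracy_change: dict = field(default_factory=lambda: {
        ("high_pp", True): 0.03,
        ("high_pp", False): 0.0,
        ("low_pp", True): 0.0,
        ("low_pp", False): 0.0,
    })
    cued_condition: str = "high_pp"
    timeout_prob: float = 0.0
    points: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        for acc in self.encoding_accuracy.values():
            if any(not 0 <= p <= 1 for p in acc):
                raise ValueError("accuracies must lie in [0, 1]")
        for cond, p in self.memory_accuracy_pre.items():
            for key, delta in self.overnight_accuracy_change.items():
                if key[0] == cond and not 0 <= p + delta <= 1:
                    raise ValueError("post-sleep accuracy outside [0, 1]")
        if not 0 <= self.timeout_prob < 1:
            raise ValueError("timeout probability must lie in [0, 1)")


def _make_words(rng: np.random.Generator, n_per_set: int) -> pd.DataFrame:
    rows = []
    seen = set()
    for set_name, rule in _SET_RULES.items():
        made = 0
        while made < n_per_set:
            word = "".join(rng.choice(list(_LETTER_GROUPS[g])) for g in rule)
            if word in seen:
                continue
            seen.add(word)
            rows.append({"word_id": word, "word_set": set_name,
                         "condition": _SET_CONDITION[set_name]})
            made += 1
    words = pd.DataFrame(rows)
    # half of each set rewarded
    rewarded = []
    for set_name in _SET_RULES:
        idx = words.index[words["word_set"] == set_name].to_numpy()
        chosen = rng.permutation(idx)[: len(idx) // 2]
        rewarded.extend(chosen)
    words["reward_category"] = "unrewarded"
    words.loc[rewarded, "reward_category"] = "rewarded"
    return words


def _simulate_trials(rng, words: pd.DataFrame, accuracy_by_cond: dict,
                     presentation: int | None, timeout_prob: float,
                     points: int) -> pd.DataFrame:
    trials = words.copy()
    acc = trials["condition"].map(accuracy_by_cond).to_numpy(dtype=float)
    correct = rng.random(len(trials)) < acc
    timeout = rng.random(len(trials)) < timeout_prob
    response, rtype, pts = [], [], []
    for cat, ok, to in zip(trials["reward_category"], correct, timeout):
        if to:
            response.append("timeout")
            rtype.append("timeout")
            pts.append(0)
            continue
        if (cat == "rewarded") == ok:
            response.append("reward_button")
        else:
            response.append("noreward_button")
        from .behavior import classify_response

        rtype.append(classify_response(cat, response[-1]))
        pts.append(points if ok else -points)
    trials["response"] = response
    trials["response_type"] = rtype
    trials["correct"] = correct & ~timeout
    trials["points"] = pts
    if presentation is not None:
        trials["presentation"] = presentation
    return trials


def generate_behavior(params: BehaviorSimParams) -> dict[str, pd.DataFrame]:
    """Simulate encoding plus pre- and post-sleep memory sessions.

    Returns a dict with keys ``encoding`` (n_words x presentations rows in
    randomized order), ``pre_sleep`` and ``post_sleep`` (n_words rows each).
    Every table carries condition, reward category, response, response type,
    correctness and points; the encoding table also carries the presentation
    index (the k-th occurrence of a word is presentation k).
    """
    rng = np.random.default_rng(params.seed)
    words = _make_words(rng, params.n_words_per_set)

    # encoding: per-presentation accuracy, order randomized with occurrence
    # order preserved (the k-th showing of a word is presentation k)
    blocks = []
    for k in range(1, params.presentations + 1):
        acc = {c: a[k - 1] for c, a in params.encoding_accuracy.items()}
        blocks.append(_simulate_trials(rng, words, acc, k, params.timeout_prob,
                                       params.points))
    encoding = pd.concat(blocks, ignore_index=True)
    order = rng.permutation(len(encoding))
    encoding = encoding.iloc[order].reset_index(drop=True)
    encoding["presentation"] = encoding.groupby("word_id").cumcount() + 1
    encoding["trial"] = np.arange(1, len(encoding) + 1)

    def memory_session(which: str) -> pd.DataFrame:
        acc = {}
        for cond, pre in params.memory_accuracy_pre.items():
            if which == "pre":
                acc[cond] = pre
            else:
                cued = cond == params.cued_condition
                acc[cond] = pre + params.overnight_accuracy_change[(cond, cued)]
        tab = _simulate_trials(rng, words, acc, None, params.timeout_prob, params.points)
        tab = tab.iloc[rng.permutation(len(tab))].reset_index(drop=True)
        tab["trial"] = np.arange(1, len(tab) + 1)
        tab["session"] = which
        tab["cued"] = tab["condition"] == params.cued_condition
        return tab

    return {
        "encoding": encoding,
        "pre_sleep": memory_session("pre"),
        "post_sleep": memory_session("post"),
    }


# ---------------------------------------------------------------------------
# Whole-session sleep simulator
# ---------------------------------------------------------------------------

@dataclass
class SleepSimParams:
    """Study conditions of one simulated TMR cueing session.

    Cues arrive every 8±2 s. A fraction of cues evokes a slow wave whose
    trough falls 0.4-1.6 s post-onset (the cue-locked density elevation);
    background slow waves occur at a low spontaneous rate. Evoked slow waves
    carry a coupled spindle at a lag of 0.3-0.8 s with probability
    ``p_coupled``; uncoupled spindles occur at a spontaneous rate. Spindle
    amplitude is condition-dependent (``spindle_amplitude``), which is the
    contrast the up-state power analysis should recover.
    """

    n_cues: int = 40
    fs: float = 500.0
    n_channels: int = 19
    background_sd: float = 20.0
    spectral_exponent: float = 1.0
    sw_amplitude: float = 150.0
    sw_freq_hz: float = 0.75
    p_sw_per_cue: float = 0.6
    sw_latency_range: tuple[float, float] = (0.4, 1.6)
    background_sw_rate: float = 0.1  # spontaneous troughs per second (NREM-like)
    p_coupled: float = 0.8
    coupling_lag_range: tuple[float, float] = (0.3, 0.8)
    spindle_amplitude: float = 12.0
    spindle_duration: float = 1.0
    spindle_freq: float = 13.0
    background_spindle_rate: float = 0.02  # uncoupled spindles per second
    spindle_topography: str = "parietal"  # or "uniform"
    condition: str = "high_pp"


#: Relative fast-spindle amplitude per channel: central-parietal maximum.
_PARIETAL_WEIGHTS = {
    "Pz": 1.0, "P3": 0.9, "P4": 0.9, "Cz": 0.8, "C3": 0.7, "C4": 0.7,
    "P7": 0.6, "P8": 0.6, "O1": 0.6, "O2": 0.6, "Fz": 0.5,
    "F3": 0.4, "F4": 0.4, "T7": 0.4, "T8": 0.4,
    "F7": 0.3, "F8": 0.3, "Fp1": 0.25, "Fp2": 0.25,
}


def spindle_topography_weights(channel_labels, kind: str = "parietal") -> np.ndarray:
    """Per-channel spindle amplitude weights (1.0 everywhere for 'uniform')."""
    if kind == "uniform":
        return np.ones(len(channel_labels))
    if kind != "parietal":
        raise ValueError(f"unknown topography {kind!r}")
    return np.asarray([_PARIETAL_WEIGHTS.get(ch, 0.4) for ch in channel_labels])


def simulate_sleep_session(params: SleepSimParams, seed: int | None = None
                           ) -> tuple[Recording, EventSet, GroundTruth]:
    """One subject's cueing session: background + cue-locked SWs + coupled spindles."""
    rng = np.random.default_rng(seed)
    events = generate_cue_events(params.n_cues, seed=rng.integers(2**31))
    duration = float(events.onsets[-1]) + 12.0
    rec = generate_background(duration, params.fs, params.n_channels,
                              params.spectral_exponent, params.background_sd,
                              seed=rng.integers(2**31))

    # cue-locked slow waves
    evoked = rng.random(params.n_cues) < params.p_sw_per_cue
    latencies = rng.uniform(*params.sw_latency_range, size=params.n_cues)
    troughs = list(events.onsets[evoked] + latencies[evoked])
    # spontaneous slow waves, kept clear of the recording edges
    n_bg = rng.poisson(params.background_sw_rate * duration)
    troughs += list(rng.uniform(3.0, duration - 3.0, size=n_bg))
    troughs = sorted(troughs)
    # enforce a minimal separation so injections do not overlap
    min_sep = 1.0 / params.sw_freq_hz
    spaced = []
    for t in troughs:
        if not spaced or t - spaced[-1] >= min_sep:
            spaced.append(t)
    rec, gt_sw = inject_slow_waves(rec, spaced, params.sw_amplitude, params.sw_freq_hz)

    # coupled spindles on a subset of the injected slow waves
    coupled_mask = rng.random(len(spaced)) < params.p_coupled
    coupled_troughs = np.asarray(spaced)[coupled_mask]
    lags = rng.uniform(*params.coupling_lag_range, size=len(coupled_troughs))
    weights = spindle_topography_weights(rec.channel_labels, params.spindle_topography)
    gt = gt_sw
    if len(coupled_troughs):
        rec, gt_sp = inject_spindles(
            rec, coupled_to=coupled_troughs, lags=lags,
            durations=params.spindle_duration, center_freqs=params.spindle_freq,
            amplitudes=params.spindle_amplitude, channel_weights=weights,
        )
        gt = gt.merge(gt_sp)
    # spontaneous, uncoupled spindles
    n_unc = rng.poisson(params.background_spindle_rate * duration)
    if n_unc:
        onsets = np.sort(rng.uniform(3.0, duration - 5.0, size=n_unc))
        rec, gt_unc = inject_spindles(
            rec, onsets=onsets, durations=params.spindle_duration,
            center_freqs=params.spindle_freq, amplitudes=params.spindle_amplitude,
            channel_weights=weights,
        )
        gt = gt.merge(gt_unc)
    return rec, events, gt
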