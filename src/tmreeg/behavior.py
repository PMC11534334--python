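"""Signal-detection-theory scoring of the reward-categorization task.

A trial presents an artificial word from either the rewarded or the
unrewarded category; the subject presses the reward or no-reward button.
Correct responses to rewarded words are hits, correct rejections are correct
responses to unrewarded words, and the usual SDT quantities follow:

    d' = z(hit rate) - z(false-alarm rate)
    c  = -0.5 * (z(false-alarm rate) + z(hit rate))

with z the standard-normal quantile. Rates of 0 and 1 are replaced by
``0.5/n`` and ``(n - 0.5)/n`` before the z-transform. Timeout trials are
excluded from the counts (n is reduced accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

__all__ = [
    "SDTResult",
    "classify_response",
    "corrected_rate",
    "dprime",
    "criterion",
    "score_session",
    "overnight_change",
]

#: (reward_category, correct) -> response type, per the task's feedback matrix.
_RESPONSE_TYPES = {
    ("rewarded", True): "hit",
    ("rewarded", False): "miss",
    ("unrewarded", True): "correct_rejection",
    ("unrewarded", False): "false_alarm",
}


@dataclass
class SDTResult:
    """Per-cell signal-detection summary (one condition and/or presentation)."""

    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    n_rewarded: int
    n_unrewarded: int
    condition: str | None = None
    presentation: int | None = None


def classify_response(reward_category: str, response: str) -> str:
    """Map (reward category, button press) to hit / miss / correct_rejection / false_alarm.

    ``response`` is one of ``reward_button``, ``noreward_button``; timeouts
    must be excluded by the caller.
    """
    if response == "timeout":
        raise ValueError("timeout trials are excluded from SDT scoring")
    if reward_category not in ("rewarded", "unrewarded"):
        raise ValueError(f"unknown reward category {reward_category!r}")
    if response not in ("reward_button", "noreward_button"):
        raise ValueError(f"unknown response {response!r}")
    correct = (reward_category == "rewarded") == (response == "reward_button")
    return _RESPONSE_TYPES[(reward_category, correct)]


def corrected_rate(count: int, n: int) -> float:
    """``count / n`` with floor/ceiling correction: 0 -> 0.5/n and n -> (n-0.5)/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError(f"count {count} outside [0, {n}]")
    if count == 0:
        return 0.5 / n
    if count == n:
        return (n - 0.5) / n
    return count / n


def _check_rate(rate: float, name: str) -> None:
    if not 0.0 < rate < 1.0:
        raise ValueError(f"{name} must lie strictly in (0, 1); correct rates first")


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Discriminability d' = z(hit rate) - z(false-alarm rate)."""
    _check_rate(hit_rate, "hit_rate")
    _check_rate(fa_rate, "fa_rate")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def criterion(hit_rate: float, fa_rate: float) -> float:
    """Response bias c = -0.5 * (z(false alarms) + z(hits)); positive = conservative."""
    _check_rate(hit_rate, "hit_rate")
    _check_rate(fa_rate, "fa_rate")
    return float(-0.5 * (norm.ppf(fa_rate) + norm.ppf(hit_rate)))


def _score_cell(cell: pd.DataFrame) -> SDTResult | None:
    cell = cell[cell["response"] != "timeout"]
    rewarded = cell[cell["reward_category"] == "rewarded"]
    unrewarded = cell[cell["reward_category"] == "unrewarded"]
    n_r, n_u = len(rewarded), len(unrewarded)
    if n_r == 0 or n_u == 0:
        return None  # empty cell: missing result, not zero
    hits = int((rewarded["response_type"] == "hit").sum())
    fas = int((unrewarded["response_type"] == "false_alarm").sum())
    h = corrected_rate(hits, n_r)
    f = corrected_rate(fas, n_u)
    return SDTResult(h, f, dprime(h, f), criterion(h, f), n_r, n_u)


def score_session(trials: pd.DataFrame, by=("condition",)) -> pd.DataFrame:
    """Score a trial table per grouping cell.

    ``trials`` needs columns ``condition``, ``reward_category``, ``response``
    and ``response_type`` (the latter is recomputed if absent). Returns one
    row per cell with hit/false-alarm rates (corrected), d' and c.
    """
    trials = trials.copy()
    if "response_type" not in trials.columns:
        trials["response_type"] = [
            "timeout" if resp == "timeout" else classify_response(cat, resp)
            for cat, resp in zip(trials["reward_category"], trials["response"])
        ]
    by = list(by)
    rows = []
    for key, cell in trials.groupby(by, sort=True):
        res = _score_cell(cell)
        if res is None:
            continue
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row.update(
            hit_rate=res.hit_rate,
            fa_rate=res.fa_rate,
            dprime=res.dprime,
            criterion=res.criterion,
            n_rewarded=res.n_rewarded,
            n_unrewarded=res.n_unrewarded,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def overnight_change(pre: SDTResult, post: SDTResult) -> tuple[float, float]:
    """(post - pre) change in d' and criterion for the same condition."""
    if pre.condition != post.condition:
        raise ValueError(
            f"condition mismatch: pre={pre.condition!r} vs post={post.condition!r}"
        )
    return post.dprime - pre.dprime, post.criterion - pre.criterion
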