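"""Behavioral scoring for the n-back task: signal-detection sensitivity with
log-linear correction, the continuous trial-performance index, and its
fMRS-matched sliding-window AUC.

Trials are congruent (a response is expected) or incongruent (responding is a
false alarm).  d' is the standardized difference between hit and false-alarm
rates, with the log-linear count adjustment so perfect scores never map to
infinity.  The dynamic performance index scores every trial in [0, 1]: fast
correct responses approach 1, misses score 0, correct rejections score 1, and
false alarms are RT-penalized into [0, 0.25], slower false alarms scoring
lower.  Averaging scores within the fMRS sliding windows gives a behavioral
curve on the same grid as the EIB kinetics, summarized by its AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SdtSummary",
    "TrialScore",
    "dprime_loglinear",
    "score_trial",
    "score_session",
    "trial_times",
    "windowed_performance_auc",
]

RT_FLOOR_MS = 400.0
RT_CEIL_MS = 800.0
FA_MAX_SCORE = 0.25


@dataclass(frozen=True)
class SdtSummary:
    """Signal-detection summary with log-linear adjusted rates."""

    hits: int
    misses: int
    fas: int
    crs: int
    hit_rate: float
    fa_rate: float
    dprime: float


@dataclass(frozen=True)
class TrialScore:
    trial: int
    block: int
    type: str
    responded: bool
    rt_ms: float
    score: float


def dprime_loglinear(hits: int, n_congruent: int, fas: int, n_incongruent: int) -> SdtSummary:
    """d' with the log-linear correction applied to all rates.

    hit_rate = (hits + 0.5) / (n_congruent + 1), likewise for false alarms;
    d' = Φ⁻¹(hit_rate) − Φ⁻¹(fa_rate).  The adjustment keeps both rates inside
    (0, 1) so d' is always finite, including for perfect performance.
    """
    if n_congruent <= 0 or n_incongruent <= 0:
        raise ValueError("trial totals must be positive")
    if not (0 <= hits <= n_congruent and 0 <= fas <= n_incongruent):
        raise ValueError("counts must lie within their totals")
    hit_rate = (hits + 0.5) / (n_congruent + 1)
    fa_rate = (fas + 0.5) / (n_incongruent + 1)
    return SdtSummary(
        hits=hits,
        misses=n_congruent - hits,
        fas=fas,
        crs=n_incongruent - fas,
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        dprime=float(norm.ppf(hit_rate) - norm.ppf(fa_rate)),
    )


def _rt_norm(rt_ms: float) -> float:
    """RT normalized to [0, 1] over the empirical 400-800 ms band."""
    return float(np.clip((rt_ms - RT_FLOOR_MS) / (RT_CEIL_MS - RT_FLOOR_MS), 0.0, 1.0))


def score_trial(trial: pd.Series | dict, hit_floor: float = 0.0) -> TrialScore:
    """Continuous [0, 1] performance score for one trial.

    Congruent + response (hit): 1 − RTn (fast hits approach 1; ``hit_floor``
    optionally lifts the slow-hit floor above a miss).  Congruent without
    response (miss): 0.  Incongruent without response (correct rejection): 1.
    Incongruent + response (false alarm): 0.25 × (1 − RTn) — at most 0.25, with
    slower false alarms penalized harder.
    """
    t = dict(trial)
    responded = bool(t["responded"])
    rt = t.get("rt_ms", np.nan)
    if responded:
        if rt is None or not np.isfinite(rt):
            raise ValueError("responded trial lacks an RT")
        if rt < 0:
            raise ValueError("negative RT")
    congruent = t["type"] == "congruent"
    if congruent:
        score = max(1.0 - _rt_norm(rt), hit_floor) if responded else 0.0
    else:
        score = FA_MAX_SCORE * (1.0 - _rt_norm(rt)) if responded else 1.0
    return TrialScore(trial=int(t.get("trial", 0)), block=int(t.get("block", 0)),
                      type=t["type"], responded=responded,
                      rt_ms=float(rt) if responded else np.nan, score=float(score))


def score_session(trials: pd.DataFrame, hit_floor: float = 0.0) -> pd.DataFrame:
    """Score every trial of a session table (columns trial block type responded
    rt_ms); returns the table with a ``score`` column appended."""
    scores = [score_trial(row, hit_floor=hit_floor).score
              for _, row in trials.iterrows()]
    out = trials.copy()
    out["score"] = scores
    return out


def trial_times(n_trials: int, trial_duration_s: float = 2.5) -> np.ndarray:
    """Trial onset times with blocks concatenated: trial t starts at
    (t − 1) × 2.5 s on the session timeline."""
    return np.arange(n_trials) * trial_duration_s


def windowed_performance_auc(
    scored: pd.DataFrame,
    grid_windows,
    n_pairs: int,
    pair_seconds: float = 4.0,
    trial_duration_s: float = 2.5,
) -> tuple[np.ndarray, float]:
    """Per-window mean trial score on the fMRS grid, and its AUC.

    The fMRS windows (pair-index ranges) are mapped proportionally onto the
    behavioral timeline: a window covering pairs [a, b) covers session time
    [a, b) × 4 s, and every trial whose onset falls in that interval
    contributes.  Empty windows carry the previous window's value forward with
    a warning.  AUC is the trapezoid of (curve − curve[0]), mirroring the EIB
    normalization to the first frame.
    """
    scores = scored["score"].to_numpy(dtype=float)
    times = trial_times(len(scored), trial_duration_s)
    session_s = n_pairs * pair_seconds
    curve = []
    for a, b in grid_windows:
        lo, hi = a * pair_seconds, b * pair_seconds
        if lo < 0 or hi > session_s + 1e-9:
            raise ValueError("window outside the session timeline")
        in_win = (times >= lo) & (times < hi)
        if not in_win.any():
            warnings.warn("empty behavioral window; carrying previous value forward")
            curve.append(curve[-1] if curve else 0.0)
        else:
            curve.append(float(scores[in_win].mean()))
    curve = np.asarray(curve)
    auc = float(np.trapezoid(curve - curve[0])) if curve.size >= 2 else 0.0
    return curve, auc
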