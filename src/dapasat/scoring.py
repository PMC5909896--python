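"""Session scoring: minimum SOA, dyad metrics, response times, reliability.

The primary capacity measure is the minimum SOA (minSOA) presented within
the analysis window (first 54 trials by default); lower is better.  The
dyad ratio — correct answers immediately preceded by a correct answer,
divided by total correct answers — indexes sustained rather than
fragmentary processing.  Note the scoring definition of a dyad is
*overlapping* (a run of n hits contains n−1 dyad hits), unlike the
non-overlapping independent pairs that drive the staircase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .staircase import SessionResult, TrialRecord

__all__ = ["SessionSummary", "classify_dyads", "summarize", "icc"]


@dataclass(frozen=True)
class SessionSummary:
    min_soa_ms: int
    n_hits: int
    n_dyad_hits: int
    dyad_ratio: Optional[float]
    mean_rt_ms: Optional[float]
    dyad_ratio_first_half: Optional[float]
    dyad_ratio_second_half: Optional[float]
    incorrect_to_miss_ratio: Optional[float]
    n_trials_analyzed: int
    completed: bool
    min_soa_assigned: bool = False  # True when assigned, not measured


def classify_dyads(trials: Sequence[TrialRecord]) -> list[bool]:
    """Flag each trial that is a hit immediately preceded by a hit.

    Delayed hits count as hits on both sides of the dyad.
    """
    flags = []
    prev_hit = False
    for tr in trials:
        hit = tr.is_hit
        flags.append(hit and prev_hit)
        prev_hit = hit
    return flags


def summarize(session: SessionResult, analysis_window: int = 54) -> SessionSummary:
    """Reduce a session to its summary scores over the analysis window."""
    if not session.trials:
        raise ValueError("cannot summarize an empty session")
    trials = session.trials[:analysis_window]
    n = len(trials)
    flags = classify_dyads(session.trials)[:n]

    hits = [tr for tr in trials if tr.is_hit]
    n_hits = len(hits)
    n_dyad = sum(flags)
    dyad_ratio = n_dyad / n_hits if n_hits else None

    rts = [tr.rt_ms for tr in hits]
    mean_rt = float(np.mean(rts)) if rts else None

    half = analysis_window // 2

    def half_ratio(lo: int, hi: int) -> Optional[float]:
        h = sum(tr.is_hit for tr in trials[lo:hi])
        if h == 0:
            return None
        return sum(flags[lo:hi]) / h

    first = half_ratio(0, half)
    second = half_ratio(half, n) if n > half else None

    itm: Optional[float] = None
    if session.config.scoring_dialect == "two-key":
        n_inc = sum(tr.outcome in ("incorrect", "delayed_incorrect") for tr in trials)
        n_miss = sum(tr.outcome == "miss" for tr in trials)
        itm = n_inc / n_miss if n_miss else None

    return SessionSummary(
        min_soa_ms=min(tr.soa_ms for tr in trials),
        n_hits=n_hits,
        n_dyad_hits=n_dyad,
        dyad_ratio=dyad_ratio,
        mean_rt_ms=mean_rt,
        dyad_ratio_first_half=first,
        dyad_ratio_second_half=second,
        incorrect_to_miss_ratio=itm,
        n_trials_analyzed=n,
        completed=session.completed,
    )


def icc(score_matrix: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``score_matrix`` is subjects × sessions with no missing cells.  Computed
    from the two-way ANOVA mean squares:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    where MSR, MSC, MSE are the rows (subjects), columns (sessions) and
    error mean squares, n subjects, k sessions.
    """
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)
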