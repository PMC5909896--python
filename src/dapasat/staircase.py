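"""Dyad-adaptive staircase engine for the paced serial addition test.

The test presents a stream of spoken digits at a stimulus onset asynchrony
(SOA) controlled by a transformed up-down (2-down-1-up) staircase: the SOA
shrinks by a fixed proportion after every *independent* pair of consecutive
correct sums and grows by the same proportion after every miss or incorrect
answer.  Such a staircase equilibrates where the subject is sqrt(0.5) ~ 70.7%
correct.  Responses may arrive after the next digit has already played; these
delayed responses are registered one trial late and compensated retroactively
in the SOA ledger.

This module owns sequence generation, the trial-by-trial state machine, and
the session record.  Scoring lives in :mod:`dapasat.scoring`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "QUIT",
    "StaircaseConfig",
    "TrialRecord",
    "StaircaseState",
    "SessionResult",
    "generate_digit_sequence",
    "correct_sum",
    "step_adjust",
    "apply_outcome",
    "run_session",
    "scripted_responder",
]

#: Sentinel a responder callback may return to abandon the session.
QUIT = "QUIT"

OUTCOMES = frozenset(
    {"hit", "incorrect", "miss", "delayed_hit", "delayed_incorrect"}
)
HIT_OUTCOMES = frozenset({"hit", "delayed_hit"})


class ConfigurationError(ValueError):
    """Raised for an inconsistent staircase configuration."""


class ProtocolError(RuntimeError):
    """Raised when a responder callback returns a malformed response."""


class StateError(RuntimeError):
    """Raised on inconsistent staircase-state transitions."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive session.

    Defaults reproduce the published protocol: 3.5 s initial SOA, 5%
    proportional steps, digits 1-5 with each digit appearing twice per ten
    presentations, 54 response opportunities (108 in the extended mode).
    """

    initial_soa_ms: int = 3500
    step_fraction: float = 0.05
    n_trials: int = 54
    digit_low: int = 1
    digit_high: int = 5
    block_size: int = 10
    per_digit_per_block: int = 2
    scoring_dialect: str = "two-key"
    soa_floor_ms: int = 200
    rng_seed: Optional[int] = None

    def validate(self) -> None:
        if not (0.0 < self.step_fraction < 1.0):
            raise ConfigurationError(
                f"step_fraction must be in (0, 1), got {self.step_fraction}"
            )
        n_digits = self.digit_high - self.digit_low + 1
        if n_digits < 1:
            raise ConfigurationError("digit_high must be >= digit_low")
        if n_digits * self.per_digit_per_block != self.block_size:
            raise ConfigurationError(
                "block constraint violated: "
                f"{n_digits} digits x {self.per_digit_per_block} per block "
                f"!= block_size {self.block_size}"
            )
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.initial_soa_ms <= self.soa_floor_ms:
            raise ConfigurationError("initial_soa_ms must exceed soa_floor_ms")
        if self.scoring_dialect not in ("one-key", "two-key"):
            raise ConfigurationError(
                f"unknown scoring dialect {self.scoring_dialect!r}"
            )


@dataclass(frozen=True)
class TrialRecord:
    """One response opportunity.

    ``soa_after_ms`` is the SOA in force when the next trial is presented;
    it includes any retroactive adjustment resolved *at* this trial for the
    previous trial's delayed response, so the full SOA trajectory can be
    replayed from the record stream alone.
    """

    index: int
    digit: int
    correct_sum: int
    soa_ms: int
    outcome: str
    rt_ms: Optional[int]
    soa_after_ms: int

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.rt_ms is None) != (self.outcome == "miss"):
            raise ValueError("rt_ms must be present iff outcome != miss")

    @property
    def is_hit(self) -> bool:
        return self.outcome in HIT_OUTCOMES


@dataclass
class PendingDelayed:
    """Bookkeeping for a response that will register one trial late.

    Holds the pair counter as it stood at that trial's start (frozen while
    the resolution is outstanding); the provisional +1 up-unit has already
    been applied to the SOA.
    """

    pair_count_at_start: int


@dataclass
class StaircaseState:
    current_soa_ms: int
    pair_count: int = 0
    pending_delayed: Optional[PendingDelayed] = None
    n_down_units: int = 0
    n_up_units: int = 0
    soa_floor_ms: int = 200
    step_fraction: float = 0.05


@dataclass
class SessionResult:
    config: StaircaseConfig
    trials: list[TrialRecord]
    seed: Optional[int] = None
    training: Optional[object] = None  # TrainingRecord, attached by callers
    terminated_early: bool = False
    termination_reason: Optional[str] = None
    final_soa_ms: Optional[int] = None

    @property
    def completed(self) -> bool:
        return len(self.trials) == self.config.n_trials


def correct_sum(prev_digit: int, digit: int, config: StaircaseConfig | None = None) -> int:
    """Sum of the current digit and the immediately preceding one."""
    cfg = config or StaircaseConfig()
    for d in (prev_digit, digit):
        if not (cfg.digit_low <= d <= cfg.digit_high):
            raise ValueError(
                f"digit {d} outside configured range "
                f"[{cfg.digit_low}, {cfg.digit_high}]"
            )
    return prev_digit + digit


def generate_digit_sequence(
    config: StaircaseConfig, seed: Optional[int] = None
) -> list[int]:
    """Constrained pseudorandom digit stream of length ``n_trials + 1``.

    Each full block of ``block_size`` digits contains every digit in the
    configured range exactly ``per_digit_per_block`` times; the trailing
    partial block is a truncated shuffled block.  Identical digits may occur
    consecutively.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    n_digits = config.n_trials + 1
    digits_in_block = np.repeat(
        np.arange(config.digit_low, config.digit_high + 1),
        config.per_digit_per_block,
    )
    out: list[int] = []
    while len(out) < n_digits:
        block = rng.permutation(digits_in_block)
        out.extend(int(d) for d in block)
    return out[:n_digits]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (1795.5 -> 1796)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def step_adjust(soa_ms: int, net_units: int, step_fraction: float,
                soa_floor_ms: int = 200) -> int:
    """Apply a trial's net step units as one multiplicative adjustment.

    The units earned by a trial (including retroactive compensation for a
    delayed hit on the previous trial) are summed and applied in a *single*
    multiplication, ``soa * (1 + f * units)`` — so −2 units means ×0.90, not
    ×0.95² — then rounded to the nearest millisecond (halves away from zero)
    and clamped at the floor.
    """
    if net_units == 0:
        return max(int(soa_ms), soa_floor_ms)
    adjusted = soa_ms * (1.0 + step_fraction * net_units)
    return max(_round_half_away(adjusted), soa_floor_ms)


def apply_outcome(
    state: StaircaseState,
    outcome: str,
    resolved_delayed_info: Optional[dict] = None,
) -> StaircaseState:
    """Advance the staircase by one trial outcome (pure function).

    ``outcome`` is the trial's *registered* classification at presentation
    time: ``hit`` / ``incorrect`` / ``miss`` for on-time responses, or
    ``pending`` when no response registered before the next digit (the
    response will arrive late or never).  ``resolved_delayed_info`` must be
    supplied iff the previous trial is pending, as a dict with key
    ``outcome`` in {'hit', 'incorrect', 'miss'} giving the true late outcome
    ('miss' when the response never registered at all).

    Pair counting never spans an SOA reduction (pairs are independent) nor a
    miss/incorrect.  A delayed hit re-enters pair counting retroactively; a
    delayed incorrect keeps its already-applied +1 unit and resets the pair.
    """
    if (resolved_delayed_info is not None) != (state.pending_delayed is not None):
        raise StateError(
            "resolution info must be supplied iff a delayed trial is pending"
        )
    units = 0
    pair = state.pair_count
    down = state.n_down_units
    up = state.n_up_units
    pending = state.pending_delayed

    if pending is not None:
        true_outcome = resolved_delayed_info["outcome"]
        if true_outcome == "hit":
            p = pending.pair_count_at_start
            if p + 1 >= 2:
                should = -1
                pair = 0
            else:
                should = 0
                pair = p + 1
            retro = should - 1  # minus the +1 already applied at that trial
            units += retro
            if should == -1:
                down += 1
            up -= 1  # the provisional up-unit is repaid
        else:
            # delayed incorrect, or a response too late to register: the +1
            # already applied stands; the pair resets.
            pair = 0
        pending = None

    if outcome == "hit":
        pair += 1
        if pair >= 2:
            units -= 1
            down += 1
            pair = 0
    elif outcome in ("miss", "incorrect"):
        units += 1
        up += 1
        pair = 0
    elif outcome == "pending":
        units += 1
        up += 1
        # pair frozen at its value entering this trial; resolved next call
        pending = PendingDelayed(pair_count_at_start=pair)
    else:
        raise StateError(f"unknown registered outcome {outcome!r}")

    new_soa = step_adjust(
        state.current_soa_ms, units, state.step_fraction, state.soa_floor_ms
    )
    return replace(
        state,
        current_soa_ms=new_soa,
        pair_count=pair,
        pending_delayed=pending,
        n_down_units=down,
        n_up_units=up,
    )


ResponderCallback = Callable[[int, int, int, int], object]


def _classify(reported: Optional[int], rt_ms: Optional[int],
              correct: int, soa_ms: int, dialect: str) -> tuple[str, Optional[int]]:
    """Map a raw response to (outcome, rt) under the scoring dialect.

    Returns one of hit/incorrect/miss for on-time responses, or
    delayed_hit/delayed_incorrect when the RT exceeds the SOA.  In the
    one-key dialect the examiner keys only correct sums, so incorrect
    answers are indistinguishable from misses and delayed incorrects never
    register at all.
    """
    if reported is None:
        return "miss", None
    if rt_ms is None or rt_ms < 0:
        raise ProtocolError("a reported sum requires a nonnegative rt_ms")
    is_correct = reported == correct
    late = rt_ms > soa_ms
    if dialect == "one-key" and not is_correct:
        return "miss", None
    if late:
        return ("delayed_hit" if is_correct else "delayed_incorrect"), rt_ms
    return ("hit" if is_correct else "incorrect"), rt_ms


def run_session(
    config: StaircaseConfig,
    responder: ResponderCallback,
    seed: Optional[int] = None,
) -> SessionResult:
    """Run a full adaptive session against a responder callback.

    The callback receives ``(trial_index, digit, correct_sum, soa_ms)`` and
    returns ``(reported_sum_or_None, rt_ms)`` — ``None`` meaning no response
    — or the :data:`QUIT` sentinel to abandon the session.  Lateness is
    decided by ``rt_ms > soa_ms``; a late response registers during the next
    trial and triggers retroactive SOA compensation if it was a hit.  A
    response still pending after the last trial is resolved in a final
    bookkeeping step without a new trial.
    """
    config.validate()
    use_seed = config.rng_seed if seed is None else seed
    digits = generate_digit_sequence(config, use_seed)
    state = StaircaseState(
        current_soa_ms=config.initial_soa_ms,
        soa_floor_ms=config.soa_floor_ms,
        step_fraction=config.step_fraction,
    )
    dialect = config.scoring_dialect
    trials: list[TrialRecord] = []
    terminated = False
    reason: Optional[str] = None
    # Raw classification of the previous trial if it is pending resolution.
    pending_raw: Optional[tuple[str, int, int]] = None  # (outcome, rt, soa)

    for t in range(1, config.n_trials + 1):
        digit = digits[t]
        csum = digits[t - 1] + digit
        soa = state.current_soa_ms
        resp = responder(t, digit, csum, soa)
        if resp == QUIT:
            terminated = True
            reason = "quit"
            break
        try:
            reported, rt = resp  # type: ignore[misc]
        except (TypeError, ValueError) as exc:
            raise ProtocolError(f"malformed responder return {resp!r}") from exc
        if reported is not None and not isinstance(reported, (int, np.integer)):
            raise ProtocolError(f"reported sum must be int or None, got {reported!r}")

        outcome, rt_kept = _classify(reported, rt, csum, soa, dialect)

        resolution = None
        if pending_raw is not None:
            p_outcome, p_rt, p_soa = pending_raw
            # More than one trial late: never registered; treat as miss.
            if p_rt >= p_soa + soa:
                resolution = {"outcome": "miss"}
                trials[-1] = replace(trials[-1], outcome="miss", rt_ms=None)
            else:
                resolution = {
                    "outcome": "hit" if p_outcome == "delayed_hit" else "incorrect"
                }
            pending_raw = None

        if outcome in ("delayed_hit", "delayed_incorrect"):
            registered = "pending"
            pending_raw = (outcome, rt_kept, soa)
        else:
            registered = outcome

        new_state = apply_outcome(state, registered, resolution)
        soa_after = new_state.current_soa_ms
        trials.append(
            TrialRecord(
                index=t,
                digit=digit,
                correct_sum=csum,
                soa_ms=soa,
                outcome=outcome,
                rt_ms=rt_kept,
                soa_after_ms=soa_after,
            )
        )
        state = new_state

    # Final bookkeeping: resolve a response still pending at session end.
    if pending_raw is not None:
        p_outcome, p_rt, p_soa = pending_raw
        if p_rt >= p_soa + state.current_soa_ms:
            resolution = {"outcome": "miss"}
            trials[-1] = replace(trials[-1], outcome="miss", rt_ms=None)
        else:
            resolution = {
                "outcome": "hit" if p_outcome == "delayed_hit" else "incorrect"
            }
        # No new trial: apply only the retroactive units.
        state = _resolve_only(state, resolution)
        if trials:
            trials[-1] = replace(trials[-1], soa_after_ms=state.current_soa_ms)

    return SessionResult(
        config=config,
        trials=trials,
        seed=use_seed,
        terminated_early=terminated,
        termination_reason=reason,
        final_soa_ms=state.current_soa_ms,
    )


def _resolve_only(state: StaircaseState, resolution: dict) -> StaircaseState:
    """Apply just the retroactive resolution of a pending delayed response."""
    if state.pending_delayed is None:
        raise StateError("no pending delayed response to resolve")
    units = 0
    pair = state.pair_count
    down, up = state.n_down_units, state.n_up_units
    if resolution["outcome"] == "hit":
        p = state.pending_delayed.pair_count_at_start
        if p + 1 >= 2:
            units -= 2  # earned -1, repay the provisional +1
            down += 1
            pair = 0
        else:
            units -= 1
            pair = p + 1
        up -= 1
    else:
        pair = 0
    new_soa = step_adjust(
        state.current_soa_ms, units, state.step_fraction, state.soa_floor_ms
    )
    return replace(
        state,
        current_soa_ms=new_soa,
        pair_count=pair,
        pending_delayed=None,
        n_down_units=down,
        n_up_units=up,
    )


def scripted_responder(
    script: Sequence[str],
    rt_on_time: int = 1000,
    late_by: int = 376,
) -> ResponderCallback:
    """Responder replaying a per-trial outcome script.

    Script tokens: ``'h'`` on-time hit, ``'H'`` same (dyad-hit notation),
    ``'L'`` late (delayed) hit, ``'i'`` on-time incorrect, ``'I'`` late
    incorrect, ``'m'`` miss, ``'q'`` quit.  Late responses report
    ``soa + late_by`` ms.
    """

    def responder(index: int, digit: int, csum: int, soa_ms: int):
        token = script[index - 1]
        if token == "q":
            return QUIT
        if token == "m":
            return (None, None)
        rt = soa_ms + late_by if token in ("L", "I") else min(rt_on_time, soa_ms)
        correct = token in ("h", "H", "L")
        reported = csum if correct else csum + 1
        return (reported, rt)

    return responder
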