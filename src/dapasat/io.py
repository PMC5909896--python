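"""Session and cohort file formats.

Tabular artifacts are CSV with period decimal separators and times in
integer milliseconds; nested session envelopes are JSON.  Round-trips are
lossless field-for-field.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Union

import pandas as pd

from .malingering import TrainingRecord
from .staircase import OUTCOMES, SessionResult, StaircaseConfig, TrialRecord

__all__ = [
    "write_session_csv",
    "read_session_csv",
    "write_session_json",
    "read_session_json",
    "write_cohort_csv",
    "read_cohort_csv",
]

PathLike = Union[str, Path]

_CSV_COLUMNS = [
    "trial", "digit", "correct_sum", "soa_ms", "outcome", "rt_ms", "soa_after_ms",
]


class SessionParseError(ValueError):
    """Malformed session file (names the offending row/field)."""


def write_session_csv(session: SessionResult, path: PathLike) -> None:
    """One row per trial; rt_ms is empty for misses."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for tr in session.trials:
            w.writerow([
                tr.index, tr.digit, tr.correct_sum, tr.soa_ms, tr.outcome,
                "" if tr.rt_ms is None else tr.rt_ms, tr.soa_after_ms,
            ])


def read_session_csv(path: PathLike,
                     config: StaircaseConfig | None = None) -> SessionResult:
    """Parse a trial log back into a session (config defaults if absent)."""
    trials: list[TrialRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SessionParseError(f"{path}: empty file")
        missing = [c for c in _CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SessionParseError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            outcome = row["outcome"]
            if outcome not in OUTCOMES:
                raise SessionParseError(
                    f"{path}: row {lineno}: unknown outcome token {outcome!r}; "
                    f"expected one of {sorted(OUTCOMES)}"
                )
            try:
                rt = None if row["rt_ms"] == "" else int(row["rt_ms"])
                trials.append(TrialRecord(
                    index=int(row["trial"]),
                    digit=int(row["digit"]),
                    correct_sum=int(row["correct_sum"]),
                    soa_ms=int(row["soa_ms"]),
                    outcome=outcome,
                    rt_ms=rt,
                    soa_after_ms=int(row["soa_after_ms"]),
                ))
            except (KeyError, ValueError) as exc:
                raise SessionParseError(f"{path}: row {lineno}: {exc}") from exc
    if not trials:
        raise SessionParseError(f"{path}: no trial rows")
    cfg = config or StaircaseConfig(n_trials=len(trials))
    return SessionResult(config=cfg, trials=trials)


def _config_to_dict(cfg: StaircaseConfig) -> dict:
    return dataclasses.asdict(cfg)


def write_session_json(session: SessionResult, path: PathLike) -> None:
    """Full session envelope: config, seed, training, trials, termination."""
    training = None
    if session.training is not None:
        tr: TrainingRecord = session.training  # type: ignore[assignment]
        training = {
            "blocks": list(tr.blocks),
            "final_accuracy": tr.final_accuracy,
            "passed": tr.passed,
            "quit": tr.quit,
        }
    payload = {
        "config": _config_to_dict(session.config),
        "seed": session.seed,
        "training": training,
        "terminated_early": session.terminated_early,
        "termination_reason": session.termination_reason,
        "final_soa_ms": session.final_soa_ms,
        "trials": [dataclasses.asdict(tr) for tr in session.trials],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_session_json(path: PathLike) -> SessionResult:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SessionParseError(f"{path}: invalid JSON: {exc}") from exc
    try:
        cfg = StaircaseConfig(**payload["config"])
        trials = [TrialRecord(**tr) for tr in payload["trials"]]
    except (KeyError, TypeError, ValueError) as exc:
        raise SessionParseError(f"{path}: {exc}") from exc
    training = None
    if payload.get("training") is not None:
        t = payload["training"]
        training = TrainingRecord(
            blocks=tuple(t["blocks"]),
            final_accuracy=t["final_accuracy"],
            passed=t["passed"],
            quit=t.get("quit", False),
        )
    return SessionResult(
        config=cfg,
        trials=trials,
        seed=payload.get("seed"),
        training=training,
        terminated_early=payload.get("terminated_early", False),
        termination_reason=payload.get("termination_reason"),
        final_soa_ms=payload.get("final_soa_ms"),
    )


def write_cohort_csv(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
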