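"""Synthetic responders and cohorts for exercising the adaptive test.

No public trial-level human data exist for this paradigm, so every pipeline
stage is validated against simulated subjects whose statistical structure
matches the published cohort anchors: a logistic-in-log-SOA psychometric
function (monotone in SOA, stabilizing the 2-down-1-up staircase near
sqrt(0.5) ~ 70.7% correct), lognormal response times that occasionally
exceed the SOA (~10% of trials, late by a few hundred ms), and a
demographic ability link anchored to the shipped normative regression.

The ability link targets the subject's staircase *equilibrium* SOA — the
SOA at which p_correct equals sqrt(0.5) — rather than the 50% threshold,
because the norm model predicts minSOA, and a subject's minSOA hovers at
their staircase equilibrium.  The equilibrium is converted to the logistic
threshold in closed form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .malingering import TrainingRecord, run_training
from .norms import Demographics, NormModel, load_default_model, predict_minsoa, score_noncompleter
from .scoring import SessionSummary, summarize
from .staircase import QUIT, SessionResult, StaircaseConfig, run_session

__all__ = [
    "ResponderParams",
    "CohortSpec",
    "p_correct",
    "make_responder",
    "simulate_session",
    "simulate_cohort",
    "simulate_retest",
    "exp1a_cohort_spec",
    "load_calibration",
]

_EQUILIBRIUM_P = math.sqrt(0.5)  # 2-down-1-up convergence point


def load_calibration() -> dict:
    """Simulator calibration constants (RT model, error mix, defaults)."""
    text = resources.files("dapasat.data").joinpath("calibration.json").read_text()
    return json.loads(text)


_CAL = load_calibration()


@dataclass(frozen=True)
class ResponderParams:
    """Psychometric description of one simulated subject.

    ``threshold_ms`` is the SOA at which the lapse-free probability of a
    correct sum is 0.5; ``slope`` is the logistic steepness in log-SOA
    units; ``lapse`` is an SOA-independent error floor.  Response times are
    lognormal (median ``rt_median_ms``, log-sd ``rt_log_sd``); with
    ``rt_soa_coupling`` > 0 the median inflates as the SOA drops below the
    threshold.  Strategies: ``standard``, ``alternate_answer`` (answers
    only non-overlapping digit pairs), ``malingerer`` (test-phase threshold
    inflated, training intact), ``quitter`` (per-trial quit hazard).
    """

    threshold_ms: float
    slope: float = _CAL["default_slope"]
    lapse: float = _CAL["default_lapse"]
    rt_median_ms: float = _CAL["rt_median_ms"]
    rt_log_sd: float = _CAL["rt_log_sd"]
    rt_soa_coupling: float = _CAL["rt_soa_coupling"]
    miss_dominance: float = _CAL["miss_dominance"]
    strategy: str = "standard"
    p_quit: float = 0.0
    malinger_threshold_multiplier: float = 1.5
    training_boost: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_ms <= 0:
            raise ValueError("threshold_ms must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.rt_log_sd <= 0:
            raise ValueError("rt_log_sd must be positive")
        if self.strategy not in (
            "standard", "alternate_answer", "malingerer", "quitter"
        ):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def _effective_threshold(params: ResponderParams, phase: str) -> float:
    if params.strategy == "malingerer" and phase == "test":
        return params.threshold_ms * params.malinger_threshold_multiplier
    return params.threshold_ms


def p_correct(soa_ms: float, params: ResponderParams, phase: str = "test") -> float:
    """Probability of a correct sum at a given SOA.

    ``(1 - lapse) * logistic(slope * (ln soa - ln threshold))`` — strictly
    increasing in SOA, approaching ``1 - lapse`` at long SOAs.  During
    training a malingerer uses the unimpaired threshold plus any
    ``training_boost``.
    """
    if soa_ms <= 0:
        raise ValueError("soa_ms must be positive")
    theta = _effective_threshold(params, phase)
    p = (1.0 - params.lapse) * float(
        expit(params.slope * (math.log(soa_ms) - math.log(theta)))
    )
    if phase == "training" and params.strategy == "malingerer":
        p = min(1.0, p + params.training_boost)
    return p


def equilibrium_to_threshold(
    equilibrium_soa_ms: float, slope: float, lapse: float
) -> float:
    """Threshold whose staircase equilibrium SOA equals the given value.

    Solves ``(1 - lapse) * logistic(slope * ln(eq / theta)) = sqrt(0.5)``.
    """
    p_star = _EQUILIBRIUM_P / (1.0 - lapse)
    if p_star >= 1.0:
        raise ValueError("lapse too large for the staircase to equilibrate")
    return equilibrium_soa_ms / math.exp(float(logit(p_star)) / slope)


def _draw_rt(params: ResponderParams, soa_ms: float, theta: float,
             rng: np.random.Generator) -> int:
    median = params.rt_median_ms
    if params.rt_soa_coupling > 0:
        deficit = max(0.0, (theta - soa_ms) / theta)
        median *= 1.0 + params.rt_soa_coupling * deficit
    rt = math.exp(rng.normal(math.log(median), params.rt_log_sd))
    return max(1, int(round(rt)))


def make_responder(
    params: ResponderParams,
    rng: np.random.Generator,
    phase: str = "test",
    sum_low: int = 2,
    sum_high: int = 10,
):
    """Build a responder callback for :func:`dapasat.staircase.run_session`."""

    def responder(index: int, digit: int, csum: int, soa_ms: int):
        if params.strategy == "quitter" and rng.random() < params.p_quit:
            return QUIT
        if params.strategy == "alternate_answer":
            # Sums only non-overlapping digit pairs: answers trials 1, 3, ...
            if index % 2 == 1:
                return (csum, _draw_rt(params, soa_ms, params.threshold_ms, rng))
            return (None, None)
        theta = _effective_threshold(params, phase)
        if rng.random() < p_correct(soa_ms, params, phase):
            return (csum, _draw_rt(params, soa_ms, theta, rng))
        if rng.random() < params.miss_dominance:
            return (None, None)
        wrong = int(rng.integers(sum_low, sum_high + 1))
        while wrong == csum:
            wrong = int(rng.integers(sum_low, sum_high + 1))
        return (wrong, _draw_rt(params, soa_ms, theta, rng))

    return responder


def respond(trial_context: tuple, params: ResponderParams,
            rng: np.random.Generator, phase: str = "test"):
    """One-shot response to ``(index, digit, correct_sum, soa_ms)``."""
    return make_responder(params, rng, phase)(*trial_context)


def simulate_session(
    params: ResponderParams,
    config: Optional[StaircaseConfig] = None,
    seed: Optional[int] = None,
) -> SessionResult:
    """Run one adaptive session for a simulated subject (deterministic per seed)."""
    cfg = config or StaircaseConfig()
    ss = np.random.SeedSequence(seed)
    digit_seed, resp_seed = ss.spawn(2)
    rng = np.random.default_rng(resp_seed)
    responder = make_responder(
        params, rng, phase="test",
        sum_low=2 * cfg.digit_low, sum_high=2 * cfg.digit_high,
    )
    return run_session(cfg, responder, seed=int(digit_seed.generate_state(1)[0] % (2**31)))


@dataclass(frozen=True)
class CohortSpec:
    """Population recipe: demographics, ability link, strategy mix.

    Defaults emulate the large normative cohort: ages 18-65 (mean 46.2),
    12.4 years of education, computer-use averaging 4.8 on the 8-point
    scale.  Each subject's staircase-equilibrium SOA is
    ``a + b * predicted_minSOA(demographics) + noise`` with defaults a=0,
    b=1; ``subject_noise_sd_ms`` carries the ability variance the
    demographics do not explain.
    """

    n: int
    age_mean: float = 46.2
    age_sd: float = 11.8
    age_range: tuple[float, float] = (18.0, 65.0)
    edu_mean: float = 12.4
    edu_sd: float = 3.4
    edu_range: tuple[float, float] = (6.0, 20.0)
    cuse_mean: float = 4.77
    cuse_sd: float = 2.25
    ability_intercept_ms: float = 0.0
    ability_slope: float = 1.0
    subject_noise_sd_ms: float = _CAL["equilibrium_noise_sd_ms"]
    psychometric_slope: float = _CAL["default_slope"]
    lapse: float = _CAL["default_lapse"]
    malingerer_fraction: float = 0.0
    noncompleter_fraction: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for f in (self.malingerer_fraction, self.noncompleter_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.malingerer_fraction + self.noncompleter_fraction > 1.0:
            raise ValueError("strategy fractions must sum to <= 1")


def exp1a_cohort_spec(n: int, seed: Optional[int] = None, **overrides) -> CohortSpec:
    """Cohort spec calibrated to the large normative population.

    The ability-link intercept compensates for the minimum-over-window
    statistic sitting systematically below the staircase equilibrium (the
    54-trial minSOA is the lowest excursion of a fluctuating trajectory);
    it is calibrated once against the normative cohort mean minSOA and
    stored with the other calibration constants.
    """
    overrides.setdefault(
        "ability_intercept_ms", _CAL["exp1a_ability_intercept_ms"]
    )
    return CohortSpec(n=n, seed=seed, **overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def draw_demographics(spec: CohortSpec, rng: np.random.Generator) -> Demographics:
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_range)
    edu = _truncated_normal(rng, spec.edu_mean, spec.edu_sd, *spec.edu_range)
    cuse = int(np.clip(round(rng.normal(spec.cuse_mean, spec.cuse_sd)), 1, 8))
    sex = "male" if rng.random() < 0.4 else "female"
    return Demographics(age=age, education=edu, computer_use=cuse, sex=sex)


def draw_responder(
    spec: CohortSpec,
    demo: Demographics,
    rng: np.random.Generator,
    model: Optional[NormModel] = None,
    strategy: str = "standard",
) -> ResponderParams:
    """Sample a subject's psychometric parameters from the ability link."""
    m = model or load_default_model()
    eq = (
        spec.ability_intercept_ms
        + spec.ability_slope * predict_minsoa(demo, m)
        + rng.normal(0.0, spec.subject_noise_sd_ms)
    )
    eq = max(600.0, eq)
    theta = equilibrium_to_threshold(eq, spec.psychometric_slope, spec.lapse)
    return ResponderParams(
        threshold_ms=theta,
        slope=spec.psychometric_slope,
        lapse=spec.lapse,
        strategy=strategy,
    )


def _subject_row(sid: int, demo: Demographics, summary: Optional[SessionSummary],
                 training: Optional[TrainingRecord],
                 session: Optional[SessionResult]) -> dict:
    row = {
        "id": sid,
        "age": round(demo.age, 2),
        "education_years": round(demo.education, 2),
        "computer_use": demo.computer_use,
        "sex": demo.sex,
        "training_final_accuracy": (
            training.final_accuracy if training is not None else None
        ),
    }
    if summary is not None:
        row.update(
            min_soa_ms=summary.min_soa_ms,
            dyad_ratio=summary.dyad_ratio,
            mean_rt_ms=summary.mean_rt_ms,
            completed=summary.completed,
            min_soa_assigned=summary.min_soa_assigned,
            n_hits=summary.n_hits,
            n_trials_analyzed=summary.n_trials_analyzed,
        )
    if session is not None:
        row["admin_time_min"] = (
            sum(tr.soa_ms for tr in session.trials) / 60000.0
        )
    return row


def simulate_cohort(
    spec: CohortSpec,
    config: Optional[StaircaseConfig] = None,
    model: Optional[NormModel] = None,
    keep_sessions: bool = False,
) -> tuple[pd.DataFrame, list[Optional[SessionResult]]]:
    """Simulate a full cohort: training, adaptive session, summary table.

    Subjects drawn as non-completers (refusals or training failures) get the
    assigned minSOA equal to the initial SOA and no adaptive session.
    Returns the cohort table and, when ``keep_sessions``, the session list
    (None for non-completers).
    """
    cfg = config or StaircaseConfig()
    m = model or load_default_model()
    root = np.random.SeedSequence(spec.seed)
    demo_ss, strat_ss, subj_ss = root.spawn(3)
    rng = np.random.default_rng(demo_ss)
    strat_rng = np.random.default_rng(strat_ss)
    subject_seeds = subj_ss.spawn(spec.n)

    rows: list[dict] = []
    sessions: list[Optional[SessionResult]] = []
    for i in range(spec.n):
        demo = draw_demographics(spec, rng)
        u = strat_rng.random()
        if u < spec.noncompleter_fraction:
            assigned = score_noncompleter(cfg.initial_soa_ms)
            row = _subject_row(i, demo, None, None, None)
            row.update(
                min_soa_ms=assigned["min_soa_ms"],
                min_soa_assigned=True,
                completed=False,
                dyad_ratio=None, mean_rt_ms=None,
                n_hits=None, n_trials_analyzed=0,
            )
            rows.append(row)
            sessions.append(None)
            continue
        strategy = (
            "malingerer"
            if u < spec.noncompleter_fraction + spec.malingerer_fraction
            else "standard"
        )
        params = draw_responder(spec, demo, rng, m, strategy)
        srng = np.random.default_rng(subject_seeds[i])
        train_seed = int(srng.integers(0, 2**31 - 1))
        sess_seed = int(srng.integers(0, 2**31 - 1))
        train_rng = np.random.default_rng(train_seed)
        training = run_training(
            make_responder(params, train_rng, phase="training"),
            fixed_soa_ms=cfg.initial_soa_ms,
            seed=train_seed,
        )
        if not training.passed:
            assigned = score_noncompleter(cfg.initial_soa_ms)
            row = _subject_row(i, demo, None, training, None)
            row.update(
                min_soa_ms=assigned["min_soa_ms"],
                min_soa_assigned=True,
                completed=False,
                dyad_ratio=None, mean_rt_ms=None,
                n_hits=None, n_trials_analyzed=0,
            )
            rows.append(row)
            sessions.append(None)
            continue
        session = simulate_session(params, cfg, seed=sess_seed)
        session.training = training
        summary = summarize(session, analysis_window=min(54, cfg.n_trials))
        rows.append(_subject_row(i, demo, summary, training, session))
        sessions.append(session if keep_sessions else None)

    table = pd.DataFrame(rows)
    return table, sessions


def simulate_retest(
    spec: CohortSpec,
    n_sessions: int = 3,
    learning_factor_per_session: float = 1.0,
    config: Optional[StaircaseConfig] = None,
    model: Optional[NormModel] = None,
) -> dict[str, np.ndarray]:
    """Repeated sessions per subject with a multiplicative learning effect.

    Subject identity (threshold) is stable across sessions apart from the
    learning factor; trial noise is fresh each session.  Returns subjects x
    sessions matrices for minSOA, dyad ratio, and mean RT.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    cfg = config or StaircaseConfig()
    m = model or load_default_model()
    root = np.random.SeedSequence(spec.seed)
    demo_ss, subj_ss = root.spawn(2)
    rng = np.random.default_rng(demo_ss)
    subject_seeds = subj_ss.spawn(spec.n)

    min_soa = np.empty((spec.n, n_sessions))
    dyad = np.empty((spec.n, n_sessions))
    mean_rt = np.empty((spec.n, n_sessions))
    for i in range(spec.n):
        demo = draw_demographics(spec, rng)
        params = draw_responder(spec, demo, rng, m)
        srng = np.random.default_rng(subject_seeds[i])
        for s in range(n_sessions):
            p = replace(
                params,
                threshold_ms=params.threshold_ms * learning_factor_per_session**s,
            )
            sess = simulate_session(p, cfg, seed=int(srng.integers(0, 2**31 - 1)))
            summ = summarize(sess, analysis_window=min(54, cfg.n_trials))
            min_soa[i, s] = summ.min_soa_ms
            dyad[i, s] = np.nan if summ.dyad_ratio is None else summ.dyad_ratio
            mean_rt[i, s] = np.nan if summ.mean_rt_ms is None else summ.mean_rt_ms
    return {"min_soa_ms": min_soa, "dyad_ratio": dyad, "mean_rt_ms": mean_rt}
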