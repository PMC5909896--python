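"""Training protocol and the training-vs-test performance-validity index.

Before the adaptive test, subjects practice in blocks of 15 trials at the
fixed initial SOA; a block below 50% accuracy triggers another block, up to
three.  Genuinely impaired subjects tend to struggle already during this
easy fixed-pace training, whereas subjects feigning impairment tend to show
normal training accuracy followed by an abnormally slow test.  The validity
index flags exactly that dissociation: an abnormal minSOA z-score combined
with training accuracy above the bottom quintile of the normative training
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .norms import is_abnormal
from .staircase import QUIT, ProtocolError, ResponderCallback

__all__ = [
    "TrainingRecord",
    "ValidityAssessment",
    "run_training",
    "training_cutoff",
    "assess_validity",
    "classify_cohort",
]


@dataclass(frozen=True)
class TrainingRecord:
    blocks: tuple[float, ...]  # per-block accuracy, in order
    final_accuracy: float
    passed: bool
    quit: bool = False

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class ValidityAssessment:
    z: float
    abnormal_test: bool
    training_final_accuracy: Optional[float]
    training_above_cutoff: Optional[bool]
    suspect_malingering: Optional[bool]


def run_training(
    responder: ResponderCallback,
    pass_threshold: float = 0.5,
    block_trials: int = 15,
    max_blocks: int = 3,
    fixed_soa_ms: int = 3500,
    seed: Optional[int] = None,
) -> TrainingRecord:
    """Run up to ``max_blocks`` fixed-SOA practice blocks.

    No staircase operates: every trial is presented at ``fixed_soa_ms``.  A
    response counts as correct iff the reported sum is right, late or not.
    Stops after the first block reaching ``pass_threshold`` accuracy or
    after ``max_blocks``; a QUIT from the responder marks the record failed
    (the session is then scored as a non-completer).
    """
    from .staircase import StaircaseConfig, generate_digit_sequence

    rng = np.random.default_rng(seed)
    blocks: list[float] = []
    for b in range(max_blocks):
        cfg = StaircaseConfig(n_trials=block_trials)
        digits = generate_digit_sequence(
            cfg, int(rng.integers(0, 2**31 - 1)) if seed is not None else None
        )
        n_correct = 0
        for t in range(1, block_trials + 1):
            csum = digits[t - 1] + digits[t]
            resp = responder(t, digits[t], csum, fixed_soa_ms)
            if resp == QUIT:
                acc = n_correct / block_trials
                return TrainingRecord(
                    blocks=tuple(blocks + [acc]),
                    final_accuracy=acc,
                    passed=False,
                    quit=True,
                )
            try:
                reported, _rt = resp  # type: ignore[misc]
            except (TypeError, ValueError) as exc:
                raise ProtocolError(f"malformed responder return {resp!r}") from exc
            if reported is not None and reported == csum:
                n_correct += 1
        acc = n_correct / block_trials
        blocks.append(acc)
        if acc >= pass_threshold:
            return TrainingRecord(tuple(blocks), final_accuracy=acc, passed=True)
    return TrainingRecord(tuple(blocks), final_accuracy=blocks[-1], passed=False)


def training_cutoff(normative_final_accuracies: Sequence[float]) -> float:
    """Bottom-quintile cutoff of a normative training-accuracy sample.

    Empirical 20th percentile with linear interpolation between order
    statistics.
    """
    vals = np.asarray(normative_final_accuracies, dtype=float)
    if vals.size < 5:
        raise ValueError("need at least 5 normative accuracies")
    return float(np.quantile(vals, 0.20))


def assess_validity(
    min_soa_z: float,
    training: Optional[TrainingRecord],
    cutoff: float,
    alpha: float = 0.05,
) -> ValidityAssessment:
    """Flag a suspected feigned impairment.

    Suspect iff the test is abnormal (upper-tail z) AND final training
    accuracy is strictly above the normative bottom-quintile cutoff.  With
    no training record the suspect flag is absent, not false.
    """
    abnormal = is_abnormal(min_soa_z, alpha)
    if training is None:
        return ValidityAssessment(
            z=min_soa_z,
            abnormal_test=abnormal,
            training_final_accuracy=None,
            training_above_cutoff=None,
            suspect_malingering=None,
        )
    above = training.final_accuracy > cutoff
    return ValidityAssessment(
        z=min_soa_z,
        abnormal_test=abnormal,
        training_final_accuracy=training.final_accuracy,
        training_above_cutoff=above,
        suspect_malingering=abnormal and above,
    )


def classify_cohort(
    assessments: Sequence[ValidityAssessment],
    true_labels: Sequence[str],
) -> dict:
    """Sensitivity/specificity of the index among abnormal-scoring subjects.

    Labels are 'malingerer' or 'control'.  Following the index's framing,
    only subjects with abnormal test scores enter the confusion table:
    sensitivity = flagged / abnormal malingerers, specificity =
    unflagged / abnormal controls.  An empty class yields an absent metric.
    """
    if len(assessments) != len(true_labels):
        raise ValueError("assessments and labels must align")
    for lab in true_labels:
        if lab not in ("malingerer", "control"):
            raise ValueError(f"unknown label {lab!r}")
    mal_flagged = mal_total = ctl_unflagged = ctl_total = 0
    for a, lab in zip(assessments, true_labels):
        if not a.abnormal_test or a.suspect_malingering is None:
            continue
        if lab == "malingerer":
            mal_total += 1
            mal_flagged += a.suspect_malingering
        else:
            ctl_total += 1
            ctl_unflagged += not a.suspect_malingering
    return {
        "sensitivity": mal_flagged / mal_total if mal_total else None,
        "specificity": ctl_unflagged / ctl_total if ctl_total else None,
        "n_abnormal_malingerers": mal_total,
        "n_abnormal_controls": ctl_total,
    }
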