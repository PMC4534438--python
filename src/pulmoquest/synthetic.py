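"""Synthetic questionnaire cohorts with controllable class separation.

The generator emulates class-conditional answer behaviour on the 6-level
ordinal scale: each diagnosis group answers each question from its own
categorical distribution, independently across questions and records.  A
single ``separation`` knob interpolates between a completely uninformative
cohort (all classes answer uniformly) and near-degenerate class-specific
answer modes, so classifier-recovery and chance-level behaviour can both
be exercised without the study's own data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    ANSWER_LEVELS,
    DIAGNOSES,
    N_QUESTIONS,
    Cohort,
    QuestionnaireRecord,
)

#: Study cohort composition: questionnaires returned per diagnosis group.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "CF": 33,
    "AS": 27,
    "PCD": 24,
    "PM": 21,
    "AB": 23,
    "PBB": 18,
    "CTRL": 24,
}


@dataclass(frozen=True)
class AnswerDistribution:
    """Categorical distribution over the six answer levels."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probs) != 6:
            raise ValueError("AnswerDistribution needs exactly 6 weights")
        if any(p < 0 for p in self.probs):
            raise ValueError("AnswerDistribution weights must be non-negative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("AnswerDistribution weights must sum to 1 within 1e-9")

    @property
    def modal_level(self) -> int:
        return int(np.argmax(self.probs)) + 1


UNIFORM = AnswerDistribution(tuple([1.0 / 6] * 6))


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort (a pure function of itself)."""

    per_class_n: dict[str, int]
    per_class_dists: dict[str, tuple[AnswerDistribution, ...]]
    seed: int
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for label, n in self.per_class_n.items():
            if label not in DIAGNOSES:
                raise ValueError(f"unknown class {label!r} in per_class_n")
            if n < 0:
                raise ValueError(f"negative count for class {label}")
        for label, dists in self.per_class_dists.items():
            if len(dists) != N_QUESTIONS:
                raise ValueError(f"class {label} needs {N_QUESTIONS} distributions")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        missing = set(self.per_class_n) - set(self.per_class_dists)
        if missing:
            raise ValueError(f"no distributions for class(es) {sorted(missing)}")

    def to_json(self) -> str:
        payload = {
            "per_class_n": self.per_class_n,
            "per_class_dists": {
                c: [list(d.probs) for d in dists] for c, dists in self.per_class_dists.items()
            },
            "seed": self.seed,
            "missing_rate": self.missing_rate,
        }
        return json.dumps(payload, indent=2)


def triangular_distribution(mode: int, neighbour_weight: float = 0.05) -> AnswerDistribution:
    """Narrow triangular kernel centred on ``mode`` over levels 1..6.

    Weight 1 at the mode, ``neighbour_weight`` at the adjacent levels, 0
    elsewhere; the default keeps the distribution near-degenerate so that
    full separation really does pin each class to its modal answers.
    """
    if mode not in ANSWER_LEVELS:
        raise ValueError(f"mode {mode} outside 1..6")
    w = np.array(
        [max(0.0, 1.0 - (1.0 - neighbour_weight) * abs(a - mode)) for a in ANSWER_LEVELS]
    )
    w /= w.sum()
    return AnswerDistribution(tuple(w))


def mixture(separation: float, peaked: AnswerDistribution) -> AnswerDistribution:
    """(1 - s) * uniform + s * peaked."""
    p = (1.0 - separation) * np.asarray(UNIFORM.probs) + separation * np.asarray(peaked.probs)
    p /= p.sum()
    return AnswerDistribution(tuple(p))


# Each class carries a distinct modal answer profile over a designated
# 42-question informative panel (questions 43-45 stay uninformative filler
# at every separation).  Profiles are drawn once from a fixed profile seed,
# independent of the cohort sampling seed, so the study conditions are the
# same for every generated cohort; any two class profiles are guaranteed to
# differ on at least one designated question.
_PROFILE_SEED = 1_234_567
_N_INFORMATIVE = 42

_profile_cache: Optional[np.ndarray] = None


def modal_profiles() -> np.ndarray:
    """(7 classes, 42 questions) matrix of modal answer levels."""
    global _profile_cache
    if _profile_cache is None:
        rng = np.random.default_rng(_PROFILE_SEED)
        while True:
            prof = rng.integers(1, 7, size=(len(DIAGNOSES), _N_INFORMATIVE))
            distinct = all(
                (prof[i] != prof[j]).any()
                for i in range(len(prof))
                for j in range(i + 1, len(prof))
            )
            if distinct:
                _profile_cache = prof
                break
    return _profile_cache


def default_cohort_spec(separation: float, seed: int, missing_rate: float = 0.0) -> CohortSpec:
    """Spec with the study composition (170 records: CF 33, AS 27, PCD 24,
    PM 21, AB 23, PBB 18, CTRL 24) and separation-controlled difficulty.

    ``separation`` in [0, 1]: 0 makes every class answer every question
    uniformly (pure chance level); 1 pins each class to a near-degenerate,
    class-specific modal answer profile on the designated questions, making
    the classes essentially perfectly separable.
    """
    if not 0.0 <= separation <= 1.0:
        raise ValueError(f"separation {separation} outside [0, 1]")
    profiles = modal_profiles()
    per_class_dists: dict[str, tuple[AnswerDistribution, ...]] = {}
    for ci, label in enumerate(DIAGNOSES):
        dists = [
            mixture(separation, triangular_distribution(int(profiles[ci, q])))
            if q < _N_INFORMATIVE
            else UNIFORM
            for q in range(N_QUESTIONS)
        ]
        per_class_dists[label] = tuple(dists)
    return CohortSpec(
        per_class_n=dict(DEFAULT_CLASS_COUNTS),
        per_class_dists=per_class_dists,
        seed=seed,
        missing_rate=missing_rate,
    )


def generate_cohort(spec: CohortSpec, questions=None) -> Cohort:
    """Draw a labelled cohort from ``spec``; deterministic in the spec alone.

    All draws consume one seeded stream in class-canonical, record-major,
    question-minor order, so identical specs give byte-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    levels = np.asarray(ANSWER_LEVELS)
    records: list[QuestionnaireRecord] = []
    for label in DIAGNOSES:
        n = spec.per_class_n.get(label, 0)
        if n == 0:
            continue
        dists = spec.per_class_dists[label]
        probs = np.array([d.probs for d in dists])  # (45, 6)
        for i in range(n):
            answers: list[Optional[int]] = []
            for q in range(N_QUESTIONS):
                level = int(levels[rng.choice(6, p=probs[q])])
                if spec.missing_rate > 0.0 and rng.random() < spec.missing_rate:
                    answers.append(None)
                else:
                    answers.append(level)
            records.append(
                QuestionnaireRecord(f"{label}-{i + 1:03d}", tuple(answers), label)
            )
    if questions is not None:
        return Cohort(records, questions)
    return Cohort(records)
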