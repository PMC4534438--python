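"""Score-summation fusion of the classifier bank's probability vectors.

Each classifier contributes a posterior over the seven diagnoses; summing
them per class yields a score vector whose argmax is proposed as the
diagnosis -- but only if its normalised (relative) score strictly exceeds
a confidence limit, otherwise the result is a no-call carrying a ranked
shortlist.  Equal-weight summation lets each member's confidence act as
its implicit vote weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DIAGNOSES, AnswerVector, ConfigurationError
from .classifiers import TrainedClassifier, predict_proba

#: Default confidence limit on the relative (normalised) score: about
#: 1.75x the 1/7 chance level.
DEFAULT_LIMIT = 0.25


@dataclass(frozen=True)
class FusionResult:
    """Summed scores, relative scores, ranking, and the proposal (if any)."""

    raw_scores: tuple[float, ...]
    relative: tuple[float, ...]
    proposed: Optional[str]
    limit: float
    ranking: tuple[str, ...]

    def top(self, n: int = 3) -> list[tuple[str, float]]:
        """Top-n classes with relative scores, e.g. for no-call shortlists."""
        rel = dict(zip(DIAGNOSES, self.relative))
        return [(c, rel[c]) for c in self.ranking[:n]]

    def as_percentages(self) -> dict[str, int]:
        """Relative scores as whole percentages (display convention)."""
        return {c: int(round(100 * r)) for c, r in zip(DIAGNOSES, self.relative)}


def fuse(outputs: Sequence[np.ndarray], limit: float = DEFAULT_LIMIT) -> FusionResult:
    """Fuse per-classifier posteriors by summation.

    raw_scores[c] = sum over classifiers of their probability for class c;
    relative = raw_scores normalised to sum 1.  The top class is proposed
    only if its relative score strictly exceeds ``limit``; argmax ties are
    broken by canonical class order.
    """
    if len(outputs) == 0:
        raise ValueError("fuse requires at least one classifier output")
    if not 0.0 <= limit < 1.0:
        raise ValueError(f"limit {limit} outside [0, 1)")
    mat = np.asarray(outputs, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != len(DIAGNOSES):
        raise ValueError("each output must be a length-7 probability vector")
    raw = mat.sum(axis=0)
    relative = raw / raw.sum()
    # stable sort on negated scores: ties fall back to canonical order
    order = np.argsort(-relative, kind="stable")
    ranking = tuple(DIAGNOSES[i] for i in order)
    best = int(order[0])
    proposed = DIAGNOSES[best] if relative[best] > limit else None
    return FusionResult(
        raw_scores=tuple(raw),
        relative=tuple(relative),
        proposed=proposed,
        limit=limit,
        ranking=ranking,
    )


@dataclass(frozen=True)
class CasePrediction:
    """Fusion outcome for one questionnaire plus the per-classifier audit
    trail (each member's own posterior, for reporting)."""

    fusion: FusionResult
    audit: dict[str, tuple[float, ...]]


def predict_case(
    models: Sequence[TrainedClassifier],
    answers: AnswerVector,
    limit: float = DEFAULT_LIMIT,
) -> CasePrediction:
    """Score one answered questionnaire with a bank of trained models."""
    if len(models) == 0:
        raise ValueError("predict_case requires at least one trained model")
    class_sets = {m.training_classes for m in models}
    if len(class_sets) != 1:
        raise ConfigurationError(
            "all models must share one training class set; got "
            + ", ".join(sorted(map(str, class_sets)))
        )
    vectors = [predict_proba(m, answers) for m in models]
    audit = {m.kind: tuple(v) for m, v in zip(models, vectors)}
    return CasePrediction(fusion=fuse(vectors, limit=limit), audit=audit)
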