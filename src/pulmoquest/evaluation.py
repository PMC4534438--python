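"""Cross-validated evaluation of the ensemble: stratified k-fold,
per-class sensitivity, overall accuracy and one-vs-rest ROC/AUC.

The fold plan reproduces the study arithmetic: stratified 10-fold on a
170-record cohort yields validation folds of exactly 17 records and
training partitions of 153.  Below-limit (no-call) fusion outcomes count
as misclassifications, matching a single correct/incorrect tally.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .classifiers import ALL_KINDS, TrainedClassifier, predict_proba, train
from .core import DIAGNOSES, Cohort
from .fusion import DEFAULT_LIMIT, fuse

NO_CALL = "NO_CALL"


@dataclass(frozen=True)
class FoldPlan:
    """Deterministic stratified fold assignment for one cohort."""

    assignments: dict[str, int]
    k: int
    seed: int

    def fold_of(self, record_id: str) -> int:
        return self.assignments[record_id]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignments.values():
            sizes[f] += 1
        return sizes


def stratified_kfold(cohort: Cohort, k: int, seed: int) -> FoldPlan:
    """Stratified fold plan by seeded within-class shuffle + round-robin deal.

    Classes are visited in canonical order; within each class the records
    are shuffled by ``seed`` and dealt to folds by a single running fold
    pointer carried across classes.  This guarantees per-class fold counts
    differing by at most 1 *and* overall fold sizes differing by at most 1
    (larger folds first when the total is not divisible by k), and is
    deterministic in (cohort order, k, seed).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labelled = [r for r in cohort if r.label is not None]
    if len(labelled) < k:
        raise ValueError(f"cannot split {len(labelled)} records into {k} folds")
    counts = {d: sum(1 for r in labelled if r.label == d) for d in DIAGNOSES}
    present = [d for d in DIAGNOSES if counts[d] > 0]
    smallest = min(counts[d] for d in present)
    if k > smallest:
        warnings.warn(
            f"k={k} exceeds the smallest class count ({smallest}); "
            "some validation folds will lack that class",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    pointer = 0
    for d in present:
        ids = [r.record_id for r in labelled if r.label == d]
        order = rng.permutation(len(ids))
        for idx in order:
            assignments[ids[idx]] = pointer % k
            pointer += 1
    return FoldPlan(assignments=assignments, k=k, seed=seed)


@dataclass(frozen=True)
class ROCCurve:
    """One-vs-rest ROC points and trapezoidal AUC for a single class."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float


def roc_one_vs_rest(scores: Sequence[float], truth: Sequence[bool]) -> ROCCurve:
    """ROC of one diagnosis against the pooled rest.

    Points at every distinct score threshold with endpoints (0,0) and
    (1,1); AUC by the trapezoidal rule, equal to the concordant-pair
    statistic with ties counted 1/2.
    """
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or (~truth).all():
        raise ValueError("ROC needs at least one positive and one negative record")
    fpr, tpr, thr = _roc_curve(truth, scores, drop_intermediate=False)
    return ROCCurve(tuple(fpr), tuple(tpr), tuple(thr), float(_trapezoid_auc(fpr, tpr)))


@dataclass
class EvaluationReport:
    """Everything the cross-validation produced, plus its provenance."""

    confusion: np.ndarray  # (7 true classes) x (7 proposed + NO_CALL)
    per_class_sensitivity: dict[str, float]
    overall_accuracy: float
    per_class_roc: dict[str, Optional[ROCCurve]]
    fold_plan: FoldPlan
    config_fingerprint: str
    kinds: tuple[str, ...]
    limit: float
    # per-record traces (cohort order restricted to labelled records)
    record_ids: tuple[str, ...] = ()
    true_labels: tuple[str, ...] = ()
    fused_relative: np.ndarray = field(default_factory=lambda: np.zeros((0, 7)))
    fused_proposals: tuple[str, ...] = ()  # class code or NO_CALL
    standalone_predictions: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (confusion, sensitivities, AUCs...)."""
        return {
            "config_fingerprint": self.config_fingerprint,
            "kinds": list(self.kinds),
            "k": self.fold_plan.k,
            "seed": self.fold_plan.seed,
            "limit": self.limit,
            "classes": list(DIAGNOSES),
            "confusion_columns": list(DIAGNOSES) + [NO_CALL],
            "confusion": self.confusion.astype(int).tolist(),
            "per_class_sensitivity": self.per_class_sensitivity,
            "overall_accuracy": self.overall_accuracy,
            "per_class_auc": {
                c: (None if r is None else r.auc) for c, r in self.per_class_roc.items()
            },
        }


def _config_fingerprint(kinds: Sequence[str], k: int, limit: float, seed: int,
                        hyperparameters: Optional[dict]) -> str:
    blob = json.dumps(
        {"kinds": list(kinds), "k": k, "limit": limit, "seed": seed,
         "hyperparameters": hyperparameters or {}},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def cross_validate(
    cohort: Cohort,
    kinds: Sequence[str] = ALL_KINDS,
    k: int = 10,
    limit: float = DEFAULT_LIMIT,
    seed: int = 0,
    hyperparameters: Optional[dict] = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the fused ensemble.

    For each fold the whole bank is retrained on the out-of-fold records
    and every validation record is fused; confusion counts, per-class
    sensitivity, overall accuracy, pooled one-vs-rest ROC/AUC per class
    and each member's stand-alone predictions are accumulated.
    """
    labelled = cohort.labelled()
    plan = stratified_kfold(labelled, k=k, seed=seed)
    by_fold: dict[int, list] = {f: [] for f in range(k)}
    for rec in labelled:
        by_fold[plan.fold_of(rec.record_id)].append(rec)

    n = len(labelled)
    record_ids: list[str] = []
    true_labels: list[str] = []
    fused_rel_rows: list[np.ndarray] = []
    fused_props: list[str] = []
    standalone: dict[str, list[str]] = {kind: [] for kind in kinds}
    confusion = np.zeros((len(DIAGNOSES), len(DIAGNOSES) + 1), dtype=int)

    for f in range(k):
        val = by_fold[f]
        train_records = [r for g in range(k) if g != f for r in by_fold[g]]
        train_cohort = Cohort(train_records, labelled.questions)
        fold_seed = (seed * 100_003 + f) % (2**31)
        try:
            models = {
                kind: train(kind, train_cohort,
                            hyperparameters=(hyperparameters or {}).get(kind),
                            seed=fold_seed)
                for kind in kinds
            }
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {f}: {exc}") from exc
        for rec in val:
            vectors = {kind: predict_proba(models[kind], rec.answers) for kind in kinds}
            result = fuse(list(vectors.values()), limit=limit)
            record_ids.append(rec.record_id)
            true_labels.append(rec.label)
            fused_rel_rows.append(np.asarray(result.relative))
            proposal = result.proposed if result.proposed is not None else NO_CALL
            fused_props.append(proposal)
            ti = DIAGNOSES.index(rec.label)
            ci = DIAGNOSES.index(proposal) if proposal != NO_CALL else len(DIAGNOSES)
            confusion[ti, ci] += 1
            for kind in kinds:
                standalone[kind].append(DIAGNOSES[int(np.argmax(vectors[kind]))])

    fused_rel = np.vstack(fused_rel_rows) if fused_rel_rows else np.zeros((0, 7))
    y = np.array([DIAGNOSES.index(t) for t in true_labels])
    correct = np.array([t == p for t, p in zip(true_labels, fused_props)])
    sens: dict[str, float] = {}
    for ci, c in enumerate(DIAGNOSES):
        mask = y == ci
        if mask.any():
            sens[c] = float(correct[mask].mean())
    per_class_roc: dict[str, Optional[ROCCurve]] = {}
    for ci, c in enumerate(DIAGNOSES):
        truth = y == ci
        if truth.any() and (~truth).any():
            per_class_roc[c] = roc_one_vs_rest(fused_rel[:, ci], truth)
        else:
            per_class_roc[c] = None

    return EvaluationReport(
        confusion=confusion,
        per_class_sensitivity=sens,
        overall_accuracy=float(correct.mean()),
        per_class_roc=per_class_roc,
        fold_plan=plan,
        config_fingerprint=_config_fingerprint(kinds, k, limit, seed, hyperparameters),
        kinds=tuple(kinds),
        limit=limit,
        record_ids=tuple(record_ids),
        true_labels=tuple(true_labels),
        fused_relative=fused_rel,
        fused_proposals=tuple(fused_props),
        standalone_predictions={kind: tuple(v) for kind, v in standalone.items()},
    )


FUSION_ROW = "FUSION"


def sensitivity_table(report: EvaluationReport) -> pd.DataFrame:
    """(classifier-or-fusion) x (class + overall) sensitivity summary.

    Stand-alone rows use each member's own argmax; the fusion row uses
    the fused proposals (no-calls counting as errors).
    """
    y = np.array(report.true_labels)
    columns = list(DIAGNOSES) + ["overall"]
    rows = {}
    present = [c for c in DIAGNOSES if (y == c).any()]

    def _row(preds: np.ndarray) -> list[float]:
        vals = []
        for c in DIAGNOSES:
            mask = y == c
            vals.append(float((preds[mask] == c).mean()) if mask.any() else np.nan)
        vals.append(float((preds == y).mean()))
        return vals

    for kind in report.kinds:
        rows[kind] = _row(np.array(report.standalone_predictions[kind]))
    rows[FUSION_ROW] = _row(np.array(report.fused_proposals))
    del present
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
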