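"""Model/Results surface for the diagnostic ensemble.

:class:`DiagnosticEnsemble` is constructed from a labelled cohort (or a
DataFrame/CSV in the canonical layout) together with the bank
configuration; :meth:`DiagnosticEnsemble.fit` trains all members and
returns an :class:`EnsembleResults` carrying the trained bank, case
prediction, a summary table and persistence.  Cross-validation hangs off
the unfitted model since it retrains per fold.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import ALL_KINDS, TrainedClassifier, train
from .core import (
    DIAGNOSES,
    AnswerVector,
    Cohort,
    ConfigurationError,
    cohort_from_dataframe,
    read_cohort,
)
from .evaluation import EvaluationReport, cross_validate
from .fusion import DEFAULT_LIMIT, CasePrediction, predict_case

_BUNDLE_FORMAT_VERSION = 1


class DiagnosticEnsemble:
    """The questionnaire diagnosis model: an eight-member classifier bank
    with score-summation fusion, built from a labelled cohort.

    Parameters
    ----------
    cohort
        Labelled training cohort (unlabelled records are ignored).
    kinds
        Bank members to use; defaults to all eight.
    limit
        Confidence limit on the fused relative score below which the
        ensemble abstains (no-call).
    hyperparameters
        Optional per-kind overrides, ``{kind: {param: value}}``.
    """

    def __init__(
        self,
        cohort: Cohort,
        kinds: Sequence[str] = ALL_KINDS,
        limit: float = DEFAULT_LIMIT,
        hyperparameters: Optional[dict] = None,
    ):
        unknown = [kind for kind in kinds if kind not in ALL_KINDS]
        if unknown:
            raise ConfigurationError(f"unknown classifier kind(s): {', '.join(unknown)}")
        if not kinds:
            raise ConfigurationError("at least one classifier kind is required")
        self.cohort = cohort.labelled()
        if len(self.cohort) == 0:
            raise ValueError("training cohort has no labelled records")
        self.kinds = tuple(kinds)
        self.limit = limit
        self.hyperparameters = hyperparameters or {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DiagnosticEnsemble":
        return cls(cohort_from_dataframe(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DiagnosticEnsemble":
        return cls(read_cohort(path), **kwargs)

    def fit(self, seed: int = 0) -> "EnsembleResults":
        """Train every bank member on the full cohort."""
        models = {
            kind: train(kind, self.cohort,
                        hyperparameters=self.hyperparameters.get(kind), seed=seed)
            for kind in self.kinds
        }
        return EnsembleResults(self, models, seed)

    def cross_validate(self, k: int = 10, seed: int = 0) -> EvaluationReport:
        """Stratified k-fold CV of the fused ensemble (retrains per fold)."""
        return cross_validate(
            self.cohort,
            kinds=self.kinds,
            k=k,
            limit=self.limit,
            seed=seed,
            hyperparameters=self.hyperparameters,
        )


@dataclass
class EnsembleResults:
    """A fitted diagnostic ensemble."""

    model: DiagnosticEnsemble
    models: dict[str, TrainedClassifier]
    seed: int

    def predict(self, answers: AnswerVector, limit: Optional[float] = None) -> CasePrediction:
        """Fused diagnosis suggestion (plus per-member audit trail) for one
        answered questionnaire."""
        lim = self.model.limit if limit is None else limit
        return predict_case(list(self.models.values()), answers, limit=lim)

    def predict_cohort(
        self,
        cohort: Cohort,
        limit: Optional[float] = None,
        audit: bool = False,
    ) -> pd.DataFrame:
        """One row per record: proposal (or NO_CALL) and top-3 shortlist
        with whole-percentage relative scores."""
        rows = []
        for rec in cohort:
            case = self.predict(rec.answers, limit=limit)
            row: dict[str, object] = {
                "record_id": rec.record_id,
                "proposed": case.fusion.proposed or "NO_CALL",
            }
            for rank, (cls_, score) in enumerate(case.fusion.top(3), start=1):
                row[f"top{rank}"] = cls_
                row[f"top{rank}_pct"] = int(round(100 * score))
            if audit:
                for kind, vec in case.audit.items():
                    for c, p in zip(DIAGNOSES, vec):
                        row[f"{kind}:{c}"] = round(float(p), 6)
            rows.append(row)
        return pd.DataFrame(rows)

    def training_accuracy(self) -> pd.DataFrame:
        """Resubstitution accuracy per member and for the fusion (an
        optimistic diagnostic, not a performance estimate)."""
        cohort = self.model.cohort
        y = np.array([r.label for r in cohort])
        per_kind = {kind: [] for kind in self.models}
        fused = []
        for rec in cohort:
            case = self.predict(rec.answers, limit=0.0)
            fused.append(case.fusion.proposed)
            for kind, vec in case.audit.items():
                per_kind[kind].append(DIAGNOSES[int(np.argmax(vec))])
        rows = {kind: float((np.array(v) == y).mean()) for kind, v in per_kind.items()}
        rows["FUSION"] = float((np.array(fused) == y).mean())
        return pd.DataFrame({"training_accuracy": rows})

    def summary(self) -> str:
        """Human-readable description of the fitted ensemble."""
        counts = self.model.cohort.class_counts
        lines = [
            "Diagnostic ensemble (questionnaire answer-pattern classifier)",
            "=" * 62,
            f"records: {len(self.model.cohort)}    classes: "
            + ", ".join(f"{c}={counts[c]}" for c in DIAGNOSES),
            f"members: {', '.join(self.models)}",
            f"fusion limit (relative score): {self.model.limit}",
            f"fit seed: {self.seed}",
            "",
            "Resubstitution accuracy",
            "-" * 30,
        ]
        acc = self.training_accuracy()
        for name, value in acc["training_accuracy"].items():
            lines.append(f"{name:<20s}{value:6.3f}")
        return "\n".join(lines)

    def save(self, path: str) -> None:
        """Persist the fitted bank as one versioned archive."""
        payload = {
            "format_version": _BUNDLE_FORMAT_VERSION,
            "package_version": __version__,
            "kinds": self.model.kinds,
            "limit": self.model.limit,
            "hyperparameters": self.model.hyperparameters,
            "seed": self.seed,
            "models": self.models,
            "cohort_frame": self.model.cohort.to_dataframe(),
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "EnsembleResults":
        """Load a persisted ensemble; refuses other package versions."""
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if (
            payload.get("format_version") != _BUNDLE_FORMAT_VERSION
            or payload.get("package_version") != __version__
        ):
            raise ConfigurationError(
                "ensemble archive was written by a different package version "
                f"({payload.get('package_version')!r})"
            )
        model = DiagnosticEnsemble(
            cohort_from_dataframe(payload["cohort_frame"]),
            kinds=payload["kinds"],
            limit=payload["limit"],
            hyperparameters=payload["hyperparameters"],
        )
        return cls(model=model, models=payload["models"], seed=payload["seed"])
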