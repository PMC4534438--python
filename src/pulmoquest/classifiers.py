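"""The eight-member classifier bank.

Each member is trained on a labelled cohort (answers used as numeric
values 1..6, missing answers imputed with the rounded per-question
training median) and emits a posterior probability vector over the seven
diagnosis classes in canonical order.  Classes absent from the training
partition receive probability exactly 0: the fusion stage must never
credit a diagnosis no classifier could have learned.

Seven kinds are standard estimators (scikit-learn); the fuzzy rule-based
kind is implemented here: histogram membership functions per class and
question (Laplace-smoothed class-conditional answer frequencies rescaled
to peak at 1), combined by the geometric mean across questions, with
rule strengths normalised into probabilities.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import CategoricalNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import __version__
from .core import (
    DIAGNOSES,
    N_QUESTIONS,
    AnswerVector,
    Cohort,
    ConfigurationError,
    impute_missing,
    imputation_reference,
    validate_record,
    QuestionnaireRecord,
)

SVM = "SVM"
ANN = "ANN"
FUZZY = "FUZZY"
RANDOM_FOREST = "RANDOM_FOREST"
LOGISTIC = "LOGISTIC"
LDA = "LDA"
NAIVE_BAYES = "NAIVE_BAYES"
NEAREST_NEIGHBOUR = "NEAREST_NEIGHBOUR"

#: The eight classifier kinds, in a fixed presentation order.
ALL_KINDS: tuple[str, ...] = (
    SVM,
    ANN,
    FUZZY,
    RANDOM_FOREST,
    LOGISTIC,
    LDA,
    NAIVE_BAYES,
    NEAREST_NEIGHBOUR,
)

#: Kinds whose fit and prediction are deterministic functions of the
#: training *set* (invariant under record order).
DETERMINISTIC_KINDS: tuple[str, ...] = (FUZZY, NAIVE_BAYES, LDA, NEAREST_NEIGHBOUR)

# One overridable block of defaults; the study reports no hyperparameters,
# so these are package choices (see docs/methods.md).
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    SVM: {"C": 1.0, "gamma": "scale"},
    ANN: {"hidden_units": 16, "max_iter": 600},
    FUZZY: {"alpha": 1.0},
    RANDOM_FOREST: {"n_estimators": 500},
    LOGISTIC: {"C": 1.0, "max_iter": 2000},
    LDA: {"shrinkage": "auto"},
    NAIVE_BAYES: {"alpha": 1.0},
    NEAREST_NEIGHBOUR: {"k": 5},
}

_MODEL_FORMAT_VERSION = 1


class _ConstantModel:
    """Degenerate model for single-class training sets."""

    def __init__(self, class_index: int):
        self.classes_ = np.array([class_index])

    def fit(self, X, y):  # pragma: no cover - trivial
        return self

    def predict_proba(self, X):
        return np.ones((len(X), 1))


class FuzzyRuleClassifier:
    """Histogram-membership fuzzy rule classifier.

    For class ``c`` and question ``q`` the membership of answer level
    ``a`` is the Laplace-smoothed class-conditional frequency
    ``(count(a | q, c) + alpha) / (n_c + 6 * alpha)`` rescaled so its
    maximum over the six levels equals 1.  A query's rule strength for
    class ``c`` is the geometric mean of its memberships across all 45
    questions; the output posterior is the strengths normalised to sum 1.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FuzzyRuleClassifier":
        X = np.asarray(X, dtype=int)
        self.classes_ = np.unique(y)
        n_q = X.shape[1]
        self.memberships_ = np.empty((len(self.classes_), n_q, 6))
        for ci, c in enumerate(self.classes_):
            Xc = X[y == c]
            counts = np.stack(
                [np.bincount(Xc[:, q] - 1, minlength=6) for q in range(n_q)]
            ).astype(float)
            freq = (counts + self.alpha) / (len(Xc) + 6 * self.alpha)
            self.memberships_[ci] = freq / freq.max(axis=1, keepdims=True)
        return self

    def rule_strengths(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=int)
        n, n_q = X.shape
        cols = np.arange(n_q)
        log_strength = np.empty((n, len(self.classes_)))
        for ci in range(len(self.classes_)):
            memb = self.memberships_[ci][cols[None, :], X - 1]  # (n, n_q)
            log_strength[:, ci] = np.log(memb).mean(axis=1)
        return np.exp(log_strength)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.rule_strengths(X)
        return s / s.sum(axis=1, keepdims=True)


class _NearestNeighbourClassifier:
    """k-nearest-neighbour with distance-weighted votes and tie-safe
    neighbourhoods.

    Every training point whose distance ties the k-th smallest is
    included, so predictions are invariant under training-record order.
    Exact matches (distance 0) take the whole vote.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NearestNeighbourClassifier":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros((len(X), len(self.classes_)))
        k = min(self.k, len(self._X))
        for i, x in enumerate(X):
            d = np.sqrt(((self._X - x) ** 2).sum(axis=1))
            kth = np.partition(d, k - 1)[k - 1]
            in_hood = d <= kth
            if np.any(d[in_hood] == 0.0):
                weights = (d == 0.0).astype(float)
            else:
                weights = np.where(in_hood, 1.0 / d, 0.0)
            for ci, c in enumerate(self.classes_):
                out[i, ci] = weights[self._y == c].sum()
        return out / out.sum(axis=1, keepdims=True)


def _build_estimator(kind: str, hp: dict, seed: int):
    if kind == SVM:
        return SVC(
            kernel="rbf", C=hp["C"], gamma=hp["gamma"], probability=True, random_state=seed
        )
    if kind == ANN:
        return MLPClassifier(
            hidden_layer_sizes=(hp["hidden_units"],),
            solver="lbfgs",
            max_iter=hp["max_iter"],
            random_state=seed,
        )
    if kind == FUZZY:
        return FuzzyRuleClassifier(alpha=hp["alpha"])
    if kind == RANDOM_FOREST:
        return RandomForestClassifier(n_estimators=hp["n_estimators"], random_state=seed)
    if kind == LOGISTIC:
        return LogisticRegression(penalty="l2", C=hp["C"], max_iter=hp["max_iter"])
    if kind == LDA:
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=hp["shrinkage"])
    if kind == NAIVE_BAYES:
        return CategoricalNB(alpha=hp["alpha"], min_categories=6)
    if kind == NEAREST_NEIGHBOUR:
        return _NearestNeighbourClassifier(k=hp["k"])
    raise ConfigurationError(f"unknown classifier kind {kind!r}")


@dataclass
class TrainedClassifier:
    """One fitted bank member plus everything needed to score a query."""

    kind: str
    estimator: object
    training_classes: tuple[str, ...]
    imputation_reference: tuple[int, ...]
    hyperparameters: dict = field(default_factory=dict)

    def predict_proba(self, answers: AnswerVector) -> np.ndarray:
        """Posterior over the 7 canonical classes for one answer vector."""
        return predict_proba(self, answers)


def _design_matrix(cohort: Cohort, reference: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    X = np.empty((len(cohort), N_QUESTIONS), dtype=float)
    y = np.empty(len(cohort), dtype=int)
    for i, rec in enumerate(cohort):
        X[i] = impute_missing(rec.answers, reference)
        y[i] = DIAGNOSES.index(rec.label)
    return X, y


def train(
    kind: str,
    cohort: Cohort,
    hyperparameters: Optional[dict] = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit one bank member on a fully labelled cohort.

    Answers enter as numeric values 1..6; the per-question rounded
    training median is stored in the model and used to impute missing
    answers at both training and prediction time.  Deterministic in
    (kind, cohort, hyperparameters, seed).
    """
    if kind not in ALL_KINDS:
        raise ConfigurationError(f"unknown classifier kind {kind!r}")
    if len(cohort) == 0:
        raise ValueError("cannot train on an empty cohort")
    if any(rec.label is None for rec in cohort):
        raise ValueError("training cohort must be fully labelled")
    hp = {**DEFAULT_HYPERPARAMETERS[kind], **(hyperparameters or {})}
    reference = imputation_reference(cohort)
    X, y = _design_matrix(cohort, reference)
    present = np.unique(y)
    if len(present) == 1 and kind not in (FUZZY, NEAREST_NEIGHBOUR):
        # sklearn estimators refuse single-class fits; our own kinds don't
        est = _ConstantModel(int(present[0]))
    else:
        est = _build_estimator(kind, hp, seed)
        if kind == NAIVE_BAYES:
            est.fit(X.astype(int) - 1, y)
        else:
            est.fit(X, y)
    return TrainedClassifier(
        kind=kind,
        estimator=est,
        training_classes=tuple(DIAGNOSES[c] for c in present),
        imputation_reference=reference,
        hyperparameters=hp,
    )


def predict_proba(model: TrainedClassifier, answers: AnswerVector) -> np.ndarray:
    """Length-7 posterior in canonical class order; zeros for classes the
    model never saw; missing answers imputed from the stored reference."""
    verdict = validate_record(QuestionnaireRecord("query", tuple(answers)))
    if not verdict.ok:
        raise ValueError("invalid answer vector: " + "; ".join(verdict.violations))
    x = np.asarray(impute_missing(tuple(answers), model.imputation_reference), dtype=float)
    x = x[None, :]
    if model.kind == NAIVE_BAYES and not isinstance(model.estimator, _ConstantModel):
        raw = model.estimator.predict_proba(x.astype(int) - 1)[0]
    else:
        raw = model.estimator.predict_proba(x)[0]
    full = np.zeros(len(DIAGNOSES))
    for p, ci in zip(raw, model.estimator.classes_):
        full[int(ci)] = p
    total = full.sum()
    if total <= 0:  # pragma: no cover - defensive
        full[:] = 1.0 / len(full)
    else:
        full /= total
    return full


def fuzzy_train(cohort: Cohort, alpha: float = 1.0) -> TrainedClassifier:
    """Train the fuzzy rule-based kind directly (internals exposed via
    ``model.estimator.memberships_`` and ``rule_strengths``)."""
    return train(FUZZY, cohort, hyperparameters={"alpha": alpha})


def fuzzy_predict(model: TrainedClassifier, answers: AnswerVector) -> np.ndarray:
    """Posterior from a fuzzy model (alias for :func:`predict_proba`)."""
    if model.kind != FUZZY:
        raise ConfigurationError("fuzzy_predict requires a FUZZY model")
    return predict_proba(model, answers)


def save_model(model: TrainedClassifier, path: str) -> None:
    """Persist a trained bank member as a versioned archive."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "package_version": __version__,
        "kind": model.kind,
        "hyperparameters": model.hyperparameters,
        "training_classes": model.training_classes,
        "imputation_reference": model.imputation_reference,
        "estimator": model.estimator,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str) -> TrainedClassifier:
    """Load a persisted model; refuses archives from other package versions."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if (
        payload.get("format_version") != _MODEL_FORMAT_VERSION
        or payload.get("package_version") != __version__
    ):
        raise ConfigurationError(
            "model archive was written by a different package version "
            f"({payload.get('package_version')!r}, format {payload.get('format_version')!r})"
        )
    return TrainedClassifier(
        kind=payload["kind"],
        estimator=payload["estimator"],
        training_classes=tuple(payload["training_classes"]),
        imputation_reference=tuple(payload["imputation_reference"]),
        hyperparameters=payload["hyperparameters"],
    )
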