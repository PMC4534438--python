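import warnings

import pytest

import pulmoquest as pq
from pulmoquest.core import N_QUESTIONS, QuestionnaireRecord


def record(record_id, answers, label=None):
    return QuestionnaireRecord(record_id, tuple(answers), label)


def uniform_answers(level=3):
    return tuple([level] * N_QUESTIONS)


@pytest.fixture(scope="session")
def questions():
    return pq.load_questions()


@pytest.fixture(scope="session")
def sep095_cohort():
    """Well-separated synthetic study cohort (170 records, separation 0.95)."""
    return pq.generate_cohort(pq.default_cohort_spec(0.95, 7))


@pytest.fixture(scope="session")
def cv_report_sep095(sep095_cohort):
    """Full-bank 10-fold CV on the well-separated cohort (shared: slow)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pq.cross_validate(sep095_cohort, k=10, seed=7)


@pytest.fixture(scope="session")
def cv_report_sep0():
    """Full-bank 10-fold CV on an uninformative (chance-level) cohort."""
    cohort = pq.generate_cohort(pq.default_cohort_spec(0.0, 11))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pq.cross_validate(cohort, k=10, seed=11)


@pytest.fixture(scope="session")
def sep0_cohort():
    return pq.generate_cohort(pq.default_cohort_spec(0.0, 11))


def small_spec(counts, separation=0.9, seed=0, missing_rate=0.0):
    """Study-profile spec restricted to the given per-class counts."""
    base = pq.default_cohort_spec(separation, seed, missing_rate=missing_rate)
    return pq.CohortSpec(
        per_class_n=counts,
        per_class_dists=base.per_class_dists,
        seed=seed,
        missing_rate=missing_rate,
    )


@pytest.fixture(scope="session")
def three_class_cohort():
    """Small, fairly separable 3-class cohort for fast classifier tests."""
    return pq.generate_cohort(small_spec({"CF": 8, "AS": 8, "PCD": 8}, separation=0.9, seed=3))
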