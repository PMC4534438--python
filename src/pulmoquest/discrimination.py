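"""Pairwise answer-frequency heat maps and information-gain question ranking.

For an ordered pair of diagnosis groups, the heat-map statistic for
question q and answer level a is the difference of the two groups'
relative answer frequencies, relfreq(a | q, d1) - relfreq(a | q, d2):
+1 means every d1 record and no d2 record chose that answer, -1 the
opposite, 0 equal frequencies.  Information gain ranks questions by the
reduction in class-label entropy (in bits) from conditioning on the
answer.  Missing answers are excluded from that question's denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import ANSWER_LEVELS, DIAGNOSES, N_QUESTIONS, Cohort


@dataclass(frozen=True)
class HeatMap:
    """45x6 relative-frequency-difference matrix for one ordered pair."""

    pair: tuple[str, str]
    delta: np.ndarray  # shape (45, 6); delta[q-1, a-1]

    def cell(self, question: int, level: int) -> float:
        """Entry for 1-based question index and answer level."""
        return float(self.delta[question - 1, level - 1])

    def question_scores(self) -> np.ndarray:
        """Per-question discriminability: max over levels of |delta|."""
        return np.abs(self.delta).max(axis=1)

    def top_questions(self, n: int = 3) -> list[int]:
        """1-based question indices ranked by discriminability (ties by
        ascending index)."""
        scores = self.question_scores()
        order = sorted(range(N_QUESTIONS), key=lambda q: (-scores[q], q))
        return [q + 1 for q in order[:n]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.delta,
            index=[f"q{i:02d}" for i in range(1, N_QUESTIONS + 1)],
            columns=[f"a{a}" for a in ANSWER_LEVELS],
        )


def _relative_frequencies(cohort: Cohort, label: str) -> np.ndarray:
    """(45, 6) within-class answer frequencies over non-missing answers."""
    rows = [r.answers for r in cohort if r.label == label]
    if not rows:
        raise ValueError(f"cohort contains no records of class {label}")
    freq = np.zeros((N_QUESTIONS, 6))
    for q in range(N_QUESTIONS):
        values = [r[q] for r in rows if r[q] is not None]
        if values:
            counts = np.bincount(np.asarray(values) - 1, minlength=6)
            freq[q] = counts / len(values)
    return freq


def heatmap_pair(cohort: Cohort, d1: str, d2: str) -> HeatMap:
    """Relative-frequency-difference matrix for the ordered pair (d1, d2)."""
    for d in (d1, d2):
        if d not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {d!r}")
    delta = _relative_frequencies(cohort, d1) - _relative_frequencies(cohort, d2)
    return HeatMap(pair=(d1, d2), delta=delta)


def heatmap_all_pairs(cohort: Cohort) -> dict[tuple[str, str], HeatMap]:
    """One heat map per unordered pair of present classes, emitted once
    each with the canonically earlier class first (21 maps for 7 classes)."""
    present = [d for d, n in cohort.class_counts.items() if n > 0]
    if len(present) < 2:
        raise ValueError("heat maps need at least two classes present")
    return {
        (d1, d2): heatmap_pair(cohort, d1, d2)
        for d1, d2 in combinations(present, 2)
    }


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(cohort: Cohort, q: int) -> float:
    """Mutual information (bits) between the diagnosis label and the
    answer to question ``q``, over labelled records with a non-missing
    answer; 0*log(0) is taken as 0."""
    if not 1 <= q <= N_QUESTIONS:
        raise ValueError(f"question index {q} outside 1..{N_QUESTIONS}")
    pairs = [
        (DIAGNOSES.index(r.label), r.answers[q - 1] - 1)
        for r in cohort
        if r.label is not None and r.answers[q - 1] is not None
    ]
    if not pairs:
        return 0.0
    table = np.zeros((len(DIAGNOSES), 6))
    for ci, ai in pairs:
        table[ci, ai] += 1
    n = table.sum()
    h_class = _entropy_bits(table.sum(axis=1))
    h_cond = sum(
        (table[:, a].sum() / n) * _entropy_bits(table[:, a]) for a in range(6)
    )
    return max(0.0, h_class - h_cond)


@dataclass(frozen=True)
class InfoGainRanking:
    """Per-question gains (bits) and the descending ranking (1-based)."""

    gains: tuple[float, ...]
    ranking: tuple[int, ...]


def rank_questions(cohort: Cohort) -> InfoGainRanking:
    """All 45 information gains, ranked descending with ties broken by
    ascending question index."""
    gains = [information_gain(cohort, q) for q in range(1, N_QUESTIONS + 1)]
    order = sorted(range(N_QUESTIONS), key=lambda i: (-gains[i], i))
    return InfoGainRanking(gains=tuple(gains), ranking=tuple(i + 1 for i in order))
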