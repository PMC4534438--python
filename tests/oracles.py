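"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by a different route than the package:
AUC as the concordant-pair fraction, the naive-Bayes posterior as an
explicit smoothed-frequency product, and information gain from the joint
answer/class distribution.  They are deliberately simple and slow.
"""

from __future__ import annotations

import math

import numpy as np

from pulmoquest.core import DIAGNOSES


def auc_concordant_pairs(scores, truth) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked
    concordantly, ties counted 1/2."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_bayes_posterior(cohort, query, alpha: float = 1.0) -> np.ndarray:
    """Posterior over the 7 canonical classes from an explicit
    Laplace-smoothed class-conditional frequency product (no missing
    answers assumed)."""
    records = [r for r in cohort if r.label is not None]
    n = len(records)
    post = np.zeros(len(DIAGNOSES))
    for ci, c in enumerate(DIAGNOSES):
        group = [r for r in records if r.label == c]
        if not group:
            continue
        log_p = math.log(len(group) / n)
        for q, a in enumerate(query):
            count = sum(1 for r in group if r.answers[q] == a)
            log_p += math.log((count + alpha) / (len(group) + 6 * alpha))
        post[ci] = math.exp(log_p)
    return post / post.sum()


def information_gain_joint(cohort, q: int) -> float:
    """Mutual information (bits) from the joint (class, answer)
    distribution: sum p(c,a) * log2(p(c,a) / (p(c) p(a)))."""
    pairs = [
        (DIAGNOSES.index(r.label), r.answers[q - 1])
        for r in cohort
        if r.label is not None and r.answers[q - 1] is not None
    ]
    n = len(pairs)
    joint: dict[tuple[int, int], float] = {}
    pc: dict[int, float] = {}
    pa: dict[int, float] = {}
    for c, a in pairs:
        joint[(c, a)] = joint.get((c, a), 0) + 1 / n
        pc[c] = pc.get(c, 0) + 1 / n
        pa[a] = pa.get(a, 0) + 1 / n
    return sum(
        p * math.log2(p / (pc[c] * pa[a])) for (c, a), p in joint.items()
    )
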