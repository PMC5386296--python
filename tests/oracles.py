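"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: AUC by exhaustive
pair enumeration, threshold selection by exhaustive cutpoint search,
Fisher's exact test by full enumeration of margin-fixed tables, and the
rank-sum null by direct combinatorics.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def auc_pair_enumeration(scores, labels) -> float:
    """AUC as the concordant-pair fraction (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def threshold_search_oracle(scores, labels, max_fpr):
    """Exhaustive search over all observed cutpoints (prediction: >= t).

    Returns (threshold, tpr, fpr, tnr, accuracy) of the cutpoint with the
    highest TPR subject to FPR <= max_fpr, breaking ties by the smallest
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    for t in list(np.unique(scores)) + [math.inf]:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fpr = fp / n_neg
        if fpr > max_fpr:
            continue
        tpr = tp / n_pos
        tn = n_neg - fp
        cand = (tpr, -t, fpr, tn / n_neg, (tp + tn) / (n_pos + n_neg), t)
        if best is None or cand[:2] > best[:2]:
            best = cand
    tpr, _, fpr, tnr, acc, t = best
    return t, tpr, fpr, tnr, acc


def fisher_two_sided_enumeration(tp: int, fp: int, fn: int, tn: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    margin-fixed tables no more likely than the observed one."""
    r1, r2 = tp + fp, fn + tn
    c1 = tp + fn
    n = r1 + r2

    def prob(a: int) -> float:
        b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
        if min(b, c, d) < 0:
            return 0.0
        return (
            math.comb(r1, a) * math.comb(r2, c) / math.comb(n, c1)
        )

    p_obs = prob(tp)
    total = 0.0
    for a in range(0, min(r1, c1) + 1):
        p = prob(a)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def ranksum_min_two_sided_p(n1: int, n2: int) -> float:
    """Smallest attainable two-sided rank-sum p for group sizes n1, n2
    (completely separated samples)."""
    return 2.0 / math.comb(n1 + n2, n1)


def exact_conservation(rows: list[str], col: int, wild_aa: str) -> float:
    """Direct per-column tally of wild/D/E over all sequences."""
    hits = sum(1 for r in rows if r[col].upper() in {wild_aa, "D", "E"})
    return hits / len(rows)


def all_subsets_auc_check(scores, labels, auc_fn, n_trials_msg=""):
    """Convenience: compare an AUC implementation to pair enumeration."""
    return abs(auc_fn(scores, labels) - auc_pair_enumeration(scores, labels))
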