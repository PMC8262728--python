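"""Independent brute-force oracles used to check the statistical kernels.

Each oracle recomputes a quantity from its definition (subset enumeration,
step-up by hand, pairwise concordance, exhaustive threshold scan) without
touching the implementation under test.
"""

from itertools import combinations

import numpy as np


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element population
    whose first K elements are marked."""
    population = range(N)
    marked = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def bh_rejections_by_definition(p_values, q: float):
    """Benjamini-Hochberg step-up applied literally: sort ascending, find the
    largest i with p_(i) <= i*q/m, reject everything at or below it."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    i_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            i_star = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:i_star]] = True
    return reject


def auroc_by_pairwise_concordance(scores, labels) -> float:
    """Fraction of (positive, negative) pairs where the positive outscores
    the negative; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def best_threshold_by_scan(scores, labels):
    """Maximum J over every threshold that changes the prediction, scanning
    all distinct scores, midpoints, and sentinels beyond both extremes."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    distinct = np.unique(s)
    candidates = list(distinct)
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(distinct[0] - 1.0)
    candidates.append(distinct[-1] + 1.0)
    pos, neg = y.sum(), (~y).sum()
    best = -np.inf
    for t in candidates:
        pred = s >= t
        j = (y & pred).sum() / pos + ((~y) & (~pred)).sum() / neg - 1.0
        best = max(best, j)
    return best
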