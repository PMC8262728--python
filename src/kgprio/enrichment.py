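"""Over-representation statistics and predictor-feature selection.

A feature node is a *predictor* for a phenotype when it is connected to
significantly more seed genes than expected by chance. Significance is the
one-sided hypergeometric upper tail (equivalent to a one-sided Fisher exact
test): drawing the ``n`` seed genes from the ``N``-gene universe, what is the
probability of hitting at least ``k`` of the ``K`` genes adjacent to the
feature? All features with at least one seed neighbor are tested jointly and
corrected with Benjamini-Hochberg FDR; survivors, grouped by feature class,
form the columns of the downstream feature matrix.

The same hypergeometric kernel is reused everywhere an over-representation
question appears in the package (held-out-gene enrichment in cross-validation,
temporal validation, gene-set enrichment of result lists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError
from .graph import KnowledgeGraph, SeedSet


@dataclass(frozen=True)
class EnrichmentTest:
    """One feature's over-representation among the seed genes.

    k of the n seed genes are adjacent to the feature; K of the N universe
    genes are. ``p`` is the hypergeometric upper tail P(X >= k), ``q`` its
    BH-adjusted value.
    """

    feature: str
    feature_class: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float = float("nan")
    significant: bool = False


@dataclass(frozen=True)
class PredictorSet:
    """The significant predictor features of one job, grouped by class."""

    tests: tuple[EnrichmentTest, ...]
    q_threshold: float
    predictors_by_class: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not any(self.predictors_by_class.values())

    @property
    def features(self) -> frozenset[str]:
        out: set[str] = set()
        for feats in self.predictors_by_class.values():
            out |= feats
        return frozenset(out)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, f in self.predictors_by_class.items() if f))

    def q_of(self, feature: str) -> float:
        for t in self.tests:
            if t.feature == feature:
                return t.q
        raise KeyError(feature)

    def to_frame(self) -> pd.DataFrame:
        """Predictor report: one row per tested feature."""
        return pd.DataFrame(
            [
                (t.feature, t.feature_class, t.k, t.K, t.n, t.N, t.p, t.q, t.significant)
                for t in self.tests
            ],
            columns=["feature", "class", "k", "K", "n", "N", "p", "q", "significant"],
        )


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed through the survival function, which scipy evaluates in a
    numerically stable form; exact 1.0 at k = 0 and when the feature covers
    the whole universe.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= min(K, n) and K <= N and n <= N and N >= 0):
        raise DomainError(
            f"hypergeometric bounds violated: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0 or K == N:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_fdr(p_values, q: float = 0.05) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg step-up correction at FDR level ``q``.

    Returns the monotone adjusted values and rejection flags, in input order.
    Empty input yields empty output.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return [], []
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise DomainError(f"FDR level must lie in (0, 1), got {q}")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted.tolist(), reject.tolist()


def find_predictors(
    kg: KnowledgeGraph,
    seeds: SeedSet | frozenset[str],
    q_threshold: float = 0.05,
    per_class: bool = False,
    exclude_features: Iterable[str] = (),
) -> PredictorSet:
    """Select predictor features: nodes over-connected to the seed genes.

    Every feature adjacent to at least one seed gene is tested against the
    full gene universe of the graph; features with no seed neighbor are not
    tested (their p is 1 by construction and would only dilute the FDR
    family). Correction is across all tested features jointly, or within each
    feature class when ``per_class`` is set.

    ``exclude_features`` removes features from consideration entirely —
    chiefly the target phenotype's own disease-gene node, whose adjacency
    *defines* the seed set and would otherwise be a trivially perfect,
    non-generalizing predictor.
    """
    excluded = frozenset(exclude_features)
    if isinstance(seeds, SeedSet):
        excluded |= frozenset(seeds.phenotypes)
        seed_genes = seeds.genes
    else:
        seed_genes = frozenset(seeds)
    universe = kg.genes
    outside = seed_genes - universe
    if outside:
        raise DomainError(f"seed genes absent from the graph: {sorted(outside)}")
    N = len(universe)
    n = len(seed_genes)

    raw: list[EnrichmentTest] = []
    for feature in sorted(kg.feature_ids - excluded):
        adjacent = kg.neighbors(feature)
        k = len(adjacent & seed_genes)
        if k == 0:
            continue
        K = len(adjacent)
        p = hypergeom_upper_tail(k, K, n, N)
        raw.append(EnrichmentTest(feature, kg.feature_class_of(feature), k, K, n, N, p))

    if not raw:
        return PredictorSet(tests=(), q_threshold=q_threshold, predictors_by_class={})

    if per_class:
        groups: dict[str, list[int]] = {}
        for i, t in enumerate(raw):
            groups.setdefault(t.feature_class, []).append(i)
        q_adj = [0.0] * len(raw)
        rejected = [False] * len(raw)
        for idx in groups.values():
            adj, rej = bh_fdr([raw[i].p for i in idx], q_threshold)
            for j, i in enumerate(idx):
                q_adj[i], rejected[i] = adj[j], rej[j]
    else:
        q_adj, rejected = bh_fdr([t.p for t in raw], q_threshold)

    tests = tuple(
        EnrichmentTest(t.feature, t.feature_class, t.k, t.K, t.n, t.N, t.p, q, sig)
        for t, q, sig in zip(raw, q_adj, rejected)
    )
    by_class: dict[str, set[str]] = {}
    for t in tests:
        if t.significant:
            by_class.setdefault(t.feature_class, set()).add(t.feature)
    return PredictorSet(
        tests=tests,
        q_threshold=q_threshold,
        predictors_by_class={c: frozenset(f) for c, f in by_class.items()},
    )
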