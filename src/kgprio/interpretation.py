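"""Result interpretation: gene-set enrichment, explanation subgraphs,
per-source contributions.

Three complementary views of a finished job. Gene-set enrichment asks what
the known genes, the predicted genes, and their union are enriched for in
user-supplied GMT libraries. Explanation subgraphs show, for one focus gene,
which predictor features it touches and which seed genes share them — the
evidence trail behind its score. Source contributions apportion a gene's
score (or the whole model) across the data sources that supplied the
supporting edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .enrichment import bh_fdr, hypergeom_upper_tail
from .exceptions import DomainError, FormatError, NodeNotFoundError
from .graph import KnowledgeGraph, SeedSet, normalize_gene_symbol
from .model import TrainedModel


@dataclass(frozen=True)
class GeneSetLibrary:
    name: str
    sets: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def coverage(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def load_gmt(path: str | Path, name: str | None = None) -> GeneSetLibrary:
    """Read a tab-delimited GMT library (set name, description, genes...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        set_name = fields[0].strip()
        genes = frozenset(
            normalize_gene_symbol(g) for g in fields[2:] if normalize_gene_symbol(g)
        )
        sets[set_name] = genes
    return GeneSetLibrary(name or path.stem, sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    lines = [
        "\t".join([set_name, library.name] + sorted(genes))
        for set_name, genes in sorted(library.sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def gene_set_enrichment(
    gene_lists: Mapping[str, Iterable[str]],
    library: GeneSetLibrary,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of each library set in each supplied gene list.

    ``gene_lists`` maps list ids (conventionally ``known``, ``predicted``,
    ``union``) to gene collections. The background is the supplied universe
    intersected with the library's coverage, which avoids inflating
    significance for genes the library never mentions. BH correction is
    applied within each (library, list) family; rows come back sorted by q.
    """
    universe = frozenset(normalize_gene_symbol(g) for g in universe)
    background = universe & library.coverage
    if not background:
        return pd.DataFrame(
            columns=["library", "set", "gene_list", "k", "K", "n", "N", "p", "q"]
        )
    N = len(background)
    rows = []
    for list_id, genes in gene_lists.items():
        members = frozenset(normalize_gene_symbol(g) for g in genes) & background
        n = len(members)
        family: list[tuple] = []
        for set_name, set_genes in sorted(library.sets.items()):
            K_set = set_genes & background
            k = len(members & K_set)
            p = hypergeom_upper_tail(k, len(K_set), n, N) if n else 1.0
            family.append((library.name, set_name, list_id, k, len(K_set), n, N, p))
        q_adj, _ = bh_fdr([r[-1] for r in family]) if family else ([], [])
        rows.extend([r + (q,) for r, q in zip(family, q_adj)])
    df = pd.DataFrame(
        rows, columns=["library", "set", "gene_list", "k", "K", "n", "N", "p", "q"]
    )
    return df.sort_values(["gene_list", "q", "p", "set"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# explanation subgraphs


def explanation_subgraph(
    kg: KnowledgeGraph,
    model: TrainedModel,
    gene: str,
    seeds: SeedSet | frozenset[str],
) -> nx.Graph:
    """Two-hop evidence subgraph: focus gene -> its predictors -> seed genes.

    Nodes carry ``kind``, ``feature_class``, ``seed`` and, for predictors,
    the enrichment ``q`` and the class ``weight``; edges carry ``relation``
    and ``sources``. Every edge exists in the parent graph.
    """
    gene = normalize_gene_symbol(gene)
    if gene not in kg.genes:
        raise NodeNotFoundError(f"no gene {gene!r} in the graph")
    seed_genes = seeds.genes if isinstance(seeds, SeedSet) else frozenset(seeds)
    pset = model.predictor_set
    if pset is None:
        raise DomainError("model carries no predictor set")

    g = nx.Graph()
    g.add_node(gene, kind="gene", feature_class="", seed=gene in seed_genes)
    weights = model.weights
    for cls_label in pset.classes:
        predictors = pset.predictors_by_class[cls_label] & kg.neighbors(gene, cls_label)
        for feat in sorted(predictors):
            try:
                q = pset.q_of(feat)
            except KeyError:
                q = float("nan")
            g.add_node(
                feat,
                kind="feature",
                feature_class=cls_label,
                seed=False,
                q=q,
                weight=float(weights.get(cls_label, 0.0)),
            )
            _add_kg_edge(g, kg, gene, feat)
            for seed in sorted(kg.neighbors(feat) & seed_genes):
                if seed == gene:
                    continue
                g.add_node(seed, kind="gene", feature_class="", seed=True)
                _add_kg_edge(g, kg, seed, feat)
    return g


def _add_kg_edge(g: nx.Graph, kg: KnowledgeGraph, gene: str, feat: str) -> None:
    for e in kg.edges_incident(gene):
        if e.target == feat:
            g.add_edge(gene, feat, relation=e.relation, sources=";".join(sorted(e.sources)))
            return
    raise NodeNotFoundError(f"edge ({gene}, {feat}) not in graph")


def write_subgraph_graphml(subgraph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(subgraph, str(path))


def write_subgraph_json(subgraph: nx.Graph, path: str | Path) -> None:
    data = nx.node_link_data(subgraph, edges="links")
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# source contributions


@dataclass(frozen=True)
class SourceContribution:
    gene: str
    by_class: dict[str, float]
    by_source: dict[str, float]
    zero_score: bool = False


def source_contributions(
    model: TrainedModel,
    scaled_row: Mapping[str, float],
    class_source_shares: Mapping[str, Mapping[str, float]] | None = None,
) -> SourceContribution:
    """Fraction of one gene's score contributed by each class (and source).

    The class contribution is ``w_c x_c / sum_c w_c x_c``; within a class the
    contribution is split across sources proportionally to the supplied
    per-class source shares (e.g. supporting-edge counts). A zero-score gene
    gets an all-zero vector with the ``zero_score`` flag set.
    """
    gene = str(scaled_row.get("gene", "")) if isinstance(scaled_row, dict) else ""
    parts = {c: float(model.weights[c]) * float(scaled_row[c]) for c in model.classes}
    total = sum(parts.values())
    if total <= 0:
        return SourceContribution(gene, {c: 0.0 for c in model.classes}, {}, zero_score=True)
    by_class = {c: v / total for c, v in parts.items()}
    by_source: dict[str, float] = {}
    if class_source_shares:
        for c, frac in by_class.items():
            shares = class_source_shares.get(c, {})
            share_total = sum(shares.values())
            if share_total <= 0:
                continue
            for src, s in shares.items():
                by_source[src] = by_source.get(src, 0.0) + frac * s / share_total
    return SourceContribution(gene, by_class, by_source)


def gene_source_shares(
    kg: KnowledgeGraph, pset, gene: str
) -> dict[str, dict[str, float]]:
    """Per-class, per-source counts of this gene's predictor-supporting edges."""
    gene = normalize_gene_symbol(gene)
    out: dict[str, dict[str, float]] = {}
    for e in kg.edges_incident(gene):
        cls_label = kg.feature_class_of(e.target)
        if e.target not in pset.predictors_by_class.get(cls_label, frozenset()):
            continue
        shares = out.setdefault(cls_label, {})
        for src in e.sources:
            # an edge carried by several sources splits its unit weight
            shares[src] = shares.get(src, 0.0) + 1.0 / len(e.sources)
    return out


def model_source_overview(pset, kg: KnowledgeGraph) -> dict[str, float]:
    """Fraction of all predictor-supporting edges attributable to each source."""
    if pset is None or pset.empty:
        raise DomainError("no predictor set: the model was not trained")
    predictors = pset.features
    counts: dict[str, float] = {}
    total = 0.0
    for e in kg.edges():
        if e.target not in predictors:
            continue
        for src in e.sources:
            counts[src] = counts.get(src, 0.0) + 1.0 / len(e.sources)
        total += 1.0
    if total == 0:
        raise DomainError("no edges support the predictor set")
    return {src: c / total for src, c in counts.items()}
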