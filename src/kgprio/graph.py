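"""Heterogeneous knowledge graph of genes and biological/phenotypic features.

The graph is undirected and bipartite-by-construction: every edge connects a
gene node (an upper-cased HGNC-style symbol) to a feature node (a GO term, an
interaction partner, a disease, ...). Feature nodes carry a ``feature_class``
label — the type grouping that later defines one column of the feature matrix
and receives one learned weight. Edges are keyed by ``(gene, target,
relation)``; loading the same triple from several source databases accumulates
the source labels on one edge, which is what makes per-source contribution
reports possible downstream.

Gene-gene relations (protein-protein interactions mapped to gene symbols) are
folded into the same shape by mirroring: each partner also appears as a
feature node with a class-qualified id (``PPI:SYMBOL``), so a gene's adjacency
within the PPI class counts its interaction partners exactly once.
"""

from __future__ import annotations

import csv
import difflib
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .exceptions import (
    ConsistencyError,
    EmptyInputError,
    EmptySeedError,
    FormatError,
    KgprioError,
    NodeNotFoundError,
    UnknownPhenotypeError,
)

logger = logging.getLogger(__name__)

GENE_KIND = "gene"
FEATURE_KIND = "feature"

#: Edge-table columns with reserved meaning; any other column is the target.
_RESERVED_COLUMNS = ("Gene", "Relation", "Source", "Class")

_WS = re.compile(r"\s+")


def normalize_gene_symbol(symbol: str) -> str:
    """Upper-case and strip a gene symbol. Idempotent."""
    return _WS.sub("", str(symbol).strip()).upper()


@dataclass(frozen=True)
class Node:
    id: str
    kind: str  # "gene" or "feature"
    feature_class: str = ""  # empty for genes

    def __post_init__(self):
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.kind not in (GENE_KIND, FEATURE_KIND):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == FEATURE_KIND and not self.feature_class:
            raise ValueError("feature nodes need a feature_class")
        if self.kind == GENE_KIND and self.feature_class:
            raise ValueError("gene nodes carry no feature_class")


@dataclass(frozen=True)
class Edge:
    gene: str
    target: str
    relation: str
    sources: frozenset[str]


@dataclass(frozen=True)
class SeedSet:
    """The phenotype(s) under study and their known associated genes.

    ``provenance`` records how the set was obtained: looked up in the
    disease-gene graph (``database``), supplied by the user to replace the
    graph's relations (``user_override``), or given as a bare list
    (``bare_list``). ``dropped`` lists symbols that did not resolve to a gene
    in the graph — reported, never silently ignored.
    """

    phenotypes: tuple[str, ...]
    genes: frozenset[str]
    provenance: str
    dropped: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.genes:
            raise EmptySeedError("seed set is empty")
        if self.provenance not in ("database", "user_override", "bare_list"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.genes)


class KnowledgeGraph:
    """Undirected gene-feature graph with a per-class adjacency index."""

    def __init__(self) -> None:
        self._genes: set[str] = set()
        self._features: dict[str, str] = {}  # feature id -> class
        self._edges: dict[tuple[str, str, str], set[str]] = {}
        self._adj: dict[str, dict[str, set[str]]] = {}  # gene -> class -> targets
        self._radj: dict[str, set[str]] = {}  # feature -> genes
        #: bookkeeping from the last load (skipped / duplicate row counts)
        self.n_skipped_rows = 0
        self.n_duplicate_rows = 0

    # -- construction -------------------------------------------------------

    def add_gene(self, symbol: str) -> str:
        sym = normalize_gene_symbol(symbol)
        if not sym:
            raise ValueError("empty gene symbol")
        if sym in self._features:
            raise ConsistencyError(f"{sym!r} already present as a feature node")
        self._genes.add(sym)
        return sym

    def add_feature(self, feature_id: str, feature_class: str) -> str:
        fid = str(feature_id).strip()
        if not fid or not feature_class:
            raise ValueError("feature id and class must be non-empty")
        if fid in self._genes:
            raise ConsistencyError(f"{fid!r} already present as a gene node")
        known = self._features.get(fid)
        if known is not None and known != feature_class:
            raise ConsistencyError(
                f"feature {fid!r} assigned two classes: {known!r} and {feature_class!r}"
            )
        self._features[fid] = feature_class
        return fid

    def add_edge(
        self,
        gene: str,
        target: str,
        relation: str = "associated_with",
        source: str | Iterable[str] = "unspecified",
        feature_class: str = "feature",
    ) -> None:
        gene = self.add_gene(gene)
        target = self.add_feature(target, self._features.get(target, feature_class))
        if gene == target:
            raise ConsistencyError(f"self-loop on {gene!r}")
        sources = {source} if isinstance(source, str) else set(source)
        key = (gene, target, relation)
        if key in self._edges:
            self._edges[key] |= sources
        else:
            self._edges[key] = set(sources)
        cls = self._features[target]
        self._adj.setdefault(gene, {}).setdefault(cls, set()).add(target)
        self._radj.setdefault(target, set()).add(gene)

    def remove_feature(self, feature_id: str) -> None:
        """Drop a feature node and every edge touching it."""
        if feature_id not in self._features:
            raise NodeNotFoundError(f"no feature node {feature_id!r}")
        cls = self._features.pop(feature_id)
        for gene in self._radj.pop(feature_id, set()):
            self._adj[gene].get(cls, set()).discard(feature_id)
        self._edges = {k: v for k, v in self._edges.items() if k[1] != feature_id}

    def copy(self) -> "KnowledgeGraph":
        out = KnowledgeGraph()
        out._genes = set(self._genes)
        out._features = dict(self._features)
        out._edges = {k: set(v) for k, v in self._edges.items()}
        out.rebuild_index()
        return out

    def rebuild_index(self) -> None:
        """Recompute the adjacency index from the edge set."""
        self._adj = {}
        self._radj = {}
        for (gene, target, _rel) in self._edges:
            cls = self._features[target]
            self._adj.setdefault(gene, {}).setdefault(cls, set()).add(target)
            self._radj.setdefault(target, set()).add(gene)

    # -- queries -------------------------------------------------------------

    @property
    def genes(self) -> frozenset[str]:
        """The gene universe: all nodes of kind gene."""
        return frozenset(self._genes)

    @property
    def feature_ids(self) -> frozenset[str]:
        return frozenset(self._features)

    def feature_class_of(self, feature_id: str) -> str:
        try:
            return self._features[feature_id]
        except KeyError:
            raise NodeNotFoundError(f"no feature node {feature_id!r}") from None

    @property
    def feature_classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self._features.values())))

    def features_of_class(self, feature_class: str) -> frozenset[str]:
        return frozenset(
            f for f, c in self._features.items() if c == feature_class
        )

    def has_node(self, node_id: str) -> bool:
        return node_id in self._genes or node_id in self._features

    def neighbors(self, node_id: str, feature_class: str | None = None) -> frozenset[str]:
        """Adjacent node ids, optionally restricted to one feature class.

        For a gene the neighbors are feature nodes (filtering by class
        restricts to that class); for a feature node the neighbors are genes
        (gene nodes have no class, so a class restriction other than the
        feature's own yields the empty set).
        """
        if node_id in self._genes:
            per_class = self._adj.get(node_id, {})
            if feature_class is None:
                out: set[str] = set()
                for targets in per_class.values():
                    out |= targets
                return frozenset(out)
            return frozenset(per_class.get(feature_class, set()))
        if node_id in self._features:
            if feature_class is not None:
                return frozenset()
            return frozenset(self._radj.get(node_id, set()))
        raise NodeNotFoundError(f"no node {node_id!r} in the graph")

    def nodes(self) -> Iterator[Node]:
        for g in sorted(self._genes):
            yield Node(g, GENE_KIND)
        for f in sorted(self._features):
            yield Node(f, FEATURE_KIND, self._features[f])

    def edges_incident(self, gene: str) -> list[Edge]:
        """All edges whose gene endpoint is ``gene``."""
        return [
            Edge(g, t, r, frozenset(s))
            for (g, t, r), s in self._edges.items()
            if g == gene
        ]

    def edges(self) -> Iterator[Edge]:
        for (gene, target, relation) in sorted(self._edges):
            yield Edge(gene, target, relation, frozenset(self._edges[(gene, target, relation)]))

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge_sources(self, gene: str, target: str, relation: str = "associated_with") -> frozenset[str]:
        try:
            return frozenset(self._edges[(gene, target, relation)])
        except KeyError:
            raise NodeNotFoundError(f"no edge ({gene!r}, {target!r}, {relation!r})") from None

    def has_edge(self, gene: str, target: str, relation: str | None = None) -> bool:
        if relation is not None:
            return (gene, target, relation) in self._edges
        return any(k[0] == gene and k[1] == target for k in self._edges)

    # -- I/O -----------------------------------------------------------------

    def to_node_table(self) -> pd.DataFrame:
        rows = [(n.id, n.kind, n.feature_class) for n in self.nodes()]
        return pd.DataFrame(rows, columns=["id", "kind", "class"])

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            (e.gene, e.target, e.relation, ";".join(sorted(e.sources)))
            for e in self.edges()
        ]
        return pd.DataFrame(rows, columns=["Gene", "Target", "Relation", "Sources"])

    def write_tables(self, node_path: str | Path, edge_path: str | Path) -> None:
        self.to_node_table().to_csv(node_path, index=False)
        self.to_edge_table().to_csv(edge_path, index=False)

    @classmethod
    def from_tables(cls, node_path: str | Path, edge_path: str | Path) -> "KnowledgeGraph":
        nodes = pd.read_csv(node_path, dtype=str, keep_default_na=False)
        edges = pd.read_csv(edge_path, dtype=str, keep_default_na=False)
        kg = cls()
        for node_id, kind, node_class in nodes[["id", "kind", "class"]].itertuples(
            index=False, name=None
        ):
            if kind == GENE_KIND:
                kg.add_gene(node_id)
            else:
                kg.add_feature(node_id, node_class)
        for gene, target, relation, sources in edges[
            ["Gene", "Target", "Relation", "Sources"]
        ].itertuples(index=False, name=None):
            kg.add_edge(
                gene,
                target,
                relation,
                source=set(sources.split(";")),
                feature_class=kg._features.get(target, "feature"),
            )
        return kg


def load_edge_table(
    path: str | Path,
    default_class: str = "feature",
    default_source: str | None = None,
    default_relation: str = "associated_with",
    gene_gene: bool = False,
) -> KnowledgeGraph:
    """Load one comma-delimited edge table into a knowledge graph.

    The file must have a header with a column named exactly ``Gene``; the
    first non-reserved other column names the related entity. Optional
    ``Relation``, ``Source`` and ``Class`` columns override the defaults per
    row. Rows with an empty gene or target cell are skipped and counted;
    duplicate rows collapse onto one edge.

    With ``gene_gene=True`` the target column is read as a partner gene
    symbol: both symbols become gene nodes and each also appears as a
    class-qualified feature node (``<class>:<symbol>``) adjacent to the other,
    so per-class adjacency counts interaction partners.
    """
    path = Path(path)
    if default_source is None:
        default_source = path.stem
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "Gene" not in df.columns:
        raise FormatError(
            f"{path}: no 'Gene' column (columns found: {', '.join(df.columns)})"
        )
    target_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    if not target_cols:
        raise FormatError(f"{path}: no target column besides {_RESERVED_COLUMNS}")
    target_col = target_cols[0]

    kg = KnowledgeGraph()
    seen: set[tuple[str, str, str, str]] = set()
    for raw in df.to_dict("records"):
        gene = normalize_gene_symbol(raw["Gene"])
        target = str(raw[target_col]).strip()
        if not gene or not target:
            kg.n_skipped_rows += 1
            continue
        relation = str(raw.get("Relation", "") or default_relation).strip()
        source = str(raw.get("Source", "") or default_source).strip()
        cls = str(raw.get("Class", "") or default_class).strip()
        if gene_gene:
            partner = normalize_gene_symbol(target)
            if partner == gene:  # self-interaction adds no adjacency information
                kg.n_skipped_rows += 1
                continue
            pair = tuple(sorted((gene, partner)))
            key = (pair[0], pair[1], relation, source)
            if key in seen:
                kg.n_duplicate_rows += 1
                continue
            seen.add(key)
            kg.add_gene(gene)
            kg.add_gene(partner)
            kg.add_edge(gene, f"{cls}:{partner}", relation, source, feature_class=cls)
            kg.add_edge(partner, f"{cls}:{gene}", relation, source, feature_class=cls)
        else:
            key = (gene, target, relation, source)
            if key in seen:
                kg.n_duplicate_rows += 1
                continue
            seen.add(key)
            kg.add_edge(gene, target, relation, source, feature_class=cls)
    if kg.n_edges == 0:
        raise EmptyInputError(f"{path}: no usable rows after filtering")
    if kg.n_skipped_rows:
        logger.info("%s: skipped %d incomplete rows", path, kg.n_skipped_rows)
    return kg


def merge_graphs(graphs: Sequence[KnowledgeGraph]) -> KnowledgeGraph:
    """Union of nodes and edges; shared edges accumulate source labels.

    A node id used as a gene in one graph and as a feature in another is a
    consistency error, as is one feature id carrying two classes.
    """
    if not graphs:
        raise EmptyInputError("merge_graphs needs at least one graph")
    out = KnowledgeGraph()
    for kg in graphs:
        for g in kg._genes:
            out.add_gene(g)
        for f, cls in kg._features.items():
            out.add_feature(f, cls)
        out.n_skipped_rows += kg.n_skipped_rows
        out.n_duplicate_rows += kg.n_duplicate_rows
    for kg in graphs:
        for key, sources in kg._edges.items():
            if key in out._edges:
                out._edges[key] |= sources
            else:
                out._edges[key] = set(sources)
    out.rebuild_index()
    return out


def _read_seed_file(path: str | Path) -> tuple[list[str], list[tuple[str, str]]]:
    """Read a seed file: one symbol per line, or CSV with Phenotype,Gene columns."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise EmptyInputError(f"{path}: empty seed file")
    first = text.splitlines()[0]
    if "," in first:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if not {"Phenotype", "Gene"} <= set(df.columns):
            raise FormatError(
                f"{path}: seed CSV needs 'Phenotype' and 'Gene' columns "
                f"(found: {', '.join(df.columns)})"
            )
        pairs = [
            (p.strip(), normalize_gene_symbol(g))
            for p, g in zip(df["Phenotype"], df["Gene"])
            if p.strip() and normalize_gene_symbol(g)
        ]
        return [], pairs
    symbols = [normalize_gene_symbol(line) for line in text.splitlines() if line.strip()]
    return symbols, []


def resolve_seeds(
    phenotypes: Sequence[str] | None = None,
    dg_graph: KnowledgeGraph | None = None,
    user_associations: Sequence[tuple[str, str]] | None = None,
    bare_genes: Sequence[str] | None = None,
    dg_class: str = "DG",
    user_source: str = "user",
) -> tuple[SeedSet, KnowledgeGraph | None]:
    """Resolve the seed specification into a SeedSet and a working graph.

    Exactly one of three modes applies:

    * phenotypes only — seeds are the union of genes linked to any listed
      phenotype in ``dg_graph`` (unknown phenotypes raise, with near-matches);
    * phenotypes + user associations — the graph's disease-gene relations for
      the listed phenotypes are removed from a copy of the graph and replaced
      by the user's pairs before seed extraction;
    * bare gene list — seeds are the normalized symbols, with no phenotype.

    Returns the seed set and the working graph (a modified copy in the
    override mode, the input graph otherwise, ``None`` when no graph given).
    """
    has_ph = bool(phenotypes)
    has_user = user_associations is not None
    has_bare = bare_genes is not None
    if has_bare and (has_ph or has_user):
        raise KgprioError("bare_genes cannot be combined with phenotypes/user_associations")
    if has_user and not has_ph:
        raise KgprioError("user_associations require the phenotypes they belong to")
    if not (has_ph or has_bare):
        raise KgprioError("supply phenotypes, phenotypes+user_associations, or bare_genes")

    if has_bare:
        normalized = [normalize_gene_symbol(g) for g in bare_genes if normalize_gene_symbol(g)]
        uniq = sorted(dict.fromkeys(normalized))
        if dg_graph is not None:
            universe = dg_graph.genes
            kept = [g for g in uniq if g in universe]
            dropped = tuple(g for g in uniq if g not in universe)
        else:
            kept, dropped = uniq, ()
        if not kept:
            raise EmptySeedError("no bare seed gene resolved to a graph gene")
        if dropped:
            logger.warning("dropped %d seed symbols absent from the graph: %s",
                           len(dropped), ", ".join(dropped))
        return SeedSet((), frozenset(kept), "bare_list", dropped), dg_graph

    if dg_graph is None:
        raise KgprioError("phenotype modes need a disease-gene graph")
    phenos = tuple(str(p).strip() for p in phenotypes)

    if has_user:
        working = dg_graph.copy()
        # replace the graph's DG relations for these phenotypes with the user's
        for ph in phenos:
            if ph in working.feature_ids:
                working.remove_feature(ph)
        pair_list = [(str(p).strip(), normalize_gene_symbol(g)) for p, g in user_associations]
        pair_list = [(p, g) for p, g in pair_list if p and g]
        if not pair_list:
            raise EmptySeedError("user_associations contained no usable pairs")
        for ph, gene in pair_list:
            working.add_edge(gene, ph, "associated_with", user_source, feature_class=dg_class)
        seeds = frozenset(g for ph, g in pair_list if ph in phenos)
        if not seeds:
            raise EmptySeedError("no user association matched the listed phenotypes")
        return SeedSet(phenos, seeds, "user_override"), working

    seeds: set[str] = set()
    for ph in phenos:
        if ph not in dg_graph.feature_ids:
            near = difflib.get_close_matches(
                ph, sorted(dg_graph.feature_ids), n=3, cutoff=0.5
            )
            raise UnknownPhenotypeError(ph, near)
        seeds |= dg_graph.neighbors(ph)
    if not seeds:
        raise EmptySeedError(f"phenotypes {phenos} have no associated genes in the graph")
    return SeedSet(phenos, frozenset(seeds), "database"), dg_graph


def write_seed_file(seeds: SeedSet, path: str | Path) -> None:
    path = Path(path)
    if seeds.phenotypes:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["Phenotype", "Gene"])
            for ph in seeds.phenotypes:
                for g in sorted(seeds.genes):
                    w.writerow([ph, g])
    else:
        path.write_text("\n".join(sorted(seeds.genes)) + "\n")
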