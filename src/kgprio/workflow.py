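"""Job orchestration: the four-step pipeline behind one configuration object.

A job runs seed specification -> knowledge-graph assembly -> training and
prediction -> reports, writing a manifest plus CSV/GraphML/JSON outputs to
the output directory. Everything is deterministic given the inputs and the
rng seed; the job id is a content hash of both, so re-runs are
self-identifying.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from .evaluation import cross_validate
from .exceptions import ConfigurationError
from .graph import (
    KnowledgeGraph,
    SeedSet,
    _read_seed_file,
    load_edge_table,
    merge_graphs,
    resolve_seeds,
)
from .interpretation import (
    explanation_subgraph,
    gene_set_enrichment,
    load_gmt,
    model_source_overview,
    write_subgraph_graphml,
    write_subgraph_json,
)
from .model import GenePrioritizer

logger = logging.getLogger(__name__)

MAX_FOLDS = 5


@dataclass(frozen=True)
class EdgeTableSpec:
    path: str
    feature_class: str = "feature"
    source: str | None = None
    gene_gene: bool = False


@dataclass
class JobConfig:
    edge_tables: list[EdgeTableSpec]
    phenotypes: list[str] = field(default_factory=list)
    seed_file: str | None = None
    bare_genes: list[str] = field(default_factory=list)
    gmt_paths: list[str] = field(default_factory=list)
    fdr_q: float = 0.05
    n_folds: int = 0  # 0 = skip cross-validation
    rng_seed: int = 0
    out_dir: str = "kgprio_out"
    top_subgraphs: int = 5

    def to_file(self, path: str | Path) -> None:
        """Flat key-value dump; edge tables as path:class:source[:gg] triples."""
        lines = []
        for spec in self.edge_tables:
            entry = f"{spec.path}:{spec.feature_class}:{spec.source or ''}"
            if spec.gene_gene:
                entry += ":gg"
            lines.append(f"edge_table = {entry}")
        for key in ("phenotypes", "bare_genes", "gmt_paths"):
            for v in getattr(self, key):
                lines.append(f"{key[:-1] if key.endswith('s') else key} = {v}")
        if self.seed_file:
            lines.append(f"seed_file = {self.seed_file}")
        for key in ("fdr_q", "n_folds", "rng_seed", "out_dir", "top_subgraphs"):
            lines.append(f"{key} = {getattr(self, key)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "JobConfig":
        cfg = cls(edge_tables=[])
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "edge_table":
                parts = value.split(":")
                gene_gene = parts[-1] == "gg"
                if gene_gene:
                    parts = parts[:-1]
                parts += [""] * (3 - len(parts))
                cfg.edge_tables.append(
                    EdgeTableSpec(parts[0], parts[1] or "feature", parts[2] or None, gene_gene)
                )
            elif key == "phenotype":
                cfg.phenotypes.append(value)
            elif key == "bare_gene":
                cfg.bare_genes.append(value)
            elif key == "gmt_path":
                cfg.gmt_paths.append(value)
            elif key == "seed_file":
                cfg.seed_file = value
            elif key == "fdr_q":
                cfg.fdr_q = float(value)
            elif key in ("n_folds", "rng_seed", "top_subgraphs"):
                setattr(cfg, key, int(value))
            elif key == "out_dir":
                cfg.out_dir = value
            else:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
        return cfg

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for spec in self.edge_tables:
            h.update(repr((spec.path, spec.feature_class, spec.source, spec.gene_gene)).encode())
            p = Path(spec.path)
            if p.exists():
                h.update(p.read_bytes())
        for item in (
            tuple(self.phenotypes),
            self.seed_file,
            tuple(self.bare_genes),
            tuple(self.gmt_paths),
            self.fdr_q,
            self.n_folds,
            self.rng_seed,
        ):
            h.update(repr(item).encode())
        if self.seed_file and Path(self.seed_file).exists():
            h.update(Path(self.seed_file).read_bytes())
        return h.hexdigest()[:16]


def validate_config(config: JobConfig) -> list[str]:
    """Check a job configuration; returns a human-readable list of problems."""
    errors: list[str] = []
    if not config.edge_tables:
        errors.append("at least one edge table is required")
    for spec in config.edge_tables:
        if not Path(spec.path).exists():
            errors.append(f"edge table not found: {spec.path}")
    if config.seed_file and not Path(config.seed_file).exists():
        errors.append(f"seed file not found: {config.seed_file}")
    for p in config.gmt_paths:
        if not Path(p).exists():
            errors.append(f"GMT library not found: {p}")
    if not (0 < config.fdr_q < 1):
        errors.append(f"fdr_q must lie in (0, 1), got {config.fdr_q}")
    if config.n_folds != 0 and not 2 <= config.n_folds <= MAX_FOLDS:
        errors.append(
            f"n_folds must be 0 (skip) or between 2 and {MAX_FOLDS}, got {config.n_folds}"
        )
    has_seed_inputs = bool(
        config.phenotypes or config.seed_file or config.bare_genes
    )
    if not has_seed_inputs:
        errors.append("no seed specification (phenotypes, seed file or gene list)")
    return errors


def _resolve_job_seeds(
    config: JobConfig, kg: KnowledgeGraph
) -> tuple[SeedSet, KnowledgeGraph]:
    bare: list[str] = list(config.bare_genes)
    pairs: list[tuple[str, str]] = []
    if config.seed_file:
        symbols, file_pairs = _read_seed_file(config.seed_file)
        bare.extend(symbols)
        pairs.extend(file_pairs)
    if pairs:
        phenos = config.phenotypes or sorted({p for p, _ in pairs})
        seeds, working = resolve_seeds(
            phenotypes=phenos, dg_graph=kg, user_associations=pairs
        )
    elif config.phenotypes:
        seeds, working = resolve_seeds(phenotypes=config.phenotypes, dg_graph=kg)
    else:
        seeds, working = resolve_seeds(bare_genes=bare, dg_graph=kg)
    return seeds, working if working is not None else kg


def run_job(config: JobConfig) -> dict:
    """Execute a full job; returns the manifest (also written to disk)."""
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage %s", name)

    stage("load")
    graphs = []
    for spec in config.edge_tables:
        graphs.append(
            load_edge_table(
                spec.path,
                default_class=spec.feature_class,
                default_source=spec.source,
                gene_gene=spec.gene_gene,
            )
        )
    stage("merge")
    kg = merge_graphs(graphs)
    logger.info("graph: %d genes, %d features, %d edges",
                len(kg.genes), len(kg.feature_ids), kg.n_edges)

    stage("resolve_seeds")
    seeds, kg = _resolve_job_seeds(config, kg)
    logger.info("seeds: %d genes (%s)", len(seeds), seeds.provenance)

    stage("train")
    pipe = GenePrioritizer(fdr_q=config.fdr_q).fit(kg, seeds)
    pipe.predictors_.to_frame().to_csv(out / "predictors.csv", index=False)

    stage("predict")
    results = pipe.predict_table()
    results.to_csv(out / "results.csv", index=False)
    predicted = frozenset(results.loc[results["label"] == "predicted", "gene"])
    pipe.model_.save(out / "model.txt")

    cv_report = None
    if config.n_folds:
        stage("cross_validate")
        cv_report = cross_validate(
            kg,
            seeds,
            n_folds=config.n_folds,
            fdr_q=config.fdr_q,
            rng_seed=config.rng_seed,
        )
        cv_report.to_frame().to_csv(out / "cv_report.csv", index=False)

    stage("interpret")
    overview = model_source_overview(pipe.predictors_, kg)
    (out / "source_overview.json").write_text(json.dumps(overview, indent=1, sort_keys=True))
    for gmt_path in config.gmt_paths:
        library = load_gmt(gmt_path)
        rows = gene_set_enrichment(
            {
                "known": seeds.genes,
                "predicted": predicted,
                "union": seeds.genes | predicted,
            },
            library,
            kg.genes,
        )
        rows.to_csv(out / f"enrichment_{library.name}.csv", index=False)

    top_predicted = list(
        results.loc[results["label"] == "predicted", "gene"].head(config.top_subgraphs)
    )
    for gene in top_predicted:
        sub = explanation_subgraph(kg, pipe.model_, gene, seeds)
        write_subgraph_graphml(sub, out / f"subgraph_{gene}.graphml")
        write_subgraph_json(sub, out / f"subgraph_{gene}.json")

    stage("manifest")
    manifest = {
        "job_id": config.content_hash(),
        "phenotypes": list(seeds.phenotypes),
        "input_genes": sorted(seeds.genes),
        "dropped_gene_symbols": list(seeds.dropped),
        "databases": [spec.path for spec in config.edge_tables],
        "n_input_genes": len(seeds),
        "n_predicted_genes": len(predicted),
        "n_graph_genes": len(kg.genes),
        "n_graph_features": len(kg.feature_ids),
        "n_predictors": len(pipe.predictors_.features),
        "training_j": pipe.training_j_,
        "threshold": pipe.model_.threshold,
        "weights": {c: float(w) for c, w in pipe.model_.weights.items()},
        "fdr_q": config.fdr_q,
        "n_folds": config.n_folds,
        "cv_significant_folds": (
            cv_report.n_significant_folds if cv_report is not None else None
        ),
        "cv_passed": cv_report.passed if cv_report is not None else None,
        "rng_seed": config.rng_seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
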