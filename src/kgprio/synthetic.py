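"""Synthetic knowledge graphs with planted predictive structure.

The generator builds the simplest graph family on which the whole pipeline
is exercisable and analytically checkable: a fixed gene universe, a chosen
seed subset, and per feature class a handful of *planted* features that
connect to each seed gene with probability ``p_in`` and to each non-seed
gene with ``p_out``, alongside *decoy* features that connect to every gene
with ``p_out``. Setting ``p_in = p_out`` yields a signal-free null graph for
calibration experiments; ``p_in = 1, p_out = 0`` yields perfectly
informative features.

All edges are independent Bernoulli draws — there is no degree correlation,
term hierarchy or scale-free structure, so passing recovery tests here says
the machinery works, not that real GO/PPI topologies are this easy.

Defaults (200 genes, 20 seeds, 3 classes of 2 planted + 20 decoy features,
p_in = 0.8, p_out = 0.05) define the standard recovery benchmark used by the
test-suite and the acceptance script.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError
from .graph import KnowledgeGraph, SeedSet

_DEFAULT_CLASSES = {"GO": (2, 20), "PPI": (2, 20), "PATH": (2, 20)}


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 200
    n_seeds: int = 20
    #: class label -> (number of planted features, number of decoy features)
    classes: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_CLASSES)
    )
    p_in: float = 0.8
    p_out: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ConfigurationError(
                f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if not 0 < self.n_seeds < self.n_genes:
            raise ConfigurationError("need 0 < n_seeds < n_genes")
        for cls_label, (n_planted, n_decoy) in self.classes.items():
            if n_planted < 0 or n_decoy < 0 or (n_planted + n_decoy) == 0:
                raise ConfigurationError(f"class {cls_label!r} has no features")


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to verify recovery: the graph plus the ground truth."""

    kg: KnowledgeGraph
    seeds: SeedSet
    planted: frozenset[str]
    decoys: frozenset[str]
    config: SyntheticConfig
    disease: str = ""
    dg_old: tuple[tuple[str, str], ...] = ()  # pre-cutoff disease-gene pairs
    dg_new: tuple[tuple[str, str], ...] = ()  # post-cutoff additions

    def truth_json(self) -> str:
        return json.dumps(
            {
                "seeds": sorted(self.seeds.genes),
                "planted": sorted(self.planted),
                "decoys": sorted(self.decoys),
                "dg_old": [list(p) for p in self.dg_old],
                "dg_new": [list(p) for p in self.dg_new],
                "rng_seed": self.config.rng_seed,
            },
            indent=1,
        )

    def write_fixture(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the graph as per-class edge tables plus seed file and truth JSON.

        Files go through the same writers users consume, so fixtures double
        as format tests.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        edge_frame = self.kg.to_edge_table()
        classes = {self.kg.feature_class_of(t) for t in self.kg.feature_ids}
        for cls_label in sorted(classes):
            targets = self.kg.features_of_class(cls_label)
            sub = edge_frame[edge_frame["Target"].isin(targets)].copy()
            sub = sub.rename(columns={"Sources": "Source"})
            p = out_dir / f"edges_{cls_label}.csv"
            sub.to_csv(p, index=False)
            paths[cls_label] = p
        seed_path = out_dir / "seeds.txt"
        seed_path.write_text("\n".join(sorted(self.seeds.genes)) + "\n")
        paths["seeds"] = seed_path
        truth_path = out_dir / "truth.json"
        truth_path.write_text(self.truth_json())
        paths["truth"] = truth_path
        return paths


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_kg(config: SyntheticConfig) -> SyntheticTruth:
    """Generate a gene-feature graph with planted predictive features."""
    rng = np.random.default_rng(config.rng_seed)
    genes = _gene_names(config.n_genes)
    seed_idx = rng.choice(config.n_genes, size=config.n_seeds, replace=False)
    is_seed = np.zeros(config.n_genes, dtype=bool)
    is_seed[seed_idx] = True
    seed_genes = frozenset(genes[i] for i in np.flatnonzero(is_seed))

    kg = KnowledgeGraph()
    for g in genes:
        kg.add_gene(g)
    planted: set[str] = set()
    decoys: set[str] = set()
    for cls_label in sorted(config.classes):
        n_planted, n_decoy = config.classes[cls_label]
        for i in range(n_planted):
            feat = f"{cls_label}:PLT{i + 1:03d}"
            planted.add(feat)
            kg.add_feature(feat, cls_label)
            probs = np.where(is_seed, config.p_in, config.p_out)
            hits = rng.random(config.n_genes) < probs
            for j in np.flatnonzero(hits):
                kg.add_edge(genes[j], feat, "associated_with", "synthetic", cls_label)
        for i in range(n_decoy):
            feat = f"{cls_label}:DEC{i + 1:03d}"
            decoys.add(feat)
            kg.add_feature(feat, cls_label)
            hits = rng.random(config.n_genes) < config.p_out
            for j in np.flatnonzero(hits):
                kg.add_edge(genes[j], feat, "associated_with", "synthetic", cls_label)

    seeds = SeedSet((), seed_genes, "bare_list")
    return SyntheticTruth(
        kg=kg,
        seeds=seeds,
        planted=frozenset(planted),
        decoys=frozenset(decoys),
        config=config,
    )


def generate_temporal_split(
    config: SyntheticConfig,
    holdout_fraction: float = 0.5,
    disease: str = "SYNTHETIC_DISEASE",
    dg_class: str = "DG",
) -> SyntheticTruth:
    """Temporal analogue: split the true seed genes at a simulated cutoff.

    All true seeds receive planted-feature edges with ``p_in`` (so the
    post-cutoff genes stay discoverable), but only the pre-cutoff subset gets
    disease-gene edges in the emitted graph. The post-cutoff pairs are
    returned as the "newly associated" edge list.
    """
    if not 0 < holdout_fraction < 1:
        raise ConfigurationError("holdout_fraction must lie in (0, 1)")
    n_new = int(round(config.n_seeds * holdout_fraction))
    n_old = config.n_seeds - n_new
    if n_new == 0 or n_old == 0:
        raise ConfigurationError(
            f"holdout_fraction {holdout_fraction} leaves an empty split "
            f"for {config.n_seeds} seeds"
        )
    truth = generate_kg(config)
    rng = np.random.default_rng(config.rng_seed + 1)
    all_seeds = sorted(truth.seeds.genes)
    new_idx = set(rng.choice(len(all_seeds), size=n_new, replace=False).tolist())
    old_genes = [g for i, g in enumerate(all_seeds) if i not in new_idx]
    new_genes = [g for i, g in enumerate(all_seeds) if i in new_idx]

    kg = truth.kg
    for g in old_genes:
        kg.add_edge(g, disease, "associated_with", "synthetic_dg", dg_class)
    seeds = SeedSet((disease,), frozenset(old_genes), "database")
    return SyntheticTruth(
        kg=kg,
        seeds=seeds,
        planted=truth.planted,
        decoys=truth.decoys,
        config=config,
        disease=disease,
        dg_old=tuple((disease, g) for g in old_genes),
        dg_new=tuple((disease, g) for g in new_genes),
    )
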