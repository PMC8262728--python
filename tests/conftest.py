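import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles importable

from kgprio.graph import KnowledgeGraph, SeedSet
from kgprio.synthetic import SyntheticConfig, generate_kg


@pytest.fixture
def tiny_kg() -> KnowledgeGraph:
    """Hand-built 6-gene graph with two GO terms, one PPI partner, one disease.

    t1 touches exactly the two seed genes; t2 touches everything (useless);
    p1 links G1-G3 as interaction partners; disease D1 is linked to G1, G2.
    """
    kg = KnowledgeGraph()
    for g in ["G1", "G2", "G3", "G4", "G5", "G6"]:
        kg.add_gene(g)
    for g in ["G1", "G2"]:
        kg.add_edge(g, "t1", "annotated_with", "go_db", feature_class="GO")
    for g in ["G1", "G2", "G3", "G4", "G5", "G6"]:
        kg.add_edge(g, "t2", "annotated_with", "go_db", feature_class="GO")
    kg.add_edge("G1", "PPI:G3", "interacts_with", "ppi_db", feature_class="PPI")
    kg.add_edge("G3", "PPI:G1", "interacts_with", "ppi_db", feature_class="PPI")
    kg.add_edge("G1", "D1", "associated_with", "dg_db", feature_class="DG")
    kg.add_edge("G2", "D1", "associated_with", "dg_db", feature_class="DG")
    return kg


@pytest.fixture
def tiny_seeds() -> SeedSet:
    return SeedSet((), frozenset({"G1", "G2"}), "bare_list")


@pytest.fixture(scope="session")
def planted_truth():
    """Default planted-signal benchmark graph (200 genes, 20 seeds)."""
    return generate_kg(SyntheticConfig(rng_seed=42))


@pytest.fixture
def edge_csv(tmp_path) -> Path:
    path = tmp_path / "edges.csv"
    path.write_text(
        "Gene,Target\n"
        "BRCA1,GO:0006281\n"
        "TP53,GO:0006281\n"
    )
    return path
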