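"""Gene-set enrichment, explanation subgraphs, source contributions."""

import json
import math

import networkx as nx
import pandas as pd
import pytest

from kgprio.exceptions import DomainError, FormatError, NodeNotFoundError
from kgprio.interpretation import (
    GeneSetLibrary,
    explanation_subgraph,
    gene_set_enrichment,
    gene_source_shares,
    load_gmt,
    model_source_overview,
    source_contributions,
    write_gmt,
    write_subgraph_graphml,
    write_subgraph_json,
)
from kgprio.model import GenePrioritizer, TrainedModel, ScalingParams


class TestLoadGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "lib.gmt"
        p.write_text("S1\tdesc\tBRCA1\tTP53\n")
        lib = load_gmt(p)
        assert lib.sets["S1"] == {"BRCA1", "TP53"}

    def test_duplicates_and_case_normalized(self, tmp_path):
        p = tmp_path / "lib.gmt"
        p.write_text("S1\tdesc\tbrca1\tBRCA1\n")
        lib = load_gmt(p)
        assert lib.sets["S1"] == {"BRCA1"}

    def test_short_line_raises_with_line_number(self, tmp_path):
        p = tmp_path / "lib.gmt"
        p.write_text("S1\tdesc\tBRCA1\nBAD\tdesc\n")
        with pytest.raises(FormatError, match=":2"):
            load_gmt(p)

    def test_empty_file_gives_empty_library(self, tmp_path):
        p = tmp_path / "lib.gmt"
        p.write_text("")
        assert len(load_gmt(p)) == 0

    def test_round_trip(self, tmp_path):
        lib = GeneSetLibrary("L", {"S1": frozenset({"A1", "B2"})})
        path = tmp_path / "out.gmt"
        write_gmt(lib, path)
        assert load_gmt(path, name="L").sets == lib.sets


class TestGeneSetEnrichment:
    @pytest.fixture
    def universe(self):
        return [f"G{i:03d}" for i in range(100)]

    def test_identical_list_is_top_row(self, universe):
        lib = GeneSetLibrary(
            "L",
            {
                "match": frozenset(universe[:5]),
                "other": frozenset(universe[50:60]),
            },
        )
        # library coverage = 15 genes, so the background is those 15
        rows = gene_set_enrichment({"known": universe[:5]}, lib, universe)
        top = rows.iloc[0]
        assert top["set"] == "match"
        # k=n=K=5 within N=15: p = 1/C(15,5)
        assert top["p"] == pytest.approx(1 / math.comb(15, 5), rel=1e-9)

    def test_disjoint_set_gets_p_one(self, universe):
        lib = GeneSetLibrary(
            "L",
            {
                "miss": frozenset(universe[50:55]),
                "hit": frozenset(universe[:5]),
            },
        )
        rows = gene_set_enrichment({"known": universe[:5]}, lib, universe)
        assert rows.loc[rows["set"] == "miss", "p"].iloc[0] == 1.0

    def test_union_list_is_set_union_not_row_sum(self, universe):
        lib = GeneSetLibrary("L", {"S": frozenset(universe[:10])})
        known = universe[:5]
        predicted = universe[3:8]  # overlaps known
        rows = gene_set_enrichment(
            {
                "known": known,
                "predicted": predicted,
                "union": set(known) | set(predicted),
            },
            lib,
            universe,
        )
        by_list = rows.set_index("gene_list")
        assert by_list.loc["union", "n"] == 8  # 5 + 5 - 2 overlap
        assert by_list.loc["union", "k"] >= max(
            by_list.loc["known", "k"], by_list.loc["predicted", "k"]
        )

    def test_no_library_overlap_yields_no_rows(self, universe):
        lib = GeneSetLibrary("L", {"S": frozenset({"NOTINUNIVERSE"})})
        rows = gene_set_enrichment({"known": universe[:5]}, lib, universe)
        assert rows.empty


@pytest.fixture
def fitted(planted_truth):
    pipe = GenePrioritizer().fit(planted_truth.kg, planted_truth.seeds)
    return planted_truth, pipe


class TestExplanationSubgraph:
    def test_two_hop_structure_and_induced_edges(self, fitted):
        truth, pipe = fitted
        table = pipe.predict_table()
        focus = table.iloc[0]["gene"]
        sub = explanation_subgraph(truth.kg, pipe.model_, focus, truth.seeds)
        assert focus in sub
        for u, v in sub.edges():
            gene, feat = (u, v) if sub.nodes[u]["kind"] == "gene" else (v, u)
            assert feat in truth.kg.neighbors(gene)
        # every included feature is a predictor adjacent to the focus gene
        predictors = pipe.predictors_.features
        for node, data in sub.nodes(data=True):
            if data["kind"] == "feature":
                assert node in predictors
                assert node in truth.kg.neighbors(focus)

    def test_gene_without_predictor_neighbors_gives_singleton(self, fitted):
        truth, pipe = fitted
        matrix = pipe.matrix_
        lonely = matrix[(matrix == 0).all(axis=1)].index
        if len(lonely) == 0:
            pytest.skip("every gene touches a predictor in this replicate")
        sub = explanation_subgraph(truth.kg, pipe.model_, lonely[0], truth.seeds)
        assert sub.number_of_nodes() == 1
        assert sub.number_of_edges() == 0

    def test_seed_focus_uses_same_rule(self, fitted):
        truth, pipe = fitted
        focus = sorted(truth.seeds.genes)[0]
        sub = explanation_subgraph(truth.kg, pipe.model_, focus, truth.seeds)
        assert sub.nodes[focus]["seed"]

    def test_unknown_gene_raises(self, fitted):
        truth, pipe = fitted
        with pytest.raises(NodeNotFoundError):
            explanation_subgraph(truth.kg, pipe.model_, "NOPE", truth.seeds)

    def test_exports_parse_with_standard_readers(self, fitted, tmp_path):
        truth, pipe = fitted
        focus = sorted(truth.seeds.genes)[0]
        sub = explanation_subgraph(truth.kg, pipe.model_, focus, truth.seeds)
        gpath = tmp_path / "sub.graphml"
        jpath = tmp_path / "sub.json"
        write_subgraph_graphml(sub, gpath)
        write_subgraph_json(sub, jpath)
        back = nx.read_graphml(gpath)
        assert set(back.nodes) == set(sub.nodes)
        data = json.loads(jpath.read_text())
        assert {n["id"] for n in data["nodes"]} == set(sub.nodes)


class TestSourceContributions:
    @pytest.fixture
    def model(self):
        return TrainedModel(
            weights=pd.Series({"GO": 0.5, "PPI": 0.5}),
            threshold=0.5,
            training_j=1.0,
            scaling=ScalingParams(
                pd.Series({"GO": 0.0, "PPI": 0.0}), pd.Series({"GO": 1.0, "PPI": 1.0})
            ),
        )

    def test_class_fractions(self, model):
        c = source_contributions(model, {"GO": 1.0, "PPI": 0.2})
        assert c.by_class["GO"] == pytest.approx(5 / 6)
        assert c.by_class["PPI"] == pytest.approx(1 / 6)

    def test_zero_score_flagged(self, model):
        c = source_contributions(model, {"GO": 0.0, "PPI": 0.0})
        assert c.zero_score
        assert all(v == 0 for v in c.by_class.values())

    def test_source_split_proportional_to_shares(self, model):
        c = source_contributions(
            model,
            {"GO": 1.0, "PPI": 0.2},
            {"GO": {"go_db": 3.0, "text": 1.0}, "PPI": {"intact": 1.0}},
        )
        assert c.by_source["go_db"] == pytest.approx(5 / 6 * 0.75)
        assert c.by_source["intact"] == pytest.approx(1 / 6)
        assert sum(c.by_source.values()) == pytest.approx(1.0)

    def test_invariant_to_uniform_weight_rescaling(self, model):
        # contributions depend on w_c * x_c ratios only
        row = {"GO": 0.7, "PPI": 0.4}
        c1 = source_contributions(model, row)
        half = TrainedModel(
            weights=pd.Series({"GO": 0.5, "PPI": 0.5}),
            threshold=0.25,
            training_j=1.0,
            scaling=model.scaling,
        )
        c2 = source_contributions(half, row)
        for cls in c1.by_class:
            assert c1.by_class[cls] == pytest.approx(c2.by_class[cls])


class TestModelSourceOverview:
    def test_single_source_graph_gives_fraction_one(self, fitted):
        truth, pipe = fitted
        overview = model_source_overview(pipe.predictors_, truth.kg)
        assert overview == {"synthetic": pytest.approx(1.0)}

    def test_fractions_sum_to_one(self, tiny_kg, tiny_seeds):
        from kgprio.enrichment import find_predictors

        pset = find_predictors(tiny_kg, tiny_seeds, q_threshold=0.25,
                               exclude_features={"D1"})
        overview = model_source_overview(pset, tiny_kg)
        assert sum(overview.values()) == pytest.approx(1.0)

    def test_empty_predictor_set_raises(self, tiny_kg):
        from kgprio.enrichment import PredictorSet

        empty = PredictorSet(tests=(), q_threshold=0.05, predictors_by_class={})
        with pytest.raises(DomainError):
            model_source_overview(empty, tiny_kg)

    def test_gene_level_shares_count_supporting_edges(self, fitted):
        truth, pipe = fitted
        gene = sorted(truth.seeds.genes)[0]
        shares = gene_source_shares(truth.kg, pipe.predictors_, gene)
        for cls, by_src in shares.items():
            assert set(by_src) == {"synthetic"}
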