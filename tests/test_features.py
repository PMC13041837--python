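import numpy as np
import pandas as pd
import pytest

from conftest import make_kg, oracle_path_features, random_kg
from perturbgraph.features import (
    FeaturesConfig,
    MinMaxScaler,
    NodeFeatureVector,
    aggregate_targets,
    all_ngrams,
    assemble_matrix,
    best_path_confidence,
    enumerate_paths,
    evidence_ngram,
    max_inverse_degree_product,
    ngram_count_features,
    node_features,
    similarity_features,
    topology_features,
)
from perturbgraph.go_embed import GoEmbedding
from perturbgraph.kgraph import GeneAttributes, Phenotype


def empty_embedding(dim=4):
    return GoEmbedding(vectors={}, dim=dim)


class TestNodeFeatures:
    def test_unannotated_gene_all_zero(self, triangle_kg):
        v = node_features(triangle_kg, "g", empty_embedding())
        assert not v.abundance.any() and not v.measured.any()
        assert not v.localization.any() and not v.go.any()
        assert v.go_present == 0
        assert v.concat().shape == (3 + 3 + 41 + 4 + 1,)

    def test_ancestor_closure_sets_parent_bit(self, triangle_kg):
        tax = triangle_kg.taxonomy
        triangle_kg.set_attrs(
            "g", GeneAttributes(localizations=tax.closure({"mitochondrial_matrix"}))
        )
        v = node_features(triangle_kg, "g", empty_embedding())
        assert v.localization[tax.index("mitochondrial_matrix")] == 1
        assert v.localization[tax.index("mitochondrion")] == 1
        assert v.localization.sum() == 2

    def test_missing_abundance_measured_bits(self, triangle_kg):
        triangle_kg.set_attrs("g", GeneAttributes(rna_cell_line=5.0, protein_cell_type=2.0))
        v = node_features(triangle_kg, "g", empty_embedding(), FeaturesConfig(log_abundance=False))
        assert v.abundance == pytest.approx([5.0, 0.0, 2.0])
        assert list(v.measured) == [1.0, 0.0, 1.0]
        vlog = node_features(triangle_kg, "g", empty_embedding())
        assert vlog.abundance[0] == pytest.approx(np.log1p(5.0))


def nfv(ab=(0, 0, 0), loc=None, go=(0, 0), present=0.0):
    loc_arr = np.zeros(41)
    for i in loc or []:
        loc_arr[i] = 1.0
    return NodeFeatureVector(
        abundance=np.array(ab, dtype=float),
        measured=(np.array(ab, dtype=float) > 0).astype(float),
        localization=loc_arr,
        go=np.array(go, dtype=float),
        go_present=present,
    )


class TestAggregate:
    def test_single_target_identity(self):
        v = nfv(ab=(1, 2, 3), loc=[0, 5], go=(2, 4), present=1.0)
        agg = aggregate_targets([v])
        assert np.array_equal(agg.concat(), v.concat())

    def test_or_and_mean_blocks(self):
        a = nfv(loc=[0], go=(2, 4), present=1.0)
        b = nfv(loc=[1], go=(4, 8), present=0.0)
        agg = aggregate_targets([a, b])
        assert agg.localization[0] == 1 and agg.localization[1] == 1
        assert agg.go == pytest.approx([3, 6])
        assert agg.go_present == 1.0

    def test_permutation_invariant(self):
        vecs = [nfv(ab=(i, 0, 1), loc=[i], go=(i, -i), present=i % 2) for i in range(4)]
        fwd = aggregate_targets(vecs).concat()
        rev = aggregate_targets(vecs[::-1]).concat()
        assert np.array_equal(fwd, rev)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_targets([])


class TestPaths:
    def test_triangle_enumeration(self, triangle_kg):
        paths = set(enumerate_paths(triangle_kg, "g", "v", max_len=2))
        assert paths == {("g", "v"), ("g", "u", "v")}

    def test_disconnected_empty(self):
        kg = make_kg([("a", "b", {"E"}, 0.5)])
        kg.add_gene("z")
        assert enumerate_paths(kg, "a", "z", 3) == []

    def test_evidence_ngram_worked_example(self):
        # strongest channels along the path: experimental, database, experimental
        kg = make_kg(
            [
                ("a", "b", {"E", "T"}, 0.9),
                ("b", "c", {"D", "T"}, 0.9),
                ("c", "d", {"E"}, 0.9),
            ]
        )
        assert evidence_ngram(("a", "b", "c", "d"), kg) == "EDE"
        assert evidence_ngram(("b", "c"), kg) == "D"
        with pytest.raises(ValueError):
            evidence_ngram(("a", "c"), kg)

    def test_triangle_ngram_counts(self, triangle_kg):
        counts = ngram_count_features(triangle_kg, "g", {"v"}, max_len=2)
        nonzero = {k: v for k, v in counts.items() if v}
        assert nonzero == {"D": 1, "ET": 1}

    def test_two_direct_targets_summed(self):
        kg = make_kg([("s", "t1", {"E"}, 0.9), ("s", "t2", {"E", "D"}, 0.8)])
        counts = ngram_count_features(kg, "s", {"t1", "t2"}, max_len=2)
        assert counts["E"] == 2

    def test_best_path_confidence(self, triangle_kg):
        # direct edge 0.5 vs two-hop 0.9 * 0.9 = 0.81
        assert best_path_confidence(triangle_kg, "g", {"v"}, 2) == pytest.approx(0.81)
        kg = make_kg([("a", "b", {"E"}, 0.9), ("b", "c", {"E"}, 0.8)])
        assert best_path_confidence(kg, "a", {"c"}, 3) == pytest.approx(0.72)
        kg.add_gene("z")
        assert best_path_confidence(kg, "a", {"z"}, 3) == 0.0

    def test_max_inverse_degree_product(self):
        kg = make_kg(
            [("g", "u", {"E"}, 0.9), ("u", "v", {"E"}, 0.9), ("v", "x", {"E"}, 0.9)]
        )
        # path (g,u,v): degree(u)=2, degree(v)=2 -> 1/4
        assert max_inverse_degree_product(kg, "g", {"v"}, 2) == pytest.approx(1 / 4)
        # direct edge to a degree-1 target
        kg2 = make_kg([("g", "leaf", {"E"}, 0.9)])
        assert max_inverse_degree_product(kg2, "g", {"leaf"}, 3) == 1.0

    def test_topology_features(self, triangle_kg):
        thermo, count, exists = topology_features(triangle_kg, "g", {"v"}, 3)
        assert list(thermo) == [1, 1, 1] and count == 2 and exists == 1
        kg = make_kg([("a", "m", {"E"}, 0.9), ("m", "b", {"E"}, 0.9)])
        thermo, count, exists = topology_features(kg, "a", {"b"}, 3)
        assert list(thermo) == [0, 1, 1]  # shortest length 2
        kg.add_gene("z")
        thermo, count, exists = topology_features(kg, "a", {"z"}, 3)
        assert list(thermo) == [0, 0, 0] and count == 0 and exists == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_path_features_match_dfs_oracle(self, seed):
        kg = random_kg(seed, n=10, p=0.35)
        nodes = kg.nodes
        source, targets = nodes[0], set(nodes[1:3])
        oracle = oracle_path_features(kg, source, targets, max_len=3)
        assert sorted(
            p for t in sorted(targets) for p in enumerate_paths(kg, source, t, 3)
        ) == oracle["paths"]
        counts = ngram_count_features(kg, source, targets, 3)
        assert {k: v for k, v in counts.items() if v} == oracle["ngrams"]
        assert best_path_confidence(kg, source, targets, 3) == pytest.approx(oracle["best_conf"])
        assert max_inverse_degree_product(kg, source, targets, 3) == pytest.approx(
            oracle["best_invdeg"]
        )
        thermo, count, exists = topology_features(kg, source, targets, 3)
        assert count == oracle["count"]
        if oracle["shortest"] is not None:
            assert list(thermo) == [int(oracle["shortest"] <= i) for i in (1, 2, 3)]


class TestSimilarity:
    def test_identical_vectors(self):
        v = nfv(ab=(1, 2, 3), loc=[0, 4], go=(1, 2), present=1)
        loc_cos, go_cos, diff, absdiff = similarity_features(v, [v])
        assert loc_cos == pytest.approx(1.0) and go_cos == pytest.approx(1.0)
        assert diff == pytest.approx([0, 0, 0]) and absdiff == pytest.approx([0, 0, 0])

    def test_orthogonal_localization(self):
        a, b = nfv(loc=[0]), nfv(loc=[1])
        loc_cos, _, _, _ = similarity_features(a, [b])
        assert loc_cos == 0.0

    def test_zero_norm_cosine_zero(self):
        a, b = nfv(go=(1, 0)), nfv(go=(0, 0))
        _, go_cos, _, _ = similarity_features(a, [b])
        assert go_cos == 0.0

    def test_aggregation_max_vs_mean(self):
        src = nfv(go=(1, 0))
        t1 = nfv(go=(0.2, np.sqrt(1 - 0.04)))  # cos = 0.2
        t2 = nfv(go=(0.8, 0.6))  # cos = 0.8
        _, mx, _, _ = similarity_features(src, [t1, t2], agg="max")
        _, mean, _, _ = similarity_features(src, [t1, t2], agg="mean")
        assert mx == pytest.approx(0.8)
        assert mean == pytest.approx(0.5)


class TestScaler:
    def test_minmax_fit_transform(self):
        df = pd.DataFrame({"x": [0.0, 5.0, 10.0]})
        assert MinMaxScaler().fit_transform(df)["x"].tolist() == [0.0, 0.5, 1.0]

    def test_test_values_clipped(self):
        sc = MinMaxScaler().fit(pd.DataFrame({"x": [0.0, 10.0]}))
        out = sc.transform(pd.DataFrame({"x": [-5.0, 15.0, 5.0]}))
        assert out["x"].tolist() == [0.0, 1.0, 0.5]

    def test_constant_column_zero(self):
        sc = MinMaxScaler().fit(pd.DataFrame({"x": [3.0, 3.0]}))
        assert sc.transform(pd.DataFrame({"x": [3.0, 7.0]}))["x"].tolist() == [0.0, 0.0]


class TestAssemble:
    def _world(self):
        kg = make_kg(
            [
                ("s1", "t", {"E"}, 0.9),
                ("s2", "m", {"D"}, 0.8),
                ("m", "t", {"T"}, 0.7),
                ("s1", "s2", {"E", "D"}, 0.6),
            ]
        )
        emb = GoEmbedding(vectors={"t": np.array([1.0, 0.5]), "s1": np.array([0.5, 1.0])}, dim=2)
        ph = Phenotype(name="p", targets=frozenset({"t"}))
        table = pd.DataFrame(
            {
                "source": ["s1", "s2", "m", "t"],
                "phenotype": "p",
                "target": None,
                "label": [1, 0, 0, 1],
                "fold": [1, 2, 1, -1],
                "is_target_instance": [0, 0, 0, 1],
            }
        )
        return kg, ph, table, emb

    def test_layout_is_config_pure(self):
        kg, ph, table, emb = self._world()
        fm1 = assemble_matrix(kg, ph, table, emb)
        ph2 = Phenotype(name="other", targets=frozenset({"m"}))
        fm2 = assemble_matrix(kg, ph2, table, emb)
        assert list(fm1.X.columns) == list(fm2.X.columns)
        assert fm1.subgraph_tags == fm2.subgraph_tags
        ngrams = len(all_ngrams(3))
        assert ngrams == 39
        assert fm1.X.shape[1] == 2 * (3 + 3 + 41 + 2 + 1) + ngrams + 1 + 3 + 2 + 1 + 3 + 2 + 6

    def test_row_order_permutation_invariant(self):
        kg, ph, table, emb = self._world()
        fm = assemble_matrix(kg, ph, table, emb)
        shuf = table.iloc[[2, 0, 3, 1]].reset_index(drop=True)
        fm2 = assemble_matrix(kg, ph, shuf, emb)
        for i, row in enumerate([2, 0, 3, 1]):
            assert np.array_equal(fm2.X.iloc[i].values, fm.X.iloc[row].values)

    def test_source_is_sole_target_identity_convention(self):
        kg, ph, table, emb = self._world()
        fm = assemble_matrix(kg, ph, table, emb)
        row = fm.X.iloc[3]  # source 't', the sole target
        assert row["rel_path_exists"] == 1
        assert row["rel_best_path_confidence"] == 1
        assert row["rel_max_inv_degree_product"] == 1
        assert [row[f"rel_sp_le_{i}"] for i in (1, 2, 3)] == [1, 1, 1]
        assert row["rel_loc_cos"] == 1 and row["rel_go_cos"] == 1

    def test_rwr_features_use_target_seeding(self):
        kg, ph, table, emb = self._world()
        fm = assemble_matrix(kg, ph, table, emb)
        from perturbgraph import diffusion

        seed = diffusion.make_seed(kg, ph.targets, mode="target")
        for a in (0.2, 0.4, 0.6):
            expected = diffusion.rwr_scores(kg, seed, a)
            for i, src in enumerate(table["source"]):
                assert fm.X.iloc[i][f"rel_rwr_a{a}"] == pytest.approx(expected.score_of(src))

    def test_unknown_source_errors(self):
        kg, ph, table, emb = self._world()
        bad = table.copy()
        bad.loc[0, "source"] = "ghost"
        with pytest.raises(KeyError):
            assemble_matrix(kg, ph, bad, emb)
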