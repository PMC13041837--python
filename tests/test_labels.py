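import numpy as np
import pandas as pd
import pytest

from conftest import make_kg
from perturbgraph import labels as lab
from perturbgraph.kgraph import Phenotype


def kg_with(genes):
    kg = make_kg([])
    for g in genes:
        kg.add_gene(g)
    return kg


def records(rows, cols=("gene", "screen_id", "stat")):
    df = pd.DataFrame(rows, columns=list(cols))
    df["stat_kind"] = "fdr"
    return df


PH = Phenotype(name="p", targets=frozenset({"tgt"}))


class TestPoolLabels:
    def test_positive_in_any_screen(self):
        kg = kg_with(["a", "b", "tgt"])
        recs = records([("a", "s1", 0.05), ("a", "s2", 0.5), ("b", "s1", 0.4)])
        t = lab.pool_labels(recs, kg, PH)
        assert dict(zip(t["source"], t["label"])) == {"a": 1, "b": 0}

    def test_boundary_is_strict(self):
        kg = kg_with(["a"])
        t = lab.pool_labels(records([("a", "s1", 0.1)]), kg, PH)
        assert t["label"].tolist() == [0]
        t = lab.pool_labels(records([("a", "s1", 0.0999)]), kg, PH)
        assert t["label"].tolist() == [1]

    def test_genes_outside_graph_excluded(self):
        kg = kg_with(["a"])
        t = lab.pool_labels(records([("a", "s1", 0.5), ("zz", "s1", 0.01)]), kg, PH)
        assert t["source"].tolist() == ["a"]

    def test_monotone_in_threshold(self):
        kg = kg_with([f"g{i}" for i in range(20)])
        rng = np.random.default_rng(0)
        recs = records([(f"g{i}", "s1", round(rng.uniform(), 3)) for i in range(20)])
        prev_pos = set()
        for thr in (0.05, 0.1, 0.3, 0.8):
            t = lab.pool_labels(recs, kg, PH, pos_threshold=thr)
            pos = set(t.loc[t["label"] == 1, "source"])
            assert prev_pos <= pos
            prev_pos = pos

    def test_invalid_stat_errors(self):
        with pytest.raises(ValueError):
            lab.pool_labels(records([("a", "s1", 1.2)]), kg_with(["a"]), PH)

    def test_conflicting_stat_kinds_error(self):
        recs = pd.DataFrame(
            {"gene": ["a", "a"], "screen_id": ["s1", "s2"], "stat": [0.1, 0.2],
             "stat_kind": ["fdr", "qvalue"]}
        )
        with pytest.raises(ValueError, match="conflicting"):
            lab.pool_labels(recs, kg_with(["a"]), PH)


class TestPerTargetLabels:
    def test_full_grid_count(self):
        sources = [f"s{i:03d}" for i in range(115)]
        targets = [f"t{j:02d}" for j in range(57)]
        kg = kg_with(sources)
        rows = [(s, "s1", 0.5, t) for s in sources for t in targets]
        recs = pd.DataFrame(rows, columns=["gene", "screen_id", "stat", "target"])
        recs["stat_kind"] = "qvalue"
        t = lab.per_target_labels(recs, kg, PH)
        assert len(t) == 6555

    def test_q_threshold_strict(self):
        kg = kg_with(["a"])
        recs = pd.DataFrame(
            {"gene": ["a", "a"], "screen_id": "s1", "stat": [0.01, 0.05],
             "target": ["t1", "t2"], "stat_kind": "qvalue"}
        )
        t = lab.per_target_labels(recs, kg, PH)
        assert dict(zip(t["target"], t["label"])) == {"t1": 1, "t2": 0}

    def test_duplicate_pair_errors(self):
        kg = kg_with(["a"])
        recs = pd.DataFrame(
            {"gene": ["a", "a"], "screen_id": "s1", "stat": [0.01, 0.02],
             "target": ["t1", "t1"], "stat_kind": "qvalue"}
        )
        with pytest.raises(ValueError, match="duplicate"):
            lab.per_target_labels(recs, kg, PH)

    def test_empty_records(self):
        recs = pd.DataFrame(columns=["gene", "screen_id", "stat", "target", "stat_kind"])
        assert len(lab.per_target_labels(recs, kg_with(["a"]), PH)) == 0


class TestStringentNegatives:
    def test_three_way_split(self):
        kg = kg_with(["a", "b", "c"])
        recs = records([("a", "s1", 0.05), ("b", "s1", 0.5), ("c", "s1", 0.95)])
        t = lab.stringent_negatives(recs, kg, PH, mode="fdr_high")
        assert dict(zip(t["source"], t["label"])) == {"a": 1, "c": 0}

    def test_round_dropout(self):
        kg = kg_with(["a", "b", "c"])
        recs = pd.DataFrame(
            {
                "gene": ["a", "a", "b", "c", "c"],
                "screen_id": "s1",
                "stat": [0.05, 0.06, 0.5, 0.5, 0.6],
                "round": [1, 2, 1, 1, 2],
                "stat_kind": "fdr",
            }
        )
        t = lab.stringent_negatives(recs, kg, PH, mode="round_dropout")
        # a: positive in both rounds; b: round-1 only -> negative; c: middle, dropped
        assert dict(zip(t["source"], t["label"])) == {"a": 1, "b": 0}

    def test_round_dropout_without_rounds_errors(self):
        with pytest.raises(ValueError, match="round"):
            lab.stringent_negatives(
                records([("a", "s1", 0.5)]), kg_with(["a"]), PH, mode="round_dropout"
            )

    def test_all_middle_leaves_only_positives(self):
        kg = kg_with(["a", "b"])
        recs = records([("a", "s1", 0.01), ("b", "s1", 0.5)])
        t = lab.stringent_negatives(recs, kg, PH, mode="fdr_high")
        assert t["label"].tolist() == [1]

    def test_positives_subset_of_pooled(self):
        kg = kg_with([f"g{i}" for i in range(30)])
        rng = np.random.default_rng(1)
        recs = records([(f"g{i}", "s1", round(rng.uniform(), 4)) for i in range(30)])
        pooled = lab.pool_labels(recs, kg, PH)
        strict = lab.stringent_negatives(recs, kg, PH)
        pooled_pos = set(pooled.loc[pooled["label"] == 1, "source"])
        strict_pos = set(strict.loc[strict["label"] == 1, "source"])
        assert strict_pos <= pooled_pos


class TestTargetInstances:
    def _table(self, sources, labels):
        return pd.DataFrame(
            {
                "source": sources,
                "phenotype": "p",
                "target": None,
                "label": labels,
                "fold": np.nan,
                "is_target_instance": 0,
            }
        )

    def test_single_target_appends_one(self):
        t = lab.add_target_instances(self._table(["a"], [0]), PH)
        assert len(t) == 2
        added = t.iloc[-1]
        assert added["source"] == "tgt" and added["label"] == 1
        assert added["is_target_instance"] == 1 and added["fold"] == lab.TRAIN_ONLY_FOLD

    def test_eight_targets_append_eight(self):
        ph = Phenotype(name="flu", targets=frozenset(f"h{i}" for i in range(8)))
        t = lab.add_target_instances(self._table(["a"], [0]), ph)
        assert (t["is_target_instance"] == 1).sum() == 8

    def test_screened_positive_target_not_duplicated(self):
        t = lab.add_target_instances(self._table(["tgt", "a"], [1, 0]), PH)
        assert len(t) == 2
        assert (t["source"] == "tgt").sum() == 1


class TestFolds:
    def _table(self, n_pos, n_neg):
        n = n_pos + n_neg
        return pd.DataFrame(
            {
                "source": [f"g{i}" for i in range(n)],
                "phenotype": "p",
                "target": None,
                "label": [1] * n_pos + [0] * n_neg,
                "fold": np.nan,
                "is_target_instance": 0,
            }
        )

    def test_stratified_balance(self):
        t = lab.make_folds(self._table(10, 90), "stratified", 5, seed=0)
        per_fold = t.groupby("fold")["label"].agg(["sum", "count"])
        assert set(per_fold["sum"]) == {2}
        assert set(per_fold["count"]) == {20}

    def test_stratified_uneven_positives_differ_by_at_most_one(self):
        t = lab.make_folds(self._table(13, 80), "stratified", 5, seed=0)
        pos = t.groupby("fold")["label"].sum()
        assert pos.max() - pos.min() <= 1

    def test_by_source_keeps_sources_together(self):
        rows = []
        for i in range(115):
            for j in range(3):
                rows.append((f"s{i:03d}", 0))
        t = pd.DataFrame(rows, columns=["source", "label"])
        t["phenotype"], t["target"], t["fold"], t["is_target_instance"] = "p", None, np.nan, 0
        t = lab.make_folds(t, "by_source", 5, seed=3)
        per_source = t.groupby("source")["fold"].nunique()
        assert (per_source == 1).all()
        sources_per_fold = t.groupby("fold")["source"].nunique()
        assert set(sources_per_fold) == {23}

    def test_seed_determinism(self):
        t1 = lab.make_folds(self._table(10, 40), "stratified", 5, seed=11)
        t2 = lab.make_folds(self._table(10, 40), "stratified", 5, seed=11)
        assert t1["fold"].tolist() == t2["fold"].tolist()

    def test_folds_partition_rows(self):
        t = lab.make_folds(self._table(7, 33), "stratified", 4, seed=2)
        assert set(t["fold"]) == {1, 2, 3, 4}
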