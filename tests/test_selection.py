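import numpy as np
import pytest

from radiomap.feature_table import FeatureTable, LabelVector, enumerate_catalog
from radiomap.selection import (
    ImportanceRanking,
    SelectedFeatures,
    group_composition,
    rf_importance,
    select_top_k,
)
from radiomap.split import CohortSplit


def _cohort_with_one_separator(seed, n=200, p=50):
    """Feature 0 separates the classes perfectly; the rest is noise."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = rng.standard_normal((n, p))
    x[:, 0] = y * 4.0 + rng.normal(0, 0.1, n)
    catalog = enumerate_catalog()[:p]
    ids = [f"P{i}" for i in range(n)]
    return FeatureTable(ids, catalog, x), LabelVector(ids, y)


class TestRfImportance:
    def test_separating_feature_wins_rank_zero_across_seeds(self):
        hits = 0
        for seed in range(20):
            table, labels = _cohort_with_one_separator(seed)
            ranking = rf_importance(table, labels, n_trees=100, seed=seed)
            hits += ranking.ranked_names()[0] == table.feature_names[0]
        assert hits >= 19

    def test_scores_sum_to_one(self):
        table, labels = _cohort_with_one_separator(1)
        ranking = rf_importance(table, labels, n_trees=50, seed=0)
        assert abs(ranking.scores.sum() - 1.0) < 1e-9

    def test_permuted_labels_dethrone_the_separator(self):
        dethroned = 0
        for rep in range(20):
            table, labels = _cohort_with_one_separator(0)
            rng = np.random.default_rng(100 + rep)
            perm = LabelVector(labels.patient_ids, rng.permutation(labels.labels))
            ranking = rf_importance(table, perm, n_trees=100, seed=rep)
            dethroned += ranking.ranked_names()[0] != table.feature_names[0]
        assert dethroned > 10

    def test_deterministic_given_seed(self):
        table, labels = _cohort_with_one_separator(2)
        r1 = rf_importance(table, labels, n_trees=60, seed=9)
        r2 = rf_importance(table, labels, n_trees=60, seed=9)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        np.testing.assert_array_equal(r1.order, r2.order)

    def test_split_restricts_fit_to_development_rows(self):
        table, labels = _cohort_with_one_separator(3)
        dev, test = tuple(table.patient_ids[:150]), tuple(table.patient_ids[150:])
        split = CohortSplit(dev, test)
        via_split = rf_importance(table, labels, split=split, n_trees=60, seed=1)
        manual = rf_importance(
            table.subset_patients(list(dev)), labels.subset(list(dev)),
            n_trees=60, seed=1,
        )
        np.testing.assert_array_equal(via_split.scores, manual.scores)

    def test_single_class_and_bad_tree_count_rejected(self):
        table, labels = _cohort_with_one_separator(4)
        ones = LabelVector(labels.patient_ids, np.ones(len(labels.patient_ids), dtype=int))
        with pytest.raises(ValueError):
            rf_importance(table, ones, n_trees=10, seed=0)
        with pytest.raises(ValueError):
            rf_importance(table, labels, n_trees=0, seed=0)

    def test_power_increases_with_effect_size(self):
        from radiomap.synthetic import SimConfig, informative_indices, simulate_cohort

        recalls = []
        for d in (0.0, 0.5, 1.5):
            hits = total = 0
            for rep in range(20):
                cfg = SimConfig(n_patients=150, n_features=60, n_informative=3,
                                effect_size=d, seed=1000 + rep)
                table, labels, _ = simulate_cohort(cfg)
                ranking = rf_importance(table, labels, n_trees=60, seed=rep)
                top = set(select_top_k(ranking, 10).names)
                info = {table.feature_names[i] for i in informative_indices(cfg)}
                hits += len(top & info)
                total += len(info)
            recalls.append(hits / total)
        assert recalls[0] < recalls[2]
        assert recalls[1] <= recalls[2] + 0.05


class TestRankingOrder:
    def test_ties_break_by_ascending_name(self):
        ranking = ImportanceRanking.from_scores(
            ["b_feat", "a_feat", "c_feat"], np.array([0.4, 0.4, 0.2])
        )
        assert ranking.ranked_names() == ["a_feat", "b_feat", "c_feat"]

    def test_column_permutation_permutes_ranking_identically(self):
        names = [f"f{i}" for i in range(10)]
        scores = np.linspace(1, 2, 10)
        base = ImportanceRanking.from_scores(names, scores)
        perm = np.random.default_rng(0).permutation(10)
        permuted = ImportanceRanking.from_scores(
            [names[i] for i in perm], scores[perm]
        )
        assert base.ranked_names() == permuted.ranked_names()

    def test_select_top_k_identity_and_range(self):
        ranking = ImportanceRanking.from_scores(["a", "b", "c"], np.array([1.0, 2.0, 3.0]))
        assert list(select_top_k(ranking, 3).names) == ranking.ranked_names()
        assert select_top_k(ranking, 2).k == 2
        for bad in (0, 4):
            with pytest.raises(ValueError):
                select_top_k(ranking, bad)

    def test_784_of_1000_selection_count(self):
        names = [d.name for d in enumerate_catalog()[:1000]]
        scores = np.random.default_rng(1).random(1000)
        ranking = ImportanceRanking.from_scores(names, scores)
        assert select_top_k(ranking, 784).k == 784


class TestGroupComposition:
    def test_all_firstorder_selection(self):
        names = tuple(f"original_firstorder_M{i}" for i in range(5))
        df = group_composition(SelectedFeatures(names))
        grp = df[df["kind"] == "group"]
        assert grp["category"].tolist() == ["firstorder"]
        assert grp["count"].tolist() == [5]
        assert grp["percent"].tolist() == [100.0]

    def test_counts_partition_k_and_percentages_sum_to_100(self):
        names = tuple(d.name for d in enumerate_catalog()[:200])
        df = group_composition(SelectedFeatures(names))
        for kind in ("group", "channel"):
            sub = df[df["kind"] == kind]
            assert sub["count"].sum() == 200
            assert abs(sub["percent"].sum() - 100.0) < 0.1

    def test_planted_composition_is_reported_exactly(self):
        names = (
            "original_shape_Sphericity",
            "wavelet-HLL_glcm_MaximumProbability",
            "wavelet-HLL_glcm_Id",
            "log-sigma-2_glszm_ZoneEntropy",
        )
        df = group_composition(SelectedFeatures(names))
        grp = dict(zip(*df[df["kind"] == "group"][["category", "count"]].T.values))
        assert grp == {"glcm": 2, "glszm": 1, "shape": 1}
        ch = dict(zip(*df[df["kind"] == "channel"][["category", "count"]].T.values))
        assert ch == {"original": 1, "wavelet-HLL": 2, "log-sigma-2": 1}
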