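"""z-scoring, two-tailed enrichment (dES), association maps and clustering."""

import numpy as np
import pandas as pd
import pytest

import regmra as r
from regmra.network import Regulon, RegulatoryNetwork


def _net(regulon_defs, universe, min_size=1):
    regs = [
        Regulon(tf=tf, targets={g: (m, 1.0) for g, m in targets.items()})
        for tf, targets in regulon_defs.items()
    ]
    return RegulatoryNetwork(regulons=regs, universe=list(universe),
                             min_size=min_size)


class TestZScore:
    def test_worked_example(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["g"])
        z = r.zscore_transform(expr)
        np.testing.assert_allclose(z.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_row_dropped(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [2.0, 5.0], "s3": [3.0, 5.0]},
            index=["g", "flat"],
        )
        z = r.zscore_transform(expr)
        assert list(z.index) == ["g"]

    def test_normalization_identity(self, cohort):
        z = r.zscore_transform(cohort.expression)
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            r.zscore_transform(pd.DataFrame({"s1": [1.0]}, index=["g"]))


class TestEnrichmentScore:
    ranked = ["g1", "g2", "g3", "g4", "g5", "g6"]
    weights = [3.0, 2.0, 1.0, 1.0, 2.0, 3.0]  # |z| of [3,2,1,-1,-2,-3]

    def test_top_hits_reach_plus_one(self):
        assert r.enrichment_score(self.ranked, self.weights, {"g1", "g2"}) == 1.0

    def test_bottom_hits_reach_minus_one(self):
        assert r.enrichment_score(self.ranked, self.weights, {"g5", "g6"}) == -1.0

    def test_reversed_ranking_negates(self):
        es = r.enrichment_score(self.ranked, self.weights, {"g2", "g3"})
        es_rev = r.enrichment_score(
            self.ranked[::-1], self.weights[::-1], {"g2", "g3"}
        )
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_bounds_on_random_inputs(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(20):
            z = np.sort(rng.standard_normal(50))[::-1]
            hits = set(rng.choice(genes, size=rng.integers(1, 49), replace=False))
            es = r.enrichment_score(genes, np.abs(z), hits)
            assert -1.0 <= es <= 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            r.enrichment_score(self.ranked, self.weights, set())
        with pytest.raises(ValueError):
            r.enrichment_score(self.ranked, self.weights, set(self.ranked))
        with pytest.raises(ValueError):
            r.enrichment_score(self.ranked, self.weights, {"nope"})


class TestActivityMatrix:
    def _z(self, col):
        genes = [f"g{i + 1}" for i in range(len(col))]
        return pd.DataFrame({"s1": col, "s2": list(reversed(col))}, index=genes)

    def test_maximal_activation_scores_two(self):
        # positive targets exactly at the top, negative exactly at the bottom
        z = self._z([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        net = _net({"tf": {"g1": 1, "g2": 1, "g5": -1, "g6": -1}},
                   z.index, min_size=4)
        act = r.regulon_activity_matrix(z, net)
        assert act.des.loc["tf", "s1"] == pytest.approx(2.0)
        assert act.des.loc["tf", "s2"] == pytest.approx(-2.0)

    def test_swapping_modes_negates_des(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        z = pd.DataFrame(rng.standard_normal((40, 5)), index=genes)
        targets = {g: (1 if i < 6 else -1) for i, g in enumerate(genes[:12])}
        swapped = {g: -m for g, m in targets.items()}
        a1 = r.regulon_activity_matrix(z, _net({"tf": targets}, genes))
        a2 = r.regulon_activity_matrix(z, _net({"tf": swapped}, genes))
        np.testing.assert_allclose(a1.des.to_numpy(), -a2.des.to_numpy(), atol=1e-12)

    def test_negating_z_negates_des(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        z = pd.DataFrame(rng.standard_normal((40, 4)), index=genes)
        targets = {g: (1 if i % 2 else -1) for i, g in enumerate(genes[:10])}
        net = _net({"tf": targets}, genes)
        a1 = r.regulon_activity_matrix(z, net)
        a2 = r.regulon_activity_matrix(-z, net)
        np.testing.assert_allclose(a1.des.to_numpy(), -a2.des.to_numpy(), atol=1e-12)

    def test_projection_flags_and_missing_targets(self, caplog):
        genes = [f"g{i}" for i in range(30)]
        z = pd.DataFrame(
            np.random.default_rng(3).standard_normal((30, 4)), index=genes
        )
        net = _net(
            {
                "lost": {f"x{i}": 1 for i in range(10)},          # nothing present
                "partial": {**{f"x{i}": 1 for i in range(8)},      # 20% present
                            "g1": 1, "g2": -1},
            },
            list(genes) + [f"x{i}" for i in range(10)],
        )
        act = r.regulon_activity_matrix(z, net)
        assert act.des.loc["lost"].isna().all()
        assert 0 < act.meta["projection_flags"]["partial"] < 0.5
        assert np.isfinite(act.des.loc["partial"]).all()

    def test_truth_activity_correlation(self, truth, tnet, cohort):
        z = r.zscore_transform(cohort.expression)
        act = r.regulon_activity_matrix(z, tnet)
        for m in truth.mrs:
            c = np.corrcoef(cohort.activities.loc[m], act.des.loc[m])[0, 1]
            assert c >= 0.7


class TestAssociationMap:
    def test_partial_agreement_is_agonist(self):
        net = _net(
            {"R1": {"g1": 1, "g2": 1, "g3": -1},
             "R2": {"g1": 1, "g2": -1, "g3": -1}},
            ["g1", "g2", "g3"],
        )
        row = r.association_map(net).iloc[0]
        assert row["shared"] == 3
        assert row["agreement"] == pytest.approx(2 / 3)
        assert row["label"] == "agonist"

    def test_full_opposition_is_antagonist(self):
        net = _net(
            {"R1": {"g1": 1, "g2": 1}, "R2": {"g1": -1, "g2": -1}},
            ["g1", "g2"],
        )
        assert r.association_map(net).iloc[0]["label"] == "antagonist"

    def test_min_shared_filters_pairs(self):
        net = _net(
            {"R1": {"g1": 1, "g2": 1}, "R2": {"g1": -1, "g3": 1}},
            ["g1", "g2", "g3"],
        )
        assert len(r.association_map(net, min_shared=2)) == 0

    def test_planted_cluster_structure(self, truth, tnet):
        assoc = r.association_map(tnet)
        for _, row in assoc.iterrows():
            same = truth.cluster_of[row["tf1"]] == truth.cluster_of[row["tf2"]]
            assert row["label"] == ("agonist" if same else "antagonist")


class TestClusterActivity:
    def test_duplicated_rows_merge_first(self):
        des = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0], [1.0, 2.0, 3.0, 1.0], [5.0, -1.0, 2.0, 0.0]],
            index=["a", "b", "c"],
        )
        tree = r.cluster_activity(des, k=2)
        assert set(tree.linkage_matrix[0, :2]) == {0.0, 1.0}
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert tree.labels["a"] == tree.labels["b"] != tree.labels["c"]

    def test_anticorrelated_rows_split_at_k2(self):
        x = np.array([1.0, -2.0, 3.0, 0.5])
        des = pd.DataFrame([x, -x], index=["up", "down"])
        tree = r.cluster_activity(des, k=2)
        assert tree.labels["up"] != tree.labels["down"]

    def test_planted_partition_recovered(self, truth, tnet, cohort):
        z = r.zscore_transform(cohort.expression)
        act = r.regulon_activity_matrix(z, tnet)
        tree = r.cluster_activity(act, k=2)
        parts = tree.partition()
        planted = [set(truth.cluster_members("A")), set(truth.cluster_members("B"))]
        assert parts == planted or parts == planted[::-1]

    def test_k_validation(self):
        des = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError):
            r.cluster_activity(des, k=4)
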