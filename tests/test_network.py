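"""MI estimation, permutation filtering, DPI pruning and regulon assembly."""

import numpy as np
import pandas as pd
import pytest

import regmra as r
from regmra.network import (
    _MIEngine,
    _bin_matrix,
    apply_dpi,
    build_regulons,
    compute_mi_matrix,
    default_bins,
    equal_frequency_bins,
    filter_edges_by_permutation,
)


def _expr(rows: dict, n=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return df


class TestMI:
    def test_monotone_pair_equals_log_bins(self):
        # a deterministic monotone map concentrates the joint on the
        # diagonal, so MI equals the bin entropy ln B exactly
        x = np.arange(120, dtype=float)
        df = _expr({"g1": x, "g2": np.exp(x / 40.0)})
        mi = compute_mi_matrix(df, ["g1"], n_bins=4)
        assert abs(mi.loc["g1", "g2"] - np.log(4)) < 1e-12

    def test_default_bin_count_is_sqrt_n(self):
        assert default_bins(120) == 10
        assert default_bins(200) == 14

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        df = _expr({f"g{i}": rng.standard_normal(64) for i in range(8)})
        mi = compute_mi_matrix(df, list(df.index))
        for a in df.index:
            for b in df.index:
                if a != b:
                    assert mi.loc[a, b] == pytest.approx(mi.loc[b, a], abs=1e-12)

    def test_independent_pair_within_permutation_null_band(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        B = 14
        bx = equal_frequency_bins(x, B)[None, :]
        by = equal_frequency_bins(y, B)[None, :]
        engine = _MIEngine(bx, by, B)
        obs = engine.mi()[0, 0]
        null = np.array(
            [engine.mi(rng.permutation(200))[0, 0] for _ in range(1000)]
        )
        assert null.min() <= obs <= np.quantile(null, 0.999)

    def test_constant_gene_flagged(self):
        df = _expr({"g1": np.arange(12.0), "g2": np.full(12, 5.0)})
        mi = compute_mi_matrix(df, ["g1"], n_bins=2)
        assert mi.attrs["constant_genes"] == ["g2"]
        assert mi.loc["g1", "g2"] == 0.0

    def test_absent_regulators_skipped(self):
        df = _expr({"g1": np.arange(12.0), "g2": np.arange(12.0) ** 2})
        mi = compute_mi_matrix(df, ["g1", "nope"], n_bins=2)
        assert list(mi.index) == ["g1"]

    def test_preconditions(self):
        df = _expr({"g1": np.arange(10.0), "g2": np.arange(10.0)})
        with pytest.raises(ValueError):
            compute_mi_matrix(df, ["g1"], n_bins=1)
        with pytest.raises(ValueError):
            compute_mi_matrix(df, ["g1"], n_bins=8)  # n < 2B


class TestPermutationFilter:
    def test_strong_edge_reaches_minimum_p(self):
        rng = np.random.default_rng(2)
        rows = {"tf": np.arange(120, dtype=float)}
        rows["hit"] = rows["tf"] ** 3  # perfect monotone partner
        for i in range(20):
            rows[f"n{i}"] = rng.standard_normal(120)
        df = _expr(rows)
        edges = filter_edges_by_permutation(df, ["tf"], n_perm=100, seed=0)
        n_valid = df.shape[0] - 1
        total = 100 * n_valid
        hit = edges.set_index("target")
        assert hit.loc["hit", "p"] == pytest.approx(1 / (1 + total))

    def test_parameter_validation(self, cohort, truth):
        with pytest.raises(ValueError):
            filter_edges_by_permutation(cohort.expression, truth.tf_ids, n_perm=10)
        with pytest.raises(ValueError):
            filter_edges_by_permutation(
                cohort.expression, truth.tf_ids, n_perm=100, alpha=1.5
            )


class TestDPI:
    def _edges(self, rows):
        return pd.DataFrame(rows, columns=["tf", "target", "mi"]).assign(
            p=0.001, p_adj=0.01
        )

    def test_triplet_rule_removes_weakest(self):
        edges = self._edges(
            [("TF1", "TF2", 0.8), ("TF2", "g", 0.7), ("TF1", "g", 0.3)]
        )
        pruned = apply_dpi(edges, dpi_eps=0.0)
        pairs = set(map(tuple, pruned[["tf", "target"]].values))
        assert ("TF1", "g") not in pairs
        assert ("TF2", "g") in pairs and ("TF1", "TF2") in pairs

    def test_eps_saturation_keeps_everything(self):
        edges = self._edges(
            [("TF1", "TF2", 0.8), ("TF2", "g", 0.7), ("TF1", "g", 0.3)]
        )
        assert len(apply_dpi(edges, dpi_eps=1.0)) == 3

    def test_empty_passes_through(self):
        assert apply_dpi(self._edges([])).empty

    def test_planted_chain_prunes_all_indirect_edges(self):
        expr = r.simulate_chain(n_samples=300, n_targets=10, seed=4)
        edges = filter_edges_by_permutation(
            expr, ["TF1", "TF2"], n_perm=200, seed=5
        )
        pre = set(map(tuple, edges[["tf", "target"]].values))
        targets = [g for g in expr.index if g.startswith("G")]
        assert all(("TF2", g) in pre for g in targets)
        pruned = apply_dpi(edges, dpi_eps=0.0)
        post = set(map(tuple, pruned[["tf", "target"]].values))
        assert all(("TF1", g) not in post for g in targets)      # indirect gone
        assert all(("TF2", g) in post for g in targets)          # direct kept
        assert ("TF1", "TF2") in post                            # anchor kept


class TestBuildRegulons:
    def test_size_boundary(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(60)
        rows = {"tf14": a, "tf15": a + rng.standard_normal(60)}
        edges = []
        for i in range(14):
            rows[f"x{i}"] = a + 0.1 * rng.standard_normal(60)
            edges.append(("tf14", f"x{i}", 0.5))
        for i in range(15):
            rows[f"y{i}"] = a + 0.1 * rng.standard_normal(60)
            edges.append(("tf15", f"y{i}", 0.5))
        expr = _expr(rows)
        net = build_regulons(
            pd.DataFrame(edges, columns=["tf", "target", "mi"]), expr, min_size=15
        )
        assert {reg.tf for reg in net.filtered_regulons} == {"tf15"}
        assert {reg.tf for reg in net.regulons} == {"tf14", "tf15"}

    def test_mode_from_correlation_sign(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(100)
        expr = _expr({"tf": a, "g": -2.0 * a + 0.05 * rng.standard_normal(100)})
        net = build_regulons(
            pd.DataFrame([("tf", "g", 0.9)], columns=["tf", "target", "mi"]),
            expr, min_size=1,
        )
        assert net.get("tf").targets["g"][0] == -1

    def test_min_size_validation(self, cohort):
        with pytest.raises(ValueError):
            build_regulons(pd.DataFrame(columns=["tf", "target", "mi"]),
                           cohort.expression, min_size=0)


class TestRecovery:
    def test_planted_regulons_recovered(self, truth, inferred):
        rec = r.evaluate_recovery(inferred, truth)
        assert rec["precision"] >= 0.8
        assert rec["recall"] >= 0.8
        assert rec["mode_agreement"] >= 0.95

    def test_decoy_regulons_stay_below_size_filter(self, truth, inferred):
        filtered = {reg.tf for reg in inferred.filtered_regulons}
        assert filtered == set(truth.mrs)
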