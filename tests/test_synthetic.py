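"""The generator must plant exactly the structure the analysis assumes."""

import numpy as np
import pytest

import regmra as r
from regmra.synthetic import _censor_horizon


def small_config(**kw):
    base = dict(
        n_tfs=3, n_mr=2, cluster_sizes=(1, 1), n_genes=60,
        targets_per_regulon=15, cross_shared_fraction=0.0,
        weight_magnitude=1.0, noise_sd=0.5, seed=5,
    )
    base.update(kw)
    return r.TruthConfig(**base)


class TestGenerateTruth:
    def test_default_cluster_sizes(self, truth):
        assert len(truth.cluster_members("A")) == 2
        assert len(truth.cluster_members("B")) == 5
        assert len(truth.non_mr_tfs) == 3

    def test_cross_cluster_sign_antagonism(self, truth):
        for ma in truth.cluster_members("A"):
            for mb in truth.cluster_members("B"):
                shared = set(truth.regulons[ma]) & set(truth.regulons[mb])
                assert shared, "cross-cluster regulons must share targets"
                for g in shared:
                    assert truth.regulons[ma][g] * truth.regulons[mb][g] < 0

    def test_within_cluster_signs_agree(self, truth):
        for cl in ("A", "B"):
            members = truth.cluster_members(cl)
            for i, m1 in enumerate(members):
                for m2 in members[i + 1:]:
                    for g in set(truth.regulons[m1]) & set(truth.regulons[m2]):
                        assert truth.regulons[m1][g] == truth.regulons[m2][g]

    def test_planted_regulons_survive_size_filter(self, truth):
        for m in truth.mrs:
            assert len(truth.regulons[m]) >= 15
        for d in truth.non_mr_tfs:
            assert len(truth.regulons[d]) < 15

    def test_zero_sharing_gives_disjoint_clusters(self):
        t = r.generate_truth(small_config(cross_shared_fraction=0.0))
        a, b = t.mrs
        assert not set(t.regulons[a]) & set(t.regulons[b])

    def test_same_seed_identical(self):
        t1 = r.generate_truth(r.TruthConfig(seed=42))
        t2 = r.generate_truth(r.TruthConfig(seed=42))
        assert t1.regulons == t2.regulons
        assert t1.cluster_of == t2.cluster_of
        assert t1.universe == t2.universe

    @pytest.mark.parametrize(
        "kw",
        [
            dict(cluster_sizes=(2, 2)),              # does not sum to n_mr
            dict(targets_per_regulon=100),           # exceeds n_genes=60
            dict(cross_shared_fraction=1.5),
            dict(targets_per_regulon=10),            # below the size filter
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestSimulateCohort:
    def test_noise_free_target_equals_activity(self):
        t = r.generate_truth(small_config())
        sim = r.simulate_cohort(t, 20, noise_sd=0.0, seed=1)
        m = t.mrs[0]
        g, w = next(iter(t.regulons[m].items()))
        expected = w * sim.activities.loc[m]
        np.testing.assert_allclose(sim.expression.loc[g], expected, atol=1e-12)

    def test_dimension_bookkeeping(self, truth, cohort):
        assert cohort.expression.shape == (510, 120)
        assert cohort.activities.shape == (7, 120)

    def test_untargeted_genes_are_pure_noise(self, truth):
        sim = r.simulate_cohort(truth, 200, noise_sd=0.0, seed=2)
        targeted = {g for tg in truth.regulons.values() for g in tg}
        noise_genes = [
            g for g in sim.expression.index
            if g not in targeted and g not in set(truth.tf_ids)
        ]
        assert noise_genes
        assert np.allclose(sim.expression.loc[noise_genes].to_numpy(), 0.0)

    def test_attenuation_matches_closed_form(self):
        # corr(a, w*a + eps) = 1 / sqrt(1 + sd^2) for w = 1
        t = r.generate_truth(small_config())
        sim = r.simulate_cohort(t, 4000, noise_sd=0.5, seed=3)
        m = t.mrs[0]
        a = sim.activities.loc[m].to_numpy()
        corrs = [
            np.corrcoef(a, np.sign(w) * sim.expression.loc[g].to_numpy())[0, 1]
            for g, w in t.regulons[m].items()
        ]
        assert abs(np.mean(corrs) - 1 / np.sqrt(1.25)) < 0.02

    def test_negative_noise_rejected(self, truth):
        with pytest.raises(ValueError):
            r.simulate_cohort(truth, 10, noise_sd=-1.0, seed=0)

    def test_determinism(self, truth):
        s1 = r.simulate_cohort(truth, 30, seed=9)
        s2 = r.simulate_cohort(truth, 30, seed=9)
        assert s1.expression.equals(s2.expression)
        assert s1.activities.equals(s2.activities)


class TestOriginCohort:
    def test_accepts_tiny_reference_group_sizes(self, truth):
        origin = r.simulate_origin_cohort(truth, 2, seed=4)
        case = r.simulate_cohort(truth, 3, activity_shift=3.0, seed=5)
        assert origin.expression.shape[1] == 2
        assert case.expression.shape[1] == 3

    def test_origin_target_means_near_zero(self, truth):
        origin = r.simulate_origin_cohort(truth, 200, seed=6)
        m = truth.mrs[0]
        targets = list(truth.regulons[m])
        means = origin.expression.loc[targets].mean(axis=1)
        assert np.abs(means).max() < 1.0
        case = r.simulate_cohort(truth, 200, activity_shift=3.0, seed=6)
        case_means = case.expression.loc[targets].mean(axis=1)
        assert np.abs(case_means).min() > 2.0


class TestSimulateSurvival:
    def test_record_contract(self, truth):
        sim = r.simulate_cohort(truth, 50, seed=8)
        recs = r.simulate_survival(sim, truth, seed=8)
        assert len(recs) == 50
        assert all(rec.time > 0 and rec.event in (0, 1) for rec in recs)

    def test_censor_rate_calibration(self, truth):
        sim = r.simulate_cohort(truth, 400, seed=9)
        recs = r.simulate_survival(sim, truth, censor_rate=0.3, seed=9)
        censored = np.mean([rec.event == 0 for rec in recs])
        assert abs(censored - 0.3) < 0.08

    def test_censor_horizon_hits_requested_rate(self):
        hazard = np.array([0.5, 1.0, 2.0])
        tau = _censor_horizon(hazard, 0.25)
        x = hazard * tau
        assert abs(np.mean((1 - np.exp(-x)) / x) - 0.25) < 1e-6

    def test_hazard_monotone_in_cluster_b_activity(self, truth):
        sim = r.simulate_cohort(truth, 300, seed=10)
        recs = r.simulate_survival(
            sim, truth, effect_a=0.0, effect_b=1.0, censor_rate=0.0, seed=10
        )
        mean_b = sim.activities.loc[truth.cluster_members("B")].mean(axis=0)
        times = np.array([rec.time for rec in recs])
        top = times[(mean_b > mean_b.median()).to_numpy()]
        bottom = times[(mean_b <= mean_b.median()).to_numpy()]
        assert np.median(top) < np.median(bottom)

    def test_null_logrank_calibration(self, truth):
        rejections = 0
        n_seeds = 60
        for seed in range(n_seeds):
            sim = r.simulate_cohort(truth, 40, seed=1000 + seed)
            recs = r.simulate_survival(
                sim, truth, effect_a=0.0, effect_b=0.0, seed=2000 + seed
            )
            res = r.logrank_test(recs[:20], recs[20:])
            rejections += res.p < 0.05
        assert rejections / n_seeds <= 0.125

    def test_invalid_params_rejected(self, truth):
        sim = r.simulate_cohort(truth, 20, seed=0)
        with pytest.raises(ValueError):
            r.simulate_survival(sim, truth, baseline_scale=0.0)
        with pytest.raises(ValueError):
            r.simulate_survival(sim, truth, censor_rate=1.0)


class TestSimulateMethylation:
    def test_default_design_and_bounds(self, truth):
        sim = r.simulate_methylation(truth, seed=3)
        assert len(sim.case_samples) == 15 and len(sim.control_samples) == 9
        b = sim.beta.to_numpy()
        assert b.min() >= 0.0 and b.max() <= 1.0
        assert set(sim.probe_map) <= set(truth.universe)

    def test_null_delta_empty_truth(self, truth):
        sim = r.simulate_methylation(truth, delta_beta=0.0, seed=4)
        assert sim.dm_truth == set()

    def test_planted_truth_is_regulon_targets(self, truth):
        sim = r.simulate_methylation(truth, dm_regulons={truth.mrs[0]}, seed=5)
        assert sim.dm_truth == set(truth.regulons[truth.mrs[0]])

    def test_small_groups_rejected(self, truth):
        with pytest.raises(ValueError):
            r.simulate_methylation(truth, n_case=1)
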