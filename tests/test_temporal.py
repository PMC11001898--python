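"""Pseudobulk time courses, fuzzy c-means, and trend labelling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import lungspan as ls
from lungspan.temporal import classify_trend

from conftest import make_norm


class TestPseudobulk:
    def test_ramp_gene_standardized_symmetric(self):
        vals = np.array([[0.0, 1, 2, 3, 4], [1, 1, 1, 1, 1]])
        norm, ann = make_norm(vals, groups=list(ls.GROUPS))
        tc = ls.pseudobulk_timecourse(norm, ann)
        row = tc.zscored.loc["g0"].to_numpy()
        np.testing.assert_allclose(row, -row[::-1])
        np.testing.assert_allclose(np.diff(row), np.diff(row)[0])

    def test_constant_gene_dropped_with_warning(self, caplog):
        vals = np.array([[0.0, 1, 2, 3, 4], [1, 1, 1, 1, 1]])
        norm, ann = make_norm(vals, groups=list(ls.GROUPS))
        with caplog.at_level("WARNING", logger="lungspan"):
            tc = ls.pseudobulk_timecourse(norm, ann)
        assert "g1" not in tc.zscored.index
        assert "g1" in tc.raw.index
        assert "constant" in caplog.text

    def test_missing_group_is_error(self):
        norm, ann = make_norm(np.ones((3, 4)), groups=["T1", "T2", "T3", "T4"])
        with pytest.raises(ValueError, match="T5"):
            ls.pseudobulk_timecourse(norm, ann)

    def test_zscore_invariants(self, small_norm):
        norm, ann, _ = small_norm
        tc = ls.pseudobulk_timecourse(norm, ann, cell_type_filter="AT2")
        z = tc.zscored.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1, atol=1e-9)

    def test_dev_up_program_rises_monotonically(self):
        cfg = ls.SimulationConfig(
            n_genes=2000,
            cells_per_group={g: 200 for g in ls.GROUPS},
            temporal_programs=[ls.TemporalProgram("dev_up", 50, 2.0)],
            seed=17,
        )
        cm, ann, truth = ls.simulate_dataset(cfg)
        cm, ann, _ = ls.qc_filter(cm, ann)
        norm = ls.normalize(cm)
        genes = [g for g, p in truth.program_of_gene.items()
                 if p == "dev_up" and g in set(norm.genes)]
        tc = ls.pseudobulk_timecourse(norm, ann, gene_filter=genes)
        raw = tc.raw.to_numpy()
        monotone = (np.diff(raw, axis=1) >= -1e-12).all(axis=1).mean()
        assert monotone >= 0.95


class TestFuzzyCMeans:
    def test_fixed_point_on_exact_clusters(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(size=(4, 5))
        X = pd.DataFrame(np.repeat(centers, 25, axis=0))
        X.columns = list(ls.GROUPS)
        res = ls.fuzzy_cmeans(X, k=4, seed=0, restarts=5)
        assert res.memberships.to_numpy().max(axis=1).min() == pytest.approx(1.0)
        got = np.sort(np.round(res.centroids.to_numpy(), 9), axis=0)
        want = np.sort(np.round(centers, 9), axis=0)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_same_seed_identical(self):
        prof, _ = ls.simulate_timecourse_profiles(n_genes_each=30, seed=1)
        a = ls.fuzzy_cmeans(prof, seed=4, restarts=5)
        b = ls.fuzzy_cmeans(prof, seed=4, restarts=5)
        pd.testing.assert_frame_equal(a.memberships, b.memberships)
        assert a.objective == b.objective

    def test_memberships_sum_to_one_and_objective_monotone(self):
        prof, _ = ls.simulate_timecourse_profiles(n_genes_each=40, seed=2)
        res = ls.fuzzy_cmeans(prof, seed=0, restarts=3)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1, atol=1e-9)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_recovers_planted_patterns(self):
        prof, labels = ls.simulate_timecourse_profiles(seed=5)
        res = ls.fuzzy_cmeans(prof, seed=5)
        assert adjusted_rand_score(labels, res.hard_labels) >= 0.9

    def test_gene_order_permutation_equivalent(self):
        # well-separated clusters: the partition is unambiguous, so the
        # permuted run must agree exactly up to module relabelling
        prof, _ = ls.simulate_timecourse_profiles(n_genes_each=50, sigma=0.15,
                                                  seed=3)
        a = ls.fuzzy_cmeans(prof, seed=1)
        perm = np.random.default_rng(0).permutation(len(prof))
        b = ls.fuzzy_cmeans(prof.iloc[perm], seed=2)
        joined = pd.concat([a.hard_labels.rename("a"),
                            b.hard_labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)

    def test_k_exceeding_genes_rejected(self):
        prof, _ = ls.simulate_timecourse_profiles(n_genes_each=1, seed=0)
        with pytest.raises(ValueError, match="need >="):
            ls.fuzzy_cmeans(prof, k=10)


class TestTrendLabels:
    @pytest.mark.parametrize("centroid,primary,flags", [
        ((-1.2, -0.4, 1.5, 0.4, -0.3), "t3_peak",
         {"development_up", "t3_peak", "aging_down"}),
        ((0, 0, 0, 0, 0), "flat", set()),
        ((-1.4, -0.7, 0, 0.7, 1.4), "development_up", {"development_up"}),
        ((0.5, 0.5, 0.5, 0.5, -2.0), "aging_down", {"aging_down"}),
    ])
    def test_rule_examples(self, centroid, primary, flags):
        got_primary, got_flags = classify_trend(centroid)
        assert got_primary == primary
        assert got_flags == flags

    def test_epsilon_suppresses_small_steps(self):
        assert classify_trend((0, 0.05, 0.09, 0.05, 0))[0] == "flat"
        assert classify_trend((0, 0.05, 0.09, 0.05, 0), epsilon=0.01)[0] == "t3_peak"

    def test_planted_centroid_labels_recovered(self):
        """Labels of estimated centroids match the rule applied to the
        noiseless planted patterns for >= 5 of 6 modules."""
        prof, labels = ls.simulate_timecourse_profiles(seed=8)
        res = ls.fuzzy_cmeans(prof, seed=8)
        # expected: label each planted pattern's noiseless centroid
        clean, clean_labels = ls.simulate_timecourse_profiles(
            n_genes_each=1, sigma=0.0, seed=0)
        expected = {p: classify_trend(clean.loc[f"{p}-1"].to_numpy())[0]
                    for p in clean_labels}
        # map each module to its majority planted pattern
        hard = res.hard_labels
        agree = 0
        for module, sub in hard.groupby(hard):
            majority = labels.loc[sub.index].mode()[0]
            got = classify_trend(res.centroids.loc[module].to_numpy())[0]
            if got == expected[majority]:
                agree += 1
        assert agree >= 5
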