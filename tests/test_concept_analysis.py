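"""Concept-space statistics: entropy, specificity, RDMs, clustering."""

import numpy as np
import pytest
from scipy import stats as st
from sklearn.metrics import adjusted_rand_score

import catsnet as cn
from catsnet.concept_analysis import (
    ResponseCounts,
    random_concept_sampler,
    upper_triangle,
    yes_counts,
)


class TestFunctionalEntropy:
    def test_uniform_counts_reach_log_k(self):
        res = cn.functional_entropy(
            ResponseCounts([f"c{i}" for i in range(1000)],
                           np.full(1000, 50)))
        assert res.e == pytest.approx(np.log(1000), abs=1e-12)

    def test_degenerate_counts_have_zero_entropy(self):
        res = cn.functional_entropy(
            ResponseCounts(list("abcd"), [37, 0, 0, 0]))
        assert res.e == pytest.approx(0.0, abs=1e-12)

    def test_worked_three_one_split(self):
        # -(0.75 ln 0.75 + 0.25 ln 0.25) = 0.5623...
        res = cn.functional_entropy(ResponseCounts(["a", "b"], [3, 1]))
        assert res.e == pytest.approx(0.562335, abs=1e-6)
        assert np.allclose(res.p, [0.75, 0.25])

    def test_all_zero_counts_undefined(self):
        with pytest.raises(cn.InvalidInputError):
            cn.functional_entropy(ResponseCounts(["a", "b"], [0, 0]))

    def test_bounds_hold_for_random_counts(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 30))
            counts = rng.integers(0, 100, size=k)
            if counts.sum() == 0:
                counts[0] = 1
            e = cn.functional_entropy(
                ResponseCounts(list(range(k)), counts)).e
            assert -1e-12 <= e <= np.log(k) + 1e-12


class TestEntropyDistribution:
    def test_singleton_sample(self, trained_instance):
        es, dropped = cn.entropy_distribution(
            trained_instance["net"], trained_instance["concepts"],
            trained_instance["eval"], n_points=1, seed=0)
        assert len(es) + dropped == 1

    def test_parameter_space_baseline_is_unselective(
            self, eight_class_world, trained_instance):
        """Pooled over parameter draws, random networks respond far less
        selectively than the trained concept space: at this scale a
        single random net accepts a coarse random subset of categories,
        so the pooled baseline sits well above the trained entropies
        (near-ln-K concentration is a large-class-count effect)."""
        w = eight_class_world
        base_es, _ = cn.parameter_space_entropy_baseline(
            [64, 32, 32, 2], 20, w["eval"], n_nets=5, points_per_net=20,
            seed=72)
        t = trained_instance
        trained_es, _ = cn.entropy_distribution(
            t["net"], t["concepts"], t["eval"], 50, seed=76)
        assert np.mean(base_es) > 0.5 * np.log(8)
        assert np.mean(base_es) > np.median(trained_es)

    def test_trained_space_below_random_parameter_baseline(
            self, trained_instance):
        """The trained concept space is category-specific: its entropy
        distribution sits significantly below the baseline pooled over
        architecture-matched random-parameter networks."""
        t = trained_instance
        trained_es, _ = cn.entropy_distribution(
            t["net"], t["concepts"], t["eval"], 100, seed=73)
        base_es, _ = cn.parameter_space_entropy_baseline(
            [64, 32, 32, 2], 20, t["eval"], n_nets=5, points_per_net=20,
            seed=75)
        assert np.median(trained_es) < np.median(base_es)
        p = st.mannwhitneyu(trained_es, base_es,
                            alternative="less").pvalue
        assert p < 0.01


class TestBasisSpecificity:
    def test_always_no_network_gives_zero_matrix(self, hyper_world):
        net = cn.CatsNet([64, 32, 2], d_c=20, seed=0)
        net.params["ts1_W"][:] = 0.0
        net.params["ts1_b"] = np.array([10.0, 0.0])  # No always wins
        mat, hyper_ids = cn.basis_specificity(
            net, hyper_world["eval"], hyper_world["hyper_map"])
        assert mat.shape == (20, 2)
        assert np.all(mat == 0)

    def test_untrained_rows_are_unselective(self, hyper_world):
        net = cn.CatsNet([64, 32, 32, 2], d_c=20, seed=81)
        mat, _ = cn.basis_specificity(net, hyper_world["eval"],
                                      hyper_world["hyper_map"])
        active = mat[mat.sum(axis=1) >= 50]
        assert len(active) > 0
        ratios = (active.max(axis=1) + 1) / (active.min(axis=1) + 1)
        assert np.median(ratios) < 2

    def test_trained_instance_has_selective_basis_dim(self, hyper_world):
        mat, _ = cn.basis_specificity(hyper_world["net"],
                                      hyper_world["eval"],
                                      hyper_world["hyper_map"])
        active = mat[mat.sum(axis=1) > 0]
        share = active.max(axis=1) / active.sum(axis=1)
        assert share.max() > 0.7

    def test_unmapped_class_raises(self, hyper_world):
        bad_map = dict(hyper_world["hyper_map"])
        bad_map.pop(hyper_world["ids"][0])
        with pytest.raises(cn.ConfigurationError):
            cn.basis_specificity(hyper_world["net"], hyper_world["eval"],
                                 bad_map)


class TestRdmFromVectors:
    def test_duplicate_vectors_distance_zero(self):
        r = cn.rdm_from_vectors({"a": [1, 2, 3], "b": [1, 2, 3],
                                 "c": [4, 5, 7]}, metric="pearson")
        assert r.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors_distance_two(self):
        v = np.array([1.0, 2.0, 5.0])
        r = cn.rdm_from_vectors({"a": v, "b": -v + v.mean() * 2,
                                 "c": [0, 1, 0]}, metric="pearson")
        assert r.d[0, 1] == pytest.approx(2.0, abs=1e-10)

    def test_worked_pearson_distance(self):
        r = cn.rdm_from_vectors({"a": [1, 2, 3], "b": [1, 2, 4],
                                 "c": [9, 1, 5]}, metric="pearson")
        assert r.d[0, 1] == pytest.approx(1 - 0.981981, abs=1e-5)

    def test_constant_vector_rejected_under_pearson(self):
        with pytest.raises(cn.DegenerateVectorError):
            cn.rdm_from_vectors({"a": [1, 1, 1], "b": [1, 2, 3],
                                 "c": [2, 0, 1]}, metric="pearson")

    @pytest.mark.parametrize("metric", ["pearson", "cosine", "euclidean"])
    def test_metric_axioms(self, metric, rng):
        vecs = {f"v{i}": rng.standard_normal(6) for i in range(5)}
        r = cn.rdm_from_vectors(vecs, metric=metric)
        assert np.allclose(r.d, r.d.T)
        assert np.allclose(np.diag(r.d), 0)
        assert np.all(r.d >= -1e-12)
        if metric == "pearson":
            assert np.all(r.d <= 2 + 1e-12)


class TestHierarchicalClustering:
    def test_identical_vectors_merge_at_height_zero(self):
        link, labels, _ = cn.hcluster_concepts(
            {"a": [1.0, 0.0], "b": [1.0, 0.0], "c": [0.0, 1.0]})
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_near_parallel_pair_merges_first(self):
        link, labels, _ = cn.hcluster_concepts(
            {"p": [1.0, 0.0], "q": [1.0, 0.01], "r": [0.0, 1.0]})
        first = {labels[int(link[0, 0])], labels[int(link[0, 1])]}
        assert first == {"p", "q"}

    def test_orthogonal_vectors_cosine_distance_one(self):
        r = cn.rdm_from_vectors({"a": [1, 0, 0], "b": [0, 1, 0],
                                 "c": [0, 0, 1]}, metric="cosine")
        assert upper_triangle(r.d) == pytest.approx([1.0] * 3, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(cn.DegenerateVectorError):
            cn.hcluster_concepts({"a": [0.0, 0.0], "b": [1.0, 0.0]})


class TestBestMatchDimensions:
    def test_copied_dimension_is_perfect_match(self, rng):
        con = rng.standard_normal((40, 8))
        ref = np.stack([con[:, 4], rng.standard_normal(40)], axis=1)
        out = cn.best_match_dimensions(ref, con)
        assert out[0][0] == pytest.approx(1.0, abs=1e-12)
        assert out[0][1] == 4

    def test_permutation_equivariance(self, rng):
        con = rng.standard_normal((30, 10))
        ref = rng.standard_normal((30, 3))
        perm = rng.permutation(10)
        base = cn.best_match_dimensions(ref, con)
        permd = cn.best_match_dimensions(ref, con[:, perm])
        for (r0, d0), (r1, d1) in zip(base, permd):
            assert r1 == pytest.approx(r0, abs=1e-12)
            assert perm[d1] == d0

    def test_null_distribution_matches_bruteforce_max_of_k(self, rng):
        """Best-match scores of an independent reference dimension follow
        the max-of-d_c null; compare against a direct simulation."""
        n_items, d_c, reps = 332, 20, 400
        con = rng.standard_normal((n_items, d_c))
        observed = []
        for _ in range(reps):
            ref = rng.standard_normal((n_items, 1))
            observed.append(cn.best_match_dimensions(ref, con)[0][0])
        # independent oracle: explicit max over manually computed r's
        null = []
        for _ in range(reps):
            x = rng.standard_normal(n_items)
            y = rng.standard_normal((n_items, d_c))
            xc = x - x.mean()
            yc = y - y.mean(axis=0)
            r = (xc @ yc) / (np.linalg.norm(xc) *
                             np.linalg.norm(yc, axis=0))
            null.append(r.max())
        assert st.ks_2samp(observed, null).pvalue > 0.01

    def test_significance_flags_match_exact_t_test(self, rng):
        """Thresholding best-match r at critical_r reproduces the exact
        two-tailed Pearson test decision."""
        n = 332
        con = rng.standard_normal((n, 20))
        ref = rng.standard_normal((n, 10))
        thresh = cn.critical_r(n - 2, 0.05, 2)
        for (r, d), col in zip(cn.best_match_dimensions(ref, con),
                               ref.T):
            p = st.pearsonr(col, con[:, d])[1]
            assert (r > thresh) == (p < 0.05)

    def test_constant_column_rejected(self):
        with pytest.raises(cn.DegenerateVectorError):
            cn.best_match_dimensions(np.ones((5, 2)),
                                     np.random.default_rng(0)
                                     .standard_normal((5, 3)))


class TestCriticalR:
    def test_reference_threshold_at_df_330(self):
        assert cn.critical_r(330, 0.05, 2) == pytest.approx(0.107,
                                                            abs=1e-3)

    def test_small_sample_worked_value(self):
        # t* = 2.306 at df 8 -> r* = 2.306 / sqrt(2.306^2 + 8)
        assert cn.critical_r(8, 0.05, 2) == pytest.approx(0.632, abs=1e-3)

    def test_vanishes_for_huge_df(self):
        assert cn.critical_r(10 ** 8, 0.05, 2) < 0.001

    def test_strictly_decreasing_in_df_and_alpha(self):
        rs_df = [cn.critical_r(df, 0.05, 2) for df in (5, 20, 100, 1000)]
        assert all(a > b for a, b in zip(rs_df, rs_df[1:]))
        rs_alpha = [cn.critical_r(50, a, 2) for a in (0.01, 0.05, 0.2)]
        assert all(a > b for a, b in zip(rs_alpha, rs_alpha[1:]))

    def test_invalid_configuration(self):
        with pytest.raises(cn.ConfigurationError):
            cn.critical_r(0, 0.05)
        with pytest.raises(cn.ConfigurationError):
            cn.critical_r(10, 1.5)


class TestKmeansRdmGroups:
    def _template_rdms(self, rng, n_per_group, noise):
        items = 8
        iu = np.triu_indices(items, 1)

        def make(template):
            out = []
            for _ in range(n_per_group):
                m = np.zeros((items, items))
                m[iu] = template + rng.standard_normal(len(iu[0])) * noise
                out.append(np.abs(m + m.T))
            return out

        t1 = rng.random(len(iu[0])) * 2
        t2 = rng.random(len(iu[0])) * 2
        return make(t1), make(t2)

    def test_duplicated_groups_split_perfectly(self, rng):
        g1, g2 = self._template_rdms(rng, 5, noise=0.0)
        labels = cn.kmeans_rdm_groups(g1 + g2, k=2, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_one_single_group(self, rng):
        g1, _ = self._template_rdms(rng, 4, noise=0.1)
        assert set(cn.kmeans_rdm_groups(g1, k=1, seed=0)) == {0}

    def test_planted_partition_recovery(self, rng):
        g1, g2 = self._template_rdms(rng, 15, noise=0.15)
        labels = cn.kmeans_rdm_groups(g1 + g2, k=2, seed=0)
        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_fewer_rdms_than_k(self, rng):
        g1, _ = self._template_rdms(rng, 1, noise=0.0)
        with pytest.raises(cn.ConfigurationError):
            cn.kmeans_rdm_groups(g1, k=2)


class TestYesCounts:
    def test_counts_bounded_by_class_sizes(self, trained_instance):
        t = trained_instance
        counts = yes_counts(t["net"], t["concepts"].vector(t["ids"][0]),
                            t["eval"])
        assert all(0 <= c <= 50 for c in counts.counts)
        # the trained concept mostly selects its own category
        own = counts.counts[counts.class_ids.index(t["ids"][0])]
        assert own > 0.8 * 50
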