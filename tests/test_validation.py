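import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from gliomanet import (RSKCConfig, SynthClusterSpec, adjusted_rand_index,
                       ari_from_contingency, calinski_harabasz,
                       cross_tabulate, make_cluster_dataset, random_baseline,
                       rskc_fit, simplified_silhouette, zscore)

X_1D = np.array([[0.0], [1.0], [10.0], [11.0]])
ASSIGN_1D = np.array([1, 1, 2, 2])


class TestSimplifiedSilhouette:
    def test_worked_example(self):
        # (a, b) = (0.5, 10.5) and (0.5, 9.5) per pair
        assert simplified_silhouette(X_1D, ASSIGN_1D) == pytest.approx(
            0.94988, abs=1e-5)

    def test_coincident_points_score_zero(self):
        X = np.zeros((4, 2))
        assert simplified_silhouette(X, ASSIGN_1D) == 0.0

    def test_scale_invariance(self, rng):
        X = rng.standard_normal((30, 3))
        lab = rng.integers(0, 3, 30)
        lab[:3] = [0, 1, 2]
        a = simplified_silhouette(X, lab)
        b = simplified_silhouette(X * 7.3, lab)
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            simplified_silhouette(X_1D, np.ones(4))

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            X = rng.standard_normal((40, 4))
            lab = rng.integers(0, 4, 40)
            lab[:4] = range(4)
            s = simplified_silhouette(X, lab)
            assert -1.0 <= s <= 1.0


class TestCalinskiHarabasz:
    def test_worked_example(self):
        # B = 100, W = 1, K=2, n=4 -> (100/1)/(1/2) = 200
        assert calinski_harabasz(X_1D, ASSIGN_1D) == pytest.approx(200.0)

    def test_matches_reference_implementation(self, rng):
        X = rng.standard_normal((50, 5))
        lab = rng.integers(0, 3, 50)
        lab[:3] = [0, 1, 2]
        assert calinski_harabasz(X, lab) == pytest.approx(
            calinski_harabasz_score(X, lab), rel=1e-10)

    def test_sample_order_invariance(self, rng):
        X = rng.standard_normal((30, 3))
        lab = np.repeat([0, 1, 2], 10)
        perm = rng.permutation(30)
        assert calinski_harabasz(X, lab) == pytest.approx(
            calinski_harabasz(X[perm], lab[perm]), rel=1e-10)

    def test_planted_clusters_beat_random_assignment(self):
        spec = SynthClusterSpec(n_per_cluster=(100, 100), p=20, q=5,
                                shift=6.0, seed=1)
        X, truth = make_cluster_dataset(spec)
        Xz = zscore(X).to_numpy()
        ch_true = calinski_harabasz(Xz, truth.cluster_labels)
        rng = np.random.default_rng(0)
        for _ in range(100):
            rand_lab = rng.integers(0, 2, 200)
            rand_lab[:2] = [0, 1]
            assert calinski_harabasz(Xz, rand_lab) < ch_true

    def test_zero_within_dispersion_is_infinite(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        with pytest.warns(RuntimeWarning):
            assert calinski_harabasz(X, ASSIGN_1D) == np.inf


class TestAdjustedRandIndex:
    def test_identical_and_relabelled_partitions_score_one(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert adjusted_rand_index(a, a) == pytest.approx(1.0)
        assert adjusted_rand_index(a, 2 - a) == pytest.approx(1.0)

    def test_matches_reference_implementation(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, 60)
            b = rng.integers(0, 3, 60)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12)

    def test_independent_partitions_score_near_zero(self):
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(50):
            a = rng.integers(0, 3, 500)
            b = rng.integers(0, 3, 500)
            vals.append(adjusted_rand_index(a, b))
        assert abs(np.mean(vals)) <= 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 40)
        b = rng.integers(0, 4, 40)
        perm = rng.permutation(4)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(perm[a], b), abs=1e-12)


class TestARIFromContingency:
    def test_glioma_type_vs_cluster_tables(self):
        """Cross-tabulations of diagnostic labels against the clusters found
        on network-selected genes: 2-class case and LGG-subtype case."""
        assert round(ari_from_contingency([[425, 59], [18, 120]]), 2) == 0.54
        assert round(ari_from_contingency([[156, 108], [40, 180]]), 2) == 0.15

    def test_diagonal_table_scores_one(self):
        assert ari_from_contingency([[10, 0], [0, 7]]) == pytest.approx(1.0)

    def test_degenerate_denominator(self):
        with pytest.warns(RuntimeWarning):
            assert ari_from_contingency([[5]]) == 1.0


class TestCrossTabulate:
    def test_diagonal_when_assignment_equals_labels(self):
        lab = np.array(["x", "x", "y", "y"])
        ct = cross_tabulate(lab, lab, margins=False)
        assert np.array_equal(np.diag(ct.to_numpy()), [2, 2])
        assert ct.to_numpy().sum() == 4

    def test_marginals_conserve_n(self, rng):
        asg = rng.integers(1, 4, 30)
        lab = rng.integers(0, 2, 30)
        ct = cross_tabulate(asg, lab)
        assert ct.loc["All", "All"] == 30

    def test_feeds_ari_identically(self, rng):
        asg = rng.integers(1, 3, 40)
        lab = rng.integers(0, 3, 40)
        ct = cross_tabulate(asg, lab, margins=False)
        assert ari_from_contingency(ct.to_numpy()) == pytest.approx(
            adjusted_rand_index(lab, asg), abs=1e-12)


class TestRandomBaseline:
    def test_order_statistics_and_reproducibility(self):
        spec = SynthClusterSpec(n_per_cluster=(40, 40), p=30, q=5, shift=4.0,
                                seed=3)
        X, _ = make_cluster_dataset(spec)
        a = random_baseline(X, subset_size=5, n_rep=5, K=2, seed=42)
        b = random_baseline(X, subset_size=5, n_rep=5, K=2, seed=42)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        s = a.summary().set_index("score")
        for score in ("silhouette", "calinski_harabasz"):
            assert s.loc[score, "best"] >= s.loc[score, "median"]
            assert s.loc[score, "best"] >= s.loc[score, "average"]

    def test_subset_size_validation(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((20, 5)))
        with pytest.raises(ValueError):
            random_baseline(X, subset_size=6, n_rep=1, K=2)

    def test_informative_subset_beats_random_subsets(self):
        """The planted informative features produce a higher CH than every
        random equal-size subset (the random-baseline null)."""
        spec = SynthClusterSpec(n_per_cluster=(100, 100), p=200, q=10,
                                shift=6.0, seed=1)
        X, truth = make_cluster_dataset(spec)
        sub = zscore(X.iloc[:, truth.informative_features])
        res = rskc_fit(sub, RSKCConfig(K=2, L1=2.0, alpha=0.1, seed=1))
        ch = calinski_harabasz(sub.to_numpy(), res.assignment)
        base = random_baseline(X, subset_size=10, n_rep=30, K=2, seed=1)
        assert ch > base.scores["calinski_harabasz"].max()
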