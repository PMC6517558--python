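import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.decomposition import KernelPCA as SkKernelPCA
from sklearn.metrics import adjusted_rand_score

from rarecohort import (
    MIKernelPCA,
    MISpectralClustering,
    binarize,
    characterize_clusters,
    default_cluster_spec,
    kernel_pca,
    mutual_information,
    similarity_matrix,
    simulate_questionnaire,
    spectral_cluster,
)


def mi_oracle(x, y):
    """Independent brute-force plug-in MI over the empirical 2x2 table, in bits."""
    n = len(x)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            p_ab = sum(1 for xi, yi in zip(x, y) if xi == a and yi == b) / n
            p_a = sum(1 for xi in x if xi == a) / n
            p_b = sum(1 for yi in y if yi == b) / n
            if p_ab > 0:
                mi += p_ab * math.log2(p_ab / (p_a * p_b))
    return mi


def entropy_bits(x):
    p = np.mean(x)
    return 0.0 if p in (0, 1) else -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


paired_binary_vectors = st.integers(min_value=2, max_value=30).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
    )
)


class TestMutualInformation:
    def test_identical_fair_vectors_give_one_bit(self):
        x = [0, 0, 1, 1]
        assert mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_empirically_independent_vectors_give_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        x, y = [0, 0, 1, 1], [0, 0, 0, 1]
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)

    def test_nats_unit_rescales_by_log2(self):
        x, y = [0, 0, 1, 1], [0, 0, 0, 1]
        assert mutual_information(x, y, unit="nats") == pytest.approx(
            mutual_information(x, y) * math.log(2), abs=1e-12
        )

    def test_missing_dropped_pairwise(self):
        x = [0, 0, 1, 1, np.nan]
        y = [0, 0, 0, 1, 1]
        assert mutual_information(x, y) == pytest.approx(mi_oracle([0, 0, 1, 1], [0, 0, 0, 1]),
                                                         abs=1e-12)

    def test_too_few_complete_pairs_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            mutual_information([np.nan, np.nan, 1], [0, 1, np.nan])

    @settings(derandomize=True, max_examples=150)
    @given(paired_binary_vectors)
    def test_symmetry_and_bounds(self, pair):
        x, y = pair
        mxy = mutual_information(x, y)
        assert mxy == mutual_information(y, x)
        assert -1e-12 <= mxy <= min(entropy_bits(x), entropy_bits(y)) + 1e-12


class TestSimilarityMatrix:
    def test_equals_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        Q = pd.DataFrame((rng.random((10, 12)) < 0.5).astype(int))
        S = similarity_matrix(Q)
        for i in range(10):
            for j in range(10):
                assert S.values[i, j] == pytest.approx(
                    mi_oracle(Q.iloc[i].tolist(), Q.iloc[j].tolist()), abs=1e-10
                )

    def test_diagonal_is_entropy_and_symmetric(self):
        rng = np.random.default_rng(5)
        Q = pd.DataFrame((rng.random((8, 20)) < 0.4).astype(int))
        S = similarity_matrix(Q)
        np.testing.assert_allclose(S.values, S.values.T, atol=1e-12)
        for i in range(8):
            assert S.values[i, i] == pytest.approx(entropy_bits(Q.iloc[i]), abs=1e-10)

    def test_identical_individuals_share_self_similarity(self):
        Q = pd.DataFrame([[0, 1, 1, 0, 1]] * 2 + [[1, 0, 0, 1, 0]])
        S = similarity_matrix(Q)
        assert S.values[0, 1] == pytest.approx(S.values[0, 0], abs=1e-12)
        assert S.values[0, 1] == pytest.approx(S.values[1, 1], abs=1e-12)

    def test_constant_individual_has_zero_mi_with_everyone(self):
        Q = pd.DataFrame([[1, 1, 1, 1], [0, 1, 0, 1], [1, 0, 1, 0]])
        S = similarity_matrix(Q)
        np.testing.assert_allclose(S.values[0], 0.0, atol=1e-12)

    def test_mostly_missing_individual_excluded(self, caplog):
        import logging
        rows = [[0, 1, 0, 1], [1, 1, 0, 0], [np.nan, np.nan, np.nan, 1.0], [0, 0, 1, 1]]
        Q = pd.DataFrame(rows, index=["a", "b", "c", "d"], dtype=float)
        with caplog.at_level(logging.WARNING):
            S = similarity_matrix(Q)
        assert S.ids == ["a", "b", "d"]
        assert "c" in caplog.text


class TestSpectralClustering:
    def test_two_block_kernel_perfectly_separated(self):
        S = np.zeros((6, 6))
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        labels = spectral_cluster(S, k=2, seed=0)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[-1]

    def test_permutation_equivariance_up_to_relabelling(self):
        spec = default_cluster_spec(n_individuals=60, k=3, n_items=60)
        Q, _ = simulate_questionnaire(spec, seed=2)
        S = similarity_matrix(Q).values
        labels = spectral_cluster(S, k=3, seed=0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(labels))
        labels_perm = spectral_cluster(S[np.ix_(perm, perm)], k=3, seed=0)
        assert adjusted_rand_score(labels[perm], labels_perm) == pytest.approx(1.0)

    def test_fixed_seed_is_deterministic(self):
        spec = default_cluster_spec(n_individuals=40, k=4, n_items=50)
        Q, _ = simulate_questionnaire(spec, seed=3)
        S = similarity_matrix(Q)
        a = MISpectralClustering(n_clusters=4, affinity="precomputed", random_state=9).fit(S)
        b = MISpectralClustering(n_clusters=4, affinity="precomputed", random_state=9).fit(S)
        np.testing.assert_array_equal(a.labels_, b.labels_)

    def test_recovers_planted_clusters_from_raw_questionnaire(self):
        spec = default_cluster_spec(n_individuals=120, k=4)
        Q, truth = simulate_questionnaire(spec, seed=5)
        model = MISpectralClustering(n_clusters=4, random_state=0).fit(Q)
        assert adjusted_rand_score(truth, model.labels_) >= 0.9

    def test_disconnected_graph_rejected(self):
        S = np.kron(np.eye(3), np.ones((2, 2)))  # 3 components
        with pytest.raises(ValueError, match="connected components"):
            spectral_cluster(S, k=2, seed=0)

    def test_asymmetric_affinity_rejected(self):
        S = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            spectral_cluster(S, k=2, seed=0)


class TestKernelPCA:
    @staticmethod
    def _kernel(n=30, seed=6):
        spec = default_cluster_spec(n_individuals=n, k=2, n_items=40)
        Q, _ = simulate_questionnaire(spec, seed=seed)
        return similarity_matrix(Q).values

    def test_centering_identity(self):
        S = self._kernel()
        emb = kernel_pca(S, d=3)
        # eigenvectors of the double-centred kernel are orthogonal to 1
        np.testing.assert_allclose(emb.mean(axis=0), 0.0, atol=1e-10)

    def test_identical_individuals_identical_coordinates(self):
        Q = pd.DataFrame([[0, 1, 1, 0, 1, 0]] * 2 + [[1, 0, 0, 1, 0, 1], [1, 1, 0, 0, 1, 1]])
        S = similarity_matrix(Q).values
        emb = kernel_pca(S, d=2)
        np.testing.assert_allclose(emb[0], emb[1], atol=1e-10)

    def test_two_block_kernel_first_axis_separates(self):
        S = np.zeros((8, 8))
        S[:4, :4] = 1.0
        S[4:, 4:] = 1.0
        emb = kernel_pca(S, d=2)
        a, b = emb[:4, 0], emb[4:, 0]
        assert max(a) < min(b) or min(a) > max(b)

    def test_matches_sklearn_reference_up_to_sign(self):
        S = self._kernel()
        ours = kernel_pca(S, d=3)
        ref = SkKernelPCA(n_components=3, kernel="precomputed").fit_transform(S)
        for c in range(3):
            assert np.allclose(ours[:, c], ref[:, c], atol=1e-8) or np.allclose(
                ours[:, c], -ref[:, c], atol=1e-8
            )

    def test_transform_reproduces_training_embedding(self):
        S = self._kernel()
        model = MIKernelPCA(n_components=3, affinity="precomputed").fit(S)
        np.testing.assert_allclose(model.transform(S), model.embedding_, atol=1e-8)

    def test_sign_convention_deterministic(self):
        S = self._kernel()
        emb = kernel_pca(S, d=3)
        for c in range(3):
            assert emb[np.argmax(np.abs(emb[:, c])), c] > 0


class TestBinarize:
    def test_rules_applied_per_item(self):
        raw = pd.DataFrame(
            {
                "already": [0, 1, 0],
                "count": [0, 1, 3],
                "cat": ["yes", "no", "maybe"],
            }
        )
        rules = {
            "already": {"kind": "binary"},
            "count": {"kind": "threshold", "ge": 1},
            "cat": {"kind": "category", "positive": ["yes", "maybe"]},
        }
        Q = binarize(raw, rules)
        expected = pd.DataFrame(
            {"already": [0.0, 1.0, 0.0], "count": [0.0, 1.0, 1.0], "cat": [1.0, 0.0, 1.0]}
        )
        pd.testing.assert_frame_equal(Q.values, expected)

    def test_missing_preserved(self):
        raw = pd.DataFrame({"count": [2.0, np.nan]})
        Q = binarize(raw, {"count": {"kind": "threshold", "ge": 1}})
        assert Q.values.iloc[0, 0] == 1.0
        assert np.isnan(Q.values.iloc[1, 0])

    def test_missing_rules_listed(self):
        raw = pd.DataFrame({"a": [0, 1], "b": [1, 0]})
        with pytest.raises(ValueError, match=r"\['a', 'b'\]"):
            binarize(raw, {})

    def test_nonbinary_values_in_binary_item_rejected(self):
        raw = pd.DataFrame({"a": [0, 2]})
        with pytest.raises(ValueError, match="non-binary"):
            binarize(raw, {"a": {"kind": "binary"}})


class TestCharacterizeClusters:
    def test_unanimous_item_has_frequency_one(self):
        Q = pd.DataFrame({"i1": [1, 1, 0], "i2": [0, 1, 1]})
        labels = np.array([0, 0, 1])
        profile, _ = characterize_clusters(Q, labels)
        assert profile.loc[0, "i1"] == 1.0
        assert profile.loc[1, "i1"] == 0.0

    def test_missing_excluded_from_denominator(self):
        Q = pd.DataFrame({"i1": [1.0, np.nan, 0.0]})
        profile, _ = characterize_clusters(Q, np.zeros(3, dtype=int))
        assert profile.loc[0, "i1"] == pytest.approx(0.5)

    def test_top_lists_tie_break_lexicographic(self):
        Q = pd.DataFrame({"b": [1, 1], "a": [1, 1], "c": [0, 0]})
        _, tops = characterize_clusters(Q, np.zeros(2, dtype=int), top=2)
        assert tops[0] == ["a", "b"]

    def test_top_lists_may_overlap_across_clusters(self):
        spec = default_cluster_spec(n_individuals=80, k=4, n_items=40,
                                    p_background=0.95)
        Q, truth = simulate_questionnaire(spec, seed=8)
        _, tops = characterize_clusters(Q, truth, top=10)
        union = set().union(*tops.values())
        assert len(union) < 40  # shared high-frequency background items overlap

    def test_planted_top_features_recovered(self):
        spec = default_cluster_spec(n_individuals=200, k=2, n_items=30,
                                    n_discriminative=30, p_background=0.0,
                                    p_high=0.95, p_low=0.05)
        Q, truth = simulate_questionnaire(spec, seed=9)
        profile, tops = characterize_clusters(Q, truth, top=10)
        for c in range(2):
            high_items = {spec.item_labels[j] for j in range(30)
                          if spec.feature_probs[c, j] == 0.95}
            assert len(set(tops[c]) & high_items) >= 8
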