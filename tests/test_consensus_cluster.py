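"""PAM, consensus matrices, CDF/delta-area k selection and final labels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from immunoscape.consensus_cluster import (ConsensusResult, cdf_delta_area,
                                           consensus_matrices, pam_cluster,
                                           pearson_distance, run_consensus,
                                           select_k_and_label)


def _blob_distance(rng, sizes, sep=10.0):
    """Euclidean distance matrix for well-separated Gaussian blobs in 2-D."""
    pts = np.vstack([rng.standard_normal((s, 2)) + sep * i * np.array([1, 0])
                     for i, s in enumerate(sizes)])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    truth = np.repeat(np.arange(len(sizes)), sizes)
    return d, truth


class TestPam:
    def test_k_equals_n_zero_cost(self, rng):
        d, _ = _blob_distance(rng, [3, 3])
        labels, medoids = pam_cluster(d, 6)
        assert sorted(medoids) == list(range(6))
        assert len(set(labels)) == 6

    def test_matches_exhaustive_search(self, rng):
        """BUILD+SWAP reaches the global optimum on small instances."""
        for trial in range(5):
            d, _ = _blob_distance(rng, [5, 5], sep=6.0)
            labels, medoids = pam_cluster(d, 2)
            cost = d[:, medoids].min(axis=1).sum()
            best = min(
                d[:, list(pair)].min(axis=1).sum()
                for pair in itertools.combinations(range(10), 2))
            assert cost == pytest.approx(best, rel=1e-12)

    def test_recovers_separated_blobs(self, rng):
        d, truth = _blob_distance(rng, [8, 7], sep=8.0)
        labels, _ = pam_cluster(d, 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_permutation_equivariance(self, rng):
        d, _ = _blob_distance(rng, [6, 6], sep=8.0)
        labels, _ = pam_cluster(d, 2)
        perm = rng.permutation(12)
        labels_p, _ = pam_cluster(d[np.ix_(perm, perm)], 2)
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_errors(self, rng):
        d, _ = _blob_distance(rng, [3, 3])
        with pytest.raises(ValueError):
            pam_cluster(d, 7)
        d[0, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            pam_cluster(d, 2)


def _planted_features(rng, n_per=10, k=2, sep=6.0, genes=40):
    centers = rng.standard_normal((k, genes)) * sep / np.sqrt(2)
    rows, truth = [], []
    for c in range(k):
        rows.append(centers[c] + rng.standard_normal((n_per, genes)))
        truth += [c] * n_per
    x = np.vstack(rows)
    idx = [f"s{i:02d}" for i in range(x.shape[0])]
    return pd.DataFrame(x, index=idx), np.array(truth)


class TestConsensusMatrices:
    def test_entries_match_brute_force_counts(self, rng):
        """M_k equals co-clustered / co-sampled recomputed independently."""
        feats, _ = _planted_features(rng)
        B, frac, seed, k = 20, 0.8, 5, 2
        res = consensus_matrices(feats, k_range=[k], B=B, frac=frac, seed=seed)
        n = feats.shape[0]
        dist = pearson_distance(feats.to_numpy())
        rng2 = np.random.default_rng(seed)
        m = int(np.ceil(frac * n))
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        for _ in range(B):
            idx = np.sort(rng2.choice(n, size=m, replace=False))
            den[np.ix_(idx, idx)] += 1
            labels, _ = pam_cluster(dist[np.ix_(idx, idx)], k)
            num[np.ix_(idx, idx)] += labels[:, None] == labels[None, :]
        expected = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_array_equal(res.matrices[k], expected)

    def test_frac_one_gives_binary_entries(self, rng):
        feats, _ = _planted_features(rng)
        res = consensus_matrices(feats, k_range=[2], B=5, frac=1.0, seed=0)
        m = res.matrices[2]
        off = m[np.triu_indices_from(m, k=1)]
        assert set(np.unique(off)) <= {0.0, 1.0}

    def test_planted_two_clusters_sharp(self, rng):
        feats, truth = _planted_features(rng, n_per=15, sep=6.0)
        res = consensus_matrices(feats, k_range=[2], B=50, frac=0.8, seed=1)
        m = res.matrices[2]
        same = truth[:, None] == truth[None, :]
        iu = np.triu_indices_from(m, k=1)
        within = m[iu][same[iu]]
        between = m[iu][~same[iu]]
        assert within.min() >= 0.95
        assert between.max() <= 0.05

    def test_matrix_validity(self, rng):
        feats, _ = _planted_features(rng)
        res = consensus_matrices(feats, k_range=[2, 3], B=10, frac=0.8, seed=2)
        for m in res.matrices.values():
            assert np.allclose(m, m.T)
            assert m.min() >= 0 and m.max() <= 1
            assert np.allclose(np.diag(m), 1.0)

    def test_bad_frac_is_error(self, rng):
        feats, _ = _planted_features(rng)
        with pytest.raises(ValueError, match="frac"):
            consensus_matrices(feats, k_range=[2], B=5, frac=1.5)


class TestCdfDeltaArea:
    def _result_with(self, matrices):
        n = next(iter(matrices.values())).shape[0]
        return ConsensusResult(sample_ids=[f"s{i}" for i in range(n)],
                               k_range=sorted(matrices), matrices=matrices,
                               B=1, frac=1.0, seed=0)

    def test_binary_matrix_area(self, rng):
        # 40% zeros in the upper triangle -> area 0.4
        n = 25
        iu = np.triu_indices(n, k=1)
        vals = (rng.random(len(iu[0])) >= 0.4).astype(float)
        m = np.eye(n)
        m[iu] = vals
        m = m + m.T - np.diag(np.diag(m))
        np.fill_diagonal(m, 1.0)
        res = cdf_delta_area(self._result_with({2: m}))
        assert res.area[2] == pytest.approx((vals == 0).mean())

    def test_identical_matrices_zero_delta(self, rng):
        n = 20
        m = np.eye(n)
        m[np.triu_indices(n, 1)] = rng.random(n * (n - 1) // 2)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        res = cdf_delta_area(self._result_with({2: m, 3: m.copy()}))
        assert res.delta_area[3] == pytest.approx(0.0, abs=1e-12)
        assert res.delta_area[2] == pytest.approx(res.area[2])

    def test_cdf_non_decreasing_and_ends_at_one(self, rng):
        feats, _ = _planted_features(rng)
        res = consensus_matrices(feats, k_range=[2, 3], B=10, frac=0.8, seed=3)
        cdf_delta_area(res)
        for k in res.k_range:
            assert np.all(np.diff(res.cdf_values[k]) >= 0)
            assert res.cdf_values[k][-1] == pytest.approx(1.0)


class TestSelectK:
    def test_manual_override(self, rng):
        feats, _ = _planted_features(rng, n_per=10, k=2)
        res = run_consensus(feats, k_range=range(2, 5), B=20, seed=0,
                            k_override=3)
        assert res.chosen_k == 3
        assert res.labels.nunique() == 3
        assert "override" in res.k_rule

    def test_labels_named_by_descending_size(self, rng):
        feats, _ = _planted_features(rng, n_per=12, k=2, sep=8.0)
        res = run_consensus(feats, k_range=range(2, 4), B=20, seed=0,
                            k_override=2)
        counts = res.labels.value_counts()
        assert list(counts.index) == sorted(counts.index)  # IS1 largest first
        assert counts.is_monotonic_decreasing

    def test_sample_order_invariance(self, rng):
        feats, _ = _planted_features(rng, n_per=10, k=2, sep=8.0)
        res1 = run_consensus(feats, k_range=range(2, 4), B=30, seed=4,
                             k_override=2)
        perm = rng.permutation(feats.shape[0])
        res2 = run_consensus(feats.iloc[perm], k_range=range(2, 4), B=30, seed=4,
                             k_override=2)
        joined = pd.concat([res1.labels, res2.labels], axis=1, keys=["a", "b"])
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0
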