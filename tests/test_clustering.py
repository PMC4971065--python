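from itertools import permutations, product

import numpy as np
import pytest

from microstate_rsn import (
    canonical_labeling,
    canonical_reference_maps,
    modified_kmeans,
    select_k,
    spatial_correlation,
    tanova,
)
from microstate_rsn.clustering import TemplateSet, default_labels

from conftest import orthonormal_templates


def exhaustive_gev_optimum(maps: np.ndarray, K: int) -> float:
    """Independent oracle: max GEV over all K^n cluster assignments.

    For a fixed cluster the polarity-invariant GEV-optimal template is
    the top eigenvector of the GFP^2-weighted outer-product sum of the
    normalized member maps, so each assignment scores
    sum_k lambda_max(S_k) / sum_p GFP_p^2.
    """
    x = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    u = x / norms[:, None]
    w = (norms / np.sqrt(x.shape[1])) ** 2  # GFP^2 weights
    outer = w[:, None, None] * np.einsum("pc,pd->pcd", u, u)
    denom = w.sum()
    best = 0.0
    n = maps.shape[0]
    for assign in product(range(K), repeat=n):
        assign = np.asarray(assign)
        total = 0.0
        for k in range(K):
            members = assign == k
            if members.any():
                total += np.linalg.eigvalsh(outer[members].sum(axis=0))[-1]
        best = max(best, total / denom)
    return best


def synth_peaks(rng, templates, n, noise=0.0):
    """Peak maps drawn from templates with random polarity and GFP scale."""
    K, C = templates.shape
    labels = rng.integers(K, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    scales = rng.uniform(0.5, 2.0, size=n)
    maps = signs[:, None] * scales[:, None] * templates[labels]
    if noise:
        maps = maps + rng.normal(0.0, noise, size=maps.shape)
    return maps, labels


class TestSpatialCorrelation:
    def test_identity_and_polarity(self, rng):
        u = rng.normal(size=16)
        assert spatial_correlation(u, u) == pytest.approx(1.0)
        assert spatial_correlation(u, -u) == pytest.approx(-1.0)

    def test_orthogonal_maps(self):
        u = np.array([1.0, 0.0, -1.0, 0.0])
        w = np.array([0.0, 1.0, 0.0, -1.0])
        assert spatial_correlation(u, w) == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))


class TestModifiedKmeans:
    def test_noise_free_exact_recovery(self, rng):
        T = orthonormal_templates(3, 12, rng)
        maps, labels = synth_peaks(rng, T, 60)
        res = modified_kmeans(maps, 3, n_restarts=10, seed=1)
        assert res.gev_total == pytest.approx(1.0, abs=1e-9)
        match = np.abs(res.templates.templates @ T.T)
        # each recovered template matches one truth template at |rho| = 1
        assert np.allclose(match.max(axis=1), 1.0, atol=1e-9)

    def test_k1_degenerate(self, rng):
        T = orthonormal_templates(2, 8, rng)
        maps, _ = synth_peaks(rng, T, 12, noise=0.05)
        res = modified_kmeans(maps, 1, n_restarts=3, seed=0)
        # GEV formula evaluated directly against the single template
        x = maps - maps.mean(axis=1, keepdims=True)
        gfp = np.linalg.norm(x, axis=1) / np.sqrt(8)
        u = x / np.linalg.norm(x, axis=1, keepdims=True)
        rho = u @ res.templates.templates[0]
        expected = np.sum((gfp * rho) ** 2) / np.sum(gfp**2)
        assert res.gev_total == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_oracle_small_instance(self, rng):
        maps = rng.normal(size=(10, 4))
        oracle = exhaustive_gev_optimum(maps, 2)
        res = modified_kmeans(maps, 2, n_restarts=50, seed=3,
                              template_update="eigen")
        assert res.gev_total == pytest.approx(oracle, abs=1e-9)

    def test_mean_update_near_optimal(self, rng):
        maps = rng.normal(size=(10, 4))
        oracle = exhaustive_gev_optimum(maps, 2)
        res = modified_kmeans(maps, 2, n_restarts=50, seed=3)
        assert res.gev_total <= oracle + 1e-9
        assert res.gev_total > 0.99 * oracle

    def test_polarity_invariance(self, rng):
        T = orthonormal_templates(2, 8, rng)
        maps, _ = synth_peaks(rng, T, 30, noise=0.1)
        res = modified_kmeans(maps, 2, n_restarts=10, seed=5)
        flip = rng.choice([-1.0, 1.0], size=30)
        res_f = modified_kmeans(flip[:, None] * maps, 2, n_restarts=10, seed=5)
        assert res_f.gev_total == pytest.approx(res.gev_total, abs=1e-9)
        match = np.abs(res_f.templates.templates @ res.templates.templates.T)
        assert np.allclose(np.sort(match.max(axis=1)), 1.0, atol=1e-9)

    def test_gev_decomposition(self, rng):
        T = orthonormal_templates(3, 10, rng)
        maps, _ = synth_peaks(rng, T, 40, noise=0.3)
        res = modified_kmeans(maps, 3, n_restarts=5, seed=2)
        assert res.gev_per_template.sum() == pytest.approx(res.gev_total, abs=1e-9)
        assert 0.0 <= res.gev_total <= 1.0
        assert res.assignments.shape == (40,)

    def test_k_larger_than_peaks_rejected(self, rng):
        with pytest.raises(ValueError):
            modified_kmeans(rng.normal(size=(3, 6)), 4)


class TestSelectK:
    def test_noise_free_single_template_prefers_k1(self, rng):
        T = orthonormal_templates(1, 8, rng)
        maps, _ = synth_peaks(rng, T, 20)
        chosen, cvs, _ = select_k(maps, k_range=[1, 2, 3], n_restarts=5, seed=0)
        assert chosen == 1
        assert cvs[1] == pytest.approx(0.0, abs=1e-12)

    def test_well_separated_four_templates(self, rng):
        T = orthonormal_templates(4, 16, rng)
        maps, _ = synth_peaks(rng, T, 200, noise=0.1)
        chosen, _, _ = select_k(maps, k_range=range(2, 7), n_restarts=5, seed=1)
        assert chosen == 4

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(size=(10, 8)), k_range=[])


class TestCanonicalLabeling:
    def test_identity(self, montage64, rng):
        ref = canonical_reference_maps(montage64)
        res = modified_kmeans(ref.templates.copy(), 4, n_restarts=5, seed=0)
        out = canonical_labeling(res, ref)
        assert out.templates.labels == ("A", "B", "C", "D")
        match = np.abs(out.templates.templates @ ref.templates.T)
        assert np.trace(match) == pytest.approx(4.0, abs=1e-6)

    def test_matches_brute_force_assignment(self, rng):
        ref = TemplateSet(orthonormal_templates(4, 12, rng), default_labels(4))
        cand = orthonormal_templates(4, 12, np.random.default_rng(7))
        res = modified_kmeans(cand.copy(), 4, n_restarts=5, seed=0)
        out = canonical_labeling(res, ref)
        score = np.abs(res.templates.templates @ ref.templates.T)
        best = max(
            sum(score[p[j], j] for j in range(4))
            for p in permutations(range(4))
        )
        achieved = sum(
            np.abs(out.templates.templates[j] @ ref.templates[j])
            for j in range(4)
        )
        assert achieved == pytest.approx(best, abs=1e-9)

    def test_k_mismatch_rejected(self, rng):
        ref = TemplateSet(orthonormal_templates(3, 12, rng), default_labels(3))
        res = modified_kmeans(rng.normal(size=(10, 12)), 4, n_restarts=2, seed=0)
        with pytest.raises(ValueError):
            canonical_labeling(res, ref)


class TestTanova:
    def test_identical_groups_null(self, rng):
        maps = rng.normal(size=(6, 8))
        diss, p = tanova(maps, maps.copy(), n_perm=200, seed=0)
        assert diss == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_polarity_invariance(self, rng):
        maps = rng.normal(size=(5, 8))
        diss, _ = tanova(maps, -maps, n_perm=50, seed=0)
        assert diss == pytest.approx(0.0, abs=1e-12)

    def test_exact_permutation_matches_enumeration(self, rng):
        from itertools import combinations

        a = rng.normal(size=(3, 4))
        b = rng.normal(size=(3, 4)) + 1.5 * np.ones(4) * np.array([[1, -1, 1, -1]])
        diss, p = tanova(a, b, n_perm="exact")

        def oracle_diss(u, w):
            # dissimilarity of GFP-normalized mean maps, polarity-aligned
            u = u - u.mean()
            w = w - w.mean()
            if u @ w < 0:
                w = -w
            u = u / np.sqrt(np.mean(u**2))
            w = w / np.sqrt(np.mean(w**2))
            return np.sqrt(np.mean((u - w) ** 2))

        # independent enumeration of all 6-choose-3 splits
        pooled = np.vstack([a, b])
        obs = oracle_diss(a.mean(axis=0), b.mean(axis=0))
        count = total = 0
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(idx)] = True
            total += 1
            d = oracle_diss(pooled[mask].mean(0), pooled[~mask].mean(0))
            if d >= obs - 1e-12:
                count += 1
        assert diss == pytest.approx(obs)
        assert p == pytest.approx(count / total)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            tanova(rng.normal(size=(3, 4)), np.empty((0, 4)))
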