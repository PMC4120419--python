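import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinecorr.connectivity import (ConnectivityError, Z_ONE_TAILED_95,
                                    Z_ONE_TAILED_999, Z_TWO_TAILED_999,
                                    correlation_stats, effective_dof,
                                    fisher_z, label_clusters, pearson_r,
                                    roi_connectivity, seed_correlation_map,
                                    zscores_batch)
from spinecorr.core import Volume4D
from spinecorr.masks import ROI_NAMES, SubRegionMasks


def flood_fill_labels(binary, in_plane_only=False):
    """Oracle: connected components by explicit flood fill."""
    binary = np.asarray(binary, bool)
    labels = np.zeros(binary.shape, int)
    if in_plane_only:
        neigh = [(dx, dy, 0) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                 if (dx, dy) != (0, 0)]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                 (0, 0, 1), (0, 0, -1)]
    nxt = 0
    for start in np.argwhere(binary):
        if labels[tuple(start)]:
            continue
        nxt += 1
        stack = [tuple(start)]
        labels[tuple(start)] = nxt
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in neigh:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < binary.shape[i] for i in range(3)) \
                        and binary[p] and not labels[p]:
                    labels[p] = nxt
                    stack.append(p)
    return labels, nxt


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(50)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_orthogonal_sinusoids(self):
        t = np.arange(120)
        s = np.sin(2 * np.pi * 3 * t / 120)
        c = np.cos(2 * np.pi * 3 * t / 120)
        assert abs(pearson_r(s, c)) < 1e-10

    def test_constant_series_rejected(self):
        with pytest.raises(ConnectivityError):
            pearson_r(np.ones(10), np.arange(10.0))


class TestEffectiveDof:
    def test_white_series_keep_full_dof(self):
        n = 64
        t = np.arange(n)
        # exact zero lag-1 autocorrelation: alternating +-1 has rho1 = -1;
        # use orthogonal sinusoid pairs instead and check near-N behavior
        a = np.sin(2 * np.pi * 16 * t / n)       # rho1 = cos(pi/2) = 0
        b = np.cos(2 * np.pi * 16 * t / n)
        assert effective_dof(a, b) == pytest.approx(n, abs=1e-6)

    def test_formula_arithmetic(self):
        """rho1a = rho1b = 0.5, N = 150 -> dof = 150 * 0.75 / 1.25 = 90.

        Checked by substituting the autocorrelation inputs directly."""
        n = 150
        from spinecorr import connectivity as cmod
        orig = cmod.lag1_autocorr
        try:
            cmod.lag1_autocorr = lambda x: 0.5
            assert cmod.effective_dof(np.zeros(n) + np.arange(n),
                                      np.arange(n)) == pytest.approx(90.0)
        finally:
            cmod.lag1_autocorr = orig

    def test_clamped_at_four(self):
        n = 100
        t = np.arange(n)
        slow = np.sin(2 * np.pi * t / n)         # lag-1 autocorr near 1
        assert effective_dof(slow, slow) >= 4.0
        from spinecorr import connectivity as cmod
        orig = cmod.lag1_autocorr
        try:
            cmod.lag1_autocorr = lambda x: 0.9999
            assert cmod.effective_dof(slow, slow) == 4.0
        finally:
            cmod.lag1_autocorr = orig

    def test_short_series_rejected(self):
        with pytest.raises(ConnectivityError):
            effective_dof(np.arange(5.0), np.arange(5.0))


class TestFisherZ:
    def test_zero_r_gives_zero_z(self):
        for dof in (10, 50, 150):
            assert fisher_z(0.0, dof) == 0.0

    def test_reference_value(self):
        """r = 0.5, dof = 103: z = atanh(0.5) * 10 = 5.4931."""
        assert fisher_z(0.5, 103) == pytest.approx(np.arctanh(0.5) * 10.0,
                                                   abs=1e-12)
        assert round(fisher_z(0.5, 103), 4) == 5.4931

    def test_two_tailed_999_threshold(self):
        from scipy.stats import norm
        assert Z_TWO_TAILED_999 == pytest.approx(norm.ppf(0.9995), abs=6e-3)
        assert Z_ONE_TAILED_95 == pytest.approx(norm.ppf(0.95), abs=6e-3)
        assert Z_ONE_TAILED_999 == pytest.approx(norm.ppf(0.999), abs=6e-3)

    def test_degenerate_r_clamped_finite(self):
        z = fisher_z(1.0, 150)
        assert np.isfinite(z)
        assert z == fisher_z(1.0 - 1e-12, 150)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-0.99, 0.99), st.floats(-0.99, 0.99),
           st.floats(5, 150), st.floats(5, 150))
    def test_odd_and_monotone(self, r1, r2, d1, d2):
        assert fisher_z(-r1, d1) == pytest.approx(-fisher_z(r1, d1))
        if abs(r1) < abs(r2):
            assert abs(fisher_z(r1, d1)) <= abs(fisher_z(r2, d1)) + 1e-12
        if d1 < d2 and r1 != 0:
            assert abs(fisher_z(r1, d1)) <= abs(fisher_z(r1, d2)) + 1e-12


class TestClusters:
    def test_exhaustive_small_maps_match_flood_fill(self):
        """All 2^12 binary 2x2x3 maps against the flood-fill oracle."""
        for bits in range(4096):
            m = np.array([(bits >> k) & 1 for k in range(12)],
                         dtype=bool).reshape(2, 2, 3)
            labels, n = label_clusters(m, min_cluster=1)
            oracle, n_o = flood_fill_labels(m)
            assert n == n_o
            # same partition (label names may differ)
            for lab in range(1, n + 1):
                cells = oracle[labels == lab]
                assert cells.size and (cells == cells[0]).all()

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.booleans())
    def test_random_4x4x3_maps_match_flood_fill(self, seed, in_plane):
        rng = np.random.default_rng(seed)
        m = rng.random((4, 4, 3)) < 0.5
        labels, n = label_clusters(m, min_cluster=1, in_plane_only=in_plane)
        oracle, n_o = flood_fill_labels(m, in_plane_only=in_plane)
        assert n == n_o
        for lab in range(1, n + 1):
            cells = oracle[labels == lab]
            assert cells.size and (cells == cells[0]).all()

    def test_minimum_cluster_size_filter(self):
        m = np.zeros((6, 6, 1), bool)
        m[0:2, 0:2, 0] = True            # 4-voxel cluster
        m[4:6, 0:3, 0] = True            # 6-voxel cluster
        labels, n = label_clusters(m, min_cluster=5)
        assert n == 1
        assert (labels > 0).sum() == 6


class TestSeedMap:
    def _volume_with_blob(self, blob_size, n=150, seed=0):
        """Seed voxel plus a contiguous blob sharing its time course."""
        rng = np.random.default_rng(seed)
        shared = rng.standard_normal(n)
        data = rng.standard_normal((8, 8, 2, n))
        mask = np.ones((8, 8, 2), bool)
        data[0, 0, 0] = shared
        count = 0
        for i in range(8):
            for j in range(8):
                if (i, j) == (0, 0) or count >= blob_size:
                    continue
                if i >= 4:
                    data[i, j, 1] = shared + 0.05 * rng.standard_normal(n)
                    count += 1
        return Volume4D(data), mask

    def test_small_blob_removed_large_blob_kept(self):
        vol8, mask = self._volume_with_blob(8)
        m8 = seed_correlation_map(vol8, (0, 0, 0), mask, min_cluster=9)
        assert m8.n_clusters == 0 or (m8.cluster_labels > 0).sum() < 8 + 9
        vol9, mask = self._volume_with_blob(9)
        m9 = seed_correlation_map(vol9, (0, 0, 0), mask, min_cluster=9)
        blob_voxels = (np.abs(np.nan_to_num(m9.zmap)) > m9.threshold).sum()
        assert m9.n_clusters >= 1
        assert (m9.cluster_labels > 0).sum() >= 9

    def test_infinite_threshold_empties_map(self):
        vol, mask = self._volume_with_blob(9)
        m = seed_correlation_map(vol, (0, 0, 0), mask, threshold=np.inf,
                                 min_cluster=0)
        assert m.n_clusters == 0 and not m.surviving.any()

    def test_seed_outside_mask_rejected(self):
        vol, mask = self._volume_with_blob(3)
        mask[0, 0, 0] = False
        with pytest.raises(ConnectivityError):
            seed_correlation_map(vol, (0, 0, 0), mask)

    def test_batch_z_matches_scalar_chain(self, rng):
        a = rng.standard_normal((5, 100))
        b = rng.standard_normal((5, 100))
        batch = zscores_batch(a, b)
        for i in range(5):
            assert batch[i] == pytest.approx(correlation_stats(
                a[i], b[i]).z, abs=1e-10)


class TestRoiConnectivity:
    def _subregions(self, n=10):
        masks = {}
        for k, name in enumerate(ROI_NAMES):
            m = np.zeros((n, n, 1), bool)
            m[k, 0:3, 0] = True
            masks[name] = m
        return SubRegionMasks(masks)

    def _volume(self, roi_series, n=10):
        data = np.random.default_rng(0).standard_normal(
            (n, n, 1, roi_series.shape[1])) * 1e-6
        for k in range(8):
            data[k, 0:3, 0, :] = roi_series[k]
        return Volume4D(data)

    def test_identical_rois_hit_the_clamp_ceiling(self, rng):
        x = rng.standard_normal(150)
        series = np.tile(x, (8, 1))
        sc = roi_connectivity(self._volume(series), self._subregions(), 0)
        # atanh(1 - 1e-7) * sqrt(dof - 3) is the documented ceiling
        assert sc.z[0, 1] > 20
        assert np.isfinite(sc.z).all()

    def test_matrix_symmetric_zero_diagonal(self, rng):
        series = rng.standard_normal((8, 150))
        sc = roi_connectivity(self._volume(series), self._subregions(), 0)
        assert np.allclose(sc.z, sc.z.T)
        assert np.allclose(np.diag(sc.z), 0.0)

    def test_planted_correlation_recovered_on_phantom(self):
        """rho_vv = 0.6 noise-free phantoms: mean recovered LV-RV r over
        many seeds stays within [0.55, 0.65]."""
        from spinecorr.masks import erode_subregions, subdivide_quadrants
        from spinecorr.phantom import PhantomConfig, generate_phantom
        from conftest import small_config
        rs = []
        for seed in range(0, 200):
            cfg = small_config(rho_vv=0.6, n_volumes=150,
                               seed=seed).quiet(sigma_thermal=1.0)
            vol, masks, _, truth = generate_phantom(cfg)
            sub = subdivide_quadrants(masks, central_halfwidth=1.0)
            sub = erode_subregions(sub, gm_radius=1, wm_radius=1)
            sc = roi_connectivity(vol, sub, 0)
            rs.append(sc.r[0, 1])
        assert 0.55 <= np.mean(rs) <= 0.65

    def test_empty_roi_rejected(self, rng):
        sub = self._subregions()
        sub.masks["LD-WM"][:] = False
        with pytest.raises(ConnectivityError, match="LD-WM"):
            roi_connectivity(self._volume(rng.standard_normal((8, 150))),
                             sub, 0)


class TestOneSidedSeedMap:
    def test_one_sided_p001_variant(self):
        """Single-voxel maps with one-sided p < 0.001 (z > 3.09) and no
        cluster-extent rule keep positive detections only."""
        rng = np.random.default_rng(4)
        n = 150
        shared = rng.standard_normal(n)
        data = rng.standard_normal((6, 6, 1, n))
        data[0, 0, 0] = shared
        data[3, 3, 0] = shared + 0.1 * rng.standard_normal(n)
        data[4, 4, 0] = -shared + 0.1 * rng.standard_normal(n)
        mask = np.ones((6, 6, 1), bool)
        m = seed_correlation_map(Volume4D(data), (0, 0, 0), mask,
                                 threshold=Z_ONE_TAILED_999,
                                 min_cluster=0, two_tailed=False)
        assert m.surviving[3, 3, 0]          # positive coupling kept
        assert not m.surviving[4, 4, 0]      # anticorrelation excluded
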