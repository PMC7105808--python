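"""First-level GLM, contrasts, group maps, cluster inference, peaks."""

import numpy as np
import pytest
from scipy import stats

from tonguepipe.core import AcquisitionProtocol, Volume4D
from tonguepipe.design import HRFParams, build_design_matrix, build_paradigm
from tonguepipe.fixturegen import head_mask
from tonguepipe.glm import (Cluster, ClusterTable, SmoothnessEstimate,
                            _grf_cluster_p, contrast_to_z, default_contrasts,
                            fit_first_level, grf_cluster_threshold,
                            group_level, label_clusters, local_maxima, t_to_z)

MASK = head_mask((24, 24, 14))
V = int(MASK.sum())
PROTO = AcquisitionProtocol(n_recorded_volumes=304, n_discard=0)
PARADIGM = build_paradigm(seed=0)
DESIGN = build_design_matrix(PARADIGM, HRFParams(), PROTO)
T = DESIGN.n_timepoints


def _vol(Y):
    data = np.zeros((24, 24, 14, Y.shape[0]))
    data[MASK] = Y.T
    return Volume4D(data, (3, 3, 3), 1.8, MASK)


class TestFirstLevel:
    def test_zero_rho_equals_ols_closed_form(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((T, 50))
        data = np.zeros((24, 24, 14, T))
        sub = np.argwhere(MASK)[:50]
        for i, (x, y, z) in enumerate(sub):
            data[x, y, z] = Y[:, i]
        m = np.zeros_like(MASK)
        m[tuple(sub.T)] = True
        vol = Volume4D(data, (3, 3, 3), 1.8, m)
        fit = fit_first_level(vol, DESIGN, rho=np.zeros(50))
        X = np.column_stack([DESIGN.matrix, np.ones(T)])
        oracle = np.linalg.solve(X.T @ X, X.T @ Y).T
        assert np.abs(fit.betas - oracle).max() < 1e-8

    def test_exact_recovery_noiseless(self):
        ev1 = DESIGN.frame["F"].to_numpy()
        Y = np.tile(2.0 * ev1[:, None], (1, V))
        fit = fit_first_level(_vol(Y), DESIGN)
        idx = fit.columns.index("F")
        assert np.abs(fit.betas[:, idx] - 2.0).max() < 1e-10

    def test_all_zero_data(self):
        fit = fit_first_level(_vol(np.zeros((T, V))), DESIGN)
        assert np.all(fit.betas == 0)

    def test_rank_deficient_design_error(self):
        import pandas as pd
        from tonguepipe.design import DesignMatrix
        col = DESIGN.frame["F"].to_numpy()
        bad = DesignMatrix(pd.DataFrame({"a": col, "b": col}),
                           DESIGN.expected_response, 1.8)
        with pytest.raises(ValueError):
            fit_first_level(_vol(np.zeros((T, V))), bad)


class TestContrasts:
    def test_registry_has_nine_named_contrasts(self):
        c = default_contrasts()
        assert len(c) == 9
        assert list(c)[:3] == ["frontal_gt_rest", "horizontal_gt_rest",
                               "vertical_gt_rest"]

    def test_null_contrast_on_identical_pes(self):
        rng = np.random.default_rng(1)
        shared = rng.standard_normal(T)
        import pandas as pd
        from tonguepipe.design import DesignMatrix
        d = DesignMatrix(pd.DataFrame({"a": shared,
                                       "b": rng.standard_normal(T)}),
                         np.zeros(T), 1.8)
        Y = rng.standard_normal((T, V))
        fit = fit_first_level(_vol(Y), d)
        # c = [1,-1] applied to (beta, beta): zero by linearity
        sm_a = contrast_to_z(fit, np.array([1.0, 0.0]))
        sm_b = contrast_to_z(fit, np.array([0.0, 1.0]))
        sm_diff = contrast_to_z(fit, np.array([1.0, -1.0]))
        assert np.allclose(sm_diff.cope, sm_a.cope - sm_b.cope, atol=1e-12)

    def test_t_to_z_transform(self):
        assert t_to_z(np.array([3.0]), 100)[0] == pytest.approx(2.93, abs=0.02)
        assert t_to_z(np.array([-3.0]), 100)[0] == pytest.approx(-2.93, abs=0.02)
        assert t_to_z(np.array([0.0]), 10)[0] == 0.0

    def test_contrast_linearity(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((T, V))
        fit = fit_first_level(_vol(Y), DESIGN)
        c1 = np.array([1.0, 0, 0, 0, 0, 0])
        c2 = np.array([0, 1.0, 0, 0, 0, 0])
        s1 = contrast_to_z(fit, c1)
        s2 = contrast_to_z(fit, c2)
        s12 = contrast_to_z(fit, c1 + c2)
        assert np.array_equal(s12.cope, s1.cope + s2.cope)


class TestGroupLevel:
    def test_identical_copes_zero_varcopes(self):
        c = np.zeros((24, 24, 14))
        c[MASK] = 3.5
        copes = np.stack([c] * 5)
        varcopes = np.zeros_like(copes)
        sm = group_level(copes, varcopes, MASK)
        assert np.allclose(sm.cope[MASK], 3.5)

    def test_equal_varcopes_matches_t_test(self):
        rng = np.random.default_rng(3)
        n = 8
        copes = np.zeros((n, 24, 24, 14))
        copes[:, MASK] = rng.standard_normal((n, V)) + 0.5
        varcopes = np.zeros_like(copes)  # pure between-subject variance
        sm = group_level(copes, varcopes, MASK)
        x = copes[:, MASK]
        t_oracle = x.mean(axis=0) / (x.std(axis=0, ddof=1) / np.sqrt(n))
        z_oracle = t_to_z(t_oracle, n - 1)
        assert np.abs(sm.zstat[MASK] - z_oracle).max() < 0.05

    def test_null_calibration(self):
        rng = np.random.default_rng(4)
        n, nv = 10, 1000
        m = np.zeros_like(MASK)
        m[np.unravel_index(np.arange(nv), MASK.shape)] = True
        copes = np.zeros((n,) + MASK.shape)
        copes[:, m] = rng.standard_normal((n, nv))
        sm = group_level(copes, np.zeros_like(copes), m)
        frac = (np.abs(sm.zstat[m]) > 1.96).mean()
        assert 0.03 <= frac <= 0.07

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            group_level(np.zeros((2, 24, 24, 14)),
                        np.zeros((2, 24, 24, 14)), MASK)


def _flood_fill_oracle(binary):
    """Brute-force 26-connected labelling by BFS."""
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    from collections import deque
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for idx in np.argwhere(binary):
        if labels[tuple(idx)]:
            continue
        current += 1
        q = deque([tuple(idx)])
        labels[tuple(idx)] = current
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                a, b, c = x + dx, y + dy, z + dz
                if (0 <= a < binary.shape[0] and 0 <= b < binary.shape[1]
                        and 0 <= c < binary.shape[2]
                        and binary[a, b, c] and not labels[a, b, c]):
                    labels[a, b, c] = current
                    q.append((a, b, c))
    return labels, current


class TestClusterMachinery:
    def test_labels_match_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            binary = rng.random((12, 12, 8)) < 0.2
            labels, n = label_clusters(binary)
            oracle, n_o = _flood_fill_oracle(binary)
            assert n == n_o
            # same partition up to relabelling
            for i in range(1, n + 1):
                vals = np.unique(oracle[labels == i])
                assert len(vals) == 1

    def test_p_decreasing_in_size(self):
        ps = [_grf_cluster_p(s, 3.1, V, 500.0) for s in (1, 5, 20, 100)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_planted_blob_survives_thresholding(self):
        rng = np.random.default_rng(6)
        z = np.zeros((24, 24, 14))
        xx, yy, zz = np.meshgrid(np.arange(24), np.arange(24), np.arange(14),
                                 indexing="ij")
        blob = 6.0 * np.exp(-((xx - 12) ** 2 + (yy - 12) ** 2 + (zz - 7) ** 2)
                            / (2 * 2.0**2))
        z[MASK] = blob[MASK]
        resid = rng.standard_normal((60,) + MASK.shape)
        from scipy import ndimage
        resid = ndimage.gaussian_filter(resid, (0, 1.0, 1.0, 1.0))[:, MASK]
        table = grf_cluster_threshold(z, MASK, resid, 3.1, 0.01)
        assert len(table.clusters) == 1
        assert table.clusters[0].p_cluster < 0.01


class TestLocalMaxima:
    def _table_for(self, z):
        labels, n = label_clusters(z > 3.1)
        clusters = [Cluster(i, int((labels == i).sum()), 0.001)
                    for i in range(1, n + 1)]
        sm = SmoothnessEstimate((2.0, 2.0, 2.0), 100.0)
        return ClusterTable(clusters, labels, sm)

    def _bumps(self, sep_vox):
        z = np.zeros((30, 30, 14))
        xx, yy, zz = np.meshgrid(np.arange(30), np.arange(30), np.arange(14),
                                 indexing="ij")
        for cx in (10, 10 + sep_vox):
            z += 5.0 * np.exp(-((xx - cx) ** 2 + (yy - 15) ** 2
                                + (zz - 7) ** 2) / (2 * 1.5**2))
        return z

    def test_single_bump_single_peak(self):
        z = self._bumps(0)
        table = local_maxima(z, self._table_for(z), (3, 3, 3))
        peaks = [p for c in table.clusters for p in c.peaks]
        assert len(peaks) == 1
        assert peaks[0][:3] == (10, 15, 7)

    def test_min_distance_suppression(self):
        # ~10 mm apart (3.33 voxels at 3 mm): one reported peak
        z_near = self._bumps(3)
        t_near = local_maxima(z_near, self._table_for(z_near), (3, 3, 3),
                              min_dist_mm=20.0)
        n_near = sum(len(c.peaks) for c in t_near.clusters)
        assert n_near == 1
        # ~25 mm apart: two peaks survive
        z_far = self._bumps(8)
        t_far = local_maxima(z_far, self._table_for(z_far), (3, 3, 3),
                             min_dist_mm=20.0)
        n_far = sum(len(c.peaks) for c in t_far.clusters)
        assert n_far == 2

    def test_max_n_cap(self):
        z = self._bumps(8)
        t = local_maxima(z, self._table_for(z), (3, 3, 3), min_dist_mm=20.0,
                         max_n=1)
        assert sum(len(c.peaks) for c in t.clusters) == 1
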