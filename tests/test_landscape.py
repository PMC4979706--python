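"""Residual surfaces, circuit resistance, and Mantel tests."""

import itertools

import numpy as np
import pytest

from foxscape import landscape as lg
from foxscape.genodata import DataError, DistanceMatrix, RasterGrid, SiteMap


def _sites_line(n, spacing=1.0):
    return SiteMap({f"s{i}": (i * spacing, 0.0) for i in range(n)})


def _random_sites(rng, n, extent=10.0):
    return SiteMap({f"s{i}": tuple(rng.uniform(0, extent, 2))
                    for i in range(n)})


class TestResiduals:
    def test_perfectly_linear_gives_zero_residuals(self):
        sm = _sites_line(5, 2.0)
        labels = sm.sites
        xy = sm.array()
        d = np.abs(xy[:, 0][:, None] - xy[:, 0][None, :]) * 0.3 + 0.0
        rs = lg.distance_decay_residuals(DistanceMatrix(labels, d), sm)
        assert np.allclose(rs.residuals, 0.0, atol=1e-12)
        assert rs.slope == pytest.approx(0.3)

    def test_constant_genetic_distance(self):
        sm = _sites_line(4)
        d = np.full((4, 4), 0.7)
        np.fill_diagonal(d, 0.0)
        rs = lg.distance_decay_residuals(DistanceMatrix(sm.sites, d), sm)
        assert rs.slope == pytest.approx(0.0)
        assert np.allclose(rs.residuals, 0.0, atol=1e-12)

    def test_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(3)
        sm = _random_sites(rng, 5)
        g = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        g[iu] = rng.uniform(0, 1, len(iu[0]))
        g = g + g.T
        rs = lg.distance_decay_residuals(DistanceMatrix(sm.sites, g), sm)
        # closed-form OLS residuals through the hat matrix
        xy = sm.array()
        e, y = [], []
        for i, j in itertools.combinations(range(5), 2):
            e.append(np.hypot(*(xy[i] - xy[j])))
            y.append(g[i, j])
        X = np.column_stack([np.ones(len(e)), e])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        expect = (np.eye(len(e)) - H) @ np.array(y)
        assert np.allclose(rs.residuals, expect, atol=1e-10)

    def test_infinite_pairs_excluded_with_count(self):
        sm = _sites_line(4)
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = np.inf
        rs = lg.distance_decay_residuals(DistanceMatrix(sm.sites, d), sm)
        assert rs.n_excluded_infinite == 1
        assert len(rs.residuals) == 5


class TestIdw:
    def _surface(self, residuals, midpoints, grid, power=2.0):
        rs = lg.ResidualSurface(0.0, 0.0, [("a", "b")] * len(residuals),
                                np.asarray(residuals, float),
                                np.asarray(midpoints, float))
        return lg.idw_residual_surface(rs, grid, power)

    def test_constant_residuals_give_constant_surface(self):
        grid = RasterGrid(np.zeros((5, 5)), 1.0)
        surf = self._surface([0.4, 0.4, 0.4],
                             [(1.2, 3.4), (2.5, 0.5), (4.0, 4.0)], grid)
        assert np.allclose(surf.values, 0.4)

    def test_exact_hit_takes_midpoint_value(self):
        grid = RasterGrid(np.zeros((3, 3)), 1.0)
        # center of cell (row 1, col 1) is (1.5, 1.5)
        surf = self._surface([5.0, -1.0], [(1.5, 1.5), (0.1, 0.1)], grid)
        assert surf.values[1, 1] == 5.0

    def test_two_midpoint_hand_computed(self):
        grid = RasterGrid(np.zeros((1, 1)), 1.0)   # single cell center (.5,.5)
        mids = [(0.5, 1.5), (3.5, 0.5)]            # distances 1 and 3
        surf = self._surface([1.0, 0.0], mids, grid, power=2.0)
        expect = (1.0 / 1 + 0.0 / 9) / (1.0 / 1 + 1.0 / 9)
        assert surf.values[0, 0] == pytest.approx(expect)

    def test_surface_bounded_by_residual_range(self):
        rng = np.random.default_rng(1)
        grid = RasterGrid(np.zeros((8, 8)), 1.0)
        res = rng.normal(size=6)
        mids = rng.uniform(0, 8, size=(6, 2))
        surf = self._surface(res, mids, grid)
        assert surf.values.min() >= res.min() - 1e-12
        assert surf.values.max() <= res.max() + 1e-12


class TestPermutationNull:
    def test_identity_member_and_nperm_guard(self):
        rng = np.random.default_rng(5)
        sm = _random_sites(rng, 5)
        g = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        g[iu] = rng.uniform(0, 1, len(iu[0]))
        g = g + g.T
        dm = DistanceMatrix(sm.sites, g)
        grid = lg.grid_over_sites(sm, n_cells=12)
        summ = lg.surface_permutation_null(dm, sm, n_perm=5, seed=0, grid=grid)
        # permutation 1 is the identity: observed equals the first member,
        # so the exceedance never exceeds (n_perm-0)/n_perm anywhere
        obs = np.where(summ.observed.nodata_mask, np.nan, summ.observed.values)
        assert np.nanmax(summ.exceedance) <= 1.0
        assert np.nanmin(summ.exceedance) >= 1.0 / summ.n_perm
        with pytest.raises(DataError):
            lg.surface_permutation_null(dm, sm, n_perm=0, seed=0, grid=grid)


class TestResistance:
    def test_series_circuit(self):
        r = RasterGrid(np.ones((1, 3)), 1.0)
        sm = SiteMap({"a": (0.5, 0.5), "b": (2.5, 0.5)})
        assert lg.resistance_distance(r, sm).loc("a", "b") == pytest.approx(2.0)

    def test_parallel_paths_halve_resistance(self):
        # two disjoint 1-wide corridors between the end columns
        vals = np.ones((3, 4))
        mask = np.zeros((3, 4), bool)
        mask[1, 1:3] = True          # block the middle row between the ends
        vals[mask] = -9999
        r2 = RasterGrid(vals, 1.0, nodata_mask=mask)
        sm = SiteMap({"a": (0.5, 1.5), "b": (3.5, 1.5)})
        # single path: mask one corridor too
        mask1 = mask.copy()
        mask1[2, 1:3] = True
        vals1 = np.ones((3, 4))
        vals1[mask1] = -9999
        r1 = RasterGrid(vals1, 1.0, nodata_mask=mask1)
        d2 = lg.resistance_distance(r2, sm).loc("a", "b")
        d1 = lg.resistance_distance(r1, sm).loc("a", "b")
        assert d2 == pytest.approx(d1 / 2.0)

    def test_matches_dense_pseudoinverse_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.5, 4.0, size=(6, 6))
        r = RasterGrid(vals, 1.0)
        sm = SiteMap({"a": (0.5, 0.5), "b": (5.5, 5.5), "c": (0.5, 5.5),
                      "d": (3.5, 2.5)})
        ours = lg.resistance_distance(r, sm)
        # dense Laplacian pseudoinverse oracle
        n = 36
        cond = 1.0 / vals
        W = np.zeros((n, n))
        for row in range(6):
            for col in range(6):
                u = row * 6 + col
                for dr, dc in ((0, 1), (1, 0)):
                    rr, cc = row + dr, col + dc
                    if rr < 6 and cc < 6:
                        v = rr * 6 + cc
                        W[u, v] = W[v, u] = (cond[row, col] + cond[rr, cc]) / 2
        # exact dense pseudoinverse of a connected-graph Laplacian:
        # pinv(L) = inv(L + J/n) - J/n with J the all-ones matrix
        J = np.ones((n, n)) / n
        Lp = np.linalg.inv(np.diag(W.sum(1)) - W + J) - J
        for x, y in itertools.combinations(sm.sites, 2):
            (rx, cx) = r.cell_of(*sm[x])
            (ry, cy) = r.cell_of(*sm[y])
            u, v = rx * 6 + cx, ry * 6 + cy
            expect = Lp[u, u] + Lp[v, v] - 2 * Lp[u, v]
            assert ours.loc(x, y) == pytest.approx(expect, abs=1e-8)

    def test_metric_on_random_instances(self):
        rng = np.random.default_rng(11)
        for rep in range(5):
            vals = rng.uniform(0.5, 3.0, size=(5, 5))
            r = RasterGrid(vals, 1.0)
            sm = SiteMap({"a": (0.5, 0.5), "b": (4.5, 0.5), "c": (2.5, 4.5)})
            d = lg.resistance_distance(r, sm)
            v = d.values
            assert np.allclose(v, v.T)
            for i, j, k in itertools.permutations(range(3), 3):
                assert v[i, j] <= v[i, k] + v[k, j] + 1e-9

    def test_uniform_raster_monotone_in_euclidean(self):
        """On a uniform strip, strictly larger separation between collinear
        sites gives strictly larger effective resistance (pairs at equal
        separation may differ slightly from boundary end effects)."""
        r = RasterGrid(np.ones((3, 30)), 1.0)
        sm = SiteMap({f"s{i}": (0.5 + 3 * i, 1.5) for i in range(8)})
        d = lg.resistance_distance(r, sm)
        e = sm.euclidean_distances()
        iu = np.triu_indices(8, 1)
        by_sep = {}
        for sep, res in zip(e.values[iu], d.values[iu]):
            by_sep.setdefault(round(sep, 6), []).append(res)
        seps = sorted(by_sep)
        for lo, hi in zip(seps, seps[1:]):
            assert max(by_sep[lo]) < min(by_sep[hi])

    def test_errors(self):
        r = RasterGrid(np.ones((2, 2)), 1.0)
        with pytest.raises(DataError, match="off-grid"):
            lg.resistance_distance(r, SiteMap({"a": (5.0, 5.0),
                                               "b": (0.5, 0.5)}))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        vals = np.ones((2, 2))
        vals[mask] = -9999
        r2 = RasterGrid(vals, 1.0, nodata_mask=mask)
        with pytest.raises(DataError, match="nodata"):
            lg.resistance_distance(r2, SiteMap({"a": (0.5, 1.5),
                                                "b": (1.5, 0.5)}))

    def test_disconnected_pair_is_infinite(self):
        vals = np.ones((1, 5))
        mask = np.zeros((1, 5), bool)
        mask[0, 2] = True
        vals[mask] = -9999
        r = RasterGrid(vals, 1.0, nodata_mask=mask)
        sm = SiteMap({"a": (0.5, 0.5), "b": (4.5, 0.5)})
        assert np.isinf(lg.resistance_distance(r, sm).loc("a", "b"))


class TestMantel:
    def _pair(self, seed=0, k=6):
        rng = np.random.default_rng(seed)
        def rand():
            m = np.zeros((k, k))
            iu = np.triu_indices(k, 1)
            m[iu] = rng.uniform(0.1, 1, len(iu[0]))
            return DistanceMatrix([f"s{i}" for i in range(k)], m + m.T)
        return rand(), rand()

    def test_self_correlation(self):
        x, _ = self._pair()
        res = lg.mantel_test(x, x, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_exhaustive_enumeration_matches_oracle(self):
        rng = np.random.default_rng(2)
        k = 4
        x, y = self._pair(seed=2, k=k)
        res = lg.mantel_test(x, y, n_perm="all")
        # independent enumeration oracle
        iu = np.triu_indices(k, 1)
        xt = x.values[iu]
        robs = np.corrcoef(xt, y.values[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(k)):
            yp = y.values[np.ix_(perm, perm)][iu]
            if np.corrcoef(xt, yp)[0, 1] >= robs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / 24)
        assert res.n_perm == 24

    def test_zero_variance_flagged(self):
        k = 4
        m = np.ones((k, k)) - np.eye(k)
        x = DistanceMatrix([f"s{i}" for i in range(k)], m)
        y, _ = self._pair(seed=3, k=k)
        with pytest.raises(DataError, match="zero-variance"):
            lg.mantel_test(x, y, n_perm=99)

    def test_log_transform_guard(self):
        x, y = self._pair(seed=4)
        x.values[0, 1] = x.values[1, 0] = 0.0
        with pytest.raises(DataError, match="log"):
            lg.mantel_test(x, y, n_perm=99, log_x=True)

    def test_partial_with_constant_z_equals_simple(self):
        x, y = self._pair(seed=5)
        k = len(x.labels)
        z = DistanceMatrix(x.labels, np.ones((k, k)) - np.eye(k))
        simple = lg.mantel_test(x, y, n_perm=99, seed=0)
        partial = lg.partial_mantel_test(x, y, z, n_perm=99, seed=0)
        assert partial.r == pytest.approx(simple.r, abs=1e-12)

    def test_partial_removes_shared_structure(self):
        # y == z exactly: controlling z leaves nothing for x to correlate
        x, y = self._pair(seed=6, k=8)
        res = lg.partial_mantel_test(x, y, y, n_perm=499, seed=1)
        assert abs(res.r) < 1e-9 or res.p > 0.2

    def test_resistance_truth_asymmetric_significance(self):
        """Genetic distance built from resistance: the partial test keeps
        resistance significant given Euclidean but not the reverse."""
        rng = np.random.default_rng(8)
        vals = np.ones((12, 12))
        vals[:, 5:7] = 25.0          # a vertical barrier band
        r = RasterGrid(vals, 1.0)
        sm = SiteMap({f"s{i}": (float(rng.uniform(0.3, 11.7)),
                                float(rng.uniform(0.3, 11.7)))
                      for i in range(8)})
        rd = lg.resistance_distance(r, sm)
        ed = sm.euclidean_distances()
        iu = np.triu_indices(8, 1)
        g = np.zeros((8, 8))
        noise = rng.normal(0, 0.02, len(iu[0]))
        g[iu] = 0.1 * rd.values[iu] + noise
        g = g + g.T
        np.fill_diagonal(g, 0.0)
        gd = DistanceMatrix(sm.sites, np.abs(g))
        pr = lg.partial_mantel_test(gd, rd, ed, n_perm=999, seed=2)
        pe = lg.partial_mantel_test(gd, ed, rd, n_perm=999, seed=2)
        assert pr.p < 0.05
        assert pe.p > 0.05
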