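"""MCP and kernel home-range estimators."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import riparia as rp
from riparia.home_range import DegenerateGeometryError, area_accumulation, contour_mask


class TestMcp:
    def test_unit_square_one_hectare(self):
        xy = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
        est = rp.mcp(xy, retention=1.0)
        assert est.area_ha == pytest.approx(1.00)

    def test_oracle_equivalence_uniform_points(self):
        """Quantile filter + exhaustive hull oracle reproduces mcp exactly."""
        rng = np.random.default_rng(11)
        xy = rng.uniform(0, 1000, (1000, 2))
        est = rp.mcp(xy, retention=0.95)
        centroid = xy.mean(axis=0)
        d = np.hypot(*(xy - centroid).T)
        kept = xy[d <= np.quantile(d, 0.95)]
        oracle = ConvexHull(kept).volume  # 2-D: volume == area
        assert est.area_ha == pytest.approx(oracle / 1e4, rel=1e-12)

    def test_degenerate_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            rp.mcp(np.array([[1.0, 1.0]] * 3), retention=1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(12)
        xy = rng.normal(0, 100, (200, 2))
        a = rp.mcp(xy).area_ha
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        b = rp.mcp(xy @ R.T).area_ha
        assert b == pytest.approx(a, rel=1e-9)


class TestHref:
    def test_closed_form(self):
        """var(x)=var(y)=1e4, n=64 -> h = 100 * 64^(-1/6) = 50."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        x = (x - x.mean()) / x.std(ddof=1) * 100.0
        y = rng.normal(size=64)
        y = (y - y.mean()) / y.std(ddof=1) * 100.0
        assert rp.href_bandwidth(np.column_stack([x, y])) == pytest.approx(50.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        xy = rng.normal(0, 50, (40, 2))
        assert rp.href_bandwidth(2 * xy) == pytest.approx(2 * rp.href_bandwidth(xy))

    def test_decreases_with_sample_size(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 100, (1000, 2))
        hs = [rp.href_bandwidth((base[:n] - base[:n].mean(0)) / base[:n].std(0, ddof=1) * 100)
              for n in (50, 200, 1000)]
        assert hs[0] > hs[1] > hs[2]

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            rp.href_bandwidth(np.ones((10, 2)))


class TestKernelUd:
    def test_normalization(self, track):
        ud = rp.kernel_ud(track, cell_size=10.0)
        assert ud.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_single_fix_mode_at_fix(self):
        ud = rp.kernel_ud(np.array([[50.0, 50.0], [50.0, 50.0001]]), h=20.0, cell_size=2.0)
        i, j = np.unravel_index(np.argmax(ud.density), ud.density.shape)
        cx = ud.x0 + (j + 0.5) * ud.cell_size
        cy = ud.y0 + (i + 0.5) * ud.cell_size
        assert abs(cx - 50.0) <= ud.cell_size and abs(cy - 50.0) <= ud.cell_size

    def test_k95_matches_smoothed_gaussian_closed_form(self):
        """K95 area ~ pi * chi2_95 * (sigma^2 + h^2) for Normal fixes."""
        rng = np.random.default_rng(3)
        sigma, h = 100.0, 50.0
        xy = rng.normal(0, sigma, (2000, 2))
        ud = rp.kernel_ud(xy, h=h, cell_size=5.0)
        k95 = rp.ud_contour(ud, 0.95, polygonize=False).area_ha
        expected = np.pi * 5.991 * (sigma**2 + h**2) / 1e4
        assert k95 == pytest.approx(expected, rel=0.05)

    def test_too_small_grid_rejected(self, track):
        with pytest.raises(ValueError, match="grid too small"):
            rp.kernel_ud(track, h=50.0, cell_size=10.0, grid=(0.0, 0.0, 10, 10))


class TestContours:
    def test_nesting(self, track):
        ud = rp.kernel_ud(track, cell_size=10.0)
        m50 = contour_mask(ud, 0.50)
        m75 = contour_mask(ud, 0.75)
        m95 = contour_mask(ud, 0.95)
        assert np.all(m50 <= m75) and np.all(m75 <= m95)

    def test_areas_monotone_in_level(self, track):
        ud = rp.kernel_ud(track, cell_size=10.0)
        a = [rp.ud_contour(ud, lv, polygonize=False).area_ha for lv in (0.5, 0.75, 0.95)]
        assert a[0] < a[1] < a[2]

    def test_uniform_ud_cell_count(self):
        """95% of a uniform UD over 100 equal cells is exactly 95 cells."""
        ud = rp.UtilizationDistribution(0.0, 0.0, 10.0, np.full((10, 10), 1e-4), h=1.0)
        est = rp.ud_contour(ud, 0.95, polygonize=False)
        assert est.area_ha == pytest.approx(95 * 100 / 1e4)

    def test_grid_quantile_oracle(self):
        """Contour area equals the direct density-quantile computation."""
        rng = np.random.default_rng(4)
        ud = rp.kernel_ud(rng.normal(0, 80, (500, 2)), h=40.0, cell_size=10.0)
        for level in (0.5, 0.95):
            est = rp.ud_contour(ud, level, polygonize=False)
            mass = np.sort(ud.density.ravel())[::-1] * ud.cell_area
            k = np.searchsorted(np.cumsum(mass), level * ud.total_mass()) + 1
            assert est.area_ha == pytest.approx(k * ud.cell_area / 1e4)

    def test_polygon_area_close_to_cell_area(self, track):
        ud = rp.kernel_ud(track, cell_size=10.0)
        est = rp.ud_contour(ud, 0.75, polygonize=True)
        assert est.polygon.area / 1e4 == pytest.approx(est.area_ha, rel=1e-9)


class TestAreaAccumulation:
    def _multi_day(self, xy_per_day):
        import pandas as pd

        frames = []
        t0 = pd.Timestamp("2015-03-01 07:00")
        for d, xy in enumerate(xy_per_day):
            t = pd.date_range(t0 + pd.Timedelta(days=d), periods=len(xy), freq="10min")
            frames.append(pd.DataFrame({"timestamp": t, "x": xy[:, 0], "y": xy[:, 1]}))
        return rp.build_trajectory(pd.concat(frames, ignore_index=True), "b")

    def test_stationary_cluster_saturates(self):
        rng = np.random.default_rng(5)
        days = [rng.normal(0, 100, (60, 2)) for _ in range(6)]
        curve = area_accumulation(self._multi_day(days), cell_size=20.0)
        assert curve.saturated_mcp and curve.saturated_k95

    def test_linear_drift_does_not_saturate(self):
        rng = np.random.default_rng(6)
        days = [rng.normal(0, 50, (40, 2)) + [3000.0 * d, 0.0] for d in range(5)]
        curve = area_accumulation(self._multi_day(days), cell_size=40.0)
        assert not curve.saturated_mcp

    def test_final_point_equals_full_estimate(self):
        rng = np.random.default_rng(7)
        days = [rng.normal(0, 100, (50, 2)) for _ in range(4)]
        tr = self._multi_day(days)
        curve = area_accumulation(tr, cell_size=20.0)
        assert curve.table["mcp95_ha"].iloc[-1] == pytest.approx(rp.mcp(tr).area_ha)
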