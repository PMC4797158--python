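"""Jacobs selectivity, sign test, movement-by-habitat, ANOVA, composition."""

import itertools

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

import riparia as rp
from riparia.habitat import movement_summary
from riparia.landcover import LandCoverMap
from shapely.geometry import LineString


def toy_map():
    """Two half-plane classes over a 1 km square, river along the boundary."""
    left = box(0, 0, 500, 1000)
    right = box(500, 0, 1000, 1000)
    return LandCoverMap(
        (0, 0, 1000, 1000),
        {"lantana": shapely.MultiPolygon([left]), "crops_high": shapely.MultiPolygon([right])},
        LineString([(500, 0), (500, 1000)]),
    )


class TestHabitatFractions:
    def test_region_inside_one_class(self):
        fr, unmapped = rp.habitat_fractions(box(100, 100, 200, 200), toy_map())
        assert fr == {"lantana": pytest.approx(1.0)}
        assert unmapped == pytest.approx(0.0)

    def test_region_straddling_half_planes(self):
        fr, _ = rp.habitat_fractions(box(400, 400, 600, 600), toy_map())
        assert fr["lantana"] == pytest.approx(0.5)
        assert fr["crops_high"] == pytest.approx(0.5)

    def test_against_clipping_oracle(self, landscape):
        region = box(600, 600, 1400, 1400)
        fr, unmapped = rp.habitat_fractions(region, landscape)
        for cls, f in fr.items():
            oracle = landscape.polygons[cls].intersection(region).area / region.area
            assert f == pytest.approx(oracle, rel=1e-9)
        assert sum(fr.values()) + unmapped == pytest.approx(1.0, abs=1e-9)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rp.habitat_fractions(shapely.Polygon(), toy_map())


class TestJacobsIndex:
    def test_no_interaction_when_used_equals_available(self):
        assert rp.jacobs_index(0.3, 0.3) == 0.0

    def test_limits(self):
        assert rp.jacobs_index(1.0, 0.5) == 1.0
        assert rp.jacobs_index(0.0, 0.5) == -1.0

    def test_printed_formula_value(self):
        assert rp.jacobs_index(0.6, 0.3) == pytest.approx(0.5556, abs=1e-4)

    def test_undefined_corners_are_nan(self):
        assert np.isnan(rp.jacobs_index(0.0, 0.0))
        assert np.isnan(rp.jacobs_index(1.0, 1.0))

    @given(r=st.floats(0.01, 0.99), p=st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, r, p):
        assert rp.jacobs_index(r, p) == pytest.approx(-rp.jacobs_index(p, r), abs=1e-12)

    @given(p=st.floats(0.01, 0.99), r1=st.floats(0.0, 1.0), r2=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_use(self, p, r1, r2):
        lo, hi = sorted([r1, r2])
        assert rp.jacobs_index(lo, p) <= rp.jacobs_index(hi, p) + 1e-12


class TestSignTest:
    def test_fourteen_of_fourteen_positive(self):
        s, p = rp.sign_test([0.5] * 14)
        assert s == 14
        assert p == pytest.approx(2 * 0.5**14, rel=1e-9)

    def test_three_up_one_down(self):
        s, p = rp.sign_test([1, 2, 3, -1])
        assert (s, p) == (3, pytest.approx(0.625))

    def test_single_positive_value(self):
        assert rp.sign_test([0.2]) == (1, pytest.approx(1.0))

    def test_zeros_dropped(self):
        s, p = rp.sign_test([0.0, 0.0, 1.0, 1.0, -1.0])
        assert s == 2

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            rp.sign_test([0.0, 0.0])

    @pytest.mark.parametrize("n", range(1, 13))
    def test_matches_exhaustive_binomial_enumeration(self, n):
        """p equals direct enumeration of the 2^n equally likely sign patterns."""
        for s in range(n + 1):
            values = [1.0] * s + [-1.0] * (n - s)
            _, p = rp.sign_test(values)
            pmf = np.array(
                [sum(1 for c in itertools.combinations(range(n), k)) for k in range(n + 1)],
                dtype=float,
            ) / 2**n
            expect = pmf[pmf <= pmf[s] * (1 + 1e-12)].sum()
            assert p == pytest.approx(expect, rel=1e-9), (n, s)


class TestMovement:
    def _traj(self, xs, ys, freq="10min"):
        import pandas as pd

        t = pd.date_range("2015-01-01", periods=len(xs), freq=freq)
        return rp.build_trajectory(pd.DataFrame({"timestamp": t, "x": xs, "y": ys}))

    def test_distance_normalized_per_10min(self):
        mv = rp.movement_by_habitat(self._traj([100, 100], [100, 250]), toy_map())
        assert mv["dist_per_10min"].iloc[0] == pytest.approx(150.0)
        assert mv["habitat"].iloc[0] == "lantana"

    def test_long_gap_excluded(self):
        tr = self._traj([100, 100], [100, 400], freq="20min")
        assert len(rp.movement_by_habitat(tr, toy_map(), max_gap_min=10.0)) == 0

    def test_generator_means_recovered(self, landscape):
        means = dict(rp.synthetic.DEFAULT_STEP_MEANS)
        tr = rp.generate_track(landscape, rp.MovementSpec(step_means=means, n_fixes=2000, seed=21))
        mv = rp.movement_by_habitat(tr, landscape)
        summ = movement_summary(mv).set_index("habitat")
        for cls in ("lantana", "crops_high"):
            assert summ.loc[cls, "mean"] == pytest.approx(means[cls], rel=0.10)

    def test_low_sample_flagged(self):
        import pandas as pd

        df = pd.DataFrame({"bird_id": "b", "habitat": ["lantana"] * 10 + ["mixed"] * 60,
                           "dist_per_10min": np.arange(70.0)})
        summ = movement_summary(df).set_index("habitat")
        assert bool(summ.loc["lantana", "low_n"]) and not bool(summ.loc["mixed", "low_n"])


class TestAnova:
    def test_hand_decomposed_example(self):
        f, d1, d2, _ = rp.one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert (d1, d2) == (1, 4)
        assert f == pytest.approx(13.5)

    def test_identical_groups_f_zero(self):
        f, *_ = rp.one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)

    def test_matches_scipy(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(13)
        groups = [rng.normal(loc, 1, 8) for loc in (0, 0.5, 1)]
        f, _, _, p = rp.one_way_anova(groups)
        ref = f_oneway(*groups)
        assert f == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_auto_transform_on_skewed_data(self):
        rng = np.random.default_rng(14)
        groups = [np.exp(rng.normal(3, 1, 30)) for _ in range(3)]
        f_auto, *_ = rp.one_way_anova(groups, transform="auto")
        f_log, *_ = rp.one_way_anova(groups, transform="log1p")
        assert f_auto == pytest.approx(f_log)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            rp.one_way_anova([[1.0], [2.0, 3.0]])


class TestComposition:
    def test_single_square_hundred_percent(self):
        lc = LandCoverMap(
            (0, 0, 1000, 1000),
            {"lantana": shapely.MultiPolygon([box(0, 0, 1000, 1000)])},
            LineString([(0, 0), (1000, 1000)]),
        )
        tab = rp.landscape_composition(lc).set_index("class")
        assert tab.loc["lantana", "ha"] == pytest.approx(100.0)
        assert tab.loc["lantana", "pct"] == pytest.approx(100.0)

    def test_percentages_from_printed_areas(self):
        tab = rp.composition_percentages(
            {"settlement": 6.4, "thicket": 44.6, "agriculture": 97.2}
        ).set_index("class")
        assert tab.loc["settlement", "pct"] == pytest.approx(4.3, abs=0.05)
        assert tab.loc["thicket", "pct"] == pytest.approx(30.1, abs=0.05)

    def test_percentages_sum_to_100(self, landscape):
        tab = rp.landscape_composition(landscape, buffer_m=400.0)
        assert tab["pct"].sum() == pytest.approx(100.0, abs=0.2)

    def test_preference_direction_on_biased_tracks(self, landscape):
        """Tracks biased into lantana yield D(lantana) > 0 > D(crops_high)."""
        pref = {"lantana": 1.0, "mixed": 0.2, "indigenous": 0.2,
                "crops_low": 0.1, "crops_high": 0.05, "settlement": 0.01}
        avail, _ = rp.habitat_fractions(box(*landscape.extent), landscape)
        ds = {"lantana": [], "crops_high": []}
        for seed in (31, 32, 33):
            tr = rp.generate_track(
                landscape,
                rp.MovementSpec(n_fixes=400, habitat_preference=pref,
                                river_attraction=0.2, seed=seed),
            )
            ud = rp.kernel_ud(tr, cell_size=10.0)
            k75 = rp.ud_contour(ud, 0.75)
            used, _ = rp.habitat_fractions(k75.polygon, landscape)
            for cls in ds:
                ds[cls].append(rp.jacobs_index(used.get(cls, 0.0), avail[cls]))
        assert np.mean(ds["lantana"]) > 0 > np.mean(ds["crops_high"])
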