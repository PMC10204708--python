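import numpy as np
import pytest

from rootridge.classify import (
    DiameterClassScheme,
    DiameterDistribution,
    aggregate_frames,
    classify_widths,
    growth_dynamics,
    rebin_fine_histogram,
)
from rootridge.imaging import CameraCalibration
from rootridge.iterate import WidthMap

SCHEME = DiameterClassScheme()


def _widthmap(widths_px, weights=None):
    n = len(widths_px)
    return WidthMap(
        rows=np.arange(n),
        cols=np.zeros(n, dtype=int),
        width_px=np.asarray(widths_px, dtype=float),
        source_step=np.zeros(n, dtype=int),
        length_weight=np.ones(n) if weights is None else np.asarray(weights),
    )


def _dist(lengths):
    return DiameterDistribution(length_mm=np.asarray(lengths, dtype=float))


class TestScheme:
    def test_default_four_classes(self):
        assert SCHEME.n_classes == 4

    @pytest.mark.parametrize(
        "d,cls", [(1.9, 0), (2.0, 1), (5.99, 1), (6.0, 2), (20.0, 3), (25.0, 3)]
    )
    def test_half_open_intervals(self, d, cls):
        assert SCHEME.classify(np.array([d]))[0] == cls

    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            DiameterClassScheme(boundaries_mm=(6.0, 2.0))


class TestClassifyWidths:
    def test_direct_binning(self):
        # 10 px at 1.5 mm and 10 px at 10 mm, unit weights, 1 mm/px
        wm = _widthmap([1.5] * 10 + [10.0] * 10)
        cal = CameraCalibration(mm_per_px=1.0)
        dist, _ = classify_widths(wm, cal)
        assert np.allclose(dist.length_mm, [10, 0, 10, 0])
        assert np.allclose(dist.fraction_pct, [50, 0, 50, 0])

    def test_storage_class_is_open_ended(self):
        wm = _widthmap([25.0])
        dist, _ = classify_widths(wm, CameraCalibration(mm_per_px=1.0))
        assert dist.length_mm[3] == pytest.approx(1.0)

    def test_empty_widthmap_flagged(self):
        dist, _ = classify_widths(WidthMap(), CameraCalibration(mm_per_px=1.0))
        assert dist.total_length_mm == 0
        assert np.isnan(dist.fraction_pct).all()

    def test_conservation_of_total_length(self, rng):
        widths = rng.uniform(0.5, 40, size=200)
        weights = rng.uniform(1.0, np.sqrt(2), size=200)
        wm = _widthmap(widths, weights)
        cal = CameraCalibration(mm_per_px=0.6)
        dist, _ = classify_widths(wm, cal)
        assert dist.total_length_mm == pytest.approx(
            weights.sum() * 0.6, rel=1e-9
        )

    def test_permutation_invariance(self, rng):
        widths = rng.uniform(0.5, 40, size=100)
        perm = rng.permutation(100)
        cal = CameraCalibration(mm_per_px=0.6)
        d1, _ = classify_widths(_widthmap(widths), cal)
        d2, _ = classify_widths(_widthmap(widths[perm]), cal)
        assert np.allclose(d1.length_mm, d2.length_mm)

    def test_fine_histogram_rebins_to_class_fractions(self, rng):
        widths = rng.uniform(0.5, 30, size=300)
        cal = CameraCalibration(mm_per_px=1.0)
        dist, hist = classify_widths(_widthmap(widths), cal)
        assert hist.prob.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(
            rebin_fine_histogram(hist), dist.fraction_pct, atol=1e-6
        )


class TestAggregateFrames:
    def test_mean_idempotent_on_copies(self):
        d = _dist([10, 20, 30, 40])
        agg = aggregate_frames([d, d, d], mode="mean")
        assert np.allclose(agg.fraction_pct, d.fraction_pct)

    def test_mean_of_fractions(self):
        agg = aggregate_frames(
            [_dist([10, 0, 0, 0]), _dist([0, 10, 0, 0])], mode="mean"
        )
        assert np.allclose(agg.fraction_pct, [50, 50, 0, 0])

    def test_max_mode_takes_per_class_maximum(self):
        dists = [_dist([0, 0, L, 0]) for L in (10, 30, 20)]
        agg = aggregate_frames(dists, mode="max")
        assert agg.length_mm[2] == pytest.approx(30.0)

    def test_percentile_mode(self):
        dists = [_dist([0, 0, L, 0]) for L in range(1, 101)]
        agg = aggregate_frames(dists, mode="percentile", percentile=95)
        assert agg.length_mm[2] == pytest.approx(np.percentile(range(1, 101), 95))

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            aggregate_frames([])

    def test_empty_frames_excluded_and_counted(self):
        agg = aggregate_frames([_dist([0, 0, 0, 0]), _dist([5, 5, 0, 0])])
        assert agg.provenance["n_excluded_empty"] == 1
        assert np.allclose(agg.fraction_pct, [50, 50, 0, 0])


class TestGrowthDynamics:
    def test_single_plant_medians_equal_fractions(self):
        d = _dist([40, 30, 20, 10])
        table = growth_dynamics({5: [d]})
        med = table.set_index("diameter_class")["median_pct"]
        assert np.allclose(med.values, [40, 30, 20, 10])

    def test_monotone_decline_preserved(self, rng):
        per_week = {}
        for k, week in enumerate(range(2, 8)):
            frac1 = 80 - 10 * k  # class-1 share declines weekly
            per_week[week] = [
                _dist([frac1 + rng.normal(0, 0.5), 100 - frac1, 0, 0])
                for _ in range(5)
            ]
        table = growth_dynamics(per_week)
        c1 = table[table.diameter_class == 1].sort_values("week")["median_pct"]
        assert (np.diff(c1.values) < 0).all()

    def test_weekly_median_sums_near_100(self, rng):
        base = np.array([40.0, 30.0, 20.0, 10.0])
        per_week = {
            w: [
                DiameterDistribution(
                    length_mm=base * rng.lognormal(0, 0.15, size=4)
                )
                for _ in range(12)
            ]
            for w in range(3, 9)
        }
        table = growth_dynamics(per_week)
        sums = table.groupby("week")["median_pct"].sum()
        assert ((sums >= 95) & (sums <= 105)).all()

    def test_tukey_whiskers_bound_outliers(self, rng):
        vals = np.concatenate([rng.normal(50, 2, size=30), [90.0]])
        dists = [_dist([v, 100 - v, 0, 0]) for v in vals]
        table = growth_dynamics({1: dists})
        row = table[table.diameter_class == 1].iloc[0]
        assert row.n_outliers >= 1
        assert row.whisker_high_pct < 90.0


class TestOutputs:
    def test_overlay_colors_centerline_by_class(self):
        from rootridge.classify import CLASS_COLORS_RGB, overlay_classes

        img = np.zeros((10, 10, 3), dtype=np.uint8)
        wm = _widthmap([1.0, 10.0])
        wm.rows = np.array([2, 5])
        wm.cols = np.array([3, 6])
        out = overlay_classes(img, wm, CameraCalibration(mm_per_px=1.0))
        assert tuple(out[2, 3]) == CLASS_COLORS_RGB[0]
        assert tuple(out[5, 6]) == CLASS_COLORS_RGB[2]
        assert (out[0, 0] == 0).all()

    def test_plant_summary_roundtrips_through_json(self):
        import json

        from rootridge.classify import plant_summary

        s = plant_summary(_dist([10, 20, 30, 40]), "plant-7", week=9, n_frames=180)
        s2 = json.loads(json.dumps(s))
        assert s2["plant_id"] == "plant-7"
        assert s2["total_length_mm"] == pytest.approx(100.0)
        assert s2["fraction_pct"] == [10, 20, 30, 40]
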