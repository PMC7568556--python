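"""Border, shininess and normal metrics; batch normalisation; total score."""

import numpy as np
import pytest

from dungscore import (
    FilterParams,
    ImageStack,
    LightRig,
    MetricSet,
    Sample,
    SampleMask,
    border_metric,
    normal_metric,
    normalise_batch,
    score_batch,
    shininess_metric,
    total_score,
)
from dungscore.errors import (
    DegenerateMaskError,
    EmptyMaskError,
    NormalisationError,
)
from dungscore.metrics import local_std_filter, weighted_median_filter, _median_offsets


def _stack(images: np.ndarray) -> ImageStack:
    n = images.shape[0]
    t = np.deg2rad(30.0)
    az = np.linspace(0, 2 * np.pi, n, endpoint=False)
    dirs = np.stack([np.sin(t) * np.cos(az), np.sin(t) * np.sin(az),
                     np.full(n, np.cos(t))], axis=1)
    return ImageStack(images=images, rig=LightRig(directions=dirs))


class TestBorderMetric:
    def test_filled_disk_is_almost_solid(self):
        yy, xx = np.mgrid[0:140, 0:140]
        disk = (yy - 70) ** 2 + (xx - 70) ** 2 <= 60**2
        assert border_metric(SampleMask(disk)) <= 0.02

    def test_star_matches_brute_force_hull(self):
        """Against an independent Delaunay point-in-hull rasterisation.

        Pixel-boundary conventions differ slightly between hull
        rasterisers, so agreement is asserted to 0.02 on a 64 px star.
        """
        from scipy.spatial import Delaunay

        n = 64
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        th = np.arctan2(yy - c, xx - c)
        star = np.hypot(yy - c, xx - c) <= 22 * (1 + 0.45 * np.cos(5 * th))
        tri = Delaunay(np.argwhere(star))
        grid = np.argwhere(np.ones((n, n), dtype=bool))
        hull_area = int(np.sum(tri.find_simplex(grid) >= 0))
        oracle = 1.0 - star.sum() / hull_area
        assert border_metric(SampleMask(star)) == pytest.approx(oracle, abs=0.02)

    def test_degenerate_masks_raise(self):
        line = np.zeros((9, 9), dtype=bool)
        line[4, 2:7] = True  # collinear
        with pytest.raises(DegenerateMaskError):
            border_metric(SampleMask(line))
        with pytest.raises(DegenerateMaskError):
            border_metric(SampleMask(np.zeros((9, 9), dtype=bool)))


class TestShininessMetric:
    def test_identical_images_score_zero(self):
        img = np.random.default_rng(0).uniform(size=(8, 8))
        stack = _stack(np.stack([img] * 4))
        assert shininess_metric(stack, SampleMask(np.ones((8, 8), bool))) == 0.0

    def test_hand_computed_toy_stack(self):
        """Per-pixel (max - min) of {0.1, 0.2, 0.3, 0.4} averages to 0.25."""
        base = np.zeros((2, 2))
        spread = np.array([[0.1, 0.2], [0.3, 0.4]])
        stack = _stack(np.stack([base + 0.3, base + 0.3 + spread,
                                 base + 0.35, base + 0.4]))
        expected = np.maximum(spread, 0.1).mean()  # brute: max-min per pixel
        got = shininess_metric(stack, SampleMask(np.ones((2, 2), bool)))
        assert got == pytest.approx(expected)

    def test_bounded_in_unit_interval(self, cohort):
        for member in cohort[::4]:
            s = shininess_metric(member.stacks["VIS"], SampleMask(member.surface.mask))
            assert 0.0 <= s <= 1.0

    def test_empty_mask_raises(self):
        stack = _stack(np.zeros((4, 4, 4)))
        with pytest.raises(EmptyMaskError):
            shininess_metric(stack, SampleMask(np.zeros((4, 4), bool)))


class TestFilterPrimitives:
    def test_median_offsets_are_centre_plus_twenty_nearest(self):
        offs = _median_offsets(20)
        assert offs[0] == (0, 0)
        assert len(offs) == 21
        dists = sorted((dy**2 + dx**2) for dy, dx in offs[1:])
        assert dists == sorted([1] * 4 + [2] * 4 + [4] * 4 + [5] * 8)

    def test_weighted_median_against_brute_force(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(size=(12, 12))
        out = weighted_median_filter(img, n_neighbours=20, centre_weight=3)
        offs = _median_offsets(20)
        pad = 2
        padded = np.pad(img, pad, mode="reflect")
        for y, x in [(0, 0), (3, 7), (11, 11), (6, 2)]:
            vals = [padded[y + pad + dy, x + pad + dx] for dy, dx in offs]
            vals += [img[y, x]] * 2  # centre already once in offsets
            assert out[y, x] == pytest.approx(np.median(vals))

    def test_local_std_against_brute_force(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(size=(10, 10))
        radius = 3
        out = local_std_filter(img, radius)
        yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        foot = yy**2 + xx**2 <= radius**2
        padded = np.pad(img, radius, mode="reflect")
        for y, x in [(0, 0), (4, 5), (9, 9)]:
            window = padded[y:y + 2 * radius + 1, x:x + 2 * radius + 1][foot]
            assert out[y, x] == pytest.approx(window.std(ddof=1), abs=1e-9)


class TestNormalMetric:
    def test_constant_field_scores_zero(self, filter_params):
        mask = SampleMask(np.ones((64, 64), bool))
        field = np.full((64, 64), 0.9)
        assert normal_metric(field, mask, filter_params) <= 1e-7

    def test_checkerboard_rougher_than_constant(self, filter_params):
        yy, xx = np.mgrid[0:64, 0:64]
        checker = 0.8 + 0.1 * ((yy + xx) % 2)
        mask = SampleMask(np.ones((64, 64), bool))
        assert (normal_metric(checker, mask, filter_params)
                > normal_metric(np.full((64, 64), 0.9), mask, filter_params))

    def test_empty_mask_raises(self, filter_params):
        with pytest.raises(EmptyMaskError):
            normal_metric(np.ones((8, 8)), SampleMask(np.zeros((8, 8), bool)),
                          filter_params)


class TestNormaliseBatch:
    def _metricset(self, i, b, s, n):
        return MetricSet(sample_id=f"s{i}", border_raw=b, shininess_raw=s,
                         normal_raw=n)

    def test_single_sample_all_ones_with_warning(self):
        with pytest.warns(UserWarning, match="single-sample"):
            out = normalise_batch([self._metricset(0, 0.3, 0.5, 0.02)])
        assert (out[0].border, out[0].shininess, out[0].normal) == (1, 1, 1)

    def test_division_by_batch_maximum(self):
        out = normalise_batch([self._metricset(0, 0.2, 0.5, 0.01),
                               self._metricset(1, 0.4, 0.25, 0.02)])
        assert [m.border for m in out] == pytest.approx([0.5, 1.0])
        assert [m.shininess for m in out] == pytest.approx([1.0, 0.5])

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(3)
        batch = [self._metricset(i, *rng.uniform(0.01, 1.0, 3)) for i in range(20)]
        once = normalise_batch(batch)
        for name in ("border", "shininess", "normal"):
            vals = [getattr(m, name) for m in once]
            raws = [getattr(m, f"{name}_raw") for m in once]
            assert max(vals) == pytest.approx(1.0)
            assert np.array_equal(np.argsort(vals), np.argsort(raws))
        twice = normalise_batch([
            MetricSet(m.sample_id, m.border, m.shininess, m.normal)
            for m in once
        ])
        for a, b in zip(once, twice):
            assert (a.border, a.shininess, a.normal) == pytest.approx(
                (b.border, b.shininess, b.normal))

    def test_zero_metric_named_in_error(self):
        batch = [self._metricset(0, 0.2, 0.0, 0.1),
                 self._metricset(1, 0.3, 0.0, 0.2)]
        with pytest.raises(NormalisationError, match="shininess"):
            normalise_batch(batch)


class TestTotalScore:
    def test_unit_metrics_score_one(self):
        m = MetricSet("x", 0, 0, 0, border=1.0, shininess=1.0, normal=1.0)
        assert total_score(m) == pytest.approx(1.0)

    def test_unsquared_variant(self):
        m = MetricSet("x", 0, 0, 0, border=0.74, shininess=0.84, normal=0.73)
        assert total_score(m, squared=False) == pytest.approx(0.73 / (0.74 * 0.84),
                                                              abs=5e-4)

    def test_monotone_in_each_metric(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            b, s, n = rng.uniform(0.05, 0.95, 3)
            base = total_score(MetricSet("x", 0, 0, 0, border=b, shininess=s, normal=n))
            up_n = total_score(MetricSet("x", 0, 0, 0, border=b, shininess=s,
                                         normal=n + 0.04))
            up_b = total_score(MetricSet("x", 0, 0, 0, border=b + 0.04, shininess=s,
                                         normal=n))
            up_s = total_score(MetricSet("x", 0, 0, 0, border=b, shininess=s + 0.04,
                                         normal=n))
            assert up_n > base > up_b and base > up_s

    def test_epsilon_guards_zero_denominator(self):
        m = MetricSet("x", 0, 0, 0, border=0.0, shininess=0.5, normal=1.0)
        assert np.isfinite(total_score(m, FilterParams(epsilon=1e-6)))


class TestScoreBatch:
    def test_identical_samples_tie_broken_by_id(self, cohort, filter_params,
                                                seg_params):
        stacks = cohort[3].stacks
        result = score_batch(
            [Sample("b", stacks), Sample("a", stacks)], filter_params, seg_params
        )
        assert [m.sample_id for m in result.metrics] == ["a", "b"]
        assert result.metrics[0].total == result.metrics[1].total
        assert [m.rank for m in result.metrics] == [1, 2]

    def test_failing_sample_isolated(self, cohort, filter_params, seg_params):
        flat = _stack(np.full((4, 64, 64), 0.5))
        samples = [Sample("good-0", cohort[0].stacks),
                   Sample("bad", {"VIS": flat}),
                   Sample("good-1", cohort[9].stacks)]
        result = score_batch(samples, filter_params, seg_params)
        assert set(result.errors) == {"bad"}
        assert sorted(m.sample_id for m in result.metrics) == ["good-0", "good-1"]

    def test_single_band_fallback(self, cohort, filter_params, seg_params):
        vis_only = [Sample(f"v{i}", {"VIS": c.stacks["VIS"]})
                    for i, c in enumerate(cohort[:3])]
        result = score_batch(vis_only, filter_params, seg_params)
        assert len(result.metrics) == 3 and not result.errors
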