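"""Fiber-organization pipeline: segmentation, orientation, variance metrics."""

import numpy as np
import pytest

from scarkit import fibers, simulate
from scarkit.fibers import (
    Box,
    CollagenMap,
    OrientationField,
    RegionLayout,
    TrichromeImage,
    UndefinedMetricError,
    blue_intensity,
    directional_variance,
    estimate_orientation_field,
    fiber_density,
    local_directional_variance,
    overall_directional_variance,
    segment_collagen,
)


def image_from_rgb(rows):
    return TrichromeImage(np.asarray(rows, dtype=float))


class TestSegmentCollagen:
    def test_pure_blue_in_mask_with_full_weight(self):
        img = image_from_rgb([[[0.0, 0.0, 1.0]]])
        cmap = segment_collagen(img)
        assert cmap.mask[0, 0]
        assert cmap.weight[0, 0] == pytest.approx(1.0)

    def test_pure_red_off_mask(self):
        img = image_from_rgb([[[1.0, 0.0, 0.0]]])
        cmap = segment_collagen(img)
        assert not cmap.mask[0, 0]
        assert cmap.weight[0, 0] == 0.0

    def test_neutral_gray_excluded_at_default_threshold(self):
        img = image_from_rgb([[[0.5, 0.5, 0.5]]])
        assert not segment_collagen(img).mask[0, 0]

    def test_all_black_image_gives_empty_mask(self):
        img = TrichromeImage(np.zeros((8, 8, 3)))
        assert not segment_collagen(img).mask.any()

    def test_phantom_mask_fraction_matches_generator_truth(self):
        spec = simulate.PhantomSpec(target_density=0.30, kappa=1.0, seed=9)
        img, truth = simulate.generate_fiber_phantom(spec)
        frac = segment_collagen(img).mask.mean()
        assert frac == pytest.approx(truth.realized_density, abs=0.02)

    def test_invalid_threshold(self):
        img = TrichromeImage(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError):
            segment_collagen(img, ratio_threshold=0.0)


def make_line_map(shape, points, weight=1.0):
    w = np.zeros(shape)
    for y, x in points:
        w[y, x] = weight
    return CollagenMap(mask=w > 0, weight=w)


class TestOrientationField:
    def test_horizontal_line_gives_zero_degrees(self):
        cmap = make_line_map((21, 41), [(10, x) for x in range(5, 36)])
        field = estimate_orientation_field(cmap, window_radius_px=5)
        interior = field.theta_deg[10, 15:26]
        assert np.allclose(np.minimum(interior, 180 - interior), 0.0, atol=1e-6)

    def test_45_degree_line(self):
        pts = [(k, k) for k in range(5, 36)]
        cmap = make_line_map((41, 41), pts)
        field = estimate_orientation_field(cmap, window_radius_px=5)
        vals = [field.theta_deg[k, k] for k in range(12, 30)]
        assert np.allclose(vals, 45.0, atol=0.5)

    def test_perpendicular_crossing_has_low_certainty(self):
        pts = [(10, x) for x in range(21)] + [(y, 10) for y in range(21)]
        cmap = make_line_map((21, 21), pts)
        field = estimate_orientation_field(cmap, window_radius_px=5)
        assert field.certainty[10, 10] < 0.1

    def test_empty_mask_gives_empty_field(self):
        cmap = CollagenMap(mask=np.zeros((8, 8), bool), weight=np.zeros((8, 8)))
        field = estimate_orientation_field(cmap)
        assert not field.defined.any()
        assert np.isnan(field.theta_deg).all()

    def test_line_of_sight_blocks_detached_parallel_line(self):
        # two parallel horizontal lines, 3 px apart: without line-of-sight the
        # neighbour line injects off-axis vectors; with it, each line sees
        # only itself and reports exactly 0 degrees
        pts = [(8, x) for x in range(20)] + [(11, x) for x in range(20)]
        cmap = make_line_map((20, 20), pts)
        strict = estimate_orientation_field(cmap, 6, line_of_sight=True)
        loose = estimate_orientation_field(cmap, 6, line_of_sight=False)
        t = strict.theta_deg[8, 10]
        assert min(t, 180 - t) == pytest.approx(0.0, abs=1e-9)
        assert strict.certainty[8, 10] > loose.certainty[8, 10]

    def test_brute_force_oracle_pixel_for_pixel(self, small_collagen_map):
        """The shifted-mask implementation equals a literal double loop."""
        radius = 5
        field = estimate_orientation_field(small_collagen_map, radius,
                                           line_of_sight=True, certainty_power=3.0)
        mask = small_collagen_map.mask
        wmap = small_collagen_map.weight
        h, w = mask.shape

        def visible(y0, x0, y1, x1):
            dy, dx = y1 - y0, x1 - x0
            n = max(abs(dy), abs(dx))
            for k in range(1, n):
                yy, xx = y0 + k * dy / n, x0 + k * dx / n
                ys = ([round(yy)] if abs(yy - round(yy)) < 0.5 - 1e-9
                      else [int(np.floor(yy)), int(np.ceil(yy))])
                xs = ([round(xx)] if abs(xx - round(xx)) < 0.5 - 1e-9
                      else [int(np.floor(xx)), int(np.ceil(xx))])
                if not any(mask[int(a), int(b)] for a in ys for b in xs
                           if 0 <= a < h and 0 <= b < w):
                    return False
            return True

        for y in range(h):
            for x in range(w):
                if not mask[y, x]:
                    assert not field.defined[y, x]
                    continue
                s = 0j
                tot = 0.0
                for j in range(h):
                    for i in range(w):
                        d2 = (j - y) ** 2 + (i - x) ** 2
                        if d2 == 0 or d2 > radius * radius or wmap[j, i] == 0:
                            continue
                        if not visible(y, x, j, i):
                            continue
                        s += wmap[j, i] * np.exp(2j * np.arctan2(j - y, i - x))
                        tot += wmap[j, i]
                if tot <= 1e-9:
                    assert not field.defined[y, x]
                    continue
                assert field.defined[y, x]
                r = min(abs(s) / tot, 1.0)
                theta = np.degrees(np.angle(s)) / 2.0 % 180.0
                assert field.certainty[y, x] == pytest.approx(r, abs=1e-9)
                dtheta = abs(field.theta_deg[y, x] - theta)
                assert min(dtheta, 180 - dtheta) == pytest.approx(0.0, abs=1e-6)
                assert field.weight[y, x] == pytest.approx(wmap[y, x] * r**3, abs=1e-9)


class TestDirectionalVariance:
    def test_identical_angles_zero(self):
        assert directional_variance([37.0] * 5, [1, 2, 3, 4, 5]) == 0.0

    def test_orthogonal_pair_is_one(self):
        assert directional_variance([10.0, 100.0]) == pytest.approx(1.0, abs=1e-12)

    def test_von_mises_closed_form(self):
        rng = np.random.default_rng(123)
        draws = simulate.sample_axial_orientations(100_000, 45.0, 2.0, rng)
        expected = simulate.theoretical_directional_variance(2.0)
        assert directional_variance(draws) == pytest.approx(expected, abs=0.01)

    def test_zero_weight_raises(self):
        with pytest.raises(UndefinedMetricError):
            directional_variance([1.0, 2.0], [0.0, 0.0])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            directional_variance([1.0], [-1.0])


class TestLocalAndOverallVariance:
    def test_aligned_phantom_local_variance_small(self, aligned_phantom):
        img, _ = aligned_phantom
        field = estimate_orientation_field(segment_collagen(img))
        _, mean = local_directional_variance(field, 50)
        assert mean < 0.05

    def test_uniform_random_field_local_variance_high(self):
        rng = np.random.default_rng(5)
        shape = (120, 120)
        theta = rng.uniform(0, 180, shape)
        field = OrientationField(
            theta_deg=theta,
            certainty=np.ones(shape),
            defined=np.ones(shape, bool),
            weight=np.ones(shape),
        )
        vmap, mean = local_directional_variance(field, 50)
        assert mean > 0.9
        assert np.nanmin(vmap) > 0.8

    def test_local_close_to_overall_on_homogeneous_phantom(self, random_phantom):
        img, _ = random_phantom
        field = estimate_orientation_field(segment_collagen(img))
        overall = overall_directional_variance(field)
        _, local_mean = local_directional_variance(field, 50)
        assert local_mean <= overall + 0.05

    def test_empty_field_raises(self):
        field = OrientationField(
            theta_deg=np.full((8, 8), np.nan),
            certainty=np.full((8, 8), np.nan),
            defined=np.zeros((8, 8), bool),
            weight=np.zeros((8, 8)),
        )
        with pytest.raises(UndefinedMetricError):
            local_directional_variance(field, 5)
        with pytest.raises(UndefinedMetricError):
            overall_directional_variance(field)


class TestDensityAndBlue:
    def test_full_and_empty_masks(self):
        full = CollagenMap(np.ones((10, 10), bool), np.ones((10, 10)))
        empty = CollagenMap(np.zeros((10, 10), bool), np.zeros((10, 10)))
        assert fiber_density(full) == 1.0
        assert fiber_density(empty) == 0.0

    def test_phantom_density_near_target(self):
        spec = simulate.PhantomSpec(target_density=0.6, kappa=2.0, seed=4)
        img, _ = simulate.generate_fiber_phantom(spec)
        assert fiber_density(segment_collagen(img)) == pytest.approx(0.6, abs=0.03)

    def test_blue_intensity_constant_cases(self):
        px = np.zeros((6, 6, 3))
        px[..., 2] = 0.72
        img = TrichromeImage(px)
        cmap = CollagenMap(np.ones((6, 6), bool), np.ones((6, 6)))
        assert blue_intensity(img, cmap) == pytest.approx(0.72)

    def test_phantom_blue_near_spec_level(self, random_phantom):
        img, _ = random_phantom
        cmap = segment_collagen(img)
        assert blue_intensity(img, cmap) == pytest.approx(0.72, abs=0.05)

    def test_empty_region_errors(self):
        cmap = CollagenMap(np.zeros((10, 10), bool), np.zeros((10, 10)))
        img = TrichromeImage(np.zeros((10, 10, 3)))
        with pytest.raises(UndefinedMetricError):
            blue_intensity(img, cmap)


class TestRotationInvariance:
    def test_right_angle_rotations_preserve_metrics(self):
        spec = simulate.PhantomSpec(kappa=1.0, seed=7)
        img, _ = simulate.generate_fiber_phantom(spec)
        ref = None
        for k in range(4):
            im = TrichromeImage(np.rot90(img.pixels, k).copy())
            cmap = segment_collagen(im)
            field = estimate_orientation_field(cmap)
            vals = (
                overall_directional_variance(field),
                fiber_density(cmap),
                blue_intensity(im, cmap),
            )
            if ref is None:
                ref = vals
            assert np.allclose(vals, ref, atol=1e-6)


class TestRegionLayout:
    def test_boxes_must_match_box_size(self):
        boxes = {n: Box(0, i * 40, 32, 32) for i, n in enumerate(("LD", "LP", "RD", "RP"))}
        with pytest.raises(ValueError, match="expected 500x500"):
            RegionLayout(scar=Box(0, 200, 32, 32), boxes=boxes)

    def test_overlapping_boxes_rejected(self):
        boxes = {
            "LD": Box(0, 0, 32, 32),
            "LP": Box(0, 16, 32, 32),  # overlaps LD
            "RD": Box(0, 64, 32, 32),
            "RP": Box(0, 128, 32, 32),
        }
        with pytest.raises(ValueError, match="overlap"):
            RegionLayout(scar=Box(0, 180, 32, 32), boxes=boxes, box_size=32)

    def test_out_of_bounds_detected(self):
        layout = simulate.standard_section_layout(box_size=32, gap=4)
        with pytest.raises(ValueError, match="bounds"):
            layout.validate_bounds((40, 40))


@pytest.fixture(scope="module")
def section():
    layout = simulate.standard_section_layout(box_size=128, gap=8)
    specs = {}
    for i, name in enumerate(("S", "LD", "LP", "RD", "RP")):
        specs[name] = simulate.PhantomSpec(
            image_height_px=128, image_width_px=128, n_fibers=120,
            kappa=0.0 if name == "S" else 5.0,
            mean_orientation_deg=0.0, seed=20 + i,
        )
    image, truths = simulate.generate_section_phantom(specs, layout)
    return image, layout, truths


class TestAnalyzeSection:
    def test_emits_five_region_rows_plus_two_pooled(self, section):
        image, layout, _ = section
        metrics = fibers.analyze_section(image, layout)
        assert list(metrics["region"]) == ["S", "LD", "LP", "RD", "RP", "RD&LD", "RP&LP"]
        for col in ("overall_directional_variance", "mean_local_directional_variance",
                    "fiber_density", "blue_intensity"):
            assert metrics[col].between(0, 1).all()

    def test_disordered_scar_exceeds_aligned_flanks(self, section):
        image, layout, _ = section
        metrics = fibers.analyze_section(image, layout).set_index("region")
        scar = metrics.loc["S", "overall_directional_variance"]
        proximal = metrics.loc["RP&LP", "overall_directional_variance"]
        assert scar > proximal
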