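"""Synthetic-data generators: determinism and ground-truth contracts."""

import numpy as np
import pandas as pd
import pytest

from scarkit import simulate
from scarkit.simulate import (
    MorphometrySimSpec,
    PhantomSpec,
    ScarDecayParams,
    generate_fiber_phantom,
    generate_morphometry_table,
    generate_rater_scores,
    generate_scar_timeseries,
    generate_section_phantom,
    sample_axial_orientations,
    theoretical_directional_variance,
)


class TestPhantomSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kappa": -1.0},
            {"target_density": 1.5},
            {"image_height_px": 32},
            {"fiber_thickness_px": 0},
            {"n_fibers": 0, "target_density": 0.3},
            {"mean_orientation_deg": 180.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)


class TestFiberPhantom:
    def test_determinism_byte_identical(self):
        spec = PhantomSpec(kappa=1.5, seed=77)
        img1, t1 = generate_fiber_phantom(spec)
        img2, t2 = generate_fiber_phantom(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(t1.orientations_deg, t2.orientations_deg)

    def test_degenerate_concentration_orientations(self):
        spec = PhantomSpec(kappa=1e6, mean_orientation_deg=30.0, seed=1)
        _, truth = generate_fiber_phantom(spec)
        dev = np.abs((truth.orientations_deg - 30.0 + 90) % 180 - 90)
        assert dev.max() < 0.1

    def test_uniform_orientations_small_resultant(self):
        rng = np.random.default_rng(11)
        draws = sample_axial_orientations(10_000, 0.0, 0.0, rng)
        resultant = np.abs(np.mean(np.exp(2j * np.radians(draws))))
        assert resultant < 0.02

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 2.0, 5.0])
    def test_drawn_variance_matches_bessel_formula(self, kappa):
        rng = np.random.default_rng(13)
        draws = sample_axial_orientations(10_000, 90.0, kappa, rng)
        v = 1 - np.abs(np.mean(np.exp(2j * np.radians(draws))))
        assert v == pytest.approx(theoretical_directional_variance(kappa), abs=0.02)

    def test_realized_density_close_to_target(self):
        for seed in (0, 1):
            spec = PhantomSpec(target_density=0.4, kappa=1.0, seed=seed)
            _, truth = generate_fiber_phantom(spec)
            assert truth.realized_density == pytest.approx(0.4, abs=0.01)

    def test_theoretical_variance_limits(self):
        assert theoretical_directional_variance(0.0) == 1.0
        assert theoretical_directional_variance(1e4) < 1e-3


class TestSectionPhantom:
    def test_empty_region_map_rejected(self):
        layout = simulate.standard_section_layout(box_size=128, gap=8)
        with pytest.raises(ValueError, match="empty"):
            generate_section_phantom({}, layout)

    def test_shared_spec_gives_matched_densities(self):
        layout = simulate.standard_section_layout(box_size=128, gap=8)
        specs = {
            name: PhantomSpec(image_height_px=128, image_width_px=128,
                              n_fibers=120, kappa=1.0, seed=50 + i)
            for i, name in enumerate(("S", "LD", "LP", "RD", "RP"))
        }
        _, truths = generate_section_phantom(specs, layout)
        densities = [t.realized_density for t in truths.values()]
        assert max(densities) - min(densities) < 0.03


class TestMorphometryTable:
    def test_defaults_reproduce_printed_day7_control_depth(self):
        """Sample mean of day-7 CONT wound depth within 3 SE of 527.2 um."""
        spec = MorphometrySimSpec(n_per_group=1000, seed=3)
        table = generate_morphometry_table(spec)
        sub = table[(table.group == "CONT") & (table.day == 7)]
        se = 279.3 / np.sqrt(1000)
        # truncation at zero biases the mean slightly upward; 3 SE still holds
        assert abs(sub["D"].mean() - 527.2) < 3 * se + 0.02 * 527.2

    def test_zero_sd_reproduces_means_exactly(self):
        moments = {("CONT", 7): {"D": (527.2, 0.0), "N": (1434.4, 0.0)}}
        spec = MorphometrySimSpec(moments=moments, n_per_group=4, seed=0)
        table = generate_morphometry_table(spec)
        assert (table["D"] == 527.2).all()
        assert (table["N"] == 1434.4).all()

    def test_no_negative_values(self):
        spec = MorphometrySimSpec(n_per_group=200, seed=8)
        table = generate_morphometry_table(spec)
        num = table.drop(columns=["animal", "group", "day"])
        assert (num >= 0).all().all()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="negative SD"):
            MorphometrySimSpec(moments={("CONT", 7): {"D": (1.0, -1.0)}})

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            MorphometrySimSpec(n_per_group=1)

    def test_determinism(self):
        a = generate_morphometry_table(MorphometrySimSpec(seed=5))
        b = generate_morphometry_table(MorphometrySimSpec(seed=5))
        pd.testing.assert_frame_equal(a, b)


class TestScarTimeseries:
    def test_zero_noise_exact_exponential_decay(self):
        params = {"CONT": ScarDecayParams(noise_sd=0.0, n_wounds=1)}
        records = generate_scar_timeseries(params, seed=0, days=(1, 4, 7))
        for rec in records:
            assert rec.area_mm2 == pytest.approx(60.0 * np.exp(-0.05 * rec.day))
            assert rec.length_mm == pytest.approx(15.0 * np.exp(-0.005 * rec.day))

    def test_nac30_smaller_early_area(self):
        """Faster decay in the 0.03% group shows up at day 3 over many wounds."""
        base = ScarDecayParams(n_wounds=300)
        fast = ScarDecayParams(area_rate=0.08, width_rate=0.08, n_wounds=300)
        records = generate_scar_timeseries({"CONT": base, "NAC30": fast},
                                           seed=2, days=(3,))
        df = pd.DataFrame([vars(r) for r in records])
        means = df.groupby("group")["area_mm2"].mean()
        assert means["NAC30"] < means["CONT"]

    def test_single_day_series(self):
        params = {"CONT": ScarDecayParams(n_wounds=1)}
        records = generate_scar_timeseries(params, seed=0, days=(1,))
        assert len(records) == 1 and records[0].day == 1

    def test_empty_day_list_rejected(self):
        with pytest.raises(ValueError, match="empty day list"):
            generate_scar_timeseries({"CONT": ScarDecayParams()}, seed=0, days=())

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            ScarDecayParams(area_rate=0.0)


class TestRaterScores:
    @pytest.fixture
    def truth(self):
        return pd.DataFrame([
            {"sample": "S1", "parameter": "granulation", "value": 1.23},
            {"sample": "S1", "parameter": "epithelialization", "value": 2.61},
        ])

    def test_zero_noise_equals_truth_rounded(self, truth):
        scores = generate_rater_scores(truth, noise_sd=0.0, seed=0)
        assert set(scores["score"]) == {1.2, 2.6}
        assert len(scores) == 6  # 2 parameters x 3 raters

    def test_scores_clipped_and_quantized(self, truth):
        scores = generate_rater_scores(truth, noise_sd=5.0, seed=1)
        vals = scores["score"].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 3.0
        assert np.allclose(vals * 10, np.round(vals * 10))

    def test_three_raters_shrink_error_like_sqrt3(self):
        truth = pd.DataFrame([{"sample": "S", "parameter": "p", "value": 1.5}])
        single, triple = [], []
        for rep in range(400):
            s3 = generate_rater_scores(truth, n_raters=3, noise_sd=0.4, seed=rep)
            triple.append(s3["score"].mean() - 1.5)
            single.append(s3["score"].iloc[0] - 1.5)
        ratio = np.std(triple) / np.std(single)
        assert ratio == pytest.approx(1 / np.sqrt(3), abs=0.12)

    def test_invalid_inputs(self, truth):
        with pytest.raises(ValueError):
            generate_rater_scores(truth, n_raters=0)
        with pytest.raises(ValueError):
            generate_rater_scores(truth, noise_sd=-0.1)
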