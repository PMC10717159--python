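"""Generators: determinism, ground-truth consistency, analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormtwitch.segmentation import segment_worm, qc_full_body
from wormtwitch.stats import one_way_anova
from wormtwitch.synthetic import (
    CohortSpec,
    ConditionSpec,
    WormSceneSpec,
    contractility_preset,
    gen_area_series,
    gen_cohort,
    gen_nuclei_image,
    gen_track_image,
    gen_worm_movie,
    rasterize_polyline,
)


class TestAreaSeries:
    def test_zero_amplitude_gives_constant_series_and_no_contractions(self):
        spec = WormSceneSpec(
            baseline_area=1000, contraction_amplitude=0, pixel_noise_sd=0,
            n_frames=50,
        )
        series, truth = gen_area_series(spec)
        assert np.all(series.area_px2 == 1000.0)
        assert truth.true_n_contractions == 0
        assert truth.true_trough_frames.size == 0

    def test_analytic_troughs_of_one_hertz_cosine(self):
        # 43 frames at 0.07 s span 3.01 s; cosine minima at 0.5/1.5/2.5 s
        spec = WormSceneSpec(
            baseline_area=1000, contraction_amplitude=200,
            contraction_freq_hz=1.0, pixel_noise_sd=0, n_frames=43,
        )
        series, truth = gen_area_series(spec)
        assert truth.true_n_contractions == 3
        np.testing.assert_array_equal(truth.true_trough_frames, [7, 21, 36])
        # trough-frame value sits near baseline - amplitude (frame 21 samples
        # t = 1.47 s, slightly off the analytic minimum at 1.5 s)
        assert series.area_px2[21] == pytest.approx(800.0, abs=2.5)

    def test_validation_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            WormSceneSpec(frame_interval_s=0.0)
        with pytest.raises(ValueError):
            WormSceneSpec(baseline_area=100, contraction_amplitude=250)
        with pytest.raises(ValueError):
            WormSceneSpec(n_frames=0)

    @given(
        n_frames=st.integers(5, 200),
        freq=st.floats(0.0, 3.0),
        amplitude=st.floats(0.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ground_truth_trough_count_consistency(self, n_frames, freq, amplitude):
        spec = WormSceneSpec(
            n_frames=n_frames, baseline_area=200.0,
            contraction_amplitude=amplitude, contraction_freq_hz=freq,
            pixel_noise_sd=0.0,
        )
        _, truth = gen_area_series(spec)
        assert truth.true_n_contractions == truth.true_trough_frames.size
        assert np.all(np.diff(truth.true_trough_frames) > 0)


class TestWormMovie:
    def test_noiseless_round_trip_is_pixel_exact(self):
        spec = WormSceneSpec(n_frames=30, pixel_noise_sd=0.0, seed=5)
        stack, truth = gen_worm_movie(spec)
        masks = segment_worm(stack, method="fixed", fixed_threshold=0.5)
        np.testing.assert_array_equal(masks.areas_px2, truth.true_area_per_frame)

    def test_border_contact_frame_touches_border(self):
        spec = WormSceneSpec(
            n_frames=12, pixel_noise_sd=0.0, seed=1,
            body_touches_border_frames=(10,),
        )
        stack, truth = gen_worm_movie(spec)
        masks = segment_worm(stack, method="fixed", fixed_threshold=0.5)
        m10 = masks.masks[10]
        assert m10[0, :].any() or m10[-1, :].any() or m10[:, 0].any() or m10[:, -1].any()
        # all other frames stay clear of the border
        for t in range(12):
            if t == 10:
                continue
            m = masks.masks[t]
            assert not (m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any())
        np.testing.assert_array_equal(masks.areas_px2, truth.true_area_per_frame)

    def test_44_frame_clean_movie_passes_downstream_qc(self):
        spec = WormSceneSpec(n_frames=44, pixel_noise_sd=0.0, seed=2)
        stack, _ = gen_worm_movie(spec)
        masks = segment_worm(stack, method="fixed", fixed_threshold=0.5)
        assert qc_full_body(masks).eligible  # 44 * 0.07 = 3.08 s > 3 s

    def test_worm_too_big_for_canvas_raises(self):
        spec = WormSceneSpec(
            image_height=24, image_width=24, baseline_area=500, n_frames=3
        )
        with pytest.raises(ValueError, match="cannot fit"):
            gen_worm_movie(spec)


class TestTrackImage:
    def test_zero_steps_gives_blank_image(self):
        img, truth = gen_track_image(0, seed=0)
        assert truth.true_trace_area == 0
        assert np.all(img.image == img.image.flat[0])

    def test_single_horizontal_segment_rasterizes_length_pixels(self):
        mask = rasterize_polyline([(30, 10), (30, 109)], 1, (60, 140))
        assert mask.sum() == 100

    def test_self_crossing_path_area_is_union_not_sum(self):
        horiz = rasterize_polyline([(50, 20), (50, 120)], 1, (140, 140))
        vert = rasterize_polyline([(20, 70), (100, 70)], 1, (140, 140))
        union = horiz | vert
        assert union.sum() < horiz.sum() + vert.sum()  # crossing pixel shared
        # a long random walk self-crosses; truth is the union pixel count
        long_walk, truth = gen_track_image(150, step_length_px=18, seed=7)
        trace = long_walk.image < 0.5
        assert truth.true_trace_area == trace.sum()

    def test_walk_stays_on_canvas(self):
        img, truth = gen_track_image(400, step_length_px=30, seed=3)
        assert truth.true_trace_area > 0  # reflection kept the walk inside


class TestNucleiImage:
    def test_zero_nuclei_is_pure_background(self):
        img, truth = gen_nuclei_image(0, seed=0)
        assert truth.true_nuclei_centers.shape == (0, 2)
        assert np.all(img.image == 0.0)

    def test_noiseless_spots_are_local_maxima_at_centers(self):
        img, truth = gen_nuclei_image(16, 12, 2.5, 0.0, seed=4)
        im = img.image
        for r, c in truth.true_nuclei_centers:
            patch = im[r - 1 : r + 2, c - 1 : c + 2]
            assert im[r, c] == patch.max()
        # pairwise separation respected
        centers = truth.true_nuclei_centers.astype(float)
        d2 = ((centers[:, None] - centers[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 12.0**2

    def test_infeasible_packing_raises_naming_constraint(self):
        with pytest.raises(ValueError, match="min_separation"):
            gen_nuclei_image(50, 40.0, 2.5, 0.0, image_size=(100, 100), seed=0)


@pytest.mark.parametrize(
    "make",
    [
        lambda seed: gen_area_series(
            WormSceneSpec(pixel_noise_sd=3.0, n_frames=60, seed=seed)
        )[0].area_px2,
        lambda seed: gen_worm_movie(
            WormSceneSpec(pixel_noise_sd=0.2, n_frames=10, seed=seed)
        )[0].frames,
        lambda seed: gen_track_image(40, seed=seed)[0].image,
        lambda seed: gen_nuclei_image(8, 12, 2.5, 0.05, seed=seed)[0].image,
        lambda seed: gen_cohort(contractility_preset(seed=seed))[0],
    ],
    ids=["series", "movie", "track", "nuclei", "cohort"],
)
def test_generators_are_deterministic_in_seed(make):
    a, b = make(7), make(7)
    if hasattr(a, "equals"):
        assert a.equals(b)
    else:
        np.testing.assert_array_equal(a, b)


class TestCohort:
    def test_zero_dispersion_equal_means_give_f_zero(self):
        cond = lambda g: ConditionSpec(
            genotype=g, endpoints={"contraction_amplitude": (2.0, 0.0)}
        )
        spec = CohortSpec((cond("a"), cond("b"), cond("c")), 10, seed=0)
        table, _ = gen_cohort(spec)
        res = one_way_anova(table, endpoint="contraction_amplitude")
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_count_endpoints_are_integral_and_nonnegative(self):
        spec = CohortSpec(
            (
                ConditionSpec(
                    genotype="wt", endpoints={"nuclei_count": (3.0, 4.0)}
                ),
            ),
            200,
            seed=3,
        )
        table, _ = gen_cohort(spec)
        vals = table["value"].to_numpy()
        assert np.all(vals >= 0)
        assert np.all(vals == np.rint(vals))

    def test_truth_records_condition_means(self):
        table, truth = gen_cohort(contractility_preset(n_animals=5, seed=1))
        labels = set(table["condition"])
        assert set(truth.true_condition_means) == labels
        amp_means = {
            lab: m["contraction_amplitude"]
            for lab, m in truth.true_condition_means.items()
        }
        # double mutant amplitude below single mutant at matched day 4
        d4 = {k: v for k, v in amp_means.items() if k.endswith("|d4")}
        assert min(d4.values()) < max(d4.values())
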