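"""Deviation series, peak detection and contraction metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormtwitch.contraction import (
    AssayConfig,
    QCFailureError,
    contraction_metrics,
    detect_peaks,
    deviation_series,
    moving_average,
    run_contraction_assay,
)
from wormtwitch.segmentation import AreaSeries
from wormtwitch.synthetic import WormSceneSpec, gen_area_series, gen_worm_movie


class TestDeviationSeries:
    def test_worked_example(self, worked_deviation):
        assert worked_deviation.mean_area_px2 == pytest.approx(9.2)
        np.testing.assert_allclose(
            worked_deviation.deviation_px2, [0.8, -1.2, 0.8, -1.2, 0.8]
        )

    def test_constant_series_has_zero_deviations(self):
        dev = deviation_series(AreaSeries([5.0] * 8, 0.07))
        assert np.all(dev.deviation_px2 == 0.0)

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=1, max_size=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_deviations_sum_to_zero(self, areas):
        dev = deviation_series(AreaSeries(areas, 0.07))
        scale = max(1.0, np.abs(dev.deviation_px2).max())
        assert abs(dev.deviation_px2.sum()) <= 1e-9 * scale * len(areas)


class TestDetectPeaks:
    def test_worked_example_peaks(self, worked_deviation):
        peaks = detect_peaks(worked_deviation, 1, 0.5)
        np.testing.assert_array_equal(peaks.lower_peak_frames, [1, 3])
        np.testing.assert_array_equal(peaks.upper_peak_frames, [2])
        np.testing.assert_allclose(peaks.lower_peak_values, [-1.2, -1.2])
        np.testing.assert_allclose(peaks.upper_peak_values, [0.8])

    def test_monotone_series_has_no_interior_peaks(self):
        dev = deviation_series(AreaSeries(np.linspace(100, 10, 20), 0.07))
        peaks = detect_peaks(dev, 1, 0.0)
        assert peaks.lower_peak_frames.size == 0
        assert peaks.upper_peak_frames.size == 0

    def test_clean_cosine_troughs_match_generator_truth(self):
        spec = WormSceneSpec(
            n_frames=143, baseline_area=1000, contraction_amplitude=200,
            contraction_freq_hz=1.0, pixel_noise_sd=0.0,
        )
        series, truth = gen_area_series(spec)
        peaks = detect_peaks(deviation_series(series), 1, 10.0)
        np.testing.assert_array_equal(
            peaks.lower_peak_frames, truth.true_trough_frames
        )

    def test_window_longer_than_series_raises(self, worked_deviation):
        with pytest.raises(ValueError, match="window"):
            detect_peaks(worked_deviation, 7, 0.1)

    def test_upper_and_lower_peaks_alternate(self, rng):
        for _ in range(20):
            dev = deviation_series(
                AreaSeries(rng.normal(100, 10, 80).clip(0), 0.07)
            )
            peaks = detect_peaks(dev, 3, 1.0)
            merged = sorted(
                [(f, "L") for f in peaks.lower_peak_frames]
                + [(f, "U") for f in peaks.upper_peak_frames]
            )
            kinds = [k for _, k in merged]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_matches_scipy_prominence_oracle_on_random_series(self, rng):
        """Peaks must equal an independent extrema+prominence oracle."""
        from _oracles import brute_force_peaks

        for _ in range(200):
            n = int(rng.integers(5, 200))
            x = rng.normal(0, 1, n)
            prom = float(rng.uniform(0.1, 2.0))
            dev = deviation_series(AreaSeries(x - x.min() + 1.0, 0.07))
            mine = detect_peaks(dev, 1, prom)
            ref_lower, ref_upper = brute_force_peaks(dev.deviation_px2, prom)
            np.testing.assert_array_equal(mine.lower_peak_frames, ref_lower)
            np.testing.assert_array_equal(mine.upper_peak_frames, ref_upper)


class TestContractionMetrics:
    def test_worked_example_metrics(self, worked_deviation):
        peaks = detect_peaks(worked_deviation, 1, 0.5)
        res = contraction_metrics(worked_deviation, peaks)
        assert res.n_contractions == 2
        np.testing.assert_allclose(res.amplitudes_px2, [2.0, 2.0])
        assert res.rate_of_change_px2 == pytest.approx(2.0)
        assert res.frequency_hz == pytest.approx(2 / (5 * 0.07))
        assert res.n_analysis_frames == 5

    def test_zero_contraction_movie_flags_undefined_rate(self):
        dev = deviation_series(AreaSeries([100.0] * 30, 0.07))
        res = contraction_metrics(dev, detect_peaks(dev, 1, 0.0))
        assert res.n_contractions == 0
        assert res.frequency_hz == 0.0
        assert not res.rate_defined
        assert np.isnan(res.rate_of_change_px2)

    def test_ten_second_one_hertz_cosine_frequency(self):
        spec = WormSceneSpec(
            n_frames=142, baseline_area=1000, contraction_amplitude=200,
            contraction_freq_hz=1.0, pixel_noise_sd=0.0,
        )
        series, truth = gen_area_series(spec)
        dev = deviation_series(series)
        res = contraction_metrics(dev, detect_peaks(dev, 1, 10.0))
        assert res.n_contractions == truth.true_n_contractions == 10
        assert res.frequency_hz == pytest.approx(10 / (142 * 0.07))

    def test_alternative_rate_formula_divides_again_by_n(self, worked_deviation):
        peaks = detect_peaks(worked_deviation, 1, 0.5)
        alt = contraction_metrics(
            worked_deviation, peaks, rate_formula="mean_excursion_per_contraction"
        )
        assert alt.rate_of_change_px2 == pytest.approx(1.0)

    def test_frequency_identity_holds_exactly(self, rng):
        for _ in range(10):
            x = rng.normal(50, 5, 60).clip(0)
            dev = deviation_series(AreaSeries(x, 0.07))
            res = contraction_metrics(dev, detect_peaks(dev, 3, 1.0))
            assert res.frequency_hz * res.n_analysis_frames * 0.07 == pytest.approx(
                res.n_contractions
            )

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance_and_shift_invariance(self, c, shift):
        base = np.array(
            [100, 90, 104, 88, 101, 93, 107, 86, 99, 95, 103.0]
        )
        dev0 = deviation_series(AreaSeries(base, 0.07))
        res0 = contraction_metrics(dev0, detect_peaks(dev0, 1, 1.0))
        scaled = deviation_series(AreaSeries(base * c, 0.07))
        res_c = contraction_metrics(scaled, detect_peaks(scaled, 1, 1.0 * c))
        assert res_c.n_contractions == res0.n_contractions
        assert res_c.frequency_hz == pytest.approx(res0.frequency_hz)
        assert res_c.rate_of_change_px2 == pytest.approx(
            c * res0.rate_of_change_px2, rel=1e-9
        )
        if shift > -base.min():
            shifted = deviation_series(AreaSeries(base + shift, 0.07))
            res_s = contraction_metrics(shifted, detect_peaks(shifted, 1, 1.0))
            assert res_s.n_contractions == res0.n_contractions
            assert res_s.rate_of_change_px2 == pytest.approx(
                res0.rate_of_change_px2, rel=1e-9
            )


class TestRunContractionAssay:
    CFG = AssayConfig(
        threshold_method="fixed", fixed_threshold=0.5,
        prominence_iqr_fraction=0.5,
    )

    def test_noiseless_movie_recovers_truth_exactly(self):
        spec = WormSceneSpec(n_frames=72, pixel_noise_sd=0.0, seed=21)
        stack, truth = gen_worm_movie(spec)
        res = run_contraction_assay(stack, self.CFG)
        assert res.n_contractions == truth.true_n_contractions
        assert res.n_analysis_frames == 72

    def test_short_movie_fails_qc_with_explicit_error(self):
        spec = WormSceneSpec(n_frames=42, pixel_noise_sd=0.0, seed=8)
        stack, _ = gen_worm_movie(spec)
        with pytest.raises(QCFailureError, match="full-body"):
            run_contraction_assay(stack, self.CFG)

    def test_noisy_movie_frequency_within_five_percent(self):
        freqs = []
        for seed in range(5):
            spec = WormSceneSpec(
                n_frames=143, baseline_area=600, contraction_amplitude=100,
                contraction_freq_hz=1.0, pixel_noise_sd=0.35, seed=300 + seed,
            )
            stack, _ = gen_worm_movie(spec)
            res = run_contraction_assay(stack, self.CFG)
            # analytic trough count over the window, not the nominal 1 Hz
            expected = 10 / (143 * 0.07)
            freqs.append(res.frequency_hz / expected)
        assert np.all(np.abs(np.asarray(freqs) - 1.0) < 0.05)

    def test_provenance_records_analysis_window(self):
        spec = WormSceneSpec(n_frames=60, pixel_noise_sd=0.0, seed=9)
        stack, _ = gen_worm_movie(spec)
        res = run_contraction_assay(stack, self.CFG)
        assert res.provenance["window_start_frame"] == 0
        assert res.provenance["window_stop_frame"] == 60
        assert res.provenance["threshold_method"] == "fixed"


def test_moving_average_edges_shrink_window():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    sm = moving_average(x, 3)
    np.testing.assert_allclose(sm, [1.5, 2.0, 3.0, 4.0, 4.5])
    np.testing.assert_allclose(moving_average(x, 1), x)
    with pytest.raises(ValueError):
        moving_average(x, 2)
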