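"""Baseline, noise, peak detection/centroiding and external calibration."""

import numpy as np
import pytest

import ttrscreen as t
from ttrscreen.errors import CalibrationError
from ttrscreen.signal import Peak

GRID = np.arange(1000.0, 20000.0, 0.5)
SIGMA_FACTOR = 2.3548200450309493


def gaussian(mz, center, sigma, amp=1000.0):
    return amp * np.exp(-((mz - center) ** 2) / (2 * sigma**2))


def make_spectrum(intensity, mz=GRID):
    return t.Spectrum(mz=mz.copy(), intensity=intensity)


class TestBaseline:
    def test_flat_spectrum_returns_constant(self):
        spec = make_spectrum(np.full_like(GRID, 7.5))
        assert np.allclose(t.estimate_baseline(spec), 7.5, atol=1e-9)

    def test_near_zero_under_isolated_peak(self):
        sigma = 13761.4 / (1500 * SIGMA_FACTOR)
        spec = make_spectrum(gaussian(GRID, 13761.4, sigma))
        baseline = t.estimate_baseline(spec, window=200.0)
        near = np.abs(GRID - 13761.4) < 50
        assert baseline[near].max() < 0.05 * spec.intensity.max()

    def test_tracks_exponential_background(self):
        truth = 60.0 * np.exp(-GRID / 3000.0)
        spec = make_spectrum(truth.copy())
        baseline = t.estimate_baseline(spec, window=200.0)
        interior = slice(1000, len(GRID) - 1000)
        rel_err = np.abs(baseline[interior] - truth[interior]) / truth[interior]
        assert rel_err.max() < 0.05

    def test_window_too_small_rejected(self):
        spec = make_spectrum(np.ones_like(GRID))
        with pytest.raises(ValueError):
            t.estimate_baseline(spec, window=1.0)


class TestNoise:
    def test_noiseless_floor_away_from_peak(self):
        sigma = 13761.4 / (1500 * SIGMA_FACTOR)
        spec = make_spectrum(gaussian(GRID, 13761.4, sigma))
        baseline = t.estimate_baseline(spec)
        noise = t.estimate_noise(spec, baseline)
        assert np.all(noise > 0)
        far = np.abs(GRID - 13761.4) > 500
        assert noise[far].max() < 1e-3

    def test_unit_gaussian_noise_recovered(self):
        rng = np.random.default_rng(42)
        spec = make_spectrum(np.clip(rng.normal(100.0, 1.0, GRID.shape), 0, None))
        baseline = np.full_like(GRID, 100.0)
        noise = t.estimate_noise(spec, baseline)
        # windowed estimates should concentrate near sd=1
        frac_ok = np.mean((noise > 0.8) & (noise < 1.2))
        assert frac_ok >= 0.95

    def test_mad_robust_to_single_spikes(self):
        rng = np.random.default_rng(7)
        base_int = np.clip(rng.normal(100.0, 1.0, GRID.shape), 0, None)
        spec_clean = make_spectrum(base_int.copy())
        spiked = base_int.copy()
        spiked[::200] += 500.0  # one huge spike per 100-Da window
        spec_spiked = make_spectrum(spiked)
        baseline = np.full_like(GRID, 100.0)
        n_clean = t.estimate_noise(spec_clean, baseline)
        n_spiked = t.estimate_noise(spec_spiked, baseline)
        assert np.median(np.abs(n_spiked - n_clean) / n_clean) < 0.10


class TestDetectPeaks:
    def test_zero_spectrum_yields_no_peaks(self):
        spec = make_spectrum(np.zeros_like(GRID))
        assert t.detect_peaks(spec, np.zeros_like(GRID), np.full_like(GRID, 1e-9)) == []

    def test_single_gaussian_centroid_and_fwhm(self):
        center, R = 13761.4, 1500.0
        sigma = center / (R * SIGMA_FACTOR)
        spec = make_spectrum(gaussian(GRID, center, sigma))
        peaks = t.detect_peaks(spec, np.zeros_like(GRID), np.full_like(GRID, 1.0))
        assert len(peaks) == 1
        pk = peaks[0]
        assert abs(pk.centroid_mz - center) <= 0.25  # grid_step / 2
        assert pk.fwhm == pytest.approx(center / R, rel=0.10)
        assert pk.snr == pytest.approx(1000.0, rel=0.01)

    @pytest.mark.parametrize("separation, n_expected", [(32.0, 2), (0.94, 1)])
    def test_doublet_resolution(self, separation, n_expected):
        center = 13761.4
        sigma = center / (1500 * SIGMA_FACTOR)
        inten = gaussian(GRID, center, sigma) + gaussian(GRID, center + separation, sigma)
        spec = make_spectrum(inten)
        peaks = t.detect_peaks(spec, np.zeros_like(GRID), np.full_like(GRID, 1.0))
        big = [p for p in peaks if p.apex_intensity > 100]
        assert len(big) == n_expected

    def test_shallow_valley_merges_into_one_peak(self):
        # 9.9-Da separation at FWHM ~9.2: two maxima exist but the valley
        # stays above 75% of the lower apex, so one peak is reported
        center = 13761.4
        sigma = center / (1500 * SIGMA_FACTOR)
        inten = gaussian(GRID, center, sigma) + gaussian(GRID, center + 9.9, sigma)
        spec = make_spectrum(inten)
        peaks = t.detect_peaks(spec, np.zeros_like(GRID), np.full_like(GRID, 1.0))
        assert len([p for p in peaks if p.apex_intensity > 100]) == 1

    def test_raising_snr_threshold_never_adds_peaks(self):
        spec, _ = t.simulate_spectrum(
            t.SimulationConfig(seed=3), t.Genotype.from_label("Val30Met")
        )
        baseline = t.estimate_baseline(spec)
        noise = t.estimate_noise(spec, baseline)
        counts = [
            len(t.detect_peaks(spec, baseline, noise, snr_min=s))
            for s in (2, 5, 10, 25, 100)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_centroid_accuracy_under_noise(self):
        """Sub-grid positioning: median error well under the 0.5-Da grid."""
        errors = []
        for seed in range(100):
            cfg = t.SimulationConfig(
                seed=seed, include_calibrants=False, include_doubly_charged=False
            )
            spec, truth = t.simulate_spectrum(cfg, t.Genotype())
            baseline = t.estimate_baseline(spec)
            noise = t.estimate_noise(spec, baseline)
            peaks = t.detect_peaks(spec, baseline, noise)
            wt = max(peaks, key=lambda p: p.apex_intensity)
            errors.append(abs(wt.centroid_mz - truth.wt_mass))
        assert np.median(errors) < 0.5
        assert max(errors) < 2.0

    def test_calibrants_always_found(self):
        for seed in (0, 5, 17):
            spec, _ = t.simulate_spectrum(t.SimulationConfig(seed=seed), t.Genotype())
            peaks = t.detect_peaks(spec, snr_min=10)
            for ref in t.calibrant_masses():
                assert any(abs(p.centroid_mz - ref) < 2.0 for p in peaks)


def peak_at(mz, intensity=500.0):
    return Peak(centroid_mz=mz, apex_intensity=intensity, fwhm=8.0, snr=100.0, area=4000.0)


class TestCalibration:
    def test_identity_when_observed_equals_reference(self):
        peaks = [peak_at(m) for m in t.calibrant_masses()]
        model = t.fit_calibration(peaks, t.calibrant_masses())
        assert model.slope == pytest.approx(1.0, abs=1e-9)
        assert model.offset == pytest.approx(0.0, abs=1e-6)
        assert model.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_recovers_affine_warp_exactly(self):
        peaks = [peak_at((m - 3.0) / 1.0005) for m in t.calibrant_masses()]
        model = t.fit_calibration(peaks, t.calibrant_masses())
        assert model.slope == pytest.approx(1.0005, abs=1e-6)
        assert model.offset == pytest.approx(3.0, abs=1e-3)
        assert model.rms_residual < 0.01

    def test_single_match_is_an_error(self):
        peaks = [peak_at(5734.51)]
        with pytest.raises(CalibrationError, match="1 of 4"):
            t.fit_calibration(peaks, t.calibrant_masses())

    def test_two_point_fit_equals_closed_form(self):
        refs = [5734.51, 16952.30]
        obs = [5730.0, 16945.0]
        model = t.fit_calibration([peak_at(o) for o in obs], refs)
        slope = (refs[1] - refs[0]) / (obs[1] - obs[0])
        offset = refs[0] - slope * obs[0]
        assert model.slope == pytest.approx(slope, abs=1e-12)
        assert model.offset == pytest.approx(offset, abs=1e-6)

    def test_equidistant_tie_goes_to_more_intense(self):
        refs = [5734.51, 16952.30]
        peaks = [
            peak_at(5734.51 - 2.0, intensity=100.0),
            peak_at(5734.51 + 2.0, intensity=900.0),
            peak_at(16952.30),
        ]
        model = t.fit_calibration(peaks, refs)
        # the intense peak at +2 won the tie: it is mapped onto the reference
        assert model(5734.51 + 2.0) == pytest.approx(5734.51, abs=1e-6)

    def test_apply_identity_is_idempotent(self):
        spec, _ = t.simulate_spectrum(t.SimulationConfig(seed=1), t.Genotype())
        model = t.CalibrationModel.identity()
        out = t.apply_calibration(spec, model)
        assert np.array_equal(out.mz, spec.mz)

    def test_apply_offset_shifts_centroids(self):
        model = t.CalibrationModel(slope=1.0, offset=5.0, rms_residual=0.0, n_points=2)
        shifted = t.apply_calibration([peak_at(1000.0), peak_at(2000.0)], model)
        assert [p.centroid_mz for p in shifted] == [1005.0, 2005.0]

    @pytest.mark.parametrize("slope", [0.999, 1.001])
    @pytest.mark.parametrize("offset", [-5.0, 0.0, 5.0])
    def test_warp_then_calibrate_round_trip(self, slope, offset):
        cfg = t.SimulationConfig(seed=11, miscal_slope=slope, miscal_offset=offset)
        spec, truth = t.simulate_spectrum(cfg, t.Genotype())
        baseline = t.estimate_baseline(spec)
        noise = t.estimate_noise(spec, baseline)
        peaks = t.detect_peaks(spec, baseline, noise)
        model = t.fit_calibration(peaks, t.calibrant_masses())
        calibrated = t.apply_calibration(peaks, model)
        wt = max(calibrated, key=lambda p: p.apex_intensity)
        assert abs(wt.centroid_mz - truth.wt_mass) < 0.5
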