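"""Phantom rendering, noise calibration, and the correlated-noise simulator."""

import math

import numpy as np
import pytest

from ct4dnr import (
    AcquisitionParams,
    PhantomSpec,
    PhaseImage,
    PhaseSeries,
    calibrate_noise,
    make_phantom,
    simulate_series,
)


class TestRendering:
    def test_water_is_uniform(self):
        img = make_phantom(PhantomSpec.water(background_hu=0.0, grid_size=64))
        assert np.all(img.pixels == 0.0)

    def test_lowcontrast_disk_levels(self):
        # direct geometry check: disk centre carries background + contrast,
        # pixels far outside the disk carry the background alone
        spec = PhantomSpec.catphan(background_hu=63.4, disk_contrast_hu=10.0)
        img = make_phantom(spec)
        n = spec.grid_size
        assert img.pixels[n // 2, n // 2] == pytest.approx(73.4)
        assert img.pixels[5, 5] == pytest.approx(63.4)

    def test_wire_peak_at_offset(self):
        # rendering oracle: brightest pixel within half a pixel of the offset
        spec = PhantomSpec.wire(wire_offset_mm=(5.0, 5.0))
        img = make_phantom(spec)
        iy, ix = np.unravel_index(np.argmax(img.pixels), img.shape)
        x, y = img.coords_mm()
        assert abs(x[iy, ix] - 5.0) <= spec.spacing_mm / 2
        assert abs(y[iy, ix] - 5.0) <= spec.spacing_mm / 2

    def test_wire_line_integral_exact(self):
        spec = PhantomSpec.wire(wire_area_hu_mm2=2500.0)
        img = make_phantom(spec)
        assert img.pixels.sum() * spec.spacing_mm ** 2 == pytest.approx(2500.0, rel=1e-9)

    @pytest.mark.parametrize("kwargs", [
        dict(kind="nonsense"),
        dict(kind="catphan_lowcontrast", disk_diameter_mm=300.0, field_of_view_mm=250.0),
        dict(kind="catphan_lowcontrast", disk_diameter_mm=-1.0),
        dict(kind="wire", wire_offset_mm=(40.0, 0.0), field_of_view_mm=50.0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)


class TestCalibration:
    def test_cnr_target(self):
        # sigma = contrast / CNR when the PSF blur is off
        spec = PhantomSpec.catphan(disk_contrast_hu=10.0)
        acq = AcquisitionParams(kernel_sigma_mm=0.0)
        assert calibrate_noise("cnr", 1.18, spec, acq) == pytest.approx(10.0 / 1.18)

    def test_mse_plateau_target(self):
        # decorrelated two-frame MSE plateau = 2 sigma^2
        spec = PhantomSpec.catphan()
        acq = AcquisitionParams()
        assert calibrate_noise("mse_plateau", 151.0, spec, acq) == pytest.approx(
            math.sqrt(151.0 / 2.0))

    def test_sd_identity(self):
        assert calibrate_noise("sd", 1.0, PhantomSpec.water(), AcquisitionParams()) == 1.0

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            calibrate_noise("sd", 0.0, PhantomSpec.water(), AcquisitionParams())

    def test_dose_scaling_law(self):
        acq = AcquisitionParams(sigma_ref_hu=8.0, mas_per_rot=114.0, reference_mas=456.0)
        assert acq.noise_sd_hu() == pytest.approx(16.0)
        ir = AcquisitionParams(sigma_ref_hu=8.0, recon_flavor="IR_like", ir_noise_scale=0.944)
        assert ir.noise_sd_hu() == pytest.approx(8.0 * 0.944)


class TestSeriesSimulation:
    def test_noiseless_limit(self):
        spec = PhantomSpec.catphan(grid_size=64)
        acq = AcquisitionParams(sigma_ref_hu=0.0)
        series = simulate_series(spec, acq, seed=0)
        for frame in series.frames:
            np.testing.assert_array_equal(frame.pixels, series.ground_truth.pixels)

    def test_noise_unbiased(self):
        # zero-mean noise: residual mean over 10 independent-phase series
        spec = PhantomSpec.water(grid_size=256)
        acq = AcquisitionParams(sigma_ref_hu=10.0)
        resid = []
        for rep in range(10):
            s = simulate_series(spec, acq, interval_ms=90.0, seed=rep)
            resid.extend((f.pixels - s.ground_truth.pixels).mean() for f in s.frames)
        assert abs(np.mean(resid)) < 0.05

    @pytest.mark.parametrize("delta,rho", [
        (10.0, 6 / 7), (30.0, 4 / 7), (35.0, 0.5), (50.0, 2 / 7), (70.0, 0.0), (90.0, 0.0),
    ])
    def test_triangular_correlation_law(self, delta, rho):
        # empirical inter-frame noise correlation matches max(0, 1 - d/70)
        spec = PhantomSpec.water(grid_size=384)
        acq = AcquisitionParams(sigma_ref_hu=8.0, window_ms=70.0)
        s = simulate_series(spec, acq, n_phases=2, interval_ms=delta, seed=7)
        a = (s[0].pixels - s.ground_truth.pixels).ravel()
        b = (s[1].pixels - s.ground_truth.pixels).ravel()
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(rho, abs=0.02)

    def test_degenerate_zero_interval_shares_noise(self):
        spec = PhantomSpec.water(grid_size=64)
        acq = AcquisitionParams(sigma_ref_hu=5.0)
        s = simulate_series(spec, acq, interval_ms=0.0, seed=0)
        np.testing.assert_array_equal(s[0].pixels, s[2].pixels)

    def test_empirical_dose_ratio(self):
        # quarter dose doubles the noise SD within 2%
        spec = PhantomSpec.water(grid_size=384)
        sds = {}
        for mas in (456.0, 114.0):
            acq = AcquisitionParams(sigma_ref_hu=8.0, mas_per_rot=mas)
            s = simulate_series(spec, acq, n_phases=1, seed=11)
            sds[mas] = (s[0].pixels - s.ground_truth.pixels).std()
        assert sds[114.0] / sds[456.0] == pytest.approx(2.0, rel=0.02)

    def test_seed_determinism(self):
        spec = PhantomSpec.catphan(grid_size=64)
        acq = AcquisitionParams(sigma_ref_hu=8.0)
        a = simulate_series(spec, acq, seed=42)
        b = simulate_series(spec, acq, seed=42)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.pixels, fb.pixels)

    def test_colored_noise_keeps_sd_and_correlation(self):
        spec = PhantomSpec.water(grid_size=384)
        acq = AcquisitionParams(sigma_ref_hu=8.0, noise_colored=True, window_ms=70.0)
        s = simulate_series(spec, acq, n_phases=2, interval_ms=35.0, seed=5)
        a = s[0].pixels - s.ground_truth.pixels
        b = s[1].pixels - s.ground_truth.pixels
        assert a.std() == pytest.approx(8.0, rel=0.02)
        assert np.corrcoef(a.ravel(), b.ravel())[0, 1] == pytest.approx(0.5, abs=0.03)

    def test_incommensurate_interval_rejected(self):
        spec = PhantomSpec.water(grid_size=32)
        with pytest.raises(ValueError):
            simulate_series(spec, AcquisitionParams(), interval_ms=12.5, seed=0)

    def test_zero_phases_rejected(self):
        with pytest.raises(ValueError):
            simulate_series(PhantomSpec.water(grid_size=32), AcquisitionParams(), n_phases=0)


class TestSeriesType:
    def test_even_length_has_no_center(self):
        img = PhaseImage(np.zeros((8, 8)), 1.0, 0.0)
        img2 = PhaseImage(np.zeros((8, 8)), 1.0, 50.0)
        series = PhaseSeries([img, img2], 50.0, img)
        with pytest.raises(ValueError):
            series.center_index

    def test_mismatched_frames_rejected(self):
        a = PhaseImage(np.zeros((8, 8)), 1.0, 0.0)
        b = PhaseImage(np.zeros((4, 4)), 1.0, 50.0)
        with pytest.raises(ValueError):
            PhaseSeries([a, b], 50.0, a)

    def test_nonfinite_pixels_rejected(self):
        with pytest.raises(ValueError):
            PhaseImage(np.array([[np.nan, 0.0], [0.0, 0.0]]), 1.0)
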