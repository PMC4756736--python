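"""CNR, MSE, wire-method MTF and radial NPS estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ct4dnr import (
    AcquisitionParams,
    PhantomSpec,
    PhaseImage,
    ROISpec,
    TNRParams,
    blurred_phantom,
    cnr,
    denoise_series,
    mse,
    mtf_wire,
    noise_from_replicates,
    noise_sd,
    nps_radial,
    simulate_series,
)
from ct4dnr.metrics import roi_mean


def _image(pixels, spacing=1.0):
    return PhaseImage(np.asarray(pixels, dtype=float), spacing)


class TestROIStatistics:
    def test_cnr_exact_arithmetic(self):
        # target constant 73.4; background pair {69.39, 57.41} has mean 63.4
        # and sample SD 8.475, so CNR = 10 / 8.475 = 1.18
        img = np.full((16, 16), 63.4)
        img[7:9, 2:4] = 73.4                       # target ROI pixels
        img[7:9, 12] = (69.3925, 57.4075)          # background ROI pixels
        pi = _image(img)
        # ROIs tight around the four target pixels / the two bg pixels
        target = ROISpec((-5.0, 0.0), 0.8, role="target")
        background = ROISpec((4.5, 0.0), 0.6, role="background")
        assert roi_mean(pi, target) == pytest.approx(73.4)
        assert roi_mean(pi, background) == pytest.approx(63.4)
        assert cnr(pi, target, background) == pytest.approx(10.0 / 8.475, rel=1e-4)

    def test_cnr_zero_for_equal_means(self):
        rng = np.random.default_rng(0)
        pi = _image(63.4 + rng.standard_normal((64, 64)))
        target = ROISpec((-10.0, 0.0), 5.0, role="target")
        background = ROISpec((12.0, 0.0), 5.0, role="background")
        assert cnr(pi, target, background) == pytest.approx(0.0, abs=0.5)

    def test_cnr_undefined_for_zero_background_sd(self):
        pi = _image(np.full((32, 32), 5.0))
        with pytest.raises(ValueError):
            cnr(pi, ROISpec((-8, 0), 3, role="target"), ROISpec((8, 0), 3))

    def test_cnr_requires_disjoint_rois(self):
        pi = _image(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            cnr(pi, ROISpec((0, 0), 5, role="target"), ROISpec((2, 0), 5))

    def test_cnr_noise_scale_equivariance(self):
        # scaling the (ROI-mean-free) noise by c scales CNR by exactly 1/c
        rng = np.random.default_rng(3)
        gt = np.full((128, 128), 63.4)
        gt[54:74, 54:74] = 73.4
        noise = rng.standard_normal((128, 128)) * 8.0
        target = ROISpec((0.0, 0.0), 8.0, role="target")
        background = ROISpec((40.0, 0.0), 15.0, role="background")
        base = _image(gt)
        for roi in (target, background):
            m = (base.coords_mm()[0] - roi.center_mm[0]) ** 2 + \
                (base.coords_mm()[1] - roi.center_mm[1]) ** 2 <= roi.radius_mm ** 2
            noise[m] -= noise[m].mean()
        c1 = cnr(_image(gt + noise), target, background)
        c3 = cnr(_image(gt + 3.0 * noise), target, background)
        assert c3 == pytest.approx(c1 / 3.0, rel=1e-9)

    def test_noise_sd_hand_value(self):
        img = np.zeros((8, 8))
        img[3:5, 4] = (62.0, 64.0)
        pi = _image(img)
        assert noise_sd(pi, ROISpec((0.5, 0.0), 0.6)) == pytest.approx(math.sqrt(2.0))

    def test_noise_sd_constant_is_zero(self):
        pi = _image(np.full((16, 16), 4.0))
        assert noise_sd(pi, ROISpec((0, 0), 5)) == 0.0

    def test_calibrated_sd_recovered(self):
        # a calibrated sigma = 8.475 field reads back within 0.2 HU on ~1e4 px
        spec = PhantomSpec.water(grid_size=256)
        s = simulate_series(spec, AcquisitionParams(sigma_ref_hu=8.475), seed=4)
        roi = ROISpec((0, 0), 45.0)
        assert noise_sd(s[0], roi) == pytest.approx(8.475, abs=0.2)

    def test_roi_outside_image_rejected(self):
        pi = _image(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            roi_mean(pi, ROISpec((7.0, 0.0), 3.0))


class TestMSE:
    def test_identical_images_zero(self):
        a = _image(np.arange(16).reshape(4, 4))
        assert mse(a, a) == 0.0

    def test_hand_arithmetic(self):
        a = _image([[0, 0], [0, 0]])
        b = _image([[1, 1], [3, 1]])
        assert mse(a, b) == pytest.approx(3.0)

    def test_independent_noise_plateau(self):
        # E[MSE] = 2 sigma^2 for independent frames
        sigma = math.sqrt(151.0 / 2.0)
        rng = np.random.default_rng(5)
        a = _image(sigma * rng.standard_normal((512, 512)))
        b = _image(sigma * rng.standard_normal((512, 512)))
        assert mse(a, b) == pytest.approx(151.0, rel=0.02)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_symmetry_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        a = _image(rng.normal(size=(8, 8)))
        b = _image(rng.normal(size=(8, 8)))
        assert mse(a, b) == mse(b, a)
        assert mse(a, b) >= 0.0
        assert (mse(a, b) == 0.0) == bool(np.array_equal(a.pixels, b.pixels))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(_image(np.zeros((4, 4))), _image(np.zeros((8, 8))))


class TestMTF:
    def test_sharp_wire_never_reaches_10_percent(self):
        # an unblurred (near-delta) wire keeps MTF well above 0.1 to Nyquist
        curve = mtf_wire(blurred_phantom(PhantomSpec.wire(), 0.0))
        assert curve.mtf10 is None
        assert curve.values[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("s", [0.4, 0.6, 0.8])
    def test_gaussian_psf_closed_form(self, s):
        # MTF(f) = exp(-2 pi^2 s^2 f^2)  =>  mtf10 = sqrt(ln 10 / 2 pi^2) / s
        spec = PhantomSpec.wire(grid_size=512, wire_fwhm_mm=0.05)
        curve = mtf_wire(blurred_phantom(spec, s))
        closed = math.sqrt(math.log(10.0) / (2 * math.pi ** 2)) / s
        assert curve.mtf10 == pytest.approx(closed, rel=0.03)

    def test_reference_width_value(self):
        # the 0.62 mm system PSF corresponds to a 0.55 cycles/mm MTF10%
        curve = mtf_wire(blurred_phantom(PhantomSpec.wire(), 0.621))
        assert curve.mtf10 == pytest.approx(0.55, abs=0.01)

    def test_temporal_averaging_preserves_resolution(self):
        # averaging registered frames is linear: MTF10% moves < 0.01 cycles/mm
        spec = PhantomSpec.wire()
        acq = AcquisitionParams(sigma_ref_hu=8.475, kernel_sigma_mm=0.62, window_ms=50.0)
        s = simulate_series(spec, acq, seed=6)
        single = mtf_wire(s.center).mtf10
        filtered = mtf_wire(denoise_series(s, TNRParams())).mtf10
        assert abs(filtered - single) < 0.01

    def test_wire_not_found_raises(self):
        rng = np.random.default_rng(7)
        img = PhaseImage(rng.standard_normal((128, 128)), 0.2)
        with pytest.raises(ValueError):
            mtf_wire(img)


class TestNPS:
    def _white_fields(self, sigma, n=10, size=256, spacing=0.5, seed=8):
        rng = np.random.default_rng(seed)
        return [PhaseImage(sigma * rng.standard_normal((size, size)), spacing)
                for _ in range(n)]

    def test_zero_noise_zero_spectrum(self):
        fields = [PhaseImage(np.zeros((64, 64)), 0.5) for _ in range(3)]
        curve = nps_radial(fields)
        assert np.all(curve.values == 0.0)
        assert curve.total_variance == 0.0

    def test_white_noise_flat_level_and_parseval(self):
        # white noise sigma^2 = 64 at 0.5 mm spacing: NPS = 64 * 0.25 = 16
        fields = self._white_fields(8.0)
        curve = nps_radial(fields)
        assert np.median(curve.values) == pytest.approx(16.0, rel=0.05)
        assert curve.total_variance == pytest.approx(64.0, rel=0.05)

    def test_parseval_for_colored_noise(self):
        spec = PhantomSpec.water(grid_size=256)
        acq = AcquisitionParams(sigma_ref_hu=8.0, noise_colored=True)
        fields = [PhaseImage(simulate_series(spec, acq, n_phases=1, seed=i)[0].pixels,
                             spec.spacing_mm) for i in range(8)]
        var = np.mean([(f.pixels - f.pixels.mean()) ** 2 for f in fields])
        curve = nps_radial(fields)
        assert curve.total_variance == pytest.approx(var, rel=0.05)

    def test_ensemble_subtraction_unbiased(self):
        fields = noise_from_replicates(self._white_fields(8.0, n=10))
        curve = nps_radial(fields)
        assert curve.total_variance == pytest.approx(64.0, rel=0.05)

    def test_three_frame_average_reduces_uniformly(self):
        # equal-weight average of 3 iid frames: NPS ratio ~ 1/3, flat in f
        singles, averaged = [], []
        for i in range(10):
            rng = np.random.default_rng(100 + i)
            frames = [8.0 * rng.standard_normal((256, 256)) for _ in range(3)]
            singles.append(PhaseImage(frames[0], 0.5))
            averaged.append(PhaseImage(np.mean(frames, axis=0), 0.5))
        r = nps_radial(singles)
        a = nps_radial(averaged)
        ratio = a.values / r.values
        assert ratio.mean() == pytest.approx(1 / 3, rel=0.05)
        assert ratio.std(ddof=1) < 0.10 * ratio.mean()

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            noise_from_replicates(self._white_fields(1.0, n=1))

    def test_roi_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            nps_radial(self._white_fields(1.0, n=2, size=32), roi_size_px=64)
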