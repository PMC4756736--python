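"""Digital CT phantoms and simulation of short-interval phase series.

This module renders noiseless 2D slices of three classic image-quality
phantoms — a Catphan-CTP515-like low-contrast slice, a thin offset wire, and
a uniform water slice — and turns them into replicate *phase series*: short
sequences of images of the same (static) object reconstructed at cardiac
phase times a few tens of milliseconds apart, as produced by retrospectively
ECG-gated cardiac CT with padding phases.

The noise model captures the two properties that matter for temporal noise
reduction on such series:

* **dose scaling** — zero-mean Gaussian noise whose standard deviation scales
  as ``1/sqrt(mAs)`` relative to a calibrated reference dose;
* **phase correlation** — two phases whose reconstruction windows overlap
  share projection data, so their noise is correlated.  With a rectangular
  reconstruction window of length ``W`` the correlation at phase lag ``d``
  is triangular, ``rho(d) = max(0, 1 - d/W)``.  A 280 ms rotation with half
  reconstruction gives ``W ~ 70 ms``, so phases 70 ms or more apart carry
  independent noise.

The correlated fields are built constructively: a pool of white noise fields
indexed by time step is summed over each frame's reconstruction window, which
realises the triangular law exactly for any commensurate interval/window pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

__all__ = [
    "PhantomSpec",
    "AcquisitionParams",
    "PhaseImage",
    "PhaseSeries",
    "make_phantom",
    "blurred_phantom",
    "effective_contrast",
    "calibrate_noise",
    "simulate_series",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

PHANTOM_KINDS = ("catphan_lowcontrast", "wire", "water")
RECON_FLAVORS = ("FBP_like", "IR_like")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material description of a noiseless phantom slice.

    Coordinates are in millimetres with the image centre as origin.

    Parameters
    ----------
    kind:
        One of ``catphan_lowcontrast``, ``wire``, ``water``.
    background_hu:
        Attenuation of the bulk material (HU).
    disk_contrast_hu, disk_diameter_mm:
        Added attenuation and diameter of the low-contrast disk
        (``catphan_lowcontrast`` only).
    wire_offset_mm:
        (x, y) offset of the wire from the isocentre; offsetting the wire
        makes the pixel grid sample the point-spread function at many
        sub-pixel phases, which is what the wire method exploits.
    wire_fwhm_mm, wire_area_hu_mm2:
        Intrinsic width (FWHM) of the wire and its total line integral
        (HU*mm^2); the wire is rendered pixel-integrated so the line
        integral is exact regardless of sampling.
    field_of_view_mm, grid_size:
        Reconstruction field of view and number of pixels per side.
    """

    kind: str
    background_hu: float = 0.0
    disk_contrast_hu: float = 10.0
    disk_diameter_mm: float = 10.0
    wire_offset_mm: tuple[float, float] = (5.0, 5.0)
    wire_fwhm_mm: float = 0.1
    wire_area_hu_mm2: float = 2500.0
    field_of_view_mm: float = 250.0
    grid_size: int = 256

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; expected one of {PHANTOM_KINDS}")
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        if self.field_of_view_mm <= 0:
            raise ValueError("field_of_view_mm must be positive")
        if self.kind == "catphan_lowcontrast":
            if self.disk_diameter_mm <= 0:
                raise ValueError("disk_diameter_mm must be positive")
            if self.disk_diameter_mm >= self.field_of_view_mm:
                raise ValueError("low-contrast disk does not fit inside the field of view")
        if self.kind == "wire":
            if self.wire_fwhm_mm <= 0:
                raise ValueError("wire_fwhm_mm must be positive")
            half = self.field_of_view_mm / 2.0
            if abs(self.wire_offset_mm[0]) >= half or abs(self.wire_offset_mm[1]) >= half:
                raise ValueError("wire offset lies outside the field of view")

    @property
    def spacing_mm(self) -> float:
        """Pixel size (mm), square pixels."""
        return self.field_of_view_mm / self.grid_size

    # convenience constructors with study-matched defaults -----------------

    @classmethod
    def catphan(cls, **kw) -> "PhantomSpec":
        """Low-contrast module slice: 63.4 HU bulk, 10 HU / 10 mm disk, 250 mm FOV."""
        defaults = dict(
            kind="catphan_lowcontrast",
            background_hu=63.4,
            disk_contrast_hu=10.0,
            disk_diameter_mm=10.0,
            field_of_view_mm=250.0,
            grid_size=256,
        )
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def wire(cls, **kw) -> "PhantomSpec":
        """Thin wire in air, small (50 mm) FOV so the PSF is oversampled."""
        defaults = dict(
            kind="wire",
            background_hu=0.0,
            wire_offset_mm=(5.0, 5.0),
            field_of_view_mm=50.0,
            grid_size=256,
        )
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def water(cls, **kw) -> "PhantomSpec":
        """Uniform water slice, 200 mm FOV."""
        defaults = dict(kind="water", background_hu=0.0, field_of_view_mm=200.0, grid_size=256)
        defaults.update(kw)
        return cls(**defaults)


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner/reconstruction parameters governing the noise model.

    ``sigma_ref_hu`` is the per-pixel noise SD at the reference dose
    (``reference_mas``); at dose ``d`` the SD is
    ``sigma_ref_hu * sqrt(reference_mas / d)``, times ``ir_noise_scale``
    for the IR-like reconstruction flavour.  ``window_ms`` is the temporal
    reconstruction-window length that sets the inter-phase noise
    correlation; ``kernel_sigma_mm`` is the Gaussian width of the system
    PSF applied to the noiseless object.
    """

    mas_per_rot: float = 456.0
    reference_mas: float = 456.0
    rotation_ms: float = 280.0
    window_ms: float = 70.0
    sigma_ref_hu: float = 8.475
    kernel_sigma_mm: float = 0.62
    recon_flavor: str = "FBP_like"
    ir_noise_scale: float = 0.944
    noise_colored: bool = False

    def __post_init__(self) -> None:
        if self.recon_flavor not in RECON_FLAVORS:
            raise ValueError(f"recon_flavor must be one of {RECON_FLAVORS}")
        for name in ("mas_per_rot", "reference_mas", "rotation_ms", "window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_ref_hu < 0 or self.kernel_sigma_mm < 0:
            raise ValueError("sigma_ref_hu and kernel_sigma_mm must be non-negative")
        if not (0 < self.ir_noise_scale <= 1):
            raise ValueError("ir_noise_scale must lie in (0, 1]")

    def noise_sd_hu(self) -> float:
        """Per-pixel noise SD (HU) at the configured dose and flavour."""
        sd = self.sigma_ref_hu * math.sqrt(self.reference_mas / self.mas_per_rot)
        if self.recon_flavor == "IR_like":
            sd *= self.ir_noise_scale
        return sd


@dataclass
class PhaseImage:
    """A single 2D slice in Hounsfield units with physical pixel spacing."""

    pixels: np.ndarray
    spacing_mm: float
    phase_ms: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("PhaseImage expects a 2D pixel array")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be strictly positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) pixel-centre coordinate grids in mm, origin at image centre."""
        ny, nx = self.pixels.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing_mm
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing_mm
        return np.meshgrid(x, y)

    def copy(self) -> "PhaseImage":
        return PhaseImage(self.pixels.copy(), self.spacing_mm, self.phase_ms)


@dataclass
class PhaseSeries:
    """An ordered series of phase images of the same static object.

    ``ground_truth`` is the noiseless image after the system PSF blur, i.e.
    what every frame converges to as the noise SD goes to zero.
    """

    frames: list[PhaseImage]
    interval_ms: float
    ground_truth: PhaseImage
    seed: object = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("PhaseSeries requires at least one frame")
        shape = self.frames[0].shape
        spacing = self.frames[0].spacing_mm
        for f in self.frames:
            if f.shape != shape or f.spacing_mm != spacing:
                raise ValueError("all frames must share grid shape and spacing")
        times = [f.phase_ms for f in self.frames]
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0) and self.interval_ms > 0:
                raise ValueError("phase times must be strictly increasing")
            if not np.allclose(steps, self.interval_ms, atol=1e-9):
                raise ValueError("phase times must be spaced by interval_ms")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> PhaseImage:
        return self.frames[i]

    @property
    def center_index(self) -> int:
        if len(self.frames) % 2 == 0:
            raise ValueError("even-length series has no unique centre frame")
        return len(self.frames) // 2

    @property
    def center(self) -> PhaseImage:
        return self.frames[self.center_index]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def make_phantom(spec: PhantomSpec) -> PhaseImage:
    """Render the noiseless phantom slice described by *spec*.

    The low-contrast disk is anti-aliased with a one-pixel linear edge ramp,
    so the pixel at the disk centre reads exactly ``background + contrast``
    and pixels well outside the disk read exactly ``background``.  The wire
    is rendered pixel-integrated (separable Gaussian via erf), so its total
    line integral equals ``wire_area_hu_mm2`` to machine precision.
    """
    n = spec.grid_size
    h = spec.spacing_mm
    img = np.full((n, n), float(spec.background_hu))

    if spec.kind == "water":
        pass
    elif spec.kind == "catphan_lowcontrast":
        probe = PhaseImage(img, h)
        x, y = probe.coords_mm()
        r = np.hypot(x, y)
        radius = spec.disk_diameter_mm / 2.0
        coverage = np.clip(0.5 + (radius - r) / h, 0.0, 1.0)
        img = img + spec.disk_contrast_hu * coverage
    elif spec.kind == "wire":
        probe = PhaseImage(img, h)
        x, y = probe.coords_mm()
        x0, y0 = spec.wire_offset_mm
        sw = spec.wire_fwhm_mm * _FWHM_TO_SIGMA
        s2 = sw * math.sqrt(2.0)

        def pixel_integral(c: np.ndarray, c0: float) -> np.ndarray:
            return 0.5 * (erf((c - c0 + h / 2.0) / s2) - erf((c - c0 - h / 2.0) / s2))

        img = img + spec.wire_area_hu_mm2 / (h * h) * pixel_integral(x, x0) * pixel_integral(y, y0)

    return PhaseImage(img, h)


def blurred_phantom(spec: PhantomSpec, kernel_sigma_mm: float) -> PhaseImage:
    """Noiseless phantom after the system PSF blur (the series ground truth)."""
    return _blur(make_phantom(spec), kernel_sigma_mm)


def _blur(image: PhaseImage, kernel_sigma_mm: float) -> PhaseImage:
    if kernel_sigma_mm <= 0:
        return image.copy()
    sigma_px = kernel_sigma_mm / image.spacing_mm
    return PhaseImage(gaussian_filter(image.pixels, sigma_px, mode="nearest"),
                      image.spacing_mm, image.phase_ms)


def _default_rois(spec: PhantomSpec) -> tuple[tuple[tuple[float, float], float],
                                              tuple[tuple[float, float], float]]:
    """Default (target, background) circular ROIs as ((x, y) mm, radius mm)."""
    r_t = 0.4 * spec.disk_diameter_mm
    r_b = 0.08 * spec.field_of_view_mm
    c_b = (0.24 * spec.field_of_view_mm, 0.0)
    return ((0.0, 0.0), r_t), (c_b, r_b)


def _circle_mean(image: PhaseImage, center_mm: tuple[float, float], radius_mm: float) -> float:
    x, y = image.coords_mm()
    mask = (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 <= radius_mm ** 2
    if not mask.any():
        raise ValueError("ROI contains no pixel centres")
    return float(image.pixels[mask].mean())


def effective_contrast(
    spec: PhantomSpec,
    acq: AcquisitionParams,
    target_roi: tuple[tuple[float, float], float] | None = None,
    background_roi: tuple[tuple[float, float], float] | None = None,
) -> float:
    """ROI-mean disk contrast of the blurred noiseless phantom (HU).

    This is the contrast a CNR measurement actually sees: the system PSF
    softens the disk edge, so an ROI close to the disk rim reads slightly
    less than the nominal ``disk_contrast_hu``.
    """
    if spec.kind != "catphan_lowcontrast":
        raise ValueError("effective_contrast is defined for the low-contrast phantom")
    t_default, b_default = _default_rois(spec)
    target_roi = target_roi or t_default
    background_roi = background_roi or b_default
    blurred = _blur(make_phantom(spec), acq.kernel_sigma_mm)
    return _circle_mean(blurred, *target_roi) - _circle_mean(blurred, *background_roi)


def calibrate_noise(
    target: str,
    value: float,
    spec: PhantomSpec,
    acq: AcquisitionParams,
    target_roi: tuple[tuple[float, float], float] | None = None,
    background_roi: tuple[tuple[float, float], float] | None = None,
) -> float:
    """Solve for ``sigma_ref_hu`` so a single reference-dose phase matches a
    printed reference quantity in expectation.

    Targets
    -------
    ``cnr``
        CNR = contrast / sigma, with contrast the blur-corrected ROI contrast
        of the phantom, so ``sigma = contrast / value``.
    ``sd``
        sigma = value (identity).
    ``mse_plateau``
        The per-pixel MSE between two phases with independent noise is
        ``2 sigma^2`` in expectation, so ``sigma = sqrt(value / 2)``.
    """
    if value <= 0:
        raise ValueError("calibration target value must be positive")
    if target == "sd":
        return float(value)
    if target == "mse_plateau":
        return math.sqrt(value / 2.0)
    if target == "cnr":
        if spec.disk_contrast_hu <= 0:
            raise ValueError("CNR calibration requires positive disk contrast")
        contrast = effective_contrast(spec, acq, target_roi, background_roi)
        return contrast / value
    raise ValueError(f"unknown calibration target {target!r}")


# ---------------------------------------------------------------------------
# series simulation
# ---------------------------------------------------------------------------


def _window_steps(interval_ms: float, window_ms: float) -> tuple[int, int]:
    """Time discretisation: (steps per window, steps per interval)."""
    iv, w = float(interval_ms), float(window_ms)
    if abs(iv - round(iv)) > 1e-6 or abs(w - round(w)) > 1e-6:
        raise ValueError("interval_ms and window_ms must be integer milliseconds")
    step = math.gcd(int(round(iv)), int(round(w)))
    if step == 0 or int(round(w)) % step:
        raise ValueError("interval not commensurate with the reconstruction window")
    return int(round(w)) // step, int(round(iv)) // step


def _color_gain(shape: tuple[int, int], sigma_px: float) -> float:
    """SD attenuation of unit white noise under the discrete Gaussian blur."""
    impulse = np.zeros(shape)
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    k = gaussian_filter(impulse, sigma_px, mode="constant")
    return float(np.sqrt((k ** 2).sum()))


def simulate_series(
    spec: PhantomSpec,
    acq: AcquisitionParams,
    n_phases: int = 3,
    interval_ms: float = 50.0,
    seed=None,
    center_phase_ms: float = -250.0,
) -> PhaseSeries:
    """Simulate one replicate phase series of a static phantom.

    Each frame is ``blur(ground truth) + noise`` where the noise fields of
    different frames are correlated according to the triangular
    reconstruction-window law ``rho(d) = max(0, 1 - d/window_ms)``.  The
    construction sums a pool of white fields indexed by time step over each
    frame's window, scaled so the per-frame SD equals the dose-scaled target
    exactly.  ``interval_ms = 0`` is the fully degenerate limit: all frames
    share one noise realisation.

    Deterministic for a fixed ``seed`` (anything accepted by
    :func:`numpy.random.default_rng`).
    """
    if n_phases < 1:
        raise ValueError("n_phases must be at least 1")
    if interval_ms < 0:
        raise ValueError("interval_ms must be non-negative")

    gt = _blur(make_phantom(spec), acq.kernel_sigma_mm)
    sigma = acq.noise_sd_hu()
    half = n_phases // 2
    times = [center_phase_ms + (i - half) * interval_ms for i in range(n_phases)]
    shape = gt.shape

    if sigma == 0:
        frames = [PhaseImage(gt.pixels.copy(), gt.spacing_mm, t) for t in times]
        return PhaseSeries(frames, interval_ms, gt, seed)

    rng = np.random.default_rng(seed)
    if interval_ms == 0:
        shared = rng.standard_normal(shape)
        noise = [shared] * n_phases
    else:
        n_win, n_step = _window_steps(interval_ms, acq.window_ms)
        total = (n_phases - 1) * n_step + n_win
        pool = rng.standard_normal((total, *shape))
        noise = [pool[i * n_step : i * n_step + n_win].sum(axis=0) / math.sqrt(n_win)
                 for i in range(n_phases)]

    if acq.noise_colored and acq.kernel_sigma_mm > 0:
        sigma_px = acq.kernel_sigma_mm / gt.spacing_mm
        gain = _color_gain(shape, sigma_px)
        noise = [gaussian_filter(f, sigma_px, mode="nearest") / gain for f in noise]

    frames = [PhaseImage(gt.pixels + sigma * f, gt.spacing_mm, t)
              for f, t in zip(noise, times)]
    return PhaseSeries(frames, interval_ms, gt, seed)
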