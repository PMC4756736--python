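"""Image-quality metrics: CNR, per-pixel MSE, wire-method MTF, radial NPS.

Conventions
-----------
* ROI coordinates are in millimetres with the image centre as origin;
  membership is pixel-centre-in-circle.
* Standard deviations use the unbiased (n-1) denominator throughout.
* MTF frequencies are in cycles/mm, NPS values in HU^2 mm^2 (2D convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantoms import PhaseImage

__all__ = [
    "ROISpec",
    "MTFCurve",
    "NPSCurve",
    "roi_mask",
    "roi_mean",
    "cnr",
    "mse",
    "noise_sd",
    "mtf_wire",
    "noise_from_replicates",
    "nps_radial",
]


@dataclass(frozen=True)
class ROISpec:
    """A circular region of interest: (x, y) centre in mm, radius in mm."""

    center_mm: tuple[float, float]
    radius_mm: float
    role: str = "background"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.role not in ("target", "background"):
            raise ValueError("role must be 'target' or 'background'")

    def disjoint_from(self, other: "ROISpec") -> bool:
        d = math.hypot(self.center_mm[0] - other.center_mm[0],
                       self.center_mm[1] - other.center_mm[1])
        return d >= self.radius_mm + other.radius_mm


def roi_mask(image: PhaseImage, roi: ROISpec) -> np.ndarray:
    """Boolean pixel mask of the ROI; raises if the ROI leaves the image."""
    ny, nx = image.shape
    half_x = nx * image.spacing_mm / 2.0
    half_y = ny * image.spacing_mm / 2.0
    cx, cy = roi.center_mm
    if abs(cx) + roi.radius_mm > half_x or abs(cy) + roi.radius_mm > half_y:
        raise ValueError("ROI extends outside the image")
    x, y = image.coords_mm()
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= roi.radius_mm ** 2
    if not mask.any():
        raise ValueError("ROI contains no pixel centres")
    return mask


def roi_mean(image: PhaseImage, roi: ROISpec) -> float:
    """Mean attenuation (HU) within the ROI."""
    return float(image.pixels[roi_mask(image, roi)].mean())


def noise_sd(image: PhaseImage, roi: ROISpec) -> float:
    """Sample SD (n-1) of attenuation within the ROI."""
    vals = image.pixels[roi_mask(image, roi)]
    if vals.size < 2:
        raise ValueError("ROI must contain at least 2 pixels for an SD")
    return float(vals.std(ddof=1))


def cnr(image: PhaseImage, target: ROISpec, background: ROISpec) -> float:
    """Contrast-to-noise ratio (mean_T - mean_B) / SD_B."""
    if not target.disjoint_from(background):
        raise ValueError("target and background ROIs must be disjoint")
    sd_b = noise_sd(image, background)
    if sd_b == 0:
        raise ValueError("background SD is zero; CNR undefined")
    return (roi_mean(image, target) - roi_mean(image, background)) / sd_b


def mse(a: PhaseImage, b: PhaseImage, region: ROISpec | None = None) -> float:
    """Mean squared per-pixel difference, over the full image or a ROI."""
    if a.shape != b.shape:
        raise ValueError("images must share grid shape")
    diff2 = (a.pixels - b.pixels) ** 2
    if region is not None:
        diff2 = diff2[roi_mask(a, region)]
    return float(diff2.mean())


# ---------------------------------------------------------------------------
# MTF (wire method)
# ---------------------------------------------------------------------------


@dataclass
class MTFCurve:
    """Modulation transfer function: MTF(0) = 1, frequencies in cycles/mm.

    ``mtf10`` is the frequency at which the MTF first falls to 0.10 (linear
    interpolation between bracketing samples), or ``None`` if it is not
    reached within the sampled band.
    """

    frequencies: np.ndarray
    values: np.ndarray
    mtf10: float | None

    def at(self, f: float) -> float:
        return float(np.interp(f, self.frequencies, self.values))


def _radial_profile(values: np.ndarray, radii: np.ndarray, bin_mm: float,
                    r_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean image value vs distance, resampled onto a uniform radius grid."""
    nbins = int(r_max / bin_mm)
    idx = np.minimum((radii / bin_mm).astype(int), nbins - 1)
    keep = radii < r_max
    sums = np.bincount(idx[keep], weights=values[keep], minlength=nbins)
    counts = np.bincount(idx[keep], minlength=nbins)
    centers = (np.arange(nbins) + 0.5) * bin_mm
    filled = counts > 0
    profile = np.interp(centers, centers[filled], sums[filled] / counts[filled])
    return centers, profile


def mtf_wire(
    image: PhaseImage,
    wire_center_mm: tuple[float, float] | None = None,
    bin_frac: float = 0.25,
    max_radius_mm: float | None = None,
    freq_step: float = 0.005,
) -> MTFCurve:
    """Wire-method MTF of a thin-wire image.

    The wire image is (up to background and noise) the system point-spread
    function.  Because the wire is offset from the isocentre, pixel centres
    sample the radially symmetric PSF at many sub-pixel distances; binning
    pixel values by distance from the fitted wire centroid (bin width
    ``bin_frac`` of a pixel) yields an oversampled 1D profile.  The profile
    is background-subtracted using its tail, area-normalised, and its
    (cosine) Fourier transform modulus gives the MTF, normalised to 1 at
    zero frequency.  Frequencies run from 0 to the image Nyquist.
    """
    h = image.spacing_mm
    px = image.pixels
    x, y = image.coords_mm()

    # background statistics from the outer 20% of the field-of-view radius
    ny, nx = image.shape
    fov_r = min(nx, ny) * h / 2.0
    r_img = np.hypot(x, y)
    bg_mask = r_img > 0.8 * fov_r
    bg_mean = float(px[bg_mask].mean())
    bg_sd = float(px[bg_mask].std(ddof=1))

    peak = float(px.max())
    if peak - bg_mean <= max(5.0 * bg_sd, 1e-12):
        raise ValueError("wire not found: no peak at least 5 background SDs above background")

    # centroid of the background-subtracted peak neighbourhood
    if wire_center_mm is None:
        iy, ix = np.unravel_index(np.argmax(px), px.shape)
        wire_center_mm = (float(x[iy, ix]), float(y[iy, ix]))
    near = np.hypot(x - wire_center_mm[0], y - wire_center_mm[1]) <= max(3.0, 10 * h)
    w = np.clip(px - bg_mean, 0.0, None) * near
    wsum = w.sum()
    cx = float((w * x).sum() / wsum)
    cy = float((w * y).sum() / wsum)

    radii = np.hypot(x - cx, y - cy)
    if max_radius_mm is None:
        edge = min(fov_r - math.hypot(cx, cy), fov_r)
        max_radius_mm = 0.9 * edge
    r, profile = _radial_profile(px.ravel(), radii.ravel(), bin_frac * h, max_radius_mm)

    # tail background subtraction and area normalisation
    tail = r > 0.8 * max_radius_mm
    profile = profile - profile[tail].mean()

    nyquist = 1.0 / (2.0 * h)
    freqs = np.arange(0.0, nyquist + freq_step / 2.0, freq_step)
    dr = r[1] - r[0]
    # symmetric profile: F(f) = 2 * sum p(r) cos(2 pi f r) dr
    ft = 2.0 * (profile[None, :] * np.cos(2.0 * math.pi * freqs[:, None] * r[None, :])
                ).sum(axis=1) * dr
    if ft[0] <= 0:
        raise ValueError("degenerate wire profile: non-positive area")
    values = np.abs(ft) / ft[0]

    mtf10 = None
    below = np.nonzero(values < 0.1)[0]
    if below.size:
        j = below[0]
        if j == 0:
            raise ValueError("MTF below 0.1 at zero frequency")
        f0, f1 = freqs[j - 1], freqs[j]
        v0, v1 = values[j - 1], values[j]
        mtf10 = float(f0 + (v0 - 0.1) / (v0 - v1) * (f1 - f0))

    return MTFCurve(freqs, values, mtf10)


# ---------------------------------------------------------------------------
# NPS
# ---------------------------------------------------------------------------


@dataclass
class NPSCurve:
    """Radially averaged 2D noise power spectrum.

    ``values`` are HU^2 mm^2; ``total_variance`` (HU^2) is the integral of
    the 2D NPS over frequency space, which by Parseval equals the ROI noise
    variance.
    """

    radial_frequencies: np.ndarray
    values: np.ndarray
    total_variance: float


def noise_from_replicates(images: Sequence[PhaseImage]) -> list[PhaseImage]:
    """Isolate noise by subtracting the ensemble mean of replicate images.

    Residuals are scaled by sqrt(n / (n - 1)) so their variance is an
    unbiased estimate of the single-image noise variance.
    """
    if len(images) < 2:
        raise ValueError("ensemble-mean noise isolation needs at least 2 replicates")
    n = len(images)
    stack = np.stack([im.pixels for im in images])
    mean = stack.mean(axis=0)
    scale = math.sqrt(n / (n - 1.0))
    return [PhaseImage(scale * (im.pixels - mean), im.spacing_mm, im.phase_ms)
            for im in images]


def nps_radial(noise_fields: Sequence[PhaseImage], roi_size_px: int = 64) -> NPSCurve:
    """Radially averaged NPS from replicate noise-only images.

    Each noise field is tiled into half-overlapping square ROIs; each ROI is
    detrended (its mean subtracted) and contributes
    ``|DFT|^2 * (dx dy) / (Nx Ny)``; periodograms are averaged over ROIs and
    replicates and binned by radial frequency (bin width = one DFT step).
    The zero-frequency cell is excluded (it is removed by detrending).
    """
    if not noise_fields:
        raise ValueError("no noise fields supplied")
    h = noise_fields[0].spacing_mm
    ny, nx = noise_fields[0].shape
    if roi_size_px > min(ny, nx):
        raise ValueError("ROI larger than image")
    step = max(roi_size_px // 2, 1)

    acc = np.zeros((roi_size_px, roi_size_px))
    count = 0
    for fieldim in noise_fields:
        if fieldim.shape != (ny, nx) or fieldim.spacing_mm != h:
            raise ValueError("noise fields must share grid shape and spacing")
        for y0 in range(0, ny - roi_size_px + 1, step):
            for x0 in range(0, nx - roi_size_px + 1, step):
                tile = fieldim.pixels[y0:y0 + roi_size_px, x0:x0 + roi_size_px]
                d = tile - tile.mean()
                acc += np.abs(np.fft.fft2(d)) ** 2
                count += 1
    nps2d = acc / count * (h * h) / (roi_size_px * roi_size_px)

    df = 1.0 / (roi_size_px * h)
    fx = np.fft.fftfreq(roi_size_px, d=h)
    fr = np.hypot(fx[None, :], fx[:, None])
    total_variance = float(nps2d.sum() * df * df)

    nbins = roi_size_px // 2
    idx = np.minimum((fr / df + 0.5).astype(int), nbins)
    flat_idx = idx.ravel()
    flat_nps = nps2d.ravel()
    keep = (flat_idx >= 1) & (flat_idx <= nbins) & (fr.ravel() > 0)
    sums = np.bincount(flat_idx[keep], weights=flat_nps[keep], minlength=nbins + 1)
    counts = np.bincount(flat_idx[keep], minlength=nbins + 1)
    valid = counts > 0
    centers = np.arange(nbins + 1) * df
    return NPSCurve(centers[valid], sums[valid] / counts[valid], total_variance)
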