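"""Wire-method MTF and water-phantom NPS on simulated images.

Renders the offset-wire phantom, calibrates the Gaussian system PSF so the
noiseless single-frame MTF10% is 0.55 cycles/mm, and shows that temporal
averaging leaves the MTF untouched.  Then estimates the radial NPS of
white noise before and after filtering to show the uniform noise reduction.
"""

import numpy as np

from ct4dnr import (
    AcquisitionParams,
    PhantomSpec,
    TNRParams,
    blurred_phantom,
    calibrate_kernel,
    denoise_series,
    mtf_wire,
    noise_from_replicates,
    nps_radial,
    simulate_series,
)

# --- MTF ------------------------------------------------------------------
wire = PhantomSpec.wire()
kernel = calibrate_kernel(wire, target_mtf10=0.55)
print(f"system PSF sigma for MTF10% = 0.55: {kernel:.4f} mm")

acq = AcquisitionParams(sigma_ref_hu=8.475, kernel_sigma_mm=kernel, window_ms=50.0)
series = simulate_series(wire, acq, seed=2)
single = mtf_wire(series.center)
filtered = mtf_wire(denoise_series(series, TNRParams()))
print(f"MTF10% single frame (noisy) : {single.mtf10:.4f} cycles/mm")
print(f"MTF10% after filtering      : {filtered.mtf10:.4f} cycles/mm")

# --- NPS ------------------------------------------------------------------
water = PhantomSpec.water()
acq = AcquisitionParams(sigma_ref_hu=8.475, window_ms=50.0)
ref_imgs, flt_imgs = [], []
for rep in range(10):
    s = simulate_series(water, acq, seed=100 + rep)
    ref_imgs.append(s.center)
    flt_imgs.append(denoise_series(s, TNRParams()))
nps_ref = nps_radial(noise_from_replicates(ref_imgs))
nps_flt = nps_radial(noise_from_replicates(flt_imgs))
ratio = nps_flt.values / nps_ref.values
print(f"noise variance (reference)  : {nps_ref.total_variance:.1f} HU^2 "
      f"(sigma^2 = {8.475**2:.1f})")
print(f"NPS ratio filtered/reference: {ratio.mean():.3f} +/- {ratio.std(ddof=1):.3f} "
      "across the band")
print()
print("Temporal averaging is spatially local, so the MTF is unchanged and "
      "the NPS drops by the same factor (~w'w = 0.34) at every frequency — "
      "no oversmoothing, unlike spatial filters.")
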