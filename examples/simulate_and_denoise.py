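"""Simulate a 3-phase low-contrast phantom series and denoise it temporally.

Builds a Catphan-like low-contrast slice (63.4 HU bulk, 10 HU / 10 mm disk),
simulates three phases 50 ms apart with noise calibrated so the single-phase
CNR is 1.18, applies the temporal filter (neighbour weight 0.3, non-cyclic,
identity registration) and prints the before/after CNR and CT value.
"""

from ct4dnr import (
    AcquisitionParams,
    PhantomSpec,
    ROISpec,
    TNRParams,
    calibrate_noise,
    cnr,
    denoise_series,
    simulate_series,
)
from ct4dnr.metrics import roi_mean

spec = PhantomSpec.catphan()
probe = AcquisitionParams(window_ms=50.0)
sigma = calibrate_noise("cnr", 1.18, spec, probe)
acq = AcquisitionParams(sigma_ref_hu=sigma, window_ms=50.0)

target = ROISpec((0.0, 0.0), 4.0, role="target")
background = ROISpec((60.0, 0.0), 20.0, role="background")

series = simulate_series(spec, acq, n_phases=3, interval_ms=50.0, seed=1)
filtered = denoise_series(series, TNRParams(neighbor_weight=0.3))

print(f"calibrated noise SD         : {sigma:.3f} HU")
print(f"single-phase CNR            : {cnr(series.center, target, background):.3f}")
print(f"filtered CNR                : {cnr(filtered, target, background):.3f}")
print(f"CT value (single / filtered): {roi_mean(series.center, background):.2f}"
      f" / {roi_mean(filtered, background):.2f} HU")
print()
print("The filter averages the centre phase with its two neighbours "
      "(weights 0.4/0.3/0.3); with independent phase noise this multiplies "
      "the noise SD by sqrt(0.34) = 0.583, so the CNR rises by ~1.7x while "
      "the mean attenuation is untouched.")
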