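# ct4dnr — temporal noise reduction for short-interval cardiac-CT phase series

Retrospectively ECG-gated cardiac CT reconstructs several "padding" phases a
few tens of milliseconds around the target cardiac phase and normally throws
them away.  For a (quasi-)static object those phases are images of the same
anatomy with different quantum-noise realisations, so a purely *temporal*
filter — a weighted average of the centre phase with its registered
neighbours — can cut image noise without any spatial smoothing, and hence
without degrading CT attenuation or spatial resolution.  Because half
reconstruction on a 280 ms-rotation dual-source scanner uses a ~70 ms data
window, phases ≥ 70 ms apart carry fully independent noise, and phases
closer together share projection data: their noise correlation falls off as
`rho(Δ) = max(0, 1 − Δ/70 ms)`.

`ct4dnr` is a desk-scale simulation pipeline for characterising this kind of
four-dimensional noise reduction (4DNR) on static digital phantoms:

* **`ct4dnr.phantoms`** — noiseless low-contrast (Catphan-CTP515-like), thin
  offset-wire and uniform water slices; replicate 3-phase series with
  dose-scaled (`sigma ∝ 1/sqrt(mAs)`) and phase-correlated Gaussian noise;
  noise calibration against printed reference quantities (single-phase CNR,
  two-phase MSE plateau).
* **`ct4dnr.tnr`** — the temporal filter: optional phase interpolation, a
  registration hook (identity / global translation), weighted averaging with
  non-cyclic boundary handling.  Default weights: centre `1 − 2w = 0.4`,
  each neighbour `w = 0.3`.
* **`ct4dnr.metrics`** — CNR `(ROI_T − ROI_B)/SD_B`, per-pixel MSE,
  wire-method MTF with MTF₁₀%, radially averaged NPS (HU²·mm²), ROI noise SD.
* **`ct4dnr.stats`** — Tukey–Kramer HSD, TOST equivalence (CT-value margin
  2 HU) and non-inferiority tests (CNR 0.1, MTF₁₀% 0.05 cycles/mm, SD 1 HU).
* **`ct4dnr.studies`** — the three end-to-end experiments (interval sweep,
  base-dose quantitative comparison, dose reduction) with seeded replicates
  and deterministic report files.

For independent phases with weights `(w, 1−2w, w)` the filter multiplies the
noise SD by `sqrt((1−2w)² + 2w²)` (= 0.583 at w = 0.3), it preserves the
mean attenuation exactly, and under identity registration it leaves the MTF
untouched — the NPS drops by the same factor at every spatial frequency.

## Worked example

```sh
python examples/simulate_and_denoise.py
```

```
calibrated noise SD         : 8.403 HU
single-phase CNR            : 1.165
filtered CNR                : 2.075
CT value (single / filtered): 63.40 / 63.24 HU
```

The noise SD is solved so a single phase of the 10 HU low-contrast disk
reads CNR ≈ 1.18; filtering the 3-phase series raises the CNR by the
predicted `1/0.583 ≈ 1.7×` while the background CT value stays at 63.4 HU.
`examples/image_quality_metrics.py` does the same for resolution and noise
texture:

```
system PSF sigma for MTF10% = 0.55: 0.6190 mm
MTF10% single frame (noisy) : 0.5454 cycles/mm
MTF10% after filtering      : 0.5479 cycles/mm
noise variance (reference)  : 71.7 HU^2 (sigma^2 = 71.8)
NPS ratio filtered/reference: 0.340 +/- 0.005 across the band
```

`examples/run_studies.py` runs all three studies (10 replicates each) and
writes per-replicate metric tables, test results and summary files to
`study_reports/`.

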