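"""File interfaces: NIfTI phase series, YAML/JSON configs, ROI lists, curves.

A phase series is stored as one NIfTI file per phase (pixel spacing in the
affine) plus a JSON sidecar carrying the temporal metadata (phase times,
interval, seed) that NIfTI has no natural slot for.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .metrics import MTFCurve, NPSCurve, ROISpec
from .phantoms import AcquisitionParams, PhantomSpec, PhaseImage, PhaseSeries

__all__ = [
    "save_series",
    "load_series",
    "load_phase_image",
    "load_config",
    "save_config",
    "load_rois",
    "save_curve",
]

_SIDECAR = "series.json"


def _affine(spacing_mm: float) -> np.ndarray:
    return np.diag([spacing_mm, spacing_mm, 1.0, 1.0])


def save_series(series: PhaseSeries, directory) -> list[Path]:
    """Write each phase (and the ground truth) as NIfTI plus a JSON sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for i, frame in enumerate(series.frames):
        p = d / f"phase_{i:02d}.nii"
        nib.save(nib.Nifti1Image(frame.pixels.astype(np.float32),
                                 _affine(frame.spacing_mm)), p)
        written.append(p)
    p = d / "ground_truth.nii"
    nib.save(nib.Nifti1Image(series.ground_truth.pixels.astype(np.float32),
                             _affine(series.ground_truth.spacing_mm)), p)
    written.append(p)
    sidecar = {
        "phase_ms": [f.phase_ms for f in series.frames],
        "interval_ms": series.interval_ms,
        "spacing_mm": series.frames[0].spacing_mm,
        "seed": repr(series.seed),
    }
    p = d / _SIDECAR
    p.write_text(json.dumps(sidecar, indent=2) + "\n")
    written.append(p)
    return written


def load_phase_image(path, phase_ms: float = 0.0, slice_index: int | None = None) -> PhaseImage:
    """Load a NIfTI image as a PhaseImage; 3D volumes need a slice index."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] == 1:
            data = data[:, :, 0]
        elif slice_index is None:
            raise ValueError("3D volume: pass slice_index to extract a slice")
        else:
            data = data[:, :, slice_index]
    spacing = float(img.header.get_zooms()[0])
    return PhaseImage(data, spacing, phase_ms)


def load_series(directory) -> PhaseSeries:
    """Inverse of :func:`save_series`."""
    d = Path(directory)
    sidecar = json.loads((d / _SIDECAR).read_text())
    frames = [load_phase_image(p, phase_ms=t)
              for p, t in zip(sorted(d.glob("phase_*.nii")), sidecar["phase_ms"])]
    gt = load_phase_image(d / "ground_truth.nii")
    return PhaseSeries(frames, sidecar["interval_ms"], gt, sidecar.get("seed"))


def _split_fields(cls, mapping: dict) -> dict:
    names = set(cls.__dataclass_fields__)
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    out = dict(mapping)
    for key in ("wire_offset_mm",):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def load_config(path) -> tuple[PhantomSpec, AcquisitionParams]:
    """Read a ``{phantom: {...}, acquisition: {...}}`` YAML or JSON file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    spec = PhantomSpec(**_split_fields(PhantomSpec, cfg.get("phantom", {})))
    acq = AcquisitionParams(**_split_fields(AcquisitionParams, cfg.get("acquisition", {})))
    return spec, acq


def save_config(spec: PhantomSpec, acq: AcquisitionParams, path) -> Path:
    p = Path(path)
    cfg = {
        "phantom": {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in spec.__dict__.items()},
        "acquisition": dict(acq.__dict__),
    }
    p.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return p


def load_rois(path) -> list[ROISpec]:
    """Read a JSON list of ``{center_mm, radius_mm, role}`` objects."""
    entries = json.loads(Path(path).read_text())
    return [ROISpec(tuple(e["center_mm"]), e["radius_mm"], e.get("role", "background"))
            for e in entries]


def save_curve(curve, path) -> Path:
    """Export an MTF or NPS curve as a two-column CSV."""
    p = Path(path)
    if isinstance(curve, MTFCurve):
        df = pd.DataFrame({"frequency_cycles_per_mm": curve.frequencies,
                           "mtf": curve.values})
    elif isinstance(curve, NPSCurve):
        df = pd.DataFrame({"frequency_cycles_per_mm": curve.radial_frequencies,
                           "nps_hu2_mm2": curve.values})
    else:
        raise TypeError("expected an MTFCurve or NPSCurve")
    df.to_csv(p, index=False)
    return p
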