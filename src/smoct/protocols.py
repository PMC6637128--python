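"""End-to-end acquisition protocols on phantoms.

A protocol bundles a phantom, scan geometry, frame count M and diffuser
correlation ρ into one deterministic pipeline run: phantom → raw frames
→ reconstruction → compounding → enhancement → metrics.  ρ=1 is the
conventional-OCT control (diffuser off), ρ=0 the speckle-modulated
branch.  The stock configurations mirror the volume protocol (6 μm
lateral pitch, 18–40 averages) and the B-scan protocol (4 μm pitch,
100 averages).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from . import io as smio
from .compound import compound_frames, contrast_vs_frames, speckle_contrast
from .enhance import EnhanceConfig, enhance_chain, flatten_volume
from .forward_model import ScanGeometry, diffuser_sequence, make_source_spectrum, simulate_frames
from .margin import enface_slab, extract_margin_curve, margin_error, segment_tumor
from .phantom import PhantomSpec, Tumor, build_scatterer_field, ground_truth_masks
from .reconstruct import DispersionModel, reconstruct_volume

__all__ = ["ProtocolSpec", "ProtocolReport", "run_protocol", "volume_protocol_defaults", "bscan_protocol_defaults"]

log = logging.getLogger(__name__)


class ProtocolSpec(BaseModel):
    """Declarative description of one simulated acquisition experiment."""

    name: str = "protocol"
    phantom: PhantomSpec
    lateral_pitch_um: float = Field(default=6.0, gt=0)
    n_ascans: int = Field(default=128, ge=1)
    n_bscans: int = Field(default=1, ge=1)
    n_samples: int = Field(default=512, ge=64)
    center_wavelength_nm: float = 1300.0
    bandwidth_fwhm_nm: float = 170.0
    lateral_psf_fwhm_um: float = Field(default=9.0, gt=0)
    x0_um: float = 0.0
    y0_um: float = 0.0
    m_frames: int = Field(default=40, ge=1)
    rho: float = Field(default=0.0, ge=0.0, le=1.0)
    a2: float = 0.0
    a3: float = 0.0
    noise_sd: float = Field(default=0.0, ge=0)
    enhance: EnhanceConfig = Field(default_factory=EnhanceConfig)
    contrast_m_values: Optional[list[int]] = None
    roi: Optional[list[tuple[int, int]]] = None  # [(z0,z1),(x0,x1),(y0,y1)]
    margin_depth_window_um: tuple[float, float] = (50.0, 150.0)
    seed: int = 0


def volume_protocol_defaults(phantom: PhantomSpec, **overrides) -> ProtocolSpec:
    """Volume raster: 6 μm lateral spacing, 40 averages."""
    kw = dict(name="volume", phantom=phantom, lateral_pitch_um=6.0, m_frames=40)
    kw.update(overrides)
    return ProtocolSpec(**kw)


def bscan_protocol_defaults(phantom: PhantomSpec, **overrides) -> ProtocolSpec:
    """Single B-scan: 4 μm lateral spacing, 100 averages."""
    kw = dict(name="bscan", phantom=phantom, lateral_pitch_um=4.0, m_frames=100, n_bscans=1)
    kw.update(overrides)
    return ProtocolSpec(**kw)


@dataclass
class ProtocolReport:
    spec: ProtocolSpec
    compounded: object  # IntensityVolume
    single_frame: object  # IntensityVolume
    metrics: dict

    def to_json(self) -> str:
        return json.dumps({"name": self.spec.name, "metrics": self.metrics}, indent=2, sort_keys=True)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"protocol stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_protocol(spec: ProtocolSpec, out_dir: str | Path | None = None) -> ProtocolReport:
    """Run the full pipeline for one protocol; deterministic under seed."""
    metrics: dict = {"rho": spec.rho, "m_frames": spec.m_frames}

    with _stage("phantom"):
        field = build_scatterer_field(spec.phantom)

    with _stage("simulate"):
        source = make_source_spectrum(spec.center_wavelength_nm, spec.bandwidth_fwhm_nm, spec.n_samples)
        geometry = ScanGeometry(
            lateral_pitch_um=spec.lateral_pitch_um,
            n_ascans=spec.n_ascans,
            n_bscans=spec.n_bscans,
            lateral_psf_fwhm_um=spec.lateral_psf_fwhm_um,
            x0_um=spec.x0_um,
            y0_um=spec.y0_um,
        )
        states = diffuser_sequence(spec.m_frames, spec.rho, field.n_scatterers, seed=spec.seed + 1)
        frames = simulate_frames(
            field, source, geometry, (spec.a2, spec.a3), states, spec.noise_sd, seed=spec.seed + 2
        )

    with _stage("reconstruct"):
        model = DispersionModel(a2=spec.a2, a3=spec.a3)
        per_frame = reconstruct_volume(frames, model=model)

    with _stage("compound"):
        compounded = compound_frames(per_frame)
        single = per_frame[0]

    roi = tuple(slice(lo, hi) for lo, hi in spec.roi) if spec.roi is not None else None
    if roi is not None:
        with _stage("contrast"):
            metrics["contrast_compound"] = speckle_contrast(compounded, roi).contrast
            metrics["contrast_single_frame"] = speckle_contrast(single, roi).contrast
            if spec.contrast_m_values:
                table = contrast_vs_frames(frames, spec.contrast_m_values, roi, model=model)
                metrics["contrast_vs_m"] = [
                    {"M": r.n_frames, "contrast": r.contrast, "mean": r.mean} for r in table.rows
                ]
                metrics["contrast_loglog_slope"] = table.slope

    has_tumor = any(isinstance(r, Tumor) for r in spec.phantom.regions)
    if has_tumor:
        with _stage("margin"):
            truth = _truth_margin_curve(spec)
            for tag, vol in (("", compounded), ("_single", single)):
                flat, _ = flatten_volume(
                    vol,
                    spec.enhance.flatten.surface_threshold_fraction,
                    spec.enhance.flatten.surface_median_filter_px,
                )
                slab = enface_slab(flat, spec.margin_depth_window_um)
                mask, threshold = segment_tumor(slab, spec.lateral_pitch_um)
                metrics[f"tumor_threshold{tag}"] = threshold
                metrics[f"tumor_area_um2{tag}"] = float(mask.sum()) * spec.lateral_pitch_um**2
                if mask.any() and truth is not None:
                    curve = extract_margin_curve(mask, spec.lateral_pitch_um)
                    mean_err, p95_err = margin_error(curve, truth)
                    metrics[f"margin_mean_abs_error_um{tag}"] = mean_err
                    metrics[f"margin_p95_error_um{tag}"] = p95_err

    with _stage("enhance"):
        enhanced = enhance_chain(compounded, spec.enhance)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        smio.save_frameset(out / "frames.h5", frames)
        smio.save_volume(out / "compounded.tif", compounded)
        smio.save_volume(out / "single_frame.tif", single)
        smio.save_volume(out / "enhanced.tif", enhanced)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))

    return ProtocolReport(spec=spec, compounded=compounded, single_frame=single, metrics=metrics)


def _truth_margin_curve(spec: ProtocolSpec) -> "np.ndarray | None":
    """Ground-truth en-face margin from the voxelized tumor mask."""
    from skimage import measure

    pitch = spec.lateral_pitch_um
    try:
        labels = ground_truth_masks(spec.phantom, (spec.phantom.extent_um[2] / 2.0, pitch, pitch))
    except ValueError:
        return None
    tumor_ids = [k for k, v in labels.legend.items() if v.startswith("tumor")]
    if not tumor_ids:
        return None
    enface = np.isin(labels.labels, tumor_ids).any(axis=0).astype(float)
    if enface.sum() == 0:
        return None
    contours = measure.find_contours(enface, 0.5)
    if not contours:
        return None
    # voxel centers sit at (i + 0.5)·pitch; shift by the scan origin so the
    # curve lands in the reconstruction's coordinate frame
    return (max(contours, key=len) + 0.5) * pitch - np.array([spec.x0_um, spec.y0_um])
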