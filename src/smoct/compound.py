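"""Frame compounding and speckle statistics.

Speckle-modulated acquisitions are averaged voxelwise in linear
intensity scale; speckle contrast C = σ/μ in a homogeneous region then
drops as 1/√M for M uncorrelated frames (and not at all for frozen
speckle), which is what the metrics here measure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forward_model import SpectralFrameSet
from .reconstruct import DispersionModel, IntensityVolume, reconstruct_volume

__all__ = [
    "SpeckleStats",
    "ContrastTable",
    "compound_frames",
    "speckle_contrast",
    "contrast_vs_frames",
]

Roi = tuple[slice, slice, slice]


@dataclass(frozen=True)
class SpeckleStats:
    n_frames: int
    roi: str
    mean: float
    sd: float
    contrast: float  # σ/μ

    @property
    def effective_n(self) -> float:
        """Equivalent number of uncorrelated frames, 1/C² (fully developed)."""
        return float("inf") if self.contrast == 0 else 1.0 / self.contrast**2


def compound_frames(volumes: Sequence[IntensityVolume]) -> IntensityVolume:
    """Voxelwise arithmetic mean of per-frame volumes (linear scale only)."""
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    first = volumes[0]
    for v in volumes:
        if v.log_scaled:
            raise ValueError("compounding requires linear-scale volumes")
        if v.shape != first.shape:
            raise ValueError("all volumes must share one shape")
        if (v.axial_pitch_um, v.lateral_pitch_um) != (first.axial_pitch_um, first.lateral_pitch_um):
            raise ValueError("all volumes must share pitches")
    mean = np.mean([v.values for v in volumes], axis=0)
    return IntensityVolume(
        values=mean,
        axial_pitch_um=first.axial_pitch_um,
        lateral_pitch_um=first.lateral_pitch_um,
        provenance="compounded SM-OCT",
        n_frames=len(volumes),
    )


def speckle_contrast(volume: IntensityVolume, roi: Roi) -> SpeckleStats:
    """μ, σ and contrast σ/μ over a box ROI of a linear-scale volume."""
    if volume.log_scaled:
        raise ValueError("speckle contrast is defined on linear intensity")
    voxels = volume.values[roi]
    if voxels.size < 100:
        raise ValueError("ROI must contain at least 100 voxels")
    mu = float(voxels.mean())
    if mu == 0:
        raise ValueError("ROI mean is zero")
    sd = float(voxels.std())
    return SpeckleStats(
        n_frames=volume.n_frames,
        roi=str(roi),
        mean=mu,
        sd=sd,
        contrast=sd / mu,
    )


@dataclass
class ContrastTable:
    """Contrast as a function of averaged-frame count, plus the log-log slope."""

    rows: list[SpeckleStats]
    slope: float  # least-squares slope of log C vs log M

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["M", "mean", "sd", "contrast", "effective_n"])
            for r in self.rows:
                writer.writerow([r.n_frames, r.mean, r.sd, r.contrast, r.effective_n])


def contrast_vs_frames(
    frames: SpectralFrameSet,
    m_values: Sequence[int],
    roi: Roi,
    model: DispersionModel | None = None,
    window: str = "hann",
) -> ContrastTable:
    """Reconstruct, compound the first M frames for each M, measure contrast.

    ``frames`` should image a homogeneous phantom and be mutually
    uncorrelated (diffuser ρ=0) for the 1/√M law to apply; the returned
    slope of log C vs log M is then ≈ −0.5.
    """
    m_values = sorted(set(int(m) for m in m_values))
    if m_values[0] < 1:
        raise ValueError("frame counts must be >= 1")
    if m_values[-1] > frames.n_frames:
        raise ValueError(f"need {m_values[-1]} frames, frame set has {frames.n_frames}")
    per_frame = reconstruct_volume(frames, model=model, window=window)
    rows = [speckle_contrast(compound_frames(per_frame[:m]), roi) for m in m_values]
    log_m = np.log([r.n_frames for r in rows])
    log_c = np.log([r.contrast for r in rows])
    slope = float(np.polyfit(log_m, log_c, 1)[0]) if len(rows) > 1 else float("nan")
    return ContrastTable(rows=rows, slope=slope)
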