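"""Volume enhancement chain for compounded OCT volumes.

Stage order follows the processing chain the volumes go through before
display: vessel-shadow gain compensation, 3-D Perona–Malik anisotropic
diffusion, histogram equalization; plus isotropic resampling to
cube-shaped voxels and surface flattening for en-face views.  Each stage
is independently callable; quantitative metrics should be computed
before equalization (it is display-only).
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage
from skimage import exposure

from .reconstruct import IntensityVolume

__all__ = [
    "EnhanceConfig",
    "remove_vessel_shadows",
    "anisotropic_diffusion_3d",
    "equalize_histogram",
    "resample_isotropic",
    "flatten_volume",
    "enhance_chain",
]

log = logging.getLogger(__name__)


class DiffusionConfig(BaseModel):
    n_iter: int = Field(default=10, ge=0)
    kappa: Optional[float] = None  # None -> 90th percentile of |∇|
    dt: float = Field(default=1.0 / 7.0, gt=0)

    @model_validator(mode="after")
    def _stable(self) -> "DiffusionConfig":
        if self.dt > 1.0 / 6.0:
            raise ValueError("dt must be <= 1/6 for 6-neighbor 3-D stability")
        return self


class EqualizationConfig(BaseModel):
    n_bins: int = Field(default=256, ge=2)
    on_log_scale: bool = True


class FlattenConfig(BaseModel):
    surface_threshold_fraction: float = Field(default=0.5, gt=0, lt=1)
    surface_median_filter_px: int = Field(default=5, ge=1)


class EnhanceConfig(BaseModel):
    gain_clip_max: float = Field(default=10.0, gt=0)
    diffusion: DiffusionConfig = Field(default_factory=DiffusionConfig)
    equalization: EqualizationConfig = Field(default_factory=EqualizationConfig)
    target_voxel_um: float = Field(default=4.0, gt=0)
    flatten: FlattenConfig = Field(default_factory=FlattenConfig)


def remove_vessel_shadows(volume: IntensityVolume, gain_clip_max: float = 10.0) -> IntensityVolume:
    """Equalize depth-mean signal across the field of view.

    Each lateral position (x, y) gets gain g = min(T / m(x,y), clip) with
    m the column's depth-mean and T the field-of-view mean of m, so the
    post-gain depth-means are identical wherever the clip was not hit.
    Vessel shadows (columns with depressed m) are thereby lifted to the
    mid-range.
    """
    if volume.log_scaled:
        raise ValueError("shadow compensation operates on linear intensity")
    m = volume.values.mean(axis=0)  # (x, y)
    target = m.mean()
    with np.errstate(divide="ignore"):
        gain = np.where(m > 0, target / np.where(m > 0, m, 1.0), gain_clip_max)
    n_zero = int((m == 0).sum())
    if n_zero:
        log.warning("%d empty columns: gain clipped to %.3g", n_zero, gain_clip_max)
    gain = np.minimum(gain, gain_clip_max)
    return volume.copy_with(volume.values * gain[None, :, :], provenance="enhanced")


def anisotropic_diffusion_3d(
    volume: IntensityVolume,
    n_iter: int = 10,
    kappa: float | None = None,
    dt: float = 1.0 / 7.0,
) -> IntensityVolume:
    """Explicit 3-D Perona–Malik diffusion with exponential conductance.

    Six-neighbor differences, conductance c(g) = exp(−(g/κ)²), zero-flux
    (reflecting) boundaries; flux form, so the global mean is conserved
    exactly and no new extrema are created for dt ≤ 1/6.  κ defaults to
    the 90th percentile of the input's gradient magnitudes.
    """
    if dt > 1.0 / 6.0:
        raise ValueError("dt must be <= 1/6 for stability")
    u = np.asarray(volume.values, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("input volume contains non-finite values")
    if kappa is None:
        axes = [ax for ax in range(u.ndim) if u.shape[ax] >= 2]
        grad = np.sqrt(sum(np.gradient(u, axis=ax) ** 2 for ax in axes))
        kappa = float(np.percentile(grad, 90.0))
    if kappa <= 0:  # constant input: nothing to diffuse
        return volume.copy_with(u.copy(), provenance="enhanced")
    u = u.copy()
    for _ in range(n_iter):
        div = np.zeros_like(u)
        for ax in range(u.ndim):
            d = np.diff(u, axis=ax)  # forward difference
            flux = np.exp(-((d / kappa) ** 2)) * d
            pad = [(0, 0)] * u.ndim
            pad[ax] = (1, 1)  # zero flux through both faces
            flux = np.pad(flux, pad)
            div += np.diff(flux, axis=ax)
        u += dt * div
    return volume.copy_with(u, provenance="enhanced")


def equalize_histogram(
    volume: IntensityVolume, n_bins: int = 256, on_log_scale: bool = True
) -> IntensityVolume:
    """Global histogram equalization (display-only output).

    If ``on_log_scale`` the volume is dB-compressed first.  The mapping
    is the standard monotone CDF map; output values lie in [0, 1] and the
    result is flagged ``log_scaled`` so downstream metrics refuse it.
    """
    v = np.asarray(volume.values, dtype=float)
    if v.min() < 0:
        raise ValueError("volume must be nonnegative")
    if np.ptp(v) == 0:
        warnings.warn("constant volume: equalization is the identity", stacklevel=2)
        return volume.copy_with(v.copy(), log_scaled=True, provenance="enhanced")
    if on_log_scale:
        floor = v[v > 0].min()
        v = 10.0 * np.log10(np.maximum(v, floor))
    with warnings.catch_warnings():
        # 3-D stacks can look like color images to skimage; histogram over
        # the flattened volume is exactly what we want
        warnings.filterwarnings("ignore", message=".*color image.*")
        out = exposure.equalize_hist(v, nbins=n_bins)
    return volume.copy_with(out, log_scaled=True, provenance="enhanced")


def resample_isotropic(volume: IntensityVolume, target_voxel_um: float = 4.0) -> IntensityVolume:
    """Trilinear resampling onto a cube-voxel grid of the given pitch.

    The output grid spans the same physical extent (within one voxel);
    pitch metadata is updated on both axes.
    """
    if target_voxel_um <= 0:
        raise ValueError("target voxel must be positive")
    pitches = np.array(
        [volume.axial_pitch_um, volume.lateral_pitch_um, volume.lateral_pitch_um]
    )
    shape = np.array(volume.values.shape)
    extent = shape * pitches
    if np.any(target_voxel_um >= extent):
        raise ValueError("target voxel exceeds the physical extent of an axis")
    new_shape = np.maximum(np.round(extent / target_voxel_um).astype(int), 1)
    if tuple(new_shape) == tuple(shape) and np.allclose(pitches, target_voxel_um):
        return volume.copy_with(volume.values.copy())
    # sample at voxel centers of the new grid, in input-index coordinates
    coords = np.meshgrid(
        *[
            ((np.arange(n) + 0.5) * target_voxel_um) / p - 0.5
            for n, p in zip(new_shape, pitches)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float), coords, order=1, mode="nearest"
    )
    return IntensityVolume(
        values=out,
        axial_pitch_um=target_voxel_um,
        lateral_pitch_um=target_voxel_um,
        provenance=volume.provenance,
        log_scaled=volume.log_scaled,
        n_frames=volume.n_frames,
    )


def flatten_volume(
    volume: IntensityVolume,
    surface_threshold_fraction: float = 0.5,
    median_filter_px: int = 5,
) -> tuple[IntensityVolume, np.ndarray]:
    """Shift every column so the detected tissue surface lies at z = 0.

    The surface of a column is the first depth where the axially smoothed
    intensity exceeds ``surface_threshold_fraction`` times that column's
    maximum; the surface map is median-filtered before shifting.  Columns
    with no crossing inherit the filtered neighborhood value (logged).
    Returns the flattened volume and the surface map z_surf(x, y) in
    voxel units.
    """
    v = np.asarray(volume.values, dtype=float)
    smoothed = ndimage.gaussian_filter1d(v, sigma=2.0, axis=0)
    colmax = smoothed.max(axis=0)
    if np.all(colmax <= 0):
        raise ValueError("no tissue surface present")
    above = smoothed >= surface_threshold_fraction * np.maximum(colmax, 1e-300)
    has_surface = above.any(axis=0)
    z_surf = np.where(has_surface, above.argmax(axis=0), 0).astype(float)
    n_missing = int((~has_surface).sum())
    if n_missing:
        log.warning("%d columns below threshold; surface interpolated from neighbors", n_missing)
        filled = ndimage.median_filter(z_surf, size=max(median_filter_px, 3), mode="nearest")
        z_surf = np.where(has_surface, z_surf, filled)
    z_surf = ndimage.median_filter(z_surf, size=median_filter_px, mode="nearest")

    shifts = np.round(z_surf).astype(int)
    nz = v.shape[0]
    out = np.zeros_like(v)
    for s in np.unique(shifts):
        cols = shifts == s
        if s >= 0:
            out[: nz - s, cols] = v[s:, cols]
        else:
            out[-s:, cols] = v[: nz + s, cols]
    flat = volume.copy_with(out, provenance="enhanced")
    return flat, z_surf


def enhance_chain(volume: IntensityVolume, config: EnhanceConfig | None = None) -> IntensityVolume:
    """Shadow gain → anisotropic diffusion → histogram equalization."""
    cfg = config or EnhanceConfig()
    out = remove_vessel_shadows(volume, cfg.gain_clip_max)
    out = anisotropic_diffusion_3d(
        out, n_iter=cfg.diffusion.n_iter, kappa=cfg.diffusion.kappa, dt=cfg.diffusion.dt
    )
    return equalize_histogram(out, cfg.equalization.n_bins, cfg.equalization.on_log_scale)
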