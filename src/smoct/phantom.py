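"""Synthetic neural-tissue scatterer phantoms with voxelized ground truth.

A phantom is an ordered list of geometric regions (layers, fascicles,
tumors, vessels) placed in a rectangular extent.  Regions later in the
list override earlier ones where they overlap.  Scatterers are drawn as a
Poisson point process per region with Rayleigh-distributed reflectivity
amplitudes, dense enough that coherent imaging of the phantom produces
fully developed speckle.

Coordinates are right-handed with ``z`` the depth axis (increasing away
from the surface), origin at the shallow corner.  All lengths are in
micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Annotated, Literal, Union

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Layer",
    "Fascicle",
    "Tumor",
    "Vessel",
    "PhantomSpec",
    "ScattererField",
    "LabelVolume",
    "build_scatterer_field",
    "ground_truth_masks",
]

_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # mean of Rayleigh(scale=1)


class Layer(BaseModel):
    """Horizontal slab spanning the full lateral extent."""

    kind: Literal["layer"] = "layer"
    z_min_um: float
    z_max_um: float
    density_per_um3: float = Field(ge=0)
    mean_reflectivity: float = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "Layer":
        if not self.z_max_um > self.z_min_um:
            raise ValueError("layer needs z_max_um > z_min_um")
        return self


class Fascicle(BaseModel):
    """Bright tubular bundle: a cylinder between two axis endpoints."""

    kind: Literal["fascicle"] = "fascicle"
    start_um: tuple[float, float, float]
    end_um: tuple[float, float, float]
    diameter_um: float = Field(gt=0)
    density_per_um3: float = Field(ge=0)
    mean_reflectivity: float = Field(ge=0)


class Tumor(BaseModel):
    """Low-reflectivity ellipsoid with optional finger-like projections.

    Fingers are cylinders of diameter ``finger_width_um`` radiating from
    the ellipsoid surface along +x, emulating margin interdigitation.
    Finger base points sit on a ring at 60% of the (y, z) radii, so the
    placement is fully determined by the spec (no extra randomness).
    """

    kind: Literal["tumor"] = "tumor"
    center_um: tuple[float, float, float]
    radii_um: tuple[float, float, float]
    n_fingers: int = Field(default=0, ge=0)
    finger_length_um: float = Field(default=0.0, ge=0)
    finger_width_um: float = Field(default=0.0, ge=0)
    density_per_um3: float = Field(ge=0)
    mean_reflectivity: float = Field(ge=0)

    @model_validator(mode="after")
    def _finger_geometry(self) -> "Tumor":
        if self.n_fingers > 0 and (self.finger_length_um <= 0 or self.finger_width_um <= 0):
            raise ValueError("fingers require positive length and width")
        if any(r <= 0 for r in self.radii_um):
            raise ValueError("tumor radii must be positive")
        return self

    def finger_axes(self) -> list[tuple[float, float, float]]:
        """(x_start, y, z) of each finger axis; axis runs along +x."""
        cx, cy, cz = self.center_um
        rx, ry, rz = self.radii_um
        out = []
        for i in range(self.n_fingers):
            theta = 2.0 * np.pi * i / max(self.n_fingers, 1)
            y = cy + 0.6 * ry * np.cos(theta)
            z = cz + 0.6 * rz * np.sin(theta)
            x0 = cx + rx * np.sqrt(1.0 - 0.6**2)
            out.append((x0, y, z))
        return out


class Vessel(BaseModel):
    """Blood vessel: a pure attenuator (no backscatter) casting a shadow."""

    kind: Literal["vessel"] = "vessel"
    start_um: tuple[float, float, float]
    end_um: tuple[float, float, float]
    diameter_um: float = Field(gt=0)
    attenuation_per_um: float = Field(ge=0)


Region = Annotated[Union[Layer, Fascicle, Tumor, Vessel], Field(discriminator="kind")]


class PhantomSpec(BaseModel):
    """Full phantom description; identical seeds give identical fields."""

    extent_um: tuple[float, float, float]
    regions: list[Region] = Field(default_factory=list)
    background_density_per_um3: float = Field(default=0.0, ge=0)
    background_reflectivity: float = Field(default=0.05, ge=0)
    seed: int = 0

    @field_validator("extent_um")
    @classmethod
    def _positive_extent(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        if any(e <= 0 for e in v):
            raise ValueError("extent_um must be strictly positive on all axes")
        return v


@dataclass
class ScattererField:
    """Continuous-coordinate point scatterers with amplitudes and labels."""

    positions_um: np.ndarray  # (N, 3)
    amplitudes: np.ndarray  # (N,)
    region_labels: np.ndarray  # (N,) int; 0 = background, i+1 = regions[i]
    spec: PhantomSpec

    @property
    def n_scatterers(self) -> int:
        return int(self.positions_um.shape[0])


@dataclass
class LabelVolume:
    """Voxelized ground-truth labels on a regular grid (z, x, y order)."""

    labels: np.ndarray  # (nz, nx, ny) int
    voxel_pitch_um: tuple[float, float, float]  # (z, x, y)
    legend: dict[int, str]


# ---------------------------------------------------------------------------
# region geometry helpers


def _tumor_bbox(region: Tumor, extent) -> tuple[np.ndarray, np.ndarray] | None:
    """Bounding box of ellipsoid ∪ fingers, clipped to the extent."""
    c = np.asarray(region.center_um)
    r = np.asarray(region.radii_um)
    lo, hi = c - r, c + r
    for x0, y, z in region.finger_axes():
        w = region.finger_width_um / 2.0
        lo = np.minimum(lo, [x0, y - w, z - w])
        hi = np.maximum(hi, [x0 + region.finger_length_um, y + w, z + w])
    lo = np.maximum(lo, 0.0)
    hi = np.minimum(hi, extent)
    if np.any(hi <= lo):
        return None
    return lo, hi


def _region_volume_um3(
    region: Region, extent: tuple[float, float, float], rng: np.random.Generator | None = None
) -> float:
    """Volume of region ∩ extent; Monte-Carlo for tumors (clipped shapes)."""
    ex, ey, _ = extent
    if isinstance(region, Layer):
        ez = min(region.z_max_um, extent[2]) - max(region.z_min_um, 0.0)
        return ex * ey * max(ez, 0.0)
    if isinstance(region, Fascicle):
        length = float(np.linalg.norm(np.subtract(region.end_um, region.start_um)))
        return np.pi * (region.diameter_um / 2.0) ** 2 * length
    if isinstance(region, Tumor):
        box = _tumor_bbox(region, extent)
        if box is None:
            return 0.0
        lo, hi = box
        v_box = float(np.prod(hi - lo))
        rng = rng if rng is not None else np.random.default_rng(0)
        pts = rng.uniform(lo, hi, size=(200_000, 3))
        return v_box * float(region_contains(region, pts).mean())
    return 0.0  # vessels carry no scatterers


def _cylinder_contains(
    pts: np.ndarray,
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    diameter: float,
) -> np.ndarray:
    a = np.asarray(start, dtype=float)
    b = np.asarray(end, dtype=float)
    axis = b - a
    length2 = float(axis @ axis)
    if length2 == 0.0:
        return np.zeros(len(pts), dtype=bool)
    t = (pts - a) @ axis / length2
    proj = a + t[:, None] * axis
    d2 = np.sum((pts - proj) ** 2, axis=1)
    return (t >= 0.0) & (t <= 1.0) & (d2 <= (diameter / 2.0) ** 2)


def region_contains(region: Region, pts: np.ndarray) -> np.ndarray:
    """Vectorized membership test; ``pts`` is (N, 3) in μm."""
    pts = np.asarray(pts, dtype=float)
    if isinstance(region, Layer):
        return (pts[:, 2] >= region.z_min_um) & (pts[:, 2] < region.z_max_um)
    if isinstance(region, (Fascicle, Vessel)):
        return _cylinder_contains(pts, region.start_um, region.end_um, region.diameter_um)
    if isinstance(region, Tumor):
        c = np.asarray(region.center_um)
        r = np.asarray(region.radii_um)
        inside = np.sum(((pts - c) / r) ** 2, axis=1) <= 1.0
        for x0, y, z in region.finger_axes():
            inside |= _cylinder_contains(
                pts, (x0, y, z), (x0 + region.finger_length_um, y, z), region.finger_width_um
            )
        return inside
    raise TypeError(f"unknown region type {type(region)!r}")


def _sample_cylinder(
    rng: np.random.Generator,
    n: int,
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    diameter: float,
) -> np.ndarray:
    a = np.asarray(start, dtype=float)
    b = np.asarray(end, dtype=float)
    axis = b - a
    length = float(np.linalg.norm(axis))
    u = axis / length
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v1 = np.cross(u, helper)
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    t = rng.uniform(0.0, length, n)
    r = (diameter / 2.0) * np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return a + t[:, None] * u + (r * np.cos(phi))[:, None] * v1 + (r * np.sin(phi))[:, None] * v2


def _sample_region(rng: np.random.Generator, region: Region, n: int, extent) -> np.ndarray:
    if n == 0:
        return np.empty((0, 3))
    if isinstance(region, Layer):
        lo = np.array([0.0, 0.0, max(region.z_min_um, 0.0)])
        hi = np.array([extent[0], extent[1], min(region.z_max_um, extent[2])])
        return rng.uniform(lo, hi, size=(n, 3))
    if isinstance(region, Fascicle):
        return _sample_cylinder(rng, n, region.start_um, region.end_um, region.diameter_um)
    if isinstance(region, Tumor):
        # rejection sampling from the extent-clipped bounding box, so huge
        # ellipsoids that mostly lie outside the extent stay tractable
        box = _tumor_bbox(region, extent)
        if box is None:
            return np.empty((0, 3))
        lo, hi = box
        chunks: list[np.ndarray] = []
        todo = n
        for _ in range(200):
            if todo <= 0:
                break
            cand = rng.uniform(lo, hi, size=(4 * todo + 64, 3))
            keep = cand[region_contains(region, cand)][:todo]
            chunks.append(keep)
            todo -= len(keep)
        if todo > 0:
            raise ValueError("tumor region has (near-)zero overlap with the extent")
        return np.concatenate(chunks, axis=0)
    raise TypeError(f"cannot sample scatterers for {type(region)!r}")


# ---------------------------------------------------------------------------
# public operations


def build_scatterer_field(spec: PhantomSpec) -> ScattererField:
    """Draw the Poisson scatterer field described by ``spec``.

    Per region the scatterer count is Poisson(density × region volume) and
    amplitudes are i.i.d. Rayleigh with the region's ``mean_reflectivity``
    as mean.  Later regions override earlier ones: a scatterer is kept only
    if the last listed region containing its position is the region that
    generated it (vessels generate none, so they carve scatterer-free
    shadow-casting lumens).  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    extent = spec.extent_um
    pos_parts: list[np.ndarray] = []
    amp_parts: list[np.ndarray] = []
    lab_parts: list[np.ndarray] = []

    def _amplitudes(n: int, mean_reflectivity: float) -> np.ndarray:
        if mean_reflectivity == 0.0:
            return np.zeros(n)
        return rng.rayleigh(scale=mean_reflectivity / _RAYLEIGH_MEAN, size=n)

    if spec.background_density_per_um3 > 0:
        vol = extent[0] * extent[1] * extent[2]
        n = int(rng.poisson(spec.background_density_per_um3 * vol))
        pos_parts.append(rng.uniform([0, 0, 0], extent, size=(n, 3)))
        amp_parts.append(_amplitudes(n, spec.background_reflectivity))
        lab_parts.append(np.zeros(n, dtype=np.int32))

    for i, region in enumerate(spec.regions):
        if isinstance(region, Vessel):
            continue
        vol = _region_volume_um3(region, extent, rng)
        if vol <= 0 or region.density_per_um3 == 0:
            if vol < 0:
                raise ValueError(f"region {i} has zero/negative overlap with the extent")
            continue
        n = int(rng.poisson(region.density_per_um3 * vol))
        pos_parts.append(_sample_region(rng, region, n, extent))
        amp_parts.append(_amplitudes(n, region.mean_reflectivity))
        lab_parts.append(np.full(n, i + 1, dtype=np.int32))

    if pos_parts:
        positions = np.concatenate(pos_parts, axis=0)
        amplitudes = np.concatenate(amp_parts)
        labels = np.concatenate(lab_parts)
    else:
        positions = np.empty((0, 3))
        amplitudes = np.empty(0)
        labels = np.empty(0, dtype=np.int32)

    # drop out-of-extent points (regions poking past the box)
    inside = np.all((positions >= 0.0) & (positions <= np.asarray(extent)), axis=1)
    positions, amplitudes, labels = positions[inside], amplitudes[inside], labels[inside]

    # last listed region containing each point wins; discard overridden draws
    winner = np.zeros(len(positions), dtype=np.int32)
    for i, region in enumerate(spec.regions):
        winner[region_contains(region, positions)] = i + 1
    keep = winner == labels
    return ScattererField(
        positions_um=positions[keep],
        amplitudes=amplitudes[keep],
        region_labels=labels[keep],
        spec=spec,
    )


def _legend(spec: PhantomSpec) -> dict[int, str]:
    legend = {0: "background"}
    counts: dict[str, int] = {}
    for i, region in enumerate(spec.regions):
        counts[region.kind] = counts.get(region.kind, 0) + 1
        legend[i + 1] = f"{region.kind}-{counts[region.kind]}"
    return legend


def ground_truth_masks(
    spec: PhantomSpec, voxel_pitch_um: tuple[float, float, float]
) -> LabelVolume:
    """Voxelize the spec: each voxel center gets the last containing region.

    ``voxel_pitch_um`` is (z, x, y); the grid covers the phantom extent.
    """
    pz, px, py = voxel_pitch_um
    if min(pz, px, py) <= 0:
        raise ValueError("voxel pitch must be positive")
    ex, ey, ez = spec.extent_um
    if pz > ez or px > ex or py > ey:
        raise ValueError("voxel pitch exceeds the phantom extent")
    nz, nx, ny = int(round(ez / pz)), int(round(ex / px)), int(round(ey / py))
    zc = (np.arange(nz) + 0.5) * pz
    xc = (np.arange(nx) + 0.5) * px
    yc = (np.arange(ny) + 0.5) * py
    Z, X, Y = np.meshgrid(zc, xc, yc, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    labels = np.zeros(len(pts), dtype=np.int32)
    for i, region in enumerate(spec.regions):
        labels[region_contains(region, pts)] = i + 1
    present = set(np.unique(labels).tolist())
    legend = {k: v for k, v in _legend(spec).items() if k in present or k == 0}
    return LabelVolume(
        labels=labels.reshape(nz, nx, ny),
        voxel_pitch_um=(pz, px, py),
        legend=legend,
    )
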