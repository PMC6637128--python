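"""Persistence for frame sets, volumes, labels and configs.

Frame sets go to HDF5 (bit-exact round trip); intensity volumes to
32-bit float multi-page TIFF with pitch metadata in the image
description; label volumes to TIFF plus a JSON legend sidecar; phantom
and protocol specs to YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .forward_model import ScanGeometry, SourceSpectrum, SpectralFrameSet
from .phantom import LabelVolume, PhantomSpec
from .reconstruct import IntensityVolume

__all__ = [
    "save_frameset",
    "load_frameset",
    "save_volume",
    "load_volume",
    "save_label_volume",
    "load_label_volume",
    "save_phantom_spec",
    "load_phantom_spec",
]


def save_frameset(path, frames: SpectralFrameSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=frames.data)
        f.create_dataset("envelope", data=frames.source.envelope)
        f.create_dataset("wavelength_nm", data=frames.source.wavelength_nm)
        f.attrs["a2"] = frames.dispersion[0]
        f.attrs["a3"] = frames.dispersion[1]
        f.attrs["noise_sd"] = frames.noise_sd
        f.attrs["seed"] = frames.seed
        f.attrs["center_wavelength_nm"] = frames.source.center_wavelength_nm
        f.attrs["bandwidth_fwhm_nm"] = frames.source.bandwidth_fwhm_nm
        if frames.diffuser_correlation is not None:
            f.attrs["diffuser_correlation"] = frames.diffuser_correlation
        for key in (
            "lateral_pitch_um",
            "n_ascans",
            "n_bscans",
            "lateral_psf_fwhm_um",
            "medium_group_index",
            "x0_um",
            "y0_um",
        ):
            f.attrs[key] = getattr(frames.geometry, key)


def load_frameset(path) -> SpectralFrameSet:
    with h5py.File(path, "r") as f:
        data = f["frames"][()]
        envelope = f["envelope"][()]
        wavelength = f["wavelength_nm"][()]
        attrs = dict(f.attrs)
    source = SourceSpectrum(
        center_wavelength_nm=float(attrs["center_wavelength_nm"]),
        bandwidth_fwhm_nm=float(attrs["bandwidth_fwhm_nm"]),
        n_samples=len(wavelength),
        wavelength_nm=wavelength,
        envelope=envelope,
    )
    geometry = ScanGeometry(
        lateral_pitch_um=float(attrs["lateral_pitch_um"]),
        n_ascans=int(attrs["n_ascans"]),
        n_bscans=int(attrs["n_bscans"]),
        lateral_psf_fwhm_um=float(attrs["lateral_psf_fwhm_um"]),
        medium_group_index=float(attrs["medium_group_index"]),
        x0_um=float(attrs["x0_um"]),
        y0_um=float(attrs["y0_um"]),
    )
    return SpectralFrameSet(
        data=data,
        source=source,
        geometry=geometry,
        dispersion=(float(attrs["a2"]), float(attrs["a3"])),
        noise_sd=float(attrs["noise_sd"]),
        seed=int(attrs["seed"]),
        diffuser_correlation=float(attrs["diffuser_correlation"])
        if "diffuser_correlation" in attrs
        else None,
    )


def save_volume(path, volume: IntensityVolume, db_export: bool = False, dynamic_range_db: float = 40.0) -> None:
    """Write (z, x, y) pages as float32 TIFF; metadata in the description.

    With ``db_export`` an additional 8-bit dB-scaled stack is written next
    to the float file, windowed over the top ``dynamic_range_db`` dB.
    """
    meta = {
        "axial_pitch_um": volume.axial_pitch_um,
        "lateral_pitch_um": volume.lateral_pitch_um,
        "provenance": volume.provenance,
        "log_scaled": volume.log_scaled,
        "n_frames": volume.n_frames,
    }
    tifffile.imwrite(
        path,
        volume.values.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )
    if db_export:
        v = np.asarray(volume.values, dtype=float)
        floor = v[v > 0].min() if (v > 0).any() else 1.0
        db = 10.0 * np.log10(np.maximum(v, floor))
        top = db.max()
        scaled = np.clip((db - (top - dynamic_range_db)) / dynamic_range_db, 0.0, 1.0)
        tifffile.imwrite(
            Path(path).with_suffix(".db8.tif"), (scaled * 255).astype(np.uint8), photometric="minisblack"
        )


def load_volume(path) -> IntensityVolume:
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return IntensityVolume(
        values=np.asarray(values, dtype=float),
        axial_pitch_um=float(meta["axial_pitch_um"]),
        lateral_pitch_um=float(meta["lateral_pitch_um"]),
        provenance=meta.get("provenance", "single-frame OCT"),
        log_scaled=bool(meta.get("log_scaled", False)),
        n_frames=int(meta.get("n_frames", 1)),
    )


def save_label_volume(path, labels: LabelVolume) -> None:
    path = Path(path)
    tifffile.imwrite(
        path,
        labels.labels.astype(np.int32),
        photometric="minisblack",
        description=json.dumps({"voxel_pitch_um": list(labels.voxel_pitch_um)}),
    )
    sidecar = path.with_suffix(".legend.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in labels.legend.items()}, indent=2))


def load_label_volume(path) -> LabelVolume:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    legend = json.loads(path.with_suffix(".legend.json").read_text())
    return LabelVolume(
        labels=np.asarray(labels, dtype=np.int32),
        voxel_pitch_um=tuple(meta["voxel_pitch_um"]),
        legend={int(k): v for k, v in legend.items()},
    )


def save_phantom_spec(path, spec: PhantomSpec) -> None:
    Path(path).write_text(yaml.safe_dump(spec.model_dump(), sort_keys=False))


def load_phantom_spec(path) -> PhantomSpec:
    return PhantomSpec.model_validate(yaml.safe_load(Path(path).read_text()))
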