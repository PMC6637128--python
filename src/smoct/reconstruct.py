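"""Spectral-domain OCT reconstruction.

Background subtraction, k-linearization (cubic interpolation from the
uniform-wavelength spectrometer grid onto a uniform wavenumber grid),
Hann apodization, polynomial dispersion compensation, inverse Fourier
transform and magnitude-squared imaging, plus an entropy-minimizing
coarse-to-fine search that estimates the dispersion coefficients from
the data itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .forward_model import SpectralFrameSet

__all__ = [
    "DispersionModel",
    "IntensityVolume",
    "reconstruct_volume",
    "axial_psf_fwhm",
    "estimate_dispersion",
]


@dataclass(frozen=True)
class DispersionModel:
    """Polynomial spectral phase exp(i[a2 (k−k0)² + a3 (k−k0)³])."""

    a2: float = 0.0  # rad·μm²
    a3: float = 0.0  # rad·μm³
    k0_per_um: float | None = None  # defaults to the source center wavenumber

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a2) and np.isfinite(self.a3)):
            raise ValueError("dispersion coefficients must be finite")

    def phase(self, k: np.ndarray, k0: float) -> np.ndarray:
        dk = k - (self.k0_per_um if self.k0_per_um is not None else k0)
        return self.a2 * dk**2 + self.a3 * dk**3


@dataclass
class IntensityVolume:
    """Reconstructed 3-D intensity image, axes ordered (z, x, y)."""

    values: np.ndarray  # nonnegative
    axial_pitch_um: float
    lateral_pitch_um: float
    provenance: str = "single-frame OCT"
    log_scaled: bool = False
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise ValueError("pitches must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.values.shape)

    def copy_with(self, values: np.ndarray, **meta) -> "IntensityVolume":
        out = replace(self, values=values)
        for key, val in meta.items():
            setattr(out, key, val)
        return out


def _linearize(frames: SpectralFrameSet) -> tuple[np.ndarray, np.ndarray, float]:
    """Background-subtract and resample spectra onto a uniform k grid.

    Returns (resampled data (M,B,A,K), uniform k grid ascending, axial
    pitch in μm).  The background is the frame-set mean spectrum, which
    removes the reference DC term.
    """
    k_desc = frames.source.wavenumber_per_um
    k_asc = k_desc[::-1]
    background = frames.data.mean(axis=(0, 1, 2))
    y = (frames.data - background)[..., ::-1]  # ascending k order
    k_uniform = np.linspace(k_asc[0], k_asc[-1], frames.source.n_samples)
    spline = CubicSpline(k_asc, y, axis=-1)
    resampled = spline(k_uniform)
    dk = (k_uniform[-1] - k_uniform[0]) / (len(k_uniform) - 1)
    axial_pitch = np.pi / (len(k_uniform) * dk * frames.geometry.medium_group_index)
    return resampled, k_uniform, axial_pitch


_WINDOWS = {
    "hann": lambda n: np.hanning(n),
    "hamming": lambda n: np.hamming(n),
    "none": lambda n: np.ones(n),
}


def reconstruct_volume(
    frames: SpectralFrameSet,
    model: DispersionModel | None = None,
    window: str = "hann",
) -> list[IntensityVolume]:
    """Reconstruct every frame into an intensity volume (z, x, y).

    Pipeline per A-scan: subtract the frame-set mean spectrum, cubic-
    interpolate onto a uniform wavenumber grid spanning the same range,
    apodize, multiply by the dispersion-compensation phase
    exp(−i[a2(k−k0)² + a3(k−k0)³]), inverse-transform and keep the
    positive-depth half as magnitude-squared intensity.
    """
    if model is None:
        model = DispersionModel()
    if window not in _WINDOWS:
        raise ValueError(f"unsupported window {window!r}; choose from {sorted(_WINDOWS)}")
    resampled, k_uniform, axial_pitch = _linearize(frames)
    k0 = frames.source.center_wavenumber_per_um
    comp = _WINDOWS[window](len(k_uniform)) * np.exp(-1j * model.phase(k_uniform, k0))
    ascans = np.fft.fft(resampled * comp, axis=-1)
    half = frames.source.n_samples // 2
    intensity = np.abs(ascans[..., :half]) ** 2  # (M, B, A, Z)
    return [
        IntensityVolume(
            values=np.ascontiguousarray(frame.transpose(2, 1, 0)),  # (Z, A, B) -> (z, x, y)
            axial_pitch_um=float(axial_pitch),
            lateral_pitch_um=frames.geometry.lateral_pitch_um,
            provenance="single-frame OCT",
        )
        for frame in intensity
    ]


def axial_psf_fwhm(
    volume: IntensityVolume,
    lateral_index: tuple[int, int] = (0, 0),
    noise_floor_factor: float = 10.0,
    on_amplitude: bool = True,
) -> float:
    """Linear-interpolated FWHM (μm) of the dominant peak of one A-scan.

    By default the width is taken on the magnitude profile √I (the fringe
    envelope), which is the convention under which a Gaussian source of
    center λ0 and bandwidth Δλ gives the textbook axial resolution
    (2 ln2/π)·λ0²/Δλ.  Set ``on_amplitude=False`` to measure the
    intensity profile directly.
    """
    ix, iy = lateral_index
    profile = np.asarray(volume.values[:, ix, iy], dtype=float)
    if on_amplitude:
        profile = np.sqrt(np.maximum(profile, 0.0))
    peak = int(np.argmax(profile))
    pmax = profile[peak]
    floor = np.median(profile)
    if pmax <= 0 or (floor > 0 and pmax < noise_floor_factor * floor):
        raise ValueError("no dominant peak above the noise floor")
    half = pmax / 2.0

    def _cross(idx_range) -> float:
        prev = peak
        for i in idx_range:
            if profile[i] <= half:
                frac = (profile[prev] - half) / (profile[prev] - profile[i])
                return prev + frac * (i - prev)
            prev = i
        return float(idx_range[-1]) if len(idx_range) else float(peak)

    left = _cross(range(peak - 1, -1, -1)) if peak > 0 else peak - 0.5
    right = _cross(range(peak + 1, len(profile))) if peak < len(profile) - 1 else peak + 0.5
    return float((right - left) * volume.axial_pitch_um)


def _entropy(intensity: np.ndarray) -> float:
    total = intensity.sum()
    if total <= 0:
        raise ValueError("flat objective: no signal to focus")
    p = intensity / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def estimate_dispersion(
    frames: SpectralFrameSet,
    a2_range: tuple[float, float],
    a3_range: tuple[float, float] | None = None,
    n_grid: int = 21,
    n_levels: int = 3,
    window: str = "hann",
) -> DispersionModel:
    """Grid-search (a2, a3) minimizing image intensity entropy.

    Coarse-to-fine: ``n_levels`` rounds of ``n_grid``-point grids, each
    refined around the previous optimum.  Ties break toward smaller
    |a2| + |a3|.  Only frame 0 is used (sharpness does not depend on
    compounding).  Deterministic.
    """
    first = SpectralFrameSet(
        data=frames.data[:1],
        source=frames.source,
        geometry=frames.geometry,
        dispersion=frames.dispersion,
        noise_sd=frames.noise_sd,
        seed=frames.seed,
    )
    resampled, k_uniform, _ = _linearize(first)
    win = _WINDOWS[window](len(k_uniform))
    pre = resampled[0] * win  # (B, A, K)
    if np.abs(pre).max() == 0:
        raise ValueError("flat objective: empty scene")
    k0 = frames.source.center_wavenumber_per_um
    dk = k_uniform - k0
    half = frames.source.n_samples // 2

    def objective(a2: float, a3: float) -> float:
        phase = np.exp(-1j * (a2 * dk**2 + a3 * dk**3))
        img = np.abs(np.fft.fft(pre * phase, axis=-1)[..., :half]) ** 2
        return _entropy(img)

    lo2, hi2 = a2_range
    lo3, hi3 = a3_range if a3_range is not None else (0.0, 0.0)
    best = (0.5 * (lo2 + hi2), 0.5 * (lo3 + hi3))
    for _ in range(n_levels):
        a2s = np.linspace(lo2, hi2, n_grid) if hi2 > lo2 else np.array([lo2])
        a3s = np.linspace(lo3, hi3, n_grid) if hi3 > lo3 else np.array([lo3])
        scores = np.array([[objective(a2, a3) for a3 in a3s] for a2 in a2s])
        tol = 1e-12 * max(1.0, abs(scores.min()))
        candidates = np.argwhere(scores <= scores.min() + tol)
        i2, i3 = min(candidates, key=lambda c: abs(a2s[c[0]]) + abs(a3s[c[1]]))
        best = (float(a2s[i2]), float(a3s[i3]))
        step2 = (hi2 - lo2) / (n_grid - 1) if hi2 > lo2 else 0.0
        step3 = (hi3 - lo3) / (n_grid - 1) if hi3 > lo3 else 0.0
        lo2, hi2 = max(best[0] - step2, a2_range[0]), min(best[0] + step2, a2_range[1])
        if a3_range is not None:
            lo3, hi3 = max(best[1] - step3, a3_range[0]), min(best[1] + step3, a3_range[1])
    return DispersionModel(a2=best[0], a3=best[1])
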