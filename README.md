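# smoct

Speckle-modulating spectral-domain OCT (SM-OCT), simulated end to end and
verifiable against known ground truth.

The package contains:

- **`smoct.phantom`** — synthetic neural-tissue phantoms: layered cortex,
  bright tubular fascicles, low-reflectivity tumors with finger-like margin
  projections, and vessels that act as pure attenuators.  Scatterers are a
  Poisson point process with Rayleigh amplitudes; voxelized ground-truth
  label volumes come from the same spec.
- **`smoct.forward_model`** — a spectral-domain interferogram simulator:
  Gaussian source (1300 nm center, 170 nm FWHM by default) sampled uniformly
  in wavelength, Gaussian lateral beam (9 µm FWHM), polynomial spectral
  dispersion, additive noise, and a rotating-diffuser model that perturbs
  per-scatterer phases with controllable frame-to-frame correlation ρ
  (ρ=1 ≙ diffuser removed / conventional OCT, ρ=0 ≙ fully decorrelated
  speckle per frame).
- **`smoct.reconstruct`** — background subtraction, k-linearization,
  Hann apodization, polynomial dispersion compensation (plus an
  entropy-minimizing coarse-to-fine estimator for the coefficients),
  FFT and magnitude imaging; axial PSF FWHM measurement.
- **`smoct.compound`** — linear-scale intensity averaging and speckle
  statistics (contrast σ/µ, contrast-vs-M tables, the 1/√M law).
- **`smoct.enhance`** — vessel-shadow gain compensation, 3-D Perona–Malik
  anisotropic diffusion, global histogram equalization, isotropic 4 µm
  resampling, and surface flattening for en-face views.
- **`smoct.margin`** — en-face tumor segmentation by Otsu threshold,
  sub-pixel margin curves, symmetric margin-localization error against
  phantom ground truth, and cortical-layer depth profiles with CNR.
- **`smoct.protocols`** — end-to-end experiment runner pairing an SM-OCT
  branch (ρ=0) with a conventional-OCT control (ρ=1) on the same phantom.

## Test

```
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which checks the
pipeline-level properties (fully developed speckle with exponential
intensity and contrast ≈ 1, the 1/√M compounding law, the in-air axial
PSF closed form, dispersion recovery, shadow-gain exactness, diffusion
safety, resampling arithmetic, tumor-margin recovery, and cortical-layer
contrast).  The heavy fixtures take a couple of minutes on one CPU.

## CLI

```
smoct simulate  --config phantom.yaml --seed 1 --out-dir out/ --frames 8 --rho 0
smoct reconstruct --frames out/frames.h5 --out-dir out/rec/
smoct compound  out/rec/frame_*.tif --out out/compound.tif
smoct enhance   --volume out/compound.tif --out out/enhanced.tif
smoct segment   --volume out/compound.tif --out-dir out/seg/
smoct metrics   --volume out/compound.tif --roi 14 56 4 60 0 1
smoct protocol run --config protocol.yaml --seed 1 --out-dir out/protocol/
```

Configs are YAML (`PhantomSpec` / `ProtocolSpec`); frame sets persist as
HDF5, volumes as float32 multi-page TIFF with pitch metadata, label
volumes as TIFF plus a JSON legend sidecar.

## Conventions

Right-handed coordinates with z the depth axis (origin at the shallow
corner), all lengths in µm; depths are optical path lengths (medium group
index 1 by default).  Compounding and all quantitative metrics operate on
linear-scale intensity; histogram equalization is display-only and flags
its output accordingly.
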