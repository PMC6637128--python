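import numpy as np
import pytest

from smoct import (
    Layer,
    PhantomSpec,
    ScanGeometry,
    ScattererField,
    diffuser_sequence,
    make_source_spectrum,
    simulate_frames,
)


@pytest.fixture(scope="session")
def default_source():
    return make_source_spectrum(1300.0, 170.0, 1024)


@pytest.fixture(scope="session")
def small_source():
    return make_source_spectrum(1300.0, 170.0, 128)


def single_reflector_frames(z_um=200.0, x_um=0.0, n_samples=1024, n_ascans=16, a2=0.0, a3=0.0):
    """Noiseless frame set imaging one reflector; exact (unbinned) route."""
    source = make_source_spectrum(1300.0, 170.0, n_samples)
    geometry = ScanGeometry(lateral_pitch_um=6.0, n_ascans=n_ascans, n_bscans=1)
    spec = PhantomSpec(extent_um=(max(6.0 * n_ascans, 10.0), 1.0, max(2 * z_um, 100.0)))
    field = ScattererField(
        positions_um=np.array([[x_um, 0.0, z_um]]),
        amplitudes=np.array([0.03]),
        region_labels=np.array([0], dtype=np.int32),
        spec=spec,
    )
    states = diffuser_sequence(1, 1.0, 1, seed=0)
    return simulate_frames(
        field, source, geometry, (a2, a3), states, noise_sd=0.0, seed=0, precision="double"
    )


@pytest.fixture(scope="session")
def reflector_frames():
    return single_reflector_frames()


@pytest.fixture(scope="session")
def speckle_slab_frames():
    """Small dense homogeneous B-scan frame set, M=8, uncorrelated speckle."""
    phantom = PhantomSpec(
        extent_um=(430.0, 20.0, 70.0),
        regions=[Layer(z_min_um=10.0, z_max_um=70.0, density_per_um3=0.5, mean_reflectivity=0.002)],
        seed=21,
    )
    from smoct import build_scatterer_field

    field = build_scatterer_field(phantom)
    source = make_source_spectrum(1300.0, 170.0, 128)
    geometry = ScanGeometry(lateral_pitch_um=6.0, n_ascans=64, n_bscans=1, x0_um=16.0, y0_um=10.0)
    states = diffuser_sequence(8, 0.0, field.n_scatterers, seed=22)
    return simulate_frames(field, source, geometry, (0.0, 0.0), states, 0.0, seed=23)
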