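import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smoct import (
    Fascicle,
    Layer,
    PhantomSpec,
    Tumor,
    Vessel,
    build_scatterer_field,
    ground_truth_masks,
)
from smoct.phantom import region_contains


def layer_spec(density=0.05, reflectivity=1.0, seed=0):
    return PhantomSpec(
        extent_um=(100.0, 100.0, 50.0),
        regions=[Layer(z_min_um=0.0, z_max_um=50.0, density_per_um3=density, mean_reflectivity=reflectivity)],
        seed=seed,
    )


class TestBuildScattererField:
    def test_zero_density_gives_empty_field(self):
        field = build_scatterer_field(layer_spec(density=0.0))
        assert field.n_scatterers == 0

    def test_positions_inside_extent(self):
        field = build_scatterer_field(layer_spec(density=0.02, seed=3))
        assert np.all(field.positions_um >= 0)
        assert np.all(field.positions_um <= np.array([100.0, 100.0, 50.0]))

    def test_amplitudes_nonnegative(self):
        field = build_scatterer_field(layer_spec(density=0.02, seed=3))
        assert np.all(field.amplitudes >= 0)

    def test_mean_amplitude_tracks_reflectivity(self):
        # tumor at 0.3 vs layer at 1.0 -> sample-mean amplitude ratio ~0.3
        spec = PhantomSpec(
            extent_um=(200.0, 200.0, 100.0),
            regions=[
                Layer(z_min_um=0.0, z_max_um=50.0, density_per_um3=0.05, mean_reflectivity=1.0),
                Tumor(
                    center_um=(100.0, 100.0, 75.0),
                    radii_um=(80.0, 80.0, 24.0),
                    density_per_um3=0.05,
                    mean_reflectivity=0.3,
                ),
            ],
            seed=8,
        )
        field = build_scatterer_field(spec)
        layer_amp = field.amplitudes[field.region_labels == 1]
        tumor_amp = field.amplitudes[field.region_labels == 2]
        assert len(layer_amp) >= 10_000 and len(tumor_amp) >= 10_000
        assert layer_amp.mean() == pytest.approx(1.0, rel=0.05)
        assert tumor_amp.mean() / layer_amp.mean() == pytest.approx(0.3, rel=0.05)

    @pytest.mark.parametrize("diameter", [40.0, 80.0])
    def test_fascicle_scatterers_inside_cylinder(self, diameter):
        fascicle = Fascicle(
            start_um=(0.0, 100.0, 100.0),
            end_um=(300.0, 100.0, 100.0),
            diameter_um=diameter,
            density_per_um3=0.05,
            mean_reflectivity=2.0,
        )
        spec = PhantomSpec(extent_um=(300.0, 200.0, 200.0), regions=[fascicle], seed=4)
        field = build_scatterer_field(spec)
        assert field.n_scatterers > 100
        radial = np.hypot(field.positions_um[:, 1] - 100.0, field.positions_um[:, 2] - 100.0)
        assert np.all(radial <= diameter / 2.0 + 1e-9)
        assert 40.0 <= diameter <= 80.0

    def test_reproducible_under_seed(self):
        a = build_scatterer_field(layer_spec(density=0.02, seed=11))
        b = build_scatterer_field(layer_spec(density=0.02, seed=11))
        assert np.array_equal(a.positions_um, b.positions_um)
        assert np.array_equal(a.amplitudes, b.amplitudes)
        assert np.array_equal(a.region_labels, b.region_labels)

    def test_different_seed_differs(self):
        a = build_scatterer_field(layer_spec(density=0.02, seed=11))
        b = build_scatterer_field(layer_spec(density=0.02, seed=12))
        assert not np.array_equal(a.positions_um, b.positions_um)

    def test_poisson_count_mean(self):
        # empirical mean count over 200 seeds within 3 SE of density * volume
        lam = 0.002 * 100 * 100 * 50  # = 1000
        counts = [
            build_scatterer_field(layer_spec(density=0.002, seed=s)).n_scatterers
            for s in range(200)
        ]
        se = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_later_region_overrides_earlier(self):
        spec = PhantomSpec(
            extent_um=(100.0, 100.0, 100.0),
            regions=[
                Layer(z_min_um=0.0, z_max_um=100.0, density_per_um3=0.01, mean_reflectivity=1.0),
                Layer(z_min_um=40.0, z_max_um=60.0, density_per_um3=0.01, mean_reflectivity=0.2),
            ],
            seed=5,
        )
        field = build_scatterer_field(spec)
        z = field.positions_um[:, 2]
        in_band = (z >= 40.0) & (z < 60.0)
        assert np.all(field.region_labels[in_band] == 2)
        assert np.all(field.region_labels[~in_band] == 1)

    def test_vessel_lumen_has_no_scatterers(self):
        spec = PhantomSpec(
            extent_um=(100.0, 100.0, 100.0),
            regions=[
                Layer(z_min_um=0.0, z_max_um=100.0, density_per_um3=0.02, mean_reflectivity=1.0),
                Vessel(start_um=(50.0, 0.0, 30.0), end_um=(50.0, 100.0, 30.0), diameter_um=20.0, attenuation_per_um=0.1),
            ],
            seed=6,
        )
        field = build_scatterer_field(spec)
        inside = region_contains(spec.regions[1], field.positions_um)
        assert not inside.any()

    def test_rejects_nonpositive_extent(self):
        with pytest.raises(ValueError):
            PhantomSpec(extent_um=(0.0, 10.0, 10.0))

    def test_rejects_negative_density(self):
        with pytest.raises(ValueError):
            Layer(z_min_um=0, z_max_um=1, density_per_um3=-1.0, mean_reflectivity=1.0)


class TestGroundTruthMasks:
    def test_empty_spec_all_background(self):
        labels = ground_truth_masks(PhantomSpec(extent_um=(40.0, 40.0, 40.0)), (4.0, 4.0, 4.0))
        assert np.all(labels.labels == 0)
        assert labels.legend[0] == "background"

    def test_full_extent_layer_labels_everything(self):
        spec = PhantomSpec(
            extent_um=(40.0, 40.0, 40.0),
            regions=[Layer(z_min_um=0.0, z_max_um=40.0, density_per_um3=0.0, mean_reflectivity=1.0)],
        )
        labels = ground_truth_masks(spec, (4.0, 4.0, 4.0))
        assert np.all(labels.labels == 1)
        assert labels.legend[1] == "layer-1"

    def test_halfspace_tumor_volume_fraction(self):
        # a giant ellipsoid covering x > 100 acts as a half-space
        spec = PhantomSpec(
            extent_um=(200.0, 80.0, 80.0),
            regions=[
                Tumor(
                    center_um=(100.0 + 5000.0, 40.0, 40.0),
                    radii_um=(5000.0, 9000.0, 9000.0),
                    density_per_um3=0.0,
                    mean_reflectivity=0.1,
                )
            ],
        )
        labels = ground_truth_masks(spec, (4.0, 4.0, 4.0))
        frac = (labels.labels > 0).mean()
        # analytic fraction 0.5, one voxel shell = 1 voxel / 50 along x
        assert frac == pytest.approx(0.5, abs=1.0 / 50.0)

    def test_rejects_pitch_larger_than_extent(self):
        with pytest.raises(ValueError):
            ground_truth_masks(PhantomSpec(extent_um=(10.0, 10.0, 10.0)), (20.0, 4.0, 4.0))

    def test_rejects_nonpositive_pitch(self):
        with pytest.raises(ValueError):
            ground_truth_masks(PhantomSpec(extent_um=(10.0, 10.0, 10.0)), (0.0, 4.0, 4.0))

    def test_mask_field_consistency(self):
        # >=99% of scatterers in non-boundary voxels carry the voxel's label
        spec = PhantomSpec(
            extent_um=(120.0, 120.0, 80.0),
            regions=[
                Layer(z_min_um=0.0, z_max_um=40.0, density_per_um3=0.02, mean_reflectivity=1.0),
                Layer(z_min_um=40.0, z_max_um=80.0, density_per_um3=0.02, mean_reflectivity=0.5),
                Fascicle(
                    start_um=(0.0, 60.0, 20.0),
                    end_um=(120.0, 60.0, 20.0),
                    diameter_um=50.0,
                    density_per_um3=0.05,
                    mean_reflectivity=2.0,
                ),
            ],
            seed=9,
        )
        field = build_scatterer_field(spec)
        labels = ground_truth_masks(spec, (4.0, 4.0, 4.0))
        grid = labels.labels
        interior = np.ones_like(grid, dtype=bool)
        for ax in range(3):
            same_fwd = np.diff(grid, axis=ax) == 0
            pad_lo = [(0, 0)] * 3
            pad_hi = [(0, 0)] * 3
            pad_lo[ax], pad_hi[ax] = (1, 0), (0, 1)
            interior &= np.pad(same_fwd, pad_lo, constant_values=True)
            interior &= np.pad(same_fwd, pad_hi, constant_values=True)
        iz = np.clip((field.positions_um[:, 2] / 4.0).astype(int), 0, grid.shape[0] - 1)
        ix = np.clip((field.positions_um[:, 0] / 4.0).astype(int), 0, grid.shape[1] - 1)
        iy = np.clip((field.positions_um[:, 1] / 4.0).astype(int), 0, grid.shape[2] - 1)
        keep = interior[iz, ix, iy]
        match = grid[iz, ix, iy][keep] == field.region_labels[keep]
        assert match.mean() >= 0.99


@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=15, deadline=None)
def test_masks_reproducible(seed):
    spec = PhantomSpec(
        extent_um=(40.0, 40.0, 40.0),
        regions=[Layer(z_min_um=10.0, z_max_um=30.0, density_per_um3=0.001, mean_reflectivity=1.0)],
        seed=seed,
    )
    a = ground_truth_masks(spec, (4.0, 4.0, 4.0))
    b = ground_truth_masks(spec, (4.0, 4.0, 4.0))
    assert np.array_equal(a.labels, b.labels)
    assert a.legend == b.legend
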