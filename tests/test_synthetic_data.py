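import math

import numpy as np
import pytest

from bonegrad import gradient_profiling as gp
from bonegrad import synthetic_data as sd
from bonegrad.segmentation import BinaryVolume
from conftest import tiny_spec


def _plan(truth, step):
    bone = BinaryVolume(truth.bone_mask, truth.spec.voxel_size)
    return gp.plan_slices(bone, step=step)


class TestPhantomGeneration:
    def test_zero_porosity_yields_solid_shell(self):
        gray, truth = sd.generate_cortical_phantom(tiny_spec(porosity=0.0))
        assert not truth.canals
        assert not truth.void_mask.any()
        tp = sd.true_profile(truth, _plan(truth, 300.0), depths=(100.0,), window=(200.0, 100.0))
        assert (tp["true_porosity"] == 0).all()

    def test_forced_single_canal_matches_voxel_counting_oracle(self):
        spec = tiny_spec(forced_canals=[(0.0, 60.0, 58.0)])
        gray, truth = sd.generate_cortical_phantom(spec)
        label = truth.label_volume
        # independent rasterization: voxel centres within 58 µm of the axis
        nz, n, dist_na, c0 = truth.label_volume.shape[0], label.shape[1], None, None
        vox = spec.voxel_size
        coords = (np.arange(n) + 0.5) * vox - n * vox / 2.0
        d2 = (coords[:, None] - 0.0) ** 2 + (coords[None, :] - 60.0) ** 2
        per_slice = int((d2 <= 58.0**2).sum())
        assert (label == 2).sum() == per_slice * nz
        shell = label == 1
        porosity = (label >= 2).sum() / (shell.sum() + (label >= 2).sum())
        assert 0 < porosity < 1

    def test_forced_single_canal_true_diameter_is_116(self):
        spec = tiny_spec(forced_canals=[(0.0, 60.0, 58.0)])
        _, truth = sd.generate_cortical_phantom(spec)
        tp = sd.true_profile(truth, _plan(truth, 600.0), depths=(180.0,), window=(400.0, 180.0))
        vals = tp["true_mean_diameter_um"].dropna()
        assert (vals == pytest.approx(116.0)).all()

    def test_two_canal_volume_weighted_mean_is_72(self):
        # 40 µm and 80 µm canals, both inside the lateral window
        spec = tiny_spec(forced_canals=[(60.0, 200.0, 20.0), (-60.0, 200.0, 40.0)])
        _, truth = sd.generate_cortical_phantom(spec)
        tp = sd.true_profile(
            truth, _plan(truth, 600.0), depths=(180.0,), window=(500.0, 180.0),
            per_direction=True,
        )
        got = tp.loc[tp["direction"] == "lateral", "true_mean_diameter_um"].dropna().iloc[0]
        # voxelized areas approximate the exact d^2 weighting (40*1 + 80*4)/5
        assert got == pytest.approx(72.0, abs=1.5)

    def test_non_overlap_bookkeeping_is_exact(self):
        for seed in (1, 2, 3):
            _, truth = sd.generate_cortical_phantom(tiny_spec(seed=seed, porosity=0.25))
            counts = np.bincount(truth.label_volume.ravel())
            assert counts[2:].sum() == truth.void_mask.sum()
            assert len(counts) - 2 <= len(truth.canals)
            # every void voxel belongs to exactly one canal id
            assert set(np.unique(truth.label_volume)) <= set(range(len(truth.canals) + 2))

    def test_fixed_seed_is_bit_reproducible(self):
        g1, t1 = sd.generate_cortical_phantom(tiny_spec(seed=5, noise_sd=8.0))
        g2, t2 = sd.generate_cortical_phantom(tiny_spec(seed=5, noise_sd=8.0))
        assert np.array_equal(g1.voxels, g2.voxels)
        assert np.array_equal(t1.label_volume, t2.label_volume)
        g3, _ = sd.generate_cortical_phantom(tiny_spec(seed=6, noise_sd=8.0))
        assert not np.array_equal(g1.voxels, g3.voxels)

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="voxel"):
            sd.generate_cortical_phantom(tiny_spec(min_diameter=12.0))

    def test_unreachable_porosity_raises_packing_error(self):
        spec = tiny_spec(porosity=0.9, diameter=100.0, max_attempts_factor=10)
        with pytest.raises(sd.PackingError):
            sd.generate_cortical_phantom(spec)

    def test_measured_porosity_tracks_target_within_two_points(self):
        """Per (band, depth-cell) void fraction vs the profile target, on ten
        reduced-geometry phantoms carrying the default gradient profiles."""
        for seed in range(10):
            spec = sd.PhantomSpec(
                outer_radius=650.0, inner_radius=220.0, wall_gain=80.0,
                length=2000.0, band_length=1000.0, seed=seed,
            )
            _, truth = sd.generate_cortical_phantom(spec)
            label = truth.label_volume
            nz, n, _ = label.shape
            vox = spec.voxel_size
            length_eff = nz * vox
            coords = (np.arange(n) + 0.5) * vox - n * vox / 2.0
            d2 = coords[:, None] ** 2 + coords[None, :] ** 2
            for z_lo, z_hi in ((0.0, 1000.0), (1000.0, length_eff)):
                s_mid = (z_lo + z_hi) / 2 / length_eff
                ss = np.linspace(z_lo, z_hi, 9) / length_eff
                wall_min = spec.outer_radius - max(spec.inner_radius_at(float(s)) for s in ss)
                iz = slice(int(math.ceil(z_lo / vox - 0.5)), int(math.ceil(z_hi / vox - 0.5)))
                for d_lo, d_hi in sd._band_cells(spec, wall_min):
                    ring = (d2 <= (spec.outer_radius - d_lo) ** 2) & (
                        d2 > (spec.outer_radius - d_hi) ** 2
                    )
                    cell = label[iz][:, ring]
                    measured = (cell >= 2).sum() / cell.size
                    target = spec.porosity_profile(s_mid, (d_lo + d_hi) / 2)
                    assert abs(measured - target) < 0.02, (seed, z_lo, d_lo)


class TestStressStrainGenerator:
    def test_degenerate_equal_moduli_is_a_straight_line(self):
        spec = sd.SyntheticCurveSpec(modulus1_true=10.0, modulus2_true=10.0,
                                     peak_stress_drop_fraction=0.0, noise_sd=0.0)
        curve, _ = sd.generate_stress_strain(spec)
        np.testing.assert_allclose(curve.stress, 10.0 * curve.strain, atol=1e-12)

    def test_piecewise_closed_form_value(self):
        spec = sd.SyntheticCurveSpec(modulus1_true=15.0, modulus2_true=1.4,
                                     breakpoint_strain=0.02, noise_sd=0.0)
        curve, _ = sd.generate_stress_strain(spec)
        i = int(np.argmin(np.abs(curve.strain - 0.04)))
        assert curve.strain[i] == pytest.approx(0.04)
        assert curve.stress[i] == pytest.approx(15 * 0.02 + 1.4 * 0.02, abs=1e-12)

    def test_terminal_drop_reduces_final_stress(self):
        curve, spec = sd.generate_stress_strain(sd.SyntheticCurveSpec(noise_sd=0.0))
        peak = curve.stress.max()
        assert curve.stress[-1] == pytest.approx(peak * (1 - spec.peak_stress_drop_fraction))

    def test_seeded_noise_is_reproducible_and_seed_sensitive(self):
        spec = dict(noise_sd=0.01)
        c1, _ = sd.generate_stress_strain(sd.SyntheticCurveSpec(seed=1, **spec))
        c2, _ = sd.generate_stress_strain(sd.SyntheticCurveSpec(seed=1, **spec))
        c3, _ = sd.generate_stress_strain(sd.SyntheticCurveSpec(seed=2, **spec))
        assert np.array_equal(c1.stress, c2.stress)
        assert not np.array_equal(c1.stress, c3.stress)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sd.SyntheticCurveSpec(n_points=5)

    def test_invalid_breakpoint_rejected(self):
        with pytest.raises(ValueError):
            sd.SyntheticCurveSpec(breakpoint_strain=0.1, failure_strain=0.08)


class TestModuliLink:
    def test_moduli_decrease_with_porosity(self):
        m1a, m2a = sd.moduli_from_porosity(0.05)
        m1b, m2b = sd.moduli_from_porosity(0.40)
        assert m1a == pytest.approx(15.0) and m2a == pytest.approx(1.4)
        assert m1b == pytest.approx(5.0) and m2b == pytest.approx(0.7)
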