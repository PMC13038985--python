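import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from bonegrad import gradient_profiling as gp
from bonegrad import morphometry as mm
from bonegrad import segmentation as seg
from bonegrad import synthetic_data as sd
from bonegrad.segmentation import BinaryVolume
from conftest import tiny_spec


def _disk(n, r, cy=None, cx=None):
    cy = (n - 1) / 2 if cy is None else cy
    cx = (n - 1) / 2 if cx is None else cx
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestPlanSlices:
    def test_50mm_volume_at_1mm_steps_gives_51_positions(self):
        vol = BinaryVolume(np.ones((500, 4, 4), bool), 100.0)  # 50 mm
        plan = gp.plan_slices(vol, step=1000.0)
        assert len(plan.positions) == 51
        assert plan.positions[-1] == 50000.0

    def test_truncated_last_slab_is_flagged(self):
        vol = BinaryVolume(np.ones((105, 4, 4), bool), 100.0)  # 10.5 mm
        plan = gp.plan_slices(vol, step=1000.0)
        assert len(plan.positions) == 11
        assert plan.truncated_last
        z0, z1 = plan.slab_range(10000.0, 105, 100.0)
        assert z1 - z0 == 5  # only 0.5 mm of material remains

    def test_single_voxel_step_visits_every_plane(self):
        vol = BinaryVolume(np.ones((20, 4, 4), bool), 5.8)
        plan = gp.plan_slices(vol, step=5.8)
        assert len(plan.positions) == 21

    def test_step_below_voxel_size_rejected(self):
        vol = BinaryVolume(np.ones((20, 4, 4), bool), 5.8)
        with pytest.raises(ValueError):
            gp.plan_slices(vol, step=2.0)


class TestLocateDirections:
    def test_centered_disk_has_equal_boundary_radii(self):
        env = _disk(61, 25)
        frame = gp.locate_directions(env)
        assert frame.centroid == pytest.approx((30.0, 30.0))
        hits = {d: gp._surface_index(env, frame, d) for d in gp.DIRECTIONS}
        radii = {
            "anterior": hits["anterior"] - 30, "posterior": 30 - hits["posterior"],
            "lateral": hits["lateral"] - 30, "medial": 30 - hits["medial"],
        }
        assert len(set(radii.values())) == 1

    def test_ellipse_boundary_distances_follow_axis_ratio(self):
        yy, xx = np.mgrid[0:81, 0:81]
        env = ((yy - 40) / 30.0) ** 2 + ((xx - 40) / 15.0) ** 2 <= 1.0
        frame = gp.locate_directions(env)
        a = gp._surface_index(env, frame, "anterior") - 40
        l = gp._surface_index(env, frame, "lateral") - 40
        assert a / l == pytest.approx(2.0, abs=0.1)

    def test_off_center_annulus_centroid_is_moment_based(self):
        env = _disk(80, 20, cy=30, cx=45) & ~_disk(80, 8, cy=30, cx=45)
        frame = gp.locate_directions(env)
        cy, cx = ndimage.center_of_mass(env)
        assert frame.centroid == pytest.approx((cy, cx))

    def test_empty_slice_returns_none(self):
        assert gp.locate_directions(np.zeros((10, 10), bool)) is None


class TestPlaceRoi:
    def test_first_depth_covers_periosteal_band_of_flat_slab(self):
        env = np.zeros((100, 100), bool)
        env[10:90, :] = True  # flat slab, anterior surface at y = 89
        roi = gp.place_roi(env, "anterior", 250.0, voxel_size=10.0, window=(500.0, 250.0))
        assert roi.valid
        assert roi.surface_index == 89
        assert roi.y_slice == slice(89 - 25 + 1, 90)

    def test_depth_beyond_all_material_is_na(self):
        env = _disk(60, 25)[None][0]
        roi = gp.place_roi(env, "lateral", 2000.0, voxel_size=10.0)
        assert not roi.valid and roi.reason

    def test_window_reaching_cavity_raises_porosity_toward_one(self):
        # annulus: outer 250 µm, wall 150 µm at 10 µm voxels
        ring = _disk(60, 25) & ~_disk(60, 10)
        bone = BinaryVolume(np.repeat(ring[None], 5, axis=0), 10.0)
        env = mm.build_envelope(bone, closing_radius=0.0)
        frame = gp.locate_directions(env.voxels[2])
        shallow = gp.place_roi(env.voxels[2], "lateral", 100.0, 10.0,
                               window=(200.0, 100.0), frame=frame)
        deep = gp.place_roi(env.voxels[2], "lateral", 250.0, 10.0,
                            window=(200.0, 100.0), frame=frame)
        roi3 = lambda r: (slice(0, 5), r.y_slice, r.x_slice)
        p_shallow = mm.roi_porosity(bone, env, roi3(shallow))
        p_deep = mm.roi_porosity(bone, env, roi3(deep))
        assert p_shallow < 0.2 and p_deep > 0.5


class TestCorticalThickness:
    def test_annulus_wall_recovered_within_one_voxel(self):
        ring = _disk(301, 120) & ~_disk(301, 40)  # wall 80 voxels = 1.2 mm at 15 µm
        bone = BinaryVolume(ring[None], 15.0)
        env = mm.build_envelope(bone, closing_radius=0.0)
        for d in gp.DIRECTIONS:
            th, flag = gp.cortical_thickness(env.voxels[0], ring, d, 15.0)
            assert flag == "ok"
            assert th == pytest.approx(1.2, abs=0.015)

    def test_solid_disk_reports_radius_flagged_no_cavity(self):
        disk = _disk(101, 40)
        env = mm.build_envelope(BinaryVolume(disk[None], 10.0), closing_radius=0.0)
        th, flag = gp.cortical_thickness(env.voxels[0], disk, "lateral", 10.0)
        assert flag == "no cavity"
        assert th == pytest.approx(0.40, abs=0.01)

    def test_tapering_wall_peaks_at_mid_shaft(self, tiny_phantom):
        spec = tiny_spec(wall_gain=60.0, porosity=0.0)
        gray, truth = sd.generate_cortical_phantom(spec)
        mask = seg.global_threshold(gray)
        env = mm.build_envelope(mask, closing_radius=50.0)
        plan = gp.plan_slices(mask, step=100.0)
        tmap = mm.ThicknessMap(np.zeros_like(gray.voxels, np.float32), spec.voxel_size)
        bundle = gp.assemble_profiles(mask, env, tmap, plan, depths=(100.0,))
        t = bundle.thickness.drop_duplicates("position_um")
        peak = t.loc[t["mean_thickness_mm"].idxmax(), "position_um"]
        assert abs(peak - spec.length / 2) <= 100.0


class TestAssembleProfiles:
    def test_direction_average_is_mean_of_emitted_directions(self, tiny_phantom):
        mask, env, tmap = (tiny_phantom[k] for k in ("mask", "envelope", "tmap"))
        plan = gp.plan_slices(mask, step=300.0)
        bundle = gp.assemble_profiles(mask, env, tmap, plan, depths=(100.0, 160.0),
                                      window=(200.0, 100.0))
        for (pos, depth), grp in bundle.directional.groupby(["position_um", "depth_um"]):
            row = bundle.radial[
                (bundle.radial.position_um == pos) & (bundle.radial.depth_um == depth)
            ].iloc[0]
            assert row["porosity"] == pytest.approx(grp["porosity"].mean(), abs=1e-12)

    def test_rotating_the_volume_permutes_directions_only(self):
        # asymmetric phantom: extra canals forced into one quadrant
        spec = tiny_spec(porosity=0.10, seed=11)
        gray, truth = sd.generate_cortical_phantom(spec)

        def profiles(gvol):
            mask = seg.despeckle_2d(seg.global_threshold(gvol))
            env = mm.build_envelope(mask, closing_radius=100.0)
            cav = mm.medullary_cavity(mask, env)
            tmap = mm.local_thickness(mm.intracortical_void(mask, env, cav))
            plan = gp.plan_slices(mask, step=300.0)
            return gp.assemble_profiles(mask, env, tmap, plan, depths=(100.0,),
                                        window=(200.0, 100.0))

        base = profiles(gray)
        rot = profiles(seg.GrayscaleVolume(
            np.rot90(gray.voxels, k=1, axes=(1, 2)).copy(), gray.voxel_size))
        np.testing.assert_allclose(
            base.radial["porosity"], rot.radial["porosity"], atol=1e-12)
        np.testing.assert_allclose(
            base.radial["mean_diameter_um"], rot.radial["mean_diameter_um"], atol=1e-9)
        # per-direction values are a permutation of each other
        b = np.sort(base.directional["porosity"].to_numpy())
        r = np.sort(rot.directional["porosity"].to_numpy())
        np.testing.assert_allclose(b, r, atol=1e-12)

    def test_asymmetric_quadrant_dominates_its_direction(self):
        spec = tiny_spec(porosity=0.0, forced_canals=[
            (200.0, 0.0, 30.0), (170.0, 60.0, 25.0), (150.0, -60.0, 25.0)])
        gray, truth = sd.generate_cortical_phantom(spec)
        mask = seg.global_threshold(gray)
        env = mm.build_envelope(mask, closing_radius=50.0)
        tmap = mm.ThicknessMap(np.zeros_like(gray.voxels, np.float32), spec.voxel_size)
        plan = gp.plan_slices(mask, step=600.0)
        bundle = gp.assemble_profiles(mask, env, tmap, plan, depths=(150.0,),
                                      window=(400.0, 150.0))
        por = bundle.directional.groupby("direction")["porosity"].mean()
        assert por["anterior"] > por["posterior"]
        assert por["anterior"] > por["medial"]
        assert por["anterior"] > por["lateral"]

    def test_empty_slab_propagates_na_rows(self):
        vol = np.zeros((20, 40, 40), bool)
        vol[:10] |= _disk(40, 15)[None]
        mask = BinaryVolume(vol, 10.0)
        env = mm.BoneEnvelope(vol.copy(), 10.0, 0.0)
        tmap = mm.ThicknessMap(np.zeros(vol.shape, np.float32), 10.0)
        plan = gp.plan_slices(mask, step=150.0)
        bundle = gp.assemble_profiles(mask, env, tmap, plan, depths=(100.0,))
        late = bundle.directional[bundle.directional.position_um >= 150.0]
        assert late["porosity"].isna().all()
        assert (late["note"] != "").all()
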