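"""Synthetic phantom construction, determinism and NIfTI round-trips."""

import dataclasses

import numpy as np
import pytest

import protonarc as pa


def test_head_phantom_tissue_values(small_head_spec):
    vol, rois = pa.make_head_phantom(small_head_spec)
    s = small_head_spec
    # center voxel is brain
    cidx = tuple(n // 2 for n in s.shape)
    assert vol.values[cidx] == s.density_brain
    # with zero noise the value multiset is exactly the specified tissues
    assert set(np.unique(vol.values)) == {s.density_air, s.density_brain, s.density_bone}
    # a voxel on the shell mid-surface is bone: walk out along +x from center
    head_center = 0.5 * np.asarray(s.shape) * np.asarray(s.voxel_size)
    mid_r = s.head_semi_axes[0] - 0.5 * s.shell_thickness_cm
    x = head_center[0] + mid_r
    ix = int(np.floor(x / s.voxel_size[0]))
    assert vol.values[ix, cidx[1], cidx[2]] == s.density_bone
    # target mask marks the ellipsoid interior and sits inside the brain
    assert rois[0].mask[cidx]
    assert vol.values[rois[0].mask].min() == s.density_brain


@pytest.mark.parametrize("noise", [0.0, 0.02])
def test_head_phantom_determinism(small_head_spec, noise):
    spec = dataclasses.replace(small_head_spec, noise_sigma=noise, seed=1234)
    v1, r1 = pa.make_head_phantom(spec)
    v2, r2 = pa.make_head_phantom(spec)
    assert np.array_equal(v1.values, v2.values)
    assert np.array_equal(r1[0].mask, r2[0].mask)


def test_noise_is_clipped_and_confined(small_head_spec):
    spec = dataclasses.replace(small_head_spec, noise_sigma=0.5, seed=9)
    vol, _ = pa.make_head_phantom(spec)
    assert vol.values.min() >= 0.0
    # exterior air is untouched by noise
    assert vol.values[0, 0, 0] == spec.density_air


def test_target_outside_brain_rejected(small_head_spec):
    bad = dataclasses.replace(
        small_head_spec,
        targets=(pa.TargetSpec((6.0, 0.0, 0.0), (1.0, 1.0, 1.0), "lateral-bad"),),
    )
    with pytest.raises(ValueError, match="lateral-bad"):
        pa.make_head_phantom(bad)


def test_sphere_phantom_concentric_analytics():
    sp = pa.make_uniform_sphere_phantom(
        radius_cm=8.0, target_radius_cm=1.0, voxel_size=(0.25, 0.25, 0.25)
    )
    # concentric target: distal depth = R + r from every direction
    for ang in (0.0, 37.0, 90.0, 200.0):
        th = np.deg2rad(ang)
        d = np.array([np.sin(th), np.cos(th), 0.0])
        assert sp.distal_depth_cm(-d) == pytest.approx(9.0)
    # unit density: radiological depth equals geometric depth along a chord
    eff = pa.effective_density(sp.volume, pa.density.WATER)
    start = sp.center + np.array([0.0, 20.0, 0.0])
    end = sp.center
    wepl = pa.radiological_path_length(eff, start, end)
    assert wepl == pytest.approx(8.0, abs=0.2)


def test_sphere_phantom_offset_target_depth_minimized_on_near_side():
    sp = pa.make_uniform_sphere_phantom(
        radius_cm=8.0, target_radius_cm=1.0, target_offset_cm=(0.0, 3.0, 0.0),
        voxel_size=(0.25, 0.25, 0.25),
    )
    # target offset toward +y (gantry 0 side): beams from +y need least depth
    depth_near = sp.distal_depth_cm(np.array([0.0, -1.0, 0.0]))  # source at +y
    depth_far = sp.distal_depth_cm(np.array([0.0, 1.0, 0.0]))
    depth_side = sp.distal_depth_cm(np.array([1.0, 0.0, 0.0]))
    assert depth_near < depth_side < depth_far
    assert depth_near == pytest.approx(8.0 - 3.0 + 1.0)
    assert depth_far == pytest.approx(8.0 + 3.0 + 1.0)


def test_sphere_phantom_protruding_target_rejected():
    with pytest.raises(ValueError, match="protrudes"):
        pa.make_uniform_sphere_phantom(radius_cm=5.0, target_radius_cm=1.0,
                                       target_offset_cm=(4.5, 0.0, 0.0))


def test_voxelized_mask_volume_converges():
    r = 1.0
    analytic = 4.0 / 3.0 * np.pi * r**3
    errs = []
    for vox in (0.2, 0.1):
        sp = pa.make_uniform_sphere_phantom(
            radius_cm=3.0, target_radius_cm=r, voxel_size=(vox,) * 3
        )
        vol = sp.target.mask.sum() * vox**3
        errs.append(abs(vol - analytic) / analytic)
    assert errs[1] < errs[0]
    assert errs[1] < 0.05


def test_nifti_round_trip(tmp_path, small_head_spec):
    vol, rois = pa.make_head_phantom(small_head_spec)
    vol = pa.DensityVolume(vol.values, vol.voxel_size, origin=(1.0, -2.0, 0.5))
    pa.write_volume(vol, tmp_path / "vol.nii")
    back = pa.read_volume(tmp_path / "vol.nii")
    assert np.array_equal(back.values, vol.values)
    assert np.allclose(back.voxel_size, vol.voxel_size)
    assert np.allclose(back.origin, vol.origin)

    roi = pa.TargetROI(rois[0].mask, "t", 0, vol.voxel_size, origin=vol.origin)
    pa.write_volume(roi, tmp_path / "roi.nii")
    back_roi = pa.read_roi(tmp_path / "roi.nii", vol, label="t")
    assert np.array_equal(back_roi.mask, roi.mask)


def test_roi_shape_mismatch_rejected(tmp_path, small_head_spec):
    vol, rois = pa.make_head_phantom(small_head_spec)
    pa.write_volume(rois[0], tmp_path / "roi.nii")
    other = pa.DensityVolume(np.ones((10, 10, 10)), (0.1, 0.1, 0.1))
    with pytest.raises(ValueError, match="does not match"):
        pa.read_roi(tmp_path / "roi.nii", other)


def test_cohort_is_seed_deterministic(tmp_path):
    a = pa.make_cohort(4, seed=11)
    b = pa.make_cohort(4, seed=11)
    assert [e["spec"] for e in a] == [e["spec"] for e in b]
    assert [e["disease"] for e in a] == [e["disease"] for e in b]
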