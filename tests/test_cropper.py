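"""Crop-window algebra, shift grids, remapping and dataset construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from craniomark.cropper import (
    CropWindow,
    TrainingExample,
    build_refinement_dataset,
    crop_stack,
    load_dataset,
    local_target,
    make_shift_grid,
    remap_to_global,
    save_dataset,
    window_for_center,
)
from craniomark.errors import InputError, ParameterError
from craniomark.volume_io import CaseVolume, RawSlice, binarize


def _volume_from_array(arr: np.ndarray, case_id="t") -> CaseVolume:
    # arr indexed (rows, cols, z)
    slices = [
        RawSlice(arr[:, :, k].astype(np.int32), 5.0 * k, k) for k in range(arr.shape[2])
    ]
    return CaseVolume(case_id=case_id, slices=slices)


def _naive_crop(bone: np.ndarray, origin, width, depth) -> np.ndarray:
    """Per-pixel reference implementation of the zero-padded crop."""
    x0, y0 = origin
    out = np.zeros((width, width, depth), dtype=np.uint8)
    h, w, nz = bone.shape
    for ly in range(width):
        for lx in range(width):
            gy, gx = y0 + ly, x0 + lx
            if 0 <= gy < h and 0 <= gx < w:
                out[ly, lx, : min(nz, depth)] = bone[gy, gx, : min(nz, depth)]
    return out


class TestShiftGrid:
    @pytest.mark.parametrize(
        "max_shift,step,expected",
        [(30, 10, 36), (15, 5, 36), (10, 10, 4)],
    )
    def test_offset_counts(self, max_shift, step, expected):
        grid = make_shift_grid(max_shift, step)
        assert len(grid) == expected
        assert len(set(grid.offsets)) == expected
        assert len(grid) == (2 * max_shift // step) ** 2

    def test_half_open_bounds(self):
        grid = make_shift_grid(30, 10)
        assert (-30, -30) in grid.offsets
        assert all(dx < 30 and dy < 30 for dx, dy in grid.offsets)
        assert (0, 0) in grid.offsets

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            make_shift_grid(30, 7)
        with pytest.raises(ParameterError):
            make_shift_grid(30, 0)


class TestCropStack:
    def test_centered_window_origin(self):
        w = window_for_center((256, 256), 100, 81)
        assert w.origin == (206, 206)

    def test_out_of_bounds_columns_are_zero(self, rng):
        arr = rng.integers(0, 4000, (512, 512, 4))
        vol = _volume_from_array(arr)
        stack, window = crop_stack(vol, (10, 256), 100, depth=4)
        assert window.origin == (-40, 206)
        # local x < 40 corresponds to global x < 0
        assert stack.voxels[:, :40, :].sum() == 0
        bone = binarize(arr, 1100)
        np.testing.assert_array_equal(
            stack.voxels, _naive_crop(bone, window.origin, 100, 4)
        )

    def test_single_bone_voxel_maps_to_local_center(self):
        arr = np.zeros((512, 512, 8), dtype=np.int32)
        arr[250, 250, 5] = 4000  # (y, x, z) = (250, 250, 5)
        vol = _volume_from_array(arr)
        stack, window = crop_stack(vol, (250, 250), 100, depth=8)
        hits = np.argwhere(stack.voxels)
        assert hits.tolist() == [[50, 50, 5]]

    def test_matches_naive_copy_on_random_windows(self, rng):
        """100 random windows, including far out-of-bounds placements."""
        arr = (rng.random((64, 64, 5)) * 4000).astype(np.int32)
        vol = _volume_from_array(arr)
        bone = binarize(arr, 1100)
        for _ in range(100):
            cx, cy = rng.uniform(-40, 104, size=2)
            stack, window = crop_stack(vol, (cx, cy), 20, depth=6)
            np.testing.assert_array_equal(
                stack.voxels, _naive_crop(bone, window.origin, 20, 6)
            )

    def test_crop_conserves_bone(self, rng):
        arr = (rng.random((64, 64, 5)) * 4000).astype(np.int32)
        vol = _volume_from_array(arr)
        total = binarize(arr, 1100).sum()
        stack, _ = crop_stack(vol, (32, 32), 40, depth=6)
        assert stack.voxels.sum() <= total


class TestRemapping:
    def test_unshifted_target_is_half_width(self):
        window = window_for_center((300, 300), 100, 81)
        np.testing.assert_array_equal(
            local_target((300, 300, 40), window), [50, 50, 40]
        )
        window50 = window_for_center((300, 300), 50, 81)
        np.testing.assert_array_equal(
            local_target((300, 300, 40), window50), [25, 25, 40]
        )

    def test_shifted_target_moves_opposite(self):
        window = window_for_center((300 + 10, 300 + 0), 100, 81)
        np.testing.assert_array_equal(
            local_target((300, 300, 40), window), [40, 50, 40]
        )

    def test_remap_arithmetic(self):
        window = CropWindow(origin=(206, 206), width=100, depth=81)
        np.testing.assert_array_equal(
            remap_to_global((50, 50, 40), window), [256, 256, 40]
        )

    def test_roundtrip_identity_on_random_pairs(self, rng):
        """remap_to_global(local_target(p, w), w) == p with error exactly 0.

        Coordinates are drawn on a 1/1024 px lattice (fixed-point, as any
        stored prediction is); the integer window shift is then exactly
        representable and the round trip loses nothing.
        """
        for _ in range(1000):
            p = rng.integers(-102_400, 614_400, size=3) / 1024.0
            w = CropWindow(
                origin=(int(rng.integers(-200, 600)), int(rng.integers(-200, 600))),
                width=int(rng.choice([50, 100])),
                depth=81,
            )
            back = remap_to_global(local_target(p, w), w)
            assert np.max(np.abs(back - p)) == 0.0

    @given(
        x=st.floats(-500, 1000),
        y=st.floats(-500, 1000),
        z=st.floats(0, 500),
        x0=st.integers(-300, 600),
        y0=st.integers(-300, 600),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_property(self, x, y, z, x0, y0):
        """For arbitrary floats the round trip is exact to one ulp."""
        w = CropWindow(origin=(x0, y0), width=100, depth=81)
        back = remap_to_global(local_target((x, y, z), w), w)
        np.testing.assert_allclose(back, (x, y, z), rtol=1e-12, atol=1e-12)


class TestRefinementDataset:
    def test_example_count_formula(self, desk_cohort, desk_config):
        spec, volumes, tables = desk_cohort
        grid = make_shift_grid(10, 10)  # 4 offsets
        data = build_refinement_dataset(
            volumes[:1], tables[:1], "L08", desk_config.phase2_width, grid,
            depth=desk_config.depth, threshold=desk_config.threshold,
        )
        assert len(data) == 4

    def test_targets_satisfy_local_semantics(self, desk_cohort, desk_config):
        spec, volumes, tables = desk_cohort
        grid = make_shift_grid(6, 3)
        data = build_refinement_dataset(
            volumes[:2], tables[:2], "L15", desk_config.phase2_width, grid,
            depth=desk_config.depth, threshold=desk_config.threshold,
        )
        assert len(data) == 2 * len(grid) == 2 * 16
        lm = tables[0].point("L15")
        for ex in data[: len(grid)]:
            expected = local_target(lm, ex.stack.window)
            np.testing.assert_array_equal(ex.target, expected)
            assert ex.stack.voxels.shape == (
                desk_config.phase2_width,
                desk_config.phase2_width,
                desk_config.depth,
            )
            # z target is global
            assert ex.target[2] == lm[2]

    def test_unknown_landmark(self, desk_cohort, desk_config):
        spec, volumes, tables = desk_cohort
        with pytest.raises(InputError):
            build_refinement_dataset(
                volumes[:1], tables[:1], "L99", 24, make_shift_grid(6, 3)
            )

    def test_hdf5_roundtrip(self, tmp_path, desk_cohort, desk_config):
        spec, volumes, tables = desk_cohort
        grid = make_shift_grid(6, 6)
        data = build_refinement_dataset(
            volumes[:1], tables[:1], "L08", desk_config.phase3_width, grid,
            depth=desk_config.depth, threshold=desk_config.threshold,
        )
        path = tmp_path / "ds.h5"
        save_dataset(data, path)
        back = load_dataset(path)
        assert len(back) == len(data)
        for a, b in zip(data, back):
            np.testing.assert_array_equal(a.stack.voxels, b.stack.voxels)
            np.testing.assert_array_equal(a.target, b.target)
            assert a.stack.window.origin == b.stack.window.origin
            assert (a.case_id, a.landmark) == (b.case_id, b.landmark)
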