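import math

import numpy as np
import pytest

from noduletex import (
    SeedPoint, nodule_volume, region_grow_3d, subtract_structures,
    volume_doubling_time,
)

from _oracles import bfs_flood_fill
from conftest import make_volume


class TestRegionGrow:
    def test_block_phantom(self, block_volume):
        seg = region_grow_3d(block_volume, SeedPoint(1, 1, 1))
        assert seg.voxel_count == 4
        expected = np.zeros((3, 3, 3), dtype=bool)
        expected[1, 1:3, 1:3] = True
        np.testing.assert_array_equal(seg.mask, expected)

    def test_seed_outside_interval_rejected(self, block_volume):
        with pytest.raises(ValueError, match="seed outside inclusion interval"):
            region_grow_3d(block_volume, SeedPoint(0, 0, 0))

    def test_seed_outside_lattice_rejected(self, block_volume):
        with pytest.raises(IndexError):
            region_grow_3d(block_volume, SeedPoint(5, 0, 0))

    def test_default_interval_is_inclusive_endpoints(self):
        voxels = np.full((1, 1, 4), -800)
        voxels[0, 0, 1:3] = [-450, 1500]   # both endpoints belong
        seg = region_grow_3d(make_volume(voxels), SeedPoint(1, 0, 0))
        assert seg.voxel_count == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_oracle_randomized(self, connectivity, rng):
        """Region growing equals an exhaustive BFS flood fill on random
        volumes up to 10x10x10."""
        for _ in range(100):
            shape = tuple(rng.integers(2, 11, size=3))
            voxels = rng.choice([-800, 50], p=[0.45, 0.55],
                                size=shape).astype(np.int16)
            zyx = tuple(int(rng.integers(0, s)) for s in shape)
            voxels[zyx] = 50
            vol = make_volume(voxels)
            seed = SeedPoint(zyx[2], zyx[1], zyx[0])
            seg = region_grow_3d(vol, seed, connectivity=connectivity)
            oracle = bfs_flood_fill(voxels, zyx, -450, 1500, connectivity)
            np.testing.assert_array_equal(seg.mask, oracle)

    def test_slice_range_restriction(self, rng):
        voxels = np.full((6, 5, 5), 50, dtype=np.int16)
        vol = make_volume(voxels)
        seg = region_grow_3d(vol, SeedPoint(2, 2, 2), slice_range=(1, 4))
        oracle = bfs_flood_fill(voxels, (2, 2, 2), -450, 1500, 6,
                                slice_range=(1, 4))
        np.testing.assert_array_equal(seg.mask, oracle)
        assert not seg.mask[0].any() and not seg.mask[4:].any()

    def test_slice_range_must_contain_seed(self, block_volume):
        with pytest.raises(ValueError, match="slice_range"):
            region_grow_3d(block_volume, SeedPoint(1, 1, 1),
                           slice_range=(2, 3))

    def test_interval_monotonicity(self, rng):
        """Enlarging the HU interval never shrinks the mask."""
        for _ in range(25):
            voxels = rng.integers(-1000, 1600, size=(6, 6, 6)).astype(np.int16)
            voxels[3, 3, 3] = 0
            vol = make_volume(voxels)
            small = region_grow_3d(vol, SeedPoint(3, 3, 3), (-100, 100))
            large = region_grow_3d(vol, SeedPoint(3, 3, 3), (-450, 1500))
            assert np.all(large.mask[small.mask])

    def test_volume_follows_spacing(self, block_volume):
        vol = make_volume(block_volume.voxels, spacing=(0.5, 0.5, 1.0))
        seg = region_grow_3d(vol, SeedPoint(1, 1, 1))
        assert seg.volume_mm3 == pytest.approx(4 * 0.25)


class TestSubtractStructures:
    def test_empty_exclusion_is_identity(self, block_volume):
        seg = region_grow_3d(block_volume, SeedPoint(1, 1, 1))
        out = subtract_structures(seg, np.zeros_like(seg.mask))
        np.testing.assert_array_equal(out.mask, seg.mask)
        assert out.voxel_count == seg.voxel_count

    def test_split_keeps_seed_component(self):
        # two lobes joined by a one-voxel bridge; excluding the bridge must
        # keep only the seed-containing lobe
        voxels = np.full((1, 1, 7), -800, dtype=np.int16)
        voxels[0, 0, :] = [50, 50, 50, 50, 50, 50, 50]
        vol = make_volume(voxels)
        seg = region_grow_3d(vol, SeedPoint(0, 0, 0))
        exclusion = np.zeros_like(seg.mask)
        exclusion[0, 0, 3] = True
        out = subtract_structures(seg, exclusion)
        assert out.voxel_count == 3
        assert out.mask[0, 0, :3].all() and not out.mask[0, 0, 3:].any()

    def test_vessel_subtraction_recovers_ground_truth(self, benign_phantom):
        truth = benign_phantom
        seg = region_grow_3d(truth.volume, SeedPoint(*truth.spec.center))
        assert seg.voxel_count > truth.mask.sum()   # vessel got included
        out = subtract_structures(seg, truth.vessel_mask)
        np.testing.assert_array_equal(out.mask, truth.mask)

    def test_excluding_seed_is_error(self, block_volume):
        seg = region_grow_3d(block_volume, SeedPoint(1, 1, 1))
        with pytest.raises(ValueError, match="seed removed"):
            subtract_structures(seg, np.ones_like(seg.mask))

    def test_shape_mismatch_rejected(self, block_volume):
        seg = region_grow_3d(block_volume, SeedPoint(1, 1, 1))
        with pytest.raises(ValueError, match="shape"):
            subtract_structures(seg, np.zeros((2, 2, 2), dtype=bool))


class TestNoduleVolume:
    @pytest.mark.parametrize("count,spacing,expected", [
        (4, (1, 1, 1), 4.0),
        (10, (0.5, 0.5, 1.0), 2.5),
    ])
    def test_arithmetic(self, count, spacing, expected):
        voxels = np.full((1, 1, count), 50, dtype=np.int16)
        seg = region_grow_3d(make_volume(voxels, spacing=spacing),
                             SeedPoint(0, 0, 0))
        assert seg.voxel_count == count
        assert nodule_volume(seg, spacing) == pytest.approx(expected)

    def test_voxelised_sphere_volume(self):
        from noduletex import PhantomSpec, TextureParams, generate_phantom
        spec = PhantomSpec(label="benign", center=(24, 24, 24), radius_mm=5.0,
                           texture=TextureParams(1.5, 3.0, 35.0, 50.0, "flat"),
                           rng_seed=1)
        truth = generate_phantom(spec)
        seg = region_grow_3d(truth.volume, SeedPoint(24, 24, 24))
        analytic = 4.0 / 3.0 * math.pi * 125.0
        assert abs(seg.volume_mm3 - analytic) / analytic < 0.10

    def test_bad_spacing_rejected(self, block_volume):
        seg = region_grow_3d(block_volume, SeedPoint(1, 1, 1))
        with pytest.raises(ValueError):
            nodule_volume(seg, (0.0, 1.0, 1.0))


class TestVolumeDoublingTime:
    def test_doubling_definition(self):
        g = volume_doubling_time(100.0, 200.0, 100.0)
        assert g.vdt_days == pytest.approx(100.0)
        assert not g.stable

    def test_slow_growth_is_stable(self):
        g = volume_doubling_time(500.0, 550.0, 365.0)
        assert g.vdt_days == pytest.approx(
            365.0 * math.log(2) / math.log(1.1))
        assert g.vdt_days == pytest.approx(2654, rel=0.001)
        assert g.stable

    def test_no_growth_infinite_vdt(self):
        g = volume_doubling_time(500.0, 500.0, 365.0)
        assert math.isinf(g.vdt_days) and g.stable
        assert volume_doubling_time(500.0, 400.0, 365.0).stable

    def test_nonpositive_inputs_rejected(self):
        for bad in [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-1, 1, 1)]:
            with pytest.raises(ValueError):
                volume_doubling_time(*bad)

    def test_antitone_in_v2(self):
        v2s = np.linspace(501, 1500, 30)
        vdts = [volume_doubling_time(500.0, v2, 365.0).vdt_days for v2 in v2s]
        assert all(a > b for a, b in zip(vdts[:-1], vdts[1:]))
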