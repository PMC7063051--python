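"""Normalization stages, resampling, cube split/stitch, HDF5 datasets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cryotrace as ct
from cryotrace.mapsim import DensityMap
from cryotrace.preprocess import (
    EmptyMapError, build_training_set, load_training_samples, make_toy_cubes,
    preprocess_map, resample_to_unit_voxel, split_into_cubes, stitch_cubes,
)


class TestPreprocessMap:
    def test_constant_map_normalizes_to_one(self):
        dm = DensityMap(np.full((6, 6, 6), 3.7))
        out = preprocess_map(dm, 0.0)
        assert np.allclose(out.grid, 1.0)

    def test_threshold_zeroes_low_voxels(self, rng):
        g = rng.uniform(0, 2, (8, 8, 8))
        out = preprocess_map(DensityMap(g), 0.7)
        assert np.all(out.grid[g < 0.7] == 0)

    def test_cap_at_98th_percentile(self, rng):
        g = rng.uniform(0.1, 1.0, (10, 10, 10))
        g[0, 0, 0] = 100.0  # outlier
        out = preprocess_map(DensityMap(g), 0.0)
        pos = g[g > 0] / np.median(g[g > 0])
        assert out.grid.max() <= np.percentile(pos, 98.0) + 1e-12

    def test_median_of_positive_is_one(self, rng):
        g = rng.uniform(0, 2, (9, 9, 9))
        out = preprocess_map(DensityMap(g), 0.5)
        pos = out.grid[out.grid > 0]
        assert np.median(pos) == pytest.approx(1.0)

    def test_all_zero_after_threshold_raises(self):
        with pytest.raises(EmptyMapError):
            preprocess_map(DensityMap(np.full((4, 4, 4), 0.1)), 1.0)

    def test_idempotent_on_own_output(self, rng):
        g = rng.uniform(0, 2, (8, 8, 8))
        once = preprocess_map(DensityMap(g), 0.5)
        twice = preprocess_map(once, 0.0)
        # median of once's positives is 1 by construction so the division is
        # a no-op; the percentile cap re-clamps only within interpolation
        # error of the cap value
        assert np.allclose(once.grid, twice.grid, rtol=1e-3)


class TestResample:
    def test_identity_at_unit_voxel(self, rng):
        dm = DensityMap(rng.normal(size=(7, 8, 9)))
        out = resample_to_unit_voxel(dm)
        assert np.array_equal(out.grid, dm.grid)

    def test_constant_halved_extent(self):
        dm = DensityMap(np.full((100, 100, 4), 2.0), voxel_size=[0.5, 0.5, 1.0])
        out = resample_to_unit_voxel(dm)
        assert out.shape == (50, 50, 4)
        assert np.allclose(out.grid, 2.0)

    def test_linear_ramp_exact(self):
        """Trilinear interpolation reproduces a linear field exactly."""
        n = 40
        vs = 0.8
        idx = np.arange(n) * vs
        ramp = idx[:, None, None] + 0 * idx[None, :, None] + 0 * idx[None, None, :]
        ramp = np.broadcast_to(ramp, (n, n, n)).copy()
        dm = DensityMap(ramp, voxel_size=vs)
        out = resample_to_unit_voxel(dm)
        xs = np.arange(out.shape[0], dtype=float)
        expect = np.broadcast_to(xs[:, None, None], out.shape)
        interior = (slice(1, -1),) * 3
        assert np.abs(out.grid[interior] - expect[interior]).max() < 1e-6

    def test_preserves_gaussian_peak_location(self):
        from cryotrace.structure import Atom, AtomicModel
        single = AtomicModel(atoms=[Atom("CA", "C", "A", 1, "ALA",
                                         np.array([10.3, 11.1, 9.7]))])
        dm = ct.simulate_density(single, 3.0, voxel_size=0.7)
        out = resample_to_unit_voxel(dm)
        p_in = dm.voxel_to_world(np.unravel_index(np.argmax(dm.grid), dm.shape))
        p_out = out.voxel_to_world(np.unravel_index(np.argmax(out.grid), out.shape))
        assert np.linalg.norm(p_in - p_out) <= np.sqrt(3.0)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            resample_to_unit_voxel(DensityMap(np.ones((1, 5, 5)), voxel_size=0.5))


class TestCubes:
    @pytest.mark.parametrize("shape,expected", [
        ((50, 50, 50), 1), ((64, 64, 64), 8), ((150, 150, 150), 27),
        ((30, 80, 120), 1 * 2 * 3),
    ])
    def test_cube_counts(self, shape, expected, rng):
        dm = DensityMap(rng.normal(size=shape))
        cubes, grid = split_into_cubes(dm)
        assert len(cubes) == expected
        assert all(c.shape == (64, 64, 64) for c in cubes)
        assert grid.margin == 7

    @settings(max_examples=12, deadline=None)
    @given(st.tuples(st.integers(1, 130), st.integers(1, 130), st.integers(1, 130)))
    def test_split_stitch_identity(self, shape):
        rng = np.random.default_rng(sum(shape))
        dm = DensityMap(rng.normal(size=shape))
        cubes, grid = split_into_cubes(dm)
        rec = stitch_cubes(cubes, grid)
        assert np.array_equal(rec, dm.grid)

    def test_cores_are_disjoint_blocks(self):
        dm = DensityMap(np.zeros((100, 100, 100)))
        cubes, grid = split_into_cubes(dm)
        marked = [np.full_like(c, i + 1.0) for i, c in enumerate(cubes)]
        rec = stitch_cubes(marked, grid)
        # every voxel collected from exactly one core: block-constant output
        assert set(np.unique(rec)) <= set(range(1, len(cubes) + 1))
        assert np.array_equal(rec[:50, :50, :50], np.full((50, 50, 50), rec[0, 0, 0]))

    def test_count_mismatch_raises(self, rng):
        dm = DensityMap(rng.normal(size=(60, 60, 60)))
        cubes, grid = split_into_cubes(dm)
        with pytest.raises(ValueError):
            stitch_cubes(cubes[:-1], grid)


class TestTrainingSet:
    def test_augmentation_quadruples_samples(self, tmp_path):
        models = [ct.generate_synthetic_protein([("helix", 6), ("loop", 3)], seed=s)
                  for s in range(2)]
        path = build_training_set(models, (2.5, 3.5), tmp_path / "train.h5",
                                  augment=True, seed=0)
        samples = load_training_samples(path)
        assert len(samples) == 8
        path2 = build_training_set(models, (2.5, 3.5), tmp_path / "plain.h5",
                                   augment=False, seed=0)
        assert len(load_training_samples(path2)) == 2

    def test_rotation_keeps_label_density_correspondence(self, tmp_path):
        models = [ct.generate_synthetic_protein([("helix", 8)], seed=1)]
        path = build_training_set(models, (3.0, 3.0), tmp_path / "rot.h5",
                                  augment=True, seed=0)
        samples = load_training_samples(path)
        base, rot90 = samples[0], samples[1]
        assert np.array_equal(np.rot90(base["density"], 1, axes=(0, 1)),
                              rot90["density"])
        assert np.array_equal(np.rot90(base["calpha"], 1, axes=(0, 1)),
                              rot90["calpha"])

    def test_reload_is_bit_exact_and_deterministic(self, tmp_path):
        models = [ct.generate_synthetic_protein([("sheet", 5), ("loop", 3)], seed=7)]
        p1 = build_training_set(models, (2.5, 4.5), tmp_path / "a.h5", seed=3)
        p2 = build_training_set(models, (2.5, 4.5), tmp_path / "b.h5", seed=3)
        s1, s2 = load_training_samples(p1), load_training_samples(p2)
        for a, b in zip(s1, s2):
            assert np.array_equal(a["density"], b["density"])
            assert np.array_equal(a["calpha"], b["calpha"])

    def test_toy_cubes_shape_and_content(self):
        samples = make_toy_cubes(2, edge=24, seed=0)
        assert len(samples) == 2
        for s in samples:
            assert s["density"].shape == (24, 24, 24)
            assert s["calpha"].any()
            assert not np.any(s["calpha"] & ~s["backbone"])
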