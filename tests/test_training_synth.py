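"""Patch extraction, offset arithmetic, summing, and the frame-group path."""

import dataclasses

import numpy as np
import pytest

from paintdense import (CameraModel, KineticsConfig, LocalizationTable, Movie,
                        SummingConfig, choose_k_for_density,
                        concentration_for_density, concentration_group_factor,
                        estimate_offset, extract_sparse_patches, simulate_movie,
                        sum_frame_groups, sum_patches, uniform_field)
from paintdense.io_formats import PatchSet


def _locs(frame, x, y):
    n = len(x)
    return LocalizationTable.from_arrays(frame=frame, x=x, y=y,
                                         photons=np.full(n, 1000.0))


def brute_force_sum(patch_list, offset, k):
    """Independent per-pixel adder: nested loops, then offset and clip."""
    P = patch_list[0].shape[0]
    out = np.zeros((P, P))
    for p in patch_list:
        for i in range(P):
            for j in range(P):
                out[i, j] += float(p[i, j])
    for i in range(P):
        for j in range(P):
            out[i, j] = max(out[i, j] - (k - 1) * offset, 0.0)
    return out


class TestExtractSparsePatches:
    @pytest.mark.parametrize("P", [16, 17])
    def test_crop_arithmetic(self, camera, P):
        # localization at (100.3, 50.7) maps to patch-local (8.3, 8.7)
        movie = Movie(np.zeros((1, 512, 512), dtype=np.uint16), 0.15, camera)
        ps = extract_sparse_patches(movie, _locs([0], [100.3], [50.7]),
                                    SummingConfig(patch_size=P))
        assert len(ps) == 1
        np.testing.assert_allclose(ps.coords[0], [[8.3, 8.7]])

    def test_border_localization_discarded(self, camera):
        movie = Movie(np.zeros((1, 512, 512), dtype=np.uint16), 0.15, camera)
        ps = extract_sparse_patches(movie, _locs([0], [3.0], [3.0]),
                                    SummingConfig(patch_size=17))
        assert len(ps) == 0

    def test_neighbouring_localizations_included(self, camera):
        # two localizations 5 px apart: each patch's list contains both
        movie = Movie(np.zeros((1, 512, 512), dtype=np.uint16), 0.15, camera)
        locs = _locs([0, 0], [100.0, 105.0], [100.0, 100.0])
        ps = extract_sparse_patches(movie, locs, SummingConfig(patch_size=17))
        assert len(ps) == 2
        assert all(len(c) == 2 for c in ps.coords)

    def test_patch_pixels_come_from_frame(self, camera, rng):
        frames = rng.integers(0, 1000, size=(2, 64, 64)).astype(np.uint16)
        movie = Movie(frames, 0.15, camera)
        ps = extract_sparse_patches(movie, _locs([1], [30.4], [20.8]),
                                    SummingConfig(patch_size=16))
        np.testing.assert_array_equal(ps.patches[0], frames[1, 12:28, 22:38])

    def test_empty_table_warns_and_returns_empty(self, camera):
        movie = Movie(np.zeros((1, 64, 64), dtype=np.uint16), 0.15, camera)
        empty = LocalizationTable.from_arrays(frame=np.empty(0, int),
                                              x=np.empty(0), y=np.empty(0),
                                              photons=np.empty(0))
        assert len(extract_sparse_patches(movie, empty, SummingConfig())) == 0


class TestEstimateOffset:
    def test_constant_and_mean(self, camera):
        m = Movie(np.full((3, 8, 8), 100, dtype=np.uint16), 0.15, camera)
        assert estimate_offset(m) == 100.0
        two = Movie(np.stack([np.full((8, 8), 99), np.full((8, 8), 101)]), 0.15, camera)
        assert estimate_offset(two) == 100.0

    def test_simulated_dark_movie(self, camera, rng):
        frames = rng.normal(100.0, 2.0, size=(100, 64, 64))
        frames = np.clip(frames, 0, None)
        m = Movie(frames, 0.15, camera)
        # SE of the mean = 2 / sqrt(100 * 64 * 64) ~= 0.0031
        assert estimate_offset(m) == pytest.approx(100.0, abs=0.01)

    def test_empty_movie_rejected(self, camera):
        with pytest.raises(ValueError):
            estimate_offset(Movie(np.zeros((0, 8, 8)), 0.15, camera))


class TestSumPatches:
    def _patchset(self, rng, n=20, P=8, camera=None):
        patches = rng.integers(80, 400, size=(n, P, P)).astype(np.float64)
        coords = [rng.uniform(0, P, size=(rng.integers(1, 4), 2)) for _ in range(n)]
        return PatchSet(patches, coords, camera=camera or CameraModel())

    def test_k1_identity(self, rng, camera):
        ps = self._patchset(rng, camera=camera)
        out = sum_patches(ps, SummingConfig(patch_size=8, k_per_output=1,
                                            n_outputs=5, seed=0), offset=100.0)
        for i in range(5):
            j = [np.array_equal(out.patches[i], p) for p in ps.patches].index(True)
            np.testing.assert_array_equal(out.patches[i], ps.patches[j])
            np.testing.assert_array_equal(out.coords[i], ps.coords[j])

    def test_pure_offset_patches_stay_at_offset(self, camera):
        ps = PatchSet(np.full((2, 8, 8), 100.0), [[], []], camera=camera)
        out = sum_patches(ps, SummingConfig(patch_size=8, k_per_output=2,
                                            n_outputs=3, seed=1), offset=100.0)
        assert (out.patches == 100.0).all()
        assert all(len(c) == 0 for c in out.coords)

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 10])
    def test_matches_brute_force_adder(self, rng, camera, k):
        ps = self._patchset(rng, n=12, camera=camera)
        cfg = SummingConfig(patch_size=8, k_per_output=k, n_outputs=6, seed=k)
        out = sum_patches(ps, cfg, offset=100.0)
        # replay the seeded choices to recover which inputs were summed
        rng2 = np.random.default_rng(cfg.seed)
        for i in range(6):
            idx = rng2.choice(len(ps), size=k, replace=False)
            expect = brute_force_sum([ps.patches[j] for j in idx], 100.0, k)
            np.testing.assert_array_equal(out.patches[i], expect)
            assert len(out.coords[i]) == sum(len(ps.coords[j]) for j in idx)

    def test_emitter_conservation(self, rng, camera):
        ps = self._patchset(rng, n=15, camera=camera)
        cfg = SummingConfig(patch_size=8, k_per_output=3, n_outputs=40, seed=2)
        out = sum_patches(ps, cfg, offset=100.0)
        rng2 = np.random.default_rng(cfg.seed)
        expected_total = sum(
            sum(len(ps.coords[j]) for j in rng2.choice(len(ps), size=3, replace=False))
            for _ in range(40))
        assert out.n_emitters == expected_total

    def test_k_exceeding_pool_rejected(self, rng, camera):
        ps = self._patchset(rng, n=4, camera=camera)
        with pytest.raises(ValueError, match="exceeds"):
            sum_patches(ps, SummingConfig(patch_size=8, k_per_output=5,
                                          n_outputs=1), offset=0.0)

    def test_deterministic_per_seed(self, rng, camera):
        ps = self._patchset(rng, camera=camera)
        cfg = SummingConfig(patch_size=8, k_per_output=2, n_outputs=10, seed=42)
        a = sum_patches(ps, cfg, offset=100.0)
        b = sum_patches(ps, cfg, offset=100.0)
        np.testing.assert_array_equal(a.patches, b.patches)


class TestChooseK:
    def test_worked_example(self):
        # 2.0 /µm² * (16 * 107 nm)² / 1.0 per patch = 5.86 -> k = 6
        assert choose_k_for_density(2.0, 1.0, 16, 107.0) == 6

    def test_floor_rule(self):
        assert choose_k_for_density(0.01, 1.0, 16, 107.0) == 1

    def test_linearity(self):
        k1 = choose_k_for_density(1.0, 1.0, 16, 107.0)
        k2 = choose_k_for_density(2.0, 1.0, 16, 107.0)
        assert abs(k2 - 2 * k1) <= 1

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            choose_k_for_density(0.0, 1.0, 16, 107.0)


class TestSumFrameGroups:
    def test_group_size_one_is_permutation(self, camera, rng):
        frames = rng.integers(0, 500, size=(10, 4, 4)).astype(np.uint16)
        movie = Movie(frames, 0.15, camera)
        out = sum_frame_groups(movie, 1, offset=100.0, seed=0)
        assert out.n_frames == 10
        got = {tuple(f.ravel()) for f in out.frames}
        want = {tuple(f.ravel()) for f in frames}
        assert got == want

    def test_4000_frames_group_10_gives_400(self, camera):
        movie = Movie(np.full((4000, 2, 2), 100, dtype=np.uint16), 0.15, camera)
        out = sum_frame_groups(movie, 10, offset=100.0, seed=0)
        assert out.n_frames == 400

    def test_constant_offset_movie_stays_at_offset(self, camera):
        movie = Movie(np.full((80, 4, 4), 100, dtype=np.uint16), 0.15, camera)
        out = sum_frame_groups(movie, 40, offset=100.0, seed=1)
        assert (out.frames == 100.0).all()

    def test_remainder_frames_dropped(self, camera):
        movie = Movie(np.zeros((45, 2, 2), dtype=np.uint16), 0.15, camera)
        assert sum_frame_groups(movie, 10, offset=0.0, seed=0).n_frames == 4

    def test_matches_brute_force(self, camera, rng):
        frames = rng.integers(50, 300, size=(12, 8, 8)).astype(np.uint16)
        movie = Movie(frames, 0.15, camera)
        out = sum_frame_groups(movie, 3, offset=100.0, seed=5)
        perm = np.random.default_rng(5).permutation(12)
        for g in range(4):
            idx = perm[3 * g:3 * g + 3]
            expect = brute_force_sum([frames[i] for i in idx], 100.0, 3)
            np.testing.assert_array_equal(out.frames[g], expect)

    def test_invalid_group_size(self, camera):
        movie = Movie(np.zeros((10, 2, 2), dtype=np.uint16), 0.15, camera)
        with pytest.raises(ValueError):
            sum_frame_groups(movie, 0, offset=0.0)
        with pytest.raises(ValueError, match="fewer"):
            sum_frame_groups(movie, 11, offset=0.0)


class TestConcentrationGroupFactor:
    @pytest.mark.parametrize("c_low,c_target,expect", [
        (0.5e-9, 20e-9, 40),   # 0.5 nM -> 20 nM
        (0.5e-9, 5e-9, 10),    # 0.5 nM -> 5 nM
        (0.5e-9, 10e-9, 20),   # 0.5 nM -> 10 nM
        (0.5e-9, 0.5e-9, 1),
    ])
    def test_linear_scaling(self, c_low, c_target, expect):
        assert concentration_group_factor(c_low, c_target) == expect

    def test_target_below_low_rejected(self):
        with pytest.raises(ValueError):
            concentration_group_factor(1e-9, 0.5e-9)


class TestDensityRealization:
    def test_summed_density_within_10pct_of_target(self, camera):
        # full chain: sparse simulation -> extraction -> k choice -> summing
        field = uniform_field(30000, (128 * 107.0, 128 * 107.0), seed=51)
        kin = KineticsConfig(concentration=concentration_for_density(
            field, KineticsConfig(), 0.028))
        movie, truth = simulate_movie(field, kin, camera, (128, 128), 250,
                                      0.15, seed=52)
        cfg = SummingConfig(patch_size=16, n_outputs=300, seed=53)
        sparse = extract_sparse_patches(movie, truth, cfg)
        target = 1.9
        k = choose_k_for_density(target, sparse.mean_emitters_per_patch, 16,
                                 camera.pixel_size)
        out = sum_patches(sparse, dataclasses.replace(cfg, k_per_output=k),
                          camera.offset)
        assert out.density_per_um2() == pytest.approx(target, rel=0.10)
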