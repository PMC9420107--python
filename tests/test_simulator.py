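"""Simulator: structure geometry, binding kinetics, image formation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from paintdense import (CameraModel, KineticsConfig, StructureSpec,
                        concentration_for_density, expected_density,
                        measured_density, place_structures, render_frames,
                        simulate_binding, simulate_movie, uniform_field)
from paintdense.simulator import _random_polyline, _sample_on_polyline

FIELD = (6848.0, 6848.0)  # 64 x 64 px at 107 nm


def _dist_to_polyline(pts, poly):
    """Min distance of each point to any segment of the polyline (oracle)."""
    d = np.full(len(pts), np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        t = np.clip(((pts - a) @ ab) / (ab @ ab), 0, 1)
        proj = a + t[:, None] * ab
        d = np.minimum(d, np.hypot(*(pts - proj).T))
    return d


class TestPlaceStructures:
    def test_zero_structures_empty_field(self):
        f = place_structures(StructureSpec(), FIELD, seed=0)
        assert f.n_sites == 0

    def test_determinism(self):
        spec = StructureSpec(n_filaments=2, n_patches=1, n_outlines=1)
        a = place_structures(spec, FIELD, seed=5)
        b = place_structures(spec, FIELD, seed=5)
        np.testing.assert_array_equal(a.x_nm, b.x_nm)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_filament_site_count_and_geometry(self):
        # 2 µm filament at 50 sites/µm: ~100 sites, Poisson spread
        spec = StructureSpec(n_filaments=1, filament_length_um=2.0,
                             filament_site_density_per_um=50.0)
        counts = [place_structures(spec, FIELD, seed=s).n_sites for s in range(30)]
        assert 70 < np.mean(counts) < 130

    def test_sampled_points_lie_on_polyline(self, rng):
        poly = _random_polyline(rng, 2000.0, 4, *FIELD)
        pts = _sample_on_polyline(rng, poly, 200)
        assert _dist_to_polyline(pts, poly).max() < 1e-6

    def test_all_sites_inside_field(self):
        spec = StructureSpec(n_filaments=3, n_patches=2, n_outlines=2)
        f = place_structures(spec, FIELD, seed=9)
        assert f.x_nm.min() >= 0 and f.x_nm.max() <= FIELD[0]
        assert f.y_nm.min() >= 0 and f.y_nm.max() <= FIELD[1]

    def test_labels_cover_requested_morphologies(self):
        spec = StructureSpec(n_filaments=1, n_patches=1, n_outlines=1)
        f = place_structures(spec, FIELD, seed=2)
        assert {"filament", "patch", "outline"} <= set(f.labels)


class TestBindingKinetics:
    def test_zero_concentration_zero_events(self):
        field = uniform_field(100, FIELD, seed=0)
        kin = KineticsConfig(concentration=0.0)
        ev = simulate_binding(field, kin, 100, 0.15, seed=1)
        assert len(ev) == 0

    def test_event_rate_matches_closed_form_and_doubles(self):
        # mean events overlapping a frame ~= N * c*k_on * (tau + t_int)
        field = uniform_field(2000, FIELD, seed=0)
        t_int, n_frames = 0.15, 400
        rates = {}
        for c in (1e-9, 2e-9):
            kin = KineticsConfig(concentration=c)
            per_frame = []
            for s in range(6):
                ev = simulate_binding(field, kin, n_frames, t_int, seed=s)
                start = ev["start_frame"].to_numpy()
                end = start + ev["duration_frames"].to_numpy()
                # events overlapping frame 100
                per_frame.append(((start < 101) & (end > 100)).sum())
            expect = field.n_sites * kin.on_rate * (kin.tau_bright + t_int)
            m, se = np.mean(per_frame), np.std(per_frame) / np.sqrt(6)
            assert abs(m - expect) < 3 * max(se, 1e-9) + 0.05 * expect
            rates[c] = m
        assert rates[2e-9] == pytest.approx(2 * rates[1e-9], rel=0.25)

    def test_occupancy_matches_stationary_formula(self):
        # total bound time per unit time ~= N * p
        field = uniform_field(3000, FIELD, seed=1)
        kin = KineticsConfig(concentration=5e-9)
        T, t_int = 60.0, 0.15
        n_frames = int(T / t_int)
        vals = []
        for s in range(8):
            ev = simulate_binding(field, kin, n_frames, t_int, seed=10 + s)
            start = np.maximum(ev["start_frame"].to_numpy() * t_int, 0.0)
            end = np.minimum((ev["start_frame"] + ev["duration_frames"]).to_numpy() * t_int, T)
            vals.append(np.clip(end - start, 0, None).sum() / T)
        expect = field.n_sites * kin.occupancy
        m, se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(8)
        assert abs(m - expect) < 3 * se

    def test_stationarity_no_bleaching(self):
        # bound time in first vs last quartile of a long movie agree within 3 SE
        field = uniform_field(2000, FIELD, seed=2)
        kin = KineticsConfig(concentration=10e-9)
        t_int, n_frames = 0.15, 2000
        q = n_frames // 4
        first, last = [], []
        for s in range(6):
            ev = simulate_binding(field, kin, n_frames, t_int, seed=30 + s)
            start = ev["start_frame"].to_numpy()
            end = start + ev["duration_frames"].to_numpy()
            for lo, hi, acc in ((0, q, first), (3 * q, n_frames, last)):
                o = np.clip(np.minimum(end, hi) - np.maximum(start, lo), 0, None)
                acc.append(o.sum() / (hi - lo))
        diff = np.array(first) - np.array(last)
        se = np.std(diff, ddof=1) / np.sqrt(len(diff))
        assert abs(np.mean(diff)) < 3 * se + 1e-9

    def test_determinism_per_seed(self):
        field = uniform_field(200, FIELD, seed=3)
        kin = KineticsConfig(concentration=2e-9)
        a = simulate_binding(field, kin, 50, 0.15, seed=7)
        b = simulate_binding(field, kin, 50, 0.15, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestDensityAccounting:
    def test_expected_density_arithmetic(self):
        # 100 sites at occupancy 0.1 in a 100 µm² field -> 0.1 emitters/µm²
        field = uniform_field(100, (10000.0, 10000.0), seed=0)
        kin = KineticsConfig(k_on=1e6, tau_bright=0.5)
        c = (1.0 / 9.0) / (kin.k_on * kin.tau_bright)  # r*tau = 1/9 -> p = 0.1
        kin = dataclasses.replace(kin, concentration=c)
        assert kin.occupancy == pytest.approx(0.1)
        assert expected_density(field, kin) == pytest.approx(0.1)

    def test_zero_concentration_density(self):
        field = uniform_field(100, FIELD, seed=0)
        assert expected_density(field, KineticsConfig(concentration=0.0)) == 0.0

    def test_concentration_for_density_inverts(self):
        field = uniform_field(5000, FIELD, seed=0)
        kin = KineticsConfig()
        for target in (0.028, 1.0, 6.0):
            c = concentration_for_density(field, kin, target)
            got = expected_density(field, dataclasses.replace(kin, concentration=c))
            assert got == pytest.approx(target, rel=1e-9)

    def test_measured_density_matches_expected(self, camera):
        field = uniform_field(4000, FIELD, seed=4)
        kin = KineticsConfig(concentration=concentration_for_density(
            field, KineticsConfig(), 1.5))
        n_frames = 150
        vals = []
        for s in range(5):
            _, truth = simulate_movie(field, kin, camera, (64, 64), n_frames,
                                      0.15, seed=40 + s, shot_noise=False)
            vals.append(measured_density(truth, kin, field.area_um2, n_frames))
        m, se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(5)
        assert abs(m - 1.5) < 3 * se


class TestRendering:
    def test_background_only(self, camera):
        field = uniform_field(10, FIELD, seed=0)
        kin = KineticsConfig(concentration=0.0, bg_photons=0.0)
        movie, truth = simulate_movie(field, kin, camera, (64, 64), 20, 0.15, seed=1)
        assert len(truth) == 0
        m = movie.frames.mean()
        se = camera.read_noise / np.sqrt(movie.frames.size)
        assert abs(m - camera.offset) < 3 * se + 0.5  # 0.5 for integer rounding

    def test_photon_conservation_noise_free(self):
        # one emitter bound for exactly one frame, no noise, gain 1, offset 0
        cam = CameraModel(offset=0.0, gain=1.0, read_noise=0.0, pixel_size=107.0)
        field = uniform_field(1, (3210.0, 3210.0), seed=5)  # 30x30 px
        kin = KineticsConfig(photons_per_frame=2000.0, bg_photons=0.0)
        ev = pd.DataFrame({"site": [0], "start_frame": [1.0], "duration_frames": [1.0]})
        movie, truth = render_frames(ev, field, kin, cam, (30, 30), 3, 0.15,
                                     seed=0, shot_noise=False)
        total = movie.frames[1].sum()
        assert total == pytest.approx(2000.0, rel=0.01)  # < 1 % kernel truncation
        assert movie.frames[0].sum() == 0
        assert list(truth["frame"]) == [1]

    def test_truth_frames_match_event_frames(self, camera):
        field = uniform_field(50, FIELD, seed=6)
        kin = KineticsConfig(concentration=5e-9)
        ev = simulate_binding(field, kin, 40, 0.15, seed=3)
        _, truth = render_frames(ev, field, kin, camera, (64, 64), 40, 0.15, seed=4)
        start = ev["start_frame"].to_numpy()
        end = start + ev["duration_frames"].to_numpy()
        expected_frames = set()
        for s, e in zip(start, end):
            for f in range(max(int(np.floor(s)), 0), min(int(np.ceil(e)), 40)):
                if min(e, f + 1) - max(s, f) > 1e-9:
                    expected_frames.add(f)
        assert set(truth["frame"]) == expected_frames

    def test_field_larger_than_frame_rejected(self, camera):
        field = uniform_field(5, (20000.0, 20000.0), seed=0)
        kin = KineticsConfig()
        with pytest.raises(ValueError, match="smaller"):
            render_frames(pd.DataFrame({"site": [], "start_frame": [],
                                        "duration_frames": []}),
                          field, kin, camera, (64, 64), 10, 0.15)

    def test_movie_determinism(self, camera):
        field = uniform_field(300, FIELD, seed=7)
        kin = KineticsConfig(concentration=2e-9)
        a, _ = simulate_movie(field, kin, camera, (64, 64), 10, 0.15, seed=9)
        b, _ = simulate_movie(field, kin, camera, (64, 64), 10, 0.15, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)
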