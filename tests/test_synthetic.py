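"""Synthetic-world generator: contracts, determinism, planted responses."""

import numpy as np
import pandas as pd
import pytest

from conftest import constant_suitability_landscape
from herdwatch.synthetic import (FLIGHT, REGROUP, UNDISTURBED, IntrusionEvent,
                                 SimulationConfig, apply_response_model,
                                 degrade_to_sensor, generate_landscape,
                                 make_intrusion, response_bookkeeping,
                                 response_fraction, sample_flight_duration,
                                 simulate_herds)


class TestLandscape:
    def test_shape_and_finiteness(self):
        L = generate_landscape(1, extent_m=3000.0, cell_m=10.0)
        assert L.shape == (300, 300)
        assert np.isfinite(L.elevation).all()
        assert np.isfinite(L.tree_cover).all()
        for arr in L.suitability.values():
            assert arr.shape == (300, 300)
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_determinism(self):
        a = generate_landscape(5, 1000.0, 10.0)
        b = generate_landscape(5, 1000.0, 10.0)
        np.testing.assert_array_equal(a.tree_cover, b.tree_cover)
        np.testing.assert_array_equal(a.elevation, b.elevation)

    def test_tree_cover_bounded_over_many_seeds(self):
        for seed in range(50):
            L = generate_landscape(seed, 400.0, 20.0)
            assert L.tree_cover.min() >= 0.0
            assert L.tree_cover.max() <= 1.0

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            generate_landscape(1, -100.0, 10.0)
        with pytest.raises(ValueError):
            generate_landscape(1, 100.0, 0.0)


class TestHerdSimulation:
    def test_track_length_contract(self, landscape, sim_config):
        tracks = simulate_herds(landscape, sim_config, 600.0, seed=2)
        assert len(tracks) == 6
        assert all(t.n == 600 for t in tracks)
        for t in tracks:
            xmin, ymin, xmax, ymax = landscape.bbox
            assert (t.positions[:, 0] >= xmin).all()
            assert (t.positions[:, 0] <= xmax).all()

    def test_determinism_under_seed(self, landscape, sim_config):
        a = simulate_herds(landscape, sim_config, 300.0, seed=9)
        b = simulate_herds(landscape, sim_config, 300.0, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)
            np.testing.assert_array_equal(ta.odba, tb.odba)

    def test_zero_cohesion_disperses(self, landscape):
        def mean_iid(tracks, t):
            p = np.array([tr.positions[t] for tr in tracks])
            d = np.linalg.norm(p[:, None] - p[None, :], axis=2)
            return d[np.triu_indices(len(p), 1)].mean()

        loose = SimulationConfig(n_per_species={"zebra": 8}, cohesion_weight=0.0,
                                 alignment_weight=0.0,
                                 state_speed_factor=(1.0, 1.0, 1.0))
        tight = SimulationConfig(n_per_species={"zebra": 8},
                                 state_speed_factor=(1.0, 1.0, 1.0))
        tl = simulate_herds(landscape, loose, 1800.0, seed=4)
        tt = simulate_herds(landscape, tight, 1800.0, seed=4)
        assert mean_iid(tl, 1799) > mean_iid(tl, 0)
        assert mean_iid(tl, 1799) > mean_iid(tt, 1799)

    def test_speed_suitability_coupling(self):
        rich = constant_suitability_landscape(1.0)
        poor = constant_suitability_landscape(0.2)
        cfg = SimulationConfig(n_per_species={"zebra": 6},
                               state_speed_factor=(1.0, 1.0, 1.0))
        tr = simulate_herds(rich, cfg, 900.0, seed=6)
        tp = simulate_herds(poor, cfg, 900.0, seed=6)
        med = lambda ts: np.median(np.concatenate(
            [np.linalg.norm(np.diff(t.positions, axis=0), axis=1) for t in ts]))
        assert med(tp) < med(tr)


class TestResponseModel:
    def _herd(self, landscape, seed=3, n=6, duration=3600.0):
        cfg = SimulationConfig(n_per_species={"zebra": n})
        return cfg, simulate_herds(landscape, cfg, duration, seed=seed)

    def test_far_intruder_is_noop(self, landscape):
        cfg, tracks = self._herd(landscape, duration=1200.0)
        t0 = tracks[0].t0
        # static route pinned far outside any detection radius
        far = np.tile([1.0, 1.0], (241, 1))
        centroid = np.mean([t.positions.mean(axis=0) for t in tracks], axis=0)
        far = np.tile(centroid + [50_000.0, 0.0], (241, 1))
        intr = IntrusionEvent("far", "foot", 2, t0, t0 + 1200.0, far)
        out = apply_response_model(tracks, intr, cfg, landscape, seed=1)
        for a, b in zip(tracks, out):
            np.testing.assert_allclose(a.positions, b.positions)
            assert (b.labels == UNDISTURBED).all()

    def test_flight_duration_sample_mean(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        draws = np.array([sample_flight_duration("zebra", cfg, rng)
                          for _ in range(200)]) / 60.0
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 47.0) < 2 * se + 1e-9

    def test_flight_heading_points_away(self, landscape):
        cfg, tracks = self._herd(landscape, duration=1800.0)
        t0 = tracks[0].t0
        centroid = np.mean([t.positions[0] for t in tracks], axis=0)
        intr = make_intrusion(landscape, 8, t_start=t0, duration_s=1800.0,
                              waypoint=centroid)
        out = apply_response_model(tracks, intr, cfg, landscape, seed=2)
        cosines = []
        for tr in out:
            flight = np.flatnonzero(tr.labels == FLIGHT)
            for i in flight:
                if i == 0 or i >= tr.n - 1:
                    continue
                step = tr.positions[i + 1] - tr.positions[i]
                if np.linalg.norm(step) < 1e-6:
                    continue
                away = tr.positions[i] - intr.position_at(tr.times[i])
                away /= np.linalg.norm(away)
                cosines.append(np.dot(step / np.linalg.norm(step), away))
        assert len(cosines) > 100
        assert np.mean(cosines) > 0.7

    def test_bookkeeping_links_responses_to_encounter(self, landscape):
        cfg, tracks = self._herd(landscape, duration=1800.0)
        t0 = tracks[0].t0
        centroid = np.mean([t.positions[0] for t in tracks], axis=0)
        intr = make_intrusion(landscape, 8, t_start=t0, duration_s=1800.0,
                              waypoint=centroid)
        out = apply_response_model(tracks, intr, cfg, landscape, seed=2)
        book = response_bookkeeping(out)
        assert len(book) > 0
        # each animal's first response is a flight that starts while the
        # intruder is inside the detection radius
        for aid, grp in book.groupby("animal_id"):
            first = grp.sort_values("start").iloc[0]
            assert first["label"] == "flight"
            tr = next(t for t in out if t.animal_id == aid)
            t_on = tr.times[int(first["start"])]
            d = np.linalg.norm(tr.positions[int(first["start"])]
                               - intr.position_at(t_on))
            assert d <= cfg.detection_radius_m * 1.05
        assert 0.0 < response_fraction(out) < 1.0


class TestSensorDegradation:
    def test_stationary_slow_cadence_and_noise_floor(self, landscape):
        from herdwatch.synthetic import TrueTrack
        cfg = SimulationConfig()
        n = 3600
        tr = TrueTrack("a0", "zebra", 0.0,
                       positions=np.tile([500.0, 500.0], (n, 1)),
                       labels=np.zeros(n, dtype=np.int8),
                       intensity=np.zeros(n, dtype=np.int8),
                       odba=np.full(n, cfg.odba_base))
        raw = degrade_to_sensor(tr, cfg, seed=3)
        assert np.allclose(np.diff(raw.fix_times), cfg.fix_interval_slow_s)
        # ODBA variance stays at the sensor-noise floor
        assert raw.odba_windows["variance"].max() < 9 * cfg.odba_noise_sd ** 2

    def test_geofence_suppresses_close_fix(self):
        from herdwatch.synthetic import TrueTrack
        cfg = SimulationConfig(gps_noise_sd_m=0.0, spike_rate=0.0,
                               odba_noise_sd=0.0)
        n = 1801
        pos = np.tile([100.0, 100.0], (n, 1))
        pos[900:, 1] = 103.0      # second scheduled fix lands 3 m away
        tr = TrueTrack("a0", "zebra", 0.0, pos,
                       np.zeros(n, dtype=np.int8), np.zeros(n, dtype=np.int8),
                       np.full(n, cfg.odba_base))
        raw = degrade_to_sensor(tr, cfg, seed=0)
        assert raw.fix_times[0] == 0.0
        assert 900.0 not in raw.fix_times

    def test_no_spikes_bounds_displacement(self, landscape, sim_config):
        sim_config.spike_rate = 0.0
        tracks = simulate_herds(landscape, sim_config, 1800.0, seed=5)
        worst_speed = max(np.linalg.norm(np.diff(t.positions, axis=0), axis=1).max()
                          for t in tracks)
        for rep in range(100):
            tr = tracks[rep % len(tracks)]
            raw = degrade_to_sensor(tr, sim_config, seed=100 + rep)
            if raw.n_fixes < 2:
                continue
            d = np.linalg.norm(np.diff(raw.fixes, axis=0), axis=1)
            dt = np.diff(raw.fix_times)
            bound = worst_speed * dt + 6 * sim_config.gps_noise_sd_m
            assert (d <= bound).all()

    def test_odba_windows_keep_continuous_grid(self, landscape, sim_config):
        tracks = simulate_herds(landscape, sim_config, 600.0, seed=7)
        raw = degrade_to_sensor(tracks[0], sim_config, seed=1)
        starts = raw.odba_windows["window_start"].to_numpy()
        assert np.allclose(np.diff(starts), 15.0)
        assert (raw.odba_windows["variance"] >= 0).all()

    def test_empty_track(self, sim_config):
        from herdwatch.synthetic import TrueTrack
        tr = TrueTrack("a0", "zebra", 0.0, np.empty((0, 2)),
                       np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int8),
                       np.empty(0))
        raw = degrade_to_sensor(tr, sim_config, seed=1)
        assert raw.n_fixes == 0


class TestIntrusionEvent:
    def test_route_cadence_and_decimation(self, landscape):
        intr = make_intrusion(landscape, 4, t_start=0.0, duration_s=600.0)
        assert len(intr.route) == 121
        assert np.allclose(np.diff(intr.route_times), 5.0)
        dec = intr.decimate(60.0)
        np.testing.assert_array_equal(dec, intr.route[::12])

    def test_roundtrip_csv_frames(self, landscape, sim_config):
        tracks = simulate_herds(landscape, sim_config, 120.0, seed=1)
        from herdwatch.synthetic import TrueTrack
        df = tracks[0].to_frame()
        back = TrueTrack.from_frame(df)
        np.testing.assert_allclose(back.positions, tracks[0].positions)
        assert back.species == tracks[0].species
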