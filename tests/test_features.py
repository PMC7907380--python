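"""Feature engineering: geometry identities, context standardization,
moving windows, discretization, translation invariance."""

import numpy as np
import pandas as pd
import pytest

from herdwatch.features import (FeatureConfig, build_feature_matrix,
                                build_reference, collective_features,
                                feature_columns, feature_report,
                                individual_geometry, space_use_features,
                                standardize, tobler_speed_ms,
                                transform_truncate_discretize, window_features)
from herdwatch.preprocess import RegularTrack
from herdwatch.synthetic import Landscape, generate_landscape


def make_track(positions, animal_id="a0", species="zebra", t0=0.0,
               odba=0.2) -> RegularTrack:
    n = len(positions)
    return RegularTrack(
        animal_id=animal_id, species=species,
        times=t0 + 60.0 * np.arange(n),
        positions=np.asarray(positions, dtype=float),
        odba_mean=np.full(n, odba), odba_max=np.full(n, odba * 1.5),
        odba_var=np.full(n, 0.01),
        provenance=np.array(["observed"] * n, dtype=object))


class TestIndividualGeometry:
    def test_straight_uniform_motion(self):
        n = 40
        pos = np.stack([60.0 * np.arange(n), np.zeros(n)], axis=1)
        f = individual_geometry(make_track(pos))
        assert f["speed"].iloc[5] == pytest.approx(1.0)
        assert f["persistence"].iloc[20] == pytest.approx(1.0)
        assert f["net_gross"].iloc[20] == pytest.approx(1.0)
        # ballistic motion: MSD ~ lag^2
        assert f["msd_alpha"].iloc[25] == pytest.approx(2.0, abs=0.05)

    def test_circle_constant_turning(self):
        steps = 36
        ang = 2 * np.pi * np.arange(3 * steps) / steps
        pos = 500.0 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        f = individual_geometry(make_track(pos))
        expected = 2 * np.pi / steps
        assert np.allclose(f["turn_angle"].iloc[5:], expected, atol=1e-6)

    def test_random_walk_diffusive(self):
        rng = np.random.default_rng(0)
        steps = rng.normal(0, 30.0, size=(1000, 2))
        pos = np.cumsum(steps, axis=0)
        f = individual_geometry(make_track(pos))
        assert f["net_gross"].iloc[-200:].mean() < 0.6
        # diffusive regime: log-log MSD slope near 1 (oracle: closed-form
        # MSD(l) = 2 sigma^2 l gives exactly slope 1)
        assert abs(f["msd_alpha"].iloc[50:].mean() - 1.0) < 0.35

    def test_zero_steps_leave_turn_missing(self):
        pos = np.zeros((10, 2))
        f = individual_geometry(make_track(pos))
        assert f["turn_angle"].isna().all()


class TestCollective:
    def test_identical_pair_fully_aligned(self):
        n = 20
        pos = np.stack([60.0 * np.arange(n), np.zeros(n)], axis=1)
        a = make_track(pos, "a0")
        b = make_track(pos + [0.0, 50.0], "a1")
        f = collective_features([a, b])
        fa = f.xs("a0", level="animal_id")
        assert fa["alignment"].iloc[5] == pytest.approx(1.0)
        assert fa["synchrony"].iloc[5] == pytest.approx(1.0, abs=1e-6)
        assert fa["nn_dist"].iloc[5] == pytest.approx(50.0)

    def test_uniform_headings_low_alignment(self):
        n_nb = 100
        tracks = []
        for k in range(n_nb + 1):
            ang = 2 * np.pi * k / (n_nb + 1)
            start = np.array([500.0, 500.0]) + 50.0 * np.array(
                [np.cos(ang), np.sin(ang)])
            pos = start + np.outer(np.arange(5) * 10.0,
                                   [np.cos(ang), np.sin(ang)])
            tracks.append(make_track(pos, f"a{k}"))
        cfg = FeatureConfig(neighbor_radius_m=500.0)
        f = collective_features(tracks, cfg)
        focal = f.xs("a0", level="animal_id")["alignment"].iloc[2]
        # null mean resultant length for n uniform headings ~ 0.5*sqrt(pi/n)
        assert focal < 4 * 0.5 * np.sqrt(np.pi / n_nb)

    def test_single_animal(self):
        pos = np.stack([np.arange(5) * 60.0, np.zeros(5)], axis=1)
        f = collective_features([make_track(pos)])
        assert (f["density"] == 0.0).all()
        assert f["alignment"].isna().all()


class TestSpaceUse:
    def test_tobler_closed_form(self):
        assert tobler_speed_ms(0.0) * 3.6 == pytest.approx(
            6.0 * np.exp(-3.5 * 0.05))
        assert tobler_speed_ms(-0.05) * 3.6 == pytest.approx(6.0)
        # symmetric around the -5% stationary point
        assert tobler_speed_ms(-0.05 + 0.1) == pytest.approx(
            tobler_speed_ms(-0.05 - 0.1))

    def test_constant_suitability_passthrough(self):
        base = generate_landscape(2, 500.0, 10.0)
        suit = {k: np.full_like(v, 0.5) for k, v in base.suitability.items()}
        L = Landscape(base.origin, base.cell_size, base.tree_cover,
                      np.zeros_like(base.elevation), suit)
        pos = np.stack([100.0 + 10.0 * np.arange(10), np.full(10, 100.0)],
                       axis=1)
        f = space_use_features(make_track(pos), L)
        assert (f["suitability"] == 0.5).all()
        # flat terrain: Tobler at slope 0 everywhere after the first step
        assert np.allclose(f["tobler_speed"].iloc[1:], tobler_speed_ms(0.0))


def _meta_matrix(rng, n=4000):
    """Hand-built matrix: speed depends on habitat; flights deviate."""
    x = rng.uniform(0, 60, n)          # two 30-m habitat bins
    habitat_fast = x >= 30
    speed = np.where(habitat_fast, rng.normal(3.0, 0.1, n),
                     rng.normal(1.0, 0.1, n))
    is_flight = np.zeros(n, dtype=bool)
    is_flight[rng.choice(n, 50, replace=False)] = True
    speed[is_flight] = 4.0
    idx = pd.MultiIndex.from_arrays(
        [np.repeat("a0", n), 60.0 * np.arange(n)], names=["animal_id", "time"])
    return pd.DataFrame({
        "species": "zebra", "x": x, "y": 10.0, "tod": "morning", "period": 0,
        "speed": speed}, index=idx), is_flight


class TestStandardization:
    def test_group_mean_maps_to_zero(self, rng=np.random.default_rng(1)):
        m, _ = _meta_matrix(rng)
        ref = build_reference(m, "species")
        z = standardize(m, ref)
        row = m["speed"].idxmax()
        mu = m["speed"].mean()
        sd = m["speed"].std(ddof=1)
        assert z.loc[row, "speed__z_species"] == pytest.approx(
            (m.loc[row, "speed"] - mu) / sd)

    def test_heldout_pool_zero_mean_unit_var(self, landscape):
        from herdwatch.synthetic import SimulationConfig, degrade_to_sensor, \
            simulate_herds
        from herdwatch.preprocess import preprocess_track
        cfg = SimulationConfig(n_per_species={"zebra": 6, "wildebeest": 6})
        tracks = simulate_herds(landscape, cfg, 5400.0, seed=3)
        regs = [preprocess_track(degrade_to_sensor(t, cfg, seed=60 + i,
                                                   fast_interval_s=120.0),
                                 landscape.bbox)
                for i, t in enumerate(tracks)]
        m = build_feature_matrix(regs, landscape)
        fit_rows = m.sample(frac=0.6, random_state=0)
        ref = build_reference(fit_rows, "species")
        z = standardize(m, ref)
        # statistics recomputed on the fitting pool itself (both species)
        for f in ("speed", "odba_mean", "suitability"):
            for sp in ("zebra", "wildebeest"):
                mask = (z["species"] == sp) & z.index.isin(fit_rows.index) \
                    & m[f].notna()
                vals = z.loc[mask, f + "__z_species"]
                assert abs(vals.mean()) < 0.05
                assert abs(vals.var(ddof=1) - 1.0) < 0.1

    def test_contextual_reference_sharpens_flights(self):
        """When normal speed varies by habitat, flights stand out more
        against the local (area) reference than the global one."""
        rng = np.random.default_rng(2)
        m, is_flight = _meta_matrix(rng)
        undisturbed = m[~is_flight]
        ref_global = build_reference(undisturbed, "species")
        ref_area = build_reference(undisturbed, "area", area_cell_m=30.0)
        zg = standardize(m, ref_global)
        za = standardize(m, ref_area)
        flights_fast = is_flight & (m["x"] >= 30).to_numpy()
        zg_mean = zg.loc[flights_fast, "speed__z_species"].abs().mean()
        za_mean = za.loc[flights_fast, "speed__z_area"].abs().mean()
        assert za_mean > 2 * zg_mean

    def test_literal_variance_mode(self):
        rng = np.random.default_rng(3)
        m, _ = _meta_matrix(rng)
        ref = build_reference(m, "species")
        z_sd = standardize(m, ref, divide_by="sd")
        z_var = standardize(m, ref, divide_by="variance")
        sd = m["speed"].std(ddof=1)
        np.testing.assert_allclose(z_var["speed__z_species"],
                                   z_sd["speed__z_species"] / sd, atol=1e-9)


class TestWindows:
    def _series_matrix(self, values):
        n = len(values)
        idx = pd.MultiIndex.from_arrays(
            [np.repeat("a0", n), 60.0 * np.arange(n)],
            names=["animal_id", "time"])
        return pd.DataFrame({"species": "zebra", "x": 0.0, "y": 0.0,
                             "tod": "morning", "period": 0,
                             "speed": np.asarray(values, float)}, index=idx)

    def test_constant_series(self):
        m = window_features(self._series_matrix(np.full(60, 3.0)), ["speed"])
        assert np.allclose(m["speed__win_5c_mean"].iloc[5:-5], 3.0)
        assert np.allclose(m["speed__win_20l_sd"].iloc[25:], 0.0)
        assert np.allclose(m["speed__win_diff_5c_20l"].iloc[25:-5], 0.0)

    def test_step_change_peaks_after_onset(self):
        v = np.concatenate([np.zeros(40), np.ones(40)])
        m = window_features(self._series_matrix(v), ["speed"])
        d = m["speed__win_diff_5c_20l"].to_numpy()
        # brute-force oracle
        naive = np.full(80, np.nan)
        for t in range(80):
            if t >= 2 and t + 2 < 80 and t >= 19:
                naive[t] = v[t - 2:t + 3].mean() - v[t - 19:t + 1].mean()
        np.testing.assert_allclose(d[20:-5], naive[20:-5], atol=1e-12)
        assert np.nanargmax(d) in range(40, 46)

    def test_insufficient_history_missing(self):
        m = window_features(self._series_matrix(np.arange(30.0)), ["speed"])
        assert m["speed__win_20l_mean"].iloc[:19].isna().all()
        assert m["speed__win_20l_mean"].iloc[19:].notna().all()


class TestDiscretization:
    def _matrix(self, values, extra=None):
        n = len(values)
        idx = pd.MultiIndex.from_arrays(
            [np.repeat("a0", n), 60.0 * np.arange(n)],
            names=["animal_id", "time"])
        d = {"species": "zebra", "x": 0.0, "y": 0.0, "tod": "morning",
             "period": 0, "speed": np.asarray(values, float)}
        if extra is not None:
            d.update(extra)
        return pd.DataFrame(d, index=idx)

    def test_winsor_count_matches_quantile_rule(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 1, 100_000)
        m = transform_truncate_discretize(self._matrix(v), n_bins=10)
        altered = int((m["speed"].to_numpy() != v).sum())
        assert altered <= 220
        assert abs(altered - 2 * 0.001 * len(v)) <= 20

    def test_monotone_transform_preserves_bins(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(1, 2, 5000)
        m1 = transform_truncate_discretize(self._matrix(v), n_bins=8)
        m2 = transform_truncate_discretize(self._matrix(np.exp(v)), n_bins=8)
        np.testing.assert_array_equal(m1["speed__ord"], m2["speed__ord"])

    def test_uniform_data_balanced_bins(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 1, 20_000)
        m = transform_truncate_discretize(self._matrix(v), n_bins=10)
        counts = m["speed__ord"].value_counts()
        assert set(counts.index) == set(range(1, 11))
        assert (np.abs(counts / len(v) - 0.1) < 0.005).all()

    def test_constant_column_single_bin(self):
        m = transform_truncate_discretize(self._matrix(np.full(100, 7.0)),
                                          n_bins=10)
        assert m["speed__ord"].nunique() == 1


class TestInvariance:
    def test_translation_in_space_and_time(self):
        """Features may not depend on absolute coordinates or timestamps."""
        base = generate_landscape(9, 800.0, 10.0)
        rng = np.random.default_rng(7)
        steps = rng.normal(0, 25.0, size=(60, 2))
        pos = np.array([400.0, 400.0]) + np.cumsum(steps, axis=0)
        pos = np.clip(pos, 0, 790)
        shift = np.array([123.0, -77.0])
        t_shift = 86400.0
        moved = Landscape((base.origin[0] + shift[0], base.origin[1] + shift[1]),
                          base.cell_size, base.tree_cover, base.elevation,
                          base.suitability)
        m1 = build_feature_matrix([make_track(pos, t0=6 * 3600.0)], base)
        m2 = build_feature_matrix(
            [make_track(pos + shift, t0=6 * 3600.0 + t_shift)], moved)
        for c in feature_columns(m1):
            np.testing.assert_allclose(m1[c].to_numpy(float),
                                       m2[c].to_numpy(float),
                                       atol=1e-9, err_msg=c)

    def test_feature_count_reported_and_stable(self, landscape):
        pos = np.stack([500.0 + 20.0 * np.arange(30),
                        np.full(30, 500.0)], axis=1)
        m = build_feature_matrix([make_track(pos)], landscape)
        rep = feature_report(m)
        assert set(rep.index) == {"individual_geometry", "accelerometer",
                                  "collective", "space_use"}
        assert rep.sum() == len(feature_columns(m))
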