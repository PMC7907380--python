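"""Localization: circular densities, odds surfaces, geometry fitting,
evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from herdwatch.localize import (GeometryParams, ProbabilitySurface,
                                SentinelSnapshot, evaluate_localization,
                                fit_geometry, lognormal_pdf,
                                make_null_observations, odds_surface,
                                probability_surface, wrapped_normal_pdf)

BBOX = (0.0, 0.0, 3000.0, 3000.0)


def default_params(**kw):
    d = dict(mu1=np.log(600.0), sigma1=0.4, rho1=0.4,
             mu0=np.log(1500.0), sigma0=1.0, rho0=2.5)
    d.update(kw)
    return GeometryParams.constant(**d)


class TestWrappedNormal:
    def test_large_sd_approaches_circular_uniform(self):
        theta = np.linspace(-np.pi, np.pi, 50)
        d = wrapped_normal_pdf(theta, 0.3, 40.0)
        np.testing.assert_allclose(d, 1 / (2 * np.pi), rtol=1e-6)

    @pytest.mark.parametrize("sd", [0.3, 1.0, 3.0])
    def test_integrates_to_one(self, sd):
        val, _ = integrate.quad(lambda a: wrapped_normal_pdf(a, 0.7, sd),
                                -np.pi, np.pi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_about_mean(self):
        for delta in (0.2, 1.0, 2.9):
            assert wrapped_normal_pdf(0.5 + delta, 0.5, 0.8) == pytest.approx(
                wrapped_normal_pdf(0.5 - delta, 0.5, 0.8))

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            wrapped_normal_pdf(0.0, 0.0, 0.0)


class TestOddsSurface:
    def test_undisturbed_animal_uninformative(self):
        params = default_params()
        cells = np.random.default_rng(0).uniform(0, 3000, (50, 2))
        o = odds_surface(cells, [1500.0, 1500.0], 0.3, p_j=0.0,
                         ts_j_min=5.0, params=params)
        np.testing.assert_allclose(o, 1.0, rtol=1e-12)

    def test_identical_state_geometries_collapse(self):
        """Response params equal to null params: the mixture ratio is 1
        for any p (the animal carries no locational information)."""
        params = default_params(mu1=np.log(1500.0), sigma1=1.0, rho1=2.5)
        cells = np.random.default_rng(1).uniform(0, 3000, (50, 2))
        for p in (0.0, 0.5, 1.0):
            o = odds_surface(cells, [1000.0, 2000.0], -1.0, p_j=p,
                             ts_j_min=10.0, params=params)
            np.testing.assert_allclose(o, 1.0, rtol=1e-9)

    def test_hand_computed_single_cell(self):
        params = default_params(rho1=0.5, rho0=2.0)
        cell = np.array([1000.0, 1000.0])
        animal = np.array([1600.0, 1800.0])
        mu_j, p_j, ts = 0.4, 0.8, 7.0
        d = animal - cell
        gamma = np.hypot(*d)
        theta = np.arctan2(d[1], d[0])
        num = (p_j * wrapped_normal_pdf(theta, mu_j, 0.5)
               * lognormal_pdf(gamma, params.mu1(ts), params.sigma1(ts))
               + (1 - p_j) * wrapped_normal_pdf(theta, mu_j, 2.0)
               * lognormal_pdf(gamma, params.mu0, params.sigma0))
        den = (wrapped_normal_pdf(theta, mu_j, 2.0)
               * lognormal_pdf(gamma, params.mu0, params.sigma0))
        got = odds_surface(cell[None, :], animal, mu_j, p_j, ts, params)[0]
        assert got == pytest.approx(num / den)

    def test_product_reading_available(self):
        params = default_params()
        cells = np.array([[500.0, 500.0]])
        a = odds_surface(cells, [800.0, 800.0], 0.0, 0.5, 5.0, params,
                         numerator="mixture")
        b = odds_surface(cells, [800.0, 800.0], 0.0, 0.5, 5.0, params,
                         numerator="product")
        assert not np.allclose(a, b)


class TestProbabilitySurface:
    def test_normalization_contract(self):
        rng = np.random.default_rng(2)
        snap = SentinelSnapshot(
            positions=rng.uniform(500, 2500, (20, 2)),
            headings=rng.uniform(-np.pi, np.pi, 20),
            probs=rng.random(20),
            ts_min=rng.uniform(0, 40, 20))
        surf = probability_surface(snap, default_params(), BBOX, 50.0)
        assert surf.integral() == pytest.approx(1.0, abs=1e-6)
        assert (surf.density >= 0).all()

    def test_single_fleeing_animal_peak_behind(self):
        """Animal fleeing east: the surface peaks west of it, at the
        distance maximizing the response/null density ratio (1-D oracle)."""
        params = default_params()
        snap = SentinelSnapshot(positions=np.array([[2000.0, 1500.0]]),
                                headings=np.array([0.0]),
                                probs=np.array([1.0]),
                                ts_min=np.array([5.0]))
        surf = probability_surface(snap, params, BBOX, 25.0)
        peak = surf.peak()
        g = np.linspace(1.0, 2500.0, 5000)
        ratio = (lognormal_pdf(g, params.mu1(5.0), params.sigma1(5.0))
                 / lognormal_pdf(g, params.mu0, params.sigma0))
        d_star = g[np.argmax(ratio)]
        assert peak[1] == pytest.approx(1500.0, abs=30.0)
        assert 2000.0 - peak[0] == pytest.approx(d_star, abs=60.0)

    def test_two_opposite_fleeing_animals_bracket_origin(self):
        params = default_params()
        origin = np.array([1500.0, 1500.0])
        d0 = 600.0
        snap = SentinelSnapshot(
            positions=np.array([origin + [d0, 0.0], origin - [d0, 0.0]]),
            headings=np.array([0.0, np.pi]),
            probs=np.array([1.0, 1.0]),
            ts_min=np.array([5.0, 5.0]))
        surf = probability_surface(snap, params, BBOX, 25.0)
        # kernel-sum brute force on a coarse line through the origin
        assert np.linalg.norm(surf.peak() - origin) < 200.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(1000, 2000, (5, 2))
        head = rng.uniform(-np.pi, np.pi, 5)
        p = rng.random(5)
        ts = rng.uniform(0, 30, 5)
        shift = np.array([400.0, -250.0])
        s1 = probability_surface(SentinelSnapshot(pos, head, p, ts),
                                 default_params(), BBOX, 50.0)
        bbox2 = (BBOX[0] + shift[0], BBOX[1] + shift[1],
                 BBOX[2] + shift[0], BBOX[3] + shift[1])
        s2 = probability_surface(SentinelSnapshot(pos + shift, head, p, ts),
                                 default_params(), bbox2, 50.0)
        np.testing.assert_allclose(s1.density, s2.density, rtol=1e-9)
        np.testing.assert_allclose(s2.peak() - s1.peak(), shift, atol=1e-9)

    def test_flat_surface_peak_undefined(self):
        surf = ProbabilitySurface((0.0, 0.0), 50.0,
                                  np.full((10, 10), 1.0 / (500.0 ** 2)), 1.0)
        with pytest.raises(ValueError):
            surf.peak()


class TestGeometryFit:
    def _simulate_observations(self, params, n_flights=200, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n_flights):
            for ts in rng.uniform(0, 45, 6):
                d = rng.lognormal(params.mu1(ts), params.sigma1(ts))
                a = rng.normal(0.0, params.rho1(ts))
                a = np.angle(np.exp(1j * a))
                rows.append({"distance_m": d, "rel_angle": a, "ts_min": ts,
                             "response": True})
        for _ in range(600):
            rows.append({"distance_m": rng.lognormal(params.mu0, params.sigma0),
                         "rel_angle": rng.uniform(-np.pi, np.pi),
                         "ts_min": 0.0, "response": False})
        return pd.DataFrame(rows)

    def test_parameter_recovery_from_known_geometry(self):
        true = GeometryParams(
            mu1_poly=np.array([0.0, -0.0005, 0.05, np.log(400.0)]),
            log_sigma1_poly=np.array([0.0, 0.0, 0.01, np.log(0.3)]),
            log_rho1_poly=np.array([0.0, 0.0, 0.015, np.log(0.3)]),
            mu0=np.log(1400.0), sigma0=0.9, rho0=2.2)
        obs = self._simulate_observations(true, n_flights=200)
        fit = fit_geometry(obs)
        for ts in (2.0, 10.0, 25.0, 40.0):
            assert fit.mu1(ts) == pytest.approx(true.mu1(ts), abs=0.15)
            assert fit.sigma1(ts) == pytest.approx(true.sigma1(ts), rel=0.35)
            assert fit.rho1(ts) == pytest.approx(true.rho1(ts), rel=0.35)
        assert fit.mu0 == pytest.approx(true.mu0, abs=0.1)
        # uniform control angles: near-uniform directionality
        assert fit.rho0 > 1.5

    def test_ts_clamped_at_truncation(self):
        params = GeometryParams(
            mu1_poly=np.array([0.0, 0.0, 0.1, 5.0]),
            log_sigma1_poly=np.zeros(4), log_rho1_poly=np.zeros(4),
            mu0=7.0, sigma0=1.0, rho0=2.0)
        assert params.mu1(60.0) == params.mu1(45.0)
        assert params.mu1(60.0) != params.mu1(44.0)

    def test_null_observations_bake_in_geometry(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 3000, (200, 2))
        head = rng.uniform(-np.pi, np.pi, 200)
        obs = make_null_observations(pos, head, BBOX, rng,
                                     n_random_intruders=10)
        assert (obs["distance_m"] > 0).all()
        assert not obs["response"].any()


class TestEvaluation:
    def _peaked_surface(self, peak_xy, spread_cells, cell=50.0, n=60):
        xs = (np.arange(n) + 0.5) * cell
        gx, gy = np.meshgrid(xs, xs)
        d2 = (gx - peak_xy[0]) ** 2 + (gy - peak_xy[1]) ** 2
        dens = np.exp(-0.5 * d2 / (spread_cells * cell) ** 2)
        dens /= dens.sum() * cell ** 2
        return ProbabilitySurface((0.0, 0.0), cell, dens, 1.0)

    def test_peak_at_truth_zero_error(self):
        truth = np.array([1525.0, 1525.0])
        surfaces = {"i0": [self._peaked_surface(truth, 3.0)]}
        out = evaluate_localization(surfaces, {"i0": truth}, n_select=1)
        assert out["per_intrusion"]["mean_error_m"].iloc[0] == pytest.approx(
            0.0, abs=1e-9)

    def test_condensation_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            dens = rng.random((30, 30)) ** 4
            cell = 50.0
            dens /= dens.sum() * cell ** 2
            s = ProbabilitySurface((0.0, 0.0), cell, dens, 1.0)
            # brute force: accumulate largest cells until 5% mass
            masses = np.sort((dens * cell ** 2).ravel())[::-1]
            acc, k = 0.0, 0
            while acc < 0.05:
                acc += masses[k]
                k += 1
            assert s.condensation_area() == pytest.approx(k * cell ** 2)

    def test_uniform_surface_ranks_last(self):
        sharp = [self._peaked_surface([700.0 + 10 * i, 700.0], 2.0)
                 for i in range(10)]
        n = 60
        flat = ProbabilitySurface((0.0, 0.0), 50.0,
                                  np.full((n, n), 1.0 / (n * n * 2500.0)), 1.0)
        ranked = sorted(sharp + [flat], key=lambda s: s.condensation_area())
        assert ranked[-1] is flat

    def test_error_decreases_with_more_sentinels(self):
        """More responding sentinels -> the peak pins the intruder better."""
        params = default_params(sigma1=0.3, rho1=0.3)
        intruder = np.array([1500.0, 1500.0])
        errors = {}
        for k in (2, 20):
            errs = []
            for seed in range(8):
                rng = np.random.default_rng(100 * k + seed)
                ang = rng.uniform(-np.pi, np.pi, k)
                dist = rng.lognormal(params.mu1(5.0), params.sigma1(5.0), k)
                pos = intruder + dist[:, None] * np.stack(
                    [np.cos(ang), np.sin(ang)], axis=1)
                head = ang + rng.normal(0, params.rho1(5.0), k)
                snap = SentinelSnapshot(pos, head, np.ones(k),
                                        np.full(k, 5.0))
                surf = probability_surface(snap, params, BBOX, 50.0)
                errs.append(np.linalg.norm(surf.peak() - intruder))
            errors[k] = np.mean(errs)
        assert errors[20] < errors[2]
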