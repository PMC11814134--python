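"""Diameter sweep, threshold classification, linear dynamics, noise
statistics and isotonic regression."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from oxispheroid import SimulationConfig, TimeSeries
from oxispheroid.analysis import (
    SweepResult,
    analytic_sweep,
    ard_fit,
    classify_thresholds,
    crossing_diameter,
    diameter_sweep,
    factorial_noise_design,
    fit_linear_dynamics,
    isotonic_fit,
    noise_study,
    ols_test,
    random_noise_design,
)


def brute_force_isotonic(y, w, increasing=True):
    """Exhaustive minimizer over all pooled-block monotone fits (n ≤ ~12).

    Enumerates every partition of the sequence into consecutive blocks,
    replaces each block by its weighted mean, keeps partitions whose block
    means are monotone, and returns the feasible fit with the smallest
    weighted squared error.  Independent of the PAVA implementation.
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n = len(y)
    best, best_obj = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        means = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            means.append(np.average(y[a:b], weights=w[a:b]))
        diffs = np.diff(means)
        ok = np.all(diffs >= -1e-12) if increasing else np.all(diffs <= 1e-12)
        if not ok:
            continue
        fit = np.concatenate([
            np.full(b - a, mv) for (a, b), mv in
            zip(zip(bounds[:-1], bounds[1:]), means)
        ])
        obj = float(np.sum(w * (y - fit) ** 2))
        if obj < best_obj:
            best, best_obj = fit, obj
    return best, best_obj


class TestIsotonic:
    def test_three_point_pooling(self):
        fit = isotonic_fit([1, 2, 3], [3, 1, 2], direction="increasing")
        np.testing.assert_allclose(fit.y_fit, [2, 2, 2])

    def test_monotone_input_unchanged(self):
        y = [1.0, 2.0, 5.0, 9.0]
        fit = isotonic_fit([1, 2, 3, 4], y, direction="increasing")
        np.testing.assert_allclose(fit.y_fit, y)

    def test_single_point_clipped_to_bounds(self):
        fit = isotonic_fit([1.0], [200.0], direction="increasing")
        assert fit.y_fit[0] == 160.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            isotonic_fit([], [], direction="increasing")

    def test_matches_exhaustive_minimizer(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 7))
            y = rng.uniform(10, 150, n)
            w = rng.uniform(0.5, 2.0, n)
            fit = isotonic_fit(np.arange(n, dtype=float), y, weights=w,
                               direction="increasing")
            obj = float(np.sum(w * (y - fit.y_fit) ** 2))
            _, best_obj = brute_force_isotonic(y, w, increasing=True)
            assert obj == pytest.approx(best_obj, abs=1e-9)


class TestSweepAndThresholds:
    def test_analytic_crossings_match_closed_form(self, default_config):
        sweep = analytic_sweep(np.arange(200.0, 501.0, 20.0), default_config)
        D, OCR, Pb = default_config.D, default_config.OCR, default_config.P_boundary
        for tau in (100.0, 50.0):
            expected = 2e6 * np.sqrt(6 * D * (Pb - tau) / OCR)  # μm
            assert crossing_diameter(sweep, tau) == pytest.approx(expected, rel=0.03)

    def test_exact_interpolation_between_two_points(self):
        table = pd.DataFrame({"diameter_um": [300.0, 320.0],
                              "min_pressure_mmHg": [110.0, 90.0]})
        sweep = SweepResult(kind="single", table=table)
        assert crossing_diameter(sweep, 100.0) == pytest.approx(310.0)

    def test_threshold_outside_range_raises(self):
        sweep = analytic_sweep([200.0, 250.0, 300.0])
        with pytest.raises(ValueError, match="outside"):
            crossing_diameter(sweep, 10.0)

    def test_classification_ranges(self, default_config):
        sweep = analytic_sweep(np.arange(200.0, 501.0, 20.0), default_config)
        rep = classify_thresholds(sweep)
        assert rep.safe_max_um == pytest.approx(309.8, rel=0.01)
        assert rep.necrotic_min_um == pytest.approx(464.8, rel=0.01)
        assert rep.forming_range_um[0] < rep.forming_range_um[1]

    def test_sweep_above_threshold_has_empty_unsafe_ranges(self):
        sweep = analytic_sweep([100.0, 150.0, 200.0])
        rep = classify_thresholds(sweep)
        assert rep.crossing_low_um is None
        assert rep.necrotic_min_um is None

    def test_threshold_order_enforced(self):
        sweep = analytic_sweep([200.0, 300.0, 400.0])
        with pytest.raises(ValueError):
            classify_thresholds(sweep, thresholds=(100.0, 50.0))

    def test_solver_sweep_tracks_analytic(self, default_config):
        diam = [220.0, 300.0, 380.0]
        sweep = diameter_sweep("single", diam, cells_per_radius=10,
                               config=default_config)
        ref = analytic_sweep(diam, default_config)
        np.testing.assert_allclose(sweep.table["min_pressure_mmHg"],
                                   ref.table["min_pressure_mmHg"], rtol=0.03)
        assert np.all(np.diff(sweep.table["min_pressure_mmHg"]) < 0)

    def test_zero_consumption_sweep_is_flat(self, default_config):
        cfg = replace(default_config, OCR=0.0)
        sweep = diameter_sweep("single", [200.0, 260.0, 320.0],
                               cells_per_radius=8, config=cfg)
        np.testing.assert_allclose(sweep.table["min_pressure_mmHg"], 140.0)

    def test_fused_sweep_is_deeper_than_single(self, default_config):
        """Two fused spheroids contain interior farther from the surface
        than one spheroid of the same constituent diameter."""
        diam = [240.0, 300.0, 360.0]
        single = diameter_sweep("single", diam, cells_per_radius=8,
                                config=default_config)
        fused = diameter_sweep("fused", diam, cells_per_radius=8,
                               config=default_config)
        assert np.all(fused.table["min_pressure_mmHg"].to_numpy() <
                      single.table["min_pressure_mmHg"].to_numpy())

    def test_too_few_diameters(self):
        with pytest.raises(ValueError):
            diameter_sweep("single", [200.0, 300.0])


class TestLinearDynamics:
    def _series(self, f, n=12, dt=0.25):
        t = np.arange(n) * dt
        return TimeSeries(times=t, min_pressure=f(t))

    def test_exact_line_recovered(self):
        ts = self._series(lambda t: 140.0 - 2.0 * t)
        fit = fit_linear_dynamics(ts, n_points=10)
        assert fit.A == pytest.approx(140.0, abs=1e-10)
        assert fit.B == pytest.approx(-2.0, abs=1e-10)

    def test_constant_series_has_zero_slope(self):
        fit = fit_linear_dynamics(self._series(lambda t: np.full_like(t, 99.0)))
        assert fit.B == pytest.approx(0.0, abs=1e-12)

    def test_log_transform(self):
        ts = self._series(lambda t: 100.0 * np.exp(-0.3 * t))
        fit = fit_linear_dynamics(ts, log_transform=True)
        assert fit.B == pytest.approx(-0.3, rel=1e-9)
        assert fit.A == pytest.approx(np.log(100.0), rel=1e-9)

    def test_insufficient_points(self):
        ts = self._series(lambda t: t, n=5)
        with pytest.raises(ValueError):
            fit_linear_dynamics(ts, n_points=10)
        with pytest.raises(ValueError):
            fit_linear_dynamics(ts, n_points=1)


def _synthetic_table(rng, n=50, coef_a=5.0, noise=0.01):
    a = rng.uniform(0, 2, n)
    q = rng.uniform(0.05, 0.4, n)
    p = rng.uniform(0, 1, n)
    y = coef_a * a + noise * rng.standard_normal(n)
    return pd.DataFrame({"a": a, "q": q, "p": p, "A": y, "B": -y})


class TestNoiseStatistics:
    def test_ols_flags_planted_amplitude_effect(self, rng):
        tab = _synthetic_table(rng)
        rep = ols_test(tab, "A")
        assert rep.adjusted_alpha == pytest.approx(0.025)
        assert rep.significant["a"]
        assert not rep.significant["q"] and not rep.significant["p"]

    def test_ols_constant_response_finds_nothing(self, rng):
        tab = _synthetic_table(rng)
        tab["A"] = 7.0
        rep = ols_test(tab, "A")
        assert not any(rep.significant.values())

    def test_ols_collinear_design_rejected(self, rng):
        tab = _synthetic_table(rng)
        tab["q"] = 2.0 * tab["a"]
        with pytest.raises(ValueError, match="collinear"):
            ols_test(tab, "A")

    def test_ard_recovers_planted_coefficient(self, rng):
        tab = _synthetic_table(rng, coef_a=3.0, noise=0.02)
        fit = ard_fit(tab, "A")
        assert abs(fit.coefficients["a"] - 3.0) < 0.3
        assert abs(fit.coefficients["q"]) < 0.05
        assert abs(fit.coefficients["p"]) < 0.05

    def test_ard_constant_response(self, rng):
        tab = _synthetic_table(rng)
        tab["B"] = 42.0
        fit = ard_fit(tab, "B")
        assert fit.intercept == pytest.approx(42.0, abs=0.01)
        for v in fit.coefficients.values():
            assert abs(v) < 0.01

    def test_ard_row_order_invariance(self, rng):
        tab = _synthetic_table(rng)
        shuffled = tab.sample(frac=1.0, random_state=3).reset_index(drop=True)
        f1, f2 = ard_fit(tab, "A"), ard_fit(shuffled, "A")
        for k in f1.coefficients:
            assert f1.coefficients[k] == pytest.approx(f2.coefficients[k],
                                                       abs=1e-8)


class TestNoiseStudy:
    def test_zero_amplitude_rows_are_identical(self, default_config):
        design = pd.DataFrame({
            "a": [0.0] * 4, "q": [0.05, 0.1, 0.2, 0.3], "p": [0, 0.5, 1, 0.25]})
        cfg = replace(default_config, t_end=2.5)
        tab = noise_study(design, radius=60.0, cells_per_radius=6, config=cfg)
        assert len(tab) == 4
        assert tab["A"].nunique() == 1 and tab["B"].nunique() == 1

    def test_factorial_design_shape_and_levels(self):
        design = factorial_noise_design(100.0)
        assert len(design) == 27
        assert design["a"].nunique() == 3
        assert design["a"].min() == 0.0
        # a_ref calibrated so the worst-case displacement is 10% of R
        from oxispheroid.geometry import GARDNER_FACTOR_BOUND
        a_ref = sorted(design["a"].unique())[1]
        assert (GARDNER_FACTOR_BOUND * a_ref) ** 3 == pytest.approx(10.0)

    def test_random_design_is_seeded(self):
        d1 = random_noise_design(100.0, 10, seed=5)
        d2 = random_noise_design(100.0, 10, seed=5)
        d3 = random_noise_design(100.0, 10, seed=6)
        pd.testing.assert_frame_equal(d1, d2)
        assert not d1.equals(d3)

    def test_consumption_makes_all_slopes_negative(self, default_config):
        design = factorial_noise_design(60.0).iloc[[0, 9, 13, 22, 26]]
        cfg = replace(default_config, t_end=2.5)
        tab = noise_study(design.reset_index(drop=True), radius=60.0,
                          cells_per_radius=6, config=cfg)
        assert np.all(tab["B"] < 0)

    def test_design_too_small(self, default_config):
        with pytest.raises(ValueError):
            noise_study(pd.DataFrame({"a": [0.0], "q": [0.1], "p": [0.0]}),
                        radius=60.0, config=default_config)
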