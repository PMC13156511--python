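"""Gaussian-process surrogate: fit, acquisition, budgeted loop, extraction."""

import dataclasses

import numpy as np
import pytest

from hipfall import (
    FallSimRecord,
    FractureResponseParams,
    SurrogateConfig,
    acquisition_objective,
    active_learning_loop,
    extract_critical_velocity,
    critical_velocity_true,
    fit_gpr,
    initial_design,
    oracle_fracture_length,
    propose_next,
)


def _records(points, fn):
    return [
        FallSimRecord(a, v, max(0.0, fn(a, v)), False, max(0.0, fn(a, v)) >= 10.0)
        for a, v in points
    ]


class TestConfig:
    def test_initial_design_default(self, surrogate_config):
        design = initial_design(surrogate_config)
        assert len(design) == 4
        for a, v in design:
            assert -90 <= a <= 90 and 0.5 <= v <= 4.5
        assert design[0] == (0.0, 0.5) and design[1] == (0.0, 4.5)

    def test_initial_design_prefix_and_determinism(self):
        cfg3 = SurrogateConfig(n_initial=3)
        cfg4 = SurrogateConfig(n_initial=4)
        assert initial_design(cfg3) == initial_design(cfg4)[:3]
        assert initial_design(cfg4) == initial_design(SurrogateConfig(n_initial=4))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SurrogateConfig(n_initial=2)  # fewer than 3 initial simulations
        with pytest.raises(ValueError):
            SurrogateConfig(n_initial=10, budget=5)
        with pytest.raises(ValueError):
            SurrogateConfig(velocity_bounds=(4.5, 0.5))
        with pytest.raises(ValueError):
            SurrogateConfig(velocity_bounds=(0.0, 4.5))


class TestFit:
    def test_linear_surface_recovered(self, surrogate_config):
        pts = [(a, v) for a in np.linspace(-90, 90, 5) for v in np.linspace(0.5, 4.5, 4)]
        model = fit_gpr(_records(pts, lambda a, v: 2 * v), surrogate_config)
        held_a = np.array([-75.0, -20.0, 10.0, 55.0, 80.0])
        held_v = np.array([0.9, 1.7, 2.6, 3.3, 4.1])
        mean, sd = model.predict(held_a, held_v)
        assert np.max(np.abs(mean - 2 * held_v)) < 0.1
        assert np.all(sd >= 0)

    def test_constant_zero_surface(self, surrogate_config):
        pts = [(a, v) for a in (-90, 0, 90) for v in (0.5, 2.5, 4.5)]
        model = fit_gpr(_records(pts, lambda a, v: 0.0), surrogate_config)
        mean, _ = model.predict(np.linspace(-80, 80, 7), np.linspace(1, 4, 7))
        assert np.max(np.abs(mean)) < 0.1

    def test_training_points_reproduced_within_noise(self, surrogate_config):
        pts = [(a, v) for a in (-60, 0, 60) for v in (1.0, 2.5, 4.0)]
        records = _records(pts, lambda a, v: 3 * v)
        model = fit_gpr(records, surrogate_config)
        noise_sd = np.sqrt(model.gp.kernel_.k2.noise_level)
        mean, _ = model.predict(
            [r.fall_angle for r in records], [r.impact_velocity for r in records]
        )
        resid = np.abs(mean - [r.fracture_length for r in records])
        assert np.all(resid <= 3 * max(noise_sd, 1e-4))

    def test_duplicate_point_well_posed(self, surrogate_config):
        records = _records([(0.0, 2.0), (0.0, 2.0), (30.0, 3.0), (-30.0, 1.0)],
                           lambda a, v: v)
        fit_gpr(records, surrogate_config)  # must not raise

    def test_too_few_or_nonfinite_rejected(self, surrogate_config):
        with pytest.raises(ValueError):
            fit_gpr(_records([(0, 1), (0, 2)], lambda a, v: v), surrogate_config)
        bad = _records([(0, 1), (0, 2), (0, 3)], lambda a, v: v)
        bad[0] = dataclasses.replace(bad[0], fracture_length=np.nan, fractured=False)
        with pytest.raises(ValueError):
            fit_gpr(bad, surrogate_config)


class _StubModel:
    """Predicts fixed (mean, sd) so the acquisition algebra is checkable."""

    def __init__(self, mean, sd):
        self._mean, self._sd = mean, sd

    def predict(self, fall_angle, impact_velocity):
        n = np.size(np.asarray(fall_angle))
        return np.full(n, self._mean), np.full(n, self._sd)


class TestAcquisition:
    def test_at_threshold_f_is_minus_sigma(self, surrogate_config):
        f = acquisition_objective(_StubModel(10.0, 2.0), 0.0, 2.0, surrogate_config)
        assert f == pytest.approx(-2.0)

    def test_zero_sigma_gives_zero(self, surrogate_config):
        assert acquisition_objective(_StubModel(10.0, 0.0), 0.0, 2.0, surrogate_config) == 0.0

    def test_one_mm_off_threshold_underflows(self, surrogate_config):
        f = acquisition_objective(_StubModel(11.0, 5.0), 0.0, 2.0, surrogate_config)
        assert abs(f) <= 5 * np.exp(-1000)

    def test_proposal_prefers_unexplored_angles(self, surrogate_config):
        """Trained only at 0 deg, the proposal moves to higher-uncertainty
        angles: sigma at the proposal is no smaller than at 0 deg."""
        pts = [(0.0, v) for v in np.linspace(0.5, 4.5, 6)]
        model = fit_gpr(_records(pts, lambda a, v: 10 * max(0.0, v - 1.8)), surrogate_config)
        a, v = propose_next(model, surrogate_config)
        assert abs(a) > 0
        _, sd_prop = model.predict([a], [v])
        _, sd_zero = model.predict([0.0], [v])
        assert sd_prop[0] >= sd_zero[0]

    def test_proposal_strictly_inside_bounds(self, surrogate_config, ramp_params):
        model, _ = active_learning_loop(
            oracle_fracture_length, ramp_params,
            dataclasses.replace(surrogate_config, budget=6), False,
        )
        for _ in range(3):
            a, v = propose_next(model, surrogate_config)
            assert -90 < a < 90
            assert 0.5 < v < 4.5

    def test_degenerate_sigma_falls_back_to_first_grid_point(self, surrogate_config):
        a, v = propose_next(_StubModel(0.0, 0.0), surrogate_config)
        assert a == pytest.approx(-90.0, abs=1e-3)
        assert v == pytest.approx(0.5, abs=1e-4)

    def test_proposals_track_the_limit_state(self, surrogate_config):
        """On a velocity-only ramp the acquired configurations concentrate
        near the 10-mm level set: median |FxL - 10| below 1 mm."""
        flat = FractureResponseParams(v_c0=1.5, angle_curvature=0.0, slope=10.0,
                                      protector_shift=0.3)
        cfg = dataclasses.replace(surrogate_config, budget=14)
        _, records = active_learning_loop(oracle_fracture_length, flat, cfg, False)
        acquired = records[cfg.n_initial:]
        med = np.median([abs(r.fracture_length - 10.0) for r in acquired])
        assert med < 1.0


class TestLoop:
    def test_budget_conserved_exactly(self, ramp_params):
        calls = 0

        def counting_oracle(params, a, v, protector=False, rng=None):
            nonlocal calls
            calls += 1
            return oracle_fracture_length(params, a, v, protector=protector, rng=rng)

        cfg = SurrogateConfig(budget=9, seed=1)
        _, records = active_learning_loop(counting_oracle, ramp_params, cfg, False)
        assert calls == 9 and len(records) == 9

    def test_budget_equal_initial_fits_once(self, ramp_params):
        cfg = SurrogateConfig(budget=4, n_initial=4, seed=1)
        model, records = active_learning_loop(oracle_fracture_length, ramp_params, cfg, False)
        assert len(records) == 4
        assert [(r.fall_angle, r.impact_velocity) for r in records] == initial_design(cfg)

    def test_same_seed_identical_trace(self, ramp_params):
        cfg = SurrogateConfig(budget=8, seed=7)
        _, rec_a = active_learning_loop(oracle_fracture_length, ramp_params, cfg, False)
        _, rec_b = active_learning_loop(oracle_fracture_length, ramp_params, cfg, False)
        assert rec_a == rec_b


class TestExtraction:
    def test_ramp_root(self, surrogate_config):
        """Exact 10*(v - 1.5) surrogate has its critical velocity at 2.5 m/s."""
        pts = [(a, v) for a in np.linspace(-90, 90, 5) for v in (1.5, 2.0, 3.0, 4.0, 4.5)]
        model = fit_gpr(_records(pts, lambda a, v: 10 * (v - 1.5)), surrogate_config)
        curve = extract_critical_velocity(model, surrogate_config, np.array([0.0]))
        assert curve.v_crit[0] == pytest.approx(2.5, abs=1e-3)

    def test_never_reaching_threshold_gives_inf(self, surrogate_config, degree_grid):
        pts = [(a, v) for a in (-90, 0, 90) for v in (0.5, 2.5, 4.5)]
        model = fit_gpr(_records(pts, lambda a, v: 1.0), surrogate_config)
        curve = extract_critical_velocity(model, surrogate_config, degree_grid)
        assert np.all(np.isinf(curve.v_crit))

    def test_above_threshold_everywhere_gives_lower_bound(self, surrogate_config):
        pts = [(a, v) for a in (-90, 0, 90) for v in (0.5, 2.5, 4.5)]
        model = fit_gpr(_records(pts, lambda a, v: 20.0), surrogate_config)
        curve = extract_critical_velocity(model, surrogate_config, np.array([-45.0, 45.0]))
        assert np.all(curve.v_crit == 0.5)

    def test_quadratic_oracle_curve_rmse(self, ramp_params, surrogate_config, degree_grid):
        """Full 20-budget loop recovers the analytic curve to < 0.15 m/s RMSE."""
        model, _ = active_learning_loop(
            oracle_fracture_length, ramp_params, surrogate_config, False
        )
        curve = extract_critical_velocity(model, surrogate_config, degree_grid)
        truth = critical_velocity_true(ramp_params, degree_grid)
        v_hat = np.where(np.isinf(curve.v_crit), 4.5, curve.v_crit)
        rmse = np.sqrt(np.mean((v_hat - truth) ** 2))
        assert rmse < 0.15

    def test_curve_monotone_in_oracle_strength(self, surrogate_config, degree_grid):
        """A tougher femur (larger onset velocity) yields a pointwise-not-lower
        extracted curve, within surrogate tolerance."""
        curves = {}
        for v_c0 in (1.5, 1.9):
            params = FractureResponseParams(
                v_c0=v_c0, angle_curvature=0.6, slope=10.0, protector_shift=0.5
            )
            model, _ = active_learning_loop(
                oracle_fracture_length, params, surrogate_config, False
            )
            curves[v_c0] = extract_critical_velocity(model, surrogate_config, degree_grid)
        weak = np.where(np.isinf(curves[1.5].v_crit), 4.5, curves[1.5].v_crit)
        strong = np.where(np.isinf(curves[1.9].v_crit), 4.5, curves[1.9].v_crit)
        assert np.all(strong >= weak - 0.05)

    def test_curve_csv_roundtrip_with_inf(self, tmp_path, degree_grid):
        from hipfall import CriticalVelocityCurve

        v = np.full(degree_grid.size, 2.0)
        v[:30] = np.inf
        curve = CriticalVelocityCurve(degree_grid, v, protector=True)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        assert "inf" in path.read_text()
        back = CriticalVelocityCurve.from_csv(path)
        assert np.array_equal(back.v_crit, curve.v_crit)
        assert back.protector is True
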