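"""Integrator correctness: uptake kinetics, Bernoulli forcings, carbon
conservation, and agreement with independent ODE solutions in the
deterministic limit."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from omaccum import (
    ModelConfig,
    ParameterRanges,
    SimulationState,
    ValidationError,
    build_specialist_matrix,
    draw_forcings,
    run_simulation,
    sample_parameters,
    step,
    subsistence_concentration,
    uptake_rate,
)
from omaccum.parameters import ParameterSet


def _deterministic_config(n, **kw):
    """Specialist config with P = q = 1 (no stochasticity)."""
    ranges = kw.pop("ranges", {})
    kw.setdefault("matrix_mode", "specialist")
    return ModelConfig(
        n_pools=n,
        n_populations=n,
        parameter_ranges=ParameterRanges(
            presence=(1.0, 1.0), supply_probability=(1.0, 1.0), **ranges
        ),
        **kw,
    )


class TestUptakeRate:
    def test_half_saturation_identity(self):
        assert uptake_rate(0.1, 2.0, 0.1) == pytest.approx(1.0)

    def test_zero_concentration(self):
        assert uptake_rate(0.0, 5.0, 0.3) == 0.0

    def test_direct_evaluation(self):
        assert uptake_rate(0.9, 10.0, 0.1) == pytest.approx(9.0)

    def test_monotone_and_bounded(self):
        c = np.linspace(0, 100, 500)
        r = uptake_rate(c, 3.0, 0.5)
        assert np.all(np.diff(r) > 0)
        assert r.max() < 3.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            uptake_rate(-1.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            uptake_rate(1.0, 1.0, 0.0)


class TestForcings:
    def test_certain_supply_and_absent_population(self, small_specialist, rng):
        _, matrix, params = small_specialist
        sure = ParameterSet(
            supply_potential=params.supply_potential,
            supply_probability=np.ones(5),
            rho_max=params.rho_max,
            k=params.k,
            yield_=params.yield_,
            presence=np.zeros(5),
            mortality_quadratic=params.mortality_quadratic,
            mortality_linear=params.mortality_linear,
        )
        for _ in range(20):
            s, I = draw_forcings(sure, rng)
            assert np.array_equal(s, sure.supply_potential)
            assert np.all(I == 0)

    def test_supply_frequency_matches_probability(self, small_specialist):
        """q = 0.3 over many steps: empirical supply frequency within the
        binomial confidence band."""
        _, matrix, params = small_specialist
        p = ParameterSet(
            supply_potential=params.supply_potential,
            supply_probability=np.full(5, 0.3),
            rho_max=params.rho_max,
            k=params.k,
            yield_=params.yield_,
            presence=params.presence,
            mortality_quadratic=params.mortality_quadratic,
            mortality_linear=params.mortality_linear,
        )
        rng = np.random.default_rng(2)
        n_steps = 20_000
        hits = sum((draw_forcings(p, rng)[0] > 0).sum() for _ in range(n_steps))
        freq = hits / (n_steps * 5)
        sigma = np.sqrt(0.3 * 0.7 / (n_steps * 5))
        assert abs(freq - 0.3) < 4 * sigma


class TestStep:
    def test_pure_accumulation_without_consumers(self):
        """All consumers absent and q = 1: C grows by sigma * dt exactly."""
        config = _deterministic_config(3, total_supply=0.03, t_end=1.0)
        matrix = build_specialist_matrix(3)
        params = sample_parameters(config, matrix, np.random.default_rng(0))
        absent = ParameterSet(
            **{
                **{f: getattr(params, f) for f in params.__dataclass_fields__},
                "presence": np.zeros(3),
            }
        )
        state = SimulationState(0.0, np.zeros(3), np.full(3, 1e-3))
        rng = np.random.default_rng(1)
        for _ in range(100):
            state = step(state, absent, matrix, 0.01, rng)
        assert np.allclose(state.C, 0.01 * 1.0, rtol=1e-12)

    def test_zero_biomass_is_absorbing_for_consumption(self):
        config = _deterministic_config(2, total_supply=0.02, t_end=1.0)
        matrix = build_specialist_matrix(2)
        params = sample_parameters(config, matrix, np.random.default_rng(0))
        state = SimulationState(0.0, np.zeros(2), np.zeros(2))
        rng = np.random.default_rng(1)
        for _ in range(50):
            state = step(state, params, matrix, 0.01, rng)
        assert np.all(state.B == 0)
        assert np.allclose(state.C, 0.01 * 0.5, rtol=1e-12)

    def test_python_step_matches_kernel_in_deterministic_limit(self):
        """The readable vectorised step and the compiled kernel produce the
        same trajectory when P = q = 1."""
        config = _deterministic_config(4, total_supply=4e-3, t_end=5.0, dt=0.05, seed=3)
        traj = run_simulation(config)
        state = SimulationState(0.0, traj.C[0].copy(), traj.B[0].copy())
        rng = np.random.default_rng(0)
        for _ in range(config.n_steps):
            state = step(state, traj.params, traj.matrix, config.dt, rng)
        assert np.allclose(state.C, traj.C_final, rtol=1e-10)
        assert np.allclose(state.B, traj.B_final, rtol=1e-10)


class TestRunSimulation:
    def test_zero_horizon_keeps_initial_state(self):
        config = _deterministic_config(3, total_supply=0.3, t_end=0.0)
        traj = run_simulation(config)
        assert traj.times.size == 1
        assert np.all(traj.C[0] == 0.0)
        assert np.all(traj.B[0] == 1e-3)

    def test_deterministic_limit_matches_adaptive_ode_oracle(self):
        """With P = q = 1 the Euler path agrees with a high-accuracy
        adaptive integration of the same right-hand side."""
        config = _deterministic_config(
            3, total_supply=0.3, t_end=200.0, dt=0.005, seed=12
        )
        traj = run_simulation(config)
        params, matrix = traj.params, traj.matrix

        def rhs(t, x):
            C, B = x[:3], x[3:]
            C = np.maximum(C, 0.0)
            rho = params.rho_max * C / (C + params.k)
            dC = params.supply_potential - rho * B
            dB = params.yield_ * rho * B - (
                params.mortality_quadratic * B + params.mortality_linear
            ) * B
            return np.concatenate([dC, dB])

        x0 = np.concatenate([np.zeros(3), np.full(3, 1e-3)])
        sol = solve_ivp(rhs, (0, 200.0), x0, method="LSODA", rtol=1e-10, atol=1e-12)
        assert np.allclose(traj.C_final, sol.y[:3, -1], rtol=0.01)
        assert np.allclose(traj.B_final, sol.y[3:, -1], rtol=0.01)

    def test_single_specialist_converges_to_subsistence_concentration(self):
        """A viable specialist (Q > 1) depletes its pool to the closed-form
        C* computed from the realised steady-state loss rate."""
        config = _deterministic_config(
            1,
            total_supply=1e-3,
            t_end=2000.0,
            dt=0.01,
            seed=4,
            ranges=dict(
                rho_max=(5.0, 5.0),
                affinity=(10.0, 10.0),
                yield_=(0.4, 0.4),
                mortality_quadratic=(0.5, 0.5),
                mortality_linear=(0.005, 0.005),
            ),
        )
        traj = run_simulation(config)
        L = traj.loss_rate_bar()[0]
        c_star = subsistence_concentration(
            traj.params.k[0], 1.0, 0.4, 5.0, L
        )
        assert np.isfinite(c_star)
        assert traj.C_final[0] == pytest.approx(c_star, rel=0.01)

    def test_final_concentration_bounded_by_potential_supply(self):
        """No pool can exceed its cumulative potential supply."""
        config = ModelConfig(
            n_pools=100, n_populations=100, total_supply=0.01, t_end=365.0, dt=0.02, seed=9
        )
        traj = run_simulation(config)
        bound = traj.params.supply_potential * 365.0 + 1e-12
        assert np.all(traj.C_final <= bound)
        assert np.all(traj.cumulative_supply <= bound)

    def test_carbon_budget_closes(self):
        config = ModelConfig(
            n_pools=50, n_populations=50, total_supply=5e-3, t_end=365.0, dt=0.01, seed=5
        )
        traj = run_simulation(config)
        assert traj.budget_residual < 1e-3
        # explicit four-term identity
        supplied = traj.cumulative_supply.sum() + traj.initial_C_total + traj.initial_B_total
        out = (
            traj.C_final.sum()
            + traj.B_final.sum()
            + traj.cumulative_respired
            + traj.cumulative_mortality
        )
        assert supplied == pytest.approx(out, rel=1e-9)

    def test_bit_identical_reruns_under_fixed_seed(self):
        config = ModelConfig(
            n_pools=30, n_populations=60, matrix_mode="mixed", total_supply=3e-3,
            t_end=50.0, dt=0.01, seed=77,
        )
        a = run_simulation(config)
        b = run_simulation(config)
        assert np.array_equal(a.C, b.C)
        assert np.array_equal(a.B, b.B)
        assert a.cumulative_respired == b.cumulative_respired

    def test_total_carbon_monotone_in_total_supply(self):
        """Raising sigma_T with the same seed never decreases final total
        organic-matter carbon."""
        totals = []
        for sigma_t in (0.002, 0.004, 0.008):
            config = ModelConfig(
                n_pools=20, n_populations=20, total_supply=sigma_t,
                t_end=365.0, dt=0.01, seed=13,
            )
            totals.append(run_simulation(config).C_final.sum())
        assert totals[0] < totals[1] < totals[2]

    def test_non_negativity(self):
        config = ModelConfig(
            n_pools=40, n_populations=80, matrix_mode="mixed", total_supply=4e-3,
            t_end=100.0, dt=0.05, seed=21,
        )
        traj = run_simulation(config)
        assert traj.C.min() >= 0
        assert traj.B.min() >= 0
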