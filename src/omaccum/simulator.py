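"""Forward integration of the stochastic consumption model.

State variables are the pool concentrations ``C_i`` and population biomasses
``B_j`` (both uM C).  Each forward-Euler step of length ``dt`` days:

1. draws the Bernoulli forcings: pool ``i`` receives supply ``sigma_i`` with
   probability ``q_i``, population ``j`` is present (``I_j = 1``) with
   probability ``P_j``;
2. computes Michaelis--Menten uptake ``rho_ij = rho_max_ij C_i/(C_i+k_ij)``
   for every present consumer and scales all consumers of a pool down
   proportionally if their combined demand would overdraw the pool;
3. updates ``C_i`` with supply minus consumption, and ``B_j`` with biomass
   synthesis ``y_ij rho_ij B_j`` minus quadratic-plus-linear mortality
   ``(m_q B_j + m_l) B_j``.  An absent population neither consumes nor
   grows but still loses biomass.

The integrator tracks a full carbon budget (supply, consumption,
respiration ``(1-y) * uptake``, mortality) and trailing-window averages of
biomass, loss rate, concentration, consumption flux, and the per-interaction
Michaelis--Menten uptake rate, which the diagnostics layer needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .config import ModelConfig
from .consumption_matrix import ConsumptionMatrix, build_matrix
from .errors import NumericalError, ValidationError
from .parameters import ParameterSet, sample_parameters

__all__ = [
    "SimulationState",
    "Trajectory",
    "uptake_rate",
    "draw_forcings",
    "step",
    "run_simulation",
    "split_seed",
]


def split_seed(seed: int) -> tuple[np.random.Generator, np.random.Generator, int]:
    """Split a root seed into the three independent consumers of randomness.

    Returns ``(matrix_rng, parameter_rng, forcing_seed)``.  Hierarchical
    splitting means that e.g. changing the snapshot cadence can never
    perturb the parameter draws.
    """
    ss = np.random.SeedSequence(seed)
    matrix_ss, param_ss, forcing_ss = ss.spawn(3)
    forcing_seed = int(forcing_ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
    return (
        np.random.default_rng(matrix_ss),
        np.random.default_rng(param_ss),
        forcing_seed,
    )


@dataclass
class SimulationState:
    """Instantaneous model state: time (d), concentrations and biomasses (uM C)."""

    t: float
    C: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if (self.C < 0).any() or (self.B < 0).any():
            raise ValidationError("state variables must be non-negative")


@dataclass
class Trajectory:
    """Recorded output of one integration.

    ``times`` holds the snapshot times (days); ``C`` and ``B`` the matching
    state snapshots.  Cumulative budget terms cover the whole run; the
    ``*_bar`` fields are averages over the trailing analysis window
    (by default the final 10% of the run) used by the diagnostics layer.
    """

    times: np.ndarray
    C: np.ndarray  # (n_snapshots, n_pools)
    B: np.ndarray  # (n_snapshots, n_populations)
    cumulative_supply: np.ndarray  # per pool, uM
    cumulative_consumed: np.ndarray  # per pool, uM
    cumulative_respired: float
    cumulative_mortality: float
    rho_bar: np.ndarray  # per edge, 1/d (Michaelis-Menten rate at ambient C)
    B_bar: np.ndarray  # per population, uM
    C_bar: np.ndarray  # per pool, uM
    consumption_rate: np.ndarray  # per pool, uM/d, window average
    window: tuple[float, float]
    config: Optional[ModelConfig] = None
    seed: Optional[int] = None
    initial_C_total: float = 0.0
    initial_B_total: float = 0.0
    matrix: Optional[ConsumptionMatrix] = None
    params: Optional[ParameterSet] = None

    @property
    def C_final(self) -> np.ndarray:
        return self.C[-1]

    @property
    def B_final(self) -> np.ndarray:
        return self.B[-1]

    def loss_rate_bar(self, params: Optional[ParameterSet] = None) -> np.ndarray:
        """Window-averaged population loss rates ``L_j = m_q B_j + m_l`` (1/d)."""
        p = params if params is not None else self.params
        if p is None:
            raise ValidationError("parameter set required to evaluate loss rates")
        return p.mortality_quadratic * self.B_bar + p.mortality_linear

    @property
    def budget_residual(self) -> float:
        """Relative carbon-budget closure error for the whole run.

        supply + initial stocks = final stocks + respiration + mortality,
        all in uM C.
        """
        supplied = float(self.cumulative_supply.sum())
        inputs = supplied + self.initial_C_total + self.initial_B_total
        outputs = (
            float(self.C_final.sum())
            + float(self.B_final.sum())
            + self.cumulative_respired
            + self.cumulative_mortality
        )
        scale = max(inputs, 1e-30)
        return abs(inputs - outputs) / scale


def uptake_rate(C: float, rho_max: float, k: float):
    """Michaelis--Menten specific uptake rate ``rho_max * C / (C + k)`` (1/d).

    Accepts scalars or broadcastable arrays.  Monotone increasing in ``C``
    and bounded above by ``rho_max``.
    """
    C = np.asarray(C, dtype=float)
    rho_max = np.asarray(rho_max, dtype=float)
    k = np.asarray(k, dtype=float)
    if (C < 0).any() or (rho_max < 0).any() or (k <= 0).any():
        raise ValidationError("uptake_rate requires C >= 0, rho_max >= 0, k > 0")
    out = rho_max * C / (C + k)
    return float(out) if out.ndim == 0 else out


def draw_forcings(
    params: ParameterSet, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one time step of Bernoulli forcings.

    Returns ``(s, I)``: the realised supply vector (``sigma_i`` or 0 per
    pool) and the 0/1 presence indicator per population.
    """
    s = np.where(
        rng.random(params.n_pools) < params.supply_probability,
        params.supply_potential,
        0.0,
    )
    I = (rng.random(params.n_populations) < params.presence).astype(np.float64)
    return s, I


def _apply_step(
    C: np.ndarray,
    B: np.ndarray,
    s: np.ndarray,
    I: np.ndarray,
    params: ParameterSet,
    matrix: ConsumptionMatrix,
    dt: float,
    rate_multiplier: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One explicit update with given forcings (vectorised reference path)."""
    ep, ej = matrix.pool_index, matrix.population_index
    rho = rate_multiplier * params.rho_max * C[ep] / (C[ep] + params.k)
    demand_e = I[ej] * rho * B[ej] * dt  # uM consumed per edge this step
    demand = np.zeros(matrix.n_pools)
    np.add.at(demand, ep, demand_e)
    avail = C + s * dt
    scale = np.ones(matrix.n_pools)
    over = demand > avail
    scale[over] = avail[over] / demand[over]
    taken_e = demand_e * scale[ep]
    consumed = np.zeros(matrix.n_pools)
    np.add.at(consumed, ep, taken_e)
    growth = np.zeros(matrix.n_populations)
    np.add.at(growth, ej, params.yield_ * taken_e)
    loss = (params.mortality_quadratic * B + params.mortality_linear) * B * dt
    loss = np.minimum(loss, B + growth)
    C_new = np.maximum(C + s * dt - consumed, 0.0)
    B_new = B + growth - loss
    return C_new, B_new


def step(
    state: SimulationState,
    params: ParameterSet,
    matrix: ConsumptionMatrix,
    dt: float,
    rng: np.random.Generator,
) -> SimulationState:
    """Advance the state by one stochastic Euler step.

    Forcings are drawn from ``rng``; the update preserves non-negativity by
    proportionally down-scaling all consumers of a pool whose combined
    demand would exceed the available stock.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    params.validate_against(matrix)
    if not (np.isfinite(state.C).all() and np.isfinite(state.B).all()):
        bad = int(np.flatnonzero(~np.isfinite(np.concatenate([state.C, state.B])))[0])
        raise NumericalError(f"non-finite state entry at flat index {bad}")
    s, I = draw_forcings(params, rng)
    C_new, B_new = _apply_step(state.C, state.B, s, I, params, matrix, dt)
    return SimulationState(state.t + dt, C_new, B_new)


@njit
def _integrate_kernel(
    C0,
    B0,
    edge_pool,
    edge_pop,
    rho_max,
    half_sat,
    yld,
    sigma,
    q,
    presence,
    mq,
    ml,
    dt,
    n_steps,
    seed,
    snap_steps,
    window_start,
    rate_mult,
):
    np.random.seed(seed)
    n = C0.size
    m = B0.size
    ne = edge_pool.size
    C = C0.copy()
    B = B0.copy()

    n_snap = snap_steps.size
    snap_C = np.zeros((n_snap, n))
    snap_B = np.zeros((n_snap, m))
    snap_ptr = 0

    cum_supply = np.zeros(n)
    cum_consumed = np.zeros(n)
    cum_resp = 0.0
    cum_mort = 0.0

    rho_win = np.zeros(ne)
    B_win = np.zeros(m)
    C_win = np.zeros(n)
    cons_win = np.zeros(n)
    win_count = 0

    s = np.zeros(n)
    I = np.zeros(m)
    demand = np.zeros(n)
    consumed = np.zeros(n)
    growth = np.zeros(m)
    upt = np.zeros(ne)

    err_step = -1

    if snap_ptr < n_snap and snap_steps[snap_ptr] == 0:
        for i in range(n):
            snap_C[snap_ptr, i] = C[i]
        for j in range(m):
            snap_B[snap_ptr, j] = B[j]
        snap_ptr += 1

    for it in range(n_steps):
        in_window = it >= window_start

        # Bernoulli forcings
        for i in range(n):
            if np.random.random() < q[i]:
                s[i] = sigma[i]
            else:
                s[i] = 0.0
            demand[i] = 0.0
            consumed[i] = 0.0
        for j in range(m):
            if np.random.random() < presence[j]:
                I[j] = 1.0
            else:
                I[j] = 0.0
            growth[j] = 0.0

        # uptake demand
        for e in range(ne):
            i = edge_pool[e]
            j = edge_pop[e]
            rho = rate_mult * rho_max[e] * C[i] / (C[i] + half_sat[e])
            if in_window:
                rho_win[e] += rho
            u = I[j] * rho * B[j] * dt
            upt[e] = u
            demand[i] += u

        # proportional limiter: a pool cannot be overdrawn within the step
        for i in range(n):
            avail = C[i] + s[i] * dt
            if demand[i] > avail:
                demand[i] = avail / demand[i]  # reuse as scale factor
            else:
                demand[i] = 1.0

        for e in range(ne):
            i = edge_pool[e]
            j = edge_pop[e]
            u = upt[e] * demand[i]
            consumed[i] += u
            growth[j] += yld[e] * u
            cum_resp += (1.0 - yld[e]) * u

        for i in range(n):
            if in_window:
                C_win[i] += C[i]
                cons_win[i] += consumed[i]
            cum_supply[i] += s[i] * dt
            cum_consumed[i] += consumed[i]
            Ci = C[i] + s[i] * dt - consumed[i]
            if Ci < 0.0:
                Ci = 0.0
            C[i] = Ci

        for j in range(m):
            if in_window:
                B_win[j] += B[j]
            loss = (mq[j] * B[j] + ml[j]) * B[j] * dt
            cap = B[j] + growth[j]
            if loss > cap:
                loss = cap
            cum_mort += loss
            B[j] = cap - loss

        if in_window:
            win_count += 1

        if snap_ptr < n_snap and snap_steps[snap_ptr] == it + 1:
            ok = True
            for i in range(n):
                snap_C[snap_ptr, i] = C[i]
                if not np.isfinite(C[i]):
                    ok = False
            for j in range(m):
                snap_B[snap_ptr, j] = B[j]
                if not np.isfinite(B[j]):
                    ok = False
            snap_ptr += 1
            if not ok:
                err_step = it + 1
                break

    if win_count > 0:
        inv = 1.0 / win_count
        for e in range(ne):
            rho_win[e] *= inv
        for j in range(m):
            B_win[j] *= inv
        for i in range(n):
            C_win[i] *= inv
            cons_win[i] *= inv / dt  # uM per step -> uM/d

    return (
        snap_C,
        snap_B,
        cum_supply,
        cum_consumed,
        cum_resp,
        cum_mort,
        rho_win,
        B_win,
        C_win,
        cons_win,
        win_count,
        err_step,
    )


def run_simulation(
    config: ModelConfig,
    params: Optional[ParameterSet] = None,
    matrix: Optional[ConsumptionMatrix] = None,
    forcing_seed: Optional[int] = None,
) -> Trajectory:
    """Integrate the model from ``t = 0`` to ``config.t_end``.

    If ``params``/``matrix`` are omitted they are built and sampled from
    streams split off ``config.seed``, so a configuration alone fully
    determines the run.  Snapshots are recorded every
    ``config.snapshot_interval`` days (plus the initial and final states).
    """
    matrix_rng, param_rng, default_forcing_seed = split_seed(config.seed)
    if matrix is None:
        matrix = build_matrix(config, matrix_rng)
    if params is None:
        params = sample_parameters(config, matrix, param_rng)
    params.validate_against(matrix)
    if forcing_seed is None:
        forcing_seed = default_forcing_seed

    n_steps = config.n_steps
    snap_every = max(1, int(round(config.snapshot_interval / config.dt)))
    snap_steps = list(range(0, n_steps + 1, snap_every))
    if snap_steps[-1] != n_steps:
        snap_steps.append(n_steps)
    snap_steps_arr = np.asarray(snap_steps, dtype=np.int64)
    window_start = int(np.ceil((1.0 - config.window_fraction) * n_steps))

    C0 = np.full(config.n_pools, config.initial_concentration, dtype=float)
    B0 = np.full(config.n_populations, config.initial_biomass, dtype=float)

    (
        snap_C,
        snap_B,
        cum_supply,
        cum_consumed,
        cum_resp,
        cum_mort,
        rho_win,
        B_win,
        C_win,
        cons_win,
        win_count,
        err_step,
    ) = _integrate_kernel(
        C0,
        B0,
        matrix.pool_index,
        matrix.population_index,
        params.rho_max,
        params.k,
        params.yield_,
        params.supply_potential,
        params.supply_probability,
        params.presence,
        params.mortality_quadratic,
        params.mortality_linear,
        float(config.dt),
        n_steps,
        int(forcing_seed),
        snap_steps_arr,
        window_start,
        float(config.rate_multiplier),
    )
    if err_step >= 0:
        raise NumericalError(
            f"non-finite state detected at step {err_step} (t = {err_step * config.dt:.3f} d)"
        )
    if win_count == 0:
        # degenerate horizon: fall back to the initial state
        rho_win = uptake_rate(C0[matrix.pool_index], params.rho_max, params.k) * config.rate_multiplier
        B_win = B0.copy()
        C_win = C0.copy()
        cons_win = np.zeros(config.n_pools)

    return Trajectory(
        times=snap_steps_arr * config.dt,
        C=snap_C,
        B=snap_B,
        cumulative_supply=cum_supply,
        cumulative_consumed=cum_consumed,
        cumulative_respired=float(cum_resp),
        cumulative_mortality=float(cum_mort),
        rho_bar=rho_win,
        B_bar=B_win,
        C_bar=C_win,
        consumption_rate=cons_win,
        window=(window_start * config.dt, config.t_end),
        config=config,
        seed=config.seed,
        initial_C_total=float(C0.sum()),
        initial_B_total=float(B0.sum()),
        matrix=matrix,
        params=params,
    )
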