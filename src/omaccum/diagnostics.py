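"""Closed-form recalcitrance theory and pool classification.

For a specialist population subsisting on a single pool, setting biomass
growth equal to loss at steady state gives the subsistence concentration

    C* = k / (P y rho_max / L - 1),

the minimum concentration to which that population can deplete its resource
(the R* of resource-competition theory).  C* is finite and positive only
when the maximum local biomass-synthesis rate ``P y rho_max`` exceeds the
loss rate ``L``; otherwise the pool cannot sustain the population and
accumulates.

The recalcitrance indicator generalises this threshold to populations that
consume several pools.  For pool ``i`` with consumers ``j``:

    Q_i = max_j  P_j rho_max_ij / L_j * ( y_ij + sum_{k != i} y_kj rho_kj / rho_max_ij )

where ``rho_kj`` is the realised (time-averaged) uptake rate of the other
pools ``k``.  The ``rho_max_ij`` in front takes an accumulating pool to be
saturating (``C_i >> k_ij``), which makes the specialist case reduce
exactly to ``Q = P y rho_max / L``.  ``Q_i > 1`` means at least one
consumer could deplete pool ``i`` to a finite subsistence concentration
("functionally labile"); ``Q_i <= 1`` means every consumer's losses match
or exceed its maximum synthesis, so the pool accumulates ("functionally
recalcitrant").  Subsidised growth on other pools raises Q — the priming
effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consumption_matrix import ConsumptionMatrix
from .errors import ValidationError
from .parameters import ParameterSet
from .simulator import Trajectory

__all__ = [
    "subsistence_concentration",
    "recalcitrance_indicator",
    "recalcitrance_indicators",
    "interaction_indicators",
    "classify_pools",
    "turnover_time",
]

#: minimum number of integration steps the trailing window must contain
MIN_WINDOW_STEPS = 10


def subsistence_concentration(k, presence, yield_, rho_max, loss_rate):
    """Subsistence concentration ``C* = k / (P y rho_max / L - 1)`` in uM.

    Returns ``inf`` where the population cannot establish
    (``P y rho_max <= L``).  Scalar or elementwise on arrays.

    Raises
    ------
    ValidationError
        If any ``loss_rate`` is not strictly positive (the steady-state
        balance is undefined without losses), any ``k`` is not positive,
        or other inputs are negative.
    """
    k = np.asarray(k, dtype=float)
    P = np.asarray(presence, dtype=float)
    y = np.asarray(yield_, dtype=float)
    rho = np.asarray(rho_max, dtype=float)
    L = np.asarray(loss_rate, dtype=float)
    if (L <= 0).any():
        raise ValidationError("loss rate must be strictly positive")
    if (k <= 0).any():
        raise ValidationError("half-saturation k must be strictly positive")
    if (P < 0).any() or (y < 0).any() or (rho < 0).any():
        raise ValidationError("inputs must be non-negative")
    denom = P * y * rho / L - 1.0
    with np.errstate(divide="ignore"):
        out = np.where(denom > 0, k / np.where(denom > 0, denom, 1.0), np.inf)
    return float(out) if out.ndim == 0 else out


def _edge_terms(
    params: ParameterSet,
    matrix: ConsumptionMatrix,
    rho_bar: np.ndarray,
    loss_bar: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge recalcitrance indicator Q_ij and subsistence concentration C*_ij.

    ``rho_bar`` is the per-edge time-averaged realised uptake rate (1/d);
    ``loss_bar`` the per-population time-averaged loss rate (1/d).
    """
    params.validate_against(matrix)
    rho_bar = np.asarray(rho_bar, dtype=float)
    loss_bar = np.asarray(loss_bar, dtype=float)
    if rho_bar.shape != (matrix.n_edges,):
        raise ValidationError("rho_bar must have one entry per interaction")
    if loss_bar.shape != (matrix.n_populations,):
        raise ValidationError("loss_bar must have one entry per population")
    ej = matrix.population_index
    consumer_pops = np.unique(ej)
    if (loss_bar[consumer_pops] <= 0).any():
        raise ValidationError("loss rates of consuming populations must be > 0")

    # per-population total realised synthesis rate  sum_k y_kj rho_bar_kj
    synth = np.zeros(matrix.n_populations)
    np.add.at(synth, ej, params.yield_ * rho_bar)
    subsidy = synth[ej] - params.yield_ * rho_bar  # exclude the focal pool

    P = params.presence[ej]
    L = loss_bar[ej]
    q_edge = P * (params.yield_ * params.rho_max + subsidy) / L

    # generalised subsistence concentration: solve
    #   P ( y rho_max C/(C+k) + subsidy ) = L   for C
    with np.errstate(divide="ignore", invalid="ignore"):
        deficit = np.where(P > 0, L / np.where(P > 0, P, 1.0), np.inf) - subsidy
    own_max = params.yield_ * params.rho_max
    c_edge = np.full(matrix.n_edges, np.inf)
    feasible = deficit < own_max
    zero = deficit <= 0
    c_edge[feasible & ~zero] = (
        params.k[feasible & ~zero]
        * deficit[feasible & ~zero]
        / (own_max[feasible & ~zero] - deficit[feasible & ~zero])
    )
    c_edge[zero] = 0.0
    return q_edge, c_edge


def _reduce_to_pools(
    matrix: ConsumptionMatrix,
    q_edge: np.ndarray,
    c_edge: np.ndarray,
    established_edge: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool-level Q (max over consumers) and C* (min over consumers).

    The subsistence concentration is a steady-state quantity, so when an
    ``established_edge`` mask is given the C* reduction only considers
    consumers that have actually built up biomass; the loss rates of
    still-transient populations are not representative of any steady
    state.  Pools whose consumers are all transient fall back to the
    unrestricted minimum.  Orphan pools (no consumers) get the sentinels
    ``Q = 0`` and ``C* = inf``: they accumulate unconditionally.
    """
    q_pool = np.zeros(matrix.n_pools)
    np.maximum.at(q_pool, matrix.pool_index, q_edge)
    c_pool_all = np.full(matrix.n_pools, np.inf)
    np.minimum.at(c_pool_all, matrix.pool_index, c_edge)
    if established_edge is not None and established_edge.any():
        c_pool = np.full(matrix.n_pools, np.inf)
        np.minimum.at(
            c_pool, matrix.pool_index[established_edge], c_edge[established_edge]
        )
        covered = np.zeros(matrix.n_pools, dtype=bool)
        covered[matrix.pool_index[established_edge]] = True
        c_pool[~covered] = c_pool_all[~covered]
    else:
        c_pool = c_pool_all
    orphan = matrix.ncons == 0
    q_pool[orphan] = 0.0
    c_pool[orphan] = np.inf
    return q_pool, c_pool


def recalcitrance_indicators(
    params: ParameterSet,
    matrix: ConsumptionMatrix,
    rho_bar: np.ndarray,
    loss_bar: np.ndarray,
) -> np.ndarray:
    """Recalcitrance indicator Q for every pool (vectorised)."""
    q_edge, _ = _edge_terms(params, matrix, rho_bar, loss_bar)
    q_pool, _ = _reduce_to_pools(matrix, q_edge, np.zeros_like(q_edge))
    return q_pool


def recalcitrance_indicator(
    pool: int,
    params: ParameterSet,
    matrix: ConsumptionMatrix,
    rho_bar: np.ndarray,
    loss_bar: np.ndarray,
) -> float:
    """Recalcitrance indicator Q_i of a single pool.

    ``Q_i`` is the maximum over the pool's consumers of
    ``P_j/L_j * (y_ij rho_max_ij + sum_k y_kj rho_bar_kj)``; an orphan pool
    returns the sentinel 0 (it accumulates unconditionally).
    """
    if not 0 <= pool < matrix.n_pools:
        raise ValidationError(f"pool index {pool} out of range")
    return float(recalcitrance_indicators(params, matrix, rho_bar, loss_bar)[pool])


def interaction_indicators(
    params: ParameterSet,
    matrix: ConsumptionMatrix,
    rho_bar: np.ndarray,
    loss_bar: np.ndarray,
) -> pd.DataFrame:
    """Per-(pool, consumer) Q_ij and C*_ij table."""
    q_edge, c_edge = _edge_terms(params, matrix, rho_bar, loss_bar)
    return pd.DataFrame(
        {
            "pool_id": matrix.pool_index,
            "population_id": matrix.population_index,
            "Q": q_edge,
            "C_star": c_edge,
        }
    )


def turnover_time(trajectory: Trajectory, pool: int | None = None):
    """Diagnostic turnover time: window-integrated concentration divided by
    window-integrated consumption rate (days).

    Returns the full per-pool array when ``pool`` is None.  Pools with zero
    consumption over the window get the sentinel ``inf``.
    """
    cons = trajectory.consumption_rate
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(cons > 0, trajectory.C_bar / np.where(cons > 0, cons, 1.0), np.inf)
    if pool is None:
        return tau
    return float(tau[pool])


def classify_pools(
    trajectory: Trajectory,
    params: ParameterSet | None = None,
    matrix: ConsumptionMatrix | None = None,
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Per-pool diagnostics of one finished run.

    Returns a data frame with, per pool: the final concentration, the
    minimum subsistence concentration over its consumers, the recalcitrance
    indicator Q, the lability class (labile iff ``Q > 1``), whether the pool
    has equilibrated to its subsistence concentration (relative mismatch
    below ``tolerance``), and the diagnostic turnover time.

    Loss rates and realised uptake rates are taken from the trajectory's
    trailing-window averages, so the window must span at least
    ``MIN_WINDOW_STEPS`` integration steps.
    """
    params = params if params is not None else trajectory.params
    matrix = matrix if matrix is not None else trajectory.matrix
    if params is None or matrix is None:
        raise ValidationError("trajectory lacks attached parameters/matrix; pass them explicitly")
    cfg = trajectory.config
    dt = cfg.dt if cfg is not None else float(np.diff(trajectory.times).min())
    window_steps = round((trajectory.window[1] - trajectory.window[0]) / dt)
    if window_steps < MIN_WINDOW_STEPS:
        raise ValidationError(
            f"analysis window spans only {window_steps:.0f} steps "
            f"(need >= {MIN_WINDOW_STEPS}); integrate longer"
        )
    loss_bar = trajectory.loss_rate_bar(params)
    q_edge, c_edge = _edge_terms(params, matrix, trajectory.rho_bar, loss_bar)
    b0 = cfg.initial_biomass if cfg is not None else 0.0
    established = trajectory.B_bar[matrix.population_index] >= max(b0, 1e-30)
    # consumers with C*_ij = 0 are still growing (subsidy exceeds current
    # losses): not a steady state, so they do not set the concentration
    steady = established & (c_edge > 0)
    q_pool, c_star = _reduce_to_pools(matrix, q_edge, c_edge, steady)
    c_final = trajectory.C_final
    with np.errstate(invalid="ignore"):
        rel = np.where(c_star > 0, np.abs(c_final - c_star) / np.where(c_star > 0, c_star, 1.0), np.inf)
    equilibrated = np.isfinite(c_star) & (c_star > 0) & (rel < tolerance)
    return pd.DataFrame(
        {
            "pool_id": np.arange(matrix.n_pools),
            "C_final": c_final,
            "C_star_min": c_star,
            "Q": q_pool,
            "classification": np.where(
                q_pool > 1.0, "functionally_labile", "functionally_recalcitrant"
            ),
            "equilibrated": equilibrated,
            "turnover_time": turnover_time(trajectory),
            "n_consumers": matrix.ncons,
        }
    )
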