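"""Stochastic assignment of all model parameters.

Every parameter is drawn independently from a uniform distribution over its
configured range; the maximum uptake rate and the uptake affinity are drawn
log-uniformly (uniform in log10).  The half-saturation concentration is
derived as ``k = rho_max / affinity``, so the affinity ``rho_max / k`` spans
[1, 100] 1/(uM d) by default and ``k / rho_max`` always lies in [1e-2, 1].

Generalist trade-off: populations that consume ``nup`` pools have their
kinetics penalised by the factor ``nup**(-gamma)`` (applied to ``rho_max``,
the yield, or both, per configuration).  With the default gamma = 1 on
``rho_max`` the total uptake capacity of a population is independent of how
many pools it spreads over.  ``k`` is derived from the penalised
``rho_max`` so the sampled affinity is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .consumption_matrix import ConsumptionMatrix
from .errors import StructuralError

__all__ = ["ParameterSet", "sample_parameters"]


def _uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    if lo == hi:
        # degenerate range: still consume one draw per value so that the
        # stream layout does not depend on the bounds
        rng.random(size)
        return np.full(size, lo, dtype=float)
    return lo + (hi - lo) * rng.random(size)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return 10.0 ** _uniform(rng, np.log10(lo), np.log10(hi), size)


@dataclass(frozen=True)
class ParameterSet:
    """All stochastic parameter draws for one model realisation.

    Per-pool arrays (length ``n``): ``supply_potential`` (sigma_i, uM/d) and
    ``supply_probability`` (q_i).  Per-interaction arrays (one entry per
    consumption-matrix edge, canonical edge order): ``rho_max`` (1/d), ``k``
    (uM), ``yield_`` (mol/mol).  Per-population arrays (length ``m``):
    ``presence`` (P_j), ``mortality_quadratic`` (1/(uM d)),
    ``mortality_linear`` (1/d).
    """

    supply_potential: np.ndarray
    supply_probability: np.ndarray
    rho_max: np.ndarray
    k: np.ndarray
    yield_: np.ndarray
    presence: np.ndarray
    mortality_quadratic: np.ndarray
    mortality_linear: np.ndarray

    @property
    def n_pools(self) -> int:
        return self.supply_potential.size

    @property
    def n_populations(self) -> int:
        return self.presence.size

    @property
    def n_edges(self) -> int:
        return self.rho_max.size

    def validate_against(self, matrix: ConsumptionMatrix) -> None:
        if self.n_pools != matrix.n_pools or self.n_populations != matrix.n_populations:
            raise StructuralError(
                f"parameter set ({self.n_pools} pools, {self.n_populations} populations) "
                f"does not match matrix ({matrix.n_pools}, {matrix.n_populations})"
            )
        if self.n_edges != matrix.n_edges:
            raise StructuralError(
                f"parameter set has {self.n_edges} interactions, matrix has {matrix.n_edges}"
            )

    # -- serialisation -----------------------------------------------------

    def to_frames(self, matrix: ConsumptionMatrix) -> dict[str, pd.DataFrame]:
        """Split into three delimited-text-friendly tables.

        Returns ``{'interactions', 'pools', 'populations'}`` data frames;
        :meth:`from_frames` round-trips losslessly.
        """
        self.validate_against(matrix)
        interactions = pd.DataFrame(
            {
                "pool_id": matrix.pool_index,
                "population_id": matrix.population_index,
                "rho_max": self.rho_max,
                "k": self.k,
                "yield": self.yield_,
            }
        )
        pools = pd.DataFrame(
            {
                "pool_id": np.arange(self.n_pools),
                "supply_potential": self.supply_potential,
                "supply_probability": self.supply_probability,
            }
        )
        populations = pd.DataFrame(
            {
                "population_id": np.arange(self.n_populations),
                "presence": self.presence,
                "mortality_quadratic": self.mortality_quadratic,
                "mortality_linear": self.mortality_linear,
            }
        )
        return {"interactions": interactions, "pools": pools, "populations": populations}

    @classmethod
    def from_frames(cls, frames: dict[str, pd.DataFrame]) -> tuple["ParameterSet", ConsumptionMatrix]:
        inter = frames["interactions"]
        pools = frames["pools"].sort_values("pool_id")
        pops = frames["populations"].sort_values("population_id")
        matrix = ConsumptionMatrix(
            len(pools),
            len(pops),
            inter["pool_id"].to_numpy(np.int64),
            inter["population_id"].to_numpy(np.int64),
        )
        # matrix construction canonicalises edge order; re-sort the kinetics
        order = np.lexsort((inter["pool_id"].to_numpy(), inter["population_id"].to_numpy()))
        params = cls(
            supply_potential=pools["supply_potential"].to_numpy(float),
            supply_probability=pools["supply_probability"].to_numpy(float),
            rho_max=inter["rho_max"].to_numpy(float)[order],
            k=inter["k"].to_numpy(float)[order],
            yield_=inter["yield"].to_numpy(float)[order],
            presence=pops["presence"].to_numpy(float),
            mortality_quadratic=pops["mortality_quadratic"].to_numpy(float),
            mortality_linear=pops["mortality_linear"].to_numpy(float),
        )
        return params, matrix


def sample_parameters(
    config: ModelConfig, matrix: ConsumptionMatrix, rng: np.random.Generator
) -> ParameterSet:
    """Draw a full :class:`ParameterSet` on the support of ``matrix``.

    The draw order is fixed (per-pool, then per-interaction, then
    per-population fields), so identical ``(config, matrix, rng state)``
    always produce an identical parameter set.
    """
    if matrix.n_pools != config.n_pools or matrix.n_populations != config.n_populations:
        raise StructuralError(
            f"matrix ({matrix.n_pools} x {matrix.n_populations}) does not match config "
            f"({config.n_pools} x {config.n_populations})"
        )
    r = config.parameter_ranges
    n, m, ne = config.n_pools, config.n_populations, matrix.n_edges

    supply_potential = np.full(n, config.supply_per_pool)
    supply_probability = _uniform(rng, *r.supply_probability, n)

    rho_max = _log_uniform(rng, *r.rho_max, ne)
    affinity = _log_uniform(rng, *r.affinity, ne)
    yield_ = _uniform(rng, *r.yield_, ne)

    presence = _uniform(rng, *r.presence, m)
    mortality_quadratic = _uniform(rng, *r.mortality_quadratic, m)
    mortality_linear = _uniform(rng, *r.mortality_linear, m)

    # generalist trade-off: spread capacity over the pools consumed
    gamma = config.generalist_penalty_exponent
    if gamma > 0:
        penalty = matrix.nup[matrix.population_index].astype(float) ** (-gamma)
        if config.penalty_target in ("rho_max", "both"):
            rho_max = rho_max * penalty
        if config.penalty_target in ("yield", "both"):
            yield_ = yield_ * penalty
    k = rho_max / affinity

    return ParameterSet(
        supply_potential=supply_potential,
        supply_probability=supply_probability,
        rho_max=rho_max,
        k=k,
        yield_=yield_,
        presence=presence,
        mortality_quadratic=mortality_quadratic,
        mortality_linear=mortality_linear,
    )
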