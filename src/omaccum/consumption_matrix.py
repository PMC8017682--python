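"""Construction of the pool x population consumption matrix.

The binary incidence matrix dictates which microbial populations consume
which organic-matter pools.  Three modes are supported:

* **specialist** -- each population consumes exactly one unique pool
  (an ``n x n`` identity);
* **generalist** -- each population consumes ``nup`` pools, with ``nup``
  drawn uniformly from ``{1, ..., n}`` and the specific pools sampled
  without replacement using linearly ramped pool weights, so that some
  pools are systematically more "popular" (larger expected number of
  consumers ``ncons``) than others;
* **mixed** -- a specialist block concatenated with additional generalist
  columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import StructuralError, ValidationError

__all__ = [
    "ConsumptionMatrix",
    "build_specialist_matrix",
    "build_generalist_matrix",
    "build_mixed_matrix",
    "build_matrix",
    "weighted_sample_without_replacement",
]


@dataclass(frozen=True)
class ConsumptionMatrix:
    """Sparse binary incidence of who eats what.

    Edges are stored as parallel ``(pool_index, population_index)`` arrays
    in canonical order (sorted by population, then pool), which is also the
    order in which per-interaction parameters are sampled and integrated.
    """

    n_pools: int
    n_populations: int
    pool_index: np.ndarray  # int64, one entry per edge
    population_index: np.ndarray  # int64, one entry per edge

    def __post_init__(self) -> None:
        if self.n_pools < 1 or self.n_populations < 1:
            raise ValidationError("matrix dimensions must be >= 1")
        pi = np.asarray(self.pool_index, dtype=np.int64)
        ji = np.asarray(self.population_index, dtype=np.int64)
        if pi.shape != ji.shape or pi.ndim != 1:
            raise StructuralError("edge index arrays must be 1-D and equally long")
        if pi.size and (pi.min() < 0 or pi.max() >= self.n_pools):
            raise StructuralError("pool index out of range")
        if ji.size and (ji.min() < 0 or ji.max() >= self.n_populations):
            raise StructuralError("population index out of range")
        order = np.lexsort((pi, ji))
        pi, ji = pi[order], ji[order]
        if pi.size > 1:
            dup = (np.diff(ji) == 0) & (np.diff(pi) == 0)
            if dup.any():
                raise StructuralError("duplicate (pool, population) entries")
        object.__setattr__(self, "pool_index", pi)
        object.__setattr__(self, "population_index", ji)

    @property
    def n_edges(self) -> int:
        return int(self.pool_index.size)

    @property
    def nup(self) -> np.ndarray:
        """Number of pools consumed by each population (column sums)."""
        return np.bincount(self.population_index, minlength=self.n_populations)

    @property
    def ncons(self) -> np.ndarray:
        """Number of consumers of each pool (row sums)."""
        return np.bincount(self.pool_index, minlength=self.n_pools)

    def to_sparse(self) -> sparse.csr_matrix:
        data = np.ones(self.n_edges, dtype=np.int8)
        return sparse.csr_matrix(
            (data, (self.pool_index, self.population_index)),
            shape=(self.n_pools, self.n_populations),
        )

    def to_edge_list(self) -> np.ndarray:
        """3-column ``(pool_id, population_id, 1)`` edge list."""
        return np.column_stack(
            [self.pool_index, self.population_index, np.ones(self.n_edges, dtype=np.int64)]
        )

    @classmethod
    def from_edge_list(
        cls, edges: np.ndarray, n_pools: int, n_populations: int
    ) -> "ConsumptionMatrix":
        edges = np.asarray(edges)
        return cls(n_pools, n_populations, edges[:, 0].astype(np.int64), edges[:, 1].astype(np.int64))


def build_specialist_matrix(n: int) -> ConsumptionMatrix:
    """Identity incidence: population ``j`` consumes pool ``j`` only."""
    if n < 1:
        raise ValidationError(f"pool count must be >= 1, got {n}")
    idx = np.arange(n, dtype=np.int64)
    return ConsumptionMatrix(n, n, idx, idx)


def weighted_sample_without_replacement(
    weights: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` distinct indices by sequential weighted sampling.

    Each draw selects an index with probability proportional to its weight
    among the indices not yet taken (draw-by-draw renormalisation).  This
    matches the semantics of sequential ``sample`` routines with probability
    weights.

    Returns the selected indices in draw order.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1:
        raise ValidationError("weights must be 1-D")
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    n_avail = int((w > 0).sum())
    if count < 0 or count > n_avail:
        raise ValidationError(
            f"cannot draw {count} distinct indices from {n_avail} positive weights"
        )
    w = w.copy()
    out = np.empty(count, dtype=np.int64)
    for d in range(count):
        total = w.sum()
        # cumulative-sum inversion of one categorical draw
        u = rng.random() * total
        idx = int(np.searchsorted(np.cumsum(w), u, side="right"))
        idx = min(idx, w.size - 1)
        out[d] = idx
        w[idx] = 0.0
    return out


def _linear_pool_weights(n: int) -> np.ndarray:
    """Linearly ramped popularity weights ``w_i`` proportional to ``i + 1``."""
    w = np.arange(1, n + 1, dtype=float)
    return w / w.sum()


def build_generalist_matrix(
    n: int, m: int, rng: np.random.Generator, pool_offset: int = 0, n_pools_total: int | None = None,
    population_offset: int = 0, n_populations_total: int | None = None,
) -> ConsumptionMatrix:
    """Generalist incidence over ``n`` pools and ``m`` populations.

    For each population, the number of pools consumed ``nup`` is drawn
    uniformly from ``{1, ..., n}``; the specific pools are then sampled
    without replacement with probabilities proportional to a linear ramp of
    weights over the pool index, making high-index pools more frequently
    consumed.

    The offset arguments allow the generalist block to be embedded into a
    larger (mixed) matrix.
    """
    if n < 1 or m < 1:
        raise ValidationError("pool and population counts must be >= 1")
    n_pools_total = n if n_pools_total is None else n_pools_total
    n_populations_total = m if n_populations_total is None else n_populations_total
    weights = _linear_pool_weights(n)
    pools: list[np.ndarray] = []
    pops: list[np.ndarray] = []
    nup_draws = rng.integers(1, n + 1, size=m)
    for j in range(m):
        chosen = weighted_sample_without_replacement(weights, int(nup_draws[j]), rng)
        pools.append(chosen + pool_offset)
        pops.append(np.full(chosen.size, j + population_offset, dtype=np.int64))
    return ConsumptionMatrix(
        n_pools_total,
        n_populations_total,
        np.concatenate(pools),
        np.concatenate(pops),
    )


def build_mixed_matrix(n: int, m_generalists: int, rng: np.random.Generator) -> ConsumptionMatrix:
    """Specialist identity block plus ``m_generalists`` generalist columns."""
    if m_generalists < 1:
        raise ValidationError("mixed mode needs at least one generalist")
    spec = build_specialist_matrix(n)
    gen = build_generalist_matrix(
        n,
        m_generalists,
        rng,
        population_offset=n,
        n_populations_total=n + m_generalists,
    )
    return ConsumptionMatrix(
        n,
        n + m_generalists,
        np.concatenate([spec.pool_index, gen.pool_index]),
        np.concatenate([spec.population_index, gen.population_index]),
    )


def build_matrix(config, rng: np.random.Generator) -> ConsumptionMatrix:
    """Build the consumption matrix prescribed by a :class:`ModelConfig`."""
    mode = config.matrix_mode
    if mode == "specialist":
        return build_specialist_matrix(config.n_pools)
    if mode == "generalist":
        return build_generalist_matrix(config.n_pools, config.n_populations, rng)
    return build_mixed_matrix(config.n_pools, config.n_populations - config.n_pools, rng)
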