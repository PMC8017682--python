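# omaccum

Stochastic consumer–resource modelling of microbial organic-matter (OM)
consumption, and of why organic carbon accumulates.

Organic matter in the ocean, soils and sediments holds several times more
carbon than the atmosphere, yet most biogeochemical models degrade it with
prescribed rate constants rather than through the microbial populations
that actually consume it. `omaccum` is for researchers who want the
ecological alternative: many OM pools supplied stochastically, consumed by
populations with randomly assigned uptake kinetics (Michaelis–Menten),
growth yields, mortalities and probabilities of presence, so that the
standing stock of each pool — vanishingly small or steadily accumulating —
*emerges* from the interaction network.

## The model in brief

Pool concentrations `C_i` and biomasses `B_j` (µM C) evolve as

    dC_i/dt = s_i(t) − Σ_j I_j(t) ρ_ij(t) B_j(t)
    dB_j/dt = Σ_i I_j(t) y_ij ρ_ij(t) B_j(t) − (m_q B_j + m_l) B_j

with `ρ_ij = ρ_max,ij C_i/(C_i + k_ij)`, Bernoulli supply
(`s_i = σ_i` with probability `q_i`) and Bernoulli presence
(`I_j = 1` with probability `P_j`) drawn every time step. Two closed forms
diagnose each pool:

* the **subsistence concentration** (R\* of resource-competition theory)
  `C* = k / (P y ρ_max / L − 1)`, the lowest concentration a consumer can
  hold its resource at, given its loss rate `L = m_q B̄ + m_l`;
* the **recalcitrance indicator**
  `Q_i = max_j (P_j ρ_max,ij / L_j) (y_ij + Σ_{k≠i} y_kj ρ̄_kj / ρ_max,ij)`.

`Q_i > 1` means some local population can deplete pool `i` to its
subsistence concentration ("functionally labile"); `Q_i ≤ 1` means every
consumer's losses match or beat its maximum biosynthesis, so the pool
accumulates ("functionally recalcitrant"). The subsidy sum is the priming
effect: eating other substrates makes a pool easier to deplete. A
reduced-complexity version (25 pools differentiated by `ρ_max` only) runs
inside a 1-D marine water column with phytoplankton, sinking particulate
OM and vertical mixing, and reproduces a smoothly decreasing dissolved
organic carbon (DOC) profile as an *ecological* transition: losses peak
with productivity at the surface, so mid-lability pools accumulate there
yet are consumed at depth.

## A worked example

```python
from omaccum import ModelConfig, run_simulation, classify_pools

config = ModelConfig(
    n_pools=50, n_populations=100, matrix_mode="mixed",  # 50 specialists + 50 generalists
    total_supply=0.005,   # µM/d over all pools -> 1e-4 µM/d each
    t_end=730.0, dt=0.01, seed=42,
)
trajectory = run_simulation(config)
print(f"carbon budget residual: {trajectory.budget_residual:.2e} (relative)")

diagnostics = classify_pools(trajectory)
print(diagnostics["classification"].value_counts().to_string())
labile = diagnostics[diagnostics.Q > 1]
print(f"min Q = {diagnostics.Q.min():.2f}, max Q = {diagnostics.Q.max():.1f}")
print(f"median labile concentration: {labile.C_final.median():.2e} uM C")
```

prints

```
carbon budget residual: 2.57e-13 (relative)
functionally_labile    50
min Q = 10.87, max Q = 69729.1
median labile concentration: 5.20e-05 uM C
```

— the budget closes to round-off, and at this (small) system size every
pool finds a viable consumer (`Q > 1` throughout) and is held at a
sub-nanomolar subsistence concentration; recalcitrant, accumulating pools
appear in specialist-only configurations, where a pool lives or dies with
a single consumer. `examples/` contains one short script per capability
(closed-form theory and priming, a single stochastic run, ensemble
statistics, the 10-fold sensitivity quadrants, and the water column), each
printing what it computes and what the numbers mean.

There is also a thin CLI mirroring the library:
`omaccum simulate|diagnose|ensemble|sensitivity|column --help`.

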