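# Methods

`omaccum` simulates the accumulation of organic matter (OM) as the emergent
outcome of stochastic microbial consumer–resource dynamics, and provides the
closed-form diagnostics that explain which OM pools equilibrate and which
accumulate.

## The consumption model

The state is a vector of OM pool concentrations `C_i` and population
biomasses `B_j`, both in µM C. Uptake follows Michaelis–Menten kinetics,

    rho_ij(t) = rho_max_ij * C_i / (C_i + k_ij),

and the coupled dynamics are

    dC_i/dt = s_i(t) − Σ_j I_j(t) rho_ij(t) B_j(t)
    dB_j/dt = Σ_i I_j(t) y_ij rho_ij(t) B_j(t) − (m_q_j B_j + m_l_j) B_j,

with two Bernoulli forcings drawn independently every time step: the supply
`s_i` equals the potential rate `sigma_i = sigma_T / n` with probability
`q_i` (zero otherwise), and the presence indicator `I_j` equals 1 with
probability `P_j`. An absent population neither consumes nor grows but still
loses biomass. Quadratic mortality `m_q B^2` stands in for predators and
viruses, linear mortality `m_l B` for maintenance and senescence; the
fraction `1 − y` of everything consumed is respired.

All parameters are sampled independently from wide uniform priors
(`rho_max` and the affinity `rho_max/k` log-uniformly); see the table in
`omaccum/config.py`. Defaults: `n = 1000` pools, `sigma_T = 0.1` µM/d, 10-y
horizon. The half-saturation is derived as `k = rho_max / affinity`, so the
affinity spans [1, 100] and `k/rho_max` always lies in [0.01, 1].

**Consumption matrix.** Specialists form an identity matrix (one unique
pool each). Generalists draw the number of pools consumed, `nup`, uniformly
from {1, …, n}, then pick that many distinct pools by sequential weighted
sampling without replacement with linearly ramped pool weights
(`w_i ∝ i`), so pool "popularity" (`ncons`) varies systematically. Mixed
mode concatenates a specialist block with generalist columns. A trade-off
penalty scales each generalist's `rho_max_ij` by `nup^(−gamma)` with
`gamma = 1` by default (fixed total uptake capacity); the penalty target
(`rho_max`, yield, or both) and `gamma` are configurable because the
strength and locus of the trade-off are genuinely open choices.

**Integration.** Forward Euler with `dt = 0.01` d by default, matching the
per-step semantics of the Bernoulli forcings. A per-step limiter scales all
consumers of a pool proportionally so the pool can never be overdrawn, and
mortality is capped at the available biomass, so non-negativity is
preserved for any admissible step. The integrator tracks cumulative supply,
consumption, respiration and mortality; by construction the discrete carbon
budget closes to round-off (~1e-13 relative), and the `budget_residual` of
every trajectory reports the realised closure. The compiled kernel and the
readable vectorised `step` function implement the same update and are
tested against each other in the deterministic limit.

**Seeding.** One root seed is split hierarchically (matrix → parameters →
forcings) with `numpy.random.SeedSequence`, so changing e.g. the snapshot
cadence can never perturb the draws, and reruns are bit-identical. Ensemble
member `i` uses root seed `base_seed + i`.

## Recalcitrance theory

Setting a specialist's growth equal to its losses at steady state gives the
subsistence concentration

    C*_ij = k_ij / (P_j y_ij rho_max_ij / L_j − 1),     L_j = m_q_j B̄_j + m_l_j,

finite and positive only when maximum local biosynthesis `P y rho_max`
exceeds the loss rate `L`. The recalcitrance indicator generalises the
threshold to populations consuming several pools:

    Q_i = max_j (P_j rho_max_ij / L_j) * (y_ij + Σ_{k≠i} y_kj rho̅_kj / rho_max_ij),

where `rho̅_kj` is the realised (trailing-window mean) uptake rate of the
other pools. `Q_i > 1` marks pool `i` functionally labile (some consumer
can deplete it, given time); `Q_i ≤ 1` marks it functionally recalcitrant
(it accumulates). Two evaluation choices matter and are deliberate:

* In the leading factor the focal pool is taken at saturation
  (`rho_ij := rho_max_ij`), because an accumulating pool has `C_i ≫ k_ij`;
  this makes the expression reduce exactly to the specialist condition.
* The subsidy sum uses the ambient Michaelis–Menten rate averaged over the
  final 10% of the run, without the presence factor; the presence
  probability `P_j` multiplies the whole bracket once. With this grouping an
  established population at growth–loss balance has `Q ≈ 1` on any pool it
  consumes at saturation, which is precisely the threshold's meaning.

`Q` is an *invasion* criterion, so it is evaluated for every consumer, even
ones with little biomass (a rare population with negligible losses can
genuinely invade an abundant pool). The pool-level `C*` is different: it is
a *steady-state* quantity, so the reported `C*_min` minimises only over
consumers that are established (window-mean biomass at or above the
inoculum) and whose subsistence balance has a positive deficit;
still-growing transients would otherwise report a spurious `C* = 0` for
every pool they touch. Orphan pools (no consumers) carry the sentinels
`Q = 0` and `C* = ∞`.

Turnover time is diagnosed as window-integrated concentration divided by
window-integrated consumption (∞ for unconsumed pools); realised
remineralization rates (consumption flux / standing stock) are fitted by a
maximum-likelihood lognormal.

## Ensembles and sensitivity

`run_ensemble` pools per-pool diagnostics over members; `binned_stats` and
`concentration_histograms` compile concentration-vs-Q means with 16th/84th
percentile bands and class-split frequency/carbon histograms (reporting
split at `Q = 1.01`; classification itself is at exactly 1).
`sensitivity_quadrants` reruns a baseline under four matched-seed 10-fold
perturbations: `rho_max` ranges ÷ 10, both mortality ranges × 10, presence
range ÷ 10, and pools × 10 at fixed total supply (per-pool supply shrinks
accordingly; both mortality parameters are scaled because the loss rate
`L = m_q B + m_l` has no single dial).

## Scale dependence of the minimum Q

At full scale (1000 pools, 1000 generalists, `nup` averaging ~500) the
trade-off penalty is strong, some pools accumulate even in the mixed
version, and each accumulating pool retains near-balanced generalist
consumers — which pins the minimum of Q across pools at ~1. The desk-scale
configuration used by the acceptance suite (200 pools, 200 generalists,
5 members) does not reach this regime: penalties are ~5× weaker, every pool
retains a comfortably viable consumer, no mixed-version pool accumulates,
and the minimum Q lands around 2.9–5 depending on seeds (single members at
400 and 800 pools gave 1.07 and 2.45 — the statistic is an extreme-value
quantity with broad spread that approaches 1 only as system size and the
number of pooled records grow). The scaled specialist version, by
contrast, does produce genuinely recalcitrant, accumulating pools (its
sole-consumer failure probability is scale-free), which is why the
concentration-regime statistics are taken from the specialist members.

## Water column

The reduced-complexity version collapses lability onto one axis: 25 DOC
pools on a log-spaced `rho_max` ladder (0.01–10 /d), each consumed by one
specialist heterotroph with `P = 1`, fixed yield 0.3 and fixed affinity 10.
They are embedded in a closed 1-D column (50 levels over 1000 m): two
phytoplankton grow on dissolved inorganic carbon and nitrogen under
`min(light, nutrient)` limitation with exponentially attenuating light;
all biomass losses route 40% to DOC — partitioned across the ladder by a
lognormal in `ln rho_max` (mode 0.3 /d, log-s.d. 1.5) — and 60% to one POM
pool that sinks at 10 m/d and hydrolyses back to DOC at 0.05 /d; every
tracer diffuses vertically (`Kz` decaying from 100 to 8 m²/d with a 150 m
e-folding). C and N travel at fixed Redfield stoichiometry, so both budgets
close to round-off; the small POM flux through the sea floor is moved to a
cumulative burial reservoir that stays in the budget (without it, POM piles
up in the bottom cell and hydrolyses into a spurious deep-DOC maximum).

Heterotroph losses are `(mq_comm · B_tot + ml) · B_j` with predation
proportional to *total* heterotroph biomass: an implicit grazer whose
pressure follows community abundance. This is the mechanism that creates
the vertical recalcitrance transition — losses peak where productivity and
biomass peak (the surface), so mid-ladder pools are accumulating
(recalcitrant) near the surface but consumable (labile) at depth, while the
slowest pool (`y·rho_max < ml`) stays recalcitrant everywhere. A
self-quadratic term is available (`het_mort_self`); with one population the
column reduces exactly to the well-mixed model, which is tested.

All water-column parameter values are this package's own choices, selected
once to yield a realistic open-ocean column (surface DOC ~80 µM falling to
~30–40 µM at 1000 m, near-surface productivity maximum) and the qualitative
structure above; they are documented defaults, not literature values.
Spin-up integrates in 1-year chunks at `dt = 0.1` d until the relative
spread of the depth-integrated DOC inventory over a trailing 10-year window
falls below 5% (typically ~60–80 model years; truly recalcitrant pools keep
accumulating slowly, so the tolerance defines "quasi-equilibrium"), with a
warning — not an error — if the horizon (250 y default) is reached first.

## What the synthetic conditions do and do not show

The simulator is its own data source; there is no external input. The
default conditions probe wide, plausible parameter ranges with independent
draws — they contain no parameter correlations (e.g. rate–yield trade-offs
beyond the generalist penalty), no substrate transformation chains, no
photolysis or other abiotic sinks, no temperature dependence (only a global
rate-multiplier hook), and the water column has no seasonality and a single
POM size class. Passing tests therefore demonstrate the internal
consistency of the ecological mechanism — threshold behaviour, priming,
supply-independence of subsistence concentrations, the vertical transition
— not a calibration to any observed ocean profile. Per-pool accumulation
over 10 years is bounded by `sigma_i q_i t ≤ 0.365` µM under the default
supply, so absolute concentrations of accumulating pools are conditions-
specific and are asserted only as upper bounds.

## Numerical choices

* Euler step `dt = 0.01` d (well-mixed) and `0.1` d (column); both are
  guarded by proportional uptake/mortality limiters that preserve
  non-negativity and exact budget accounting.
* Trailing analysis window: final 10% of the run (min. 10 steps);
  equilibration tolerance 1% relative; histogram split cutoff 1.01.
* Diffusion uses a conservative flux form with zero-flux boundaries; POM
  sinking is first-order upwind (CFL-checked at configuration time).
* Weighted sampling without replacement is sequential with renormalisation
  (cumulative-sum inversion), so matrices are reproducible from the seed
  across platforms.
* Degenerate inputs: zero-length horizons keep the initial state; collapsed
  parameter ranges become point masses but still consume one RNG draw per
  value so the stream layout is range-independent; `t_end = 0` trajectories
  fall back to initial-state window averages.

## Known limitations

* The mixed-mode desk-scale ensembles produce no accumulating pools, so
  statements about the carbon dominance of recalcitrant OM are only
  exercised through the specialist version (see "Scale dependence" above).
* The generalist subsistence concentration inverts the same growth–loss
  balance as Q given realised uptake of the other pools; when a consumer's
  subsidy exceeds its current losses the pool-level `C*` falls back to the
  remaining consumers rather than reporting the transient zero.
* Presence/absence is i.i.d. per step, so the presence autocorrelation time
  equals `dt`; duty-cycle averages match `P` but residence-time statistics
  of presence are not resolved.
* The column's C:N is fixed at Redfield by default; fully independent C and
  N cycling is out of scope.
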