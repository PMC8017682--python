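"""Reduced-complexity organic-matter model embedded in a 1-D marine water
column.

The stochastic consumption model is collapsed onto one master lability
axis: 25 aggregate DOC pools differentiated only by their maximum uptake
rate (a fixed log-spaced ladder), each consumed by one specialist
heterotroph population with probability of presence P = 1.  The pools sit
inside a fully dynamic ecosystem of a stratified column:

* two phytoplankton populations fix dissolved inorganic carbon and
  nitrogen using light (attenuating exponentially with depth), with
  growth set by the minimum of the light and nutrient limitations;
* biomass losses of all populations route a fixed fraction to the DOC
  pools — partitioned by a lognormal distribution over the uptake-rate
  ladder — and the rest to one aggregate POM pool;
* POM sinks at a constant speed and is hydrolysed back to DOC with the
  same lognormal partition; the small POM flux that reaches the sea floor
  is buried (moved to a cumulative sediment reservoir that stays in the
  budget);
* heterotrophs take up DOC with Michaelis--Menten kinetics, respire a
  fraction ``1 - y`` to DIC and excrete the matching nitrogen to DIN;
* all tracers mix vertically with a depth-dependent eddy diffusivity.

Heterotroph losses combine linear maintenance, an optional self-quadratic
term, and a predation term proportional to *total* heterotroph biomass
(an implicit grazer whose pressure follows community abundance).  Because
productivity — and hence biomass — peaks at the surface, population loss
rates peak there too, which is what drives the depth transition of pools
from functionally recalcitrant (surface) to functionally labile (deep).

Apart from light input and the burial reservoir the domain is closed,
carbon and nitrogen are carried at fixed Redfield-like stoichiometry, and
both budgets close to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import NumericalError, ValidationError

__all__ = [
    "ColumnConfig",
    "ColumnGrid",
    "ColumnState",
    "partition_fractions",
    "partition_production",
    "column_step",
    "run_to_quasi_equilibrium",
    "column_diagnostics",
]


@dataclass(frozen=True)
class ColumnConfig:
    """Water-column experiment configuration.

    All rates are per day, depths in metres, concentrations in uM (mmol per
    cubic metre) of carbon or nitrogen.  The defaults describe a 1,000 m
    stratified open-ocean column at a desk-scale resolution (50 levels)
    and spin-up horizon.
    """

    n_levels: int = 50
    depth_max: float = 1000.0
    kz_surface: float = 100.0  # m^2/d, mixed-layer eddy diffusivity
    kz_deep: float = 8.0  # m^2/d, interior diffusivity
    kz_decay_depth: float = 150.0  # e-folding depth of the Kz profile
    surface_light: float = 1.0  # normalised irradiance
    light_attenuation: float = 0.04  # 1/m
    light_half_sat: float = 0.2

    # phytoplankton (two populations: fast/low-affinity, slow/high-affinity)
    phyto_mu_max: tuple[float, float] = (1.4, 0.7)
    phyto_k_din: tuple[float, float] = (0.3, 0.05)
    phyto_mort_quad: float = 0.5  # 1/(uM d)
    phyto_mort_lin: float = 0.01  # 1/d

    # DOC pools and their specialist heterotrophs
    n_doc_pools: int = 25
    rho_max_min: float = 1e-2
    rho_max_max: float = 10.0
    het_affinity: float = 10.0  # rho_max / k
    het_yield: float = 0.3
    het_mort_comm: float = 1.0  # 1/(uM d), predation ~ total heterotroph biomass
    het_mort_self: float = 0.0  # 1/(uM d), optional self-quadratic term
    het_mort_lin: float = 0.004  # 1/d

    # organic-matter routing
    partition_log_mu: float = float(np.log(0.3))  # ln rho_max at the partition mode
    partition_log_sigma: float = 1.5
    mortality_doc_fraction: float = 0.4  # rest goes to POM
    pom_sinking: float = 10.0  # m/d
    pom_hydrolysis: float = 0.05  # 1/d

    redfield_c_to_n: float = 106.0 / 16.0
    din_initial: float = 16.0  # uM N
    dic_initial: float = 2000.0  # uM C
    phyto_initial: float = 0.05  # uM C each
    het_initial: float = 1e-3  # uM C each

    dt: float = 0.1  # d
    t_max_years: float = 250.0
    drift_window_years: float = 10.0
    drift_tolerance: float = 0.05  # relative drift of column DOC over the window

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValidationError("n_levels must be >= 1")
        if self.depth_max <= 0 or self.dt <= 0:
            raise ValidationError("depth_max and dt must be positive")
        if self.kz_surface < 0 or self.kz_deep < 0:
            raise ValidationError("diffusivities must be non-negative")
        if not 0 <= self.mortality_doc_fraction <= 1:
            raise ValidationError("mortality_doc_fraction must lie in [0, 1]")
        if not 0 < self.het_yield <= 1:
            raise ValidationError("het_yield must lie in (0, 1]")
        dz = self.depth_max / self.n_levels
        if self.pom_sinking * self.dt > dz:
            raise ValidationError("sinking CFL violated: w * dt must not exceed dz")
        if max(self.kz_surface, self.kz_deep) * self.dt > 0.5 * dz**2:
            raise ValidationError("diffusion stability violated: Kz * dt > dz^2 / 2")

    @property
    def rho_ladder(self) -> np.ndarray:
        """Log-spaced maximum uptake rates of the 25 pools (1/d)."""
        return np.geomspace(self.rho_max_min, self.rho_max_max, self.n_doc_pools)

    @property
    def half_sat_ladder(self) -> np.ndarray:
        return self.rho_ladder / self.het_affinity


@dataclass(frozen=True)
class ColumnGrid:
    """Depth grid and physical profiles derived from a configuration."""

    z: np.ndarray  # layer-centre depths, m, increasing
    dz: float
    kz: np.ndarray  # diffusivity at interior interfaces, length n_levels - 1
    light: np.ndarray  # normalised irradiance at layer centres

    @classmethod
    def from_config(cls, config: ColumnConfig) -> "ColumnGrid":
        dz = config.depth_max / config.n_levels
        z = (np.arange(config.n_levels) + 0.5) * dz
        z_if = np.arange(1, config.n_levels) * dz
        kz = config.kz_deep + (config.kz_surface - config.kz_deep) * np.exp(
            -z_if / config.kz_decay_depth
        )
        light = config.surface_light * np.exp(-config.light_attenuation * z)
        return cls(z=z, dz=dz, kz=kz, light=light)


@dataclass
class ColumnState:
    """Depth-resolved ecosystem state (all concentrations uM)."""

    t: float
    din: np.ndarray  # (nz,) uM N
    dic: np.ndarray  # (nz,) uM C
    phyto: np.ndarray  # (2, nz) uM C
    doc: np.ndarray  # (n_pools, nz) uM C
    het: np.ndarray  # (n_pools, nz) uM C
    pom: np.ndarray  # (nz,) uM C
    buried: float = 0.0  # cumulative sediment reservoir, uM C equivalent

    def total_carbon(self) -> float:
        return float(
            self.dic.sum()
            + self.phyto.sum()
            + self.doc.sum()
            + self.het.sum()
            + self.pom.sum()
            + self.buried
        )

    def total_nitrogen(self, c_to_n: float) -> float:
        organic = self.phyto.sum() + self.doc.sum() + self.het.sum() + self.pom.sum() + self.buried
        return float(self.din.sum() + organic / c_to_n)

    def total_doc_profile(self) -> np.ndarray:
        return self.doc.sum(axis=0)

    @classmethod
    def initial(cls, config: ColumnConfig) -> "ColumnState":
        nz = config.n_levels
        npool = config.n_doc_pools
        return cls(
            t=0.0,
            din=np.full(nz, config.din_initial),
            dic=np.full(nz, config.dic_initial),
            phyto=np.full((2, nz), config.phyto_initial),
            doc=np.zeros((npool, nz)),
            het=np.full((npool, nz), config.het_initial),
            pom=np.zeros(nz),
        )


def partition_fractions(rho_ladder: np.ndarray, log_mu: float, log_sigma: float) -> np.ndarray:
    """Lognormal partition of organic-matter production over the uptake ladder.

    Fractions are proportional to a Gaussian in ``ln(rho_max)`` evaluated at
    the ladder values and normalised to sum to one.  ``log_sigma -> 0``
    degenerates to a point mass on the ladder entry closest to the mode.
    """
    rho = np.asarray(rho_ladder, dtype=float)
    if (rho <= 0).any():
        raise ValidationError("rho ladder must be positive")
    if log_sigma < 0:
        raise ValidationError("log_sigma must be >= 0")
    x = np.log(rho)
    if log_sigma == 0:
        f = np.zeros(rho.size)
        f[np.argmin(np.abs(x - log_mu))] = 1.0
        return f
    w = np.exp(-0.5 * ((x - log_mu) / log_sigma) ** 2)
    return w / w.sum()


def partition_production(total: float, fractions: np.ndarray) -> np.ndarray:
    """Split a total OM production rate over the pools (same units as input)."""
    if total < 0:
        raise ValidationError("total production must be >= 0")
    return total * np.asarray(fractions, dtype=float)


@njit
def _column_kernel(
    din,
    dic,
    phyto,
    doc,
    het,
    pom,
    n_steps,
    dt,
    dz,
    kz,
    light,
    mu_max,
    k_din,
    mq_p,
    ml_p,
    rho,
    half_sat,
    yld,
    mq_comm,
    mq_self,
    ml_h,
    fractions,
    f_doc,
    w_sink,
    hydrolysis,
    rcn,
    k_light,
):
    nz = din.size
    npool = rho.size
    nphy = phyto.shape[0]
    buried = 0.0

    for _ in range(n_steps):
        for l in range(nz):
            # --- phytoplankton growth (min of light and nutrient limitation)
            llim = light[l] / (light[l] + k_light)
            demand_n = 0.0
            growth_p = np.zeros(nphy)
            for p in range(nphy):
                nlim = din[l] / (din[l] + k_din[p])
                lim = llim if llim < nlim else nlim
                g = mu_max[p] * lim * phyto[p, l] * dt
                growth_p[p] = g
                demand_n += g / rcn
            # do not overdraw DIN (or DIC) within the step
            scale = 1.0
            if demand_n > din[l] and demand_n > 0.0:
                scale = din[l] / demand_n
            if demand_n * rcn * scale > dic[l] and demand_n > 0.0:
                scale = dic[l] / (demand_n * rcn)
            mort_c = 0.0
            for p in range(nphy):
                g = growth_p[p] * scale
                loss = (mq_p * phyto[p, l] + ml_p) * phyto[p, l] * dt
                if loss > phyto[p, l] + g:
                    loss = phyto[p, l] + g
                phyto[p, l] += g - loss
                din[l] -= g / rcn
                dic[l] -= g
                mort_c += loss

            # --- heterotrophic DOC consumption
            bh_tot = 0.0
            for i in range(npool):
                bh_tot += het[i, l]
            for i in range(npool):
                u = rho[i] * doc[i, l] / (doc[i, l] + half_sat[i]) * het[i, l] * dt
                if u > doc[i, l]:
                    u = doc[i, l]
                doc[i, l] -= u
                growth = yld * u
                dic[l] += (1.0 - yld) * u
                din[l] += (1.0 - yld) * u / rcn
                loss = (mq_self * het[i, l] + mq_comm * bh_tot + ml_h) * het[i, l] * dt
                if loss > het[i, l] + growth:
                    loss = het[i, l] + growth
                het[i, l] += growth - loss
                mort_c += loss

            # --- organic-matter routing: mortality to DOC (partitioned) + POM
            to_doc = f_doc * mort_c
            pom[l] += (1.0 - f_doc) * mort_c
            hyd = hydrolysis * pom[l] * dt
            if hyd > pom[l]:
                hyd = pom[l]
            pom[l] -= hyd
            release = to_doc + hyd
            for i in range(npool):
                doc[i, l] += fractions[i] * release

        # --- POM sinking (first-order upwind); flux through the floor is buried
        if w_sink > 0.0:
            cfl = w_sink * dt / dz
            export = cfl * pom[nz - 1]
            pom[nz - 1] -= export
            buried += export
            for l in range(nz - 1, 0, -1):
                flux = cfl * pom[l - 1]
                pom[l] += flux
                pom[l - 1] -= flux

        # --- vertical diffusion of every tracer (flux form, closed boundaries)
        if nz > 1:
            _diffuse(din, kz, dt, dz)
            _diffuse(dic, kz, dt, dz)
            _diffuse(pom, kz, dt, dz)
            for p in range(nphy):
                _diffuse(phyto[p], kz, dt, dz)
            for i in range(npool):
                _diffuse(doc[i], kz, dt, dz)
                _diffuse(het[i], kz, dt, dz)

    return buried


@njit
def _diffuse(x, kz, dt, dz):
    n = x.size
    prev_flux = 0.0  # downward flux entering the top layer (closed surface)
    for l in range(n - 1):
        flux = kz[l] * (x[l + 1] - x[l]) / dz * dt / dz
        x[l] += flux + prev_flux
        prev_flux = -flux
    x[n - 1] += prev_flux


def _run_kernel(state: ColumnState, config: ColumnConfig, grid: ColumnGrid, n_steps: int) -> None:
    buried = _column_kernel(
        state.din,
        state.dic,
        state.phyto,
        state.doc,
        state.het,
        state.pom,
        n_steps,
        config.dt,
        grid.dz,
        grid.kz,
        grid.light,
        np.asarray(config.phyto_mu_max),
        np.asarray(config.phyto_k_din),
        config.phyto_mort_quad,
        config.phyto_mort_lin,
        config.rho_ladder,
        config.half_sat_ladder,
        config.het_yield,
        config.het_mort_comm,
        config.het_mort_self,
        config.het_mort_lin,
        partition_fractions(
            config.rho_ladder, config.partition_log_mu, config.partition_log_sigma
        ),
        config.mortality_doc_fraction,
        config.pom_sinking,
        config.pom_hydrolysis,
        config.redfield_c_to_n,
        config.light_half_sat,
    )
    state.buried += float(buried)
    state.t += n_steps * config.dt


def column_step(state: ColumnState, config: ColumnConfig, grid: ColumnGrid | None = None, n_steps: int = 1) -> ColumnState:
    """Advance the column state in place by ``n_steps`` explicit steps.

    Raises :class:`~omaccum.errors.NumericalError` if the state leaves the
    finite non-negative domain.
    """
    if grid is None:
        grid = ColumnGrid.from_config(config)
    _run_kernel(state, config, grid, n_steps)
    for name in ("din", "dic", "phyto", "doc", "het", "pom"):
        arr = getattr(state, name)
        if not np.isfinite(arr).all():
            raise NumericalError(f"non-finite values in {name} at t = {state.t:.2f} d")
        if (arr < -1e-9).any():
            raise NumericalError(f"negative values in {name} at t = {state.t:.2f} d; reduce dt")
    return state


def run_to_quasi_equilibrium(
    config: ColumnConfig, state: ColumnState | None = None
) -> tuple[ColumnState, dict]:
    """Spin the column up until the depth-integrated DOC stock stops drifting.

    Integrates in one-year chunks, recording the column DOC inventory, and
    stops once the relative spread of the inventory over the trailing
    ``drift_window_years`` falls below ``drift_tolerance`` (or ``t_max_years``
    is reached, in which case the report carries ``converged = False`` —
    a warning status, not a failure).

    Returns the final state and a convergence report with the drift, the
    inventory series, and carbon/nitrogen budget residuals.
    """
    grid = ColumnGrid.from_config(config)
    if state is None:
        state = ColumnState.initial(config)
    c0 = state.total_carbon()
    n0 = state.total_nitrogen(config.redfield_c_to_n)

    steps_per_year = int(round(365.0 / config.dt))
    n_years = int(np.ceil(config.t_max_years))
    window = max(2, int(round(config.drift_window_years)))
    doc_series = [float(state.total_doc_profile().sum() * grid.dz)]
    converged = False
    drift = np.inf
    for year in range(n_years):
        column_step(state, config, grid, steps_per_year)
        doc_series.append(float(state.total_doc_profile().sum() * grid.dz))
        if year + 1 >= window:
            recent = np.asarray(doc_series[-window:])
            mean = recent.mean()
            drift = float((recent.max() - recent.min()) / mean) if mean > 0 else 0.0
            if drift < config.drift_tolerance:
                converged = True
                break
    c1 = state.total_carbon()
    n1 = state.total_nitrogen(config.redfield_c_to_n)
    report = {
        "converged": converged,
        "drift": drift,
        "t_years": state.t / 365.0,
        "doc_inventory": np.asarray(doc_series),
        "carbon_residual": abs(c1 - c0) / c0,
        "nitrogen_residual": abs(n1 - n0) / n0,
    }
    return state, report


def column_diagnostics(state: ColumnState, config: ColumnConfig) -> pd.DataFrame:
    """Per-depth, per-pool recalcitrance diagnostics of a (quasi-)equilibrated
    column.

    With one specialist consumer per pool and P = 1, the recalcitrance
    indicator reduces to ``Q = y rho_max / L`` with the local loss rate
    ``L = mq_self B_j + mq_comm B_tot + ml``; pools with Q > 1 at a depth are
    functionally labile there.  Returns a long-form table over
    (depth, pool).
    """
    grid = ColumnGrid.from_config(config)
    rho = config.rho_ladder
    ks = config.half_sat_ladder
    y = config.het_yield
    bh_tot = state.het.sum(axis=0)  # (nz,)
    loss = (
        config.het_mort_self * state.het
        + config.het_mort_comm * bh_tot[None, :]
        + config.het_mort_lin
    )  # (npool, nz)
    q = y * rho[:, None] / loss
    with np.errstate(divide="ignore"):
        denom = q - 1.0
        c_star = np.where(denom > 0, ks[:, None] / np.where(denom > 0, denom, 1.0), np.inf)
    flux = rho[:, None] * state.doc / (state.doc + ks[:, None]) * state.het
    with np.errstate(divide="ignore", invalid="ignore"):
        turnover = np.where(flux > 0, state.doc / np.where(flux > 0, flux, 1.0), np.inf)
    npool, nz = q.shape
    return pd.DataFrame(
        {
            "depth": np.tile(grid.z, npool),
            "pool": np.repeat(np.arange(npool), nz),
            "rho_max": np.repeat(rho, nz),
            "doc": state.doc.ravel(),
            "biomass": state.het.ravel(),
            "loss_rate": loss.ravel(),
            "Q": q.ravel(),
            "C_star": c_star.ravel(),
            "labile": q.ravel() > 1.0,
            "turnover_time": turnover.ravel(),
        }
    )
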