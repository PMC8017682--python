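"""Model configuration: pool/population counts, parameter ranges, integration
settings, and reproducible seeding.

The default parameter ranges are the wide, plausible-ocean uniform (and
log-uniform) ranges used throughout the package:

======================  ==================  =====================
quantity                default range        units
======================  ==================  =====================
presence probability P  [0, 1]              --
supply probability q    [0, 1]              --
max uptake rate rho_max [1e-2, 1e2] (log)   1/d
uptake affinity         [1, 100] (log)      1/(uM d) -- k = rho_max/affinity
yield y                 [0, 0.5]            mol/mol
quadratic mortality mq  [0.1, 1]            1/(uM d)
linear mortality ml     [0, 0.01]           1/d
======================  ==================  =====================

Total organic-matter supply defaults to ``sigma_T = 0.1`` uM/d spread evenly
over the pools (``sigma_i = sigma_T / n``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import hashlib
import json
import math
from typing import Any

import yaml

from .errors import ValidationError

__all__ = [
    "ParameterRanges",
    "ModelConfig",
    "load_config",
    "save_config",
    "config_hash",
]

#: parameters that are sampled on a logarithmic scale
LOG_SAMPLED = frozenset({"rho_max", "affinity"})

MATRIX_MODES = ("specialist", "generalist", "mixed")
PENALTY_TARGETS = ("rho_max", "yield", "both")


@dataclass(frozen=True)
class ParameterRanges:
    """Lower/upper bounds of the uniform (or log-uniform) parameter priors.

    Each field is a ``(low, high)`` pair; a collapsed pair ``(v, v)``
    degenerates to a point mass, which is convenient for controlled
    experiments.
    """

    presence: tuple[float, float] = (0.0, 1.0)
    supply_probability: tuple[float, float] = (0.0, 1.0)
    rho_max: tuple[float, float] = (1e-2, 1e2)
    affinity: tuple[float, float] = (1.0, 1e2)
    yield_: tuple[float, float] = (0.0, 0.5)
    mortality_quadratic: tuple[float, float] = (0.1, 1.0)
    mortality_linear: tuple[float, float] = (0.0, 0.01)

    # mapping between YAML keys and field names ("yield" is reserved-ish)
    _ALIASES = {"yield": "yield_"}

    def validate(self) -> None:
        for name, (lo, hi) in self.items():
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValidationError(f"range {name!r} must be finite, got ({lo}, {hi})")
            if lo > hi:
                raise ValidationError(f"range {name!r} has lower bound {lo} > upper bound {hi}")
            if name in LOG_SAMPLED and lo <= 0:
                raise ValidationError(f"log-sampled range {name!r} needs a positive lower bound")
            if name not in LOG_SAMPLED and lo < 0:
                raise ValidationError(f"range {name!r} must be non-negative")
        for name in ("presence", "supply_probability"):
            lo, hi = getattr(self, name)
            if hi > 1.0:
                raise ValidationError(f"probability range {name!r} exceeds 1: ({lo}, {hi})")
        lo, hi = self.yield_
        if hi > 0.5 + 1e-12:
            raise ValidationError(f"yield range upper bound {hi} exceeds 0.5")

    def items(self):
        d = asdict(self)
        return [(k, tuple(v)) for k, v in d.items()]

    def scaled(self, **factors: float) -> "ParameterRanges":
        """Return a copy with selected ranges multiplied by a factor.

        Used by the sensitivity-quadrant experiment, e.g.
        ``ranges.scaled(rho_max=0.1, presence=0.1)``.
        """
        updates: dict[str, tuple[float, float]] = {}
        for key, f in factors.items():
            fname = self._ALIASES.get(key, key)
            lo, hi = getattr(self, fname)
            updates[fname] = (lo * f, hi * f)
        out = replace(self, **updates)
        out.validate()
        return out


@dataclass(frozen=True)
class ModelConfig:
    """Full configuration of one stochastic consumption-model experiment.

    Parameters
    ----------
    n_pools
        Number of organic-matter pools ``n``.
    n_populations
        Number of microbial populations ``m``.  For ``matrix_mode
        'specialist'`` this must equal ``n_pools``; for ``'mixed'`` the
        first ``n_pools`` populations are the specialist block and the
        remaining ``n_populations - n_pools`` are generalists.
    total_supply
        Total potential organic-matter supply ``sigma_T`` (uM/d), split
        evenly so each pool receives ``sigma_T / n`` when supplied.
    dt, t_end
        Forward-Euler step and integration horizon, in days.  The Bernoulli
        supply/presence draws are made once per step.
    seed
        Root seed; parameter draws, matrix construction, and the forcing
        stream are split deterministically from it.
    matrix_mode
        'specialist', 'generalist', or 'mixed'.
    generalist_penalty_exponent
        Exponent ``gamma`` of the generalist trade-off: penalised rates are
        scaled by ``nup**(-gamma)`` where ``nup`` is the number of pools a
        population consumes.
    penalty_target
        Which kinetic parameter the penalty scales: 'rho_max' (default),
        'yield', or 'both'.
    q_cutoff
        Reporting cutoff used when splitting histograms into the
        functionally labile / recalcitrant classes (classification itself
        uses the threshold Q = 1 exactly).
    rate_multiplier
        Global multiplier applied to all biological rates (uptake and
        mortality); a hook for e.g. temperature scalings.
    """

    n_pools: int = 1000
    n_populations: int = 1000
    total_supply: float = 0.1
    dt: float = 0.01
    t_end: float = 3650.0
    seed: int = 0
    matrix_mode: str = "specialist"
    generalist_penalty_exponent: float = 1.0
    penalty_target: str = "rho_max"
    q_cutoff: float = 1.01
    initial_concentration: float = 0.0
    initial_biomass: float = 1e-3
    snapshot_interval: float = 1.0
    window_fraction: float = 0.1
    rate_multiplier: float = 1.0
    parameter_ranges: ParameterRanges = field(default_factory=ParameterRanges)

    def __post_init__(self) -> None:
        if self.n_pools < 1:
            raise ValidationError(f"n_pools must be >= 1, got {self.n_pools}")
        if self.n_populations < 1:
            raise ValidationError(f"n_populations must be >= 1, got {self.n_populations}")
        if self.total_supply <= 0:
            raise ValidationError(f"total_supply must be > 0, got {self.total_supply}")
        if self.dt <= 0:
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        if self.t_end < 0:
            raise ValidationError(f"t_end must be >= 0, got {self.t_end}")
        if self.matrix_mode not in MATRIX_MODES:
            raise ValidationError(
                f"matrix_mode must be one of {MATRIX_MODES}, got {self.matrix_mode!r}"
            )
        if self.matrix_mode == "specialist" and self.n_populations != self.n_pools:
            raise ValidationError(
                "specialist mode requires n_populations == n_pools "
                f"(got {self.n_populations} != {self.n_pools})"
            )
        if self.matrix_mode == "mixed" and self.n_populations <= self.n_pools:
            raise ValidationError(
                "mixed mode requires n_populations > n_pools (specialist block "
                "plus at least one generalist)"
            )
        if self.generalist_penalty_exponent < 0:
            raise ValidationError("generalist_penalty_exponent must be >= 0")
        if self.penalty_target not in PENALTY_TARGETS:
            raise ValidationError(
                f"penalty_target must be one of {PENALTY_TARGETS}, got {self.penalty_target!r}"
            )
        if not (0 < self.window_fraction <= 1):
            raise ValidationError("window_fraction must lie in (0, 1]")
        if self.snapshot_interval < self.dt:
            raise ValidationError("snapshot_interval must be >= dt")
        if self.initial_biomass < 0 or self.initial_concentration < 0:
            raise ValidationError("initial stocks must be non-negative")
        if self.rate_multiplier <= 0:
            raise ValidationError("rate_multiplier must be > 0")
        self.parameter_ranges.validate()

    @property
    def supply_per_pool(self) -> float:
        """Per-pool potential supply ``sigma_i = sigma_T / n`` (uM/d)."""
        return self.total_supply / self.n_pools

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        ranges = d.pop("parameter_ranges")
        d["parameter_ranges"] = {
            ("yield" if k == "yield_" else k): list(v) for k, v in ranges.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelConfig":
        data = dict(data)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown configuration key(s): {sorted(unknown)}")
        if "parameter_ranges" in data and data["parameter_ranges"] is not None:
            raw = data["parameter_ranges"]
            if not isinstance(raw, dict):
                raise ValidationError("parameter_ranges must be a mapping")
            fields = {f for f in ParameterRanges.__dataclass_fields__}
            kwargs: dict[str, tuple[float, float]] = {}
            for key, val in raw.items():
                fname = ParameterRanges._ALIASES.get(key, key)
                if fname not in fields:
                    raise ValidationError(f"unknown parameter range key: {key!r}")
                try:
                    lo, hi = (float(val[0]), float(val[1]))
                except (TypeError, ValueError, IndexError) as exc:
                    raise ValidationError(f"range {key!r} must be a [low, high] pair") from exc
                kwargs[fname] = (lo, hi)
            data["parameter_ranges"] = ParameterRanges(**kwargs)
        for int_key in ("n_pools", "n_populations", "seed"):
            if int_key in data:
                v = data[int_key]
                if not isinstance(v, int) or isinstance(v, bool):
                    raise ValidationError(f"{int_key} must be an integer, got {v!r}")
        return cls(**data)


def load_config(path: str) -> ModelConfig:
    """Load a :class:`ModelConfig` from a YAML file.

    An empty file yields the full default configuration.  Unknown keys are
    rejected with a :class:`~omaccum.errors.ValidationError` naming the key.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"configuration file {path!r} must contain a mapping")
    return ModelConfig.from_dict(data)


def save_config(config: ModelConfig, path: str) -> None:
    """Write the fully resolved configuration to YAML (round-trips with
    :func:`load_config`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: ModelConfig) -> str:
    """Stable hex digest of a configuration (key order independent)."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
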