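"""Configuration objects for the simulation and modelling stages.

Everything that downstream stages treat as a tunable lives here as a frozen
dataclass with explicit validation, so a bad value fails fast with the name
of the offending field.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Tuple

from .errors import ConfigurationError

__all__ = [
    "EffectBand",
    "SimulationConfig",
    "TreeParams",
    "BoostingParams",
]


@dataclass(frozen=True)
class EffectBand:
    """Links a baseline-variable interval (or sex category) to risk dynamics.

    A patient whose baseline value falls in ``[lo, hi)`` (or whose sex equals
    ``category``) picks up this band's channel coefficients and intercept
    offset.  Bands of one variable should partition its range; when several
    bands match a patient (e.g. bands on different variables) their
    contributions add.

    Parameters
    ----------
    variable:
        Baseline variable the band conditions on: age, height, weight or sex.
    coef:
        Per-channel weights applied to the noise-free latent channels when
        forming the log-odds of state 1.
    lo, hi:
        Half-open numeric interval ``[lo, hi)``; ignored for sex bands.
    category:
        Sex category ("M"/"F") for categorical bands; None for numeric bands.
    offset:
        Additive log-odds shift for members of the band.
    """

    variable: str
    coef: Tuple[float, ...]
    lo: float = -math.inf
    hi: float = math.inf
    category: str | None = None
    offset: float = 0.0

    def matches(self, row: Mapping[str, object]) -> bool:
        value = row.get(self.variable)
        if value is None:
            return False
        if self.category is not None:
            return value == self.category
        try:
            v = float(value)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return False
        if math.isnan(v):
            return False
        return self.lo <= v < self.hi


#: Plausible adult ICU sampling ranges for the four baseline variables.
DEFAULT_BASELINE_RANGES: Mapping[str, tuple] = {
    "age": (18.0, 90.0),
    "height": (150.0, 200.0),
    "weight": (45.0, 120.0),
    "sex": ("M", "F"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort.

    The latent channel model is the sum of a patient-level offset, a slow
    sinusoidal trend, a mildly persistent AR(1) component and a narrowband
    damped oscillation; observed channels add white Gaussian noise of
    standard deviation ``noise_sd``.  The binary state is a Bernoulli draw
    whose log-odds is an affine function (per matching :class:`EffectBand`)
    of the noise-free latent channels ``gap_effect_lag`` steps earlier, with
    the global intercept calibrated so the pooled state-1 fraction
    approximates ``prevalence_target``.
    """

    n_patients: int = 200
    t_min: int = 240
    t_max: int = 360
    n_channels: int = 6
    baseline_ranges: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RANGES)
    )
    subgroup_effects: Tuple[EffectBand, ...] = ()
    noise_sd: float = 1.75
    prevalence_target: float = 0.08
    gap_effect_lag: int = 1
    seed: int = 0
    # latent-process shape (units: channel value / time steps on the grid)
    offset_sd: float = 1.0
    slow_sd: float = 1.0
    slow_period_range: Tuple[float, float] = (180.0, 300.0)
    ar_coef: float = 0.95
    ar_sd: float = 0.3
    osc_damping: float = 0.97
    osc_period: float = 16.0
    osc_sd: float = 0.85

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 0:
            raise ConfigurationError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.t_min < 1:
            raise ConfigurationError(f"t_min must be >= 1, got {self.t_min}")
        if self.t_min > self.t_max:
            raise ConfigurationError(
                f"t_min must be <= t_max, got t_min={self.t_min} > t_max={self.t_max}"
            )
        if self.n_channels < 1:
            raise ConfigurationError(f"n_channels must be >= 1, got {self.n_channels}")
        if not 0.0 < self.prevalence_target < 0.5:
            raise ConfigurationError(
                f"prevalence_target must lie in (0, 0.5), got {self.prevalence_target}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.gap_effect_lag < 0:
            raise ConfigurationError(
                f"gap_effect_lag must be >= 0, got {self.gap_effect_lag}"
            )
        for band in self.subgroup_effects:
            if len(band.coef) != self.n_channels:
                raise ConfigurationError(
                    "subgroup_effects: band on "
                    f"{band.variable!r} has {len(band.coef)} coefficients, "
                    f"expected n_channels={self.n_channels}"
                )
        for name in ("age", "height", "weight"):
            rng = self.baseline_ranges.get(name)
            if rng is None or len(rng) != 2 or not rng[0] < rng[1]:
                raise ConfigurationError(
                    f"baseline_ranges[{name!r}] must be an increasing (lo, hi) pair"
                )
        if not self.baseline_ranges.get("sex"):
            raise ConfigurationError("baseline_ranges['sex'] must list categories")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_ranges"] = {k: list(v) for k, v in self.baseline_ranges.items()}
        d["subgroup_effects"] = [asdict(b) for b in self.subgroup_effects]
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "subgroup_effects" in d:
            bands = []
            for b in d["subgroup_effects"]:
                b = dict(b)
                b["coef"] = tuple(b["coef"])
                for bound in ("lo", "hi"):
                    if isinstance(b.get(bound), str):
                        b[bound] = float(b[bound])
                bands.append(EffectBand(**b))
            d["subgroup_effects"] = tuple(bands)
        if "baseline_ranges" in d:
            d["baseline_ranges"] = {k: tuple(v) for k, v in d["baseline_ranges"].items()}
        if "slow_period_range" in d:
            d["slow_period_range"] = tuple(d["slow_period_range"])
        return SimulationConfig(**d).validate()


@dataclass(frozen=True)
class TreeParams:
    """Settings of the depth-2 subgroup-discovery regression tree.

    ``complexity`` is the minimum relative SSE improvement (against the root
    node SSE) a split must achieve; ``min_leaf`` the minimum patients per
    child.
    """

    complexity: float = 1e-4
    max_depth: int = 2
    min_leaf: int = 20

    def validate(self) -> "TreeParams":
        if self.complexity < 0:
            raise ConfigurationError(f"complexity must be >= 0, got {self.complexity}")
        if self.max_depth not in (1, 2):
            raise ConfigurationError(f"max_depth must be 1 or 2, got {self.max_depth}")
        if self.min_leaf < 1:
            raise ConfigurationError(f"min_leaf must be >= 1, got {self.min_leaf}")
        return self


@dataclass(frozen=True)
class BoostingParams:
    """Gradient-boosting settings shared by all subgroup models."""

    n_estimators: int = 200
    max_depth: int = 4
    learning_rate: float = 0.1
    scale_pos_weight: float | None = None

    def validate(self) -> "BoostingParams":
        if self.n_estimators < 1:
            raise ConfigurationError(
                f"n_estimators must be >= 1, got {self.n_estimators}"
            )
        if self.max_depth < 1:
            raise ConfigurationError(f"max_depth must be >= 1, got {self.max_depth}")
        if not self.learning_rate > 0:
            raise ConfigurationError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )
        return self

    def xgb_kwargs(self) -> dict:
        kw = dict(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
        )
        if self.scale_pos_weight is not None:
            kw["scale_pos_weight"] = self.scale_pos_weight
        return kw
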