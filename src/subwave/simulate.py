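"""Synthetic ICU-style cohort generator.

Emulates the statistical structure the downstream pipeline assumes: many
patients with heterogeneous series lengths on a fixed (5-minute-style) time
grid, several continuous physiological channels observed with additive
monitor noise, a rare binary state driven by the *noise-free* latent
channels a fixed number of steps earlier, and baseline covariates that
modulate the state dynamics so subgroup-specific models genuinely differ.

Latent channel model (per patient n, channel k)::

    L[t] = mu + slow sinusoid + AR(1) + damped oscillation
    X[t] = L[t] + white noise                       (observed channel)
    logit P(y[t] = 1) = c + offset(n) + sum_k coef_k(n) * L[k, t - lag]

``mu`` is a patient-level set point (chronic baseline differences), the slow
sinusoid a drifting trend over hours, the AR(1) term short-range physiological
variation, and the damped oscillation (AR(2) with complex poles) a narrowband
rhythm whose period sits between the 4-point and 16-point smoothing windows —
it is the component a level-2 smooth preserves and heavier smoothing destroys.
The global intercept ``c`` is calibrated numerically so the pooled state-1
fraction matches the configured prevalence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, special

from .config import EffectBand, SimulationConfig
from .errors import ConfigurationError

__all__ = ["SignalPanel", "Cohort", "simulate_cohort", "inject_noise"]

BASELINE_COLUMNS = ["patient_id", "age", "sex", "weight", "height"]


@dataclass
class SignalPanel:
    """One patient's multichannel series: a K x T channel matrix plus state.

    ``channels[k, t]`` is channel k at grid time t; ``state[t]`` is the
    binary patient state at the same time.
    """

    patient_id: str
    channels: np.ndarray  # shape (K, T), float
    state: np.ndarray  # shape (T,), int {0, 1}

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.state = np.asarray(self.state)
        if self.channels.ndim != 2:
            raise ValueError("channels must be a K x T matrix")
        if self.state.shape != (self.channels.shape[1],):
            raise ValueError("state length must equal the channel series length")
        if self.state.size and not np.isin(self.state, (0, 1)).all():
            raise ValueError("state values must be 0 or 1")
        self.state = self.state.astype(np.int8)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_times(self) -> int:
        return self.channels.shape[1]


@dataclass
class Cohort:
    """A baseline table plus one :class:`SignalPanel` per patient."""

    baselines: pd.DataFrame
    panels: List[SignalPanel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = list(self.baselines["patient_id"])
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient_id in baselines")
        known = set(ids)
        for p in self.panels:
            if p.patient_id not in known:
                raise ValueError(f"panel patient {p.patient_id!r} missing from baselines")

    @property
    def n_patients(self) -> int:
        return len(self.panels)

    def panel(self, patient_id: str) -> SignalPanel:
        for p in self.panels:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def states(self) -> Dict[str, np.ndarray]:
        return {p.patient_id: p.state for p in self.panels}

    def state_prevalence(self) -> float:
        total = sum(p.n_times for p in self.panels)
        if total == 0:
            return math.nan
        return sum(int(p.state.sum()) for p in self.panels) / total


def _ar1(rng: np.random.Generator, phi: float, sd: float, shape: tuple) -> np.ndarray:
    """Stationary AR(1) paths with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=shape)
    out = signal.lfilter([1.0], [1.0, -phi], eps, axis=-1)
    # start from a stationary draw instead of zero
    out += rng.normal(0.0, sd, size=shape[:-1] + (1,)) * phi ** np.arange(shape[-1])
    return out


def _damped_oscillation(
    rng: np.random.Generator, r: float, period: float, sd: float, shape: tuple
) -> np.ndarray:
    """AR(2) with complex poles r·e^{±iω}: a narrowband stochastic rhythm."""
    if sd == 0:
        return np.zeros(shape)
    a1 = 2.0 * r * math.cos(2.0 * math.pi / period)
    a2 = -r * r
    # stationary variance of AR(2) x_t = a1 x_{t-1} + a2 x_{t-2} + e_t
    gamma0_unit = (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1 * a1))
    innov_sd = sd / math.sqrt(gamma0_unit)
    burn = int(max(200, 8.0 / max(1e-6, 1.0 - r)))
    eps = rng.normal(0.0, innov_sd, size=shape[:-1] + (shape[-1] + burn,))
    out = signal.lfilter([1.0], [1.0, -a1, -a2], eps, axis=-1)
    return out[..., burn:]


def _latent_channels(
    rng: np.random.Generator, config: SimulationConfig, n_times: int
) -> np.ndarray:
    """Noise-free latent channel matrix of shape (K, n_times)."""
    k = config.n_channels
    shape = (k, n_times)
    t = np.arange(n_times, dtype=float)
    mu = rng.normal(0.0, config.offset_sd, size=(k, 1))
    lo, hi = config.slow_period_range
    periods = rng.uniform(lo, hi, size=(k, 1))
    phases = rng.uniform(0.0, 2.0 * math.pi, size=(k, 1))
    slow = (config.slow_sd * math.sqrt(2.0)) * np.sin(
        2.0 * math.pi * t[None, :] / periods + phases
    )
    ar = _ar1(rng, config.ar_coef, config.ar_sd, shape)
    osc = _damped_oscillation(
        rng, config.osc_damping, config.osc_period, config.osc_sd, shape
    )
    return mu + slow + ar + osc


def _effect_for(
    baseline_row: dict, config: SimulationConfig
) -> tuple[np.ndarray, float]:
    """Sum of coefficient vectors and offsets of all matching effect bands."""
    coef = np.zeros(config.n_channels)
    offset = 0.0
    for band in config.subgroup_effects:
        if band.matches(baseline_row):
            coef += np.asarray(band.coef, dtype=float)
            offset += band.offset
    return coef, offset


def _sample_baselines(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    n = config.n_patients
    ranges = config.baseline_ranges
    ids = [f"p{i + 1:04d}" for i in range(n)]
    frame = pd.DataFrame(
        {
            "patient_id": ids,
            "age": rng.uniform(*ranges["age"], size=n),
            "sex": rng.choice(list(ranges["sex"]), size=n),
            "weight": rng.uniform(*ranges["weight"], size=n),
            "height": rng.uniform(*ranges["height"], size=n),
        }
    )
    return frame[BASELINE_COLUMNS]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a seeded synthetic cohort.

    The latent risk series uses the noise-free channels ``gap_effect_lag``
    steps before the state time, so a supervised dataset built with that gap
    is the correctly specified model.  Identical configuration (including
    seed) yields bitwise-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    baselines = _sample_baselines(rng, config)
    if config.n_patients == 0:
        return Cohort(baselines=baselines, panels=[])

    lag = config.gap_effect_lag
    lengths = rng.integers(config.t_min, config.t_max + 1, size=config.n_patients)
    panels_raw = []  # (patient_id, observed channels, linear risk series)
    for pid, t_n in zip(baselines["patient_id"], lengths):
        row = baselines.loc[baselines["patient_id"] == pid].iloc[0].to_dict()
        latent = _latent_channels(rng, config, int(t_n) + lag)
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_channels, int(t_n)))
        observed = latent[:, lag:] + noise
        coef, offset = _effect_for(row, config)
        # state at observed time t is driven by the latent at time t - lag,
        # i.e. index t in the extended latent array
        risk_lin = coef @ latent[:, : int(t_n)] + offset
        panels_raw.append((pid, observed, risk_lin))

    pooled = np.concatenate([r for _, _, r in panels_raw])
    intercept = _calibrate_intercept(pooled, config.prevalence_target)

    panels = []
    for pid, observed, risk_lin in panels_raw:
        prob = special.expit(intercept + risk_lin)
        state = (rng.random(prob.shape) < prob).astype(np.int8)
        panels.append(SignalPanel(patient_id=pid, channels=observed, state=state))
    return Cohort(baselines=baselines, panels=panels)


def _calibrate_intercept(risk_lin: np.ndarray, target: float) -> float:
    """Solve mean(sigmoid(c + risk)) = target for the global intercept c."""

    def excess(c: float) -> float:
        return float(special.expit(c + risk_lin).mean() - target)

    lo, hi = -40.0, 40.0
    if excess(lo) > 0 or excess(hi) < 0:  # pragma: no cover - defensive
        return float(special.logit(target) - risk_lin.mean())
    return float(optimize.brentq(excess, lo, hi, xtol=1e-12))


def inject_noise(cohort: Cohort, extra_sd: float, seed: int) -> Cohort:
    """Return a copy with extra iid Gaussian noise on every channel value.

    States and baselines are untouched; ``extra_sd = 0`` returns an exact
    copy.  Deterministic in (cohort, extra_sd, seed).
    """
    if extra_sd < 0:
        raise ConfigurationError(f"extra_sd must be >= 0, got {extra_sd}")
    rng = np.random.default_rng(seed)
    panels = []
    for p in cohort.panels:
        chans = p.channels.copy()
        if extra_sd > 0:
            chans = chans + rng.normal(0.0, extra_sd, size=chans.shape)
        panels.append(
            SignalPanel(patient_id=p.patient_id, channels=chans, state=p.state.copy())
        )
    return Cohort(baselines=cohort.baselines.copy(), panels=panels)
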