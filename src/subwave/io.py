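"""CSV/YAML interchange and the end-to-end pipeline driver.

Two CSV schemas carry the cohort:

* panel CSV: ``patient_id, time_index, v1..vK, state`` — one row per
  (patient, grid time), time as an integer grid index;
* baseline CSV: ``patient_id, age, sex, weight, height`` — blanks allowed
  (missing), sex normalized to {M, F}.

Both are comma-separated UTF-8 with a header row and "." decimals.
"""
from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import BoostingParams, SimulationConfig, TreeParams
from .errors import ConfigurationError, SchemaError
from .simulate import BASELINE_COLUMNS, Cohort, SignalPanel, simulate_cohort

log = logging.getLogger("subwave")

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "read_baseline_csv",
    "write_baseline_csv",
    "read_cohort",
    "write_cohort",
    "PipelineConfig",
    "run_pipeline",
]

_SEX_MAP = {
    "m": "M", "male": "M",
    "f": "F", "female": "F",
}


def write_panel_csv(panels: Sequence[SignalPanel], path) -> None:
    frames = []
    for p in panels:
        frame = pd.DataFrame(
            p.channels.T, columns=[f"v{k + 1}" for k in range(p.n_channels)]
        )
        frame.insert(0, "patient_id", p.patient_id)
        frame.insert(1, "time_index", np.arange(p.n_times))
        frame["state"] = p.state.astype(int)
        frames.append(frame)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["patient_id", "time_index", "state"])
    out.to_csv(path, index=False)


def read_panel_csv(path) -> List[SignalPanel]:
    """Parse a panel CSV into per-patient panels, sorted by time index."""
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("patient_id", "time_index", "state"):
        if col not in frame.columns:
            raise SchemaError(f"panel CSV missing required column {col!r}")
    channel_cols = sorted(
        (c for c in frame.columns if c.startswith("v") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not channel_cols:
        raise SchemaError("panel CSV has no channel columns v1..vK")
    bad = frame.loc[~frame["state"].isin([0, 1])]
    if not bad.empty:
        row = int(bad.index[0]) + 2  # header + 1-based
        raise SchemaError(
            f"non-binary state value {bad['state'].iloc[0]!r} at row {row}"
        )
    if frame.duplicated(subset=["patient_id", "time_index"]).any():
        dup = frame[frame.duplicated(subset=["patient_id", "time_index"])].iloc[0]
        raise SchemaError(
            f"duplicate (patient, time) pair ({dup['patient_id']}, "
            f"{dup['time_index']})"
        )
    panels = []
    for pid, grp in frame.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_index")
        panels.append(
            SignalPanel(
                patient_id=str(pid),
                channels=grp[channel_cols].to_numpy(dtype=float).T,
                state=grp["state"].to_numpy(dtype=int),
            )
        )
    return panels


def write_baseline_csv(baselines: pd.DataFrame, path) -> None:
    baselines.to_csv(path, index=False)


def read_baseline_csv(path) -> pd.DataFrame:
    """Parse and validate a baseline CSV (one row per patient)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in BASELINE_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"baseline CSV missing required column {col!r}")
    if frame["patient_id"].duplicated().any():
        dup = frame.loc[frame["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SchemaError(f"duplicate patient_id {dup!r} in baseline CSV")
    frame["patient_id"] = frame["patient_id"].astype(str)
    for col in ("age", "weight", "height"):
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.loc[coerced.isna() & frame[col].notna()]
            row = int(bad.index[0]) + 2 if not bad.empty else "?"
            raise SchemaError(
                f"unparseable numeric {col!r} at row {row}"
            ) from exc

    def norm_sex(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        key = str(v).strip().lower()
        if key in ("", "nan"):
            return None
        if key not in _SEX_MAP:
            raise SchemaError(f"unrecognized sex value {v!r}")
        return _SEX_MAP[key]

    frame["sex"] = frame["sex"].map(norm_sex)
    return frame[BASELINE_COLUMNS]


def write_cohort(cohort: Cohort, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_panel_csv(cohort.panels, out_dir / "panels.csv")
    write_baseline_csv(cohort.baselines, out_dir / "baselines.csv")


def read_cohort(panel_path, baseline_path) -> Cohort:
    return Cohort(
        baselines=read_baseline_csv(baseline_path),
        panels=read_panel_csv(panel_path),
    )


# ---------------------------------------------------------------------------
# pipeline configuration and umbrella driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run settings (see the shipped ``configs/`` examples)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    levels: Sequence[int] = (0, 1, 2, 4, 8)
    gaps: Sequence[int] = (1, 5, 10, 20)
    tree: TreeParams = field(default_factory=TreeParams)
    boosting: BoostingParams = field(default_factory=BoostingParams)
    val_fraction: float = 0.3
    drop_wrap_prefix: bool = False
    seed: int = 0
    scheme_path: str | None = None  # hand-authored scheme instead of tree fit
    panel_path: str | None = None  # load a cohort instead of simulating
    baseline_path: str | None = None

    def validate(self) -> "PipelineConfig":
        if not self.levels or not self.gaps:
            raise ConfigurationError("levels and gaps must be non-empty")
        if any(l < 0 for l in self.levels):
            raise ConfigurationError("levels must be >= 0")
        if any(g < 1 for g in self.gaps):
            raise ConfigurationError("gaps must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ConfigurationError(
                f"val_fraction must lie in (0, 1), got {self.val_fraction}"
            )
        for attr in ("scheme_path", "panel_path", "baseline_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{attr} does not exist: {p}")
        self.simulation.validate()
        self.tree.validate()
        self.boosting.validate()
        return self

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"])
        if "tree" in kwargs:
            kwargs["tree"] = TreeParams(**kwargs["tree"])
        if "boosting" in kwargs:
            kwargs["boosting"] = BoostingParams(**kwargs["boosting"])
        try:
            config = PipelineConfig(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"bad pipeline config: {exc}") from exc
        return config.validate()


def run_pipeline(config: PipelineConfig, out_dir) -> pd.DataFrame:
    """simulate/load -> subgroups -> grid -> reports; returns the metrics table.

    Writes ``cohort/`` CSVs (when simulating), ``scheme.json``,
    ``grid_metrics.csv`` and ``importance_level*.csv`` under ``out_dir``,
    logging each stage with its timing at INFO.
    """
    from .evaluation import run_grid
    from .subgroups import SubgroupScheme, build_scheme, state_ratio

    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if config.panel_path and config.baseline_path:
        cohort = read_cohort(config.panel_path, config.baseline_path)
        log.info("loaded cohort of %d patients (%.1fs)",
                 cohort.n_patients, time.perf_counter() - t0)
    else:
        cohort = simulate_cohort(config.simulation)
        write_cohort(cohort, out_dir / "cohort")
        log.info("simulated cohort of %d patients, prevalence %.4f (%.1fs)",
                 cohort.n_patients, cohort.state_prevalence(),
                 time.perf_counter() - t0)

    t0 = time.perf_counter()
    if config.scheme_path:
        scheme = SubgroupScheme.from_json(config.scheme_path)
    else:
        ratios = {p.patient_id: state_ratio(p) for p in cohort.panels}
        scheme = build_scheme(cohort.baselines, ratios, config.tree)
    scheme.to_json(out_dir / "scheme.json")
    log.info("subgroup scheme: %d rules over %d variables (%.1fs)",
             scheme.n_subgroups, scheme.n_baseline_vars, time.perf_counter() - t0)

    t0 = time.perf_counter()
    metrics = run_grid(
        cohort, scheme, config.levels, config.gaps, config.boosting,
        seed=config.seed, val_fraction=config.val_fraction,
        drop_wrap_prefix=config.drop_wrap_prefix,
    )
    metrics.to_csv(out_dir / "grid_metrics.csv", index=False)
    log.info("grid: %d cells (%.1fs)", len(metrics), time.perf_counter() - t0)
    return metrics
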