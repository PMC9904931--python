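"""Performance metrics, split-frequency importance, and the experiment grid.

The grid crosses denoising levels and prediction gaps and, in every cell,
runs the full pipeline — smooth, split patients into train/validation, pool
gap-lagged datasets per subgroup, train the 13+1 boosted models, score the
held-out patients with both the aggregated and the original method — and
reports AUC, F1, sensitivity, specificity and the confusion counts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import BoostingParams
from .datasets import SupervisedDataset, assemble
from .errors import GridCellError, MetricUndefinedError, TrainingError
from .models import SubgroupModelSet, _proba, train_all
from .simulate import Cohort
from .subgroups import SubgroupScheme, membership
from .wavelets import smooth_panel

__all__ = [
    "MetricsReport",
    "auc",
    "confusion_metrics",
    "variable_importance",
    "run_grid",
    "split_patients",
    "score_validation",
]


@dataclass(frozen=True)
class MetricsReport:
    """All metrics of one (method, level, gap) grid cell."""

    method: str
    level: int
    gap: int
    auc: float
    f1: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) statistic.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, with ties counted one half (midranks).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D of equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("AUC undefined: labels contain a single class")
    ranks = rankdata(s)  # midranks
    rank_sum_pos = float(ranks[y == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def confusion_metrics(
    labels: Sequence[int],
    predicted: Sequence[int],
    *,
    method: str = "",
    level: int = -1,
    gap: int = -1,
    auc_value: float = float("nan"),
) -> MetricsReport:
    """F1, sensitivity, specificity and counts at the 0.5-threshold labels.

    ``f1 = 2*tp / (2*tp + fp + fn)``; when no positives exist anywhere
    (tp = fp = fn = 0) F1 is reported as 1.0 with a warning (vacuous
    perfection).  Sensitivity (specificity) requires at least one actual
    positive (negative).
    """
    y = np.asarray(labels)
    p = np.asarray(predicted)
    if y.shape != p.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("labels and predictions must be equal-length, non-empty")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    if tp + fn == 0:
        raise MetricUndefinedError("sensitivity undefined: no actual positives")
    if tn + fp == 0:
        raise MetricUndefinedError("specificity undefined: no actual negatives")
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    if tp == 0 and fp + fn == 0:  # unreachable once both classes exist
        warnings.warn("F1 reported as 1.0 with no positives anywhere", stacklevel=2)
        f1 = 1.0
    else:
        f1 = 2.0 * tp / (2.0 * tp + fp + fn)
    return MetricsReport(
        method=method,
        level=level,
        gap=gap,
        auc=auc_value,
        f1=f1,
        sensitivity=sensitivity,
        specificity=specificity,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------


def _split_counts(model, n_channels: int) -> np.ndarray:
    """Per-channel internal-split counts of one boosted model."""
    booster = model.get_booster()
    score = booster.get_score(importance_type="weight")
    counts = np.zeros(n_channels)
    for feat, w in score.items():
        counts[int(feat.lstrip("f"))] = w
    return counts


def variable_importance(
    modelset: SubgroupModelSet, method: str = "aggregated"
) -> pd.DataFrame:
    """Selection-frequency importance: each channel's share of split nodes.

    For the original method the shares come from the global model; for the
    aggregated method each subgroup model's shares are computed first and
    then averaged with equal model weight, so small subgroups count as much
    as large ones.  Frequencies sum to 1.
    """
    if method == "original":
        models = [modelset.global_model]
    elif method == "aggregated":
        models = list(modelset.models.values())
    else:
        raise ValueError(f"method must be 'aggregated' or 'original', got {method!r}")
    n_channels = int(models[0].n_features_in_)
    freqs = []
    for m in models:
        counts = _split_counts(m, n_channels)
        total = counts.sum()
        if total == 0:
            raise ValueError("model has no split nodes; importance undefined")
        freqs.append(counts / total)
    frequency = np.mean(freqs, axis=0)
    return pd.DataFrame(
        {
            "variable": [f"v{k + 1}" for k in range(n_channels)],
            "frequency": frequency,
            "level": modelset.level,
            "gap": modelset.gap,
            "method": method,
        }
    )


# ---------------------------------------------------------------------------
# grid experiment
# ---------------------------------------------------------------------------


def split_patients(
    patient_ids: Sequence[str], seed: int, val_fraction: float = 0.3
) -> Tuple[List[str], List[str]]:
    """Seeded split *by patient* into train and validation id lists."""
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("need at least two patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_val = max(1, int(round(val_fraction * len(ids))))
    n_val = min(n_val, len(ids) - 1)
    val = [ids[i] for i in perm[:n_val]]
    train = [ids[i] for i in perm[n_val:]]
    return train, val


def _members_per_rule(
    baselines: pd.DataFrame, scheme: SubgroupScheme, restrict_to: set
) -> Dict[int, List[str]]:
    members: Dict[int, List[str]] = {r.subgroup_id: [] for r in scheme.rules}
    for _, row in baselines.iterrows():
        pid = row["patient_id"]
        if pid not in restrict_to:
            continue
        for rule in scheme.rules:
            if rule.matches(row.get(rule.variable)):
                members[rule.subgroup_id].append(pid)
    return members


def score_validation(
    modelset: SubgroupModelSet,
    scheme: SubgroupScheme,
    baselines: pd.DataFrame,
    smoothed: Sequence,
    states: Mapping[str, np.ndarray],
    val_ids: Sequence[str],
    gap: int,
    drop_wrap_prefix: bool = False,
) -> pd.DataFrame:
    """Row-level probabilities of both methods on the held-out patients.

    Returns a frame with columns patient_id, t, label, p_aggregated,
    p_original, m.  Each subgroup model is run once on the stacked rows of
    its member patients, then the per-row mean over the m contributing
    models forms the aggregated probability.
    """
    ds = assemble(
        smoothed, states, val_ids, gap, drop_wrap_prefix=drop_wrap_prefix
    )
    if ds.n_rows == 0:
        raise ValueError("validation set has no rows at this gap")
    base_by_id = baselines.set_index("patient_id", drop=False)
    member_ids = {
        pid: membership(base_by_id.loc[pid].to_dict(), scheme) for pid in val_ids
    }
    p_sum = np.zeros(ds.n_rows)
    m_count = np.zeros(ds.n_rows, dtype=int)
    for sid, model in modelset.models.items():
        mask = np.fromiter(
            (sid in member_ids[pid] for pid in ds.patient_ids),
            dtype=bool,
            count=ds.n_rows,
        )
        if mask.any():
            p_sum[mask] += _proba(model, ds.features[mask])
            m_count[mask] += 1
    if (m_count == 0).any():
        raise ValueError("some validation rows match no subgroup model")
    p_agg = p_sum / m_count
    p_orig = _proba(modelset.global_model, ds.features)
    return pd.DataFrame(
        {
            "patient_id": ds.patient_ids,
            "t": ds.times,
            "label": ds.labels.astype(int),
            "p_aggregated": p_agg,
            "p_original": p_orig,
            "m": m_count,
        }
    )


def run_grid(
    cohort: Cohort,
    scheme: SubgroupScheme,
    levels: Iterable[int],
    gaps: Iterable[int],
    hyperparams: BoostingParams | None = None,
    seed: int = 0,
    *,
    val_fraction: float = 0.3,
    drop_wrap_prefix: bool = False,
) -> pd.DataFrame:
    """Full level x gap x method experiment; one metrics row per cell.

    Patients are split once (seeded, by patient) and the same split is used
    in every cell, so cells differ only in the denoising level and gap.
    Deterministic given the cohort, scheme and seed; cell results do not
    depend on evaluation order.
    """
    levels = sorted(set(levels))
    gaps = sorted(set(gaps))
    if not levels or not gaps:
        raise ValueError("levels and gaps must be non-empty")
    hp = (hyperparams or BoostingParams()).validate()
    all_ids = [p.patient_id for p in cohort.panels]
    train_ids, val_ids = split_patients(all_ids, seed, val_fraction)
    train_set = set(train_ids)
    states = cohort.states()
    train_members = _members_per_rule(cohort.baselines, scheme, train_set)

    rows: List[dict] = []
    for level in levels:
        smoothed = [smooth_panel(p, level) for p in cohort.panels]
        for gap in gaps:
            try:
                datasets = {
                    sid: assemble(
                        smoothed, states, mem, gap,
                        drop_wrap_prefix=drop_wrap_prefix, subgroup_id=sid,
                    )
                    for sid, mem in train_members.items()
                }
                global_ds = assemble(
                    smoothed, states, train_ids, gap,
                    drop_wrap_prefix=drop_wrap_prefix,
                )
                modelset = train_all(datasets, global_ds, hp, seed)
                scored = score_validation(
                    modelset, scheme, cohort.baselines, smoothed, states,
                    val_ids, gap, drop_wrap_prefix=drop_wrap_prefix,
                )
            except (TrainingError, ValueError) as exc:
                raise GridCellError(
                    f"grid cell (level={level}, gap={gap}) failed: {exc}"
                ) from exc
            y = scored["label"].to_numpy()
            for method, col in (
                ("aggregated", "p_aggregated"),
                ("original", "p_original"),
            ):
                p = scored[col].to_numpy()
                report = confusion_metrics(
                    y, (p > 0.5).astype(int),
                    method=method, level=level, gap=gap, auc_value=auc(y, p),
                )
                rows.append(report.to_dict())
    return pd.DataFrame(rows)
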