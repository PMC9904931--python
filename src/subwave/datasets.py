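"""Pooling smoothed panels into gap-lagged supervised datasets.

For prediction gap g, each member patient contributes one row per feature
time t = 0..T_n - g - 1: the K level-j scaling coefficients at t, labelled
with the state at t + g.  Rows never mix patients; patients shorter than the
gap contribute nothing.  With the causal smoothing convention the only rows
whose features touch future samples are the first 2^j - 1 per patient
(circular wrap); ``drop_wrap_prefix`` excludes them.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .wavelets import SmoothedPanel, wrap_prefix_length

__all__ = ["SupervisedDataset", "assemble"]


@dataclass
class SupervisedDataset:
    """Pooled feature matrix plus gap-shifted labels for one subgroup."""

    features: np.ndarray  # shape (R, K)
    labels: np.ndarray  # shape (R,), int {0, 1}
    gap: int
    level: int
    subgroup_id: int | None
    patient_ids: np.ndarray  # shape (R,), per-row patient
    times: np.ndarray  # shape (R,), per-row feature time t (0-based)

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    def has_both_classes(self) -> bool:
        return self.n_rows > 0 and 0 < int(self.labels.sum()) < self.n_rows


def assemble(
    smoothed: Sequence[SmoothedPanel],
    states: Mapping[str, np.ndarray],
    members: Iterable[str],
    gap: int,
    drop_wrap_prefix: bool = False,
    subgroup_id: int | None = None,
) -> SupervisedDataset:
    """Pool the smoothed panels of ``members`` into one supervised dataset.

    Raises
    ------
    ValueError
        If the gap is < 1, a member has no smoothed panel, or panels disagree
        on the channel count or smoothing level.
    """
    if gap < 1:
        raise ValueError(f"gap must be >= 1, got {gap}")
    by_id = {p.patient_id: p for p in smoothed}
    members = list(members)
    missing = [m for m in members if m not in by_id]
    if missing:
        raise ValueError(f"no smoothed panel for members: {missing[:5]}")

    panels = [by_id[m] for m in members]
    levels = {p.level for p in panels}
    if len(levels) > 1:
        raise ValueError(f"panels smoothed at inconsistent levels: {sorted(levels)}")
    level = levels.pop() if levels else 0
    channel_counts = {p.n_channels for p in panels}
    if len(channel_counts) > 1:
        raise ValueError(
            f"inconsistent channel counts across panels: {sorted(channel_counts)}"
        )
    n_channels = channel_counts.pop() if channel_counts else 0

    start = wrap_prefix_length(level) if drop_wrap_prefix else 0
    feats, labs, pids, times = [], [], [], []
    for p in panels:
        t_n = p.n_times
        state = np.asarray(states[p.patient_id])
        if state.shape != (t_n,):
            raise ValueError(
                f"state length {state.shape} does not match panel length {t_n} "
                f"for patient {p.patient_id!r}"
            )
        t0 = min(start, t_n)
        if t_n - gap <= t0:
            continue
        t_idx = np.arange(t0, t_n - gap)
        feats.append(p.coefficients[:, t_idx].T)
        labs.append(state[t_idx + gap])
        pids.append(np.full(t_idx.size, p.patient_id, dtype=object))
        times.append(t_idx)

    if feats:
        features = np.concatenate(feats, axis=0)
        labels = np.concatenate(labs).astype(np.int8)
        patient_ids = np.concatenate(pids)
        time_idx = np.concatenate(times)
    else:
        features = np.empty((0, n_channels))
        labels = np.empty(0, dtype=np.int8)
        patient_ids = np.empty(0, dtype=object)
        time_idx = np.empty(0, dtype=int)
    return SupervisedDataset(
        features=features,
        labels=labels,
        gap=gap,
        level=level,
        subgroup_id=subgroup_id,
        patient_ids=patient_ids,
        times=time_idx,
    )
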