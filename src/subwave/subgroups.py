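"""Baseline-variable subgroup discovery and membership resolution.

For every numeric baseline variable (age, height, weight) a shallow
regression tree is fitted against each patient's *state ratio* — the
fraction of their time points spent in state 1.  The accepted split
thresholds become half-open interval rules partitioning that variable's
range; sex contributes a fixed two-category split.  A patient belongs to
exactly one subgroup per baseline variable with a non-missing value, so a
fully observed patient has one membership per variable.

The tree is greedy binary recursive partitioning minimizing the sum of
squared errors, with two acceptance conditions mirroring cost-complexity
pre-pruning: a split must improve the SSE by at least ``complexity`` times
the root-node SSE, and both children must hold at least ``min_leaf``
patients.  Thresholds are midpoints between the adjacent distinct covariate
values straddling the optimal cut; SSE ties break toward the smaller
threshold.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import TreeParams
from .errors import MembershipError, SchemaError
from .simulate import SignalPanel

__all__ = [
    "SplitRule",
    "SubgroupScheme",
    "state_ratio",
    "fit_depth2_tree",
    "build_scheme",
    "scheme_from_thresholds",
    "membership",
]

NUMERIC_VARIABLES = ("age", "height", "weight")
#: Rule ordering within a scheme (matches the conventional reporting order).
VARIABLE_ORDER = ("age", "height", "sex", "weight")


def state_ratio(panel: SignalPanel) -> float:
    """Fraction of a patient's time points in state 1."""
    if panel.n_times < 1:
        raise ValueError("panel has an empty state sequence")
    return float(panel.state.sum()) / panel.n_times


# ---------------------------------------------------------------------------
# depth-2 regression tree
# ---------------------------------------------------------------------------


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best SSE-reducing cut of (x, y), or None.

    Returns ``(delta_sse, threshold)`` where the threshold is the midpoint of
    the straddling distinct x values.  Ties in delta_sse keep the smaller
    threshold (first found while scanning x in increasing order).
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = xs.size
    if n < 2 * min_leaf:
        return None
    csum = np.cumsum(ys)
    csq = np.cumsum(ys * ys)
    total_sum, total_sq = csum[-1], csq[-1]
    best = None
    # candidate cut after position i (left = xs[:i+1]); valid only between
    # distinct x values and with both sides >= min_leaf
    for i in range(min_leaf - 1, n - min_leaf):
        if xs[i] == xs[i + 1]:
            continue
        n_l = i + 1
        n_r = n - n_l
        sse_l = csq[i] - csum[i] ** 2 / n_l
        s_r = total_sum - csum[i]
        sse_r = (total_sq - csq[i]) - s_r**2 / n_r
        children = sse_l + sse_r
        if best is None or children < best[0] - 1e-12:
            best = (children, 0.5 * (xs[i] + xs[i + 1]), i)
    if best is None:
        return None
    sse_parent = total_sq - total_sum**2 / n
    delta = sse_parent - best[0]
    return delta, best[1]


def fit_depth2_tree(
    x: Sequence[float],
    y: Sequence[float],
    complexity: float = 1e-4,
    max_depth: int = 2,
    min_leaf: int = 20,
) -> List[float]:
    """Accepted split thresholds of a shallow SSE-minimizing tree.

    A split (at the root or in a child) is accepted only if its absolute SSE
    reduction is at least ``complexity`` times the *root* SSE and both
    children hold at least ``min_leaf`` observations.  Returns the sorted
    thresholds (0 to 3 values); fewer than ``2 * min_leaf`` observations or a
    constant response yield an empty list.
    """
    TreeParams(complexity=complexity, max_depth=max_depth, min_leaf=min_leaf).validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"x and y must be 1-D of equal length, got {x.shape} and {y.shape}"
        )
    n = x.size
    if n < 2 * min_leaf:
        return []
    root_sse = float(np.sum((y - y.mean()) ** 2))
    if root_sse <= 0.0:
        return []
    min_gain = complexity * root_sse

    thresholds: List[float] = []
    root = _best_split(x, y, min_leaf)
    if root is None or root[0] < min_gain:
        return []
    thresholds.append(root[1])
    if max_depth >= 2:
        left = x < root[1]
        for mask in (left, ~left):
            child = _best_split(x[mask], y[mask], min_leaf)
            if child is not None and child[0] >= min_gain:
                thresholds.append(child[1])
    return sorted(thresholds)


# ---------------------------------------------------------------------------
# subgroup scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitRule:
    """One subgroup rule: a half-open numeric interval or a sex category.

    Numeric rules match ``lo <= value < hi``; category rules match equality
    (a ``category`` of None matches any non-missing value, used when only one
    sex occurs in the cohort).
    """

    subgroup_id: int
    variable: str
    kind: str  # "interval" | "category"
    lo: float = -math.inf
    hi: float = math.inf
    category: str | None = None

    def matches(self, value) -> bool:
        if value is None:
            return False
        if self.kind == "category":
            return self.category is None or value == self.category
        try:
            v = float(value)
        except (TypeError, ValueError):
            return False
        if math.isnan(v):
            return False
        return self.lo <= v < self.hi

    def describe(self) -> str:
        if self.kind == "category":
            return f"{self.variable} = {self.category if self.category else 'any'}"
        if math.isinf(self.lo) and math.isinf(self.hi):
            return f"{self.variable}: all"
        if math.isinf(self.lo):
            return f"{self.variable} < {self.hi:g}"
        if math.isinf(self.hi):
            return f"{self.lo:g} <= {self.variable}"
        return f"{self.lo:g} <= {self.variable} < {self.hi:g}"


@dataclass
class SubgroupScheme:
    """Ordered list of :class:`SplitRule`; per variable the rules partition
    that variable's domain, so subgroup ids run 1..S."""

    rules: List[SplitRule] = field(default_factory=list)

    @property
    def n_subgroups(self) -> int:
        return len(self.rules)

    @property
    def variables(self) -> List[str]:
        seen: List[str] = []
        for r in self.rules:
            if r.variable not in seen:
                seen.append(r.variable)
        return seen

    @property
    def n_baseline_vars(self) -> int:
        return len(self.variables)

    def rules_for(self, variable: str) -> List[SplitRule]:
        return [r for r in self.rules if r.variable == variable]

    def to_json(self, path) -> None:
        payload = []
        for r in self.rules:
            payload.append(
                {
                    "subgroup_id": r.subgroup_id,
                    "variable": r.variable,
                    "kind": r.kind,
                    "lo": None if math.isinf(r.lo) else r.lo,
                    "hi": None if math.isinf(r.hi) else r.hi,
                    "category": r.category,
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"rules": payload}, fh, indent=2)

    @staticmethod
    def from_json(path) -> "SubgroupScheme":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if "rules" not in payload:
            raise SchemaError("scheme file lacks a 'rules' key")
        rules = []
        for r in payload["rules"]:
            rules.append(
                SplitRule(
                    subgroup_id=int(r["subgroup_id"]),
                    variable=r["variable"],
                    kind=r["kind"],
                    lo=-math.inf if r.get("lo") is None else float(r["lo"]),
                    hi=math.inf if r.get("hi") is None else float(r["hi"]),
                    category=r.get("category"),
                )
            )
        return SubgroupScheme(rules=rules)


def _interval_rules(variable: str, thresholds: Sequence[float], start_id: int):
    edges = [-math.inf, *sorted(thresholds), math.inf]
    return [
        SplitRule(
            subgroup_id=start_id + i,
            variable=variable,
            kind="interval",
            lo=edges[i],
            hi=edges[i + 1],
        )
        for i in range(len(edges) - 1)
    ]


def scheme_from_thresholds(thresholds: Mapping[str, Sequence]) -> SubgroupScheme:
    """Author a scheme directly from per-variable thresholds/categories.

    ``thresholds`` maps numeric variables to cut points (e.g.
    ``{"age": [38, 53, 68]}``) and optionally ``"sex"`` to its categories.
    Variables are emitted in the order age, height, sex, weight.
    """
    rules: List[SplitRule] = []
    next_id = 1
    for var in VARIABLE_ORDER:
        if var not in thresholds:
            continue
        if var == "sex":
            cats = list(thresholds["sex"])
            if len(cats) >= 2:
                for c in cats:
                    rules.append(
                        SplitRule(next_id, "sex", "category", category=str(c))
                    )
                    next_id += 1
            else:
                rules.append(SplitRule(next_id, "sex", "category", category=None))
                next_id += 1
        else:
            new = _interval_rules(var, [float(t) for t in thresholds[var]], next_id)
            rules.extend(new)
            next_id += len(new)
    return SubgroupScheme(rules=rules)


def build_scheme(
    baselines: pd.DataFrame,
    ratios: Mapping[str, float],
    tree_params: TreeParams | None = None,
) -> SubgroupScheme:
    """Fit one depth-2 tree per numeric baseline variable and assemble rules.

    ``ratios`` maps patient_id to that patient's state ratio.  Variables with
    no accepted split contribute a single all-covering rule; sex contributes
    one rule per occurring category (two when both occur).
    """
    if baselines.empty:
        raise ValueError("empty cohort: no baseline rows")
    missing = [pid for pid in baselines["patient_id"] if pid not in ratios]
    if missing:
        raise ValueError(f"no state ratio for patients: {missing[:5]}")
    params = (tree_params or TreeParams()).validate()
    y_all = baselines["patient_id"].map(ratios).to_numpy(dtype=float)

    per_var_thresholds: Dict[str, List[float]] = {}
    for var in NUMERIC_VARIABLES:
        if var not in baselines.columns:
            continue
        x = pd.to_numeric(baselines[var], errors="coerce").to_numpy(dtype=float)
        ok = ~np.isnan(x)
        per_var_thresholds[var] = fit_depth2_tree(
            x[ok],
            y_all[ok],
            complexity=params.complexity,
            max_depth=params.max_depth,
            min_leaf=params.min_leaf,
        )

    spec: Dict[str, Sequence] = dict(per_var_thresholds)
    if "sex" in baselines.columns:
        cats = sorted({s for s in baselines["sex"].dropna() if s in ("M", "F")},
                      reverse=True)  # M before F
        spec["sex"] = cats if cats else [None]
    return scheme_from_thresholds(spec)


def membership(baseline_row: Mapping[str, object], scheme: SubgroupScheme) -> List[int]:
    """Subgroup ids matching a patient: one per variable with a value.

    Raises :class:`MembershipError` when every scheme variable is missing,
    since such a patient cannot be scored by the aggregated method.
    """
    ids: List[int] = []
    for var in scheme.variables:
        value = baseline_row.get(var)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        matches = [r.subgroup_id for r in scheme.rules_for(var) if r.matches(value)]
        if len(matches) > 1:
            raise ValueError(
                f"rules for {var!r} are not a partition: value {value!r} "
                f"matches subgroups {matches}"
            )
        if matches:
            ids.append(matches[0])
    if not ids:
        raise MembershipError(
            "patient matches no subgroup: all baseline values missing"
        )
    return ids
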