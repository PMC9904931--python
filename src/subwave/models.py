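"""Per-subgroup boosted-tree classifiers and the aggregated prediction rule.

One gradient-boosted binary classifier is trained per subgroup, plus one
*global* model on the pooled data (the "original" method).  The aggregated
prediction for a patient is the unweighted mean of the probabilities of the
m subgroup models the patient belongs to (one per baseline variable with a
value); the label is 1 iff that mean is strictly above 0.5.
"""
from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
from xgboost import XGBClassifier

from .config import BoostingParams
from .datasets import SupervisedDataset
from .errors import TrainingError
from .subgroups import SubgroupScheme, membership

__all__ = [
    "SubgroupModelSet",
    "PredictionResult",
    "train_all",
    "predict_aggregated",
    "predict_original",
    "save_model_set",
    "load_model_set",
]


@dataclass
class SubgroupModelSet:
    """Trained classifier per subgroup plus one global model, at one (j, g)."""

    models: Dict[int, object]  # subgroup id -> classifier
    global_model: object
    level: int
    gap: int
    hyperparams: BoostingParams
    train_seed: int

    @property
    def n_models(self) -> int:
        return len(self.models) + 1


@dataclass(frozen=True)
class PredictionResult:
    """One prediction: probability, 0.5-thresholded label, and provenance."""

    probability: float
    label: int
    m: int
    contributing_ids: tuple = ()


def _new_classifier(hyperparams: BoostingParams, seed: int) -> XGBClassifier:
    return XGBClassifier(
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        **hyperparams.xgb_kwargs(),
    )


def train_all(
    datasets: Mapping[int, SupervisedDataset],
    global_dataset: SupervisedDataset,
    hyperparams: BoostingParams | None = None,
    seed: int = 0,
) -> SubgroupModelSet:
    """Fit one boosted classifier per subgroup dataset plus the global model.

    Deterministic given the datasets, hyperparameters and seed.  Raises
    :class:`TrainingError` naming the subgroup when a dataset is empty or
    contains a single label class.
    """
    hp = (hyperparams or BoostingParams()).validate()
    levels = {d.level for d in datasets.values()} | {global_dataset.level}
    if len(levels) > 1:
        raise TrainingError(f"datasets mix smoothing levels: {sorted(levels)}")
    gaps = {d.gap for d in datasets.values()} | {global_dataset.gap}
    if len(gaps) > 1:
        raise TrainingError(f"datasets mix prediction gaps: {sorted(gaps)}")

    def fit(ds: SupervisedDataset, name: str):
        if ds.n_rows == 0:
            raise TrainingError(f"dataset for {name} is empty")
        if not ds.has_both_classes():
            raise TrainingError(f"dataset for {name} contains a single label class")
        clf = _new_classifier(hp, seed)
        clf.fit(ds.features, ds.labels)
        return clf

    models = {sid: fit(ds, f"subgroup {sid}") for sid, ds in sorted(datasets.items())}
    global_model = fit(global_dataset, "the global model")
    return SubgroupModelSet(
        models=models,
        global_model=global_model,
        level=global_dataset.level,
        gap=global_dataset.gap,
        hyperparams=hp,
        train_seed=seed,
    )


def _proba(model, features: np.ndarray) -> np.ndarray:
    """Positive-class probabilities for an (R, K) feature matrix."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return np.asarray(model.predict_proba(features))[:, 1]


def predict_aggregated(
    modelset: SubgroupModelSet,
    scheme: SubgroupScheme,
    baseline_row: Mapping[str, object],
    features: Sequence[float],
) -> PredictionResult:
    """Membership-averaged prediction for one feature vector.

    The probability is the unweighted mean over the m subgroup models
    matching the patient's baseline values; the label uses the strict
    ``> 0.5`` rule (exactly 0.5 maps to 0).
    """
    ids = membership(baseline_row, scheme)
    probs = [float(_proba(modelset.models[s], features)[0]) for s in ids]
    p = float(np.mean(probs))
    return PredictionResult(
        probability=p, label=int(p > 0.5), m=len(ids), contributing_ids=tuple(ids)
    )


def predict_original(
    modelset: SubgroupModelSet, features: Sequence[float]
) -> PredictionResult:
    """Prediction from the single global model (m recorded as 0)."""
    p = float(_proba(modelset.global_model, features)[0])
    return PredictionResult(probability=p, label=int(p > 0.5), m=0)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def scheme_hash(scheme: SubgroupScheme) -> str:
    text = json.dumps(
        [(r.subgroup_id, r.variable, r.kind, r.lo, r.hi, r.category)
         for r in scheme.rules],
        default=str,
    )
    return hashlib.sha256(text.encode()).hexdigest()[:16]


class _BoosterClassifier:
    """Minimal predict_proba adapter around a raw loaded booster."""

    def __init__(self, booster):
        self._booster = booster

    def get_booster(self):
        return self._booster

    @property
    def n_features_in_(self) -> int:
        return self._booster.num_features()

    def predict_proba(self, features) -> np.ndarray:
        import xgboost

        mat = xgboost.DMatrix(np.atleast_2d(np.asarray(features, dtype=float)))
        p = self._booster.predict(mat, validate_features=False)
        return np.column_stack([1.0 - p, p])


def save_model_set(
    modelset: SubgroupModelSet, directory, scheme: SubgroupScheme | None = None
) -> None:
    """Write each booster in its native JSON format plus a metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, model in modelset.models.items():
        model.get_booster().save_model(directory / f"subgroup_{sid:03d}.ubj.json")
    modelset.global_model.get_booster().save_model(directory / "global.ubj.json")
    meta = {
        "level": modelset.level,
        "gap": modelset.gap,
        "train_seed": modelset.train_seed,
        "subgroup_ids": sorted(modelset.models),
        "hyperparams": modelset.hyperparams.__dict__,
        "scheme_hash": scheme_hash(scheme) if scheme is not None else None,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_model_set(directory) -> SubgroupModelSet:
    import xgboost

    def load(path) -> _BoosterClassifier:
        booster = xgboost.Booster()
        booster.load_model(path)
        return _BoosterClassifier(booster)

    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    hp = BoostingParams(**meta["hyperparams"])
    models: Dict[int, object] = {
        sid: load(directory / f"subgroup_{sid:03d}.ubj.json")
        for sid in meta["subgroup_ids"]
    }
    global_model = load(directory / "global.ubj.json")
    return SubgroupModelSet(
        models=models,
        global_model=global_model,
        level=meta["level"],
        gap=meta["gap"],
        hyperparams=hp,
        train_seed=meta["train_seed"],
    )
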