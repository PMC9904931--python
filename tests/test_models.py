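"""Subgroup model training and the membership-averaged prediction rule."""
import numpy as np
import pytest

from subwave import (
    SupervisedDataset,
    TrainingError,
    predict_aggregated,
    predict_original,
    scheme_from_thresholds,
    train_all,
)
from subwave.config import BoostingParams
from subwave.models import SubgroupModelSet, load_model_set, save_model_set


def _dataset(features, labels, subgroup_id=None, level=0, gap=1):
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    return SupervisedDataset(
        features=features,
        labels=labels,
        gap=gap,
        level=level,
        subgroup_id=subgroup_id,
        patient_ids=np.array(["p"] * len(labels), dtype=object),
        times=np.arange(len(labels)),
    )


def _random_dataset(rng, n=300, k=3, subgroup_id=None):
    x = rng.normal(size=(n, k))
    y = (x[:, 0] + 0.3 * rng.normal(size=n) > 0).astype(int)
    return _dataset(x, y, subgroup_id=subgroup_id)


class _StubModel:
    """Fixed-probability classifier used to pin down the aggregation rule."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, features):
        n = np.atleast_2d(features).shape[0]
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])


def _stub_modelset(probs, global_p=0.5):
    return SubgroupModelSet(
        models={i + 1: _StubModel(p) for i, p in enumerate(probs)},
        global_model=_StubModel(global_p),
        level=0,
        gap=1,
        hyperparams=BoostingParams(),
        train_seed=0,
    )


# scheme with one all-covering rule per variable: ids age=1, height=2,
# sex=3 (any), weight=4
FLAT_SCHEME = scheme_from_thresholds(
    {"age": [], "height": [], "sex": ["M"], "weight": []}
)
FULL_ROW = {"age": 50, "height": 170, "sex": "M", "weight": 70}


class TestTrainAll:
    def test_thirteen_subgroups_plus_global_is_fourteen_models(
        self, rng, fast_boosting
    ):
        datasets = {
            sid: _random_dataset(rng, n=120, subgroup_id=sid)
            for sid in range(1, 14)
        }
        modelset = train_all(datasets, _random_dataset(rng, n=200), fast_boosting)
        assert modelset.n_models == 14

    def test_degenerate_scheme_gives_five_models(self, rng, fast_boosting):
        datasets = {
            sid: _random_dataset(rng, n=80, subgroup_id=sid) for sid in range(1, 5)
        }
        modelset = train_all(datasets, _random_dataset(rng, n=80), fast_boosting)
        assert modelset.n_models == 5

    def test_training_is_deterministic(self, rng, fast_boosting):
        datasets = {1: _random_dataset(rng, n=200, subgroup_id=1)}
        global_ds = _random_dataset(rng, n=200)
        probe = rng.normal(size=(50, 3))
        a = train_all(datasets, global_ds, fast_boosting, seed=3)
        b = train_all(datasets, global_ds, fast_boosting, seed=3)
        np.testing.assert_array_equal(
            a.models[1].predict_proba(probe), b.models[1].predict_proba(probe)
        )
        np.testing.assert_array_equal(
            a.global_model.predict_proba(probe),
            b.global_model.predict_proba(probe),
        )

    def test_single_class_dataset_names_the_subgroup(self, rng, fast_boosting):
        bad = _dataset(rng.normal(size=(50, 3)), np.zeros(50, dtype=int),
                       subgroup_id=7)
        good = _random_dataset(rng)
        with pytest.raises(TrainingError, match="subgroup 7"):
            train_all({7: bad}, good, fast_boosting)

    def test_empty_dataset_rejected(self, rng, fast_boosting):
        empty = _dataset(np.empty((0, 3)), np.empty(0, dtype=int), subgroup_id=2)
        with pytest.raises(TrainingError, match="subgroup 2"):
            train_all({2: empty}, _random_dataset(rng), fast_boosting)


class TestAggregatedPrediction:
    def test_identical_outputs_aggregate_to_themselves(self):
        ms = _stub_modelset([0.6, 0.6, 0.6, 0.6])
        res = predict_aggregated(ms, FLAT_SCHEME, FULL_ROW, [0.0, 0.0])
        assert res.probability == pytest.approx(0.6)
        assert res.label == 1 and res.m == 4

    def test_mean_of_distinct_outputs_and_strict_threshold(self):
        ms = _stub_modelset([0.2, 0.4, 0.6, 0.8])
        res = predict_aggregated(ms, FLAT_SCHEME, FULL_ROW, [0.0, 0.0])
        assert res.probability == pytest.approx(0.5)
        assert res.label == 0  # strictly greater than 0.5 required

    def test_missing_baselines_reduce_to_singleton_mean(self):
        ms = _stub_modelset([0.2, 0.4, 0.6, 0.8])
        row = {"age": 50, "height": None, "sex": None, "weight": None}
        res = predict_aggregated(ms, FLAT_SCHEME, row, [0.0])
        assert res.m == 1
        assert res.probability == pytest.approx(0.2)
        assert res.contributing_ids == (1,)

    def test_aggregate_bounded_by_contributors(self, rng, fast_boosting):
        datasets = {
            sid: _random_dataset(rng, n=150, subgroup_id=sid) for sid in (1, 2, 3, 4)
        }
        ms = train_all(datasets, _random_dataset(rng, n=150), fast_boosting)
        for _ in range(20):
            feats = rng.normal(size=3)
            res = predict_aggregated(ms, FLAT_SCHEME, FULL_ROW, feats)
            probs = [
                float(ms.models[s].predict_proba(feats.reshape(1, -1))[0, 1])
                for s in res.contributing_ids
            ]
            assert min(probs) - 1e-12 <= res.probability <= max(probs) + 1e-12


class TestOriginalPrediction:
    def test_probability_in_range_and_m_zero(self, rng, fast_boosting):
        ms = train_all({}, _random_dataset(rng), fast_boosting)
        res = predict_original(ms, rng.normal(size=3))
        assert 0.0 <= res.probability <= 1.0
        assert res.m == 0

    def test_identical_rows_get_identical_probabilities(self, rng, fast_boosting):
        ms = train_all({}, _random_dataset(rng), fast_boosting)
        feats = rng.normal(size=3)
        assert predict_original(ms, feats) == predict_original(ms, feats)

    def test_separable_labels_recovered_on_held_out_rows(self, rng):
        x = rng.normal(size=(3000, 4))
        y = (x[:, 0] > 0).astype(int)
        train = _dataset(x[:2000], y[:2000])
        ms = train_all({}, train, BoostingParams(n_estimators=50, max_depth=3))
        probs = ms.global_model.predict_proba(x[2000:])[:, 1]
        accuracy = ((probs > 0.5).astype(int) == y[2000:]).mean()
        assert accuracy > 0.95


def test_model_set_round_trips_through_disk(tmp_path, rng, fast_boosting):
    datasets = {1: _random_dataset(rng, subgroup_id=1)}
    ms = train_all(datasets, _random_dataset(rng), fast_boosting, seed=5)
    save_model_set(ms, tmp_path / "models", FLAT_SCHEME)
    back = load_model_set(tmp_path / "models")
    probe = rng.normal(size=(20, 3))
    np.testing.assert_allclose(
        back.models[1].predict_proba(probe), ms.models[1].predict_proba(probe)
    )
    np.testing.assert_allclose(
        back.global_model.predict_proba(probe),
        ms.global_model.predict_proba(probe),
    )
    assert (back.level, back.gap, back.train_seed) == (ms.level, ms.gap, 5)
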