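"""Metrics, selection-frequency importance, and the evaluation grid."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from subwave import (
    MetricUndefinedError,
    SupervisedDataset,
    auc,
    confusion_metrics,
    run_grid,
    split_patients,
    train_all,
    variable_importance,
)
from subwave.config import BoostingParams
from subwave.study import STUDY_TREE
from subwave.subgroups import build_scheme, state_ratio

from _oracles import allpairs_auc


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.0, 0.0, 1.0, 1.0]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc([0, 1, 0, 1], [0.3] * 4) == 0.5

    def test_worked_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(MetricUndefinedError):
            auc([1, 1], [0.2, 0.4])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_allpairs_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        # discrete scores force ties
        s = rng.choice([0.1, 0.25, 0.5, 0.5, 0.75, 0.9], size=n)
        got = auc(y, s)
        assert got == pytest.approx(allpairs_auc(y, s), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_complementation_identity(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert auc(y, s) + auc(y, -s) == pytest.approx(1.0)

    def test_invariance_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert auc(y, np.exp(3 * s) + 1) == pytest.approx(auc(y, s))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1, 1])
        r = confusion_metrics(y, y)
        assert (r.sensitivity, r.specificity, r.f1) == (1.0, 1.0, 1.0)

    def test_formula_example(self):
        y = np.concatenate([np.ones(10, int), np.zeros(90, int)])
        p = np.concatenate(
            [np.ones(8, int), np.zeros(2, int), np.ones(2, int), np.zeros(88, int)]
        )
        r = confusion_metrics(y, p)
        assert (r.tp, r.fp, r.fn, r.tn) == (8, 2, 2, 88)
        assert r.f1 == pytest.approx(16 / 20)
        assert r.sensitivity == pytest.approx(0.8)

    def test_sensitivity_count_ratio(self):
        y = np.array([1, 1, 1, 1, 0])
        p = np.array([1, 1, 1, 0, 0])
        assert confusion_metrics(y, p).sensitivity == pytest.approx(0.75)

    def test_f1_zero_when_no_true_positives(self):
        y = np.array([1, 0, 0])
        p = np.array([0, 1, 0])
        assert confusion_metrics(y, p).f1 == 0.0

    def test_f1_is_harmonic_mean_of_precision_and_sensitivity(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=40)
            p = rng.integers(0, 2, size=40)
            if y.min() == y.max() or (p == 1).sum() == 0:
                continue
            r = confusion_metrics(y, p)
            if r.tp == 0:
                continue
            precision = r.tp / (r.tp + r.fp)
            harmonic = 2 / (1 / precision + 1 / r.sensitivity)
            assert r.f1 == pytest.approx(harmonic)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(MetricUndefinedError, match="sensitivity"):
            confusion_metrics([0, 0], [0, 1])
        with pytest.raises(MetricUndefinedError, match="specificity"):
            confusion_metrics([1, 1], [0, 1])


class TestVariableImportance:
    def _dataset(self, rng, informative_only=True):
        n = 400
        x = np.zeros((n, 4))
        x[:, 2] = rng.normal(size=n)  # v3 is the only non-constant channel
        if not informative_only:
            x = rng.normal(size=(n, 4))
        y = (x[:, 2] > 0).astype(int)
        return SupervisedDataset(
            features=x, labels=y, gap=1, level=0, subgroup_id=None,
            patient_ids=np.array(["p"] * n, dtype=object), times=np.arange(n),
        )

    def test_single_informative_variable_takes_all_frequency(self, rng):
        ms = train_all({}, self._dataset(rng),
                       BoostingParams(n_estimators=20, max_depth=2))
        table = variable_importance(ms, "original")
        freq = dict(zip(table["variable"], table["frequency"]))
        assert freq["v3"] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self, rng, fast_boosting):
        ms = train_all({}, self._dataset(rng, informative_only=False),
                       fast_boosting)
        table = variable_importance(ms, "original")
        assert table["frequency"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_tree_dump_traversal(self, rng):
        ms = train_all({}, self._dataset(rng, informative_only=False),
                       BoostingParams(n_estimators=15, max_depth=3))
        table = variable_importance(ms, "original")
        dump = ms.global_model.get_booster().trees_to_dataframe()
        splits = dump[dump["Feature"] != "Leaf"]
        oracle = splits["Feature"].value_counts(normalize=True)
        for var, freq in zip(table["variable"], table["frequency"]):
            feat = f"f{int(var[1:]) - 1}"
            assert freq == pytest.approx(float(oracle.get(feat, 0.0)), abs=1e-9)


@pytest.fixture(scope="module")
def scheme(tiny_cohort):
    ratios = {p.patient_id: state_ratio(p) for p in tiny_cohort.panels}
    return build_scheme(tiny_cohort.baselines, ratios, STUDY_TREE)


class TestGrid:
    def test_split_is_by_patient_and_seeded(self):
        ids = [f"p{i}" for i in range(10)]
        train, val = split_patients(ids, seed=1, val_fraction=0.3)
        assert sorted(train + val) == sorted(ids)
        assert len(val) == 3
        assert (train, val) == split_patients(ids, seed=1, val_fraction=0.3)

    def test_grid_cardinality_and_determinism(
        self, tiny_cohort, scheme, fast_boosting
    ):
        a = run_grid(tiny_cohort, scheme, [0, 2], [1, 5], fast_boosting, seed=2)
        assert len(a) == 8  # 2 levels x 2 gaps x 2 methods
        assert set(a["method"]) == {"aggregated", "original"}
        b = run_grid(tiny_cohort, scheme, [2, 0], [5, 1], fast_boosting, seed=2)
        pd.testing.assert_frame_equal(
            a.sort_values(["level", "gap", "method"]).reset_index(drop=True),
            b.sort_values(["level", "gap", "method"]).reset_index(drop=True),
        )

    def test_empty_grid_rejected(self, tiny_cohort, scheme, fast_boosting):
        with pytest.raises(ValueError, match="non-empty"):
            run_grid(tiny_cohort, scheme, [], [1], fast_boosting)
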