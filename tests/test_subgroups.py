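"""Subgroup discovery: state ratios, the shallow tree, schemes, membership."""
import math

import numpy as np
import pandas as pd
import pytest

from subwave import (
    MembershipError,
    SignalPanel,
    build_scheme,
    fit_depth2_tree,
    membership,
    scheme_from_thresholds,
    state_ratio,
)
from subwave.config import TreeParams
from subwave.subgroups import SubgroupScheme

from _oracles import exhaustive_depth2_tree

PAPER_THRESHOLDS = {
    "age": (38, 53, 68),
    "height": (173, 183, 188),
    "sex": ("M", "F"),
    "weight": (63, 93),
}


def _panel(states):
    states = np.asarray(states)
    return SignalPanel(
        patient_id="p", channels=np.zeros((1, states.size)), state=states
    )


class TestStateRatio:
    @pytest.mark.parametrize(
        "states,expected",
        [
            (np.zeros(100, dtype=int), 0.0),
            (np.ones(7, dtype=int), 1.0),
            ([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], 0.3),
        ],
    )
    def test_ratio(self, states, expected):
        assert state_ratio(_panel(states)) == pytest.approx(expected)


class TestFitDepth2Tree:
    def test_constant_response_yields_no_split(self):
        assert fit_depth2_tree([1, 2, 3, 4], [0.5] * 4, min_leaf=1) == []

    def test_single_step_midpoint(self):
        thr = fit_depth2_tree([40, 45, 55, 60], [0, 0, 1, 1], min_leaf=1)
        assert thr == [50.0]

    def test_three_bands_recover_both_boundaries(self):
        x = np.concatenate([np.arange(20), 30 + np.arange(20), 60 + np.arange(20)])
        y = np.repeat([0.1, 0.5, 0.9], 20)
        thr = fit_depth2_tree(x, y, min_leaf=5)
        assert len(thr) == 2
        assert 19 < thr[0] < 30 and 49 < thr[1] < 60

    def test_too_few_patients_returns_empty(self):
        assert fit_depth2_tree([1, 2, 3], [0, 1, 0], min_leaf=2) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            fit_depth2_tree([1, 2], [1.0], min_leaf=1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        x = np.round(rng.uniform(0, 100, size=n), 1)
        cuts = np.sort(rng.uniform(10, 90, size=rng.integers(1, 3)))
        y = np.zeros(n)
        for c in cuts:
            y += 0.3 * (x >= c)
        y += rng.normal(0, 0.05, size=n)
        for min_leaf in (5, 10):
            got = fit_depth2_tree(x, y, complexity=1e-4, min_leaf=min_leaf)
            want = exhaustive_depth2_tree(x, y, complexity=1e-4, min_leaf=min_leaf)
            assert got == pytest.approx(want)

    def test_complexity_monotonicity(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 100, size=150)
        y = 0.2 * (x > 40) + 0.3 * (x > 70) + rng.normal(0, 0.1, size=150)
        counts = [
            len(fit_depth2_tree(x, y, complexity=c, min_leaf=10))
            for c in (0.0, 1e-4, 1e-2, 0.1, 0.5, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestScheme:
    def test_published_thresholds_yield_13_rules(self):
        scheme = scheme_from_thresholds(PAPER_THRESHOLDS)
        assert scheme.n_subgroups == 13
        assert scheme.n_baseline_vars == 4
        assert [len(scheme.rules_for(v)) for v in ("age", "height", "sex", "weight")] \
            == [4, 4, 2, 3]

    def test_no_split_variable_gets_one_covering_rule(self):
        scheme = scheme_from_thresholds({"age": [], "sex": ("M", "F")})
        age_rules = scheme.rules_for("age")
        assert len(age_rules) == 1
        assert math.isinf(age_rules[0].lo) and math.isinf(age_rules[0].hi)

    def test_build_scheme_recovers_age_step_only(self):
        rng = np.random.default_rng(42)
        n = 200
        baselines = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "age": rng.uniform(18, 90, size=n),
                "sex": rng.choice(["M", "F"], size=n),
                "weight": rng.uniform(45, 120, size=n),
                "height": rng.uniform(150, 200, size=n),
            }
        )
        ratios = {
            row.patient_id: 0.1 + 0.4 * (row.age >= 50.0)
            for row in baselines.itertuples()
        }
        # complexity well above the chance-level SSE reduction a spurious
        # split can reach on 200 patients, but far below the age step's
        scheme = build_scheme(
            baselines, ratios, TreeParams(complexity=0.1, min_leaf=20)
        )
        age_rules = scheme.rules_for("age")
        assert len(age_rules) >= 2
        finite = [r.hi for r in age_rules if math.isfinite(r.hi)]
        assert any(abs(t - 50.0) < 2.0 for t in finite)
        assert len(scheme.rules_for("height")) == 1
        assert len(scheme.rules_for("weight")) == 1

    def test_json_round_trip(self, tmp_path):
        scheme = scheme_from_thresholds(PAPER_THRESHOLDS)
        path = tmp_path / "scheme.json"
        scheme.to_json(path)
        back = SubgroupScheme.from_json(path)
        assert back.rules == scheme.rules

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            build_scheme(pd.DataFrame(columns=["patient_id"]), {})


class TestMembership:
    scheme = scheme_from_thresholds(PAPER_THRESHOLDS)

    def test_fully_observed_patient_has_one_id_per_variable(self):
        ids = membership(
            {"age": 35, "height": 170, "sex": "M", "weight": 60}, self.scheme
        )
        assert ids == [1, 5, 9, 11]  # age<38, height<173, sex=M, weight<63

    def test_missing_baselines_reduce_m(self):
        ids = membership(
            {"age": 70, "height": None, "sex": None, "weight": float("nan")},
            self.scheme,
        )
        assert ids == [4]  # 68 <= age

    def test_boundary_value_falls_in_upper_interval(self):
        ids = membership({"age": 38}, self.scheme)
        assert ids == [2]  # 38 <= age < 53

    def test_all_missing_raises(self):
        with pytest.raises(MembershipError):
            membership({"age": None}, self.scheme)

    def test_partition_property_random_rows(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            row = {
                "age": rng.uniform(0, 120),
                "height": rng.uniform(100, 230),
                "sex": rng.choice(["M", "F"]),
                "weight": rng.uniform(20, 200),
            }
            for var in self.scheme.variables:
                hits = [
                    r for r in self.scheme.rules_for(var) if r.matches(row[var])
                ]
                assert len(hits) == 1
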