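"""Fuzzy membership functions, aggregation, grading, quantile schemes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfce.ahp import WeightVector
from pfce.exceptions import SchemeError, StructureError
from pfce.fuzzy_eval import (
    GRADE_VALUES,
    GradeScheme,
    build_R,
    default_grade_scheme,
    evaluate,
    membership,
)
from pfce.trial_data import IndicatorMeta, TrialTable, factorial_design

POS = GradeScheme("x", "positive", (10.0, 8.0, 6.0, 4.0, 2.0))
NEG = GradeScheme("x", "negative", (2.0, 4.0, 6.0, 8.0, 10.0))


@st.composite
def scheme_and_value(draw):
    orientation = draw(st.sampled_from(["positive", "negative"]))
    base = draw(st.floats(-100, 100))
    gaps = draw(
        st.lists(st.floats(0.1, 50), min_size=4, max_size=4)
    )
    thresholds = [base]
    for g in gaps:
        thresholds.append(thresholds[-1] - g)
    if orientation == "negative":
        thresholds = thresholds[::-1]
    x = draw(st.floats(min(thresholds) - 20, max(thresholds) + 20))
    return GradeScheme("x", orientation, tuple(thresholds)), x


class TestMembership:
    def test_saturation_at_best_grade(self):
        np.testing.assert_allclose(membership(12.0, POS), [1, 0, 0, 0, 0])
        np.testing.assert_allclose(membership(10.0, POS), [1, 0, 0, 0, 0])

    def test_apex_at_interior_threshold(self):
        np.testing.assert_allclose(membership(6.0, POS), [0, 0, 1, 0, 0])

    def test_midpoint_splits_membership_evenly(self):
        np.testing.assert_allclose(membership(9.0, POS), [0.5, 0.5, 0, 0, 0])

    def test_saturation_at_worst_grade(self):
        np.testing.assert_allclose(membership(1.0, POS), [0, 0, 0, 0, 1])

    def test_negative_orientation_mirrors_positive(self):
        np.testing.assert_allclose(membership(1.0, NEG), [1, 0, 0, 0, 0])
        np.testing.assert_allclose(membership(6.0, NEG), [0, 0, 1, 0, 0])
        np.testing.assert_allclose(membership(3.0, NEG), [0.5, 0.5, 0, 0, 0])
        np.testing.assert_allclose(membership(11.0, NEG), [0, 0, 0, 0, 1])

    @pytest.mark.parametrize(
        "orientation,thresholds",
        [
            ("positive", (10, 8, 8, 4, 2)),  # tie
            ("positive", (2, 4, 6, 8, 10)),  # wrong direction
            ("negative", (10, 8, 6, 4, 2)),
        ],
    )
    def test_non_monotone_thresholds_rejected(self, orientation, thresholds):
        with pytest.raises(SchemeError):
            GradeScheme("x", orientation, tuple(float(t) for t in thresholds))

    @settings(max_examples=300, derandomize=True)
    @given(scheme_and_value())
    def test_partition_of_unity(self, pair):
        scheme, x = pair
        row = membership(x, scheme)
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(row >= 0) and np.all(row <= 1)

    def test_positive_monotonicity_of_implied_row_score(self):
        xs = np.linspace(0.0, 12.0, 241)
        scores = [membership(x, POS) @ GRADE_VALUES for x in xs]
        assert np.all(np.diff(scores) >= -1e-12)


class TestBuildRAndEvaluate:
    def test_rows_match_individual_membership(self):
        values = {"a": 9.0, "b": 3.0}
        schemes = {"a": GradeScheme("a", "positive", POS.thresholds), "b": NEG}
        r = build_R(values, schemes)
        np.testing.assert_allclose(r.values[0], membership(9.0, schemes["a"]))
        np.testing.assert_allclose(r.values[1], membership(3.0, schemes["b"]))

    def test_missing_scheme_rejected(self):
        with pytest.raises(StructureError, match="no grade scheme"):
            build_R({"a": 1.0}, {})

    def test_all_excellent_gives_score_five(self):
        schemes = {f"i{k}": GradeScheme(f"i{k}", "positive", POS.thresholds) for k in range(3)}
        r = build_R({f"i{k}": 11.0 for k in range(3)}, schemes)
        w = WeightVector.from_values(list(schemes), [0.2, 0.3, 0.5])
        res = evaluate(w, r)
        np.testing.assert_allclose(res.B, [1, 0, 0, 0, 0])
        assert res.grade == "Excellent"
        assert res.score == 5.0

    def test_uniform_memberships_score_three(self):
        # five indicators sitting exactly at the five grade apexes
        schemes = {f"i{k}": GradeScheme(f"i{k}", "positive", POS.thresholds) for k in range(5)}
        xs = dict(zip(schemes, [10.0, 8.0, 6.0, 4.0, 2.0]))
        r = build_R(xs, schemes)
        w = WeightVector.from_values(list(schemes), [0.2] * 5)
        res = evaluate(w, r)
        np.testing.assert_allclose(res.B, [0.2] * 5)
        assert res.score == pytest.approx(3.0)

    def test_hand_weighted_average(self):
        schemes = {
            "a": GradeScheme("a", "positive", POS.thresholds),
            "b": GradeScheme("b", "positive", POS.thresholds),
        }
        r = build_R({"a": 11.0, "b": 8.0}, schemes)  # rows e1 and e2
        res = evaluate(WeightVector.from_values(["a", "b"], [0.5, 0.5]), r)
        np.testing.assert_allclose(res.B, [0.5, 0.5, 0, 0, 0])
        assert res.score == pytest.approx(4.5)
        assert res.grade == "Excellent"  # tie resolved toward the better grade
        assert res.tie

    def test_dimension_mismatch_rejected(self):
        r = build_R({"a": 11.0}, {"a": POS})
        with pytest.raises(StructureError):
            evaluate(WeightVector.from_values(["a", "b"], [0.5, 0.5]), r)

    def test_score_bounded_and_clamp_inactive(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 8))
            schemes = {
                f"i{k}": GradeScheme(f"i{k}", "positive", POS.thresholds)
                for k in range(n)
            }
            xs = {k: float(rng.uniform(-2, 14)) for k in schemes}
            w = WeightVector.from_values(list(schemes), rng.dirichlet(np.ones(n)))
            res = evaluate(w, build_R(xs, schemes))
            assert 1.0 - 1e-9 <= res.score <= 5.0 + 1e-9
            assert not res.clamped
            assert res.B.sum() == pytest.approx(1.0, abs=1e-9)


class TestDefaultGradeScheme:
    def _table(self, values, orientation="positive"):
        n = len(values)
        treatments = list(factorial_design())[:n]
        meta = {"a": IndicatorMeta("a", "a", orientation)}
        return TrialTable(
            "x",
            pd.DataFrame({"a": values}, index=treatments),
            {t: factorial_design()[t] for t in treatments},
            meta,
        )

    def test_quantile_thresholds_positive(self):
        values = list(np.arange(1.0, 11.0))
        scheme = default_grade_scheme(self._table(values))["a"]
        expected = np.quantile(values, [0.9, 0.7, 0.5, 0.3, 0.1])
        np.testing.assert_allclose(scheme.thresholds, expected)

    def test_quantile_thresholds_negative_reversed(self):
        values = list(np.arange(1.0, 11.0))
        scheme = default_grade_scheme(self._table(values, "negative"))["a"]
        expected = np.quantile(values, [0.1, 0.3, 0.5, 0.7, 0.9])
        np.testing.assert_allclose(scheme.thresholds, expected)

    def test_two_distinct_values_jittered_with_warning(self):
        with pytest.warns(UserWarning, match="epsilon jitter"):
            scheme = default_grade_scheme(self._table([1.0, 1.0, 2.0]))["a"]
        assert np.all(np.diff(scheme.thresholds) < 0)

    def test_constant_indicator_rejected(self):
        with pytest.raises(SchemeError, match="constant"):
            default_grade_scheme(self._table([3.0, 3.0, 3.0]))
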