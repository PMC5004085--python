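"""Monotonicity, slope classification and sensitivity-group summaries."""

import numpy as np
import pytest

from famscape.family_analysis import build_families
from famscape.gridspace import GridSpec, InstanceRecord, ParameterPoint
from famscape.sensitivity import (
    FamilyCurve,
    average_change,
    classify_sensitivity,
    group_summary,
    is_monotonic,
)

XS = (0.0, 0.875, 1.75)


def line(slope, intercept=12.0, xs=XS):
    return FamilyCurve(x=xs, y=tuple(intercept + slope * x for x in xs))


class TestMonotonicity:
    @pytest.mark.parametrize(
        "ys, expected",
        [
            ((12, 10, 7, 5), "decreasing"),
            ((5, 7, 6), "non_monotonic"),
            ((5, 5, 6), "increasing"),  # ties are non-strict
            ((3, 4, 9), "increasing"),
        ],
    )
    def test_sign_test(self, ys, expected):
        curve = FamilyCurve(x=tuple(range(len(ys))), y=ys)
        assert is_monotonic(curve) == expected


class TestClassifySensitivity:
    @pytest.mark.parametrize(
        "slope, expected",
        [(-4.0, "high"), (-2.5, "high"), (-1.0, "medium"),
         (-0.4, "low"), (-0.2, "low"), (0.5, "low")],
    )
    def test_linear_curves_by_threshold(self, slope, expected):
        cls = classify_sensitivity(line(slope))
        assert cls.label == expected
        assert cls.max_descent_slope == pytest.approx(slope, abs=1e-9)

    def test_steep_descent_anywhere_triggers_high(self):
        # flat then a steep drop: the max-descent tangent decides
        xs = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75)
        ys = (12.0, 11.9, 11.7, 10.0, 6.0, 5.2, 5.0, 4.9)
        cls = classify_sensitivity(FamilyCurve(x=xs, y=ys))
        assert cls.label == "high"
        assert cls.max_descent_slope < -2.5

    def test_degree_reduced_for_short_curves(self):
        cls = classify_sensitivity(line(-1.0, xs=(0.0, 0.5, 1.0)))
        assert cls.label == "medium"

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            classify_sensitivity(FamilyCurve(x=(0.0, 1.0), y=(1.0, 2.0)))

    def test_collinear_extension_keeps_class(self):
        xs = (0.0, 0.5, 1.0, 1.5)
        base = line(-1.0, xs=xs[:3])
        extended = line(-1.0, xs=xs)
        assert classify_sensitivity(base).label == classify_sensitivity(extended).label

    def test_every_curve_gets_exactly_one_class(self):
        rng = np.random.default_rng(5)
        xs = tuple(np.linspace(0, 1.75, 8))
        for _ in range(25):
            ys = tuple(np.sort(rng.uniform(5, 15, 8))[::-1])
            cls = classify_sensitivity(FamilyCurve(x=xs, y=ys))
            assert cls.label in {"high", "medium", "low"}


class TestAverageChange:
    def test_mean_of_last_minus_first(self):
        curves = [FamilyCurve(x=(0, 1), y=(10.0, 7.0)),
                  FamilyCurve(x=(0, 1), y=(12.0, 7.0))]
        assert average_change(curves) == pytest.approx(-4.0)

    def test_flat_family_zero(self):
        assert average_change([FamilyCurve(x=(0, 1), y=(5.0, 5.0))]) == 0.0

    def test_period_decrease_is_negative(self):
        assert average_change([line(-1.0)]) < 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            average_change([])


class TestGroupSummary:
    def test_counts_equal_direct_tally(self, toy_spec, toy_db):
        rhcos = [r for r in toy_db if r.label == "rHCO"]
        by_point = {r.point: r for r in rhcos}
        fams = [f for f in build_families(rhcos, "x_h", toy_spec) if f.size >= 3]
        classified = []
        for fam in fams[:30]:
            ys = tuple(by_point[fam.member_point(v)].period_s for v in fam.members)
            curve = FamilyCurve(x=fam.members, y=ys, family=fam)
            classified.append((curve, classify_sensitivity(curve)))
        summary = group_summary(classified)
        # tally one class/parameter cell by hand
        label = classified[0][1].label
        want = {}
        for curve, cls in classified:
            if cls.label != label:
                continue
            v = dict(curve.family.context)["x_CaS"]
            want[v] = want.get(v, 0) + 1
        assert summary[label]["x_CaS"] == dict(sorted(want.items()))

    def test_median_marker(self):
        base = ParameterPoint(1, 1, 1, 1, 1, 1, 1, -60.0)
        spec = GridSpec()
        classified = []
        for x_cas in (0.25, 0.5, 1.75):
            group = [InstanceRecord(point=base.replace(x_CaS=x_cas, x_h=v), label="rHCO")
                     for v in (0.25, 0.5, 0.75)]
            (fam,) = build_families(group, "x_h", spec)
            curve = FamilyCurve(x=fam.members, y=(12.0, 10.0, 8.0), family=fam)
            classified.append((curve, classify_sensitivity(curve)))
        summary = group_summary(classified)
        label = classified[0][1].label
        assert summary[label]["x_CaS_median"] == pytest.approx(0.5)

    def test_table3_eight_member_classes_sum_to_census_count(self, fixtures):
        high, med, low = fixtures.table3_counts(8)
        total, _ = fixtures.table1_counts("h", 8)
        assert high + med + low == total == 144
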