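import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from streamhab.centerline import centerline_from_points, medial_axis, sinuosity
from streamhab.mmi import (
    aggregate,
    assess_continuous,
    assess_transects,
    assess_vicinity,
    classify_gradient,
    classify_total,
    score_stations,
    score_value,
)
from streamhab.model import (
    AssessmentConfig,
    CATEGORY_SCORES,
    MetricCategory,
    MetricResult,
    PoolInterval,
    StationRecord,
)
from streamhab.parameters import detect_pools, extract_stations
from streamhab.synthetic import MeanderSpec, PiecewiseProfile, degrade, generate_site

EPS = 1e-9


class TestGradientClass:
    @pytest.mark.parametrize("slope,expected", [
        (0.0023, "M"),   # mild study reach
        (0.02, "M"),     # boundary: strictly greater only
        (0.021, "H"),
        (0.0, "M"),
    ])
    def test_threshold(self, slope, expected):
        assert classify_gradient(slope) == expected

    def test_negative_classified_on_magnitude(self):
        with pytest.warns(UserWarning, match="negative"):
            assert classify_gradient(-0.05) == "H"


# Every printed bin boundary, probed just inside each side.
BIN_CASES = [
    # M2: >=10 / [5,10) / [1,5) / <1
    ("M2", "M", 10.0, "excellent"), ("M2", "M", 10.0 - EPS, "good"),
    ("M2", "M", 5.0, "good"), ("M2", "M", 5.0 - EPS, "fair"),
    ("M2", "M", 1.0, "fair"), ("M2", "M", 1.0 - EPS, "poor"),
    ("M2", "M", 12.0, "excellent"), ("M2", "M", 0.0, "poor"),
    # M3: <0.2 / [0.2,0.5) / [0.5,1) / >=1
    ("M3", "M", 0.2 - EPS, "excellent"), ("M3", "M", 0.2, "good"),
    ("M3", "M", 0.5 - EPS, "good"), ("M3", "M", 0.5, "fair"),
    ("M3", "M", 1.0 - EPS, "fair"), ("M3", "M", 1.0, "poor"),
    # M4: <7 / [7,15) / [15,25) / >=25
    ("M4", "M", 7.0 - EPS, "excellent"), ("M4", "M", 7.0, "good"),
    ("M4", "M", 15.0 - EPS, "good"), ("M4", "M", 15.0, "fair"),
    ("M4", "M", 25.0 - EPS, "fair"), ("M4", "M", 25.0, "poor"),
    ("M4", "M", 26.0, "poor"),
    # M5 high-gradient branch mirrors the M4 thresholds
    ("M5", "H", 7.0 - EPS, "excellent"), ("M5", "H", 7.0, "good"),
    ("M5", "H", 15.0 - EPS, "good"), ("M5", "H", 15.0, "fair"),
    ("M5", "H", 25.0 - EPS, "fair"), ("M5", "H", 25.0, "poor"),
    # M5 mild: >3 / (2,3] / (1,2] / 1
    ("M5", "M", 3.0 + EPS, "excellent"), ("M5", "M", 3.0, "good"),
    ("M5", "M", 2.0 + EPS, "good"), ("M5", "M", 2.0, "fair"),
    ("M5", "M", 1.0 + EPS, "fair"), ("M5", "M", 1.0, "poor"),
    ("M5", "M", 1.09, "fair"),
    # M6: 100 / [75,100) / [25,75) / [0,25)
    ("M6", "M", 100.0, "excellent"), ("M6", "M", 100.0 - 1e-7, "good"),
    ("M6", "M", 75.0, "good"), ("M6", "M", 75.0 - EPS, "fair"),
    ("M6", "M", 25.0, "fair"), ("M6", "M", 25.0 - EPS, "poor"),
    ("M6", "M", 0.0, "poor"),
    # M7 high: >=70 / [40,70) / [20,40) / <20
    ("M7", "H", 70.0, "excellent"), ("M7", "H", 70.0 - EPS, "good"),
    ("M7", "H", 40.0, "good"), ("M7", "H", 40.0 - EPS, "fair"),
    ("M7", "H", 20.0, "fair"), ("M7", "H", 20.0 - EPS, "poor"),
    # M7 mild: >=50 / [30,50) / [10,30) / <10
    ("M7", "M", 50.0, "excellent"), ("M7", "M", 50.0 - EPS, "good"),
    ("M7", "M", 30.0, "good"), ("M7", "M", 30.0 - EPS, "fair"),
    ("M7", "M", 10.0, "fair"), ("M7", "M", 10.0 - EPS, "poor"),
    # M8: >=12 / [7,12) / [2,7) / <2
    ("M8", "M", 12.0, "excellent"), ("M8", "M", 12.0 - EPS, "good"),
    ("M8", "M", 7.0, "good"), ("M8", "M", 7.0 - EPS, "fair"),
    ("M8", "M", 2.0, "fair"), ("M8", "M", 2.0 - EPS, "poor"),
    # M9 non-monotone: (40,60) best, [0,10] and [90,100] worst
    ("M9", "M", 50.0, "excellent"),
    ("M9", "M", 40.0 + 1e-7, "excellent"), ("M9", "M", 60.0 - 1e-7, "excellent"),
    ("M9", "M", 40.0, "good"), ("M9", "M", 60.0, "good"),
    ("M9", "M", 30.0 + 1e-7, "good"), ("M9", "M", 70.0 - 1e-7, "good"),
    ("M9", "M", 30.0, "fair"), ("M9", "M", 70.0, "fair"),
    ("M9", "M", 10.0 + 1e-7, "fair"), ("M9", "M", 90.0 - 1e-7, "fair"),
    ("M9", "M", 10.0, "poor"), ("M9", "M", 90.0, "poor"),
    ("M9", "M", 0.0, "poor"), ("M9", "M", 100.0, "poor"),
    ("M9", "M", 10.68, "fair"),  # study-reach pool fraction
]


@pytest.mark.parametrize("code,grad,value,label", BIN_CASES)
def test_metric_bins_at_boundaries(code, grad, value, label):
    cat = score_value(code, value, grad)
    assert cat.label == label
    assert cat.score == CATEGORY_SCORES[label]


def test_out_of_domain_value_rejected():
    with pytest.raises(ValueError):
        score_value("M9", 101.0, "M")
    with pytest.raises(ValueError):
        score_value("M5", 0.5, "M")


class TestScoreStations:
    def test_all_excellent_buffer(self):
        res = score_stations("M2", [10.0, 11.0, 15.0], None, "M")
        assert res.pct_by_category["excellent"] == pytest.approx(1.0)
        assert res.category.label == "excellent"

    def test_half_half_erosion_weighted_mean(self):
        # half length at E = 0.1 (excellent), half at E = 1.2 (poor)
        res = score_stations("M3", [0.1, 1.2], [0.5, 0.5], "M")
        assert res.pct_by_category == pytest.approx(
            {"excellent": 0.5, "good": 0.0, "fair": 0.0, "poor": 0.5})
        assert res.site_value == pytest.approx(0.65)
        assert res.category.label == "fair"

    def test_single_station_unit_mass(self):
        res = score_stations("M6", [80.0])
        assert res.pct_by_category["good"] == pytest.approx(1.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            score_stations("M2", [])


def _mk(code, label):
    return MetricResult(code=code, category=MetricCategory(label))


def _mk2(code, left, right):
    return MetricResult(code=code, category_per_side={
        "left": MetricCategory(left), "right": MetricCategory(right)})


class TestAggregate:
    def transect_metrics(self):
        return {
            "M2": _mk2("M2", "good", "excellent"),
            "M3": _mk("M3", "fair"), "M4": _mk("M4", "good"),
            "M5": _mk("M5", "fair"), "M6": _mk("M6", "good"),
            "M7": _mk("M7", "poor"), "M8": _mk("M8", "fair"),
            "M9": _mk("M9", "poor"),
        }

    def continuous_metrics(self):
        return {
            "M2": _mk2("M2", "excellent", "excellent"),
            "M3": _mk2("M3", "fair", "fair"), "M4": _mk("M4", "good"),
            "M5": _mk("M5", "fair"), "M6": _mk("M6", "good"),
            "M7": _mk("M7", "poor"), "M8": _mk("M8", "fair"),
            "M9": _mk("M9", "fair"),
        }

    def test_transect_study_total(self):
        total, overall = aggregate(self.transect_metrics())
        assert total == 43.75
        assert overall == "fair"

    def test_continuous_study_total(self):
        total, overall = aggregate(self.continuous_metrics())
        assert total == 47.5
        assert overall == "good"

    def test_all_excellent(self):
        metrics = {c: _mk(c, "excellent") for c in
                   ("M2", "M3", "M4", "M5", "M6", "M7", "M8", "M9")}
        assert aggregate(metrics) == (80.0, "excellent")

    def test_missing_metric_rejected(self):
        m = self.transect_metrics()
        del m["M6"]
        with pytest.raises(ValueError, match="M6"):
            aggregate(m)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(labels=st.lists(st.sampled_from(list(CATEGORY_SCORES)), min_size=10, max_size=10))
    def test_total_is_multiple_of_1_25(self, labels):
        metrics = {
            "M2": _mk2("M2", labels[0], labels[1]),
            "M3": _mk2("M3", labels[2], labels[3]),
        }
        for k, code in enumerate(("M4", "M5", "M6", "M7", "M8", "M9")):
            metrics[code] = _mk(code, labels[4 + k])
        total, _ = aggregate(metrics)
        assert 20.0 <= total <= 80.0
        assert abs(total / 1.25 - round(total / 1.25)) < 1e-9

    def test_total_bins(self):
        assert classify_total(60.0) == "excellent"
        assert classify_total(59.999) == "good"
        assert classify_total(45.0) == "good"
        assert classify_total(44.999) == "fair"
        assert classify_total(30.0) == "fair"
        assert classify_total(29.999) == "poor"


def _uniform_records(n=50, spacing=4.0, **overrides):
    defaults = dict(W=5.0, D=0.5, BT=9.0, B_left=12.0, B_right=12.0,
                    E_left=0.1, E_right=0.1, F_left=0.3, F_right=0.3,
                    wet_fraction=1.0, white_fraction=0.2)
    defaults.update(overrides)
    out = []
    for i in range(n):
        s = i * spacing
        rec = StationRecord(s=s, x=s, y=0.0, v_proxy=0.4, **defaults)
        out.append(rec)
    return out


class TestAssessModes:
    cfg = AssessmentConfig()

    def straight_cl(self, length):
        return centerline_from_points([(x, 0.0) for x in np.linspace(0, length, 50)])

    def test_fixture_matches_hand_scored_categories(self, meander_bundle, meander_stations):
        _, banks, layers, truth = meander_bundle
        cl, records = meander_stations
        pools = detect_pools(records, self.cfg)
        report = assess_continuous(records, pools, cl, self.cfg, slope=0.001,
                                   banks=banks, layers=layers)
        expected = truth.expected_categories["categories"]
        assert report.metrics["M2"].category_per_side["left"].label == expected["M2_left"]
        assert report.metrics["M2"].category_per_side["right"].label == expected["M2_right"]
        assert report.metrics["M4"].category.label == expected["M4"]
        assert report.metrics["M5"].category.label == expected["M5"]
        assert report.metrics["M6"].category.label == expected["M6"]
        assert report.metrics["M7"].category.label == expected["M7"]
        assert report.metrics["M8"].category.label == expected["M8"]
        assert report.metrics["M9"].category.label == expected["M9"]

    def test_straight_pristine_fixture(self):
        records = _uniform_records(F_left=0.0, F_right=0.0, E_left=0.0, E_right=0.0)
        cl = self.straight_cl(records[-1].s)
        report = assess_continuous(records, [], cl, self.cfg, slope=0.001)
        assert report.metrics["M5"].category.label == "poor"     # sinuosity 1:1
        assert report.metrics["M2"].category_per_side["left"].label == "excellent"
        assert report.metrics["M3"].category_per_side["left"].label == "excellent"
        assert report.metrics["M6"].category.label == "excellent"

    def test_transect_equals_continuous_when_constant(self):
        records = _uniform_records()
        cl = self.straight_cl(records[-1].s)
        cont = assess_continuous(records, [], cl, self.cfg, slope=0.001)
        trans = assess_transects(records, 14, self.cfg, cl, pools=[], slope=0.001)
        for code in ("M2", "M3", "M4", "M5", "M6", "M7", "M8", "M9"):
            assert cont.metrics[code].score() == trans.metrics[code].score()
        assert cont.total == trans.total

    def test_two_endpoint_transects_use_first_and_last(self):
        records = _uniform_records()
        records[0].B_left = 0.0  # poor buffer only at the first station
        cl = self.straight_cl(records[-1].s)
        trans = assess_transects(records, 2, self.cfg, cl, pools=[], slope=0.001)
        # mean of first/last: (0 + 12)/2 = 6 -> good
        assert trans.metrics["M2"].per_side["left"] == pytest.approx(6.0)

    def test_too_many_transects_rejected(self):
        records = _uniform_records(n=10)
        cl = self.straight_cl(records[-1].s)
        with pytest.raises(ValueError, match="exceed"):
            assess_transects(records, 11, self.cfg, cl)

    def test_vicinity_uniform_equals_transect_categories(self):
        records = _uniform_records()
        rows = assess_vicinity(records, 14, self.cfg, sinuosity_value=1.0)
        for row in rows:
            assert row["M2_left"].label == "excellent"
            assert row["M6"].label == "excellent"

    def test_vicinity_flags_pocket_inside_window(self):
        records = _uniform_records(n=100, spacing=2.0)
        # poor-buffer pocket at s in [96, 104]: between transect stations
        for rec in records:
            if 96 <= rec.s <= 104:
                rec.B_left = 0.5
        n = 14
        rows = assess_vicinity(records, n, self.cfg)
        s = np.array([r.s for r in records])
        targets = np.linspace(s[0], s[-1], n)
        half = (s[-1] - s[0]) / (n - 1) / 2
        for t, row in zip(targets, rows):
            if abs(t - 100.0) <= half + 4:   # windows overlapping the pocket
                continue
            assert row["M2_left"].label == "excellent"
        hit = [row for t, row in zip(targets, rows) if abs(t - 100) <= half]
        assert any(r["M2_left"].label == "poor" for r in hit)

    def test_vicinity_never_better_than_transect_station(self):
        rng = np.random.default_rng(5)
        records = _uniform_records(n=100, spacing=2.0)
        for rec in records:
            rec.B_left = float(rng.uniform(0, 15))
        rows = assess_vicinity(records, 14, self.cfg)
        s = np.array([r.s for r in records])
        targets = np.linspace(s[0], s[-1], 14)
        for t, row in zip(targets, rows):
            i = int(np.argmin(np.abs(s - t)))
            at_station = score_value("M2", records[i].B_left, "M")
            assert row["M2_left"].rank <= at_station.rank

    def test_degrading_a_station_never_improves_total(self):
        records = _uniform_records()
        cl = self.straight_cl(records[-1].s)
        base = assess_continuous(records, [], cl, self.cfg, slope=0.001)
        records[20].B_left = 0.0
        records[20].E_left = 2.0
        worse = assess_continuous(records, [], cl, self.cfg, slope=0.001)
        assert worse.total <= base.total
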