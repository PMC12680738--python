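"""Multi-metric index (MMI) scoring of stream habitat health.

Nine physical metrics are categorized against fixed thresholds
(excellent / good / fair / poor, scored 10 / 7.5 / 5 / 2.5), summed to a
total score, and the total mapped to an overall class.  The channel
gradient M1 is not scored itself; it selects which threshold variant
applies for metrics with high-gradient (H) and mild-gradient (M)
branches (M5, M7).

Metrics
-------
M1  channel gradient (m/m); H if > 0.02, else M
M2  riparian vegetation buffer width (m), per bank side
M3  eroded / erodible bank width (m), per bank side
M4  width-to-depth ratio (m/m)
M5  sinuosity (mild) / riffle-spacing-to-width ratio (high)
M6  fraction of channel saturated with water (%)
M7  fraction of banks covered by coarse woody debris (%)
M8  fraction of stream surface with overtop fish cover (%)
M9  fraction of stream length occupied by pools (%)

Three assessment modes are provided: spatially continuous (every
station, length-weighted), transect-based (n equally spaced stations,
emulating a tape survey), and vicinity-based (worst station category
within half a transect spacing of each transect).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .model import (
    AssessmentConfig,
    AssessmentReport,
    BankGeometry,
    CATEGORY_SCORES,
    Centerline,
    LayerSet,
    MetricCategory,
    MetricResult,
    PoolInterval,
    StationRecord,
    check_station_series,
    worst_category,
)
from .parameters import coverage_fraction

__all__ = [
    "classify_gradient",
    "score_value",
    "score_stations",
    "aggregate",
    "classify_total",
    "assess_continuous",
    "assess_transects",
    "assess_vicinity",
    "METRIC_NAMES",
    "TWO_SIDED",
]

METRIC_NAMES = {
    "M1": "Channel Gradient",
    "M2": "Riparian Vegetation Buffer",
    "M3": "Bank Stability",
    "M4": "Width/depth Ratio",
    "M5": "Sinuosity",
    "M6": "Stream Flow Status",
    "M7": "Coarse Woody Debris",
    "M8": "In-stream Cover",
    "M9": "Channel Bed Forms",
}

#: Metrics measured independently on each bank and entering the total as
#: the mean of the two side scores.
TWO_SIDED = ("M2", "M3")


def classify_gradient(slope: float) -> str:
    """High-gradient ('H') if slope > 0.02 m/m strictly, else mild ('M').

    A negative slope (inverted endpoint elevations) is classified on its
    absolute value with a warning.
    """
    if not np.isfinite(slope):
        raise ValueError(f"slope must be finite, got {slope}")
    if slope < 0:
        warnings.warn(
            f"negative channel slope {slope}; classifying on absolute value",
            stacklevel=2,
        )
        slope = abs(slope)
    return "H" if slope > 0.02 else "M"


def _bin_m2(v: float) -> str:
    if v >= 10:
        return "excellent"
    if v >= 5:
        return "good"
    if v >= 1:
        return "fair"
    return "poor"


def _bin_m3(v: float) -> str:
    if v < 0.2:
        return "excellent"
    if v < 0.5:
        return "good"
    if v < 1:
        return "fair"
    return "poor"


def _bin_ratio_low_good(v: float) -> str:
    # shared by M4 and the high-gradient M5 branch
    if v < 7:
        return "excellent"
    if v < 15:
        return "good"
    if v < 25:
        return "fair"
    return "poor"


def _bin_m5_mild(v: float) -> str:
    if v > 3:
        return "excellent"
    if v > 2:
        return "good"
    if v > 1:
        return "fair"
    return "poor"  # exactly 1:1 (straight channel)


def _bin_m6(v: float) -> str:
    # the excellent bin is the single value 100; tolerate summation roundoff
    if v >= 100 - 1e-9:
        return "excellent"
    if v >= 75:
        return "good"
    if v >= 25:
        return "fair"
    return "poor"


def _bin_m7_high(v: float) -> str:
    if v >= 70:
        return "excellent"
    if v >= 40:
        return "good"
    if v >= 20:
        return "fair"
    return "poor"


def _bin_m7_mild(v: float) -> str:
    if v >= 50:
        return "excellent"
    if v >= 30:
        return "good"
    if v >= 10:
        return "fair"
    return "poor"


def _bin_m8(v: float) -> str:
    if v >= 12:
        return "excellent"
    if v >= 7:
        return "good"
    if v >= 2:
        return "fair"
    return "poor"


def _bin_m9(v: float) -> str:
    # Non-monotone: mid-range pool fractions are best.
    if 40 < v < 60:
        return "excellent"
    if 30 < v <= 40 or 60 <= v < 70:
        return "good"
    if 10 < v <= 30 or 70 <= v < 90:
        return "fair"
    return "poor"  # [0, 10] and [90, 100]


def score_value(code: str, value: float, gradient_class: str = "M") -> MetricCategory:
    """Categorize one metric value against its printed threshold bins.

    ``gradient_class`` selects the branch for M5 and M7.  Percent-valued
    metrics (M6–M9) take values in [0, 100].
    """
    if code not in METRIC_NAMES or code == "M1":
        raise ValueError(f"unknown scored metric code {code!r}")
    if gradient_class not in {"H", "M"}:
        raise ValueError("gradient_class must be H or M")
    if not np.isfinite(value):
        raise ValueError(f"{code} value must be finite, got {value}")

    if code in {"M6", "M7", "M8", "M9"} and not (0.0 <= value <= 100.0):
        raise ValueError(f"{code} is a percentage; {value} outside [0, 100]")
    if code in {"M2", "M3", "M4"} and value < 0:
        raise ValueError(f"{code} value must be non-negative, got {value}")
    if code == "M5" and gradient_class == "M" and value < 1.0:
        raise ValueError(f"sinuosity must be >= 1, got {value}")

    if code == "M2":
        label = _bin_m2(value)
    elif code == "M3":
        label = _bin_m3(value)
    elif code == "M4":
        label = _bin_ratio_low_good(value)
    elif code == "M5":
        label = _bin_ratio_low_good(value) if gradient_class == "H" else _bin_m5_mild(value)
    elif code == "M6":
        label = _bin_m6(value)
    elif code == "M7":
        label = _bin_m7_high(value) if gradient_class == "H" else _bin_m7_mild(value)
    elif code == "M8":
        label = _bin_m8(value)
    else:  # M9
        label = _bin_m9(value)
    return MetricCategory(label)


def _segment_weights(s: np.ndarray) -> np.ndarray:
    """Length weight of each station: half the span to its neighbours."""
    if len(s) == 1:
        return np.array([1.0])
    w = np.zeros(len(s))
    gaps = np.diff(s)
    w[:-1] += gaps / 2
    w[1:] += gaps / 2
    return w


def score_stations(
    code: str,
    station_values: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    gradient_class: str = "M",
    site_rule: str = "mean",
) -> MetricResult:
    """Score a spatially continuous metric from its per-station values.

    Per-station categories give the length-weighted category
    distribution; the site-level category comes from the length-weighted
    mean value re-binned (``site_rule='mean'``), the modal category
    (``'majority'``) or the worst category present (``'worst'``).
    """
    values = np.asarray(station_values, dtype=float)
    if values.size == 0:
        raise ValueError(f"empty station series for {code}")
    if weights is None:
        w = np.ones_like(values)
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    cats = [score_value(code, v, gradient_class) for v in values]
    pct = {label: 0.0 for label in CATEGORY_SCORES}
    for c, wi in zip(cats, w):
        pct[c.label] += float(wi)

    if site_rule == "mean":
        site_value = float(np.sum(values * w))
        site_cat = score_value(code, site_value, gradient_class)
    elif site_rule == "majority":
        site_value = float(np.sum(values * w))
        site_cat = MetricCategory(max(pct, key=lambda k: pct[k]))
    elif site_rule == "worst":
        site_value = float(np.sum(values * w))
        site_cat = worst_category(cats)
    else:
        raise ValueError(f"unknown site rule {site_rule!r}")

    return MetricResult(
        code=code,
        site_value=site_value,
        category=site_cat,
        station_categories=[c.label for c in cats],
        pct_by_category=pct,
    ).validate()


def classify_total(total: float) -> str:
    """Overall class from the total score: >=60 / [45,60) / [30,45) / <30."""
    if total >= 60:
        return "excellent"
    if total >= 45:
        return "good"
    if total >= 30:
        return "fair"
    return "poor"


def aggregate(metrics: dict[str, MetricResult]) -> tuple[float, str]:
    """Sum the eight metric scores (M2–M9) into a total and overall class.

    Two-sided metrics contribute the mean of their left/right scores, so
    every total is a multiple of 1.25.
    """
    missing = [c for c in AssessmentReport.REQUIRED if c not in metrics]
    if missing:
        raise ValueError(f"cannot aggregate: missing metrics {', '.join(missing)}")
    total = float(sum(metrics[c].score() for c in AssessmentReport.REQUIRED))
    return total, classify_total(total)


# --------------------------------------------------------------------------
# Assessment modes
# --------------------------------------------------------------------------

def _station_arrays(records: Sequence[StationRecord]) -> dict[str, np.ndarray]:
    check_station_series(records)
    get = lambda name: np.array([getattr(r, name) for r in records], dtype=float)
    return {k: get(k) for k in (
        "s", "W", "D", "BT", "E_left", "E_right", "B_left", "B_right",
        "F_left", "F_right", "wet_fraction",
    )}


def _pool_membership(s: np.ndarray, pools: Sequence[PoolInterval]) -> np.ndarray:
    member = np.zeros(len(s), dtype=bool)
    for p in pools:
        member |= (s >= p.s_start) & (s <= p.s_end)
    return member


def _pool_fraction_pct(pools: Sequence[PoolInterval], length: float) -> float:
    return 100.0 * sum(p.length for p in pools) / length


def _debris_pct(
    banks: Optional[BankGeometry],
    layers: Optional[LayerSet],
    cfg: AssessmentConfig,
    debris_cover_pct: Optional[float],
) -> float:
    """Site-level woody-debris bank coverage (%) for M7."""
    if debris_cover_pct is not None:
        return float(debris_cover_pct)
    if banks is None or layers is None:
        return 0.0
    total_len = banks.left_bank.length + banks.right_bank.length
    covered = (
        coverage_fraction(banks.left_bank, layers.woody_debris["left"], cfg.debris_max_dist_m)
        * banks.left_bank.length
        + coverage_fraction(banks.right_bank, layers.woody_debris["right"], cfg.debris_max_dist_m)
        * banks.right_bank.length
    )
    return 100.0 * covered / total_len


def _station_metric_values(arr: dict[str, np.ndarray],
                           pools: Sequence[PoolInterval]) -> dict:
    """Per-station input series for each station-wise metric."""
    with np.errstate(divide="ignore", invalid="ignore"):
        wd_ratio = np.where(arr["D"] > 0, arr["W"] / arr["D"], np.inf)
        cover_pct = np.where(
            arr["W"] > 0, 100.0 * (arr["F_left"] + arr["F_right"]) / arr["W"], 0.0
        )
    cover_pct = np.clip(cover_pct, 0.0, 100.0)
    return {
        ("M2", "left"): arr["B_left"],
        ("M2", "right"): arr["B_right"],
        ("M3", "left"): arr["E_left"],
        ("M3", "right"): arr["E_right"],
        ("M4", None): wd_ratio,
        ("M6", None): 100.0 * arr["wet_fraction"],
        ("M8", None): cover_pct,
        ("M9", None): 100.0 * _pool_membership(arr["s"], pools).astype(float),
    }


def _finalize(gradient_class: str, slope: float,
              metrics: dict[str, MetricResult]) -> AssessmentReport:
    total, overall = aggregate(metrics)
    return AssessmentReport(
        gradient_class=gradient_class, slope=slope, metrics=metrics,
        total=total, overall=overall,
    ).validate()


def assess_continuous(
    records: Sequence[StationRecord],
    pools: Sequence[PoolInterval],
    cl: Centerline,
    cfg: AssessmentConfig,
    slope: float = 0.0,
    banks: Optional[BankGeometry] = None,
    layers: Optional[LayerSet] = None,
    debris_cover_pct: Optional[float] = None,
) -> AssessmentReport:
    """Spatially continuous whole-site assessment.

    Station-wise metrics (M2, M3, M4, M6, M8) are scored from the full
    station series with segment-length weights; M5 from the centerline
    sinuosity, M9 from the total pool length, M7 from woody-debris bank
    coverage (``debris_cover_pct`` overrides, else measured from
    ``banks``/``layers``, else 0).
    """
    from .centerline import sinuosity

    arr = _station_arrays(records)
    g = classify_gradient(slope)
    weights = _segment_weights(arr["s"])
    series = _station_metric_values(arr, pools)

    metrics: dict[str, MetricResult] = {}
    for code in ("M2", "M3"):
        per_side_cat, per_side_val, per_side_pct = {}, {}, {}
        for side in ("left", "right"):
            res = score_stations(code, series[(code, side)], weights, g,
                                 cfg.site_category_rule)
            per_side_cat[side] = res.category
            per_side_val[side] = res.site_value
            per_side_pct[side] = res.pct_by_category
        both = {label: (per_side_pct["left"][label] + per_side_pct["right"][label]) / 2
                for label in per_side_pct["left"]}
        metrics[code] = MetricResult(
            code=code, per_side=per_side_val, category_per_side=per_side_cat,
            pct_by_category=both, pct_per_side=per_side_pct,
        )

    # M4: ratio of average width to average depth over the assessed extent
    mean_W = float(np.sum(arr["W"] * weights) / weights.sum())
    mean_D = float(np.sum(arr["D"] * weights) / weights.sum())
    m4_value = mean_W / mean_D if mean_D > 0 else np.inf
    m4 = score_stations("M4", series[("M4", None)], weights, g, cfg.site_category_rule)
    m4.site_value = m4_value
    m4.category = score_value("M4", m4_value, g)
    metrics["M4"] = m4

    sin = sinuosity(cl)
    metrics["M5"] = MetricResult(code="M5", site_value=sin,
                                 category=score_value("M5", sin, g))

    metrics["M6"] = score_stations("M6", series[("M6", None)], weights, g,
                                   cfg.site_category_rule)

    m7_pct = _debris_pct(banks, layers, cfg, debris_cover_pct)
    metrics["M7"] = MetricResult(code="M7", site_value=m7_pct,
                                 category=score_value("M7", m7_pct, g))

    metrics["M8"] = score_stations("M8", series[("M8", None)], weights, g,
                                   cfg.site_category_rule)

    m9_pct = _pool_fraction_pct(pools, cl.length)
    m9 = score_stations("M9", series[("M9", None)], weights, g, "mean")
    m9.site_value = m9_pct
    m9.category = score_value("M9", m9_pct, g)
    metrics["M9"] = m9

    return _finalize(g, slope, metrics)


def _transect_indices(s: np.ndarray, n: int) -> np.ndarray:
    """Indices of the stations nearest n equally spaced positions."""
    if n < 2:
        raise ValueError("need at least 2 transects")
    if n > len(s):
        raise ValueError(f"{n} transects exceed the {len(s)} available stations")
    targets = np.linspace(s[0], s[-1], n)
    idx = np.array([int(np.argmin(np.abs(s - t))) for t in targets])
    return idx


def assess_transects(
    records: Sequence[StationRecord],
    n: int,
    cfg: AssessmentConfig,
    cl: Centerline,
    pools: Sequence[PoolInterval] = (),
    slope: float = 0.0,
    banks: Optional[BankGeometry] = None,
    layers: Optional[LayerSet] = None,
    debris_cover_pct: Optional[float] = None,
) -> AssessmentReport:
    """Transect-based assessment emulating an n-transect tape survey.

    The station series is sampled at n equally spaced stations; each
    station-wise metric's site value is the unweighted mean over the
    sampled transects (M9 becomes the percentage of transects lying in a
    pool).  Whole-site metrics (M5, M7) are unchanged.
    """
    from .centerline import sinuosity

    arr = _station_arrays(records)
    g = classify_gradient(slope)
    idx = _transect_indices(arr["s"], n)
    series = _station_metric_values(arr, pools)

    metrics: dict[str, MetricResult] = {}
    for code in ("M2", "M3"):
        per_side_cat, per_side_val = {}, {}
        for side in ("left", "right"):
            vals = series[(code, side)][idx]
            res = score_stations(code, vals, None, g, "mean")
            per_side_cat[side] = res.category
            per_side_val[side] = res.site_value
        metrics[code] = MetricResult(code=code, per_side=per_side_val,
                                     category_per_side=per_side_cat)

    mean_W = float(np.mean(arr["W"][idx]))
    mean_D = float(np.mean(arr["D"][idx]))
    m4_value = mean_W / mean_D if mean_D > 0 else np.inf
    metrics["M4"] = MetricResult(code="M4", site_value=m4_value,
                                 category=score_value("M4", m4_value, g))

    sin = sinuosity(cl)
    metrics["M5"] = MetricResult(code="M5", site_value=sin,
                                 category=score_value("M5", sin, g))

    m6_value = float(np.mean(series[("M6", None)][idx]))
    metrics["M6"] = MetricResult(code="M6", site_value=m6_value,
                                 category=score_value("M6", m6_value, g))

    m7_pct = _debris_pct(banks, layers, cfg, debris_cover_pct)
    metrics["M7"] = MetricResult(code="M7", site_value=m7_pct,
                                 category=score_value("M7", m7_pct, g))

    m8_value = float(np.mean(series[("M8", None)][idx]))
    metrics["M8"] = MetricResult(code="M8", site_value=m8_value,
                                 category=score_value("M8", m8_value, g))

    m9_value = float(np.mean(series[("M9", None)][idx]))
    metrics["M9"] = MetricResult(code="M9", site_value=m9_value,
                                 category=score_value("M9", m9_value, g))

    return _finalize(g, slope, metrics)


def assess_vicinity(
    records: Sequence[StationRecord],
    n: int,
    cfg: AssessmentConfig,
    pools: Sequence[PoolInterval] = (),
    slope: float = 0.0,
    sinuosity_value: Optional[float] = None,
    debris_cover_pct: Optional[float] = None,
) -> list[dict[str, MetricCategory]]:
    """Vicinity-based assessment: worst conditions near each transect.

    For each of n transects, each station-wise metric's category is the
    worst station category found within ±ΔL/2 of the transect, where ΔL
    is the transect spacing.  Whole-site metrics (M5, M7) keep their
    site category at every transect.  Returns one code→category mapping
    per transect.
    """
    arr = _station_arrays(records)
    g = classify_gradient(slope)
    s = arr["s"]
    idx = _transect_indices(s, n)
    delta_L = cfg.delta_L if cfg.delta_L is not None else (s[-1] - s[0]) / (n - 1)
    half = delta_L / 2.0
    series = _station_metric_values(arr, pools)

    with np.errstate(divide="ignore", invalid="ignore"):
        wd = series[("M4", None)]

    out: list[dict[str, MetricCategory]] = []
    for i in idx:
        window = np.abs(s - s[i]) <= half + 1e-9
        row: dict[str, MetricCategory] = {}
        for (code, side), values in series.items():
            cats = [score_value(code, v, g) for v in values[window] if np.isfinite(v)]
            key = f"{code}_{side}" if side else code
            row[key] = worst_category(cats) if cats else MetricCategory("poor")
        if sinuosity_value is not None:
            row["M5"] = score_value("M5", sinuosity_value, g)
        m7_pct = debris_cover_pct if debris_cover_pct is not None else 0.0
        row["M7"] = score_value("M7", m7_pct, g)
        out.append(row)
    return out
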