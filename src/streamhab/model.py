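"""Shared domain types for survey planning and habitat assessment.

All geometry is planar, in metres, in a single projected coordinate
reference system; elevations are metres above the datum.  Nothing here
reprojects — callers are expected to deliver metric coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "CRSContext",
    "Obstacle",
    "SitePlan",
    "BankGeometry",
    "LayerSet",
    "StationRecord",
    "AssessmentConfig",
    "CameraModel",
    "FlightConfig",
    "FlightRoute",
    "Centerline",
    "Bend",
    "TransectChord",
    "PoolInterval",
    "MetricCategory",
    "MetricResult",
    "AssessmentReport",
    "CATEGORY_SCORES",
    "SCORE_CATEGORIES",
]

#: EPSG codes that are geographic (degree-valued) and therefore rejected.
_GEOGRAPHIC_EPSG = {4326, 4269, 4267, 4258}


@dataclass(frozen=True)
class CRSContext:
    """A projected coordinate reference system with metre units.

    Only the identifier is stored; the package never transforms
    coordinates.  Geographic (degree) systems are rejected because every
    width/length threshold in the scoring tables is metric.
    """

    epsg_or_wkt: str
    unit: str = "metre"

    def __post_init__(self) -> None:
        if self.unit.lower() not in {"metre", "meter", "m", "metres", "meters"}:
            raise ValueError(
                f"projected metric CRS required: unit {self.unit!r} is not metres"
            )
        code = self.epsg_code()
        if code is not None and code in _GEOGRAPHIC_EPSG:
            raise ValueError(
                f"projected metric CRS required: EPSG:{code} is geographic (degrees)"
            )

    def epsg_code(self) -> Optional[int]:
        text = self.epsg_or_wkt.strip().upper()
        if text.startswith("EPSG:"):
            try:
                return int(text.split(":", 1)[1])
            except ValueError:
                return None
        if text.isdigit():
            return int(text)
        return None


@dataclass
class Obstacle:
    """A no-fly feature (tree canopy or building footprint)."""

    geometry: Polygon
    kind: str  # "tree" | "building"

    def __post_init__(self) -> None:
        if self.kind not in {"tree", "building"}:
            raise ValueError(f"obstacle kind must be tree|building, got {self.kind!r}")


@dataclass
class SitePlan:
    """Flight area, obstacles and the stream channel to be surveyed."""

    boundary: Polygon
    obstacles: list[Obstacle] = field(default_factory=list)
    stream_channel: Optional[Polygon] = None
    focus_corridor_width_m: float = 10.0
    crs: Optional[CRSContext] = None

    def validate(self) -> "SitePlan":
        if self.boundary.is_empty or not self.boundary.is_valid:
            raise ValueError("site boundary must be a simple non-empty polygon")
        if self.stream_channel is not None and not self.stream_channel.intersects(
            self.boundary
        ):
            raise ValueError("stream channel does not intersect the flight boundary")
        for i, obs in enumerate(self.obstacles):
            if not obs.geometry.is_valid:
                raise ValueError(f"obstacle {i} ({obs.kind}) has invalid geometry")
        return self


@dataclass
class BankGeometry:
    """Left/right banks and bank tops, oriented with flow (inlet -> outlet).

    "Left" is the left-hand side when facing downstream.  Islands are
    polygons inside the channel; the centerline ignores them but widths
    and wetted fractions subtract them.
    """

    left_bank: LineString
    right_bank: LineString
    inlet: Point
    outlet: Point
    left_bank_top: Optional[LineString] = None
    right_bank_top: Optional[LineString] = None
    islands: list[Polygon] = field(default_factory=list)

    def channel_polygon(self) -> Polygon:
        """Channel polygon bounded by the two banks (islands excluded)."""
        left = list(self.left_bank.coords)
        right = list(self.right_bank.coords)
        poly = Polygon(left + right[::-1])
        if not poly.is_valid:
            poly = Polygon(left + right)
        if not poly.is_valid or poly.is_empty:
            raise ValueError("bank polylines cross: cannot form a simple channel")
        return poly

    def validate(self) -> "BankGeometry":
        if self.left_bank.crosses(self.right_bank):
            raise ValueError("left and right bank polylines cross each other")
        self.channel_polygon()
        return self


def _as_profile(value) -> Callable[[np.ndarray], np.ndarray]:
    """Accept a constant, an (s, value) table, or a callable; return f(s)."""
    if callable(value):
        return value
    if np.isscalar(value):
        v = float(value)
        return lambda s: np.full_like(np.asarray(s, dtype=float), v)
    table = np.asarray(value, dtype=float)
    return lambda s: np.interp(np.asarray(s, dtype=float), table[:, 0], table[:, 1])


@dataclass
class LayerSet:
    """Delineated habitat layers accompanying the bank geometry.

    Per-side polygon lists use keys ``"left"`` and ``"right"``.  The
    water surface may be a constant elevation or an (s, elevation)
    series; the optional white-water fraction is an (s, fraction) series
    from near-white pixel classification of the orthophoto.
    """

    erosion: dict[str, list[Polygon]] = field(default_factory=lambda: {"left": [], "right": []})
    veg_buffer: dict[str, list[Polygon]] = field(default_factory=lambda: {"left": [], "right": []})
    instream_cover: dict[str, list[Polygon]] = field(default_factory=lambda: {"left": [], "right": []})
    woody_debris: dict[str, list[Polygon]] = field(default_factory=lambda: {"left": [], "right": []})
    bed_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    water_surface: object = 0.0  # constant, (s, elev) table, or callable
    white_fraction: Optional[object] = None  # (s, fraction) table or callable

    def surface_at(self, s) -> np.ndarray:
        return _as_profile(self.water_surface)(s)

    def white_at(self, s) -> Optional[np.ndarray]:
        if self.white_fraction is None:
            return None
        out = _as_profile(self.white_fraction)(s)
        arr = np.asarray(out, dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("white_fraction entries must lie in [0, 1]")
        return out

    def validate(self) -> "LayerSet":
        for name in ("erosion", "veg_buffer", "instream_cover", "woody_debris"):
            for side, polys in getattr(self, name).items():
                for p in polys:
                    if not p.is_valid:
                        raise ValueError(f"invalid {name} polygon on {side} side")
        self.white_at([0.0])
        return self


@dataclass
class StationRecord:
    """All per-station measurements at one centerline station.

    Widths in metres; ``wet_fraction`` and ``white_fraction`` are
    fractions in [0, 1]; ``v_proxy`` is a dimensionless relative
    velocity used only ordinally.
    """

    s: float
    x: float
    y: float
    W: float = np.nan
    D: float = np.nan
    BT: float = np.nan
    E_left: float = 0.0
    E_right: float = 0.0
    B_left: float = 0.0
    B_right: float = 0.0
    F_left: float = 0.0
    F_right: float = 0.0
    wet_fraction: float = 1.0
    white_fraction: float = np.nan
    v_proxy: float = np.nan

    def validate(self) -> "StationRecord":
        for name in ("W", "D", "BT", "E_left", "E_right", "B_left", "B_right",
                     "F_left", "F_right"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not (0.0 <= self.wet_fraction <= 1.0):
            raise ValueError(f"wet_fraction must lie in [0,1], got {self.wet_fraction}")
        return self


def check_station_series(records: Sequence[StationRecord]) -> None:
    """Series must be strictly increasing in s (duplicates raise)."""
    s = np.array([r.s for r in records])
    if len(s) and not (np.diff(s) > 0).all():
        raise ValueError("station series must be strictly increasing in s")


@dataclass
class AssessmentConfig:
    """Tunable assessment parameters.

    ``vel_pct`` is the percentile below which a station counts as
    slow for pool detection (mirror of ``depth_pct`` above which it
    counts as deep); ``white_max`` is the maximum white-pixel fraction
    of a smooth-surfaced pool.
    """

    n_transects: int = 14
    delta_L: Optional[float] = None
    theta_bend_deg: float = 30.0
    bend_window_m: float = 5.0
    depth_pct: float = 70.0
    vel_pct: float = 30.0
    white_max: float = 0.10
    station_spacing_m: float = 2.0
    side_ray_max_m: float = 100.0
    debris_max_dist_m: float = 2.0
    site_category_rule: str = "mean"  # mean | majority | worst

    def __post_init__(self) -> None:
        for name in ("depth_pct", "vel_pct"):
            v = getattr(self, name)
            if not (0.0 < v < 100.0):
                raise ValueError(f"{name} must lie in (0, 100), got {v}")
        if not (0.0 < self.theta_bend_deg < 180.0):
            raise ValueError("theta_bend_deg must lie in (0, 180)")
        if self.site_category_rule not in {"mean", "majority", "worst"}:
            raise ValueError("site_category_rule must be mean|majority|worst")


# --------------------------------------------------------------------------
# Flight planning types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Pinhole field-of-view model used to derive sweep-line spacing."""

    fov_cross_track_deg: float = 84.0
    fov_along_track_deg: float = 62.0

    def __post_init__(self) -> None:
        for v in (self.fov_cross_track_deg, self.fov_along_track_deg):
            if not (0.0 < v < 180.0):
                raise ValueError(f"field of view must lie in (0, 180), got {v}")


@dataclass(frozen=True)
class FlightConfig:
    """Survey flight parameters (altitudes, overlaps, speeds, battery)."""

    alt_high_m: float = 30.0
    alt_low_m: float = 5.0
    overlap_default: float = 0.75
    overlap_focus: float = 0.90
    buffer_obstacle_m: float = 5.0
    focus_corridor_m: float = 10.0
    speed_survey_low: float = 1.0
    speed_transit_low: float = 2.0
    speed_survey_high: float = 4.0
    speed_transit_high: float = 8.0
    battery_min: float = 20.0
    usable_fraction: float = 0.75
    overhead_s: float = 30.0

    def __post_init__(self) -> None:
        for v in (self.overlap_default, self.overlap_focus):
            if not (0.0 <= v < 1.0):
                raise ValueError(f"overlap must lie in [0, 1), got {v}")
        for name in ("speed_survey_low", "speed_transit_low",
                     "speed_survey_high", "speed_transit_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.usable_fraction <= 1.0):
            raise ValueError("usable_fraction must lie in (0, 1]")

    def speeds(self, elevation: str) -> tuple[float, float]:
        """(survey, transit) speed in m/s for 'high' or 'low' elevation."""
        if elevation == "high":
            return self.speed_survey_high, self.speed_transit_high
        if elevation == "low":
            return self.speed_survey_low, self.speed_transit_low
        raise ValueError(f"elevation must be high|low, got {elevation!r}")


@dataclass
class FlightRoute:
    """Ordered waypoints with altitudes and per-edge segment classes.

    ``segment_class[i]`` classifies the edge from waypoint i to i+1 as
    ``"survey"`` (a sweep line) or ``"transit"`` (connector / lead-in).
    """

    waypoints: np.ndarray  # (N, 3): x, y, altitude
    segment_class: list[str]
    sweep_lines: list[LineString] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        if self.waypoints.ndim != 2 or self.waypoints.shape[1] != 3:
            raise ValueError("waypoints must be an (N, 3) array of x, y, altitude")
        n_edges = max(len(self.waypoints) - 1, 0)
        if len(self.segment_class) != n_edges:
            raise ValueError(
                f"segment_class length {len(self.segment_class)} != edge count {n_edges}"
            )
        for c in self.segment_class:
            if c not in {"survey", "transit"}:
                raise ValueError(f"unknown segment class {c!r}")
        xy = self.waypoints[:, :2]
        if len(xy) >= 2 and (np.linalg.norm(np.diff(xy, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive waypoints must be distinct")

    def edge_lengths(self) -> np.ndarray:
        xy = self.waypoints[:, :2]
        return np.linalg.norm(np.diff(xy, axis=0), axis=1)

    def length_by_class(self) -> dict[str, float]:
        lengths = self.edge_lengths()
        out = {"survey": 0.0, "transit": 0.0}
        for L, c in zip(lengths, self.segment_class):
            out[c] += float(L)
        return out

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())


# --------------------------------------------------------------------------
# Centerline / parameter types
# --------------------------------------------------------------------------

@dataclass
class Centerline:
    """Arc-length-parameterized stream centerline (medial axis)."""

    nodes: np.ndarray      # (N, 2)
    s: np.ndarray          # (N,) arc length from inlet, s[0] == 0
    tangent: np.ndarray    # (N, 2) unit downstream tangents
    straight_dist: float   # inlet-to-outlet straight-line distance

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.tangent = np.asarray(self.tangent, dtype=float)
        if len(self.s) and abs(self.s[0]) > 1e-9:
            raise ValueError("centerline arc length must start at 0")
        if len(self.s) > 1 and not (np.diff(self.s) > 0).all():
            raise ValueError("centerline arc length must be strictly increasing")

    @property
    def length(self) -> float:
        """Meandered stream length L0."""
        return float(self.s[-1])

    def as_linestring(self) -> LineString:
        return LineString(self.nodes)

    def point_at(self, s: float) -> np.ndarray:
        x = np.interp(s, self.s, self.nodes[:, 0])
        y = np.interp(s, self.s, self.nodes[:, 1])
        return np.array([x, y])

    def tangent_at(self, s: float) -> np.ndarray:
        tx = np.interp(s, self.s, self.tangent[:, 0])
        ty = np.interp(s, self.s, self.tangent[:, 1])
        t = np.array([tx, ty])
        n = np.linalg.norm(t)
        return t / n if n > 0 else t


@dataclass(frozen=True)
class Bend:
    """A channel bend: station and turning angle over the detection window."""

    s: float
    theta_deg: float


@dataclass
class TransectChord:
    """Shortest bank-to-bank chord through a centerline node."""

    s: float
    node: Point
    left_point: Point
    right_point: Point
    length: float
    island_overlap_m: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chord length must be positive")


@dataclass(frozen=True)
class PoolInterval:
    """A pool reach [s_start, s_end] along the centerline."""

    s_start: float
    s_end: float

    def __post_init__(self) -> None:
        if not self.s_start < self.s_end:
            raise ValueError("pool interval requires s_start < s_end")

    @property
    def length(self) -> float:
        return self.s_end - self.s_start


# --------------------------------------------------------------------------
# Scoring types
# --------------------------------------------------------------------------

CATEGORY_SCORES = {"excellent": 10.0, "good": 7.5, "fair": 5.0, "poor": 2.5}
SCORE_CATEGORIES = {v: k for k, v in CATEGORY_SCORES.items()}
CATEGORY_ORDER = ["poor", "fair", "good", "excellent"]  # worst -> best


@dataclass(frozen=True)
class MetricCategory:
    """A health category label with its fixed score (10/7.5/5/2.5)."""

    label: str
    score: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.label not in CATEGORY_SCORES:
            raise ValueError(f"unknown category label {self.label!r}")
        expected = CATEGORY_SCORES[self.label]
        if self.score == 0.0:
            object.__setattr__(self, "score", expected)
        elif self.score != expected:
            raise ValueError(
                f"category {self.label!r} must score {expected}, got {self.score}"
            )

    @property
    def rank(self) -> int:
        """0 = poor ... 3 = excellent."""
        return CATEGORY_ORDER.index(self.label)

    def __lt__(self, other: "MetricCategory") -> bool:
        return self.rank < other.rank


@dataclass
class MetricResult:
    """Per-metric outcome: site value(s), category and spatial distribution."""

    code: str
    site_value: Optional[float] = None
    per_side: Optional[dict[str, float]] = None
    category: Optional[MetricCategory] = None
    category_per_side: Optional[dict[str, MetricCategory]] = None
    station_categories: Optional[list[str]] = None
    pct_by_category: Optional[dict[str, float]] = None
    pct_per_side: Optional[dict[str, dict[str, float]]] = None

    def score(self) -> float:
        """Score entering the total: mean of sides for two-sided metrics."""
        if self.category_per_side:
            vals = [c.score for c in self.category_per_side.values()]
            return float(np.mean(vals))
        if self.category is None:
            raise ValueError(f"metric {self.code} has no category")
        return self.category.score

    def validate(self) -> "MetricResult":
        if self.pct_by_category is not None:
            total = sum(self.pct_by_category.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"pct_by_category must sum to 1, got {total} for {self.code}"
                )
        return self


@dataclass
class AssessmentReport:
    """Gradient class, the eight scored metrics, total score and overall class."""

    gradient_class: str          # "H" | "M"
    slope: float                 # channel gradient, m/m
    metrics: dict[str, MetricResult]
    total: float = np.nan
    overall: str = ""

    REQUIRED = ("M2", "M3", "M4", "M5", "M6", "M7", "M8", "M9")

    def validate(self) -> "AssessmentReport":
        missing = [c for c in self.REQUIRED if c not in self.metrics]
        if missing:
            raise ValueError(f"report missing metrics: {', '.join(missing)}")
        if self.gradient_class not in {"H", "M"}:
            raise ValueError("gradient_class must be H or M")
        if np.isfinite(self.total) and not (20.0 - 1e-9 <= self.total <= 80.0 + 1e-9):
            raise ValueError(f"total score {self.total} outside [20, 80]")
        return self


def worst_category(categories: Sequence[MetricCategory]) -> MetricCategory:
    return min(categories, key=lambda c: c.rank)
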