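"""Parametric synthetic stream sites with analytically known ground truth.

Sites are sine-generated meanders: the centerline is
``y = A·sin(2πx/λ)`` over an axis of given length, and the banks are
normal offsets by half the width profile.  All habitat layers (buffer,
erosion, in-stream cover, woody debris) are piecewise-constant offset
strips along the banks, so every extracted parameter has a closed-form
expected value; sinuosity comes from a quadrature of the arc-length
integrand, and bend stations from the analytic heading.  Everything is
deterministic given the spec (the seed only drives random obstacle
fields).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad
from shapely.geometry import LineString, Point, Polygon, box

from .model import (
    BankGeometry,
    Centerline,
    LayerSet,
    Obstacle,
    PoolInterval,
    SitePlan,
)

__all__ = ["PiecewiseProfile", "MeanderSpec", "GroundTruth",
           "generate_site", "generate_obstacle_field", "degrade"]

_DENSE_STEP = 0.5  # m; internal sampling step for banks and layers


@dataclass(frozen=True)
class PiecewiseProfile:
    """Piecewise-constant profile along arc length: base value plus windows.

    ``windows`` are (s_start, s_end, value) overrides; later windows
    shadow earlier ones.
    """

    base: float = 0.0
    windows: tuple = ()

    def __call__(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        out = np.full(s.shape, self.base)
        for s0, s1, v in self.windows:
            out = np.where((s >= s0) & (s <= s1), v, out)
        return out

    def with_window(self, s0: float, s1: float, value: float) -> "PiecewiseProfile":
        return replace(self, windows=self.windows + ((s0, s1, value),))

    def breakpoints(self, length: float) -> list[float]:
        pts = {0.0, length}
        for s0, s1, _ in self.windows:
            pts.update((max(0.0, s0), min(length, s1)))
        return sorted(pts)


@dataclass(frozen=True)
class MeanderSpec:
    """Specification of a synthetic meandering stream site."""

    axis_length: float = 200.0
    amplitude: float = 8.0
    wavelength: float = 100.0
    width: PiecewiseProfile = field(default_factory=lambda: PiecewiseProfile(5.0))
    depth: PiecewiseProfile = field(default_factory=lambda: PiecewiseProfile(0.4))
    buffer_left: PiecewiseProfile = field(default_factory=lambda: PiecewiseProfile(12.0))
    buffer_right: PiecewiseProfile = field(default_factory=lambda: PiecewiseProfile(12.0))
    erosion_left: PiecewiseProfile = field(default_factory=lambda: PiecewiseProfile(0.0))
    erosion_right: PiecewiseProfile = field(default_factory=lambda: PiecewiseProfile(0.0))
    cover_left: PiecewiseProfile = field(default_factory=lambda: PiecewiseProfile(0.35))
    cover_right: PiecewiseProfile = field(default_factory=lambda: PiecewiseProfile(0.35))
    pool_reaches: tuple = ()          # ((s_start, s_end), ...)
    pool_depth: float = 1.2
    white_base: float = 0.20
    white_pool: float = 0.02
    bank_top_offset: float = 2.0
    water_surface_elev: float = 100.0
    bed_point_spacing: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.wavelength <= 0 or self.axis_length <= 0:
            raise ValueError("amplitude >= 0 and wavelength, axis_length > 0 required")
        reaches = sorted(self.pool_reaches)
        for (a0, a1), (b0, b1) in zip(reaches[:-1], reaches[1:]):
            if b0 < a1:
                raise ValueError("pool reaches must be disjoint")
        for s0, s1 in reaches:
            if not s0 < s1:
                raise ValueError("pool reach requires s_start < s_end")

    # -- analytic centerline -------------------------------------------------

    def _y(self, x):
        return self.amplitude * np.sin(2 * np.pi * x / self.wavelength)

    def _dydx(self, x):
        k = 2 * np.pi / self.wavelength
        return self.amplitude * k * np.cos(k * x)

    def arc_integrand(self, x):
        return np.sqrt(1.0 + self._dydx(x) ** 2)

    def exact_length(self) -> float:
        """Meandered length by quadrature of the arc-length integrand."""
        val, _ = quad(self.arc_integrand, 0.0, self.axis_length, limit=200)
        return val

    def exact_sinuosity(self) -> float:
        return self.exact_length() / self.axis_length

    def depth_at(self, s) -> np.ndarray:
        d = self.depth(s)
        s = np.asarray(s, dtype=float)
        for s0, s1 in self.pool_reaches:
            d = np.where((s >= s0) & (s <= s1), self.pool_depth, d)
        return d

    def white_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        w = np.full(s.shape, self.white_base)
        for s0, s1 in self.pool_reaches:
            w = np.where((s >= s0) & (s <= s1), self.white_pool, w)
        return w


@dataclass
class GroundTruth:
    """Analytic expectations for a generated site."""

    centerline: Centerline
    sinuosity: float
    length: float
    straight_dist: float
    width_at: PiecewiseProfile
    depth_at: object            # callable s -> D
    bend_stations: list[float]
    pool_intervals: list[PoolInterval]
    expected_categories: dict[str, object]


def _dense_frame(spec: MeanderSpec):
    """Dense centerline samples: x, y, s, unit tangent, left normal."""
    n = max(int(math.ceil(spec.axis_length / (_DENSE_STEP / 2))), 64)
    x = np.linspace(0.0, spec.axis_length, n + 1)
    y = spec._y(x)
    dy = spec._dydx(x)
    ds = np.sqrt(1.0 + dy ** 2)
    s = np.concatenate([[0.0], np.cumsum((ds[:-1] + ds[1:]) / 2 * np.diff(x))])
    t = np.stack([np.ones_like(x), dy], axis=1)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    n_left = np.stack([-t[:, 1], t[:, 0]], axis=1)
    nodes = np.stack([x, y], axis=1)
    return nodes, s, t, n_left


def _offset_line(nodes, normals, offsets) -> np.ndarray:
    return nodes + normals * np.asarray(offsets)[:, None]


def _strip(nodes, normals, inner, outer) -> Optional[Polygon]:
    """Quad strip between two offset curves (same sampling)."""
    a = _offset_line(nodes, normals, inner)
    b = _offset_line(nodes, normals, outer)
    poly = Polygon(np.vstack([a, b[::-1]]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return None if poly.is_empty else poly


def _layer_strips(spec: MeanderSpec, nodes, s, normals, side: str,
                  profile: PiecewiseProfile, anchor: str) -> list[Polygon]:
    """Strips for one per-side layer.

    ``anchor='out'`` builds outward from the bank (buffer, erosion,
    debris); ``anchor='in'`` builds inward from the bank (in-stream
    cover).
    """
    sign = 1.0 if side == "left" else -1.0
    halfw = spec.width(s) / 2.0
    polys = []
    brk = profile.breakpoints(float(s[-1]))
    for s0, s1 in zip(brk[:-1], brk[1:]):
        mid = (s0 + s1) / 2.0
        value = float(profile(np.array([mid]))[0])
        if value <= 0:
            continue
        mask = (s >= s0 - 1e-9) & (s <= s1 + 1e-9)
        if mask.sum() < 2:
            continue
        hw = halfw[mask]
        if anchor == "out":
            inner, outer = sign * hw, sign * (hw + value)
        else:
            inner, outer = sign * (hw - value), sign * hw
        poly = _strip(nodes[mask], normals[mask], inner, outer)
        if poly is not None:
            polys.append(poly)
    return polys


def _analytic_bends(spec: MeanderSpec, s, x, theta_deg: float = 30.0,
                    window_m: float = 5.0) -> list[float]:
    """Bend stations from the analytic heading change over the window."""
    heading = np.unwrap(np.arctan2(spec._dydx(x), np.ones_like(x)))
    h_lo = np.interp(s - window_m / 2, s, heading)
    h_hi = np.interp(s + window_m / 2, s, heading)
    theta = np.degrees(np.abs(h_hi - h_lo))
    flagged = theta > theta_deg
    stations = []
    i, n = 0, len(s)
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            k = i + int(np.argmax(theta[i:j + 1]))
            stations.append(float(s[k]))
            i = j + 1
        else:
            i += 1
    return stations


def _expected_categories(spec: MeanderSpec, s: np.ndarray, length: float) -> dict:
    """Length-weighted site values of each metric, binned per the tables."""
    from .mmi import score_value

    w = np.gradient(s)
    w = w / w.sum()
    mean = lambda v: float(np.sum(np.asarray(v) * w))

    W = spec.width(s)
    D = spec.depth_at(s)
    pool_len = sum(s1 - s0 for s0, s1 in spec.pool_reaches)
    values = {
        "M2_left": mean(spec.buffer_left(s)),
        "M2_right": mean(spec.buffer_right(s)),
        "M3_left": mean(spec.erosion_left(s)),
        "M3_right": mean(spec.erosion_right(s)),
        "M4": mean(W) / mean(D),
        "M5": spec.exact_sinuosity(),
        "M6": 100.0,  # no islands/dry zones by construction
        "M7": 0.0,    # debris coverage of banks handled separately
        "M8": mean(100.0 * (spec.cover_left(s) + spec.cover_right(s)) / W),
        "M9": 100.0 * pool_len / length,
    }
    cats = {k: score_value(k.split("_")[0], v, "M") for k, v in values.items()}
    return {"values": values, "categories": {k: c.label for k, c in cats.items()}}


def generate_site(spec: MeanderSpec) -> tuple[SitePlan, BankGeometry, LayerSet, GroundTruth]:
    """Build the full synthetic input bundle for one meander spec.

    Banks are the sine centerline offset by ±W(s)/2; every layer is an
    offset strip per its width profile; bed points put the channel bed
    at ``water_surface_elev − D(s)``.  Raises when the meander
    self-intersects (amplitude too large for the wavelength/width).
    """
    nodes, s, t, n_left = _dense_frame(spec)
    length = float(s[-1])
    halfw = spec.width(s) / 2.0

    left = _offset_line(nodes, n_left, halfw)
    right = _offset_line(nodes, n_left, -halfw)
    left_line, right_line = LineString(left), LineString(right)
    if not (left_line.is_simple and right_line.is_simple):
        raise ValueError("self-intersecting meander: amplitude too large for wavelength")

    banks = BankGeometry(
        left_bank=left_line,
        right_bank=right_line,
        inlet=Point(nodes[0]),
        outlet=Point(nodes[-1]),
        left_bank_top=LineString(_offset_line(nodes, n_left, halfw + spec.bank_top_offset)),
        right_bank_top=LineString(_offset_line(nodes, n_left, -(halfw + spec.bank_top_offset))),
    ).validate()

    layers = LayerSet(
        erosion={
            "left": _layer_strips(spec, nodes, s, n_left, "left", spec.erosion_left, "out"),
            "right": _layer_strips(spec, nodes, s, n_left, "right", spec.erosion_right, "out"),
        },
        veg_buffer={
            "left": _layer_strips(spec, nodes, s, n_left, "left", spec.buffer_left, "out"),
            "right": _layer_strips(spec, nodes, s, n_left, "right", spec.buffer_right, "out"),
        },
        instream_cover={
            "left": _layer_strips(spec, nodes, s, n_left, "left", spec.cover_left, "in"),
            "right": _layer_strips(spec, nodes, s, n_left, "right", spec.cover_right, "in"),
        },
        woody_debris={"left": [], "right": []},
    )

    n_bed = max(int(length / spec.bed_point_spacing), 2)
    s_bed = np.linspace(0.0, length, n_bed + 1)
    xy_bed = np.stack([np.interp(s_bed, s, nodes[:, 0]),
                       np.interp(s_bed, s, nodes[:, 1])], axis=1)
    z_bed = spec.water_surface_elev - spec.depth_at(s_bed)
    layers.bed_points = np.column_stack([xy_bed, z_bed])
    layers.water_surface = spec.water_surface_elev
    layers.white_fraction = np.column_stack([s_bed, spec.white_at(s_bed)])
    layers.validate()

    channel = banks.channel_polygon()
    minx, miny, maxx, maxy = channel.buffer(60.0).bounds
    site = SitePlan(boundary=box(minx, miny, maxx, maxy),
                    stream_channel=channel).validate()

    tangents = t
    truth = GroundTruth(
        centerline=Centerline(nodes=nodes, s=s, tangent=tangents,
                              straight_dist=float(np.linalg.norm(nodes[-1] - nodes[0]))),
        sinuosity=spec.exact_sinuosity(),
        length=spec.exact_length(),
        straight_dist=spec.axis_length,
        width_at=spec.width,
        depth_at=spec.depth_at,
        bend_stations=_analytic_bends(spec, s, nodes[:, 0]),
        pool_intervals=[PoolInterval(s0, s1) for s0, s1 in sorted(spec.pool_reaches)],
        expected_categories=_expected_categories(spec, s, length),
    )
    return site, banks, layers, truth


def generate_obstacle_field(extent: tuple[float, float], n_obstacles: int,
                            seed: int = 0, margin: float = 2.0) -> SitePlan:
    """Random non-overlapping obstacle polygons in a rectangular site.

    Rectangles and circles, tagged tree or building, reproducible by
    seed; raises when placement without overlap fails after bounded
    retries.
    """
    if n_obstacles < 0:
        raise ValueError("n_obstacles must be >= 0")
    rng = np.random.default_rng(seed)
    W, H = extent
    boundary = box(0.0, 0.0, W, H)
    obstacles: list[Obstacle] = []
    attempts = 0
    max_attempts = 200 * max(n_obstacles, 1)
    while len(obstacles) < n_obstacles:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_obstacles} disjoint obstacles in {extent} "
                f"after {max_attempts} attempts"
            )
        cx, cy = rng.uniform(5, W - 5), rng.uniform(5, H - 5)
        size = rng.uniform(1.0, 6.0)
        if rng.random() < 0.5:
            geom = box(cx - size / 2, cy - size / 2, cx + size / 2, cy + size / 2)
            kind = "building"
        else:
            geom = Point(cx, cy).buffer(size / 2, quad_segs=8)
            kind = "tree"
        if not boundary.contains(geom):
            continue
        if any(geom.distance(o.geometry) < margin for o in obstacles):
            continue
        obstacles.append(Obstacle(geometry=geom, kind=kind))
    return SitePlan(boundary=boundary, obstacles=obstacles).validate()


def degrade(spec: MeanderSpec, window: tuple[float, float], which: str,
            side: str = "left") -> MeanderSpec:
    """Insert a localized impairment into a meander spec.

    ``which`` selects the impairment: ``"M2"`` removes the vegetation
    buffer inside the window, ``"M3"`` widens erosion to 1.5 m,
    ``"M8"`` removes in-stream cover.  Returns a new spec; regenerate
    with :func:`generate_site` to obtain the modified layers and the
    updated ground truth.  A zero-length window is a no-op.
    """
    s0, s1 = window
    if s1 < s0:
        raise ValueError("window must have s_start <= s_end")
    if s1 == s0:
        return spec
    if side not in {"left", "right"}:
        raise ValueError("side must be left|right")
    if which == "M2":
        prof = getattr(spec, f"buffer_{side}").with_window(s0, s1, 0.0)
        return replace(spec, **{f"buffer_{side}": prof})
    if which == "M3":
        prof = getattr(spec, f"erosion_{side}").with_window(s0, s1, 1.5)
        return replace(spec, **{f"erosion_{side}": prof})
    if which == "M8":
        left = spec.cover_left.with_window(s0, s1, 0.0)
        right = spec.cover_right.with_window(s0, s1, 0.0)
        return replace(spec, cover_left=left, cover_right=right)
    raise ValueError(f"unknown metric code for degradation: {which!r}")
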