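"""Per-station stream habitat parameter measurement.

Given an arc-length-parameterized centerline and delineated vector
layers, measure at every station: wetted width W (shortest bank-to-bank
chord through the node, islands excluded), bank-top width BT, per-side
erosion width E, vegetation buffer width B and in-stream cover width F
(lengths of the station's side rays inside the respective layers),
depth D (water surface minus interpolated bed), wetted fraction, a
continuity-based relative velocity, and pool intervals from percentile
thresholds on depth, velocity and white-water fraction.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring, unary_union

from .model import (
    AssessmentConfig,
    BankGeometry,
    Centerline,
    LayerSet,
    PoolInterval,
    StationRecord,
    TransectChord,
)

__all__ = [
    "width_at",
    "side_width",
    "bank_top_width",
    "depth_series",
    "wet_fraction",
    "velocity_proxy",
    "detect_pools",
    "coverage_fraction",
    "extract_stations",
]


def _chord_piece(line: LineString, polygon: Polygon, node: Point):
    """Connected component of line ∩ polygon containing the node, or None."""
    inter = line.intersection(polygon)
    if inter.is_empty:
        return None
    parts = getattr(inter, "geoms", [inter])
    best, best_d = None, 1e-6
    for part in parts:
        if part.geom_type != "LineString":
            continue
        d = part.distance(node)
        if d <= best_d:
            best, best_d = part, d
    return best


def width_at(
    cl: Centerline,
    index: int,
    banks: BankGeometry,
    channel: Optional[Polygon] = None,
    islands_union=None,
    angle_step_deg: float = 1.0,
) -> tuple[float, TransectChord]:
    """Wetted width at a centerline node: the shortest chord through the
    node between the left and right banks, minus any island crossing.

    Minimality is found by sweeping chord orientations at
    ``angle_step_deg`` resolution over a half-turn, seeded around the
    normal to the local tangent.
    """
    if channel is None:
        channel = banks.channel_polygon()
    node_xy = cl.nodes[index]
    node = Point(node_xy)
    if not channel.covers(node):
        raise ValueError(f"centerline node at s={cl.s[index]:.2f} lies outside the channel")
    if islands_union is None and banks.islands:
        islands_union = unary_union(banks.islands)

    # chord half-length bound: the channel cannot be wider than its bbox diagonal
    minx, miny, maxx, maxy = channel.bounds
    R = math.hypot(maxx - minx, maxy - miny)

    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dx, dy = np.cos(angles), np.sin(angles)
    starts = np.stack([node_xy[0] - R * dx, node_xy[1] - R * dy], axis=1)
    ends = np.stack([node_xy[0] + R * dx, node_xy[1] + R * dy], axis=1)
    lines = shapely.linestrings(np.stack([starts, ends], axis=1))

    def spans_banks(piece) -> bool:
        # both ends must lie on the bank polylines, not on the artificial
        # end caps closing the channel polygon
        p0 = Point(piece.coords[0])
        p1 = Point(piece.coords[-1])
        tol = 1e-6
        return ((banks.left_bank.distance(p0) < tol and banks.right_bank.distance(p1) < tol)
                or (banks.left_bank.distance(p1) < tol and banks.right_bank.distance(p0) < tol))

    candidates = []
    pieces = shapely.intersection(lines, channel)
    for piece in pieces:
        part = None
        if piece.is_empty:
            continue
        if piece.geom_type == "LineString":
            part = piece if piece.distance(node) <= 1e-6 else None
        else:
            best_d = 1e-6
            for sub in piece.geoms:
                if sub.geom_type == "LineString" and sub.distance(node) <= best_d:
                    part, best_d = sub, sub.distance(node)
        if part is not None:
            candidates.append(part)

    candidates.sort(key=lambda p: p.length)
    best_piece = None
    for part in candidates:
        if spans_banks(part):
            best_piece = part
            break
    if best_piece is None:
        raise ValueError(f"no bank-to-bank chord found at s={cl.s[index]:.2f} "
                         "(station too close to the channel end?)")
    best_len = best_piece.length

    island_overlap = 0.0
    if islands_union is not None:
        overlap = best_piece.intersection(islands_union)
        island_overlap = overlap.length if not overlap.is_empty else 0.0

    (x0, y0), (x1, y1) = best_piece.coords[0], best_piece.coords[-1]
    # orient endpoints: left is the side with positive cross(tangent, v)
    t = cl.tangent[index]
    cross0 = t[0] * (y0 - node_xy[1]) - t[1] * (x0 - node_xy[0])
    left_pt, right_pt = (Point(x0, y0), Point(x1, y1)) if cross0 > 0 else (
        Point(x1, y1), Point(x0, y0))

    chord = TransectChord(
        s=float(cl.s[index]), node=node, left_point=left_pt, right_point=right_pt,
        length=float(best_len), island_overlap_m=float(island_overlap),
    )
    return float(best_len - island_overlap), chord


def _side_ray(chord: TransectChord, side: str, max_dist_m: float) -> LineString:
    """Ray from the node through the bank point on the given side, extended
    ``max_dist_m`` beyond the bank."""
    node = np.array([chord.node.x, chord.node.y])
    bank = (np.array([chord.left_point.x, chord.left_point.y]) if side == "left"
            else np.array([chord.right_point.x, chord.right_point.y]))
    d = bank - node
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("degenerate chord: node coincides with bank point")
    u = d / norm
    return LineString([node, bank + u * max_dist_m])


def _clip_ray_at_channel_reentry(ray: LineString, channel: Polygon) -> LineString:
    """Truncate a side ray where it re-enters the stream channel.

    In a tightly meandering channel a long side ray can cross into an
    adjacent limb of the same stream; anything beyond that crossing
    belongs to a different reach and must not count toward this
    station's side widths.
    """
    inter = ray.intersection(channel)
    segs = []
    for g in getattr(inter, "geoms", [inter]):
        if g.geom_type == "LineString" and g.length > 1e-9:
            t0 = ray.project(Point(g.coords[0]))
            t1 = ray.project(Point(g.coords[-1]))
            segs.append((min(t0, t1), max(t0, t1)))
    segs.sort()
    if len(segs) <= 1:
        return ray
    first_exit = segs[0][1]
    for a, _ in segs[1:]:
        if a > first_exit + 1e-6:
            return substring(ray, 0.0, a)
    return ray


def side_width(chord: TransectChord, layer: Sequence[Polygon], side: str,
               max_dist_m: float = 100.0,
               channel: Optional[Polygon] = None,
               contiguous: bool = False,
               attach_tol_m: float = 0.5) -> float:
    """Width of a bank-side layer along the station's side ray.

    The ray runs from the centerline node through the bank point on the
    requested side, extended ``max_dist_m`` past the bank (truncated
    where it would re-enter the ``channel``, if given).  By default the
    returned width is the total (union) length of the ray inside the
    layer polygons — disjoint patches sum, 0 when the layer misses the
    ray.  With ``contiguous=True`` only the connected run attached to
    the bank counts (the field definition of buffer and erosion widths:
    a gap of other land cover ends the zone); the run must begin within
    ``attach_tol_m`` of the bank.
    """
    if side not in {"left", "right"}:
        raise ValueError("side must be left|right")
    if not layer:
        return 0.0
    ray = _side_ray(chord, side, max_dist_m)
    if channel is not None:
        ray = _clip_ray_at_channel_reentry(ray, channel)
    inter = ray.intersection(unary_union(list(layer)))
    if inter.is_empty:
        return 0.0
    if not contiguous:
        return float(inter.length)

    t_bank = chord.node.distance(
        chord.left_point if side == "left" else chord.right_point)
    segs = []
    for g in getattr(inter, "geoms", [inter]):
        if g.geom_type == "LineString" and g.length > 1e-9:
            t0 = ray.project(Point(g.coords[0]))
            t1 = ray.project(Point(g.coords[-1]))
            segs.append([min(t0, t1), max(t0, t1)])
    segs.sort()
    # chain segments separated by sub-tolerance slivers
    merged = []
    for a, b in segs:
        if merged and a - merged[-1][1] < 1e-6:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    for a, b in merged:
        if b > t_bank and a <= t_bank + attach_tol_m:
            return float(b - max(a, t_bank))
    return 0.0


def bank_top_width(chord: TransectChord, left_bank_top: Optional[LineString],
                   right_bank_top: Optional[LineString],
                   search_dist_m: float = 200.0) -> Optional[float]:
    """Bank-top width BT: distance between the chord line's intersections
    with the left and right bank-top polylines; None (flagged missing)
    when either side has no intersection within the search distance.
    """
    node = np.array([chord.node.x, chord.node.y])
    points = {}
    for side, top in (("left", left_bank_top), ("right", right_bank_top)):
        if top is None:
            return None
        ray = _side_ray(chord, side, search_dist_m)
        inter = ray.intersection(top)
        if inter.is_empty:
            return None
        cands = getattr(inter, "geoms", [inter])
        pts = []
        for g in cands:
            pts.extend([Point(c) for c in getattr(g, "coords", [])] or [g])
        points[side] = min(pts, key=lambda p: p.distance(chord.node))
    return float(points["left"].distance(points["right"]))


def depth_series(
    station_s: np.ndarray,
    cl: Centerline,
    water_surface,
    bed_points: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Depth D(s) = water surface elevation − interpolated bed elevation.

    Bed points (x, y, z) are projected to the nearest centerline station
    and linearly interpolated along s; negative depths are clipped to 0
    and counted in the returned warning count.
    """
    bed_points = np.asarray(bed_points, dtype=float)
    if bed_points.ndim != 2 or bed_points.shape[0] < 2:
        raise ValueError("need at least 2 bed points (x, y, elevation)")
    line = cl.as_linestring()
    proj_s = np.array([line.project(Point(p[0], p[1])) for p in bed_points])
    order = np.argsort(proj_s)
    proj_s, bed_z = proj_s[order], bed_points[order, 2]
    # collapse duplicate projections
    uniq_s, idx = np.unique(proj_s, return_index=True)
    bed = np.interp(station_s, uniq_s, bed_z[idx])

    if callable(water_surface):
        surf = np.asarray(water_surface(station_s), dtype=float)
    elif np.isscalar(water_surface):
        surf = np.full_like(np.asarray(station_s, dtype=float), float(water_surface))
    else:
        table = np.asarray(water_surface, dtype=float)
        surf = np.interp(station_s, table[:, 0], table[:, 1])

    depth = surf - bed
    n_clipped = int((depth < 0).sum())
    return np.clip(depth, 0.0, None), n_clipped


def wet_fraction(chord: TransectChord, channel: Polygon,
                 islands: Sequence[Polygon] = (),
                 dry_polygons: Sequence[Polygon] = ()) -> float:
    """Fraction of the chord's in-channel length that is wetted.

    Islands and explicitly dry polygons subtract from the wetted length;
    the result lies in [0, 1].
    """
    line = LineString([chord.left_point, chord.right_point])
    inside = line.intersection(channel)
    total = inside.length if not inside.is_empty else 0.0
    if total <= 0:
        return 0.0
    dry_geoms = list(islands) + list(dry_polygons)
    dry_len = 0.0
    if dry_geoms:
        dry = inside.intersection(unary_union(dry_geoms))
        dry_len = dry.length if not dry.is_empty else 0.0
    return float(np.clip((total - dry_len) / total, 0.0, 1.0))


def velocity_proxy(W: float, D: float, reference_discharge: float = 1.0) -> float:
    """Relative flow velocity from continuity: v ∝ Q / (W·D).

    Dimensionless and only ordinally meaningful — it ranks stations as
    faster or slower for pool detection.  Returns NaN (missing) when the
    section area W·D is zero.
    """
    area = W * D
    if not np.isfinite(area) or area <= 0:
        return float("nan")
    return reference_discharge / area


def detect_pools(records: Sequence[StationRecord],
                 cfg: AssessmentConfig) -> list[PoolInterval]:
    """Pool reaches from the three-threshold rule.

    A station is pool-flagged iff its depth exceeds the ``depth_pct``
    percentile of all stations, its velocity proxy is below the
    ``vel_pct`` percentile, and its white-water fraction is below
    ``white_max`` (this criterion is skipped with a warning when no
    white fractions are available).  Maximal runs of flagged stations
    become intervals; runs separated by less than one station spacing
    merge.
    """
    import warnings

    if len(records) < 10:
        raise ValueError(f"need at least 10 stations for pool detection, got {len(records)}")
    s = np.array([r.s for r in records])
    D = np.array([r.D for r in records])
    v = np.array([r.v_proxy for r in records])
    white = np.array([r.white_fraction for r in records])

    if not np.isfinite(D).all():
        raise ValueError("pool detection requires a complete depth series")
    finite_v = np.isfinite(v)
    if not finite_v.any():
        raise ValueError("pool detection requires velocity proxies")

    d_thr = np.percentile(D, cfg.depth_pct)
    v_thr = np.percentile(v[finite_v], cfg.vel_pct)
    flagged = (D > d_thr) & finite_v & (v < v_thr)

    if np.isfinite(white).any():
        flagged &= np.where(np.isfinite(white), white < cfg.white_max, False)
    else:
        warnings.warn("white-water fractions absent; pool rule uses depth and "
                      "velocity thresholds only", stacklevel=2)

    spacing = float(np.median(np.diff(s)))
    intervals: list[PoolInterval] = []
    i, n = 0, len(s)
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            intervals.append(PoolInterval(s_start=float(s[i] - spacing / 2),
                                          s_end=float(s[j] + spacing / 2)))
            i = j + 1
        else:
            i += 1

    # merge runs separated by less than one station spacing
    merged: list[PoolInterval] = []
    for iv in intervals:
        if merged and iv.s_start - merged[-1].s_end < spacing * (1 - 1e-9):
            merged[-1] = PoolInterval(merged[-1].s_start, iv.s_end)
        else:
            merged.append(iv)
    return merged


def coverage_fraction(bank: LineString, layer: Sequence[Polygon],
                      max_dist_m: float) -> float:
    """Fraction of bank arc-length within ``max_dist_m`` of the layer."""
    if bank.length <= 0:
        raise ValueError("bank polyline is degenerate")
    if not layer:
        return 0.0
    near = unary_union(list(layer)).buffer(max_dist_m)
    covered = bank.intersection(near)
    return float(covered.length / bank.length)


def extract_stations(
    cl: Centerline,
    banks: BankGeometry,
    layers: LayerSet,
    cfg: Optional[AssessmentConfig] = None,
    reference_discharge: float = 1.0,
    node_stride: int = 1,
) -> list[StationRecord]:
    """Measure the full per-station parameter bundle along a centerline.

    Convenience driver over the individual measurement operations;
    stations are every ``node_stride``-th centerline node (a centerline
    can be resolved finer than the station spacing).  End nodes that
    touch the channel boundary or admit no bank-to-bank chord are
    skipped.
    """
    cfg = cfg or AssessmentConfig()
    channel = banks.channel_polygon()
    islands_union = unary_union(banks.islands) if banks.islands else None

    records: list[StationRecord] = []
    chords: list[TransectChord] = []
    kept_idx: list[int] = []
    for i in range(0, len(cl.nodes), max(int(node_stride), 1)):
        node = Point(cl.nodes[i])
        if not channel.covers(node) or channel.exterior.distance(node) < 1e-9:
            continue
        try:
            W, chord = width_at(cl, i, banks, channel=channel,
                                islands_union=islands_union)
        except ValueError:
            # unmeasurable end-of-channel station
            continue
        rec = StationRecord(s=float(cl.s[i]), x=float(cl.nodes[i, 0]),
                            y=float(cl.nodes[i, 1]), W=W)
        # buffer/erosion are contiguous zones from the bank; cover patches sum
        sw = lambda lyr, side, cont: side_width(chord, lyr[side], side,
                                                cfg.side_ray_max_m,
                                                channel=channel, contiguous=cont)
        rec.E_left = sw(layers.erosion, "left", True)
        rec.E_right = sw(layers.erosion, "right", True)
        rec.B_left = sw(layers.veg_buffer, "left", True)
        rec.B_right = sw(layers.veg_buffer, "right", True)
        rec.F_left = sw(layers.instream_cover, "left", False)
        rec.F_right = sw(layers.instream_cover, "right", False)
        bt = bank_top_width(chord, banks.left_bank_top, banks.right_bank_top)
        rec.BT = float("nan") if bt is None else bt
        rec.wet_fraction = wet_fraction(chord, channel, banks.islands)
        records.append(rec)
        chords.append(chord)
        kept_idx.append(i)

    if not records:
        raise ValueError("no interior stations: channel too short for the spacing")

    s_arr = np.array([r.s for r in records])
    if layers.bed_points.shape[0] >= 2:
        D, _ = depth_series(s_arr, cl, layers.water_surface, layers.bed_points)
        for rec, d in zip(records, D):
            rec.D = float(d)
            rec.v_proxy = velocity_proxy(rec.W, float(d), reference_discharge)
    white = layers.white_at(s_arr)
    if white is not None:
        for rec, wf in zip(records, np.asarray(white, dtype=float)):
            rec.white_fraction = float(wf)
    for rec in records:
        rec.validate()
    return records
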