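"""UAV survey flight-route planning.

Workflow: buffer obstacles and mark the riparian focus corridor, derive
the sweep-line spacing Δd from the camera footprint and target image
overlap, lay out an S-shaped (boustrophedon) coverage sweep, detour any
blocked segment with an optimal 8-connected grid search over a
conservative occupancy grid, remove redundant route nodes, and budget
the flight time against the battery.

The grid search is a single-shot optimal shortest path (Dijkstra over
(cell, heading) states so that equal-length paths deterministically
prefer fewer turns, then the lexicographically smallest node sequence),
followed by the two node-removal rules: strictly collinear interior
nodes, and interior nodes whose neighbours see each other past all
obstacles.
"""

from __future__ import annotations

import heapq
import math
from typing import Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .model import CameraModel, FlightConfig, FlightRoute, SitePlan

__all__ = [
    "buffer_features",
    "line_spacing",
    "generate_sweep",
    "rasterize_obstacles",
    "OccupancyGrid",
    "grid_shortest_path",
    "detour_mdl",
    "simplify_route",
    "flight_time",
    "plan_route",
]

SQRT2 = math.sqrt(2.0)


def buffer_features(site: SitePlan, cfg: FlightConfig) -> tuple[list[Polygon], Optional[Polygon]]:
    """Dilate obstacles into no-fly zones and the stream into a focus zone.

    Returns ``(blocked_zones, focus_zone)``: each obstacle polygon
    dilated by ``buffer_obstacle_m``, and the stream channel dilated by
    ``focus_corridor_m`` clipped to the boundary (None without a
    channel).
    """
    site.validate()
    blocked = [obs.geometry.buffer(cfg.buffer_obstacle_m) for obs in site.obstacles]
    if blocked:
        flyable = site.boundary.difference(unary_union(blocked))
        if flyable.is_empty or flyable.area < 1e-9:
            raise ValueError("no flyable area: buffered obstacles cover the boundary")
    focus = None
    if site.stream_channel is not None:
        focus = site.stream_channel.buffer(cfg.focus_corridor_m).intersection(site.boundary)
    return blocked, focus


def line_spacing(alt_m: float, overlap: float, cam: CameraModel) -> float:
    """Sweep-line spacing Δd for a target cross-track image overlap.

    The ground footprint across track is ``2·h·tan(FOV/2)`` for a
    pinhole camera at altitude h; adjacent lines overlap by ``overlap``
    when spaced at ``footprint · (1 − overlap)``.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    if alt_m <= 0:
        raise ValueError("altitude must be positive")
    footprint = 2.0 * alt_m * math.tan(math.radians(cam.fov_cross_track_deg) / 2.0)
    return footprint * (1.0 - overlap)


def _sweep_ys(ymin: float, ymax: float, delta_d: float,
              focus: Optional[Polygon], delta_d_focus: float,
              xmin: float, xmax: float) -> np.ndarray:
    extent = ymax - ymin
    if extent < delta_d:
        return np.array([(ymin + ymax) / 2.0])
    n = int(math.ceil(extent / delta_d)) + 1
    ys = list(np.linspace(ymin, ymax, n))
    if focus is None or focus.is_empty or delta_d_focus >= delta_d:
        return np.array(ys)
    refined: list[float] = []
    for y0, y1 in zip(ys[:-1], ys[1:]):
        refined.append(y0)
        band = box(xmin, y0, xmax, y1)
        if band.intersects(focus):
            k = int(math.ceil((y1 - y0) / delta_d_focus))
            refined.extend(np.linspace(y0, y1, k + 1)[1:-1])
    refined.append(ys[-1])
    return np.array(refined)


def generate_sweep(boundary: Polygon, delta_d: float,
                   focus: Optional[Polygon] = None,
                   delta_d_focus: Optional[float] = None,
                   altitude_m: float = 30.0) -> FlightRoute:
    """S-shaped boustrophedon sweep of parallel lines over the boundary.

    Lines run parallel to the x-axis, spaced at most ``delta_d`` apart
    (at most ``delta_d_focus`` across bands touching the focus zone),
    clipped to the boundary and connected end-to-end in alternating
    direction.  Sweep-line edges are classed ``survey``; connectors
    ``transit``.
    """
    if boundary.is_empty or boundary.area <= 0:
        raise ValueError("degenerate boundary: zero area")
    if delta_d <= 0:
        raise ValueError("delta_d must be positive")
    if delta_d_focus is None:
        delta_d_focus = delta_d
    if delta_d_focus > delta_d:
        raise ValueError("focus spacing must not exceed default spacing")

    xmin, ymin, xmax, ymax = boundary.bounds
    ys = _sweep_ys(ymin, ymax, delta_d, focus, delta_d_focus, xmin, xmax)

    sweep_lines: list[LineString] = []
    rows: list[list[LineString]] = []
    for y in ys:
        scan = LineString([(xmin - 1.0, y), (xmax + 1.0, y)])
        clip = scan.intersection(boundary)
        pieces = [g for g in getattr(clip, "geoms", [clip])
                  if g.geom_type == "LineString" and g.length > 1e-9]
        if not pieces:
            # boundary edge grazing: nudge inside
            eps = min(1e-6, (ymax - ymin) / 1e6)
            y_adj = y + eps if abs(y - ymin) < abs(y - ymax) else y - eps
            clip = LineString([(xmin - 1.0, y_adj), (xmax + 1.0, y_adj)]).intersection(boundary)
            pieces = [g for g in getattr(clip, "geoms", [clip])
                      if g.geom_type == "LineString" and g.length > 1e-9]
        pieces.sort(key=lambda g: g.bounds[0])
        rows.append(pieces)
        sweep_lines.extend(pieces)

    waypoints: list[tuple[float, float, float]] = []
    classes: list[str] = []
    forward = True
    for pieces in rows:
        ordered = pieces if forward else pieces[::-1]
        for piece in ordered:
            coords = list(piece.coords)
            if not forward:
                coords = coords[::-1]
            start, end = coords[0], coords[-1]
            if waypoints:
                last = waypoints[-1]
                if (last[0], last[1]) != start:
                    waypoints.append((start[0], start[1], altitude_m))
                    classes.append("transit")
            else:
                waypoints.append((start[0], start[1], altitude_m))
            waypoints.append((end[0], end[1], altitude_m))
            classes.append("survey")
        if pieces:
            forward = not forward

    return FlightRoute(waypoints=np.array(waypoints), segment_class=classes,
                       sweep_lines=sweep_lines)


class OccupancyGrid:
    """Conservative boolean occupancy lattice over the flight area.

    A cell is blocked when it intersects any buffered obstacle at all
    (partial overlap blocks) or is not fully inside the boundary.
    """

    def __init__(self, origin: tuple[float, float], cell_m: float,
                 blocked: np.ndarray):
        if cell_m <= 0:
            raise ValueError("cell size must be positive")
        self.origin = (float(origin[0]), float(origin[1]))
        self.cell_m = float(cell_m)
        self.blocked = np.asarray(blocked, dtype=bool)
        self._tree: Optional[STRtree] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.blocked.shape  # (ny, nx)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        j = int((x - self.origin[0]) // self.cell_m)
        i = int((y - self.origin[1]) // self.cell_m)
        return i, j

    def center(self, i: int, j: int) -> tuple[float, float]:
        return (self.origin[0] + (j + 0.5) * self.cell_m,
                self.origin[1] + (i + 0.5) * self.cell_m)

    def in_bounds(self, i: int, j: int) -> bool:
        ny, nx = self.blocked.shape
        return 0 <= i < ny and 0 <= j < nx

    def is_free(self, i: int, j: int) -> bool:
        return self.in_bounds(i, j) and not self.blocked[i, j]

    def _blocked_tree(self) -> STRtree:
        if self._tree is None:
            boxes = []
            ii, jj = np.nonzero(self.blocked)
            x0, y0 = self.origin
            c = self.cell_m
            for i, j in zip(ii, jj):
                boxes.append(box(x0 + j * c, y0 + i * c,
                                 x0 + (j + 1) * c, y0 + (i + 1) * c))
            self._tree = STRtree(boxes) if boxes else STRtree([box(0, 0, 0, 0).buffer(0)])
            self._boxes = boxes
        return self._tree

    def segment_blocked(self, p: Sequence[float], q: Sequence[float]) -> bool:
        """Does the open segment p→q intersect any blocked cell interior?"""
        if not np.any(self.blocked):
            return False
        seg = LineString([tuple(p[:2]), tuple(q[:2])])
        tree = self._blocked_tree()
        for idx in tree.query(seg):
            cell_box = self._boxes[idx]
            inter = seg.intersection(cell_box)
            # grazing a cell edge with zero penetration length is allowed
            if not inter.is_empty and inter.length > 1e-9:
                return True
        return False


def rasterize_obstacles(blocked_zones: Sequence[Polygon], boundary: Polygon,
                        cell_m: float = 1.0) -> OccupancyGrid:
    """Conservative rasterization of no-fly zones over the boundary bbox."""
    if cell_m <= 0:
        raise ValueError("cell size must be positive")
    xmin, ymin, xmax, ymax = boundary.bounds
    if cell_m > max(xmax - xmin, ymax - ymin):
        raise ValueError("cell size exceeds the boundary extent")
    nx = int(math.ceil((xmax - xmin) / cell_m))
    ny = int(math.ceil((ymax - ymin) / cell_m))

    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    x0 = xmin + jj * cell_m
    y0 = ymin + ii * cell_m
    cells = shapely.box(x0.ravel(), y0.ravel(),
                        x0.ravel() + cell_m, y0.ravel() + cell_m)

    inside = shapely.contains(boundary, cells).reshape(ny, nx)
    blocked = ~inside
    if blocked_zones:
        union = unary_union(list(blocked_zones))
        hits = shapely.intersects(union, cells).reshape(ny, nx)
        blocked |= hits
    return OccupancyGrid(origin=(xmin, ymin), cell_m=cell_m, blocked=blocked)


_DIRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def grid_shortest_path(grid: OccupancyGrid, start: tuple[int, int],
                       goal: tuple[int, int]) -> tuple[list[tuple[int, int]], float]:
    """Optimal 8-connected grid path (diagonal cost √2), deterministic.

    Dijkstra over (cell, incoming-direction) states; ties on length are
    broken by fewer turns, then the smaller node index, so equal-cost
    paths resolve identically across runs.  Diagonal moves must not cut
    a blocked corner.  Raises when no free path exists.
    """
    if not grid.is_free(*start):
        raise ValueError(f"start cell {start} is blocked or out of bounds")
    if not grid.is_free(*goal):
        raise ValueError(f"goal cell {goal} is blocked or out of bounds")
    if start == goal:
        return [start], 0.0

    best: dict[tuple, tuple] = {}
    # heap entries: (dist, turns, cell, dir_idx)
    heap: list[tuple] = [(0.0, 0, start, -1)]
    parent: dict[tuple, tuple] = {}
    goal_state = None

    while heap:
        dist, turns, cell, d_in = heapq.heappop(heap)
        state = (cell, d_in)
        if state in best and (dist, turns) > best[state]:
            continue
        if cell == goal:
            goal_state = state
            break
        for d_idx, (di, dj) in enumerate(_DIRS):
            ni, nj = cell[0] + di, cell[1] + dj
            if not grid.is_free(ni, nj):
                continue
            if di and dj:  # no corner cutting
                if not (grid.is_free(cell[0] + di, cell[1])
                        and grid.is_free(cell[0], cell[1] + dj)):
                    continue
            step = SQRT2 if (di and dj) else 1.0
            ndist = dist + step
            nturns = turns + (1 if (d_in != -1 and d_idx != d_in) else 0)
            nstate = ((ni, nj), d_idx)
            key = (ndist, nturns)
            if nstate not in best or key < best[nstate]:
                best[nstate] = key
                parent[nstate] = state
                heapq.heappush(heap, (ndist, nturns, (ni, nj), d_idx))

    if goal_state is None:
        raise ValueError(f"no free path between {start} and {goal}")

    path = []
    state = goal_state
    while True:
        path.append(state[0])
        if state[0] == start and state[1] == -1:
            break
        state = parent[state]
    path.reverse()
    cost = sum(SQRT2 if (abs(a[0] - b[0]) + abs(a[1] - b[1]) == 2) else 1.0
               for a, b in zip(path[:-1], path[1:]))
    return path, cost


def detour_mdl(route: FlightRoute, grid: OccupancyGrid) -> FlightRoute:
    """Replace blocked route edges with optimal grid detours.

    Each edge that crosses a blocked cell is substituted by the optimal
    8-connected grid path between its endpoints' cells (waypoints at
    cell centers); free edges pass through untouched.  Raises when an
    endpoint sits on a blocked cell or a blocked edge has no free
    detour.
    """
    wpts = route.waypoints
    for k, p in enumerate(wpts):
        cell = grid.cell_of(p[0], p[1])
        if not grid.is_free(*cell):
            raise ValueError(f"route waypoint {k} at {tuple(p[:2])} lies on a blocked cell")

    new_wpts: list[tuple[float, float, float]] = [tuple(wpts[0])]
    new_classes: list[str] = []
    for k in range(len(wpts) - 1):
        p, q = wpts[k], wpts[k + 1]
        cls = route.segment_class[k]
        if not grid.segment_blocked(p, q):
            new_wpts.append(tuple(q))
            new_classes.append(cls)
            continue
        start = grid.cell_of(p[0], p[1])
        goal = grid.cell_of(q[0], q[1])
        try:
            cells, _ = grid_shortest_path(grid, start, goal)
        except ValueError as exc:
            raise ValueError(
                f"no free detour for blocked segment {tuple(p[:2])} -> {tuple(q[:2])}"
            ) from exc
        alt = p[2]
        for cell in cells:
            cx, cy = grid.center(*cell)
            last = new_wpts[-1]
            if (last[0], last[1]) != (cx, cy):
                new_wpts.append((cx, cy, alt))
                new_classes.append(cls)
        last = new_wpts[-1]
        if (last[0], last[1]) != (q[0], q[1]):
            new_wpts.append(tuple(q))
            new_classes.append(cls)

    return FlightRoute(waypoints=np.array(new_wpts), segment_class=new_classes,
                       sweep_lines=route.sweep_lines)


def _collinear(a, b, c, tol: float = 1e-9) -> bool:
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    return abs(cross) <= tol * max(1.0, abs(b[0] - a[0]) + abs(b[1] - a[1]))


def simplify_route(route: FlightRoute, grid: OccupancyGrid) -> FlightRoute:
    """Remove redundant route nodes.

    Two rules, applied until fixed point: (a) strictly collinear
    interior nodes are dropped; (b) greedy line-of-sight shortcutting —
    an interior node is dropped when the segment joining its neighbours
    misses every blocked cell.  The result still avoids all blocked
    cells, and the path length never increases.  Survey/transit classes
    survive; an edge produced by merging takes the class of its first
    constituent.
    """
    wpts = [tuple(p) for p in route.waypoints]
    classes = list(route.segment_class)
    changed = True
    while changed and len(wpts) > 2:
        changed = False
        k = 1
        while k < len(wpts) - 1:
            a, b, c = wpts[k - 1], wpts[k], wpts[k + 1]
            removable = _collinear(a, b, c) or not grid.segment_blocked(a, c)
            # only merge edges of the same class; removing a node that joins
            # survey to transit would misclassify flight time
            if removable and classes[k - 1] == classes[k]:
                del wpts[k]
                del classes[k]
                changed = True
            else:
                k += 1
    return FlightRoute(waypoints=np.array(wpts), segment_class=classes,
                       sweep_lines=route.sweep_lines)


def flight_time(route: FlightRoute, cfg: FlightConfig,
                elevation: str) -> tuple[float, bool]:
    """Route duration in seconds and battery feasibility.

    Duration = survey length / survey speed + transit length / transit
    speed + fixed liftoff/landing overhead; feasible iff within
    ``usable_fraction`` of the battery endurance.
    """
    if len(route.waypoints) == 0:
        raise ValueError("empty route")
    survey_speed, transit_speed = cfg.speeds(elevation)
    lengths = route.length_by_class()
    seconds = (lengths["survey"] / survey_speed
               + lengths["transit"] / transit_speed
               + cfg.overhead_s)
    budget = cfg.usable_fraction * cfg.battery_min * 60.0
    return float(seconds), bool(seconds <= budget)


def plan_route(site: SitePlan, cfg: FlightConfig, cam: CameraModel,
               elevation: str = "high", cell_m: float = 1.0) -> FlightRoute:
    """End-to-end planning: buffer, sweep, detour, simplify."""
    alt = cfg.alt_high_m if elevation == "high" else cfg.alt_low_m
    blocked, focus = buffer_features(site, cfg)
    dd = line_spacing(alt, cfg.overlap_default, cam)
    dd_focus = line_spacing(alt, cfg.overlap_focus, cam)
    # inset the sweep area by one grid cell so sweep waypoints land in
    # cells fully interior to the boundary (edge cells are blocked by
    # the conservative rasterization)
    sweep_area = site.boundary.buffer(-cell_m)
    if sweep_area.is_empty:
        raise ValueError("boundary too small for the grid cell size")
    route = generate_sweep(sweep_area, dd, focus, min(dd_focus, dd), altitude_m=alt)
    grid = rasterize_obstacles(blocked, site.boundary, cell_m)

    # drop sweep waypoints inside blocked cells (the sweep is geometry-only);
    # a merged edge is survey only if both constituents were survey
    wpts: list[np.ndarray] = []
    classes: list[str] = []
    pending: Optional[str] = None
    for k, p in enumerate(route.waypoints):
        free = grid.is_free(*grid.cell_of(p[0], p[1]))
        edge_cls = route.segment_class[k - 1] if k > 0 else None
        if edge_cls is not None and pending is not None:
            edge_cls = "transit" if "transit" in (edge_cls, pending) else "survey"
        if free:
            if wpts and edge_cls is not None:
                classes.append(edge_cls)
            wpts.append(p)
            pending = None
        else:
            pending = edge_cls if edge_cls is not None else "transit"
    if len(wpts) < 2:
        raise ValueError("no flyable sweep waypoints after rasterization")
    route = FlightRoute(waypoints=np.array(wpts), segment_class=classes,
                        sweep_lines=route.sweep_lines)
    route = detour_mdl(route, grid)
    return simplify_route(route, grid)
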