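"""Stream centerline extraction and longitudinal channel descriptors.

The centerline is the medial axis of the channel polygon bounded by the
left and right banks: the locus of centers of maximal inscribed disks.
It is approximated from the Voronoi diagram of densely sampled boundary
vertices — Voronoi edges interior to the polygon converge to the medial
axis as the sampling step shrinks.  Side spurs (branches toward bank
corners) are pruned by keeping only the path between the skeleton nodes
nearest the inlet and outlet, which is then extended to the inlet and
outlet points, resampled at a uniform step, and arc-length
parameterized.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString, MultiPoint, Point

from .model import BankGeometry, Bend, Centerline

__all__ = ["medial_axis", "sinuosity", "sinuosity_from_lengths",
           "detect_bends", "gradient", "centerline_from_points"]


def centerline_from_points(coords) -> Centerline:
    """Build an arc-length-parameterized centerline from raw polyline points."""
    nodes = np.asarray(coords, dtype=float)
    if nodes.ndim != 2 or nodes.shape[0] < 2:
        raise ValueError("need at least two points")
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    if (seg == 0).any():
        raise ValueError("consecutive points must be distinct")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    tangents = np.gradient(nodes, s, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Centerline(nodes=nodes, s=s, tangent=tangents / norms,
                      straight_dist=float(np.linalg.norm(nodes[-1] - nodes[0])))


def _skeleton_graph(polygon, step: float) -> nx.Graph:
    """Graph of Voronoi edges of the densified boundary, clipped to the interior."""
    boundary = polygon.exterior
    n = max(int(math.ceil(boundary.length / step)), 8)
    pts = [boundary.interpolate(i * boundary.length / n) for i in range(n)]
    edges = shapely.voronoi_polygons(MultiPoint(pts), only_edges=True)

    # keep only edge segments strictly interior to the channel
    interior = polygon.buffer(-1e-9) if polygon.area > 0 else polygon
    clipped = shapely.intersection(edges, interior)

    graph = nx.Graph()
    parts = getattr(clipped, "geoms", [clipped])
    for part in parts:
        if part.is_empty or part.geom_type != "LineString":
            continue
        coords = list(part.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            pa = (round(a[0], 9), round(a[1], 9))
            pb = (round(b[0], 9), round(b[1], 9))
            if pa != pb:
                graph.add_edge(pa, pb, weight=math.dist(pa, pb))
    return graph


def _nearest_node(graph: nx.Graph, point: Point):
    return min(graph.nodes, key=lambda n: (n[0] - point.x) ** 2 + (n[1] - point.y) ** 2)


def _resample(coords: np.ndarray, spacing: float) -> np.ndarray:
    line = LineString(coords)
    n = max(int(round(line.length / spacing)), 2)
    stations = np.linspace(0.0, line.length, n + 1)
    return np.array([line.interpolate(t).coords[0] for t in stations])


def medial_axis(banks: BankGeometry, spacing_m: float) -> Centerline:
    """Medial-axis centerline of the channel between the banks.

    Parameters
    ----------
    banks
        Bank geometry with inlet and outlet points; islands are ignored
        (the axis follows the outer banks).
    spacing_m
        Output node spacing in metres.  The boundary is densified at
        half this step, which also bounds the skeleton discretization
        error.
    """
    if spacing_m <= 0:
        raise ValueError("spacing_m must be positive")
    banks.validate()
    polygon = banks.channel_polygon()

    graph = _skeleton_graph(polygon, spacing_m / 2.0)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty skeleton: channel polygon degenerate")
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        # keep the dominant component; a fragmented skeleton means the
        # banks do not bound a single open channel
        components.sort(key=lambda c: -len(c))
        main = graph.subgraph(components[0]).copy()
        if len(components[0]) < 0.5 * graph.number_of_nodes():
            raise ValueError("disconnected skeleton: banks do not form one channel")
        graph = main

    start = _nearest_node(graph, banks.inlet)
    goal = _nearest_node(graph, banks.outlet)
    try:
        path = nx.shortest_path(graph, start, goal, weight="weight")
    except nx.NetworkXNoPath:
        raise ValueError("disconnected skeleton between inlet and outlet")

    coords = np.array(path, dtype=float)
    # extend the pruned axis to the actual inlet/outlet points
    inlet = np.array([banks.inlet.x, banks.inlet.y])
    outlet = np.array([banks.outlet.x, banks.outlet.y])
    if np.linalg.norm(coords[0] - inlet) > 1e-9:
        coords = np.vstack([inlet, coords])
    if np.linalg.norm(coords[-1] - outlet) > 1e-9:
        coords = np.vstack([coords, outlet])

    nodes = _resample(coords, spacing_m)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])

    tangents = np.gradient(nodes, s, axis=0)
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangents = tangents / norms

    straight = float(np.linalg.norm(nodes[-1] - nodes[0]))
    return Centerline(nodes=nodes, s=s, tangent=tangents, straight_dist=straight)


def sinuosity_from_lengths(meander_length_m: float, straight_dist_m: float) -> float:
    """Sinuosity ratio: meandered channel length over straight-line distance."""
    if straight_dist_m <= 0:
        raise ValueError("straight distance must be positive (coincident endpoints?)")
    return meander_length_m / straight_dist_m


def sinuosity(cl: Centerline) -> float:
    """Sinuosity of a centerline; 1.0 for a straight channel, >= 1 always."""
    return sinuosity_from_lengths(cl.length, cl.straight_dist)


def detect_bends(cl: Centerline, theta_deg: float = 30.0,
                 window_m: float = 5.0) -> list[Bend]:
    """Bends: stations where the heading change over a window exceeds θ.

    The turning angle at a node is the absolute change of centerline
    heading between the points half a window upstream and downstream.
    Contiguous super-threshold runs collapse to a single bend at their
    angle-maximal node.
    """
    spacing = float(np.median(np.diff(cl.s))) if len(cl.s) > 1 else 0.0
    if window_m < 2 * spacing:
        raise ValueError(
            f"window {window_m} m must be at least twice the node spacing {spacing} m"
        )
    half = window_m / 2.0
    headings = np.arctan2(cl.tangent[:, 1], cl.tangent[:, 0])
    unwrapped = np.unwrap(headings)
    h_lo = np.interp(cl.s - half, cl.s, unwrapped)
    h_hi = np.interp(cl.s + half, cl.s, unwrapped)
    theta = np.degrees(np.abs(h_hi - h_lo))

    # clip window overhang at the ends
    flagged = theta > theta_deg
    bends: list[Bend] = []
    i = 0
    n = len(cl.s)
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            k = i + int(np.argmax(theta[i:j + 1]))
            bends.append(Bend(s=float(cl.s[k]), theta_deg=float(theta[k])))
            i = j + 1
        else:
            i += 1
    return bends


def gradient(elev_up_m: float, elev_down_m: float, cl: Centerline) -> float:
    """Channel gradient: bed elevation drop per unit meandered length (m/m).

    Negative results (inverted elevations) are returned as-is so callers
    can flag them; classification uses the absolute value.
    """
    if cl.length <= 0:
        raise ValueError("centerline length must be positive")
    return (elev_up_m - elev_down_m) / cl.length


def gradient_segments(station_s: np.ndarray, station_elev: np.ndarray) -> float:
    """Mean of per-segment slopes; telescopes to the end-to-end slope."""
    s = np.asarray(station_s, dtype=float)
    z = np.asarray(station_elev, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least two stations")
    slopes = -np.diff(z) / np.diff(s)
    weights = np.diff(s) / (s[-1] - s[0])
    return float(np.sum(slopes * weights))
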