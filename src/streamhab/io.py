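"""Readers and writers: GeoJSON vector layers, station CSV, report JSON.

GeoJSON features are distinguished by a ``role`` property (boundary,
obstacle, stream_channel, left_bank, ...).  Files must carry a ``crs``
member naming a projected metric system; geographic (degree) systems
are rejected because every scoring threshold is metric.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .model import (
    AssessmentConfig,
    AssessmentReport,
    BankGeometry,
    CRSContext,
    FlightConfig,
    FlightRoute,
    LayerSet,
    MetricCategory,
    MetricResult,
    Obstacle,
    SitePlan,
    StationRecord,
    check_station_series,
)

__all__ = [
    "load_site_plan", "write_site_plan",
    "load_banks", "write_banks",
    "write_station_table", "read_station_table",
    "write_report", "read_report",
    "load_config", "write_route_geojson", "write_route_csv",
]

STATION_COLUMNS = ["s", "x", "y", "W", "D", "BT", "E_left", "E_right",
                   "B_left", "B_right", "F_left", "F_right",
                   "wet_fraction", "white_fraction", "v_proxy"]


def _crs_from_geojson(doc: dict, coords_sample) -> CRSContext:
    crs = doc.get("crs")
    if crs is not None:
        name = crs.get("properties", {}).get("name", "")
        name = name.replace("urn:ogc:def:crs:", "").replace("::", ":")
        if "CRS84" in name or "4326" in name:
            raise ValueError("projected metric CRS required, got geographic "
                             f"{name!r} (degrees)")
        return CRSContext(epsg_or_wkt=name or "unknown")
    # no declared CRS: reject coordinates that look like lon/lat degrees
    xs = [abs(c[0]) for c in coords_sample]
    ys = [abs(c[1]) for c in coords_sample]
    if xs and max(xs) <= 180.0 and max(ys) <= 90.0:
        raise ValueError("projected metric CRS required: file has no crs member "
                         "and coordinates look geographic (degrees)")
    return CRSContext(epsg_or_wkt="unknown")


def _sample_coords(features) -> list:
    pts = []
    for f in features[:5]:
        geom = f.get("geometry") or {}
        coords = geom.get("coordinates", [])
        while isinstance(coords, (list, tuple)) and coords and \
                isinstance(coords[0], (list, tuple)):
            coords = coords[0]
        if isinstance(coords, (list, tuple)) and len(coords) >= 2:
            pts.append(coords)
    return pts


def _read_feature_collection(path) -> tuple[list[dict], CRSContext]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vector file not found: {path}")
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    features = doc.get("features", [])
    crs = _crs_from_geojson(doc, _sample_coords(features))
    return features, crs


def _collection(features: list[dict], crs: Optional[CRSContext]) -> dict:
    doc = {"type": "FeatureCollection", "features": features}
    if crs is not None:
        doc["crs"] = {"type": "name", "properties": {"name": crs.epsg_or_wkt}}
    return doc


def _feature(geom, role: str, **props) -> dict:
    return {"type": "Feature", "properties": {"role": role, **props},
            "geometry": mapping(geom)}


def load_site_plan(path, config: Optional[AssessmentConfig] = None) -> SitePlan:
    """Read a site plan (boundary, obstacles, stream channel) from GeoJSON."""
    features, crs = _read_feature_collection(path)
    boundary = None
    channel = None
    obstacles: list[Obstacle] = []
    for f in features:
        role = (f.get("properties") or {}).get("role")
        geom = shape(f["geometry"])
        if not geom.is_valid:
            geom = geom.buffer(0)
            if not geom.is_valid or geom.is_empty:
                raise ValueError(f"feature with role {role!r} has unrepairable geometry")
        if role == "boundary":
            boundary = geom
        elif role == "obstacle":
            kind = (f.get("properties") or {}).get("kind", "tree")
            obstacles.append(Obstacle(geometry=geom, kind=kind))
        elif role == "stream_channel":
            channel = geom
    if boundary is None:
        raise ValueError(f"missing required layer 'boundary' in {path}")
    plan = SitePlan(boundary=boundary, obstacles=obstacles, stream_channel=channel,
                    crs=crs)
    return plan.validate()


def write_site_plan(site: SitePlan, path) -> None:
    features = [_feature(site.boundary, "boundary")]
    for obs in site.obstacles:
        features.append(_feature(obs.geometry, "obstacle", kind=obs.kind))
    if site.stream_channel is not None:
        features.append(_feature(site.stream_channel, "stream_channel"))
    crs = site.crs or CRSContext(epsg_or_wkt="EPSG:32616")
    Path(path).write_text(json.dumps(_collection(features, crs)))


def load_banks(path) -> BankGeometry:
    """Read bank geometry (banks, bank tops, islands, inlet/outlet)."""
    features, _ = _read_feature_collection(path)
    parts: dict[str, object] = {"islands": []}
    for f in features:
        role = (f.get("properties") or {}).get("role")
        geom = shape(f["geometry"])
        if role == "island":
            parts["islands"].append(geom)
        elif role is not None:
            parts[role] = geom
    required = ("left_bank", "right_bank", "inlet", "outlet")
    missing = [r for r in required if r not in parts]
    if missing:
        raise ValueError(f"missing required layer(s) {', '.join(missing)} in {path}")
    return BankGeometry(
        left_bank=parts["left_bank"], right_bank=parts["right_bank"],
        inlet=parts["inlet"], outlet=parts["outlet"],
        left_bank_top=parts.get("left_bank_top"),
        right_bank_top=parts.get("right_bank_top"),
        islands=parts["islands"],
    ).validate()


def write_banks(banks: BankGeometry, path,
                crs: Optional[CRSContext] = None) -> None:
    features = [
        _feature(banks.left_bank, "left_bank"),
        _feature(banks.right_bank, "right_bank"),
        _feature(banks.inlet, "inlet"),
        _feature(banks.outlet, "outlet"),
    ]
    if banks.left_bank_top is not None:
        features.append(_feature(banks.left_bank_top, "left_bank_top"))
    if banks.right_bank_top is not None:
        features.append(_feature(banks.right_bank_top, "right_bank_top"))
    for isl in banks.islands:
        features.append(_feature(isl, "island"))
    crs = crs or CRSContext(epsg_or_wkt="EPSG:32616")
    Path(path).write_text(json.dumps(_collection(features, crs)))


def write_station_table(records: Sequence[StationRecord], path) -> None:
    """Write per-station measurements as CSV (one row per station).

    A leading comment line documents units: metres for all widths and
    depth, fractions in [0, 1], v_proxy dimensionless.
    """
    if not records:
        raise ValueError("cannot write an empty station table")
    check_station_series(records)
    frame = pd.DataFrame([{c: getattr(r, c) for c in STATION_COLUMNS}
                          for r in records])
    with open(path, "w") as fh:
        fh.write("# units: s,x,y,W,D,BT,E_*,B_*,F_* in metres; "
                 "wet_fraction,white_fraction in [0,1]; v_proxy dimensionless\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_station_table(path) -> list[StationRecord]:
    frame = pd.read_csv(path, comment="#")
    records = [StationRecord(**{c: row[c] for c in STATION_COLUMNS})
               for _, row in frame.iterrows()]
    check_station_series(records)
    return records


def _metric_to_dict(m: MetricResult) -> dict:
    out: dict = {"code": m.code}
    if m.site_value is not None and np.isfinite(m.site_value):
        out["site_value"] = float(m.site_value)
    if m.per_side is not None:
        out["per_side"] = {k: float(v) for k, v in m.per_side.items()}
    if m.category is not None:
        out["category"] = m.category.label
        out["score"] = m.category.score
    if m.category_per_side is not None:
        out["category_per_side"] = {k: c.label for k, c in m.category_per_side.items()}
    if m.pct_by_category is not None:
        out["pct_by_category"] = {k: float(v) for k, v in m.pct_by_category.items()}
    out["score_contribution"] = m.score()
    return out


def _metric_from_dict(d: dict) -> MetricResult:
    cat = MetricCategory(d["category"]) if "category" in d else None
    cps = ({k: MetricCategory(v) for k, v in d["category_per_side"].items()}
           if "category_per_side" in d else None)
    return MetricResult(
        code=d["code"], site_value=d.get("site_value"), per_side=d.get("per_side"),
        category=cat, category_per_side=cps,
        pct_by_category=d.get("pct_by_category"),
    )


def write_report(report: AssessmentReport, path) -> None:
    """Write an assessment report as structured JSON."""
    report.validate()
    doc = {
        "gradient_class": report.gradient_class,
        "slope_m_per_m": float(report.slope),
        "metrics": {c: _metric_to_dict(report.metrics[c])
                    for c in AssessmentReport.REQUIRED},
        "total_score": float(report.total),
        "overall_class": report.overall,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_report(path) -> AssessmentReport:
    doc = json.loads(Path(path).read_text())
    metrics = {c: _metric_from_dict(d) for c, d in doc["metrics"].items()}
    return AssessmentReport(
        gradient_class=doc["gradient_class"], slope=doc["slope_m_per_m"],
        metrics=metrics, total=doc["total_score"], overall=doc["overall_class"],
    ).validate()


def load_config(path) -> tuple[AssessmentConfig, FlightConfig]:
    """Read assessment + flight configuration from YAML or JSON."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    acfg = AssessmentConfig(**doc.get("assessment", {}))
    fcfg = FlightConfig(**doc.get("flight", {}))
    return acfg, fcfg


def write_route_geojson(route: FlightRoute, path,
                        crs: Optional[CRSContext] = None) -> None:
    """Export a flight route as a GeoJSON LineString with altitude/classes."""
    coords = [(float(x), float(y), float(z)) for x, y, z in route.waypoints]
    feature = {
        "type": "Feature",
        "properties": {"segment_class": list(route.segment_class)},
        "geometry": {"type": "LineString", "coordinates": coords},
    }
    crs = crs or CRSContext(epsg_or_wkt="EPSG:32616")
    Path(path).write_text(json.dumps(_collection([feature], crs)))


def write_route_csv(route: FlightRoute, path, cfg: FlightConfig,
                    elevation: str) -> None:
    """Flight-controller export: planar x, y, alt_m, speed_mps per waypoint."""
    survey_speed, transit_speed = cfg.speeds(elevation)
    rows = []
    for k, (x, y, z) in enumerate(route.waypoints):
        cls = route.segment_class[min(k, len(route.segment_class) - 1)] \
            if route.segment_class else "transit"
        speed = survey_speed if cls == "survey" else transit_speed
        rows.append({"x": x, "y": y, "alt_m": z, "speed_mps": speed})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.3f")
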