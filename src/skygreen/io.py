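"""File I/O: single-channel PNG label masks, projected-metre GeoJSON layers,
and the CSV tables the pipeline exchanges."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import LineString, Point, Polygon, mapping, shape

from .geoexposure import RoadNetwork
from .skyproj import EquirectangularMask, GreenVisibilityRecord


def read_label_png(path: str | Path,
                   vegetation_ids: Iterable[int] = (8,)) -> EquirectangularMask:
    """Read an 8-bit single-channel PNG of class ids as a panorama mask."""
    img = Image.open(path)
    if img.mode not in ("L", "P", "I", "I;16"):
        img = img.convert("L")
    labels = np.asarray(img)
    return EquirectangularMask(labels=labels,
                               vegetation_ids=frozenset(vegetation_ids))


def write_label_png(path: str | Path, labels: np.ndarray) -> None:
    Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="L").save(path)


def visibility_records_to_csv(records: Iterable[GreenVisibilityRecord],
                              path: str | Path) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"site_id": r.site_id, "overall_pct": r.overall_pct}
        for i, p in enumerate(r.band_pct):
            row[f"band{i + 1}_pct"] = p
        row["n_disc_pixels"] = r.n_disc_pixels
        for i, c in enumerate(r.n_band_pixels):
            row[f"n_band{i + 1}_pixels"] = c
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_roads_geojson(path: str | Path,
                       class_property: str = "road_class",
                       excluded_classes: Iterable[str] = ("motorway",)) -> RoadNetwork:
    """Roads from a GeoJSON FeatureCollection of LineStrings in projected
    metres; the feature id (or an ``id`` property) keys each edge."""
    with open(path) as fh:
        gj = json.load(fh)
    edges = {}
    for k, feat in enumerate(gj["features"]):
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"feature {k} is not a LineString")
        props = feat.get("properties") or {}
        eid = str(feat.get("id", props.get("id", f"e{k:04d}")))
        edges[eid] = (geom, str(props.get(class_property, "street")))
    return RoadNetwork(edges=edges, excluded_classes=frozenset(excluded_classes))


def write_roads_geojson(roads: RoadNetwork, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "id": eid,
            "geometry": mapping(geom),
            "properties": {"road_class": cls},
        }
        for eid, (geom, cls) in roads.edges.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_points_geojson(path: str | Path) -> list[tuple[float, float]]:
    with open(path) as fh:
        gj = json.load(fh)
    pts = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, Point):
            raise ValueError("expected Point features")
        pts.append((geom.x, geom.y))
    return pts


def write_points_geojson(points: Iterable[tuple[float, float]],
                         path: str | Path) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(Point(p)), "properties": {}}
        for p in points
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_population_grid_geojson(
    path: str | Path, population_property: str = "population"
) -> list[tuple[Polygon, float]]:
    with open(path) as fh:
        gj = json.load(fh)
    cells = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        cells.append((geom, float(props[population_property])))
    return cells


def write_population_grid_geojson(
    cells: Iterable[tuple[Polygon, float]], path: str | Path
) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"population": pop},
        }
        for poly, pop in cells
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
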