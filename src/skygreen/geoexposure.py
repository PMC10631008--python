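"""Road-network sampling, network-distance buffers and neighbourhood exposure.

All geometry lives in a single projected metric coordinate system.  Roads are
polylines with a road-class attribute; motorway-class edges are excluded from
both sampling and buffering.  A participant's neighbourhood is the set of
road locations within 1000 m *along the network* of their residence, and the
exposure is the unweighted mean of site-level green visibility over the
sample sites inside that buffer, subject to a minimum-site inclusion rule.

Density and park counts need an areal neighbourhood, so the 1-D reachable
edge set is dilated into a corridor polygon of configurable half-width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring, unary_union

__all__ = [
    "RoadNetwork",
    "SamplePoint",
    "NetworkBuffer",
    "NeighbourhoodExposure",
    "PipelineConfig",
    "sample_points_along_network",
    "network_buffer",
    "neighbourhood_exposure",
    "population_density",
    "count_parks",
]


class SnapError(ValueError):
    """Origin too far from any road edge to snap."""


@dataclass(frozen=True)
class PipelineConfig:
    """The pipeline constants: sampling interval, image search radius,
    network buffer distance, minimum-site inclusion rule, band edges."""

    sample_interval_m: float = 50.0
    image_search_radius_m: float = 10.0
    buffer_network_m: float = 1000.0
    min_sites: int = 20
    corridor_halfwidth_m: float = 50.0
    snap_tolerance_m: float = 500.0
    band_edges_deg: tuple[float, ...] = (0.0, 22.5, 45.0, 67.5, 90.0)
    vegetation_ids: frozenset[int] = frozenset({8})
    map_resolution_px: int = 1024

    def __post_init__(self) -> None:
        for name in ("sample_interval_m", "image_search_radius_m",
                     "buffer_network_m", "min_sites", "corridor_halfwidth_m",
                     "snap_tolerance_m", "map_resolution_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RoadNetwork:
    """Road polylines with lengths in metres and a road-class attribute.

    ``edges`` maps edge id -> (LineString, road_class).  Edges whose class is
    in ``excluded_classes`` (motorways) take no part in sampling or buffers.
    """

    edges: dict[str, tuple[LineString, str]]
    excluded_classes: frozenset[str] = frozenset({"motorway"})
    node_tolerance_m: float = 0.01

    def __post_init__(self) -> None:
        for eid, (geom, _cls) in self.edges.items():
            if geom.length <= 0:
                raise ValueError(f"edge {eid} has non-positive length")

    def active_edges(self) -> dict[str, LineString]:
        return {
            eid: geom
            for eid, (geom, cls) in self.edges.items()
            if cls not in self.excluded_classes
        }

    def graph(self) -> nx.Graph:
        """Undirected graph over active edges; nodes are snapped endpoints."""
        g = nx.Graph()
        for eid, geom in self.active_edges().items():
            u = self._node_key(geom.coords[0])
            v = self._node_key(geom.coords[-1])
            # parallel edges are rare in the toy networks; keep the shorter
            if g.has_edge(u, v) and g[u][v]["length"] <= geom.length:
                continue
            g.add_edge(u, v, length=geom.length, edge_id=eid, geom=geom)
        return g

    def _node_key(self, coord: Sequence[float]) -> tuple[float, float]:
        tol = self.node_tolerance_m
        return (round(coord[0] / tol) * tol, round(coord[1] / tol) * tol)


@dataclass(frozen=True)
class SamplePoint:
    """A streetscape sample site on a road edge."""

    site_id: str
    x: float
    y: float
    edge_id: str
    offset_m: float


def sample_points_along_network(
    roads: RoadNetwork, interval_m: float = 50.0
) -> list[SamplePoint]:
    """Place sample sites at fixed intervals along every non-excluded edge.

    Each edge gets points at offsets 0, interval, 2·interval, …; an exact
    terminal point is not emitted (the next edge sharing the node emits it at
    its own offset 0), and points coinciding with an already-emitted node
    within the network's node tolerance are dropped once.
    """
    if interval_m <= 0:
        raise ValueError("interval_m must be positive")
    active = roads.active_edges()
    if not active:
        raise ValueError("road network has no non-excluded edges")

    points: list[SamplePoint] = []
    seen_nodes: set[tuple[float, float]] = set()
    counter = 0
    for eid in sorted(active):
        geom = active[eid]
        n = int(np.ceil(geom.length / interval_m))
        for k in range(n):
            off = k * interval_m
            p = geom.interpolate(off)
            if off == 0.0:
                key = roads._node_key((p.x, p.y))
                if key in seen_nodes:
                    continue
                seen_nodes.add(key)
            points.append(
                SamplePoint(
                    site_id=f"s{counter:06d}",
                    x=p.x, y=p.y, edge_id=eid, offset_m=off,
                )
            )
            counter += 1
    return points


@dataclass(frozen=True)
class NetworkBuffer:
    """Edge portions reachable within a network distance of a snapped origin.

    ``portions`` maps edge id -> list of (lo, hi) offset intervals along the
    edge geometry that lie within the buffer distance.
    """

    origin_edge_id: str
    origin_offset_m: float
    max_dist_m: float
    portions: dict[str, list[tuple[float, float]]]
    roads: RoadNetwork

    def contains(self, edge_id: str, offset_m: float) -> bool:
        eps = 1e-9
        return any(
            lo - eps <= offset_m <= hi + eps
            for lo, hi in self.portions.get(edge_id, ())
        )

    def contains_site(self, site: SamplePoint) -> bool:
        return self.contains(site.edge_id, site.offset_m)

    def total_length(self) -> float:
        return sum(hi - lo for ivs in self.portions.values() for lo, hi in ivs)

    def geometries(self) -> list[LineString]:
        geoms = []
        active = self.roads.active_edges()
        for eid, ivs in self.portions.items():
            g = active[eid]
            for lo, hi in ivs:
                if hi - lo > 1e-9:
                    geoms.append(substring(g, lo, hi))
        return geoms

    def corridor_polygon(self, halfwidth_m: float = 50.0) -> Polygon:
        """The reachable edge set dilated into an areal neighbourhood."""
        geoms = self.geometries()
        if not geoms:
            active = self.roads.active_edges()
            geoms = [active[self.origin_edge_id].interpolate(self.origin_offset_m)]
        return unary_union([g.buffer(halfwidth_m) for g in geoms])


def _snap_to_network(
    roads: RoadNetwork, origin: tuple[float, float], tolerance_m: float
) -> tuple[str, float, float]:
    pt = Point(origin)
    best: tuple[float, str, float] | None = None
    for eid, geom in sorted(roads.active_edges().items()):
        d = geom.distance(pt)
        if best is None or d < best[0] - 1e-12:
            best = (d, eid, geom.project(pt))
    if best is None or best[0] > tolerance_m:
        raise SnapError(
            f"origin {origin} is farther than {tolerance_m} m from any road edge"
        )
    return best[1], best[2], best[0]


def network_buffer(
    roads: RoadNetwork,
    origin: tuple[float, float],
    max_dist_m: float = 1000.0,
    snap_tolerance_m: float = 500.0,
) -> NetworkBuffer:
    """All edge portions within ``max_dist_m`` along the network of ``origin``.

    The origin is snapped to the nearest point on a non-excluded edge; the
    snap offset itself does not count against the distance budget.  Dijkstra
    runs from the two endpoints of the snapped edge (seeded with the along-
    edge distances from the origin), and every edge's reachable portion is
    reconstructed from its endpoint distances, including interior islands on
    the origin edge itself.
    """
    if max_dist_m < 0:
        raise ValueError("max_dist_m must be non-negative")
    eid0, off0, _snap_d = _snap_to_network(roads, origin, snap_tolerance_m)
    g = roads.graph()
    geom0 = roads.active_edges()[eid0]
    u0 = roads._node_key(geom0.coords[0])
    v0 = roads._node_key(geom0.coords[-1])

    # node distances seeded from the snapped origin
    sources = {u0: off0}
    sources[v0] = min(sources.get(v0, np.inf), geom0.length - off0)
    dist = _multi_source_dijkstra(g, sources)

    portions: dict[str, list[tuple[float, float]]] = {}
    for eid, geom in roads.active_edges().items():
        length = geom.length
        # orient offsets along geometry: distance from the coords[0] end
        du = dist.get(roads._node_key(geom.coords[0]), np.inf)
        dv = dist.get(roads._node_key(geom.coords[-1]), np.inf)
        ivs: list[tuple[float, float]] = []
        if du <= max_dist_m:
            ivs.append((0.0, min(length, max_dist_m - du)))
        if dv <= max_dist_m:
            ivs.append((max(0.0, length - (max_dist_m - dv)), length))
        if eid == eid0:
            # interior access straight from the origin, both directions
            lo = max(0.0, off0 - max_dist_m)
            hi = min(length, off0 + max_dist_m)
            ivs.append((lo, hi))
        merged = _merge_intervals(ivs)
        if merged:
            portions[eid] = merged
    return NetworkBuffer(
        origin_edge_id=eid0, origin_offset_m=off0, max_dist_m=max_dist_m,
        portions=portions, roads=roads,
    )


def _multi_source_dijkstra(
    g: nx.Graph, sources: dict[tuple[float, float], float]
) -> dict[tuple[float, float], float]:
    import heapq

    dist: dict[tuple[float, float], float] = {}
    heap = [(d, n) for n, d in sources.items() if n in g]
    heapq.heapify(heap)
    while heap:
        d, n = heapq.heappop(heap)
        if n in dist:
            continue
        dist[n] = d
        for nb, data in g[n].items():
            nd = d + data["length"]
            if nb not in dist:
                heapq.heappush(heap, (nd, nb))
    return dist


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    ivs = [(lo, hi) for lo, hi in ivs if hi > lo - 1e-12]
    if not ivs:
        return []
    ivs.sort()
    merged = [ivs[0]]
    for lo, hi in ivs[1:]:
        plo, phi = merged[-1]
        if lo <= phi + 1e-9:
            merged[-1] = (plo, max(phi, hi))
        else:
            merged.append((lo, hi))
    return merged


@dataclass(frozen=True)
class NeighbourhoodExposure:
    """Per-participant buffer-mean greenery indices plus context variables."""

    participant_id: str
    n_sites: int
    mean_overall_pct: float
    mean_band_pct: tuple[float, ...]
    population_density_per_km2: float = float("nan")
    n_parks: int = 0
    included: bool = False


def neighbourhood_exposure(
    participant_id: str,
    sites_with_visibility: pd.DataFrame,
    buffer: NetworkBuffer,
    cfg: PipelineConfig | None = None,
    population_density_per_km2: float = float("nan"),
    n_parks: int = 0,
) -> NeighbourhoodExposure:
    """Unweighted mean of each greenery index over in-buffer resolved sites.

    ``sites_with_visibility`` needs columns ``edge_id``, ``offset_m``,
    ``overall_pct`` and ``band{i}_pct``; rows with a missing overall index
    (unresolved imagery) are ignored.  The participant is flagged included
    iff at least ``cfg.min_sites`` resolved sites fall in the buffer.
    """
    cfg = cfg or PipelineConfig()
    n_bands = len(cfg.band_edges_deg) - 1
    band_cols = [f"band{i + 1}_pct" for i in range(n_bands)]

    resolved = sites_with_visibility.dropna(subset=["overall_pct"])
    in_buf = resolved[
        [
            buffer.contains(e, o)
            for e, o in zip(resolved["edge_id"], resolved["offset_m"])
        ]
    ]
    n = len(in_buf)
    if n == 0:
        means = [float("nan")] * (1 + n_bands)
    else:
        means = [float(in_buf["overall_pct"].mean())] + [
            float(in_buf[c].mean()) for c in band_cols
        ]
    return NeighbourhoodExposure(
        participant_id=participant_id,
        n_sites=n,
        mean_overall_pct=means[0],
        mean_band_pct=tuple(means[1:]),
        population_density_per_km2=population_density_per_km2,
        n_parks=n_parks,
        included=n >= cfg.min_sites,
    )


def population_density(
    grid_cells: Sequence[tuple[Polygon, float]], buffer_region: Polygon
) -> float:
    """Areal-weighted population density of the buffer region, persons/km².

    Each grid cell's population is distributed proportionally by the area of
    its intersection with the buffer; the total is divided by the buffer
    area.
    """
    area = buffer_region.area
    if area <= 0:
        raise ValueError("buffer region has zero area")
    pop = 0.0
    for poly, cell_pop in grid_cells:
        if poly.area <= 0:
            continue
        inter = poly.intersection(buffer_region).area
        if inter > 0:
            pop += cell_pop * inter / poly.area
    return pop / (area / 1e6)


def count_parks(parks: Iterable[Point | tuple[float, float]],
                buffer_region: Polygon) -> int:
    """Park points within the buffer polygon, boundary-inclusive."""
    n = 0
    for p in parks:
        pt = p if isinstance(p, Point) else Point(p)
        if buffer_region.covers(pt):
            n += 1
    return n
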