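"""Road sampling, network buffers and neighbourhood aggregation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, box

from skygreen.geoexposure import (
    PipelineConfig,
    RoadNetwork,
    SnapError,
    count_parks,
    neighbourhood_exposure,
    network_buffer,
    population_density,
    sample_points_along_network,
)
from skygreen.synthgen import generate_town


def straight_road(length=3000.0, cls="street"):
    return RoadNetwork(edges={"e0": (LineString([(0, 0), (length, 0)]), cls)})


def cross_network(arm=1500.0):
    c = (0.0, 0.0)
    return RoadNetwork(edges={
        "n": (LineString([c, (0, arm)]), "street"),
        "s": (LineString([c, (0, -arm)]), "street"),
        "e": (LineString([c, (arm, 0)]), "street"),
        "w": (LineString([c, (-arm, 0)]), "street"),
    })


class TestSamplePoints:
    def test_200m_edge_gets_four_points(self):
        pts = sample_points_along_network(straight_road(200.0), 50.0)
        assert [p.offset_m for p in pts] == [0.0, 50.0, 100.0, 150.0]

    def test_edge_shorter_than_interval(self):
        pts = sample_points_along_network(straight_road(49.0), 50.0)
        assert len(pts) == 1 and pts[0].offset_m == 0.0

    def test_motorway_edges_excluded(self):
        roads = RoadNetwork(edges={
            "a": (LineString([(0, 0), (200, 0)]), "street"),
            "b": (LineString([(0, 100), (200, 100)]), "motorway"),
        })
        pts = sample_points_along_network(roads, 50.0)
        assert all(p.edge_id == "a" for p in pts)

    def test_shared_node_emitted_once(self):
        roads = RoadNetwork(edges={
            "a": (LineString([(0, 0), (100, 0)]), "street"),
            "b": (LineString([(100, 0), (200, 0)]), "street"),
        })
        pts = sample_points_along_network(roads, 50.0)
        coords = {(round(p.x, 3), round(p.y, 3)) for p in pts}
        assert len(coords) == len(pts)  # no duplicate site locations

    def test_count_bookkeeping_bound_on_town(self):
        roads, _, _ = generate_town(grid_size=5, edge_length_m=250.0, seed=3)
        pts = sample_points_along_network(roads, 50.0)
        lower = sum(int(np.ceil(g.length / 50.0))
                    for g in roads.active_edges().values())
        n_nodes = 25
        assert lower <= len(pts) + n_nodes  # de-duplication removes <= n_nodes
        assert len(pts) <= lower

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            sample_points_along_network(straight_road(), 0.0)


class TestNetworkBuffer:
    def test_isolated_straight_road_centred_segment(self):
        buf = network_buffer(straight_road(3000.0), (1500.0, 0.0), 1000.0)
        assert buf.total_length() == pytest.approx(2000.0, abs=1e-6)
        assert buf.portions["e0"] == [(500.0, 2500.0)]

    def test_zero_distance_single_point(self):
        buf = network_buffer(straight_road(3000.0), (1500.0, 0.0), 0.0)
        assert buf.total_length() == pytest.approx(0.0, abs=1e-9)
        assert buf.contains("e0", 1500.0)
        assert not buf.contains("e0", 1501.0)

    def test_cross_centre_reaches_1000_per_arm(self):
        buf = network_buffer(cross_network(), (0.0, 0.0), 1000.0)
        assert buf.total_length() == pytest.approx(4000.0, abs=1e-6)
        for eid in "nsew":
            (lo, hi), = buf.portions[eid]
            assert (lo, hi) == pytest.approx((0.0, 1000.0), abs=1e-6)

    def test_matches_bruteforce_on_densified_cross(self):
        """Buffer frontier agrees with shortest paths on a 1-m node graph."""
        import networkx as nx

        buf = network_buffer(cross_network(), (200.0, 0.0), 1000.0)

        g = nx.Graph()
        for eid, (geom, _c) in cross_network().edges.items():
            n = int(geom.length)
            pts = [geom.interpolate(i) for i in range(n + 1)]
            for i in range(n):
                a = (round(pts[i].x, 6), round(pts[i].y, 6))
                b = (round(pts[i + 1].x, 6), round(pts[i + 1].y, 6))
                g.add_edge(a, b, weight=1.0)
        dist = nx.single_source_dijkstra_path_length(g, (200.0, 0.0))
        for eid, (geom, _c) in cross_network().edges.items():
            for off in range(0, int(geom.length) + 1, 25):
                p = geom.interpolate(off)
                d = dist[(round(p.x, 6), round(p.y, 6))]
                if d <= 999.0:
                    assert buf.contains(eid, float(off)), (eid, off, d)
                if d >= 1001.0:
                    assert not buf.contains(eid, float(off)), (eid, off, d)

    def test_monotone_in_distance(self):
        roads, _, _ = generate_town(grid_size=4, edge_length_m=300.0, seed=1)
        small = network_buffer(roads, (450.0, 450.0), 400.0)
        large = network_buffer(roads, (450.0, 450.0), 900.0)
        for eid, ivs in small.portions.items():
            for lo, hi in ivs:
                for off in np.linspace(lo, hi, 5):
                    assert large.contains(eid, float(off))

    def test_snap_error_beyond_tolerance(self):
        with pytest.raises(SnapError):
            network_buffer(straight_road(100.0), (0.0, 10000.0), 1000.0)

    def test_origin_snaps_through_excluded_edges(self):
        roads = RoadNetwork(edges={
            "m": (LineString([(0, 0), (1000, 0)]), "motorway"),
            "s": (LineString([(0, 100), (1000, 100)]), "street"),
        })
        buf = network_buffer(roads, (500.0, 10.0), 200.0)
        assert buf.origin_edge_id == "s"
        assert "m" not in buf.portions


def site_table(values, edge="e0", spacing=50.0, start=600.0):
    # offsets start at 600 m so they sit inside the [500, 2500] m portion
    # that a 1000-m buffer from mid-road covers
    rows = []
    for i, v in enumerate(values):
        rows.append({"site_id": f"s{i}", "edge_id": edge,
                     "offset_m": start + i * spacing, "overall_pct": v,
                     **{f"band{b}_pct": v for b in range(1, 5)}})
    return pd.DataFrame(rows)


class TestNeighbourhoodExposure:
    def test_constant_field_mean(self):
        buf = network_buffer(straight_road(3000.0), (1500.0, 0.0), 1000.0)
        df = site_table([7.0] * 60)
        e = neighbourhood_exposure("p", df, buf)
        assert e.mean_overall_pct == pytest.approx(7.0)
        assert e.included and e.n_sites >= 20

    def test_below_min_sites_excluded(self):
        buf = network_buffer(straight_road(3000.0), (1500.0, 0.0), 1000.0)
        df = site_table([5.0] * 19, spacing=100.0)
        e = neighbourhood_exposure("p", df, buf)
        assert e.n_sites == 19 and not e.included

    def test_mean_with_custom_min_sites(self):
        cfg = PipelineConfig(min_sites=2)
        buf = network_buffer(straight_road(3000.0), (1500.0, 0.0), 1000.0)
        df = site_table([10.0, 20.0, 30.0], spacing=600.0)
        e = neighbourhood_exposure("p", df, buf, cfg)
        assert e.mean_overall_pct == pytest.approx(20.0)
        assert e.included

    def test_unresolved_sites_ignored(self):
        buf = network_buffer(straight_road(3000.0), (1500.0, 0.0), 1000.0)
        df = site_table([10.0, 20.0, 30.0], spacing=600.0)
        df.loc[1, ["overall_pct"] + [f"band{b}_pct" for b in range(1, 5)]] = np.nan
        e = neighbourhood_exposure("p", df, buf, PipelineConfig(min_sites=2))
        assert e.n_sites == 2
        assert e.mean_overall_pct == pytest.approx(20.0)

    def test_mean_invariant_to_order(self):
        buf = network_buffer(straight_road(3000.0), (1500.0, 0.0), 1000.0)
        df = site_table(list(range(30)))
        shuffled = df.sample(frac=1.0, random_state=0)
        a = neighbourhood_exposure("p", df, buf)
        b = neighbourhood_exposure("p", shuffled, buf)
        assert a.mean_overall_pct == pytest.approx(b.mean_overall_pct)


class TestPopulationDensity:
    def test_buffer_inside_one_cell(self):
        cell = box(0, 0, 250, 250)
        d = population_density([(cell, 1000.0)], box(50, 50, 150, 150))
        # cell density = 1000 / 0.0625 km2 = 16000 per km2
        assert d == pytest.approx(16000.0, rel=1e-9)

    def test_two_equal_cells_symmetric_overlap(self):
        c1, c2 = box(0, 0, 250, 250), box(250, 0, 500, 250)
        buf = box(150, 50, 350, 150)  # 100 m into each cell
        d = population_density([(c1, 500.0), (c2, 1500.0)], buf)
        d1, d2 = 500.0 / 0.0625, 1500.0 / 0.0625
        assert d == pytest.approx((d1 + d2) / 2, rel=1e-9)

    def test_half_cell_worked_example(self):
        cell = box(0, 0, 250, 250)
        buf = box(0, 0, 125, 250)  # exactly half the cell
        assert population_density([(cell, 100.0)], buf) == pytest.approx(1600.0)

    def test_uniform_grid_recovers_density_for_odd_shapes(self):
        cells = [(box(i * 250, j * 250, (i + 1) * 250, (j + 1) * 250), 375.0)
                 for i in range(4) for j in range(4)]  # 6000 per km2 each
        blob = Point(430, 510).buffer(180).union(box(100, 100, 600, 220))
        assert population_density(cells, blob) == pytest.approx(6000.0, rel=1e-9)

    def test_zero_area_buffer_rejected(self):
        with pytest.raises(ValueError):
            population_density([(box(0, 0, 1, 1), 1.0)], Point(0, 0).buffer(0))


class TestCountParks:
    def test_counts_inside_only(self):
        buf = box(0, 0, 100, 100)
        parks = [(10, 10), (50, 50), (99, 99), (150, 50), (-5, 5)]
        assert count_parks(parks, buf) == 3

    def test_boundary_point_counted(self):
        assert count_parks([(100.0, 50.0)], box(0, 0, 100, 100)) == 1

    def test_no_parks(self):
        assert count_parks([], box(0, 0, 1, 1)) == 0
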