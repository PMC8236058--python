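"""Contextual features: Delaunay graph, lateral neighbors, chains, K-sets."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xenoclass.catalog import (
    INTRINSIC_NAMES,
    N_FEATURES,
    N_INTRINSIC,
    N_NEIGHBOR_DERIVED,
    N_ORGANIZATION,
    catalog_names,
    feature_catalog,
)
from xenoclass.contextual import (
    assemble_feature_matrix,
    build_chains,
    build_delaunay,
    direct_neighbor_features,
    extract_contextual_features,
    find_lateral_neighbors,
    k_connected_features,
    k_nearest_features,
)
from xenoclass.delineate import CellRecord
from xenoclass.intrinsic import EllipseFit


def make_records(coords, major=8.0, minor=4.0, thetas=None):
    recs = []
    for i, (x, y) in enumerate(coords):
        theta = 0.0 if thetas is None else thetas[i]
        ell = EllipseFit(major, minor, theta % np.pi)
        recs.append(
            CellRecord(i + 1, i + 1, (float(x), float(y)), ell, ell, 10.0, 15.0)
        )
    return recs


def circumcircle_edges(points):
    """Brute-force Delaunay oracle: an edge joins two points belonging to a
    triple whose circumcircle is empty of all other points."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = (
            (ax**2 + ay**2) * (by - cy)
            + (bx**2 + by**2) * (cy - ay)
            + (cx**2 + cy**2) * (ay - by)
        ) / d
        uy = (
            (ax**2 + ay**2) * (cx - bx)
            + (bx**2 + by**2) * (ax - cx)
            + (cx**2 + cy**2) * (bx - ax)
        ) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        empty = all(
            (pts[m, 0] - ux) ** 2 + (pts[m, 1] - uy) ** 2 > r2 + 1e-9
            for m in range(n)
            if m not in (i, j, k)
        )
        if empty:
            for a, b in ((i, j), (j, k), (i, k)):
                edges.add((min(a, b), max(a, b)))
    return edges


class TestDelaunay:
    def test_triangle_is_complete_graph(self):
        g = build_delaunay(make_records([(0, 0), (10, 0), (5, 8)]))
        assert set(g.edges) == {(0, 1), (0, 2), (1, 2)}

    def test_matches_circumcircle_oracle(self, rng):
        coords = rng.uniform(0, 100, (12, 2))
        g = build_delaunay(make_records(coords))
        assert set(g.edges) == circumcircle_edges(coords)

    def test_adjacency_symmetric(self, rng):
        coords = rng.uniform(0, 50, (20, 2))
        g = build_delaunay(make_records(coords))
        for i, j in g.edges:
            assert j in g.neighbors[i] and i in g.neighbors[j]

    def test_too_few_points_empty_graph(self):
        g = build_delaunay(make_records([(0, 0), (5, 5)]))
        assert g.edges == []

    def test_duplicate_centroids_jittered(self):
        coords = [(0, 0), (0, 0), (10, 0), (5, 8)]
        with pytest.warns(UserWarning, match="duplicate"):
            g = build_delaunay(make_records(coords))
        assert g.n == 4


class TestDirectNeighbors:
    def test_grid_equidistant(self):
        # interior point of a unit-spaced cross
        coords = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]
        g = build_delaunay(make_records(coords))
        cnt, mean_d, var_d = direct_neighbor_features(g, 0)
        assert cnt == 4.0
        assert mean_d == pytest.approx(1.0)
        assert var_d == pytest.approx(0.0)

    def test_matches_edge_list_recomputation(self, rng):
        coords = rng.uniform(0, 80, (15, 2))
        g = build_delaunay(make_records(coords))
        for i in range(g.n):
            cnt, mean_d, var_d = direct_neighbor_features(g, i)
            ds = [g.edge_length(i, j) for j in g.neighbors[i]]
            assert cnt == len(ds)
            assert mean_d == pytest.approx(np.mean(ds))
            assert var_d == pytest.approx(np.var(ds))

    def test_hull_cell_higher_variance_than_interior(self, rng):
        # jittered lattice: border cells see a wider spread of neighbor
        # distances than interior ones
        base = np.array(
            [(x * 10.0, y * 10.0) for x in range(6) for y in range(6)]
        )
        coords = base + rng.normal(0, 0.8, base.shape)
        g = build_delaunay(make_records(coords))
        from scipy.spatial import ConvexHull

        hull = set(ConvexHull(coords).vertices)
        var_hull = np.mean(
            [direct_neighbor_features(g, i)[2] for i in hull]
        )
        interior = [i for i in range(g.n) if i not in hull]
        var_int = np.mean(
            [direct_neighbor_features(g, i)[2] for i in interior]
        )
        assert var_hull > var_int


class TestLateralNeighbors:
    def test_straight_row_interior_cells_linked(self):
        # major axes perpendicular to the row (theta = pi/2, row along x);
        # a whisker of y-jitter keeps the triangulation non-degenerate
        coords = [(i * 6.0, 0.001 * (-1) ** i) for i in range(5)]
        recs = make_records(coords, major=8.0, minor=4.0, thetas=[np.pi / 2] * 5)
        g = build_delaunay(recs)
        links = find_lateral_neighbors(recs, g)
        for i in (1, 2, 3):
            assert links.left[i] >= 0 and links.right[i] >= 0
            sides = {int(links.left[i]), int(links.right[i])}
            assert sides == {i - 1, i + 1}
            # displacement is essentially along N: alignment 1, same orientation
            assert links.left_stats[i, 1] == pytest.approx(1.0, abs=1e-5)
            assert links.left_stats[i, 2] == pytest.approx(0.0)

    def test_displacement_along_major_axis_rejected(self):
        # two cells separated along the major axis direction (theta=0 ->
        # major along x); |d.u| = 20 >= major/2 = 4
        coords = [(0.0, 0.0), (20.0, 0.0), (10.0, 30.0)]
        recs = make_records(coords, major=8.0, thetas=[0.0, 0.0, 0.0])
        g = build_delaunay(recs)
        links = find_lateral_neighbors(recs, g)
        assert links.left[0] != 1 and links.right[0] != 1

    def test_matches_direct_inequality_oracle(self, rng):
        coords = rng.uniform(0, 100, (20, 2))
        thetas = rng.uniform(0, np.pi, 20)
        recs = make_records(coords, major=14.0, thetas=thetas)
        g = build_delaunay(recs)
        links = find_lateral_neighbors(recs, g)
        for i in range(g.n):
            u = np.array([np.cos(thetas[i]), np.sin(thetas[i])])
            nvec = np.array([-np.sin(thetas[i]), np.cos(thetas[i])])
            qualifying = {+1: [], -1: []}
            for j in g.neighbors[i]:
                d = np.asarray(coords[j]) - np.asarray(coords[i])
                if abs(d @ u) < 14.0 / 2:
                    side = 1 if d @ nvec >= 0 else -1
                    qualifying[side].append((np.linalg.norm(d), j))
            for side, arr in ((1, links.right), (-1, links.left)):
                expect = min(qualifying[side])[1] if qualifying[side] else -1
                assert arr[i] == expect


class TestChains:
    def _linked(self, coords, thetas):
        recs = make_records(coords, major=10.0, thetas=thetas)
        g = build_delaunay(recs)
        links = find_lateral_neighbors(recs, g)
        return build_chains(links, recs), recs

    def test_collinear_chain_straight(self):
        coords = [(i * 5.0, 1e-4 * (-1) ** i) for i in range(6)]
        chains, _ = self._linked(coords, [np.pi / 2] * 6)
        assert len(chains) == 1
        assert chains[0].size == 6
        assert chains[0].tortuosity == pytest.approx(1.0, abs=1e-6)

    def test_semicircle_tortuosity_matches_polyline(self):
        r = 30.0
        angles = np.linspace(0, np.pi, 9)
        coords = [(r * np.cos(a), r * np.sin(a)) for a in angles]
        thetas = [float(a) for a in angles]  # radial major axes
        chains, recs = self._linked(coords, thetas)
        assert len(chains) == 1 and chains[0].size == 9
        pts = np.array([recs[i].centroid for i in chains[0].member_idx])
        path = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        endpoint = np.linalg.norm(pts[-1] - pts[0])
        assert chains[0].tortuosity == pytest.approx(path / endpoint)
        assert chains[0].tortuosity == pytest.approx(path / (2 * r), rel=0.01)

    def test_no_mutual_pairs_no_chains(self):
        # far-apart cells with major axes too short for any lateral link
        coords = [(0, 0), (50, 0), (25, 60)]
        recs = make_records(coords, major=2.0, minor=1.0)
        g = build_delaunay(recs)
        links = find_lateral_neighbors(recs, g)
        assert build_chains(links, recs) == []

    def test_chains_partition_members(self, rng):
        coords = rng.uniform(0, 120, (30, 2))
        thetas = rng.uniform(0, np.pi, 30)
        chains, _ = self._linked(list(coords), list(thetas))
        seen = [i for ch in chains for i in ch.member_idx]
        assert len(seen) == len(set(seen))
        for ch in chains:
            assert ch.size >= 2
            assert ch.tortuosity >= 1.0 - 1e-9


class TestKNearest:
    def test_ring_center_close_to_centroid(self):
        k = 5
        ring = [
            (10 * np.cos(a), 10 * np.sin(a))
            for a in np.linspace(0, 2 * np.pi, k, endpoint=False)
        ]
        coords = np.array([(0.0, 0.0)] + ring)
        members, stats = k_nearest_features(coords, 0, k)
        assert stats["dist_to_centroid"] == pytest.approx(0.0, abs=1e-9)
        assert stats["mean_dist"] == pytest.approx(10.0)

    def test_matches_exhaustive_sort(self, rng):
        coords = rng.uniform(0, 100, (25, 2))
        for idx in (0, 7, 24):
            members, stats = k_nearest_features(coords, idx, 10)
            d = np.linalg.norm(coords - coords[idx], axis=1)
            expect = sorted(
                (dist, j) for j, dist in enumerate(d) if j != idx
            )[:10]
            assert list(members) == [j for _, j in expect]

    def test_insufficient_cells_returns_none(self, rng):
        coords = rng.uniform(0, 10, (4, 2))
        assert k_nearest_features(coords, 0, 5) is None


def exhaustive_shortest_paths(n, edges, weights, source):
    """All-simple-paths Dijkstra oracle for tiny graphs."""
    import math

    adj = {i: [] for i in range(n)}
    for (i, j), w in zip(edges, weights):
        adj[i].append((j, w))
        adj[j].append((i, w))
    best = [math.inf] * n
    best[source] = 0.0

    def walk(node, dist, visited):
        for nxt, w in adj[node]:
            if nxt in visited:
                continue
            nd = dist + w
            if nd < best[nxt]:
                best[nxt] = nd
            walk(nxt, nd, visited | {nxt})

    walk(source, 0.0, {source})
    return best


class TestKConnected:
    def test_path_graph_distances_are_gap_sums(self):
        from xenoclass.contextual import NeighborhoodGraph

        xs = (0, 4, 9, 15, 22, 30)
        g = NeighborhoodGraph(
            ids=np.arange(1, 7),
            coords=np.array([(float(x), 0.0) for x in xs]),
            edges=[(i, i + 1) for i in range(5)],
        )
        from scipy.sparse.csgraph import dijkstra

        sp = dijkstra(g.csgraph(), directed=False)
        members, stats = k_connected_features(g, sp, 0, 3)
        assert list(members) == [1, 2, 3]
        np.testing.assert_allclose(sp[0, [1, 2, 3]], [4, 9, 15])
        assert stats["mean_dist"] == pytest.approx(np.mean([4, 9, 15]))

    def test_dijkstra_matches_exhaustive_paths(self, rng):
        coords = rng.uniform(0, 40, (7, 2))
        recs = make_records(coords)
        g = build_delaunay(recs)
        from scipy.sparse.csgraph import dijkstra

        sp = dijkstra(g.csgraph(), directed=False)
        weights = [g.edge_length(i, j) for i, j in g.edges]
        for src in range(7):
            oracle = exhaustive_shortest_paths(7, g.edges, weights, src)
            np.testing.assert_allclose(sp[src], oracle, atol=1e-9)

    def test_triangle_inequality_on_graph_metric(self, rng):
        coords = rng.uniform(0, 60, (15, 2))
        g = build_delaunay(make_records(coords))
        from scipy.sparse.csgraph import dijkstra

        sp = dijkstra(g.csgraph(), directed=False)
        for i in range(15):
            for j in range(15):
                for k in range(15):
                    assert sp[i, j] <= sp[i, k] + sp[k, j] + 1e-9

    def test_member_aggregates_match_direct_recomputation(self, rng):
        coords = rng.uniform(0, 80, (12, 2))
        recs = make_records(coords)
        imat = pd.DataFrame(
            rng.normal(size=(12, N_INTRINSIC)), columns=list(INTRINSIC_NAMES)
        )
        nd, org = extract_contextual_features(recs, imat, k_values=(5,))
        g = build_delaunay(recs)
        from scipy.sparse.csgraph import dijkstra

        sp = dijkstra(g.csgraph(), directed=False)
        for i in range(12):
            res = k_connected_features(g, sp, i, 5)
            assert res is not None
            members = res[0]
            block = imat.to_numpy()[members]
            np.testing.assert_allclose(
                nd.loc[i, [f"kconn5_mean_{n}" for n in INTRINSIC_NAMES]],
                block.mean(axis=0),
            )
            np.testing.assert_allclose(
                nd.loc[i, [f"kconn5_var_{n}" for n in INTRINSIC_NAMES]],
                block.var(axis=0),
            )


class TestAssembly:
    def test_block_sizes(self):
        cats = [d.category for d in feature_catalog()]
        assert cats.count("intrinsic") == N_INTRINSIC == 47
        assert cats.count("neighbor_derived") == N_NEIGHBOR_DERIVED == 376
        assert cats.count("organization") == N_ORGANIZATION == 61
        assert len(cats) == N_FEATURES == 484

    def test_vector_length_and_finiteness(self, rng):
        coords = rng.uniform(0, 150, (50, 2))
        recs = make_records(coords)
        imat = pd.DataFrame(
            rng.normal(size=(50, N_INTRINSIC)), columns=list(INTRINSIC_NAMES)
        )
        nd, org = extract_contextual_features(recs, imat)
        full = assemble_feature_matrix(imat, nd, org)
        assert full.shape == (50, N_FEATURES)
        assert list(full.columns) == catalog_names()
        assert np.isfinite(full.to_numpy()).all()

    def test_isolated_cells_get_default_fills(self, rng):
        # two cells: below the 3-cell minimum, every contextual feature is
        # its documented fill (0, tortuosity 1)
        recs = make_records([(0, 0), (30, 30)])
        imat = pd.DataFrame(
            rng.normal(size=(2, N_INTRINSIC)), columns=list(INTRINSIC_NAMES)
        )
        nd, org = extract_contextual_features(recs, imat)
        assert (nd.to_numpy() == 0).all()
        assert (org["chain_tortuosity"] == 1.0).all()
        other = org.drop(columns="chain_tortuosity")
        assert (other.to_numpy() == 0).all()

    def test_non_finite_value_names_feature(self, rng):
        recs = make_records([(0, 0), (10, 0), (0, 10)])
        imat = pd.DataFrame(
            rng.normal(size=(3, N_INTRINSIC)), columns=list(INTRINSIC_NAMES)
        )
        imat.iloc[1, 0] = np.nan
        nd, org = extract_contextual_features(recs, imat)
        with pytest.raises(ValueError, match="nucleus_major_um"):
            assemble_feature_matrix(imat, nd, org)

    def test_deterministic_repeat(self, rng):
        coords = rng.uniform(0, 100, (20, 2))
        recs = make_records(coords)
        imat = pd.DataFrame(
            rng.normal(size=(20, N_INTRINSIC)), columns=list(INTRINSIC_NAMES)
        )
        a = assemble_feature_matrix(*(
            (imat,) + extract_contextual_features(recs, imat)
        ))
        b = assemble_feature_matrix(*(
            (imat,) + extract_contextual_features(recs, imat)
        ))
        assert a.equals(b)

    def test_distance_features_scale_linearly(self, rng):
        coords = rng.uniform(0, 100, (15, 2))
        imat = pd.DataFrame(
            rng.normal(size=(15, N_INTRINSIC)), columns=list(INTRINSIC_NAMES)
        )
        _, org1 = extract_contextual_features(make_records(coords), imat)
        _, org2 = extract_contextual_features(
            make_records(coords * 2.0), imat
        )
        np.testing.assert_allclose(
            org2["direct_mean_dist"], org1["direct_mean_dist"] * 2.0, rtol=1e-9
        )
        np.testing.assert_allclose(
            org2["knear5_dist_to_centroid"],
            org1["knear5_dist_to_centroid"] * 2.0,
            rtol=1e-9,
        )
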