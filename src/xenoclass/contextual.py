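"""Contextual features: how a cell sits among its neighbors.

The neighborhood structure is a Delaunay triangulation of cell centroids
(edges weighted by Euclidean distance in µm). From it we derive:

* direct neighbors — cells sharing a Delaunay edge; the spread of their
  distances flags border vs interior positions in a cluster;
* lateral neighbors — the cells to the left and right of a cell along the
  line N normal to its nucleus' major axis: a candidate qualifies when its
  centroid lies within major/2 of N (perpendicular distance), mutual lateral
  pairs link into chains described by size and tortuosity — arrangements
  characteristic of human epithelial cells threading along ducts;
* K-nearest sets (Euclidean) and K-connected sets (K smallest shortest-path
  distances on the graph, Dijkstra) for K in 5, 10, 20, 40, capturing local to
  global organization; the K-connected sets also carry the mean/variance of
  every intrinsic feature over their members (physically connected cells tend
  to share intrinsic properties) and the moment ellipse of member centroids.

Cells lacking the required neighborhood receive each feature's catalog fill
value (0, or 1 for tortuosity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay, QhullError

from .catalog import (
    INTRINSIC_NAMES,
    K_VALUES,
    N_FEATURES,
    catalog_names,
    feature_catalog,
)

__all__ = [
    "NeighborhoodGraph",
    "LateralLinks",
    "CellChain",
    "build_delaunay",
    "direct_neighbor_features",
    "find_lateral_neighbors",
    "build_chains",
    "k_nearest_features",
    "k_connected_features",
    "assemble_feature_matrix",
    "extract_contextual_features",
]

#: Below this many cells no contextual structure is computed at all.
MIN_CELLS_FOR_CONTEXT = 3


@dataclass
class NeighborhoodGraph:
    """Delaunay adjacency over cell centroids (coordinates in µm)."""

    ids: np.ndarray  # cell labels, index-aligned with coords
    coords: np.ndarray  # (n, 2) centroid (x, y) µm
    edges: list[tuple[int, int]]  # index pairs, i < j
    neighbors: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.neighbors:
            self.neighbors = [[] for _ in self.ids]
            for i, j in self.edges:
                self.neighbors[i].append(j)
                self.neighbors[j].append(i)
            self.neighbors = [sorted(n) for n in self.neighbors]

    @property
    def n(self) -> int:
        return len(self.ids)

    def edge_length(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def csgraph(self) -> csr_matrix:
        if not self.edges:
            return csr_matrix((self.n, self.n))
        ii, jj = np.array(self.edges).T
        w = np.linalg.norm(self.coords[ii] - self.coords[jj], axis=1)
        rows = np.concatenate([ii, jj])
        cols = np.concatenate([jj, ii])
        data = np.concatenate([w, w])
        return csr_matrix((data, (rows, cols)), shape=(self.n, self.n))


def build_delaunay(records) -> NeighborhoodGraph:
    """Delaunay triangulation of cell centroids.

    Fewer than 3 cells, or degenerate (collinear) layouts, give an edgeless
    graph; exact duplicate centroids are jittered by 1e-6 µm (fixed seed) with
    a warning.
    """
    ids = np.array([r.cell_label for r in records], dtype=np.int64)
    coords = np.array([r.centroid for r in records], dtype=float).reshape(-1, 2)
    if len(ids) < MIN_CELLS_FOR_CONTEXT:
        return NeighborhoodGraph(ids, coords, [])
    pts = coords
    _, first = np.unique(pts, axis=0, return_index=True)
    if len(first) < len(pts):
        warnings.warn("duplicate centroids; jittering by 1e-6 µm")
        rng = np.random.default_rng(0)
        pts = pts + rng.normal(0.0, 1e-6, pts.shape)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return NeighborhoodGraph(ids, coords, [])
    edge_set: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edge_set.add((min(i, j), max(i, j)))
    return NeighborhoodGraph(ids, coords, sorted(edge_set))


def direct_neighbor_features(
    graph: NeighborhoodGraph, idx: int
) -> tuple[float, float, float]:
    """(count, mean distance, population variance of distance) over the
    Delaunay-adjacent cells; zeros for an isolated node."""
    nbrs = graph.neighbors[idx]
    if not nbrs:
        return 0.0, 0.0, 0.0
    d = np.linalg.norm(graph.coords[nbrs] - graph.coords[idx], axis=1)
    return float(len(nbrs)), float(d.mean()), float(d.var())


@dataclass
class LateralLinks:
    """Left/right lateral neighbor (index, or -1) and per-side statistics
    (distance µm, alignment in [0,1], orientation difference in [0, pi/2])."""

    left: np.ndarray
    right: np.ndarray
    left_stats: np.ndarray  # (n, 3)
    right_stats: np.ndarray


def _acute_angle(a: float, b: float) -> float:
    d = abs(a - b) % np.pi
    return float(min(d, np.pi - d))


def find_lateral_neighbors(records, graph: NeighborhoodGraph) -> LateralLinks:
    """Select left/right lateral neighbors among Delaunay neighbors.

    For cell c1 with nucleus major-axis direction u, the line N through c1's
    centroid normal to u has direction nvec. A Delaunay neighbor c2 with
    displacement d qualifies when |d·u| < major(c1)/2; its side is the sign of
    d·nvec, and per side the closest qualifying candidate is kept. Alignment is
    |cos| of the angle between d and N.
    """
    n = graph.n
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    lstats = np.zeros((n, 3))
    rstats = np.zeros((n, 3))
    thetas = np.array([r.nucleus_ellipse.orientation_rad for r in records])
    majors = np.array([r.nucleus_ellipse.major_um for r in records])
    for i in range(n):
        u = np.array([np.cos(thetas[i]), np.sin(thetas[i])])
        nvec = np.array([-np.sin(thetas[i]), np.cos(thetas[i])])
        best = {+1: (np.inf, -1), -1: (np.inf, -1)}
        for j in graph.neighbors[i]:
            d = graph.coords[j] - graph.coords[i]
            if abs(d @ u) >= majors[i] / 2.0:
                continue
            side = 1 if d @ nvec >= 0 else -1
            dist = float(np.linalg.norm(d))
            if dist < best[side][0]:
                best[side] = (dist, j)
        for side, (dist, j), arr, stats in (
            (+1, best[+1], right, rstats),
            (-1, best[-1], left, lstats),
        ):
            if j < 0:
                continue
            arr[i] = j
            d = graph.coords[j] - graph.coords[i]
            align = abs(d @ nvec) / max(np.linalg.norm(d), 1e-12)
            stats[i] = (dist, align, _acute_angle(thetas[i], thetas[j]))
    return LateralLinks(left, right, lstats, rstats)


@dataclass
class CellChain:
    """An ordered run of mutually-lateral cells."""

    member_idx: list[int]
    size: int
    tortuosity: float
    mean_link_dist: float
    mean_orientation_diff: float


def _mutual_edges(links: LateralLinks) -> set[tuple[int, int]]:
    edges = set()
    n = len(links.left)
    for i in range(n):
        for j in (links.left[i], links.right[i]):
            if j < 0:
                continue
            if links.left[j] == i or links.right[j] == i:
                edges.add((min(i, int(j)), max(i, int(j))))
    return edges


def build_chains(links: LateralLinks, records) -> list[CellChain]:
    """Chains = connected components of the mutual-lateral relation.

    Each cell has at most one mutual partner per side, so components are paths
    or cycles; cycles are opened at their longest link before measuring
    tortuosity (path length through centroids over endpoint distance).
    """
    edges = _mutual_edges(links)
    if not edges:
        return []
    coords = np.array([r.centroid for r in records], dtype=float)
    thetas = np.array([r.nucleus_ellipse.orientation_rad for r in records])
    adj: dict[int, list[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)

    seen: set[int] = set()
    chains: list[CellChain] = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp = _component(adj, start)
        seen.update(comp)
        order = _order_path(adj, comp, coords)
        dists = [
            float(np.linalg.norm(coords[order[k + 1]] - coords[order[k]]))
            for k in range(len(order) - 1)
        ]
        odiffs = [
            _acute_angle(thetas[order[k]], thetas[order[k + 1]])
            for k in range(len(order) - 1)
        ]
        endpoint = float(np.linalg.norm(coords[order[-1]] - coords[order[0]]))
        tort = sum(dists) / max(endpoint, 1e-12)
        chains.append(
            CellChain(
                member_idx=order,
                size=len(order),
                tortuosity=tort,
                mean_link_dist=float(np.mean(dists)),
                mean_orientation_diff=float(np.mean(odiffs)),
            )
        )
    return chains


def _component(adj: dict[int, list[int]], start: int) -> list[int]:
    comp, stack, seen = [], [start], {start}
    while stack:
        v = stack.pop()
        comp.append(v)
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return comp


def _order_path(
    adj: dict[int, list[int]], comp: list[int], coords: np.ndarray
) -> list[int]:
    degree = {v: len(adj[v]) for v in comp}
    ends = sorted(v for v in comp if degree[v] == 1)
    drop: tuple[int, int] | None = None
    if not ends:  # cycle: open at the longest link
        warnings.warn("closed cell chain; opening at its longest link")
        longest, best = -1.0, None
        for v in comp:
            for w in adj[v]:
                if v < w:
                    d = float(np.linalg.norm(coords[v] - coords[w]))
                    if d > longest:
                        longest, best = d, (v, w)
        drop = best
        ends = [min(best)]
    order = [ends[0]]
    prev = -1
    while True:
        nxt = [
            w
            for w in adj[order[-1]]
            if w != prev
            and not (drop and {w, order[-1]} == set(drop))
        ]
        if not nxt:
            break
        prev = order[-1]
        order.append(nxt[0])
        if len(order) > len(comp):  # pragma: no cover - safety
            break
    return order


def k_nearest_features(
    coords: np.ndarray, idx: int, k: int
) -> tuple[np.ndarray, dict[str, float]] | None:
    """Statistics of the K Euclidean-nearest cells, or None when fewer than K
    other cells exist. Ties in distance break on the lower index."""
    n = len(coords)
    if n - 1 < k:
        return None
    d = np.linalg.norm(coords - coords[idx], axis=1)
    order = sorted((dist, j) for j, dist in enumerate(d) if j != idx)
    members = np.array([j for _, j in order[:k]], dtype=np.int64)
    md = np.array([dist for dist, _ in order[:k]])
    centroid = coords[members].mean(axis=0)
    return members, {
        "mean_dist": float(md.mean()),
        "var_dist": float(md.var()),
        "dist_to_centroid": float(np.linalg.norm(coords[idx] - centroid)),
        "member_count": float(k),
    }


def k_connected_features(
    graph: NeighborhoodGraph,
    sp_dist: np.ndarray,
    idx: int,
    k: int,
) -> tuple[np.ndarray, dict[str, float]] | None:
    """Statistics of the K cells with smallest shortest-path (Dijkstra)
    distance from ``idx`` on the Delaunay graph, or None when the connected
    component is too small. Includes the moment ellipse of member centroids."""
    from .intrinsic import ellipse_from_points

    d = sp_dist[idx]
    reach = sorted(
        (dist, j) for j, dist in enumerate(d) if j != idx and np.isfinite(dist)
    )
    if len(reach) < k:
        return None
    members = np.array([j for _, j in reach[:k]], dtype=np.int64)
    md = np.array([dist for dist, _ in reach[:k]])
    pts = graph.coords[members]
    centroid = pts.mean(axis=0)
    ell = ellipse_from_points(pts)
    return members, {
        "mean_dist": float(md.mean()),
        "var_dist": float(md.var()),
        "dist_to_centroid": float(np.linalg.norm(graph.coords[idx] - centroid)),
        "member_count": float(k),
        "ellipse_major": ell.major_um,
        "ellipse_minor": ell.minor_um,
        "ellipse_elongation": ell.elongation,
        "ellipse_area": np.pi * (ell.major_um / 2.0) * (ell.minor_um / 2.0),
    }


def extract_contextual_features(
    records,
    intrinsic: pd.DataFrame,
    k_values: tuple[int, ...] = K_VALUES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Neighbor-derived (47 x 2 x |K|) and organization (61) feature tables.

    Rows align with ``records``. Cells whose neighborhood cannot be computed
    (too few cells, component smaller than K, no lateral partner) carry the
    catalog fill values.
    """
    n = len(records)
    cat = {d.name: d.fill for d in feature_catalog()}
    nd_names = [
        f"kconn{k}_{stat}_{name}"
        for k in k_values
        for name in INTRINSIC_NAMES
        for stat in ("mean", "var")
    ]
    org_names = [
        d.name for d in feature_catalog() if d.category == "organization"
    ]
    nd = pd.DataFrame(
        np.tile([cat[c] for c in nd_names], (n, 1)), columns=nd_names
    )
    org = pd.DataFrame(
        np.tile([cat[c] for c in org_names], (n, 1)), columns=org_names
    )
    if n < MIN_CELLS_FOR_CONTEXT:
        return nd, org

    graph = build_delaunay(records)
    links = find_lateral_neighbors(records, graph)
    chains = build_chains(links, records)
    sp = dijkstra(graph.csgraph(), directed=False)
    imat = intrinsic.to_numpy(dtype=float)

    for i in range(n):
        cnt, mean_d, var_d = direct_neighbor_features(graph, i)
        org.loc[i, ["direct_count", "direct_mean_dist", "direct_var_dist"]] = (
            cnt,
            mean_d,
            var_d,
        )
        for side, arr, stats in (
            ("left", links.left, links.left_stats),
            ("right", links.right, links.right_stats),
        ):
            if arr[i] >= 0:
                org.loc[
                    i,
                    [
                        f"lateral_{side}_dist",
                        f"lateral_{side}_alignment",
                        f"lateral_{side}_orientation_diff",
                    ],
                ] = stats[i]
        for k in k_values:
            res = k_nearest_features(graph.coords, i, k)
            if res is not None:
                for key, v in res[1].items():
                    org.loc[i, f"knear{k}_{key}"] = v
            resc = k_connected_features(graph, sp, i, k)
            if resc is not None:
                members, stats_c = resc
                for key, v in stats_c.items():
                    org.loc[i, f"kconn{k}_{key}"] = v
                block = imat[members]
                nd.loc[i, [f"kconn{k}_mean_{nm}" for nm in INTRINSIC_NAMES]] = (
                    block.mean(axis=0)
                )
                nd.loc[i, [f"kconn{k}_var_{nm}" for nm in INTRINSIC_NAMES]] = (
                    block.var(axis=0)
                )

    for chain in chains:
        for i in chain.member_idx:
            org.loc[
                i,
                [
                    "chain_size",
                    "chain_tortuosity",
                    "chain_mean_link_dist",
                    "chain_mean_orientation_diff",
                ],
            ] = (
                chain.size,
                chain.tortuosity,
                chain.mean_link_dist,
                chain.mean_orientation_diff,
            )
    return nd, org


def assemble_feature_matrix(
    intrinsic: pd.DataFrame,
    neighbor_derived: pd.DataFrame,
    organization: pd.DataFrame,
) -> pd.DataFrame:
    """Concatenate the three blocks in canonical catalog order and verify
    finiteness; any non-finite value raises, naming the feature."""
    full = pd.concat(
        [
            intrinsic.reset_index(drop=True),
            neighbor_derived.reset_index(drop=True),
            organization.reset_index(drop=True),
        ],
        axis=1,
    )
    names = catalog_names()
    full = full[names]
    if full.shape[1] != N_FEATURES:  # pragma: no cover
        raise AssertionError("feature matrix width mismatch")
    arr = full.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite value in feature {names[bad[1]]!r} (cell row {bad[0]})"
        )
    return full
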