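"""Lattice method for quantifying map order, orientation and precision.

Center nodes are spread approximately equidistantly over the mapped
retinal extent (farthest-point sampling); each center's SC node is the
centroid of the strongest targets of RGCs within a small circle around
it.  A Delaunay lattice built on the retinal centers is projected to the
SC; crossing projected edges indicate local map disorder.  Nodes are
removed greedily (most crossings first) until the remaining submap is
crossing-free — the largest ordered submap.  Reported measures:

* % nodes retaining all their edges (node and all its neighbours kept)
* % edges retained
* AP / ML polarity: % of lattice edges whose SC order matches their
  retinal order along the corresponding axis
* mean absolute orientation difference between retinal and SC edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from ephmap.analysis.mapping import PointMapping

N_CENTERS = 100
CIRCLE_RADIUS = 0.07  # fraction of the unit retinal diameter


class InsufficientCoverageError(ValueError):
    """Raised when too many center circles capture no RGC."""


@dataclass
class LatticeResult:
    centers_retina: np.ndarray  # (M, 2)
    nodes_sc: np.ndarray  # (M, 2) centroids of strongest targets
    edges: np.ndarray  # (E, 2) node index pairs of the full lattice
    removed_nodes: np.ndarray  # indices removed to reach the ordered submap
    pct_nodes: float  # % nodes that kept every incident edge
    pct_edges: float  # % edges with both endpoints kept
    ap_polarity: float  # % edges in correct AP order given NT order
    ml_polarity: float
    orientation_diff_deg: float
    members_per_center: np.ndarray = field(default=None, repr=False)

    @property
    def kept_nodes(self) -> np.ndarray:
        mask = np.ones(len(self.centers_retina), dtype=bool)
        mask[self.removed_nodes] = False
        return np.nonzero(mask)[0]


def farthest_point_sample(points: np.ndarray, n: int) -> np.ndarray:
    """Indices of ``n`` approximately equidistant points.

    Deterministic: starts from the point nearest the centroid and
    repeatedly adds the point farthest from the chosen set.
    """
    n_pts = points.shape[0]
    if n > n_pts:
        raise ValueError("cannot sample more centers than points")
    start = int(np.argmin(np.sum((points - points.mean(axis=0)) ** 2, axis=1)))
    chosen = [start]
    dist = np.linalg.norm(points - points[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen)


def _proper_crossings(p1, p2, edges):
    """Pairs of edge indices whose SC segments properly intersect.

    Edges sharing a node are never counted.  Touching/collinear contacts
    do not count as crossings.
    """
    E = edges.shape[0]
    if E < 2:
        return np.empty((0, 2), dtype=int)

    def cross_sign(o, a, b):
        v = (a[:, None, 0] - o[:, None, 0]) * (b[None, :, 1] - o[:, None, 1]) - (
            a[:, None, 1] - o[:, None, 1]
        ) * (b[None, :, 0] - o[:, None, 0])
        return np.sign(v)

    # d1[e, f]: orientation of f's endpoints relative to segment e
    d1 = cross_sign(p1, p2, p1)  # ccw(p1_e, p2_e, p1_f)
    d2 = cross_sign(p1, p2, p2)
    cross = (d1 * d2 < 0) & (d1.T * d2.T < 0)
    shared = (
        (edges[:, None, 0] == edges[None, :, 0])
        | (edges[:, None, 0] == edges[None, :, 1])
        | (edges[:, None, 1] == edges[None, :, 0])
        | (edges[:, None, 1] == edges[None, :, 1])
    )
    cross &= ~shared
    iu = np.triu_indices(E, k=1)
    mask = cross[iu]
    return np.column_stack([iu[0][mask], iu[1][mask]])


def _edge_set(simplices: np.ndarray) -> np.ndarray:
    edges = set()
    for s in simplices:
        for a, b in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])):
            edges.add((min(a, b), max(a, b)))
    return np.array(sorted(edges), dtype=int)


def lattice_analysis(
    mapping: PointMapping,
    n_centers: int = N_CENTERS,
    circle_radius: float = CIRCLE_RADIUS,
    max_empty_fraction: float = 0.2,
) -> LatticeResult:
    if len(mapping) < n_centers:
        raise ValueError(
            f"need at least {n_centers} mapped RGCs, got {len(mapping)}"
        )
    centers_idx = farthest_point_sample(mapping.retina, n_centers)
    circle_centers = mapping.retina[centers_idx]
    tree = cKDTree(mapping.retina)
    members = tree.query_ball_point(circle_centers, circle_radius)
    counts = np.array([len(m) for m in members])
    empty = counts == 0
    if np.mean(empty) > max_empty_fraction:
        raise InsufficientCoverageError(
            f"{int(np.sum(empty))}/{n_centers} center circles captured no RGC"
        )
    valid = ~empty
    # Both lattice nodes are centroids over the same member set (retinal
    # positions and their SC projections), so an exactly affine map
    # projects the lattice without any distortion.
    centers = np.array(
        [mapping.retina[m].mean(axis=0) for m, v in zip(members, valid) if v]
    )
    nodes_sc = np.array(
        [mapping.sc[m].mean(axis=0) for m, v in zip(members, valid) if v]
    )
    counts = counts[valid]

    tri = Delaunay(centers)
    edges = _edge_set(tri.simplices)
    n_nodes = centers.shape[0]
    n_edges = edges.shape[0]

    # adjacency for the "retained all edges" count
    neighbours = [set() for _ in range(n_nodes)]
    for a, b in edges:
        neighbours[a].add(b)
        neighbours[b].add(a)

    # greedy node removal until the projected submap is crossing-free
    removed: list[int] = []
    active_node = np.ones(n_nodes, dtype=bool)
    while True:
        keep_edge = active_node[edges[:, 0]] & active_node[edges[:, 1]]
        act_edges = edges[keep_edge]
        p1 = nodes_sc[act_edges[:, 0]]
        p2 = nodes_sc[act_edges[:, 1]]
        pairs = _proper_crossings(p1, p2, act_edges)
        if pairs.shape[0] == 0:
            break
        lengths = np.linalg.norm(p2 - p1, axis=1)
        score = np.zeros(n_nodes)
        length_score = np.zeros(n_nodes)
        for e, f in pairs:
            for eidx in (e, f):
                for node in act_edges[eidx]:
                    score[node] += 1.0
                    length_score[node] += lengths[eidx]
        # most crossings; ties by larger total crossing length, then index
        best = np.lexsort((np.arange(n_nodes), -length_score, -score))[0]
        active_node[best] = False
        removed.append(int(best))

    removed_arr = np.array(removed, dtype=int)
    kept = active_node
    full_edge_nodes = [
        v for v in range(n_nodes) if kept[v] and all(kept[u] for u in neighbours[v])
    ]
    pct_nodes = 100.0 * len(full_edge_nodes) / n_nodes
    keep_edge = kept[edges[:, 0]] & kept[edges[:, 1]]
    pct_edges = 100.0 * np.sum(keep_edge) / max(n_edges, 1)

    # audit: the retained submap must be crossing-free
    act_edges = edges[keep_edge]
    assert _proper_crossings(
        nodes_sc[act_edges[:, 0]], nodes_sc[act_edges[:, 1]], act_edges
    ).shape[0] == 0, "ordered submap still contains crossing edges"

    # Polarity over every lattice edge (global order measures).  In the
    # biologically correct map the axes anti-align (temporal retina maps
    # to anterior SC, ventral retina to medial SC), so "correct order"
    # means opposite coordinate differences in retina and SC.
    d_ret = centers[edges[:, 1]] - centers[edges[:, 0]]
    d_sc = nodes_sc[edges[:, 1]] - nodes_sc[edges[:, 0]]
    with np.errstate(invalid="ignore"):
        ap_ok = d_ret[:, 0] * d_sc[:, 0] < 0
        ap_def = (d_ret[:, 0] != 0) & (d_sc[:, 0] != 0)
        ml_ok = d_ret[:, 1] * d_sc[:, 1] < 0
        ml_def = (d_ret[:, 1] != 0) & (d_sc[:, 1] != 0)
    ap_polarity = 100.0 * np.sum(ap_ok & ap_def) / max(np.sum(ap_def), 1)
    ml_polarity = 100.0 * np.sum(ml_ok & ml_def) / max(np.sum(ml_def), 1)

    # Orientation difference relative to the canonical transfer (which
    # rotates edges by 180 degrees): 0 for a perfectly oriented map.
    ang_ret = np.arctan2(-d_ret[:, 1], -d_ret[:, 0])
    ang_sc = np.arctan2(d_sc[:, 1], d_sc[:, 0])
    diff = np.degrees(np.angle(np.exp(1j * (ang_sc - ang_ret))))
    orientation = float(np.mean(np.abs(diff)))

    return LatticeResult(
        centers_retina=centers,
        nodes_sc=nodes_sc,
        edges=edges,
        removed_nodes=removed_arr,
        pct_nodes=float(pct_nodes),
        pct_edges=float(pct_edges),
        ap_polarity=float(ap_polarity),
        ml_polarity=float(ml_polarity),
        orientation_diff_deg=orientation,
        members_per_center=counts,
    )
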