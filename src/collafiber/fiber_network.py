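"""Fiber network extraction from a refined collagen mask.

The refined binary mask is thinned to a 1-px skeleton, the skeleton is cut
into a graph of edges between endpoints and junctions, and the graph is
decomposed into fibers — ordered vertex sequences — by pairing, at each
junction, the incident branches whose tangents are most nearly collinear.
This realizes fiber tracing in the spirit of FIRE-style network extraction:
a fiber crossing another continues straight through the junction, while a
branch meeting at a steep angle terminates there.  Any vertex shared by two
or more fibers' sequences is a cross-link point, and the Euclidean distance
transform of the mask provides per-fiber width estimates.

Pairing rule.  At a junction, each incident branch has an outward unit
tangent estimated from its last few skeleton pixels.  Two branches may be
chained iff their turning angle (180 deg minus the angle between outward
tangents; 0 for a perfectly straight continuation) does not exceed
``max_join_angle_deg``.  Candidate pairs across all junctions are accepted
greedily, globally smallest turning angle first (ties broken by edge id),
each branch pairing at most once per junction end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from collafiber.segmentation import BinaryMask

__all__ = [
    "SkeletonGraph",
    "SkeletonEdge",
    "Fiber",
    "CrossLink",
    "FiberNetwork",
    "skeletonize_mask",
    "extract_fibers",
    "detect_cross_links",
    "estimate_widths",
]

DEFAULT_MAX_JOIN_ANGLE_DEG = 40.0
DEFAULT_MIN_FIBER_LENGTH_PX = 15.0
DEFAULT_SPUR_PRUNE_PX = 4
TANGENT_WINDOW_PX = 5  # pixels used to estimate a branch tangent
JUNCTION_MERGE_PX = 2  # junction pixels this close collapse to one node
WIDTH_EXCLUSION_PX = 3.0  # radius around cross-links/ends excluded from width

_NBRS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonEdge:
    """A simple skeleton path between two nodes.

    ``pixels`` runs from the pixel attached to ``node_a`` to the pixel
    attached to ``node_b`` and excludes junction-cluster pixels (endpoint
    pixels are included).  May be empty for two directly adjacent junctions.
    """

    edge_id: int
    node_a: int
    node_b: int
    pixels: list[tuple[int, int]]

    def arc_length(self) -> float:
        if len(self.pixels) < 2:
            return 0.0
        p = np.asarray(self.pixels, dtype=float)
        return float(np.sqrt(((p[1:] - p[:-1]) ** 2).sum(axis=1)).sum())


@dataclass
class SkeletonGraph:
    """Skeleton pixels organised as nodes (endpoints/junctions) and edges."""

    nodes: dict[int, tuple[float, float]]  # node id -> representative (r, c)
    node_kind: dict[int, str]  # "endpoint" | "junction"
    edges: list[SkeletonEdge]
    edt: np.ndarray  # Euclidean distance transform of the mask, px
    skeleton: np.ndarray  # bool, post-pruning
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.skeleton.shape


GEOM_SMOOTH_WINDOW = 5  # moving-average window for geometric measurement


@dataclass
class Fiber:
    """A traced collagen fiber: an ordered vertex sequence with geometry.

    ``vertices`` is the raw ordered vertex sequence (skeleton pixels plus
    junction representatives); cross-link detection operates on it.
    Geometric measurements (length, chord, orientation, straightness) use a
    lightly smoothed copy of the polyline — a moving average with pinned
    endpoints — because the staircase of an 8-connected skeleton inflates
    raw arc length by several percent.
    """

    fiber_id: int
    vertices: list[tuple[float, float]]
    mean_radius_px: float = float("nan")

    def _measurement_polyline(self) -> np.ndarray:
        v = np.asarray(self.vertices, dtype=float)
        if len(v) <= GEOM_SMOOTH_WINDOW:
            return v
        sm = ndi.uniform_filter1d(v, size=GEOM_SMOOTH_WINDOW, axis=0, mode="nearest")
        sm[0], sm[-1] = v[0], v[-1]
        return sm

    @property
    def length_px(self) -> float:
        v = self._measurement_polyline()
        return float(np.sqrt(((v[1:] - v[:-1]) ** 2).sum(axis=1)).sum())

    @property
    def endpoint_distance_px(self) -> float:
        v0 = np.asarray(self.vertices[0], dtype=float)
        v1 = np.asarray(self.vertices[-1], dtype=float)
        return float(np.linalg.norm(v1 - v0))

    @property
    def orientation_rad(self) -> float:
        """End-to-end chord angle in [0, pi) (axial; row axis -> angle 0)."""
        dr = self.vertices[-1][0] - self.vertices[0][0]
        dc = self.vertices[-1][1] - self.vertices[0][1]
        return math.atan2(dc, dr) % math.pi

    @property
    def straightness(self) -> float:
        arc = self.length_px
        return min(self.endpoint_distance_px / arc, 1.0) if arc > 0 else 1.0


@dataclass
class CrossLink:
    """A vertex position shared by >= 2 distinct fibers."""

    position: tuple[float, float]
    incident_fiber_ids: frozenset[int]


@dataclass
class FiberNetwork:
    fibers: list[Fiber]
    cross_links: list[CrossLink]
    roi_area_px2: int
    pixel_size_um: float


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndi.convolve(skel.astype(int), k, mode="constant")


def _prune_spurs(skel: np.ndarray, prune_px: int) -> np.ndarray:
    """Iteratively remove terminal branches shorter than prune_px that end
    at a junction; free-standing short segments are kept."""
    skel = skel.copy()
    if prune_px <= 0:
        return skel
    for _ in range(16):  # converges in a few passes
        nbrs = _neighbor_count(skel)
        endpoints = np.argwhere(skel & (nbrs == 1))
        removed_any = False
        for r0, c0 in endpoints:
            if not skel[r0, c0]:
                continue
            path = [(int(r0), int(c0))]
            prev: tuple[int, int] | None = None
            cur = (int(r0), int(c0))
            while len(path) <= prune_px:
                nxt = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr, dc in _NBRS8
                    if 0 <= cur[0] + dr < skel.shape[0]
                    and 0 <= cur[1] + dc < skel.shape[1]
                    and skel[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nxt) != 1:
                    break
                n = nxt[0]
                if nbrs[n] >= 3:  # reached a junction: path is a spur
                    if len(path) < prune_px:
                        for p in path:
                            skel[p] = False
                        removed_any = True
                    break
                prev, cur = cur, n
                path.append(n)
        if not removed_any:
            break
    return skel


def _trace_from(
    start: tuple[int, int],
    prev: tuple[int, int] | None,
    skel: np.ndarray,
    is_junction: np.ndarray,
    visited: np.ndarray,
) -> tuple[list[tuple[int, int]], tuple[int, int] | None]:
    """Walk a degree-<=2 chain from ``start`` until a junction pixel, a dead
    end, or an already-visited pixel.  Returns (path, junction_pixel|None)."""
    path: list[tuple[int, int]] = []
    cur = start
    while True:
        path.append(cur)
        visited[cur] = True
        nxt = None
        for dr, dc in _NBRS8:
            q = (cur[0] + dr, cur[1] + dc)
            if not (0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]):
                continue
            if not skel[q] or q == prev:
                continue
            if is_junction[q]:
                return path, q
            if not visited[q]:
                nxt = q
        if nxt is None:
            return path, None
        prev, cur = cur, nxt


def skeletonize_mask(
    mask: BinaryMask,
    spur_prune_px: int = DEFAULT_SPUR_PRUNE_PX,
    junction_merge_px: int = JUNCTION_MERGE_PX,
) -> SkeletonGraph:
    """Thin the refined mask to a skeleton graph with classified nodes.

    Medial-axis thinning produces a 1-px 8-connected skeleton; spur branches
    shorter than ``spur_prune_px`` are removed; junction pixels within
    ``junction_merge_px`` (Chebyshev) collapse into single junction nodes
    (thinning emits junction "clumps"); remaining pixels form simple edges
    between endpoint/junction nodes.  The mask's Euclidean distance
    transform is stored for later width estimation.
    """
    if not mask.refined:
        raise ValueError("skeletonize_mask requires a refined mask")
    edt = ndi.distance_transform_edt(mask.pixels)
    skel = skeletonize(mask.pixels)
    skel = _prune_spurs(skel, spur_prune_px)

    nbrs = _neighbor_count(skel)
    is_junction = skel & (nbrs >= 3)
    # merge nearby junction pixels: pixels within Chebyshev distance
    # junction_merge_px share a label after dilation by (merge-1)
    grow = max(junction_merge_px - 1, 0)
    if grow > 0:
        dil = ndi.binary_dilation(is_junction, iterations=grow)
    else:
        dil = is_junction
    cluster_lbl, n_clusters = ndi.label(dil, structure=np.ones((3, 3), int))
    cluster_lbl = np.where(is_junction, cluster_lbl, 0)

    nodes: dict[int, tuple[float, float]] = {}
    node_kind: dict[int, str] = {}
    cluster_members: dict[int, list[tuple[int, int]]] = {}
    for cid in range(1, n_clusters + 1):
        members = np.argwhere(cluster_lbl == cid)
        if members.size == 0:
            continue
        cluster_members[cid] = [tuple(m) for m in members]
        centroid = members.mean(axis=0)
        rep = members[np.argmin(((members - centroid) ** 2).sum(axis=1))]
        nodes[cid] = (float(rep[0]), float(rep[1]))
        node_kind[cid] = "junction"

    next_node_id = n_clusters + 1
    visited = np.zeros_like(skel, dtype=bool)
    edges: list[SkeletonEdge] = []

    def _endpoint_node(px: tuple[int, int]) -> int:
        nonlocal next_node_id
        nid = next_node_id
        next_node_id += 1
        nodes[nid] = (float(px[0]), float(px[1]))
        node_kind[nid] = "endpoint"
        return nid

    # 1) edges emanating from junction clusters
    junction_pixels = np.argwhere(is_junction)
    seen_jj_pairs: set[frozenset[tuple[int, int]]] = set()
    for r, c in junction_pixels:
        cid = int(cluster_lbl[r, c])
        for dr, dc in _NBRS8:
            q = (int(r) + dr, int(c) + dc)
            if not (0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]):
                continue
            if not skel[q]:
                continue
            if is_junction[q]:
                qcid = int(cluster_lbl[q])
                if qcid != cid:  # adjacent distinct clusters: 0-length edge
                    key = frozenset([(int(r), int(c)), q])
                    if key not in seen_jj_pairs:
                        seen_jj_pairs.add(key)
                        edges.append(
                            SkeletonEdge(len(edges), cid, qcid, [])
                        )
                continue
            if visited[q]:
                continue
            path, jpx = _trace_from(q, (int(r), int(c)), skel, is_junction, visited)
            if jpx is not None:
                edges.append(SkeletonEdge(len(edges), cid, int(cluster_lbl[jpx]), path))
            else:
                edges.append(SkeletonEdge(len(edges), cid, _endpoint_node(path[-1]), path))

    # 2) free chains (no junction): start from unvisited degree<=1 pixels
    free_starts = np.argwhere(skel & (nbrs <= 1) & ~is_junction & ~visited)
    for r, c in free_starts:
        if visited[r, c]:
            continue
        path, jpx = _trace_from((int(r), int(c)), None, skel, is_junction, visited)
        na = _endpoint_node(path[0])
        nb = int(cluster_lbl[jpx]) if jpx is not None else _endpoint_node(path[-1])
        edges.append(SkeletonEdge(len(edges), na, nb, path))

    # 3) pure cycles: whatever degree-2 pixels remain
    remaining = np.argwhere(skel & ~is_junction & ~visited)
    for r, c in remaining:
        if visited[r, c]:
            continue
        path, _ = _trace_from((int(r), int(c)), None, skel, is_junction, visited)
        na = _endpoint_node(path[0])
        edges.append(SkeletonEdge(len(edges), na, na, path))

    # Merge junction clusters connected by edges shorter than the local
    # crossing-zone diameter (2x the EDT radius at either junction):
    # shallow crossings of wide fibers thin into two Y-junctions joined by
    # a short bar, which must act as one crossing node for branch pairing.
    parent = {cid: cid for cid in cluster_members}

    def _find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    absorbed: set[int] = set()
    for e in edges:
        if (
            node_kind.get(e.node_a) == "junction"
            and node_kind.get(e.node_b) == "junction"
        ):
            ra, rb = nodes[e.node_a], nodes[e.node_b]
            # crossing-zone diameter: shallow crossings separate their two
            # Y-junctions by up to ~1.5 fiber diameters along the skeleton
            zone = 3.0 * max(
                edt[int(ra[0]), int(ra[1])], edt[int(rb[0]), int(rb[1])]
            )
            if len(e.pixels) + 1 <= math.ceil(zone):
                # short connectors merge their junctions; short self-loops
                # (thinning artifacts around crossings) dissolve into theirs
                pa, pb = _find(e.node_a), _find(e.node_b)
                if pa != pb:
                    parent[max(pa, pb)] = min(pa, pb)
                absorbed.add(e.edge_id)
                cluster_members[_find(e.node_a)] = (
                    cluster_members[_find(e.node_a)] + e.pixels
                )

    if absorbed:
        # regroup members under root ids and recompute representatives
        merged_members: dict[int, list[tuple[int, int]]] = {}
        for cid, mem in cluster_members.items():
            merged_members.setdefault(_find(cid), []).extend(mem)
        for root, mem in merged_members.items():
            arr = np.asarray(mem, dtype=float)
            centroid = arr.mean(axis=0)
            rep = arr[np.argmin(((arr - centroid) ** 2).sum(axis=1))]
            nodes[root] = (float(rep[0]), float(rep[1]))
        new_edges: list[SkeletonEdge] = []
        for e in edges:
            if e.edge_id in absorbed:
                continue
            na = _find(e.node_a) if node_kind.get(e.node_a) == "junction" else e.node_a
            nb = _find(e.node_b) if node_kind.get(e.node_b) == "junction" else e.node_b
            new_edges.append(SkeletonEdge(len(new_edges), na, nb, e.pixels))
        edges = new_edges
        live = {_find(c) for c in cluster_members}
        for cid in list(cluster_members):
            if cid not in live:
                nodes.pop(cid, None)
                node_kind.pop(cid, None)

    return SkeletonGraph(
        nodes=nodes,
        node_kind=node_kind,
        edges=edges,
        edt=edt,
        skeleton=skel,
        pixel_size_um=mask.pixel_size_um,
    )


def _outward_tangent(
    edge: SkeletonEdge, node_id: int, graph: SkeletonGraph
) -> np.ndarray:
    """Unit tangent of ``edge`` at ``node_id``, pointing away from the node,
    estimated from the last TANGENT_WINDOW_PX path pixels."""
    node_pos = np.asarray(graph.nodes[node_id], dtype=float)
    if not edge.pixels:  # junction-junction adjacency
        other = edge.node_b if edge.node_a == node_id else edge.node_a
        v = np.asarray(graph.nodes[other], dtype=float) - node_pos
    else:
        path = edge.pixels if edge.node_a == node_id else edge.pixels[::-1]
        # skip pixels inside the crossing zone, where thinning displaces
        # the skeleton off the fiber axis, then fit over the window
        rr, cc = int(node_pos[0]), int(node_pos[1])
        skip = int(graph.edt[rr, cc]) if 0 <= rr < graph.edt.shape[0] else 0
        skip = min(skip, max(len(path) - 2, 0))
        window = np.asarray(path[skip : skip + TANGENT_WINDOW_PX], dtype=float)
        if len(window) >= 2:
            # direction from the edge's own pixels: robust to junction
            # representatives displaced off the fiber axis
            v = window[-1] - window[0]
        else:
            v = window[-1] - node_pos
        if np.allclose(v, 0):
            v = window[-1] - node_pos
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def extract_fibers(
    graph: SkeletonGraph,
    max_join_angle_deg: float = DEFAULT_MAX_JOIN_ANGLE_DEG,
    min_fiber_length_px: float = DEFAULT_MIN_FIBER_LENGTH_PX,
) -> FiberNetwork:
    """Decompose the skeleton graph into fibers by collinearity pairing.

    Every skeleton edge belongs to exactly one fiber before the length
    filter; fibers shorter than ``min_fiber_length_px`` are then discarded.
    When chaining passes through a junction (or a branch terminates at one),
    the junction's representative vertex is appended to the fiber's vertex
    sequence, so fibers meeting at a junction share that vertex.
    """
    # ends: (edge_id, which) with which in {0 (node_a), 1 (node_b)}
    ends_at_junction: dict[int, list[tuple[int, int]]] = {}
    for e in graph.edges:
        for which, nid in ((0, e.node_a), (1, e.node_b)):
            if graph.node_kind.get(nid) == "junction":
                ends_at_junction.setdefault(nid, []).append((e.edge_id, which))

    tangent: dict[tuple[int, int], np.ndarray] = {}
    for nid, ends in ends_at_junction.items():
        for eid, which in ends:
            tangent[(eid, which)] = _outward_tangent(graph.edges[eid], nid, graph)

    candidates: list[tuple[float, int, int, int, int, int]] = []
    for nid, ends in ends_at_junction.items():
        for i in range(len(ends)):
            for j in range(i + 1, len(ends)):
                u = tangent[ends[i]]
                v = tangent[ends[j]]
                cosang = float(np.clip(np.dot(u, v), -1.0, 1.0))
                turning = 180.0 - math.degrees(math.acos(cosang))
                if turning <= max_join_angle_deg:
                    candidates.append((turning, ends[i][0], ends[i][1],
                                       ends[j][0], ends[j][1], nid))
    candidates.sort()

    partner: dict[tuple[int, int], tuple[int, int]] = {}
    for turning, e1, w1, e2, w2, nid in candidates:
        if (e1, w1) in partner or (e2, w2) in partner:
            continue
        partner[(e1, w1)] = (e2, w2)
        partner[(e2, w2)] = (e1, w1)

    def _end_node(eid: int, which: int) -> int:
        e = graph.edges[eid]
        return e.node_a if which == 0 else e.node_b

    def _oriented_pixels(eid: int, start_which: int) -> list[tuple[int, int]]:
        px = graph.edges[eid].pixels
        return px if start_which == 0 else px[::-1]

    assigned: set[int] = set()
    fibers: list[Fiber] = []

    def _build_chain(start_end: tuple[int, int]) -> list[tuple[float, float]]:
        """Walk the chain starting at an edge-end, collecting vertices.

        Junction representatives are inserted wherever the chain touches a
        junction — between paired edges and at terminating ends — so every
        fiber incident to a junction carries its vertex.
        """
        vertices: list[tuple[float, float]] = []
        eid, which = start_end
        start_nid = _end_node(eid, which)
        if graph.node_kind.get(start_nid) == "junction":
            vertices.append(graph.nodes[start_nid])
        while True:
            assigned.add(eid)
            for p in _oriented_pixels(eid, which):
                vertices.append((float(p[0]), float(p[1])))
            far = (eid, 1 - which)
            far_nid = _end_node(*far)
            if graph.node_kind.get(far_nid) == "junction":
                vertices.append(graph.nodes[far_nid])
            nxt = partner.get(far)
            if nxt is None or nxt == start_end or nxt[0] in assigned:
                break
            eid, which = nxt
        return vertices

    # chains starting at terminal (unpaired) ends
    for e in graph.edges:
        for which in (0, 1):
            if e.edge_id in assigned:
                continue
            if (e.edge_id, which) not in partner:
                verts = _build_chain((e.edge_id, which))
                if len(verts) >= 2:
                    fibers.append(Fiber(len(fibers), verts))
                elif len(verts) == 1:
                    pass  # single-pixel fragment: below any length threshold
                break
    # closed loops: every end paired
    for e in graph.edges:
        if e.edge_id not in assigned:
            verts = _build_chain((e.edge_id, 0))
            if len(verts) >= 2:
                fibers.append(Fiber(len(fibers), verts))

    kept = [f for f in fibers if f.length_px >= min_fiber_length_px]
    fibers = [replace(f, fiber_id=i) for i, f in enumerate(kept)]

    h, w = graph.shape
    return FiberNetwork(
        fibers=fibers,
        cross_links=[],
        roi_area_px2=int(h * w),
        pixel_size_um=graph.pixel_size_um,
    )


def detect_cross_links(net: FiberNetwork) -> FiberNetwork:
    """Mark every vertex position shared by >= 2 distinct fibers as a
    cross-link; duplicate positions merge into one cross-link recording all
    incident fiber ids.

    A position shared only by fiber ENDPOINTS is not counted: two chains
    abutting end-to-end at a junction are a tracing split, not a physical
    crossing.  At least one incident fiber must carry the position as an
    interior vertex.
    """
    owners: dict[tuple[float, float], set[int]] = {}
    interior: dict[tuple[float, float], bool] = {}
    for f in net.fibers:
        for i, v in enumerate(f.vertices):
            owners.setdefault(v, set()).add(f.fiber_id)
            if 0 < i < len(f.vertices) - 1:
                interior[v] = True
    cross = [
        CrossLink(position=pos, incident_fiber_ids=frozenset(ids))
        for pos, ids in sorted(owners.items())
        if len(ids) >= 2 and interior.get(pos, False)
    ]
    return replace(net, cross_links=cross)


def estimate_widths(net: FiberNetwork, graph: SkeletonGraph) -> FiberNetwork:
    """Estimate each fiber's width as twice its mean distance-transform
    radius along the centerline.

    Vertices within WIDTH_EXCLUSION_PX of a cross-link or of either fiber
    end are excluded (the EDT is inflated at crossings and deflated at
    ends); if nothing survives the exclusion, all vertices are used.
    """
    edt = graph.edt
    cross_pos = np.asarray([cl.position for cl in net.cross_links], dtype=float)
    fibers = []
    for f in net.fibers:
        v = np.asarray(f.vertices, dtype=float)
        keep = np.ones(len(v), dtype=bool)
        if len(v) > 1:
            d_start = np.linalg.norm(v - v[0], axis=1)
            d_end = np.linalg.norm(v - v[-1], axis=1)
            keep &= (d_start > WIDTH_EXCLUSION_PX) & (d_end > WIDTH_EXCLUSION_PX)
        if cross_pos.size:
            d_cross = np.sqrt(
                ((v[:, None, :] - cross_pos[None, :, :]) ** 2).sum(axis=2)
            ).min(axis=1)
            keep &= d_cross > WIDTH_EXCLUSION_PX
        sel = v[keep] if keep.any() else v
        rr = np.clip(np.round(sel[:, 0]).astype(int), 0, edt.shape[0] - 1)
        cc = np.clip(np.round(sel[:, 1]).astype(int), 0, edt.shape[1] - 1)
        fibers.append(replace(f, mean_radius_px=float(edt[rr, cc].mean())))
    return replace(net, fibers=fibers)
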