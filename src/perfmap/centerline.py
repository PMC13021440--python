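"""Vessel centerline extraction from binary masks.

A candidate-vessel mask is thinned to a one-voxel skeleton, each 26-connected
skeleton component is turned into a single ordered path (the graph-diameter
path between its two farthest endpoints, which at bifurcations keeps the
longest branch and discards side branches), and physical path lengths are
measured in millimetres using the voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .volume_io import Geometry, Mask, VoxelPoint, points_to_world

__all__ = [
    "Centerline",
    "skeletonize_mask",
    "order_path",
    "extract_centerlines",
    "path_length_mm",
    "straight_line_length_mm",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Centerline:
    """Ordered voxel path of one vessel; consecutive points are 26-neighbours."""

    points: list[VoxelPoint]
    geometry: Geometry
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("a centerline needs at least one point")
        seen = set()
        prev = None
        for p in self.points:
            t = p.as_tuple()
            if t in seen:
                raise ValueError(f"repeated point {t} in centerline")
            seen.add(t)
            if prev is not None:
                if max(abs(a - b) for a, b in zip(t, prev)) != 1:
                    raise ValueError(f"points {prev} and {t} are not 26-neighbours")
            prev = t

    def as_array(self) -> np.ndarray:
        return np.array([p.as_tuple() for p in self.points], dtype=int)

    def world_points(self) -> np.ndarray:
        return points_to_world(self.as_array(), self.geometry)

    def __len__(self) -> int:
        return len(self.points)


def skeletonize_mask(mask: Mask) -> Mask:
    """Thin a binary mask to a ~1-voxel-wide skeleton.

    The skeleton is a subset of the input and preserves the number of
    26-connected components (topology-preserving thinning).
    """
    if not mask.values.any():
        return Mask(geometry=mask.geometry, values=np.zeros_like(mask.values))
    skel = skeletonize(mask.as_bool())
    return Mask(geometry=mask.geometry, values=skel.astype(np.uint8))


def _component_graph(coords: np.ndarray, spacing: np.ndarray) -> sparse.csr_matrix:
    """Sparse 26-connectivity adjacency with physical (mm) edge weights."""
    n = len(coords)
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    rows, cols, w = [], [], []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    off_len = {o: float(np.linalg.norm(np.asarray(o) * spacing)) for o in offsets}
    for i, c in enumerate(map(tuple, coords)):
        for o in offsets:
            j = index.get((c[0] + o[0], c[1] + o[1], c[2] + o[2]))
            if j is not None and j > i:
                rows.append(i)
                cols.append(j)
                w.append(off_len[o])
    m = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
    return m + m.T


def order_path(skeleton_component: Mask) -> Centerline:
    """Order one 26-connected skeleton component into a single path.

    Returns the geodesic between the two endpoints whose pairwise geodesic
    (mm-weighted) distance is largest — the graph-diameter path.  Side
    branches shorter than the main course are discarded.  Ties between
    equal-length diameter paths go to the lexicographically smallest
    endpoint (z, y, x).
    """
    g = skeleton_component.geometry
    coords = np.argwhere(skeleton_component.as_bool())
    if len(coords) == 0:
        raise ValueError("empty skeleton component")
    # canonical voxel order so tie-breaks are deterministic
    coords = coords[np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))]
    if len(coords) == 1:
        return Centerline(points=[VoxelPoint(*coords[0])], geometry=g)

    adj = _component_graph(coords, np.asarray(g.spacing))
    degrees = np.diff(adj.indptr)
    endpoints = np.flatnonzero(degrees == 1)
    if len(endpoints) == 0:
        # closed loop: fall back to all nodes as candidate endpoints
        endpoints = np.arange(len(coords))

    best = None  # (distance, src_idx, dst_idx, predecessors_row)
    for src in endpoints:
        dist, pred = dijkstra(adj, indices=src, return_predecessors=True)
        reach = np.where(np.isfinite(dist))[0]
        targets = reach[np.isin(reach, endpoints)]
        dst = targets[np.argmax(dist[targets])]
        d = dist[dst]
        if best is None or d > best[0] + 1e-12:
            best = (d, src, dst, pred)
    _, src, dst, pred = best
    path = [dst]
    while path[-1] != src:
        path.append(pred[path[-1]])
    path.reverse()
    return Centerline(points=[VoxelPoint(*coords[i]) for i in path], geometry=g)


def _extend_path_into_mask(
    path: list[tuple[int, int, int]],
    mask_coords: np.ndarray,
    spacing: np.ndarray,
) -> list[tuple[int, int, int]]:
    """Re-extend a skeleton path to the geodesic extremes of its mask component.

    3D thinning can retract the free end of a tube by many voxels (flat or
    even-width runs are a known pathology), so the ordered skeleton path is
    prolonged at each end: mask voxels nearest (by geodesic distance) to a
    terminal path node form that end's catchment region, and the geodesic to
    the region's farthest voxel is appended.
    """
    k = len(path)
    if k < 4 or len(mask_coords) <= k:
        return path
    index = {tuple(c): i for i, c in enumerate(map(tuple, mask_coords))}
    path_idx = np.array([index[p] for p in path])
    adj = _component_graph(mask_coords, spacing)
    dmat = dijkstra(adj, indices=path_idx)
    nearest = np.argmin(dmat, axis=0)

    def extension(end: str) -> list[tuple[int, int, int]]:
        if end == "start":
            terminal = {0, 1}
            node = path_idx[0]
        else:
            terminal = {k - 2, k - 1}
            node = path_idx[k - 1]
        region = np.flatnonzero(np.isin(nearest, list(terminal)))
        region = np.setdiff1d(region, path_idx, assume_unique=False)
        if region.size == 0:
            return []
        keep = np.concatenate([[node], region])
        sub = adj[np.ix_(keep, keep)]
        dist, pred = dijkstra(sub, indices=0, return_predecessors=True)
        reach = np.flatnonzero(np.isfinite(dist))
        reach = reach[reach != 0]
        if reach.size == 0:
            return []
        best = dist[reach].max()
        cands = reach[np.isclose(dist[reach], best)]
        coords = mask_coords[keep[cands]]
        far = cands[np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))[0]]
        chain = [far]
        while pred[chain[-1]] != 0 and pred[chain[-1]] >= 0:
            chain.append(pred[chain[-1]])
        chain.reverse()
        return [tuple(int(v) for v in mask_coords[keep[i]]) for i in chain]

    head = extension("start")
    tail = extension("end")
    return list(reversed(head)) + path + tail


def extract_centerlines(
    candidates: Mask, min_length_mm: float = 0.0, extend_into_mask: bool = True
) -> list[Centerline]:
    """One ordered centerline per 26-connected component of the candidate mask.

    Each component is thinned, ordered along its graph diameter, and (by
    default) re-extended through the mask where thinning retracted a free
    end.  Point 0 of each path is its most posterior endpoint (highest Y);
    paths shorter than ``min_length_mm`` are dropped; the result is sorted
    by descending path length.
    """
    g = candidates.geometry
    spacing = np.asarray(g.spacing)
    skel = skeletonize_mask(candidates)
    mask_labels, n = ndimage.label(candidates.as_bool(), structure=_STRUCT_26)
    out: list[Centerline] = []
    for lab in range(1, n + 1):
        comp = mask_labels == lab
        skel_comp = skel.as_bool() & comp
        if not skel_comp.any():
            continue
        c = order_path(Mask(geometry=g, values=skel_comp.astype(np.uint8)))
        if extend_into_mask:
            path = [p.as_tuple() for p in c.points]
            path = _extend_path_into_mask(path, np.argwhere(comp), spacing)
            c = Centerline(points=[VoxelPoint(*p) for p in path], geometry=g)
        first, last = c.points[0], c.points[-1]
        if last.y > first.y or (last.y == first.y and last.as_tuple() < first.as_tuple()):
            c = Centerline(points=list(reversed(c.points)), geometry=c.geometry)
        if path_length_mm(c) >= min_length_mm:
            out.append(c)
    out.sort(key=path_length_mm, reverse=True)
    for i, c in enumerate(out):
        c.id = c.id or f"cl{i:02d}"
    return out


def path_length_mm(c: Centerline) -> float:
    """Summed Euclidean mm distance over consecutive physical points."""
    if len(c) < 2:
        return 0.0
    pts = c.world_points()
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def straight_line_length_mm(c: Centerline) -> float:
    """Euclidean mm distance between a path's first and last points.

    Against path_length_mm this is the control for ordering failures: a
    centerline that jumps between branches inflates its path length but not
    its endpoint distance.
    """
    if len(c) < 2:
        return 0.0
    pts = c.world_points()
    return float(np.linalg.norm(pts[-1] - pts[0]))
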