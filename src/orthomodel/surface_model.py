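"""Optical-scan surface processing.

Covers the digital mouth model workflow: rigid ICP registration of
impression and cast scans, tolerance-based merging, implicit-surface mesh
reconstruction, local surface-variation curvature from covariance
eigenanalysis, closed margin-line splines, and the crown/gingiva
segmentation of the merged mouth mesh.

The surface-variation parameter of a point p with neighbourhood N_p is

    delta_n(p) = lambda0 / (lambda0 + lambda1 + lambda2),

the eigenvalues (ascending) of the covariance matrix of the neighbours
about their centroid.  delta_n = 0 means the neighbours lie exactly in a
plane; delta_n = 1/3 is a perfectly isotropic distribution; the eigenvector
v0 of lambda0 estimates the surface normal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree, breadth_first_order
from scipy.spatial import cKDTree
from skimage import measure
import trimesh

from .core import PointCloud, RigidTransform
from .errors import (ConvergenceError, InputError, ParameterError,
                     ReconstructionError, SegmentationError)

__all__ = [
    "PointCloud", "RigidTransform", "CurvatureField", "MarginLine",
    "SegmentedMouthModel", "icp_register", "merge_scans", "reconstruct_mesh",
    "surface_variation", "estimate_normals", "fit_margin_spline",
    "segment_crowns", "coverage_fraction", "kabsch",
]


@dataclass
class CurvatureField:
    """Per-point surface variation delta_n in [0, 1/3] with the estimated
    normals; points with fewer than 3 neighbours are flagged undefined."""

    delta_n: np.ndarray       # (N,) float, NaN where undefined
    normals: np.ndarray       # (N, 3) v0 estimates
    defined: np.ndarray       # (N,) bool
    radius: float             # neighbourhood radius, mm
    eigenvalues: np.ndarray   # (N, 3) ascending


@dataclass
class MarginLine:
    """Closed periodic cubic spline around one tooth's cervical margin."""

    tooth_id: str
    seeds: np.ndarray                 # (K, 3) interpolation points, mm
    _splines: tuple                   # one CubicSpline per coordinate
    knots: np.ndarray                 # chord-length parameter values

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.mod(np.asarray(t, dtype=float), self.knots[-1])
        return np.column_stack([s(t) for s in self._splines])

    def sample(self, n: int = 200) -> np.ndarray:
        return self.evaluate(np.linspace(0.0, self.knots[-1], n, endpoint=False))


@dataclass
class SegmentedMouthModel:
    """Mouth mesh partitioned into per-tooth crowns and gingiva.

    ``assignment`` holds a tooth_id per vertex or '' for gingiva.
    """

    mesh: trimesh.Trimesh
    assignment: np.ndarray            # (V,) object/str
    tooth_ids: list[str]

    def crown_vertex_mask(self, tooth_id: str) -> np.ndarray:
        return self.assignment == tooth_id

    def crown_submesh(self, tooth_id: str) -> trimesh.Trimesh:
        """Faces whose three vertices carry ``tooth_id``; stray islands
        (isolated crease patches) are dropped, keeping the main shell."""
        mask = self.crown_vertex_mask(tooth_id)
        faces_keep = mask[self.mesh.faces].all(axis=1)
        sub = self.mesh.submesh([np.nonzero(faces_keep)[0]], append=True)
        parts = sub.split(only_watertight=False)
        if len(parts) > 1:
            sub = max(parts, key=lambda m: len(m.faces))
        return sub


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform source -> target (SVD);
    reflections corrected by flipping the smallest singular vector."""
    src_c = source.mean(axis=0)
    tgt_c = target.mean(axis=0)
    H = (source - src_c).T @ (target - tgt_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tgt_c - R @ src_c)


def icp_register(source: PointCloud, target: PointCloud,
                 init: RigidTransform | None = None,
                 max_iter: int = 50, tol: float = 1e-6,
                 reject_dist: float = 5.0) -> tuple[RigidTransform, float]:
    """Point-to-point ICP with mutual-nearest correspondences and distance
    rejection.

    Returns the transform mapping source into the target frame and the
    final RMS (mm) over accepted correspondences.  RMS is monotone
    non-increasing across iterations (an increasing step is reverted and
    iteration stops); fewer than 3 usable correspondences raises
    :class:`ConvergenceError`.
    """
    if len(source) < 3 or len(target) < 3:
        raise InputError("both clouds need at least 3 points")
    T = init or RigidTransform.identity()
    tgt = target.positions
    tree_t = cKDTree(tgt)
    best_rms = np.inf
    best_T = T
    stalled = 0
    for _ in range(max_iter):
        moved = T.apply(source.positions)
        d_st, idx_st = tree_t.query(moved, distance_upper_bound=reject_dist)
        ok = np.isfinite(d_st)
        # mutual-nearest filter: the target point's nearest moved-source
        # point must be the one that selected it
        d_ts, idx_ts = cKDTree(moved).query(tgt, distance_upper_bound=reject_dist)
        mutual = np.zeros(len(moved), dtype=bool)
        s_idx = np.nonzero(ok)[0]
        mutual[s_idx] = idx_ts[idx_st[s_idx]] == s_idx
        pairs = ok & mutual
        if pairs.sum() < 3:
            raise ConvergenceError(
                f"only {int(pairs.sum())} usable correspondences "
                f"(reject_dist = {reject_dist} mm)")
        src_pts = moved[pairs]
        tgt_pts = tgt[idx_st[pairs]]
        rms = float(np.sqrt(np.mean(np.sum((src_pts - tgt_pts) ** 2, axis=1))))
        # the best (transform, rms) seen is returned, so the reported rms
        # is non-increasing in the iteration budget even though the raw
        # per-iteration rms may fluctuate as correspondences switch
        if rms < best_rms - tol:
            stalled = 0
        else:
            stalled += 1
        if rms < best_rms:
            best_rms = rms
            best_T = T
        if stalled >= 3 or best_rms < tol:
            break
        step = kabsch(src_pts, tgt_pts)
        T = step.compose(T)
    return best_T, best_rms


# ---------------------------------------------------------------------------
# merging & reconstruction
# ---------------------------------------------------------------------------

def merge_scans(impression: PointCloud, cast: PointCloud,
                transform: RigidTransform | None = None,
                merge_tolerance: float = 0.05) -> PointCloud:
    """Merge the impression scan (mapped by ``transform`` into the cast
    frame) with the cast scan.

    Point pairs closer than ``merge_tolerance`` are deduplicated by
    averaging; everything else is kept verbatim, so the union's coverage is
    at least each input's.  ``merge_tolerance = 0`` degenerates to pure
    concatenation.
    """
    imp = impression.transformed(transform) if transform else impression
    if merge_tolerance <= 0 or len(imp) == 0 or len(cast) == 0:
        return imp.concatenated(cast)
    tree_c = cKDTree(cast.positions)
    d, idx = tree_c.query(imp.positions, distance_upper_bound=merge_tolerance)
    matched = np.isfinite(d)
    # average matched impression points into their cast counterpart
    merged_positions = cast.positions.copy()
    counts = np.ones(len(cast))
    np.add.at(merged_positions, idx[matched], imp.positions[matched])
    np.add.at(counts, idx[matched], 1.0)
    merged_positions /= counts[:, None]
    merged = PointCloud(merged_positions, cast.normals,
                        {k: v.copy() for k, v in cast.labels.items()})
    return merged.concatenated(imp.select(~matched))


def estimate_normals(cloud: PointCloud, radius: float = 2.0,
                     outside_point=None) -> np.ndarray:
    """Covariance normals (v0) with consistent orientation.

    Orientation is propagated along a Euclidean minimum spanning tree,
    seeded so the normal of the point farthest from the centroid points
    away from ``outside_point`` (default: cloud centroid, giving outward
    normals on closed surfaces).
    """
    field = surface_variation(cloud, radius=radius)
    normals = field.normals.copy()
    P = cloud.positions
    n = len(P)
    k = min(8, n)
    tree = cKDTree(P)
    d, j = tree.query(P, k=k)
    rows = np.repeat(np.arange(n), k - 1)
    cols = j[:, 1:].ravel()
    vals = d[:, 1:].ravel() + 1e-12
    graph = coo_matrix((vals, (rows, cols)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    sym = mst + mst.T
    start = int(np.argmax(np.linalg.norm(P - P.mean(axis=0), axis=1)))
    if outside_point is None:
        outward = P[start] - P.mean(axis=0)
    else:
        outward = np.asarray(outside_point, dtype=float) - P[start]
    if np.dot(normals[start], outward) < 0:
        normals[start] *= -1
    order, pred = breadth_first_order(sym, start, directed=False)
    for v in order[1:]:
        p = pred[v]
        if p >= 0 and np.dot(normals[v], normals[p]) < 0:
            normals[v] *= -1
    return normals


def reconstruct_mesh(cloud: PointCloud, voxel_pitch: float = 0.2,
                     band: float | None = None) -> trimesh.Trimesh:
    """Implicit-surface reconstruction: signed-distance grid from oriented
    points, tessellated by marching cubes.

    The signed distance at a grid node is the projection of the offset to
    the nearest sample onto that sample's normal.  Raises
    :class:`ReconstructionError` for under-sampled (< 100 points) or
    degenerate (coplanar) clouds.
    """
    if len(cloud) < 100:
        raise ReconstructionError("at least 100 points are required")
    if voxel_pitch <= 0:
        raise ParameterError("voxel_pitch must be positive")
    P = cloud.positions
    evals = np.linalg.eigvalsh(np.cov(P.T))
    if evals[0] < 1e-10 * max(evals[2], 1e-12):
        raise ReconstructionError("cloud is degenerate (coplanar)")
    normals = cloud.normals
    if normals is None:
        normals = estimate_normals(cloud, radius=6 * voxel_pitch)
    band = band if band is not None else 3 * voxel_pitch
    lo = P.min(axis=0) - 3 * voxel_pitch
    hi = P.max(axis=0) + 3 * voxel_pitch
    axes = [np.arange(lo[i], hi[i] + voxel_pitch, voxel_pitch) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    tree = cKDTree(P)
    d, idx = tree.query(nodes)
    offset = nodes - P[idx]
    dot = np.einsum("ij,ij->i", offset, normals[idx])
    sdf = dot
    # far from the samples the tangent-plane projection is unreliable:
    # use the full distance with the side given by the projection's sign
    far = d > band
    sdf[far] = np.sign(dot[far]) * d[far]
    sdf = sdf.reshape(X.shape)
    try:
        verts, faces, _, _ = measure.marching_cubes(sdf, 0.0)
    except (ValueError, RuntimeError) as e:
        raise ReconstructionError(f"marching cubes failed: {e}") from None
    verts = verts * voxel_pitch + lo
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def point_to_surface_distance(mesh: trimesh.Trimesh, points: np.ndarray,
                              n_candidates: int = 12,
                              return_faces: bool = False):
    """Unsigned distance from each point to the mesh surface.

    Candidate faces come from a KD-tree over face centroids; the exact
    point-triangle distance is evaluated on those candidates.  With
    ``return_faces`` the index of the closest face is returned as well.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.triangles
    centroids = tri.mean(axis=1)
    k = min(n_candidates, len(centroids))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand.T).T if k > 1 else cand.reshape(-1, 1)
    out = np.full(len(points), np.inf)
    best = np.zeros(len(points), dtype=int)
    for j in range(cand.shape[1]):
        d = _point_triangle_distance(points, tri[cand[:, j]])
        better = d < out
        out[better] = d[better]
        best[better] = cand[better, j]
    if return_faces:
        return out, best
    return out


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from points p[i] to triangles tri[i] (vectorized
    closest-point-on-triangle, Ericson's region test)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    closest = a.copy()
    # vertex regions
    va_reg = (d1 <= 0) & (d2 <= 0)
    vb_reg = (d3 >= 0) & (d4 <= d3)
    vc_reg = (d6 >= 0) & (d5 <= d6)
    closest[vb_reg] = b[vb_reg]
    closest[vc_reg] = c[vc_reg]
    done = va_reg | vb_reg | vc_reg
    # edge AB
    vc_ = d1 * d4 - d3 * d2
    ab_reg = ~done & (vc_ <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(np.abs(d1 - d3) > 1e-300, d1 / (d1 - d3 + 1e-300), 0.0)
    closest[ab_reg] = a[ab_reg] + t[ab_reg, None] * ab[ab_reg]
    done |= ab_reg
    # edge AC
    vb_ = d5 * d2 - d1 * d6
    ac_reg = ~done & (vb_ <= 0) & (d2 >= 0) & (d6 <= 0)
    w = d2 / (d2 - d6 + 1e-300)
    closest[ac_reg] = a[ac_reg] + w[ac_reg, None] * ac[ac_reg]
    done |= ac_reg
    # edge BC
    va_ = d3 * d6 - d5 * d4
    bc_reg = ~done & (va_ <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    w2 = (d4 - d3) / ((d4 - d3) + (d5 - d6) + 1e-300)
    closest[bc_reg] = b[bc_reg] + w2[bc_reg, None] * (c[bc_reg] - b[bc_reg])
    done |= bc_reg
    # interior
    interior = ~done
    denom = va_ + vb_ + vc_
    denom = np.where(np.abs(denom) > 1e-300, denom, 1.0)
    v = vb_ / denom
    w3 = vc_ / denom
    closest[interior] = (a[interior] + v[interior, None] * ab[interior]
                         + w3[interior, None] * ac[interior])
    return np.linalg.norm(p - closest, axis=1)


def coverage_fraction(reference: np.ndarray, cloud: PointCloud,
                      radius: float = 0.3) -> float:
    """Fraction of reference surface samples having a cloud point within
    ``radius`` mm — the area-coverage oracle used in scan-merging checks."""
    if len(cloud) == 0:
        return 0.0
    tree = cKDTree(cloud.positions)
    d, _ = tree.query(reference)
    return float(np.mean(d <= radius))


# ---------------------------------------------------------------------------
# surface variation (covariance eigenanalysis)
# ---------------------------------------------------------------------------

def surface_variation(cloud: PointCloud, radius: float = 2.0) -> CurvatureField:
    """Surface-variation curvature over spherical neighbourhoods.

    For each point, the covariance of its neighbours about their centroid
    is eigen-decomposed (lambda0 <= lambda1 <= lambda2);
    delta_n = lambda0 / (lambda0 + lambda1 + lambda2) and the normal
    estimate is v0.  The 2 mm default radius suits dental scans at
    ~0.1 mm sampling.  Points with fewer than 3 neighbours (themselves
    included) are flagged undefined.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    P = cloud.positions
    n = len(P)
    tree = cKDTree(P)
    neighbor_lists = tree.query_ball_point(P, radius)
    delta = np.full(n, np.nan)
    normals = np.zeros((n, 3))
    evals_out = np.full((n, 3), np.nan)
    defined = np.zeros(n, dtype=bool)
    for i, nbrs in enumerate(neighbor_lists):
        if len(nbrs) < 3:
            continue
        Q = P[nbrs]
        centered = Q - Q.mean(axis=0)
        C = centered.T @ centered
        evals, evecs = np.linalg.eigh(C)   # ascending
        evals = np.clip(evals, 0.0, None)  # C is PSD; clip rounding noise
        total = evals.sum()
        delta[i] = 0.0 if total <= 0 else evals[0] / total
        normals[i] = evecs[:, 0]
        evals_out[i] = evals
        defined[i] = True
    return CurvatureField(delta_n=delta, normals=normals, defined=defined,
                          radius=radius, eigenvalues=evals_out)


# ---------------------------------------------------------------------------
# margin lines & crown segmentation
# ---------------------------------------------------------------------------

def fit_margin_spline(seed_points, tooth_id: str = "") -> MarginLine:
    """Closed periodic cubic spline through ordered margin seed points.

    Chord-length parameterization; requires >= 4 non-collinear seeds whose
    loop does not self-intersect when projected onto its best-fit plane.
    """
    seeds = np.asarray(seed_points, dtype=float).reshape(-1, 3)
    if len(seeds) < 4:
        raise InputError("at least 4 seed points are required")
    evals = np.linalg.eigvalsh(np.cov(seeds.T))
    if evals[1] < 1e-10 * max(evals[2], 1e-12):
        raise InputError("seed points are collinear")
    if _projected_loop_self_intersects(seeds):
        raise InputError("seed loop self-intersects in its best-fit plane")
    closed = np.vstack([seeds, seeds[:1]])
    chords = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    knots = np.concatenate([[0.0], np.cumsum(chords)])
    splines = tuple(CubicSpline(knots, closed[:, c], bc_type="periodic")
                    for c in range(3))
    return MarginLine(tooth_id=tooth_id, seeds=seeds, _splines=splines, knots=knots)


def _projected_loop_self_intersects(seeds: np.ndarray) -> bool:
    from shapely.geometry import LinearRing
    centered = seeds - seeds.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    uv = centered @ Vt[:2].T
    try:
        return not LinearRing(uv).is_simple
    except Exception:
        return True


def segment_crowns(mesh: trimesh.Trimesh, curvature: CurvatureField,
                   margins: list[MarginLine],
                   snap_band: float = 1.0) -> SegmentedMouthModel:
    """Partition the mouth mesh into per-tooth crowns and gingiva.

    Each margin spline is projected onto the mesh and snapped to the
    locally maximal-delta_n vertices within ``snap_band`` mm (the crown /
    gingiva crease is a curvature ridge).  The crown region is grown from
    an interior seed above the margin loop, bounded by the snapped ring;
    everything else is gingiva.
    """
    V = mesh.vertices
    tree = cKDTree(V)
    adjacency = _vertex_adjacency(mesh)
    assignment = np.full(len(V), "", dtype=object)
    edge_len = float(np.median(mesh.edges_unique_length))
    delta = np.nan_to_num(curvature.delta_n, nan=0.0)

    from shapely import contains_xy
    from shapely.geometry import Polygon

    # pass 1: per-margin membership of every vertex in the (buffered)
    # margin polygon, so contested vertices between close neighbours can
    # be resolved to the nearest loop before any region grows
    inside_all = np.zeros((len(margins), len(V)), dtype=bool)
    loop_trees = []
    frames = []
    for mi, margin in enumerate(margins):
        samples = margin.sample(max(200, 8 * len(margin.seeds)))
        d_proj, _ = tree.query(samples)
        if np.min(d_proj) > snap_band:
            raise SegmentationError(
                f"margin of tooth {margin.tooth_id} does not project onto the mesh")
        centroid = samples.mean(axis=0)
        normal = _loop_normal(samples)
        if np.dot(normal, centroid - V.mean(axis=0)) < 0:
            normal = -normal  # normal points toward the crown side
        u = np.zeros(3)
        u[np.argmin(np.abs(normal))] = 1.0
        u = np.cross(normal, u)
        u /= np.linalg.norm(u)
        w = np.cross(normal, u)
        loop2d = Polygon((samples - centroid) @ np.column_stack([u, w]))
        # a small buffer keeps the near-vertical crown wall just below the
        # ring inside the region; the crease itself is recovered by the
        # ridge-snapping pass
        loop2d = loop2d.buffer(1.0 * edge_len)
        vert2d = (V - centroid) @ np.column_stack([u, w])
        inside2d = contains_xy(loop2d, vert2d[:, 0], vert2d[:, 1])
        height = (V - centroid) @ normal
        inside_all[mi] = inside2d & (height > -3.0 * edge_len)
        loop_trees.append(cKDTree(samples))
        frames.append((samples, centroid, normal))
    contested = inside_all.sum(axis=0) > 1
    if np.any(contested):
        idx = np.nonzero(contested)[0]
        d_loops = np.stack([lt.query(V[idx])[0] for lt in loop_trees])
        nearest = np.argmin(d_loops, axis=0)
        for mi in range(len(margins)):
            inside_all[mi, idx] = nearest == mi

    for mi, margin in enumerate(margins):
        samples, centroid, normal = frames[mi]
        allowed = inside_all[mi]
        seed = int(tree.query(centroid + 2.0 * normal)[1])
        if not allowed[seed]:
            cand = np.nonzero(allowed)[0]
            if len(cand) == 0:
                raise SegmentationError(
                    f"margin of tooth {margin.tooth_id} encloses no vertices")
            seed = int(cand[np.argmin(np.linalg.norm(
                V[cand] - (centroid + 2.0 * normal), axis=1))])
        blocked = set(np.nonzero(~allowed)[0].tolist())
        region = _flood(adjacency, seed, blocked)
        if not region:
            raise SegmentationError(
                f"margin of tooth {margin.tooth_id} encloses no vertices")
        if len(region) > 0.6 * len(V):
            raise SegmentationError(
                f"margin of tooth {margin.tooth_id} is not closable on the mesh")
        # snap outward onto the curvature ridge: absorb immediate
        # neighbours sitting in the crease right at the loop
        near_loop = np.zeros(len(V), dtype=bool)
        for s in samples:
            near_loop[tree.query_ball_point(s, 0.4 * snap_band)] = True
        ridge_floor = float(np.nanpercentile(delta[near_loop], 70)) \
            if near_loop.any() else np.inf
        for v in list(region):
            for n in adjacency[v]:
                if (n not in region and near_loop[n] and assignment[n] == ""
                        and delta[n] >= ridge_floor):
                    region.add(n)
        for v in region:
            if assignment[v] == "":
                assignment[v] = margin.tooth_id
    return SegmentedMouthModel(mesh=mesh, assignment=assignment,
                               tooth_ids=[m.tooth_id for m in margins])


def _vertex_adjacency(mesh: trimesh.Trimesh) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(len(mesh.vertices))]
    for a, b in mesh.edges_unique:
        adj[a].append(int(b))
        adj[b].append(int(a))
    return adj


def _loop_normal(samples: np.ndarray) -> np.ndarray:
    centered = samples - samples.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    n = Vt[2]
    return n / np.linalg.norm(n)


def _flood(adjacency, seed: int, blocked: set) -> set:
    region = {seed}
    frontier = [seed]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adjacency[v]:
                if w not in region and w not in blocked:
                    region.add(w)
                    nxt.append(w)
        frontier = nxt
    return region
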