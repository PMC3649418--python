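"""Multi-body orthodontic model assembly.

Fuses each optically scanned crown with its CBCT-segmented root into a
single tooth body (the optical crown geometry is kept verbatim — it is the
more accurate sensor for enamel surfaces — and the CBCT mesh contributes
only the root below the margin), sockets the alveolar bone by per-slice
tooth subtraction, and exposes per-tooth rigid manipulation with a
collision report, so treatment motions can be simulated body by body.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
import trimesh

from .core import RigidTransform
from .errors import FrameError, FusionError, LookupError_

__all__ = ["ToothModel", "MultiBodyModel", "fuse_crown_root",
           "build_orthodontic_model", "transform_tooth", "export_model",
           "import_model"]

PROV_OPTICAL = "optical"
PROV_CBCT = "cbct"
PROV_SEAM = "seam"


@dataclass
class ToothModel:
    """One tooth: optical crown, CBCT root, fused surface and a rigid pose.

    ``provenance`` tags every fused face as optical, cbct or seam; the
    fused mesh contains every crown vertex unmodified and is a single
    edge-connected surface.
    """

    tooth_id: str
    crown_mesh: trimesh.Trimesh
    root_mesh: trimesh.Trimesh
    fused_mesh: trimesh.Trimesh
    provenance: np.ndarray
    pose: RigidTransform = field(default_factory=RigidTransform.identity)

    def posed_vertices(self) -> np.ndarray:
        return self.pose.apply(self.fused_mesh.vertices)

    def posed_mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.posed_vertices(),
                               faces=self.fused_mesh.faces, process=False)


@dataclass
class MultiBodyModel:
    """Teeth + gingiva + socketed bone, each an independent body.

    All bodies live in the common (CBCT) frame; ``collisions`` holds the
    current pairwise interpenetration flags between posed teeth.
    """

    teeth: list[ToothModel]
    gingiva_mesh: trimesh.Trimesh | None
    bone_mesh: trimesh.Trimesh | None
    frame: dict = field(default_factory=lambda: {"frame": "cbct", "units": "mm"})
    collisions: list[tuple[str, str]] = field(default_factory=list)

    def tooth(self, tooth_id: str) -> ToothModel:
        for t in self.teeth:
            if t.tooth_id == tooth_id:
                return t
        raise LookupError_(f"unknown tooth id '{tooth_id}'")


# ---------------------------------------------------------------------------
# crown/root fusion
# ---------------------------------------------------------------------------

def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex-index loops of the mesh's open boundary."""
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary_edges = unique[counts == 1]
    if len(boundary_edges) == 0:
        return []
    adj: dict[int, list[int]] = {}
    for a, b in boundary_edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen: set[int] = set()
    loops = []
    for start in adj:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur, prev = start, -1
        while True:
            nbrs = [v for v in adj[cur] if v != prev]
            nxt = next((v for v in nbrs if v not in seen), None)
            if nxt is None:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=int))
    return loops


def _loop_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - center, full_matrices=False)
    n = Vt[2]
    return center, n / np.linalg.norm(n)


def _zipper(loop_a: np.ndarray, loop_b: np.ndarray, pts_a: np.ndarray,
            pts_b: np.ndarray, center: np.ndarray, normal: np.ndarray,
            offset_b: int) -> np.ndarray:
    """Triangulate the band between two roughly parallel rings by marching
    both loops in angle order around the seam axis."""
    u = np.zeros(3)
    u[np.argmin(np.abs(normal))] = 1.0
    u = np.cross(normal, u)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)

    def angles(P):
        d = P - center
        return np.arctan2(d @ v, d @ u)

    ord_a = loop_a[np.argsort(angles(pts_a[loop_a]))]
    ord_b = loop_b[np.argsort(angles(pts_b[loop_b]))]
    ang_a = np.sort(angles(pts_a[loop_a]))
    ang_b = np.sort(angles(pts_b[loop_b]))
    faces = []
    i = j = 0
    na, nb = len(ord_a), len(ord_b)
    # advance whichever ring's next angle is smaller, forming a triangle fan
    while i < na or j < nb:
        a0 = ord_a[i % na]
        b0 = ord_b[j % nb] + offset_b
        next_a = ang_a[(i + 1) % na] + (2 * np.pi if i + 1 >= na else 0)
        next_b = ang_b[(j + 1) % nb] + (2 * np.pi if j + 1 >= nb else 0)
        if (i < na and next_a <= next_b) or j >= nb:
            a1 = ord_a[(i + 1) % na]
            faces.append([a0, a1, b0])
            i += 1
        else:
            b1 = ord_b[(j + 1) % nb] + offset_b
            faces.append([a0, b1, b0])
            j += 1
    faces = np.asarray(faces, dtype=int)
    # orient the band radially outward so face normals agree with the
    # closed bodies on either side
    all_pts = np.vstack([pts_a, pts_b])
    tri = all_pts[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    cen = tri.mean(axis=1)
    radial = cen - center
    radial -= np.outer(radial @ normal, normal)
    flip = np.einsum("ij,ij->i", fn, radial) < 0
    faces[flip] = faces[flip][:, ::-1]
    return faces


def fuse_crown_root(crown_mesh: trimesh.Trimesh, root_stack_mesh: trimesh.Trimesh,
                    seam_band: float = 0.5, tooth_id: str = "") -> ToothModel:
    """Fuse the optical crown with the CBCT tooth mesh.

    The CBCT mesh region lying on the crown side of the crown's margin
    plane (where the two sensors double each other) is discarded; the
    remaining root surface is stitched to the crown's open margin loop
    across ``seam_band``.  Every crown vertex appears verbatim in the
    fused mesh.  Disjoint inputs raise :class:`FusionError`.
    """
    loops = _boundary_loops(crown_mesh)
    if not loops:
        raise FusionError("crown mesh has no open margin boundary to stitch")
    margin = max(loops, key=lambda l: len(l))
    ring_pts = crown_mesh.vertices[margin]
    center, normal = _loop_plane(ring_pts)
    crown_side = crown_mesh.vertices.mean(axis=0) - center
    if np.dot(normal, crown_side) < 0:
        normal = -normal  # normal points into the crown occupancy

    root_d = cKDTree(root_stack_mesh.vertices).query(ring_pts)[0]
    if root_d.min() > max(10.0, 20 * seam_band):
        raise FusionError("crown and root meshes do not overlap "
                          "(misalignment suspected)")
    centroids = root_stack_mesh.triangles_center
    signed = (centroids - center) @ normal
    keep_faces = signed <= 0.0  # root side of the margin plane
    if keep_faces.all() or not keep_faces.any():
        raise FusionError("no crown/root overlap band found")
    trimmed = root_stack_mesh.submesh([np.nonzero(keep_faces)[0]], append=True)
    comps = trimmed.split(only_watertight=False)
    if len(comps) > 1:
        trimmed = max(comps, key=lambda m: len(m.faces))
    root_loops = _boundary_loops(trimmed)
    if not root_loops:
        raise FusionError("trimmed root has no boundary loop to stitch")
    # stitch to the root loop closest to the margin plane
    root_ring = min(root_loops, key=lambda l: abs(np.mean(
        (trimmed.vertices[l] - center) @ normal)))

    n_crown_v = len(crown_mesh.vertices)
    vertices = np.vstack([crown_mesh.vertices, trimmed.vertices])
    seam_faces = _zipper(margin, root_ring, crown_mesh.vertices,
                         trimmed.vertices, center, normal, offset_b=n_crown_v)
    faces = np.vstack([crown_mesh.faces, trimmed.faces + n_crown_v, seam_faces])
    provenance = np.concatenate([
        np.full(len(crown_mesh.faces), PROV_OPTICAL, dtype=object),
        np.full(len(trimmed.faces), PROV_CBCT, dtype=object),
        np.full(len(seam_faces), PROV_SEAM, dtype=object)])
    fused = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    return ToothModel(tooth_id=tooth_id, crown_mesh=crown_mesh,
                      root_mesh=root_stack_mesh, fused_mesh=fused,
                      provenance=provenance)


# ---------------------------------------------------------------------------
# scene assembly and manipulation
# ---------------------------------------------------------------------------

def build_orthodontic_model(teeth: list[ToothModel],
                            gingiva: trimesh.Trimesh | None = None,
                            bone_mesh: trimesh.Trimesh | None = None,
                            frame: dict | None = None) -> MultiBodyModel:
    """Assemble independent bodies into one scene (common CBCT frame).

    ``frame`` metadata must agree across callers composing scenes; a
    mismatch raises :class:`FrameError`.
    """
    frame = frame or {"frame": "cbct", "units": "mm"}
    if frame.get("units", "mm") != "mm":
        raise FrameError("all bodies must be expressed in mm")
    model = MultiBodyModel(teeth=list(teeth), gingiva_mesh=gingiva,
                           bone_mesh=bone_mesh, frame=dict(frame))
    model.collisions = _collision_report(model)
    return model


def _collision_report(model: MultiBodyModel, n_samples: int = 300) -> list:
    """Pairwise interpenetration flags between posed teeth (sampled
    containment, not exact booleans)."""
    flags = []
    posed = [(t.tooth_id, t.posed_mesh()) for t in model.teeth]
    for i in range(len(posed)):
        for j in range(i + 1, len(posed)):
            id_a, mesh_a = posed[i]
            id_b, mesh_b = posed[j]
            if not _boxes_touch(mesh_a.bounds, mesh_b.bounds):
                continue
            if _penetrates(mesh_a, mesh_b, n_samples) or \
               _penetrates(mesh_b, mesh_a, n_samples):
                flags.append((id_a, id_b))
    return flags


def _boxes_touch(ba: np.ndarray, bb: np.ndarray) -> bool:
    return bool(np.all(ba[0] <= bb[1]) and np.all(bb[0] <= ba[1]))


def _penetrates(inner: trimesh.Trimesh, outer: trimesh.Trimesh,
                n_samples: int, depth_tol: float = 0.3) -> bool:
    """Sampled signed-distance interpenetration: a sampled vertex of
    ``inner`` lying more than ``depth_tol`` mm behind the closest face of
    ``outer`` flags the pair.  The tolerance is set at the mesh-resolution
    scale so crease-contact between neighbouring teeth does not flag."""
    from .surface_model import point_to_surface_distance
    verts = inner.vertices
    if len(verts) > n_samples:
        step = len(verts) // n_samples
        verts = verts[::step]
    dist, faces = point_to_surface_distance(outer, verts, return_faces=True)
    normals = outer.face_normals[faces]
    centers = outer.triangles_center[faces]
    signed_side = np.einsum("ij,ij->i", verts - centers, normals)
    # trust the face-normal side only where the face actually faces the
    # point (closest point in the face interior, not an edge or rim)
    facing = np.abs(signed_side) > 0.8 * dist
    return bool(np.any(facing & (signed_side < 0) & (dist > depth_tol)))


def transform_tooth(model: MultiBodyModel, tooth_id: str,
                    T: RigidTransform) -> MultiBodyModel:
    """Compose ``T`` onto one tooth's pose; every other body is untouched
    (bit-identical) and the collision report is refreshed."""
    target = model.tooth(tooth_id)  # raises LookupError_ when unknown
    new_teeth = [replace(t, pose=T.compose(t.pose)) if t is target else t
                 for t in model.teeth]
    new = MultiBodyModel(teeth=new_teeth, gingiva_mesh=model.gingiva_mesh,
                         bone_mesh=model.bone_mesh, frame=dict(model.frame))
    new.collisions = _collision_report(new)
    return new


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_model(model: MultiBodyModel, directory) -> dict:
    """Write one STL per body plus a JSON manifest (ids, poses, provenance
    counts, units).  Returns the manifest dict."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {directory}: {e}")
    manifest = {"units": "mm", "frame": model.frame, "bodies": []}
    for t in model.teeth:
        fname = f"tooth_{t.tooth_id}.stl"
        t.fused_mesh.export(directory / fname)
        prov, counts = np.unique(t.provenance.astype(str), return_counts=True)
        manifest["bodies"].append({
            "kind": "tooth", "tooth_id": t.tooth_id, "file": fname,
            "pose": t.pose.matrix().tolist(),
            "provenance_faces": dict(zip(prov.tolist(),
                                         [int(c) for c in counts])),
        })
    for name, mesh in (("gingiva", model.gingiva_mesh),
                       ("bone", model.bone_mesh)):
        if mesh is None:
            continue
        fname = f"{name}.stl"
        mesh.export(directory / fname)
        manifest["bodies"].append({"kind": name, "file": fname,
                                   "pose": np.eye(4).tolist()})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def import_model(directory) -> MultiBodyModel:
    """Rebuild a MultiBodyModel from an exported directory."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    teeth = []
    gingiva = bone = None
    for body in manifest["bodies"]:
        mesh = trimesh.load(directory / body["file"], process=True)
        if body["kind"] == "tooth":
            teeth.append(ToothModel(
                tooth_id=body["tooth_id"], crown_mesh=mesh, root_mesh=mesh,
                fused_mesh=mesh,
                provenance=np.full(len(mesh.faces), PROV_OPTICAL, dtype=object),
                pose=RigidTransform.from_matrix(np.asarray(body["pose"]))))
        elif body["kind"] == "gingiva":
            gingiva = mesh
        elif body["kind"] == "bone":
            bone = mesh
    return build_orthodontic_model(teeth, gingiva, bone,
                                   frame=manifest.get("frame"))
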