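"""Synthetic dental phantoms.

Deterministic, seeded generators for every fixture the pipeline consumes:
parametric teeth (superellipsoid crown blended to tapered roots) placed on
an arch, a gingiva collar, an alveolar-bone envelope, CBCT-like voxel
volumes with tissue-specific intensities, and complementary partial surface
scans (impression mode keeps interproximal walls, cast mode keeps cusp
tops).

Geometry is analytic: each tooth exposes vectorized inside/outside
membership functions, so segmentation results can be scored against exact
cross-sections and volumes.  All world coordinates are mm; the tooth local
frame has z up with the crown/gingiva margin at z = 0, the crown occupying
z in (0, crown_height] and the roots z in [-root_length, 0].
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure
import trimesh

from .core import PointCloud, RigidTransform, VoxelVolume
from .errors import ParameterError, PlacementError

__all__ = [
    "ToothPhantomSpec", "ArchParameters", "IntensityModel", "PlacedTooth",
    "JawPhantom", "make_jaw_phantom", "voxelize_phantom",
    "simulate_surface_scan", "write_dicom_series", "write_raw_volume",
    "load_raw_volume", "default_arch_specs",
]

# tissue label codes used by voxelize_phantom
LABEL_BACKGROUND = 0
LABEL_SOFT_TISSUE = 1
LABEL_BONE = 2
LABEL_TOOTH = 3

_CROWN_EXPONENT = 4.0     # superellipse exponent (boxy molar-like section)
_CROWN_TIP_POWER = 3.0    # vertical profile power (bulge then rounded tip)


def _valid_iso3950(tooth_id: str) -> bool:
    """FDI / ISO 3950 two-digit code: quadrant 1-8, position 1-8
    (quadrants 5-8 are the deciduous dentition, positions 1-5)."""
    if not (isinstance(tooth_id, str) and len(tooth_id) == 2 and tooth_id.isdigit()):
        return False
    q, p = int(tooth_id[0]), int(tooth_id[1])
    if q in (1, 2, 3, 4):
        return 1 <= p <= 8
    if q in (5, 6, 7, 8):
        return 1 <= p <= 5
    return False


@dataclass
class ToothPhantomSpec:
    """Parameters of one synthetic tooth.

    crown_radii are the superellipsoid semi-axes (radial, tangential) in mm;
    root_taper is the tip/base radius ratio in (0, 1).
    """

    tooth_id: str
    crown_height: float = 8.0
    crown_radii: tuple[float, float] = (4.0, 3.5)
    root_count: int = 1
    root_length: float = 12.0
    root_taper: float = 0.35
    pose: RigidTransform | None = None

    def __post_init__(self):
        if not _valid_iso3950(self.tooth_id):
            raise ParameterError(f"'{self.tooth_id}' is not a valid ISO 3950 code")
        if self.root_count not in (1, 2, 3):
            raise ParameterError("root_count must be 1, 2 or 3")
        if min(self.crown_height, self.root_length, *self.crown_radii) <= 0:
            raise ParameterError("all lengths must be positive")
        if not 0 < self.root_taper < 1:
            raise ParameterError("root_taper must lie in (0, 1)")


@dataclass
class ArchParameters:
    """Circular dental-arch layout: teeth centres on a radius-mm circle,
    separated along the arc by interproximal_gap mm of clear space."""

    radius: float = 24.0
    interproximal_gap: float = 0.5
    start_angle_deg: float = 90.0  # first tooth at the front of the arch

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError("arch radius must be positive")
        if self.interproximal_gap < 0:
            raise ParameterError("interproximal gap must be non-negative")


@dataclass
class IntensityModel:
    """HU-like tissue intensities for voxelization.

    Ordering hu_tooth > hu_bone > hu_soft_tissue > hu_background is
    enforced; streak_amplitude > 0 adds high-intensity rays through a
    designated metal voxel, emulating restoration artifacts.
    """

    hu_background: float = -1000.0
    hu_soft_tissue: float = 50.0
    hu_bone: float = 700.0
    hu_tooth: float = 1500.0
    noise_sd: float = 0.0
    streak_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.hu_tooth > self.hu_bone > self.hu_soft_tissue > self.hu_background):
            raise ParameterError("tissue intensities must be strictly ordered")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


class PlacedTooth:
    """A tooth spec with its rigid pose and analytic membership functions."""

    def __init__(self, spec: ToothPhantomSpec, pose: RigidTransform):
        self.spec = spec
        self.pose = pose
        self._inv = pose.inverse()
        a, b = spec.crown_radii
        # root layout in the local frame: base centres and branch radius.
        # The root trunk at the cemento-enamel junction carries the crown's
        # cervical cross-section (no abrupt step, as in real anatomy);
        # multi-root teeth split below the furcation depth.
        if spec.root_count == 1:
            self._root_offsets = np.array([[0.0, 0.0]])
            self._root_base_r = 0.92 * min(a, b)
        elif spec.root_count == 2:
            self._root_offsets = np.array([[-0.45 * a, 0.0], [0.45 * a, 0.0]])
            self._root_base_r = 0.45 * min(a, b)
        else:
            self._root_offsets = np.array(
                [[0.5 * a, 0.0], [-0.4 * a, 0.45 * b], [-0.4 * a, -0.45 * b]])
            self._root_base_r = 0.40 * min(a, b)
        self._trunk_base_r = 0.92 * min(a, b)
        self._furcation_depth = 0.35 * spec.root_length

    @property
    def tooth_id(self) -> str:
        return self.spec.tooth_id

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return self._inv.apply(points)

    # -- analytic membership -------------------------------------------------
    def crown_contains_local(self, local: np.ndarray) -> np.ndarray:
        a, b = self.spec.crown_radii
        h = self.spec.crown_height
        x, y, z = local[:, 0], local[:, 1], local[:, 2]
        with np.errstate(invalid="ignore"):
            prof = 1.0 - np.clip(z / h, 0.0, 1.0) ** _CROWN_TIP_POWER
        se = (np.abs(x) / a) ** _CROWN_EXPONENT + (np.abs(y) / b) ** _CROWN_EXPONENT
        return (z >= 0) & (z <= h) & (se <= prof)

    def root_contains_local(self, local: np.ndarray, inflate: float = 0.0
                            ) -> np.ndarray:
        L = self.spec.root_length + inflate
        z = local[:, 2]
        depth = -z
        inside = np.zeros(len(local), dtype=bool)
        in_band = (depth >= 0) & (depth <= L)
        frac = np.clip(depth / L, 0, 1)
        r = inflate + self._root_base_r * (1.0 + (self.spec.root_taper - 1.0) * frac)
        # branch centres slide outward from the axis down to the furcation
        spread = np.clip(depth / self._furcation_depth, 0.0, 1.0)
        for off in self._root_offsets:
            cx = off[0] * spread
            cy = off[1] * spread
            d2 = (local[:, 0] - cx) ** 2 + (local[:, 1] - cy) ** 2
            inside |= in_band & (d2 <= r ** 2)
        if self.spec.root_count > 1:
            # root trunk above the furcation carries the cervical width
            r_t = inflate + self._trunk_base_r * (
                1.0 - 0.25 * np.clip(depth / self._furcation_depth, 0, 1))
            d2 = local[:, 0] ** 2 + local[:, 1] ** 2
            inside |= in_band & (depth <= self._furcation_depth) & (d2 <= r_t ** 2)
        return inside

    def crown_contains(self, points: np.ndarray) -> np.ndarray:
        return self.crown_contains_local(self.to_local(points))

    def socket_collar_contains(self, points: np.ndarray, width: float,
                               depth: float = 1.5) -> np.ndarray:
        """Cervical part of the alveolar socket: a collar matching the
        crown footprint (inflated by ``width``) over the top ``depth`` mm
        below the cemento-enamel junction."""
        local = self.to_local(points)
        a, b = self.spec.crown_radii
        z = local[:, 2]
        se = ((np.abs(local[:, 0]) / (a + width)) ** _CROWN_EXPONENT
              + (np.abs(local[:, 1]) / (b + width)) ** _CROWN_EXPONENT)
        return (z <= 0) & (z >= -depth) & (se <= 1.0)

    def root_contains(self, points: np.ndarray, inflate: float = 0.0
                      ) -> np.ndarray:
        return self.root_contains_local(self.to_local(points), inflate=inflate)

    def contains(self, points: np.ndarray) -> np.ndarray:
        local = self.to_local(points)
        return self.crown_contains_local(local) | self.root_contains_local(local)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.spec.crown_radii
        m = max(a, b, self._root_base_r + max(np.abs(self._root_offsets).max(), 0))
        lo_l = np.array([-m, -m, -self.spec.root_length])
        hi_l = np.array([m, m, self.spec.crown_height])
        corners = np.array([[x, y, z] for x in (lo_l[0], hi_l[0])
                            for y in (lo_l[1], hi_l[1]) for z in (lo_l[2], hi_l[2])])
        w = self.pose.apply(corners)
        return w.min(axis=0), w.max(axis=0)

    def volume_mm3(self, pitch: float = 0.1) -> float:
        """Numerical tooth volume from the membership function (oracle)."""
        lo, hi = self.bounding_box()
        axes = [np.arange(lo[i] + pitch / 2, hi[i] + pitch / 2, pitch) for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        return float(np.count_nonzero(self.contains(pts)) * pitch ** 3)

    def cross_section_mask(self, z_world: float, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Exact in-plane membership raster at a world-z slice (oracle)."""
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z_world)])
        return self.contains(pts).reshape(X.shape)

    def crown_mesh(self, pitch: float = 0.2) -> trimesh.Trimesh:
        """Marching-cubes surface of the crown solid alone (closed mesh)."""
        lo, hi = self.bounding_box()
        lo = lo - pitch
        hi = hi + pitch
        axes = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        occ = self.crown_contains(pts).reshape(X.shape).astype(float)
        verts, faces, _, _ = measure.marching_cubes(occ, 0.5,
                                                    gradient_direction="ascent")
        return trimesh.Trimesh(vertices=verts * pitch + lo, faces=faces,
                               process=False)

    def margin_ring(self, z_local: float, n: int = 8) -> np.ndarray:
        """n world points on the crown surface ring at local height
        ``z_local`` — the phantom's stand-in for operator-picked margin
        seed points."""
        a, b = self.spec.crown_radii
        h = self.spec.crown_height
        e = _CROWN_EXPONENT
        prof = 1.0 - np.clip(z_local / h, 0.0, 1.0) ** _CROWN_TIP_POWER
        u = prof ** (1.0 / e)
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        c, s = np.cos(th), np.sin(th)
        x = a * u * np.sign(c) * np.abs(c) ** (2.0 / e)
        y = b * u * np.sign(s) * np.abs(s) ** (2.0 / e)
        local = np.column_stack([x, y, np.full(n, z_local)])
        return self.pose.apply(local)


@dataclass
class JawPhantom:
    """Teeth on an arch plus analytic gingiva and bone regions.

    The gingiva is a collar following the arch (soft tissue from
    gingiva_bottom up to gingiva_top); alveolar bone fills the slab below
    z = 0 within bone_halfwidth of the arch curve, so every root lies in
    bone and every crown (z > 0) lies outside it.
    """

    teeth: list[PlacedTooth]
    arch: ArchParameters
    gingiva_top: float = 1.0
    gingiva_bottom: float = -6.0
    gingiva_halfwidth: float = 6.0
    bone_top: float = 0.0
    bone_bottom: float = -18.0
    bone_halfwidth: float = 9.0
    # periodontal-ligament gap between root and socket wall: radiolucent in
    # CBCT, it is what makes the root/bone boundary detectable.  Wider than
    # anatomical (0.15-0.4 mm) because the gap must span >= 2-3 voxels at
    # the 0.4 mm CBCT resolution to survive partial-volume blurring.
    pdl_width: float = 1.2
    # angular sector of the arch actually occupied (radians); keeps the
    # soft-tissue/bone slabs local to the modelled quadrant
    arch_sector: tuple[float, float] | None = None
    _mesh_cache: dict = field(default_factory=dict, repr=False)

    # -- analytic regions ----------------------------------------------------
    def _arch_distance_xy(self, points: np.ndarray) -> np.ndarray:
        r = np.hypot(points[:, 0], points[:, 1])
        return np.abs(r - self.arch.radius)

    def _in_sector(self, points: np.ndarray) -> np.ndarray:
        if self.arch_sector is None:
            return np.ones(points.shape[0], dtype=bool)
        lo, hi = self.arch_sector
        th = np.arctan2(points[:, 1], points[:, 0])
        # normalize into a window starting at lo
        th = lo + np.mod(th - lo, 2 * np.pi)
        return th <= hi

    def gingiva_contains(self, points: np.ndarray) -> np.ndarray:
        z = points[:, 2]
        return ((self._arch_distance_xy(points) <= self.gingiva_halfwidth)
                & (z >= self.gingiva_bottom) & (z <= self.gingiva_top)
                & self._in_sector(points))

    def bone_contains(self, points: np.ndarray) -> np.ndarray:
        z = points[:, 2]
        return ((self._arch_distance_xy(points) <= self.bone_halfwidth)
                & (z >= self.bone_bottom) & (z <= self.bone_top)
                & self._in_sector(points))

    def tooth_index(self, points: np.ndarray) -> np.ndarray:
        """Index of the containing tooth per point, -1 where none."""
        idx = np.full(points.shape[0], -1, dtype=int)
        for i, t in enumerate(self.teeth):
            m = t.contains(points)
            idx[m & (idx < 0)] = i
        return idx

    def tissue_label(self, points: np.ndarray) -> np.ndarray:
        """Priority tooth > periodontal gap > bone > soft tissue > background."""
        lab = np.full(points.shape[0], LABEL_BACKGROUND, dtype=np.int8)
        lab[self.gingiva_contains(points)] = LABEL_SOFT_TISSUE
        bone = self.bone_contains(points)
        lab[bone] = LABEL_BONE
        for t in self.teeth:
            # periodontal-ligament gap inside the socket; the socket rim
            # follows the tooth cervix, so the crown never abuts bone
            pdl = (t.root_contains(points, inflate=self.pdl_width)
                   | t.socket_collar_contains(points, self.pdl_width)) & bone
            lab[pdl] = LABEL_SOFT_TISSUE
        for t in self.teeth:
            lab[t.contains(points)] = LABEL_TOOTH
        return lab

    def bounding_box(self, margin: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*(t.bounding_box() for t in self.teeth))
        lo = np.min(los, axis=0)
        hi = np.max(his, axis=0)
        lo = np.minimum(lo, [lo[0], lo[1], self.bone_bottom])
        return lo - margin, hi + margin

    # -- visible (optical) surface ------------------------------------------
    def mouth_occupancy(self, points: np.ndarray) -> np.ndarray:
        """The optically visible solid: gingiva collar plus crowns."""
        occ = self.gingiva_contains(points)
        for t in self.teeth:
            occ |= t.crown_contains(points)
        return occ

    def mouth_mesh(self, pitch: float = 0.3) -> trimesh.Trimesh:
        """Marching-cubes surface of the visible solid with per-vertex
        ground-truth labels in ``mesh.vertex_attributes``:
        ``tooth_index`` (-1 for gingiva)."""
        key = ("mouth", pitch)
        if key in self._mesh_cache:
            return self._mesh_cache[key]
        lo, hi = self.bounding_box()
        lo = lo.copy()
        lo[2] = self.gingiva_bottom - 1.0
        axes = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        occ = self.mouth_occupancy(pts).reshape(X.shape).astype(float)
        verts, faces, _, _ = measure.marching_cubes(occ, 0.5,
                                                    gradient_direction="ascent")
        verts = verts * pitch + lo
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        mesh.vertex_attributes["tooth_index"] = self.label_surface_points(verts)
        self._mesh_cache[key] = mesh
        return mesh

    def label_surface_points(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth label for points on/near the visible surface:
        tooth index where the point sits on an exposed crown (above the
        gingiva top), else -1 (gingiva)."""
        idx = np.full(points.shape[0], -1, dtype=int)
        exposed = points[:, 2] > self.gingiva_top - 0.15
        for i, t in enumerate(self.teeth):
            local = t.to_local(points)
            a, b = t.spec.crown_radii
            # within a shell of the crown implicit surface
            near = (np.abs(local[:, 0]) <= a + 0.6) & (np.abs(local[:, 1]) <= b + 0.6) \
                & (local[:, 2] >= -0.6) & (local[:, 2] <= t.spec.crown_height + 0.6)
            idx[near & exposed & (idx < 0)] = i
        return idx


def default_arch_specs(n_teeth: int = 4) -> list[ToothPhantomSpec]:
    """A small mixed arch: incisor-like single roots and molar-like
    two-root teeth, ids from the upper-right quadrant."""
    ids = ["11", "12", "13", "14", "15", "16", "17", "18"]
    specs = []
    for i in range(n_teeth):
        two_root = i % 3 == 2
        specs.append(ToothPhantomSpec(
            tooth_id=ids[i % len(ids)],
            crown_height=8.0,
            crown_radii=(5.0, 4.2) if two_root else (3.6, 3.0),
            root_count=2 if two_root else 1,
            root_length=12.0,
            root_taper=0.5 if two_root else 0.35,
        ))
    return specs


def make_jaw_phantom(specs: list[ToothPhantomSpec],
                     arch_parameters: ArchParameters | None = None) -> JawPhantom:
    """Place tooth specs along the arch and assemble the jaw phantom.

    Specs without a pose are laid out consecutively along the arch circle
    with the configured interproximal gap; supplied poses are honoured.
    Raises :class:`PlacementError` naming the first colliding pair.
    """
    if not specs:
        raise ParameterError("at least one tooth spec is required")
    arch = arch_parameters or ArchParameters()
    placed: list[PlacedTooth] = []
    theta = np.deg2rad(arch.start_angle_deg)
    for i, spec in enumerate(specs):
        if spec.pose is not None:
            pose = spec.pose
        else:
            half_w = spec.crown_radii[1]
            if i > 0 and specs[i - 1].pose is None:
                prev_w = specs[i - 1].crown_radii[1]
                theta -= (prev_w + arch.interproximal_gap + half_w) / arch.radius
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            t = np.array([arch.radius * c, arch.radius * s, 0.0])
            pose = RigidTransform(R, t)
        placed.append(PlacedTooth(spec, pose))
    _check_no_overlap(placed)
    angles = [np.arctan2(t.pose.translation[1], t.pose.translation[0])
              for t in placed]
    pad = max(s.crown_radii[1] for s in specs) / arch.radius + np.deg2rad(6)
    sector = (min(angles) - pad, max(angles) + pad)
    if sector[1] - sector[0] >= 2 * np.pi - 1e-9:
        sector = None
    return JawPhantom(teeth=placed, arch=arch, arch_sector=sector)


def _check_no_overlap(teeth: list[PlacedTooth], pitch: float = 0.25) -> None:
    for i in range(len(teeth)):
        for j in range(i + 1, len(teeth)):
            lo_i, hi_i = teeth[i].bounding_box()
            lo_j, hi_j = teeth[j].bounding_box()
            lo = np.maximum(lo_i, lo_j)
            hi = np.minimum(hi_i, hi_j)
            if np.any(hi <= lo):
                continue
            axes = [np.arange(lo[k] + pitch / 2, hi[k], pitch) for k in range(3)]
            if any(len(a) == 0 for a in axes):
                continue
            X, Y, Z = np.meshgrid(*axes, indexing="ij")
            pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
            if np.any(teeth[i].contains(pts) & teeth[j].contains(pts)):
                raise PlacementError(teeth[i].tooth_id, teeth[j].tooth_id)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def voxelize_phantom(jaw: JawPhantom, spacing, intensity: IntensityModel,
                     margin: float = 2.0) -> tuple[VoxelVolume, np.ndarray]:
    """Rasterize the jaw into a CBCT-like volume.

    Returns ``(volume, labels)`` where labels is the ground-truth tissue
    grid (codes LABEL_*) on the same lattice.  Voxel intensity is the
    tissue HU at the voxel centre plus Gaussian noise; streak artifacts
    (if enabled) radiate from the first tooth's crown centre.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise ParameterError("spacing must be positive")
    lo, hi = jaw.bounding_box(margin=0.0)
    margin = np.broadcast_to(np.asarray(margin, dtype=float), (3,))
    lo = lo - margin
    hi = hi + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    axes = [lo[i] + np.arange(shape[i]) * spacing[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    labels = jaw.tissue_label(pts).reshape(tuple(shape))

    hu = np.array([intensity.hu_background, intensity.hu_soft_tissue,
                   intensity.hu_bone, intensity.hu_tooth])
    data = hu[labels]
    if intensity.streak_amplitude > 0:
        data = data + _streak_field(jaw, axes, intensity.streak_amplitude)
    if intensity.noise_sd > 0:
        rng = np.random.default_rng(intensity.seed)
        data = data + rng.normal(0.0, intensity.noise_sd, size=data.shape)
    vol = VoxelVolume(data, spacing, lo)
    return vol, labels


def _streak_field(jaw: JawPhantom, axes, amplitude: float, n_rays: int = 12) -> np.ndarray:
    """Additive high-intensity rays through a 'metal' point (the first
    tooth's mid-crown), amplitude decaying with distance — a crude stand-in
    for restoration streak artifacts."""
    metal = jaw.teeth[0].pose.apply(
        np.array([[0.0, 0.0, jaw.teeth[0].spec.crown_height * 0.5]]))[0]
    X, Y = np.meshgrid(axes[0], axes[1], indexing="ij")
    dx = X - metal[0]
    dy = Y - metal[1]
    dist = np.hypot(dx, dy)
    ang = np.arctan2(dy, dx)
    step = np.pi / (n_rays // 2)
    d_ang = np.abs(((ang + step / 2) % step) - step / 2)
    perp = dist * np.sin(d_ang)
    plane = amplitude * np.exp(-(perp ** 2) / (2 * 0.4 ** 2)) * np.exp(-dist / 25.0)
    z = np.asarray(axes[2])
    fall = np.exp(-np.abs(z - metal[2]) / 3.0)
    return plane[:, :, None] * fall[None, None, :]


# ---------------------------------------------------------------------------
# surface scanning
# ---------------------------------------------------------------------------

_TIP_BAND = 1.2        # mm below the cusp tip tagged "cusp_tip"
_PROX_HALF_ANGLE = 40  # degrees around the tangent direction tagged interproximal

FEATURE_NONE = 0
FEATURE_CUSP_TIP = 1
FEATURE_INTERPROXIMAL = 2


def _feature_tags(jaw: JawPhantom, points: np.ndarray, tooth_idx: np.ndarray) -> np.ndarray:
    tags = np.full(points.shape[0], FEATURE_NONE, dtype=np.int8)
    cos_lim = np.cos(np.deg2rad(_PROX_HALF_ANGLE))
    for i, t in enumerate(jaw.teeth):
        m = tooth_idx == i
        if not np.any(m):
            continue
        local = t.to_local(points[m])
        h = t.spec.crown_height
        tip = local[:, 2] > h - _TIP_BAND
        # interproximal walls face along the arch tangent (local ±y)
        horiz = np.hypot(local[:, 0], local[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_t = np.abs(local[:, 1]) / np.maximum(horiz, 1e-12)
        mid = (local[:, 2] > jaw.gingiva_top - 0.2) & (local[:, 2] < h - _TIP_BAND)
        prox = mid & (cos_t > cos_lim)
        sub = tags[m]
        sub[prox] = FEATURE_INTERPROXIMAL
        sub[tip] = FEATURE_CUSP_TIP
        tags[m] = sub
    return tags


def _sample_mesh_surface(mesh: trimesh.Trimesh, n_points: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted face sampling with barycentric jitter; returns points
    and their face normals."""
    areas = mesh.area_faces
    probs = areas / areas.sum()
    faces = rng.choice(len(areas), size=n_points, p=probs)
    tri = mesh.triangles[faces]
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    pts = (1 - r1)[:, None] * tri[:, 0] + (r1 * (1 - r2))[:, None] * tri[:, 1] \
        + (r1 * r2)[:, None] * tri[:, 2]
    return pts, mesh.face_normals[faces]


def simulate_surface_scan(jaw: JawPhantom, mode: str, view_count: int = 8,
                          noise_sd: float = 0.0, seed: int = 0,
                          point_spacing: float = 0.15,
                          mesh_pitch: float = 0.3,
                          ) -> tuple[list[PointCloud], list[RigidTransform]]:
    """Visibility-culled partial scans of the visible (crown + gingiva)
    surface from ``view_count`` turntable directions.

    ``mode='impression'`` emulates scanning the impression's inner surface:
    cusp-tip bands are unreachable and dropped.  ``mode='cast'`` emulates
    the plaster cast: interproximal wall bands are occluded and dropped.
    Views are returned in the common frame together with the true per-view
    rigid transforms (rotation about the turntable z axis).
    """
    if mode not in ("impression", "cast"):
        raise ParameterError(f"unknown scan mode '{mode}'")
    if view_count < 1:
        raise ParameterError("view_count must be >= 1")
    rng = np.random.default_rng(seed)
    mesh = jaw.mouth_mesh(pitch=mesh_pitch)
    n_total = max(int(mesh.area / point_spacing ** 2), 100)
    pts, nrm = _sample_mesh_surface(mesh, n_total, rng)
    tooth_idx = jaw.label_surface_points(pts)
    tags = _feature_tags(jaw, pts, tooth_idx)

    elev = np.deg2rad(35.0)  # looking down onto the occlusal surface
    clouds: list[PointCloud] = []
    transforms: list[RigidTransform] = []
    for v in range(view_count):
        az = 2 * np.pi * v / view_count
        direction = -np.array([np.cos(az) * np.cos(elev),
                               np.sin(az) * np.cos(elev),
                               np.sin(elev)])  # from camera toward scene
        visible = (nrm @ -direction) > 0.15
        keep = visible.copy()
        if mode == "impression":
            keep &= tags != FEATURE_CUSP_TIP
        else:
            keep &= tags != FEATURE_INTERPROXIMAL
        p = pts[keep]
        if noise_sd > 0:
            p = p + rng.normal(0.0, noise_sd, size=p.shape)
        clouds.append(PointCloud(
            p, nrm[keep],
            labels={"tooth_index": tooth_idx[keep], "feature": tags[keep],
                    "view": np.full(keep.sum(), v, dtype=int)}))
        transforms.append(RigidTransform.from_axis_angle(
            (0, 0, 1), np.degrees(az)))
    return clouds, transforms


# ---------------------------------------------------------------------------
# volume writers / readers
# ---------------------------------------------------------------------------

def write_dicom_series(volume: VoxelVolume, directory,
                       series_description: str = "synthetic CBCT phantom") -> list[Path]:
    """Write the volume as a single-frame-per-slice DICOM series with
    standard CT geometry tags (PixelSpacing, SliceThickness,
    ImagePositionPatient, RescaleIntercept/Slope)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid, CTImageStorage

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if volume.slice_axis != 2:
        raise ParameterError("DICOM writer expects slice axis 2 (z)")
    intercept = -1024.0
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    paths = []
    nz = volume.shape[2]
    for k in range(nz):
        img = volume.intensities[:, :, k].T  # rows = y, cols = x
        stored = np.clip(np.rint(img - intercept), 0, 65535).astype(np.uint16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesDescription = series_description
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = stored.shape
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[0])]
        ds.SliceThickness = float(volume.spacing[2])
        ds.ImagePositionPatient = [float(volume.origin[0]), float(volume.origin[1]),
                                   float(volume.origin[2] + k * volume.spacing[2])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = 1.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


def write_raw_volume(volume: VoxelVolume, stem) -> tuple[Path, Path]:
    """Write the volume as a .npy array plus a JSON metadata sidecar."""
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    meta = stem.with_suffix(".json")
    np.save(npy, volume.intensities)
    meta.write_text(json.dumps({
        "spacing_mm": volume.spacing.tolist(),
        "origin_mm": volume.origin.tolist(),
        "slice_axis": volume.slice_axis,
        "units": "HU",
    }, indent=2))
    return npy, meta


def load_raw_volume(stem) -> VoxelVolume:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return VoxelVolume(data, meta["spacing_mm"], meta["origin_mm"],
                       meta.get("slice_axis", 2))
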