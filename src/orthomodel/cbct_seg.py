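"""CBCT volume segmentation.

Two cooperating stages:

1. *Spatial referencing* — iso-surfaces are extracted from the volume at a
   sweep of Hounsfield thresholds; the optically scanned crown mesh is
   aligned to each (3-landmark Procrustes then ICP restricted to mating
   pairs within ``delta_eps`` = 1 mm) and the threshold minimizing the mean
   crown/iso-surface discrepancy is selected.

2. *Distance-regularized level-set evolution (DRLSE)* — each tooth is
   contoured slice by slice.  The level-set function phi (negative inside
   the contour, positive outside) evolves under the gradient flow of

       E(phi) = mu * R_p(phi) + lambda * int g delta(phi) |grad phi|
                + alpha * int g H(-phi),

   where g = 1 / (1 + |grad(G_sigma * I)|^2) is the edge indicator,
   R_p the double-well distance-regularization potential, delta / H the
   smoothed Dirac / Heaviside pair, and alpha a signed balloon weight
   (positive shrinks a contour initialized outside the target, negative
   expands one initialized inside).  The first slice is initialized from
   the aligned crown's cross-section dilated by a disk; each converged
   contour initializes the next slice, propagating through the root until
   the zero-level area vanishes.  Topological splits (single crown into
   several roots) are handled natively by the level set.

All level-set arithmetic is in pixel units on one slice grid; conversions
to mm use the volume's spacing and origin.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk
import trimesh

from .core import RigidTransform, VoxelVolume
from .errors import (AlignmentError, FormatError, InputError,
                     ManualInitRequired, ParameterError, PropagationError,
                     ReconstructionError, SweepError)
from .surface_model import (PointCloud, icp_register, kabsch,
                            point_to_surface_distance)

__all__ = [
    "VoxelVolume", "LevelSetField", "DrlseParams", "SliceContourStack",
    "ThresholdSweepResult", "load_dicom_series", "extract_iso_surface",
    "align_crowns_to_volume", "optimize_threshold", "edge_indicator",
    "drlse_step", "drlse_evolve", "init_from_crown", "segment_tooth",
    "contours_to_mesh", "segment_bone", "binary_step_lsf",
]

_LSF_STEP = 2.0  # magnitude of the binary step initialization


@dataclass
class LevelSetField:
    """Signed 2D level-set function on one slice grid.

    Convention: phi < 0 inside the zero-level contour, phi > 0 outside.
    """

    phi: np.ndarray
    grid_spacing: np.ndarray      # (2,) mm, in-plane
    origin: np.ndarray            # (2,) mm, in-plane world position of pixel (0, 0)
    iterations: int = 0

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.all(np.isfinite(self.phi)):
            raise ParameterError("phi must be finite")
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float).reshape(2)
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)

    @property
    def inside_mask(self) -> np.ndarray:
        return self.phi < 0

    def contours_mm(self) -> list[np.ndarray]:
        """Closed zero-level contours in in-plane mm coordinates."""
        out = []
        for c in measure.find_contours(self.phi, 0.0):
            out.append(self.origin + c * self.grid_spacing)
        return out


@dataclass
class DrlseParams:
    """DRLSE weights and schedule.

    mu is the distance-regularization weight (stability needs
    mu * timestep < 1/4), lambda_ the edge-length weight, alpha the signed
    balloon weight (in (0, 1] for crown-initialized shrinking contours),
    sigma the Gaussian SD of the edge indicator in pixels.
    """

    mu: float = 0.2
    lambda_: float = 3.0
    alpha: float = 0.2
    sigma: float = 1.2
    timestep: float = 1.0
    iterations: int = 120
    first_slice_iterations: int = 150
    epsilon: float = 1.5
    convergence_tol: int = 0          # zero-level pixels allowed to move
    check_interval: int = 10          # iterations between movement checks
    stable_checks: int = 2            # consecutive quiet checks to stop
    carry_outward_px: float = 1.5     # outward shift of the carried zero level
    propagation_dilation_px: int = 2  # dilation of a manual initial region
    stop_area_px: float = 2.0         # propagation stop floor (voxel areas)
    min_loop_px: float = 4.0          # components below this are noise, dropped
    # slice images are rescaled to this dynamic range before the edge
    # indicator: gradients of order 1-10 keep g informative (a raw HU range
    # of thousands flattens g to ~0 in a wide band, so the contour cannot
    # lock onto the edge); 0 disables the normalization
    norm_range: float = 15.0

    def __post_init__(self):
        if self.mu < 0:
            raise ParameterError("mu must be non-negative")
        if min(self.lambda_, self.sigma, self.timestep) <= 0:
            raise ParameterError("lambda, sigma and timestep must be positive")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")


@dataclass
class SliceContourStack:
    """Per-slice closed contours (and filled masks) for one structure."""

    tooth_id: str
    slice_axis: int
    slice_indices: list[int] = field(default_factory=list)
    contours: dict[int, list[np.ndarray]] = field(default_factory=dict)
    masks: dict[int, np.ndarray] = field(default_factory=dict)
    spacing: np.ndarray | None = None     # full 3-vector mm
    origin: np.ndarray | None = None

    def add(self, k: int, contours: list[np.ndarray], mask: np.ndarray) -> None:
        self.slice_indices.append(k)
        self.contours[k] = contours
        self.masks[k] = mask

    def loop_count(self, k: int) -> int:
        """Number of disjoint regions on slice k (1 crown -> several roots)."""
        return int(measure.label(self.masks[k]).max())

    def volume_mm3(self, method: str = "mask") -> float:
        """Enclosed volume: slice areas times slice thickness.

        ``method='contour'`` integrates the zero-level polygon areas
        (sub-pixel accurate, assumes loops without holes); ``'mask'``
        counts filled pixels (robust to holes, half-pixel-shell biased).
        """
        dz = float(self.spacing[self.slice_axis])
        if method == "contour":
            total = 0.0
            for k in self.slice_indices:
                total += sum(_polygon_area(c) for c in self.contours[k]) * dz
            return total
        a, b = [i for i in range(3) if i != self.slice_axis]
        pixel_area = float(self.spacing[a] * self.spacing[b])
        return sum(float(m.sum()) * pixel_area * dz for m in self.masks.values())

    def save_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k in self.slice_indices:
            for i, c in enumerate(self.contours[k]):
                np.savetxt(directory / f"{self.tooth_id}_s{k:04d}_c{i}.csv",
                           c, delimiter=",", header="u_mm,v_mm")


@dataclass
class ThresholdSweepResult:
    """Discrepancy sweep over iso-surface thresholds."""

    thresholds: np.ndarray
    mean_discrepancy: np.ndarray   # mm, NaN where the surface was empty
    sd_discrepancy: np.ndarray
    tau_opt: float
    transforms: list[RigidTransform | None]

    @property
    def optimal_index(self) -> int:
        return int(np.nonzero(self.thresholds == self.tau_opt)[0][0])


# ---------------------------------------------------------------------------
# volume IO and iso-surfaces
# ---------------------------------------------------------------------------

def load_dicom_series(path) -> VoxelVolume:
    """Read a directory of single-frame DICOM slices into a volume.

    Slices are sorted by position along the stack normal; RescaleSlope /
    RescaleIntercept are applied so intensities come out in HU.
    """
    import pydicom

    files = sorted(Path(path).glob("*.dcm")) or sorted(Path(path).iterdir())
    datasets = [pydicom.dcmread(str(f)) for f in files if f.is_file()]
    if not datasets:
        raise FormatError(f"no DICOM slices found in {path}")
    ref = datasets[0]
    for tag in ("PixelSpacing", "ImagePositionPatient", "ImageOrientationPatient"):
        if tag not in ref:
            raise FormatError(f"slice missing required tag {tag}")
    orient = np.asarray(ref.ImageOrientationPatient, dtype=float)
    for ds in datasets[1:]:
        if "ImageOrientationPatient" not in ds or not np.allclose(
                np.asarray(ds.ImageOrientationPatient, dtype=float), orient,
                atol=1e-6):
            raise FormatError("slices have inconsistent orientation")
        if "PixelSpacing" not in ds:
            raise FormatError("slice missing PixelSpacing")
    row_dir = orient[:3]
    col_dir = orient[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda ds: float(
        np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal)))
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    stack = np.stack(slices, axis=0)          # (nz, rows, cols)
    intensities = np.transpose(stack, (2, 1, 0))  # (x, y, z): cols, rows, slice
    dy, dx = (float(v) for v in ref.PixelSpacing)
    if len(datasets) > 1:
        z0 = np.dot(np.asarray(datasets[0].ImagePositionPatient, float), normal)
        z1 = np.dot(np.asarray(datasets[1].ImagePositionPatient, float), normal)
        dz = float(z1 - z0)
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0))
    origin = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    return VoxelVolume(intensities, (dx, dy, dz), origin, slice_axis=2)


def extract_iso_surface(volume: VoxelVolume, tau: float) -> trimesh.Trimesh:
    """Marching-cubes iso-surface at HU threshold ``tau`` in world mm.

    A threshold outside the intensity range yields an empty mesh (flagged
    via ``mesh.metadata['empty']``), not an error.
    """
    data = volume.intensities
    if not (data.min() < tau < data.max()):
        mesh = trimesh.Trimesh(vertices=np.zeros((0, 3)),
                               faces=np.zeros((0, 3), dtype=int), process=False)
        mesh.metadata["empty"] = True
        return mesh
    verts, faces, _, _ = measure.marching_cubes(
        data, level=tau, spacing=tuple(volume.spacing),
        gradient_direction="ascent")
    verts = verts + volume.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.metadata["empty"] = False
    return mesh


# ---------------------------------------------------------------------------
# crown-to-volume alignment and threshold optimization
# ---------------------------------------------------------------------------

def align_crowns_to_volume(crown_mesh: trimesh.Trimesh, volume: VoxelVolume,
                           tau: float, landmarks,
                           delta_eps: float = 1.0,
                           max_icp_iter: int = 30,
                           ) -> tuple[RigidTransform, float, float]:
    """Align the optical crown mesh to the iso-surface at ``tau``.

    ``landmarks`` is a sequence of >= 3 (crown_point, volume_point) pairs
    (mm) used for the closed-form Procrustes initialization; ICP then
    refines it using only mating pairs within ``delta_eps`` mm, guarding
    against noise-driven misalignment.  Returns the transform and the mean
    and SD of the absolute point-to-surface discrepancy over mating pairs.
    """
    lm = np.asarray(landmarks, dtype=float)
    if lm.ndim != 3 or lm.shape[0] < 3 or lm.shape[1:] != (2, 3):
        raise InputError("at least 3 (crown, volume) landmark point pairs required")
    iso = extract_iso_surface(volume, tau)
    if iso.metadata.get("empty") or len(iso.vertices) == 0:
        raise AlignmentError(f"iso-surface at tau = {tau} HU is empty")
    T0 = kabsch(lm[:, 0, :], lm[:, 1, :])
    crown_pts = PointCloud(crown_mesh.vertices)
    iso_pts = PointCloud(iso.vertices)
    from .errors import ConvergenceError
    try:
        T, _ = icp_register(crown_pts, iso_pts, init=T0,
                            max_iter=max_icp_iter, reject_dist=delta_eps)
    except ConvergenceError:
        T = T0  # landmark alignment stands when no mating pairs refine it
    moved = T.apply(crown_mesh.vertices)
    dist = point_to_surface_distance(iso, moved)
    mating = dist <= delta_eps
    if not np.any(mating):
        raise AlignmentError(
            f"no mating pairs within delta_eps = {delta_eps} mm at tau = {tau}")
    return T, float(np.mean(dist[mating])), float(np.std(dist[mating]))


def optimize_threshold(crown_mesh: trimesh.Trimesh, volume: VoxelVolume,
                       tau_grid, landmarks, delta_eps: float = 1.0,
                       ) -> ThresholdSweepResult:
    """Sweep iso-surface thresholds and pick tau_opt minimizing the mean
    crown/iso-surface discrepancy; ties break toward the lower threshold."""
    taus = np.asarray(tau_grid, dtype=float)
    if taus.size < 2:
        raise ParameterError("tau_grid needs at least 2 thresholds")
    means = np.full(taus.size, np.nan)
    sds = np.full(taus.size, np.nan)
    transforms: list[RigidTransform | None] = [None] * taus.size
    for i, tau in enumerate(taus):
        try:
            T, m, s = align_crowns_to_volume(crown_mesh, volume, tau,
                                             landmarks, delta_eps)
        except AlignmentError:
            continue
        transforms[i] = T
        means[i] = m
        sds[i] = s
    if np.all(np.isnan(means)):
        raise SweepError("every threshold yielded an empty or unmatable surface")
    best = np.nanmin(means)
    # lowest tau attaining the minimum (within float noise)
    idx = int(np.nonzero(means <= best + 1e-12)[0][0])
    return ThresholdSweepResult(thresholds=taus, mean_discrepancy=means,
                                sd_discrepancy=sds, tau_opt=float(taus[idx]),
                                transforms=transforms)


# ---------------------------------------------------------------------------
# DRLSE core
# ---------------------------------------------------------------------------

def edge_indicator(slice_image: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """g = 1 / (1 + |grad(G_sigma * I)|^2), computed in pixel units.

    g is in (0, 1]; exactly 1 on constant images, near 0 at strong edges.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    smoothed = ndimage.gaussian_filter(np.asarray(slice_image, dtype=float),
                                       sigma, mode="nearest")
    gx, gy = np.gradient(smoothed)
    return 1.0 / (1.0 + gx ** 2 + gy ** 2)


def _neumann(f: np.ndarray) -> np.ndarray:
    """Replicate-inward boundary condition (border row/col mirrors the one
    two pixels inside), applied before each evolution step."""
    g = f.copy()
    g[0, :] = g[2, :]
    g[-1, :] = g[-3, :]
    g[:, 0] = g[:, 2]
    g[:, -1] = g[:, -3]
    return g


def _dp(s: np.ndarray) -> np.ndarray:
    """d_p(s) = p'(s)/s for the double-well potential p: sin(2 pi s)/(2 pi s)
    for s <= 1 (limit 1 at 0) and (s - 1)/s for s > 1."""
    small = s <= 1.0
    out = np.empty_like(s)
    out[small] = np.sinc(2.0 * s[small])        # sin(2 pi s) / (2 pi s)
    big = ~small
    out[big] = (s[big] - 1.0) / s[big]
    return out


def _dirac(phi: np.ndarray, eps: float) -> np.ndarray:
    d = np.zeros_like(phi)
    band = np.abs(phi) <= eps
    d[band] = (1.0 / (2.0 * eps)) * (1.0 + np.cos(np.pi * phi[band] / eps))
    return d


def _div(ax: np.ndarray, ay: np.ndarray) -> np.ndarray:
    return np.gradient(ax)[0] + np.gradient(ay)[1]


def drlse_step(phi: np.ndarray, g: np.ndarray, params: DrlseParams,
               g_grad: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """One explicit Euler step of the DRLSE gradient flow.

    phi_{t+1} = phi + dt * ( mu * div(d_p(|grad phi|) grad phi)
                           + lambda * delta_eps(phi) * div(g grad phi / |grad phi|)
                           + alpha * g * delta_eps(phi) )
    """
    phi = _neumann(phi)
    px, py = np.gradient(phi)
    mag = np.sqrt(px ** 2 + py ** 2)
    dist_term = _div(_dp(np.maximum(mag, 1e-12)) * px,
                     _dp(np.maximum(mag, 1e-12)) * py)
    nx = px / (mag + 1e-10)
    ny = py / (mag + 1e-10)
    delta = _dirac(phi, params.epsilon)
    edge_term = delta * _div(g * nx, g * ny)
    area_term = params.alpha * g * delta
    return phi + params.timestep * (params.mu * dist_term
                                    + params.lambda_ * edge_term + area_term)


def binary_step_lsf(inside_mask: np.ndarray, grid_spacing, origin,
                    c: float = _LSF_STEP) -> LevelSetField:
    """Binary step initialization: -c inside the contour, +c outside."""
    phi = np.where(inside_mask, -c, c).astype(float)
    return LevelSetField(phi, grid_spacing, origin)


def signed_distance_lsf(inside_mask: np.ndarray, grid_spacing, origin,
                        outward_shift: float = 0.0) -> LevelSetField:
    """Signed-distance initialization from a region mask (pixel units,
    negative inside); ``outward_shift`` moves the zero level outward by
    that many pixels, used when carrying a converged contour to the next
    slice so a shrink-biased evolution can follow widening sections."""
    inside = ndimage.distance_transform_edt(inside_mask)
    outside = ndimage.distance_transform_edt(~inside_mask)
    return LevelSetField((outside - inside) - outward_shift,
                         grid_spacing, origin)


def drlse_evolve(phi_init: LevelSetField, g: np.ndarray, params: DrlseParams,
                 iterations: int | None = None) -> LevelSetField:
    """Evolve the LSF until the zero level stops moving or the iteration
    cap is reached.  Raises :class:`ParameterError` when the explicit time
    step violates the distance-regularization stability bound
    (mu * timestep < 1/4)."""
    if params.timestep * params.mu >= 0.25:
        raise ParameterError(
            f"CFL violation: mu * timestep = {params.mu * params.timestep} >= 0.25")
    if g.shape != phi_init.phi.shape:
        raise ParameterError("g field and phi must share a grid")
    cap = iterations if iterations is not None else params.iterations
    phi = phi_init.phi.copy()
    check_mask = phi < 0
    stable = 0
    it = 0
    for it in range(1, cap + 1):
        phi = drlse_step(phi, g, params)
        # the zero level moves a fraction of a pixel per step, so movement
        # is judged over a window of iterations, not per step
        if it % params.check_interval == 0:
            mask = phi < 0
            moved = int(np.count_nonzero(mask ^ check_mask))
            check_mask = mask
            stable = stable + 1 if moved <= params.convergence_tol else 0
            if stable >= params.stable_checks:
                break
    return LevelSetField(phi, phi_init.grid_spacing, phi_init.origin,
                         iterations=phi_init.iterations + it)


# ---------------------------------------------------------------------------
# crown-guided initialization and slice propagation
# ---------------------------------------------------------------------------

def _drop_small_components(mask: np.ndarray, min_px: float) -> np.ndarray:
    if min_px <= 0 or not mask.any():
        return mask
    lab = measure.label(mask)
    keep = np.zeros_like(mask)
    for region in measure.regionprops(lab):
        if region.area >= min_px:
            keep[lab == region.label] = True
    return keep


def _slice_plane(volume: VoxelVolume, k: int) -> tuple[np.ndarray, np.ndarray]:
    normal = np.zeros(3)
    normal[volume.slice_axis] = 1.0
    origin = volume.origin.copy()
    origin[volume.slice_axis] = volume.slice_world_position(k)
    return origin, normal


def _mesh_slice_polygons(mesh: trimesh.Trimesh, volume: VoxelVolume,
                         k: int) -> list[np.ndarray]:
    """Closed in-plane (mm) polygons of the mesh cross-section at slice k."""
    origin, normal = _slice_plane(volume, k)
    section = mesh.section(plane_origin=origin, plane_normal=normal)
    if section is None:
        return []
    a, b = volume.in_plane_axes()
    polys = []
    for line in section.discrete:
        if len(line) < 3:
            continue
        if np.linalg.norm(line[0] - line[-1]) > 1e-6:
            continue  # open polyline: not a closed intersection
        polys.append(line[:, [a, b]])
    return polys


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _rasterize_polygons(polys: list[np.ndarray], volume: VoxelVolume) -> np.ndarray:
    a, b = volume.in_plane_axes()
    shape = (volume.shape[a], volume.shape[b])
    mask = np.zeros(shape, dtype=bool)
    for poly in polys:
        u = (poly[:, 0] - volume.origin[a]) / volume.spacing[a]
        v = (poly[:, 1] - volume.origin[b]) / volume.spacing[b]
        rr, cc = draw_polygon(u, v, shape=shape)
        mask[rr, cc] = True
    return mask


def _inplane_origin_spacing(volume: VoxelVolume) -> tuple[np.ndarray, np.ndarray]:
    a, b = volume.in_plane_axes()
    return volume.origin[[a, b]], volume.spacing[[a, b]]


def _section_area_px(crown_mesh: trimesh.Trimesh, volume: VoxelVolume,
                     k: int) -> float:
    a, b = volume.in_plane_axes()
    polys = _mesh_slice_polygons(crown_mesh, volume, k)
    if not polys:
        return 0.0
    return sum(_polygon_area(p) for p in polys) / (
        volume.spacing[a] * volume.spacing[b])


def _crown_entry(crown_mesh: trimesh.Trimesh, volume: VoxelVolume,
                 min_area_px: float) -> tuple[int, int]:
    """First slice to segment and the propagation direction.

    The stack is entered from the occlusal (cusp) end of the crown — the
    end whose first non-empty cross-section is the smaller — so that
    propagation runs through the crown and onward through the root, as a
    clinician reading the stack from the occlusal side would.
    """
    k_lo, k_hi = _crown_slice_range(crown_mesh, volume)
    if k_hi < k_lo:
        raise ManualInitRequired("crown mesh intersects no slice")
    vol_lo = volume.origin
    vol_hi = volume.origin + (np.array(volume.shape) - 1) * volume.spacing
    if np.any(crown_mesh.bounds[1] < vol_lo) or np.any(crown_mesh.bounds[0] > vol_hi):
        raise ManualInitRequired("crown mesh lies outside the volume extent")
    a_lo = next((_section_area_px(crown_mesh, volume, k)
                 for k in range(k_lo, k_hi + 1)
                 if _section_area_px(crown_mesh, volume, k) > 0), 0.0)
    a_hi = next((_section_area_px(crown_mesh, volume, k)
                 for k in range(k_hi, k_lo - 1, -1)
                 if _section_area_px(crown_mesh, volume, k) > 0), 0.0)
    if a_lo == 0.0 and a_hi == 0.0:
        raise ManualInitRequired("crown mesh intersects no slice")
    if a_hi <= a_lo:
        scan = range(k_hi, k_lo - 1, -1)
        direction = -1
    else:
        scan = range(k_lo, k_hi + 1)
        direction = 1
    for k in scan:
        if _section_area_px(crown_mesh, volume, k) >= min_area_px:
            return k, direction
    raise ManualInitRequired("no crown cross-section reaches the area floor")


def init_from_crown(crown_mesh_aligned: trimesh.Trimesh, volume: VoxelVolume,
                    tooth_id: str = "", dilation_radius: int = 3,
                    min_area_px: float = 4.0,
                    ) -> tuple[int, np.ndarray, list[np.ndarray], LevelSetField]:
    """Crown-guided LSF initialization.

    Scans the stack from the occlusal end for the first slice whose plane
    cuts the aligned crown mesh in a closed cross-section of at least
    ``min_area_px`` voxel areas; that filled polygon is R0, the initial
    contour C_init is the boundary of R0 dilated by a disk of
    ``dilation_radius`` px, and phi_init is the binary step LSF.  Raises
    :class:`ManualInitRequired` when no slice intersects (the
    impacted-tooth path: the operator must supply a contour).
    """
    try:
        k, _ = _crown_entry(crown_mesh_aligned, volume, min_area_px)
    except ManualInitRequired:
        raise ManualInitRequired(
            f"crown mesh of tooth '{tooth_id}' intersects no slice; supply a "
            "manual initial contour and start slice (impacted-tooth path)")
    polys = _mesh_slice_polygons(crown_mesh_aligned, volume, k)
    r0 = _rasterize_polygons(polys, volume)
    c_init_mask = ndimage.binary_dilation(r0, structure=disk(dilation_radius))
    origin2, spacing2 = _inplane_origin_spacing(volume)
    phi = binary_step_lsf(c_init_mask, spacing2, origin2)
    return k, r0, phi.contours_mm(), phi


def _evolve_slice(volume: VoxelVolume, k: int, phi: LevelSetField,
                  params: DrlseParams, iterations: int,
                  norm: tuple[float, float] | None = None) -> LevelSetField:
    img = volume.slice_image(k)
    if params.norm_range > 0:
        lo, hi = norm if norm is not None else (
            float(volume.intensities.min()), float(volume.intensities.max()))
        if hi > lo:
            img = (img - lo) / (hi - lo) * params.norm_range
    g = edge_indicator(img, params.sigma)
    return drlse_evolve(phi, g, params, iterations=iterations)


def _crown_slice_range(crown_mesh: trimesh.Trimesh, volume: VoxelVolume
                       ) -> tuple[int, int]:
    ax = volume.slice_axis
    zmin, zmax = crown_mesh.bounds[:, ax]
    k_lo = int(np.floor((zmin - volume.origin[ax]) / volume.spacing[ax]))
    k_hi = int(np.ceil((zmax - volume.origin[ax]) / volume.spacing[ax]))
    return max(k_lo, 0), min(k_hi, volume.n_slices - 1)


def segment_tooth(volume: VoxelVolume,
                  crown_mesh_aligned: trimesh.Trimesh | None = None,
                  manual_init_contour: np.ndarray | None = None,
                  start_slice: int | None = None,
                  params: DrlseParams | None = None,
                  tooth_id: str = "",
                  direction: int = 1,
                  max_slices: int | None = None) -> SliceContourStack:
    """Slice-propagated DRLSE segmentation of one tooth.

    Erupted path: the aligned optical crown initializes the first slice
    (see :func:`init_from_crown`) and propagation runs from the crown tip
    through the root.  Impacted path: a manual polygon (in-plane mm) plus
    ``start_slice`` and ``direction`` replace the crown guidance.

    Propagation stops when the zero-level area falls below the stop floor;
    an area growing more than 3x between adjacent slices raises
    :class:`PropagationError`.
    """
    params = params or DrlseParams()
    origin2, spacing2 = _inplane_origin_spacing(volume)
    if crown_mesh_aligned is not None:
        k0, r0, _, phi = init_from_crown(crown_mesh_aligned, volume, tooth_id)
        _, direction = _crown_entry(crown_mesh_aligned, volume, min_area_px=4.0)
    elif manual_init_contour is not None and start_slice is not None:
        poly = np.asarray(manual_init_contour, dtype=float)
        mask0 = _rasterize_polygons([poly], volume)
        if not mask0.any():
            raise InputError("manual contour rasterizes to an empty region")
        mask0 = ndimage.binary_dilation(mask0, structure=disk(
            params.propagation_dilation_px))
        phi = binary_step_lsf(mask0, spacing2, origin2)
        k0 = int(start_slice)
    else:
        raise InputError("provide either crown_mesh_aligned or "
                         "manual_init_contour + start_slice")

    stack = SliceContourStack(tooth_id=tooth_id, slice_axis=volume.slice_axis,
                              spacing=volume.spacing.copy(),
                              origin=volume.origin.copy())
    prev_area = None
    k = k0
    n_done = 0
    iterations = params.first_slice_iterations
    norm = (float(volume.intensities.min()), float(volume.intensities.max()))
    while 0 <= k < volume.n_slices:
        evolved = _evolve_slice(volume, k, phi, params, iterations, norm)
        mask = _drop_small_components(evolved.inside_mask, params.min_loop_px)
        if not np.array_equal(mask, evolved.inside_mask):
            evolved = LevelSetField(
                np.where(mask | (evolved.phi > 0), evolved.phi,
                         -evolved.phi),  # flip dropped specks to outside
                evolved.grid_spacing, evolved.origin, evolved.iterations)
        area = float(mask.sum())
        if area < params.stop_area_px:
            break
        if prev_area is not None and area > 3.0 * prev_area:
            raise PropagationError(k, f"zero-level area grew {area / prev_area:.1f}x "
                                      f"at slice {k}")
        stack.add(k, evolved.contours_mm(), mask)
        prev_area = area
        n_done += 1
        if max_slices is not None and n_done >= max_slices:
            break
        # carry the converged contour to the next slice as a signed
        # distance, shifted slightly outward so a shrink-biased contour
        # can follow widening cross-sections
        phi = signed_distance_lsf(mask, spacing2, origin2,
                                  outward_shift=params.carry_outward_px)
        iterations = params.iterations
        k += direction
    if not stack.slice_indices:
        raise PropagationError(k0, "no slice produced a contour")
    return stack


def contours_to_mesh(stack: SliceContourStack, spacing=None) -> trimesh.Trimesh:
    """Closed surface from a slice contour stack: the filled masks are
    stacked into a binary volume (zero-padded at both ends) and tessellated
    by marching cubes at 0.5."""
    if len(stack.slice_indices) < 2:
        raise ReconstructionError("need contours on at least 2 slices")
    spacing = np.asarray(spacing if spacing is not None else stack.spacing,
                         dtype=float)
    ks = sorted(stack.slice_indices)
    shape2 = stack.masks[ks[0]].shape
    n = ks[-1] - ks[0] + 1
    grid = np.zeros((shape2[0], shape2[1], n + 2), dtype=float)
    for k in ks:
        grid[:, :, k - ks[0] + 1] = stack.masks[k].astype(float)
    ax = stack.slice_axis
    a, b = [i for i in range(3) if i != ax]
    sp = (spacing[a], spacing[b], spacing[ax])
    verts, faces, _, _ = measure.marching_cubes(grid, 0.5, spacing=sp,
                                                gradient_direction="ascent")
    # map (u, v, w) back to world axes
    world = np.empty_like(verts)
    world[:, a] = verts[:, 0] + stack.origin[a]
    world[:, b] = verts[:, 1] + stack.origin[b]
    world[:, ax] = verts[:, 2] + stack.origin[ax] + (ks[0] - 1) * spacing[ax]
    return trimesh.Trimesh(vertices=world, faces=faces, process=False)


def segment_bone(volume: VoxelVolume, manual_init_contour: np.ndarray,
                 start_slice: int, params: DrlseParams | None = None,
                 tooth_stacks: list[SliceContourStack] = (),
                 direction: int = 1,
                 max_slices: int | None = None,
                 ) -> tuple[SliceContourStack, list[str]]:
    """DRLSE propagation of the alveolar-bone envelope followed by
    per-slice subtraction of every tooth region, yielding the socketed
    bone (multi-loop contours with holes).

    Returns ``(stack, warnings)``; a tooth region escaping its bone
    envelope on a slice is recorded as a warning and subtraction proceeds.
    """
    params = params or DrlseParams()
    bone = segment_tooth(volume, manual_init_contour=manual_init_contour,
                         start_slice=start_slice, params=params,
                         tooth_id="bone", direction=direction,
                         max_slices=max_slices)
    warnings: list[str] = []
    socket = SliceContourStack(tooth_id="bone_socketed",
                               slice_axis=volume.slice_axis,
                               spacing=volume.spacing.copy(),
                               origin=volume.origin.copy())
    origin2, spacing2 = _inplane_origin_spacing(volume)
    for k in bone.slice_indices:
        mask = bone.masks[k].copy()
        for ts in tooth_stacks:
            tm = ts.masks.get(k)
            if tm is None:
                continue
            if np.any(tm & ~mask):
                warnings.append(
                    f"tooth {ts.tooth_id} extends outside the bone contour "
                    f"on slice {k}")
            mask &= ~tm
        lsf = binary_step_lsf(mask, spacing2, origin2)
        socket.add(k, lsf.contours_mm(), mask)
    return socket, warnings
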