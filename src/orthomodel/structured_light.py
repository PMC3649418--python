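"""Binary-coded structured-light profilometry simulator and decoder.

A projector throws a temporal sequence of n black/white stripe patterns
whose period is progressively halved; each camera pixel accumulates an
n-bit binary code (0 = black, 1 = white) identifying the light plane that
illuminated it, giving l = 2**n - 1 encoded stripe boundaries.  3D points
come from intersecting the camera pixel ray with the decoded plane.
Turntable views are composed into a common frame from the known rotation
angles.

Only the binary coding stage is modelled; phase-shift refinement and real
camera/projector calibration are out of scope (the rig here is analytic).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PointCloud, RigidTransform
from .errors import ParameterError, ShapeError

__all__ = [
    "GrayCodePatternSet", "ProjectorCameraRig", "CodeMap",
    "generate_patterns", "encode_pixels", "triangulate",
    "compose_turntable_views", "make_simulated_rig", "render_views",
    "triangulate_simulated", "turntable_transform",
]


@dataclass
class GrayCodePatternSet:
    """n binary stripe images at projector resolution l_h x l_v.

    ``patterns[k]`` carries bit k (most significant first) of the per-column
    code; its stripe period is half that of pattern k-1.
    """

    n: int
    l_h: int
    l_v: int
    patterns: np.ndarray  # (n, l_v, l_h) uint8 in {0, 1}

    @property
    def encoded_lines(self) -> int:
        """Number of encoded stripe boundaries, l = 2**n - 1."""
        return 2 ** self.n - 1

    @property
    def encoded_points(self) -> int:
        """Encoded point budget n_p = l_h x l_v."""
        return self.l_h * self.l_v

    def stripe_period(self, k: int) -> float:
        """Stripe period of pattern k in projector columns."""
        return self.l_h / 2 ** (k + 1) * 2

    def column_codes(self) -> np.ndarray:
        """The n-bit code of every projector column."""
        cols = np.arange(self.l_h)
        return (cols * 2 ** self.n) // self.l_h


@dataclass
class ProjectorCameraRig:
    """Analytic stereo rig: one ray per camera pixel plus one light plane
    per code value.

    ``planes`` stores (unit normal, offset) with the plane equation
    ``n . x = d`` in mm; ``working_volume`` is an axis-aligned (lo, hi) box.
    """

    camera_center: np.ndarray          # (3,) mm
    ray_directions: np.ndarray         # (H, W, 3) unit vectors
    plane_normals: np.ndarray          # (n_codes, 3) unit vectors
    plane_offsets: np.ndarray          # (n_codes,) mm
    working_volume: tuple[np.ndarray, np.ndarray]

    def __post_init__(self):
        self.camera_center = np.asarray(self.camera_center, dtype=float).reshape(3)
        self.ray_directions = np.asarray(self.ray_directions, dtype=float)
        norms = np.linalg.norm(self.ray_directions, axis=-1, keepdims=True)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ParameterError("ray directions must be unit vectors")
        pn = np.asarray(self.plane_normals, dtype=float)
        if np.any(np.abs(np.linalg.norm(pn, axis=1) - 1.0) > 1e-6):
            raise ParameterError("plane normals must be unit vectors")
        self.plane_normals = pn
        self.plane_offsets = np.asarray(self.plane_offsets, dtype=float)


@dataclass
class CodeMap:
    """Per-pixel integer stripe code with a validity mask."""

    codes: np.ndarray   # (H, W) int
    valid: np.ndarray   # (H, W) bool
    n_bits: int

    def __post_init__(self):
        inside = (self.codes >= 0) & (self.codes <= 2 ** self.n_bits - 1)
        if np.any(self.valid & ~inside):
            raise ParameterError("valid codes out of range")


def generate_patterns(n: int, l_h: int, l_v: int) -> GrayCodePatternSet:
    """Binary stripe pattern sequence with period halving.

    Pattern k is bit k (MSB first) of the column code
    ``floor(col * 2**n / l_h)``; successive patterns halve the stripe
    period, encoding ``2**n - 1`` stripe boundary lines.
    """
    if not 1 <= n <= 16:
        raise ParameterError("n must be in [1, 16]")
    if l_h <= 0 or l_v <= 0:
        raise ParameterError("projector resolution must be positive")
    cols = np.arange(l_h)
    codes = (cols * 2 ** n) // l_h
    bits = (codes[None, :] >> np.arange(n - 1, -1, -1)[:, None]) & 1
    patterns = np.repeat(bits[:, None, :], l_v, axis=1).astype(np.uint8)
    return GrayCodePatternSet(n=n, l_h=l_h, l_v=l_v, patterns=patterns)


def encode_pixels(intensity_stack: np.ndarray,
                  contrast_floor: float = 0.05) -> CodeMap:
    """Decode an n-image capture stack into per-pixel codes.

    Each pixel is binarized at the midpoint of its own min/max over the
    stack (robust to albedo); pixels whose min-max contrast falls below
    ``contrast_floor`` (relative to the global stack range) are masked
    invalid.  Bits are assembled bright = 1 / dark = 0 in projection order,
    most significant first.
    """
    stack = np.asarray(intensity_stack, dtype=float)
    if stack.ndim != 3:
        raise ShapeError("intensity stack must be (n, H, W)")
    n = stack.shape[0]
    lo = stack.min(axis=0)
    hi = stack.max(axis=0)
    rng = float(np.ptp(stack))
    floor = contrast_floor * max(rng, 1e-12)
    modulated = (hi - lo) > floor
    # an all-bright pixel decodes to the all-ones code via the global
    # midpoint; an all-dark pixel is indistinguishable from an unlit one
    # and is masked (so code 0 is never a valid observation and the number
    # of distinct valid codes stays <= 2**n - 1, the encoded line count)
    global_mid = 0.5 * float(stack.min() + stack.max())
    flat_bright = ~modulated & ((lo - global_mid) > floor)
    valid = modulated | flat_bright
    thresh = np.where(modulated, 0.5 * (lo + hi), global_mid)
    bits = stack > thresh[None]
    weights = 2 ** np.arange(n - 1, -1, -1)
    codes = np.tensordot(weights, bits.astype(np.int64), axes=(0, 0))
    codes[~valid] = -1
    return CodeMap(codes=codes, valid=valid, n_bits=n)


def triangulate(code_map: CodeMap, rig: ProjectorCameraRig,
                parallel_tol: float = 1e-9) -> tuple[PointCloud, dict]:
    """Ray-plane intersection per valid pixel.

    Pixels whose ray is (near-)parallel to their plane or whose point
    falls outside the working volume are masked; a diagnostics dict
    reports the counts.
    """
    H, W = code_map.codes.shape
    valid = code_map.valid.copy()
    codes = np.where(valid, code_map.codes, 0)
    if codes.max(initial=0) >= len(rig.plane_normals):
        raise ParameterError("code map contains codes without plane equations")
    n = rig.plane_normals[codes]            # (H, W, 3)
    d = rig.plane_offsets[codes]            # (H, W)
    dirs = rig.ray_directions
    denom = np.einsum("hwc,hwc->hw", n, dirs)
    parallel = np.abs(denom) < parallel_tol
    safe = np.where(parallel, 1.0, denom)
    t = (d - n @ rig.camera_center) / safe
    pts = rig.camera_center + t[..., None] * dirs
    lo, hi = rig.working_volume
    in_box = np.all((pts >= lo) & (pts <= hi), axis=-1)
    keep = valid & ~parallel & in_box & (t > 0)
    diagnostics = {
        "n_valid_codes": int(valid.sum()),
        "n_parallel": int((valid & parallel).sum()),
        "n_outside_volume": int((valid & ~parallel & ~in_box).sum()),
        "n_points": int(keep.sum()),
    }
    return PointCloud(pts[keep]), diagnostics


def turntable_transform(rotation_deg: float, tilt_deg: float,
                        axis_calibration: RigidTransform) -> RigidTransform:
    """Rigid map from a view frame to the common frame for one (rotation,
    tilt) turntable position.  The calibration maps the turntable's own
    frame (rotation about z, tilt about x) into the common frame."""
    R_table = RigidTransform.from_axis_angle((0, 0, 1), rotation_deg).compose(
        RigidTransform.from_axis_angle((1, 0, 0), tilt_deg))
    return axis_calibration.compose(R_table).compose(axis_calibration.inverse())


def compose_turntable_views(views: list[PointCloud],
                            angles: list[tuple[float, float]],
                            axis_calibration: RigidTransform | None = None,
                            ) -> PointCloud:
    """Map each view by its exact turntable rotation and concatenate in the
    common frame, carrying per-view provenance indices."""
    if len(views) != len(angles):
        raise ParameterError("one (rotation, tilt) pair is required per view")
    cal = axis_calibration or RigidTransform.identity()
    out: PointCloud | None = None
    for i, (view, (rot, tilt)) in enumerate(zip(views, angles)):
        T = turntable_transform(rot, tilt, cal)
        mapped = view.transformed(T)
        mapped.labels["view_index"] = np.full(len(mapped), i, dtype=int)
        out = mapped if out is None else out.concatenated(mapped)
    return out


# ---------------------------------------------------------------------------
# analytic simulation (telecentric camera over a height field)
# ---------------------------------------------------------------------------

def make_simulated_rig(patterns: GrayCodePatternSet,
                       extent_mm: float = 100.0,
                       standoff_mm: float = 300.0,
                       projector_angle_deg: float = 20.0,
                       height: int | None = None,
                       width: int | None = None,
                       ) -> ProjectorCameraRig:
    """Build an analytic rig whose camera pixel rays hit the centre of one
    code band each on the reference plane z = 0.

    The camera looks straight down from ``standoff_mm``; the projector's
    parallel light planes are inclined by ``projector_angle_deg`` about y,
    so plane normals are (cos b, 0, sin b).  One camera column per code
    band keeps decode->triangulate exact on the reference plane.
    """
    n_codes = 2 ** patterns.n
    W = width or n_codes
    H = height or max(patterns.l_v // 16, 8)
    beta = np.deg2rad(projector_angle_deg)
    normal = np.array([np.cos(beta), 0.0, np.sin(beta)])
    band = extent_mm / n_codes
    offsets = (np.arange(n_codes) + 0.5) * band - extent_mm / 2
    # camera columns at plane-centre x positions on z = 0
    xs = np.interp(np.arange(W), [0, W - 1],
                   [offsets[0], offsets[-1]]) if W != n_codes else offsets.copy()
    xs = xs / normal[0]  # n.x = off with y=0,z=0  ->  x = off / cos b
    ys = (np.arange(H) - (H - 1) / 2) * band
    dirs = np.zeros((H, W, 3))
    dirs[..., 2] = -1.0
    center = np.array([0.0, 0.0, standoff_mm])
    # per-pixel rays are parallel (telecentric) but originate above (x, y)
    # encode origin offsets via per-pixel ray bundles: store directions and
    # reconstruct per-pixel origins when rendering/triangulating
    rig = ProjectorCameraRig(
        camera_center=center,
        ray_directions=dirs,
        plane_normals=np.repeat(normal[None], n_codes, axis=0),
        plane_offsets=offsets,
        working_volume=(np.array([-extent_mm, -extent_mm, -50.0]),
                        np.array([extent_mm, extent_mm, standoff_mm])),
    )
    YY, XX = np.meshgrid(ys, xs, indexing="ij")
    rig.pixel_origins = np.stack(  # type: ignore[attr-defined]
        [XX, YY, np.full((H, W), standoff_mm)], axis=-1)
    return rig


def render_views(rig: ProjectorCameraRig, patterns: GrayCodePatternSet,
                 height_fn=None) -> np.ndarray:
    """Forward-render the capture stack of a height field z = h(x, y) seen
    by the simulated telecentric rig (bright = 1, dark = 0)."""
    origins = rig.pixel_origins  # type: ignore[attr-defined]
    h = np.zeros(origins.shape[:2]) if height_fn is None else \
        height_fn(origins[..., 0], origins[..., 1])
    pts = origins.copy()
    pts[..., 2] = h
    normal = rig.plane_normals[0]
    band = rig.plane_offsets[1] - rig.plane_offsets[0] if len(rig.plane_offsets) > 1 \
        else 1.0
    s = pts @ normal
    codes = np.clip(np.floor((s - (rig.plane_offsets[0] - 0.5 * band)) / band),
                    0, 2 ** patterns.n - 1).astype(int)
    bits = (codes[None] >> np.arange(patterns.n - 1, -1, -1)[:, None, None]) & 1
    return bits.astype(float)


def triangulate_simulated(code_map: CodeMap, rig: ProjectorCameraRig) -> PointCloud:
    """Triangulation for the telecentric simulated rig (per-pixel ray
    origins instead of a single pinhole centre)."""
    origins = rig.pixel_origins  # type: ignore[attr-defined]
    valid = code_map.valid
    codes = np.where(valid, code_map.codes, 0)
    n = rig.plane_normals[codes]
    d = rig.plane_offsets[codes]
    dirs = rig.ray_directions
    denom = np.einsum("hwc,hwc->hw", n, dirs)
    parallel = np.abs(denom) < 1e-9
    t = (d - np.einsum("hwc,hwc->hw", n, origins)) / np.where(parallel, 1.0, denom)
    pts = origins + t[..., None] * dirs
    keep = valid & ~parallel
    return PointCloud(pts[keep])
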