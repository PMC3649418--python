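"""Shared data currencies: point clouds, rigid transforms, voxel volumes.

Units are millimetres everywhere; voxel volumes use the centre-of-voxel
convention ``world = origin + index * spacing`` with 0-based indices.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

__all__ = ["RigidTransform", "PointCloud", "VoxelVolume"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` in mm.

    ``rotation`` must be orthonormal with det = +1 (reflections rejected).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ParameterError("rotation must be proper (det = +1)")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise ParameterError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0),
                        center=None) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis``; optional rotation center."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        t = np.asarray(translation, dtype=float)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return cls(M[:3, :3], M[:3, 3])

    @property
    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class PointCloud:
    """N x 3 positions in mm with optional unit normals and labels.

    ``labels`` is a free-form mapping of per-point arrays (length N); the
    phantom uses it to carry ground-truth tags through the pipeline.
    """

    positions: np.ndarray
    normals: np.ndarray | None = None
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        P = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if P.size and (P.ndim != 2 or P.shape[1] != 3):
            raise ParameterError("positions must be N x 3")
        if P.size and not np.all(np.isfinite(P)):
            raise ParameterError("positions must be finite")
        self.positions = P.reshape(-1, 3)
        if self.normals is not None:
            N = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if N.shape != self.positions.shape:
                raise ParameterError("normals must match positions")
            norms = np.linalg.norm(N, axis=1)
            ok = norms > 0
            N[ok] = N[ok] / norms[ok, None]
            self.normals = N
        for k, v in self.labels.items():
            v = np.asarray(v)
            if v.shape[0] != len(self):
                raise ParameterError(f"label '{k}' length mismatch")
            self.labels[k] = v

    def __len__(self) -> int:
        return self.positions.shape[0]

    def transformed(self, T: RigidTransform) -> "PointCloud":
        return PointCloud(
            T.apply(self.positions),
            None if self.normals is None else T.apply_vectors(self.normals),
            {k: v.copy() for k, v in self.labels.items()},
        )

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.positions[mask],
            None if self.normals is None else self.normals[mask],
            {k: v[mask] for k, v in self.labels.items()},
        )

    def concatenated(self, other: "PointCloud") -> "PointCloud":
        keys = set(self.labels) & set(other.labels)
        return PointCloud(
            np.vstack([self.positions, other.positions]),
            (np.vstack([self.normals, other.normals])
             if self.normals is not None and other.normals is not None else None),
            {k: np.concatenate([self.labels[k], other.labels[k]]) for k in keys},
        )

    def save_xyz(self, path) -> None:
        cols = [self.positions]
        if self.normals is not None:
            cols.append(self.normals)
        np.savetxt(path, np.hstack(cols), fmt="%.6f")

    @classmethod
    def load_xyz(cls, path) -> "PointCloud":
        data = np.atleast_2d(np.loadtxt(path))
        if data.shape[1] >= 6:
            return cls(data[:, :3], data[:, 3:6])
        return cls(data[:, :3])


@dataclass
class VoxelVolume:
    """3D intensity grid (HU-like) with mm spacing and origin.

    ``intensities`` is indexed ``[i, j, k]`` along (x, y, z) world axes; the
    slice axis (default the last) designates the CBCT stack direction.
    """

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    slice_axis: int = 2

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.intensities.ndim != 3:
            raise ParameterError("intensities must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ParameterError("spacing must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ParameterError("intensities must be finite")
        if self.slice_axis not in (0, 1, 2):
            raise ParameterError("slice_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[self.slice_axis]

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def index_coords(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def slice_image(self, k: int) -> np.ndarray:
        """2D image of slice ``k`` along the slice axis (in-plane axes kept
        in world-axis order)."""
        return np.take(self.intensities, k, axis=self.slice_axis)

    def slice_world_position(self, k: int) -> float:
        ax = self.slice_axis
        return float(self.origin[ax] + k * self.spacing[ax])

    def in_plane_axes(self) -> tuple[int, int]:
        return tuple(a for a in (0, 1, 2) if a != self.slice_axis)

    def in_plane_spacing(self) -> np.ndarray:
        a, b = self.in_plane_axes()
        return self.spacing[[a, b]]

    def copy_with(self, **kw) -> "VoxelVolume":
        return replace(self, **kw)
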