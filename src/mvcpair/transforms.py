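"""Rigid motions and bilateral mirroring.

Right-side elements are mirrored before comparison so that a left bone and
its antimere become directly superimposable; everything downstream then
deals only in proper rigid motions (rotation + translation, no scaling:
the comparison deliberately measures size as well as shape differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MvcError
from .mesh_io import TriangleMesh

_ORTHO_TOL = 1e-8

MIRROR_PLANES = {"x": 0, "y": 1, "z": 2}


def _nearest_rotation(matrix: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) (polar decomposition via SVD)."""
    u, _, vt = np.linalg.svd(matrix)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        u[:, -1] *= -1
        rot = u @ vt
    return rot


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``v -> R v + t`` in millimetres."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(rot.T @ rot - np.eye(3)).max()
        if err > _ORTHO_TOL or abs(np.linalg.det(rot) - 1.0) > _ORTHO_TOL:
            raise MvcError(
                f"matrix is not a proper rotation (orthonormality error {err:.2e}, "
                f"det {np.linalg.det(rot):.6f})"
            )
        # renormalise tiny drift so long composition chains stay rigid
        if err > 1e-14:
            rot = _nearest_rotation(rot)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix."""
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (4, 4):
            raise MvcError("expected a 4x4 homogeneous matrix")
        return cls(matrix[:3, :3], matrix[:3, 3])

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (used in JSON run reports)."""
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def apply_normals(self, normals: np.ndarray) -> np.ndarray:
        return np.asarray(normals, dtype=np.float64) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """The rigid motion equivalent to applying ``first`` then ``second``."""
    return RigidTransform(
        second.rotation @ first.rotation,
        second.rotation @ first.translation + second.translation,
    )


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Map a mesh through a rigid motion; cached normals are rotated too."""
    normals = None
    if mesh._vertex_normals is not None:
        normals = transform.apply_normals(mesh._vertex_normals)
    return TriangleMesh(mesh.id, transform.apply(mesh.vertices), mesh.faces.copy(), normals)


def mirror_mesh(mesh: TriangleMesh, plane: str = "x") -> TriangleMesh:
    """Reflect a mesh across a coordinate plane through the origin.

    The face winding is reversed so normals stay outward (a reflection has
    determinant -1 and would otherwise turn the surface inside out). The id
    gets a ``_mirrored`` suffix. Mirroring its own output restores the
    original coordinates exactly.
    """
    if plane not in MIRROR_PLANES:
        raise ValueError(f"mirror plane must be one of {sorted(MIRROR_PLANES)}")
    axis = MIRROR_PLANES[plane]
    vertices = mesh.vertices.copy()
    vertices[:, axis] *= -1.0
    faces = mesh.faces[:, ::-1].copy()
    new_id = (
        mesh.id[: -len("_mirrored")]
        if mesh.id.endswith("_mirrored")
        else mesh.id + "_mirrored"
    )
    return TriangleMesh(new_id, vertices, faces)
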