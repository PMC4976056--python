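"""Triangle meshes, side-labelled specimen collections, and file I/O.

Meshes are plain vertex/face surfaces in millimetres. STL stores three
vertices per facet, so STL input is welded (duplicate vertices merged at a
tolerance proportional to the bounding-box diagonal) before use: every
nearest-neighbour structure downstream needs a deduplicated vertex set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

from .errors import DuplicateIdError, EmptyMeshError, MeshFormatError

SUPPORTED_EXTENSIONS = {".obj", ".stl", ".ply"}

#: Welding tolerance as a fraction of the bounding-box diagonal.
WELD_RELATIVE_TOL = 1e-8

#: Faces with area below this (mm^2) are dropped as degenerate.
DEGENERATE_AREA_TOL = 1e-12


@dataclass
class TriangleMesh:
    """A triangle surface mesh: the unit of all comparisons.

    Parameters
    ----------
    id : str
        Specimen label, unique within a collection.
    vertices : (n, 3) float array
        Vertex coordinates in millimetres.
    faces : (m, 3) int array
        Vertex-index triples; counter-clockwise winding is taken as
        outward-facing.
    """

    id: str
    vertices: np.ndarray
    faces: np.ndarray
    _vertex_normals: Optional[np.ndarray] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError(f"{self.id}: vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError(f"{self.id}: faces must be (m, 3)")
        if not np.isfinite(self.vertices).all():
            raise MeshFormatError(f"{self.id}: non-finite vertex coordinate")
        if len(self.faces) == 0:
            raise EmptyMeshError(f"{self.id}: mesh has no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshFormatError(f"{self.id}: face index out of range")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise MeshFormatError(f"{self.id}: face with repeated vertex index")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def bbox_diagonal(self) -> float:
        extent = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(extent))

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals (unit length; zero for
        isolated vertices). Computed lazily and cached."""
        if self._vertex_normals is None:
            self._vertex_normals = compute_vertex_normals(self)
        return self._vertex_normals

    @property
    def isolated_vertices(self) -> np.ndarray:
        """Boolean mask of vertices with no incident face (their normal is
        the zero vector and they are skipped by normal-compatibility
        tests)."""
        return np.linalg.norm(self.vertex_normals, axis=1) == 0.0

    def with_id(self, new_id: str) -> "TriangleMesh":
        return TriangleMesh(new_id, self.vertices, self.faces, self._vertex_normals)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.id,
            self.vertices.copy(),
            self.faces.copy(),
            None if self._vertex_normals is None else self._vertex_normals.copy(),
        )


def compute_vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted average of incident face normals, normalised to unit
    length.

    The cross product of two face edges has magnitude twice the face area,
    so summing raw cross products per vertex is exactly area weighting.
    Isolated vertices get a zero normal.
    """
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, f[:, k], cross)
    norms = np.linalg.norm(normals, axis=1)
    nonzero = norms > 0
    normals[nonzero] /= norms[nonzero, None]
    return normals


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (default: 1e-8 x bbox diagonal)
    and drop faces that become degenerate. Idempotent."""
    if tol is None:
        extent = vertices.max(axis=0) - vertices.min(axis=0)
        tol = WELD_RELATIVE_TOL * float(np.linalg.norm(extent))
    if tol > 0:
        quant = np.round(vertices / tol).astype(np.int64)
    else:
        quant = vertices
    _, first, inverse = np.unique(
        quant, axis=0, return_index=True, return_inverse=True
    )
    # keep the original order of first appearance for determinism
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    new_faces = rank[inverse][faces]
    new_faces = _drop_degenerate_faces(new_vertices, new_faces)
    return new_vertices, new_faces


def _drop_degenerate_faces(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[distinct]
    if len(faces):
        cross = np.cross(
            vertices[faces[:, 1]] - vertices[faces[:, 0]],
            vertices[faces[:, 2]] - vertices[faces[:, 0]],
        )
        area2 = np.linalg.norm(cross, axis=1)
        faces = faces[area2 > 2.0 * DEGENERATE_AREA_TOL]
    return faces


def read_mesh(path: str | Path, id: Optional[str] = None) -> TriangleMesh:
    """Read an OBJ, STL or PLY surface mesh.

    STL input is welded (STL stores per-facet vertices); OBJ/PLY vertices
    are taken as stored. Stored normals are ignored and recomputed from the
    face winding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise MeshFormatError(f"unsupported mesh format: {path.name}")
    mesh_id = id if id is not None else path.stem
    try:
        tm = trimesh.load(path, file_type=ext.lstrip("."), process=False, force="mesh")
    except Exception as exc:  # trimesh raises a zoo of exception types
        raise MeshFormatError(f"cannot read {path}: {exc}") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path}: mesh has no faces")
    if not np.isfinite(vertices).all():
        raise MeshFormatError(f"{path}: non-finite vertex coordinate")
    if ext == ".stl":
        vertices, faces = weld_vertices(vertices, faces)
    else:
        faces = _drop_degenerate_faces(vertices, faces)
    return TriangleMesh(mesh_id, vertices, faces)


def write_mesh(mesh: TriangleMesh, path: str | Path) -> Path:
    """Write a mesh as OBJ, STL or PLY (by extension)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise MeshFormatError(f"unsupported mesh format: {path.name}")
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(path)
    return path


# -- specimen collections ---------------------------------------------------

LEFT = "left"
RIGHT = "right"


@dataclass
class SpecimenSet:
    """An ordered, side-labelled collection of meshes."""

    side: str
    meshes: list[TriangleMesh]
    manifest: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        ids = [m.id for m in self.meshes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate specimen ids: {dup}")

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.meshes]

    def __len__(self) -> int:
        return len(self.meshes)

    def __iter__(self):
        return iter(self.meshes)

    def __getitem__(self, id: str) -> TriangleMesh:
        for m in self.meshes:
            if m.id == id:
                return m
        raise KeyError(id)


def _side_from_filename(stem: str) -> Optional[str]:
    lower = stem.lower()
    if lower.endswith("_l"):
        return LEFT
    if lower.endswith("_r"):
        return RIGHT
    return None


def read_manifest(path: str | Path) -> list[dict[str, str]]:
    """Read a manifest CSV with header ``id,path,side``."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "path", "side"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise MeshFormatError(f"manifest {path} must have columns id,path,side")
        for row in reader:
            side = row["side"].strip().lower()
            if side not in (LEFT, RIGHT):
                raise MeshFormatError(
                    f"manifest {path}: side must be left/right, got {row['side']!r}"
                )
            rows.append({"id": row["id"].strip(), "path": row["path"].strip(), "side": side})
    return rows


def load_specimen_set(
    directory: str | Path,
    side: str,
    manifest: Optional[str | Path] = None,
) -> SpecimenSet:
    """Load all meshes of one side from a directory.

    Side is inferred from the ``_L``/``_R`` filename suffix (case
    insensitive) unless a manifest CSV (``id,path,side``) overrides it.
    Files are loaded in sorted order so the set is deterministic.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    if side not in (LEFT, RIGHT):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    entries: list[tuple[str, Path]] = []
    if manifest is not None:
        for row in read_manifest(manifest):
            if row["side"] != side:
                continue
            mesh_path = Path(row["path"])
            if not mesh_path.is_absolute():
                mesh_path = directory / mesh_path
            entries.append((row["id"], mesh_path))
        entries.sort()
    else:
        for path in sorted(directory.iterdir()):
            if path.suffix.lower() not in SUPPORTED_EXTENSIONS:
                continue
            if _side_from_filename(path.stem) == side:
                entries.append((path.stem, path))

    meshes = []
    manifest_map: dict[str, str] = {}
    seen: set[str] = set()
    for mesh_id, path in entries:
        if mesh_id in seen:
            raise DuplicateIdError(f"duplicate specimen id {mesh_id!r} in {directory}")
        seen.add(mesh_id)
        try:
            meshes.append(read_mesh(path, id=mesh_id))
        except MeshFormatError as exc:
            raise MeshFormatError(f"while reading {path}: {exc}") from exc
        manifest_map[mesh_id] = str(path)
    return SpecimenSet(side=side, meshes=meshes, manifest=manifest_map)
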