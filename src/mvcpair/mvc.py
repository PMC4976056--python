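"""The mesh-to-mesh value: one millimetre-scale number per registered pair.

After two-stage registration the residual difference between a left bone
and a mirrored right bone is summarised as the symmetric RMS
nearest-neighbour distance: the square root of the mean of squared
exact-NN distances taken in both directions under the final transform.
The metric is symmetric, is zero iff the surfaces coincide, and is
evaluated on *all* vertices of both meshes regardless of how the optimiser
sampled — the value characterises the surfaces, not the optimiser. Lower
values mean more similar bones; the all-vs-all table of values is the
object the pair-matching rule consumes.
"""

from __future__ import annotations

import io
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AlignmentFailureError, DegenerateGeometryError, MvcError
from .icp import AlignmentSettings, _Target, fine_align, rough_align
from .mesh_io import SpecimenSet, TriangleMesh
from .transforms import RigidTransform, mirror_mesh

logger = logging.getLogger(__name__)

VALUE_METRICS = ("symmetric_rms", "mean_absolute", "hausdorff", "one_directional_rms")


@dataclass
class MeshToMeshValue:
    """A single registration summarised as one value in millimetres."""

    left_id: str
    right_id: str
    value: float
    transform: Optional[RigidTransform] = None
    failed: bool = False
    residual_trace: list[float] = field(default_factory=list)


def surface_distance(
    left_points: np.ndarray, right_points: np.ndarray, metric: str = "symmetric_rms"
) -> float:
    """Distance between two aligned vertex clouds under the chosen metric."""
    d_lr, _ = cKDTree(right_points).query(left_points)
    d_rl, _ = cKDTree(left_points).query(right_points)
    if metric == "symmetric_rms":
        return float(
            np.sqrt((np.sum(d_lr**2) + np.sum(d_rl**2)) / (len(d_lr) + len(d_rl)))
        )
    if metric == "mean_absolute":
        return float(np.concatenate([d_lr, d_rl]).mean())
    if metric == "hausdorff":
        return float(max(d_lr.max(), d_rl.max()))
    if metric == "one_directional_rms":
        return float(np.sqrt(np.mean(d_lr**2)))
    raise ValueError(f"unknown value metric {metric!r}; choose from {VALUE_METRICS}")


def mesh_to_mesh_value(
    left: TriangleMesh,
    right_mirrored: TriangleMesh,
    settings: Optional[AlignmentSettings] = None,
) -> MeshToMeshValue:
    """Register two meshes (rough then fine) and compute their value.

    The registration direction is canonicalised (the lexicographically
    smaller id is the moving mesh) so that swapping the arguments returns
    the identical value; the reported transform always maps the left mesh
    into the frame of the mirrored right mesh. An alignment failure is
    reported as a failed value (NaN), never as a silently large number.
    """
    settings = settings or AlignmentSettings()
    swap = (right_mirrored.id, right_mirrored.n_vertices) < (left.id, left.n_vertices)
    source, target = (right_mirrored, left) if swap else (left, right_mirrored)
    cache = _Target(target)
    try:
        rough = rough_align(source, target, settings, target_cache=cache)
        fine = fine_align(source, target, rough.transform, settings, target_cache=cache)
    except (AlignmentFailureError, DegenerateGeometryError) as exc:
        logger.warning(
            "alignment failed for (%s, %s): %s", left.id, right_mirrored.id, exc
        )
        return MeshToMeshValue(left.id, right_mirrored.id, float("nan"), None, True)
    value = surface_distance(
        fine.transform.apply(source.vertices), target.vertices, settings.value_metric
    )
    transform = fine.transform.inverse() if swap else fine.transform
    return MeshToMeshValue(
        left.id, right_mirrored.id, value, transform, False, fine.residual_trace
    )


@dataclass
class ComparisonMatrix:
    """Left x right table of mesh-to-mesh values in millimetres.

    Failed registrations are stored as NaN and written as ``NA``; the
    matching rule treats them as absent candidates, never as evidence
    either way.
    """

    values: pd.DataFrame
    transforms: dict[tuple[str, str], RigidTransform] = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.values.to_numpy(dtype=float)
        if np.nanmin(finite, initial=0.0) < 0:
            raise MvcError("mesh-to-mesh values must be non-negative")

    @property
    def left_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def right_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_failed(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def to_csv(self, path: str | Path | None = None) -> str:
        """CSV with left ids in the first column, right ids as the header,
        cells in mm with 6 significant digits, ``NA`` for failed cells."""
        buf = io.StringIO()
        self.values.to_csv(
            buf, float_format="%.6g", na_rep="NA", index_label="left_id"
        )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComparisonMatrix":
        try:
            df = pd.read_csv(path, index_col=0, na_values=["NA"])
            df.index = df.index.astype(str)
            df.columns = df.columns.astype(str)
            values = df.astype(float)
        except (ValueError, pd.errors.ParserError) as exc:
            raise MvcError(f"malformed comparison matrix {path}: {exc}") from exc
        if values.size == 0:
            raise MvcError(f"comparison matrix {path} is empty")
        return cls(values)


def cell_seed(global_seed: int, left_id: str, right_id: str) -> int:
    """Stable per-cell seed below 2**31, so cells can be computed in any
    order (or in parallel) with identical results."""
    key = f"{global_seed}:{left_id}:{right_id}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def compare_all(
    lefts: SpecimenSet,
    rights: SpecimenSet,
    settings: Optional[AlignmentSettings] = None,
    mirror: bool = True,
    n_jobs: int = 1,
) -> ComparisonMatrix:
    """Mirror every right mesh once and compute all left x right values.

    Each cell uses a seed derived from the global seed and the two ids, so
    the result is independent of evaluation order and of ``n_jobs``.
    """
    if len(lefts) == 0 or len(rights) == 0:
        raise MvcError("both specimen sets must be nonempty")
    settings = settings or AlignmentSettings()
    mirrored = [mirror_mesh(m).with_id(m.id) if mirror else m for m in rights]

    def one_cell(left: TriangleMesh, right: TriangleMesh) -> MeshToMeshValue:
        cell = settings.replace(seed=cell_seed(settings.seed, left.id, right.id))
        return mesh_to_mesh_value(left, right, cell)

    tasks = [(left, right) for left in lefts for right in mirrored]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one_cell)(l, r) for l, r in tasks)
    else:
        results = []
        for i, (left, right) in enumerate(tasks, 1):
            results.append(one_cell(left, right))
            logger.info(
                "compare_all: %d/%d (%s vs %s)", i, len(tasks), left.id, right.id
            )
    values = pd.DataFrame(
        np.array([r.value for r in results]).reshape(len(lefts), len(mirrored)),
        index=pd.Index(lefts.ids, name="left_id"),
        columns=[m.id for m in mirrored],
    )
    transforms = {
        (r.left_id, r.right_id): r.transform for r in results if r.transform is not None
    }
    return ComparisonMatrix(values, transforms)


# -- deviation maps ---------------------------------------------------------

BAND_WITHIN = "within"
BAND_LARGER = "larger"
BAND_SMALLER = "smaller"


@dataclass
class DeviationMap:
    """Per-vertex signed deviation of a comparison mesh from a reference.

    Positive distances mean the comparison surface lies outside the
    reference (along the reference normals); band labels classify each
    vertex against a half-width in mm, mimicking the colour-coded deviation
    rendering used to inspect where two bones differ.
    """

    signed_distance: np.ndarray
    band: np.ndarray
    band_halfwidth: float

    @property
    def fraction_within(self) -> float:
        return float(np.mean(self.band == BAND_WITHIN))


def deviation_map(
    reference: TriangleMesh,
    comparison: TriangleMesh,
    transform: Optional[RigidTransform] = None,
    band: float = 0.645,
) -> DeviationMap:
    """Signed nearest-vertex distances from comparison to reference.

    ``transform`` (from a completed registration) maps the comparison mesh
    into the reference frame; the sign comes from the reference vertex
    normal. The default band half-width of 0.645 mm is a convenient scale
    for humeri, where sub-band regions read as 'same size'.
    """
    points = comparison.vertices if transform is None else transform.apply(
        comparison.vertices
    )
    tree = cKDTree(reference.vertices)
    dist, idx = tree.query(points)
    offset = points - reference.vertices[idx]
    sign = np.sign(np.einsum("ij,ij->i", offset, reference.vertex_normals[idx]))
    sign[sign == 0] = 1.0
    signed = dist * sign
    labels = np.where(
        np.abs(signed) < band,
        BAND_WITHIN,
        np.where(signed > 0, BAND_LARGER, BAND_SMALLER),
    )
    return DeviationMap(signed, labels, band)


def write_deviation_ply(
    comparison: TriangleMesh,
    devmap: DeviationMap,
    path: str | Path,
    transform: Optional[RigidTransform] = None,
) -> Path:
    """Write the comparison mesh as ASCII PLY with a per-vertex signed
    deviation scalar and a band label code (0 within, 1 larger, 2 smaller)."""
    path = Path(path)
    verts = comparison.vertices if transform is None else transform.apply(
        comparison.vertices
    )
    codes = {BAND_WITHIN: 0, BAND_LARGER: 1, BAND_SMALLER: 2}
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(verts)}",
        "property float x",
        "property float y",
        "property float z",
        "property float deviation",
        "property uchar band",
        f"element face {comparison.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, d, b in zip(verts, devmap.signed_distance, devmap.band):
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {d:.6f} {codes[str(b)]}")
    for f in comparison.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")
    return path
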