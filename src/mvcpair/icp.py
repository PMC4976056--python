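"""Two-stage rigid registration by iterative closest point (ICP).

The registration recipe mimics the automated comparison protocol for
bilateral bone matching:

* **rough stage** — multi-start point-to-point ICP on a small fixed random
  subsample (1 % of source vertices by default) with approximate
  nearest-neighbour lookups; 20 starting orientations built from principal
  axes, their proper axis flips, and quasi-uniform rotations.
* **fine stage** — point-to-plane ICP on all source vertices with exact
  nearest neighbours, correspondences rejected when surface normals
  disagree by more than a compatibility angle, optionally trimmed to the
  best ``overlap_fraction`` of residuals.

Both stages run a fixed iteration budget (100 by default) with an early
stop when the RMS residual stops changing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import AlignmentFailureError, DegenerateGeometryError
from .mesh_io import TriangleMesh
from .transforms import RigidTransform, _nearest_rotation, compose

NN_APPROXIMATE = "approximate"
NN_EXACT = "exact"
NN_EXACT_NORMAL = "exact_normal_compatible"

#: slack of the approximate KD-tree query: returned neighbours are within
#: (1 + eps) of the true nearest distance.
APPROX_NN_EPS = 0.1


@dataclass
class AlignmentSettings:
    """Every knob of the two-stage registration.

    Defaults follow the automated comparison protocol: estimated overlap
    100 % (no residual trimming), 20 initial positions for the rough
    alignment, rough stage point-to-point with approximate nearest
    neighbours on a 1 % point sample, fine stage point-to-plane with exact
    normal-compatible nearest neighbours on 100 % of points, 100 iterations
    each. The convergence tolerance, compatibility angle and approximate-NN
    slack are implementation parameters; the protocol fixes only the
    iteration caps.
    """

    overlap_fraction: float = 1.0
    n_initial_positions: int = 20
    rough_sampling: float = 0.01
    rough_metric: str = "point_to_point"
    rough_nn: str = NN_APPROXIMATE
    rough_iterations: int = 100
    fine_sampling: float = 1.0
    fine_metric: str = "point_to_plane"
    fine_nn: str = NN_EXACT_NORMAL
    fine_iterations: int = 100
    normal_angle_max: float = 45.0
    convergence_tol: float = 1e-7
    seed: int = 0
    approx_nn_eps: float = APPROX_NN_EPS
    value_metric: str = "symmetric_rms"
    #: redraw the rough-stage sample every iteration instead of fixing it
    #: per run (both deterministic given the seed)
    resample_each_iteration: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.rough_sampling <= 1.0 and 0.0 < self.fine_sampling <= 1.0):
            raise ValueError("sampling fractions must be in (0, 1]")
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.rough_iterations < 1 or self.fine_iterations < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.n_initial_positions < 1:
            raise ValueError("n_initial_positions must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AlignmentSettings":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def from_file(cls, path: str | Path) -> "AlignmentSettings":
        """Load from a JSON or TOML config file (by extension)."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                return cls(**tomllib.load(fh))
        return cls.from_json(path)

    def replace(self, **kwargs) -> "AlignmentSettings":
        return replace(self, **kwargs)


@dataclass
class AlignmentResult:
    """Outcome of one registration stage.

    ``transform`` maps source coordinates into the target frame;
    ``rms_residual`` is the RMS nearest-neighbour distance (mm) of the
    points the stage optimised over.
    """

    transform: RigidTransform
    rms_residual: float
    n_iterations_run: int
    converged: bool
    residual_trace: list[float] = field(default_factory=list)


@dataclass
class NeighborResult:
    """Nearest-neighbour correspondences against a target mesh."""

    indices: np.ndarray
    points: np.ndarray
    normals: np.ndarray
    distances: np.ndarray
    accepted: np.ndarray


class _Target:
    """A target mesh with its KD-tree and normals, built once per registration."""

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        self.vertices = mesh.vertices
        self.normals = mesh.vertex_normals
        self.tree = cKDTree(mesh.vertices)


def nearest_neighbors(
    query_points: np.ndarray,
    target: TriangleMesh | _Target,
    mode: str = NN_EXACT,
    query_normals: Optional[np.ndarray] = None,
    angle_max: float = 45.0,
    eps: float = APPROX_NN_EPS,
) -> NeighborResult:
    """Nearest target vertices for a set of query points.

    ``approximate`` mode may return any vertex within ``(1 + eps)`` of the
    true nearest distance; ``exact`` returns the true nearest vertex;
    ``exact_normal_compatible`` additionally marks a correspondence
    rejected when query and target normals subtend more than ``angle_max``
    degrees (zero normals never pass the test).
    """
    if not isinstance(target, _Target):
        target = _Target(target)
    query_points = np.asarray(query_points, dtype=np.float64).reshape(-1, 3)
    if len(query_points) == 0:
        empty = np.empty(0)
        return NeighborResult(
            np.empty(0, dtype=np.int64),
            np.empty((0, 3)),
            np.empty((0, 3)),
            empty,
            np.empty(0, dtype=bool),
        )
    if mode == NN_APPROXIMATE:
        dist, idx = target.tree.query(query_points, eps=eps)
    elif mode in (NN_EXACT, NN_EXACT_NORMAL):
        dist, idx = target.tree.query(query_points)
    else:
        raise ValueError(f"unknown nearest-neighbour mode: {mode!r}")
    accepted = np.ones(len(query_points), dtype=bool)
    if mode == NN_EXACT_NORMAL:
        if query_normals is None:
            raise ValueError("normal-compatible mode requires query_normals")
        query_normals = np.asarray(query_normals, dtype=np.float64).reshape(-1, 3)
        tn = target.normals[idx]
        cos = np.einsum("ij,ij->i", query_normals, tn)
        valid = (np.linalg.norm(query_normals, axis=1) > 0) & (
            np.linalg.norm(tn, axis=1) > 0
        )
        accepted = valid & (cos >= np.cos(np.radians(angle_max)))
    return NeighborResult(idx, target.vertices[idx], target.normals[idx], dist, accepted)


# -- single-step rigid estimators -------------------------------------------


def estimate_rigid_point_to_point(
    source_points: np.ndarray,
    target_points: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> RigidTransform:
    """Least-squares rigid motion mapping source points onto target points
    (Kabsch/Procrustes via SVD, reflection-guarded)."""
    src = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if len(src) < 3 or len(src) != len(tgt):
        raise DegenerateGeometryError(
            f"need >=3 paired correspondences, got {len(src)}/{len(tgt)}"
        )
    if weights is None:
        w = np.full(len(src), 1.0 / len(src))
    else:
        w = np.asarray(weights, dtype=np.float64)
        total = w.sum()
        if total <= 0:
            raise DegenerateGeometryError("correspondence weights sum to zero")
        w = w / total
    mu_s = w @ src
    mu_t = w @ tgt
    src_c = src - mu_s
    tgt_c = tgt - mu_t
    cov = (src_c * w[:, None]).T @ tgt_c
    u, s, vt = np.linalg.svd(cov)
    # collinear points leave the rotation about the line unconstrained
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError(
            "correspondences are collinear; rotation about the line is unconstrained"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return RigidTransform(rot, mu_t - rot @ mu_s)


def estimate_rigid_point_to_plane(
    source_points: np.ndarray,
    target_points: np.ndarray,
    target_normals: np.ndarray,
) -> RigidTransform:
    """Rigid motion minimising the point-to-plane error
    ``sum(((R s + t - q) . n)^2)``.

    Solved with the standard small-angle linearisation as a 6x6 normal
    system; the linearised rotation is projected back onto SO(3) by SVD.
    Raises when the system is ill-conditioned (e.g. all normals parallel),
    naming the unconstrained motion.
    """
    src = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    nrm = np.asarray(target_normals, dtype=np.float64).reshape(-1, 3)
    n = len(src)
    if n < 6 or len(tgt) != n or len(nrm) != n:
        raise DegenerateGeometryError(
            f"need >=6 correspondences with normals, got {n}"
        )
    a = np.empty((n, 6))
    a[:, :3] = np.cross(src, nrm)
    a[:, 3:] = nrm
    b = np.einsum("ij,ij->i", tgt - src, nrm)
    ata = a.T @ a
    atb = a.T @ b
    eigvals, eigvecs = np.linalg.eigh(ata)
    scale = max(eigvals[-1], 1e-300)
    if eigvals[0] <= 1e-10 * scale:
        null = eigvecs[:, 0]
        raise DegenerateGeometryError(
            "point-to-plane system is rank deficient; unconstrained motion: "
            f"rotation axis ~ {np.round(null[:3], 3).tolist()}, "
            f"translation ~ {np.round(null[3:], 3).tolist()}"
        )
    x = np.linalg.solve(ata, atb)
    omega, t = x[:3], x[3:]
    skew = np.array(
        [
            [0.0, -omega[2], omega[1]],
            [omega[2], 0.0, -omega[0]],
            [-omega[1], omega[0], 0.0],
        ]
    )
    rot = _nearest_rotation(np.eye(3) + skew)
    return RigidTransform(rot, t)


# -- stage drivers ----------------------------------------------------------


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Right-handed principal axes (columns), largest variance first."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axes = eigvecs[:, ::-1]  # descending variance
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1
    return axes


_PROPER_FLIPS = (
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)


def initial_positions(
    source: TriangleMesh,
    target: TriangleMesh,
    n_positions: int,
    seed: int,
) -> list[RigidTransform]:
    """Candidate starting transforms for the rough stage.

    The first four candidates align the principal axes of the source with
    those of the target under the four proper axis flips (covering the
    180-degree ambiguities of elongated bones); the remaining budget is
    filled with quasi-uniform random rotations about the matched centroids.
    """
    axes_s = _principal_axes(source.vertices)
    axes_t = _principal_axes(target.vertices)
    mu_s = source.centroid
    mu_t = target.centroid
    rotations = [axes_t @ flip @ axes_s.T for flip in _PROPER_FLIPS]
    n_extra = max(0, n_positions - len(rotations))
    if n_extra:
        rng = np.random.default_rng(seed)
        extra = Rotation.random(n_extra, random_state=rng)
        base = rotations[0]
        rotations.extend(r.as_matrix() @ base for r in extra)
    rotations = rotations[:n_positions]
    return [RigidTransform(rot, mu_t - rot @ mu_s) for rot in rotations]


def _icp_point_to_point(
    sample: np.ndarray,
    target: _Target,
    start: RigidTransform,
    max_iterations: int,
    tol: float,
    nn_mode: str,
    eps: float,
    resample_pool: Optional[np.ndarray] = None,
    resample_rng: Optional[np.random.Generator] = None,
) -> AlignmentResult:
    """Point-to-point ICP from one start.

    Trace entries record the RMS at correspondence time, so with exact
    neighbours the trace is the classic nonincreasing ICP objective; with
    the approximate query it may overestimate by at most the query slack.
    The best transform seen is returned, which makes the result robust to
    the (rare, slack-sized) non-monotone step of the approximate mode.
    When a resampling pool and generator are given, the sample is redrawn
    from the pool every iteration (still deterministic given the seed)."""
    transform = start
    trace: list[float] = []
    converged = False
    best: tuple[float, RigidTransform] = (np.inf, start)
    prev_rms = None
    iterations = 0
    query_eps = eps if nn_mode == NN_APPROXIMATE else 0.0
    for iterations in range(1, max_iterations + 1):
        if resample_pool is not None and resample_rng is not None:
            idx_pool = resample_rng.choice(
                len(resample_pool), size=len(sample), replace=False
            )
            sample = resample_pool[idx_pool]
        moved = transform.apply(sample)
        dist, idx = target.tree.query(moved, eps=query_eps)
        rms = float(np.sqrt(np.mean(dist**2)))
        trace.append(rms)
        if rms < best[0]:
            best = (rms, transform)
        if prev_rms is not None and abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
        try:
            step = estimate_rigid_point_to_point(moved, target.vertices[idx])
        except DegenerateGeometryError:
            # tiny samples can collapse onto collinear target vertices; the
            # start simply cannot be refined further
            break
        transform = compose(transform, step)
    return AlignmentResult(best[1], best[0], iterations, converged, trace)


def rough_align(
    source: TriangleMesh,
    target: TriangleMesh,
    settings: Optional[AlignmentSettings] = None,
    target_cache: Optional[_Target] = None,
) -> AlignmentResult:
    """Multi-start coarse registration of ``source`` onto ``target``.

    A fixed random subsample of the source vertices (seeded) is registered
    from every candidate start by point-to-point ICP with approximate
    nearest neighbours; candidates are then ranked by exact-NN RMS on a
    denser evaluation subset (small 1 % samples are too noisy to rank 20
    finishes reliably) and the best transform is returned. Deterministic
    given the seed.
    """
    settings = settings or AlignmentSettings()
    tgt = target_cache or _Target(target)
    rng = np.random.default_rng(settings.seed)
    n = source.n_vertices
    n_sample = min(n, max(4, int(np.ceil(settings.rough_sampling * n))))
    sample_idx = rng.choice(n, size=n_sample, replace=False)
    sample = source.vertices[sample_idx]
    n_eval = min(n, max(n_sample, 1000))
    eval_idx = rng.choice(n, size=n_eval, replace=False)
    eval_points = source.vertices[eval_idx]

    starts = initial_positions(
        source, target, settings.n_initial_positions, settings.seed
    )
    best: Optional[AlignmentResult] = None
    best_eval = np.inf
    for start_index, start in enumerate(starts):
        run = _icp_point_to_point(
            sample,
            tgt,
            start,
            settings.rough_iterations,
            settings.convergence_tol,
            settings.rough_nn,
            settings.approx_nn_eps,
            resample_pool=source.vertices if settings.resample_each_iteration else None,
            resample_rng=np.random.default_rng([settings.seed, start_index])
            if settings.resample_each_iteration
            else None,
        )
        dist, _ = tgt.tree.query(run.transform.apply(eval_points))
        eval_rms = float(np.sqrt(np.mean(dist**2)))
        if eval_rms < best_eval:
            best_eval = eval_rms
            best = AlignmentResult(
                run.transform, eval_rms, run.n_iterations_run, run.converged, run.residual_trace
            )
    assert best is not None
    return best


def fine_align(
    source: TriangleMesh,
    target: TriangleMesh,
    initial: RigidTransform,
    settings: Optional[AlignmentSettings] = None,
    target_cache: Optional[_Target] = None,
) -> AlignmentResult:
    """Point-to-plane refinement from an initial transform.

    Uses all source vertices (at the default 100 % sampling), exact nearest
    neighbours, normal-compatibility rejection, and residual trimming to
    ``overlap_fraction`` (1.0 = keep everything). Raises
    :class:`AlignmentFailureError` when every correspondence is rejected.
    """
    settings = settings or AlignmentSettings()
    tgt = target_cache or _Target(target)
    n = source.n_vertices
    if settings.fine_sampling < 1.0:
        rng = np.random.default_rng(settings.seed + 1)
        n_sample = min(n, max(6, int(np.ceil(settings.fine_sampling * n))))
        idx = rng.choice(n, size=n_sample, replace=False)
        points = source.vertices[idx]
        normals = source.vertex_normals[idx]
    else:
        points = source.vertices
        normals = source.vertex_normals

    cos_max = np.cos(np.radians(settings.normal_angle_max))
    scale = source.bbox_diagonal
    transform = initial
    trace: list[float] = []
    converged = False
    prev_rms = None
    iterations = 0
    # rotations preserve normal lengths, so zero-normal (isolated) vertices
    # can be masked once up front
    source_valid = np.linalg.norm(normals, axis=1) > 0
    target_valid = np.linalg.norm(tgt.normals, axis=1) > 0
    for iterations in range(1, settings.fine_iterations + 1):
        moved = transform.apply(points)
        moved_normals = transform.apply_normals(normals)
        dist, idx_t = tgt.tree.query(moved)
        tn = tgt.normals[idx_t]
        cos = np.einsum("ij,ij->i", moved_normals, tn)
        accepted = source_valid & target_valid[idx_t] & (cos >= cos_max)
        if settings.overlap_fraction < 1.0 and accepted.sum() > 0:
            keep = max(6, int(np.floor(settings.overlap_fraction * accepted.sum())))
            cutoff = np.partition(dist[accepted], keep - 1)[keep - 1]
            accepted &= dist <= cutoff
        n_acc = int(accepted.sum())
        if n_acc < 6:
            raise AlignmentFailureError(
                f"fine alignment rejected all correspondences "
                f"({n_acc} of {len(points)} accepted)"
            )
        rms = float(np.sqrt(np.mean(dist[accepted] ** 2)))
        trace.append(rms)
        if prev_rms is not None and abs(prev_rms - rms) < settings.convergence_tol:
            converged = True
            break
        prev_rms = rms
        try:
            step = estimate_rigid_point_to_plane(
                moved[accepted], tgt.vertices[idx_t[accepted]], tn[accepted]
            )
        except DegenerateGeometryError:
            # the accepted set no longer constrains all six degrees of
            # freedom (e.g. only a near-cylindrical patch survives the
            # normal gate on a badly mismatched pair); the current
            # alignment is still a valid measurement, so stop refining
            break
        # a negligible increment means a fixed point: correspondences can
        # no longer change, so stop without spending the iteration budget
        step_motion = np.linalg.norm(step.translation) + 0.5 * scale * np.linalg.norm(
            step.rotation - np.eye(3)
        )
        if step_motion < settings.convergence_tol:
            converged = True
            break
        transform = compose(transform, step)
    return AlignmentResult(transform, trace[-1], iterations, converged, trace)
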