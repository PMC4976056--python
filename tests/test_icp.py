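import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mvcpair import (
    AlignmentSettings,
    DegenerateGeometryError,
    RigidTransform,
    TriangleMesh,
    apply_transform,
    estimate_rigid_point_to_plane,
    estimate_rigid_point_to_point,
    fine_align,
    nearest_neighbors,
    rough_align,
)
from mvcpair.icp import NN_APPROXIMATE, NN_EXACT, NN_EXACT_NORMAL, _icp_point_to_point, _Target


def random_transform(seed, tmax=50.0):
    rng = np.random.default_rng(seed)
    return RigidTransform(
        Rotation.random(random_state=rng).as_matrix(), rng.uniform(-tmax, tmax, 3)
    )


class TestNearestNeighbors:
    def test_query_at_target_vertex_is_zero(self, bone_coarse):
        res = nearest_neighbors(bone_coarse.vertices[:5], bone_coarse, NN_EXACT)
        np.testing.assert_allclose(res.distances, 0.0, atol=1e-12)
        np.testing.assert_array_equal(res.indices, np.arange(5))

    def test_exact_matches_brute_force(self, bone, rng):
        # O(n^2) oracle on 200 random query points
        queries = rng.uniform(-50, 350, (200, 3))
        res = nearest_neighbors(queries, bone, NN_EXACT)
        brute = np.linalg.norm(
            queries[:, None, :] - bone.vertices[None, :, :], axis=-1
        ).argmin(axis=1)
        np.testing.assert_array_equal(res.indices, brute)

    def test_approximate_within_slack(self, bone, rng):
        queries = rng.uniform(-50, 350, (200, 3))
        exact = nearest_neighbors(queries, bone, NN_EXACT)
        approx = nearest_neighbors(queries, bone, NN_APPROXIMATE)
        assert np.all(approx.distances <= (1.0 + 0.1) * exact.distances + 1e-12)

    def test_opposed_planes_all_rejected(self):
        # two coincident squares facing opposite ways: every normal pair is
        # 180 degrees apart, far beyond the 45-degree gate
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        up = TriangleMesh("up", verts, np.array([[0, 1, 2], [0, 2, 3]]))
        down = TriangleMesh("down", verts, np.array([[0, 2, 1], [0, 3, 2]]))
        res = nearest_neighbors(
            up.vertices, down, NN_EXACT_NORMAL, query_normals=up.vertex_normals,
            angle_max=45.0,
        )
        assert not res.accepted.any()

    def test_empty_query(self, bone_coarse):
        res = nearest_neighbors(np.empty((0, 3)), bone_coarse, NN_EXACT)
        assert len(res.distances) == 0

    def test_normal_mode_requires_normals(self, bone_coarse):
        with pytest.raises(ValueError):
            nearest_neighbors(bone_coarse.vertices[:3], bone_coarse, NN_EXACT_NORMAL)


class TestPointToPoint:
    def test_coincident_gives_identity(self, rng):
        pts = rng.uniform(-10, 10, (50, 3))
        t = estimate_rigid_point_to_point(pts, pts)
        assert t.is_identity(atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_known_motion(self, seed, rng):
        # construct-and-recover oracle
        src = rng.uniform(-20, 20, (100, 3))
        truth = random_transform(seed)
        t = estimate_rigid_point_to_point(src, truth.apply(src))
        np.testing.assert_allclose(t.rotation, truth.rotation, atol=1e-9)
        np.testing.assert_allclose(t.translation, truth.translation, atol=1e-9)

    def test_three_points_exact_fit(self, rng):
        src = rng.uniform(-5, 5, (3, 3))
        truth = random_transform(9)
        tgt = truth.apply(src)
        t = estimate_rigid_point_to_point(src, tgt)
        np.testing.assert_allclose(t.apply(src), tgt, atol=1e-9)

    def test_collinear_rejected(self):
        src = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_point_to_point(src, src + [0, 1, 0])

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_point_to_point(np.zeros((2, 3)), np.zeros((2, 3)))


class TestPointToPlane:
    def test_coincident_gives_identity(self, icosphere):
        t = estimate_rigid_point_to_plane(
            icosphere.vertices, icosphere.vertices, icosphere.vertex_normals
        )
        assert t.is_identity(atol=1e-9)

    def test_recovers_small_rigid_displacement(self, bone):
        # construct-and-recover oracle: a 0.1 mm translation plus a tiny
        # rotation is inside the small-angle regime, so one linearised step
        # must undo it to machine-level accuracy (note a sphere would not
        # do here: rotations about its centre are invisible to the
        # point-to-plane objective)
        normals = bone.vertex_normals
        small = RigidTransform(
            Rotation.from_rotvec([1e-5, -5e-6, 2e-6]).as_matrix(),
            [0.1, -0.05, 0.02],
        )
        src = small.apply(bone.vertices)
        t = estimate_rigid_point_to_plane(src, bone.vertices, normals)
        residual = np.einsum("ij,ij->i", t.apply(src) - bone.vertices, normals)
        assert np.abs(residual).max() < 1e-6

    def test_sphere_rotations_unconstrained(self, icosphere):
        # for a sphere every surface normal is radial, so rotations about
        # the centre drop out of the 6x6 system entirely (exact radial
        # normals; the faceted mesh normals are only near-singular)
        radial = icosphere.vertices / np.linalg.norm(
            icosphere.vertices, axis=1, keepdims=True
        )
        with pytest.raises(DegenerateGeometryError, match="unconstrained"):
            estimate_rigid_point_to_plane(
                icosphere.vertices, icosphere.vertices, radial
            )

    def test_parallel_normals_rejected(self, rng):
        src = rng.uniform(-10, 10, (50, 3))
        normals = np.tile([0.0, 0, 1], (50, 1))
        with pytest.raises(DegenerateGeometryError, match="unconstrained"):
            estimate_rigid_point_to_plane(src, src, normals)


class TestRoughAlign:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_arbitrary_pose(self, bone, seed):
        truth = random_transform(seed, tmax=150.0)
        moved = apply_transform(bone, truth)
        result = rough_align(moved, bone, AlignmentSettings(seed=seed))
        assert result.rms_residual < 1.0  # coarse: within fine-stage capture range

    def test_identical_meshes_from_pca_start(self, bone):
        result = rough_align(bone, bone, AlignmentSettings())
        assert result.rms_residual < 1e-9

    def test_multistart_no_worse_than_single_start(self, bone):
        truth = random_transform(5, tmax=100.0)
        moved = apply_transform(bone, truth)
        one = rough_align(moved, bone, AlignmentSettings(n_initial_positions=1, seed=2))
        many = rough_align(moved, bone, AlignmentSettings(n_initial_positions=20, seed=2))
        assert many.rms_residual <= one.rms_residual + 1e-12

    def test_per_iteration_resampling_mode(self, bone):
        # redrawing the 1 % sample each iteration must stay deterministic
        # and still land in the capture range of the fine stage
        moved = apply_transform(bone, random_transform(6, tmax=80.0))
        settings = AlignmentSettings(seed=4, resample_each_iteration=True)
        a = rough_align(moved, bone, settings)
        b = rough_align(moved, bone, settings)
        assert a.rms_residual == b.rms_residual
        assert a.rms_residual < 1.0

    def test_deterministic_given_seed(self, bone):
        moved = apply_transform(bone, random_transform(3))
        a = rough_align(moved, bone, AlignmentSettings(seed=7))
        b = rough_align(moved, bone, AlignmentSettings(seed=7))
        assert a.residual_trace == b.residual_trace
        np.testing.assert_array_equal(a.transform.as_matrix(), b.transform.as_matrix())


class TestFineAlign:
    def test_exact_initial_is_fixed_point(self, bone):
        result = fine_align(bone, bone, RigidTransform.identity(), AlignmentSettings())
        assert result.converged
        assert result.n_iterations_run == 1
        assert result.rms_residual < 1e-12
        assert result.transform.is_identity(atol=1e-9)

    def test_residual_at_noise_floor(self, bone, rng):
        # noise-floor oracle: with 0.2 mm surface noise the best achievable
        # RMS is about sigma, certainly below 3 sigma
        sigma = 0.2
        noisy = TriangleMesh(
            "noisy",
            bone.vertices + sigma * rng.standard_normal(bone.vertices.shape),
            bone.faces,
        )
        truth = random_transform(4, tmax=20.0)
        moved = apply_transform(noisy, truth)
        settings = AlignmentSettings(seed=1)
        rough = rough_align(moved, bone, settings)
        fine = fine_align(moved, bone, rough.transform, settings)
        assert fine.rms_residual < 3.0 * sigma

    def test_trimming_reduces_residual_under_damage(self, bone, rng):
        # simulated damage: 30 % of vertices pushed out 10 mm; keeping the
        # best 70 % of residuals must beat keeping everything
        damaged_vertices = bone.vertices.copy()
        n = len(damaged_vertices)
        idx = rng.choice(n, size=int(0.3 * n), replace=False)
        damaged_vertices[idx] += 10.0 * bone.vertex_normals[idx]
        damaged = TriangleMesh("damaged", damaged_vertices, bone.faces)
        full = fine_align(
            damaged, bone, RigidTransform.identity(),
            AlignmentSettings(overlap_fraction=1.0, normal_angle_max=89.0),
        )
        trimmed = fine_align(
            damaged, bone, RigidTransform.identity(),
            AlignmentSettings(overlap_fraction=0.7, normal_angle_max=89.0),
        )
        assert trimmed.rms_residual < full.rms_residual


class TestIcpProperties:
    def test_point_to_point_objective_nonincreasing(self, bone, rng):
        # classic ICP guarantee, checked with exact correspondences
        truth = random_transform(8, tmax=30.0)
        moved = apply_transform(bone, truth)
        sample = moved.vertices[rng.choice(bone.n_vertices, 200, replace=False)]
        start = RigidTransform(np.eye(3), bone.centroid - sample.mean(axis=0))
        run = _icp_point_to_point(
            sample, _Target(bone), start, 50, 0.0, NN_EXACT, 0.0
        )
        trace = np.array(run.residual_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_pose_invariance_of_registration(self, bone, seed):
        # residual after rough+fine must not depend on initial placement
        settings = AlignmentSettings(seed=3)
        results = []
        for pose_seed in (10 + seed, 20 + seed):
            moved = apply_transform(bone, random_transform(pose_seed, tmax=100.0))
            rough = rough_align(moved, bone, settings)
            fine = fine_align(moved, bone, rough.transform, settings)
            results.append(fine.rms_residual)
        assert abs(results[0] - results[1]) < 1e-6


class TestAlignmentSettings:
    def test_json_roundtrip(self, tmp_path):
        settings = AlignmentSettings(seed=42, overlap_fraction=0.8)
        path = tmp_path / "settings.json"
        settings.to_json(path)
        assert AlignmentSettings.from_json(path) == settings

    def test_toml_config(self, tmp_path):
        path = tmp_path / "settings.toml"
        path.write_text('seed = 9\nnormal_angle_max = 30.0\n')
        settings = AlignmentSettings.from_file(path)
        assert settings.seed == 9
        assert settings.normal_angle_max == 30.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rough_sampling": 0.0},
            {"fine_sampling": 1.5},
            {"overlap_fraction": 0.0},
            {"rough_iterations": 0},
            {"n_initial_positions": 0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AlignmentSettings(**kwargs)
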