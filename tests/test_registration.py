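import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from jawmotion import (
    ExcursionParams,
    PoseLabel,
    RegistrationError,
    RigidTransform,
    break_correspondence,
    estimate_pose_set,
    generate_arch_mesh,
    generate_pose_records,
    icp,
    kabsch,
    kabsch_fit,
    rebase_anchor,
    rotation_angle_between,
)
from jawmotion.motion import apply_pose
from jawmotion.registration import PoseSet


def rot_z(deg):
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


NON_COPLANAR = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


class TestRigidTransform:
    def test_identity(self):
        t = RigidTransform.identity()
        assert t.rotation_angle() == 0.0
        assert t.translation_norm() == 0.0
        np.testing.assert_array_equal(t.matrix, np.eye(4))

    def test_quaternion_normalized_and_canonical(self):
        t = RigidTransform(np.array([-2.0, 0.0, 0.0, 0.0]), np.zeros(3))
        np.testing.assert_allclose(t.quaternion, [1, 0, 0, 0], atol=0)
        assert abs(np.linalg.norm(t.quaternion) - 1) <= 1e-9

    def test_rejects_zero_quaternion(self):
        with pytest.raises(ValueError):
            RigidTransform(np.zeros(4), np.zeros(3))

    def test_rejects_bad_translation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.array([1.0, 0, 0, 0]), np.array([1.0, np.inf, 0.0]))

    def test_determinant_plus_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = rng.normal(size=4)
            t = RigidTransform(q, rng.normal(size=3))
            assert np.linalg.det(t.rotation_matrix) == pytest.approx(1.0, abs=1e-9)

    def test_compose_matches_matrix_product(self):
        rng = np.random.default_rng(1)
        a = RigidTransform(rng.normal(size=4), rng.normal(size=3))
        b = RigidTransform(rng.normal(size=4), rng.normal(size=3))
        np.testing.assert_allclose(a.compose(b).matrix, a.matrix @ b.matrix, atol=1e-12)

    def test_from_matrix_round_trip(self):
        rng = np.random.default_rng(2)
        t = RigidTransform(rng.normal(size=4), rng.normal(size=3))
        t2 = RigidTransform.from_matrix(t.matrix)
        assert t.isclose(t2, atol=1e-12)


class TestKabsch:
    def test_identity_on_equal_sets(self):
        t = kabsch(NON_COPLANAR, NON_COPLANAR)
        assert t.rotation_angle() <= 1e-12
        assert t.translation_norm() <= 1e-12

    def test_recovers_generating_transform(self):
        rng = np.random.default_rng(42)
        src = rng.normal(scale=10.0, size=(50, 3))
        rotation = rot_z(30.0)
        translation = np.array([1.0, 2.0, 3.0])
        tgt = src @ rotation.T + translation
        truth = RigidTransform.from_rotation_translation(rotation, translation)
        est = kabsch(src, tgt)
        assert rotation_angle_between(est, truth) <= 1e-9
        assert np.linalg.norm(est.translation - truth.translation) <= 1e-9

    def test_mirror_target_gets_proper_rotation(self):
        rng = np.random.default_rng(7)
        src = rng.normal(size=(30, 3))
        src[:, 2] = 0.0  # planar
        tgt = src.copy()
        tgt[:, 0] *= -1  # mirror image
        fit = kabsch_fit(src, tgt)
        assert np.linalg.det(fit.transform.rotation_matrix) == pytest.approx(1.0, abs=1e-9)
        assert fit.rms > 0

    def test_residual_optimality_brute_force(self):
        # closed form must beat 10k random proper rotations (with optimal
        # translation for each) on small instances
        rng = np.random.default_rng(11)
        for n in (3, 4, 5):
            src = rng.normal(scale=5.0, size=(n, 3))
            tgt = rng.normal(scale=5.0, size=(n, 3))
            fit = kabsch_fit(src, tgt)
            rots = Rotation.random(10_000, rng=rng).as_matrix()
            src_c = src - src.mean(axis=0)
            tgt_c = tgt - tgt.mean(axis=0)
            rotated = np.einsum("kij,nj->kni", rots, src_c)
            rss = np.sum((rotated - tgt_c) ** 2, axis=(1, 2))
            assert n * fit.rms**2 <= rss.min() + 1e-9

    def test_too_few_points(self):
        with pytest.raises(RegistrationError, match="at least 3"):
            kabsch(NON_COPLANAR[:2], NON_COPLANAR[:2])

    def test_mismatched_lengths(self):
        with pytest.raises(RegistrationError):
            kabsch(NON_COPLANAR, NON_COPLANAR[:3])

    def test_coincident_points_rejected(self):
        pts = np.ones((4, 3))
        with pytest.raises(RegistrationError, match="coincident"):
            kabsch(pts, pts)

    def test_collinear_flagged_degenerate(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        fit = kabsch_fit(src, src + [0.0, 1.0, 0.0])
        assert fit.degenerate
        assert not kabsch_fit(NON_COPLANAR, NON_COPLANAR).degenerate

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_never_a_reflection(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.normal(size=(rng.integers(3, 12), 3))
        tgt = rng.normal(size=src.shape)
        t = kabsch(src, tgt)
        assert np.linalg.det(t.rotation_matrix) == pytest.approx(1.0, abs=1e-9)


class TestICP:
    def test_identity_on_same_mesh(self, arch):
        result = icp(arch, arch)
        assert result.converged
        assert result.rms <= 1e-9
        assert result.transform.rotation_angle() <= 1e-9

    def test_agrees_with_kabsch_when_corresponded(self, arch):
        t = RigidTransform(np.array([0.999, 0.01, 0.015, 0.02]), np.array([0.5, -0.8, 0.3]))
        target = apply_pose(arch, t)
        direct = kabsch(arch.vertices, target.vertices)
        result = icp(arch, target)
        assert result.converged
        assert np.linalg.norm(result.transform.translation - direct.translation) <= 1e-6
        assert rotation_angle_between(result.transform, direct) <= 1e-6

    def test_recovers_motion_with_shuffled_vertices(self, arch):
        rotation = rot_z(2.0)
        translation = np.array([1.0, 0.0, 0.0])
        truth = RigidTransform.from_rotation_translation(rotation, translation)
        moved = apply_pose(arch, truth)
        shuffled = break_correspondence(moved, seed=3)
        result = icp(arch, shuffled, max_iterations=100)
        assert result.converged
        assert rotation_angle_between(result.transform, truth) <= 1e-3
        assert np.linalg.norm(result.transform.translation - truth.translation) <= 1e-3

    def test_non_converged_flag(self, arch):
        t = RigidTransform(np.array([0.999, 0.0, 0.0, 0.04]), np.array([0.5, 0.0, 0.0]))
        result = icp(arch, apply_pose(arch, t), max_iterations=1)
        assert not result.converged  # one iteration cannot certify convergence

    def test_bad_iteration_count(self, arch):
        with pytest.raises(RegistrationError):
            icp(arch, arch, max_iterations=0)


class TestEstimatePoseSet:
    def test_identical_meshes_give_identities(self, arch):
        meshes = {label: arch for label in PoseLabel}
        ps = estimate_pose_set(meshes)
        for label in PoseLabel:
            assert ps.poses[label].rotation_angle() <= 1e-12
            assert ps.poses[label].translation_norm() <= 1e-12

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_noiseless_parameter_recovery(self, seed):
        mesh = generate_arch_mesh(500, seed=seed)
        records, truths = generate_pose_records(mesh, ExcursionParams(seed=seed))
        ps = estimate_pose_set(records)
        for label in PoseLabel:
            assert ps.provenance[label] in ("reference", "corresponded")
            assert rotation_angle_between(ps.poses[label], truths[label]) <= 1e-9
            assert (
                np.linalg.norm(ps.poses[label].translation - truths[label].translation)
                <= 1e-9
            )

    def test_noisy_recovery_beats_sigma(self):
        # Monte-Carlo: with sigma = 0.05 mm the translation error on a
        # 1000-vertex arch shrinks like sigma/sqrt(n), far below sigma
        sigma = 0.05
        errors = []
        for seed in range(1, 21):
            mesh = generate_arch_mesh(1000, seed=seed)
            records, truths = generate_pose_records(
                mesh, ExcursionParams(noise_sigma=sigma, seed=seed)
            )
            ps = estimate_pose_set(records)
            for label in PoseLabel:
                if label is PoseLabel.MIP:
                    continue
                errors.append(
                    np.linalg.norm(ps.poses[label].translation - truths[label].translation)
                )
        assert np.mean(errors) < sigma

    def test_missing_label_errors_with_name(self, arch):
        meshes = {label: arch for label in PoseLabel if label is not PoseLabel.PROTRUSIVE}
        with pytest.raises(RegistrationError, match="PROTRUSIVE"):
            estimate_pose_set(meshes)

    def test_uncorresponded_without_icp_errors(self, arch):
        records, _ = generate_pose_records(arch, ExcursionParams(seed=2))
        records[PoseLabel.PROTRUSIVE] = break_correspondence(
            records[PoseLabel.PROTRUSIVE], seed=2
        )
        with pytest.raises(RegistrationError, match="ICP fallback is disabled"):
            estimate_pose_set(records, icp_enabled=False)

    def test_icp_fallback_provenance(self, arch):
        records, truths = generate_pose_records(arch, ExcursionParams(seed=2))
        records[PoseLabel.PROTRUSIVE] = break_correspondence(
            records[PoseLabel.PROTRUSIVE], seed=2
        )
        ps = estimate_pose_set(records)
        assert ps.provenance[PoseLabel.PROTRUSIVE].startswith("icp")
        assert ps.provenance[PoseLabel.LEFT_LATEROTRUSIVE] == "corresponded"
        truth = truths[PoseLabel.PROTRUSIVE]
        assert np.linalg.norm(
            ps.poses[PoseLabel.PROTRUSIVE].translation - truth.translation
        ) <= 1e-3

    def test_vertex_subset(self, arch):
        records, truths = generate_pose_records(arch, ExcursionParams(seed=4))
        ps = estimate_pose_set(records, vertex_indices=np.arange(0, arch.n_vertices, 7))
        truth = truths[PoseLabel.PROTRUSIVE]
        assert rotation_angle_between(ps.poses[PoseLabel.PROTRUSIVE], truth) <= 1e-9

    def test_pose_set_rejects_non_identity_mip(self, arch):
        bad = RigidTransform(np.array([1.0, 0, 0, 0]), np.array([1.0, 0, 0]))
        with pytest.raises(RegistrationError, match="identity"):
            PoseSet(
                reference_mesh=arch,
                poses={label: bad for label in PoseLabel},
                provenance={label: "corresponded" for label in PoseLabel},
            )


class TestRebaseAnchor:
    def test_identity(self):
        assert rebase_anchor(RigidTransform.identity()).isclose(
            RigidTransform.identity(), atol=1e-15
        )

    def test_group_inverse(self):
        rng = np.random.default_rng(5)
        t = RigidTransform(rng.normal(size=4), rng.normal(size=3))
        composed = t.compose(rebase_anchor(t))
        assert composed.rotation_angle() <= 1e-12
        assert composed.translation_norm() <= 1e-12

    def test_matches_matrix_inverse_oracle(self):
        t = RigidTransform.from_rotation_translation(rot_z(30.0), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            rebase_anchor(t).matrix, np.linalg.inv(t.matrix), atol=1e-12
        )
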