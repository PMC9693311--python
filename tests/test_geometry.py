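import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from earmorph import (
    CorrespondenceSet,
    PointCloud,
    RigidTransform,
    estimate_rigid,
    nearest_neighbors,
    reject_outliers,
)
from earmorph.errors import (
    DegenerateRegistrationError,
    InvalidInputError,
)


def brute_force_nn(src, tgt):
    d = np.linalg.norm(src[:, None, :] - tgt[None, :, :], axis=2)
    return d.argmin(axis=1), d.min(axis=1)


class TestPointCloud:
    def test_validates_shape_and_finiteness(self):
        with pytest.raises(InvalidInputError):
            PointCloud(np.zeros((0, 3)))
        with pytest.raises(InvalidInputError):
            PointCloud(np.array([[0.0, np.nan, 0.0]]))
        with pytest.raises(InvalidInputError):
            PointCloud(np.zeros((4, 2)))

    def test_transformed_round_trip(self, rng):
        pc = PointCloud(rng.random((20, 3)))
        ang = 0.3
        T = RigidTransform(
            np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]),
            np.array([1.0, -2.0, 0.5]),
        )
        back = pc.transformed(T).transformed(T.inverse())
        np.testing.assert_allclose(back.points, pc.points, atol=1e-12)


class TestRigidTransform:
    def test_rejects_reflection_and_non_orthonormal(self):
        with pytest.raises(InvalidInputError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
        with pytest.raises(InvalidInputError):
            RigidTransform(np.eye(3) * 1.5, np.zeros(3))

    def test_compose_then_invert_is_identity(self, rng):
        def random_rot(r):
            q = r.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            return np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])

        A = RigidTransform(random_rot(rng), rng.normal(size=3))
        B = RigidTransform(random_rot(rng), rng.normal(size=3))
        C = A.compose(B)  # apply B then A
        pts = rng.random((7, 3))
        np.testing.assert_allclose(C.apply(pts), A.apply(B.apply(pts)), atol=1e-12)
        np.testing.assert_allclose(C.inverse().apply(C.apply(pts)), pts, atol=1e-10)


class TestNearestNeighbors:
    def test_identity_matches_self_with_zero_distance(self, rng):
        pts = rng.random((50, 3))
        corr = nearest_neighbors(pts, pts)
        np.testing.assert_array_equal(corr.target_indices, np.arange(50))
        np.testing.assert_allclose(corr.distances, 0.0)
        assert corr.inlier_mask.all()

    def test_analytically_forced_match(self):
        corr = nearest_neighbors(
            np.array([[0.0, 0.0, 0.0]]), np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        )
        assert corr.target_indices[0] == 0
        assert corr.distances[0] == pytest.approx(1.0)

    def test_agrees_with_brute_force_oracle(self, rng):
        src, tgt = rng.random((100, 3)), rng.random((120, 3))
        corr = nearest_neighbors(src, tgt)
        idx, dist = brute_force_nn(src, tgt)
        np.testing.assert_array_equal(corr.target_indices, idx)
        np.testing.assert_allclose(corr.distances, dist, atol=1e-12)

    def test_empty_cloud_rejected(self):
        with pytest.raises(InvalidInputError):
            nearest_neighbors(np.zeros((0, 3)), np.ones((3, 3)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        src=arrays(float, (37, 3), elements=st.floats(-50, 50)),
        tgt=arrays(float, (41, 3), elements=st.floats(-50, 50)),
    )
    def test_property_matches_exhaustive_scan(self, src, tgt):
        corr = nearest_neighbors(src, tgt)
        _, dist = brute_force_nn(src, tgt)
        np.testing.assert_allclose(corr.distances, dist, atol=1e-9)


class TestRejectOutliers:
    def test_constant_distances_all_retained(self):
        corr = CorrespondenceSet(np.arange(5), np.arange(5), np.full(5, 2.5))
        out = reject_outliers(corr)
        assert out.inlier_mask.all()
        assert out.threshold == pytest.approx(2.5)

    def test_population_sd_convention_retains_borderline_point(self):
        # distances {0,0,0,0,100}: mean 20, population sd 40, th = 100; the
        # 100 is not strictly greater than th so everything is retained
        corr = CorrespondenceSet(np.arange(5), np.arange(5), [0, 0, 0, 0, 100.0])
        out = reject_outliers(corr)
        assert out.threshold == pytest.approx(100.0)
        assert out.inlier_mask.all()

    def test_clear_outlier_flagged(self):
        corr = CorrespondenceSet(np.arange(6), np.arange(6), [1, 1, 1, 1, 1, 50.0])
        out = reject_outliers(corr)
        assert out.inlier_mask.sum() == 5
        assert not out.inlier_mask[5]

    def test_flagged_set_monotone_in_distance(self, rng):
        d = np.sort(rng.exponential(1.0, size=40))
        out = reject_outliers(CorrespondenceSet(np.arange(40), np.arange(40), d))
        flagged = ~out.inlier_mask
        # if a point is flagged, every point with larger distance is flagged
        if flagged.any():
            first = np.argmax(flagged)
            assert flagged[first:].all()

    def test_too_few_inliers_is_degenerate(self):
        corr = CorrespondenceSet([0, 1], [0, 1], [1.0, 2.0])
        with pytest.raises(DegenerateRegistrationError):
            reject_outliers(corr)


class TestEstimateRigid:
    def test_identity_for_identical_sets(self, rng):
        pts = rng.random((10, 3))
        T = estimate_rigid(pts, pts)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-12)

    def test_recovers_known_transform(self, rng):
        pts = rng.random((25, 3))
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg about z
        t = np.array([1.0, 2.0, 3.0])
        T = estimate_rigid(pts, pts @ R.T + t)
        np.testing.assert_allclose(T.rotation, R, atol=1e-8)
        np.testing.assert_allclose(T.translation, t, atol=1e-8)

    def test_noisy_recovery_close_in_frobenius(self, rng):
        pts = rng.random((200, 3))
        ang = 0.4
        R = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        tgt = pts @ R.T + np.array([0.3, -0.2, 0.9]) + rng.normal(0, 0.01, (200, 3))
        T = estimate_rigid(pts, tgt)
        assert np.linalg.norm(T.rotation - R) < 1e-2

    def test_collinear_points_degenerate(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateRegistrationError):
            estimate_rigid(line, line + 1.0)

    def test_left_invariance_of_residual(self, rng):
        src = rng.random((30, 3))
        tgt = rng.random((30, 3))
        T = estimate_rigid(src, tgt)
        res = np.linalg.norm(T.apply(src) - tgt)
        ang = 1.1
        Q = np.array([[np.cos(ang), 0, np.sin(ang)], [0, 1, 0], [-np.sin(ang), 0, np.cos(ang)]])
        T2 = estimate_rigid(src @ Q.T, tgt @ Q.T)
        res2 = np.linalg.norm(T2.apply(src @ Q.T) - tgt @ Q.T)
        assert abs(res - res2) < 1e-10

    def test_no_reflection_even_when_it_fits_better(self, rng):
        pts = rng.random((12, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        T = estimate_rigid(pts, mirrored)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-10)
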