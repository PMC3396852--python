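"""Closed-form similarity registration: exactness, optimality, conventions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereoreg.registration import (
    CorrespondenceError,
    DegenerateGeometryError,
    EulerAngles,
    PointSet,
    SimilarityTransform,
    UnderdeterminedError,
    apply_transform,
    compose_euler_rotation,
    decompose_rotation,
    horn_register,
    registration_residual,
)

from .conftest import kabsch_register, multistart_lsq_sse

angles = st.floats(-math.pi, math.pi, allow_nan=False)


def random_similarity(rng, max_angle=np.pi, max_t=50.0, s_range=(0.9, 1.1)):
    ang = EulerAngles(*rng.uniform(-max_angle, max_angle, 3))
    return SimilarityTransform(
        compose_euler_rotation(ang),
        rng.uniform(-max_t, max_t, 3),
        rng.uniform(*s_range),
    )


class TestApplyTransform:
    def test_identity_is_noop(self, arc):
        out = apply_transform(SimilarityTransform.identity(), arc)
        assert out.labels == arc.labels
        np.testing.assert_array_equal(out.coords, arc.coords)

    @pytest.mark.parametrize(
        "transform, point, expected",
        [
            (  # translation only
                SimilarityTransform(np.eye(3), [1.0, 2.0, 3.0], 1.0),
                [0.0, 0.0, 0.0],
                [1.0, 2.0, 3.0],
            ),
            (  # scale 2 with a 90 deg rotation about z sends x-hat to 2 y-hat
                SimilarityTransform(
                    compose_euler_rotation(EulerAngles(0, 0, math.pi / 2)),
                    [0.0, 0.0, 0.0],
                    2.0,
                ),
                [1.0, 0.0, 0.0],
                [0.0, 2.0, 0.0],
            ),
        ],
    )
    def test_known_mappings(self, transform, point, expected):
        out = transform.apply(np.asarray(point))
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestEulerConvention:
    def test_zero_angles_identity(self):
        np.testing.assert_array_equal(
            compose_euler_rotation(EulerAngles(0, 0, 0)), np.eye(3)
        )

    def test_matches_entrywise_elemental_product(self):
        a, b, g = 0.3, -0.2, 0.1
        ca, sa, cb, sb, cg, sg = (
            math.cos(a), math.sin(a), math.cos(b), math.sin(b),
            math.cos(g), math.sin(g),
        )
        rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
        expected = rx @ ry @ rz
        np.testing.assert_allclose(
            compose_euler_rotation(EulerAngles(a, b, g)), expected, atol=1e-15
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=angles, b=angles, g=angles)
    def test_composition_is_a_rotation(self, a, b, g):
        r = compose_euler_rotation(EulerAngles(a, b, g))
        assert np.max(np.abs(r.T @ r - np.eye(3))) < 1e-12
        assert abs(np.linalg.det(r) - 1) < 1e-12

    def test_decompose_identity(self):
        ang = decompose_rotation(np.eye(3))
        assert (ang.alpha, ang.beta, ang.gamma) == (0.0, 0.0, 0.0)

    def test_round_trip_named_angles(self):
        ang = EulerAngles(0.3, -0.2, 0.1)
        out = decompose_rotation(compose_euler_rotation(ang))
        np.testing.assert_allclose(
            [out.alpha, out.beta, out.gamma], [0.3, -0.2, 0.1], atol=1e-9
        )

    def test_round_trip_random_sweep(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(200):
            r = compose_euler_rotation(EulerAngles(*rng.uniform(-np.pi, np.pi, 3)))
            r2 = compose_euler_rotation(decompose_rotation(r))
            worst = max(worst, np.max(np.abs(r2 - r)))
        assert worst < 1e-8

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_gimbal_lock_canonical(self, sign):
        r = compose_euler_rotation(EulerAngles(0.4, sign * math.pi / 2, 0.0))
        ang = decompose_rotation(r)
        assert ang.gamma == 0.0
        r2 = compose_euler_rotation(ang)
        np.testing.assert_allclose(r2, r, atol=1e-9)

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            decompose_rotation(np.eye(3) * 1.01)


class TestHornRegister:
    def test_identity_pair(self, arc):
        res = horn_register(arc, arc)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.transform.translation, 0, atol=1e-12)
        assert res.transform.scale == pytest.approx(1.0, abs=1e-12)
        assert res.residual_e == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation(self, arc):
        post = PointSet(arc.labels, arc.coords + [10.0, -5.0, 2.0])
        res = horn_register(arc, post)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(
            res.transform.translation, [10, -5, 2], atol=1e-10
        )
        assert res.transform.scale == pytest.approx(1.0, abs=1e-10)
        assert res.residual_e < 1e-10

    def test_recovers_known_similarity_and_beats_oracle(self, arc):
        truth = SimilarityTransform(
            compose_euler_rotation(EulerAngles(0, 0, math.radians(10))),
            [5.0, -3.0, 2.0],
            1.02,
        )
        post = apply_transform(truth, arc)
        res = horn_register(arc, post)
        assert np.max(np.abs(res.transform.rotation - truth.rotation)) < 1e-9
        assert np.max(np.abs(res.transform.translation - truth.translation)) < 1e-9
        assert res.transform.scale == pytest.approx(1.02, abs=1e-9)
        assert res.residual_e < 1e-9
        oracle = multistart_lsq_sse(arc.coords, post.coords, n_starts=20, seed=3)
        assert res.sum_squared_residuals <= oracle + 1e-8

    def test_exact_recovery_random_transforms(self, arc):
        rng = np.random.default_rng(11)
        for _ in range(25):
            truth = random_similarity(rng)
            post = apply_transform(truth, arc)
            res = horn_register(arc, post)
            assert np.max(np.abs(res.transform.rotation - truth.rotation)) < 1e-8
            assert np.max(np.abs(res.transform.translation - truth.translation)) < 1e-8
            assert abs(res.transform.scale - truth.scale) < 1e-8
            assert res.residual_e < 1e-8

    def test_agrees_with_kabsch_oracle_under_noise(self, arc):
        rng = np.random.default_rng(5)
        for _ in range(20):
            truth = random_similarity(rng)
            pre = arc.coords + rng.normal(0, 0.3, arc.coords.shape)
            post = truth.apply(arc.coords) + rng.normal(0, 0.3, arc.coords.shape)
            res = horn_register(PointSet(arc.labels, pre), PointSet(arc.labels, post))
            r_ref, t_ref, s_ref = kabsch_register(pre, post)
            assert np.max(np.abs(res.transform.rotation - r_ref)) < 1e-8
            assert np.max(np.abs(res.transform.translation - t_ref)) < 1e-8
            assert abs(res.transform.scale - s_ref) < 1e-10

    def test_without_scale_forces_unit_scale(self, arc):
        rng = np.random.default_rng(2)
        pre = arc.coords + rng.normal(0, 0.2, arc.coords.shape)
        post = arc.coords + rng.normal(0, 0.2, arc.coords.shape)
        res = horn_register(PointSet(arc.labels, pre), PointSet(arc.labels, post),
                            with_scale=False)
        assert res.transform.scale == 1.0

    def test_scale_modes_agree_on_rigid_data(self, arc):
        truth = SimilarityTransform(
            compose_euler_rotation(EulerAngles(0.2, -0.1, 0.4)), [3.0, 1.0, -2.0], 1.0
        )
        post = apply_transform(truth, arc)
        res_s = horn_register(arc, post, with_scale=True)
        res_r = horn_register(arc, post, with_scale=False)
        assert abs(res_s.transform.scale - 1.0) < 1e-9
        assert np.max(np.abs(res_s.transform.rotation - res_r.transform.rotation)) < 1e-9
        assert np.max(np.abs(res_s.transform.translation - res_r.transform.translation)) < 1e-9

    def test_mismatched_lengths_rejected(self, arc):
        short = PointSet(arc.labels[:5], arc.coords[:5])
        with pytest.raises(CorrespondenceError):
            horn_register(arc, short)

    def test_two_points_underdetermined(self):
        two = PointSet(("a", "b"), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(UnderdeterminedError):
            horn_register(two, two)

    def test_collinear_rejected(self):
        line = PointSet(
            ("a", "b", "c", "d"),
            np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float),
        )
        with pytest.raises(DegenerateGeometryError):
            horn_register(line, line)


class TestResidual:
    def test_perfect_correspondence_zero(self, arc):
        e, per_point, ss = registration_residual(
            arc, arc, SimilarityTransform.identity()
        )
        assert e == 0.0 and ss == 0.0
        np.testing.assert_array_equal(per_point, np.zeros(9))

    def test_single_displaced_fiducial_rms(self, arc):
        post = arc.coords.copy()
        post[0] += [0.1, 0.0, 0.0]
        e, per_point, ss = registration_residual(
            arc, PointSet(arc.labels, post), SimilarityTransform.identity()
        )
        np.testing.assert_allclose(per_point, [0.1] + [0.0] * 8, atol=1e-12)
        assert e == pytest.approx(0.1 / 3, abs=1e-12)
        assert ss == pytest.approx(0.01, abs=1e-12)

    def test_mean_residual_matches_independent_simulation(self, arc):
        """Mean FRE at sigma = 0.1 mm matches a Monte-Carlo oracle built on an
        independently coded (Kabsch) registration, within 5%."""
        rng = np.random.default_rng(42)
        own, ref = [], []
        for _ in range(1000):
            pre = arc.coords + rng.normal(0, 0.1, arc.coords.shape)
            post = arc.coords + rng.normal(0, 0.1, arc.coords.shape)
            res = horn_register(PointSet(arc.labels, pre), PointSet(arc.labels, post))
            own.append(res.residual_e)
            r_ref, t_ref, s_ref = kabsch_register(pre, post)
            d = post - (s_ref * pre @ r_ref.T + t_ref)
            ref.append(np.sqrt((d**2).sum() / len(pre)))
        assert np.mean(own) == pytest.approx(np.mean(ref), rel=0.05)

    def test_invariant_under_common_rigid_motion(self, arc):
        rng = np.random.default_rng(9)
        pre = arc.coords + rng.normal(0, 0.3, arc.coords.shape)
        post = arc.coords + rng.normal(0, 0.3, arc.coords.shape)
        base = horn_register(PointSet(arc.labels, pre), PointSet(arc.labels, post))
        common = random_similarity(rng, s_range=(1.0, 1.0))
        moved = horn_register(
            PointSet(arc.labels, common.apply(pre)),
            PointSet(arc.labels, common.apply(post)),
        )
        assert moved.residual_e == pytest.approx(base.residual_e, abs=1e-9)

    def test_mismatched_lengths_rejected(self, arc):
        with pytest.raises(CorrespondenceError):
            registration_residual(
                arc,
                PointSet(arc.labels[:4], arc.coords[:4]),
                SimilarityTransform.identity(),
            )


class TestInvariantsOnReturnedRotations:
    def test_orthonormality_under_noise(self, arc):
        rng = np.random.default_rng(1)
        for _ in range(30):
            pre = arc.coords + rng.normal(0, 0.5, arc.coords.shape)
            post = arc.coords + rng.normal(0, 0.5, arc.coords.shape)
            r = horn_register(
                PointSet(arc.labels, pre), PointSet(arc.labels, post)
            ).transform.rotation
            assert np.max(np.abs(r.T @ r - np.eye(3))) < 1e-9
            assert abs(np.linalg.det(r) - 1) < 1e-9
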