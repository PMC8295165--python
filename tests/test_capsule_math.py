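"""Capsule primitives: closed-form values, invariants and routing oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ref_route_dual, ref_route_dynamic

from ivuscaps.capsule_math import (PoseTreatment, RoutingSpec, add_coordinates,
                                   normalize_pose, psquash, route_dual,
                                   route_dynamic, squash, transform_appearance,
                                   transform_pose)


class TestSquash:
    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(squash(np.zeros(5)), np.zeros(5))

    @pytest.mark.parametrize("norm,expected", [(1.0, 0.5), (3.0, 0.9)])
    def test_norm_mapping(self, norm, expected):
        v = np.array([norm, 0.0, 0.0])
        out = squash(v)
        assert np.linalg.norm(out) == pytest.approx(expected, abs=1e-9)
        # direction preserved
        assert out[0] > 0 and out[1] == out[2] == 0

    def test_matrix_input_uses_frobenius_norm(self, rng):
        m = rng.normal(size=(3, 3))
        out = squash(m)
        n = np.linalg.norm(m)
        assert np.linalg.norm(out) == pytest.approx(n * n / (1 + n * n), rel=1e-7)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_output_norm_below_one_and_monotone(self, norm):
        base = np.array([1.0, 2.0, -2.0])
        base /= np.linalg.norm(base)
        n1 = np.linalg.norm(squash(base * norm))
        n2 = np.linalg.norm(squash(base * norm * 1.5))
        assert n1 < 1.0 and n2 < 1.0
        assert n2 > n1

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            squash(np.array([np.nan, 1.0]))


class TestPsquash:
    def test_uniform_matrix(self):
        np.testing.assert_allclose(psquash(np.full((2, 2), 2.0)), np.ones((2, 2)))

    def test_worked_example(self):
        m = np.array([[1.0, -4.0], [2.0, 0.0]])
        np.testing.assert_allclose(psquash(m), [[0.25, -1.0], [0.5, 0.0]])

    def test_fixed_point_when_max_abs_is_one(self):
        m = np.array([[0.3, -1.0], [0.2, 0.5]])
        np.testing.assert_allclose(psquash(m), m)

    def test_zero_matrix_maps_to_itself(self):
        np.testing.assert_array_equal(psquash(np.zeros((3, 3))), np.zeros((3, 3)))

    def test_max_abs_is_exactly_one_on_random_matrices(self, rng):
        for _ in range(200):
            m = rng.normal(size=(4, 4)) * 10 ** rng.uniform(-3, 3)
            assert np.abs(psquash(m)).max() == pytest.approx(1.0, abs=1e-12)


class TestTransforms:
    def test_pose_identity_transform(self, rng):
        p = rng.normal(size=(3, 3))
        np.testing.assert_allclose(transform_pose(p, np.eye(3)), p)

    def test_pose_identity_child_gives_transform(self, rng):
        w = rng.normal(size=(4, 4))
        np.testing.assert_allclose(transform_pose(np.eye(4), w), w)

    def test_pose_matches_matrix_product(self, rng):
        p, w = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        expected = np.array([[p[i] @ w[:, j] for j in range(2)] for i in range(2)])
        np.testing.assert_allclose(transform_pose(p, w), expected, atol=1e-12)

    def test_pose_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            transform_pose(rng.normal(size=(3, 3)), rng.normal(size=(4, 4)))

    def test_appearance_zero_bias_identity(self, rng):
        a = rng.normal(size=(5, 5))
        np.testing.assert_allclose(transform_appearance(a, np.eye(5), 0.0), a)

    def test_appearance_bias_broadcasts_entrywise(self):
        out = transform_appearance(np.zeros((3, 3)), np.eye(3), 1.0)
        np.testing.assert_allclose(out, np.ones((3, 3)))

    def test_appearance_matches_brute_force(self, rng):
        a, w, b = rng.normal(size=(3, 3)), rng.normal(size=(3, 3)), 0.37
        np.testing.assert_allclose(transform_appearance(a, w, b),
                                   (a + b) @ w, atol=1e-12)


class TestNormalizeAndCoordinates:
    def test_column_normalization(self):
        m = np.array([[3.0, 0.0], [4.0, 0.0]])
        out = normalize_pose(m)
        np.testing.assert_allclose(out[:, 0], [0.6, 0.8])
        np.testing.assert_allclose(out[:, 1], 0.0)   # zero column untouched

    def test_orthonormal_matrix_unchanged(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(4, 4)))
        np.testing.assert_allclose(normalize_pose(q), q, atol=1e-12)

    def test_mode_none_is_identity(self, rng):
        m = rng.normal(size=(4, 4))
        assert normalize_pose(m, PoseTreatment(mode="none")) is m

    def test_coordinates_added_to_last_column(self):
        p = np.zeros((4, 4))
        out = add_coordinates(p, (0.5, 0.25), scale=1.0)
        assert out[0, -1] == 0.5 and out[1, -1] == 0.25
        out[0, -1] = out[1, -1] = 0.0
        np.testing.assert_array_equal(out, np.zeros((4, 4)))

    def test_zero_scale_is_identity(self, rng):
        p = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(add_coordinates(p, (0.3, 0.9), 0.0), p)

    def test_negated_scale_inverts(self, rng):
        p = rng.normal(size=(4, 4))
        out = add_coordinates(add_coordinates(p, (0.3, 0.9), 1.7),
                              (0.3, 0.9), -1.7)
        np.testing.assert_allclose(out, p, atol=1e-12)

    def test_position_outside_unit_square_rejected(self):
        with pytest.raises(ValueError):
            add_coordinates(np.zeros((4, 4)), (1.5, 0.0), 1.0)


class TestRouting:
    def test_single_child_single_parent_dynamic(self, rng):
        u = rng.normal(size=(1, 1, 4))
        spec = RoutingSpec(algorithm="dynamic", iterations=3, window=1)
        v, c = route_dynamic(u, spec)
        np.testing.assert_allclose(c, 1.0)
        ref, _ = ref_route_dynamic(u, 3)
        np.testing.assert_allclose(v, ref, atol=1e-12)

    def test_single_child_single_parent_dual(self, rng):
        p = rng.normal(size=(1, 1, 2, 2))
        a = rng.normal(size=(1, 1, 3, 3))
        spec = RoutingSpec(algorithm="dual", iterations=2, window=1)
        po, ao, c = route_dual(p, a, spec)
        np.testing.assert_allclose(c, 1.0)
        assert np.abs(po).max() == pytest.approx(1.0)
        assert np.linalg.norm(ao) < 1.0

    def test_identical_children_give_uniform_coefficients(self, rng):
        child = rng.normal(size=(4,))
        u = np.tile(child, (3, 2, 1))  # identical in every parent frame
        spec = RoutingSpec(algorithm="dynamic", iterations=3, window=1)
        _, c = route_dynamic(u, spec)
        np.testing.assert_allclose(c, 0.5, atol=1e-7)

    @pytest.mark.parametrize("iterations", [1, 2, 3])
    def test_dynamic_matches_loop_reference(self, iterations, rng):
        for _ in range(20):
            ni = int(rng.integers(1, 5))
            nj = int(rng.integers(1, 4))
            u = rng.normal(size=(ni, nj, int(rng.integers(2, 5))))
            spec = RoutingSpec(algorithm="dynamic", iterations=iterations,
                               window=1)
            v, c = route_dynamic(u, spec)
            v_ref, c_ref = ref_route_dynamic(u, iterations)
            np.testing.assert_allclose(v, v_ref, atol=1e-5)
            np.testing.assert_allclose(c, c_ref, atol=1e-5)

    @pytest.mark.parametrize("iterations", [1, 2, 3])
    def test_dual_matches_loop_reference(self, iterations, rng):
        for _ in range(20):
            ni = int(rng.integers(1, 5))
            nj = int(rng.integers(1, 4))
            p = rng.normal(size=(ni, nj, 2, 2))
            a = rng.normal(size=(ni, nj, 3, 3))
            spec = RoutingSpec(algorithm="dual", iterations=iterations, window=1)
            po, ao, c = route_dual(p, a, spec)
            po_r, ao_r, c_r = ref_route_dual(p, a, iterations)
            np.testing.assert_allclose(po, po_r, atol=1e-5)
            np.testing.assert_allclose(ao, ao_r, atol=1e-5)
            np.testing.assert_allclose(c, c_r, atol=1e-5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_coefficients_form_a_simplex_over_parents(self, seed):
        rng = np.random.default_rng(seed)
        ni, nj, iters = (int(rng.integers(1, 6)), int(rng.integers(1, 5)),
                         int(rng.integers(1, 4)))
        p = rng.normal(size=(ni, nj, 2, 2))
        a = rng.normal(size=(ni, nj, 2, 2))
        spec = RoutingSpec(algorithm="dual", iterations=iters, window=1)
        _, _, c = route_dual(p, a, spec)
        assert np.all(c >= 0)
        np.testing.assert_allclose(c.sum(axis=-1), 1.0, atol=1e-6)

    def test_misaligned_dual_children_rejected(self, rng):
        spec = RoutingSpec(algorithm="dual", iterations=2, window=1)
        with pytest.raises(ValueError):
            route_dual(rng.normal(size=(3, 2, 2, 2)),
                       rng.normal(size=(2, 2, 3, 3)), spec)

    def test_empty_child_set_rejected(self, rng):
        spec = RoutingSpec(algorithm="dynamic", iterations=2, window=1)
        with pytest.raises(ValueError):
            route_dynamic(rng.normal(size=(0, 2, 3)), spec)

    def test_wrong_algorithm_rejected(self, rng):
        with pytest.raises(ValueError):
            route_dynamic(rng.normal(size=(2, 2, 3)),
                          RoutingSpec(algorithm="dual", iterations=1, window=1))


def test_routing_spec_validation():
    with pytest.raises(ValueError):
        RoutingSpec(algorithm="em", iterations=3, window=5)
    with pytest.raises(ValueError):
        RoutingSpec(iterations=0)
    with pytest.raises(ValueError):
        RoutingSpec(window=4)
    with pytest.raises(ValueError):
        PoseTreatment(mode="bogus")
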