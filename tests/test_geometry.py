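"""Rigid-body geometry: centroids, axes, minimal rotations, signed angles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heartbend.geometry import (
    DegenerateAxisError,
    RigidRotation,
    UndefinedAngleError,
    centroid,
    chamber_axis,
    minimal_rotation,
    signed_angle_about_axis,
    signed_angles_about_axis,
)
from conftest import rodrigues_matrix


def random_unit(rng, n=None):
    v = rng.normal(size=(n, 3) if n else 3)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


class TestCentroid:
    def test_single_and_symmetric_points(self):
        assert np.allclose(centroid([(2, 0, 0)]), (2, 0, 0))
        assert np.allclose(centroid([(0, 0, 0), (2, 0, 0)]), (1, 0, 0))

    def test_matches_summation_oracle(self, rng):
        pts = rng.normal(size=(7, 3))
        expected = np.array([pts[:, k].sum() / 7 for k in range(3)])
        assert np.allclose(centroid(pts), expected, atol=1e-12)

    def test_empty_is_domain_error(self):
        with pytest.raises(ValueError):
            centroid([])


class TestChamberAxis:
    def test_axis_from_origin(self):
        pts = [(3, 1, 0), (3, -1, 0)]  # centroid (3,0,0)
        assert np.allclose(chamber_axis((0, 0, 0), pts), (1, 0, 0))

    def test_axis_from_offset_av(self):
        assert np.allclose(chamber_axis((1, 1, 1), [(1, 1, 2)]), (0, 0, 1))

    def test_matches_normalize_oracle(self, rng):
        av = rng.normal(size=3)
        pts = rng.normal(size=(9, 3)) + 10
        d = pts.mean(axis=0) - av
        assert np.allclose(chamber_axis(av, pts), d / np.linalg.norm(d), atol=1e-12)

    def test_coincident_centroids_degenerate(self):
        with pytest.raises(DegenerateAxisError):
            chamber_axis((1, 2, 3), [(1, 2, 3)])


class TestMinimalRotation:
    def test_identity_when_aligned(self):
        r = minimal_rotation((1, 0, 0), (1, 0, 0))
        assert r.angle_deg == 0.0
        assert np.allclose(r.matrix, np.eye(3), atol=1e-12)

    def test_quarter_turn_matches_rodrigues_oracle(self):
        r = minimal_rotation((1, 0, 0), (0, 1, 0))
        assert np.isclose(r.angle_deg, 90.0)
        assert np.allclose(r.matrix, rodrigues_matrix((0, 0, 1), 90.0), atol=1e-12)
        assert np.allclose(r.apply((1, 0, 0)), (0, 1, 0), atol=1e-12)
        assert np.allclose(r.apply((0, 0, 1)), (0, 0, 1), atol=1e-12)

    def test_antiparallel_tie_break_maps_u_to_v(self):
        # u along x: fallback axis is global +z (already perpendicular to u)
        r = minimal_rotation((1, 0, 0), (-1, 0, 0))
        assert np.isclose(r.angle_deg, 180.0)
        assert np.allclose(r.axis, (0, 0, 1), atol=1e-12)
        assert np.allclose(r.apply((1, 0, 0)), (-1, 0, 0), atol=1e-9)
        # u along z: z-fallback degenerate, documented fallback is +x
        r2 = minimal_rotation((0, 0, 1), (0, 0, -1))
        assert np.allclose(r2.axis, (1, 0, 0), atol=1e-12)
        assert np.allclose(r2.apply((0, 0, 1)), (0, 0, -1), atol=1e-9)

    def test_orthonormal_det_plus_one_and_arccos_angle(self, rng):
        for _ in range(50):
            u, v = random_unit(rng), random_unit(rng)
            r = minimal_rotation(u, v)
            m = r.matrix
            assert np.allclose(m @ m.T, np.eye(3), atol=1e-9)
            assert np.isclose(np.linalg.det(m), 1.0, atol=1e-9)
            assert np.allclose(m @ u, v, atol=1e-9)
            expected = np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1)))
            assert np.isclose(r.angle_deg, expected, atol=1e-9)


class TestSignedAngleAboutAxis:
    def test_no_motion_is_zero(self):
        assert signed_angle_about_axis((1, 0, 0), (1, 0, 0), (0, 0, 1)) == 0.0

    def test_right_handed_quarter_turn(self):
        a = signed_angle_about_axis((1, 0, 0), (0, 1, 0), (0, 0, 1))
        assert np.isclose(a, 90.0, atol=1e-12)

    def test_purely_axial_motion_is_zero(self):
        a = signed_angle_about_axis((1, 0, 0), (1, 0, 5), (0, 0, 1))
        assert np.isclose(a, 0.0, atol=1e-12)

    def test_antisymmetry_under_swap(self, rng):
        p, q = rng.normal(size=3) * 10, rng.normal(size=3) * 10
        ax = random_unit(rng)
        a1 = signed_angle_about_axis(p, q, ax)
        a2 = signed_angle_about_axis(q, p, ax)
        assert np.isclose(a1, -a2, atol=1e-9)

    def test_axis_flip_negates_angle(self, rng):
        p, q = rng.normal(size=3) * 10, rng.normal(size=3) * 10
        ax = random_unit(rng)
        a1 = signed_angle_about_axis(p, q, ax)
        a2 = signed_angle_about_axis(p, q, -ax)
        assert np.isclose(a1, -a2, atol=1e-9)

    def test_scaling_perpendicular_component_invariance(self, rng):
        ax = random_unit(rng)
        p = rng.normal(size=3) * 10
        q = rng.normal(size=3) * 10
        base = signed_angle_about_axis(p, q, ax)
        for s in (0.3, 2.0, 17.0):
            q_perp = q - np.dot(q, ax) * ax
            q_scaled = np.dot(q, ax) * ax + s * q_perp
            assert np.isclose(
                signed_angle_about_axis(p, q_scaled, ax), base, atol=1e-9
            )

    def test_on_axis_point_raises(self):
        with pytest.raises(UndefinedAngleError):
            signed_angle_about_axis((0, 0, 7), (1, 0, 0), (0, 0, 1))

    def test_recovers_rotation_angle_against_matrix_oracle(self, rng):
        """1000 random (point, axis, β): the angle of p -> R(axis, β)·p about
        the axis must equal β exactly, including sign."""
        for _ in range(1000):
            ax = random_unit(rng)
            p = rng.normal(size=3) * 20
            # keep the perpendicular offset clearly defined
            if np.linalg.norm(p - np.dot(p, ax) * ax) < 1.0:
                p += 5 * np.array([ax[1], ax[2], ax[0]])
                if np.linalg.norm(p - np.dot(p, ax) * ax) < 1.0:
                    continue
            beta = rng.uniform(-179.9, 179.9)
            q = rodrigues_matrix(ax, beta) @ p
            assert np.isclose(
                signed_angle_about_axis(p, q, ax), beta, atol=1e-9
            )

    def test_vectorized_matches_scalar(self, rng):
        ax = random_unit(rng)
        p = rng.normal(size=(40, 3)) * 15
        q = rng.normal(size=(40, 3)) * 15
        vec = signed_angles_about_axis(p, q, ax)
        for k in range(40):
            try:
                expected = signed_angle_about_axis(p[k], q[k], ax)
            except UndefinedAngleError:
                assert np.isnan(vec[k])
            else:
                assert np.isclose(vec[k], expected, atol=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    u=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    v=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
)
def test_minimal_rotation_always_maps_u_to_v(u, v):
    u, v = np.asarray(u), np.asarray(v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-3 or nv < 1e-3:
        return
    u, v = u / nu, v / nv
    r = minimal_rotation(u, v)
    assert np.allclose(r.matrix @ u, v, atol=1e-8)
    assert 0.0 <= r.angle_deg <= 180.0


def test_rigid_rotation_validates_axis_and_angle():
    with pytest.raises(ValueError):
        RigidRotation(axis=np.array([2.0, 0, 0]), angle_deg=10)
    with pytest.raises(ValueError):
        RigidRotation(axis=np.array([1.0, 0, 0]), angle_deg=270)
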