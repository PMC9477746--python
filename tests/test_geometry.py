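"""Geometry primitives: centroids, Kabsch superposition, RMSD, torsions, azimuths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ruvmotor.errors import GeometryError
from ruvmotor.geometry import (
    RigidTransform,
    angular_positions,
    centroid,
    dihedral,
    kabsch_superpose,
    rmsd,
    vertex_angle,
)


def _random_transform(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.uniform(-20, 20, 3))


# ---------------------------------------------------------------------------
# centroid / rmsd


@pytest.mark.parametrize("points,expected", [
    ([(0, 0, 0), (2, 0, 0)], (1, 0, 0)),
    ([(3.5, -1, 2)], (3.5, -1, 2)),
    ([(np.cos(k * np.pi / 3), np.sin(k * np.pi / 3), 1) for k in range(6)], (0, 0, 1)),
])
def test_centroid_basic(points, expected):
    assert np.allclose(centroid(np.array(points, dtype=float)), expected)


def test_centroid_empty_is_an_error():
    with pytest.raises(GeometryError):
        centroid(np.zeros((0, 3)))


def test_rmsd_closed_forms():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(10, 3))
    assert rmsd(a, a) == 0.0
    assert np.isclose(rmsd(a, a + np.array([0, 0, 2.0])), 2.0)
    # independent recomputation from the definition
    b = rng.normal(size=(10, 3))
    expected = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
    assert np.isclose(rmsd(a, b), expected)
    assert np.isclose(rmsd(a, b), rmsd(b, a))
    with pytest.raises(GeometryError):
        rmsd(a, b[:5])


# ---------------------------------------------------------------------------
# Kabsch superposition


def test_kabsch_identity_on_self():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(8, 3))
    tr, r = kabsch_superpose(pts, pts)
    assert r < 1e-12
    assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(tr.translation, 0, atol=1e-9)


def test_kabsch_recovers_known_rigid_motion():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 3)) * 5
    R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
    moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
    tr, r = kabsch_superpose(moved, pts)
    assert r < 1e-9
    assert np.allclose(tr.apply(moved), pts, atol=1e-8)
    # recovered rotation inverts the applied one
    assert np.allclose(tr.rotation @ R, np.eye(3), atol=1e-8)


def test_kabsch_matches_bruteforce_rotation_search():
    """Minimised RMSD equals a dense sample over SO(3) (with optimal translation).

    For centred sets P, Q and any rotation R the residual is
    (|P|^2 + |Q|^2 - 2 tr(R H)) / n with H = P^T Q, which is an independent
    closed form requiring only centroid-matching optimality of translation.
    """
    rng = np.random.default_rng(3)
    P = rng.normal(size=(4, 3)) * 2
    Q = rng.normal(size=(4, 3)) * 2
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    H = Pc.T @ Qc
    Rs = Rotation.random(200_000, random_state=np.random.RandomState(4)).as_matrix()
    traces = np.einsum("nij,ji->n", Rs, H)
    sq = ((Pc ** 2).sum() + (Qc ** 2).sum() - 2 * traces) / len(P)
    brute = float(np.sqrt(np.clip(sq, 0, None).min()))
    _, r = kabsch_superpose(P, Q)
    assert r <= brute + 1e-9
    assert brute - r < 0.1  # sampling resolution of the rotation grid
    # independent library oracle
    rot, rssd = Rotation.align_vectors(Qc, Pc)
    assert np.isclose(r, rssd / np.sqrt(len(P)), atol=1e-8)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_kabsch_not_beaten_by_random_transforms(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(7, 3)) * 3
    b = rng.normal(size=(7, 3)) * 3
    _, best = kabsch_superpose(a, b)
    for _ in range(5):
        assert best <= rmsd(a, b, _random_transform(rng)) + 1e-9


def test_kabsch_rejects_degenerate_input():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
    good = np.random.default_rng(5).normal(size=(4, 3))
    with pytest.raises(GeometryError):
        kabsch_superpose(line, good)
    with pytest.raises(GeometryError):  # length mismatch
        kabsch_superpose(good, good[:3])
    with pytest.raises(GeometryError):  # too few points
        kabsch_superpose(good[:2], good[:2])


# ---------------------------------------------------------------------------
# dihedral


def _dihedral_oracle(p1, p2, p3, p4):
    """Independent normal-vector construction of the signed torsion."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    cosang = np.clip(n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2)), -1, 1)
    ang = np.degrees(np.arccos(cosang))
    if np.cross(n1, n2) @ b2 < 0:
        ang = -ang
    return ang


def test_dihedral_planar_constructions():
    p = [np.array(v, dtype=float) for v in
         [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)]]
    assert np.isclose(abs(dihedral(*p)), 90.0)
    trans = [np.array(v, dtype=float) for v in
             [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]]
    assert np.isclose(dihedral(*trans), 180.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_dihedral_matches_independent_constructions(seed):
    import biotite.structure as struc

    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3)) * 4
    try:
        ours = dihedral(*pts)
    except GeometryError:
        return
    assert np.isclose(ours, _dihedral_oracle(*pts), atol=1e-6)
    ref = np.degrees(struc.dihedral(*pts))
    assert np.isclose(ours, ref, atol=1e-4)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_angles_invariant_under_common_rigid_transform(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3)) * 4
    try:
        d0 = dihedral(*pts)
    except GeometryError:
        return
    v0 = vertex_angle(pts[0], pts[1], pts[2])
    tr = _random_transform(rng)
    moved = tr.apply(pts)
    assert np.isclose(dihedral(*moved), d0, atol=1e-6)
    assert np.isclose(vertex_angle(moved[0], moved[1], moved[2]), v0, atol=1e-6)


def test_dihedral_degenerate_axis_is_an_error():
    p = np.zeros(3)
    with pytest.raises(GeometryError):
        dihedral(p, p, np.array([1.0, 0, 0]), np.array([1.0, 1, 0]))


# ---------------------------------------------------------------------------
# angular positions


def test_angular_positions_regular_hexagon():
    pts = np.array([[np.cos(np.radians(60 * k)), np.sin(np.radians(60 * k)), 0.3]
                    for k in range(6)])
    az = angular_positions(pts, np.zeros(3), np.array([0, 0, 1.0]))
    diffs = np.diff(np.sort(az))
    assert np.allclose(diffs, 60.0, atol=1e-9)


def test_angular_positions_right_angle_and_perturbation():
    a = angular_positions(np.array([[1, 0, 0], [0, 1, 5.0]]),
                          np.zeros(3), np.array([0, 0, 1.0]))
    assert np.isclose(abs(a[1] - a[0]), 90.0)
    # known perturbation of one hexagon vertex shifts only its spacing
    angles = [0, 60, 120, 187, 240, 300]  # vertex 3 pushed by +7 degrees
    pts = np.array([[np.cos(np.radians(t)), np.sin(np.radians(t)), 0] for t in angles])
    az = np.sort(angular_positions(pts, np.zeros(3), np.array([0, 0, 1.0])))
    spacings = np.diff(np.concatenate([az, [az[0] + 360]]))
    assert np.allclose(sorted(spacings), sorted([60, 60, 67, 53, 60, 60]), atol=1e-9)


def test_angular_positions_point_on_axis_is_an_error():
    with pytest.raises(GeometryError, match="1"):
        angular_positions(np.array([[1, 0, 0], [0, 0, 2.0]]),
                          np.zeros(3), np.array([0, 0, 1.0]))
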