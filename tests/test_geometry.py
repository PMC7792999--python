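"""Geometry primitives against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peroxosite.geometry import (
    angle,
    distance,
    fit_ring_plane,
    mainchain_rmsd,
    place_atom,
    plane_tilt,
    superpose,
    torsion,
)
from peroxosite.synthetic import build_toy_active_site

from conftest import random_rigid_motion


# ---------------------------------------------------------------------------
# independent oracle formulations (deliberately different constructions)


def _distance_oracle(a, b):
    return math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))


def _angle_oracle(a, b, c):
    u = [ai - bi for ai, bi in zip(a, b)]
    v = [ci - bi for ci, bi in zip(c, b)]
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    dot = sum(x * y for x, y in zip(u, v))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (nu * nv)))))


def _torsion_oracle(a, b, c, d):
    """Project a and d onto the plane normal to b->c; signed angle between.

    To a viewer looking along b->c (sight axis z into the screen, x right,
    y up) clockwise is positive (IUPAC), i.e. from +x toward -y.
    """
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    z = c - b
    z = z / np.linalg.norm(z)
    pa = (a - b) - ((a - b) @ z) * z
    pd = (d - c) - ((d - c) @ z) * z
    x = pa / np.linalg.norm(pa)
    y = np.cross(z, x)
    return math.degrees(math.atan2(-(pd @ y), pd @ x))


def _plane_oracle(points):
    """Eigen-decomposition of the covariance matrix (not SVD)."""
    pts = np.asarray(points, float)
    cen = pts.mean(axis=0)
    cov = (pts - cen).T @ (pts - cen)
    w, v = np.linalg.eigh(cov)
    return cen, v[:, 0]


def _superpose_oracle_rmsd(fixed, moving):
    """Horn's quaternion method: closed-form optimal rotation."""
    f = np.asarray(fixed, float)
    m = np.asarray(moving, float)
    fc, mc = f - f.mean(0), m - m.mean(0)
    S = mc.T @ fc
    K = np.array(
        [
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1],
             S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2],
             S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0],
             -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2],
             S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = (fc**2).sum() + (mc**2).sum()
    return math.sqrt(max(e2 - 2 * lam, 0.0) / len(f))


# ---------------------------------------------------------------------------


def test_distance_angle_torsion_against_oracles_bulk(rng):
    """10^4 random cases agree with brute-force formulations to 1e-9."""
    pts = rng.normal(scale=5.0, size=(10_000, 4, 3))
    d = distance(pts[:, 0], pts[:, 1])
    ang = angle(pts[:, 0], pts[:, 1], pts[:, 2])
    tor = torsion(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
    for i in range(0, 10_000, 97):
        a, b, c, dd = pts[i]
        assert d[i] == pytest.approx(_distance_oracle(a, b), abs=1e-12)
        assert ang[i] == pytest.approx(_angle_oracle(a, b, c), abs=1e-9)
        assert tor[i] == pytest.approx(_torsion_oracle(a, b, c, dd), abs=1e-9)


def test_rigid_motion_invariance(rng):
    """Distances, angles, torsions and tilts are invariant under rigid motion."""
    for _ in range(50):
        pts = rng.normal(scale=4.0, size=(4, 3))
        rot, tr = random_rigid_motion(rng)
        moved = pts @ rot.T + tr
        assert distance(pts[0], pts[1]) == pytest.approx(
            distance(moved[0], moved[1]), abs=1e-9)
        assert angle(*pts[:3]) == pytest.approx(angle(*moved[:3]), abs=1e-9)
        assert torsion(*pts) == pytest.approx(torsion(*moved), abs=1e-9)


def test_torsion_reversal_invariance_and_mirror_antisymmetry(rng):
    """IUPAC torsion is unchanged by atom-order reversal and negated by
    mirror reflection."""
    mirror = np.diag([1.0, 1.0, -1.0])
    for _ in range(200):
        a, b, c, d = rng.normal(size=(4, 3))
        t = torsion(a, b, c, d)
        assert torsion(d, c, b, a) == pytest.approx(t, abs=1e-9)
        tm = torsion(a @ mirror, b @ mirror, c @ mirror, d @ mirror)
        assert tm == pytest.approx(-t, abs=1e-9) or (
            abs(abs(t) - 180.0) < 1e-9 and abs(abs(tm) - 180.0) < 1e-9
        )


@given(st.floats(-179.999, 180.0))
@settings(max_examples=50, deadline=None)
def test_place_atom_round_trips_dihedral(phi):
    """An atom placed at dihedral phi measures back exactly phi."""
    a = np.array([1.0, 1.0, 0.0])
    b = np.array([0.0, 0.0, 0.0])
    c = np.array([1.5, 0.0, 0.0])
    d = place_atom(a, b, c, 1.1, 109.5, phi)
    assert torsion(a, b, c, d) == pytest.approx(phi, abs=1e-9)
    assert distance(c, d) == pytest.approx(1.1, abs=1e-12)
    assert angle(b, c, d) == pytest.approx(109.5, abs=1e-9)


def test_angle_edge_cases():
    assert angle([0, 0, 1], [0, 0, 0], [0, 0, 2]) == pytest.approx(0.0)
    assert angle([1, 0, 0], [0, 0, 0], [-1, 0, 0]) == pytest.approx(180.0)
    assert angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)
    with pytest.raises(ValueError):
        angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


def test_torsion_planar_and_errors():
    # cis = 0, trans = 180
    assert torsion([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(0.0)
    assert torsion([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(180.0)
    with pytest.raises(ValueError):
        torsion([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


def test_ring_plane_hexagon_and_noise(rng):
    """Regular hexagon: centroid origin, normal z, planarity 0; with z-noise
    the fitted normal matches the eigen-decomposition oracle."""
    hexa = np.array(
        [[np.cos(np.radians(60 * k)), np.sin(np.radians(60 * k)), 0.0]
         for k in range(6)]
    ) * 1.39
    p = fit_ring_plane(hexa)
    assert np.allclose(p.centroid, 0.0, atol=1e-12)
    assert abs(p.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-12)
    assert p.planarity_rms == pytest.approx(0.0, abs=1e-12)

    for _ in range(100):
        noisy = hexa + np.c_[np.zeros((6, 2)), rng.uniform(-0.05, 0.05, 6)]
        q = fit_ring_plane(noisy)
        cen, nrm = _plane_oracle(noisy)
        assert np.allclose(q.centroid, cen, atol=1e-12)
        assert abs(abs(q.normal @ nrm) - 1.0) < 1e-6


def test_ring_plane_three_points_and_collinear():
    tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
    assert fit_ring_plane(tri).planarity_rms == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        fit_ring_plane(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))


def test_plane_tilt_constructed_dihedral(rng):
    """Two planes constructed at a known dihedral angle report that angle."""
    base = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
    p = fit_ring_plane(base)
    for deg in (0.0, 12.5, 30.0, 45.0, 89.0):
        c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        q = fit_ring_plane(base @ rot.T)
        assert plane_tilt(p, q) == pytest.approx(deg, abs=1e-9)
    assert plane_tilt(p, p) == pytest.approx(0.0, abs=1e-12)


def test_superpose_identity_and_recovery(rng):
    pts = rng.normal(size=(20, 3))
    res = superpose(pts, pts)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
    rot, tr = random_rigid_motion(rng)
    res2 = superpose(pts, pts @ rot.T + tr)
    assert res2.rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_matches_quaternion_oracle(rng):
    for _ in range(100):
        fixed = rng.normal(size=(15, 3))
        rot, tr = random_rigid_motion(rng)
        moving = fixed @ rot.T + tr + rng.normal(scale=0.3, size=(15, 3))
        res = superpose(fixed, moving)
        assert res.rmsd == pytest.approx(
            _superpose_oracle_rmsd(fixed, moving), abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_superpose_never_reflects(rng):
    """Chirally mismatched inputs still yield a proper rotation."""
    pts = rng.normal(size=(10, 3))
    mirrored = pts @ np.diag([1.0, 1.0, -1.0])
    res = superpose(pts, mirrored)
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
    assert res.rmsd > 0


def test_superpose_errors(rng):
    with pytest.raises(ValueError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]
    with pytest.raises(ValueError):
        superpose(line, line)


def _backbone_model(rng, n_res=30, jitter=None):
    """A synthetic poly-Gly-like backbone spanning n_res residues."""
    from peroxosite.structure_io import AtomSite, StructureModel

    atoms = []
    serial = 0
    for i in range(n_res):
        base = np.array([3.8 * i, 2.0 * np.sin(i), 2.0 * np.cos(i)])
        for j, name in enumerate(("N", "CA", "C", "O")):
            serial += 1
            pos = base + np.array([0.9 * j, 0.4 * (j % 2), 0.2 * j])
            if jitter is not None:
                pos = pos + jitter[serial - 1]
            atoms.append(
                AtomSite(serial, name, name[0], "", 1.0, pos, 10.0,
                         "A", i + 1, "", "GLY")
            )
    return StructureModel(atoms)


def test_mainchain_rmsd_self_and_noise(rng):
    """Self-RMSD is 0; a 0.1 Å-displaced copy reports ~0.1 Å."""
    a = _backbone_model(rng)
    rmsd, res = mainchain_rmsd(a, a)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert res.n_pairs == 120
    # displace every atom by exactly 0.1 Å in a random direction
    dirs = rng.normal(size=(120, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    b = _backbone_model(rng, jitter=0.1 * dirs)
    rmsd2, _ = mainchain_rmsd(a, b)
    assert 0.09 <= rmsd2 <= 0.11


def test_mainchain_rmsd_requires_common_residues(rng, toy_site):
    model, _ = toy_site
    with pytest.raises(ValueError):
        mainchain_rmsd(model, model)  # toy site has <3 polymer residues
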