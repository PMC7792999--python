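"""Exact vector geometry for structural analysis.

Distances, bond angles, signed torsions, least-squares ring planes and
rigid-body (Kabsch) superposition.  All functions accept either single
3-vectors or arrays of shape ``(..., 3)`` and broadcast over the leading
axes, so a whole trajectory of torsions is one call.

Conventions
-----------
* Torsions follow the IUPAC sign convention: looking down the b->c bond,
  a clockwise rotation of d relative to a is positive.  Values are
  reported in degrees on ``(-180, 180]``.
* Ring-plane normals are unit vectors; the inter-plane tilt is always
  reported acute, in ``[0, 90]`` degrees.
* Superposition returns a proper rotation (det = +1) even for
  chirally mismatched inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RingPlane",
    "SuperpositionResult",
    "distance",
    "angle",
    "torsion",
    "fit_ring_plane",
    "plane_tilt",
    "superpose",
    "mainchain_rmsd",
    "place_atom",
    "wrap_degrees",
]

_MAINCHAIN_ATOMS = ("N", "CA", "C", "O")

_EPS = 1e-12


def wrap_degrees(a):
    """Wrap angle(s) in degrees onto the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    w = -np.remainder(-a + 180.0, 360.0) + 180.0
    return w if w.ndim else float(w)


def distance(a, b):
    """Euclidean distance |a - b| in the units of the inputs (Å here)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.linalg.norm(a - b, axis=-1)
    return d if d.ndim else float(d)


def angle(a, b, c):
    """Angle a-b-c at vertex b, in degrees in [0, 180].

    Raises ValueError on a zero-length arm.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < _EPS) or np.any(nv < _EPS):
        raise ValueError("angle(): zero-length arm (b coincides with a or c)")
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang if ang.ndim else float(ang)


def torsion(a, b, c, d):
    """Signed dihedral a-b-c-d in degrees on (-180, 180] (IUPAC sign).

    Antisymmetric: ``torsion(a,b,c,d) == -torsion(d,c,b,a)``.  Raises
    ValueError when a,b,c or b,c,d are collinear (torsion undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    u1 = b - a
    u2 = c - b
    u3 = d - c
    n1 = np.cross(u1, u2)
    n2 = np.cross(u2, u3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-9) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-9
    ):
        raise ValueError("torsion(): collinear arms, dihedral undefined")
    u2n = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)
    m1 = np.cross(n1, u2n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    t = np.degrees(np.arctan2(y, x))
    t = wrap_degrees(t)
    return t if np.ndim(t) else float(t)


@dataclass(frozen=True)
class RingPlane:
    """Least-squares plane through a set of (ring) atoms.

    Attributes
    ----------
    positions : (n, 3) array of the member atom positions (Å).
    centroid : 3-vector, arithmetic mean of members (the ring midpoint m).
    normal : unit normal of the best-fit plane.
    planarity_rms : root-mean-square out-of-plane deviation (Å).
    """

    positions: np.ndarray
    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float

    def oriented_normal(self, reference_point) -> np.ndarray:
        """Normal flipped so that *reference_point* lies on its positive side."""
        v = np.asarray(reference_point, dtype=float) - self.centroid
        return self.normal if float(v @ self.normal) >= 0.0 else -self.normal


def fit_ring_plane(positions) -> RingPlane:
    """Fit the least-squares plane through >=3 non-collinear points.

    The normal is the singular vector of the centered coordinates with the
    smallest singular value, i.e. it minimizes the sum of squared
    out-of-plane distances.  Sign is canonicalized so the largest-magnitude
    component is positive (callers needing a donor-side orientation use
    :meth:`RingPlane.oriented_normal`).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 3 or pos.shape[1] != 3:
        raise ValueError("fit_ring_plane(): need an (n>=3, 3) coordinate array")
    centroid = pos.mean(axis=0)
    centered = pos - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:
        raise ValueError("fit_ring_plane(): points are collinear")
    normal = vt[2]
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RingPlane(pos, centroid, normal / np.linalg.norm(normal), rms)


def plane_tilt(p: RingPlane, q: RingPlane) -> float:
    """Acute angle between two planes, degrees in [0, 90]."""
    c = abs(float(np.clip(p.normal @ q.normal, -1.0, 1.0)))
    return float(np.degrees(np.arccos(c)))


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of a moving onto a fixed atom set."""

    rotation: np.ndarray  # (3,3), proper: det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å, after applying the transform
    n_pairs: int

    def apply(self, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=float)
        return pos @ self.rotation.T + self.translation


def superpose(fixed, moving) -> SuperpositionResult:
    """Least-squares rigid superposition of *moving* onto *fixed* (Kabsch).

    Requires >=3 paired, non-collinear positions.  The rotation is forced
    proper (no reflection) by flipping the smallest singular direction when
    the raw solution has determinant -1.
    """
    f = np.asarray(fixed, dtype=float)
    m = np.asarray(moving, dtype=float)
    if f.shape != m.shape or f.ndim != 2 or f.shape[1] != 3:
        raise ValueError("superpose(): paired (n,3) arrays required")
    n = f.shape[0]
    if n < 3:
        raise ValueError("superpose(): need at least 3 atom pairs")
    fc = f.mean(axis=0)
    mc = m.mean(axis=0)
    F = f - fc
    M = m - mc
    cov = M.T @ F
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12:
        raise ValueError("superpose(): degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    D = np.diag([1.0, 1.0, d])
    rot = vt.T @ D @ u.T
    trans = fc - rot @ mc
    moved = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - f) ** 2, axis=-1))))
    return SuperpositionResult(rot, trans, rmsd, n)


def mainchain_rmsd(model_a, model_b, atoms=_MAINCHAIN_ATOMS,
                   frame_a: int = 0, frame_b: int = 0):
    """Superpose-then-RMSD over common main-chain atoms of two structures.

    Residues are paired by (chain, author residue number, insertion code);
    within a pair, only atoms present on both sides (names in *atoms*, with
    blank or highest-occupancy altloc) enter the fit.  The models are
    superposed on those pairs first, then the RMSD is measured — "common
    main-chain atoms" implies pair-then-fit, not distance on fixed frames.

    Returns ``(rmsd_Å, SuperpositionResult)``; the result carries the pair
    count so alternative pairings can be compared.
    """
    from .structure_io import _AA3  # polymer residue names

    pos_a = model_a.frame_positions(frame_a)
    pos_b = model_b.frame_positions(frame_b)

    def mainchain_map(model):
        out = {}
        for a in model.atoms:
            if a.name in atoms and a.resname in _AA3:
                key = (a.chain, a.resnum, a.icode, a.name)
                prev = out.get(key)
                if prev is None or (prev.altloc and a.occupancy > prev.occupancy):
                    out[key] = a
        return out

    ma = mainchain_map(model_a)
    mb = mainchain_map(model_b)
    common = sorted(set(ma) & set(mb))
    if len({(c, r, i) for c, r, i, _ in common}) < 3:
        raise ValueError("mainchain_rmsd(): fewer than 3 common residues")
    fixed = np.array([pos_a[ma[k].index] for k in common])
    moving = np.array([pos_b[mb[k].index] for k in common])
    res = superpose(fixed, moving)
    return res.rmsd, res


def place_atom(a, b, c, bond: float, ang: float, dihedral: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a-b-c.

    d is at distance *bond* (Å) from c, forming angle b-c-d of *ang*
    degrees, with torsion(a, b, c, d) equal to *dihedral* degrees (IUPAC
    sign).  The standard natural-extension construction; vectorized over
    leading axes of a, b, c (and of scalar-or-array internal coordinates).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    bond = np.asarray(bond, dtype=float)[..., None]
    th = np.radians(np.asarray(ang, dtype=float))[..., None]
    phi = -np.radians(np.asarray(dihedral, dtype=float))[..., None]
    b1 = c - b
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b - a
    nrm = np.cross(v, b1)
    nn = np.linalg.norm(nrm, axis=-1, keepdims=True)
    if np.any(nn < 1e-9):
        raise ValueError("place_atom(): reference atoms a,b,c are collinear")
    nrm = nrm / nn
    m = np.cross(nrm, b1)
    d = c + bond * (
        -np.cos(th) * b1 + np.sin(th) * (np.cos(phi) * m + np.sin(phi) * nrm)
    )
    return d
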