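"""Synthetic fixtures: a toy active site and coupled conformational ensembles.

The toy active site emulates the geometry of a urate-oxidase-like pocket:
a planar bicyclic ligand (six-membered pyrimidine-like ring fused to a
five-membered triazole-like ring, ideal 1.39 Å ring bonds), a Thr-like
hydroxyl, a Lys-like ammonium, an Asn-like amide in two alternate
conformations, and waters.  Every quantity of interest — hydrogen-bond
distances, the hydroxyl torsion, the water's radial (r, theta)
coordinates, an X-H...pi parameter triple — is *planted*: the coordinates
are constructed so the quantity takes a requested value exactly (to 1e-6,
before PDB 3-decimal rounding), and a manifest records all planted values.
The templates' ideal bond lengths and angles are fixed documented
scaffolding, not claims about ligand chemistry.

Ensembles couple a hidden two-state Markov chain (major/minor side-chain
conformation, persistent in time) to torsion-angle von Mises mixtures and
to the water's (r, theta) distribution, so that end-to-end parameter
recovery — torsion modes, toroidal cluster centers, residence occupancy,
state association — is testable against ground truth.  Frames realize the
sampled values through actual 3D coordinates, so analysis runs the full
geometry path rather than reading the manifest back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import distance, fit_ring_plane, place_atom, plane_tilt, torsion, wrap_degrees
from .structure_io import AtomSite, StructureModel, write_frame_table, write_structure

__all__ = [
    "ToyActiveSiteSpec",
    "EnsembleSpec",
    "MixtureComponent",
    "build_toy_active_site",
    "sample_torsion_mixture",
    "generate_ensemble",
    "write_fixture_set",
]

# water internal geometry used throughout (scaffolding constants)
_OH = 0.96  # Å
_HOH = 104.5  # degrees
_OD_MID = _OH * np.cos(np.radians(_HOH / 2.0))  # O to H1/H2 midpoint


@dataclass
class ToyActiveSiteSpec:
    """Requested internal geometry of the toy site.  All angles degrees, Å."""

    w1_r: float = 3.47  # ligand C5 to W1 oxygen
    w1_theta: float = 6.0  # torsion C4-C5-Ow-midpoint(H1,H2)
    w1_alpha: float = 80.0  # angle C4-C5-Ow (placement elevation)
    w1_psi: float = 100.0  # dihedral N3-C4-C5-Ow (placement azimuth)
    w1_tilt: float | None = 45.0  # W1 plane vs six-ring plane; None = free spin
    thr_torsion: float = -110.4  # CA-CB-OG1-DG1
    d_thr_dg1_w1o: float = 2.16  # planted H-bond, Thr hydroxyl D to W1 O
    d_thr_dg1_n7: float = 2.77  # planted contact, Thr hydroxyl D to ring N7
    thr_hbond_angle: float = 165.0  # OG1-DG1...W1O angle
    d_lys_dz1_og1: float = 1.97  # planted H-bond, Lys DZ1 to Thr OG1
    d_aza_d9_w2o: float = 1.84  # planted H-bond, ligand D9 to W2 O
    asn_d21_w1o: tuple = (2.23, 2.25)  # per-altloc amide D to W1 O
    asn_occupancies: tuple = (0.75, 0.25)
    pi_site: tuple | None = (3.64, 23.8, 141.0)  # planted (d_Om, omega, angle)
    include_asn_altlocs: bool = True


def _hexagon(bond: float = 1.39) -> dict:
    """Regular six-ring in the xy-plane, centroid at origin.

    Circumradius of a regular hexagon equals the bond length, so ideal
    1.39 Å ring bonds come out exactly.
    """
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    out = {}
    for k, nm in enumerate(names):
        a = np.radians(60.0 * k)
        out[nm] = bond * np.array([np.cos(a), np.sin(a), 0.0])
    return out


def _perp(u: np.ndarray, prefer: np.ndarray | None = None) -> np.ndarray:
    """A unit vector perpendicular to u, biased toward *prefer* if given."""
    if prefer is not None:
        p = prefer - (prefer @ u) * u
        n = np.linalg.norm(p)
        if n > 1e-9:
            return p / n
    trial = np.array([1.0, 0.0, 0.0])
    if abs(u @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = trial - (trial @ u) * u
    return p / np.linalg.norm(p)


def _sphere_circle_point(c1, r1, c2, r2, prefer_dir) -> np.ndarray:
    """A point on the intersection circle of two spheres.

    Deterministic: among the circle the point whose offset from the circle
    center best aligns with *prefer_dir* is returned.  Raises when the
    spheres do not intersect (infeasible planted geometry).
    """
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    d = float(np.linalg.norm(c2 - c1))
    if d < 1e-9 or d > r1 + r2 or d < abs(r1 - r2):
        raise ValueError(
            f"planted geometry infeasible: spheres r={r1:.2f}, r={r2:.2f} "
            f"with center separation {d:.2f} Å do not intersect"
        )
    u = (c2 - c1) / d
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = np.sqrt(max(r1 * r1 - a * a, 0.0))
    center = c1 + a * u
    return center + h * _perp(u, np.asarray(prefer_dir, float))


def _water_from_r_theta(c4, c5, ref, r, theta, alpha, psi, spin) -> tuple:
    """Place a water so that |C5-Ow| = r and torsion(C4,C5,Ow,mid(H)) = theta.

    Ow comes from internal coordinates (r, alpha, psi) off the ring; the
    H-midpoint direction is then placed by the theta torsion, and the two
    hydrogens open symmetrically about it, rotated by *spin* about the
    O->midpoint axis (which leaves theta invariant).
    """
    ow = place_atom(ref, c4, c5, r, alpha, psi)
    mid = place_atom(c4, c5, ow, _OD_MID, 120.0, theta)
    u = (mid - ow) / np.linalg.norm(mid - ow)
    v0 = _perp(u)
    sp = np.radians(spin)
    axis_rot = np.cos(sp) * v0 + np.sin(sp) * np.cross(u, v0)
    half = np.radians(_HOH / 2.0)
    h1 = ow + _OH * (np.cos(half) * u + np.sin(half) * axis_rot)
    h2 = ow + _OH * (np.cos(half) * u - np.sin(half) * axis_rot)
    return ow, h1, h2


def _solve_water_spin(c4, c5, ref, r, theta, alpha, psi, ring_pos, target_tilt):
    """Spin angle that makes the water plane tilt match *target_tilt*."""
    ring = fit_ring_plane(ring_pos)

    def tilt_at(spin):
        ow, h1, h2 = _water_from_r_theta(c4, c5, ref, r, theta, alpha, psi, spin)
        return plane_tilt(fit_ring_plane(np.array([ow, h1, h2])), ring)

    spins = np.linspace(0.0, 180.0, 361)
    tilts = np.array([tilt_at(s) for s in spins])
    best = int(np.argmin(np.abs(tilts - target_tilt)))
    lo = max(best - 1, 0)
    hi = min(best + 1, len(spins) - 1)
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda s: abs(tilt_at(s) - target_tilt),
        bounds=(spins[lo], spins[hi]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if res.fun > 0.5:
        raise ValueError(
            f"requested water-plane tilt {target_tilt}° unreachable "
            f"(closest achievable differs by {res.fun:.2f}°)"
        )
    return float(res.x)


def _pi_planted_water(ring_pos, d_om, omega, angle_xhm) -> tuple:
    """Place a water O and one H realizing an exact X-H...pi triple.

    O sits at distance d_om from the ring midpoint, at angle omega from the
    normal; H is put in the O-m-normal plane so the O-H...m angle at H is
    exactly *angle_xhm* (law of sines in the O-H-m triangle).
    """
    ring = fit_ring_plane(ring_pos)
    m = ring.centroid
    n = ring.normal
    side = _perp(n)
    w = np.radians(omega)
    o = m + d_om * (np.cos(w) * n + np.sin(w) * side)
    # triangle O-H-m: |Om| = d_om, |OH| = 0.96, angle at H = angle_xhm
    sin_at_m = _OH * np.sin(np.radians(angle_xhm)) / d_om
    if abs(sin_at_m) > 1.0:
        raise ValueError("pi-contact planting infeasible: no triangle solution")
    ang_m = np.degrees(np.arcsin(sin_at_m))
    ang_o = 180.0 - angle_xhm - ang_m
    u_om = (m - o) / np.linalg.norm(m - o)
    # rotate u_om by ang_o within the O-m-side plane, toward the ring plane
    axis = np.cross(n, side)
    axis /= np.linalg.norm(axis)
    c, s = np.cos(np.radians(ang_o)), np.sin(np.radians(ang_o))
    rot_u = (
        u_om * c + np.cross(axis, u_om) * s + axis * (axis @ u_om) * (1 - c)
    )
    h1 = o + _OH * rot_u
    # second hydrogen: complete the H-O-H angle in the same plane, away
    h2_dir_c = np.cos(np.radians(_HOH))
    h2 = o + _OH * (
        rot_u * h2_dir_c
        + np.cross(axis, rot_u) * np.sin(np.radians(_HOH))
        + axis * (axis @ rot_u) * (1 - h2_dir_c)
    )
    return o, h1, h2


class _Builder:
    """Accumulates AtomSites with sequential serials."""

    def __init__(self):
        self.atoms: list = []

    def add(self, name, element, pos, chain, resnum, resname,
            altloc="", occ=1.0, b=10.0):
        self.atoms.append(
            AtomSite(
                serial=len(self.atoms) + 1, name=name, element=element,
                altloc=altloc, occupancy=occ, position=np.asarray(pos, float),
                b_iso=b, chain=chain, resnum=resnum, icode="", resname=resname,
            )
        )
        return self.atoms[-1]


def build_toy_active_site(spec: ToyActiveSiteSpec | None = None):
    """Construct the toy active site and its ground-truth manifest.

    Returns ``(StructureModel, manifest)`` where the manifest maps every
    planted quantity (distances, the Thr torsion, W1's (r, theta) and plane
    tilt, the pi triple) to the exact value realized in the coordinates.
    """
    spec = spec or ToyActiveSiteSpec()
    b = _Builder()
    manifest: dict = {"distances": {}, "torsions": {}, "water_sites": {},
                      "pi_contacts": {}, "plane_tilts": {}}

    # --- ligand: fused 6-ring + 5-ring, coplanar, plus D9 ------------------
    hexa = _hexagon()
    ring6 = [hexa[n] for n in ("N1", "C2", "N3", "C4", "C5", "C6")]
    n3, c4, c5, c6 = hexa["N3"], hexa["C4"], hexa["C5"], hexa["C6"]
    n7 = place_atom(n3, c4, c5, 1.35, 132.0, 180.0)
    n9 = place_atom(c6, c5, c4, 1.35, 132.0, 180.0)
    n8 = place_atom(c4, c5, n7, 1.30, 104.0, 0.0)
    d9 = place_atom(c5, c4, n9, 1.01, 125.0, 180.0)
    for nm, el, p in [("N1", "N", hexa["N1"]), ("C2", "C", hexa["C2"]),
                      ("N3", "N", n3), ("C4", "C", c4), ("C5", "C", c5),
                      ("C6", "C", c6), ("N7", "N", n7), ("N8", "N", n8),
                      ("N9", "N", n9), ("D9", "D", d9)]:
        b.add(nm, el, p, "A", 400, "AZA")

    # --- W1 from (r, theta), optional tilt target --------------------------
    ring6_pos = np.array(ring6)
    if spec.w1_tilt is not None:
        spin = _solve_water_spin(c4, c5, n3, spec.w1_r, spec.w1_theta,
                                 spec.w1_alpha, spec.w1_psi, ring6_pos,
                                 spec.w1_tilt)
    else:
        spin = 30.0
    w1o, w1d1, w1d2 = _water_from_r_theta(
        c4, c5, n3, spec.w1_r, spec.w1_theta, spec.w1_alpha, spec.w1_psi, spin
    )
    b.add("O", "O", w1o, "S", 601, "DOD")
    b.add("D1", "D", w1d1, "S", 601, "DOD")
    b.add("D2", "D", w1d2, "S", 601, "DOD")
    manifest["water_sites"]["W1"] = {
        "r_A": spec.w1_r, "theta_deg": wrap_degrees(spec.w1_theta),
    }
    if spec.w1_tilt is not None:
        manifest["plane_tilts"]["W1_vs_ring6"] = spec.w1_tilt

    # --- Thr-like hydroxyl: planted torsion + two planted distances --------
    # DG1 must sit on both spheres (d to W1 O, d to ring N7); orient its
    # hydroxyl so the O-D...W1 hydrogen-bond angle is the requested value.
    up = np.array([0.0, 0.0, 1.0])
    dg1 = _sphere_circle_point(w1o, spec.d_thr_dg1_w1o, n7, spec.d_thr_dg1_n7,
                               prefer_dir=up + np.array([0.6, -0.8, 0.0]))
    w_dir = (w1o - dg1) / np.linalg.norm(w1o - dg1)
    p_dir = _perp(w_dir, prefer=up)
    hb = np.radians(spec.thr_hbond_angle)
    og1 = dg1 + _OH * (np.cos(hb) * w_dir + np.sin(hb) * p_dir)
    cb = place_atom(w1o, dg1, og1, 1.42, 107.0, 60.0)
    # IUPAC torsions are invariant under atom-order reversal, so placing CA
    # with dihedral(DG1,OG1,CB,CA) = t realizes torsion(CA,CB,OG1,DG1) = t
    ca = place_atom(dg1, og1, cb, 1.53, 109.5, spec.thr_torsion)
    n_thr = place_atom(og1, cb, ca, 1.45, 110.0, 180.0)
    for nm, el, p in [("N", "N", n_thr), ("CA", "C", ca), ("CB", "C", cb),
                      ("OG1", "O", og1), ("DG1", "D", dg1)]:
        b.add(nm, el, p, "B", 57, "THR")
    manifest["torsions"]["THR57_CA-CB-OG1-DG1"] = spec.thr_torsion
    manifest["distances"]["THR57_DG1-W1_O"] = spec.d_thr_dg1_w1o
    manifest["distances"]["THR57_DG1-AZA_N7"] = spec.d_thr_dg1_n7

    # --- Lys-like ammonium: planted salt-bridge-like H-bond to Thr OG1 -----
    out_dir = (og1 - cb) / np.linalg.norm(og1 - cb)
    dz1 = og1 + spec.d_lys_dz1_og1 * out_dir
    u_back = (og1 - dz1) / np.linalg.norm(og1 - dz1)
    p2 = _perp(u_back)
    a172 = np.radians(172.0)
    nz = dz1 + 1.01 * (np.cos(a172) * u_back + np.sin(a172) * p2)
    dz2 = place_atom(og1, dz1, nz, 1.01, 109.5, 60.0)
    dz3 = place_atom(og1, dz1, nz, 1.01, 109.5, 180.0)
    ce = place_atom(og1, dz1, nz, 1.51, 109.5, -60.0)
    for nm, el, p in [("CE", "C", ce), ("NZ", "N", nz), ("DZ1", "D", dz1),
                      ("DZ2", "D", dz2), ("DZ3", "D", dz3)]:
        b.add(nm, el, p, "B", 10, "LYS")
    manifest["distances"]["LYS10_DZ1-THR57_OG1"] = spec.d_lys_dz1_og1

    # --- W2: planted acceptor for the ligand's D9 --------------------------
    d9_dir = (d9 - n9) / np.linalg.norm(d9 - n9)
    w2o = d9 + spec.d_aza_d9_w2o * d9_dir
    # N9-D9-W2O is collinear by construction; use C4 as torsion reference
    w2d1 = place_atom(c4, d9, w2o, _OH, 109.0, 90.0)
    w2d2 = place_atom(c4, d9, w2o, _OH, 109.0, 90.0 + _HOH)
    b.add("O", "O", w2o, "S", 602, "DOD")
    b.add("D1", "D", w2d1, "S", 602, "DOD")
    b.add("D2", "D", w2d2, "S", 602, "DOD")
    manifest["distances"]["AZA_D9-W2_O"] = spec.d_aza_d9_w2o

    # --- Asn-like amide in two conformations, planted deuteron...W1 O ------
    if spec.include_asn_altlocs:
        occs = spec.asn_occupancies
        dirs = [
            _perp((w1o - ring6_pos.mean(axis=0)) / np.linalg.norm(w1o),
                  prefer=np.array([-0.5, 0.9, 0.3])),
            _perp((w1o - ring6_pos.mean(axis=0)) / np.linalg.norm(w1o),
                  prefer=np.array([-0.8, 0.2, 0.6])),
        ]
        # shared backbone (blank altloc)
        back_anchor = w1o + 3.8 * np.array([0.0, -0.4, 0.9]) / np.linalg.norm(
            [0.0, -0.4, 0.9])
        ca_a = back_anchor + np.array([1.2, 0.6, 0.8])
        n_a = ca_a + np.array([0.9, 1.0, 0.2])
        b.add("N", "N", n_a, "B", 254, "ASN")
        b.add("CA", "C", ca_a, "B", 254, "ASN")
        for tag, occ, ddir, dist in zip(("A", "B"), occs, dirs,
                                        spec.asn_d21_w1o):
            d21 = w1o + dist * ddir
            u_b = (w1o - d21) / np.linalg.norm(w1o - d21)
            pp = _perp(u_b)
            a160 = np.radians(160.0)
            nd2 = d21 + 1.01 * (np.cos(a160) * u_b + np.sin(a160) * pp)
            d22 = place_atom(w1o, d21, nd2, 1.01, 120.0, 180.0)
            cg = place_atom(w1o, d21, nd2, 1.33, 120.0, 0.0)
            od1 = place_atom(d21, nd2, cg, 1.23, 122.0, 180.0)
            cb_a = place_atom(d21, nd2, cg, 1.52, 116.0, 0.0)
            for nm, el, p in [("CB", "C", cb_a), ("CG", "C", cg),
                              ("OD1", "O", od1), ("ND2", "N", nd2),
                              ("D21", "D", d21), ("D22", "D", d22)]:
                b.add(nm, el, p, "B", 254, "ASN", altloc=tag, occ=occ)
            manifest["distances"][f"ASN254_D21_{tag}-W1_O"] = dist

    # --- optional exactly-planted pi-contact water -------------------------
    if spec.pi_site is not None:
        d_om, omega, ang = spec.pi_site
        po, ph1, ph2 = _pi_planted_water(ring6_pos, d_om, omega, ang)
        b.add("O", "O", po, "S", 603, "DOD")
        b.add("D1", "D", ph1, "S", 603, "DOD")
        b.add("D2", "D", ph2, "S", 603, "DOD")
        manifest["pi_contacts"]["W3_O-D1...ring6"] = {
            "d_xm_A": d_om, "omega_deg": omega, "angle_xhm_deg": ang,
        }

    model = StructureModel(b.atoms, cell=(60.0, 70.0, 80.0, 90.0, 90.0, 90.0),
                           spacegroup="I 2 2 2", source="synthetic-toy-site")
    return model, manifest


# ---------------------------------------------------------------------------
# ensembles


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float  # degrees
    kappa: float  # von Mises concentration


def sample_torsion_mixture(components, n: int, rng) -> np.ndarray:
    """Sample n angles (degrees) from a von Mises mixture, reproducibly.

    *rng* is a ``numpy.random.Generator`` or an integer seed.  Component
    weights must sum to 1.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    comps = [c if isinstance(c, MixtureComponent) else MixtureComponent(*c)
             for c in components]
    if not comps:
        raise ValueError("sample_torsion_mixture(): no components")
    w = np.array([c.weight for c in comps], float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("sample_torsion_mixture(): weights must sum to 1")
    choice = rng.choice(len(comps), size=n, p=w)
    out = np.empty(n)
    for k, c in enumerate(comps):
        m = choice == k
        out[m] = rng.vonmises(np.radians(c.mean), c.kappa, size=int(m.sum()))
    return np.asarray(wrap_degrees(np.degrees(out)))


@dataclass
class EnsembleSpec:
    """Parameters of a synthetic coupled ensemble.

    Defaults echo the study conditions the analysis is meant to resolve: a
    broad asymmetric hydroxyl-torsion profile with a dominant mode near
    -72° and a shoulder near -135°; four side-chain amide clusters on the
    torus, the crystallographic major conformation at (179°, 192°) and the
    minor at (272°, 81°) (printed in the 0-360° convention) at an
    approximate 75:25 ratio; a persistent two-state chain; a bound water
    state centred near r = 3.6 Å with a narrow dihedral distribution around
    10°, versus a displaced state near r = 4.3 Å with broad dihedrals in
    the 225-255° band.
    """

    n_frames: int = 10_000
    seed: int = 0
    # Thr-like hydroxyl torsion mixture (state-independent channel)
    thr_components: tuple = (
        MixtureComponent(0.8, -72.0, 12.0),
        MixtureComponent(0.2, -135.0, 20.0),
    )
    # hidden state chain
    states: tuple = ("major", "minor")
    transition: tuple = ((0.99, 0.01), (0.03, 0.97))  # rows sum to 1
    # 2D amide torsion components: (name, chi1 mean, chi2 mean, kappa,
    # weight in major state, weight in minor state); printed 0-360 means
    asn_components: tuple = (
        ("yellow", 179.0, 192.0, 40.0, 0.60, 0.0),
        ("green", 60.0, 210.0, 40.0, 0.20, 0.0),
        ("aqua", 330.0, 330.0, 40.0, 0.20, 0.0),
        ("grey", 272.0, 81.0, 40.0, 0.0, 1.0),
    )
    # water (r, theta) by state: (r mean Å, r sd Å, theta mean °, theta kappa)
    water_by_state: dict = field(default_factory=lambda: {
        "major": (3.6, 0.18, 10.0, 80.0),
        "minor": (4.3, 0.07, 240.0, 12.0),
    })
    jitter: float = 0.02  # Å Gaussian noise on non-planted atoms

    def __post_init__(self):
        for row in self.transition:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("transition matrix rows must sum to 1")
        for st in self.states:
            wsum = sum(c[4] if st == self.states[0] else c[5]
                       for c in self.asn_components)
            if abs(wsum - 1.0) > 1e-9:
                raise ValueError(f"asn component weights for state {st!r} "
                                 "must sum to 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _markov_chain(transition, n, rng) -> np.ndarray:
    """Sample a 2-state chain started from its stationary distribution."""
    t = np.asarray(transition, float)
    p01, p10 = t[0, 1], t[1, 0]
    pi0 = p10 / (p01 + p10)
    states = np.empty(n, dtype=int)
    u = rng.random(n)
    states[0] = 0 if u[0] < pi0 else 1
    stay = np.array([t[0, 0], t[1, 1]])
    for i in range(1, n):
        s = states[i - 1]
        states[i] = s if u[i] < stay[s] else 1 - s
    return states


def generate_ensemble(spec: EnsembleSpec | None = None):
    """Generate a coupled ensemble and its ground-truth manifest.

    Returns ``(StructureModel, manifest)``.  The manifest is a DataFrame
    with one row per frame: hidden state, amide component name, the sampled
    Thr torsion, chi1/chi2 amide torsions (wrapped to (-180, 180]), and the
    water's planted (r, theta).  All sampled quantities are realized
    through 3D coordinates, so re-measuring them from the frames exercises
    the full analysis path.
    """
    spec = spec or EnsembleSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    template, _ = build_toy_active_site(
        ToyActiveSiteSpec(w1_tilt=None, pi_site=None, include_asn_altlocs=False)
    )
    # a single-conformer Asn-like side chain for the torsion channels
    atoms = list(template.atoms)
    base = template.coords[0]
    w1o0 = next(a for a in atoms if a.resnum == 601 and a.name == "O")
    anchor = base[w1o0.index] + np.array([0.5, -1.5, 2.5])
    bld = _Builder()
    bld.atoms = atoms
    n_a = anchor + np.array([1.45, 0.0, 0.0])
    ca_a = anchor
    cb_a = anchor + np.array([-0.45, 1.10, 0.95])
    for nm, el, p in [("N", "N", n_a), ("CA", "C", ca_a), ("CB", "C", cb_a)]:
        bld.add(nm, el, p, "B", 254, "ASN")
    # CG/ND2 placed per frame; template positions are placeholders
    cg0 = place_atom(n_a, ca_a, cb_a, 1.52, 114.0, 180.0)
    nd20 = place_atom(ca_a, cb_a, cg0, 1.33, 120.0, 180.0)
    bld.add("CG", "C", cg0, "B", 254, "ASN")
    bld.add("ND2", "N", nd20, "B", 254, "ASN")
    atoms = bld.atoms
    for i, a in enumerate(atoms):
        a.index = i
    idx = {(a.chain, a.resnum, a.name): a.index for a in atoms}

    # --- sample the hidden chain and all channels --------------------------
    states = _markov_chain(spec.transition, n, rng)
    thr_vals = sample_torsion_mixture(spec.thr_components, n, rng)

    comp_names = [c[0] for c in spec.asn_components]
    w_major = np.array([c[4] for c in spec.asn_components])
    w_minor = np.array([c[5] for c in spec.asn_components])
    comp_idx = np.empty(n, dtype=int)
    for s, w in ((0, w_major), (1, w_minor)):
        m = states == s
        comp_idx[m] = rng.choice(len(comp_names), size=int(m.sum()), p=w)
    chi1 = np.empty(n)
    chi2 = np.empty(n)
    for k, c in enumerate(spec.asn_components):
        m = comp_idx == k
        nk = int(m.sum())
        chi1[m] = np.degrees(rng.vonmises(np.radians(c[1]), c[3], size=nk))
        chi2[m] = np.degrees(rng.vonmises(np.radians(c[2]), c[3], size=nk))
    chi1 = np.asarray(wrap_degrees(chi1))
    chi2 = np.asarray(wrap_degrees(chi2))

    r_w = np.empty(n)
    th_w = np.empty(n)
    for s, name in enumerate(spec.states):
        m = states == s
        rm, rs, tm, tk = spec.water_by_state[name]
        nk = int(m.sum())
        r_w[m] = np.abs(rng.normal(rm, rs, size=nk))
        th_w[m] = np.degrees(rng.vonmises(np.radians(tm), tk, size=nk))
    th_w = np.asarray(wrap_degrees(th_w))

    # --- realize through coordinates ---------------------------------------
    base = np.array([a.position for a in atoms])
    coords = np.broadcast_to(base, (n,) + base.shape).copy()
    if spec.jitter > 0:
        coords += rng.normal(0.0, spec.jitter, size=coords.shape)

    def at(chain, resnum, name):
        return idx[(chain, resnum, name)]

    c4 = coords[:, at("A", 400, "C4")]
    c5 = coords[:, at("A", 400, "C5")]
    n3 = coords[:, at("A", 400, "N3")]
    # Thr hydroxyl deuteron from the sampled torsion
    ca = coords[:, at("B", 57, "CA")]
    cb = coords[:, at("B", 57, "CB")]
    og1 = coords[:, at("B", 57, "OG1")]
    coords[:, at("B", 57, "DG1")] = place_atom(ca, cb, og1, _OH, 107.0, thr_vals)
    # amide side chain from chi1/chi2
    n_at = coords[:, at("B", 254, "N")]
    ca_at = coords[:, at("B", 254, "CA")]
    cb_at = coords[:, at("B", 254, "CB")]
    cg = place_atom(n_at, ca_at, cb_at, 1.52, 114.0, chi1)
    coords[:, at("B", 254, "CG")] = cg
    coords[:, at("B", 254, "ND2")] = place_atom(ca_at, cb_at, cg, 1.33, 120.0,
                                                chi2)
    # water from (r, theta); vectorized mirror of _water_from_r_theta
    ow = place_atom(n3, c4, c5, r_w, 80.0, 100.0)
    mid = place_atom(c4, c5, ow, np.full(n, _OD_MID), 120.0, th_w)
    u = mid - ow
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    trial = np.where(np.abs(u[:, :1]) > 0.9,
                     np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    v = trial - np.sum(trial * u, axis=-1, keepdims=True) * u
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    spin = rng.uniform(0.0, 360.0, size=n)[:, None]
    vq = (np.cos(np.radians(spin)) * v
          + np.sin(np.radians(spin)) * np.cross(u, v))
    half = np.radians(_HOH / 2.0)
    coords[:, at("S", 601, "O")] = ow
    coords[:, at("S", 601, "D1")] = ow + _OH * (np.cos(half) * u + np.sin(half) * vq)
    coords[:, at("S", 601, "D2")] = ow + _OH * (np.cos(half) * u - np.sin(half) * vq)

    model = StructureModel(atoms, coords, source="synthetic-ensemble")
    manifest = pd.DataFrame({
        "frame": np.arange(n),
        "state": [spec.states[s] for s in states],
        "component": [comp_names[k] for k in comp_idx],
        "thr_torsion_deg": thr_vals,
        "chi1_deg": chi1,
        "chi2_deg": chi2,
        "r_A": r_w,
        "theta_deg": th_w,
    })
    return model, manifest


def write_fixture_set(outdir, seed: int = 0, n_frames: int = 300) -> dict:
    """Write the canonical fixture corpus: toy PDB, ensemble table, manifests.

    Regeneration with the same seed is byte-identical.  Returns the file
    paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    toy, toy_manifest = build_toy_active_site()
    toy_path = outdir / "toy_active_site.pdb"
    write_structure(toy, toy_path)
    (outdir / "toy_active_site.manifest.json").write_text(
        json.dumps(toy_manifest, indent=1, sort_keys=True)
    )
    ens, ens_manifest = generate_ensemble(
        EnsembleSpec(n_frames=n_frames, seed=seed)
    )
    ens_path = outdir / "ensemble_frames.csv"
    write_frame_table(ens, ens_path)
    man_path = outdir / "ensemble_manifest.csv"
    ens_manifest.to_csv(man_path, index=False, float_format="%.6f")
    return {
        "toy_pdb": str(toy_path),
        "toy_manifest": str(outdir / "toy_active_site.manifest.json"),
        "ensemble": str(ens_path),
        "ensemble_manifest": str(man_path),
    }
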