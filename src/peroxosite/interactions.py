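"""Hydrogen-bond and X-H...pi contact detection and the active-site report.

Hydrogen bonds are located from explicit hydrogen (or deuterium) positions,
as resolved in neutron structures: a donor is any N/O/S heavy atom with a
covalently attached H/D (< 1.3 Å), an acceptor any N/O not belonging to the
same donor group.  Default geometric criteria — d(H...A) <= 2.5 Å and
angle(D-H...A) >= 120° — follow common neutron-structure practice and are
fully configurable; every report echoes the thresholds used.

An X-H...pi contact is parameterized classically by three quantities: the
distance d(X...m) from the donor heavy atom X to the ring midpoint m, the
angle omega(X) between the X...m line and the ring normal (acute), and the
angle at the hydrogen, X-H...m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .geometry import RingPlane
from .structure_io import AtomSite, Selection, StructureModel, select

log = logging.getLogger(__name__)

__all__ = [
    "HydrogenBond",
    "PiContact",
    "ActiveSiteReport",
    "HBondCriteria",
    "PiThresholds",
    "detect_hbonds",
    "characterize_pi_contact",
    "classify_pi_contact",
    "active_site_report",
]

_DONOR_ELEMENTS = {"N", "O", "S"}
_ACCEPTOR_ELEMENTS = {"N", "O"}
_COVALENT_XH_MAX = 1.3  # Å; upper bound for an X-H covalent bond


@dataclass(frozen=True)
class HBondCriteria:
    max_h_acceptor: float = 2.5  # Å, d(H...A)
    min_angle: float = 120.0  # degrees, D-H...A

    def as_dict(self):
        return {"max_h_acceptor_A": self.max_h_acceptor,
                "min_angle_deg": self.min_angle}


@dataclass(frozen=True)
class PiThresholds:
    max_d_xm: float = 4.3  # Å, donor heavy atom to ring midpoint
    max_omega: float = 30.0  # degrees, X...m line vs ring normal
    min_xhm_angle: float = 120.0  # degrees, angle at H

    def as_dict(self):
        return {"max_d_xm_A": self.max_d_xm, "max_omega_deg": self.max_omega,
                "min_xhm_angle_deg": self.min_xhm_angle}


@dataclass(frozen=True)
class HydrogenBond:
    donor: AtomSite
    hydrogen: AtomSite
    acceptor: AtomSite
    d_h_acceptor: float  # Å, H...A
    d_donor_acceptor: float  # Å, heavy donor...A
    angle_dha: float  # degrees, D-H...A

    def label(self) -> str:
        return f"{self.donor!r}-{self.hydrogen.name}...{self.acceptor!r}"


@dataclass(frozen=True)
class PiContact:
    donor: AtomSite
    hydrogen: AtomSite
    ring: RingPlane
    d_xm: float  # Å, X to ring midpoint
    omega: float  # degrees in [0, 90]
    angle_xhm: float  # degrees, X-H...m
    passes_classification: bool = False


def detect_hbonds(
    model: StructureModel,
    criteria: HBondCriteria | None = None,
    donor_scope: str | Selection | None = None,
    acceptor_scope: str | Selection | None = None,
    frame: int = 0,
) -> list:
    """Find hydrogen bonds from explicit H/D positions.

    Returns bonds sorted by d(H...A) then by atom keys, so the output is
    deterministic under any permutation of the input atom order.  Donors
    without an attached hydrogen are skipped with a log entry.
    """
    criteria = criteria or HBondCriteria()
    pos = model.frame_positions(frame)
    donors = [a for a in (select(model, donor_scope) if donor_scope else model.atoms)
              if a.element in _DONOR_ELEMENTS]
    acceptors = [a for a in (select(model, acceptor_scope) if acceptor_scope else model.atoms)
                 if a.element in _ACCEPTOR_ELEMENTS]
    hydrogens = [a for a in model.atoms if a.is_hydrogen]
    if not donors or not acceptors or not hydrogens:
        return []
    hpos = np.array([pos[h.index] for h in hydrogens])
    htree = cKDTree(hpos)
    bonds = []
    for d in donors:
        dp = pos[d.index]
        attached = [
            hydrogens[i]
            for i in htree.query_ball_point(dp, _COVALENT_XH_MAX)
            if _compatible_altloc(d, hydrogens[i])
        ]
        if not attached:
            log.debug("donor %r has no attached hydrogen; skipped", d)
            continue
        for h in attached:
            hp = pos[h.index]
            for a in acceptors:
                if a.index in (d.index, h.index):
                    continue
                if not (_compatible_altloc(d, a) and _compatible_altloc(h, a)):
                    continue
                ap = pos[a.index]
                dha = float(np.linalg.norm(hp - ap))
                if dha > criteria.max_h_acceptor:
                    continue
                # acceptor covalently bound to the donor is not an H-bond
                dda = float(np.linalg.norm(dp - ap))
                if dda < 1.8:
                    continue
                ang = geometry.angle(dp, hp, ap)
                if ang < criteria.min_angle:
                    continue
                bonds.append(
                    HydrogenBond(d, h, a, dha, dda, ang)
                )
    bonds.sort(key=lambda b: (b.d_h_acceptor, b.donor.key, b.acceptor.key))
    return bonds


def _compatible_altloc(a: AtomSite, b: AtomSite) -> bool:
    """Blank altloc is shared by every conformer; tags must match otherwise."""
    return a.altloc == "" or b.altloc == "" or a.altloc == b.altloc


def characterize_pi_contact(
    x_atom: AtomSite,
    h_atom: AtomSite,
    ring_atoms: list,
    positions: np.ndarray | None = None,
) -> PiContact:
    """Compute the (d_X...m, omega(X), angle X-H...m) triple for one contact.

    The ring plane is least-squares fitted through *ring_atoms*; omega is
    the acute angle between the X->m line and the ring normal.  H must be
    covalently bonded to X (< 1.3 Å).
    """
    xp = positions[x_atom.index] if positions is not None else x_atom.position
    hp = positions[h_atom.index] if positions is not None else h_atom.position
    if float(np.linalg.norm(xp - hp)) >= _COVALENT_XH_MAX:
        raise ValueError(
            f"pi contact: hydrogen {h_atom!r} is not bonded to {x_atom!r}"
        )
    ring_pos = np.array(
        [positions[a.index] if positions is not None else a.position
         for a in ring_atoms]
    )
    ring = geometry.fit_ring_plane(ring_pos)
    m = ring.centroid
    xm = xp - m
    d_xm = float(np.linalg.norm(xm))
    cosw = abs(float(np.clip(xm @ ring.normal / d_xm, -1.0, 1.0)))
    omega = float(np.degrees(np.arccos(cosw)))
    angle_xhm = geometry.angle(xp, hp, m)
    return PiContact(x_atom, h_atom, ring, d_xm, omega, angle_xhm)


def classify_pi_contact(c: PiContact, thresholds: PiThresholds | None = None) -> bool:
    """Pure threshold predicate on an already-characterized contact."""
    t = thresholds or PiThresholds()
    return (
        c.d_xm <= t.max_d_xm
        and c.omega <= t.max_omega
        and c.angle_xhm >= t.min_xhm_angle
    )


# ---------------------------------------------------------------------------
# active-site report


@dataclass
class ActiveSiteReport:
    """Machine-readable geometry report for a configured active site."""

    distances: dict = field(default_factory=dict)  # label -> Å (per altloc)
    torsions: dict = field(default_factory=dict)  # label -> degrees
    hbonds: list = field(default_factory=list)
    pi_contacts: dict = field(default_factory=dict)  # label -> PiContact
    plane_tilts: dict = field(default_factory=dict)  # label -> degrees
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "distances_A": self.distances,
            "torsions_deg": self.torsions,
            "plane_tilts_deg": self.plane_tilts,
            "pi_contacts": {
                lbl: {
                    "d_xm_A": c.d_xm,
                    "omega_deg": c.omega,
                    "angle_xhm_deg": c.angle_xhm,
                    "passes": c.passes_classification,
                }
                for lbl, c in self.pi_contacts.items()
            },
            "hbonds": [
                {
                    "donor": repr(b.donor),
                    "hydrogen": b.hydrogen.name,
                    "acceptor": repr(b.acceptor),
                    "d_h_acceptor_A": b.d_h_acceptor,
                    "d_donor_acceptor_A": b.d_donor_acceptor,
                    "angle_deg": b.angle_dha,
                }
                for b in self.hbonds
            ],
            "provenance": self.provenance,
        }


def _resolve_role(model: StructureModel, role) -> list:
    """Resolve a role spec to the matching atoms.

    A role is (chain, resnum, atomname[, altloc]) or a selection string.
    Without an altloc, all altloc variants of the atom are returned
    (possibly just the blank one); with one, only that conformer.
    """
    if isinstance(role, (tuple, list)) and len(role) in (3, 4):
        chain, resnum, name = role[:3]
        altloc = role[3] if len(role) == 4 else None
        rv = model.residue(str(chain), int(resnum))
        atoms = [a for a in rv.atoms
                 if a.name == name and (altloc is None or a.altloc == altloc)
                 ] if rv else []
    else:
        atoms = select(model, role)
    return atoms


def _per_altloc_values(atoms_a, atoms_b, fn) -> dict:
    """Evaluate fn(a, b) for every compatible altloc pairing.

    Returns {"" or tag: value}; when either atom has altlocs, one value per
    tag is emitted (never a silent average).
    """
    out = {}
    for a in atoms_a:
        for b in atoms_b:
            if not _compatible_altloc(a, b):
                continue
            tag = a.altloc or b.altloc or ""
            out[tag] = fn(a, b)
    return out


def active_site_report(model: StructureModel, config: dict,
                       frame: int = 0) -> ActiveSiteReport:
    """Emit every configured distance/torsion/pi-contact/tilt for a model.

    *config* keys (all optional):

    - ``distances``: list of [label, role_a, role_b]
    - ``torsions``: list of [label, role_a, role_b, role_c, role_d]
    - ``pi_contacts``: list of [label, X role, H role, ring role (selection)]
    - ``plane_tilts``: list of [label, plane-1 role, plane-2 role] where each
      plane role is a selection resolving to >=3 atoms
    - ``hbond_scope``: [donor selection, acceptor selection]
    - ``hbond_criteria`` / ``pi_thresholds``: threshold overrides

    Quantities touching an atom with alternate conformations are reported
    once per altloc tag.  Unresolved roles raise, listing the missing atoms.
    """
    rep = ActiveSiteReport()
    pos = model.frame_positions(frame)
    criteria = HBondCriteria(**config.get("hbond_criteria", {}))
    thresholds = PiThresholds(**config.get("pi_thresholds", {}))
    rep.provenance = {
        "source": model.source,
        "frame": frame,
        "hbond_criteria": criteria.as_dict(),
        "pi_thresholds": thresholds.as_dict(),
        "altloc_policy": "per-altloc values; blank shared by all conformers",
    }

    def must_resolve(role, label):
        atoms = _resolve_role(model, role)
        if not atoms:
            raise ValueError(f"report role {role!r} (for {label!r}) "
                             "resolved to no atoms")
        return atoms

    for label, ra, rb in config.get("distances", []):
        aa = must_resolve(ra, label)
        bb = must_resolve(rb, label)
        vals = _per_altloc_values(
            aa, bb, lambda a, b: float(np.linalg.norm(pos[a.index] - pos[b.index]))
        )
        rep.distances[label] = vals

    for label, *roles in config.get("torsions", []):
        quads = [must_resolve(r, label) for r in roles]
        # use highest-occupancy variant of each role; report per-altloc when
        # exactly one role carries the alternates
        tags = sorted({a.altloc for atoms in quads for a in atoms if a.altloc}) or [""]
        vals = {}
        for tag in tags:
            chosen = []
            for atoms in quads:
                cands = [a for a in atoms if a.altloc in ("", tag)]
                cands.sort(key=lambda a: (a.altloc == "", -a.occupancy))
                chosen.append(cands[0] if cands else None)
            if any(c is None for c in chosen):
                continue
            vals[tag] = geometry.torsion(*[pos[c.index] for c in chosen])
        rep.torsions[label] = vals

    for label, rx, rh, rring in config.get("pi_contacts", []):
        x = must_resolve(rx, label)[0]
        h = must_resolve(rh, label)[0]
        ring_atoms = must_resolve(rring, label)
        c = characterize_pi_contact(x, h, ring_atoms, pos)
        c = PiContact(c.donor, c.hydrogen, c.ring, c.d_xm, c.omega, c.angle_xhm,
                      classify_pi_contact(c, thresholds))
        rep.pi_contacts[label] = c

    for label, rp, rq in config.get("plane_tilts", []):
        pa = must_resolve(rp, label)
        qa = must_resolve(rq, label)
        plane_p = geometry.fit_ring_plane(np.array([pos[a.index] for a in pa]))
        plane_q = geometry.fit_ring_plane(np.array([pos[a.index] for a in qa]))
        rep.plane_tilts[label] = geometry.plane_tilt(plane_p, plane_q)

    scope = config.get("hbond_scope")
    if scope:
        rep.hbonds = detect_hbonds(model, criteria, scope[0], scope[1], frame)
    return rep
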