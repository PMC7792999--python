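"""Crystallographic coordinate I/O with altloc, occupancy and deuterium fidelity.

Reading and writing go through :mod:`gemmi`; the in-memory model is a thin
set of dataclasses tailored to geometry analysis.  Deuterium atoms keep
element "D" (they are treated as hydrogen for donor roles downstream but
never renamed).  Atoms with a blank altloc are shared by every conformer
of their residue; ``conformer_atoms`` expands one complete atom set per
tag.

Ensembles are either multi-model PDB files or a plain frame table (one row
per atom per frame, columns frame, chain, resnum, resname, atomname,
altloc, x, y, z; comma- or whitespace-delimited) so no binary trajectory
dependency is needed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomSite",
    "ResidueView",
    "StructureModel",
    "Selection",
    "read_structure",
    "write_structure",
    "select",
    "read_ensemble",
]

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


@dataclass
class AtomSite:
    """One atom site of one conformer (or the shared blank conformer)."""

    serial: int
    name: str
    element: str
    altloc: str  # single char, "" for blank
    occupancy: float
    position: np.ndarray  # 3-vector, Å, orthogonal frame
    b_iso: float
    chain: str
    resnum: int
    icode: str
    resname: str
    index: int = -1  # stable index into the model's atom list

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")

    @property
    def is_hydrogen(self) -> bool:
        """True for H and D alike — deuterium is chemically hydrogen."""
        return self.element in _HYDROGEN_ELEMENTS

    @property
    def key(self):
        return (self.chain, self.resnum, self.icode, self.name, self.altloc)

    def __repr__(self):  # compact, for error messages
        alt = f".{self.altloc}" if self.altloc else ""
        return f"<{self.chain}/{self.resname}{self.resnum}/{self.name}{alt}>"


@dataclass
class ResidueView:
    chain: str
    resnum: int
    icode: str
    resname: str
    atoms: list = field(default_factory=list)

    @property
    def altlocs(self) -> list:
        """Non-blank altloc tags present, sorted."""
        return sorted({a.altloc for a in self.atoms if a.altloc})

    def conformer_atoms(self, tag: str) -> list:
        """Complete atom set of conformer *tag*: blank atoms plus tag atoms."""
        return [a for a in self.atoms if a.altloc in ("", tag)]

    def atom(self, name: str, altloc: str | None = None):
        hits = [
            a
            for a in self.atoms
            if a.name == name and (altloc is None or a.altloc in ("", altloc))
        ]
        if not hits:
            return None
        # prefer exact altloc match, then highest occupancy
        hits.sort(key=lambda a: (a.altloc != (altloc or a.altloc), -a.occupancy))
        return hits[0]


class StructureModel:
    """A crystal structure or conformational ensemble.

    ``atoms`` holds the topology (one entry per unique atom site);
    ``coords`` has shape (n_frames, n_atoms, 3).  Frame 0 positions are
    mirrored into each :class:`AtomSite` for single-structure use.
    """

    def __init__(
        self,
        atoms: list,
        coords: np.ndarray | None = None,
        cell=None,
        spacegroup: str = "",
        source: str = "",
    ):
        # copy the sites: a model owns its atoms (index/frame-0 position are
        # model-specific, and callers may share AtomSites between models)
        self.atoms = [dataclasses.replace(a) for a in atoms]
        for i, a in enumerate(self.atoms):
            a.index = i
        seen = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom key {a.key}")
            seen.add(a.key)
        if coords is None:
            coords = np.array([[a.position for a in self.atoms]], dtype=float)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        for a, p in zip(self.atoms, self.coords[0]):
            a.position = p
        if cell is not None:
            a_, b_, c_ = cell[:3]
            if min(a_, b_, c_) <= 0:
                raise ValueError("unit-cell lengths must be positive")
        self.cell = tuple(cell) if cell is not None else None
        self.spacegroup = spacegroup
        self.source = source

    # -- basic introspection -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame_positions(self, i: int = 0) -> np.ndarray:
        return self.coords[i]

    def residues(self) -> list:
        by_key: dict = {}
        for a in self.atoms:
            k = (a.chain, a.resnum, a.icode, a.resname)
            rv = by_key.get(k)
            if rv is None:
                rv = by_key[k] = ResidueView(*k)
            rv.atoms.append(a)
        return list(by_key.values())

    def residue(self, chain: str, resnum: int, icode: str = ""):
        for rv in self.residues():
            if (rv.chain, rv.resnum, rv.icode) == (chain, resnum, icode):
                return rv
        return None

    def atom(self, chain: str, resnum: int, name: str, altloc: str | None = None):
        rv = self.residue(chain, resnum)
        return rv.atom(name, altloc) if rv else None

    def summary(self) -> dict:
        """Composition counts: polymer residues, waters, ligands, ions."""
        n_protein = n_water = 0
        ligands: dict = {}
        for rv in self.residues():
            if rv.resname in ("HOH", "DOD", "WAT"):
                n_water += 1
            elif rv.resname in _AA3:
                n_protein += 1
            else:
                ligands[rv.resname] = ligands.get(rv.resname, 0) + 1
        return {
            "protein_residues": n_protein,
            "waters": n_water,
            "heterogens": ligands,
        }


_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


# ---------------------------------------------------------------------------
# reading / writing


def _atoms_from_gemmi_model(gm) -> list:
    out = []
    for chain in gm:
        for res in chain:
            icode = res.seqid.icode.strip()
            for at in res:
                elem = at.element.name
                if elem == "X" or not elem:
                    raise ValueError(
                        f"unknown element for atom {at.name} in "
                        f"{chain.name}/{res.name}{res.seqid.num}"
                    )
                out.append(
                    AtomSite(
                        serial=at.serial,
                        name=at.name,
                        element=elem,
                        altloc=at.altloc if at.altloc != "\0" else "",
                        occupancy=at.occ,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        b_iso=at.b_iso,
                        chain=chain.name,
                        resnum=res.seqid.num,
                        icode=icode,
                        resname=res.name,
                    )
                )
    return out


def read_structure(path, dialect: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    *dialect* is "pdb" or "mmcif"; by default it is inferred from the file
    extension.  Every ATOM/HETATM site is captured with element, altloc and
    occupancy; deuterium stays element "D".  A multi-model file yields one
    coordinate frame per MODEL, matched to the first model's atom order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    fmt = gemmi.CoorFormat.Mmcif if dialect == "mmcif" else gemmi.CoorFormat.Pdb
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"cannot parse {path} as {dialect}: {e}") from e
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    atoms = _atoms_from_gemmi_model(st[0])
    if not atoms:
        raise ValueError(f"{path}: no atom sites found")
    frames = [np.array([a.position for a in atoms])]
    if len(st) > 1:
        index = {a.key: i for i, a in enumerate(atoms)}
        for mi in range(1, len(st)):
            fr = _atoms_from_gemmi_model(st[mi])
            if len(fr) != len(atoms):
                raise ValueError(
                    f"{path}: model {mi + 1} has {len(fr)} atoms, "
                    f"expected {len(atoms)}"
                )
            pos = np.empty((len(atoms), 3))
            for a in fr:
                j = index.get(a.key)
                if j is None:
                    raise ValueError(
                        f"{path}: model {mi + 1} atom {a!r} absent from model 1"
                    )
                pos[j] = a.position
            frames.append(pos)
    cell = None
    if st.cell and st.cell.a > 0:
        c = st.cell
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    return StructureModel(
        atoms,
        np.stack(frames),
        cell=cell,
        spacegroup=st.spacegroup_hm or "",
        source=str(path),
    )


def write_structure(model: StructureModel, path, frame: int | None = None) -> None:
    """Write a model (or all its frames) as PDB v3.3.

    Coordinates go out at the fixed 3-decimal PDB precision; occupancies and
    altlocs are preserved.  With *frame* = None every frame becomes a MODEL
    record; otherwise the single requested frame is written.
    """
    if not model.atoms:
        raise ValueError("write_structure(): refusing to write an empty model")
    st = gemmi.Structure()
    st.name = "peroxosite"
    if model.cell:
        st.cell = gemmi.UnitCell(*model.cell)
    if model.spacegroup:
        st.spacegroup_hm = model.spacegroup
    frames = range(model.n_frames) if frame is None else [frame]
    for fi in frames:
        gm = gemmi.Model(fi + 1)
        pos = model.coords[fi]
        # group atoms into chains/residues preserving model order; gemmi
        # copies on add_chain/add_model, so build each chain fully first
        chains: list = []
        for a in model.atoms:
            if not chains or chains[-1][0] != a.chain:
                chains.append((a.chain, []))
            ch_atoms = chains[-1][1]
            rkey = (a.resnum, a.icode, a.resname)
            if not ch_atoms or ch_atoms[-1][0] != rkey:
                ch_atoms.append((rkey, []))
            ch_atoms[-1][1].append(a)
        for chain_name, residues in chains:
            gch = gemmi.Chain(chain_name)
            for (resnum, icode, resname), res_atoms in residues:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(resnum, icode or " ")
                res.het_flag = "A" if resname in _AA3 else "H"
                for a in res_atoms:
                    at = gemmi.Atom()
                    at.name = a.name
                    at.element = gemmi.Element(a.element)
                    at.altloc = a.altloc or "\0"
                    at.occ = a.occupancy
                    at.b_iso = a.b_iso
                    p = pos[a.index]
                    at.pos = gemmi.Position(p[0], p[1], p[2])
                    res.add_atom(at)
                gch.add_residue(res)
            gm.add_chain(gch)
        st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# selections
#
# Tiny expression language over atom attributes:
#   chain A B | resname AZA HOH | resnum 57 or resnum 10:20
#   name OG1 DG1 | altloc A | element O D | water | hydrogen | all
# combined with `and`, `or`, `not` and parentheses.  An `altloc X` filter
# keeps blank-altloc atoms (PDB convention: blank is shared by all
# conformers).


class Selection:
    """Parsed, reusable selection expression."""

    def __init__(self, expr: str):
        self.expr = expr
        self._ast = _parse(_tokenize(expr))

    def mask(self, model: StructureModel) -> np.ndarray:
        return self._ast(model)

    def __repr__(self):
        return f"Selection({self.expr!r})"


def _tokenize(expr: str) -> list:
    out = []
    for raw in expr.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


_KEYWORDS = {"and", "or", "not", "(", ")", "chain", "resname", "resnum",
             "name", "altloc", "element", "water", "hydrogen", "all"}


def _parse(tokens: list):
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else None

    def take():
        t = peek()
        pos[0] += 1
        return t

    def parse_or():
        node = parse_and()
        while peek() == "or":
            take()
            rhs = parse_and()
            node = _combine(np.logical_or, node, rhs)
        return node

    def parse_and():
        node = parse_not()
        while peek() == "and":
            take()
            rhs = parse_not()
            node = _combine(np.logical_and, node, rhs)
        return node

    def parse_not():
        if peek() == "not":
            take()
            inner = parse_not()
            return lambda m: np.logical_not(inner(m))
        return parse_primary()

    def parse_primary():
        t = take()
        if t is None:
            raise ValueError("selection: unexpected end of expression")
        if t == "(":
            node = parse_or()
            if take() != ")":
                raise ValueError("selection: unbalanced parentheses")
            return node
        if t == "all":
            return lambda m: np.ones(len(m.atoms), dtype=bool)
        if t == "water":
            return lambda m: np.array(
                [a.resname in ("HOH", "DOD", "WAT") for a in m.atoms]
            )
        if t == "hydrogen":
            return lambda m: np.array([a.is_hydrogen for a in m.atoms])
        if t in ("chain", "resname", "name", "element", "altloc", "resnum"):
            args = []
            while peek() is not None and peek() not in _KEYWORDS:
                args.append(take())
            if not args:
                raise ValueError(f"selection: '{t}' needs at least one argument")
            return _field_test(t, args)
        raise ValueError(f"selection: unknown token {t!r}")

    node = parse_or()
    if peek() is not None:
        raise ValueError(f"selection: trailing tokens at {peek()!r}")
    return node


def _combine(op, lhs, rhs):
    return lambda m: op(lhs(m), rhs(m))


def _field_test(field: str, args: list):
    if field == "resnum":
        ranges = []
        for a in args:
            if ":" in a:
                lo, hi = a.split(":")
                ranges.append((int(lo), int(hi)))
            else:
                ranges.append((int(a), int(a)))

        def test(m):
            return np.array(
                [any(lo <= at.resnum <= hi for lo, hi in ranges) for at in m.atoms]
            )

        return test
    if field == "altloc":
        tags = set(args)

        def test(m):
            # blank-altloc atoms are shared by every conformer
            return np.array([(a.altloc == "" or a.altloc in tags) for a in m.atoms])

        return test
    vals = set(args)
    getter = {
        "chain": lambda a: a.chain,
        "resname": lambda a: a.resname,
        "name": lambda a: a.name,
        "element": lambda a: a.element,
    }[field]
    return lambda m: np.array([getter(a) in vals for a in m.atoms])


def select(model: StructureModel, expr, strict: bool = False) -> list:
    """Resolve a selection to a deterministic, order-stable atom list.

    *expr* may be a string or a :class:`Selection`.  An empty result is
    returned silently unless *strict*, in which case it raises.
    """
    sel = expr if isinstance(expr, Selection) else Selection(str(expr))
    mask = sel.mask(model)
    atoms = [a for a, keep in zip(model.atoms, mask) if keep]
    if strict and not atoms:
        raise ValueError(f"selection {sel.expr!r} matched no atoms")
    return atoms


# ---------------------------------------------------------------------------
# ensembles

_FRAME_COLUMNS = [
    "frame", "chain", "resnum", "resname", "atomname", "altloc", "x", "y", "z",
]


def read_ensemble(path, fmt: str | None = None) -> StructureModel:
    """Read a conformational ensemble.

    *fmt* is "multi-model-pdb" or "frame-table"; inferred from the
    extension by default (.pdb vs .csv/.tsv/.dat).  Frames must share a
    consistent atom set; a short frame raises an error naming it.
    """
    path = Path(path)
    if fmt is None:
        fmt = "multi-model-pdb" if path.suffix.lower() in (".pdb", ".ent") else "frame-table"
    if fmt == "multi-model-pdb":
        return read_structure(path, dialect="pdb")
    if fmt != "frame-table":
        raise ValueError(f"unknown ensemble format {fmt!r}")
    head = path.open().readline()
    sep = "," if "," in head else r"\s+"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in _FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: frame table missing columns {missing}")
    df["altloc"] = df["altloc"].fillna("").astype(str).str.replace(".", "", regex=False)
    frames = []
    atoms = None
    ref_keys = None
    for fi, grp in df.groupby("frame", sort=True):
        keys = list(
            zip(grp["chain"], grp["resnum"], grp["atomname"], grp["altloc"])
        )
        if atoms is None:
            atoms = [
                AtomSite(
                    serial=i + 1,
                    name=str(r.atomname),
                    element=_guess_element(str(r.atomname)),
                    altloc=str(r.altloc),
                    occupancy=1.0,
                    position=np.array([r.x, r.y, r.z]),
                    b_iso=0.0,
                    chain=str(r.chain),
                    resnum=int(r.resnum),
                    icode="",
                    resname=str(r.resname),
                )
                for i, r in enumerate(grp.itertuples())
            ]
            ref_keys = keys
        elif keys != ref_keys:
            missing_atoms = set(ref_keys) - set(keys)
            raise ValueError(
                f"{path}: frame {fi} atom set differs from frame 0"
                + (f" (missing {sorted(missing_atoms)[:3]})" if missing_atoms else "")
            )
        frames.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
    if atoms is None:
        raise ValueError(f"{path}: empty frame table")
    return StructureModel(atoms, np.stack(frames), source=str(path))


def write_frame_table(model: StructureModel, path) -> None:
    """Write an ensemble as the plain frame-table CSV dialect."""
    rows = []
    for fi in range(model.n_frames):
        pos = model.coords[fi]
        for a in model.atoms:
            p = pos[a.index]
            rows.append(
                (fi, a.chain, a.resnum, a.resname, a.name, a.altloc or "",
                 round(p[0], 6), round(p[1], 6), round(p[2], 6))
            )
    pd.DataFrame(rows, columns=_FRAME_COLUMNS).to_csv(path, index=False)


def _guess_element(name: str) -> str:
    """Element from an atom name (frame tables carry no element column)."""
    s = name.strip()
    if not s:
        raise ValueError("empty atom name")
    if s[0].isdigit():
        s = s.lstrip("0123456789")
    for two in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN"):
        if s.upper().startswith(two) and len(s) > 1:
            return two.capitalize()
    c = s[0].upper()
    if c in "CNOSPHDFKI":
        return "D" if c == "D" else c
    raise ValueError(f"cannot infer element from atom name {name!r}")
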