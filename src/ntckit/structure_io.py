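"""Reading, writing and symmetry expansion of nucleic-acid structures.

The in-memory model is deliberately small: a :class:`Structure` holds ordered
chains of :class:`Nucleotide` objects plus a list of heteroatom groups (ions
and other non-polymer residues).  Parsing and serialisation of mmCIF/PDB files
is delegated to :mod:`gemmi`; only the polymer bookkeeping (parent-base
mapping, altloc policy, hydrogen stripping) lives here.

Conventions
-----------
* author residue numbering is authoritative and never rewritten;
* for alternate locations the highest-occupancy conformer is kept
  (ties broken by the lexicographically first altloc id);
* hydrogens are dropped on input -- all downstream geometry is heavy-atom only;
* coordinates are Cartesian angstroms; fractional coordinates appear only
  inside the symmetry arithmetic.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Nucleotide",
    "HetGroup",
    "Structure",
    "SymmetryCopy",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "map_parent_base",
    "count_heavy_atoms",
    "expand_symmetry",
    "load_sequence",
    "SUGAR_ATOMS",
    "PHOSPHATE_ATOMS",
    "BASE_HEAVY_ATOMS",
]


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed in the requested dialect."""


#: heavy atoms of the 2'-deoxyribose (8 per residue)
SUGAR_ATOMS = ("C1'", "C2'", "C3'", "C4'", "C5'", "O3'", "O4'", "O5'")
#: phosphate group atoms, absent on a 5'-OH terminal residue
PHOSPHATE_ATOMS = ("P", "OP1", "OP2")
#: heavy base atoms per parent base (A=10, C=8, G=11, T=9, U=8)
BASE_HEAVY_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "T": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

_PARENT_BASE = {
    "DA": "A", "A": "A", "ADE": "A",
    "DC": "C", "C": "C", "CYT": "C",
    "DG": "G", "G": "G", "GUA": "G",
    "DT": "T", "T": "T", "THY": "T",
    "DU": "U", "U": "U", "URA": "U",
    # brominated uracil substitutes a thymine position; the bromine atom is
    # ignored for pairing and torsion purposes
    "BRU": "T", "5BU": "T", "BU": "T",
}


def map_parent_base(res_name: str) -> str:
    """Map a residue name to its parent base letter (sentinel ``X`` if unknown)."""
    return _PARENT_BASE.get(res_name.strip().upper(), "X")


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 20.0
    altloc: str = ""

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_iso < 0:
            raise ValueError("negative B factor")


@dataclass
class Nucleotide:
    chain_id: str
    res_num: int
    res_name: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    icode: str = ""
    parent_base: str = field(default="", repr=True)

    def __post_init__(self):
        if not self.parent_base:
            self.parent_base = map_parent_base(self.res_name)

    @property
    def res_id(self) -> str:
        return f"{self.chain_id}/{self.res_num}{self.icode}"

    def has(self, name: str) -> bool:
        return name in self.atoms

    def pos(self, name: str) -> np.ndarray:
        return self.atoms[name].pos

    @property
    def is_purine(self) -> bool:
        return self.parent_base in ("A", "G")


@dataclass
class HetGroup:
    """A non-polymer residue (ion, ligand) kept outside the chains."""

    chain_id: str
    res_num: int
    res_name: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    icode: str = ""


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Nucleotide]] = field(default_factory=dict)
    hets: list[HetGroup] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] = (1, 1, 1, 90, 90, 90)
    space_group: str = "P 1"
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        if not self.sym_ops:
            try:
                self.sym_ops = _spacegroup_ops(self.space_group)
            except Exception:
                self.sym_ops = []
        if not self.sym_ops:
            self.sym_ops = [(np.eye(3), np.zeros(3))]
        for chain in self.chains.values():
            chain.sort(key=lambda nt: (nt.res_num, nt.icode))

    def nucleotides(self):
        for chain in self.chains.values():
            yield from chain

    def all_atoms(self, include_het: bool = True):
        for nt in self.nucleotides():
            yield from nt.atoms.values()
        if include_het:
            for het in self.hets:
                yield from het.atoms.values()

    def coords(self, include_het: bool = True) -> np.ndarray:
        pts = [a.pos for a in self.all_atoms(include_het)]
        return np.array(pts) if pts else np.zeros((0, 3))

    def sequence(self, chain_id: str) -> str:
        return "".join(nt.parent_base for nt in self.chains[chain_id])


@dataclass
class SymmetryCopy:
    """One symmetry/lattice image of a structure, with its generating operator."""

    op_triplet: str
    shift: tuple[int, int, int]
    structure: Structure
    min_distance: float


# ---------------------------------------------------------------------------
# reading / writing


def _spacegroup_ops(hm_symbol: str) -> list[tuple[np.ndarray, np.ndarray]]:
    sg = gemmi.SpaceGroup(hm_symbol)
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
        ops.append((rot, tran))
    return ops


def _select_altlocs(raw_atoms: list[Atom]) -> dict[str, Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc id."""
    out: dict[str, Atom] = {}
    for atom in sorted(raw_atoms, key=lambda a: (a.name, -a.occupancy, a.altloc)):
        out.setdefault(atom.name, atom)
    return out


def _from_gemmi(st: gemmi.Structure) -> Structure:
    st.setup_entities()
    model = st[0]
    chains: dict[str, list[Nucleotide]] = {}
    hets: list[HetGroup] = []
    for chain in model:
        for res in chain:
            raw = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                raw.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_iso=max(at.b_iso, 0.0),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    )
                )
            atoms = _select_altlocs(raw)
            seqid = res.seqid.num if res.seqid.num is not None else 0
            icode = res.seqid.icode.strip()
            parent = map_parent_base(res.name)
            if parent != "X" and "C1'" in atoms:
                chains.setdefault(chain.name, []).append(
                    Nucleotide(chain.name, seqid, res.name, atoms, icode)
                )
            else:
                hets.append(HetGroup(chain.name, seqid, res.name, atoms, icode))
    cell = st.cell
    hm = st.spacegroup_hm or "P 1"
    try:
        ops = _spacegroup_ops(hm)
    except Exception:  # unknown symbol: fall back to identity
        logger.warning("unknown space group %r; using identity only", hm)
        ops = []
    structure = Structure(
        id=st.name or "structure",
        chains=chains,
        hets=hets,
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
        space_group=hm,
        sym_ops=ops,
    )
    if not chains:
        warnings.warn(f"no nucleic-acid residues found in {st.name!r}", stacklevel=3)
    return structure


_FORMATS = {
    "mmcif": gemmi.CoorFormat.Mmcif,
    "pdb": gemmi.CoorFormat.Pdb,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path, dialect: str = "auto") -> Structure:
    """Read an mmCIF or PDB coordinate file into a :class:`Structure`.

    Non-nucleotide residues (e.g. Sr2+ ions) are retained in ``structure.hets``.
    Raises :class:`StructureFormatError` if the file does not parse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    key = dialect.lower()
    if key not in _FORMATS:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[key])
        if len(st) == 0 or st[0].count_atom_sites() == 0:
            raise StructureFormatError(f"{path}: no atoms parsed in any model")
    except StructureFormatError:
        raise
    except Exception as exc:
        raise StructureFormatError(f"{path}: not a valid {dialect} file: {exc}") from exc
    st.name = path.stem
    return _from_gemmi(st)


def to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    a, b, c, al, be, ga = structure.cell
    st.cell = gemmi.UnitCell(a, b, c, al, be, ga)
    st.spacegroup_hm = structure.space_group
    model = gemmi.Model("1")
    for chain_id, nts in structure.chains.items():
        chain = gemmi.Chain(chain_id)
        for nt in nts:
            res = gemmi.Residue()
            res.name = nt.res_name
            res.seqid = gemmi.SeqId(nt.res_num, nt.icode or " ")
            for atom in nt.atoms.values():
                ga_at = gemmi.Atom()
                ga_at.name = atom.name
                ga_at.element = gemmi.Element(atom.element)
                ga_at.pos = gemmi.Position(*atom.pos)
                ga_at.occ = atom.occupancy
                ga_at.b_iso = atom.b_iso
                res.add_atom(ga_at)
            chain.add_residue(res)
        model.add_chain(chain)
    # heteroatoms go into their own chains to keep author numbering intact
    het_chains: dict[str, gemmi.Chain] = {}
    for het in structure.hets:
        ch = het_chains.setdefault(het.chain_id + "_het", gemmi.Chain(het.chain_id))
        res = gemmi.Residue()
        res.name = het.res_name
        res.seqid = gemmi.SeqId(het.res_num, het.icode or " ")
        res.het_flag = "H"
        for atom in het.atoms.values():
            ga_at = gemmi.Atom()
            ga_at.name = atom.name
            ga_at.element = gemmi.Element(atom.element)
            ga_at.pos = gemmi.Position(*atom.pos)
            ga_at.occ = atom.occupancy
            ga_at.b_iso = atom.b_iso
            res.add_atom(ga_at)
        ch.add_residue(res)
    for ch in het_chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path, dialect: str | None = None) -> None:
    """Write a structure as PDB or mmCIF (dialect inferred from the suffix)."""
    path = Path(path)
    st = to_gemmi(structure)
    fmt = dialect or ("pdb" if path.suffix.lower() in (".pdb", ".ent") else "mmcif")
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def load_sequence(source) -> str:
    """Return an upper-case base string from a plain string or a FASTA file."""
    text = str(source)
    p = Path(text)
    if p.exists() and p.is_file():
        from Bio import SeqIO

        records = list(SeqIO.parse(str(p), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected a single FASTA record in {p}, got {len(records)}")
        return str(records[0].seq).upper()
    return text.strip().upper()


# ---------------------------------------------------------------------------
# heavy-atom bookkeeping


def count_heavy_atoms(sequence: str, has_5prime_phosphate: bool = False) -> int:
    """Number of non-hydrogen atoms of a single DNA strand of this sequence.

    Per residue: 8 deoxyribose atoms, the base heavy atoms (A 10, C 8, G 11,
    T 9) and 3 phosphate atoms; the phosphate of the first residue is omitted
    for the default 5'-OH terminus.
    """
    total = 0
    for i, letter in enumerate(sequence.upper()):
        if letter not in "ACGT":
            raise ValueError(f"invalid base letter {letter!r} at position {i + 1}")
        total += len(SUGAR_ATOMS) + len(BASE_HEAVY_ATOMS[letter])
        if i > 0 or has_5prime_phosphate:
            total += len(PHOSPHATE_ATOMS)
    return total


# ---------------------------------------------------------------------------
# symmetry expansion


def _orth_frac_matrices(cell):
    a, b, c, al, be, ga = cell
    uc = gemmi.UnitCell(a, b, c, al, be, ga)
    orth = np.array(uc.orth.mat.tolist())
    frac = np.array(uc.frac.mat.tolist())
    return orth, frac


def _transform_structure(structure: Structure, func) -> Structure:
    """Deep-copy the structure applying ``func`` to every atom position."""
    chains = {}
    for cid, nts in structure.chains.items():
        chains[cid] = [
            Nucleotide(
                nt.chain_id,
                nt.res_num,
                nt.res_name,
                {
                    n: Atom(a.name, a.element, func(a.pos), a.occupancy, a.b_iso, a.altloc)
                    for n, a in nt.atoms.items()
                },
                nt.icode,
            )
            for nt in nts
        ]
    hets = [
        HetGroup(
            h.chain_id,
            h.res_num,
            h.res_name,
            {
                n: Atom(a.name, a.element, func(a.pos), a.occupancy, a.b_iso, a.altloc)
                for n, a in h.atoms.items()
            },
            h.icode,
        )
        for h in structure.hets
    ]
    return Structure(
        structure.id, chains, hets, structure.cell, structure.space_group, list(structure.sym_ops)
    )


def _op_triplet(rot: np.ndarray, tran: np.ndarray) -> str:
    op = gemmi.Op()
    op.rot = [[int(round(v * gemmi.Op.DEN)) for v in row] for row in rot]
    op.tran = [int(round(v * gemmi.Op.DEN)) for v in tran]
    return op.triplet()

def expand_symmetry(structure: Structure, radius: float, max_shift: int = 2) -> list[SymmetryCopy]:
    """Symmetry/lattice images with at least one atom within ``radius``.

    Every space-group operator combined with lattice translations up to
    ``max_shift`` cells in each direction is tested; the identity image at
    zero shift is excluded.  Copies are labelled by the operator triplet and
    the integer lattice shift.
    """
    if structure.cell[0] <= 0:
        raise ValueError("missing unit cell")
    coords = structure.coords()
    if coords.size == 0 or radius <= 0:
        return []
    orth, frac_m = _orth_frac_matrices(structure.cell)
    F = coords @ frac_m.T
    tree = cKDTree(coords)
    copies = []
    shifts = list(itertools.product(range(-max_shift, max_shift + 1), repeat=3))
    for rot, tran in structure.sym_ops:
        F_img_base = F @ rot.T + tran
        is_identity = np.allclose(rot, np.eye(3)) and np.allclose(tran % 1.0, 0.0)
        for shift in shifts:
            if is_identity and shift == (0, 0, 0):
                continue
            F_img = F_img_base + np.array(shift, dtype=float)
            X_img = F_img @ orth.T
            dmin = tree.query(X_img, k=1)[0].min()
            if dmin <= radius:
                full_tran = tran + np.array(shift, dtype=float)

                def _apply(p, rot=rot, full_tran=full_tran):
                    return orth @ (rot @ (frac_m @ p) + full_tran)

                copy = _transform_structure(structure, _apply)
                copies.append(
                    SymmetryCopy(
                        op_triplet=_op_triplet(rot, tran),
                        shift=shift,
                        structure=copy,
                        min_distance=float(dmin),
                    )
                )
    copies.sort(key=lambda c: c.min_distance)
    return copies
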