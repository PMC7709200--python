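"""Dihedral angles, dinucleotide-step dissection and least-squares superposition.

A dinucleotide step is a pair of consecutive, covalently linked nucleotides.
Its conformation is summarised by nine torsions — delta, epsilon, zeta of the
first residue, alpha, beta, gamma, delta of the second, and the two glycosidic
chi angles — and by the Cartesian coordinates of 18 defining atoms (8 of the
first residue, 10 of the second: the backbone span from C5' of residue i to
O3' of residue i+1 plus the O4'/C1' sugar anchors and the two glycosidic base
anchors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Nucleotide, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "TorsionVector",
    "TORSION_NAMES",
    "DinucleotideStep",
    "StepAtoms",
    "SuperpositionResult",
    "UndefinedTorsionError",
    "dihedral",
    "wrap_degrees",
    "circular_distance",
    "dissect_steps",
    "step_torsions",
    "step_atoms",
    "superpose",
    "rmsd_structures",
    "LINKAGE_CUTOFF",
]

#: maximum O3'(i)-P(i+1) distance treated as a covalent linkage, angstroms.
#: The bond itself is ~1.6 A; the generous cutoff tolerates low-resolution models.
LINKAGE_CUTOFF = 2.5

TORSION_NAMES = (
    "delta1",
    "epsilon1",
    "zeta1",
    "alpha2",
    "beta2",
    "gamma2",
    "delta2",
    "chi1",
    "chi2",
)


class UndefinedTorsionError(ValueError):
    """Raised when three consecutive points of a torsion are collinear."""


def wrap_degrees(x):
    """Wrap angles (degrees) to the interval (-180, 180]."""
    w = -((-np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0)
    return w


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC convention (cis = 0, trans = 180).

    Looking down the p2->p3 bond, the angle is positive for a clockwise
    rotation of p4 relative to p1.  Returns a value in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-9:
        raise UndefinedTorsionError("central bond degenerate")
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedTorsionError("collinear points, torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / norm_b2
    ang = np.degrees(np.arctan2(y, x))
    return float(wrap_degrees(ang))


@dataclass
class TorsionVector:
    """The nine torsions of one dinucleotide step, degrees in (-180, 180]."""

    delta1: float | None = None
    epsilon1: float | None = None
    zeta1: float | None = None
    alpha2: float | None = None
    beta2: float | None = None
    gamma2: float | None = None
    delta2: float | None = None
    chi1: float | None = None
    chi2: float | None = None
    missing: tuple[str, ...] = ()

    @property
    def complete(self) -> bool:
        return all(getattr(self, n) is not None for n in TORSION_NAMES)

    def as_array(self) -> np.ndarray:
        if not self.complete:
            raise ValueError(f"incomplete torsion vector (missing {self.missing})")
        return np.array([getattr(self, n) for n in TORSION_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "TorsionVector":
        values = wrap_degrees(np.asarray(values, dtype=float))
        if values.shape != (9,):
            raise ValueError("expected nine torsions")
        return cls(**dict(zip(TORSION_NAMES, map(float, values))))


def circular_distance(a: TorsionVector | np.ndarray, b: TorsionVector | np.ndarray) -> float:
    """Euclidean norm of the wrapped per-torsion differences, degrees."""
    va = a.as_array() if isinstance(a, TorsionVector) else np.asarray(a, float)
    vb = b.as_array() if isinstance(b, TorsionVector) else np.asarray(b, float)
    return float(np.linalg.norm(wrap_degrees(va - vb)))


@dataclass
class DinucleotideStep:
    nt1: Nucleotide
    nt2: Nucleotide

    @property
    def step_id(self) -> str:
        return f"{self.nt1.res_id}_{self.nt2.res_id}"


def _glyc_atoms(nt: Nucleotide) -> tuple[str, str]:
    """(glycosidic nitrogen, in-base chi partner): (N9, C4) purines, (N1, C2) pyrimidines."""
    return ("N9", "C4") if nt.is_purine else ("N1", "C2")


#: the 18-atom step definition: 8 atoms of residue i, 10 of residue i+1.
#: ``N*``/``C*`` resolve to N9/C4 for purines and N1/C2 for pyrimidines.
STEP_ATOM_SPEC = (
    ("1", ("C5'", "C4'", "C3'", "O3'", "O4'", "C1'", "N*", "C*")),
    ("2", ("P", "O5'", "C5'", "C4'", "C3'", "O3'", "O4'", "C1'", "N*", "C*")),
)


@dataclass
class StepAtoms:
    """Ordered, labelled coordinates of the 18 atoms defining a step geometry."""

    labels: tuple[str, ...]
    coords: np.ndarray

    @property
    def complete(self) -> bool:
        return len(self.labels) == 18


def step_atoms(step: DinucleotideStep, spec=STEP_ATOM_SPEC) -> StepAtoms:
    labels, coords = [], []
    for tag, names in spec:
        nt = step.nt1 if tag == "1" else step.nt2
        n_glyc, c_glyc = _glyc_atoms(nt)
        for name in names:
            resolved = {"N*": n_glyc, "C*": c_glyc}.get(name, name)
            if nt.has(resolved):
                labels.append(f"{tag}:{name}")
                coords.append(nt.pos(resolved))
    return StepAtoms(tuple(labels), np.array(coords) if coords else np.zeros((0, 3)))


def dissect_steps(chain: list[Nucleotide], linkage_cutoff: float = LINKAGE_CUTOFF) -> list[DinucleotideStep]:
    """One step per covalently linked pair of consecutive residues.

    Linkage requires an O3'(i)-P(i+1) distance at or below ``linkage_cutoff``;
    chain breaks and missing linkage atoms yield no step (logged, not raised).
    """
    steps = []
    for nt1, nt2 in zip(chain, chain[1:]):
        if not (nt1.has("O3'") and nt2.has("P")):
            logger.info("no step %s-%s: missing O3'/P linkage atoms", nt1.res_id, nt2.res_id)
            continue
        d = float(np.linalg.norm(nt1.pos("O3'") - nt2.pos("P")))
        if d > linkage_cutoff:
            logger.info("no step %s-%s: O3'-P distance %.2f A exceeds %.2f A", nt1.res_id, nt2.res_id, d, linkage_cutoff)
            continue
        steps.append(DinucleotideStep(nt1, nt2))
    return steps


_BACKBONE_TORSION_ATOMS = {
    "delta1": (("1", "C5'"), ("1", "C4'"), ("1", "C3'"), ("1", "O3'")),
    "epsilon1": (("1", "C4'"), ("1", "C3'"), ("1", "O3'"), ("2", "P")),
    "zeta1": (("1", "C3'"), ("1", "O3'"), ("2", "P"), ("2", "O5'")),
    "alpha2": (("1", "O3'"), ("2", "P"), ("2", "O5'"), ("2", "C5'")),
    "beta2": (("2", "P"), ("2", "O5'"), ("2", "C5'"), ("2", "C4'")),
    "gamma2": (("2", "O5'"), ("2", "C5'"), ("2", "C4'"), ("2", "C3'")),
    "delta2": (("2", "C5'"), ("2", "C4'"), ("2", "C3'"), ("2", "O3'")),
}


def step_torsions(step: DinucleotideStep) -> TorsionVector:
    """Measure the nine step torsions; missing atoms flag the vector incomplete.

    chi is O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for pyrimidines.
    """
    values: dict[str, float | None] = {}
    missing: list[str] = []
    residues = {"1": step.nt1, "2": step.nt2}
    for name, quad in _BACKBONE_TORSION_ATOMS.items():
        pts = []
        for tag, atom in quad:
            nt = residues[tag]
            if not nt.has(atom):
                missing.append(atom)
                break
            pts.append(nt.pos(atom))
        values[name] = dihedral(*pts) if len(pts) == 4 else None
    for name, nt in (("chi1", step.nt1), ("chi2", step.nt2)):
        n_glyc, c_glyc = _glyc_atoms(nt)
        needed = ("O4'", "C1'", n_glyc, c_glyc)
        if all(nt.has(a) for a in needed):
            values[name] = dihedral(*(nt.pos(a) for a in needed))
        else:
            values[name] = None
            missing.extend(a for a in needed if not nt.has(a))
    return TorsionVector(missing=tuple(dict.fromkeys(missing)), **values)


# ---------------------------------------------------------------------------
# superposition


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _as_labelled(points) -> tuple[list[str], np.ndarray]:
    if isinstance(points, StepAtoms):
        return list(points.labels), np.asarray(points.coords, float)
    if isinstance(points, dict):
        labels = sorted(points)
        return labels, np.array([points[k] for k in labels], float)
    labels, coords = points
    return list(labels), np.asarray(coords, float)


def superpose(movable, reference) -> SuperpositionResult:
    """Least-squares proper superposition (Kabsch) of labelled point sets.

    Accepts :class:`StepAtoms`, ``{label: xyz}`` dicts or ``(labels, coords)``
    pairs.  Labels must agree between the two sets; points are matched by
    label.  The result maps the movable set onto the reference; the rotation
    is always proper (determinant +1, no reflections).
    """
    mov_labels, mov = _as_labelled(movable)
    ref_labels, ref = _as_labelled(reference)
    if mov_labels != ref_labels:
        common = [l for l in mov_labels if l in set(ref_labels)]
        if sorted(mov_labels) == sorted(ref_labels):
            order = {l: i for i, l in enumerate(ref_labels)}
            idx = sorted(range(len(mov_labels)), key=lambda i: order[mov_labels[i]])
            mov = mov[idx]
            mov_labels = [mov_labels[i] for i in idx]
        elif len(common) >= 3:
            raise ValueError("label mismatch between point sets")
        else:
            raise ValueError("label mismatch between point sets")
    n = len(mov_labels)
    if n < 3:
        raise ValueError("need at least three points")
    mov_c = mov.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - ref_c, mov - mov_c)
    R = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(n)
    t = ref_c - R @ mov_c
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_structures(A: Structure, B: Structure, selection=None) -> float:
    """Superposition r.m.s.d. over atoms matched by (chain, residue, atom name).

    When the two structures differ in sequence, base atoms that exist in only
    one residue are dropped and the r.m.s.d. runs over the shared atom names —
    the only way to compare all non-H atoms of different sequences.
    ``selection`` is an optional predicate on :class:`~ntckit.structure_io.Atom`.
    """
    def collect(s: Structure) -> dict:
        out = {}
        for nt in s.nucleotides():
            for name, atom in nt.atoms.items():
                if selection is None or selection(atom):
                    out[(nt.chain_id, nt.res_num, nt.icode, name)] = atom.pos
        return out

    # match chains positionally so that differently named chains still compare
    a_ids = list(A.chains)
    b_ids = list(B.chains)
    remap = dict(zip(b_ids, a_ids))
    mapped_b = {}
    for nt in B.nucleotides():
        for name, atom in nt.atoms.items():
            if selection is None or selection(atom):
                mapped_b[(remap.get(nt.chain_id, nt.chain_id), nt.res_num, nt.icode, name)] = atom.pos
    da = collect(A)
    keys = sorted(set(da) & set(mapped_b))
    if not keys:
        raise ValueError("no matched atoms between structures")
    pa = np.array([da[k] for k in keys])
    pb = np.array([mapped_b[k] for k in keys])
    return superpose((keys, pb), (keys, pa)).rmsd
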