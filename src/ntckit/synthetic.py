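"""Synthetic-data generators: ideal duplexes, torsion noise, maps, fixture corpora.

The builders emulate the study system — near-palindromic DNA 18-mers that
crystallize as A-form duplexes with two central T-T mismatches — and provide
the ground truth for every downstream stage:

* :func:`build_duplex` constructs an ideal antiparallel duplex from a
  sequence.  Strands are generated from constant per-step backbone torsions
  (the catalog's AA00/BB00 centroids), which makes each strand an exact
  uniform helix; the complementary strand is posed by a twofold (dyad)
  rotation perpendicular to the helix axis, refined so that every canonical
  pair has clean Watson-Crick hydrogen-bond geometry.  At mismatch positions
  the same base is placed opposite, and its base ring is re-posed to the
  symmetric N3...O4 double hydrogen bond of the wobble-type T-T pair seen in
  antiparallel duplexes (the sugar-phosphate backbone stays on the helical
  path).
* :func:`perturb_torsions` applies wrapped-Gaussian noise to every backbone/
  glycosidic torsion and rebuilds the strand coordinates downstream, the
  noise model for class-recovery experiments.
* :func:`synth_map` rasterizes a Gaussian-atom model density plus seeded
  voxel noise, standing in for an experimental map.
* :func:`make_fixture_corpus` writes small annotated mmCIF duplexes with a
  controlled fraction of deliberately mislabeled canonical pairs, plus a
  manifest recording all planted truths.

All stochastic operations take an explicit seed and are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from ._nerf import ResidueTorsions, build_strand, per_residue_torsions
from .step_geometry import (
    TorsionVector,
    dihedral,
    dissect_steps,
    step_torsions,
    superpose,
)
from .structure_io import Atom, BASE_HEAVY_ATOMS, HetGroup, Nucleotide, Structure, write_structure

logger = logging.getLogger(__name__)

__all__ = [
    "BuildSpec",
    "HelicalForm",
    "FORMS",
    "FixtureManifest",
    "build_duplex",
    "build_strand_of_classes",
    "build_parallel_duplex",
    "perturb_torsions",
    "synth_map",
    "make_fixture_corpus",
]

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Watson-Crick hydrogen-bond atom pairs, keyed by (base1, base2)
WC_BOND_ATOMS = {
    ("G", "C"): (("N1", "N3"), ("N2", "O2"), ("O6", "N4")),
    ("C", "G"): (("N3", "N1"), ("O2", "N2"), ("N4", "O6")),
    ("A", "T"): (("N1", "N3"), ("N6", "O4")),
    ("T", "A"): (("N3", "N1"), ("O4", "N6")),
}

#: symmetric wobble-type T-T pattern of antiparallel duplexes
TT_ANTIPARALLEL_BONDS = (("N3", "O4"), ("O4", "N3"))
#: alternative symmetric pattern seen in parallel-strand contexts
TT_PARALLEL_BONDS = (("N3", "O2"), ("O2", "N3"))

HBOND_TARGET = 2.90  # angstroms


@dataclass(frozen=True)
class HelicalForm:
    """A uniform helix defined by one backbone torsion set.

    ``dyad_phi4``/``dyad_z4`` are the fitted dyad parameters for a reference
    4-mer; screw symmetry extrapolates them to any length (phi shifts by
    -twist and z by +rise per residue) before a local refit.
    """

    name: str
    torsions: TorsionVector
    twist: float
    rise: float
    dyad_phi4: float
    dyad_z4: float


def _tv(delta, epsilon, zeta, alpha, beta, gamma, chi) -> TorsionVector:
    return TorsionVector(
        delta1=delta, epsilon1=epsilon, zeta1=zeta, alpha2=alpha,
        beta2=beta, gamma2=gamma, delta2=delta, chi1=chi, chi2=chi,
    )


#: calibrated fiber-like forms; torsions equal the AA00/BB00 catalog centroids
FORMS: dict[str, HelicalForm] = {
    "A": HelicalForm("A", _tv(83.0, -143.3, -80.0, -59.9, 153.3, 55.1, -162.2),
                     twist=28.48, rise=2.519, dyad_phi4=285.01, dyad_z4=1.28),
    "B": HelicalForm("B", _tv(135.0, -145.7, -144.6, -38.7, 141.3, 39.5, -149.2),
                     twist=34.30, rise=3.368, dyad_phi4=202.63, dyad_z4=19.58),
}


@dataclass
class BuildSpec:
    """Recipe for one synthetic duplex.

    ``mismatch_positions`` are 1-based positions on the first strand where
    the same base is placed opposite instead of the complement.  ``form`` is
    "A" or "B"; ``step_classes`` may instead give one conformer-class name per
    step for a single mixed-form strand (no duplex mate is built then).
    Helical rise/twist are derived from the form's torsions; explicit values
    are accepted for reporting but do not re-shape the backbone.
    """

    sequence: str
    form: str = "A"
    mismatch_positions: tuple[int, ...] = ()
    step_classes: tuple[str, ...] | None = None
    rise: float | None = None
    twist: float | None = None
    add_central_ion: bool = False
    seed: int = 0

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.step_classes is not None and len(self.step_classes) != len(self.sequence) - 1:
            raise ValueError("need one step class per step (len(sequence) - 1)")
        for p in self.mismatch_positions:
            if not 1 <= p <= len(self.sequence):
                raise ValueError(f"mismatch position {p} outside 1..{len(self.sequence)}")


# ---------------------------------------------------------------------------
# helix canonicalization


_SCREW_ATOMS = ["O5'", "C5'", "C4'", "C3'", "O3'", "O4'", "C1'", "C2'"]


def _screw(nts: list[Nucleotide]):
    """Screw transform between consecutive residues: (axis u, point p, twist, rise)."""
    mid = len(nts) // 2 - 1
    A = np.array([nts[mid].pos(n) for n in _SCREW_ATOMS])
    B = np.array([nts[mid + 1].pos(n) for n in _SCREW_ATOMS])
    sup = superpose((_SCREW_ATOMS, A), (_SCREW_ATOMS, B))
    R, t = sup.rotation, sup.translation
    w = Rotation.from_matrix(R).as_rotvec()
    u = w / np.linalg.norm(w)
    rise = float(u @ t)
    if rise < 0:
        u, rise = -u, -rise
    twist = float(np.degrees(np.linalg.norm(w)))
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t - rise * u, rcond=None)
    p = p - (p @ u) * u
    return u, p, twist, rise


def _canonicalize(nts: list[Nucleotide]):
    """Rigidly move a uniform strand so its helix axis is +z through the origin."""
    u, p, twist, rise = _screw(nts)
    v = np.cross(u, [0.0, 0.0, 1.0])
    s = np.linalg.norm(v)
    c = float(u @ [0.0, 0.0, 1.0])
    if s < 1e-9:
        R = np.eye(3) if c > 0 else Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    else:
        R = Rotation.from_rotvec(v / s * np.arctan2(s, c)).as_matrix()
    for nt in nts:
        for a in nt.atoms.values():
            a.pos = R @ (a.pos - p)
    return nts, twist, rise


def _transform(nts: list[Nucleotide], R: np.ndarray, t: np.ndarray) -> None:
    for nt in nts:
        for a in nt.atoms.values():
            a.pos = R @ a.pos + t


# ---------------------------------------------------------------------------
# duplex assembly


def _pair_residuals(s1, s2, seq1, pairs_only=None):
    """WC hydrogen-bond + C1'-C1' residuals for strand1 pos i vs strand2 pos L-1-i."""
    L = len(seq1)
    res = []
    for i in pairs_only if pairs_only is not None else range(L):
        b1 = seq1[i]
        b2 = COMPLEMENT[b1]
        nt1, nt2 = s1[i], s2[L - 1 - i]
        for a1, a2 in WC_BOND_ATOMS[(b1, b2)]:
            res.append(np.linalg.norm(nt1.pos(a1) - nt2.pos(a2)) - HBOND_TARGET)
        res.append((np.linalg.norm(nt1.pos("C1'") - nt2.pos("C1'")) - 10.4) * 0.5)
    return np.array(res)


def _dyad_matrix(phi: float) -> np.ndarray:
    return Rotation.from_euler("zx", [phi, 180.0], degrees=True).as_matrix()


def _ring_atoms(nt: Nucleotide) -> list[str]:
    return ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1"] if nt.is_purine else \
           ["N1", "C2", "N3", "C4", "C5", "C6"]


def _base_plane(nt: Nucleotide):
    pts = np.array([nt.pos(n) for n in _ring_atoms(nt) if nt.has(n)])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def _plant_pair_geometry(nt1: Nucleotide, nt2: Nucleotide, bonds, length=HBOND_TARGET) -> None:
    """Re-pose the base ring of nt2 as the symmetric pairing partner of nt1.

    ``bonds`` lists two reciprocal (atom_on_nt1, atom_on_nt2) hydrogen bonds
    of a symmetric same-base pair (e.g. N3-O4 / O4-N3 for the wobble-type
    T-T).  The partner base is generated as the image of nt1's base under a
    twofold rotation about the base-plane normal through a point offset half
    the bond length from the midpoint of the two nt1 bond atoms — this places
    the two hydrogen bonds as parallel rungs of exactly ``length`` with the
    bases coplanar and clash-free.  Only base atoms move; the sugar-phosphate
    backbone of nt2 stays on its helical path.
    """
    if nt1.parent_base != nt2.parent_base:
        raise ValueError("symmetric pair planting requires a same-base pair")
    _, n1_hat = _base_plane(nt1)
    ring = [n for n in _ring_atoms(nt2) if nt2.has(n)]
    base_names = [n for n in BASE_HEAVY_ATOMS[nt2.parent_base] if nt2.has(n)]
    X0 = np.array([nt2.pos(n) for n in base_names])
    centroid0 = X0.mean(axis=0)
    idx = {n: i for i, n in enumerate(base_names)}
    ring_idx = [idx[n] for n in ring]
    bond_targets = [(nt1.pos(a1), idx[a2]) for a1, a2 in bonds]

    def moved(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return (X0 - centroid0) @ R.T + centroid0 + params[3:]

    def residuals(params):
        X = moved(params)
        res = [10.0 * (np.linalg.norm(p1 - X[i2]) - length) for p1, i2 in bond_targets]
        pts = X[ring_idx]
        _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
        res.append(20.0 * (1.0 - abs(float(vt[2] @ n1_hat))))
        res.extend(0.3 * (X - X0).ravel())
        return np.array(res)

    fit = least_squares(residuals, np.zeros(6), diff_step=1e-4)
    X = moved(fit.x)
    for n, i in idx.items():
        nt2.atoms[n].pos = X[i]


def _bounding_cell(nucleotides, margin: float = 10.0):
    pts = np.array([a.pos for nt in nucleotides for a in nt.atoms.values()])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    shift = margin - lo
    cell = tuple(hi - lo + 2 * margin) + (90.0, 90.0, 90.0)
    return shift, cell


def build_duplex(spec: BuildSpec) -> Structure:
    """Build an ideal antiparallel duplex (chains A and B) from a sequence.

    Canonical positions pair Watson-Crick; at ``mismatch_positions`` the same
    base sits opposite, re-posed to the symmetric wobble-type double hydrogen
    bond.  With ``add_central_ion`` a Sr2+ cation is placed at the centroid of
    the mismatch thymine O4 atoms, mimicking the major-groove metal site of
    T-T mismatched duplexes.
    """
    seq1 = spec.sequence
    L = len(seq1)
    if L < 2:
        raise ValueError("sequence too short")
    bad = set(seq1) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)}")
    if spec.step_classes is not None:
        raise ValueError("step_classes builds a single strand; use build_strand_of_classes")
    form = FORMS[spec.form]
    mism = set(spec.mismatch_positions)

    s1 = build_strand(seq1, [form.torsions] * (L - 1), chain_id="A")
    s1, twist, rise = _canonicalize(s1)
    # strand 2: reverse complement, except the same base at mismatch positions
    seq2 = "".join(
        seq1[i - 1] if i in mism else COMPLEMENT[seq1[i - 1]]
        for i in range(L, 0, -1)
    )
    s2 = build_strand(seq2, [form.torsions] * (L - 1), chain_id="B")
    s2, _, _ = _canonicalize(s2)

    # dyad predicted by screw symmetry from the calibrated 4-mer, then refined
    phi0 = (form.dyad_phi4 - (L - 4) * form.twist) % 360.0
    z00 = form.dyad_z4 + (L - 4) * form.rise
    canonical_idx = [i for i in range(L) if (i + 1) not in mism and (L - i) not in mism]

    # fixed reference targets on strand 1 and matching movable points on strand 2
    ref_pts, mov_pts, targets = [], [], []
    for i in canonical_idx:
        b1 = seq1[i]
        nt1, nt2 = s1[i], s2[L - 1 - i]
        for a1, a2 in WC_BOND_ATOMS[(b1, COMPLEMENT[b1])]:
            ref_pts.append(nt1.pos(a1))
            mov_pts.append(nt2.pos(a2))
            targets.append((HBOND_TARGET, 1.0))
        ref_pts.append(nt1.pos("C1'"))
        mov_pts.append(nt2.pos("C1'"))
        targets.append((10.4, 0.5))
    ref_pts = np.array(ref_pts)
    mov_pts = np.array(mov_pts)
    target_d = np.array([t for t, _ in targets])
    weights = np.array([w for _, w in targets])

    def residuals(x):
        moved = mov_pts @ _dyad_matrix(x[0]).T + np.array([0.0, 0.0, x[1]])
        d = np.linalg.norm(moved - ref_pts, axis=1)
        return (d - target_d) * weights

    fit = least_squares(residuals, [phi0, z00], diff_step=1e-3)
    _transform(s2, _dyad_matrix(fit.x[0]), np.array([0.0, 0.0, fit.x[1]]))
    worst = np.abs(residuals(fit.x)).max() if canonical_idx else 0.0
    logger.info("duplex dyad fit: phi=%.2f z=%.2f worst WC residual %.3f A", fit.x[0] % 360, fit.x[1], worst)

    # plant mismatch base geometry (wobble-type symmetric N3/O4 bonds for T-T
    # and analogous symmetric W-edge bonds for other same-base pairs)
    for p in sorted(mism):
        nt1 = s1[p - 1]
        nt2 = s2[L - p]  # strand-2 list index of pairing partner
        if nt1.parent_base == "T":
            bonds = TT_ANTIPARALLEL_BONDS
        elif nt1.parent_base == "G":
            bonds = (("N1", "O6"), ("O6", "N1"))
        elif nt1.parent_base == "A":
            bonds = (("N6", "N1"), ("N1", "N6"))
        else:  # C
            bonds = (("N4", "N3"), ("N3", "N4"))
        _plant_pair_geometry(nt1, nt2, bonds)

    hets: list[HetGroup] = []
    if spec.add_central_ion:
        o4 = []
        for p in sorted(mism):
            for nt in (s1[p - 1], s2[L - p]):
                if nt.has("O4"):
                    o4.append(nt.pos("O4"))
        if o4:
            # place the cation at the major-groove O4 cluster, refined so the
            # coordination distances approach the observed 2.2-2.4 A range
            target = 2.3
            o4_arr = np.array(o4)
            fit = least_squares(
                lambda x: np.linalg.norm(o4_arr - x, axis=1) - target,
                o4_arr.mean(axis=0) + np.array([0.0, 0.0, 1e-3]),
            )
            pos = fit.x
            hets.append(
                HetGroup("S", 101, "SR", {"SR": Atom("SR", "Sr", pos, 1.0, 30.0)})
            )
            d = [float(np.linalg.norm(pos - q)) for q in o4]
            logger.info("central Sr placed; O4 distances %s", np.round(d, 2))

    shift, cell = _bounding_cell(s1 + s2)
    for nt in s1 + s2:
        for a in nt.atoms.values():
            a.pos = a.pos + shift
    for h in hets:
        for a in h.atoms.values():
            a.pos = a.pos + shift
    return Structure(
        id=f"synthetic_{spec.form}_duplex",
        chains={"A": s1, "B": s2},
        hets=hets,
        cell=cell,
        space_group="P 1",
    )


def build_strand_of_classes(sequence: str, class_names: list[str], chain_id="A") -> Structure:
    """Single strand whose k-th step follows the k-th catalog class centroid."""
    from .ntc_assign import builtin_catalog

    cat = builtin_catalog()
    steps = [cat[name].centroid for name in class_names]
    nts = build_strand(sequence, steps, chain_id=chain_id)
    shift, cell = _bounding_cell(nts)
    for nt in nts:
        for a in nt.atoms.values():
            a.pos = a.pos + shift
    return Structure(id="synthetic_classes", chains={chain_id: nts}, cell=cell, space_group="P 1")


def build_parallel_duplex(sequence: str, form: str = "B", tt_position: int | None = None) -> Structure:
    """Toy parallel-strand duplex: a translated copy runs 5'->3' alongside.

    Pairs are planted base-by-base (position i with position i); with
    ``tt_position`` the T at that position is re-posed to the alternative
    symmetric N3/O2 double bond characteristic of parallel-strand T-T pairs.
    Used to exercise strand-orientation and parallel-pair classification.
    """
    f = FORMS[form]
    L = len(sequence)
    s1 = build_strand(sequence, [f.torsions] * (L - 1), chain_id="A")
    s1, _, _ = _canonicalize(s1)
    s2 = build_strand(sequence, [f.torsions] * (L - 1), chain_id="B")
    s2, _, _ = _canonicalize(s2)
    _transform(s2, np.eye(3), np.array([12.0, 0.0, 0.0]))
    for i in range(L):
        if sequence[i] == "T" and (tt_position is None or tt_position == i + 1):
            _plant_pair_geometry(s1[i], s2[i], TT_PARALLEL_BONDS)
    shift, cell = _bounding_cell(s1 + s2)
    for nt in s1 + s2:
        for a in nt.atoms.values():
            a.pos = a.pos + shift
    return Structure(id="synthetic_parallel", chains={"A": s1, "B": s2}, cell=cell, space_group="P 1")


# ---------------------------------------------------------------------------
# torsion noise


def _measure_residue_torsions(chain: list[Nucleotide]) -> list[ResidueTorsions]:
    steps = [step_torsions(s) for s in dissect_steps(chain)]
    if len(steps) != len(chain) - 1:
        raise ValueError("chain has breaks; cannot rebuild from torsions")
    res = per_residue_torsions(steps)
    if len(chain) >= 1:
        nt = chain[0]
        if all(nt.has(a) for a in ("O5'", "C5'", "C4'", "C3'")):
            res[0].gamma = dihedral(nt.pos("O5'"), nt.pos("C5'"), nt.pos("C4'"), nt.pos("C3'"))
    return res


def perturb_torsions(structure: Structure, sigma: float, seed: int,
                     return_deltas: bool = False):
    """Wrapped-Gaussian torsion noise with downstream coordinate rebuild.

    Every defined backbone/glycosidic torsion of every chain receives an
    independent N(0, sigma) perturbation (degrees, wrapped); each strand is
    rebuilt from its perturbed internal coordinates and superposed back onto
    the original backbone to preserve the overall placement.  sigma = 0
    reproduces the input coordinates; results are deterministic per seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        # exact identity: a rebuild would re-idealize planted mismatch bases
        out = Structure(
            structure.id,
            {cid: [
                Nucleotide(nt.chain_id, nt.res_num, nt.res_name,
                           {n: Atom(a.name, a.element, a.pos.copy(), a.occupancy, a.b_iso, a.altloc)
                            for n, a in nt.atoms.items()}, nt.icode)
                for nt in chain
            ] for cid, chain in structure.chains.items()},
            list(structure.hets), structure.cell, structure.space_group,
            list(structure.sym_ops),
        )
        if return_deltas:
            return out, np.zeros(0)
        return out
    rng = np.random.default_rng(seed)
    new_chains: dict[str, list[Nucleotide]] = {}
    deltas: list[float] = []
    for chain_id, chain in structure.chains.items():
        res_t = _measure_residue_torsions(chain)
        for rt in res_t:
            for name in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi"):
                val = getattr(rt, name)
                if val is None:
                    continue
                d = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
                deltas.append(d)
                setattr(rt, name, float((val + d + 180.0) % 360.0 - 180.0))
        seq = "".join(nt.parent_base for nt in chain)
        rebuilt = build_strand(seq, res_t, chain_id=chain_id,
                               start_res=chain[0].res_num)
        # keep author residue names (e.g. BRU) and numbering gaps
        for new, old in zip(rebuilt, chain):
            new.res_num = old.res_num
            new.res_name = old.res_name
            new.icode = old.icode
        # superpose rebuilt strand onto the original backbone
        names = [(i, n) for i, nt in enumerate(chain) for n in _SCREW_ATOMS if nt.has(n)]
        ref = np.array([chain[i].pos(n) for i, n in names])
        mov = np.array([rebuilt[i].pos(n) for i, n in names])
        labels = [f"{i}:{n}" for i, n in names]
        sup = superpose((labels, mov), (labels, ref))
        for nt in rebuilt:
            for a in nt.atoms.values():
                a.pos = sup.apply(a.pos[None, :])[0]
        new_chains[chain_id] = rebuilt
    out = Structure(structure.id, new_chains, list(structure.hets), structure.cell,
                    structure.space_group, list(structure.sym_ops))
    if return_deltas:
        return out, np.array(deltas)
    return out


# ---------------------------------------------------------------------------
# synthetic maps


def synth_map(structure: Structure, spacing: float = 0.8, noise_sigma: float = 0.0,
              seed: int = 0, b_floor: float = 10.0):
    """Model density of the structure plus seeded Gaussian voxel noise.

    ``noise_sigma`` is expressed as a fraction of the noise-free map's
    standard deviation.  The map lives on the structure's own (orthorhombic)
    cell.
    """
    from .density_fit import calc_model_map

    if spacing <= 0:
        raise ValueError("spacing must be positive")
    dmap = calc_model_map(list(structure.all_atoms()), structure.cell,
                          spacing=spacing, b_floor=b_floor)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        dmap.values = dmap.values + rng.normal(
            0.0, noise_sigma * float(dmap.values.std()), size=dmap.values.shape
        )
    return dmap


# ---------------------------------------------------------------------------
# annotated fixture corpora


@dataclass
class FixtureManifest:
    """Ground truth for a generated corpus; determines all expected outputs."""

    seed: int
    mislabel_fraction: float
    structures: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "mislabel_fraction": self.mislabel_fraction,
             "structures": self.structures}, indent=1))

    @classmethod
    def from_json(cls, path) -> "FixtureManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["seed"], d["mislabel_fraction"], d["structures"])

    @property
    def pairs(self):
        for s in self.structures:
            yield from s["pairs"]


_NA_BASE_PAIR_TAGS = [
    "i_auth_asym_id", "i_auth_seq_id", "j_auth_asym_id", "j_auth_seq_id",
    "hbond_type_28", "hbond_type_12",
]


def _append_pair_category(cif_path: Path, rows: list[dict]) -> None:
    doc = gemmi.cif.read(str(cif_path))
    block = doc.sole_block()
    loop = block.init_loop("_ndb_struct_na_base_pair.", _NA_BASE_PAIR_TAGS)
    for r in rows:
        loop.add_row([str(r[t]) for t in _NA_BASE_PAIR_TAGS])
    doc.write_file(str(cif_path))


def make_fixture_corpus(n_structures: int, mislabel_fraction: float, seed: int,
                        out_dir, tt_fraction: float = 0.5,
                        length: int = 8) -> FixtureManifest:
    """Generate annotated mmCIF duplexes with planted (mis)labels.

    Each structure is a B-form duplex of the given length; a ``tt_fraction``
    of them carries one central T-T mismatch annotated with its true wobble
    code "16".  A ``mislabel_fraction`` of the canonical pairs is annotated
    with a noncanonical code instead of the correct canonical 19/20 — the
    planted analogue of the wrongly labelled Watson-Crick pairs found in
    archival files.  Returns the manifest of all planted truths; files are
    ``<out_dir>/fixture_###.cif`` plus ``manifest.json``.
    """
    if not 0.0 <= mislabel_fraction <= 1.0:
        raise ValueError("mislabel_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = FixtureManifest(seed=seed, mislabel_fraction=mislabel_fraction)
    for k in range(n_structures):
        with_tt = bool(rng.random() < tt_fraction)
        # random sequence; central position forced to T when a mismatch is planted
        letters = rng.choice(list("ACGT"), size=length)
        seq = "".join(letters)
        mism: tuple[int, ...] = ()
        if with_tt:
            center = length // 2
            seq = seq[: center - 1] + "T" + seq[center:]
            mism = (center,)
        struct = build_duplex(BuildSpec(sequence=seq, form="B", mismatch_positions=mism,
                                        seed=int(rng.integers(2**31))))
        struct.id = f"fixture_{k:03d}"
        rows, truth_pairs = [], []
        L = length
        for i in range(1, L + 1):
            j = L + 1 - i  # strand-B author residue number of the partner
            if i > j:
                continue
            b1 = seq[i - 1]
            is_mismatch = i in mism or j in mism
            b2 = b1 if is_mismatch else COMPLEMENT[b1]
            combo = "-".join(sorted((b1, b2)))
            if is_mismatch:
                true_code = "16"
                annotated = "16"
                mislabeled = False
            else:
                true_code = "19" if combo == "C-G" else "20"
                mislabeled = bool(rng.random() < mislabel_fraction)
                annotated = str(rng.choice(["16", "12", "28", "8"])) if mislabeled else true_code
            rows.append(dict(i_auth_asym_id="A", i_auth_seq_id=i,
                             j_auth_asym_id="B", j_auth_seq_id=j,
                             hbond_type_28=annotated, hbond_type_12="1"))
            truth_pairs.append(dict(
                structure_id=struct.id, chain1="A", res1=i, chain2="B", res2=j,
                combo=combo, true_code=true_code, annotated_code=annotated,
                mislabeled=mislabeled, orientation="antiparallel",
            ))
        cif_path = out_dir / f"{struct.id}.cif"
        write_structure(struct, cif_path)
        _append_pair_category(cif_path, rows)
        manifest.structures.append(dict(
            structure_id=struct.id, path=cif_path.name, sequence=seq,
            form="B", mismatch_positions=list(mism), pairs=truth_pairs,
        ))
    manifest.to_json(out_dir / "manifest.json")
    return manifest
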