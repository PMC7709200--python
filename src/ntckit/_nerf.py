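"""Internal-coordinate (NeRF) construction of DNA strands.

Bond lengths, bond angles and auxiliary dihedrals are harvested once per
process from the ideal residue geometries of the chemical component
dictionary bundled with :mod:`biotite` (``biotite.structure.info.residue``).
Backbone and glycosidic torsions are free parameters supplied by the caller,
so a strand built from a constant per-step torsion set reproduces those
torsions exactly when re-measured, and — because repeated identical internal
coordinates generate a screw symmetry — traces an exact helix whose rise and
twist are implied by the torsions.

Base rings are placed as rigid bodies: the glycosidic nitrogen and two ring
anchors are positioned by NeRF (the first anchor's dihedral *is* chi), then
the full ideal base is superposed onto the three anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .step_geometry import TorsionVector, dihedral, superpose, wrap_degrees
from .structure_io import Atom, BASE_HEAVY_ATOMS, Nucleotide

__all__ = ["build_strand", "per_residue_torsions", "ResidueTorsions", "base_template"]

RES_NAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DU"}
_ELEMENTS = {"C": "C", "N": "N", "O": "O", "P": "P"}

# inter-residue linkage constants (not measurable within a single CCD residue)
O3_P_BOND = 1.607       # O3'(i)-P(i+1), angstroms
C3_O3_P_ANGLE = 119.7   # C3'(i)-O3'(i)-P(i+1), degrees
O3_P_O5_ANGLE = 104.0   # O3'(i)-P(i+1)-O5'(i+1), degrees


def _element_of(name: str) -> str:
    return _ELEMENTS.get(name.lstrip("0123456789")[0], name[0])


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D so that |CD|=bond, angle(B,C,D)=angle, dihedral(A,B,C,D)=torsion."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _angle(p1, p2, p3) -> float:
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@lru_cache(maxsize=None)
def _ccd_coords(res_name: str) -> dict[str, np.ndarray]:
    import biotite.structure.info as info

    res = info.residue(res_name)
    out = {}
    for name, coord, element in zip(res.atom_name, res.coord, res.element):
        if element == "H":
            continue
        out[name] = np.asarray(coord, float)
    return out


def _anchors(parent: str) -> tuple[str, str, str]:
    """Glycosidic nitrogen and the two ring anchors used to pose the base."""
    return ("N9", "C4", "C8") if parent in ("A", "G") else ("N1", "C2", "C6")


@lru_cache(maxsize=None)
def _internal_coords(parent: str) -> dict:
    """Harvest bonds/angles/reference dihedrals from CCD ideal residues.

    Backbone and sugar internal coordinates are taken from a single reference
    residue (DG) for every base type so that a constant-torsion strand of any
    sequence is an exact uniform helix; only the glycosidic attachment and the
    base template are residue-specific.
    """
    cb = _ccd_coords(RES_NAMES["G"])  # shared backbone/sugar reference
    c = _ccd_coords(RES_NAMES[parent])
    n_glyc, anchor1, anchor2 = _anchors(parent)

    def entry(src, x, refs):
        a, b, d = refs
        return {
            "bond": float(np.linalg.norm(src[x] - src[d])),
            "angle": _angle(src[x], src[d], src[b]),
            "torsion": dihedral(src[a], src[b], src[d], src[x]),
        }

    ic = {
        "bonds": {
            "P-O5'": float(np.linalg.norm(cb["P"] - cb["O5'"])),
            "O5'-C5'": float(np.linalg.norm(cb["O5'"] - cb["C5'"])),
            "C5'-C4'": float(np.linalg.norm(cb["C5'"] - cb["C4'"])),
            "C4'-C3'": float(np.linalg.norm(cb["C4'"] - cb["C3'"])),
            "C3'-O3'": float(np.linalg.norm(cb["C3'"] - cb["O3'"])),
        },
        "angles": {
            "P-O5'-C5'": _angle(cb["P"], cb["O5'"], cb["C5'"]),
            "O5'-C5'-C4'": _angle(cb["O5'"], cb["C5'"], cb["C4'"]),
            "C5'-C4'-C3'": _angle(cb["C5'"], cb["C4'"], cb["C3'"]),
            "C4'-C3'-O3'": _angle(cb["C4'"], cb["C3'"], cb["O3'"]),
        },
        # side atoms: (bond to last ref atom, angle, harvested dihedral)
        "O4'": entry(cb, "O4'", ("O3'", "C3'", "C4'")),
        "C1'": entry(cb, "C1'", ("C3'", "C4'", "O4'")),
        "C2'": entry(cb, "C2'", ("C4'", "O4'", "C1'")),
        "N": entry(c, n_glyc, ("C4'", "O4'", "C1'")),
        "anchor1": entry(c, anchor1, ("O4'", "C1'", n_glyc)),
        "anchor2": entry(c, anchor2, ("O4'", "C1'", n_glyc)),
        "OP1": entry(cb, "OP1", ("C5'", "O5'", "P")),
        "OP2": entry(cb, "OP2", ("C5'", "O5'", "P")),
    }
    # the second anchor trails the first by a fixed in-plane offset
    ic["anchor2_offset"] = float(wrap_degrees(ic["anchor2"]["torsion"] - ic["anchor1"]["torsion"]))
    ic["base"] = {name: c[name] for name in BASE_HEAVY_ATOMS[parent] if name in c}
    return ic


def base_template(parent: str) -> dict[str, np.ndarray]:
    """Ideal heavy-atom coordinates of the free base, CCD frame."""
    return dict(_internal_coords(parent)["base"])


@dataclass
class ResidueTorsions:
    """Per-residue backbone/glycosidic torsions, degrees.

    alpha/beta are undefined for a 5'-OH first residue; epsilon/zeta for the
    3'-terminal residue.
    """

    alpha: float | None = None
    beta: float | None = None
    gamma: float = 54.0
    delta: float = 83.0
    epsilon: float | None = None
    zeta: float | None = None
    chi: float = -160.0


def per_residue_torsions(steps: list[TorsionVector]) -> list[ResidueTorsions]:
    """Convert a list of L-1 step torsion vectors into L per-residue records.

    Where consecutive steps disagree on the shared residue (delta2 of step k
    vs delta1 of step k+1, likewise chi), the incoming step's value wins.
    The first residue's gamma is taken from the first step's gamma2.
    """
    n = len(steps) + 1
    res = [ResidueTorsions() for _ in range(n)]
    for k, tv in enumerate(steps):
        res[k].delta = tv.delta1 if k == 0 else res[k].delta
        res[k].chi = tv.chi1 if k == 0 else res[k].chi
        res[k].epsilon = tv.epsilon1
        res[k].zeta = tv.zeta1
        res[k + 1].alpha = tv.alpha2
        res[k + 1].beta = tv.beta2
        res[k + 1].gamma = tv.gamma2
        res[k + 1].delta = tv.delta2
        res[k + 1].chi = tv.chi2
    res[0].gamma = steps[0].gamma2 if steps else res[0].gamma
    return res


def build_strand(
    sequence: str,
    torsions: list[ResidueTorsions] | list[TorsionVector],
    chain_id: str = "A",
    start_res: int = 1,
    b_iso: float = 20.0,
) -> list[Nucleotide]:
    """Build one DNA strand from internal coordinates.

    ``torsions`` is either one :class:`ResidueTorsions` per residue or one
    :class:`TorsionVector` per step (length ``len(sequence) - 1``).  The strand
    gets a 5'-OH terminus (no 5' phosphate).
    """
    sequence = sequence.upper()
    if torsions and isinstance(torsions[0], TorsionVector):
        torsions = per_residue_torsions(list(torsions))
    if len(torsions) != len(sequence):
        raise ValueError("need one torsion record per residue")

    nucleotides: list[Nucleotide] = []
    prev: dict[str, np.ndarray] | None = None
    for i, (letter, tv) in enumerate(zip(sequence, torsions)):
        if letter not in RES_NAMES:
            raise ValueError(f"invalid base letter {letter!r}")
        ic = _internal_coords(letter)
        bonds, angles = ic["bonds"], ic["angles"]
        pos: dict[str, np.ndarray] = {}
        if prev is None:
            # seed frame for the 5'-OH terminal residue
            pos["O5'"] = np.zeros(3)
            pos["C5'"] = np.array([bonds["O5'-C5'"], 0.0, 0.0])
            pos["C4'"] = place_atom(
                np.array([0.0, 1.0, 0.0]), pos["O5'"], pos["C5'"],
                bonds["C5'-C4'"], angles["O5'-C5'-C4'"], 60.0,
            )
            gamma_refs = (pos["O5'"], pos["C5'"], pos["C4'"])
        else:
            pos["P"] = place_atom(
                prev["C4'"], prev["C3'"], prev["O3'"],
                O3_P_BOND, C3_O3_P_ANGLE, torsions[i - 1].epsilon,
            )
            pos["O5'"] = place_atom(
                prev["C3'"], prev["O3'"], pos["P"],
                bonds["P-O5'"], O3_P_O5_ANGLE, torsions[i - 1].zeta,
            )
            pos["C5'"] = place_atom(
                prev["O3'"], pos["P"], pos["O5'"],
                bonds["O5'-C5'"], angles["P-O5'-C5'"], tv.alpha,
            )
            pos["C4'"] = place_atom(
                pos["P"], pos["O5'"], pos["C5'"],
                bonds["C5'-C4'"], angles["O5'-C5'-C4'"], tv.beta,
            )
            gamma_refs = (pos["O5'"], pos["C5'"], pos["C4'"])
        pos["C3'"] = place_atom(
            *gamma_refs, bonds["C4'-C3'"], angles["C5'-C4'-C3'"], tv.gamma
        )
        pos["O3'"] = place_atom(
            pos["C5'"], pos["C4'"], pos["C3'"],
            bonds["C3'-O3'"], angles["C4'-C3'-O3'"], tv.delta,
        )
        for side, refs in (
            ("O4'", ("O3'", "C3'", "C4'")),
            ("C1'", ("C3'", "C4'", "O4'")),
            ("C2'", ("C4'", "O4'", "C1'")),
        ):
            e = ic[side]
            pos[side] = place_atom(
                pos[refs[0]], pos[refs[1]], pos[refs[2]], e["bond"], e["angle"], e["torsion"]
            )
        n_glyc, anchor1, anchor2 = _anchors(letter)
        e = ic["N"]
        pos[n_glyc] = place_atom(pos["C4'"], pos["O4'"], pos["C1'"], e["bond"], e["angle"], e["torsion"])
        e1, e2 = ic["anchor1"], ic["anchor2"]
        pos[anchor1] = place_atom(
            pos["O4'"], pos["C1'"], pos[n_glyc], e1["bond"], e1["angle"], tv.chi
        )
        pos[anchor2] = place_atom(
            pos["O4'"], pos["C1'"], pos[n_glyc],
            e2["bond"], e2["angle"], tv.chi + ic["anchor2_offset"],
        )
        # rigid base posed on the three anchors
        tmpl = ic["base"]
        anchor_names = (n_glyc, anchor1, anchor2)
        sup = superpose(
            (list(anchor_names), np.array([tmpl[a] for a in anchor_names])),
            (list(anchor_names), np.array([pos[a] for a in anchor_names])),
        )
        for name, xyz in tmpl.items():
            pos[name] = sup.apply(xyz[None, :])[0]
        if "P" in pos:
            for opname in ("OP1", "OP2"):
                e = ic[opname]
                pos[opname] = place_atom(
                    pos["C5'"], pos["O5'"], pos["P"], e["bond"], e["angle"], e["torsion"]
                )
        atoms = {
            name: Atom(name=name, element=_element_of(name), pos=xyz, b_iso=b_iso)
            for name, xyz in pos.items()
        }
        nucleotides.append(
            Nucleotide(chain_id, start_res + i, RES_NAMES[letter], atoms)
        )
        prev = pos
    return nucleotides
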