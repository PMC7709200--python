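"""Base-pair detection, Leontis-Westhof/Saenger classification and sequence pairing.

Pairs are detected purely geometrically: two bases pair when enough
donor-acceptor contacts fall inside the hydrogen-bond window, their ring
planes are roughly parallel and the glycosidic C1' atoms sit at duplex-like
separation.  Classification then reads the interacting edges (Watson-Crick,
Hoogsteen or sugar) off the participating atoms, the cis/trans glycosidic
orientation off the C1'-N...N-C1' pseudo-torsion, and the Saenger class from
a shipped lookup table keyed by the hydrogen-bond atom patterns (canonical
G-C and A-T are Saenger 19/20; the wobble-type T-T pair of antiparallel
duplexes is 16, its parallel-strand variant 12, G-T wobble 28).  Patterns
outside the table are reported unclassified rather than guessed.

Default thresholds are deliberately tolerant: the crystal structures this
package targets diffract at 2.6-2.9 angstrom resolution.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .structure_io import BASE_HEAVY_ATOMS, Nucleotide, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "HBond",
    "BasePair",
    "PairParams",
    "PairingSummary",
    "find_pairs",
    "classify_pair",
    "strand_orientation",
    "pair_self_duplex",
    "LW_CLASS_NUMBERS",
]

#: Leontis-Westhof family numbering: (glycosidic orientation, edge pair) -> 1..12
LW_CLASS_NUMBERS = {
    ("cis", ("W", "W")): 1,
    ("trans", ("W", "W")): 2,
    ("cis", ("W", "H")): 3,
    ("trans", ("W", "H")): 4,
    ("cis", ("W", "S")): 5,
    ("trans", ("W", "S")): 6,
    ("cis", ("H", "H")): 7,
    ("trans", ("H", "H")): 8,
    ("cis", ("H", "S")): 9,
    ("trans", ("H", "S")): 10,
    ("cis", ("S", "S")): 11,
    ("trans", ("S", "S")): 12,
}


def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("ntckit") / "data" / name
    return yaml.safe_load(ref.read_text())


_CHEM = _load_yaml("edges.yaml")
_SAENGER = _load_yaml("saenger.yaml")["classes"]

EDGE_ATOMS = _CHEM["edges"]
DONORS = _CHEM["donors"]
ACCEPTORS = _CHEM["acceptors"]


@dataclass(frozen=True)
class PairParams:
    """Geometric thresholds for hydrogen-bond and pair detection."""

    hbond_min: float = 2.4
    hbond_max: float = 3.6
    planarity_max_deg: float = 65.0
    min_hbonds: int = 2
    c1c1_min: float = 8.0
    c1c1_max: float = 12.0


@dataclass
class HBond:
    donor: tuple[Nucleotide, str]
    acceptor: tuple[Nucleotide, str]
    distance: float


@dataclass
class BasePair:
    nt1: Nucleotide
    nt2: Nucleotide
    hbonds: list[HBond] = field(default_factory=list)
    edge1: str | None = None
    edge2: str | None = None
    glyc_orientation: str | None = None
    lw_class: int | None = None
    saenger: int | None = None
    canonical: bool = False
    strand_orientation: str = "n/a"

    @property
    def combo(self) -> str:
        """Order-normalized base-letter pair, e.g. ``"T-T"`` or ``"C-G"``."""
        return "-".join(sorted((self.nt1.parent_base, self.nt2.parent_base)))

    def swapped(self) -> "BasePair":
        return BasePair(self.nt2, self.nt1, list(self.hbonds))


def _ring_atoms(nt: Nucleotide) -> list[str]:
    return ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1"] if nt.is_purine else \
           ["N1", "C2", "N3", "C4", "C5", "C6"]


def _base_normal(nt: Nucleotide) -> np.ndarray | None:
    pts = np.array([nt.pos(n) for n in _ring_atoms(nt) if nt.has(n)])
    if len(pts) < 3:
        return None
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    return vt[2]


def _hbonds_between(nt1: Nucleotide, nt2: Nucleotide, params: PairParams) -> list[HBond]:
    """Donor-acceptor contacts between the base polar atoms of two nucleotides."""
    out = []
    for a, b in ((nt1, nt2), (nt2, nt1)):
        pa, pb = a.parent_base, b.parent_base
        if pa not in DONORS or pb not in ACCEPTORS:
            continue
        for dn in DONORS[pa]:
            if not a.has(dn):
                continue
            for ac in ACCEPTORS[pb]:
                if not b.has(ac):
                    continue
                d = float(np.linalg.norm(a.pos(dn) - b.pos(ac)))
                if params.hbond_min <= d <= params.hbond_max:
                    out.append(HBond((a, dn), (b, ac), d))
    # deduplicate reciprocal duplicates on the same atom pair
    seen, uniq = set(), []
    for hb in sorted(out, key=lambda h: h.distance):
        key = frozenset([(id(hb.donor[0]), hb.donor[1]), (id(hb.acceptor[0]), hb.acceptor[1])])
        if key not in seen:
            seen.add(key)
            uniq.append(hb)
    return uniq


def _plane_angle(nt1: Nucleotide, nt2: Nucleotide) -> float | None:
    n1, n2 = _base_normal(nt1), _base_normal(nt2)
    if n1 is None or n2 is None:
        return None
    ang = np.degrees(np.arccos(np.clip(abs(float(n1 @ n2)), 0.0, 1.0)))
    return float(ang)


def find_pairs(structure: Structure | list[Nucleotide],
               params: PairParams = PairParams(),
               classify: bool = True) -> list[BasePair]:
    """Detect base pairs geometrically; each nucleotide pairs at most once.

    Candidates are nucleotide pairs whose C1'-C1' distance lies in the duplex
    window, with base planes within the planarity limit and at least
    ``params.min_hbonds`` donor-acceptor contacts inside the hydrogen-bond
    window.  Overlapping candidates are resolved best-score-first (more
    hydrogen bonds, then shorter mean bond length).
    """
    nts = list(structure.nucleotides()) if isinstance(structure, Structure) else list(structure)
    nts = [nt for nt in nts if nt.has("C1'") and nt.parent_base in BASE_HEAVY_ATOMS]
    if len(nts) < 2:
        return []
    pos = np.array([nt.pos("C1'") for nt in nts])
    tree = cKDTree(pos)
    candidates = []
    for i, j in tree.query_pairs(params.c1c1_max):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d < params.c1c1_min:
            continue
        ang = _plane_angle(nts[i], nts[j])
        if ang is None or ang > params.planarity_max_deg:
            continue
        hbonds = _hbonds_between(nts[i], nts[j], params)
        if len(hbonds) < params.min_hbonds:
            continue
        score = (-len(hbonds), float(np.mean([h.distance for h in hbonds])))
        candidates.append((score, i, j, hbonds))
    candidates.sort(key=lambda c: c[0])
    used: set[int] = set()
    pairs = []
    for _, i, j, hbonds in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pair = BasePair(nts[i], nts[j], hbonds)
        if classify:
            classify_pair(pair)
            if isinstance(structure, Structure):
                pair.strand_orientation = strand_orientation(pair, structure.chains)
        pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# classification


def _bond_signature(pair: BasePair) -> tuple[frozenset, dict]:
    """Normalized hydrogen-bond pattern, as ``"X.a1-Y.a2"`` strings.

    Hetero pairs are written purine side first (alphabetical for same-category
    pairs); same-base pairs keep each bond in its natural side order, so
    symmetric patterns (N3-O4 plus O4-N3) stay distinguishable from single
    bonds.  The resulting set is invariant under swapping nt1/nt2.
    """
    b1, b2 = pair.nt1.parent_base, pair.nt2.parent_base
    purines = {"A", "G"}
    if b1 == b2:
        side0_first = True
        same = True
    else:
        same = False
        if (b1 in purines) != (b2 in purines):
            side0_first = b1 in purines
        else:
            side0_first = b1 <= b2
    sigs = set()
    atoms_by_side: dict[int, set[str]] = {0: set(), 1: set()}
    for hb in pair.hbonds:
        (nd, da), (na, aa) = hb.donor, hb.acceptor
        side_d = 0 if nd is pair.nt1 else 1
        ends = {side_d: (nd.parent_base, da), 1 - side_d: (na.parent_base, aa)}
        atoms_by_side[side_d].add(da)
        atoms_by_side[1 - side_d].add(aa)
        lo, hi = (ends[0], ends[1]) if (same or side0_first) else (ends[1], ends[0])
        sigs.add(f"{lo[0]}.{lo[1]}-{hi[0]}.{hi[1]}")
    return frozenset(sigs), atoms_by_side


def _edge_of(base: str, atoms: set[str]) -> str | None:
    """Majority edge of the participating atoms; ties prefer W over H over S."""
    votes = {"W": 0, "H": 0, "S": 0}
    for edge in ("W", "H", "S"):
        members = set(EDGE_ATOMS.get(base, {}).get(edge, ()))
        votes[edge] = len(atoms & members)
    best = max(votes.values())
    if best == 0:
        return None
    for edge in ("W", "H", "S"):
        if votes[edge] == best:
            return edge


def _glyc_orientation(pair: BasePair) -> str | None:
    from .step_geometry import UndefinedTorsionError, dihedral

    def glyc(nt):
        n = "N9" if nt.is_purine else "N1"
        return (nt.pos("C1'"), nt.pos(n)) if (nt.has("C1'") and nt.has(n)) else None

    g1, g2 = glyc(pair.nt1), glyc(pair.nt2)
    if g1 is None or g2 is None:
        return None
    try:
        tau = dihedral(g1[0], g1[1], g2[1], g2[0])
    except UndefinedTorsionError:
        return None
    return "cis" if abs(tau) <= 90.0 else "trans"


def classify_pair(pair: BasePair) -> BasePair:
    """Fill in edges, cis/trans, Leontis-Westhof family, Saenger class, canonical flag.

    Canonical means cis Watson-Crick/Watson-Crick G-C (Saenger 19) or A-T
    (Saenger 20).  Unrecognized bond patterns leave ``saenger`` unset (logged).
    """
    if not pair.hbonds:
        raise ValueError("pair has no hydrogen bonds to classify")
    sigs, atoms_by_side = _bond_signature(pair)
    pair.edge1 = _edge_of(pair.nt1.parent_base, atoms_by_side[0])
    pair.edge2 = _edge_of(pair.nt2.parent_base, atoms_by_side[1])
    pair.glyc_orientation = _glyc_orientation(pair)
    if pair.edge1 and pair.edge2 and pair.glyc_orientation:
        edges = tuple(sorted((pair.edge1, pair.edge2), key="WHS".index))
        pair.lw_class = LW_CLASS_NUMBERS.get((pair.glyc_orientation, edges))
    combo = tuple(sorted((pair.nt1.parent_base, pair.nt2.parent_base)))
    best = None
    for entry in _SAENGER:
        if tuple(entry["combo"]) != combo:
            continue
        if "glyc" in entry and pair.glyc_orientation != entry["glyc"]:
            continue
        required = set(entry["required"])
        if required <= sigs:
            if best is None or len(required) > len(set(best["required"])):
                best = entry
    if best is not None:
        pair.saenger = int(best["saenger"])
    else:
        logger.info("unrecognized hydrogen-bond pattern %s for %s-%s",
                    sorted(sigs), pair.nt1.res_id, pair.nt2.res_id)
        pair.saenger = None
    pair.canonical = (
        pair.saenger in (19, 20)
        and pair.glyc_orientation == "cis"
        and pair.edge1 == "W"
        and pair.edge2 == "W"
    )
    return pair


def strand_orientation(pair: BasePair, chains: dict[str, list[Nucleotide]]) -> str:
    """Parallel/antiparallel from the local 5'->3' chain directions at the pair.

    The direction at each nucleotide is the C1'(next) - C1'(previous) vector
    (falling back to a single neighbor at chain termini); a negative dot
    product means antiparallel.  Nucleotides without any neighbor give "n/a".
    """
    def direction(nt: Nucleotide) -> np.ndarray | None:
        chain = chains.get(nt.chain_id)
        if not chain:
            return None
        idx = next((i for i, x in enumerate(chain)
                    if x.res_num == nt.res_num and x.icode == nt.icode), None)
        if idx is None:
            return None
        prev_nt = chain[idx - 1] if idx > 0 else None
        next_nt = chain[idx + 1] if idx + 1 < len(chain) else None
        a = prev_nt if (prev_nt and prev_nt.has("C1'")) else nt
        b = next_nt if (next_nt and next_nt.has("C1'")) else nt
        if a is b or not (a.has("C1'") and b.has("C1'")):
            return None
        v = b.pos("C1'") - a.pos("C1'")
        n = np.linalg.norm(v)
        return v / n if n > 0 else None

    d1, d2 = direction(pair.nt1), direction(pair.nt2)
    if d1 is None or d2 is None:
        return "n/a"
    return "antiparallel" if float(d1 @ d2) < 0 else "parallel"


# ---------------------------------------------------------------------------
# sequence-level pairing of a self-annealed duplex


@dataclass
class PairRecord:
    position_i: int
    position_j: int
    combo: str
    canonical: bool
    self_pair: bool = False


@dataclass
class PairingSummary:
    """Pairing of two copies of one sequence annealed antiparallel.

    Position i of the first strand pairs with position L+1-i of the second;
    the ``pairs`` list has one record per first-strand position.  ``segments``
    are the lengths of maximal runs of consecutive canonical pairs, so a
    duplex with a central double mismatch reports two flanking segments.
    """

    pairs: list[PairRecord]
    n_wc: int
    mismatches: list[PairRecord]
    segments: list[int]


_WC_SET = {frozenset(("A", "T")), frozenset(("G", "C"))}


def pair_self_duplex(sequence: str) -> PairingSummary:
    seq = sequence.strip().upper()
    L = len(seq)
    if L < 2:
        raise ValueError("sequence too short to pair")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)}")
    pairs: list[PairRecord] = []
    for i in range(1, L + 1):
        j = L + 1 - i
        b1, b2 = seq[i - 1], seq[j - 1]
        canonical = frozenset((b1, b2)) in _WC_SET
        pairs.append(PairRecord(i, j, "-".join(sorted((b1, b2))), canonical,
                                self_pair=(i == j)))
    counted = [p for p in pairs if not p.self_pair]
    n_wc = sum(p.canonical for p in counted)
    mismatches = [p for p in counted if not p.canonical]
    segments, run = [], 0
    for p in pairs:
        if p.canonical and not p.self_pair:
            run += 1
        else:
            if run:
                segments.append(run)
            run = 0
    if run:
        segments.append(run)
    return PairingSummary(pairs, n_wc, mismatches, segments)
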