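"""Dinucleotide conformer-class catalog, step assignment and torsion restraints.

A conformer class (NtC-style) is a named point in the nine-dimensional torsion
space of a dinucleotide step (delta/epsilon/zeta of residue i, alpha/beta/
gamma/delta of residue i+1, chi of both) together with a coarser structural-
alphabet (CANA-style) code and an 18-atom representative geometry.  A step is
assigned to the nearest class by circular Euclidean distance, provided the
aggregate distance and every per-torsion deviation stay under configurable
caps; otherwise it falls back to the NANT ("not assigned") class.  The
Cartesian r.m.s.d. to the nearest representative is computed regardless of
the torsion-space verdict, because a step can be Cartesian-close to a class
while failing the torsion criteria.

The shipped catalog is a documented stand-in: the canonical A- and B-form
classes come from the package's own calibrated fiber-like torsion sets and
the remaining classes from literature-informed offsets.  It makes no claim
of reproducing the reference "golden set" used by the DNATCO service, and is
user-extensible via :meth:`Catalog.add`.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .step_geometry import (
    StepAtoms,
    TORSION_NAMES,
    TorsionVector,
    circular_distance,
    dissect_steps,
    step_atoms,
    step_torsions,
    superpose,
    wrap_degrees,
)
from .structure_io import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "NtCClass",
    "Catalog",
    "StepAssignment",
    "AnnotatedStep",
    "builtin_catalog",
    "assign_step",
    "annotate_structure",
    "nearest_class_rmsd",
    "export_restraints",
    "parse_restraints",
    "NANT",
    "D_MAX_DEFAULT",
    "PER_TORSION_CAP_DEFAULT",
    "CONFAL_TAU",
]

NANT = "NANT"
#: aggregate circular-Euclidean cutoff for assignment, degrees
D_MAX_DEFAULT = 100.0
#: per-torsion absolute deviation cap, degrees
PER_TORSION_CAP_DEFAULT = 60.0
#: width of the goodness-of-fit score 100*exp(-(d/tau)^2), degrees.
#: A documented stand-in for the unpublished confal formula.
CONFAL_TAU = 60.0


@dataclass
class NtCClass:
    name: str
    cana: str
    centroid: TorsionVector
    tol: float = 25.0

    _rep_atoms: StepAtoms | None = field(default=None, repr=False, compare=False)

    @property
    def rep_atoms(self) -> StepAtoms:
        """18-atom representative geometry, built from the centroid torsions.

        Generated on first access with the internal-coordinate strand builder
        (purine-purine dinucleotide), which guarantees that the representative
        reproduces the centroid torsions.
        """
        if self._rep_atoms is None:
            from ._nerf import build_strand

            nts = build_strand("GG", [self.centroid])
            steps = dissect_steps(nts)
            self._rep_atoms = step_atoms(steps[0])
        return self._rep_atoms


class Catalog:
    """An ordered collection of conformer classes, loadable from TSV."""

    def __init__(self, classes: list[NtCClass]):
        if not classes:
            raise ValueError("empty catalog")
        self._classes = {c.name: c for c in classes}
        if len(self._classes) != len(classes):
            raise ValueError("duplicate class names in catalog")

    def __len__(self):
        return len(self._classes)

    def __contains__(self, name):
        return name in self._classes

    def __getitem__(self, name) -> NtCClass:
        return self._classes[name]

    def __iter__(self):
        return iter(self._classes.values())

    @property
    def names(self) -> list[str]:
        return list(self._classes)

    def cana(self, name: str) -> str:
        return self._classes[name].cana

    def add(self, cls: NtCClass) -> None:
        if cls.name in self._classes:
            raise ValueError(f"class {cls.name} already in catalog")
        self._classes[cls.name] = cls

    def centroid_matrix(self) -> np.ndarray:
        return np.vstack([c.centroid.as_array() for c in self])

    @classmethod
    def from_tsv(cls, path) -> "Catalog":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"name", "cana", *TORSION_NAMES}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"corrupt catalog {path}: missing columns {sorted(missing)}")
        classes = []
        for _, row in df.iterrows():
            centroid = TorsionVector(**{n: float(row[n]) for n in TORSION_NAMES})
            tol = float(row["tol"]) if "tol" in df.columns else 25.0
            if tol <= 0:
                raise ValueError(f"corrupt catalog {path}: non-positive tolerance for {row['name']}")
            classes.append(NtCClass(str(row["name"]), str(row["cana"]), centroid, tol))
        return cls(classes)

    def to_tsv(self, path) -> None:
        rows = []
        for c in self:
            row = {"name": c.name, "cana": c.cana, "tol": c.tol}
            row.update({n: getattr(c.centroid, n) for n in TORSION_NAMES})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_BUILTIN: Catalog | None = None


def builtin_catalog() -> Catalog:
    """The packaged conformer-class catalog (see data/ntc_catalog.tsv)."""
    global _BUILTIN
    if _BUILTIN is None:
        ref = importlib.resources.files("ntckit") / "data" / "ntc_catalog.tsv"
        _BUILTIN = Catalog.from_tsv(Path(str(ref)))
    return _BUILTIN


@dataclass
class StepAssignment:
    ntc: str
    nearest: str
    torsion_distance: float
    confal_like: float
    cart_rmsd: float | None = None
    reason: str = ""

    @property
    def assigned(self) -> bool:
        return self.ntc != NANT


def confal_like(torsion_distance: float, tau: float = CONFAL_TAU) -> float:
    """Goodness-of-fit score in [0, 100]: 100 at distance 0, strictly decreasing."""
    return float(100.0 * np.exp(-((torsion_distance / tau) ** 2)))


def assign_step(
    tv: TorsionVector,
    step_atoms_: StepAtoms | None = None,
    catalog: Catalog | None = None,
    d_max: float = D_MAX_DEFAULT,
    per_torsion_cap: float = PER_TORSION_CAP_DEFAULT,
) -> StepAssignment:
    """Assign one step to its nearest conformer class, or NANT.

    The nearest class is found by circular Euclidean distance over the nine
    torsions (equal weights); the assignment stands only if the aggregate
    distance is at most ``d_max`` *and* every per-torsion deviation is at most
    ``per_torsion_cap``.  Distance ties break to the lexicographically smaller
    class name.  When ``step_atoms_`` is given, the Cartesian r.m.s.d. against
    the nearest class representative is attached (also for NANT steps).
    """
    catalog = catalog or builtin_catalog()
    if not tv.complete:
        return StepAssignment(
            ntc=NANT,
            nearest="",
            torsion_distance=float("nan"),
            confal_like=0.0,
            reason=f"missing atoms: {', '.join(tv.missing) or 'unknown'}",
        )
    v = tv.as_array()
    centroids = catalog.centroid_matrix()
    deltas = wrap_degrees(v[None, :] - centroids)
    dists = np.linalg.norm(deltas, axis=1)
    names = catalog.names
    order = sorted(range(len(names)), key=lambda i: (dists[i], names[i]))
    best = order[0]
    if len(order) > 1 and abs(dists[order[0]] - dists[order[1]]) < 1e-9:
        logger.info("distance tie between %s and %s; keeping %s",
                    names[order[0]], names[order[1]], names[best])
    dist = float(dists[best])
    nearest = names[best]
    cart = None
    if step_atoms_ is not None and step_atoms_.complete:
        cart = superpose(step_atoms_, catalog[nearest].rep_atoms).rmsd
    worst = np.abs(deltas[best]).max()
    if dist > d_max:
        return StepAssignment(NANT, nearest, dist, confal_like(dist), cart,
                              reason="distance exceeds threshold")
    if worst > per_torsion_cap:
        i = int(np.abs(deltas[best]).argmax())
        return StepAssignment(NANT, nearest, dist, confal_like(dist), cart,
                              reason=f"torsion {TORSION_NAMES[i]} deviates {worst:.1f} deg")
    return StepAssignment(nearest, nearest, dist, confal_like(dist), cart)


def nearest_class_rmsd(step_atoms_: StepAtoms, catalog: Catalog | None = None) -> tuple[str, float]:
    """Minimum superposition r.m.s.d. over all class representatives.

    This Cartesian criterion is independent of the torsion-space assignment:
    NANT steps still receive a finite value, and it serves as the geometric
    axis of the density-fit scattergram.
    """
    catalog = catalog or builtin_catalog()
    if not step_atoms_.complete:
        raise ValueError("incomplete 18-atom step")
    best_name, best_rmsd = "", float("inf")
    for c in catalog:
        r = superpose(step_atoms_, c.rep_atoms).rmsd
        if r < best_rmsd or (r == best_rmsd and c.name < best_name):
            best_name, best_rmsd = c.name, r
    return best_name, float(best_rmsd)


@dataclass
class AnnotatedStep:
    step_id: str
    chain_id: str
    res_num1: int
    res_num2: int
    torsions: TorsionVector
    assignment: StepAssignment


def annotate_structure(
    structure: Structure,
    catalog: Catalog | None = None,
    d_max: float = D_MAX_DEFAULT,
    per_torsion_cap: float = PER_TORSION_CAP_DEFAULT,
) -> tuple[list[AnnotatedStep], dict]:
    """Assign every dinucleotide step of every chain; NANT steps count as outliers."""
    catalog = catalog or builtin_catalog()
    out: list[AnnotatedStep] = []
    for chain_id, chain in structure.chains.items():
        for step in dissect_steps(chain):
            tv = step_torsions(step)
            sa = step_atoms(step)
            assignment = assign_step(tv, sa if sa.complete else None, catalog,
                                     d_max=d_max, per_torsion_cap=per_torsion_cap)
            out.append(
                AnnotatedStep(step.step_id, chain_id, step.nt1.res_num, step.nt2.res_num,
                              tv, assignment)
            )
    n_assigned = sum(1 for s in out if s.assignment.assigned)
    summary = {
        "n_steps": len(out),
        "n_assigned": n_assigned,
        "n_outliers": len(out) - n_assigned,
    }
    return out, summary


# ---------------------------------------------------------------------------
# torsion restraints

_RESTRAINT_ATOMS = {
    "delta1": ((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")),
    "epsilon1": ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")),
    "zeta1": ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")),
    "alpha2": ((0, "O3'"), (1, "P"), (1, "O5'"), (1, "C5'")),
    "beta2": ((1, "P"), (1, "O5'"), (1, "C5'"), (1, "C4'")),
    "gamma2": ((1, "O5'"), (1, "C5'"), (1, "C4'"), (1, "C3'")),
    "delta2": ((1, "C5'"), (1, "C4'"), (1, "C3'"), (1, "O3'")),
    "chi1": ((0, "O4'"), (0, "C1'"), (0, "N*"), (0, "C*")),
    "chi2": ((1, "O4'"), (1, "C1'"), (1, "N*"), (1, "C*")),
}

_RESTRAINT_HEADER = (
    "# ntckit torsion restraints\n"
    "# columns: torsion chain res1 res2 atom1 atom2 atom3 atom4 target_deg sigma_deg ntc\n"
)


def export_restraints(
    annotated: list[AnnotatedStep],
    catalog: Catalog | None = None,
    sigma_scale: float = 1.0,
) -> str:
    """Render per-step torsion restraints targeting the assigned class centroid.

    Each assigned step emits nine records; the restraint sigma is the class
    tolerance scaled by ``sigma_scale``.  NANT steps emit nothing (logged).
    The plain-text format round-trips through :func:`parse_restraints`.
    """
    catalog = catalog or builtin_catalog()
    lines = [_RESTRAINT_HEADER.rstrip("\n")]
    n_skipped = 0
    for rec in annotated:
        if not rec.assignment.assigned:
            n_skipped += 1
            logger.warning("step %s is NANT (%s); no restraint emitted",
                           rec.step_id, rec.assignment.reason)
            continue
        cls = catalog[rec.assignment.ntc]
        res = (rec.res_num1, rec.res_num2)
        for name, quad in _RESTRAINT_ATOMS.items():
            atoms = " ".join(a for _, a in quad)
            resnums = sorted({res[i] for i, _ in quad})
            res1 = res[0] if any(i == 0 for i, _ in quad) else res[1]
            res2 = res[1] if any(i == 1 for i, _ in quad) else res[0]
            target = getattr(cls.centroid, name)
            sigma = cls.tol * sigma_scale
            lines.append(
                f"{name}\t{rec.chain_id}\t{res1}\t{res2}\t{atoms}\t{target:.2f}\t{sigma:.2f}\t{cls.name}"
            )
    if n_skipped and len(lines) == 1:
        logger.warning("all %d steps were NANT; restraint output is empty", n_skipped)
    return "\n".join(lines) + "\n"


def parse_restraints(text: str) -> pd.DataFrame:
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        name, chain, res1, res2, atoms, target, sigma, ntc = line.split("\t")
        rows.append(
            dict(torsion=name, chain=chain, res1=int(res1), res2=int(res2),
                 atoms=atoms, target=float(target), sigma=float(sigma), ntc=ntc)
        )
    return pd.DataFrame(rows)
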