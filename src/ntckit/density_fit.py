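"""Model density, real-space correlation and the RSCC-vs-r.m.s.d. scattergram.

The real-space correlation coefficient (RSCC) is the Pearson correlation of
an observed and a model-computed density map over the voxels within a mask
radius of a set of atoms — here, the 18 atoms defining a dinucleotide step.
Plotted against the Cartesian r.m.s.d. of the step to the nearest conformer
class, it separates fragments that fit the experimental density and known
backbone conformations (the "good" quadrant) from fragments that fail either
criterion.  The geometric threshold defaults to 1.0 angstrom: steps further
than that from every known class are typically beyond what automated
re-refinement can remediate.

Model density uses one isotropic Gaussian per atom — amplitude proportional
to the electron count, variance (B + b_floor)/(8 pi^2) — with periodic
wrapping over the cell.  This single-Gaussian profile is a documented
simplification of the multi-Gaussian atomic scattering factors; it is
adequate for correlation analysis, not for structure-factor work.  Map
synthesis and masking require orthorhombic cells (all synthetic maps are P1
orthorhombic); CCP4/MRC input with permuted axis order is re-indexed to
canonical X,Y,Z on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "ScatterPoint",
    "read_map",
    "write_map",
    "calc_model_map",
    "rscc",
    "scattergram",
    "plot_scattergram",
    "RMSD_MAX_DEFAULT",
    "RSCC_MIN_DEFAULT",
    "MASK_RADIUS_DEFAULT",
    "ELECTRON_COUNTS",
]

#: geometric threshold of the scattergram, angstroms
RMSD_MAX_DEFAULT = 1.0
#: density threshold of the scattergram (no universal published value; tunable)
RSCC_MIN_DEFAULT = 0.8
#: mask radius around the selected atoms, angstroms
MASK_RADIUS_DEFAULT = 2.0

ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
    "BR": 35, "SR": 38, "MG": 12, "NA": 11, "K": 19, "LI": 3,
}

QUADRANTS = ("good", "poor-density", "poor-geometry", "poor-both")


@dataclass
class DensityMap:
    """A real-space map on a regular fractional grid of an orthorhombic cell.

    ``values[ix, iy, iz]`` covers fractional coordinate ix/nx etc.; axis
    order is canonical X, Y, Z.
    """

    values: np.ndarray
    cell: tuple[float, float, float, float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("map values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite map values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.array(self.cell[:3]) / np.array(self.shape)

    def _require_orthorhombic(self):
        if not np.allclose(self.cell[3:], 90.0):
            raise NotImplementedError("map arithmetic requires an orthorhombic cell")


def read_map(path) -> DensityMap:
    """Read a CCP4/MRC map, re-indexing permuted axis order to X,Y,Z."""
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: not a readable CCP4/MRC map: {exc}") from exc
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = m.grid
    values = np.array(grid, copy=True)
    if np.isnan(values).any():
        raise ValueError(f"{path}: map does not cover the full cell")
    cell = grid.unit_cell
    return DensityMap(values, (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma))


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as CCP4 format (canonical axis order, full cell)."""
    grid = gemmi.FloatGrid(*dmap.shape)
    grid.set_unit_cell(gemmi.UnitCell(*dmap.cell))
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    np.asarray(grid)[...] = dmap.values
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def _atom_fields(atom) -> tuple[str, np.ndarray, float, float]:
    if isinstance(atom, tuple):
        element, pos, occ, b = atom
    else:
        element, pos, occ, b = atom.element, atom.pos, atom.occupancy, atom.b_iso
    return str(element).upper(), np.asarray(pos, float), float(occ), float(b)


def calc_model_map(atoms, cell, spacing: float = 0.8, shape=None,
                   b_floor: float = 10.0, cutoff_sigmas: float = 4.5) -> DensityMap:
    """Sum-of-Gaussians model density on a periodic orthorhombic grid.

    One isotropic Gaussian per atom, normalized so its integral equals
    (electron count x occupancy); variance (B + b_floor)/(8 pi^2) per
    Cartesian axis.  ``atoms`` holds objects with element/pos/occupancy/b_iso
    or (element, pos, occ, b) tuples.
    """
    if spacing is not None and spacing <= 0:
        raise ValueError("grid spacing must be positive")
    cell = tuple(float(c) for c in cell)
    if not np.allclose(cell[3:], 90.0):
        raise NotImplementedError("model maps require an orthorhombic cell")
    abc = np.array(cell[:3])
    if shape is None:
        shape = tuple(int(np.ceil(L / spacing)) for L in abc)
    values = np.zeros(shape, dtype=np.float64)
    steps = abc / np.array(shape)
    for atom in atoms:
        element, pos, occ, b = _atom_fields(atom)
        z = ELECTRON_COUNTS.get(element)
        if z is None:
            logger.warning("unknown element %r; skipping in model map", element)
            continue
        var = (b + b_floor) / (8.0 * np.pi**2)
        sigma = np.sqrt(var)
        amp = z * occ / (2.0 * np.pi * var) ** 1.5
        half = cutoff_sigmas * sigma
        idx_ranges, axes = [], []
        for d in range(3):
            lo = int(np.floor((pos[d] - half) / steps[d]))
            hi = int(np.ceil((pos[d] + half) / steps[d]))
            idx = np.arange(lo, hi + 1)
            x = idx * steps[d] - pos[d]
            idx_ranges.append(idx % shape[d])
            axes.append(np.exp(-(x**2) / (2.0 * var)))
        g = amp * axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        ix, iy, iz = np.meshgrid(*idx_ranges, indexing="ij")
        np.add.at(values, (ix, iy, iz), g)
    return DensityMap(values.astype(np.float32), cell)


def _mask_indices(dmap: DensityMap, atoms, radius: float) -> tuple[np.ndarray, ...]:
    dmap._require_orthorhombic()
    shape = dmap.shape
    steps = dmap.spacing
    mask = np.zeros(shape, dtype=bool)
    for atom in atoms:
        _, pos, _, _ = _atom_fields(atom)
        idx_ranges, dist2 = [], []
        for d in range(3):
            lo = int(np.floor((pos[d] - radius) / steps[d]))
            hi = int(np.ceil((pos[d] + radius) / steps[d]))
            idx = np.arange(lo, hi + 1)
            x = idx * steps[d] - pos[d]
            idx_ranges.append(idx % shape[d])
            dist2.append(x**2)
        d2 = dist2[0][:, None, None] + dist2[1][None, :, None] + dist2[2][None, None, :]
        inside = d2 <= radius**2
        ix, iy, iz = np.meshgrid(*idx_ranges, indexing="ij")
        mask[ix[inside], iy[inside], iz[inside]] = True
    return np.nonzero(mask)


def rscc(obs: DensityMap, calc: DensityMap, atoms, mask_radius: float = MASK_RADIUS_DEFAULT) -> float:
    """Pearson correlation of observed vs model density near the given atoms.

    Both maps must share grid and cell.  Raises on an empty mask or a
    zero-variance masked region (RSCC undefined there).
    """
    if obs.shape != calc.shape or not np.allclose(obs.cell, calc.cell):
        raise ValueError("observed and calculated maps must share grid and cell")
    idx = _mask_indices(obs, atoms, mask_radius)
    if len(idx[0]) == 0:
        raise ValueError("empty mask: no voxels within mask_radius of the atoms")
    a = obs.values[idx].astype(np.float64)
    b = calc.values[idx].astype(np.float64)
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero-variance region: RSCC undefined")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# scattergram


@dataclass
class ScatterPoint:
    """One dinucleotide step in RSCC-vs-r.m.s.d. space."""

    step_id: str
    ntc: str
    rmsd: float
    rscc: float
    quadrant: str = ""


def scattergram(points: list[ScatterPoint],
                rmsd_max: float = RMSD_MAX_DEFAULT,
                rscc_min: float = RSCC_MIN_DEFAULT) -> dict:
    """Label each point's quadrant and summarize fractions per quadrant/class.

    "good" combines high density correlation with closeness to a known
    conformer (rscc >= rscc_min and rmsd <= rmsd_max) — with RSCC increasing
    on x and r.m.s.d. increasing on y this is the lower-right rectangle of
    the plot.  The partition is exhaustive and exclusive for finite inputs.
    """
    counts = dict.fromkeys(QUADRANTS, 0)
    by_class: dict[str, dict] = {}
    for p in points:
        if not (np.isfinite(p.rmsd) and np.isfinite(p.rscc)):
            raise ValueError(f"non-finite scatter point {p.step_id}")
        good_density = p.rscc >= rscc_min
        good_geometry = p.rmsd <= rmsd_max
        if good_density and good_geometry:
            p.quadrant = "good"
        elif good_geometry:
            p.quadrant = "poor-density"
        elif good_density:
            p.quadrant = "poor-geometry"
        else:
            p.quadrant = "poor-both"
        counts[p.quadrant] += 1
        cls = by_class.setdefault(p.ntc, dict.fromkeys(QUADRANTS, 0))
        cls[p.quadrant] += 1
    n = len(points)
    return {
        "n": n,
        "counts": counts,
        "fractions": {q: (counts[q] / n if n else 0.0) for q in QUADRANTS},
        "by_class": by_class,
        "thresholds": {"rmsd_max": rmsd_max, "rscc_min": rscc_min},
    }


def plot_scattergram(points: list[ScatterPoint], path,
                     rmsd_max: float = RMSD_MAX_DEFAULT,
                     rscc_min: float = RSCC_MIN_DEFAULT) -> None:
    """Scatter plot: RSCC on x (increasing), r.m.s.d. on y (increasing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    classes = sorted({p.ntc for p in points})
    for cls in classes:
        xs = [p.rscc for p in points if p.ntc == cls]
        ys = [p.rmsd for p in points if p.ntc == cls]
        ax.scatter(xs, ys, s=14, label=cls, alpha=0.75)
    ax.axvline(rscc_min, color="gray", lw=0.8, ls="--")
    ax.axhline(rmsd_max, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("RSCC")
    ax.set_ylabel("r.m.s.d. to nearest class (Å)")
    ax.set_xlim(min(0.0, *(p.rscc for p in points)) if points else 0, 1.02)
    if len(classes) <= 12:
        ax.legend(fontsize=7, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
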