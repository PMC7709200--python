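# Methods

This note documents the models, the numerical choices and the limits of what
the test suite demonstrates.  Nothing here states an empirical result that
the tests or `scripts/acceptance.py` do not themselves compute.

## Step torsions and the 18-atom step

A dinucleotide step spans two consecutive nucleotides joined by an
O3′(i)–P(i+1) linkage; the covalent-linkage cutoff is 2.5 Å (the bond itself
is ≈1.6 Å; the slack tolerates low-resolution models).  The nine torsions
are δ(i), ε(i), ζ(i), α(i+1), β(i+1), γ(i+1), δ(i+1) and the glycosidic
χ(i), χ(i+1), with χ measured O4′–C1′–N9–C4 for purines and O4′–C1′–N1–C2
for pyrimidines.  Dihedrals follow the IUPAC sign convention (cis = 0°,
trans = 180°), range (−180°, 180°].

The 18 atoms that define a step's Cartesian geometry are the 8 of residue i
(C5′, C4′, C3′, O3′, O4′, C1′ and the two glycosidic anchors N9/C4 or
N1/C2) and the 10 of residue i+1 (the same plus P and O5′).  This list
supports all nine torsions, spans the backbone from C5′(i) to O3′(i+1), and
is exposed as a configurable catalog property (`STEP_ATOM_SPEC`) so an
alternative definition can be substituted.

Superposition is least-squares with a proper rotation (no reflections),
computed via `scipy.spatial.transform.Rotation.align_vectors` on centered
coordinates; the tests check it against an independent quaternion
(eigenvalue) implementation to 10⁻⁶ Å.

## The conformer catalog

The shipped catalog (`data/ntc_catalog.tsv`) holds 11 classes.  It is a
stand-in with explicit provenance, not a reproduction of the external
"golden set" that defines the published 96 conformer classes:

* **AA00 / BB00** are this package's calibrated A-form and B-form step
  torsion sets (below).  Because the synthetic builder uses exactly these
  values, generator output at zero noise re-assigns to its generating class
  with distance 0 — a designed identity, which the tests exploit.
* The other nine classes (AA08, AA06, AA10, AA11, AA12, BB01, BB07, BA05,
  AB01) are literature-informed offsets chosen to span the qualitative
  phenomena: the B-II ε/ζ crankshaft, unusual α/γ combinations with low or
  high β, and A/B mixed steps.  Their exact centroids are design constants,
  deliberately separated pairwise by ≥ 50° (aggregate circular distance) so
  that class recovery under realistic torsion noise is well-posed.

Assignment is nearest-centroid by circular Euclidean distance with equal
torsion weights.  Defaults: aggregate cutoff D_max = 100°, per-torsion cap
60°; both configurable.  Distance ties break to the lexicographically
smaller class name.  The goodness-of-fit score `100·exp(−(d/τ)²)` with
τ = 60° is a documented placeholder for the unpublished confal formula — it
shares only its range [0, 100], its value 100 at distance 0 and its strict
monotonicity.  The Cartesian r.m.s.d. to the nearest representative is
computed for every step including NANT ones, because a step can be
Cartesian-close to a class while failing the torsion criteria; this value is
the geometric axis of the scattergram.

Class representatives (the 18-atom coordinates) are generated at catalog
load by building a purine dinucleotide from the class centroid with the
internal-coordinate engine, which guarantees the representative reproduces
its centroid torsions (checked to 0.5°).

## The synthetic builder

**Geometry source.** Bond lengths, bond angles and auxiliary dihedrals are
harvested at run time from the ideal residue geometries of the chemical
component dictionary bundled with biotite (`biotite.structure.info.residue`:
DA, DC, DG, DT).  Backbone and sugar internal coordinates are taken from a
single reference residue (DG) for every base type, so that a strand built
with constant per-step torsions is an exact uniform helix for any sequence;
only the glycosidic attachment and the planar base templates are
residue-specific.  Bases are posed rigidly on three NeRF-placed anchors, so
the glycosidic χ is honoured exactly.

**Strands and duplexes.** A strand is built residue-by-residue by natural
extension (NeRF) from the torsion list; re-measuring its torsions returns
the input values to ≈10⁻⁶ degrees (round-trip identity, tested).  Because
repeated identical internal coordinates generate a screw symmetry, the
strand is an exact helix; its twist and rise are *implied* by the torsions
rather than imposed.  The duplex mate is the reverse complement built the
same way, placed by a twofold (dyad) rotation perpendicular to the helix
axis.  The two dyad parameters (phase and axial shift) are predicted from a
calibrated 4-mer by screw symmetry — phase shifts by −twist and height by
+rise per residue — then refined by least squares against the canonical
Watson–Crick hydrogen-bond targets (2.90 Å) and C1′–C1′ (10.4 Å).  Residual
worst-case H-bond error is ≲ 0.1 Å at any length (logged per build).

**Calibrated forms.** The A- and B-form torsion sets were fixed once by a
joint least-squares fit that started from fiber-model literature values,
held δ at the mid-range of its form (83° A, 135° B) and balanced three
terms: clean Watson–Crick geometry of the assembled duplex, closeness to the
literature torsions, and helical twist/rise near fiber values.  The result
(A: twist 28.5°, rise 2.52 Å; B: 34.3°, 3.37 Å) is close to, but not
identical with, textbook fiber parameters — the residual discrepancy is the
price of exact internal-coordinate consistency, and is documented rather
than hidden: `BuildSpec.rise/twist` report derived values and do not
re-shape the backbone.

**Mismatches.** At a mismatch position the same base is placed opposite
(T opposite T).  Its base ring is then re-posed by a minimal-displacement
rigid fit that enforces the two reciprocal hydrogen bonds of the symmetric
wobble pattern (N3···O4 / O4···N3 for antiparallel T–T, N3···O2 / O2···N3
for the parallel-strand variant) at 2.90 Å plus coplanarity with the partner
base, while moving the base as little as possible.  The sugar-phosphate
backbone stays on the helical path, so the glycosidic C1′–N1 attachment of
the re-posed base is stretched (≈3.6 Å instead of 1.47 Å) — an accepted
artificiality: pyrimidine–pyrimidine pairs are naturally narrower than the
Watson–Crick C1′–C1′ separation the ideal backbone dictates, and the ~2 Å
of slack has to be absorbed somewhere.  Geometry tests (pair detection,
edge/Saenger classification, orientation) are unaffected; energetic or
stereochemical realism is out of scope.  A Sr²⁺ cation can be placed at the
mismatch site, its position refined so the O4 coordination distances
approach 2.2–2.4 Å, emulating the major-groove metal site of T–T mismatched
duplexes.

**Torsion noise.** `perturb_torsions` adds independent wrapped-Gaussian
noise (σ in degrees) to every defined backbone/glycosidic torsion and
rebuilds each strand from its perturbed internal coordinates, superposing
the result back onto the original backbone.  σ = 0 returns an exact copy
(a rebuild would re-idealize planted mismatch bases); for mismatch-free
structures the rebuild path itself is exact to 10⁻¹³ Å, which the round-trip
tests verify.  All stochastic operations take an explicit seed and are
bit-reproducible.

**Fixture corpora.** Annotated mmCIF files are written with coordinates plus
an `ndb_struct_na_base_pair` loop (auth chain/seq ids, `hbond_type_28`,
`hbond_type_12`).  True codes are 19/20 for canonical pairs and 16 for the
planted T–T wobble; a configurable fraction of canonical pairs is
deliberately annotated with a noncanonical code.  The JSON manifest records
every planted truth, and the pipeline round-trip test requires
zero-discrepancy recovery of it.

**What passing tests do and do not show.** The generator produces idealized,
noise-controlled geometry: uniform helices, exact hydrogen-bond distances,
no solvent, no crystal packing, no refinement artefacts, single-Gaussian
density.  Passing tests therefore demonstrate the *correctness of the
algorithms* against known ground truth — not that thresholds are optimal for
deposited structures, where altlocs, chain breaks, modified residues and
genuinely ambiguous density occur.  The reader pointed at real data should
treat the detection thresholds (hydrogen-bond window 2.4–3.6 Å, planarity
65°, C1′–C1′ 8–12 Å) as tolerant defaults chosen for 2.6–2.9 Å-resolution
crystal structures, all configurable.

## Base-pair classification

Hydrogen-bond donors/acceptors are inferred from heavy-atom chemistry tables
(`data/edges.yaml`) since hydrogens are absent at the target resolutions.
Edges are decided by majority vote of the bonded atoms' edge memberships
(atoms at edge boundaries, e.g. pyrimidine O2 or purine O6/N6, belong to
every edge they can serve; ties prefer W over H over S).  Glycosidic
orientation is the sign of the C1′–N(glyc)···N(glyc)–C1′ pseudo-torsion
(|τ| ≤ 90° → cis).  The Leontis–Westhof family number is the standard 1–12
grid of (cis/trans) × (edge pair).  Saenger classes come from a shipped
lookup (`data/saenger.yaml`) keyed by the normalized hydrogen-bond atom
pattern, combo and orientation; the table covers the classes this package's
scope exercises (19, 20, 16, 12, 28) and returns *unclassified* for anything
else rather than guessing.  When several patterns match, the one requiring
more bonds wins; residual ties resolve to the earlier table entry (the
antiparallel wobble precedes the parallel variant deliberately).

`pair_self_duplex` is purely sequence-level: two copies of the sequence
annealed antiparallel, position i against L+1−i; segments are maximal runs
of canonical pairs, so the 18-mer reports [8, 8] around its two central
T–T records.  The odd-length center position is flagged a self-pair and
excluded from counts.

## Annotation mining

`hbond_type_28` tokens are compared as trimmed strings with leading-zero
normalization ("016" → "16"); 19/20/? mean canonical-or-unknown and
everything else is treated as an opaque noncanonical label (the full code
dictionary is not re-interpreted).  i–j/j–i duplicate listings collapse on
an order-normalized key.  The cross-check recomputes each annotated pair
from coordinates: `mislabeled-WC` when an annotated-noncanonical pair is
geometrically canonical Watson–Crick, `unresolvable` when the residues are
absent or form no hydrogen bond, `consistent` otherwise.  Strand orientation
is the sign of the dot product of local 5′→3′ C1′ chain-direction vectors.

## Density and the scattergram

Model density uses one isotropic Gaussian per atom, amplitude proportional
to electron count × occupancy and per-axis variance (B + b_floor)/(8π²) with
b_floor = 10 Å², wrapped periodically over the cell.  The single-Gaussian
profile is a documented simplification of multi-Gaussian atomic scattering
factors: adequate for correlation analysis, not for structure factors.  Map
synthesis and masking require orthorhombic cells (all synthetic maps are P1
orthorhombic); CCP4/MRC input with permuted axis order is canonicalized on
read.  RSCC is the Pearson correlation over voxels within 2.0 Å of the
supplied atoms; it is undefined (raises) on an empty mask or zero-variance
region, and is invariant under positive affine rescaling of either map.
Because the RSCC protocol (mask, grid, atom profile) is this package's own,
absolute RSCC values are comparable within this artifact, not across
programs.

Scattergram axes put RSCC increasing on x and r.m.s.d. increasing on y, so
the favourable region — good density fit *and* proximity to a known
conformer — is the lower-right rectangle.  Defaults: r.m.s.d. ≤ 1.0 Å
(geometry deviations beyond that are typically too large for automated
remediation) and RSCC ≥ 0.8 (no universal published value exists; the
threshold is configurable and recorded in every report).

## Symmetry expansion

Space-group operators (from the Hermann–Mauguin symbol via gemmi) combined
with lattice translations up to ±2 cells are applied in fractional
coordinates; images with any atom within the query radius of the input are
returned, labelled by operator triplet and integer shift, identity-at-zero-
shift excluded.  Partial-occupancy ions are included in contact searches
with their occupancy reported, since there is no principled reason to drop
them.

## Deposited structures

The three crystal structures that motivate the synthetic 18-mer system (an
18-mer strand per asymmetric unit, duplex generated by a crystallographic
twofold, P4₃2₁2) are supported through the same code paths — `read_structure`
on mmCIF/PDB, `expand_symmetry` to build the biological duplex and packing
contacts, `rmsd_structures` with shared-atom-name matching for
cross-sequence comparisons — but no deposited coordinates ship with the
package and the test suite runs entirely on generated data.  Cross-sequence
r.m.s.d. matches atoms by identical name within the same residue index and
drops the rest; that convention is the only well-defined way to compare all
heavy atoms of sequences that differ at a few positions.

## Known limitations

* The conformer catalog is an 11-class stand-in; class-by-class agreement
  with the published 96-class assignments is explicitly not claimed.
* The goodness-of-fit score is a placeholder formula.
* Sugar pseudorotation (phase/amplitude) and base-pair step parameters
  (roll/twist/slide) are out of scope.
* Mismatch planting stretches the glycosidic attachment of the re-posed
  base (see above).
* Density arithmetic is orthorhombic-only; non-orthogonal cells raise
  `NotImplementedError` rather than silently approximating.
* Saenger coverage is the five classes the scope exercises plus explicit
  *unclassified*; protonation-dependent classes are not modelled.
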