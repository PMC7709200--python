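# ntckit

Geometric analysis of DNA duplexes that carry mismatched (noncanonical) base
pairs: dinucleotide-step conformer assignment, base-pair detection with
Leontis–Westhof and Saenger classification, mining of base-pair annotations
from archival mmCIF files with a geometric cross-check, and a correlative
RSCC-vs-r.m.s.d. analysis of how well dinucleotide fragments fit both the
electron density and the known backbone conformations.

The package is aimed at structural biologists working with low-resolution
nucleic-acid crystal (or cryo-EM) structures — the regime where backbone
geometry is poorly determined by density alone and conformer-class
information becomes a practical refinement aid.  The model system throughout
is a near-palindromic CG-rich 18-mer, `GGTGGGGCTTGCCCCACC`, which
self-anneals into an A-form duplex of two 8-bp Watson–Crick segments
separated by two consecutive T–T mismatches.

## What it computes

**Step conformers.** A DNA chain is dissected into dinucleotide steps (one
per covalently linked pair of residues, O3′–P ≤ 2.5 Å).  Each step is
summarised by nine torsions — δ, ε, ζ of the first residue, α, β, γ, δ of the
second, and both glycosidic χ — and assigned to the nearest class of a
conformer catalog by circular Euclidean distance, with an aggregate cutoff
(100° by default) and a per-torsion cap (60°); steps failing either fall back
to the NANT ("not assigned") class.  A goodness-of-fit score
`100·exp(−(d/60°)²)` and the Cartesian r.m.s.d. of the 18 step-defining atoms
to the nearest class representative accompany every assignment, and assigned
steps can be exported as nine-torsion restraint records for use in
refinement.

**Base pairs.** Pairs are detected from geometry alone (donor–acceptor
contacts at 2.4–3.6 Å, base planes within 65°, C1′–C1′ at 8–12 Å, at least
two hydrogen bonds) and classified by interacting edge (Watson–Crick /
Hoogsteen / sugar), glycosidic orientation (cis/trans), Leontis–Westhof
family 1–12 and Saenger class.  Canonical means cis W/W G–C (Saenger 19) or
A–T (Saenger 20); the wobble-type T–T pair of antiparallel duplexes is
Saenger 16, its parallel-strand variant 12.

**Annotation mining.** The `ndb_struct_na_base_pair.hbond_type_28` category
of mmCIF files is parsed; records whose code is not 19/20/? are treated as
annotated-noncanonical, re-classified from coordinates, and flagged
`mislabeled-WC` when the geometry is actually a canonical Watson–Crick pair.
Incidences are tabulated by base combination × strand orientation.

**Density fit.** Model density is a sum of isotropic Gaussians (amplitude ∝
electron count, variance (B+b_floor)/8π²); RSCC is the Pearson correlation
of observed vs model density over voxels within 2 Å of the 18 step atoms.
The scattergram of RSCC (x) against r.m.s.d.-to-nearest-class (y) labels
each step `good`, `poor-density`, `poor-geometry` or `poor-both` with
thresholds RSCC ≥ 0.8 and r.m.s.d. ≤ 1.0 Å.

**Synthetic data.** All of the above is exercised on generated ground truth:
ideal A/B-form duplexes built from internal coordinates with exactly known
step torsions, planted mismatches with the wobble hydrogen-bond pattern,
wrapped-Gaussian torsion noise with downstream coordinate rebuild, Gaussian
density maps with seeded noise, and annotated mmCIF corpora with a manifest
of planted truths (including deliberate mislabelings).

## Worked example

```python
from ntckit.basepair import find_pairs, pair_self_duplex
from ntckit.ntc_assign import annotate_structure
from ntckit.structure_io import count_heavy_atoms
from ntckit.synthetic import BuildSpec, build_duplex

seq = "GGTGGGGCTTGCCCCACC"
print(pair_self_duplex(seq).segments)   # [8, 8]   two WC segments
print(count_heavy_atoms(seq))           # 365      heavy atoms per strand

duplex = build_duplex(BuildSpec(sequence=seq, form="A",
                                mismatch_positions=(9, 10),
                                add_central_ion=True))
pairs = find_pairs(duplex)
print(len(pairs), sum(p.canonical for p in pairs))   # 18 16
tt = next(p for p in pairs if p.combo == "T-T")
print(tt.lw_class, tt.saenger, tt.strand_orientation)  # 1 16 antiparallel

steps, summary = annotate_structure(duplex)
print(summary)  # {'n_steps': 34, 'n_assigned': 34, 'n_outliers': 0}
```

The printed numbers read: the sequence self-anneals into two 8-pair
Watson–Crick segments flanking two central T–T mismatches; one strand has
365 non-hydrogen atoms; all 18 base pairs of the built duplex are recovered
geometrically (16 canonical, 2 T–T classified Leontis–Westhof family 1 /
Saenger 16 in antiparallel strands); and all 34 dinucleotide steps assign to
the A-form conformer class with no outliers.

The same pipeline is available from the shell:

```sh
ntckit simulate --form A --mismatch 9 --mismatch 10 --ion --map -o out/
ntckit annotate out/synthetic_A_duplex.cif -o out/ann
ntckit pairs    out/synthetic_A_duplex.cif -o out/pairs
ntckit scatter  out/synthetic_A_duplex.cif out/synthetic_A_duplex.ccp4 -o out/scatter
```

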