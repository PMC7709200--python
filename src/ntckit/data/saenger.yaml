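# Saenger base-pair classes recognised by ntckit.
#
# Each entry is matched against the geometrically detected hydrogen-bond
# set of a pair.  A bond is written "X.atom1-Y.atom2" where X/Y are the
# parent-base letters of the two nucleotides in alphabetical order of
# (base letter); for same-base pairs the two directions of a symmetric
# bond are written explicitly.  An entry matches when all bonds in
# `required` are present; among several matches the one with the most
# required bonds wins.  `glyc` restricts the match to cis or trans
# glycosidic orientation when given.
#
# Coverage: the canonical Watson-Crick classes (19 G-C, 20 A-T), the
# T-T/U-U wobble classes seen in antiparallel (16) and parallel (12)
# duplex contexts, and the common G-T wobble (28).  Unknown patterns are
# reported as unclassified rather than guessed.
classes:
  - saenger: 19
    combo: [C, G]
    glyc: cis
    required: ["G.N1-C.N3", "G.O6-C.N4"]
    lw_edges: [W, W]
  - saenger: 19
    combo: [C, G]
    glyc: cis
    required: ["G.N1-C.N3", "G.N2-C.O2"]
    lw_edges: [W, W]
  - saenger: 20
    combo: [A, T]
    glyc: cis
    required: ["A.N1-T.N3", "A.N6-T.O4"]
    lw_edges: [W, W]
  - saenger: 20
    combo: [A, U]
    glyc: cis
    required: ["A.N1-U.N3", "A.N6-U.O4"]
    lw_edges: [W, W]
  - saenger: 16
    combo: [T, T]
    glyc: cis
    required: ["T.N3-T.O4", "T.O4-T.N3"]
    lw_edges: [W, W]
  - saenger: 16
    combo: [U, U]
    glyc: cis
    required: ["U.N3-U.O4", "U.O4-U.N3"]
    lw_edges: [W, W]
  - saenger: 12
    combo: [T, T]
    required: ["T.N3-T.O2", "T.O2-T.N3"]
    lw_edges: [W, W]
  - saenger: 12
    combo: [U, U]
    required: ["U.N3-U.O2", "U.O2-U.N3"]
    lw_edges: [W, W]
  - saenger: 28
    combo: [G, T]
    glyc: cis
    required: ["G.O6-T.N3", "G.N1-T.O2"]
    lw_edges: [W, W]
  - saenger: 28
    combo: [G, U]
    glyc: cis
    required: ["G.O6-U.N3", "G.N1-U.O2"]
    lw_edges: [W, W]
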