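# Base-edge membership and hydrogen-bonding chemistry of the nucleobases.
#
# edges: which Leontis-Westhof interacting edge (W = Watson-Crick,
# H = Hoogsteen, S = sugar) each polar/ring atom can serve.  Atoms that sit
# at an edge boundary (e.g. pyrimidine O2, purine N6/O6) are listed on every
# edge they can serve; pair-edge classification votes over the atoms that
# actually form hydrogen bonds, preferring W over H over S on ties.
#
# donors/acceptors: heavy-atom hydrogen-bond roles inferred from base
# chemistry (structures without modelled hydrogens are the norm at the
# resolutions this package targets).
edges:
  A:
    W: [N1, N6, C2]
    H: [N6, N7, C5]
    S: [N3, C2]
  G:
    W: [N1, N2, O6]
    H: [O6, N7]
    S: [N2, N3]
  C:
    W: [N3, N4, O2]
    H: [N4, C5]
    S: [O2]
  T:
    W: [N3, O4, O2]
    H: [O4, C7]
    S: [O2]
  U:
    W: [N3, O4, O2]
    H: [O4, C5]
    S: [O2]
donors:
  A: [N6]
  G: [N1, N2]
  C: [N4]
  T: [N3]
  U: [N3]
acceptors:
  A: [N1, N3, N7]
  G: [O6, N3, N7]
  C: [O2, N3]
  T: [O2, O4]
  U: [O2, O4]
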