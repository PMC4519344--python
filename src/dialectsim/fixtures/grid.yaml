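# Grid: 3x3 lattice of equal-population dialects (spatially non-tree-like).
# Row-major layout A B C / D E F / G H I; E is the centre; rook adjacency.
# Lattice spacing 2.0 keeps neighbour coupling weak enough that innovations
# survive locally and the conflicting grid geometry shows in the distances.
nodes:
  - {id: A, population: 1.0}
  - {id: B, population: 1.0}
  - {id: C, population: 1.0}
  - {id: D, population: 1.0}
  - {id: E, population: 1.0}
  - {id: F, population: 1.0}
  - {id: G, population: 1.0}
  - {id: H, population: 1.0}
  - {id: I, population: 1.0}
edges:
  - {i: A, j: B, distance: 2.0}
  - {i: B, j: C, distance: 2.0}
  - {i: D, j: E, distance: 2.0}
  - {i: E, j: F, distance: 2.0}
  - {i: G, j: H, distance: 2.0}
  - {i: H, j: I, distance: 2.0}
  - {i: A, j: D, distance: 2.0}
  - {i: D, j: G, distance: 2.0}
  - {i: B, j: E, distance: 2.0}
  - {i: E, j: H, distance: 2.0}
  - {i: C, j: F, distance: 2.0}
  - {i: F, j: I, distance: 2.0}
params: {s: 4.0, b: 1.0, d: 3.0, T: 1000, n_concepts: 100}
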