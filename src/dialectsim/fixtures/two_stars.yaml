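# TwoStars: two large centres A and B, each with four exclusive peripheries,
# plus nodes H and K that are equidistant from the two centres.  Short spokes
# (0.675) keep each centre dominant over its own peripheries; the high birth
# score (b=1.0) still feeds in fresh variation.
nodes:
  - {id: A, population: 10.0}
  - {id: B, population: 10.0}
  - {id: C, population: 1.0}
  - {id: D, population: 1.0}
  - {id: E, population: 1.0}
  - {id: F, population: 1.0}
  - {id: G, population: 1.0}
  - {id: I, population: 1.0}
  - {id: J, population: 1.0}
  - {id: L, population: 1.0}
  - {id: H, population: 1.0}
  - {id: K, population: 1.0}
edges:
  - {i: A, j: B, distance: 2.0}
  - {i: A, j: C, distance: 0.675}
  - {i: A, j: D, distance: 0.675}
  - {i: A, j: E, distance: 0.675}
  - {i: A, j: F, distance: 0.675}
  - {i: B, j: G, distance: 0.675}
  - {i: B, j: I, distance: 0.675}
  - {i: B, j: J, distance: 0.675}
  - {i: B, j: L, distance: 0.675}
  - {i: A, j: H, distance: 0.675}
  - {i: B, j: H, distance: 0.675}
  - {i: A, j: K, distance: 0.675}
  - {i: B, j: K, distance: 0.675}
params: {s: 2.0, b: 1.0, d: 3.0, T: 1000, n_concepts: 100}
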