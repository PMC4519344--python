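# Star: a politico-cultural centre A (large population) surrounded by eight
# small peripheries; spokes only, no periphery-periphery contact.  Half the
# peripheries sit closer to the centre (2.25), half further out (2.75):
# the near ones stay anchored to the centre's lexicon while the far ones
# innovate, which keeps the network's overall diversity away from the
# all-or-nothing extremes.
nodes:
  - {id: A, population: 10.0}
  - {id: B, population: 1.0}
  - {id: C, population: 1.0}
  - {id: D, population: 1.0}
  - {id: E, population: 1.0}
  - {id: F, population: 1.0}
  - {id: G, population: 1.0}
  - {id: H, population: 1.0}
  - {id: I, population: 1.0}
edges:
  - {i: A, j: B, distance: 2.25}
  - {i: A, j: C, distance: 2.25}
  - {i: A, j: D, distance: 2.25}
  - {i: A, j: E, distance: 2.25}
  - {i: A, j: F, distance: 2.75}
  - {i: A, j: G, distance: 2.75}
  - {i: A, j: H, distance: 2.75}
  - {i: A, j: I, distance: 2.75}
params: {s: 2.0, b: 0.1, d: 3.0, T: 1000, n_concepts: 100}
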