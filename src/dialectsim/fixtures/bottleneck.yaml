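# Bottleneck: a western cluster A-E and an eastern cluster F-G-H joined only
# by a single bridge edge, mimicking a branching event with residual contact.
# The west is organised around a regional hub C; E sits slightly apart from
# the core, carries the bridge, and is therefore closest to the eastern
# group, which itself is a tight triangle.
nodes:
  - {id: A, population: 1.0}
  - {id: B, population: 1.0}
  - {id: C, population: 5.0}
  - {id: D, population: 1.0}
  - {id: E, population: 1.0}
  - {id: F, population: 1.0}
  - {id: G, population: 1.0}
  - {id: H, population: 1.0}
edges:
  - {i: C, j: A, distance: 1.75}
  - {i: C, j: B, distance: 1.75}
  - {i: C, j: D, distance: 1.75}
  - {i: C, j: E, distance: 2.0}
  - {i: F, j: G, distance: 1.0}
  - {i: G, j: H, distance: 1.0}
  - {i: F, j: H, distance: 1.0}
  - {i: E, j: F, distance: 2.0}
params: {s: 4.0, b: 0.1, d: 3.0, T: 1000, n_concepts: 100}
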