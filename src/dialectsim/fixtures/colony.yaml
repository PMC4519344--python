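# Colony: a bottleneck-style layout (western ring A-C-D-E, eastern ring
# F..K, single long E-F bridge) run for 750 steps, after which node B -- a
# large colony of the western dialect group -- is copied from node A and
# placed among the eastern nodes for the remaining 250 steps.  B's moderate
# ties (distance 2.0) to every eastern node leave the east only partially
# converted by step 1000, blurring the two dialect groups.
nodes:
  - {id: A, population: 1.0}
  - {id: C, population: 1.0}
  - {id: D, population: 1.0}
  - {id: E, population: 1.0}
  - {id: F, population: 1.0}
  - {id: G, population: 1.0}
  - {id: H, population: 1.0}
  - {id: I, population: 1.0}
  - {id: J, population: 1.0}
  - {id: K, population: 1.0}
edges:
  - {i: A, j: C, distance: 1.5}
  - {i: C, j: D, distance: 1.5}
  - {i: D, j: E, distance: 1.5}
  - {i: E, j: A, distance: 1.5}
  - {i: F, j: G, distance: 1.5}
  - {i: G, j: H, distance: 1.5}
  - {i: H, j: I, distance: 1.5}
  - {i: I, j: J, distance: 1.5}
  - {i: J, j: K, distance: 1.5}
  - {i: K, j: F, distance: 1.5}
  - {i: E, j: F, distance: 3.0}
events:
  - kind: copy_node
    time: 750
    source: A
    target: B
    target_population: 10.0
    new_edges:
      - {neighbor: F, distance: 2.0}
      - {neighbor: G, distance: 2.0}
      - {neighbor: H, distance: 2.0}
      - {neighbor: I, distance: 2.0}
      - {neighbor: J, distance: 2.0}
      - {neighbor: K, distance: 2.0}
params: {s: 4.0, b: 0.1, d: 3.0, T: 1000, n_concepts: 100}
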