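# dialectsim

Contact-based simulation of dialect lexicon evolution on spatial networks,
with quartet-based tree-likeness analysis of the resulting data.

## The problem

Phylogenetic methods model the history of languages (or any cultural traits)
as a series of branching events. For groups of dialects that stay in
constant contact this assumption is questionable: innovations spread
wave-like through space from influential centres, without any lineage ever
splitting. `dialectsim` is for researchers who want to probe this gap: it
generates basic-vocabulary data from an explicitly *spatial, non-branching*
process and then asks how tree-like the synthetic data look to standard
distance-based diagnostics — and exports them for split-network and
Bayesian phylogenetic tools.

## The model

Dialects are nodes of a weighted contact network. Node *i* has population
*p<sub>i</sub>*; an edge (*i*, *j*) has distance *d<sub>ij</sub>*. The
influence of *j* on *i* is

    w_ij = p_j / d_ij²   if j ∈ N_i,
    w_ii = s·p_i,        (self-influence)
    w_ij = 0             otherwise.

For each basic-vocabulary concept, node *i* holds a non-empty set
*V<sub>i</sub><sup>t</sup>* of cognates. All nodes start from one shared
cognate. At each step every node draws its next set from the candidate pool
*C<sub>i</sub><sup>t</sup>* = {new word} ∪ ⋃<sub>j∈{i}∪N_i</sub>
*V<sub>j</sub><sup>t−1</sup>*, where each candidate scores

    wscore(c) = Σ_{j holds c} w_ij / |V_j^{t−1}|     (existing cognate)
    wscore(new word) = b·p_i,

a set *v* scores sscore(*v*) = Σ<sub>c∈v</sub> wscore(c) − d·|v|², and the
next set is drawn with probability ∝ exp(sscore(*v*)) over the non-empty
power set of the pool (sampled exactly, via the elementary-symmetric-
polynomial factorization — no enumeration). Words born once can spread,
die, and never revive. After *T* steps the per-concept snapshots are encoded
as a binary taxa × cognates matrix, pairwise distances are the ratio of
mismatching digits, and tree-likeness is summarized by the δ score: for
each quartet of taxa sort the three pairings of distance sums
s₁ ≤ s₂ ≤ s₃ and take (s₃−s₂)/(s₃−s₁), averaged over all C(n,4) quartets.
δ = 0 means perfectly additive (tree-like) distances.

Five fixture networks ship with the package: `grid` (3×3 lattice), `star`
(one dominant centre), `two_stars` (two centres with shared border nodes),
`bottleneck` (two clusters, one bridge) and `colony` (a node copied into
the opposite cluster mid-run — the only genuine branching event in any
fixture).

## Worked example

```python
from dialectsim import (fixture_topology, run_simulation, encode_binary,
                        distance_matrix, delta_score)

topo, params = fixture_topology("bottleneck")
result = run_simulation(topo, params.with_overrides(seed=1))
matrix = encode_binary(result)          # taxa x binary characters
dm = distance_matrix(matrix)            # Hamming-ratio distances
print(matrix.n_taxa, "taxa,", matrix.n_chars, "characters")
print("delta =", round(delta_score(dm).mean_delta, 3))
```

prints

```
8 taxa, 186 characters
delta = 0.138
```

— after 1000 steps the eight dialects hold 186 surviving cognates across
100 concepts, and the low δ (≈ 0.14) says the two bridged clusters produce
rather tree-like distances even though no lineage ever split. Running the
`grid` fixture the same way gives δ ≈ 0.44: lattice-style contact produces
distinctly non-tree-like data. The `examples/` directory has one short
script per capability (simulation, δ scores, survival times, NEXUS/PHYLIP
export, custom topologies), and the same workflow is available from the
shell:

```bash
dialectsim experiment --config bottleneck --replicates 20 --seed 1 --out runs/bn
dialectsim fixtures list
```

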