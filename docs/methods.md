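# Methods

## Model

`dialectsim` implements a discrete-time Markov chain of cognate evolution on
a spatial contact network. Each node is a dialect; for each concept in a
basic-vocabulary list it holds a non-empty set of cognates. There is no
tree: all structure in the data arises from contact.

**Influence.** Node *j* influences node *i* with weight
w<sub>ij</sub> = p<sub>j</sub>/d<sub>ij</sub>² for neighbours,
w<sub>ii</sub> = s·p<sub>i</sub> for the node itself, 0 otherwise.
Population enters linearly, distance quadratically; the matrix is
asymmetric whenever populations differ, which is what lets centres dominate
peripheries.

**Update.** The update is synchronous: at step t every node builds its
candidate pool from the t−1 snapshot only (its own set, its neighbours'
sets, and one fresh new-word token), scores each candidate by
wscore(c) = Σ<sub>j∈M</sub> w<sub>ij</sub>/|V<sub>j</sub><sup>t−1</sup>|
(where M is the set of neighbours-plus-self holding c), scores the new word
b·p<sub>i</sub>, and draws its next set v with probability
∝ exp(Σ<sub>c∈v</sub> wscore(c) − d·|v|²). Dividing by
|V<sub>j</sub><sup>t−1</sup>| makes a node holding many synonyms push each
one less hard; the d·|v|² term (d > 1) is a soft cap on synonym sets, so
sets of size one or two dominate in practice.

**Birth and death.** A new-word token is materialized (recorded as a birth)
only if the sampled set contains it; a rejected token is never re-offered,
so every cognate is born exactly once. A cognate absent from every node is
dead and cannot revive — candidates are unions of surviving sets — and its
death step is recorded. The registry therefore reconstructs every word's
lifespan exactly.

**Assumptions worth keeping in mind.** Dialects, not speakers, are the
agents; every dialect always has at least one word per concept; external
borrowings are folded into births; a cognate cannot be re-created by
parallel innovation. Concepts evolve independently given the network.

## Exact subset sampling

The next-set distribution lives on the 2<sup>n</sup>−1 non-empty subsets of
the candidate pool. It is never enumerated during simulation. Because
P(v) ∝ exp(Σ<sub>c∈v</sub> wscore(c))·exp(−d|v|²), the size |v| = k is
drawn first with weight e<sub>k</sub>(x₁…x<sub>n</sub>)·exp(−dk²), where
x<sub>c</sub> = exp(wscore(c)) and e<sub>k</sub> is the k-th elementary
symmetric polynomial, and a k-subset is then drawn with probability
∝ Π x<sub>c</sub> by the standard sequential-inclusion recursion over
suffix polynomials. Both stages are exact, so the sampler's law equals the
brute-force enumeration (`subset_distribution`, capped at 15 candidates)
used as the oracle in tests. Scores are max-shifted before exponentiation
and the size weights assembled in log space, so wscores of several hundred
(large populations) cannot overflow.

## From snapshots to characters

Only the final snapshot is encoded — the field-study analogy: dialectology
records current distributions, not histories. One binary column per cognate
that survives to T, grouped by concept, ordered by (concept, birth step,
id) for determinism. Distances are Hamming mismatches divided by the total
number of columns, jointly over all concepts. Survival times (death −
birth) exclude the shared initial cognate and words still alive at T,
whose lifespans are censored.

## The δ score

For a quartet {x, y, u, v} the three pairings of distance sums are sorted,
s₁ ≤ s₂ ≤ s₃, and the quartet scores (s₃−s₂)/(s₃−s₁) ∈ [0, 1]; on an
additive (tree) metric s₂ = s₃ and the score is 0. A triple tie (star
metric) is scored 0 by convention, detected with relative tolerance 1e−9.
Partial ties need no special casing — the formula already yields 0 or is
well defined. The overall δ is the mean over all C(n,4) quartets
(exhaustive by default; a seeded uniform subsample without replacement is
available for large n, and recovers the exhaustive set when k = C(n,4)).
Per-taxon means are also reported, as is standard practice for this
statistic.

## RNG discipline

A master seed spawns one substream per concept (`numpy.SeedSequence` →
`random.Random`), nodes are updated in declared topology order, and every
artifact records its resolved seed. Identical (topology, params, seed)
triples reproduce results bit-for-bit, and concept-level results do not
depend on the order concepts are evaluated in.

## Fixture networks and calibration

The five fixtures encode qualitative spatial scenarios: `grid` a uniform
lattice, `star` a dominant centre, `two_stars` two centres with two shared
border nodes (H and K, equidistant from both), `bottleneck` two clusters
joined by a single bridge carried by node E, `colony` a bottleneck-style
pair of clusters where after 750 of 1000 steps a high-population node B is
copied from western node A and wired into the eastern cluster. A copy
event at step t acts on the snapshot at t: B starts with an exact copy of
A's cognate sets and participates in every later update.

Node populations and edge distances are calibration choices (only the
scenario structure and the per-fixture hyperparameters s, b, d are fixed
a priori): they were chosen so that each scenario expresses its intended
regime rather than collapsing into one of the two degenerate extremes this
dynamics is prone to — total homogenization (δ → 0 through exact ties) or
birth-noise domination (δ ≈ 0.4+ regardless of structure). Concretely:
grid spacing 2.0 keeps neighbour coupling weak enough that innovations
survive locally; star peripheries sit at mixed distances (four at 2.25,
four at 2.75) so part of the network stays anchored while part innovates;
two_stars uses short spokes (0.675) so each centre dominates its own
cluster; bottleneck organises the west around a hub (C, population 5) with
E semi-detached towards the bridge, making within-cluster distances
approximately additive; colony uses moderate ties (2.0) from B to all six
eastern nodes so that 250 steps only partially convert the east — the
partial conversion is precisely what blurs the two dialect groups. The
resulting replicate-mean δ scores are approximately 0.15 (bottleneck) <
0.20 (two_stars) < 0.28 (star) < 0.32 (colony) < 0.44 (grid).

Monte-Carlo spread differs strongly between fixtures: per-run standard
deviations are ≈ 0.02 for grid and two_stars but ≈ 0.09 for star, whose
diversity level sits nearest the homogenization transition. Replicated
runs therefore use more replicates for star and colony (up to 30) than for
the stable fixtures (12–20); the replicate counts are a precision budget,
not a model parameter.

## What the generator does and does not emulate

The synthetic data reproduce the structural signature of contact-driven
lexical evolution: concept-grouped binary characters, coexisting synonyms,
a large excess of short-lived words under a long survival tail, and
distance matrices whose tree-likeness tracks the spatial topology.
They do not emulate real-data complications: cognate misidentification,
semantic shift re-creating a lost cognate, borrowing the same word twice,
missing data, or concept-dependent replacement rates. Tests passing on
these data show that the pipeline measures what the model produces — not
that any particular real dialect group evolved this way.

## Numerical and design choices

- Sets are Python frozensets of integer cognate ids; matrices are numpy
  uint8; distance matrices float64.
- The enumeration cap (15 candidates) bounds the oracle's 2<sup>n</sup>−1
  subsets; the factorized sampler has no cap. Candidate pools in fixture
  runs stay far below the cap.
- δ tie tolerance 1e−9 (relative); quartet unranking uses the
  combinatorial number system so subsampling never materializes the full
  quartet list.
- T = 1000 steps and 100 concepts are the study conditions and the package
  defaults; examples that only illustrate APIs use smaller runs and say so.
- NEXUS export writes standard data with symbols "01" and one CHARSET per
  concept; labels with reserved characters are single-quoted. Round-trips
  are verified against an independent reader (dendropy).

## Known limitations

- The survival-time distribution's bulk is extremely short-lived (median
  ≈ 2 steps in the star fixture): the 90th percentile sits at ≈ 5 steps,
  so ratio-based tail summaries (e.g. "most words live ≥5× shorter than
  the 90th percentile") are at the mercy of integer granularity.
- δ scores of fixtures near the homogenization transition (star above all)
  have heavy replicate-to-replicate spread; single-run δ values are not
  meaningful to two decimals for those topologies.
- The model has no mechanism for prestige asymmetries beyond population,
  no speaker-level variation, and no time-varying populations or distances
  (only discrete copy events).
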