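"""Candidate sets, scores, exact subset sampling and network updates."""

import math
from collections import Counter
from random import Random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dialectsim import (
    CognateRegistry,
    NetworkState,
    SimParams,
    candidate_set,
    cognate_score,
    influence_weights,
    make_topology,
    run_concept,
    run_simulation,
    sample_subset,
    set_score,
    step_network,
    subset_distribution,
)
from dialectsim.dynamics import ENUMERATION_CAP, _sample_indices


def _registry_with(n: int) -> CognateRegistry:
    reg = CognateRegistry()
    for _ in range(n):
        reg.register_birth(None, 0)
    return reg


class TestCandidateSet:
    def test_union_of_self_and_neighbours_plus_new_token(self, pair_topology):
        reg = _registry_with(1)
        state = NetworkState(0, {"A": frozenset({0}), "B": frozenset({0})})
        cand = candidate_set(
            state, "A", pair_topology, reg, params=SimParams(s=1.0, b=1.0, d=3.0)
        )
        assert cand.cognates == frozenset({0, cand.new_word})
        assert cand.new_word not in state.V["A"]

    def test_distinct_neighbour_sets_all_contribute(self, triangle_topology):
        reg = _registry_with(3)
        state = NetworkState(
            0,
            {"A": frozenset({0}), "B": frozenset({1}), "C": frozenset({0, 2})},
        )
        cand = candidate_set(
            state, "A", triangle_topology, reg, params=SimParams(s=1.0, b=1.0, d=3.0)
        )
        assert cand.cognates == frozenset({0, 1, 2, cand.new_word})

    def test_isolated_node_sees_only_itself(self):
        topo = make_topology([("A", 1.0)], [])
        reg = _registry_with(1)
        state = NetworkState(0, {"A": frozenset({0})})
        cand = candidate_set(
            state, "A", topo, reg, params=SimParams(s=1.0, b=1.0, d=3.0)
        )
        assert cand.cognates == frozenset({0, cand.new_word})

    def test_unknown_node_rejected(self, pair_topology):
        reg = _registry_with(1)
        state = NetworkState(0, {"A": frozenset({0}), "B": frozenset({0})})
        with pytest.raises(KeyError):
            candidate_set(
                state, "Z", pair_topology, reg, params=SimParams(s=1.0, b=1.0, d=3.0)
            )


class TestCognateScore:
    def test_single_neighbour_term(self):
        # c held only by neighbour j: w_ij / |V_j| = 1.0 / 2
        topo = make_topology([("A", 1.0), ("B", 1.0)], [("A", "B", 1.0)])
        params = SimParams(s=0.0, b=1.0, d=3.0)
        w = influence_weights(topo, params.s)
        state = NetworkState(0, {"A": frozenset({9}), "B": frozenset({0, 1})})
        assert cognate_score(0, "A", state, w, params, topo) == pytest.approx(0.5)

    def test_self_and_neighbour_terms_sum(self):
        # held by i (w_ii=2, |V_i|=1) and neighbour j (w_ij=1, |V_j|=1)
        topo = make_topology([("A", 1.0), ("B", 1.0)], [("A", "B", 1.0)])
        params = SimParams(s=2.0, b=1.0, d=3.0)
        w = influence_weights(topo, params.s)
        state = NetworkState(0, {"A": frozenset({0}), "B": frozenset({0})})
        assert cognate_score(0, "A", state, w, params, topo) == pytest.approx(3.0)

    def test_new_word_scores_b_times_population(self):
        topo = make_topology([("A", 10.0)], [])
        params = SimParams(s=1.0, b=0.1, d=3.0)
        w = influence_weights(topo, params.s)
        state = NetworkState(0, {"A": frozenset({0})})
        assert cognate_score(
            99, "A", state, w, params, topo, is_new_word=True
        ) == pytest.approx(1.0)

    def test_non_candidate_rejected(self, pair_topology):
        params = SimParams(s=1.0, b=1.0, d=3.0)
        w = influence_weights(pair_topology, params.s)
        state = NetworkState(0, {"A": frozenset({0}), "B": frozenset({0})})
        with pytest.raises(ValueError, match="not a candidate"):
            cognate_score(42, "A", state, w, params, pair_topology)


class TestSetScore:
    @pytest.mark.parametrize(
        "scores, subset, expected",
        [
            ({1: 2.0}, [1], -1.0),  # 2 - 3*1
            ({1: 2.0, 2: 1.0}, [1, 2], -9.0),  # 3 - 3*4
            ({1: 0.0, 2: 0.0, 3: 0.0}, [1, 2, 3], -27.0),  # -3*9
        ],
    )
    def test_score_minus_quadratic_cardinality_cost(self, scores, subset, expected):
        assert set_score(subset, scores, d=3.0) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            set_score([], {1: 1.0}, d=3.0)


class TestSubsetDistribution:
    def test_single_candidate_is_certain(self):
        dist = subset_distribution({7: 0.3}, d=3.0)
        assert dist == {frozenset({7}): 1.0}

    def test_two_candidate_softmax(self):
        # sscores: {1} -> -1, {2} -> -2, {1,2} -> -9
        dist = subset_distribution({1: 2.0, 2: 1.0}, d=3.0)
        z = math.exp(-1) + math.exp(-2) + math.exp(-9)
        assert dist[frozenset({1})] == pytest.approx(math.exp(-1) / z)
        assert dist[frozenset({2})] == pytest.approx(math.exp(-2) / z)
        assert dist[frozenset({1, 2})] == pytest.approx(math.exp(-9) / z, rel=1e-9)
        assert dist[frozenset({1})] == pytest.approx(0.7309, abs=1e-4)
        assert dist[frozenset({2})] == pytest.approx(0.2689, abs=1e-4)

    def test_equal_scores_give_symmetric_probabilities(self):
        dist = subset_distribution({1: 0.8, 2: 0.8}, d=2.0)
        assert dist[frozenset({1})] == pytest.approx(dist[frozenset({2})])

    @given(
        st.lists(st.floats(-30, 60), min_size=1, max_size=6),
        st.floats(1.01, 10.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_probabilities_sum_to_one(self, scores, d):
        dist = subset_distribution(dict(enumerate(scores)), d)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert len(dist) == 2 ** len(scores) - 1
        assert all(p >= 0 for p in dist.values())

    def test_enumeration_cap_enforced(self):
        scores = {i: 0.0 for i in range(ENUMERATION_CAP + 1)}
        with pytest.raises(ValueError, match="enumeration cap"):
            subset_distribution(scores, d=3.0)


def _total_variation(empirical: Counter, exact: dict, n: int) -> float:
    keys = set(empirical) | set(exact)
    return 0.5 * sum(abs(empirical[k] / n - exact.get(k, 0.0)) for k in keys)


class TestSampleSubset:
    def test_single_candidate_always_returned(self):
        rng = Random(0)
        assert all(
            sample_subset({5: -2.0}, 3.0, rng) == frozenset({5}) for _ in range(20)
        )

    @pytest.mark.parametrize(
        "scores",
        [
            {1: 2.0, 2: 1.0},
            {1: 0.0, 2: 0.0, 3: 0.0},
            {1: 3.0, 2: -1.0, 3: 1.5, 4: 0.2},
            {i: 0.4 * i for i in range(6)},  # forces the factorized path scale
        ],
    )
    def test_matches_enumeration_oracle(self, scores):
        exact = subset_distribution(scores, d=3.0)
        rng = Random(1234)
        n = 20_000
        counts = Counter(sample_subset(scores, 3.0, rng) for _ in range(n))
        assert _total_variation(counts, exact, n) < 0.02

    def test_large_scores_do_not_overflow(self):
        rng = Random(5)
        scores = {1: 500.0, 2: 499.0, 3: -200.0}
        counts = Counter(sample_subset(scores, 3.0, rng) for _ in range(2000))
        # sscore({1,2}) = 999 - 12 dwarfs every set containing candidate 3
        assert counts[frozenset({1, 2})] == 2000
        assert frozenset({3}) not in counts

    def test_size_conditional_distribution_is_shift_invariant(self):
        # adding a constant to every wscore cancels within a fixed size |v|
        base = {1: 1.0, 2: 0.2, 3: -0.5}
        shifted = {c: w + 7.0 for c, w in base.items()}

        def conditional(dist, k):
            sub = {v: p for v, p in dist.items() if len(v) == k}
            z = sum(sub.values())
            return {v: p / z for v, p in sub.items()}

        d_base = subset_distribution(base, 3.0)
        d_shift = subset_distribution(shifted, 3.0)
        for k in (1, 2, 3):
            cb, cs = conditional(d_base, k), conditional(d_shift, k)
            for v in cb:
                assert cb[v] == pytest.approx(cs[v], rel=1e-9)
        # but the size marginals themselves do move under the shift
        p1_base = sum(p for v, p in d_base.items() if len(v) == 1)
        p1_shift = sum(p for v, p in d_shift.items() if len(v) == 1)
        assert p1_base != pytest.approx(p1_shift)

    def test_raising_a_score_raises_its_marginal(self):
        # checked by enumeration on 3 candidates
        def marginal(scores, c):
            return sum(
                p for v, p in subset_distribution(scores, 3.0).items() if c in v
            )

        lo = marginal({1: 0.0, 2: 1.0, 3: 2.0}, 1)
        hi = marginal({1: 1.5, 2: 1.0, 3: 2.0}, 1)
        assert hi > lo

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            _sample_indices([], 3.0, Random(0))


class TestStepNetwork:
    def _setup(self, topology, params):
        reg = CognateRegistry()
        root = reg.register_birth(None, 0)
        state = NetworkState(0, {n: frozenset({root}) for n in topology.node_ids})
        w = influence_weights(topology, params.s)
        return reg, state, w

    def test_sets_never_empty_and_time_advances(self, triangle_topology):
        params = SimParams(s=2.0, b=0.5, d=3.0)
        reg, state, w = self._setup(triangle_topology, params)
        rng = Random(3)
        for _ in range(200):
            state = step_network(state, triangle_topology, w, reg, params, rng)
            assert all(len(v) > 0 for v in state.V.values())
        assert state.t == 200

    def test_dead_cognates_never_reappear(self, triangle_topology):
        params = SimParams(s=2.0, b=1.0, d=3.0)
        reg, state, w = self._setup(triangle_topology, params)
        rng = Random(11)
        died_at: dict[int, int] = {}
        for _ in range(300):
            state = step_network(state, triangle_topology, w, reg, params, rng)
            present = set().union(*state.V.values())
            for cid, t in died_at.items():
                assert cid not in present, f"cognate {cid} revived after dying at {t}"
            for rec in reg:
                if rec.death_time is not None and rec.cognate_id not in died_at:
                    died_at[rec.cognate_id] = rec.death_time
        assert died_at, "expected at least one death in 300 steps"

    def test_each_birth_recorded_once(self, triangle_topology):
        params = SimParams(s=1.0, b=2.0, d=3.0)
        reg, state, w = self._setup(triangle_topology, params)
        rng = Random(2)
        for _ in range(100):
            state = step_network(state, triangle_topology, w, reg, params, rng)
        ids = [rec.cognate_id for rec in reg]
        assert len(ids) == len(set(ids))
        # at most one birth per node per step, plus the shared root
        assert len(ids) <= 1 + 3 * 100

    def test_node_order_does_not_bias_the_update(self):
        # same network declared in two node orders; marginal next-state law
        # of the synchronous update must agree
        nodes = [("A", 1.0), ("B", 2.0)]
        edges = [("A", "B", 1.0)]
        t1 = make_topology(nodes, edges)
        t2 = make_topology(list(reversed(nodes)), edges)
        params = SimParams(s=1.0, b=0.5, d=3.0)

        def next_state_counts(topology, n=4000):
            w = influence_weights(topology, params.s)
            counts = Counter()
            rng = Random(99)
            for _ in range(n):
                reg = CognateRegistry()
                root = reg.register_birth(None, 0)
                state = NetworkState(
                    0, {m: frozenset({root}) for m in topology.node_ids}
                )
                nxt = step_network(state, topology, w, reg, params, rng)
                counts[(root in nxt.V["A"], root in nxt.V["B"],
                        len(nxt.V["A"]), len(nxt.V["B"]))] += 1
            return counts, n

        c1, n = next_state_counts(t1)
        c2, _ = next_state_counts(t2)
        tv = 0.5 * sum(abs(c1[k] - c2[k]) / n for k in set(c1) | set(c2))
        assert tv < 0.05


class TestRunConcept:
    def test_zero_steps_keeps_initial_cognate(self, pair_topology):
        params = SimParams(s=1.0, b=1.0, d=3.0, T=0)
        final, reg = run_concept(pair_topology, params, Random(0))
        assert final == {"A": frozenset({0}), "B": frozenset({0})}
        assert len(reg) == 1
        assert reg[0].birth_time == 0

    def test_copy_event_duplicates_source_state(self):
        from dialectsim import TopologyEvent

        ev = TopologyEvent(
            time=30,
            kind="copy_node",
            source="A",
            target="B",
            new_edges=(("C", 1.0),),
            target_population=5.0,
        )
        topo = make_topology(
            [("A", 1.0), ("C", 1.0)], [("A", "C", 1.0)], [ev]
        )
        params = SimParams(s=2.0, b=0.5, d=3.0, T=30)
        final, _ = run_concept(topo, params, Random(4))
        # T equals the event time: B holds an exact copy of A's set
        assert final["B"] == final["A"]

    def test_final_sets_non_empty(self, triangle_topology):
        params = SimParams(s=1.0, b=1.0, d=3.0, T=120)
        final, _ = run_concept(triangle_topology, params, Random(8))
        assert all(final[n] for n in triangle_topology.node_ids)


class TestRunSimulation:
    def test_same_seed_reproduces_everything(self, triangle_topology, quick_params):
        r1 = run_simulation(triangle_topology, quick_params)
        r2 = run_simulation(triangle_topology, quick_params)
        assert r1.states == r2.states
        for a, b in zip(r1.registries, r2.registries):
            assert [(r.cognate_id, r.birth_time, r.death_time) for r in a] == [
                (r.cognate_id, r.birth_time, r.death_time) for r in b
            ]

    def test_different_seeds_differ(self, triangle_topology, quick_params):
        r1 = run_simulation(triangle_topology, quick_params)
        r2 = run_simulation(
            triangle_topology, quick_params.with_overrides(seed=quick_params.seed + 1)
        )

        def history(result):
            return [
                [(r.cognate_id, r.birth_node, r.birth_time, r.death_time) for r in reg]
                for reg in result.registries
            ]

        assert history(r1) != history(r2)

    def test_registry_consistent_with_final_state(self, triangle_topology, quick_params):
        result = run_simulation(triangle_topology, quick_params)
        for final, reg in zip(result.states, result.registries):
            present = set().union(*final.values())
            alive = {rec.cognate_id for rec in reg if rec.alive}
            assert alive == present
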