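import itertools
import math

import numpy as np
import pytest

from _oracles import fixation_oracle
from resic import (
    FitnessLandscape,
    build_network,
    fixation_probability,
    ordering_flux,
    pairwise_ordering_fluxes,
    path_fluxes,
    steady_state,
    transition_rate,
)
from resic.simulate import binary_events


def asym_landscape(net, bump: dict):
    r = {s: 1.0 for s in net.states}
    r.update(bump)
    return FitnessLandscape(r)


class TestFixationProbability:
    def test_neutral_is_one_over_n(self):
        assert fixation_probability(1.0, 100) == pytest.approx(0.01, abs=1e-15)

    def test_small_population_closed_form(self):
        assert fixation_probability(2.0, 2) == pytest.approx(2 / 3, abs=1e-14)

    @pytest.mark.parametrize("r", [0.5, 0.9, 1.1, 2.0, 5.0])
    @pytest.mark.parametrize("N", [2, 10, 100])
    def test_matches_birth_death_linear_solve(self, r, N):
        assert fixation_probability(r, N) == pytest.approx(
            fixation_oracle(r, N), abs=1e-10
        )

    def test_monotone_in_fitness_ratio(self):
        rs = np.linspace(0.5, 5.0, 40)
        ps = [fixation_probability(r, 50) for r in rs]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_large_population_limit_for_advantageous_mutant(self):
        assert fixation_probability(2.0, 10**6) == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("r, N", [(0.0, 10), (-1.0, 10), (2.0, 0)])
    def test_domain_errors(self, r, N):
        with pytest.raises(ValueError):
            fixation_probability(r, N)


class TestBuildNetwork:
    def test_two_binary_events(self, pair_events):
        net = build_network(pair_events)
        assert len(net.states) == 4
        assert len(net.edges) == 4
        assert len(net.enumerate_paths()) == 2

    def test_two_gene_events_two_levels(self, gene_events_two_level):
        net = build_network(gene_events_two_level)
        assert len(net.states) == 9
        assert len(net.edges) == 12
        assert len(net.enumerate_paths()) == math.comb(4, 2)

    def test_three_binary_events(self, triple_events):
        net = build_network(triple_events)
        assert len(net.states) == 8
        assert len(net.edges) == 12
        assert len(net.enumerate_paths()) == math.factorial(3)

    def test_state_count_guard(self):
        with pytest.raises(ValueError):
            build_network(binary_events(["A", "B", "C", "D"]))
        with pytest.raises(ValueError):
            build_network(binary_events(["A"]))

    def test_origin_and_terminal_unique(self, triple_events):
        net = build_network(triple_events)
        assert net.states[net.origin] == (0, 0, 0)
        assert net.states[net.terminal] == (1, 1, 1)

    def test_gene_event_allele_supply_depletes(self, gene_events_two_level):
        net = build_network(gene_events_two_level, N=100, mu=1e-7)
        first = [e.u for e in net.edges if net.states[e.src] == (0, 0)]
        second = [
            e.u for e in net.edges
            if net.states[e.src] == (1, 0) and net.states[e.dst] == (2, 0)
        ]
        assert first == pytest.approx([2e-7 * 100] * 2)
        assert second == pytest.approx([1e-7 * 100])


class TestTransitionRate:
    def test_neutral_pathway_rate_cancels_population_size(self):
        # pathway event with 3 member genes: neutral rate = M * mu_g,
        # independent of N
        for N in (10, 100, 1000):
            net = build_network(binary_events(["A", "B"], M=3), N=N)
            neutral = FitnessLandscape.neutral(net)
            e = net.edges[0]
            assert transition_rate(e, neutral, net) == pytest.approx(3 * 2.0e-7)

    def test_advantageous_edge_closed_form(self, pair_events):
        net = build_network(pair_events, N=100)
        r = {s: 1.0 for s in net.states}
        r[(1, 0)] = 1.5
        land = FitnessLandscape(r)
        e = next(
            e for e in net.edges
            if net.states[e.src] == (0, 0) and net.states[e.dst] == (1, 0)
        )
        expected = e.u * (1 - 1 / 1.5) / (1 - 1.5**-100)
        assert transition_rate(e, land, net) == pytest.approx(expected, rel=1e-12)


class TestSteadyState:
    def test_two_event_occupancies_match_hand_balance(self, pair_events):
        net = build_network(pair_events, N=100, mu=1e-7)
        sol = steady_state(net, FitnessLandscape.neutral(net), influx=1.0, delta=0.5)
        rates = sol.rates
        q = {(net.states[e.src], net.states[e.dst]): rates[j]
             for j, e in enumerate(net.edges)}
        x00 = 1.0 / (q[(0, 0), (1, 0)] + q[(0, 0), (0, 1)])
        x10 = q[(0, 0), (1, 0)] * x00 / q[(1, 0), (1, 1)]
        x01 = q[(0, 0), (0, 1)] * x00 / q[(0, 1), (1, 1)]
        x11 = (q[(1, 0), (1, 1)] * x10 + q[(0, 1), (1, 1)] * x01) / 0.5
        expect = np.array([x00, x10, x01, x11])
        by_state = {s: sol.occupancy[i] for i, s in enumerate(net.states)}
        got = np.array([by_state[(0, 0)], by_state[(1, 0)],
                        by_state[(0, 1)], by_state[(1, 1)]])
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_frequencies_normalized_and_balanced(self, triple_events):
        net = build_network(triple_events)
        land = asym_landscape(net, {(1, 0, 0): 1.4, (1, 1, 0): 1.9, (1, 1, 1): 2.2})
        sol = steady_state(net, land)
        assert sol.freq.sum() == pytest.approx(1.0, abs=1e-12)
        assert (sol.freq >= 0).all()
        assert sol.balance_residual() < 1e-10 * sol.influx

    def test_symmetric_network_equalizes_single_mutants(self, pair_events):
        net = build_network(pair_events)
        sol = steady_state(net, FitnessLandscape.neutral(net))
        f = sol.freq_by_state
        assert f[(1, 0)] == pytest.approx(f[(0, 1)], rel=1e-12)

    def test_occupancy_matches_sojourn_time_simulation(self, pair_events):
        """Monte-Carlo oracle: patient occupancies are proportional to mean
        sojourn times of the injection/removal jump process."""
        net = build_network(pair_events, N=100, mu=1e-3)
        land = asym_landscape(net, {(1, 0): 1.02, (1, 1): 1.05})
        delta = 0.05
        sol = steady_state(net, land, delta=delta)
        rng = np.random.default_rng(42)
        K = 30_000  # ~1e5 jump events across patients
        time_in = np.zeros(len(net.states))
        state = np.full(K, net.origin)
        for i in range(len(net.states)):  # topological order
            here = state == i
            n_here = int(here.sum())
            if n_here == 0:
                continue
            if i == net.terminal:
                time_in[i] += rng.exponential(1 / delta, n_here).sum()
                continue
            out = net._out_edges[i]
            qs = sol.rates[out]
            tot = qs.sum()
            time_in[i] += rng.exponential(1 / tot, n_here).sum()
            nxt = rng.choice([net.edges[j].dst for j in out], size=n_here,
                             p=qs / tot)
            state[here] = nxt
        emp = time_in / time_in.sum()
        assert 0.5 * np.abs(emp - sol.freq).sum() < 0.01

    def test_zero_rate_network_rejected(self):
        net = build_network(binary_events(["A", "B"], per_gene_rate=0.0), mu=0.0)
        with pytest.raises(ValueError):
            steady_state(net, FitnessLandscape.neutral(net), delta=1.0)


class TestPathFluxes:
    def test_symmetric_two_event_split(self, pair_events):
        net = build_network(pair_events)
        sol = steady_state(net, FitnessLandscape.neutral(net))
        probs = sorted(pf.probability for pf in path_fluxes(sol))
        assert probs == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_probabilities_sum_to_one(self, gene_events_two_level):
        net = build_network(gene_events_two_level)
        land = asym_landscape(net, {(1, 0): 1.3, (2, 1): 1.6, (2, 2): 2.0})
        fluxes = path_fluxes(steady_state(net, land))
        assert sum(pf.probability for pf in fluxes) == pytest.approx(1.0, abs=1e-10)
        assert all(pf.probability >= 0 for pf in fluxes)

    def test_fitter_intermediate_attracts_flux(self, pair_events):
        net = build_network(pair_events)
        land = asym_landscape(net, {(1, 0): 1.2})
        f = pairwise_ordering_fluxes(path_fluxes(steady_state(net, land)), net)
        assert f[("A", "B")] > 0.5

    def test_matches_exhaustive_lattice_enumeration(self, gene_events_two_level):
        """Independent oracle: recompute each multiset permutation of hits
        by walking the lattice with scalar rate arithmetic."""
        net = build_network(gene_events_two_level, N=100, mu=1e-7)
        land = asym_landscape(net, {(1, 0): 1.25, (2, 0): 1.4, (2, 1): 1.5,
                                    (2, 2): 1.8, (1, 1): 1.1})
        r = land.r
        N, mu = net.N, net.mu

        def rate(src, dst):
            k = next(i for i in range(2) if dst[i] != src[i])
            u = (2 - src[k]) * mu * N
            return u * fixation_probability(r[dst] / r[src], N)

        oracle = {}
        for order in set(itertools.permutations([0, 0, 1, 1])):
            s = (0, 0)
            p = 1.0
            for k in order:
                nxts = []
                for j in range(2):
                    t = list(s)
                    if t[j] < 2:
                        t[j] += 1
                        nxts.append((j, tuple(t)))
                tot = sum(rate(s, t) for _, t in nxts)
                chosen = next(t for j, t in nxts if j == k)
                p *= rate(s, chosen) / tot
                s = chosen
            oracle[order] = p

        fluxes = path_fluxes(steady_state(net, land))
        for pf in fluxes:
            assert pf.probability == pytest.approx(
                oracle[pf.event_sequence], rel=1e-10
            )

    def test_matches_absorbing_walk_frequencies(self, triple_events):
        """Stochastic oracle: 1e5 absorbing walks of the embedded jump chain."""
        net = build_network(triple_events)
        land = asym_landscape(
            net, {(1, 0, 0): 1.3, (1, 1, 0): 1.5, (1, 1, 1): 1.7, (0, 1, 0): 1.1}
        )
        sol = steady_state(net, land)
        fluxes = path_fluxes(sol)
        rng = np.random.default_rng(7)
        n_walks = 100_000
        counts = {pf.event_sequence: 0 for pf in fluxes}
        state = np.full(n_walks, net.origin)
        seqs = [[] for _ in range(n_walks)]
        for i in range(len(net.states)):
            here = np.where(state == i)[0]
            if here.size == 0 or i == net.terminal:
                continue
            out = net._out_edges[i]
            qs = sol.rates[out]
            pick = rng.choice(len(out), size=here.size, p=qs / qs.sum())
            for w, jj in zip(here, pick):
                e = net.edges[out[jj]]
                seqs[w].append(e.event_index)
                state[w] = e.dst
        for s in seqs:
            counts[tuple(s)] += 1
        for pf in fluxes:
            emp = counts[pf.event_sequence] / n_walks
            se = math.sqrt(pf.probability * (1 - pf.probability) / n_walks)
            assert abs(emp - pf.probability) <= 3 * se + 1e-12


class TestOrderingFlux:
    def test_symmetric_pair_is_half(self, pair_events):
        net = build_network(pair_events)
        fluxes = path_fluxes(steady_state(net, FitnessLandscape.neutral(net)))
        assert ordering_flux(fluxes, net, "A", "B") == pytest.approx(0.5, abs=1e-9)

    def test_three_event_exchangeability(self, triple_events):
        net = build_network(triple_events)
        fluxes = path_fluxes(steady_state(net, FitnessLandscape.neutral(net)))
        for a, b in itertools.combinations("ABC", 2):
            assert ordering_flux(fluxes, net, a, b) == pytest.approx(0.5, abs=1e-9)

    def test_complementarity(self, gene_events_two_level):
        net = build_network(gene_events_two_level)
        land = asym_landscape(net, {(1, 0): 1.2, (2, 2): 1.5})
        fluxes = path_fluxes(steady_state(net, land))
        ab = ordering_flux(fluxes, net, "EGFR_amp", "PTEN_del")
        ba = ordering_flux(fluxes, net, "PTEN_del", "EGFR_amp")
        assert ab + ba == pytest.approx(1.0, abs=1e-12)

    def test_unknown_event_rejected(self, pair_events):
        net = build_network(pair_events)
        fluxes = path_fluxes(steady_state(net, FitnessLandscape.neutral(net)))
        with pytest.raises(ValueError):
            ordering_flux(fluxes, net, "A", "Z")


class TestNeutralPopulationSizeInvariance:
    def test_fluxes_invariant_across_orders_of_magnitude(self, pair_events):
        ref = None
        for N in (10, 100, 1000):
            net = build_network(pair_events, N=N)
            fluxes = path_fluxes(steady_state(net, FitnessLandscape.neutral(net)))
            probs = sorted(pf.probability for pf in fluxes)
            if ref is None:
                ref = probs
            else:
                assert probs == pytest.approx(ref, abs=1e-9)
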