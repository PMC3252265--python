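import logging

import numpy as np
import pytest

from resic import (
    BootstrapSummary,
    Consistency,
    FitnessLandscape,
    ObservedCounts,
    bootstrap_orderings,
    build_network,
    compare_orderings,
    counts_from_matrix,
    dominant_order,
    fit_fitness,
    steady_state,
)
from resic.simulate import planted_pair_config, sample_cohort_from_steady_state


def exact_counts(net, landscape, total=10**6):
    """Deterministic large-cohort counts from the exact steady state."""
    sol = steady_state(net, landscape)
    counts = {s: int(round(f * total)) for s, f in sol.freq_by_state.items()}
    return ObservedCounts(counts=counts, total=sum(counts.values()))


class TestFitFitness:
    def test_recovers_planted_dominant_order(self):
        cfg = planted_pair_config()
        net = cfg.network()
        obs = exact_counts(net, cfg.landscape())
        fit = fit_fitness(net, obs, seed=11)
        assert fit.dominant == (("A", "B"),)
        assert fit.objective < 1e-8
        truth = cfg.fitness[(1, 0)] / cfg.fitness[(0, 1)]
        fitted = fit.landscape.r[(1, 0)] / fit.landscape.r[(0, 1)]
        assert fitted == pytest.approx(truth, rel=0.05)

    def test_symmetric_counts_give_even_fluxes(self, pair_events):
        net = build_network(pair_events)
        obs = exact_counts(net, FitnessLandscape.neutral(net))
        fit = fit_fitness(net, obs, seed=5)
        assert fit.ordering_fluxes[("A", "B")] == pytest.approx(0.5, abs=0.02)

    def test_deterministic_under_fixed_seed(self):
        cfg = planted_pair_config(seed=2)
        cohort = sample_cohort_from_steady_state(cfg)
        net = cfg.network()
        f1 = fit_fitness(net, cohort.observed, seed=9)
        f2 = fit_fitness(net, cohort.observed, seed=9)
        assert f1.objective == f2.objective
        assert f1.landscape.r == f2.landscape.r
        assert f1.ordering_fluxes == f2.ordering_fluxes

    def test_objective_no_worse_than_generating_landscape(self):
        cfg = planted_pair_config(seed=4)
        cohort = sample_cohort_from_steady_state(cfg)
        net = cfg.network()
        fit = fit_fitness(net, cohort.observed, seed=3)
        truth_r = cfg.landscape().to_array(net)
        sol = steady_state(net, truth_r)
        obs = cohort.observed.frequencies(net)
        truth_obj = float(((sol.freq - obs) ** 2).sum())
        assert fit.objective <= truth_obj + 1e-9

    def test_bad_bounds_rejected(self, pair_events):
        net = build_network(pair_events)
        obs = exact_counts(net, FitnessLandscape.neutral(net), total=100)
        with pytest.raises(ValueError):
            fit_fitness(net, obs, bounds=(2.0, 1.0))


class TestDominantOrder:
    def test_larger_flux_wins(self):
        cfg = planted_pair_config()
        net = cfg.network()
        fit = fit_fitness(net, exact_counts(net, cfg.landscape()), seed=1)
        assert dominant_order(fit) == (("A", "B"),)

    def test_exact_tie_breaks_lexicographically_with_warning(self, caplog):
        fake = type(
            "F", (), {"ordering_fluxes": {("A", "B"): 0.5, ("B", "A"): 0.5}}
        )()
        with caplog.at_level(logging.WARNING):
            assert dominant_order(fake) == (("A", "B"),)
        assert any("tie" in r.message for r in caplog.records)

    def test_three_event_relations_match_enumerated_fluxes(self, triple_events):
        net = build_network(triple_events)
        land = {s: 1.0 for s in net.states}
        land.update({(1, 0, 0): 1.3, (1, 1, 0): 1.5, (1, 1, 1): 1.6})
        obs = exact_counts(net, FitnessLandscape(land))
        fit = fit_fitness(net, obs, seed=21, n_starts=30)
        rel = dict.fromkeys(fit.dominant)
        for a, b in fit.dominant:
            assert fit.ordering_fluxes[(a, b)] >= fit.ordering_fluxes[(b, a)]
        assert len(rel) == 3


class TestBootstrap:
    def test_single_iteration_support_is_binary(self):
        cfg = planted_pair_config(seed=8)
        cohort = sample_cohort_from_steady_state(cfg)
        s = bootstrap_orderings(cfg.network(), cohort.observed, B=1, seed=1)
        assert set(s.support.values()) <= {0.0, 1.0}

    def test_strong_asymmetry_yields_full_support(self):
        cfg = planted_pair_config(r_first=1.1, seed=6)
        cohort = sample_cohort_from_steady_state(cfg)
        s = bootstrap_orderings(cfg.network(), cohort.observed, B=200, seed=2)
        assert s.support[("A", "B")] >= 0.95
        assert s.significant
        assert s.n_failed == 0

    def test_symmetric_data_not_significant(self, pair_events):
        net = build_network(pair_events)
        obs = exact_counts(net, FitnessLandscape.neutral(net), total=400)
        s = bootstrap_orderings(net, obs, B=100, seed=3)
        assert not s.significant
        assert s.support[("A", "B")] + s.support[("B", "A")] == pytest.approx(
            1.0, abs=1e-12
        )

    def test_mean_fluxes_are_complementary(self):
        cfg = planted_pair_config(seed=5)
        cohort = sample_cohort_from_steady_state(cfg)
        s = bootstrap_orderings(cfg.network(), cohort.observed, B=50, seed=4)
        assert s.mean_flux[("A", "B")] + s.mean_flux[("B", "A")] == pytest.approx(1.0)

    def test_deterministic_under_fixed_seed(self):
        cfg = planted_pair_config(seed=10)
        cohort = sample_cohort_from_steady_state(cfg)
        s1 = bootstrap_orderings(cfg.network(), cohort.observed, B=25, seed=7)
        s2 = bootstrap_orderings(cfg.network(), cohort.observed, B=25, seed=7)
        assert s1.support == s2.support
        assert s1.mean_flux == s2.mean_flux


class TestCountsFromMatrix:
    def test_tabulation(self, make_event_matrix, pair_events):
        m = make_event_matrix({"A": [0, 1, 1, 0], "B": [0, 0, 1, 1]}, pair_events)
        net = build_network(pair_events)
        obs = counts_from_matrix(m, net)
        assert obs.total == 4
        assert obs.counts == {(0, 0): 1, (1, 0): 1, (1, 1): 1, (0, 1): 1}

    def test_total_must_match(self):
        with pytest.raises(ValueError):
            ObservedCounts(counts={(0, 0): 2}, total=3)


def summary(events, support, mean_flux):
    return BootstrapSummary(
        events=events, B=100, seed=0, support=support, mean_flux=mean_flux
    )


class TestCompareOrderings:
    def test_small_flux_shift_same_dominant_is_consistent(self):
        a = summary(("E", "P"), {("P", "E"): 0.9, ("E", "P"): 0.1},
                    {("P", "E"): 0.435, ("E", "P"): 0.565})
        b = summary(("E", "P"), {("P", "E"): 0.92, ("E", "P"): 0.08},
                    {("P", "E"): 0.438, ("E", "P"): 0.562})
        cmpr = compare_orderings(a, b)
        assert cmpr.classification is Consistency.consistent
        assert cmpr.flux_delta == pytest.approx(0.3, abs=1e-9)

    def test_flux_drop_beyond_three_points_weakens(self):
        a = summary(("E", "P"), {("P", "E"): 0.9, ("E", "P"): 0.1},
                    {("P", "E"): 0.70, ("E", "P"): 0.30})
        b = summary(("E", "P"), {("P", "E"): 0.85, ("E", "P"): 0.15},
                    {("P", "E"): 0.65, ("E", "P"): 0.35})
        assert compare_orderings(a, b).classification is Consistency.weakened

    def test_dominant_reversal_is_inconsistent(self):
        a = summary(("E", "P"), {("P", "E"): 0.9, ("E", "P"): 0.1},
                    {("P", "E"): 0.70, ("E", "P"): 0.30})
        b = summary(("E", "P"), {("P", "E"): 0.2, ("E", "P"): 0.8},
                    {("P", "E"): 0.40, ("E", "P"): 0.60})
        cmpr = compare_orderings(a, b)
        assert cmpr.classification is Consistency.inconsistent
        assert cmpr.dominant_changed

    def test_fewer_alleles_flag_weakens(self):
        a = summary(("E", "P"), {("P", "E"): 0.9, ("E", "P"): 0.1},
                    {("P", "E"): 0.70, ("E", "P"): 0.30})
        assert (
            compare_orderings(a, a, fewer_alleles=True).classification
            is Consistency.weakened
        )

    def test_mismatched_pairs_rejected(self):
        a = summary(("E", "P"), {("P", "E"): 1.0, ("E", "P"): 0.0},
                    {("P", "E"): 0.7, ("E", "P"): 0.3})
        b = summary(("E", "Q"), {("Q", "E"): 1.0, ("E", "Q"): 0.0},
                    {("Q", "E"): 0.7, ("E", "Q"): 0.3})
        with pytest.raises(ValueError):
            compare_orderings(a, b)
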