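"""Agents, contact structure, and the three peer-inference rules."""

import itertools

import numpy as np
import pytest
from scipy.special import zeta

from fuzzyhybrid.membership import ConstantDistributionSpec
from fuzzyhybrid.population import (
    ContactModel,
    ContactModelSpec,
    InteractionRuleSpec,
    contact_pairs,
    init_agents,
    interaction_round,
    optimistic_update,
    perceive,
    pessimistic_update,
    realistic_update,
)

SPEC = ConstantDistributionSpec(2, 5, 8, 0.3, 0.3, 0.3)
SPEC0 = ConstantDistributionSpec(2, 5, 8)  # degenerate (sigma = 0)


class TestInitAgents:
    def test_sigma_zero_gives_identical_agents(self, rng):
        pop = init_agents(2, [SPEC0, SPEC0], [0.5, 0.5], rng)
        assert (pop.b[0] == pop.b[1]).all()
        assert (pop.mu_low_geo[0] == pop.mu_low_geo[1]).all()

    def test_fixed_seed_reproducible(self):
        a = init_agents(50, [SPEC, SPEC], [1.0, 1.0], np.random.default_rng(3))
        b = init_agents(50, [SPEC, SPEC], [1.0, 1.0], np.random.default_rng(3))
        assert (a.b == b.b).all() and (a.c == b.c).all() and (a.d == b.d).all()

    def test_structural_shape(self, rng):
        pop = init_agents(1000, [SPEC, SPEC], [0.5, 0.5], rng)
        assert pop.n_agents == 1000 and pop.n_variables == 2
        assert pop.b.shape == pop.mu_low_social.shape == (1000, 2)

    def test_rejects_single_agent(self, rng):
        with pytest.raises(ValueError):
            init_agents(1, [SPEC], [0.5], rng)


class TestContactPairs:
    def test_two_agents_single_pair(self, rng):
        spec = ContactModelSpec(mode="random", n_agents=2, k=1)
        assert contact_pairs(spec, rng) == [(0, 1)]

    def test_no_self_pairs(self, rng):
        spec = ContactModelSpec(mode="random", n_agents=10, k=3)
        model = ContactModel(spec, rng)
        for _ in range(300):
            assert all(i != r for i, r in model.draw_pairs(rng))

    def test_k_at_least_population_rejected(self):
        with pytest.raises(ValueError):
            ContactModelSpec(mode="random", n_agents=3, k=3)

    def test_k_cap_and_exponent_range_enforced(self):
        with pytest.raises(ValueError):
            ContactModelSpec(mode="random", n_agents=100, k=6)
        with pytest.raises(ValueError):
            ContactModelSpec(mode="scale_free", n_agents=100, k=3, q_exponent=3.5)

    def test_random_contact_fairness(self, rng):
        # an unordered pair meets if either side picks the other:
        # P(meet) = 1 - (1 - k/(n-1))^2, identical for every pair
        spec = ContactModelSpec(mode="random", n_agents=5, k=2)
        model = ContactModel(spec, rng)
        rounds = 2000
        counts = {}
        for _ in range(rounds):
            for i, r in model.draw_pairs(rng):
                counts[(i, r)] = counts.get((i, r), 0) + 1
        p0 = spec.k / (spec.n_agents - 1)
        p_meet = 1 - (1 - p0) ** 2
        sigma = np.sqrt(rounds * p_meet * (1 - p_meet))
        assert len(counts) == 10  # all unordered pairs occur
        freqs = np.array(list(counts.values()))
        assert np.abs(freqs - rounds * p_meet).max() <= 5 * sigma

    def test_scale_free_degree_exponent(self, rng):
        """Discrete power-law MLE on the generated degrees recovers q in (2,3)."""
        spec = ContactModelSpec(mode="scale_free", n_agents=5000, k=3, q_exponent=2.5)
        model = ContactModel(spec, rng)
        deg = np.array([d for _, d in model.graph.degree() if d > 0])
        qs = np.linspace(1.5, 4.0, 251)
        ll = [-q * np.log(deg).sum() - len(deg) * np.log(zeta(q, 1)) for q in qs]
        q_hat = qs[int(np.argmax(ll))]
        assert 2.0 < q_hat < 3.0

    def test_scale_free_respects_k_budget(self, rng):
        spec = ContactModelSpec(mode="scale_free", n_agents=500, k=2, q_exponent=2.5)
        model = ContactModel(spec, rng)
        pairs = model.draw_pairs(rng)
        initiated = np.zeros(500)
        for i, r in pairs:
            initiated[i] += 1
            initiated[r] += 1
        # an agent appears at most k times as chooser, but may be chosen by
        # many neighbors; every pair must at least be a real edge
        assert all(model.graph.has_edge(i, r) for i, r in pairs)


class TestUpdateRules:
    def test_pessimistic_takes_min(self):
        assert pessimistic_update(0.3, 0.7) == (0.3, 0.3)
        assert pessimistic_update(0.4, 0.4) == (0.4, 0.4)

    def test_optimistic_takes_max(self):
        assert optimistic_update(0.3, 0.7) == (0.7, 0.7)
        assert optimistic_update(0.4, 0.4) == (0.4, 0.4)

    def test_realistic_equal_constants_average(self):
        mi, mr = realistic_update(0.2, 0.6, b_i=2.0, b_r=2.0)
        assert mi == pytest.approx(0.4) and mr == pytest.approx(0.4)

    def test_realistic_equal_values_fixed_point(self):
        assert realistic_update(0.5, 0.5, 1.0, 3.0) == (0.5, 0.5)

    def test_realistic_smaller_constant_defers_more(self):
        # b_r > b_i: agent i weights the peer's value more than its own
        mi, _ = realistic_update(0.0, 1.0, b_i=1.0, b_r=3.0)
        assert mi == pytest.approx(0.75)  # omega_i = 3/4 > phi_i = 1/4
        # and the peer, from its own perspective, defers less
        _, mr = realistic_update(0.0, 1.0, b_i=1.0, b_r=3.0)
        assert mr == pytest.approx(0.75)  # omega_r = 1/4 on mu_i = 0

    def test_realistic_stays_in_range(self, rng):
        for _ in range(500):
            mi, mr = rng.uniform(0, 1, 2)
            bi, br = rng.uniform(0.5, 5, 2)
            lo, hi = min(mi, mr), max(mi, mr)
            for v in realistic_update(mi, mr, bi, br):
                assert lo - 1e-12 <= v <= hi + 1e-12


def _tiny_population(lows, rng):
    pop = init_agents(len(lows), [SPEC0], [0.5], rng)
    pop.mu_low_social[:, 0] = lows
    return pop


class TestInteractionRound:
    def test_empty_pair_list_is_noop(self, rng):
        pop = _tiny_population([0.1, 0.5, 0.9], rng)
        before = pop.mu_low_social.copy()
        interaction_round(pop, [], InteractionRuleSpec("pessimistic"))
        assert (pop.mu_low_social == before).all()

    def test_pessimistic_all_pairs_converges_to_min(self, rng):
        """Any complete round order drives everyone to the population min."""
        base_pairs = list(itertools.combinations(range(3), 2))
        for order in itertools.permutations(base_pairs):
            pop = _tiny_population([0.1, 0.5, 0.9], rng)
            interaction_round(pop, list(order), InteractionRuleSpec("pessimistic"))
            assert pop.mu_low_social[:, 0] == pytest.approx([0.1, 0.1, 0.1])

    def test_optimistic_all_pairs_converges_to_max(self, rng):
        base_pairs = list(itertools.combinations(range(3), 2))
        for order in itertools.permutations(base_pairs):
            pop = _tiny_population([0.1, 0.5, 0.9], rng)
            interaction_round(pop, list(order), InteractionRuleSpec("optimistic"))
            assert pop.mu_low_social[:, 0] == pytest.approx([0.9, 0.9, 0.9])

    def test_pessimistic_round_nonincreasing(self, rng):
        pop = init_agents(20, [SPEC, SPEC], [4.0, 4.0], rng)
        before = pop.mu_low_social.copy()
        pairs = contact_pairs(ContactModelSpec("random", 20, 3), rng)
        interaction_round(pop, pairs, InteractionRuleSpec("pessimistic"))
        assert (pop.mu_low_social <= before + 1e-15).all()
        assert pop.mu_low_social.min() == pytest.approx(before.min())

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            InteractionRuleSpec("contrarian")


class TestPerceive:
    def test_signal_below_all_b_gives_full_low(self, rng):
        pop = init_agents(30, [SPEC, SPEC], [5.0, 5.0], rng)
        perceive(pop, [0.1, 0.1])
        assert (pop.mu_low_geo == 1.0).all()
        assert (pop.mu_low_social == 1.0).all()

    def test_signal_above_all_d_gives_full_high(self, rng):
        pop = init_agents(30, [SPEC, SPEC], [5.0, 5.0], rng)
        perceive(pop, [50.0, 50.0])
        assert (pop.mu_high == 1.0).all()
        assert (pop.mu_low_social == 0.0).all()

    def test_heterogeneous_constants_give_different_memberships(self, rng):
        pop = init_agents(30, [SPEC, SPEC], [4.0, 4.0], rng)
        assert len(np.unique(pop.mu_low_geo[:, 0])) > 1

    def test_negative_signal_rejected(self, rng):
        pop = init_agents(5, [SPEC], [1.0], rng)
        with pytest.raises(ValueError, match=">= 0"):
            perceive(pop, [-1.0])

    def test_perceive_overwrites_social_value(self, rng):
        pop = init_agents(5, [SPEC0], [4.0], rng)
        pop.mu_low_social[:] = 0.99
        perceive(pop, [4.0])
        assert (pop.mu_low_social == pop.mu_low_geo).all()
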