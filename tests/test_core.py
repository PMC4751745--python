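"""Unit tests for the population types and single-iteration update rules."""

import numpy as np
import pytest
from scipy import stats

import painsim as ps
from painsim import (
    ModelParams,
    PopulationCollapse,
    advance_pain,
    apply_mortality_and_replacement,
    forage,
    init_population,
    sample_connectedness,
    select_injuries,
    select_interactions,
    step,
)
from painsim.core import strategy_code
from painsim.fixtures import make_fixture_population


def two_agent_state(params, injured_strategy, partner_strategy, *,
                    injured_energy=10.0, partner_energy=10.0, pain=5):
    """Slot 0 injured with the given strategy, slot 1 healthy partner."""
    state = make_fixture_population("one_injured_expresser_one_altruist", params)
    state.expresses[:] = [injured_strategy.expresses, partner_strategy.expresses]
    state.altruistic[:] = [injured_strategy.altruistic, partner_strategy.altruistic]
    state.energy[:] = [injured_energy, partner_energy]
    state.pain[0] = pain
    return state


# ---------------------------------------------------------------- init


def test_init_population_default(params):
    state = init_population(params, seed=1)
    assert state.n_agents == 100
    assert np.all(state.energy == 10.0)
    assert np.all(state.pain == 0)
    assert np.all((state.age >= 1) & (state.age <= 100))
    assert np.all((state.connectedness >= 0.1) & (state.connectedness <= 0.9))


def test_init_population_single_agent():
    p = ModelParams(n_agents=1)
    state = init_population(p, seed=7)
    assert state.n_agents == 1
    assert 1 <= state.age[0] <= 100


def test_init_population_reproducible(params):
    a, b = init_population(params, seed=3), init_population(params, seed=3)
    for attr in ("age", "energy", "expresses", "altruistic", "connectedness"):
        assert np.array_equal(getattr(a, attr), getattr(b, attr))


def test_initial_ages_uniform(params):
    # pool ages over many initializations and test uniformity on 1..100
    ages = np.concatenate(
        [init_population(params, seed=s).age for s in range(100)]
    )
    counts = np.bincount(ages, minlength=101)[1:101]
    assert ages.min() >= 1 and ages.max() <= 100
    chi2 = stats.chisquare(counts)
    assert chi2.pvalue > 0.01


def test_initial_strategies_near_half(params):
    exp = np.concatenate(
        [init_population(params, seed=s).expresses for s in range(100)]
    )
    assert abs(exp.mean() - 0.5) < 0.02


def test_default_population_balanced(params):
    state = ps.default_population(params, seed=5)
    assert np.array_equal(state.strategy_counts(), [25, 25, 25, 25])
    assert np.all(state.energy == params.e_init)
    assert np.all(state.pain == 0)
    again = ps.default_population(params, seed=5)
    assert np.array_equal(state.age, again.age)
    assert np.array_equal(state.connectedness, again.connectedness)


def test_default_population_remainder_spread():
    p = ModelParams(n_agents=6)
    state = ps.default_population(p, seed=1)
    assert np.array_equal(state.strategy_counts(), [2, 2, 1, 1])


# ---------------------------------------------------------------- connectedness


def test_connectedness_bounds_and_skew(params, rng):
    draws = sample_connectedness(params, rng, size=100_000)
    assert draws.min() >= params.conn_min
    assert draws.max() <= params.conn_max
    # right-skewed: median below mean, density decreasing above the floor
    assert np.median(draws) < draws.mean()


def test_connectedness_degenerate_high_rate(rng):
    p = ModelParams(conn_rate=1e9)
    draws = sample_connectedness(p, rng, size=1000)
    assert np.allclose(draws, p.conn_min, atol=1e-6)


# ---------------------------------------------------------------- forage


def test_forage_rules(params):
    state = make_fixture_population("all_nonalt_nonexp", params)
    state.energy[:3] = [10.0, 20.0, 10.0]
    state.pain[2] = 5  # injured: cannot forage
    forage(state, params)
    assert state.energy[0] == 11.0
    assert state.energy[1] == 20.0  # capped at e_max
    assert state.energy[2] == 10.0


# ---------------------------------------------------------------- injuries


def test_select_injuries_count(params, rng):
    state = make_fixture_population("all_nonalt_nonexp", params)
    injured = select_injuries(state, params, rng)
    assert len(injured) == 1
    assert np.count_nonzero(state.pain == params.t_p) == 1


def test_select_injuries_limited_by_healthy(rng):
    p = ModelParams(n_injury=10)
    state = make_fixture_population("all_nonalt_nonexp", p)
    state.pain[:] = 5
    state.pain[:3] = 0  # only 3 healthy agents left
    injured = select_injuries(state, p, rng)
    assert len(injured) == 3


def test_select_injuries_expression_cost(rng):
    p = ModelParams(c_exp=3.0, n_injury=10)
    state = make_fixture_population("all_nonalt_exp", p.replace(n_agents=10))
    state.energy[:] = 10.0
    injured = select_injuries(state, p.replace(n_agents=10), rng)
    assert np.all(state.energy[injured] == 7.0)
    assert np.all(state.pain[injured] == p.t_p)


def test_expression_cost_floors_at_zero(rng):
    p = ModelParams(c_exp=20.0, n_injury=10).replace(n_agents=10)
    state = make_fixture_population("all_nonalt_exp", p)
    state.energy[:] = 5.0
    injured = select_injuries(state, p, rng)
    assert np.all(state.energy[injured] == 0.0)


# ---------------------------------------------------------------- interactions


def test_interactions_clamp_at_probability_one(rng):
    p = ModelParams(s=1.0)
    state = make_fixture_population("all_alt_exp", p)
    state.pain[:10] = 5
    pairs = select_interactions(state, p, rng)
    assert sorted(i for i, _ in pairs) == list(range(10))


def test_no_injured_no_interactions(params, rng):
    state = make_fixture_population("all_alt_exp", params)
    assert select_interactions(state, params, rng) == []


def test_interaction_frequency_matches_connectedness(params, rng):
    # a lone injured agent with connectedness 0.5 should interact in
    # half of iterations: Monte-Carlo check of the Bernoulli rate
    state = make_fixture_population("half_expressers", params)
    state.pain[0] = 5
    state.connectedness[0] = 0.5
    hits = sum(
        bool(select_interactions(state, params, rng)) for _ in range(100_000)
    )
    assert abs(hits / 100_000 - 0.5) < 0.01


def test_partner_never_self(params, rng):
    state = make_fixture_population("all_alt_exp", params)
    state.pain[:] = 5
    for _ in range(200):
        for i, j in select_interactions(state, params, rng):
            assert i != j


# ---------------------------------------------------------------- pain countdown


def test_advance_pain(params):
    state = make_fixture_population("all_alt_exp", params)
    state.pain[:4] = [50, 50, 1, 0]
    advance_pain(state, helped=[1])
    assert state.pain[0] == 49   # not helped: counts down
    assert state.pain[1] == 0    # helped: recovers now
    assert state.pain[2] == 0    # natural recovery
    assert state.pain[3] == 0


# ---------------------------------------------------------------- replacement


def test_homogeneous_parents_breed_true(rng):
    p = ModelParams()
    state = make_fixture_population("all_nonalt_nonexp", p)
    state.age[0] = p.max_age  # force one death
    apply_mortality_and_replacement(state, p, rng)
    assert state.age[0] == 1
    assert state.energy[0] == p.e_init
    assert not state.expresses[0] and not state.altruistic[0]


def test_trait_inheritance_independent_uniform(params):
    # two forced parents with opposite strategies: offspring should carry
    # each of the 4 combinations with probability 1/4
    rng = np.random.default_rng(0)
    combos = np.zeros(4, dtype=int)
    n = 10_000
    for _ in range(n):
        state = make_fixture_population("half_expressers", params.replace(n_agents=3))
        state.expresses[:] = [True, False, False]
        state.altruistic[:] = [True, False, True]
        state.energy[:] = [10.0, 10.0, 0.0]  # slot 2 dies; parents are 0 and 1
        state.altruistic[1] = False
        apply_mortality_and_replacement(state, params.replace(n_agents=3), rng)
        combos[strategy_code(state.expresses[2], state.altruistic[2])] += 1
    assert np.all(np.abs(combos / n - 0.25) < 0.02)


def test_old_age_removal_even_at_full_energy(rng):
    p = ModelParams()
    state = make_fixture_population("all_alt_exp", p)
    state.energy[:] = 20.0
    state.age[5] = p.max_age
    old_id = state.ids[5]
    apply_mortality_and_replacement(state, p, rng)
    assert state.ids[5] != old_id
    assert state.age[5] == 1


def test_fitness_proportional_parent_selection(params):
    # one survivor holds nearly all energy: offspring should almost
    # always inherit its traits (the other parent rarely contributes)
    rng = np.random.default_rng(1)
    p = params.replace(n_agents=4)
    hits = 0
    n = 2000
    for _ in range(n):
        state = make_fixture_population("all_nonalt_nonexp", p)
        state.expresses[:] = [True, False, False, False]
        state.altruistic[:] = [True, False, False, False]
        state.energy[:] = [1000.0, 0.5, 0.5, 0.0]
        apply_mortality_and_replacement(state, p, rng)
        if state.expresses[3] and state.altruistic[3]:
            hits += 1
    # both traits from the dominant parent: >= (1/2 + ~1/2)^2 ~ 0.56; with
    # weight 1000:1 the dominant parent is chosen as one of the two parents
    # always, and supplies each trait with prob ~1/2 -> expect ~0.25 only if
    # uniform; fitness weighting pushes trait copies toward ~0.25 as well
    # (the 2nd parent is uniform among the rest), so check dominance is
    # at least well above the uniform-parents rate of ~ (2/4 choose)...
    assert hits / n > 0.2


def test_top2_parent_rule_deterministic_parents():
    p = ModelParams(parent_rule="top2").replace(n_agents=5)
    rng = np.random.default_rng(2)
    state = make_fixture_population("all_nonalt_nonexp", p)
    state.expresses[:] = [True, True, False, False, False]
    state.altruistic[:] = [True, True, False, False, False]
    state.energy[:] = [20.0, 19.0, 5.0, 5.0, 0.0]
    apply_mortality_and_replacement(state, p, rng)
    # both top-2 parents are altruistic expressers -> so is the newborn
    assert state.expresses[4] and state.altruistic[4]


def test_population_collapse_signalled(rng):
    p = ModelParams().replace(n_agents=2)
    state = make_fixture_population("all_nonalt_nonexp", p)
    state.energy[:] = 0.0
    with pytest.raises(PopulationCollapse):
        apply_mortality_and_replacement(state, p, rng)


# ---------------------------------------------------------------- step


def test_step_keeps_population_size(params):
    state = init_population(params, seed=9)
    for _ in range(20):
        step(state, params)
        assert state.n_agents == 100
    assert state.iteration == 20


def test_energies_nondecreasing_without_injury(params):
    # with injuries disabled, energy can only rise (newborns reset to
    # e_init but no agent's trajectory ever decreases)
    p = ModelParams()
    p.n_injury = 0  # bypass the floor of 1: a no-injury environment
    state = init_population(p, seed=4)
    prev = {int(i): e for i, e in zip(state.ids, state.energy)}
    for _ in range(150):
        step(state, p)
        for i, e in zip(state.ids, state.energy):
            if int(i) in prev:
                assert e >= prev[int(i)]
        prev = {int(i): e for i, e in zip(state.ids, state.energy)}
        assert np.all(state.pain == 0)


def test_helped_agent_forages_next_iteration():
    # 2-agent trace: injured expresser + healthy altruist with certain
    # interaction; after one step the injured agent is pain-free and
    # gains energy on the following step
    p = ModelParams(s=1.0, c_alt=2.0).replace(n_agents=2)
    p.n_injury = 0  # no new injuries: isolate the help effect
    state = make_fixture_population("one_injured_expresser_one_altruist", p)
    state.age[:] = 1
    e_before = state.energy[0]
    step(state, p)
    assert state.pain[0] == 0
    assert state.energy[1] == 10.0 + 1.0 - 2.0  # forage then pay c_alt
    step(state, p)
    assert state.energy[0] == e_before + 1.0  # foraging again
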