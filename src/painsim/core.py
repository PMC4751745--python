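"""Agent and population types plus the single-iteration update rules.

The population is held as a struct-of-arrays (:class:`PopulationState`) so
one iteration of the model is a handful of vectorized operations; the
few pairwise interactions per iteration are resolved agent-by-agent
through :func:`resolve_interaction`, the canonical implementation of the
interaction cost/benefit table.

One iteration (:func:`step`) is, in order: foraging, injury, interactions,
pain countdown, ageing, death and replacement.  This ordering makes
"injury prevents foraging" hold within the injury iteration itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "Strategy",
    "Agent",
    "InteractionOutcome",
    "PopulationState",
    "PopulationCollapse",
    "init_population",
    "default_population",
    "sample_connectedness",
    "forage",
    "select_injuries",
    "select_interactions",
    "resolve_interaction",
    "advance_pain",
    "apply_mortality_and_replacement",
    "step",
    "strategy_code",
    "COMBO_LABELS",
]

#: Order of the four strategy combinations everywhere counts are reported.
COMBO_LABELS = ("alt_exp", "alt_nonexp", "nonalt_exp", "nonalt_nonexp")


class PopulationCollapse(RuntimeError):
    """Fewer than 2 agents survived an iteration; the run cannot continue."""


@dataclass(frozen=True)
class Strategy:
    """A heritable behavioural type: expression x altruism.

    ``expresses``: display pain when injured (visible to partners) or
    suppress it.  ``altruistic``: help an expressing injured partner (at
    energy cost) or ignore it (at reputation cost).  Fixed for life.
    """

    expresses: bool
    altruistic: bool


@dataclass
class Agent:
    """One individual: age, energy (fitness), strategy, reputation, pain."""

    id: int
    age: int
    energy: float
    strategy: Strategy
    connectedness: float
    pain_remaining: int = 0


@dataclass(frozen=True)
class InteractionOutcome:
    """Resolved effect of one injured-focal encounter.

    Deltas are to be applied (with clamping to the energy and
    connectedness bounds) by the caller; ``injured_helped`` means the
    injured agent's remaining pain is cancelled this iteration.
    """

    injured_id: int
    partner_id: int
    injured_helped: bool
    injured_energy_delta: float = 0.0
    partner_energy_delta: float = 0.0
    partner_connectedness_delta: float = 0.0


class PopulationState:
    """The whole population as parallel arrays, plus iteration and RNG.

    Arrays are indexed by population slot (0..n_agents-1); ``ids`` are
    unique per individual ever born, so a slot's occupant can be tracked
    across replacement.
    """

    __slots__ = (
        "ids",
        "age",
        "energy",
        "expresses",
        "altruistic",
        "connectedness",
        "pain",
        "iteration",
        "rng",
        "next_id",
    )

    def __init__(
        self,
        ids: np.ndarray,
        age: np.ndarray,
        energy: np.ndarray,
        expresses: np.ndarray,
        altruistic: np.ndarray,
        connectedness: np.ndarray,
        pain: np.ndarray,
        rng: np.random.Generator,
        iteration: int = 0,
        next_id: int | None = None,
    ) -> None:
        n = len(ids)
        for arr in (age, energy, expresses, altruistic, connectedness, pain):
            if len(arr) != n:
                raise ValueError("population arrays must share one length")
        self.ids = np.asarray(ids, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.int64)
        self.energy = np.asarray(energy, dtype=np.float64)
        self.expresses = np.asarray(expresses, dtype=bool)
        self.altruistic = np.asarray(altruistic, dtype=bool)
        self.connectedness = np.asarray(connectedness, dtype=np.float64)
        self.pain = np.asarray(pain, dtype=np.int64)
        self.iteration = iteration
        self.rng = rng
        self.next_id = int(self.ids.max()) + 1 if next_id is None else next_id

    @property
    def n_agents(self) -> int:
        return len(self.ids)

    def agent(self, i: int) -> Agent:
        """Materialize slot ``i`` as an :class:`Agent` record."""
        return Agent(
            id=int(self.ids[i]),
            age=int(self.age[i]),
            energy=float(self.energy[i]),
            strategy=Strategy(bool(self.expresses[i]), bool(self.altruistic[i])),
            connectedness=float(self.connectedness[i]),
            pain_remaining=int(self.pain[i]),
        )

    @property
    def agents(self) -> list[Agent]:
        return [self.agent(i) for i in range(self.n_agents)]

    def strategy_counts(self) -> np.ndarray:
        """Counts of the four combinations, ordered as :data:`COMBO_LABELS`."""
        return np.bincount(strategy_code(self.expresses, self.altruistic), minlength=4)

    def copy(self, rng: np.random.Generator | None = None) -> "PopulationState":
        """Deep copy; optionally with a fresh random generator."""
        import copy as _copy

        return PopulationState(
            ids=self.ids.copy(),
            age=self.age.copy(),
            energy=self.energy.copy(),
            expresses=self.expresses.copy(),
            altruistic=self.altruistic.copy(),
            connectedness=self.connectedness.copy(),
            pain=self.pain.copy(),
            rng=rng if rng is not None else _copy.deepcopy(self.rng),
            iteration=self.iteration,
            next_id=self.next_id,
        )

    @classmethod
    def from_agents(
        cls, agents: list[Agent], rng: np.random.Generator, iteration: int = 0
    ) -> "PopulationState":
        return cls(
            ids=np.array([a.id for a in agents]),
            age=np.array([a.age for a in agents]),
            energy=np.array([a.energy for a in agents], dtype=float),
            expresses=np.array([a.strategy.expresses for a in agents]),
            altruistic=np.array([a.strategy.altruistic for a in agents]),
            connectedness=np.array([a.connectedness for a in agents], dtype=float),
            pain=np.array([a.pain_remaining for a in agents]),
            rng=rng,
            iteration=iteration,
        )


def strategy_code(expresses, altruistic) -> np.ndarray:
    """Map (expresses, altruistic) to 0..3 in :data:`COMBO_LABELS` order."""
    expresses = np.asarray(expresses)
    altruistic = np.asarray(altruistic)
    return (~expresses).astype(np.intp) + 2 * (~altruistic).astype(np.intp)


def sample_connectedness(params: ModelParams, rng: np.random.Generator, size=None):
    """Draw connectedness at birth: shifted exponential, clamped.

    ``conn_min + Exponential(rate=conn_rate)`` truncated at ``conn_max``:
    most individuals sit just above the floor and few are highly
    connected, the right-skewed shape seen in real social networks.
    """
    x = params.conn_min + rng.exponential(1.0 / params.conn_rate, size=size)
    return np.minimum(x, params.conn_max) if size is not None else min(x, params.conn_max)


def init_population(params: ModelParams, seed: int) -> PopulationState:
    """A fresh population: ages uniform on 1..max_age, energy at e_init,
    connectedness from the shifted exponential, strategies independent
    fair coin flips per trait, everyone healthy.
    """
    if not isinstance(params, ModelParams):
        raise TypeError("params must be a ModelParams")
    rng = np.random.default_rng(seed)
    n = params.n_agents
    age = rng.integers(1, params.max_age + 1, size=n)
    conn = sample_connectedness(params, rng, size=n)
    expresses = rng.random(n) < 0.5
    altruistic = rng.random(n) < 0.5
    return PopulationState(
        ids=np.arange(n, dtype=np.int64),
        age=age,
        energy=np.full(n, params.e_init),
        expresses=expresses,
        altruistic=altruistic,
        connectedness=conn,
        pain=np.zeros(n, dtype=np.int64),
        rng=rng,
    )


def default_population(params: ModelParams, seed: int) -> PopulationState:
    """The distinguished baseline ("default") initial population.

    Strategy combinations are assigned in exactly equal shares (n // 4
    agents each, any remainder spread in :data:`COMBO_LABELS` order), so
    the population starts at the centre of the space of random initial
    mixes; ages, energies and connectedness are drawn exactly as in
    :func:`init_population`.  Used by the baseline replicate protocols,
    where a single canonical starting population is wanted rather than
    an arbitrary (and possibly skewed) random draw.
    """
    if not isinstance(params, ModelParams):
        raise TypeError("params must be a ModelParams")
    rng = np.random.default_rng(seed)
    n = params.n_agents
    age = rng.integers(1, params.max_age + 1, size=n)
    conn = sample_connectedness(params, rng, size=n)
    code = np.arange(n) % 4
    expresses = np.isin(code, (0, 2))
    altruistic = np.isin(code, (0, 1))
    return PopulationState(
        ids=np.arange(n, dtype=np.int64),
        age=age,
        energy=np.full(n, params.e_init),
        expresses=expresses,
        altruistic=altruistic,
        connectedness=conn,
        pain=np.zeros(n, dtype=np.int64),
        rng=rng,
    )


def forage(state: PopulationState, params: ModelParams) -> PopulationState:
    """Healthy agents gain ``forage_gain`` energy, capped at ``e_max``;
    agents in pain cannot forage."""
    healthy = state.pain == 0
    state.energy[healthy] = np.minimum(
        state.energy[healthy] + params.forage_gain, params.e_max
    )
    return state


def select_injuries(
    state: PopulationState, params: ModelParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Injure up to ``n_injury`` (per 100 agents) healthy agents at random.

    Newly injured agents start a pain episode of ``t_p`` iterations;
    expressers pay the expression cost ``c_exp`` immediately (energy
    floored at 0 — a drained agent dies in the mortality phase).
    Returns the slot indices of the newly injured.
    """
    rng = state.rng if rng is None else rng
    target = int(round(params.n_injury * state.n_agents / 100))
    healthy = np.flatnonzero(state.pain == 0)
    k = min(target, healthy.size)
    if k == 0:
        return np.empty(0, dtype=np.intp)
    chosen = rng.choice(healthy, size=k, replace=False)
    state.pain[chosen] = params.t_p
    payers = chosen[state.expresses[chosen]]
    state.energy[payers] = np.maximum(0.0, state.energy[payers] - params.c_exp)
    return np.sort(chosen)


def select_interactions(
    state: PopulationState, params: ModelParams, rng: np.random.Generator | None = None
) -> list[tuple[int, int]]:
    """Pair each injured agent, with probability min(1, connectedness + s),
    with a uniformly random other agent.

    Each injured agent is the focal party of at most one encounter per
    iteration; partners may be healthy or injured and are drawn without
    regard to strategy.
    """
    rng = state.rng if rng is None else rng
    injured = np.flatnonzero(state.pain > 0)
    if injured.size == 0:
        return []
    p = np.clip(state.connectedness[injured] + params.s, 0.0, 1.0)
    interacting = injured[rng.random(injured.size) < p]
    pairs: list[tuple[int, int]] = []
    n = state.n_agents
    for i in interacting:
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        pairs.append((int(i), j))
    return pairs


def resolve_interaction(
    injured: Agent, partner: Agent, params: ModelParams
) -> InteractionOutcome:
    """Resolve one encounter between an injured focal agent and a partner.

    The outcome depends on the focal agent's expression strategy and, if
    the focal agent expresses and the partner is healthy, on the
    partner's altruism strategy:

    * focal suppresses -> nothing happens (need is invisible; the
      suppressor can neither be helped nor exploited);
    * partner also injured -> nothing happens (only healthy partners
      respond);
    * expressing focal meets healthy altruist -> focal is helped (pain
      cancelled), helper pays ``c_alt`` energy and gains ``b_alt``
      reputation (or, in ``b_alt_mode="energy"``, the helped agent gains
      ``b_alt`` energy instead);
    * expressing focal meets healthy non-altruist -> no help, partner
      loses ``c_self`` reputation, and — if exploitation is enabled —
      steals ``e_steal`` energy from the focal agent, capped so the
      victim's energy cannot go below 0 nor the thief's above ``e_max``.
    """
    if injured.pain_remaining <= 0:
        raise ValueError("focal agent of an interaction must be in pain")
    base = dict(injured_id=injured.id, partner_id=partner.id)
    if not injured.strategy.expresses or partner.pain_remaining > 0:
        return InteractionOutcome(injured_helped=False, **base)
    if partner.strategy.altruistic:
        if params.b_alt_mode == "energy":
            return InteractionOutcome(
                injured_helped=True,
                injured_energy_delta=params.b_alt,
                partner_energy_delta=-params.c_alt,
                **base,
            )
        return InteractionOutcome(
            injured_helped=True,
            partner_energy_delta=-params.c_alt,
            partner_connectedness_delta=params.b_alt,
            **base,
        )
    # ignored; exploitation on top when enabled
    stolen = min(params.e_steal, injured.energy)
    gained = (
        min(stolen, params.e_max - partner.energy)
        if params.steal_mode == "transfer"
        else 0.0
    )
    return InteractionOutcome(
        injured_helped=False,
        injured_energy_delta=-stolen,
        partner_energy_delta=gained,
        partner_connectedness_delta=-params.c_self,
        **base,
    )


def _apply_outcome(
    state: PopulationState, i: int, j: int, out: InteractionOutcome, params: ModelParams
) -> None:
    if out.injured_energy_delta:
        state.energy[i] = min(
            max(state.energy[i] + out.injured_energy_delta, 0.0), params.e_max
        )
    if out.partner_energy_delta:
        state.energy[j] = min(
            max(state.energy[j] + out.partner_energy_delta, 0.0), params.e_max
        )
    if out.partner_connectedness_delta:
        state.connectedness[j] = min(
            max(state.connectedness[j] + out.partner_connectedness_delta, params.conn_min),
            params.conn_max,
        )


def advance_pain(state: PopulationState, helped=()) -> PopulationState:
    """Helped agents recover now; everyone else in pain counts down one."""
    helped = np.asarray(list(helped), dtype=np.intp)
    if helped.size:
        state.pain[helped] = 0
    in_pain = state.pain > 0
    state.pain[in_pain] -= 1
    return state


def apply_mortality_and_replacement(
    state: PopulationState, params: ModelParams, rng: np.random.Generator | None = None
) -> PopulationState:
    """Remove the dead (energy spent or old age) and fill each slot with a
    newborn inheriting its strategy from two parents among the survivors.

    Parents are drawn per newborn: two distinct survivors with
    probability proportional to energy (``parent_rule="fitness"``), or
    the two highest-energy survivors (``parent_rule="top2"``).  Each
    trait is copied from one parent picked uniformly, independently of
    the other trait.  Newborns: age 1, energy ``e_init``, fresh
    connectedness draw, healthy.
    """
    rng = state.rng if rng is None else rng
    dead_mask = (state.energy <= 0.0) | (state.age >= params.max_age)
    dead = np.flatnonzero(dead_mask)
    if dead.size == 0:
        return state
    survivors = np.flatnonzero(~dead_mask)
    if survivors.size < 2:
        raise PopulationCollapse(
            f"only {survivors.size} agent(s) survived iteration {state.iteration}"
        )
    surv_expresses = state.expresses[survivors].copy()
    surv_altruistic = state.altruistic[survivors].copy()
    if params.parent_rule == "top2":
        # ties broken by slot order (stable sort on negated energy)
        order = np.argsort(-state.energy[survivors], kind="stable")[:2]
    else:
        w = state.energy[survivors]
        total = w.sum()
        probs = w / total if total > 0 else None
    m = survivors.size
    for slot in dead:
        if params.parent_rule == "top2":
            parents = order
        else:
            parents = rng.choice(m, size=2, replace=False, p=probs)
        state.expresses[slot] = surv_expresses[parents[rng.integers(2)]]
        state.altruistic[slot] = surv_altruistic[parents[rng.integers(2)]]
        state.age[slot] = 1
        state.energy[slot] = params.e_init
        state.connectedness[slot] = sample_connectedness(params, rng)
        state.pain[slot] = 0
        state.ids[slot] = state.next_id
        state.next_id += 1
    return state


def step(state: PopulationState, params: ModelParams) -> PopulationState:
    """Advance the population one iteration (in place).

    Order: forage -> injure -> interact -> pain countdown -> age ->
    death & replacement.  Raises :class:`PopulationCollapse` if fewer
    than two agents survive.
    """
    rng = state.rng
    forage(state, params)
    select_injuries(state, params, rng)
    pairs = select_interactions(state, params, rng)
    helped: list[int] = []
    for i, j in pairs:
        out = resolve_interaction(state.agent(i), state.agent(j), params)
        _apply_outcome(state, i, j, out, params)
        if out.injured_helped:
            helped.append(i)
    advance_pain(state, helped)
    state.age += 1
    apply_mortality_and_replacement(state, params, rng)
    state.iteration += 1
    return state
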