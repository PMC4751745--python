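"""Deterministic populations with known composition, for tests and demos."""

from __future__ import annotations

import numpy as np

from .core import PopulationState
from .params import ModelParams

__all__ = ["make_fixture_population", "FIXTURE_SCENARIOS"]

FIXTURE_SCENARIOS = (
    "all_alt_exp",
    "all_alt_nonexp",
    "all_nonalt_exp",
    "all_nonalt_nonexp",
    "half_expressers",
    "quarter_each",
    "one_injured_expresser_one_altruist",
)


def _uniform_population(
    params: ModelParams, expresses: np.ndarray, altruistic: np.ndarray, seed: int
) -> PopulationState:
    n = len(expresses)
    rng = np.random.default_rng(seed)
    mid = 0.5 * (params.conn_min + params.conn_max)
    return PopulationState(
        ids=np.arange(n, dtype=np.int64),
        age=np.full(n, 1, dtype=np.int64),
        energy=np.full(n, params.e_init),
        expresses=np.asarray(expresses, dtype=bool),
        altruistic=np.asarray(altruistic, dtype=bool),
        connectedness=np.full(n, mid),
        pain=np.zeros(n, dtype=np.int64),
        rng=rng,
    )


def make_fixture_population(
    scenario_name: str, params: ModelParams | None = None, seed: int = 0
) -> PopulationState:
    """A population of documented composition.

    Scenarios: ``all_<combo>`` (homogeneous in one of the four strategy
    combinations), ``half_expressers`` (expression split 50/50, altruism
    alternating within each half), ``quarter_each`` (the four
    combinations in equal blocks), and
    ``one_injured_expresser_one_altruist`` (a 2-agent trace fixture:
    slot 0 an injured expresser, slot 1 a healthy altruist).
    """
    params = ModelParams() if params is None else params
    n = params.n_agents
    if scenario_name.startswith("all_"):
        combo = scenario_name[4:]
        table = {
            "alt_exp": (True, True),
            "alt_nonexp": (False, True),
            "nonalt_exp": (True, False),
            "nonalt_nonexp": (False, False),
        }
        if combo not in table:
            raise ValueError(f"unknown fixture scenario {scenario_name!r}")
        exp, alt = table[combo]
        return _uniform_population(
            params, np.full(n, exp), np.full(n, alt), seed
        )
    if scenario_name == "half_expressers":
        expresses = np.arange(n) < n // 2
        altruistic = np.arange(n) % 2 == 0
        return _uniform_population(params, expresses, altruistic, seed)
    if scenario_name == "quarter_each":
        block = np.arange(n) * 4 // n
        expresses = np.isin(block, (0, 2))
        altruistic = np.isin(block, (0, 1))
        return _uniform_population(params, expresses, altruistic, seed)
    if scenario_name == "one_injured_expresser_one_altruist":
        p2 = params if params.n_agents == 2 else params.replace(n_agents=2)
        state = _uniform_population(
            p2, np.array([True, False]), np.array([False, True]), seed
        )
        state.pain[0] = max(params.t_p, 1)
        return state
    raise ValueError(f"unknown fixture scenario {scenario_name!r}")
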