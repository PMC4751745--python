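"""Full runs and replicate batches with reproducible seeding."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    PopulationCollapse,
    PopulationState,
    init_population,
    step,
)
from .params import ModelParams

__all__ = ["SimulationResult", "run_simulation", "run_replicates"]

SERIES_COLUMNS = (
    "iteration",
    "n_alt_exp",
    "n_alt_nonexp",
    "n_nonalt_exp",
    "n_nonalt_nonexp",
    "n_injured",
    "mean_energy",
    "mean_connectedness",
)


@dataclass
class SimulationResult:
    """Time series and final state of one run.

    ``counts`` has one row per recorded iteration with the four strategy
    combination counts in :data:`painsim.core.COMBO_LABELS` order; rows
    always sum to ``n_agents``.  ``fixed_at`` is set when the run was
    stopped early because a single strategy combination had taken over
    the whole population (an absorbing state: strategies never mutate,
    so the composition is constant from that iteration on).
    """

    params: ModelParams
    seed: int
    counts: np.ndarray
    injured: np.ndarray
    mean_energy: np.ndarray
    mean_connectedness: np.ndarray
    n_iterations_run: int
    iterations_requested: int
    terminated_early: bool
    fixed_at: int | None = None
    final_state: PopulationState | None = field(default=None, repr=False)

    @property
    def final_counts(self) -> np.ndarray:
        """Strategy-combination counts of the last recorded iteration."""
        return self.counts[-1]

    @property
    def final_proportions(self) -> np.ndarray:
        c = self.final_counts
        return c / c.sum()

    def counts_at(self, iteration: int) -> np.ndarray:
        """Composition at a 1-based iteration; runs that ended earlier
        (fixation or collapse) carry their last composition forward."""
        if iteration < 1:
            raise ValueError("iteration is 1-based")
        idx = min(iteration, self.n_iterations_run) - 1
        return self.counts[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-iteration series with the documented column contract."""
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.n_iterations_run + 1),
                "n_alt_exp": self.counts[:, 0],
                "n_alt_nonexp": self.counts[:, 1],
                "n_nonalt_exp": self.counts[:, 2],
                "n_nonalt_nonexp": self.counts[:, 3],
                "n_injured": self.injured,
                "mean_energy": self.mean_energy,
                "mean_connectedness": self.mean_connectedness,
            }
        )


def run_simulation(
    params: ModelParams,
    iterations: int,
    seed: int,
    initial_population: PopulationState | None = None,
    stop_on_fixation: bool = False,
    keep_final_state: bool = True,
) -> SimulationResult:
    """Run the model for ``iterations`` iterations from a fresh (or given)
    initial population.  Deterministic given (params, iterations, seed,
    initial_population).

    With ``stop_on_fixation`` the loop ends as soon as all agents share
    one strategy combination; this is exact for every strategy-based
    summary because fixation is absorbing.  A population collapse (fewer
    than 2 survivors) ends the run with ``terminated_early=True``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if initial_population is not None:
        state = initial_population.copy(rng=np.random.default_rng(seed))
    else:
        state = init_population(params, seed)
    if state.n_agents != params.n_agents:
        raise ValueError("initial population size does not match params.n_agents")
    counts = np.empty((iterations, 4), dtype=np.int64)
    injured = np.empty(iterations, dtype=np.int64)
    mean_energy = np.empty(iterations)
    mean_conn = np.empty(iterations)
    n = params.n_agents
    terminated = False
    fixed_at = None
    t = 0
    for t in range(iterations):
        try:
            step(state, params)
        except PopulationCollapse:
            # mortality aborts before any replacement, so the arrays still
            # hold the pre-removal population: record it as the last row
            terminated = True
            counts[t] = state.strategy_counts()
            injured[t] = int((state.pain > 0).sum())
            mean_energy[t] = state.energy.mean()
            mean_conn[t] = state.connectedness.mean()
            break
        counts[t] = state.strategy_counts()
        injured[t] = int((state.pain > 0).sum())
        mean_energy[t] = state.energy.mean()
        mean_conn[t] = state.connectedness.mean()
        if stop_on_fixation and counts[t].max() == n:
            fixed_at = t + 1
            break
    n_run = t + 1
    return SimulationResult(
        params=params,
        seed=seed,
        counts=counts[:n_run].copy(),
        injured=injured[:n_run].copy(),
        mean_energy=mean_energy[:n_run].copy(),
        mean_connectedness=mean_conn[:n_run].copy(),
        n_iterations_run=n_run,
        iterations_requested=iterations,
        terminated_early=terminated,
        fixed_at=fixed_at,
        final_state=state if keep_final_state else None,
    )


def run_replicates(
    params: ModelParams,
    iterations: int,
    n_trials: int,
    base_seed: int,
    shared_initial_population: bool = False,
    stop_on_fixation: bool = False,
    keep_final_state: bool = False,
    initial_population: PopulationState | None = None,
) -> list[SimulationResult]:
    """``n_trials`` independent runs with isolated seeds.

    Replicate ``k`` uses dynamics seed ``base_seed + 1 + k``.  With
    ``shared_initial_population`` all replicates start from the same
    population — ``initial_population`` if supplied, else one drawn with
    seed ``base_seed``; otherwise each replicate draws its own initial
    population from its dynamics seed.  Runs are independent of
    execution order.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if initial_population is not None:
        shared = initial_population
    elif shared_initial_population:
        shared = init_population(params, base_seed)
    else:
        shared = None
    results = []
    for k in range(n_trials):
        results.append(
            run_simulation(
                params,
                iterations,
                seed=base_seed + 1 + k,
                initial_population=shared,
                stop_on_fixation=stop_on_fixation,
                keep_final_state=keep_final_state,
            )
        )
    return results
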