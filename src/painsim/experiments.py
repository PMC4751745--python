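"""The six parameter-sweep experiments and the preliminary protocol.

Each experiment varies one parameter while the others stay at their
baseline values, runs a replicate batch per swept value, and reports the
mean final strategy proportions (with Monte-Carlo standard errors) and
the outcome-category distribution.

The preliminary protocol contrasts two batch designs — all replicates
started from one shared initial population versus each replicate drawing
its own — and tests whether the final strategy proportions differ.

``calibrate_defaults`` grid-searches small values of the two interaction
energy costs (expression cost ``c_exp``, helping cost ``c_alt``), which
have no canonical baseline, for the pair whose outcome distribution best
matches a reference outcome mix under baseline conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (
    OutcomeCategory,
    OutcomeDistribution,
    compare_conditions,
    outcome_distribution,
    per_run_proportions,
)
from .core import COMBO_LABELS, default_population
from .engine import SimulationResult, run_replicates
from .params import INT_FIELDS, ConfigurationError, ModelParams

__all__ = [
    "SweepSpec",
    "SweepResult",
    "PreliminaryResult",
    "run_sweep",
    "preliminary_protocol",
    "calibrate_defaults",
    "DEFAULT_GRIDS",
    "REFERENCE_OUTCOME_MIX",
]

SWEEPABLE = ("c_exp", "c_alt", "c_self", "b_alt", "s", "e_steal", "n_injury", "t_p")

#: Default sweep grids spanning each parameter's allowed range.
DEFAULT_GRIDS: dict[str, tuple] = {
    "c_exp": tuple(np.arange(0.0, 21.0, 2.0)),
    "c_alt": tuple(np.arange(0.0, 21.0, 2.0)),
    "c_self": tuple(np.round(np.arange(0.0, 1.01, 0.1), 2)),
    "b_alt": tuple(np.round(np.arange(0.0, 1.01, 0.1), 2)),
    "s": tuple(np.round(np.arange(0.0, 1.01, 0.1), 2)),
    "e_steal": (0.0, 5.0, 10.0, 15.0, 20.0),
    "n_injury": tuple(range(1, 11)),
    "t_p": tuple(range(0, 101, 10)),
}

#: Outcome mix under baseline conditions that the cost calibration
#: targets: proportions of batches ending in each category.
REFERENCE_OUTCOME_MIX: dict[OutcomeCategory, float] = {
    OutcomeCategory.NONALT_NONEXP: 0.60,
    OutcomeCategory.ALT_EXP: 0.24,
    OutcomeCategory.ALT_NONEXP: 0.06,
    OutcomeCategory.NONALT_EXP: 0.04,
    OutcomeCategory.MIXED_NONEXPRESSER: 0.04,
    OutcomeCategory.MIXED_EXPRESSER: 0.02,
}


@dataclass
class SweepSpec:
    """One parameter sweep: which parameter, over which values, at what
    replication."""

    param_name: str
    values: tuple
    n_trials: int = 100
    iterations: int = 10_000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.param_name not in SWEEPABLE:
            raise ConfigurationError(
                f"param_name={self.param_name!r} not sweepable ({SWEEPABLE})"
            )
        self.values = tuple(self.values)
        if not self.values:
            raise ConfigurationError("values must be non-empty")
        if self.n_trials < 1 or self.iterations < 1:
            raise ConfigurationError("n_trials and iterations must be >= 1")


@dataclass
class SweepResult:
    """Aggregated sweep output.

    ``table`` has one row per swept value: mean final proportion of each
    strategy combination across replicates (columns ``p_<combo>``),
    Monte-Carlo standard errors (``se_<combo>``), and the count of runs
    per outcome category.
    """

    spec: SweepSpec
    defaults: ModelParams
    table: pd.DataFrame
    distributions: list[OutcomeDistribution] = field(repr=False, default_factory=list)


def _override(defaults: ModelParams, name: str, value) -> ModelParams:
    value = int(value) if name in INT_FIELDS else float(value)
    return defaults.replace(**{name: value})


def run_sweep(
    spec: SweepSpec,
    defaults: ModelParams | None = None,
    stop_on_fixation: bool = False,
    shared_initial_population: bool = False,
) -> SweepResult:
    """Run one replicate batch per swept value and aggregate.

    Each value gets its own disjoint seed block derived from
    ``spec.base_seed`` so rows are independent and order-insensitive.
    """
    defaults = ModelParams.calibrated() if defaults is None else defaults
    rows = []
    dists = []
    for v_idx, value in enumerate(spec.values):
        params = _override(defaults, spec.param_name, value)
        seed = spec.base_seed + v_idx * (spec.n_trials + 1)
        results = run_replicates(
            params,
            spec.iterations,
            spec.n_trials,
            base_seed=seed,
            shared_initial_population=shared_initial_population,
            stop_on_fixation=stop_on_fixation,
        )
        props = per_run_proportions(results)
        dist = outcome_distribution(results)
        dists.append(dist)
        row = {spec.param_name: value}
        m = len(results)
        for k, label in enumerate(COMBO_LABELS):
            row[f"p_{label}"] = props[:, k].mean()
            # Monte-Carlo standard error; undefined for a single replicate
            row[f"se_{label}"] = (
                props[:, k].std(ddof=1) / np.sqrt(m) if m > 1 else np.nan
            )
        row["p_expresser"] = row["p_alt_exp"] + row["p_nonalt_exp"]
        row["p_altruist"] = row["p_alt_exp"] + row["p_alt_nonexp"]
        for cat in OutcomeCategory:
            row[f"n_{cat.value}"] = dist.counts.get(cat, 0)
        rows.append(row)
    return SweepResult(
        spec=spec, defaults=defaults, table=pd.DataFrame(rows), distributions=dists
    )


@dataclass
class PreliminaryResult:
    """Shared- vs fresh-initial-population batches plus their comparison."""

    shared: OutcomeDistribution
    fresh: OutcomeDistribution
    comparison: pd.DataFrame
    shared_runs: list[SimulationResult] = field(repr=False, default_factory=list)
    fresh_runs: list[SimulationResult] = field(repr=False, default_factory=list)


def preliminary_protocol(
    defaults: ModelParams | None = None,
    n_trials: int = 100,
    iterations: int = 10_000,
    base_seed: int = 0,
    stop_on_fixation: bool = False,
) -> PreliminaryResult:
    """Run the two preliminary batch designs and compare them.

    Batch A: ``n_trials`` runs from the shared *default* initial
    population (balanced strategy mix, see
    :func:`painsim.core.default_population`) with distinct dynamics
    seeds.  Batch B: ``n_trials`` runs each drawing a fresh random
    initial population.  The comparison is a per-strategy two-sample t
    test (plus variance F test) on the per-run final strategy
    proportions.
    """
    defaults = ModelParams.calibrated() if defaults is None else defaults
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    shared_runs = run_replicates(
        defaults,
        iterations,
        n_trials,
        base_seed=base_seed,
        shared_initial_population=True,
        initial_population=default_population(defaults, base_seed),
        stop_on_fixation=stop_on_fixation,
    )
    fresh_runs = run_replicates(
        defaults,
        iterations,
        n_trials,
        base_seed=base_seed + n_trials + 1,
        shared_initial_population=False,
        stop_on_fixation=stop_on_fixation,
    )
    return PreliminaryResult(
        shared=outcome_distribution(shared_runs),
        fresh=outcome_distribution(fresh_runs),
        comparison=compare_conditions(shared_runs, fresh_runs),
        shared_runs=shared_runs,
        fresh_runs=fresh_runs,
    )


def calibrate_defaults(
    c_exp_grid=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0),
    c_alt_grid=(0.0, 0.5, 1.0, 2.0, 3.0, 4.0),
    n_trials: int = 100,
    iterations: int = 10_000,
    base_seed: int = 0,
    defaults: ModelParams | None = None,
    target: dict[OutcomeCategory, float] | None = None,
    stop_on_fixation: bool = True,
) -> pd.DataFrame:
    """Grid-search (c_exp, c_alt) for the best match to a reference
    outcome mix under otherwise-baseline conditions.

    For each grid pair, runs a batch from the shared default (balanced)
    initial population, computes the outcome distribution, and scores it
    by total variation (half-L1) distance to the target mix.  Returns
    the scored grid sorted best first; the first row's pair is the
    calibrated default.
    """
    target = REFERENCE_OUTCOME_MIX if target is None else target
    base = ModelParams() if defaults is None else defaults
    rows = []
    block = 0
    for ce in c_exp_grid:
        for ca in c_alt_grid:
            params = base.replace(c_exp=float(ce), c_alt=float(ca))
            seed = base_seed + block * (n_trials + 1)
            results = run_replicates(
                params,
                iterations,
                n_trials,
                base_seed=seed,
                shared_initial_population=True,
                initial_population=default_population(params, seed),
                stop_on_fixation=stop_on_fixation,
            )
            block += 1
            dist = outcome_distribution(results)
            tv = 0.5 * sum(
                abs(dist.proportion(cat) - target.get(cat, 0.0))
                for cat in OutcomeCategory
            )
            row = {"c_exp": float(ce), "c_alt": float(ca), "tv_distance": tv}
            for cat in OutcomeCategory:
                row[f"p_{cat.value}"] = dist.proportion(cat)
            rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["tv_distance", "c_exp", "c_alt"], kind="stable", ignore_index=True
    )
    return table
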