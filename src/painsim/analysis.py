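"""Outcome classification and batch-level summaries.

A run's final population is classified by its strategy composition:
either one of the four pure fixation outcomes (every agent shares one
expression x altruism combination) or one of three mixed categories.
Batches of runs are summarized as outcome distributions and mean
strategy proportions, and two batches can be compared per strategy with
two-sample t tests (Welch and pooled) plus a variance-ratio F test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import COMBO_LABELS
from .engine import SimulationResult

__all__ = [
    "OutcomeCategory",
    "OutcomeDistribution",
    "classify_outcome",
    "classify_counts",
    "outcome_distribution",
    "strategy_proportions",
    "per_run_proportions",
    "compare_conditions",
]


class OutcomeCategory(str, enum.Enum):
    """Final-population categories.

    The four pure categories require 100% of agents sharing that
    combination (fixation).  MIXED_EXPRESSER / MIXED_NONEXPRESSER mean
    the expression trait is fixed but altruism is still mixed;
    MIXED_OTHER covers every other composition.
    """

    ALT_EXP = "ALT_EXP"
    ALT_NONEXP = "ALT_NONEXP"
    NONALT_EXP = "NONALT_EXP"
    NONALT_NONEXP = "NONALT_NONEXP"
    MIXED_EXPRESSER = "MIXED_EXPRESSER"
    MIXED_NONEXPRESSER = "MIXED_NONEXPRESSER"
    MIXED_OTHER = "MIXED_OTHER"


_PURE = {
    "alt_exp": OutcomeCategory.ALT_EXP,
    "alt_nonexp": OutcomeCategory.ALT_NONEXP,
    "nonalt_exp": OutcomeCategory.NONALT_EXP,
    "nonalt_nonexp": OutcomeCategory.NONALT_NONEXP,
}


def classify_counts(counts, dominance: float = 1.0) -> OutcomeCategory:
    """Classify a 4-vector of strategy-combination counts
    (alt_exp, alt_nonexp, nonalt_exp, nonalt_nonexp).

    ``dominance`` relaxes the pure categories for sensitivity analysis:
    a combination holding at least that fraction of agents counts as
    dominant.  At the default 1.0 a pure category means strict fixation.
    """
    counts = np.asarray(counts)
    if counts.shape != (4,) or counts.sum() == 0:
        raise ValueError("counts must be 4 non-negative values with a positive sum")
    n = counts.sum()
    top = int(np.argmax(counts))
    if counts[top] >= dominance * n:
        return _PURE[COMBO_LABELS[top]]
    n_exp = counts[0] + counts[2]
    if n_exp == n:
        return OutcomeCategory.MIXED_EXPRESSER
    if n_exp == 0:
        return OutcomeCategory.MIXED_NONEXPRESSER
    return OutcomeCategory.MIXED_OTHER


def classify_outcome(
    result: SimulationResult, dominance: float = 1.0
) -> OutcomeCategory:
    """Classify a run by its last recorded composition (early-terminated
    runs are classified from the composition they ended with)."""
    return classify_counts(result.final_counts, dominance=dominance)


@dataclass
class OutcomeDistribution:
    """Counts and proportions of outcome categories over a batch."""

    counts: dict[OutcomeCategory, int]
    n_trials: int

    @property
    def proportions(self) -> dict[OutcomeCategory, float]:
        return {c: k / self.n_trials for c, k in self.counts.items()}

    def proportion(self, category: OutcomeCategory) -> float:
        return self.counts.get(category, 0) / self.n_trials

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [c.value for c in OutcomeCategory],
                "count": [self.counts.get(c, 0) for c in OutcomeCategory],
                "proportion": [self.proportion(c) for c in OutcomeCategory],
            }
        )


def outcome_distribution(
    results: list[SimulationResult], dominance: float = 1.0
) -> OutcomeDistribution:
    """Tally outcome categories over a non-empty batch of runs."""
    if not results:
        raise ValueError("need at least one run")
    counts: dict[OutcomeCategory, int] = {}
    for r in results:
        c = classify_outcome(r, dominance=dominance)
        counts[c] = counts.get(c, 0) + 1
    return OutcomeDistribution(counts=counts, n_trials=len(results))


def strategy_proportions(
    results: list[SimulationResult], at_iteration: int | None = None
) -> np.ndarray:
    """Mean fraction of agents holding each strategy combination, in
    (alt_exp, alt_nonexp, nonalt_exp, nonalt_nonexp) order; sums to 1.

    ``at_iteration`` reads the composition at that (1-based) iteration;
    runs that ended earlier carry their final composition forward (exact
    for fixated runs; the documented convention for collapsed ones).
    Default: each run's last composition.
    """
    if not results:
        raise ValueError("need at least one run")
    rows = []
    for r in results:
        c = r.final_counts if at_iteration is None else r.counts_at(at_iteration)
        rows.append(c / c.sum())
    return np.mean(rows, axis=0)


def per_run_proportions(
    results: list[SimulationResult], at_iteration: int | None = None
) -> np.ndarray:
    """(n_runs, 4) array of per-run strategy proportions."""
    rows = [
        (r.final_counts if at_iteration is None else r.counts_at(at_iteration))
        for r in results
    ]
    rows = np.asarray(rows, dtype=float)
    return rows / rows.sum(axis=1, keepdims=True)


def compare_conditions(a, b) -> pd.DataFrame:
    """Compare two batches of per-run strategy proportions per strategy.

    ``a`` and ``b`` are (n_runs, 4) arrays (see
    :func:`per_run_proportions`) or lists of SimulationResult.  Returns
    one row per strategy combination with Welch and pooled two-sample t
    statistics and a two-sided variance-ratio F test.  When a strategy
    has zero variance in both batches the comparison is degenerate and
    reported as t = 0, p = 1 if the means agree (p = 0 otherwise).
    """
    if isinstance(a, (list, tuple)) and a and isinstance(a[0], SimulationResult):
        a = per_run_proportions(a)
    if isinstance(b, (list, tuple)) and b and isinstance(b[0], SimulationResult):
        b = per_run_proportions(b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 4 or b.shape[1] != 4:
        raise ValueError("expected (n_runs, 4) proportion arrays")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each batch needs at least 2 runs")
    rows = []
    for k, label in enumerate(COMBO_LABELS):
        x, y = a[:, k], b[:, k]
        degenerate = x.var(ddof=1) == 0 and y.var(ddof=1) == 0
        if degenerate:
            equal = x.mean() == y.mean()
            t_w = t_p = 0.0 if equal else np.inf
            p_w = p_p = 1.0 if equal else 0.0
            f_stat, p_f = np.nan, 1.0
        else:
            t_w, p_w = stats.ttest_ind(x, y, equal_var=False)
            t_p, p_p = stats.ttest_ind(x, y, equal_var=True)
            vx, vy = x.var(ddof=1), y.var(ddof=1)
            if vy == 0:
                f_stat, p_f = np.inf, 0.0
            else:
                f_stat = vx / vy
                dfx, dfy = len(x) - 1, len(y) - 1
                cdf = stats.f.cdf(f_stat, dfx, dfy)
                p_f = 2 * min(cdf, 1 - cdf)
        rows.append(
            {
                "strategy": label,
                "mean_a": x.mean(),
                "mean_b": y.mean(),
                "t_welch": t_w,
                "p_welch": p_w,
                "t_pooled": t_p,
                "p_pooled": p_p,
                "f_stat": f_stat,
                "p_f": p_f,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
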