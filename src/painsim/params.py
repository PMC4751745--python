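"""Model parameters and their validation.

Every cost, benefit and environmental rate of the simulation lives in
:class:`ModelParams`.  Defaults are the baseline conditions of the model:
a population of 100 agents, lifespan 100 iterations, energy 10 of a
maximum 20 at birth, foraging gain 1 per iteration, reputation benefit
and cost ``b_alt = c_self = 0.5``, recovery time ``t_p = 50``, sociability
offset ``s = 0``, one injury per 100 agents per iteration, and no
exploitation (``e_steal = 0``).

The two interaction energy costs ``c_exp`` (expressing pain) and ``c_alt``
(helping) have no canonical baseline; the shipped defaults come from the
calibration routine in :mod:`painsim.experiments` (see
:func:`painsim.experiments.calibrate_defaults` and docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


class ConfigurationError(ValueError):
    """A parameter or configuration value is outside its allowed range."""


#: (c_exp, c_alt) selected by the documented calibration grid search
#: (see docs/methods.md, "Calibrating the interaction costs").
CALIBRATED_COSTS: dict[str, float] = {"c_exp": 4.0, "c_alt": 2.0}


@dataclass
class ModelParams:
    """All tunable parameters of the model, with range validation.

    Attributes
    ----------
    n_agents:
        Population size (constant over a run; deaths are replaced).
    max_age:
        Lifespan in iterations; an agent reaching it dies that iteration.
    e_init, e_max, forage_gain:
        Energy at birth, energy ceiling, and foraging gain per healthy
        iteration, in energy units.
    c_exp:
        Energy cost of expressing pain, charged once at injury onset,
        range [0, 20].
    c_alt:
        Energy cost of helping an expressing injured agent, range [0, 20].
    b_alt:
        Connectedness (reputation) gained by a helper, range [0, 1].
        With ``b_alt_mode="energy"`` it is instead an energy gain to the
        helped agent.
    c_self:
        Connectedness lost by a healthy agent that ignores an expressing
        injured agent, range [0, 1].
    t_p:
        Time in pain: iterations an injured agent cannot forage unless
        helped, range [0, 100].
    s:
        Sociability: environment-wide additive offset to the interaction
        probability of injured agents, range [0, 1].
    n_injury:
        New injuries per iteration per 100 agents, range [1, 10].
    e_steal:
        Energy a healthy non-altruist steals from an expressing injured
        agent; 0 (no exploitation) or in [5, 20].
    conn_min, conn_max, conn_rate:
        Bounds of the connectedness index and the rate of the shifted
        exponential it is drawn from at birth.
    b_alt_mode:
        "connectedness" (default): ``b_alt`` raises the helper's
        reputation.  "energy": ``b_alt`` is an energy benefit to the
        helped agent instead.
    parent_rule:
        "fitness" (default): parents drawn with probability proportional
        to energy among survivors.  "top2": the two highest-energy
        survivors parent every newborn of the iteration.
    steal_mode:
        "transfer" (default): stolen energy goes to the thief (capped at
        its energy ceiling).  "destroy": stolen energy is simply lost.
    """

    n_agents: int = 100
    max_age: int = 100
    e_init: float = 10.0
    e_max: float = 20.0
    forage_gain: float = 1.0
    c_exp: float = 1.0
    c_alt: float = 1.0
    b_alt: float = 0.5
    c_self: float = 0.5
    t_p: int = 50
    s: float = 0.0
    n_injury: int = 1
    e_steal: float = 0.0
    conn_min: float = 0.1
    conn_max: float = 0.9
    conn_rate: float = 10.0
    b_alt_mode: str = "connectedness"
    parent_rule: str = "fitness"
    steal_mode: str = "transfer"

    def __post_init__(self) -> None:
        def check(name: str, lo, hi) -> None:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(
                    f"{name}={v!r} outside allowed range [{lo}, {hi}]"
                )

        if self.n_agents < 1:
            raise ConfigurationError(f"n_agents={self.n_agents} must be >= 1")
        if self.max_age < 1:
            raise ConfigurationError(f"max_age={self.max_age} must be >= 1")
        check("e_init", 0.0, self.e_max)
        if self.e_max <= 0:
            raise ConfigurationError(f"e_max={self.e_max} must be > 0")
        if self.forage_gain < 0:
            raise ConfigurationError(f"forage_gain={self.forage_gain} must be >= 0")
        check("c_exp", 0.0, 20.0)
        check("c_alt", 0.0, 20.0)
        check("b_alt", 0.0, 1.0)
        check("c_self", 0.0, 1.0)
        check("t_p", 0, 100)
        check("s", 0.0, 1.0)
        check("n_injury", 1, 10)
        if self.e_steal != 0.0 and not (5.0 <= self.e_steal <= 20.0):
            raise ConfigurationError(
                f"e_steal={self.e_steal} must be 0 or within [5, 20]"
            )
        if not (0.0 < self.conn_min < self.conn_max):
            raise ConfigurationError(
                f"need 0 < conn_min < conn_max, got {self.conn_min}, {self.conn_max}"
            )
        if self.conn_rate <= 0:
            raise ConfigurationError(f"conn_rate={self.conn_rate} must be > 0")
        if self.b_alt_mode not in ("connectedness", "energy"):
            raise ConfigurationError(f"b_alt_mode={self.b_alt_mode!r} unknown")
        if self.parent_rule not in ("fitness", "top2"):
            raise ConfigurationError(f"parent_rule={self.parent_rule!r} unknown")
        if self.steal_mode not in ("transfer", "destroy"):
            raise ConfigurationError(f"steal_mode={self.steal_mode!r} unknown")

    @classmethod
    def calibrated(cls, **overrides) -> "ModelParams":
        """Baseline parameters with the calibrated interaction costs."""
        merged = {**CALIBRATED_COSTS, **overrides}
        return cls(**merged)

    def replace(self, **changes) -> "ModelParams":
        """A copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def params_hash(self) -> str:
        """Short stable hash of the parameter set, for provenance logging."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


#: ModelParams fields whose values are integers (coerced on config load).
INT_FIELDS = {"n_agents", "max_age", "t_p", "n_injury"}

PARAM_FIELDS = tuple(f.name for f in dataclasses.fields(ModelParams))
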