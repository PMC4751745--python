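"""Configuration files, result serialization and provenance.

Configs are flat YAML or JSON mappings: one key per model parameter plus
run-level keys (``iterations``, ``seed``, ``mode``, ``trials``,
``sweep``, ``out``).  Unknown keys are rejected with the offending name.

Results round-trip losslessly: a single run to JSON, a batch to
JSON-lines (one run per line), per-iteration series to CSV with the
documented column contract.  Every output embeds the parameter hash,
seed and package version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import OutcomeDistribution, OutcomeCategory, classify_outcome
from .engine import SERIES_COLUMNS, SimulationResult
from .experiments import SweepResult, SweepSpec
from .params import INT_FIELDS, PARAM_FIELDS, ConfigurationError, ModelParams

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_results",
    "read_results",
    "write_series_csv",
    "sweep_table_long",
    "write_sweep",
]

MODES = ("run", "replicate", "sweep", "preliminary", "calibrate")

RUN_KEYS = ("iterations", "seed", "mode", "trials", "sweep", "out",
            "shared_initial_population", "stop_on_fixation")
SWEEP_KEYS = ("param_name", "values", "n_trials", "iterations", "base_seed")


@dataclass
class RunConfig:
    """A validated run request: model parameters plus execution settings."""

    model: ModelParams = field(default_factory=ModelParams)
    iterations: int = 10_000
    seed: int = 0
    mode: str = "run"
    trials: int = 100
    sweep: SweepSpec | None = None
    out: str | None = None
    shared_initial_population: bool = False
    stop_on_fixation: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode={self.mode!r} not one of {MODES}")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.trials < 1:
            raise ConfigurationError("trials must be >= 1")
        if self.mode == "sweep" and self.sweep is None:
            raise ConfigurationError("mode 'sweep' requires a 'sweep' section")

    def to_dict(self) -> dict:
        d: dict = dict(self.model.to_dict())
        d.update(
            iterations=self.iterations,
            seed=self.seed,
            mode=self.mode,
            trials=self.trials,
            out=self.out,
            shared_initial_population=self.shared_initial_population,
            stop_on_fixation=self.stop_on_fixation,
        )
        if self.sweep is not None:
            d["sweep"] = {
                "param_name": self.sweep.param_name,
                "values": list(self.sweep.values),
                "n_trials": self.sweep.n_trials,
                "iterations": self.sweep.iterations,
                "base_seed": self.sweep.base_seed,
            }
        return d


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    unknown = set(raw) - set(PARAM_FIELDS) - set(RUN_KEYS)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )
    model_kwargs = {}
    for name in PARAM_FIELDS:
        if name in raw:
            v = raw.pop(name)
            model_kwargs[name] = int(v) if name in INT_FIELDS else v
    sweep_raw = raw.pop("sweep", None)
    sweep = None
    if sweep_raw is not None:
        bad = set(sweep_raw) - set(SWEEP_KEYS)
        if bad:
            raise ConfigurationError(
                f"unknown sweep key(s): {', '.join(sorted(bad))}"
            )
        sweep = SweepSpec(**sweep_raw)
    return RunConfig(model=ModelParams(**model_kwargs), sweep=sweep, **raw)


def load_config(path) -> RunConfig:
    """Read and validate a YAML or JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    return config_from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _provenance(params: ModelParams, seed: int) -> dict:
    return {"params_hash": params.params_hash(), "seed": seed, "version": __version__}


def result_to_dict(result: SimulationResult, include_series: bool = True) -> dict:
    d = {
        "params": result.params.to_dict(),
        "seed": result.seed,
        "n_iterations_run": result.n_iterations_run,
        "iterations_requested": result.iterations_requested,
        "terminated_early": result.terminated_early,
        "fixed_at": result.fixed_at,
        "classification": classify_outcome(result).value,
        "final_counts": result.final_counts.tolist(),
        "provenance": _provenance(result.params, result.seed),
    }
    if include_series:
        d["series"] = {
            "counts": result.counts.tolist(),
            "injured": result.injured.tolist(),
            "mean_energy": result.mean_energy.tolist(),
            "mean_connectedness": result.mean_connectedness.tolist(),
        }
    return d


def result_from_dict(d: dict) -> SimulationResult:
    series = d.get("series")
    if series is None:
        raise ValueError("cannot rebuild a SimulationResult without its series")
    return SimulationResult(
        params=ModelParams(**d["params"]),
        seed=d["seed"],
        counts=np.asarray(series["counts"], dtype=np.int64),
        injured=np.asarray(series["injured"], dtype=np.int64),
        mean_energy=np.asarray(series["mean_energy"]),
        mean_connectedness=np.asarray(series["mean_connectedness"]),
        n_iterations_run=d["n_iterations_run"],
        iterations_requested=d["iterations_requested"],
        terminated_early=d["terminated_early"],
        fixed_at=d["fixed_at"],
    )


def write_results(results, path, include_series: bool = True) -> None:
    """Write one run as JSON or a batch as JSON-lines (one run/line)."""
    path = Path(path)
    if isinstance(results, SimulationResult):
        path.write_text(json.dumps(result_to_dict(results, include_series), indent=2))
        return
    with path.open("w") as fh:
        for r in results:
            fh.write(json.dumps(result_to_dict(r, include_series)))
            fh.write("\n")


def read_results(path):
    """Inverse of :func:`write_results` (series must be present)."""
    path = Path(path)
    text = path.read_text().strip()
    if text.startswith("{"):
        try:
            return result_from_dict(json.loads(text))
        except json.JSONDecodeError:
            pass  # multi-line JSON-lines batch
    return [result_from_dict(json.loads(line)) for line in text.splitlines() if line]


def write_series_csv(result: SimulationResult, path) -> None:
    """Per-iteration series as CSV with the documented column order."""
    frame = result.to_frame()[list(SERIES_COLUMNS)]
    frame.to_csv(path, index=False)


def distribution_to_dict(dist: OutcomeDistribution) -> dict:
    return {
        "n_trials": dist.n_trials,
        "counts": {c.value: dist.counts.get(c, 0) for c in OutcomeCategory},
    }


def distribution_from_dict(d: dict) -> OutcomeDistribution:
    counts = {
        OutcomeCategory(k): v for k, v in d["counts"].items() if v
    }
    return OutcomeDistribution(counts=counts, n_trials=d["n_trials"])


def sweep_table_long(sweep: SweepResult) -> pd.DataFrame:
    """Tidy long table: one row per (swept value, strategy combination)."""
    name = sweep.spec.param_name
    rows = []
    for _, r in sweep.table.iterrows():
        for label in ("alt_exp", "alt_nonexp", "nonalt_exp", "nonalt_nonexp"):
            rows.append(
                {
                    "param": name,
                    "value": r[name],
                    "strategy": label,
                    "proportion": r[f"p_{label}"],
                    "se": r[f"se_{label}"],
                }
            )
    return pd.DataFrame(rows)


def write_sweep(sweep: SweepResult, path, long_format: bool = True) -> None:
    """Sweep summary as CSV (tidy long by default, wide otherwise)."""
    frame = sweep_table_long(sweep) if long_format else sweep.table
    frame.to_csv(path, index=False)
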