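"""Exploitation, injury frequency and recovery time.

Three small sweeps of environmental harshness:

* e_steal — when healthy non-altruists can rob an injured expresser,
  expressing pain becomes a liability and disappears, while altruism
  (no longer exercised) persists by drift;
* n_injury — a more dangerous environment depresses both expression and
  helping;
* t_p — longer recovery raises the cost of suffering in silence, so
  expression grows with t_p, but only to about half the population.
"""

from painsim import ModelParams, SweepSpec, run_sweep

base = ModelParams.calibrated()
for pname, values in (
    ("e_steal", (0.0, 5.0, 10.0, 20.0)),
    ("n_injury", (1, 4, 7, 10)),
    ("t_p", (0, 25, 50, 75, 100)),
):
    spec = SweepSpec(
        param_name=pname, values=values, n_trials=20, iterations=5_000, base_seed=11
    )
    sweep = run_sweep(spec, base, stop_on_fixation=True)
    print(sweep.table[[pname, "p_expresser", "p_altruist"]].to_string(index=False))
    print()
print(
    "p_expresser / p_altruist are mean final fractions of agents carrying "
    "the expressing / helping trait, averaged over 20 replicates."
)
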