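"""Does the particular initial population matter?

Compares two batch designs: 30 runs restarted from one shared initial
population (only the dynamics seed differs) versus 30 runs each drawing
a fresh initial population.  A per-strategy two-sample t test on the
final strategy proportions shows whether outcome variability comes from
the stochastic dynamics or from the initial draw — high p-values mean
the initial population is not what decides the outcome.
"""

from painsim import ModelParams, preliminary_protocol

res = preliminary_protocol(
    ModelParams.calibrated(), n_trials=30, iterations=5_000, base_seed=3,
    stop_on_fixation=True,
)
print("shared initial population:")
print(res.shared.to_frame().to_string(index=False))
print("\nfresh initial populations:")
print(res.fresh.to_frame().to_string(index=False))
print("\nper-strategy comparison (Welch t, pooled t, variance F):")
print(
    res.comparison[["strategy", "mean_a", "mean_b", "p_welch", "p_pooled", "p_f"]]
    .to_string(index=False)
)
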