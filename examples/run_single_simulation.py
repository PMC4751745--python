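"""One simulation at baseline conditions, from initial mix to fixation.

Runs 10,000 iterations of a 100-agent population and prints the final
strategy composition and outcome category.  Most runs end with a single
expression x altruism strategy combination owning the whole population.
"""

from painsim import ModelParams, classify_outcome, run_simulation

params = ModelParams.calibrated()
result = run_simulation(params, iterations=10_000, seed=42)

frame = result.to_frame()
print(frame.head())
print("...")
print(frame.tail())

labels = ("alt_exp", "alt_nonexp", "nonalt_exp", "nonalt_nonexp")
print("\nfinal composition (agents per strategy combination):")
for label, n in zip(labels, result.final_counts):
    print(f"  {label:>14}: {n}")
print("outcome category:", classify_outcome(result).value)
print(
    "\nThe composition above is the population at the last iteration; the "
    "outcome category says whether one strategy combination took over "
    "completely (fixation) or the run ended mixed."
)
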