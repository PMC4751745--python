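# painsim

Agent-based simulation of the evolution of pain expression and of
altruistic responses to others' pain.

## The problem

Displaying pain is a costly signal: it can summon help from conspecifics,
but it also advertises vulnerability to exploitation. Whether expressing
pain — and whether helping those who express it — can persist over
evolutionary time is hard to study observationally. `painsim` explores
the question in silico: a population of generic social foragers carries
two heritable binary strategies, *express vs suppress* pain when injured
and *help vs ignore* an injured agent that expresses, and the balance of
strategies evolves through energy-mediated selection.

Each of 100 agents forages (+1 energy per iteration, ceiling 20), is
randomly injured (`n_injury` per 100 per iteration), and while in pain
(`t_p` iterations, unless helped) cannot forage. An injured expresser
pays the expression cost `c_exp` and, with probability
`min(1, connectedness + s)`, meets a random partner: a healthy altruist
helps (ending the pain episode) at energy cost `c_alt` and reputation
gain `b_alt`; a healthy non-altruist ignores (reputation loss `c_self`)
and, if exploitation is enabled, steals `e_steal` energy from the
victim. Suppressors are invisible: never helped, never robbed. Agents
die at age 100 or energy 0 and are replaced by offspring of
energy-proportionally selected parents, inheriting each strategy trait
from one parent. Runs are classified by their final composition —
usually one strategy combination reaches fixation.

The package provides the model core, a reproducible simulation engine,
outcome classification and batch statistics, the six standard parameter
sweeps (costs of expression and helping, reputation effects, sociability,
exploitation, injury frequency, recovery time), a calibration routine
for the two interaction costs, and a thin CLI. See `docs/methods.md`
for the full model description and design rationale.

## A worked example

```python
from painsim import (
    ModelParams, default_population, outcome_distribution, run_replicates,
)

params = ModelParams.calibrated()        # baseline + calibrated costs
runs = run_replicates(
    params, iterations=10_000, n_trials=100, base_seed=1,
    shared_initial_population=True,
    initial_population=default_population(params, 1),
    stop_on_fixation=True,
)
print(outcome_distribution(runs).to_frame().to_string(index=False))
```

prints (seed 1):

```
          category  count  proportion
           ALT_EXP     20        0.20
        ALT_NONEXP     23        0.23
        NONALT_EXP      9        0.09
     NONALT_NONEXP     42        0.42
   MIXED_EXPRESSER      0        0.00
MIXED_NONEXPRESSER      5        0.05
       MIXED_OTHER      1        0.01
```

Each row is the share of the 100 replicate histories ending in that
outcome: `NONALT_NONEXP` means every agent ended suppressing pain and
ignoring others (the modal, "asocial" outcome); `ALT_EXP` means pain
expression plus helping took over — evolutionarily viable in a fifth of
histories; the `MIXED_*` rows are runs where the expression trait had
fixed but altruism was still drifting after 10,000 iterations.

Narrative scripts in `examples/` cover each capability: a single run,
the outcome distribution, the expression-cost sweep, exploitation and
environmental harshness, and the initial-population sensitivity check.
The same operations are available from the shell:

```bash
painsim run --seed 1 --iterations 10000
painsim sweep --param c_exp --trials 20 --iterations 5000 --seed 7
painsim replicate --trials 100 --seed 1
painsim calibrate-defaults --trials 50
```

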