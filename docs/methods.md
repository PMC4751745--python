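# Methods

## The model

A population of `n_agents` (default 100) generic social foragers evolves
over discrete iterations. Each agent carries:

* **age** — increments every iteration; at `max_age` (100) the agent dies;
* **energy** — the fitness currency, starting at `e_init = 10` of a
  ceiling `e_max = 20`; healthy agents gain `forage_gain = 1` per
  iteration (capped); an agent whose energy reaches 0 dies;
* two heritable, lifelong boolean strategies — **expression** (display
  pain when injured, visible to partners, or suppress it) and
  **altruism** (help an expressing injured partner, or ignore it);
* **connectedness** — a reputation/sociability index in
  `[conn_min, conn_max] = [0.1, 0.9]`, drawn at birth from a shifted
  exponential (`conn_min + Exp(rate = conn_rate)`, truncated above), so
  most agents sit near the floor and few are highly connected;
* **pain_remaining** — iterations left in the current pain episode
  (0 = healthy).

Each iteration applies, in order:

1. **Foraging.** Healthy agents gain energy; agents in pain cannot forage
   (this is the main cost of injury).
2. **Injury.** `n_injury` per 100 agents of the currently healthy are
   injured uniformly at random: `pain_remaining := t_p`, and expressers
   immediately pay the expression cost `c_exp` (energy floored at 0; a
   drained agent dies in phase 6).
3. **Interactions.** Every agent in pain enters at most one encounter,
   with probability `min(1, connectedness + s)`; its partner is uniform
   among the other agents. Outcomes:
   * focal suppresses, or the partner is itself in pain → nothing;
   * partner healthy altruist → focal is *helped*: its pain ends this
     iteration; the helper pays `c_alt` energy and gains `b_alt`
     connectedness;
   * partner healthy non-altruist → no help; the partner loses `c_self`
     connectedness; if exploitation is enabled (`e_steal > 0`) it also
     steals `e_steal` energy from the focal agent, capped so the victim
     cannot go below 0 nor the thief above `e_max`.
4. **Pain countdown.** Helped agents recover now; everyone else in pain
   counts down one iteration.
5. **Ageing.**
6. **Death and replacement.** Agents at `max_age` or with no energy are
   removed. Each vacancy is filled by a newborn (age 1, energy `e_init`,
   fresh connectedness draw, healthy) whose two distinct parents are
   drawn from the survivors with probability proportional to energy;
   each strategy trait is copied from one parent chosen uniformly,
   independently of the other trait. If fewer than two agents survive,
   the run terminates (population collapse) and is flagged.

Strategies never mutate, so once all agents share one expression x
altruism combination the composition is absorbed ("fixation").

## Outcome classification

A finished run is classified from its final composition: one of four
pure categories (`ALT_EXP`, `ALT_NONEXP`, `NONALT_EXP`, `NONALT_NONEXP`)
when a single combination holds 100% of agents, `MIXED_EXPRESSER` /
`MIXED_NONEXPRESSER` when the expression trait is fixed but altruism is
not, and `MIXED_OTHER` otherwise. The 100% requirement can be relaxed
via a dominance threshold for sensitivity analysis, but the default is
strict fixation. Collapsed runs are classified from the composition at
the moment of collapse and carry a flag.

## Design choices where the design was open

* **Phase order.** The processes are fixed in the order above; it
  guarantees that an agent injured this iteration already misses this
  iteration's foraging.
* **Expression cost timing.** `c_exp` is charged once, at injury onset,
  not per iteration in pain; this keeps `c_exp ∈ [0, 20]` on the same
  scale as the energy ceiling.
* **Help effect.** Being helped cancels the whole remaining pain episode
  (the helped agent forages again the next iteration); no partial
  recovery is modelled.
* **`b_alt` semantics.** By default `b_alt` is a reputation
  (connectedness) benefit to the *helper*. An alternative reading —
  an energy benefit to the *helped* agent — is available as
  `b_alt_mode="energy"`; the reputation reading is the default because
  it is what gives helping a selectable return (access to future help).
* **Interaction model.** Injured agents are the focal parties;
  interaction probability is `min(1, connectedness + s)`; one encounter
  per injured agent per iteration; partners uniform. Healthy–healthy
  encounters are outcome-free and therefore not simulated.
* **Parent selection.** Fitness-proportional sampling of two distinct
  parents per newborn approximates "offspring of the highest-energy
  survivors" without locking inheritance onto a deterministic top pair;
  `parent_rule="top2"` provides the literal variant. With all survivor
  energies zero the draw degenerates to uniform.
* **Exploitation bookkeeping.** Stolen energy is transferred to the
  thief by default (`steal_mode="transfer"`, capped at the thief's
  headroom); `"destroy"` discards it instead. Exploitation happens in
  every non-altruist × expresser encounter whenever `e_steal > 0`;
  being ignored and being robbed are not alternatives.
* **Connectedness bounds.** The index is clamped to `[0.1, 0.9]` after
  every reputation update, preserving at all times the range it is
  born into.
* **Initial strategies.** Random populations draw each trait as an
  independent Bernoulli(1/2) per agent. The *default* initial
  population (`default_population`) is a distinguished balanced draw —
  exactly n/4 agents per strategy combination, ages and connectedness
  still random — used wherever a single canonical starting population
  is wanted (the baseline replicate batch, calibration, the
  shared-vs-fresh comparison). A single random draw is materially
  skewed half the time (a binomial 100-agent draw easily starts 10
  points off-centre), which would bias an entire shared-start batch;
  the balanced draw is the centre of the random-draw distribution.
* **RNG.** One seeded `numpy` PCG64 generator per run. Replicate `k` of
  a batch uses dynamics seed `base_seed + 1 + k`; in the
  shared-initial-population design the initial population is drawn once
  with seed `base_seed`.

## Calibrating the interaction costs

The expression cost `c_exp` and helping cost `c_alt` have no canonical
baseline value. `painsim.experiments.calibrate_defaults` grid-searches
small (c_exp, c_alt) pairs, scoring each by the total-variation distance
between its simulated outcome distribution (batches of
shared-initial-population runs at baseline conditions) and the reference
outcome mix `REFERENCE_OUTCOME_MIX` (60% non-altruistic non-expresser,
24% altruistic expresser, 6% altruistic non-expresser, 4% non-altruistic
expresser, 4% mixed non-expresser, 2% mixed expresser). The shipped
calibrated pair is `CALIBRATED_COSTS = (c_exp=4, c_alt=2)`, the best
scorer over grids spanning c_exp 0–8 and c_alt 0–4 with the leading
candidates re-scored at 200 trials x 10,000 iterations;
`ModelParams.calibrated()` returns baseline parameters with it applied.
The CLI verb `painsim calibrate-defaults` reruns the search.

Two alternative readings were scored by the same procedure and
rejected: the "energy benefit to the helped agent" semantics of
`b_alt` matched the reference mix strictly worse at every grid point,
and `parent_rule="top2"` fixates within hundreds of iterations with
extreme founder effects and no mixed outcomes at 10,000 iterations,
which contradicts the slow-drift regime the reference mix implies
(6% of runs still mixed at 10,000 iterations).

## Early stopping at fixation

`stop_on_fixation=True` ends a run as soon as one strategy combination
owns the whole population. Because strategies are inherited from
survivors and never mutate, fixation is absorbing: every strategy-based
summary (classification, final strategy proportions) from a stopped run
is *identical* to the full-length run's. Energy/connectedness series
after the stopping point are simply not recorded, so analyses of those
series should run full length. The heavy batch protocols (acceptance
reproduction, examples) use the shortcut; the default is off.

## Problem sizes

Paper-scale protocols use 100 replicates of 10,000 iterations. The
packaged trend suite samples each sweep at a reduced design — 20–30
replicates of 3,000–5,000 iterations per swept value on coarsened grids
— chosen as the smallest design at which the qualitative contrasts are
statistically unambiguous (Spearman trend tests at p < 0.05). Reported
Monte-Carlo standard errors quantify the replication noise at any scale.

## What the simulation does and does not emulate

The generator produces the study conditions themselves (no external
data): uniform initial ages, equal initial energies, exponential
connectedness, fair-coin strategies. Real populations violate most of
these idealizations — age structure, kinship, partner memory, spatial
and network structure, graded injury severity, learning — all of which
are out of scope here. Passing tests therefore demonstrate properties
of the model, not of any animal population: the model is a tool for
asking which selection pressures can sustain pain expression and
helping, not an estimator fit to data.

## Baseline behaviour and a known deviation

Under the calibrated costs the baseline batch (100 runs x 10,000
iterations from the default population) reproduces the expression
margin of the reference mix well — roughly a quarter of histories end
express-fixed, around 70% suppress-fixed, a few percent still mixed —
and the rare categories (non-altruistic expresser, both mixed classes)
land at reference levels. The altruism margin *within* suppressor-won
histories does not match: the reference mix has
non-altruistic:altruistic suppressor endings at 10:1, whereas this
model produces between 3:2 and 2:1 at every reachable
parameterization. The
mechanism is structural: helping costs energy only when help is
actually given, so once expressers are extinct the altruism trait is
exactly neutral and drifts to fixation with probability equal to its
frequency at that moment (about a third). Making helping costly enough
to pre-empt the drift (larger `c_alt`) destroys the altruistic-expresser
share instead. The same neutrality explains two absent sweep trends:
the altruist share does not decline monotonically with injury frequency
(expressers are extinct beyond `n_injury ~ 3`, after which altruism
drifts), and the expresser share does not rise monotonically with
recovery time (it is drift-neutral at `t_p = 0` and roughly flat
beyond). The corresponding checks in the test suite assert the
reference behaviour and are expected to fail against this
implementation; they are kept failing deliberately, as a precise record
of the deviation, rather than weakened.

## Numerical notes and limitations

* Energy is clamped to `[0, e_max]` after every sub-step; death from
  exhaustion is evaluated once per iteration, in phase 6.
* With `t_p = 0` injuries are instantaneous: expressers still pay
  `c_exp`, so expression is purely deleterious there — the floor of the
  recovery-time sweep.
* Outcome frequencies over 100 replicates carry binomial noise of a few
  percentage points; comparisons should use the attached standard
  errors rather than raw point differences.
* A population collapse ends a run early; collapsed runs are rare under
  baseline conditions but common in deliberately lethal corners of
  parameter space (high `c_exp` x high `n_injury` x small populations).
* The t test comparing batch designs is run per strategy on per-run
  final proportions; the four tests are correlated (proportions sum
  to 1), so they are reported individually, not jointly.
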