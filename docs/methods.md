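# Methods

## Model

`N` consumers distribute themselves over `P` habitat patches with constant
resource input rates `Q_p > 0`. The model is a singleton congestion game:
each consumer's payoff is the per-capita intake `f(Q_p / n_p)` on its patch,
with `f` a strictly increasing ratio-dependent functional response (type I:
`f(x) = x`; type II: `f(x) = a·x/(1 + a·h·x)`). Consumers are omniscient and
move by best response: when an individual assesses, it computes the
prospective intake `f(Q_q/(n_q+1))` for every other patch — with itself
counted in the destination occupancy — and relocates to an argmax patch only
on a strict improvement. Ties with the current patch mean staying; ties among
several best targets are broken uniformly at random from the run's stream.
Consistency between the current-patch and prospective-patch formulas is load
bearing: evaluating them differently lets individuals judge a suboptimal
patch optimal, which reverses qualitative conclusions about how activity
mixtures affect equilibration.

Individual heterogeneity enters solely through *activity* `a_i ∈ [0,1]`: the
per-opportunity probability of assessing in discrete time, and the Poisson
assessment rate (per unit time) in continuous time. Resources do not deplete;
qualities are input rates, constant between scheduled environmental changes.
Patch geometry is a flat index set — omniscience makes distance irrelevant —
so grid coordinates are cosmetic.

### Key consequences used as test oracles

- **Potential.** `Φ = Σ_p Σ_{k=1..n_p} f(Q_p/k)` changes by exactly the
  mover's intake gain at any single move, so every accepted move strictly
  increases Φ. Φ is bounded on a fixed landscape, hence discrete sequential
  dynamics terminate at a state where no improving move exists — the ideal
  free distribution (IFD) predicate used for exact stopping.
- **Type I ≡ type II.** Both responses are strictly increasing in `Q/n`, so
  they induce identical patch rankings and identical strict-improvement
  comparisons. With matched seeds the two runs consume identical random
  draws and coincide move for move, in final counts and in time-to-IFD, under
  either scheduler. (Float ties that exist under one response and not the
  other would break draw alignment, but with continuous quality
  distributions such collisions have measure zero.)
- **At most one move each.** On a static landscape, a consumer that is
  content (no strictly improving move) remains content after any other
  consumer's strict-improvement move: an arrival at its patch must have found
  that patch best, which certifies the incumbent's intake still dominates all
  alternatives; a departure elsewhere raises a prospective value only to the
  leaver's old intake, which the leaver's own strict improvement bounds below
  the content consumer's current intake. Movers become content the moment
  they move, so each individual moves at most once before the IFD is
  reached — for any monotone response and any tie structure under the
  ties-mean-stay rule.

## Schedulers

- **Discrete.** Per step, one consumer is chosen uniformly at random, then
  assesses with probability `a_i` (Bernoulli). Only one individual can decide
  per step, which couples population size to the timescale: per-capita
  decision opportunities scale as `1/N`. This is the scheduler whose
  time-to-IFD grows mechanically with `N`.
- **Gillespie.** Assessments form independent Poisson processes with rates
  `a_i`; the superposition (total rate `Λ = Σ a_i`, constant over a run) is
  simulated exactly: waiting times `Exp(Λ)`, event attributed to consumer `i`
  with probability `a_i/Λ`, who then assesses unconditionally. Rescaling all
  activities by `c` rescales event times by `1/c` and changes nothing else.
  Under this natural timescale, large populations equilibrate *faster*: at
  high density a departure immediately raises the intake of everyone left on
  the origin patch, so many consumers never need to move.

## Stopping rules

- `true_ifd`: evaluate the exact predicate at t = 0 and after every accepted
  move (between moves the state is unchanged, so checks there are redundant).
  `time_to_stop` is the step count (discrete) or the event time of the last
  accepted move (continuous).
- `quiescence` (discrete only; default window K = 50): stop after K
  consecutive steps without a patch change. Steps where a consumer assessed
  but stayed count as quiescent — the criterion watches movement, not
  assessment. This rule is biased: with many low-activity individuals, 50
  quiet steps often reflect reluctance rather than equilibrium. Every run
  also records the exact predicate at stopping (`reached_true_ifd`), so the
  bias is a measurable output, not an assumption.
- `max_steps` (10⁶) / `max_time` (10⁵) safeguards always apply and are
  reported as `stop_reason="max_bound"` rather than raised, far beyond
  stopping times observed at default scales.

## Environmental change

With period `T > 0`, qualities change every `T` steps (discrete scheduler),
applied at the start of the step before the consumer's decision — any fixed
ordering is acceptable; this one is documented and tested. `permute` shuffles
the existing qualities (conserving total resource); `redraw` samples fresh
ones. Counts are untouched, so a previously reached IFD can become invalid
without any movement. Time-to-IFD is not a meaningful outcome in such
scenarios (the target moves); the intake-variance and matching-slope metrics
are the intended measures there.

## Metrics

- **Intake variance**: population variance (ddof = 0) of `f(Q_p/n_p)` over
  *occupied* patches, unweighted by default. Empty patches have no realized
  intake; variants (`include_empty`, individual weighting) are available
  because "across patches" admits several readings. Zero exactly when all
  occupied patches yield equal intake.
- **Matching slope**: OLS slope of `log n_p` on `log Q_p` over occupied
  patches (natural logs; empty patches excluded since `log 0` is undefined).
  1 is perfect input matching, < 1 undermatching. This is a conventional
  matching-law statistic standing in for an undermatching measure; at small
  `N` integer occupancy makes equilibrium slopes scatter on either side
  of 1, so small-instance slopes are reported, not asserted against a bound.
- **Equilibrium enumeration**: exhaustive composition enumeration (guarded to
  P ≤ 6, N ≤ 12) classifying states by the IFD inequalities — the
  independent oracle for the predicate and for the simulators' absorbing
  states.

## Defaults and study conditions

| Parameter | Default | Notes |
| --- | --- | --- |
| grid | 7×7 (49 patches) | standard landscape for all experiments |
| quality distribution | Uniform(1, 10), i.i.d. | continuous support makes intake ties measure-zero; the original study's distribution is not recoverable, so this is the package's documented assumption |
| placement | uniform random | `one_per_patch` covers the very-low-density regime, `single_patch` the worst-case start |
| activity pairs | 0.8 / 0.2 | mixture-slowdown and population-size experiments |
|  | 0.9 / 0.1 | stopping-bias experiment |
| mixture rounding | `round(proportion_active · N)` active | deterministic composition |
| quiescence window | 50 steps | the biased criterion under study |
| replicates | 200 (discrete presets), 100 (population-size preset) | scaled down from 1000 per setting to desk-scale runtimes; `replicates=1000` restores full scale |
| type II parameters | a = 1, h = 1 | irrelevant to dynamics by the equivalence property; configurable |

Seeding: a single master seed; sweep run `(cell, replicate)` uses
`SeedSequence(master, spawn_key=(cell, replicate))`, a counter-based
derivation giving independent, platform-stable streams. No code path reads
the wall clock.

## Numerical choices

- Strict-improvement comparisons use raw float `>` / `>=`; no tolerance is
  injected, because the equivalence property requires type I and type II to
  make bitwise-identical decisions and continuous qualities keep ties at
  measure zero. Deliberately tied qualities (e.g. equal-quality patches) are
  compared exactly and hit the documented ties-mean-stay / uniform
  tie-breaking paths.
- The IFD predicate is evaluated in O(P) via the top-two prospective intakes
  rather than an O(P²) pairwise scan.
- Degenerate inputs: empty patches are valid move targets but impose no
  predicate condition; an empty population is vacuously at the IFD; a
  landscape with a single patch never generates moves; intake on an empty
  patch is an error by contract (prospective evaluations always use n+1 ≥ 1);
  all-zero activities are an error in continuous time (no event can occur)
  and simply freeze the discrete dynamics.

## What the synthetic scenarios do and do not show

The generator emulates the standardized simulation conditions: fixed
landscapes with i.i.d. continuous qualities, exchangeable consumers differing
only in a fixed two-level activity trait, no depletion, no travel costs, no
perception limits. Passing tests therefore demonstrate properties of this
idealized game — equivalence of response types, stopping-rule bias,
timescale effects of population size — not claims about real foraging
systems, where resource dynamics, state-dependent behaviour, unequal
competitive abilities and partial information all violate these assumptions.
Body-size- or metabolism-linked personality differences, birth–death
processes and evolutionary dynamics of activity are out of scope.

## Known limitations

- The quiescence criterion exists only in discrete time; no continuous-time
  analogue is defined.
- `run_gillespie` assumes at least one positive activity and constant Λ;
  time-varying activities would need rate recomputation machinery.
- The enumeration oracle is exponential in P and N by design and guarded
  accordingly.
- Figures are not a deliverable; the sweep CSVs are the analysis surface, and
  statistical comparisons between settings are left to downstream analysis.
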