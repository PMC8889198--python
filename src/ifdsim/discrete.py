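"""Discrete-time sequential scheduler with both stopping rules.

One time step = one decision opportunity for one individual: a consumer is
chosen uniformly at random, and with probability equal to its activity level
it assesses its situation (computes a best response) and moves if a strictly
better patch exists.  Only one individual can decide per step, so in a larger
population each individual decides proportionally less often — this coupling
of population size to the timescale is a property of the discrete scheduler
that the continuous-time scheduler in :mod:`ifdsim.gillespie` removes.

Two stopping rules:

* ``true_ifd`` — stop the first time the exact IFD predicate holds (checked
  at t=0 and after every accepted move; between moves the state is unchanged,
  so further checks would be redundant).
* ``quiescence`` — stop after K consecutive steps without a patch change
  (default K=50).  A step in which a consumer assessed but chose to stay
  counts as quiescent: the criterion watches movement, not assessment.  This
  rule is *biased*: with enough low-activity individuals movement can cease
  for K steps while the population is still far from the IFD.

Optionally, patch qualities change every ``env_change_period`` steps (either
permuted across patches or re-drawn), applied before the consumer's decision
within the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RunResult, SimConfig, SimState, apply_move, best_move, is_ifd
from .metrics import intake_variance, matching_slope

__all__ = ["DiscreteRunState", "step", "apply_env_change", "run_discrete"]


@dataclass
class DiscreteRunState:
    """Simulation state plus the discrete clock and the quiescence counter."""

    state: SimState
    t: int = 0
    quiescent_steps: int = 0
    env_clock: int = 0


def step(run: DiscreteRunState, fr, rng) -> bool:
    """Advance one time step; return whether a patch change occurred.

    The move (if any) is logged at the step index at which it happened,
    i.e. the value of ``run.t`` before the clock advances.
    """
    state = run.state
    i = int(rng.integers(state.n_consumers))
    moved = False
    if rng.random() < state.activity[i]:
        target = best_move(state, i, fr, rng)
        if target is not None:
            apply_move(state, i, target, t=run.t)
            moved = True
    run.t += 1
    run.env_clock += 1
    run.quiescent_steps = 0 if moved else run.quiescent_steps + 1
    return moved


def apply_env_change(state: SimState, config: SimConfig, rng) -> SimState:
    """Change patch qualities in place; consumer positions are untouched.

    ``permute`` shuffles the existing qualities across patches (total resource
    conserved); ``redraw`` samples fresh qualities from the configured
    distribution.  Either can invalidate a previously reached IFD without any
    consumer having moved.
    """
    if config.env_change_mode == "permute":
        state.landscape.quality = rng.permutation(state.landscape.quality)
    else:
        from .experiments import draw_qualities

        state.landscape.quality = draw_qualities(
            config.quality_dist, state.landscape.n_patches, rng
        )
    return state


def _finish(state, config, time_to_stop, stop_reason, initial_counts, seed) -> RunResult:
    reached = is_ifd(state, config.fr)
    metrics = {
        "intake_variance": intake_variance(state, config.fr)
        if state.n_consumers
        else float("nan"),
        "matching_slope": matching_slope(state) if state.n_consumers else None,
    }
    return RunResult(
        time_to_stop=float(time_to_stop),
        stop_reason=stop_reason,
        reached_true_ifd=reached,
        moves=state.moves.copy(),
        initial_counts=initial_counts,
        final_counts=state.counts.copy(),
        quality=state.quality.copy(),
        metrics=metrics,
        seed=seed,
        events=list(state.events),
    )


def run_discrete(config: SimConfig, rng=None, state: SimState | None = None) -> RunResult:
    """Run the discrete-time scheduler to completion.

    If ``state`` is omitted it is built from the config (landscape drawn,
    population placed) using the same ``rng`` stream.  ``time_to_stop`` is
    the step count at stopping; hitting ``max_steps`` is reported as
    ``stop_reason="max_bound"``, not raised.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if state is None:
        from .experiments import build_state

        state = build_state(config, rng)
    fr = config.fr
    run = DiscreteRunState(state)
    initial_counts = state.counts.copy()

    if config.stopping == "true_ifd" and is_ifd(state, fr):
        return _finish(state, config, 0.0, "true_ifd", initial_counts, config.seed)

    T = config.env_change_period
    while run.t < config.max_steps:
        if T > 0 and run.env_clock == T:
            apply_env_change(state, config, rng)
            run.env_clock = 0
            if config.stopping == "true_ifd" and is_ifd(state, fr):
                return _finish(state, config, run.t, "true_ifd", initial_counts, config.seed)
        moved = step(run, fr, rng)
        if moved:
            if config.stopping == "true_ifd" and is_ifd(state, fr):
                return _finish(state, config, run.t, "true_ifd", initial_counts, config.seed)
        elif config.stopping == "quiescence" and run.quiescent_steps >= config.quiescence_window:
            return _finish(state, config, run.t, "quiescence", initial_counts, config.seed)
    return _finish(state, config, run.t, "max_bound", initial_counts, config.seed)
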