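"""Continuous-time event-based scheduler (Gillespie algorithm).

In the discrete scheduler only one individual can decide per time step, so
the timescale is coupled to population size: more individuals means each one
decides less often.  The natural alternative is continuous time, where every
consumer assesses its situation independently at a rate equal to its activity
level.  The superposition of these Poisson assessment processes has total
rate ``Λ = Σ_i a_i``; the Gillespie algorithm simulates it exactly by drawing
exponential waiting times with rate Λ and attributing each event to consumer
``i`` with probability ``a_i / Λ``.  The selected consumer assesses
unconditionally — its rate *is* its activity, so no second Bernoulli filter
is applied.

The movement rule (best response, strict improvement, ties broken uniformly)
is shared verbatim with the discrete scheduler; only the clock differs.
Runs stop when the exact IFD predicate holds (quiescence has no natural
continuous-time analogue) or at ``max_time`` as a safeguard.
"""

from __future__ import annotations

import numpy as np

from .core import RunResult, SimConfig, SimState, apply_move, best_move, is_ifd
from .discrete import _finish

__all__ = ["next_event", "run_gillespie"]


def next_event(state: SimState, rng, cum_rate: np.ndarray | None = None):
    """Draw the next assessment event: ``(waiting_time, consumer_id)``.

    ``cum_rate`` is the cumulative sum of activities, precomputable once per
    run because activities never change.  Raises if all activities are zero
    (no event can ever occur).
    """
    if cum_rate is None:
        cum_rate = np.cumsum(state.activity)
    total = cum_rate[-1]
    if total <= 0:
        raise ValueError("total assessment rate is zero; no event can occur")
    dt = rng.exponential(1.0 / total)
    i = int(np.searchsorted(cum_rate, rng.random() * total, side="right"))
    return dt, i


def run_gillespie(config: SimConfig, rng=None, state: SimState | None = None) -> RunResult:
    """Run the event-based scheduler until the IFD is reached.

    ``time_to_stop`` is the continuous event time of the last accepted move
    (0 if the initial state is already at the IFD).  Hitting ``max_time`` is
    reported as ``stop_reason="max_bound"``.
    """
    if config.stopping != "true_ifd":
        raise ValueError("the event-based scheduler supports only the true_ifd stopping rule")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if state is None:
        from .experiments import build_state

        state = build_state(config, rng)
    fr = config.fr
    initial_counts = state.counts.copy()

    if is_ifd(state, fr):
        return _finish(state, config, 0.0, "true_ifd", initial_counts, config.seed)

    cum_rate = np.cumsum(state.activity)
    if cum_rate.size == 0 or cum_rate[-1] <= 0:
        raise ValueError("total assessment rate is zero; no event can occur")
    t = 0.0
    last_move_time = 0.0
    while t < config.max_time:
        dt, i = next_event(state, rng, cum_rate)
        t += dt
        if t >= config.max_time:
            break
        target = best_move(state, i, fr, rng)
        if target is not None:
            apply_move(state, i, target, t=t)
            last_move_time = t
            if is_ifd(state, fr):
                return _finish(state, config, last_move_time, "true_ifd", initial_counts, config.seed)
    return _finish(state, config, t, "max_bound", initial_counts, config.seed)
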