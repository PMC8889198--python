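"""Deviation-from-IFD measures and a brute-force equilibrium oracle.

Time-to-IFD is a fragile outcome measure: it is set by the single slowest
mover, depends on initial conditions, and is undefined whenever the
environment keeps changing.  The population-level alternatives implemented
here — the variance of realized intake rates across occupied patches, and the
log-log matching slope of occupancy against quality — remain well defined in
any state.  A matching slope of 1 is perfect input matching (consumer numbers
proportional to patch input rates); a slope below 1 is undermatching, the
commonly observed pattern where rich patches are relatively underexploited.
The slope is a conventional matching-law statistic, used here as a stand-in
for an undermatching measure rather than a quantity with a canonical
definition in this model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import FunctionalResponse, PatchLandscape, RunResult, SimState, is_ifd

__all__ = [
    "MetricReport",
    "intake_variance",
    "matching_slope",
    "enumerate_equilibria",
    "summarize_batch",
    "runs_table",
]


def intake_variance(
    state: SimState,
    fr: FunctionalResponse,
    include_empty: bool = False,
    weight: str = "patch",
) -> float:
    """Population variance of per-capita intake rates across patches.

    By default the (unweighted, ddof=0) variance is taken over occupied
    patches only: empty patches have no realized intake.  ``weight`` may be
    ``"patch"`` (each occupied patch one observation) or ``"individual"``
    (each consumer one observation, i.e. patches weighted by occupancy).
    With ``include_empty=True`` empty patches enter as zero realized intake.

    Zero exactly when all occupied patches yield equal intake, i.e. at an
    interior IFD.
    """
    if weight not in ("patch", "individual"):
        raise ValueError(f"unknown weighting: {weight!r}")
    n = state.counts
    q = state.quality
    occ = n > 0
    if not occ.any():
        raise ValueError("intake variance undefined with no occupied patch")
    intakes = fr.per_capita(q[occ] / n[occ])
    if weight == "individual":
        w = n[occ].astype(float)
    else:
        w = np.ones(intakes.size)
    if include_empty:
        intakes = np.concatenate([intakes, np.zeros(int((~occ).sum()))])
        w = np.concatenate([w, np.ones(int((~occ).sum()))])
    mean = np.average(intakes, weights=w)
    return float(np.average((intakes - mean) ** 2, weights=w))


def matching_slope(state: SimState) -> Optional[float]:
    """OLS slope of ``log n_p`` on ``log Q_p`` over occupied patches.

    Returns ``None`` when fewer than two occupied patches with distinct
    qualities are available (the regressor would be degenerate).  Empty
    patches are excluded because ``log 0`` is undefined — standard
    matching-law practice.
    """
    n = state.counts
    q = state.quality
    occ = n > 0
    x = np.log(q[occ])
    y = np.log(n[occ].astype(float))
    if x.size < 2 or np.allclose(x, x[0]):
        return None
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def _compositions(total: int, parts: int):
    """Yield all tuples of ``parts`` non-negative ints summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def enumerate_equilibria(
    Q: Sequence[float], N: int, fr: Optional[FunctionalResponse] = None
) -> set:
    """All occupancy vectors of ``N`` consumers over patches ``Q`` that are
    ideal free distributions, by exhaustive enumeration.

    This is a testing oracle; a combinatorial guard restricts it to at most
    6 patches and 12 consumers.
    """
    q = np.asarray(Q, dtype=float).ravel()
    if fr is None:
        fr = FunctionalResponse()
    if q.size > 6 or N > 12:
        raise ValueError("enumeration guard exceeded (P <= 6, N <= 12)")
    if N < 0:
        raise ValueError("N must be non-negative")
    out = set()
    for counts in _compositions(N, q.size):
        # consumer identities are irrelevant to the predicate; place by counts
        patches = np.repeat(np.arange(q.size), counts)
        state = SimState(PatchLandscape.from_qualities(q), np.zeros(N), patches)
        if is_ifd(state, fr):
            out.add(counts)
    return out


@dataclass
class MetricReport:
    """Batch-level aggregate of run outcomes."""

    time_to_ifd: Optional[float]  # mean over runs that truly reached the IFD
    intake_variance: float  # mean final intake variance across runs
    matching_slope: Optional[float]  # mean over runs where defined
    proportion_true_ifd: float
    max_moves_per_consumer: int


def runs_table(results: Iterable[RunResult]) -> pd.DataFrame:
    """One tidy row per run."""
    rows = []
    for r in results:
        row = {
            "time_to_stop": r.time_to_stop,
            "stop_reason": r.stop_reason,
            "reached_true_ifd": r.reached_true_ifd,
            "max_moves": r.max_moves,
            "total_moves": int(r.moves.sum()),
            "seed": str(r.seed),
        }
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_batch(results: Sequence[RunResult]):
    """Aggregate a collection of runs into a :class:`MetricReport` plus the
    per-run tidy table from :func:`runs_table`.

    ``time_to_ifd`` averages ``time_to_stop`` over runs whose final state
    satisfies the exact IFD predicate (``None`` if no run did);
    ``proportion_true_ifd`` is the fraction of runs that did.
    """
    results = list(results)
    if not results:
        raise ValueError("summarize_batch requires at least one run")
    table = runs_table(results)
    reached = table["reached_true_ifd"]
    time_to_ifd = float(table.loc[reached, "time_to_stop"].mean()) if reached.any() else None
    slopes = table.get("matching_slope")
    slope = None
    if slopes is not None and slopes.notna().any():
        slope = float(slopes.dropna().mean())
    report = MetricReport(
        time_to_ifd=time_to_ifd,
        intake_variance=float(table["intake_variance"].mean()),
        matching_slope=slope,
        proportion_true_ifd=float(reached.mean()),
        max_moves_per_consumer=int(table["max_moves"].max()),
    )
    return report, table
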