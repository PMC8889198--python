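"""Core model: patches, consumers, ratio-dependent intake, best-response moves.

The model world is a set of habitat patches, each with a constant resource
input rate ``Q_p`` and an integer consumer count ``n_p``.  Consumers are
omniscient: every individual knows the quality and occupancy of every patch at
all times.  Per-capita intake on a patch is a *ratio-dependent* functional
response, i.e. a function of the resource share ``Q/n`` alone:

* type I  — linear, ``f(Q/n) = Q/n`` (equal split of the input rate);
* type II — saturating Arditi–Ginzburg/Holling form,
  ``f(x) = a*x / (1 + a*h*x)`` with attack rate ``a`` and handling time ``h``.

Both are strictly increasing in ``Q/n``, so they rank patches identically and
induce exactly the same movement dynamics; the choice only rescales realized
intake values.

A *best-response move* relocates a consumer to the patch maximizing its
prospective intake, where the prospective occupancy of a candidate patch
counts the focal individual itself (``n_q + 1``) while the current intake
counts it at the origin (``n_p``).  Consistency between these two evaluations
is essential: mixing formulas lets consumers "believe" they are optimally
placed when they are not.  Moves happen only on a *strict* improvement; ties
between staying and the best alternative mean staying, and ties among several
best alternatives are broken uniformly at random.

The population is at the ideal free distribution (IFD) exactly when no
consumer has a strictly improving move.  Because every accepted move raises a
Rosenthal-style congestion potential by the mover's intake gain, sequential
best-response dynamics on a static landscape always terminate at such a state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TYPE_I",
    "TYPE_II",
    "FunctionalResponse",
    "PatchLandscape",
    "Consumer",
    "SimState",
    "SimConfig",
    "RunResult",
    "intake_rate",
    "best_move",
    "apply_move",
    "is_ifd",
    "potential",
]

TYPE_I = "type_I"
TYPE_II = "type_II"


@dataclass(frozen=True)
class FunctionalResponse:
    """Ratio-dependent per-capita intake as a function of the share Q/n.

    Parameters
    ----------
    kind : {"type_I", "type_II"}
        Linear or saturating response.
    attack_rate : float
        Attack rate ``a`` (type II only); must be positive.
    handling_time : float
        Handling time ``h`` (type II only); must be non-negative.  With
        ``h = 0`` type II reduces to ``a * Q/n``.
    """

    kind: str = TYPE_I
    attack_rate: float = 1.0
    handling_time: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (TYPE_I, TYPE_II):
            raise ValueError(f"unknown functional response kind: {self.kind!r}")
        if self.attack_rate <= 0:
            raise ValueError("attack_rate must be positive")
        if self.handling_time < 0:
            raise ValueError("handling_time must be non-negative")

    def per_capita(self, ratio):
        """Intake at resource share ``ratio = Q/n`` (scalar or array)."""
        if self.kind == TYPE_I:
            return ratio
        a = self.attack_rate
        return a * ratio / (1.0 + a * self.handling_time * ratio)


def intake_rate(fr: FunctionalResponse, Q, n):
    """Per-capita intake of each of ``n`` consumers on a patch of quality ``Q``.

    ``n`` must be at least 1: intake is undefined on an empty patch
    (prospective evaluations always use ``n + 1 >= 1``).
    Accepts scalars or equal-shaped arrays.
    """
    Q = np.asarray(Q, dtype=float)
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("intake undefined on an empty patch (n must be >= 1)")
    if np.any(Q <= 0):
        raise ValueError("patch quality must be positive")
    out = fr.per_capita(Q / n)
    return float(out) if out.ndim == 0 else out


@dataclass
class PatchLandscape:
    """Rectangular grid of habitat patches.

    Grid coordinates are cosmetic: consumers are omniscient, so distance plays
    no role and patches form a flat index set ``0 .. n_rows*n_cols - 1``.
    """

    n_rows: int
    n_cols: int
    quality: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=float).ravel()
        self.counts = np.asarray(self.counts, dtype=np.int64).ravel()
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.quality.size != self.n_rows * self.n_cols:
            raise ValueError("quality length must equal n_rows * n_cols")
        if self.counts.size != self.quality.size:
            raise ValueError("counts length must equal number of patches")
        if np.any(self.quality <= 0):
            raise ValueError("all patch qualities must be positive")
        if np.any(self.counts < 0):
            raise ValueError("patch counts must be non-negative")

    @property
    def n_patches(self) -> int:
        return self.quality.size

    @classmethod
    def from_qualities(
        cls, quality: Sequence[float], n_rows: Optional[int] = None, n_cols: Optional[int] = None
    ) -> "PatchLandscape":
        q = np.asarray(quality, dtype=float).ravel()
        if n_rows is None and n_cols is None:
            n_rows, n_cols = 1, q.size
        elif n_rows is None:
            n_rows = q.size // int(n_cols)
        elif n_cols is None:
            n_cols = q.size // int(n_rows)
        return cls(int(n_rows), int(n_cols), q, np.zeros(q.size, dtype=np.int64))

    def copy(self) -> "PatchLandscape":
        return PatchLandscape(self.n_rows, self.n_cols, self.quality.copy(), self.counts.copy())

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(self.n_patches)
        return pd.DataFrame(
            {
                "patch_id": idx,
                "row": idx // self.n_cols,
                "col": idx % self.n_cols,
                "quality": self.quality,
                "count": self.counts,
            }
        )

    def to_csv(self, path) -> None:
        """Write the landscape as comma-separated UTF-8 with a header row."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PatchLandscape":
        df = pd.read_csv(path)
        required = {"patch_id", "row", "col", "quality", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"landscape CSV missing columns: {sorted(missing)}")
        df = df.sort_values("patch_id").reset_index(drop=True)
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        if len(df) != n_rows * n_cols:
            raise ValueError("landscape CSV does not describe a full grid")
        return cls(n_rows, n_cols, df["quality"].to_numpy(), df["count"].to_numpy())


@dataclass(frozen=True)
class Consumer:
    """Read-only snapshot of one consumer."""

    id: int
    activity: float
    patch: int
    moves: int


class SimState:
    """Mutable joint state of landscape and consumer population.

    Consumers are stored as parallel arrays for speed: ``activity[i]`` is
    consumer *i*'s assessment probability (discrete time) or rate (continuous
    time), ``patch[i]`` its current patch, ``moves[i]`` its cumulative move
    count.  ``events`` is the move log, a list of
    ``(time, consumer_id, origin, destination)`` tuples.
    """

    def __init__(self, landscape: PatchLandscape, activity, patch) -> None:
        self.landscape = landscape
        self.activity = np.asarray(activity, dtype=float).ravel()
        self.patch = np.asarray(patch, dtype=np.int64).ravel()
        if self.activity.size != self.patch.size:
            raise ValueError("activity and patch must have equal length")
        if np.any((self.activity < 0) | (self.activity > 1)):
            raise ValueError("activity levels must lie in [0, 1]")
        if self.patch.size and (self.patch.min() < 0 or self.patch.max() >= landscape.n_patches):
            raise ValueError("consumer patch index out of range")
        self.moves = np.zeros(self.patch.size, dtype=np.int64)
        self.events: list[tuple] = []
        # counts are derived from consumer positions and kept in sync
        landscape.counts = np.bincount(self.patch, minlength=landscape.n_patches).astype(np.int64)

    @property
    def n_consumers(self) -> int:
        return self.patch.size

    @property
    def quality(self) -> np.ndarray:
        return self.landscape.quality

    @property
    def counts(self) -> np.ndarray:
        return self.landscape.counts

    def consumer(self, i: int) -> Consumer:
        return Consumer(int(i), float(self.activity[i]), int(self.patch[i]), int(self.moves[i]))

    def copy(self) -> "SimState":
        st = SimState(self.landscape.copy(), self.activity.copy(), self.patch.copy())
        st.moves = self.moves.copy()
        st.events = list(self.events)
        return st

    def validate(self) -> None:
        expect = np.bincount(self.patch, minlength=self.landscape.n_patches)
        if not np.array_equal(expect, self.counts):
            raise AssertionError("patch counts inconsistent with consumer positions")


def best_move(state: SimState, i: int, fr: FunctionalResponse, rng) -> Optional[int]:
    """Best-response target patch for consumer ``i``, or ``None`` to stay.

    Compares the current intake ``f(Q_p / n_p)`` against the prospective
    intake ``f(Q_q / (n_q + 1))`` on every other patch; returns an argmax
    patch only if it is *strictly* better than staying, breaking ties among
    maximizers uniformly with ``rng``.
    """
    q = state.quality
    n = state.counts
    p = int(state.patch[i])
    current = fr.per_capita(q[p] / n[p])
    prospective = fr.per_capita(q / (n + 1))
    prospective[p] = -np.inf
    best = prospective.max()
    if not best > current:
        return None
    ties = np.flatnonzero(prospective == best)
    if ties.size == 1:
        return int(ties[0])
    return int(ties[rng.integers(ties.size)])


def apply_move(state: SimState, i: int, target: int, t: float = 0.0) -> SimState:
    """Relocate consumer ``i`` to ``target``, updating counts, its move
    counter and the event log.  Total population size is conserved."""
    origin = int(state.patch[i])
    if not 0 <= target < state.landscape.n_patches:
        raise ValueError(f"target patch {target} out of range")
    if target == origin:
        raise ValueError("target must differ from the consumer's current patch")
    state.landscape.counts[origin] -= 1
    state.landscape.counts[target] += 1
    state.patch[i] = target
    state.moves[i] += 1
    state.events.append((t, int(i), origin, int(target)))
    return state


def is_ifd(state: SimState, fr: FunctionalResponse) -> bool:
    """True iff no consumer has a strictly improving move.

    Equivalently: for every occupied patch ``p``,
    ``f(Q_p/n_p) >= f(Q_q/(n_q+1))`` for all ``q != p``.  Empty patches are
    valid move targets but impose no condition of their own.
    """
    q = state.quality
    n = state.counts
    occ = np.flatnonzero(n > 0)
    if occ.size == 0:
        return True
    prospective = fr.per_capita(q / (n + 1))
    i1 = int(np.argmax(prospective))
    m1 = prospective[i1]
    if prospective.size > 1:
        tmp = prospective[i1]
        prospective[i1] = -np.inf
        m2 = prospective.max()
        prospective[i1] = tmp
    else:
        m2 = -np.inf
    current = fr.per_capita(q[occ] / n[occ])
    best_other = np.where(occ == i1, m2, m1)
    return bool(np.all(current >= best_other))


def potential(state: SimState, fr: FunctionalResponse) -> float:
    """Rosenthal congestion potential ``Φ = Σ_p Σ_{k=1..n_p} f(Q_p/k)``.

    Any single accepted move changes Φ by exactly the mover's intake gain,
    so Φ strictly increases along best-response dynamics and certifies
    termination on a static landscape.
    """
    q = state.quality
    n = state.counts
    total = 0.0
    for p in np.flatnonzero(n > 0):
        k = np.arange(1, n[p] + 1, dtype=float)
        total += float(np.sum(fr.per_capita(q[p] / k)))
    return total


# ---------------------------------------------------------------------------
# scenario configuration and run results
# ---------------------------------------------------------------------------

_DEFAULT_QDIST = {"kind": "uniform", "low": 1.0, "high": 10.0}


@dataclass
class SimConfig:
    """Full description of one simulation scenario.

    Landscape: either explicit ``quality`` values, or a ``quality_dist`` from
    which qualities are drawn (default continuous uniform on [1, 10]; a
    continuous distribution makes intake ties measure-zero).

    Population: ``n_consumers`` individuals; ``round(proportion_active * N)``
    of them get ``activity_high``, the rest ``activity_low``; placement mode
    is one of ``uniform_random``, ``one_per_patch``, ``single_patch``.

    Scheduler: ``discrete`` (one uniformly chosen consumer per step assesses
    with probability equal to its activity) or ``gillespie`` (continuous time,
    each consumer assesses at rate equal to its activity).

    Stopping: ``true_ifd`` stops at the first instant the exact IFD predicate
    holds; ``quiescence`` stops after ``quiescence_window`` consecutive steps
    without a move (discrete scheduler only — this is the biased criterion).
    ``max_steps`` / ``max_time`` are always-on safeguards.

    Environment: if ``env_change_period`` T > 0, every T steps the qualities
    are permuted across patches (``permute``) or re-drawn (``redraw``).
    """

    n_rows: int = 7
    n_cols: int = 7
    quality: Optional[Sequence[float]] = None
    quality_dist: dict = field(default_factory=lambda: dict(_DEFAULT_QDIST))
    n_consumers: int = 40
    activity_high: float = 0.8
    activity_low: float = 0.2
    proportion_active: float = 0.5
    placement: str = "uniform_random"
    fr: FunctionalResponse = field(default_factory=FunctionalResponse)
    scheduler: str = "discrete"
    stopping: str = "true_ifd"
    quiescence_window: int = 50
    max_steps: int = 1_000_000
    max_time: float = 1e5
    env_change_period: int = 0
    env_change_mode: str = "permute"
    seed: Optional[int] = 0

    def __post_init__(self) -> None:
        if self.scheduler not in ("discrete", "gillespie"):
            raise ValueError(f"unknown scheduler: {self.scheduler!r}")
        if self.stopping not in ("true_ifd", "quiescence"):
            raise ValueError(f"unknown stopping rule: {self.stopping!r}")
        if self.scheduler == "gillespie" and self.stopping == "quiescence":
            raise ValueError("quiescence stopping is undefined in continuous time")
        if self.quiescence_window < 1:
            raise ValueError("quiescence_window must be positive")
        if not 0.0 <= self.proportion_active <= 1.0:
            raise ValueError("proportion_active must lie in [0, 1]")
        if self.placement not in ("uniform_random", "one_per_patch", "single_patch"):
            raise ValueError(f"unknown placement mode: {self.placement!r}")
        if self.env_change_period < 0:
            raise ValueError("env_change_period must be >= 0")
        if self.env_change_mode not in ("permute", "redraw"):
            raise ValueError(f"unknown env_change_mode: {self.env_change_mode!r}")

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fr"] = {
            "kind": self.fr.kind,
            "attack_rate": self.fr.attack_rate,
            "handling_time": self.fr.handling_time,
        }
        if d["quality"] is not None:
            d["quality"] = [float(x) for x in np.asarray(d["quality"]).ravel()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        fr = d.pop("fr", d.pop("functional_response", None))
        if fr is not None and not isinstance(fr, FunctionalResponse):
            fr = FunctionalResponse(**fr)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if fr is not None:
            d["fr"] = fr
        return cls(**d)


@dataclass
class RunResult:
    """Outcome of a single simulation run.

    ``time_to_stop`` is the step count (discrete) or the continuous event time
    of the last accepted move (Gillespie) at stopping.  ``reached_true_ifd``
    is always evaluated with the exact IFD predicate at the moment of
    stopping, regardless of which stopping rule terminated the run — the
    discrepancy between the two is the stopping-criterion bias.
    """

    time_to_stop: float
    stop_reason: str  # "true_ifd" | "quiescence" | "max_bound"
    reached_true_ifd: bool
    moves: np.ndarray
    initial_counts: np.ndarray
    final_counts: np.ndarray
    quality: np.ndarray
    metrics: dict
    seed: object
    events: list

    def __post_init__(self) -> None:
        if self.stop_reason == "true_ifd" and not self.reached_true_ifd:
            raise AssertionError("stop_reason true_ifd requires reached_true_ifd")

    @property
    def max_moves(self) -> int:
        return int(self.moves.max()) if self.moves.size else 0

    def events_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events, columns=["time", "consumer_id", "origin", "destination"]
        )
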