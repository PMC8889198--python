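"""Scenario generators, seed management, and reproducible parameter sweeps.

The landscape generator and placement rules define the study conditions for
all experiments: a 7x7 grid (49 patches) with qualities drawn independently
from a continuous uniform distribution on [1, 10] (continuous support makes
intake ties measure-zero), and populations mixing "active" and "inactive"
consumers at configurable proportions.  Activity-level pairs of interest are
0.8/0.2 (mixture-slowdown and population-size experiments) and 0.9/0.1
(stopping-criterion bias experiment).

Every (cell, replicate) of a sweep receives its own deterministic random
stream derived from the master seed with ``numpy``'s ``SeedSequence`` spawn
keys — a counter-based derivation, so runs are independent and the whole
sweep replays byte-identically from the master seed alone.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import FunctionalResponse, PatchLandscape, RunResult, SimConfig, SimState
from .discrete import run_discrete
from .gillespie import run_gillespie

__all__ = [
    "draw_qualities",
    "generate_landscape",
    "make_activities",
    "place_population",
    "build_state",
    "simulate",
    "SweepSpec",
    "child_rng",
    "run_sweep",
    "get_preset",
    "PRESETS",
]

log = logging.getLogger("ifdsim")


def draw_qualities(quality_dist: dict, size: int, rng) -> np.ndarray:
    """Sample patch qualities from a distribution spec.

    Supported kinds: ``uniform`` (keys ``low``, ``high``; requires
    ``0 < low <= high``) and ``constant`` (key ``value`` > 0).
    """
    kind = quality_dist.get("kind", "uniform")
    if kind == "uniform":
        low = float(quality_dist.get("low", 1.0))
        high = float(quality_dist.get("high", 10.0))
        if low <= 0 or high < low:
            raise ValueError("uniform quality support must satisfy 0 < low <= high")
        return rng.uniform(low, high, size=size)
    if kind == "constant":
        value = float(quality_dist.get("value", 1.0))
        if value <= 0:
            raise ValueError("constant quality must be positive")
        return np.full(size, value)
    raise ValueError(f"unknown quality distribution kind: {kind!r}")


def generate_landscape(n_rows: int, n_cols: int, quality_dist: dict, rng) -> PatchLandscape:
    """Empty landscape with i.i.d. qualities; all counts zero."""
    q = draw_qualities(quality_dist, n_rows * n_cols, rng)
    return PatchLandscape(n_rows, n_cols, q, np.zeros(n_rows * n_cols, dtype=np.int64))


def make_activities(
    n: int, activity_high: float, activity_low: float, proportion_active: float
) -> np.ndarray:
    """Mixture of activity levels: exactly ``round(proportion_active * n)``
    consumers at ``activity_high``, the rest at ``activity_low``.

    The rounding rule (nearest integer, ties to even via ``round``) makes the
    realized composition deterministic, so "proportion" means what it says.
    Consumer order is immaterial — individuals are exchangeable apart from
    their activity level.
    """
    n_active = int(round(proportion_active * n))
    return np.concatenate(
        [np.full(n_active, activity_high), np.full(n - n_active, activity_low)]
    )


def place_population(
    landscape: PatchLandscape, n: int, activities: Sequence[float], mode: str, rng
) -> SimState:
    """Create consumers with the given activities and place them on patches.

    Modes: ``uniform_random`` (each consumer on an independently uniform
    patch), ``one_per_patch`` (distinct patches, requires ``n <= P`` — the
    very-low-density regime), ``single_patch`` (everyone on one random patch).
    """
    P = landscape.n_patches
    activities = np.asarray(activities, dtype=float)
    if activities.size != n:
        raise ValueError("activities length must equal population size")
    if mode == "uniform_random":
        patches = rng.integers(P, size=n)
    elif mode == "one_per_patch":
        if n > P:
            raise ValueError("one_per_patch placement requires N <= number of patches")
        patches = rng.choice(P, size=n, replace=False)
    elif mode == "single_patch":
        patches = np.full(n, rng.integers(P))
    else:
        raise ValueError(f"unknown placement mode: {mode!r}")
    return SimState(landscape, activities, patches)


def build_state(config: SimConfig, rng) -> SimState:
    """Materialize the initial simulation state described by a config."""
    if config.quality is not None:
        landscape = PatchLandscape(
            config.n_rows,
            config.n_cols,
            np.asarray(config.quality, dtype=float),
            np.zeros(config.n_rows * config.n_cols, dtype=np.int64),
        )
    else:
        landscape = generate_landscape(config.n_rows, config.n_cols, config.quality_dist, rng)
    activities = make_activities(
        config.n_consumers, config.activity_high, config.activity_low, config.proportion_active
    )
    return place_population(landscape, config.n_consumers, activities, config.placement, rng)


def simulate(config: SimConfig, rng=None) -> RunResult:
    """Run one scenario with the scheduler named in the config."""
    if config.scheduler == "discrete":
        return run_discrete(config, rng=rng)
    return run_gillespie(config, rng=rng)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepSpec:
    """A factorial sweep: a base config, a grid of field overrides, and a
    replicate count.  Grid keys are :class:`SimConfig` field names."""

    base: SimConfig
    grid: dict = field(default_factory=dict)
    replicates: int = 100
    master_seed: int = 0
    name: str = "sweep"

    def cells(self) -> list[dict]:
        if not self.grid:
            return [{}]
        keys = sorted(self.grid)
        return [dict(zip(keys, vals)) for vals in itertools.product(*(self.grid[k] for k in keys))]


def child_rng(master_seed: int, cell_index: int, replicate: int) -> np.random.Generator:
    """Independent, deterministic stream for one (cell, replicate)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(cell_index, replicate))
    return np.random.default_rng(ss)


def _cell_label(cell: dict) -> dict:
    out = {}
    for k, v in cell.items():
        if isinstance(v, FunctionalResponse):
            out[k] = v.kind
        else:
            out[k] = v
    return out


def run_sweep(
    spec: SweepSpec, out_dir: Optional[str] = None, write_events: bool = False
) -> pd.DataFrame:
    """Execute every (cell, replicate) and return the tidy per-run table.

    Each run uses its own counter-derived stream, so the output is a pure
    function of the spec.  Individual run failures are recorded in the
    ``status`` column and do not abort the sweep.  If ``out_dir`` is given,
    ``runs.csv`` (one row per run) and ``summary.csv`` (one row per cell) are
    written there, plus per-run event logs when ``write_events`` is set.
    """
    cells = spec.cells()
    frames = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for ci, cell in enumerate(cells):
        rows = []
        n_err = 0
        for rep in range(spec.replicates):
            row = {"cell": ci, "replicate": rep, **_cell_label(cell)}
            rng = child_rng(spec.master_seed, ci, rep)
            try:
                cfg = spec.base.replace(seed=None, **cell)
                res = simulate(cfg, rng=rng)
                row.update(
                    time_to_stop=res.time_to_stop,
                    stop_reason=res.stop_reason,
                    reached_true_ifd=res.reached_true_ifd,
                    max_moves=res.max_moves,
                    total_moves=int(res.moves.sum()),
                    status="ok",
                    **res.metrics,
                )
                if out_path is not None and write_events:
                    res.events_to_frame().to_csv(
                        out_path / f"events_cell{ci}_rep{rep}.csv", index=False
                    )
            except Exception as exc:  # noqa: BLE001 — sweep must survive bad cells
                log.warning("run failed (cell %d, rep %d): %s", ci, rep, exc)
                row["status"] = f"error: {exc}"
                n_err += 1
            rows.append(row)
        frames.append(pd.DataFrame(rows))
        log.info("cell %d/%d done (%d runs, %d failed)", ci + 1, len(cells), len(rows), n_err)
    runs = pd.concat(frames, ignore_index=True)
    runs["master_seed"] = spec.master_seed
    if out_path is not None:
        runs.drop(columns=["seed"], errors="ignore").to_csv(out_path / "runs.csv", index=False)
        summary = summarize_sweep(runs, cells)
        summary.to_csv(out_path / "summary.csv", index=False)
    return runs


def summarize_sweep(runs: pd.DataFrame, cells: Optional[list] = None) -> pd.DataFrame:
    """One summary row per sweep cell: time-to-stop quantiles, the fraction
    of runs truly at the IFD, and the move-count maximum."""
    ok = runs[runs["status"] == "ok"]
    grouped = ok.groupby("cell")
    summary = grouped.agg(
        n_runs=("time_to_stop", "size"),
        mean_time=("time_to_stop", "mean"),
        median_time=("time_to_stop", "median"),
        q25_time=("time_to_stop", lambda s: s.quantile(0.25)),
        q75_time=("time_to_stop", lambda s: s.quantile(0.75)),
        proportion_true_ifd=("reached_true_ifd", "mean"),
        max_moves=("max_moves", "max"),
        mean_intake_variance=("intake_variance", "mean"),
    ).reset_index()
    if cells:
        labels = pd.DataFrame([_cell_label(c) for c in cells])
        labels["cell"] = range(len(cells))
        summary = summary.merge(labels, on="cell", how="left")
    return summary


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _preset_mixture_slowdown(scheduler: str = "discrete", replicates: int = 200, **over) -> SweepSpec:
    """Time-to-IFD versus the active/inactive mixture (activities 0.8/0.2,
    N=40): mean time-to-IFD should fall as the proportion of active
    consumers rises."""
    base = SimConfig(
        n_consumers=40,
        activity_high=0.8,
        activity_low=0.2,
        scheduler=scheduler,
        stopping="true_ifd",
        **over,
    )
    return SweepSpec(
        base=base,
        grid={"proportion_active": [0.0, 0.25, 0.5, 0.75, 1.0]},
        replicates=replicates,
        name=f"mixture_slowdown_{scheduler}",
    )


def _preset_stopping_bias(replicates: int = 200, **over) -> SweepSpec:
    """Premature-termination bias of the 50-step quiescence criterion
    (activities 0.9/0.1, N=40): compare the quiescence rule against stopping
    only when the IFD actually holds."""
    base = SimConfig(
        n_consumers=40,
        activity_high=0.9,
        activity_low=0.1,
        scheduler="discrete",
        quiescence_window=50,
        **over,
    )
    return SweepSpec(
        base=base,
        grid={
            "proportion_active": [0.0, 0.1, 0.2, 0.3, 0.5, 1.0],
            "stopping": ["quiescence", "true_ifd"],
        },
        replicates=replicates,
        name="stopping_bias",
    )


def _preset_popsize_gillespie(replicates: int = 100, **over) -> SweepSpec:
    """Population-size effect under the event-based scheduler (rates
    0.8/0.2, 49 patches): at high density the IFD is reached *faster* because
    departures relax within-patch competition."""
    base = SimConfig(
        activity_high=0.8,
        activity_low=0.2,
        scheduler="gillespie",
        stopping="true_ifd",
        **over,
    )
    return SweepSpec(
        base=base,
        grid={
            "n_consumers": [8, 40, 100, 1000],
            "proportion_active": [0.0, 0.25, 0.5, 0.75, 1.0],
        },
        replicates=replicates,
        name="popsize_gillespie",
    )


PRESETS = {
    "mixture_slowdown": _preset_mixture_slowdown,
    "stopping_bias": _preset_stopping_bias,
    "popsize_gillespie": _preset_popsize_gillespie,
}


def get_preset(name: str, master_seed: int = 0, **overrides) -> SweepSpec:
    """Build a named preset sweep; ``overrides`` adjust the base config or
    the replicate count (e.g. ``replicates=1000`` for full scale)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    spec = PRESETS[name](**overrides)
    spec.master_seed = master_seed
    return spec
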