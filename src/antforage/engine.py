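"""Whole-simulation orchestration: runs, replicates, experiments, sweeps.

A run initialises the T-maze with zero pheromone and the whole colony idle
at the nest centre, then advances in discrete time steps.  Each step
updates the agents grouped by behavioural state in a fixed sequence
(idle, searching, feeding, dissatisfied, recruiting, unloading — or the
reverse for the robustness variant), applies one global pheromone decay,
and records the feeding counts per patch, the summed pheromone per arm,
and the behavioural-state census.

Two named experiments reproduce the headline settings: a stable
environment with two identical patches opened simultaneously at one of
four crowding thresholds, and a changing environment where a second patch
with three times the feeding capacity opens after a delay.  ``sweep``
drives the sensitivity analyses (colony size, decay rate, maze size,
dissatisfied-routing probability).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from ._kernels import run_core
from .agents import BehaviourParams
from .errors import ConfigError
from .world import Geometry, PheromoneParams, World, build_world

#: Default number of replicate runs for the headline experiments.
N_RUNS_HEADLINE = 30
#: Default number of replicate runs per grid point in sensitivity sweeps.
N_RUNS_SWEEP = 10
#: Persistence window (steps) a crossing must be sustained for to count as
#: a switch; one simulated minute, suppressing single-step noise.
CROSSING_PERSISTENCE = 60
#: Step at which the majority patch of a stable-environment run is read off.
MAJORITY_AT_STEP = 600


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one run (defaults are the standard model
    settings: 500 agents, 5400 steps, decay 0.4 %/step, deposit 60)."""

    colony_size: int = 500
    total_steps: int = 5400
    thresholds: tuple[int, int] = (8, 8)
    patch2_delay: int = 0
    pheromone: PheromoneParams = field(default_factory=PheromoneParams)
    behaviour: BehaviourParams = field(default_factory=BehaviourParams)
    geometry: Geometry = field(default_factory=Geometry)
    update_order: str = "forward"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.colony_size < 1:
            raise ConfigError("colony_size must be >= 1")
        if self.total_steps < 1:
            raise ConfigError("total_steps must be >= 1")
        if self.patch2_delay < 0:
            raise ConfigError("patch2_delay must be >= 0")
        th = self.thresholds
        if len(th) != 2 or any(int(v) < 1 for v in th):
            raise ConfigError("thresholds must be a pair of positive integers")
        if self.update_order not in ("forward", "reversed"):
            raise ConfigError(f"update_order must be 'forward' or 'reversed', got {self.update_order!r}")
        if not 0 <= int(self.seed) < 2**31:
            raise ConfigError("seed must lie in [0, 2**31)")


@dataclass
class RunResult:
    """Per-step series of one seeded run.

    ``feeding_counts[t]`` is the pair (N1, N2) of agents in state feeding
    on each patch at the end of step t+1; ``arm_pheromone[t]`` the summed
    pheromone over each arm's cells (junction excluded); ``state_census``
    the six-state head count; ``final_pheromone`` the full field after the
    last step.
    """

    feeding_counts: np.ndarray   # (T, 2) int
    arm_pheromone: np.ndarray    # (T, 2) float
    dissatisfied: np.ndarray     # (T,) int
    state_census: np.ndarray     # (T, 6) int
    final_pheromone: np.ndarray  # (H, W) float
    seed: int
    config: SimConfig

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.feeding_counts.shape[0] + 1)

    def count_series(self) -> metrics.CountSeries:
        return metrics.CountSeries(
            times=self.times,
            counts_1=self.feeding_counts[:, 0],
            counts_2=self.feeding_counts[:, 1],
            source="simulation",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.times,
                "N1": self.feeding_counts[:, 0],
                "N2": self.feeding_counts[:, 1],
                "P1": self.arm_pheromone[:, 0],
                "P2": self.arm_pheromone[:, 1],
                "dissatisfied": self.dissatisfied,
            }
        )


@dataclass
class ReplicateSet:
    """Independent runs of one parameterisation under distinct seeds."""

    runs: list[RunResult]
    config: SimConfig
    seeds: list[int]

    def mean_feeding(self) -> np.ndarray:
        """Across-run mean feeding counts, shape (T, 2)."""
        return np.mean([r.feeding_counts for r in self.runs], axis=0)

    def mean_arm_pheromone(self) -> np.ndarray:
        return np.mean([r.arm_pheromone for r in self.runs], axis=0)

    def switch_summary(self, persistence: int = CROSSING_PERSISTENCE) -> metrics.SwitchSummary:
        """Crossing times of the across-run mean count and mean pheromone
        series (patch/branch 2 overtaking 1)."""
        mf = self.mean_feeding()
        mp = self.mean_arm_pheromone()
        t = self.runs[0].times
        return metrics.SwitchSummary(
            crossing_time_agents=metrics.crossing_time(mf[:, 0], mf[:, 1], persistence, times=t),
            crossing_time_pheromone=metrics.crossing_time(mp[:, 0], mp[:, 1], persistence, times=t),
        )

    def reallocated(self, persistence: int = CROSSING_PERSISTENCE) -> bool:
        """Whether the colony durably reallocated its majority to patch 2:
        a sustained crossing of the across-run mean counts occurs within
        the run *and* the patch-2 majority still holds over the final
        ``persistence`` window (a transient blip crossing does not count)."""
        mf = self.mean_feeding()
        t = self.runs[0].times
        ct = metrics.crossing_time(mf[:, 0], mf[:, 1], persistence, times=t)
        if ct is None:
            return False
        return float(mf[-persistence:, 1].mean()) > float(mf[-persistence:, 0].mean())


def build_world_for(config: SimConfig) -> World:
    return build_world(config.geometry, patch_open_at=(0, config.patch2_delay))


def run_simulation(config: SimConfig) -> RunResult:
    """Execute one seeded run and collect its full time series."""
    world = build_world_for(config)
    b = config.behaviour
    start = (world.nest_centre[0] + 0.5, world.nest_centre[1] + 0.5)
    feed, pher, dis, census, final_pher = run_core(
        np.uint32(config.seed),
        config.colony_size,
        config.total_steps,
        world.region,
        world.target_scent,
        world.patch_open_at,
        np.asarray(config.thresholds, dtype=np.int64),
        config.pheromone.deposit_amount,
        config.pheromone.decay_factor,
        config.pheromone.detection_threshold,
        b.leave_probability,
        b.drinking_time,
        b.unloading_time,
        start[0],
        start[1],
        config.update_order == "reversed",
        b.routing_mode == "routed",
        -1.0 if b.p_nest_when_dissatisfied is None else b.p_nest_when_dissatisfied,
    )
    return RunResult(
        feeding_counts=feed,
        arm_pheromone=pher,
        dissatisfied=dis,
        state_census=census,
        final_pheromone=final_pher,
        seed=config.seed,
        config=config,
    )


def derive_seeds(seed_base: int, key: tuple[int, ...], n: int) -> list[int]:
    """``n`` distinct sub-2**31 run seeds derived deterministically from a
    base seed and a context key (experiment/grid-point indices)."""
    ss = np.random.SeedSequence([int(seed_base), *[int(k) for k in key]])
    seeds: list[int] = []
    seen: set[int] = set()
    pool = ss.generate_state(max(4 * n, 16), dtype=np.uint32)
    j = 0
    while len(seeds) < n:
        if j >= pool.size:
            pool = ss.generate_state(pool.size * 2, dtype=np.uint32)
            j = 0
        s = int(pool[j]) % 2**31
        j += 1
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return seeds


def run_replicates(
    config: SimConfig,
    n_runs: int = N_RUNS_HEADLINE,
    seed_base: int | None = None,
    key: tuple[int, ...] = (),
) -> ReplicateSet:
    """Run ``n_runs`` independent replicates under distinct derived seeds."""
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    base = config.seed if seed_base is None else seed_base
    seeds = derive_seeds(base, key, n_runs)
    runs = [
        run_simulation(dataclasses.replace(config, seed=s)) for s in seeds
    ]
    return ReplicateSet(runs=runs, config=config, seeds=seeds)


# ---------------------------------------------------------------------------
# Named experiments
# ---------------------------------------------------------------------------

def majority_proportion(
    repset: ReplicateSet, at_step: int = MAJORITY_AT_STEP
) -> tuple[np.ndarray, np.ndarray, float]:
    """Across-run mean (and SD) of the per-step proportion of feeding
    agents at each run's majority patch (the patch ahead at ``at_step``),
    plus the grand mean over runs of the per-run time-averaged proportion.

    Timepoints where no agent is feeding are undefined and ignored.
    """
    per_run = []
    for r in repset.runs:
        series = r.count_series()
        maj = metrics.majority_patch(series, at_step)
        p1, p2 = metrics.proportions(series)
        per_run.append(p1 if maj == 1 else p2)
    stacked = np.vstack(per_run)
    mean_series = np.nanmean(stacked, axis=0)
    sd_series = np.nanstd(stacked, axis=0, ddof=1)
    run_means = np.nanmean(stacked, axis=1)
    return mean_series, sd_series, float(np.mean(run_means))


def stable_summary(repset: ReplicateSet) -> dict[str, float]:
    """Replicate-mean symmetry index and majority-patch proportion of one
    stable-environment replicate set."""
    sym = [metrics.symmetry_index(r.count_series()) for r in repset.runs]
    _, _, maj_mean = majority_proportion(repset)
    return {
        "symmetry_index_mean": float(np.mean(sym)),
        "symmetry_index_sd": float(np.std(sym, ddof=1)),
        "majority_proportion_mean": maj_mean,
    }


def experiment_stable(
    thresholds: tuple[int, ...] = (8, 24, 72, 216),
    config: SimConfig | None = None,
    n_runs: int = N_RUNS_HEADLINE,
    seed_base: int = 0,
) -> tuple[dict[int, ReplicateSet], pd.DataFrame]:
    """Stable environment: both patches identical and open from the start,
    one replicate set per crowding threshold.

    Returns the per-threshold replicate sets and a tidy summary with one
    row per threshold (symmetry index and majority-patch proportion,
    replicate means).
    """
    base = config or SimConfig()
    out: dict[int, ReplicateSet] = {}
    rows = []
    for k, th in enumerate(thresholds):
        cfg = dataclasses.replace(base, thresholds=(int(th), int(th)), patch2_delay=0)
        rs = run_replicates(cfg, n_runs=n_runs, seed_base=seed_base, key=(1, k))
        out[int(th)] = rs
        rows.append({"threshold": int(th), **stable_summary(rs)})
    return out, pd.DataFrame(rows)


def experiment_changing(
    threshold_pairs: tuple[tuple[int, int], ...] = ((8, 24), (24, 72), (72, 216)),
    delay: int = 900,
    config: SimConfig | None = None,
    n_runs: int = N_RUNS_HEADLINE,
    seed_base: int = 0,
) -> tuple[dict[tuple[int, int], ReplicateSet], pd.DataFrame]:
    """Changing environment: patch 2, with three times the feeding
    capacity, opens ``delay`` steps into the run.

    Returns per-pair replicate sets and a summary with the agent-count and
    branch-pheromone crossing times of the across-run mean series.
    """
    base = config or SimConfig()
    out: dict[tuple[int, int], ReplicateSet] = {}
    rows = []
    for k, pair in enumerate(threshold_pairs):
        cfg = dataclasses.replace(
            base, thresholds=(int(pair[0]), int(pair[1])), patch2_delay=delay
        )
        rs = run_replicates(cfg, n_runs=n_runs, seed_base=seed_base, key=(2, k))
        out[(int(pair[0]), int(pair[1]))] = rs
        sw = rs.switch_summary()
        rows.append(
            {
                "threshold_1": int(pair[0]),
                "threshold_2": int(pair[1]),
                "crossing_time_agents": sw.crossing_time_agents,
                "crossing_time_pheromone": sw.crossing_time_pheromone,
                "switched": sw.switched,
            }
        )
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sensitivity sweeps
# ---------------------------------------------------------------------------

_SWEEP_PARAM_KEY = {
    "colony_size": 0,
    "decay_rate": 1,
    "stem_multiplier": 2,
    "arm_multiplier": 3,
    "p_nest": 4,
}


def _apply_sweep_value(config: SimConfig, parameter: str, value) -> SimConfig:
    if parameter == "colony_size":
        return dataclasses.replace(config, colony_size=int(value))
    if parameter == "decay_rate":
        return dataclasses.replace(
            config, pheromone=dataclasses.replace(config.pheromone, decay_rate=float(value))
        )
    if parameter == "stem_multiplier":
        return dataclasses.replace(
            config, geometry=dataclasses.replace(config.geometry, stem_multiplier=int(value))
        )
    if parameter == "arm_multiplier":
        return dataclasses.replace(
            config, geometry=dataclasses.replace(config.geometry, arm_multiplier=int(value))
        )
    if parameter == "p_nest":
        return dataclasses.replace(
            config,
            behaviour=dataclasses.replace(
                config.behaviour, routing_mode="routed", p_nest_when_dissatisfied=float(value)
            ),
        )
    raise ConfigError(f"unknown sweep parameter {parameter!r}")


def sweep(
    parameter: str,
    values,
    config: SimConfig | None = None,
    n_runs: int = N_RUNS_SWEEP,
    seed_base: int = 0,
    persistence: int = CROSSING_PERSISTENCE,
) -> tuple[pd.DataFrame, dict]:
    """Vary one parameter over a grid, ``n_runs`` replicates per point.

    Returns a tidy table with one row per (grid point, replicate) —
    per-run crossing time and switched flag — and a dict mapping each grid
    value to the ReplicateSet (whose ``switch_summary`` gives the
    mean-series crossing).
    """
    values = list(values)
    if not values:
        raise ConfigError("sweep grid must be non-empty")
    base = config or SimConfig()
    rows = []
    repsets: dict = {}
    for k, v in enumerate(values):
        cfg = _apply_sweep_value(base, parameter, v)
        rs = run_replicates(
            cfg, n_runs=n_runs, seed_base=seed_base, key=(3, _SWEEP_PARAM_KEY[parameter], k)
        )
        repsets[v] = rs
        for rep, r in enumerate(rs.runs):
            ct = metrics.crossing_time(
                r.feeding_counts[:, 0], r.feeding_counts[:, 1], persistence, times=r.times
            )
            rows.append(
                {
                    "parameter": parameter,
                    "value": v,
                    "replicate": rep,
                    "seed": rs.seeds[rep],
                    "crossing_time": ct,
                    "switched": ct is not None,
                }
            )
    return pd.DataFrame(rows), repsets


def minimal_switching_size(
    sizes,
    thresholds: tuple[int, int],
    delay: int = 900,
    config: SimConfig | None = None,
    n_runs: int = N_RUNS_SWEEP,
    seed_base: int = 0,
) -> tuple[int | None, pd.DataFrame]:
    """Smallest colony size (over an ascending grid) that durably
    reallocates its forager majority to patch 2 (see
    :meth:`ReplicateSet.reallocated`); ``None`` when no grid size does."""
    base = dataclasses.replace(
        config or SimConfig(),
        thresholds=(int(thresholds[0]), int(thresholds[1])),
        patch2_delay=delay,
    )
    rows = []
    smallest: int | None = None
    for size in sorted(int(s) for s in sizes):
        cfg = dataclasses.replace(base, colony_size=size)
        rs = run_replicates(cfg, n_runs=n_runs, seed_base=seed_base, key=(4, size))
        sw = rs.switch_summary()
        realloc = rs.reallocated()
        rows.append(
            {
                "colony_size": size,
                "crossing_time_agents": sw.crossing_time_agents,
                "crossed": sw.switched,
                "reallocated": realloc,
            }
        )
        if smallest is None and realloc:
            smallest = size
    return smallest, pd.DataFrame(rows)
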