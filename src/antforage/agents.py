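"""The six-state forager behavioural machine, agent by agent.

An agent is idle in the nest, searching for food, feeding at a patch,
dissatisfied (turned away from a crowded patch), recruiting (walking home
full while laying trail), or unloading in the nest.  Movement is
off-lattice: continuous coordinates, one of 8 compass headings, step
length exactly one cell per step regardless of direction; the occupied
cell is the floor of the coordinates.

This module is the per-agent reference implementation of the rules, built
for inspection and unit testing; whole runs go through the compiled loop
in :mod:`antforage._kernels`, which applies the same rules to flat state
arrays.  Randomness here comes from a caller-supplied
:class:`numpy.random.Generator`.

Movement rules shared by several states:

* sensing samples the three cells in walking direction (0, +-45 degrees)
  and picks the one with the most field value (trail pheromone above the
  detection threshold for searchers; nest scent, no threshold, for
  homing recruiters), ties broken uniformly at random;
* when nothing is sensed, the agent moves uniformly at random over the
  8 directions whose destination cell is walkable; in a dead end (no
  admissible direction) it reverses heading without moving.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from . import world as wd
from ._kernels import DX, DY
from .errors import ConfigError


class AgentState(IntEnum):
    IDLE = 0
    SEARCHING = 1
    FEEDING = 2
    DISSATISFIED = 3
    RECRUITING = 4
    UNLOADING = 5


# Routed-variant commitment targets.
TARGET_NEST = 0
TARGET_PATCH_1 = 1
TARGET_PATCH_2 = 2


@dataclass(frozen=True)
class BehaviourParams:
    """Behavioural constants of the forager state machine.

    leave_probability
        Per-step probability that an idle forager leaves the nest
        (2/1000 per agent per second, so the expected number of leavers
        per step is 0.002 times the idle pool).
    drinking_time, unloading_time
        Time steps spent feeding at a patch / unloading in the nest.
    routing_mode
        ``random_walk`` (default): dissatisfied agents wander blindly.
        ``routed``: on becoming dissatisfied an agent commits, with
        probability ``p_nest_when_dissatisfied``, to walking directly home
        (resuming search on arrival) and otherwise directly to the other
        patch; if both patches are at threshold it heads home.
    """

    leave_probability: float = 2.0 / 1000.0
    drinking_time: int = 60
    unloading_time: int = 60
    routing_mode: str = "random_walk"
    p_nest_when_dissatisfied: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.leave_probability <= 1.0:
            raise ConfigError("leave_probability must be a probability")
        if self.drinking_time < 1 or self.unloading_time < 1:
            raise ConfigError("drinking_time and unloading_time must be >= 1 step")
        if self.routing_mode not in ("random_walk", "routed"):
            raise ConfigError(f"unknown routing_mode {self.routing_mode!r}")
        if self.routing_mode == "routed":
            p = self.p_nest_when_dissatisfied
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigError(
                    "routed mode requires p_nest_when_dissatisfied in [0, 1]"
                )


@dataclass
class Agent:
    """One forager: position, heading, behavioural state and bookkeeping."""

    id: int
    position: tuple[float, float]
    heading: int = 0
    state: AgentState = AgentState.IDLE
    timer: int = 0
    crop: str = "empty"           # "empty" | "full"
    patch: int | None = None      # patch index (0/1) while feeding
    target: int | None = None     # routed-variant commitment while dissatisfied

    @property
    def cell(self) -> tuple[int, int]:
        return (int(np.floor(self.position[0])), int(np.floor(self.position[1])))


def admissible_directions(world: wd.World, position: tuple[float, float]) -> list[int]:
    """Directions whose one-step destination cell is walkable."""
    x, y = position
    out = []
    for d in range(8):
        cx = int(np.floor(x + DX[d]))
        cy = int(np.floor(y + DY[d]))
        if world.is_walkable((cx, cy)):
            out.append(d)
    return out


def sense_forward(
    field: np.ndarray,
    world: wd.World,
    position: tuple[float, float],
    heading: int,
    threshold: float,
    rng: np.random.Generator,
) -> int | None:
    """Direction (absolute, 0..7) of the richest of the three forward cells.

    Only walkable cells with field value strictly above ``threshold``
    qualify; ties among maxima are broken uniformly at random; ``None``
    when no forward cell qualifies.
    """
    x, y = position
    if not world.is_walkable((int(np.floor(x)), int(np.floor(y)))):
        raise ValueError(f"position {position} is outside the walkable region")
    candidates: list[int] = []
    best = threshold
    for k in (-1, 0, 1):
        d = (heading + k) % 8
        cx = int(np.floor(x + DX[d]))
        cy = int(np.floor(y + DY[d]))
        if not world.is_walkable((cx, cy)):
            continue
        v = field[cy, cx]
        if v > best:
            best = v
            candidates = [d]
        elif candidates and v == best:
            candidates.append(d)
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    return int(rng.choice(candidates))


def _move(agent: Agent, direction: int) -> None:
    x, y = agent.position
    agent.position = (x + DX[direction], y + DY[direction])
    agent.heading = int(direction)


def _walk_or_turn(agent: Agent, world: wd.World, rng: np.random.Generator) -> bool:
    """Uniform random step over admissible directions; on a dead end the
    agent reverses heading and stays put.  Returns whether it moved."""
    dirs = admissible_directions(world, agent.position)
    if not dirs:
        agent.heading = (agent.heading + 4) % 8
        return False
    _move(agent, int(rng.choice(dirs)))
    return True


def _patch_index_at(world: wd.World, cell: tuple[int, int]) -> int | None:
    rc = world.region[cell[1], cell[0]]
    if rc == wd.PATCH_1:
        return 0
    if rc == wd.PATCH_2:
        return 1
    return None


def try_enter_patch(
    agent: Agent,
    patch: int,
    t: int,
    thresholds: tuple[int, int],
    feeding_counts: np.ndarray,
    world: wd.World,
    behaviour: BehaviourParams,
) -> str:
    """Feeding admission under the crowding threshold.

    Returns ``"fed"`` (admitted: state feeding, timer set, live count
    bumped), ``"crowded"`` (open patch at threshold) or ``"closed"``
    (patch not yet available: nothing happens).
    """
    if not wd.patch_is_open(world, patch + 1, t):
        return "closed"
    if feeding_counts[patch] < thresholds[patch]:
        feeding_counts[patch] += 1
        agent.state = AgentState.FEEDING
        agent.timer = behaviour.drinking_time
        agent.patch = patch
        return "fed"
    return "crowded"


def step_idle(agent: Agent, behaviour: BehaviourParams, rng: np.random.Generator) -> Agent:
    """Leaving lottery: with the per-step leave probability the idle agent
    starts searching (fresh random heading); otherwise unchanged."""
    assert agent.state == AgentState.IDLE
    if rng.random() < behaviour.leave_probability:
        agent.state = AgentState.SEARCHING
        agent.heading = int(rng.integers(0, 8))
    return agent


def step_searching(
    agent: Agent,
    world: wd.World,
    behaviour: BehaviourParams,
    pheromone: wd.PheromoneParams,
    thresholds: tuple[int, int],
    feeding_counts: np.ndarray,
    t: int,
    rng: np.random.Generator,
) -> Agent:
    """Trail-guided (or random) search step, with feeding admission or
    dissatisfaction on arriving in an open patch."""
    assert agent.state == AgentState.SEARCHING
    d = sense_forward(
        world.pheromone, world, agent.position, agent.heading,
        pheromone.detection_threshold, rng,
    )
    if d is None:
        if not _walk_or_turn(agent, world, rng):
            return agent
    else:
        _move(agent, d)
    p = _patch_index_at(world, agent.cell)
    if p is not None:
        res = try_enter_patch(agent, p, t, thresholds, feeding_counts, world, behaviour)
        if res == "crowded":
            agent.state = AgentState.DISSATISFIED
            if behaviour.routing_mode == "routed":
                _commit(agent, p, t, thresholds, feeding_counts, world, behaviour, rng)
    return agent


def step_feeding(agent: Agent, feeding_counts: np.ndarray) -> Agent:
    """Countdown at the patch; on the last tick the crop fills and the
    agent turns recruiter (freeing its feeding slot)."""
    assert agent.state == AgentState.FEEDING and agent.timer >= 1
    agent.timer -= 1
    if agent.timer <= 0:
        feeding_counts[agent.patch] -= 1
        agent.patch = None
        agent.crop = "full"
        agent.state = AgentState.RECRUITING
    return agent


def step_recruiting(
    agent: Agent,
    world: wd.World,
    pheromone: wd.PheromoneParams,
    behaviour: BehaviourParams,
    rng: np.random.Generator,
) -> Agent:
    """Homing step up the nest-scent gradient, laying one trail mark on the
    cell entered; on reaching the nest the agent starts unloading."""
    assert agent.state == AgentState.RECRUITING and agent.crop == "full"
    d = sense_forward(
        world.nest_scent, world, agent.position, agent.heading, -np.inf, rng
    )
    if d is None:
        if not _walk_or_turn(agent, world, rng):
            return agent
    else:
        _move(agent, d)
    wd.deposit(world, agent.cell, pheromone)
    if world.region[agent.cell[1], agent.cell[0]] == wd.NEST:
        agent.state = AgentState.UNLOADING
        agent.timer = behaviour.unloading_time
    return agent


def _commit(
    agent: Agent,
    p: int,
    t: int,
    thresholds: tuple[int, int],
    feeding_counts: np.ndarray,
    world: wd.World,
    behaviour: BehaviourParams,
    rng: np.random.Generator,
) -> None:
    other = 1 - p
    if (
        not wd.patch_is_open(world, other + 1, t)
        or feeding_counts[other] >= thresholds[other]
    ):
        agent.target = TARGET_NEST
    elif rng.random() < behaviour.p_nest_when_dissatisfied:
        agent.target = TARGET_NEST
    else:
        agent.target = other + 1


def step_dissatisfied(
    agent: Agent,
    world: wd.World,
    behaviour: BehaviourParams,
    thresholds: tuple[int, int],
    feeding_counts: np.ndarray,
    t: int,
    rng: np.random.Generator,
) -> Agent:
    """Turned-away behaviour.

    Default mode: blind random walk — pheromone is neither followed nor
    laid — resuming feeding on wandering into any open patch with a free
    slot, and rejoining the idle pool (idle is the in-nest state) if the
    walk carries it back inside the nest.  Routed mode: walk the committed
    direct path (nest or the other patch) down the matching scent
    gradient; reaching the nest resumes searching, reaching a
    still-crowded patch re-routes home.
    """
    assert agent.state == AgentState.DISSATISFIED
    if behaviour.routing_mode == "routed" and agent.target is not None:
        d = sense_forward(
            world.target_scent[agent.target], world, agent.position, agent.heading,
            -np.inf, rng,
        )
        if d is None:
            if not _walk_or_turn(agent, world, rng):
                return agent
        else:
            _move(agent, d)
        rc = world.region[agent.cell[1], agent.cell[0]]
        if agent.target == TARGET_NEST:
            if rc == wd.NEST:
                agent.state = AgentState.SEARCHING
                agent.target = None
        elif rc == wd.PATCH_1 + (agent.target - 1):
            res = try_enter_patch(
                agent, agent.target - 1, t, thresholds, feeding_counts, world, behaviour
            )
            if res == "fed":
                agent.target = None
            elif res == "crowded":
                agent.target = TARGET_NEST
        return agent

    if not _walk_or_turn(agent, world, rng):
        return agent
    rc = world.region[agent.cell[1], agent.cell[0]]
    if rc == wd.NEST:
        # unsuccessful forager back inside the nest: rejoin the idle pool
        agent.state = AgentState.IDLE
        return agent
    p = _patch_index_at(world, agent.cell)
    if p is not None:
        try_enter_patch(agent, p, t, thresholds, feeding_counts, world, behaviour)
    return agent


def step_unloading(agent: Agent) -> Agent:
    """Countdown in the nest; on the last tick the crop empties and the
    agent rejoins the idle pool (and its leaving lottery)."""
    assert agent.state == AgentState.UNLOADING and agent.timer >= 1
    agent.timer -= 1
    if agent.timer <= 0:
        agent.crop = "empty"
        agent.state = AgentState.IDLE
    return agent
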