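"""T-maze world: geometry, the static nest-scent field and the pheromone field.

The arena is a two-dimensional grid of unit cells shaped like a T connected
to a nest: a rectangular nest at the base, a vertical stem, two
mirror-image horizontal arms, and a square food-patch block at the distal
end of each arm.  Agents move off-lattice (continuous coordinates, step
length one cell), but all fields — trail pheromone and the nest-scent
gradient used by homing foragers — live on the integer cell grid.

Coordinate convention: ``(x, y)`` with ``x`` the column and ``y`` the row,
0-based, origin at the bottom-left corner of the bounding box; arrays are
indexed ``[y, x]``.  A continuous position belongs to the cell given by the
integer floor of each coordinate.

Pheromone dynamics on a cell are deposition (``+c`` per crossing by a
trail-laying forager) and per-step exponential decay
``C(t) = C(t-1) * (100 - r) / 100`` with ``r`` in percent per time step.
There is no diffusion between cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

# Region codes (values of the region grid; WALL marks non-walkable cells).
NEST = 0
STEM = 1
LEFT_ARM = 2
RIGHT_ARM = 3
PATCH_1 = 4
PATCH_2 = 5
WALL = -1

REGION_NAMES = {
    NEST: "nest",
    STEM: "stem",
    LEFT_ARM: "left_arm",
    RIGHT_ARM: "right_arm",
    PATCH_1: "patch_1",
    PATCH_2: "patch_2",
    WALL: "wall",
}


@dataclass(frozen=True)
class Geometry:
    """T-maze dimensions in cells.

    Defaults give a stem of 24x5 cells, arms of 11x4, a 5x4 nest and 4x4
    food patches, so that a direct walk from a patch centre to the nest
    centre takes roughly 40 steps at speed one cell per step.  The
    multipliers scale the stem and arm lengths for the larger-maze
    sensitivity variants.
    """

    stem_length: int = 24
    stem_width: int = 5
    arm_length: int = 11
    arm_width: int = 4
    nest_width: int = 5
    nest_height: int = 4
    patch_size: int = 4
    stem_multiplier: int = 1
    arm_multiplier: int = 1

    def __post_init__(self) -> None:
        for name in (
            "stem_length",
            "stem_width",
            "arm_length",
            "arm_width",
            "nest_width",
            "nest_height",
            "patch_size",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"geometry field {name!r} must be a positive integer, got {v!r}")
        for name in ("stem_multiplier", "arm_multiplier"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or not 1 <= v <= 10:
                raise ConfigError(f"geometry field {name!r} must be an integer in 1..10, got {v!r}")
        if self.patch_size > self.arm_width:
            raise ConfigError("patch_size must not exceed arm_width")
        if self.nest_width > self.total_width():
            raise ConfigError("nest wider than the maze")
        if self.effective_stem_length() < self.arm_width:
            raise ConfigError("stem too short to carry the arm corridor")

    def effective_stem_length(self) -> int:
        return self.stem_length * self.stem_multiplier

    def effective_arm_length(self) -> int:
        return self.arm_length * self.arm_multiplier

    def total_width(self) -> int:
        return 2 * (self.effective_arm_length() + self.patch_size) + self.stem_width

    def total_height(self) -> int:
        return self.nest_height + self.effective_stem_length()


@dataclass(frozen=True)
class PheromoneParams:
    """Trail-pheromone constants.

    deposit_amount
        Pheromone units added to each cell a trail-laying forager enters on
        the way back to the nest (symbol ``c``).
    decay_rate
        Percent of the standing amount lost per time step (symbol ``r``);
        ``C(t) = C(t-1) * (100 - r) / 100``.
    detection_threshold
        Amount below which foragers cannot perceive the trail.
    """

    deposit_amount: float = 60.0
    decay_rate: float = 0.4
    detection_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.deposit_amount <= 0:
            raise ConfigError("deposit_amount must be positive")
        if not 0.0 <= self.decay_rate <= 100.0:
            raise ConfigError("decay_rate must lie in [0, 100] percent per step")
        if self.detection_threshold <= 0:
            raise ConfigError("detection_threshold must be positive")

    @property
    def decay_factor(self) -> float:
        return (100.0 - self.decay_rate) / 100.0


@dataclass
class World:
    """The built arena: region labels plus the scalar fields on the grid.

    ``target_scent`` stacks three gradient fields of the form
    ``100 - euclidean_distance(cell centre, target centre)`` for the nest
    and the two patch centres; index 0 (the nest field) is the nest scent
    used by homing foragers, the patch fields serve the routed
    dissatisfied-agent variant.
    """

    geometry: Geometry
    region: np.ndarray           # (H, W) int8, WALL outside the maze
    pheromone: np.ndarray        # (H, W) float64, >= 0
    target_scent: np.ndarray     # (3, H, W) float64
    patch_open_at: np.ndarray    # (2,) int64: first time step each patch provides food
    nest_centre: tuple[int, int]          # cell (x, y) of maximal nest scent
    patch_centres: tuple[tuple[float, float], tuple[float, float]]  # (x, y) points

    @property
    def nest_scent(self) -> np.ndarray:
        return self.target_scent[0]

    @property
    def walkable(self) -> np.ndarray:
        return self.region >= 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.region.shape

    def is_walkable(self, cell: tuple[int, int]) -> bool:
        x, y = cell
        h, w = self.region.shape
        return 0 <= x < w and 0 <= y < h and self.region[y, x] >= 0

    def region_cells(self, code: int) -> np.ndarray:
        """All (x, y) cells carrying the given region code, as an (n, 2) array."""
        ys, xs = np.nonzero(self.region == code)
        return np.column_stack([xs, ys])

    def arm_pheromone_sums(self) -> tuple[float, float]:
        """Summed pheromone over each arm's cells (junction cells are stem,
        hence excluded by construction)."""
        return (
            float(self.pheromone[self.region == LEFT_ARM].sum()),
            float(self.pheromone[self.region == RIGHT_ARM].sum()),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per walkable cell: x, y, region, pheromone, nest_scent."""
        ys, xs = np.nonzero(self.walkable)
        return pd.DataFrame(
            {
                "x": xs,
                "y": ys,
                "region": [REGION_NAMES[int(c)] for c in self.region[ys, xs]],
                "pheromone": self.pheromone[ys, xs],
                "nest_scent": self.nest_scent[ys, xs],
            }
        )


def build_world(geometry: Geometry, patch_open_at: tuple[int, int] = (0, 0)) -> World:
    """Construct the T-maze, zero the pheromone field and set up the scent
    gradients.

    The nest sits at the base of the stem; the stem rises to the arm
    corridor (the top ``arm_width`` stem rows form the junction, labelled
    stem so the two arms stay mirror-symmetric); the arms run left and
    right, each ending in a ``patch_size`` x ``patch_size`` food patch.
    Nest scent is ``100 - distance`` from the nest centre cell and is
    therefore maximal (100) there.
    """
    g = geometry
    stem_len = g.effective_stem_length()
    arm_len = g.effective_arm_length()
    ps, aw, sw = g.patch_size, g.arm_width, g.stem_width
    W = g.total_width()
    H = g.total_height()

    region = np.full((H, W), WALL, dtype=np.int8)
    cs0 = arm_len + ps               # first stem column
    x0 = cs0 + sw // 2               # stem axis column
    nx0 = x0 - g.nest_width // 2
    region[0 : g.nest_height, nx0 : nx0 + g.nest_width] = NEST
    region[g.nest_height : H, cs0 : cs0 + sw] = STEM
    ar0 = H - aw                     # arm corridor rows
    region[ar0:H, ps:cs0] = LEFT_ARM
    region[ar0:H, cs0 + sw : cs0 + sw + arm_len] = RIGHT_ARM
    pr0 = H - ps                     # patch rows (top-aligned with the arms)
    region[pr0:H, 0:ps] = PATCH_1
    region[pr0:H, W - ps : W] = PATCH_2

    nest_centre = (x0, g.nest_height // 2)
    p1_centre = (ps / 2.0, pr0 + ps / 2.0)
    p2_centre = (W - ps / 2.0, pr0 + ps / 2.0)

    yy, xx = np.indices((H, W), dtype=np.float64)
    cx, cy = xx + 0.5, yy + 0.5
    targets = [(nest_centre[0] + 0.5, nest_centre[1] + 0.5), p1_centre, p2_centre]
    target_scent = np.stack(
        [100.0 - np.hypot(cx - tx, cy - ty) for tx, ty in targets]
    )

    opens = np.asarray(patch_open_at, dtype=np.int64)
    if opens.shape != (2,) or (opens < 0).any():
        raise ConfigError("patch_open_at must be two non-negative time steps")

    return World(
        geometry=g,
        region=region,
        pheromone=np.zeros((H, W), dtype=np.float64),
        target_scent=target_scent,
        patch_open_at=opens,
        nest_centre=nest_centre,
        patch_centres=(p1_centre, p2_centre),
    )


def deposit(world: World, cell: tuple[int, int], params: PheromoneParams) -> World:
    """Add one trail mark (``deposit_amount``) to a walkable cell. Mutates
    and returns the world; deposits are purely additive, with no per-step cap."""
    if not world.is_walkable(cell):
        raise ValueError(f"cannot deposit on non-walkable cell {cell}")
    x, y = cell
    world.pheromone[y, x] += params.deposit_amount
    return world


def decay_step(world: World, params: PheromoneParams) -> World:
    """Apply one global decay step: every cell's pheromone is multiplied by
    ``(100 - r) / 100`` simultaneously."""
    world.pheromone *= params.decay_factor
    return world


def patch_is_open(world: World, patch_id: int, t: int) -> bool:
    """Whether patch ``patch_id`` (1 or 2) provides food at time step ``t``.

    A closed patch neither feeds agents nor makes them dissatisfied.
    """
    if patch_id not in (1, 2):
        raise ValueError(f"patch_id must be 1 or 2, got {patch_id}")
    return t >= int(world.patch_open_at[patch_id - 1])


def steps_to_undetectable(amount: float, params: PheromoneParams) -> float:
    """Number of decay steps after which a standing amount first falls below
    the detection threshold (closed form; ``inf`` for zero decay)."""
    if amount <= params.detection_threshold:
        return 0.0
    if params.decay_rate <= 0.0:
        return math.inf
    return math.ceil(
        math.log(amount / params.detection_threshold) / -math.log(params.decay_factor)
    )
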