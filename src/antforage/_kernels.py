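"""Compiled (numba) core of the simulation.

The whole-run loop lives here so that hundreds of replicate runs (5400
steps x hundreds of agents each) stay cheap.  The per-agent rules are the
same six-state machine exposed agent-by-agent in :mod:`antforage.agents`;
the kernels operate on flat state arrays.

Randomness: each run seeds numba's internal Mersenne state once
(``np.random.seed(seed)`` inside the jitted function), which makes a run
bit-reproducible for a given seed, independent of numpy's global state.

Scheduling per time step: agent groups are updated state by state in the
configured order (forward: idle, searching, feeding, dissatisfied,
recruiting, unloading; or the reverse), with group membership snapshotted
at the start of the step and members visited in freshly shuffled order;
then the whole pheromone field decays once; then the step is recorded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Agent states.
IDLE = 0
SEARCHING = 1
FEEDING = 2
DISSATISFIED = 3
RECRUITING = 4
UNLOADING = 5

# Region codes (must match antforage.world).
NEST = 0
PATCH_1 = 4
PATCH_2 = 5

# Unit step vectors for the 8 compass headings (multiples of 45 degrees,
# heading 0 = +x).  Axis components are exact; diagonals are sqrt(2)/2 so
# every move has length exactly 1.
_ANG = np.arange(8) * (np.pi / 4.0)
DX = np.cos(_ANG)
DY = np.sin(_ANG)
DX[2] = 0.0
DX[6] = 0.0
DY[0] = 0.0
DY[4] = 0.0

_NO_THRESHOLD = -1.0e30


@njit(cache=True)
def sense3(field, region, x, y, heading, threshold):
    """Pick the richest of the three forward cells (0, +-45 degrees).

    Returns the absolute direction (0..7) of the forward cell with the
    greatest field value strictly above ``threshold``, ties broken
    uniformly at random (reservoir draw); -1 if no forward cell qualifies.
    Non-walkable or out-of-bounds cells never qualify.
    """
    h, w = region.shape
    best = -1
    best_val = threshold
    n_best = 0
    for k in range(-1, 2):
        d = (heading + k) % 8
        cx = int(np.floor(x + DX[d]))
        cy = int(np.floor(y + DY[d]))
        if cx < 0 or cy < 0 or cx >= w or cy >= h:
            continue
        if region[cy, cx] < 0:
            continue
        v = field[cy, cx]
        if v > best_val:
            best = d
            best_val = v
            n_best = 1
        elif n_best > 0 and v == best_val:
            n_best += 1
            if np.random.random() * n_best < 1.0:
                best = d
    return best


@njit(cache=True)
def random_dir(region, x, y):
    """Uniform draw over the admissible compass directions (those whose
    one-step destination cell is walkable); -1 if none is admissible."""
    h, w = region.shape
    count = 0
    choice = -1
    for d in range(8):
        cx = int(np.floor(x + DX[d]))
        cy = int(np.floor(y + DY[d]))
        if cx < 0 or cy < 0 or cx >= w or cy >= h:
            continue
        if region[cy, cx] < 0:
            continue
        count += 1
        if np.random.random() * count < 1.0:
            choice = d
    return choice


@njit(cache=True)
def _try_feed(p, t, open_at, thresholds, feeding_count):
    """Attempt to start feeding on patch index ``p`` (0 or 1) at step ``t``.

    Returns 1 (admitted; the live feeding count is incremented), -1
    (patch open but at its crowding threshold) or 0 (patch not yet open:
    no feeding and no dissatisfaction).
    """
    if t < open_at[p]:
        return 0
    if feeding_count[p] < thresholds[p]:
        feeding_count[p] += 1
        return 1
    return -1


@njit(cache=True)
def _commit_target(p, t, open_at, thresholds, feeding_count, p_nest):
    """Routed-variant commitment drawn at the moment of dissatisfaction on
    patch ``p``: nest (0) with probability ``p_nest``, else the other patch
    (1 or 2); if the other patch is closed or itself at threshold the agent
    heads for the nest."""
    other = 1 - p
    if t < open_at[other] or feeding_count[other] >= thresholds[other]:
        return 0
    if np.random.random() < p_nest:
        return 0
    return other + 1


@njit(cache=True)
def run_core(
    seed,
    n_agents,
    total_steps,
    region,
    target_scent,
    open_at,
    thresholds,
    deposit_c,
    decay_factor,
    detect_threshold,
    p_leave,
    drinking_time,
    unloading_time,
    start_x,
    start_y,
    reversed_order,
    routed,
    p_nest,
):
    """One full seeded simulation run.

    Returns per-step series: feeding counts per patch (T, 2), summed arm
    pheromone per branch (T, 2), dissatisfied-agent count (T,), the full
    six-state census (T, 6) for invariant auditing, and the final
    pheromone grid.
    """
    np.random.seed(seed)
    h, w = region.shape
    pher = np.zeros((h, w), dtype=np.float64)
    nest_scent = target_scent[0]

    states = np.zeros(n_agents, dtype=np.int8)
    x = np.full(n_agents, start_x, dtype=np.float64)
    y = np.full(n_agents, start_y, dtype=np.float64)
    heading = np.empty(n_agents, dtype=np.int8)
    for i in range(n_agents):
        heading[i] = np.random.randint(0, 8)
    timer = np.zeros(n_agents, dtype=np.int64)
    patch_of = np.full(n_agents, -1, dtype=np.int8)
    target = np.full(n_agents, -1, dtype=np.int8)
    feeding_count = np.zeros(2, dtype=np.int64)

    # Arm cell coordinates for the per-step branch pheromone sums.
    n_left = 0
    n_right = 0
    for yy in range(h):
        for xx in range(w):
            if region[yy, xx] == 2:
                n_left += 1
            elif region[yy, xx] == 3:
                n_right += 1
    left_y = np.empty(n_left, dtype=np.int64)
    left_x = np.empty(n_left, dtype=np.int64)
    right_y = np.empty(n_right, dtype=np.int64)
    right_x = np.empty(n_right, dtype=np.int64)
    il = 0
    ir = 0
    for yy in range(h):
        for xx in range(w):
            if region[yy, xx] == 2:
                left_y[il] = yy
                left_x[il] = xx
                il += 1
            elif region[yy, xx] == 3:
                right_y[ir] = yy
                right_x[ir] = xx
                ir += 1

    feed_ts = np.zeros((total_steps, 2), dtype=np.int64)
    pher_ts = np.zeros((total_steps, 2), dtype=np.float64)
    dis_ts = np.zeros(total_steps, dtype=np.int64)
    census_ts = np.zeros((total_steps, 6), dtype=np.int64)

    prev = np.empty(n_agents, dtype=np.int8)
    members = np.empty(n_agents, dtype=np.int64)

    for t in range(1, total_steps + 1):
        for i in range(n_agents):
            prev[i] = states[i]
        for gi in range(6):
            g = (5 - gi) if reversed_order else gi
            m = 0
            for i in range(n_agents):
                if prev[i] == g:
                    members[m] = i
                    m += 1
            for j in range(m - 1, 0, -1):  # Fisher-Yates shuffle
                k = np.random.randint(0, j + 1)
                tmp = members[j]
                members[j] = members[k]
                members[k] = tmp

            for j in range(m):
                i = members[j]

                if g == IDLE:
                    if np.random.random() < p_leave:
                        states[i] = SEARCHING
                        heading[i] = np.random.randint(0, 8)

                elif g == SEARCHING:
                    d = sense3(pher, region, x[i], y[i], heading[i], detect_threshold)
                    if d < 0:
                        d = random_dir(region, x[i], y[i])
                    if d < 0:
                        heading[i] = (heading[i] + 4) % 8
                    else:
                        x[i] += DX[d]
                        y[i] += DY[d]
                        heading[i] = d
                        rc = region[int(np.floor(y[i])), int(np.floor(x[i]))]
                        if rc == PATCH_1 or rc == PATCH_2:
                            p = rc - PATCH_1
                            res = _try_feed(p, t, open_at, thresholds, feeding_count)
                            if res == 1:
                                states[i] = FEEDING
                                timer[i] = drinking_time
                                patch_of[i] = p
                            elif res == -1:
                                states[i] = DISSATISFIED
                                if routed:
                                    target[i] = _commit_target(
                                        p, t, open_at, thresholds, feeding_count, p_nest
                                    )

                elif g == FEEDING:
                    timer[i] -= 1
                    if timer[i] <= 0:
                        feeding_count[patch_of[i]] -= 1
                        patch_of[i] = -1
                        states[i] = RECRUITING

                elif g == DISSATISFIED:
                    if routed and target[i] >= 0:
                        d = sense3(
                            target_scent[target[i]], region, x[i], y[i], heading[i], _NO_THRESHOLD
                        )
                        if d < 0:
                            d = random_dir(region, x[i], y[i])
                        if d >= 0:
                            x[i] += DX[d]
                            y[i] += DY[d]
                            heading[i] = d
                            rc = region[int(np.floor(y[i])), int(np.floor(x[i]))]
                            if target[i] == 0:
                                if rc == NEST:
                                    states[i] = SEARCHING
                                    target[i] = -1
                            elif rc == PATCH_1 + (target[i] - 1):
                                p = target[i] - 1
                                res = _try_feed(p, t, open_at, thresholds, feeding_count)
                                if res == 1:
                                    states[i] = FEEDING
                                    timer[i] = drinking_time
                                    patch_of[i] = p
                                    target[i] = -1
                                elif res == -1:
                                    target[i] = 0  # still crowded: head home
                    else:
                        # Random walk ignoring (and never laying) pheromone.
                        d = random_dir(region, x[i], y[i])
                        if d < 0:
                            heading[i] = (heading[i] + 4) % 8
                        else:
                            x[i] += DX[d]
                            y[i] += DY[d]
                            heading[i] = d
                            rc = region[int(np.floor(y[i])), int(np.floor(x[i]))]
                            if rc == PATCH_1 or rc == PATCH_2:
                                p = rc - PATCH_1
                                res = _try_feed(p, t, open_at, thresholds, feeding_count)
                                if res == 1:
                                    states[i] = FEEDING
                                    timer[i] = drinking_time
                                    patch_of[i] = p
                            elif rc == NEST:
                                # An unsuccessful forager back inside the
                                # nest rejoins the idle pool.
                                states[i] = IDLE

                elif g == RECRUITING:
                    d = sense3(nest_scent, region, x[i], y[i], heading[i], _NO_THRESHOLD)
                    if d < 0:
                        d = random_dir(region, x[i], y[i])
                    if d >= 0:
                        x[i] += DX[d]
                        y[i] += DY[d]
                        heading[i] = d
                        cy = int(np.floor(y[i]))
                        cx = int(np.floor(x[i]))
                        pher[cy, cx] += deposit_c  # trail mark on each cell entered
                        if region[cy, cx] == NEST:
                            states[i] = UNLOADING
                            timer[i] = unloading_time

                else:  # UNLOADING
                    timer[i] -= 1
                    if timer[i] <= 0:
                        states[i] = IDLE

        # Global decay, applied once per step after all deposits.
        for yy in range(h):
            for xx in range(w):
                pher[yy, xx] *= decay_factor

        idx = t - 1
        feed_ts[idx, 0] = feeding_count[0]
        feed_ts[idx, 1] = feeding_count[1]
        s = 0.0
        for k in range(n_left):
            s += pher[left_y[k], left_x[k]]
        pher_ts[idx, 0] = s
        s = 0.0
        for k in range(n_right):
            s += pher[right_y[k], right_x[k]]
        pher_ts[idx, 1] = s
        for i in range(n_agents):
            census_ts[idx, states[i]] += 1
        dis_ts[idx] = census_ts[idx, DISSATISFIED]

    return feed_ts, pher_ts, dis_ts, census_ts, pher


@njit(cache=True)
def seed_kernel_rng(seed):
    """Seed the compiled kernels' RNG stream (used by the single-agent API)."""
    np.random.seed(seed)
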