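# Methods

## The model

`antforage` is a spatially explicit, discrete-time agent-based model of
mass-recruiting ant foraging on a T-maze, built to study how negative
feedback from crowding at food patches interacts with the positive
feedback of trail-pheromone recruitment.

**Arena.** A grid of unit cells shaped like a T connected to a nest: a
5×4-cell nest at the base, a 24×5-cell stem, two mirror-symmetric
11×4-cell arms, and a 4×4-cell food patch at the distal end of each arm.
Junction cells (where the arm corridor crosses the stem columns) are
labelled stem, so the per-branch pheromone sums are symmetric by
construction. One cell corresponds to roughly 1 cm and one time step to
roughly one second: the geometry is sized so that a direct walk from a
patch to the nest takes about 40 steps at speed one cell/step, matching
the ~40 s the live ants need. Agents move off-lattice: continuous
coordinates, 8 compass headings, step length exactly 1 regardless of
direction; the occupied cell is the floor of the coordinates.

**Fields.** Each cell carries a trail-pheromone amount C (deposition
`+c = 60` units per cell entered by a returning forager; per-step decay
`C(t) = C(t-1)·(100−r)/100` with `r = 0.4` %/step by default, i.e. an
established trail fades below the 0.05-unit detection threshold in
roughly 45 simulated minutes) and a static nest scent `100 − d`, the
Euclidean distance to the nest centre cell. Scent fields of the same
form toward each patch centre support the routed dissatisfied-agent
variant. There is no pheromone diffusion.

**Behavioural states.** idle (in the nest; leaves with probability
2/1000 per step, so the expected outflow is 0.002 × idle pool),
searching (follows the strongest of the three forward cells — 0°, ±45° —
if any exceeds the detection threshold, else steps uniformly at random
over the admissible 8 directions), feeding (60 steps at a patch, subject
to the patch's crowding threshold), dissatisfied (turned away from a
full patch; random-walks ignoring and never laying pheromone),
recruiting (full; homes on the nest-scent gradient with the same 3-cell
rule, depositing 60 units on every cell entered), unloading (60 steps,
then idle). Crowding is all-or-nothing: a patch holding its threshold
number of feeding agents turns new arrivals away.

**Scheduling.** Each step updates the agents grouped by state in a fixed
sequence (idle → searching → feeding → dissatisfied → recruiting →
unloading; a reversed variant exists for robustness checks), then decays
the whole pheromone field once, then records the step. Group membership
is snapshotted at the start of the step so each agent updates exactly
once; within a group, agents are visited in freshly shuffled order,
which makes admission to a nearly-full patch order-fair. The per-patch
feeding count is maintained live, so the crowding ceiling holds after
every single update, not just at step boundaries.

**Experiments.** Model 1 (stable environment): both patches open from
the start with the same threshold (8, 24, 72 or 216 — calibrated to 1,
3, 9 or 27 feeding holes at ~8 ants/hole). Model 2 (changing
environment): patch 2, with three times the threshold of patch 1, opens
900 steps in (pairs 8/24, 24/72, 72/216). Headline experiments use 30
replicate runs, sensitivity sweeps 10, with seeds derived from a base
seed through `numpy`'s `SeedSequence`; a run is bit-reproducible given
its seed.

## Design choices where the description was open

- **Dissatisfied agents that wander back into the nest go idle.** The
  in-nest state of a non-unloading forager is idle, and the lab
  observations show a large share of unsuccessful ants returning to the
  nest. Without this reversion, the dissatisfied pool grows
  monotonically until most of the colony circulates dissatisfied, which
  distorts every reallocation result. Dissatisfied agents may also
  re-enter any open patch with a free slot (including the one that
  turned them away). Searching agents are *not* absorbed at the nest:
  search continues until a patch or a trail is found.
- **Sensing cone and tie-breaks.** The three sampled cells are the cells
  containing `position + unit vector` at 0°, ±45° of the heading;
  non-walkable cells never qualify; exact ties are broken uniformly at
  random. When no forward cell qualifies the agent steps uniformly over
  the admissible directions; in a dead end it reverses heading in place.
- **Deposit-then-decay.** Recruiters deposit on entering a cell; the
  global decay is applied after all agent updates of the step. The
  order only rescales the recorded trail by a constant factor, but is
  fixed for bit-reproducibility.
- **Crossing/switch time.** The switch to the superior patch is the
  first time the across-replicate mean count (or mean branch pheromone)
  at patch 2 exceeds patch 1 for 60 consecutive steps (one simulated
  minute; suppresses single-step noise). For the colony-size sweeps,
  "reallocated" additionally requires the patch-2 majority still to hold
  over the run's final minute — a transient blip crossing in a small,
  noisy colony does not count as reallocation. Plain first-crossing
  times are exposed alongside.
- **Zero-total timepoints** have undefined (not 0.5) proportions and are
  excluded from symmetry/majority means.
- **Statistics.** The trial-bias test is a Pearson goodness-of-fit
  against equal expected frequencies without continuity correction
  (this reproduces the 8.33 value exactly); the switch-time regression
  uses the natural log of the decay rate (base choice affects the slope
  but not t or R²); multiple tests are adjusted with Holm's step-down
  procedure.

## The synthetic experiment generator

`antforage.synth` produces two-feeder count series with planted ground
truth so the metrics are testable without the simulator. `gen_stable`
emulates a 120-minute stable-environment trial counted every 5 minutes:
a Poisson per-timepoint total split beta-binomially with planted bias
and overdispersion (`noise = 0` degenerates to an exact rounded split so
statistics have closed forms). `gen_changing` emulates a 90-minute
changing-environment trial counted every 2 minutes: feeder 2 is zero
before its onset, ramps, and — when a switch is planted — strictly
exceeds feeder 1 from the switch index onward, with optional isolated
single-point "blips" earlier that a sound persistence rule must ignore.
`gen_trialset` draws trial-level bias outcomes binomially. The
generators are structural fixtures: they emulate the sampling scheme of
real trials, not the behavioural trajectories, so metric tests passing
on them show correctness of the statistics, not realism of the model.

## Problem sizes and runtime

The compiled (numba) core runs a default 500-agent, 5400-step replicate
in ~0.3 s, so the test suite and the acceptance script run the full
30-replicate headline experiments and the 10-replicate sweeps (colony
grids 50–300 by 50 and 500–3000 by 250) exactly as specified, in a few
minutes each. The trail-decay calibration uses 5 replicates and the
zero-decay check 10; both quantities are stable well below that many.

## Known limitations

- Reproduced faithfully at the qualitative level but with quantitative
  drift: the model's searchers funnel onto the first trail efficiently,
  so a sizeable dissatisfied pool roams the maze by the time the second
  patch opens. The measured agent crossing at thresholds 8/24
  (~900–1000 steps) is therefore earlier than the ~1115 of the original
  simulations, and the crossing time is nearly independent of the decay
  rate (the reported tight log-linear decay–switch relationship does not
  reproduce here: the switch is carried by dissatisfied walkers rather
  than by trail competition). The pheromone crossing (~1250 vs 1374)
  and the decay calibration (~2620 vs ~2700 steps) agree well.
- Symmetry breaking in the stable environment is strong early (majority
  proportion ≈ 0.9 at step 600 without crowding) but erodes over the
  full 90 minutes as stray discoveries seed and reinforce the minority
  trail; the whole-run mean majority proportion at threshold 216 is
  ≈ 0.6 rather than ≥ 0.8, and the symmetry indices of thresholds 72
  and 216 are statistically tied.
- No individual variation, learning, satiation or U-turn behaviour;
  patches never deplete; the maze is a single T (no general graphs).
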