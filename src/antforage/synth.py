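"""Synthetic two-feeder count data with known ground truth.

These generators emulate the *structure* of laboratory two-feeder trials —
per-timepoint headcounts at two feeders, trial-level bias outcomes, and a
changing-environment series where the second feeder appears mid-trial —
so that every statistic in :mod:`antforage.metrics` can be exercised
against planted truth without running the simulator.

They make no attempt to mimic real trajectories; the stable generator is
a two-stage count draw (per-timepoint total, then a beta-binomial split
whose expected share is the planted bias), the changing generator is a
deterministic ramp construction with optional jitter and sub-persistence
"blip" exceedances that a sound change-point rule must ignore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import CountSeries, TrialBias


@dataclass(frozen=True)
class StableTrialSpec:
    """Stable-environment trial: two feeders available throughout.

    Defaults emulate a 120-minute trial counted every 5 minutes.  ``bias``
    is the planted expected share of feeder 1; ``noise`` is an
    overdispersion factor (0 gives a deterministic rounded split, larger
    values inflate the between-timepoint variance of the split beyond
    binomial).
    """

    n_timepoints: int = 24
    mean_total: float = 40.0
    bias: float = 0.5
    noise: float = 0.0
    seed: int = 0
    interval: float = 5.0   # minutes between counts

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")
        if self.mean_total <= 0:
            raise ValueError("mean_total must be positive")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")


@dataclass(frozen=True)
class ChangingTrialSpec:
    """Changing-environment trial: feeder 2 appears at ``onset_index``.

    Defaults emulate a 90-minute trial counted every 2 minutes with the
    second feeder introduced 15 minutes in.  When ``switch_index`` is set,
    feeder 2 strictly exceeds feeder 1 from that index onward (reached via
    a ``ramp``-point rise); otherwise it plateaus below feeder 1.
    ``blips`` single-point pre-switch exceedances are planted to probe
    persistence-window robustness.
    """

    n_timepoints: int = 45
    onset_index: int = 8
    switch_index: int | None = 20
    ramp: int = 3
    plateau: int = 30       # feeder-1 standing count
    blips: int = 0
    noise: float = 0.0
    seed: int = 0
    interval: float = 2.0   # minutes between counts

    def __post_init__(self) -> None:
        if not 0 <= self.onset_index < self.n_timepoints:
            raise ValueError("onset_index must lie within the series")
        if self.switch_index is not None:
            if self.switch_index <= self.onset_index:
                raise ValueError("switch_index must come after onset_index")
            if self.switch_index >= self.n_timepoints:
                raise ValueError("switch_index must lie within the series")
        if self.ramp < 1:
            raise ValueError("ramp must be >= 1")
        if self.plateau < 2:
            raise ValueError("plateau must be >= 2")


def gen_stable(spec: StableTrialSpec) -> tuple[CountSeries, float]:
    """Draw a stable-environment series; returns it with the planted bias.

    With ``noise == 0`` the split is deterministic
    (``round(mean_total * bias)`` versus the remainder), so statistics on
    the series have exact closed forms; with ``noise > 0`` the total is
    Poisson and the split beta-binomial with mean ``bias`` and
    concentration ``1 / noise``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_timepoints
    times = (np.arange(n) + 1) * spec.interval
    if spec.noise == 0.0:
        c1 = np.full(n, int(round(spec.mean_total * spec.bias)))
        c2 = np.full(n, int(round(spec.mean_total))) - c1
    else:
        total = rng.poisson(spec.mean_total, size=n)
        if spec.bias in (0.0, 1.0):
            share = np.full(n, spec.bias)
        else:
            kappa = 1.0 / spec.noise
            share = rng.beta(spec.bias * kappa, (1.0 - spec.bias) * kappa, size=n)
        c1 = rng.binomial(total, share)
        c2 = total - c1
    series = CountSeries(times=times, counts_1=c1, counts_2=c2, source="synthetic")
    return series, spec.bias


def gen_changing(spec: ChangingTrialSpec) -> CountSeries:
    """Construct a changing-environment series with a planted crossing.

    Guarantees: feeder-2 counts are identically zero before the onset;
    when a switch is planted, feeder 2 strictly exceeds feeder 1 at every
    index from ``switch_index`` on, and never before except at isolated
    single-point blips; without a planted switch feeder 2 stays strictly
    below feeder 1 after its onset ramp.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_timepoints
    times = (np.arange(n) + 1) * spec.interval
    idx = np.arange(n)

    c1 = np.full(n, spec.plateau, dtype=np.int64)
    if spec.noise > 0:
        c1 = c1 + rng.integers(-1, 2, size=n) * int(np.ceil(spec.noise))
        c1 = np.maximum(c1, 2)

    c2 = np.zeros(n, dtype=np.int64)
    after = idx >= spec.onset_index
    if spec.switch_index is None:
        # Plateau strictly below feeder 1.
        rise = np.minimum((idx - spec.onset_index + 1), spec.ramp) / spec.ramp
        c2[after] = np.floor(0.6 * c1[after] * rise[after]).astype(np.int64)
        c2 = np.minimum(c2, c1 - 1)
        c2 = np.maximum(c2, 0)
    else:
        pre = after & (idx < spec.switch_index)
        rise = np.minimum((idx - spec.onset_index + 1), spec.ramp) / spec.ramp
        c2[pre] = np.minimum(
            np.floor(0.8 * c1[pre] * rise[pre]).astype(np.int64), c1[pre] - 1
        )
        c2[pre] = np.maximum(c2[pre], 0)
        post = idx >= spec.switch_index
        margin = 1 + (rng.integers(0, 3, size=n) if spec.noise > 0 else np.zeros(n, dtype=np.int64))
        c2[post] = c1[post] + margin[post]
        if spec.blips > 0:
            lo, hi = spec.onset_index + 1, spec.switch_index - 2
            if hi > lo:
                pool = np.arange(lo, hi, 2)  # spacing keeps blips isolated
                take = min(spec.blips, pool.size)
                for b in rng.choice(pool, size=take, replace=False):
                    c2[b] = c1[b] + 1
    return CountSeries(times=times, counts_1=c1, counts_2=c2, source="synthetic")


def gen_trialset(n_trials: int, p_bias_toward_leader: float, seed: int = 0) -> TrialBias:
    """Binomial draw of how many of ``n_trials`` trials end up biased
    toward their early-leading feeder."""
    if not 0.0 <= p_bias_toward_leader <= 1.0:
        raise ValueError("p_bias_toward_leader must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n_trials, p_bias_toward_leader))
    return TrialBias(n_trials=n_trials, n_biased=k)
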