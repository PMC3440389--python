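"""Summary statistics for two-feeder count data.

Works on either simulated per-step feeding counts or experiment-like
per-timepoint counts: per-patch proportions, the symmetry index (mean
absolute proportion difference), sustained crossing/switch times, the
goodness-of-fit test on trial-bias counts, one-sample t-tests of
proportions against 0.5, the switch-time versus log(decay-rate)
regression, and Holm's sequential (step-down Bonferroni) multiple-testing
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests


@dataclass
class CountSeries:
    """Aligned per-timepoint counts at the two feeders/patches."""

    times: np.ndarray
    counts_1: np.ndarray
    counts_2: np.ndarray
    source: str = "manual"   # "simulation" | "synthetic" | "manual"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts_1 = np.asarray(self.counts_1)
        self.counts_2 = np.asarray(self.counts_2)
        if not (len(self.times) == len(self.counts_1) == len(self.counts_2)):
            raise ValueError("times, counts_1 and counts_2 must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if (np.asarray(self.counts_1) < 0).any() or (np.asarray(self.counts_2) < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class TrialBias:
    """Trial-level outcome tally: how many of ``n_trials`` ended up biased
    toward the feeder that led early on."""

    n_trials: int
    n_biased: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.n_biased <= self.n_trials:
            raise ValueError("n_biased must lie in [0, n_trials]")


@dataclass(frozen=True)
class SwitchSummary:
    """Crossing times of a changing-environment run or run-set."""

    crossing_time_agents: float | None
    crossing_time_pheromone: float | None

    @property
    def switched(self) -> bool:
        return self.crossing_time_agents is not None


def proportions(series: CountSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint proportion of the total at each feeder.

    Timepoints with zero total are undefined (NaN), not 0.5, and are
    excluded from downstream means.
    """
    c1 = np.asarray(series.counts_1, dtype=float)
    c2 = np.asarray(series.counts_2, dtype=float)
    total = c1 + c2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(total > 0, c1 / total, np.nan)
    return p1, 1.0 - p1


def majority_patch(series: CountSeries, at_time: float) -> int:
    """Feeder (1 or 2) with strictly more individuals at ``at_time``.

    Ties fall to the feeder with the greater cumulative count up to and
    including ``at_time``; a still-standing tie goes to feeder 1.
    """
    idx = np.nonzero(series.times == at_time)[0]
    if idx.size == 0:
        raise ValueError(f"time {at_time} is not in the series")
    i = int(idx[0])
    c1, c2 = series.counts_1[i], series.counts_2[i]
    if c1 != c2:
        return 1 if c1 > c2 else 2
    cum1 = float(np.sum(series.counts_1[: i + 1]))
    cum2 = float(np.sum(series.counts_2[: i + 1]))
    return 2 if cum2 > cum1 else 1


def symmetry_index(series: CountSeries) -> float:
    """Mean absolute difference of the two feeders' proportions over the
    defined timepoints; 0 for perfectly equal use, 1 for total bias."""
    p1, p2 = proportions(series)
    if np.isnan(p1).all():
        raise ValueError("symmetry index undefined: no timepoint has a nonzero total")
    return float(np.nanmean(np.abs(p1 - p2)))


def crossing_time(
    series_1: np.ndarray,
    series_2: np.ndarray,
    persistence: int = 60,
    times: np.ndarray | None = None,
) -> float | None:
    """Earliest time at which series 2 exceeds series 1 and stays above for
    ``persistence`` consecutive points.

    The exceedance must be sustained over a full window inside the series;
    ``None`` when no such sustained crossing exists.  Applied to
    across-replicate mean feeding counts (agent crossing) or mean branch
    pheromone sums (pheromone crossing).
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    a = np.asarray(series_1, dtype=float)
    b = np.asarray(series_2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be aligned")
    above = b > a
    if len(above) < persistence:
        return None
    window = np.convolve(above.astype(np.int64), np.ones(persistence, dtype=np.int64), "valid")
    hits = np.nonzero(window == persistence)[0]
    if hits.size == 0:
        return None
    i = int(hits[0])
    return float(times[i]) if times is not None else float(i)


def chisq_equal_bias(trials: TrialBias) -> tuple[float, float]:
    """Pearson goodness-of-fit of the biased/unbiased trial split against
    equal expected frequencies (df = 1, no continuity correction).

    Returns (statistic, p-value); (12 trials, 11 biased) gives 8.33.
    """
    observed = [trials.n_biased, trials.n_trials - trials.n_biased]
    res = stats.chisquare(observed)
    return float(res.statistic), float(res.pvalue)


def one_sample_t(values: np.ndarray, mu: float = 0.5) -> tuple[float, int, float]:
    """One-sample t-test of the mean against ``mu``.

    Returns (t, df, p).  With zero sample variance the statistic is 0 when
    the mean equals ``mu`` and signed infinity otherwise.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    df = v.size - 1
    if np.std(v, ddof=1) == 0.0:
        m = float(np.mean(v))
        if m == mu:
            return 0.0, df, 1.0
        return float(np.sign(m - mu) * np.inf), df, 0.0
    res = stats.ttest_1samp(v, popmean=mu)
    return float(res.statistic), df, float(res.pvalue)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_t: float
    slope_p: float
    r_squared: float


def regress_switch_logdecay(
    decay_rates: np.ndarray, crossing_times: np.ndarray
) -> RegressionResult:
    """OLS of mean switch time on the natural log of the pheromone decay
    rate (zero decay is excluded by construction: its log is undefined).

    A negative slope means faster decay shortens the time the colony needs
    to reallocate to the superior patch.
    """
    r = np.asarray(decay_rates, dtype=float)
    y = np.asarray(crossing_times, dtype=float)
    if r.size != y.size:
        raise ValueError("decay_rates and crossing_times must be aligned")
    if r.size < 3:
        raise ValueError("need at least three decay levels")
    if (r <= 0).any():
        raise ValueError("decay rates must be strictly positive (log regression)")
    fit = OLS(y, add_constant(np.log(r))).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_t=float(fit.tvalues[1]),
        slope_p=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
    )


def holm_adjust(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) reject/retain decisions, in
    the input order.  Rejects a superset of plain Bonferroni's set."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject
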