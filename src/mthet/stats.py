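"""Cohort statistics: Spearman correlation, Kaplan-Meier survival, log-rank
and Gehan tests, Mann-Whitney U, and t-test sample-size calculation.

These are the tests used to relate repeat-length heteroplasmy to lifespan and
copy number in a two-strain mouse cohort: Spearman rank correlation (ties by
midranks, exact permutation p for small n), the product-limit survival
estimator with median and log(-log) 95% CI, the log-rank and Gehan-Breslow
two-sample tests, the Mann-Whitney U test, and the per-group sample size of a
two-sided two-sample t-test via the noncentral-t power function.  P-values
are reported unadjusted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CohortRecord",
    "SurvivalCurve",
    "spearman",
    "km_estimate",
    "logrank_test",
    "gehan_test",
    "mann_whitney_u",
    "power_sample_size",
    "t_test_power",
    "monte_carlo_power",
]


@dataclass(frozen=True)
class CohortRecord:
    """One animal in the lifespan cohort."""

    animal_id: str
    strain: str
    sex: str
    lifespan_days: float
    event: bool
    het_12A: float
    copy_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.lifespan_days <= 0:
            raise ValueError("lifespan must be > 0")
        if not 0.0 <= self.het_12A <= 1.0:
            raise ValueError("heteroplasmy fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    rho is the Pearson correlation of midranks.  For n <= 9 the p-value is
    exact, by enumerating all permutations of one rank vector; for larger n
    it uses the t-approximation with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant input: rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # exact null distribution: permute one rank vector; rho is monotone in
        # dot(rx, perm(ry)) given fixed marginals, but ties make the variance
        # fixed too, so compare |rho| directly
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
        obs = abs(float(cx @ cy) / denom)
        perms = np.array(list(itertools.permutations(range(n))))
        stats = np.abs(cy[perms] @ cx) / denom
        p = float(np.mean(stats >= obs - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit estimate at the distinct event times.

    ``median`` is the first time with S <= 0.5 (None when S never reaches
    0.5, e.g. everything censored); the 95% CI uses the log(-log) transform
    with Greenwood variance.  ``censor_times`` carry the cross marks."""

    times: np.ndarray
    survival: np.ndarray
    greenwood_variance: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(durations, events) -> SurvivalCurve:
    """Kaplan-Meier estimate from durations and event flags (False = censored)."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.shape != events.shape or durations.ndim != 1 or len(durations) == 0:
        raise ValueError("durations and events must be equal-length non-empty 1-d sequences")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    times = table.index.to_numpy(dtype=float)[mask]
    d = table["observed"].to_numpy(dtype=float)[mask]
    n_at_risk = table["at_risk"].to_numpy(dtype=float)[mask]
    surv = np.array([kmf.predict(t) for t in times], dtype=float)
    # Greenwood: var S(t) = S(t)^2 * cumsum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
    greenwood = surv**2 * np.cumsum(inc)
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    if median is None:
        ci: tuple[float | None, float | None] = (None, None)
    else:
        ci_df = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1])
        ci = (lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None)
    return SurvivalCurve(
        times=times,
        survival=surv,
        greenwood_variance=greenwood,
        median=median,
        median_ci=ci,
        censor_times=np.sort(durations[~events]),
    )


# ---------------------------------------------------------------------------
# Two-sample survival tests
# ---------------------------------------------------------------------------

def _weighted_survival_test(dur_a, ev_a, dur_b, ev_b, gehan: bool) -> tuple[float, float]:
    dur_a = np.asarray(dur_a, dtype=float)
    dur_b = np.asarray(dur_b, dtype=float)
    ev_a = np.asarray(ev_a, dtype=bool)
    ev_b = np.asarray(ev_b, dtype=bool)
    if len(dur_a) == 0 or len(dur_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (ev_a.any() or ev_b.any()):
        raise ValueError("need at least one event")
    event_times = np.unique(np.concatenate([dur_a[ev_a], dur_b[ev_b]]))
    # at risk / events per group at each distinct event time (vectorized)
    n1 = (dur_a[:, None] >= event_times[None, :]).sum(axis=0).astype(float)
    n2 = (dur_b[:, None] >= event_times[None, :]).sum(axis=0).astype(float)
    d1 = ((dur_a[:, None] == event_times[None, :]) & ev_a[:, None]).sum(axis=0).astype(float)
    d2 = ((dur_b[:, None] == event_times[None, :]) & ev_b[:, None]).sum(axis=0).astype(float)
    n = n1 + n2
    d = d1 + d2
    o_minus_e = d1 - d * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(n > 1, d * (n1 / n) * (n2 / n) * (n - d) / (n - 1), 0.0)
    w = n if gehan else np.ones_like(n)
    denom = float(np.sum(w**2 * var))
    if denom == 0:
        return 0.0, 1.0
    stat = float(np.sum(w * o_minus_e)) ** 2 / denom
    return stat, float(sps.chi2.sf(stat, 1))


def logrank_test(dur_a, ev_a, dur_b, ev_b) -> tuple[float, float]:
    """Two-sample log-rank test: chi-square statistic (1 df) and p-value.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk set.
    """
    return _weighted_survival_test(dur_a, ev_a, dur_b, ev_b, gehan=False)


def gehan_test(dur_a, ev_a, dur_b, ev_b) -> tuple[float, float]:
    """Gehan-Breslow test: the log-rank O-E sums weighted by the number at
    risk, emphasizing early differences; chi-square with 1 df."""
    return _weighted_survival_test(dur_a, ev_a, dur_b, ev_b, gehan=True)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample, mid-ranks for ties).

    Exact p by enumeration when min(n_a, n_b) <= 8 and there are no ties,
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Power / sample size for the two-sample t-test
# ---------------------------------------------------------------------------

def t_test_power(effect_size_d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test with n per group and
    standardized difference d, via the noncentral t distribution."""
    df = 2 * n_per_group - 2
    if df < 1:
        return 0.0
    nc = effect_size_d * math.sqrt(n_per_group / 2.0)
    crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc))


def power_sample_size(effect_size_d: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Smallest n per group at which the two-sided two-sample t-test reaches
    the target power.

    With d = 0.5 (a 10% mean lifespan difference against an assumed 20% SD),
    alpha = 0.05 and power 0.8 this reconstructs 64 mice per group.
    """
    if effect_size_d <= 0:
        raise ValueError("effect size must be > 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    n = 2
    while t_test_power(effect_size_d, n, alpha) < power:
        n += 1
        if n > 10_000_000:
            raise RuntimeError("sample size search did not converge")
    return n


def monte_carlo_power(
    effect_size_d: float,
    n_per_group: int,
    alpha: float = 0.05,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Simulated power of the two-sample t-test (normal data, unit SD)."""
    rng = rng or np.random.default_rng()
    a = rng.standard_normal((reps, n_per_group))
    b = rng.standard_normal((reps, n_per_group)) + effect_size_d
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp = np.sqrt((va + vb) / 2.0)
    t = (mb - ma) / (sp * math.sqrt(2.0 / n_per_group))
    crit = sps.t.ppf(1.0 - alpha / 2.0, 2 * n_per_group - 2)
    return float(np.mean(np.abs(t) > crit))
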