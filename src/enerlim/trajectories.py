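"""Mutation-accumulation and frequency-trajectory statistics.

For each population the accumulation of mutations by day *t* is summarized
as ``M(t)``, the sum of derived allele frequencies over all segregating
mutations, and its between-timepoint change ``dM(t) = log10 M(t)/M(t-1)``.
Each mutation is further summarized by ``f_max``, the maximum frequency it
is ever observed at.  Transfer regimes are compared through
Kolmogorov-Smirnov distances between pooled f_max distributions and through
the slope of log10 M_final on log10 transfer time: if genome replication
(and hence mutational input) stopped once the medium was exhausted, M_final
should fall in proportion to the number of transfers, i.e. a log-log slope
of -1; a slope greater than -1 indicates continued (cryptic) growth under
energy limitation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "estimate_frequency",
    "accumulation",
    "AccumulationSeries",
    "fmax_distribution",
    "FmaxDistribution",
    "ks_distance",
    "pairwise_ks_table",
    "accumulation_slope_test",
    "SlopeTestResult",
]


def estimate_frequency(alt_counts, depths):
    """Naive allele-frequency estimator ``f = A / D``; NaN where ``D = 0``.

    Accepts scalars or arrays; raises if any A > D.
    """
    A = np.asarray(alt_counts, dtype=float)
    D = np.asarray(depths, dtype=float)
    if np.any(A > D):
        raise ValueError("alternate count exceeds depth")
    if np.any(A < 0) or np.any(D < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(D > 0, A / np.where(D > 0, D, 1.0), np.nan)
    if np.isscalar(alt_counts) and np.isscalar(depths):
        return float(f)
    return f


@dataclass
class AccumulationSeries:
    """M(t) and dM(t) for one population."""

    population_id: str
    times: np.ndarray
    M: np.ndarray
    delta_M: np.ndarray  # log10 M(t)/M(t-1); NaN at t=0 and where either M <= 0


def accumulation(population) -> AccumulationSeries:
    """Sum of derived allele frequencies per timepoint, skipping D = 0 points."""
    all_times = sorted({t for traj in population.trajectories for t in traj.times})
    times = np.asarray(all_times, dtype=float)
    M = np.zeros(len(times))
    for traj in population.trajectories:
        f = traj.frequencies()
        idx = np.searchsorted(times, traj.times)
        obs = ~np.isnan(f)
        M[idx[obs]] += f[obs]
    delta = np.full(len(times), np.nan)
    for i in range(1, len(times)):
        if M[i] > 0 and M[i - 1] > 0:
            delta[i] = np.log10(M[i] / M[i - 1])
    return AccumulationSeries(population.population_id, times, M, delta)


@dataclass
class FmaxDistribution:
    """f_max values pooled across the replicate populations of one taxon-treatment."""

    taxon: str
    treatment_days: int
    values: np.ndarray

    def ecdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        v = np.sort(self.values)
        return np.searchsorted(v, x, side="right") / v.size


def fmax_distribution(taxon, treatment_days, populations) -> FmaxDistribution:
    """Pool per-trajectory f_max over the replicate populations of one regime.

    Trajectories never observed above frequency zero are excluded (a called
    mutation must have been seen at least once), so all values lie in (0, 1].
    """
    values = []
    for pop in populations:
        if pop.taxon != taxon or pop.treatment_days != treatment_days:
            continue
        for traj in pop.trajectories:
            fm = traj.fmax()
            if np.isfinite(fm) and fm > 0:
                values.append(fm)
    return FmaxDistribution(taxon, treatment_days, np.asarray(values, dtype=float))


def ks_distance(sample1, sample2) -> float:
    """Sup-norm distance between the two empirical CDFs."""
    sample1 = np.asarray(sample1, dtype=float)
    sample2 = np.asarray(sample2, dtype=float)
    if sample1.size == 0 or sample2.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(sample1, sample2, method="asymp").statistic)


def pairwise_ks_table(distributions) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KS distance per taxon for each pair of transfer regimes, with pair summaries.

    ``distributions`` is an iterable of :class:`FmaxDistribution`.  Returns
    ``(per_taxon, summary)`` frames; ``summary`` holds the mean and standard
    error of each regime pair across taxa.
    """
    by_key = {(d.taxon, d.treatment_days): d for d in distributions}
    taxa = sorted({t for t, _ in by_key})
    regimes = sorted({r for _, r in by_key})
    rows = []
    for taxon in taxa:
        for r1, r2 in itertools.combinations(regimes, 2):
            d1 = by_key.get((taxon, r1))
            d2 = by_key.get((taxon, r2))
            if d1 is None or d2 is None or d1.values.size == 0 or d2.values.size == 0:
                continue
            rows.append(
                {
                    "taxon": taxon,
                    "pair": f"{r1}v{r2}",
                    "D_KS": ks_distance(d1.values, d2.values),
                }
            )
    per_taxon = pd.DataFrame(rows, columns=["taxon", "pair", "D_KS"])
    if per_taxon.empty:
        return per_taxon, pd.DataFrame(columns=["pair", "mean", "se", "n_taxa"])
    grouped = per_taxon.groupby("pair")["D_KS"]
    summary = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "se": grouped.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
            "n_taxa": grouped.size(),
        }
    ).reset_index()
    return per_taxon, summary


@dataclass
class SlopeTestResult:
    """OLS slope of log10 M_final on log10 transfer days, tested against -1."""

    taxon: str
    beta1: float
    se: float
    t: float
    pvalue: float
    n: int
    method: str  # "ols" or "ttest"


def accumulation_slope_test(m_final, transfer_days, taxon: str = "") -> SlopeTestResult:
    """Test whether accumulated diversity decays more slowly than 1/transfers.

    Regresses log10(M_final) on log10(transfer_days) across the populations
    of one taxon and tests H0: slope = -1 (two-sided).  With exactly two
    distinct transfer times the slope cannot be distinguished from curvature
    and the test falls back to a pooled two-sample t-test of log10(M_final)
    shifted by the null prediction.  Populations with M_final <= 0 are
    excluded with a warning.
    """
    m_final = np.asarray(m_final, dtype=float)
    transfer_days = np.asarray(transfer_days, dtype=float)
    keep = m_final > 0
    if not np.all(keep):
        warnings.warn(f"excluding {np.sum(~keep)} populations with M_final <= 0", stacklevel=2)
    y = np.log10(m_final[keep])
    x = np.log10(transfer_days[keep])
    levels = np.unique(x)
    n = y.size
    if n < 3 or levels.size < 2:
        raise ValueError("need >= 3 populations over >= 2 distinct transfer times")
    if levels.size == 2:
        # two-group fallback: slope from group means, t-test on null-shifted values
        y1, y2 = y[x == levels[0]], y[x == levels[1]]
        if min(y1.size, y2.size) < 2:
            raise ValueError("two-level fallback needs >= 2 populations per level")
        dx = levels[1] - levels[0]
        beta1 = (y2.mean() - y1.mean()) / dx
        # H0: beta1 = -1  <=>  mean(y2) - mean(y1) = -dx
        res = stats.ttest_ind(y2, y1 + (-1.0) * dx, equal_var=True)
        sp2 = ((y1.size - 1) * y1.var(ddof=1) + (y2.size - 1) * y2.var(ddof=1)) / (n - 2)
        se = np.sqrt(sp2 * (1 / y1.size + 1 / y2.size)) / dx
        return SlopeTestResult(taxon, float(beta1), float(se), float(res.statistic),
                               float(res.pvalue), n, "ttest")
    fit = stats.linregress(x, y)
    if fit.stderr == 0:  # exact fit: t is 0 under H0, +-inf otherwise
        t = 0.0 if np.isclose(fit.slope, -1.0) else np.inf * np.sign(fit.slope + 1.0)
    else:
        t = (fit.slope - (-1.0)) / fit.stderr
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return SlopeTestResult(taxon, float(fit.slope), float(fit.stderr), float(t), float(p), n, "ols")
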