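"""Gene-level parallelism: multiplicity, the genome-wide log-likelihood
statistic, and identification of significantly enriched genes.

The multiplicity of a gene of length ``L_i`` carrying ``n_i`` pooled
nonsynonymous mutations is ``m_i = n_i * Lbar / L_i`` (Lbar = mean gene
length), so equal multiplicity means equal per-base mutation density.
Under the null that mutations land on genes in proportion to length, all
genes share the multiplicity ``mbar = n_tot / N_genes``, and the net
log-likelihood gain of gene-specific rates is

    delta_ell = sum_i n_i * log(m_i / mbar)

which equals ``n_tot`` times the Kullback-Leibler divergence between the
observed per-gene mutation fractions and the length-proportional null, and
is therefore non-negative.  Genome-wide significance comes from multinomial
resampling of mutation placements; per-gene significance uses a Poisson
survival probability on ``n_i`` with the length-proportional rate, BH
corrected, requiring a minimum count (default 2, since a single mutation
cannot evidence parallelism).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .extinction import bh_adjust
from .resampling import addone_pvalue

__all__ = [
    "multiplicity",
    "MultiplicityTable",
    "multiplicity_table",
    "nonsynonymous_gene_counts",
    "delta_ell",
    "genomewide_test",
    "significant_genes",
    "delta_ell_vs_fmax",
]


def multiplicity(n, L, Lbar) -> float:
    """Gene multiplicity ``n * Lbar / L``."""
    if np.any(np.asarray(L) <= 0):
        raise ValueError("gene length must be positive")
    return n * Lbar / L


class MultiplicityTable:
    """Per-gene multiplicity statistics plus genome-level summaries.

    ``table`` is a frame indexed by gene_id with columns ``n``, ``L``, ``m``,
    ``pvalue``, ``significant``; genome-level scalars are attributes.
    """

    def __init__(self, counts: pd.Series, lengths: pd.Series, fdr: float = 0.05,
                 min_count: int = 2):
        lengths = lengths.astype(float)
        counts = counts.reindex(lengths.index).fillna(0).astype(float)
        self.n_genes = int(len(lengths))
        self.l_bar = float(lengths.mean())
        self.n_tot = float(counts.sum())
        self.m_bar = self.n_tot / self.n_genes if self.n_genes else float("nan")
        m = multiplicity(counts.to_numpy(), lengths.to_numpy(), self.l_bar)
        lam = self.n_tot * lengths.to_numpy() / lengths.to_numpy().sum()
        # P(X >= n_i) under the length-proportional Poisson null
        pvals = stats.poisson.sf(counts.to_numpy() - 1, lam)
        self.table = pd.DataFrame(
            {"n": counts, "L": lengths, "m": m, "pvalue": pvals}, index=lengths.index
        )
        adjusted = bh_adjust(pvals)
        self.table["p_bh"] = adjusted
        self.table["significant"] = (adjusted <= fdr) & (counts.to_numpy() >= min_count)
        self.fdr = fdr
        self.min_count = min_count

    @property
    def delta_ell(self) -> float:
        return delta_ell(self.table["n"], self.table["L"])


def nonsynonymous_gene_counts(populations, min_fmax: float = 0.0) -> pd.Series:
    """Nonsynonymous mutation counts per gene, pooled across populations.

    Mutations must reach ``f_max >= min_fmax`` to be counted; synonymous and
    noncoding mutations are excluded.
    """
    counts: dict = {}
    for pop in populations:
        for traj in pop.trajectories:
            if traj.annotation_class != "nonsynonymous":
                continue
            fm = traj.fmax()
            if not np.isfinite(fm) or fm < min_fmax or fm <= 0:
                continue
            counts[traj.gene_id] = counts.get(traj.gene_id, 0) + 1
    return pd.Series(counts, dtype=float).sort_index()


def multiplicity_table(populations, gene_table, fdr: float = 0.05, min_count: int = 2,
                       min_fmax: float = 0.0) -> MultiplicityTable:
    """Build the multiplicity table for a set of replicate populations."""
    lengths = pd.Series({g.gene_id: g.length for g in gene_table}, dtype=float).sort_index()
    counts = nonsynonymous_gene_counts(populations, min_fmax=min_fmax)
    unknown = set(counts.index) - set(lengths.index)
    if unknown:
        raise ValueError(f"mutations in genes absent from gene table: {sorted(unknown)[:5]}")
    return MultiplicityTable(counts, lengths, fdr=fdr, min_count=min_count)


def delta_ell(counts, lengths) -> float:
    """Genome-wide parallelism statistic; 0 when counts match the uniform null."""
    n = np.asarray(counts, dtype=float)
    L = np.asarray(lengths, dtype=float)
    n_tot = n.sum()
    if n_tot <= 0:
        raise ValueError("need at least one mutation")
    l_bar = L.mean()
    m_bar = n_tot / L.size
    nz = n > 0
    m = n[nz] * l_bar / L[nz]
    return float(np.sum(n[nz] * np.log(m / m_bar)))


def genomewide_test(counts, lengths, n_sim: int = 10_000,
                    seed: int | np.random.Generator | None = None) -> float:
    """Monte-Carlo p for delta_ell against multinomial placement proportional to length."""
    n = np.asarray(counts, dtype=float)
    L = np.asarray(lengths, dtype=float)
    n_tot = int(round(n.sum()))
    if n_tot < 1:
        raise ValueError("need at least one mutation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = L / L.sum()
    observed = delta_ell(n, L)
    draws = rng.multinomial(n_tot, probs, size=n_sim)
    l_bar = L.mean()
    m_bar = n_tot / L.size
    safe = np.where(draws > 0, draws, 1)
    logs = np.log((safe * l_bar / L) / m_bar)
    null = np.sum(np.where(draws > 0, draws * logs, 0.0), axis=1)
    return addone_pvalue(observed, null, side="greater")


def significant_genes(table: MultiplicityTable) -> set:
    """Genes with significantly elevated multiplicity (Poisson survival + BH)."""
    return set(table.table.index[table.table["significant"]])


def delta_ell_vs_fmax(mutations: pd.DataFrame, lengths: pd.Series, thresholds) -> pd.DataFrame:
    """delta_ell recomputed on the subset of mutations with f_max >= x per threshold.

    ``mutations`` needs columns ``gene_id`` and ``fmax`` (nonsynonymous
    mutations only).  Thresholds with no qualifying mutations yield NaN.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    rows = []
    for x in thresholds:
        sub = mutations[mutations["fmax"] >= x]
        if len(sub) == 0:
            rows.append({"threshold": x, "delta_ell": np.nan, "n_tot": 0})
            continue
        counts = sub.groupby("gene_id").size().reindex(lengths.index).fillna(0)
        rows.append(
            {
                "threshold": x,
                "delta_ell": delta_ell(counts.to_numpy(), lengths.to_numpy()),
                "n_tot": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)
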