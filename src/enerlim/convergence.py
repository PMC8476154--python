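"""Within-taxon convergent and divergent evolution across transfer regimes.

Two complementary views are implemented.  At the level of gene *identity*,
the sets of significantly enriched genes from two regimes are compared with
a multivariate-hypergeometric intersection null (closed form for two sets,
Monte-Carlo for more) and a Jaccard-similarity randomization test: an
overlap larger than chance is convergence, smaller is divergence.  At the
level of mutation *counts*, the squared Pearson correlation of relative
multiplicities over the enriched genes is standardized (Z_rho) against a
null of fixed-margin randomized gene-by-regime count tables (rcont-style
sequential hypergeometric construction, the distribution induced by
independent placements conditioned on the row and column sums); negative
Z_rho indicates divergence, positive convergence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .resampling import addone_pvalue
from .spectra import permanova_restricted

__all__ = [
    "intersection_pmf",
    "IntersectionTest",
    "jaccard_test",
    "fixed_margin_randomize",
    "CorrelationDivergence",
    "z_rho",
    "zrho_anova",
]


def _intersection_pmf_exact(sizes, n_genes: int, k: int) -> float:
    """Inclusion-exclusion evaluation of the multivariate hypergeometric pmf."""
    from math import comb

    total = 0
    for j in range(0, min(sizes) - k + 1):
        prod = comb(n_genes - k, j)
        for s in sizes:
            prod *= comb(n_genes - j - k, s - j - k)
        total += (-1) ** j * prod
    denom = 1
    for s in sizes:
        denom *= comb(n_genes, s)
    return comb(n_genes, k) * total / denom


def intersection_pmf(
    set_sizes,
    n_genes: int,
    k: int,
    method: str = "auto",
    n_sim: int = 100_000,
    seed: int | None = None,
) -> float:
    """P(|I_1 ∩ ... ∩ I_m| = k) for independent uniform subsets of the given sizes.

    For two sets this is the hypergeometric pmf in closed form.  For m > 2
    the alternating inclusion-exclusion sum is evaluated exactly when the
    genome is small; at genome scale (thousands of genes) the products of
    binomial coefficients are prohibitive, and the subset-drawing process is
    simulated instead.  ``method`` is ``auto``, ``exact`` or ``simulate``.
    """
    sizes = [int(s) for s in set_sizes]
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    if any(s > n_genes for s in sizes):
        raise ValueError("set size exceeds number of genes")
    if k > min(sizes):
        return 0.0
    if len(sizes) == 2:
        return float(stats.hypergeom.pmf(k, n_genes, sizes[0], sizes[1]))
    if method == "auto":
        method = "exact" if n_genes <= 200 else "simulate"
    if method == "exact":
        return _intersection_pmf_exact(sizes, n_genes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    genes = np.arange(n_genes)
    for _ in range(n_sim):
        inter = set(rng.choice(genes, size=sizes[0], replace=False))
        for s in sizes[1:]:
            inter &= set(rng.choice(genes, size=s, replace=False))
            if len(inter) < k:
                break
        if len(inter) == k:
            hits += 1
    return hits / n_sim


def _jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 0.0  # two empty sets: degenerate, uninformative overlap
    return len(a & b) / len(union)


@dataclass
class IntersectionTest:
    taxon: str
    pair: str
    size_i: int
    size_j: int
    n_genes: int
    jaccard: float
    null_mean: float
    null_sd: float
    p_convergence: float  # J >= observed under the null
    p_divergence: float  # J <= observed under the null
    n_sim: int


def jaccard_test(
    set_i,
    set_j,
    n_genes: int,
    n_sim: int = 10_000,
    seed: int | None = None,
    taxon: str = "",
    pair: str = "",
) -> IntersectionTest:
    """Randomization test of gene-set overlap between two regimes.

    The null draws independent uniform subsets of the observed sizes from
    the ``n_genes`` genome and computes their Jaccard similarity; both
    one-sided add-one p-values are reported (enrichment = convergence,
    depletion = divergence).
    """
    set_i, set_j = set(set_i), set(set_j)
    if len(set_i | set_j) > n_genes:
        raise ValueError("union of sets exceeds the genome")
    rng = np.random.default_rng(seed)
    observed = _jaccard(set_i, set_j)
    genes = np.arange(n_genes)
    null = np.empty(n_sim)
    for s in range(n_sim):
        a = rng.choice(genes, size=len(set_i), replace=False)
        b = rng.choice(genes, size=len(set_j), replace=False)
        null[s] = _jaccard(set(a), set(b))
    return IntersectionTest(
        taxon=taxon,
        pair=pair,
        size_i=len(set_i),
        size_j=len(set_j),
        n_genes=n_genes,
        jaccard=observed,
        null_mean=float(np.mean(null)),
        null_sd=float(np.std(null, ddof=1)),
        p_convergence=addone_pvalue(observed, null, side="greater"),
        p_divergence=addone_pvalue(observed, null, side="less"),
        n_sim=n_sim,
    )


def fixed_margin_randomize(matrix, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """One random contingency table with the row and column sums of ``matrix``.

    Rows are drawn sequentially from the multivariate hypergeometric
    distribution of the remaining column totals (rcont-style), which samples
    tables from the distribution induced by uniform placement conditioned on
    both margins.  Zero rows are returned unchanged by construction.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    matrix = np.asarray(matrix, dtype=int)
    if np.any(matrix < 0):
        raise ValueError("matrix must be non-negative")
    n_rows, n_cols = matrix.shape
    col_left = matrix.sum(axis=0).copy()
    out = np.zeros_like(matrix)
    for i in range(n_rows - 1):
        r = int(matrix[i].sum())
        if r == 0:
            continue
        if n_cols == 2:
            x = rng.hypergeometric(col_left[0], col_left[1], r)
            row = np.array([x, r - x])
        else:
            row = stats.multivariate_hypergeom.rvs(col_left, r, random_state=rng)
        out[i] = row
        col_left -= row
    out[-1] = col_left
    return out


def _fixed_margin_randomize_two_col_batch(
    matrix: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_draws, n_rows, 2) batch of margin-preserving tables, vectorized over draws."""
    row_sums = matrix.sum(axis=1)
    c0_left = np.full(n_draws, matrix[:, 0].sum())
    c1_left = np.full(n_draws, matrix[:, 1].sum())
    out = np.zeros((n_draws, matrix.shape[0], 2), dtype=int)
    for i, r in enumerate(row_sums[:-1]):
        if r == 0:
            continue
        x = rng.hypergeometric(c0_left, c1_left, int(r))
        out[:, i, 0] = x
        out[:, i, 1] = r - x
        c0_left -= x
        c1_left -= r - x
    out[:, -1, 0] = c0_left
    out[:, -1, 1] = c1_left
    return out


@dataclass
class CorrelationDivergence:
    taxon: str
    pair: str
    rho_raw: float  # Pearson r of relative multiplicities
    rho_squared: float
    z_raw: float
    z_squared: float
    null_mean: float  # of the squared statistic
    null_sd: float
    n_rand: int
    n_genes: int


def _relative_multiplicity(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    dens = counts / lengths
    total = dens.sum()
    if total == 0:
        return np.full_like(dens, np.nan)
    return dens / total


def z_rho(
    count_matrix: pd.DataFrame,
    lengths: pd.Series,
    n_rand: int = 10_000,
    seed: int | None = None,
    taxon: str = "",
    pair: str = "",
) -> CorrelationDivergence:
    """Standardized correlation of relative multiplicities under fixed-margin nulls.

    ``count_matrix`` is a genes x 2 frame of nonsynonymous mutation counts
    for the two regimes (typically over the union of genes enriched in
    either regime); ``lengths`` gives the gene lengths.  The observed
    squared Pearson correlation of relative multiplicities (mu_i =
    m_i / sum m_i) is standardized against correlations from fixed-margin
    randomized tables.  Raw-correlation variants are reported alongside.
    """
    if count_matrix.shape[1] != 2:
        raise ValueError("count matrix must have exactly two regime columns")
    if count_matrix.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    L = lengths.reindex(count_matrix.index).to_numpy(dtype=float)
    obs = count_matrix.to_numpy(dtype=int)

    def correlations(table: np.ndarray) -> tuple[float, float]:
        mu1 = _relative_multiplicity(table[:, 0].astype(float), L)
        mu2 = _relative_multiplicity(table[:, 1].astype(float), L)
        if np.any(np.isnan(mu1)) or np.any(np.isnan(mu2)):
            return float("nan"), float("nan")
        if np.std(mu1) == 0 or np.std(mu2) == 0:
            return float("nan"), float("nan")
        r = float(np.corrcoef(mu1, mu2)[0, 1])
        return r, r**2

    r_obs, r2_obs = correlations(obs)
    batch = _fixed_margin_randomize_two_col_batch(obs, n_rand, rng)
    null_r = np.empty(n_rand)
    null_r2 = np.empty(n_rand)
    for s in range(n_rand):
        null_r[s], null_r2[s] = correlations(batch[s])
    valid = np.isfinite(null_r2)
    null_r, null_r2 = null_r[valid], null_r2[valid]
    sd2 = float(np.std(null_r2, ddof=1)) if null_r2.size > 1 else 0.0
    sd1 = float(np.std(null_r, ddof=1)) if null_r.size > 1 else 0.0
    z2 = (r2_obs - float(np.mean(null_r2))) / sd2 if sd2 > 0 else float("nan")
    z1 = (r_obs - float(np.mean(null_r))) / sd1 if sd1 > 0 else float("nan")
    return CorrelationDivergence(
        taxon=taxon,
        pair=pair,
        rho_raw=r_obs,
        rho_squared=r2_obs,
        z_raw=z1,
        z_squared=z2,
        null_mean=float(np.mean(null_r2)) if null_r2.size else float("nan"),
        null_sd=sd2,
        n_rand=n_rand,
        n_genes=count_matrix.shape[0],
    )


def zrho_anova(per_taxon: pd.DataFrame, n_perm: int = 10_000, seed: int | None = None,
               value_col: str = "z_squared"):
    """Blocked permutational ANOVA on per-taxon Z_rho values (pair as label, taxon as block)."""
    return permanova_restricted(
        per_taxon[value_col].to_numpy()[:, None],
        per_taxon["pair"].to_numpy(),
        per_taxon["taxon"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
    )
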