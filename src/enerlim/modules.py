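"""Cross-taxa convergent evolution at the functional-module level.

Phylogenetically distant taxa share few genes, so enriched genes are lifted
to functional modules (KEGG/MAPLE-style, a many-to-many gene-to-module map
per taxon).  Convergence within a transfer regime is assessed by how slowly
the number of shared modules decays as more taxa are intersected, against a
null that draws the same number of annotated genes uniformly from each
taxon's annotated universe.  The decay curve at k taxa is the average
intersection size over all C(n, k) taxon combinations (the simpler ">= k
taxa" tail curve is reported alongside).  The dependence of module-set
overlap (Jaccard index) on phylogenetic distance is summarized by an OLS
slope with a permutation test, and the module-by-taxon/treatment matrix is
ordinated by PCA with a PERMANOVA restricted to within-taxon label
permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .resampling import addone_pvalue
from .spectra import pca_with_permuted_loadings, permanova_restricted

__all__ = [
    "map_to_modules",
    "decay_curve_observed",
    "decay_null",
    "DecayCurve",
    "distance_decay",
    "DistanceDecayFit",
    "slope_difference_test",
    "module_ordination",
]


def map_to_modules(gene_set, module_map) -> tuple[set, int]:
    """Union of module ids over the annotated genes; also counts unannotated genes."""
    modules: set = set()
    dropped = 0
    for g in gene_set:
        mods = module_map.modules_of(g)
        if mods:
            modules |= set(mods)
        else:
            dropped += 1
    return modules, dropped


def _mean_intersection_sizes(module_sets: list[set]) -> np.ndarray:
    """Per k = 1..n: mean |intersection| over all C(n, k) taxon combinations."""
    n = len(module_sets)
    out = np.zeros(n)
    for k in range(1, n + 1):
        sizes = [
            len(set.intersection(*combo))
            for combo in itertools.combinations(module_sets, k)
        ]
        out[k - 1] = float(np.mean(sizes))
    return out


def _tail_counts(module_sets: list[set]) -> np.ndarray:
    """Per k: number of modules present in at least k of the taxa."""
    n = len(module_sets)
    freq: dict = {}
    for s in module_sets:
        for m in s:
            freq[m] = freq.get(m, 0) + 1
    return np.array([sum(1 for v in freq.values() if v >= k) for k in range(1, n + 1)], dtype=float)


@dataclass
class DecayCurve:
    treatment_days: int
    k: np.ndarray
    observed: np.ndarray  # combination-averaged exact-k intersection sizes
    observed_tail: np.ndarray  # modules present in >= k taxa
    null_mean: np.ndarray
    null_q05: np.ndarray
    null_q95: np.ndarray
    pvalues: np.ndarray  # per-k add-one p, one-sided (observed >= null)
    n_sim: int


def decay_curve_observed(module_sets: dict) -> tuple[np.ndarray, np.ndarray]:
    """Observed decay curves from per-taxon module sets (dict taxon -> set)."""
    sets = [module_sets[t] for t in sorted(module_sets)]
    return _mean_intersection_sizes(sets), _tail_counts(sets)


def decay_null(
    universes: dict,
    sample_sizes: dict,
    n_sim: int = 1000,
    seed: int | None = None,
    observed_sets: dict | None = None,
    treatment_days: int = 0,
) -> DecayCurve:
    """Null decay curves by uniform gene sampling from each taxon's annotated universe.

    ``universes`` maps taxon -> :class:`~enerlim.io.ModuleMap` restricted to
    annotated genes; ``sample_sizes`` maps taxon -> number of enriched
    annotated genes.  Per iteration that many genes are drawn without
    replacement per taxon, mapped to modules, and the combination-averaged
    intersection curve recomputed.  ``observed_sets`` (taxon -> module set)
    adds observed curves and per-k p-values.
    """
    taxa = sorted(universes)
    rng = np.random.default_rng(seed)
    gene_lists = {t: sorted(universes[t].genes) for t in taxa}
    for t in taxa:
        if sample_sizes[t] > len(gene_lists[t]):
            raise ValueError(f"sample size exceeds annotated universe for {t}")
    n = len(taxa)
    null = np.empty((n_sim, n))
    for s in range(n_sim):
        sets = []
        for t in taxa:
            genes = rng.choice(gene_lists[t], size=sample_sizes[t], replace=False)
            mods, _ = map_to_modules(genes, universes[t])
            sets.append(mods)
        null[s] = _mean_intersection_sizes(sets)
    if observed_sets is not None:
        obs_sets = [observed_sets[t] for t in taxa]
        observed = _mean_intersection_sizes(obs_sets)
        tail = _tail_counts(obs_sets)
        pvals = np.array(
            [addone_pvalue(observed[i], null[:, i], side="greater") for i in range(n)]
        )
    else:
        observed = np.full(n, np.nan)
        tail = np.full(n, np.nan)
        pvals = np.full(n, np.nan)
    return DecayCurve(
        treatment_days=treatment_days,
        k=np.arange(1, n + 1),
        observed=observed,
        observed_tail=tail,
        null_mean=null.mean(axis=0),
        null_q05=np.quantile(null, 0.05, axis=0),
        null_q95=np.quantile(null, 0.95, axis=0),
        pvalues=pvals,
        n_sim=n_sim,
    )


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


@dataclass
class DistanceDecayFit:
    treatment_days: int
    points: pd.DataFrame  # taxon pair, distance, jaccard
    slope: float
    intercept: float
    pvalue: float  # permutation p for the slope
    n_perm: int


def distance_decay(
    module_sets: dict,
    distances: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    treatment_days: int = 0,
    alternative: str = "two-sided",
) -> DistanceDecayFit:
    """OLS of module-set Jaccard similarity on phylogenetic distance, permutation-tested.

    The null shuffles the Jaccard values across taxon pairs (the response
    variable; equivalent under exchangeability to shuffling distances) and
    recomputes the slope.  ``alternative`` is ``two-sided`` or ``less``
    (negative slope = similarity decays with distance).
    """
    taxa = sorted(module_sets)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    rows = []
    for t1, t2 in itertools.combinations(taxa, 2):
        rows.append(
            {
                "pair": f"{t1}|{t2}",
                "distance": float(distances.loc[t1, t2]),
                "jaccard": _jaccard(module_sets[t1], module_sets[t2]),
            }
        )
    points = pd.DataFrame(rows)
    x = points["distance"].to_numpy()
    y = points["jaccard"].to_numpy()
    fit = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for s in range(n_perm):
        null[s] = stats.linregress(x, y[rng.permutation(y.size)]).slope
    side = {"two-sided": "two-sided", "less": "less"}[alternative]
    p = addone_pvalue(fit.slope, null, side=side)
    return DistanceDecayFit(treatment_days, points, float(fit.slope), float(fit.intercept),
                            p, n_perm)


def slope_difference_test(
    fit_a: DistanceDecayFit,
    fit_b: DistanceDecayFit,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test of |slope_a - slope_b| by reshuffling treatment labels over points."""
    pts = pd.concat(
        [fit_a.points.assign(regime=0), fit_b.points.assign(regime=1)], ignore_index=True
    )
    x = pts["distance"].to_numpy()
    y = pts["jaccard"].to_numpy()
    lab = pts["regime"].to_numpy()

    def absdiff(labels: np.ndarray) -> float:
        s0 = stats.linregress(x[labels == 0], y[labels == 0]).slope
        s1 = stats.linregress(x[labels == 1], y[labels == 1]).slope
        return abs(s0 - s1)

    observed = absdiff(lab)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for s in range(n_perm):
        null[s] = absdiff(lab[rng.permutation(lab.size)])
    return observed, addone_pvalue(observed, null, side="greater")


def module_ordination(
    presence: pd.DataFrame,
    taxa,
    treatments,
    n_perm: int = 10_000,
    seed: int | None = None,
):
    """PCA + restricted PERMANOVA on a module-by-taxon/treatment presence matrix.

    ``presence`` has one row per taxon-treatment combination (binary module
    columns); ``taxa`` and ``treatments`` label the rows.  Treatment is
    tested with permutations restricted within taxon.
    """
    ordination = pca_with_permuted_loadings(presence, n_perm=min(n_perm, 1000), seed=seed)
    result = permanova_restricted(
        presence.to_numpy(dtype=float),
        np.asarray(treatments),
        np.asarray(taxa),
        n_perm=n_perm,
        seed=seed,
    )
    return ordination, result
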