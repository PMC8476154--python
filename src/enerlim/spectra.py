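"""Nucleotide-spectrum analysis at 4-fold degenerate sites.

Mutations at third codon positions whose codon family is 4-fold degenerate
are synonymous whatever the substituted base, so their spectrum reflects
mutational (and repair) biases rather than selection.  Substitutions are
collapsed by strand into six classes (A:T->C:G, A:T->G:C, A:T->T:A,
G:C->A:T, G:C->C:G, G:C->T:A).  Populations are compared by PCA on their
relative spectra, with per-class loading significance calibrated by
column-wise permutation, and by a PERMANOVA whose permutations shuffle
treatment labels only within each taxon (controlling for taxon identity).
The default pseudo-F is a Welch-type statistic based on inverse-variance
weighted group centroids, which tolerates unequal group covariances; the
classical PERMANOVA pseudo-F is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from sklearn.decomposition import PCA

from .resampling import addone_pvalue, blocked_permutation_indices

SPECTRUM_CLASSES = (
    "A:T->C:G",
    "A:T->G:C",
    "A:T->T:A",
    "G:C->A:T",
    "G:C->C:G",
    "G:C->T:A",
)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

__all__ = [
    "SPECTRUM_CLASSES",
    "collapse_substitution",
    "fourfold_sites",
    "count_spectra",
    "pca_with_permuted_loadings",
    "OrdinationResult",
    "permanova_restricted",
    "PermanovaResult",
]


def collapse_substitution(ref: str, alt: str) -> str:
    """Strand-collapsed class of a substitution (genomic A->C and T->G are one class)."""
    ref, alt = ref.upper(), alt.upper()
    if ref in "TC":  # report on the A/G strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    pair = {"A": "A:T", "G": "G:C"}[ref]
    alt_pair = {"A": "A:T", "C": "C:G", "G": "G:C", "T": "T:A"}[alt]
    return f"{pair}->{alt_pair}"


def _fourfold_third_positions(table_id: int = 11) -> set[str]:
    """Codon prefixes XY such that XY[ACGT] all encode the same amino acid."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    prefixes = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = set()
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                aas.add(table.forward_table.get(codon, "*"))
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(b1 + b2)
    return prefixes


def fourfold_sites(reference, gene_table, table_id: int = 11) -> set:
    """Genomic positions (contig, 1-based pos) that are 4-fold degenerate third codon positions.

    Degeneracy is evaluated on the coding (sense) strand; minus-strand genes
    are read reverse-complemented.  Genes whose length is not a multiple of
    three are skipped with a warning.
    """
    prefixes = _fourfold_third_positions(table_id)
    sites = set()
    for gene in gene_table:
        if gene.length % 3 != 0:
            warnings.warn(f"gene {gene.gene_id}: length not divisible by 3, skipped", stacklevel=2)
            continue
        cds = reference.gene_cds(gene)
        for codon_start in range(0, len(cds) - 2, 3):
            if cds[codon_start : codon_start + 2] in prefixes:
                # genomic coordinate of the codon's third position
                if gene.strand == "+":
                    pos = gene.start + codon_start + 2
                else:
                    pos = gene.end - (codon_start + 2)
                sites.add((gene.contig, pos))
    return sites


def count_spectra(populations, site_set) -> pd.DataFrame:
    """Per-population counts and proportions of the six classes at 4-fold sites.

    Returns a frame indexed by population_id with count columns (one per
    class) plus ``total`` and proportion columns (``p_<class>``).
    """
    rows = {}
    for pop in populations:
        counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
        for traj in pop.trajectories:
            if (traj.contig, traj.position) in site_set:
                counts[collapse_substitution(traj.ref_allele, traj.alt_allele)] += 1
        rows[pop.population_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(SPECTRUM_CLASSES))
    df["total"] = df.sum(axis=1)
    for cls in SPECTRUM_CLASSES:
        with np.errstate(invalid="ignore"):
            df[f"p_{cls}"] = np.where(df["total"] > 0, df[cls] / df["total"], np.nan)
    return df


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # populations x axes
    loadings: pd.DataFrame  # classes x axes
    explained_variance_ratio: np.ndarray
    rho2: pd.DataFrame  # squared Pearson correlation of each class with each axis
    loading_pvalues: pd.DataFrame  # permutation p for |loading|, classes x axes
    n_perm: int


def pca_with_permuted_loadings(
    X: pd.DataFrame, n_perm: int = 10_000, seed: int | None = None, scale: bool = False
) -> OrdinationResult:
    """PCA on column-centered proportions with permutation-calibrated loadings.

    Null loadings are generated by independently permuting each column across
    rows (destroying inter-class correlation while keeping marginals) and
    re-running the PCA; the p-value for class j on axis a is the add-one
    fraction of null ``|loading|`` at least as large as observed.
    """
    if X.shape[0] < 3:
        raise ValueError("need at least 3 populations")
    rng = np.random.default_rng(seed)
    values = X.to_numpy(dtype=float)
    if scale:
        values = (values - values.mean(axis=0)) / values.std(axis=0, ddof=0)
    n_axes = min(values.shape)
    pca = PCA(n_components=n_axes)
    scores = pca.fit_transform(values - values.mean(axis=0))
    loadings = pca.components_.T  # classes x axes
    axes = [f"PC{i + 1}" for i in range(n_axes)]

    rho2 = np.zeros((values.shape[1], n_axes))
    for j in range(values.shape[1]):
        for a in range(n_axes):
            if np.std(values[:, j]) == 0 or np.std(scores[:, a]) == 0:
                rho2[j, a] = np.nan
            else:
                rho2[j, a] = np.corrcoef(values[:, j], scores[:, a])[0, 1] ** 2

    exceed = np.zeros_like(loadings)
    for _ in range(n_perm):
        perm = values.copy()
        for j in range(perm.shape[1]):
            perm[:, j] = perm[rng.permutation(perm.shape[0]), j]
        null_pca = PCA(n_components=n_axes)
        null_pca.fit(perm - perm.mean(axis=0))
        exceed += np.abs(null_pca.components_.T) >= np.abs(loadings)
    pvals = (1 + exceed) / (n_perm + 1)

    idx = list(X.columns)
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=X.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=idx, columns=axes),
        explained_variance_ratio=pca.explained_variance_ratio_,
        rho2=pd.DataFrame(rho2, index=idx, columns=axes),
        loading_pvalues=pd.DataFrame(pvals, index=idx, columns=axes),
        n_perm=n_perm,
    )


@dataclass
class PermanovaResult:
    statistic: float
    pvalue: float
    n_perm: int
    scheme: str  # description of the permutation structure
    method: str  # "welch" or "classical"


def _group_stats(X: np.ndarray, labels: np.ndarray):
    groups = np.unique(labels)
    means = np.array([X[labels == g].mean(axis=0) for g in groups])
    sizes = np.array([(labels == g).sum() for g in groups])
    # total within-group variance (trace of covariance), sample convention
    variances = np.array(
        [
            ((X[labels == g] - means[i]) ** 2).sum() / max(sizes[i] - 1, 1)
            for i, g in enumerate(groups)
        ]
    )
    return groups, means, sizes, variances


def _welch_statistic(X: np.ndarray, labels: np.ndarray) -> float:
    """Welch-type (unequal-covariance) multivariate test statistic on Euclidean distances."""
    groups, means, sizes, variances = _group_stats(X, labels)
    k = len(groups)
    if np.any(variances == 0):
        # degenerate: zero within-group spread; infinite separation unless means coincide
        grand = means.mean(axis=0)
        return 0.0 if np.allclose(means, grand) else np.inf
    W = sizes / variances
    Wsum = W.sum()
    center = (W[:, None] * means).sum(axis=0) / Wsum
    num = np.sum(W * np.sum((means - center) ** 2, axis=1)) / (k - 1)
    h = np.sum((1 - W / Wsum) ** 2 / (sizes - 1))
    den = 1 + 2 * (k - 2) / (k**2 - 1) * h if k > 1 else 1.0
    return float(num / den)


def _classical_pseudo_f(X: np.ndarray, labels: np.ndarray) -> float:
    groups, means, sizes, _ = _group_stats(X, labels)
    k, n = len(groups), X.shape[0]
    grand = X.mean(axis=0)
    ss_between = float(np.sum(sizes[:, None] * (means - grand) ** 2))
    ss_within = float(
        sum(((X[labels == g] - means[i]) ** 2).sum() for i, g in enumerate(groups))
    )
    if ss_within == 0:
        return 0.0 if np.allclose(means, grand) else np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova_restricted(
    X,
    labels,
    blocks,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "welch",
) -> PermanovaResult:
    """Permutational (M)ANOVA with label permutations restricted to blocks.

    ``X`` is an (n x p) response matrix (p = 1 for scalar responses),
    ``labels`` the grouping being tested and ``blocks`` the structure to
    control for (labels are only ever shuffled within a block).  Blocks with
    a single distinct label carry no information and are excluded with a
    warning.  ``method`` selects the Welch-type unequal-covariance statistic
    (default) or the classical pseudo-F.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    labels = np.asarray(labels)
    blocks = np.asarray(blocks)
    keep = np.ones(len(labels), dtype=bool)
    for b in np.unique(blocks):
        idx = blocks == b
        if len(np.unique(labels[idx])) < 2:
            warnings.warn(f"block {b!r} has a single label: excluded", stacklevel=2)
            keep &= ~idx
    X, labels, blocks = X[keep], labels[keep], blocks[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two distinct labels after exclusions")
    sizes = pd.Series(labels).value_counts()
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise ValueError(f"groups with fewer than 2 members: {small}")

    stat_fn = {"welch": _welch_statistic, "classical": _classical_pseudo_f}[method]
    observed = stat_fn(X, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = blocked_permutation_indices(blocks, rng)
        null[i] = stat_fn(X, labels[perm])
    p = addone_pvalue(observed, null, side="greater")
    return PermanovaResult(observed, p, n_perm, "within-block label permutation", method)
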