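"""pN/pS as a function of f_max, with genome-wide site-count correction.

The ratio of nonsynonymous to synonymous polymorphisms is corrected for
mutational opportunity by Nei-Gojobori-style fractional site counting over
all coding sequence: at each codon position the fraction of the three
possible substitutions that is synonymous contributes to the synonymous
site total S_sites, the remainder to N_sites, so pN/pS =
(N_obs / N_sites) / (S_obs / S_sites).  Curves are computed on a shared
grid of f_max thresholds (cumulative from above by default: all mutations
with f_max >= x), and regimes are compared per taxon by the mean absolute
deviation (MAD) between curves, with a blocked permutational ANOVA on the
per-taxon MADs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .spectra import permanova_restricted

__all__ = [
    "SiteCounts",
    "site_counts",
    "pnps_curve",
    "PnPsCurve",
    "curve_mad",
    "mad_summary",
    "mad_anova",
    "default_threshold_grid",
]


@dataclass
class SiteCounts:
    """Expected nonsynonymous and synonymous site counts (fractional)."""

    n_sites: float
    s_sites: float

    @property
    def total(self) -> float:
        return self.n_sites + self.s_sites


def _codon_site_fractions(table_id: int = 11) -> dict:
    """codon -> (n_fraction, s_fraction) summed over its three positions."""
    table = CodonTable.unambiguous_dna_by_id[table_id]

    def aa(codon: str) -> str:
        return table.forward_table.get(codon, "*")

    out = {}
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                syn = 0.0
                for pos in range(3):
                    for alt in "ACGT":
                        if alt == codon[pos]:
                            continue
                        mutant = codon[:pos] + alt + codon[pos + 1 :]
                        if aa(mutant) == aa(codon):
                            syn += 1 / 3
                out[codon] = (3.0 - syn, syn)
    return out


def site_counts(reference, gene_table, table_id: int = 11) -> SiteCounts:
    """Fractional N/S site counts over all valid CDS (length divisible by 3)."""
    fractions = _codon_site_fractions(table_id)
    n_tot = s_tot = 0.0
    for gene in gene_table:
        if gene.length % 3 != 0:
            warnings.warn(f"gene {gene.gene_id}: length not divisible by 3, skipped", stacklevel=2)
            continue
        cds = reference.gene_cds(gene)
        for i in range(0, len(cds) - 2, 3):
            n, s = fractions[cds[i : i + 3]]
            n_tot += n
            s_tot += s
    return SiteCounts(n_sites=n_tot, s_sites=s_tot)


@dataclass
class PnPsCurve:
    taxon: str
    treatment_days: int
    thresholds: np.ndarray
    pnps: np.ndarray  # NaN where S_obs = 0 or no mutations in the bin
    n_counts: np.ndarray
    s_counts: np.ndarray


def pnps_curve(
    mutations: pd.DataFrame,
    counts: SiteCounts,
    thresholds,
    taxon: str = "",
    treatment_days: int = 0,
    mode: str = "cumulative",
) -> PnPsCurve:
    """pN/pS at each f_max threshold.

    ``mutations`` needs columns ``class`` (synonymous/nonsynonymous/noncoding)
    and ``fmax``.  Noncoding mutations are excluded from both numerator and
    denominator.  ``mode='cumulative'`` uses all mutations with f_max >= x;
    ``mode='binned'`` uses x <= f_max < next threshold.  Empty bins and bins
    with no synonymous mutations yield NaN, never 0.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    coding = mutations[mutations["class"].isin(["synonymous", "nonsynonymous"])]
    fmax = coding["fmax"].to_numpy(dtype=float)
    is_n = (coding["class"] == "nonsynonymous").to_numpy()
    n_obs = np.zeros(thresholds.size)
    s_obs = np.zeros(thresholds.size)
    for i, x in enumerate(thresholds):
        if mode == "cumulative":
            sel = fmax >= x
        elif mode == "binned":
            upper = thresholds[i + 1] if i + 1 < thresholds.size else np.inf
            sel = (fmax >= x) & (fmax < upper)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        n_obs[i] = np.sum(sel & is_n)
        s_obs[i] = np.sum(sel & ~is_n)
    with np.errstate(divide="ignore", invalid="ignore"):
        pnps = np.where(
            s_obs > 0,
            (n_obs / counts.n_sites) / (np.maximum(s_obs, 1) / counts.s_sites),
            np.nan,
        )
    return PnPsCurve(taxon, treatment_days, thresholds, pnps, n_obs, s_obs)


def default_threshold_grid(fmax_by_group: dict, lo=0.1, hi=0.9, step=0.1) -> np.ndarray:
    """Regular grid restricted to thresholds represented in every group.

    A threshold x is kept only if every group has at least one mutation with
    f_max >= x, so curves are compared where all taxa and treatments have
    data.
    """
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    keep = []
    for x in grid:
        if all(np.any(np.asarray(v, dtype=float) >= x) for v in fmax_by_group.values()):
            keep.append(x)
    return np.asarray(keep)


def curve_mad(curve_a: PnPsCurve, curve_b: PnPsCurve) -> float:
    """Mean absolute deviation between two curves over their shared valid grid points."""
    if not np.array_equal(curve_a.thresholds, curve_b.thresholds):
        raise ValueError("curves must share the threshold grid")
    valid = np.isfinite(curve_a.pnps) & np.isfinite(curve_b.pnps)
    if not np.any(valid):
        return float("nan")
    return float(np.mean(np.abs(curve_a.pnps[valid] - curve_b.pnps[valid])))


def mad_summary(curves: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon MAD for each regime pair, plus mean +- SE across taxa.

    ``curves`` maps (taxon, treatment_days) -> PnPsCurve.
    """
    import itertools

    taxa = sorted({t for t, _ in curves})
    regimes = sorted({r for _, r in curves})
    rows = []
    for taxon in taxa:
        for r1, r2 in itertools.combinations(regimes, 2):
            if (taxon, r1) in curves and (taxon, r2) in curves:
                mad = curve_mad(curves[(taxon, r1)], curves[(taxon, r2)])
                if np.isfinite(mad):
                    rows.append({"taxon": taxon, "pair": f"{r1}v{r2}", "MAD": mad})
    per_taxon = pd.DataFrame(rows, columns=["taxon", "pair", "MAD"])
    if per_taxon.empty:
        return per_taxon, pd.DataFrame(columns=["pair", "mean", "se", "n_taxa"])
    g = per_taxon.groupby("pair")["MAD"]
    summary = pd.DataFrame(
        {
            "mean": g.mean(),
            "se": g.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
            "n_taxa": g.size(),
        }
    ).reset_index()
    return per_taxon, summary


def mad_anova(per_taxon: pd.DataFrame, n_perm: int = 10_000, seed: int | None = None):
    """Blocked permutational ANOVA on per-taxon MADs (regime pair as label, taxon as block)."""
    return permanova_restricted(
        per_taxon["MAD"].to_numpy()[:, None],
        per_taxon["pair"].to_numpy(),
        per_taxon["taxon"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
    )
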