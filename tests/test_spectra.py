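import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from enerlim import spectra as sp

from conftest import make_population, make_trajectory


class TestCollapse:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("A", "C", "A:T->C:G"),
            ("T", "G", "A:T->C:G"),
            ("G", "T", "G:C->T:A"),
            ("C", "A", "G:C->T:A"),
            ("A", "G", "A:T->G:C"),
            ("C", "G", "G:C->C:G"),
        ],
    )
    def test_strand_collapse(self, ref, alt, expected):
        assert sp.collapse_substitution(ref, alt) == expected

    def test_complementing_is_identity(self):
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert sp.collapse_substitution(ref, alt) == sp.collapse_substitution(
                    comp[ref], comp[alt]
                )


def codon_enumeration_oracle(reference, genes):
    """Independent 4-fold site finder: translate all 9 third-position variants."""
    sites = set()
    for gene in genes:
        if gene.length % 3:
            continue
        cds = reference.gene_cds(gene)
        for c0 in range(0, len(cds), 3):
            codon = cds[c0 : c0 + 3]
            aa = str(Seq(codon).translate(table=11))
            variants = {
                str(Seq(codon[:2] + b).translate(table=11)) for b in "ACGT"
            }
            if variants == {aa} and aa != "*":
                cds_idx = c0 + 2
                pos = gene.start + cds_idx if gene.strand == "+" else gene.end - cds_idx
                sites.add((gene.contig, pos))
    return sites


class TestFourfoldSites:
    def test_gly_codon_included_met_excluded(self, toy_reference_and_genes):
        reference, genes = toy_reference_and_genes
        sites = sp.fourfold_sites(reference, genes)
        # gene_plus CDS = ATG GGA GGG CTT: GGA and GGG third positions are 4-fold
        assert ("chr", 6) in sites and ("chr", 9) in sites
        # ATG (Met) is a singleton codon: no site at position 3
        assert ("chr", 3) not in sites

    def test_minus_strand_matches_enumeration_oracle(self, toy_reference_and_genes):
        reference, genes = toy_reference_and_genes
        assert sp.fourfold_sites(reference, genes) == codon_enumeration_oracle(reference, genes)

    def test_generator_genome_matches_oracle(self, small_experiment):
        genome = next(iter(small_experiment.genomes.values()))
        assert sp.fourfold_sites(genome.reference, genome.genes) == codon_enumeration_oracle(
            genome.reference, genome.genes
        )

    def test_unframed_gene_skipped_with_warning(self, toy_reference_and_genes):
        reference, genes = toy_reference_and_genes
        bad = [type(genes[0])("bad", 1, 11, "+", contig="chr")]
        with pytest.warns(UserWarning, match="divisible"):
            assert sp.fourfold_sites(reference, bad) == set()


class TestCountSpectra:
    def test_single_mutation_single_class(self):
        pop = make_population(
            [make_trajectory([5], [10], position=7, ref_allele="G", alt_allele="T")]
        )
        df = sp.count_spectra([pop], {("chr", 7)})
        assert df.loc[pop.population_id, "G:C->T:A"] == 1
        assert df.loc[pop.population_id, "total"] == 1

    def test_counts_conserved_and_off_site_ignored(self):
        pop = make_population(
            [
                make_trajectory([5], [10], position=1, ref_allele="A", alt_allele="C"),
                make_trajectory([5], [10], position=2, ref_allele="T", alt_allele="G"),
                make_trajectory([5], [10], position=99, ref_allele="G", alt_allele="A"),
            ]
        )
        df = sp.count_spectra([pop], {("chr", 1), ("chr", 2)})
        assert df.loc[pop.population_id, "total"] == 2
        # A->C and T->G collapse to the same class
        assert df.loc[pop.population_id, "A:T->C:G"] == 2


class TestPCA:
    def test_dominant_column_tops_pc1_loading(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 0.01, size=(20, 6)), columns=list(sp.SPECTRUM_CLASSES))
        X.iloc[:, 0] += rng.normal(0, 1.0, size=20)
        res = sp.pca_with_permuted_loadings(X, n_perm=200, seed=1)
        assert res.loadings["PC1"].abs().idxmax() == sp.SPECTRUM_CLASSES[0]
        assert res.rho2.loc[sp.SPECTRUM_CLASSES[0], "PC1"] > 0.9

    def test_pvalues_respect_addone_floor(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((10, 6)))
        res = sp.pca_with_permuted_loadings(X, n_perm=99, seed=0)
        assert (res.loading_pvalues.to_numpy() >= 1 / 100).all()

    def test_axes_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.random((6, 6)))
        res = sp.pca_with_permuted_loadings(X, n_perm=10, seed=0)
        centered = X.to_numpy() - X.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(centered, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        var = res.explained_variance_ratio * evals.sum() / res.explained_variance_ratio.sum()
        np.testing.assert_allclose(
            res.explained_variance_ratio, evals / evals.sum(), atol=1e-10
        )
        for a in range(evecs.shape[1]):
            dot = abs(np.dot(res.loadings.iloc[:, a], evecs[:, a]))
            if evals[a] > 1e-12:
                assert dot == pytest.approx(1.0, abs=1e-8)


class TestPermanova:
    def _blocks_data(self, seed=0, effect=0.0, n_taxa=4, reps=3):
        rng = np.random.default_rng(seed)
        rows, labels, blocks = [], [], []
        for taxon in range(n_taxa):
            base = rng.normal(0, 1, size=2)
            for treatment in range(2):
                for _ in range(reps):
                    rows.append(base + rng.normal(0, 0.5, size=2) + effect * treatment)
                    labels.append(treatment)
                    blocks.append(taxon)
        return np.array(rows), np.array(labels), np.array(blocks)

    def test_perfect_separation_hits_addone_floor(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]] * 2)
        labels = np.array([0, 0, 0, 1, 1, 1] * 2)
        blocks = np.repeat([0, 1], 6)
        res = sp.permanova_restricted(X, labels, blocks, n_perm=99, seed=0)
        assert res.pvalue == pytest.approx(1 / 100, abs=0.03)

    def test_statistic_invariant_to_block_order(self):
        X, labels, blocks = self._blocks_data(seed=1, effect=1.0)
        r1 = sp.permanova_restricted(X, labels, blocks, n_perm=49, seed=0)
        order = np.argsort(-blocks, kind="stable")
        r2 = sp.permanova_restricted(X[order], labels[order], blocks[order], n_perm=49, seed=0)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_single_label_block_excluded_with_warning(self):
        X, labels, blocks = self._blocks_data(seed=2, effect=1.0)
        labels2 = labels.copy()
        labels2[blocks == 0] = 0  # block 0 becomes uninformative
        with pytest.warns(UserWarning, match="single label"):
            res = sp.permanova_restricted(X, labels2, blocks, n_perm=49, seed=0)
        assert np.isfinite(res.statistic)

    def test_classical_f_matches_scikit_bio(self):
        """Classical pseudo-F cross-checked against an independent implementation."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        X, labels, blocks = self._blocks_data(seed=3, effect=0.8)
        res = sp.permanova_restricted(X, labels, blocks, n_perm=9, seed=0, method="classical")
        dm = skbio_stats.DistanceMatrix(squareform(pdist(X)))
        ref = skbio_stats.permanova(dm, labels.astype(str), permutations=9)
        assert res.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_type_one_error_near_nominal(self):
        """Under a treatment-free null, rejection at 5% stays within binomial 3 SE."""
        n_sims, alpha = 200, 0.05
        rejections = 0
        for s in range(n_sims):
            X, labels, blocks = self._blocks_data(seed=1000 + s, effect=0.0)
            res = sp.permanova_restricted(X, labels, blocks, n_perm=199, seed=s)
            rejections += res.pvalue <= alpha
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) <= 3 * se
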