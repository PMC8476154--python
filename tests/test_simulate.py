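import numpy as np
import pytest

from enerlim import simulate as sim


class TestGenerationsArithmetic:
    def test_tenfold_dilution(self):
        assert sim.generations_per_transfer(10.0) == pytest.approx(np.log2(10))

    def test_thousand_transfers(self):
        assert sim.total_generations(10.0, 1000) == pytest.approx(1000 * np.log2(10))


class TestGenerateGenome:
    def test_fixed_lengths_total_cds(self):
        config = sim.SimulationConfig(n_genes=10, gene_length_mean=300, gene_length_sigma=1e-9)
        genome = sim.generate_genome(config, "T", np.random.default_rng(0))
        assert sum(g.length for g in genome.genes) == 3000

    def test_same_seed_identical_outputs(self):
        config = sim.SimulationConfig(n_genes=30)
        g1 = sim.generate_genome(config, "T", np.random.default_rng(5))
        g2 = sim.generate_genome(config, "T", np.random.default_rng(5))
        assert g1.reference.sequences == g2.reference.sequences
        assert g1.genes == g2.genes
        assert g1.module_map == g2.module_map

    def test_genes_non_overlapping_and_in_bounds(self):
        config = sim.SimulationConfig(n_genes=50)
        genome = sim.generate_genome(config, "T", np.random.default_rng(1))
        genes = sorted(genome.genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start
        assert genes[-1].end <= len(genome.reference.sequences[genes[0].contig])

    def test_gene_length_mean_within_five_percent(self):
        config = sim.SimulationConfig(n_genes=3000, gene_length_mean=900)
        genome = sim.generate_genome(config, "T", np.random.default_rng(2))
        mean = np.mean([g.length for g in genome.genes])
        assert abs(mean - 900) / 900 < 0.05

    def test_unfittable_gene_count_rejected(self):
        config = sim.SimulationConfig(n_genes=100, genome_length=1000)
        with pytest.raises(ValueError, match="genome_length"):
            sim.generate_genome(config, "T", np.random.default_rng(0))

    def test_driver_overlap_controls_core_size(self):
        config = sim.SimulationConfig(n_driver_genes=10, driver_overlap=0.6)
        rng = np.random.default_rng(3)
        drivers = sim.assign_driver_sets(config, [f"g{i}" for i in range(200)], rng)
        for t1 in config.treatments:
            assert len(drivers[t1]) == 10
        assert len(drivers[1] & drivers[10]) == 6

    def test_ultrametric_distances_symmetric_positive(self):
        dist = sim.random_ultrametric_distances(["A", "B", "C", "D"], np.random.default_rng(0))
        arr = dist.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        assert np.all(np.diag(arr) == 0)
        off = arr[~np.eye(4, dtype=bool)]
        assert np.all(off > 0)


class TestSimulatePopulation:
    def _config(self, **kw):
        defaults = dict(n_genes=30, horizon_days=300, effective_size=1000)
        defaults.update(kw)
        return sim.SimulationConfig(**defaults)

    def test_zero_influx_zero_trajectories(self):
        config = self._config(influx_per_cycle={1: 0.0, 10: 0.0, 100: 0.0})
        genome = sim.generate_genome(config, "T", np.random.default_rng(0))
        pop = sim.simulate_population(config, genome, 10, 1, seed=1)
        assert pop.trajectories == []

    def test_same_seed_identical_trajectories(self):
        config = self._config()
        genome = sim.generate_genome(config, "T", np.random.default_rng(0))
        p1 = sim.simulate_population(config, genome, 10, 1, seed=9)
        p2 = sim.simulate_population(config, genome, 10, 1, seed=9)
        assert len(p1.trajectories) == len(p2.trajectories)
        for a, b in zip(p1.trajectories, p2.trajectories):
            assert a.position == b.position
            np.testing.assert_array_equal(a.alt_counts, b.alt_counts)

    def test_neutral_no_bottleneck_preserves_expected_frequency(self):
        """E[f] stays 0.5 for s=0 without a bottleneck (neutral WF martingale)."""
        rng = np.random.default_rng(0)
        f = np.full(4000, 0.5)
        s = np.zeros_like(f)
        for _ in range(20):
            f = sim.wright_fisher_cycle(f, s, 10_000, 1.0, 3.3, rng)
        assert np.mean(f) == pytest.approx(0.5, abs=3 * np.std(f) / np.sqrt(f.size))

    def test_neutral_fixation_probability_matches_diffusion(self):
        """P(fix) = f0 for a neutral allele (Wright-Fisher diffusion oracle), +-3 SE."""
        rng = np.random.default_rng(7)
        f0, n_e, n_rep = 0.1, 100, 3000
        f = np.full(n_rep, f0)
        s = np.zeros_like(f)
        for _ in range(5000):
            active = (f > 0) & (f < 1)
            if not np.any(active):
                break
            f[active] = sim.wright_fisher_cycle(f[active], s[active], n_e, 1.0, 3.3, rng)
        p_fix = np.mean(f == 1.0)
        se = np.sqrt(f0 * (1 - f0) / n_rep)
        assert abs(p_fix - f0) <= 3 * se

    def test_selection_increases_frequency(self):
        rng = np.random.default_rng(1)
        f = np.full(2000, 0.5)
        s = np.full_like(f, 0.1)
        for _ in range(10):
            f = sim.wright_fisher_cycle(f, s, 10_000, 1.0, 3.3, rng)
        assert np.mean(f) > 0.8


class TestSimulateExtinctions:
    def test_poisson_cv_matches_prediction(self):
        counts = sim.simulate_extinctions(4.0, None, 100_000, seed=0)
        cv = counts.std() / counts.mean()
        # CV of Poisson(4) is 0.5; SE of sample CV ~ CV/sqrt(2n)
        assert cv == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(2 * counts.size))

    def test_finite_dispersion_overdisperses(self):
        rng_counts = sim.simulate_extinctions(4.0, 2.0, 100_000, seed=1)
        assert rng_counts.std() / rng_counts.mean() > 0.5

    def test_nb_variance_mean_identity(self):
        """var/mean = 1 + lambda/k for the negative binomial parameterization."""
        lam, k = 5.0, 3.0
        counts = sim.simulate_extinctions(lam, k, 200_000, seed=2)
        ratio = counts.var() / counts.mean()
        assert ratio == pytest.approx(1 + lam / k, rel=0.03)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            sim.simulate_extinctions(0.0, None, 10, seed=0)


class TestExperimentLevel:
    def test_full_determinism(self):
        config = sim.SimulationConfig(
            taxa=("A", "B"), n_genes=20, replicates=2, horizon_days=200
        )
        e1 = sim.simulate_experiment(config, seed=4)
        e2 = sim.simulate_experiment(config, seed=4)
        assert e1.distances.equals(e2.distances)
        for p1, p2 in zip(e1.populations, e2.populations):
            assert p1.extinction_count == p2.extinction_count
            assert len(p1.trajectories) == len(p2.trajectories)

    def test_annotation_classes_consistent_with_reference(self, small_experiment):
        """Simulated variant classes agree with a direct codon-table check."""
        from Bio.Seq import Seq

        checked = 0
        for pop in small_experiment.populations:
            genome = small_experiment.genomes[pop.taxon]
            genes = {g.gene_id: g for g in genome.genes}
            for traj in pop.trajectories:
                assert genome.reference.base(traj.contig, traj.position) == traj.ref_allele
                if traj.gene_id == "intergenic":
                    assert traj.annotation_class == "noncoding"
                    continue
                gene = genes[traj.gene_id]
                cds = genome.reference.gene_cds(gene)
                idx = (traj.position - gene.start) if gene.strand == "+" else (
                    gene.end - traj.position
                )
                alt = traj.alt_allele if gene.strand == "+" else {
                    "A": "T", "T": "A", "G": "C", "C": "G"
                }[traj.alt_allele]
                codon_i, within = divmod(idx, 3)
                codon = cds[codon_i * 3 : codon_i * 3 + 3]
                mutant = codon[:within] + alt + codon[within + 1 :]
                same = str(Seq(codon).translate(table=11)) == str(
                    Seq(mutant).translate(table=11)
                )
                assert traj.annotation_class == ("synonymous" if same else "nonsynonymous")
                checked += 1
        assert checked > 50
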