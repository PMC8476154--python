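import numpy as np
import pytest

from enerlim.io import GeneAnnotation, MutationTrajectory, PopulationRecord, ReferenceGenome
from enerlim.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete synthetic experiment shared across tests."""
    config = SimulationConfig(
        taxa=("Alpha", "Beta", "Gamma", "Delta"),
        n_genes=80,
        replicates=3,
        horizon_days=600,
        seed=42,
    )
    return simulate_experiment(config, seed=42)


@pytest.fixture
def toy_reference_and_genes():
    """Handcrafted two-gene reference: one plus-strand, one minus-strand gene.

    gene_plus  (1-12, +): CDS ATG GGA GGG CTT
    gene_minus (16-27, -): CDS ATG CCG AAA TTC, stored reverse-complemented.
    """
    cds_plus = "ATGGGAGGGCTT"
    cds_minus = "ATGCCGAAATTC"
    rc = cds_minus[::-1].translate(str.maketrans("ACGT", "TGCA"))
    sequence = cds_plus + "TTT" + rc + "GG"
    reference = ReferenceGenome({"chr": sequence})
    genes = [
        GeneAnnotation("gene_plus", 1, 12, "+", contig="chr"),
        GeneAnnotation("gene_minus", 16, 27, "-", contig="chr"),
    ]
    return reference, genes


def make_trajectory(alt_counts, depths, times=None, **kwargs):
    """Convenience constructor with sensible defaults for tests."""
    alt_counts = np.asarray(alt_counts)
    times = np.asarray(times if times is not None else np.arange(1, alt_counts.size + 1) * 100.0)
    defaults = dict(
        population_id="Tax__1d__1",
        contig="chr",
        position=1,
        gene_id="intergenic",
        ref_allele="A",
        alt_allele="G",
        annotation_class="noncoding",
    )
    defaults.update(kwargs)
    return MutationTrajectory(times=times, alt_counts=alt_counts, depths=np.asarray(depths), **defaults)


def make_population(trajectories, taxon="Tax", treatment_days=1, replicate=1, n_ext=0):
    pop = PopulationRecord(taxon, treatment_days, replicate, n_ext)
    pop.trajectories = list(trajectories)
    return pop
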