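"""Synthetic serial-transfer evolution experiments.

Generates complete experiments with the statistical structure the analysis
pipeline assumes: per-taxon random genomes with non-overlapping genes and a
many-to-many gene-to-module map, taxa related by a random ultrametric tree,
and replicate populations evolved by Wright-Fisher dynamics on a
per-transfer-cycle timescale.  A tenfold dilution implies
``g = log2(10) ~ 3.3`` generations per transfer, so 1,000 daily transfers
span ~3,300 generations.

Within each cycle, each segregating mutation's frequency is advanced
deterministically under selection for ``g`` generations, then resampled
binomially at the effective size (drift) and again at the bottleneck size
(transfer).  New mutations arrive per cycle at a treatment-dependent Poisson
rate: longer transfer intervals have fewer cycles but a larger per-cycle
influx (the statistical signature of cryptic growth during starvation, which
is what makes the accumulation-vs-transfer-time slope shallower than -1).
Sites evolve independently (no linkage); substitution types are drawn from
treatment-specific six-class spectra; driver genes receive an enriched
nonsynonymous rate with configurable overlap between treatments.  Observed
counts are ``A ~ Binomial(D, f)`` at ``D ~ Poisson(mean depth)`` on a
100-day sampling grid.  Extinction counts are Poisson, or negative binomial
with matched mean when overdispersion is requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import (
    GeneAnnotation,
    ModuleMap,
    MutationTrajectory,
    PopulationRecord,
    ReferenceGenome,
    write_distance_matrix,
    write_gene_table,
    write_module_map,
    write_population_table,
    write_reference,
    write_trajectory_table,
)
from .spectra import SPECTRUM_CLASSES

__all__ = [
    "SimulationConfig",
    "GenomeBundle",
    "Experiment",
    "generations_per_transfer",
    "total_generations",
    "generate_genome",
    "assign_driver_sets",
    "simulate_population",
    "simulate_extinctions",
    "simulate_experiment",
    "write_experiment",
    "planted_fate_population",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# alt allele for each (ref base, collapsed class) combination
_CLASS_TO_ALT = {}
for _ref in "AG":
    for _cls in SPECTRUM_CLASSES:
        pair, alt_pair = _cls.split("->")
        if (pair == "A:T") == (_ref == "A"):
            alt = alt_pair[0]
            _CLASS_TO_ALT[(_ref, _cls)] = alt
            _CLASS_TO_ALT[(_COMPLEMENT[_ref], _cls)] = _COMPLEMENT[alt]


def generations_per_transfer(dilution: float = 10.0) -> float:
    """Generations of regrowth implied by a 1:dilution transfer: log2(dilution)."""
    return math.log2(dilution)


def total_generations(dilution: float, n_transfers: int) -> float:
    """Evolutionary timescale of an experiment: generations/transfer x transfers."""
    return generations_per_transfer(dilution) * n_transfers


def _default_spectra() -> dict:
    # treatment-shifted six-class vectors; starvation shifts mass toward the
    # A:T->C:G transversion, the class that separates regimes on PC1
    return {
        1: (0.10, 0.26, 0.10, 0.34, 0.07, 0.13),
        10: (0.22, 0.21, 0.09, 0.29, 0.07, 0.12),
        100: (0.28, 0.19, 0.08, 0.27, 0.06, 0.12),
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic experiment."""

    taxa: tuple = ("Taxon1", "Taxon2", "Taxon3", "Taxon4", "Taxon5", "Taxon6")
    treatments: tuple = (1, 10, 100)
    replicates: int = 5
    horizon_days: int = 1000
    sampling_interval_days: int = 100
    # genome
    n_genes: int = 200
    gene_length_mean: float = 900.0
    gene_length_sigma: float = 0.35  # lognormal shape on the log scale
    gc_content: float = 0.5
    intergenic_fraction: float = 0.12
    genome_length: int | None = None  # derived when None
    n_modules: int = 30
    # population
    effective_size: int = 10_000
    dilution: float = 10.0
    # mutation influx per transfer cycle by treatment (days)
    influx_per_cycle: dict = field(default_factory=lambda: {1: 0.3, 10: 1.0, 100: 3.0})
    influx_damping: float = 1.0  # < 1 models spore-like buffering
    # fitness-effect mixture for non-driver nonsynonymous mutations
    weight_neutral: float = 0.5
    weight_deleterious: float = 0.4
    weight_beneficial: float = 0.1
    mean_deleterious_s: float = 0.05
    mean_beneficial_s: float = 0.03
    # driver genes
    n_driver_genes: int = 10
    driver_enrichment: float = 10.0
    driver_overlap: float = 0.8
    driver_beneficial_s: float = 0.08
    # spectra and sequencing
    spectra: dict = field(default_factory=_default_spectra)
    mean_depth: float = 100.0
    # extinction
    extinction_rate: dict = field(default_factory=lambda: {1: 0.4, 10: 4.0, 100: 1.5})
    extinction_dispersion: float | None = None  # NB size k; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.weight_neutral + self.weight_deleterious + self.weight_beneficial
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError("fitness mixture weights must sum to 1")
        for t, vec in self.spectra.items():
            if not math.isclose(sum(vec), 1.0, abs_tol=1e-9):
                raise ValueError(f"spectrum vector for treatment {t} must sum to 1")
        if not 0.0 <= self.driver_overlap <= 1.0:
            raise ValueError("driver_overlap must be in [0, 1]")


@dataclass
class GenomeBundle:
    taxon: str
    reference: ReferenceGenome
    genes: list
    module_map: ModuleMap
    drivers: dict  # treatment -> set of gene ids


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(length: int, rng: np.random.Generator, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=probs)
    # resample in-frame stop codons so CDS are readable open frames
    for i in range(0, length - 2, 3):
        while "".join(seq[i : i + 3]) in _STOPS:
            seq[i : i + 3] = rng.choice(bases, size=3, p=probs)
    return "".join(seq)


def generate_genome(
    config: SimulationConfig, taxon: str, rng: np.random.Generator
) -> GenomeBundle:
    """One taxon's genome: non-overlapping genes, module map, driver sets."""
    mu = math.log(config.gene_length_mean) - config.gene_length_sigma**2 / 2
    lengths = np.exp(rng.normal(mu, config.gene_length_sigma, size=config.n_genes))
    lengths = np.maximum((np.round(lengths / 3).astype(int)) * 3, 90)
    mean_gap = config.intergenic_fraction * config.gene_length_mean / max(
        1 - config.intergenic_fraction, 1e-9
    )
    gaps = rng.poisson(mean_gap, size=config.n_genes + 1)
    needed = int(lengths.sum() + gaps.sum())
    if config.genome_length is not None and needed > config.genome_length:
        raise ValueError(
            f"{config.n_genes} genes need {needed} bp but genome_length is "
            f"{config.genome_length}"
        )
    genome_length = config.genome_length or needed

    probs = np.array(
        [(1 - config.gc_content) / 2, config.gc_content / 2, config.gc_content / 2,
         (1 - config.gc_content) / 2]
    )
    seq = list(rng.choice(np.array(list("ACGT")), size=genome_length, p=probs))
    genes = []
    pos = 0
    module_ids = [f"M{i + 1:04d}" for i in range(config.n_modules)]
    pairs = []
    for i, L in enumerate(lengths):
        pos += int(gaps[i])
        start = pos + 1  # 1-based inclusive
        end = pos + int(L)
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _random_cds(int(L), rng, config.gc_content)
        placed = cds if strand == "+" else "".join(_COMPLEMENT[b] for b in reversed(cds))
        seq[pos : pos + int(L)] = list(placed)
        gene_id = f"{taxon}_g{i + 1:04d}"
        n_mods = rng.choice([0, 1, 2, 3], p=[0.3, 0.4, 0.2, 0.1])
        mods = rng.choice(module_ids, size=n_mods, replace=False) if n_mods else []
        genes.append(
            GeneAnnotation(gene_id, start, end, strand, contig=f"{taxon}_chr",
                           module_ids=frozenset(mods))
        )
        pairs.extend((gene_id, m) for m in mods)
        pos = end
    reference = ReferenceGenome({f"{taxon}_chr": "".join(seq)})
    drivers = assign_driver_sets(config, [g.gene_id for g in genes], rng)
    return GenomeBundle(taxon, reference, genes, ModuleMap(pairs), drivers)


def assign_driver_sets(config: SimulationConfig, gene_ids, rng: np.random.Generator) -> dict:
    """Per-treatment driver-gene sets with a shared core of size overlap x n_drivers."""
    gene_ids = list(gene_ids)
    n = config.n_driver_genes
    n_core = int(round(config.driver_overlap * n))
    pool = list(rng.permutation(gene_ids))
    core = set(pool[:n_core])
    cursor = n_core
    drivers = {}
    for t in config.treatments:
        own = set(pool[cursor : cursor + (n - n_core)])
        cursor += n - n_core
        drivers[t] = core | own
    return drivers


def random_ultrametric_distances(taxa, rng: np.random.Generator) -> pd.DataFrame:
    """Patristic distances from a random ultrametric tree (sequential random merges)."""
    clusters = [{t} for t in taxa]
    n = len(taxa)
    dist = pd.DataFrame(0.0, index=list(taxa), columns=list(taxa))
    height = 0.0
    while len(clusters) > 1:
        height += rng.exponential(1.0)
        i, j = rng.choice(len(clusters), size=2, replace=False)
        a, b = clusters[i], clusters[j]
        for t1 in a:
            for t2 in b:
                dist.loc[t1, t2] = dist.loc[t2, t1] = 2 * height
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [a | b]
    return dist


# ---------------------------------------------------------------------------
# population dynamics
# ---------------------------------------------------------------------------


def _annotation_class(cds: str, cds_idx: int, sense_alt: str, table) -> str:
    codon_i = cds_idx // 3
    within = cds_idx % 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    mutant = codon[:within] + sense_alt + codon[within + 1 :]
    aa_ref = table.forward_table.get(codon, "*")
    aa_alt = table.forward_table.get(mutant, "*")
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _draw_mutation(genome: GenomeBundle, treatment: int, config: SimulationConfig,
                   rng: np.random.Generator, used_positions: set, table):
    """Sample one new mutation: site, alleles, annotation class, fitness effect."""
    genes = genome.genes
    lengths = np.array([g.length for g in genes], dtype=float)
    weights = lengths.copy()
    driver_set = genome.drivers[treatment]
    for i, g in enumerate(genes):
        if g.gene_id in driver_set:
            weights[i] *= config.driver_enrichment
    contig = genome.reference.contigs[0]
    genome_len = len(genome.reference.sequences[contig])
    coding_len = lengths.sum()
    intergenic_len = genome_len - coding_len
    total_weight = weights.sum() + intergenic_len
    spectrum = np.asarray(config.spectra[treatment], dtype=float)

    for _ in range(200):  # resample on position collisions
        u = rng.random() * total_weight
        if u < intergenic_len and intergenic_len > 0:
            # uniform over intergenic sites
            gene = None
            covered = np.zeros(genome_len + 1, dtype=bool)
            for g in genes:
                covered[g.start : g.end + 1] = True
            free = np.flatnonzero(~covered[1:]) + 1
            pos = int(rng.choice(free))
        else:
            gi = int(np.searchsorted(np.cumsum(weights), u - intergenic_len, side="right"))
            gi = min(gi, len(genes) - 1)
            gene = genes[gi]
            pos = int(rng.integers(gene.start, gene.end + 1))
        if pos in used_positions:
            continue
        ref = genome.reference.base(contig, pos)
        pair_classes = [c for c in SPECTRUM_CLASSES if (ref in "AT") == c.startswith("A:T")]
        idx = [SPECTRUM_CLASSES.index(c) for c in pair_classes]
        p = spectrum[idx] / spectrum[idx].sum()
        cls = pair_classes[rng.choice(3, p=p)]
        alt = _CLASS_TO_ALT[(ref, cls)]
        if gene is None:
            ann = "noncoding"
            gene_id = "intergenic"
        else:
            gene_id = gene.gene_id
            cds = genome.reference.gene_cds(gene)
            cds_idx = (pos - gene.start) if gene.strand == "+" else (gene.end - pos)
            sense_alt = alt if gene.strand == "+" else _COMPLEMENT[alt]
            ann = _annotation_class(cds, cds_idx, sense_alt, table)
        # fitness effect
        if ann == "nonsynonymous":
            if gene is not None and gene.gene_id in genome.drivers[treatment]:
                s = rng.exponential(config.driver_beneficial_s)
            else:
                u2 = rng.random()
                if u2 < config.weight_neutral:
                    s = 0.0
                elif u2 < config.weight_neutral + config.weight_deleterious:
                    s = -rng.exponential(config.mean_deleterious_s)
                else:
                    s = rng.exponential(config.mean_beneficial_s)
        else:
            s = 0.0
        used_positions.add(pos)
        return pos, ref, alt, gene_id, ann, s
    raise RuntimeError("could not place a new mutation (genome saturated?)")


def wright_fisher_cycle(
    freqs: np.ndarray,
    s: np.ndarray,
    n_e: int,
    dilution: float,
    g: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance frequencies through one transfer cycle.

    Deterministic selection over ``g`` generations, binomial drift at the
    effective size, then a 1/dilution bottleneck.  With s = 0, no bottleneck
    (dilution = 1) and large N_e this reduces to neutral Wright-Fisher
    sampling whose expectation preserves the frequency.
    """
    w = (1.0 + s) ** g
    f = freqs * w / (freqs * w + (1.0 - freqs))
    f = rng.binomial(n_e, np.clip(f, 0.0, 1.0)) / n_e
    if dilution > 1.0:
        n_b = max(int(n_e / dilution), 1)
        f = rng.binomial(n_b, f) / n_b
    return f


def simulate_population(
    config: SimulationConfig,
    genome: GenomeBundle,
    treatment: int,
    replicate: int,
    seed: int | np.random.Generator | None = None,
) -> PopulationRecord:
    """Evolve one replicate population and return its observed trajectories."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = CodonTable.unambiguous_dna_by_id[11]
    n_cycles = config.horizon_days // treatment
    sample_days = list(
        range(config.sampling_interval_days, config.horizon_days + 1,
              config.sampling_interval_days)
    )
    g = generations_per_transfer(config.dilution)
    influx = config.influx_per_cycle[treatment] * config.influx_damping

    freqs = np.empty(0)
    sels = np.empty(0)
    meta: list = []  # (pos, ref, alt, gene_id, class)
    recorded: list = []  # per-mutation dict day -> frequency
    used_positions: set = set()

    next_sample = 0
    for cycle in range(1, n_cycles + 1):
        n_new = rng.poisson(influx)
        if n_new:
            new_f = np.full(n_new, 1.0 / config.effective_size)
            new_s = np.empty(n_new)
            for k in range(n_new):
                pos, ref, alt, gene_id, ann, s = _draw_mutation(
                    genome, treatment, config, rng, used_positions, table
                )
                meta.append((pos, ref, alt, gene_id, ann))
                recorded.append({})
                new_s[k] = s
            freqs = np.concatenate([freqs, new_f])
            sels = np.concatenate([sels, new_s])
        if freqs.size:
            freqs = wright_fisher_cycle(
                freqs, sels, config.effective_size, config.dilution, g, rng
            )
        day = cycle * treatment
        while next_sample < len(sample_days) and sample_days[next_sample] <= day:
            d = sample_days[next_sample]
            for k in range(freqs.size):
                recorded[k][d] = float(freqs[k])
            next_sample += 1

    pop = PopulationRecord(
        taxon=genome.taxon,
        treatment_days=treatment,
        replicate=replicate,
        extinction_count=0,
    )
    contig = genome.reference.contigs[0]
    times = np.asarray(sample_days, dtype=float)
    for k, (pos, ref, alt, gene_id, ann) in enumerate(meta):
        f = np.array([recorded[k].get(d, 0.0) for d in sample_days])
        if not np.any(f > 0):
            continue
        depths = rng.poisson(config.mean_depth, size=times.size)
        alts = rng.binomial(depths, f)
        if not np.any(alts > 0):
            continue
        pop.trajectories.append(
            MutationTrajectory(
                population_id=pop.population_id,
                contig=contig,
                position=pos,
                gene_id=gene_id,
                ref_allele=ref,
                alt_allele=alt,
                annotation_class=ann,
                times=times,
                alt_counts=alts,
                depths=depths,
            )
        )
    return pop


def simulate_extinctions(
    lam: float,
    dispersion: float | None,
    n_replicates: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Replicate extinction counts: Poisson(lam), or NB with matched mean.

    With negative-binomial size ``k`` the variance is lam * (1 + lam / k),
    recovering the Poisson as k -> infinity.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(lam, size=n_replicates)
    k = float(dispersion)
    return rng.negative_binomial(k, k / (k + lam), size=n_replicates)


@dataclass
class Experiment:
    config: SimulationConfig
    genomes: dict  # taxon -> GenomeBundle
    distances: pd.DataFrame
    populations: list


def simulate_experiment(config: SimulationConfig, seed: int | None = None) -> Experiment:
    """Full synthetic experiment: genomes, tree distances, evolved populations."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genomes = {t: generate_genome(config, t, rng) for t in config.taxa}
    distances = random_ultrametric_distances(config.taxa, rng)
    populations = []
    for taxon in config.taxa:
        for treatment in config.treatments:
            ext = simulate_extinctions(
                config.extinction_rate[treatment],
                config.extinction_dispersion,
                config.replicates,
                rng,
            )
            for rep in range(1, config.replicates + 1):
                pop = simulate_population(config, genomes[taxon], treatment, rep, rng)
                pop.extinction_count = int(ext[rep - 1])
                populations.append(pop)
    return Experiment(config, genomes, distances, populations)


def write_experiment(experiment: Experiment, outdir) -> None:
    """Write an experiment in the package's on-disk formats (one subdir per taxon)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_distance_matrix(experiment.distances, outdir / "distances.tsv")
    by_taxon: dict = {}
    for pop in experiment.populations:
        by_taxon.setdefault(pop.taxon, []).append(pop)
    for taxon, genome in experiment.genomes.items():
        tdir = outdir / taxon
        tdir.mkdir(exist_ok=True)
        write_reference(genome.reference, tdir / "reference.fasta")
        write_gene_table(genome.genes, tdir / "genes.tsv")
        write_module_map(genome.module_map, tdir / "modules.tsv")
        pops = by_taxon.get(taxon, [])
        write_population_table(pops, tdir / "populations.tsv")
        write_trajectory_table(pops, tdir / "trajectories.tsv")


def planted_fate_population(
    n_fixed: int,
    n_extinct: int,
    n_polymorphic: int,
    depth: int = 100,
    times=None,
    seed: int | None = None,
    error_rate: float = 0.005,
    taxon: str = "Planted",
) -> PopulationRecord:
    """Population with known terminal fates, for fate-calling recovery checks.

    Fixed mutations sweep to 1 and stay; extinct ones rise briefly and drop
    to 0; polymorphic ones fluctuate around 0.5.  Observations include a
    small symmetric error rate so fixed/extinct sites are not noiseless.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times if times is not None else np.arange(100, 1001, 100), dtype=float)
    T = times.size
    pop = PopulationRecord(taxon=taxon, treatment_days=1, replicate=1)
    paths = (
        [np.minimum(1.0, np.linspace(0.2, 2.0, T)) for _ in range(n_fixed)]
        + [np.maximum(0.0, np.concatenate([[0.2, 0.1], np.zeros(T - 2)])) for _ in range(n_extinct)]
        + [np.clip(0.5 + rng.normal(0, 0.05, T), 0.05, 0.95) for _ in range(n_polymorphic)]
    )
    for i, f in enumerate(paths):
        f_err = f * (1 - error_rate) + (1 - f) * error_rate
        D = np.full(T, depth)
        A = rng.binomial(D, f_err)
        pop.trajectories.append(
            MutationTrajectory(
                population_id=pop.population_id,
                contig="chr",
                position=i + 1,
                gene_id="intergenic",
                ref_allele="A",
                alt_allele="G",
                annotation_class="noncoding",
                times=times,
                alt_counts=A,
                depths=D,
            )
        )
    return pop
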