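"""On-disk formats and in-memory data model shared by all analysis stages.

The central objects are :class:`MutationTrajectory` (one variant's
per-timepoint alternate-allele counts and sequencing depths within one
population) and :class:`PopulationRecord` (one replicate population of one
taxon under one transfer regime, holding its trajectories and its extinction
count).  Formats are plain TSV throughout; reference sequences are FASTA and
pairwise taxon distances may be given either as a square matrix or as a
newick tree (patristic distances are computed by summing branch lengths).

Coordinates are 1-based inclusive everywhere in the data model; any
half-open arithmetic is confined to the helpers that need it.

Missing timepoints (failed libraries) are encoded as depth ``D = 0``; every
downstream statistic skips ``D = 0`` points rather than imputing.
"""

from __future__ import annotations

import io as _io
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("enerlim")

NUCLEOTIDES = frozenset("ACGT")
ANNOTATION_CLASSES = frozenset({"synonymous", "nonsynonymous", "noncoding"})

__all__ = [
    "MutationTrajectory",
    "PopulationRecord",
    "GeneAnnotation",
    "ReferenceGenome",
    "ModuleMap",
    "read_trajectory_table",
    "write_trajectory_table",
    "read_gene_table",
    "write_gene_table",
    "read_module_map",
    "write_module_map",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_reference",
    "write_reference",
    "read_population_table",
    "write_population_table",
    "validate_experiment",
]


class FormatError(ValueError):
    """A file violated the on-disk format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MutationTrajectory:
    """One variant's allele-count time series within one population.

    ``alt_counts[t] <= depths[t]`` at every timepoint; times are strictly
    increasing days.  ``gene_id`` is ``"intergenic"`` for noncoding variants
    outside any gene.
    """

    population_id: str
    position: int
    gene_id: str
    ref_allele: str
    alt_allele: str
    annotation_class: str
    times: np.ndarray
    alt_counts: np.ndarray
    depths: np.ndarray
    contig: str = "chr"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.alt_counts = np.asarray(self.alt_counts, dtype=int)
        self.depths = np.asarray(self.depths, dtype=int)
        if not (len(self.times) == len(self.alt_counts) == len(self.depths)):
            raise ValueError("times, alt_counts and depths must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.alt_counts < 0) or np.any(self.depths < 0):
            raise ValueError("counts and depths must be non-negative")
        if np.any(self.alt_counts > self.depths):
            raise ValueError("alternate count exceeds depth")
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError("alleles must be one of A, C, G, T")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.annotation_class not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.annotation_class!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based")

    def frequencies(self) -> np.ndarray:
        """Naive frequency estimate A/D, NaN where D = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(self.depths > 0, self.alt_counts / np.maximum(self.depths, 1), np.nan)
        return f

    def fmax(self) -> float:
        """Maximum observed frequency over timepoints with D > 0 (NaN if none)."""
        f = self.frequencies()
        if np.all(np.isnan(f)):
            return float("nan")
        return float(np.nanmax(f))


@dataclass
class PopulationRecord:
    """One replicate population: taxon x transfer regime x replicate."""

    taxon: str
    treatment_days: int
    replicate: int
    extinction_count: int = 0
    trajectories: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.extinction_count < 0:
            raise ValueError("extinction_count must be non-negative")
        if self.treatment_days <= 0:
            raise ValueError("treatment_days must be positive")

    @property
    def population_id(self) -> str:
        return f"{self.taxon}__{self.treatment_days}d__{self.replicate}"


_POP_ID_RE = re.compile(r"^(?P<taxon>.+)__(?P<days>\d+)d__(?P<rep>\d+)$")


def parse_population_id(population_id: str) -> tuple[str, int, int]:
    m = _POP_ID_RE.match(population_id)
    if m is None:
        raise FormatError(
            f"population_id {population_id!r} does not match '<taxon>__<days>d__<replicate>'"
        )
    return m.group("taxon"), int(m.group("days")), int(m.group("rep"))


@dataclass
class GeneAnnotation:
    """One gene: 1-based inclusive coordinates, strand, and optional module ids."""

    gene_id: str
    start: int
    end: int
    strand: str
    contig: str = "chr"
    module_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        self.module_ids = frozenset(self.module_ids)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReferenceGenome:
    """Nucleotide sequence per contig."""

    sequences: dict

    def __post_init__(self) -> None:
        self.sequences = {c: str(s).upper() for c, s in self.sequences.items()}

    @property
    def contigs(self) -> list:
        return list(self.sequences)

    def base(self, contig: str, position: int) -> str:
        """Base at a 1-based position."""
        return self.sequences[contig][position - 1]

    def gene_cds(self, gene: GeneAnnotation) -> str:
        """Coding sequence of a gene in reading (sense) orientation."""
        seq = self.sequences[gene.contig][gene.start - 1 : gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


class ModuleMap:
    """Many-to-many gene -> functional-module relation for one taxon."""

    def __init__(self, pairs):
        self._gene_to_modules: dict = {}
        for gene_id, module_id in pairs:
            self._gene_to_modules.setdefault(gene_id, set()).add(module_id)

    def modules_of(self, gene_id: str) -> frozenset:
        return frozenset(self._gene_to_modules.get(gene_id, ()))

    @property
    def genes(self) -> set:
        return set(self._gene_to_modules)

    @property
    def modules(self) -> set:
        out = set()
        for mods in self._gene_to_modules.values():
            out |= mods
        return out

    def pairs(self):
        for g in sorted(self._gene_to_modules):
            for m in sorted(self._gene_to_modules[g]):
                yield g, m

    def __len__(self) -> int:
        return len(self._gene_to_modules)

    def __eq__(self, other) -> bool:
        return isinstance(other, ModuleMap) and list(self.pairs()) == list(other.pairs())


# ---------------------------------------------------------------------------
# trajectory tables
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ["population_id", "contig", "position", "gene_id", "ref", "alt", "class"]


def _parse_time_columns(columns) -> list[float]:
    """Extract the day grid from paired A_<day>/D_<day> columns; validate pairing."""
    a_days, d_days = [], []
    for col in columns:
        if col.startswith("A_"):
            a_days.append(float(col[2:]))
        elif col.startswith("D_"):
            d_days.append(float(col[2:]))
    if a_days != d_days:
        raise FormatError("A_<day> and D_<day> columns are not paired")
    if not a_days:
        raise FormatError("no A_<day>/D_<day> columns found")
    if any(b <= a for a, b in zip(a_days, a_days[1:])):
        raise FormatError("time header is not strictly increasing")
    return a_days


def read_trajectory_table(path, population_table=None) -> list[PopulationRecord]:
    """Read a trajectory TSV into validated :class:`PopulationRecord` objects.

    Columns: ``population_id contig position gene_id ref alt class`` followed
    by paired ``A_<day>``/``D_<day>`` columns.  Rows violating invariants are
    rejected with row-numbered errors.  ``population_table`` (from
    :func:`read_population_table`) supplies extinction counts; without it,
    metadata is parsed from the population id and extinction counts are 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"population_id": str, "contig": str})
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory table missing columns: {missing}")
    days = _parse_time_columns(df.columns)
    a_cols = [f"A_{d:g}" for d in days]
    d_cols = [f"D_{d:g}" for d in days]

    meta = {}
    if population_table is not None:
        meta = {r.population_id: r for r in population_table}

    populations: dict = {}
    for i, rowd in enumerate(df.to_dict("records"), start=2):  # 2 = first data line
        A = np.array([rowd[c] for c in a_cols], dtype=int)
        D = np.array([rowd[c] for c in d_cols], dtype=int)
        try:
            traj = MutationTrajectory(
                population_id=rowd["population_id"],
                contig=rowd["contig"],
                position=int(rowd["position"]),
                gene_id=rowd["gene_id"],
                ref_allele=rowd["ref"],
                alt_allele=rowd["alt"],
                annotation_class=rowd["class"],
                times=np.asarray(days),
                alt_counts=A,
                depths=D,
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
        pid = traj.population_id
        if pid not in populations:
            if pid in meta:
                m = meta[pid]
                populations[pid] = PopulationRecord(
                    m.taxon, m.treatment_days, m.replicate, m.extinction_count
                )
            else:
                taxon, days_, rep = parse_population_id(pid)
                populations[pid] = PopulationRecord(taxon, days_, rep)
        populations[pid].trajectories.append(traj)
    return list(populations.values())


def write_trajectory_table(populations, path) -> None:
    """Write populations to the trajectory TSV format (shared time grid required)."""
    all_times = sorted(
        {t for p in populations for traj in p.trajectories for t in traj.times}
    )
    header = _FIXED_COLUMNS + [c for d in all_times for c in (f"A_{d:g}", f"D_{d:g}")]
    rows = []
    for pop in populations:
        for traj in pop.trajectories:
            a_by_t = dict(zip(traj.times, traj.alt_counts))
            d_by_t = dict(zip(traj.times, traj.depths))
            row = [
                pop.population_id,
                traj.contig,
                traj.position,
                traj.gene_id,
                traj.ref_allele,
                traj.alt_allele,
                traj.annotation_class,
            ]
            for d in all_times:
                row += [int(a_by_t.get(d, 0)), int(d_by_t.get(d, 0))]
            rows.append(row)
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def read_population_table(path) -> list[PopulationRecord]:
    """TSV of population metadata: population_id, taxon, treatment_days, replicate, extinction_count."""
    df = pd.read_csv(path, sep="\t", dtype={"population_id": str, "taxon": str})
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.taxon, int(row.treatment_days), int(row.replicate))
        if key in seen:
            raise FormatError(f"{path}: row {i}: duplicate replicate {key}")
        seen.add(key)
        records.append(
            PopulationRecord(
                taxon=row.taxon,
                treatment_days=int(row.treatment_days),
                replicate=int(row.replicate),
                extinction_count=int(row.extinction_count),
            )
        )
    return records


def write_population_table(populations, path) -> None:
    rows = [
        {
            "population_id": p.population_id,
            "taxon": p.taxon,
            "treatment_days": p.treatment_days,
            "replicate": p.replicate,
            "extinction_count": p.extinction_count,
        }
        for p in populations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene tables and module maps
# ---------------------------------------------------------------------------


def read_gene_table(path) -> list[GeneAnnotation]:
    """Gene TSV: gene_id, contig, start, end, strand, modules (semicolon-joined, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str, "modules": str})
    genes = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.gene_id in seen:
            raise FormatError(f"{path}: row {i}: duplicate gene_id {row.gene_id!r}")
        seen.add(row.gene_id)
        modules = ()
        if hasattr(row, "modules") and isinstance(row.modules, str) and row.modules:
            modules = tuple(row.modules.split(";"))
        try:
            genes.append(
                GeneAnnotation(
                    gene_id=row.gene_id,
                    contig=row.contig,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    module_ids=modules,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return genes


def write_gene_table(genes, path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "contig": g.contig,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "modules": ";".join(sorted(g.module_ids)),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_module_map(path, gene_table=None) -> ModuleMap:
    """Module map TSV (gene_id, module_id); genes absent from ``gene_table`` warn but are kept."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "module_id"} <= set(df.columns):
        raise FormatError(f"{path}: module map needs columns gene_id, module_id")
    mm = ModuleMap(zip(df["gene_id"], df["module_id"]))
    if gene_table is not None:
        known = {g.gene_id for g in gene_table}
        orphans = mm.genes - known
        if orphans:
            warnings.warn(
                f"{len(orphans)} module-map genes absent from gene table (kept)",
                stacklevel=2,
            )
    return mm


def write_module_map(module_map: ModuleMap, path) -> None:
    pd.DataFrame(list(module_map.pairs()), columns=["gene_id", "module_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# distances and reference sequences
# ---------------------------------------------------------------------------


def _distances_from_newick(text: str) -> pd.DataFrame:
    tree = dendropy.Tree.get(data=text, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(mat, index=labels, columns=labels)


def read_distance_matrix(path, tol: float = 1e-9) -> pd.DataFrame:
    """Read pairwise taxon distances from a square TSV or a newick tree.

    Newick input (detected by a leading ``(``) yields patristic distances by
    summing branch lengths; quoted labels are supported.  A matrix asymmetric
    beyond ``tol`` is an error.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith("("):
        return _distances_from_newick(text)
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: distance matrix rows and columns differ")
    arr = df.to_numpy(dtype=float)
    if np.max(np.abs(arr - arr.T)) > tol:
        raise FormatError(f"{path}: distance matrix asymmetric beyond {tol}")
    return df


def write_distance_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_reference(path) -> ReferenceGenome:
    return ReferenceGenome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_reference(reference: ReferenceGenome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig, description="")
        for contig, seq in reference.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_experiment(populations, genes=None, reference=None, module_map=None) -> list[str]:
    """Cross-file consistency checks; returns a list of human-readable issues."""
    issues: list[str] = []
    seen = set()
    for pop in populations:
        key = (pop.taxon, pop.treatment_days, pop.replicate)
        if key in seen:
            issues.append(f"duplicate replicate {key}")
        seen.add(key)
    gene_ids = {g.gene_id for g in genes} if genes is not None else None
    for pop in populations:
        for traj in pop.trajectories:
            if gene_ids is not None and traj.gene_id != "intergenic" and traj.gene_id not in gene_ids:
                issues.append(f"{pop.population_id}: unknown gene {traj.gene_id!r}")
            if reference is not None:
                if traj.contig not in reference.sequences:
                    issues.append(f"{pop.population_id}: unknown contig {traj.contig!r}")
                elif traj.position > len(reference.sequences[traj.contig]):
                    issues.append(
                        f"{pop.population_id}: position {traj.position} beyond contig end"
                    )
                elif reference.base(traj.contig, traj.position) != traj.ref_allele:
                    issues.append(
                        f"{pop.population_id}: ref allele mismatch at "
                        f"{traj.contig}:{traj.position}"
                    )
    if genes is not None and reference is not None:
        for g in genes:
            if g.contig not in reference.sequences or g.end > len(reference.sequences[g.contig]):
                issues.append(f"gene {g.gene_id} outside reference bounds")
    if module_map is not None and gene_ids is not None:
        orphans = module_map.genes - gene_ids
        if orphans:
            issues.append(f"{len(orphans)} module-map genes absent from gene table")
    return issues
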