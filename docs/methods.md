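# Methods

This note documents the statistical models implemented in `enerlim`, the
synthetic-data generator's assumptions, the numerical conventions, and the
design choices made where the problem was genuinely open.

## Data model

A mutation trajectory is a per-timepoint pair (A, D) of alternate-allele
count and sequencing depth; the frequency estimator is the naive ratio
f̂ = A/D.  Missing timepoints (failed libraries) are encoded as D = 0 and
every statistic skips them — nothing is imputed.  Coordinates are 1-based
inclusive throughout; multi-replicon genomes are supported through
contig-qualified positions.  Every randomized operation takes an explicit
seed, and all Monte-Carlo p-values use the add-one convention
p = (1 + #{null at least as extreme})/(n + 1), implemented once in
`enerlim.resampling.addone_pvalue`, so no reported p is exactly zero and the
attainable floor is 1/(n+1) (10⁻⁴ at the default 10,000 iterations).

## Trajectory statistics

M(t) is the sum of derived allele frequencies over all mutations observed
(D > 0) at time t; ΔM(t) = log10 M(t)/M(t−1) is defined only where both
values are positive.  "Final M" is M at the last timepoint with data for
that population — the choice is a convention, since a single accumulation
value per population is regressed on transfer time and late M(t) is
saturated under all regimes.  The slope test regresses log10 M_final on
log10 transfer days and tests H0: β1 = −1 with a t statistic (df = n − 2);
β1 = −1 is the decay expected if mutational input were proportional to the
number of transfers.  With exactly two transfer-time levels a slope is
indistinguishable from curvature, so the test falls back to a pooled
two-sample t-test of log10 M_final shifted by the null prediction.
Populations with M_final ≤ 0 are excluded with a warning.  f_max is the
maximum of f̂ over observed timepoints; distributions are pooled across
replicate populations within a taxon-treatment before Kolmogorov–Smirnov
comparison, so each regime contributes one empirical CDF per taxon.

## Fate HMM

Three hidden states (extinct, polymorphic, fixed) with emission
probabilities at an observed (A, D): Binomial(D, ε) for extinct,
Binomial(D, 1 − ε) for fixed, and for polymorphic the binomial marginalized
over a uniform frequency on (0, 1), which is exactly 1/(D + 1) for every A.
Transitions keep the state with probability κ and split the remainder
evenly; the initial distribution is uniform.  The fate is the Viterbi state
at the last observed timepoint.  Defaults ε = 0.01, κ = 0.9 classify
deterministic all-zero / all-one trajectories correctly and are exposed in
the CLI.  This is a deliberately simplified terminal-state caller, not a
re-derivation of any previously published HMM's exact parameterization; it
does no frequency-path smoothing and no clade/cohort detection.  A property
worth knowing: because the polymorphic emission falls only polynomially in
D while the extinct/fixed emissions at the boundary fall exponentially, a
*single* terminal observation at f̂ = 0 or 1 becomes ambiguous at very high
depth; sustained terminal runs are classified stably (tested at D ∈ {50,
500}).

## Nucleotide spectra

4-fold degenerate sites are third codon positions whose codon family
encodes one amino acid for all four bases, computed on the coding strand
(minus-strand genes are read reverse-complemented; bacterial table 11;
genes with length not divisible by 3 are skipped with a warning).
Substitutions are strand-collapsed into six classes (A:T→C:G, A:T→G:C,
A:T→T:A, G:C→A:T, G:C→C:G, G:C→T:A).  Ordination is PCA on column-centered
relative spectra — centered but not scaled, since the proportions share a
scale; scaling is available as an option.  Loading significance follows a
column-permutation scheme: each class column is permuted independently
across populations, PCA is re-run, and the observed |loading| is compared
with its null distribution per class × axis.  Squared Pearson correlations
between each class and each axis's scores are reported alongside.

The PERMANOVA uses restricted permutations — treatment labels are shuffled
only within taxa, never across — so taxon identity can never masquerade as
a treatment effect.  The default statistic is a Welch-type pseudo-F:
groups are summarized by their centroids and total within-group variances,
centroids are combined with inverse-variance weights n_j/s_j², and the
weighted between-group sum of squares is normalized by a Welch correction
term.  This realizes an unequal-covariance correction without assuming a
common within-group dispersion; the classical pseudo-F
(SS_between/(k−1))/(SS_within/(n−k)) is available behind a flag and is
cross-checked in the tests against scikit-bio's PERMANOVA.  Groups need at
least two members; blocks with a single label are excluded with a warning.

## pN/pS

Site counts are fractional (Nei–Gojobori style): at each codon position the
fraction of the three possible substitutions that is synonymous accrues to
S_sites and the remainder to N_sites, so N + S = 3 × codons exactly.
Changes to or from stop codons count as nonsynonymous.  pN/pS at threshold
x is (N_obs/N_sites)/(S_obs/S_sites) over mutations with f_max ≥ x
(cumulative from above, the default, keeps sample sizes monotone; a binned
variant is available).  Bins with no synonymous mutations or no mutations
are undefined (NaN), never zero.  Noncoding mutations are excluded from
both numerator and denominator.  The default grid is 0.1–0.9 in steps of
0.1, intersected with thresholds at which every compared group still has
mutations.  Curves are compared per taxon by the mean absolute deviation
over shared defined grid points; regime-pair MADs are compared by the same
blocked permutational ANOVA used elsewhere (taxa as blocks).

## Extinction overdispersion

Under history-independent rare extinction, replicate extinction counts are
Poisson and CV = λ^−1/2.  The test estimates λ by the mean count, draws
n_sim null replicate sets from Poisson(λ), computes the null CV
distribution (sets with zero mean are redrawn, since their CV is
undefined; assigning CV = 0 instead is available behind a flag), and
reports the one-sided (overdispersion) add-one p.  BH correction is
applied across taxon-treatment combinations; only combinations where at
least three replicates went extinct are tested.

**SD convention.** The CV uses the population SD (ddof = 0, numpy's
default) by default, with the sample SD (ddof = 1) behind a flag.  The
choice matters for five replicates (the two differ by √(5/4) ≈ 1.118), and
ddof = 0 is the convention under which the published adjusted p-values for
the printed (λ, CV) pairs are recovered by this package's own simulation
(e.g. ≈ 0.03 / 0.005 / 0.41 for the three 10-day combinations at 10⁴
draws); ddof = 1 yields systematically larger p-values (≈ 0.08 / 0.02 /
0.63).  Both conventions are first-class.

## Gene-level parallelism

With n_i pooled nonsynonymous mutations in a gene of length L_i,
multiplicity is m_i = n_i·L̄/L_i and the null multiplicity is
m̄ = n_tot/N_genes.  The genome-wide statistic Δℓ = Σ n_i log(m_i/m̄)
equals n_tot × KL(observed gene fractions ‖ length-proportional null) and
is therefore non-negative; its null distribution is obtained by
multinomially re-assigning n_tot mutations to genes with probabilities
L_i/ΣL.  (Note the null mean of Δℓ *grows* with N_genes at fixed n_tot —
spreading a fixed count over more genes moves the empirical distribution
further from uniform.)  Per-gene significance uses the Poisson survival
probability P(X ≥ n_i) at rate n_tot·L_i/ΣL with BH at FDR 0.05 and a
minimum-count filter (default 2: one mutation is never parallelism).  This
is a faithful-in-spirit substitute for critical-multiplicity procedures
whose details live in other publications; the FDR level and minimum count
are exposed.  Counts are pooled across the replicate populations of a
taxon-treatment; synonymous and noncoding mutations are excluded.

## Convergence and divergence within a taxon

The probability that m independently, uniformly drawn gene sets of given
sizes intersect in exactly k genes is a multivariate hypergeometric: the
closed-form hypergeometric for m = 2, the alternating inclusion-exclusion
sum evaluated exactly for small genomes (N ≤ 200), and Monte-Carlo
simulation of the subset-drawing process at genome scale, where the
products of binomial coefficients are numerically prohibitive.  The
Jaccard test draws null subset pairs of the observed sizes and reports
both one-sided p-values: overlap above chance is convergence, below chance
divergence.

Count-level divergence uses the squared Pearson correlation of relative
multiplicities μ_i = m_i/Σm_i over the union of genes enriched in either
regime (union rather than intersection keeps genes that dropped out of one
regime informative; an intersection mode exists).  No pseudocount is
added.  The null randomizes the gene-by-regime count matrix with both
margins fixed, by sequential (multivariate) hypergeometric row draws —
the distribution induced by independent placements conditioned on row and
column sums, as sampled by rcont-type algorithms.  Z_ρ standardizes the
observed correlation against 10,000 such tables; negative values indicate
divergence.  Both the squared and the raw correlation variants are
reported, since the squared statistic is sign-blind while the
divergence/convergence language refers to the standardized score.

## Convergence across taxa

Enriched genes are lifted to functional modules through a many-to-many
per-taxon map; genes without annotation are dropped and counted, and the
per-taxon sample size for the null is the number of enriched *annotated*
genes.  The decay curve at k taxa is the mean intersection size over all
C(n, k) taxon combinations (the "≥ k taxa" tail curve is emitted
alongside); the null redraws each taxon's sample uniformly from its
annotated universe and recomputes the curve, giving per-k add-one
p-values.  Distance–decay fits regress the pairwise Jaccard index of
module sets on phylogenetic distance; the permutation null shuffles the
Jaccard values across taxon pairs (equivalent under exchangeability to
shuffling distances — the response is what this implementation permutes,
and logs), two-sided by default.  Slope differences between regimes are
tested by permuting regime labels over the pooled points.  The
module-by-taxon/treatment presence matrix is ordinated by PCA and tested
by the same within-taxon restricted PERMANOVA.

## Synthetic-data generator

The generator emulates the study design: six taxa (configurable), five
replicates, transfer intervals of 1/10/100 days over a 1,000-day horizon,
sampling every 100 days.  A tenfold dilution implies g = log2(10) ≈ 3.3
generations per transfer, hence ≈ 3,300 / 330 / 33 generations for the
three regimes.

Genomes are random: lognormal gene lengths (mean 900 bp, rounded to
codons), non-overlapping genes on both strands with stop-free reading
frames, 0–3 functional modules per gene, and taxa related by a random
ultrametric tree (patristic distances from sequential random merges).

Population dynamics are Wright–Fisher on the transfer-cycle timescale:
each mutation's frequency is advanced deterministically under selection
for g generations, then binomially resampled at the effective size N_e
(drift) and at N_e/dilution (bottleneck).  Sites evolve independently —
no linkage, clonal interference, or clade structure; the study system
showed no clade formation, and the statistics tested here are
per-mutation or per-gene counts for which independent sites are the right
level of realism.  New mutations arrive per cycle at a treatment-dependent
Poisson rate (defaults 0.3 / 1.0 / 3.0 per cycle for 1 / 10 / 100-day
regimes): fewer cycles but larger per-cycle influx in long regimes is the
statistical signature of cryptic growth during starvation, and is what
produces accumulation slopes shallower than −1.  No quantitative
per-regime influx is published; these defaults are free parameters chosen
to give detectable but not saturated diversity at desk scale, and
spore-like buffering is a single damping multiplier on the influx.
Substitution types are drawn from treatment-specific six-class spectra
(defaults shift mass toward A:T→C:G as starvation lengthens); the
annotation class of each mutation is computed from the actual codon
change, so spectrum and pN/pS analyses see self-consistent data.  Driver
genes (default 10 per taxon-treatment) receive an enrichment-multiplied
placement weight and exponentially distributed beneficial effects, with a
configurable overlap fraction between treatments' driver sets.  Observed
counts are A ~ Binomial(D, f) with D ~ Poisson(mean depth, default 100×).
Extinction counts per replicate are Poisson(λ) per taxon-treatment, or
negative binomial with matched mean (variance λ(1 + λ/k)) when
overdispersion is wanted.

What the generator does *not* emulate: linkage and genetic hitchhiking,
mechanistic dormancy/scavenging, depth heterogeneity along the genome,
mapping artifacts, or shared mutational hotspots between taxa.  Passing
tests on generator output therefore validate the statistical machinery
under the stated sampling models, not robustness to those real-data
features.

## Problem sizes and numerical conventions

Tests run the generator at reduced scale (3–4 taxa, 60–120 genes, 2–3
replicates, 200–600 days, N_e = 10³–10⁴), sizes chosen so planted effects
are unambiguous while the full suite stays fast.  Calibration checks use
500 null simulations with 999-draw inner tests; the discreteness of count
data makes the CV overdispersion test slightly conservative (ties at the
observed CV are counted against rejection), which is visible as a
rejection rate a little under the nominal 5% but within the binomial
3-SE band.  Distance-matrix symmetry is enforced to 1e-9.  Degenerate
PERMANOVA inputs (zero within-group variance with distinct means) yield an
infinite statistic and the add-one floor p-value; identical group means
yield zero.  Viterbi is computed in log space; ties in the argmax resolve
to the lowest state index (extinct < polymorphic < fixed).
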