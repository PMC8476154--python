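# enerlim

Statistical analysis of **energy-limited microbial evolution experiments**:
serial-transfer experiments in which the interval between transfers (1, 10,
or 100 days) sets how long populations starve between resource pulses, and
pooled population sequencing tracks every mutation's frequency through time.

The package takes already-called allele-frequency trajectories (plus gene
annotations, reference sequences, a gene→module map, and pairwise
phylogenetic distances) and computes, per taxon and transfer regime:

- **Mutation accumulation** — `M(t) = Σ_m f̂_m(t)`, the sum of derived allele
  frequencies, its log-ratio change `ΔM(t)`, and the regression of
  `log10 M_final` on `log10` transfer time against the null slope of −1
  (the slope expected if mutational input scaled with the number of
  transfers; a shallower slope is the signature of continued "cryptic"
  growth during starvation).
- **Mutation fates** — a three-state HMM (extinct / polymorphic / fixed)
  with binomial emissions assigns each trajectory a terminal fate;
  fixation counts per taxon-treatment.
- **f_max distributions** — the maximum frequency each mutation reaches,
  compared between regimes by Kolmogorov–Smirnov distances.
- **Nucleotide spectra** — six strand-collapsed substitution classes at
  4-fold degenerate sites, PCA with permutation-calibrated loadings, and a
  PERMANOVA whose permutations shuffle treatment labels only within taxa
  (a Welch-type statistic tolerant of unequal group covariances).
- **Selection** — pN/pS as a function of f_max with Nei–Gojobori-style
  fractional site counting, mean-absolute-deviation curve comparisons, and
  a blocked permutational ANOVA.
- **Extinction contingency** — the coefficient of variation of replicate
  extinction counts against a simulated Poisson null (CV = λ^−1/2);
  overdispersion signals historically contingent extinction. BH-corrected.
- **Gene-level parallelism** — multiplicity `m_i = n_i·L̄/L_i`, the
  genome-wide statistic `Δℓ = Σ_i n_i log(m_i/m̄)` with a multinomial null,
  and per-gene enrichment (Poisson survival + BH).
- **Convergent/divergent evolution** — within taxa: multivariate
  hypergeometric intersection nulls, Jaccard randomization tests, and the
  standardized correlation `Z_ρ` of relative multiplicities under
  fixed-margin (rcont-style) table randomization; across taxa: functional-
  module decay curves with gene-resampling nulls, distance–decay
  regressions, and module-by-taxon/treatment ordination.

A **synthetic-data generator** (`enerlim.simulate`) produces complete
experiments — random genomes, Wright–Fisher population dynamics on the
transfer-cycle timescale, treatment-dependent mutational influx and
spectra, driver genes with tunable between-treatment overlap, binomial
sequencing noise — so the whole pipeline is testable end to end without any
sequencing data.

## Worked example

```python
from enerlim.simulate import SimulationConfig, simulate_experiment
from enerlim.trajectories import (accumulation, accumulation_slope_test,
                                  fmax_distribution, pairwise_ks_table)

config = SimulationConfig(taxa=("Bacillus_like",), n_genes=120, replicates=5,
                          horizon_days=1000, seed=1)
exp = simulate_experiment(config, seed=1)

finals, days = [], []
for pop in exp.populations:
    series = accumulation(pop)
    if series.M.size and series.M[-1] > 0:
        finals.append(series.M[-1]); days.append(pop.treatment_days)
res = accumulation_slope_test(finals, days, taxon="Bacillus_like")
print(f"slope test: beta1 = {res.beta1:.3f} +/- {res.se:.3f}, "
      f"t = {res.t:.2f}, p = {res.pvalue:.3g} (H0: beta1 = -1, n = {res.n})")

dists = [fmax_distribution("Bacillus_like", t, exp.populations) for t in (1, 10, 100)]
per_taxon, _ = pairwise_ks_table(dists)
print(per_taxon.to_string(index=False))
```

prints

```
slope test: beta1 = -0.401 +/- 0.074, t = 8.09, p = 4.01e-05 (H0: beta1 = -1, n = 10)
        taxon   pair     D_KS
Bacillus_like   1v10 0.200466
Bacillus_like  1v100 0.969697
Bacillus_like 10v100 0.846154
```

The fitted slope of −0.40 is far from the null of −1 (p ≈ 4×10⁻⁵): the
synthetic populations keep acquiring diversity under energy limitation
(larger per-cycle mutational influx in long-transfer regimes), exactly the
deviation the slope test is built to detect.  The `D_KS` column gives the
distance between pooled f_max distributions for each regime pair.

The same stages are available from the shell: `enerlim simulate`,
`enerlim validate`, `enerlim trajstats`, `enerlim fates`, `enerlim spectra`,
`enerlim pnps`, `enerlim extinction`, `enerlim parallelism`,
`enerlim converge-within`, `enerlim converge-across` (see `enerlim --help`).

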