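# wintermoth-abc

Population-genetic analysis of winter moth (*Operophtera brumata*)
microsatellite data: diversity and differentiation statistics with
null-allele correction, Bayesian admixture clustering with Evanno ΔK model
choice, and coalescent-based approximate Bayesian computation (ABC) over
explicit demographic scenarios. The package targets the question of whether
the outbreaking Tunisian winter moth population is a native lineage that
persisted in a North African refugium through the Last Glacial Maximum
(LGM, ~20 ka) or a recent introduction from Europe — but every component is
a general tool for diploid microsatellite data.

## What it computes

**Diversity and differentiation.** For each population: *n*, mean alleles
per locus *Na*, effective number of alleles *Eff_Na* = 1/Σpᵢ², observed
heterozygosity *H*₀, Nei's unbiased gene diversity *H*ₛ, total diversity
*H*ₜ, inbreeding coefficient *G*ᴵˢ = 1 − *H*₀/*H*ₛ, and a one-sided
permutation test of Hardy–Weinberg equilibrium. Null-allele frequencies are
estimated per locus and population by an EM algorithm (apparent homozygotes
decomposed into true homozygotes vs null carriers; missing genotypes as
candidate null homozygotes), and pairwise *F*ₛₜ is the Weir & Cockerham
θ (ratio of summed variance components over alleles and loci) with an
optional "excluding null alleles" (ENA) correction that appends the
estimated null as an extra allelic state and excludes it from the sums.
A GenePop-style exact test (Markov chain over contingency tables with fixed
margins, Fisher-combined across loci) tests differentiation.

**Clustering.** A Gibbs sampler for the admixture model with correlated
allele frequencies returns per-individual assignment proportions *Q* and a
log-likelihood estimate per run; replicate runs are aligned by optimal
column permutation and averaged per mode (CLUMPAK-style), and the number of
clusters is chosen by Evanno's ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(K).

**Demographic inference.** A backward-in-time coalescent simulator generates
microsatellite datasets under split/admixture/bottleneck scenarios with
generalized stepwise mutation (geometric step sizes, coefficient P) plus
single-nucleotide indels. The ABC engine builds reference tables of summary
statistics (per population: mean allele number, genic diversity, allele-size
variance; per pair: *F*ₛₜ, classification index, (δµ)²), retains the 1 % of
simulations closest to the observed vector, chooses among scenarios by
weighted multinomial logistic regression, estimates parameter posteriors by
local-linear regression adjustment on logit-transformed parameters, checks
the fit by PCA of the statistic cloud, and measures scenario-choice error on
pseudo-observed datasets. The scenario sets of the two-step Tunisia analysis
(3 step-1 topologies for the Italian population, 9 step-2 origins for the
Tunisian population, plus the reverse "out-of-Africa" alternatives) ship as
ready-made fixtures with their prior table.

## Worked example

```python
from wintermoth_abc.synthetic_data import SyntheticSpec, generate_island_dataset
from wintermoth_abc.popstats import population_summary, summary_frame
from wintermoth_abc.null_fst import estimate_null_frequencies, ena_fst_matrix

spec = SyntheticSpec(n_pops=3, sample_sizes=[30, 30, 20], n_loci=12,
                     target_fst=0.15, null_freqs=0.1, seed=7)
ds, truth = generate_island_dataset(spec)
print(summary_frame(population_summary(ds, n_perm=999, seed=1)).round(3))
nulls = estimate_null_frequencies(ds)
print(f"mean null-allele frequency: {nulls.grand_mean():.3f}")
for corrected in (False, True):
    m = ena_fst_matrix(ds, nulls, correct=corrected)
    print(f"mean pairwise F_ST ({'ENA' if corrected else 'raw'}): {m.mean_pairwise():.3f}")
```

prints

```
population  n   Na  Eff_Na    Ho    Hs    Ht   GIS  HWE_p
      pop1 30 5.25   3.071 0.541 0.662 0.662 0.183  0.001
      pop2 30 5.75   2.920 0.541 0.620 0.620 0.128  0.001
      pop3 20 5.25   2.959 0.422 0.633 0.633 0.334  0.001
mean null-allele frequency: 0.120
mean pairwise F_ST (raw): 0.174
mean pairwise F_ST (ENA): 0.153
```

The dataset was generated with a true island-model *F*ₛₜ of 0.15 and a true
null-allele frequency of 0.10 at every locus: the EM estimate (0.120) tracks
the injected nulls, the heterozygote deficit they create shows up as
inflated *G*ᴵˢ and *p* = 0.001 HWE rejections, and the ENA-corrected mean
*F*ₛₜ (0.153) removes most of the upward bias of the raw estimate (0.174).

A command-line pipeline wraps the same stages
(`wintermoth-abc simulate | popstats | fst | cluster | abc-step1 | abc-step2
| check | confidence`); each subcommand takes `--config`, `--seed` and
`--out` and writes CSV/JSON reports.

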