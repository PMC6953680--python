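# Methods

This note records the models implemented in `wintermoth_abc`, the
conventions chosen where several are in field use, and what the synthetic
data do and do not establish.

## Genotype data and filters

Genotypes are diploid microsatellite calls stored as fragment sizes in bp,
with a single missing sentinel (−9 on disk, STRUCTURE convention; GenePop
export writes `000000`). Half-called genotypes are rejected at parse time.
Individuals are retained when typed at ≥ 20 of 24 loci (configurable); for
ABC the four loci with the largest allelic ranges (in ladder steps,
`(max − min) / motif`) are excluded by default because extreme-range loci
distort the simulated-statistic cloud — the exclusion list is a config
option and `largest_range_loci` only supplies the default. Conversion to
repeat units divides sizes by the motif length; the offset is irrelevant for
every statistic used (counts, diversities, variances, differences).

## Diversity statistics

Per locus and population with n typed individuals and allele frequencies pᵢ:

* `Na` — number of distinct alleles; `Eff_Na` = 1/Σpᵢ². GenoDive's exact
  Eff_Na formula is not published in a citable form; 1/Σpᵢ² is the standard
  inverse-Simpson convention and is the documented choice here (the
  alternative 1/(1 − Hs) differs at second order in 1/n).
* `Ho` — proportion of heterozygous individuals.
* `Hs` — Nei's (1987) unbiased gene diversity,
  n/(n−1) · (1 − Σpᵢ² − Ho/2n).
* `Ht` in the per-population report equals that population's own diversity
  (for a single population the "total" is the within value); the
  across-population Ht on pooled, equally weighted frequencies is a separate
  function and is used for the Ht ≥ mean(Hs) pooling property.
* `G_IS` = 1 − Ho/Hs, undefined (reported missing, with a warning) for
  monomorphic populations.
* HWE: a permutation test that shuffles genes among typed individuals
  within the population independently per locus, recomputing G_IS;
  one-sided toward heterozygote deficit, p = (#{G_IS* ≥ G_IS} + 1)/(n_perm
  + 1), so 999 permutations give a floor of 0.001.

## Null alleles and F_ST

The EM estimator assumes HWE within each population with one unobservable
null allele at frequency r. Observed categories per locus/population are
heterozygotes (i, j), apparent homozygotes (i) with probability
pᵢ² + 2pᵢr, and (optionally) whole-locus missing genotypes as null/null
homozygotes with probability r². The E-step allocates expected gene counts,
the M-step renormalizes; the log-likelihood is non-decreasing and iteration
stops at |Δlog L| < 1e−8. The missing-as-null treatment is the default; a
"missing excluded" mode identifies r from homozygote excess alone. Cells
with < 2 typed individuals are skipped and flagged.

Pairwise F_ST is Weir & Cockerham's θ with components a (among), b, c
(within) computed per allelic state and summed over states and loci — the
ratio-of-sums, not a mean of ratios. With the ENA correction, each
population's frequency vector is the EM-corrected visible vector (summing to
1 − r) with the null appended as an extra state; the null state is excluded
from both numerator and denominator sums. Because true heterozygote counts
are unobservable when nulls are present, the heterozygosity entering the
corrected components is its HWE expectation 2p(1 − p) under the corrected
frequencies; the uncorrected estimator uses observed heterozygote counts.
Under the population-genetic null model (the null drifts like any allele),
the uncorrected θ is biased upward because observed frequencies are
renormalized by a population-specific factor 1/(1 − r_pop); the correction
removes most of this, as the bias test demonstrates.

The exact test of genic differentiation follows the GenePop algorithm: per
locus, a Metropolis chain over allele-count contingency tables with fixed
margins (swap moves, acceptance ratio from the hypergeometric likelihood);
the p-value is the chain fraction of tables no more probable than the
observed one; loci combine by Fisher's method. Defaults are 10,000
dememorization steps and 100 batches × 5,000 iterations; tests use reduced
chains. Both a two-population genic table and any number of populations are
supported; the genotypic variant is not implemented (genic is the default
convention here).

## Admixture clustering

The Gibbs sampler implements the admixture model: latent cluster-of-origin
indicators per gene copy, cluster allele frequencies with conjugate
Dirichlet updates, individual admixture proportions Dirichlet(α + counts),
and a Metropolis step for α (uniform prior on (0, 10]). The correlated-
frequency model uses a single global drift parameter F: cluster frequencies
have prior Dirichlet(p̄·(1 − F)/F) anchored at the pooled sample frequencies
p̄, with F updated by Metropolis — a deliberate simplification of the
per-population-F model; the uncorrelated model (λ = 1) is available. F is
initialized at 0.25: starting near 0 pins all clusters to p̄ and the chain
can stall in that symmetric mode. The per-run likelihood summary is the
STRUCTURE-style ln P(D) ≈ mean(ln L) − var(ln L)/2 over post-burn-in sweeps.
Production settings mirroring the study protocol are burn-in 100,000 /
1,000,000 sweeps / 10 replicate runs / K = 1…8; tests and examples use
reduced chains (hundreds to thousands of sweeps), which suffice for the
well-separated synthetic conditions but not necessarily for weak structure.

Replicate runs at one K are aligned to the first run by Hungarian assignment
on column overlap QᵀQ′. Mode detection uses mean per-individual **cosine**
similarity of aligned Q rows (threshold 0.9): a plain dot product — the
first design considered — is bounded by Σq² < 1 for diffuse rows, so
identical diffuse runs would fail any fixed threshold; the normalized form
is 1 for identical rows regardless of sharpness. The consensus is the major
mode's average, renormalized. Evanno's ΔK is computed from means and
standard deviations of ln P(D) across runs; sd = 0 or an exactly linear
profile is flagged as "no optimum".

## Coalescent simulator

Demographies are event lists over named populations interpreted backward in
time (splits, two-source admixture, size changes), with symbolic parameters
resolved from a draw; simple arithmetic expressions over parameter names are
allowed (used for the bottleneck end time `tRecentIntro − tBottleneck`).
Between events each population coalesces independently in continuous time at
rate k(k−1)/(4N); times are years divided by the generation time (1 year —
the winter moth is univoltine). Lineages left in more than one population
after the last event are a validation error.

Mutations on each branch number Poisson((µ + s)·length); an event is a
single-nucleotide indel (±1 bp, off-ladder) with probability s/(µ + s), else
a generalized-stepwise step of k motif units, k geometric with mean
1/(1 − P), sign ± ½. Ladder states are confined to a contiguous window of
R = 40 states centred on the root allele (window midpoint); out-of-window
steps are redrawn (fresh size and direction) rather than reflected, with a
step-to-the-edge fallback for the degenerate P ≈ 1 / narrow-window corner.
Root allele size defaults to 200 bp. Per-locus rates scatter around the mean
parameters with Gamma(shape 2) draws truncated to per-locus bounds
(µ ∈ [10⁻⁶, 10⁻³], P ∈ [0.01, 1], SNI ∈ [10⁻⁹, 10⁻⁴]) — the shape and
bounds are documented knobs, chosen to match common ABC practice for
microsatellites. Priors are uniform over their bounds (log-uniform for the
SNI mean, which spans three decades); ordering constraints are enforced by
whole-vector rejection.

The simulator is validated against E[T₂] = 2N, the stepwise-model
within-population size variance 2Nµ, and an independent coalescent simulator
(msprime) for tree-length distributions.

## Scenario sets

The backbone tree has Spain diverging before the Serbia–Georgia split (at
t2, ancestor size NE3a), Germany formed at t1 by admixture with proportion
ra from the Spanish lineage (else Serbian), and the deepest merges at t3/t4
(sizes NE3b, NE1). Step 1 grafts Italy onto the Spanish branch (via an
ancestor at t3), or into Serbia or Georgia (at t3, constrained below t2 so
the attachment is to that terminal branch). Step 2, on the Italy-from-Spain
winner, attaches Tunisia either at tTunisia (LGM window, 5–20 ka; four
sources) or at tRecentIntro (1–10 ka; five sources including Germany) with a
founding bottleneck of size NBottleneck lasting tBottleneck years after
establishment — tBottleneck is read as a duration, the more natural reading
of a 10–200-year bound against a 1,000-year-scale introduction time. The
bottleneck-size prior is not published; Uniform(10, 10,000) spans
founding-event sizes. Three "out-of-Africa" alternatives (Tunisia ancestral
to Spain and/or Italy) are provided for the direction-of-colonization
contrast; their internal constraint sets are in `scenarios.py`, deliberately
isolated so the node-time assignments can be revised in one place.

`STUDY_DEMOGRAPHY` pins a point demography for synthetic "study-shaped"
data: the inferred LGM-from-Spain history with sizes and times at their
point estimates. The two deepest merge-time estimates overlap (the inference
cannot order them); t4 is set to 40 ka, inside its credible range and above
t3, so the event order is strict. Synthetic study datasets additionally get
5 % null alleles per locus and 2 % random missingness, emulating the data
quality the filters address.

## ABC engine

Summary statistics per dataset: per population mean allele count, mean Nei
unbiased genic diversity (the same estimator as Hs, shared code), and mean
allele-size variance in repeat units; per pair the uncorrected Weir &
Cockerham F_ST (same implementation as the differentiation module), the
classification index (mean per-individual natural-log likelihood of one
population's genotypes under the other's allele frequencies, with
Rannala–Mountain 1/A smoothing over the pair's allele set and leave-one-out
for self-assignment; both orderings are reported), and Goldstein's (δµ)².
Simulated data contain no nulls or missingness, so observed data are
summarized after the same locus exclusions to keep vectors comparable.

Statistics are normalized by median/MAD over the reference table (robust to
the heavy tails of size-variance statistics); zero-MAD statistics are
dropped from distances with a warning. Rejection retains ⌈fraction·n⌉ rows
by Euclidean distance, ties broken by row index. Scenario probabilities come
from a ridge-regularized multinomial logistic regression of the scenario
label on the statistic offsets over retained rows, Epanechnikov-weighted by
distance, evaluated at the origin; the ridge (C = 10⁴) also handles complete
separation. Parameter posteriors use Beaumont-style local-linear adjustment:
parameters are logit-mapped to their prior bounds (guaranteeing credible
intervals inside the support), regressed on the normalized offsets by
weighted least squares, residual-adjusted to the origin, and back-mapped;
summaries are weighted means/quantiles, with the mode from a weighted
Gaussian KDE with Silverman bandwidth. The model check fits a PCA to the
normalized reference statistics, projects the posterior-predictive
simulations and the observed vector, and flags the observed point by
Mahalanobis distance to the predictive cloud on the leading components
against the χ²(0.95) quantile. Scenario-choice error simulates
pseudo-observed datasets per scenario from the priors and reports the
fraction whose modal scenario differs from the generating one.

All randomness flows through `numpy` `SeedSequence` substreams keyed by
(scenario, replicate), so reference tables are independent of chunking and a
smaller build is a prefix of a larger one — this is also how the
million-simulation protocol would be distributed.

## Problem sizes and what the tests show

The bundled analyses run at deliberately reduced scale, chosen as the
package's own desk-scale defaults: reference tables of a few hundred
simulations per scenario (the full protocol uses 10⁶), retention fractions
scaled so that a few hundred rows are kept (the 1 % convention presumes
millions of rows; keeping ⌈0.01·3,600⌉ = 36 rows would starve the local
regressions), Gibbs chains of ~10³ sweeps, and coverage experiments of 200
trials on a single-population toy demography. At these sizes the pipeline
demonstrates: correct coalescent calibration, EM recovery of null
frequencies within ±0.03, bias reduction by the ENA correction, exact
retention counts, twin-scenario symmetry and separable-scenario certainty in
the logistic estimator, ~95 % credible-interval coverage, the Evanno
worked example, and crisp two-cluster recovery. Scenario discrimination
among the nine closely related step-2 topologies is weaker at reduced scale
than at 10⁶ simulations — the step-1 pseudo-observed error rate reported by
the acceptance script is accordingly an upper bound on the full-scale error,
not an estimate of it.

The synthetic generators emulate the study's shape (6 populations of 17–30
diploids, 24 loci on a 2 bp ladder, nulls and missingness) but not
real-data features such as locus-specific amplification quality, allele
binning error, or departures from the island/Balding–Nichols and
coalescent models; passing tests establish internal correctness and
calibration under the stated models, not the field accuracy of any
biological conclusion.

## Known limitations

* The correlated-frequency clustering model uses one global F rather than
  per-cluster drift; strong asymmetric drift may be summarized poorly.
* The logistic scenario-choice CI is not reported (point probabilities
  only); a bootstrap would be straightforward but is not wired in.
* The exact test implements the genic variant only.
* NeighborNet itself is out of scope: the package exports the ENA-F_ST
  matrix as a NEXUS DISTANCES block for SplitsTree.
* Full-scale (10⁶ simulations/scenario) runs are supported by the API and
  chunk-consistent seeding but are compute-bound in pure Python; expect to
  distribute them.
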