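"""ABC summary statistics, computed identically on observed and simulated data.

One-sample (per population, averaged over typed loci): mean number of
alleles, mean genic diversity (Nei's unbiased estimator, shared with the
diversity module), mean allele-size variance in repeat units. Two-sample (per
population pair): Weir & Cockerham F_ST (shared with the differentiation
module, uncorrected), the classification index (mean individual log-likelihood
of assigning one population's genotypes to the other's allele frequencies,
with Rannala-Mountain 1/A smoothing and leave-one-out for self-assignment)
for both orderings, and Goldstein's (delta-mu)^2 distance.

The statistic vector has a fixed, dataset-determined ordering so that observed
and simulated vectors are directly comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .null_fst import _pair_fst
from .popstats import _locus_stats


def one_sample_stats(ds: GenotypeDataset) -> dict[str, tuple[float, float, float]]:
    """Per population: (mean allele count, mean genic diversity, mean size variance).

    Loci with fewer than 2 typed individuals in a population are skipped for
    that population; sizes are converted to repeat units with each locus's
    motif length.
    """
    if ds.n_individuals == 0 or ds.n_loci == 0:
        raise ValueError("dataset is empty")
    pops = ds.population_indices()
    out = {}
    for pop, idx in pops.items():
        nals, gds, svars = [], [], []
        for l, loc in enumerate(ds.loci):
            genos = ds.calls[idx, l, :]
            st = _locus_stats(genos)
            if st is None:
                continue
            na, _eff, _ho, hs = st
            typed = genos[genos[:, 0] != MISSING]
            units = typed.ravel() / loc.motif_length
            nals.append(na)
            gds.append(hs)
            svars.append(float(np.var(units, ddof=1)))
        if not nals:
            raise ValueError(f"population {pop!r} has no usable locus")
        out[pop] = (
            float(np.mean(nals)),
            float(np.mean(gds)),
            float(np.mean(svars)),
        )
    return out


def classification_index(
    ds: GenotypeDataset, source: str, reference: str
) -> float:
    """Mean log-likelihood of assigning ``source`` individuals to ``reference``.

    Genotype likelihoods use Rannala-Mountain smoothed reference frequencies,
    (count + 1/A) / (n_genes + 1) with A the number of distinct alleles at the
    locus across the two populations, on the natural-log scale. When
    ``source == reference`` each individual's own genes are removed from the
    reference counts before scoring (leave-one-out).
    """
    pops = ds.population_indices()
    idx_s, idx_r = pops[source], pops[reference]
    loo = source == reference
    totals = np.zeros(idx_s.size)
    used = np.zeros(idx_s.size, dtype=bool)
    for l in range(ds.n_loci):
        gs = ds.calls[idx_s, l, :]  # (ns, 2)
        gr = ds.calls[idx_r, l, :].ravel()
        gr = gr[gr != MISSING]
        typed = gs[:, 0] != MISSING
        if gr.size == 0 or not typed.any():
            continue
        alleles = np.unique(np.concatenate([gr, gs[typed].ravel()]))
        A = alleles.size
        counts = np.bincount(
            np.searchsorted(alleles, gr), minlength=A
        ).astype(float)
        ca = np.searchsorted(alleles, gs[typed, 0])
        cb = np.searchsorted(alleles, gs[typed, 1])
        if loo:
            # each typed individual's own two genes leave the counts
            cnt_a = counts[ca] - 1.0
            cnt_b = counts[cb] - 1.0 - (ca == cb)
            tot = gr.size - 2.0
        else:
            cnt_a = counts[ca]
            cnt_b = counts[cb]
            tot = float(gr.size)
        if tot <= 0:
            continue
        fa = (cnt_a + 1.0 / A) / (tot + 1.0)
        fb = (cnt_b + 1.0 / A) / (tot + 1.0)
        het = ca != cb
        logp = np.log(fa) + np.log(fb) + np.where(het, np.log(2.0), 0.0)
        totals[typed] += logp
        used |= typed
    if not used.any():
        raise ValueError(f"no scorable individuals for {source!r} vs {reference!r}")
    return float(np.mean(totals[used]))


def delta_mu_squared(ds: GenotypeDataset, pair: tuple[str, str]) -> float:
    """Goldstein's (delta-mu)^2: squared difference of mean allele sizes
    (repeat units), averaged over loci typed in both populations."""
    pops = ds.population_indices()
    idx_a, idx_b = pops[pair[0]], pops[pair[1]]
    vals = []
    for l, loc in enumerate(ds.loci):
        ga = ds.calls[idx_a, l, :].ravel()
        gb = ds.calls[idx_b, l, :].ravel()
        ga = ga[ga != MISSING] / loc.motif_length
        gb = gb[gb != MISSING] / loc.motif_length
        if ga.size == 0 or gb.size == 0:
            continue
        vals.append((ga.mean() - gb.mean()) ** 2)
    if not vals:
        raise ValueError(f"populations {pair} share no typed locus")
    return float(np.mean(vals))


def two_sample_stats(
    ds: GenotypeDataset, pair: tuple[str, str]
) -> tuple[float, tuple[float, float], float]:
    """(F_ST, (classification index both orderings), (delta-mu)^2) for a pair."""
    pops = ds.population_indices()
    fst = _pair_fst(ds, pops[pair[0]], pops[pair[1]], None)
    if np.isnan(fst):
        raise ValueError(f"populations {pair} share no typed locus")
    lik = (
        classification_index(ds, pair[0], pair[1]),
        classification_index(ds, pair[1], pair[0]),
    )
    return fst, lik, delta_mu_squared(ds, pair)


def stat_vector(ds: GenotypeDataset, populations: list[str] | None = None) -> pd.Series:
    """The full ordered summary-statistic vector for a dataset.

    Ordering: per population (in ``populations`` order, default order of
    first appearance) the one-sample triple, then per unordered pair F_ST and
    (delta-mu)^2, then per ordered pair the classification index.
    """
    pops = populations or ds.population_labels()
    ones = one_sample_stats(ds)
    names, values = [], []
    for p in pops:
        na, gd, sv = ones[p]
        names += [f"nal_{p}", f"het_{p}", f"var_{p}"]
        values += [na, gd, sv]
    pop_idx = ds.population_indices()
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            fst = _pair_fst(ds, pop_idx[a], pop_idx[b], None)
            names += [f"fst_{a}~{b}", f"dmu2_{a}~{b}"]
            values += [fst, delta_mu_squared(ds, (a, b))]
    for a in pops:
        for b in pops:
            if a != b:
                names.append(f"lik_{a}~{b}")
                values.append(classification_index(ds, a, b))
    return pd.Series(values, index=names, dtype=float)
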