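"""Per-population microsatellite diversity statistics and a permutation HWE test.

Statistics follow the GenoDive-style summary: number of individuals genotyped
(n), mean alleles per locus (Na), effective number of alleles (Eff_Na =
1/sum p^2 per locus, averaged), observed heterozygosity (Ho), Nei's unbiased
within-population gene diversity (Hs), total gene diversity (Ht), inbreeding
coefficient G_IS = 1 - Ho/Hs, and a one-sided permutation test of
Hardy-Weinberg equilibrium (statistic G_IS, alternative: heterozygote deficit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import MISSING, GenotypeDataset


@dataclass
class AlleleFrequencyTable:
    """Per locus, per population allele frequencies over non-missing genes.

    ``freqs[locus_id][pop]`` maps allele size -> frequency;
    ``gene_counts[locus_id][pop]`` is the number of typed genes (2 x typed
    individuals). Populations with zero typed genes at a locus get an empty
    map and are listed in ``empty``.
    """

    freqs: dict[str, dict[str, dict[int, float]]]
    gene_counts: dict[str, dict[str, int]]
    empty: list[tuple[str, str]]


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Tabulate allele frequencies per locus and population.

    Missing genes never enter the counts; per locus/pop frequencies sum to 1
    over the typed genes.
    """
    if ds.n_individuals == 0 or ds.n_loci == 0:
        raise ValueError("dataset is empty")
    pops = ds.population_indices()
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    gene_counts: dict[str, dict[str, int]] = {}
    empty: list[tuple[str, str]] = []
    for l, loc in enumerate(ds.loci):
        freqs[loc.id] = {}
        gene_counts[loc.id] = {}
        for pop, idx in pops.items():
            genes = ds.calls[idx, l, :].ravel()
            genes = genes[genes != MISSING]
            gene_counts[loc.id][pop] = int(genes.size)
            if genes.size == 0:
                freqs[loc.id][pop] = {}
                empty.append((loc.id, pop))
                continue
            sizes, counts = np.unique(genes, return_counts=True)
            freqs[loc.id][pop] = {
                int(s): c / genes.size for s, c in zip(sizes, counts)
            }
    return AlleleFrequencyTable(freqs, gene_counts, empty)


@dataclass
class PopSummary:
    """Diversity summary for one population (see module docstring)."""

    population: str
    n: int
    Na: float
    Eff_Na: float
    Ho: float
    Hs: float
    Ht: float
    GIS: float | None
    hwe_p: float | None


def _locus_stats(genotypes: np.ndarray) -> tuple[float, float, float, float] | None:
    """(allele count, Eff_Na, Ho, unbiased Hs) for one locus of one population.

    ``genotypes`` is (n, 2) with MISSING rows allowed; returns None when fewer
    than 2 typed individuals. Hs uses Nei's (1987) small-sample correction
    n/(n-1) * (1 - sum p^2 - Ho/(2n)).
    """
    typed = genotypes[genotypes[:, 0] != MISSING]
    n = typed.shape[0]
    if n < 2:
        return None
    genes = typed.ravel()
    _, counts = np.unique(genes, return_counts=True)
    p = counts / genes.size
    sum_p2 = float(np.sum(p**2))
    ho = float(np.mean(typed[:, 0] != typed[:, 1]))
    hs = n / (n - 1) * (1.0 - sum_p2 - ho / (2 * n))
    return float(len(p)), 1.0 / sum_p2, ho, max(hs, 0.0)


def _population_row(genotypes: np.ndarray) -> tuple[float, float, float, float, int]:
    """Mean (Na, Eff_Na, Ho, Hs) over typed loci + max typed n for one pop."""
    nas, effs, hos, hss = [], [], [], []
    for l in range(genotypes.shape[1]):
        st = _locus_stats(genotypes[:, l, :])
        if st is None:
            continue
        na, eff, ho, hs = st
        nas.append(na)
        effs.append(eff)
        hos.append(ho)
        hss.append(hs)
    if not nas:
        raise ValueError("population has no locus with >= 2 typed individuals")
    n = int((genotypes[:, :, 0] != MISSING).any(axis=1).sum())
    return (
        float(np.mean(nas)),
        float(np.mean(effs)),
        float(np.mean(hos)),
        float(np.mean(hss)),
        n,
    )


def _permute_within(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle genes among typed individuals independently at each locus."""
    out = genotypes.copy()
    for l in range(genotypes.shape[1]):
        typed = np.flatnonzero(genotypes[:, l, 0] != MISSING)
        if typed.size < 2:
            continue
        genes = genotypes[typed, l, :].ravel()
        rng.shuffle(genes)
        out[typed, l, :] = genes.reshape(-1, 2)
    return out


def population_summary(
    ds: GenotypeDataset,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[PopSummary]:
    """Compute diversity summaries for every population.

    The HWE permutation test shuffles alleles among individuals within the
    population (per locus) and recomputes G_IS; the one-sided p-value is
    ``(#{permuted G_IS >= observed} + 1) / (n_perm + 1)``, so with the default
    ``n_perm=999`` the smallest attainable p is 0.001. ``Ht`` in each row is
    the population's own gene diversity (equal to Hs for a single population);
    use :func:`total_gene_diversity` for the across-population Ht.
    """
    rng = np.random.default_rng(seed)
    pops = ds.population_indices()
    out = []
    for pop, idx in pops.items():
        if idx.size < 2:
            warnings.warn(f"population {pop!r} has < 2 individuals; estimators biased")
        genos = ds.calls[idx]
        na, eff, ho, hs, n = _population_row(genos)
        if hs > 0:
            gis = 1.0 - ho / hs
            exceed = 0
            for _ in range(n_perm):
                perm = _permute_within(genos, rng)
                _, _, ho_p, hs_p, _ = _population_row(perm)
                gis_p = 1.0 - ho_p / hs_p if hs_p > 0 else -np.inf
                if gis_p >= gis:
                    exceed += 1
            hwe_p = (exceed + 1) / (n_perm + 1)
        else:
            warnings.warn(f"population {pop!r} is monomorphic; G_IS undefined")
            gis, hwe_p = None, None
        out.append(PopSummary(pop, n, na, eff, ho, hs, hs, gis, hwe_p))
    return out


def total_gene_diversity(ds: GenotypeDataset) -> float:
    """Ht: gene diversity of pooled, equally-weighted population frequencies.

    Per locus, 1 - sum(p_bar^2) with p_bar the unweighted mean of population
    frequencies over populations typed at that locus; averaged across loci.
    """
    table = allele_frequencies(ds)
    hts = []
    for locus, by_pop in table.freqs.items():
        maps = [m for m in by_pop.values() if m]
        if not maps:
            continue
        alleles = sorted({a for m in maps for a in m})
        pbar = np.array([np.mean([m.get(a, 0.0) for m in maps]) for a in alleles])
        hts.append(1.0 - float(np.sum(pbar**2)))
    if not hts:
        raise ValueError("no typed locus")
    return float(np.mean(hts))


def summary_frame(summaries: list[PopSummary]):
    """Summaries as a pandas DataFrame in report column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "population": s.population,
                "n": s.n,
                "Na": s.Na,
                "Eff_Na": s.Eff_Na,
                "Ho": s.Ho,
                "Hs": s.Hs,
                "Ht": s.Ht,
                "GIS": s.GIS,
                "HWE_p": s.hwe_p,
            }
            for s in summaries
        ]
    )
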