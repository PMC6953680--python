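"""Null-allele EM estimation, ENA-corrected pairwise F_ST, and exact tests.

Null alleles fail to amplify in PCR: a null/visible genotype scores as an
apparent homozygote and a null/null genotype as a missing genotype, inflating
homozygosity and upward-biasing F_ST. Per locus and population, an EM
algorithm (Dempster-style, as in FreeNA) decomposes apparent homozygotes into
true homozygotes vs null carriers and (optionally) missing genotypes into
null/null homozygotes, under within-population HWE.

Pairwise F_ST uses Weir & Cockerham variance components summed over alleles
and loci (ratio of sums). The ENA ("excluding null alleles") correction
appends the estimated null as an extra allelic state per locus/population —
with visible frequencies rescaled accordingly — and excludes that state from
the numerator and denominator sums.

The exact test of differentiation follows GenePop: per-locus Markov-chain
exploration of allele-count contingency tables with fixed margins
(probability test), loci combined by Fisher's method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .dataset import MISSING, GenotypeDataset

# ---------------------------------------------------------------------------
# Null-allele EM
# ---------------------------------------------------------------------------


@dataclass
class NullEstimates:
    """Per-locus, per-population null-allele frequency estimates.

    ``freq[locus_id][pop]`` is the estimated null frequency in [0, 1);
    ``visible[locus_id][pop]`` maps allele size -> corrected frequency (these
    sum to ``1 - freq``); ``iterations`` and ``loglik_trace`` record EM
    convergence; ``skipped`` lists (locus, pop) pairs with < 2 typed
    individuals.
    """

    freq: dict[str, dict[str, float]]
    visible: dict[str, dict[str, dict[int, float]]]
    iterations: dict[str, dict[str, int]]
    loglik_trace: dict[str, dict[str, list[float]]] = field(repr=False, default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def grand_mean(self) -> float:
        """Mean null frequency over all estimated locus x population cells."""
        vals = [v for by_pop in self.freq.values() for v in by_pop.values()]
        if not vals:
            raise ValueError("no null-allele estimates available")
        return float(np.mean(vals))

    def population_means(self) -> dict[str, float]:
        pops: dict[str, list[float]] = {}
        for by_pop in self.freq.values():
            for pop, v in by_pop.items():
                pops.setdefault(pop, []).append(v)
        return {p: float(np.mean(v)) for p, v in pops.items()}


def _em_one(
    genotypes: np.ndarray,
    missing_as_null: bool,
    tol: float,
    max_iter: int,
) -> tuple[float, dict[int, float], int, list[float]] | None:
    """EM for one locus in one population.

    Returns (null freq, visible freqs, iterations, loglik trace) or None when
    fewer than 2 typed individuals.
    """
    typed = genotypes[genotypes[:, 0] != MISSING]
    n_typed = typed.shape[0]
    n_miss = genotypes.shape[0] - n_typed if missing_as_null else 0
    if n_typed < 2:
        return None
    alleles = np.unique(typed)
    k = alleles.size
    a_index = {int(a): i for i, a in enumerate(alleles)}
    # category counts
    hom = np.zeros(k)
    het = np.zeros((k, k))
    for a, b in typed:
        i, j = a_index[int(a)], a_index[int(b)]
        if i == j:
            hom[i] += 1
        else:
            het[min(i, j), max(i, j)] += 1
    n_total = n_typed + n_miss
    eps = 1e-12

    # init: visible uniform-ish from gene counts, small null mass
    r = 0.1 if (n_miss > 0 or hom.sum() > 0) else 1e-6
    counts = hom * 2 + het.sum(axis=0) + het.sum(axis=1)
    p = counts / counts.sum() * (1 - r)

    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # log-likelihood of observed categories
        ll = 0.0
        for i in range(k):
            if hom[i]:
                ll += hom[i] * np.log(p[i] ** 2 + 2 * p[i] * r + eps)
            for j in range(i + 1, k):
                if het[i, j]:
                    ll += het[i, j] * np.log(2 * p[i] * p[j] + eps)
        if n_miss:
            ll += n_miss * np.log(r**2 + eps)
        trace.append(float(ll))
        # E-step: expected gene counts
        g = np.zeros(k)
        g_null = 0.0
        for i in range(k):
            if hom[i]:
                denom = p[i] ** 2 + 2 * p[i] * r + eps
                w_true = p[i] ** 2 / denom
                g[i] += hom[i] * (2 * w_true + (1 - w_true))
                g_null += hom[i] * (1 - w_true)
            for j in range(i + 1, k):
                g[i] += het[i, j]
                g[j] += het[i, j]
        g_null += 2.0 * n_miss
        # M-step
        total = 2.0 * n_total
        p_new = g / total
        r_new = g_null / total
        delta = len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol
        p, r = p_new, r_new
        if delta:
            break
    visible = {int(a): float(p[a_index[int(a)]]) for a in alleles}
    return float(min(r, 1 - 1e-12)), visible, it, trace


def estimate_null_frequencies(
    ds: GenotypeDataset,
    tol: float = 1e-8,
    max_iter: int = 2000,
    missing_as_null: bool = True,
) -> NullEstimates:
    """Estimate per-locus, per-population null-allele frequencies by EM.

    With ``missing_as_null`` (the FreeNA treatment, default) whole-locus
    missing genotypes are treated as candidate null/null homozygotes;
    otherwise they are excluded and the null frequency is identified from the
    homozygote excess alone.
    """
    pops = ds.population_indices()
    freq: dict[str, dict[str, float]] = {}
    visible: dict[str, dict[str, dict[int, float]]] = {}
    iterations: dict[str, dict[str, int]] = {}
    traces: dict[str, dict[str, list[float]]] = {}
    skipped: list[tuple[str, str]] = []
    for l, loc in enumerate(ds.loci):
        freq[loc.id], visible[loc.id] = {}, {}
        iterations[loc.id], traces[loc.id] = {}, {}
        for pop, idx in pops.items():
            res = _em_one(ds.calls[idx, l, :], missing_as_null, tol, max_iter)
            if res is None:
                skipped.append((loc.id, pop))
                continue
            r, vis, it, trace = res
            freq[loc.id][pop] = r
            visible[loc.id][pop] = vis
            iterations[loc.id][pop] = it
            traces[loc.id][pop] = trace
    if skipped:
        warnings.warn(f"null-allele EM skipped {len(skipped)} locus/pop cells")
    return NullEstimates(freq, visible, iterations, traces, skipped)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST with optional ENA correction
# ---------------------------------------------------------------------------


@dataclass
class FstMatrix:
    labels: list[str]
    matrix: np.ndarray
    ena_corrected: bool

    def mean_pairwise(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.matrix[iu]
        return float(np.nanmean(vals))


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) a, b, c per allele over r populations.

    ``n``: diploid sample sizes (r,); ``p``: allele frequencies (r, A);
    ``h``: observed frequencies of heterozygotes carrying each allele (r, A).
    Returns three length-A arrays.
    """
    p = np.atleast_2d(p)
    h = np.atleast_2d(h)
    r = n.size
    nbar = n.mean()
    A = p.shape[1]
    if r < 2 or nbar <= 1:
        return np.zeros(A), np.zeros(A), np.zeros(A)
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return np.zeros(A), np.zeros(A), np.zeros(A)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def _pair_fst(
    ds: GenotypeDataset,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    nulls: NullEstimates | None,
    pop_a: str = "",
    pop_b: str = "",
) -> float:
    """Multilocus pairwise theta (ratio of summed components)."""
    num = 0.0
    den = 0.0
    any_locus = False
    for l, loc in enumerate(ds.loci):
        if nulls is not None:
            cells = nulls.visible.get(loc.id, {})
            if pop_a not in cells or pop_b not in cells:
                continue
            # corrected frequency vectors over visible alleles + null state
            alleles = sorted(set(cells[pop_a]) | set(cells[pop_b]))
            n_arr = np.array([len(idx_a), len(idx_b)], dtype=float)
            pA = np.array([cells[pop_a].get(a, 0.0) for a in alleles])
            pB = np.array([cells[pop_b].get(a, 0.0) for a in alleles])
            any_locus = True
            # null state excluded from the sums over allelic states;
            # heterozygosity at its HWE expectation under the corrected
            # frequencies (true heterozygote counts are unobservable when
            # nulls are present); the null state counts as "other allele"
            p = np.stack([pA, pB])
            h = 2 * p * (1 - p)
            a_, b_, c_ = _wc_components(n_arr, p, h)
            num += a_.sum()
            den += (a_ + b_ + c_).sum()
        else:
            ga = ds.calls[idx_a, l, :]
            gb = ds.calls[idx_b, l, :]
            ga = ga[ga[:, 0] != MISSING]
            gb = gb[gb[:, 0] != MISSING]
            if ga.shape[0] < 2 or gb.shape[0] < 2:
                continue
            any_locus = True
            alleles = np.unique(np.concatenate([ga.ravel(), gb.ravel()]))
            A = alleles.size
            n_arr = np.array([ga.shape[0], gb.shape[0]], dtype=float)
            p = np.empty((2, A))
            h = np.empty((2, A))
            for row, g in enumerate((ga, gb)):
                codes = np.searchsorted(alleles, g)
                p[row] = np.bincount(codes.ravel(), minlength=A) / (2.0 * g.shape[0])
                het = codes[:, 0] != codes[:, 1]
                h[row] = (
                    np.bincount(codes[het].ravel(), minlength=A) / g.shape[0]
                )
            a_, b_, c_ = _wc_components(n_arr, p, h)
            num += a_.sum()
            den += (a_ + b_ + c_).sum()
    if not any_locus:
        return np.nan
    if den == 0:
        return 0.0
    return num / den


def ena_fst_matrix(
    ds: GenotypeDataset,
    nulls: NullEstimates | None = None,
    correct: bool = True,
) -> FstMatrix:
    """Pairwise multilocus F_ST matrix, optionally ENA-corrected.

    When ``correct`` is true, ``nulls`` must come from the same dataset; the
    corrected per-population frequency vectors (visible alleles rescaled, null
    appended) replace the raw frequencies and the null state is excluded from
    the component sums.
    """
    if correct and nulls is None:
        raise ValueError("ENA correction requires null-allele estimates")
    labels = ds.population_labels()
    pops = ds.population_indices()
    k = len(labels)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = _pair_fst(
                ds,
                pops[labels[i]],
                pops[labels[j]],
                nulls if correct else None,
                labels[i],
                labels[j],
            )
            if np.isnan(v):
                warnings.warn(
                    f"populations {labels[i]!r}/{labels[j]!r} share no usable locus"
                )
            mat[i, j] = mat[j, i] = v
    return FstMatrix(labels, mat, bool(correct))


# ---------------------------------------------------------------------------
# Exact test of differentiation (GenePop-style)
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of a contingency table (fixed margins),
    up to the margin-dependent constant: -sum log(x_ij!)."""
    return float(-gammaln(table + 1).sum())


def _mcmc_table_p(
    table: np.ndarray,
    rng: np.random.Generator,
    dememorization: int,
    batches: int,
    iterations: int,
) -> tuple[float, float]:
    """Probability test p-value via Metropolis walk over tables with fixed
    margins; returns (p, SE over batches)."""
    table = table.astype(np.int64).copy()
    nr, nc = table.shape
    lp_obs = _log_table_prob(table)
    lp = lp_obs

    def step() -> None:
        nonlocal lp
        r1, r2 = rng.choice(nr, 2, replace=False)
        c1, c2 = rng.choice(nc, 2, replace=False)
        if table[r1, c1] == 0 or table[r2, c2] == 0:
            return
        # move: x[r1,c1]--, x[r2,c2]--, x[r1,c2]++, x[r2,c1]++
        ratio = (table[r1, c1] * table[r2, c2]) / (
            (table[r1, c2] + 1) * (table[r2, c1] + 1)
        )
        if ratio >= 1 or rng.random() < ratio:
            table[r1, c1] -= 1
            table[r2, c2] -= 1
            table[r1, c2] += 1
            table[r2, c1] += 1
            lp = _log_table_prob(table)

    for _ in range(dememorization):
        step()
    tol = 1e-9
    batch_ps = []
    for _ in range(batches):
        hits = 0
        for _ in range(iterations):
            step()
            if lp <= lp_obs + tol:
                hits += 1
        batch_ps.append(hits / iterations)
    p = float(np.mean(batch_ps))
    se = float(np.std(batch_ps, ddof=1) / np.sqrt(batches)) if batches > 1 else 0.0
    return p, se


def differentiation_exact_test(
    ds: GenotypeDataset,
    pair: tuple[str, str],
    mc: tuple[int, int, int] = (10_000, 100, 5_000),
    seed: int | None = None,
) -> dict:
    """Exact test of genic differentiation for one population pair.

    Per polymorphic locus, a Markov chain explores allele-count contingency
    tables with the observed margins; the per-locus p-value is the chain
    fraction of tables no more probable than the observed one. Loci are
    combined with Fisher's method. ``mc`` is (dememorization, batches,
    iterations per batch). Returns a dict with ``p_combined``, ``per_locus``
    (locus id -> p), ``excluded`` (monomorphic loci) and per-locus standard
    errors.
    """
    rng = np.random.default_rng(seed)
    pops = ds.population_indices()
    for p in pair:
        if p not in pops:
            raise ValueError(f"unknown population {p!r}")
    idx = [pops[pair[0]], pops[pair[1]]]
    per_locus: dict[str, float] = {}
    ses: dict[str, float] = {}
    excluded: list[str] = []
    demem, batches, iters = mc
    for l, loc in enumerate(ds.loci):
        genes = []
        for ix in idx:
            g = ds.calls[ix, l, :].ravel()
            genes.append(g[g != MISSING])
        alleles = np.unique(np.concatenate(genes))
        if alleles.size < 2 or any(g.size == 0 for g in genes):
            excluded.append(loc.id)
            continue
        tab = np.stack(
            [np.array([(g == a).sum() for a in alleles]) for g in genes]
        )
        p, se = _mcmc_table_p(tab, rng, demem, batches, iters)
        per_locus[loc.id] = p
        ses[loc.id] = se
    if excluded:
        warnings.warn(f"monomorphic/untyped loci excluded from exact test: {excluded}")
    if not per_locus:
        raise ValueError("no polymorphic locus for the exact test")
    ps = np.clip(np.array(list(per_locus.values())), 1e-300, 1.0)
    stat = -2.0 * np.log(ps).sum()
    p_comb = float(chi2.sf(stat, df=2 * ps.size))
    return {
        "p_combined": p_comb,
        "per_locus": per_locus,
        "per_locus_se": ses,
        "excluded": excluded,
    }
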