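"""Bayesian admixture clustering, replicate-run alignment, and Evanno delta-K.

A compact Gibbs sampler for the admixture model with (optionally) correlated
allele frequencies: each gene copy carries a latent cluster-of-origin
indicator; cluster allele frequencies get conjugate Dirichlet updates (in the
correlated model the Dirichlet prior is anchored at the pooled ancestral
frequencies with concentration (1-F)/F, F a single global drift parameter
updated by Metropolis); individual admixture proportions get Dirichlet
updates; the Dirichlet concentration alpha gets a Metropolis step.

Replicate runs at one K are aligned by optimally permuting cluster columns
(Hungarian assignment on column-overlap), clustered into modes by mean
per-individual cosine similarity, and averaged per mode — the Clumpak-style
summary. The Evanno delta-K statistic selects K from the mean and standard
deviation of run log-likelihoods: delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .dataset import MISSING, GenotypeDataset


@dataclass
class StructureRun:
    """One clustering run: posterior-mean Q plus a log-likelihood estimate.

    ``lnPD`` is the STRUCTURE-style estimate mean(lnL) - var(lnL)/2 over
    post-burn-in sweeps; ``mean_lnl`` the raw mean.
    """

    K: int
    Q: np.ndarray
    lnPD: float
    mean_lnl: float
    seed: int | None
    iterations: int
    burnin: int

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of Q must sum to 1")


@dataclass
class RunEnsemble:
    """Replicate runs grouped by K (all on the same individual ordering)."""

    runs: dict[int, list[StructureRun]] = field(default_factory=dict)

    def add(self, run: StructureRun) -> None:
        self.runs.setdefault(run.K, []).append(run)


def _encode(ds: GenotypeDataset) -> tuple[np.ndarray, list[int]]:
    """Integer-code alleles per locus; missing genes get -1."""
    codes = np.full(ds.calls.shape, -1, dtype=np.int64)
    n_alleles = []
    for l in range(ds.n_loci):
        genes = ds.calls[:, l, :]
        typed = genes != MISSING
        alleles = np.unique(genes[typed])
        n_alleles.append(max(len(alleles), 1))
        if len(alleles):
            codes[:, l, :][typed] = np.searchsorted(alleles, genes[typed])
    return codes, n_alleles


def admixture_gibbs(
    ds: GenotypeDataset,
    K: int,
    iterations: int = 10_000,
    burnin: int = 2_000,
    seed: int | None = None,
    freq_model: str = "correlated",
    lambda_: float = 1.0,
) -> StructureRun:
    """Run the admixture-model Gibbs sampler at a fixed K.

    Defaults in production use mirror the study protocol (burn-in 100,000 and
    1,000,000 sweeps, ten replicates); the reduced defaults here are for
    interactive and test use — pass larger values for real analyses.
    """
    if iterations <= burnin:
        raise ValueError("iterations must exceed burnin")
    if K > ds.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    if freq_model not in ("correlated", "uncorrelated"):
        raise ValueError(f"unknown freq_model {freq_model!r}")
    rng = np.random.default_rng(seed)
    codes, n_alleles = _encode(ds)
    n, L = ds.n_individuals, ds.n_loci
    if all(a < 2 for a in n_alleles):
        raise ValueError("dataset has no polymorphic locus")

    # ancestral (pooled) frequencies for the correlated model
    ancestral = []
    for l in range(L):
        genes = codes[:, l, :]
        genes = genes[genes >= 0]
        c = np.bincount(genes, minlength=n_alleles[l]).astype(float)
        c = c + 1e-6
        ancestral.append(c / c.sum())

    # start F away from 0: a tiny initial F pins every cluster to the
    # ancestral frequencies and the chain can stall in that symmetric mode
    F = 0.25
    if freq_model == "correlated":
        P = [
            rng.dirichlet(np.clip(anc * (1 - F) / F, 1e-3, None), size=K)
            for anc in ancestral
        ]
    else:
        P = [rng.dirichlet(np.ones(a), size=K) for a in n_alleles]
    Q = rng.dirichlet(np.ones(K), size=n)
    alpha = 1.0

    masks = [codes[:, l, 0] >= 0 for l in range(L)]
    q_sum = np.zeros_like(Q)
    lnls: list[float] = []
    n_kept = 0

    for sweep in range(iterations):
        n_ik = np.zeros((n, K))
        counts = [np.zeros((K, a)) for a in n_alleles]
        lnl = 0.0
        for l in range(L):
            m = masks[l]
            if not m.any():
                continue
            arr = codes[m, l, :]  # (nm, 2)
            pl = P[l]  # (K, A)
            lik = pl[:, arr]  # (K, nm, 2)
            probs = np.transpose(lik, (1, 2, 0)) * Q[m][:, None, :]
            tot = probs.sum(axis=2, keepdims=True)
            lnl += float(np.log(tot[..., 0]).sum())
            probs /= tot
            u = rng.random(arr.shape)[..., None]
            z = (np.cumsum(probs, axis=2) < u).sum(axis=2)
            z = np.minimum(z, K - 1)
            np.add.at(counts[l], (z.ravel(), arr.ravel()), 1.0)
            rows = np.repeat(np.flatnonzero(m), 2)
            np.add.at(n_ik, (rows, z.ravel()), 1.0)
        # cluster allele frequencies
        for l in range(L):
            prior = (
                ancestral[l] * (1.0 - F) / F
                if freq_model == "correlated"
                else np.full(n_alleles[l], lambda_)
            )
            g = counts[l] + prior[None, :]
            draw = rng.standard_gamma(g)
            P[l] = draw / draw.sum(axis=1, keepdims=True)
        # admixture proportions
        g = n_ik + alpha
        draw = rng.standard_gamma(g)
        Q = draw / draw.sum(axis=1, keepdims=True)
        # alpha Metropolis step (uniform prior on (0, 10])
        if K > 1:
            prop = alpha + rng.normal(0.0, 0.25)
            if 0.0 < prop <= 10.0:
                logq = np.log(np.clip(Q, 1e-300, None)).sum()
                cur = n * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1) * logq
                new = n * (gammaln(K * prop) - K * gammaln(prop)) + (prop - 1) * logq
                if np.log(rng.random()) < new - cur:
                    alpha = prop
        # drift parameter Metropolis step
        if freq_model == "correlated":
            prop = F + rng.normal(0.0, 0.05)
            if 1e-4 < prop < 0.999:

                def flik(f: float) -> float:
                    tot = 0.0
                    for l in range(L):
                        a = ancestral[l] * (1.0 - f) / f
                        tot += K * (gammaln(a.sum()) - gammaln(a).sum())
                        tot += float(((a - 1.0)[None, :] * np.log(P[l] + 1e-300)).sum())
                    return tot

                if np.log(rng.random()) < flik(prop) - flik(F):
                    F = prop
        if sweep >= burnin:
            q_sum += Q
            lnls.append(lnl)
            n_kept += 1

    q_mean = q_sum / n_kept
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    arr = np.asarray(lnls)
    mean_lnl = float(arr.mean())
    lnpd = float(mean_lnl - arr.var() / 2.0)
    return StructureRun(K, q_mean, lnpd, mean_lnl, seed, iterations, burnin)


# ---------------------------------------------------------------------------
# Run alignment and averaging
# ---------------------------------------------------------------------------


def _align_pair(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Column permutation of ``q`` maximizing overlap with ``q_ref``."""
    S = q_ref.T @ q  # (K, K) column overlap
    rows, cols = linear_sum_assignment(-S)
    perm = np.empty_like(cols)
    perm[rows] = cols
    return q[:, perm]


def _similarity(q1: np.ndarray, q2: np.ndarray) -> float:
    """Mean per-individual cosine similarity between aligned Q matrices."""
    num = (q1 * q2).sum(axis=1)
    den = np.linalg.norm(q1, axis=1) * np.linalg.norm(q2, axis=1)
    return float(np.mean(num / den))


@dataclass
class AlignmentResult:
    consensus: np.ndarray
    modes: list[list[int]]
    aligned: list[np.ndarray]
    similarity: np.ndarray

    @property
    def major_mode(self) -> list[int]:
        return self.modes[0]


def align_runs(
    runs: list[StructureRun], similarity_threshold: float = 0.9
) -> AlignmentResult:
    """Align replicate runs at one K, detect modes, and average per mode.

    Runs are aligned to the first run's column order; runs cluster greedily
    into modes (joining the first mode whose members all have similarity >=
    the threshold); modes are ordered by size (major mode first) and the
    consensus is the major mode's per-individual average, renormalized.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    n = runs[0].Q.shape[0]
    for r in runs:
        if r.K != K:
            raise ValueError(f"runs mix K={K} and K={r.K}")
        if r.Q.shape[0] != n:
            raise ValueError("runs disagree on the number of individuals")
    aligned = [runs[0].Q.copy()]
    for r in runs[1:]:
        aligned.append(_align_pair(aligned[0], r.Q))
    m = len(runs)
    sim = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            # align j onto i directly so mode detection is anchor-free
            s = _similarity(aligned[i], _align_pair(aligned[i], aligned[j]))
            sim[i, j] = sim[j, i] = s
    modes: list[list[int]] = []
    for i in range(m):
        for mode in modes:
            if all(sim[i, j] >= similarity_threshold for j in mode):
                mode.append(i)
                break
        else:
            modes.append([i])
    modes.sort(key=len, reverse=True)
    major = modes[0]
    ref = aligned[major[0]]
    acc = np.zeros_like(ref)
    for i in major:
        acc += _align_pair(ref, aligned[i])
    consensus = acc / len(major)
    consensus /= consensus.sum(axis=1, keepdims=True)
    return AlignmentResult(consensus, modes, aligned, sim)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------


def evanno_delta_k(ensemble: RunEnsemble) -> tuple[pd.DataFrame, int | None]:
    """Evanno table (K, mean lnPD, sd, delta-K) and the optimal K.

    Requires at least three consecutive K values with >= 2 runs each for a
    defined delta-K; returns (table, optimal K) with ``None`` when no interior
    K has a positive delta-K (flat/linear likelihood profile) or sd is zero
    everywhere.
    """
    ks = sorted(ensemble.runs)
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    means = {k: float(np.mean([r.lnPD for r in ensemble.runs[k]])) for k in ks}
    sds = {
        k: float(np.std([r.lnPD for r in ensemble.runs[k]], ddof=1))
        if len(ensemble.runs[k]) >= 2
        else np.nan
        for k in ks
    }
    rows = []
    for k in ks:
        dk = np.nan
        if (k - 1) in means and (k + 1) in means:
            if sds[k] == 0:
                warnings.warn(f"sd of lnPD is zero at K={k}; delta-K undefined")
            elif np.isfinite(sds[k]):
                dk = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
        rows.append({"K": k, "mean_lnPD": means[k], "sd_lnPD": sds[k], "delta_K": dk})
    table = pd.DataFrame(rows)
    finite = table["delta_K"].dropna()
    if finite.empty or np.allclose(finite, 0.0):
        if not finite.empty:
            warnings.warn("delta-K is zero everywhere (linear lnPD); no optimum")
        return table, None
    best = int(table.loc[table["delta_K"].idxmax(), "K"])
    return table, best


# ---------------------------------------------------------------------------
# Q-table IO (STRUCTURE-output style)
# ---------------------------------------------------------------------------


def write_q_table(run: StructureRun, individuals: list[str]) -> str:
    """Q matrix as tab-separated text (individual, then K columns)."""
    lines = ["individual\t" + "\t".join(f"Q{k + 1}" for k in range(run.K))]
    for ind, row in zip(individuals, run.Q):
        lines.append(ind + "\t" + "\t".join(f"{v:.6f}" for v in row))
    return "\n".join(lines) + "\n"


def read_q_table(text: str, lnPD: float = 0.0) -> StructureRun:
    """Parse a Q table written by :func:`write_q_table` (or equivalent);
    allows ingesting runs from the original STRUCTURE binary for delta-K and
    alignment without the bundled sampler."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    rows = [ln.split("\t") for ln in lines[1:]]
    q = np.array([[float(v) for v in r[1:]] for r in rows])
    q = q / q.sum(axis=1, keepdims=True)
    return StructureRun(q.shape[1], q, lnPD, lnPD, None, 0, 0)
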