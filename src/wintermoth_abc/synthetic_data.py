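"""Synthetic genotype datasets and clustering-run ensembles with known truth.

Everything downstream can be validated without external data: island-model
datasets with a target F_ST (Balding-Nichols frequency model), null-allele
injection at known per-locus frequencies, study-shaped datasets simulated from
the demographic scenarios, and replicate clustering-run ensembles with
controlled modes and likelihood profiles. Each generator returns the record
of generating values needed to score downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster_summary import RunEnsemble, StructureRun
from .dataset import MISSING, GenotypeDataset, LocusInfo
from .coalescent_sim import LocusModel, simulate_dataset
from .scenarios import (
    STUDY_DEMOGRAPHY,
    STUDY_N_LOCI,
    STUDY_SAMPLING,
    priors_table,
    sample_for_scenario,
    step2_scenarios,
)


@dataclass
class SyntheticSpec:
    """Shape and truth parameters for an island-model synthetic dataset.

    Defaults mirror the study's shape: 6 populations of 10-30 diploids, 24
    microsatellite loci on a 2 bp ladder.
    """

    n_pops: int = 6
    sample_sizes: list[int] = field(
        default_factory=lambda: [28, 30, 26, 30, 30, 17]
    )
    n_loci: int = STUDY_N_LOCI
    target_fst: float = 0.1
    n_alleles: int = 8
    motif_length: int = 2
    base_size: int = 200
    null_freqs: list[float] | None = None
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.sample_sizes) != self.n_pops:
            raise ValueError("sample_sizes length must equal n_pops")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")


def fst_from_migration(n_migrants: float) -> float:
    """Island-model expectation F_ST = 1 / (1 + 4 Nm)."""
    if n_migrants == np.inf:
        return 0.0
    return 1.0 / (1.0 + 4.0 * n_migrants)


def generate_island_dataset(
    spec: SyntheticSpec,
) -> tuple[GenotypeDataset, dict]:
    """Island-model dataset with expected F_ST equal to ``spec.target_fst``.

    Population allele frequencies follow the Balding-Nichols model: per locus,
    ancestral frequencies p are drawn Dirichlet(1,...,1) and each population's
    frequencies Dirichlet(p (1-F)/F), so E[F_ST] = F; genotypes are drawn
    under within-population HWE. ``F = 0`` uses the ancestral frequencies
    directly in every population (the infinite-migration limit).

    When ``spec.null_freqs`` is set, each locus carries one additional,
    unobservable allele whose ancestral frequency is the requested null
    frequency and which drifts among populations like any other allele — the
    standard population-genetic null-allele model. Null/visible genotypes are
    recorded as apparent homozygotes and null/null genotypes as missing.

    Returns (dataset, truth) where truth records all generating values,
    including per-locus, per-population frequency vectors.
    """
    rng = np.random.default_rng(spec.seed)
    F = spec.target_fst
    pops = [f"pop{i + 1}" for i in range(spec.n_pops)]
    null = spec.null_freqs
    if null is not None and np.isscalar(null):
        null = [float(null)] * spec.n_loci
    n_states = spec.n_alleles + (1 if null is not None else 0)
    sizes = spec.base_size + spec.motif_length * np.arange(spec.n_alleles)
    pop_freqs = np.empty((spec.n_loci, spec.n_pops, n_states))
    for l in range(spec.n_loci):
        anc = rng.dirichlet(np.ones(spec.n_alleles))
        if null is not None:
            anc = np.append(anc * (1.0 - null[l]), null[l])
        if F == 0.0:
            pop_freqs[l] = np.tile(anc, (spec.n_pops, 1))
        else:
            conc = anc * (1.0 - F) / F
            pop_freqs[l] = rng.dirichlet(np.clip(conc, 1e-6, None), size=spec.n_pops)
    null_state = n_states - 1 if null is not None else -1
    individuals, populations, rows = [], {}, []
    for pi, pop in enumerate(pops):
        for i in range(spec.sample_sizes[pi]):
            ind = f"{pop}_{i + 1}"
            individuals.append(ind)
            populations[ind] = pop
            genos = np.empty((spec.n_loci, 2), dtype=np.int64)
            for l in range(spec.n_loci):
                idx = rng.choice(n_states, size=2, p=pop_freqs[l, pi])
                if null is not None:
                    if (idx == null_state).all():
                        genos[l] = MISSING
                        continue
                    if idx[0] == null_state:
                        idx[0] = idx[1]
                    elif idx[1] == null_state:
                        idx[1] = idx[0]
                genos[l] = sizes[idx]
            rows.append(genos)
    calls = np.stack(rows)
    if spec.missing_rate > 0:
        drop = rng.random((calls.shape[0], calls.shape[1])) < spec.missing_rate
        calls[drop] = MISSING
    loci = [LocusInfo(f"L{l + 1}", spec.motif_length) for l in range(spec.n_loci)]
    ds = GenotypeDataset(individuals, populations, loci, calls).with_recomputed_ranges()
    truth = {
        "target_fst": F,
        "n_migrants": np.inf if F == 0 else (1.0 - F) / (4.0 * F),
        "pop_freqs": pop_freqs,
        "allele_sizes": sizes,
        "spec": spec,
    }
    if null is not None:
        truth["null_freqs_by_pop"] = pop_freqs[:, :, null_state]
    return ds, truth


def inject_null_alleles(
    ds: GenotypeDataset,
    freqs: dict[str, float] | float,
    seed: int | None = None,
) -> tuple[GenotypeDataset, dict]:
    """Convert genes to null alleles at known per-locus frequencies.

    Each gene independently becomes null with its locus's frequency; a
    null/visible genotype is recorded as an apparent homozygote for the
    visible allele, null/null as a missing genotype. Returns (dataset, truth)
    with the per-locus frequencies and the boolean null mask.
    """
    if isinstance(freqs, (int, float)):
        freqs = {loc.id: float(freqs) for loc in ds.loci}
    for lid, f in freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"null frequency for {lid!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    calls = ds.calls.copy()
    null_mask = np.zeros(calls.shape, dtype=bool)
    for l, loc in enumerate(ds.loci):
        f = freqs.get(loc.id, 0.0)
        if f == 0.0:
            continue
        typed = calls[:, l, 0] != MISSING
        is_null = rng.random((calls.shape[0], 2)) < f
        is_null[~typed] = False
        null_mask[:, l, :] = is_null
        both = is_null.all(axis=1)
        calls[both, l, :] = MISSING
        only_a = is_null[:, 0] & ~is_null[:, 1]
        calls[only_a, l, 0] = calls[only_a, l, 1]
        only_b = is_null[:, 1] & ~is_null[:, 0]
        calls[only_b, l, 1] = calls[only_b, l, 0]
    out = GenotypeDataset(
        list(ds.individuals), dict(ds.populations), list(ds.loci), calls
    ).with_recomputed_ranges()
    return out, {"null_freqs": dict(freqs), "null_mask": null_mask}


def generate_run_ensemble(
    q_truth: np.ndarray,
    lnpd_profile: dict[int, float],
    n_runs: int = 10,
    q_noise: float = 0.0,
    lnpd_sd: float = 1.0,
    seed: int | None = None,
    minor_mode_q: np.ndarray | None = None,
    minor_count: int = 0,
) -> RunEnsemble:
    """Replicate clustering runs with label permutation and controlled noise.

    At the truth K (``q_truth.shape[1]``), ``n_runs - minor_count`` runs are
    noisy label-permuted copies of ``q_truth`` and ``minor_count`` of
    ``minor_mode_q``; at other K values in ``lnpd_profile`` runs carry
    uninformative Dirichlet Q. ``q_noise = 0`` reproduces the truth exactly
    (up to permutation); otherwise rows are resampled Dirichlet with
    concentration ``q / q_noise``. Log-likelihoods are Normal(profile mean,
    ``lnpd_sd``).
    """
    rng = np.random.default_rng(seed)
    k_truth = q_truth.shape[1]
    n = q_truth.shape[0]
    ens = RunEnsemble()
    for K, mean_lnpd in sorted(lnpd_profile.items()):
        for r in range(n_runs):
            lnpd = float(rng.normal(mean_lnpd, lnpd_sd))
            if K == k_truth:
                base = (
                    minor_mode_q
                    if (minor_mode_q is not None and r < minor_count)
                    else q_truth
                )
                q = base.copy()
                if q_noise > 0:
                    conc = np.clip(q / q_noise, 1e-3, None)
                    q = np.vstack([rng.dirichlet(c) for c in conc])
                perm = rng.permutation(K)
                q = q[:, perm]
            else:
                q = rng.dirichlet(np.ones(K) * 50.0, size=n)
            q = q / q.sum(axis=1, keepdims=True)
            ens.add(StructureRun(K, q, lnpd, lnpd, None, 0, 0))
    return ens


def generate_study_dataset(
    seed: int | None = None,
    scenario_name: str = "tunisia-lgm-from-spain",
    n_loci: int = STUDY_N_LOCI,
    null_freq: float = 0.05,
    missing_rate: float = 0.02,
    sampling: dict[str, int] | None = None,
    values: dict[str, float] | None = None,
) -> tuple[GenotypeDataset, dict]:
    """A study-shaped dataset simulated from one of the demographic scenarios.

    Six populations at the study sample sizes, ``n_loci`` microsatellites,
    null alleles injected at ``null_freq`` per locus, plus random missingness.
    By default the demography is pinned to :data:`~wintermoth_abc.scenarios.
    STUDY_DEMOGRAPHY` (the study-system point estimates); pass ``values`` to
    override any subset, or ``values={}`` for a fresh prior draw.
    Returns (dataset, truth) with the scenario, parameter draw and null truth.
    """
    rng = np.random.default_rng(seed)
    scen = {s.name: s for s in step2_scenarios()}[scenario_name]
    priors = priors_table()
    overrides = STUDY_DEMOGRAPHY if values is None else values
    draw = sample_for_scenario(
        scen, priors, rng, n_loci=n_loci, overrides=overrides
    )
    sampling = dict(sampling or STUDY_SAMPLING)
    ds = simulate_dataset(scen, draw, sampling, rng=rng)
    ds, null_truth = inject_null_alleles(
        ds, null_freq, seed=int(rng.integers(2**31))
    )
    if missing_rate > 0:
        calls = ds.calls.copy()
        drop = rng.random(calls.shape[:2]) < missing_rate
        calls[drop] = MISSING
        ds = GenotypeDataset(
            list(ds.individuals), dict(ds.populations), list(ds.loci), calls
        ).with_recomputed_ranges()
    return ds, {"scenario": scen, "draw": draw, **null_truth}
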