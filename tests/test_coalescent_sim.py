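"""Coalescent simulator: waiting times, mutation model, demography, priors."""

import numpy as np
import pytest
from scipy.stats import kstest

from wintermoth_abc.coalescent_sim import (
    Admixture,
    LocusModel,
    ParameterDraw,
    PriorDist,
    PriorSpec,
    Scenario,
    ScenarioError,
    SizeChange,
    Split,
    _simulate_genealogy,
    sample_parameters,
    simulate_dataset,
)
from wintermoth_abc.dataset import MISSING


def neutral_locus(mu=0.0, **kw):
    return LocusModel("L1", mu=mu, **kw)


class TestGenealogy:
    def test_pairwise_coalescence_time_is_2n(self):
        """E[T2] = 2N generations for two genes in a diploid population."""
        N = 1000.0
        sc = Scenario("one", {"A": N}, [])
        res = sc.resolve({})
        rng = np.random.default_rng(1)
        ts = np.empty(10_000)
        for i in range(ts.size):
            parent, node_time, leaves = _simulate_genealogy(res, {"A": 1}, rng)
            ts[i] = node_time[parent[leaves["A"][0]]]
        se = ts.std() / np.sqrt(ts.size)
        assert abs(ts.mean() - 2 * N) <= 3 * se

    def test_zero_mutation_rate_monomorphic(self):
        sc = Scenario("one", {"A": 500.0}, [])
        ds = simulate_dataset(
            sc, ParameterDraw({}), {"A": 10}, [neutral_locus(0.0)], rng=2
        )
        assert np.unique(ds.calls).size == 1

    def test_admixture_ra_one_routes_all_lineages(self):
        """With ra = 1 every target lineage goes to source A; an isolated
        source B would otherwise strand lineages and raise."""
        sc = Scenario(
            "adm",
            {"T": 100.0, "A": 100.0, "B": 100.0, "Root": 100.0},
            [
                Admixture(50.0, "T", "A", "B", 1.0),
                Split(500.0, "A", "Root"),
                # B never merges: any lineage sent there is stranded
            ],
        )
        ds = simulate_dataset(
            sc, ParameterDraw({}), {"T": 5, "A": 5}, [neutral_locus(1e-3)], rng=3
        )
        assert ds.n_individuals == 10
        sc_half = Scenario(
            "adm",
            {"T": 100.0, "A": 100.0, "B": 100.0, "Root": 100.0},
            [Admixture(50.0, "T", "A", "B", 0.5), Split(500.0, "A", "Root")],
        )
        with pytest.raises(ScenarioError, match="left in"):
            for seed in range(20):  # some lineage lands in B quickly
                simulate_dataset(
                    sc_half, ParameterDraw({}), {"T": 5, "A": 5},
                    [neutral_locus(1e-3)], rng=seed,
                )

    def test_nonpositive_size_rejected(self):
        sc = Scenario("bad", {"A": 0.0}, [])
        with pytest.raises(ScenarioError, match="nonpositive"):
            simulate_dataset(sc, ParameterDraw({}), {"A": 2}, [neutral_locus()], rng=0)

    def test_size_change_takes_effect(self):
        """A huge pastward size slows coalescence: mean depth grows."""
        rng = np.random.default_rng(8)
        small = Scenario("s", {"A": 100.0}, []).resolve({})
        big = Scenario(
            "b", {"A": 100.0}, [SizeChange(10.0, "A", 100_000.0)]
        ).resolve({})
        t_small = np.mean(
            [_simulate_genealogy(small, {"A": 1}, rng)[1].max() for _ in range(400)]
        )
        t_big = np.mean(
            [_simulate_genealogy(big, {"A": 1}, rng)[1].max() for _ in range(400)]
        )
        assert t_big > 10 * t_small

    def test_smm_within_population_size_variance(self):
        """Strict stepwise model: E[allele-size variance] ~ 2 N mu
        (theta/2 in squared repeat units)."""
        N, mu = 2500.0, 1e-3
        sc = Scenario("one", {"A": N}, [])
        locus = LocusModel("L1", mu=mu, p_gsm=0.0, range_width=400, motif_length=2)
        rng = np.random.default_rng(11)
        vs = np.empty(2000)
        for i in range(vs.size):
            ds = simulate_dataset(sc, ParameterDraw({}), {"A": 5}, [locus], rng=rng)
            units = ds.calls[:, 0, :].ravel() / 2.0
            vs[i] = units.var(ddof=1)
        se = vs.std() / np.sqrt(vs.size)
        assert abs(vs.mean() - 2 * N * mu) <= 3 * se

    def test_exchangeability_of_sampled_individuals(self):
        """Permuting individuals leaves summary distributions unchanged."""
        from wintermoth_abc.summary_stats import stat_vector

        sc = Scenario(
            "two", {"A": 500.0, "B": 500.0, "R": 500.0},
            [Split(1000.0, "A", "R"), Split(1000.0, "B", "R")],
        )
        loci = [LocusModel(f"L{i}", mu=5e-4) for i in range(4)]
        ds = simulate_dataset(sc, ParameterDraw({}), {"A": 8, "B": 8}, loci, rng=5)
        sv = stat_vector(ds)
        perm = np.random.default_rng(0).permutation(ds.n_individuals)
        sv2 = stat_vector(ds.take_individuals(perm))
        assert np.allclose(sv.to_numpy(), sv2.to_numpy())


class TestMutationModel:
    def test_states_confined_to_window(self):
        locus = LocusModel("L1", mu=0.05, p_gsm=0.7, range_width=10, root_size=200)
        sc = Scenario("one", {"A": 2000.0}, [])
        ds = simulate_dataset(sc, ParameterDraw({}), {"A": 20}, [locus], rng=6)
        steps = (ds.calls - 200) / 2
        assert steps.min() >= -(10 // 2) - 1  # -1 bp SNI slack
        assert steps.max() <= (10 - 1 - 10 // 2) + 1

    def test_sni_produces_off_ladder_alleles(self):
        locus = LocusModel(
            "L1", mu=1e-4, sni_rate=5e-3, motif_length=2, root_size=200
        )
        sc = Scenario("one", {"A": 5000.0}, [])
        ds = simulate_dataset(sc, ParameterDraw({}), {"A": 30}, [locus], rng=7)
        assert (ds.calls % 2 == 1).any()

    def test_cross_check_against_msprime_tree_length(self):
        """Independent oracle: mean total branch length of the standard
        coalescent matches msprime for the same sample size and N."""
        msprime = pytest.importorskip("msprime")
        N, n = 1000.0, 10
        rng = np.random.default_rng(12)
        sc = Scenario("one", {"A": N}, []).resolve({})
        mine = np.empty(1500)
        for i in range(mine.size):
            parent, node_time, _ = _simulate_genealogy(sc, {"A": n // 2}, rng)
            lengths = node_time[parent[parent >= 0]] - node_time[parent >= 0]
            mine[i] = lengths.sum()
        theirs = np.empty(1500)
        reps = msprime.sim_ancestry(
            samples=n // 2, population_size=N, ploidy=2,
            num_replicates=theirs.size, random_seed=13,
        )
        for i, ts in enumerate(reps):
            theirs[i] = ts.first().total_branch_length
        se = np.sqrt(mine.var() / mine.size + theirs.var() / theirs.size)
        assert abs(mine.mean() - theirs.mean()) <= 3 * se


class TestPriors:
    def test_bounds_respected(self):
        spec = PriorSpec(
            params={
                "tTunisia": PriorDist("tTunisia", 5_000, 20_000),
                "ra": PriorDist("ra", 0.001, 0.999),
            }
        )
        rng = np.random.default_rng(1)
        for _ in range(500):
            d = sample_parameters(spec, rng)
            assert 5_000 <= d.values["tTunisia"] <= 20_000
            assert 0.001 <= d.values["ra"] <= 0.999

    def test_uniform_prior_ks(self):
        spec = PriorSpec(params={"x": PriorDist("x", 2.0, 7.0)})
        rng = np.random.default_rng(2)
        draws = np.array(
            [sample_parameters(spec, rng).values["x"] for _ in range(5000)]
        )
        assert kstest((draws - 2.0) / 5.0, "uniform").pvalue > 0.01

    def test_ordering_constraints_enforced(self):
        spec = PriorSpec(
            params={
                "a": PriorDist("a", 0.0, 10.0),
                "b": PriorDist("b", 0.0, 10.0),
            },
            constraints=[("a", "b")],
        )
        rng = np.random.default_rng(3)
        for _ in range(200):
            d = sample_parameters(spec, rng)
            assert d.values["a"] < d.values["b"]

    def test_infeasible_constraints_raise(self):
        spec = PriorSpec(
            params={
                "a": PriorDist("a", 9.0, 10.0),
                "b": PriorDist("b", 0.0, 1.0),
            },
            constraints=[("a", "b")],
        )
        with pytest.raises(ValueError, match="infeasible"):
            sample_parameters(spec, np.random.default_rng(4), max_rejects=2000)

    def test_cyclic_constraints_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PriorSpec(
                params={
                    "a": PriorDist("a", 0, 1),
                    "b": PriorDist("b", 0, 1),
                },
                constraints=[("a", "b"), ("b", "a")],
            )

    def test_per_locus_models_within_bounds(self):
        spec = PriorSpec(
            params={
                "mean_mu": PriorDist("mean_mu", 1e-5, 1e-4),
                "mean_p": PriorDist("mean_p", 0.1, 1.0),
                "mean_sni": PriorDist("mean_sni", 1e-8, 1e-5, "loguniform"),
            }
        )
        rng = np.random.default_rng(5)
        d = sample_parameters(spec, rng, n_loci=20)
        assert len(d.locus_models) == 20
        lo, hi = spec.locus_bounds["mu"]
        for m in d.locus_models:
            assert lo <= m.mu <= hi
            assert 0.0 <= m.p_gsm <= 0.999
            assert m.sni_rate >= 0.0
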