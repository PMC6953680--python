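"""ABC engine: rejection, logistic scenario choice, regression adjustment,
model checking, and scenario-choice error."""

import numpy as np
import pandas as pd
import pytest

from wintermoth_abc import abc_engine as abc
from wintermoth_abc.abc_engine import (
    ReferenceTable,
    _mad_norm,
    build_reference_table,
    estimate_parameters,
    model_check_pca,
    rejection_sample,
    scenario_choice_error,
    scenario_posterior_logistic,
)
from wintermoth_abc.coalescent_sim import PriorDist, PriorSpec


@pytest.fixture(scope="module")
def toy_ref(toy_scenarios, toy_priors, toy_sampling):
    return build_reference_table(
        toy_scenarios, toy_priors, 150, toy_sampling, 8, seed=11
    )


def synthetic_table(n, k_stats=3, k_params=1, seed=0, scenario="s1", link=None):
    """Reference table from an explicit linear model (no coalescent)."""
    rng = np.random.default_rng(seed)
    params = rng.uniform(0.0, 1.0, size=(n, k_params))
    stats = rng.normal(size=(n, k_stats)) * 0.1
    if link is not None:
        stats = stats + link(params)
    df = pd.DataFrame({"scenario": [scenario] * n})
    pnames = [f"theta{j}" for j in range(k_params)]
    snames = [f"s{j}" for j in range(k_stats)]
    for j, p in enumerate(pnames):
        df[f"param:{p}"] = params[:, j]
    for j, s in enumerate(snames):
        df[f"stat:{s}"] = stats[:, j]
    return ReferenceTable(df, snames, pnames, _mad_norm(df, snames))


class TestReferenceTable:
    def test_row_count(self, toy_ref):
        assert toy_ref.n_rows == 300
        assert (toy_ref.data["scenario"].value_counts() == 150).all()

    def test_determinism(self, toy_ref, toy_scenarios, toy_priors, toy_sampling):
        again = build_reference_table(
            toy_scenarios, toy_priors, 150, toy_sampling, 8, seed=11
        )
        pd.testing.assert_frame_equal(toy_ref.data, again.data)

    def test_chunking_consistency(self, toy_ref, toy_scenarios, toy_priors, toy_sampling):
        """Per-replicate seed substreams: a smaller build reproduces the
        first rows of a larger one, so chunked builds are resumable."""
        small = build_reference_table(
            toy_scenarios, toy_priors, 40, toy_sampling, 8, seed=11
        )
        for scen in ("recent", "ancient"):
            a = small.data[small.data["scenario"] == scen].reset_index(drop=True)
            b = (
                toy_ref.data[toy_ref.data["scenario"] == scen]
                .head(40)
                .reset_index(drop=True)
            )
            pd.testing.assert_frame_equal(a, b)

    def test_scenario_means_stable_across_seeds(self, toy_scenarios, toy_priors, toy_sampling):
        r1 = build_reference_table(toy_scenarios, toy_priors, 120, toy_sampling, 6, seed=1)
        r2 = build_reference_table(toy_scenarios, toy_priors, 120, toy_sampling, 6, seed=2)
        for scen in ("recent", "ancient"):
            for s in ["het_A", "nal_A"]:
                x1 = r1.data.loc[r1.data.scenario == scen, f"stat:{s}"]
                x2 = r2.data.loc[r2.data.scenario == scen, f"stat:{s}"]
                se = np.sqrt(x1.var() / len(x1) + x2.var() / len(x2))
                assert abs(x1.mean() - x2.mean()) <= 4 * se


class TestRejection:
    def test_exact_count_and_zero_distance(self):
        ref = synthetic_table(10_000, seed=1)
        observed = pd.Series(
            {s: ref.data[f"stat:{s}"].iloc[123] for s in ref.stat_names}
        )
        res = rejection_sample(ref, observed, fraction=0.01)
        assert len(res.retained) == 100
        assert res.indices[0] == 123
        assert res.distances[0] == 0.0

    def test_affine_rescaling_leaves_retained_set(self):
        ref = synthetic_table(2000, seed=2)
        observed = pd.Series({s: 0.05 for s in ref.stat_names})
        base = rejection_sample(ref, observed, 0.02).indices
        df = ref.data.copy()
        df["stat:s0"] = 7.0 * df["stat:s0"] - 3.0
        ref2 = ReferenceTable(df, ref.stat_names, ref.param_names, _mad_norm(df, ref.stat_names))
        obs2 = observed.copy()
        obs2["s0"] = 7.0 * obs2["s0"] - 3.0
        assert np.array_equal(rejection_sample(ref2, obs2, 0.02).indices, base)

    def test_zero_mad_statistic_dropped(self):
        ref = synthetic_table(500, seed=3)
        df = ref.data.copy()
        df["stat:s0"] = 1.0
        ref2 = ReferenceTable(df, ref.stat_names, ref.param_names, _mad_norm(df, ref.stat_names))
        observed = pd.Series({s: 0.0 for s in ref.stat_names})
        with pytest.warns(UserWarning, match="zero-MAD"):
            res = rejection_sample(ref2, observed, 0.05)
        assert "s0" not in res.kept_stats

    def test_bad_fraction(self, toy_ref):
        observed = pd.Series({s: 0.0 for s in toy_ref.stat_names})
        with pytest.raises(ValueError, match="fraction"):
            rejection_sample(toy_ref, observed, 0.0)


class TestScenarioChoice:
    def test_twin_scenarios_give_half_half(self):
        """Two scenarios with identical generative distributions."""
        rng = np.random.default_rng(4)
        half = synthetic_table(1500, seed=5, scenario="a").data
        other = synthetic_table(1500, seed=6, scenario="b").data
        df = pd.concat([half, other], ignore_index=True)
        snames = [c[5:] for c in df.columns if c.startswith("stat:")]
        ref = ReferenceTable(df, snames, ["theta0"], _mad_norm(df, snames))
        observed = pd.Series({s: 0.0 for s in snames})
        probs = scenario_posterior_logistic(ref, observed, fraction=0.1)
        assert sum(probs.values()) == pytest.approx(1.0)
        assert probs["a"] == pytest.approx(0.5, abs=0.1)
        del rng

    def test_separable_clouds(self):
        a = synthetic_table(800, seed=7, scenario="a").data
        b = synthetic_table(800, seed=8, scenario="b").data
        for c in [c for c in b.columns if c.startswith("stat:")]:
            b[c] += 25.0
        df = pd.concat([a, b], ignore_index=True)
        snames = [c[5:] for c in df.columns if c.startswith("stat:")]
        ref = ReferenceTable(df, snames, ["theta0"], _mad_norm(df, snames))
        observed = pd.Series({s: 0.0 for s in snames})  # deep inside cloud a
        probs = scenario_posterior_logistic(ref, observed, fraction=0.05)
        assert probs["a"] >= 0.99

    def test_recovers_generating_scenario(self, toy_ref, toy_scenarios, toy_priors, toy_sampling):
        rng = np.random.default_rng(5)
        _, sv = abc.simulate_stat_row(
            toy_scenarios[1], toy_priors, toy_sampling, 8, rng
        )
        probs = scenario_posterior_logistic(toy_ref, sv, fraction=0.1)
        assert probs["ancient"] > 0.9


class TestParameterEstimation:
    def test_zero_slopes_equal_rejection_quantiles(self):
        """Statistics independent of the parameter: adjustment is a no-op."""
        ref = synthetic_table(3000, seed=9, link=None)
        observed = pd.Series({s: 0.0 for s in ref.stat_names})
        post = estimate_parameters(ref, observed, fraction=0.1)
        rej = rejection_sample(ref, observed, 0.1)
        y = rej.retained["param:theta0"].to_numpy()
        w = abc._epanechnikov(rej.distances)
        assert post.table.loc["theta0", "mean"] == pytest.approx(
            np.average(y, weights=w), abs=0.05
        )

    def test_adjustment_beats_rejection_on_linear_model(self):
        """stat = param + noise: regression adjustment shrinks the error."""
        errs_adj, errs_rej = [], []
        for trial in range(60):
            rng = np.random.default_rng(100 + trial)
            truth = rng.uniform(0.2, 0.8)
            ref = synthetic_table(
                1500, seed=200 + trial,
                link=lambda p: np.repeat(p, 3, axis=1),
            )
            observed = pd.Series({s: truth for s in ref.stat_names})
            post = estimate_parameters(ref, observed, fraction=0.1)
            rej = rejection_sample(ref, observed, 0.1)
            w = abc._epanechnikov(rej.distances)
            rej_mean = np.average(rej.retained["param:theta0"], weights=w)
            errs_adj.append((post.table.loc["theta0", "mean"] - truth) ** 2)
            errs_rej.append((rej_mean - truth) ** 2)
        assert np.mean(errs_adj) < np.mean(errs_rej)

    def test_ci_within_prior_support_and_ordered(self, toy_ref, toy_priors):
        observed = pd.Series(
            {s: toy_ref.data[f"stat:{s}"].median() for s in toy_ref.stat_names}
        )
        post = estimate_parameters(
            toy_ref.restrict_to("ancient"), observed, 0.2, priors=toy_priors
        )
        for p, row in post.table.iterrows():
            lo, hi = toy_priors.params[p].minimum, toy_priors.params[p].maximum
            assert lo <= row["ci_low"] <= row["median"] <= row["ci_high"] <= hi


class TestModelCheck:
    def test_coordinates_invariant_to_stat_ordering(self):
        ref = synthetic_table(400, seed=10)
        pred = pd.DataFrame(
            np.random.default_rng(0).normal(size=(50, 3)) * 0.1,
            columns=ref.stat_names,
        )
        observed = pd.Series({s: 0.0 for s in ref.stat_names})
        r1 = model_check_pca(ref, pred, observed)
        shuffled = list(reversed(ref.stat_names))
        df = ref.data.copy()
        ref2 = ReferenceTable(df, shuffled, ref.param_names, ref.norm)
        r2 = model_check_pca(ref2, pred[shuffled], observed)
        assert r1.within_cloud == r2.within_cloud
        assert r1.mahalanobis == pytest.approx(r2.mahalanobis, rel=1e-6)

    def test_outlier_flagged_outside_cloud(self):
        ref = synthetic_table(400, seed=11)
        pred = pd.DataFrame(
            np.random.default_rng(1).normal(size=(60, 3)) * 0.1,
            columns=ref.stat_names,
        )
        inside = pd.Series({s: 0.0 for s in ref.stat_names})
        assert model_check_pca(ref, pred, inside).within_cloud
        outside = pd.Series(
            {s: 10 * max(ref.norm[s][1], 0.1) + 5 for s in ref.stat_names}
        )
        assert not model_check_pca(ref, pred, outside).within_cloud


class TestScenarioChoiceError:
    def test_separable_scenarios_low_error(self, toy_scenarios, toy_priors, toy_sampling):
        ref = build_reference_table(
            toy_scenarios, toy_priors, 120, toy_sampling, 8, seed=21
        )
        res = scenario_choice_error(
            toy_scenarios, toy_priors, ref, toy_sampling, 8,
            n_pods=12, fraction=0.1, seed=22,
        )
        assert res["error_rate"] <= 0.15

    def test_twin_scenarios_near_half(self, toy_priors, toy_sampling):
        from conftest import make_toy_split_scenario

        twins = [
            make_toy_split_scenario("twin1", 5000.0),
            make_toy_split_scenario("twin2", 5000.0),
        ]
        ref = build_reference_table(twins, toy_priors, 120, toy_sampling, 6, seed=23)
        res = scenario_choice_error(
            twins, toy_priors, ref, toy_sampling, 6,
            n_pods=15, fraction=0.1, seed=24,
        )
        assert res["error_rate"] == pytest.approx(0.5, abs=0.25)
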