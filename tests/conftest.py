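"""Shared fixtures: small synthetic datasets and toy demographies."""

from __future__ import annotations

import numpy as np
import pytest

from wintermoth_abc.coalescent_sim import PriorDist, PriorSpec, Scenario, Split
from wintermoth_abc.synthetic_data import SyntheticSpec, generate_island_dataset


@pytest.fixture(scope="session")
def island_ds():
    """6-pop, 24-locus island dataset at F_ST 0.15 with some missingness."""
    spec = SyntheticSpec(target_fst=0.15, missing_rate=0.03, seed=42)
    ds, truth = generate_island_dataset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def two_pop_ds():
    """Two well-differentiated populations (F_ST ~ 0.2), no missingness."""
    spec = SyntheticSpec(
        n_pops=2, sample_sizes=[30, 30], n_loci=12, target_fst=0.2, seed=7
    )
    ds, truth = generate_island_dataset(spec)
    return ds, truth


def make_toy_split_scenario(name: str, t: float) -> Scenario:
    """Two populations splitting from an ancestor at time t."""
    return Scenario(
        name,
        {"A": "NA_", "B": "NB_", "Anc": "NAnc_"},
        [Split(t, "A", "Anc"), Split(t, "B", "Anc")],
    )


@pytest.fixture(scope="session")
def toy_priors() -> PriorSpec:
    return PriorSpec(
        params={
            "NA_": PriorDist("NA_", 500, 5000),
            "NB_": PriorDist("NB_", 500, 5000),
            "NAnc_": PriorDist("NAnc_", 500, 5000),
            "mean_mu": PriorDist("mean_mu", 1e-4, 1e-3),
            "mean_p": PriorDist("mean_p", 0.1, 0.5),
            "mean_sni": PriorDist("mean_sni", 1e-8, 1e-7, "loguniform"),
        }
    )


@pytest.fixture(scope="session")
def toy_scenarios():
    return [
        make_toy_split_scenario("recent", 200.0),
        make_toy_split_scenario("ancient", 20_000.0),
    ]


@pytest.fixture(scope="session")
def toy_sampling():
    return {"A": 15, "B": 15}
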