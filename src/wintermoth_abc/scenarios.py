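"""Concrete demographic scenarios and priors for winter-moth phylogeography.

The study populations are Georgia (Tbilisi), Germany, Italy (Orti), Serbia,
Spain and Tunisia (Mzara Forest). The backbone tree has the Spanish lineage
diverging before the Serbian-Georgian split, with the German population formed
by admixture between the Spanish and Serbian lineages after the LGM.

Two scenario sets mirror the two-step analysis:

* **Step 1** (3 scenarios): where does the southern-Italian population attach —
  to the Spanish, Serbian or Georgian branch?
* **Step 2** (9 scenarios): given the step-1 winner, the Tunisian population
  either diverged from Spain/Italy/Serbia/Georgia around the LGM (4 scenarios,
  time ``tTunisia``), or was established recently from Spain/Italy/Serbia/
  Georgia/Germany (5 scenarios, time ``tRecentIntro``) with an extra
  founding-bottleneck size parameter active for ``tBottleneck`` years after
  establishment.

An optional "out-of-Africa" set encodes the discarded alternative in which
Tunisia is the source of the Spanish and Italian populations.

All priors are uniform over their bounds (log-uniform for the SNI rate);
ordering constraints are attached per scenario and enforced by rejection.
"""

from __future__ import annotations

import numpy as np

from .coalescent_sim import (
    Admixture,
    ParameterDraw,
    PriorDist,
    PriorSpec,
    Scenario,
    SizeChange,
    Split,
    sample_parameters,
)

POPULATIONS = ["Georgia", "Germany", "Italy", "Serbia", "Spain", "Tunisia"]

#: Diploid sample sizes of the study dataset (individuals per population).
STUDY_SAMPLING = {
    "Georgia": 28,
    "Germany": 30,
    "Italy": 26,
    "Serbia": 30,
    "Spain": 30,
    "Tunisia": 17,
}

STUDY_N_LOCI = 24
ABC_N_LOCI = 20  # after removing the four widest-range loci

#: Point demography used as the default truth when emulating the study
#: system: the inferred LGM divergence of Tunisia from the Spanish lineage,
#: with sizes/times at their posterior point estimates. The two deepest merge
#: times overlap in the inference; t4 is placed above t3 (within its
#: credible range) so the event ordering is strict.
STUDY_DEMOGRAPHY = {
    "NGeorgia": 49_800.0,
    "NGermany": 491_000.0,
    "NItaly": 164_000.0,
    "NSerbia": 332_000.0,
    "NSpain": 49_800.0,
    "NTunisia": 23_300.0,
    "NE3a": 26_700.0,
    "NE3b": 64_000.0,
    "NE1": 32_600.0,
    "t1": 8_900.0,
    "tTunisia": 16_200.0,
    "t2": 26_600.0,
    "t3": 35_000.0,
    "t4": 40_000.0,
    "ra": 0.746,
    "mean_mu": 3.16e-5,
    "mean_p": 0.457,
    "mean_sni": 2.65e-7,
}


def priors_table() -> PriorSpec:
    """The demographic/mutational prior table (min/max bounds, uniform).

    Sizes are diploid effective sizes; times are years (generation time 1 for
    the univoltine winter moth); ``ra`` is the admixture proportion
    contributed by the Spanish lineage to Germany. ``NBottleneck`` is the
    founding size of contemporary-introduction scenarios.
    """
    u = PriorDist
    params = {
        "NGeorgia": u("NGeorgia", 10_000, 500_000),
        "NGermany": u("NGermany", 10_000, 1_000_000),
        "NItaly": u("NItaly", 10_000, 500_000),
        "NSerbia": u("NSerbia", 10_000, 1_000_000),
        "NSpain": u("NSpain", 10_000, 500_000),
        "NTunisia": u("NTunisia", 10_000, 500_000),
        "NE3a": u("NE3a", 10_000, 100_000),
        "NE3b": u("NE3b", 10_000, 100_000),
        "NE1": u("NE1", 10_000, 100_000),
        "NBottleneck": u("NBottleneck", 10, 10_000),
        "tBottleneck": u("tBottleneck", 10, 200),
        "tRecentIntro": u("tRecentIntro", 1_000, 10_000),
        "t1": u("t1", 1_000, 15_000),
        "tTunisia": u("tTunisia", 5_000, 20_000),
        "t2": u("t2", 10_000, 30_000),
        "t3": u("t3", 20_000, 40_000),
        "t4": u("t4", 20_000, 50_000),
        "ra": u("ra", 0.001, 0.999),
        "mean_mu": u("mean_mu", 1e-5, 1e-4),
        "mean_p": u("mean_p", 0.1, 1.0),
        "mean_sni": u("mean_sni", 1e-8, 1e-5, "loguniform"),
    }
    return PriorSpec(params=params)


_BASE_SIZES = {
    "Georgia": "NGeorgia",
    "Germany": "NGermany",
    "Serbia": "NSerbia",
    "Spain": "NSpain",
    "AncSG": "NE3a",
    "Root": "NE1",
}

# Backbone events: Germany is an admixture of the Spanish (weight ra) and
# Serbian lineages at t1; Georgia and Serbia merge at t2 into AncSG.
_BASE_EVENTS = [
    Admixture("t1", "Germany", "Spain", "Serbia", "ra"),
    Split("t2", "Georgia", "AncSG"),
    Split("t2", "Serbia", "AncSG"),
]


def root_tree_scenario() -> Scenario:
    """Four-population backbone: Spain diverges before the Serbia-Georgia split.

    Root merge (Spain + AncSG) at ``t3`` into ``Root`` (size NE1); constraints
    enforce t1 < t2 < t3.
    """
    events = _BASE_EVENTS + [
        Split("t3", "Spain", "Root"),
        Split("t3", "AncSG", "Root"),
    ]
    return Scenario(
        name="root-tree",
        sizes=dict(_BASE_SIZES),
        events=events,
        constraints=[("t1", "t2"), ("t2", "t3")],
    )


def step1_scenarios() -> list[Scenario]:
    """Three scenarios differing only in where Italy attaches.

    Italy diverges at ``t3`` from the Spanish branch (through an ancestor of
    size NE3b), or merges into the Serbian or Georgian branch before the
    Serbia-Georgia split (t3 < t2 there); the root merge is at ``t4``.
    """
    out = []
    # Italy from the Spanish branch
    sizes = dict(_BASE_SIZES) | {"Italy": "NItaly", "AncSI": "NE3b"}
    events = _BASE_EVENTS + [
        Split("t3", "Italy", "AncSI"),
        Split("t3", "Spain", "AncSI"),
        Split("t4", "AncSI", "Root"),
        Split("t4", "AncSG", "Root"),
    ]
    out.append(
        Scenario(
            "italy-from-spain",
            sizes,
            events,
            constraints=[("t1", "t2"), ("t2", "t3"), ("t3", "t4")],
        )
    )
    for src in ("Serbia", "Georgia"):
        sizes = dict(_BASE_SIZES) | {"Italy": "NItaly"}
        events = [Split("t3", "Italy", src)] + _BASE_EVENTS + [
            Split("t4", "Spain", "Root"),
            Split("t4", "AncSG", "Root"),
        ]
        out.append(
            Scenario(
                f"italy-from-{src.lower()}",
                sizes,
                events,
                constraints=[("t1", "t3"), ("t3", "t2"), ("t2", "t4")],
            )
        )
    return out


def _winner_base() -> tuple[dict, list]:
    """Sizes/events of the step-1 winning topology (Italy from Spain)."""
    sizes = dict(_BASE_SIZES) | {"Italy": "NItaly", "AncSI": "NE3b"}
    events = _BASE_EVENTS + [
        Split("t3", "Italy", "AncSI"),
        Split("t3", "Spain", "AncSI"),
        Split("t4", "AncSI", "Root"),
        Split("t4", "AncSG", "Root"),
    ]
    return sizes, events


def step2_scenarios(step1_winner: Scenario | None = None) -> list[Scenario]:
    """Nine scenarios for the origin of the Tunisian population.

    Four LGM-divergence scenarios (from Spain, Italy, Serbia, Georgia at
    ``tTunisia``) and five contemporary-establishment scenarios (from Spain,
    Italy, Serbia, Georgia, Germany at ``tRecentIntro``), the latter with a
    founding bottleneck of size ``NBottleneck`` lasting ``tBottleneck`` years
    after establishment.

    ``step1_winner`` must be the Italy-from-Spain topology when given;
    alternative winners are not encoded.
    """
    if step1_winner is not None and step1_winner.name != "italy-from-spain":
        raise ValueError(
            f"step-2 scenarios are encoded for the Italy-from-Spain backbone, "
            f"got {step1_winner.name!r}"
        )
    base_constraints = [("t1", "t2"), ("t2", "t3"), ("t3", "t4")]
    out = []
    lgm_limits = {"Spain": "t3", "Italy": "t3", "Serbia": "t2", "Georgia": "t2"}
    for src, limit in lgm_limits.items():
        sizes, events = _winner_base()
        sizes["Tunisia"] = "NTunisia"
        events = [Split("tTunisia", "Tunisia", src)] + events
        out.append(
            Scenario(
                f"tunisia-lgm-from-{src.lower()}",
                sizes,
                events,
                constraints=base_constraints + [("tTunisia", limit)],
            )
        )
    recent_limits = {
        "Spain": "t3",
        "Italy": "t3",
        "Serbia": "t2",
        "Georgia": "t2",
        "Germany": "t1",
    }
    for src, limit in recent_limits.items():
        sizes, events = _winner_base()
        sizes["Tunisia"] = "NTunisia"
        events = [
            SizeChange("tRecentIntro - tBottleneck", "Tunisia", "NBottleneck"),
            Split("tRecentIntro", "Tunisia", src),
        ] + events
        out.append(
            Scenario(
                f"tunisia-recent-from-{src.lower()}",
                sizes,
                events,
                constraints=base_constraints + [("tRecentIntro", limit)],
            )
        )
    return out


def out_of_africa_scenarios() -> list[Scenario]:
    """Alternative set with Tunisia as the source of Spain and Italy.

    Synthetic stand-ins for the three discarded reverse-direction scenarios
    (not shown in the source study's figures): Tunisia is ancestral in the
    west, with Spain and/or Italy budding off it, and joins the Serbian/
    Georgian lineage at the root.
    """
    base_constraints = [("t1", "t2"), ("t2", "t4")]
    scen = []
    # (a) both Spain and Italy bud off Tunisia
    sizes = dict(_BASE_SIZES) | {"Italy": "NItaly", "Tunisia": "NTunisia"}
    events = [
        Split("tTunisia", "Italy", "Tunisia"),
        Split("t3", "Spain", "Tunisia"),
    ] + [
        Admixture("t1", "Germany", "Spain", "Serbia", "ra"),
        Split("t2", "Georgia", "AncSG"),
        Split("t2", "Serbia", "AncSG"),
        Split("t4", "Tunisia", "Root"),
        Split("t4", "AncSG", "Root"),
    ]
    scen.append(
        Scenario(
            "ooa-both-from-tunisia",
            sizes,
            events,
            constraints=base_constraints + [("t1", "tTunisia"), ("t3", "t4")],
        )
    )
    # (b) Spain from Tunisia, Italy from Spain
    sizes = dict(_BASE_SIZES) | {"Italy": "NItaly", "Tunisia": "NTunisia"}
    events = [
        Split("tTunisia", "Italy", "Spain"),
        Split("t3", "Spain", "Tunisia"),
        Admixture("t1", "Germany", "Spain", "Serbia", "ra"),
        Split("t2", "Georgia", "AncSG"),
        Split("t2", "Serbia", "AncSG"),
        Split("t4", "Tunisia", "Root"),
        Split("t4", "AncSG", "Root"),
    ]
    scen.append(
        Scenario(
            "ooa-spain-from-tunisia",
            sizes,
            events,
            constraints=base_constraints
            + [("t1", "tTunisia"), ("tTunisia", "t3"), ("t3", "t4")],
        )
    )
    # (c) Italy from Tunisia, Spain diverging at the root as in the backbone
    sizes = dict(_BASE_SIZES) | {"Italy": "NItaly", "Tunisia": "NTunisia"}
    events = [
        Split("tTunisia", "Italy", "Tunisia"),
        Admixture("t1", "Germany", "Spain", "Serbia", "ra"),
        Split("t2", "Georgia", "AncSG"),
        Split("t2", "Serbia", "AncSG"),
        Split("t3", "Spain", "Root"),
        Split("t3", "AncSG", "Root"),
        Split("t4", "Tunisia", "Root"),
    ]
    scen.append(
        Scenario(
            "ooa-italy-from-tunisia",
            sizes,
            events,
            constraints=base_constraints
            + [("t1", "tTunisia"), ("t2", "t3"), ("t3", "t4")],
        )
    )
    return scen


def check_scenario_parameters(
    scenarios: list[Scenario], priors: PriorSpec
) -> None:
    """Refuse to simulate if a scenario uses a parameter absent from the priors."""
    known = set(priors.params)
    for sc in scenarios:
        missing = sc.parameter_names() - known
        if missing:
            raise ValueError(
                f"scenario {sc.name!r} uses parameters with no prior: {sorted(missing)}"
            )


def sample_for_scenario(
    scenario: Scenario,
    priors: PriorSpec,
    rng: np.random.Generator,
    n_loci: int = ABC_N_LOCI,
    **kwargs,
) -> ParameterDraw:
    """Draw parameters honouring the scenario's own ordering constraints."""
    check_scenario_parameters([scenario], priors)
    spec = PriorSpec(
        params=priors.params,
        constraints=list(scenario.constraints),
        mean_mu=priors.mean_mu,
        mean_p=priors.mean_p,
        mean_sni=priors.mean_sni,
        locus_bounds=priors.locus_bounds,
    )
    return sample_parameters(spec, rng, n_loci=n_loci, **kwargs)
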