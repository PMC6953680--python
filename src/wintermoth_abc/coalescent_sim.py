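"""Backward-in-time coalescent simulation of diploid microsatellites.

Demographies are declared as a set of named populations with (symbolic)
diploid effective sizes and an ordered backward-time event list:

* ``Split(time, derived, parent)`` — looking back, every lineage in
  ``derived`` moves into ``parent`` (forward in time: ``derived`` budded off
  ``parent`` at that time);
* ``Admixture(time, target, source_a, source_b, proportion)`` — each lineage
  in ``target`` independently moves to ``source_a`` with the admixture
  proportion, else to ``source_b``;
* ``SizeChange(time, population, size)`` — the population's effective size
  switches to ``size`` pastward of the event.

Between events each active population coalesces independently at rate
k(k-1)/(4N) per generation for k gene lineages (continuous time,
piecewise-constant rates). Event times are given in years and converted with
``generation_time`` (1 year for the univoltine winter moth).

Mutation follows the generalized stepwise model (GSM) with single-nucleotide
indels (SNI): along a branch of length L the number of events is
Poisson((mu + s) L); each event is an SNI (allele size +-1 bp, off the repeat
ladder) with probability s/(mu+s), otherwise a repeat-ladder step of k motif
units with k geometric (mean 1/(1-P)) and random sign. Ladder states are
confined to a contiguous window of R states centred on the root allele;
out-of-window steps are redrawn.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .dataset import GenotypeDataset, LocusInfo

# ---------------------------------------------------------------------------
# Demography declaration
# ---------------------------------------------------------------------------

Param = str | float


@dataclass(frozen=True)
class Split:
    time: Param
    derived: str
    parent: str


@dataclass(frozen=True)
class Admixture:
    time: Param
    target: str
    source_a: str
    source_b: str
    proportion: Param


@dataclass(frozen=True)
class SizeChange:
    time: Param
    population: str
    size: Param


Event = Split | Admixture | SizeChange


class ScenarioError(ValueError):
    """Raised when a demographic scenario is inconsistent."""


@dataclass
class Scenario:
    """A demographic scenario over named populations.

    ``sizes`` maps every population (sampled leaves and ancestors) to a
    diploid effective size — a number or the name of a prior parameter.
    ``events`` are interpreted backward in time; their resolved times must
    leave all lineages in a single population at the root. Symbolic values may
    be simple arithmetic expressions over parameter names (e.g.
    ``"tRecentIntro - tBottleneck"``). ``constraints`` lists (smaller, larger)
    parameter-name pairs that accepted prior draws must satisfy.
    """

    name: str
    sizes: dict[str, Param]
    events: list[Event]
    generation_time: float = 1.0
    constraints: list[tuple[str, str]] = field(default_factory=list)

    def parameter_names(self) -> set[str]:
        names: set[str] = set()

        def add(p: Param) -> None:
            if isinstance(p, str):
                names.update(re.findall(r"[A-Za-z_]\w*", p))

        for v in self.sizes.values():
            add(v)
        for ev in self.events:
            add(ev.time)
            if isinstance(ev, Admixture):
                add(ev.proportion)
            if isinstance(ev, SizeChange):
                add(ev.size)
        return names

    def resolve(self, values: dict[str, float]) -> "_ResolvedScenario":
        def val(p: Param) -> float:
            if isinstance(p, str):
                if p in values:
                    return float(values[p])
                try:
                    return float(eval(p, {"__builtins__": {}}, dict(values)))
                except Exception:
                    raise ScenarioError(
                        f"{self.name}: cannot resolve parameter {p!r}"
                    ) from None
            return float(p)

        sizes = {pop: val(s) for pop, s in self.sizes.items()}
        for pop, n in sizes.items():
            if n <= 0:
                raise ScenarioError(f"{self.name}: nonpositive size for {pop!r}")
        events = []
        for ev in self.events:
            t = val(ev.time) / self.generation_time
            if isinstance(ev, Split):
                events.append(("split", t, ev))
            elif isinstance(ev, Admixture):
                ra = val(ev.proportion)
                if not 0.0 < ra < 1.0 and ra not in (0.0, 1.0):
                    raise ScenarioError(f"{self.name}: admixture proportion {ra} invalid")
                events.append(("admix", t, ev, ra))
            else:
                events.append(("size", t, ev, val(ev.size)))
        events.sort(key=lambda e: e[1])
        return _ResolvedScenario(self.name, sizes, events)

    def validate(self, values: dict[str, float], sampling: dict[str, int]) -> None:
        """Check that all sampled lineages reach a single root population."""
        res = self.resolve(values)
        active = {p: True for p in sampling}
        for item in res.events:
            kind, _t, ev = item[0], item[1], item[2]
            if kind == "split":
                if active.pop(ev.derived, False):
                    active[ev.parent] = True
                if ev.parent not in res.sizes:
                    raise ScenarioError(f"{self.name}: no size for {ev.parent!r}")
            elif kind == "admix":
                ra = item[3]
                if active.pop(ev.target, False):
                    if ra > 0:
                        active[ev.source_a] = True
                    if ra < 1:
                        active[ev.source_b] = True
        if len(active) > 1:
            raise ScenarioError(
                f"{self.name}: lineages in {sorted(active)} never coalesce to one root"
            )


@dataclass
class _ResolvedScenario:
    name: str
    sizes: dict[str, float]
    events: list[tuple]


# ---------------------------------------------------------------------------
# Mutation model per locus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusModel:
    """Per-locus mutation model.

    ``mu``: mean-anchored GSM mutation rate per generation; ``p_gsm``:
    geometric coefficient P (mean step 1/(1-P) motif units); ``sni_rate``:
    single-nucleotide indel rate; ``range_width``: width R of the contiguous
    allowed ladder window; ``root_size``: root allele fragment length in bp.
    """

    id: str
    mu: float
    p_gsm: float = 0.0
    sni_rate: float = 0.0
    motif_length: int = 2
    range_width: int = 40
    root_size: int = 200

    def __post_init__(self) -> None:
        if self.mu < 0 or self.sni_rate < 0:
            raise ValueError(f"locus {self.id}: rates must be >= 0")
        if not 0.0 <= self.p_gsm <= 1.0:
            raise ValueError(f"locus {self.id}: P must be in [0, 1]")
        if self.range_width < 2:
            raise ValueError(f"locus {self.id}: range width must be >= 2")


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorDist:
    """Bounded prior: uniform or log-uniform over [min, max]."""

    name: str
    minimum: float
    maximum: float
    dist: str = "uniform"

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ValueError(f"{self.name}: min must be < max")
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.minimum, self.maximum))
        lo, hi = np.log(self.minimum), np.log(self.maximum)
        return float(np.exp(rng.uniform(lo, hi)))


@dataclass
class PriorSpec:
    """Named bounded priors plus pairwise ordering constraints.

    ``constraints`` is a list of (smaller, larger) parameter-name pairs,
    enforced by rejection at sampling time. ``mean_mu``/``mean_p``/``mean_sni``
    name the mean mutation-model parameters around which per-locus rates
    scatter; ``locus_bounds`` bound the individual-locus realizations.
    """

    params: dict[str, PriorDist]
    constraints: list[tuple[str, str]] = field(default_factory=list)
    mean_mu: str = "mean_mu"
    mean_p: str = "mean_p"
    mean_sni: str = "mean_sni"
    locus_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mu": (1e-6, 1e-3),
            "p": (1e-2, 1.0),
            "sni": (1e-9, 1e-4),
        }
    )

    def __post_init__(self) -> None:
        for a, b in self.constraints:
            for nm in (a, b):
                if nm not in self.params:
                    raise ValueError(f"constraint references unknown parameter {nm!r}")
        # cycle check by iterative pruning
        order = {a: set() for pair in self.constraints for a in pair}
        for a, b in self.constraints:
            order[b].add(a)
        remaining = dict(order)
        while remaining:
            free = [k for k, deps in remaining.items() if not deps & remaining.keys()]
            if not free:
                raise ValueError("ordering constraints contain a cycle")
            for k in free:
                del remaining[k]


@dataclass
class ParameterDraw:
    """One draw of every symbolic parameter plus per-locus mutation models."""

    values: dict[str, float]
    locus_models: list[LocusModel] = field(default_factory=list)


def _truncated_gamma_around(
    mean: float, lo: float, hi: float, shape: float, rng: np.random.Generator
) -> float:
    """Gamma(shape) with the given mean, rejected into [lo, hi]."""
    mean = min(max(mean, lo), hi)
    for _ in range(1000):
        v = rng.gamma(shape, mean / shape)
        if lo <= v <= hi:
            return float(v)
    return float(mean)


def sample_parameters(
    priors: PriorSpec,
    rng: np.random.Generator,
    n_loci: int = 0,
    motif_lengths: list[int] | None = None,
    locus_shape: float = 2.0,
    range_width: int = 40,
    root_size: int = 200,
    max_rejects: int = 10_000,
    overrides: dict[str, float] | None = None,
) -> ParameterDraw:
    """Draw parameters from their priors, honouring ordering constraints.

    Constraints are enforced by whole-vector rejection; an acceptance rate
    below 1/``max_rejects`` raises. When ``n_loci`` > 0, per-locus mutation
    models are drawn around the mean parameters with Gamma(shape
    ``locus_shape``) spread, truncated to ``priors.locus_bounds``.
    ``overrides`` pins named parameters to fixed values after the draw (used
    to simulate at a known truth); they are not re-checked against the
    ordering constraints.
    """
    for _ in range(max_rejects):
        values = {nm: d.draw(rng) for nm, d in priors.params.items()}
        if all(values[a] < values[b] for a, b in priors.constraints):
            break
    else:
        raise ValueError("constraint set looks infeasible (rejection acceptance < 1e-4)")
    if overrides:
        values.update(overrides)

    locus_models: list[LocusModel] = []
    if n_loci:
        motifs = motif_lengths or [2] * n_loci
        mu_m = values.get(priors.mean_mu, 5e-4)
        p_m = values.get(priors.mean_p, 0.0)
        sni_m = values.get(priors.mean_sni, 0.0)
        blo, bhi = priors.locus_bounds["mu"]
        plo, phi = priors.locus_bounds["p"]
        slo, shi = priors.locus_bounds["sni"]
        for l in range(n_loci):
            mu_l = _truncated_gamma_around(mu_m, blo, bhi, locus_shape, rng)
            p_l = (
                _truncated_gamma_around(p_m, plo, phi, locus_shape, rng)
                if p_m > 0
                else 0.0
            )
            sni_l = (
                _truncated_gamma_around(sni_m, slo, shi, locus_shape, rng)
                if sni_m > 0
                else 0.0
            )
            locus_models.append(
                LocusModel(
                    id=f"L{l + 1}",
                    mu=mu_l,
                    p_gsm=min(p_l, 0.999),
                    sni_rate=sni_l,
                    motif_length=motifs[l],
                    range_width=range_width,
                    root_size=root_size,
                )
            )
    return ParameterDraw(values, locus_models)


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------


def _simulate_genealogy(
    res: _ResolvedScenario,
    sampling: dict[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[str, list[int]]]:
    """Coalescent genealogy of 2 x sampling[pop] genes per population.

    Returns (parent, node_time, leaves_by_pop); the root has parent -1.
    """
    n_genes = {p: 2 * n for p, n in sampling.items()}
    total = sum(n_genes.values())
    n_nodes = 2 * total - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    leaves_by_pop: dict[str, list[int]] = {}
    lineages: dict[str, list[int]] = {}
    nid = 0
    for pop, k in n_genes.items():
        if pop not in res.sizes:
            raise ScenarioError(f"{res.name}: sampled population {pop!r} has no size")
        ids = list(range(nid, nid + k))
        nid += k
        leaves_by_pop[pop] = ids
        lineages[pop] = list(ids)
    next_node = total

    sizes = dict(res.sizes)
    t = 0.0
    events = list(res.events)
    inactive: set[str] = set()
    expo = rng.exponential
    randint = rng.integers

    def coalesce_epoch(pop: str, t_start: float, t_end: float) -> float:
        """Coalesce one population's lineages within [t_start, t_end)."""
        nonlocal next_node
        lin = lineages[pop]
        k = len(lin)
        if k < 2:
            return t_start
        four_n = 4.0 * sizes[pop]
        cur = t_start
        while k >= 2:
            cur += expo(four_n / (k * (k - 1)))
            if cur >= t_end:
                return t_end
            i = int(randint(k))
            j = int(randint(k - 1))
            if j >= i:
                j += 1
            a, b = lin[i], lin[j]
            node = next_node
            next_node += 1
            parent[a] = parent[b] = node
            node_time[node] = cur
            # replace slot i with the new node, drop slot j
            lin[i] = node
            lin[j] = lin[-1]
            lin.pop()
            k -= 1
        return cur

    for ei in range(len(events) + 1):
        t_end = events[ei][1] if ei < len(events) else np.inf
        for pop in list(lineages):
            coalesce_epoch(pop, t, t_end)
        if ei >= len(events):
            break
        item = events[ei]
        kind, t_ev, ev = item[0], item[1], item[2]
        t = t_ev
        if kind == "split":
            if ev.derived in inactive:
                raise ScenarioError(f"{res.name}: {ev.derived!r} already merged")
            moved = lineages.pop(ev.derived, [])
            if ev.parent not in sizes:
                raise ScenarioError(f"{res.name}: no size for {ev.parent!r}")
            lineages.setdefault(ev.parent, []).extend(moved)
            inactive.add(ev.derived)
        elif kind == "admix":
            ra = item[3]
            moved = lineages.pop(ev.target, [])
            inactive.add(ev.target)
            for x in moved:
                dest = ev.source_a if rng.random() < ra else ev.source_b
                if dest not in sizes:
                    raise ScenarioError(f"{res.name}: no size for {dest!r}")
                lineages.setdefault(dest, []).append(x)
        else:  # size change
            new_size = item[3]
            if new_size <= 0:
                raise ScenarioError(f"{res.name}: nonpositive size change")
            sizes[ev.population] = new_size
    n_left = sum(len(l) for l in lineages.values())
    if n_left != 1:
        stuck = sorted(p for p, l in lineages.items() if l)
        raise ScenarioError(
            f"{res.name}: lineages left in {stuck} after the last event"
        )
    return parent, node_time, leaves_by_pop


def _mutate_states(
    parent: np.ndarray,
    node_time: np.ndarray,
    locus: LocusModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele size in bp per node, mutating down from the root."""
    n = parent.size
    children: list[list[int]] = [[] for _ in range(n)]
    root = -1
    for i, p in enumerate(parent):
        if p == -1:
            root = i
        else:
            children[p].append(i)
    R = locus.range_width
    lo_step, hi_step = -(R // 2), R - 1 - (R // 2)
    total_rate = locus.mu + locus.sni_rate
    p_sni = locus.sni_rate / total_rate if total_rate > 0 else 0.0

    steps = np.zeros(n, dtype=np.int64)  # ladder offset from root
    snis = np.zeros(n, dtype=np.int64)  # off-ladder bp offset
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in children[node]:
            s, o = steps[node], snis[node]
            if total_rate > 0:
                blen = node_time[node] - node_time[ch]
                for _ in range(rng.poisson(total_rate * blen)):
                    if p_sni > 0 and rng.random() < p_sni:
                        o += 1 if rng.random() < 0.5 else -1
                    else:
                        for _try in range(1000):
                            k = rng.geometric(1.0 - locus.p_gsm) if locus.p_gsm > 0 else 1
                            s_new = s + (k if rng.random() < 0.5 else -k)
                            if lo_step <= s_new <= hi_step:
                                s = s_new
                                break
                        else:
                            # pathological P ~ 1 with a narrow window: step to
                            # the window edge in a random direction
                            s = hi_step if rng.random() < 0.5 else lo_step
            steps[ch], snis[ch] = s, o
            stack.append(ch)
    return locus.root_size + locus.motif_length * steps + snis


def simulate_dataset(
    scenario: Scenario,
    draw: ParameterDraw,
    sampling: dict[str, int],
    loci: list[LocusModel] | None = None,
    rng: np.random.Generator | int | None = None,
) -> GenotypeDataset:
    """Simulate a diploid microsatellite dataset under a scenario.

    ``sampling`` maps population label -> number of diploid individuals; each
    locus is an independent coalescent. Genes are paired consecutively into
    diploid individuals (exchangeable under panmixia).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    loci = loci if loci is not None else draw.locus_models
    if not loci:
        raise ValueError("no locus models supplied")
    if any(n < 1 for n in sampling.values()):
        raise ValueError("sampling sizes must be >= 1")
    res = scenario.resolve(draw.values)
    pops = list(sampling)
    n_ind = {p: sampling[p] for p in pops}
    calls = np.zeros((sum(n_ind.values()), len(loci), 2), dtype=np.int64)
    for l, locus in enumerate(loci):
        parent, node_time, leaves = _simulate_genealogy(res, sampling, rng)
        sizes_bp = _mutate_states(parent, node_time, locus, rng)
        row = 0
        for p in pops:
            ids = leaves[p]
            vals = sizes_bp[ids].reshape(-1, 2)
            calls[row : row + n_ind[p], l, :] = vals
            row += n_ind[p]
    individuals, populations = [], {}
    for p in pops:
        for i in range(n_ind[p]):
            ind = f"{p}_{i + 1}"
            individuals.append(ind)
            populations[ind] = p
    loci_info = [LocusInfo(m.id, m.motif_length) for m in loci]
    ds = GenotypeDataset(individuals, populations, loci_info, calls)
    return ds.with_recomputed_ranges()
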