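"""Approximate Bayesian computation: reference tables, scenario choice,
parameter posteriors, model checking, and error-rate evaluation.

The engine follows the DiyABC-style workflow: simulate a reference table of
(scenario, parameter draw, summary-statistic vector) rows; retain the small
fraction of rows closest to the observed vector (Euclidean distance on
median/MAD-normalized statistics); estimate scenario posterior probabilities
by weighted multinomial logistic regression of the scenario indicator on the
statistic offsets (Epanechnikov distance weights, evaluated at the origin);
estimate parameter posteriors by Beaumont-style local-linear regression
adjustment on logit-transformed parameters; check the fitted scenario by PCA
of the statistic cloud; and measure scenario-choice error on pseudo-observed
datasets (PODs).

All randomness flows through ``numpy`` SeedSequence substreams so that a
reference table is reproducible from its seed regardless of chunking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, gaussian_kde
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .coalescent_sim import ParameterDraw, PriorSpec, Scenario, simulate_dataset
from .scenarios import check_scenario_parameters, sample_for_scenario
from .summary_stats import stat_vector

# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Rows of (scenario id, parameter values, statistic vector).

    ``data`` holds one row per simulated dataset with a ``scenario`` column,
    ``param:<name>`` columns and ``stat:<name>`` columns. ``norm`` maps each
    statistic to its (median, MAD) over the table.
    """

    data: pd.DataFrame
    stat_names: list[str]
    param_names: list[str]
    norm: dict[str, tuple[float, float]]
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def stats_matrix(self) -> np.ndarray:
        return self.data[[f"stat:{s}" for s in self.stat_names]].to_numpy()

    def normalized_stats(self, drop_zero_mad: bool = True) -> tuple[np.ndarray, list[str]]:
        """(matrix, kept stat names) after median/MAD normalization."""
        kept, cols = [], []
        for s in self.stat_names:
            med, mad = self.norm[s]
            if mad == 0:
                if drop_zero_mad:
                    continue
                mad = 1.0
            kept.append(s)
            cols.append((self.data[f"stat:{s}"].to_numpy() - med) / mad)
        return np.column_stack(cols), kept

    def normalize_observed(self, observed: pd.Series, kept: list[str]) -> np.ndarray:
        out = []
        for s in kept:
            med, mad = self.norm[s]
            out.append((float(observed[s]) - med) / (mad if mad else 1.0))
        return np.asarray(out)

    def restrict_to(self, scenario: str) -> "ReferenceTable":
        sub = self.data[self.data["scenario"] == scenario].reset_index(drop=True)
        norm = _mad_norm(sub, self.stat_names)
        return ReferenceTable(sub, self.stat_names, self.param_names, norm, dict(self.provenance))


def _mad_norm(df: pd.DataFrame, stat_names: list[str]) -> dict[str, tuple[float, float]]:
    norm = {}
    for s in stat_names:
        x = df[f"stat:{s}"].to_numpy()
        med = float(np.median(x))
        norm[s] = (med, float(np.median(np.abs(x - med))))
    return norm


def simulate_stat_row(
    scenario: Scenario,
    priors: PriorSpec,
    sampling: dict[str, int],
    n_loci: int,
    rng: np.random.Generator,
    populations: list[str] | None = None,
    draw: ParameterDraw | None = None,
) -> tuple[ParameterDraw, pd.Series]:
    """One simulated dataset's parameter draw and statistic vector."""
    if draw is None:
        draw = sample_for_scenario(scenario, priors, rng, n_loci=n_loci)
    ds = simulate_dataset(scenario, draw, sampling, rng=rng)
    return draw, stat_vector(ds, populations or list(sampling))


def build_reference_table(
    scenarios: list[Scenario],
    priors: PriorSpec,
    n_per_scenario: int,
    sampling: dict[str, int],
    n_loci: int,
    seed: int,
    workers: int = 1,
) -> ReferenceTable:
    """Simulate the ABC reference table (deterministic given ``seed``).

    Each (scenario, replicate) pair gets its own SeedSequence substream, so
    results do not depend on execution order or chunking. ``workers`` is
    accepted for API compatibility; simulation is sequential.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    check_scenario_parameters(scenarios, priors)
    pops = list(sampling)
    rows = []
    stat_names: list[str] | None = None
    for si, scen in enumerate(scenarios):
        for rep in range(n_per_scenario):
            ss = np.random.SeedSequence(seed, spawn_key=(si, rep))
            rng = np.random.default_rng(ss)
            try:
                draw, sv = simulate_stat_row(scen, priors, sampling, n_loci, rng, pops)
            except Exception as e:
                raise RuntimeError(
                    f"simulation failed for scenario {scen.name!r}, replicate {rep}: {e}"
                ) from e
            if stat_names is None:
                stat_names = list(sv.index)
            row = {"scenario": scen.name}
            row.update({f"param:{k}": v for k, v in draw.values.items()})
            row.update({f"stat:{k}": float(sv[k]) for k in stat_names})
            rows.append(row)
    df = pd.DataFrame(rows)
    param_names = sorted(k[len("param:"):] for k in df.columns if k.startswith("param:"))
    assert stat_names is not None
    return ReferenceTable(
        df,
        stat_names,
        param_names,
        _mad_norm(df, stat_names),
        provenance={
            "seed": seed,
            "n_per_scenario": n_per_scenario,
            "scenarios": [s.name for s in scenarios],
            "sampling": dict(sampling),
            "n_loci": n_loci,
        },
    )


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------


@dataclass
class RejectionResult:
    indices: np.ndarray
    distances: np.ndarray
    retained: pd.DataFrame
    kept_stats: list[str]
    X: np.ndarray  # normalized stat offsets (retained rows - observed)


def rejection_sample(
    ref: ReferenceTable, observed: pd.Series, fraction: float = 0.01
) -> RejectionResult:
    """Retain the ``ceil(fraction * n)`` rows closest to the observed vector.

    Distances are Euclidean on median/MAD-normalized statistics; statistics
    with zero MAD over the table are dropped with a warning; ties are broken
    by row index (stable sort).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    M, kept = ref.normalized_stats()
    if len(kept) < len(ref.stat_names):
        dropped = sorted(set(ref.stat_names) - set(kept))
        warnings.warn(f"zero-MAD statistics dropped from distance: {dropped}")
    obs = ref.normalize_observed(observed, kept)
    d = np.sqrt(((M - obs) ** 2).sum(axis=1))
    n_keep = int(np.ceil(fraction * ref.n_rows))
    order = np.argsort(d, kind="stable")[:n_keep]
    return RejectionResult(
        order,
        d[order],
        ref.data.iloc[order].reset_index(drop=True),
        kept,
        M[order] - obs,
    )


def _epanechnikov(distances: np.ndarray) -> np.ndarray:
    dmax = distances.max()
    if dmax == 0:
        return np.ones_like(distances)
    w = 1.0 - (distances / (dmax * (1 + 1e-12))) ** 2
    return np.clip(w, 1e-12, None)


# ---------------------------------------------------------------------------
# Scenario choice
# ---------------------------------------------------------------------------


def scenario_posterior_logistic(
    ref: ReferenceTable,
    observed: pd.Series,
    fraction: float = 0.01,
    ridge_c: float = 1e4,
) -> dict[str, float]:
    """Posterior probability of each scenario by weighted logistic regression.

    A multinomial logistic regression of the scenario indicator on the
    normalized statistic offsets over the retained rows (Epanechnikov
    distance weights) is evaluated at the origin — the observed dataset.
    The fit is ridge-regularized (``C = ridge_c``), which also handles
    complete separation. Scenarios absent from the retained rows get
    probability 0. Probabilities sum to 1.
    """
    rej = rejection_sample(ref, observed, fraction)
    y = rej.retained["scenario"].to_numpy()
    classes = sorted(set(ref.data["scenario"]))
    present = sorted(set(y))
    if len(present) == 1:
        return {c: (1.0 if c == present[0] else 0.0) for c in classes}
    w = _epanechnikov(rej.distances)
    model = LogisticRegression(C=ridge_c, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(rej.X, y, sample_weight=w)
    probs = model.predict_proba(np.zeros((1, rej.X.shape[1])))[0]
    out = {c: 0.0 for c in classes}
    for c, p in zip(model.classes_, probs):
        out[c] = float(p)
    total = sum(out.values())
    return {c: p / total for c, p in out.items()}


# ---------------------------------------------------------------------------
# Parameter estimation (local-linear regression adjustment)
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Weighted posterior summaries per parameter.

    ``table`` has one row per parameter with mean, median, mode and the 95%
    credible interval; ``samples``/``weights`` hold the adjusted posterior
    draws for downstream use (e.g. posterior-predictive simulation).
    """

    table: pd.DataFrame
    samples: pd.DataFrame
    weights: np.ndarray
    adjusted: bool


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, x[order]))


def _weighted_mode(x: np.ndarray, w: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    try:
        kde = gaussian_kde(x, weights=w, bw_method="silverman")
        grid = np.linspace(x.min(), x.max(), 512)
        return float(grid[np.argmax(kde(grid))])
    except np.linalg.LinAlgError:
        return float(x[np.argmax(w)])


def estimate_parameters(
    ref: ReferenceTable,
    observed: pd.Series,
    fraction: float = 0.01,
    parameters: list[str] | None = None,
    priors: PriorSpec | None = None,
    min_rows_per_param: int = 10,
) -> PosteriorSummary:
    """Regression-adjusted parameter posterior for a (single-scenario) table.

    Parameters are logit-transformed to their prior bounds, regressed locally
    (weighted least squares, Epanechnikov weights) on the normalized statistic
    offsets, residual-adjusted to the origin, and back-transformed; summaries
    are weighted. A singular design falls back to the rejection-only
    posterior with a warning.
    """
    parameters = parameters or ref.param_names
    rej = rejection_sample(ref, observed, fraction)
    n = len(rej.retained)
    if n < min_rows_per_param * len(parameters):
        warnings.warn(
            f"only {n} retained rows for {len(parameters)} parameters; "
            "posterior may be unstable"
        )
    w = _epanechnikov(rej.distances)
    X = np.column_stack([np.ones(n), rej.X])
    adjusted = True
    samples = {}
    for p in parameters:
        y = rej.retained[f"param:{p}"].to_numpy().astype(float)
        lo = hi = None
        if priors is not None and p in priors.params:
            lo, hi = priors.params[p].minimum, priors.params[p].maximum
        if lo is not None:
            z = np.clip((y - lo) / (hi - lo), 1e-9, 1 - 1e-9)
            t = np.log(z / (1 - z))
        else:
            t = y
        sw = np.sqrt(w)
        try:
            beta, *_ = np.linalg.lstsq(X * sw[:, None], t * sw, rcond=None)
            fit_at_origin = beta[0]
            resid = t - X @ beta
            t_adj = fit_at_origin + resid
        except np.linalg.LinAlgError:
            warnings.warn("singular regression design; rejection-only posterior")
            t_adj = t
            adjusted = False
        if not np.all(np.isfinite(t_adj)):
            warnings.warn("non-finite adjustment; rejection-only posterior")
            t_adj = t
            adjusted = False
        if lo is not None:
            back = lo + (hi - lo) / (1.0 + np.exp(-t_adj))
        else:
            back = t_adj
        samples[p] = back
    rows = []
    for p in parameters:
        x = samples[p]
        rows.append(
            {
                "parameter": p,
                "mean": float(np.average(x, weights=w)),
                "median": _weighted_quantile(x, w, 0.5),
                "mode": _weighted_mode(x, w),
                "ci_low": _weighted_quantile(x, w, 0.025),
                "ci_high": _weighted_quantile(x, w, 0.975),
            }
        )
    return PosteriorSummary(
        pd.DataFrame(rows).set_index("parameter"),
        pd.DataFrame(samples),
        w,
        adjusted,
    )


# ---------------------------------------------------------------------------
# Model checking
# ---------------------------------------------------------------------------


@dataclass
class ModelCheckResult:
    ref_coords: np.ndarray
    predictive_coords: np.ndarray
    observed_coords: np.ndarray
    within_cloud: bool
    mahalanobis: float
    threshold: float


def model_check_pca(
    ref: ReferenceTable,
    predictive_stats: pd.DataFrame,
    observed: pd.Series,
    n_components: int = 2,
) -> ModelCheckResult:
    """PCA model check: does the observed vector sit inside the
    posterior-predictive cloud?

    The PCA is fitted on the reference table's normalized statistics
    (constant statistics excluded); the posterior-predictive simulations and
    the observed vector are projected, and the flag tests the observed
    point's Mahalanobis distance to the predictive cloud on the leading
    components against the chi-square 95% quantile.
    """
    M, kept = ref.normalized_stats()
    if len(kept) < 2 or len(predictive_stats) < 3:
        raise ValueError("need >= 2 usable statistics and >= 3 simulations")
    n_components = min(n_components, len(kept))
    pca = PCA(n_components=n_components)
    ref_coords = pca.fit_transform(M)
    P = np.column_stack(
        [
            (predictive_stats[s].to_numpy() - ref.norm[s][0])
            / (ref.norm[s][1] if ref.norm[s][1] else 1.0)
            for s in kept
        ]
    )
    pred_coords = pca.transform(P)
    obs_coords = pca.transform(ref.normalize_observed(observed, kept)[None, :])
    mu = pred_coords.mean(axis=0)
    cov = np.cov(pred_coords.T)
    cov = np.atleast_2d(cov) + 1e-9 * np.eye(n_components)
    diff = obs_coords[0] - mu
    m2 = float(diff @ np.linalg.solve(cov, diff))
    thr = float(chi2.ppf(0.95, df=n_components))
    return ModelCheckResult(ref_coords, pred_coords, obs_coords[0], m2 <= thr, m2, thr)


def posterior_predictive_stats(
    scenario: Scenario,
    posterior: PosteriorSummary,
    priors: PriorSpec,
    sampling: dict[str, int],
    n_loci: int,
    n_sims: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate statistic vectors under parameter draws from the posterior."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(997,)))
    idx = rng.choice(
        len(posterior.samples),
        size=n_sims,
        p=posterior.weights / posterior.weights.sum(),
    )
    rows = []
    pops = list(sampling)
    for i in idx:
        values = posterior.samples.iloc[int(i)].to_dict()
        base = sample_for_scenario(scenario, priors, rng, n_loci=n_loci)
        base.values.update(values)
        try:
            ds = simulate_dataset(scenario, base, sampling, rng=rng)
        except Exception:
            continue
        rows.append(stat_vector(ds, pops))
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Confidence in scenario choice
# ---------------------------------------------------------------------------


def scenario_choice_error(
    scenarios: list[Scenario],
    priors: PriorSpec,
    ref: ReferenceTable,
    sampling: dict[str, int],
    n_loci: int,
    n_pods: int,
    fraction: float = 0.01,
    seed: int = 0,
) -> dict:
    """Posterior predictive error rate of the scenario choice.

    Simulates ``n_pods`` pseudo-observed datasets per scenario from the
    priors, classifies each against ``ref`` with the logistic estimator, and
    reports the fraction whose modal scenario differs from the generating
    one (overall and per scenario).
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    pops = list(sampling)
    wrong = 0
    total = 0
    per_scenario: dict[str, float] = {}
    for si, scen in enumerate(scenarios):
        errs = 0
        for rep in range(n_pods):
            ss = np.random.SeedSequence(seed, spawn_key=(7001, si, rep))
            rng = np.random.default_rng(ss)
            _, sv = simulate_stat_row(scen, priors, sampling, n_loci, rng, pops)
            probs = scenario_posterior_logistic(ref, sv, fraction)
            modal = max(probs, key=probs.get)
            if modal != scen.name:
                errs += 1
        per_scenario[scen.name] = errs / n_pods
        wrong += errs
        total += n_pods
    return {"error_rate": wrong / total, "per_scenario": per_scenario, "n_pods": n_pods}
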