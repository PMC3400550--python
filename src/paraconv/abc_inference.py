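"""Rejection ABC with local-linear regression adjustment.

The estimator follows the classic rejection + regression recipe: draw
parameters from uniform priors, simulate the duplicated-locus coalescent,
summarise each dataset, standardize every statistic by its standard
deviation across the reference table, retain the k simulations closest to
the observed vector in Euclidean distance, and correct the retained draws
by a weighted local-linear regression of parameter on statistics
(Epanechnikov kernel on the distance, bandwidth equal to the largest
retained distance).  Model choice between the no-conversion model (M1)
and the conversion model (M2) uses the acceptance-ratio Bayes factor:
pool both reference tables, retain the overall best k, and take the ratio
of per-model acceptance counts.

Demographic calibration (:func:`fit_demography`) applies the same
machinery to a panel of independent single-copy reference loci, using the
across-locus mean and variance of (S, pi per site, Tajima's D) as the
observed summary vector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .coalsim import SimParams, simulate
from .sumstats import (
    DEFAULT_ABC_STATS,
    SummaryVector,
    summary_vector,
    tajimas_d_from_counts,
    _binary_locus_stats,
)

__all__ = [
    "PriorSpec",
    "PosteriorSummary",
    "sample_priors",
    "run_simulations",
    "rejection",
    "regression_adjust",
    "posterior_summary",
    "model_choice",
    "fit_demography",
    "DEFAULT_GC_PRIORS",
]

#: default prior bounds for the gene-conversion ABC: C = 4Nc per nucleotide,
#: mean tract length in bp, duplication time in 4N generations
DEFAULT_GC_PRIORS = {
    "C": (0.0, 20.0),
    "lambda_tract": (50.0, 2000.0),
    "t_dup": (0.05, 2.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: {parameter: (lower, upper)}."""

    bounds: dict

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name} needs lower < upper")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)


@dataclass
class PosteriorSummary:
    """Retained and adjusted draws with mode / CI / Bayes-factor summaries."""

    retained: pd.DataFrame
    adjusted: pd.DataFrame
    delta: np.ndarray
    mode: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    bayes_factor: float | None = None
    bf_is_lower_bound: bool = False
    notes: list = field(default_factory=list)


def sample_priors(spec: PriorSpec, n: int, seed=None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    data = {
        name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in spec.bounds.items()
    }
    return pd.DataFrame(data)


def _simulate_stats(params: SimParams, rng, stat_names) -> np.ndarray:
    """One replicate's statistic vector; resample until every entry is finite."""
    for _ in range(20):
        rep = simulate(params, rng=rng)
        sv = summary_vector(rep)
        vec = sv.to_array(stat_names)
        if np.all(np.isfinite(vec)):
            return vec
    raise RuntimeError("could not obtain finite summary statistics in 20 tries")


def run_simulations(
    param_table: pd.DataFrame,
    fixed: dict,
    stat_names=DEFAULT_ABC_STATS,
    seed=None,
    model: str | None = None,
) -> pd.DataFrame:
    """Simulate one dataset per parameter row and append its statistics.

    ``fixed`` supplies the SimParams fields not drawn from the prior
    (n_A, n_B, L, theta, ...).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = np.empty((len(param_table), len(stat_names)))
    for i, (_, draw) in enumerate(param_table.iterrows()):
        kwargs = dict(fixed)
        kwargs.update({k: float(v) for k, v in draw.items()})
        rows[i] = _simulate_stats(SimParams(**kwargs), rng, stat_names)
    out = param_table.copy().reset_index(drop=True)
    for j, nm in enumerate(stat_names):
        out[nm] = rows[:, j]
    if model is not None:
        out["model"] = model
    return out


def _standardize(table_stats: np.ndarray, observed: np.ndarray):
    """Scale columns by their SD over the table; drop zero-variance columns."""
    sd = table_stats.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {np.sum(~keep)} zero-variance statistic(s) from the ABC distance"
        )
    return table_stats[:, keep] / sd[keep], observed[keep] / sd[keep]


def rejection(
    observed: SummaryVector | np.ndarray,
    table: pd.DataFrame,
    k: int,
    stat_names=DEFAULT_ABC_STATS,
    param_names: list[str] | None = None,
) -> PosteriorSummary:
    """Retain the k simulations closest to the observed statistics.

    Distances are Euclidean in SD-standardized statistic space; ties are
    broken by row index (stable sort).
    """
    if isinstance(observed, SummaryVector):
        observed = observed.to_array(stat_names)
    observed = np.asarray(observed, dtype=float)
    if k > len(table):
        raise ValueError("k exceeds the number of simulations")
    if param_names is None:
        param_names = [c for c in table.columns if c not in stat_names and c != "model"]
    stats = table[list(stat_names)].to_numpy(dtype=float)
    z, z_obs = _standardize(stats, observed)
    delta = np.sqrt(np.sum((z - z_obs) ** 2, axis=1))
    order = np.argsort(delta, kind="stable")[:k]
    retained = table.iloc[order][param_names].reset_index(drop=True)
    return PosteriorSummary(
        retained=retained,
        adjusted=retained.copy(),
        delta=delta[order],
    )


def regression_adjust(
    post: PosteriorSummary,
    observed: SummaryVector | np.ndarray,
    table: pd.DataFrame,
    prior: PriorSpec | None = None,
    stat_names=DEFAULT_ABC_STATS,
) -> PosteriorSummary:
    """Beaumont-style local-linear adjustment of the retained draws.

    Weighted least squares of each parameter on the standardized retained
    statistics with Epanechnikov weights on delta (bandwidth = max retained
    delta); each draw is shifted to its fitted value at the observed
    statistics plus its residual, then clamped to the prior support.
    """
    if isinstance(observed, SummaryVector):
        observed = observed.to_array(stat_names)
    observed = np.asarray(observed, dtype=float)
    stats = table[list(stat_names)].to_numpy(dtype=float)
    z_all, z_obs = _standardize(stats, observed)
    delta_all = np.sqrt(np.sum((z_all - z_obs) ** 2, axis=1))
    order = np.argsort(delta_all, kind="stable")[: len(post.retained)]
    z = z_all[order]
    delta = delta_all[order]
    k, p = z.shape
    if k < p + 2:
        post.notes.append("too few retained draws for regression; left unadjusted")
        return post
    dmax = delta.max()
    w = 1.0 - (delta / dmax) ** 2 if dmax > 0 else np.ones(k)
    w = np.clip(w, 1e-12, None)
    X = np.column_stack([np.ones(k), z - z_obs])
    sw = np.sqrt(w)
    adjusted = post.retained.copy()
    for name in post.retained.columns:
        y = post.retained[name].to_numpy(dtype=float)
        try:
            beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        except np.linalg.LinAlgError:
            post.notes.append(f"singular design for {name}; left unadjusted")
            continue
        fitted = X @ beta
        adj = beta[0] + (y - fitted)
        if prior is not None and name in prior.bounds:
            lo, hi = prior.bounds[name]
            adj = np.clip(adj, lo, hi)
        adjusted[name] = adj
    post.adjusted = adjusted
    return post


def posterior_summary(
    draws: np.ndarray, support: tuple[float, float] | None = None
) -> tuple[float, tuple[float, float]]:
    """Posterior mode (Gaussian KDE argmax, Silverman bandwidth, 512-point
    grid over the support) and central 95% credibility interval."""
    draws = np.asarray(draws, dtype=float)
    if len(draws) < 50:
        raise ValueError("need at least 50 draws for a posterior summary")
    lo_q, hi_q = np.quantile(draws, [0.025, 0.975])
    if np.ptp(draws) == 0:
        return float(draws[0]), (float(lo_q), float(hi_q))
    if support is None:
        support = (draws.min(), draws.max())
    grid = np.linspace(support[0], support[1], 512)
    dens = gaussian_kde(draws)(grid)
    return float(grid[np.argmax(dens)]), (float(lo_q), float(hi_q))


def summarize(post: PosteriorSummary, prior: PriorSpec | None = None) -> PosteriorSummary:
    """Fill mode / CI fields for every parameter from the adjusted draws."""
    for name in post.adjusted.columns:
        support = prior.bounds.get(name) if prior is not None else None
        mode, ci = posterior_summary(post.adjusted[name].to_numpy(), support)
        post.mode[name] = mode
        post.ci95[name] = ci
    return post


def model_choice(
    observed: SummaryVector | np.ndarray,
    table_m1: pd.DataFrame,
    table_m2: pd.DataFrame,
    k: int,
    stat_names=DEFAULT_ABC_STATS,
) -> tuple[float, bool]:
    """Acceptance-ratio Bayes factor BF(M2:M1).

    Both tables are pooled and standardized jointly; the best k overall are
    retained and the BF is the ratio of per-model acceptance counts.  When
    no M1 simulation is retained the BF is reported as the lower bound k
    (flagged by the second return value).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(table_m1) != len(table_m2):
        raise ValueError("model tables must have equal row counts")
    if isinstance(observed, SummaryVector):
        observed = observed.to_array(stat_names)
    observed = np.asarray(observed, dtype=float)
    s1 = table_m1[list(stat_names)].to_numpy(dtype=float)
    s2 = table_m2[list(stat_names)].to_numpy(dtype=float)
    pooled = np.vstack([s1, s2])
    z, z_obs = _standardize(pooled, observed)
    delta = np.sqrt(np.sum((z - z_obs) ** 2, axis=1))
    order = np.argsort(delta, kind="stable")[:k]
    n2 = int(np.sum(order >= len(s1)))
    n1 = k - n2
    if n1 == 0:
        return float(k), True
    return n2 / n1, False


# ---------------------------------------------------------------------------
# demographic calibration from single-copy reference loci

DEMOG_STAT_NAMES = ("mean_S", "mean_pi", "mean_D", "var_S", "var_pi", "var_D")


def reference_panel_stats(per_locus: list[tuple[float, float, float]]) -> np.ndarray:
    """Across-locus mean and variance of (S, pi per site, Tajima's D)."""
    arr = np.asarray(per_locus, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr, axis=0)
        vars_ = np.nanvar(arr, axis=0, ddof=1)
    return np.concatenate([means, vars_])


def _simulate_panel(theta, f, t_exp, n, L, n_loci, rng) -> np.ndarray:
    per_locus = []
    for _ in range(n_loci):
        rep = simulate(
            SimParams(
                n_A=n, n_B=0, L=L, theta=theta, growth_factor=f, t_exp=t_exp, t_dup=1.0
            ),
            rng=rng,
        )
        S, pi_total, pi_site, _, D = _binary_locus_stats(rep.haplotypes_A, L)
        per_locus.append((S, pi_site, D))
    return reference_panel_stats(per_locus)


def fit_demography(
    ref_loci_stats: list[tuple[float, float, float]],
    priors: PriorSpec,
    n_sims: int,
    k: int,
    n: int,
    L: int,
    seed=None,
) -> PosteriorSummary:
    """ABC fit of the stepwise-expansion demography (theta, f, t_exp).

    ``ref_loci_stats`` holds (S, pi per site, Tajima's D) per reference
    locus; simulated datasets mirror the panel (the same number of
    independent single-copy loci per draw).
    """
    if len(ref_loci_stats) < 2:
        raise ValueError("need at least two reference loci")
    observed = reference_panel_stats(ref_loci_stats)
    rng = np.random.default_rng(seed)
    params = sample_priors(priors, n_sims, seed=rng)
    names = priors.names
    stats = np.empty((n_sims, len(DEMOG_STAT_NAMES)))
    defaults = {"theta": None, "f": 1.0, "t_exp": 0.0}
    for i in range(n_sims):
        draw = {nm: float(params.iloc[i][nm]) for nm in names}
        for _ in range(20):
            vec = _simulate_panel(
                draw.get("theta", defaults["theta"]),
                draw.get("f", defaults["f"]),
                draw.get("t_exp", defaults["t_exp"]),
                n,
                L,
                len(ref_loci_stats),
                rng,
            )
            if np.all(np.isfinite(vec)):
                break
        stats[i] = vec
    table = params.copy()
    for j, nm in enumerate(DEMOG_STAT_NAMES):
        table[nm] = stats[:, j]
    post = rejection(observed, table, k, stat_names=DEMOG_STAT_NAMES, param_names=names)
    post = regression_adjust(post, observed, table, prior=priors, stat_names=DEMOG_STAT_NAMES)
    return summarize(post, priors)
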