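"""Score-based test statistics and p-values for parameter invariance.

Six functionals of the decorrelated cumulative score process are
implemented, keyed to the covariate type:

======  ===========  ==========================================
name    covariate    statistic
======  ===========  ==========================================
DM      metric       double maximum  max_v max_j |B_vj|
CvM     metric       Cramer-von Mises  N^-1 sum_v sum_j B_vj^2
maxLM   metric       max_v [t(1-t)]^-1 sum_j B_vj^2, trimmed
WDMo    ordinal      weighted double maximum at category bounds
maxLMo  ordinal      maxLM evaluated at category bounds
LMuo    categorical  sum of scaled squared category increments
======  ===========  ==========================================

p-values are analytic for DM (Kolmogorov distribution, independent
components), WDMo (joint normal law of the bridge at the category
boundaries) and LMuo (chi-square with (m-1)k degrees of freedom), and are
obtained from Monte-Carlo simulated Brownian-bridge paths for CvM, maxLM
and maxLMo.

``LMuo`` scales each category increment by the inverse category proportion
(t_l - t_{l-1})^-1, which yields the chi-square((m-1)k) null distribution
the analytic p-value assumes; an unscaled variant is available for
sensitivity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .estimation import FittedModel
from .score_process import (
    CovariateOrdering,
    CumProcess,
    cumulative_process,
    score_contributions,
)

__all__ = [
    "TestResult",
    "stat_metric",
    "stat_ordinal",
    "stat_categorical",
    "p_value",
    "sctest",
    "resolve_subset",
    "DEFAULT_STATISTIC",
]

METRIC_STATS = ("DM", "CvM", "maxLM")
ORDINAL_STATS = ("WDMo", "maxLMo")
CATEGORICAL_STATS = ("LMuo",)
ALL_STATS = METRIC_STATS + ORDINAL_STATS + CATEGORICAL_STATS

#: statistic used by default for each covariate kind
DEFAULT_STATISTIC = {"metric": "DM", "ordinal": "WDMo", "categorical": "LMuo"}

DEFAULT_TRIM = (0.1, 0.9)


@dataclass
class TestResult:
    """Outcome of one score-based invariance test."""

    statistic_name: str
    statistic_value: float
    p_value: float
    subset: list[str]
    k: int
    covariate: str
    covariate_kind: str
    pvalue_method: str  # "analytic" | "simulated"
    nsim: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.statistic_value < 0:
            raise ValueError("statistic must be nonnegative")

    def to_json(self) -> str:
        d = {
            "statistic_name": self.statistic_name,
            "statistic_value": self.statistic_value,
            "p_value": self.p_value,
            "subset": self.subset,
            "k": self.k,
            "covariate": self.covariate,
            "covariate_kind": self.covariate_kind,
            "pvalue_method": self.pvalue_method,
            "nsim": self.nsim,
            "seed": self.seed,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "TestResult":
        return cls(**json.loads(s))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _check_trim(trim) -> tuple[float, float]:
    lo, hi = (trim if np.ndim(trim) else (trim, 1.0 - trim))
    if not (0.0 < lo < 0.5 and 0.5 < hi < 1.0):
        raise ValueError("trim must lie inside (0, .5)")
    return lo, hi


def stat_metric(B: CumProcess, which: str = "DM", trim=DEFAULT_TRIM) -> float:
    """DM, CvM or maxLM for a metric (or metric-by-request) covariate.

    All evaluations are restricted to tie-block boundaries, so the
    arbitrary order of tied persons cannot affect the value.
    """
    if which not in METRIC_STATS:
        raise ValueError(f"{which!r} is not a metric-covariate statistic")
    Bv = B.boundary_values()
    n = B.n_persons
    t = B.ordering.t
    if which == "DM":
        return float(np.abs(Bv).max())
    ssq = (Bv**2).sum(axis=1)
    if which == "CvM":
        return float(ssq.sum() / n)
    lo, hi = _check_trim(trim)
    keep = (t >= lo) & (t <= hi) & (t < 1.0)
    if not keep.any():
        raise ValueError("trimmed range contains no evaluation point")
    tt = t[keep]
    return float((ssq[keep] / (tt * (1.0 - tt))).max())


def stat_ordinal(B: CumProcess, ordering: CovariateOrdering | None = None,
                 which: str = "WDMo") -> float:
    """WDMo or maxLMo, evaluated at the m-1 interior category boundaries."""
    if which not in ORDINAL_STATS:
        raise ValueError(f"{which!r} is not an ordinal-covariate statistic")
    ordering = ordering or B.ordering
    if ordering.n_blocks < 2:
        raise ValueError("ordinal covariate needs at least 2 non-empty categories")
    Bv = B.B[ordering.boundaries[:-1] - 1]  # interior boundaries only
    t = ordering.t[:-1]
    w = t * (1.0 - t)
    if which == "WDMo":
        return float((np.abs(Bv).max(axis=1) / np.sqrt(w)).max())
    return float(((Bv**2).sum(axis=1) / w).max())


def stat_categorical(B: CumProcess, ordering: CovariateOrdering | None = None,
                     scaled: bool = True) -> float:
    """LMuo: squared within-category increments of the process.

    With ``scaled=True`` (default) each category's increment is scaled by
    the inverse category proportion, giving a chi-square((m-1)k) null; the
    unscaled literal sum is available for sensitivity checks.
    """
    ordering = ordering or B.ordering
    if ordering.n_blocks < 2:
        raise ValueError("categorical covariate needs at least 2 non-empty categories")
    Bv = B.B[ordering.boundaries - 1]  # m x k, last row ~ 0
    prev = np.vstack([np.zeros(B.k), Bv[:-1]])
    inc = Bv - prev
    dt = np.diff(np.r_[0.0, ordering.t])
    if scaled:
        return float(((inc**2).sum(axis=1) / dt).sum())
    return float((inc**2).sum())


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------

def _dm_pvalue(stat: float, k: int) -> float:
    # sup |bridge| per component follows the Kolmogorov distribution;
    # components are independent after decorrelation
    if stat <= 0:
        return 1.0
    return float(1.0 - stats.kstwobign.cdf(stat) ** k)


def _wdmo_pvalue(stat: float, k: int, t: np.ndarray) -> float:
    """Joint normal law of the weighted bridge at the category boundaries.

    Z_l = B(t_l)/sqrt(t_l(1-t_l)) is standard normal with
    corr(Z_l, Z_l') = sqrt(t_l(1-t_l') / (t_l'(1-t_l))) for t_l <= t_l'.
    """
    if stat <= 0:
        return 1.0
    tl = np.asarray(t, dtype=float)
    m1 = tl.size
    if m1 == 1:
        inside = stats.norm.cdf(stat) - stats.norm.cdf(-stat)
        return float(1.0 - inside**k)
    ti, tj = np.meshgrid(tl, tl, indexing="ij")
    lo = np.minimum(ti, tj)
    hi = np.maximum(ti, tj)
    corr = np.sqrt(lo * (1.0 - hi) / (hi * (1.0 - lo)))
    np.fill_diagonal(corr, 1.0)
    mvn = stats.multivariate_normal(mean=np.zeros(m1), cov=corr,
                                    allow_singular=True)
    inside = mvn.cdf(np.full(m1, stat), lower_limit=np.full(m1, -stat))
    inside = min(max(float(inside), 0.0), 1.0)
    return float(1.0 - inside**k)


def _simulate_null(statistic_name: str, k: int, t: np.ndarray | None,
                   trim, nsim: int, seed: int | None,
                   ngrid: int = 1000) -> np.ndarray:
    """Monte-Carlo null distribution from simulated Brownian-bridge paths."""
    rng = np.random.default_rng(seed)
    grid_t = np.arange(1, ngrid + 1) / ngrid
    out = np.empty(nsim)
    block = max(1, int(2e7 // (ngrid * k)))
    done = 0
    while done < nsim:
        b = min(block, nsim - done)
        incr = rng.standard_normal((b, ngrid, k)) / np.sqrt(ngrid)
        W = np.cumsum(incr, axis=1)
        B = W - grid_t[None, :, None] * W[:, -1:, :]
        if statistic_name == "CvM":
            out[done:done + b] = (B**2).sum(axis=2).mean(axis=1)
        elif statistic_name == "maxLM":
            lo, hi = _check_trim(trim)
            keep = (grid_t >= lo) & (grid_t <= hi) & (grid_t < 1.0)
            ssq = (B[:, keep, :] ** 2).sum(axis=2)
            w = grid_t[keep] * (1.0 - grid_t[keep])
            out[done:done + b] = (ssq / w[None, :]).max(axis=1)
        elif statistic_name == "maxLMo":
            tl = np.asarray(t, dtype=float)
            idx = np.clip(np.round(tl * ngrid).astype(int) - 1, 0, ngrid - 1)
            Bv = B[:, idx, :]
            w = tl * (1.0 - tl)
            out[done:done + b] = ((Bv**2).sum(axis=2) / w[None, :]).max(axis=1)
        elif statistic_name == "WDMo":
            tl = np.asarray(t, dtype=float)
            idx = np.clip(np.round(tl * ngrid).astype(int) - 1, 0, ngrid - 1)
            Bv = B[:, idx, :]
            w = np.sqrt(tl * (1.0 - tl))
            out[done:done + b] = (np.abs(Bv).max(axis=2) / w[None, :]).max(axis=1)
        elif statistic_name == "DM":
            out[done:done + b] = np.abs(B).max(axis=(1, 2))
        else:
            raise ValueError(f"no simulated null for {statistic_name!r}")
        done += b
    return out


def p_value(
    statistic: float,
    statistic_name: str,
    k: int,
    ordering: CovariateOrdering | None = None,
    trim=DEFAULT_TRIM,
    nsim: int = 10_000,
    seed: int | None = 0,
) -> tuple[float, str]:
    """p-value of a statistic; returns (p, method).

    DM, WDMo and LMuo have analytic asymptotic p-values; CvM, maxLM and
    maxLMo are referred to a Monte-Carlo sample of Brownian-bridge paths
    (``nsim`` paths on a 1000-point grid, fixed ``seed``).
    """
    if not np.isfinite(statistic):
        raise ValueError("statistic must be finite")
    if statistic_name not in ALL_STATS:
        raise ValueError(f"unknown statistic {statistic_name!r}")
    if statistic_name == "DM":
        return _dm_pvalue(statistic, k), "analytic"
    if statistic_name == "LMuo":
        if ordering is None:
            raise ValueError("LMuo p-value needs the covariate ordering")
        m = ordering.n_blocks
        return float(stats.chi2.sf(statistic, (m - 1) * k)), "analytic"
    if statistic_name == "WDMo":
        if ordering is None:
            raise ValueError("WDMo p-value needs the covariate ordering")
        return _wdmo_pvalue(statistic, k, ordering.t[:-1]), "analytic"
    t = None if ordering is None else ordering.t[:-1]
    if statistic_name == "maxLMo" and t is None:
        raise ValueError("maxLMo p-value needs the covariate ordering")
    null = _simulate_null(statistic_name, k, t, trim, nsim, seed)
    p = (1.0 + np.sum(null >= statistic)) / (nsim + 1.0)
    return float(p), "simulated"


# ---------------------------------------------------------------------------
# End-to-end test
# ---------------------------------------------------------------------------

def resolve_subset(registry: Sequence[str], subset) -> list[str]:
    """Resolve a named parameter subset against the registry.

    ``subset`` may be one of the shorthand names ``alpha_nm``, ``alpha_e``,
    ``loadings_nm``, ``loadings_e``, ``loadings_1``, ``intercepts`` or an
    explicit list of registry names.
    """
    registry = list(registry)
    if not isinstance(subset, str):
        names = list(subset)
        missing = [n for n in names if n not in registry]
        if missing:
            raise KeyError(f"parameters {missing} not in registry")
        return names
    prefix = {
        "alpha_nm": "alpha_nm", "loadings_nm": "alpha_nm",
        "alpha_e": "alpha_e", "loadings_e": "alpha_e",
        "loadings_1": "alpha_1",
        "intercepts": "delta",
    }.get(subset)
    if prefix is None:
        if subset in registry:
            return [subset]
        raise KeyError(f"unknown subset {subset!r}")
    names = [n for n in registry if n == prefix or n.startswith(prefix + "_")
             or (prefix == "delta" and n.startswith("delta"))]
    if not names:
        raise KeyError(f"subset {subset!r} resolves to no parameters")
    return names


def sctest(
    fitted: FittedModel,
    pseudo_data: np.ndarray,
    covariate: np.ndarray,
    kind: str,
    subset="alpha_nm",
    statistic_name: str | None = None,
    covariate_name: str = "covariate",
    trim=DEFAULT_TRIM,
    nsim: int = 10_000,
    seed: int | None = 0,
    scores=None,
    decorrelate: str = "subset",
) -> TestResult:
    """Score-based invariance test for a parameter subset.

    Runs the full pipeline: score contributions at the MLE, subset OPG
    block, decorrelated cumulative process, test statistic, p-value.
    ``scores`` may pass a precomputed :class:`ScoreMatrix` to share one
    score computation across several subset tests.
    """
    statistic_name = statistic_name or DEFAULT_STATISTIC[kind]
    if kind == "metric" and statistic_name not in METRIC_STATS:
        raise ValueError(f"{statistic_name} is not defined for a metric covariate")
    if kind == "categorical" and statistic_name != "LMuo":
        raise ValueError("a categorical covariate requires the LMuo statistic")

    if scores is None:
        scores = score_contributions(fitted, pseudo_data)
    names = resolve_subset(scores.param_registry, subset)
    ordering = CovariateOrdering.from_covariate(covariate, kind)
    proc = cumulative_process(scores, ordering, names, decorrelate=decorrelate)
    k = len(names)

    if statistic_name in METRIC_STATS:
        value = stat_metric(proc, statistic_name, trim)
    elif statistic_name in ORDINAL_STATS:
        if kind not in ("ordinal",):
            raise ValueError(f"{statistic_name} requires an ordinal covariate")
        value = stat_ordinal(proc, ordering, statistic_name)
    else:
        value = stat_categorical(proc, ordering)

    p, method = p_value(value, statistic_name, k, ordering, trim, nsim, seed)
    return TestResult(
        statistic_name=statistic_name, statistic_value=value, p_value=p,
        subset=names, k=k, covariate=covariate_name, covariate_kind=kind,
        pvalue_method=method,
        nsim=nsim if method == "simulated" else None,
        seed=seed if method == "simulated" else None,
    )


def plot_process(proc: CumProcess, path=None, title: str | None = None):
    """Plot the fluctuation process with category-boundary markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    tgrid = np.arange(1, proc.n_persons + 1) / proc.n_persons
    for j, name in enumerate(proc.subset):
        ax.plot(tgrid, proc.B[:, j], label=name, lw=1.0)
    for t in proc.ordering.t[:-1]:
        ax.axvline(t, color="grey", ls=":", lw=0.8)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("ordered sample fraction t")
    ax.set_ylabel("decorrelated cumulative score")
    if title:
        ax.set_title(title)
    if len(proc.subset) <= 8:
        ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig, ax
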