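"""Empirical fluctuation process of the item-parameter scores.

Per-person score contributions s(Psi-hat; y_v) are cumulated in the order
of a person covariate and decorrelated with an outer-product-of-gradients
(OPG) estimate of their covariance. Under parameter invariance the
resulting process behaves like a (multivariate) Brownian bridge, which is
the reference distribution of every test statistic in
:mod:`irtreescan.invariance`.

Conventions pinned here (the literature leaves them open):

* the OPG covariance is the *uncentered* cross-product (1/N) sum s_v s_v';
  at the MLE the mean score vanishes so centering is asymptotically
  irrelevant;
* for subset tests the decorrelation uses the subset block of the OPG
  matrix (the default), not the subset of the fully decorrelated process;
* the cumulated subset scores are mean-centered before cumulation, which
  pins the bridge endpoint B_N = 0 exactly; at an exact MLE this is a
  no-op, and it removes the residual drift left by a finite convergence
  threshold;
* persons with tied covariate values form one block and the process may
  only be evaluated at block boundaries, so the arbitrary within-block
  order cannot affect any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .estimation import FittedModel, score_contributions_at

__all__ = [
    "ScoreMatrix",
    "CovariateOrdering",
    "CumProcess",
    "RankDeficiencyError",
    "score_contributions",
    "opg_covariance",
    "cumulative_process",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


@dataclass
class ScoreMatrix:
    """N x p matrix of per-person score contributions, with the registry."""

    values: np.ndarray
    param_registry: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.param_registry):
            raise ValueError("score matrix width must match the registry")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    def column_indices(self, subset: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.param_registry)}
        try:
            return np.array([lookup[n] for n in subset], dtype=int)
        except KeyError as e:
            raise KeyError(f"parameter {e.args[0]!r} not in registry") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.param_registry)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CovariateOrdering:
    """Ordering of the sample by a person covariate.

    ``order`` is a stable permutation sorting the covariate; ``boundaries``
    holds the (1-based) indices v_l of the last member of each tie block
    (metric) or covariate category (ordinal/categorical); ``t`` holds the
    cumulative proportions v_l / N.
    """

    kind: str  # "metric" | "ordinal" | "categorical"
    order: np.ndarray
    boundaries: np.ndarray
    t: np.ndarray
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def from_covariate(cls, x: np.ndarray, kind: str) -> "CovariateOrdering":
        if kind not in ("metric", "ordinal", "categorical"):
            raise ValueError(f"unknown covariate kind {kind!r}")
        x = np.asarray(x)
        if x.ndim != 1:
            raise ValueError("covariate must be 1-D")
        uniq = pd.unique(x)
        if len(uniq) < 2:
            raise ValueError("constant covariate carries no ordering information")
        if kind == "categorical":
            # category order is arbitrary; use order of first appearance
            codes = pd.Series(x).map({v: i for i, v in enumerate(uniq)}).to_numpy()
            order = np.argsort(codes, kind="stable")
            sorted_codes = codes[order]
            block_vals = uniq
        else:
            order = np.argsort(x, kind="stable")
            sorted_x = x[order]
            change = np.r_[sorted_x[1:] != sorted_x[:-1], True]
            sorted_codes = np.cumsum(np.r_[0, sorted_x[1:] != sorted_x[:-1]])
            block_vals = sorted_x[np.where(change)[0]]
        n = x.size
        change = np.r_[sorted_codes[1:] != sorted_codes[:-1], True]
        boundaries = np.where(change)[0] + 1  # 1-based v_l
        t = boundaries / n
        return cls(kind=kind, order=order, boundaries=boundaries, t=t,
                   values=np.asarray(block_vals))

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries)


@dataclass
class CumProcess:
    """Decorrelated cumulative score process for a parameter subset.

    ``B`` has one row per person (in covariate order); row v is
    ``Ihat^{-1/2} N^{-1/2} sum_{u<=v} s_(u)``. ``eval_idx`` are the 0-based
    rows at which the process may be evaluated (tie-block boundaries).
    """

    B: np.ndarray
    subset: list[str]
    info_hat: np.ndarray
    ordering: CovariateOrdering

    @property
    def n_persons(self) -> int:
        return self.B.shape[0]

    @property
    def k(self) -> int:
        return self.B.shape[1]

    @property
    def eval_idx(self) -> np.ndarray:
        return self.ordering.boundaries - 1

    def boundary_values(self) -> np.ndarray:
        """Process values at the evaluation boundaries (n_blocks x k)."""
        return self.B[self.eval_idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.B, columns=self.subset)
        df.insert(0, "t", np.arange(1, self.n_persons + 1) / self.n_persons)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def score_contributions(fitted: FittedModel, pseudo_data: np.ndarray) -> ScoreMatrix:
    """Per-person score contributions at the MLE.

    Row v is the gradient of person v's marginal log-likelihood with
    respect to the item-parameter vector Psi, evaluated at Psi-hat with the
    same quadrature rule used for fitting; the columns sum to approximately
    zero.
    """
    if not fitted.converged:
        warnings.warn(
            "computing scores from a non-converged fit; the zero-sum property "
            "holds only approximately", UserWarning,
        )
    values = score_contributions_at(
        fitted.params, pseudo_data, fitted.spec, fitted.options
    )
    return ScoreMatrix(values=values, param_registry=fitted.params.param_names())


def opg_covariance(scores: ScoreMatrix | np.ndarray) -> np.ndarray:
    """OPG estimate of the score covariance: (1/N) sum s_v s_v' (uncentered)."""
    S = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    n, p = S.shape
    if n <= p:
        warnings.warn(
            f"OPG covariance from N={n} <= p={p} score rows is rank deficient",
            UserWarning,
        )
    return (S.T @ S) / n


def _inv_sqrt(mat: np.ndarray, floor_ratio: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root with an eigenvalue floor.

    Eigenvalues below ``floor_ratio`` times the largest raise
    :class:`RankDeficiencyError` rather than being silently regularized.
    """
    vals, vecs = np.linalg.eigh(mat)
    lam_max = vals.max()
    if lam_max <= 0 or vals.min() < floor_ratio * lam_max:
        raise RankDeficiencyError(
            "score covariance is (near-)rank-deficient; test a smaller "
            "parameter subset"
        )
    return (vecs / np.sqrt(vals)) @ vecs.T


def cumulative_process(
    scores: ScoreMatrix,
    ordering: CovariateOrdering,
    subset: Sequence[str] | None = None,
    decorrelate: str = "subset",
) -> CumProcess:
    """Decorrelated cumulative score process ordered by a covariate.

    ``decorrelate="subset"`` (default) decorrelates with the subset block
    of the OPG covariance; ``"full"`` decorrelates the full process first
    and then selects columns (a non-default alternative).
    """
    if subset is None:
        subset = list(scores.param_registry)
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    idx = scores.column_indices(subset)
    n = scores.n_persons
    if ordering.order.size != n:
        raise ValueError("ordering and score matrix disagree on N")

    if decorrelate == "subset":
        S = scores.values[:, idx]
        info = opg_covariance(S)
        root = _inv_sqrt(info)
    elif decorrelate == "full":
        info_full = opg_covariance(scores)
        root = _inv_sqrt(info_full)[idx][:, idx]
        info = info_full[np.ix_(idx, idx)]
        S = scores.values[:, idx]
    else:
        raise ValueError(f"unknown decorrelation mode {decorrelate!r}")

    S_ord = S[ordering.order]
    S_ord = S_ord - S_ord.mean(axis=0, keepdims=True)  # pins B_N = 0
    B = np.cumsum(S_ord, axis=0) @ root.T / np.sqrt(n)
    return CumProcess(B=B, subset=subset, info_hat=info, ordering=ordering)
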