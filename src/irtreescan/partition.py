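"""Model-based partitioning along a person covariate.

After a significant invariance test, the sample is split at the covariate
value that maximizes the summed log-likelihood of two independently
refitted IRTree models, subject to a minimum subgroup size (default 300
persons per side). The procedure is applied recursively: each subgroup is
retested and split again until non-significance, the minimum size, or a
depth limit.

For metric and ordinal covariates the candidate cuts are the boundaries
between distinct covariate values; for unordered categorical covariates
with up to 6 categories all binary partitions of the category set are
searched exhaustively (beyond that, greedily by category).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .estimation import (
    FitOptions,
    FittedModel,
    ModelSpec,
    NonConvergenceWarning,
    fit_irtree,
    loglik_profile_at_split,
)
from .invariance import DEFAULT_STATISTIC, TestResult, sctest
from .tree_model import flatten_pseudo

__all__ = [
    "CutpointResult",
    "PartitionNode",
    "PartitionOptions",
    "find_cutpoint",
    "partition",
]


@dataclass
class PartitionOptions:
    """Tuning of the cutpoint search and recursion."""

    min_size: int = 300
    level: float = 0.05
    max_depth: int = 3
    statistic_name: str | None = None  # default chosen by covariate kind
    profile: str = "exact"  # "exact" | "fixed_sigma" (fast approximation)
    max_candidates: int | None = None  # subsample the candidate cuts
    warm_start: bool = True
    retest_all_subsets: bool = False
    nsim: int = 10_000
    seed: int | None = 0


@dataclass
class CutpointResult:
    cutpoint: object  # covariate value (metric/ordinal) or category set
    loglik_sum: float
    profile: pd.DataFrame  # candidate cut -> summed log-likelihood
    fit_left: FittedModel
    fit_right: FittedModel
    left_mask: np.ndarray


@dataclass
class PartitionNode:
    """One node of the partition tree."""

    condition: str
    n: int
    fitted: FittedModel
    test: TestResult | None = None
    tested: list[TestResult] = field(default_factory=list)
    cutpoint: object = None
    children: list["PartitionNode"] = field(default_factory=list)
    note: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        def alpha_summary(p):
            return {
                "alpha_nm": np.mean(np.atleast_1d(p.alpha_nm)).item(),
                "alpha_e": np.mean(np.atleast_1d(p.alpha_e)).item(),
            }

        return {
            "condition": self.condition,
            "n": self.n,
            "loglik": self.fitted.loglik,
            "estimates": alpha_summary(self.fitted.params),
            "tests": [json.loads(t.to_json()) for t in self.tested],
            "cutpoint": self.cutpoint if not isinstance(self.cutpoint, np.generic)
            else self.cutpoint.item(),
            "note": self.note,
            "children": [c.to_dict() for c in self.children],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), default=str)

    def report(self, indent: int = 0) -> str:
        pad = "  " * indent
        est = self.to_dict()["estimates"]
        lines = [
            f"{pad}{self.condition}  (N={self.n}, "
            f"alpha_nm={est['alpha_nm']:.3f}, alpha_e={est['alpha_e']:.3f})"
        ]
        for t in self.tested:
            lines.append(
                f"{pad}  test {t.statistic_name}[{'+'.join(t.subset[:2])}"
                f"{'...' if len(t.subset) > 2 else ''}] = "
                f"{t.statistic_value:.3f}, p = {t.p_value:.4f}"
            )
        if self.note:
            lines.append(f"{pad}  note: {self.note}")
        if self.cutpoint is not None:
            lines.append(f"{pad}  split at: {self.cutpoint}")
        for c in self.children:
            lines.append(c.report(indent + 1))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cutpoint search
# ---------------------------------------------------------------------------

def _ordered_candidates(x: np.ndarray, min_size: int,
                        max_candidates: int | None) -> list:
    """Admissible cuts 'x <= c' between distinct values, both sides >= min."""
    vals, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)
    n = x.size
    ok = (cum >= min_size) & (n - cum >= min_size) & (cum < n)
    cands = vals[ok].tolist()
    if max_candidates is not None and len(cands) > max_candidates:
        idx = np.unique(np.linspace(0, len(cands) - 1, max_candidates).round().astype(int))
        cands = [cands[i] for i in idx]
    return cands


def _categorical_candidates(x: np.ndarray, min_size: int) -> list:
    cats = list(pd.unique(x))
    m = len(cats)
    out = []
    if m <= 6:
        for r in range(1, m // 2 + 1):
            for left in combinations(cats, r):
                if r == m - r and cats[0] not in left:
                    continue  # avoid mirrored duplicates at even splits
                mask = np.isin(x, left)
                if min_size <= mask.sum() <= x.size - min_size:
                    out.append(frozenset(left))
    else:
        # greedy beyond the exhaustive range: grow the left set category by
        # category in order of marginal frequency (documented extension)
        order = sorted(cats, key=lambda c: -(x == c).sum())
        left: list = []
        for c in order[:-1]:
            left.append(c)
            mask = np.isin(x, left)
            if min_size <= mask.sum() <= x.size - min_size:
                out.append(frozenset(left))
    return out


def find_cutpoint(
    pseudo_data: np.ndarray,
    covariate: np.ndarray,
    kind: str = "metric",
    model_spec: ModelSpec | None = None,
    fit_options: FitOptions | None = None,
    options: PartitionOptions | None = None,
    pooled: FittedModel | None = None,
) -> CutpointResult:
    """Locate the covariate value at which the model parameters change.

    Every admissible candidate cut is evaluated by two independent full
    refits; the cut maximizing the summed log-likelihood is returned along
    with the whole profile. Raises ``ValueError`` when no admissible split
    exists.
    """
    options = options or PartitionOptions()
    fit_options = fit_options or FitOptions()
    flat = flatten_pseudo(np.asarray(pseudo_data))
    x = np.asarray(covariate)
    if model_spec is None:
        model_spec = ModelSpec(n_items=flat.shape[1] // 5)

    if kind == "categorical":
        cands = _categorical_candidates(x, options.min_size)
    else:
        cands = _ordered_candidates(x, options.min_size, options.max_candidates)
    if not cands:
        raise ValueError(
            f"no admissible split: no cut leaves {options.min_size} or more "
            "persons on both sides"
        )

    init = None
    side_opts = fit_options
    if options.warm_start or options.profile == "fixed_sigma":
        if pooled is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NonConvergenceWarning)
                pooled = fit_irtree(flat, model_spec, fit_options)
        init = pooled.params
    if options.profile == "fixed_sigma":
        side_opts = FitOptions(
            method=fit_options.method,
            quad_points_per_dim=fit_options.quad_points_per_dim,
            tol=fit_options.tol, max_iter=fit_options.max_iter,
            seed=fit_options.seed, m_step_maxiter=fit_options.m_step_maxiter,
            min_persons=min(fit_options.min_persons, options.min_size),
            fix_sigma=True,
        )
    elif options.profile != "exact":
        raise ValueError(f"unknown profile mode {options.profile!r}")

    rows = []
    best = None
    for cut in cands:
        if kind == "categorical":
            left = np.isin(x, list(cut))
            z = np.where(left, 0, 1)  # reduce to an ordered pseudo-covariate
            total, fl, fr = loglik_profile_at_split(
                flat, z, 0, model_spec, side_opts, options.min_size, init=init
            )
        else:
            left = x <= cut
            total, fl, fr = loglik_profile_at_split(
                flat, x, cut, model_spec, side_opts, options.min_size, init=init
            )
        rows.append({"cut": set(cut) if kind == "categorical" else cut,
                     "loglik_sum": total,
                     "converged": fl.converged and fr.converged})
        if best is None or total > best[1]:
            best = (cut, total, fl, fr, left)

    cut, total, fl, fr, left = best
    return CutpointResult(
        cutpoint=set(cut) if kind == "categorical" else cut,
        loglik_sum=total,
        profile=pd.DataFrame(rows),
        fit_left=fl, fit_right=fr, left_mask=left,
    )


# ---------------------------------------------------------------------------
# Recursive partitioning
# ---------------------------------------------------------------------------

def partition(
    pseudo_data: np.ndarray,
    covariate: np.ndarray,
    kind: str = "metric",
    subsets=("alpha_nm", "alpha_e"),
    model_spec: ModelSpec | None = None,
    fit_options: FitOptions | None = None,
    options: PartitionOptions | None = None,
    covariate_name: str = "covariate",
) -> PartitionNode:
    """Recursive score-based partitioning of the sample.

    At each node the requested parameter subsets are tested with the
    covariate-appropriate statistic; if the smallest p-value is below
    ``options.level`` the node is split at :func:`find_cutpoint` and the
    children are retested (by default only on the subsets that triggered
    the split). The returned tree records every fit and test.
    """
    options = options or PartitionOptions()
    fit_options = fit_options or FitOptions()
    flat = flatten_pseudo(np.asarray(pseudo_data))
    if model_spec is None:
        model_spec = ModelSpec(n_items=flat.shape[1] // 5)
    return _grow(
        flat, np.asarray(covariate), kind, list(subsets), model_spec,
        fit_options, options, covariate_name,
        condition=f"{covariate_name}: all", depth=0,
    )


def _grow(flat, x, kind, subsets, model_spec, fit_options, options,
          covariate_name, condition, depth) -> PartitionNode:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonConvergenceWarning)
        fitted = fit_irtree(flat, model_spec, fit_options)
    node = PartitionNode(condition=condition, n=flat.shape[0], fitted=fitted)
    if not fitted.converged:
        node.note = "fit did not converge"

    if depth >= options.max_depth:
        node.note = (node.note + "; " if node.note else "") + "max depth reached"
        return node
    if len(pd.unique(x)) < 2:
        node.note = (node.note + "; " if node.note else "") + "constant covariate"
        return node

    stat = options.statistic_name or DEFAULT_STATISTIC[kind]
    from .score_process import score_contributions

    shared_scores = score_contributions(fitted, flat)
    for sub in subsets:
        res = sctest(
            fitted, flat, x, kind, subset=sub, statistic_name=stat,
            covariate_name=covariate_name, nsim=options.nsim,
            seed=options.seed, scores=shared_scores,
        )
        node.tested.append(res)
    best = min(node.tested, key=lambda r: r.p_value)
    node.test = best
    if best.p_value >= options.level:
        return node

    try:
        cut = find_cutpoint(
            flat, x, kind, model_spec, fit_options, options, pooled=fitted
        )
    except ValueError:
        node.note = (node.note + "; " if node.note else "") + "no admissible split"
        return node

    node.cutpoint = cut.cutpoint
    if options.retest_all_subsets:
        triggering = subsets
    else:
        triggering = [
            sub for sub, r in zip(subsets, node.tested) if r.p_value < options.level
        ]
    left = cut.left_mask
    if kind == "categorical":
        cond_l = f"{covariate_name} in {sorted(map(str, cut.cutpoint))}"
        cond_r = f"{covariate_name} not in {sorted(map(str, cut.cutpoint))}"
    else:
        cond_l = f"{covariate_name} <= {cut.cutpoint}"
        cond_r = f"{covariate_name} > {cut.cutpoint}"
    for mask, cond in ((left, cond_l), (~left, cond_r)):
        child = _grow(
            flat[mask], x[mask], kind, triggering, model_spec, fit_options,
            options, covariate_name, condition=cond, depth=depth + 1,
        )
        node.children.append(child)
    return node
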