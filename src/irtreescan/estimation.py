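"""Marginal maximum likelihood estimation of IRTree models.

The latent vector x = (traits..., eta_nm, eta_e) is integrated out on a
fixed Gauss-Hermite grid placed in standardized space: z follows the grid
of a standard normal and x = L z with L the Cholesky factor of the latent
covariance Sigma. Because the grid lives in z-space, Sigma is an ordinary
smooth parameter of the (quadrature-approximated) marginal likelihood and
EM is exactly monotone.

Identification follows the usual IRTree conventions: latent means are fixed
at 0 and

* constant-loading (Rasch style) variant - the trait loading at the
  agreement node and both response-style loadings are fixed at 1, Sigma is
  fully free;
* item-specific variant - loadings are free at all five nodes per item and
  each trait dimension's variance is fixed at 1 (style variances stay free).

The default estimator is a quadrature-EM algorithm (deterministic and
reproducible); a stochastic-approximation alternative in the spirit of
Metropolis-Hastings Robbins-Monro is available via ``method="sa"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .tree_model import (
    SIX_POINT_TREE,
    IRTreeParams,
    ParamVector,
    TreeSpec,
    flatten_pseudo,
)

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FittedModel",
    "NonConvergenceWarning",
    "fit_irtree",
    "person_loglik",
    "marginal_loglik",
    "score_contributions_at",
    "loglik_profile_at_split",
]


class NonConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Specifications and options
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Structural layout of the model: trait space and loading variant."""

    n_items: int
    n_traits: int = 1
    item_trait_map: np.ndarray | None = None
    item_specific: bool = False
    tree: TreeSpec = field(default_factory=lambda: SIX_POINT_TREE)

    def __post_init__(self):
        if self.item_trait_map is None:
            self.item_trait_map = np.zeros(self.n_items, dtype=int)
        else:
            self.item_trait_map = np.asarray(self.item_trait_map, dtype=int)

    @property
    def n_dims(self) -> int:
        return self.n_traits + 2


@dataclass
class FitOptions:
    """Options of the marginal-ML fit.

    ``quad_points_per_dim`` defaults to 11 for up to three latent
    dimensions and 7 for four or more. Convergence is declared when the
    largest absolute change of any structural parameter (loadings,
    intercepts, Sigma entries) drops below ``tol``.
    """

    method: str = "em"  # "em" (quadrature EM) or "sa" (stochastic approximation)
    quad_points_per_dim: int | None = None
    tol: float = 1e-3
    max_iter: int = 500
    seed: int | None = None
    m_step_maxiter: int = 40
    min_persons: int = 50
    fix_sigma: bool = False

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.quad_points_per_dim is not None and self.quad_points_per_dim < 3:
            raise ValueError("quad_points_per_dim must be >= 3")
        if self.method not in ("em", "sa"):
            raise ValueError(f"unknown method {self.method!r}")

    def resolve_quad(self, n_dims: int) -> int:
        if self.quad_points_per_dim is not None:
            return self.quad_points_per_dim
        return 11 if n_dims <= 3 else 7


@dataclass
class FittedModel:
    """Result of a marginal-ML fit."""

    params: IRTreeParams
    spec: ModelSpec
    loglik: float
    n_persons: int
    converged: bool
    n_iter: int
    method: str
    options: FitOptions
    grad_norm: float
    loglik_path: np.ndarray

    @property
    def psi_hat(self) -> ParamVector:
        return self.params.to_psi()

    @property
    def sigma_hat(self) -> np.ndarray:
        return self.params.sigma

    def to_json(self) -> str:
        return json.dumps({
            "params": json.loads(self.params.to_json()),
            "loglik": self.loglik,
            "n_persons": self.n_persons,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "method": self.method,
            "grad_norm": self.grad_norm,
            "n_traits": self.spec.n_traits,
            "item_specific": self.spec.item_specific,
        })

    @classmethod
    def from_json(cls, s: str) -> "FittedModel":
        d = json.loads(s)
        params = IRTreeParams.from_json(json.dumps(d["params"]))
        spec = ModelSpec(
            n_items=params.n_items, n_traits=d["n_traits"],
            item_trait_map=params.item_trait_map,
            item_specific=d["item_specific"],
        )
        return cls(
            params=params, spec=spec, loglik=d["loglik"],
            n_persons=d["n_persons"], converged=d["converged"],
            n_iter=d["n_iter"], method=d["method"], options=FitOptions(),
            grad_norm=d["grad_norm"], loglik_path=np.array([]),
        )


# ---------------------------------------------------------------------------
# Internal design / quadrature machinery
# ---------------------------------------------------------------------------

class _Design:
    """Index bookkeeping for the J = 5*I pseudo-items."""

    def __init__(self, spec: ModelSpec):
        I = spec.n_items
        self.spec = spec
        self.J = 5 * I
        self.item_of = np.repeat(np.arange(I), 5)
        self.node_of = np.tile(np.arange(1, 6), I)
        self.trait_dim = spec.item_trait_map[self.item_of]
        # style dimension: eta_nm for nodes 2/3, eta_e for nodes 4/5
        self.style_dim = np.full(self.J, -1)
        self.style_dim[np.isin(self.node_of, (2, 3))] = spec.n_traits
        self.style_dim[np.isin(self.node_of, (4, 5))] = spec.n_traits + 1
        # sign of the trait coefficient: disagree-side nodes get -alpha
        self.sign = np.where(np.isin(self.node_of, (2, 4)), -1.0, 1.0)
        # which loading family each node belongs to
        self.family = np.array(
            ["alpha_1", "alpha_nm", "alpha_nm", "alpha_e", "alpha_e"]
        )[self.node_of - 1]

    def loading_matrix(self, params: IRTreeParams) -> np.ndarray:
        """J x D loading matrix of the pseudo-items on the latent dims."""
        D = self.spec.n_dims
        M = np.zeros((self.J, D))
        for fam in ("alpha_1", "alpha_nm", "alpha_e"):
            sel = self.family == fam
            a = getattr(params, fam)
            av = a[self.item_of[sel]] if np.ndim(a) else float(a)
            M[sel, self.trait_dim[sel]] = self.sign[sel] * av
        has_style = self.style_dim >= 0
        M[has_style, self.style_dim[has_style]] = 1.0
        return M


def _gh_grid(n_dims: int, n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor Gauss-Hermite grid for a standard normal in n_dims."""
    x, w = np.polynomial.hermite_e.hermegauss(n_points)
    w = w / w.sum()
    grids = np.meshgrid(*([x] * n_dims), indexing="ij")
    Z = np.stack([g.ravel() for g in grids], axis=1)
    lw = np.meshgrid(*([np.log(w)] * n_dims), indexing="ij")
    logw = sum(g.ravel() for g in lw)
    return Z, logw


class _CholParam:
    """Pack/unpack of the Cholesky factor L of Sigma.

    Rows of L corresponding to dimensions with a fixed unit variance (the
    trait dimensions of the item-specific variant) are parameterized as
    (v, 1)/sqrt(1+|v|^2); free rows carry raw off-diagonal entries plus a
    log-diagonal.
    """

    def __init__(self, n_dims: int, fixed_var: np.ndarray):
        self.D = n_dims
        self.fixed_var = fixed_var
        self.n_free = sum(
            (d if fixed_var[d] else d + 1) for d in range(n_dims)
        )

    def pack(self, L: np.ndarray) -> np.ndarray:
        out = []
        for d in range(self.D):
            row = L[d, : d + 1]
            if self.fixed_var[d]:
                out.extend(row[:d] / row[d])  # recover raw v from normalized row
            else:
                out.extend(row[:d])
                out.append(np.log(row[d]))
        return np.array(out)

    def unpack(self, vec: np.ndarray) -> np.ndarray:
        L = np.zeros((self.D, self.D))
        i = 0
        for d in range(self.D):
            if self.fixed_var[d]:
                v = vec[i : i + d]
                i += d
                u = np.concatenate([v, [1.0]])
                L[d, : d + 1] = u / np.sqrt(1.0 + v @ v)
            else:
                L[d, :d] = vec[i : i + d]
                L[d, d] = np.exp(vec[i + d])
                i += d + 1
        return L

    def grad(self, vec: np.ndarray, dL: np.ndarray) -> np.ndarray:
        """Chain-rule a gradient w.r.t. L into the packed parameterization."""
        g = np.zeros_like(vec)
        i = 0
        for d in range(self.D):
            if self.fixed_var[d]:
                v = vec[i : i + d]
                u = np.concatenate([v, [1.0]])
                s = np.sqrt(1.0 + v @ v)
                drow = dL[d, : d + 1]
                g[i : i + d] = drow[:d] / s - (drow @ u) * v / s**3
                i += d
            else:
                g[i : i + d] = dL[d, :d]
                g[i + d] = dL[d, d] * np.exp(vec[i + d])
                i += d + 1
        return g


class _Packer:
    """Flat optimizer vector <-> (loadings, intercepts, L)."""

    def __init__(self, design: _Design, fix_sigma: bool):
        spec = design.spec
        self.design = design
        self.fix_sigma = fix_sigma
        self.item_specific = spec.item_specific
        I = spec.n_items
        self.n_alpha = 3 * I if self.item_specific else 2
        self.n_delta = design.J
        fixed_var = np.zeros(spec.n_dims, dtype=bool)
        if self.item_specific:
            fixed_var[: spec.n_traits] = True
        self.chol = _CholParam(spec.n_dims, fixed_var)
        self.n_L = 0 if fix_sigma else self.chol.n_free

    def pack(self, params: IRTreeParams) -> np.ndarray:
        I = params.n_items
        if self.item_specific:
            head = np.concatenate([
                np.broadcast_to(np.atleast_1d(params.alpha_1), (I,)).astype(float),
                np.atleast_1d(params.alpha_nm).astype(float),
                np.atleast_1d(params.alpha_e).astype(float),
            ])
        else:
            head = np.array([float(params.alpha_nm), float(params.alpha_e)])
        parts = [head, params.delta.ravel()]
        if not self.fix_sigma:
            parts.append(self.chol.pack(np.linalg.cholesky(params.sigma)))
        return np.concatenate(parts)

    def unpack(self, vec: np.ndarray, template: IRTreeParams) -> IRTreeParams:
        out = template.copy()
        I = template.n_items
        if self.item_specific:
            out.alpha_1 = vec[:I].copy()
            out.alpha_nm = vec[I : 2 * I].copy()
            out.alpha_e = vec[2 * I : 3 * I].copy()
        else:
            out.alpha_nm, out.alpha_e = float(vec[0]), float(vec[1])
        off = self.n_alpha
        out.delta = vec[off : off + self.n_delta].reshape(I, 5).copy()
        if not self.fix_sigma:
            L = self.chol.unpack(vec[off + self.n_delta :])
            out.sigma = L @ L.T
        return out

    def split(self, vec: np.ndarray):
        off = self.n_alpha
        return vec[:off], vec[off : off + self.n_delta], vec[off + self.n_delta :]

    def natural(self, vec: np.ndarray, template: IRTreeParams) -> np.ndarray:
        """Natural-scale vector (alphas, deltas, Sigma entries) for the
        convergence check."""
        p = self.unpack(vec, template)
        head = [np.atleast_1d(p.alpha_nm), np.atleast_1d(p.alpha_e)]
        if self.item_specific:
            head.insert(0, np.atleast_1d(p.alpha_1))
        return np.concatenate([*head, p.delta.ravel(), p.sigma.ravel()])


def _masks(pseudo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    flat = flatten_pseudo(pseudo)
    A = (flat == 1).astype(float)
    B = (flat == 0).astype(float)
    return A, B


def _check_pseudo_items(A: np.ndarray, B: np.ndarray, design: _Design) -> None:
    ones = A.sum(axis=0)
    zeros = B.sum(axis=0)
    bad = np.where((ones == 0) | (zeros == 0))[0]
    if bad.size:
        j = bad[0]
        item, node = design.item_of[j], design.node_of[j]
        kind = "never observed" if ones[j] + zeros[j] == 0 else (
            "always 1" if zeros[j] == 0 else "always 0"
        )
        raise ValueError(
            f"degenerate pseudo-item Y{node} of item {item}: {kind}"
        )


def _node_logliks(M, delta, L, Z, A, B):
    """Conditional Bernoulli log-likelihood of every person at every node.

    Returns (ll (N x Q), eta (J x Q)).
    """
    X = Z @ L.T
    eta = M @ X.T + delta[:, None]
    logp = -np.logaddexp(0.0, -eta)
    log1mp = -np.logaddexp(0.0, eta)
    ll = A @ logp + B @ log1mp
    return ll, eta, X


def _e_step(M, delta, L, Z, logw, A, B):
    ll, eta, X = _node_logliks(M, delta, L, Z, A, B)
    lw = ll + logw[None, :]
    per = logsumexp(lw, axis=1)
    W = np.exp(lw - per[:, None])
    return per, W, eta, X


def _mstep_objective(vec, packer: _Packer, template, design, Z, n1, n0, L_fixed):
    spec = design.spec
    _, d_vec, l_vec = packer.split(vec)
    params = packer.unpack(vec, template)
    M = design.loading_matrix(params)
    L = L_fixed if packer.fix_sigma else packer.chol.unpack(l_vec)
    X = Z @ L.T
    eta = M @ X.T + d_vec[:, None]
    logp = -np.logaddexp(0.0, -eta)
    log1mp = -np.logaddexp(0.0, eta)
    f = float(np.sum(n1 * logp) + np.sum(n0 * log1mp))
    P = expit(eta)
    r = n1 - (n1 + n0) * P  # J x Q
    g_delta = r.sum(axis=1)
    dM = r @ X  # J x D
    # chain to the loading parameters
    tvals = dM[np.arange(design.J), design.trait_dim] * design.sign
    if packer.item_specific:
        I = spec.n_items
        g_alpha = np.zeros(3 * I)
        for k, fam in enumerate(("alpha_1", "alpha_nm", "alpha_e")):
            sel = design.family == fam
            g_alpha[k * I : (k + 1) * I] = np.bincount(
                design.item_of[sel], weights=tvals[sel], minlength=I
            )
    else:
        g_alpha = np.array([
            tvals[design.family == "alpha_nm"].sum(),
            tvals[design.family == "alpha_e"].sum(),
        ])
    grads = [g_alpha, g_delta]
    if not packer.fix_sigma:
        dX = r.T @ M  # Q x D
        dL = dX.T @ Z  # D x D
        dL = np.tril(dL)
        grads.append(packer.chol.grad(l_vec, dL))
    g = np.concatenate(grads)
    return -f, -g


def _init_params(spec: ModelSpec, A, B) -> IRTreeParams:
    obs = A.sum(0) + B.sum(0)
    frac = np.where(obs > 0, A.sum(0) / np.maximum(obs, 1.0), 0.5)
    delta = np.log(np.clip(frac, 0.02, 0.98) / (1 - np.clip(frac, 0.02, 0.98)))
    I = spec.n_items
    sigma = np.eye(spec.n_dims)
    if spec.item_specific:
        return IRTreeParams(
            alpha_nm=np.full(I, 0.5), alpha_e=np.full(I, 0.5),
            alpha_1=np.full(I, 1.0), delta=delta.reshape(I, 5),
            sigma=sigma, item_trait_map=spec.item_trait_map,
            n_traits=spec.n_traits,
        )
    return IRTreeParams(
        alpha_nm=0.5, alpha_e=0.5, alpha_1=1.0, delta=delta.reshape(I, 5),
        sigma=sigma, item_trait_map=spec.item_trait_map, n_traits=spec.n_traits,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_irtree(
    pseudo_data: np.ndarray,
    model_spec: ModelSpec | None = None,
    options: FitOptions | None = None,
    init: IRTreeParams | None = None,
) -> FittedModel:
    """Fit the IRTree model by marginal maximum likelihood.

    ``pseudo_data`` is the expanded (N, I, 5) pseudo-response array (or its
    flat (N, 5I) form). Latent means are fixed at 0; the latent covariance
    is freely estimated unless ``options.fix_sigma`` is set, in which case
    it is held at its value in ``init``.

    Non-convergence within ``max_iter`` yields a flagged result plus a
    :class:`NonConvergenceWarning`, not an exception. A pseudo-item with
    only one observed outcome raises a :class:`ValueError` naming it.
    """
    options = options or FitOptions()
    flat = flatten_pseudo(np.asarray(pseudo_data))
    N = flat.shape[0]
    if model_spec is None:
        model_spec = ModelSpec(n_items=flat.shape[1] // 5)
    if flat.shape[1] != 5 * model_spec.n_items:
        raise ValueError("pseudo data width does not match 5 * n_items")
    if N < options.min_persons:
        raise ValueError(
            f"N={N} is below the supported minimum of {options.min_persons} persons"
        )
    design = _Design(model_spec)
    A, B = _masks(flat)
    _check_pseudo_items(A, B, design)
    if options.fix_sigma and init is None:
        raise ValueError("fix_sigma requires an init with the Sigma to hold fixed")
    template = init.copy() if init is not None else _init_params(model_spec, A, B)

    if options.method == "sa":
        return _fit_sa(flat, A, B, design, template, options)

    n_quad = options.resolve_quad(model_spec.n_dims)
    Z, logw = _gh_grid(model_spec.n_dims, n_quad)
    packer = _Packer(design, fix_sigma=options.fix_sigma)
    L_fixed = np.linalg.cholesky(template.sigma)
    vec = packer.pack(template)
    if options.fix_sigma:
        vec = vec[: packer.n_alpha + packer.n_delta]
    nat = packer.natural(vec, template)

    loglik_path = []
    converged = False
    n_iter = 0
    for it in range(1, options.max_iter + 1):
        n_iter = it
        params = packer.unpack(vec, template)
        M = design.loading_matrix(params)
        L = np.linalg.cholesky(params.sigma)
        per, W, _, _ = _e_step(M, params.delta.ravel(), L, Z, logw, A, B)
        loglik_path.append(per.sum())
        n1 = A.T @ W
        n0 = B.T @ W
        res = minimize(
            _mstep_objective, vec, jac=True, method="L-BFGS-B",
            args=(packer, template, design, Z, n1, n0, L_fixed),
            options={"maxiter": options.m_step_maxiter},
        )
        vec = res.x
        nat_new = packer.natural(vec, template)
        delta_max = np.max(np.abs(nat_new - nat))
        nat = nat_new
        if delta_max < options.tol:
            converged = True
            break

    params = packer.unpack(vec, template)
    M = design.loading_matrix(params)
    L = np.linalg.cholesky(params.sigma)
    per, W, eta, X = _e_step(M, params.delta.ravel(), L, Z, logw, A, B)
    loglik = float(per.sum())
    loglik_path.append(loglik)
    scores = _person_scores(params, design, A, B, W, eta, X)
    grad_norm = float(np.linalg.norm(scores.sum(axis=0)))

    if not converged:
        warnings.warn(
            f"EM did not converge within {options.max_iter} iterations "
            f"(last max parameter change above tol={options.tol})",
            NonConvergenceWarning,
        )
    neg = []
    for name in ("alpha_nm", "alpha_e"):
        if np.any(np.atleast_1d(getattr(params, name)) < 0):
            neg.append(name)
    if neg:
        warnings.warn(
            f"estimated loading(s) {', '.join(neg)} negative; the model assumes "
            "positive trait loadings at the nonmoderate/extreme nodes",
            UserWarning,
        )
    return FittedModel(
        params=params, spec=model_spec, loglik=loglik, n_persons=N,
        converged=converged, n_iter=n_iter, method=options.method,
        options=options, grad_norm=grad_norm,
        loglik_path=np.asarray(loglik_path),
    )


def _fit_sa(flat, A, B, design, template, options: FitOptions) -> FittedModel:
    """Stochastic-approximation fit: Metropolis-Hastings imputation of the
    latent vectors with a Robbins-Monro averaged M-step (an MHRM-style
    alternative to quadrature EM)."""
    rng = np.random.default_rng(options.seed)
    spec = design.spec
    N, D = flat.shape[0], spec.n_dims
    params = template.copy()
    X = rng.standard_normal((N, D))
    tau = 1.0
    packer = _Packer(design, fix_sigma=True)
    vec = packer.pack(params)[: packer.n_alpha + packer.n_delta]
    avg_vec, avg_sigma, n_avg = None, None, 0
    burnin = max(20, options.max_iter // 3)

    def cond_loglik(params, Xcur):
        M = design.loading_matrix(params)
        eta = Xcur @ M.T + params.delta.ravel()[None, :]
        ll = np.sum(A * -np.logaddexp(0.0, -eta), axis=1)
        ll += np.sum(B * -np.logaddexp(0.0, eta), axis=1)
        return ll

    sigma_inv = np.linalg.inv(params.sigma)
    cur_ll = cond_loglik(params, X) - 0.5 * np.einsum("nd,de,ne->n", X, sigma_inv, X)
    for it in range(1, options.max_iter + 1):
        for _ in range(3):
            prop = X + tau * rng.standard_normal((N, D))
            prop_ll = cond_loglik(params, prop) - 0.5 * np.einsum(
                "nd,de,ne->n", prop, sigma_inv, prop
            )
            acc = np.log(rng.random(N)) < prop_ll - cur_ll
            X[acc] = prop[acc]
            cur_ll[acc] = prop_ll[acc]
            rate = acc.mean()
            if it <= burnin:
                tau *= 1.1 if rate > 0.45 else 0.9
        # complete-data M-step: logistic part via the shared objective with
        # the sampled latents as "nodes", Sigma in closed form
        n1 = A.T.copy()
        n0 = B.T.copy()
        res = minimize(
            _mstep_objective, vec, jac=True, method="L-BFGS-B",
            args=(packer, params, design, X, n1, n0, np.eye(D)),
            options={"maxiter": 15},
        )
        gain = 1.0 if it <= burnin else 1.0 / (it - burnin)
        vec = vec + gain * (res.x - vec)
        sigma_new = (X.T @ X) / N
        params = packer.unpack(vec, params)
        params.sigma = params.sigma + gain * (sigma_new - params.sigma)
        sigma_inv = np.linalg.inv(params.sigma)
        cur_ll = cond_loglik(params, X) - 0.5 * np.einsum(
            "nd,de,ne->n", X, sigma_inv, X
        )

    # evaluate the marginal loglik of the SA solution on the quadrature grid
    n_quad = options.resolve_quad(D)
    Z, logw = _gh_grid(D, n_quad)
    M = design.loading_matrix(params)
    L = np.linalg.cholesky(params.sigma)
    per, W, eta, Xq = _e_step(M, params.delta.ravel(), L, Z, logw, A, B)
    scores = _person_scores(params, design, A, B, W, eta, Xq)
    return FittedModel(
        params=params, spec=spec, loglik=float(per.sum()), n_persons=N,
        converged=True, n_iter=options.max_iter, method="sa", options=options,
        grad_norm=float(np.linalg.norm(scores.sum(axis=0))),
        loglik_path=np.array([float(per.sum())]),
    )


# ---------------------------------------------------------------------------
# Marginal log-likelihood and per-person quantities
# ---------------------------------------------------------------------------

def _prepare(fitted_or_params, spec=None, options=None):
    if isinstance(fitted_or_params, FittedModel):
        params = fitted_or_params.params
        spec = fitted_or_params.spec
        options = fitted_or_params.options
    else:
        params = fitted_or_params
        if spec is None:
            spec = ModelSpec(
                n_items=params.n_items, n_traits=params.n_traits,
                item_trait_map=params.item_trait_map,
                item_specific=params.item_specific,
            )
        options = options or FitOptions()
    design = _Design(spec)
    Z, logw = _gh_grid(spec.n_dims, options.resolve_quad(spec.n_dims))
    return params, spec, design, Z, logw


def marginal_loglik(
    params: IRTreeParams,
    pseudo_data: np.ndarray,
    spec: ModelSpec | None = None,
    options: FitOptions | None = None,
) -> tuple[float, np.ndarray]:
    """Marginal log-likelihood (total, per person) at arbitrary parameters.

    Uses the same fixed Gauss-Hermite rule as fitting, so per-person values
    sum exactly to the total reported by :func:`fit_irtree`.
    """
    params, spec, design, Z, logw = _prepare(params, spec, options)
    A, B = _masks(np.asarray(pseudo_data))
    M = design.loading_matrix(params)
    L = np.linalg.cholesky(params.sigma)
    per, _, _, _ = _e_step(M, params.delta.ravel(), L, Z, logw, A, B)
    return float(per.sum()), per


def person_loglik(fitted: FittedModel, pseudo_row: np.ndarray) -> float:
    """Marginal log-likelihood of a single person under a fitted model.

    A person with no observed responses contributes an empty product,
    i.e. 0.
    """
    row = np.asarray(pseudo_row).reshape(1, -1)
    _, per = marginal_loglik(fitted.params, row, fitted.spec, fitted.options)
    return float(per[0])


def _person_scores(params, design, A, B, W, eta, X) -> np.ndarray:
    """N x p score contributions w.r.t. the item parameters (Psi order)."""
    P = expit(eta)  # J x Q
    obs = A + B
    Pbar = W @ P.T  # N x J
    s_delta = A - obs * Pbar
    # trait-coordinate of each pseudo-item at each node, signed
    C = design.sign[:, None] * X[:, design.trait_dim].T  # J x Q
    WX = W @ X  # N x D
    t1 = A * (design.sign[None, :] * WX[:, design.trait_dim])
    t2 = obs * (W @ (C * P).T)
    s_load = t1 - t2  # N x J, contribution to the loading of pseudo-item j
    spec = design.spec
    I = spec.n_items
    cols = []
    if spec.item_specific:
        for fam in ("alpha_1", "alpha_nm", "alpha_e"):
            sel = design.family == fam
            block = np.zeros((A.shape[0], I))
            items = design.item_of[sel]
            np.add.at(block.T, items, s_load[:, sel].T)
            cols.append(block)
    else:
        for fam in ("alpha_nm", "alpha_e"):
            sel = design.family == fam
            cols.append(s_load[:, sel].sum(axis=1, keepdims=True))
    cols.append(s_delta)
    return np.concatenate(cols, axis=1)


def score_contributions_at(
    params: IRTreeParams,
    pseudo_data: np.ndarray,
    spec: ModelSpec | None = None,
    options: FitOptions | None = None,
) -> np.ndarray:
    """Per-person gradients of the marginal log-likelihood w.r.t. Psi.

    Valid at any parameter value (Fisher's identity: the marginal score is
    the posterior expectation of the complete-data score); at the MLE the
    columns sum to approximately zero.
    """
    params, spec, design, Z, logw = _prepare(params, spec, options)
    A, B = _masks(np.asarray(pseudo_data))
    M = design.loading_matrix(params)
    L = np.linalg.cholesky(params.sigma)
    _, W, eta, X = _e_step(M, params.delta.ravel(), L, Z, logw, A, B)
    return _person_scores(params, design, A, B, W, eta, X)


# ---------------------------------------------------------------------------
# Split profile
# ---------------------------------------------------------------------------

def loglik_profile_at_split(
    pseudo_data: np.ndarray,
    covariate: np.ndarray,
    cutvalue,
    model_spec: ModelSpec | None = None,
    options: FitOptions | None = None,
    min_size: int = 300,
    init: IRTreeParams | None = None,
) -> tuple[float, FittedModel, FittedModel]:
    """Refit the model independently on {covariate <= cut} and the rest.

    All item parameters (and Sigma, unless ``options.fix_sigma``) are free
    to differ between the sides; returns the summed log-likelihood and the
    two fits. ``init`` warm-starts both side fits (typically the pooled
    estimate).
    """
    flat = flatten_pseudo(np.asarray(pseudo_data))
    covariate = np.asarray(covariate)
    left = covariate <= cutvalue
    n_left, n_right = int(left.sum()), int((~left).sum())
    if n_left < min_size or n_right < min_size:
        raise ValueError(
            f"split at {cutvalue!r} leaves sides of {n_left} and {n_right} "
            f"persons; both must have at least {min_size}"
        )
    opts = options or FitOptions()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonConvergenceWarning)
        fit_l = fit_irtree(flat[left], model_spec, opts, init=init)
        fit_r = fit_irtree(flat[~left], model_spec, opts, init=init)
    return fit_l.loglik + fit_r.loglik, fit_l, fit_r
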