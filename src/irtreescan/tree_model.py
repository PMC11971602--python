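"""IRTree model structure for Likert responses with response styles.

A six-point Likert response (categories 0-5) is decomposed into a sequence
of binary decisions: agreement vs. disagreement, nonmoderate vs. moderate,
and extreme vs. nonextreme. Each decision node is a binary pseudo-item with
a logistic IRT parameterization. The substantive trait ``theta`` drives the
agreement node directly and enters the nonmoderate/extreme nodes with
loadings ``alpha_nm`` / ``alpha_e`` and branch-dependent sign; the response
styles ``eta_nm`` (nonmoderate responding) and ``eta_e`` (extreme
responding) load on their nodes with fixed weight 1.

Node equations (item i, person v)::

    p(Y1=1) = logistic( alpha_1 * theta            + delta_1i )   agree
    p(Y2=1) = logistic( eta_nm - alpha_nm * theta  + delta_2i )   nonmoderate | disagree
    p(Y3=1) = logistic( eta_nm + alpha_nm * theta  + delta_3i )   nonmoderate | agree
    p(Y4=1) = logistic( eta_e  - alpha_e  * theta  + delta_4i )   extreme | nonmoderate disagree
    p(Y5=1) = logistic( eta_e  + alpha_e  * theta  + delta_5i )   extreme | nonmoderate agree

Category probabilities are products of node probabilities along the branch
of the tree that terminates in the category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "STRUCTURAL_MISSING",
    "PERSON_MISSING",
    "TreeSpec",
    "SIX_POINT_TREE",
    "register_tree",
    "get_tree",
    "LatentPerson",
    "IRTreeParams",
    "ParamVector",
    "expand_responses",
    "flatten_pseudo",
    "node_probabilities",
    "category_probabilities",
]

# Pseudo-response codes. Structural missingness (node not on the observed
# branch) is distinct from person-level missingness (no response at all);
# both are excluded from likelihood terms, but only the latter is ordinary
# missing data.
STRUCTURAL_MISSING: int = -1
PERSON_MISSING: int = -2


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Tree specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSpec:
    """Decision-tree mapping from response categories to node outcomes.

    ``branch_table[c]`` gives, for category ``c``, the ordered outcomes on
    the nodes Y1..Y{n_nodes}; ``None`` marks a node that is not on the
    category's branch (structurally missing in the expanded data).
    """

    n_categories: int
    n_nodes: int
    branch_table: Mapping[int, tuple]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        cats = set(self.branch_table)
        if cats != set(range(self.n_categories)):
            raise ValueError(
                f"branch table categories {sorted(cats)} do not cover "
                f"0..{self.n_categories - 1}"
            )
        seen = set()
        for c, branch in self.branch_table.items():
            if len(branch) != self.n_nodes:
                raise ValueError(f"category {c}: branch length {len(branch)} != {self.n_nodes}")
            for o in branch:
                if o not in (0, 1, None):
                    raise ValueError(f"category {c}: invalid node outcome {o!r}")
            key = tuple(branch)
            if key in seen:
                raise ValueError(f"category {c}: duplicate branch {key}")
            seen.add(key)

    def expand_one(self, category: int) -> np.ndarray:
        """Pseudo-responses (int8 codes) for one observed category."""
        branch = self.branch_table[int(category)]
        return np.array(
            [STRUCTURAL_MISSING if o is None else o for o in branch], dtype=np.int8
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_categories": self.n_categories,
                "n_nodes": self.n_nodes,
                "branch_table": {str(c): list(b) for c, b in self.branch_table.items()},
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TreeSpec":
        d = json.loads(s)
        table = {int(c): tuple(None if o is None else int(o) for o in b)
                 for c, b in d["branch_table"].items()}
        return cls(d["n_categories"], d["n_nodes"], table)


#: The six-category tree: node 1 separates disagreement (0,1,2) from
#: agreement (3,4,5); nodes 2/3 separate moderate (2 resp. 3) from
#: nonmoderate; nodes 4/5 separate nonextreme (1 resp. 4) from extreme
#: (0 resp. 5).
SIX_POINT_TREE = TreeSpec(
    n_categories=6,
    n_nodes=5,
    branch_table={
        0: (0, 1, None, 1, None),
        1: (0, 1, None, 0, None),
        2: (0, 0, None, None, None),
        3: (1, None, 0, None, None),
        4: (1, None, 1, None, 0),
        5: (1, None, 1, None, 1),
    },
)

_TREE_REGISTRY: dict[str, TreeSpec] = {"six_point": SIX_POINT_TREE}


def register_tree(name: str, spec: TreeSpec) -> None:
    """Register an alternate tree (e.g. for 4/5/7-point scales).

    Only the six-category tree ships with validated tests; registered trees
    are the caller's responsibility.
    """
    _TREE_REGISTRY[name] = spec


def get_tree(name: str = "six_point") -> TreeSpec:
    return _TREE_REGISTRY[name]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LatentPerson:
    """Latent values of one person: trait(s) plus the two response styles."""

    theta: np.ndarray  # (n_traits,)
    eta_nm: float
    eta_e: float

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))

    def as_vector(self) -> np.ndarray:
        """Latent vector ordered (traits..., eta_nm, eta_e)."""
        return np.concatenate([self.theta, [self.eta_nm, self.eta_e]])


@dataclass
class IRTreeParams:
    """Structural parameters of the IRTree model.

    ``alpha_nm``/``alpha_e`` are scalars in the constant-loading (Rasch
    style) variant or per-item arrays in the item-specific variant;
    ``alpha_1`` is the trait loading at the agreement node (fixed to 1 in
    the Rasch-style variant). ``delta`` holds the five intercepts per item,
    ``sigma`` the latent covariance over (traits..., eta_nm, eta_e), and
    ``item_trait_map`` assigns each item its trait dimension.
    """

    alpha_nm: float | np.ndarray
    alpha_e: float | np.ndarray
    delta: np.ndarray  # (n_items, 5)
    sigma: np.ndarray  # (D, D)
    alpha_1: float | np.ndarray = 1.0
    item_trait_map: np.ndarray | None = None
    n_traits: int = 1

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 2 or self.delta.shape[1] != 5:
            raise ValueError("delta must have shape (n_items, 5)")
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.item_trait_map is None:
            self.item_trait_map = np.zeros(self.n_items, dtype=int)
        else:
            self.item_trait_map = np.asarray(self.item_trait_map, dtype=int)
        for name in ("alpha_nm", "alpha_e", "alpha_1"):
            v = getattr(self, name)
            if np.ndim(v) > 0:
                setattr(self, name, np.asarray(v, dtype=float))
        self.validate()

    @property
    def n_items(self) -> int:
        return self.delta.shape[0]

    @property
    def n_dims(self) -> int:
        return self.n_traits + 2

    @property
    def item_specific(self) -> bool:
        return np.ndim(self.alpha_nm) > 0

    def validate(self) -> None:
        D = self.n_dims
        if self.sigma.shape != (D, D):
            raise ValueError(f"sigma must be {D}x{D} for {self.n_traits} trait(s) + 2 styles")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValueError("sigma must be positive definite")
        if self.item_trait_map.shape != (self.n_items,):
            raise ValueError("item_trait_map must have one entry per item")
        if self.item_trait_map.min() < 0 or self.item_trait_map.max() >= self.n_traits:
            raise ValueError("item_trait_map entries must index a trait dimension")
        for name in ("alpha_nm", "alpha_e", "alpha_1"):
            v = getattr(self, name)
            if np.ndim(v) > 0 and np.shape(v) != (self.n_items,):
                raise ValueError(f"{name} must be scalar or length n_items")

    def _alpha_for_item(self, name: str, item: int) -> float:
        v = getattr(self, name)
        return float(v[item]) if np.ndim(v) > 0 else float(v)

    def copy(self) -> "IRTreeParams":
        return replace(
            self,
            alpha_nm=np.array(self.alpha_nm) if np.ndim(self.alpha_nm) else self.alpha_nm,
            alpha_e=np.array(self.alpha_e) if np.ndim(self.alpha_e) else self.alpha_e,
            alpha_1=np.array(self.alpha_1) if np.ndim(self.alpha_1) else self.alpha_1,
            delta=self.delta.copy(),
            sigma=self.sigma.copy(),
            item_trait_map=self.item_trait_map.copy(),
        )

    # -- flat item-parameter vector (Psi) ----------------------------------

    def param_names(self) -> list[str]:
        """Registry of the free structural item parameters, in Psi order."""
        names: list[str] = []
        if self.item_specific:
            names += [f"alpha_1_item{i}" for i in range(self.n_items)]
            names += [f"alpha_nm_item{i}" for i in range(self.n_items)]
            names += [f"alpha_e_item{i}" for i in range(self.n_items)]
        else:
            names += ["alpha_nm", "alpha_e"]
        for i in range(self.n_items):
            names += [f"delta{n}_item{i}" for n in range(1, 6)]
        return names

    def to_psi(self) -> "ParamVector":
        if self.item_specific:
            head = np.concatenate([
                np.broadcast_to(np.atleast_1d(self.alpha_1), (self.n_items,)),
                np.atleast_1d(self.alpha_nm),
                np.atleast_1d(self.alpha_e),
            ])
        else:
            head = np.array([float(self.alpha_nm), float(self.alpha_e)])
        return ParamVector(
            names=self.param_names(),
            values=np.concatenate([head, self.delta.ravel()]),
        )

    def with_psi(self, psi: "ParamVector") -> "IRTreeParams":
        """Rebuild params from a flat Psi (sigma is untouched)."""
        if psi.names != self.param_names():
            raise ValueError("parameter registry mismatch")
        out = self.copy()
        v = psi.values
        I = self.n_items
        if self.item_specific:
            out.alpha_1 = v[:I].copy()
            out.alpha_nm = v[I:2 * I].copy()
            out.alpha_e = v[2 * I:3 * I].copy()
            off = 3 * I
        else:
            out.alpha_nm, out.alpha_e = float(v[0]), float(v[1])
            off = 2
        out.delta = v[off:off + 5 * I].reshape(I, 5).copy()
        return out

    def to_json(self) -> str:
        def enc(v):
            return v.tolist() if np.ndim(v) else float(v)

        return json.dumps({
            "alpha_nm": enc(self.alpha_nm),
            "alpha_e": enc(self.alpha_e),
            "alpha_1": enc(self.alpha_1),
            "delta": self.delta.tolist(),
            "sigma": self.sigma.tolist(),
            "item_trait_map": self.item_trait_map.tolist(),
            "n_traits": self.n_traits,
        })

    @classmethod
    def from_json(cls, s: str) -> "IRTreeParams":
        d = json.loads(s)
        return cls(
            alpha_nm=d["alpha_nm"], alpha_e=d["alpha_e"], alpha_1=d["alpha_1"],
            delta=np.array(d["delta"]), sigma=np.array(d["sigma"]),
            item_trait_map=np.array(d["item_trait_map"]), n_traits=d["n_traits"],
        )


@dataclass
class ParamVector:
    """Flat vector Psi of the free structural item parameters."""

    names: list[str]
    values: np.ndarray
    free: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("registry names must be unique")
        if self.free is None:
            self.free = np.ones(self.values.size, dtype=bool)

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"parameter {e.args[0]!r} not in registry") from None

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def expand_responses(
    responses: np.ndarray,
    tree: TreeSpec = SIX_POINT_TREE,
) -> np.ndarray:
    """Map an N x I matrix of observed categories to pseudo-item responses.

    Returns an ``int8`` array of shape (N, I, n_nodes) holding 0/1 node
    outcomes, ``STRUCTURAL_MISSING`` for nodes off the observed branch, and
    ``PERSON_MISSING`` for cells where the response itself is missing
    (``NaN`` or a negative integer in the input).
    """
    resp = np.asarray(responses)
    if resp.ndim != 2:
        raise ValueError("responses must be a 2-D person x item matrix")
    if np.issubdtype(resp.dtype, np.floating):
        person_missing = ~np.isfinite(resp)
        work = np.where(person_missing, 0, resp)
        if not np.allclose(work, np.round(work)):
            bad = np.argwhere(~np.isclose(resp, np.round(resp)) & ~person_missing)
            r, c = bad[0]
            raise ValueError(f"non-integer response {resp[r, c]!r} at row {r}, column {c}")
        work = np.round(work).astype(int)
    else:
        work = resp.astype(int)
        person_missing = work < 0
        work = np.where(person_missing, 0, work)

    out_of_range = (~person_missing) & ((work < 0) | (work >= tree.n_categories))
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"response category {resp[r, c]!r} at row {r}, column {c} is outside "
            f"0..{tree.n_categories - 1}"
        )

    lut = np.stack([tree.expand_one(c) for c in range(tree.n_categories)])  # (C, nodes)
    out = lut[work]  # (N, I, nodes)
    out[person_missing] = PERSON_MISSING
    return out


def flatten_pseudo(pseudo: np.ndarray) -> np.ndarray:
    """Flatten (N, I, nodes) pseudo-responses to (N, I*nodes), item-major."""
    if pseudo.ndim == 2:
        return pseudo
    n, i, k = pseudo.shape
    return pseudo.reshape(n, i * k)


def node_probabilities(
    person: LatentPerson, params: IRTreeParams, item: int
) -> np.ndarray:
    """Success probabilities of the five pseudo-items of one rating item."""
    t = float(person.theta[params.item_trait_map[item]])
    a1 = params._alpha_for_item("alpha_1", item)
    anm = params._alpha_for_item("alpha_nm", item)
    ae = params._alpha_for_item("alpha_e", item)
    d = params.delta[item]
    lin = np.array([
        a1 * t + d[0],
        person.eta_nm - anm * t + d[1],
        person.eta_nm + anm * t + d[2],
        person.eta_e - ae * t + d[3],
        person.eta_e + ae * t + d[4],
    ])
    return _logistic(lin)


def category_probabilities(
    person: LatentPerson,
    params: IRTreeParams,
    item: int,
    tree: TreeSpec = SIX_POINT_TREE,
) -> np.ndarray:
    """Category probabilities as branch products over the pseudo-items."""
    p = node_probabilities(person, params, item)
    out = np.empty(tree.n_categories)
    for c in range(tree.n_categories):
        branch = tree.branch_table[c]
        prob = 1.0
        for node, o in enumerate(branch):
            if o is None:
                continue
            prob *= p[node] if o == 1 else 1.0 - p[node]
        out[c] = prob
    return out
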