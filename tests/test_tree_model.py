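"""Tree structure, pseudo-item expansion, and category probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import irtreescan as irt
from irtreescan.tree_model import PERSON_MISSING, STRUCTURAL_MISSING

M = STRUCTURAL_MISSING


@pytest.mark.parametrize(
    "category, expected",
    [
        (0, (0, 1, M, 1, M)),
        (1, (0, 1, M, 0, M)),
        (2, (0, 0, M, M, M)),
        (3, (1, M, 0, M, M)),
        (4, (1, M, 1, M, 0)),
        (5, (1, M, 1, M, 1)),
    ],
)
def test_expand_responses_branch_table(category, expected):
    """Each category expands to the node outcomes of exactly its branch."""
    out = irt.expand_responses(np.array([[category]]))
    assert out.shape == (1, 1, 5)
    assert tuple(out[0, 0]) == expected


def test_expand_responses_out_of_range_names_cell():
    with pytest.raises(ValueError, match="row 1, column 0"):
        irt.expand_responses(np.array([[3], [6]]))


def test_expand_responses_person_missing():
    out = irt.expand_responses(np.array([[np.nan, 2.0]]))
    assert (out[0, 0] == PERSON_MISSING).all()
    assert tuple(out[0, 1]) == (0, 0, M, M, M)


def test_branches_partition_categories():
    """Every category maps to one distinct branch of the six-point tree."""
    tree = irt.SIX_POINT_TREE
    assert set(tree.branch_table) == set(range(6))
    branches = {tuple(b) for b in tree.branch_table.values()}
    assert len(branches) == 6
    # a node outcome is defined iff its ancestors on the branch are defined
    for branch in tree.branch_table.values():
        y1, y2, y3, y4, y5 = branch
        assert y1 is not None
        assert (y2 is not None) == (y1 == 0)
        assert (y3 is not None) == (y1 == 1)
        assert (y4 is not None) == (y2 == 1)
        assert (y5 is not None) == (y3 == 1)


def test_tree_spec_json_roundtrip():
    s = irt.SIX_POINT_TREE.to_json()
    back = irt.TreeSpec.from_json(s)
    assert back.branch_table == dict(irt.SIX_POINT_TREE.branch_table)


def test_invalid_tree_rejected():
    with pytest.raises(ValueError, match="duplicate branch"):
        irt.TreeSpec(2, 1, {0: (1,), 1: (1,)})


def _params(alpha_nm=0.8, alpha_e=0.8, delta=None, sigma=None):
    delta = np.zeros((1, 5)) if delta is None else np.asarray(delta, float)
    sigma = np.eye(3) if sigma is None else sigma
    return irt.IRTreeParams(alpha_nm=alpha_nm, alpha_e=alpha_e, delta=delta,
                            sigma=sigma, n_traits=1)


def test_node_probabilities_all_zero_latent():
    """All latent values and intercepts zero force 0.5 at every node."""
    person = irt.LatentPerson(theta=0.0, eta_nm=0.0, eta_e=0.0)
    p = irt.node_probabilities(person, _params(), 0)
    assert np.allclose(p, 0.5)


def test_node1_free_of_style_loadings():
    """The agreement node depends on theta only, not on alpha_nm."""
    person = irt.LatentPerson(theta=0.0, eta_nm=0.7, eta_e=-0.3)
    for a in (0.2, 0.8, 1.5):
        p = irt.node_probabilities(person, _params(alpha_nm=a), 0)
        assert p[0] == pytest.approx(0.5)


def test_node2_linear_predictor():
    """Node 2 combines eta_nm - alpha_nm*theta + delta_2."""
    person = irt.LatentPerson(theta=1.0, eta_nm=0.5, eta_e=0.0)
    delta = np.array([[0.0, -0.3, 0.0, 0.0, 0.0]])
    p = irt.node_probabilities(person, _params(alpha_nm=0.8, delta=delta), 0)
    expected = 1.0 / (1.0 + np.exp(0.6))  # logistic(0.5 - 0.8 - 0.3)
    assert p[1] == pytest.approx(expected, abs=1e-12)


def test_category_probabilities_uniform_tree():
    person = irt.LatentPerson(theta=0.0, eta_nm=0.0, eta_e=0.0)
    probs = irt.category_probabilities(person, _params(), 0)
    assert np.allclose(probs, [0.125, 0.125, 0.25, 0.25, 0.125, 0.125])


def _brute_force_category_probs(person, params, item):
    """Independent oracle: enumerate the branch table explicitly."""
    p = irt.node_probabilities(person, params, item)
    q = 1 - p
    return np.array([
        q[0] * p[1] * p[3],
        q[0] * p[1] * q[3],
        q[0] * q[1],
        p[0] * q[2],
        p[0] * p[2] * q[4],
        p[0] * p[2] * p[4],
    ])


def test_category_probabilities_match_brute_force():
    person = irt.LatentPerson(theta=1.0, eta_nm=0.0, eta_e=0.0)
    params = _params(alpha_nm=0.8, alpha_e=0.8)
    probs = irt.category_probabilities(person, params, 0)
    assert np.allclose(probs, _brute_force_category_probs(person, params, 0),
                       atol=1e-14)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    theta=st.floats(-3, 3), eta_nm=st.floats(-3, 3), eta_e=st.floats(-3, 3),
    anm=st.floats(0.05, 2), ae=st.floats(0.05, 2),
    d=st.lists(st.floats(-3, 3), min_size=5, max_size=5),
)
def test_category_probabilities_sum_to_one(theta, eta_nm, eta_e, anm, ae, d):
    person = irt.LatentPerson(theta=theta, eta_nm=eta_nm, eta_e=eta_e)
    params = _params(anm, ae, delta=np.array(d)[None, :])
    probs = irt.category_probabilities(person, params, 0)
    assert probs.min() >= 0
    assert probs.sum() == pytest.approx(1.0, abs=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    theta=st.floats(-2, 2), eta_nm=st.floats(-2, 2), eta_e=st.floats(-2, 2),
    d=st.lists(st.floats(-2, 2), min_size=5, max_size=5),
)
def test_symmetry_reverses_category_vector(theta, eta_nm, eta_e, d):
    """Negating theta and d1 while swapping d2/d3 and d4/d5 mirrors the scale."""
    d = np.array(d)
    params = _params(0.8, 0.6, delta=d[None, :])
    mirrored = _params(0.8, 0.6,
                       delta=np.array([-d[0], d[2], d[1], d[4], d[3]])[None, :])
    p1 = irt.category_probabilities(
        irt.LatentPerson(theta, eta_nm, eta_e), params, 0)
    p2 = irt.category_probabilities(
        irt.LatentPerson(-theta, eta_nm, eta_e), mirrored, 0)
    assert np.allclose(p1, p2[::-1], atol=1e-12)


def test_categorical_equals_pseudo_bernoulli_likelihood():
    """Category likelihood equals the Bernoulli product over pseudo-items,
    with structurally missing cells contributing factor 1."""
    rng = np.random.default_rng(5)
    params = _params(0.7, 0.5, delta=rng.normal(0, 1, (1, 5)))
    person = irt.LatentPerson(theta=0.4, eta_nm=-0.2, eta_e=0.9)
    p = irt.node_probabilities(person, params, 0)
    cat_probs = irt.category_probabilities(person, params, 0)
    for c in range(6):
        pseudo = irt.expand_responses(np.array([[c]]))[0, 0]
        bern = 1.0
        for node, y in enumerate(pseudo):
            if y == STRUCTURAL_MISSING:
                continue
            bern *= p[node] if y == 1 else 1 - p[node]
        assert bern == pytest.approx(cat_probs[c], abs=1e-10)


def test_param_vector_roundtrip(item_params):
    psi = item_params.to_psi()
    assert len(set(psi.names)) == len(psi)
    back = item_params.with_psi(psi)
    assert np.allclose(back.delta, item_params.delta)
    assert back.alpha_nm == item_params.alpha_nm
    # perturb and map back
    psi.values[:] = psi.values + 0.1
    shifted = item_params.with_psi(psi)
    assert shifted.alpha_nm == pytest.approx(item_params.alpha_nm + 0.1)
    assert np.allclose(shifted.delta, item_params.delta + 0.1)


def test_param_vector_roundtrip_item_specific():
    sigma = np.eye(3)
    params = irt.IRTreeParams(
        alpha_nm=np.array([0.5, 0.9]), alpha_e=np.array([0.4, 0.7]),
        alpha_1=np.array([1.0, 1.2]), delta=np.zeros((2, 5)), sigma=sigma,
        n_traits=1,
    )
    psi = params.to_psi()
    assert psi.names[0] == "alpha_1_item0"
    back = params.with_psi(psi)
    assert np.allclose(back.alpha_nm, params.alpha_nm)
    assert np.allclose(back.alpha_1, params.alpha_1)


def test_params_json_roundtrip(item_params):
    back = irt.IRTreeParams.from_json(item_params.to_json())
    assert np.allclose(back.delta, item_params.delta)
    assert np.allclose(back.sigma, item_params.sigma)
    assert back.n_traits == item_params.n_traits


def test_invalid_params_rejected():
    with pytest.raises(ValueError, match="positive definite"):
        irt.IRTreeParams(alpha_nm=0.8, alpha_e=0.8, delta=np.zeros((1, 5)),
                         sigma=np.zeros((3, 3)), n_traits=1)
    with pytest.raises(ValueError, match="delta"):
        irt.IRTreeParams(alpha_nm=0.8, alpha_e=0.8, delta=np.zeros((5,)),
                         sigma=np.eye(3), n_traits=1)
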