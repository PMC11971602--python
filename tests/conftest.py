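import numpy as np
import pytest

import irtreescan as irt


@pytest.fixture(scope="session")
def item_params():
    """Six-item parameter set of the validation design (length-keyed seed)."""
    return irt.gen_item_params(6, 0.8, 0.8, seed=1)


@pytest.fixture(scope="session")
def model_spec(item_params):
    return irt.ModelSpec(
        n_items=6, n_traits=2, item_trait_map=item_params.item_trait_map
    )


@pytest.fixture(scope="session")
def fit_options():
    # 5 quadrature points per dimension keep the 4-dimensional fits fast in
    # routine runs; quadrature-stability is checked separately
    return irt.FitOptions(quad_points_per_dim=5)


@pytest.fixture(scope="session")
def null_data(item_params):
    """Homogeneous (no heterogeneity) sample with a metric covariate."""
    n = 500
    persons = irt.gen_persons(n, seed=11)
    x, _ = irt.gen_covariate("metric", n, seed=12)
    y = irt.simulate_responses(persons, item_params, seed=13)
    pseudo = irt.expand_responses(y)
    return {"responses": y, "pseudo": pseudo, "covariate": x, "persons": persons}


@pytest.fixture(scope="session")
def fitted_null(null_data, model_spec, fit_options):
    return irt.fit_irtree(null_data["pseudo"], model_spec, fit_options)


@pytest.fixture(scope="session")
def scores_null(fitted_null, null_data):
    return irt.score_contributions(fitted_null, null_data["pseudo"])


@pytest.fixture(scope="session")
def single_trait_params():
    """A 3-dimensional (1 trait + 2 styles) parameter set for small fits."""
    sigma = np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.4], [0.2, 0.4, 1.5]])
    rng = np.random.default_rng(21)
    delta = np.column_stack([
        rng.uniform(-1, 1, 4),
        rng.uniform(-1, 0.5, 4), rng.uniform(-1, 0.5, 4),
        rng.uniform(-2.0, -1.0, 4), rng.uniform(-2.0, -1.0, 4),
    ])
    return irt.IRTreeParams(
        alpha_nm=0.7, alpha_e=0.6, delta=delta, sigma=sigma, n_traits=1
    )
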