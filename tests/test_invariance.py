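"""Test statistics and p-values against hand values and Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy import stats

import irtreescan as irt
from irtreescan.invariance import _simulate_null
from irtreescan.score_process import CovariateOrdering, CumProcess


def _proc_from_B(B, x, kind):
    """Wrap an explicit process matrix for statistic evaluation."""
    B = np.asarray(B, dtype=float)
    ordering = CovariateOrdering.from_covariate(np.asarray(x), kind)
    return CumProcess(B=B, subset=[f"p{j}" for j in range(B.shape[1])],
                      info_hat=np.eye(B.shape[1]), ordering=ordering)


def _gaussian_process(rng, n, k, kind="metric", x=None):
    """Null process built from i.i.d. Gaussian score rows via the pipeline."""
    S = rng.normal(size=(n, k))
    scores = irt.ScoreMatrix(S, [f"p{j}" for j in range(k)])
    if x is None:
        x = rng.normal(size=n)
    ordering = CovariateOrdering.from_covariate(x, kind)
    return irt.cumulative_process(scores, ordering), ordering


def test_zero_process_gives_zero_stats_and_p_one():
    proc = _proc_from_B(np.zeros((4, 2)), [1.0, 2.0, 3.0, 4.0], "metric")
    assert irt.stat_metric(proc, "DM") == 0.0
    assert irt.stat_metric(proc, "CvM") == 0.0
    assert irt.stat_metric(proc, "maxLM") == 0.0
    for name in ("DM", "CvM", "maxLM"):
        p, _ = irt.p_value(0.0, name, k=2, ordering=proc.ordering, nsim=200)
        assert p == pytest.approx(1.0, abs=0.01)


def test_dm_is_direct_max():
    proc = _proc_from_B([[0.5], [1.2], [0.0]], [1.0, 2.0, 3.0], "metric")
    assert irt.stat_metric(proc, "DM") == pytest.approx(1.2)


def test_cvm_and_maxlm_forms():
    B = np.array([[0.3, -0.1], [0.6, 0.2], [0.0, 0.0]])
    proc = _proc_from_B(B, [1.0, 2.0, 3.0], "metric")
    assert irt.stat_metric(proc, "CvM") == pytest.approx((B**2).sum() / 3)
    # maxLM over t in {1/3, 2/3} with trim (.1,.9)
    ssq = (B**2).sum(1)
    w = np.array([1 / 3 * 2 / 3, 2 / 3 * 1 / 3])
    assert irt.stat_metric(proc, "maxLM") == pytest.approx((ssq[:2] / w).max())
    with pytest.raises(ValueError, match="trim"):
        irt.stat_metric(proc, "maxLM", trim=(0.0, 0.9))


def test_ordinal_hand_example():
    """m=2, t1=.5, |B_v1|=1: WDMo = 2 and maxLMo = 4."""
    x = np.array([1, 1, 2, 2])
    B = np.array([[0.3], [1.0], [0.2], [0.0]])
    proc = _proc_from_B(B, x, "ordinal")
    assert irt.stat_ordinal(proc, which="WDMo") == pytest.approx(2.0)
    assert irt.stat_ordinal(proc, which="maxLMo") == pytest.approx(4.0)


def test_lmuo_equals_two_sample_lm_oracle():
    """For m=2 LMuo reduces to the two-sample score (chi-square) statistic."""
    rng = np.random.default_rng(9)
    n, k = 400, 3
    S = rng.normal(size=(n, k))
    g = rng.integers(0, 2, n)
    scores = irt.ScoreMatrix(S, ["a", "b", "c"])
    ordering = CovariateOrdering.from_covariate(g, "categorical")
    proc = irt.cumulative_process(scores, ordering)
    lmuo = irt.stat_categorical(proc, ordering)
    # oracle: decorrelate, then the Wald/score form of the group contrast
    info = irt.opg_covariance(scores)
    root = np.linalg.inv(np.linalg.cholesky(info))
    Sd = (S - S.mean(0)) @ root.T
    n1, n2 = (g == 0).sum(), (g == 1).sum()
    diff = Sd[g == 0].mean(0) - Sd[g == 1].mean(0)
    oracle = float(diff @ diff / (1 / n1 + 1 / n2))
    assert lmuo == pytest.approx(oracle, rel=1e-8)


def test_lmuo_null_matches_chi_square():
    """LMuo on homogeneous Gaussian scores follows chi-square((m-1)k)."""
    rng = np.random.default_rng(10)
    m, k, reps = 3, 2, 1500
    vals = []
    for _ in range(reps):
        proc, ordering = _gaussian_process(
            rng, 240, k, "categorical", x=rng.integers(0, m, 240))
        vals.append(irt.stat_categorical(proc, ordering))
    vals = np.array(vals)
    df = (m - 1) * k
    qs = np.array([0.5, 0.8, 0.9, 0.95])
    emp = np.quantile(vals, qs)
    theo = stats.chi2.ppf(qs, df)
    assert np.allclose(emp, theo, rtol=0.12)


def test_lmuo_unscaled_option_differs():
    rng = np.random.default_rng(11)
    proc, ordering = _gaussian_process(
        rng, 300, 2, "categorical", x=rng.integers(0, 3, 300))
    scaled = irt.stat_categorical(proc, ordering, scaled=True)
    unscaled = irt.stat_categorical(proc, ordering, scaled=False)
    assert scaled != pytest.approx(unscaled)


def test_lmuo_invariant_to_category_relabeling():
    rng = np.random.default_rng(12)
    n = 300
    S = rng.normal(size=(n, 2))
    x = rng.choice(["a", "b", "c"], n)
    scores = irt.ScoreMatrix(S, ["p0", "p1"])
    relabel = {"a": "z", "b": "q", "c": "m"}
    x2 = np.array([relabel[v] for v in x])
    o1 = CovariateOrdering.from_covariate(x, "categorical")
    o2 = CovariateOrdering.from_covariate(x2, "categorical")
    s1 = irt.stat_categorical(irt.cumulative_process(scores, o1), o1)
    s2 = irt.stat_categorical(irt.cumulative_process(scores, o2), o2)
    assert s1 == pytest.approx(s2, abs=1e-10)


def test_dm_critical_value_kolmogorov():
    """The .95 null quantile of sup|bridge| is about 1.358 for k=1."""
    p, method = irt.p_value(1.358, "DM", k=1)
    assert method == "analytic"
    assert p == pytest.approx(0.05, abs=0.002)


def test_lmuo_chi2_reference_point():
    """m=2, k=1: p(3.841) ~ .05 (chi-square(1) critical value)."""
    ordering = CovariateOrdering.from_covariate(np.array([0, 0, 1, 1]), "categorical")
    p, method = irt.p_value(3.841, "LMuo", k=1, ordering=ordering)
    assert method == "analytic"
    assert p == pytest.approx(0.05, abs=0.001)


@pytest.mark.parametrize("kfac", [1, 4])
def test_dm_analytic_matches_monte_carlo(kfac):
    """Analytic DM p-values agree with Brownian-bridge simulation."""
    nsim = 4000
    # a fine grid keeps the discretization bias of the simulated supremum
    # below the Monte-Carlo resolution
    null = _simulate_null("DM", kfac, None, (0.1, 0.9), nsim, seed=100,
                          ngrid=3000)
    for c in (1.0, 1.3, 1.6):
        mc = (null >= c).mean()
        se = np.sqrt(mc * (1 - mc) / nsim)
        ana, _ = irt.p_value(c, "DM", k=kfac)
        assert abs(ana - mc) < 3 * se + 0.015


def test_wdmo_analytic_matches_monte_carlo():
    t = np.array([0.25, 0.5, 0.75])
    x = np.repeat([1, 2, 3, 4], 25)
    ordering = CovariateOrdering.from_covariate(x, "ordinal")
    nsim = 4000
    null = _simulate_null("WDMo", 2, t, (0.1, 0.9), nsim, seed=101, ngrid=400)
    for c in (2.2, 2.6, 3.0):
        mc = (null >= c).mean()
        se = np.sqrt(mc * (1 - mc) / nsim)
        ana, _ = irt.p_value(c, "WDMo", k=2, ordering=ordering)
        assert abs(ana - mc) < 3 * se + 0.01


def test_p_value_monotone_in_statistic():
    x_ord = np.repeat([1, 2, 3], 30)
    ordering = CovariateOrdering.from_covariate(x_ord, "ordinal")
    grid = np.linspace(0.2, 4.0, 12)
    for name in ("DM", "WDMo", "LMuo", "maxLM", "CvM", "maxLMo"):
        ps = [
            irt.p_value(c, name, k=2, ordering=ordering, nsim=1500, seed=7)[0]
            for c in grid
        ]
        assert np.all(np.diff(ps) <= 1e-12)


def test_p_value_errors():
    with pytest.raises(ValueError, match="unknown statistic"):
        irt.p_value(1.0, "XYZ", k=1)
    with pytest.raises(ValueError, match="finite"):
        irt.p_value(np.inf, "DM", k=1)


def test_sctest_end_to_end_null(fitted_null, null_data):
    res = irt.sctest(
        fitted_null, null_data["pseudo"], null_data["covariate"], "metric",
        subset="alpha_nm",
    )
    assert res.statistic_name == "DM"
    assert res.k == 1
    assert res.subset == ["alpha_nm"]
    assert 0.0 <= res.p_value <= 1.0
    assert res.pvalue_method == "analytic"
    back = irt.TestResult.from_json(res.to_json())
    assert back.statistic_value == pytest.approx(res.statistic_value)


def test_sctest_subset_not_in_registry(fitted_null, null_data):
    with pytest.raises(KeyError, match="unknown subset"):
        irt.sctest(fitted_null, null_data["pseudo"], null_data["covariate"],
                   "metric", subset="alpha_zz")


def test_sctest_statistic_guards(fitted_null, null_data):
    with pytest.raises(ValueError, match="not defined for a metric"):
        irt.sctest(fitted_null, null_data["pseudo"], null_data["covariate"],
                   "metric", statistic_name="WDMo")
    with pytest.raises(ValueError, match="LMuo"):
        irt.sctest(fitted_null, null_data["pseudo"],
                   (null_data["covariate"] > 50).astype(int), "categorical",
                   statistic_name="DM")


def test_intercept_subset_size(fitted_null, null_data, scores_null):
    res = irt.sctest(
        fitted_null, null_data["pseudo"], null_data["covariate"], "metric",
        subset="intercepts", scores=scores_null,
    )
    assert res.k == 30


def test_metric_statistics_invariant_to_monotone_transform(
        fitted_null, null_data, scores_null):
    x = null_data["covariate"]
    r1 = irt.sctest(fitted_null, null_data["pseudo"], x, "metric",
                    subset="alpha_e", scores=scores_null)
    r2 = irt.sctest(fitted_null, null_data["pseudo"], x**3, "metric",
                    subset="alpha_e", scores=scores_null)
    assert r1.statistic_value == pytest.approx(r2.statistic_value, abs=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
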