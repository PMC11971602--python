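# irtreescan

Score-based tests of parameter heterogeneity and model-based partitioning
for IRTree (item response tree) models of Likert responses with response
styles.

## The problem

Six-point Likert responses mix the substantive trait a questionnaire is
meant to measure with content-independent *response styles*: a tendency to
avoid or prefer the scale midpoint (nonmoderate responding) and a tendency
to pick the endpoints (extreme responding). IRTree models disentangle
these processes by decomposing each observed category into a sequence of
binary decisions — agree vs. disagree, nonmoderate vs. moderate, extreme
vs. nonextreme — each parameterized as a logistic pseudo-item:

```
P(Y1 = 1) = logistic( theta                    + delta_1i )   agreement
P(Y2 = 1) = logistic( eta_nm - a_nm * theta    + delta_2i )   nonmoderate | disagree
P(Y3 = 1) = logistic( eta_nm + a_nm * theta    + delta_3i )   nonmoderate | agree
P(Y4 = 1) = logistic( eta_e  - a_e  * theta    + delta_4i )   extreme | nonmod. disagree
P(Y5 = 1) = logistic( eta_e  + a_e  * theta    + delta_5i )   extreme | nonmod. agree
```

with latent vector (theta, eta_nm, eta_e) ~ N(0, Sigma) and category
probabilities given by products along the tree branches. The loadings
`a_nm` and `a_e` weight the trait in the finer category choices relative
to the agreement decision.

Standard IRTree models assume these structural parameters are identical
for everyone. This package tests that assumption against person
covariates and, when it fails, locates where the parameters change:

1. **Score-based tests.** Per-person score contributions s(Psi-hat; y_v)
   (gradients of the marginal log-likelihood at the ML estimate) are
   ordered by a covariate, decorrelated with the outer-product-of-gradients
   covariance, and cumulated into an empirical fluctuation process
   B(t, Psi-hat), a Brownian bridge under parameter invariance. Functionals
   of B give test statistics for metric (DM, CvM, maxLM), ordinal (WDMo,
   maxLMo), and unordered categorical (LMuo) covariates, with analytic or
   simulated p-values. Tests can target parameter subsets — e.g. only
   `a_nm` or only `a_e` — to identify *which* response process differs.
2. **Partitioning.** After a significant test, the sample is split at the
   covariate value maximizing the summed log-likelihood of two
   independently refitted models (minimum 300 persons per side), applied
   recursively with retests inside the subgroups.

The package is aimed at psychometricians and survey methodologists
analyzing rating-scale data with suspected subgroup differences in
response behavior.

## Worked example

```python
import irtreescan as irt

# simulate a survey with a loading change at metric covariate value 40
params = irt.gen_item_params(6, alpha_nm=0.8, alpha_e=0.8, seed=1)
persons = irt.gen_persons(1000, seed=7)
covariate, focal = irt.gen_covariate("metric", 1000, seed=8)
responses = irt.simulate_responses(persons, params, focal, shift=0.5, seed=9)
pseudo = irt.expand_responses(responses)

spec = irt.ModelSpec(n_items=6, n_traits=2, item_trait_map=params.item_trait_map)
fitted = irt.fit_irtree(pseudo, spec, irt.FitOptions(quad_points_per_dim=5))

for subset in ("alpha_nm", "alpha_e"):
    r = irt.sctest(fitted, pseudo, covariate, "metric", subset=subset)
    print(f"{subset}: DM = {r.statistic_value:.3f}, p = {r.p_value:.4f}")

cut = irt.find_cutpoint(pseudo, covariate, "metric", spec,
                        irt.FitOptions(quad_points_per_dim=5),
                        irt.PartitionOptions(min_size=300, profile="fixed_sigma",
                                             max_candidates=10))
print(f"selected cutpoint: {cut.cutpoint:.1f}")
```

prints

```
alpha_nm: DM = 2.074, p = 0.0004
alpha_e: DM = 2.422, p = 0.0000
selected cutpoint: 41.0
```

Both loading tests reject invariance (the simulated focal group below
covariate 40 responds with loadings shifted by +.5), and the cutpoint
search places the change at 41 — just above the true value of 40, the
upward bias expected because the focal group holds only a third of the
sample. A pooled fit on these heterogeneous data lands between the two
groups (here `a_nm` = 0.989 against group values 0.8 and 1.3).

The same workflows are available from the shell: `irtreescan fit`,
`irtreescan sctest`, `irtreescan partition`, and `irtreescan simulate`
operate on CSV/TSV tables and YAML configs and write JSON artifacts with a
run manifest (see `irtreescan --help`). Responses coded 1–6 must be
declared with `--categories 1-6`; they are never shifted silently.

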