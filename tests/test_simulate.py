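import numpy as np
import pytest
from scipy import stats

from anchorbn import (
    ScenarioParams,
    Study1Params,
    Study3Config,
    generate_snp_effects,
    scenario,
    simulate_study1,
    simulate_study2,
    simulate_study3,
)


# ---------------------------------------------------------------------------
# Study 1: quantitative models
# ---------------------------------------------------------------------------


def test_effect_recovered_by_adjusted_regression():
    """At large n the regression of Y on (X, Z) recovers beta_XY."""
    p = Study1Params.preset(1, "weak", effect=0.5, n=100_000)
    d = simulate_study1(p, 42)
    X = np.column_stack([np.ones(d.n), d.column("X"), d.column("Z")])
    coef, *_ = np.linalg.lstsq(X, d.column("Y"), rcond=None)
    assert abs(coef[1] - 0.5) < 0.02


def test_fully_disconnected_model_gives_independent_unit_normals():
    p = Study1Params(model=1, beta_GX=0.0, beta_ZY=0.0, n=2500)
    d = simulate_study1(p, 7)
    r = np.corrcoef(d.column("X"), d.column("Y"))[0, 1]
    assert abs(r) < 4 / np.sqrt(d.n)
    assert abs(d.column("X").std() - 1) < 0.1
    assert abs(d.column("Y").std() - 1) < 0.1


def test_variance_of_exposure_matches_analytic_value():
    """Var(X) = beta_GX^2 * 2 maf (1-maf) + 1 under the null model."""
    p = Study1Params.preset(1, "weak", effect=0.0, n=100_000, maf_G=0.3)
    d = simulate_study1(p, 3)
    expected = 0.1 ** 2 * 2 * 0.3 * 0.7 + 1.0
    assert abs(d.column("X").var() - expected) < 0.02


@pytest.mark.parametrize("model,confounding", [(1, "weak"), (2, "weak"),
                                               (2, "strong"), (3, "weak")])
def test_residual_sd_converges_to_one(model, confounding):
    """Empirical residual SD of the Y structural equation is 1 (+-2%)."""
    p = Study1Params.preset(model, confounding, effect=0.5, n=100_000)
    d = simulate_study1(p, 11)
    preds = {1: ["X", "Z"], 2: ["X", "Z", "C"], 3: ["X", "Z", "S"]}[model]
    X = np.column_stack([np.ones(d.n)] + [d.column(c) for c in preds])
    coef, *_ = np.linalg.lstsq(X, d.column("Y"), rcond=None)
    resid = d.column("Y") - X @ coef
    assert abs(resid.std() - 1.0) < 0.02


def test_genotype_hardy_weinberg_proportions():
    p = Study1Params.preset(1, "weak", n=50_000, maf_G=0.3)
    d = simulate_study1(p, 5)
    counts = np.bincount(d.column("G").astype(int), minlength=3)
    exp = d.n * np.array([0.49, 0.42, 0.09])
    chi2 = ((counts - exp) ** 2 / exp).sum()
    assert stats.chi2.sf(chi2, 2) > 1e-4


def test_seed_determinism_and_reverse_direction_columns():
    p = Study1Params.preset(3, "strong", effect=0.4, direction="y_to_x")
    d1 = simulate_study1(p, 9)
    d2 = simulate_study1(p, 9)
    assert d1.values.equals(d2.values)
    assert d1.var_names == ["G", "Z", "X", "Y", "S"]
    # reverse direction: X depends on Y, so cor(X, Y) reflects beta_YX
    r = np.corrcoef(d1.column("X"), d1.column("Y"))[0, 1]
    assert r > 0.2


def test_confounding_induces_marginal_correlation_model2_not_model1():
    """At beta_XY = 0, cor(X,Y) is 0 under model 1 and
    beta_CX*beta_CY/(sd_X sd_Y) under model 2 (analytic oracle)."""
    n = 100_000
    d1 = simulate_study1(Study1Params.preset(1, "weak", 0.0, n=n), 13)
    d2 = simulate_study1(Study1Params.preset(2, "weak", 0.0, n=n), 13)
    r1 = np.corrcoef(d1.column("X"), d1.column("Y"))[0, 1]
    r2 = np.corrcoef(d2.column("X"), d2.column("Y"))[0, 1]
    var_g = 2 * 0.3 * 0.7
    sd_x = np.sqrt(0.1 ** 2 * var_g + 0.25 ** 2 + 1)
    sd_y = np.sqrt(0.075 ** 2 + 0.25 ** 2 + 1)
    expected = 0.25 * 0.25 / (sd_x * sd_y)
    assert abs(r1) < 4 / np.sqrt(n)
    assert abs(r2 - expected) < 4 / np.sqrt(n)


def test_study1_parameter_validation():
    with pytest.raises(ValueError, match="model"):
        simulate_study1(Study1Params(model=4), 0)
    with pytest.raises(ValueError, match="positive"):
        simulate_study1(Study1Params(model=1, n=0), 0)
    with pytest.raises(ValueError, match="beta_YX"):
        simulate_study1(Study1Params(model=1, beta_XY=0.5, beta_YX=0.5), 0)


# ---------------------------------------------------------------------------
# Study 2: binary scenarios
# ---------------------------------------------------------------------------


def test_scenario_a_gene_frequency():
    d = simulate_study2(scenario("A"), 21)
    freq = d.column("Q").mean()
    se = np.sqrt(0.49 * 0.51 / d.n)
    assert abs(freq - 0.49) < 3 * se


def test_scenario_b_alcohol_rate_matches_logistic_mixture():
    """P(W=1) = P(Q=0) expit(d0) + P(Q=1) expit(d0+dq), analytically."""
    from scipy.special import expit
    d = simulate_study2(scenario("B", n=200_000), 22)
    expected = 0.51 * expit(0.2) + 0.49 * expit(0.5)
    assert abs(d.column("W").mean() - expected) < 4 * np.sqrt(0.25 / d.n)


def test_null_scenario_gives_independent_fair_coins():
    p = ScenarioParams(0.5, 0, 0, 0, 0, 0, 0, 0, 0, 0, n=20_000)
    d = simulate_study2(p, 23)
    cols = [d.column(c) for c in "QWHY"]
    for c in cols:
        assert abs(c.mean() - 0.5) < 4 * np.sqrt(0.25 / d.n)
    for i in range(4):
        for j in range(i + 1, 4):
            assert abs(np.corrcoef(cols[i], cols[j])[0, 1]) < 4 / np.sqrt(d.n)


def test_study2_levels_and_validation():
    d = simulate_study2(scenario("D"), 1)
    assert all(set(np.unique(d.column(c))) <= {0.0, 1.0} for c in "QWHY")
    assert d.levels["Y"] == (0, 1)
    with pytest.raises(ValueError, match="finite"):
        simulate_study2(ScenarioParams(0.5, np.inf, 0, 0, 0, 0, 0, 0, 0, 0), 0)
    with pytest.raises(ValueError, match="freq_Q"):
        simulate_study2(ScenarioParams(1.5, 0, 0, 0, 0, 0, 0, 0, 0, 0), 0)


# ---------------------------------------------------------------------------
# Study 3: pleiotropy
# ---------------------------------------------------------------------------


def test_effect_table_shape_sparsity_and_determinism():
    cfg = Study3Config()
    t1 = generate_snp_effects(cfg, 4)
    t2 = generate_snp_effects(cfg, 4)
    assert t1.beta.shape == (150, 12)
    assert ((t1.beta != 0).sum(axis=0) >= 1).all()   # every metabolite covered
    assert ((t1.beta != 0).sum(axis=1) >= 1).all()   # every SNP affects one
    assert np.array_equal(t1.beta, t2.beta)          # bit-identical under seed
    dense = generate_snp_effects(
        Study3Config(sparsity=1.0), 4)
    assert np.count_nonzero(dense.beta == 0) == 0


def test_study3_dataset_dimensions_and_genotypes():
    cfg = Study3Config(n=300, n_snps_total=500, n_metabolite_snps=60,
                       n_outcome_snps=30)
    eff = generate_snp_effects(cfg, 1)
    d, roles = simulate_study3(cfg, eff, 2)
    assert d.values.shape == (300, 500 + 12 + 1)
    snp_cols = roles["metabolite_snps"] + roles["outcome_snps"]
    geno = d.values[snp_cols].to_numpy()
    assert set(np.unique(geno)) <= {0, 1, 2}
    assert sorted(roles["metabolites"].values()) == ["causal"] * 4 + ["null"] * 4 + ["reverse"] * 4


def test_causal_metabolite_effect_recovered():
    """Regressing Y on the causal metabolites plus the known direct SNP
    contribution recovers the generating coefficient 0.3."""
    cfg = Study3Config(n=20_000, n_snps_total=400, n_metabolite_snps=60,
                       n_outcome_snps=30)
    eff = generate_snp_effects(cfg, 3)
    d, roles = simulate_study3(cfg, eff, 4)
    causal = [m for m, r in roles["metabolites"].items() if r == "causal"]
    Go = d.values[roles["outcome_snps"]].to_numpy(dtype=float)
    direct = Go @ eff.outcome_beta
    X = np.column_stack([np.ones(d.n)] +
                        [d.column(m) for m in causal] + [direct])
    coef, *_ = np.linalg.lstsq(X, d.column("Y"), rcond=None)
    assert np.allclose(coef[1:5], 0.3, atol=0.03)
    assert abs(coef[5] - 1.0) < 0.05


def test_null_effects_give_uniform_pvalues():
    """With all metabolite-outcome couplings removed, marginal regression
    p-values of Y on a metabolite are Uniform(0,1) across replicates."""
    from anchorbn.mr import _marginal_regression_p
    cfg = Study3Config(n=200, n_snps_total=100, n_metabolite_snps=30,
                       n_outcome_snps=20, causal_beta=0.0)
    pvals = []
    for rep in range(200):
        eff = generate_snp_effects(cfg, 50)
        d, roles = simulate_study3(cfg, eff, 1000 + rep)
        null_m = next(m for m, r in roles["metabolites"].items() if r == "null")
        _, p = _marginal_regression_p(d.column(null_m), d.column("Y"))
        pvals.append(p)
    assert stats.kstest(pvals, "uniform").pvalue > 1e-3


def test_study3_config_validation():
    with pytest.raises(ValueError, match="exceed"):
        Study3Config(n_snps_total=100).validate()
    with pytest.raises(ValueError, match="sparsity"):
        Study3Config(sparsity=0.0).validate()
    cfg = Study3Config()
    eff = generate_snp_effects(cfg, 0)
    with pytest.raises(ValueError, match="match"):
        simulate_study3(Study3Config(n_metabolite_snps=100,
                                     n_outcome_snps=125), eff, 0)
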