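import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from anchorbn import (
    Dataset,
    Study1Params,
    build_allele_score,
    fit_2sls,
    mr_steiger,
    simulate_study1,
    steiger_direction_test,
)


def _dataset(**cols):
    df = pd.DataFrame(cols)
    return Dataset(df, {c: "continuous" for c in df},
                   {c: "phenotype" for c in df})


# ---------------------------------------------------------------------------
# Two-stage least squares
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_uncorrected_pvalue_equals_outcome_on_instrument_regression(seed):
    """The naive-residual 2SLS p-value is identical (to machine
    precision) to that of regressing the outcome directly on the
    instrument; statsmodels supplies the reference regression."""
    d = simulate_study1(Study1Params.preset(1, "weak", 0.3), seed)
    res = fit_2sls(d, "X", "Y", ["G"], correct_first_stage=False)
    ref = sm.OLS(d.column("Y"), sm.add_constant(d.column("G"))).fit()
    assert res.p_value == pytest.approx(ref.pvalues[1], rel=1e-12, abs=0)


def test_modes_share_estimate_but_not_se():
    d = simulate_study1(Study1Params.preset(2, "strong", 0.5), 5)
    corrected = fit_2sls(d, "X", "Y", ["G"], correct_first_stage=True)
    naive = fit_2sls(d, "X", "Y", ["G"], correct_first_stage=False)
    assert corrected.estimate == naive.estimate
    assert corrected.se != naive.se
    assert corrected.mode == "corrected" and naive.mode == "uncorrected"
    for r in (corrected, naive):
        assert 0.0 <= r.p_value <= 1.0 and r.se > 0


def test_single_instrument_estimate_is_wald_ratio():
    """cov(G,Y)/cov(G,X) computed by direct arithmetic."""
    g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
    x = np.array([0.1, -0.1, 0.5, 0.6, 1.0, 1.1])
    y = np.array([0.0, 0.2, 1.1, 1.3, 2.0, 2.2])
    d = _dataset(G=g, X=x, Y=y)
    res = fit_2sls(d, "X", "Y", ["G"])
    wald = np.cov(g, y)[0, 1] / np.cov(g, x)[0, 1]
    assert res.estimate == pytest.approx(wald, rel=1e-12)


def test_instrument_identical_to_exposure_reduces_to_ols():
    rng = np.random.default_rng(8)
    x = rng.normal(size=300)
    y = 0.7 * x + rng.normal(size=300)
    d = _dataset(G=x.copy(), X=x, Y=y)
    res = fit_2sls(d, "X", "Y", ["G"])
    slope = sm.OLS(y, sm.add_constant(x)).fit().params[1]
    assert res.estimate == pytest.approx(slope, rel=1e-10)


def test_two_instruments_supported_and_first_stage_ps_reported():
    d = simulate_study1(Study1Params.preset(1, "weak", 0.5), 6)
    res = fit_2sls(d, "X", "Y", ["G", "Z"])
    assert set(res.first_stage_p) == {"G", "Z"}
    assert res.first_stage_p["G"] < res.first_stage_p["Z"]  # G drives X


@given(seed=st.integers(0, 10_000), beta=st.floats(-1.0, 1.0))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_estimate_invariance_between_modes_property(seed, beta):
    """On arbitrary simulated inputs the two SE conventions return the
    same point estimate, and p-values stay in [0, 1]."""
    rng = np.random.default_rng(seed)
    n = 120
    g = rng.binomial(2, 0.4, n).astype(float)
    x = 0.5 * g + rng.normal(size=n)
    y = beta * x + rng.normal(size=n)
    d = _dataset(G=g, X=x, Y=y)
    corrected = fit_2sls(d, "X", "Y", ["G"], correct_first_stage=True)
    naive = fit_2sls(d, "X", "Y", ["G"], correct_first_stage=False)
    assert corrected.estimate == naive.estimate
    for r in (corrected, naive):
        assert 0.0 <= r.p_value <= 1.0


def test_degenerate_inputs_raise():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    d = _dataset(G=np.ones(50), X=x, Y=x + rng.normal(size=50))
    with pytest.raises(ValueError, match="zero variance"):
        fit_2sls(d, "X", "Y", ["G"])
    g = rng.normal(size=50)
    d2 = _dataset(G=g, G2=2 * g, X=x, Y=x)
    with pytest.raises(ValueError, match="collinear"):
        fit_2sls(d2, "X", "Y", ["G", "G2"])
    with pytest.raises(ValueError, match="instrument"):
        fit_2sls(d, "X", "Y", [])


# ---------------------------------------------------------------------------
# Allele scores
# ---------------------------------------------------------------------------


def test_weighted_score_is_exact_weighted_allele_sum():
    d = _dataset(s1=np.array([0.0, 2.0]), s2=np.array([1.0, 0.0]),
                 s3=np.array([2.0, 1.0]), T=np.array([0.0, 1.0]))
    sc = build_allele_score(d, ["s1", "s2", "s3"], "T",
                            weights=[0.5, -0.2, 1.0])
    assert np.allclose(sc.values, [1.8, 2.0])


def test_independent_target_selection_is_flagged_empty():
    """With 100 null SNPs at threshold 5e-6, the expected number of
    selections is ~5e-4, so essentially every replicate is empty."""
    rng = np.random.default_rng(17)
    n = 400
    cols = {f"s{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(100)}
    cols["T"] = rng.normal(size=n)
    d = _dataset(**cols)
    empty = 0
    for rep in range(20):
        d.values["T"] = rng.normal(size=n)
        sc = build_allele_score(d, [f"s{i}" for i in range(100)], "T")
        empty += not sc.valid
    assert empty == 20


def test_single_true_snp_selected_and_score_collinear():
    rng = np.random.default_rng(19)
    n = 2500
    g = rng.binomial(2, 0.3, n).astype(float)
    cols = {"hit": g, "nul": rng.binomial(2, 0.3, n).astype(float),
            "T": g * 1.0 + rng.normal(size=n)}
    d = _dataset(**cols)
    sc = build_allele_score(d, ["hit", "nul"], "T")
    assert sc.valid and sc.snp_ids == ("hit",)
    assert abs(np.corrcoef(sc.values, g)[0, 1]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# MR Steiger
# ---------------------------------------------------------------------------


def _oracle_steiger_p(r_ja, r_jb, r_ab, n):
    """Independent re-implementation of the dependent-correlations test
    (Fisher transforms; shared-variable form)."""
    import math
    z1, z2 = math.atanh(r_ja), math.atanh(r_jb)
    rm2 = (r_ja ** 2 + r_jb ** 2) / 2
    f = min((1 - r_ab) / (2 * (1 - rm2)), 1.0)
    h = (1 - f * rm2) / (1 - rm2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - r_ab) * h))
    return z, 2 * stats.norm.sf(abs(z))


def test_symmetric_correlations_give_null_decision():
    """Constructed data with r(G,A) = r(G,B) exactly: no orientation."""
    g = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
    a = 0.5 * g + np.array([0.3, 0.3, -0.3, -0.3, 0.0, 0.0])
    d = _dataset(G=g, A=a, B=a.copy())
    res = steiger_direction_test(d, "G", "A", "B")
    assert res.z_stat == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert not res.instrument_valid


def test_statistic_matches_standalone_oracle():
    rng = np.random.default_rng(23)
    n = 500
    g = rng.normal(size=n)
    a = 0.9 * g + 0.2 * rng.normal(size=n)   # r(G,A) ~ 0.9
    b = 0.1 * g + rng.normal(size=n)          # r(G,B) ~ 0.1
    d = _dataset(G=g, A=a, B=b)
    res = steiger_direction_test(d, "G", "A", "B")
    z, p = _oracle_steiger_p(abs(res.r_gx), abs(res.r_gy), res.r_xy, n)
    assert res.preferred_exposure == "A"
    assert res.z_stat == pytest.approx(z, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-12)
    assert res.instrument_valid


def test_instrumented_trait_preferred_in_most_replicates():
    """Under the no-confounding model G instruments X, so X should be
    the preferred exposure in the large majority of replicates."""
    wins = 0
    for rep in range(50):
        d = simulate_study1(Study1Params.preset(1, "weak", 0.5), 300 + rep)
        res = steiger_direction_test(d, "G", "X", "Y")
        wins += res.preferred_exposure == "X"
    assert wins >= 45


def test_gate_passthrough_and_gated_sentinel():
    d = simulate_study1(Study1Params.preset(1, "weak", 0.5), 31)
    res = mr_steiger(d, "G", "X", "Y")
    if res.valid:
        direct = fit_2sls(d, "X", "Y", ["G"])
        assert res.p_value == direct.p_value
        assert res.steiger is not None
    # an instrument unrelated to both traits fails the first-stage gate
    rng = np.random.default_rng(32)
    d.values["J"] = rng.normal(size=d.n)
    d.kinds["J"] = "continuous"
    d.roles["J"] = "instrument"
    gated = mr_steiger(d, "J", "X", "Y")
    assert not gated.valid
    assert gated.p_value == 1.0
    assert np.isnan(gated.estimate)
    assert gated.steiger.first_stage_p > 0.05
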