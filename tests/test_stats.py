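import numpy as np
import pytest

import microtissue as mt
from microtissue.stats import (
    ModelInput,
    fit_linear,
    fit_logistic,
    format_results_text,
    qq_normality,
    results_table,
)

from oracles import logit_grid_oracle, ols_oracle


def make_input(y, age, male, st_, name="r"):
    return ModelInput(name, np.asarray(y, float), np.asarray(age, float),
                      np.asarray(male, float), np.asarray(st_, float))


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(5)
    n = 12
    age = rng.uniform(12, 55, n)
    male = (rng.random(n) < 0.5).astype(float)
    st_ = (rng.random(n) < 0.7).astype(float)
    y = 3.0 + 0.5 * age - 2.0 * male + rng.normal(0, 4, n)
    return y, age, male, st_


# ------------------------------------------------------------ linear
def test_noiseless_fit_is_exact():
    rng = np.random.default_rng(1)
    age = rng.uniform(12, 55, 20)
    male = (rng.random(20) < 0.5).astype(float)
    st_ = (rng.random(20) < 0.7).astype(float)
    res = fit_linear(make_input(3.0 + 2.0 * age, age, male, st_))
    assert res.terms["age"][0] == pytest.approx(2.0, abs=1e-10)
    assert res.terms["gender_male"][0] == pytest.approx(0.0, abs=1e-10)
    assert res.terms["tendon_semitendinosus"][0] == pytest.approx(0.0, abs=1e-10)
    assert res.fit_statistic == pytest.approx(1.0, abs=1e-12)


def test_ols_matches_normal_equations_oracle(random_table):
    y, age, male, st_ = random_table
    res = fit_linear(make_input(y, age, male, st_))
    X = np.column_stack([np.ones_like(age), age, male, st_])
    beta, se, pvals, r2 = ols_oracle(y, X)
    for j, cov in enumerate(("age", "gender_male", "tendon_semitendinosus"), start=1):
        est, s, p = res.terms[cov]
        assert est == pytest.approx(beta[j], rel=1e-10)
        assert s == pytest.approx(se[j], rel=1e-10)
        assert p == pytest.approx(pvals[j], rel=1e-8)
    assert res.fit_statistic == pytest.approx(r2, rel=1e-10)
    assert res.intercept[0] == pytest.approx(beta[0], rel=1e-10)


def test_collinear_design_refused_with_names():
    age = np.arange(10.0)
    with pytest.raises(ValueError, match="collinear"):
        fit_linear(make_input(np.arange(10.0), age, np.ones(10), np.ones(10)))


def test_too_few_rows_refused():
    with pytest.raises(ValueError, match="rows"):
        fit_linear(make_input([1, 2, 3], [1, 2, 3], [0, 1, 0], [1, 0, 1]))


def test_area_slope_recovery_at_500_tendons(big_readouts):
    res = fit_linear(ModelInput.from_frame(big_readouts, "relative_area_pct",
                                           "surface area 48 h (%)"))
    assert res.terms["age"][0] == pytest.approx(0.96, abs=0.15)
    assert res.terms["age"][2] < 0.05


def test_gender_coding_invariance(random_table):
    y, age, male, st_ = random_table
    a = fit_linear(make_input(y, age, male, st_))
    b = fit_linear(make_input(y, age, 1 - male, st_))
    assert b.terms["gender_male"][0] == pytest.approx(-a.terms["gender_male"][0])
    assert b.terms["gender_male"][1] == pytest.approx(a.terms["gender_male"][1])
    assert b.terms["age"][0] == pytest.approx(a.terms["age"][0])
    assert b.terms["tendon_semitendinosus"][0] == pytest.approx(
        a.terms["tendon_semitendinosus"][0]
    )


# ---------------------------------------------------------- logistic
def test_logistic_recovers_release_age_coefficient(big_readouts):
    res = fit_logistic(ModelInput.from_frame(big_readouts, "intact", "intact/released"))
    assert res.terms["age"][0] == pytest.approx(0.19, abs=0.1)
    assert res.fit_statistic_name == "pseudo-R2"
    assert 0.0 <= res.fit_statistic <= 1.0


def test_logistic_matches_grid_search_oracle():
    """Hand-built 8-row table with one binary covariate of interest."""
    y = np.array([0, 1, 0, 1, 0, 1, 1, 1], float)
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
    male = np.array([0, 1, 1, 0, 0, 1, 0, 1], float)
    st_ = np.array([1, 1, 0, 0, 1, 0, 0, 1], float)
    inp = make_input(y, x, male, st_)
    res = fit_logistic(inp)
    beta = logit_grid_oracle(y, inp.design())
    assert res.intercept[0] == pytest.approx(beta[0], abs=1e-3)
    for j, cov in enumerate(("age", "gender_male", "tendon_semitendinosus"), start=1):
        assert res.terms[cov][0] == pytest.approx(beta[j], abs=1e-3)


def test_single_class_outcome_refused():
    with pytest.raises(ValueError, match="classes"):
        fit_logistic(make_input(np.ones(8), np.arange(8), np.zeros(8) + [0, 1] * 4,
                                [1, 0] * 4))


def test_perfect_separation_refused():
    age = np.array([1, 2, 3, 4, 10, 11, 12, 13], float)
    y = (age > 5).astype(float)
    male = np.array([0, 1, 0, 1, 0, 1, 0, 1], float)
    st_ = np.array([1, 0, 0, 1, 1, 0, 0, 1], float)
    with pytest.raises(ValueError, match="separation|converge"):
        fit_logistic(make_input(y, age, male, st_))


def test_null_model_calibration():
    """With the outcome independent of the covariates the pseudo-R^2 is
    near zero and the age test rejects at roughly the 5% level."""
    rng = np.random.default_rng(42)
    n, reps, rejections, prs = 400, 60, 0, []
    for _ in range(reps):
        age = rng.uniform(12, 55, n)
        male = (rng.random(n) < 0.5).astype(float)
        st_ = (rng.random(n) < 0.7).astype(float)
        y = (rng.random(n) < 0.6).astype(float)
        res = fit_logistic(make_input(y, age, male, st_))
        rejections += res.terms["age"][2] < 0.05
        prs.append(res.fit_statistic)
    assert np.mean(prs) < 0.02
    assert rejections / reps < 0.15


# ---------------------------------------------------------- qq plot
def test_qq_identity_correlation_is_one():
    from scipy import stats as sps

    n = 50
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    _, _, corr = qq_normality(theo)
    assert corr == pytest.approx(1.0, abs=1e-12)


def test_qq_two_point_distribution_detected():
    resid = np.array([-1.0] * 50 + [1.0] * 50)
    _, _, corr = qq_normality(resid)
    assert corr < 0.95


def test_qq_sign_flip_symmetric():
    rng = np.random.default_rng(3)
    x = rng.gamma(2.0, size=80) - 2.0
    _, _, c1 = qq_normality(x)
    _, _, c2 = qq_normality(-x)
    assert c1 == pytest.approx(c2, abs=1e-9)


def test_qq_constant_residuals_refused():
    with pytest.raises(ValueError):
        qq_normality(np.zeros(10))


# ----------------------------------------------------- results table
def test_single_linear_result_table(random_table):
    y, age, male, st_ = random_table
    res = fit_linear(make_input(y, age, male, st_, name="surface area 48 h (%)"))
    table = results_table([res])
    assert len(table) == 1
    assert table.fit_statistic_name.item() == "R2"


def test_mixed_table_marks_logistic_row(study_readouts):
    lin = fit_linear(ModelInput.from_frame(study_readouts, "relative_area_pct",
                                           "surface area 48 h (%)"))
    log = fit_logistic(ModelInput.from_frame(study_readouts, "intact",
                                             "intact/released"))
    table = results_table([lin, log])
    assert list(table.readout) == ["intact/released", "surface area 48 h (%)"]
    assert table.iloc[0].fit_statistic_name == "pseudo-R2"
    text = format_results_text(table)
    assert "pseudo-R2" in text and "* p < 0.05" in text


def test_full_readout_battery_has_seven_rows(study_readouts):
    """All seven study read-outs produce one results row each."""
    results = [fit_logistic(ModelInput.from_frame(study_readouts, "intact",
                                                  "intact/released"))]
    for col, name in (
        ("relative_area_pct", "surface area 48 h (%)"),
        ("pro_collagen_ng_ml", "pro-collagen I (ng/ml)"),
        ("tenomodulin_ratio", "tenomodulin / tubulin (-)"),
        ("asma_ratio", "aSMA / tubulin (-)"),
        ("mmp2_active_au", "active MMP2 (A.U.)"),
        ("mmp2_active_fraction", "MMP2 active fraction (-)"),
    ):
        results.append(fit_linear(ModelInput.from_frame(study_readouts, col, name)))
    table = results_table(results)
    assert len(table) == 7
    assert (table.fit_statistic_name == "pseudo-R2").sum() == 1
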