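"""GLM correctness: closed forms, brute-force likelihood oracle, reference
implementation concordance, nested tests and backward selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ovibias import (
    GLMError,
    GLMFit,
    ModelSpec,
    backward_select,
    eggs_given_receipt_test,
    exponentiate_report,
    fit_glm,
    lr_test,
)
from ovibias.glm import build_design


def _sim_logistic(rng, n=200, beta=(0.3, 0.8, -0.5)):
    df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    eta = beta[0] + beta[1] * df.x1 + beta[2] * df.x2
    df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return df


def nll_oracle(X, y, family):
    """Direct likelihood maximization, independent of IRLS."""
    if family == "binomial":
        def nll(b):
            eta = X @ b
            return float(np.sum(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta))
    else:  # poisson
        def nll(b):
            eta = np.clip(X @ b, -30, 30)
            return float(np.sum(np.exp(eta) - y * eta))
    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    return res.x


# --------------------------- closed forms ----------------------------- #

def test_intercept_only_binomial_closed_form():
    """Intercept-only fit returns the sample proportion and the closed-form
    Bernoulli deviance -2[k log p + (n-k) log(1-p)]."""
    k, n = 7, 20
    df = pd.DataFrame({"y": [1] * k + [0] * (n - k)})
    fit = fit_glm(ModelSpec("y", (), "binomial"), df)
    p_hat = 1 / (1 + np.exp(-fit.coefficients["(Intercept)"]))
    assert p_hat == pytest.approx(k / n, abs=1e-9)
    expected_dev = -2 * (k * np.log(k / n) + (n - k) * np.log(1 - k / n))
    assert fit.deviance == pytest.approx(expected_dev, rel=1e-9)
    assert fit.dispersion == 1.0
    assert fit.df_residual == n - 1


@pytest.mark.parametrize("family", ["binomial", "poisson"])
def test_small_sample_matches_likelihood_oracle(family):
    """Coefficients within 1e-6 of direct likelihood maximization on
    30-observation, 2-predictor datasets."""
    rng = np.random.default_rng(42)
    for rep in range(5):
        df = pd.DataFrame({"x1": rng.normal(size=30), "x2": rng.normal(size=30)})
        if family == "binomial":
            eta = 0.2 + 0.9 * df.x1 - 0.6 * df.x2
            df["y"] = (rng.random(30) < 1 / (1 + np.exp(-eta))).astype(int)
        else:
            eta = 1.0 + 0.4 * df.x1 + 0.3 * df.x2
            df["y"] = rng.poisson(np.exp(eta))
        if df.y.nunique() == 1:
            continue
        fit = fit_glm(ModelSpec("y", ("x1", "x2"), family), df)
        if fit.warnings:
            continue  # separation: oracle comparison meaningless
        X, names, _ = build_design(df, ("x1", "x2"))
        ref = nll_oracle(X, df.y.to_numpy(float), family)
        np.testing.assert_allclose(fit.params, ref, atol=1e-6)


def test_quasipoisson_dispersion_recovery():
    """Pearson dispersion estimate recovers the generating overdispersion."""
    rng = np.random.default_rng(7)
    n = 5000
    x = rng.normal(size=n)
    mu = np.exp(1.0 + 0.3 * x)
    # nbinom with var = mu * 2  =>  quasi-Poisson dispersion 2
    r = mu / 1.0
    y = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame({"x": x, "y": y})
    fit = fit_glm(ModelSpec("y", ("x",), "quasipoisson"), df)
    assert fit.dispersion == pytest.approx(2.0, rel=0.1)


# ------------------------- reference concordance ---------------------- #

def test_reference_glm_concordance():
    """LR-test significance decisions agree with an independent reference GLM
    implementation on every one of 200 simulated stem datasets
    (odds ratio 2 on sex, ~20% baseline receipt, n = 300)."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(11)
    agreements = 0
    for rep in range(200):
        n = 300
        sexh = rng.random(n) < 0.5
        eta = np.log(0.25) + 0.693 * sexh
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"sex": np.where(sexh, "H", "F"), "y": y})
        full = fit_glm(ModelSpec("y", ("sex",), "binomial"), df)
        red = fit_glm(ModelSpec("y", (), "binomial"), df)
        ours = lr_test(red, full, "chisq")
        Xr = np.column_stack([np.ones(n), sexh.astype(float)])
        f_sm = sm.GLM(y, Xr, family=sm.families.Binomial()).fit()
        r_sm = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial()).fit()
        stat_sm = r_sm.deviance - f_sm.deviance
        p_sm = stats.chi2.sf(stat_sm, 1)
        assert abs(ours.statistic - stat_sm) < 1e-6
        agreements += (ours.p_value < 0.05) == (p_sm < 0.05)
    assert agreements == 200


# --------------------------- nested tests ----------------------------- #

def test_identical_models_give_p_one():
    rng = np.random.default_rng(1)
    df = _sim_logistic(rng)
    fit = fit_glm(ModelSpec("y", ("x1",), "binomial"), df)
    res = lr_test(fit, fit, "chisq")
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_non_nested_rejected():
    rng = np.random.default_rng(2)
    df = _sim_logistic(rng)
    f1 = fit_glm(ModelSpec("y", ("x1",), "binomial"), df)
    f2 = fit_glm(ModelSpec("y", ("x2",), "binomial"), df)
    with pytest.raises(GLMError, match="not nested"):
        lr_test(f1, f2)
    with pytest.raises(GLMError, match="same data"):
        lr_test(
            fit_glm(ModelSpec("y", (), "binomial"), df.iloc[:100]),
            fit_glm(ModelSpec("y", ("x1",), "binomial"), df),
        )


def test_deviance_monotone_in_nesting():
    """Adding a term never increases the deviance."""
    rng = np.random.default_rng(3)
    for rep in range(10):
        df = _sim_logistic(rng, n=80)
        devs = [
            fit_glm(ModelSpec("y", terms, "binomial"), df).deviance
            for terms in [(), ("x1",), ("x1", "x2")]
        ]
        assert devs[0] >= devs[1] - 1e-9 >= devs[2] - 2e-9


def test_chisq_and_f_agree_when_dispersion_is_one():
    """On large non-overdispersed data the F statistic times df1 approaches
    the chi-square statistic."""
    rng = np.random.default_rng(4)
    n = 4000
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(0.5 + 0.2 * x))
    df = pd.DataFrame({"x": x, "y": y})
    full_q = fit_glm(ModelSpec("y", ("x",), "quasipoisson"), df)
    red_q = fit_glm(ModelSpec("y", (), "quasipoisson"), df)
    full_p = fit_glm(ModelSpec("y", ("x",), "poisson"), df)
    red_p = fit_glm(ModelSpec("y", (), "poisson"), df)
    assert full_q.dispersion == pytest.approx(1.0, abs=0.1)
    f = lr_test(red_q, full_q, "f")
    c = lr_test(red_p, full_p, "chisq")
    assert f.statistic * f.df1 == pytest.approx(c.statistic, rel=0.05)


def test_lr_type_one_error_nominal():
    """Null sex term rejected at ~5% over simulated binomial datasets."""
    rng = np.random.default_rng(5)
    reps, rej = 400, 0
    for _ in range(reps):
        n = 120
        df = pd.DataFrame({"sex": np.where(rng.random(n) < 0.5, "F", "H"),
                           "y": (rng.random(n) < 0.3).astype(int)})
        full = fit_glm(ModelSpec("y", ("sex",), "binomial"), df)
        red = fit_glm(ModelSpec("y", (), "binomial"), df)
        rej += lr_test(red, full, "chisq").p_value < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rej / reps - 0.05) < 3.5 * se


# ------------------------ diagnostics & errors ------------------------ #

def test_separation_flagged():
    df = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)],
                       "y": np.r_[np.zeros(10), np.ones(10)].astype(int)})
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_glm(ModelSpec("y", ("x",), "binomial"), df)
    assert any("separation" in w for w in fit.warnings)


def test_rank_deficiency_names_term():
    rng = np.random.default_rng(6)
    df = _sim_logistic(rng, n=50)
    df["x3"] = df["x1"] * 2.0  # aliased
    with pytest.raises(GLMError, match="x3"):
        fit_glm(ModelSpec("y", ("x1", "x2", "x3"), "binomial"), df)


def test_binary_response_required():
    df = pd.DataFrame({"y": [0, 1, 2, 1]})
    with pytest.raises(GLMError, match="binary"):
        fit_glm(ModelSpec("y", (), "binomial"), df)
    with pytest.raises(GLMError, match="interaction"):
        ModelSpec("y", ("a:b",), "binomial")


# -------------------------- backward selection ------------------------ #

def _sim_selection_data(rng, n=250, noise_beta=0.0):
    df = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "noise": rng.normal(size=n),
    })
    eta = -0.3 + 1.2 * df.x1 + 1.0 * df.x2 + noise_beta * df.noise
    df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return df


def test_all_significant_terms_kept():
    rng = np.random.default_rng(8)
    df = _sim_selection_data(rng, n=400)
    sel = backward_select(ModelSpec("y", ("x1", "x2"), "binomial"), df)
    assert set(sel.final.spec.predictors) == {"x1", "x2"}
    assert sel.dropped == {}
    assert all(r.p_value < 0.05 for r in sel.retained.values())


def test_noise_predictor_dropped_and_retested():
    """A pure-noise predictor is dropped in >= 95% of datasets; its reported
    test compares the final model to final + that term."""
    rng = np.random.default_rng(9)
    dropped = 0
    reps = 100
    for _ in range(reps):
        df = _sim_selection_data(rng)
        sel = backward_select(ModelSpec("y", ("x1", "x2", "noise"), "binomial"), df)
        if "noise" not in sel.final.spec.predictors:
            dropped += 1
            assert "noise" in sel.dropped
            assert sel.dropped["noise"].term_tested == "noise"
    assert dropped >= 95


def test_interactions_removed_before_main_effects():
    rng = np.random.default_rng(10)
    n = 300
    df = pd.DataFrame({"sex": np.where(rng.random(n) < 0.5, "F", "H"),
                       "pop": np.where(rng.random(n) < 0.5, "P1", "P2")})
    df["y"] = (rng.random(n) < 0.3).astype(int)
    sel = backward_select(ModelSpec("y", ("sex", "pop", "sex:pop"), "binomial"), df)
    if sel.history:
        first = sel.history[0]["dropped"]
        assert first == "sex:pop"


# --------------------------- reporting ops ---------------------------- #

def test_exponentiate_report_convention():
    """Exponentiated coefficients follow the multiplicative-effect convention:
    0.029 -> 1.029 (3 dp), -0.14 -> 0.87 (2 dp), 0 -> 1."""
    fit = GLMFit(
        spec=ModelSpec("fruits", ("flower_number", "flower_depth", "null_term"), "quasipoisson"),
        coefficients={"flower_number": 0.029, "flower_depth": -0.14, "null_term": 0.0},
        deviance=0.0, df_residual=1, dispersion=1.0, pearson_chi2=0.0,
        converged=True, iterations=1, n_obs=10,
    )
    tab = exponentiate_report(fit).set_index("term")["exp_coefficient"]
    assert round(tab["flower_number"], 3) == 1.029
    assert round(tab["flower_depth"], 2) == 0.87
    assert tab["null_term"] == 1.0


def test_eggs_given_receipt():
    rng = np.random.default_rng(12)
    n = 500
    df = pd.DataFrame({"sex": np.where(rng.random(n) < 0.5, "F", "H")})
    df["eggs"] = rng.poisson(np.exp(0.1 + 0.5 * (df.sex == "H")))
    res = eggs_given_receipt_test(df)
    assert res.kind == "chisq" and res.df1 == 1
    with pytest.raises(GLMError, match="degenerate"):
        eggs_given_receipt_test(df[df.sex == "F"])
    ones = pd.DataFrame({"sex": ["F", "H"] * 10, "eggs": [1] * 20})
    with pytest.warns(UserWarning, match="zero-variance"):
        res0 = eggs_given_receipt_test(ones)
    assert res0.p_value == pytest.approx(1.0, abs=1e-6)


def test_eggs_given_receipt_power():
    """Log-mean sex effect of 0.5 detected with power > 0.8 at n = 500."""
    rng = np.random.default_rng(13)
    hits = 0
    reps = 100
    for _ in range(reps):
        n = 500
        sexh = rng.random(n) < 0.5
        eggs = 1 + rng.poisson(np.exp(-0.5 + 0.5 * sexh))
        df = pd.DataFrame({"sex": np.where(sexh, "H", "F"), "eggs": eggs})
        hits += eggs_given_receipt_test(df).p_value < 0.05
    assert hits / reps > 0.8
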