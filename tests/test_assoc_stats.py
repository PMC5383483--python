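import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import sexflux as sf
from sexflux.assoc_stats import MODEL_TERMS, _marginal_loglik
from tests._oracles import naive_g_statistic, quadrature_marginal_loglik


# ---------------------------------------------------------------------------
# G-test
# ---------------------------------------------------------------------------


def test_g_test_identical_rows_is_null():
    res = sf.g_test([[10, 20], [10, 20]])
    assert res.g == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_g_test_hand_value():
    res = sf.g_test([[10, 20], [20, 10]])
    assert round(res.g, 3) == 6.796
    assert res.df == 1


def test_g_test_zero_margin_rejected():
    with pytest.raises(ValueError, match="column 'M'"):
        sf.g_test([[10, 0], [20, 0]], col_labels=["F", "M"])


@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=40), min_size=3, max_size=3),
        min_size=2,
        max_size=4,
    )
)
def test_g_test_matches_naive_loop_and_scipy(rows):
    table = np.array(rows)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return
    res = sf.g_test(table)
    assert res.g == pytest.approx(naive_g_statistic(table), abs=1e-9)
    g_scipy, p_scipy, df_scipy, _ = chi2_contingency(
        table, correction=False, lambda_="log-likelihood"
    )
    assert res.g == pytest.approx(g_scipy, abs=1e-9)
    assert res.df == df_scipy
    assert res.p == pytest.approx(p_scipy, abs=1e-12)


@given(
    st.lists(
        st.lists(st.integers(min_value=1, max_value=30), min_size=2, max_size=2),
        min_size=2,
        max_size=2,
    ),
    st.integers(min_value=2, max_value=9),
)
def test_g_statistic_scales_linearly_in_counts(rows, k):
    table = np.array(rows)
    assert sf.g_test(table * k).g == pytest.approx(k * sf.g_test(table).g, rel=1e-12)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def test_kruskal_wallis_hand_value():
    res = sf.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert round(res.h, 3) == 3.857
    assert res.df == 1


def test_kruskal_wallis_identical_groups_degenerate():
    with pytest.warns(UserWarning, match="identical"):
        res = sf.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
    assert res.h == 0.0
    assert res.p == 1.0


def test_kruskal_wallis_needs_two_nonempty_groups():
    with pytest.raises(ValueError):
        sf.kruskal_wallis([[1.0, 2.0]])
    with pytest.raises(ValueError):
        sf.kruskal_wallis([[1.0], []])


@given(
    st.lists(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False).map(
                lambda v: round(v, 3)
            ),
            min_size=2,
            max_size=8,
        ),
        min_size=2,
        max_size=4,
    )
)
@settings(max_examples=50)
def test_kruskal_wallis_invariant_to_monotone_transform(groups):
    pooled = [v for g in groups for v in g]
    if len(set(pooled)) == 1:
        return
    base = sf.kruskal_wallis(groups)
    transformed = sf.kruskal_wallis([[np.exp(v / 25.0) for v in g] for g in groups])
    assert base.h == pytest.approx(transformed.h, abs=1e-9)


# ---------------------------------------------------------------------------
# mixed logistic
# ---------------------------------------------------------------------------


def _sim_frame(seed=11, n=600, sigma=0.5, beta=(-0.5, 0.8, -0.4), n_groups=4):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, len(beta) - 1))
    g = rng.integers(0, n_groups, size=n)
    u = rng.normal(0.0, sigma, size=n_groups)
    eta = beta[0] + x @ np.array(beta[1:]) + u[g]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    cols = {f"x{i}": x[:, i] for i in range(x.shape[1])}
    return pd.DataFrame(
        {"response": y, "plot_id": [f"P{i}" for i in g], **cols}
    )


def test_intercept_only_no_variance_closed_form():
    frame = pd.DataFrame(
        {"response": [1.0] * 30 + [0.0] * 70, "plot_id": ["P1"] * 100}
    )
    fit = sf.fit_mixed_logistic(frame, [], re_variance=0.0)
    assert fit.intercept == pytest.approx(np.log(30 / 70), abs=1e-6)
    assert fit.aic == pytest.approx(-2.0 * fit.loglik + 2.0)


def test_variance_zero_matches_plain_logistic():
    import statsmodels.api as smapi

    frame = _sim_frame()
    fit = sf.fit_mixed_logistic(frame, ["x0", "x1"], re_variance=0.0)
    x = smapi.add_constant(frame[["x0", "x1"]].to_numpy())
    oracle = smapi.Logit(frame.response.to_numpy(), x).fit(disp=0)
    assert fit.intercept == pytest.approx(oracle.params[0], abs=1e-5)
    assert fit.coefficients["x0"] == pytest.approx(oracle.params[1], abs=1e-5)
    assert fit.coefficients["x1"] == pytest.approx(oracle.params[2], abs=1e-5)
    assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)


def test_adaptive_quadrature_matches_dense_oracle():
    frame = _sim_frame(n=200, n_groups=2)
    y = frame.response.to_numpy()
    x = np.column_stack([np.ones(len(frame)), frame[["x0", "x1"]].to_numpy()])
    codes, _ = pd.factorize(frame.plot_id, sort=True)
    from numpy.polynomial.hermite import hermgauss

    z, w = hermgauss(15)
    beta = np.array([-0.4, 0.7, -0.3])
    for sigma in (0.2, 0.6, 1.5):
        ll = _marginal_loglik(beta, sigma, x, y, codes, 2, z, np.log(w))
        oracle = quadrature_marginal_loglik(beta, sigma, x, y, codes, 2)
        assert ll == pytest.approx(oracle, abs=1e-4)


def test_fit_matches_lme4_glmer():
    """Full ML fit agrees with R lme4::glmer at the same quadrature order."""
    frame = _sim_frame(seed=11)
    fit = sf.fit_mixed_logistic(frame, ["x0", "x1"])
    csv = "/tmp/sexflux_glmm_oracle.csv"
    frame.to_csv(csv, index=False)
    script = textwrap.dedent(
        f"""
        d <- read.csv("{csv}")
        suppressMessages(library(lme4))
        m <- glmer(response ~ x0 + x1 + (1|plot_id), data=d, family=binomial, nAGQ=15)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep="\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    intercept, b0, b1, sd, loglik = map(float, out.stdout.strip().split("\n")[-5:])
    assert fit.intercept == pytest.approx(intercept, abs=2e-3)
    assert fit.coefficients["x0"] == pytest.approx(b0, abs=2e-3)
    assert fit.coefficients["x1"] == pytest.approx(b1, abs=2e-3)
    assert fit.re_sd == pytest.approx(sd, abs=5e-3)
    assert fit.loglik == pytest.approx(loglik, abs=1e-3)


def test_parameter_recovery_from_synthetic_census():
    config = sf.SimConfig(
        mode="covariate",
        n_individuals=(250, 250, 250, 250),
        years=(2010, 2011, 2012, 2013, 2014, 2015),
        seed=5,
        p_nonflower=0.05,
    )
    records = sf.simulate_census(config)
    data = sf.prepare_change_data(records)
    assert len(data.frame) > 3000
    fit = sf.fit_mixed_logistic(data.frame, list(MODEL_TERMS))
    truth = config.beta
    assert fit.converged
    for term in MODEL_TERMS:
        se = fit.std_errors[term]
        assert abs(fit.coefficients[term] - truth[term]) < 3.0 * se


def test_constant_response_rejected():
    frame = pd.DataFrame({"response": [1.0] * 10, "plot_id": ["P1"] * 10})
    with pytest.raises(ValueError, match="constant"):
        sf.fit_mixed_logistic(frame, [], re_variance=0.0)


# ---------------------------------------------------------------------------
# backward AIC selection
# ---------------------------------------------------------------------------


def _selection_frame(seed, n=1200, strong=1.2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 4))
    g = rng.integers(0, 4, size=n)
    u = rng.normal(0.0, 0.3, size=4)
    eta = -0.8 + strong * x[:, 0] + u[g]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return pd.DataFrame(
        {
            "response": y,
            "plot_id": [f"P{i}" for i in g],
            "strong": x[:, 0],
            "noise1": x[:, 1],
            "noise2": x[:, 2],
            "noise3": x[:, 3],
        }
    )


def test_backward_aic_keeps_strong_drops_noise():
    # under the null each term survives backward AIC with prob
    # P(chi2_1 > 2) ~ 0.157, so 20 term-rep draws retain ~3 on average
    retained_strong = 0
    retained_noise_under_null = 0
    for seed in range(5):
        frame = _selection_frame(seed)
        sel = sf.backward_aic(frame, ["strong", "noise1", "noise2", "noise3"])
        if "strong" in sel.final.terms:
            retained_strong += 1
        null_sel = sf.backward_aic(
            _selection_frame(seed + 100, strong=0.0),
            ["strong", "noise1", "noise2", "noise3"],
        )
        retained_noise_under_null += len(null_sel.final.terms)
    assert retained_strong == 5
    assert retained_noise_under_null <= 8


def test_backward_aic_trace_and_nesting():
    frame = _selection_frame(3)
    sel = sf.backward_aic(frame, ["strong", "noise1"])
    assert sel.trace.iloc[0]["dropped"] == ""
    assert (sel.trace["aic"].diff().dropna() < 0).all()
    # nested fits: the larger model never has lower log-likelihood
    full = sf.fit_mixed_logistic(frame, ["strong", "noise1"], compute_se=False)
    reduced = sf.fit_mixed_logistic(frame, ["strong"], compute_se=False)
    assert full.loglik >= reduced.loglik - 1e-6
    assert full.aic == pytest.approx(-2 * full.loglik + 2 * full.n_params)


def test_backward_aic_minimal_model_untouched():
    frame = _selection_frame(7, n=2000, strong=1.5)
    sel = sf.backward_aic(frame, ["strong"])
    assert sel.final.terms == ("strong",)
    assert len(sel.trace) == 1


# ---------------------------------------------------------------------------
# change-model data preparation
# ---------------------------------------------------------------------------


def test_prepare_change_data_rows_and_standardization():
    records = []
    dbh = {2010: 2.0, 2011: 2.1, 2012: 2.4}
    states = {2010: "F", 2011: "F", 2012: "HF"}
    for year in (2010, 2011, 2012):
        records.append(
            sf.CensusRecord(
                "P1", "a", year, states[year],
                dbh=dbh[year], rppfd_winter=0.3, rppfd_summer=0.1,
            )
        )
    data = sf.prepare_change_data(records, pooling=sf.POOL_TO_HALL)
    # the 2010 pair lacks a previous-year DBH, only (2011, 2012) survives
    assert len(data.frame) == 1
    row = data.frame.iloc[0]
    assert row.year == 2011
    assert row.response == 1  # F -> HALL
    assert data.means["growth"] == pytest.approx(1.0)  # |2.1-2.0| cm = 1 mm


def test_prepare_change_data_focal_at_risk_subset():
    records = []
    for ind, seq in (("a", ["HF", "F", "F"]), ("b", ["M", "M", "HM"])):
        for i, state in enumerate(seq):
            records.append(
                sf.CensusRecord(
                    "P1", ind, 2010 + i, state,
                    dbh=2.0 + 0.1 * i, rppfd_winter=0.2, rppfd_summer=0.1,
                )
            )
    data = sf.prepare_change_data(
        records, pooling=sf.POOL_TO_HALL, focal=("M", "HALL")
    )
    # only individual b's 2011 pair is at risk (origin pooled M)
    assert list(data.frame.individual_id) == ["b"]
    assert data.frame.iloc[0].response == 1
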