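"""Growth-curve analysis: basis, model fits, degenerate limits, LRT ladder."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import statsmodels.api as sm

from vocogaze.gca import (
    GCASpec,
    build_design,
    default_ladder,
    fit_gca,
    lrt_compare,
    orthogonal_basis,
    sequential_comparison,
)


def make_linear_data(rng, n_p=8, cond_effects=(0.0, 0.0), re_sd=(0.8, 0.6, 0.4, 0.2),
                     noise=1.0, beta=(5.0, 8.0, -3.0, 1.0), step=100.0):
    """Participant curves simulated directly from the order-3 mixed model."""
    times = np.arange(200.0, 1800.0, step)
    B = orthogonal_basis(times, 3).columns
    rows = []
    for p in range(n_p):
        b = rng.normal(0, re_sd)
        for ci, cond in enumerate(("match", "mismatch")):
            c = -0.5 if ci == 0 else 0.5
            eta = B @ (np.array(beta) + b)
            eta = eta + c * (cond_effects[0] * B[:, 0] + cond_effects[1] * B[:, 1])
            rows.append(pd.DataFrame({
                "participant": f"p{p:02d}", "time_ms": times,
                "y": eta + rng.normal(0, noise, len(times)), "condition": cond,
            }))
    return pd.concat(rows, ignore_index=True)


class TestOrthogonalBasis:
    def test_order_4_gives_5_orthonormal_columns(self):
        basis = orthogonal_basis(np.arange(200.0, 1800.0, 4.0), 4)
        Q = basis.columns
        assert Q.shape[1] == 5
        assert np.max(np.abs(Q.T @ Q - np.eye(5))) < 1e-10

    def test_constant_first_column(self):
        Q = orthogonal_basis(np.arange(10.0), 2).columns
        assert np.allclose(Q[:, 0], Q[0, 0])
        assert Q[0, 0] > 0

    def test_linear_column_odd_on_symmetric_grid(self):
        t = np.linspace(-5, 5, 11)
        col = orthogonal_basis(t, 1).columns[:, 1]
        assert np.allclose(col + col[::-1], 0.0)
        assert col[-1] > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_basis(np.arange(3.0), 4)


class TestDegenerateLimits:
    def test_identity_no_random_equals_ols(self):
        rng = np.random.default_rng(0)
        df = make_linear_data(rng, n_p=6, re_sd=(0, 0, 0, 0))
        spec = GCASpec(response="erpd", order=3, factors=("condition",), random=None)
        fit = fit_gca(df, spec)
        X, names, *_ = build_design(df, spec)
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        assert np.max(np.abs(fit.coefficients.to_numpy() - ols.params)) < 1e-6

    def test_logistic_no_random_equals_glm(self):
        rng = np.random.default_rng(1)
        times = np.arange(200.0, 1800.0, 100.0)
        B = orthogonal_basis(times, 2).columns
        rows = []
        for p in range(8):
            c = -0.5 if p % 2 else 0.5
            eta = -0.3 * B[:, 0] * 4 + 3.0 * B[:, 1] + c * B[:, 1]
            n = np.full(len(times), 12.0)
            k = rng.binomial(12, expit(eta))
            rows.append(pd.DataFrame({
                "participant": f"p{p}", "time_ms": times, "y": k / n, "n": n,
                "condition": "a" if c < 0 else "b"}))
        df = pd.concat(rows, ignore_index=True)
        spec = GCASpec(response="fixation", order=2, factors=("condition",),
                       random=None)
        fit = fit_gca(df, spec)
        X, names, *_ = build_design(df, spec)
        k = (df["y"] * df["n"]).to_numpy()
        glm = sm.GLM(np.column_stack([k, df["n"].to_numpy() - k]), X,
                     family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.coefficients.to_numpy() - glm.params)) < 1e-6
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)


@pytest.fixture(scope="module")
def glmm_fixture():
    """Small binomial GLMM dataset with known random-coefficient structure."""
    rng = np.random.default_rng(7)
    times = np.arange(200.0, 1800.0, 80.0)
    B = orthogonal_basis(times, 2).columns
    rows = []
    for p in range(10):
        c = -0.5 if p % 2 else 0.5
        b = rng.normal(0, [0.5, 0.4, 0.3])
        eta = (-0.5 + b[0]) + (4.8 + b[1] * 4) * B[:, 1] + (-3.2 + b[2] * 4) * B[:, 2]
        eta = eta + 0.6 * c
        n = np.full(len(times), 13.0)
        k = rng.binomial(13, expit(eta))
        rows.append(pd.DataFrame({
            "participant": f"p{p:02d}", "time_ms": times, "y": k / n, "n": n,
            "condition": "mismatch" if c > 0 else "match"}))
    return pd.concat(rows, ignore_index=True)


class TestLogisticGLMM:
    def test_laplace_fit_matches_lme4_glmer(self, glmm_fixture, tmp_path):
        """Independent oracle: lme4's glmer uses the same Laplace
        approximation; log-likelihood and fixed effects must agree."""
        spec = GCASpec(response="fixation", order=2, factors=("condition",))
        fit = fit_gca(glmm_fixture, spec)
        X, names, blocks, Z, basis = build_design(glmm_fixture, spec)
        out = glmm_fixture.copy()
        for i in range(X.shape[1]):
            out[f"x{i}"] = X[:, i]
        for j in range(Z.shape[1]):
            out[f"z{j}"] = Z[:, j]
        out["k"] = (out.y * out.n).round().astype(int)
        out["nk"] = (out.n - out.k).round().astype(int)
        csv = tmp_path / "fixture.csv"
        out.to_csv(csv, index=False)
        xterms = "+".join(f"x{i}" for i in range(X.shape[1]))
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            f <- glmer(cbind(k, nk) ~ 0 + {xterms} + (0 + z0+z1+z2 || participant),
                       data=d, family=binomial)
            cat(sprintf("%.6f\\n", as.numeric(logLik(f))))
            cat(sprintf("%.6f\\n", fixef(f)))
        """))
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        values = [float(v) for v in res.stdout.split()]
        assert fit.loglik == pytest.approx(values[0], abs=1e-2)
        assert np.allclose(fit.coefficients.to_numpy(), values[1:], atol=1e-2)

    def test_random_effect_sds_recovered_in_scale(self, glmm_fixture):
        spec = GCASpec(response="fixation", order=2, factors=("condition",))
        fit = fit_gca(glmm_fixture, spec)
        assert fit.re_sd is not None and (fit.re_sd >= 0).all()
        assert fit.converged


class TestLRT:
    def test_identical_models_chi0_p1(self):
        rng = np.random.default_rng(2)
        df = make_linear_data(rng, n_p=5)
        spec = GCASpec(response="erpd", order=3, factors=("condition",), random=None)
        fit = fit_gca(df, spec)
        res = lrt_compare(fit, fit)
        assert res.chi_sq == 0.0 and res.p_value == 1.0 and res.df == 0

    def test_df_equals_added_terms(self):
        rng = np.random.default_rng(3)
        df = make_linear_data(rng, n_p=5)
        spec = GCASpec(response="erpd", order=3, factors=("condition",), random=None)
        small = fit_gca(df, spec, fixed_terms=[])
        ladder = default_ladder(df, spec)
        cols = [c for _, block in ladder for c in block]
        big = fit_gca(df, spec, fixed_terms=cols)
        res = lrt_compare(small, big)
        assert res.df == len(cols)

    def test_chi_sq_grows_with_participants_under_true_effect(self):
        spec = GCASpec(response="erpd", order=3, factors=("condition",))
        chis = []
        for n_p in (6, 30):
            rng = np.random.default_rng(44)
            df = make_linear_data(rng, n_p=n_p, cond_effects=(2.0, 2.0))
            base = fit_gca(df, spec, fixed_terms=[])
            full = fit_gca(df, spec)
            chis.append(lrt_compare(base, full).chi_sq)
        assert chis[1] > chis[0]


class TestSequentialComparison:
    def test_empty_ladder_empty_table(self):
        rng = np.random.default_rng(4)
        df = make_linear_data(rng, n_p=5)
        spec = GCASpec(response="erpd", order=3, factors=("condition",), random=None)
        table = sequential_comparison(df, spec, ladder=[])
        assert len(table) == 0

    def test_default_ladder_one_row_per_basis_term(self):
        rng = np.random.default_rng(5)
        df = make_linear_data(rng, n_p=5)
        spec = GCASpec(response="erpd", order=3, factors=("condition",), random=None)
        table = sequential_comparison(df, spec)
        assert len(table) == 4  # intercept, linear, quadratic, cubic blocks
        assert list(table["block"]) == ["intercept", "linear", "quadratic", "cubic"]
        assert (table["df"] == 1).all()  # two-level condition: one contrast


class TestInvariance:
    def test_fit_invariant_under_affine_time_rescaling(self):
        rng = np.random.default_rng(6)
        df = make_linear_data(rng, n_p=6, re_sd=(0, 0, 0, 0))
        spec = GCASpec(response="erpd", order=3, factors=("condition",), random=None)
        fit1 = fit_gca(df, spec)
        df2 = df.copy()
        df2["time_ms"] = df2["time_ms"] * 3.0 + 500.0
        fit2 = fit_gca(df2, spec)
        assert np.allclose(fit1.coefficients.to_numpy(),
                           fit2.coefficients.to_numpy(), atol=1e-8)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_single_participant_identity_equals_ols(self):
        rng = np.random.default_rng(8)
        df = make_linear_data(rng, n_p=1, re_sd=(0, 0, 0, 0))
        spec = GCASpec(response="erpd", order=3, factors=("condition",), random=None)
        fit = fit_gca(df, spec)
        X, *_ = build_design(df, spec)
        beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
        assert np.allclose(fit.coefficients.to_numpy(), beta, atol=1e-6)
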