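"""Growth-curve analysis (GCA) with orthogonal polynomials.

Time courses are modelled on an orthonormal polynomial basis over the
observed time grid: intercept, slope, rise-and-fall around the inflection
(quadratic), tail curvature (cubic), and a quartic term for the fixation
analysis.  Fixed effects are the basis terms and their interactions with the
experimental factors (Condition: target-matching vs target-mismatching cues;
Presentation: natural vs degraded speech); each participant gets random
coefficients on all basis terms (diagonal covariance).

Response families:

* fixation probability - binomial with a logistic link, 4th order, fitted on
  per-sample binary fixation indicators aggregated to counts (equivalently,
  per-sample binaries); an empirical-logit linear mode is also offered;
* %ERPD - Gaussian with identity link, 3rd order, on participant mean curves.

Linear mixed fits use statsmodels' MixedLM (maximum likelihood, diagonal
random covariance).  The logistic mixed fit maximises a Laplace
approximation to the marginal likelihood (the same approximation lme4's
glmer uses by default); in the zero-random-effect limit both reduce exactly
to ordinary least squares / plain logistic regression, which the tests
verify against independent fits.  Nested models are compared with likelihood
ratio tests, added block by block as in a sequential model-building ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = [
    "PolyBasis",
    "GCASpec",
    "GCAFit",
    "LRTResult",
    "orthogonal_basis",
    "build_design",
    "fit_gca",
    "lrt_compare",
    "default_ladder",
    "sequential_comparison",
]

TERM_NAMES = ["intercept", "linear", "quadratic", "cubic", "quartic"]

MAX_ITER = 200
REL_TOL = 1e-6  # relative log-likelihood change


@dataclass(frozen=True)
class PolyBasis:
    """Orthonormal polynomial columns over a time grid."""

    order: int
    times: np.ndarray
    columns: np.ndarray  # shape (len(times), order+1)

    def term_name(self, j: int) -> str:
        return TERM_NAMES[j] if j < len(TERM_NAMES) else f"poly{j}"


def orthogonal_basis(times, order: int) -> PolyBasis:
    """Orthonormalised powers of time, deterministic, column 0 constant.

    Times are affinely mapped to [-1, 1] before building the Vandermonde
    matrix, so fits are invariant under affine rescaling of the time axis.
    """
    times = np.asarray(times, dtype=np.float64)
    uniq = np.unique(times)
    if len(uniq) < order + 1:
        raise ValueError(f"need at least {order + 1} distinct time points")
    lo, hi = uniq[0], uniq[-1]
    z = (times - lo) / (hi - lo) * 2.0 - 1.0
    V = np.vander(z, order + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return PolyBasis(order, times, Q)


@dataclass(frozen=True)
class GCASpec:
    """What to fit: response family, polynomial order, factors, random part."""

    response: str = "fixation"  # "fixation" (logistic) | "erpd" (identity)
    order: int | None = None  # default: 4 for fixation, 3 for erpd
    factors: tuple = ("condition", "presentation")
    random: str | None = "participant"
    binary_mode: str = "per_sample"  # or "empirical_logit" (fixation only)

    def __post_init__(self) -> None:
        if self.response not in ("fixation", "erpd"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.order is None:
            object.__setattr__(self, "order", 4 if self.response == "fixation" else 3)
        if self.binary_mode not in ("per_sample", "empirical_logit"):
            raise ValueError(f"unknown binary_mode {self.binary_mode!r}")

    @property
    def link(self) -> str:
        if self.response == "fixation" and self.binary_mode == "per_sample":
            return "logistic"
        return "identity"


@dataclass(frozen=True)
class GCAFit:
    coefficients: pd.Series
    se: pd.Series
    re_sd: pd.Series | None
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    method: str
    spec: GCASpec

    def __post_init__(self) -> None:
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")

    def table(self) -> pd.DataFrame:
        """Model table: Factor / Estimate / Standard error / Significance."""
        z = self.coefficients / self.se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "Factor": self.coefficients.index,
            "Estimate": self.coefficients.to_numpy(),
            "Standard error": self.se.to_numpy(),
            "Significance": p,
        })


@dataclass(frozen=True)
class LRTResult:
    chi_sq: float
    df: int
    p_value: float
    label_small: str = ""
    label_big: str = ""

    def __post_init__(self) -> None:
        if self.chi_sq < 0 or self.df < 0:
            raise ValueError("invalid LRT")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _factor_contrasts(df: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Centred treatment contrasts (L-1 columns) for one factor."""
    levels = sorted(pd.unique(df[factor].astype(str)))
    cols = {}
    for lev in levels[1:]:
        ind = (df[factor].astype(str) == lev).astype(float)
        cols[f"{factor}[{lev}]"] = ind - ind.mean()
    return pd.DataFrame(cols, index=df.index)


def build_design(df: pd.DataFrame, spec: GCASpec):
    """Fixed design matrix, basis-term blocks and random design.

    Returns ``(X, names, blocks, Z, basis)`` where ``blocks`` maps each basis
    term name to the column names of its factor interactions (used by the
    sequential ladder) and ``Z`` is the per-row basis (random design).
    """
    grid = np.unique(df["time_ms"].to_numpy())
    basis = orthogonal_basis(grid, spec.order)
    rows = np.searchsorted(grid, df["time_ms"].to_numpy())
    Z = basis.columns[rows]  # n_obs x (order+1)

    contrast_sets = []
    for f in spec.factors:
        if f in df.columns and df[f].nunique() > 1:
            contrast_sets.append(_factor_contrasts(df, f))
    inter = None
    if len(contrast_sets) == 2:
        a, b = contrast_sets
        inter = pd.DataFrame(
            {f"{ca}:{cb}": a[ca] * b[cb] for ca in a.columns for cb in b.columns},
            index=df.index,
        )

    cols, names = [], []
    blocks: dict[str, list[str]] = {}
    for j in range(spec.order + 1):
        term = basis.term_name(j)
        cols.append(Z[:, j])
        names.append(term)
        block_cols = []
        for cs in contrast_sets + ([inter] if inter is not None else []):
            for c in cs.columns:
                name = f"{term}:{c}"
                cols.append(Z[:, j] * cs[c].to_numpy())
                names.append(name)
                block_cols.append(name)
        blocks[term] = block_cols
    X = np.column_stack(cols)
    return X, names, blocks, Z, basis


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _binom_loglik(k, n, eta):
    p = special.expit(eta)
    eps = 1e-12
    ll = k * np.log(p + eps) + (n - k) * np.log(1 - p + eps)
    const = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    return float(np.sum(ll + const))


def _irls_logistic(X, k, n, tol=1e-12, max_iter=100):
    """Plain binomial logistic regression by iteratively reweighted LS."""
    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = n * p * (1 - p) + 1e-10
        z = eta + (k - n * p) / w
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX + 1e-10 * np.eye(X.shape[1]), X.T @ (w * z))
        ll = _binom_loglik(k, n, X @ beta)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    p = special.expit(eta)
    w = n * p * (1 - p) + 1e-10
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + 1e-10 * np.eye(X.shape[1]))
    return beta, np.sqrt(np.diag(cov)), _binom_loglik(k, n, eta), converged


def _gaussian_mle(X, y):
    """Ordinary least squares with the Gaussian maximum likelihood."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    cov = sigma2 * n / max(n - X.shape[1], 1) * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), ll, sigma2


class _LaplaceGLMM:
    """Binomial GLMM with diagonal random covariance, Laplace approximation."""

    def __init__(self, X, Z, k, n, groups):
        self.X, self.Z, self.k, self.n = X, Z, k, n
        self.group_ids = pd.unique(groups)
        self.idx = {g: np.nonzero(groups == g)[0] for g in self.group_ids}
        self.q = Z.shape[1]
        self._warm = {g: np.zeros(self.q) for g in self.group_ids}

    def _group_nll(self, g, beta, var, update_warm=True):
        i = self.idx[g]
        Xg, Zg, kg, ng = self.X[i], self.Z[i], self.k[i], self.n[i]
        off = Xg @ beta
        b = self._warm[g].copy()
        Dinv = 1.0 / var

        def pen_ll(bv):
            eta = off + Zg @ bv
            p = special.expit(eta)
            eps = 1e-12
            return float(np.sum(kg * np.log(p + eps) + (ng - kg) * np.log(1 - p + eps))
                         - 0.5 * np.sum(bv * bv * Dinv))

        f = pen_ll(b)
        for _ in range(50):
            eta = off + Zg @ b
            p = special.expit(eta)
            w = ng * p * (1 - p) + 1e-10
            grad = Zg.T @ (kg - ng * p) - b * Dinv
            H = Zg.T @ (Zg * w[:, None]) + np.diag(Dinv)
            step = np.linalg.solve(H, grad)
            t = 1.0
            for _ in range(20):  # backtracking
                f_new = pen_ll(b + t * step)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            b = b + t * step
            if abs(f_new - f) < 1e-10 * max(1.0, abs(f)):
                f = f_new
                break
            f = f_new
        if update_warm:
            self._warm[g] = b
        eta = off + Zg @ b
        p = special.expit(eta)
        w = ng * p * (1 - p) + 1e-10
        H = Zg.T @ (Zg * w[:, None]) + np.diag(Dinv)
        sign, logdetH = np.linalg.slogdet(H)
        const = float(np.sum(special.gammaln(ng + 1) - special.gammaln(kg + 1)
                             - special.gammaln(ng - kg + 1)))
        log_marg = f + const - 0.5 * (logdetH + np.sum(np.log(var)))
        return -log_marg

    def nll(self, params):
        p = self.X.shape[1]
        beta = params[:p]
        var = np.exp(2.0 * params[p:])  # params hold log-SDs
        return sum(self._group_nll(g, beta, var) for g in self.group_ids)


def fit_gca(
    df: pd.DataFrame,
    spec: GCASpec,
    fixed_terms: list[str] | None = None,
) -> GCAFit:
    """Fit one growth-curve model.

    ``df`` columns: ``participant``, ``time_ms``, ``y`` (binary/0-1 success
    proportion for fixation, %ERPD value for erpd), optional ``n`` (binomial
    trial count per row, default 1), plus the factor columns named in the
    spec.  ``fixed_terms`` restricts the fixed part to the named design
    columns (basis terms themselves are always included); the default keeps
    the full factorial design.
    """
    X, names, blocks, Z, basis = build_design(df, spec)
    base_terms = [basis.term_name(j) for j in range(spec.order + 1)]
    if fixed_terms is None:
        keep = names
    else:
        keep = base_terms + [t for t in names if t in fixed_terms and t not in base_terms]
    sel = [names.index(t) for t in keep]
    Xs = X[:, sel]
    y = df["y"].to_numpy(dtype=float)
    n_trials = df["n"].to_numpy(dtype=float) if "n" in df.columns else np.ones(len(df))
    groups = df["participant"].to_numpy()
    if spec.response == "fixation" and spec.binary_mode == "empirical_logit":
        k = y * n_trials
        y = np.log((k + 0.5) / (n_trials - k + 0.5))

    if spec.link == "logistic":
        k = y * n_trials
        if spec.random is None:
            beta, se, ll, conv = _irls_logistic(Xs, k, n_trials)
            return GCAFit(pd.Series(beta, index=keep), pd.Series(se, index=keep),
                          None, ll, len(keep), len(df), conv, "irls_logistic", spec)
        model = _LaplaceGLMM(Xs, Z, k, n_trials, groups)
        beta0, *_ = _irls_logistic(Xs, k, n_trials)
        x0 = np.concatenate([beta0, np.full(Z.shape[1], np.log(0.5))])
        res = optimize.minimize(
            model.nll, x0, method="L-BFGS-B",
            bounds=[(None, None)] * len(beta0) + [(-6.0, 3.0)] * Z.shape[1],
            options={"maxiter": MAX_ITER, "ftol": REL_TOL * 1e-2},
        )
        p = Xs.shape[1]
        beta = res.x[:p]
        re_sd = np.exp(res.x[p:])
        # observed information for the fixed part, random part held at optimum
        def nll_beta(b):
            return model.nll(np.concatenate([b, res.x[p:]]))
        se = _numeric_se(nll_beta, beta)
        if not res.success and res.status != 1:  # status 1 = maxiter
            raise RuntimeError(f"logistic GLMM did not converge: {res.message}")
        return GCAFit(
            pd.Series(beta, index=keep), pd.Series(se, index=keep),
            pd.Series(re_sd, index=base_terms), float(-res.fun),
            p + Z.shape[1], len(df), bool(res.success), "laplace_glmm", spec,
        )

    # identity link
    if spec.random is None:
        beta, se, ll, _ = _gaussian_mle(Xs, y)
        return GCAFit(pd.Series(beta, index=keep), pd.Series(se, index=keep),
                      None, ll, len(keep) + 1, len(df), True, "ols", spec)
    q = Z.shape[1]
    free = MixedLMParams.from_components(
        fe_params=np.ones(Xs.shape[1]), cov_re=np.eye(q))
    model = MixedLM(y, Xs, groups=groups, exog_re=Z)
    # boundary fits (a variance component at zero) warn but their ML
    # log-likelihood is still the one the LRT needs
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, free=free, method="lbfgs",
                        maxiter=MAX_ITER, disp=False)
    re_sd = np.sqrt(np.maximum(np.diag(res.cov_re), 0.0) * res.scale)
    return GCAFit(
        pd.Series(np.asarray(res.fe_params), index=keep),
        pd.Series(np.asarray(res.bse_fe), index=keep),
        pd.Series(re_sd, index=base_terms),
        float(res.llf), Xs.shape[1] + q + 1, len(df),
        bool(res.converged), "mixedlm_ml", spec,
    )


def _numeric_se(f, x, h=1e-4):
    """Standard errors from a finite-difference Hessian of a negative ll."""
    p = len(x)
    H = np.zeros((p, p))
    f0 = f(x)
    fp = np.zeros(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h
        fp[i] = f(x + e)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            H[i, j] = H[j, i] = (f(x + ei + ej) - fp[i] - fp[j] + f0) / h**2
    try:
        cov = np.linalg.inv(H)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def lrt_compare(fit_small: GCAFit, fit_big: GCAFit) -> LRTResult:
    """Likelihood ratio test of nested fits on the same data."""
    if fit_small.n_obs != fit_big.n_obs:
        raise ValueError("fits must be on the same data")
    df = fit_big.n_params - fit_small.n_params
    if df < 0:
        raise ValueError("fit_big must have at least as many parameters")
    chi = max(0.0, 2.0 * (fit_big.loglik - fit_small.loglik))
    p = float(stats.chi2.sf(chi, df)) if df > 0 else 1.0
    return LRTResult(chi, df, p, fit_small.method, fit_big.method)


def default_ladder(df: pd.DataFrame, spec: GCASpec) -> list[tuple[str, list[str]]]:
    """One block per basis term: that term's interactions with the factors."""
    _, _, blocks, _, _ = build_design(df, spec)
    return [(term, cols) for term, cols in blocks.items() if cols]


def sequential_comparison(
    df: pd.DataFrame,
    spec: GCASpec,
    ladder: list[tuple[str, list[str]]] | None = None,
) -> pd.DataFrame:
    """Sequentially add fixed-effect blocks, LRT at each step.

    Mirrors the model-building tables: starting from the basis-only model,
    each ladder block (by default the factor interactions of one basis term,
    in term order) is added and the change in fit evaluated by a likelihood
    ratio test.  Returns one row per block.
    """
    if ladder is None:
        ladder = default_ladder(df, spec)
    rows = []
    included: list[str] = []
    current = fit_gca(df, spec, fixed_terms=included)
    for label, cols in ladder:
        bigger = fit_gca(df, spec, fixed_terms=included + cols)
        lrt = lrt_compare(current, bigger)
        rows.append({
            "block": label, "added_terms": len(cols), "chi_sq": lrt.chi_sq,
            "df": lrt.df, "p_value": lrt.p_value, "loglik": bigger.loglik,
        })
        included += cols
        current = bigger
    return pd.DataFrame(rows, columns=["block", "added_terms", "chi_sq", "df",
                                       "p_value", "loglik"])
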