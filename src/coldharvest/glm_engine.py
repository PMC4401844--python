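"""Log-linear count models for the annual and weekly mortality analyses.

Four families are supported:

``poisson``
    Maximum-likelihood Poisson regression.
``quasipoisson``
    Poisson point estimates with standard errors inflated by the square root
    of the Pearson dispersion ``phi = X^2 / (n - p)`` — the conventional
    quasi-likelihood treatment of overdispersed counts.
``negbin``
    Negative binomial (NB2) with the shape parameter estimated by ML.
``simple``
    Ordinary least squares of log(counts) on the design, coefficients read as
    log-rate effects.  No count likelihood exists, so AIC is undefined.

A stratum-conditional Poisson (the time-stratified case-crossover model) is
fitted by Newton iteration on the conditional log-likelihood in which the
stratum totals are conditioned out; its coefficients coincide with those of an
unconditional Poisson carrying one fixed effect per stratum.

Exposure coefficients live on the log-rate-per-degC scale; results are
reported as percent increase per degC, ``100 * (exp(beta) - 1)``, with Wald
95% intervals transformed from the log scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile

FAMILIES = ("poisson", "quasipoisson", "negbin", "simple")


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge; carries the trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


# --------------------------------------------------------------------------
# natural cubic spline basis


def natural_spline_basis(t: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) evaluated at ``t``.

    Boundary knots sit at min(t) and max(t); ``df - 1`` interior knots sit at
    equally spaced quantiles of ``t``.  With ``df + 1`` knots in total this
    reproduces the usual knots-minus-one parameterisation (e.g. a 6-knot
    natural spline has 5 degrees of freedom).  The basis is linear beyond the
    boundary knots: every column has zero second derivative there.

    Construction: with knots ``k_1 < ... < k_K`` define

        d_j(x) = [ (x - k_j)_+^3 - (x - k_K)_+^3 ] / (k_K - k_j)

    and take columns ``x`` and ``d_j(x) - d_{K-1}(x)`` for j = 1..K-2.

    Parameters
    ----------
    t
        Evaluation points (typically the year index 1..T).
    df
        Degrees of freedom, ``1 <= df <= len(unique(t)) - 2``; df=1 returns a
        single column affine in ``t``.
    """
    t = np.asarray(t, dtype=float)
    n_unique = len(np.unique(t))
    if not 1 <= df <= max(n_unique - 2, 1):
        raise ValueError(f"spline df={df} out of range for {n_unique} distinct points")
    if df == 1:
        return t[:, None].copy()
    # df+1 knots: boundaries at extremes, df-1 interior at equispaced quantiles
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(t, probs)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("degenerate (tied) spline knots; reduce df")
    k_last, k_penult = knots[-1], knots[-2]

    def d(x, kj):
        return (np.maximum(x - kj, 0) ** 3 - np.maximum(x - k_last, 0) ** 3) / (k_last - kj)

    basis = np.empty((len(t), df))
    basis[:, 0] = t
    for j in range(df - 1):
        basis[:, j + 1] = d(t, knots[j]) - d(t, k_penult)
    return basis


# --------------------------------------------------------------------------
# results container


@dataclass
class FitResult:
    """Fitted log-linear model with dispersion-scaled inference.

    Attributes
    ----------
    params, bse
        Coefficients (log-rate scale) and standard errors, indexed by term
        name.  For quasi-Poisson and the conditional model, ``bse`` is already
        scaled by sqrt(dispersion).
    dispersion
        Pearson dispersion ``phi``; 1.0 by convention for plain Poisson
        inference, NaN where it does not apply (simple regression).
    loglik
        Poisson (or NB) log-likelihood at the fitted values; NaN for simple
        regression and for the conditional model (which has only a conditional
        likelihood, stored in ``cond_loglik``).
    """

    params: pd.Series
    bse: pd.Series
    family: str
    dispersion: float
    loglik: float
    nobs: int
    df_resid: int
    fitted: np.ndarray
    response: np.ndarray
    cond_loglik: float = float("nan")
    n_strata: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n_terms(self) -> int:
        """Number of estimated mean-model terms."""
        return len(self.params)

    def conf_int(self, term: str) -> tuple[float, float]:
        b, se = self.params[term], self.bse[term]
        return b - Z95 * se, b + Z95 * se

    def percent_increase(self, term: str) -> tuple[float, float, float]:
        """Percent increase in deaths per unit of ``term``: (point, lo, hi)."""
        lo, hi = self.conf_int(term)
        return (
            100.0 * np.expm1(self.params[term]),
            100.0 * np.expm1(lo),
            100.0 * np.expm1(hi),
        )

    @property
    def aic(self) -> float:
        return model_aic(self)

    def summary_frame(self, percent_terms: tuple[str, ...] = ()) -> pd.DataFrame:
        """Tidy per-term table: beta, se, percent scale, phi, AIC."""
        rows = []
        for term in self.params.index:
            pct, lo, hi = self.percent_increase(term)
            rows.append(
                {
                    "term": term,
                    "beta": self.params[term],
                    "se": self.bse[term],
                    "pct": pct,
                    "pct_lo": lo,
                    "pct_hi": hi,
                    "phi": self.dispersion,
                    "aic": self.aic,
                }
            )
        out = pd.DataFrame(rows)
        if percent_terms:
            out = out[out["term"].isin(percent_terms)].reset_index(drop=True)
        return out


# --------------------------------------------------------------------------
# unconditional fits


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(np.asarray(X, dtype=float))
    if rank < X.shape[1]:
        # name the offending columns by greedy QR elimination
        bad = []
        cols = list(X.columns)
        arr = np.asarray(X, dtype=float)
        keep: list[int] = []
        for j in range(arr.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(arr[:, trial]) == len(trial):
                keep.append(j)
            else:
                bad.append(cols[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood including the y! normalising term."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    from scipy.special import gammaln

    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def fit_loglinear(y, X: pd.DataFrame, family: str = "quasipoisson") -> FitResult:
    """Fit a log-linear count model of ``y`` on design ``X``.

    ``X`` must include its intercept column explicitly.  See the module
    docstring for the family semantics.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    _check_design(X)
    n, p = X.shape

    if family == "simple":
        if (y <= 0).any():
            raise ValueError("family='simple' requires strictly positive counts (log response)")
        res = sm.OLS(np.log(y), X).fit()
        return FitResult(
            params=pd.Series(res.params, index=X.columns),
            bse=pd.Series(res.bse, index=X.columns),
            family=family,
            dispersion=float("nan"),
            loglik=float("nan"),
            nobs=n,
            df_resid=n - p,
            fitted=np.exp(np.asarray(res.fittedvalues)),
            response=y,
        )

    if family == "negbin":
        return _fit_negbin_profile(y, X)

    # poisson / quasipoisson share the ML point estimates
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=1e-10, maxiter=200)
    if not res.converged:
        raise ConvergenceError("Poisson IRLS did not converge", getattr(res, "fit_history", None))
    mu = np.asarray(res.mu)
    phi = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else float("nan")
    bse = np.asarray(res.bse)
    if family == "quasipoisson":
        bse = bse * np.sqrt(phi)
    return FitResult(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        family=family,
        dispersion=phi if family == "quasipoisson" else 1.0,
        loglik=poisson_loglik(y, mu),
        nobs=n,
        df_resid=n - p,
        fitted=mu,
        response=y,
        extra={"pearson_phi": phi},
    )


def _negbin_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood (var = mu + alpha*mu^2); valid for non-integer y."""
    from scipy.special import gammaln

    if alpha < 1e-10:
        return poisson_loglik(y, mu)
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv)
            - gammaln(inv)
            - gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _fit_negbin_profile(y: np.ndarray, X: pd.DataFrame) -> FitResult:
    """Negative binomial by profiling the shape: outer 1-D ML over log(alpha),
    inner IRLS GLM at fixed alpha.  Robust at the Poisson limit (alpha -> 0),
    where joint Newton-type optimisers stall on the boundary."""
    from scipy.optimize import minimize_scalar

    n, p = X.shape

    def fit_at(alpha: float):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=max(alpha, 1e-10))
            ).fit(tol=1e-10, maxiter=200)

    def neg_profile(log_alpha: float) -> float:
        res = fit_at(np.exp(log_alpha))
        return -_negbin_loglik(y, np.asarray(res.mu), np.exp(log_alpha))

    opt = minimize_scalar(neg_profile, bounds=(np.log(1e-8), np.log(1e4)),
                          method="bounded", options={"xatol": 1e-6})
    if not opt.success:
        raise ConvergenceError("negative binomial profile likelihood failed", opt)
    alpha = float(np.exp(opt.x))
    res = fit_at(alpha)
    mu = np.asarray(res.mu)
    return FitResult(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        bse=pd.Series(np.asarray(res.bse), index=X.columns),
        family="negbin",
        dispersion=float("nan"),
        loglik=_negbin_loglik(y, mu, alpha),
        nobs=n,
        df_resid=n - p,
        fitted=mu,
        response=y,
        extra={"nb_alpha": alpha},
    )


# --------------------------------------------------------------------------
# conditional (stratum-conditioned) Poisson


def fit_conditional_poisson(
    y,
    X: pd.DataFrame,
    strata,
    scale_dispersion: bool = True,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> FitResult:
    """Conditional quasi-Poisson: Poisson regression with stratum totals
    conditioned out (time-stratified case-crossover).

    Maximises ``sum_s sum_{i in s} y_i (x_i b - log sum_{j in s} exp(x_j b))``
    by Newton iteration with step-halving.  Strata with a single observation
    or zero total deaths carry no information and are dropped with a warning.
    Standard errors are scaled by the Pearson dispersion computed from the
    conditional fitted means ``mu_i = Y_s softmax(X_s b)_i`` with residual
    degrees of freedom ``n_kept - n_strata - p``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    _check_design(X)
    terms = list(X.columns)
    if "const" in terms or "intercept" in terms:
        raise ValueError("conditional model admits no intercept (absorbed by strata)")

    codes, uniques = pd.factorize(strata)
    keep = np.ones(len(y), dtype=bool)
    n_single = n_zero = 0
    for s in range(len(uniques)):
        mask = codes == s
        if mask.sum() < 2:
            keep[mask] = False
            n_single += 1
        elif y[mask].sum() == 0:
            keep[mask] = False
            n_zero += 1
    if n_single or n_zero:
        logger.warning(
            "dropped %d single-observation and %d all-zero strata", n_single, n_zero
        )
    y, Xa, codes = y[keep], np.asarray(X, dtype=float)[keep], codes[keep]
    codes = pd.factorize(codes)[0]  # recompact
    n_strata = codes.max() + 1
    n, p = Xa.shape

    # within-stratum centred exposures must vary somewhere
    centred = Xa - _stratum_mean(Xa, codes, np.ones(n))
    if np.allclose(centred, 0):
        raise ValueError("exposures constant within every stratum; coefficients inestimable")

    beta = np.zeros(p)
    ll = _cond_loglik(beta, y, Xa, codes, n_strata)
    trace = [ll]
    for _ in range(maxiter):
        g, H = _cond_score_hess(beta, y, Xa, codes, n_strata)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise ConvergenceError(f"singular conditional Hessian: {e}", trace) from e
        # step-halving on the conditional log-likelihood
        for half in range(30):
            cand = beta + step / (2**half)
            ll_new = _cond_loglik(cand, y, Xa, codes, n_strata)
            if ll_new >= ll - 1e-12:
                break
        else:
            raise ConvergenceError("step-halving failed in conditional Poisson", trace)
        beta, ll = cand, ll_new
        trace.append(ll)
        if np.max(np.abs(g)) < 1e-8 and np.linalg.norm(step) < tol * (1 + np.linalg.norm(beta)):
            break
    else:
        g, _ = _cond_score_hess(beta, y, Xa, codes, n_strata)
        if np.max(np.abs(g)) > 1e-6:
            raise ConvergenceError("conditional Poisson did not converge", trace)

    _, H = _cond_score_hess(beta, y, Xa, codes, n_strata)
    cov = np.linalg.inv(H)
    mu = _cond_fitted(beta, y, Xa, codes, n_strata)
    df_resid = n - n_strata - p
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / df_resid if df_resid > 0 else float("nan")
    bse = np.sqrt(np.diag(cov))
    if scale_dispersion:
        bse = bse * np.sqrt(phi)
    return FitResult(
        params=pd.Series(beta, index=terms),
        bse=pd.Series(bse, index=terms),
        family="conditional_quasipoisson" if scale_dispersion else "conditional_poisson",
        dispersion=phi if scale_dispersion else 1.0,
        loglik=float("nan"),
        nobs=n,
        df_resid=df_resid,
        fitted=mu,
        response=y,
        cond_loglik=ll,
        n_strata=int(n_strata),
    )


def _stratum_sum(values: np.ndarray, codes: np.ndarray, n_strata: int | None = None):
    n_strata = n_strata or codes.max() + 1
    if values.ndim == 1:
        return np.bincount(codes, weights=values, minlength=n_strata)
    return np.column_stack(
        [np.bincount(codes, weights=values[:, j], minlength=n_strata) for j in range(values.shape[1])]
    )


def _stratum_mean(values: np.ndarray, codes: np.ndarray, weights: np.ndarray):
    n_strata = codes.max() + 1
    wsum = np.bincount(codes, weights=weights, minlength=n_strata)
    if values.ndim == 1:
        return np.bincount(codes, weights=weights * values, minlength=n_strata)[codes] / wsum[codes]
    num = np.column_stack(
        [
            np.bincount(codes, weights=weights * values[:, j], minlength=n_strata)
            for j in range(values.shape[1])
        ]
    )
    return num[codes] / wsum[codes, None]


def _softmax_by_stratum(eta: np.ndarray, codes: np.ndarray, n_strata: int) -> np.ndarray:
    emax = np.full(n_strata, -np.inf)
    np.maximum.at(emax, codes, eta)
    w = np.exp(eta - emax[codes])
    denom = np.bincount(codes, weights=w, minlength=n_strata)
    return w / denom[codes]


def _cond_loglik(beta, y, X, codes, n_strata) -> float:
    eta = X @ beta
    emax = np.full(n_strata, -np.inf)
    np.maximum.at(emax, codes, eta)
    logdenom = emax + np.log(
        np.bincount(codes, weights=np.exp(eta - emax[codes]), minlength=n_strata)
    )
    return float(np.sum(y * (eta - logdenom[codes])))


def _cond_fitted(beta, y, X, codes, n_strata) -> np.ndarray:
    p = _softmax_by_stratum(X @ beta, codes, n_strata)
    Ys = np.bincount(codes, weights=y, minlength=n_strata)
    return Ys[codes] * p


def _cond_score_hess(beta, y, X, codes, n_strata):
    p = _softmax_by_stratum(X @ beta, codes, n_strata)
    Ys = np.bincount(codes, weights=y, minlength=n_strata)
    mu = Ys[codes] * p
    g = X.T @ (y - mu)
    # Hessian of the NEGATIVE loglik: sum_s Y_s (X' diag(p) X - (X'p)(X'p)')
    Xp = X * p[:, None]
    A = np.zeros((X.shape[1], X.shape[1]))
    # per-stratum outer products of X'p, accumulated without a python loop over rows
    Sxp = _stratum_sum(Xp, codes, n_strata)  # n_strata x p
    A += (X * (Ys[codes] * p)[:, None]).T @ X
    A -= (Sxp * Ys[:, None]).T @ Sxp
    return g, A


# --------------------------------------------------------------------------
# AIC and residual diagnostics


def model_aic(fit: FitResult) -> float:
    """Akaike information criterion, ``-2 log L + 2 k``.

    ``k`` counts the estimated mean-model terms (the NB shape parameter adds
    one).  For quasi-Poisson the unscaled Poisson likelihood is used.  Simple
    regression has no count likelihood: returns NaN (printed as NA).
    """
    if fit.family == "simple" or not np.isfinite(fit.loglik):
        return float("nan")
    k = fit.n_terms + (1 if fit.family == "negbin" else 0)
    return -2.0 * fit.loglik + 2.0 * k


def deviance_residuals(fit: FitResult) -> np.ndarray:
    """Signed square-root Poisson deviance residuals."""
    y, mu = fit.response, fit.fitted
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    d2 = 2.0 * (term - (y - mu))
    return np.sign(y - mu) * np.sqrt(np.maximum(d2, 0.0))


def residual_diagnostics(fit: FitResult, time_order: np.ndarray | None = None) -> dict:
    """Basic residual checks: deviance residuals in time order, residual-vs-
    fitted pairs, and the lag-1 autocorrelation with its ~95% null band
    ``+/- 1.96/sqrt(n)``."""
    resid = deviance_residuals(fit)
    order = np.argsort(time_order) if time_order is not None else np.arange(len(resid))
    r = resid[order]
    n = len(r)
    rc = r - r.mean()
    denom = float(rc @ rc)
    lag1 = float(rc[1:] @ rc[:-1] / denom) if denom > 0 else 0.0
    band = Z95 / np.sqrt(n)
    return {
        "deviance_residuals": r,
        "fitted": fit.fitted[order],
        "lag1_autocorrelation": lag1,
        "autocorrelation_band": band,
        "within_band": abs(lag1) < band,
        "mean_residual": float(r.mean()),
    }
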