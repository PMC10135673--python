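"""Trait-response curve estimation.

Per-trait counts are modelled with a negative-binomial GLM (log link,
variance ``mu + mu**2/k`` with overdispersion parameter ``k``); per-metric
diversity responses with a Gaussian linear model.  The predictor (flow
velocity, turbidity or elevation) is centred by subtracting its mean before
fitting, which weakens the collinearity between the linear and quadratic
terms; the centring constant is stored so predictions map back to the
original scale.

Model selection is backward elimination: the quadratic model is fitted
first; if the quadratic term is not significant at level ``alpha`` it is
dropped and the linear term is tested at the same level; if that also fails
an intercept-only model is returned.  Term tests are likelihood-ratio tests
(chi-square, 1 df) for both families.

Negative-binomial maximum likelihood alternates IRLS for the coefficients
at fixed ``k`` with a bounded one-dimensional profile maximisation of the
likelihood over ``log k`` (``k`` constrained to [1e-3, 1e6]; boundary hits
are flagged).  Gaussian fits are closed-form least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import EstimationError, ValidationError

__all__ = [
    "ResponseFit",
    "center_predictor",
    "fit_negbin",
    "fit_linear",
    "backward_select",
    "response_curve",
    "residual_diagnostics",
]

K_MIN, K_MAX = 1e-3, 1e6
_LL_RTOL = 1e-8
_MAX_OUTER = 100

FORMS = ("intercept", "linear", "quadratic")


def center_predictor(x: np.ndarray | list) -> tuple[np.ndarray, float]:
    """Centre a predictor by subtracting its mean; returns (centred, mean)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot centre an empty predictor vector")
    if np.any(~np.isfinite(x)):
        raise ValidationError("predictor contains missing values; filter incomplete sites first")
    m = float(x.mean())
    return x - m, m


def _design(xc: np.ndarray, form: str) -> np.ndarray:
    if form not in FORMS:
        raise ValidationError(f"form must be one of {FORMS}, got {form!r}")
    cols = [np.ones_like(xc)]
    if form in ("linear", "quadratic"):
        cols.append(xc)
    if form == "quadratic":
        cols.append(xc**2)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# low-level fitters (shared with the segmented module, arbitrary design)
# ---------------------------------------------------------------------------


@dataclass
class GlmFit:
    """Raw fit of y on an arbitrary design matrix."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    family: str
    k: float | None = None
    converged: bool = True
    k_at_boundary: bool = False
    mu: np.ndarray | None = None
    sigma2: float | None = None  # Gaussian ML variance


def nb_loglik(y: np.ndarray, mu: np.ndarray, k: float) -> float:
    mu = np.clip(mu, 1e-12, None)
    return float(
        np.sum(
            special.gammaln(y + k)
            - special.gammaln(k)
            - special.gammaln(y + 1)
            + k * np.log(k / (k + mu))
            + y * np.log(mu / (k + mu))
        )
    )


def _irls_nb(y: np.ndarray, X: np.ndarray, k: float, beta: np.ndarray,
             tol: float = 1e-10, maxit: int = 50) -> tuple[np.ndarray, bool]:
    """IRLS for the NB2 log-link coefficients at fixed k."""
    ll_old = -np.inf
    ok = False
    for _ in range(maxit):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu * k / (k + mu)
        z = eta + (y - mu) / mu
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular design in negative-binomial IRLS: {exc}") from exc
        ll = nb_loglik(y, np.exp(np.clip(X @ beta, -30.0, 30.0)), k)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            ok = True
            break
        ll_old = ll
    return beta, ok


def nb_fit(y: np.ndarray, X: np.ndarray) -> GlmFit:
    """Negative-binomial ML: alternate IRLS for beta with bounded profile ML for k."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValidationError("count response must be non-negative integers")
    if y.sum() == 0:
        raise EstimationError(
            "all-zero count response: exclude this trait via the sparsity filter before modelling"
        )
    n, p = X.shape
    if n < p + 2:
        raise ValidationError(f"need at least {p + 2} observations for {p} parameters, got {n}")

    beta = np.zeros(p)
    beta[0] = np.log(y.mean() + 1e-8)
    m, v = y.mean(), y.var()
    k = float(np.clip(m**2 / (v - m), K_MIN, K_MAX)) if v > m else 1e4

    ll_old = -np.inf
    converged = False
    for _ in range(_MAX_OUTER):
        beta, _ = _irls_nb(y, X, k, beta)
        mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
        res = optimize.minimize_scalar(
            lambda lk: -nb_loglik(y, mu, np.exp(lk)),
            bounds=(np.log(K_MIN), np.log(K_MAX)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        k = float(np.exp(res.x))
        ll = nb_loglik(y, mu, k)
        if abs(ll - ll_old) < _LL_RTOL * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll

    mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
    w = mu * k / (k + mu)
    cov = np.linalg.inv((X.T * w) @ X)
    boundary = k <= K_MIN * 1.01 or k >= K_MAX * 0.99
    return GlmFit(beta=beta, cov=cov, loglik=nb_loglik(y, mu, k), family="negative-binomial",
                  k=k, converged=converged, k_at_boundary=boundary, mu=mu)


def gaussian_fit(y: np.ndarray, X: np.ndarray) -> GlmFit:
    """Gaussian ML via least squares; sigma^2 is the ML (1/n) estimate."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValidationError(f"need at least {p + 2} observations for {p} parameters, got {n}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    # Wald covariance uses the unbiased variance estimate
    s2 = rss / max(n - p, 1)
    try:
        cov = s2 * np.linalg.inv(X.T @ X)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular design in least squares: {exc}") from exc
    return GlmFit(beta=beta, cov=cov, loglik=ll, family="gaussian", mu=X @ beta, sigma2=sigma2)


# ---------------------------------------------------------------------------
# public single-predictor response fits
# ---------------------------------------------------------------------------


@dataclass
class ResponseFit:
    """A fitted single-predictor response curve on the centred scale."""

    response: str
    predictor: str
    family: str
    form: str
    coefficients: np.ndarray
    center: float
    loglik: float
    converged: bool
    k: float | None = None
    k_at_boundary: bool = False
    cov: np.ndarray | None = None
    p_values: dict[str, float] = field(default_factory=dict)
    trace: list[dict] = field(default_factory=list)
    x_range: tuple[float, float] = (-np.inf, np.inf)
    y: np.ndarray | None = None
    xc: np.ndarray | None = None
    mu: np.ndarray | None = None

    def linear_predictor(self, xc: np.ndarray) -> np.ndarray:
        eta = np.full_like(np.asarray(xc, dtype=float), self.coefficients[0])
        if self.form in ("linear", "quadratic"):
            eta = eta + self.coefficients[1] * xc
        if self.form == "quadratic":
            eta = eta + self.coefficients[2] * xc**2
        return eta


def _wald_p(fit: GlmFit) -> dict[str, float]:
    names = ["intercept", "linear", "quadratic"][: fit.beta.size]
    se = np.sqrt(np.diag(fit.cov))
    z = fit.beta / np.where(se > 0, se, np.inf)
    return {nm: float(2 * stats.norm.sf(abs(zi))) for nm, zi in zip(names, z)}


def _wrap(fit: GlmFit, form: str, xc: np.ndarray, y: np.ndarray, center: float,
          response: str, predictor: str) -> ResponseFit:
    return ResponseFit(
        response=response, predictor=predictor, family=fit.family, form=form,
        coefficients=fit.beta, center=center, loglik=fit.loglik, converged=fit.converged,
        k=fit.k, k_at_boundary=fit.k_at_boundary, cov=fit.cov, p_values=_wald_p(fit),
        x_range=(float(xc.min() + center), float(xc.max() + center)),
        y=y, xc=xc, mu=fit.mu,
    )


def fit_negbin(y, xc, form: str = "linear", *, center: float = 0.0,
               response: str = "trait", predictor: str = "x") -> ResponseFit:
    """Negative-binomial response fit of counts on a centred predictor."""
    xc = np.asarray(xc, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = nb_fit(y, _design(xc, form))
    return _wrap(fit, form, xc, y, center, response, predictor)


def fit_linear(y, xc, form: str = "linear", *, center: float = 0.0,
               response: str = "metric", predictor: str = "x") -> ResponseFit:
    """Gaussian response fit of a diversity metric on a centred predictor."""
    xc = np.asarray(xc, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    if not mask.all():
        y, xc = y[mask], xc[mask]
    fit = gaussian_fit(y, _design(xc, form))
    return _wrap(fit, form, xc, y, center, response, predictor)


def _fit(y, xc, family: str, form: str, **kw) -> ResponseFit:
    if family in ("negative-binomial", "negbin", "nb"):
        return fit_negbin(y, xc, form, **kw)
    if family in ("gaussian", "linear", "lrm"):
        return fit_linear(y, xc, form, **kw)
    raise ValidationError(f"unknown family {family!r}")


def backward_select(y, x, family: str, alpha: float = 0.05, *,
                    response: str = "y", predictor: str = "x") -> ResponseFit:
    """Quadratic -> linear -> intercept backward elimination with LR tests.

    Lower-order terms are always retained under a significant higher-order
    term (hierarchy principle).  The selection trace records every fitted
    form, the LR statistic and p-value, and the keep/drop decision.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    xc, center = center_predictor(x)
    kw = dict(center=center, response=response, predictor=predictor)
    trace: list[dict] = []

    quad = _fit(y, xc, family, "quadratic", **kw)
    lin = _fit(y, xc, family, "linear", **kw)
    lr_q = max(2.0 * (quad.loglik - lin.loglik), 0.0)
    p_q = float(stats.chi2.sf(lr_q, 1))
    trace.append({"term": "quadratic", "lr_stat": lr_q, "p_value": p_q, "kept": p_q < alpha})
    if p_q < alpha:
        quad.trace = trace
        quad.p_values["quadratic_lr"] = p_q
        return quad

    inter = _fit(y, xc, family, "intercept", **kw)
    lr_l = max(2.0 * (lin.loglik - inter.loglik), 0.0)
    p_l = float(stats.chi2.sf(lr_l, 1))
    trace.append({"term": "linear", "lr_stat": lr_l, "p_value": p_l, "kept": p_l < alpha})
    chosen = lin if p_l < alpha else inter
    chosen.trace = trace
    chosen.p_values["linear_lr"] = p_l
    return chosen


def response_curve(fit: ResponseFit, grid, *, extrapolation_band: float = 0.0):
    """Predicted mean response over a grid on the *original* predictor scale.

    Returns (predicted mean, extrapolation-warning flags).  Grid points more
    than ``extrapolation_band`` times the observed range outside that range
    are flagged (never suppressed).
    """
    if not fit.converged:
        raise EstimationError("cannot predict from a non-converged fit")
    grid = np.asarray(grid, dtype=float)
    eta = fit.linear_predictor(grid - fit.center)
    mean = np.exp(np.clip(eta, -700, 700)) if fit.family == "negative-binomial" else eta
    lo, hi = fit.x_range
    slack = extrapolation_band * (hi - lo)
    flags = (grid < lo - slack) | (grid > hi + slack)
    return mean, flags


def residual_diagnostics(fit: ResponseFit) -> pd.DataFrame:
    """Deviance residual vs fitted value pairs (for homogeneity checks).

    The returned frame carries ``mean`` and ``spread`` attributes summarising
    the residuals; no automatic pass/fail is applied.
    """
    if fit.y is None or fit.mu is None:
        raise ValidationError("fit does not carry its training data")
    y, mu = fit.y, fit.mu
    if fit.family == "negative-binomial":
        k = fit.k
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        dev = 2.0 * (term - (y + k) * np.log((y + k) / (mu + k)))
        resid = np.sign(y - mu) * np.sqrt(np.clip(dev, 0.0, None))
    else:
        resid = y - mu
    out = pd.DataFrame({"fitted": mu, "deviance_residual": resid})
    out.attrs["mean"] = float(resid.mean())
    out.attrs["spread"] = float(resid.std(ddof=1)) if resid.size > 1 else 0.0
    return out
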