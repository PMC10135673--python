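"""Tipping-point (breakpoint) estimation via segmented regression.

A segmented (broken-line) relationship on the linear-predictor scale is

    y = alpha + beta1 * x                           for x <  psi
    y = (alpha - beta2 * psi) + (beta1 + beta2) * x for x >  psi

where ``psi`` is the tipping point and ``beta2`` the difference in slopes;
the two lines meet at ``x = psi``.  Estimation follows the iterative
linearisation of Muggeo: the model is refitted with the hinge term
``U = (x - psi)+`` and the correction term ``V = -1(x > psi)``, and ``psi``
is updated by the ratio of the two coefficients until it stabilises.  The
standard error of ``psi`` comes from the delta method on that ratio.

Because ``beta2`` vanishes when no breakpoint exists, its null distribution
is non-standard (``psi`` is undefined under the null).  Existence is tested
by maximising a one-degree statistic over K interior candidate breakpoints
and applying the Davies (1987) bound to the maximum: a Wald t statistic per
candidate for Gaussian responses (Davies test) and a Rao score statistic
per candidate for negative-binomial responses (score test).

Among segmented fits started from a grid of initial values, the final
estimate is the converged one closest to the candidate the existence test
ranked best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import EstimationError, ValidationError
from .models import GlmFit, _irls_nb, gaussian_fit, nb_fit, nb_loglik

__all__ = [
    "SegmentedResult",
    "ExistenceTest",
    "piecewise_predict",
    "segmented_fit",
    "davies_test",
    "score_test",
    "select_tipping_point",
]

_NB_ALIASES = ("negative-binomial", "negbin", "nb")
_GAUSS_ALIASES = ("gaussian", "linear", "lrm")


def _local_profile_max(profile_ll, left: float, right: float, tol: float,
                       n_scan: int = 25) -> float:
    """Maximise a kinked profile likelihood over [left, right]: coarse scan to
    bracket the dominant local optimum, then a bounded scalar refinement."""
    grid = np.linspace(left, right, n_scan)
    lls = np.array([profile_ll(p) for p in grid])
    j = int(np.nanargmax(lls))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, n_scan - 1)]
    if hi <= lo:
        return float(grid[j])
    res = optimize.minimize_scalar(lambda p: -profile_ll(p), bounds=(lo, hi),
                                   method="bounded", options={"xatol": max(tol, 1e-10)})
    if np.isfinite(res.fun) and -res.fun >= lls[j]:
        return float(res.x)
    return float(grid[j])


def piecewise_predict(params, x) -> np.ndarray:
    """Evaluate the broken line (alpha, beta1, beta2, psi) on the
    linear-predictor scale; both branch formulas agree at x = psi."""
    alpha, beta1, beta2, psi = (float(v) for v in params)
    x = np.asarray(x, dtype=float)
    return np.where(x < psi, alpha + beta1 * x, (alpha - beta2 * psi) + (beta1 + beta2) * x)


@dataclass
class SegmentedResult:
    """One fitted breakpoint model plus its existence-test verdict."""

    response: str
    predictor: str
    family: str
    psi: float
    psi_se: float
    alpha: float          # left-segment intercept
    beta1: float          # left-segment slope
    beta2: float          # difference in slopes; right slope = beta1 + beta2
    loglik: float
    converged: bool
    k: float | None = None
    test_name: str | None = None
    statistic: float | None = None
    p_value: float | None = None
    test_best_psi: float | None = None
    significant: bool | None = None
    n_iter: int = 0
    trace: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.alpha, self.beta1, self.beta2, self.psi)

    def predict(self, x) -> np.ndarray:
        """Mean response on the original scale (exp link for counts)."""
        eta = piecewise_predict(self.params, x)
        if self.family in _NB_ALIASES:
            return np.exp(np.clip(eta, -700, 700))
        return eta


def _family_fit(y: np.ndarray, X: np.ndarray, family: str, *, k_fixed: float | None = None) -> GlmFit:
    if family in _GAUSS_ALIASES:
        return gaussian_fit(y, X)
    if family in _NB_ALIASES:
        if k_fixed is None:
            return nb_fit(y, X)
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(y.mean() + 1e-8)
        beta, ok = _irls_nb(y, X, k_fixed, beta)
        mu = np.exp(np.clip(X @ beta, -30, 30))
        w = mu * k_fixed / (k_fixed + mu)
        cov = np.linalg.inv((X.T * w) @ X)
        return GlmFit(beta=beta, cov=cov, loglik=nb_loglik(y, mu, k_fixed),
                      family="negative-binomial", k=k_fixed, converged=ok, mu=mu)
    raise ValidationError(f"unknown family {family!r}")


def segmented_fit(y, x, family: str, psi_start: float, *,
                  response: str = "y", predictor: str = "x",
                  tol_factor: float = 1e-6, max_iter: int = 50,
                  reestimate_k: bool = True, min_segment: int = 10) -> SegmentedResult:
    """Iteratively estimate a single breakpoint from one starting value.

    ``reestimate_k`` controls whether the NB dispersion is re-estimated at
    every iteration (default) or held at the null linear fit's value.  A
    start with fewer than ``min_segment`` observations on either side gets a
    warning; the estimate is still attempted.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if not (lo < psi_start < hi):
        raise ValidationError(f"psi_start {psi_start} must lie strictly inside ({lo}, {hi})")
    warnings: list[str] = []
    if min((x < psi_start).sum(), (x > psi_start).sum()) < min_segment:
        warnings.append(f"fewer than {min_segment} observations on one side of the start {psi_start:.4g}")

    k_fixed = None
    if family in _NB_ALIASES and not reestimate_k:
        null = nb_fit(y, np.column_stack([np.ones_like(x), x]))
        k_fixed = null.k

    tol = tol_factor * (hi - lo)

    def _profile_ll(psi_val: float) -> float:
        Xh = np.column_stack([np.ones_like(x), x, np.clip(x - psi_val, 0.0, None)])
        try:
            return _family_fit(y, Xh, family, k_fixed=k_fixed).loglik
        except (EstimationError, np.linalg.LinAlgError):
            return -np.inf

    psi = float(psi_start)
    psi_hist = [psi]
    converged = False
    last_fit: GlmFit | None = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        U = np.clip(x - psi, 0.0, None)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        try:
            fit = _family_fit(y, X, family, k_fixed=k_fixed)
        except (EstimationError, np.linalg.LinAlgError) as exc:
            return SegmentedResult(response, predictor, family, psi, np.nan,
                                   np.nan, np.nan, np.nan, -np.inf, False,
                                   n_iter=n_iter, warnings=warnings + [f"fit failed: {exc}"])
        last_fit = fit
        b2, gamma = fit.beta[2], fit.beta[3]
        if abs(b2) < 1e-12:
            warnings.append("difference-in-slopes estimate collapsed to zero")
            break
        step = gamma / b2
        psi_new = psi + step
        # step-halve back inside the data range rather than diverging
        halvings = 0
        while not (lo < psi_new < hi) and halvings < 20:
            step *= 0.5
            psi_new = psi + step
            halvings += 1
        if not (lo < psi_new < hi):
            warnings.append("breakpoint escaped the data range; last in-range iterate reported")
            break
        if abs(psi_new - psi) < tol:
            psi = psi_new
            converged = True
            break
        # the hinge moves in discrete jumps between data points, so the
        # iteration can settle into a cycle; resolve a revisit by a bounded
        # profile-likelihood search over the cycle's span
        revisits = [j for j, p in enumerate(psi_hist[:-1]) if abs(psi_new - p) < tol]
        if revisits:
            cycle = psi_hist[revisits[-1]:] + [psi_new]
            pad = (hi - lo) / x.size
            left = max(lo + 1e-12, min(cycle) - pad)
            right = min(hi - 1e-12, max(cycle) + pad)
            psi = _local_profile_max(_profile_ll, left, right, tol)
            converged = True
            break
        psi_hist.append(psi_new)
        psi = psi_new

    if last_fit is None:  # pragma: no cover - loop always runs once
        raise EstimationError("segmented iteration produced no fit")

    if converged:
        # the profile likelihood is kinked at the data points, so the working
        # fixed point can sit a fraction of a data gap off the argmax; polish
        # by a bounded scalar search between the surrounding observations
        xs = np.unique(x)
        i = int(np.searchsorted(xs, psi))
        left = max(float(xs[max(i - 4, 0)]), lo + 1e-12)
        right = min(float(xs[min(i + 3, xs.size - 1)]), hi - 1e-12)
        if left < right:
            cand = _local_profile_max(_profile_ll, left, right, tol)
            if _profile_ll(cand) > _profile_ll(psi):
                psi = cand

    # delta-method SE of psi from the (U, V) block of the working fit at the
    # final iterate
    try:
        Xw = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None),
                              -(x > psi).astype(float)])
        last_fit = _family_fit(y, Xw, family, k_fixed=k_fixed)
    except (EstimationError, np.linalg.LinAlgError):
        pass  # keep the last successful working fit for the SE
    b2, gamma = last_fit.beta[2], last_fit.beta[3]
    cov = last_fit.cov
    if abs(b2) > 1e-12:
        r = gamma / b2
        var_psi = (cov[3, 3] + r * r * cov[2, 2] - 2.0 * r * cov[2, 3]) / (b2 * b2)
        psi_se = float(np.sqrt(max(var_psi, 0.0)))
    else:
        psi_se = np.nan

    # clean refit at the final psi: hinge only, exact continuity at psi
    U = np.clip(x - psi, 0.0, None)
    Xc = np.column_stack([np.ones_like(x), x, U])
    try:
        clean = _family_fit(y, Xc, family, k_fixed=k_fixed)
    except (EstimationError, np.linalg.LinAlgError) as exc:
        return SegmentedResult(response, predictor, family, psi, psi_se,
                               np.nan, np.nan, np.nan, -np.inf, False,
                               n_iter=n_iter, warnings=warnings + [f"final refit failed: {exc}"])
    if min((x < psi).sum(), (x > psi).sum()) < min_segment:
        warnings.append(f"fewer than {min_segment} observations on one side of psi = {psi:.4g}")
    return SegmentedResult(
        response=response, predictor=predictor,
        family="negative-binomial" if family in _NB_ALIASES else "gaussian",
        psi=psi, psi_se=psi_se,
        alpha=float(clean.beta[0]), beta1=float(clean.beta[1]), beta2=float(clean.beta[2]),
        loglik=clean.loglik, converged=converged, k=clean.k,
        n_iter=n_iter, warnings=warnings,
    )


# ---------------------------------------------------------------------------
# breakpoint-existence tests
# ---------------------------------------------------------------------------


@dataclass
class ExistenceTest:
    name: str
    best_psi: float
    statistic: float
    p_value: float
    candidates: np.ndarray
    statistics: np.ndarray


def _candidates(x: np.ndarray, K: int) -> np.ndarray:
    probs = np.arange(1, K + 1) / (K + 1)
    cand = np.unique(np.quantile(x, probs))
    lo, hi = x.min(), x.max()
    return cand[(cand > lo) & (cand < hi)]


def _davies_bound_p(tstats: np.ndarray, df: float | None = None) -> float:
    """Two-sided Davies (1987) bound for the max of |W| over candidates.

    Union bound over the process and its negative: each one-sided tail is
    ``sf(M) + V * exp(-M^2/2) / sqrt(8*pi)`` with V the total variation of
    the statistic sequence; ``df`` switches the tail to Student t (Gaussian
    responses with estimated variance)."""
    M = float(np.max(np.abs(tstats)))
    total_variation = float(np.sum(np.abs(np.diff(tstats))))
    tail = stats.t.sf(M, df) if df is not None else stats.norm.sf(M)
    p = 2.0 * (tail + total_variation * np.exp(-0.5 * M * M) / np.sqrt(8.0 * np.pi))
    return float(min(p, 1.0))


def davies_test(y, x, K: int = 10) -> ExistenceTest:
    """Breakpoint-existence test for Gaussian responses.

    Fits ``y ~ 1 + x + (x - psi)+`` at K interior candidate quantiles of x,
    takes the Wald t statistic of the hinge term at each, and bounds the
    p-value of the extreme statistic with the Davies adjustment.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 10:
        raise ValidationError(f"Davies test needs at least 10 observations, got {y.size}")
    if K < 2:
        raise ValidationError("need at least 2 candidate breakpoints")
    cand = _candidates(x, K)
    y_scale = float(y @ y) + 1.0
    tstats = np.empty(cand.size)
    for i, psi in enumerate(cand):
        X = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
        fit = gaussian_fit(y, X)
        se = np.sqrt(fit.cov[2, 2])
        # a (near-)perfect fit carries no evidence for a slope change
        perfect = fit.sigma2 is not None and fit.sigma2 * y.size <= 1e-12 * y_scale
        tstats[i] = fit.beta[2] / se if (se > 0 and not perfect) else 0.0
    best = int(np.argmax(np.abs(tstats)))
    return ExistenceTest("davies", float(cand[best]), float(tstats[best]),
                         _davies_bound_p(tstats, df=y.size - 3), cand, tstats)


def score_test(y, x, K: int = 10) -> ExistenceTest:
    """Breakpoint-existence score test for negative-binomial responses.

    Under the null linear NB fit, the Rao score statistic for adding the
    hinge ``(x - psi)+`` is evaluated at K candidates (dispersion held at
    the null estimate) and the maximum receives the Davies-bound p-value.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 10:
        raise ValidationError(f"score test needs at least 10 observations, got {y.size}")
    X0 = np.column_stack([np.ones_like(x), x])
    null = nb_fit(y, X0)
    if not null.converged:
        raise EstimationError("null negative-binomial fit did not converge")
    mu, k = null.mu, null.k
    w = mu * k / (k + mu)
    score_resid = (y - mu) * k / (k + mu)
    XtWX_inv = np.linalg.inv((X0.T * w) @ X0)
    cand = _candidates(x, K)
    zstats = np.empty(cand.size)
    for i, psi in enumerate(cand):
        u = np.clip(x - psi, 0.0, None)
        U_stat = float(u @ score_resid)
        wu = w * u
        v_eff = float(u @ wu) - float(wu @ X0 @ XtWX_inv @ (X0.T @ wu))
        zstats[i] = U_stat / np.sqrt(v_eff) if v_eff > 0 else 0.0
    best = int(np.argmax(np.abs(zstats)))
    return ExistenceTest("score", float(cand[best]), float(zstats[best]),
                         _davies_bound_p(zstats), cand, zstats)


# ---------------------------------------------------------------------------
# selection rule
# ---------------------------------------------------------------------------


def _start_grid(x: np.ndarray, n_starts: int = 9) -> np.ndarray:
    probs = np.linspace(0.1, 0.9, n_starts)
    q05, q95 = np.quantile(x, [0.05, 0.95])
    starts = np.unique(np.quantile(x, probs))
    return starts[(starts >= q05) & (starts <= q95)]


def select_tipping_point(y, x, family: str, *, K: int = 10, alpha: float = 0.05,
                         start_grid=None, response: str = "y", predictor: str = "x",
                         reestimate_k: bool = True, min_segment: int = 5) -> SegmentedResult:
    """Existence test + multi-start segmented fits + closest-estimate rule.

    The Davies test (Gaussian) or score test (negative-binomial) provides a
    "best" candidate breakpoint and a p-value.  Segmented fits are run from
    a grid of starting values spanning the interior of x; among converged
    fits the estimate closest to the test's best candidate wins (ties: the
    higher log-likelihood, then the smaller psi).  The verdict flag is
    ``p < alpha``; a non-significant estimate is still reported.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    test = davies_test(y, x, K) if family in _GAUSS_ALIASES else score_test(y, x, K)

    starts = np.asarray(start_grid, dtype=float) if start_grid is not None else _start_grid(x)
    fits: list[SegmentedResult] = []
    trace: list[dict] = []
    for s in starts:
        try:
            res = segmented_fit(y, x, family, float(s), response=response, predictor=predictor,
                                reestimate_k=reestimate_k, min_segment=min_segment)
        except ValidationError as exc:
            trace.append({"start": float(s), "converged": False, "error": str(exc)})
            continue
        trace.append({
            "start": float(s), "converged": res.converged, "psi": res.psi,
            "loglik": res.loglik, "distance_to_test_best": abs(res.psi - test.best_psi),
        })
        if res.converged:
            fits.append(res)

    if not fits:
        out = SegmentedResult(response, predictor, family, np.nan, np.nan, np.nan, np.nan,
                              np.nan, -np.inf, False,
                              warnings=["no estimable tipping point: no start converged"])
    else:
        # closest to the test's best candidate; ties -> loglik, then smaller psi
        fits.sort(key=lambda r: (abs(r.psi - test.best_psi), -r.loglik, r.psi))
        out = fits[0]
    out.test_name = test.name
    out.statistic = test.statistic
    out.p_value = test.p_value
    out.test_best_psi = test.best_psi
    out.significant = bool(test.p_value < alpha)
    out.trace = trace
    return out
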