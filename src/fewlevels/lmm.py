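"""Linear mixed-model engine: profiled REML/ML, singular-fit detection,
Satterthwaite tests.

The model is y = X beta + Z b + eps with one grouping factor (mountain),
b_i ~ N(0, sigma_e^2 * Lambda Lambda') independently across groups, and
eps ~ N(0, sigma_e^2 I).  Lambda is the *relative* Cholesky factor of the
random-effect covariance — the parameterization under which singular fits
are boundary points (a diagonal of Lambda at zero, or an implied
correlation at +/-1).

For a fixed theta (the free entries of Lambda), beta and sigma_e^2 have
closed-form profile estimates, so fitting reduces to minimizing the
profiled -2 log (restricted) likelihood over a handful of bounded
parameters.  Because groups are independent and each group carries at
most two random terms, every criterion evaluation works on per-group
q x q blocks (Woodbury identity) and costs O(m) tiny matrix operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .datasets import Dataset

__all__ = [
    "LMMSpec",
    "VarComp",
    "LMMFit",
    "TestResult",
    "profiled_criterion",
    "fit_lmm",
    "is_singular",
    "satterthwaite_test",
    "SINGULAR_TOL",
]

log = logging.getLogger(__name__)

#: boundary tolerance on the relative-Cholesky diagonal (and 1 - |corr|)
SINGULAR_TOL = 1e-4

_MODEL_TERMS = {
    # model id -> (random terms, correlated)
    "M4": (("intercept",), False),
    "M9": (("intercept",), False),
    "M5": (("intercept", "slope"), False),
    "M10": (("intercept", "slope"), False),
    "M11": (("intercept", "slope"), True),
}

_COEF_INDEX = {"intercept": 0, "slope": 1}


@dataclass(frozen=True)
class LMMSpec:
    """Which random-effect structure to fit, and with which estimator."""

    model_id: str
    estimator: str = "REML"

    def __post_init__(self):
        if self.model_id not in _MODEL_TERMS:
            raise ValueError(f"unknown mixed model {self.model_id!r}")
        if self.estimator not in ("REML", "ML"):
            raise ValueError("estimator must be 'REML' or 'ML'")

    @property
    def random_terms(self) -> tuple[str, ...]:
        return _MODEL_TERMS[self.model_id][0]

    @property
    def correlated(self) -> bool:
        return _MODEL_TERMS[self.model_id][1]

    @property
    def q(self) -> int:
        return len(self.random_terms)

    @property
    def n_theta(self) -> int:
        return 3 if self.correlated else self.q

    def lambda_from_theta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self.correlated:
            return np.array([[theta[0], 0.0], [theta[1], theta[2]]])
        return np.diag(theta)

    def theta_bounds(self) -> list[tuple[float | None, float | None]]:
        # generous finite caps: a scaled-variance ratio of 1e8 is far past
        # anything identifiable, and float64 Woodbury algebra fails beyond
        hi = 1e4
        if self.correlated:
            return [(0.0, hi), (-hi, hi), (0.0, hi)]
        return [(0.0, hi)] * self.q


@dataclass
class VarComp:
    """Variance components on the data scale (cm^2)."""

    theta: np.ndarray
    sigma2_intercept: float
    sigma2_slope: float | None
    correlation: float | None
    sigma2_resid: float


@dataclass
class TestResult:
    """t-test of one population-level coefficient."""

    coefficient: str
    estimate: float
    se: float
    df: float
    t: float
    p: float


@dataclass
class LMMFit:
    spec: LMMSpec
    beta: np.ndarray
    beta_cov: np.ndarray
    varcomp: VarComp
    criterion: float
    converged: bool
    singular: bool
    predicted_level_effects: np.ndarray
    n: int = 0
    _ss: "Suffstats" = field(default=None, repr=False)


class Suffstats:
    """Per-group sufficient statistics; one pass over the data, then every
    criterion evaluation is O(m) on q x q blocks."""

    def __init__(self, dataset: Dataset, spec: LMMSpec):
        y = dataset.height
        t = dataset.temperature
        if np.ptp(t) == 0:
            raise ValueError("design is rank deficient: 'temperature' is constant")
        X = np.column_stack([np.ones_like(t), t])
        g = dataset.mountain - 1
        m = dataset.n_levels
        q = spec.q
        cols = {"intercept": np.ones_like(t), "slope": t}
        Z = np.column_stack([cols[term] for term in spec.random_terms])

        self.n = y.size
        self.p = 2
        self.m = m
        self.q = q
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZ = np.zeros((m, q, q))
        self.ZtX = np.zeros((m, q, 2))
        self.Zty = np.zeros((m, q))
        for i in range(m):
            idx = g == i
            Zi = Z[idx]
            self.ZtZ[i] = Zi.T @ Zi
            self.ZtX[i] = Zi.T @ X[idx]
            self.Zty[i] = Zi.T @ y[idx]


def _inv_small(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Explicit inverse and total log-determinant of a stack of 1x1 or 2x2
    positive-definite matrices (LAPACK overhead dominates at this size)."""
    q = M.shape[-1]
    if q == 1:
        det = M[:, 0, 0]
        if np.any(det <= 0):
            raise np.linalg.LinAlgError("indefinite within-group system")
        return 1.0 / M, float(np.log(det).sum())
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    if np.any(det <= 0):
        raise np.linalg.LinAlgError("indefinite within-group system")
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1]
    inv[:, 1, 1] = M[:, 0, 0]
    inv[:, 0, 1] = -M[:, 0, 1]
    inv[:, 1, 0] = -M[:, 1, 0]
    inv /= det[:, None, None]
    return inv, float(np.log(det).sum())


def _solve_blocks(ss: Suffstats, Lam: np.ndarray):
    """Woodbury pieces: per-group M_i = I + Lam' Z_i'Z_i Lam and the
    whitened cross-products X'V*^-1 X, X'V*^-1 y, y'V*^-1 y."""
    q = ss.q
    M = np.eye(q) + Lam.T @ ss.ZtZ @ Lam          # (m, q, q)
    W = Lam.T @ ss.ZtX                             # (m, q, p)
    u = (ss.Zty @ Lam)[..., None]                  # (m, q, 1)
    Minv, logdet = _inv_small(M)
    S = Minv @ W                                   # M^-1 W
    v = Minv @ u                                   # M^-1 u
    XtVX = ss.XtX - np.einsum("ijk,ijl->kl", W, S)
    XtVy = ss.Xty - np.einsum("ijk,ijl->k", W, v)
    yVy = ss.yty - float(np.einsum("ijk,ijk->", u, v))
    return logdet, XtVX, XtVy, yVy, M, u


def _det2(A: np.ndarray) -> float:
    return A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]


def _criterion_parts(ss: Suffstats, spec: LMMSpec, theta: np.ndarray):
    Lam = spec.lambda_from_theta(theta)
    logdet, XtVX, XtVy, yVy, M, u = _solve_blocks(ss, Lam)
    det = _det2(XtVX)
    if det <= 0 or not np.isfinite(det):
        raise np.linalg.LinAlgError("whitened fixed-effect system is singular")
    beta = np.array([
        (XtVX[1, 1] * XtVy[0] - XtVX[0, 1] * XtVy[1]) / det,
        (XtVX[0, 0] * XtVy[1] - XtVX[1, 0] * XtVy[0]) / det,
    ])
    r2 = yVy - float(beta @ XtVy)
    # at extreme theta the Woodbury difference cancels catastrophically and
    # r2 collapses to rounding error; treat that as degenerate, not optimal
    if not r2 > 1e-10 * ss.yty:
        raise np.linalg.LinAlgError("profiled residual sum lost all precision")
    return Lam, logdet, XtVX, XtVy, beta, r2, M


def _criterion(ss: Suffstats, spec: LMMSpec, theta: np.ndarray, sigma: float | None = None) -> float:
    """-2 log (restricted) likelihood; sigma=None profiles sigma_e out.

    Far outside the plausible region (huge theta) the whitened fixed-effect
    cross-product can underflow to numerical singularity — there the
    criterion is returned as a large finite value so line searches back off.
    """
    try:
        _, logdet, XtVX, _, _, r2, _ = _criterion_parts(ss, spec, theta)
    except np.linalg.LinAlgError:
        return 1e12
    n, p = ss.n, ss.p
    if spec.estimator == "REML":
        det = _det2(XtVX)
        if det <= 0:
            return 1e12
        ld_fixed = np.log(det)
        if sigma is None:
            return logdet + ld_fixed + (n - p) * (1.0 + np.log(2 * np.pi * r2 / (n - p)))
        return logdet + ld_fixed + r2 / sigma**2 + (n - p) * np.log(2 * np.pi * sigma**2)
    if sigma is None:
        return logdet + n * (1.0 + np.log(2 * np.pi * r2 / n))
    return logdet + r2 / sigma**2 + n * np.log(2 * np.pi * sigma**2)


def profiled_criterion(dataset: Dataset, spec: LMMSpec, theta) -> float:
    """-2 log restricted (REML) or full (ML) likelihood with beta and
    sigma_e^2 profiled out in closed form at the given theta."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.size != spec.n_theta:
        raise ValueError(f"{spec.model_id} expects {spec.n_theta} theta parameters")
    return _criterion(Suffstats(dataset, spec), spec, theta)


def _moment_start(dataset: Dataset, spec: LMMSpec) -> np.ndarray:
    """Crude moment-based start: between-group spread of per-group OLS
    intercepts/slopes relative to the pooled residual variance."""
    y, t, g = dataset.height, dataset.temperature, dataset.mountain - 1
    m = dataset.n_levels
    X = np.column_stack([np.ones_like(t), t])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = max(float(res[0]) / (y.size - 2), 1e-8) if res.size else 1.0
    b0 = np.empty(m)
    b1 = np.empty(m)
    for i in range(m):
        idx = g == i
        ci, *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
        b0[i], b1[i] = ci
    start = {"intercept": np.sqrt(max(b0.var(ddof=1), 0.0) / s2),
             "slope": np.sqrt(max(b1.var(ddof=1), 0.0) / s2)}
    diag = [start[term] for term in spec.random_terms]
    if spec.correlated:
        return np.array([diag[0], 0.0, diag[1]])
    return np.array(diag)


def _starts(dataset: Dataset, spec: LMMSpec) -> list[np.ndarray]:
    k = spec.n_theta
    zeros = np.zeros(k)
    ones = np.ones(k)
    small = np.full(k, 0.1)
    if spec.correlated:
        ones[1] = small[1] = 0.0
    try:
        moment = _moment_start(dataset, spec)
    except Exception:
        moment = small.copy()
    return [zeros, ones, small, moment, 0.5 * (moment + ones)]


def fit_lmm(dataset: Dataset, spec: LMMSpec, tol: float = SINGULAR_TOL) -> LMMFit:
    """Fit by bounded quasi-Newton on the profiled criterion with five
    deterministic starts (boundary optima — singular fits — are legitimate
    solutions and must be reachable, hence the theta = 0 start)."""
    ss = Suffstats(dataset, spec)
    fun = lambda th: _criterion(ss, spec, th)
    best = None
    converged = False
    for x0 in _starts(dataset, spec):
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B", bounds=spec.theta_bounds(),
            options={"ftol": 1e-10, "gtol": 1e-5, "maxiter": 200},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        converged = converged or bool(res.success)
    # polish with central-difference gradients for closed-form-grade accuracy
    res = optimize.minimize(
        fun, best.x, method="L-BFGS-B", bounds=spec.theta_bounds(), jac="3-point",
        options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 100},
    )
    if res.fun <= best.fun:
        best = res
    if not converged:
        log.warning("mixed-model optimizer did not converge: %s", best.message)

    theta = np.asarray(best.x, dtype=float)
    Lam, logdet, XtVX, XtVy, beta, r2, M = _criterion_parts(ss, spec, theta)
    n, p = ss.n, ss.p
    dof = n - p if spec.estimator == "REML" else n
    sigma2 = r2 / dof
    beta_cov = sigma2 * np.linalg.inv(XtVX)

    Sigma_b = sigma2 * (Lam @ Lam.T)
    terms = spec.random_terms
    s2_int = float(Sigma_b[0, 0]) if "intercept" in terms else 0.0
    s2_slope = float(Sigma_b[-1, -1]) if "slope" in terms else None
    corr = None
    if spec.correlated:
        denom = np.sqrt(Sigma_b[0, 0] * Sigma_b[1, 1])
        corr = float(Sigma_b[0, 1] / denom) if denom > 0 else 0.0
    varcomp = VarComp(theta=theta, sigma2_intercept=s2_int, sigma2_slope=s2_slope,
                      correlation=corr, sigma2_resid=float(sigma2))

    # conditional means (BLUPs): b_i = Lam M_i^-1 Lam' (Z'y - Z'X beta)_i
    resid_proj = ss.Zty - ss.ZtX @ beta
    blup = (Lam @ np.linalg.solve(M, (resid_proj @ Lam)[..., None]))[..., 0]

    fit = LMMFit(
        spec=spec, beta=beta, beta_cov=beta_cov, varcomp=varcomp,
        criterion=float(best.fun), converged=converged, singular=False,
        predicted_level_effects=blup, n=n, _ss=ss,
    )
    fit.singular = is_singular(fit, tol=tol)
    return fit


def is_singular(fit: LMMFit, tol: float = SINGULAR_TOL) -> bool:
    """Boundary estimate: a relative-Cholesky diagonal (scaled variance)
    at zero, or an implied random-effect correlation at +/-1."""
    theta = fit.varcomp.theta
    Lam = fit.spec.lambda_from_theta(theta)
    if np.min(np.diag(Lam)) < tol:
        return True
    if fit.spec.correlated:
        corr = fit.varcomp.correlation
        if corr is not None and abs(corr) > 1 - tol:
            return True
    return False


def _coef_variance(ss: Suffstats, spec: LMMSpec, theta: np.ndarray, sigma: float, idx: int) -> float:
    Lam = spec.lambda_from_theta(theta)
    _, XtVX, _, _, _, _ = _solve_blocks(ss, Lam)
    return sigma**2 * float(np.linalg.inv(XtVX)[idx, idx])


def satterthwaite_test(dataset: Dataset, fit: LMMFit, coefficient: str = "slope") -> TestResult:
    """Moment-matching denominator df for the t-test of one fixed effect.

    df = 2 v^2 / (g' A g), where v is the estimated coefficient variance as
    a function of the variance parameters (theta, sigma_e), g its gradient
    at the optimum, and A the asymptotic covariance of those parameters
    (twice the inverse Hessian of the -2 log-likelihood).  Derivatives use
    central finite differences; a non-invertible curvature falls back to
    the residual df n - p.
    """
    if coefficient not in _COEF_INDEX:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    idx = _COEF_INDEX[coefficient]
    spec = fit.spec
    ss = fit._ss if fit._ss is not None else Suffstats(dataset, spec)
    theta = fit.varcomp.theta
    sigma = np.sqrt(fit.varcomp.sigma2_resid)
    params = np.append(theta, sigma)
    k = params.size

    def vfun(pars):
        return _coef_variance(ss, spec, pars[:-1], pars[-1], idx)

    def dev(pars):
        return _criterion(ss, spec, pars[:-1], sigma=pars[-1])

    h = 1e-4 * (1.0 + np.abs(params))
    grad = np.empty(k)
    for j in range(k):
        e = np.zeros(k)
        e[j] = h[j]
        grad[j] = (vfun(params + e) - vfun(params - e)) / (2 * h[j])

    H = np.empty((k, k))
    f0 = dev(params)
    for j in range(k):
        ej = np.zeros(k)
        ej[j] = h[j]
        H[j, j] = (dev(params + ej) - 2 * f0 + dev(params - ej)) / h[j] ** 2
        for l in range(j + 1, k):
            el = np.zeros(k)
            el[l] = h[l]
            H[j, l] = H[l, j] = (
                dev(params + ej + el) - dev(params + ej - el)
                - dev(params - ej + el) + dev(params - ej - el)
            ) / (4 * h[j] * h[l])

    n, p = ss.n, ss.p
    v = vfun(params)
    df = float(n - p)
    try:
        # asymptotic covariance of (theta, sigma): 2 * H^-1 of the deviance
        A = 2.0 * np.linalg.inv(H)
        quad = float(grad @ A @ grad)
        if quad > 0 and np.isfinite(quad):
            df = 2.0 * v**2 / quad
        else:
            log.warning("Satterthwaite curvature not usable; falling back to residual df")
    except np.linalg.LinAlgError:
        log.warning("Satterthwaite curvature singular; falling back to residual df")
    df = float(np.clip(df, 1.0, n - p))

    est = float(fit.beta[idx])
    se = float(np.sqrt(fit.beta_cov[idx, idx]))
    t = est / se
    pval = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(coefficient=coefficient, estimate=est, se=se, df=df, t=t, p=float(pval))
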