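"""Design-factor sweep: how number of levels, random-effect variance,
total sample size and unbalance shape type I error and power.

Random study designs are sampled (scenario-B data-generating process),
each evaluated by repeated simulation with the correctly specified mixed
model (non-singular fits only) and the per-level fixed-effects model
(all fits), and the per-design rates are then smoothed by an additive
median (quantile) spline regression on the four design factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .datasets import DesignPoint, ScenarioConfig, sample_design_point, simulate_dataset
from .fixed import BootstrapConfig, fit_ols, population_slope_bootstrap
from .lmm import LMMSpec, fit_lmm, satterthwaite_test

__all__ = [
    "run_sweep",
    "QuantileSplineConfig",
    "QuantileSplineFit",
    "fit_quantile_spline",
    "pinball_loss",
]

log = logging.getLogger(__name__)

COVARIATES = ["m", "variance", "total_n", "unbalance_proxy"]


def _rates_for_point(
    point: DesignPoint,
    effect: float,
    fits_per_point: int,
    alpha: float,
    seed: int,
    bootstrap_draws: int,
    retry_factor: int,
) -> tuple[float, float, int] | None:
    """(mixed rate over non-singular fits, fixed rate over all fits, n mixed).

    Simulates datasets until ``fits_per_point`` non-singular mixed fits are
    accumulated (within a retry budget); the fixed-effects model is
    evaluated on the first ``fits_per_point`` datasets regardless.
    """
    mean = point.total_n // point.m
    config = ScenarioConfig(
        scenario="B",
        n_mountains=point.m,
        mean_plants_per_mountain=max(mean, 3),
        count_range=(3, point.total_n),
        beta_intercept=effect,
        beta_slope=effect,
        var_intercept=point.var_random,
        var_slope=point.var_random,
        resid_sd=1.0,
        seed=0,
    )
    spec = LMMSpec("M10")
    mixed_rej = []
    fixed_rej = []
    budget = retry_factor * fits_per_point
    for attempt in range(budget):
        rep_seed = (seed + attempt) % (2**31 - 1)
        dataset = simulate_dataset(config.replace(seed=rep_seed), counts=point.counts)
        if len(fixed_rej) < fits_per_point:
            ols = fit_ols(dataset, "M8")
            pb = population_slope_bootstrap(
                ols, BootstrapConfig(n_draws=bootstrap_draws, seed=rep_seed)
            )
            fixed_rej.append(pb.p < alpha)
        fit = fit_lmm(dataset, spec)
        if not fit.singular:
            mixed_rej.append(satterthwaite_test(dataset, fit, "slope").p < alpha)
            if len(mixed_rej) >= fits_per_point and len(fixed_rej) >= fits_per_point:
                break
    if not mixed_rej:
        return None
    return float(np.mean(mixed_rej)), float(np.mean(fixed_rej)), len(mixed_rej)


def run_sweep(
    n_points: int = 200,
    fits_per_point: int = 200,
    master_seed: int = 0,
    alpha: float = 0.05,
    bootstrap_draws: int = 500,
    retry_factor: int = 4,
) -> pd.DataFrame:
    """Sample ``n_points`` designs and measure per-design type I error and
    power for the mixed (M10, non-singular) and fixed (M8, all) models.

    Designs where the retry budget cannot accumulate any non-singular mixed
    fit (tiny variances at few levels) are flagged ``valid=False`` and
    excluded from downstream smoothing.
    """
    if n_points < 10:
        raise ValueError("need at least 10 design points")
    rows = []
    for i in range(n_points):
        pseed = (master_seed + 7_919 * (i + 1)) % (2**31 - 1)
        point = sample_design_point(pseed)
        out = {
            "point": i,
            "m": point.m,
            "variance": point.var_random,
            "total_n": point.total_n,
            "unbalance_proxy": point.unbalance_proxy,
            "valid": True,
        }
        null = _rates_for_point(point, 0.0, fits_per_point, alpha, pseed + 1,
                                bootstrap_draws, retry_factor)
        powr = _rates_for_point(point, 0.4, fits_per_point, alpha, pseed + 2,
                                bootstrap_draws, retry_factor)
        if null is None or powr is None:
            log.warning("design point %d (m=%d, var=%.2g) exhausted its retry "
                        "budget without non-singular fits; excluded", i, point.m,
                        point.var_random)
            out.update(valid=False, type_I_mixed=np.nan, type_I_fixed=np.nan,
                       power_mixed=np.nan, power_fixed=np.nan, n_fits_used=0)
        else:
            out.update(
                type_I_mixed=null[0], type_I_fixed=null[1],
                power_mixed=powr[0], power_fixed=powr[1],
                n_fits_used=min(null[2], powr[2]),
            )
        rows.append(out)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- quantile splines


def pinball_loss(resid: np.ndarray, tau: float) -> float:
    """Mean check loss rho_tau(r) = r (tau - 1[r < 0])."""
    r = np.asarray(resid, dtype=float)
    return float(np.mean(r * (tau - (r < 0))))


@dataclass(frozen=True)
class QuantileSplineConfig:
    tau: float = 0.5
    knots: int = 10
    penalties: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    cv_folds: int = 5
    max_iter: int = 200
    tol: float = 1e-9

    def __post_init__(self):
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.knots < 4:
            raise ValueError("need at least 4 knots")


def _basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix on a fixed augmented knot vector."""
    t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
    xc = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(xc, t, 3).toarray()


class _Smooth:
    """One covariate's centered cubic P-spline basis with a
    second-difference penalty."""

    def __init__(self, x: np.ndarray, n_knots: int):
        lo, hi = float(np.min(x)), float(np.max(x))
        self.degenerate = hi - lo <= 0
        if self.degenerate:
            self.n_coef = 0
            return
        self.knots = np.linspace(lo, hi, n_knots)
        B = _basis(x, self.knots)
        self.center = B.mean(axis=0)
        self.n_coef = B.shape[1]
        D = np.diff(np.eye(self.n_coef), n=2, axis=0)
        self.penalty = D.T @ D

    def design(self, x: np.ndarray) -> np.ndarray:
        return _basis(x, self.knots) - self.center


@dataclass
class QuantileSplineFit:
    """Additive quantile curves: yhat = intercept + sum_j f_j(x_j)."""

    config: QuantileSplineConfig
    columns: list[str]
    smooths: list[_Smooth]
    coef: np.ndarray = None
    penalty_weight: float = None
    cv_losses: dict = field(default_factory=dict)

    def _design(self, X: np.ndarray) -> np.ndarray:
        parts = [np.ones((X.shape[0], 1))]
        for j, sm in enumerate(self.smooths):
            if not sm.degenerate:
                parts.append(sm.design(X[:, j]))
        return np.hstack(parts)

    def _block(self, j: int) -> slice:
        start = 1
        for k in range(j):
            start += self.smooths[k].n_coef
        return slice(start, start + self.smooths[j].n_coef)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._design(X) @ self.coef

    def partial_effect(self, covariate: str, grid: np.ndarray) -> np.ndarray:
        """Centered effect of one covariate along ``grid``, holding the
        others at their (implicitly centered-out) values."""
        j = self.columns.index(covariate)
        sm = self.smooths[j]
        if sm.degenerate:
            return np.zeros_like(np.asarray(grid, dtype=float))
        return sm.design(np.asarray(grid, dtype=float)) @ self.coef[self._block(j)]

    @property
    def intercept(self) -> float:
        return float(self.coef[0])


def _irls_quantile(B, y, P, lam, tau, max_iter, tol):
    """Iteratively reweighted least squares for the penalized check loss.

    Weights tau/|r| (r > 0) and (1-tau)/|r| (r < 0) with a floored |r|
    turn each step into a weighted ridge solve; the floor smooths the loss
    near zero residuals.
    """
    scale = max(float(np.std(y)), 1e-12)
    eps = 1e-6 * scale
    # centered partition-of-unity bases leave one exactly-null direction per
    # block (it predicts zero everywhere); a scaled ridge pins it down
    BtB = B.T @ B
    ridge = (1e-7 * np.trace(BtB) / B.shape[1]) * np.eye(B.shape[1])
    coef = np.linalg.solve(B.T @ B + lam * P + ridge, B.T @ y)
    last = np.inf
    for _ in range(max_iter):
        r = y - B @ coef
        w = np.where(r >= 0, tau, 1 - tau) / np.maximum(np.abs(r), eps)
        BW = B * w[:, None]
        coef = np.linalg.solve(BW.T @ B + lam * P + ridge, BW.T @ y)
        loss = pinball_loss(y - B @ coef, tau) + lam * float(coef @ P @ coef)
        if abs(last - loss) < tol * (1 + abs(loss)):
            break
        last = loss
    return coef


def fit_quantile_spline(
    covariates,
    response,
    cfg: QuantileSplineConfig = QuantileSplineConfig(),
) -> QuantileSplineFit:
    """Fit an additive quantile regression with cubic P-spline smooths.

    Minimizes the pinball (check) loss at ``cfg.tau`` plus a
    second-difference smoothness penalty per covariate; the penalty weight
    is chosen from ``cfg.penalties`` by K-fold cross-validated pinball
    loss.  Constant covariates contribute a flat (zero) curve.
    """
    if isinstance(covariates, pd.DataFrame):
        columns = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        columns = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    if X.shape[0] < 50:
        raise ValueError("need at least 50 observations to fit the smooths")

    smooths = [_Smooth(X[:, j], cfg.knots) for j in range(X.shape[1])]
    for j, sm in enumerate(smooths):
        if sm.degenerate:
            log.warning("covariate %r is constant; its curve is flat", columns[j])
    fit = QuantileSplineFit(config=cfg, columns=columns, smooths=smooths)
    B = fit._design(X)
    P = np.zeros((B.shape[1], B.shape[1]))
    for j, sm in enumerate(smooths):
        if not sm.degenerate:
            blk = fit._block(j)
            P[blk, blk] = sm.penalty

    rng = np.random.default_rng(0)
    folds = rng.permutation(len(y)) % cfg.cv_folds
    cv = {}
    for lam in cfg.penalties:
        losses = []
        for k in range(cfg.cv_folds):
            tr, te = folds != k, folds == k
            coef = _irls_quantile(B[tr], y[tr], P, lam, cfg.tau, cfg.max_iter, cfg.tol)
            losses.append(pinball_loss(y[te] - B[te] @ coef, cfg.tau))
        cv[lam] = float(np.mean(losses))
    best = min(cv, key=cv.get)
    fit.coef = _irls_quantile(B, y, P, best, cfg.tau, cfg.max_iter, cfg.tol)
    fit.penalty_weight = best
    fit.cv_losses = cv
    return fit
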