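"""Fixed-effects alternatives: pooled and per-mountain least squares, plus
the coefficient-covariance bootstrap for the population-level slope.

Model ids mirror the study grid: M2/M7 pool everything (``height ~ T``,
the model omitting the grouping variable), M3 gives each mountain its own
intercept with a common slope, M8 gives each mountain its own intercept
and slope.  M8 has no single slope coefficient, so its population-level
slope is the (weighted) average of the m per-mountain slopes; its standard
error comes from a parametric bootstrap that redraws the coefficient
vector from the fitted multivariate-normal sampling distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datasets import Dataset
from .lmm import TestResult

__all__ = ["OLSFit", "BootstrapConfig", "fit_ols", "population_slope_bootstrap", "coef_test"]

_FIXED_MODELS = ("M2", "M3", "M7", "M8")


@dataclass
class OLSFit:
    model_id: str
    names: list[str]
    coefficients: np.ndarray
    coef_cov: np.ndarray
    resid_var: float
    df_resid: int
    n_levels: int
    per_level_counts: np.ndarray

    @property
    def slope_indices(self) -> np.ndarray:
        """Indices of the per-level (or pooled) slope coefficients."""
        return np.array([i for i, nm in enumerate(self.names) if nm.startswith("slope")])


def _design(dataset: Dataset, model_id: str) -> tuple[np.ndarray, list[str]]:
    t = dataset.temperature
    m = dataset.n_levels
    dummies = (dataset.mountain[:, None] == np.arange(1, m + 1)).astype(float)
    if model_id in ("M2", "M7"):
        return np.column_stack([np.ones_like(t), t]), ["intercept", "slope"]
    if model_id == "M3":
        names = [f"mountain_{i}" for i in range(1, m + 1)] + ["slope"]
        return np.column_stack([dummies, t]), names
    # M8: per-mountain intercepts and slopes
    names = [f"mountain_{i}" for i in range(1, m + 1)] + [f"slope_{i}" for i in range(1, m + 1)]
    return np.column_stack([dummies, dummies * t[:, None]]), names


def fit_ols(dataset: Dataset, model_id: str) -> OLSFit:
    """Ordinary least squares with the classical covariance resid_var * (X'X)^-1."""
    if model_id not in _FIXED_MODELS:
        raise ValueError(f"unknown fixed-effects model {model_id!r}")
    X, names = _design(dataset, model_id)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"{model_id} design is rank deficient: a mountain has too few "
            "observations (or no temperature spread) for its per-level parameters"
        )
    res = sm.OLS(dataset.height, X).fit()
    return OLSFit(
        model_id=model_id,
        names=names,
        coefficients=np.asarray(res.params),
        coef_cov=np.asarray(res.cov_params()),
        resid_var=float(res.mse_resid),
        df_resid=int(res.df_resid),
        n_levels=dataset.n_levels,
        per_level_counts=dataset.per_level_counts,
    )


def coef_test(fit: OLSFit, name: str) -> TestResult:
    """Classical two-sided t-test of one coefficient."""
    idx = fit.names.index(name)
    est = float(fit.coefficients[idx])
    se = float(np.sqrt(fit.coef_cov[idx, idx]))
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
    return TestResult(coefficient=name, estimate=est, se=se, df=float(fit.df_resid), t=t, p=float(p))


@dataclass(frozen=True)
class BootstrapConfig:
    n_draws: int = 10_000
    weights: str = "equal"  # or "by_count"
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 100:
            raise ValueError("need at least 100 bootstrap draws")
        if self.weights not in ("equal", "by_count"):
            raise ValueError("weights must be 'equal' or 'by_count'")


def population_slope_bootstrap(fit: OLSFit, cfg: BootstrapConfig = BootstrapConfig()) -> TestResult:
    """Population-level slope of the per-mountain fixed-effects model (M8).

    Draws ``n_draws`` coefficient vectors from N(coefficients, coef_cov),
    averages the m per-level slopes within each draw ('equal' weights 1/m,
    or 'by_count' weights n_i/n), and reports the spread of those averages
    as the standard error.  The point estimate is the weighted average of
    the fitted slopes; the p-value refers |estimate/se| to a standard
    normal.
    """
    if fit.model_id != "M8":
        raise ValueError("the population-slope bootstrap applies to the M8 fit")
    idx = fit.slope_indices
    m = idx.size
    if cfg.weights == "equal":
        w = np.full(m, 1.0 / m)
    else:
        w = fit.per_level_counts / fit.per_level_counts.sum()
    if np.allclose(fit.coef_cov, 0.0):  # noiseless degenerate limit
        boot = np.full(cfg.n_draws, fit.coefficients[idx] @ w)
    else:
        try:
            L = np.linalg.cholesky(fit.coef_cov)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "coefficient covariance is singular; try weights='by_count' or more data"
            ) from err
        rng = np.random.default_rng(cfg.seed)
        draws = fit.coefficients + rng.standard_normal((cfg.n_draws, len(fit.coefficients))) @ L.T
        boot = draws[:, idx] @ w
    est = float(fit.coefficients[idx] @ w)
    se = float(boot.std(ddof=1))
    t = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    p = 2.0 * stats.norm.sf(abs(t))
    return TestResult(coefficient="slope", estimate=est, se=se, df=np.inf, t=float(t), p=float(p))
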