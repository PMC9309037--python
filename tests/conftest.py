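import numpy as np
import pytest

from fewlevels import Dataset, LMMSpec, ScenarioConfig, simulate_dataset


def make_balanced(m, k, var_intercept=0.25, var_slope=0.0, beta=(0.4, 0.4),
                  resid_sd=1.0, scenario=None, seed=0):
    """Balanced design: exactly k plants on each of m mountains."""
    scenario = scenario or ("B" if var_slope > 0 else "A")
    cfg = ScenarioConfig(
        scenario=scenario, n_mountains=m, mean_plants_per_mountain=max(k, 3),
        count_range=(3, m * k), beta_intercept=beta[0], beta_slope=beta[1],
        var_intercept=var_intercept, var_slope=var_slope, resid_sd=resid_sd, seed=seed,
    )
    return simulate_dataset(cfg, counts=np.full(m, k))


def dense_criterion(dataset: Dataset, spec: LMMSpec, theta) -> float:
    """Independent dense-matrix evaluation of the profiled -2 log
    (restricted) likelihood: builds the full n x n relative covariance
    V* = I + Z G Z' explicitly and uses generic linear algebra only."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    y = dataset.height
    t = dataset.temperature
    n = y.size
    m = dataset.n_levels
    X = np.column_stack([np.ones(n), t])
    cols = {"intercept": np.ones(n), "slope": t}
    Lam = spec.lambda_from_theta(theta)
    G = Lam @ Lam.T
    V = np.eye(n)
    for i in range(1, m + 1):
        idx = dataset.mountain == i
        Zi = np.column_stack([cols[term][idx] for term in spec.random_terms])
        V[np.ix_(idx, idx)] += Zi @ G @ Zi.T
    sign, logdet = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    r2 = float(r @ Vi @ r)
    p = 2
    if spec.estimator == "REML":
        return (logdet + np.linalg.slogdet(XtVX)[1]
                + (n - p) * (1 + np.log(2 * np.pi * r2 / (n - p))))
    return logdet + n * (1 + np.log(2 * np.pi * r2 / n))


def make_orthogonal_oneway(m, k, var_intercept=0.25, resid_sd=1.0, seed=0,
                           beta=(0.4, 0.4)):
    """Balanced random-intercept data whose temperature is exactly centered
    within every mountain, so the slope is orthogonal to the group means
    and the restricted likelihood factorizes into between/within pieces."""
    rng = np.random.default_rng(seed)
    t = rng.standard_normal((m, k))
    t -= t.mean(axis=1, keepdims=True)
    t = (t / t.std()).ravel()
    mountain = np.repeat(np.arange(1, m + 1), k)
    b0 = rng.normal(0, np.sqrt(var_intercept), m)
    y = beta[0] + b0[mountain - 1] + beta[1] * t + rng.standard_normal(m * k) * resid_sd
    return Dataset(height=y, temperature=t, mountain=mountain,
                   per_level_counts=np.full(m, k))


def anova_one_way(dataset: Dataset):
    """Balanced one-way REML closed form for the random-intercept model
    with a within-group-centered covariate: the slope uses the within
    space only, sigma_e^2 = within RSS / (n - m - 1) and
    sigma_b^2 = (MSB - sigma_e^2) / k from the between mean square."""
    y = dataset.height
    t = dataset.temperature
    m = dataset.n_levels
    k = dataset.per_level_counts[0]
    assert np.all(dataset.per_level_counts == k)
    slope = (t @ y) / (t @ t)
    means = np.array([y[dataset.mountain == i].mean() for i in range(1, m + 1)])
    msb = k * np.sum((means - y.mean()) ** 2) / (m - 1)
    resid = y - means[dataset.mountain - 1] - slope * t
    msw = np.sum(resid**2) / (m * k - m - 1)
    return (msb - msw) / k, msw


@pytest.fixture(scope="session")
def dataset_a():
    """Scenario-A study: 5 mountains, variance 0.25, effects 0.4."""
    return simulate_dataset(ScenarioConfig(
        scenario="A", n_mountains=5, var_intercept=0.25,
        beta_intercept=0.4, beta_slope=0.4, seed=42))


@pytest.fixture(scope="session")
def dataset_b():
    """Scenario-B null study: 4 mountains, both variances 0.01."""
    return simulate_dataset(ScenarioConfig(
        scenario="B", n_mountains=4, var_intercept=0.01, var_slope=0.01,
        beta_intercept=0.0, beta_slope=0.0, seed=3))
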