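"""Synthetic data for the plant-height-on-mountains study design.

Each simulated dataset mimics an unbalanced altitudinal survey: ``m``
mountains, a varying number of plants per mountain, a standardized
temperature covariate, and a Gaussian response (plant height in cm).
Mountains differ by normally distributed random intercepts (scenario A)
or by random intercepts *and* random temperature slopes (scenario B).

The data-generating model is

    height_ij = (beta0 + b0_i) + (beta1 + b1_i) * T_ij + eps_ij

with b0_i ~ N(0, var_intercept), b1_i ~ N(0, var_slope) (b1_i = 0 in
scenario A), and eps_ij ~ N(0, resid_sd**2), all independent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "Dataset",
    "DesignPoint",
    "allocate_counts",
    "sample_random_effects",
    "simulate_dataset",
    "sample_design_point",
]

#: lower/upper bound of the raw per-mountain share draws
SHARE_RANGE = (0.1, 0.9)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulated study.

    ``scenario`` 'A' draws random intercepts only; 'B' additionally draws
    uncorrelated random temperature slopes.  Total sample size is
    ``mean_plants_per_mountain * n_mountains``; per-mountain counts are
    unbalanced within ``count_range``.
    """

    scenario: str = "A"
    n_mountains: int = 2
    mean_plants_per_mountain: int = 200
    count_range: tuple[int, int] = (40, 360)
    beta_intercept: float = 0.4
    beta_slope: float = 0.4
    var_intercept: float = 0.01
    var_slope: float = 0.0
    resid_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("A", "B"):
            raise ValueError(f"scenario must be 'A' or 'B', got {self.scenario!r}")
        if self.n_mountains < 2:
            raise ValueError("need at least 2 mountains")
        if self.var_intercept < 0 or self.var_slope < 0 or self.resid_sd < 0:
            raise ValueError("variances and resid_sd must be non-negative")
        if self.scenario == "A" and self.var_slope != 0:
            raise ValueError("scenario A has no random slope; var_slope must be 0")
        lo, hi = self.count_range
        if lo < 3:
            raise ValueError("count_range minimum must be >= 3")
        if not lo <= self.mean_plants_per_mountain <= hi:
            raise ValueError("mean_plants_per_mountain must lie within count_range")

    @property
    def total_n(self) -> int:
        return self.mean_plants_per_mountain * self.n_mountains

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Dataset:
    """One simulated study: height (cm), standardized temperature, mountain label (1..m)."""

    height: np.ndarray
    temperature: np.ndarray
    mountain: np.ndarray
    per_level_counts: np.ndarray

    def __post_init__(self):
        self.height = np.asarray(self.height, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.mountain = np.asarray(self.mountain, dtype=int)
        self.per_level_counts = np.asarray(self.per_level_counts, dtype=int)
        n = self.height.size
        if self.temperature.size != n or self.mountain.size != n:
            raise ValueError("height, temperature and mountain must have equal length")
        if self.per_level_counts.sum() != n:
            raise ValueError("per_level_counts must sum to the total sample size")
        m = self.per_level_counts.size
        levels, counts = np.unique(self.mountain, return_counts=True)
        if not np.array_equal(levels, np.arange(1, m + 1)):
            raise ValueError("mountain labels must cover 1..m")
        if counts.min() < 3:
            raise ValueError("every mountain needs at least 3 observations")

    @property
    def n(self) -> int:
        return self.height.size

    @property
    def n_levels(self) -> int:
        return self.per_level_counts.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"height": self.height, "temperature": self.temperature, "mountain": self.mountain}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        mountain = df["mountain"].to_numpy(dtype=int)
        counts = np.bincount(mountain)[1:]
        return cls(
            height=df["height"].to_numpy(dtype=float),
            temperature=df["temperature"].to_numpy(dtype=float),
            mountain=mountain,
            per_level_counts=counts,
        )

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        return cls.from_frame(pd.read_csv(path))


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Round ``shares * total`` to integers summing exactly to ``total``."""
    raw = shares * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(raw - base)[::-1]
    base[order[:short]] += 1
    return base


def allocate_counts(
    m: int,
    total_n: int,
    count_range: tuple[int, int] = (40, 360),
    seed=0,
    shares: Sequence[float] | None = None,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Draw unbalanced per-mountain sample sizes summing to ``total_n``.

    Raw shares are uniform on [0.1, 0.9], normalized, and rounded by
    largest remainder; draws are rejected until every count lies inside
    ``count_range``.  Passing explicit ``shares`` makes the allocation
    deterministic (e.g. equal shares give a balanced design).
    """
    lo, hi = count_range
    if total_n < m * lo:
        raise ValueError(
            f"cannot place {total_n} observations on {m} levels with at least {lo} each"
        )
    if shares is not None:
        shares = np.asarray(shares, dtype=float)
        counts = _largest_remainder(shares / shares.sum(), total_n)
        if counts.min() < lo or counts.max() > hi:
            raise ValueError("explicit shares violate count_range")
        return counts
    rng = _as_rng(seed)
    for _ in range(max_tries):
        raw = rng.uniform(*SHARE_RANGE, size=m)
        counts = _largest_remainder(raw / raw.sum(), total_n)
        if counts.min() >= lo and counts.max() <= hi:
            return counts
    raise RuntimeError("could not find per-level counts within count_range")


def sample_random_effects(m: int, variance: float, seed=0) -> np.ndarray:
    """Draw m i.i.d. mean-zero normal level deviations with the given variance.

    A zero variance short-circuits to an all-zero vector without consuming
    random numbers, so scenario A is bit-identical to scenario B with
    ``var_slope = 0`` under the same seed.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0:
        return np.zeros(m)
    rng = _as_rng(seed)
    return rng.normal(0.0, np.sqrt(variance), size=m)


def simulate_dataset(config: ScenarioConfig, counts: np.ndarray | None = None) -> Dataset:
    """Simulate one study from the scenario's data-generating model.

    All randomness flows through one generator seeded by ``config.seed``;
    regenerating with the same config is bit-identical.  ``counts`` may pin
    the per-mountain sample sizes (used by the design sweep, where the
    allocation is part of the study design rather than redrawn).
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_mountains
    if counts is None:
        counts = allocate_counts(m, config.total_n, config.count_range, seed=rng)
    else:
        counts = np.asarray(counts, dtype=int)
    n = int(counts.sum())
    mountain = np.repeat(np.arange(1, m + 1), counts)

    temp = rng.standard_normal(n)
    temp = (temp - temp.mean()) / temp.std()

    b0 = sample_random_effects(m, config.var_intercept, seed=rng)
    if config.scenario == "B":
        b1 = sample_random_effects(m, config.var_slope, seed=rng)
    else:
        b1 = np.zeros(m)
    eps = rng.standard_normal(n) * config.resid_sd if config.resid_sd > 0 else np.zeros(n)

    g = mountain - 1
    height = (config.beta_intercept + b0[g]) + (config.beta_slope + b1[g]) * temp + eps
    return Dataset(height=height, temperature=temp, mountain=mountain, per_level_counts=counts)


@dataclass(frozen=True)
class DesignPoint:
    """One randomly sampled study design for the design-factor sweep."""

    m: int
    var_random: float
    obs_per_level_factor: int
    level_shares: np.ndarray
    seed: int
    counts: np.ndarray = field(repr=False, default=None)

    @property
    def total_n(self) -> int:
        return self.m * self.obs_per_level_factor

    @property
    def unbalance_proxy(self) -> float:
        return float(self.level_shares.max() - self.level_shares.min())


def sample_design_point(seed: int) -> DesignPoint:
    """Sample one design: m ~ U{2..20}, variance ~ U[1e-4, 4], total n =
    factor*m with factor ~ U{10..500}, per-level shares uniform on [0.1, 0.9]
    normalized and redrawn until every level receives >= 3 observations."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 21))
    var_random = float(rng.uniform(1e-4, 4.0))
    factor = int(rng.integers(10, 501))
    total_n = m * factor
    while True:
        raw = rng.uniform(*SHARE_RANGE, size=m)
        shares = raw / raw.sum()
        counts = _largest_remainder(shares, total_n)
        if counts.min() >= 3:
            break
    return DesignPoint(
        m=m,
        var_random=var_random,
        obs_per_level_factor=factor,
        level_shares=shares,
        seed=seed,
        counts=counts,
    )
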