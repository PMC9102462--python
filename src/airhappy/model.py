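"""Multilevel cumulative-logit (proportional-odds) model core.

The latent-variable formulation: each respondent ``i`` in city ``k`` carries an
unobserved continuous happiness ``h* = x'beta + z'gamma + u_k + e`` with
standard-logistic residual ``e``; the observed ordinal category is the interval
of ``h*`` between strictly increasing thresholds ``alpha_1 < ... < alpha_{J-1}``.
Equivalently ``logit P(y <= j) = alpha_j - eta`` with ``eta = x'beta + z'gamma +
u_k``, so a positive coefficient raises the odds of reporting a *higher*
category.

This module holds the model specification and parameter containers, the
category-probability and log-likelihood computations, and the two
data-preparation rules used by the analysis: conversion of banded income to a
continuous monthly figure, and the 5-to-3 collapse of the happiness scale used
as a robustness check.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DEFAULT_INCOME_BANDS",
    "ModelSpec",
    "Parameters",
    "PriorSpec",
    "Dataset",
    "augment_design_columns",
    "design_matrix",
    "linear_predictor",
    "category_probabilities",
    "log_likelihood",
    "income_to_continuous",
    "collapse_categories",
]

#: Default monthly-income bands in RMB. The survey instrument records income in
#: seven ordered bands; these defaults bracket a mean near 6,870 RMB/month with
#: an open-ended top band. ``None`` marks the open upper bound.
DEFAULT_INCOME_BANDS: tuple[tuple[float, float | None], ...] = (
    (0.0, 2000.0),
    (2000.0, 4000.0),
    (4000.0, 6000.0),
    (6000.0, 8000.0),
    (8000.0, 12000.0),
    (12000.0, 20000.0),
    (20000.0, None),
)

_VALID_TRANSFORMS = ("identity", "log")


@dataclass(frozen=True)
class ModelSpec:
    """Declares which columns enter the model and how.

    ``individual_predictors`` (the X block) and ``city_predictors`` (the Z
    block) are ordered column names; ``transforms`` maps a column to
    ``"identity"`` (default) or ``"log"`` (natural log, applied before the
    coefficient multiplies).
    """

    response: str = "happiness"
    individual_predictors: tuple[str, ...] = ("income_rmb",)
    city_predictors: tuple[str, ...] = ("polluted_days",)
    n_categories: int = 5
    income_column: str | None = "income_rmb"
    transforms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "individual_predictors", tuple(self.individual_predictors))
        object.__setattr__(self, "city_predictors", tuple(self.city_predictors))
        object.__setattr__(self, "transforms", dict(self.transforms))
        if self.n_categories < 2:
            raise ValueError(f"n_categories must be >= 2, got {self.n_categories}")
        overlap = set(self.individual_predictors) & set(self.city_predictors)
        if overlap:
            raise ValueError(f"predictor lists must be disjoint; shared: {sorted(overlap)}")
        for col, tr in self.transforms.items():
            if tr not in _VALID_TRANSFORMS:
                raise ValueError(f"unknown transform {tr!r} for column {col!r}")

    @property
    def predictors(self) -> tuple[str, ...]:
        return self.individual_predictors + self.city_predictors

    def transform_of(self, column: str) -> str:
        return self.transforms.get(column, "identity")

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "individual_predictors": list(self.individual_predictors),
            "city_predictors": list(self.city_predictors),
            "n_categories": self.n_categories,
            "income_column": self.income_column,
            "transforms": dict(self.transforms),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            response=d["response"],
            individual_predictors=tuple(d["individual_predictors"]),
            city_predictors=tuple(d["city_predictors"]),
            n_categories=int(d["n_categories"]),
            income_column=d.get("income_column"),
            transforms=dict(d.get("transforms", {})),
        )


@dataclass
class Parameters:
    """One point in parameter space.

    alpha: thresholds on the latent scale, strictly increasing, length J-1.
    beta / gamma: coefficients for the X / Z blocks.
    u: city random intercepts (one per city, latent units).
    sigma_u2: between-city variance of u, >= 0.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    u: np.ndarray
    sigma_u2: float

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float)) if np.size(self.beta) else np.empty(0)
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float)) if np.size(self.gamma) else np.empty(0)
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float)) if np.size(self.u) else np.empty(0)
        if self.alpha.size and np.any(np.diff(self.alpha) <= 0):
            raise ValueError("thresholds alpha must be strictly increasing")
        if self.sigma_u2 < 0:
            raise ValueError(f"sigma_u2 must be >= 0, got {self.sigma_u2}")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors: Normal(0, coef_prior_variance) on every
    threshold and regression coefficient, Inverse-Gamma(ig_shape, ig_scale)
    on the between-city variance."""

    coef_prior_variance: float = 1.0e6
    ig_shape: float = 0.001
    ig_scale: float = 0.001

    def __post_init__(self) -> None:
        for name in ("coef_prior_variance", "ig_shape", "ig_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def augment_design_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add the derived design columns the default analysis uses.

    - ``gdp_pc_10k``: per-capita GDP in units of 10,000 RMB (keeps the
      coefficient away from machine precision).
    - ``health_2`` .. ``health_5``: dummies for the 5-level self-rated health
      item against the lowest ("very bad") reference category.

    Source columns that are absent are skipped; existing derived columns are
    left untouched.
    """
    df = df.copy()
    if "gdp_pc" in df.columns and "gdp_pc_10k" not in df.columns:
        df["gdp_pc_10k"] = df["gdp_pc"] / 1.0e4
    if "health" in df.columns:
        for j in range(2, 6):
            col = f"health_{j}"
            if col not in df.columns:
                df[col] = (df["health"].to_numpy() == j).astype(float)
    return df


def _transformed(values: np.ndarray, transform: str, column: str) -> np.ndarray:
    if transform == "identity":
        return values
    if np.any(values <= 0):
        raise ValueError(f"log transform of column {column!r} requires strictly positive values")
    return np.log(values)


def design_matrix(df: pd.DataFrame, columns: Sequence[str], transforms: Mapping[str, str]) -> np.ndarray:
    """Stack the named columns into an (n, p) float design matrix, applying
    per-column transforms. Raises a KeyError naming the first missing column."""
    out = np.empty((len(df), len(columns)), dtype=float)
    for m, col in enumerate(columns):
        if col not in df.columns:
            raise KeyError(f"missing covariate column: {col!r}")
        vals = np.asarray(df[col], dtype=float)
        out[:, m] = _transformed(vals, transforms.get(col, "identity"), col)
    return out


@dataclass
class Dataset:
    """A prepared two-level dataset: response, design matrix and city index.

    Rows are sorted by city so that each city's respondents form a contiguous
    block (``group_starts`` gives block offsets), which the sampler exploits.
    """

    y: np.ndarray               # observed categories, 1..J
    D: np.ndarray               # (n, p) design: X block then Z block
    columns: tuple[str, ...]
    n_individual: int           # width of the X block
    city_index: np.ndarray      # (n,), 0..K-1, non-decreasing
    city_ids: tuple
    group_starts: np.ndarray
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def J(self) -> int:
        return self.spec.n_categories

    @property
    def n_cities(self) -> int:
        return len(self.city_ids)

    @property
    def y0(self) -> np.ndarray:
        return self.y - 1

    @property
    def x_columns(self) -> tuple[str, ...]:
        return self.columns[: self.n_individual]

    @property
    def z_columns(self) -> tuple[str, ...]:
        return self.columns[self.n_individual:]

    @classmethod
    def from_frames(cls, individuals: pd.DataFrame, cities: pd.DataFrame, spec: ModelSpec) -> "Dataset":
        if "city_id" not in individuals.columns:
            raise KeyError("individuals table must carry a 'city_id' column")
        if "city_id" not in cities.columns:
            raise KeyError("cities table must carry a 'city_id' column")
        unknown = set(individuals["city_id"]) - set(cities["city_id"])
        if unknown:
            raise ValueError(f"individuals reference unknown city_id(s): {sorted(map(str, unknown))[:5]}")
        merged = individuals.merge(cities, on="city_id", how="left", validate="many_to_one")
        merged = augment_design_columns(merged)
        if spec.response not in merged.columns:
            raise KeyError(f"missing response column: {spec.response!r}")
        merged = merged.sort_values("city_id", kind="stable").reset_index(drop=True)

        y = np.asarray(merged[spec.response], dtype=int)
        if y.min() < 1 or y.max() > spec.n_categories:
            raise ValueError(
                f"response {spec.response!r} must lie in 1..{spec.n_categories}; "
                f"observed range {y.min()}..{y.max()}"
            )
        D = design_matrix(merged, spec.predictors, spec.transforms)
        codes, uniques = pd.factorize(merged["city_id"], sort=True)
        group_starts = np.searchsorted(codes, np.arange(len(uniques)))
        return cls(
            y=y,
            D=D,
            columns=tuple(spec.predictors),
            n_individual=len(spec.individual_predictors),
            city_index=codes.astype(np.int64),
            city_ids=tuple(uniques),
            group_starts=group_starts.astype(np.int64),
            spec=spec,
        )

    def eta(self, params: Parameters) -> np.ndarray:
        """Latent-scale linear predictor eta = X beta + Z gamma + u_k per row."""
        nx = self.n_individual
        if params.beta.size != nx or params.gamma.size != len(self.columns) - nx:
            raise ValueError(
                f"parameter dimensions (beta {params.beta.size}, gamma {params.gamma.size}) "
                f"do not match design ({nx} individual + {len(self.columns) - nx} city columns)"
            )
        coef = np.concatenate([params.beta, params.gamma])
        eta = self.D @ coef
        if params.u.size:
            if params.u.size != self.n_cities:
                raise ValueError(f"u has {params.u.size} entries for {self.n_cities} cities")
            eta = eta + params.u[self.city_index]
        return eta


def linear_predictor(
    record: Mapping,
    city: Mapping,
    spec: ModelSpec,
    params: Parameters,
    city_index: int = 0,
) -> float:
    """Latent-scale eta for a single respondent: x'beta + z'gamma + u_k.

    ``record`` and ``city`` are mappings (a dict, a pandas Series) holding the
    covariate columns named by ``spec``; declared transforms are applied before
    the dot products. ``city_index`` selects the entry of ``params.u`` (ignored
    when no city effects are present).
    """
    merged: dict = {**dict(city), **dict(record)}

    def term(columns: tuple[str, ...], coefs: np.ndarray) -> float:
        if coefs.size != len(columns):
            raise ValueError(f"coefficient vector of length {coefs.size} for {len(columns)} columns")
        total = 0.0
        for col, c in zip(columns, coefs):
            if col not in merged:
                raise KeyError(f"missing covariate column: {col!r}")
            val = float(merged[col])
            if spec.transform_of(col) == "log":
                if val <= 0:
                    raise ValueError(f"log transform of column {col!r} requires a positive value")
                val = math.log(val)
            total += c * val
        return total

    eta = term(spec.individual_predictors, params.beta) + term(spec.city_predictors, params.gamma)
    if params.u.size:
        eta += float(params.u[city_index])
    return eta


def category_probabilities(eta, alpha) -> np.ndarray:
    """Category probabilities under the cumulative logit: P(y <= j) =
    logistic(alpha_j - eta), categories as successive differences.

    ``eta`` may be a scalar or an array; the returned array has one trailing
    axis of length J = len(alpha) + 1. Probabilities are strictly positive for
    finite inputs and sum to one.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size < 1:
        raise ValueError("alpha must be a 1-D vector of at least one threshold")
    if np.any(np.diff(alpha) <= 0):
        raise ValueError("thresholds alpha must be strictly increasing")
    eta_arr = np.asarray(eta, dtype=float)
    scalar = eta_arr.ndim == 0
    cdf = expit(alpha - eta_arr[..., None])
    probs = np.concatenate(
        [cdf[..., :1], np.diff(cdf, axis=-1), 1.0 - cdf[..., -1:]], axis=-1
    )
    return probs[0] if scalar and probs.ndim == 2 else probs


_LOG_FLOOR = 1e-300


def observation_log_probs(y: np.ndarray, eta: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """log P(y_i | eta_i) for observed categories y in 1..J, vectorised via the
    difference of the two bracketing logistic CDF values."""
    alpha = np.asarray(alpha, dtype=float)
    J = alpha.size + 1
    y = np.asarray(y, dtype=int)
    if y.min() < 1 or y.max() > J:
        raise ValueError(f"observed category outside 1..{J}")
    y0 = y - 1
    a_hi = np.where(y0 == J - 1, np.inf, alpha[np.minimum(y0, J - 2)])
    a_lo = np.where(y0 == 0, -np.inf, alpha[np.maximum(y0 - 1, 0)])
    p = expit(a_hi - eta) - expit(a_lo - eta)
    return np.log(np.maximum(p, _LOG_FLOOR))


def log_likelihood(data, params: Parameters, spec: ModelSpec | None = None) -> float:
    """Joint log-likelihood of the observed categories given parameters.

    ``data`` is either a prepared :class:`Dataset` or an ``(individuals,
    cities)`` pair of DataFrames, in which case ``spec`` is required.
    """
    if not isinstance(data, Dataset):
        individuals, cities = data
        if spec is None:
            raise ValueError("spec is required when passing raw data frames")
        data = Dataset.from_frames(individuals, cities, spec)
    eta = data.eta(params)
    return float(observation_log_probs(data.y, eta, params.alpha).sum())


def income_to_continuous(band: int, bands: Sequence[tuple[float, float | None]] = DEFAULT_INCOME_BANDS) -> float:
    """Convert an ordinal income band (1-based) to a continuous RMB/month value.

    Closed bands map to their midpoint; the open-ended top band maps to 1.5x
    its lower bound, a simple documented extrapolation rule.
    """
    if not 1 <= band <= len(bands):
        raise ValueError(f"income band {band} outside 1..{len(bands)}")
    lo, hi = bands[band - 1]
    if hi is None:
        return 1.5 * lo
    return 0.5 * (lo + hi)


_COLLAPSE_MAP = {1: 1, 2: 1, 3: 2, 4: 3, 5: 3}


def collapse_categories(y):
    """Collapse the 5-level happiness scale to 3 levels: the two lowest
    responses merge, the two highest merge, the middle stays. Accepts a scalar
    or an array and conserves total counts."""
    arr = np.asarray(y)
    if arr.size and (arr.min() < 1 or arr.max() > 5):
        raise ValueError("happiness categories must lie in 1..5")
    collapsed = np.clip(arr.astype(int) - 1, 0, 4)
    lut = np.array([1, 1, 2, 3, 3])
    out = lut[collapsed]
    return int(out) if np.isscalar(y) or np.asarray(y).ndim == 0 else out
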