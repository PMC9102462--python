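"""Synthetic two-level survey generator.

Emulates the statistical structure of a city-clustered happiness survey in a
heavily polluted urban agglomeration: 43 cities, 82-208 respondents each,
city-level covariates (annual polluted days, climate, per-capita GDP, secondary
industry share) with realistic means/SDs, individual socio-demographics with
realistic proportions, log-normal monthly income recorded both continuously and
in seven ordered bands, and an ordinal 5-level happiness response drawn from
the latent cumulative-logit model with city random intercepts.

All "true" coefficients in :class:`TrueParameters` are synthetic truths of
plausible magnitude chosen for testability; they are inputs of the generator,
not empirical claims.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import DEFAULT_INCOME_BANDS, augment_design_columns, design_matrix

__all__ = [
    "TrueParameters",
    "ScenarioConfig",
    "default_scenario",
    "generate_cities",
    "generate_individuals",
    "simulate_survey",
    "write_survey",
    "read_survey",
]

# Synthetic truth defaults. Signs follow the field's stylised facts (income,
# homeownership, marriage, education and better health raise latent happiness;
# pollution and being male lower it); magnitudes are plausible for a logit scale.
_DEFAULT_BETA = {
    "income_rmb": 0.28,     # per log-RMB (income enters as natural log)
    "commodity": -0.07,
    "owner": 0.30,
    "male": -0.18,
    "age_band": -0.01,      # per band index, treated as continuous
    "college": 0.14,
    "married": 0.31,
    "health_2": 0.5,        # dummies vs the "very bad" reference
    "health_3": 1.2,
    "health_4": 2.0,
    "health_5": 2.5,
}
_DEFAULT_GAMMA = {
    "polluted_days": -0.003,  # per polluted day per year
    "wind": 0.10,             # per m/s
    "temperature": 0.02,      # per deg C
    "precipitation": 0.0,
    "industry_share": 0.02,   # per percentage point
    "gdp_pc_10k": 0.01,       # per 10,000 RMB
}
_DEFAULT_TRANSFORMS = {"income_rmb": "log"}


@dataclass(frozen=True)
class TrueParameters:
    """Generating truth for the latent model, keyed by design column."""

    alpha: tuple[float, ...] = (1.1, 2.5, 4.8, 7.1)
    beta: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BETA))
    gamma: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_GAMMA))
    sigma_u2: float = 0.1
    transforms: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_TRANSFORMS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        object.__setattr__(self, "beta", dict(self.beta))
        object.__setattr__(self, "gamma", dict(self.gamma))
        object.__setattr__(self, "transforms", dict(self.transforms))
        if len(self.alpha) >= 2 and np.any(np.diff(self.alpha) <= 0):
            raise ValueError("true_parameters.alpha must be strictly increasing")
        if self.sigma_u2 < 0:
            raise ValueError("true_parameters.sigma_u2 must be >= 0")

    def to_dict(self) -> dict:
        return {
            "alpha": list(self.alpha),
            "beta": dict(self.beta),
            "gamma": dict(self.gamma),
            "sigma_u2": self.sigma_u2,
            "transforms": dict(self.transforms),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrueParameters":
        return cls(
            alpha=tuple(d["alpha"]),
            beta=dict(d["beta"]),
            gamma=dict(d["gamma"]),
            sigma_u2=float(d["sigma_u2"]),
            transforms=dict(d.get("transforms", _DEFAULT_TRANSFORMS)),
        )


_PROPORTION_FIELDS = (
    "prop_male",
    "prop_college",
    "prop_married",
    "prop_owner",
    "prop_commodity",
    "prop_local_hukou",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study scenario.

    Defaults reproduce the survey-region calibration: 43 cities averaging about
    150 respondents, polluted days 153 (SD 69) per year, per-capita GDP and
    industry share correlated at 0.5, monthly income log-normal around a mean
    of 6,868 RMB (SD 5,311) recorded in seven bands.
    """

    n_cities: int = 43
    city_size_range: tuple[int, int] = (82, 208)

    polluted_days_mean: float = 153.0
    polluted_days_sd: float = 69.0
    wind_mean: float = 2.40
    wind_sd: float = 0.27
    temperature_mean: float = 12.0
    temperature_sd: float = 2.28
    precipitation_mean: float = 594.0
    precipitation_sd: float = 115.13
    gdp_pc_mean: float = 60217.0
    gdp_pc_sd: float = 29809.0
    industry_share_mean: float = 46.69
    industry_share_sd: float = 8.0
    gdp_industry_corr: float = 0.5

    # log-normal monthly income; these values give mean 6868, SD 5311 RMB
    income_log_mean: float = 8.600108
    income_log_sd: float = 0.684653
    income_bands: tuple[tuple[float, float | None], ...] = DEFAULT_INCOME_BANDS

    prop_male: float = 0.5343
    prop_college: float = 0.6204
    prop_married: float = 0.70
    prop_owner: float = 0.6371
    prop_commodity: float = 0.4304
    prop_local_hukou: float = 0.70

    age_band_probs: tuple[float, ...] = (0.0368, 0.3974, 0.2953, 0.2521, 0.0184)
    health_probs: tuple[float, ...] = (0.0049, 0.0417, 0.2747, 0.4843, 0.1944)

    true_parameters: TrueParameters = field(default_factory=TrueParameters)
    seed: int = 20150217

    def __post_init__(self) -> None:
        object.__setattr__(self, "city_size_range", tuple(int(v) for v in self.city_size_range))
        object.__setattr__(self, "income_bands", tuple(
            (float(lo), None if hi is None else float(hi)) for lo, hi in self.income_bands
        ))
        object.__setattr__(self, "age_band_probs", tuple(float(p) for p in self.age_band_probs))
        object.__setattr__(self, "health_probs", tuple(float(p) for p in self.health_probs))
        if self.n_cities < 1:
            raise ValueError("n_cities must be >= 1")
        lo, hi = self.city_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"city_size_range must satisfy 1 <= min <= max, got {self.city_size_range}")
        for name in _PROPORTION_FIELDS:
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not -1.0 <= self.gdp_industry_corr <= 1.0:
            raise ValueError(f"gdp_industry_corr must lie in [-1, 1], got {self.gdp_industry_corr}")
        for name in ("age_band_probs", "health_probs"):
            probs = np.asarray(getattr(self, name))
            if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a probability simplex summing to 1")
        for name in ("polluted_days_sd", "wind_sd", "temperature_sd", "precipitation_sd",
                     "gdp_pc_sd", "industry_share_sd", "income_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self._validate_bands()

    def _validate_bands(self) -> None:
        bands = self.income_bands
        if len(bands) < 1 or bands[-1][1] is not None:
            raise ValueError("income_bands must end with an open top band")
        prev_hi = 0.0
        for i, (lo, hi) in enumerate(bands):
            if lo != prev_hi:
                raise ValueError(f"income_bands must be contiguous from 0; band {i + 1} starts at {lo}")
            if hi is not None:
                if hi <= lo:
                    raise ValueError(f"income_bands band {i + 1} must have hi > lo")
                prev_hi = hi

    @property
    def band_edges(self) -> np.ndarray:
        """Interior band edges for np.searchsorted binning."""
        return np.array([hi for _, hi in self.income_bands[:-1]], dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["city_size_range"] = list(self.city_size_range)
        d["income_bands"] = [[lo, hi] for lo, hi in self.income_bands]
        d["age_band_probs"] = list(self.age_band_probs)
        d["health_probs"] = list(self.health_probs)
        d["true_parameters"] = self.true_parameters.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        d["city_size_range"] = tuple(d["city_size_range"])
        d["income_bands"] = tuple((lo, hi) for lo, hi in d["income_bands"])
        d["true_parameters"] = TrueParameters.from_dict(d["true_parameters"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def default_scenario() -> ScenarioConfig:
    """The calibrated default scenario every downstream stage is tested on."""
    return ScenarioConfig()


def _rng_for(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


CITY_COLUMNS = ("city_id", "polluted_days", "wind", "temperature", "precipitation",
                "gdp_pc", "industry_share")
INDIVIDUAL_COLUMNS = ("city_id", "happiness", "income_band", "income_rmb", "male",
                      "college", "married", "owner", "commodity", "local_hukou",
                      "age_band", "health")


def generate_cities(config: ScenarioConfig) -> pd.DataFrame:
    """Draw the city-level table.

    Covariates are independent normals clipped to their domains, except
    (gdp_pc, industry_share) which are drawn bivariate-normal with the
    configured correlation. Deterministic given ``config.seed``.
    """
    rng = _rng_for(config, 0)
    K = config.n_cities
    days = np.rint(rng.normal(config.polluted_days_mean, config.polluted_days_sd, K))
    days = np.clip(days, 0, 365).astype(int)
    wind = np.clip(rng.normal(config.wind_mean, config.wind_sd, K), 0.05, None)
    temp = rng.normal(config.temperature_mean, config.temperature_sd, K)
    precip = np.clip(rng.normal(config.precipitation_mean, config.precipitation_sd, K), 0.0, None)

    cov = config.gdp_industry_corr * config.gdp_pc_sd * config.industry_share_sd
    mean = [config.gdp_pc_mean, config.industry_share_mean]
    cov_mat = [[config.gdp_pc_sd ** 2, cov], [cov, config.industry_share_sd ** 2]]
    gdp_ind = rng.multivariate_normal(mean, cov_mat, size=K)  # svd method: tolerates degenerate SDs
    gdp = np.clip(gdp_ind[:, 0], 1000.0, None)
    industry = np.clip(gdp_ind[:, 1], 0.0, 100.0)

    width = max(2, len(str(K)))
    return pd.DataFrame({
        "city_id": [f"C{k + 1:0{width}d}" for k in range(K)],
        "polluted_days": days,
        "wind": wind,
        "temperature": temp,
        "precipitation": precip,
        "gdp_pc": gdp,
        "industry_share": industry,
    })


def generate_individuals(cities: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Draw the individual-level table and the ordinal happiness response.

    Per-city counts are uniform on ``city_size_range``. The response comes from
    the latent model: h* = x'beta + z'gamma + u_k + e with standard-logistic e
    and u_k ~ N(0, sigma_u2); the observed category is the interval of h*
    within the true thresholds. Deterministic given ``config.seed``.
    """
    if len(cities) == 0:
        raise ValueError("cities table is empty")
    rng = _rng_for(config, 1)
    truth = config.true_parameters
    K = len(cities)
    lo, hi = config.city_size_range
    sizes = rng.integers(lo, hi + 1, size=K)
    n = int(sizes.sum())
    city_ids = np.repeat(cities["city_id"].to_numpy(), sizes)

    income = rng.lognormal(config.income_log_mean, config.income_log_sd, n)
    band = 1 + np.searchsorted(config.band_edges, income, side="right")

    df = pd.DataFrame({
        "city_id": city_ids,
        "income_band": band.astype(int),
        "income_rmb": income,
        "male": (rng.random(n) < config.prop_male).astype(int),
        "college": (rng.random(n) < config.prop_college).astype(int),
        "married": (rng.random(n) < config.prop_married).astype(int),
        "owner": (rng.random(n) < config.prop_owner).astype(int),
        "commodity": (rng.random(n) < config.prop_commodity).astype(int),
        "local_hukou": (rng.random(n) < config.prop_local_hukou).astype(int),
        "age_band": rng.choice(np.arange(1, 6), size=n, p=config.age_band_probs),
        "health": rng.choice(np.arange(1, 6), size=n, p=config.health_probs),
    })

    merged = augment_design_columns(df.merge(cities, on="city_id", how="left"))
    beta_cols, gamma_cols = tuple(truth.beta), tuple(truth.gamma)
    missing = [c for c in beta_cols + gamma_cols if c not in merged.columns]
    if missing:
        raise ValueError(f"true_parameters reference columns absent from the design: {missing}")
    eta = np.zeros(n)
    if beta_cols:
        eta += design_matrix(merged, beta_cols, truth.transforms) @ np.array(
            [truth.beta[c] for c in beta_cols])
    if gamma_cols:
        eta += design_matrix(merged, gamma_cols, truth.transforms) @ np.array(
            [truth.gamma[c] for c in gamma_cols])

    u = rng.normal(0.0, np.sqrt(truth.sigma_u2), K) if truth.sigma_u2 > 0 else np.zeros(K)
    hstar = eta + np.repeat(u, sizes) + rng.logistic(0.0, 1.0, n)
    alpha = np.asarray(truth.alpha)
    df.insert(1, "happiness", (1 + np.searchsorted(alpha, hstar, side="left")).astype(int))
    return df[list(INDIVIDUAL_COLUMNS)]


def simulate_survey(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate both tables; the returned cities table additionally carries
    ``mean_income`` (RMB/month), derived from that city's residents."""
    cities = generate_cities(config)
    individuals = generate_individuals(cities, config)
    mean_income = individuals.groupby("city_id")["income_rmb"].mean()
    cities = cities.assign(mean_income=cities["city_id"].map(mean_income).to_numpy())
    return individuals, cities


def write_survey(outdir, individuals: pd.DataFrame, cities: pd.DataFrame,
                 config: ScenarioConfig | None = None) -> dict[str, Path]:
    """Write individuals.csv / cities.csv (fixed column order) and, when a
    config is given, scenario.yaml carrying the full scenario incl. the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "individuals": outdir / "individuals.csv",
        "cities": outdir / "cities.csv",
    }
    individuals.to_csv(paths["individuals"], index=False)
    cities.to_csv(paths["cities"], index=False)
    if config is not None:
        paths["scenario"] = outdir / "scenario.yaml"
        config.to_yaml(paths["scenario"])
    return paths


def read_survey(individuals_csv, cities_csv) -> tuple[pd.DataFrame, pd.DataFrame]:
    return pd.read_csv(individuals_csv), pd.read_csv(cities_csv)
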