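"""MCMC estimation, posterior summaries, diagnostics, DIC and VPC.

The user-facing entry point is :class:`HierarchicalOrdinalRegression`, a
scikit-learn-style estimator (``fit`` / ``predict_proba`` / ``get_params``)
over the Metropolis-within-Gibbs kernel in :mod:`airhappy.sampler`; the
module-level functions (:func:`run_mcmc`, :func:`posterior_summary`,
:func:`gelman_rubin`, :func:`compute_dic`, :func:`vpc`) are the underlying
operations and remain usable on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.base import BaseEstimator

from . import sampler
from .model import (
    Dataset,
    ModelSpec,
    Parameters,
    PriorSpec,
    category_probabilities,
    observation_log_probs,
)

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "run_mcmc",
    "posterior_summary",
    "gelman_rubin",
    "compute_dic",
    "vpc",
    "prior_sensitivity",
    "HierarchicalOrdinalRegression",
]

LOGISTIC_VARIANCE = np.pi ** 2 / 3.0

RHAT_WARN_THRESHOLD = 1.05


@dataclass(frozen=True)
class McmcConfig:
    """Chain-length and adaptation settings.

    Defaults follow the full estimation protocol (3 chains of 50,000
    iterations, 30,000 burn-in, every 10th draw retained); tests and the
    simulation experiments use shorter, scaled-down runs.
    """

    n_chains: int = 3
    n_iterations: int = 50_000
    burn_in: int = 30_000
    thin: int = 10
    seed: int = 0
    adapt_interval: int = 50
    target_acceptance: float = 0.44

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")
        if self.adapt_interval < 1:
            raise ValueError("adapt_interval must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples across chains.

    ``samples`` has one row per retained draw with labelled columns
    (``alpha_1``..; ``b_<col>`` for individual coefficients; ``g_<col>`` for
    city coefficients; ``u_<city_id>``; ``sigma_u2``) plus a ``chain`` id.
    """

    samples: pd.DataFrame
    x_names: tuple[str, ...]
    z_names: tuple[str, ...]
    city_ids: tuple
    n_categories: int
    config: McmcConfig
    acceptance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = self.alpha_array()
        if a.shape[1] >= 2 and np.any(np.diff(a, axis=1) <= 0):
            raise ValueError("retained threshold draws must be strictly increasing")
        if np.any(self.samples["sigma_u2"].to_numpy() <= 0):
            raise ValueError("retained sigma_u2 draws must be strictly positive")

    # -- column naming ------------------------------------------------
    @property
    def alpha_names(self) -> list[str]:
        return [f"alpha_{j + 1}" for j in range(self.n_categories - 1)]

    @property
    def coef_names(self) -> list[str]:
        return [f"b_{c}" for c in self.x_names] + [f"g_{c}" for c in self.z_names]

    @property
    def u_names(self) -> list[str]:
        return [f"u_{cid}" for cid in self.city_ids]

    @property
    def parameter_names(self) -> list[str]:
        return self.alpha_names + self.coef_names + self.u_names + ["sigma_u2"]

    # -- accessors ----------------------------------------------------
    def pooled(self, name: str) -> np.ndarray:
        """All retained draws for one parameter, pooled across chains."""
        return self.samples[name].to_numpy()

    def by_chain(self, name: str) -> np.ndarray:
        """(n_chains, n_draws) array for one parameter."""
        groups = [g.to_numpy() for _, g in self.samples.groupby("chain")[name]]
        return np.vstack(groups)

    def alpha_array(self) -> np.ndarray:
        return self.samples[self.alpha_names].to_numpy()

    def coef_array(self) -> np.ndarray:
        return self.samples[self.coef_names].to_numpy()

    def u_array(self) -> np.ndarray:
        return self.samples[self.u_names].to_numpy()

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    def median_parameters(self) -> Parameters:
        """Posterior medians bundled as a Parameters value (elementwise
        medians; the threshold ordering survives because every draw is
        ordered)."""
        med = self.samples.median(numeric_only=True)
        return Parameters(
            alpha=med[self.alpha_names].to_numpy(),
            beta=med[[f"b_{c}" for c in self.x_names]].to_numpy() if self.x_names else np.empty(0),
            gamma=med[[f"g_{c}" for c in self.z_names]].to_numpy() if self.z_names else np.empty(0),
            u=med[self.u_names].to_numpy() if self.city_ids else np.empty(0),
            sigma_u2=float(med["sigma_u2"]),
        )

    # -- persistence ---------------------------------------------------
    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: McmcConfig | None = None) -> "PosteriorDraws":
        samples = pd.read_csv(path)
        alpha_cols = sorted(
            (c for c in samples.columns if c.startswith("alpha_")),
            key=lambda c: int(c.split("_")[1]),
        )
        x_names = tuple(c[2:] for c in samples.columns if c.startswith("b_"))
        z_names = tuple(c[2:] for c in samples.columns if c.startswith("g_"))
        city_ids = tuple(c[2:] for c in samples.columns if c.startswith("u_"))
        n_chains = samples["chain"].nunique()
        if config is None:
            config = McmcConfig(n_chains=n_chains, n_iterations=2, burn_in=0, thin=1)
        return cls(
            samples=samples,
            x_names=x_names,
            z_names=z_names,
            city_ids=city_ids,
            n_categories=len(alpha_cols) + 1,
            config=config,
        )


def _initial_alpha(y0: np.ndarray, J: int) -> np.ndarray:
    """Empirical cumulative logits of the observed response, nudged into
    strict order when categories are empty."""
    counts = np.bincount(y0, minlength=J).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-3, 1.0 - 1e-3)
    cum = np.maximum.accumulate(cum + 1e-6 * np.arange(J - 1))
    return logit(np.minimum(cum, 1.0 - 1e-9))


def run_mcmc(
    data,
    spec: ModelSpec | None = None,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
) -> PosteriorDraws:
    """Estimate the multilevel cumulative-logit model by MCMC.

    ``data`` is a prepared :class:`Dataset` or an ``(individuals, cities)``
    pair of DataFrames (then ``spec`` is required). Runs ``config.n_chains``
    independent adaptive Metropolis-within-Gibbs chains, deterministic given
    ``config.seed``.
    """
    if not isinstance(data, Dataset):
        individuals, cities = data
        if spec is None:
            raise ValueError("spec is required when passing raw data frames")
        data = Dataset.from_frames(individuals, cities, spec)
    priors = priors or PriorSpec()
    config = config or McmcConfig()

    y0 = data.y0
    J = data.J
    counts = np.bincount(y0, minlength=J)
    if np.any(counts == 0):
        empty = [int(j + 1) for j in np.flatnonzero(counts == 0)]
        warnings.warn(
            f"response categories {empty} are empty; the adjacent thresholds are weakly identified",
            UserWarning,
            stacklevel=2,
        )

    # Mean-centre the design for sampling; thresholds are shifted back on
    # output (alpha = alpha_centred + mu'coef), leaving the model unchanged.
    mu = data.D.mean(axis=0)
    Dc = data.D - mu

    alpha0 = _initial_alpha(y0, J)
    p = data.D.shape[1]
    K = data.n_cities

    frames = []
    acceptance: dict[int, dict] = {}
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        res = None
        for attempt in range(5):
            try:
                res = sampler.sample_chain(
                    y0, Dc, data.city_index, data.group_starts, J,
                    prior_var=priors.coef_prior_variance,
                    ig_shape=priors.ig_shape,
                    ig_scale=priors.ig_scale,
                    n_iterations=config.n_iterations,
                    burn_in=config.burn_in,
                    thin=config.thin,
                    adapt_interval=config.adapt_interval,
                    target_acceptance=config.target_acceptance,
                    alpha_init=alpha0 + 1e-3 * attempt,
                    coef_init=np.zeros(p),
                    u_init=np.zeros(K),
                    sigma_u2_init=0.1,
                    rng=rng,
                )
                break
            except FloatingPointError:
                continue
        if res is None:
            raise RuntimeError("could not initialize the sampler with a finite log-likelihood")

        alpha_out = res["alpha"] + res["coef"] @ mu[:, None]  # undo centring
        frame = pd.DataFrame(
            np.column_stack([alpha_out, res["coef"], res["u"], res["sigma_u2"]]),
            columns=(
                [f"alpha_{j + 1}" for j in range(J - 1)]
                + [f"b_{col}" for col in data.x_columns]
                + [f"g_{col}" for col in data.z_columns]
                + [f"u_{cid}" for cid in data.city_ids]
                + ["sigma_u2"]
            ),
        )
        frame["chain"] = c
        frames.append(frame)
        acceptance[c] = res["acceptance"]

    return PosteriorDraws(
        samples=pd.concat(frames, ignore_index=True),
        x_names=tuple(data.x_columns),
        z_names=tuple(data.z_columns),
        city_ids=tuple(data.city_ids),
        n_categories=J,
        config=config,
        acceptance=acceptance,
    )


def prior_sensitivity(
    data,
    priors_list: list[PriorSpec],
    config: McmcConfig | None = None,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Refit the model under alternative hyperprior settings and stack the
    posterior summaries, one block per prior, for a quick sensitivity read.

    The returned frame is indexed by (prior label, parameter); labels encode
    the inverse-gamma hyperparameters and coefficient prior variance.
    """
    blocks = {}
    for priors in priors_list:
        label = (f"N(0,{priors.coef_prior_variance:g})/"
                 f"IG({priors.ig_shape:g},{priors.ig_scale:g})")
        draws = run_mcmc(data, spec=spec, priors=priors, config=config)
        blocks[label] = posterior_summary(draws)
    return pd.concat(blocks, names=["prior", "parameter"])


def _stars(draws: np.ndarray) -> str:
    """Significance marker: the equal-tailed 99/95/90% interval excludes 0."""
    for level, mark in ((0.99, "***"), (0.95, "**"), (0.90, "*")):
        lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2])
        if lo > 0 or hi < 0:
            return mark
    return ""


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-parameter posterior median and equal-tailed 95% interval, pooled
    across chains, with significance markers. Quantiles use the linear
    interpolation (type-7) convention."""
    if draws.n_draws == 0:
        raise ValueError("no retained draws to summarize")
    rows = []
    for name in draws.parameter_names:
        v = draws.pooled(name)
        med, lo, hi = np.quantile(v, [0.5, 0.025, 0.975])
        rows.append({"parameter": name, "median": med, "ci_2.5": lo, "ci_97.5": hi,
                     "sig": _stars(v)})
    return pd.DataFrame(rows).set_index("parameter")


def gelman_rubin(draws: PosteriorDraws) -> pd.Series:
    """Split-R-hat per parameter (each chain halved, between/within variance
    ratio). Values near 1 indicate convergence."""
    if draws.config.n_chains < 2 and draws.samples["chain"].nunique() < 2:
        raise ValueError("gelman_rubin requires at least two chains")
    out = {}
    for name in draws.parameter_names:
        chains = draws.by_chain(name)
        half = chains.shape[1] // 2
        if half < 2:
            raise ValueError("chains too short to split for R-hat")
        split = np.vstack([chains[:, :half], chains[:, half:2 * half]])
        m, n_len = split.shape
        W = split.var(axis=1, ddof=1).mean()
        B = n_len * split.mean(axis=1).var(ddof=1)
        if W <= 0:
            out[name] = 1.0
        else:
            var_hat = (n_len - 1) / n_len * W + B / n_len
            out[name] = float(np.sqrt(var_hat / W))
    return pd.Series(out, name="rhat")


def compute_dic(draws: PosteriorDraws, data: Dataset) -> tuple[float, float, float]:
    """Deviance information criterion.

    Returns ``(DIC, pD, Dbar)`` with ``Dbar`` the posterior mean deviance and
    ``pD = Dbar - D(theta_bar)`` the Spiegelhalter plug-in effective number of
    parameters at the posterior mean (city intercepts included, i.e. the
    likelihood is conditional on u).
    """
    expected = list(data.x_columns) + list(data.z_columns)
    got = list(draws.x_names) + list(draws.z_names)
    if expected != got or tuple(draws.city_ids) != tuple(data.city_ids):
        raise ValueError("draws were not produced from a dataset with this design")
    A = draws.alpha_array()
    C = draws.coef_array()
    U = draws.u_array()
    y = data.y
    D = data.D
    ci = data.city_index
    dev = np.empty(len(A))
    for s in range(len(A)):
        eta = D @ C[s] + U[s][ci]
        dev[s] = -2.0 * observation_log_probs(y, eta, A[s]).sum()
    dbar = float(dev.mean())
    eta_bar = D @ C.mean(axis=0) + U.mean(axis=0)[ci]
    d_hat = -2.0 * float(observation_log_probs(y, eta_bar, A.mean(axis=0)).sum())
    p_d = dbar - d_hat
    return dbar + p_d, p_d, dbar


def vpc(sigma_u2):
    """Variance partitioning coefficient: the share of latent-scale variance
    attributable to the city level, sigma_u^2 / (sigma_u^2 + pi^2/3)."""
    s2 = np.asarray(sigma_u2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("sigma_u2 must be >= 0")
    out = s2 / (s2 + LOGISTIC_VARIANCE)
    return float(out) if out.ndim == 0 else out


class HierarchicalOrdinalRegression(BaseEstimator):
    """Bayesian multilevel proportional-odds regression, sklearn style.

    Fits ``logit P(y <= j) = alpha_j - x'beta - z'gamma - u_k`` by adaptive
    Metropolis-within-Gibbs MCMC, with Normal(0, ``coef_prior_variance``)
    priors on thresholds and coefficients and an Inverse-Gamma prior on the
    between-city variance.

    Parameters mirror :class:`ModelSpec`, :class:`PriorSpec` and
    :class:`McmcConfig`; fitted attributes carry the trailing underscore
    (``draws_``, ``summary_``, ``dic_``, ``vpc_``, ``rhat_``).

    Examples
    --------
    >>> est = HierarchicalOrdinalRegression(
    ...     individual_predictors=("income_rmb",),
    ...     city_predictors=("polluted_days",),
    ...     transforms={"income_rmb": "log"},
    ...     n_iterations=2000, burn_in=1000, thin=2, n_chains=2, random_state=0)
    >>> est.fit(individuals, cities=cities)        # doctest: +SKIP
    """

    def __init__(
        self,
        individual_predictors=("income_rmb",),
        city_predictors=("polluted_days",),
        transforms=None,
        n_categories=5,
        response="happiness",
        coef_prior_variance=1.0e6,
        ig_shape=0.001,
        ig_scale=0.001,
        n_chains=3,
        n_iterations=50_000,
        burn_in=30_000,
        thin=10,
        adapt_interval=50,
        target_acceptance=0.44,
        random_state=None,
    ):
        self.individual_predictors = individual_predictors
        self.city_predictors = city_predictors
        self.transforms = transforms
        self.n_categories = n_categories
        self.response = response
        self.coef_prior_variance = coef_prior_variance
        self.ig_shape = ig_shape
        self.ig_scale = ig_scale
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.adapt_interval = adapt_interval
        self.target_acceptance = target_acceptance
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _spec(self) -> ModelSpec:
        return ModelSpec(
            response=self.response,
            individual_predictors=tuple(self.individual_predictors),
            city_predictors=tuple(self.city_predictors),
            n_categories=self.n_categories,
            transforms=dict(self.transforms or {}),
        )

    def _mcmc_config(self) -> McmcConfig:
        return McmcConfig(
            n_chains=self.n_chains,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=0 if self.random_state is None else int(self.random_state),
            adapt_interval=self.adapt_interval,
            target_acceptance=self.target_acceptance,
        )

    def _priors(self) -> PriorSpec:
        return PriorSpec(self.coef_prior_variance, self.ig_shape, self.ig_scale)

    def fit(self, X: pd.DataFrame, y=None, *, cities: pd.DataFrame):
        """Fit on an individuals table ``X`` and a ``cities`` table.

        ``X`` must contain ``city_id`` and all individual predictors; the
        ordinal response is taken from ``y`` when given, else from the
        ``response`` column of ``X``.
        """
        X = pd.DataFrame(X)
        if y is not None:
            X = X.copy()
            X[self.response] = np.asarray(y)
        spec = self._spec()
        dataset = Dataset.from_frames(X, cities, spec)
        draws = run_mcmc(dataset, priors=self._priors(), config=self._mcmc_config())

        self.spec_ = spec
        self.dataset_ = dataset
        self.draws_ = draws
        self.summary_ = posterior_summary(draws)
        if self.n_chains >= 2:
            self.rhat_ = gelman_rubin(draws)
            bad = self.rhat_[self.rhat_ > RHAT_WARN_THRESHOLD]
            if len(bad):
                warnings.warn(
                    f"R-hat above {RHAT_WARN_THRESHOLD} for {len(bad)} parameter(s): "
                    f"{', '.join(bad.index[:5])}",
                    UserWarning,
                    stacklevel=2,
                )
        else:
            self.rhat_ = None
        self.dic_, self.p_d_, self.dbar_ = compute_dic(draws, dataset)
        self.sigma_u2_ = float(np.median(draws.pooled("sigma_u2")))
        self.vpc_ = vpc(self.sigma_u2_)
        self.params_ = draws.median_parameters()
        self.n_features_in_ = dataset.D.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise AttributeError("this estimator is not fitted yet; call fit first")

    def predict_proba(self, X: pd.DataFrame, *, cities: pd.DataFrame | None = None) -> np.ndarray:
        """Posterior-median category probabilities, one row per respondent.
        Cities unseen during fitting receive a zero random intercept."""
        self._check_fitted()
        X = pd.DataFrame(X)
        if cities is not None:
            X = X.merge(cities, on="city_id", how="left", validate="many_to_one")
        from .model import augment_design_columns, design_matrix

        X = augment_design_columns(X)
        D = design_matrix(X, self.spec_.predictors, self.spec_.transforms)
        params = self.params_
        coef = np.concatenate([params.beta, params.gamma])
        eta = D @ coef
        if "city_id" in X.columns and params.u.size:
            u_map = dict(zip(self.dataset_.city_ids, params.u))
            eta = eta + np.array([u_map.get(c, 0.0) for c in X["city_id"]])
        return category_probabilities(eta, params.alpha)

    def predict(self, X: pd.DataFrame, *, cities: pd.DataFrame | None = None) -> np.ndarray:
        """Most probable happiness category (1..J) per respondent."""
        return np.argmax(self.predict_proba(X, cities=cities), axis=-1) + 1
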