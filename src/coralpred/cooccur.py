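"""Bayesian binary co-occurrence model with weakly informative Cauchy priors.

Prey presence on a coral head is modelled per species as Bernoulli with a
logit that depends only on the predator category (none / small / large),
using cell-means coding (one coefficient per category).  Independent
Cauchy(0, scale) priors on the coefficients keep the posterior proper under
complete separation — a category whose outcomes are all 0 (or all 1), which
is common in small presence/absence surveys and makes the unpenalised MLE
infinite.

Sampling is componentwise random-walk Metropolis with the proposal scale
adapted during burn-in toward ~0.3 acceptance and frozen afterwards; draws
after burn-in are thinned.  Because the cell-means likelihood factorises by
category, each coefficient's conditional update only needs the category's
(successes, rows) sufficient statistics, so long chains are cheap.

Species are modelled independently (the survey reports per-species
predictions only; no cross-species covariance is estimated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import arviz as az
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CATEGORIES",
    "SurveyTable",
    "CoocConfig",
    "Design",
    "PosteriorChains",
    "CategoryPrediction",
    "CooccurrenceMCMC",
    "encode_categories",
    "log_posterior",
    "mcmc_fit",
    "posterior_predict",
    "predictions_table",
    "chain_diagnostics",
]

CATEGORIES = ("none", "small", "large")


@dataclass
class SurveyTable:
    """Coral-head survey: one row per head with a predator category and
    binary presence flags for one or more prey species.

    ``data`` columns: head_id, hawkfish (none|small|large), one 0/1 column
    per species named ``<species>_present``, and optional head dimensions
    (length_cm, width_cm, height_cm) which are carried through I/O but not
    modelled.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"head_id", "hawkfish"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survey table missing columns: {sorted(missing)}")
        bad = ~self.data["hawkfish"].isin(CATEGORIES)
        if bad.any():
            rows = self.data.loc[bad, "head_id"].tolist()
            raise ValueError(f"unknown hawkfish category in rows {rows}")
        if not self.species:
            raise ValueError("survey table has no *_present species columns")
        for sp in self.species:
            col = self.data[f"{sp}_present"]
            if not col.isin([0, 1]).all():
                raise ValueError(f"{sp}_present must be 0/1")

    @property
    def species(self) -> list[str]:
        return [c[: -len("_present")] for c in self.data.columns if c.endswith("_present")]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class CoocConfig:
    """MCMC configuration.

    The reference (production) configuration is 3,000,000 iterations with a
    100,000-iteration burn-in and thinning of 1000 (2900 retained draws);
    the default here is a desk-scale configuration with the same structure.
    The residual variance of a binary response is unidentifiable and is
    fixed at 1, so coefficients are on the plain logit scale.
    """

    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    prior_scale: float = 2.5
    residual_variance: float = 1.0
    seed: int = 0
    proposal_sd: float = 1.0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be > 0")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")
        if self.residual_variance != 1.0:
            raise ValueError("residual variance is fixed at 1 for binary responses")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def reference(cls, seed: int = 0) -> "CoocConfig":
        """The long production chain (2900 retained draws)."""
        return cls(iterations=3_000_000, burn_in=100_000, thin=1000, seed=seed)


@dataclass
class Design:
    """Cell-means design for the three predator categories."""

    matrix: np.ndarray  # (n_rows, 3) indicators; rows sum to 1
    categories: tuple[str, ...]
    absent_levels: tuple[str, ...]  # categories with no rows in the data


def encode_categories(survey: SurveyTable) -> Design:
    """Cell-means (one-indicator-per-category) encoding of predator category.

    Row order is preserved; categories with no rows are retained as all-zero
    columns and flagged so downstream summaries can mark them data-absent.
    """
    cats = survey.data["hawkfish"].to_numpy()
    matrix = np.stack([(cats == c).astype(float) for c in CATEGORIES], axis=1)
    sums = matrix.sum(axis=0)
    absent = tuple(c for c, s in zip(CATEGORIES, sums) if s == 0)
    return Design(matrix=matrix, categories=CATEGORIES, absent_levels=absent)


def _cauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return -np.log(math.pi * scale) - np.log1p((x / scale) ** 2)


def log_posterior(
    coefs: np.ndarray, y: np.ndarray, design: np.ndarray, prior_scale: float
) -> float:
    """Unnormalised log posterior: Bernoulli-logit log-likelihood plus
    independent Cauchy(0, prior_scale) log prior densities.

    Finite for all finite coefficients; with zero data rows it reduces to
    the prior alone.
    """
    coefs = np.asarray(coefs, dtype=float)
    if not np.all(np.isfinite(coefs)):
        raise ValueError("coefficients must be finite")
    eta = np.asarray(design, dtype=float) @ coefs
    y = np.asarray(y, dtype=float)
    # log sigma(eta) = -log(1+e^-eta); log(1-sigma(eta)) = -log(1+e^eta)
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    logprior = float(np.sum(_cauchy_logpdf(coefs, prior_scale)))
    return loglik + logprior


@dataclass
class PosteriorChains:
    """Retained MCMC draws: (n_draws, n_species, n_categories)."""

    samples: np.ndarray
    species: tuple[str, ...]
    categories: tuple[str, ...]
    acceptance_rate: float
    config: CoocConfig
    absent_levels: tuple[str, ...] = ()

    def __post_init__(self):
        expected = self.config.n_retained
        if self.samples.shape != (expected, len(self.species), len(self.categories)):
            raise ValueError("sample array shape does not match config/labels")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite posterior draws")

    def coef_draws(self, species: str, category: str) -> np.ndarray:
        return self.samples[:, self.species.index(species), self.categories.index(category)]

    def trace_frame(self) -> pd.DataFrame:
        """Tidy trace table (draw, species, category, coef) for plotting."""
        n, s, c = self.samples.shape
        return pd.DataFrame(
            {
                "draw": np.repeat(np.arange(n), s * c),
                "species": np.tile(np.repeat(self.species, c), n),
                "category": np.tile(self.categories, n * s),
                "coef": self.samples.reshape(-1),
            }
        )


@dataclass(frozen=True)
class CategoryPrediction:
    """Posterior predicted presence probability for one species/category."""

    species: str
    category: str
    point: float  # posterior median
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    level: float = 0.95

    def __post_init__(self):
        if not (0 <= self.lower <= self.point <= self.upper <= 1):
            raise ValueError("credible interval must satisfy 0<=lower<=point<=upper<=1")


class CooccurrenceMCMC(BaseEstimator):
    """Bayesian logistic co-occurrence model fitted by random-walk Metropolis.

    Parameters mirror :class:`CoocConfig`.  ``fit`` takes the predator
    category per head (X) and a binary presence matrix (y, one column per
    species); ``predict_proba`` returns the posterior-median presence
    probability per row and species.

    Attributes
    ----------
    chains_ : PosteriorChains
    acceptance_rate_ : float
    species_ : tuple of str
    categories_ : tuple of str
    """

    def __init__(
        self,
        iterations: int = 20_000,
        burn_in: int = 2_000,
        thin: int = 10,
        prior_scale: float = 2.5,
        proposal_sd: float = 1.0,
        random_state: int = 0,
    ):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.prior_scale = prior_scale
        self.proposal_sd = proposal_sd
        self.random_state = random_state

    def _config(self) -> CoocConfig:
        return CoocConfig(
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            prior_scale=self.prior_scale,
            seed=self.random_state,
            proposal_sd=self.proposal_sd,
        )

    def fit(self, X, y):
        """X: categories per head (array-like of {'none','small','large'});
        y: 0/1 presence, shape (n,) or (n, n_species) / DataFrame."""
        config = self._config()
        cats = np.asarray(X).astype(str).reshape(-1)
        bad = ~np.isin(cats, CATEGORIES)
        if bad.any():
            raise ValueError(
                f"unknown predator category at rows {np.flatnonzero(bad).tolist()}"
            )
        if isinstance(y, pd.DataFrame):
            species = tuple(str(c) for c in y.columns)
            Y = y.to_numpy(dtype=float)
        else:
            Y = np.asarray(y, dtype=float)
            if Y.ndim == 1:
                Y = Y[:, None]
            species = tuple(f"species_{i}" for i in range(Y.shape[1]))
        if Y.shape[0] != cats.shape[0]:
            raise ValueError("X and y disagree on the number of heads")
        if not np.isin(Y, [0.0, 1.0]).all():
            raise ValueError("presence responses must be 0/1")
        if Y.shape[0] < 1:
            raise ValueError("at least one survey row is required")

        # per-category sufficient statistics: rows and successes
        cat_index = np.array([CATEGORIES.index(c) for c in cats])
        n_by_cat = np.bincount(cat_index, minlength=3).astype(float)
        k_by_cat = np.stack(
            [np.bincount(cat_index, weights=Y[:, j], minlength=3) for j in range(Y.shape[1])]
        )  # (n_species, 3)

        rng = np.random.default_rng(config.seed)
        samples, acc_rate, final_sd = _run_metropolis(
            k_by_cat, n_by_cat, config, rng
        )
        absent = tuple(c for c, n in zip(CATEGORIES, n_by_cat) if n == 0)
        self.chains_ = PosteriorChains(
            samples=samples,
            species=species,
            categories=CATEGORIES,
            acceptance_rate=acc_rate,
            config=config,
            absent_levels=absent,
        )
        self.acceptance_rate_ = acc_rate
        self.proposal_sd_ = final_sd
        self.species_ = species
        self.categories_ = CATEGORIES
        return self

    def predict_proba(self, X) -> pd.DataFrame:
        """Posterior-median presence probability per row, one column per species."""
        check_is_fitted(self, "chains_")
        cats = np.asarray(X).astype(str).reshape(-1)
        out = {}
        for sp in self.species_:
            med = {
                c: float(np.median(expit(self.chains_.coef_draws(sp, c))))
                for c in self.categories_
            }
            out[sp] = [med[c] for c in cats]
        return pd.DataFrame(out)

    def predict(self, X) -> np.ndarray:
        """Most probable presence (probability > 0.5) per row and species."""
        return (self.predict_proba(X).to_numpy() > 0.5).astype(int)


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _run_metropolis(k_by_cat: np.ndarray, n_by_cat: np.ndarray, config: CoocConfig, rng):
    """Componentwise random-walk Metropolis over all (species, category)
    coefficients at once, exploiting the factorised cell-means likelihood."""
    n_species, n_cat = k_by_cat.shape
    shape = (n_species, n_cat)
    coefs = np.zeros(shape)
    step = np.full(shape, config.proposal_sd)
    scale = config.prior_scale

    def logpost_comp(w):
        # per-coefficient posterior term: k*w - n*log(1+e^w) + Cauchy prior
        return (
            k_by_cat * w
            - n_by_cat[None, :] * _log1pexp(w)
            - np.log1p((w / scale) ** 2)
        )

    current_lp = logpost_comp(coefs)
    n_retained = config.n_retained
    samples = np.empty((n_retained, n_species, n_cat))
    kept = 0
    accepted_post = 0
    proposed_post = 0
    window_acc = np.zeros(shape)
    window_len = 50

    for it in range(1, config.iterations + 1):
        prop = coefs + step * rng.standard_normal(shape)
        prop_lp = logpost_comp(prop)
        accept = np.log(rng.random(shape)) < (prop_lp - current_lp)
        coefs = np.where(accept, prop, coefs)
        current_lp = np.where(accept, prop_lp, current_lp)

        if it <= config.burn_in:
            window_acc += accept
            if it % window_len == 0:
                rate = window_acc / window_len
                step *= np.exp(rate - 0.3)
                window_acc[:] = 0.0
        else:
            accepted_post += int(accept.sum())
            proposed_post += accept.size
            offset = it - config.burn_in
            if offset % config.thin == 0 and kept < n_retained:
                samples[kept] = coefs
                kept += 1

    acc_rate = accepted_post / proposed_post if proposed_post else float("nan")
    return samples[:kept], float(acc_rate), step


def mcmc_fit(survey: SurveyTable, config: CoocConfig | None = None) -> PosteriorChains:
    """Fit the co-occurrence model to a survey table (wrapper over
    :class:`CooccurrenceMCMC`)."""
    config = config or CoocConfig()
    est = CooccurrenceMCMC(
        iterations=config.iterations,
        burn_in=config.burn_in,
        thin=config.thin,
        prior_scale=config.prior_scale,
        proposal_sd=config.proposal_sd,
        random_state=config.seed,
    )
    y = survey.data[[f"{sp}_present" for sp in survey.species]].rename(
        columns={f"{sp}_present": sp for sp in survey.species}
    )
    est.fit(survey.data["hawkfish"].to_numpy(), y)
    return est.chains_


def posterior_predict(
    chains: PosteriorChains, species: str, category: str
) -> CategoryPrediction:
    """Posterior median and 95% credible interval of the presence probability
    for one species under one predator category (inverse-logit of the
    retained coefficient draws)."""
    if species not in chains.species:
        raise KeyError(f"species {species!r} not in chains")
    if category not in chains.categories:
        raise KeyError(f"category {category!r} not in chains")
    p = expit(chains.coef_draws(species, category))
    lower, point, upper = np.quantile(p, [0.025, 0.5, 0.975])
    return CategoryPrediction(
        species=species,
        category=category,
        point=float(point),
        lower=float(lower),
        upper=float(upper),
    )


def predictions_table(chains: PosteriorChains) -> pd.DataFrame:
    """Tidy per-(species, category) prediction table: point and 95% CrI."""
    rows = []
    for sp in chains.species:
        for cat in chains.categories:
            pr = posterior_predict(chains, sp, cat)
            rows.append(
                {
                    "species": sp,
                    "category": cat,
                    "point": pr.point,
                    "lower": pr.lower,
                    "upper": pr.upper,
                    "data_absent_level": cat in chains.absent_levels,
                }
            )
    return pd.DataFrame(rows)


def chain_diagnostics(chains: PosteriorChains) -> pd.DataFrame:
    """Per-coefficient convergence diagnostics.

    Effective sample size (autocorrelation-based, via ArviZ), a Geweke
    z-score comparing the first 10% against the last 50% of the chain, and
    the overall acceptance rate.  Constant (degenerate) chains are flagged
    instead of producing spurious statistics.
    """
    if chains.samples.shape[0] < 10:
        raise ValueError("need at least 10 retained draws for diagnostics")
    rows = []
    for si, sp in enumerate(chains.species):
        for ci, cat in enumerate(chains.categories):
            x = chains.samples[:, si, ci]
            degenerate = bool(np.ptp(x) == 0.0)
            if degenerate:
                ess = float("nan")
                geweke = float("nan")
            else:
                ess = float(az.ess(np.asarray(x)))
                geweke = _geweke_z(x)
            rows.append(
                {
                    "species": sp,
                    "category": cat,
                    "ess": ess,
                    "geweke_z": geweke,
                    "acceptance_rate": chains.acceptance_rate,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def diagnostics_from_trace(trace: pd.DataFrame, acceptance_rate: float = float("nan")) -> pd.DataFrame:
    """Diagnostics computed from a tidy trace table (draw, species, category,
    coef), e.g. one previously written to CSV."""
    rows = []
    for (sp, cat), grp in trace.groupby(["species", "category"], sort=False):
        x = grp.sort_values("draw")["coef"].to_numpy()
        if x.shape[0] < 10:
            raise ValueError("need at least 10 retained draws for diagnostics")
        degenerate = bool(np.ptp(x) == 0.0)
        rows.append(
            {
                "species": sp,
                "category": cat,
                "ess": float("nan") if degenerate else float(az.ess(np.asarray(x))),
                "geweke_z": float("nan") if degenerate else _geweke_z(x),
                "acceptance_rate": acceptance_rate,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def _geweke_z(x: np.ndarray, first: float = 0.10, last: float = 0.50) -> float:
    """Geweke convergence z-score with ESS-adjusted standard errors."""
    n = x.shape[0]
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    var_a, var_b = np.var(a, ddof=1), np.var(b, ddof=1)
    if var_a == 0.0 or var_b == 0.0:
        return float("nan")
    se2 = var_a / max(float(az.ess(np.asarray(a))), 1.0) + var_b / max(
        float(az.ess(np.asarray(b))), 1.0
    )
    return float((a.mean() - b.mean()) / math.sqrt(se2))
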