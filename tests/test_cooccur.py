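import math

import numpy as np
import pandas as pd
import pytest

from coralpred.cooccur import (
    CATEGORIES,
    CoocConfig,
    CooccurrenceMCMC,
    PosteriorChains,
    SurveyTable,
    chain_diagnostics,
    encode_categories,
    log_posterior,
    mcmc_fit,
    posterior_predict,
    predictions_table,
)
from coralpred.synthetic import SurveyGenSpec, reference_survey_spec, simulate_survey


def make_survey(categories, presence):
    return SurveyTable(
        data=pd.DataFrame(
            {
                "head_id": [f"h{i}" for i in range(len(categories))],
                "hawkfish": categories,
                "prey_present": presence,
            }
        )
    )


class TestEncodeCategories:
    def test_identity_pattern(self):
        survey = make_survey(["none", "small", "large"], [1, 0, 1])
        design = encode_categories(survey)
        assert np.array_equal(design.matrix, np.eye(3))
        assert design.absent_levels == ()

    def test_degenerate_single_level_flagged(self):
        survey = make_survey(["none"] * 5, [1, 0, 1, 0, 0])
        design = encode_categories(survey)
        assert design.matrix[:, 0].sum() == 5
        assert set(design.absent_levels) == {"small", "large"}

    def test_column_sums_match_generated_counts(self):
        survey = simulate_survey(reference_survey_spec(seed=3))
        design = encode_categories(survey)
        counts = survey.data["hawkfish"].value_counts()
        for j, cat in enumerate(CATEGORIES):
            assert design.matrix[:, j].sum() == counts.get(cat, 0)
        assert np.all(design.matrix.sum(axis=1) == 1)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="h1"):
            make_survey(["none", "medium"], [0, 1])


class TestLogPosterior:
    def test_prior_only_with_no_rows(self):
        from scipy.stats import cauchy

        coefs = np.array([0.3, -1.2, 2.0])
        value = log_posterior(coefs, np.empty(0), np.empty((0, 3)), prior_scale=2.5)
        assert value == pytest.approx(cauchy.logpdf(coefs, scale=2.5).sum(), rel=1e-12)

    def test_single_row_at_zero_coef(self):
        from scipy.stats import cauchy

        value = log_posterior(
            np.zeros(3), np.array([1.0]), np.array([[1.0, 0, 0]]), prior_scale=2.5
        )
        expected = math.log(0.5) + 3 * cauchy.logpdf(0.0, scale=2.5)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_matches_row_by_row_sum(self, rng):
        # brute-force re-summation over a 10-row fixture
        design = np.eye(3)[rng.integers(0, 3, size=10)]
        y = rng.integers(0, 2, size=10).astype(float)
        coefs = rng.normal(size=3)
        expected = 0.0
        for yi, row in zip(y, design):
            eta = float(row @ coefs)
            p = 1.0 / (1.0 + math.exp(-eta))
            expected += math.log(p if yi == 1 else 1 - p)
        for c in coefs:
            expected += math.log(1.0 / (math.pi * 2.5 * (1 + (c / 2.5) ** 2)))
        assert log_posterior(coefs, y, design, 2.5) == pytest.approx(expected, rel=1e-10)

    def test_nonfinite_coefs_rejected(self):
        with pytest.raises(ValueError):
            log_posterior(np.array([np.inf, 0, 0]), np.array([1.0]), np.eye(3)[:1], 2.5)


class TestConfig:
    def test_retained_draw_count_formula(self):
        cfg = CoocConfig(iterations=20_000, burn_in=2_000, thin=10)
        assert cfg.n_retained == 1800
        assert CoocConfig(iterations=105, burn_in=5, thin=7).n_retained == 14

    def test_reference_config_gives_2900_draws(self):
        assert CoocConfig.reference().n_retained == 2900

    @pytest.mark.parametrize(
        "kw",
        [
            {"burn_in": 30_000},
            {"thin": 0},
            {"prior_scale": 0.0},
            {"proposal_sd": 0.0},
            {"residual_variance": 2.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            CoocConfig(**kw)


class TestSampler:
    def test_deterministic_under_seed(self):
        survey = simulate_survey(reference_survey_spec(seed=2))
        cfg = CoocConfig(iterations=3000, burn_in=500, thin=5, seed=9)
        c1, c2 = mcmc_fit(survey, cfg), mcmc_fit(survey, cfg)
        assert np.array_equal(c1.samples, c2.samples)
        assert c1.acceptance_rate == c2.acceptance_rate

    def test_retained_draws_match_config(self):
        survey = simulate_survey(reference_survey_spec(seed=2))
        cfg = CoocConfig(iterations=3100, burn_in=600, thin=7, seed=1)
        chains = mcmc_fit(survey, cfg)
        assert chains.samples.shape[0] == (3100 - 600) // 7

    def test_posterior_mean_matches_quadrature_oracle(self):
        # 4 rows, one category, 1 success: integrate the posterior numerically
        survey = make_survey(["none"] * 4, [1, 0, 0, 0])
        cfg = CoocConfig(iterations=80_000, burn_in=5_000, thin=5, seed=4)
        chains = mcmc_fit(survey, cfg)
        draws = chains.coef_draws("prey", "none")

        w = np.linspace(-40, 40, 200_001)
        loglik = w - 4 * np.logaddexp(0.0, w)  # k=1, n=4
        logprior = -np.log1p((w / 2.5) ** 2)
        dens = np.exp(loglik + logprior - (loglik + logprior).max())
        dens /= np.trapezoid(dens, w)
        mean_oracle = np.trapezoid(w * dens, w)

        import arviz as az

        mc_se = draws.std(ddof=1) / math.sqrt(float(az.ess(draws)))
        assert abs(draws.mean() - mean_oracle) < 3 * mc_se

    def test_recovery_of_presence_probabilities(self):
        spec = SurveyGenSpec(
            n_heads=600,
            category_probs=(1 / 3, 1 / 3, 1 / 3),
            presence_probs={"prey": (0.6, 0.25, 0.25)},
            seed=42,
        )
        chains = mcmc_fit(simulate_survey(spec), CoocConfig(seed=0))
        for cat, truth in zip(CATEGORIES, (0.6, 0.25, 0.25)):
            pred = posterior_predict(chains, "prey", cat)
            assert abs(pred.point - truth) < 0.05
            assert pred.lower < truth < pred.upper

    def test_complete_separation_stays_finite(self):
        # 'large' heads all lack prey: unpenalised MLE would be -infinity
        cats = ["none"] * 8 + ["small"] * 6 + ["large"] * 6
        pres = [1, 1, 0, 1, 0, 1, 1, 0] + [1, 0, 0, 1, 0, 0] + [0] * 6
        chains = mcmc_fit(
            make_survey(cats, pres), CoocConfig(iterations=40_000, burn_in=4_000, seed=3)
        )
        pred = posterior_predict(chains, "prey", "large")
        assert np.isfinite(chains.samples).all()
        assert 0.0 < pred.point < 1.0
        assert pred.upper < 1.0

    def test_shrinkage_monotone_in_prior_scale(self):
        cats = ["none"] * 10 + ["large"] * 10
        pres = [1, 0, 1, 1, 0, 1, 0, 1, 1, 0] + [0] * 10
        medians = []
        for scale in (10.0, 2.5, 1.0, 0.5):
            cfg = CoocConfig(
                iterations=60_000, burn_in=5_000, thin=10, prior_scale=scale, seed=8
            )
            chains = mcmc_fit(make_survey(cats, pres), cfg)
            medians.append(posterior_predict(chains, "prey", "large").point)
        # tighter prior pulls the separated category's probability toward 0.5
        assert all(m2 > m1 for m1, m2 in zip(medians, medians[1:]))
        assert all(0.0 < m < 0.5 for m in medians)

    def test_unknown_category_rejected(self):
        est = CooccurrenceMCMC(iterations=100, burn_in=10, thin=1)
        with pytest.raises(ValueError):
            est.fit(np.array(["none", "medium"]), np.array([0, 1]))

    def test_multi_species_columns_named_from_frame(self):
        survey = simulate_survey(reference_survey_spec(seed=6))
        chains = mcmc_fit(survey, CoocConfig(iterations=2000, burn_in=200, thin=5))
        assert chains.species == ("chromis", "dascyllus")
        table = predictions_table(chains)
        assert len(table) == 6  # 2 species x 3 categories


class TestPosteriorPredict:
    def _constant_chains(self, value=0.0, n=100):
        cfg = CoocConfig(iterations=n * 10 + 100, burn_in=100, thin=10, seed=0)
        samples = np.full((cfg.n_retained, 1, 3), value)
        return PosteriorChains(
            samples=samples,
            species=("prey",),
            categories=CATEGORIES,
            acceptance_rate=0.3,
            config=cfg,
        )

    def test_degenerate_chain_gives_half_and_zero_width(self):
        pred = posterior_predict(self._constant_chains(0.0), "prey", "none")
        assert pred.point == pytest.approx(0.5)
        assert pred.upper - pred.lower == pytest.approx(0.0)

    def test_quantile_ordering_everywhere(self):
        survey = simulate_survey(reference_survey_spec(seed=1))
        chains = mcmc_fit(survey, CoocConfig(iterations=4000, burn_in=400, thin=4))
        for sp in chains.species:
            for cat in CATEGORIES:
                pred = posterior_predict(chains, sp, cat)
                assert 0.0 <= pred.lower <= pred.point <= pred.upper <= 1.0

    def test_unknown_labels_rejected(self):
        chains = self._constant_chains()
        with pytest.raises(KeyError):
            posterior_predict(chains, "nope", "none")
        with pytest.raises(KeyError):
            posterior_predict(chains, "prey", "medium")


class TestDiagnostics:
    def test_ess_close_to_length_for_iid_chain(self, rng):
        cfg = CoocConfig(iterations=20_100, burn_in=100, thin=10, seed=0)
        n = cfg.n_retained
        samples = rng.normal(size=(n, 1, 3))
        chains = PosteriorChains(
            samples=samples,
            species=("prey",),
            categories=CATEGORIES,
            acceptance_rate=0.3,
            config=cfg,
        )
        diag = chain_diagnostics(chains)
        assert ((diag["ess"] > 0.7 * n) & (diag["ess"] < 1.3 * n)).all()
        assert (diag["geweke_z"].abs() < 3).all()
        assert not diag["degenerate"].any()

    def test_constant_chain_flagged(self):
        cfg = CoocConfig(iterations=1100, burn_in=100, thin=10, seed=0)
        samples = np.zeros((cfg.n_retained, 1, 3))
        chains = PosteriorChains(
            samples=samples,
            species=("prey",),
            categories=CATEGORIES,
            acceptance_rate=0.3,
            config=cfg,
        )
        diag = chain_diagnostics(chains)
        assert diag["degenerate"].all()
        assert diag["ess"].isna().all()

    def test_too_short_chain_rejected(self):
        cfg = CoocConfig(iterations=150, burn_in=100, thin=10, seed=0)
        chains = PosteriorChains(
            samples=np.zeros((cfg.n_retained, 1, 3)),
            species=("prey",),
            categories=CATEGORIES,
            acceptance_rate=0.3,
            config=cfg,
        )
        with pytest.raises(ValueError):
            chain_diagnostics(chains)

    def test_geweke_calibrated_over_seeds(self):
        # on a well-mixed sampler the first/last-segment z-score should be
        # within +/-3 for essentially all runs
        spec = SurveyGenSpec(
            n_heads=100,
            category_probs=(0.5, 0.3, 0.2),
            presence_probs={"prey": (0.6, 0.3, 0.3)},
            seed=0,
        )
        ok = 0
        runs = 20
        for s in range(runs):
            survey = simulate_survey(
                SurveyGenSpec(
                    n_heads=spec.n_heads,
                    category_probs=spec.category_probs,
                    presence_probs=spec.presence_probs,
                    seed=s,
                )
            )
            cfg = CoocConfig(iterations=6000, burn_in=1000, thin=2, seed=100 + s)
            diag = chain_diagnostics(mcmc_fit(survey, cfg))
            ok += int((diag["geweke_z"].abs() < 3).all())
        assert ok >= 0.95 * runs
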