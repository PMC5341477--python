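"""Usual-intake model: transform, weighted mixed-model fitting, parameter
recovery against generator truth, and the back-transformed distribution."""
import numpy as np
import pandas as pd
import pytest

from snacksub import (NutrientTruth, fit_amount_model, fit_episodic_model,
                      population_mean, simulate_intakes, truth_summary,
                      usual_distribution)
from snacksub.usual_intake import (LAMBDA_GRID, boxcox, inv_boxcox,
                                   usual_amounts)


class TestTransform:
    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 1.0])
    def test_round_trip(self, lam):
        y = np.array([0.5, 1.0, 10.0, 250.0])
        assert inv_boxcox(boxcox(y, lam), lam) == pytest.approx(y, rel=1e-12)

    def test_out_of_domain_truncates_to_zero(self):
        assert inv_boxcox(np.array([-10.0]), 0.5)[0] == 0.0


class TestAmountModelRecovery:
    def test_identity_lambda_parameter_recovery(self):
        """Simulated truth (lam=1, b0=10, su=2, se=1, n=2000) is recovered
        within 5% (intercept, sigma_e) and 10% (sigma_u)."""
        truth = NutrientTruth("x", lam=1.0, mu=10.0, sigma_u=2.0, sigma_e=1.0,
                              beta_weekend=0.5, beta_sequence=-0.2)
        df = simulate_intakes(truth, 2000, seed=101, weight_sigma=0.3)
        m = fit_amount_model(df, lambda_grid=[1.0])
        assert m.beta["intercept"] == pytest.approx(10.0, rel=0.05)
        assert m.sigma_e == pytest.approx(1.0, rel=0.05)
        assert m.sigma_u == pytest.approx(2.0, rel=0.10)
        assert m.beta["weekend"] == pytest.approx(0.5, abs=0.2)

    def test_lambda_selected_near_truth(self):
        """Profile likelihood over the grid picks lambda within +-0.1."""
        truth = NutrientTruth("x", lam=0.5, mu=25.0, sigma_u=2.0, sigma_e=3.0)
        df = simulate_intakes(truth, 5000, seed=102)
        m = fit_amount_model(df)
        assert abs(m.lam - 0.5) <= 0.1

    def test_zero_between_person_variance(self):
        truth = NutrientTruth("x", lam=1.0, mu=10.0, sigma_u=0.0, sigma_e=1.0)
        df = simulate_intakes(truth, 1500, seed=103)
        m = fit_amount_model(df, lambda_grid=[1.0])
        assert m.sigma_u < 0.15

    def test_single_recall_only_unidentifiable(self):
        truth = NutrientTruth("x", lam=1.0, mu=10.0, sigma_u=1.0, sigma_e=1.0)
        df = simulate_intakes(truth, 200, seed=104, p_two_recalls=0.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_amount_model(df, lambda_grid=[1.0])

    def test_negative_intake_rejected(self):
        df = pd.DataFrame({"person_id": ["a", "a"], "intake": [1.0, -1.0],
                           "weekend": [0, 0], "sequence": [0, 1],
                           "weight": [1.0, 1.0]})
        with pytest.raises(ValueError, match="negative"):
            fit_amount_model(df)

    def test_unweighted_fit_matches_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM on equal-weight data."""
        import statsmodels.formula.api as smf
        truth = NutrientTruth("x", lam=1.0, mu=10.0, sigma_u=1.5, sigma_e=1.0,
                              beta_weekend=0.4)
        df = simulate_intakes(truth, 800, seed=105)
        m = fit_amount_model(df, lambda_grid=[1.0])
        sm_df = df.assign(z=boxcox(df["intake"].to_numpy(), 1.0))
        fit = smf.mixedlm("z ~ weekend + sequence", sm_df,
                          groups=sm_df["person_id"]).fit(reml=False)
        assert m.beta["intercept"] == pytest.approx(fit.params["Intercept"],
                                                    abs=0.02)
        assert m.beta["weekend"] == pytest.approx(fit.params["weekend"],
                                                  abs=0.02)
        assert m.sigma_u**2 == pytest.approx(float(fit.cov_re.iloc[0, 0]),
                                             rel=0.05, abs=0.02)
        assert m.sigma_e**2 == pytest.approx(fit.scale, rel=0.05)


class TestUsualDistribution:
    def _fit(self, truth, n=2000, seed=201, grid=None):
        df = simulate_intakes(truth, n, seed=seed)
        return fit_amount_model(df, lambda_grid=grid or [truth.lam])

    def test_identity_lambda_closed_form(self):
        """With lam=1 and no covariates, T(u) = 1 + b0 + u exactly."""
        truth = NutrientTruth("x", lam=1.0, mu=99.0, sigma_u=5.0, sigma_e=2.0)
        m = self._fit(truth)
        u = np.array([-5.0, 0.0, 5.0])
        t, _ = usual_amounts(m, u)
        expected = 1.0 + m.beta["intercept"] + (2 / 7) * m.beta["weekend"] + u
        assert t == pytest.approx(expected, rel=1e-9)

    def test_shrinkage_usual_sd_below_day_sd(self):
        truth = NutrientTruth("x", lam=0.5, mu=25.0, sigma_u=2.0, sigma_e=3.0)
        df = simulate_intakes(truth, 2000, seed=202)
        m = fit_amount_model(df, lambda_grid=[0.5])
        dist = usual_distribution(m, seed=0)
        day_sd = df["intake"].std()
        usual_sd = dist.percentiles.std()  # proxy; true SD via draws below
        assert np.percentile(dist.percentiles, 97) - \
            np.percentile(dist.percentiles, 3) < 2 * 3.5 * day_sd
        draws_sd = (dist.percentiles[74] - dist.percentiles[24]) / 1.349
        assert draws_sd < day_sd

    def test_percentiles_consistent_with_threshold_percents(self):
        truth = NutrientTruth("x", lam=0.5, mu=25.0, sigma_u=2.0, sigma_e=3.0)
        m = self._fit(truth)
        probe = usual_distribution(m, seed=3)
        c = float(probe.percentiles[49])  # the median
        dist = usual_distribution(m, seed=3, thresholds_below=(c,),
                                  thresholds_above=(c,))
        assert dist.pct_below[c] + dist.pct_above[c] == pytest.approx(
            100.0, abs=0.01)
        assert np.all(np.diff(dist.percentiles) >= -1e-9)
        assert dist.pct_below[c] == pytest.approx(50.0, abs=1.5)

    def test_quadrature_converges(self):
        """9- vs 21-point Gauss-Hermite agree within 0.1%."""
        truth = NutrientTruth("x", lam=0.25, mu=28.0, sigma_u=2.0, sigma_e=2.5)
        m = self._fit(truth)
        d9 = usual_distribution(m, seed=4, quad_points=9)
        d21 = usual_distribution(m, seed=4, quad_points=21)
        assert d9.mean == pytest.approx(d21.mean, rel=1e-3)
        assert d9.percentiles == pytest.approx(d21.percentiles, rel=1e-3)

    def test_quarter_power_vs_brute_force_threshold(self):
        """Percent-below from quadrature draws matches a brute-force
        double Monte-Carlo within 0.3 points."""
        truth = NutrientTruth("x", lam=0.25, mu=28.0, sigma_u=2.0, sigma_e=2.5)
        m = self._fit(truth, n=4000, seed=205)
        c = float(inv_boxcox(np.array([26.5]), 0.25)[0])
        dist = usual_distribution(m, n_draws=200_000, seed=5,
                                  thresholds_below=(c,))
        rng = np.random.default_rng(6)
        hits = 0
        n_u, n_eps = 200_000, 500
        for _ in range(10):
            u = rng.normal(0, m.sigma_u, n_u // 10)
            eps = rng.normal(0, m.sigma_e, (n_u // 10, n_eps))
            z = m.beta["intercept"] + (2 / 7) * m.beta["weekend"]
            # same reference point: mixture mean approximated by the small
            # weekend effect folded into the intercept (fit has ~0 effect)
            t = inv_boxcox(z + u[:, None] + eps, 0.25).mean(axis=1)
            hits += np.sum(t < c)
        pct_mc = 100.0 * hits / n_u
        assert dist.pct_below[c] == pytest.approx(pct_mc, abs=0.3)


class TestEpisodicModel:
    def test_requires_zero_days(self):
        truth = NutrientTruth("x", lam=1.0, mu=10.0, sigma_u=1.0, sigma_e=1.0)
        df = simulate_intakes(truth, 100, seed=301)
        with pytest.raises(ValueError, match="ubiquitous"):
            fit_episodic_model(df)

    def test_requires_positive_days(self):
        df = pd.DataFrame({"person_id": list("aabb"), "intake": [0.0] * 4,
                           "weekend": [0] * 4, "sequence": [0, 1, 0, 1],
                           "weight": [1.0] * 4})
        with pytest.raises(ValueError, match="positive"):
            fit_episodic_model(df)

    def test_homogeneous_half_probability_recovery(self):
        """Truth p=0.5, amount mean 11 (lam=1, mu=10): usual mean ~5.5
        recovered within 5% at n=2000."""
        truth = NutrientTruth("wg", lam=1.0, mu=10.0, sigma_u=2.0,
                              sigma_e=1.0, prob_intercept=0.0,
                              prob_sigma_u=0.0)
        df = simulate_intakes(truth, 2000, seed=302)
        m = fit_episodic_model(df, lambda_grid=[1.0])
        dist = usual_distribution(m, seed=7)
        true_mean = truth_summary({"wg": truth}).loc[0, "usual_mean"]
        assert dist.mean == pytest.approx(true_mean, rel=0.05)

    def test_probability_heterogeneity_recovered(self):
        """Positive person-level probability SD is detected and recovered
        within 25%."""
        truth = NutrientTruth("wg", lam=1.0, mu=10.0, sigma_u=1.0,
                              sigma_e=1.0, prob_intercept=0.3,
                              prob_sigma_u=1.0)
        df = simulate_intakes(truth, 5000, seed=303)
        m = fit_episodic_model(df, lambda_grid=[1.0])
        assert m.prob_sigma_u > 0
        assert m.prob_sigma_u == pytest.approx(1.0, rel=0.25)


class TestPopulationMean:
    def test_constant_intake(self, small_study):
        from snacksub import build_brr_weights
        _, persons, _, _ = small_study
        day = pd.DataFrame({"person_id": persons["person_id"], "intake": 7.5})
        scheme = build_brr_weights(persons)
        mean, se = population_mean(day, persons, scheme)
        assert mean == pytest.approx(7.5, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_recovers_truth_within_brr_ses(self):
        from snacksub import build_brr_weights
        truth = NutrientTruth("na", lam=1.0, mu=3499.0, sigma_u=800.0,
                              sigma_e=500.0)
        df = simulate_intakes(truth, 2000, seed=304, weight_sigma=0.3)
        n, n_strata = 2000, 16
        persons = pd.DataFrame({
            "person_id": sorted(df["person_id"].unique()),
            "survey_weight": df.groupby("person_id")["weight"].first()
                               .sort_index().to_numpy(),
            "stratum_id": [f"s{i % n_strata:02d}" for i in range(n)],
            "psu_id": [f"s{i % n_strata:02d}_u{(i // n_strata) % 2}"
                       for i in range(n)],
        })
        scheme = build_brr_weights(persons)
        mean, se = population_mean(df, persons, scheme)
        assert abs(mean - 3500.0) < 3 * se
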