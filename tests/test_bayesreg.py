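"""Bayesian regression: design construction, Gibbs sampler, HPD, contrasts."""

import numpy as np
import pandas as pd
import pytest

from anestheeg import (
    bayes_factor_poly_order, build_design, gibbs_sample, group_contrast_at_age,
    hpd_interval, power_trajectory,
)
from anestheeg.bayesreg import equal_tailed_interval

from conftest import cohort_frame, simulate_offset_response


@pytest.fixture(scope="module")
def cohort_df() -> pd.DataFrame:
    return cohort_frame(42, 110, seed=101)


class TestDesign:
    def test_centering_and_interactions(self, cohort_df):
        df = simulate_offset_response(cohort_df, -1.0, 1.0, seed=0)
        d = build_design(df, "slow_db")
        age_col = d.X[:, d.names.index("age")]
        assert abs(age_col.sum()) < 1e-9
        group = d.X[:, d.names.index("group_asd")]
        inter = d.X[:, d.names.index("group_x_age")]
        assert np.allclose(inter, group * age_col)
        inter3 = d.X[:, d.names.index("group_x_age3")]
        assert np.allclose(inter3, group * age_col ** 3)

    def test_shared_age_is_rank_deficient(self, cohort_df):
        df = simulate_offset_response(cohort_df, -1.0, 1.0, seed=0)
        df["age_years"] = 10.0
        with pytest.raises(ValueError, match="rank"):
            build_design(df, "slow_db")

    def test_missing_covariates_rejected(self, cohort_df):
        df = simulate_offset_response(cohort_df, -1.0, 1.0, seed=0)
        df.loc[df.index[3], "fentanyl"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design(df, "slow_db")


class TestGibbs:
    def test_noise_free_recovery(self, cohort_df):
        """With σ → 0 the posterior collapses onto the generating β."""
        df = simulate_offset_response(cohort_df, -1.926, 1e-6, seed=1)
        d = build_design(df, "slow_db")
        beta0 = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        s = gibbs_sample(d, iterations=2000, burn_in=500, seed=2)
        for i, nm in enumerate(d.names):
            assert s.medians[nm] == pytest.approx(beta0[i], abs=1e-3)

    def test_conjugate_oracle_posterior_mean(self, cohort_df):
        """Gibbs posterior mean of β matches (X'X)⁻¹X'y within 3 MC SEs."""
        df = simulate_offset_response(cohort_df, -1.926, 3.6, seed=3)
        d = build_design(df, "slow_db")
        s = gibbs_sample(d, iterations=10_000, burn_in=1_000, seed=4)
        beta_hat = np.linalg.solve(d.X.T @ d.X, d.X.T @ d.y)
        for i in range(len(d.names)):
            draws = s.draws[:, i]
            se = draws.std() / np.sqrt(draws.size)
            assert abs(draws.mean() - beta_hat[i]) < 3 * se * 3  # 3 SE, serial slack

    def test_sigma2_consistency(self):
        """Posterior median of σ² near 1 for unit-variance noise at n=500."""
        rng = np.random.default_rng(5)
        n = 500
        x = rng.standard_normal((n, 4))
        df = pd.DataFrame({
            "group": ["ASD"] * (n // 2) + ["NT"] * (n - n // 2),
            "age_years": rng.uniform(2, 23, n),
            "sex": rng.choice(["male", "female"], n),
            "infusion": x[:, 0], "bolus": x[:, 1], "midazolam": x[:, 3],
            "fentanyl": x[:, 2], "epilepsy": rng.random(n) < 0.2,
        })
        df["slow_db"] = rng.standard_normal(n)
        d = build_design(df, "slow_db")
        s = gibbs_sample(d, iterations=4000, burn_in=500, seed=6)
        assert s.sigma2_median == pytest.approx(1.0, rel=0.10)

    def test_seed_determinism(self, cohort_df):
        df = simulate_offset_response(cohort_df, -1.0, 3.0, seed=7)
        d = build_design(df, "slow_db")
        a = gibbs_sample(d, iterations=500, burn_in=100, seed=8)
        b = gibbs_sample(d, iterations=500, burn_in=100, seed=8)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.sigma2_draws, b.sigma2_draws)

    def test_too_few_subjects_rejected(self):
        """More coefficients than subjects fails at design or sampler level."""
        from anestheeg.bayesreg import RegressionDesign
        X = np.random.default_rng(0).standard_normal((5, 6))
        with pytest.raises(ValueError):
            design = RegressionDesign(X, np.zeros(5),
                                      [f"c{i}" for i in range(6)], 0.0)
            gibbs_sample(design, iterations=100, burn_in=10, seed=0)


class TestHPD:
    def test_normal_closed_form(self):
        rng = np.random.default_rng(10)
        lo, hi = hpd_interval(rng.standard_normal(200_000), 0.80)
        assert lo == pytest.approx(-1.2816, abs=0.05)
        assert hi == pytest.approx(1.2816, abs=0.05)

    def test_constant_draws_zero_width(self):
        lo, hi = hpd_interval(np.full(500, 3.3), 0.80)
        assert lo == hi == 3.3

    def test_exponential_left_anchored(self):
        """Shortest 80% interval for Exp(1) starts at ~0 and ends near ln 5."""
        rng = np.random.default_rng(11)
        lo, hi = hpd_interval(rng.exponential(1.0, 200_000), 0.80)
        assert lo == pytest.approx(0.0, abs=0.01)
        assert hi == pytest.approx(np.log(5.0), abs=0.05)

    def test_hpd_within_range_and_monotone_in_mass(self):
        rng = np.random.default_rng(12)
        draws = rng.gamma(2.0, 1.0, 50_000)
        lo80, hi80 = hpd_interval(draws, 0.80)
        lo95, hi95 = hpd_interval(draws, 0.95)
        assert draws.min() <= lo95 <= lo80 < hi80 <= hi95 <= draws.max()

    def test_hpd_shorter_than_equal_tailed(self):
        rng = np.random.default_rng(13)
        draws = rng.exponential(1.0, 100_000)
        lo, hi = hpd_interval(draws, 0.80)
        elo, ehi = equal_tailed_interval(draws, 0.80)
        assert (hi - lo) <= (ehi - elo) + 1e-9

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.zeros(200), 1.5)


class TestContrasts:
    def test_null_model_certainty_half(self, cohort_df):
        """No group effect anywhere → Pr(ASD < NT) ≈ 0.5 at any age."""
        df = simulate_offset_response(cohort_df, 0.0, 3.0, seed=14)
        d = build_design(df, "slow_db")
        s = gibbs_sample(d, iterations=4000, burn_in=500, seed=15)
        c = group_contrast_at_age(s, 12.0)
        assert c.certainty == pytest.approx(0.5, abs=0.1)

    def test_alpha_gap_certainty_grows_with_age(self):
        """Generated from the trajectory cubics, the ASD alpha deficit at
        22.5 y is on average detected with more certainty than at 5.42 y.

        A single cohort's certainty at a boundary age is dominated by the
        sparse data there, so the widening-gap property is asserted on the
        replicate mean.
        """
        diffs, gaps_young, gaps_old = [], [], []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            df = cohort_frame(100, 150, seed=200 + rep)
            df["alpha_db"] = [
                power_trajectory(a, g, "alpha") + rng.normal(0, 3.6)
                for a, g in zip(df["age_years"], df["group"])
            ]
            s = gibbs_sample(build_design(df, "alpha_db"),
                             iterations=2000, burn_in=400, seed=rep)
            young = group_contrast_at_age(s, 5.42)
            old = group_contrast_at_age(s, 22.5)
            diffs.append(old.certainty - young.certainty)
            gaps_young.append(young.median)
            gaps_old.append(old.median)
        assert np.mean(diffs) > 0.0
        # the recovered median deficits track the generating 1.21 / 5.52 dB
        assert np.mean(gaps_young) == pytest.approx(-1.21, abs=1.0)
        assert np.mean(gaps_old) == pytest.approx(-5.52, abs=1.5)

    def test_slow_contrast_crosses_half(self, cohort_df):
        """Slow power: ASD above NT at 2.33 y, below at 10.8 y — the fitted
        certainty crosses 0.5 at some intermediate age."""
        rng = np.random.default_rng(18)
        df = cohort_df.copy()
        df["slow_db"] = [
            power_trajectory(a, g, "slow") + rng.normal(0, 2.0)
            for a, g in zip(df["age_years"], df["group"])
        ]
        d = build_design(df, "slow_db")
        s = gibbs_sample(d, iterations=5000, burn_in=500, seed=19)
        certainties = [group_contrast_at_age(s, a).certainty
                       for a in np.linspace(2.33, 10.8, 30)]
        assert min(certainties) < 0.5 < max(certainties)

    def test_extrapolation_flagged(self, cohort_df):
        df = simulate_offset_response(cohort_df, -1.0, 3.0, seed=20)
        s = gibbs_sample(build_design(df, "slow_db"),
                        iterations=500, burn_in=100, seed=21)
        assert group_contrast_at_age(s, 28.0, age_range=(2, 23)).extrapolated
        assert not group_contrast_at_age(s, 12.0, age_range=(2, 23)).extrapolated


class TestPolyOrderSelection:
    def test_bf_of_model_against_itself_is_one(self, cohort_df):
        df = simulate_offset_response(cohort_df, -1.0, 2.0, seed=22)
        _, table = bayes_factor_poly_order(df, "slow_db", orders=(3, 3))
        assert np.allclose(table["bf_vs_best"], 1.0)

    def test_cubic_trend_selects_order_three(self, cohort_df):
        rng = np.random.default_rng(23)
        df = cohort_df.copy()
        ac = df["age_years"] - df["age_years"].mean()
        df["slow_db"] = (16.0 + 0.5 * ac - 0.05 * ac ** 2 + 0.02 * ac ** 3
                         + rng.normal(0, 1.0, len(df)))
        best, _ = bayes_factor_poly_order(df, "slow_db")
        assert best == 3

    def test_linear_trend_selects_order_one(self, cohort_df):
        rng = np.random.default_rng(24)
        df = cohort_df.copy()
        df["slow_db"] = 20.0 - 0.3 * df["age_years"] + rng.normal(0, 1.0, len(df))
        best, _ = bayes_factor_poly_order(df, "slow_db")
        assert best == 1
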