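"""ZIP, SHASH standardization, percentiles and curve-fit recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neomotif.stat_models import (
    FitError,
    fit_4pl,
    fit_shash,
    fit_weibull_growth,
    fit_zip,
    four_pl,
    normal_percentile,
    shash_standardize,
    standardize,
    weibull_growth,
    zscale_within_protein,
)


def zip_sample(lam, pi, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.poisson(lam, n)
    x[rng.random(n) < pi] = 0
    return x


class TestZip:
    def test_all_zero_sample_is_degenerate(self):
        fit = fit_zip([0] * 50)
        assert fit.degenerate and fit.pi_hat == 1.0

    def test_recovers_lambda_and_pi_at_scale(self):
        fit = fit_zip(zip_sample(5.0, 0.10, 100_000, seed=0))
        assert 4.9 <= fit.lambda_hat <= 5.1
        assert 0.08 <= fit.pi_hat <= 0.12
        assert fit.ci_lambda[0] <= 5.0 <= fit.ci_lambda[1]
        assert fit.ci_pi[0] <= 0.10 <= fit.ci_pi[1]

    def test_pure_poisson_yields_near_zero_pi(self):
        rng = np.random.default_rng(1)
        fit = fit_zip(rng.poisson(3.0, 100_000))
        assert fit.pi_hat <= 0.02
        assert abs(fit.lambda_hat - 3.0) < 0.05

    def test_agrees_with_statsmodels_oracle(self):
        # independent cross-check on a smaller sample
        import statsmodels.api as sm

        x = zip_sample(4.0, 0.25, 5000, seed=2)
        fit = fit_zip(x)
        zm = sm.ZeroInflatedPoisson(x, np.ones_like(x)).fit(disp=0)
        lam_sm = float(np.exp(zm.params[1]))
        pi_sm = float(stats.logistic.cdf(zm.params[0]))
        assert abs(fit.lambda_hat - lam_sm) < 0.02
        assert abs(fit.pi_hat - pi_sm) < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_zip([1, 2, -1] * 10)


class TestShash:
    def test_output_is_zero_mean_unit_variance(self):
        rng = np.random.default_rng(3)
        for sample in (rng.normal(2, 5, 5000), rng.lognormal(0, 1, 5000)):
            z = shash_standardize(sample)
            assert abs(z.mean()) < 0.02
            assert abs(z.var() - 1.0) < 0.05

    def test_normal_input_stays_symmetric(self):
        rng = np.random.default_rng(4)
        z = shash_standardize(rng.normal(size=10_000))
        assert abs(stats.skew(z)) < 0.05

    def test_lognormal_input_is_gaussianized(self):
        rng = np.random.default_rng(5)
        z = shash_standardize(rng.lognormal(0, 1, 10_000))
        assert abs(stats.skew(z)) < 0.1

    def test_transform_is_rank_preserving(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0, 1, 2000)
        z = shash_standardize(x)
        assert stats.spearmanr(x, z).statistic == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(2.0, 3.0, 4000)
        z1 = shash_standardize(x)
        z2 = shash_standardize(5.0 * x - 11.0)
        assert np.allclose(z1, z2, atol=5e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(FitError):
            fit_shash([2.0] * 100)

    def test_small_samples_use_rank_fallback(self):
        fit = fit_shash([1.0, 2.0, 5.0, 9.0])
        assert fit.method == "rank"
        z = standardize([1.0, 2.0, 5.0, 9.0], fit)
        assert abs(z.mean()) < 1e-12 and np.all(np.diff(z) > 0)


class TestZscaleWithinProtein:
    def make_table(self):
        rng = np.random.default_rng(8)
        rows = []
        for pid, shift in (("p1", 0.0), ("p2", 4.0)):
            for allele in ("A*02:01", "B*07:02"):
                for i in range(40):
                    rows.append((pid, allele, f"PEP{i}", rng.normal(8 + shift, 1)))
        return pd.DataFrame(rows, columns=["protein_id", "allele", "peptide", "ln_ic50"])

    def test_groupwise_unit_variance(self):
        out = zscale_within_protein(self.make_table())
        for _, grp in out.groupby(["protein_id", "allele"]):
            assert abs(grp.zscore.mean()) < 0.02
            assert abs(grp.zscore.var(ddof=0) - 1.0) < 0.05

    def test_location_shift_invariance_per_group(self):
        df = self.make_table()
        out1 = zscale_within_protein(df)
        df2 = df.copy()
        mask = df2.allele == "A*02:01"
        df2.loc[mask, "ln_ic50"] += 3.0
        out2 = zscale_within_protein(df2)
        assert np.allclose(
            out1.loc[mask, "zscore"], out2.loc[mask, "zscore"], atol=5e-3
        )

    def test_small_group_flagged_rank(self):
        df = self.make_table().groupby(["protein_id", "allele"]).head(5)
        out = zscale_within_protein(df)
        assert (out.zscore_method == "rank").all()


class TestPercentile:
    def test_reference_points(self):
        assert normal_percentile(0.0) == pytest.approx(50.0)
        assert normal_percentile(-1.0) == pytest.approx(15.87, abs=0.01)
        assert normal_percentile(-2.26) == pytest.approx(1.19, abs=0.01)

    def test_symmetry(self):
        for z in (-2.5, -0.3, 0.0, 1.7):
            assert normal_percentile(z) + normal_percentile(-z) == pytest.approx(100.0)


class TestCurveFits:
    def test_4pl_noiseless_recovery(self):
        x = np.linspace(-5, 3, 50)
        y = four_pl(x, 0.0, 1.0, -1.12, 2.0)
        fit = fit_4pl(x, y)
        assert fit.lower == pytest.approx(0.0, abs=1e-6)
        assert fit.upper == pytest.approx(1.0, abs=1e-6)
        assert fit.inflection_x == pytest.approx(-1.12, abs=1e-6)
        assert fit.hill == pytest.approx(2.0, abs=1e-6)

    def test_4pl_constant_input_rejected(self):
        with pytest.raises(FitError):
            fit_4pl(np.arange(10.0), np.ones(10))

    def test_4pl_inflection_at_half_maximum(self):
        x = np.linspace(-6, 6, 60)
        y = four_pl(x, 0.2, 0.9, 1.3, 1.1)
        fit = fit_4pl(x, y)
        half = 0.5 * (fit.lower + fit.upper)
        assert four_pl(np.array([fit.inflection_x]), fit.lower, fit.upper,
                       fit.inflection_x, fit.hill)[0] == pytest.approx(half, abs=1e-9)

    def test_weibull_noiseless_recovery(self):
        x = np.linspace(0, 10, 40)
        y = weibull_growth(x, 0.8, 1.5, 3.0)
        fit = fit_weibull_growth(x, y)
        assert fit.a == pytest.approx(0.8, abs=1e-6)
        assert fit.b == pytest.approx(1.5, abs=1e-6)
        assert fit.c == pytest.approx(3.0, abs=1e-6)

    def test_weibull_passes_through_origin(self):
        assert weibull_growth(np.array([0.0]), 0.7, 2.0, 4.0)[0] == 0.0

    def test_weibull_bounded_asymptote_for_fractions(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 8, 30)
        y = np.clip(weibull_growth(x, 0.97, 1.2, 2.0) + rng.normal(0, 0.05, 30), 0, 1)
        fit = fit_weibull_growth(x, y, bound_a=1.0)
        assert fit.a <= 1.0 + 1e-12
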