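"""Triplicate-bin mixture model: bin probabilities, counting, fitting
and the TP/FP curve."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from shapescreen.power import (PowerFit, bin_probabilities, bins_from_scores,
                               fit_power_model, tp_at_fp, tp_fp_curve,
                               truncated_normal_moments)
from shapescreen.simulate import simulate_triplicate_scores


class TestTruncatedMoments:
    @pytest.mark.parametrize("mean,sd", [(0.4, 0.15), (0.05, 0.3),
                                         (0.9, 0.5), (0.5, 1.0)])
    def test_matches_numerical_integration(self, mean, sd):
        m = truncated_normal_moments(mean, sd)
        z = stats.norm.cdf((1 - mean) / sd) - stats.norm.cdf((0 - mean) / sd)
        for k in range(4):
            num, _ = integrate.quad(
                lambda x: x ** k * stats.norm.pdf(x, mean, sd) / z, 0, 1)
            assert m[k] == pytest.approx(num, abs=1e-9)

    def test_zero_sd_is_point_mass(self):
        m = truncated_normal_moments(0.3, 0.0)
        np.testing.assert_allclose(m, [1, 0.3, 0.09, 0.027], atol=1e-12)


class TestBinProbabilities:
    def test_point_mass_reduces_to_binomial(self):
        p = bin_probabilities(h=1.0, alpha=0.0, beta0=0.4, sigma=0.0)
        assert p.hit[3] == pytest.approx(0.6 ** 3, abs=1e-12)
        assert p.hit[0] == pytest.approx(0.4 ** 3, abs=1e-12)

    def test_pure_negative_mixture(self):
        p = bin_probabilities(h=0.0, alpha=0.1, beta0=0.5, sigma=0.1)
        assert p.mixture[2] + p.mixture[3] == pytest.approx(
            3 * 0.01 * 0.9 + 0.001, abs=1e-12)

    @pytest.mark.parametrize("h,a,b,s", [(0.2, 0.05, 0.5, 0.2),
                                         (0.0, 0.3, 0.5, 0.0),
                                         (1.0, 0.5, 0.05, 0.4),
                                         (0.5, 0.9, 0.95, 0.1)])
    def test_probabilities_sum_to_one(self, h, a, b, s):
        p = bin_probabilities(h, a, b, s)
        assert p.hit.sum() == pytest.approx(1.0, abs=1e-10)
        assert p.negative.sum() == pytest.approx(1.0, abs=1e-10)
        assert p.mixture.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_monte_carlo_generative_process(self, rng):
        """Forward simulation of the stated generative model (truncated
        Gaussian FN rates for hits, binomial negatives)."""
        h, alpha, beta0, sigma = 0.2, 0.05, 0.5, 0.2
        n = 200000
        is_hit = rng.random(n) < h
        a_, b_ = (0 - beta0) / sigma, (1 - beta0) / sigma
        beta = stats.truncnorm.rvs(a_, b_, loc=beta0, scale=sigma,
                                   size=n, random_state=rng)
        p_above = np.where(is_hit, 1 - beta, alpha)
        times = rng.binomial(3, p_above)
        mc = np.bincount(times, minlength=4) / n
        model = bin_probabilities(h, alpha, beta0, sigma).mixture
        se = np.sqrt(model * (1 - model) / n)
        assert (np.abs(mc - model) < 3 * se + 1e-4).all()

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bin_probabilities(1.5, 0.1, 0.1, 0.1)
        with pytest.raises(ValueError):
            bin_probabilities(0.5, 0.1, 0.1, -0.1)


class TestBinsFromScores:
    def test_four_gene_example(self):
        scores = np.array([[4, 4, 4], [4, 4, 0], [4, 0, 0], [0, 0, 0]],
                          dtype=float)
        bins = bins_from_scores(scores, [3.0])
        row = bins.iloc[0]
        assert (row.n0, row.n1, row.n2, row.n3) == (1, 1, 1, 1)

    def test_threshold_below_all_scores(self):
        scores = np.full((5, 3), 2.0)
        row = bins_from_scores(scores, [1.0]).iloc[0]
        assert (row.n0, row.n3) == (0, 5)

    def test_matches_per_gene_recount(self, rng):
        scores = rng.normal(size=(500, 3)) * 2
        bins = bins_from_scores(scores, [0.5, 1.5, 2.5])
        for _, row in bins.iterrows():
            counts = np.zeros(4, dtype=int)
            for g in range(500):
                counts[int(np.sum(scores[g] > row["threshold"]))] += 1
            assert (row[["n0", "n1", "n2", "n3"]].to_numpy() ==
                    counts).all()

    def test_monotone_in_threshold(self, rng):
        scores = rng.normal(size=(300, 3))
        bins = bins_from_scores(scores, np.arange(0, 3, 0.25))
        assert bins["n3"].is_monotonic_decreasing
        assert bins["n0"].is_monotonic_increasing


def exact_bins(h, params, n=10 ** 6):
    rows = []
    for t, (a, b, s) in params.items():
        p = bin_probabilities(h, a, b, s).mixture
        rows.append({"threshold": t, "n0": p[0] * n, "n1": p[1] * n,
                     "n2": p[2] * n, "n3": p[3] * n, "total": n})
    return pd.DataFrame(rows)


class TestFitPowerModel:
    def test_noiseless_fit_reproduces_generating_model(self):
        """With bins generated exactly from the model the fit attains a
        ~zero residual and reproduces the generating bin probabilities;
        h is recovered up to the model's partial identifiability (the
        exact-fit set is an interval in h whose lower edge the
        parsimony tie-break reports)."""
        params = {1.5: (0.30, 0.2, 0.1), 2.5: (0.10, 0.3, 0.12),
                  3.0: (0.05, 0.4, 0.15), 3.5: (0.02, 0.5, 0.18),
                  4.5: (0.005, 0.65, 0.2)}
        h_true = 0.15
        fit = fit_power_model(exact_bins(h_true, params), seed=0)
        assert fit.sse < 1e-12
        assert fit.converged
        assert 0.10 <= fit.h <= 0.25
        for t, (a, b, s) in params.items():
            p = fit.params_at(t)
            model = bin_probabilities(fit.h, p.alpha, p.beta0,
                                      p.sigma).mixture
            generating = bin_probabilities(h_true, a, b, s).mixture
            np.testing.assert_allclose(model, generating, atol=1e-6)

    def test_recovers_parameters_from_simulated_screen(self):
        sim = simulate_triplicate_scores(10000, 0.15, 0.05, 0.4, 0.15,
                                         threshold=3.0, seed=11)
        bins = bins_from_scores(sim.scores, [2.0, 2.5, 3.0, 3.5, 4.0])
        fit = fit_power_model(bins, seed=1)
        p = fit.params_at(3.0)
        assert fit.h == pytest.approx(0.15, abs=0.05)
        assert p.alpha == pytest.approx(0.05, abs=0.02)
        assert p.beta0 == pytest.approx(0.4, abs=0.05)
        assert p.sigma == pytest.approx(0.15, abs=0.07)

    def test_null_screen_recovers_empirical_alpha(self):
        sim = simulate_triplicate_scores(8000, 0.0, 0.05, 0.4, 0.15,
                                         threshold=3.0, seed=2)
        bins = bins_from_scores(sim.scores, [2.5, 3.0, 3.5])
        fit = fit_power_model(bins, seed=2)
        assert fit.h <= 0.02
        empirical = float(np.mean(sim.scores > 3.0))
        assert fit.params_at(3.0).alpha == pytest.approx(empirical,
                                                         abs=0.01)

    def test_single_threshold_flagged_under_determined(self):
        params = {3.0: (0.05, 0.4, 0.15)}
        fit = fit_power_model(exact_bins(0.15, params), seed=0)
        assert fit.under_determined
        assert not fit.converged


class TestTpFpCurve:
    def make_fit(self, rows):
        table = pd.DataFrame(rows)
        return PowerFit(h=0.15, table=table, sse=0.0, converged=True,
                        under_determined=False, n_genes=1000)

    def test_band_arithmetic(self):
        fit = self.make_fit([{"threshold": 3.0, "alpha": 0.05,
                              "beta0": 0.5, "sigma": 0.1, "sse": 0.0}])
        curve = tp_fp_curve(fit)
        assert curve["tp_mean"].iloc[0] == pytest.approx(0.5)
        assert curve["tp_lo"].iloc[0] == pytest.approx(0.4)
        assert curve["tp_hi"].iloc[0] == pytest.approx(0.6)

    def test_zero_sigma_collapses_band(self):
        fit = self.make_fit([{"threshold": 3.0, "alpha": 0.05,
                              "beta0": 0.5, "sigma": 0.0, "sse": 0.0}])
        curve = tp_fp_curve(fit)
        assert curve["tp_lo"].iloc[0] == curve["tp_hi"].iloc[0]

    def test_tp_at_fp_interpolates(self):
        fit = self.make_fit([
            {"threshold": 2.0, "alpha": 0.2, "beta0": 0.2, "sigma": 0.1,
             "sse": 0.0},
            {"threshold": 3.0, "alpha": 0.0, "beta0": 0.6, "sigma": 0.1,
             "sse": 0.0}])
        assert tp_at_fp(fit, 0.1) == pytest.approx(0.6)

    def test_tp_at_fp_outside_range_rejected(self):
        fit = self.make_fit([{"threshold": 3.0, "alpha": 0.05,
                              "beta0": 0.5, "sigma": 0.1, "sse": 0.0}])
        with pytest.raises(ValueError, match="outside"):
            tp_at_fp(fit, 0.5)
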