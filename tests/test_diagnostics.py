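"""Normalization, moments, ANOVA diagnostics and partial normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapescreen.diagnostics import (anova_f, distribution_moments,
                                     normalize_distribution,
                                     partial_normalize,
                                     rescale_convergence_check)
from shapescreen.errors import DegenerateDistributionError


class TestNormalize:
    def test_three_point_example(self):
        out = normalize_distribution([2.0, 4.0, 6.0])
        expected = np.array([-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_idempotent(self, rng):
        v = rng.gamma(2, 1, 500)
        once = normalize_distribution(v)
        twice = normalize_distribution(once)
        np.testing.assert_allclose(once, twice, atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            normalize_distribution([5.0, 5.0, 5.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 100), st.floats(-100, 100))
    def test_affine_invariant(self, scale, offset):
        rng = np.random.default_rng(7)
        v = rng.normal(size=100)
        np.testing.assert_allclose(normalize_distribution(v),
                                   normalize_distribution(scale * v + offset),
                                   atol=1e-9)


class TestMoments:
    def test_symmetric_input_zero_skew(self):
        assert distribution_moments([-1.0, 0.0, 1.0]).skewness == \
            pytest.approx(0.0, abs=1e-12)

    def test_against_direct_central_moment_sums(self):
        v = np.array([0.0, 0.0, 0.0, 1.0])
        m = distribution_moments(v)
        c = v - v.mean()
        m2, m3, m4 = (np.mean(c ** k) for k in (2, 3, 4))
        assert m.mean == pytest.approx(0.25)
        assert m.variance == pytest.approx(m2)
        assert m.skewness == pytest.approx(m3 / m2 ** 1.5)
        assert m.kurtosis == pytest.approx(m4 / m2 ** 2)

    def test_shape_moments_affine_invariant(self, rng):
        v = rng.gamma(3, 2, 400)
        m1 = distribution_moments(v)
        m2 = distribution_moments(2.5 * v - 7.0)
        assert m1.skewness == pytest.approx(m2.skewness, abs=1e-9)
        assert m1.kurtosis == pytest.approx(m2.kurtosis, abs=1e-9)
        m3 = distribution_moments(normalize_distribution(v))
        assert m1.skewness == pytest.approx(m3.skewness, abs=1e-9)


class TestAnova:
    def test_equal_groups_give_zero(self):
        res = anova_f([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df_between == 1 and res.df_within == 4

    def test_degenerate_within_variance_flagged(self):
        res = anova_f([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert np.isnan(res.f_statistic)

    def test_small_groups_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res = anova_f([1, 2, 3, 4, 9], ["a", "a", "b", "b", "c"])
        assert res.df_between == 1

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_f([1, 2, 3], ["a", "a", "a"])

    def test_matches_sum_of_squares_oracle(self, rng):
        values = rng.normal(size=300)
        groups = np.repeat(np.arange(10), 30)
        res = anova_f(values, groups)
        grand = values.mean()
        ssb = sum(30 * (values[groups == g].mean() - grand) ** 2
                  for g in range(10))
        ssw = sum(((values[groups == g] - values[groups == g].mean()) ** 2)
                  .sum() for g in range(10))
        f = (ssb / 9) / (ssw / (300 - 10))
        assert res.f_statistic == pytest.approx(f, abs=1e-9)


class TestRescaleConvergence:
    def make_affine_wells(self, rng, offsets=True):
        base = rng.gamma(2, 1, 4000) + 1.0
        wells = {}
        # offsets comparable to the data range, so a log pre-transform
        # visibly warps the shape differently in each well
        for i, (a, b) in enumerate([(1.0, 0.0), (2.0, 10.0 if offsets else 0),
                                    (0.3, 5.0 if offsets else 0)]):
            wells[f"w{i}"] = a * base + b
        return wells

    def test_affine_wells_converge_without_transform(self, rng):
        wells = self.make_affine_wells(rng)
        table = rescale_convergence_check(wells, transform=("power", 1.0))
        # identical-up-to-affine wells differ only by float rounding, so
        # D collapses to at most a couple of ECDF steps (~1/n)
        assert (table["d_normalized"] <= 2 / 4000).all()

    def test_log_breaks_affine_equivalence_with_offsets(self, rng):
        wells = self.make_affine_wells(rng, offsets=True)
        table = rescale_convergence_check(wells, transform="log")
        assert (table["d_normalized"] <= 2 / 4000).all()
        assert (table["d_transformed"] > 0.05).any()

    def test_log_removes_pure_scale_differences(self, rng):
        wells = self.make_affine_wells(rng, offsets=False)
        table = rescale_convergence_check(wells, transform="log")
        # log turns a pure scale into a shift, which normalization
        # removes exactly (up to float rounding: a few ECDF steps)
        assert (table["d_transformed"] <= 2 / 4000).all()

    def test_log_of_nonpositive_values_names_wells(self):
        with pytest.raises(ValueError, match="w0"):
            rescale_convergence_check({"w0": np.array([-1.0, 2.0, 5.0]),
                                       "w1": np.array([1.0, 2.0, 3.0])},
                                      transform="log")


class TestPartialNormalize:
    def toy_slide(self, rng):
        wells, positions = {}, {}
        for r in range(1, 4):
            for c in range(1, 4):
                w = f"r{r}c{c}"
                wells[w] = rng.normal(loc=r * 2.0, scale=c, size=200)
                positions[w] = (r, c)
        return wells, positions

    def test_center_well_matches_neighbor_averages(self, rng):
        wells, positions = self.toy_slide(rng)
        out = partial_normalize(wells, positions, "r2c2")
        neighbors = [w for w in wells if w != "r2c2"]
        target_mean = np.mean([wells[w].mean() for w in neighbors])
        target_var = np.mean([wells[w].var() for w in neighbors])
        assert out.mean() == pytest.approx(target_mean, abs=1e-9)
        assert out.std() == pytest.approx(np.sqrt(target_var), abs=1e-9)

    def test_corner_well_uses_three_neighbors(self, rng):
        wells, positions = self.toy_slide(rng)
        out = partial_normalize(wells, positions, "r1c1")
        neighbors = ["r1c2", "r2c1", "r2c2"]
        assert out.mean() == pytest.approx(
            np.mean([wells[w].mean() for w in neighbors]), abs=1e-9)

    def test_unit_neighbors_reduce_to_plain_normalization(self, rng):
        wells, positions = self.toy_slide(rng)
        for w in wells:
            if w != "r2c2":
                wells[w] = normalize_distribution(wells[w])
        out = partial_normalize(wells, positions, "r2c2")
        np.testing.assert_allclose(out, normalize_distribution(wells["r2c2"]),
                                   atol=1e-9)

    def test_degenerate_neighbors_rejected(self):
        wells = {"r1c1": np.array([1.0, 2.0]), "r1c2": np.array([3.0, 3.0])}
        positions = {"r1c1": (1, 1), "r1c2": (1, 2)}
        with pytest.raises(DegenerateDistributionError):
            partial_normalize(wells, positions, "r1c1")
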