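import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnsmooth.core_data import ProbeSeries, Profile
from cnsmooth.segmentation import (
    PenaltyGrid,
    choose_k_lavielle,
    choose_k_penalty,
    flsa_norm_penalty,
    fused_lasso_1d,
    segment_dp,
    smooth_profile,
)
from tests.oracles import enumerate_best_rss, fused_lasso_kkt_residual


class TestSegmentDP:
    def test_single_segment_is_mean(self, rng):
        x = rng.normal(0, 1, 17)
        seg = segment_dp(x, 1)
        np.testing.assert_allclose(seg.fitted[0], np.full(17, x.mean()))

    def test_saturated_model_interpolates(self, rng):
        x = rng.choice(20, size=6, replace=False).astype(float)
        seg = segment_dp(x, 6)
        np.testing.assert_allclose(seg.fitted[5], x)
        assert seg.rss[5] == pytest.approx(0.0, abs=1e-12)

    def test_three_level_signal(self):
        # expected optimum verified by enumeration of all C(7,2) cut pairs
        x = np.array([0, 0, 0, 5, 5, 5, 2, 2], dtype=float)
        seg = segment_dp(x, 3)
        assert seg.rss[2] == pytest.approx(enumerate_best_rss(x, 3), abs=1e-12)
        assert seg.rss[2] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(seg.fitted[2], x)

    def test_rss_non_increasing(self, rng):
        x = rng.normal(0, 1, 30)
        seg = segment_dp(x, 10)
        assert np.all(np.diff(seg.rss) <= 1e-12)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(40):
            m = int(rng.integers(2, 13))
            kmax = int(rng.integers(1, min(5, m) + 1))
            x = rng.normal(0, 1, m)
            seg = segment_dp(x, kmax)
            for k in range(1, kmax + 1):
                assert seg.rss[k - 1] == pytest.approx(
                    enumerate_best_rss(x, k), abs=1e-9)

    def test_kmax_bounds_rejected(self):
        with pytest.raises(ValueError):
            segment_dp(np.zeros(3), 4)
        with pytest.raises(ValueError):
            segment_dp(np.zeros(3), 0)


class TestChooseK:
    def test_large_lambda_selects_one_segment(self, rng):
        x = rng.normal(0, 1, 25)
        seg = segment_dp(x, 5)
        assert choose_k_lavielle(seg, 25, lam=1e9) == 1

    def test_zero_lambda_smallest_k_at_min_rss(self):
        rss = np.array([5.0, 1.0, 1.0, 1.0])
        assert choose_k_lavielle(rss, m=10, lam=0.0) == 2
        assert choose_k_penalty(rss, beta=0.0) == 2

    def test_lavielle_worked_example(self):
        # criteria: 0.3*1+1.0=1.3, 0.3*2+0.2=0.8, 0.3*3+0.15=1.05
        assert choose_k_lavielle(np.array([10, 2, 1.5]), m=10, lam=0.3) == 2

    def test_penalty_worked_example(self):
        # criteria: 10, 3+2=5, 6+1.5=7.5
        assert choose_k_penalty(np.array([10, 2, 1.5]), beta=3.0) == 2

    def test_equivalence_beta_lambda_m(self, rng):
        for _ in range(50):
            kmax = int(rng.integers(1, 8))
            rss = np.sort(rng.uniform(0, 10, kmax))[::-1]
            m = int(rng.integers(2, 500))
            lam = float(rng.uniform(0, 2))
            assert choose_k_penalty(rss, lam * m) == choose_k_lavielle(rss, m, lam)

    def test_selected_k_non_increasing_in_lambda(self, rng):
        x = rng.normal(0, 1, 40) + np.repeat([0, 3, -1, 2], 10)
        seg = segment_dp(x, 10)
        lams = np.logspace(-6, 3, 60)
        ks = [choose_k_lavielle(seg, 40, lam) for lam in lams]
        assert np.all(np.diff(ks) <= 0)
        betas = lams * 40
        ks = [choose_k_penalty(seg, b) for b in betas]
        assert np.all(np.diff(ks) <= 0)


class TestFusedLasso:
    def test_zero_penalty_identity(self, rng):
        x = rng.normal(0, 1, 20)
        np.testing.assert_array_equal(fused_lasso_1d(x, 0.0), x)

    def test_saturation_to_mean(self, rng):
        x = rng.normal(0, 2, 35)
        out = fused_lasso_1d(x, 1e8)
        np.testing.assert_allclose(out, np.full(35, x.mean()), atol=1e-10)

    def test_two_point_worked_example(self):
        # stationarity solved by hand; cross-checked by grid search below
        np.testing.assert_allclose(fused_lasso_1d(np.array([0.0, 1.0]), 0.25),
                                   [0.25, 0.75])

    def test_two_point_grid_search_oracle(self):
        a = np.linspace(-0.5, 1.5, 801)
        A, B = np.meshgrid(a, a, indexing="ij")
        obj = 0.5 * (A ** 2 + (B - 1.0) ** 2) + 0.25 * np.abs(B - A)
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        np.testing.assert_allclose([a[i], a[j]], [0.25, 0.75], atol=2e-3)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fused_lasso_1d(np.zeros(3), -0.1)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=40),
           st.floats(0, 10))
    def test_kkt_conditions_hold(self, values, lam):
        x = np.asarray(values)
        out = fused_lasso_1d(x, lam)
        assert fused_lasso_kkt_residual(x, out, lam) <= 1e-8

    def test_breakpoint_count_non_increasing_in_penalty(self, rng):
        x = rng.normal(0, 0.3, 60) + np.repeat([0, 2, -1], 20)
        tol = 1e-9 * (1 + np.max(np.abs(x)))
        counts = []
        for lam in np.logspace(-3, 3, 30):
            out = fused_lasso_1d(x, lam)
            counts.append(int(np.sum(np.abs(np.diff(out)) > tol)))
        assert np.all(np.diff(counts) <= 0)


class TestFlsaNormPenalty:
    def test_zero(self):
        assert flsa_norm_penalty(0.0, 100, 1e8) == 0.0

    def test_worked_examples(self):
        assert flsa_norm_penalty(1.0, 100, 1e8) == pytest.approx(1.0)
        assert flsa_norm_penalty(2.0, 50, 1e6) == pytest.approx(100.0)

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            flsa_norm_penalty(1.0, 10, 0)


class TestPenaltyGrid:
    def test_rejects_decreasing(self):
        with pytest.raises(ValueError):
            PenaltyGrid(np.array([2.0, 1.0]))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            PenaltyGrid(np.array([-1.0, 1.0]))

    def test_defaults(self):
        grid = PenaltyGrid.default_for("cghseg.k")
        assert len(grid) == 100
        assert grid.values[0] == pytest.approx(1e-8)
        assert grid.values[-1] == pytest.approx(1e4)
        grid = PenaltyGrid.default_for("flsa")
        assert grid.values[0] == pytest.approx(1e-5)
        assert grid.values[-1] == pytest.approx(1e12)


def _random_profile(rng, m=50, chroms=("1",)):
    chromosomes = {}
    for chrom in chroms:
        positions = np.sort(rng.choice(10 ** 7, size=m, replace=False)) + 1
        signal = np.repeat(rng.normal(0, 1, 2), m - m // 2)[:m]
        chromosomes[chrom] = ProbeSeries(
            chrom, positions, signal + rng.normal(0, 0.3, m))
    return Profile(f"r{rng.integers(1e9)}", chromosomes)


class TestSmoothProfile:
    def test_single_probe_chromosome_never_breaks(self):
        profile = Profile("p", {"1": ProbeSeries("1", [100], [0.7])})
        for model in ("cghseg.k", "pelt.n", "flsa", "flsa.norm"):
            grid = PenaltyGrid(np.array([0.1, 10.0]))
            for fit in smooth_profile(profile, model, grid=grid, kmax=1):
                assert fit.total_breakpoints() == 0

    def test_unknown_model_rejected(self):
        profile = Profile("p", {"1": ProbeSeries("1", [100], [0.7])})
        with pytest.raises(ValueError, match="unknown model"):
            smooth_profile(profile, "dnacopy")

    def test_cghseg_pelt_identical_breakpoints(self, rng):
        grid = PenaltyGrid.default_for("cghseg.k", count=40)
        for _ in range(50):
            profile = _random_profile(rng, m=30)
            fits_a = smooth_profile(profile, "cghseg.k", grid=grid, kmax=10)
            fits_b = smooth_profile(profile, "pelt.n", grid=grid, kmax=10)
            for fa, fb in zip(fits_a, fits_b):
                np.testing.assert_array_equal(fa.breakpoints["1"],
                                              fb.breakpoints["1"])

    def test_noiseless_two_level_recovers_exact_midpoint(self):
        positions = np.array([100, 200, 300, 400, 500, 600])
        values = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        profile = Profile("p", {"1": ProbeSeries("1", positions, values)})
        grid = PenaltyGrid(np.array([1e-3]))  # intermediate penalty
        (fit,) = smooth_profile(profile, "cghseg.k", grid=grid, kmax=6)
        np.testing.assert_array_equal(fit.breakpoints["1"], [350.0])

    def test_breakpoints_tagged_by_chromosome(self, rng):
        profile = _random_profile(rng, m=40, chroms=("1", "2"))
        grid = PenaltyGrid(np.array([1e-4]))
        (fit,) = smooth_profile(profile, "cghseg.k", grid=grid, kmax=5)
        assert set(fit.breakpoints) == {"1", "2"}
        for chrom, series in profile.chromosomes.items():
            b = fit.breakpoints[chrom]
            assert np.all(b > series.positions[0])
            assert np.all(b < series.positions[-1])
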