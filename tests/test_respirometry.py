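"""Slope fitting, MO2 conversion, blank correction, SMR extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respiro.respirometry import (
    BlankSeries,
    blank_correct,
    compute_mo2,
    extract_smr,
    fit_o2_slope,
    summarize_metabolism,
)


class TestSlopeFit:
    def test_exact_linear_decline(self):
        t = np.arange(0, 900, 5.0)
        o2 = 8.0 - 0.05 * t / 60.0
        c = fit_o2_slope(t, o2)
        assert c.slope_mgL_per_min == pytest.approx(-0.05, abs=1e-14)
        assert c.r_squared == pytest.approx(1.0)
        assert c.n_points == t.size

    def test_constant_o2_zero_slope(self):
        t = np.arange(0, 100, 5.0)
        c = fit_o2_slope(t, np.full(t.size, 7.5))
        assert c.slope_mgL_per_min == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        t = np.arange(0, 870, 5.0)
        o2 = 8.0 - 0.05 * t / 60.0 + rng.normal(0, 0.01, t.size)
        c = fit_o2_slope(t, o2)
        # independent brute-force normal equations [n, St; St, Stt] b = [Sy, Sty]
        A = np.vstack([np.ones_like(t), t]).T
        coef = np.linalg.solve(A.T @ A, A.T @ o2)
        assert c.slope_mgL_per_min == pytest.approx(coef[1] * 60.0, abs=1e-12)

    def test_trimming_discards_leading_seconds(self):
        t = np.arange(0, 100, 5.0)
        o2 = 8.0 - 0.01 * t
        o2[:4] = 9.0  # corrupted mixing transient in the first 20 s
        c = fit_o2_slope(t, o2, trim_leading_s=30.0)
        assert c.slope_mgL_per_min == pytest.approx(-0.6, abs=1e-12)
        assert c.t_start == 30.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_o2_slope(np.array([0.0, 5.0]), np.array([8.0, 7.9]))

    def test_nonmonotone_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            fit_o2_slope(np.array([0.0, 5.0, 5.0, 10.0]), np.full(4, 8.0))


class TestComputeMo2:
    @pytest.mark.parametrize(
        "slope, vr, vf, expected",
        [(-0.05, 40.0, 2.0, 1.9), (0.0, 40.0, 2.0, 0.0), (-0.01, 40.0, 0.0, 0.4)],
    )
    def test_equation(self, slope, vr, vf, expected):
        assert compute_mo2(slope, vr, vf) == pytest.approx(expected, abs=1e-12)

    def test_fish_exceeding_chamber_rejected(self):
        with pytest.raises(ValueError, match="chamber"):
            compute_mo2(-0.05, 40.0, 40.0)


class TestBlankCorrection:
    def test_midpoint_interpolation(self):
        blanks = BlankSeries(
            pre_time_s=0.0, pre_rate=0.1, post_time_s=36000.0, post_rate=0.3
        )
        assert blank_correct(2.0, 18000.0, blanks) == pytest.approx(1.8)

    def test_equal_blanks_constant_subtraction(self):
        blanks = BlankSeries(
            pre_time_s=0.0, pre_rate=0.2, post_time_s=100.0, post_rate=0.2
        )
        for t in (-50.0, 0.0, 37.0, 100.0, 1e6):
            assert blank_correct(1.0, t, blanks) == pytest.approx(0.8)

    def test_clamped_outside_interval(self):
        blanks = BlankSeries(
            pre_time_s=100.0, pre_rate=0.1, post_time_s=200.0, post_rate=0.3
        )
        assert blanks.rate_at(0.0) == 0.1
        assert blanks.rate_at(1e9) == 0.3

    def test_overcorrection_goes_negative_not_clipped(self):
        blanks = BlankSeries(
            pre_time_s=0.0, pre_rate=0.5, post_time_s=10.0, post_rate=0.5
        )
        assert blank_correct(0.2, 5.0, blanks) == pytest.approx(-0.3)

    def test_single_blank_warns_and_is_constant(self):
        with pytest.warns(UserWarning, match="one blank"):
            blanks = BlankSeries(pre_time_s=0.0, pre_rate=0.15)
        assert blanks.rate_at(12345.0) == 0.15

    def test_no_blanks_error(self):
        with pytest.raises(ValueError, match="at least one"):
            BlankSeries()


class TestExtractSmr:
    def test_lowest_decile_of_twenty(self):
        smr, n_out = extract_smr(np.arange(1.0, 21.0))
        assert smr == pytest.approx(1.5)
        assert n_out == 0

    def test_all_equal(self):
        smr, n_out = extract_smr([5.0] * 12)
        assert smr == 5.0 and n_out == 0

    def test_single_spike_excluded_globally(self):
        # nineteen cycles at 5 plus one at 50: mean 7.25, sd 10.06, so the
        # spike sits beyond +2 sd and is screened out before the decile
        smr, n_out = extract_smr([5.0] * 19 + [50.0])
        assert smr == 5.0 and n_out == 1

    def test_subset_order_option(self):
        smr, n_out = extract_smr([5.0] * 19 + [50.0], outlier_order="subset")
        assert smr == 5.0 and n_out == 0

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            extract_smr([1.0])

    @given(
        values=st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2, max_size=40),
        scale=st.floats(min_value=0.01, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(deadline=None, max_examples=60)
    def test_permutation_invariant_and_scale_equivariant(self, values, scale, seed):
        x = np.array(values)
        smr, _ = extract_smr(x)
        rng = np.random.default_rng(seed)
        smr_perm, _ = extract_smr(rng.permutation(x))
        assert smr_perm == pytest.approx(smr, rel=1e-12)
        smr_scaled, _ = extract_smr(scale * x)
        assert smr_scaled == pytest.approx(scale * smr, rel=1e-9)


class TestSummarize:
    def test_scope_arithmetic(self):
        est = summarize_metabolism("f", smr=1.0, rmr=None, mmr=3.0)
        assert est.aerobic_scope == 2.0 and est.factorial_scope == 3.0
        assert est.flags == []

    def test_equal_smr_mmr_flagged(self):
        est = summarize_metabolism("f", smr=2.0, rmr=None, mmr=2.0)
        assert est.aerobic_scope == 0.0 and est.factorial_scope == 1.0
        assert "mmr_not_above_smr" in est.flags

    def test_ordered_rates_no_flag(self):
        est = summarize_metabolism("f", smr=1.0, rmr=1.35, mmr=1.7)
        assert est.factorial_scope == pytest.approx(1.7)
        assert est.flags == []
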