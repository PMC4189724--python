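import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnapipe import diffexpr
from srnapipe.diffexpr import (
    audic_claverie_p,
    audic_claverie_p_exact,
    benjamini_hochberg,
    compare_libraries,
    compare_pair,
    cumulative_tails,
    ddct_relative_expression,
    log2_fold_change,
    low_expression_filter,
    normalize,
    significance_call,
)


class TestNormalize:
    def test_scaling(self):
        assert normalize(50, 2_000_000) == pytest.approx(25.0)

    def test_zero_revision(self):
        assert normalize(0, 123_456) == 0.01

    def test_identity_scale(self):
        assert normalize(1_000_000, 1_000_000) == pytest.approx(1e6)

    def test_negative_count_errors(self):
        with pytest.raises(ValueError, match="negative"):
            normalize(-1, 100)

    def test_bad_total_errors(self):
        with pytest.raises(ValueError, match="total"):
            normalize(1, 0)


class TestLowExpressionFilter:
    def test_all_below_one_dropped(self):
        assert low_expression_filter([0.5, 0.8, 0.9]) is False

    def test_boundary_kept(self):
        assert low_expression_filter([0.5, 1.0, 0.2]) is True

    def test_one_expressed_kept(self):
        assert low_expression_filter([0.01, 0.01, 2.0]) is True


class TestFoldChange:
    def test_basic(self):
        assert log2_fold_change(40, 10) == pytest.approx(2.0)

    def test_identity(self):
        assert log2_fold_change(7.3, 7.3) == 0.0

    def test_zero_revised_ratio(self):
        assert log2_fold_change(10, normalize(0, 1_000_000)) == pytest.approx(
            math.log2(1000), abs=1e-9
        )

    def test_antisymmetry(self):
        assert log2_fold_change(3.7, 9.2) == pytest.approx(-log2_fold_change(9.2, 3.7))

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            log2_fold_change(0.0, 5.0)


class TestPointProbability:
    def test_x0_y0_equal_totals(self):
        assert audic_claverie_p(0, 0, 10_000, 10_000) == pytest.approx(0.5)

    def test_x5_y5_equal_totals(self):
        assert audic_claverie_p(5, 5, 7, 7) == pytest.approx(252 / 2048, abs=1e-12)

    def test_x10_y0_double_total(self):
        assert audic_claverie_p(10, 0, 1_000, 2_000) == pytest.approx(3.0**-11, rel=1e-9)

    def test_symmetric_in_role_swap_for_equal_totals(self):
        assert audic_claverie_p(3, 8, 500, 500) == pytest.approx(
            audic_claverie_p(8, 3, 500, 500)
        )

    def test_non_integer_counts_error(self):
        with pytest.raises(ValueError, match="integer"):
            audic_claverie_p(1.5, 2, 10, 10)

    def test_matches_exact_rational(self):
        for x in (0, 3, 17):
            for y in (0, 5, 40):
                for n1, n2 in ((10, 10), (10, 20), (30, 15)):
                    exact = float(audic_claverie_p_exact(x, y, n1, n2))
                    assert audic_claverie_p(x, y, n1, n2) == pytest.approx(exact, rel=1e-10)

    def test_large_counts_no_overflow(self):
        # x + y of 1e6: log-space evaluation, no factorial overflow
        p = audic_claverie_p(500_500, 499_500, 1e6, 1e6)
        assert 0.0 < p < 1.0
        far = audic_claverie_p(600_000, 400_000, 1e6, 1e6)
        assert 0.0 <= far < 1e-30 and math.isfinite(far)

    @given(
        x=st.integers(0, 12),
        y=st.integers(0, 12),
        n1=st.integers(1, 50),
        n2=st.integers(1, 50),
    )
    @settings(max_examples=60, deadline=None)
    def test_probability_bounds(self, x, y, n1, n2):
        p = audic_claverie_p(x, y, n1, n2)
        assert 0.0 < p <= 1.0


class TestBinomialLimit:
    def test_equal_totals_reduce_to_binomial(self):
        # p(x|y) = C(x+y, y) / 2^(x+y+1) when N1 == N2, exactly
        for total in range(0, 21):
            for y in range(total + 1):
                x = total - y
                expected = Fraction(math.comb(x + y, y), 2 ** (x + y + 1))
                assert audic_claverie_p_exact(x, y, 42, 42) == expected


class TestCumulativeTails:
    def test_y_obs_zero(self):
        c, d = cumulative_tails(4, 0, 100, 100)
        assert c == pytest.approx(audic_claverie_p(4, 0, 100, 100))
        assert d == pytest.approx(1.0)

    def test_kernel_normalised(self):
        for x in (0, 3, 25, 100):
            for ratio in (0.5, 1.0, 2.0):
                c, _ = cumulative_tails(x, int(40 * (x + 1) * max(ratio, 1)) + 400, 1.0, ratio)
                assert c == pytest.approx(1.0, abs=1e-9)

    def test_tails_overlap_at_observed_point(self):
        for x, y in ((5, 5), (2, 9), (40, 13)):
            c, d = cumulative_tails(x, y, 1000, 1500)
            p_obs = audic_claverie_p_direct_y_given_x(x, y, 1000, 1500)
            assert c + d == pytest.approx(1.0 + p_obs, abs=1e-9)

    def test_brute_force_summation_oracle(self):
        # independent log-free summation of the kernel
        x, y_obs, n1, n2 = 5, 5, 300, 300
        r = Fraction(n2, n1)
        direct = sum(
            r**y * math.comb(x + y, y) / (1 + r) ** (x + y + 1) for y in range(y_obs + 1)
        )
        c, d = cumulative_tails(x, y_obs, n1, n2)
        assert c == pytest.approx(float(direct), rel=1e-12)
        p_obs = float(r**y_obs * math.comb(x + y_obs, y_obs) / (1 + r) ** (x + y_obs + 1))
        assert c == pytest.approx(1.0 - d + p_obs, abs=1e-12)


def audic_claverie_p_direct_y_given_x(x, y, n1, n2):
    r = Fraction(int(n2), int(n1))
    return float(r**y * math.comb(x + y, y) / (1 + r) ** (x + y + 1))


class TestSignificanceCall:
    def _result(self, fc, p):
        return diffexpr.ExpressionResult(
            mirna="m", x=1, y=1, N1=1e6, N2=1e6, norm_control=1.0,
            norm_treatment=1.0, fold_change=fc, C=p, D=p, p=p,
        )

    def test_zero_fold_change_unchanged(self):
        assert significance_call(self._result(0.0, 1e-12)) == "unchanged"

    def test_up_and_down(self):
        assert significance_call(self._result(2.5, 1e-4)) == "up"
        assert significance_call(self._result(-2.5, 1e-4)) == "down"

    def test_degenerate_thresholds_call_everything(self):
        # with p_threshold 1 and fc_threshold 0 every result is significant
        for fc in (-0.3, 0.0, 0.4):
            call = significance_call(self._result(fc, 0.9), p_threshold=1.0, fc_threshold=0.0)
            assert call in ("up", "down")

    def test_filtered_never_called(self):
        result = self._result(5.0, 1e-9)
        result.filtered = True
        assert significance_call(result) == "unchanged"

    def test_planted_change_called_up(self):
        # 4x planted change at depth 1e6 and moderate expression
        rng = np.random.default_rng(12)
        x = int(rng.poisson(200))
        y = int(rng.poisson(800))
        result = compare_pair("m", x, y, 1e6, 1e6)
        assert result.call == "up"


class TestCompareLibraries:
    def _counts(self):
        return pd.DataFrame(
            {"SD8": [100, 5, 0], "C5": [400, 5, 0], "LD3": [100, 4, 0]},
            index=["up_in_C5", "steady", "absent"],
        )

    def test_table_shape_and_calls(self):
        table = compare_libraries(self._counts(), {"SD8": 1e6, "C5": 1e6, "LD3": 1e6}, "SD8")
        assert set(table["treatment"]) == {"C5", "LD3"}
        row = table[(table.mirna == "up_in_C5") & (table.treatment == "C5")].iloc[0]
        assert row["call"] == "up"
        assert row["log2_fold_change"] == pytest.approx(2.0)

    def test_low_expression_filtered(self):
        table = compare_libraries(self._counts(), {"SD8": 1e9, "C5": 1e9, "LD3": 1e9}, "SD8")
        assert table[table.mirna == "up_in_C5"].filtered.all()
        assert (table[table.mirna == "up_in_C5"].call == "unchanged").all()

    def test_unknown_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            compare_libraries(self._counts(), {"SD8": 1e6, "C5": 1e6, "LD3": 1e6}, "XX")

    def test_antisymmetry_under_swap(self):
        a = compare_pair("m", 120, 480, 1e6, 2e6)
        b = compare_pair("m", 480, 120, 2e6, 1e6)
        assert a.fold_change == pytest.approx(-b.fold_change)

    def test_bh_option(self):
        table = compare_libraries(
            self._counts(), {"SD8": 1e6, "C5": 1e6, "LD3": 1e6}, "SD8", bh_correct=True
        )
        assert "p_adjusted" in table.columns
        assert (table["p_adjusted"] >= table["p"] - 1e-15).all()


class TestBenjaminiHochberg:
    def test_known_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert (adj <= 1.0).all() and (adj >= p - 1e-12).all()


class TestDdct:
    def test_identity(self):
        assert ddct_relative_expression(20, 15, 22, 17) == pytest.approx(1.0)

    def test_ddct_two(self):
        assert ddct_relative_expression(24, 15, 22, 15) == pytest.approx(0.25)

    def test_ddct_minus_three(self):
        assert ddct_relative_expression(19, 15, 22, 15) == pytest.approx(8.0)


class TestTypeIError:
    def test_null_simulation_calibrated(self):
        # equal-abundance tags at depth 1e6: smaller tail <= 0.01 in <= 2%
        rng = np.random.default_rng(1)
        n = 2000
        lam = rng.uniform(20, 500, size=n)
        x = rng.poisson(lam)
        y = rng.poisson(lam)
        hits = sum(
            min(cumulative_tails(int(xi), int(yi), 1e6, 1e6)) <= 0.01
            for xi, yi in zip(x, y)
        )
        assert hits / n <= 0.02
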