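"""TPM arithmetic, fold changes, the exact count test and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirswim import published
from mirswim.diffexpr import (classify, ddct, log2_fold, tpm,
                              two_library_test, build_expression_table)

from .oracles import audic_claverie_p

HIST_TOTAL = 27_877_781
NC_TOTAL = 20_658_317


class TestTPM:
    def test_published_mir182_values(self):
        assert round(tpm(1_638_730, HIST_TOTAL), 2) == 58_782.66
        assert round(tpm(326_627, NC_TOTAL), 2) == 15_810.92

    def test_zero_count(self):
        assert tpm(0, 1000) == 0.0

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            tpm(1, 0)


class TestLog2Fold:
    @pytest.mark.parametrize("a,b,expected", [
        (214.33, 52.96, 2.02),     # up-regulated example row
        (770.29, 1543.64, -1.00),  # rounds to -1.00 but exceeds the gate
        (5.0, 5.0, 0.00),
    ])
    def test_reported_rounding(self, a, b, expected):
        assert round(log2_fold(a, b), 2) == expected

    def test_zero_floor_reproduces_hist_only_value(self):
        # present at 1.51 TPM in one library, absent in the other
        assert round(log2_fold(1.51, 0.0, floor=0.01), 2) == 7.24

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_fold(-1.0, 2.0)


class TestTwoLibraryTest:
    def test_symmetric_null_is_one(self):
        assert two_library_test(5, 5, 1000, 1000) == pytest.approx(1.0)
        assert two_library_test(0, 0, 1000, 1000) == pytest.approx(1.0)

    def test_extreme_difference(self):
        assert two_library_test(0, 50, 10_000, 10_000) < 1e-10

    @pytest.mark.parametrize("x,y,n1,n2", [
        (5, 10, 10_000, 10_000),
        (0, 7, 5_000, 8_000),
        (20, 3, 12_345, 9_876),
        (50, 50, 1_000_000, 2_000_000),
        (1, 0, 27_877_781, 20_658_317),
    ])
    def test_matches_exact_tail_summation(self, x, y, n1, n2):
        assert two_library_test(x, y, n1, n2) == pytest.approx(
            audic_claverie_p(x, y, n1, n2), rel=1e-9, abs=1e-300)

    @given(x=st.integers(0, 200), y=st.integers(0, 200),
           n1=st.integers(1_000, 10_000_000), n2=st.integers(1_000, 10_000_000))
    @settings(max_examples=80, deadline=None)
    def test_library_swap_symmetry(self, x, y, n1, n2):
        assert two_library_test(x, y, n1, n2) == pytest.approx(
            two_library_test(y, x, n2, n1), rel=1e-12)

    def test_large_counts_stable(self):
        p = two_library_test(1_638_730, 326_627, HIST_TOTAL, NC_TOTAL)
        assert 0.0 <= p < 1e-100


class TestClassify:
    def test_published_table_yields_16_up_18_down(self):
        """Re-applying the significance rule to the 34 published rows
        (recomputing log2fc from the printed normalized values) reproduces
        the published direction split."""
        df = published.de_table().copy()
        df["log2fc"] = [log2_fold(a, b) for a, b in zip(df.hist_std, df.nc_std)]
        df = df.rename(columns={"p_value": "p_value"})
        out, summary = classify(df)
        assert (summary["n_up"], summary["n_down"]) == (16, 18)
        assert summary["n_sig"] == 34
        # every row exceeds the fold gate on unrounded values
        assert (out.log2fc.abs() > 1.0).all()
        # directions agree with the published marks
        assert (out.direction == df.mark.str.lower()).all()

    def test_fold_gate_blocks_small_changes(self):
        import pandas as pd
        df = pd.DataFrame({"name": ["x"], "log2fc": [0.5], "p_value": [1e-6]})
        out, summary = classify(df)
        assert summary["n_sig"] == 0
        assert out.direction.iloc[0] == "none"

    def test_significance_marks(self):
        import pandas as pd
        df = pd.DataFrame({"name": list("abc"),
                           "log2fc": [2.0, -2.0, 2.0],
                           "p_value": [0.001, 0.03, 0.2]})
        out, _ = classify(df)
        assert list(out.significance) == ["**", "*", ""]


class TestCalibration:
    def test_type_i_error_controlled_under_null(self):
        """Under planted null counts the rejection rate at 0.05 stays below
        0.05 + 3 standard errors."""
        from mirswim.synth import sample_counts
        rng = np.random.default_rng(2024)
        a, b = sample_counts(rng, 600, lfc=0.0)
        n1 = n2 = 1_000_000
        rejected = sum(two_library_test(int(x), int(y), n1, n2) < 0.05
                       for x, y in zip(a, b))
        frac = rejected / 600
        se = np.sqrt(0.05 * 0.95 / 600)
        assert frac <= 0.05 + 3 * se

    def test_power_at_large_fold_change(self):
        """Planted |log2fc| = 2 with at least 50 reads per library is
        detected (p < 0.05 and |log2fc| > 1) in at least 95% of tags."""
        from mirswim.synth import sample_counts
        rng = np.random.default_rng(99)
        a, b = sample_counts(rng, 400, lfc=2.0, base_low=100, base_high=1000)
        keep = (a >= 50) & (b >= 50)
        n1 = n2 = 1_000_000
        hits = 0
        for x, y in zip(a[keep], b[keep]):
            p = two_library_test(int(x), int(y), n1, n2)
            lfc = log2_fold(tpm(int(x), n1), tpm(int(y), n2))
            hits += (p < 0.05) and (abs(lfc) > 1)
        assert hits / keep.sum() >= 0.95


class TestDDCT:
    @pytest.mark.parametrize("ddct_val,expected", [
        (0.0, 1.0), (-1.0, 2.0), (3.3, 0.1015),
    ])
    def test_relative_expression(self, ddct_val, expected):
        # arrange CT values so the double difference equals ddct_val
        got = ddct(10.0 + ddct_val, 10.0, 5.0, 5.0)
        assert got == pytest.approx(expected, abs=1e-4)


def test_expression_table_round_trip():
    df = build_expression_table(["m1", "m2"], [100, 0], [50, 10], 10_000, 10_000)
    assert df.loc[0, "tpm_HIST"] == pytest.approx(10_000.0)
    assert df.loc[1, "log2fc"] == pytest.approx(np.log2(0.01 / 1000))
    out, summary = classify(df)
    assert set(out.columns) >= {"significance", "direction"}
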