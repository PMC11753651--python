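"""CMD, ICC(3,k), SEM/MDC and band classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitrel as g
from gaitrel.errors import (
    DegenerateInputWarning,
    IncompleteMatrixError,
    ValidationError,
)
from gaitrel.reliability import MDC_FACTOR


class TestCmd:
    def test_identical_repetitions_give_one(self):
        assert g.cmd(np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]])) == pytest.approx(1.0)

    def test_hand_computed_negative_value(self):
        # numerator SS 1 / (T(W-1)) = 0.5; denominator SS 1 / (WT-1) = 1/3
        assert g.cmd(np.array([[0.0, 1.0], [1.0, 0.0]])) == pytest.approx(-0.5)

    def test_tends_to_one_as_noise_vanishes(self):
        rng = np.random.default_rng(5)
        signal = np.sin(np.linspace(0, 2 * np.pi, 101)) * 30
        prev = -np.inf
        for noise_sd in (3.0, 0.3, 0.03):
            reps = signal + rng.normal(0, noise_sd, size=(5, 101))
            value = g.cmd(reps)
            assert value > prev
            prev = value
        assert prev > 0.999

    def test_zero_variance_flagged(self):
        with pytest.warns(DegenerateInputWarning):
            assert g.cmd(np.full((3, 5), 2.0)) == 1.0

    @given(st.floats(-50, 50), st.floats(0.1, 10))
    def test_shift_and_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(17)
        reps = rng.normal(size=(4, 20))
        base = g.cmd(reps)
        assert g.cmd(reps * scale + shift) == pytest.approx(base, abs=1e-9)
        assert base <= 1.0

    def test_shape_validation(self):
        with pytest.raises(ValidationError):
            g.cmd(np.zeros((1, 10)))
        with pytest.raises(IncompleteMatrixError):
            g.cmd(np.array([[0.0, np.nan], [1.0, 2.0]]))


class TestSummarizeCmd:
    def test_two_values(self):
        s = g.summarize_cmd([0.0, 1.0])
        assert s.mean == pytest.approx(0.5)
        assert s.sd == pytest.approx(math.sqrt(0.5), abs=1e-4)
        # t(0.975, 1) = 12.706; half-width = 12.706 * sd / sqrt(2)
        assert s.ci95[1] - s.mean == pytest.approx(12.706 * 0.5, abs=1e-2)

    def test_equal_values_collapse(self):
        s = g.summarize_cmd([0.9, 0.9, 0.9])
        assert (s.mean, s.sd) == (0.9, 0.0)
        assert s.ci95 == (0.9, 0.9)

    def test_nine_subject_interval_matches_printed_style(self):
        """n=9, mean .975, SD .019 must give a CI of about [.960, .990]."""
        rng = np.random.default_rng(2)
        vals = rng.normal(size=9)
        vals = (vals - vals.mean()) / vals.std(ddof=1) * 0.019 + 0.975
        s = g.summarize_cmd(vals)
        assert s.ci95[0] == pytest.approx(0.960, abs=5e-4)
        assert s.ci95[1] == pytest.approx(0.990, abs=5e-4)

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            g.summarize_cmd([0.5])


class TestIcc:
    def test_hand_anova_example(self):
        r = g.icc_3k(np.array([[1.0, 2.0], [4.0, 3.0], [5.0, 6.0]]))
        # SS_rows 16, SS_cols 1/6, SS_err 4/3 -> BMS 8, EMS 2/3
        assert r.icc == pytest.approx((8 - 2 / 3) / 8, abs=1e-12)
        assert r.icc == pytest.approx(0.917, abs=1e-3)
        assert r.icc_single == pytest.approx((8 - 2 / 3) / (8 + 2 / 3), abs=1e-12)

    def test_constant_column_offsets_give_one(self):
        rows = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])  # col2 = col1 + 1
        with pytest.warns(DegenerateInputWarning):
            r = g.icc_3k(rows)
        assert r.icc == 1.0
        assert r.ci95 == (1.0, 1.0)

    def test_column_shift_invariance(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(12, 4))
        shifted = m + np.array([0.0, 5.0, -3.0, 100.0])
        a, b = g.icc_3k(m), g.icc_3k(shifted)
        assert a.icc == pytest.approx(b.icc, abs=1e-9)

    @given(st.integers(0, 1000))
    def test_spearman_brown_identity(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(3, 12)), int(rng.integers(2, 6))
        m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
        r = g.icc_3k(m)
        assert g.spearman_brown(r.icc_single, k) == pytest.approx(r.icc, abs=1e-12)

    def test_matches_pingouin_oracle(self):
        """Independent cross-check of estimate and CI against pingouin."""
        import pandas as pd
        import pingouin

        rng = np.random.default_rng(4)
        for _ in range(5):
            n, k = 10, 4
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 1.5
            long = pd.DataFrame({
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": m.ravel(),
            })
            table = pingouin.intraclass_corr(
                long, targets="targets", raters="raters", ratings="ratings"
            ).set_index("Type")
            ours = g.icc_3k(m)
            icc3k = table.loc["ICC(C,k)"]  # two-way mixed, consistency, avg of k
            assert ours.icc == pytest.approx(icc3k["ICC"], abs=1e-10)
            assert ours.icc_single == pytest.approx(
                table.loc["ICC(C,1)", "ICC"], abs=1e-10)
            # pingouin rounds its CI bounds to 2 decimals
            ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
            assert ours.ci95[0] == pytest.approx(icc3k[ci_col][0], abs=6e-3)
            assert ours.ci95[1] == pytest.approx(icc3k[ci_col][1], abs=6e-3)

    def test_variance_ratio_recovery(self):
        """Simulated subject SD 1, error SD 0.5: ICC(3,1) ~ 1/(1+0.25)."""
        rng = np.random.default_rng(12)
        n, k = 500, 3
        m = rng.normal(size=(n, 1)) + rng.normal(0, 0.5, size=(n, k))
        assert g.icc_3k(m).icc_single == pytest.approx(0.8, abs=0.02)

    def test_no_row_variance_flagged(self):
        with pytest.warns(DegenerateInputWarning):
            r = g.icc_3k(np.tile([[1.0, 2.0]], (4, 1)))
        assert r.degenerate and math.isnan(r.icc)

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(IncompleteMatrixError):
            g.icc_3k(m)


class TestSemMdc:
    def test_perfect_reliability_zero_sem(self):
        assert g.sem(2.0, 1.0) == 0.0

    def test_arithmetic(self):
        assert g.sem(2.0, 0.75) == pytest.approx(1.0)

    def test_mdc_from_abstract_pair(self):
        assert round(g.mdc(0.018), 3) == 0.050

    def test_mdc_of_unit_sem(self):
        assert g.mdc(1.0) == pytest.approx(2.7719, abs=1e-4)

    @given(st.floats(1e-6, 100.0), st.floats(0.0, 1.0))
    def test_ratio_is_constant(self, sd, icc1):
        s = g.sem(sd, icc1)
        if s > 0:
            assert g.mdc(s) / s == pytest.approx(MDC_FACTOR, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            g.sem(1.0, 1.5)
        with pytest.raises(ValidationError):
            g.mdc(-0.1)


class TestBands:
    @pytest.mark.parametrize("value,band", [
        (0.969, "large"), (0.327, "medium"), (0.037, "below_small"),
        (0.65, "large"), (0.64, "medium"), (0.25, "small"), (0.04, "below_small"),
        (-0.5, "below_small"),
    ])
    def test_cmd_bands(self, value, band):
        assert g.classify_cmd(value) == band

    @pytest.mark.parametrize("value,band", [
        (0.896, "good"), (0.991, "excellent"), (0.3, "poor"),
        (0.5, "moderate"), (0.75, "good"), (0.9, "good"), (0.901, "excellent"),
    ])
    def test_icc_bands(self, value, band):
        assert g.classify_icc(value) == band
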