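"""Tissue-modulus back-calculation and the paired statistics engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bonefe.calib_stats import (
    back_calculate_tissue_modulus,
    cohort_report,
    two_sided_t_test,
    wilcoxon_signed_rank,
)


class TestBackCalculation:
    def test_identity_and_double(self):
        assert back_calculate_tissue_modulus(100.0, 100.0).e_tissue_gpa == pytest.approx(10.0)
        assert back_calculate_tissue_modulus(200.0, 100.0).e_tissue_gpa == pytest.approx(20.0)

    def test_scale_equivariance(self):
        a = back_calculate_tissue_modulus(123.0, 87.0)
        b = back_calculate_tissue_modulus(123.0 * 7.5, 87.0 * 7.5)
        assert a.e_tissue_gpa == pytest.approx(b.e_tissue_gpa, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            back_calculate_tissue_modulus(-1.0, 100.0)
        with pytest.raises(ValueError):
            back_calculate_tissue_modulus(100.0, 0.0)


class TestWilcoxon:
    """The n=3 asymptotic p-values {0.109, 0.285, 0.593} for T in {0, 1, 2}
    anchor the implementation to the emulated statistical engine."""

    @pytest.mark.parametrize(
        "treated,control,T,p",
        [
            # all three differences one sign -> T=0
            ([1.0, 2.0, 3.0], [2.0, 4.0, 6.0], 0.0, 0.109),
            # smallest-magnitude difference opposite sign -> T=1
            ([2.5, 2.0, 3.0], [2.0, 4.0, 6.0], 1.0, 0.285),
            # middle rank opposite -> T=2
            ([1.0, 6.0, 3.0], [2.0, 4.0, 6.0], 2.0, 0.593),
        ],
    )
    def test_n3_asymptotic_anchor(self, treated, control, T, p):
        res = wilcoxon_signed_rank(list(zip(treated, control)))
        assert res.statistic == T
        assert res.p == pytest.approx(p, abs=5e-4)

    def test_n3_t0_z_value(self):
        res = wilcoxon_signed_rank([(1.0, 2.0), (2.0, 4.0), (3.0, 6.0)])
        assert res.z == pytest.approx(-1.604, abs=1e-3)

    def test_exact_mode_t0_enumeration(self):
        res = wilcoxon_signed_rank(
            [(1.0, 2.0), (2.0, 4.0), (3.0, 6.0)], mode="exact"
        )
        assert res.p == pytest.approx(0.25)

    def test_asymptotic_matches_scipy_without_correction(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            t = rng.normal(10, 2, 12)
            c = t + rng.normal(0.5, 1.0, 12)
            ours = wilcoxon_signed_rank(list(zip(t, c)))
            ref = sps.wilcoxon(t, c, correction=False, method="approx")
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_asymptotic_agree_for_larger_n(self):
        rng = np.random.default_rng(2)
        t = rng.normal(10, 2, 25)
        c = t + rng.normal(0.3, 1.0, 25)
        p_exact = wilcoxon_signed_rank(list(zip(t, c)), mode="exact").p
        p_asym = wilcoxon_signed_rank(list(zip(t, c))).p
        assert abs(p_exact - p_asym) < 0.02

    def test_zero_differences_dropped_then_all_zero_error(self):
        res = wilcoxon_signed_rank([(5.0, 5.0), (1.0, 2.0), (2.0, 4.0), (3.0, 6.0)])
        assert res.n_used == 3
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([(5.0, 5.0), (3.0, 3.0)])


class TestTTest:
    def test_identical_samples(self):
        t, df, p = two_sided_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert t == 0.0 and p == 1.0

    def test_pooled_closed_form(self):
        # means 12 vs 22, each variance 4, pooled sd 2:
        # t = -10 / (2 * sqrt(2/3)) = -6.1237, df = 4
        t, df, p = two_sided_t_test([10.0, 12.0, 14.0], [20.0, 22.0, 24.0])
        assert t == pytest.approx(-10.0 / (2.0 * np.sqrt(2.0 / 3.0)), rel=1e-12)
        assert df == 4
        ref = 2 * sps.t.sf(abs(t), 4)
        assert p == pytest.approx(ref, rel=1e-12)

    def test_welch_option(self):
        a = [10.0, 12.0, 14.0, 16.0]
        b = [20.0, 30.0, 40.0]
        t, df, p = two_sided_t_test(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sided_t_test([1.0], [2.0, 3.0])


def make_summaries(ratio=0.84, n=3, timepoints=("7d",)):
    rows = []
    rng = np.random.default_rng(3)
    for tp in timepoints:
        for i in range(n):
            control = 300.0 + 30 * rng.random()
            rows.append({"animal": f"a{i}", "timepoint": tp, "side": "control",
                         "elastic_stiffness_n_per_mm": control,
                         "yield_load_n": control * 0.12,
                         "ultimate_load_n": control * 0.18})
            rows.append({"animal": f"a{i}", "timepoint": tp, "side": "treated",
                         "elastic_stiffness_n_per_mm": control * ratio,
                         "yield_load_n": control * 0.12 * ratio,
                         "ultimate_load_n": control * 0.18 * ratio})
    return pd.DataFrame(rows)


class TestCohortReport:
    def test_constant_ratio_gives_16_pct_less_with_zero_sd(self):
        report = cohort_report(make_summaries(ratio=0.84))
        entry = report["timepoints"]["7d"]["elastic_stiffness_n_per_mm"]
        assert entry["percent_difference_mean"] == pytest.approx(-16.0, abs=1e-9)
        assert entry["percent_difference_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_exact_mode_cannot_reject_at_n3(self):
        # smallest attainable exact two-sided p at n=3 is 2/8 = 0.25 > 0.05
        rng = np.random.default_rng(4)
        for seed in range(50):
            df = make_summaries(ratio=1.0 + 0.2 * rng.standard_normal())
            report = cohort_report(df, wilcoxon_mode="exact")
            for entry in report["timepoints"]["7d"].values():
                assert entry["p"] >= 0.25
                assert not entry["significant"]

    def test_unmatched_pair_error_names_specimen(self):
        df = make_summaries().iloc[:-1]  # drop one treated row
        with pytest.raises(ValueError, match="a2"):
            cohort_report(df)

    def test_across_timepoint_ttest_present(self):
        df = make_summaries(timepoints=("7d", "1m"))
        # perturb one timepoint so variances are nonzero
        sel = df["timepoint"] == "1m"
        rng = np.random.default_rng(5)
        df.loc[sel & (df["side"] == "treated"), "elastic_stiffness_n_per_mm"] *= (
            1.0 + 0.05 * rng.random((sel & (df["side"] == "treated")).sum())
        )
        report = cohort_report(df)
        assert "elastic_stiffness_n_per_mm" in report["across_timepoints"]
        assert 0.0 <= report["across_timepoints"]["elastic_stiffness_n_per_mm"]["p"] <= 1.0
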