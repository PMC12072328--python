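"""Agreement metrics, ICC, subgroups, cohort summary, sample size."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedweight.agreement_eval import (
    assign_subgroup,
    bland_altman_plot,
    cohort_summary,
    icc,
    icc_band,
    percentage,
    percentage_errors,
    rmse_from_loa,
    sample_size_two_proportions,
    subgroup_reports,
    summarize,
)


class TestPercentageErrors:
    def test_perfect_agreement_is_all_zero(self):
        a = np.array([5.0, 10.0, 20.0])
        assert np.all(percentage_errors(a, a) == 0.0)

    def test_hand_values(self):
        assert percentage_errors([10.0], [11.0])[0] == pytest.approx(10.0)
        got = percentage_errors([8.0, 20.0], [9.0, 18.0])
        assert got == pytest.approx([12.5, -10.0])

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(ValueError):
            percentage_errors([0.0, 5.0], [1.0, 5.0])


class TestSummarize:
    def test_hand_oracle(self):
        rep = summarize([8.0, 20.0], [9.0, 18.0])
        assert rep.mpe == pytest.approx(1.25)
        assert rep.mape == pytest.approx(11.25)
        assert rep.rmspe == pytest.approx(np.sqrt((12.5**2 + 10**2) / 2))
        assert rep.rmse == pytest.approx(np.sqrt((1 + 4) / 2))
        assert rep.mean_diff == pytest.approx(-0.5)
        assert rep.loa_lower == pytest.approx(-0.5 - 1.96 * 1.5)
        assert rep.loa_upper == pytest.approx(-0.5 + 1.96 * 1.5)
        assert rep.pw10 == 50.0
        assert rep.pw20 == 100.0

    def test_perfect_agreement(self):
        a = np.array([4.0, 9.0, 16.0])
        rep = summarize(a, a)
        assert rep.mpe == rep.mape == rep.rmspe == rep.rmse == 0.0
        assert (rep.loa_lower, rep.loa_upper) == (0.0, 0.0)
        assert rep.pw10 == rep.pw20 == 100.0

    def test_metric_inequalities_on_random_datasets(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 40)
            a = rng.uniform(3, 50, n)
            p = a * rng.uniform(0.5, 1.5, n)
            rep = summarize(a, p)
            assert rep.mape <= rep.rmspe + 1e-9
            assert abs(rep.mpe) <= rep.mape + 1e-9
            assert rep.pw10 <= rep.pw20
            # LOA symmetric about the mean difference
            assert (rep.loa_upper + rep.loa_lower) / 2 == pytest.approx(rep.mean_diff)
            # algebraic identity behind the LOA→RMSE reconstruction
            sd = (rep.loa_upper - rep.loa_lower) / (2 * 1.96)
            assert rep.rmse**2 == pytest.approx(rep.mean_diff**2 + sd**2, abs=1e-9)

    def test_pw_boundary_inclusive(self):
        rep = summarize([10.0, 10.0], [11.0, 12.0])  # errors exactly 10% and 20%
        assert rep.pw10 == 50.0
        assert rep.pw20 == 100.0

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            summarize([5.0], [5.0])


class TestRmseFromLoa:
    def test_reconstruction_identity_against_summarize(self, rng):
        for _ in range(50):
            a = rng.uniform(3, 50, 30)
            p = a + rng.normal(0, 2, 30)
            rep = summarize(a, p)
            assert rmse_from_loa(rep.loa_lower, rep.loa_upper) == pytest.approx(
                rep.rmse, abs=1e-9
            )

    def test_symmetric_limits_reduce_to_sd(self):
        assert rmse_from_loa(-3.92, 3.92) == pytest.approx(2.0)
        assert rmse_from_loa(-1.96, 1.96) == pytest.approx(1.0)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            rmse_from_loa(2.0, -2.0)


class TestIcc:
    def test_perfect_agreement_is_excellent_unity(self):
        a = np.array([5.0, 8.0, 12.0, 20.0, 30.0])
        res = icc(a, a.copy())
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_matches_pingouin_two_way_absolute_single(self, rng):
        pg = pytest.importorskip("pingouin")
        for trial in range(20):
            n = int(rng.integers(6, 25))
            a = rng.uniform(4, 40, n)
            p = a + rng.normal(0, rng.uniform(0.5, 4), n) + rng.normal(0, 1)
            mine = icc(a, p)
            long = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), 2),
                    "raters": ["A", "B"] * n,
                    "ratings": np.column_stack([a, p]).ravel(),
                }
            )
            ref = pg.intraclass_corr(
                long, targets="targets", raters="raters", ratings="ratings"
            )
            row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
            assert mine.icc == pytest.approx(float(row["ICC"]), abs=1e-9)
            assert mine.p_value == pytest.approx(float(row["pval"]), rel=1e-6)
            lo, hi = row["CI95"]
            assert mine.ci_lower == pytest.approx(lo, abs=0.006)
            assert mine.ci_upper == pytest.approx(hi, abs=0.006)

    def test_matches_anova_mean_squares_oracle(self, rng):
        # independent route: build the two-way ANOVA table by brute force
        for _ in range(20):
            n = int(rng.integers(6, 30))
            a = rng.uniform(4, 40, n)
            p = a + rng.normal(0, 2, n)
            y = np.column_stack([a, p])
            grand = y.mean()
            msr = 2 * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
            msc = n * ((y.mean(axis=0) - grand) ** 2).sum() / 1
            mse = (
                ((y - y.mean(axis=1, keepdims=True) - y.mean(axis=0) + grand) ** 2).sum()
                / (n - 1)
            )
            expect = (msr - mse) / (msr + mse + (2 / n) * (msc - mse))
            assert icc(a, p).icc == pytest.approx(expect, abs=1e-9)

    def test_equivariance(self, rng):
        a = rng.uniform(5, 30, 40)
        p = a + rng.normal(0, 2, 40)
        base = icc(a, p).icc
        assert icc(a + 7.0, p + 7.0).icc == pytest.approx(base, abs=1e-12)
        assert icc(a * 3.0, p * 3.0).icc == pytest.approx(base, abs=1e-12)
        # constant offset on one column degrades absolute agreement
        assert icc(a, p + 5.0).icc < base

    def test_band_cutoffs(self):
        assert icc_band(0.959) == "excellent"
        assert icc_band(0.870) == "good"
        assert icc_band(0.10) == "poor"
        assert icc_band(0.25) == "low"
        assert icc_band(0.50) == "moderate"
        assert icc_band(0.70) == "good"
        assert icc_band(0.90) == "excellent"

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            icc([1.0, 1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            icc([1.0, 2.0], [1.0, 2.0])


class TestSubgroups:
    def test_boundary_assignment(self):
        assert assign_subgroup(12) == "1-12 months"
        assert assign_subgroup(13) == "2-5 years"
        assert assign_subgroup(71) == "2-5 years"
        assert assign_subgroup(72) == "6-12 years"
        with pytest.raises(ValueError):
            assign_subgroup(0)

    def test_partition_sums_to_overall(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "age_months": rng.integers(1, 156, n),
                "actual_kg": rng.uniform(4, 40, n),
            }
        )
        df["predicted_kg"] = df["actual_kg"] * rng.uniform(0.8, 1.2, n)
        groups = subgroup_reports(df)
        subtotal = sum(
            g["agreement"].n for label, g in groups.items() if label != "overall"
        )
        assert subtotal == groups["overall"]["agreement"].n == n

    def test_cohort_mix_proportions(self, chart):
        from pedweight.anthro_synth import sample_cohort, subjects_to_frame

        subs = subjects_to_frame(sample_cohort(1335, chart, seed=1))
        labels = subs["age_months"].map(assign_subgroup)
        counts = labels.value_counts()
        assert abs(counts["1-12 months"] - 150) < 45
        assert abs(counts["2-5 years"] - 825) < 65
        assert abs(counts["6-12 years"] - 360) < 60


class TestCohortSummary:
    def _printed_counts_cohort(self):
        """Cohort reproducing the printed subgroup/sex/habitus counts."""
        blocks = [
            # (age_months, n, males, thin, normal, overweight)
            (6, 150, 77, 0, 141, 9),
            (36, 825, 480, 22, 749, 54),
            (100, 360, 210, 36, 281, 43),
        ]
        rows = []
        for age, n, males, thin, normal, over in blocks:
            sex = ["male"] * males + ["female"] * (n - males)
            bt = ["thin"] * thin + ["normal"] * normal + ["overweight"] * over
            for i in range(n):
                rows.append(
                    {
                        "age_months": age, "sex": sex[i], "body_type": bt[i],
                        "height_cm": 100.0, "weight_kg": 16.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_count_percentages_match_printed_table(self):
        s = cohort_summary(self._printed_counts_cohort())
        assert s["2-5 years"]["sex"]["male"]["pct"] == 58.2
        assert s["overall"]["body_type"]["normal"]["pct"] == 87.7
        assert s["6-12 years"]["body_type"]["overweight"]["pct"] == 11.9
        # 767/1335 males overall → 57.5 at 1 dp (57.4531…)
        assert s["overall"]["sex"]["male"]["pct"] == 57.5

    def test_single_subject_degenerate_iqr(self):
        df = pd.DataFrame(
            [{"age_months": 24, "sex": "male", "body_type": "normal",
              "height_cm": 88.0, "weight_kg": 12.0}]
        )
        s = cohort_summary(df)
        w = s["overall"]["weight_kg"]
        assert w["median"] == w["q1"] == w["q3"] == 12.0

    def test_median_iqr_matches_sort_oracle(self, rng):
        for n in (5, 6, 51, 52):
            w = rng.uniform(5, 40, n)
            df = pd.DataFrame(
                {
                    "age_months": np.full(n, 36), "sex": ["male"] * n,
                    "body_type": ["normal"] * n,
                    "height_cm": np.full(n, 100.0), "weight_kg": w,
                }
            )
            s = cohort_summary(df)["overall"]["weight_kg"]
            x = np.sort(w)

            def quantile(q):  # linear-interpolation convention
                pos = q * (n - 1)
                lo = int(np.floor(pos))
                frac = pos - lo
                return x[lo] * (1 - frac) + x[min(lo + 1, n - 1)] * frac

            assert s["median"] == pytest.approx(quantile(0.5))
            assert s["q1"] == pytest.approx(quantile(0.25))
            assert s["q3"] == pytest.approx(quantile(0.75))

    def test_percentage_rounding(self):
        assert percentage(480, 825) == 58.2
        assert percentage(1171, 1335) == 87.7
        assert percentage(43, 360) == 11.9
        assert percentage(1, 3) == 33.3


class TestSampleSize:
    def test_reference_case(self):
        assert sample_size_two_proportions(0.6, 0.7, 0.05, 0.8) == 356

    def test_monotone_in_power(self):
        ns = [
            sample_size_two_proportions(0.6, 0.7, 0.05, power)
            for power in (0.5, 0.7, 0.8, 0.9, 0.99)
        ]
        assert all(a <= b for a, b in zip(ns, ns[1:]))

    def test_symmetric_in_p1_p2(self):
        assert sample_size_two_proportions(0.6, 0.7) == sample_size_two_proportions(0.7, 0.6)

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_proportions(0.5, 0.5)


class TestPooling:
    def test_equal_n_subgroup_pooling(self, rng):
        # MPE pools linearly, RMSPE in quadrature, for equal-sized halves
        a1, a2 = rng.uniform(5, 40, 50), rng.uniform(5, 40, 50)
        p1, p2 = a1 * rng.uniform(0.8, 1.2, 50), a2 * rng.uniform(0.8, 1.2, 50)
        r1, r2 = summarize(a1, p1), summarize(a2, p2)
        pooled = summarize(np.r_[a1, a2], np.r_[p1, p2])
        assert pooled.mpe == pytest.approx((r1.mpe + r2.mpe) / 2)
        assert pooled.rmspe == pytest.approx(
            np.sqrt((r1.rmspe**2 + r2.rmspe**2) / 2)
        )


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=1.0, max_value=100.0),
            st.floats(min_value=0.1, max_value=200.0),
        ),
        min_size=2,
        max_size=40,
    )
)
def test_report_invariants_hold_for_arbitrary_pairs(pairs):
    """MAPE ≤ RMSPE, |MPE| ≤ MAPE, PW10 ≤ PW20 and the RMSE/LOA identity
    hold for any positive actual weights and finite predictions."""
    actual = np.array([a for a, _ in pairs])
    pred = np.array([p for _, p in pairs])
    rep = summarize(actual, pred)
    assert rep.mape <= rep.rmspe * (1 + 1e-12) + 1e-9
    assert abs(rep.mpe) <= rep.mape * (1 + 1e-12) + 1e-9
    assert rep.pw10 <= rep.pw20
    sd = (rep.loa_upper - rep.loa_lower) / (2 * 1.96)
    assert rep.rmse**2 == pytest.approx(rep.mean_diff**2 + sd**2, rel=1e-9, abs=1e-9)


def test_bland_altman_plot_writes_file(tmp_path, rng):
    a = rng.uniform(5, 40, 80)
    p = a + rng.normal(0, 2, 80)
    out = tmp_path / "ba.png"
    bland_altman_plot(a, p, out)
    assert out.exists() and out.stat().st_size > 0
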