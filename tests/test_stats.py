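"""Tests for effect sizes, gated paired comparisons, monthly summaries and
delta-vs-descriptor correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stepvar.exceptions import InsufficientDataError, UndefinedEffectError
from stepvar.poincare import PoincareConfig, descriptor_table
from stepvar.stats import (
    OutcomePair,
    delta_correlations,
    monthly_summary,
    paired_comparison,
    paired_t_from_summary,
    rank_biserial,
    srm,
    srm_from_summary,
)

from conftest import make_series


def pairs_from_deltas(deltas, outcome="y"):
    return [
        OutcomePair(f"S{i:02d}", outcome, 10.0, 10.0 + d) for i, d in enumerate(deltas)
    ]


class TestSrm:
    def test_matches_mean_over_sd(self):
        rng = np.random.default_rng(0)
        d = rng.normal(1, 2, 40)
        assert srm(d) == pytest.approx(np.mean(d) / np.std(d, ddof=1))

    def test_zero_mean_deltas(self):
        assert srm([1.0, -1.0]) == 0.0

    def test_summary_form(self):
        assert srm_from_summary(-1.46, 3.31) == pytest.approx(-0.4411, abs=5e-5)

    def test_zero_sd_undefined(self):
        with pytest.raises(UndefinedEffectError):
            srm([2.0, 2.0, 2.0])


class TestPairedTFromSummary:
    def test_null_mean_gives_p_one(self):
        t, p = paired_t_from_summary(0.0, 1.0, 10)
        assert t == 0.0
        assert p == 1.0

    def test_matches_scipy_on_raw_data(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 1.0, 25)
        t, p = paired_t_from_summary(np.mean(d), np.std(d, ddof=1), len(d))
        ref = sps.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(UndefinedEffectError):
            paired_t_from_summary(1.0, 0.0, 10)


class TestRankBiserial:
    def test_all_positive_is_one(self):
        assert rank_biserial([0.5, 1.0, 2.0]) == 1.0

    def test_symmetric_pair_is_zero(self):
        assert rank_biserial([1.0, -1.0]) == 0.0

    def test_hand_ranked_example(self):
        # |3|->rank 3, |-1|->rank 1, |2|->rank 2; (W+ - W-)/(W+ + W-) = 4/6
        assert rank_biserial([3.0, -1.0, 2.0]) == pytest.approx(2 / 3)

    def test_zeros_dropped(self):
        assert rank_biserial([0.0, 0.0, 1.0]) == 1.0

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedEffectError):
            rank_biserial([0.0, 0.0])

    @given(st.lists(st.floats(-100, 100).filter(lambda v: abs(v) > 1e-6),
                    min_size=2, max_size=30))
    def test_antisymmetry(self, deltas):
        assert rank_biserial([-d for d in deltas]) == pytest.approx(
            -rank_biserial(deltas), abs=1e-12
        )


class TestPairedComparison:
    def test_normal_deltas_use_paired_t(self):
        rng = np.random.default_rng(2024)
        deltas = rng.standard_normal(30)
        comp = paired_comparison(pairs_from_deltas(deltas))
        assert comp.test_used == "paired_t"
        assert comp.normality_p > 0.05
        assert comp.effect_size == pytest.approx(comp.srm)
        assert comp.srm == pytest.approx(np.mean(deltas) / np.std(deltas, ddof=1))

    def test_skewed_deltas_use_wilcoxon(self):
        rng = np.random.default_rng(7)
        deltas = rng.exponential(1.0, 30) ** 3 - 0.5
        comp = paired_comparison(pairs_from_deltas(deltas))
        assert comp.test_used == "wilcoxon_signed_rank"
        assert comp.normality_p <= 0.05
        assert -1 <= comp.effect_size <= 1

    def test_identical_baseline_and_followup_undefined(self):
        pairs = [OutcomePair(f"S{i}", "y", 5.0, 5.0) for i in range(10)]
        with pytest.raises(UndefinedEffectError):
            paired_comparison(pairs)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            paired_comparison(pairs_from_deltas([1.0, 2.0]))

    def test_p_value_matches_summary_form_for_t_branch(self):
        rng = np.random.default_rng(5)
        deltas = rng.normal(0.5, 1.0, 30)
        comp = paired_comparison(pairs_from_deltas(deltas))
        assert comp.test_used == "paired_t"
        _, p = paired_t_from_summary(comp.delta_mean, comp.delta_sd, comp.n)
        assert comp.p_value == pytest.approx(p)


class TestMonthlySummary:
    def test_constant_subject(self):
        table = monthly_summary([make_series([100.0] * 60)], block_days=30)
        assert list(table["month_index"]) == [1, 2]
        assert (table["mean"] == 100).all()
        assert (table["sd"] == 0).all()
        assert (table["cv"] == 0).all()

    def test_cv_is_mean_of_per_subject_cvs(self):
        # subject A: cv 0.2; subject B: cv 0.6 -> month cv 0.4
        rng = np.random.default_rng(11)

        def subject(cv, sid):
            vals = rng.normal(100, 1, 30)
            vals = 100 + (vals - vals.mean()) * (cv * 100 / vals.std(ddof=1))
            return make_series(vals, subject_id=sid)

        table = monthly_summary([subject(0.2, "A"), subject(0.6, "B")], block_days=30)
        assert table.loc[0, "cv"] == pytest.approx(0.4, abs=1e-9)

    def test_months_count_from_each_subjects_first_record(self):
        a = make_series([1.0] * 30)
        b = make_series([2.0] * 30, subject_id="B",
                        dates=np.datetime64("2020-09-15") + np.arange(30))
        table = monthly_summary([a, b], block_days=30)
        assert list(table["month_index"]) == [1]
        assert table.loc[0, "n_days"] == 60

    def test_simulated_decline_visible_in_monthly_means(self, default_cohort):
        from stepvar.data import series_from_frame

        series = list(series_from_frame(default_cohort.activity, "steps"))
        table = monthly_summary(series, block_days=30)
        first, last = table.iloc[0]["mean"], table.iloc[5]["mean"]
        assert first > last  # downward trend built into the defaults


def _descriptor_frame(values_by_subject):
    rows = [
        dict(subject_id=sid, metric="steps", n_days=10, n_pairs=9,
             avg=v, sd=v, sd1=v, sd2=v, sd12=1.0, afe=v)
        for sid, v in values_by_subject.items()
    ]
    return pd.DataFrame(rows)


def _outcomes_frame(deltas_by_subject, outcome="y"):
    return pd.DataFrame(
        [
            dict(subject_id=sid, outcome=outcome, baseline=0.0, followup=d)
            for sid, d in deltas_by_subject.items()
        ]
    )


class TestDeltaCorrelations:
    def test_perfect_linear_relation(self):
        subjects = {f"S{i}": float(i) for i in range(1, 11)}
        table = delta_correlations(
            _outcomes_frame(subjects), _descriptor_frame(subjects), policy="pearson"
        )
        row = table[table["descriptor"] == "steps.sd2"].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_constant_descriptor_flagged_undefined(self):
        deltas = {f"S{i}": float(i) for i in range(1, 8)}
        desc = {sid: 3.0 for sid in deltas}
        table = delta_correlations(
            _outcomes_frame(deltas), _descriptor_frame(desc), policy="pearson"
        )
        row = table[table["descriptor"] == "steps.sd2"].iloc[0]
        assert not row["defined"]
        assert math.isnan(row["r"])

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        desc = {f"S{i:02d}": float(v) for i, v in enumerate(rng.uniform(1, 10, 20))}
        deltas = {sid: rng.normal(v, 1.0) for sid, v in desc.items()}
        base = delta_correlations(
            _outcomes_frame(deltas), _descriptor_frame(desc), policy="spearman"
        )
        transformed = delta_correlations(
            _outcomes_frame(deltas),
            _descriptor_frame({s: math.exp(v / 3) for s, v in desc.items()}),
            policy="spearman",
        )
        for col in ("steps.sd1", "steps.avg"):
            a = base[base["descriptor"] == col].iloc[0]["r"]
            b = transformed[transformed["descriptor"] == col].iloc[0]["r"]
            assert a == pytest.approx(b)

    def test_pearson_on_standardized_inputs_equals_covariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 50)
        y = 0.6 * x + rng.normal(0, 0.8, 50)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        desc = {f"S{i:02d}": float(v) for i, v in enumerate(xs)}
        deltas = {f"S{i:02d}": float(v) for i, v in enumerate(ys)}
        table = delta_correlations(
            _outcomes_frame(deltas), _descriptor_frame(desc), policy="pearson"
        )
        r = table[table["descriptor"] == "steps.sd2"].iloc[0]["r"]
        assert r == pytest.approx(float(np.cov(xs, ys, ddof=1)[0, 1]), rel=1e-9)

    def test_bh_adjustment_column_appended(self):
        rng = np.random.default_rng(4)
        desc = {f"S{i:02d}": float(v) for i, v in enumerate(rng.normal(5, 1, 15))}
        deltas = {sid: rng.normal(0, 1) for sid in desc}
        table = delta_correlations(
            _outcomes_frame(deltas), _descriptor_frame(desc),
            policy="pearson", bh_adjust=True,
        )
        assert "p_adj_bh" in table.columns
        assert (table.loc[table["defined"], "p_adj_bh"]
                >= table.loc[table["defined"], "p_value"] - 1e-12).all()

    def test_auto_policy_gates_on_normality(self, default_cohort):
        from stepvar.data import series_from_frame

        desc, _ = descriptor_table(
            series_from_frame(default_cohort.activity, "steps"),
            PoincareConfig(1, "calendar", 10),
        )
        table = delta_correlations(default_cohort.outcomes, desc, policy="auto")
        assert set(table.loc[table["defined"], "method"]) <= {"pearson", "spearman"}
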