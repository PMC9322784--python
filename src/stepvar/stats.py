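"""Cohort statistics: paired pre/post comparisons, effect sizes, monthly
activity summaries and delta-vs-variability correlations.

The comparison workflow mirrors standard clinical-trial reporting for a
single-arm pre/post design: Shapiro–Wilk on the paired differences gates the
choice between a paired t-test (effect size Cohen's d = mean(Δ)/SD(Δ)) and
Wilcoxon's matched-pairs signed-rank test (effect size rank-biserial
correlation); the standardised response mean (SRM) is reported either way.
Correlations between clinical-outcome changes and variability descriptors
use Pearson when both variables pass the normality gate, Spearman otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import ActivitySeries
from .exceptions import (
    InsufficientDataError,
    UndefinedEffectError,
    ValidationError,
)


@dataclass(frozen=True)
class OutcomePair:
    """Baseline/follow-up values of one clinical outcome for one subject."""

    subject_id: str
    outcome: str
    baseline: float
    followup: float

    @property
    def delta(self) -> float:
        return self.followup - self.baseline


@dataclass(frozen=True)
class PairedComparison:
    """Summary of one outcome's pre/post comparison.

    ``test_used`` is ``"paired_t"`` or ``"wilcoxon_signed_rank"``, chosen by
    the Shapiro–Wilk normality gate on the deltas.  ``effect_size`` is
    Cohen's d for the t-test and the rank-biserial correlation for Wilcoxon;
    ``srm`` (standardised response mean) is always mean(Δ)/SD(Δ).
    """

    outcome: str
    n: int
    baseline_mean: float
    baseline_sd: float
    baseline_median: float
    baseline_q1: float
    baseline_q3: float
    delta_mean: float
    delta_sd: float
    delta_median: float
    delta_q1: float
    delta_q3: float
    normality_p: float
    test_used: str
    p_value: float
    effect_size: float
    srm: float


# ---------------------------------------------------------------------------
# effect sizes and summary-statistic tests
# ---------------------------------------------------------------------------

def srm(deltas: Sequence[float]) -> float:
    """Standardised response mean: mean(Δ) / sample SD(Δ)."""
    d = np.asarray(deltas, dtype=float)
    if len(d) < 2:
        raise InsufficientDataError("SRM needs at least 2 deltas", n=len(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise UndefinedEffectError("SRM undefined: zero SD of deltas")
    return float(np.mean(d)) / sd


def srm_from_summary(mean_delta: float, sd_delta: float) -> float:
    """SRM from a printed change summary (mean and SD of the differences)."""
    if sd_delta <= 0:
        raise UndefinedEffectError("SRM undefined: SD of deltas must be > 0")
    return mean_delta / sd_delta


#: Cohen's d for the paired design, defined on the differences: mean(Δ)/SD(Δ).
cohens_d = srm


def paired_t_from_summary(
    mean_delta: float, sd_delta: float, n: int
) -> tuple[float, float]:
    """Paired t-test from the summary of the differences.

    Returns (t, two-sided p) with t = mean(Δ)/(SD(Δ)/√n) on n−1 degrees of
    freedom.  Lets printed change columns (mean ± SD, known n) be re-tested
    without subject-level data.
    """
    if n < 2:
        raise InsufficientDataError("paired t needs n >= 2", n=n)
    if sd_delta <= 0:
        raise UndefinedEffectError("degenerate input: SD of deltas must be > 0")
    t = mean_delta / (sd_delta / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def rank_biserial(deltas: Sequence[float]) -> float:
    """Rank-biserial correlation, the Wilcoxon signed-rank effect size.

    Zero deltas are dropped (signed-rank convention); |Δ| are ranked with
    average ranks for ties; returns (W⁺ − W⁻)/(W⁺ + W⁻) ∈ [−1, 1].
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise UndefinedEffectError("rank-biserial undefined: all deltas zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    return (w_pos - w_neg) / (w_pos + w_neg)


# ---------------------------------------------------------------------------
# normality-gated paired comparison
# ---------------------------------------------------------------------------

def paired_comparison(
    pairs: Iterable[OutcomePair], alpha: float = 0.05
) -> PairedComparison:
    """Compare baseline vs follow-up for one outcome across subjects.

    Shapiro–Wilk on the deltas decides the test: normality accepted
    (p > alpha) → paired t with Cohen's d; rejected → Wilcoxon signed-rank
    (zeros dropped, exact distribution for ≤ 25 nonzero deltas, otherwise
    normal approximation with continuity correction) with rank-biserial.
    """
    pairs = list(pairs)
    outcomes = {p.outcome for p in pairs}
    if len(outcomes) != 1:
        raise ValidationError(f"pairs must share one outcome, got {sorted(outcomes)}")
    n = len(pairs)
    if n < 3:
        raise InsufficientDataError("paired comparison needs >= 3 pairs", n=n)
    baseline = np.array([p.baseline for p in pairs], dtype=float)
    deltas = np.array([p.delta for p in pairs], dtype=float)
    if np.all(deltas == 0) or np.std(deltas, ddof=1) == 0:
        raise UndefinedEffectError("all deltas identical: effect size undefined")

    normality_p = float(sps.shapiro(deltas).pvalue)
    srm_value = srm(deltas)
    if normality_p > alpha:
        test_used = "paired_t"
        t, p_value = paired_t_from_summary(
            float(np.mean(deltas)), float(np.std(deltas, ddof=1)), n
        )
        effect = srm_value  # Cohen's d on the differences
    else:
        test_used = "wilcoxon_signed_rank"
        nonzero = deltas[deltas != 0]
        method = "exact" if len(nonzero) <= 25 else "approx"
        res = sps.wilcoxon(
            deltas, zero_method="wilcox", correction=True, method=method
        )
        p_value = float(res.pvalue)
        effect = rank_biserial(deltas)

    b_q1, b_med, b_q3 = np.percentile(baseline, [25, 50, 75])
    d_q1, d_med, d_q3 = np.percentile(deltas, [25, 50, 75])
    return PairedComparison(
        outcome=pairs[0].outcome,
        n=n,
        baseline_mean=float(np.mean(baseline)),
        baseline_sd=float(np.std(baseline, ddof=1)),
        baseline_median=float(b_med),
        baseline_q1=float(b_q1),
        baseline_q3=float(b_q3),
        delta_mean=float(np.mean(deltas)),
        delta_sd=float(np.std(deltas, ddof=1)),
        delta_median=float(d_med),
        delta_q1=float(d_q1),
        delta_q3=float(d_q3),
        normality_p=normality_p,
        test_used=test_used,
        p_value=p_value,
        effect_size=float(effect),
        srm=float(srm_value),
    )


def compare_outcomes(outcomes: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired comparisons for every outcome in a flat outcomes table.

    ``outcomes`` has columns subject_id, outcome, baseline, followup.
    Outcomes whose comparison is undefined (all deltas equal) are skipped.
    """
    rows = []
    for outcome, group in outcomes.groupby("outcome", sort=True):
        pairs = [
            OutcomePair(str(r.subject_id), str(outcome), float(r.baseline), float(r.followup))
            for r in group.itertuples(index=False)
        ]
        try:
            comp = paired_comparison(pairs, alpha=alpha)
        except (UndefinedEffectError, InsufficientDataError):
            continue
        rows.append(vars(comp))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# monthly activity summaries
# ---------------------------------------------------------------------------

def monthly_summary(
    series_list: Sequence[ActivitySeries],
    block_days: int = 30,
) -> pd.DataFrame:
    """Block-wise ("monthly") mean, SD and CV of one metric across subjects.

    Month k for a subject covers days (k−1)·block_days … k·block_days − 1
    counted from that subject's first record.  The mean and SD are pooled
    over all subject-days in the month; the CV is the mean over subjects of
    each subject's within-month SD/mean (subjects with zero within-month
    mean, or fewer than two days in the month, are excluded from the CV).
    """
    if block_days < 7:
        raise ValidationError("block_days must be >= 7")
    metrics = {s.metric for s in series_list}
    if len(metrics) != 1:
        raise ValidationError(f"series must share one metric, got {sorted(metrics)}")
    metric = metrics.pop()

    per_month_values: dict[int, list[np.ndarray]] = {}
    for s in series_list:
        if len(s) == 0:
            raise ValidationError(f"empty series for subject {s.subject_id}")
        offset = (s.dates - s.dates[0]).astype(int)
        month = offset // block_days + 1
        for m in np.unique(month):
            per_month_values.setdefault(int(m), []).append(s.values[month == m])

    rows = []
    for m in sorted(per_month_values):
        chunks = per_month_values[m]
        pooled = np.concatenate(chunks)
        cvs = [
            float(np.std(c, ddof=1) / np.mean(c))
            for c in chunks
            if len(c) >= 2 and np.mean(c) != 0
        ]
        rows.append(
            {
                "metric": metric,
                "month_index": m,
                "n_days": len(pooled),
                "mean": float(np.mean(pooled)),
                "sd": float(np.std(pooled, ddof=1)) if len(pooled) >= 2 else 0.0,
                "cv": float(np.mean(cvs)) if cvs else math.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delta-vs-descriptor correlations
# ---------------------------------------------------------------------------

def pearson_critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical |r| for the Pearson correlation test."""
    t_crit = sps.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t_crit / math.sqrt(t_crit**2 + n - 2))


def descriptor_wide(descriptors: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long descriptor table to one row per subject.

    Columns are named ``<metric>.<descriptor>`` (e.g. ``steps.sd2``).
    """
    blocks = []
    for desc in ("avg", "sd", "sd1", "sd2", "sd12", "afe"):
        wide = descriptors.pivot(index="subject_id", columns="metric", values=desc)
        wide.columns = [f"{m}.{desc}" for m in wide.columns]
        blocks.append(wide)
    out = pd.concat(blocks, axis=1)
    return out[sorted(out.columns)]


def delta_correlations(
    outcomes: pd.DataFrame,
    descriptors: pd.DataFrame,
    policy: str = "auto",
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Correlate clinical-outcome changes with variability descriptors.

    Parameters
    ----------
    outcomes
        Flat table (subject_id, outcome, baseline, followup).
    descriptors
        Long descriptor table as produced by
        :func:`stepvar.poincare.descriptor_table`.
    policy
        ``"pearson"``, ``"spearman"``, or ``"auto"`` — Pearson when
        Shapiro–Wilk accepts normality (p > alpha) for both variables,
        Spearman otherwise.
    bh_adjust
        Append a Benjamini–Hochberg adjusted p-value column.

    Returns one row per (outcome delta, metric.descriptor) pair with
    r, p_value, n and a ``defined`` flag (False when either variable has
    zero variance, in which case r and p are NaN).
    """
    if policy not in ("auto", "pearson", "spearman"):
        raise ValidationError(f"unknown correlation policy {policy!r}")
    wide = descriptor_wide(descriptors)
    deltas = (
        outcomes.assign(delta=outcomes["followup"] - outcomes["baseline"])
        .pivot(index="subject_id", columns="outcome", values="delta")
    )
    joined = deltas.join(wide, how="inner")

    rows = []
    for outcome in deltas.columns:
        for desc_col in wide.columns:
            sub = joined[[outcome, desc_col]].dropna()
            n = len(sub)
            x = sub[outcome].to_numpy(dtype=float)
            y = sub[desc_col].to_numpy(dtype=float)
            if n < 3:
                continue
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(
                    dict(outcome_delta=outcome, descriptor=desc_col,
                         method="undefined", r=math.nan, p_value=math.nan,
                         n=n, defined=False)
                )
                continue
            if policy == "auto":
                normal = (
                    sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
                )
                method = "pearson" if normal else "spearman"
            else:
                method = policy
            if method == "pearson":
                r, p = sps.pearsonr(x, y)
            else:
                r, p = sps.spearmanr(x, y)
            rows.append(
                dict(outcome_delta=outcome, descriptor=desc_col, method=method,
                     r=float(r), p_value=float(p), n=n, defined=True)
            )
    table = pd.DataFrame(
        rows,
        columns=["outcome_delta", "descriptor", "method", "r", "p_value", "n", "defined"],
    )
    if bh_adjust and len(table):
        from statsmodels.stats.multitest import multipletests

        p_adj = np.full(len(table), math.nan)
        mask = table["defined"].to_numpy()
        if mask.any():
            p_adj[mask] = multipletests(
                table.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        table["p_adj_bh"] = p_adj
    return table
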