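"""Diagnostic-test accuracy: confusion tables, exact CIs, group comparisons.

Implements the evaluation stage of the classifier comparison: 2x2
confusion counts of each binary imaging rule against the thrombolysis
eligibility ground truth; sensitivity, specificity, positive and negative
predictive value with exact Clopper-Pearson 95% confidence intervals; the
AUC of a binary test, which reduces to (sensitivity + specificity)/2; and
the group-comparison tests used for baseline tables (Pearson chi-square,
Student's t, Mann-Whitney U).

Exact binomial intervals come from the beta-quantile construction
(statsmodels' ``proportion_confint(method="beta")``); chi-square is
computed without continuity correction, matching the SPSS "Pearson
Chi-Square" convention of clinical papers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

_METRICS = ("sensitivity", "specificity", "ppv", "npv", "auc")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of clinical tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 confusion counts of a binary test against a binary truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionTable":
        """The table with positive and negative classes exchanged."""
        return ConfusionTable(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, as proportions.

    Built by inverting the binomial tail probabilities via beta quantiles;
    the lower bound is 0 when ``successes`` is 0 and the upper bound 1 when
    all trials succeeded.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"need 0 <= successes <= trials, got {successes}/{trials}")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    low, high = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the boundaries where the tail is degenerate
    low = 0.0 if np.isnan(low) else float(low)
    high = 1.0 if np.isnan(high) else float(high)
    return low, high


@dataclass(frozen=True)
class MetricEstimate:
    """One accuracy metric (percent) with its 95% CI and defining counts."""

    value_pct: float
    ci_low_pct: float
    ci_high_pct: float
    numerator: int | None = None
    denominator: int | None = None

    def rounded(self, decimals: int = 1) -> tuple[float, float, float]:
        return tuple(round_half_up(v, decimals)
                     for v in (self.value_pct, self.ci_low_pct, self.ci_high_pct))


class DiagnosticAccuracy:
    """Accuracy metrics of one binary test, with exact CIs and a summary table.

    Percentages are on the 0-100 scale.  Metrics whose denominator is zero
    are reported as ``None`` (undefined), never fabricated.  The AUC of a
    binary test is (sensitivity + specificity)/2; its CI uses the
    Hanley-McNeil standard-error formula (normal approximation, clipped to
    [0, 1]) — exact intervals exist only for the binomial proportions.
    """

    def __init__(self, table: ConfusionTable, level: float = 0.95):
        self.table = table
        self.level = level
        if table.total == 0:
            raise ValueError("empty confusion table")
        t = table
        self.sensitivity = self._proportion(t.tp, t.tp + t.fn)
        self.specificity = self._proportion(t.tn, t.tn + t.fp)
        self.ppv = self._proportion(t.tp, t.tp + t.fp)
        self.npv = self._proportion(t.tn, t.tn + t.fn)
        self.auc = self._auc()

    def _proportion(self, k: int, n: int) -> MetricEstimate | None:
        if n == 0:
            return None
        low, high = clopper_pearson(k, n, self.level)
        return MetricEstimate(
            value_pct=100.0 * k / n,
            ci_low_pct=100.0 * low,
            ci_high_pct=100.0 * high,
            numerator=k,
            denominator=n,
        )

    def _auc(self) -> MetricEstimate | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        a = (self.sensitivity.value_pct + self.specificity.value_pct) / 200.0
        n_pos = self.table.tp + self.table.fn
        n_neg = self.table.tn + self.table.fp
        # Hanley & McNeil SE for an AUC estimated from n_pos/n_neg subjects
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
               + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
        se = float(np.sqrt(max(var, 0.0)))
        z = stats.norm.ppf(0.5 + self.level / 2.0)
        return MetricEstimate(
            value_pct=100.0 * a,
            ci_low_pct=100.0 * max(a - z * se, 0.0),
            ci_high_pct=100.0 * min(a + z * se, 1.0),
        )

    @property
    def false_omission_rate(self) -> float | None:
        """100 - NPV: the rate of truly-positive patients among test negatives."""
        return None if self.npv is None else 100.0 - self.npv.value_pct

    def metric(self, name: str) -> MetricEstimate | None:
        if name not in _METRICS:
            raise KeyError(name)
        return getattr(self, name)

    def summary(self, decimals: int = 1) -> pd.DataFrame:
        """Table-style report: metric, % (half-up rounded), 95% CI bounds."""
        rows = []
        for name in _METRICS:
            est = getattr(self, name)
            if est is None:
                rows.append({"metric": name, "pct": None,
                             "ci_low_pct": None, "ci_high_pct": None})
            else:
                v, lo, hi = est.rounded(decimals)
                rows.append({"metric": name, "pct": v,
                             "ci_low_pct": lo, "ci_high_pct": hi})
        return pd.DataFrame(rows).set_index("metric")

    def __repr__(self) -> str:
        t = self.table
        return (f"DiagnosticAccuracy(tp={t.tp}, fp={t.fp}, fn={t.fn}, tn={t.tn})")


def accuracy_metrics(table: ConfusionTable, level: float = 0.95) -> DiagnosticAccuracy:
    """Sensitivity/specificity/PPV/NPV (exact CIs) and binary-test AUC."""
    return DiagnosticAccuracy(table, level=level)


def confusion_from_cohort(records, classifier_field: str) -> ConfusionTable:
    """Count a labelled cohort against one classifier's calls.

    ``records`` is a list of :class:`~hhmismatch.cohort.CohortRecord` or a
    DataFrame with ``eligible`` and the named classifier column.  Any record
    missing either value aborts with the offending patient ids.
    """
    if isinstance(records, pd.DataFrame):
        from .cohort import frame_to_records
        records = frame_to_records(records)
    if not records:
        raise ValueError("empty cohort")
    missing = [r.patient_id for r in records
               if r.eligible is None or getattr(r, classifier_field, None) is None]
    if missing:
        raise ValueError(
            f"records missing eligibility or '{classifier_field}': {missing}"
        )
    tp = fp = fn = tn = 0
    for r in records:
        positive = bool(getattr(r, classifier_field))
        if r.eligible:
            tp, fn = (tp + 1, fn) if positive else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if positive else (fp, tn + 1)
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# group-comparison tests


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, method: str = "chi2"
) -> float:
    """Two-sided p-value comparing k1/n1 vs k2/n2.

    ``chi2``: Pearson chi-square on the 2x2 table without continuity
    correction; ``fisher``: Fisher's exact test.  A table with an empty
    margin has no defined chi-square and raises.
    """
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if np.any(table < 0):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if method == "fisher":
        return float(stats.fisher_exact(table)[1])
    if method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a table with an empty margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def compare_continuous(x1, x2, method: str = "mann_whitney") -> float:
    """Two-sided p-value comparing two continuous samples.

    ``t_test``: Student's t (equal variances); raises when both samples are
    constant (zero pooled variance).  ``mann_whitney``: U test with the
    normal approximation and tie correction, no continuity correction —
    identical samples then give exactly p = 1.
    """
    x1, x2 = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "t_test":
        if np.var(x1) == 0 and np.var(x2) == 0:
            raise ValueError("degenerate t-test: both samples have zero variance")
        return float(stats.ttest_ind(x1, x2).pvalue)
    if method == "mann_whitney":
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        return float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# baseline ("Table 1"-style) cohort summary


def cohort_summary(records, group_field: str = "eligible") -> pd.DataFrame:
    """Per-group baseline summary with group-comparison p-values.

    Continuous covariates get mean (SD) and median (IQR) plus a
    Mann-Whitney p; binary ones get n (%) plus a chi-square p (Fisher
    fallback for sparse tables).  Missing values are counted per group and
    excluded from the statistics.  Single observations report SD as NaN.
    """
    from .cohort import CohortRecord, records_to_frame

    if records and isinstance(records[0], CohortRecord):
        df = records_to_frame(list(records))
    else:
        df = pd.DataFrame(records)
    if group_field not in df or df[group_field].isna().any():
        raise ValueError(f"every record needs a '{group_field}' value")
    groups = {bool(g): sub for g, sub in df.groupby(group_field)}
    skip = {"patient_id", "stratum", group_field, "hhm_positive",
            "extend_positive", "phantom_seed"}
    rows = []
    for col in df.columns:
        if col in skip:
            continue
        series = df[col]
        values = series.dropna()
        if values.empty:
            continue
        binary = values.isin([0, 1, True, False]).all()
        row = {"covariate": col}
        for label, sub in groups.items():
            v = sub[col].dropna()
            key = "eligible" if label else "noneligible"
            row[f"missing_{key}"] = int(sub[col].isna().sum())
            row[f"n_{key}"] = int(len(v))
            if binary:
                k = int(v.astype(bool).sum())
                row[f"count_{key}"] = k
                row[f"pct_{key}"] = (round_half_up(100.0 * k / len(v), 1)
                                     if len(v) else None)
            else:
                row[f"mean_{key}"] = float(v.mean())
                row[f"sd_{key}"] = float(v.std(ddof=1)) if len(v) > 1 else np.nan
                row[f"median_{key}"] = float(v.median())
                row[f"iqr_{key}"] = (float(v.quantile(0.75) - v.quantile(0.25))
                                     if len(v) > 1 else np.nan)
        if len(groups) == 2:
            g1 = groups[True][col].dropna()
            g0 = groups[False][col].dropna()
            try:
                if binary:
                    row["p_value"] = compare_proportions(
                        int(g1.astype(bool).sum()), len(g1),
                        int(g0.astype(bool).sum()), len(g0))
                else:
                    row["p_value"] = compare_continuous(g1, g0, "mann_whitney")
            except ValueError:
                row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")
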