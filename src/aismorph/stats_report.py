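"""The statistical layer: outlier gating, normality-gated comparisons,
longitudinal paired analysis, and condition-level plasticity summaries.

Branching convention for group comparisons:

* two groups, both normal (Shapiro–Wilk at α=0.05 per group) → paired or
  unpaired t-test;
* two groups, non-normal → Mann–Whitney U;
* more than two groups, normal → one-way ANOVA with Tukey's HSD post-hoc;
* more than two groups, non-normal → Kruskal–Wallis with Dunn's post-hoc
  (Bonferroni-adjusted).

STED-derived data are first gated through an iterated two-sided Grubbs test
(critical values computed from the t-distribution, not a lookup table).
Summaries report mean, median, and SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupData:
    """Measurements with group labels and optional pairing structure."""

    values: np.ndarray
    group_labels: np.ndarray
    pairing_ids: np.ndarray | None = None
    aggregation_level: str = "AIS"     # AIS | OTC | animal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        if self.values.shape != self.group_labels.shape:
            raise ValueError("values and group_labels must align")
        if self.pairing_ids is not None:
            self.pairing_ids = np.asarray(self.pairing_ids)
            if self.pairing_ids.shape != self.values.shape:
                raise ValueError("pairing_ids must align with values")

    def groups(self) -> dict:
        return {g: self.values[self.group_labels == g]
                for g in pd.unique(self.group_labels)}


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    group_summaries: pd.DataFrame
    posthoc: pd.DataFrame | None = None
    flags: tuple = ()


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# Grubbs outlier gate

def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t-distribution."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(values, alpha: float = 0.05):
    """Iterated single-Grubbs removal until no outlier remains at ``alpha``.

    Returns ``(retained, removed)`` arrays; the removal order is the order
    of the ``removed`` array.  Undefined for n < 3.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError("Grubbs test undefined for n < 3")
    removed: list[float] = []
    while x.size >= 3:
        mean, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - mean)
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical_value(x.size, alpha):
            removed.append(x[i])
            x = np.delete(x, i)
        else:
            break
    return x, np.asarray(removed)


# ---------------------------------------------------------------------------
# Group comparisons

def _summaries(groups: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": g, "mean": np.mean(v), "median": np.median(v),
          "sd": np.std(v, ddof=1) if len(v) > 1 else np.nan, "n": len(v)}
         for g, v in groups.items()])


def _all_normal(groups: dict, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk per group; groups too small to test count as normal."""
    for v in groups.values():
        if len(v) >= 3 and np.ptp(v) > 0:
            if stats.shapiro(v).pvalue < alpha:
                return False
    return True


def two_group_ttest(a, b, labels=("A", "B"), paired: bool = False) -> ComparisonResult:
    """Plain (not normality-gated) two-sample t-test with summaries."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    groups = {labels[0]: a, labels[1]: b}
    flags: tuple = ()
    if paired:
        d = a - b
        if np.ptp(d) == 0:
            return ComparisonResult("paired t-test", np.nan, np.nan,
                                    _summaries(groups),
                                    flags=("degenerate-differences",))
        res = stats.ttest_rel(a, b)
        name = "paired t-test"
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            # identical constant groups: difference 0 by construction
            return ComparisonResult("unpaired t-test", 0.0, 1.0,
                                    _summaries(groups))
        res = stats.ttest_ind(a, b)
        name = "unpaired t-test"
    return ComparisonResult(name, float(res.statistic), float(res.pvalue),
                            _summaries(groups), flags=flags)


def dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Dunn's multiple-comparison z-tests on pooled ranks after
    Kruskal–Wallis, Bonferroni-adjusted over all pairwise contrasts."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12 * (n_total - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            se = np.sqrt((n_total * (n_total + 1) / 12 - tie_term)
                         * (1 / sizes[gi] + 1 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else np.nan
            p = min(1.0, 2 * stats.norm.sf(abs(z)) * m) if np.isfinite(z) else np.nan
            rows.append({"group_1": gi, "group_2": gj, "statistic": z,
                         "p_adj": p})
    return pd.DataFrame(rows)


def _tukey_table(groups: dict) -> pd.DataFrame:
    names = list(groups)
    res = stats.tukey_hsd(*[groups[g] for g in names])
    rows = []
    for i, gi in enumerate(names):
        for j, gj in enumerate(names):
            if j <= i:
                continue
            rows.append({"group_1": gi, "group_2": gj,
                         "statistic": res.statistic[i, j],
                         "p_adj": res.pvalue[i, j]})
    return pd.DataFrame(rows)


def compare_groups(data: GroupData, alpha: float = 0.05,
                   normality: str = "auto") -> ComparisonResult:
    """Normality-gated comparison across two or more groups.

    ``test_name`` records the exact branch taken.  Paired two-group designs
    (``pairing_ids`` set) require complete pairs.  ``normality`` may force
    the parametric (``"normal"``) or nonparametric (``"nonnormal"``) branch
    instead of the Shapiro-Wilk gate.
    """
    groups = data.groups()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    if normality == "auto":
        normal = _all_normal(groups, alpha)
    elif normality in ("normal", "nonnormal"):
        normal = normality == "normal"
    else:
        raise ValueError("normality must be 'auto', 'normal' or 'nonnormal'")
    names = list(groups)

    if len(groups) == 2:
        a, b = groups[names[0]], groups[names[1]]
        if data.pairing_ids is not None:
            a, b = _align_pairs(data, names)
            if not normal:
                # the paper's paired analyses are all t-tests; still record
                # non-normality so the reader can judge
                pass
            res = two_group_ttest(a, b, labels=tuple(names), paired=True)
            return res
        if normal:
            return two_group_ttest(a, b, labels=tuple(names), paired=False)
        if np.ptp(np.concatenate([a, b])) == 0:
            return ComparisonResult("mann-whitney", np.nan, 1.0,
                                    _summaries(groups))
        mw = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult("mann-whitney", float(mw.statistic),
                                float(mw.pvalue), _summaries(groups))

    arrays = [groups[g] for g in names]
    if normal:
        f = stats.f_oneway(*arrays)
        return ComparisonResult("one-way ANOVA + Tukey", float(f.statistic),
                                float(f.pvalue), _summaries(groups),
                                posthoc=_tukey_table(groups))
    kw = stats.kruskal(*arrays)
    return ComparisonResult("kruskal-wallis + Dunn", float(kw.statistic),
                            float(kw.pvalue), _summaries(groups),
                            posthoc=dunn_posthoc(groups))


def _align_pairs(data: GroupData, names) -> tuple:
    """Order both groups by pairing id; error on incomplete pairs."""
    mask_a = data.group_labels == names[0]
    mask_b = data.group_labels == names[1]
    ids_a = data.pairing_ids[mask_a]
    ids_b = data.pairing_ids[mask_b]
    if sorted(ids_a.tolist()) != sorted(ids_b.tolist()):
        raise ValueError("paired design requires complete pairs")
    a = data.values[mask_a][np.argsort(ids_a, kind="stable")]
    b = data.values[mask_b][np.argsort(ids_b, kind="stable")]
    return a, b


# ---------------------------------------------------------------------------
# Longitudinal analysis and plasticity summaries

def longitudinal_analysis(week1, week2, pairs=None):
    """Paired comparison and week-2-on-week-1 regression for repeated AIS
    length measurements of the same objects.

    Returns ``(ComparisonResult, RegressionResult)``.  Zero-variance
    differences (e.g. identical sessions) flag the paired test as
    degenerate rather than reporting a p-value.
    """
    w1 = np.asarray(week1, dtype=float)
    w2 = np.asarray(week2, dtype=float)
    if pairs is not None:
        order = np.argsort(np.asarray(pairs), kind="stable")
        w1, w2 = w1[order], w2[order]
    if w1.shape != w2.shape:
        raise ValueError("week1/week2 must pair one-to-one")
    comp = two_group_ttest(w1, w2, labels=("week1", "week2"), paired=True)
    reg = stats.linregress(w1, w2)
    return comp, RegressionResult(float(reg.slope), float(reg.intercept),
                                  float(reg.rvalue ** 2), float(reg.pvalue),
                                  int(w1.size))


def plasticity_summary(measurements: pd.DataFrame, value_col: str = "length_um",
                       condition_col: str = "condition", unit_col: str = "otc",
                       unit: str = "OTC"):
    """Condition table (mean, median, SD over statistical units) with the
    appropriate pairwise comparisons.

    The statistical unit defaults to the per-OTC mean (one value per
    culture); per-AIS pooling is available by passing the AIS id column.
    Conditions with a single unit are summarized but excluded from
    comparisons.
    """
    per_unit = (measurements.groupby([condition_col, unit_col])[value_col]
                .mean().reset_index())
    summary = (per_unit.groupby(condition_col)[value_col]
               .agg(mean="mean", median="median", sd="std", n="count")
               .reset_index())
    summary["unit"] = unit

    usable = {c: g[value_col].to_numpy()
              for c, g in per_unit.groupby(condition_col) if len(g) >= 2}
    comparison = None
    flags = []
    skipped = sorted(set(per_unit[condition_col]) - set(usable))
    if skipped:
        flags.append("comparison-refused:" + ",".join(map(str, skipped)))
    if len(usable) >= 2:
        labels = np.concatenate([[c] * len(v) for c, v in usable.items()])
        values = np.concatenate(list(usable.values()))
        comparison = compare_groups(GroupData(values, labels))
        comparison.flags = comparison.flags + tuple(flags)
    return summary, comparison


__all__ = [
    "GroupData", "ComparisonResult", "RegressionResult",
    "grubbs_outliers", "grubbs_critical_value", "compare_groups",
    "two_group_ttest", "dunn_posthoc", "longitudinal_analysis",
    "plasticity_summary",
]
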