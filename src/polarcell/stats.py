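"""Frequency summaries and condition comparisons.

Per-condition class frequencies are reported two ways, matching how
imaging cohorts are usually analyzed: replicate-level percentages
summarized as mean +/- sample SD and compared with a two-tailed pooled
Student's t test, and pooled 2x2 counts compared with a two-sided
Fisher's exact test (probability-mass rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientReplicates, LabelError

#: significance thresholds rendered as stars (display only)
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    p_value: float
    statistic: float | None = None
    df: float | None = None
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class CohortSummary:
    """Per-condition frequencies with replicate-level dispersion."""

    per_replicate: pd.DataFrame  # condition, replicate, class, n, percent
    per_condition: pd.DataFrame  # condition, class, mean_pct, sd_pct, n
    pooled_counts: pd.DataFrame  # condition x class counts
    comparisons: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------


def fisher_exact_two_sided(table: np.ndarray) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's (with a 1e-7 relative gate on the comparison). A table with a
    zero margin is degenerate and reported as p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return TestResult("fisher_exact", 1.0, degenerate=True)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(sps.hypergeom.pmf(a, n, r1, c1))
    included = pmf <= p_obs * (1.0 + 1e-7)
    if included.all():
        return TestResult("fisher_exact", 1.0)
    return TestResult("fisher_exact", min(float(pmf[included].sum()), 1.0))


def t_test_two_tailed(
    group1: np.ndarray, group2: np.ndarray
) -> TestResult:
    """Unpaired two-tailed Student's t test with pooled variance."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise InsufficientReplicates(
            f"need >= 2 replicates per group, got {len(g1)} and {len(g2)}"
        )
    res = sps.ttest_ind(g1, g2, equal_var=True)
    return TestResult(
        "student_t",
        float(res.pvalue),
        statistic=float(res.statistic),
        df=float(len(g1) + len(g2) - 2),
    )


# ---------------------------------------------------------------------------


def summarize_cohort(
    calls: pd.DataFrame,
    class_column: str,
    include_classes: list[str] | None = None,
    condition_column: str = "condition",
    replicate_column: str = "replicate",
) -> CohortSummary:
    """Aggregate per-cell/per-pair calls into a cohort summary.

    ``calls`` needs one row per scored item with condition, replicate and
    a class label in ``class_column``. ``include_classes`` restricts the
    percentage denominator (e.g. dropping indeterminate divisions);
    percentages over the included classes sum to 100 per replicate. The
    mean and sample SD (ddof=1) are taken across replicates; replicates
    without items are an error, single-replicate conditions report SD as
    missing. Pairwise condition comparisons are run per class with
    Fisher's exact test on pooled counts and a t test on replicate
    percentages.
    """
    required = {condition_column, replicate_column, class_column}
    missing = required - set(calls.columns)
    if missing:
        raise LabelError(f"calls table missing columns: {sorted(missing)}")
    df = calls.copy()
    if df[class_column].isna().any():
        raise LabelError(f"missing labels in column {class_column!r}")
    if include_classes is not None:
        df = df[df[class_column].isin(include_classes)]
    classes = (
        include_classes
        if include_classes is not None
        else sorted(df[class_column].unique())
    )

    counts = (
        df.groupby([condition_column, replicate_column, class_column])
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby([condition_column, replicate_column])["n"].sum()
    counts = counts.merge(
        totals.rename("total").reset_index(),
        on=[condition_column, replicate_column],
    )
    # complete the grid so absent classes count as 0%
    grid = (
        counts[[condition_column, replicate_column, "total"]]
        .drop_duplicates()
        .merge(pd.DataFrame({class_column: classes}), how="cross")
    )
    counts = grid.merge(
        counts, on=[condition_column, replicate_column, class_column,
                    "total"],
        how="left",
    ).fillna({"n": 0})
    counts["n"] = counts["n"].astype(int)
    counts["percent"] = 100.0 * counts["n"] / counts["total"]

    per_condition = (
        counts.groupby([condition_column, class_column])
        .agg(
            mean_pct=("percent", "mean"),
            sd_pct=("percent", lambda s: s.std(ddof=1)),
            n_replicates=("percent", "size"),
            n_items=("n", "sum"),
        )
        .reset_index()
    )

    pooled = (
        df.groupby([condition_column, class_column])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=classes, fill_value=0)
    )

    comparisons = []
    conditions = list(pooled.index)
    for i, cond1 in enumerate(conditions):
        for cond2 in conditions[i + 1:]:
            for cls in classes:
                in1 = int(pooled.loc[cond1, cls])
                in2 = int(pooled.loc[cond2, cls])
                out1 = int(pooled.loc[cond1].sum() - in1)
                out2 = int(pooled.loc[cond2].sum() - in2)
                fisher = fisher_exact_two_sided(
                    np.array([[in1, out1], [in2, out2]])
                )
                pct1 = counts.loc[
                    (counts[condition_column] == cond1)
                    & (counts[class_column] == cls),
                    "percent",
                ].to_numpy()
                pct2 = counts.loc[
                    (counts[condition_column] == cond2)
                    & (counts[class_column] == cls),
                    "percent",
                ].to_numpy()
                row = {
                    "condition_1": cond1,
                    "condition_2": cond2,
                    "class": cls,
                    "fisher_p": fisher.p_value,
                    "fisher_stars": fisher.stars,
                    "n_1": in1 + out1,
                    "n_2": in2 + out2,
                }
                try:
                    ttest = t_test_two_tailed(pct1, pct2)
                    row.update(
                        t_p=ttest.p_value,
                        t_statistic=ttest.statistic,
                        t_df=ttest.df,
                        t_stars=ttest.stars,
                    )
                except InsufficientReplicates:
                    row.update(
                        t_p=np.nan, t_statistic=np.nan, t_df=np.nan,
                        t_stars="",
                    )
                comparisons.append(row)

    return CohortSummary(
        per_replicate=counts,
        per_condition=per_condition,
        pooled_counts=pooled.reset_index(),
        comparisons=comparisons,
    )
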