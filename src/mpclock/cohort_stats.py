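"""Group-comparison statistics for age-acceleration classes.

Builds group x class contingency tables (e.g. AVR vs CABG against
decelerated/normal/accelerated), tests them with Pearson's chi-squared,
runs per-class one-vs-rest post hoc tests with Benjamini-Hochberg
adjustment, stratifies by binary risk factors (generalized
Cochran-Mantel-Haenszel across strata), estimates per-class multinomial
odds ratios, and compares continuous outcomes across class-by-group
cells with Welch tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .bioage import CLASS_LABELS
from .io import CohortTable

__all__ = [
    "ClassContingency",
    "TestResult",
    "build_contingency",
    "pearson_chi2",
    "posthoc_bh",
    "cmh_test",
    "multinomial_group_or",
    "stratified_ratio_table",
    "compare_continuous",
    "round_ratio",
]


@dataclass(frozen=True)
class ClassContingency:
    """A groups x classes count table, optionally tagged with a stratum."""

    counts: pd.DataFrame
    stratum: Optional[str] = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts in contingency table")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError(
                f"contingency table must be at least 2x2, got {self.counts.shape}"
            )

    @property
    def row_labels(self) -> list:
        return list(self.counts.index)

    @property
    def col_labels(self) -> list:
        return list(self.counts.columns)

    def row_percentages(self, decimals: Optional[int] = None) -> pd.DataFrame:
        pct = self.counts.div(self.counts.sum(axis=1), axis=0) * 100.0
        return pct.round(decimals) if decimals is not None else pct


@dataclass(frozen=True)
class TestResult:
    """A test statistic with raw and (optionally) adjusted p-values."""

    statistic: float
    df: int
    p_raw: float
    p_adjusted: Optional[float] = None
    adjust_method: Optional[str] = None
    effects: dict = field(default_factory=dict)


def build_contingency(
    delta_table: pd.DataFrame,
    cohort: CohortTable,
    by: str = "group",
    stratify_by: Optional[str] = None,
    class_order: Sequence[str] = CLASS_LABELS,
):
    """Cross-tabulate band classes against a cohort grouping column.

    Returns a single :class:`ClassContingency`, or a dict of them per
    stratum level when ``stratify_by`` names a cohort column.
    """
    meta = cohort.data.loc[delta_table.index]
    groups = meta[by]
    classes = pd.Categorical(
        delta_table["class"], categories=list(class_order), ordered=True
    )

    def tab(mask) -> ClassContingency:
        ct = pd.crosstab(groups[mask], classes[np.asarray(mask)], dropna=False)
        ct = ct.reindex(columns=list(class_order), fill_value=0)
        ct = ct.loc[ct.sum(axis=1) > 0]
        if ct.shape[0] == 0:
            raise ValueError("empty group: no samples to tabulate")
        return ct

    if stratify_by is None:
        return ClassContingency(tab(np.ones(len(meta), dtype=bool)))
    out = {}
    for level in pd.unique(meta[stratify_by].dropna()):
        mask = (meta[stratify_by] == level).to_numpy()
        out[level] = ClassContingency(tab(mask), stratum=f"{stratify_by}={level}")
    if not out:
        raise ValueError(f"stratification column {stratify_by!r} is all-missing")
    return out


def pearson_chi2(table: ClassContingency) -> TestResult:
    """Classic Pearson chi-squared of independence, no continuity correction."""
    counts = table.counts.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(statistic=float(chi2), df=int(dof), p_raw=float(p))


def posthoc_bh(table: ClassContingency) -> dict[str, TestResult]:
    """Per-class one-vs-rest 2x2 chi-squared tests, BH-adjusted across classes.

    For a 2 x J table each class j is collapsed against the rest and
    tested for association with the group; the J raw p-values receive a
    Benjamini-Hochberg step-up adjustment.  Effects carry the two row
    percentages and their ratio (first row over second).
    """
    counts = table.counts
    if counts.shape[0] != 2 or counts.shape[1] < 3:
        raise ValueError("post hoc scheme expects a 2 x J table with J >= 3")
    row_tot = counts.sum(axis=1).to_numpy(dtype=float)
    raw, effects = [], []
    for cls in counts.columns:
        col = counts[cls].to_numpy(dtype=float)
        collapsed = np.column_stack([col, row_tot - col])
        if (collapsed.sum(axis=0) == 0).any():
            raise ValueError(f"zero margin in collapsed table for class {cls!r}")
        chi2, p, _, _ = stats.chi2_contingency(collapsed, correction=False)
        raw.append(float(p))
        pct = 100.0 * col / row_tot
        effects.append(
            {
                f"pct_{counts.index[0]}": float(pct[0]),
                f"pct_{counts.index[1]}": float(pct[1]),
                "ratio": float(pct[0] / pct[1]) if pct[1] > 0 else np.inf,
                "statistic": float(chi2),
            }
        )
    adjusted = multipletests(raw, method="fdr_bh")[1]
    return {
        cls: TestResult(
            statistic=eff.pop("statistic"),
            df=1,
            p_raw=p,
            p_adjusted=float(q),
            adjust_method="benjamini-hochberg",
            effects=eff,
        )
        for cls, p, q, eff in zip(counts.columns, raw, adjusted, effects)
    }


def cmh_test(tables: Sequence[ClassContingency]) -> TestResult:
    """Generalized Cochran-Mantel-Haenszel test for 2 x J x K strata.

    Sums the observed-minus-expected vectors of the first row's first
    J-1 cells across strata with their pooled hypergeometric covariance;
    the quadratic form is chi-squared with J-1 degrees of freedom under
    conditional independence of group and class in every stratum.
    """
    if len(tables) == 0:
        raise ValueError("need at least one stratum")
    J = tables[0].counts.shape[1]
    diff = np.zeros(J - 1)
    cov = np.zeros((J - 1, J - 1))
    for t in tables:
        c = t.counts.to_numpy(dtype=float)
        if c.shape[0] != 2 or c.shape[1] != J:
            raise ValueError("all strata must be 2 x J with the same classes")
        N = c.sum()
        row1 = c.sum(axis=1)[0]
        row2 = c.sum(axis=1)[1]
        colsum = c.sum(axis=0)
        if N < 2 or row1 == 0 or row2 == 0 or (colsum == 0).all():
            raise ValueError(f"degenerate stratum {t.stratum!r}")
        obs = c[0, : J - 1]
        exp = row1 * colsum[: J - 1] / N
        p = colsum[: J - 1] / N
        V = (
            row1
            * row2
            / (N - 1.0)
            * (np.diag(p) - np.outer(p, p))
        )
        diff += obs - exp
        cov += V
    stat = float(diff @ np.linalg.solve(cov, diff))
    dfree = J - 1
    p_val = float(stats.chi2.sf(stat, dfree))
    return TestResult(statistic=stat, df=dfree, p_raw=p_val)


def multinomial_group_or(
    table: ClassContingency,
    reference_class: str = "normal",
    reference_group: str = "AVR",
) -> dict[str, TestResult]:
    """Per-class odds ratios from a multinomial logit of class on group.

    Fits class ~ group (maximum likelihood) on the expanded table; for
    the saturated 2 x J design each odds ratio equals the cross-ratio of
    counts.  Reported per non-reference class as OR of being in that
    class versus the reference class for the non-reference group
    relative to ``reference_group``, with a Wald p-value.
    """
    counts = table.counts
    if counts.shape[0] != 2:
        raise ValueError("multinomial group model expects exactly 2 groups")
    if reference_class not in counts.columns:
        raise KeyError(f"reference class {reference_class!r} not in table")
    if reference_group not in counts.index:
        raise KeyError(f"reference group {reference_group!r} not in table")
    other_group = [g for g in counts.index if g != reference_group][0]
    classes = [reference_class] + [c for c in counts.columns if c != reference_class]

    # expand to one row per subject: y = class code, x = group indicator
    y_codes, xs = [], []
    for gi, grp in enumerate((reference_group, other_group)):
        for ci, cls in enumerate(classes):
            n = int(counts.loc[grp, cls])
            y_codes.extend([ci] * n)
            xs.extend([gi] * n)
    y = np.asarray(y_codes)
    X = sm.add_constant(np.asarray(xs, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(y, X).fit(disp=0, maxiter=200)

    results: dict[str, TestResult] = {}
    for j, cls in enumerate(classes[1:]):
        a = counts.loc[reference_group, reference_class]
        b = counts.loc[reference_group, cls]
        c = counts.loc[other_group, reference_class]
        d = counts.loc[other_group, cls]
        estimable = min(a, b, c, d) > 0
        beta = float(fit.params[1, j])
        se = float(fit.bse[1, j])
        p = float(fit.pvalues[1, j])
        results[cls] = TestResult(
            statistic=beta / se if se > 0 else np.nan,
            df=1,
            p_raw=p,
            effects={
                "odds_ratio": float(np.exp(beta)) if estimable else np.nan,
                "log_or_se": se,
                "estimable": bool(estimable),
                "vs_class": reference_class,
                "group": f"{other_group} vs {reference_group}",
            },
        )
    return results


def round_ratio(x: float) -> float:
    """Two-significant-figure display rounding used in the ratio tables."""
    if not np.isfinite(x) or x == 0:
        return float(x)
    from math import floor, log10

    digits = 1 - floor(log10(abs(x)))
    return round(x, digits)


def stratified_ratio_table(
    delta_table: pd.DataFrame,
    cohort: CohortTable,
    risk_factor: str,
    by: str = "group",
) -> pd.DataFrame:
    """Per-stratum class percentages, group ratios, and BH post hoc p-values.

    For each level of a binary risk factor: the class distribution (%)
    within each group, the first-group/second-group percentage ratio per
    class, and the BH-adjusted one-vs-rest chi-squared p-value.
    """
    strata = build_contingency(delta_table, cohort, by=by, stratify_by=risk_factor)
    rows = []
    for level, tab in sorted(strata.items(), key=lambda kv: str(kv[0])):
        post = posthoc_bh(tab)
        pct = tab.row_percentages()
        g1, g2 = tab.counts.index[0], tab.counts.index[1]
        for cls in tab.counts.columns:
            res = post[cls]
            rows.append(
                {
                    "stratum": f"{risk_factor}={level}",
                    "class": cls,
                    f"pct_{g1}": round(float(pct.loc[g1, cls]), 1),
                    f"pct_{g2}": round(float(pct.loc[g2, cls]), 1),
                    "ratio": float(pct.loc[g1, cls] / pct.loc[g2, cls])
                    if pct.loc[g2, cls] > 0
                    else np.inf,
                    "ratio_display": round_ratio(
                        float(pct.loc[g1, cls] / pct.loc[g2, cls])
                    )
                    if pct.loc[g2, cls] > 0
                    else np.inf,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                }
            )
    return pd.DataFrame(rows)


def compare_continuous(
    cohort: CohortTable,
    outcome: str,
    delta_table: pd.DataFrame,
    *,
    classes: Sequence[str] = ("accelerated", "decelerated"),
    by: str = "group",
) -> pd.DataFrame:
    """Pairwise Welch tests of a continuous outcome across class x group cells.

    Cells are the combinations of the selected band classes and cohort
    groups (by default accelerated/decelerated x the groups present);
    all pairwise two-sided unequal-variance t-tests are BH-adjusted.
    """
    meta = cohort.data.loc[delta_table.index]
    frame = pd.DataFrame(
        {
            "outcome": pd.to_numeric(meta[outcome], errors="coerce"),
            "group": meta[by],
            "class": delta_table["class"],
        }
    ).dropna()
    cells: dict[str, np.ndarray] = {}
    for grp in pd.unique(frame["group"]):
        for cls in classes:
            sel = frame[(frame["group"] == grp) & (frame["class"] == cls)]
            if len(sel):
                cells[f"{grp}:{cls}"] = sel["outcome"].to_numpy(dtype=float)
    labels = sorted(cells)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            xa, xb = cells[a], cells[b]
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError(
                    f"cell {a if len(xa) < 2 else b} has fewer than 2 observations"
                )
            if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa.mean() == xb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {
                    "cell_a": a,
                    "cell_b": b,
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "statistic": float(t),
                    "p_raw": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out
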