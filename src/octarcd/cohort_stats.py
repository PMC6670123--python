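"""Cohort statistics: contingency tests, summary t/ANOVA, subgroup tables, OLS.

Choices that matter for reproducing printed tables:

* Pearson chi-square carries **no** continuity correction;
* two-sample t-tests use the pooled (equal-variance) Student form by
  default, Welch behind a flag;
* dichotomization sends values exactly at the cutoff to the high arm;
* no multiple-testing correction is applied anywhere; significance flags
  mirror raw 0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ContingencyTable",
    "SummaryStats",
    "TestResult",
    "SubgroupRule",
    "RegressionResult",
    "chi_square",
    "pooled_t_from_summary",
    "one_way_anova",
    "anova_from_summary",
    "dichotomize",
    "subgroup_analysis",
    "multiple_regression",
    "significance_flag",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("grand total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class SummaryStats:
    """Mean +/- SD summary of one sample."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class SubgroupRule:
    """Dichotomization rule: split the diabetic cohort at a cutoff."""

    variable: str
    cutoff: float
    low_label: str = ""
    high_label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if not self.low_label:
            object.__setattr__(self, "low_label", f"{self.variable} < {self.cutoff}")
        if not self.high_label:
            object.__setattr__(self, "high_label", f"{self.variable} > {self.cutoff}")


@dataclass(frozen=True)
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    df_resid: float


def significance_flag(p: float) -> str:
    """Footnote-style flag: '' / a (<0.05) / b (<0.01) / c (<0.001)."""
    if p < 0.001:
        return "c"
    if p < 0.01:
        return "b"
    if p < 0.05:
        return "a"
    return ""


def chi_square(table: ContingencyTable | list | tuple | np.ndarray) -> TestResult:
    """Pearson chi-square on an r x c table, no continuity correction."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(tuple(tuple(int(v) for v in row) for row in table))
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column total; expected counts undefined")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult(
        statistic=float(chi2), df=float(dof), p_value=float(p), test_name="chi_square"
    )


def pooled_t_from_summary(
    a: SummaryStats, b: SummaryStats, welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test from mean/SD/n summaries.

    Pooled-variance Student form by default; ``welch=True`` uses the
    Welch-Satterthwaite df instead.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TestResult(0.0, float(a.n + b.n - 2), 1.0, "pooled_t")
        log.warning("both SDs zero with unequal means; p = 0 by convention")
        return TestResult(math.inf, float(a.n + b.n - 2), 0.0, "pooled_t")
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        t = (a.mean - b.mean) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        name = "welch_t"
    else:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        t = (a.mean - b.mean) / math.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = float(a.n + b.n - 2)
        name = "pooled_t"
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=df, p_value=float(p), test_name=name)


def _anova_from_ss(
    ss_between: float, ss_within: float, df_between: float, df_within: float
) -> TestResult:
    if ss_within <= 0:
        if ss_between <= 1e-12:
            return TestResult(0.0, (df_between, df_within), 1.0, "one_way_anova")
        log.warning("zero within-group variance with unequal means; p = 0")
        return TestResult(math.inf, (df_between, df_within), 0.0, "one_way_anova")
    f = (ss_between / df_between) / (ss_within / df_within)
    p = stats.f.sf(f, df_between, df_within)
    return TestResult(
        statistic=float(f),
        df=(float(df_between), float(df_within)),
        p_value=float(p),
        test_name="one_way_anova",
    )


def one_way_anova(groups: list[np.ndarray]) -> TestResult:
    """One-way ANOVA on raw samples (F = MS_between / MS_within)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n_total = len(all_vals)
    return _anova_from_ss(ss_between, ss_within, k - 1, n_total - k)


def anova_from_summary(groups: list[SummaryStats]) -> TestResult:
    """One-way ANOVA reconstructed from mean/SD/n summaries.

    Matches :func:`one_way_anova` exactly on raw samples sharing the same
    summaries (SDs interpreted as sample SDs, ddof=1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two group summaries")
    n_total = sum(g.n for g in groups)
    grand = sum(g.n * g.mean for g in groups) / n_total
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ss_within = sum((g.n - 1) * g.sd**2 for g in groups)
    k = len(groups)
    return _anova_from_ss(ss_between, ss_within, k - 1, n_total - k)


@dataclass(frozen=True)
class DichotomyResult:
    """Two diabetic arms plus their NDR/MDR composition bookkeeping."""

    rule: SubgroupRule
    low: pd.DataFrame
    high: pd.DataFrame
    composition: dict
    n_missing: int


DIABETIC_GROUPS = ("NDR", "MDR")


def _arm_composition(arm: pd.DataFrame) -> dict:
    n_ndr = int((arm["group"] == "NDR").sum())
    n_mdr = int((arm["group"] == "MDR").sum())
    total = n_ndr + n_mdr
    if total == 0:
        return {"ndr_n": 0, "mdr_n": 0, "ndr_pct": None, "mdr_pct": None,
                "undefined": True}
    return {
        "ndr_n": n_ndr,
        "mdr_n": n_mdr,
        "ndr_pct": round(100.0 * n_ndr / total, 1),
        "mdr_pct": round(100.0 * n_mdr / total, 1),
        "undefined": False,
    }


def dichotomize(cohort: pd.DataFrame, rule: SubgroupRule) -> DichotomyResult:
    """Split diabetic rows at the rule's cutoff (ties go to the high arm).

    Rows with a missing value for the rule variable are excluded from both
    arms (their count is logged and returned). Control rows are not part of
    either arm; they remain available as the comparison group.
    """
    if rule.variable not in cohort.columns:
        raise KeyError(f"variable {rule.variable!r} not in cohort table")
    diabetic = cohort[cohort["group"].isin(DIABETIC_GROUPS)]
    vals = pd.to_numeric(diabetic[rule.variable], errors="coerce")
    missing = vals.isna()
    n_missing = int(missing.sum())
    if n_missing:
        log.info(
            "dichotomize(%s): excluded %d rows with missing values",
            rule.variable,
            n_missing,
        )
    low = diabetic[~missing & (vals < rule.cutoff)]
    high = diabetic[~missing & (vals >= rule.cutoff)]
    composition = {
        rule.low_label: _arm_composition(low),
        rule.high_label: _arm_composition(high),
    }
    return DichotomyResult(
        rule=rule, low=low, high=high, composition=composition, n_missing=n_missing
    )


def subgroup_analysis(
    cohort: pd.DataFrame,
    rules: list[SubgroupRule],
    layers: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Risk-factor subgroup report: each arm vs control, and arm vs arm.

    ``layers`` maps layer name -> RCD column (defaults to SRCL/DRCL
    columns). Each comparison is a one-way ANOVA (two groups); arms with
    n < 2 are reported as not testable (NaN p with a note).
    """
    if layers is None:
        layers = {"SRCL": "rcd_srcl", "DRCL": "rcd_drcl"}
    control = cohort[cohort["group"] == "Control"]
    records = []
    for rule in rules:
        d = dichotomize(cohort, rule)
        for arm_name, arm in ((rule.low_label, d.low), (rule.high_label, d.high)):
            comp = d.composition[arm_name]
            rec = {
                "rule": rule.variable,
                "arm": arm_name,
                "n": len(arm),
                "ndr_pct": comp["ndr_pct"],
                "mdr_pct": comp["mdr_pct"],
            }
            for layer, col in layers.items():
                vals = arm[col].dropna().to_numpy()
                ctrl = control[col].dropna().to_numpy()
                rec[f"{layer}_mean"] = vals.mean() if len(vals) else np.nan
                rec[f"{layer}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
                if len(vals) >= 2 and len(ctrl) >= 2:
                    r = one_way_anova([vals, ctrl])
                    rec[f"{layer}_p_vs_control"] = r.p_value
                    rec[f"{layer}_flag_vs_control"] = significance_flag(r.p_value)
                else:
                    rec[f"{layer}_p_vs_control"] = np.nan
                    rec[f"{layer}_flag_vs_control"] = "not testable"
            records.append(rec)
        # arm-vs-arm row
        rec = {"rule": rule.variable, "arm": "low vs high", "n": len(d.low) + len(d.high),
               "ndr_pct": None, "mdr_pct": None}
        for layer, col in layers.items():
            lo = d.low[col].dropna().to_numpy()
            hi = d.high[col].dropna().to_numpy()
            rec[f"{layer}_mean"] = np.nan
            rec[f"{layer}_sd"] = np.nan
            if len(lo) >= 2 and len(hi) >= 2:
                r = one_way_anova([lo, hi])
                rec[f"{layer}_p_vs_control"] = r.p_value
                rec[f"{layer}_flag_vs_control"] = significance_flag(r.p_value)
            else:
                rec[f"{layer}_p_vs_control"] = np.nan
                rec[f"{layer}_flag_vs_control"] = "not testable"
        records.append(rec)
    columns = ["rule", "arm", "n", "ndr_pct", "mdr_pct"] + [
        f"{layer}_{suffix}"
        for layer in layers
        for suffix in ("mean", "sd", "p_vs_control", "flag_vs_control")
    ]
    return pd.DataFrame.from_records(records, columns=columns)


def multiple_regression(
    cohort: pd.DataFrame, y_column: str, covariate_columns: list[str]
) -> RegressionResult:
    """OLS of an RCD column on covariates (intercept added, complete-case).

    Raises
    ------
    ValueError
        If the complete-case sample is too small or the design matrix is
        rank deficient (the collinear columns are named).
    """
    cols = [y_column] + list(covariate_columns)
    data = cohort[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n_dropped = len(cohort) - len(data)
    if n_dropped:
        log.info("multiple_regression: dropped %d incomplete rows", n_dropped)
    if len(data) < len(covariate_columns) + 2:
        raise ValueError(
            f"only {len(data)} complete-case rows for "
            f"{len(covariate_columns)} covariates"
        )
    X = sm.add_constant(data[covariate_columns], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns via pairwise correlation / zero variance
        bad = []
        arr = data[covariate_columns]
        for i, ci in enumerate(covariate_columns):
            if arr[ci].std() == 0:
                bad.append(ci)
                continue
            for cj in covariate_columns[i + 1 :]:
                if arr[cj].std() > 0 and abs(arr[ci].corr(arr[cj])) > 1 - 1e-10:
                    bad.extend([ci, cj])
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            + (", ".join(dict.fromkeys(bad)) or "unidentified")
        )
    fit = sm.OLS(data[y_column], X).fit()
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        rsquared=float(fit.rsquared),
        df_resid=float(fit.df_resid),
    )
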