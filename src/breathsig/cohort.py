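"""Clinical cohort handling: BDR endpoint labeling and group comparisons.

Bronchodilator responsiveness (BDR) follows the 2022 ERS/ATS criterion: a
positive test is an increase of FEV1 or FVC greater than 10% of the predicted
value after salbutamol. Group comparisons route each variable through a
decision tree — Shapiro-Wilk normality in every group decides parametric
(Welch's t / ANOVA) versus non-parametric (Mann-Whitney U / Kruskal-Wallis)
tests for continuous variables; categorical variables use Pearson's chi-square,
or Fisher's exact test when any expected cell count is below 5. Raw p-values
are reported; no multiplicity correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COHORT_COLUMNS = [
    "group", "fev1_pct_pred", "fvc_pct_pred", "delta_fev1_pct_pred",
    "delta_fvc_pct_pred", "feno_ppb", "eos_10e9_l", "ige_iu_ml", "smoking", "bmi",
]


class LabelingError(ValueError):
    pass


class StatTestError(ValueError):
    pass


@dataclass
class GroupTestResult:
    variable: str
    groups: tuple[str, ...]
    test_used: str   # welch | anova | mannwhitney | kruskal | chi2 | fisher
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    normality_p: dict[str, float] | None = None


def label_bdr(record, threshold: float = 10.0, strict: bool = True) -> str:
    """Label bronchodilator responsiveness from post-salbutamol spirometry.

    ``record`` is any mapping (dict, Series, dataclass via vars()) providing
    ``delta_fev1_pct_pred`` and/or ``delta_fvc_pct_pred`` in percent-predicted
    units. Positive iff either delta exceeds ``threshold`` (strictly, by
    default).
    """
    if not isinstance(record, (dict, pd.Series)):
        record = vars(record)
    deltas = [record.get(k) for k in ("delta_fev1_pct_pred", "delta_fvc_pct_pred")]
    deltas = [d for d in deltas if d is not None and not (isinstance(d, float) and math.isnan(d))]
    if not deltas:
        raise LabelingError("both delta_fev1_pct_pred and delta_fvc_pct_pred are missing")
    cmp = (lambda d: d > threshold) if strict else (lambda d: d >= threshold)
    return "positive" if any(cmp(float(d)) for d in deltas) else "negative"


def _is_continuous(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series)


def compare_groups(table: pd.DataFrame, variable: str, groups=None,
                   group_col: str = "group", alpha_normality: float = 0.05
                   ) -> GroupTestResult:
    """Test ``variable`` across groups with the routed test.

    Missing values are excluded pairwise per variable; per-group counts are
    reported on the result.
    """
    if variable not in table.columns:
        raise StatTestError(f"unknown variable {variable!r}")
    if groups is None:
        groups = tuple(sorted(table[group_col].dropna().unique()))
    else:
        groups = tuple(groups)
    if len(groups) < 2:
        raise StatTestError("at least two groups are required")
    sub = table[table[group_col].isin(groups)][[group_col, variable]].dropna()

    if _is_continuous(sub[variable]):
        samples = [sub.loc[sub[group_col] == g, variable].to_numpy(dtype=float)
                   for g in groups]
        n_per = {g: len(s) for g, s in zip(groups, samples)}
        if any(len(s) < 3 for s in samples):
            raise StatTestError("each group needs at least 3 observations")
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            raise StatTestError(f"variable {variable!r} is constant across groups")
        norm_p = {}
        for g, s in zip(groups, samples):
            if np.ptp(s) == 0:
                norm_p[g] = 0.0  # degenerate within group: treat as non-normal
            else:
                norm_p[g] = float(stats.shapiro(s).pvalue)
        normal = all(p > alpha_normality for p in norm_p.values())
        if len(groups) == 2:
            if normal:
                res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
                test = "welch"
            else:
                res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
                test = "mannwhitney"
        else:
            if normal:
                res = stats.f_oneway(*samples)
                test = "anova"
            else:
                res = stats.kruskal(*samples)
                test = "kruskal"
        return GroupTestResult(variable, groups, test, float(res.statistic),
                               float(res.pvalue), n_per, norm_p)

    # categorical route
    contingency = pd.crosstab(sub[group_col], sub[variable])
    contingency = contingency.loc[[g for g in groups if g in contingency.index]]
    if contingency.shape[0] < 2 or contingency.shape[1] < 2:
        raise StatTestError(f"variable {variable!r} is degenerate in the selected groups")
    n_per = {g: int(contingency.loc[g].sum()) for g in contingency.index}
    observed = contingency.to_numpy()
    expected = stats.contingency.expected_freq(observed)
    if (expected < 5).any():
        res = stats.fisher_exact(observed)
        return GroupTestResult(variable, groups, "fisher", float(res.statistic),
                               float(res.pvalue), n_per)
    chi2 = stats.chi2_contingency(observed)
    return GroupTestResult(variable, groups, "chi2", float(chi2.statistic),
                           float(chi2.pvalue), n_per)


def summarize_cohort(table: pd.DataFrame, variables=None, groups=None,
                     group_col: str = "group") -> pd.DataFrame:
    """Tidy table of routed group comparisons for a list of variables."""
    if variables is None:
        variables = [c for c in table.columns if c != group_col]
    rows = []
    for v in variables:
        try:
            r = compare_groups(table, v, groups=groups, group_col=group_col)
        except StatTestError:
            continue
        rows.append({"variable": r.variable, "test": r.test_used,
                     "statistic": r.statistic, "p_value": r.p_value,
                     **{f"n_{g}": n for g, n in r.n_per_group.items()}})
    return pd.DataFrame(rows)
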