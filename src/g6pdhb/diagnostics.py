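"""Stratified diagnostic performance of HbA1c against the OGTT standard.

HbA1c >= 5.7% is the index test, OGTT abnormal glucose tolerance the
reference. Sensitivity and specificity are computed per G6PD-status stratum
with Wilson score intervals (well behaved at 0/n and n/n). The mean-shift
re-evaluation adds the deficiency-associated HbA1c deficit back to deficient
participants' values and reclassifies at the unchanged threshold, which is
equivalent to lowering the threshold by the shift for that stratum only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .glycemia import _HBA1C_TOL

__all__ = [
    "AdjustmentReport",
    "ConfusionCounts",
    "DiagnosticSummary",
    "GroupComparison",
    "GroupShift",
    "adjusted_hba1c_evaluation",
    "build_confusion",
    "compare_groups",
    "estimate_group_shift",
    "sensitivity_specificity",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts of HbA1c flag (index) vs OGTT Abnl-GT (reference)."""

    tp: int
    fp: int
    tn: int
    fn: int
    stratum: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticSummary:
    stratum: str
    sensitivity: Optional[float]
    specificity: Optional[float]
    wilson_ci_sens: Optional[tuple[float, float]]
    wilson_ci_spec: Optional[tuple[float, float]]
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "stratum": self.stratum,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "wilson_ci_sens": self.wilson_ci_sens,
            "wilson_ci_spec": self.wilson_ci_spec,
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
        }


def build_confusion(df: pd.DataFrame,
                    strata: Sequence[str] = ("DEFICIENT", "NORMAL"),
                    status_col: str = "status",
                    index_col: str = "hba1c_abnl",
                    reference_col: str = "abnl_gt",
                    ) -> tuple[list[ConfusionCounts], pd.DataFrame]:
    """Per-stratum 2x2 counts of the HbA1c flag against OGTT Abnl-GT.

    Rows with INDETERMINATE status or a missing classification are excluded
    and returned in a log. Totals over the returned strata plus the log equal
    the input row count.
    """
    log_rows = []
    usable = df
    indet = usable[status_col] == "INDETERMINATE"
    for pid in usable.loc[indet, "participant_id"]:
        log_rows.append({"participant_id": pid, "reason": "indeterminate G6PD status"})
    usable = usable.loc[~indet]
    missing = usable[index_col].isna() | usable[reference_col].isna()
    for pid in usable.loc[missing, "participant_id"]:
        log_rows.append({"participant_id": pid, "reason": "missing classification"})
    usable = usable.loc[~missing]

    out = []
    for stratum in strata:
        sub = usable.loc[usable[status_col] == stratum]
        idx = sub[index_col].astype(bool)
        ref = sub[reference_col].astype(bool)
        out.append(ConfusionCounts(
            tp=int((idx & ref).sum()), fp=int((idx & ~ref).sum()),
            tn=int((~idx & ~ref).sum()), fn=int((~idx & ref).sum()),
            stratum=stratum))
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return out, log


def _wilson(count: int, nobs: int, ci_level: float) -> Optional[tuple[float, float]]:
    if nobs == 0:
        return None
    lo, hi = proportion_confint(count, nobs, alpha=1 - ci_level, method="wilson")
    return (float(lo), float(hi))


def sensitivity_specificity(c: ConfusionCounts, ci_level: float = 0.95,
                            ) -> DiagnosticSummary:
    """Sensitivity tp/(tp+fn), specificity tn/(tn+fp), Wilson intervals.

    A metric whose denominator is zero is None (never reported as 0).
    """
    n_pos, n_neg = c.tp + c.fn, c.tn + c.fp
    sens = c.tp / n_pos if n_pos else None
    spec = c.tn / n_neg if n_neg else None
    return DiagnosticSummary(
        stratum=c.stratum, sensitivity=sens, specificity=spec,
        wilson_ci_sens=_wilson(c.tp, n_pos, ci_level),
        wilson_ci_spec=_wilson(c.tn, n_neg, ci_level),
        counts=c)


@dataclass
class AdjustmentReport:
    before: DiagnosticSummary
    after: DiagnosticSummary
    shift: float
    n_stratum: int
    empty: bool


def adjusted_hba1c_evaluation(df: pd.DataFrame, shift: float,
                              hba1c_threshold: float = 5.7,
                              target_stratum: str = "DEFICIENT",
                              status_col: str = "status",
                              ) -> AdjustmentReport:
    """Re-evaluate HbA1c in one stratum after adding back the mean shift.

    Stratum members' HbA1c values are incremented by ``shift`` and
    reclassified at the unchanged threshold; non-members are untouched.
    Returns before/after diagnostics for the target stratum.
    """
    if shift < 0:
        raise ValueError("shift must be nonnegative")
    sub = df.loc[df[status_col] == target_stratum]
    ref = sub["abnl_gt"].astype(bool) if len(sub) else pd.Series(dtype=bool)

    def confusion(values: pd.Series) -> ConfusionCounts:
        idx = values >= hba1c_threshold - _HBA1C_TOL
        return ConfusionCounts(
            tp=int((idx & ref).sum()), fp=int((idx & ~ref).sum()),
            tn=int((~idx & ~ref).sum()), fn=int((~idx & ref).sum()),
            stratum=target_stratum)

    before = sensitivity_specificity(confusion(sub["hba1c"]))
    after = sensitivity_specificity(confusion(sub["hba1c"] + shift))
    return AdjustmentReport(before=before, after=after, shift=shift,
                            n_stratum=len(sub), empty=len(sub) == 0)


@dataclass
class GroupShift:
    """Deficient vs normal-activity group comparison of one variable."""

    variable: str
    n_deficient: int
    mean_deficient: Optional[float]
    sd_deficient: Optional[float]
    range_deficient: Optional[tuple[float, float]]
    n_normal: int
    mean_normal: Optional[float]
    sd_normal: Optional[float]
    range_normal: Optional[tuple[float, float]]
    difference: Optional[float]  # mean_normal - mean_deficient
    welch_t: Optional[float]
    p_value: Optional[float]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def estimate_group_shift(df: pd.DataFrame, variable: str = "hba1c",
                         status_col: str = "status") -> GroupShift:
    """Mean difference in ``variable`` between normal-activity and deficient
    groups, with a Welch (unequal-variance) t-test."""
    g_def = df.loc[df[status_col] == "DEFICIENT", variable].dropna().to_numpy(float)
    g_norm = df.loc[df[status_col] == "NORMAL", variable].dropna().to_numpy(float)

    def summarize(x: np.ndarray) -> tuple:
        if len(x) == 0:
            return None, None, None
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) >= 2 else None
        return mean, sd, (float(np.min(x)), float(np.max(x)))

    m_d, s_d, r_d = summarize(g_def)
    m_n, s_n, r_n = summarize(g_norm)
    diff = m_n - m_d if (m_n is not None and m_d is not None) else None
    t = p = None
    if len(g_def) >= 2 and len(g_norm) >= 2:
        res = stats.ttest_ind(g_def, g_norm, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupShift(variable, len(g_def), m_d, s_d, r_d,
                      len(g_norm), m_n, s_n, r_n, diff, t, p)


@dataclass
class GroupComparison:
    variable: str
    test: str
    groups: dict
    statistic: Optional[float]
    p_value: Optional[float]
    pairwise: list
    warnings: list

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


_PAIR_LABELS = {
    frozenset({"West", "EastSouth"}): "a",   # West vs East
    frozenset({"West", "Central"}): "b",     # West vs Central
    frozenset({"EastSouth", "Central"}): "c",  # East vs Central
}


def compare_groups(df: pd.DataFrame, variable: str, group_col: str, test: str,
                   bonferroni: bool = False) -> GroupComparison:
    """Group comparison with the study's test battery.

    ``test`` is one of welch_t, mann_whitney, chi_square, one_way_anova.
    Continuous tests need >= 2 groups (exactly 2 except ANOVA); chi-square
    takes a boolean/categorical variable. ANOVA is followed by uncorrected
    pairwise Welch tests (Bonferroni optional) labelled a/b/c for
    West-vs-East / West-vs-Central / East-vs-Central when those regions are
    present.
    """
    warns: list[str] = []
    sub = df[[variable, group_col]].dropna()
    groups = {g: v[variable] for g, v in sub.groupby(group_col, observed=True, sort=True)}
    names = list(groups)

    if test == "chi_square":
        tab = pd.crosstab(sub[group_col], sub[variable])
        chi2, p, _, expected = stats.chi2_contingency(tab, correction=False)
        if (expected < 1).any():
            warns.append("chi-square expected cell count < 1")
        summary = {g: {"n": int(v.count()),
                       "count": int(pd.Series(v).astype(bool).sum())}
                   for g, v in groups.items()}
        return GroupComparison(variable, test, summary, float(chi2), float(p), [], warns)

    summary = {g: {"n": int(len(v)), "mean": float(np.mean(v)),
                   "sd": float(np.std(v, ddof=1)) if len(v) >= 2 else None}
               for g, v in groups.items()}
    vals = [np.asarray(v, float) for v in groups.values()]

    if test == "welch_t":
        if len(vals) != 2:
            raise ValueError("welch_t requires exactly two groups")
        res = stats.ttest_ind(*vals, equal_var=False)
        return GroupComparison(variable, test, summary,
                               float(res.statistic), float(res.pvalue), [], warns)
    if test == "mann_whitney":
        if len(vals) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        res = stats.mannwhitneyu(*vals, alternative="two-sided")
        return GroupComparison(variable, test, summary,
                               float(res.statistic), float(res.pvalue), [], warns)
    if test == "one_way_anova":
        if len(vals) < 2:
            raise ValueError("one_way_anova requires at least two groups")
        res = stats.f_oneway(*vals)
        pairwise = []
        n_pairs = len(names) * (len(names) - 1) // 2
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pres = stats.ttest_ind(vals[i], vals[j], equal_var=False)
                p_pair = float(pres.pvalue)
                if bonferroni:
                    p_pair = min(1.0, p_pair * n_pairs)
                pairwise.append({
                    "groups": (names[i], names[j]),
                    "label": _PAIR_LABELS.get(frozenset({names[i], names[j]})),
                    "statistic": float(pres.statistic),
                    "p_value": p_pair,
                    "significant": p_pair <= 0.05,
                })
        return GroupComparison(variable, test, summary,
                               float(res.statistic), float(res.pvalue), pairwise, warns)
    raise ValueError(f"unknown test {test!r}")
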