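"""Glycemic classification from the OGTT (reference standard) and HbA1c.

Abnormal glucose tolerance (Abnl-GT) is the union of prediabetes and type 2
diabetes. The OGTT rule uses fasting and 2-hour post-load plasma glucose with
the standard inclusive thresholds (mg/dL): prediabetes at fasting >= 100
and/or 2h >= 140; T2D at fasting >= 126 and/or 2h >= 200. The HbA1c index
test flags Abnl-GT at >= 5.7% and T2D at >= 6.5% (NGSP percent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "GlycemicResult",
    "Thresholds",
    "apply_exclusions",
    "classify_cohort",
    "classify_hba1c",
    "classify_ogtt",
]

MMOL_TO_MGDL = 18.0182

# absolute tolerance for HbA1c threshold comparisons; makes "shift the values
# by s" and "shift the threshold by -s" bit-for-bit equivalent in floating
# point while being far below the 0.1% resolution of reported HbA1c
_HBA1C_TOL = 1e-9


@dataclass(frozen=True)
class Thresholds:
    """Inclusive diagnostic thresholds; glucose in mg/dL, HbA1c in percent."""

    fasting_abnl: float = 100.0
    fasting_t2d: float = 126.0
    two_hour_abnl: float = 140.0
    two_hour_t2d: float = 200.0
    hba1c_abnl: float = 5.7
    hba1c_t2d: float = 6.5

    def __post_init__(self) -> None:
        if min(self.fasting_abnl, self.fasting_t2d, self.two_hour_abnl,
               self.two_hour_t2d, self.hba1c_abnl, self.hba1c_t2d) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class GlycemicResult:
    """OGTT class plus HbA1c flags for one participant."""

    ogtt_class: str  # "NGT", "PREDIABETES", "T2D"
    abnl_gt: bool
    hba1c_abnl: Optional[bool] = None
    hba1c_t2d: Optional[bool] = None
    basis_fasting: bool = False
    basis_two_hour: bool = False


def _check_glucose(value: float, name: str) -> None:
    if value is None or pd.isna(value):
        raise ValueError(f"{name} is missing; classification refused")
    if not (0 <= value < float("inf")):
        raise ValueError(f"{name}={value} is not a finite nonnegative value")
    if not 20 <= value <= 800:
        warnings.warn(f"{name}={value} mg/dL outside plausibility bounds 20-800",
                      stacklevel=3)


def classify_ogtt(fasting_glucose: float, two_hour_glucose: float,
                  thresholds: Thresholds = Thresholds()) -> GlycemicResult:
    """Classify NGT / prediabetes / T2D from an OGTT (mg/dL)."""
    _check_glucose(fasting_glucose, "fasting_glucose")
    _check_glucose(two_hour_glucose, "two_hour_glucose")
    basis_fasting = fasting_glucose >= thresholds.fasting_abnl
    basis_two_hour = two_hour_glucose >= thresholds.two_hour_abnl
    if (fasting_glucose >= thresholds.fasting_t2d
            or two_hour_glucose >= thresholds.two_hour_t2d):
        cls = "T2D"
    elif basis_fasting or basis_two_hour:
        cls = "PREDIABETES"
    else:
        cls = "NGT"
    return GlycemicResult(ogtt_class=cls, abnl_gt=cls != "NGT",
                          basis_fasting=basis_fasting, basis_two_hour=basis_two_hour)


def classify_hba1c(hba1c: float, thresholds: Thresholds = Thresholds(),
                   ) -> tuple[bool, bool]:
    """HbA1c flags (abnormal-glucose-tolerance, T2D) at the >= thresholds."""
    if hba1c is None or pd.isna(hba1c) or not 2.0 < hba1c < 20.0:
        raise ValueError(f"HbA1c {hba1c!r} outside the plausible range (2, 20)%")
    return (hba1c >= thresholds.hba1c_abnl - _HBA1C_TOL,
            hba1c >= thresholds.hba1c_t2d - _HBA1C_TOL)


def classify_cohort(df: pd.DataFrame, thresholds: Thresholds = Thresholds(),
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised classification of a phenotype table.

    Requires columns ``fasting_glucose``, ``two_hour_glucose``, ``hba1c``.
    Participants with a missing value are refused classification and listed
    in the returned exclusion report instead.
    """
    needed = ["fasting_glucose", "two_hour_glucose", "hba1c"]
    missing_mask = df[needed].isna().any(axis=1)
    refused = df.loc[missing_mask, ["participant_id"]].copy()
    refused["reason"] = "missing glucose or HbA1c value"
    out = df.loc[~missing_mask].copy()
    t = thresholds
    fast, two = out.fasting_glucose, out.two_hour_glucose
    t2d = (fast >= t.fasting_t2d) | (two >= t.two_hour_t2d)
    abnl = (fast >= t.fasting_abnl) | (two >= t.two_hour_abnl) | t2d
    out["ogtt_class"] = "NGT"
    out.loc[abnl, "ogtt_class"] = "PREDIABETES"
    out.loc[t2d, "ogtt_class"] = "T2D"
    out["abnl_gt"] = abnl
    out["basis_fasting"] = fast >= t.fasting_abnl
    out["basis_two_hour"] = two >= t.two_hour_abnl
    out["hba1c_abnl"] = out.hba1c >= t.hba1c_abnl - _HBA1C_TOL
    out["hba1c_t2d"] = out.hba1c >= t.hba1c_t2d - _HBA1C_TOL
    return out, refused


def apply_exclusions(df: pd.DataFrame,
                     hemoglobinopathy_col: str = "hemoglobinopathy",
                     indeterminate_col: str = "status_indeterminate",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows whose HbA1c or G6PD status cannot be used for analysis.

    Two exclusion reasons, applied in order (one reason per participant):
    hemoglobinopathies that make HbA1c indeterminate, and G6PD status that
    could not be resolved from either genotype or assay. Returns the retained
    rows and a log with one (participant_id, reason) row per exclusion.
    """
    log_rows = []
    retained = df
    for col, reason in ((hemoglobinopathy_col, "hemoglobinopathy-indeterminate HbA1c"),
                        (indeterminate_col, "indeterminate G6PD status")):
        if col not in retained.columns:
            continue
        flag = retained[col].fillna(False).astype(bool)
        for pid in retained.loc[flag, "participant_id"]:
            log_rows.append({"participant_id": pid, "reason": reason})
        retained = retained.loc[~flag]
    log = pd.DataFrame(log_rows, columns=["participant_id", "reason"])
    return retained.copy(), log
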