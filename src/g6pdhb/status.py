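"""G6PD deficiency status resolution and genotype-assay concordance.

Deficiency can be established by genotype (the A- haplotype call) or by the
qualitative enzymatic fluorescence screen. The assay measures the phenotype
directly, so when both are available the assay result is used and any
disagreement is logged; when only genotype is available, heterozygous women
(and erroneous or missing genotypes) are INDETERMINATE because random
X-inactivation makes their enzymatic phenotype unpredictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .variants import Call, HaplotypeCall

__all__ = [
    "Assay",
    "ConcordanceReport",
    "G6PDStatus",
    "concordance_analysis",
    "prevalence_by_group",
    "resolve_status",
]


class Assay(str, Enum):
    DEFICIENT = "DEFICIENT"
    NORMAL = "NORMAL"
    NOT_DONE = "NOT_DONE"


@dataclass
class G6PDStatus:
    participant_id: str
    status: str  # DEFICIENT | NORMAL | INDETERMINATE
    provenance: str  # genotype_only | assay_only | both_concordant |
    #                  both_discordant_assay_used | assay_overrides_het
    discordant: bool = False


_GENO_STATUS = {Call.A_MINUS: "DEFICIENT", Call.NORMAL: "NORMAL"}


def resolve_status(hap: Optional[HaplotypeCall], assay: Assay) -> G6PDStatus:
    """Resolve deficiency status from a haplotype call and/or assay result.

    A performed assay always determines the status; the genotype is kept for
    concordance accounting. Without an assay, only decisive haplotype calls
    (A- or normal) resolve; everything else is INDETERMINATE.
    """
    assay = Assay(assay)
    if hap is None and assay is Assay.NOT_DONE:
        raise ValueError("neither genotype call nor assay result available")
    pid = hap.participant_id if hap is not None else None

    if assay is not Assay.NOT_DONE:
        status = assay.value
        if hap is None or hap.call in (Call.MISSING, Call.ERROR):
            prov = "assay_only"
            discordant = False
        elif hap.call is Call.HET_INDETERMINATE:
            prov = "assay_overrides_het"
            discordant = False
        else:
            discordant = _GENO_STATUS[hap.call] != status
            prov = "both_discordant_assay_used" if discordant else "both_concordant"
        return G6PDStatus(pid, status, prov, discordant)

    if hap.call in _GENO_STATUS:
        return G6PDStatus(pid, _GENO_STATUS[hap.call], "genotype_only")
    return G6PDStatus(pid, "INDETERMINATE", "genotype_only")


@dataclass
class ConcordanceReport:
    """Agreement between genotype-predicted and assay-determined deficiency."""

    n_total: int
    n_excluded_het: int
    n_excluded_undecidable: int
    n_compared: int
    n_agree: int
    percent_agreement: Optional[float]
    kappa: Optional[float]
    cross_tab: dict = field(default_factory=dict)
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded_het": self.n_excluded_het,
            "n_excluded_undecidable": self.n_excluded_undecidable,
            "n_compared": self.n_compared,
            "n_agree": self.n_agree,
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "cross_tab": self.cross_tab,
            "empty": self.empty,
        }


def concordance_analysis(pairs: Iterable[tuple[HaplotypeCall, Assay]],
                         ) -> ConcordanceReport:
    """Percent agreement and Cohen's kappa between haplotype and assay.

    Heterozygous-indeterminate women are excluded before comparison (genotype
    cannot predict their phenotype); undecidable haplotypes (MISSING/ERROR)
    are likewise excluded and counted. Agreement is (both deficient or both
    normal) / n_compared. Kappa is defined as 1.0 under perfect agreement
    even when a margin is degenerate.
    """
    pairs = list(pairs)
    n_total = len(pairs)
    n_het = n_undec = n_agree = 0
    tab = {("A_MINUS", "DEFICIENT"): 0, ("A_MINUS", "NORMAL"): 0,
           ("NORMAL", "DEFICIENT"): 0, ("NORMAL", "NORMAL"): 0}
    for hap, assay in pairs:
        assay = Assay(assay)
        if assay is Assay.NOT_DONE:
            raise ValueError(f"{hap.participant_id}: concordance requires a performed assay")
        if hap.call is Call.HET_INDETERMINATE:
            n_het += 1
            continue
        if hap.call in (Call.MISSING, Call.ERROR):
            n_undec += 1
            continue
        tab[(hap.call.value, assay.value)] += 1
        if _GENO_STATUS[hap.call] == assay.value:
            n_agree += 1
    n_compared = n_total - n_het - n_undec
    cross_tab = {f"{g}|{a}": v for (g, a), v in tab.items()}
    if n_compared == 0:
        return ConcordanceReport(n_total, n_het, n_undec, 0, 0, None, None,
                                 cross_tab, empty=True)
    po = n_agree / n_compared
    if po == 1.0:
        kappa = 1.0
    else:
        p_geno_def = (tab[("A_MINUS", "DEFICIENT")] + tab[("A_MINUS", "NORMAL")]) / n_compared
        p_assay_def = (tab[("A_MINUS", "DEFICIENT")] + tab[("NORMAL", "DEFICIENT")]) / n_compared
        pe = p_geno_def * p_assay_def + (1 - p_geno_def) * (1 - p_assay_def)
        kappa = (po - pe) / (1 - pe) if pe < 1.0 else 1.0
    return ConcordanceReport(n_total, n_het, n_undec, n_compared, n_agree,
                             100.0 * po, kappa, cross_tab)


def prevalence_by_group(statuses: pd.DataFrame, by: str) -> pd.DataFrame:
    """Deficiency prevalence per group (e.g. by 'sex' or 'region').

    ``statuses`` needs columns ``status`` and the grouping column;
    INDETERMINATE rows must have been excluded by the caller (their count is
    reported separately in the pipeline). Empty groups get percent = None.
    """
    if (statuses["status"] == "INDETERMINATE").any():
        raise ValueError("exclude INDETERMINATE statuses before computing prevalence")
    rows = []
    for group, sub in statuses.groupby(by, observed=True, sort=True):
        n = len(sub)
        n_def = int((sub["status"] == "DEFICIENT").sum())
        rows.append({"group": group, "n": n, "n_deficient": n_def,
                     "percent": 100.0 * n_def / n if n else None})
    return pd.DataFrame(rows, columns=["group", "n", "n_deficient", "percent"])
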