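"""G6PD A- variant definitions and sex-specific haplotype calling.

The African G6PD A- deficiency haplotype is defined by the common background
allele rs1050829-C together with at least one of three causal alleles:
rs1050828-T (by far the most frequent), rs76723693-C, or rs137852328-A.
Because *G6PD* is X-linked, the calling rule differs by sex:

* men carry a single X, so A- requires hemizygosity for the background allele
  and hemizygosity for at least one causal allele;
* women require homozygosity for the background allele and homozygosity for
  at least one causal allele; a woman carrying at least one background risk
  allele and at least one causal risk allele, without satisfying the
  homozygous rule, is a heterozygous carrier whose enzymatic phenotype cannot
  be predicted from genotype (random X-inactivation) and is called
  ``HET_INDETERMINATE``.

A male genotype that is genuinely heterozygous at any of the four sites is an
``ERROR`` (a single X cannot carry two alleles); hemizygous calls encoded
diploid-style (``0/0`` or ``1/1``) are silently normalised to dosage 0/1.

Missing data policy: a call is returned if and only if it would be identical
under *every* completion of the missing dosages; otherwise the record is
``MISSING``. This uses partial genotypes maximally without guessing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "BACKGROUND_RSID",
    "CAUSAL_RSIDS",
    "RSIDS",
    "Call",
    "GenotypeRecord",
    "GenotypeError",
    "HaplotypeCall",
    "VariantDef",
    "call_haplotype",
    "call_haplotype_single_variant",
    "compare_screening_strategies",
    "default_variant_defs",
]

BACKGROUND_RSID = "rs1050829"
CAUSAL_RSIDS = ("rs1050828", "rs76723693", "rs137852328")
RSIDS = (BACKGROUND_RSID,) + CAUSAL_RSIDS

#: risk allele as reported on the genotyping arrays used here (no strand
#: complementing is ever applied automatically; remap per file if needed)
RISK_ALLELES = {
    "rs1050829": "C",
    "rs1050828": "T",
    "rs76723693": "C",
    "rs137852328": "A",
}


class GenotypeError(ValueError):
    """Invalid genotype input or variant configuration."""


class Call(str, Enum):
    """Outcome of the sex-specific G6PD A- haplotype rule."""

    A_MINUS = "A_MINUS"
    NORMAL = "NORMAL"
    HET_INDETERMINATE = "HET_INDETERMINATE"
    ERROR = "ERROR"
    MISSING = "MISSING"


@dataclass(frozen=True)
class VariantDef:
    """One of the four variants making up the G6PD A- haplotype."""

    rsid: str
    risk_allele: str
    role: str  # "background" or "causal"

    def __post_init__(self) -> None:
        if self.role not in ("background", "causal"):
            raise GenotypeError(f"unknown variant role {self.role!r}")
        if self.risk_allele not in "ACGT":
            raise GenotypeError(f"invalid risk allele {self.risk_allele!r}")


def default_variant_defs() -> tuple[VariantDef, ...]:
    """The four G6PD A- variants with their risk alleles."""
    return tuple(
        VariantDef(rsid, RISK_ALLELES[rsid],
                   "background" if rsid == BACKGROUND_RSID else "causal")
        for rsid in RSIDS
    )


def _validate_defs(defs: Sequence[VariantDef]) -> None:
    rsids = sorted(d.rsid for d in defs)
    if rsids != sorted(RSIDS):
        raise GenotypeError(f"variant set must be exactly {set(RSIDS)}, got {set(rsids)}")
    background = [d for d in defs if d.role == "background"]
    if len(background) != 1 or background[0].rsid != BACKGROUND_RSID:
        raise GenotypeError("exactly one background variant (rs1050829) is required")


@dataclass
class GenotypeRecord:
    """Per-participant risk-allele dosages at the four G6PD A- sites.

    ``calls`` maps rsid to risk-allele dosage (0, 1, 2) or ``None`` for
    missing; an rsid absent from the mapping is also treated as missing.
    ``source_ploidy`` records how each site was encoded in the input file
    ("haploid" or "diploid"), which matters only for males: diploid-encoded
    hemizygous calls are normalised, diploid heterozygous calls are errors.
    """

    participant_id: str
    sex: str  # "male" or "female"
    calls: dict = field(default_factory=dict)
    source_ploidy: dict = field(default_factory=dict)

    def ploidy(self, rsid: str) -> str:
        default = "haploid" if self.sex == "male" else "diploid"
        return self.source_ploidy.get(rsid, default)


@dataclass
class HaplotypeCall:
    """Categorical outcome of the haplotype rule for one participant."""

    participant_id: str
    call: Call
    causal_variant: Optional[str] = None
    notes: str = ""


def _check_record(record: GenotypeRecord) -> None:
    if record.sex not in ("male", "female"):
        raise GenotypeError(
            f"{record.participant_id}: sex must be 'male' or 'female', got {record.sex!r}")
    unknown = set(record.calls) - set(RSIDS)
    if unknown:
        raise GenotypeError(f"{record.participant_id}: unknown rsid(s) {sorted(unknown)}")
    if all(record.calls.get(r) is None for r in RSIDS):
        raise GenotypeError(f"{record.participant_id}: no non-missing genotype calls")


def _normalize_male(record: GenotypeRecord) -> tuple[dict, list[str]]:
    """Return hemizygous dosages (0/1/None) and a list of heterozygous sites."""
    dosages: dict = {}
    het_sites: list[str] = []
    for rsid in RSIDS:
        d = record.calls.get(rsid)
        if d is None:
            dosages[rsid] = None
            continue
        if record.ploidy(rsid) == "diploid":
            if d == 2:
                d = 1
            elif d == 1:
                het_sites.append(rsid)
        elif d not in (0, 1):
            raise GenotypeError(
                f"{record.participant_id}: haploid dosage {d} at {rsid} is not 0/1")
        if d not in (0, 1, None):
            raise GenotypeError(
                f"{record.participant_id}: dosage {d} at {rsid} out of range")
        dosages[rsid] = d
    return dosages, het_sites


def _decide_male(d: Mapping[str, int]) -> Call:
    """Rule for a fully observed male record (dosages 0/1)."""
    if d[BACKGROUND_RSID] == 1 and any(d[c] == 1 for c in CAUSAL_RSIDS):
        return Call.A_MINUS
    return Call.NORMAL


def _decide_female(d: Mapping[str, int]) -> Call:
    """Rule for a fully observed female record (dosages 0/1/2)."""
    if d[BACKGROUND_RSID] == 2 and any(d[c] == 2 for c in CAUSAL_RSIDS):
        return Call.A_MINUS
    if d[BACKGROUND_RSID] >= 1 and any(d[c] >= 1 for c in CAUSAL_RSIDS):
        return Call.HET_INDETERMINATE
    return Call.NORMAL


def _decide_with_missing(dosages: Mapping[str, Optional[int]], sex: str,
                         ) -> tuple[Call, str]:
    """Evaluate the rule under every completion of the missing dosages."""
    domain = (0, 1) if sex == "male" else (0, 1, 2)
    decide = _decide_male if sex == "male" else _decide_female
    missing = [r for r in RSIDS if dosages.get(r) is None]
    if not missing:
        return decide(dosages), ""
    outcomes = set()
    for combo in itertools.product(domain, repeat=len(missing)):
        completed = dict(dosages)
        completed.update(zip(missing, combo))
        outcomes.add(decide(completed))
        if len(outcomes) > 1:
            return Call.MISSING, (
                "call depends on missing genotypes at " + ", ".join(missing))
    return outcomes.pop(), ""


def _satisfied_causal(dosages: Mapping[str, Optional[int]], required: int) -> Optional[str]:
    for rsid in CAUSAL_RSIDS:
        if dosages.get(rsid) == required:
            return rsid
    return None


def _inconsistency_note(dosages: Mapping[str, Optional[int]], sex: str) -> str:
    """Causal risk alleles essentially never occur off the rs1050829-C background."""
    bg = dosages.get(BACKGROUND_RSID)
    if bg is None:
        return ""
    causal_max = max((dosages.get(c) or 0) for c in CAUSAL_RSIDS)
    if causal_max > bg:
        return (f"haplotype-inconsistent: causal dosage {causal_max} exceeds "
                f"rs1050829 dosage {bg}")
    return ""


def call_haplotype(record: GenotypeRecord,
                   defs: Optional[Sequence[VariantDef]] = None) -> HaplotypeCall:
    """Apply the sex-specific G6PD A- haplotype rule to one participant.

    Returns ``A_MINUS``, ``NORMAL``, ``HET_INDETERMINATE`` (females only),
    ``ERROR`` (heterozygous male genotype) or ``MISSING`` (undecidable under
    the missing-data policy). ``causal_variant`` names the first causal site
    that satisfied the rule for an ``A_MINUS`` call.
    """
    _validate_defs(defs if defs is not None else default_variant_defs())
    _check_record(record)

    if record.sex == "male":
        dosages, het_sites = _normalize_male(record)
        if het_sites:
            return HaplotypeCall(
                record.participant_id, Call.ERROR,
                notes=("heterozygous diploid call at " + ", ".join(het_sites)
                       + " in a male (single X chromosome expected)"))
        required = 1
    else:
        dosages = {r: record.calls.get(r) for r in RSIDS}
        for rsid, d in dosages.items():
            if d is not None and d not in (0, 1, 2):
                raise GenotypeError(
                    f"{record.participant_id}: dosage {d} at {rsid} out of range")
        required = 2

    call, note = _decide_with_missing(dosages, record.sex)
    causal = _satisfied_causal(dosages, required) if call is Call.A_MINUS else None
    notes = [n for n in (note, _inconsistency_note(dosages, record.sex)) if n]
    return HaplotypeCall(record.participant_id, call, causal_variant=causal,
                         notes="; ".join(notes))


def call_haplotype_single_variant(record: GenotypeRecord) -> HaplotypeCall:
    """Expedient screen using rs1050828 alone.

    The rs1050829-C background is presumed present whenever rs1050828-T is
    observed (rs1050828-T arose on that background), so the rule reduces to
    the dosage at rs1050828: males 1 -> A-; females 2 -> A-,
    1 -> heterozygous-indeterminate. Carriers of the two rarer causal alleles
    are invisible to this screen.
    """
    _check_record(record)
    rsid = "rs1050828"
    if record.sex == "male":
        d = record.calls.get(rsid)
        if d is not None and record.ploidy(rsid) == "diploid":
            if d == 1:
                return HaplotypeCall(
                    record.participant_id, Call.ERROR,
                    notes=f"heterozygous diploid call at {rsid} in a male "
                          "(single X chromosome expected)")
            if d == 2:
                d = 1
        elif d is not None and d not in (0, 1):
            raise GenotypeError(
                f"{record.participant_id}: haploid dosage {d} at {rsid} is not 0/1")
        if d is None:
            return HaplotypeCall(record.participant_id, Call.MISSING,
                                 notes=f"{rsid} not genotyped")
        call = Call.A_MINUS if d == 1 else Call.NORMAL
    else:
        d = record.calls.get(rsid)
        if d is None:
            return HaplotypeCall(record.participant_id, Call.MISSING,
                                 notes=f"{rsid} not genotyped")
        if d not in (0, 1, 2):
            raise GenotypeError(
                f"{record.participant_id}: dosage {d} at {rsid} out of range")
        call = {2: Call.A_MINUS, 1: Call.HET_INDETERMINATE, 0: Call.NORMAL}[d]
    causal = rsid if call is Call.A_MINUS else None
    return HaplotypeCall(record.participant_id, call, causal_variant=causal)


def compare_screening_strategies(records: Iterable[GenotypeRecord],
                                 ) -> tuple[pd.DataFrame, dict]:
    """Full four-variant rule vs the rs1050828-only screen, per participant.

    Returns a per-record table (participant_id, full_call,
    single_variant_call, discrepant) and a summary with the count of A-
    individuals the single-variant screen would miss.
    """
    records = list(records)
    if not records:
        raise GenotypeError("at least one genotype record is required")
    rows = []
    for rec in records:
        full = call_haplotype(rec)
        single = call_haplotype_single_variant(rec)
        rows.append({
            "participant_id": rec.participant_id,
            "full_call": full.call.value,
            "single_variant_call": single.call.value,
            "discrepant": full.call != single.call,
            "full_causal_variant": full.causal_variant,
        })
    table = pd.DataFrame(rows)
    missed = table[(table.full_call == Call.A_MINUS.value)
                   & (table.single_variant_call != Call.A_MINUS.value)]
    summary = {
        "n": len(table),
        "n_discrepant": int(table.discrepant.sum()),
        "n_a_minus_full": int((table.full_call == Call.A_MINUS.value).sum()),
        "n_a_minus_missed_by_single": int(len(missed)),
        "missed_participants": missed.participant_id.tolist(),
    }
    return table, summary
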