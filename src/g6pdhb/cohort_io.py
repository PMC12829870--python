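"""Reading and writing cohort files: chrX VCF genotypes and phenotype TSVs.

Genotypes are matched by rsID in the VCF ID column; the record positions
written here are approximate chrX coordinates for synthetic output only and
are never used for matching. Risk-allele dosage is counted against the
configured risk allele with **no automatic strand complementing** — a risk
allele absent from REF/ALT is a configuration error, not a flip.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import cyvcf2
import pandas as pd
import pysam

from .variants import RISK_ALLELES, RSIDS, GenotypeError, GenotypeRecord

__all__ = [
    "read_genotypes_table",
    "read_genotypes_vcf",
    "read_phenotypes",
    "write_cohort",
    "write_vcf",
]

#: rsid -> (pos, ref, alt) with alt = risk allele; positions are approximate
VARIANT_TABLE = {
    "rs76723693": (154534419, "T", "C"),
    "rs137852328": (154535045, "G", "A"),
    "rs1050829": (154535277, "T", "C"),
    "rs1050828": (154536002, "C", "T"),
}

PHENOTYPE_COLUMNS = [
    "participant_id", "sex", "region", "fasting_glucose", "two_hour_glucose",
    "hba1c", "assay_result", "reticulocyte_pct", "reticulocyte_abs",
    "hemoglobinopathy",
]

TRUTH_COLUMNS = [
    "participant_id", "true_haplotype", "true_causal_variant", "true_deficient",
    "glycemic_state", "assay_masked", "genotype_available", "assay_done",
]


def _sep(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_vcf(df: pd.DataFrame, path: str, diploid_males: bool = False) -> str:
    """Write the four G6PD A- sites for all cohort participants.

    Males are emitted haploid (``1``) by default, or in the homozygous
    diploid encoding (``1/1``) with ``diploid_males``; ungenotyped
    participants get missing genotypes.
    """
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=chrX,length=156040895>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for pid in df["participant_id"]:
        header.add_sample(str(pid))
    sex = dict(zip(df["participant_id"], df["sex"]))
    genotyped = dict(zip(df["participant_id"], df["genotype_available"]))
    try:
        with pysam.VariantFile(path, "w", header=header) as vf:
            for rsid, (pos, ref, alt) in VARIANT_TABLE.items():
                rec = vf.new_record(contig="chrX", start=pos - 1, stop=pos,
                                    alleles=(ref, alt), id=rsid)
                for pid, dosage in zip(df["participant_id"], df[rsid]):
                    male = sex[pid] == "male"
                    if not genotyped[pid] or pd.isna(dosage):
                        gt = (None,) if (male and not diploid_males) else (None, None)
                    elif male and not diploid_males:
                        gt = (int(dosage),)
                    elif male:
                        gt = (int(dosage > 0), int(dosage > 0))
                    else:
                        d = int(dosage)
                        gt = (int(d >= 1), int(d == 2))
                    rec.samples[str(pid)]["GT"] = gt
                vf.write(rec)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc
    return path


def read_genotypes_vcf(path: str, sex_by_id: Mapping[str, str],
                       risk_alleles: Optional[Mapping[str, str]] = None,
                       ) -> list[GenotypeRecord]:
    """Read risk-allele dosages for the four G6PD A- sites from a VCF.

    Records are matched by the ID column; sites with other rsIDs are ignored.
    ``sex_by_id`` supplies participant sex (VCFs do not carry it). Ploidy is
    taken from each sample's genotype as written in the file.
    """
    risk = dict(RISK_ALLELES if risk_alleles is None else risk_alleles)
    vcf = cyvcf2.VCF(str(path))
    samples = vcf.samples
    calls: dict[str, dict] = {s: {} for s in samples}
    ploidy: dict[str, dict] = {s: {} for s in samples}
    seen = set()
    for var in vcf:
        rsid = var.ID
        if rsid not in RSIDS:
            continue
        seen.add(rsid)
        alleles = [var.REF] + list(var.ALT)
        if risk[rsid] not in alleles:
            raise GenotypeError(
                f"risk allele {risk[rsid]} for {rsid} not among alleles {alleles} "
                "in the VCF; remap explicitly (no automatic strand complementing)")
        risk_idx = alleles.index(risk[rsid])
        for s, gt in zip(samples, var.genotypes):
            allele_idx = gt[:-1]  # last element is the phased flag
            if all(a < 0 for a in allele_idx):
                calls[s][rsid] = None
            else:
                calls[s][rsid] = sum(1 for a in allele_idx if a == risk_idx)
            ploidy[s][rsid] = "haploid" if len(allele_idx) == 1 else "diploid"
    missing_sex = [s for s in samples if s not in sex_by_id]
    if missing_sex:
        raise GenotypeError(f"no sex provided for sample(s) {missing_sex[:5]}")
    records = []
    for s in samples:
        for rsid in set(RSIDS) - seen:
            calls[s][rsid] = None
        records.append(GenotypeRecord(s, sex_by_id[s], calls[s], ploidy[s]))
    return records


def _parse_tabular_call(value, rsid: str, sex: str) -> tuple[Optional[int], str]:
    """Dosage and ploidy from a dosage number, 'C/T' pair, or bare allele."""
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None, "haploid" if sex == "male" else "diploid"
    risk = RISK_ALLELES[rsid]
    s = str(value).strip()
    if s.replace(".", "", 1).isdigit():
        return int(float(s)), "haploid" if sex == "male" else "diploid"
    if "/" in s or "|" in s:
        alleles = s.replace("|", "/").split("/")
        if "." in alleles:
            return None, "diploid"
        return sum(a == risk for a in alleles), "diploid"
    if s in "ACGT":
        return int(s == risk), "haploid"
    raise GenotypeError(f"cannot parse genotype {value!r} at {rsid}")


def read_genotypes_table(path: str) -> list[GenotypeRecord]:
    """Read a tabular genotype file (participant_id, sex, one column per rsid).

    Genotype cells may be risk-allele dosages, diploid allele pairs like
    ``C/T``, or a bare allele for hemizygous males.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"participant_id", "sex"}
    if not required <= set(df.columns):
        raise GenotypeError(f"genotype table needs columns {sorted(required)}")
    records = []
    for row in df.to_dict("records"):
        calls, ploidy = {}, {}
        for rsid in RSIDS:
            d, p = _parse_tabular_call(row.get(rsid), rsid, row["sex"])
            calls[rsid], ploidy[rsid] = d, p
        records.append(GenotypeRecord(row["participant_id"], row["sex"], calls, ploidy))
    return records


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs a participant_id column")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_cohort(df: pd.DataFrame, outdir: str,
                 diploid_males: bool = False) -> dict[str, str]:
    """Write a simulated cohort as VCF + phenotype TSV + ground-truth TSV."""
    if len(df) == 0:
        raise ValueError("cannot write an empty cohort")
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_vcf(df, paths["vcf"], diploid_males=diploid_males)
    df[PHENOTYPE_COLUMNS].to_csv(paths["phenotypes"], sep="\t", index=False)
    df[TRUTH_COLUMNS].to_csv(paths["truth"], sep="\t", index=False)
    return paths
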