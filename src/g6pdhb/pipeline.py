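"""End-to-end analysis pipeline and report assembly.

Composes the stages: genotype ingest -> haplotype calls -> G6PD status
resolution -> OGTT/HbA1c classification -> exclusions -> prevalence tables ->
stratified diagnostics -> mean-shift adjustment -> genotype-assay concordance
-> hemolysis comparison, with exclusion accounting throughout. Reports are
plain JSON/TSV and are byte-identical across reruns of the same
configuration.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from . import cohort_io
from .diagnostics import (ConfusionCounts, DiagnosticSummary,
                          adjusted_hba1c_evaluation, build_confusion,
                          compare_groups, estimate_group_shift,
                          sensitivity_specificity)
from .glycemia import Thresholds, apply_exclusions, classify_cohort
from .simulate import CohortConfig, calibrate_default_config, cohort_genotype_records, simulate_cohort
from .status import Assay, concordance_analysis, prevalence_by_group, resolve_status
from .variants import (GenotypeError, GenotypeRecord, call_haplotype,
                       compare_screening_strategies)

__all__ = [
    "RunConfig",
    "cohort_concordance",
    "evaluate_confusion_fixture",
    "haplotype_table",
    "load_confusion_fixture",
    "prepare_cohort",
    "render_table_one",
    "resolve_status_table",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Inputs (files or a simulation block), thresholds, and output options."""

    vcf_path: Optional[str] = None
    genotypes_path: Optional[str] = None
    phenotypes_path: Optional[str] = None
    cohort_config: Optional[CohortConfig] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    shift: float = 0.9
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        has_files = self.phenotypes_path is not None
        if has_files == (self.cohort_config is not None):
            raise ValueError("exactly one of input paths or a simulation block "
                             "must be configured")
        if has_files and not (self.vcf_path or self.genotypes_path):
            raise ValueError("genotype input (VCF or table) is required with "
                             "a phenotype table")
        if self.shift < 0:
            raise ValueError("adjustment shift must be nonnegative")


def load_confusion_fixture(path: Optional[str] = None) -> list[ConfusionCounts]:
    """The packaged 2x2 confusion counts observed in the Africans in America
    cohort (HbA1c >= 5.7% vs OGTT abnormal glucose tolerance, by G6PD
    stratum), or counts in the same JSON layout from ``path``."""
    if path is None:
        text = (resources.files("g6pdhb") / "data" / "results_confusion.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    payload = json.loads(text)
    return [ConfusionCounts(tp=s["tp"], fp=s["fp"], tn=s["tn"], fn=s["fn"],
                            stratum=s["stratum"]) for s in payload["strata"]]


def evaluate_confusion_fixture(path: Optional[str] = None) -> list[DiagnosticSummary]:
    """Sensitivity/specificity for each stratum of the confusion fixture."""
    return [sensitivity_specificity(c) for c in load_confusion_fixture(path)]


def haplotype_table(records: list[GenotypeRecord]) -> pd.DataFrame:
    """Full-rule haplotype calls, one row per genotyped participant."""
    rows = []
    for rec in records:
        try:
            hap = call_haplotype(rec)
        except GenotypeError:  # record with no usable calls
            continue
        rows.append({"participant_id": rec.participant_id, "call": hap.call.value,
                     "causal_variant": hap.causal_variant, "notes": hap.notes,
                     "_hap": hap})
    return pd.DataFrame(rows, columns=["participant_id", "call", "causal_variant",
                                       "notes", "_hap"])


def resolve_status_table(haps: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Resolved G6PD status per participant from haplotype call and/or assay.

    Participants with neither a usable genotype call nor a performed assay
    get status ``UNDETERMINABLE`` (they are excluded downstream, mirroring
    the study's flow chart).
    """
    hap_by_id = dict(zip(haps["participant_id"], haps["_hap"])) if len(haps) else {}
    rows = []
    for row in phenotypes.itertuples(index=False):
        raw = getattr(row, "assay_result", None)
        assay = Assay("NOT_DONE" if raw is None or pd.isna(raw) else raw)
        hap = hap_by_id.get(row.participant_id)
        if hap is None and assay is Assay.NOT_DONE:
            rows.append({"participant_id": row.participant_id,
                         "status": "UNDETERMINABLE", "provenance": "none",
                         "discordant": False})
            continue
        st = resolve_status(hap, assay)
        rows.append({"participant_id": row.participant_id, "status": st.status,
                     "provenance": st.provenance, "discordant": st.discordant})
    return pd.DataFrame(rows)


def prepare_cohort(df: pd.DataFrame,
                   thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Analysis-ready frame for a cohort table: haplotype calls, resolved
    G6PD status, glycemic classification, and exclusions applied."""
    haps = haplotype_table(cohort_genotype_records(df))
    statuses = resolve_status_table(haps, df)
    merged = df.merge(statuses, on="participant_id", how="left")
    classified, _ = classify_cohort(merged, thresholds)
    classified["status_indeterminate"] = classified["status"].isin(
        ["INDETERMINATE", "UNDETERMINABLE"])
    if "hemoglobinopathy" not in classified.columns:
        classified["hemoglobinopathy"] = False
    retained, _ = apply_exclusions(classified)
    return retained


def cohort_concordance(df: pd.DataFrame):
    """Genotype-assay concordance for the participants of a cohort table who
    have both a haplotype call and a performed assay."""
    haps = haplotype_table(cohort_genotype_records(df))
    assay_by_id = dict(zip(df["participant_id"], df["assay_result"]))
    pairs = []
    for hap in haps["_hap"]:
        raw = assay_by_id.get(hap.participant_id)
        assay = Assay("NOT_DONE" if raw is None or pd.isna(raw) else raw)
        if assay is not Assay.NOT_DONE:
            pairs.append((hap, assay))
    return concordance_analysis(pairs)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict("records"))
    return obj


_TABLE_ONE_ROWS = [
    ("age", "Age (y)", "continuous"),
    ("bmi", "BMI (kg/m2)", "continuous"),
    ("male", "Male (%)", "binary"),
    ("years_us_residence", "Years of US Residence", "continuous"),
    ("sickle_trait", "Sickle Cell Trait (%)", "binary"),
    ("hbc_trait", "HbC trait (%)", "binary"),
    ("g6pd_deficient", "G6PD-D (%)", "binary"),
]


def render_table_one(df: pd.DataFrame, group_col: str = "region") -> pd.DataFrame:
    """Demographics table: one row per characteristic, one column per region
    plus a total column and a group-comparison p-value (one-way ANOVA for
    continuous rows, chi-square for binary rows). Rows whose column is absent
    from the cohort are omitted with a warning; with a single region the
    comparison columns are suppressed."""
    work = df.copy()
    if "sex" in work.columns and "male" not in work.columns:
        work["male"] = work["sex"] == "male"
    if "status" in work.columns and "g6pd_deficient" not in work.columns:
        sub = work.loc[work["status"].isin(["DEFICIENT", "NORMAL"])]
        work = work.assign(g6pd_deficient=pd.NA)
        work.loc[sub.index, "g6pd_deficient"] = sub["status"] == "DEFICIENT"
    groups = sorted(work[group_col].dropna().unique()) if group_col in work.columns else []
    multi = len(groups) > 1

    rows = []
    for col, label, kind in _TABLE_ONE_ROWS:
        if col not in work.columns:
            warnings.warn(f"table-one row {label!r} omitted: column {col!r} absent")
            continue
        series = work[col].dropna()
        if len(series) == 0:
            warnings.warn(f"table-one row {label!r} omitted: column {col!r} empty")
            continue
        row = {"characteristic": label}
        if kind == "binary":
            vals = series.astype(bool)
            row["total"] = f"{100 * vals.mean():.0f}%"
            for g in groups:
                gv = work.loc[work[group_col] == g, col].dropna().astype(bool)
                row[g] = f"{100 * gv.mean():.0f}%" if len(gv) else ""
            test = "chi_square"
        else:
            row["total"] = f"{series.mean():.1f} ± {series.std(ddof=1):.1f}"
            for g in groups:
                gv = work.loc[work[group_col] == g, col].dropna()
                row[g] = (f"{gv.mean():.1f} ± {gv.std(ddof=1):.1f}"
                          if len(gv) >= 2 else "")
            test = "one_way_anova"
        if multi:
            sub = work[[col, group_col]].dropna()
            if kind == "binary":
                sub = sub.assign(**{col: sub[col].astype(bool)})
            try:
                comp = compare_groups(sub, col, group_col, test)
                row["p_value"] = comp.p_value
            except ValueError:
                row["p_value"] = None
        rows.append(row)
    cols = ["characteristic", "total"] + (list(groups) if multi else []) + (
        ["p_value"] if multi else [])
    return pd.DataFrame(rows, columns=cols if rows else ["characteristic", "total"])


def _assemble(cfg: RunConfig) -> tuple[pd.DataFrame, list[GenotypeRecord]]:
    if cfg.cohort_config is not None:
        df = simulate_cohort(cfg.cohort_config)
        return df, cohort_genotype_records(df)
    phenotypes = cohort_io.read_phenotypes(cfg.phenotypes_path)
    if cfg.vcf_path:
        sex_by_id = dict(zip(phenotypes["participant_id"], phenotypes["sex"]))
        records = cohort_io.read_genotypes_vcf(cfg.vcf_path, sex_by_id)
    else:
        records = cohort_io.read_genotypes_table(cfg.genotypes_path)
    # keep only records with at least one observed call
    records = [r for r in records if any(r.calls.get(k) is not None for k in r.calls)]
    return phenotypes, records


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the report and optionally writes it.

    Output files (when ``cfg.outdir`` is set): ``report.json``,
    ``diagnostics.tsv``, ``concordance.json``, ``table1.tsv``,
    ``prevalence.tsv`` and ``exclusions.log``.
    """
    phenotypes, records = _assemble(cfg)
    n_input = len(phenotypes)

    haps = haplotype_table(records)
    statuses = resolve_status_table(haps, phenotypes)
    merged = phenotypes.merge(statuses, on="participant_id", how="left")

    classified, refused = classify_cohort(merged, cfg.thresholds)
    refused = refused.assign(reason="missing glucose or HbA1c value")

    classified["status_indeterminate"] = classified["status"].isin(
        ["INDETERMINATE", "UNDETERMINABLE"])
    if "hemoglobinopathy" not in classified.columns:
        classified["hemoglobinopathy"] = False
    retained, exclusion_log = apply_exclusions(classified)
    exclusion_log = pd.concat([refused[["participant_id", "reason"]], exclusion_log],
                              ignore_index=True)

    prevalence = {
        by: prevalence_by_group(retained[["participant_id", "status", by]], by)
        for by in ("sex", "region") if by in retained.columns
    }
    prev_tests = {}
    for by, table in prevalence.items():
        sub = retained[["status", by]].assign(deficient=retained["status"] == "DEFICIENT")
        if sub[by].nunique() > 1:
            prev_tests[by] = compare_groups(sub, "deficient", by, "chi_square").to_dict()

    confusions, confusion_log = build_confusion(retained)
    diagnostics = [sensitivity_specificity(c) for c in confusions]

    shift_est = estimate_group_shift(retained, "hba1c")
    adjustment = adjusted_hba1c_evaluation(
        retained, cfg.shift, hba1c_threshold=cfg.thresholds.hba1c_abnl)

    hemolysis = {
        var: estimate_group_shift(retained, var).to_dict()
        for var in ("reticulocyte_pct", "reticulocyte_abs")
        if var in retained.columns and retained[var].notna().any()
    }

    # concordance: genotyped participants with a performed assay
    pairs = []
    if len(haps) and "assay_result" in phenotypes.columns:
        assay_by_id = dict(zip(phenotypes["participant_id"], phenotypes["assay_result"]))
        for hap in haps["_hap"]:
            raw = assay_by_id.get(hap.participant_id)
            assay = Assay("NOT_DONE" if raw is None or pd.isna(raw) else raw)
            if assay is not Assay.NOT_DONE:
                pairs.append((hap, assay))
    concordance = concordance_analysis(pairs)

    screening_table, screening_summary = (
        compare_screening_strategies(records) if records else (pd.DataFrame(), {}))

    table_one = render_table_one(retained)

    provenance_counts = (statuses.loc[statuses["status"] != "UNDETERMINABLE",
                                      "provenance"].value_counts().to_dict())
    report = {
        "n_input": n_input,
        "n_retained": len(retained),
        "exclusions": {
            "n_excluded": len(exclusion_log),
            "by_reason": exclusion_log["reason"].value_counts().to_dict(),
        },
        "status_provenance": provenance_counts,
        "n_discordant_genotype_assay": int(statuses["discordant"].sum()),
        "prevalence": {by: t.to_dict("records") for by, t in prevalence.items()},
        "prevalence_tests": prev_tests,
        "diagnostics": [d.to_dict() for d in diagnostics],
        "diagnostics_excluded": len(confusion_log),
        "hba1c_shift": shift_est.to_dict(),
        "adjustment": {
            "shift": adjustment.shift,
            "before": adjustment.before.to_dict(),
            "after": adjustment.after.to_dict(),
            "n_stratum": adjustment.n_stratum,
            "empty": adjustment.empty,
        },
        "hemolysis": hemolysis,
        "concordance": concordance.to_dict(),
        "screening_comparison": screening_summary,
    }
    report = _jsonify(report)

    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame([d.to_dict() for d in diagnostics]).to_csv(
            os.path.join(cfg.outdir, "diagnostics.tsv"), sep="\t", index=False)
        with open(os.path.join(cfg.outdir, "concordance.json"), "w") as fh:
            json.dump(_jsonify(concordance.to_dict()), fh, indent=2, sort_keys=True)
            fh.write("\n")
        table_one.to_csv(os.path.join(cfg.outdir, "table1.tsv"), sep="\t", index=False)
        if prevalence:
            pd.concat([t.assign(by=by) for by, t in prevalence.items()]).to_csv(
                os.path.join(cfg.outdir, "prevalence.tsv"), sep="\t", index=False)
        exclusion_log.to_csv(os.path.join(cfg.outdir, "exclusions.log"),
                             sep="\t", index=False)
    return report
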