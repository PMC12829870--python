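"""Synthetic cohort generator for the G6PD / HbA1c diagnostic analysis.

Emulates the statistical structure of a cohort of sub-Saharan African adults
without diabetes history: 61% male; region mix West 47% / East+South 39% /
Central 14%; region-specific G6PD A- allele frequencies calibrated so that
cohort deficiency prevalence hits the observed regional targets (West 16%,
East+South 5%, Central 8%) under X-linked Hardy-Weinberg (males deficient
with probability q, females homozygous with q^2, heterozygous with 2q(1-q));
abnormal glucose tolerance in ~41% of participants with T2D ~19% of that;
HbA1c driven by a latent glycemia scale plus a fixed deficiency-associated
deficit (default -0.9%) with the normal-activity group calibrated to
5.5 +/- 0.6%; reticulocyte percent 2.92 +/- 0.61 in deficiency vs
1.45 +/- 0.42 with normal activity.

The enzymatic assay observes the deficiency *phenotype* (heterozygous women
are phenotype-deficient with probability 0.5, an X-inactivation coin flip)
and can be masked — flipped to normal — with a configurable per-sex
probability, emulating the malaria-context discordance reported elsewhere.
Every participant carries ground-truth labels so pipeline estimates can be
checked against the injected truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .variants import BACKGROUND_RSID, CAUSAL_RSIDS, RSIDS, GenotypeRecord

__all__ = [
    "CohortConfig",
    "HbA1cModel",
    "calibrate_default_config",
    "cohort_genotype_records",
    "simulate_cohort",
    "solve_region_q",
]

REGION_PREVALENCE_TARGETS = {"West": 0.16, "EastSouth": 0.05, "Central": 0.08}


def solve_region_q(target: float, male_frac: float = 0.61) -> float:
    """Allele frequency q giving cohort deficiency prevalence ``target``.

    Under X-linked Hardy-Weinberg with male fraction m, the deficient
    (hemizygous or homozygous) fraction is m*q + (1-m)*q^2; this solves the
    quadratic for its root in [0, 1).
    """
    if not 0 <= target < 1:
        raise ValueError(f"target prevalence {target} outside [0, 1)")
    if target == 0:
        return 0.0
    f = 1.0 - male_frac
    if f == 0:
        return target / male_frac
    q = (-male_frac + math.sqrt(male_frac**2 + 4 * f * target)) / (2 * f)
    return float(q)


@dataclass(frozen=True)
class HbA1cModel:
    """HbA1c = alpha + beta * latent + delta * 1{deficient} + N(0, sigma).

    ``latent`` is a per-participant glycemia scale, normal around a glycemic
    state mean with SD ``tau``. ``delta_deficiency`` is the hemolysis-driven
    deficit (percent HbA1c) applied to the deficient phenotype only — red
    cell turnover lowers HbA1c without changing glycemia.
    """

    alpha: float
    beta: float = 0.45
    delta_deficiency: float = -0.9
    sigma: float = 0.48
    tau: float = 0.3
    state_means: tuple = (("NGT", 0.0), ("PREDIABETES", 1.0), ("T2D", 2.5))


#: state-conditional glucose proposal (mean_fasting, sd_fasting, mean_2h, sd_2h)
_GLUCOSE_PROPOSALS = {
    "NGT": (88.0, 7.0, 105.0, 18.0),
    "PREDIABETES": (99.0, 8.0, 150.0, 22.0),
    "T2D": (125.0, 18.0, 215.0, 35.0),
}


@dataclass(frozen=True)
class CohortConfig:
    n: int = 5000
    seed: int = 0
    sex_male_frac: float = 0.61
    region_weights: tuple = (("West", 0.47), ("EastSouth", 0.39), ("Central", 0.14))
    region_q: tuple = ()  # filled by calibrate_default_config when empty
    causal_mix: tuple = (("rs1050828", 0.95), ("rs76723693", 0.04), ("rs137852328", 0.01))
    background_allele_freq: float = 0.35  # rs1050829-C on non-A- X chromosomes
    glycemic_state_probs: tuple = (("NGT", 0.59), ("PREDIABETES", 0.3321), ("T2D", 0.0779))
    hba1c_model: Optional[HbA1cModel] = None
    retic_pct_model: tuple = (("DEFICIENT", (2.92, 0.61)), ("NORMAL", (1.45, 0.42)))
    retic_abs_model: tuple = (("DEFICIENT", (94.1, 27.6)), ("NORMAL", (70.4, 20.6)))
    assay_masking: tuple = (("male", 0.0), ("female", 0.0))
    het_female_deficient_prob: float = 0.5
    genotype_missing_rate: float = 0.155
    assay_done_prob: tuple = (("genotyped", 0.42), ("ungenotyped", 0.87))
    hemoglobinopathy_rate: float = 0.0075

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, probs in (("region_weights", dict(self.region_weights)),
                            ("causal_mix", dict(self.causal_mix)),
                            ("glycemic_state_probs", dict(self.glycemic_state_probs))):
            vals = list(probs.values())
            if any(not 0 <= p <= 1 for p in vals) or abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be probabilities summing to 1")
        for name, p in [("sex_male_frac", self.sex_male_frac),
                        ("background_allele_freq", self.background_allele_freq),
                        ("het_female_deficient_prob", self.het_female_deficient_prob),
                        ("genotype_missing_rate", self.genotype_missing_rate),
                        ("hemoglobinopathy_rate", self.hemoglobinopathy_rate),
                        *dict(self.assay_masking).items(),
                        *dict(self.assay_done_prob).items(),
                        *dict(self.region_q).items()]:
            if not 0 <= p <= 1:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if self.hba1c_model is not None and self.hba1c_model.sigma <= 0:
            raise ValueError("hba1c sigma must be positive")


def calibrate_default_config(n: int = 5000, seed: int = 0, **overrides) -> CohortConfig:
    """Default configuration calibrated to the emulation targets.

    Region allele frequencies solve m*q + (1-m)*q^2 = regional prevalence
    target; the HbA1c intercept and residual SD are set analytically so the
    normal-activity group has mean 5.5% and SD 0.6% given the glycemic state
    mix, with the deficient group shifted by delta (default -0.9%, mean 4.6%).
    """
    base = CohortConfig(n=n, seed=seed)
    male_frac = overrides.get("sex_male_frac", base.sex_male_frac)
    region_q = overrides.pop("region_q", None)
    if region_q is None:
        region_q = tuple((r, solve_region_q(t, male_frac))
                         for r, t in REGION_PREVALENCE_TARGETS.items())

    probs = dict(overrides.get("glycemic_state_probs", base.glycemic_state_probs))
    target_mean, target_sd = 5.5, 0.6
    beta, tau = 0.45, 0.3
    state_means = {"NGT": 0.0, "PREDIABETES": 1.0, "T2D": 2.5}
    e_m = sum(probs[s] * state_means[s] for s in probs)
    var_m = sum(probs[s] * state_means[s] ** 2 for s in probs) - e_m**2
    var_latent = var_m + tau**2
    sigma2 = target_sd**2 - beta**2 * var_latent
    sigma = math.sqrt(max(sigma2, 0.05**2))
    model = overrides.pop("hba1c_model", None)
    if model is None:
        model = HbA1cModel(alpha=target_mean - beta * e_m, beta=beta, sigma=sigma,
                           tau=tau, state_means=tuple(state_means.items()))
    return replace(base, region_q=region_q, hba1c_model=model, n=n, seed=seed,
                   **overrides)


def _draw_glucose(rng: np.random.Generator, states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """State-conditional (fasting, 2h) glucose by vectorised rejection.

    Proposals are independent normals per state; draws are rejected until the
    OGTT classification of the pair matches the intended state, so the
    100/126/140/200 mg/dL boundaries are respected exactly.
    """
    n = len(states)
    fasting = np.empty(n)
    two_hour = np.empty(n)
    pending = np.ones(n, dtype=bool)
    for _ in range(200):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            break
        for state, (mf, sf, m2, s2) in _GLUCOSE_PROPOSALS.items():
            sel = idx[states[idx] == state]
            if sel.size == 0:
                continue
            # round to integer mg/dL before the acceptance check so that
            # reported values classify exactly into the intended state
            f = np.round(np.clip(rng.normal(mf, sf, sel.size), 40.0, 450.0))
            h = np.round(np.clip(rng.normal(m2, s2, sel.size), 40.0, 600.0))
            t2d = (f >= 126) | (h >= 200)
            abnl = (f >= 100) | (h >= 140) | t2d
            got = np.where(t2d, "T2D", np.where(abnl, "PREDIABETES", "NGT"))
            ok = got == state
            fasting[sel[ok]] = f[ok]
            two_hour[sel[ok]] = h[ok]
            pending[sel[ok]] = False
    if pending.any():  # pragma: no cover - acceptance rates are all > 0.8
        raise RuntimeError("glucose rejection sampling did not converge")
    return fasting, two_hour


def simulate_cohort(cfg: Optional[CohortConfig] = None, *, n: Optional[int] = None,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Generate a cohort table with observables and ground-truth labels.

    Deterministic given (config, seed): the same configuration always yields
    an identical DataFrame. Columns cover genotype dosages at the four G6PD
    A- sites (nullable Int64; all-missing when genotyping "failed"), the
    phenotype table (glucose, HbA1c, reticulocytes, assay, sex, region) and
    ground truth (true haplotype, causal variant, deficiency phenotype,
    glycemic state, masked-assay flag).
    """
    if cfg is None:
        cfg = calibrate_default_config()
    if n is not None or seed is not None:
        cfg = replace(cfg, n=n if n is not None else cfg.n,
                      seed=seed if seed is not None else cfg.seed)
    if cfg.hba1c_model is None or not cfg.region_q:
        cfg = calibrate_default_config(n=cfg.n, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    sex = np.where(rng.random(n) < cfg.sex_male_frac, "male", "female")
    regions, weights = zip(*cfg.region_weights)
    region = rng.choice(regions, size=n, p=weights)
    q_map = dict(cfg.region_q)
    q = np.array([q_map[r] for r in region])

    # X-linked Hardy-Weinberg haplotype state
    u = rng.random(n)
    male = sex == "male"
    hap = np.full(n, "NORMAL", dtype=object)
    hap[male & (u < q)] = "A_MINUS"
    hap[~male & (u < q**2)] = "A_MINUS"
    hap[~male & (u >= q**2) & (u < q**2 + 2 * q * (1 - q))] = "HET_INDETERMINATE"

    causal_ids, causal_p = zip(*cfg.causal_mix)
    carrier = hap != "NORMAL"
    causal = np.full(n, None, dtype=object)
    causal[carrier] = rng.choice(causal_ids, size=int(carrier.sum()), p=causal_p)

    # genotype dosages consistent with the haplotype state
    bgf = cfg.background_allele_freq
    dosages = {rsid: np.zeros(n, dtype=np.int64) for rsid in RSIDS}
    bg = dosages[BACKGROUND_RSID]
    bg[male] = (rng.random(n)[male] < bgf).astype(np.int64)
    bg[~male] = rng.binomial(2, bgf, size=n)[~male]
    bg[male & (hap == "A_MINUS")] = 1
    homo_f = ~male & (hap == "A_MINUS")
    bg[homo_f] = 2
    het_f = hap == "HET_INDETERMINATE"
    bg[het_f] = 1 + (rng.random(n)[het_f] < bgf).astype(np.int64)  # second X
    for rsid in CAUSAL_RSIDS:
        dosages[rsid][(causal == rsid) & (hap == "A_MINUS") & male] = 1
        dosages[rsid][(causal == rsid) & homo_f] = 2
        dosages[rsid][(causal == rsid) & het_f] = 1

    # deficiency phenotype: X-inactivation coin flip for heterozygous women
    deficient = hap == "A_MINUS"
    deficient = deficient | (het_f & (rng.random(n) < cfg.het_female_deficient_prob))

    states, sprobs = zip(*cfg.glycemic_state_probs)
    state = rng.choice(states, size=n, p=sprobs)
    fasting, two_hour = _draw_glucose(rng, state)

    m = cfg.hba1c_model
    state_mean = dict(m.state_means)
    latent = np.array([state_mean[s] for s in state]) + rng.normal(0, m.tau, n)
    hba1c = (m.alpha + m.beta * latent + m.delta_deficiency * deficient
             + rng.normal(0, m.sigma, n))
    hba1c = np.clip(np.round(hba1c, 1), 2.1, 19.9)  # 0.1% assay resolution

    retic_pct = np.empty(n)
    retic_abs = np.empty(n)
    for status, sel in (("DEFICIENT", deficient), ("NORMAL", ~deficient)):
        mu, sd = dict(cfg.retic_pct_model)[status]
        retic_pct[sel] = np.clip(rng.normal(mu, sd, int(sel.sum())), 0.05, None)
        mu, sd = dict(cfg.retic_abs_model)[status]
        retic_abs[sel] = np.clip(rng.normal(mu, sd, int(sel.sum())), 1.0, None)

    mask_p = dict(cfg.assay_masking)
    masked = deficient & (rng.random(n) < np.where(male, mask_p["male"], mask_p["female"]))
    assay_phenotype = np.where(deficient & ~masked, "DEFICIENT", "NORMAL")

    genotyped = rng.random(n) >= cfg.genotype_missing_rate
    done_p = dict(cfg.assay_done_prob)
    assay_done = rng.random(n) < np.where(genotyped, done_p["genotyped"],
                                          done_p["ungenotyped"])
    assay_result = np.where(assay_done, assay_phenotype, "NOT_DONE")

    hemoglobinopathy = rng.random(n) < cfg.hemoglobinopathy_rate

    df = pd.DataFrame({
        "participant_id": [f"P{i:05d}" for i in range(n)],
        "sex": sex,
        "region": region,
        "true_haplotype": hap,
        "true_causal_variant": causal,
        "true_deficient": deficient,
        "glycemic_state": state,
        "fasting_glucose": fasting,
        "two_hour_glucose": two_hour,
        "hba1c": hba1c,
        "reticulocyte_pct": np.round(retic_pct, 2),
        "reticulocyte_abs": np.round(retic_abs, 1),
        "assay_result": assay_result,
        "assay_masked": masked & assay_done,
        "genotype_available": genotyped,
        "assay_done": assay_done,
        "hemoglobinopathy": hemoglobinopathy,
    })
    for rsid in RSIDS:
        col = pd.array(dosages[rsid], dtype="Int64")
        col[~genotyped] = pd.NA
        df[rsid] = col
    return df


def cohort_genotype_records(df: pd.DataFrame,
                            diploid_males: bool = False) -> list[GenotypeRecord]:
    """GenotypeRecords for the genotyped participants of a cohort table.

    Males are haploid by default; with ``diploid_males`` their hemizygous
    dosages are emitted in the homozygous diploid encoding (0 -> 0, 1 -> 2)
    some array pipelines produce.
    """
    records = []
    for row in df.loc[df["genotype_available"]].itertuples(index=False):
        calls = {}
        ploidy = {}
        for rsid in RSIDS:
            d = getattr(row, rsid)
            d = None if pd.isna(d) else int(d)
            if row.sex == "male" and diploid_males and d is not None:
                d *= 2
            calls[rsid] = d
            ploidy[rsid] = ("diploid" if (row.sex == "female" or diploid_males)
                            else "haploid")
        records.append(GenotypeRecord(row.participant_id, row.sex, calls, ploidy))
    return records
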