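"""Haplotype-calling rules, checked against an independent rule transcription."""

import itertools

import pytest

from g6pdhb.variants import (BACKGROUND_RSID, CAUSAL_RSIDS, RSIDS, Call,
                             GenotypeError, GenotypeRecord,
                             call_haplotype, call_haplotype_single_variant,
                             compare_screening_strategies)

# ---------------------------------------------------------------------------
# Independent oracle: a straight-line transcription of the calling rules,
# written without reference to the library implementation. Missing dosages
# are handled by brute-force enumeration of every completion.


def _oracle_decided(sex, d):
    bg = d[BACKGROUND_RSID]
    causal = [d[c] for c in CAUSAL_RSIDS]
    if sex == "male":
        # hemizygous for rs1050829-C and hemizygous for any causal allele
        return "A_MINUS" if (bg == 1 and 1 in causal) else "NORMAL"
    # women: homozygous for both; heterozygous if at least carrier of both
    if bg == 2 and 2 in causal:
        return "A_MINUS"
    if bg >= 1 and any(c >= 1 for c in causal):
        return "HET_INDETERMINATE"
    return "NORMAL"


def _oracle(sex, dosages):
    domain = (0, 1) if sex == "male" else (0, 1, 2)
    missing = [r for r in RSIDS if dosages[r] is None]
    outcomes = set()
    for combo in itertools.product(domain, repeat=len(missing)):
        filled = dict(dosages, **dict(zip(missing, combo)))
        outcomes.add(_oracle_decided(sex, filled))
    return outcomes.pop() if len(outcomes) == 1 else "MISSING"


def _record(sex, **dosages):
    ploidy = "haploid" if sex == "male" else "diploid"
    return GenotypeRecord("p1", sex, dict(dosages),
                          {r: ploidy for r in dosages})


def _all_combinations(sex):
    domain = (0, 1, None) if sex == "male" else (0, 1, 2, None)
    for combo in itertools.product(domain, repeat=4):
        if all(c is None for c in combo):
            continue  # rejected by precondition, tested separately
        yield dict(zip(RSIDS, combo))


@pytest.mark.parametrize("sex", ["male", "female"])
def test_exhaustive_agreement_with_rule_transcription(sex):
    """Over every dosage combination (including missing), the caller matches
    an independently written transcription of the sex-specific rules."""
    n = 0
    for dosages in _all_combinations(sex):
        got = call_haplotype(_record(sex, **dosages))
        assert got.call.value == _oracle(sex, dosages), dosages
        n += 1
    assert n == (3**4 - 1 if sex == "male" else 4**4 - 1)


@pytest.mark.parametrize("sex", ["male", "female"])
def test_call_partition(sex):
    """Every decidable record gets exactly one substantive call; ERROR and
    MISSING never co-occur with them, and HET_INDETERMINATE is female-only."""
    for dosages in _all_combinations(sex):
        call = call_haplotype(_record(sex, **dosages)).call
        assert call in {Call.A_MINUS, Call.NORMAL, Call.HET_INDETERMINATE,
                        Call.MISSING}
        if sex == "male":
            assert call is not Call.HET_INDETERMINATE


@pytest.mark.parametrize("sex,dosages,expected,causal", [
    # hemizygous background + most common causal allele
    ("male", dict(rs1050829=1, rs1050828=1, rs76723693=0, rs137852328=0),
     Call.A_MINUS, "rs1050828"),
    ("male", dict(rs1050829=0, rs1050828=0, rs76723693=0, rs137852328=0),
     Call.NORMAL, None),
    # homozygous background + homozygous rare causal allele
    ("female", dict(rs1050829=2, rs1050828=0, rs76723693=2, rs137852328=0),
     Call.A_MINUS, "rs76723693"),
    ("female", dict(rs1050829=2, rs1050828=1, rs76723693=0, rs137852328=0),
     Call.HET_INDETERMINATE, None),
    # background carrier without any causal allele is NOT a carrier
    ("female", dict(rs1050829=1, rs1050828=0, rs76723693=0, rs137852328=0),
     Call.NORMAL, None),
])
def test_known_calls(sex, dosages, expected, causal):
    hap = call_haplotype(_record(sex, **dosages))
    assert hap.call is expected
    assert hap.causal_variant == causal


def test_heterozygous_diploid_male_is_error():
    """A male cannot be heterozygous on his single X; diploid-encoded
    heterozygous calls are flagged as errors with an explanation."""
    rec = GenotypeRecord("m1", "male",
                         {"rs1050829": 2, "rs1050828": 1},
                         {"rs1050829": "diploid", "rs1050828": "diploid"})
    hap = call_haplotype(rec)
    assert hap.call is Call.ERROR
    assert "rs1050828" in hap.notes and hap.notes


def test_diploid_homozygous_male_is_normalised():
    """0/0 and 1/1 encodings of hemizygous males give the same call as
    haploid encodings."""
    rec = GenotypeRecord("m1", "male",
                         {"rs1050829": 2, "rs1050828": 2,
                          "rs76723693": 0, "rs137852328": 0},
                         {r: "diploid" for r in RSIDS})
    hap = call_haplotype(rec)
    assert hap.call is Call.A_MINUS and hap.causal_variant == "rs1050828"


def test_missing_policy_decided_under_every_completion():
    # male with background absent: no completion can be A-
    assert call_haplotype(_record("male", rs1050829=0, rs1050828=None,
                                  rs76723693=None, rs137852328=None)
                          ).call is Call.NORMAL
    # male carrying background with unread causal sites: undecidable
    hap = call_haplotype(_record("male", rs1050829=1, rs1050828=None,
                                 rs76723693=None, rs137852328=None))
    assert hap.call is Call.MISSING and hap.notes


def test_female_haplotype_inconsistency_is_noted():
    """Causal risk alleles off the rs1050829-C background are called by the
    literal rule but carry an inconsistency note."""
    hap = call_haplotype(_record("female", rs1050829=1, rs1050828=2,
                                 rs76723693=0, rs137852328=0))
    assert hap.call is Call.HET_INDETERMINATE
    assert "inconsistent" in hap.notes


def test_monotonicity_adding_risk_alleles_never_reaches_error():
    """Raising any dosage of a NORMAL female record never yields ERROR."""
    for dosages in _all_combinations("female"):
        if any(v is None for v in dosages.values()):
            continue
        if call_haplotype(_record("female", **dosages)).call is not Call.NORMAL:
            continue
        for rsid in RSIDS:
            if dosages[rsid] < 2:
                bumped = dict(dosages, **{rsid: dosages[rsid] + 1})
                assert call_haplotype(_record("female", **bumped)
                                      ).call is not Call.ERROR


def test_input_validation():
    with pytest.raises(GenotypeError):
        call_haplotype(GenotypeRecord("x", "male", {"rs9999": 1}, {}))
    with pytest.raises(GenotypeError):
        call_haplotype(GenotypeRecord("x", "", {"rs1050828": 1}, {}))
    with pytest.raises(GenotypeError):  # no observed calls at all
        call_haplotype(GenotypeRecord("x", "male", {}, {}))


# --- single-variant screen -------------------------------------------------


@pytest.mark.parametrize("sex,dosages,expected", [
    # rs1050829-C presumed present when rs1050828-T is seen
    ("male", dict(rs1050828=1), Call.A_MINUS),
    ("male", dict(rs1050829=1, rs76723693=1, rs1050828=0), Call.NORMAL),
    ("female", dict(rs1050829=0, rs1050828=0, rs76723693=0, rs137852328=0),
     Call.NORMAL),
    ("female", dict(rs1050828=2), Call.A_MINUS),
    ("female", dict(rs1050828=1), Call.HET_INDETERMINATE),
])
def test_single_variant_screen(sex, dosages, expected):
    assert call_haplotype_single_variant(_record(sex, **dosages)).call is expected


def _consistent(dosages, sex):
    """Haplotype-consistent: causal dosages never exceed the background."""
    bg = dosages[BACKGROUND_RSID]
    return (bg is not None and all(dosages[c] is not None and dosages[c] <= bg
                                   for c in CAUSAL_RSIDS))


@pytest.mark.parametrize("sex", ["male", "female"])
def test_single_variant_misses_are_one_directional(sex):
    """On haplotype-consistent data, the rs1050828-only screen never calls
    A- when the full rule would not, and its misses are exactly the A-
    haplotypes whose causal variant is one of the two rare alleles."""
    for dosages in _all_combinations(sex):
        if not _consistent(dosages, sex):
            continue
        full = call_haplotype(_record(sex, **dosages))
        single = call_haplotype_single_variant(_record(sex, **dosages))
        if single.call is Call.A_MINUS:
            assert full.call is Call.A_MINUS
        if full.call is Call.A_MINUS:
            required = 1 if sex == "male" else 2
            missed = single.call is not Call.A_MINUS
            assert missed == (dosages["rs1050828"] != required)


def test_compare_screening_strategies_counts_misses():
    """Two rs76723693 hemi-/homozygotes plus one rs137852328 heterozygous
    woman are all discrepant under the single-variant screen."""
    records = [
        _record("male", rs1050829=1, rs1050828=0, rs76723693=1, rs137852328=0),
        _record("female", rs1050829=2, rs1050828=0, rs76723693=2, rs137852328=0),
        _record("female", rs1050829=1, rs1050828=0, rs76723693=0, rs137852328=1),
        _record("male", rs1050829=1, rs1050828=1, rs76723693=0, rs137852328=0),
        _record("female", rs1050829=0, rs1050828=0, rs76723693=0, rs137852328=0),
    ]
    for i, r in enumerate(records):
        r.participant_id = f"p{i}"
    table, summary = compare_screening_strategies(records)
    assert len(table) == 5
    assert summary["n_discrepant"] == 3
    # the het woman is discrepant (HET vs NORMAL) but not an A- miss
    assert summary["n_a_minus_missed_by_single"] == 2
    assert table.discrepant.sum() == 3


def test_compare_screening_strategies_matches_brute_force(default_cohort):
    """On a randomised synthetic cohort the discrepancy count equals an
    independent per-record recount."""
    from g6pdhb.simulate import cohort_genotype_records
    records = cohort_genotype_records(default_cohort.head(800))
    table, summary = compare_screening_strategies(records)
    recount = sum(
        call_haplotype(r).call != call_haplotype_single_variant(r).call
        for r in records)
    assert summary["n_discrepant"] == recount == table.discrepant.sum()
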