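"""Stratified diagnostic metrics, the mean-shift re-evaluation, group tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from g6pdhb.diagnostics import (ConfusionCounts, adjusted_hba1c_evaluation,
                                build_confusion, compare_groups,
                                estimate_group_shift, sensitivity_specificity)
from g6pdhb.pipeline import evaluate_confusion_fixture, load_confusion_fixture


def test_fixture_reproduces_observed_diagnostics():
    """The transcribed cohort counts give sensitivity 0/17 and specificity
    37/37 under deficiency, and 98/195, 217/272 with normal activity."""
    by = {d.stratum: d for d in evaluate_confusion_fixture()}
    d = by["DEFICIENT"]
    assert d.sensitivity == 0.0 and d.counts.tp + d.counts.fn == 17
    assert d.specificity == 1.0 and d.counts.tn + d.counts.fp == 37
    n = by["NORMAL"]
    assert n.sensitivity == 98 / 195
    assert n.specificity == 217 / 272


def test_sensitivity_specificity_null_on_empty_denominators():
    d = sensitivity_specificity(ConfusionCounts(0, 0, 0, 0, "empty"))
    assert d.sensitivity is None and d.specificity is None
    assert d.wilson_ci_sens is None and d.wilson_ci_spec is None


def test_wilson_intervals_contain_estimate_and_stay_in_unit_interval():
    for c in load_confusion_fixture():
        d = sensitivity_specificity(c)
        for est, ci in ((d.sensitivity, d.wilson_ci_sens),
                        (d.specificity, d.wilson_ci_spec)):
            assert 0.0 <= ci[0] <= est <= ci[1] <= 1.0


def test_wilson_interval_narrows_with_n():
    widths = []
    for n in (10, 40, 160, 640):
        c = ConfusionCounts(tp=n // 2, fn=n // 2, fp=0, tn=0)
        lo, hi = sensitivity_specificity(c).wilson_ci_sens
        widths.append(hi - lo)
    assert widths == sorted(widths, reverse=True)


def test_build_confusion_counts_match_brute_force(prepared_default_cohort):
    r = prepared_default_cohort
    confusions, log = build_confusion(r)
    for c in confusions:
        sub = r[r.status == c.stratum]
        assert c.tp == int((sub.hba1c_abnl & sub.abnl_gt).sum())
        assert c.fn == int((~sub.hba1c_abnl & sub.abnl_gt).sum())
        assert c.fp == int((sub.hba1c_abnl & ~sub.abnl_gt).sum())
        assert c.tn == int((~sub.hba1c_abnl & ~sub.abnl_gt).sum())
    assert sum(c.n for c in confusions) + len(log) == len(r)


def test_build_confusion_perfect_index():
    df = pd.DataFrame({
        "participant_id": list("abcd"),
        "status": ["NORMAL"] * 4,
        "abnl_gt": [True, True, False, False],
        "hba1c_abnl": [True, True, False, False],
    })
    (c,), _ = build_confusion(df, strata=("NORMAL",))
    assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 2)


# --- mean-shift adjustment ---------------------------------------------------


def _toy_stratum():
    return pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(6)],
        "status": ["DEFICIENT"] * 6,
        "hba1c": [4.9, 5.0, 4.2, 5.6, 4.5, 5.8],
        "abnl_gt": [True, True, False, True, False, True],
    })


def test_shift_flips_near_threshold_member():
    """4.9% + 0.9% = 5.8% crosses the 5.7% threshold."""
    rep = adjusted_hba1c_evaluation(_toy_stratum(), shift=0.9)
    assert rep.before.counts.tp == 1          # only the 5.8 was index-positive
    assert rep.after.counts.tp == 4           # 4.9, 5.0 and 5.6 flip positive
    assert rep.after.sensitivity > rep.before.sensitivity


def test_shift_zero_is_identity():
    rep = adjusted_hba1c_evaluation(_toy_stratum(), shift=0.0)
    assert rep.before.counts == rep.after.counts


def test_shift_direction_on_synthetic_cohort(prepared_default_cohort):
    """Adding the deficiency shift back never lowers sensitivity and never
    raises specificity in the deficient stratum."""
    rep = adjusted_hba1c_evaluation(prepared_default_cohort, shift=0.9)
    assert rep.after.sensitivity >= rep.before.sensitivity
    assert rep.after.specificity <= rep.before.specificity
    # exhaustive reclassification oracle
    sub = prepared_default_cohort[prepared_default_cohort.status == "DEFICIENT"]
    manual_tp = int(((sub.hba1c + 0.9 >= 5.7 - 1e-9) & sub.abnl_gt).sum())
    assert rep.after.counts.tp == manual_tp


@given(st.lists(st.integers(42, 239), min_size=1, max_size=30),
       st.integers(0, 20))
@settings(deadline=None, max_examples=100)
def test_shift_equivalent_to_threshold_shift(values_scaled, shift_scaled):
    """Shifting members' values by s classifies identically to lowering the
    threshold by s for those members (values on the 0.05% grid)."""
    hba1c = [v * 0.05 for v in values_scaled]
    shift = shift_scaled * 0.05
    df = pd.DataFrame({
        "participant_id": range(len(hba1c)),
        "status": ["DEFICIENT"] * len(hba1c),
        "hba1c": hba1c,
        "abnl_gt": [i % 2 == 0 for i in range(len(hba1c))],
    })
    shifted = adjusted_hba1c_evaluation(df, shift=shift, hba1c_threshold=5.7).after
    lowered = adjusted_hba1c_evaluation(df, shift=0.0,
                                        hba1c_threshold=5.7 - shift).after
    assert shifted.counts == lowered.counts


def test_shift_empty_stratum_flagged():
    df = pd.DataFrame({"participant_id": [], "status": [], "hba1c": [],
                       "abnl_gt": []})
    rep = adjusted_hba1c_evaluation(df, shift=0.9)
    assert rep.empty and rep.before.sensitivity is None


# --- group shift and comparison tests ----------------------------------------


def test_group_shift_degenerate_constant_groups():
    df = pd.DataFrame({
        "status": ["DEFICIENT"] * 5 + ["NORMAL"] * 5,
        "hba1c": [4.6] * 5 + [5.5] * 5,
    })
    s = estimate_group_shift(df)
    assert s.difference == pytest.approx(0.9)
    assert s.mean_deficient == 4.6 and s.mean_normal == 5.5


def test_group_shift_identical_groups():
    vals = [4.8, 5.1, 5.6, 5.9, 6.2]
    df = pd.DataFrame({"status": ["DEFICIENT"] * 5 + ["NORMAL"] * 5,
                       "hba1c": vals + vals})
    s = estimate_group_shift(df)
    assert s.difference == 0.0
    assert s.p_value == pytest.approx(1.0)


def test_group_shift_small_group_skips_test():
    df = pd.DataFrame({"status": ["DEFICIENT", "NORMAL", "NORMAL"],
                       "hba1c": [4.4, 5.2, 5.9]})
    s = estimate_group_shift(df)
    assert s.sd_deficient is None and s.p_value is None


def test_group_shift_recovers_injected_difference(prepared_default_cohort):
    s = estimate_group_shift(prepared_default_cohort, "hba1c")
    assert s.difference == pytest.approx(0.9, abs=0.1)
    assert s.p_value < 1e-6


def test_chi_square_on_published_sex_counts():
    """Deficiency in 45/324 men vs 9/197 women is significant, P < 0.001."""
    rows = ([{"deficient": True, "sex": "male"}] * 45
            + [{"deficient": False, "sex": "male"}] * 279
            + [{"deficient": True, "sex": "female"}] * 9
            + [{"deficient": False, "sex": "female"}] * 188)
    comp = compare_groups(pd.DataFrame(rows), "deficient", "sex", "chi_square")
    assert comp.p_value < 0.001


def test_welch_t_matches_textbook_formula():
    a = np.array([4.1, 4.8, 5.2, 4.4, 4.9, 5.0])
    b = np.array([5.6, 5.2, 6.0, 5.8, 5.1, 5.9, 5.4])
    df = pd.DataFrame({"v": np.concatenate([a, b]),
                       "g": ["a"] * len(a) + ["b"] * len(b)})
    comp = compare_groups(df, "v", "g", "welch_t")
    # hand computation: Welch statistic and Welch-Satterthwaite dof
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), dof)
    assert comp.statistic == pytest.approx(t, rel=1e-12)
    assert comp.p_value == pytest.approx(p, rel=1e-9)


def test_anova_pairwise_labels_and_bonferroni():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "region": ["West"] * 40 + ["EastSouth"] * 40 + ["Central"] * 40,
        "v": np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40),
                             rng.normal(0.2, 1, 40)]),
    })
    comp = compare_groups(df, "v", "region", "one_way_anova")
    labels = {p["label"] for p in comp.pairwise}
    assert labels == {"a", "b", "c"}
    bonf = compare_groups(df, "v", "region", "one_way_anova", bonferroni=True)
    for raw, adj in zip(comp.pairwise, bonf.pairwise):
        assert adj["p_value"] == pytest.approx(min(1.0, raw["p_value"] * 3))


def test_chi_square_sparse_cells_warn():
    df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3,
                       "v": [True, False, False, False, False, False]})
    comp = compare_groups(df, "v", "g", "chi_square")
    assert comp.warnings  # expected counts < 1


def test_confusion_counts_validate():
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 0)
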