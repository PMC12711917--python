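"""Burden statistics: OR, LR/G test, profile CI, Fisher, BH, Dunnett."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from calmlobe.stats import (
    ContingencyTable,
    anova_dunnett,
    bh_adjust,
    burden_table,
    carrier_frequency,
    dunnett_critical_value,
    fisher_exact_2x2,
    lr_test,
    profile_ci,
    sample_or,
)

CLOBE = ContingencyTable(7, 24241, 5, 97317)
NLOBE = ContingencyTable(0, 24248, 15, 97307)


# ---------------------------------------------------------------------------
# odds ratio


def test_sample_or_published_values():
    assert sample_or(CLOBE) == pytest.approx(5.62, abs=0.005)
    assert sample_or(ContingencyTable(3, 24245, 1, 97321)) == pytest.approx(
        12.0, abs=0.05
    )


def test_sample_or_symmetric_table_is_one():
    assert sample_or(ContingencyTable(4, 100, 4, 100)) == 1.0


def test_sample_or_not_estimable_with_zero_carrier_cell():
    assert math.isnan(sample_or(NLOBE))
    assert math.isnan(sample_or(ContingencyTable(3, 10, 0, 10)))


def test_sample_or_invariances():
    t = ContingencyTable(3, 7, 11, 13)
    swapped = ContingencyTable(13, 11, 7, 3)     # both rows and columns
    assert sample_or(t) == pytest.approx(sample_or(swapped))
    cohort_swap = ContingencyTable(11, 13, 3, 7)
    assert sample_or(cohort_swap) == pytest.approx(1.0 / sample_or(t))


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# likelihood-ratio test


def test_lr_test_published_pvalues():
    assert lr_test(CLOBE)[1] == pytest.approx(0.0036, abs=0.00005)
    assert lr_test(NLOBE)[1] == pytest.approx(0.0098, abs=0.00005)


def test_lr_test_null_table():
    lr, p = lr_test(ContingencyTable(5, 95, 50, 950))  # equal proportions
    assert lr == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_lr_test_empty_margin():
    assert lr_test(ContingencyTable(0, 10, 0, 20)) == (0.0, 1.0)
    assert lr_test(ContingencyTable(0, 0, 0, 0)) == (0.0, 1.0)


def _g_test_oracle(a, b, c, d):
    """Independently coded G statistic (loop form, no shared code)."""
    obs = [a, b, c, d]
    n = sum(obs)
    row = [a + b, c + d]
    col = [a + c, b + d]
    exp = [row[0] * col[0] / n, row[0] * col[1] / n,
           row[1] * col[0] / n, row[1] * col[1] / n]
    g = 0.0
    for o, e in zip(obs, exp):
        if o > 0:
            g += o * math.log(o / e)
    return 2.0 * g


def test_lr_equals_g_oracle_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(200):
        a, b, c, d = rng.integers(1, 500, size=4)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        lr, _ = lr_test(t)
        oracle = _g_test_oracle(int(a), int(b), int(c), int(d))
        assert abs(lr - oracle) <= 1e-10 * max(oracle, 1.0)


# ---------------------------------------------------------------------------
# profile-likelihood CI


def test_profile_ci_published_intervals():
    lo, hi = profile_ci(CLOBE, 0.95)
    assert lo == pytest.approx(1.8, rel=0.15)
    assert hi == pytest.approx(19.0, rel=0.15)
    assert lo < 5.62 < hi
    lo, hi = profile_ci(ContingencyTable(7, 24241, 20, 97302), 0.95)
    assert lo < 1.40 < hi
    assert lo == pytest.approx(0.55, rel=0.15)
    assert hi == pytest.approx(3.2, rel=0.15)


def test_profile_ci_tightens_with_level():
    t = ContingencyTable(7, 24241, 5, 97317)
    lo90, hi90 = profile_ci(t, 0.90)
    lo99, hi99 = profile_ci(t, 0.99)
    assert lo99 < lo90 < hi90 < hi99


def test_profile_ci_one_sided_for_zero_cell():
    lo, hi = profile_ci(NLOBE, 0.95)
    assert lo == 0.0 and 0 < hi < 1.0
    lo, hi = profile_ci(ContingencyTable(5, 100, 0, 100), 0.95)
    assert lo > 1.0 and math.isinf(hi)


def test_profile_ci_level_validation():
    with pytest.raises(ValueError):
        profile_ci(CLOBE, 1.0)


# ---------------------------------------------------------------------------
# Fisher exact


def test_fisher_lobe_distribution_table():
    # rows = N-lobe / C-lobe carrier counts, columns = SCZ / control
    t = ContingencyTable(0, 15, 7, 5)
    assert fisher_exact_2x2(t) == pytest.approx(0.0009, abs=0.00005)


def test_fisher_no_carriers_anywhere():
    assert fisher_exact_2x2(ContingencyTable(0, 30, 0, 50)) == 1.0


def _fisher_enumeration_oracle(a, b, c, d):
    """Two-sided probability-mass rule by exhaustive enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    p_obs = sps.hypergeom.pmf(a, r1 + r2, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = sps.hypergeom.pmf(x, r1 + r2, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def test_fisher_matches_enumeration_small_tables():
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 60:
        a, b, c, d = rng.integers(0, 8, size=4)
        if a + b + c + d == 0 or a + b + c + d > 30:
            continue
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        assert fisher_exact_2x2(t) == pytest.approx(
            _fisher_enumeration_oracle(int(a), int(b), int(c), int(d)),
            rel=1e-9, abs=1e-12,
        )
        checked += 1


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_smallest_table1_adjusted_value(schema_counts):
    tab = burden_table(schema_counts)
    assert tab["p_adj"].min() == pytest.approx(0.043, abs=0.0005)


def test_bh_trivia():
    assert bh_adjust([0.03])[0] == pytest.approx(0.03)
    out = bh_adjust([0.2, 0.2, 0.2])
    assert np.allclose(out, 0.2)
    assert bh_adjust([]).size == 0
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_bh_monotone_bounded_and_stable(pvals):
    adj = bh_adjust(pvals)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)       # monotone in p order
    assert np.all((adj >= np.asarray(pvals) - 1e-12) & (adj <= 1.0))
    # re-adjustment never decreases any value
    again = bh_adjust(adj)
    assert np.all(again >= adj - 1e-12)


def test_bh_idempotent_on_fixed_points():
    # constant sequences and step sequences anchored at the largest rank
    # are BH fixed points
    for p in ([0.2, 0.2, 0.2, 0.2], [0.0, 1.0], [0.5], [0.0, 0.0, 0.7]):
        adj = bh_adjust(p)
        assert np.allclose(bh_adjust(adj), adj)


# ---------------------------------------------------------------------------
# carrier frequency


@pytest.mark.parametrize(
    "k,n,expected",
    [(7, 24248, "1:3500"), (20, 97322, "1:4900"), (1, 100, "1:100")],
)
def test_carrier_frequency_formatting(k, n, expected):
    assert carrier_frequency(k, n) == expected


def test_carrier_frequency_undefined_and_invalid():
    assert carrier_frequency(0, 100) is None
    with pytest.raises(ValueError):
        carrier_frequency(5, 3)


# ---------------------------------------------------------------------------
# Dunnett many-to-one


def test_dunnett_two_groups_equals_pooled_t_test():
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 8), rng.normal(0.8, 1, 6)
    res = anova_dunnett([("WT", a), ("V", b)], reference="WT")
    t_p = sps.ttest_ind(b, a, equal_var=True).pvalue
    assert res.p_adjusted[0] == pytest.approx(t_p, rel=1e-4)


def test_dunnett_matches_scipy_reference():
    rng = np.random.default_rng(3)
    ref = rng.normal(0, 1, 7)
    g1, g2, g3 = rng.normal(0.5, 1, 5), rng.normal(1.5, 1, 9), rng.normal(0, 1, 6)
    ours = anova_dunnett(
        [("WT", ref), ("A", g1), ("B", g2), ("C", g3)], reference="WT"
    )
    theirs = sps.dunnett(g1, g2, g3, control=ref)
    assert np.allclose(ours.p_adjusted, theirs.pvalue, atol=2e-3)


def test_dunnett_identical_groups_do_not_reject():
    vals = [1.0, 1.1, 0.9, 1.05]
    res = anova_dunnett(
        [("WT", vals), ("A", vals), ("B", vals)], reference="WT"
    )
    assert all(p > 0.9 for p in res.p_adjusted)


def test_dunnett_large_shift_rejects():
    rng = np.random.default_rng(5)
    ref = rng.normal(0, 1, 6)
    shifted = rng.normal(10, 1, 6)   # ten pooled SDs away
    null = rng.normal(0, 1, 6)
    res = anova_dunnett(
        [("WT", ref), ("far", shifted), ("null", null)], reference="WT"
    )
    p = dict(zip(res.labels, res.p_adjusted))
    assert p["far"] < 1e-3
    assert p["null"] > 0.05


def test_dunnett_validation():
    with pytest.raises(ValueError):
        anova_dunnett([("WT", [1.0]), ("A", [1, 2])], reference="WT")
    with pytest.raises(ValueError):
        anova_dunnett([("A", [1, 2]), ("B", [1, 2])], reference="WT")


def test_dunnett_critical_value_balanced_reference():
    # k=3 balanced comparisons, df=36: Monte-Carlo oracle (4e5 draws of the
    # equicorrelated max-|t|) gives 2.451; normal-limit value is 2.349
    a = np.full(3, math.sqrt(0.5))
    assert dunnett_critical_value(a, df=36, alpha=0.05) == pytest.approx(2.451, abs=0.01)
    assert dunnett_critical_value(a, df=math.inf, alpha=0.05) == pytest.approx(
        2.349, abs=0.005
    )


# ---------------------------------------------------------------------------
# burden table reproduction


PRINTED = {
    "CALM1+2+3": (1.40, 0.52),
    "CALM1+2+3 C-lobe": (5.62, 0.0036),
    "CALM1": (4.01, 0.10),
    "CALM1 C-lobe": (12.0, 0.018),
    "CALM2": (2.40, 0.25),
    "CALM2 C-lobe": (12.0, 0.018),
    "CALM3": (0.330, 0.22),
    "CALM3 C-lobe": (1.34, 0.81),
}


def test_burden_table_reproduces_published_rows(schema_counts):
    tab = burden_table(schema_counts).set_index("stratum")
    for stratum, (or_printed, _) in PRINTED.items():
        assert tab.loc[stratum, "or"] == pytest.approx(or_printed, rel=0.015), stratum
    # p-values to printed precision (the combined row's published p is not
    # reproduced by the LR test and is excluded here)
    for stratum in PRINTED:
        if stratum == "CALM1+2+3":
            continue
        assert tab.loc[stratum, "p"] == pytest.approx(
            PRINTED[stratum][1], rel=0.05
        ), stratum
    assert tab.loc["CALM1+2+3 N-lobe", "p"] == pytest.approx(0.0098, abs=0.0001)
    assert not tab.loc["CALM1+2+3 N-lobe", "estimable"]
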