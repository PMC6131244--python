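from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aiscape as ai
from aiscape.peaks import Peak
from conftest import make_segments


def test_contingency_oncogene_mutation_stratification():
    """Printed cohort counts: 72% mutated with gain AI vs 31% without AI."""
    res = ai.contingency_2x2(129, 49, 279, 614)
    assert res.row1_pct == 72
    assert res.row2_pct == 31
    assert res.odds_ratio == pytest.approx((129 * 614) / (49 * 279), rel=1e-12)
    assert res.odds_ratio == pytest.approx(5.80, abs=0.01)
    assert res.fisher_p < 1e-20


def test_contingency_uniform_table():
    res = ai.contingency_2x2(1, 1, 1, 1)
    assert res.odds_ratio == 1.0
    assert res.fisher_p == pytest.approx(1.0)


def test_contingency_haldane_on_zero_cell():
    res = ai.contingency_2x2(10, 0, 0, 10)
    assert res.haldane_corrected
    assert res.odds_ratio == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))


def test_contingency_rejects_bad_tables():
    with pytest.raises(ValueError):
        ai.contingency_2x2(0, 0, 1, 1)
    with pytest.raises(ValueError):
        ai.contingency_2x2(-1, 1, 1, 1)


def test_fisher_p_matches_enumeration_oracle():
    """Two-sided Fisher p re-derived by full table enumeration at fixed margins."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        a, b, c, d = rng.integers(0, 11, 4)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        res = ai.contingency_2x2(a, b, c, d)
        r1, r2, c1 = a + b, c + d, a + c
        def pmf(x):
            return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(r1 + r2, c1))
        support = [x for x in range(0, min(r1, c1) + 1) if c1 - x <= r2]
        p_obs = pmf(a)
        p_exact = float(sum(pmf(x) for x in support if pmf(x) <= p_obs))
        assert res.fisher_p == pytest.approx(p_exact, rel=1e-9)


def test_hypergeometric_screen_overlap_enrichment():
    """Top-12 dependency genes all re-identified among 795 shared genes."""
    p = ai.hypergeometric_tail(795, 61, 12, 12)
    exact = Fraction(comb(61, 12), comb(795, 12))
    assert p == pytest.approx(float(exact), rel=1e-9)
    assert p <= 1e-13


@pytest.mark.parametrize("N,K,n,x,expected", [
    (10, 10, 3, 3, 1.0),
    (5, 1, 1, 1, 0.2),
    (8, 3, 2, 0, 1.0),
])
def test_hypergeometric_simple_values(N, K, n, x, expected):
    assert ai.hypergeometric_tail(N, K, n, x) == pytest.approx(expected)


def test_hypergeometric_matches_rational_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        N = int(rng.integers(2, 61))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        x = int(rng.integers(0, n + 1))
        exact = Fraction(0)
        for k in range(x, min(n, K) + 1):
            if n - k <= N - K:
                exact += Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))
        assert ai.hypergeometric_tail(N, K, n, x) == pytest.approx(float(exact),
                                                                   rel=1e-9, abs=1e-300)


def test_hypergeometric_pmf_sums_to_one():
    rng = np.random.default_rng(2)
    for _ in range(5):
        N = int(rng.integers(5, 200))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        assert ai.hypergeometric_tail(N, K, n, 0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        ai.hypergeometric_tail(10, 11, 3, 1)


def test_bonferroni_adjustment():
    np.testing.assert_allclose(ai.multiple_testing([0.01], "bonferroni"), [0.01])
    np.testing.assert_allclose(ai.multiple_testing([0.01, 0.04], "bonferroni"),
                               [0.02, 0.08])


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.uniform(0, 1, rng.integers(1, 30))
        adj = ai.multiple_testing(p, "fdr_bh")
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        np.testing.assert_allclose(adj, brute, rtol=1e-12)


def test_multiple_testing_validates_input():
    with pytest.raises(ValueError):
        ai.multiple_testing([0.5, 1.5])
    with pytest.raises(ValueError):
        ai.multiple_testing([0.5], method="fdr_by")


def test_logistic_null_pvalues_are_uniform():
    rng = np.random.default_rng(4)
    ps = []
    for _ in range(60):
        x = (rng.random(400) < 0.3).astype(float)
        y = (rng.random(400) < 0.4).astype(float)
        burden = rng.gamma(2.0, 5e7, 400)
        ps.append(ai.logistic_association(y, x, burden).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_logistic_detects_planted_coupling():
    """Coupled indicators (OR about 4) found at p < 0.001 in most replicates."""
    rng = np.random.default_rng(5)
    hits = 0
    reps = 20
    for _ in range(reps):
        n = 500
        x = (rng.random(n) < 0.35).astype(float)
        base = 0.25
        p_y = np.where(x == 1, base * 4 / (1 + base * 3), base)  # OR = 4
        y = (rng.random(n) < p_y).astype(float)
        burden = rng.gamma(2.0, 5e7, n)
        res = ai.logistic_association(y, x, burden)
        if res.coef > 0 and res.p_value < 0.001:
            hits += 1
    assert hits >= 0.9 * reps


def test_logistic_separation_falls_back_to_firth():
    y = np.array([0.0] * 20 + [1.0] * 20)
    x = y.copy()                              # perfect separation
    res = ai.logistic_association(y, x)
    assert res.separated
    assert np.isfinite(res.coef) and np.isfinite(res.p_value)
    assert res.coef > 0
    const = ai.logistic_association(np.ones(40), x)
    assert const.separated and const.p_value == 1.0


def _peak(chrom, start, end, klass="loss"):
    return Peak(chrom, klass, start, end, 20, 20)


def test_peak_pair_logistic_on_constructed_cohort():
    rng = np.random.default_rng(6)
    n = 200
    samples = [f"s{i}" for i in range(n)]
    rows = []
    for i, s in enumerate(samples):
        has_i = rng.random() < 0.4
        has_j = rng.random() < (0.7 if has_i else 0.2)
        if has_i:
            rows.append(("chr1", 10_000_000, 30_000_000, s, "loss", -0.2, 0.2, 10))
        if has_j:
            rows.append(("chr2", 50_000_000, 70_000_000, s, "loss", -0.2, 0.2, 10))
    segs = make_segments(rows)
    res = ai.peak_pair_logistic(segs, samples,
                                _peak("chr1", 15_000_000, 25_000_000),
                                _peak("chr2", 55_000_000, 65_000_000))
    assert res.coef > 0 and res.p_value < 1e-6
    with pytest.raises(ValueError, match="different chromosomes"):
        ai.peak_pair_logistic(segs, samples,
                              _peak("chr1", 0, 10), _peak("chr1", 20, 30))
    with pytest.raises(ValueError, match="30 samples"):
        ai.peak_pair_logistic(segs, samples[:10],
                              _peak("chr1", 0, 10), _peak("chr2", 20, 30))


def test_phenotype_logistic_planted_effect():
    rng = np.random.default_rng(7)
    n = 200
    samples = [f"s{i}" for i in range(n)]
    msi = rng.random(n) < 0.4
    rows = []
    for i, s in enumerate(samples):
        p = 0.5 if msi[i] else 0.1       # fragile-site deletion enriched in MSI
        if rng.random() < p:
            rows.append(("chr3", 60_000_000, 61_000_000, s, "loss", -0.3, 0.2, 10))
    res = ai.phenotype_logistic(make_segments(rows), samples,
                                _peak("chr3", 60_200_000, 60_800_000),
                                msi.astype(float))
    assert res.coef > 0 and res.p_value < 0.01
    with pytest.raises(ValueError, match="single-class"):
        ai.phenotype_logistic(make_segments(rows), samples,
                              _peak("chr3", 0, 10), np.ones(n))
    with pytest.raises(ValueError, match="binary"):
        ai.phenotype_logistic(make_segments(rows), samples,
                              _peak("chr3", 0, 10), np.full(n, 0.5))


def test_expression_dosage_power_and_degenerate_cases():
    rng = np.random.default_rng(8)
    n = 200
    purity = rng.beta(5, 3, n)
    rows = []
    lrr = rng.normal(0, 0.25, n)
    expr = 1.0 * lrr + 0.5 * purity + rng.normal(0, 0.5, n)
    for i in range(n):
        rows.append(("dosage", f"s{i}", lrr[i], expr[i], purity[i]))
        rows.append(("flat", f"s{i}", lrr[i], 3.0, purity[i]))
        rows.append(("zerovar", f"s{i}", 0.0, expr[i], purity[i]))
    table = pd.DataFrame(rows, columns=["gene", "sample_id", "lrr",
                                        "expression", "purity"])
    res = ai.expression_dosage_test(table).set_index("gene")
    assert res.loc["dosage", "q"] < 0.1
    assert res.loc["dosage", "slope"] == pytest.approx(1.0, abs=0.2)
    assert res.loc["flat", "slope"] == pytest.approx(0.0, abs=1e-9)
    assert res.loc["flat", "p"] > 0.9
    assert bool(res.loc["zerovar", "flagged"])


def test_events_per_tumor_counts_expected_class_only():
    peaks = [_peak("chr1", 100, 200, "gain"), _peak("chr2", 100, 200, "gain"),
             _peak("chr3", 100, 200, "gain"), _peak("chr4", 100, 200, "loss")]
    rows = [("chr1", 50, 250, "s1", "gain", 0.3, 0.1, 10),
            ("chr2", 150, 300, "s1", "gain", 0.3, 0.1, 10),
            ("chr3", 100, 200, "s1", "loss", -0.3, 0.2, 10),   # wrong class
            ("chr4", 0, 500, "s1", "loss", -0.3, 0.2, 10)]
    counts = ai.events_per_tumor(make_segments(rows), ["s1", "s2"], peaks)
    assert counts["s1"] == 3
    assert counts["s2"] == 0
    assert ai.events_per_tumor(make_segments(rows), ["s1"], []).iloc[0] == 0


def test_events_per_tumor_monotone_under_added_segment():
    peaks = [_peak("chr1", 100, 200, "gain")]
    rows = [("chr1", 50, 250, "s1", "gain", 0.3, 0.1, 10)]
    before = ai.events_per_tumor(make_segments(rows), ["s1", "s2"], peaks)
    rows.append(("chr1", 120, 180, "s2", "gain", 0.3, 0.1, 10))
    after = ai.events_per_tumor(make_segments(rows), ["s1", "s2"], peaks)
    assert (after >= before).all()


def test_stratified_event_summary_rank_test():
    counts = pd.Series({f"a{i}": c for i, c in enumerate([12, 13, 11, 14, 12, 13])}
                       | {f"b{i}": c for i, c in enumerate([6, 7, 5, 8, 6, 7])})
    groups = pd.Series({k: ("mutated" if k.startswith("a") else "WT")
                        for k in counts.index})
    res = ai.stratified_event_summary(counts, groups, "mutated", "WT")
    assert res.mean1 > res.mean2
    assert res.mannwhitney_p < 0.01
    with pytest.raises(ValueError):
        ai.stratified_event_summary(counts, groups, "mutated", "absent")
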