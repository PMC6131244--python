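import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aiscape as ai
from aiscape.segmentation import changepoints, _merge_adjacent
from aiscape.simulate import SimulationConfig, Event, emit_probes
from conftest import make_probes, make_segments


@given(st.floats(min_value=0.0, max_value=1.0))
@settings(deadline=None, max_examples=50)
def test_mirror_baf_range_and_symmetry(baf):
    m = ai.mirror_baf(baf)
    assert 0.0 <= m <= 0.5
    assert m == pytest.approx(ai.mirror_baf(1.0 - baf))


def test_mirror_baf_examples():
    np.testing.assert_allclose(ai.mirror_baf([0.5, 0.25, 0.9, 0.1]),
                               [0.0, 0.25, 0.4, 0.4])


def test_changepoints_recover_clean_steps():
    y = np.concatenate([np.zeros(50), np.full(60, 0.4), np.zeros(40)])
    rng = np.random.default_rng(0)
    cps = changepoints(y + rng.normal(0, 0.03, len(y)))
    assert any(abs(c - 50) <= 2 for c in cps)
    assert any(abs(c - 110) <= 2 for c in cps)


def test_changepoints_constant_signal_has_none():
    assert changepoints(np.full(200, 0.1)) == []


def test_flat_null_genome_yields_no_segments():
    cfg = SimulationConfig()
    probes = emit_probes(cfg, np.random.default_rng(1), [], purity=0.8)
    probes.insert(0, "sample_id", "s1")
    assert ai.segment_sample(probes).empty


def test_cnloh_recovery_boundaries_within_five_spacings():
    """10 Mb clonal cn-LOH at purity 0.7 -> one AI segment near truth."""
    cfg = SimulationConfig()
    rng = np.random.default_rng(11)
    ev = Event("chr1", 45_000_000, 55_000_000, "cnloh", 1.0, 2, 0, "t")
    probes = emit_probes(cfg, rng, [ev], purity=0.7)
    probes.insert(0, "sample_id", "s1")
    segs = ai.segment_sample(probes)
    hit = segs[(segs["chrom"] == "chr1") & (segs["start"] < 55e6)
               & (segs["end"] > 45e6)]
    assert len(hit) == 1
    spacing = 1e6 / cfg.snp_density_per_mb
    assert abs(hit["start"].iloc[0] - 45e6) <= 5 * spacing
    assert abs(hit["end"].iloc[0] - 55e6) <= 5 * spacing
    assert hit["klass"].iloc[0] == "loss"


def test_mbaf_below_threshold_not_called():
    """Deviation just under the AI threshold stays uncalled; above is called."""
    for delta, expect_called in ((0.065, False), (0.09, True)):
        baf = 0.5 + delta * np.tile([1, -1], 300)
        probes = make_probes(baf=baf)
        segs = ai.segment_sample(probes)
        assert (len(segs) > 0) == expect_called, delta


def test_unsorted_probes_error():
    probes = make_probes(baf=np.full(30, 0.5))
    probes.loc[5, "pos"] = 0
    with pytest.raises(ValueError, match="unsorted"):
        ai.segment_sample(probes)


@pytest.mark.parametrize("lrr,expected", [
    (0.3, "gain"), (0.0, "loss"), (-0.4, "loss")])
def test_classification_by_mean_lrr(lrr, expected):
    seg = make_segments([("chr1", 0, 1000, "s", "loss", lrr, 0.2, 50)])
    assert ai.classify_segments(seg)["klass"].iloc[0] == expected


def test_simulated_gain_and_cnloh_classification():
    """c_t=3 at rho>=0.5 classifies gain; cn-LOH classifies loss."""
    cfg = SimulationConfig()
    rng = np.random.default_rng(5)
    events = [Event("chr1", 10_000_000, 30_000_000, "gain", 1.0, 3, 2, "t"),
              Event("chr2", 10_000_000, 30_000_000, "cnloh", 1.0, 2, 0, "t")]
    probes = emit_probes(cfg, rng, events, purity=0.6)
    probes.insert(0, "sample_id", "s1")
    segs = ai.segment_sample(probes)
    gain = segs[(segs["chrom"] == "chr1") & (segs["start"] < 3e7)
                & (segs["end"] > 1e7)]
    loss = segs[(segs["chrom"] == "chr2") & (segs["start"] < 3e7)
                & (segs["end"] > 1e7)]
    assert (gain["klass"] == "gain").all() and len(gain)
    assert (loss["klass"] == "loss").all() and len(loss)


def test_merge_adjacent_same_class_segments():
    segs = [dict(chrom="chr1", start=0, end=1_000_000, sample_id="s",
                 klass="loss", mean_lrr=-0.2, mean_mbaf=0.2, n_probes=100),
            dict(chrom="chr1", start=1_500_000, end=2_500_000, sample_id="s",
                 klass="loss", mean_lrr=-0.4, mean_mbaf=0.3, n_probes=100),
            dict(chrom="chr1", start=10_000_000, end=11_000_000, sample_id="s",
                 klass="loss", mean_lrr=-0.2, mean_mbaf=0.2, n_probes=50)]
    merged = _merge_adjacent(segs, gap=1_000_000)
    assert len(merged) == 2
    assert merged[0]["end"] == 2_500_000
    assert merged[0]["mean_mbaf"] == pytest.approx(0.25)


def test_homozygous_deletion_run_calling():
    lrr = np.zeros(100)
    lrr[40:50] = -2.0      # 10-probe deep-loss run
    lrr[70] = -2.0         # isolated probe: below min run length
    probes = make_probes(baf=np.full(100, 0.5), lrr=lrr)
    calls = ai.call_homozygous_deletions(probes)
    assert len(calls) == 1
    assert calls["n_probes"].iloc[0] == 10
    assert calls["klass"].iloc[0] == "homozygous_deletion"
    # nothing below threshold -> no calls
    quiet = make_probes(baf=np.full(50, 0.5), lrr=np.full(50, -0.5))
    assert ai.call_homozygous_deletions(quiet).empty


def test_estimate_purity_from_clonal_cnloh():
    segs = make_segments([
        ("chr1", 0, 10**7, "s", "loss", 0.02, 0.40, 500),   # clonal cn-LOH, rho=0.8
        ("chr2", 0, 10**7, "s", "loss", -0.3, 0.25, 500)])  # deletion, ignored
    assert ai.estimate_purity(segs) == pytest.approx(0.8)
    assert ai.estimate_purity(segs, metadata_purity=0.65) == 0.65
    gains_only = make_segments([("chr1", 0, 10**7, "s", "gain", 0.3, 0.15, 500)])
    assert ai.estimate_purity(gains_only) is None


@pytest.mark.parametrize("mbaf,lrr,rho,model,expected_f", [
    (0.30, 0.0, 0.6, "cnloh", 1.0),
    (1 / 6, -0.25, 0.5, "deletion", 1.0),   # observed BAF 1/3
    (0.0, 0.0, 0.7, "cnloh", 0.0),
])
def test_estimate_clonality(mbaf, lrr, rho, model, expected_f):
    seg = make_segments([("chr1", 0, 1000, "s", "loss", lrr, mbaf, 50)]).iloc[0]
    est = ai.estimate_clonality(seg, rho)
    assert est.model == model
    assert est.clonality == pytest.approx(expected_f, abs=1e-9)
    assert not est.flagged


def test_estimate_clonality_requires_positive_purity():
    seg = make_segments([("chr1", 0, 1000, "s", "loss", 0.0, 0.2, 50)]).iloc[0]
    with pytest.raises(ValueError):
        ai.estimate_clonality(seg, 0.0)


def test_clonality_recovery_unbiased_on_simulation():
    """f-hat within 0.05 of truth for clonal and subclonal events."""
    cfg = SimulationConfig()
    for rho in (0.4, 0.6, 0.8):
        for f_true in (1.0, 0.6):
            ests = []
            for rep in range(5):
                rng = np.random.default_rng(1000 * rep + int(10 * rho + 100 * f_true))
                ev = Event("chr1", 40_000_000, 60_000_000, "cnloh", f_true, 2, 0, "t")
                probes = emit_probes(cfg, rng, [ev], purity=rho)
                probes.insert(0, "sample_id", "s1")
                segs = ai.segment_sample(probes)
                hit = segs[(segs["chrom"] == "chr1") & (segs["start"] < 6e7)
                           & (segs["end"] > 4e7)]
                ests.append(ai.estimate_clonality(hit.iloc[0], rho).clonality)
            assert abs(np.mean(ests) - f_true) <= 0.05, (rho, f_true)


def test_ai_burden_and_group_fold():
    segs = make_segments([
        ("chr1", 0, 1_000_000, "a", "loss", -0.2, 0.2, 100),
        ("chr1", 5_000_000, 7_000_000, "a", "gain", 0.3, 0.1, 100),
        ("chr2", 0, 2_000_000, "b", "loss", -0.2, 0.2, 100),
        ("chr2", 1_000_000, 3_000_000, "b", "loss", -0.2, 0.2, 100)])
    burdens = ai.ai_burden(segs)
    assert burdens["a"] == 3_000_000
    assert burdens["b"] == 3_000_000        # overlap counted once
    groups = pd.Series({"a": "MSS", "b": "MSI"})
    burdens2 = pd.Series({"a": 39e6, "b": 10e6})
    assert ai.group_fold(burdens2, groups, "MSS", "MSI") == pytest.approx(3.9)
    with pytest.raises(ValueError):
        ai.group_fold(burdens2, groups, "MSS", "unknown")


def test_burden_overlap_union_matches_brute_force():
    rng = np.random.default_rng(4)
    starts = rng.integers(0, 900, 20)
    ends = starts + rng.integers(1, 100, 20)
    segs = make_segments([("chr1", s, e, "s", "loss", -0.2, 0.2, 10)
                          for s, e in zip(starts, ends)])
    # brute force on a 1 kb toy genome
    covered = np.zeros(1000, dtype=bool)
    for s, e in zip(starts, ends):
        covered[s:e] = True
    assert ai.ai_burden(segs)["s"] == covered.sum()
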