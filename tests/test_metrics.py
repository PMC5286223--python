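"""Window metrics, cumulative skew, clustering and propensity labels."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from telodrip import (
    CompositionBlock,
    SubtelomereRecord,
    SyntheticSubteloConfig,
    classify_hybrid_prone,
    cluster_profiles,
    cumulative_gc_skew,
    make_subtelomere,
    sliding_window_profile,
    window_metrics,
)
from conftest import random_dna

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(REVCOMP)[::-1]


def naive_metrics(seq: str):
    """Independent recount: explicit base tally and dinucleotide scan."""
    counts = Counter(seq)
    g, c = counts["G"], counts["C"]
    non_n = len(seq) - counts["N"]
    cg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    skew = (g - c) / (g + c) if g + c else float("nan")
    return skew, (g + c) / non_n if non_n else float("nan"), cg / len(seq)


dna = hst.text(alphabet="ACGT", min_size=1, max_size=300)


@pytest.mark.parametrize("seq,exp_skew,exp_gc,exp_cpg", [
    ("GGGG", 1.0, 1.0, 0.0),
    ("TTAGGG" * 40, 1.0, 0.5, 0.0),
    ("ACGCGT", 0.0, 4 / 6, 2 / 6),
])
def test_window_metrics_worked_examples(seq, exp_skew, exp_gc, exp_cpg):
    skew, gc, cpg = window_metrics(seq)
    assert skew == pytest.approx(exp_skew)
    assert gc == pytest.approx(exp_gc)
    assert cpg == pytest.approx(exp_cpg)


def test_window_metrics_zero_gc_undefined():
    skew, gc, _ = window_metrics("ATAT")
    assert np.isnan(skew)
    assert gc == 0.0


def test_window_metrics_excludes_n():
    # Ns drop out of counts and of the gc denominator
    skew, gc, _ = window_metrics("GGNN")
    assert skew == 1.0
    assert gc == 1.0


def test_window_metrics_empty_errors():
    with pytest.raises(ValueError):
        window_metrics("")


def test_obs_exp_cpg_mode():
    # CG content: 2 C, 2 G, 2 CG in 6 bp -> obs/exp = 2*6/(2*2)
    _, _, oe = window_metrics("ACGCGT", cpg_mode="obs_exp")
    assert oe == pytest.approx(3.0)


@given(dna)
def test_skew_antisymmetric_under_revcomp(s):
    skew, _, _ = window_metrics(s)
    skew_rc, _, _ = window_metrics(revcomp(s))
    if np.isnan(skew):
        assert np.isnan(skew_rc)
    else:
        assert skew_rc == pytest.approx(-skew)


@given(dna)
def test_gc_and_cpg_strand_invariant(s):
    # CpG is its own reverse complement as a dinucleotide pattern
    _, gc, cpg = window_metrics(s)
    _, gc_rc, cpg_rc = window_metrics(revcomp(s))
    assert gc_rc == pytest.approx(gc)
    assert cpg_rc == pytest.approx(cpg)


@given(dna)
def test_metric_ranges(s):
    skew, gc, cpg = window_metrics(s)
    if not np.isnan(skew):
        assert -1.0 <= skew <= 1.0
    assert 0.0 <= gc <= 1.0
    assert 0.0 <= cpg <= 0.5


def test_windowed_equals_bruteforce_recount(rng):
    """Profiled metrics equal an independent per-window recount on 100
    random 2 kb sequences."""
    for _ in range(100):
        seq = random_dna(rng, 2000, "ACGTN")
        rec = SubtelomereRecord(id="r", seq=seq)
        prof = sliding_window_profile(rec, window_len=200, step=100)
        assert prof.n_windows == 19  # floor((2000-200)/100)+1
        for i, s in enumerate(prof.window_starts):
            exp = naive_metrics(seq[s:s + 200])
            got = (prof.skew[i], prof.gc_content[i], prof.cpg_density[i])
            for e, g in zip(exp, got):
                assert (np.isnan(e) and np.isnan(g)) or g == pytest.approx(e)


def test_profile_region_and_errors(simple_record):
    record, _ = simple_record
    prof = sliding_window_profile(record, region=(0, 1000), window_len=200,
                                  step=100)
    assert prof.n_windows == 9
    with pytest.raises(ValueError):
        sliding_window_profile(record, region=(0, 100), window_len=200)
    with pytest.raises(ValueError):
        sliding_window_profile(record, window_len=200, step=300)


def test_homogeneous_block_window_skew():
    """Windows of a g=0.4/c=0.1 block scatter around expected skew 0.6;
    bounds are the +-0.35 per-window / +-0.05 mean band established by
    simulating the 200 bp binomial draw."""
    cfg = SyntheticSubteloConfig(
        record_id="h", blocks=[CompositionBlock(2000, 0.4, 0.1, 0.25, 0.25)],
        seed=13)
    record, _ = make_subtelomere(cfg)
    prof = sliding_window_profile(record)
    assert np.all(np.abs(prof.skew - 0.6) < 0.35)
    assert abs(prof.skew.mean() - 0.6) < 0.05


# ---------------------------------------------------------------------------
# cumulative downstream skew
# ---------------------------------------------------------------------------

def test_cumulative_skew_pure_repeats():
    rec = SubtelomereRecord(id="t", seq="AT" * 100 + "TTAGGG" * 50,
                            tss_pos=200)
    assert cumulative_gc_skew(rec) == 1.0


def test_cumulative_skew_balanced_zero():
    rec = SubtelomereRecord(id="b", seq="A" * 100 + "GC" * 100, tss_pos=100)
    assert cumulative_gc_skew(rec) == 0.0


def test_cumulative_skew_block_expectation():
    """g=0.6/c=0.2 1 kb block: skew 0.5 +- 0.05 (about 1.6 sigma of the
    multinomial draw; verified by simulation)."""
    cfg = SyntheticSubteloConfig(
        record_id="c", blocks=[CompositionBlock(1000, 0.6, 0.2, 0.1, 0.1)],
        tss_pos=0, seed=17)
    record, _ = make_subtelomere(cfg)
    assert cumulative_gc_skew(record) == pytest.approx(0.5, abs=0.05)


def test_cumulative_skew_ignores_windowing(simple_record):
    """The score is a raw-count statistic over [TSS, tract): recomputing it
    from the sequence slice gives the identical value."""
    record, _ = simple_record
    region = record.seq[record.tss_pos:record.subtelomere_end]
    g, c = region.count("G"), region.count("C")
    assert cumulative_gc_skew(record) == pytest.approx((g - c) / (g + c))


def test_cumulative_skew_requires_tss():
    rec = SubtelomereRecord(id="n", seq="ACGT" * 100)
    with pytest.raises(ValueError, match="TSS"):
        cumulative_gc_skew(rec)


def test_cumulative_skew_promoter_anchor(simple_record):
    record, _ = simple_record
    s_tss = cumulative_gc_skew(record, anchor="tss")
    s_prom = cumulative_gc_skew(record, anchor="promoter_start")
    region = record.seq[record.promoter[0]:record.subtelomere_end]
    g, c = region.count("G"), region.count("C")
    assert s_prom == pytest.approx((g - c) / (g + c))
    assert s_prom != s_tss  # different anchors, different regions


# ---------------------------------------------------------------------------
# clustering and classification
# ---------------------------------------------------------------------------

def _skewed_cohort(n_high=10, n_zero=10, seed0=100):
    records, labels = [], {}
    for i in range(n_high + n_zero):
        high = i < n_high
        g, c = (0.4, 0.1) if high else (0.25, 0.25)
        cfg = SyntheticSubteloConfig(
            record_id=f"r{i:02d}",
            blocks=[CompositionBlock(1000, 0.25, 0.25, 0.25, 0.25),
                    CompositionBlock(1000, g, c, (1 - g - c) / 2,
                                     (1 - g - c) / 2)],
            tss_pos=1000, promoter=(900, 1000), seed=seed0 + i)
        rec, _ = make_subtelomere(cfg)
        records.append(rec)
        labels[rec.id] = high
    return records, labels


def test_cluster_two_groups_top_level_split():
    """A cohort of 10 high-skew and 10 neutral records splits into the two
    truth groups at the top of the dendrogram."""
    records, labels = _skewed_cohort()
    profiles = [sliding_window_profile(r) for r in records]
    order, Z, excluded = cluster_profiles(profiles,
                                          [r.promoter[1] for r in records])
    assert excluded == []
    # the top-level merge separates leaves into the two truth groups
    from scipy.cluster.hierarchy import fcluster

    assign = fcluster(Z, t=2, criterion="maxclust")
    ids = [p.record_id for p in profiles]
    groups = {}
    for rid, a in zip(ids, assign):
        groups.setdefault(a, set()).add(labels[rid])
    assert sorted(map(tuple, groups.values())) == [(False,), (True,)]


def test_cluster_identical_profiles_merge_first():
    records, _ = _skewed_cohort(n_high=3, n_zero=0)
    profiles = [sliding_window_profile(r) for r in records]
    profiles[1] = profiles[0]  # duplicate profile under a different id
    order, Z, _ = cluster_profiles(profiles,
                                   [r.promoter[1] for r in records])
    assert Z[0, 2] == 0.0  # first merge at distance zero
    assert set(map(int, Z[0, :2])) == {0, 1}


def test_cluster_excludes_undefined_with_warning():
    records, _ = _skewed_cohort(n_high=5, n_zero=0)
    profiles = [sliding_window_profile(r) for r in records]
    bad = SubtelomereRecord(id="undef", seq="AT" * 1000, tss_pos=100,
                            promoter=(0, 100))
    profiles.append(sliding_window_profile(bad))
    bounds = [r.promoter[1] for r in records] + [100]
    with pytest.warns(UserWarning, match="undef"):
        order, _, excluded = cluster_profiles(profiles, bounds)
    assert excluded == ["undef"]
    assert len(order) == 5


def test_classifier_recovers_planted_labels():
    """Cumulative-skew labels match generator truth at |skew| = 0.3."""
    records, labels = [], {}
    for i in range(20):
        prone = i % 2 == 0
        g, c = (0.325, 0.175) if prone else (0.175, 0.325)  # skew +-0.3
        cfg = SyntheticSubteloConfig(
            record_id=f"s{i:02d}",
            blocks=[CompositionBlock(2000, g, c, 0.25, 0.25)],
            tss_pos=0, seed=300 + i)
        rec, truth = make_subtelomere(cfg)
        assert truth.prone is prone
        records.append(rec)
        labels[rec.id] = prone
    got = classify_hybrid_prone(records)
    assert got == labels


def test_classifier_threshold_strict():
    # skew exactly at the threshold is NOT prone (strict inequality)
    rec = SubtelomereRecord(id="tie", seq="A" * 10 + "GCGC" * 50, tss_pos=10)
    assert cumulative_gc_skew(rec) == 0.0
    assert classify_hybrid_prone([rec], threshold=0.0) == {"tie": False}


def test_classifier_unscorable_never_false():
    rec = SubtelomereRecord(id="u", seq="ATATAT" * 50, tss_pos=0)
    assert classify_hybrid_prone([rec]) == {"u": None}


def test_pure_telomere_downstream_is_prone():
    rec = SubtelomereRecord(id="tel", seq="AT" * 50 + "TTAGGG" * 40,
                            tss_pos=100)
    assert classify_hybrid_prone([rec]) == {"tel": True}
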