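"""Unit and oracle tests for the anchored varietal SNP caller."""

import numpy as np
import pytest

from homeosnp.io_formats import AlignedRead
from homeosnp.transcriptome import (
    CallerConfig,
    Region,
    SnpCall,
    build_pileup,
    call_transcriptome,
    call_varietal_snps,
    classify_subgenome_sites,
    find_dense_regions,
    merge_nonredundant,
)
from oracles import brute_pileup, run_micro_comparison


def mread(rid, v, start, seq, cigar=None):
    return AlignedRead(rid, v, "c1", start, cigar or [("M", len(seq))], seq)


def pileup_of(reads, length=30):
    reads = sorted(reads, key=lambda r: (r.ref_start, r.read_id))
    varieties = sorted({r.variety_id for r in reads})
    return build_pileup(reads, length, "c1", varieties)


# ---------------------------------------------------------------------------
# build_pileup


def test_pileup_counts_identical_reads():
    pile = pileup_of([mread("a", "v1", 0, "A" * 10), mread("b", "v1", 0, "A" * 10)])
    for pos in range(10):
        assert pile.site_counts(pos) == {"v1": {"A": 2}}
    assert pile.site_counts(10) == {}


def test_pileup_deletion_contributes_nothing():
    pile = pileup_of([mread("a", "v1", 0, "AAAACCCC", [("M", 4), ("D", 2), ("M", 4)])])
    assert pile.site_counts(3) == {"v1": {"A": 1}}
    assert pile.site_counts(4) == {} and pile.site_counts(5) == {}
    assert pile.site_counts(6) == {"v1": {"C": 1}}


def test_pileup_matches_bruteforce_on_random_reads():
    rng = np.random.default_rng(31)
    bases = "ACGT"
    for _ in range(20):
        reads = []
        for i in range(int(rng.integers(5, 25))):
            v = f"v{rng.integers(1, 4)}"
            rl = int(rng.integers(5, 15))
            start = int(rng.integers(0, 30 - rl))
            seq = "".join(bases[j] for j in rng.integers(0, 4, rl))
            # sprinkle in splice/softclip ops
            if rng.random() < 0.3 and rl >= 6:
                cigar = [("M", 3), ("N", 4), ("M", rl - 3)]
            elif rng.random() < 0.3 and rl >= 4:
                cigar = [("S", 2), ("M", rl - 2)]
            else:
                cigar = [("M", rl)]
            reads.append(mread(f"r{i}", v, start, seq, cigar))
        pile = pileup_of(reads, 40)
        expected = brute_pileup(reads, 40)
        for pos in range(40):
            assert pile.site_counts(pos) == expected.get(pos, {})


def test_pileup_rejects_unsorted_reads():
    reads = [mread("a", "v1", 5, "AAAA"), mread("b", "v1", 0, "AAAA")]
    with pytest.raises(ValueError):
        build_pileup(reads, 30, "c1", ["v1"])


# ---------------------------------------------------------------------------
# find_dense_regions


def _uniform_reads(varieties, length=400, depth=40, read_len=20):
    reads = []
    for v in varieties:
        n = depth * length // read_len
        for i in range(n):
            start = (i * 7919) % (length - read_len)
            reads.append(mread(f"{v}_{i}", v, start, "A" * read_len))
    return sorted(reads, key=lambda r: (r.ref_start, r.read_id))


def test_uniform_coverage_yields_single_region():
    reads = _uniform_reads(["v1", "v2"])
    pile = build_pileup(reads, 400, "c1", ["v1", "v2"])
    regions = find_dense_regions(pile, min_depth=8, window=100, step=50)
    assert len(regions) == 1
    assert regions[0].start == 0 and regions[0].end >= 350


def test_region_requires_every_variety():
    reads = _uniform_reads(["v1"])
    pile = build_pileup(reads, 400, "c1", ["v1", "v2"])
    assert find_dense_regions(pile, min_depth=8) == []


def test_coverage_gap_splits_regions():
    reads = [r for r in _uniform_reads(["v1", "v2"], length=1000)
             if not (300 <= r.ref_start < 500)]
    pile = build_pileup(reads, 1000, "c1", ["v1", "v2"])
    regions = find_dense_regions(pile, min_depth=8, window=100, step=50)
    assert len(regions) == 2
    assert regions[0].end <= 450 and regions[1].start >= 300


# ---------------------------------------------------------------------------
# subgenome anchors


def _phased_reads(spec_by_variety, length=10):
    """spec: variety -> list of (count, {pos: base}) fragments over A-runs."""
    reads = []
    i = 0
    for v, frag_specs in spec_by_variety.items():
        for count, overrides in frag_specs:
            for _ in range(count):
                seq = "".join(overrides.get(p, "C") for p in range(length))
                reads.append(mread(f"{v}_{i}", v, 0, seq))
                i += 1
    return reads


def test_consistently_phased_biallelic_sites_are_anchors():
    # both varieties half A/half T at positions 2 and 8, phased together
    reads = _phased_reads({
        "v1": [(10, {2: "A", 8: "A"}), (10, {2: "T", 8: "T"})],
        "v2": [(10, {2: "A", 8: "A"}), (10, {2: "T", 8: "T"})],
    })
    pile = pileup_of(reads, 10)
    anchors = classify_subgenome_sites(Region("c1", 0, 10), pile)
    assert sorted(a.pos for a in anchors) == [2, 8]


def test_monoallelic_variety_blocks_anchor():
    reads = _phased_reads({
        "v1": [(10, {2: "A"}), (10, {2: "T"})],
        "v2": [(20, {2: "A"})],
    })
    pile = pileup_of(reads, 10)
    assert classify_subgenome_sites(Region("c1", 0, 10), pile) == []


def test_inconsistent_phasing_prunes_weaker_candidate():
    # sites 2 and 8 phase consistently with strong support; site 5 shows
    # three joint haplotypes against them and has lower support
    reads = _phased_reads({
        "v1": [(8, {2: "A", 5: "A", 8: "A"}), (8, {2: "T", 5: "T", 8: "T"}),
               (4, {2: "A", 5: "T", 8: "A"})],
        "v2": [(10, {2: "A", 5: "A", 8: "A"}), (10, {2: "T", 5: "T", 8: "T"})],
    })
    pile = pileup_of(reads, 10)
    anchors = classify_subgenome_sites(Region("c1", 0, 10), pile)
    assert sorted(a.pos for a in anchors) == [2, 8]


# ---------------------------------------------------------------------------
# varietal calling


def test_worked_example_phased_varietal_call():
    # anchor g=8 (A/T in both varieties); target s=2: v1 splits by phase
    # (A-phase carries A, T-phase carries G), v2 carries G in both phases
    reads = _phased_reads({
        "v1": [(5, {2: "A", 8: "A"}), (5, {2: "G", 8: "T"})],
        "v2": [(5, {2: "G", 8: "A"}), (5, {2: "G", 8: "T"})],
    })
    pile = pileup_of(reads, 10)
    region = Region("c1", 0, 10)
    anchors = classify_subgenome_sites(region, pile, min_depth=8)
    assert [a.pos for a in anchors] == [8]
    calls = call_varietal_snps(region, pile, anchors, min_depth=8)
    (call,) = calls
    assert call.class_label == "VARIETAL"
    assert call.pos == 2 and call.alleles == ("A", "G")
    assert call.anchors == [8]
    assert call.variety_alleles == {"v1": ("A", "G"), "v2": ("G", "G")}


def test_unanchored_difference_is_equivocal():
    reads = _phased_reads({
        "v1": [(5, {2: "A"}), (5, {2: "G"})],
        "v2": [(10, {2: "G"})],
    })
    pile = pileup_of(reads, 10)
    region = Region("c1", 0, 10)
    calls = call_varietal_snps(region, pile, anchors=[], min_depth=8)
    (call,) = calls
    assert call.class_label == "EQUIVOCAL" and call.pos == 2
    assert call.anchors == []


def test_identical_varieties_yield_no_varietal_calls():
    reads = _phased_reads({
        "v1": [(5, {2: "A", 8: "A"}), (5, {2: "G", 8: "T"})],
        "v2": [(5, {2: "A", 8: "A"}), (5, {2: "G", 8: "T"})],
    })
    pile = pileup_of(reads, 10)
    region = Region("c1", 0, 10)
    anchors = classify_subgenome_sites(region, pile, min_depth=8)
    calls = call_varietal_snps(region, pile, anchors, min_depth=8)
    assert [c for c in calls if c.class_label == "VARIETAL"] == []


def test_anchor_beyond_distance_is_not_used():
    reads = _phased_reads({
        "v1": [(5, {2: "A", 8: "A"}), (5, {2: "G", 8: "T"})],
        "v2": [(5, {2: "G", 8: "A"}), (5, {2: "G", 8: "T"})],
    })
    pile = pileup_of(reads, 10)
    region = Region("c1", 0, 10)
    anchors = classify_subgenome_sites(region, pile, min_depth=8)
    calls = call_varietal_snps(region, pile, anchors, min_depth=8,
                               anchor_distance=3)
    assert [c.class_label for c in calls] == ["EQUIVOCAL"]


# ---------------------------------------------------------------------------
# merging


def _call(pos, alleles=("A", "G"), label="VARIETAL", anchors=(8,),
          va=None):
    return SnpCall("c1", pos, alleles, label, "U", list(anchors),
                   va or {"v1": ("A", "G")}, 10)


def test_merge_deduplicates_same_key():
    merged = merge_nonredundant([_call(5), _call(5)])
    assert len(merged) == 1


def test_merge_keeps_distinct_allele_pairs():
    merged = merge_nonredundant([_call(5, ("A", "G")), _call(5, ("A", "C"))])
    assert len(merged) == 2


def test_merge_incompatible_variety_alleles_demoted_to_conflict():
    a = _call(5, va={"v1": ("A", "G")})
    b = _call(5, va={"v1": ("G", "A")})
    (merged,) = merge_nonredundant([a, b])
    assert merged.class_label == "CONFLICT"


def test_merge_is_order_independent():
    calls = [_call(5, va={"v1": ("A", "G")}), _call(5, va={"v2": ("G", "G")}),
             _call(9, ("C", "T"), "EQUIVOCAL", (), va={}), _call(2)]
    a = merge_nonredundant(calls)
    b = merge_nonredundant(calls[::-1])
    assert [(c.pos, c.class_label, c.variety_alleles, c.anchors) for c in a] == \
           [(c.pos, c.class_label, c.variety_alleles, c.anchors) for c in b]


# ---------------------------------------------------------------------------
# whole-pipeline properties


def test_caller_is_invariant_to_read_input_order(small_dataset):
    from homeosnp.synthetic import simulate_rnaseq

    reads, _ = simulate_rnaseq(small_dataset.varieties, depth=20, seed=41)
    ref_lengths = {small_dataset.reference.name: len(small_dataset.reference)}
    calls1, _, _ = call_transcriptome(reads, ref_lengths)
    rng = np.random.default_rng(42)
    shuffled = list(reads)
    rng.shuffle(shuffled)
    calls2, _, _ = call_transcriptome(shuffled, ref_lengths)
    key = lambda c: (c.pos, c.class_label, c.alleles, tuple(c.anchors),
                     tuple(sorted(c.variety_alleles.items())))
    assert sorted(map(key, calls1)) == sorted(map(key, calls2))


def test_no_varietal_call_lacks_a_nearby_anchor(recovery_run):
    ds, reads, calls, anchors, stats = recovery_run
    cfg = CallerConfig()
    anchor_pos = np.array(sorted(a.pos for a in anchors))
    for c in calls:
        if c.class_label == "VARIETAL":
            assert c.anchors, "varietal call without anchors"
            assert min(abs(a - c.pos) for a in c.anchors) <= cfg.anchor_distance


def test_caller_matches_bruteforce_oracle_on_micro_regions():
    agree, mismatches = run_micro_comparison(200, seed=5)
    assert agree == 200, mismatches[:1]
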