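"""Subgenome-anchored varietal SNP calling from RNA-seq pileups.

The central idea: over a single diploid reference, reads from both homeologs
(A and D subgenomes) of every variety co-align.  A biallelic site seen in
*every* variety with both alleles well supported is a subgenome-specific SNP
— useless as a varietal marker but invaluable as a phase anchor.  A
candidate varietal SNP is accepted only when reads covering both it and a
flanking anchor can be partitioned by the anchor allele into two phases
(i.e. subgenomes) such that exactly one phase is polymorphic *between*
varieties.  Between-variety differences with no qualifying anchor are
deliberately refused (EQUIVOCAL): without phase information they cannot be
told apart from unequal homeolog expression or shallow sampling.

Pipeline: `build_pileup` -> `find_dense_regions` ->
`classify_subgenome_sites` -> `call_varietal_snps` -> `merge_nonredundant`,
wrapped by `call_transcriptome`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._util import BASE_INDEX, DNA
from .io_formats import AlignedRead, ReferenceSequence, SnpRecordOut

logger = logging.getLogger(__name__)

VARIETAL = "VARIETAL"
SUBGENOME = "SUBGENOME"
EQUIVOCAL = "EQUIVOCAL"
CONFLICT = "CONFLICT"


@dataclass
class CallerConfig:
    """All thresholds of the transcriptome caller, with their defaults.

    min_depth: mean per-variety coverage a window needs (and the per-variety
        depth above which a site must show the subgenome pattern).  Default 8
        because resolving two phases in two varieties needs at least two
        reads per phase per variety under 1:1 homeolog expression.
    window/step: sliding read-density window geometry (bp).
    anchor_distance: maximum distance (bp) between a varietal candidate and
        its anchor; default 90 = the RNA read length, since phasing requires
        co-occurrence on single reads.
    min_allele_support: reads required for an allele to be "observed".
    min_within_freq: minimum within-variety frequency of each allele at a
        subgenome-anchor candidate.
    min_phase_support / phase_purity: reads and majority fraction required
        for a per-variety per-phase consensus allele.
    """

    min_depth: int = 8
    window: int = 100
    step: int = 50
    region_max: int = 10_000
    min_allele_support: int = 2
    min_within_freq: float = 0.2
    max_iter: int = 10
    min_phase_support: int = 2
    phase_purity: float = 0.9
    anchor_distance: int = 90

    def as_header_lines(self) -> list[str]:
        return [f"##homeosnp_param={k}:{v}" for k, v in vars(self).items()]


@dataclass
class Region:
    """A read-dense interval (0-based half-open) on one reference."""

    ref_name: str
    start: int
    end: int


@dataclass
class Anchor:
    """A subgenome-specific SNP usable as a phase anchor."""

    pos: int
    alleles: tuple[str, str]  # phase0 allele first (higher total support)
    support: int


@dataclass
class SnpCall:
    """A classified site with its phase evidence."""

    ref_name: str
    pos: int  # 0-based
    alleles: tuple[str, str]
    class_label: str
    subgenome: str = "U"
    anchors: list[int] = field(default_factory=list)  # 0-based anchor positions
    variety_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    depth: int = 0

    def to_record(self, reference: ReferenceSequence) -> SnpRecordOut | None:
        """Serialize against the reference; None if the reference base is
        not among the observed alleles (cannot be expressed as REF/ALT)."""
        ref_base = reference.seq[self.pos]
        if ref_base not in self.alleles:
            logger.warning("%s:%d reference base %s not among alleles %s; dropped",
                           self.ref_name, self.pos + 1, ref_base, self.alleles)
            return None
        alt = self.alleles[0] if self.alleles[1] == ref_base else self.alleles[1]
        return SnpRecordOut(
            ref_name=self.ref_name, pos_1based=self.pos + 1,
            ref_allele=ref_base, alt_allele=alt, class_label=self.class_label,
            subgenome_label=self.subgenome,
            anchor_positions=[p + 1 for p in self.anchors],
            variety_alleles=dict(self.variety_alleles), depth=self.depth)


class Pileup:
    """Per-variety base counts over one reference, plus the reads themselves.

    Counts live in (length, 4) arrays per variety.  For phase evidence the
    unit is the *fragment*: mates of a read pair come from one molecule and
    therefore one subgenome/haplotype, so joint allele counts at a site
    pair are taken per fragment (reads sharing a read id up to a trailing
    ``/1``/``/2`` mate suffix), not per read.
    """

    def __init__(self, ref_name: str, length: int, varieties: list[str]):
        self.ref_name = ref_name
        self.length = length
        self.varieties = list(varieties)
        self.counts = {v: np.zeros((length, 4), dtype=np.int32) for v in varieties}
        self._reads: dict[str, list[AlignedRead]] = {v: [] for v in varieties}
        self._frags: dict[str, list[list[AlignedRead]]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._max_span: dict[str, int] = {}
        self._total: np.ndarray | None = None

    def add_read(self, read: AlignedRead) -> None:
        arr = self.counts[read.variety_id]
        qidx = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        r, q = read.ref_start, 0
        for op, n in read.cigar:
            if op in "M=X":
                block = qidx[q : q + n]
                keep = np.isin(block, self._ACGT)
                ref_pos = np.arange(r, r + n)[keep]
                in_range = ref_pos < self.length
                arr[ref_pos[in_range], self._LUT[block[keep][in_range]]] += 1
                r += n
                q += n
            elif op in "DN":
                r += n
            elif op in "IS":
                q += n
        self._reads[read.variety_id].append(read)

    _ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
    _LUT = np.zeros(256, dtype=np.int64)
    for _i, _b in enumerate(b"ACGT"):
        _LUT[_b] = _i

    @staticmethod
    def fragment_id(read_id: str) -> str:
        if read_id.endswith(("/1", "/2")):
            return read_id[:-2]
        return read_id

    def finalize(self) -> None:
        for v, reads in self._reads.items():
            frags: dict[str, list[AlignedRead]] = {}
            for r in reads:
                frags.setdefault(self.fragment_id(r.read_id), []).append(r)
            groups = sorted(frags.values(),
                            key=lambda g: (min(r.ref_start for r in g),
                                           g[0].read_id))
            self._frags[v] = groups
            self._starts[v] = np.array(
                [min(r.ref_start for r in g) for g in groups], dtype=np.int64)
            self._max_span[v] = max(
                (max(r.ref_end for r in g) - min(r.ref_start for r in g)
                 for g in groups), default=0)

    def site_counts(self, pos: int) -> dict[str, dict[str, int]]:
        """Per-variety base->count map at one position (zero counts omitted)."""
        out = {}
        for v in self.varieties:
            row = self.counts[v][pos]
            m = {DNA[i]: int(row[i]) for i in range(4) if row[i] > 0}
            if m:
                out[v] = m
        return out

    def coverage(self, variety: str) -> np.ndarray:
        return self.counts[variety].sum(axis=1)

    def total_counts(self) -> np.ndarray:
        """(length, 4) base counts summed over varieties (cached)."""
        if self._total is None:
            total = np.zeros((self.length, 4), dtype=np.int64)
            for v in self.varieties:
                total += self.counts[v]
            self._total = total
        return self._total

    def co_covering(self, variety: str, lo: int, hi: int) -> list[list[AlignedRead]]:
        """Fragments of one variety whose alignment extent spans lo and hi.

        A fragment is returned when its [start, end) extent contains both
        positions; bases inside the inter-mate gap resolve to None later.
        """
        frags = self._frags.get(variety, [])
        if not frags:
            return []
        starts = self._starts[variety]
        span = self._max_span[variety]
        i0 = int(np.searchsorted(starts, lo - span, side="left"))
        i1 = int(np.searchsorted(starts, lo, side="right"))
        return [g for g in frags[i0:i1]
                if max(r.ref_end for r in g) > hi]

    @staticmethod
    def fragment_base(frag: list[AlignedRead], pos: int) -> str | None:
        """The fragment's base at pos; None if uncovered or mates disagree."""
        bases = {b for r in frag if (b := r.base_at(pos)) is not None}
        if len(bases) == 1:
            return bases.pop()
        return None


def build_pileup(reads: list[AlignedRead], ref_length: int,
                 ref_name: str | None = None,
                 varieties: list[str] | None = None) -> Pileup:
    """Accumulate per-variety base counts from position-sorted reads.

    Deleted/skipped (D/N) reference positions contribute nothing; soft
    clips are excluded; non-ACGT read bases are dropped.
    """
    if varieties is None:
        seen = []
        for r in reads:
            if r.variety_id not in seen:
                seen.append(r.variety_id)
        varieties = sorted(seen)
    if ref_name is None:
        if not reads:
            raise ValueError("cannot infer ref_name from empty read list")
        ref_name = reads[0].ref_name
    pile = Pileup(ref_name, ref_length, varieties)
    last = -1
    for r in reads:
        if r.ref_name != ref_name:
            raise ValueError("build_pileup handles one reference at a time")
        if r.ref_start < last:
            raise ValueError("reads must be sorted by ref_start")
        last = r.ref_start
        pile.add_read(r)
    pile.finalize()
    return pile


def find_dense_regions(pileup: Pileup, varieties: list[str] | None = None,
                       min_depth: int = 8, window: int = 100, step: int = 50,
                       region_max: int = 10_000, chunk_overlap: int = 0) -> list[Region]:
    """Sliding-window read-density scan.

    A window qualifies iff *every* listed variety has at least ``min_depth``
    mean coverage in it; overlapping qualifying windows are merged and the
    merged runs split into chunks of at most ``region_max``.  A positive
    ``chunk_overlap`` makes consecutive chunks overlap so that a candidate
    site near a chunk edge still sees its anchors (duplicated calls are
    removed by the nonredundant merge).
    """
    if varieties is None:
        varieties = pileup.varieties
    length = pileup.length
    if length == 0 or not varieties:
        return []
    starts = np.arange(0, length, step)
    ok = np.ones(len(starts), dtype=bool)
    for v in varieties:
        cov = pileup.coverage(v)
        csum = np.concatenate([[0], np.cumsum(cov)])
        ends = np.minimum(starts + window, length)
        means = (csum[ends] - csum[starts]) / (ends - starts)
        ok &= means >= min_depth
    regions: list[Region] = []
    run_start = None
    prev_end = None
    for i, w in enumerate(starts):
        w_end = min(int(w) + window, length)
        if ok[i]:
            if run_start is None:
                run_start = int(w)
            prev_end = w_end
        elif run_start is not None:
            regions.append(Region(pileup.ref_name, run_start, prev_end))
            run_start = None
    if run_start is not None:
        regions.append(Region(pileup.ref_name, run_start, prev_end))
    out: list[Region] = []
    for reg in regions:
        s = reg.start
        while reg.end - s > region_max:
            out.append(Region(reg.ref_name, s, s + region_max))
            s += region_max - chunk_overlap
        out.append(Region(reg.ref_name, s, reg.end))
    return out


def _observed_alleles(pileup: Pileup, pos: int, min_support: int) -> list[str]:
    total = pileup.total_counts()[pos]
    return [DNA[i] for i in range(4) if total[i] >= min_support]


def _biallelic_positions(region: Region, pileup: Pileup,
                         min_support: int) -> list[tuple[int, tuple[str, str]]]:
    """Positions in the region with exactly two observed alleles overall."""
    total = pileup.total_counts()[region.start : region.end]
    obs = total >= min_support
    hits = np.flatnonzero(obs.sum(axis=1) == 2)
    out = []
    for off in hits:
        i0, i1 = np.flatnonzero(obs[off])
        out.append((region.start + int(off), (DNA[i0], DNA[i1])))
    return out


def _site_total(pileup: Pileup, pos: int, alleles: tuple[str, str]) -> int:
    t = 0
    for v in pileup.varieties:
        row = pileup.counts[v][pos]
        t += int(row[BASE_INDEX[alleles[0]]] + row[BASE_INDEX[alleles[1]]])
    return t


def _anchor_candidates(region: Region, pileup: Pileup, min_allele_support: int,
                       min_within_freq: float, min_depth: int) -> list[Anchor]:
    """Sites matching the per-variety subgenome pattern (before pruning).

    A candidate shows exactly two observed alleles overall, and in every
    variety with depth >= min_depth both alleles appear with count >=
    min_allele_support and within-variety frequency >= min_within_freq.
    """
    cands: list[Anchor] = []
    for pos, alleles in _biallelic_positions(region, pileup, min_allele_support):
        b0, b1 = BASE_INDEX[alleles[0]], BASE_INDEX[alleles[1]]
        deep = 0
        ok = True
        for v in pileup.varieties:
            row = pileup.counts[v][pos]
            depth = int(row.sum())
            if depth < min_depth:
                continue
            deep += 1
            c0, c1 = int(row[b0]), int(row[b1])
            if (c0 < min_allele_support or c1 < min_allele_support
                    or c0 < min_within_freq * depth or c1 < min_within_freq * depth):
                ok = False
                break
        if not ok or deep == 0:
            continue
        tot = _site_total(pileup, pos, (alleles[0], alleles[1]))
        row_sum = pileup.total_counts()[pos]
        # phase0 allele = higher total support (ties broken alphabetically)
        a0, a1 = sorted(alleles, key=lambda b: (-row_sum[BASE_INDEX[b]], b))
        cands.append(Anchor(pos=pos, alleles=(a0, a1), support=tot))
    return cands


def _joint_counts(pileup: Pileup, variety: str, p: int, q: int) -> Counter:
    """Per-fragment joint allele counts at a site pair."""
    lo, hi = (p, q) if p <= q else (q, p)
    counts: Counter = Counter()
    for frag in pileup.co_covering(variety, lo, hi):
        a = pileup.fragment_base(frag, p)
        b = pileup.fragment_base(frag, q)
        if a is not None and b is not None:
            counts[(a, b)] += 1
    return counts


def classify_subgenome_sites(region: Region, pileup: Pileup,
                             min_allele_support: int = 2,
                             min_within_freq: float = 0.2,
                             min_depth: int = 8,
                             max_iter: int = 10) -> list[Anchor]:
    """Identify well-supported subgenome-specific SNPs in a dense region.

    Candidates from the per-variety biallelism pattern are pruned against a
    pairwise conflict graph: a co-covered candidate pair conflicts when some
    variety shows more than two well-supported joint haplotypes
    (inconsistent phasing).  The worst offender — most conflicts, then
    lowest total support, then the rightmost site — is removed and the
    survivors re-examined, up to ``max_iter`` removals.
    """
    cands = _anchor_candidates(region, pileup, min_allele_support,
                               min_within_freq, min_depth)
    # pair joints never change, so the conflict graph is computed once;
    # pairs farther apart than any fragment cannot be co-covered
    span = max((pileup._max_span.get(v, 0) for v in pileup.varieties), default=0)
    conflicts: dict[int, set[int]] = {c.pos: set() for c in cands}
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            a, b = cands[i], cands[j]
            if b.pos - a.pos > span:
                break  # cands are position-sorted
            for v in pileup.varieties:
                joint = _joint_counts(pileup, v, a.pos, b.pos)
                cells = sum(
                    1 for (x, y), n in joint.items()
                    if n >= min_allele_support and x in a.alleles and y in b.alleles)
                if cells > 2:
                    conflicts[a.pos].add(b.pos)
                    conflicts[b.pos].add(a.pos)
                    break
    support = {c.pos: c.support for c in cands}
    alive = {c.pos for c in cands}
    for _ in range(max_iter):
        active = {p: conflicts[p] & alive for p in alive}
        worst = max((p for p in alive if active[p]),
                    key=lambda p: (len(active[p]), -support[p], p),
                    default=None)
        if worst is None:
            break
        alive.discard(worst)
    return [c for c in cands if c.pos in alive]


def _phase_consensus(joint: Counter, phase_allele: str, min_phase_support: int,
                     phase_purity: float) -> tuple[str | None, int]:
    """Consensus target allele among reads carrying one anchor allele.

    Returns (allele or None, phase read count).  None when support or
    purity is insufficient — such sites are skipped, never guessed.
    """
    counts: Counter = Counter()
    for (a, b), n in joint.items():
        if a == phase_allele:
            counts[b] += n
    total = sum(counts.values())
    if total < min_phase_support:
        return None, total
    base, top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    if top < min_phase_support or top < phase_purity * total:
        return None, total
    return base, total


def _try_anchor(pileup: Pileup, s: int, anchor: Anchor, min_phase_support: int,
                phase_purity: float) -> dict[str, tuple[str, str]] | None:
    """Partition reads by anchor allele; return per-variety phase alleles if
    the varietal pattern holds, else None.

    Pattern: every variety with reads covering both sites shows both anchor
    phases with sufficient support and a clean consensus at the target in
    each phase; exactly one phase splits the varieties into >= 2 allele
    groups while the other phase is uniform.
    """
    per_variety: dict[str, tuple[str, str]] = {}
    for v in pileup.varieties:
        joint = _joint_counts(pileup, v, anchor.pos, s)
        # joint keys are (anchor base, target base); restrict to anchor alleles
        joint = Counter({k: n for k, n in joint.items() if k[0] in anchor.alleles})
        if not joint:
            continue  # variety not covered here; not compared
        cons = []
        for phase_allele in anchor.alleles:
            c, total = _phase_consensus(joint, phase_allele, min_phase_support,
                                        phase_purity)
            if total < min_phase_support or c is None:
                return None  # covered variety lacking clean two-phase evidence
            cons.append(c)
        per_variety[v] = (cons[0], cons[1])
    if len(per_variety) < 2:
        return None
    groups0 = {pa[0] for pa in per_variety.values()}
    groups1 = {pa[1] for pa in per_variety.values()}
    split0 = len(groups0) == 2 and len(groups1) == 1
    split1 = len(groups1) == 2 and len(groups0) == 1
    if split0 == split1:  # neither, or both phases polymorphic
        return None
    return per_variety


def _between_variety_polymorphic(pileup: Pileup, pos: int,
                                 min_allele_support: int) -> bool:
    sets = []
    for v in pileup.varieties:
        row = pileup.counts[v][pos]
        obs = frozenset(DNA[i] for i in range(4) if row[i] >= min_allele_support)
        if obs:
            sets.append(obs)
    return len(set(sets)) > 1


def call_varietal_snps(region: Region, pileup: Pileup, anchors: list[Anchor],
                       min_allele_support: int = 2, min_phase_support: int = 2,
                       phase_purity: float = 0.9, anchor_distance: int = 90,
                       min_depth: int = 8, min_within_freq: float = 0.2,
                       ancestral_alleles: dict[int, tuple[str, str]] | None = None,
                       ) -> list[SnpCall]:
    """Call varietal SNPs in a region, given its subgenome anchors.

    Every biallelic non-anchor site is tested against each anchor within
    ``anchor_distance``.  Sites passing the phased varietal pattern for some
    anchor become VARIETAL (or CONFLICT if the site itself also matched the
    subgenome pattern); between-variety differences with no qualifying
    anchor become EQUIVOCAL.
    """
    anchor_pos = {a.pos for a in anchors}
    candidate_pattern = {c.pos for c in _anchor_candidates(
        region, pileup, min_allele_support, min_within_freq, min_depth)}
    calls: list[SnpCall] = []
    for s, alleles in _biallelic_positions(region, pileup, min_allele_support):
        if s in anchor_pos:
            continue
        used: list[int] = []
        evidence: dict[str, tuple[str, str]] | None = None
        for anchor in anchors:
            if anchor.pos == s or abs(anchor.pos - s) > anchor_distance:
                continue
            pv = _try_anchor(pileup, s, anchor, min_phase_support, phase_purity)
            if pv is not None:
                used.append(anchor.pos)
                if evidence is None:
                    evidence = pv
        depth = _site_total(pileup, s, (alleles[0], alleles[1]))
        if evidence is not None:
            groups0 = {pa[0] for pa in evidence.values()}
            split = sorted(groups0 if len(groups0) == 2
                           else {pa[1] for pa in evidence.values()})
            label = CONFLICT if s in candidate_pattern else VARIETAL
            subg = "U"
            if ancestral_alleles is not None and label == VARIETAL:
                subg = _assign_subgenome(evidence, used, anchors, ancestral_alleles)
            calls.append(SnpCall(
                ref_name=pileup.ref_name, pos=s, alleles=(split[0], split[1]),
                class_label=label, subgenome=subg, anchors=sorted(used),
                variety_alleles=evidence, depth=depth))
        elif (s not in candidate_pattern
              and _between_variety_polymorphic(pileup, s, min_allele_support)):
            calls.append(SnpCall(
                ref_name=pileup.ref_name, pos=s,
                alleles=(alleles[0], alleles[1]), class_label=EQUIVOCAL,
                depth=depth))
    return calls


def _assign_subgenome(evidence: dict[str, tuple[str, str]], used: list[int],
                      anchors: list[Anchor],
                      ancestral: dict[int, tuple[str, str]]) -> str:
    """Label the splitting phase A or D via an ancestral-diploid allele table."""
    by_pos = {a.pos: a for a in anchors}
    groups0 = {pa[0] for pa in evidence.values()}
    split_phase = 0 if len(groups0) == 2 else 1
    votes: Counter = Counter()
    for pos in used:
        anc = ancestral.get(pos)
        if anc is None:
            continue
        a_base, d_base = anc
        phase0_allele = by_pos[pos].alleles[0]
        phase0_subg = "A" if phase0_allele == a_base else ("D" if phase0_allele == d_base else None)
        if phase0_subg is None:
            continue
        other = "D" if phase0_subg == "A" else "A"
        votes[phase0_subg if split_phase == 0 else other] += 1
    if not votes:
        return "U"
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "U"
    return top[0][0]


def merge_nonredundant(calls: list[SnpCall]) -> list[SnpCall]:
    """Deduplicate per-region calls into one sorted nonredundant list.

    Key is (ref_name, pos, unordered allele pair).  Variety allele matrices
    are merged; a merge with incompatible per-variety alleles is demoted to
    CONFLICT.  Same-position calls with distinct allele pairs are kept (with
    a warning).
    """
    order = {VARIETAL: 0, CONFLICT: 1, SUBGENOME: 2, EQUIVOCAL: 3}
    merged: dict[tuple, SnpCall] = {}
    for call in calls:
        key = (call.ref_name, call.pos, frozenset(call.alleles))
        if key not in merged:
            merged[key] = SnpCall(call.ref_name, call.pos, tuple(sorted(call.alleles)),
                                  call.class_label, call.subgenome,
                                  sorted(call.anchors), dict(call.variety_alleles),
                                  call.depth)
            continue
        cur = merged[key]
        conflict = False
        for v, pa in call.variety_alleles.items():
            if v in cur.variety_alleles and cur.variety_alleles[v] != pa:
                conflict = True
            else:
                cur.variety_alleles[v] = pa
        cur.anchors = sorted(set(cur.anchors) | set(call.anchors))
        cur.depth = max(cur.depth, call.depth)
        if conflict:
            cur.class_label = CONFLICT
        elif order[call.class_label] < order[cur.class_label]:
            cur.class_label = call.class_label
            if call.subgenome != "U":
                cur.subgenome = call.subgenome
        if cur.subgenome == "U" and call.subgenome != "U":
            cur.subgenome = call.subgenome
    by_pos: Counter = Counter((c.ref_name, c.pos) for c in merged.values())
    for (rn, pos), n in by_pos.items():
        if n > 1:
            logger.warning("multiple allele pairs called at %s:%d", rn, pos + 1)
    return sorted(merged.values(), key=lambda c: (c.ref_name, c.pos, c.alleles))


def call_transcriptome(reads: list[AlignedRead], ref_lengths: dict[str, int],
                       config: CallerConfig | None = None,
                       ancestral_alleles: dict[tuple[str, int], tuple[str, str]] | None = None,
                       ) -> tuple[list[SnpCall], list[Anchor], dict]:
    """Full pipeline over one or more references.

    Returns (merged calls incl. EQUIVOCAL/CONFLICT, all anchors, run stats).
    """
    cfg = config or CallerConfig()
    by_ref: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_ref.setdefault(r.ref_name, []).append(r)
    all_calls: list[SnpCall] = []
    all_anchors: list[Anchor] = []
    stats = {"regions": 0, "anchors": 0, VARIETAL: 0, EQUIVOCAL: 0, CONFLICT: 0}
    for ref_name in sorted(by_ref):
        sub = sorted(by_ref[ref_name], key=lambda r: (r.ref_start, r.read_id))
        pile = build_pileup(sub, ref_lengths[ref_name], ref_name)
        regions = find_dense_regions(pile, min_depth=cfg.min_depth,
                                     window=cfg.window, step=cfg.step,
                                     region_max=cfg.region_max,
                                     chunk_overlap=2 * cfg.anchor_distance)
        stats["regions"] += len(regions)
        anc_table = None
        if ancestral_alleles is not None:
            anc_table = {p: ad for (rn, p), ad in ancestral_alleles.items()
                         if rn == ref_name}
        region_calls: list[SnpCall] = []
        for reg in regions:
            anchors = classify_subgenome_sites(
                reg, pile, cfg.min_allele_support, cfg.min_within_freq,
                cfg.min_depth, cfg.max_iter)
            all_anchors.extend(anchors)
            region_calls.extend(call_varietal_snps(
                reg, pile, anchors, cfg.min_allele_support,
                cfg.min_phase_support, cfg.phase_purity, cfg.anchor_distance,
                cfg.min_depth, cfg.min_within_freq, ancestral_alleles=anc_table))
        all_calls.extend(merge_nonredundant(region_calls))
    stats["anchors"] = len(all_anchors)
    for c in all_calls:
        if c.class_label in stats:
            stats[c.class_label] += 1
    return all_calls, all_anchors, stats
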