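"""RAD-seq varietal SNP calling from collapsed sequence tags.

Raw reads carrying an inline barcode and a restriction-site remnant are
demultiplexed, trimmed to a fixed tag length, and collapsed into unique
tags; tags below the depth threshold (default 4) are discarded, which
removes essentially all sequencing-error tags while keeping real ones.
Tags aligned to the same reference position form a locus; the informative
pattern is the 4-tag locus — exactly two tags per variety, one per
subgenome.  At such a locus a 2:2 column pairing one tag from each variety
on each side is a subgenome-specific anchor; a 1:3 column is a candidate
varietal SNP, accepted only when the locus has an anchor and the minority
tag lies in a well-defined phase of the anchor partition.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from ._util import IUPAC
from .io_formats import RadTag
from .transcriptome import SnpCall, EQUIVOCAL, VARIETAL

logger = logging.getLogger(__name__)

#: Remnants left on the read after ligation/digestion, per enzyme (IUPAC).
ENZYME_REMNANTS = {"EcoRI": "AATTC", "ApeKI": "CWGC", "SbfI": "TGCAGG"}

PASS = "PASS"
MONOMORPHIC = "MONOMORPHIC"
REPETITIVE = "REPETITIVE"
UNBALANCED = "UNBALANCED"


class ConfigurationError(ValueError):
    pass


@dataclass
class TagAlignment:
    """One tag placed on the reference (sequence in reference orientation)."""

    tag: RadTag
    ref_name: str
    ref_start: int
    strand: str = "+"
    aligned_seq: str | None = None  # defaults to tag.seq

    @property
    def seq(self) -> str:
        return self.aligned_seq if self.aligned_seq is not None else self.tag.seq


@dataclass
class RadLocus:
    """Tags sharing one alignment start/orientation, with a pattern label."""

    ref_name: str
    ref_start: int
    strand: str
    tags: list[TagAlignment]
    status: str = PASS

    def tags_by_variety(self) -> dict[str, list[TagAlignment]]:
        by_v: dict[str, list[TagAlignment]] = defaultdict(list)
        for t in self.tags:
            by_v[t.tag.variety_id].append(t)
        return dict(by_v)


def demultiplex(raw_reads: list[str], barcode_map: dict[str, str],
                enzyme_remnants: dict[str, str] | None = None,
                keep_remnant: bool = True,
                ) -> tuple[dict[tuple[str, str], list[str]], dict[str, int]]:
    """Assign raw reads to (variety, enzyme) by exact barcode + remnant prefix.

    ``barcode_map`` maps variety -> barcode; barcodes must be prefix-free.
    Remnant matching is IUPAC-aware (e.g. ApeKI's CWGC).  Reads matching no
    barcode or no remnant are counted as discarded.
    """
    if enzyme_remnants is None:
        enzyme_remnants = ENZYME_REMNANTS
    barcodes = sorted(barcode_map.items(), key=lambda kv: -len(kv[1]))
    for v1, b1 in barcode_map.items():
        for v2, b2 in barcode_map.items():
            if v1 != v2 and b1.startswith(b2):
                raise ConfigurationError(
                    f"barcodes are not prefix-free: {b1!r} vs {b2!r}")
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    discards = {"no_barcode": 0, "no_remnant": 0}
    for read in raw_reads:
        variety = None
        for v, b in barcodes:
            if read.startswith(b):
                variety = v
                rest = read[len(b):]
                break
        if variety is None:
            discards["no_barcode"] += 1
            continue
        enzyme = None
        for e, remnant in enzyme_remnants.items():
            if len(rest) >= len(remnant) and all(
                    rest[i] in IUPAC[c] for i, c in enumerate(remnant)):
                enzyme = e
                break
        if enzyme is None:
            discards["no_remnant"] += 1
            continue
        payload = rest if keep_remnant else rest[len(enzyme_remnants[enzyme]):]
        groups[(variety, enzyme)].append(payload)
    return dict(groups), discards


def trim_and_collapse(reads: list[str], variety_id: str, enzyme: str,
                      tag_len: int = 78, min_depth: int = 4,
                      ) -> tuple[list[RadTag], dict[str, int]]:
    """3'-trim reads to ``tag_len`` and collapse identical ones into tags.

    Tags supported by fewer than ``min_depth`` reads are dropped — the
    depth filter that stands in for per-base quality filtering once reads
    are reduced to consensus tags.
    """
    counts: Counter = Counter()
    report = {"too_short": 0, "kept_tags": 0, "dropped_tags": 0}
    for read in reads:
        if len(read) < tag_len:
            report["too_short"] += 1
            continue
        counts[read[:tag_len]] += 1
    tags = []
    for seq, depth in sorted(counts.items()):
        if depth >= min_depth:
            tags.append(RadTag(variety_id, enzyme, seq, depth))
            report["kept_tags"] += 1
        else:
            report["dropped_tags"] += 1
    return tags, report


def group_loci(alignments: list[TagAlignment],
               expected_varieties: list[str] | None = None) -> list[RadLocus]:
    """Group aligned tags by (ref_name, ref_start, strand) into loci.

    A locus is PASS when every variety contributes exactly two distinct
    tags (one per subgenome); one-per-variety loci are monomorphic
    pass-throughs, more than two is repetitive, anything mixed is
    unbalanced.  Only PASS loci are used for calling.
    """
    by_key: dict[tuple, list[TagAlignment]] = defaultdict(list)
    for a in alignments:
        by_key[(a.ref_name, a.ref_start, a.strand)].append(a)
    loci = []
    for (rn, rs, strand), tags in sorted(by_key.items()):
        tags = sorted(tags, key=lambda a: (a.tag.variety_id, a.seq))
        by_v: dict[str, set] = defaultdict(set)
        for a in tags:
            by_v[a.tag.variety_id].add(a.seq)
        varieties = expected_varieties or sorted(by_v)
        n_distinct = [len(by_v.get(v, ())) for v in varieties]
        if all(n == 2 for n in n_distinct):
            status = PASS
        elif all(n == 1 for n in n_distinct):
            status = MONOMORPHIC
        elif any(n > 2 for n in n_distinct):
            status = REPETITIVE
        else:
            status = UNBALANCED
        loci.append(RadLocus(rn, rs, strand, tags, status))
    return loci


@dataclass
class RadCallResult:
    calls: list[SnpCall] = field(default_factory=list)
    #: 2:2 columns pairing tags within varieties (subgenome anchors), 0-based
    anchor_positions: list[int] = field(default_factory=list)
    #: variety-discordant 2:2 columns: putative homozygous varietal
    #: differences, reported but never used as anchors
    homozygous_diff_positions: list[int] = field(default_factory=list)


def _column_bases(locus: RadLocus) -> list[dict[tuple[str, int], str]]:
    """Per column: (variety, tag index within variety) -> base."""
    by_v = locus.tags_by_variety()
    keyed = []
    for v in sorted(by_v):
        uniq = sorted({a.seq for a in by_v[v]})
        for i, seq in enumerate(uniq):
            keyed.append(((v, i), seq))
    if not keyed:
        return []
    tag_len = len(keyed[0][1])
    cols = []
    for j in range(tag_len):
        cols.append({key: seq[j] for key, seq in keyed})
    return cols


def call_rad_snps(locus: RadLocus, min_coverage: int = 4) -> RadCallResult:
    """Call varietal SNPs at one PASS locus from its aligned tag columns.

    2:2 columns whose split pairs one tag from each variety per side define
    the subgenome partition; 1:3 columns (exactly one variety's single tag
    deviating) become VARIETAL calls when that partition is unique and the
    minority tag phase is well defined.  Generalizes to >2 varieties as an
    n:n split / single-deviating-tag rule.
    """
    result = RadCallResult()
    if locus.status != PASS:
        return result
    if any(a.tag.depth < min_coverage for a in locus.tags):
        return result
    cols = _column_bases(locus)
    varieties = sorted(locus.tags_by_variety())
    n_tags = 2 * len(varieties)

    anchor_partitions: list[frozenset] = []
    anchors: list[int] = []
    candidates: list[tuple[int, dict]] = []
    for j, col in enumerate(cols):
        alleles = Counter(col.values())
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            continue  # >2 alleles in a column: discarded
        (a1, n1), (a2, n2) = alleles.most_common()
        if n1 == n2 == n_tags // 2:
            side = frozenset(k for k, b in col.items() if b == min(a1, a2))
            # canonical bipartition representative: the side holding the
            # smallest tag key, so complementary descriptions compare equal
            if min(col) not in side:
                side = frozenset(col) - side
            per_v = Counter(v for v, _ in side)
            if all(per_v.get(v, 0) == 1 for v in varieties):
                anchors.append(j)
                anchor_partitions.append(side)
            elif all(per_v.get(v, 0) in (0, 2) for v in varieties):
                result.homozygous_diff_positions.append(locus.ref_start + j)
            # other mixed 2:2 partitions are uninformative
        elif n2 == 1:
            candidates.append((j, col))

    result.anchor_positions = [locus.ref_start + j for j in anchors]
    if not anchors:
        # candidate varietal columns with no in-locus anchor: refused
        for j, col in candidates:
            alleles = Counter(col.values())
            result.calls.append(SnpCall(
                ref_name=locus.ref_name, pos=locus.ref_start + j,
                alleles=tuple(sorted(alleles)), class_label=EQUIVOCAL,
                depth=sum(a.tag.depth for a in locus.tags)))
        return result

    partitions = set(anchor_partitions)
    unique_partition = len(partitions) == 1
    partition = anchor_partitions[0]
    for j, col in candidates:
        alleles = Counter(col.values())
        (major, _), (minor, _) = alleles.most_common()
        minority_key = next(k for k, b in col.items() if b == minor)
        if not unique_partition:
            result.calls.append(SnpCall(
                ref_name=locus.ref_name, pos=locus.ref_start + j,
                alleles=tuple(sorted((major, minor))), class_label=EQUIVOCAL,
                depth=sum(a.tag.depth for a in locus.tags)))
            continue
        phase0 = minority_key in partition
        phase_keys = partition if phase0 else frozenset(col) - partition
        # the varietal difference lives within the minority tag's phase:
        # its phase-mates from the other varieties carry the major allele
        mates = [k for k in phase_keys if k != minority_key]
        mate_alleles = {col[k] for k in mates}
        if mate_alleles != {major}:
            result.calls.append(SnpCall(
                ref_name=locus.ref_name, pos=locus.ref_start + j,
                alleles=tuple(sorted((major, minor))), class_label=EQUIVOCAL,
                depth=sum(a.tag.depth for a in locus.tags)))
            continue
        variety_alleles = {}
        for v in varieties:
            in_phase = col[(v, 0)] if (v, 0) in phase_keys else col[(v, 1)]
            other = col[(v, 1)] if (v, 0) in phase_keys else col[(v, 0)]
            variety_alleles[v] = (in_phase, other)
        result.calls.append(SnpCall(
            ref_name=locus.ref_name, pos=locus.ref_start + j,
            alleles=tuple(sorted((major, minor))), class_label=VARIETAL,
            anchors=sorted(result.anchor_positions),
            variety_alleles=variety_alleles,
            depth=sum(a.tag.depth for a in locus.tags)))
    return result


def alignments_from_sam(path) -> list[TagAlignment]:
    """Read tag alignments from a SAM of collapsed tags vs the reference.

    Query names must be ``variety|enzyme|depth|serial`` (the naming used
    when tags are exported for external alignment).  Only mapped primary
    records are used; SEQ is reference-oriented in SAM, so the original
    read-orientation tag is recovered via the strand flag.
    """
    import pysam

    from ._util import revcomp

    out = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            variety, enzyme, depth, _ = aln.query_name.split("|", 3)
            aligned = aln.query_sequence
            tag_seq = revcomp(aligned) if aln.is_reverse else aligned
            out.append(TagAlignment(
                tag=RadTag(variety, enzyme, tag_seq, int(depth)),
                ref_name=aln.reference_name, ref_start=aln.reference_start,
                strand="-" if aln.is_reverse else "+", aligned_seq=aligned))
    return out


def call_rad_pipeline(raw_reads: list[str], barcode_map: dict[str, str],
                      alignments_for: "callable",
                      enzyme: str = "EcoRI", tag_len: int = 78,
                      min_depth: int = 4, min_coverage: int = 4,
                      ) -> tuple[list[SnpCall], list[RadLocus], dict]:
    """Demultiplex -> collapse -> group -> call, end to end.

    ``alignments_for(tags)`` must place the collapsed tags on the
    reference (externally aligned SAM in production; true coordinates for
    simulated data) and return TagAlignment records.
    """
    groups, discards = demultiplex(raw_reads, barcode_map)
    tags: list[RadTag] = []
    reports = {}
    for (variety, enz), reads in sorted(groups.items()):
        if enz != enzyme:
            continue
        t, rep = trim_and_collapse(reads, variety, enz, tag_len, min_depth)
        tags.extend(t)
        reports[variety] = rep
    alignments = alignments_for(tags)
    loci = group_loci(alignments, expected_varieties=sorted(barcode_map))
    calls: list[SnpCall] = []
    n_pass = 0
    for locus in loci:
        if locus.status == PASS:
            n_pass += 1
        calls.extend(call_rad_snps(locus, min_coverage).calls)
    stats = {"discards": discards, "collapse": reports,
             "loci": len(loci), "pass_loci": n_pass,
             "calls": Counter(c.class_label for c in calls)}
    return calls, loci, stats
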