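"""Readers and writers for the formats the pipeline touches.

FASTA references, a documented SAM subset (mapped, primary alignments with a
restricted CIGAR alphabet), a small VCFv4.2 dialect for classified SNP calls,
and the tab-separated tag table used as the RAD interchange format.

Coordinates are 0-based half-open everywhere in memory; 1-based coordinates
appear only in VCF records and in ``ChrNN_pos`` style SNP names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO

from ._util import xopen

logger = logging.getLogger(__name__)

#: CIGAR operations the pipeline understands.  Hard clips are tolerated on
#: input (they consume nothing we track) and dropped.
ALLOWED_CIGAR_OPS = frozenset("M=XIDNSH")
_QUERY_OPS = frozenset("M=XIS")
_REF_OPS = frozenset("M=XDN")

CLASS_LABELS = ("SUBGENOME", "VARIETAL", "EQUIVOCAL", "CONFLICT")


class FormatError(ValueError):
    """Raised when an input file violates the documented subset."""


@dataclass(frozen=True)
class ReferenceSequence:
    """A named chromosome/scaffold sequence over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self):
        if not self.name:
            raise FormatError("reference name must be nonempty")
        if len(self.seq) < 1:
            raise FormatError(f"reference {self.name!r} is empty")
        if any(c.isspace() for c in self.seq):
            raise FormatError(f"reference {self.name!r} contains whitespace")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignedRead:
    """Minimal alignment record: one read placed on the reference.

    ``cigar`` is a list of ``(op, length)`` pairs over the allowed alphabet;
    the sum of query-consuming op lengths must equal ``len(seq)``.
    """

    read_id: str
    variety_id: str
    ref_name: str
    ref_start: int
    cigar: list[tuple[str, int]]
    seq: str
    mapq: int = 60
    is_unique: bool = True

    def __post_init__(self):
        if self.ref_start < 0:
            raise FormatError(f"{self.read_id}: negative ref_start")
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.seq):
            raise FormatError(
                f"{self.read_id}: CIGAR query length {qlen} != seq length {len(self.seq)}"
            )
        if self.ref_span <= 0:
            raise FormatError(f"{self.read_id}: CIGAR consumes no reference")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield ``(ref_pos, query_pos)`` for aligned (M/=/X) bases."""
        r, q = self.ref_start, 0
        for op, n in self.cigar:
            if op in "M=X":
                for i in range(n):
                    yield r + i, q + i
                r += n
                q += n
            elif op in "DN":
                r += n
            elif op in "IS":
                q += n

    def base_at(self, ref_pos: int) -> str | None:
        """The read base aligned at ``ref_pos``, or None if not aligned there."""
        if not (self.ref_start <= ref_pos < self.ref_end):
            return None
        r, q = self.ref_start, 0
        for op, n in self.cigar:
            if op in "M=X":
                if r <= ref_pos < r + n:
                    return self.seq[q + (ref_pos - r)]
                r += n
                q += n
            elif op in "DN":
                if r <= ref_pos < r + n:
                    return None
                r += n
            elif op in "IS":
                q += n
        return None


@dataclass
class SnpRecordOut:
    """A classified site ready for serialization.

    ``variety_alleles`` maps variety id to its two phase alleles (phase 0 is
    the phase carrying the anchor's first allele); ``'.'`` marks a phase with
    no confident consensus.
    """

    ref_name: str
    pos_1based: int
    ref_allele: str
    alt_allele: str
    class_label: str
    subgenome_label: str = "U"
    anchor_positions: list[int] = field(default_factory=list)  # 1-based
    variety_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    depth: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise FormatError(f"unknown class label {self.class_label!r}")
        if self.ref_allele == self.alt_allele:
            raise FormatError("ref and alt allele are identical")
        for a in (self.ref_allele, self.alt_allele):
            if a not in "ACGT" or len(a) != 1:
                raise FormatError(f"allele {a!r} is not a single A/C/G/T base")
        if (self.class_label == "VARIETAL") != bool(self.anchor_positions):
            raise FormatError("anchor positions must be nonempty iff class is VARIETAL")

    @property
    def name(self) -> str:
        """``ChrNN_pos`` style SNP name (1-based coordinate)."""
        return f"{self.ref_name}_{self.pos_1based}"


@dataclass
class RadTag:
    """A collapsed, fixed-length RAD sequence tag with its read depth."""

    variety_id: str
    enzyme: str
    seq: str
    depth: int

    def __post_init__(self):
        if self.depth < 1:
            raise FormatError(f"tag depth must be >= 1, got {self.depth}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ReferenceSequence]:
    """Read a (possibly gzipped) FASTA file into ReferenceSequence records."""
    records: list[ReferenceSequence] = []
    seen: set[str] = set()
    with xopen(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA record name {rec.id!r}")
            seen.add(rec.id)
            records.append(ReferenceSequence(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ReferenceSequence], path, width: int = 70) -> None:
    with xopen(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM


def _cigar_from_pysam(aln: "pysam.AlignedSegment") -> list[tuple[str, int]]:
    ops = "MIDNSHP=X"
    out = []
    for code, n in aln.cigartuples or []:
        op = ops[code]
        if op not in ALLOWED_CIGAR_OPS:
            raise FormatError(
                f"{aln.query_name}: unsupported CIGAR op {op!r}"
            )
        if op == "H":
            continue  # hard clips consume neither sequence we hold nor counts
        out.append((op, n))
    return out


def read_sam_min(
    path,
    variety_map: dict[str, str] | None = None,
    default_variety: str | None = None,
    min_mapq: int = 0,
) -> Iterator[AlignedRead]:
    """Stream the documented SAM subset as AlignedRead records.

    Unmapped, secondary and supplementary records are skipped (counted in a
    logged summary), matching a caller that consumes only single best unique
    alignments.  The variety is taken from the read-group tag via
    ``variety_map`` (RG id -> variety) when present, else ``default_variety``.
    """
    skipped = {"not_unique": 0, "unmapped": 0, "low_mapq": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        refs = set(sam.references)
        for aln in sam:
            if aln.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                skipped["not_unique"] += 1
                continue
            if aln.mapping_quality < min_mapq:
                skipped["low_mapq"] += 1
                continue
            if aln.reference_name not in refs:  # pragma: no cover - pysam enforces
                raise FormatError(f"missing @SQ for {aln.reference_name}")
            variety = None
            if variety_map is not None and aln.has_tag("RG"):
                variety = variety_map.get(aln.get_tag("RG"))
            if variety is None:
                variety = default_variety
            if variety is None:
                raise FormatError(
                    f"{aln.query_name}: no variety assignment (no RG mapping and no default)"
                )
            yield AlignedRead(
                read_id=aln.query_name,
                variety_id=variety,
                ref_name=aln.reference_name,
                ref_start=aln.reference_start,
                cigar=_cigar_from_pysam(aln),
                seq=aln.query_sequence or "",
                mapq=aln.mapping_quality,
                is_unique=True,
            )
    if any(skipped.values()):
        logger.info("read_sam_min skipped records: %s", skipped)


def write_sam(
    reads: Iterable[AlignedRead],
    reference_lengths: dict[str, int],
    path,
    read_groups: dict[str, str] | None = None,
) -> None:
    """Write AlignedReads as SAM text with @SQ (and optional @RG) headers.

    ``read_groups`` maps variety id -> RG id; when given, each record carries
    an RG tag so `read_sam_min` can recover the variety.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in reference_lengths.items()],
    }
    if read_groups:
        header["RG"] = [{"ID": rg, "SM": v} for v, rg in read_groups.items()]
    ops = "MIDNSHP=X"
    op_code = {op: i for i, op in enumerate(ops)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {n: i for i, n in enumerate(reference_lengths)}
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.flag = 0
            a.reference_id = tid[r.ref_name]
            a.reference_start = r.ref_start
            a.mapping_quality = r.mapq
            a.cigartuples = [(op_code[op], n) for op, n in r.cigar]
            if read_groups:
                a.set_tag("RG", read_groups[r.variety_id])
            out.write(a)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    calls: list[SnpRecordOut],
    reference: dict[str, ReferenceSequence] | list[ReferenceSequence],
    path,
    varieties: list[str] | None = None,
    extra_header_lines: list[str] | None = None,
) -> None:
    """Write classified calls as a small VCFv4.2 dialect.

    INFO keys: CLASS (classification), SUBG (subgenome label), ANCHORS
    (1-based anchor positions, comma list), DP.  Per-variety sample columns
    carry ``PA``, the two phase alleles as bases (e.g. ``A|G``), with ``.``
    for an unresolved phase.  REF must equal the reference base at the site.
    """
    if isinstance(reference, list):
        reference = {r.name: r for r in reference}
    if varieties is None:
        seen: list[str] = []
        for c in calls:
            for v in c.variety_alleles:
                if v not in seen:
                    seen.append(v)
        varieties = sorted(seen)
    with xopen(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Site classification">\n')
        fh.write('##INFO=<ID=SUBG,Number=1,Type=String,Description="Subgenome label (A/D/U)">\n')
        fh.write('##INFO=<ID=ANCHORS,Number=.,Type=Integer,Description="1-based positions of subgenome-specific anchor SNPs">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=PA,Number=1,Type=String,Description="Phase alleles (phase0|phase1)">\n')
        for line in extra_header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        for name, rec in reference.items():
            fh.write(f"##contig=<ID={name},length={len(rec)}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if varieties:
            cols += ["FORMAT"] + list(varieties)
        fh.write("\t".join(cols) + "\n")
        for c in calls:
            ref_base = reference[c.ref_name].seq[c.pos_1based - 1]
            if ref_base != c.ref_allele:
                raise FormatError(
                    f"{c.name}: REF allele {c.ref_allele} does not match reference base {ref_base}"
                )
            info = f"CLASS={c.class_label};SUBG={c.subgenome_label}"
            if c.anchor_positions:
                info += ";ANCHORS=" + ",".join(str(p) for p in c.anchor_positions)
            info += f";DP={c.depth}"
            row = [c.ref_name, str(c.pos_1based), c.name, c.ref_allele, c.alt_allele,
                   ".", "PASS", info]
            if varieties:
                row.append("PA")
                for v in varieties:
                    pa = c.variety_alleles.get(v)
                    row.append(f"{pa[0]}|{pa[1]}" if pa else ".")
            fh.write("\t".join(row) + "\n")


def read_vcf(path) -> list[SnpRecordOut]:
    """Read back the dialect written by `write_vcf` (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    varieties = list(vcf.samples)
    out: list[SnpRecordOut] = []
    for v in vcf:
        anchors = v.INFO.get("ANCHORS")
        if anchors is None:
            anchor_list: list[int] = []
        elif isinstance(anchors, (tuple, list)):
            anchor_list = [int(x) for x in anchors]
        elif isinstance(anchors, int):
            anchor_list = [anchors]
        else:
            anchor_list = [int(x) for x in str(anchors).split(",")]
        alleles: dict[str, tuple[str, str]] = {}
        if varieties:
            pa = v.format("PA")
            if pa is not None:
                for name, val in zip(varieties, pa):
                    val = val if isinstance(val, str) else val.decode()
                    if val and val != ".":
                        p0, p1 = val.split("|")
                        alleles[name] = (p0, p1)
        out.append(
            SnpRecordOut(
                ref_name=v.CHROM,
                pos_1based=v.POS,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                class_label=str(v.INFO.get("CLASS")),
                subgenome_label=str(v.INFO.get("SUBG", "U")),
                anchor_positions=anchor_list,
                variety_alleles=alleles,
                depth=int(v.INFO.get("DP", 0)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tag table TSV

_TAG_COLUMNS = ["variety_id", "enzyme", "tag_seq", "depth"]


def read_tag_table(path) -> list[RadTag]:
    """Read a RAD tag table (TSV: variety_id, enzyme, tag_seq, depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"variety_id": str, "enzyme": str, "tag_seq": str})
    missing = [c for c in _TAG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"tag table missing columns {missing}")
    if len(df) and df["tag_seq"].str.len().nunique() > 1:
        raise FormatError("mixed tag lengths in tag table")
    tags = []
    for row in df.itertuples(index=False):
        depth = int(row.depth)
        if depth < 1:
            raise FormatError(f"tag depth must be positive, got {depth}")
        tags.append(RadTag(row.variety_id, row.enzyme, row.tag_seq, depth))
    return tags


def write_tag_table(tags: Iterable[RadTag], path) -> None:
    df = pd.DataFrame(
        [(t.variety_id, t.enzyme, t.seq, t.depth) for t in tags],
        columns=_TAG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
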