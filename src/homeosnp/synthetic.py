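"""Truth-annotated allotetraploid simulator.

Builds a diploid-like reference (the "D" progenitor role), derives an "A"
subgenome by random substitutions, spawns tetraploid varieties carrying
subgenome-confined varietal substitutions, and samples RNA-seq reads and
EcoRI RAD reads from them.  Divergence is substitution-only, so both
subgenomes share the reference coordinate system and every simulated read is
emitted with its true alignment — callers can be tested without an external
aligner.

Defaults mirror the cotton setting the package targets: homeologous
subgenomes with ~99% identity (rate 0.01), varietal substitution rates of a
few per ten kilobases (5e-4), 90-bp paired-end RNA-seq reads, and 78-bp RAD
tags anchored at EcoRI (GAATTC) sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import DNA, revcomp
from .io_formats import AlignedRead, ReferenceSequence

SUBGENOME = "SUBGENOME"
VARIETAL = "VARIETAL"

#: Default per-site rates: subgenome divergence and varietal polymorphism.
DEFAULT_SUBGENOME_RATE = 0.01
DEFAULT_VARIETAL_RATE = 5e-4
DEFAULT_ANCHOR_DISTANCE = 90

_BARCODE_POOL = [
    "ACGTA", "CAGTC", "GTACG", "TGCAT", "AAGGT", "CCTTA", "GGAAC", "TTCCG",
]


class ParameterError(ValueError):
    pass


@dataclass
class TetraploidVariety:
    """One tetraploid variety: its A- and D-subgenome sequences."""

    variety_id: str
    seq_A: str
    seq_D: str
    expression_bias: float = 1.0  # A-homeolog : D-homeolog read sampling ratio

    def __post_init__(self):
        if len(self.seq_A) != len(self.seq_D):
            raise ParameterError("subgenome sequences must have equal length")
        if self.expression_bias <= 0:
            raise ParameterError("expression bias must be > 0")


@dataclass
class TruthRecord:
    """Ground truth for one introduced substitution.

    ``allele_map`` maps variety id to its (A-base, D-base) pair at this
    position; the wildcard key ``"*"`` stands for every variety (used by
    SUBGENOME records, whose pair is shared).  ``anchored`` is set on
    varietal records that lie within ``anchor_distance`` of a
    subgenome-divergent site.
    """

    pos: int
    kind: str  # SUBGENOME | VARIETAL
    subgenome: str  # A | D | BOTH
    allele_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    anchored: bool = False


@dataclass
class RadTagTruth:
    """True origin of one simulated RAD tag."""

    locus_id: str
    ref_name: str
    site_pos: int  # 0-based start of the recognition site
    side: str  # L | R
    ref_start: int  # 0-based leftmost reference coordinate of the aligned tag
    strand: str  # + | -
    variety_id: str
    subgenome: str
    tag_seq: str  # read orientation (starts with the enzyme remnant)
    aligned_seq: str  # reference orientation
    depth: int


# ---------------------------------------------------------------------------


def make_reference(length: int, gc_fraction: float = 0.35, seed: int = 0,
                   name: str = "Chr01") -> ReferenceSequence:
    """Random reference sequence with the requested GC content."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    if not 0 < gc_fraction < 1:
        raise ParameterError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    bases = rng.choice(list(DNA), size=length, p=[at, gc, gc, at])
    return ReferenceSequence(name, "".join(bases))


def plant_restriction_sites(ref: ReferenceSequence, site: str, n_sites: int,
                            seed: int = 0, min_spacing: int = 300) -> ReferenceSequence:
    """Overwrite ``n_sites`` well-spaced positions with a recognition site.

    Used to guarantee a target density of RAD loci in a random reference.
    """
    rng = np.random.default_rng(seed)
    margin = min_spacing
    usable = len(ref) - 2 * margin - len(site)
    if usable < n_sites * min_spacing:
        raise ParameterError("reference too short for requested site count/spacing")
    offsets = rng.random(n_sites)
    offsets = offsets / offsets.sum() * (usable - n_sites * min_spacing)
    positions = []
    p = margin
    for off in offsets:
        p += off + min_spacing
        positions.append(int(p))
    seq = list(ref.seq)
    for p in positions:
        seq[p : p + len(site)] = site
    return ReferenceSequence(ref.name, "".join(seq))


def diverge_subgenomes(ref: ReferenceSequence, subgenome_rate: float = DEFAULT_SUBGENOME_RATE,
                       seed: int = 0) -> tuple[str, str, list[TruthRecord]]:
    """Derive the A subgenome from the reference by i.i.d. substitutions.

    The D subgenome is the reference itself.  Returns one SUBGENOME truth
    record per substituted site.
    """
    if not 0 <= subgenome_rate < 1:
        raise ParameterError("subgenome_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seq_d = ref.seq
    seq_a = list(seq_d)
    hits = np.flatnonzero(rng.random(len(seq_d)) < subgenome_rate)
    truth = []
    for pos in hits:
        old = seq_d[pos]
        choices = [b for b in DNA if b != old]
        new = choices[rng.integers(3)]
        seq_a[pos] = new
        truth.append(TruthRecord(pos=int(pos), kind=SUBGENOME, subgenome="BOTH",
                                 allele_map={"*": (new, old)}))
    return "".join(seq_a), seq_d, truth


def spawn_varieties(seq_a: str, seq_d: str, n_varieties: int,
                    varietal_rate: float = DEFAULT_VARIETAL_RATE, seed: int = 0,
                    anchor_distance: int = DEFAULT_ANCHOR_DISTANCE,
                    variety_ids: list[str] | None = None,
                    ) -> tuple[list[TetraploidVariety], list[TruthRecord]]:
    """Spawn varieties carrying subgenome-confined varietal substitutions.

    Each varietal substitution lands in exactly one subgenome of a random
    nonempty proper subset of the varieties, at a position where the two
    subgenomes agree (sites colliding with subgenome divergence are
    resampled).  Varietal truth records carry the per-variety allele map and
    an ``anchored`` flag (a subgenome-divergent site within
    ``anchor_distance``).
    """
    if n_varieties < 2:
        raise ParameterError("need at least 2 varieties")
    if varietal_rate < 0:
        raise ParameterError("varietal_rate must be >= 0")
    rng = np.random.default_rng(seed)
    length = len(seq_d)
    if variety_ids is None:
        variety_ids = [f"v{i + 1}" for i in range(n_varieties)]
    sub_positions = np.flatnonzero(np.frombuffer(seq_a.encode(), dtype=np.uint8)
                                   != np.frombuffer(seq_d.encode(), dtype=np.uint8))
    free = np.setdiff1d(np.arange(length), sub_positions, assume_unique=True)
    n_hits = rng.binomial(length, varietal_rate)
    n_hits = min(n_hits, len(free))
    var_positions = np.sort(rng.choice(free, size=n_hits, replace=False))

    a_seqs = {v: list(seq_a) for v in variety_ids}
    d_seqs = {v: list(seq_d) for v in variety_ids}
    truth: list[TruthRecord] = []
    for pos in var_positions:
        pos = int(pos)
        subg = "A" if rng.random() < 0.5 else "D"
        # nonempty proper subset of varieties carries the new allele
        while True:
            carriers = [v for v in variety_ids if rng.random() < 0.5]
            if 0 < len(carriers) < n_varieties:
                break
        old = (seq_a if subg == "A" else seq_d)[pos]
        choices = [b for b in DNA if b != old]
        new = choices[rng.integers(3)]
        allele_map = {}
        for v in variety_ids:
            a, d = a_seqs[v][pos], d_seqs[v][pos]
            if v in carriers:
                if subg == "A":
                    a = new
                    a_seqs[v][pos] = new
                else:
                    d = new
                    d_seqs[v][pos] = new
            allele_map[v] = (a, d)
        truth.append(TruthRecord(pos=pos, kind=VARIETAL, subgenome=subg,
                                 allele_map=allele_map))
    if len(sub_positions):
        for rec in truth:
            i = np.searchsorted(sub_positions, rec.pos)
            near = []
            if i < len(sub_positions):
                near.append(abs(int(sub_positions[i]) - rec.pos))
            if i > 0:
                near.append(abs(int(sub_positions[i - 1]) - rec.pos))
            rec.anchored = bool(near and min(near) <= anchor_distance)
    varieties = [TetraploidVariety(v, "".join(a_seqs[v]), "".join(d_seqs[v]))
                 for v in variety_ids]
    return varieties, truth


def _apply_errors(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if not len(hits):
        return seq
    out = list(seq)
    for i in hits:
        old = out[i]
        choices = [b for b in DNA if b != old]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def simulate_rnaseq(varieties: list[TetraploidVariety], depth: float,
                    read_len: int = 90, paired: bool = True,
                    fragment_len: int = 200, error_rate: float = 0.0,
                    seed: int = 0, ref_name: str = "Chr01",
                    ) -> tuple[list[AlignedRead], dict[str, str]]:
    """Sample reads per variety from its two subgenomes.

    Reads come from the A homeolog with probability bias/(bias+1) and carry
    i.i.d. substitution errors.  Because divergence is substitution-only,
    every read is emitted at its true reference coordinate with a plain
    match CIGAR.  Returns the reads sorted by position plus a map
    read_id -> true subgenome of origin.
    """
    if depth <= 0:
        raise ParameterError("depth must be > 0")
    if paired and read_len > fragment_len:
        raise ParameterError("read_len must be <= fragment_len for paired reads")
    rng = np.random.default_rng(seed)
    reads: list[AlignedRead] = []
    origins: dict[str, str] = {}
    for var in varieties:
        length = len(var.seq_D)
        p_a = var.expression_bias / (var.expression_bias + 1.0)
        n_reads = int(round(depth * length / read_len))
        if paired:
            n_frag = n_reads // 2
            starts = rng.integers(0, max(1, length - fragment_len + 1), size=n_frag)
            from_a = rng.random(n_frag) < p_a
            for i in range(n_frag):
                seq = var.seq_A if from_a[i] else var.seq_D
                subg = "A" if from_a[i] else "D"
                s = int(starts[i])
                for mate, rs in (("1", s), ("2", s + fragment_len - read_len)):
                    rid = f"{var.variety_id}_f{i}/{mate}"
                    bases = _apply_errors(seq[rs : rs + read_len], error_rate, rng)
                    reads.append(AlignedRead(rid, var.variety_id, ref_name, rs,
                                             [("M", read_len)], bases))
                    origins[rid] = subg
        else:
            starts = rng.integers(0, max(1, length - read_len + 1), size=n_reads)
            from_a = rng.random(n_reads) < p_a
            for i in range(n_reads):
                seq = var.seq_A if from_a[i] else var.seq_D
                s = int(starts[i])
                rid = f"{var.variety_id}_r{i}"
                bases = _apply_errors(seq[s : s + read_len], error_rate, rng)
                reads.append(AlignedRead(rid, var.variety_id, ref_name, s,
                                         [("M", read_len)], bases))
                origins[rid] = "A" if from_a[i] else "D"
    reads.sort(key=lambda r: (r.ref_start, r.read_id))
    return reads, origins


def default_barcodes(varieties: list[TetraploidVariety]) -> dict[str, str]:
    if len(varieties) > len(_BARCODE_POOL):
        raise ParameterError("not enough built-in barcodes; supply barcode_map")
    return {v.variety_id: _BARCODE_POOL[i] for i, v in enumerate(varieties)}


def simulate_rad(varieties: list[TetraploidVariety],
                 enzyme: str = "EcoRI", enzyme_site: str = "GAATTC",
                 tag_len: int = 78, barcode_map: dict[str, str] | None = None,
                 mean_depth: float = 12.0, error_rate: float = 0.0,
                 seed: int = 0, ref_name: str = "Chr01",
                 ) -> tuple[list[str], list[RadTagTruth]]:
    """Simulate raw RAD reads anchored at restriction sites.

    For every intact recognition-site occurrence in each subgenome of each
    variety, both flanks yield reads of the form ``barcode + remnant +
    genomic sequence`` with depth ~ Poisson(mean_depth).  A substitution
    inside the site in one subgenome silences that subgenome's tags at the
    locus (restriction-site loss).  The left-flank tag is recorded with its
    reference-orientation sequence for alignment-free locus grouping.
    """
    rng = np.random.default_rng(seed)
    if barcode_map is None:
        barcode_map = default_barcodes(varieties)
    site_len = len(enzyme_site)
    remnant_len = site_len - 1  # EcoRI-style 5' overhang remnant, e.g. AATTC
    reads: list[str] = []
    truth: list[RadTagTruth] = []
    any_site = False
    for var in varieties:
        barcode = barcode_map[var.variety_id]
        for subg, seq in (("A", var.seq_A), ("D", var.seq_D)):
            p = seq.find(enzyme_site)
            while p != -1:
                any_site = True
                flanks = []
                if p + 1 + tag_len <= len(seq):
                    aligned = seq[p + 1 : p + 1 + tag_len]
                    flanks.append(("R", p + 1, "+", aligned, aligned))
                if p + site_len - 1 - tag_len >= 0:
                    start = p + site_len - 1 - tag_len
                    aligned = seq[start : start + tag_len]
                    flanks.append(("L", start, "-", revcomp(aligned), aligned))
                for side, ref_start, strand, tag_seq, aligned_seq in flanks:
                    depth = int(rng.poisson(mean_depth))
                    truth.append(RadTagTruth(
                        locus_id=f"{ref_name}:{p}:{side}", ref_name=ref_name,
                        site_pos=p, side=side, ref_start=ref_start,
                        strand=strand, variety_id=var.variety_id,
                        subgenome=subg, tag_seq=tag_seq,
                        aligned_seq=aligned_seq, depth=depth))
                    raw = barcode + tag_seq
                    for _ in range(depth):
                        reads.append(_apply_errors(raw, error_rate, rng))
                p = seq.find(enzyme_site, p + 1)
    if not any_site:
        raise ParameterError(
            "no recognition sites in any subgenome; plant sites first "
            "(plant_restriction_sites) or use a different enzyme")
    return reads, truth


def align_tags_to_truth(tags, truth: list[RadTagTruth]):
    """Place collapsed tags at their true coordinates via the RAD truth set.

    The simulator stands in for an external tag aligner: a collapsed tag
    whose sequence matches a truth tag of the same variety is placed at the
    truth alignment; error tags (no exact truth match) are left unaligned
    and dropped, mimicking a stringent aligner.
    """
    from .rad import TagAlignment

    lookup = {(t.variety_id, t.tag_seq): t for t in truth}
    out = []
    for tag in tags:
        tr = lookup.get((tag.variety_id, tag.seq))
        if tr is not None:
            out.append(TagAlignment(tag, tr.ref_name, tr.ref_start, tr.strand,
                                    tr.aligned_seq))
    return out


def rebuild_variety(ref: ReferenceSequence, truth: list[TruthRecord],
                    variety_id: str) -> tuple[str, str]:
    """Reconstruct one variety's subgenome sequences from ref + truth.

    Used as the simulator's self-consistency check: the result must equal
    the sequences held by the corresponding TetraploidVariety.
    """
    seq_a, seq_d = list(ref.seq), list(ref.seq)
    for rec in truth:
        pair = rec.allele_map.get(variety_id, rec.allele_map.get("*"))
        if pair is not None:
            seq_a[rec.pos], seq_d[rec.pos] = pair
    return "".join(seq_a), "".join(seq_d)


@dataclass
class SimulatedDataset:
    """Everything one tetraploid simulation run produced."""

    reference: ReferenceSequence
    seq_A: str
    seq_D: str
    varieties: list[TetraploidVariety]
    truth: list[TruthRecord]  # SUBGENOME + VARIETAL, sorted by position

    @property
    def subgenome_truth(self) -> list[TruthRecord]:
        return [t for t in self.truth if t.kind == SUBGENOME]

    @property
    def varietal_truth(self) -> list[TruthRecord]:
        return [t for t in self.truth if t.kind == VARIETAL]

    def ancestral_alleles(self) -> dict[int, tuple[str, str]]:
        """pos -> (A-base, D-base) at subgenome-divergent sites."""
        return {t.pos: t.allele_map["*"] for t in self.subgenome_truth}


def simulate_tetraploid(length: int = 200_000, n_varieties: int = 4,
                        subgenome_rate: float = DEFAULT_SUBGENOME_RATE,
                        varietal_rate: float = DEFAULT_VARIETAL_RATE,
                        gc_fraction: float = 0.35, seed: int = 0,
                        anchor_distance: int = DEFAULT_ANCHOR_DISTANCE,
                        n_rad_sites: int = 0, enzyme_site: str = "GAATTC",
                        ref_name: str = "Chr01") -> SimulatedDataset:
    """Reference -> diverged subgenomes -> varieties, in one call.

    ``n_rad_sites > 0`` plants that many recognition sites before divergence
    so the RAD simulator has a controlled locus count.
    """
    ss = np.random.SeedSequence(seed)
    s_ref, s_sites, s_div, s_var = (int(s) % (2**31) for s in ss.generate_state(4))
    ref = make_reference(length, gc_fraction, seed=s_ref, name=ref_name)
    if n_rad_sites > 0:
        ref = plant_restriction_sites(ref, enzyme_site, n_rad_sites, seed=s_sites)
    seq_a, seq_d, sub_truth = diverge_subgenomes(ref, subgenome_rate, seed=s_div)
    varieties, var_truth = spawn_varieties(seq_a, seq_d, n_varieties,
                                           varietal_rate, seed=s_var,
                                           anchor_distance=anchor_distance)
    truth = sorted(sub_truth + var_truth, key=lambda t: t.pos)
    return SimulatedDataset(ref, seq_a, seq_d, varieties, truth)
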