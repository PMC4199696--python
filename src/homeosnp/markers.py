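"""Downstream marker engineering for called varietal SNPs.

Flank typing (how close the nearest other varietal SNP sits), primer
footprint profiling and codominance prediction for extension/ligation
genotyping assays, CAPS (cleaved amplified polymorphic sequence)
differential-digest discovery, and SNP density tracks.

In a tetraploid, an assay that co-amplifies the homeologous locus behaves
as a dominant marker; subgenome-specific SNPs inside the primer footprints
destabilise binding to the other homeolog and push the assay toward
codominant behaviour — the shipped empirical grid quantifies that effect.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from . import calibration
from ._util import revcomp, site_matches_at

CODOMINANT = "codominant"
DOMINANT = "dominant"
BINS = ("I", "II", "III", "IV")


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class FlankType:
    """Flank class of a varietal SNP by distance to its nearest neighbour.

    III: another varietal SNP within 20 bp; II: within 21-100 bp;
    I: none within 100 bp (distance may be infinite).
    """

    label: str
    distance: float

    @staticmethod
    def from_distance(distance: float) -> "FlankType":
        if distance <= 20:
            return FlankType("III", distance)
        if distance <= 100:
            return FlankType("II", distance)
        return FlankType("I", distance)


def classify_flank_type(snp_pos: int, all_positions: list[int]) -> FlankType:
    """Classify one SNP against the sorted positions on its chromosome.

    The SNP itself is excluded; distance is to the nearest other varietal
    SNP on either side.
    """
    i = bisect_left(all_positions, snp_pos)
    best = math.inf
    j = i
    while j < len(all_positions):  # skip entries equal to snp_pos itself
        if all_positions[j] != snp_pos:
            best = min(best, all_positions[j] - snp_pos)
            break
        j += 1
    j = i - 1
    while j >= 0:
        if all_positions[j] != snp_pos:
            best = min(best, snp_pos - all_positions[j])
            break
        j -= 1
    return FlankType.from_distance(best)


# ---------------------------------------------------------------------------
# Assay primer profiling


def distance_bin(offset: int) -> str:
    """3'-distance bin of a subgenome SNP inside a primer footprint."""
    if offset < 1:
        raise ValueError("offset from the 3' end must be >= 1")
    if offset <= 5:
        return "I"
    if offset <= 10:
        return "II"
    if offset <= 15:
        return "III"
    return "IV"


@dataclass
class PrimerFootprint:
    """Closed interval of reference positions plus the 3'-end position."""

    start: int
    end: int  # inclusive
    three_prime: int

    def __post_init__(self):
        if not self.start <= self.three_prime <= self.end:
            raise GeometryError("3' end must lie inside the primer interval")
        if self.three_prime not in (self.start, self.end):
            raise GeometryError("3' end must be one of the interval ends")

    def offsets(self, positions: list[int], snp_pos: int) -> list[int]:
        """1-based distances from the 3' end for positions in the footprint.

        When the 3'-terminal base is the assayed SNP itself (allele-specific
        oligo), the distance to the SNP is the distance from the 3' end;
        otherwise the terminal base counts as offset 1.
        """
        shift = 0 if self.three_prime == snp_pos else 1
        return sorted(abs(self.three_prime - p) + shift
                      for p in positions if self.start <= p <= self.end)


@dataclass
class AssayProfile:
    """Subgenome-SNP content of the two primer footprints of one assay."""

    snp_pos: int
    n_aso: int
    n_uni: int
    aso_offsets: list[int] = field(default_factory=list)
    uni_offsets: list[int] = field(default_factory=list)
    aso_bin: str = "Null"  # bin of the closest subgenome SNP, or Null
    uni_bin: str = "Null"


def primer_profile(snp_pos: int, subgenome_snp_positions: list[int],
                   aso_len: int = 25, uni_len: int = 25,
                   aso: PrimerFootprint | None = None,
                   uni: PrimerFootprint | None = None) -> AssayProfile:
    """Profile the subgenome-SNP content of an assay's primer footprints.

    Default geometry: the allele-specific oligo (ASO) ends at the SNP (its
    3'-terminal base interrogates the SNP); the universal primer sits
    immediately 3' of the SNP on the other side, its 3' end proximal.  The
    SNP position itself is never counted.
    """
    if aso is None:
        aso = PrimerFootprint(snp_pos - aso_len + 1, snp_pos, snp_pos)
    if uni is None:
        uni = PrimerFootprint(snp_pos + 1, snp_pos + uni_len, snp_pos + 1)
    if uni.start <= snp_pos <= uni.end:
        raise GeometryError("universal primer footprint overlaps the SNP")
    if not (aso.three_prime == snp_pos or not aso.start <= snp_pos <= aso.end):
        raise GeometryError("ASO may overlap the SNP only at its designed 3' base")
    positions = [p for p in subgenome_snp_positions if p != snp_pos]
    aso_off = aso.offsets(positions, snp_pos)
    uni_off = uni.offsets(positions, snp_pos)
    return AssayProfile(
        snp_pos=snp_pos, n_aso=len(aso_off), n_uni=len(uni_off),
        aso_offsets=aso_off, uni_offsets=uni_off,
        aso_bin=distance_bin(aso_off[0]) if aso_off else "Null",
        uni_bin=distance_bin(uni_off[0]) if uni_off else "Null")


def profile_from_bins(aso_bin: str, uni_bin: str, snp_pos: int = 0) -> AssayProfile:
    """Synthesize a profile with representative offsets for given bins.

    Used to rebuild labelled assay sets from published bin grids.
    """
    rep = {"I": 3, "II": 8, "III": 13, "IV": 18}
    aso_off = [rep[aso_bin]] if aso_bin != "Null" else []
    uni_off = [rep[uni_bin]] if uni_bin != "Null" else []
    return AssayProfile(snp_pos=snp_pos, n_aso=len(aso_off), n_uni=len(uni_off),
                        aso_offsets=aso_off, uni_offsets=uni_off,
                        aso_bin=aso_bin, uni_bin=uni_bin)


def predict_assay_behavior(profile: AssayProfile | tuple[int, int],
                           grid: dict[tuple[int, int], tuple[int, int]] | None = None,
                           ) -> tuple[str, float]:
    """Predict codominant vs dominant behaviour from primer subgenome-SNP counts.

    The probability is the empirical codominant proportion of the matching
    grid cell; empty cells fall back to the average of the row and column
    marginal proportions.  Hard rules: no subgenome SNP in either primer ->
    dominant (p = 0); four in either primer -> codominant (p = 1).
    """
    if grid is None:
        grid = calibration.ASSAY_BEHAVIOUR_GRID
    if isinstance(profile, AssayProfile):
        n_aso, n_uni = profile.n_aso, profile.n_uni
    else:
        n_aso, n_uni = profile
    if n_aso == 0 and n_uni == 0:
        return DOMINANT, 0.0
    if n_aso >= 4 or n_uni >= 4:
        return CODOMINANT, 1.0
    cell = grid.get((n_aso, n_uni))
    if cell and cell[1] > 0:
        p = cell[0] / cell[1]
    else:
        p = (_marginal(grid, n_aso, axis=0) + _marginal(grid, n_uni, axis=1)) / 2
    return (CODOMINANT if p >= 0.5 else DOMINANT), p


def _marginal(grid, n: int, axis: int) -> float:
    codo = total = 0
    for (i, j), (c, t) in grid.items():
        if (i if axis == 0 else j) == n:
            codo += c
            total += t
    return codo / total if total else 0.5


@dataclass
class AssayTableSummary:
    """Count grids and derived percentages over a labelled assay set."""

    grid: dict[tuple[int, int], tuple[int, int]]  # (n_aso, n_uni) -> (codom, total)
    row_marginals: dict[int, tuple[int, int]]
    col_marginals: dict[int, tuple[int, int]]
    bin_grids: dict[str, dict[tuple[str, str], int]]  # label -> bin x bin counts
    bin1_share: dict[str, float]  # label -> % with closest bin I in either primer

    def cell_percent(self, n_aso: int, n_uni: int) -> float:
        c, t = self.grid[(n_aso, n_uni)]
        return 100.0 * c / t

    def col_percent(self, n_uni: int) -> float:
        c, t = self.col_marginals[n_uni]
        return 100.0 * c / t


def summarize_assay_table(profiles: list[AssayProfile],
                          observed_labels: list[str]) -> AssayTableSummary:
    """Tabulate observed assay behaviour against primer subgenome-SNP content.

    Produces the (n_aso x n_uni) codominant/total grid with marginals, the
    per-label bin x bin grids for assays with at most one subgenome SNP per
    primer, and each label's share of those assays whose closest subgenome
    SNP falls in bin I (<=5 bp of a 3' end).
    """
    grid: dict[tuple[int, int], list[int]] = {}
    rows: dict[int, list[int]] = {}
    cols: dict[int, list[int]] = {}
    bin_grids: dict[str, dict[tuple[str, str], int]] = {}
    bin1_num: dict[str, int] = {}
    bin1_den: dict[str, int] = {}
    for prof, label in zip(profiles, observed_labels):
        key = (prof.n_aso, prof.n_uni)
        is_codo = 1 if label == CODOMINANT else 0
        for store, k in ((grid, key), (rows, prof.n_aso), (cols, prof.n_uni)):
            cell = store.setdefault(k, [0, 0])
            cell[0] += is_codo
            cell[1] += 1
        if prof.n_aso <= 1 and prof.n_uni <= 1 and prof.n_aso + prof.n_uni >= 1:
            bg = bin_grids.setdefault(label, {})
            bkey = (prof.aso_bin, prof.uni_bin)
            bg[bkey] = bg.get(bkey, 0) + 1
            bin1_den[label] = bin1_den.get(label, 0) + 1
            if prof.aso_bin == "I" or prof.uni_bin == "I":
                bin1_num[label] = bin1_num.get(label, 0) + 1
    share = {lab: 100.0 * bin1_num.get(lab, 0) / den
             for lab, den in bin1_den.items()}
    return AssayTableSummary(
        grid={k: (c, t) for k, (c, t) in grid.items()},
        row_marginals={k: (c, t) for k, (c, t) in rows.items()},
        col_marginals={k: (c, t) for k, (c, t) in cols.items()},
        bin_grids=bin_grids, bin1_share=share)


# ---------------------------------------------------------------------------
# CAPS


@dataclass
class CapsHit:
    """A restriction enzyme whose digest differs between the two alleles."""

    enzyme: str
    sites_allele1: list[int]
    sites_allele2: list[int]
    fragments_allele1: list[int]
    fragments_allele2: list[int]


def _site_positions(seq: str, site: str) -> list[int]:
    """Start positions where the recognition site matches on either strand."""
    hits = {p for p in range(len(seq) - len(site) + 1)
            if site_matches_at(seq, p, site)}
    rc = revcomp(site)
    if rc != site:
        hits |= {p for p in range(len(seq) - len(rc) + 1)
                 if site_matches_at(seq, p, rc)}
    return sorted(hits)


def _fragments(length: int, cuts: list[int]) -> list[int]:
    edges = [0] + sorted(cuts) + [length]
    return [b - a for a, b in zip(edges, edges[1:]) if b > a]


def caps_differential(flank_seq_allele1: str, flank_seq_allele2: str,
                      enzyme_dict: dict[str, str] | None = None) -> list[CapsHit]:
    """Find enzymes whose recognition-site matches differ between alleles.

    The two amplicon sequences must differ at exactly one base (the SNP).
    Matching is IUPAC-aware on both strands; diagnostic fragment lengths
    use the site start as the nominal cut position.
    """
    if enzyme_dict is None:
        enzyme_dict = calibration.ENZYME_SITES
    s1, s2 = flank_seq_allele1.upper(), flank_seq_allele2.upper()
    if len(s1) != len(s2):
        raise ValueError("allele amplicons must have equal length")
    diffs = [i for i, (a, b) in enumerate(zip(s1, s2)) if a != b]
    if len(diffs) != 1:
        raise ValueError(
            f"allele amplicons must differ at exactly the SNP base (found {len(diffs)} diffs)")
    hits = []
    for enzyme, site in sorted(enzyme_dict.items()):
        p1 = _site_positions(s1, site)
        p2 = _site_positions(s2, site)
        if p1 != p2:
            hits.append(CapsHit(enzyme, p1, p2,
                                _fragments(len(s1), p1), _fragments(len(s2), p2)))
    return hits


# ---------------------------------------------------------------------------
# Density


def snp_density_track(positions: list[int], chrom_len: int,
                      window: int = 50_000, step: int = 25_000,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window SNP counts: windows start at 0, step apart.

    Each window counts SNPs with start <= pos < start + window; the last
    partial window is included.  Returns (window_starts, counts).
    """
    starts = np.arange(0, max(chrom_len, 1), step)
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, np.minimum(starts + window, chrom_len), side="left")
    return starts, (hi - lo).astype(np.int64)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def density_per_chromosome(counts: dict[str, int], lengths_mb: dict[str, float],
                           ) -> tuple[dict[str, int], int]:
    """SNPs/Mb per chromosome (integer, half away from zero) and overall."""
    per = {}
    for chrom, n in counts.items():
        mb = lengths_mb[chrom]
        if mb <= 0:
            raise ValueError(f"chromosome length must be > 0 Mb ({chrom})")
        per[chrom] = _round_half_away(n / mb)
    total = sum(counts.values())
    total_mb = sum(lengths_mb[c] for c in counts)
    overall = _round_half_away(total / total_mb) if total_mb else 0
    return per, overall
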