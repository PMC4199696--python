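"""Marker engineering: flank types, assay prediction, CAPS, density."""

import math

import numpy as np
import pytest

from homeosnp import calibration
from homeosnp.markers import (
    CODOMINANT,
    DOMINANT,
    GeometryError,
    PrimerFootprint,
    caps_differential,
    classify_flank_type,
    density_per_chromosome,
    distance_bin,
    predict_assay_behavior,
    primer_profile,
    profile_from_bins,
    snp_density_track,
    summarize_assay_table,
)
from oracles import brute_caps_enzymes, brute_site_positions, random_amplicon_pair


# ---------------------------------------------------------------------------
# flank types


@pytest.mark.parametrize("neighbour_offset,label", [
    (15, "III"), (20, "III"), (21, "II"), (60, "II"), (100, "II"), (150, "I"),
])
def test_flank_type_thresholds(neighbour_offset, label):
    ft = classify_flank_type(1000, [1000, 1000 + neighbour_offset])
    assert ft.label == label and ft.distance == neighbour_offset


def test_flank_type_is_symmetric():
    left = classify_flank_type(1000, [985, 1000])
    right = classify_flank_type(1000, [1000, 1015])
    assert left.label == right.label == "III"


def test_single_snp_is_type_one_with_infinite_distance():
    ft = classify_flank_type(1000, [1000])
    assert ft.label == "I" and math.isinf(ft.distance)


def test_flank_counts_partition_consistently():
    rng = np.random.default_rng(50)
    positions = sorted(int(p) for p in rng.choice(100_000, 400, replace=False))
    types = [classify_flank_type(p, positions) for p in positions]
    n_i_ii = sum(t.label in ("I", "II") for t in types)
    no_close = sum(
        1 for p in positions
        if not any(q != p and abs(q - p) <= 20 for q in positions))
    assert n_i_ii == no_close


# ---------------------------------------------------------------------------
# primer profiles


def test_primer_profile_bins_and_counts():
    # subgenome SNP 3 bp from the ASO 3' end (= the assayed SNP position)
    prof = primer_profile(1000, [997])
    assert (prof.n_aso, prof.n_uni) == (1, 0)
    assert prof.aso_bin == "I" and prof.uni_bin == "Null"
    prof = primer_profile(1000, [1016])  # offset 16 on the universal side
    assert (prof.n_aso, prof.n_uni) == (0, 1)
    assert prof.uni_bin == "IV"
    prof = primer_profile(1000, [])
    assert (prof.aso_bin, prof.uni_bin) == ("Null", "Null")
    assert (prof.n_aso, prof.n_uni) == (0, 0)


def test_primer_profile_never_counts_the_snp_itself():
    prof = primer_profile(1000, [1000])
    assert (prof.n_aso, prof.n_uni) == (0, 0)


def test_bad_geometry_rejected():
    with pytest.raises(GeometryError):
        primer_profile(1000, [], uni=PrimerFootprint(995, 1019, 995))
    with pytest.raises(GeometryError):
        PrimerFootprint(10, 20, 15)  # 3' end must be an interval end


@pytest.mark.parametrize("offset,expected", [(1, "I"), (5, "I"), (6, "II"),
                                             (10, "II"), (11, "III"),
                                             (15, "III"), (16, "IV")])
def test_distance_bins(offset, expected):
    assert distance_bin(offset) == expected


# ---------------------------------------------------------------------------
# behaviour prediction


def test_hard_rules_and_grid_cells():
    assert predict_assay_behavior((0, 0)) == (DOMINANT, 0.0)
    label, p = predict_assay_behavior((0, 2))
    assert label == CODOMINANT and round(100 * p, 1) == 76.9
    assert predict_assay_behavior((4, 0)) == (CODOMINANT, 1.0)
    assert predict_assay_behavior((0, 4)) == (CODOMINANT, 1.0)


def test_empty_cell_falls_back_to_marginals():
    grid = {(0, 1): (1, 2), (1, 0): (1, 4), (1, 1): (3, 4)}
    label, p = predict_assay_behavior((0, 0), grid)  # hard rule wins
    assert (label, p) == (DOMINANT, 0.0)
    label, p = predict_assay_behavior((2, 1), grid)  # empty cell
    row = 0.5  # no assays with n_aso=2: neutral 0.5
    col = (1 + 3) / (2 + 4)
    assert p == pytest.approx((row + col) / 2)
    assert label == CODOMINANT


def test_marginal_proportions_are_label_monotone():
    from homeosnp.markers import _marginal

    grid = calibration.ASSAY_BEHAVIOUR_GRID
    for axis in (0, 1):
        seen_codominant = False
        for n in range(5):
            label = CODOMINANT if _marginal(grid, n, axis) >= 0.5 else DOMINANT
            if label == CODOMINANT:
                seen_codominant = True
            else:
                assert not seen_codominant


# ---------------------------------------------------------------------------
# summary grids


def _labelled_profiles_from_bin_grids():
    profiles, labels = [], []
    for grid, label in ((calibration.BIN_GRID_CODOMINANT, CODOMINANT),
                        (calibration.BIN_GRID_DOMINANT, DOMINANT)):
        for (aso_bin, uni_bin), n in grid.items():
            for _ in range(n):
                profiles.append(profile_from_bins(aso_bin, uni_bin))
                labels.append(label)
    return profiles, labels


def test_summary_reproduces_single_snp_bin_one_shares():
    profiles, labels = _labelled_profiles_from_bin_grids()
    summary = summarize_assay_table(profiles, labels)
    assert round(summary.bin1_share[CODOMINANT], 1) == 50.0
    assert round(summary.bin1_share[DOMINANT], 1) == 36.4
    nonzero = lambda g: {k: n for k, n in g.items() if n}
    assert summary.bin_grids[CODOMINANT] == nonzero(calibration.BIN_GRID_CODOMINANT)
    assert summary.bin_grids[DOMINANT] == nonzero(calibration.BIN_GRID_DOMINANT)


def test_summary_reproduces_behaviour_grid_marginals():
    profiles, labels = [], []
    rng = np.random.default_rng(51)
    for (n_aso, n_uni), (codo, total) in calibration.ASSAY_BEHAVIOUR_GRID.items():
        for k in range(total):
            prof = profile_from_bins("I" if n_aso else "Null",
                                     "I" if n_uni else "Null")
            prof.n_aso, prof.n_uni = n_aso, n_uni
            profiles.append(prof)
            labels.append(CODOMINANT if k < codo else DOMINANT)
    order = rng.permutation(len(profiles))
    summary = summarize_assay_table([profiles[i] for i in order],
                                    [labels[i] for i in order])
    assert summary.grid == calibration.ASSAY_BEHAVIOUR_GRID
    assert round(summary.col_percent(0), 1) == 24.7
    assert summary.col_marginals[0] == (20, 81)
    assert summary.row_marginals[4] == (3, 3)


def test_summary_of_empty_input_has_no_divisions():
    summary = summarize_assay_table([], [])
    assert summary.grid == {} and summary.bin1_share == {}


# ---------------------------------------------------------------------------
# CAPS


def test_snp_creating_ecori_site_is_differential():
    base = "T" * 50 + "GAATT" + "T" * 50
    allele_g = base[:55] + "C" + base[56:]
    allele_a = base[:55] + "A" + base[56:]
    hits = {h.enzyme: h for h in caps_differential(allele_g, allele_a)}
    assert "EcoRI" in hits
    assert hits["EcoRI"].sites_allele1 == [50] and hits["EcoRI"].sites_allele2 == []
    assert hits["EcoRI"].fragments_allele1 == [50, 55]  # cut at the site start
    assert hits["EcoRI"].fragments_allele2 == [105]


def test_snp_touching_no_site_yields_empty_list():
    s1 = "T" * 101
    s2 = "T" * 50 + "A" + "T" * 50
    assert caps_differential(s1, s2) == []


def test_caps_rejects_multiple_differences():
    with pytest.raises(ValueError):
        caps_differential("AAAA", "TTAA")


def test_caps_detects_reverse_strand_sites():
    # a non-palindromic recognition site planted only as its reverse
    # complement: the double-strand scan must still see it
    site = "GGATG"
    rc = "CATCC"
    s1 = "T" * 40 + rc + "T" * 40
    s2 = s1[:42] + "G" + s1[43:]  # breaks the reverse-strand match
    assert site not in s1 and site not in s2
    enzymes = {h.enzyme for h in caps_differential(s1, s2, {"TestEnz": site})}
    assert enzymes == {"TestEnz"}


def test_caps_matches_bruteforce_scanner_on_random_amplicons():
    rng = np.random.default_rng(52)
    for _ in range(100):
        s1, s2 = random_amplicon_pair(rng, calibration.ENZYME_SITES)
        impl = sorted(h.enzyme for h in caps_differential(s1, s2))
        assert impl == brute_caps_enzymes(s1, s2, calibration.ENZYME_SITES)
        for enzyme, site in calibration.ENZYME_SITES.items():
            from homeosnp.markers import _site_positions

            assert _site_positions(s1, site) == brute_site_positions(s1, site)


# ---------------------------------------------------------------------------
# density


def test_density_track_window_geometry():
    rng = np.random.default_rng(53)
    positions = sorted(int(p) for p in rng.integers(0, 50_000, 10))
    starts, counts = snp_density_track(positions, 100_000)
    assert list(starts) == [0, 25_000, 50_000, 75_000]
    assert counts[0] == 10 and counts[2] == 0 and counts[3] == 0


def test_density_track_empty_calls():
    _, counts = snp_density_track([], 100_000)
    assert counts.sum() == 0


def test_density_track_conserves_total_without_overlap():
    rng = np.random.default_rng(54)
    positions = sorted(int(p) for p in rng.integers(0, 100_000, 500))
    _, counts = snp_density_track(positions, 100_000, window=50_000, step=50_000)
    assert counts.sum() == 500


def test_chromosome_densities_from_shipped_tallies():
    counts = {c: n for c, (n, _, _, _) in calibration.CHROMOSOME_SNP_COUNTS.items()}
    lengths = {c: mb for c, (_, _, _, mb) in calibration.CHROMOSOME_SNP_COUNTS.items()}
    per, overall = density_per_chromosome(counts, lengths)
    assert per["Chr09"] == 78  # the densest chromosome
    assert per["Chr02"] == 42  # the sparsest
    assert overall == 53
    assert sum(counts.values()) == 40_503


def test_zero_snps_density_is_zero():
    per, overall = density_per_chromosome({"c1": 0}, {"c1": 10.0})
    assert per == {"c1": 0} and overall == 0
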