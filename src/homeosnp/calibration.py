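"""Shipped empirical calibration data for the marker utilities.

These counts come from a published genotyping survey of SNP assays in
allotetraploid cotton (*G. hirsutum*), in which 258 RAD-derived varietal
SNP assays were scored as codominant or dominant and related to the number
and 3'-proximity of subgenome-specific SNPs in their primer footprints,
and ~40,000 varietal SNPs were tallied per *G. raimondii* chromosome.
They are the default lookup grid for assay-behaviour prediction and the
worked inputs for the density utilities.
"""

from __future__ import annotations

#: (n subgenome SNPs in allele-specific primer,
#:  n subgenome SNPs in universal primer) -> (codominant assays, total assays)
ASSAY_BEHAVIOUR_GRID: dict[tuple[int, int], tuple[int, int]] = {
    (0, 0): (0, 18), (0, 1): (11, 29), (0, 2): (10, 13), (0, 3): (2, 5), (0, 4): (1, 1),
    (1, 0): (5, 38), (1, 1): (13, 39), (1, 2): (10, 21), (1, 3): (11, 13), (1, 4): (2, 3),
    (2, 0): (7, 15), (2, 1): (15, 25), (2, 2): (7, 9), (2, 3): (2, 3),
    (3, 0): (5, 7), (3, 1): (4, 6), (3, 2): (4, 6), (3, 3): (4, 4),
    (4, 0): (3, 3),
}

#: Distance-bin grids for assays with a single subgenome SNP per primer
#: footprint: (allele-specific primer bin, universal primer bin) -> count.
#: Bins: I <=5 bp, II 6-10 bp, III 11-15 bp, IV >=16 bp from the 3' end;
#: NULL = no subgenome SNP in that primer.
BIN_GRID_CODOMINANT: dict[tuple[str, str], int] = {
    ("I", "I"): 2, ("I", "II"): 1, ("I", "III"): 1, ("I", "IV"): 0, ("I", "Null"): 3,
    ("II", "I"): 1, ("II", "II"): 1, ("II", "III"): 0, ("II", "IV"): 2, ("II", "Null"): 0,
    ("III", "I"): 1, ("III", "II"): 0, ("III", "III"): 0, ("III", "IV"): 1, ("III", "Null"): 1,
    ("IV", "I"): 4, ("IV", "II"): 0, ("IV", "III"): 0, ("IV", "IV"): 0, ("IV", "Null"): 1,
    ("Null", "I"): 2, ("Null", "II"): 3, ("Null", "III"): 5, ("Null", "IV"): 1,
}

BIN_GRID_DOMINANT: dict[tuple[str, str], int] = {
    ("I", "I"): 1, ("I", "II"): 1, ("I", "III"): 2, ("I", "IV"): 5, ("I", "Null"): 9,
    ("II", "I"): 1, ("II", "II"): 2, ("II", "III"): 2, ("II", "IV"): 2, ("II", "Null"): 4,
    ("III", "I"): 1, ("III", "II"): 2, ("III", "III"): 0, ("III", "IV"): 1, ("III", "Null"): 8,
    ("IV", "I"): 2, ("IV", "II"): 2, ("IV", "III"): 1, ("IV", "IV"): 1, ("IV", "Null"): 12,
    ("Null", "I"): 6, ("Null", "II"): 1, ("Null", "III"): 5, ("Null", "IV"): 6,
}

#: Per-chromosome varietal SNP tallies on the *G. raimondii* reference:
#: chromosome -> (total SNPs, transcriptome-derived, RAD-derived, length in Mb)
CHROMOSOME_SNP_COUNTS: dict[str, tuple[int, int, int, float]] = {
    "Chr01": (2711, 2467, 244, 55.9),
    "Chr02": (2613, 2385, 228, 62.7),
    "Chr03": (1960, 1860, 100, 45.8),
    "Chr04": (3349, 3003, 346, 62.2),
    "Chr05": (3524, 3188, 336, 64.1),
    "Chr06": (2666, 2426, 240, 51.1),
    "Chr07": (4049, 3863, 186, 61.0),
    "Chr08": (3076, 2883, 193, 57.1),
    "Chr09": (5502, 5223, 279, 70.7),
    "Chr10": (3256, 2870, 386, 62.2),
    "Chr11": (2778, 2601, 177, 62.7),
    "Chr12": (1817, 1681, 136, 35.4),
    "Chr13": (3069, 2844, 225, 58.3),
    "scaffolds": (133, 119, 14, 12.2),
}

#: Restriction enzymes for CAPS conversion: name -> IUPAC recognition site.
ENZYME_SITES: dict[str, str] = {
    "EcoRI": "GAATTC",
    "ApeKI": "GCWGC",
    "SbfI": "CCTGCAGG",
    "BamHI": "GGATCC",
    "HindIII": "AAGCTT",
    "EcoRV": "GATATC",
    "PstI": "CTGCAG",
    "SalI": "GTCGAC",
    "XbaI": "TCTAGA",
    "XhoI": "CTCGAG",
    "KpnI": "GGTACC",
    "SacI": "GAGCTC",
    "SmaI": "CCCGGG",
    "ApaI": "GGGCCC",
    "NcoI": "CCATGG",
    "NdeI": "CATATG",
    "NheI": "GCTAGC",
    "SpeI": "ACTAGT",
    "BglII": "AGATCT",
    "ClaI": "ATCGAT",
    "DraI": "TTTAAA",
    "ScaI": "AGTACT",
    "HpaI": "GTTAAC",
    "StuI": "AGGCCT",
}
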