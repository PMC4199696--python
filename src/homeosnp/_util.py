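"""Small shared helpers: alphabets, complements, IUPAC expansion, gzip-aware open."""

from __future__ import annotations

import gzip
from typing import IO

DNA = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(DNA)}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def site_matches_at(seq: str, pos: int, site: str) -> bool:
    """IUPAC-aware exact match of `site` against seq[pos:pos+len(site)]."""
    if pos < 0 or pos + len(site) > len(seq):
        return False
    return all(seq[pos + i] in IUPAC[c] for i, c in enumerate(site))


def xopen(path, mode: str = "rt") -> IO:
    """Open a path, transparently decompressing ``.gz``."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
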