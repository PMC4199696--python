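"""Independent brute-force oracles.

Naive, dictionary-based re-implementations of the documented calling rules
and of double-strand restriction-site scanning.  They share no code with
the package's implementations (no numpy pileups, no interval indexes, no
IUPAC regex tricks) and exist to cross-check them on small random inputs.
"""

from collections import Counter
from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def read_base_at(read, pos):
    """Walk the CIGAR from scratch for every query (no caching)."""
    r, q = read.ref_start, 0
    for op, n in read.cigar:
        if op in "M=X":
            if r <= pos < r + n:
                return read.seq[q + (pos - r)]
            r += n
            q += n
        elif op in "DN":
            if r <= pos < r + n:
                return None
            r += n
        elif op in "IS":
            q += n
    return None


def brute_pileup(reads, length):
    """pos -> variety -> base -> count, by scanning every (pos, read) pair."""
    out = {}
    for pos in range(length):
        per_v = {}
        for read in reads:
            b = read_base_at(read, pos)
            if b is not None and b in "ACGT":
                per_v.setdefault(read.variety_id, Counter())[b] += 1
        if per_v:
            out[pos] = {v: dict(c) for v, c in per_v.items()}
    return out


def _fragments(reads):
    """Group reads into fragments by id up to a trailing /1 or /2."""
    frags = {}
    for read in reads:
        fid = read.read_id[:-2] if read.read_id.endswith(("/1", "/2")) else read.read_id
        frags.setdefault((read.variety_id, fid), []).append(read)
    return frags


def _fragment_base(frag, pos):
    bases = {b for r in frag if (b := read_base_at(r, pos)) is not None}
    return bases.pop() if len(bases) == 1 else None


def _joint(reads, variety, p, q):
    counts = Counter()
    for (v, _), frag in _fragments(reads).items():
        if v != variety:
            continue
        a, b = _fragment_base(frag, p), _fragment_base(frag, q)
        if a is not None and b is not None:
            counts[(a, b)] += 1
    return counts


def oracle_transcriptome(reads, varieties, start, end, min_depth=2,
                         min_allele_support=2, min_within_freq=0.2,
                         min_phase_support=2, phase_purity=0.9,
                         anchor_distance=10_000, max_iter=10):
    """Exhaustively classify every site in [start, end).

    Returns (anchor position -> ordered allele pair,
             call position -> (class, frozenset(alleles), tuple(anchors))).
    """
    pile = brute_pileup(reads, end)

    def overall(pos):
        c = Counter()
        for v in varieties:
            c.update(pile.get(pos, {}).get(v, {}))
        return c

    biallelic = {}
    for pos in range(start, end):
        obs = sorted(b for b, n in overall(pos).items() if n >= min_allele_support)
        if len(obs) == 2:
            biallelic[pos] = tuple(obs)

    # -- subgenome-pattern candidates
    def is_candidate(pos):
        if pos not in biallelic:
            return False
        b0, b1 = biallelic[pos]
        deep = 0
        for v in varieties:
            counts = pile.get(pos, {}).get(v, {})
            depth = sum(counts.values())
            if depth < min_depth:
                continue
            deep += 1
            for b in (b0, b1):
                n = counts.get(b, 0)
                if n < min_allele_support or n < min_within_freq * depth:
                    return False
        return deep >= 1

    def ordered_pair(pos):
        tot = overall(pos)
        return tuple(sorted(biallelic[pos], key=lambda b: (-tot[b], b)))

    def support(pos):
        tot = overall(pos)
        return sum(tot[b] for b in biallelic[pos])

    candidates = [p for p in sorted(biallelic) if is_candidate(p)]
    cand_set = set(candidates)

    # -- pairwise joint-haplotype conflict graph, then greedy removal of the
    #    worst offender (most conflicts, lowest support, rightmost) until
    #    the surviving set is conflict-free
    def pair_conflicts(a, b):
        for v in varieties:
            joint = _joint(reads, v, a, b)
            cells = sum(1 for (x, y), n in joint.items()
                        if n >= min_allele_support
                        and x in biallelic[a] and y in biallelic[b])
            if cells > 2:
                return True
        return False

    edges = {(a, b) for i, a in enumerate(candidates)
             for b in candidates[i + 1:] if pair_conflicts(a, b)}
    alive = set(candidates)
    for _ in range(max_iter):
        degree = Counter()
        for a, b in edges:
            if a in alive and b in alive:
                degree[a] += 1
                degree[b] += 1
        if not degree:
            break
        worst = max(degree, key=lambda p: (degree[p], -support(p), p))
        alive.discard(worst)
    anchor_map = {p: ordered_pair(p) for p in candidates if p in alive}

    # -- varietal calling: enumerate every (site, anchor) combination
    def phase_consensus(joint, phase_allele):
        counts = Counter({b: n for (a, b), n in joint.items() if a == phase_allele})
        total = sum(counts.values())
        if total < min_phase_support:
            return None
        base, top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if top < min_phase_support or top < phase_purity * total:
            return None
        return base

    calls = {}
    for s in sorted(biallelic):
        if not start <= s < end or s in anchor_map:
            continue
        used = []
        evidence = None
        for g in sorted(anchor_map):
            if g == s or abs(g - s) > anchor_distance:
                continue
            pair = anchor_map[g]
            per_v = {}
            ok = True
            for v in varieties:
                joint = Counter({k: n for k, n in _joint(reads, v, g, s).items()
                                 if k[0] in pair})
                if not joint:
                    continue
                cons = []
                for allele in pair:
                    c = phase_consensus(joint, allele)
                    if c is None:
                        ok = False
                        break
                    cons.append(c)
                if not ok:
                    break
                per_v[v] = tuple(cons)
            if not ok or len(per_v) < 2:
                continue
            g0 = {c[0] for c in per_v.values()}
            g1 = {c[1] for c in per_v.values()}
            if (len(g0) == 2 and len(g1) == 1) != (len(g1) == 2 and len(g0) == 1):
                used.append(g)
                if evidence is None:
                    evidence = per_v
        if evidence is not None:
            g0 = {c[0] for c in evidence.values()}
            split = g0 if len(g0) == 2 else {c[1] for c in evidence.values()}
            label = "CONFLICT" if s in cand_set else "VARIETAL"
            calls[s] = (label, frozenset(split), tuple(sorted(used)))
        else:
            sets = set()
            for v in varieties:
                counts = pile.get(s, {}).get(v, {})
                obs = frozenset(b for b, n in counts.items()
                                if n >= min_allele_support)
                if obs:
                    sets.add(obs)
            if s not in cand_set and len(sets) > 1:
                calls[s] = ("EQUIVOCAL", frozenset(biallelic[s]), ())
    return anchor_map, calls


# ---------------------------------------------------------------------------
# Random micro-scenarios for oracle-equivalence checks


def random_micro_scenario(rng):
    """A tiny random read set: <=5 polymorphic sites, <=40 reads.

    Reads draw from a random reference with per-site alternative alleles
    sprinkled at random, some grouped into mate pairs (shared fragment id).
    Returns (reads sorted by start, variety ids, region length).
    """
    from homeosnp.io_formats import AlignedRead

    length = 30
    bases = "ACGT"
    ref = [bases[rng.integers(4)] for _ in range(length)]
    n_sites = int(rng.integers(1, 6))
    sites = {}
    for pos in rng.choice(length, size=n_sites, replace=False):
        alt = bases[rng.integers(4)]
        while alt == ref[pos]:
            alt = bases[rng.integers(4)]
        sites[int(pos)] = alt
    varieties = [f"v{i+1}" for i in range(int(rng.integers(2, 4)))]
    reads = []
    n_frags = int(rng.integers(6, 21))
    for i in range(n_frags):
        v = varieties[int(rng.integers(len(varieties)))]
        # the fragment's haplotype: allele choice per polymorphic site
        hap = {p: (sites[p] if rng.random() < 0.5 else ref[p]) for p in sites}
        paired = rng.random() < 0.4
        n_mates = 2 if paired else 1
        for mate in range(n_mates):
            rl = int(rng.integers(8, 17))
            start = int(rng.integers(0, length - rl + 1))
            seq = "".join(hap.get(p, ref[p]) for p in range(start, start + rl))
            rid = f"{v}_f{i}/{mate+1}" if paired else f"{v}_f{i}"
            reads.append(AlignedRead(rid, v, "c1", start, [("M", rl)], seq))
    reads.sort(key=lambda r: (r.ref_start, r.read_id))
    return reads, varieties, length


def run_micro_comparison(n_scenarios, seed):
    """Compare the caller against the oracle on random micro-regions.

    Returns the number of scenarios (out of ``n_scenarios``) where anchors
    and calls agree exactly.
    """
    import numpy as np

    from homeosnp.transcriptome import (Region, build_pileup, call_varietal_snps,
                                        classify_subgenome_sites)

    rng = np.random.default_rng(seed)
    agree = 0
    mismatches = []
    for k in range(n_scenarios):
        reads, varieties, length = random_micro_scenario(rng)
        pile = build_pileup(reads, length, "c1", varieties)
        region = Region("c1", 0, length)
        anchors = classify_subgenome_sites(region, pile, min_allele_support=2,
                                           min_within_freq=0.2, min_depth=2)
        calls = call_varietal_snps(region, pile, anchors, min_allele_support=2,
                                   min_phase_support=2, phase_purity=0.9,
                                   anchor_distance=length, min_depth=2,
                                   min_within_freq=0.2)
        got_anchors = {a.pos: a.alleles for a in anchors}
        got_calls = {c.pos: (c.class_label, frozenset(c.alleles), tuple(c.anchors))
                     for c in calls}
        exp_anchors, exp_calls = oracle_transcriptome(
            reads, varieties, 0, length, min_depth=2, anchor_distance=length)
        if got_anchors == exp_anchors and got_calls == exp_calls:
            agree += 1
        else:
            mismatches.append((k, got_anchors, exp_anchors, got_calls, exp_calls))
    return agree, mismatches


# ---------------------------------------------------------------------------
# CAPS


def _expand(site):
    return ["".join(p) for p in product(*[IUPAC[c] for c in site])]


def _rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def brute_site_positions(seq, site):
    """All start positions of the site on either strand, by expanding the
    IUPAC code into every concrete sequence and string-scanning both."""
    hits = set()
    for concrete in _expand(site):
        for probe in {concrete, _rc(concrete)}:
            start = seq.find(probe)
            while start != -1:
                hits.add(start)
                start = seq.find(probe, start + 1)
    return sorted(hits)


def random_amplicon_pair(rng, enzyme_dict, length=200):
    """Two random ~200-bp amplicons differing at one SNP base, with a few
    planted recognition sites so digests are non-trivial."""
    bases = "ACGT"
    seq = [bases[i] for i in rng.integers(0, 4, length)]
    sites = list(enzyme_dict.values())
    for _ in range(3):
        site = sites[rng.integers(len(sites))]
        site = "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in site)
        p = rng.integers(0, length - len(site))
        seq[p : p + len(site)] = site
    pos = int(rng.integers(0, length))
    s1 = "".join(seq)
    alt = bases[rng.integers(4)]
    while alt == s1[pos]:
        alt = bases[rng.integers(4)]
    return s1, s1[:pos] + alt + s1[pos + 1:]


def brute_caps_enzymes(seq1, seq2, enzyme_dict):
    """Enzymes whose double-strand match positions differ between alleles."""
    return sorted(e for e, site in enzyme_dict.items()
                  if brute_site_positions(seq1, site) != brute_site_positions(seq2, site))
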