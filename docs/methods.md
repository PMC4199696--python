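# Methods

## Model of the data

The package assumes an allotetraploid whose two subgenomes (A and D) are
substitution-diverged copies of one coordinate system: reads from both
homeologs of every variety co-align to a single diploid reference, so a
per-variety pileup at one position mixes two phases (subgenomes) in
unknown, possibly unequal proportions.  Three site classes follow:

- a **subgenome-specific SNP** is biallelic with the *same* allele pair in
  every variety (both homeologs expressed and sampled);
- a **varietal SNP** is a between-variety difference confined to one
  subgenome: conditioned on the phase, one phase splits the varieties into
  two allele groups and the other phase is uniform;
- an **equivocal site** is a between-variety difference that cannot be
  phased; unequal homeolog expression or shallow sampling can produce the
  identical pileup pattern, so the caller refuses it.

The central identifiability assumption: a varietal SNP can be called if
and only if some subgenome-specific SNP lies close enough to co-occur with
it on sequenced molecules.  The caller never guesses at sites where that
evidence is absent; the cost is a known blind spot (genuinely unanchored
varietal SNPs are reported as equivocal at best).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_depth` | 8 | reads/variety, window mean | two phases × ≥2 fragments per phase needs ≥8 under 1:1 expression; also the per-variety depth above which the subgenome pattern is *required* at anchor candidates |
| `window`, `step` | 100, 50 | bp | read-density scan granularity; the window equals the span within which phasing is attempted |
| `anchor_distance` | 90 | bp | the RNA read length: co-occurrence on one fragment is what phasing uses |
| `min_allele_support` | 2 | reads | an allele "observed" below this is treated as noise |
| `min_within_freq` | 0.2 | fraction | both anchor alleles must be credible within each well-covered variety |
| `min_phase_support` | 2 | fragments | minimum evidence per phase per variety |
| `phase_purity` | 0.9 | fraction | per-phase consensus must be near-unanimous; ties are skipped, never guessed |
| `region_max` | 10 000 | bp | caps region size; chunks overlap by 2×`anchor_distance` so border sites keep their anchors |
| RAD `tag_len` | 78 | bp | fixed tag length after barcode removal |
| RAD `min_depth` | 4 | reads/tag | removes essentially all error tags while keeping real ones once reads are collapsed to consensus tags |

## Design choices that were genuinely open

- **Read-density rule.** "Dense enough" is operationalised as ≥`min_depth`
  mean coverage for *every* variety in a window; qualifying windows merge
  into maximal regions, split into ≤10-kb overlapping chunks.
- **Anchor pruning.** Per-site biallelism in every variety is necessary
  but not sufficient (paralogs and repeats imitate it).  Candidate pairs
  co-covered by fragments are checked for joint-haplotype consistency: a
  2×2 table with more than two well-supported cells in any variety marks
  both as conflicting.  Because the pairwise tables never change, the
  conflict graph is computed once and the worst offender (most conflicts,
  then lowest support, then the rightmost site) is removed greedily until
  the surviving set is conflict-free (≤ `max_iter` removals).  This is
  this package's concrete realisation of an iterative
  "all pairwise combinations" consistency step.
- **Fragment-level phasing.** The unit of phase evidence is the fragment
  (read pair), not the single read: mates come from one molecule, hence
  one subgenome.  Mates that disagree at a position contribute nothing
  there.  This roughly triples the usable co-coverage at anchor distances
  near the read length.
- **Joint multi-variety calling.** All varieties are phased against an
  anchor simultaneously and the call records the induced variety
  partition, rather than calling pairs of varieties and merging.
- **Anchor support scope.** Both anchor phases must be supported in every
  variety that has fragments covering the site pair — not in varieties
  with no informative fragments there (they are simply not compared; at
  least two compared varieties are required).
- **Subgenome labels.** Calls are labelled A/D only when an
  ancestral-diploid allele table is supplied (the simulator provides one);
  otherwise U.  Real assignments need the second progenitor's genome,
  which is out of scope.
- **Conflicts.** A site matching both the subgenome-anchor pattern and the
  varietal pattern, or a nonredundant merge with incompatible per-variety
  alleles, is demoted to CONFLICT and excluded from the default output.
- **RAD locus patterns.** Only the 4-tag pattern (exactly two distinct
  tags per variety) is called.  One tag per variety is monomorphic
  pass-through; more than two is repetitive; mixtures (including
  restriction-site loss in one subgenome) are unbalanced — reported, never
  called.  A 2:2 column grouping whole varieties against each other is a
  putative homozygous varietal difference, reported separately and never
  used as an anchor.  Anchor bipartitions are canonicalised (the side
  containing the lexicographically first tag) before the uniqueness check.
  With >2 varieties the pattern generalises to an n:n variety-concordant
  split and a single-deviating-tag rule.
- **CLC-style per-base quality filters** have no analogue once reads are
  collapsed to consensus tags; the depth-≥4 collapse filter replaces them
  deliberately.
- **Primer geometry.** The allele-specific oligo's 3′-terminal base sits
  on the assayed SNP; the universal primer starts on the opposite flank
  with its 3′ end proximal; both default to 25 nt and are overridable.
  Offsets count from the 3′ end with the terminal base as position 1
  (equivalently: distance from the assayed SNP).  Bins: I ≤5, II 6–10,
  III 11–15, IV ≥16 bp, Null = none.
- **Codominance prediction** looks up the shipped empirical
  (n_aso × n_uni) grid; hard rules (0,0)→dominant, ≥4 in either
  primer→codominant; an empty cell falls back to the mean of the row and
  column marginal proportions.  The raw cell percentages are not monotone
  (sparse cells); the marginals are, and the prediction is only claimed
  monotone along them.
- **CAPS cuts** are reported at recognition-site starts (the shipped
  enzyme table carries recognition sites, not cut offsets); fragment
  lengths are therefore nominal and the *differential* pattern, which is
  what a gel shows, is exact.
- **Densities** round half-away-from-zero to integers, matching how such
  per-chromosome tables are conventionally printed.

## The simulator

`simulate_tetraploid` emulates: a D-like reference (GC 0.35 by default),
an A subgenome derived by i.i.d. substitutions (default rate 0.01 ≈ the
high end of homeolog divergence), varieties carrying subgenome-confined
substitutions at rate 5×10⁻⁴ placed in a random nonempty proper subset of
varieties (A vs D 50:50 — the true split is unknown, so unbiased),
homeolog expression bias per variety, 90-bp paired-end RNA-seq reads on
200-bp fragments (a standard short-insert library), and EcoRI RAD reads
(barcode + AATTC remnant + genomic sequence, 78-bp tags, Poisson depth).
Substitution-only divergence keeps one coordinate system, so reads carry
their true alignments and no external aligner is needed anywhere in the
tests.

What it does **not** model — and hence what passing tests do not show
about real data: indels and structural variation (real homeologs differ by
micro-indels; an aligner must absorb them), transcript structure and
splicing (reads are sampled from genomic sequence; spliced N-CIGARs are
exercised by dedicated fixtures only), position- and quality-dependent
error profiles, PCR duplicates, paralogous gene families (the main cause
of anchor-pruning work in real data), and reference bias in alignment.
Precision/recall on simulation is therefore an upper bound on real-data
performance of the *logic*, not of an end-to-end pipeline including
alignment.

## Problem sizes and numerics

The recovery analyses use a 200-kb chromosome, 4 varieties at 40×
(RNA-seq) and 300 planted EcoRI loci, 2 varieties at mean tag depth 12
(RAD) — large enough that binomial/Poisson fluctuations put hundreds of
anchors and ~100 varietal truth sites in play, small enough to run in
seconds on one CPU.  Oracle-equivalence checks use 1,000 micro-regions
(≤5 polymorphic sites, ≤40 reads) against an exhaustive classifier and
500 random amplicons against a brute-force double-strand scanner.  All
randomness flows through `numpy` generators seeded explicitly; identical
seeds give byte-identical outputs, and caller output is invariant to read
input order (reads are sorted internally; merging is order-free).

## Known limitations

- Recall decays for varietal SNPs whose only anchor lies near the
  `anchor_distance` limit: few fragments co-cover both sites, and the
  ≥2-per-phase rule then fails in some variety.  This is the price of the
  refuse-don't-guess contract.
- Strong homeolog expression bias suppresses anchors themselves (the rare
  phase drops below `min_within_freq`), so whole regions degrade to
  equivocal: precision is preserved, recall is not.
- The RAD caller requires the strict 4-tag pattern; site loss, repeats and
  uneven digestion all shrink the callable locus set rather than produce
  calls.
- Multi-allelic sites (≥3 observed alleles) are discarded everywhere.
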