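# homeosnp

Subgenome-anchored varietal SNP discovery for allotetraploid genomes.

## The problem

Allotetraploids such as Upland cotton (*Gossypium hirsutum*) carry two
subgenomes (A_t and D_t) whose homeologous genes are often >95% identical.
When short reads from several varieties are aligned to a single diploid
progenitor reference (the *G. raimondii* D₅ genome plays this role in
cotton), reads from both homeologs co-align, and two very different kinds
of polymorphism look alike in a pileup:

- **subgenome-specific SNPs** — fixed A_t/D_t differences, present in every
  variety, useless as markers between varieties;
- **varietal (allelic, "hemi-") SNPs** — differences *within one subgenome*
  between varieties, the class breeders actually want, occurring at least an
  order of magnitude more rarely (≲0.01–0.04% per bp in cotton cultivars).

The trap: if variety 1 shows A/G at a site and variety 2 shows only G, that
may be a real varietal SNP — or variety 2's other homeolog was simply never
sampled, because homeolog expression is biased or coverage was shallow.
Calling such sites naively produces a flood of false positives.

## The method

A varietal SNP is accepted **only when it can be phased to a flanking
subgenome-specific SNP** on the same sequenced molecules:

1. Find read-dense regions with a sliding window (100 bp, step 50) in which
   every variety has enough mean coverage (default ≥8×).
2. Classify **anchors**: sites where *every* well-covered variety shows the
   same two alleles, both well supported (≥2 reads, ≥20% within-variety
   frequency).  Candidate anchors whose pairwise joint-haplotype tables are
   inconsistent (>2 well-supported haplotypes in some variety) are pruned,
   worst offender first, to a conflict-free set.
3. For each remaining biallelic site, partition each variety's fragments
   (read pairs) by the allele they carry at a nearby anchor (≤90 bp).  The
   two phases are the two subgenomes.  A **VARIETAL** call requires, for
   some anchor: both phases present with ≥2 fragments in every compared
   variety, a clean per-phase consensus (purity ≥0.9), and *exactly one*
   phase splitting the varieties into two allele groups while the other
   phase is uniform.  Between-variety differences with no qualifying anchor
   are refused (**EQUIVOCAL**) rather than guessed.

The same anchor logic drives the RAD-seq caller: raw reads are
demultiplexed by inline barcode + EcoRI remnant (`AATTC`), trimmed to 78-bp
tags, collapsed, and depth-filtered (≥4 reads per tag).  At a reference
position where exactly two tags per variety align (the 4-tag pattern, one
tag per subgenome), a variety-concordant 2:2 column is a subgenome anchor
and a 1:3 column whose minority tag lies in a well-defined anchor phase is
a varietal SNP.

Marker utilities cover the downstream engineering: flank typing
(I: no other varietal SNP within 100 bp, II: within 21–100 bp, III: within
20 bp), primer-footprint profiling with 3′-distance bins (I ≤5 bp … IV ≥16
bp), empirical codominance prediction (in a tetraploid, an assay that
co-amplifies the homeolog is dominant; subgenome SNPs in primer footprints
restore codominance), CAPS differential-digest discovery, and SNP density
tracks (50-kb windows, 25-kb step).

A truth-annotated simulator generates the whole setting — D-like
reference, substitution-diverged A subgenome, varieties with
subgenome-confined varietal substitutions, biased homeolog expression,
90-bp paired-end RNA-seq reads and 78-bp EcoRI RAD tags — with exact truth
alignments, so every caller is tested against known ground truth without
downloads or an external aligner.

## Worked example

```python
import homeosnp as h

ds = h.simulate_tetraploid(length=20_000, n_varieties=3, seed=11)
reads, _ = h.simulate_rnaseq(ds.varieties, depth=40, seed=12)
calls, anchors, stats = h.call_transcriptome(
    reads, {ds.reference.name: len(ds.reference)})
print(stats)
```

prints

```
{'regions': 3, 'anchors': 210, 'VARIETAL': 10, 'EQUIVOCAL': 0, 'CONFLICT': 0}
```

The simulated 20-kb chromosome carries 209 subgenome-divergent sites and 10
varietal substitutions; the caller recovers all 10 varietal SNPs with no
false positives, anchored like:

```
Chr01_1110 G>T  anchors [1160, 1172]  {'v1': ('T', 'G'), 'v2': ('G', 'G'), 'v3': ('T', 'G')}
```

i.e. at position 1110 (1-based), varieties v1 and v3 carry a T in the
phase defined by the anchors at 1160/1172 while v2 carries the reference G
there, and all varieties agree (G) in the other phase — a varietal SNP
confined to one subgenome.  The same objects feed the marker tools:

```python
from homeosnp import classify_flank_type, predict_assay_behavior
positions = sorted(c.pos + 1 for c in calls if c.class_label == "VARIETAL")
classify_flank_type(positions[0], positions)   # FlankType(label='I', distance=1877)
predict_assay_behavior((0, 2))                 # ('codominant', 0.769...)
```

The command line mirrors this: `homeosnp simulate`, `call-rnaseq`,
`call-rad`, `classify`, `assay`, `caps`, `density` (see `homeosnp --help`);
every stochastic subcommand requires `--seed`, and all thresholds are
written into output VCF headers.

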