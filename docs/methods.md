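# Methods

This note documents the models behind `capxcise`, the parameters that
matter, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would want spelled out.

## Coordinate and geometry conventions

All public coordinates are 1-based inclusive; PAF records keep their
native 0-based half-open convention and are converted internally.  A
guide occupies a 23 bp site (20 nt protospacer + NGG PAM) on one strand;
protospacer positions are numbered 1..20 with 1 at the PAM-distal end,
and the seed region is positions 11–20 (PAM-proximal half).

Cas9 cleaves both strands 3 bp upstream of the PAM, leaving a blunt end.
For a site `[start, end]` the cut falls between `end−6` and `end−5` on a
forward guide, and between `start+5` and `start+6` on a reverse guide.
After cleavage the enzyme remains bound on the PAM-distal side; only the
PAM-proximal side presents a ligatable end.  `orientation()` reports
"toward" when that free side faces the region of interest — the rule
that makes guide layout determine read directionality.

The on-target window is implemented in two explicit bases because both
appear in practice and they disagree: `cut_span` is the inclusive
interval between the outermost predicted cuts (the excised DNA), and
`site_span` is the start-to-start distance of the innermost flanking
guide pair (the quoted locus length between the inner guides).  The
innermost pair is identified as the adjacent pair (by site start) across
the widest gap — with two guides per side this is exactly the inner
flanking pair.  Neither basis is silently preferred; callers choose.

## Specificity and SNP cleavage classes

Off-target search is an exhaustive, vectorised Hamming scan of the
protospacer against both strands, keeping sites with an adjacent NGG and
at most `max_mismatches` (≤6) mismatches.  A seed-and-extend shortcut
would give identical results at the genome sizes this toolkit targets,
so the provably exhaustive scan is used.

The specificity score aggregates hits as `100 · w(on) / Σ w(site)` with
`w = Π (1 − penalty[p])` over mismatched positions.  The 20-entry
per-position penalty table (package data, swappable) rises toward the
PAM: seed mismatches disrupt cleavage most, so a seed-mismatched site
retains little weight and barely dents the score.  The score is 100
exactly when the intended site is the only hit, and any secondary hit
strictly lowers it (all penalties are < 1).

SNP effects on cleavage are classified from the haplotype sequence at
the best-matching site (≤4 protospacer mismatches, PAM unconstrained):

| class | condition | efficiency multiplier |
|---|---|---|
| `full` | perfect protospacer, NGG intact | 1.0 |
| `reduced` (distal) | mismatches only at positions 1–10 | 0.5 |
| `reduced` (seed) | any mismatch at positions 11–20 | 0.1 |
| `none` | PAM no longer NGG | ε = 0.05 |

The multipliers are ordinal model choices, not measurements.  ε is
deliberately nonzero: a PAM-disrupted guide still digests naked
amplicons occasionally while contributing essentially no enriched
genomic reads — both behaviours are observed in this chemistry, and the
simulator reproduces them with one parameter.  Multipliers of exactly
0/1 are applied deterministically; anything in between is a seeded
per-molecule draw.

On-target *activity* scoring (as opposed to specificity) is exposed only
as a pluggable interface with a documented GC/position heuristic
default; published activity models need extended genomic context and a
trained regressor, and the default is not comparable with any published
score.

## Synthetic genomes

`make_genome` builds a diploid genome from a config: i.i.d.-nucleotide
backbone chromosomes at configured GC, a tandem repeat array inserted
into the target chromosome (per-haplotype copy number — the default
experiment is a 1-copy / 6-copy heterozygote), an optional paralog
(a copy of the target locus mutated position-wise to a configured
identity, placed on another chromosome or a non-overlapping position of
the same one), and planted SNPs in final haplotype coordinates.  Decoys
are shared verbatim between haplotypes.  Identical config + seed gives
byte-identical FASTA and truth JSON.

The repeat unit defaults to a random 23-mer drawn from the seed: the
unit length is a free parameter of the locus model (conveniently equal
to a guide site's length, which keeps the toolkit's arithmetic easy to
eyeball), and no claim is made about the real motif's sequence.  The
generator does not model transposable elements, methylation contexts,
organellar genomes, or repeat families beyond the one planted array —
passing tests demonstrate the *mechanics* (geometry, bookkeeping,
statistics, phasing) on a clean genome, not performance on real plant
DNA.

## Library and run simulation

The simulator is mechanistic and follows the bench protocol's order:
dephosphorylate pre-existing ends (cut ends introduced later keep their
phosphates), cut, dA-tail everything, ligate adapters to ends that are
phosphorylated ∧ dA-tailed ∧ ¬blocked.  Blocked (Cas9-bound) ends
receive adapters at a small leak rate (`blocked_end_leak = 0.05`),
modelling molecules whose Cas9 dissociated.

Read sources are sampled uniformly from a pool of adapter-bearing ends:

* **cut ends** — the target chromosome is digested as a population of
  `cut_end_molecules = 100` molecules per haplotype, each with
  independent cleavage draws, so a 0.5-multiplier guide cuts about half
  the pool rather than all-or-none;
* **background ends** — breaks scattered along each haplotype at
  `background_break_rate = 0.025` per bp (an *aggregate* density across
  the whole sequenced molecule population, not a per-molecule rate),
  each break yielding two ends that each escape dephosphorylation with
  probability `1 − 0.95`.

A read starts at its end and extends into the molecule on the implied
strand: background molecule lengths are log-normal (median 10 kb,
σ = 1.064, giving the characteristic long N50 tail), cut reads are
bounded by their fragment, and all reads are subject to a pore
truncation hazard of 0.005/kb and a 100 kb cap.  Per-read mean quality
is drawn from a named profile (two bundled profiles at median Q 9.11 and
Q 11.22, after the two common base callers); per-base qualities add
jitter.  Substitution/insertion/deletion rates default to
0.04/0.018/0.018 — totalling ≈7.6%, the error probability implied by the
default profile's median Phred.  Every read carries truth (haplotype,
interval, strand, source class) and the run emits truth alignments in
PAF convention; the toolkit does not re-align its own simulated reads
(aligning real data is an external aligner's job).

**Calibration.**  `dephosphorylation_efficiency`, `background_break_rate`,
`cut_end_molecules` and `blocked_end_leak` are *calibrated, not
measured*: no public measurements of ligation efficiency or residual
break density exist for this chemistry, so the defaults were chosen once
so that the bundled 7,000-read run sits in the documented enrichment
regime of a real targeted-excision MinION run — ≈3% of reads on-target
at >80× window depth, with a multi-kb median read length and a
median-vs-N50 gap.  Across seeds the simulated on-target percentage is
3.08 ± 0.23 (sd), whose spread is dominated by read-level binomial noise
at n = 7,000 plus Poisson variation of the background source pool.

## The bundled experiment

`calibrated_experiment(seed)` assembles the full study layout on a
synthetic 4 Mb haploid genome (1 Mb target chromosome + three 1 Mb
decoys, one carrying a 95%-identity paralog of the locus): an excision
panel of four guides (two per side, all oriented toward the ROI), then
two planted SNPs on both haplotypes — one destroying the PAM of the
inner upstream guide (class `none`), one in the distal protospacer of
the outer downstream guide (class `reduced`).  The guide panel is
designed on hapA; every guide is re-located per haplotype by best-match
search, so the 6-copy haplotype's shifted coordinates are handled
exactly.  The genome is generated twice with the same seed (design pass,
then SNP-planting pass), which is deterministic by construction.

## QC statistics

* N50 is the largest L such that reads of length ≥ L contain at least
  half of all bases.
* Per-read mean quality is the Phred of the arithmetic mean *error
  probability* (probability-space mean), and the pass partition is
  mean quality ≥ 7, inclusive.
* A read is on-target iff its best (primary) alignment — highest mapq,
  deterministic tie-break by first target coordinate — overlaps the
  window by ≥1 bp.  "On-target coverage" follows the read-count
  convention (forward + reverse on-target reads); mean per-base depth
  over the window is reported separately and labelled as such.
* Off-target regions merge adjacent 1 kb coverage bins (bin size is a
  default, not a published value) whose mean depth under the mapq ≥ 40
  filter reaches 25×, excluding the on-target window.  The threshold
  phrasing is interpreted as mapq ≥ 40 *and* depth ≥ 25×.

A scaled-down caveat: with 7,000 reads on a 4 Mb genome the background
depth is orders of magnitude higher than on a real several-hundred-Mb
genome, so the absolute 25× off-target threshold is not meaningful on
the bundled simulation (background alone can approach it).  Off-target
detection is therefore validated on constructed pileups with planted
truth, not on the calibrated run.

## Repeat counting and phasing

`count_repeat_units` anchors at the best approximate motif match in the
read (edlib, infix mode) and greedily extends the tandem run in both
directions with prefix alignments, each unit allowed
`floor(0.2 × unit_length)` edits (nanopore-scale error).  A unit whose
own edit distance exceeds the budget is still counted when the unit
after it matches in frame (single-unit re-anchoring, charged the full
budget); without this, one bad unit in the middle of an array would
split the run and systematically undercount.  Reads are unoriented, so
both the motif and its reverse complement are tried and the better call
kept.  Multiple arrays in one read would be resolved in favour of the
best-anchored one; the toolkit targets single-locus reads.

`phase_alleles` clusters the per-read integer estimates by greedy mode
extraction with a merge window of one copy: the unassigned value with
the largest support (ties toward the smaller copy number) becomes a
mode, and an adjacent value is absorbed only if its support is at most
half the mode's.  Counting noise thus collapses onto the allele it
blurs, while genuinely adjacent alleles of comparable support (a 2/3
heterozygote) survive as separate modes.  Alleles need `min_support = 5`
reads; zero-copy calls never cluster; all-zero input is "ambiguous".
The result is invariant under read order.  This read-level route
deliberately replaces assembly-based haplotype separation: the object of
interest is the allele set, not a contig.

## Degenerate inputs and tie-breaks

Ambiguity codes never match in any scan and candidate guides containing
them are dropped.  Two cuts at the same position are an error (the
fragment model cannot represent a zero-length piece).  Circular
templates are unsupported.  Equal-mapq alignments resolve to the first
by target coordinate; equal-support copy-number modes resolve to the
smaller copy number; panel candidates at equal distance resolve by
scan order (position, then strand).

## Problem sizes

The default test and acceptance workloads were sized for quick desk
runs: 4 Mb haploid genomes, 7,000 reads (the read count of the run the
regime is calibrated to), 100-molecule digest populations, and
phasing-property replicates of 20 simulations × 100 reads.  The full
test suite runs in well under a minute; the acceptance script in a few
seconds.

## Known limitations

No raw-signal or base-caller emulation; no chromatin or bulge-aware
off-target models; no Cas9 kinetics or partial nicks; no homopolymer
error inflation (off by default, no published parametrisation here); no
barcoded multiplexing.  The consensus-polishing artefact in which a
polisher can delete repeat units from a collapsed-haplotype contig is
out of scope — the read-level phasing route avoids the collapsed
consensus entirely.
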