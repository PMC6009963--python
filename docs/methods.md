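# Methods

This note documents the models, conventions, and numerical choices behind
isokit, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and the data model

All intervals are 0-based, half-open; GTF emission converts to 1-based
closed and parsing converts back. A `TranscriptModel` is a strand-aware
chain of sorted, disjoint exons on one contig; its intron chain (the gaps
between consecutive exons) is the identity of an isoform's splicing
structure. On the '+' strand an intron's donor is its genomic start and
its acceptor its genomic end; on the '−' strand the roles swap. Junctions
are keyed by (contig, intron start, intron end, strand).

## The mis-mapping test

**Model.** Sequencing errors are assumed independent and identically
distributed per base at a per-library rate *p* (observed range for
size-fractionated long-read libraries: roughly 0.0072–0.055). For an
alignment of length *L* with *K* observed errors (mismatches plus indel
bases, uniformly — the error rates that calibrate *p* mix both), *K* ~
Binomial(*L*, *p*) when the read is aligned to its true locus. An
alignment to a merely homologous locus adds locus divergence on top, so
large *K* is evidence of mis-mapping.

**Statistic.** `mismap_pvalue` returns the de Moivre–Laplace normal tail
1 − Φ((K − Lp)/√(Lp(1−p))). Note the √: dividing by the raw variance
Lp(1−p) would not produce a z-score and the tail-probability reading
would fail. No continuity correction is applied by default (it is exposed
as an option); the uncorrected tail has the property that K = Lp maps
exactly to 0.5.

**Accuracy of the approximation.** The sup-norm distance between this
tail and the exact binomial survival function is ≈ pmf(mode)/2 ≈ 0.2/σ
with σ = √(Lp(1−p)). It is therefore below 0.02 only when σ ≳ 10 (e.g.
L = 5000 at p = 0.055, σ = 16.1, gap 0.009), and grows to ≈ 0.12 at
L = 200, p = 0.0072 (σ = 1.2). The continuity-corrected variant roughly
halves the gap. Users needing calibrated tail probabilities for short
alignments at low error rates should use `scipy.stats.binom.sf` directly;
the *decision rule* below does not depend on the approximation.

**Decision rule.** `mismap_flag` flags an alignment as mis-mapped when
K > L(p + margin), margin 0.03 by default. The flag rate on correctly
mapped reads is the binomial tail beyond L(p+0.03) — about
1 − Φ(0.03·√(L/(p(1−p)))) — which is already negligible (≈ 10⁻²²) at
L = 2000, p = 0.02 and shrinks with L; mis-mappings whose effective
mismatch rate exceeds p + 0.06 are caught essentially always at such
lengths.

**Error-rate bookkeeping.** `evaluate_fpr_fnr` reports both orientations
of the 2×2 table, since "positive" is ambiguous here: with positive =
flagged, FPR is the flagged fraction of correct-locus alignments and FNR
the unflagged fraction of wrong-locus alignments; the acceptance-oriented
labels are the swap and are exposed as properties.

## Triage

Primers are matched by edit distance (edlib) inside a 100 bp terminal
window, allowing ⌈0.2 × primer length⌉ edits — enough to tolerate raw
long-read error rates while keeping random 24–30-mer matches negligible.
The polyA detector requires a ≥ 20 nt window immediately 5′ of the 3′
primer hit (or at the read end when the primer is absent) with at most
one non-A per 10 nt. Both read orientations are tried and the one with
more signals wins, ties going to forward. A primer hit outside both
terminal windows flags the read as a putative concatemer; the heuristic
is deliberately simple and errs toward specificity. The length filter is
strict (`> 300` bp kept). The instrument's "prediction accuracy" read
metadata is not modeled; it is a pass-through column.

## Fusion calling

The four criteria (≥ 2 loci; each ≥ 5% of the read; combined ≥ 85%;
same-contig loci ≥ 100 kbp apart) are applied per read; `audit_fusion`
reports which criterion failed, enabling post-hoc audits. "Distinct loci"
on one contig are defined purely by the 100 kbp rule — no annotation is
required. Boundary grouping uses a 50 bp tolerance (configurable); the
longest read represents a group, ties broken by smallest transcript id,
making grouping idempotent and order-invariant. For matching long-read
segments against paired short-read links, a locus is keyed as (contig,
10 kb bin of the segment midpoint); the bin width is configurable and
synthetic layouts place loci in distinct bins. Calls with > 2 segments
must satisfy the distance rule for every segment pair.

## Annotation comparison

The nine class codes are made mutually exclusive by a fixed priority —
structural match > novel isoform > contained-in-CDS > contains-gene >
gene-in-intron > intronic > same-strand partial > opposite-strand overlap
> novel locus — with strongest structural evidence winning across genes.
Two disambiguations make the codes genuinely disjoint: "contained in the
coding region" is evaluated against CDS-clipped *exons* (otherwise any
intronic transcript inside the genomic CDS span would be swallowed), and
"contains gene" excludes the case where the gene sits wholly inside one
intron of the query (that is gene-in-intron). "Same structure" means an
identical intron chain; terminal ends are free; single-exon transcripts
match at ≥ 50% reciprocal overlap (configurable).

Gene-level differences use the precedence span-multiple-loci > split >
gene-structure > sequence-span > UTR-only > identical, evaluated over
best-matching transcript pairs (most shared junctions). Identical chains
with different ends are UTR-only unless CDS annotation on both sides
disagrees; a chain that extends the other's chain only at the termini is
a sequence-span difference; anything else structural. These precedence
conventions are this package's own — upstream literature reports the
categories without defining a tie-break.

Transcript collapsing merges identical intron chains to the outermost
observed ends (FL iff any member is FL) and single-exon transcripts at
≥ 50% reciprocal overlap via a sorted sweep; the operation is idempotent.

## AS events

Events come from pairwise comparison of a locus's isoforms: IR when an
exon fully spans the other's intron; ES when an *internal* exon lies
wholly inside the other's intron; A5SS/A3SS when two introns share
exactly one boundary, typed relative to transcription direction (donor =
5′ side); OTHER when a transcript starts/ends strictly inside the other's
intron, plus a catch-all for structurally different pairs matching no
pattern (alternative terminal exons). One suppression rule keeps the
types disjoint: a shared-boundary intron pair whose differing stretch
contains a complete exon of the shorter-intron isoform is the junction
signature of exon skipping and is not additionally reported as
A5SS/A3SS. Events are deduplicated by (type, variable-region
coordinates) with participating isoforms accumulated, so per-event and
per-transcript tallies are both available.

Junction support is counted by exact junction key; "supported" means
≥ 5 reads in at least one sample, with a mean-over-samples mode also
provided. Event-level short-read validation requires ≥ 1 inclusion read,
≥ 1 exclusion read, and ≥ 10 total. Reference-transcript validation
applies only to IR (reference exon covers the retained intron) and ES
(reference intron covers the skipped exon); other types return
not-applicable. Junction canonicity (GT–AG / GC–AG) is emitted as a
column when a genome is supplied; no classifier-based junction filtering
is attempted.

## Downstream filters

Expression: a transcript is expressed in a tissue iff its assembled model
matches the reference intron chain and FPKM ≥ 0.01 (inclusive) in ≥ 2
replicates. Tissue-specific means expressed in exactly one tissue (a
stated convention). The lncRNA cascade takes candidates with longest
ORF ≤ 350 nt (ATG→stop, three forward frames, stop included — the
transcript-length reading of the candidacy rule was rejected because it
contradicts how short-ORF transcripts behave), removes coding-homology
hits, and calls strong at score < −1 (strict) and weak in [−1, 0); the
weak band is this package's convention, recorded in output metadata. The
homology filter keeps e-value strictly below the cutoff and bit-score at
least the given fraction of the query's best hit, optionally requiring
mutual best hits.

## The synthetic generator

The generator emulates the study conditions: random-GC genomes (default
GC 0.45), non-overlapping multi-exon genes on both strands with canonical
GT..AG dinucleotides written into the genome, per-base i.i.d. errors in
the 0.0072–0.055 library range with an indel:substitution mix of 2:1
(insertions and deletions equally likely — the raw error composition is
not published, so this PacBio-like default is a stated choice), FL
decoration with the template-switching primer pair and a 30 nt polyA,
and a non-FL class mix of 47% missing all signals, 21% missing 3′+polyA,
22% missing 5′, remainder uniform. Undecorated ends are truncated by a
uniform 5–30% of the transcript. Fusion reads join the 5′ 55% of one
isoform to the 3′ 45% of another; concatemers join two complete decorated
cDNAs.

Event planting assigns each requested event to a distinct intron/exon
(an OTHER event claims a terminal intron and shields the adjacent exon;
ES shields its flanking introns from IR; alternative splice-site shifts
avoid exons claimed by ES/OTHER, with a 12 nt default shift) so that the
planted event multiset round-trips exactly through the caller — slightly
stricter preconditions than each event needs in isolation, in exchange
for an exact oracle. Short-read junction counts are exact sums of the
depths of isoforms containing the junction (every fragment spans every
junction of its isoform): a deliberate idealization.

What the generator does **not** emulate: signal-level noise, quality
strings, polymerase-pass structure, expression-dependent coverage decay,
non-canonical splice sites, overlapping genes, paralogy (the genome is
random, so homologous decoy loci do not arise spontaneously — wrong-locus
alignments are modeled by elevated mismatch rates instead), and genome
mis-assembly. Passing tests therefore demonstrate correctness of the
rules and statistics on planted truth, not end-to-end performance on
real libraries.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small instances —
genomes of 2–4 contigs (0.3–2.5 Mb), 8–40 genes, 200–1500 long reads,
10⁴ binomial draws for rule calibration, 300–500 random fixtures for
oracle comparisons — chosen so the whole suite completes in well under a
minute while every check remains exact (planted-truth comparisons) or
statistically decisive (≥ 3 Monte-Carlo standard deviations). All
randomness flows through numpy `default_rng` seeds; generators are
bit-reproducible for a fixed seed.

## Known limitations

* The Gaussian tail is a poor approximation of the binomial survival
  function for σ = √(Lp(1−p)) ≲ 10 (see above); the exact binomial is one
  scipy call away when calibration matters.
* The concatemer heuristic cannot see concatemers whose junction lost
  both primers, and boundary grouping with a fixed tolerance can split
  one breakpoint cluster under extreme alignment jitter.
* Gene-difference categories depend on the stated precedence; other
  reasonable precedences yield different marginal counts.
* FPKM estimation, consensus polishing, spliced alignment itself, and
  coding-potential scoring are out of scope: the package consumes their
  outputs as tables.
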