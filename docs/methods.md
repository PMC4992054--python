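# Methods

This note documents the models, rules and numerical choices behind
`racekit`, and what its synthetic experiments do and do not demonstrate.

## Coordinate model

All internal coordinates are 0-based half-open; GTF I/O converts to/from
1-based inclusive at the file boundary and BED is read natively. Strand
is `+`, `-` or `.` (unstranded); unstranded features fail every
"same strand" test, so evidence of unknown orientation never supports a
stranded call. Gene loci are taken from the annotation's `gene_id`
grouping as given — no re-clustering happens on load; loci only merge in
`merge_loci`, when a new transcript overlaps two or more of them
exonically on the same strand.

## Target selection and primer design

RPKM is `1e9 · reads_in_exons / (exonic_length · total_mapped)` per
sample. A transcript is eligible when its maximum per-sample RPKM
strictly exceeds 5 and no same-strand CAGE tag lies within ±50 nt of its
annotated TSS; eligible transcripts are ranked by mean RPKM and the top
`n_targets` kept.

**Specificity masking.** Candidate spliced sequence is hard-masked
wherever it takes part in a sense-vs-sense local alignment of identity
> 0.80 over ≥ 50 aligned nt against any transcript of a *different*
locus. The search is k-mer-seeded (k = 11) ungapped X-drop extension
(+1 match / −2 mismatch, drop 20): for primer-sized decisions, ungapped
identity is an adequate and fully reproducible criterion, and the test
suite cross-checks it against an independent Smith–Waterman oracle.
Reverse-complement similarity never masks: a RACE primer can only
misprime on cDNA of its own sense. Masking is monotone — adding foreign
transcripts can only grow the masked set.

**Thermodynamics.** Oligo Tm is the SantaLucia unified nearest-neighbour
model (Biopython `Tm_NN`) at 50 mM monovalent cation and 200 nM oligo —
primer in excess, matching a PCR at the stated primer concentration. The
tests verify it against an independent hand summation of the published
NN parameters to 0.5 °C.

**Enumeration and pairing.** All 23–27-nt windows fully outside masked
segments with Tm ∈ [68, 72] °C and GC ∈ [50, 70] % are candidates,
scored by distance to the optima (25 nt, 70 °C, 60 % GC; weights 0.5/°C
·1/10 % GC·1). The outer primer is the best-scoring candidate whose
predicted product span — annealing site to the targeted annotated end —
falls within 300–3,000 nt, a window chosen for a platform whose reads
average ~600 bp; the nested primer is the candidate closest downstream
(toward the targeted end) of the outer footprint without overlapping it,
and may be absent. Directions are designed independently; primer
uniqueness across targets is not enforced.

## Read preprocessing

Order is fixed: adapters → quality → length.

* Adapter matching combines a full-adapter infix search (edit distance
  ≤ 0.1 × adapter length, via edlib) with partial terminal overlaps of
  ≥ 10 nt; internal occurrences are honoured only when flush with a read
  end or anchored within the terminal 60 % of the read, because a
  central hit in an amplicon read is more likely chimeric than a real
  adapter. Everything distal to an accepted occurrence is removed, with
  qualities trimmed in lockstep.
* Quality trimming removes 3′ bases one at a time while the mean phred
  of the last three bases is ≤ 20; reads shorter than the window are
  left untouched (the rule is defined on the last three nucleotides).
* Reads shorter than 100 nt are counted and dropped, never written.

The treatment is idempotent (verified by property test), and the output
always satisfies: length < 3 or mean(last 3) > 20.

## Alignment features

Only uniquely mapping reads are analysed: any secondary/supplementary
record, an `NH` tag > 1, or a primary mapping quality below the
configurable floor (default 0) removes the read entirely.

An alignment gap becomes an intron when it is > 20 nt *and* ≥ 30 nt and
is flanked by a canonical dinucleotide pair — GT–AG, GC–AG or AT–AC — on
either genome strand; other gaps are deletions. Junction identity is
(chrom, intron start, intron end, strand) with 0-based half-open intron
coordinates, and junction strand comes from the motif orientation, not
the read flag: amplicon libraries are unstranded at the read level (a 5′
product aligns antisense to its transcript).

Junction support entropy is the Shannon entropy (base 2) of the
distribution of distinct supporting-read alignment starts relative to
the donor. The published analysis used an external splice-analysis tool
with an entropy cutoff of 3; that tool's precise offset definition is
not public, so this package documents its own (read start vs donor) and
makes the threshold configurable. For RACE reads, which all start at
their primer, the boundary pipeline defaults the filter to 0 —
primer-anchored reads legitimately stack.

Top-quartile selection keeps ceil(n/4) junctions by read count with a
deterministic coordinate tie-break; set comparison is restricted to
junctions fully inside a target locus span ± 5 kb on the locus strand.

## Boundary annotation

**Direction assignment.** A post-RACE model is a 5′ product when it
extends its locus further 5′ or its 3′ end lies within 50 bp (inclusive,
distance to the nearest footprint base) of a 5′ primer on the opposite
strand; mirrored for 3′ products (same-strand 3′ primers, 5′ ends). Both
rules firing yields `both`, and such models enter both the TSS and TTS
analyses; models firing neither are flagged `unassigned` rather than
guessed.

**Read collapse.** Unique spliced reads sharing an identical intron
chain become one model spanning the widest member; single-exon reads
merge by overlap and stay unstranded until locus assignment, when they
inherit the strand of the locus they attach to (largest exonic overlap).
This automated intron-chain collapse stands in for expert manual
curation of alignments; it cannot distinguish isoforms that differ only
in their ends while sharing a chain — their termini fold into one model.

**Clustering and labels.** TSSs merge by single linkage when adjacent
sorted sites are < 51 bp apart; TTSs when < 151 bp apart (termination is
"leakier" than initiation). "<51" is read literally: a gap of exactly 50
merges, 51 splits; both sides are unit-tested. The cluster
representative is the 5′-most member on the transcription axis — the
conservative choice for extension calls. A cluster is novel when its
representative lies > 100 bp from every targeted annotated site of its
kind (vacuously novel when none exists), and supported when a same-
strand tag lies within ±50 bp (CAGE/TSS) or ±100 bp (polyA/TTS),
inclusive.

**PolyA inference.** A terminal soft clip yields a polyA site when it
carries a run of ≥ 21 bases that is ≥ 90 % A (right clip, + site at the
last aligned base) or ≥ 90 % T read boundary-outward (left clip, − site
at the first aligned base). The run must start within 2 nt of the clip
boundary — preventing internal A-rich clip sequence from being misread
as a tail — and must start and end on a matching base, so mismatches
interrupt but never pad a tail. Sites are deduplicated by exact
coordinate (no windowed merging), with read counts summed.

**Extension.** Signed lengths live on the transcription axis:
`(new − old)` on `+`, `(old − new)` on `-`; negative values are novel
TSSs upstream of the annotated extreme, positive values novel TTSs
downstream. Only 5′ products inform the 5′ end and 3′ products the 3′
end, because the opposite end of a product is anchored at its primer.

## Enrichment reporting

A read is on-target iff ≥ 1 aligned block overlaps ≥ 1 base of the
exonic union of a targeted locus (introns do not count). The enrichment
statistic is R/E with R and E unweighted means of per-tissue on-target
proportions — the most literal reading of a "proportion across tissues";
per-library weighting is available behind the config. A locus "produces
reads" at a configurable floor of 1 read. Percentages are rounded
half-up to integers and folds/means half-up to one decimal; these
conventions reproduce the published tables' derivable cells exactly.

## The synthetic experiment

The generator emulates the targeted amplification study end to end with
every stage's inputs and truths known:

* **Geometry.** 50 target and 100 decoy loci on one chromosome;
  transcripts of 4–6 exons of 180–400 nt separated by 80–600 nt introns;
  1–2 isoforms per locus, alternates differing by one skipped internal
  exon plus end shifts, so intron-chain collapse can resolve their
  termini. Exonic GC is 0.55 — GC-rich enough that every target admits a
  full outer+nested primer panel, as the real study achieved for all its
  targets. Canonical GT–AG motifs are planted at every intron boundary.
* **Truncation.** The "pre-RACE" annotation hides 15 % of each
  transcript's spliced length at both ends (minimum 20 nt, capped to
  keep a designable ≥ ~460-nt core), guaranteeing a nonzero extension
  truth at every locus end.
* **Reads.** Nested mode plants 36.4 % on-target reads, standard mode
  3.9 % — the specificity contrast the nested protocol produces. Each
  on-target read starts at its primer (nested when available) on a
  uniformly chosen isoform containing the primer footprint and runs
  toward the targeted end, reaching it with probability 0.5 (roughly the
  observed full-length rate); complete 3′ reads gain a non-templated
  A-tail of 15–45 nt (uniform — short enough that the >20 detection
  boundary is exercised on both sides) and the 3′ adapter; complete 5′
  reads gain the 5′ adapter. Background reads are random fragments of
  decoy transcripts in random orientation. Substitutions occur at 1 %
  per base; 30 % of reads have their last 5–20 bases degraded to phred
  2–12; 1 % of retained reads receive a fake secondary alignment to
  exercise the unique-mapping filter.
* **SAM and ledger.** The SAM holds the generator's own true placements
  of reads *as they would look after preprocessing* (adapter removed,
  expected quality trim applied, tail kept as a soft clip) — no external
  aligner runs, keeping tests hermetic. The ledger records, per read,
  origin, isoform, primer, aligned span, tail length and cleanliness,
  planted polyA coordinate, and an expected post-preprocessing length
  computed by an independent replay of the trimming rules (exact as
  stated for error-free adapters; the strict ledger-equality test
  therefore runs at error rate 0).
* **Evidence.** CAGE-like tags are planted near true TSSs and polyA-like
  tags near true TTSs with ≤ 10 nt jitter and 10 % dropout, each with an
  opposite-strand distractor so stranded support rules are exercised.

Identical seed and configuration give byte-identical outputs.

**What passing does not show.** The simulator draws uniform-composition
sequence (no repeats or paralogy beyond what masking tests construct
explicitly), models substitutions but not the homopolymer indels typical
of pyrosequencing, uses flat expression across targets, and emits
correctly placed alignments rather than running an aligner. Recovery
rates on it therefore validate the *rules* — thresholds, windows, signs,
bookkeeping — not robustness to alignment error or genomic repeat
structure on real data.

## Problem sizes

The reference simulated experiment is 50 target loci at 200 reads per
target (≈ 27,500 reads at nested specificity); the standard-primer
contrast library is capped at 20,000 reads. Unit and property tests use
4–10-locus fixtures. These sizes give binomial standard errors ≈ 0.3 %
on the on-target estimate and > 500 planted tails per run, ample for the
stated tolerances, while a full test-plus-acceptance cycle stays within
a couple of minutes on one CPU.

## Known limitations

* Biotype reclassification is reported as overlap only, never decided.
* The junction entropy definition is package-specific (see above).
* Tm is a nearest-neighbour model, not a primer3 re-implementation;
  hairpin/self-dimer screening is out of scope.
* Single-exon product models cannot be oriented without a locus; reads
  from unannotated single-exon transcription remain unstranded and are
  excluded from stranded boundary calls.
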