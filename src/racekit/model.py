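"""Core genomic data model shared by every analysis stage.

All internal coordinates are 0-based, half-open ``[start, end)``.  GTF I/O
converts to and from the 1-based inclusive convention at the file boundary;
BED is read natively.  A single internal convention keeps every windowed
rule in the boundary analyses (±50 nt CAGE windows, ±100 nt polyA windows,
±5 kb locus flanks, ...) free of off-by-one drift.

Strand is one of ``'+'``, ``'-'`` or ``'.'`` (unstranded).  Unstranded
features deliberately fail every "same strand" test: evidence of unknown
orientation never supports a stranded call.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ModelError(ValueError):
    """Raised when a genomic object violates its structural invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ModelError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position < self.end

    def distance_to(self, position: int) -> int:
        """Distance (0 if inside) from a point to the nearest base."""
        if position < self.start:
            return self.start - position
        if position >= self.end:
            return position - (self.end - 1)
        return 0


@dataclass(frozen=True)
class PointFeature:
    """Single-base evidence tag (CAGE 5' end, polyA-Seq site, ...)."""

    chrom: str
    position: int
    strand: str = "."
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ModelError("point feature position must be >= 0")
        if self.strand not in STRANDS:
            raise ModelError(f"invalid strand {self.strand!r}")


@dataclass
class TranscriptModel:
    """Stranded exon chain on one chromosome.

    Exons are sorted by start, non-overlapping and separated by at least
    one base; they all share the transcript's chromosome and strand.
    """

    transcript_id: str
    locus_id: str
    exons: list[GenomicInterval]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError(f"transcript {self.transcript_id} has no exons")
        ex = sorted(self.exons, key=lambda e: e.start)
        chrom, strand = ex[0].chrom, ex[0].strand
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end + 1:
                raise ModelError(
                    f"transcript {self.transcript_id}: exons overlap or abut "
                    f"({a.start}-{a.end} / {b.start}-{b.end})"
                )
        for e in ex:
            if e.chrom != chrom or e.strand != strand:
                raise ModelError(
                    f"transcript {self.transcript_id}: exons span multiple "
                    "chromosomes/strands"
                )
        self.exons = ex

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def tss_position(self) -> int:
        """First transcribed base (genomic coordinate)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def tts_position(self) -> int:
        """Last transcribed base (genomic coordinate)."""
        return self.end - 1 if self.strand != "-" else self.start

    def introns(self) -> list[GenomicInterval]:
        """Intron intervals (gaps between consecutive exons)."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Hashable (start, end) intron chain; empty for single-exon."""
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))

    # -- transcript <-> genome coordinate mapping -------------------------

    def to_genomic(self, t_lo: int, t_hi: int) -> list[GenomicInterval]:
        """Map a spliced-transcript interval ``[t_lo, t_hi)`` onto the genome.

        Transcript coordinates run 5'→3' along the transcript; the result
        is a list of genomic intervals in ascending genomic order.
        """
        if not (0 <= t_lo < t_hi <= self.spliced_length):
            raise ModelError(
                f"transcript interval [{t_lo},{t_hi}) outside "
                f"[0,{self.spliced_length})"
            )
        exons = self.exons if self.strand != "-" else list(reversed(self.exons))
        out: list[GenomicInterval] = []
        offset = 0
        for e in exons:
            lo = max(t_lo, offset)
            hi = min(t_hi, offset + e.length)
            if lo < hi:
                if self.strand != "-":
                    g_lo = e.start + (lo - offset)
                    g_hi = e.start + (hi - offset)
                else:
                    g_hi = e.end - (lo - offset)
                    g_lo = e.end - (hi - offset)
                out.append(GenomicInterval(self.chrom, g_lo, g_hi, self.strand))
            offset += e.length
        out.sort(key=lambda iv: iv.start)
        return out

    def genomic_to_transcript(self, position: int) -> int | None:
        """Spliced-transcript coordinate of a genomic base, or None if intronic."""
        exons = self.exons if self.strand != "-" else list(reversed(self.exons))
        offset = 0
        for e in exons:
            if e.start <= position < e.end:
                if self.strand != "-":
                    return offset + (position - e.start)
                return offset + (e.end - 1 - position)
            offset += e.length
        return None

    def contains_genomic_interval(self, iv: GenomicInterval) -> bool:
        """True when every base of ``iv`` is exonic in this transcript."""
        if iv.chrom != self.chrom:
            return False
        covered = 0
        for e in self.exons:
            lo, hi = max(e.start, iv.start), min(e.end, iv.end)
            if lo < hi:
                covered += hi - lo
        return covered == iv.length


@dataclass
class GeneLocus:
    """Gene-level grouping of transcript models on one chromosome/strand."""

    locus_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelError(f"locus {self.locus_id} has no transcripts")
        chrom, strand = self.transcripts[0].chrom, self.transcripts[0].strand
        for t in self.transcripts:
            if t.chrom != chrom or t.strand != strand:
                raise ModelError(
                    f"locus {self.locus_id}: transcripts on different "
                    "chromosomes/strands"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )

    @property
    def tss_extreme(self) -> int:
        """5'-most annotated TSS of the locus on the transcription axis."""
        positions = [t.tss_position for t in self.transcripts]
        return min(positions) if self.strand != "-" else max(positions)

    @property
    def tts_extreme(self) -> int:
        """3'-most annotated TTS of the locus on the transcription axis."""
        positions = [t.tts_position for t in self.transcripts]
        return max(positions) if self.strand != "-" else min(positions)


@dataclass
class ThresholdConfig:
    """Every numeric constant used by the analysis rules, in one place.

    The defaults encode the published workflow: primer specificity masking
    at >80% identity, the 100-nt read-length floor, mean-of-last-3 > Q20
    quality trimming, <51 / <151 bp TSS / TTS clustering, >100 bp novelty,
    ±50 / ±100 nt CAGE / polyA support windows, 50 bp primer proximity,
    >20 nt polyA tails with 10% mismatches, ±5 kb comparison flanks,
    offset-entropy 3 bits, >20 nt alignment gaps with a 30 nt intron floor,
    and RPKM > 5 target selection over a 398-locus panel.
    """

    mask_identity_min: float = 0.80
    read_min_len: int = 100
    qtrim_window: int = 3
    qtrim_mean_min: float = 20.0
    tss_cluster_gap: int = 51
    tts_cluster_gap: int = 151
    novelty_dist: int = 100
    cage_window: int = 50
    polya_window: int = 100
    primer_proximity: int = 50
    tail_min_len: int = 21
    tail_mismatch_frac: float = 0.10
    target_flank: int = 5000
    junction_entropy_min: float = 3.0
    gap_intron_min: int = 21
    intron_min_len: int = 30
    rpkm_min: float = 5.0
    n_targets: int = 398

    # implementation-level knobs (documented in docs/methods.md)
    mask_min_align_len: int = 50
    mask_seed_k: int = 11
    primer_len_min: int = 23
    primer_len_max: int = 27
    primer_len_opt: int = 25
    primer_tm_min: float = 68.0
    primer_tm_max: float = 72.0
    primer_tm_opt: float = 70.0
    primer_gc_min: float = 0.50
    primer_gc_max: float = 0.70
    primer_gc_opt: float = 0.60
    product_span_min: int = 300
    product_span_max: int = 3000
    adapter_min_overlap: int = 10
    adapter_max_err_frac: float = 0.10
    mapq_min: int = 0
    tail_anchor_slop: int = 2
    min_reads_detected: int = 1

    def __post_init__(self) -> None:
        for name in ("mask_identity_min", "tail_mismatch_frac",
                     "adapter_max_err_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ModelError(f"{name} must be in (0,1), got {v}")
        for name, v in vars(self).items():
            if isinstance(v, (int, float)) and v < 0:
                raise ModelError(f"{name} must be non-negative, got {v}")


DEFAULT_CONFIG = ThresholdConfig()


# -- operations ----------------------------------------------------------


def transcript_tss(t: TranscriptModel) -> PointFeature:
    """First transcribed base of a transcript as a point feature."""
    return PointFeature(t.chrom, t.tss_position, t.strand, "TSS")


def transcript_tts(t: TranscriptModel) -> PointFeature:
    """Last transcribed base of a transcript as a point feature."""
    return PointFeature(t.chrom, t.tts_position, t.strand, "TTS")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/abutting intervals into sorted disjoint ones.

    Chromosome and strand are taken from the inputs, which must agree.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(iv)
    return out


def exonic_union(locus: GeneLocus) -> tuple[list[GenomicInterval], int]:
    """Merged disjoint exonic intervals of a locus and their total length.

    Shared exons are counted once; this is the denominator substrate for
    exonic-overlap rules (on-target read classification, locus merging).
    """
    merged = merge_intervals(e for t in locus.transcripts for e in t.exons)
    return merged, sum(iv.length for iv in merged)


def spliced_sequence(t: TranscriptModel, genome) -> str:
    """Spliced sense-strand sequence of a transcript.

    ``genome`` is any mapping from chromosome name to sliceable sequence
    (a ``pyfaidx.Fasta`` or a plain dict of strings).
    """
    parts = []
    for e in t.exons:
        seg = genome[t.chrom][e.start:e.end]
        parts.append(str(seg).upper())
    seq = "".join(parts)
    return revcomp(seq) if t.strand == "-" else seq


def median_spliced_length(loci: Sequence[GeneLocus]) -> float:
    lengths = [t.spliced_length for l in loci for t in l.transcripts]
    return statistics.median(lengths) if lengths else float("nan")


def iter_transcripts(loci: Iterable[GeneLocus]) -> Iterator[TranscriptModel]:
    for locus in loci:
        yield from locus.transcripts
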