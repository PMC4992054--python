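"""Splice-junction extraction and statistics from spliced alignments.

Alignments come in as SAM/BAM (via :mod:`pysam`).  Reads with more than
one reported locus are removed entirely, then every inter-block alignment
gap longer than the configured minimum and flanked by a canonical splice
dinucleotide pair (on either strand) is called an intron.  Junction strand
is taken from the motif orientation, not the read flag, because RACE
amplicon reads are effectively unstranded at the alignment level.

Each pooled junction carries a read count and the Shannon entropy (bits)
of the distinct alignment start offsets of its supporting reads; a low
entropy marks PCR stacking artefacts, so junction sets can be filtered at
a minimum entropy before comparison.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import pysam

from .model import (
    DEFAULT_CONFIG,
    GeneLocus,
    GenomicInterval,
    ThresholdConfig,
    revcomp,
)

# donor/acceptor dinucleotide pairs as seen on the forward genome strand
_FWD_MOTIFS = {("GT", "AG"): "GT-AG", ("GC", "AG"): "GC-AG",
               ("AT", "AC"): "AT-AC"}
_REV_MOTIFS = {("CT", "AC"): "GT-AG", ("CT", "GC"): "GC-AG",
               ("GT", "AT"): "AT-AC"}

# CIGAR operations that consume the reference inside an alignment
_REF_GAP_OPS = {2, 3}        # D, N
_ALN_OPS = {0, 7, 8}         # M, =, X


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class SpliceJunction:
    """An intron: 0-based half-open genomic interval plus motif class."""

    chrom: str
    start: int   # first intronic base (donor side on '+')
    end: int     # exclusive intron end (acceptor side on '+')
    strand: str
    motif: str = "noncanonical"

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class JunctionRecord:
    """A pooled junction with its read support statistics."""

    junction: SpliceJunction
    read_count: int = 0
    offsets: Counter = field(default_factory=Counter)

    @property
    def offset_entropy(self) -> float:
        return offset_entropy(self.offsets)


def offset_entropy(offsets: Counter | Sequence[int]) -> float:
    """Shannon entropy (base 2) of a read start-offset distribution."""
    counts = (list(offsets.values()) if isinstance(offsets, Counter)
              else list(Counter(offsets).values()))
    total = sum(counts)
    if total == 0:
        raise AlignmentError("entropy of an empty offset set")
    return -sum((c / total) * math.log2(c / total) for c in counts)


def filter_unique(alignments: Iterable[pysam.AlignedSegment],
                  cfg: ThresholdConfig = DEFAULT_CONFIG
                  ) -> list[pysam.AlignedSegment]:
    """Keep only reads mapping to a single locus.

    A read is dropped entirely when any of its records is secondary or
    supplementary, when an ``NH`` tag reports more than one hit, or when
    its primary mapping quality is below ``mapq_min``.
    """
    records: dict[str, list[pysam.AlignedSegment]] = {}
    multi: set[str] = set()
    for a in alignments:
        if a.is_unmapped:
            continue
        name = a.query_name
        if a.is_secondary or a.is_supplementary:
            multi.add(name)
            continue
        try:
            if a.get_tag("NH") > 1:
                multi.add(name)
        except KeyError:
            pass
        records.setdefault(name, []).append(a)
    out = []
    for name, recs in records.items():
        if name in multi or len(recs) > 1:
            continue
        if recs[0].mapping_quality >= cfg.mapq_min:
            out.append(recs[0])
    return out


def aligned_blocks(a: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference-aligned segments separated by reference gaps (D/N)."""
    blocks: list[tuple[int, int]] = []
    pos = a.reference_start
    cur_start = None
    for op, length in a.cigartuples or ():
        if op in _ALN_OPS:
            if cur_start is None:
                cur_start = pos
            pos += length
        elif op in _REF_GAP_OPS:
            if cur_start is not None:
                blocks.append((cur_start, pos))
                cur_start = None
            pos += length
        # I, S, H, P do not consume reference
    if cur_start is not None:
        blocks.append((cur_start, pos))
    return blocks


def _motif_for_gap(genome, chrom: str, start: int, end: int
                   ) -> tuple[str, str] | None:
    donor = str(genome[chrom][start:start + 2]).upper()
    acceptor = str(genome[chrom][end - 2:end]).upper()
    fwd = _FWD_MOTIFS.get((donor, acceptor))
    if fwd:
        return fwd, "+"
    rev = _REV_MOTIFS.get((donor, acceptor))
    if rev:
        return rev, "-"
    return None


def infer_introns(a: pysam.AlignedSegment, genome,
                  cfg: ThresholdConfig = DEFAULT_CONFIG
                  ) -> list[SpliceJunction]:
    """Call introns from a read's alignment gaps.

    A gap becomes an intron when its size strictly exceeds
    ``gap_intron_min - 1`` (">20"), is at least ``intron_min_len``, and is
    flanked by a canonical dinucleotide pair on either strand; any other
    gap is treated as a deletion.  Gaps with non-canonical ends are
    likewise ignored rather than emitted, mirroring splice-consensus
    based intron prediction.
    """
    chrom = a.reference_name
    try:
        genome[chrom]
    except KeyError as exc:
        raise AlignmentError(f"chromosome {chrom!r} absent from genome") from exc
    blocks = aligned_blocks(a)
    out = []
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        gap = s2 - e1
        if gap < cfg.gap_intron_min or gap < cfg.intron_min_len:
            continue
        hit = _motif_for_gap(genome, chrom, e1, s2)
        if hit is None:
            continue
        motif, strand = hit
        out.append(SpliceJunction(chrom, e1, s2, strand, motif))
    return out


def extract_junction_set(alignments: Iterable[pysam.AlignedSegment], genome,
                         cfg: ThresholdConfig = DEFAULT_CONFIG,
                         entropy_min: float | None = None
                         ) -> dict[tuple, JunctionRecord]:
    """Pool junctions over unique-filtered reads and filter by entropy.

    ``entropy_min`` defaults to ``cfg.junction_entropy_min``; pass 0 to
    keep everything.  Offsets are read alignment starts relative to the
    junction donor.
    """
    if entropy_min is None:
        entropy_min = cfg.junction_entropy_min
    pool: dict[tuple, JunctionRecord] = {}
    for a in alignments:
        for j in infer_introns(a, genome, cfg):
            rec = pool.setdefault(j.key, JunctionRecord(j))
            rec.read_count += 1
            rec.offsets[a.reference_start - j.start] += 1
    return {
        key: rec for key, rec in pool.items()
        if rec.offset_entropy >= entropy_min
    }


def select_top_quartile(junctions: Sequence[JunctionRecord]
                        ) -> list[JunctionRecord]:
    """Top ceil(n/4) junctions ranked by read count, descending.

    Ties at the cut are broken deterministically by (chrom, start, end).
    """
    n = len(junctions)
    if n == 0:
        return []
    keep = math.ceil(n / 4)
    ranked = sorted(
        junctions,
        key=lambda r: (-r.read_count, r.junction.chrom, r.junction.start,
                       r.junction.end),
    )
    return ranked[:keep]


@dataclass
class JunctionComparison:
    only_a: int
    only_b: int
    shared: int

    @property
    def support_rate_a(self) -> float:
        """Fraction of A's junctions also seen by B."""
        total = self.only_a + self.shared
        return self.shared / total if total else float("nan")

    @property
    def support_rate_b(self) -> float:
        total = self.only_b + self.shared
        return self.shared / total if total else float("nan")


def _within_flanked_loci(j: SpliceJunction, loci: Sequence[GeneLocus],
                         flank: int) -> bool:
    for locus in loci:
        span = locus.span
        if (j.chrom == span.chrom and j.strand == span.strand
                and j.start >= span.start - flank
                and j.end <= span.end + flank):
            return True
    return False


def compare_junction_sets(set_a: Iterable[SpliceJunction],
                          set_b: Iterable[SpliceJunction],
                          target_loci: Sequence[GeneLocus],
                          flank: int | None = None,
                          cfg: ThresholdConfig = DEFAULT_CONFIG
                          ) -> JunctionComparison:
    """Venn counts of two junction sets inside flanked target loci.

    Only junctions lying fully inside some target locus span extended by
    ``flank`` on both sides (and on the locus strand) are compared.
    """
    flank = cfg.target_flank if flank is None else flank
    a = {j.key for j in set_a if _within_flanked_loci(j, target_loci, flank)}
    b = {j.key for j in set_b if _within_flanked_loci(j, target_loci, flank)}
    return JunctionComparison(len(a - b), len(b - a), len(a & b))


def write_junction_table(records: Iterable[JunctionRecord], fh: TextIO) -> None:
    fh.write("chrom\tstart\tend\tstrand\tmotif\tread_count\toffset_entropy\n")
    for r in sorted(records, key=lambda r: r.junction.key):
        j = r.junction
        fh.write(
            f"{j.chrom}\t{j.start}\t{j.end}\t{j.strand}\t{j.motif}"
            f"\t{r.read_count}\t{r.offset_entropy:.4f}\n"
        )
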