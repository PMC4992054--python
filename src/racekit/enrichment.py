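"""On-target accounting, enrichment folds and annotation summary tables.

A read is on-target when at least one aligned block overlaps at least one
base of the exonic union of a targeted locus.  The enrichment statistic is
R/E, where R is the proportion of mapped reads on-target in the targeted
experiment and E the proportion expected from untargeted sequencing; both
are unweighted means of per-tissue proportions when several libraries are
combined.

Percentages are rounded half-up to integers and folds/means half-up to
one decimal, matching the conventions of the published summary tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

from .junctions import aligned_blocks
from .model import (
    DEFAULT_CONFIG,
    GeneLocus,
    ThresholdConfig,
    exonic_union,
    median_spliced_length,
)


class ReportingError(ValueError):
    pass


def round_half_up(value: float | Decimal, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int | float, den: int | float) -> Decimal:
    if den == 0:
        raise ReportingError("division by zero in ratio")
    return Decimal(str(num)) / Decimal(str(den))


def ratio_1dp(num: int | float, den: int | float) -> float:
    """Exact quotient rounded half-up to one decimal."""
    return float(_ratio(num, den).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


def percent_int(num: int | float, den: int | float) -> int:
    """Exact percentage rounded half-up to an integer."""
    return int((_ratio(num, den) * 100).quantize(Decimal("1"),
                                                 rounding=ROUND_HALF_UP))


# -- on-target classification --------------------------------------------


@dataclass
class OnTargetResult:
    on_count: int
    off_count: int
    per_locus: Counter

    @property
    def total(self) -> int:
        return self.on_count + self.off_count

    @property
    def on_fraction(self) -> float:
        return self.on_count / self.total if self.total else float("nan")


def _exon_trees(loci: Sequence[GeneLocus]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for locus in loci:
        for iv in exonic_union(locus)[0]:
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, locus.locus_id
            )
    return trees


def classify_on_target(reads: Iterable[pysam.AlignedSegment],
                       targets: Sequence[GeneLocus]) -> OnTargetResult:
    """Count reads overlapping >= 1 exonic base of any targeted locus.

    Per-locus tallies count each read once per locus it touches.
    """
    trees = _exon_trees(targets)
    on = off = 0
    per_locus: Counter = Counter()
    for a in reads:
        if a.is_unmapped:
            continue
        tree = trees.get(a.reference_name)
        hit_loci: set[str] = set()
        if tree is not None:
            for s, e in aligned_blocks(a):
                for iv in tree.overlap(s, e):
                    hit_loci.add(iv.data)
        if hit_loci:
            on += 1
            for lid in hit_loci:
                per_locus[lid] += 1
        else:
            off += 1
    return OnTargetResult(on, off, per_locus)


def tally_by_locus(reads: Iterable[pysam.AlignedSegment],
                   loci: Sequence[GeneLocus]) -> Counter:
    """Per-locus read tallies over an arbitrary annotation."""
    return classify_on_target(reads, loci).per_locus


def enrichment_fold(R: float, E: float) -> float:
    """On-target enrichment R/E; undefined (NaN) when E is zero."""
    if not (0.0 <= R <= 1.0) or not (0.0 <= E <= 1.0):
        raise ReportingError("R and E must be proportions in [0,1]")
    if E == 0:
        return float("nan")
    return R / E


@dataclass
class EnrichmentSummary:
    """Observed vs expected on-target proportions and their ratio."""

    R: float
    E: float

    @property
    def enrichment(self) -> float:
        return enrichment_fold(self.R, self.E)

    @classmethod
    def from_tissues(cls, r_by_tissue: Mapping[str, float],
                     e_by_tissue: Mapping[str, float]) -> "EnrichmentSummary":
        """Unweighted mean of per-tissue on-target proportions."""
        if not r_by_tissue or not e_by_tissue:
            raise ReportingError("empty tissue proportion map")
        r = sum(r_by_tissue.values()) / len(r_by_tissue)
        e = sum(e_by_tissue.values()) / len(e_by_tissue)
        return cls(r, e)


def detect_amplified_targets(per_locus: Mapping[str, int],
                             target_ids: Iterable[str],
                             min_reads: int = DEFAULT_CONFIG.min_reads_detected
                             ) -> tuple[set[str], int]:
    """Targets with >= ``min_reads`` reads, and the count of non-targeted
    loci producing reads."""
    targets = set(target_ids)
    positive = {lid for lid in targets
                if per_locus.get(lid, 0) >= min_reads}
    off_loci = sum(1 for lid, n in per_locus.items()
                   if lid not in targets and n >= min_reads)
    return positive, off_loci


# -- annotation summary (Table 3 style) ----------------------------------


@dataclass
class AnnotationSummary:
    n_loci: int
    n_transcripts: int
    n_exons_all: int
    n_exons_unique: int
    n_unique_junctions: int
    median_transcript_length: float
    n_exons_novel_unique: int | None = None

    @property
    def transcripts_per_locus(self) -> float:
        return ratio_1dp(self.n_transcripts, self.n_loci)

    @property
    def exons_per_transcript(self) -> float:
        return ratio_1dp(self.n_exons_all, self.n_transcripts)


def annotation_summary(loci: Sequence[GeneLocus],
                       reference_exons: set[tuple] | None = None
                       ) -> AnnotationSummary:
    """Locus/transcript/exon/junction counts of an annotation set.

    Unique exons are keyed by (chrom, start, end, strand); when a
    reference exon set is given, unique exons absent from it are counted
    as novel.  The median transcript length is over spliced lengths.
    """
    transcripts = [t for l in loci for t in l.transcripts]
    exon_keys = [
        (e.chrom, e.start, e.end, e.strand)
        for t in transcripts for e in t.exons
    ]
    unique_exons = set(exon_keys)
    junction_keys = {
        (t.chrom, s, e, t.strand)
        for t in transcripts for (s, e) in t.intron_chain()
    }
    novel = (len(unique_exons - reference_exons)
             if reference_exons is not None else None)
    return AnnotationSummary(
        n_loci=len(loci),
        n_transcripts=len(transcripts),
        n_exons_all=len(exon_keys),
        n_exons_unique=len(unique_exons),
        n_unique_junctions=len(junction_keys),
        median_transcript_length=median_spliced_length(loci),
        n_exons_novel_unique=novel,
    )


def exon_key_set(loci: Sequence[GeneLocus]) -> set[tuple]:
    return {
        (e.chrom, e.start, e.end, e.strand)
        for l in loci for t in l.transcripts for e in t.exons
    }


# -- support tables and prose ratios -------------------------------------


@dataclass
class SupportRow:
    set_label: str
    total_sites: int
    supported_count: int

    @property
    def supported_pct(self) -> int:
        return percent_int(self.supported_count, self.total_sites)


def support_rate_table(rows: Iterable[tuple[str, int, int]]
                       ) -> list[SupportRow]:
    """Rows of (label, total, supported) -> rows with integer percent."""
    out = []
    for label, total, supported in rows:
        if supported > total:
            raise ReportingError(
                f"{label}: supported ({supported}) exceeds total ({total})"
            )
        out.append(SupportRow(label, total, supported))
    return out


def ratio_stats(a: float, b: float, mode: str) -> float:
    """Prose-style ratios: ``fold_1dp`` = a/b to one decimal;
    ``pct_excess``/``pct_increase`` = 100*(a-b)/b rounded to an integer."""
    if b == 0:
        raise ReportingError("ratio_stats with zero denominator")
    if mode == "fold_1dp":
        return ratio_1dp(a, b)
    if mode in ("pct_excess", "pct_increase"):
        return percent_int(a - b, b)
    raise ReportingError(f"unknown mode {mode!r}")
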