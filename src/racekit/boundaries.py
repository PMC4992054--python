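"""Transcript-boundary characterization from RACE products.

This module carries the analysis at the heart of the workflow: each
post-RACE transcript model is assigned its most probable originating RACE
direction (a 5' product is anchored at its primer on the 3' side, so only
its 5' end is informative, and vice versa); TSSs of 5' products and TTSs
of 3' products are clustered on the genome (<51 bp single linkage for
TSSs, <151 bp for TTSs -- termination being 'leakier' than initiation);
clusters are called novel when farther than 100 bp from any targeted
annotated site of the same kind, and supported when a same-strand CAGE
(+-50 bp) or polyA-Seq (+-100 bp) tag lies nearby.  PolyA sites are also
inferred directly from 3' RACE reads via non-templated A/T tails in their
terminal soft clips, and locus 5'/3' extensions are measured as signed
genomic lengths on the transcription axis (negative = novel TSS upstream,
positive = novel TTS downstream).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .junctions import aligned_blocks, infer_introns
from .model import (
    DEFAULT_CONFIG,
    GeneLocus,
    GenomicInterval,
    ModelError,
    PointFeature,
    ThresholdConfig,
    TranscriptModel,
    exonic_union,
    merge_intervals,
)


@dataclass(frozen=True)
class RacePrimerSite:
    """Genomic annealing footprint of a RACE primer.

    ``strand`` is the strand of the oligo as placed on the genome; for a
    5' RACE primer this is the strand opposite its target transcript.
    The footprint may be split across exons; ``intervals`` are the exonic
    pieces in genomic order.
    """

    primer_id: str
    chrom: str
    intervals: tuple[GenomicInterval, ...]
    strand: str
    direction: str  # 5prime | 3prime

    def distance_to(self, position: int) -> int:
        return min(iv.distance_to(position) for iv in self.intervals)


@dataclass
class DirectionCall:
    transcript_id: str
    call: str  # five_prime_product | three_prime_product | both | unassigned
    by_extension: tuple[bool, bool] = (False, False)
    by_primer: tuple[bool, bool] = (False, False)


@dataclass
class SiteCluster:
    """A merged set of transcript end positions of one kind."""

    site_type: str  # TSS | TTS
    chrom: str
    strand: str
    members: list[int]
    representative: int
    novel: bool = False
    supported: bool = False


@dataclass(frozen=True)
class PolyASite:
    chrom: str
    position: int
    strand: str
    tail_length: int
    supporting_reads: int = 1


@dataclass
class ExtensionRecord:
    """Signed extension of one locus end.

    ``signed_length`` is measured on the transcription axis: negative
    values are novel TSSs upstream of the annotated locus, positive
    values novel TTSs downstream of it.
    """

    locus_id: str
    end: str  # five_prime | three_prime
    signed_length: int
    extending: bool


# -- RACE direction assignment -------------------------------------------


def assign_race_direction(t: TranscriptModel, pre_locus: GeneLocus,
                          primers: Sequence[RacePrimerSite],
                          cfg: ThresholdConfig = DEFAULT_CONFIG
                          ) -> DirectionCall:
    """Label a post-RACE transcript as a 5' and/or 3' RACE product.

    5' rule: the transcript extends the annotated locus further 5', or
    its 3' end lies within ``primer_proximity`` of a 5' RACE primer
    footprint on the opposite strand.  The 3' rule is the mirror image
    with same-strand 3' primers.  Both rules firing yields ``both``.
    """
    if t.chrom != pre_locus.chrom or t.strand != pre_locus.strand:
        raise ModelError(
            f"transcript {t.transcript_id} and locus {pre_locus.locus_id} "
            "on different chromosome/strand"
        )
    sign = 1 if t.strand != "-" else -1
    ext5 = sign * (t.tss_position - pre_locus.tss_extreme) < 0
    ext3 = sign * (t.tts_position - pre_locus.tts_extreme) > 0

    prox5 = prox3 = False
    for p in primers:
        if p.chrom != t.chrom:
            continue
        if (p.direction == "5prime" and p.strand != t.strand
                and p.distance_to(t.tts_position) <= cfg.primer_proximity):
            prox5 = True
        if (p.direction == "3prime" and p.strand == t.strand
                and p.distance_to(t.tss_position) <= cfg.primer_proximity):
            prox3 = True

    five = ext5 or prox5
    three = ext3 or prox3
    call = ("both" if five and three
            else "five_prime_product" if five
            else "three_prime_product" if three
            else "unassigned")
    return DirectionCall(t.transcript_id, call, (ext5, ext3), (prox5, prox3))


# -- site clustering and labelling ---------------------------------------


def cluster_sites(positions: Sequence[int], site_type: str, chrom: str,
                  strand: str, cfg: ThresholdConfig = DEFAULT_CONFIG
                  ) -> list[SiteCluster]:
    """Single-linkage clustering of end positions on one chrom/strand.

    Adjacent sorted positions closer than the type's clustering gap
    (<51 bp for TSS, <151 bp for TTS) join one cluster.  The cluster
    representative is the 5'-most member with respect to the strand.
    """
    if site_type not in ("TSS", "TTS"):
        raise ValueError(f"bad site_type {site_type!r}")
    gap = cfg.tss_cluster_gap if site_type == "TSS" else cfg.tts_cluster_gap
    if not positions:
        return []
    srt = sorted(positions)
    groups: list[list[int]] = [[srt[0]]]
    for pos in srt[1:]:
        if pos - groups[-1][-1] < gap:
            groups[-1].append(pos)
        else:
            groups.append([pos])
    out = []
    for members in groups:
        rep = members[0] if strand != "-" else members[-1]
        out.append(SiteCluster(site_type, chrom, strand, members, rep))
    return out


def classify_tss_novelty(cluster: SiteCluster,
                         annotated_positions: Sequence[int],
                         cfg: ThresholdConfig = DEFAULT_CONFIG) -> bool:
    """Novel iff the representative lies farther than ``novelty_dist``
    from every annotated site on the same chrom/strand (vacuously novel
    when there are none)."""
    return all(abs(cluster.representative - p) > cfg.novelty_dist
               for p in annotated_positions)


def tag_support(cluster: SiteCluster, tags: Sequence[PointFeature],
                window: int, same_strand: bool = True) -> bool:
    """Supported iff a tag lies within ``window`` of the representative
    (inclusive on either side), matching strand when required.

    Unstranded tags never satisfy a same-strand requirement.
    """
    for tag in tags:
        if tag.chrom != cluster.chrom:
            continue
        if same_strand and tag.strand != cluster.strand:
            continue
        if abs(tag.position - cluster.representative) <= window:
            return True
    return False


# -- polyA tail inference ------------------------------------------------


def find_tail(clip: str, base: str,
              cfg: ThresholdConfig = DEFAULT_CONFIG) -> int | None:
    """Length of a non-templated tail at the start of a clip, or None.

    The tail must begin within ``tail_anchor_slop`` nt of the clip
    boundary (``clip`` is oriented boundary-outward), reach at least
    ``tail_min_len`` bases and contain at most ``tail_mismatch_frac``
    non-``base`` characters over its span.  The stretch must start and
    end on a matching base (mismatches are interruptions, not padding);
    the longest qualifying stretch is reported.
    """
    clip = clip.upper()
    best = None
    for skip in range(0, cfg.tail_anchor_slop + 1):
        if skip >= len(clip) or clip[skip] != base:
            continue
        mismatches = 0
        for length in range(1, len(clip) - skip + 1):
            if clip[skip + length - 1] != base:
                mismatches += 1
                continue
            if (length >= cfg.tail_min_len
                    and mismatches / length <= cfg.tail_mismatch_frac):
                if best is None or length > best:
                    best = length
    return best


def soft_clips(a: pysam.AlignedSegment) -> tuple[str, str]:
    """(left, right) soft-clipped sequences of an aligned read."""
    seq = a.query_sequence or ""
    cig = a.cigartuples or []
    left = seq[: cig[0][1]] if cig and cig[0][0] == 4 else ""
    right = seq[len(seq) - cig[-1][1]:] if cig and cig[-1][0] == 4 else ""
    return left, right


def infer_polya_sites(reads: Iterable[pysam.AlignedSegment],
                      cfg: ThresholdConfig = DEFAULT_CONFIG
                      ) -> list[PolyASite]:
    """Map polyA sites from non-templated tails in terminal soft clips.

    An A-tail in the right clip of an alignment yields a site on the
    ``+`` strand at the last aligned base; a T-head in the left clip
    (read antisense to the transcript on the genome) yields a site on
    the ``-`` strand at the first aligned base.  Sites sharing
    (chrom, position, strand) are merged with read counts summed and the
    longest tail retained.
    """
    found: dict[tuple[str, int, str], list[int]] = defaultdict(list)
    for a in reads:
        if a.is_unmapped:
            continue
        left, right = soft_clips(a)
        if right:
            tail = find_tail(right, "A", cfg)
            if tail:
                found[(a.reference_name, a.reference_end - 1, "+")].append(tail)
        if left:
            # the tail abuts the alignment start; read it boundary-outward
            tail = find_tail(left[::-1], "T", cfg)
            if tail:
                found[(a.reference_name, a.reference_start, "-")].append(tail)
    return [
        PolyASite(chrom, pos, strand, max(tails), len(tails))
        for (chrom, pos, strand), tails in sorted(found.items())
    ]


# -- locus extension and merging -----------------------------------------


def axis_delta(strand: str, new_pos: int, old_pos: int) -> int:
    """Signed offset of ``new_pos`` from ``old_pos`` on the transcription
    axis (negative = upstream / 5'-ward)."""
    return (new_pos - old_pos) if strand != "-" else (old_pos - new_pos)


def label_locus_extension(pre_locus: GeneLocus,
                          post_transcripts: Sequence[TranscriptModel],
                          calls: Mapping[str, DirectionCall],
                          cfg: ThresholdConfig = DEFAULT_CONFIG
                          ) -> list[ExtensionRecord]:
    """Signed 5'/3' extension of a locus by its RACE product models.

    Only 5' RACE products inform the 5' end and 3' products the 3' end
    (the opposite end of a product is anchored at its primer).  The most
    extreme qualifying new end defines each record's signed length.
    """
    for t in post_transcripts:
        if t.chrom != pre_locus.chrom or t.strand != pre_locus.strand:
            raise ModelError(
                f"transcript {t.transcript_id} not on locus "
                f"{pre_locus.locus_id} chromosome/strand"
            )
    out = []
    five_products = [
        t for t in post_transcripts
        if calls[t.transcript_id].call in ("five_prime_product", "both")
    ]
    three_products = [
        t for t in post_transcripts
        if calls[t.transcript_id].call in ("three_prime_product", "both")
    ]
    if five_products:
        deltas = [axis_delta(pre_locus.strand, t.tss_position,
                             pre_locus.tss_extreme) for t in five_products]
        d = min(deltas)
        out.append(ExtensionRecord(pre_locus.locus_id, "five_prime", d, d < 0))
    if three_products:
        deltas = [axis_delta(pre_locus.strand, t.tts_position,
                             pre_locus.tts_extreme) for t in three_products]
        d = max(deltas)
        out.append(ExtensionRecord(pre_locus.locus_id, "three_prime", d, d > 0))
    return out


def merge_loci(annotation: Sequence[GeneLocus],
               new_transcripts: Sequence[TranscriptModel]
               ) -> tuple[list[GeneLocus], list[tuple[tuple[str, ...], str]]]:
    """Union loci bridged by new transcripts with exonic overlap to >= 2.

    Overlap must be exonic and same-strand.  Bridging is transitive: a
    chain of new transcripts can collapse several loci into one.  Returns
    the updated annotation (original transcripts plus the new ones, which
    join their overlapping locus or found singleton novel loci) and a log
    of (old locus ids, merged id) entries.
    """
    unions = {l.locus_id: exonic_union(l)[0] for l in annotation}
    parent: dict[str, str] = {l.locus_id: l.locus_id for l in annotation}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def link(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    def overlapping_loci(t: TranscriptModel) -> list[str]:
        hits = []
        for locus in annotation:
            if locus.chrom != t.chrom or locus.strand != t.strand:
                continue
            ivs = unions[locus.locus_id]
            if any(e.start < iv.end and iv.start < e.end
                   for e in t.exons for iv in ivs):
                hits.append(locus.locus_id)
        return hits

    attachment: dict[str, list[str]] = {}
    for t in new_transcripts:
        hits = overlapping_loci(t)
        attachment[t.transcript_id] = hits
        for a, b in zip(hits, hits[1:]):
            link(a, b)

    groups: dict[str, list[GeneLocus]] = defaultdict(list)
    for locus in annotation:
        groups[find(locus.locus_id)].append(locus)

    log: list[tuple[tuple[str, ...], str]] = []
    merged: dict[str, GeneLocus] = {}
    for root, members in groups.items():
        ids = tuple(sorted(l.locus_id for l in members))
        new_id = root if len(members) == 1 else "+".join(ids)
        transcripts = [t for l in members for t in l.transcripts]
        merged_locus = GeneLocus(new_id, transcripts)
        for l in members:
            merged[l.locus_id] = merged_locus
        if len(members) > 1:
            log.append((ids, new_id))

    novel_count = 0
    for t in new_transcripts:
        hits = attachment[t.transcript_id]
        if hits:
            merged[hits[0]].transcripts.append(t)
        else:
            novel_count += 1
            out_id = f"NOVEL{novel_count:04d}"
            merged[out_id] = GeneLocus(out_id, [t])

    seen: set[int] = set()
    out = []
    for locus in merged.values():
        if id(locus) not in seen:
            seen.add(id(locus))
            out.append(locus)
    out.sort(key=lambda l: l.locus_id)
    return out, log


# -- read-to-model collapse ----------------------------------------------


def collapse_reads_to_models(reads: Sequence[pysam.AlignedSegment],
                             genome=None,
                             cfg: ThresholdConfig = DEFAULT_CONFIG,
                             id_prefix: str = "RM") -> list[TranscriptModel]:
    """Collapse unique-filtered spliced reads into transcript models.

    Reads sharing an identical intron chain (chromosome, strand and exact
    intron coordinates) become one model whose span is the widest of the
    group; single-exon reads are merged by overlap instead.  Amplicon
    libraries are unstranded at the read level (a 5' RACE product aligns
    antisense to its transcript), so when a genome is supplied the model
    strand is taken from the splice motif orientation and single-exon
    models are left unstranded for downstream locus assignment; without a
    genome the alignment flag is used as-is.  This is an automated
    stand-in for manual curation of alignments into transcript models.
    """
    def read_strand(a: pysam.AlignedSegment) -> str:
        return "-" if a.is_reverse else "+"

    spliced: dict[tuple, list[tuple[int, int]]] = {}
    single: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for a in reads:
        if a.is_unmapped:
            continue
        blocks = aligned_blocks(a)
        if genome is not None:
            junctions = infer_introns(a, genome, cfg)
            introns = [(j.start, j.end) for j in junctions]
            strands = Counter(j.strand for j in junctions)
            strand = (strands.most_common(1)[0][0] if strands else ".")
        else:
            introns = [(e1, s2) for (s1, e1), (s2, e2)
                       in zip(blocks, blocks[1:])
                       if s2 - e1 >= cfg.intron_min_len]
            strand = read_strand(a)
        chrom = a.reference_name
        span = (blocks[0][0], blocks[-1][1])
        if introns:
            key = (chrom, strand, tuple(introns))
            spliced.setdefault(key, []).append(span)
        else:
            single[(chrom, strand)].append(span)

    models: list[TranscriptModel] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{id_prefix}{counter:05d}"

    for (chrom, strand, chain), spans in sorted(spliced.items()):
        start = min(s for s, _ in spans)
        end = max(e for _, e in spans)
        bounds = [start] + [x for intron in chain for x in intron] + [end]
        exons = [
            GenomicInterval(chrom, bounds[i], bounds[i + 1], strand)
            for i in range(0, len(bounds), 2)
        ]
        models.append(TranscriptModel(next_id(), "", exons))

    for (chrom, strand), spans in sorted(single.items()):
        ivs = merge_intervals(
            GenomicInterval(chrom, s, e, strand) for s, e in spans
        )
        for iv in ivs:
            models.append(TranscriptModel(next_id(), "", [iv]))
    return models


def assign_models_to_loci(models: Sequence[TranscriptModel],
                          loci: Sequence[GeneLocus]
                          ) -> dict[str, str | None]:
    """Attach each model to the same-strand locus with the largest exonic
    overlap (None when it overlaps no locus exonically).

    Unstranded models (single-exon collapses) may attach to a locus of
    either strand: a primer-anchored amplicon inherits its orientation
    from the locus it was amplified from.
    """
    unions = {l.locus_id: exonic_union(l)[0] for l in loci}
    out: dict[str, str | None] = {}
    for m in models:
        best, best_ov = None, 0
        for l in loci:
            if l.chrom != m.chrom:
                continue
            if m.strand != "." and l.strand != m.strand:
                continue
            ov = sum(
                max(0, min(e.end, iv.end) - max(e.start, iv.start))
                for e in m.exons for iv in unions[l.locus_id]
            )
            if ov > best_ov:
                best, best_ov = l.locus_id, ov
        out[m.transcript_id] = best
    return out
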