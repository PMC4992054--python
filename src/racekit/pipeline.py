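"""End-to-end orchestration: panel design and boundary analysis.

These functions wire the per-stage operations into the two workflows a
user actually runs: designing a specificity-masked primer panel against
an annotation, and characterizing transcript boundaries from aligned RACE
reads (model collapse, direction assignment, TSS/TTS clustering with
novelty and evidence support, polyA inference, locus extension and
on-target accounting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pysam

from . import boundaries as bd
from . import enrichment as er
from . import junctions as jc
from . import primers as pr
from .model import (
    DEFAULT_CONFIG,
    GeneLocus,
    GenomicInterval,
    PointFeature,
    ThresholdConfig,
    TranscriptModel,
    spliced_sequence,
    transcript_tss,
    transcript_tts,
)


@dataclass
class PlacedPrimer:
    """A designed primer with its genomic annealing footprint."""

    candidate: pr.PrimerCandidate
    site: bd.RacePrimerSite
    transcript_id: str


@dataclass
class Panel:
    """A designed RACE primer panel over a set of target loci."""

    primers: dict[tuple[str, str, str], PlacedPrimer] = field(
        default_factory=dict
    )  # (locus_id, direction, role) -> placed primer
    undesignable: list[tuple[str, str, str]] = field(default_factory=list)

    def get(self, locus_id: str, direction: str,
            role: str) -> PlacedPrimer | None:
        return self.primers.get((locus_id, direction, role))

    def sites(self) -> list[bd.RacePrimerSite]:
        return [p.site for p in self.primers.values()]

    def designable_loci(self) -> list[str]:
        return sorted({lid for (lid, _, role) in self.primers
                       if role == "outer"})

    def candidates(self) -> list[pr.PrimerCandidate]:
        return [p.candidate for _, p in sorted(self.primers.items())]


def place_primer(t: TranscriptModel, candidate: pr.PrimerCandidate
                 ) -> bd.RacePrimerSite:
    """Genomic annealing footprint of a primer on its target transcript.

    A 3' RACE primer lies on the transcript strand, a 5' RACE primer on
    the opposite strand (it primes first-strand synthesis toward the 5'
    end of the template).
    """
    pieces = t.to_genomic(candidate.t_start, candidate.t_end)
    if candidate.direction == "3prime":
        strand = t.strand
    else:
        strand = "-" if t.strand == "+" else "+"
    pid = f"{candidate.target_transcript_id}_{candidate.direction}_{candidate.role}"
    return bd.RacePrimerSite(pid, t.chrom, tuple(pieces), strand,
                             candidate.direction)


def design_panel(annotation: Sequence[GeneLocus], target_ids: Sequence[str],
                 genome, cfg: ThresholdConfig = DEFAULT_CONFIG) -> Panel:
    """Design outer + nested 5' and 3' primers for every target locus.

    The design substrate per locus is its longest annotated transcript;
    specificity masking runs against every transcript of every *other*
    locus in the annotation (sense strand only).  Directions are designed
    independently; a missing nested primer does not disqualify a target.
    """
    loci = {l.locus_id: l for l in annotation}
    index = pr.TranscriptomeIndex(cfg.mask_seed_k)
    seqs: dict[str, str] = {}
    for locus in annotation:
        for t in locus.transcripts:
            s = spliced_sequence(t, genome)
            seqs[t.transcript_id] = s
            index.add(locus.locus_id, t.transcript_id, s)

    panel = Panel()
    for lid in sorted(target_ids):
        locus = loci[lid]
        design_t = max(locus.transcripts, key=lambda t: t.spliced_length)
        ms = pr.mask_nonspecific(design_t.transcript_id,
                                 seqs[design_t.transcript_id], lid, index, cfg)
        for direction in ("5prime", "3prime"):
            cands = pr.enumerate_primer_candidates(ms, direction, cfg)
            try:
                outer, nested = pr.choose_primer_pair(
                    cands, direction, design_t.spliced_length, cfg
                )
            except pr.UndesignableTarget as exc:
                panel.undesignable.append((lid, direction, str(exc)))
                continue
            panel.primers[(lid, direction, "outer")] = PlacedPrimer(
                outer, place_primer(design_t, outer), design_t.transcript_id
            )
            if nested is not None:
                panel.primers[(lid, direction, "nested")] = PlacedPrimer(
                    nested, place_primer(design_t, nested),
                    design_t.transcript_id,
                )
    return panel


def load_panel_sites(manifest_path: str, annotation: Sequence[GeneLocus]
                     ) -> list[bd.RacePrimerSite]:
    """Re-derive genomic primer footprints from a manifest + annotation."""
    by_tid = {t.transcript_id: t for l in annotation for t in l.transcripts}
    sites = []
    for cand in pr.read_primer_manifest(manifest_path):
        t = by_tid.get(cand.target_transcript_id)
        if t is None:
            continue
        sites.append(place_primer(t, cand))
    return sites


# -- boundary analysis ----------------------------------------------------


@dataclass
class BoundaryResults:
    """Everything the boundary workflow derives from one aligned read set."""

    models: list[TranscriptModel]
    model_locus: dict[str, str | None]
    calls: dict[str, bd.DirectionCall]
    tss_clusters: list[bd.SiteCluster]
    tts_clusters: list[bd.SiteCluster]
    extensions: list[bd.ExtensionRecord]
    polya_sites: list[bd.PolyASite]
    on_target: er.OnTargetResult
    per_locus: Mapping[str, int]
    junctions: dict[tuple, jc.JunctionRecord]
    n_unique_reads: int


def run_boundary_analysis(sam_path: str, genome,
                          annotation: Sequence[GeneLocus],
                          target_ids: Sequence[str],
                          primer_sites: Sequence[bd.RacePrimerSite],
                          cage_tags: Sequence[PointFeature] = (),
                          polya_tags: Sequence[PointFeature] = (),
                          cfg: ThresholdConfig = DEFAULT_CONFIG,
                          junction_entropy_min: float = 0.0
                          ) -> BoundaryResults:
    """Full boundary characterization of one RACE-Seq alignment set.

    RACE products all start at their originating primer, so junction
    offset entropy is left unfiltered by default here (pass a positive
    ``junction_entropy_min`` for conventional RNA-seq input).
    """
    targets = [l for l in annotation if l.locus_id in set(target_ids)]
    with pysam.AlignmentFile(sam_path, "r") as fh:
        reads = jc.filter_unique(fh, cfg)
    n_unique = len(reads)

    on_target = er.classify_on_target(reads, targets)
    per_locus = er.tally_by_locus(reads, annotation)
    junction_set = jc.extract_junction_set(reads, genome, cfg,
                                           entropy_min=junction_entropy_min)
    polya_sites = bd.infer_polya_sites(reads, cfg)

    models = bd.collapse_reads_to_models(reads, genome, cfg)
    model_locus = bd.assign_models_to_loci(models, targets)
    by_lid = {l.locus_id: l for l in targets}

    calls: dict[str, bd.DirectionCall] = {}
    by_target: dict[str, list[TranscriptModel]] = {}
    oriented: list[TranscriptModel] = []
    for m in models:
        lid = model_locus[m.transcript_id]
        if lid is None:
            oriented.append(m)
            continue
        locus = by_lid[lid]
        if m.strand == ".":
            # unspliced model: inherit orientation from its locus
            m = TranscriptModel(m.transcript_id, m.locus_id, [
                GenomicInterval(e.chrom, e.start, e.end, locus.strand)
                for e in m.exons
            ], m.attributes)
        oriented.append(m)
        if locus.chrom != m.chrom or locus.strand != m.strand:
            continue
        calls[m.transcript_id] = bd.assign_race_direction(
            m, locus, primer_sites, cfg
        )
        by_target.setdefault(lid, []).append(m)
    models = oriented

    extensions: list[bd.ExtensionRecord] = []
    for lid in sorted(by_target):
        extensions.extend(
            bd.label_locus_extension(by_lid[lid], by_target[lid], calls, cfg)
        )

    # pooled TSS/TTS clustering per chrom/strand, restricted by product kind
    five_ends: dict[tuple[str, str], list[int]] = {}
    three_ends: dict[tuple[str, str], list[int]] = {}
    for m in models:
        call = calls.get(m.transcript_id)
        if call is None:
            continue
        if call.call in ("five_prime_product", "both"):
            five_ends.setdefault((m.chrom, m.strand), []).append(
                m.tss_position)
        if call.call in ("three_prime_product", "both"):
            three_ends.setdefault((m.chrom, m.strand), []).append(
                m.tts_position)

    annotated_tss: dict[tuple[str, str], list[int]] = {}
    annotated_tts: dict[tuple[str, str], list[int]] = {}
    for l in targets:
        for t in l.transcripts:
            annotated_tss.setdefault((t.chrom, t.strand), []).append(
                t.tss_position)
            annotated_tts.setdefault((t.chrom, t.strand), []).append(
                t.tts_position)

    tss_clusters: list[bd.SiteCluster] = []
    for (chrom, strand), positions in sorted(five_ends.items()):
        for c in bd.cluster_sites(positions, "TSS", chrom, strand, cfg):
            c.novel = bd.classify_tss_novelty(
                c, annotated_tss.get((chrom, strand), ()), cfg
            )
            c.supported = bd.tag_support(c, cage_tags, cfg.cage_window)
            tss_clusters.append(c)

    tts_clusters: list[bd.SiteCluster] = []
    for (chrom, strand), positions in sorted(three_ends.items()):
        for c in bd.cluster_sites(positions, "TTS", chrom, strand, cfg):
            c.novel = bd.classify_tss_novelty(
                c, annotated_tts.get((chrom, strand), ()), cfg
            )
            c.supported = bd.tag_support(c, polya_tags, cfg.polya_window)
            tts_clusters.append(c)

    return BoundaryResults(
        models=models,
        model_locus=model_locus,
        calls=calls,
        tss_clusters=tss_clusters,
        tts_clusters=tts_clusters,
        extensions=extensions,
        polya_sites=polya_sites,
        on_target=on_target,
        per_locus=per_locus,
        junctions=junction_set,
        n_unique_reads=n_unique,
    )
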