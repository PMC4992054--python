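"""Readers and writers for the standard annotation formats.

GTF (GENCODE dialect, ``gene_id``/``transcript_id`` attributes) is parsed
with :mod:`gffutils`; only exon records define transcript structure, which
is all the boundary analyses require.  BED6 carries point evidence (CAGE
tag 5' ends, polyA-Seq sites) with the position taken from the interval
start.  Coordinates are converted to the internal 0-based half-open
convention on read and restored to 1-based inclusive on write.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .model import (
    GeneLocus,
    GenomicInterval,
    PointFeature,
    TranscriptModel,
)


class AnnotationError(ValueError):
    """Raised for malformed or incomplete annotation records."""


def _has_data_lines(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return True
    return False


def load_annotation(path: str, dialect: str = "gtf") -> list[GeneLocus]:
    """Load a GTF into gene loci of transcript models.

    Transcripts are grouped into loci by ``gene_id`` exactly as annotated;
    no re-clustering happens on load.  Returns loci sorted by id.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect.lower() not in ("gtf", "gencode"):
        raise AnnotationError(f"unsupported annotation dialect {dialect!r}")
    if not _has_data_lines(path):
        return []
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"malformed annotation {path!r}: {exc}") from exc

    by_transcript: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    attrs_of: dict[str, dict[str, str]] = {}
    for feat in db.features_of_type("exon"):
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks transcript_id"
            ) from exc
        try:
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: exon of transcript {tid} lacks gene_id"
            ) from exc
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        by_transcript.setdefault(tid, []).append(iv)
        gene_of[tid] = gid
        attrs_of.setdefault(tid, {}).update(
            {k: v[0] for k, v in feat.attributes.items()}
        )

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, exons in by_transcript.items():
        t = TranscriptModel(tid, gene_of[tid], exons, attrs_of.get(tid, {}))
        by_gene.setdefault(gene_of[tid], []).append(t)

    loci = [
        GeneLocus(gid, sorted(ts, key=lambda t: t.transcript_id))
        for gid, ts in by_gene.items()
    ]
    loci.sort(key=lambda l: l.locus_id)
    return loci


def write_annotation(loci: Iterable[GeneLocus], path: str,
                     source: str = "racekit") -> None:
    """Write loci as GTF exon records (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for locus in sorted(loci, key=lambda l: l.locus_id):
            for t in locus.transcripts:
                for e in t.exons:
                    attrs = (
                        f'gene_id "{locus.locus_id}"; '
                        f'transcript_id "{t.transcript_id}";'
                    )
                    fh.write(
                        f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{e.strand}\t.\t{attrs}\n"
                    )


def load_point_features(path: str, source_label: str = "") -> list[PointFeature]:
    """Read a BED6 evidence track as single-base point features.

    The feature position is the BED ``chromStart`` (0-based); strand comes
    from column 6 and defaults to unstranded when absent.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        return []
    cols = df.shape[1]
    out = []
    for row in df.itertuples(index=False):
        strand = str(row[5]) if cols >= 6 else "."
        label = source_label or (str(row[3]) if cols >= 4 else "")
        out.append(PointFeature(str(row[0]), int(row[1]), strand, label))
    return out


def write_point_features(features: Sequence[PointFeature], path: str) -> None:
    """Write point features as BED6 (single-base intervals)."""
    with open(path, "w") as fh:
        for f in features:
            name = f.source_label or "."
            fh.write(
                f"{f.chrom}\t{f.position}\t{f.position + 1}\t{name}\t0"
                f"\t{f.strand}\n"
            )
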