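"""Target selection and specificity-masked RACE primer design.

Targets are ranked by RPKM computed from exonic read counts and filtered
for the absence of nearby same-strand CAGE evidence (the design goal being
loci whose 5' ends are *not* already well supported).  Candidate spliced
sequences are hard-masked wherever they share >80% identity with a
transcript from a different locus (sense strand only), and internal
oligos of 23-27 nt with Tm 68-72 degC and GC 50-70% are enumerated over the
unmasked sequence.  For each RACE direction an outer primer is chosen by
closeness to the optima (25 nt, 70 degC, 60% GC) subject to a suitable
predicted product span, plus a nested primer placed as close as possible
downstream of it (toward the targeted transcript end).

Melting temperatures come from the SantaLucia unified nearest-neighbour
model (Biopython's ``Tm_NN``) at 50 mM monovalent salt and 200 nM oligo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .model import (
    DEFAULT_CONFIG,
    GeneLocus,
    PointFeature,
    ThresholdConfig,
    TranscriptModel,
    revcomp,
)

MASK_CHAR = "N"


class PrimerDesignError(ValueError):
    pass


class UndesignableTarget(PrimerDesignError):
    """No acceptable outer primer exists for a target/direction."""


@dataclass
class ExpressionRecord:
    """Per-transcript exonic read counts across samples."""

    transcript_id: str
    reads_in_exons: dict[str, int]
    exonic_length: int
    total_mapped: dict[str, int]

    def __post_init__(self) -> None:
        if self.exonic_length <= 0:
            raise PrimerDesignError("exonic_length must be > 0")
        if any(v < 0 for v in self.reads_in_exons.values()):
            raise PrimerDesignError("negative read count")


@dataclass
class MaskedSequence:
    """Spliced sense-strand sequence with non-specific regions hard-masked."""

    transcript_id: str
    sequence: str
    mask_segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def masked_fraction(self) -> float:
        covered = sum(e - s for s, e in self.mask_segments)
        return covered / len(self.sequence) if self.sequence else 0.0


@dataclass
class PrimerCandidate:
    """An oriented internal oligo annealing on a target transcript.

    ``t_start``/``t_end`` are spliced-transcript coordinates of the
    annealing site; for 5' RACE the oligo sequence is the reverse
    complement of that window (it primes synthesis toward the 5' end).
    """

    target_transcript_id: str
    direction: str  # 5prime | 3prime
    role: str       # outer | nested
    t_start: int
    t_end: int
    sequence: str
    tm: float
    gc_frac: float
    score: float = 0.0


# -- expression / target selection ---------------------------------------


def compute_rpkm(rec: ExpressionRecord) -> dict[str, float]:
    """Reads per kilobase of exon per million mapped reads, per sample."""
    out = {}
    for sample, reads in rec.reads_in_exons.items():
        total = rec.total_mapped.get(sample, 0)
        if total <= 0:
            raise PrimerDesignError(
                f"{rec.transcript_id}/{sample}: total mapped reads must be > 0"
            )
        out[sample] = 1e9 * reads / (rec.exonic_length * total)
    return out


def select_targets(records: Sequence[ExpressionRecord],
                   cage_tags: Sequence[PointFeature],
                   annotation: Sequence[GeneLocus],
                   cfg: ThresholdConfig = DEFAULT_CONFIG
                   ) -> list[tuple[str, float]]:
    """Rank CAGE-unsupported, expressed transcripts for targeting.

    Keeps transcripts whose maximum per-sample RPKM strictly exceeds
    ``rpkm_min`` and whose annotated TSS has no same-strand CAGE tag
    within ``cage_window``; returns up to ``n_targets`` (transcript_id,
    mean RPKM) pairs sorted by mean RPKM, descending.
    """
    tss_of = {
        t.transcript_id: (t.chrom, t.tss_position, t.strand)
        for locus in annotation for t in locus.transcripts
    }
    tags_by_chrom: dict[str, list[PointFeature]] = {}
    for tag in cage_tags:
        tags_by_chrom.setdefault(tag.chrom, []).append(tag)

    ranked = []
    for rec in records:
        rpkms = compute_rpkm(rec)
        if max(rpkms.values(), default=0.0) <= cfg.rpkm_min:
            continue
        loc = tss_of.get(rec.transcript_id)
        if loc is None:
            continue
        chrom, pos, strand = loc
        supported = any(
            tag.strand == strand and abs(tag.position - pos) <= cfg.cage_window
            for tag in tags_by_chrom.get(chrom, ())
        )
        if supported:
            continue
        mean_rpkm = sum(rpkms.values()) / len(rpkms)
        ranked.append((rec.transcript_id, mean_rpkm))
    ranked.sort(key=lambda x: (-x[1], x[0]))
    return ranked[: cfg.n_targets]


# -- specificity masking -------------------------------------------------


class TranscriptomeIndex:
    """K-mer index over transcript sense sequences for similarity seeding."""

    def __init__(self, k: int = DEFAULT_CONFIG.mask_seed_k):
        self.k = k
        self.entries: list[tuple[str, str, str]] = []  # (locus, tid, seq)
        self._kmers: dict[str, list[tuple[int, int]]] = {}

    def add(self, locus_id: str, transcript_id: str, sequence: str) -> None:
        idx = len(self.entries)
        seq = sequence.upper()
        self.entries.append((locus_id, transcript_id, seq))
        k = self.k
        for i in range(len(seq) - k + 1):
            self._kmers.setdefault(seq[i:i + k], []).append((idx, i))

    def seeds(self, kmer: str) -> list[tuple[int, int]]:
        return self._kmers.get(kmer, [])


def _extend_gapless(a: str, b: str, i: int, j: int, k: int,
                    xdrop: int = 20) -> tuple[int, int, int]:
    """X-drop ungapped extension of a seed match a[i:i+k] == b[j:j+k].

    Scores +1 per match, -2 per mismatch; extension stops once the score
    falls ``xdrop`` below the running maximum.  Returns the candidate-side
    span (start, end) of the maximal-scoring segment and its match count.
    """
    # right extension
    score = k
    best = score
    best_right = i + k
    matches = k
    best_matches = k
    x, y = i + k, j + k
    while x < len(a) and y < len(b):
        if a[x] == b[y]:
            score += 1
            matches += 1
        else:
            score -= 2
        if score > best:
            best, best_right, best_matches = score, x + 1, matches
        if best - score > xdrop:
            break
        x += 1
        y += 1
    # left extension
    score = best
    best2 = score
    best_left = i
    matches = best_matches
    best_matches2 = matches
    x, y = i - 1, j - 1
    while x >= 0 and y >= 0:
        if a[x] == b[y]:
            score += 1
            matches += 1
        else:
            score -= 2
        if score > best2:
            best2, best_left, best_matches2 = score, x, matches
        if best2 - score > xdrop:
            break
        x -= 1
        y -= 1
    return best_left, best_right, best_matches2


def mask_nonspecific(transcript_id: str, sequence: str, own_locus_id: str,
                     transcriptome: TranscriptomeIndex,
                     cfg: ThresholdConfig = DEFAULT_CONFIG) -> MaskedSequence:
    """Hard-mask candidate regions similar to transcripts of other loci.

    A region is masked when it participates in a sense-vs-sense ungapped
    local alignment of length >= ``mask_min_align_len`` and identity
    > ``mask_identity_min`` against any transcript from a distinct locus.
    Reverse-complement similarity never masks (stranded rule): a RACE
    primer only misprimes on cDNA of the same sense.
    """
    seq = sequence.upper()
    k = transcriptome.k
    segments: list[tuple[int, int]] = []
    visited: dict[tuple[int, int], int] = {}  # (entry, diagonal) -> pos bound
    for i in range(len(seq) - k + 1):
        for idx, j in transcriptome.seeds(seq[i:i + k]):
            locus_id, _, other = transcriptome.entries[idx]
            if locus_id == own_locus_id:
                continue
            key = (idx, i - j)
            if visited.get(key, -1) >= i:
                continue
            lo, hi, matches = _extend_gapless(seq, other, i, j, k)
            visited[key] = hi
            span = hi - lo
            if span >= cfg.mask_min_align_len and matches / span > cfg.mask_identity_min:
                segments.append((lo, hi))
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(segments):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    chars = list(seq)
    for lo, hi in merged:
        chars[lo:hi] = MASK_CHAR * (hi - lo)
    return MaskedSequence(transcript_id, "".join(chars), merged)


# -- thermodynamics and candidate enumeration ----------------------------


def melting_temperature(oligo: str, na_mM: float = 50.0,
                        oligo_nM: float = 200.0) -> float:
    """Nearest-neighbour duplex Tm (degC) of an oligo against its complement.

    Uses the SantaLucia unified parameter set at ``na_mM`` monovalent
    cation and ``oligo_nM`` oligo concentration (primer in excess over
    template, as in a PCR).
    """
    oligo = oligo.upper()
    if len(oligo) < 8:
        raise PrimerDesignError("oligo shorter than 8 nt")
    if any(b not in "ACGT" for b in oligo):
        raise PrimerDesignError(f"ambiguous base in oligo {oligo!r}")
    return _tm_default(oligo) if (na_mM, oligo_nM) == (50.0, 200.0) else \
        _mt.Tm_NN(oligo, Na=na_mM, dnac1=oligo_nM, dnac2=0)


@lru_cache(maxsize=1 << 18)
def _tm_default(oligo: str) -> float:
    # window Tm at the default assay conditions; cached because the same
    # windows are evaluated for both RACE directions
    return _mt.Tm_NN(oligo, Na=50.0, dnac1=200.0, dnac2=0)


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _score(length: int, tm: float, gc: float, cfg: ThresholdConfig) -> float:
    """Distance of a window from the design optima; lower is better."""
    return (
        abs(tm - cfg.primer_tm_opt)
        + 0.5 * abs(length - cfg.primer_len_opt)
        + 10.0 * abs(gc - cfg.primer_gc_opt)
    )


def enumerate_primer_candidates(ms: MaskedSequence, direction: str,
                                cfg: ThresholdConfig = DEFAULT_CONFIG
                                ) -> list[PrimerCandidate]:
    """All windows passing the length/Tm/GC bounds, outside masked regions.

    3' RACE primers take the sense-strand window sequence, 5' RACE primers
    its reverse complement.  The returned list is sorted by score
    (distance to the optima), ascending.
    """
    if direction not in ("5prime", "3prime"):
        raise PrimerDesignError(f"bad direction {direction!r}")
    seq = ms.sequence.upper()
    n = len(seq)
    prefix_gc = [0] * (n + 1)
    prefix_bad = [0] * (n + 1)
    for i, b in enumerate(seq):
        prefix_gc[i + 1] = prefix_gc[i] + (b in "GC")
        prefix_bad[i + 1] = prefix_bad[i] + (b not in "ACGT")
    out: list[PrimerCandidate] = []
    for L in range(cfg.primer_len_min, cfg.primer_len_max + 1):
        for i in range(0, n - L + 1):
            if prefix_bad[i + L] - prefix_bad[i]:
                continue  # overlaps a masked (or ambiguous) base
            gc = (prefix_gc[i + L] - prefix_gc[i]) / L
            if not (cfg.primer_gc_min <= gc <= cfg.primer_gc_max):
                continue
            window = seq[i:i + L]
            tm = melting_temperature(window)
            if not (cfg.primer_tm_min <= tm <= cfg.primer_tm_max):
                continue
            oligo = window if direction == "3prime" else revcomp(window)
            out.append(PrimerCandidate(
                ms.transcript_id, direction, "outer", i, i + L, oligo,
                tm, gc, _score(L, tm, gc, cfg),
            ))
    out.sort(key=lambda c: (c.score, c.t_start, c.t_end))
    return out


def choose_primer_pair(candidates: Sequence[PrimerCandidate], direction: str,
                       transcript_length: int,
                       cfg: ThresholdConfig = DEFAULT_CONFIG
                       ) -> tuple[PrimerCandidate, PrimerCandidate | None]:
    """Pick the outer primer and, when possible, a nested primer.

    The outer primer is the best-scoring candidate whose predicted product
    span (annealing site to the targeted annotated transcript end) falls
    in ``[product_span_min, product_span_max]``.  The nested primer is the
    candidate whose annealing site lies closest downstream of the outer
    one (downstream meaning toward the targeted end), not overlapping it;
    it may be absent.
    """
    def span(c: PrimerCandidate) -> int:
        return c.t_end if direction == "5prime" else transcript_length - c.t_start

    eligible = [c for c in candidates
                if cfg.product_span_min <= span(c) <= cfg.product_span_max]
    if not eligible:
        raise UndesignableTarget(
            f"no outer {direction} primer with product span in "
            f"[{cfg.product_span_min},{cfg.product_span_max}]"
        )
    outer = min(eligible, key=lambda c: (c.score, c.t_start))

    if direction == "3prime":
        downstream = [(c.t_start - outer.t_end, c) for c in candidates
                      if c.t_start >= outer.t_end]
    else:
        downstream = [(outer.t_start - c.t_end, c) for c in candidates
                      if c.t_end <= outer.t_start]
    nested = None
    if downstream:
        nested = min(downstream, key=lambda dc: (dc[0], dc[1].score))[1]
        nested = PrimerCandidate(
            nested.target_transcript_id, nested.direction, "nested",
            nested.t_start, nested.t_end, nested.sequence, nested.tm,
            nested.gc_frac, nested.score,
        )
    outer = PrimerCandidate(
        outer.target_transcript_id, outer.direction, "outer",
        outer.t_start, outer.t_end, outer.sequence, outer.tm,
        outer.gc_frac, outer.score,
    )
    return outer, nested


# -- primer manifest -----------------------------------------------------

MANIFEST_COLUMNS = ["primer_id", "target_transcript", "direction", "role",
                    "sequence", "tm", "gc", "t_start", "t_end"]


def write_primer_manifest(primers: Iterable[PrimerCandidate],
                          path: str) -> None:
    rows = []
    for p in primers:
        pid = f"{p.target_transcript_id}_{p.direction}_{p.role}"
        rows.append([pid, p.target_transcript_id, p.direction, p.role,
                     p.sequence, round(p.tm, 2), round(p.gc_frac, 4),
                     p.t_start, p.t_end])
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_primer_manifest(path: str) -> list[PrimerCandidate]:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise PrimerDesignError(f"primer manifest lacks columns {missing}")
    return [
        PrimerCandidate(r.target_transcript, r.direction, r.role,
                        int(r.t_start), int(r.t_end), r.sequence,
                        float(r.tm), float(r.gc))
        for r in df.itertuples(index=False)
    ]
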