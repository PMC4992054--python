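"""Preprocessing of RACE long reads before alignment.

The pipeline applies, in order: adapter removal (both read ends, tolerant
of sequencing errors), 3' quality trimming by the mean of the last three
phred scores, and a minimum-length filter.  Reads failing the length floor
are counted but not written, so downstream mapping never sees them.

Adapter matching combines a full-adapter infix search (edit distance at
most ``max_err_frac`` x adapter length, via :mod:`edlib`) with partial
terminal overlaps of at least ``min_overlap`` bases.  Internal occurrences
are honoured only when anchored in the terminal 60% of the read: RACE
amplicons carry the universal adapter at one molecule end, so a central
hit in a long read is far more likely a chimeric artefact than a real
adapter, and trimming on it would destroy the insert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import edlib
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import ThresholdConfig, DEFAULT_CONFIG


class FastqError(ValueError):
    """Raised for unreadable or truncated FASTQ input."""


@dataclass
class RawRead:
    """A read with Sanger-scale phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqError(
                f"{self.read_id}: sequence/quality length mismatch"
            )
        if self.qualities and not (0 <= min(self.qualities)
                                   and max(self.qualities) <= 93):
            raise FastqError(f"{self.read_id}: phred score outside [0,93]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProcessedRead(RawRead):
    """A read after adapter/quality/length treatment, with trim provenance."""

    adapter_trimmed: str = "none"  # none | 5prime | 3prime | both
    bases_adapter_trimmed: int = 0
    bases_quality_trimmed: int = 0


@dataclass
class PreprocessReport:
    """Aggregate outcome of a preprocessing run."""

    reads_in: int = 0
    reads_out: int = 0
    reads_discarded_short: int = 0
    bases_adapter_trimmed: int = 0
    bases_quality_trimmed: int = 0
    reads_adapter_trimmed: int = 0

    def to_tsv(self, fh: TextIO) -> None:
        names = [f.name for f in __import__("dataclasses").fields(self)]
        fh.write("\t".join(names) + "\n")
        fh.write("\t".join(str(getattr(self, n)) for n in names) + "\n")


def _edit_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _best_terminal_overlap(read: str, adapter: str, end: str,
                           min_overlap: int, max_err_frac: float) -> int:
    """Length of the best partial adapter overlap hanging off a read end.

    ``end='5prime'``: a suffix of the adapter matches the read prefix.
    ``end='3prime'``: a prefix of the adapter matches the read suffix.
    Returns the number of read bases to cut (0 when no acceptable overlap).
    Among acceptable overlaps the longest is preferred, ties by fewer
    errors, mirroring how adapter trimmers resolve ambiguity.
    """
    best = 0
    best_err = None
    max_ov = min(len(adapter), len(read))
    for ov in range(min_overlap, max_ov + 1):
        if end == "5prime":
            a, b = adapter[-ov:], read[:ov]
        else:
            a, b = adapter[:ov], read[-ov:]
        k = math.floor(max_err_frac * ov)
        h = _hamming(a, b)
        err = h if h <= k else (_edit_distance(a, b) if h <= k + 3 else None)
        if err is not None and err <= k:
            if ov > best or (ov == best and (best_err is None or err < best_err)):
                best, best_err = ov, err
    return best


def _full_occurrence(read: str, adapter: str,
                     max_err_frac: float) -> tuple[int, int] | None:
    """Best complete adapter occurrence inside the read, or None.

    Returns half-open (start, end) read coordinates of the match.
    """
    k = math.floor(max_err_frac * len(adapter))
    pos = read.find(adapter)
    if pos >= 0:
        return pos, pos + len(adapter)
    res = edlib.align(adapter, read, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    return s, e + 1


def trim_adapters(read: RawRead, adapters: Sequence[str],
                  min_overlap: int | None = None,
                  max_err_frac: float | None = None,
                  cfg: ThresholdConfig = DEFAULT_CONFIG) -> ProcessedRead:
    """Remove adapter occurrences (and bases distal to them) from both ends."""
    if not adapters:
        raise ValueError("adapter list is empty")
    min_overlap = cfg.adapter_min_overlap if min_overlap is None else min_overlap
    max_err_frac = cfg.adapter_max_err_frac if max_err_frac is None else max_err_frac

    seq = read.sequence
    n = len(seq)
    cut5, cut3 = 0, n
    for adapter in adapters:
        occ = _full_occurrence(seq, adapter.upper(), max_err_frac)
        if occ is not None:
            s, e = occ
            if s == 0:             # flush with the read start
                cut5 = max(cut5, e)
            elif e == n:           # flush with the read end
                cut3 = min(cut3, s)
            elif s >= 0.4 * n:     # internal, anchored in the last 60%
                cut3 = min(cut3, s)
            elif e <= 0.6 * n:     # internal, anchored in the first 60%
                cut5 = max(cut5, e)
            continue
        ov5 = _best_terminal_overlap(seq, adapter.upper(), "5prime",
                                     min_overlap, max_err_frac)
        cut5 = max(cut5, ov5)
        ov3 = _best_terminal_overlap(seq, adapter.upper(), "3prime",
                                     min_overlap, max_err_frac)
        if ov3:
            cut3 = min(cut3, n - ov3)

    cut3 = max(cut3, cut5)
    trimmed = ("both" if cut5 and cut3 < n
               else "5prime" if cut5
               else "3prime" if cut3 < n
               else "none")
    return ProcessedRead(
        read.read_id,
        seq[cut5:cut3],
        read.qualities[cut5:cut3],
        adapter_trimmed=trimmed,
        bases_adapter_trimmed=cut5 + (n - cut3),
    )


def quality_trim_3prime(read: RawRead,
                        cfg: ThresholdConfig = DEFAULT_CONFIG) -> ProcessedRead:
    """Trim the 3' end until the mean of the last ``qtrim_window`` phred
    scores exceeds ``qtrim_mean_min``.

    Bases are removed one at a time while the window mean is <= the
    threshold; a read shorter than the window is returned untouched (the
    rule is defined on the last three nucleotides and cannot fire).
    """
    w = cfg.qtrim_window
    quals = list(read.qualities)
    n = len(quals)
    while n >= w and sum(quals[n - w:n]) / w <= cfg.qtrim_mean_min:
        n -= 1
    removed = len(quals) - n
    base = read if isinstance(read, ProcessedRead) else None
    out = ProcessedRead(
        read.read_id, read.sequence[:n], quals[:n],
        adapter_trimmed=base.adapter_trimmed if base else "none",
        bases_adapter_trimmed=base.bases_adapter_trimmed if base else 0,
        bases_quality_trimmed=(base.bases_quality_trimmed if base else 0)
        + removed,
    )
    return out


def length_filter(reads: Iterable[ProcessedRead],
                  cfg: ThresholdConfig = DEFAULT_CONFIG
                  ) -> tuple[list[ProcessedRead], int]:
    """Drop reads shorter than ``read_min_len``; exactly-threshold reads pass."""
    kept, discarded = [], 0
    for r in reads:
        if len(r) < cfg.read_min_len:
            discarded += 1
        else:
            kept.append(r)
    return kept, discarded


def preprocess_read(read: RawRead, adapters: Sequence[str],
                    cfg: ThresholdConfig = DEFAULT_CONFIG) -> ProcessedRead:
    """Adapter removal then 3' quality trimming for one read."""
    return quality_trim_3prime(trim_adapters(read, adapters, cfg=cfg), cfg)


def iter_fastq(path: str) -> Iterable[RawRead]:
    """Stream a Sanger-scale FASTQ; truncated records raise with an index."""
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqError(
                    f"{path}: bad FASTQ record near record {index}: {exc}"
                ) from exc
            index += 1
            yield RawRead(title.split()[0], seq.upper(),
                          [ord(c) - 33 for c in qual])


def write_fastq(reads: Iterable[RawRead], fh: TextIO) -> None:
    for r in reads:
        qual = "".join(chr(q + 33) for q in r.qualities)
        fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def preprocess_stream(fastq_in: str, fastq_out: str,
                      adapters: Sequence[str],
                      cfg: ThresholdConfig = DEFAULT_CONFIG
                      ) -> PreprocessReport:
    """Run the full preprocessing pipeline file-to-file.

    Order of operations is fixed: adapters, then quality, then length.
    """
    report = PreprocessReport()
    with open(fastq_out, "w") as out:
        for raw in iter_fastq(fastq_in):
            report.reads_in += 1
            r = preprocess_read(raw, adapters, cfg)
            report.bases_adapter_trimmed += r.bases_adapter_trimmed
            report.bases_quality_trimmed += r.bases_quality_trimmed
            if r.adapter_trimmed != "none":
                report.reads_adapter_trimmed += 1
            if len(r) < cfg.read_min_len:
                report.reads_discarded_short += 1
                continue
            report.reads_out += 1
            write_fastq([r], out)
    return report
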