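"""Shared fixtures: in-memory alignment builders and a small simulated
experiment reused across test modules."""

from __future__ import annotations

import pysam
import pytest

from racekit.model import GenomicInterval, TranscriptModel
from racekit.simulate import SimConfig, simulate_fixture


def make_header(chroms: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": n} for c, n in chroms.items()],
    })


def make_read(header: pysam.AlignmentHeader, name: str, chrom: str,
              pos: int, cigar: list[tuple[int, int]], seq: str | None = None,
              flag: int = 0, mapq: int = 60) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    if seq is not None:
        a.query_sequence = seq
    a.flag = flag
    a.reference_id = header.get_tid(chrom)
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigartuples = cigar
    return a


@pytest.fixture(scope="session")
def sam_header() -> pysam.AlignmentHeader:
    return make_header({"chr1": 1_000_000, "chr2": 1_000_000})


def transcript(tid: str, chrom: str, strand: str,
               exons: list[tuple[int, int]],
               locus: str = "L1") -> TranscriptModel:
    return TranscriptModel(tid, locus, [
        GenomicInterval(chrom, s, e, strand) for s, e in exons
    ])


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A compact error-free simulated experiment for exact-truth checks."""
    outdir = tmp_path_factory.mktemp("sim_small")
    cfg = SimConfig(seed=101, n_target_loci=6, n_offtarget_loci=10,
                    reads_per_target=40, error_rate=0.0)
    return simulate_fixture(str(outdir), cfg, mode="nested")
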