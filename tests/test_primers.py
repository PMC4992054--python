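"""Target selection, specificity masking and primer enumeration."""

import math

import pytest
from Bio import Align

from racekit.model import GeneLocus, PointFeature, ThresholdConfig, revcomp
from racekit.primers import (
    ExpressionRecord,
    MaskedSequence,
    PrimerDesignError,
    TranscriptomeIndex,
    UndesignableTarget,
    choose_primer_pair,
    compute_rpkm,
    enumerate_primer_candidates,
    gc_fraction,
    mask_nonspecific,
    melting_temperature,
    read_primer_manifest,
    select_targets,
    write_primer_manifest,
)
from conftest import transcript

import numpy as np

CFG = ThresholdConfig()


class TestRpkm:
    def test_zero_reads(self):
        rec = ExpressionRecord("t", {"s": 0}, 1000, {"s": 10 ** 6})
        assert compute_rpkm(rec) == {"s": 0.0}

    def test_direct_arithmetic(self):
        rec = ExpressionRecord("t", {"s": 100}, 1000, {"s": 10 ** 6})
        assert compute_rpkm(rec)["s"] == pytest.approx(100.0)

    def test_small_value(self):
        rec = ExpressionRecord("t", {"s": 1}, 1000, {"s": 10 ** 9})
        assert compute_rpkm(rec)["s"] == pytest.approx(1e-3)

    def test_zero_total_mapped_errors(self):
        rec = ExpressionRecord("t", {"s": 5}, 1000, {"s": 0})
        with pytest.raises(PrimerDesignError):
            compute_rpkm(rec)


class TestSelectTargets:
    def _annotation(self):
        return [
            GeneLocus(f"g{i}", [transcript(f"t{i}", "chr1", "+",
                                           [(1000 * i, 1000 * i + 500)],
                                           f"g{i}")])
            for i in range(1, 5)
        ]

    def _rec(self, tid, rpkms):
        # with 1 kb exonic length and 1e6 mapped reads, rpkm == read count
        n = {f"s{j}": int(v) for j, v in enumerate(rpkms)}
        return ExpressionRecord(tid, n, 1000, {k: 10 ** 6 for k in n})

    def test_rpkm_exactly_at_threshold_excluded(self):
        ann = self._annotation()
        recs = [self._rec("t1", [5.0, 5.0])]
        assert select_targets(recs, [], ann) == []

    def test_cage_tag_near_tss_excludes(self):
        ann = self._annotation()
        recs = [self._rec("t1", [6.0])]
        tag = PointFeature("chr1", 1010, "+", "CAGE")  # 10 bp from TSS
        assert select_targets(recs, [tag], ann) == []
        # same distance, opposite strand: stays eligible
        tag_rev = PointFeature("chr1", 1010, "-", "CAGE")
        assert len(select_targets(recs, [tag_rev], ann)) == 1

    def test_top_n_by_mean_rpkm(self):
        ann = self._annotation()
        recs = [self._rec("t1", [6.0, 8.0]),
                self._rec("t2", [20.0, 2.0]),
                self._rec("t3", [9.0, 9.0])]
        cfg = ThresholdConfig(n_targets=2)
        out = select_targets(recs, [], ann, cfg)
        assert [tid for tid, _ in out] == ["t2", "t3"]
        means = [m for _, m in out]
        assert means == sorted(means, reverse=True)


class TestMeltingTemperature:
    def test_reverse_complement_symmetry(self):
        oligo = "ACGTTGCAGGCATCGATCGTAGCTA"
        assert melting_temperature(oligo) == pytest.approx(
            melting_temperature(revcomp(oligo)), abs=1e-6
        )

    def test_gc_raises_tm(self):
        assert (melting_temperature("AT" * 12 + "A")
                < melting_temperature("GC" * 12 + "G"))

    def test_rejects_ambiguous_and_short(self):
        with pytest.raises(PrimerDesignError):
            melting_temperature("ACGTNACGTACGT")
        with pytest.raises(PrimerDesignError):
            melting_temperature("ACGTAETC"[:7])

    @pytest.mark.parametrize("seq", [
        "CGTTGAACGTGCACGTGCACGTGC",
        "ATGCATGCATGCATGCATGCATGCA",
        "GCGCGCAATTGCGCGCAATTGCGCG",
    ])
    def test_matches_independent_nearest_neighbour_summation(self, seq):
        """Unified NN summation oracle at 50 mM Na+, 200 nM oligo."""
        nn = {"AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
              "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
              "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
              "GG": (-8.0, -19.9)}
        comp = str.maketrans("ACGT", "TGCA")

        def canon(p):
            return p if p in nn else p.translate(comp)[::-1]

        dh, ds = 0.2, -5.7  # duplex initiation
        for b in (seq[0], seq[-1]):
            if b in "AT":
                dh += 2.2
                ds += 6.9
        for i in range(len(seq) - 1):
            h, s = nn[canon(seq[i:i + 2])]
            dh += h
            ds += s
        ds += 0.368 * (len(seq) - 1) * math.log(0.05)
        tm = 1000 * dh / (ds + 1.987 * math.log(200e-9)) - 273.15
        assert melting_temperature(seq) == pytest.approx(tm, abs=0.5)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMasking:
    def test_same_locus_identity_not_masked(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 300)
        index = TranscriptomeIndex()
        index.add("L1", "sibling", seq)
        ms = mask_nonspecific("cand", seq, "L1", index)
        assert ms.mask_segments == []
        assert ms.sequence == seq

    def test_shared_block_masked_and_matches_sw_oracle(self):
        rng = np.random.default_rng(1)
        block = _random_seq(rng, 100)
        # corrupt 10% of the foreign copy -> ~90% identity
        foreign_block = list(block)
        for i in rng.choice(100, size=10, replace=False):
            foreign_block[i] = {"A": "C", "C": "G", "G": "T",
                                "T": "A"}[foreign_block[i]]
        cand = _random_seq(rng, 80) + block + _random_seq(rng, 80)
        foreign = _random_seq(rng, 60) + "".join(foreign_block) \
            + _random_seq(rng, 60)
        index = TranscriptomeIndex()
        index.add("L2", "other", foreign)
        ms = mask_nonspecific("cand", cand, "L1", index)
        masked = {b for s, e in ms.mask_segments for b in range(s, e)}
        # independent Smith-Waterman oracle locates the shared block
        aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                        mismatch_score=-2,
                                        open_gap_score=-5,
                                        extend_gap_score=-5)
        aln = aligner.align(cand, foreign)[0]
        lo, hi = aln.aligned[0][0][0], aln.aligned[0][-1][1]
        overlap = len(masked & set(range(lo, hi)))
        assert overlap / (hi - lo) > 0.8
        # masking stays inside the similar region (plus seed-length slack)
        assert not masked - set(range(lo - 25, hi + 25))

    def test_reverse_complement_similarity_not_masked(self):
        rng = np.random.default_rng(2)
        cand = _random_seq(rng, 250)
        index = TranscriptomeIndex()
        index.add("L2", "other", revcomp(cand))
        ms = mask_nonspecific("cand", cand, "L1", index)
        assert ms.mask_segments == []

    def test_masking_is_monotone_in_foreign_set(self):
        rng = np.random.default_rng(3)
        cand = _random_seq(rng, 400)
        f1 = cand[50:150]
        f2 = cand[200:320]
        idx1 = TranscriptomeIndex()
        idx1.add("L2", "a", f1)
        masked1 = {b for s, e in
                   mask_nonspecific("c", cand, "L1", idx1).mask_segments
                   for b in range(s, e)}
        idx2 = TranscriptomeIndex()
        idx2.add("L2", "a", f1)
        idx2.add("L3", "b", f2)
        masked2 = {b for s, e in
                   mask_nonspecific("c", cand, "L1", idx2).mask_segments
                   for b in range(s, e)}
        assert masked1 <= masked2
        assert masked1  # the exact copy really is masked


def _island_sequence():
    """An AT desert with one 60%-GC island long enough for one window set."""
    rng = np.random.default_rng(4)
    while True:
        island = "".join(rng.choice(list("ACGT"), size=40,
                                    p=[0.2, 0.3, 0.3, 0.2]))
        if 0.55 <= gc_fraction(island) <= 0.65:
            return "AT" * 60 + island + "TA" * 60


class TestEnumeration:
    def test_fully_masked_gives_empty(self):
        ms = MaskedSequence("t", "N" * 200, [(0, 200)])
        assert enumerate_primer_candidates(ms, "3prime") == []

    def test_window_overlapping_single_masked_base_rejected(self):
        seq = _island_sequence()
        free = enumerate_primer_candidates(MaskedSequence("t", seq, []),
                                           "3prime")
        assert free
        hit = free[0]
        mid = (hit.t_start + hit.t_end) // 2
        masked_seq = seq[:mid] + "N" + seq[mid + 1:]
        blocked = enumerate_primer_candidates(
            MaskedSequence("t", masked_seq, [(mid, mid + 1)]), "3prime"
        )
        assert all(c.t_end <= mid or c.t_start > mid for c in blocked)

    def test_island_windows_match_exhaustive_scan(self):
        seq = _island_sequence()
        cfg = CFG
        got = {(c.t_start, c.t_end) for c in enumerate_primer_candidates(
            MaskedSequence("t", seq, []), "3prime")}
        expected = set()
        for L in range(cfg.primer_len_min, cfg.primer_len_max + 1):
            for i in range(len(seq) - L + 1):
                w = seq[i:i + L]
                if not (cfg.primer_gc_min <= gc_fraction(w)
                        <= cfg.primer_gc_max):
                    continue
                if (cfg.primer_tm_min <= melting_temperature(w)
                        <= cfg.primer_tm_max):
                    expected.add((i, i + L))
        assert got == expected
        # every passing window must draw on the island for its GC content
        assert all(s < 160 and e > 120 for s, e in got)

    def test_five_prime_candidates_are_reverse_complements(self):
        seq = _island_sequence()
        three = enumerate_primer_candidates(MaskedSequence("t", seq, []),
                                            "3prime")
        five = enumerate_primer_candidates(MaskedSequence("t", seq, []),
                                           "5prime")
        by_pos3 = {(c.t_start, c.t_end): c.sequence for c in three}
        for c in five:
            assert c.sequence == revcomp(by_pos3[(c.t_start, c.t_end)])

    def test_all_candidates_satisfy_bounds(self):
        seq = _island_sequence()
        for c in enumerate_primer_candidates(MaskedSequence("t", seq, []),
                                             "3prime"):
            assert CFG.primer_len_min <= len(c.sequence) <= CFG.primer_len_max
            assert CFG.primer_tm_min <= c.tm <= CFG.primer_tm_max
            assert CFG.primer_gc_min <= c.gc_frac <= CFG.primer_gc_max


def _cand(t_start, t_end, score=1.0, direction="3prime"):
    from racekit.primers import PrimerCandidate
    return PrimerCandidate("t", direction, "outer", t_start, t_end,
                           "A" * (t_end - t_start), 70.0, 0.6, score)


class TestChoosePair:
    def test_single_candidate_is_outer_without_nested(self):
        outer, nested = choose_primer_pair([_cand(100, 125)], "3prime", 1000)
        assert (outer.t_start, nested) == (100, None)

    def test_nested_minimizes_downstream_distance(self):
        cands = [_cand(100, 125, score=0.1), _cand(135, 160),
                 _cand(325, 350)]
        outer, nested = choose_primer_pair(cands, "3prime", 1000)
        assert outer.t_start == 100
        assert nested.t_start == 135  # 10 nt downstream beats 200 nt
        assert nested.role == "nested"

    def test_candidates_only_upstream_leave_nested_absent(self):
        cands = [_cand(500, 525, score=0.1), _cand(100, 125),
                 _cand(300, 325)]
        outer, nested = choose_primer_pair(cands, "3prime", 1000)
        assert outer.t_start == 500
        assert nested is None

    def test_five_prime_downstream_is_toward_tss(self):
        cands = [_cand(500, 525, score=0.1, direction="5prime"),
                 _cand(450, 475, direction="5prime"),
                 _cand(100, 125, direction="5prime")]
        outer, nested = choose_primer_pair(cands, "5prime", 1000)
        assert outer.t_start == 500
        assert nested.t_start == 450

    def test_no_span_eligible_candidate_is_undesignable(self):
        # product span (to the 3' end) below the configured minimum
        with pytest.raises(UndesignableTarget):
            choose_primer_pair([_cand(900, 925)], "3prime", 1000)


def test_manifest_round_trip(tmp_path):
    cands = [_cand(10, 35), _cand(200, 226, direction="5prime")]
    p = tmp_path / "primers.tsv"
    write_primer_manifest(cands, str(p))
    back = read_primer_manifest(str(p))
    assert [(c.t_start, c.t_end, c.direction) for c in back] == \
        [(10, 35, "3prime"), (200, 226, "5prime")]
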