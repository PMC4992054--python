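"""Direction assignment, end clustering, polyA tails, locus extension."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from racekit.boundaries import (
    RacePrimerSite,
    assign_race_direction,
    assign_models_to_loci,
    axis_delta,
    classify_tss_novelty,
    cluster_sites,
    collapse_reads_to_models,
    find_tail,
    infer_polya_sites,
    label_locus_extension,
    merge_loci,
    tag_support,
)
from racekit.model import (
    GeneLocus,
    GenomicInterval,
    ModelError,
    PointFeature,
    ThresholdConfig,
)
from conftest import make_read, transcript

CFG = ThresholdConfig()


def primer_site(pos, strand, direction, chrom="chr1", width=25):
    return RacePrimerSite(
        f"p_{direction}", chrom,
        (GenomicInterval(chrom, pos, pos + width, strand),),
        strand, direction,
    )


class TestDirectionAssignment:
    def _locus(self):
        return GeneLocus("g", [
            transcript("pre", "chr1", "+", [(5000, 5500), (6000, 6500)], "g")
        ])

    def test_five_prime_extension_rule(self):
        t = transcript("m", "chr1", "+", [(4500, 5500), (6000, 6200)])
        call = assign_race_direction(t, self._locus(), [])
        assert call.call == "five_prime_product"

    def test_primer_proximity_boundary_inclusive_at_50(self):
        # transcript 3' end at 6200-1=6199; 5' primer (opposite strand)
        # starting exactly 50 bp away
        t = transcript("m", "chr1", "+", [(5100, 5500), (6000, 6200)])
        site50 = primer_site(6199 + 50, "-", "5prime")
        site51 = primer_site(6199 + 51, "-", "5prime")
        assert assign_race_direction(t, self._locus(),
                                     [site50]).call == "five_prime_product"
        assert assign_race_direction(t, self._locus(),
                                     [site51]).call == "unassigned"

    def test_primer_strand_requirements(self):
        t = transcript("m", "chr1", "+", [(5100, 5500), (6000, 6200)])
        same_strand_5p = primer_site(6210, "+", "5prime")
        assert assign_race_direction(t, self._locus(),
                                     [same_strand_5p]).call == "unassigned"
        same_strand_3p = primer_site(5100, "+", "3prime")
        assert assign_race_direction(
            t, self._locus(), [same_strand_3p]
        ).call == "three_prime_product"

    def test_extending_both_ends_is_both(self):
        t = transcript("m", "chr1", "+", [(4500, 5500), (6000, 7000)])
        assert assign_race_direction(t, self._locus(), []).call == "both"

    def test_chrom_mismatch_errors(self):
        t = transcript("m", "chr2", "+", [(4500, 5500)])
        with pytest.raises(ModelError):
            assign_race_direction(t, self._locus(), [])


class TestClustering:
    def test_tss_gap_50_merges_51_splits(self):
        one = cluster_sites([100, 150], "TSS", "chr1", "+")
        two = cluster_sites([100, 151], "TSS", "chr1", "+")
        assert len(one) == 1 and one[0].members == [100, 150]
        assert len(two) == 2

    def test_tts_gap_150_merges_151_splits(self):
        one = cluster_sites([100, 250], "TTS", "chr1", "+")
        two = cluster_sites([100, 251], "TTS", "chr1", "+")
        assert len(one) == 1
        assert len(two) == 2

    def test_representative_is_five_prime_most(self):
        plus = cluster_sites([100, 120, 140], "TSS", "chr1", "+")
        minus = cluster_sites([100, 120, 140], "TSS", "chr1", "-")
        assert plus[0].representative == 100
        assert minus[0].representative == 140

    @given(st.lists(st.integers(0, 3000), min_size=1, max_size=200),
           st.sampled_from(["TSS", "TTS"]))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_transitive_closure(self, positions,
                                                   site_type):
        gap = (CFG.tss_cluster_gap if site_type == "TSS"
               else CFG.tts_cluster_gap)
        clusters = cluster_sites(positions, site_type, "chr1", "+")
        # brute-force closure of the |a-b| < gap relation
        parent = list(range(len(positions)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                if abs(positions[i] - positions[j]) < gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i, p in enumerate(positions):
            groups.setdefault(find(i), []).append(p)
        expected = sorted(sorted(g) for g in groups.values())
        got = sorted(sorted(c.members) for c in clusters)
        assert got == expected

    @given(st.lists(st.integers(0, 3000), min_size=1, max_size=100))
    @settings(max_examples=50, deadline=None)
    def test_clustering_representatives_is_idempotent(self, positions):
        clusters = cluster_sites(positions, "TSS", "chr1", "+")
        reps = [c.representative for c in clusters]
        again = cluster_sites(reps, "TSS", "chr1", "+")
        assert all(len(c.members) == 1 for c in again)
        assert sorted(c.representative for c in again) == sorted(reps)


class TestNoveltyAndSupport:
    def _cluster(self, rep, strand="+"):
        from racekit.boundaries import SiteCluster
        return SiteCluster("TSS", "chr1", strand, [rep], rep)

    def test_novelty_boundary_100_vs_101(self):
        assert not classify_tss_novelty(self._cluster(1000), [1100])
        assert classify_tss_novelty(self._cluster(1000), [1101])

    def test_no_annotated_sites_is_vacuously_novel(self):
        assert classify_tss_novelty(self._cluster(1000), [])

    def test_novelty_translation_invariance(self):
        for shift in (0, 777, 12345):
            assert classify_tss_novelty(self._cluster(1000 + shift),
                                        [1101 + shift])

    def test_support_boundary_and_strand(self):
        c = self._cluster(1000)
        at50 = PointFeature("chr1", 1050, "+", "CAGE")
        at51 = PointFeature("chr1", 1051, "+", "CAGE")
        flipped = PointFeature("chr1", 1050, "-", "CAGE")
        unstranded = PointFeature("chr1", 1050, ".", "CAGE")
        assert tag_support(c, [at50], 50)
        assert not tag_support(c, [at51], 50)
        assert not tag_support(c, [flipped], 50)
        assert not tag_support(c, [unstranded], 50)
        assert tag_support(c, [flipped], 50, same_strand=False)


class TestTailDetection:
    def test_boundary_21_detected_20_not(self):
        assert find_tail("A" * 21, "A") == 21
        assert find_tail("A" * 20, "A") is None

    def test_ten_percent_mismatch_allowance(self):
        # 30-mer with 3 interior non-A bases (10%): full tail reported
        clip_ok = "A" * 5 + "C" + "A" * 9 + "C" + "A" * 9 + "C" + "A" * 4
        assert len(clip_ok) == 30 and clip_ok.count("C") == 3
        assert find_tail(clip_ok, "A") == 30
        # with 4 mismatches (13%) no stretch may exceed the 10% budget
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = rng.choice(28, size=4, replace=False) + 1
            clip = "".join("C" if i in pos else "A" for i in range(30))
            t = find_tail(clip, "A")
            if t is not None:  # a shorter qualifying stretch may remain
                subs = [clip[k:k + t] for k in range(3)
                        if clip[k:k + t].startswith("A")]
                assert any(s.count("C") / len(s) <= 0.10 for s in subs)
                assert t < 30  # the full 13%-mismatch clip never qualifies

    def test_anchor_slop_of_two(self):
        assert find_tail("CC" + "A" * 21, "A") == 21
        assert find_tail("CCC" + "A" * 21, "A") is None

    def test_longest_qualifying_stretch_reported(self):
        assert find_tail("A" * 30 + "C" * 10, "A") == 30


class TestPolyASites:
    def test_right_clip_a_tail_plus_strand_site(self, sam_header):
        r = make_read(sam_header, "r1", "chr1", 100,
                      [(0, 150), (4, 25)], "G" * 150 + "A" * 25)
        (site,) = infer_polya_sites([r])
        assert (site.chrom, site.position, site.strand) == ("chr1", 249, "+")
        assert site.tail_length == 25

    def test_left_clip_t_head_minus_strand_site(self, sam_header):
        r = make_read(sam_header, "r1", "chr1", 300,
                      [(4, 25), (0, 150)], "T" * 25 + "G" * 150)
        (site,) = infer_polya_sites([r])
        assert (site.position, site.strand) == (300, "-")

    def test_twenty_base_clip_yields_nothing(self, sam_header):
        r = make_read(sam_header, "r1", "chr1", 100,
                      [(0, 150), (4, 20)], "G" * 150 + "A" * 20)
        assert infer_polya_sites([r]) == []

    def test_exact_coordinate_deduplication(self, sam_header):
        reads = [
            make_read(sam_header, f"r{i}", "chr1", 100,
                      [(0, 150), (4, 21 + i)], "G" * 150 + "A" * (21 + i))
            for i in range(3)
        ]
        (site,) = infer_polya_sites(reads)
        assert site.supporting_reads == 3
        assert site.tail_length == 23


class TestExtension:
    def _pre(self, strand="+"):
        return GeneLocus("g", [
            transcript("pre", "chr1", strand, [(5000, 5500), (6000, 6500)],
                       "g")
        ])

    def _call(self, tid, call):
        from racekit.boundaries import DirectionCall
        return {tid: DirectionCall(tid, call)}

    def test_upstream_tss_has_negative_signed_length(self):
        t = transcript("m", "chr1", "+", [(4624, 5500), (6000, 6200)])
        recs = label_locus_extension(self._pre(), [t],
                                     self._call("m", "five_prime_product"))
        (r,) = recs
        assert (r.end, r.signed_length, r.extending) == \
            ("five_prime", -376, True)

    def test_tts_equal_to_annotated_extreme_not_extending(self):
        t = transcript("m", "chr1", "+", [(5100, 5500), (6000, 6500)])
        recs = label_locus_extension(self._pre(), [t],
                                     self._call("m", "three_prime_product"))
        (r,) = recs
        assert (r.end, r.signed_length, r.extending) == \
            ("three_prime", 0, False)

    def test_minus_strand_upstream_is_higher_coordinate(self):
        pre = self._pre("-")  # 5' extreme at 6499
        t = transcript("m", "chr1", "-", [(5100, 5500), (6000, 6875)])
        recs = label_locus_extension(pre, [t],
                                     self._call("m", "five_prime_product"))
        (r,) = recs
        assert r.signed_length == -375
        assert r.extending

    def test_wrong_direction_product_does_not_inform_tss(self):
        t = transcript("m", "chr1", "+", [(4500, 5500)])
        recs = label_locus_extension(self._pre(), [t],
                                     self._call("m", "three_prime_product"))
        assert all(r.end != "five_prime" for r in recs)

    def test_axis_delta_strand_flip(self):
        assert axis_delta("+", 90, 100) == -10
        assert axis_delta("-", 110, 100) == -10


class TestMergeLoci:
    def _loci(self):
        return [
            GeneLocus("A", [transcript("a1", "chr1", "+",
                                       [(1000, 2000)], "A")]),
            GeneLocus("B", [transcript("b1", "chr1", "+",
                                       [(5000, 6000)], "B")]),
            GeneLocus("C", [transcript("c1", "chr1", "+",
                                       [(9000, 10000)], "C")]),
        ]

    def test_bridge_merges_two_loci(self):
        bridge = transcript("n1", "chr1", "+", [(1500, 2500), (4500, 5500)],
                            "")
        merged, log = merge_loci(self._loci(), [bridge])
        assert len(merged) == 2
        assert log == [(("A", "B"), "A+B")]

    def test_intronic_overlap_does_not_merge(self):
        # second exon hops over locus B entirely: overlap is intronic only
        bridge = transcript("n1", "chr1", "+", [(1500, 2500), (7000, 7200)],
                            "")
        merged, log = merge_loci(self._loci(), [bridge])
        assert log == []  # no loci were united
        # the bridge joins A (exonic overlap) but only spans B intronically
        assert len(merged) == 3
        b = next(l for l in merged if l.locus_id == "B")
        assert [t.transcript_id for t in b.transcripts] == ["b1"]

    def test_transitive_chain_collapses_three_loci(self):
        b1 = transcript("n1", "chr1", "+", [(1500, 2500), (4500, 5500)], "")
        b2 = transcript("n2", "chr1", "+", [(5500, 6500), (8500, 9500)], "")
        merged, log = merge_loci(self._loci(), [b1, b2])
        assert len(merged) == 1
        assert log == [(("A", "B", "C"), "A+B+C")]

    def test_counts_conserved_and_locus_count_never_increases(self):
        loci = self._loci()
        new = [transcript("n1", "chr1", "+", [(1500, 2500)], ""),
               transcript("n2", "chr1", "+", [(20000, 21000)], "")]
        merged, _ = merge_loci(loci, new)
        n_transcripts = sum(len(l.transcripts) for l in merged)
        assert n_transcripts == 3 + 2
        # pre-existing loci never multiply; novel singletons may appear
        pre_ids = {"A", "B", "C"}
        surviving = [l for l in merged
                     if any(x in pre_ids for x in l.locus_id.split("+"))]
        assert len(surviving) <= len(loci)


class TestCollapse:
    def _genome(self):
        seq = list("C" * 2000)
        for s, e in [(200, 500), (700, 1000)]:
            seq[s:s + 2] = "GT"
            seq[e - 2:e] = "AG"
        return {"chr1": "".join(seq)}

    def test_same_chain_different_ends_merge(self, sam_header):
        genome = self._genome()
        r1 = make_read(sam_header, "r1", "chr1", 100,
                       [(0, 100), (3, 300), (0, 100)], "C" * 200)
        r2 = make_read(sam_header, "r2", "chr1", 150,
                       [(0, 50), (3, 300), (0, 150)], "C" * 200)
        models = collapse_reads_to_models([r1, r2], genome)
        assert len(models) == 1
        m = models[0]
        assert (m.start, m.end) == (100, 650)
        assert m.intron_chain() == ((200, 500),)
        assert m.strand == "+"

    def test_different_chains_stay_separate(self, sam_header):
        genome = self._genome()
        r1 = make_read(sam_header, "r1", "chr1", 100,
                       [(0, 100), (3, 300), (0, 100)], "C" * 200)
        r2 = make_read(sam_header, "r2", "chr1", 600,
                       [(0, 100), (3, 300), (0, 100)], "C" * 200)
        models = collapse_reads_to_models([r1, r2], genome)
        assert len(models) == 2
        chains = {m.intron_chain() for m in models}
        assert chains == {((200, 500),), ((700, 1000),)}

    def test_single_exon_reads_merge_by_overlap_unstranded(self, sam_header):
        genome = self._genome()
        r1 = make_read(sam_header, "r1", "chr1", 100, [(0, 200)], "C" * 200)
        r2 = make_read(sam_header, "r2", "chr1", 250, [(0, 200)], "C" * 200,
                       flag=16)
        models = collapse_reads_to_models([r1, r2], genome)
        assert len(models) == 1
        assert models[0].strand == "."
        assert (models[0].start, models[0].end) == (100, 450)

    def test_unstranded_model_assignment_ignores_strand(self, sam_header):
        genome = self._genome()
        r1 = make_read(sam_header, "r1", "chr1", 100, [(0, 200)], "C" * 200)
        (m,) = collapse_reads_to_models([r1], genome)
        locus = GeneLocus("g", [transcript("t", "chr1", "-",
                                           [(50, 400)], "g")])
        assert assign_models_to_loci([m], [locus])[m.transcript_id] == "g"
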