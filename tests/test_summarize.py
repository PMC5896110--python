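"""Fragment extraction and counting: CIGAR handling, mate union, counting
rules, chunk/parallel invariance and brute-force oracle equivalence."""

import numpy as np
import pysam
import pytest

from intrest.refprep import GenomicInterval, JunctionRef, ReferenceRow
from intrest.summarize import (
    CountingOptions,
    FragmentBlocks,
    count_exon_junctions,
    count_intron_retention,
    iterate_fragments,
    merge_partials,
    run_summarization,
)

from conftest import (
    oracle_fragments,
    oracle_intron_counts,
    oracle_junction_counts,
)


def write_bam(path, reads, chrom_len=100_000, chrom="chr1"):
    """reads: (qname, flag, pos, cigar, mate_pos or None)."""
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": chrom, "LN": chrom_len}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for qname, flag, pos, cigar, mate_pos in reads:
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = qname
            seg.flag = flag
            seg.reference_id = 0
            seg.reference_start = pos
            seg.mapping_quality = 60
            seg.cigarstring = cigar
            qlen = seg.infer_query_length() or 1
            seg.query_sequence = "A" * qlen
            seg.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            if mate_pos is not None:
                seg.next_reference_id = 0
                seg.next_reference_start = mate_pos
            else:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            bam.write(seg)
    return path


def frags_of(path, paired=False, chunk=10**6):
    out = []
    for batch in iterate_fragments(path, chunk_size=chunk, paired=paired):
        out.extend(batch)
    return out


class TestIterateFragments:
    def test_simple_match_cigar(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [("r1", 0, 100, "50M", None)])
        (frag,) = frags_of(bam)
        assert frag.blocks == ((100, 150),)
        assert frag.splice_gaps == ()

    def test_n_operation_splits_blocks_and_records_gap(self, tmp_path):
        bam = write_bam(tmp_path / "b.bam", [("r1", 0, 0, "20M100N30M", None)])
        (frag,) = frags_of(bam)
        assert frag.blocks == ((0, 20), (120, 150))
        assert frag.splice_gaps == ((20, 120),)

    def test_deletion_absorbed_into_block(self, tmp_path):
        bam = write_bam(tmp_path / "c.bam", [("r1", 0, 10, "10M5D10M", None)])
        (frag,) = frags_of(bam)
        assert frag.blocks == ((10, 35),)

    def test_proper_pair_mates_unioned_without_splice_gap(self, tmp_path):
        bam = write_bam(tmp_path / "d.bam", [
            ("p1", 0x1 | 0x2 | 0x40, 100, "50M", 300),
            ("p1", 0x1 | 0x2 | 0x80 | 0x10, 300, "50M", 100),
        ])
        (frag,) = frags_of(bam, paired=True)
        assert frag.is_paired
        assert frag.blocks == ((100, 150), (300, 350))
        assert frag.splice_gaps == ()  # mate gap is not a splice

    def test_overlapping_mates_merge_into_one_block(self, tmp_path):
        bam = write_bam(tmp_path / "e.bam", [
            ("p1", 0x1 | 0x2 | 0x40, 100, "50M", 120),
            ("p1", 0x1 | 0x2 | 0x80 | 0x10, 120, "50M", 100),
        ])
        (frag,) = frags_of(bam, paired=True)
        assert frag.blocks == ((100, 170),)

    def test_orphan_mate_emitted_as_single_fragment(self, tmp_path):
        bam = write_bam(tmp_path / "f.bam", [
            ("p1", 0x1 | 0x2 | 0x40, 100, "50M", 900),
        ])
        frags = frags_of(bam, paired=True)
        assert len(frags) == 1 and frags[0].blocks == ((100, 150),)

    def test_secondary_supplementary_unmapped_dropped(self, tmp_path):
        bam = write_bam(tmp_path / "g.bam", [
            ("r1", 0, 100, "50M", None),
            ("r2", 0x100, 100, "50M", None),
            ("r3", 0x800, 100, "50M", None),
            ("r4", 0x4, 100, "50M", None),
        ])
        assert len(frags_of(bam)) == 1

    def test_batches_respect_chunk_size_and_cover_all_fragments(self, tmp_path):
        bam = write_bam(tmp_path / "h.bam",
                        [(f"r{i}", 0, 10 * i, "20M", None) for i in range(25)])
        batches = list(iterate_fragments(bam, chunk_size=10))
        assert [len(b) for b in batches] == [10, 10, 5]


def intron(start, end, gene="g1", ordinal=1, strand="+"):
    return ReferenceRow(
        interval=GenomicInterval("chr1", start, end, strand),
        feature_kind="intron", gene_id=gene,
        collapsed_transcript_ids=frozenset({"t"}), ordinal=ordinal)


def frag(blocks, gaps=(), chrom="chr1"):
    return FragmentBlocks(fragment_id="f", chrom=chrom,
                          blocks=tuple(blocks), splice_gaps=tuple(gaps))


class TestCountIntronRetention:
    def test_boundary_spanning_block_counts(self):
        c = count_intron_retention([frag([(240, 260)])], [intron(250, 400)],
                                   junction_anchor=1)
        assert c.tolist() == [1]

    def test_contained_block_obeys_include_contained_switch(self):
        f = [frag([(300, 350)])]
        ref = [intron(250, 400)]
        assert count_intron_retention(f, ref, include_contained=True).tolist() == [1]
        assert count_intron_retention(f, ref, include_contained=False).tolist() == [0]

    def test_spliced_fragment_counts_exons_not_intron(self):
        ref = [ReferenceRow(GenomicInterval("chr1", 200, 250), "exon", "g1",
                            frozenset({"t"}), 1),
               intron(250, 400),
               ReferenceRow(GenomicInterval("chr1", 400, 450), "exon", "g1",
                            frozenset({"t"}), 2)]
        f = [frag([(230, 250), (400, 430)], gaps=[(250, 400)])]
        assert count_intron_retention(f, ref).tolist() == [1, 0, 1]

    def test_anchor_requirement(self):
        ref = [intron(250, 400)]
        f = [frag([(246, 254)])]  # 4 bases each side of the 250 boundary
        assert count_intron_retention(f, ref, include_contained=False,
                                      junction_anchor=4).tolist() == [1]
        assert count_intron_retention(f, ref, include_contained=False,
                                      junction_anchor=5).tolist() == [0]

    def test_fragment_increments_feature_at_most_once(self):
        # both blocks overlap the same intron
        f = [frag([(240, 260), (380, 410)])]
        assert count_intron_retention(f, [intron(250, 400)]).tolist() == [1]

    def test_repeat_masked_overlap_skipped(self):
        from dataclasses import replace

        row = replace(intron(250, 400), masked_subintervals=((250, 400),),
                      repeat_overlap_fraction=1.0)
        f = [frag([(300, 350)])]
        assert count_intron_retention(f, [row], exclude_repeats=True).tolist() == [0]
        assert count_intron_retention(f, [row], exclude_repeats=False).tolist() == [1]

    def test_donor_boundary_mode_is_strand_aware(self):
        f_left = [frag([(240, 260)])]
        f_right = [frag([(390, 410)])]
        plus = [intron(250, 400, strand="+")]
        minus = [intron(250, 400, strand="-")]
        kw = dict(include_contained=False, retention_boundary="donor")
        assert count_intron_retention(f_left, plus, **kw).tolist() == [1]
        assert count_intron_retention(f_right, plus, **kw).tolist() == [0]
        assert count_intron_retention(f_left, minus, **kw).tolist() == [0]
        assert count_intron_retention(f_right, minus, **kw).tolist() == [1]

    def test_include_contained_never_decreases_counts(self, small_sim):
        frags = []
        for batch in iterate_fragments(next(iter(small_sim["bams"].values())),
                                       paired=True):
            frags.extend(batch)
        ref = small_sim["reference"]
        with_c = count_intron_retention(frags, ref, include_contained=True)
        without = count_intron_retention(frags, ref, include_contained=False)
        assert (with_c >= without).all()


class TestCountExonJunctions:
    J = [JunctionRef("g1", "chr1", 20, 120, 1)]

    def test_exact_gap_match_counts(self):
        f = [frag([(0, 20), (120, 150)], gaps=[(20, 120)])]
        assert count_exon_junctions(f, self.J).tolist() == [1]

    def test_near_miss_gap_does_not_count(self):
        j = [JunctionRef("g1", "chr1", 20, 119, 1)]
        f = [frag([(0, 20), (120, 150)], gaps=[(20, 120)])]
        assert count_exon_junctions(f, j).tolist() == [0]

    def test_anchor_on_flanking_blocks(self):
        f = [frag([(17, 20), (120, 150)], gaps=[(20, 120)])]
        assert count_exon_junctions(f, self.J, junction_anchor=3).tolist() == [1]
        assert count_exon_junctions(f, self.J, junction_anchor=4).tolist() == [0]

    def test_fragment_level_counting_single_increment(self):
        # mate2 alone spans the junction; fragment counts once
        f = [frag([(0, 20), (120, 150), (300, 350)], gaps=[(20, 120)])]
        assert count_exon_junctions(f, self.J).tolist() == [1]


class TestMergePartials:
    def test_elementwise_sum(self):
        out = merge_partials([np.array([1, 0, 2]), np.array([0, 3, 1])])
        assert out.tolist() == [1, 3, 3]

    def test_empty_list_gives_zero_vector(self):
        assert merge_partials([], n_features=3).tolist() == [0, 0, 0]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        parts = [rng.integers(0, 5, size=7) for _ in range(5)]
        ref = merge_partials(parts)
        for _ in range(3):
            rng.shuffle(parts)
            assert (merge_partials(parts) == ref).all()

    def test_mismatched_feature_space_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            merge_partials([np.zeros(3), np.zeros(4)])


class TestRunSummarization:
    def test_chunk_and_worker_invariance(self, small_sim):
        """Raw counts are bit-identical across chunk sizes and worker counts."""
        sample, bam = next(iter(small_sim["bams"].items()))
        opts = CountingOptions(paired=True)
        results = {}
        for m in (10, 1000):
            for n in (1, 4):
                res = run_summarization({sample: bam},
                                        reference=small_sim["reference"],
                                        mode="IntRet", chunk_size=m,
                                        n_workers=n, options=opts)
                results[(m, n)] = res.raw_counts
        base = results[(10, 1)]
        for key, counts in results.items():
            assert (counts == base).all(), key

    def test_counts_match_brute_force_oracle(self, small_sim):
        """IntRet and ExEx counts equal the independent all-pairs oracle."""
        opts = CountingOptions(paired=True)
        bams = small_sim["bams"]
        intret = run_summarization(bams, reference=small_sim["reference"],
                                   mode="IntRet", options=opts)
        exex = run_summarization(bams, mode="ExEx",
                                 junction_ref=small_sim["junctions"],
                                 options=opts)
        for k, sample in enumerate(intret.samples):
            frags = oracle_fragments(bams[sample], paired=True)
            assert (intret.raw_counts[:, k] ==
                    oracle_intron_counts(frags, small_sim["reference"])).all()
            assert (exex.raw_counts[:, k] ==
                    oracle_junction_counts(frags, small_sim["junctions"])).all()

    def test_zero_read_bam_gives_valid_zero_result(self, tmp_path, small_sim):
        bam = write_bam(tmp_path / "empty.bam", [])
        res = run_summarization({"s": bam}, reference=small_sim["reference"],
                                mode="IntRet")
        assert res.raw_counts.sum() == 0
        assert res.raw_counts.shape == (len(small_sim["reference"]), 1)

    def test_missing_bam_reports_path(self, small_sim):
        with pytest.raises(FileNotFoundError, match="nope.bam"):
            run_summarization({"s": "nope.bam"},
                              reference=small_sim["reference"], mode="IntRet")

    def test_fpkm_attached_in_intret_mode(self, small_sim):
        res = run_summarization(small_sim["bams"],
                                reference=small_sim["reference"],
                                mode="IntRet",
                                options=CountingOptions(paired=True))
        assert res.normalized is not None
        assert res.normalized.shape == res.raw_counts.shape
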