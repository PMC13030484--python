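import textwrap

import numpy as np
import pytest

from aavjunct._util import revcomp
from aavjunct.align import (
    AlignmentBlock,
    SeedExtendAligner,
    match_score,
    parse_psl_blocks,
    parse_sam_blocks,
    read_blocks_tsv,
    reduce_overlaps,
    write_blocks_tsv,
)
from oracle_sw import smith_waterman


def mk_block(**kw):
    defaults = dict(
        read_id="r", read_len=300, read_start=0, read_end=100, strand="+",
        ref_name="chr1", ref_start=1000, ref_end=1100, matches=100,
    )
    defaults.update(kw)
    return AlignmentBlock(**defaults)


class TestMatchScore:
    @pytest.mark.parametrize(
        "matches,span,expected", [(90, 100, 0.90), (70, 70, 1.0), (35, 70, 0.5)]
    )
    def test_ratio(self, matches, span, expected):
        block = mk_block(read_end=span, matches=matches)
        assert match_score(block) == pytest.approx(expected)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            mk_block(matches=0)
        with pytest.raises(ValueError):
            mk_block(matches=200)  # above the aligned span
        with pytest.raises(ValueError):
            mk_block(read_start=50, read_end=50)


class TestInternalAligner:
    def test_planted_exact_substring(self, hybrid, aligner):
        chrom = hybrid.genome.sequences["chr1"]
        read = chrom[5000:5100]
        (block,) = aligner.align("r1", read)
        assert (block.read_start, block.read_end) == (0, 100)
        assert (block.ref_name, block.ref_start, block.ref_end) == ("chr1", 5000, 5100)
        assert block.matches == 100 and block.strand == "+"

    def test_chimeric_read_partitions_at_junction(self, hybrid, vector, aligner):
        chrom = hybrid.genome.sequences["chr1"]
        read = vector.sequence[-150:] + chrom[2000:2150]
        blocks = reduce_overlaps(aligner.align("chimera", read))
        assert len(blocks) == 2
        vec, host = blocks
        assert vec.is_vector and not host.is_vector
        # junction-adjacent boundaries meet at read offset 150 (allowing
        # score-positive extension through incidental homology)
        assert abs(vec.read_end - 150) <= 4 and abs(host.read_start - 150) <= 4
        assert host.ref_name == "chr1" and abs(host.ref_start - 2000) <= 4

    def test_strand_involution(self, hybrid, aligner):
        chrom = hybrid.genome.sequences["chr2"]
        read = chrom[1000:1160]
        fwd = aligner.align("f", read)
        rev = aligner.align("r", revcomp(read))
        assert len(fwd) == len(rev) == 1
        f, r = fwd[0], rev[0]
        assert (f.ref_name, f.ref_start, f.ref_end) == (r.ref_name, r.ref_start, r.ref_end)
        assert {f.strand, r.strand} == {"+", "-"}
        assert (r.read_start, r.read_end) == (
            f.read_len - f.read_end, f.read_len - f.read_start
        )

    def test_no_alignment_returns_empty(self, aligner):
        rng = np.random.default_rng(99)
        read = "".join(rng.choice(list("ACGT"), size=80))
        assert aligner.align("noise", read) == [] or all(
            b.aligned_span < 80 for b in aligner.align("noise", read)
        )

    def test_matches_oracle_on_planted_instances(self):
        """Internal aligner equals exhaustive local alignment on 200 instances."""
        from aavjunct.refmodel import Genome
        from aavjunct.scenarios import oracle_instances

        mismatched = []
        for i, read, ref, start, end, strand in oracle_instances(n=200, seed=17):
            genome = Genome({"ref": ref})
            blocks = SeedExtendAligner(genome, k=13, min_block=30).align("r", read)
            assert blocks, f"instance {i}: no alignment found"
            best = max(blocks, key=lambda b: b.matches)
            oriented = read if strand == "+" else revcomp(read)
            score, (q0, q1), (t0, t1) = smith_waterman(oriented, ref)
            if strand == "+":
                got = (best.read_start, best.read_end)
            else:
                got = (best.read_len - best.read_end, best.read_len - best.read_start)
            if got != (q0, q1) or (best.ref_start, best.ref_end) != (t0, t1):
                mismatched.append(i)
        assert mismatched == []


class TestSamImport:
    def _parse(self, tmp_path, body, ref=None):
        header = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:AAV\tLN:2928\n"
        path = tmp_path / "in.sam"
        path.write_text(header + textwrap.dedent(body))
        return parse_sam_blocks(str(path), ref=ref)

    def test_soft_clip_forward(self, tmp_path):
        seq = "A" * 150
        (block,) = self._parse(
            tmp_path, f"r1\t0\tchr1\t200\t60\t50S100M\t*\t0\t0\t{seq}\t*\tNM:i:0\n"
        )
        assert (block.read_start, block.read_end) == (50, 150)
        assert (block.ref_start, block.ref_end) == (199, 299)
        assert block.matches == 100 and block.strand == "+"

    def test_reverse_strand_coordinates_flipped(self, tmp_path):
        seq = "A" * 150
        (block,) = self._parse(
            tmp_path, f"r1\t16\tchr1\t200\t60\t100M50S\t*\t0\t0\t{seq}\t*\tNM:i:0\n"
        )
        # [0,100) on the aligned orientation becomes [50,150) forward
        assert (block.read_start, block.read_end) == (50, 150)
        assert block.strand == "-"

    def test_hard_clips_count_like_soft_clips(self, tmp_path):
        seq = "A" * 100
        (block,) = self._parse(
            tmp_path, f"r1\t2048\tchr1\t200\t60\t50H100M\t*\t0\t0\t{seq}\t*\tNM:i:0\n"
        )
        assert block.read_len == 150
        assert (block.read_start, block.read_end) == (50, 150)

    def test_nm_deletion_semantics(self, tmp_path):
        # 10M2D10M with NM=2: both edits are the deleted reference bases, so
        # all 20 aligned read bases match
        seq = "A" * 20
        (block,) = self._parse(
            tmp_path, f"r1\t0\tchr1\t100\t60\t10M2D10M\t*\t0\t0\t{seq}\t*\tNM:i:2\n"
        )
        assert block.aligned_span == 20
        assert block.ref_end - block.ref_start == 22
        assert block.matches == 20

    def test_md_tag_beats_nm(self, tmp_path):
        # MD shows 2 true mismatches inside 20M; NM alone would say the same,
        # but the MD path counts them exactly
        seq = "A" * 20
        (block,) = self._parse(
            tmp_path,
            f"r1\t0\tchr1\t100\t60\t20M\t*\t0\t0\t{seq}\t*\tNM:i:2\tMD:Z:5C8G5\n",
        )
        assert block.matches == 18

    def test_unmapped_and_secondary_skipped(self, tmp_path, hybrid):
        seq = "A" * 50
        blocks = self._parse(
            tmp_path,
            f"r1\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n"
            f"r2\t256\tchr1\t100\t0\t50M\t*\t0\t0\t{seq}\t*\tNM:i:0\n"
            f"r3\t0\tAAV\t100\t60\t50M\t*\t0\t0\t{seq}\t*\tNM:i:0\n",
            ref=hybrid,
        )
        assert [b.read_id for b in blocks] == ["r3"]
        assert blocks[0].is_vector


PSL_HEADER = """\
psLayout version 3

match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ        \tQ   \tQ    \tQ  \tT        \tT   \tT    \tT  \tblock\tblockSizes \tqStarts\t tStarts
     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname     \tsize\tstart\tend\tname     \tsize\tstart\tend\tcount
---------------------------------------------------------------------------------------------------------------------------------------------------------------
"""


class TestPslImport:
    def test_fields_and_score(self, tmp_path):
        line = (
            "95\t5\t0\t0\t0\t0\t0\t0\t+\tread1\t100\t0\t100\t"
            "chr1\t100000\t5000\t5100\t1\t100,\t0,\t5000,\n"
        )
        path = tmp_path / "a.psl"
        path.write_text(PSL_HEADER + line)
        (block,) = parse_psl_blocks(str(path))
        assert block.matches == 95 and block.aligned_span == 100
        assert match_score(block) == pytest.approx(0.95)
        assert (block.ref_start, block.ref_end) == (5000, 5100)
        assert block.source == "psl"

    def test_header_only_yields_nothing(self, tmp_path):
        path = tmp_path / "b.psl"
        path.write_text(PSL_HEADER)
        assert parse_psl_blocks(str(path)) == []

    def test_minus_strand_keeps_forward_query_coords(self):
        line = (
            "80\t0\t10\t0\t0\t0\t0\t0\t-\tread2\t150\t20\t110\t"
            "AAV\t2928\t100\t190\t1\t90,\t40,\t100,\n"
        )
        (block,) = parse_psl_blocks([line])
        assert block.strand == "-"
        # PSL qStart/qEnd are forward-query coordinates already
        assert (block.read_start, block.read_end) == (20, 110)
        assert block.matches == 90  # matches + repMatches

    def test_malformed_line_rejected(self, caplog):
        blocks = parse_psl_blocks(["1\t2\t3\n"])
        assert blocks == []


class TestOverlapReduction:
    def test_duplicate_vector_hits_collapse_to_best(self):
        a = mk_block(read_start=0, read_end=140, matches=140, ref_name="AAV",
                     ref_start=0, ref_end=140)
        b = mk_block(read_start=0, read_end=140, matches=120, ref_name="AAV",
                     ref_start=2783, ref_end=2923)
        assert reduce_overlaps([a, b]) == [a]

    def test_disjoint_blocks_kept_in_read_order(self):
        a = mk_block(read_start=150, read_end=300, ref_start=2000, ref_end=2150,
                     matches=150)
        b = mk_block(read_start=0, read_end=150, ref_name="AAV", matches=150,
                     ref_start=0, ref_end=150)
        assert reduce_overlaps([a, b]) == [b, a]

    def test_tie_breaks_deterministic(self):
        a = mk_block(read_start=0, read_end=100, matches=100, ref_name="AAV",
                     ref_start=0, ref_end=100)
        b = mk_block(read_start=0, read_end=100, matches=100, ref_name="AAV",
                     ref_start=2828, ref_end=2928)
        assert reduce_overlaps([a, b]) == reduce_overlaps([b, a]) == [a]


class TestBlockTsvRoundTrip:
    def test_round_trip_identical(self, tmp_path):
        blocks = [
            mk_block(),
            mk_block(read_id="r2", strand="-", ref_name="AAV", is_vector=True,
                     source="psl", matches=90),
        ]
        path = tmp_path / "blocks.tsv"
        write_blocks_tsv(blocks, str(path), header_lines=["test provenance"])
        assert read_blocks_tsv(str(path)) == blocks
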