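import re

import numpy as np
import pysam
import pytest

from irquant import signal as sig
from irquant.annotation import IntronUnit


def make_bam(path, reads, contig="chr1", length=10_000):
    """Write (name, flag, pos, cigar-string) alignments, sorted and indexed."""
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": length}]}
    tmp = str(path) + ".tmp.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for name, flag, pos, cigar in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name, a.flag = name, flag
            a.reference_id, a.reference_start = 0, pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = "A" * sum(
                int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar)
            )
            out.write(a)
    pysam.sort("-o", str(path), tmp)
    pysam.index(str(path))
    return str(path)


INTRON = IntronUnit("chr1", 100, 200, "+", ("g",), ("t",))


class TestDepthProfile:
    def test_identical_unspliced_reads_give_flat_depth(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [(f"r{i}", 0, 80, "140M") for i in range(10)])
        with pysam.AlignmentFile(bam) as fh:
            prof = sig.depth_profile(fh, INTRON)
        assert prof.depth.shape == (100,)
        assert (prof.depth == 10).all()

    def test_no_reads_gives_zero_profile(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [])
        with pysam.AlignmentFile(bam) as fh:
            prof = sig.depth_profile(fh, INTRON)
        assert (prof.depth == 0).all()

    def test_gaps_and_deletions_do_not_count_as_coverage(self, tmp_path):
        # 50M100N50M spans the intron without covering it; 10M5D10M covers
        # only its aligned blocks
        bam = make_bam(
            tmp_path / "a.bam",
            [("gap", 0, 50, "50M100N50M"), ("del", 0, 120, "10M5D10M")],
        )
        with pysam.AlignmentFile(bam) as fh:
            prof = sig.depth_profile(fh, INTRON)
        expect = np.zeros(100, dtype=int)
        expect[20:30] = 1  # 120-130
        expect[35:45] = 1  # 135-145 after the 5-base deletion
        assert (prof.depth == expect).all()

    def test_masked_positions_flagged_and_excluded(self, tmp_path):
        unit = IntronUnit("chr1", 100, 200, "+", ("g",), ("t",), mask=((150, 170),))
        bam = make_bam(tmp_path / "a.bam", [(f"r{i}", 0, 0, "300M") for i in range(5)])
        with pysam.AlignmentFile(bam) as fh:
            prof = sig.depth_profile(fh, unit)
        assert prof.mask.sum() == 20
        assert prof.unmasked_depth.size == 80

    def test_depth_matches_pysam_pileup_oracle(self, sim_bundle):
        unit = sim_bundle["catalog"][2]
        with pysam.AlignmentFile(sim_bundle["short_bam"]) as fh:
            prof = sig.depth_profile(fh, unit)
            cov = np.sum(
                fh.count_coverage(
                    unit.contig, unit.start, unit.end, quality_threshold=0
                ),
                axis=0,
            )
        assert (prof.depth == cov).all()

    def test_unknown_contig_raises_naming_it(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [])
        unit = IntronUnit("chrZ", 100, 200, "+", ("g",), ("t",))
        with pysam.AlignmentFile(bam) as fh:
            with pytest.raises(ValueError, match="chrZ"):
                sig.depth_profile(fh, unit)

    def test_flanks_captured_at_native_resolution(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [("r", 0, 0, "300M")])
        with pysam.AlignmentFile(bam) as fh:
            prof = sig.depth_profile(fh, INTRON, flank=30)
        assert prof.left_flank.shape == (30,) and (prof.left_flank == 1).all()
        assert prof.right_flank.shape == (30,) and (prof.right_flank == 1).all()


def splice_oracle(bam_path, intron, jitter):
    """Brute-force per-read enumeration of alignment gaps from CIGAR text."""
    n_l = n_r = n_e = 0
    with pysam.AlignmentFile(bam_path) as fh:
        for read in fh.fetch():
            pos, gaps = read.reference_start, []
            for n, op in re.findall(r"(\d+)([MIDNSHP=X])", read.cigarstring):
                n = int(n)
                if op == "N":
                    gaps.append((pos, pos + n))
                if op in "MDN=X":
                    pos += n
            left = any(abs(gs - intron.start) <= jitter for gs, _ in gaps)
            right = any(abs(ge - intron.end) <= jitter for _, ge in gaps)
            exact = any(
                abs(gs - intron.start) <= jitter and abs(ge - intron.end) <= jitter
                for gs, ge in gaps
            )
            n_l += left
            n_r += right
            n_e += exact
    if intron.strand == "-":
        n_l, n_r = n_r, n_l
    return n_l, n_r, n_e


class TestCountSplices:
    def test_exact_gap_at_jitter_zero(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [("r", 0, 50, "50M100N50M")])
        with pysam.AlignmentFile(bam) as fh:
            c = sig.count_splices(fh, INTRON, 0)
        assert (c.splice_left, c.splice_right, c.exact_splice) == (1, 1, 1)

    def test_displaced_gap_needs_jitter(self, tmp_path):
        # gap [102, 197): +2 at donor, -3 at acceptor
        bam = make_bam(tmp_path / "a.bam", [("r", 0, 50, "52M95N50M")])
        with pysam.AlignmentFile(bam) as fh:
            c0 = sig.count_splices(fh, INTRON, 0)
            c3 = sig.count_splices(fh, INTRON, 3)
        assert (c0.splice_left, c0.splice_right, c0.exact_splice) == (0, 0, 0)
        assert (c3.splice_left, c3.splice_right, c3.exact_splice) == (1, 1, 1)

    def test_negative_jitter_rejected(self, tmp_path):
        bam = make_bam(tmp_path / "a.bam", [])
        with pysam.AlignmentFile(bam) as fh:
            with pytest.raises(ValueError, match="jitter"):
                sig.count_splices(fh, INTRON, -1)

    def test_read_counts_once_per_tally_despite_two_matching_gaps(self, tmp_path):
        # both gaps match the donor within jitter 3
        bam = make_bam(tmp_path / "a.bam", [("r", 0, 50, "50M30N20M47N50M")])
        with pysam.AlignmentFile(bam) as fh:
            c = sig.count_splices(fh, INTRON, 3)
        assert c.splice_left == 1

    @pytest.mark.parametrize("jitter", [0, 1, 3])
    def test_counts_equal_bruteforce_oracle_on_noisy_long_reads(
        self, sim_bundle, jitter
    ):
        for unit in sim_bundle["catalog"][:4]:
            with pysam.AlignmentFile(sim_bundle["long_bam"]) as fh:
                c = sig.count_splices(fh, unit, jitter)
            assert (c.splice_left, c.splice_right, c.exact_splice) == splice_oracle(
                sim_bundle["long_bam"], unit, jitter
            )

    def test_jitter_monotonicity(self, sim_bundle):
        unit = sim_bundle["catalog"][1]
        with pysam.AlignmentFile(sim_bundle["long_bam"]) as fh:
            counts = [sig.count_splices(fh, unit, j) for j in range(5)]
        for a, b in zip(counts, counts[1:]):
            assert b.splice_left >= a.splice_left
            assert b.splice_right >= a.splice_right
            assert b.exact_splice >= a.exact_splice
        for c in counts:
            assert c.exact_splice <= min(c.splice_left, c.splice_right)

    def test_directional_mode_filters_opposite_strand_reads(self, tmp_path):
        bam = make_bam(
            tmp_path / "a.bam",
            [("fwd", 0, 50, "50M100N50M"), ("rev", 16, 50, "50M100N50M")],
        )
        with pysam.AlignmentFile(bam) as fh:
            both = sig.count_splices(fh, INTRON, 0)
            fwd = sig.count_splices(fh, INTRON, 0, stranded="forward")
        assert both.exact_splice == 2
        assert fwd.exact_splice == 1


class TestAbundances:
    def _profile(self, depths, mask=None):
        d = np.asarray(depths)
        m = np.zeros(d.size, dtype=bool) if mask is None else np.asarray(mask)
        unit = IntronUnit("chr1", 0, d.size, "+", ("g",), ("t",))
        return sig.DepthProfile(unit, d, m)

    def test_short_median_even_count(self):
        assert sig.intron_abundance_short(self._profile([0, 0, 5, 5])) == 2.5

    def test_short_constant(self):
        assert sig.intron_abundance_short(self._profile([7] * 9)) == 7

    def test_short_matches_sort_oracle(self, sim_bundle):
        unit = sim_bundle["catalog"][3]
        with pysam.AlignmentFile(sim_bundle["short_bam"]) as fh:
            prof = sig.depth_profile(fh, unit)
        vals = sorted(prof.unmasked_depth)
        n = len(vals)
        oracle = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
        assert sig.intron_abundance_short(prof) == oracle

    def test_long_minimum(self):
        assert sig.intron_abundance_long(self._profile([4, 9, 4, 12])) == 4

    def test_long_zero_if_any_unmasked_zero(self):
        assert sig.intron_abundance_long(self._profile([5, 0, 8])) == 0

    def test_long_never_exceeds_short(self, sim_bundle):
        with pysam.AlignmentFile(sim_bundle["short_bam"]) as fh:
            for unit in sim_bundle["catalog"]:
                prof = sig.depth_profile(fh, unit)
                assert sig.intron_abundance_long(prof) <= sig.intron_abundance_short(
                    prof
                )

    def test_fully_masked_raises(self):
        with pytest.raises(sig.NoEvaluablePositionsError):
            sig.intron_abundance_short(self._profile([1, 2], mask=[True, True]))
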