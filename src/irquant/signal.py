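"""Per-base intron depth and splice-junction counts from aligned reads.

Depth counts aligned (match/mismatch) bases only: deletions and skips in a
read consume reference but contribute no coverage.  Splice counting matches
each alignment gap (CIGAR ``N``) against the intron's donor/acceptor pair
with a per-endpoint jitter tolerance, the mechanism that compensates the
basecalling imprecision of long reads around exon boundaries:

* SpliceLeft  — reads with a gap endpoint within ``jitter`` nt of the donor
  boundary (the reference-left boundary on ``+`` strand, right on ``-``);
* SpliceRight — likewise for the acceptor boundary;
* ExactSplice — reads with a single gap matching *both* boundaries, each
  within the jitter.

Each read counts at most once per tally regardless of how many of its gaps
match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pysam

from .annotation import IntronUnit

__all__ = [
    "DepthProfile",
    "SpliceCounts",
    "NoEvaluablePositionsError",
    "depth_profile",
    "count_splices",
    "intron_abundance_short",
    "intron_abundance_long",
    "read_gaps",
    "read_blocks",
]


class NoEvaluablePositionsError(ValueError):
    """An intron whose body is fully masked has no depth statistic."""


@dataclass
class DepthProfile:
    """Per-base aligned-read depth over one intron body, plus flanks.

    ``depth[p]`` covers intron position ``start + p``; ``mask`` flags
    positions excluded from statistics.  ``left_flank``/``right_flank`` hold
    exonic coverage immediately outside the body (reference orientation) for
    downstream coverage-array rendering; they carry no mask.
    """

    intron: IntronUnit
    depth: np.ndarray
    mask: np.ndarray  # bool, True = excluded
    left_flank: np.ndarray | None = None
    right_flank: np.ndarray | None = None

    @property
    def unmasked_depth(self) -> np.ndarray:
        return self.depth[~self.mask]


@dataclass(frozen=True)
class SpliceCounts:
    splice_left: int
    splice_right: int
    exact_splice: int
    jitter: int

    def __post_init__(self) -> None:
        if min(self.splice_left, self.splice_right, self.exact_splice) < 0:
            raise ValueError("splice counts must be non-negative")
        if self.exact_splice > min(self.splice_left, self.splice_right):
            raise ValueError("exact_splice exceeds a per-boundary tally")


def _passes(read: pysam.AlignedSegment, strand: str, mapq: int, stranded: str) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.mapping_quality < mapq:
        return False
    if stranded == "none":
        return True
    read_strand = "-" if read.is_reverse else "+"
    if stranded == "reverse":
        read_strand = "+" if read_strand == "-" else "-"
    return read_strand == strand


def read_blocks(read: pysam.AlignedSegment) -> Iterator[tuple[int, int]]:
    """Reference intervals of aligned (M/=/X) bases, split at D and N."""
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            yield pos, pos + length
            pos += length
        elif op in (2, 3):  # D, N consume reference only
            pos += length
        # I, S, H, P consume no reference


def read_gaps(read: pysam.AlignedSegment) -> Iterator[tuple[int, int]]:
    """Reference intervals skipped by CIGAR N operations (introns)."""
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 2, 7, 8):  # M, D, =, X
            pos += length
        elif op == 3:  # N
            yield pos, pos + length
            pos += length


def _fetch(
    alignments: pysam.AlignmentFile, contig: str, start: int, end: int
) -> Iterable[pysam.AlignedSegment]:
    try:
        return alignments.fetch(contig, max(0, start), end)
    except ValueError as exc:
        raise ValueError(f"cannot fetch region on contig {contig!r}: {exc}") from exc


def depth_profile(
    alignments: pysam.AlignmentFile,
    intron: IntronUnit,
    *,
    flank: int = 0,
    mapq: int = 0,
    stranded: str = "none",
) -> DepthProfile:
    """Pile up aligned-base depth over the intron body (and optional flanks)."""
    lo, hi = intron.start - flank, intron.end + flank
    span = np.zeros(hi - lo, dtype=np.int64)
    for read in _fetch(alignments, intron.contig, lo, hi):
        if not _passes(read, intron.strand, mapq, stranded):
            continue
        for bs, be in read_blocks(read):
            s, e = max(bs, lo), min(be, hi)
            if s < e:
                span[s - lo : e - lo] += 1
    body = span[flank : flank + intron.length] if flank else span
    mask = np.zeros(intron.length, dtype=bool)
    for ms, me in intron.mask:
        mask[ms - intron.start : me - intron.start] = True
    return DepthProfile(
        intron=intron,
        depth=body.copy(),
        mask=mask,
        left_flank=span[:flank].copy() if flank else None,
        right_flank=span[flank + intron.length :].copy() if flank else None,
    )


def count_splices(
    alignments: pysam.AlignmentFile,
    intron: IntronUnit,
    jitter: int = 0,
    *,
    mapq: int = 0,
    stranded: str = "none",
) -> SpliceCounts:
    """Count SpliceLeft / SpliceRight / ExactSplice reads for one intron."""
    if jitter < 0:
        raise ValueError(f"jitter must be non-negative, got {jitter}")
    n_left = n_right = n_exact = 0
    pad = jitter + 1
    for read in _fetch(
        alignments, intron.contig, intron.start - pad, intron.end + pad
    ):
        if not _passes(read, intron.strand, mapq, stranded):
            continue
        hit_left = hit_right = hit_exact = False
        for gs, ge in read_gaps(read):
            left_ok = abs(gs - intron.start) <= jitter
            right_ok = abs(ge - intron.end) <= jitter
            hit_left |= left_ok
            hit_right |= right_ok
            hit_exact |= left_ok and right_ok
        n_left += hit_left
        n_right += hit_right
        n_exact += hit_exact
    if intron.strand == "-":  # donor sits at the reference-right boundary
        n_left, n_right = n_right, n_left
    return SpliceCounts(n_left, n_right, n_exact, jitter)


def intron_abundance_short(profile: DepthProfile) -> float:
    """Intron abundance for short reads: median depth over unmasked positions."""
    vals = profile.unmasked_depth
    if vals.size == 0:
        raise NoEvaluablePositionsError(
            f"intron {profile.intron.name} has no evaluable positions"
        )
    return float(np.median(vals))


def intron_abundance_long(profile: DepthProfile) -> float:
    """Intron abundance for long reads: minimum depth over unmasked positions.

    A single uncovered base drives the abundance to zero, which is what makes
    the long-read estimator reject partial-coverage artifacts such as
    alternative 3' ends that mimic retention under the median.
    """
    vals = profile.unmasked_depth
    if vals.size == 0:
        raise NoEvaluablePositionsError(
            f"intron {profile.intron.name} has no evaluable positions"
        )
    return float(vals.min())
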