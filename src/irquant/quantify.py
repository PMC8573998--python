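"""IRratio quantification per intron, warnings, classification and table I/O.

The central statistic is

    IRratio = A_i / (A_i + A_e)

the estimated fraction of transcripts retaining the intron, where A_i is the
intronic abundance (median unmasked depth in short-read mode, minimum in
long-read mode) and A_e the exonic abundance (max(SpliceLeft, SpliceRight)
in short-read mode, ExactSplice in long-read mode).

Warnings flag calls whose ratio is unreliable rather than suppressing them:

* ``LowCover``             — informative depth A_i + A_e below a threshold
  (default 10), the ratio of two tiny numbers is noise;
* ``MinorIsoform``         — long-read mode only: ExactSplice much smaller
  than max(SpliceLeft, SpliceRight), i.e. most spliced reads use some other
  boundary pair, so the annotated intron is a minor isoform of the locus;
* ``NoEvaluablePositions`` — every intronic base is masked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import pysam

from .annotation import IntronUnit, intron_id
from .signal import (
    NoEvaluablePositionsError,
    SpliceCounts,
    count_splices,
    depth_profile,
    intron_abundance_long,
    intron_abundance_short,
)

__all__ = [
    "IRRecord",
    "WARN_LOWCOVER",
    "WARN_MINOR_ISOFORM",
    "WARN_NO_EVALUABLE",
    "DEFAULT_LOWCOVER_MIN_DEPTH",
    "DEFAULT_MINOR_ISOFORM_FRACTION",
    "DEFAULT_JITTER",
    "irratio",
    "format_irratio",
    "exon_abundance_short",
    "exon_abundance_long",
    "assign_warnings",
    "quantify_sample",
    "classify",
    "write_ir_table",
    "read_ir_table",
]

WARN_LOWCOVER = "LowCover"
WARN_MINOR_ISOFORM = "MinorIsoform"
WARN_NO_EVALUABLE = "NoEvaluablePositions"

DEFAULT_LOWCOVER_MIN_DEPTH = 10
DEFAULT_MINOR_ISOFORM_FRACTION = 0.5
#: default jitter per mode: short reads align boundaries exactly, long reads
#: get a 3-nt per-endpoint tolerance
DEFAULT_JITTER = {"short": 0, "long": 3}

TABLE_COLUMNS = [
    "Chr",
    "Start",
    "End",
    "Name",
    "Score",
    "Strand",
    "ExactSplice",
    "SpliceLeft",
    "SpliceRight",
    "IntronDepth",
    "ExonAbundance",
    "IRratio",
    "Warnings",
]


@dataclass
class IRRecord:
    """Per-intron quantification result for one sample."""

    contig: str
    start: int  # 0-based half-open, as everywhere internally
    end: int
    strand: str
    name: str
    a_i: float
    a_e: float
    splice_left: int
    splice_right: int
    exact_splice: int
    warnings: tuple[str, ...] = ()

    @property
    def depth(self) -> float:
        """Informative depth: A_i + A_e."""
        return self.a_i + self.a_e

    @property
    def irratio(self) -> float:
        return irratio(self.a_i, self.a_e)

    @property
    def intron_key(self) -> str:
        return intron_id(self.contig, self.start, self.end, self.strand)


def irratio(a_i: float, a_e: float) -> float:
    """A_i / (A_i + A_e); 0 when both abundances are zero (caller warns)."""
    if a_i < 0 or a_e < 0:
        raise ValueError(f"abundances must be non-negative, got ({a_i}, {a_e})")
    total = a_i + a_e
    if total == 0:
        return 0.0
    return a_i / total


def format_irratio(value: float, digits: int = 3) -> str:
    """Render an IRratio for text output (3 decimals, round-half-even)."""
    return f"{round(value, digits):.{digits}f}"


def exon_abundance_short(counts: SpliceCounts) -> float:
    """Short-read A_e: the better-supported of the two boundary tallies."""
    return float(max(counts.splice_left, counts.splice_right))


def exon_abundance_long(counts: SpliceCounts) -> float:
    """Long-read A_e: reads spliced at both boundaries of this intron."""
    return float(counts.exact_splice)


def assign_warnings(
    record: IRRecord,
    mode: str = "short",
    lowcover_min_depth: float = DEFAULT_LOWCOVER_MIN_DEPTH,
    minor_isoform_fraction: float = DEFAULT_MINOR_ISOFORM_FRACTION,
    *,
    no_evaluable: bool = False,
) -> tuple[str, ...]:
    """Compute the warning set for a quantified record."""
    warns: list[str] = []
    if no_evaluable:
        warns.append(WARN_NO_EVALUABLE)
    if record.depth < lowcover_min_depth:
        warns.append(WARN_LOWCOVER)
    if mode == "long":
        best_side = max(record.splice_left, record.splice_right)
        if best_side > 0 and record.exact_splice < minor_isoform_fraction * best_side:
            warns.append(WARN_MINOR_ISOFORM)
    return tuple(warns)


def quantify_sample(
    alignments: pysam.AlignmentFile | str,
    catalog: Sequence[IntronUnit],
    mode: str = "short",
    jitter: int | None = None,
    *,
    lowcover_min_depth: float = DEFAULT_LOWCOVER_MIN_DEPTH,
    minor_isoform_fraction: float = DEFAULT_MINOR_ISOFORM_FRACTION,
    mapq: int = 0,
    stranded: str = "none",
) -> list[IRRecord]:
    """Quantify every catalog intron in one aligned sample.

    ``mode`` selects the estimator pair: ``short`` uses median intron depth
    and max(SpliceLeft, SpliceRight); ``long`` uses minimum depth and
    ExactSplice.  ``jitter`` defaults to 0 (short) / 3 (long).
    """
    if mode not in ("short", "long"):
        raise ValueError(f"mode must be 'short' or 'long', got {mode!r}")
    if jitter is None:
        jitter = DEFAULT_JITTER[mode]
    own = isinstance(alignments, str)
    bam = pysam.AlignmentFile(alignments) if own else alignments
    try:
        records = []
        for unit in catalog:
            profile = depth_profile(bam, unit, mapq=mapq, stranded=stranded)
            counts = count_splices(bam, unit, jitter, mapq=mapq, stranded=stranded)
            no_eval = False
            try:
                if mode == "short":
                    a_i = intron_abundance_short(profile)
                else:
                    a_i = intron_abundance_long(profile)
            except NoEvaluablePositionsError:
                a_i, no_eval = 0.0, True
            a_e = (
                exon_abundance_short(counts)
                if mode == "short"
                else exon_abundance_long(counts)
            )
            rec = IRRecord(
                contig=unit.contig,
                start=unit.start,
                end=unit.end,
                strand=unit.strand,
                name="{}/{}".format(
                    ",".join(unit.gene_ids), ",".join(unit.transcript_ids)
                ),
                a_i=a_i,
                a_e=a_e,
                splice_left=counts.splice_left,
                splice_right=counts.splice_right,
                exact_splice=counts.exact_splice,
            )
            rec.warnings = assign_warnings(
                rec,
                mode,
                lowcover_min_depth,
                minor_isoform_fraction,
                no_evaluable=no_eval,
            )
            records.append(rec)
        return records
    finally:
        if own:
            bam.close()


def classify(record: IRRecord, threshold: float) -> bool:
    """Call an intron retained: IRratio at or above threshold and no warnings."""
    return record.irratio >= threshold and not record.warnings


def _fmt_num(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else repr(float(x))


def write_ir_table(
    records: Iterable[IRRecord], stream: TextIO, digits: int = 3
) -> None:
    """Write the per-sample result table (tab-delimited, 1-based inclusive).

    The printed IRratio is rounded to ``digits`` decimals for display; a
    reader recovers the exact value from the abundance columns.
    """
    stream.write("\t".join(TABLE_COLUMNS) + "\n")
    for r in records:
        fields = [
            r.contig,
            str(r.start + 1),
            str(r.end),
            r.name,
            "0",
            r.strand,
            str(r.exact_splice),
            str(r.splice_left),
            str(r.splice_right),
            _fmt_num(r.a_i),
            _fmt_num(r.a_e),
            format_irratio(r.irratio, digits),
            ",".join(r.warnings) if r.warnings else "-",
        ]
        stream.write("\t".join(fields) + "\n")


def read_ir_table(stream: TextIO) -> list[IRRecord]:
    """Parse a result table back into records (inverse of write_ir_table)."""
    header = stream.readline().rstrip("\n").split("\t")
    if header != TABLE_COLUMNS:
        raise ValueError(f"unexpected result-table header: {header}")
    records = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        f = line.split("\t")
        warn_field = f[12]
        records.append(
            IRRecord(
                contig=f[0],
                start=int(f[1]) - 1,
                end=int(f[2]),
                strand=f[5],
                name=f[3],
                a_i=float(f[9]),
                a_e=float(f[10]),
                splice_left=int(f[7]),
                splice_right=int(f[8]),
                exact_splice=int(f[6]),
                warnings=tuple(warn_field.split(",")) if warn_field != "-" else (),
            )
        )
    return records
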