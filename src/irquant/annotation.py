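"""Gene annotation parsing and intron catalog construction.

The quantification unit throughout the package is the annotated intron: the
gap between two consecutive exons of a transcript, carrying the donor and
acceptor splice boundaries and a per-base exclusion mask.  Intronic positions
overlapped by exons of *other* transcripts, or by user-supplied
low-mappability regions, are masked out of all depth statistics, because read
coverage there cannot be attributed to retention of this intron.

Coordinates are 0-based half-open internally; text outputs (BED, result
tables) use the 1-based inclusive convention of the GTF/BED ecosystem.
"""

from __future__ import annotations

import sys
import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

__all__ = [
    "GtfParseError",
    "Transcript",
    "GenomeAnnotation",
    "IntronUnit",
    "ExclusionMask",
    "parse_annotation",
    "build_intron_catalog",
    "build_exclusion_mask",
    "attach_masks",
    "read_bed_intervals",
    "catalog_to_bed",
    "intron_id",
]

REASON_OVERLAP = "overlapping-feature"
REASON_MAPPABILITY = "low-mappability"


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    #: ordered, non-overlapping (start, end) 0-based half-open intervals
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    """Parsed gene models: transcripts with ordered exons, grouped by gene."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)
    #: contig name -> rightmost annotated coordinate (a lower bound on length)
    contig_lengths: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class IntronUnit:
    """One annotated intron; the unit of IR quantification.

    ``start``/``end`` delimit the intron body (0-based half-open).  The donor
    is the boundary at the 5' end of the intron on its strand, the acceptor
    the 3' one; both coincide with the outer intron boundaries.  ``mask``
    holds half-open sub-intervals of the body excluded from depth statistics.
    """

    contig: str
    start: int
    end: int
    strand: str
    gene_ids: tuple[str, ...]
    transcript_ids: tuple[str, ...]
    mask: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"intron has non-positive length: {self}")
        for s, e in self.mask:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"mask interval ({s},{e}) outside intron body")

    @property
    def donor(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return intron_id(self.contig, self.start, self.end, self.strand)


def intron_id(contig: str, start: int, end: int, strand: str) -> str:
    """Canonical intron key, 1-based inclusive for display: ``chr:101-200:+``."""
    return f"{contig}:{start + 1}-{end}:{strand}"


@dataclass
class ExclusionMask:
    """Per-contig merged excluded intervals, tagged by reason."""

    #: reason -> contig -> sorted merged (start, end) intervals
    intervals: dict[str, dict[str, list[tuple[int, int]]]] = field(
        default_factory=dict
    )

    def add(self, reason: str, contig: str, start: int, end: int) -> None:
        self.intervals.setdefault(reason, {}).setdefault(contig, []).append(
            (start, end)
        )

    def merge(self) -> None:
        for per_contig in self.intervals.values():
            for contig, ivals in per_contig.items():
                per_contig[contig] = _merge_intervals(ivals)

    def overlapping(self, contig: str, start: int, end: int) -> list[tuple[int, int]]:
        """All excluded sub-intervals of [start, end), any reason, merged."""
        hits: list[tuple[int, int]] = []
        for per_contig in self.intervals.values():
            for s, e in per_contig.get(contig, ()):
                if s < end and e > start:
                    hits.append((max(s, start), min(e, end)))
        return _merge_intervals(hits)


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    # tolerates both `key "value";` and `key value;` forms
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_annotation(gtf_stream: TextIO | Iterable[str]) -> GenomeAnnotation:
    """Parse a GTF text stream into a :class:`GenomeAnnotation`.

    Only ``exon`` features are structural (grouped by ``transcript_id``);
    ``gene``/``transcript`` lines register identifiers and all other feature
    types are ignored.  Malformed lines raise :class:`GtfParseError` naming
    the line number; an exon without a ``transcript_id`` is an error.
    """
    ann = GenomeAnnotation()
    for lineno, line in enumerate(gtf_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        contig, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
        if start1 < 1 or end1 < start1:
            raise GtfParseError(f"line {lineno}: invalid interval {start1}-{end1}")
        start, end = start1 - 1, end1  # GTF is 1-based inclusive
        ann.contig_lengths[contig] = max(ann.contig_lengths.get(contig, 0), end)
        if feature not in ("gene", "transcript", "exon"):
            continue
        attrs = _parse_attributes(attr_s, lineno)
        gene_id = attrs.get("gene_id", "")
        if feature == "gene":
            ann.genes.setdefault(gene_id, [])
            continue
        tx_id = attrs.get("transcript_id")
        if not tx_id:
            raise GtfParseError(f"line {lineno}: {feature} without transcript_id")
        tx = ann.transcripts.get(tx_id)
        if tx is None:
            tx = Transcript(tx_id, gene_id, contig, strand)
            ann.transcripts[tx_id] = tx
            ann.genes.setdefault(gene_id, []).append(tx_id)
        if feature == "exon":
            tx.exons.append((start, end))
    for tx in ann.transcripts.values():
        tx.exons.sort()
        for (s1, e1), (s2, _e2) in zip(tx.exons, tx.exons[1:]):
            if s2 < e1:
                raise GtfParseError(
                    f"transcript {tx.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{_e2})"
                )
    return ann


def build_intron_catalog(annotation: GenomeAnnotation) -> list[IntronUnit]:
    """Derive the catalog of quantifiable introns from an annotation.

    One unit per gap between consecutive exons of each transcript; units with
    identical (contig, start, end, strand) from different transcripts are
    collapsed, retaining all parent gene/transcript ids.  Transcripts with a
    single exon contribute nothing.  Deterministic: catalog sorted by
    coordinates, parent ids sorted within each unit.
    """
    by_key: dict[tuple[str, int, int, str], tuple[set[str], set[str]]] = {}
    for tx_id in sorted(annotation.transcripts):
        tx = annotation.transcripts[tx_id]
        for (_, left_end), (right_start, _) in zip(tx.exons, tx.exons[1:]):
            if right_start <= left_end:
                continue  # adjacent exons leave no gap
            key = (tx.contig, left_end, right_start, tx.strand)
            genes, txs = by_key.setdefault(key, (set(), set()))
            genes.add(tx.gene_id)
            txs.add(tx_id)
    catalog = [
        IntronUnit(
            contig=contig,
            start=start,
            end=end,
            strand=strand,
            gene_ids=tuple(sorted(genes)),
            transcript_ids=tuple(sorted(txs)),
        )
        for (contig, start, end, strand), (genes, txs) in sorted(by_key.items())
    ]
    return catalog


def read_bed_intervals(
    bed_stream: TextIO | Iterable[str],
    known_contigs: set[str] | None = None,
) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (0-based half-open, as BED is defined).

    Intervals on contigs absent from ``known_contigs`` are skipped with a
    warning rather than failing the run.
    """
    out: list[tuple[str, int, int]] = []
    for lineno, line in enumerate(bed_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        contig, start, end = fields[0], int(fields[1]), int(fields[2])
        if known_contigs is not None and contig not in known_contigs:
            _warnings.warn(
                f"BED line {lineno}: unknown contig {contig!r}, interval skipped",
                stacklevel=2,
            )
            continue
        out.append((contig, start, end))
    return out


def build_exclusion_mask(
    annotation: GenomeAnnotation,
    mappability_regions: Sequence[tuple[str, int, int]] | None = None,
) -> ExclusionMask:
    """Build the genome-wide exclusion mask.

    Every annotated exon is an excluded region tagged ``overlapping-feature``
    (a parent transcript's own exons never intersect its introns, so when the
    mask is intersected with an intron body only *other* transcripts'
    exons contribute).  Optional low-mappability intervals are tagged
    ``low-mappability``.
    """
    mask = ExclusionMask()
    for tx in annotation.transcripts.values():
        for s, e in tx.exons:
            mask.add(REASON_OVERLAP, tx.contig, s, e)
    if mappability_regions:
        known = set(annotation.contig_lengths)
        for contig, s, e in mappability_regions:
            if contig not in known:
                _warnings.warn(
                    f"low-mappability interval on unknown contig {contig!r} skipped",
                    stacklevel=2,
                )
                continue
            mask.add(REASON_MAPPABILITY, contig, s, e)
    mask.merge()
    return mask


def attach_masks(
    catalog: Sequence[IntronUnit], exclusion: ExclusionMask
) -> list[IntronUnit]:
    """Return the catalog with each intron's mask filled in from ``exclusion``."""
    return [
        replace(
            unit,
            mask=tuple(exclusion.overlapping(unit.contig, unit.start, unit.end)),
        )
        for unit in catalog
    ]


def catalog_to_bed(catalog: Sequence[IntronUnit], stream: TextIO = sys.stdout) -> None:
    """Serialize the intron catalog as BED6 (name = gene/transcript ids)."""
    for unit in catalog:
        name = "{}/{}".format(",".join(unit.gene_ids), ",".join(unit.transcript_ids))
        stream.write(
            f"{unit.contig}\t{unit.start}\t{unit.end}\t{name}\t0\t{unit.strand}\n"
        )
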