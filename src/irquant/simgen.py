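"""Synthetic annotations and aligned reads with known intron-retention truth.

Every generator here plants a ground truth (per-intron retention fraction,
splice-endpoint jitter magnitude, masked regions, group differences) and is
fully reproducible from its seed, so the quantification, CNN-filter and
differential modules can be exercised end to end without external data.

Reads are emitted directly as coordinate-level alignments (sorted, indexed
BAM): transcript copies are tiled with non-overlapping reads so each copy
contributes exactly one unit of coverage, retention is decided per intron
per copy with the planted probability, and spliced junctions become CIGAR
``N`` gaps — optionally displaced endpoint-by-endpoint to emulate the
basecalling jitter of long reads.  There is no sequence-level error model:
aligners are outside this package, alignment coordinates are the simulated
object.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pysam
from scipy.special import expit, logit

from .annotation import IntronUnit, intron_id
from .quantify import IRRecord, assign_warnings

__all__ = [
    "SimTruth",
    "SimIntron",
    "SimGene",
    "simulate_model",
    "simulate_short_reads",
    "simulate_long_reads",
    "simulate_groups",
    "write_truth_table",
]

CONTIG = "simchr"


@dataclass(frozen=True)
class SimIntron:
    key: str
    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    true_ir: float


@dataclass
class SimGene:
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    #: planted IR fraction per intron, in transcript order
    intron_ir: list[float]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1[1], e2[0]) for e1, e2 in zip(self.exons, self.exons[1:])
        ]


@dataclass
class SimTruth:
    """Ground truth bookkeeping for one simulated gene model."""

    genes: list[SimGene]
    introns: dict[str, SimIntron]
    contig: str
    contig_length: int
    seed: int
    #: spans occupied by planted antisense exons (mask truth)
    masked_regions: list[tuple[str, int, int]] = field(default_factory=list)
    #: single-exon antisense genes (generate opposite-strand coverage)
    antisense_genes: list[SimGene] = field(default_factory=list)


def simulate_model(
    n_genes: int = 5,
    introns_per_gene: int = 3,
    seed: int = 0,
    *,
    ir_values: Sequence[float] | None = None,
    exon_length: int = 100,
    intron_length: int = 200,
    plant_antisense: bool = False,
) -> tuple[str, SimTruth]:
    """Build toy multi-exon gene models and return (GTF text, truth).

    Genes sit on one synthetic contig, plus strand, regularly spaced.  Each
    intron gets a planted retention fraction: cycled from ``ir_values`` if
    given, otherwise drawn from {0, 0.1, 0.3, 0.5}.  With
    ``plant_antisense`` a single-exon minus-strand gene is placed inside the
    first intron of the first gene, which must end up masked downstream.
    """
    rng = np.random.default_rng(seed)
    genes: list[SimGene] = []
    introns: dict[str, SimIntron] = {}
    gene_span = (introns_per_gene + 1) * exon_length + introns_per_gene * intron_length
    spacing = gene_span + 1000
    ir_idx = 0
    for g in range(n_genes):
        offset = 1000 + g * spacing
        exons = []
        pos = offset
        for _ in range(introns_per_gene + 1):
            exons.append((pos, pos + exon_length))
            pos += exon_length + intron_length
        gene_id = f"g{g + 1}"
        gene = SimGene(gene_id, f"{gene_id}.t1", CONTIG, "+", exons, [])
        for istart, iend in gene.introns:
            if ir_values is not None:
                r = float(ir_values[ir_idx % len(ir_values)])
                ir_idx += 1
            else:
                r = float(rng.choice([0.0, 0.1, 0.3, 0.5]))
            gene.intron_ir.append(r)
            key = intron_id(CONTIG, istart, iend, "+")
            introns[key] = SimIntron(key, CONTIG, istart, iend, "+", gene_id, r)
        genes.append(gene)
    truth = SimTruth(
        genes=genes,
        introns=introns,
        contig=CONTIG,
        contig_length=1000 + n_genes * spacing + 1000,
        seed=seed,
    )
    if plant_antisense and genes and genes[0].introns:
        istart, iend = genes[0].introns[0]
        a_start, a_end = istart + 50, min(istart + 90, iend)
        anti = SimGene("anti1", "anti1.t1", CONTIG, "-", [(a_start, a_end)], [])
        truth.antisense_genes.append(anti)
        truth.masked_regions.append((CONTIG, a_start, a_end))
    return _render_gtf(truth), truth


def _render_gtf(truth: SimTruth) -> str:
    buf = io.StringIO()
    for gene in truth.genes + truth.antisense_genes:
        lo, hi = gene.exons[0][0], gene.exons[-1][1]
        attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.transcript_id}";'
        gene_attrs = f'gene_id "{gene.gene_id}";'
        buf.write(
            f"{gene.contig}\tsim\tgene\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t{gene_attrs}\n"
        )
        buf.write(
            f"{gene.contig}\tsim\ttranscript\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t{attrs}\n"
        )
        for s, e in gene.exons:
            buf.write(
                f"{gene.contig}\tsim\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
    return buf.getvalue()


def _isoform_blocks(
    gene: SimGene, retained: Sequence[bool]
) -> list[tuple[int, int]]:
    """Genomic blocks of one molecule: exons plus retained introns, merged."""
    blocks: list[tuple[int, int]] = [gene.exons[0]]
    for keep, (istart, iend), exon in zip(retained, gene.introns, gene.exons[1:]):
        if keep:  # retained intron bridges into the next exon
            blocks[-1] = (blocks[-1][0], exon[1])
        else:
            blocks.append(exon)
    return blocks


def _tile_reads(
    blocks: Sequence[tuple[int, int]],
    read_length: int,
    phase: int,
    jitter_fn=None,
) -> Iterable[tuple[int, list[tuple[int, int]]]]:
    """Tile a molecule with non-overlapping reads; yield (pos, cigartuples).

    Reads are laid back to back along transcript coordinates starting at a
    random phase so every transcript base is covered exactly once per copy.
    ``jitter_fn(gap_start, gap_end)`` may displace gap endpoints.
    """
    tlen = sum(e - s for s, e in blocks)
    p = phase % read_length
    starts = range(p - read_length if p else 0, tlen, read_length)
    for ts in starts:
        te = min(ts + read_length, tlen)
        ts = max(ts, 0)
        if te <= ts:
            continue
        yield _transcript_to_genome(blocks, ts, te, jitter_fn)


def _transcript_to_genome(
    blocks: Sequence[tuple[int, int]], ts: int, te: int, jitter_fn=None
) -> tuple[int, list[tuple[int, int]]]:
    """Map transcript interval [ts, te) to (pos, cigartuples) with N gaps."""
    segs: list[tuple[int, int]] = []  # genomic sub-blocks covered
    off = 0
    for bs, be in blocks:
        blen = be - bs
        lo, hi = max(ts - off, 0), min(te - off, blen)
        if lo < hi:
            segs.append((bs + lo, bs + hi))
        off += blen
        if off >= te:
            break
    if jitter_fn is not None and len(segs) > 1:
        segs = _apply_gap_jitter(segs, jitter_fn)
    pos = segs[0][0]
    cig: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(segs):
        if i:
            cig.append((3, s - segs[i - 1][1]))  # N
        cig.append((0, e - s))  # M
    return pos, cig


def _apply_gap_jitter(segs, jitter_fn):
    out = [list(segs[0])]
    for nxt in segs[1:]:
        gap_s, gap_e = out[-1][1], nxt[0]
        d1, d2 = jitter_fn(gap_s, gap_e)
        out[-1][1] = gap_s + d1
        out.append([nxt[0] + d2, nxt[1]])
    return [tuple(x) for x in out]


def _write_bam(
    path: str,
    contig: str,
    contig_length: int,
    reads: Iterable[tuple[str, str, int, list[tuple[int, int]]]],
) -> str:
    """Write (name, strand, pos, cigar) alignments as a sorted, indexed BAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": contig, "LN": contig_length}],
    }
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for name, strand, pos, cig in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = 16 if strand == "-" else 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = cig
            qlen = sum(l for op, l in cig if op in (0, 1, 7, 8))
            a.query_sequence = "A" * qlen
            out.write(a)
    pysam.sort("-o", path, tmp)
    os.remove(tmp)
    pysam.index(path)
    return path


def _gene_reads_short(gene, gene_idx, depth, read_length, rng):
    for copy in range(depth):
        retained = [rng.random() < r for r in gene.intron_ir]
        blocks = _isoform_blocks(gene, retained)
        phase = int(rng.integers(read_length))
        for i, (pos, cig) in enumerate(_tile_reads(blocks, read_length, phase)):
            yield (f"g{gene_idx}c{copy}r{i}", gene.strand, pos, cig)


def simulate_short_reads(
    truth: SimTruth,
    depth: int = 100,
    read_length: int = 75,
    seed: int = 0,
    path: str = "short.bam",
) -> str:
    """Emit short reads: ``depth`` molecule copies per gene, tiled reads.

    Spliced molecules produce gapped reads with exact annotated boundaries;
    molecules retaining an intron tile straight through it, so the intron's
    median depth approaches ``depth x true_ir`` while the junction tallies
    approach ``depth x (1 - true_ir)``.
    """
    rng = np.random.default_rng(seed)

    def reads():
        for gi, gene in enumerate(truth.genes):
            yield from _gene_reads_short(gene, gi, depth, read_length, rng)
        for ai, anti in enumerate(truth.antisense_genes):
            yield from _gene_reads_short(anti, 1000 + ai, depth, read_length, rng)

    return _write_bam(path, truth.contig, truth.contig_length, reads())


def simulate_long_reads(
    truth: SimTruth,
    depth: int = 100,
    endpoint_noise: int = 0,
    seed: int = 0,
    path: str = "long.bam",
    alt3_fraction: Mapping[str, float] | None = None,
    alt3_extent: float = 0.6,
) -> str:
    """Emit long reads: one full-length read per molecule copy.

    Spliced junctions get independent per-endpoint displacements drawn
    uniformly from ``[-endpoint_noise, endpoint_noise]``, emulating the
    boundary imprecision that the jitter-tolerant splice counter absorbs.
    ``alt3_fraction`` maps intron keys to the fraction of molecules that use
    an alternative 3' end: those reads run from the transcript start into
    the intron and stop at ``alt3_extent`` of its length, creating partial
    intron coverage with no evidence over the 3' remainder.
    """
    rng = np.random.default_rng(seed)
    alt3_fraction = alt3_fraction or {}

    def jitter_fn(_gs, _ge):
        if endpoint_noise == 0:
            return 0, 0
        return (
            int(rng.integers(-endpoint_noise, endpoint_noise + 1)),
            int(rng.integers(-endpoint_noise, endpoint_noise + 1)),
        )

    def reads():
        for gi, gene in enumerate(truth.genes):
            alt3_at = None
            for idx, (istart, iend) in enumerate(gene.introns):
                key = intron_id(gene.contig, istart, iend, gene.strand)
                if key in alt3_fraction:
                    alt3_at = (idx, istart, iend, alt3_fraction[key])
                    break
            for copy in range(depth):
                if alt3_at is not None and rng.random() < alt3_at[3]:
                    idx, istart, iend, _ = alt3_at
                    stop = istart + int(alt3_extent * (iend - istart))
                    retained = [rng.random() < r for r in gene.intron_ir[:idx]]
                    blocks = _isoform_blocks(
                        SimGene(
                            gene.gene_id,
                            gene.transcript_id,
                            gene.contig,
                            gene.strand,
                            gene.exons[: idx + 1],
                            gene.intron_ir[:idx],
                        ),
                        retained,
                    )
                    blocks[-1] = (blocks[-1][0], stop)  # run into the intron
                    pos, cig = _transcript_to_genome(
                        blocks, 0, sum(e - s for s, e in blocks), jitter_fn
                    )
                else:
                    retained = [rng.random() < r for r in gene.intron_ir]
                    blocks = _isoform_blocks(gene, retained)
                    pos, cig = _transcript_to_genome(
                        blocks, 0, sum(e - s for s, e in blocks), jitter_fn
                    )
                yield (f"g{gi}c{copy}", gene.strand, pos, cig)

    return _write_bam(path, truth.contig, truth.contig_length, reads())


def simulate_groups(
    truth: SimTruth,
    n_per_group: int = 3,
    delta_map: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    conditions: Sequence[str] = ("ctrl", "case"),
    depth: int = 100,
    sigma: float = 0.2,
) -> dict[str, list[dict[str, IRRecord]]]:
    """Simulate replicate-level IR result tables for two or more conditions.

    Per replicate and intron, the planted retention fraction receives
    logit-normal biological noise (scale ``sigma``; structural 0/1 stay
    fixed), the informative depth is Poisson around ``depth`` with a
    lognormal library-size factor, and the intronic count is binomial —
    yielding the overdispersed counts the differential tests must cope
    with.  ``delta_map`` adds a retention shift in every non-reference
    condition (all conditions after the first).
    """
    rng = np.random.default_rng(seed)
    delta_map = delta_map or {}
    out: dict[str, list[dict[str, IRRecord]]] = {}
    for ci, cond in enumerate(conditions):
        samples = []
        for _rep in range(n_per_group):
            lib = float(rng.lognormal(0.0, 0.1))
            recs: dict[str, IRRecord] = {}
            for key, intron in truth.introns.items():
                r = intron.true_ir + (delta_map.get(key, 0.0) if ci > 0 else 0.0)
                r = min(max(r, 0.0), 1.0)
                if 0.0 < r < 1.0:
                    r = float(expit(logit(r) + rng.normal(0.0, sigma)))
                d = int(rng.poisson(depth * lib))
                n_i = int(rng.binomial(d, r)) if d > 0 else 0
                n_s = d - n_i
                rec = IRRecord(
                    contig=intron.contig,
                    start=intron.start,
                    end=intron.end,
                    strand=intron.strand,
                    name=f"{intron.gene_id}/{intron.gene_id}.t1",
                    a_i=float(n_i),
                    a_e=float(n_s),
                    splice_left=n_s,
                    splice_right=n_s,
                    exact_splice=n_s,
                )
                rec.warnings = assign_warnings(rec, "short")
                recs[key] = rec
            samples.append(recs)
        out[cond] = samples
    return out


def simulate_cnn_examples(
    n_per_class: int = 100,
    seed: int = 0,
    noise: float = 1.0,
    flank: int = 30,
    width: int = 160,
):
    """Labeled coverage arrays emulating genuine vs artifactual IR loci.

    Genuine events show even intron-body coverage at a fraction of the
    flanking-exon depth with Poisson counting noise and a mild linear tilt.
    Artifacts mimic what misleads the short-read estimator: a partial
    coverage block (alternative end), a few narrow spikes (repeat pile-ups),
    or ramps decaying from the exon edges — all with strong splice support.
    ``noise`` scales the Poisson sampling (0 disables it).  Arrays are
    rendered through the same transform used on real profiles.
    """
    from .cnnfilter import FALSE_IR, TRUE_IR, LabeledExample, make_input_array
    from .signal import DepthProfile, SpliceCounts

    rng = np.random.default_rng(seed)
    examples = []

    def sample_depth(mean_profile):
        if noise <= 0:
            return np.asarray(mean_profile, dtype=float)
        return rng.poisson(np.maximum(mean_profile, 0.0) * noise) / noise

    for label in (TRUE_IR, FALSE_IR):
        for i in range(n_per_class):
            ilen = int(rng.integers(150, 600))
            exon_depth = float(rng.uniform(30, 120))
            body = np.zeros(ilen)
            if label == TRUE_IR:
                ir = float(rng.uniform(0.15, 0.6))
                tilt = rng.uniform(-0.3, 0.3)
                level = ir * exon_depth
                body = level * (1 + tilt * np.linspace(-1, 1, ilen))
                spliced = (1 - ir) * exon_depth
            else:
                kind = rng.integers(3)
                peak = float(rng.uniform(0.2, 0.7)) * exon_depth
                if kind == 0:  # partial block (alternative end)
                    w = int(rng.uniform(0.2, 0.6) * ilen)
                    s = int(rng.integers(0, ilen - w + 1))
                    body[s : s + w] = peak
                elif kind == 1:  # narrow spikes
                    for _ in range(int(rng.integers(1, 4))):
                        w = int(rng.integers(5, 25))
                        s = int(rng.integers(0, ilen - w + 1))
                        body[s : s + w] += peak
                else:  # edge ramps
                    ramp = int(rng.uniform(0.1, 0.3) * ilen)
                    body[:ramp] = peak * np.linspace(1, 0, ramp)
                    body[-ramp:] = peak * np.linspace(0, 1, ramp)
                spliced = exon_depth
            start = 10_000 * (i + 1)
            unit = IntronUnit(
                contig="cnn_sim",
                start=start,
                end=start + ilen,
                strand="+",
                gene_ids=(f"sim{label}{i}",),
                transcript_ids=(f"sim{label}{i}.t1",),
            )
            prof = DepthProfile(
                intron=unit,
                depth=sample_depth(body).astype(np.int64),
                mask=np.zeros(ilen, dtype=bool),
                left_flank=sample_depth(np.full(flank, exon_depth)),
                right_flank=sample_depth(np.full(flank, exon_depth)),
            )
            n_spl = int(max(spliced, 0))
            counts = SpliceCounts(n_spl, n_spl, n_spl, jitter=0)
            examples.append(
                LabeledExample(make_input_array(prof, counts, flank, width), label)
            )
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]


def write_truth_table(
    truth: SimTruth,
    stream: TextIO,
    delta_map: Mapping[str, float] | None = None,
    conditions: Sequence[str] = ("ctrl",),
) -> None:
    """Write the planted truth: intron id, condition, true IRratio."""
    delta_map = delta_map or {}
    stream.write("intron\tcondition\ttrue_irratio\n")
    for ci, cond in enumerate(conditions):
        for key, intron in truth.introns.items():
            r = intron.true_ir + (delta_map.get(key, 0.0) if ci > 0 else 0.0)
            r = min(max(r, 0.0), 1.0)
            stream.write(f"{key}\t{cond}\t{r:.4f}\n")
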