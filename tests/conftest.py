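import io

import pytest

from irquant import annotation as ann
from irquant import simgen

TOY_GTF = """\
chr1\ttoy\tgene\t1\t300\t.\t+\t.\tgene_id "gA";
chr1\ttoy\ttranscript\t1\t300\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttoy\texon\t201\t300\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
"""


@pytest.fixture
def toy_annotation():
    return ann.parse_annotation(io.StringIO(TOY_GTF))


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A 5-gene model with planted IR levels plus short- and long-read BAMs."""
    d = tmp_path_factory.mktemp("sim")
    gtf_text, truth = simgen.simulate_model(
        5, 3, seed=7, ir_values=[0.0, 0.1, 0.3, 0.5]
    )
    annotation = ann.parse_annotation(io.StringIO(gtf_text))
    catalog = ann.attach_masks(
        ann.build_intron_catalog(annotation), ann.build_exclusion_mask(annotation)
    )
    short_bam = simgen.simulate_short_reads(
        truth, depth=200, seed=8, path=str(d / "short.bam")
    )
    long_bam = simgen.simulate_long_reads(
        truth, depth=200, endpoint_noise=2, seed=9, path=str(d / "long.bam")
    )
    return {
        "gtf": gtf_text,
        "truth": truth,
        "annotation": annotation,
        "catalog": catalog,
        "short_bam": short_bam,
        "long_bam": long_bam,
    }
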