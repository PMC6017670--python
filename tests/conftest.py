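import textwrap

import pysam
import pytest

from race3seq.pipeline import run_pipeline
from race3seq.refmodel import GeneModelSet, GenomeSequence, TranscriptModel
from race3seq.simulator import SimConfig, simulate

SIM_SEED = 11


@pytest.fixture(scope="session")
def sim():
    """One full simulated two-experiment run shared by the suite."""
    return simulate(SimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def pipe(sim):
    """Pipeline output on the shared simulation's truth alignments."""
    return run_pipeline(sim.contigs, sim.genes, sim.alignments)


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    """Small FASTA + GFF3 pair: one two-model gene and one single-exon gene."""
    d = tmp_path_factory.mktemp("toyref")
    seq = ("ACGT" * 120)[:480]
    fa = d / "toy.fa"
    fa.write_text(f">ctg\n{seq}\n")
    gff = d / "toy.gff3"
    gff.write_text(
        textwrap.dedent(
            """\
            ##gff-version 3
            ctg\ttoy\tgene\t1\t380\t.\t+\t.\tID=g1
            ctg\ttoy\tmRNA\t1\t380\t.\t+\t.\tID=g1.m1;Parent=g1
            ctg\ttoy\texon\t1\t100\t.\t+\t.\tParent=g1.m1
            ctg\ttoy\texon\t151\t250\t.\t+\t.\tParent=g1.m1
            ctg\ttoy\texon\t301\t380\t.\t+\t.\tParent=g1.m1
            ctg\ttoy\tCDS\t31\t100\t.\t+\t0\tParent=g1.m1
            ctg\ttoy\tCDS\t151\t250\t.\t+\t0\tParent=g1.m1
            ctg\ttoy\tCDS\t301\t330\t.\t+\t0\tParent=g1.m1
            ctg\ttoy\tmRNA\t1\t380\t.\t+\t.\tID=g1.m2;Parent=g1
            ctg\ttoy\texon\t1\t100\t.\t+\t.\tParent=g1.m2
            ctg\ttoy\texon\t301\t380\t.\t+\t.\tParent=g1.m2
            ctg\ttoy\tgene\t391\t470\t.\t+\t.\tID=g2
            ctg\ttoy\tmRNA\t391\t470\t.\t+\t.\tID=g2.m1;Parent=g2
            ctg\ttoy\texon\t391\t470\t.\t+\t.\tParent=g2.m1
            """
        )
    )
    return fa, gff


def make_minus_gene(gene_id="gm", contig="ctg"):
    """Hand-drawn minus-strand gene: exons [0,100) and [150,250), CDS [50,200)."""
    model = TranscriptModel(
        model_id="Model 1",
        exons=[(0, 100), (150, 250)],
        strand="-",
        cds=(50, 200),
        utr5=[(200, 250)],
        utr3=[(0, 50)],
    )
    return GeneModelSet(gene_id=gene_id, contig=contig, strand="-", models=[model])


@pytest.fixture
def minus_gene():
    return make_minus_gene()


def make_header(contig="ctg", length=10000):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": length}]}
    )


def spliced_read(header, name, start, blocks, md=None, nm=0, seq_char="A"):
    """A single-end spliced read with M/N CIGAR from genomic match blocks."""
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.flag = 0
    seg.reference_id = 0
    seg.reference_start = start
    seg.mapping_quality = 60
    cig = []
    qlen = 0
    pos = start
    for i, (a, b) in enumerate(blocks):
        if i:
            cig.append((3, a - pos))
        cig.append((0, b - a))
        qlen += b - a
        pos = b
    seg.cigartuples = cig
    seg.query_sequence = seq_char * qlen
    seg.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    seg.set_tag("NM", nm)
    if md is not None:
        seg.set_tag("MD", md)
    return seg


@pytest.fixture
def plain_genome():
    """A 600-nt genome with a canonical GT..AG intron at [200, 320)."""
    seq = list("GC" * 300)
    seq[200:202] = "GT"
    seq[318:320] = "AG"
    return GenomeSequence("ctg", "".join(seq))


@pytest.fixture
def plus_gene():
    model = TranscriptModel(
        model_id="Model 1",
        exons=[(50, 200), (320, 550)],
        strand="+",
        cds=(80, 500),
        utr5=[(50, 80)],
        utr3=[(500, 550)],
    )
    return {
        "g+": GeneModelSet(gene_id="g+", contig="ctg", strand="+", models=[model])
    }
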