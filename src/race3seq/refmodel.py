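"""Reference genome and gene-model handling.

Loads a FASTA genome and a GFF3 annotation into strand-aware containers and
answers the two questions the rest of the pipeline keeps asking: "what is the
sequence of this window on the transcribed strand?" and "which region of the
gene (5'-UTR / exon / intron / 3'-UTR / intergenic) does this position fall
in, according to a given transcript model?".

All coordinates are 0-based, half-open on the genome forward strand. GFF3
(1-based, inclusive) is converted at the parsing boundary and nowhere else.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedAnnotationError(ValueError):
    """Annotation feature is inconsistent with the genome or gene structure."""


class MissingSequenceError(KeyError):
    """Annotation refers to a contig absent from the genome FASTA."""


class Region(str, enum.Enum):
    """Transcript-relative region of a genomic position."""

    UTR5 = "UTR5"
    EXON = "EXON"
    INTRON = "INTRON"
    UTR3 = "UTR3"
    INTERGENIC = "INTERGENIC"


@dataclass
class GenomeSequence:
    """One contig, upper-cased, with strand-aware slicing.

    Parameters
    ----------
    contig_name:
        FASTA record id.
    sequence:
        Forward-strand sequence over {A, C, G, T, N}.
    """

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"contig {self.contig_name!r} has empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the requested strand.

        The minus-strand result is the reverse complement of the forward
        slice, i.e. it reads 5'->3' on the transcribed strand of a
        minus-strand gene.
        """
        if start < 0 or end > len(self.sequence) or start > end:
            raise IndexError(
                f"interval [{start}, {end}) out of bounds for contig "
                f"{self.contig_name!r} of length {len(self.sequence)}"
            )
        s = self.sequence[start:end]
        return revcomp(s) if strand == "-" else s

    def fetch_clipped(self, start: int, end: int, strand: str = "+") -> str:
        """Like :meth:`fetch` but truncates the window at contig edges."""
        return self.fetch(max(start, 0), min(end, len(self.sequence)), strand)


@dataclass
class TranscriptModel:
    """One annotated transcript (mRNA) of a gene.

    Exons are non-overlapping half-open intervals sorted in genomic order;
    introns are the gaps between consecutive exons. ``cds``, ``utr5`` and
    ``utr3`` partition the exonic extent when all are present.
    """

    model_id: str
    exons: list[tuple[int, int]]
    strand: str
    cds: tuple[int, int] | None = None
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise MalformedAnnotationError(
                    f"model {self.model_id}: overlapping exons [{a},{b}) and [{c},{d})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        ]

    def donor_acceptor(self, intron: tuple[int, int]) -> tuple[int, int]:
        """(donor, acceptor) genomic boundary coordinates of an intron.

        On the plus strand the donor is the intron start and the acceptor the
        intron end; on the minus strand the roles flip.
        """
        s, e = intron
        return (s, e) if self.strand == "+" else (e, s)


@dataclass
class GeneModelSet:
    """All transcript models of one gene plus the 3'-RACE primer anchor.

    ``inner_primer_pos`` is the genomic coordinate of the inner gene-specific
    primer's 5' anchor — primers sit adjacent to the initiation codon so that
    the amplicon covers most of the gene body downstream of it.
    """

    gene_id: str
    contig: str
    strand: str
    models: list[TranscriptModel]
    inner_primer_pos: int | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise MalformedAnnotationError(f"gene {self.gene_id}: no transcript models")
        if self.inner_primer_pos is None:
            # Default anchor: the initiation codon of the first model.
            m = self.models[0]
            if m.cds is not None:
                self.inner_primer_pos = m.cds[0] if self.strand == "+" else m.cds[1] - 1
            else:
                self.inner_primer_pos = m.start if self.strand == "+" else m.end - 1

    @property
    def start(self) -> int:
        return min(m.start for m in self.models)

    @property
    def end(self) -> int:
        return max(m.end for m in self.models)

    def model(self, model_id: str) -> TranscriptModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(f"gene {self.gene_id}: unknown model {model_id!r}")

    @property
    def all_introns(self) -> set[tuple[int, int]]:
        """Union of annotated introns across every model of the gene."""
        out: set[tuple[int, int]] = set()
        for m in self.models:
            out.update(m.introns)
        return out


def classify_position(gene: GeneModelSet, pos: int, model_id: str) -> Region:
    """Region of ``pos`` relative to one named transcript model.

    Strand-aware: the 5'-UTR is 5' on the transcribed strand, so for a
    minus-strand gene it occupies the genomically *last* exonic segment.
    Positions outside the model span are INTERGENIC; exonic positions inside
    an annotated (or CDS-derived) UTR get the UTR label, remaining exonic
    positions are EXON, and gaps between exons are INTRON.
    """
    model = gene.model(model_id)
    if pos < model.start or pos >= model.end:
        return Region.INTERGENIC
    for a, b in model.utr5:
        if a <= pos < b:
            return Region.UTR5
    for a, b in model.utr3:
        if a <= pos < b:
            return Region.UTR3
    for a, b in model.exons:
        if a <= pos < b:
            return Region.EXON
    return Region.INTRON


def _derive_utrs(model: TranscriptModel) -> None:
    """Fill utr5/utr3 from CDS vs exon extent when GFF3 lacks UTR features."""
    if model.cds is None or (model.utr5 or model.utr3):
        return
    cs, ce = model.cds
    left: list[tuple[int, int]] = []
    right: list[tuple[int, int]] = []
    for a, b in model.exons:
        if a < cs:
            left.append((a, min(b, cs)))
        if b > ce:
            right.append((max(a, ce), b))
    if model.strand == "+":
        model.utr5, model.utr3 = left, right
    else:
        model.utr5, model.utr3 = right, left


def load_reference(
    genome_path: str | Path,
    annotation_path: str | Path,
    primary_model_attribute: str | None = None,
) -> tuple[dict[str, GenomeSequence], dict[str, GeneModelSet]]:
    """Load a FASTA genome and GFF3 annotation.

    Every GFF3 ``mRNA`` becomes a :class:`TranscriptModel`. Models of a gene
    are renamed "Model 1", "Model 2", ... in file order, except that a model
    whose attributes contain ``primary_model_attribute`` (truthy value) is
    promoted to "Model 1" — annotation sources differ in how they order
    primary vs alternative models, so the designation is configurable.

    Returns
    -------
    (contigs, genes):
        ``contigs`` maps contig name to :class:`GenomeSequence`; ``genes``
        maps gene id to :class:`GeneModelSet`.
    """
    fasta = Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    contigs = {name: GenomeSequence(name, str(fasta[name][:])) for name in fasta.keys()}

    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, GeneModelSet] = {}
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid not in contigs:
            raise MissingSequenceError(
                f"gene {gene.id}: contig {gene.seqid!r} not in genome FASTA"
            )
        contig = contigs[gene.seqid]
        models: list[TranscriptModel] = []
        primary_idx: int | None = None
        for i, mrna in enumerate(db.children(gene, featuretype="mRNA", order_by="start")):
            exons = []
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                if ex.end > len(contig) or ex.start < 1:
                    raise MalformedAnnotationError(
                        f"exon of {mrna.id} at {ex.start}-{ex.end} outside contig "
                        f"{gene.seqid!r} (length {len(contig)})"
                    )
                exons.append((ex.start - 1, ex.end))
            if not exons:
                raise MalformedAnnotationError(f"mRNA {mrna.id} has no exons")
            span = (min(a for a, _ in exons), max(b for _, b in exons))
            if span[0] < gene.start - 1 or span[1] > gene.end:
                raise MalformedAnnotationError(
                    f"mRNA {mrna.id} exons exceed gene {gene.id} span"
                )
            cds_feats = list(db.children(mrna, featuretype="CDS", order_by="start"))
            cds = None
            if cds_feats:
                cds = (min(c.start for c in cds_feats) - 1, max(c.end for c in cds_feats))
            utr5 = [
                (u.start - 1, u.end)
                for u in db.children(mrna, featuretype="five_prime_UTR", order_by="start")
            ]
            utr3 = [
                (u.start - 1, u.end)
                for u in db.children(mrna, featuretype="three_prime_UTR", order_by="start")
            ]
            model = TranscriptModel(
                model_id=mrna.id, exons=exons, strand=gene.strand, cds=cds,
                utr5=utr5, utr3=utr3,
            )
            _derive_utrs(model)
            models.append(model)
            if primary_model_attribute and mrna.attributes.get(primary_model_attribute):
                val = mrna.attributes[primary_model_attribute][0].lower()
                if val not in ("0", "false", "no", ""):
                    primary_idx = i
        if not models:
            continue
        if primary_idx is not None and primary_idx != 0:
            models.insert(0, models.pop(primary_idx))
        for i, m in enumerate(models):
            m.model_id = f"Model {i + 1}"
        genes[gene.id] = GeneModelSet(
            gene_id=gene.id, contig=gene.seqid, strand=gene.strand, models=models
        )
    return contigs, genes
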