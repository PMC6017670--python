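"""Splice-junction extraction and artifact triage.

A 3'-RACE amplicon library covers a handful of target genes at very high
depth, so junction calling is dominated not by sensitivity but by telling
authentic splice sites apart from PCR artifacts. Three signals drive the
triage:

* **canonical dinucleotides** — authentic plant introns virtually always
  begin GT and end AG on the transcribed strand, while deletion chimeras
  seeded by direct-repeat mega-primers produce arbitrary boundary sequence;
* **direct repetitive sequences (DRS)** — an incomplete extension product
  ending inside a repeat copy can re-anneal at the other copy and loop out
  the intervening fragment, so chimeric junctions tend to be flanked by
  repeats (>=4 bp, often 6-10 bp) whose copies each end at a junction
  boundary;
* **reproducibility between independent amplifications** — low-copy
  templates amplify early or late at random (the Monte Carlo effect), so
  junctions seen in only one of two independent experiments are suspect.

The verdict itself rests on the dinucleotide rule (canonical = authentic);
DRS length and reproducibility are reported as supporting evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pysam
from intervaltree import IntervalTree

from race3seq.refmodel import GeneModelSet, GenomeSequence

WELL = "WELL"
POOR = "POOR"
AUTHENTIC = "AUTHENTIC"
SUSPECT_ARTIFACT = "SUSPECT_ARTIFACT"

#: DRS length at or above which a repeat is reported at all.
DRS_FLAG_MIN = 4
#: DRS length at or above which the repeat counts as "long".
DRS_LONG_MIN = 6


class MalformedJunctionError(ValueError):
    """Intron interval too short to carry donor and acceptor dinucleotides."""


class CoverageInconsistencyError(ValueError):
    """Junction reads reported for a gene with zero covering reads."""


@dataclass
class JunctionCall:
    """One observed splice junction with its evidence trail.

    ``intron_start``/``intron_end`` delimit the skipped (intronic) interval,
    half-open on the genome forward strand. Support and percentage coverage
    are tracked per experiment; ``dinucleotides`` are the first and last two
    intron bases read on the transcribed strand.
    """

    contig: str
    strand: str
    intron_start: int
    intron_end: int
    gene_id: str
    reads_by_experiment: dict[str, int] = field(default_factory=dict)
    pct_coverage_by_experiment: dict[str, float] = field(default_factory=dict)
    dinucleotides: tuple[str, str] | None = None
    canonical: bool | None = None
    coverage_class: str | None = None
    drs_up_len: int = 0
    drs_down_len: int = 0
    reproducible: bool | None = None
    verdict: str | None = None
    ambiguous_gene: bool = False

    def __post_init__(self) -> None:
        if self.intron_end - self.intron_start < 4:
            raise MalformedJunctionError(
                f"intron [{self.intron_start},{self.intron_end}) shorter than 4 nt"
            )

    @property
    def total_reads(self) -> int:
        return sum(self.reads_by_experiment.values())

    @property
    def long_drs(self) -> bool:
        """A repeat of >=6 bp flanks the junction (artifact-prone geometry)."""
        return max(self.drs_up_len, self.drs_down_len) >= DRS_LONG_MIN


def percentage_coverage(junction_reads: int, gene_reads: int) -> float:
    """Reads spanning the intron / reads covering the target gene x 100 (%)."""
    if junction_reads < 0 or gene_reads < 0:
        raise ValueError("read counts must be non-negative")
    if gene_reads == 0:
        if junction_reads == 0:
            return 0.0
        raise CoverageInconsistencyError(
            f"{junction_reads} junction reads but 0 gene-covering reads"
        )
    return 100.0 * junction_reads / gene_reads


def classify_coverage(call: JunctionCall, well_min_reads: int = 3800) -> str:
    """WELL iff total support across experiments strictly exceeds the cutoff."""
    return WELL if call.total_reads > well_min_reads else POOR


def classify_canonical(call: JunctionCall, genome: GenomeSequence) -> bool:
    """True iff the intron begins GT and ends AG on the transcribed strand."""
    if call.intron_end - call.intron_start < 4:
        raise MalformedJunctionError("intron shorter than 4 nt")
    fwd_donor = genome.fetch(call.intron_start, call.intron_start + 2)
    fwd_acceptor = genome.fetch(call.intron_end - 2, call.intron_end)
    if call.strand == "+":
        donor, acceptor = fwd_donor, fwd_acceptor
    else:
        # Transcribed-strand donor is the revcomp of the forward acceptor end.
        donor = genome.fetch(call.intron_end - 2, call.intron_end, "-")
        acceptor = genome.fetch(call.intron_start, call.intron_start + 2, "-")
    call.dinucleotides = (donor, acceptor)
    call.canonical = donor == "GT" and acceptor == "AG"
    return call.canonical


def drs_lengths(
    call: JunctionCall, genome: GenomeSequence, max_scan: int = 15
) -> tuple[int, int]:
    """Longest direct repeat with one copy ending (resp. starting) at each boundary.

    The mega-primer geometry places one repeat copy immediately upstream of
    each junction boundary (``drs_up_len``: longest L with
    ``genome[start-L:start] == genome[end-L:end]``) or immediately downstream
    of each (``drs_down_len``: longest L with
    ``genome[start:start+L] == genome[end:end+L]``). Repeat identity is
    strand-symmetric so both are computed on the forward strand, capped at
    ``max_scan`` and truncated at contig edges.
    """
    s, e = call.intron_start, call.intron_end
    n = len(genome)
    up = 0
    for length in range(1, max_scan + 1):
        if s - length < 0:
            break
        if genome.sequence[s - length : s] == genome.sequence[e - length : e]:
            up = length
    down = 0
    for length in range(1, max_scan + 1):
        if e + length > n:
            break
        if genome.sequence[s : s + length] == genome.sequence[e : e + length]:
            down = length
    call.drs_up_len, call.drs_down_len = up, down
    return up, down


def assess_reproducibility(
    calls: list[JunctionCall],
    experiments: Iterable[str] | None = None,
    min_detect: int = 1,
) -> dict[str, int]:
    """Mark each call reproducible iff supported in every experiment.

    Returns the three-way partition used in the replicate Venn summaries:
    counts of junctions detected only in the first experiment, in both/all,
    and only in later experiments.
    """
    if not calls:
        return {"first_only": 0, "all": 0, "rest_only": 0}
    if experiments is None:
        exps: list[str] = sorted({e for c in calls for e in c.reads_by_experiment})
    else:
        exps = list(experiments)
    if len(exps) < 2:
        warnings.warn(
            "fewer than two experiments: reproducibility cannot be assessed",
            stacklevel=2,
        )
        for c in calls:
            c.reproducible = None
        return {"first_only": 0, "all": 0, "rest_only": 0}
    partition = {"first_only": 0, "all": 0, "rest_only": 0}
    for c in calls:
        detected = [c.reads_by_experiment.get(e, 0) >= min_detect for e in exps]
        c.reproducible = all(detected)
        if c.reproducible:
            partition["all"] += 1
        elif detected[0]:
            partition["first_only"] += 1
        else:
            partition["rest_only"] += 1
    return partition


def junction_verdict(call: JunctionCall) -> str:
    """AUTHENTIC iff canonical; DRS length is evidence, not the decision rule."""
    if call.canonical is None:
        raise ValueError("classify_canonical must run before junction_verdict")
    call.verdict = AUTHENTIC if call.canonical else SUSPECT_ARTIFACT
    return call.verdict


def _gene_trees(genes: Mapping[str, GeneModelSet]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes.values():
        trees.setdefault(g.contig, IntervalTree())[g.start : g.end] = g
    return trees


def _assign_gene(
    genes_hit: list[GeneModelSet], intron: tuple[int, int]
) -> tuple[list[GeneModelSet], bool]:
    """Pick host gene(s) for a junction; ties go to every candidate, flagged.

    When two genes overlap the intron, prefer the one whose inner-primer
    anchor lies upstream of the junction on the transcribed strand (the
    amplicon that could actually contain it); if that still leaves several,
    report to all with the ambiguity flag set.
    """
    if len(genes_hit) <= 1:
        return genes_hit, False
    s, e = intron
    upstream = [
        g
        for g in genes_hit
        if (g.strand == "+" and g.inner_primer_pos <= s)
        or (g.strand == "-" and g.inner_primer_pos >= e - 1)
    ]
    cands = upstream or genes_hit
    return cands, len(cands) > 1


def _read_mismatch_positions(read: pysam.AlignedSegment) -> list[int]:
    """Reference positions of substitution mismatches, from MD/NM if present."""
    if not read.has_tag("MD") and not read.has_tag("NM"):
        return []
    if read.has_tag("NM") and read.get_tag("NM") == 0:
        return []
    if not read.has_tag("MD"):
        return []
    pos = []
    try:
        for qpos, refpos, refbase in read.get_aligned_pairs(with_seq=True):
            if qpos is None or refpos is None or refbase is None:
                continue
            if refbase.islower():
                pos.append(refpos)
    except ValueError:
        return []
    return pos


def _junctions_of(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Intron intervals implied by the read's N CIGAR operations."""
    out = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            pos += length
        elif op == 3:  # N
            out.append((pos, pos + length))
            pos += length
    return out


def extract_junctions(
    alignments: Mapping[str, str | Path | Iterable[pysam.AlignedSegment]],
    genes: Mapping[str, GeneModelSet],
    min_reads: int = 10,
    max_mismatch_near_ss: int = 1,
    ss_window: int = 10,
) -> list[JunctionCall]:
    """Extract splice junctions from per-experiment spliced alignments.

    Parameters
    ----------
    alignments:
        Map of experiment id to a SAM/BAM path (or an iterable of mapped
        ``pysam.AlignedSegment``).
    genes:
        Target gene models; junctions not overlapping any target gene are
        ignored, as are alignments on unknown contigs (counted, warned).
    min_reads:
        A junction is retained if its support reaches this threshold in at
        least one experiment. Support is recorded for every experiment,
        including zeros.
    max_mismatch_near_ss:
        Reads with more than this many substitution mismatches within
        ``ss_window`` nt of either junction boundary do not count toward that
        junction's support.

    Returns calls sorted by (contig, intron_start, intron_end), with
    per-experiment percentage coverage (junction reads / gene-covering reads
    x 100) already filled in. Canonical status, DRS lengths, coverage class
    and verdicts are computed by the dedicated functions downstream.
    """
    trees = _gene_trees(genes)
    exp_ids = list(alignments.keys())
    # (contig, s, e, gene_id) -> per-experiment counts
    support: dict[tuple[str, int, int, str], dict[str, int]] = {}
    meta: dict[tuple[str, int, int, str], tuple[str, bool]] = {}
    gene_reads: dict[tuple[str, str], int] = {}
    skipped_unknown = 0

    for exp in exp_ids:
        src = alignments[exp]
        if isinstance(src, (str, Path)):
            handle = pysam.AlignmentFile(str(src), check_sq=False)
            reads: Iterable[pysam.AlignedSegment] = handle
        else:
            handle = None
            reads = src
        counted_gene_read: set[tuple[str, str]] = set()
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            contig = read.reference_name
            if contig not in trees:
                skipped_unknown += 1
                continue
            hits = trees[contig][read.reference_start : read.reference_end]
            for hit in hits:
                key = (exp, hit.data.gene_id)
                # Count each template once per gene (paired mates share a name).
                tkey = (read.query_name, hit.data.gene_id)
                if tkey in counted_gene_read:
                    continue
                counted_gene_read.add(tkey)
                gene_reads[key] = gene_reads.get(key, 0) + 1
            introns = _junctions_of(read)
            if not introns:
                continue
            mm = _read_mismatch_positions(read)
            for s, e in introns:
                if mm:
                    near = sum(
                        1
                        for p in mm
                        if abs(p - s) <= ss_window
                        or abs(p - (e - 1)) <= ss_window
                    )
                    if near > max_mismatch_near_ss:
                        continue
                genes_hit = [iv.data for iv in trees[contig][s:e]]
                host, ambiguous = _assign_gene(genes_hit, (s, e))
                for g in host:
                    jkey = (contig, s, e, g.gene_id)
                    support.setdefault(jkey, {ex: 0 for ex in exp_ids})
                    support[jkey][exp] += 1
                    meta[jkey] = (g.strand, ambiguous)
        if handle is not None:
            handle.close()

    if skipped_unknown:
        warnings.warn(
            f"{skipped_unknown} alignment(s) on contigs absent from the "
            "annotation were skipped",
            stacklevel=2,
        )

    calls: list[JunctionCall] = []
    for (contig, s, e, gene_id), counts in support.items():
        if max(counts.values()) < min_reads:
            continue
        strand, ambiguous = meta[(contig, s, e, gene_id)]
        pct = {
            exp: percentage_coverage(counts[exp], gene_reads.get((exp, gene_id), 0))
            for exp in exp_ids
        }
        calls.append(
            JunctionCall(
                contig=contig,
                strand=strand,
                intron_start=s,
                intron_end=e,
                gene_id=gene_id,
                reads_by_experiment=dict(counts),
                pct_coverage_by_experiment=pct,
                ambiguous_gene=ambiguous,
            )
        )
    calls.sort(key=lambda c: (c.contig, c.intron_start, c.intron_end, c.gene_id))
    return calls


def annotate_junctions(
    calls: list[JunctionCall],
    contigs: Mapping[str, GenomeSequence],
    well_min_reads: int = 3800,
    max_scan: int = 15,
    min_detect: int = 1,
) -> dict[str, int]:
    """Run the full evidence chain on freshly extracted calls, in place.

    Computes canonical status, DRS lengths, coverage class, reproducibility
    and the final verdict; returns the reproducibility partition.
    """
    for c in calls:
        genome = contigs[c.contig]
        classify_canonical(c, genome)
        drs_lengths(c, genome, max_scan=max_scan)
        c.coverage_class = classify_coverage(c, well_min_reads)
    partition = assess_reproducibility(calls, min_detect=min_detect)
    for c in calls:
        junction_verdict(c)
    return partition
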