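"""Polyadenylation-site calling with internal-priming removal.

Reads carrying a poly(A) tail followed by the 3'-RACE adaptor pin the
cleavage site of the molecule they came from — unless the oligo(dT) adaptor
annealed to an A-rich stretch *inside* the transcript during reverse
transcription (internal priming), which yields a truncated cDNA whose end
mimics a cleavage site. Because genuine tails (tens of adenosines) out-prime
short internal A-tracts, internal-priming artifacts betray themselves by the
genomic adenosine content immediately downstream of the apparent site and by
poor reproducibility between independent amplifications.

Candidate sites are screened by two region-specific criterion cascades. In
5'-UTR / exon / intron, where internal priming dominates, the stringent
cascade requires: (1) downstream A-stretch <= 1; (2) <= 3 adenosines in the
downstream 10-nt window; (3) no candidate failing (1) or (2) within +/-5 nt
(guards against primer sliding around an A-tract); (4) detection in every
independent experiment. In the 3'-UTR, where most sites are genuine, the
lenient cascade requires stretch <= 3, window <= 4 and reproducibility.
Surviving "marker" sites within 50 nt of each other are chained into
polyadenylation site clusters (PACs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from race3seq.refmodel import GeneModelSet, GenomeSequence, Region, revcomp

#: Downstream-window A count at or above which a site is an internal-priming suspect.
INTERNAL_PRIMING_MIN_A = 5


@dataclass(frozen=True)
class AdaptorSpec:
    """The anchored oligo(dT) 3'-RACE adaptor.

    ``stem`` is the constant 5' part of the RT primer; the tail is twelve T's
    plus a VN anchor that seats the primer at the tail/transcript boundary.
    On the mRNA-sense strand of an amplicon the adaptor therefore appears as
    the reverse complement of the stem, immediately preceded by the poly(A)
    run. ``min_stem_match`` exact 5' bases of that reverse complement are
    required to call the adaptor in a read.
    """

    stem: str = "GCGAGCACAGAATTAATACGACTCACTATAGG"
    tail: str = "T" * 12 + "VN"
    min_stem_match: int = 12

    def __post_init__(self) -> None:
        if not self.stem:
            raise ValueError("adaptor stem must be non-empty")
        if self.min_stem_match > len(self.stem):
            raise ValueError("min_stem_match exceeds stem length")

    @property
    def rc_stem(self) -> str:
        return revcomp(self.stem)


@dataclass
class TailedRead:
    """A read with its poly(A) tail and adaptor trimmed off."""

    name: str
    trimmed_seq: str
    tail_len: int
    flipped: bool  # adaptor found on the reverse complement of the input


@dataclass
class PASCall:
    """One candidate cleavage/polyadenylation site.

    ``cleavage_pos`` is the genomic coordinate of the last transcribed base.
    ``a_stretch_len`` counts consecutive genomic adenosines immediately 3' of
    the site on the transcribed strand; ``a_count_10nt`` counts adenosines in
    the downstream 10-nt window. ``criteria_flags`` records the outcome of
    each cascade criterion by name.
    """

    contig: str
    strand: str
    cleavage_pos: int
    gene_id: str
    region: Region
    reads_by_experiment: dict[str, int] = field(default_factory=dict)
    a_stretch_len: int = 0
    a_count_10nt: int = 0
    window_truncated: bool = False
    criteria_flags: dict[str, bool] = field(default_factory=dict)
    marker: bool = False

    @property
    def internal_priming_suspect(self) -> bool:
        return self.a_count_10nt >= INTERNAL_PRIMING_MIN_A

    @property
    def total_reads(self) -> int:
        return sum(self.reads_by_experiment.values())


@dataclass
class PACluster:
    """A chain of marker sites within the clustering gap of each other."""

    member_sites: list[PASCall]

    @property
    def span(self) -> tuple[int, int]:
        pos = [m.cleavage_pos for m in self.member_sites]
        return (min(pos), max(pos) + 1)

    @property
    def total_reads(self) -> int:
        return sum(m.total_reads for m in self.member_sites)

    @property
    def representative(self) -> PASCall:
        """Member with the highest support (ties: 5'-most on the genome)."""
        return max(self.member_sites, key=lambda m: (m.total_reads, -m.cleavage_pos))


def find_polyA_reads(
    reads: Iterable[tuple[str, str]],
    adaptor: AdaptorSpec | None = None,
    min_tail_A: int = 8,
) -> tuple[list[TailedRead], int]:
    """Select reads whose 3' end carries a poly(A) run plus the adaptor.

    ``reads`` yields (name, sequence) pairs (mRNA-sense or antisense; both
    orientations are searched). A read qualifies if a run of at least
    ``min_tail_A`` adenosines is immediately followed by the reverse
    complement of the adaptor stem (at least ``min_stem_match`` exact 5'
    bases of it). The returned reads are trimmed at the last base before the
    A-run, with the tail length recorded. Reads showing the adaptor without a
    preceding A-run are rejected and counted in the second return value.
    """
    if adaptor is None:
        adaptor = AdaptorSpec()
    probe = adaptor.rc_stem[: adaptor.min_stem_match]
    out: list[TailedRead] = []
    n_rejected = 0
    for name, seq in reads:
        seq = seq.upper()
        hit = None
        for flipped, s in ((False, seq), (True, revcomp(seq))):
            idx = s.find(probe)
            while idx != -1:
                tail = 0
                while idx - tail - 1 >= 0 and s[idx - tail - 1] == "A":
                    tail += 1
                if tail >= min_tail_A:
                    hit = TailedRead(name, s[: idx - tail], tail, flipped)
                    break
                idx = s.find(probe, idx + 1)
            if hit is not None:
                break
        if hit is not None:
            out.append(hit)
        elif probe in seq or probe in revcomp(seq):
            n_rejected += 1
    return out, n_rejected


def _three_prime_end(read: pysam.AlignedSegment, strand: str) -> int:
    """Genomic coordinate of the read's 3'-terminal aligned base (transcribed strand)."""
    return read.reference_end - 1 if strand == "+" else read.reference_start


def _trim_templated_A(pos: int, strand: str, genome: GenomeSequence) -> int:
    """Slide the cleavage site upstream past trailing genomic adenosines.

    Genuine tail adenosines and genomically templated ones are
    indistinguishable in the read, so every trailing A is trimmed and the
    site placed at the last remaining aligned base (the 5'-most, i.e.
    leftmost, consistent placement).
    """
    if strand == "+":
        while pos >= 0 and genome.sequence[pos] == "A":
            pos -= 1
    else:
        while pos < len(genome) and genome.sequence[pos] == "T":
            pos += 1
    return pos


def call_candidate_pas(
    alignments: Mapping[str, str | Path | Iterable[pysam.AlignedSegment]],
    genes: Mapping[str, GeneModelSet],
    contigs: Mapping[str, GenomeSequence],
    polya_read_names: set[str] | None = None,
    min_reads: int = 5,
    reference_models: Mapping[str, str] | None = None,
) -> list[PASCall]:
    """Aggregate 3' read ends into candidate cleavage sites.

    Parameters
    ----------
    alignments:
        Per-experiment SAM/BAM paths or alignment iterables of the trimmed
        poly(A) reads.
    polya_read_names:
        When given, only alignments whose query name is in this set (the
        output of :func:`find_polyA_reads`) are used.
    min_reads:
        A position becomes a candidate with at least this many reads in at
        least one experiment.
    reference_models:
        Optional gene_id -> model_id map (the dominant model per gene) used
        for region assignment; defaults to "Model 1".

    Downstream adenosine profiles are filled in for every returned candidate.
    """
    from race3seq.refmodel import classify_position

    exp_ids = list(alignments.keys())
    counts: dict[tuple[str, int], dict[str, int]] = {}
    gene_span = [(g, g.start, g.end) for g in genes.values()]

    def _host_gene(contig: str, pos: int) -> GeneModelSet | None:
        best = None
        for g, s, e in gene_span:
            if g.contig == contig and s <= pos < e + 500:  # allow 3'-UTR overhang
                if best is None or abs(pos - (s + e) // 2) < abs(
                    pos - (best.start + best.end) // 2
                ):
                    best = g
        return best

    n_skipped = 0
    for exp in exp_ids:
        src = alignments[exp]
        if isinstance(src, (str, Path)):
            handle = pysam.AlignmentFile(str(src), check_sq=False)
            reads: Iterable[pysam.AlignedSegment] = handle
        else:
            handle = None
            reads = src
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if polya_read_names is not None and read.query_name not in polya_read_names:
                continue
            contig = read.reference_name
            if contig not in contigs:
                n_skipped += 1
                continue
            gene = _host_gene(contig, read.reference_start)
            if gene is None:
                continue
            genome = contigs[contig]
            end = _three_prime_end(read, gene.strand)
            if end < 0 or end >= len(genome):
                n_skipped += 1
                continue
            pos = _trim_templated_A(end, gene.strand, genome)
            if pos < 0 or pos >= len(genome):
                n_skipped += 1
                continue
            key = (gene.gene_id, pos)
            counts.setdefault(key, {e: 0 for e in exp_ids})
            counts[key][exp] += 1
        if handle is not None:
            handle.close()
    if n_skipped:
        warnings.warn(f"{n_skipped} trimmed read(s) fell outside usable bounds", stacklevel=2)

    out: list[PASCall] = []
    for (gene_id, pos), per_exp in counts.items():
        if max(per_exp.values()) < min_reads:
            continue
        gene = genes[gene_id]
        model_id = (
            reference_models.get(gene_id, gene.models[0].model_id)
            if reference_models
            else gene.models[0].model_id
        )
        call = PASCall(
            contig=gene.contig,
            strand=gene.strand,
            cleavage_pos=pos,
            gene_id=gene_id,
            region=classify_position(gene, pos, model_id),
            reads_by_experiment=dict(per_exp),
        )
        profile_downstream_A(call, contigs[gene.contig])
        out.append(call)
    out.sort(key=lambda c: (c.contig, c.cleavage_pos, c.gene_id))
    return out


def profile_downstream_A(
    pas: PASCall, genome: GenomeSequence, window: int = 10
) -> tuple[int, int]:
    """Adenosine profile of the window 3' of the cleavage site.

    Returns (a_stretch_len, a_count_10nt), computed on the transcribed
    strand over positions cleavage_pos+1 .. cleavage_pos+window. N bases
    count as non-A. A window truncated by the contig edge is flagged and the
    thresholds downstream apply to the available bases.
    """
    if pas.strand == "+":
        start, end = pas.cleavage_pos + 1, pas.cleavage_pos + 1 + window
        seq = genome.fetch_clipped(start, end, "+")
    else:
        start, end = pas.cleavage_pos - window, pas.cleavage_pos
        seq = genome.fetch_clipped(start, end, "-")
    pas.window_truncated = len(seq) < window
    count = seq.count("A")
    stretch = 0
    for base in seq:
        if base != "A":
            break
        stretch += 1
    if stretch == len(seq) == window:
        # The run may continue past the window; extend until it stops.
        pos = end if pas.strand == "+" else start - 1
        step = 1 if pas.strand == "+" else -1
        target = "A" if pas.strand == "+" else "T"
        while 0 <= pos < len(genome) and genome.sequence[pos] == target:
            stretch += 1
            pos += step
    pas.a_stretch_len, pas.a_count_10nt = stretch, count
    return stretch, count


def _reproducible(call: PASCall, exp_ids: Sequence[str], min_detect: int) -> bool:
    return all(call.reads_by_experiment.get(e, 0) >= min_detect for e in exp_ids)


def filter_internal_region(
    candidates: list[PASCall],
    max_stretch: int = 1,
    max_window_a: int = 3,
    neighborhood: int = 5,
    min_detect: int = 1,
) -> list[PASCall]:
    """Stringent cascade for candidates in 5'-UTR / exon / intron.

    Marker iff (1) downstream A-stretch <= ``max_stretch``; (2) downstream
    10-nt window has <= ``max_window_a`` adenosines; (3) no candidate failing
    (1) or (2) lies within ``neighborhood`` nt up- or downstream (judged
    against the full pre-filter candidate set of the same gene and strand);
    and (4) the site is detected in every experiment. Candidates outside the
    internal regions are left untouched. Returns the new markers.
    """
    exp_ids = sorted({e for c in candidates for e in c.reads_by_experiment})
    internal = {Region.UTR5, Region.EXON, Region.INTRON}
    failing_pos: dict[tuple[str, str], list[int]] = {}
    for c in candidates:
        if c.a_stretch_len > max_stretch or c.a_count_10nt > max_window_a:
            failing_pos.setdefault((c.gene_id, c.strand), []).append(c.cleavage_pos)
    markers = []
    for c in candidates:
        if c.region not in internal:
            continue
        f1 = c.a_stretch_len <= max_stretch
        f2 = c.a_count_10nt <= max_window_a
        bad = failing_pos.get((c.gene_id, c.strand), [])
        f3 = not any(
            p != c.cleavage_pos and abs(p - c.cleavage_pos) <= neighborhood for p in bad
        )
        f4 = _reproducible(c, exp_ids, min_detect)
        c.criteria_flags.update(
            {"stretch": f1, "window": f2, "neighborhood": f3, "reproducible": f4}
        )
        c.marker = f1 and f2 and f3 and f4
        if c.marker:
            markers.append(c)
    return markers


def filter_utr3(
    candidates: list[PASCall],
    max_stretch: int = 3,
    max_window_a: int = 4,
    min_detect: int = 1,
) -> list[PASCall]:
    """Lenient cascade for 3'-UTR candidates.

    Marker iff downstream A-stretch <= ``max_stretch``, downstream 10-nt
    window has <= ``max_window_a`` adenosines, and the site is detected in
    every experiment. Returns the new markers.
    """
    exp_ids = sorted({e for c in candidates for e in c.reads_by_experiment})
    markers = []
    for c in candidates:
        if c.region != Region.UTR3:
            continue
        f1 = c.a_stretch_len <= max_stretch
        f2 = c.a_count_10nt <= max_window_a
        f3 = _reproducible(c, exp_ids, min_detect)
        c.criteria_flags.update({"stretch": f1, "window": f2, "reproducible": f3})
        c.marker = f1 and f2 and f3
        if c.marker:
            markers.append(c)
    return markers


def apply_filters(candidates: list[PASCall], min_detect: int = 1) -> list[PASCall]:
    """Run the region-appropriate cascade on every candidate; return markers."""
    markers = filter_internal_region(candidates, min_detect=min_detect)
    markers += filter_utr3(candidates, min_detect=min_detect)
    return sorted(markers, key=lambda c: (c.contig, c.cleavage_pos))


def cluster_pacs(markers: list[PASCall], max_gap: int = 50) -> list[PACluster]:
    """Single-linkage chaining of markers into polyadenylation site clusters.

    Within each gene and strand, consecutive marker positions at most
    ``max_gap`` nt apart (inclusive) join one cluster; isolated markers come
    back as singleton clusters.
    """
    by_group: dict[tuple[str, str], list[PASCall]] = {}
    for m in markers:
        by_group.setdefault((m.gene_id, m.strand), []).append(m)
    clusters: list[PACluster] = []
    for key in sorted(by_group):
        sites = sorted(by_group[key], key=lambda m: m.cleavage_pos)
        current = [sites[0]]
        for site in sites[1:]:
            if site.cleavage_pos - current[-1].cleavage_pos <= max_gap:
                current.append(site)
            else:
                clusters.append(PACluster(current))
                current = [site]
        clusters.append(PACluster(current))
    clusters.sort(key=lambda c: (c.member_sites[0].contig, c.span[0]))
    return clusters
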