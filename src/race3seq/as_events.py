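"""Alternative-splicing event classification against a reference model.

Authentic junctions are compared to one reference transcript model per gene
(the dominant model by well-covered model-specific junction support — a
gene's most used alternative model can outrank the annotated primary one).
Each junction gets exactly one event type:

* ANNOTATED — intron equals a reference intron;
* A5SS / A3SS — shares the acceptor (resp. donor) of a reference intron but
  not the other boundary, donor/acceptor defined on the transcribed strand;
* A5A3SS — overlaps exactly one reference intron without sharing either
  boundary;
* ES (exon skipping) — the intron spans one or more complete reference
  exons, both boundaries lying in reference introns or matching reference
  boundaries; junctions straddling several reference introns without clean
  exon containment are also filed under ES with a ``complex`` flag;
* EI (exitron) — the intron lies strictly inside one reference exon;
  ``frame_preserving`` marks lengths divisible by three (EIx3), which delete
  amino acids in frame rather than shifting it.

Novelty is assessed against *all* annotated models of the gene, not just the
selected reference.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import pandas as pd

from race3seq.junctions import WELL, JunctionCall
from race3seq.refmodel import GeneModelSet, TranscriptModel


class EventType(str, enum.Enum):
    ANNOTATED = "ANNOTATED"
    A5SS = "A5SS"
    A3SS = "A3SS"
    A5A3SS = "A5A3SS"
    ES = "ES"
    EI = "EI"


class ClassificationError(ValueError):
    """Junction cannot be classified against the given model."""


@dataclass
class ASEvent:
    """One classified junction.

    ``skipped_exons`` holds 1-based indices (in transcription order) of the
    complete reference exons removed by an ES junction. ``frame_preserving``
    is only meaningful for EI events.
    """

    gene_id: str
    junction: JunctionCall
    event_type: EventType
    reference_model: str
    frame_preserving: bool | None = None
    skipped_exons: list[int] = field(default_factory=list)
    novel: bool = False
    complex: bool = False


def select_reference_model(gene: GeneModelSet, calls: list[JunctionCall]) -> str:
    """Dominant transcript model of the gene given observed junction support.

    Scores each model by the summed support of WELL-covered junctions that
    match introns specific to that model (annotated there and in no other
    model of the gene). Ties — including a gene with no well-covered
    model-specific support at all — default to "Model 1".
    """
    if len(gene.models) == 1:
        return gene.models[0].model_id
    intron_sets = {m.model_id: set(m.introns) for m in gene.models}
    scores: dict[str, int] = {}
    for m in gene.models:
        others: set[tuple[int, int]] = set()
        for other in gene.models:
            if other.model_id != m.model_id:
                others |= intron_sets[other.model_id]
        specific = intron_sets[m.model_id] - others
        scores[m.model_id] = sum(
            c.total_reads
            for c in calls
            if c.gene_id == gene.gene_id
            and c.coverage_class == WELL
            and (c.intron_start, c.intron_end) in specific
        )
    if not any(scores.values()):
        if not calls:
            warnings.warn(
                f"gene {gene.gene_id}: no junction support; defaulting to Model 1",
                stacklevel=2,
            )
        return gene.models[0].model_id
    best = max(scores.values())
    for m in gene.models:  # ties resolve to the primary model by order
        if scores[m.model_id] == best:
            return m.model_id
    return gene.models[0].model_id


def classify_event(
    call: JunctionCall, ref: TranscriptModel, gene: GeneModelSet | None = None
) -> ASEvent:
    """Assign exactly one AS event type to an authentic junction.

    ``gene`` (when given) supplies all annotated models for the novelty
    check; otherwise novelty is judged against ``ref`` alone.
    """
    s, e = call.intron_start, call.intron_end
    if s < ref.start - 1 or e > ref.end + 1:
        raise ClassificationError(
            f"junction [{s},{e}) outside model {ref.model_id} span "
            f"[{ref.start},{ref.end})"
        )
    gene_id = call.gene_id
    known = gene.all_introns if gene is not None else set(ref.introns)
    novel = (s, e) not in known
    ref_introns = ref.introns
    ev = lambda et, **kw: ASEvent(  # noqa: E731
        gene_id=gene_id,
        junction=call,
        event_type=et,
        reference_model=ref.model_id,
        novel=novel,
        **kw,
    )

    if (s, e) in ref_introns:
        return ev(EventType.ANNOTATED)

    # Exitron: strictly inside one annotated exon.
    for a, b in ref.exons:
        if a < s and e < b:
            return ev(EventType.EI, frame_preserving=(e - s) % 3 == 0)

    donor_pos, acceptor_pos = (s, e) if call.strand == "+" else (e, s)
    ref_boundaries = {x for i in ref_introns for x in i}
    shares_donor = any(ref.donor_acceptor(i)[0] == donor_pos for i in ref_introns)
    shares_acceptor = any(ref.donor_acceptor(i)[1] == acceptor_pos for i in ref_introns)

    def _in_ref_intron(pos: int) -> bool:
        return any(a <= pos <= b for a, b in ref_introns)

    # Exon skipping: intron spans >=1 complete reference exon, with both
    # boundaries in reference introns or at reference boundaries.
    exon_order = ref.exons if call.strand == "+" else ref.exons[::-1]
    skipped = [
        i + 1
        for i, (a, b) in enumerate(exon_order)
        if s < a and b < e  # strictly inside the observed intron
    ]
    if skipped:
        ok = all(
            pos in ref_boundaries or _in_ref_intron(pos) for pos in (s, e)
        )
        return ev(EventType.ES, skipped_exons=skipped, complex=not ok)

    overlapped = [i for i in ref_introns if i[0] < e and s < i[1]]
    if shares_acceptor and not shares_donor:
        return ev(EventType.A5SS)
    if shares_donor and not shares_acceptor:
        return ev(EventType.A3SS)
    if len(overlapped) == 1 and not shares_donor and not shares_acceptor:
        return ev(EventType.A5A3SS)
    if len(overlapped) >= 2:
        # Straddles several reference introns with no complete exon skipped.
        return ev(EventType.ES, complex=True)
    # No reference intron overlap and not inside a single exon (e.g. a
    # boundary-straddling novel intron): closest bucket is A5A3SS.
    return ev(EventType.A5A3SS)


def summarize_as(events: list[ASEvent]) -> pd.DataFrame:
    """Tabulate event counts per type with novelty and EIx3 splits.

    One row per event type (all types always present), with columns ``n``,
    ``novel``, ``frame_preserving`` (EIx3, EI rows only) and ``complex``.
    Counting is per junction.
    """
    rows = []
    for et in EventType:
        sub = [ev for ev in events if ev.event_type == et]
        rows.append(
            {
                "event_type": et.value,
                "n": len(sub),
                "novel": sum(ev.novel for ev in sub),
                "frame_preserving": sum(bool(ev.frame_preserving) for ev in sub)
                if et == EventType.EI
                else 0,
                "complex": sum(ev.complex for ev in sub),
            }
        )
    return pd.DataFrame(rows).set_index("event_type")
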