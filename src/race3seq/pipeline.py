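"""End-to-end orchestration: alignments in, junction/AS/PAS/PAC tables out.

Thin glue over the analysis modules. Holds the run-level thresholds (all of
them config), executes the stages in order, keeps a filter funnel (input =
passed + rejected at every stage) and writes deterministic, coordinate-sorted
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from race3seq import as_events as ase
from race3seq import junctions as jx
from race3seq import pas as pasmod
from race3seq.pas import AdaptorSpec
from race3seq.refmodel import GeneModelSet, GenomeSequence, load_reference


@dataclass
class Thresholds:
    """All pipeline thresholds, with the method's standard defaults."""

    min_ss_reads: int = 10
    max_mismatch_near_ss: int = 1
    ss_window: int = 10
    well_min_reads: int = 3800
    drs_max_scan: int = 15
    min_detect: int = 1
    min_pas_reads: int = 5
    min_tail_A: int = 8
    internal_max_stretch: int = 1
    internal_max_window_a: int = 3
    internal_neighborhood: int = 5
    utr3_max_stretch: int = 3
    utr3_max_window_a: int = 4
    pac_gap: int = 50

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")


@dataclass
class PipelineResult:
    junction_calls: list[jx.JunctionCall]
    venn: dict[str, int]
    reference_models: dict[str, str]
    events: list[ase.ASEvent]
    as_summary: pd.DataFrame
    candidates: list[pasmod.PASCall]
    markers: list[pasmod.PASCall]
    clusters: list[pasmod.PACluster]
    manifest: dict


def _read_seqs(source) -> Iterable[tuple[str, str]]:
    """(name, sequence) pairs from a SAM/BAM path or AlignedSegment iterable."""
    if isinstance(source, (str, Path)):
        with pysam.AlignmentFile(str(source), check_sq=False) as fh:
            for read in fh:
                if read.query_sequence:
                    yield read.query_name, read.query_sequence
    else:
        for read in source:
            if read.query_sequence:
                yield read.query_name, read.query_sequence


def run_pipeline(
    contigs: Mapping[str, GenomeSequence],
    genes: Mapping[str, GeneModelSet],
    alignments: Mapping[str, object],
    adaptor: AdaptorSpec | None = None,
    thresholds: Thresholds | None = None,
) -> PipelineResult:
    """Run junction calling, AS classification and PAS/PAC analysis.

    ``alignments`` maps experiment id to a SAM/BAM path or an in-memory list
    of ``pysam.AlignedSegment``.
    """
    th = thresholds or Thresholds()
    adaptor = adaptor or AdaptorSpec()

    calls = jx.extract_junctions(
        alignments,
        genes,
        min_reads=th.min_ss_reads,
        max_mismatch_near_ss=th.max_mismatch_near_ss,
        ss_window=th.ss_window,
    )
    venn = jx.annotate_junctions(
        calls,
        contigs,
        well_min_reads=th.well_min_reads,
        max_scan=th.drs_max_scan,
        min_detect=th.min_detect,
    )
    authentic = [c for c in calls if c.verdict == jx.AUTHENTIC]

    reference_models: dict[str, str] = {}
    events: list[ase.ASEvent] = []
    for gene_id in sorted(genes):
        gene = genes[gene_id]
        gene_calls = [c for c in calls if c.gene_id == gene_id]
        ref_id = ase.select_reference_model(gene, gene_calls)
        reference_models[gene_id] = ref_id
        ref = gene.model(ref_id)
        for c in gene_calls:
            if c.verdict == jx.AUTHENTIC:
                events.append(ase.classify_event(c, ref, gene))
    as_summary = ase.summarize_as(events)

    polya_sources = {e: _read_seqs(src) for e, src in alignments.items()}
    polya_names: set[str] = set()
    n_polya = 0
    n_no_tail = 0
    for exp, seqs in polya_sources.items():
        tailed, rejected = pasmod.find_polyA_reads(seqs, adaptor, th.min_tail_A)
        polya_names.update(t.name for t in tailed)
        n_polya += len(tailed)
        n_no_tail += rejected
    candidates = pasmod.call_candidate_pas(
        alignments,
        genes,
        contigs,
        polya_read_names=polya_names,
        min_reads=th.min_pas_reads,
        reference_models=reference_models,
    )
    internal_markers = pasmod.filter_internal_region(
        candidates,
        max_stretch=th.internal_max_stretch,
        max_window_a=th.internal_max_window_a,
        neighborhood=th.internal_neighborhood,
        min_detect=th.min_detect,
    )
    utr3_markers = pasmod.filter_utr3(
        candidates,
        max_stretch=th.utr3_max_stretch,
        max_window_a=th.utr3_max_window_a,
        min_detect=th.min_detect,
    )
    markers = sorted(
        internal_markers + utr3_markers, key=lambda c: (c.contig, c.cleavage_pos)
    )
    clusters = pasmod.cluster_pacs(markers, max_gap=th.pac_gap) if markers else []

    rejected_by = {"stretch": 0, "window": 0, "neighborhood": 0, "reproducible": 0}
    n_rejected = 0
    for c in candidates:
        if not c.marker:
            n_rejected += 1
            for k, ok in c.criteria_flags.items():
                if not ok:
                    rejected_by[k] += 1
    manifest = {
        "thresholds": asdict(th),
        "experiments": sorted(alignments.keys()),
        "junctions": {
            "called": len(calls),
            "authentic": len(authentic),
            "suspect_artifact": len(calls) - len(authentic),
            "well_covered": sum(c.coverage_class == jx.WELL for c in calls),
            "venn": venn,
        },
        "as_events": {row[0]: int(row[1]["n"]) for row in as_summary.iterrows()},
        "pas": {
            "polya_reads": n_polya,
            "adaptor_without_tail": n_no_tail,
            "candidates": len(candidates),
            "suspect_internal_priming": sum(
                c.internal_priming_suspect for c in candidates
            ),
            "markers": len(markers),
            "rejected": n_rejected,
            "rejected_by_criterion": rejected_by,
            "pacs": len(clusters),
        },
    }
    return PipelineResult(
        junction_calls=calls,
        venn=venn,
        reference_models=reference_models,
        events=events,
        as_summary=as_summary,
        candidates=candidates,
        markers=markers,
        clusters=clusters,
        manifest=manifest,
    )


def run_pipeline_files(
    genome_path: str | Path,
    annotation_path: str | Path,
    alignments: Mapping[str, str | Path],
    outdir: str | Path | None = None,
    adaptor: AdaptorSpec | None = None,
    thresholds: Thresholds | None = None,
    primary_model_attribute: str | None = None,
) -> PipelineResult:
    """File-based entry point; optionally writes the report bundle."""
    for label, p in [("genome", genome_path), ("annotation", annotation_path)] + [
        (f"alignments[{e}]", p) for e, p in alignments.items()
    ]:
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} path does not exist: {p}")
    contigs, genes = load_reference(
        genome_path, annotation_path, primary_model_attribute
    )
    result = run_pipeline(contigs, genes, alignments, adaptor, thresholds)
    if outdir is not None:
        write_report(result, Path(outdir))
    return result


def junctions_table(result: PipelineResult) -> pd.DataFrame:
    exps = result.manifest["experiments"]
    rows = []
    for c in result.junction_calls:
        row = {
            "contig": c.contig,
            "intron_start": c.intron_start,
            "intron_end": c.intron_end,
            "strand": c.strand,
            "gene_id": c.gene_id,
            "donor": c.dinucleotides[0] if c.dinucleotides else "",
            "acceptor": c.dinucleotides[1] if c.dinucleotides else "",
            "canonical": c.canonical,
            "coverage_class": c.coverage_class,
            "drs_up_len": c.drs_up_len,
            "drs_down_len": c.drs_down_len,
            "long_drs": c.long_drs,
            "reproducible": c.reproducible,
            "verdict": c.verdict,
            "ambiguous_gene": c.ambiguous_gene,
        }
        for e in exps:
            row[f"reads_{e}"] = c.reads_by_experiment.get(e, 0)
            row[f"pct_{e}"] = round(c.pct_coverage_by_experiment.get(e, 0.0), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def events_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for ev in result.events:
        rows.append(
            {
                "gene_id": ev.gene_id,
                "contig": ev.junction.contig,
                "intron_start": ev.junction.intron_start,
                "intron_end": ev.junction.intron_end,
                "event_type": ev.event_type.value,
                "reference_model": ev.reference_model,
                "novel": ev.novel,
                "frame_preserving": ev.frame_preserving,
                "skipped_exons": ",".join(map(str, ev.skipped_exons)),
                "complex": ev.complex,
            }
        )
    return pd.DataFrame(rows)


def pas_table(result: PipelineResult) -> pd.DataFrame:
    exps = result.manifest["experiments"]
    rows = []
    for c in result.candidates:
        row = {
            "gene_id": c.gene_id,
            "contig": c.contig,
            "cleavage_pos": c.cleavage_pos,
            "strand": c.strand,
            "region": c.region.value,
            "a_stretch_len": c.a_stretch_len,
            "a_count_10nt": c.a_count_10nt,
            "internal_priming_suspect": c.internal_priming_suspect,
            "marker": c.marker,
        }
        for e in exps:
            row[f"reads_{e}"] = c.reads_by_experiment.get(e, 0)
        for k, v in c.criteria_flags.items():
            row[f"crit_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def pac_bed(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for cl in result.clusters:
        a, b = cl.span
        rows.append(
            {
                "contig": cl.member_sites[0].contig,
                "start": a,
                "end": b,
                "name": f"{cl.member_sites[0].gene_id}_PAC",
                "score": cl.total_reads,
                "strand": cl.member_sites[0].strand,
                "n_members": len(cl.member_sites),
            }
        )
    return pd.DataFrame(rows)


def write_report(result: PipelineResult, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("junctions.tsv", junctions_table(result)),
        ("as_events.tsv", events_table(result)),
        ("pas.tsv", pas_table(result)),
        ("pacs.bed", pac_bed(result)),
    ]:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    venn = outdir / "venn_summary.tsv"
    pd.DataFrame([result.venn]).to_csv(venn, sep="\t", index=False)
    paths["venn_summary.tsv"] = venn
    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps(result.manifest, indent=1, default=str))
    paths["manifest.json"] = manifest
    return paths
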