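import pytest

from race3seq.as_events import (
    ClassificationError,
    EventType,
    classify_event,
    select_reference_model,
    summarize_as,
)
from race3seq.junctions import JunctionCall
from race3seq.refmodel import GeneModelSet, TranscriptModel

# Reference used throughout: 4 exons, introns (100,200), (300,400), (500,600).
EXONS = [(0, 100), (200, 300), (400, 500), (600, 700)]


def make_gene(strand="+", extra_models=()):
    models = [TranscriptModel(model_id="Model 1", exons=EXONS, strand=strand)]
    for i, exons in enumerate(extra_models, start=2):
        models.append(
            TranscriptModel(model_id=f"Model {i}", exons=exons, strand=strand)
        )
    return GeneModelSet(gene_id="g", contig="ctg", strand=strand, models=models)


def jcall(s, e, strand="+", reads=None, coverage_class=None):
    return JunctionCall(
        contig="ctg",
        strand=strand,
        intron_start=s,
        intron_end=e,
        gene_id="g",
        reads_by_experiment=reads or {"e1": 50},
        coverage_class=coverage_class,
    )


class TestClassifyEvent:
    @pytest.mark.parametrize(
        "intron,expected",
        [
            ((300, 400), EventType.ANNOTATED),
            ((280, 400), EventType.A5SS),  # donor moved into the exon
            ((300, 430), EventType.A3SS),  # acceptor moved into the exon
            ((320, 380), EventType.A5A3SS),  # inside one ref intron, no boundary
            ((620, 680), EventType.EI),  # strictly inside the last exon
            ((300, 600), EventType.ES),  # removes exon 3 entirely
        ],
    )
    def test_plus_strand_taxonomy(self, intron, expected):
        gene = make_gene("+")
        ev = classify_event(jcall(*intron), gene.models[0], gene)
        assert ev.event_type == expected

    def test_each_junction_gets_exactly_one_type(self):
        gene = make_gene("+")
        for s in range(80, 660, 37):
            ev = classify_event(jcall(s, s + 30), gene.models[0], gene)
            assert isinstance(ev.event_type, EventType)

    @pytest.mark.parametrize("length,preserving", [(9, True), (60, True), (10, False)])
    def test_exitron_frame_annotation(self, length, preserving):
        gene = make_gene("+")
        ev = classify_event(jcall(620, 620 + length), gene.models[0], gene)
        assert ev.event_type == EventType.EI
        assert ev.frame_preserving is preserving

    def test_es_skipped_exons_by_containment(self):
        gene = make_gene("+")
        ev = classify_event(jcall(300, 600), gene.models[0], gene)
        # Brute-force containment: exons strictly inside [300, 600).
        expected = [
            i + 1 for i, (a, b) in enumerate(EXONS) if 300 < a and b < 600
        ]
        assert ev.skipped_exons == expected == [3]
        assert not ev.complex

    def test_multi_exon_skip(self):
        gene = make_gene("+")
        ev = classify_event(jcall(100, 600), gene.models[0], gene)
        assert ev.event_type == EventType.ES
        assert ev.skipped_exons == [2, 3]

    def test_minus_strand_mirrors_a5ss(self):
        # Same geometry mirrored to the minus strand: the alternative donor
        # of intron (300,400) sits at the genomic *end* boundary.
        gene = make_gene("-")
        ev = classify_event(jcall(300, 420, strand="-"), gene.models[0], gene)
        assert ev.event_type == EventType.A5SS
        ev2 = classify_event(jcall(280, 400, strand="-"), gene.models[0], gene)
        assert ev2.event_type == EventType.A3SS

    def test_novelty_checked_against_all_models(self):
        # Model 2 annotates the A5SS intron (280,400); the event stays A5SS
        # against Model 1 but is not novel.
        m2 = [(0, 100), (200, 280), (400, 500), (600, 700)]
        gene = make_gene("+", extra_models=[m2])
        ev = classify_event(jcall(280, 400), gene.models[0], gene)
        assert ev.event_type == EventType.A5SS
        assert ev.novel is False
        ev2 = classify_event(jcall(270, 400), gene.models[0], gene)
        assert ev2.novel is True

    def test_junction_outside_span_raises(self):
        gene = make_gene("+")
        with pytest.raises(ClassificationError):
            classify_event(jcall(900, 1000), gene.models[0], gene)


class TestSelectReferenceModel:
    def test_all_well_junctions_match_model1(self):
        gene = make_gene("+", extra_models=[[(0, 100), (200, 280), (400, 700)]])
        calls = [
            jcall(100, 200, reads={"e1": 5000}, coverage_class="WELL"),
            jcall(300, 400, reads={"e1": 4000}, coverage_class="WELL"),
        ]
        assert select_reference_model(gene, calls) == "Model 1"

    def test_dominant_alternative_model_wins(self):
        m2 = [(0, 100), (200, 280), (400, 500), (600, 700)]  # specific intron (280,400)
        gene = make_gene("+", extra_models=[m2])
        calls = [
            jcall(280, 400, reads={"e1": 6000}, coverage_class="WELL"),
            jcall(300, 400, reads={"e1": 100}, coverage_class="POOR"),
        ]
        assert select_reference_model(gene, calls) == "Model 2"

    def test_no_support_defaults_to_model1_with_warning(self):
        gene = make_gene("+", extra_models=[[(0, 100), (200, 700)]])
        with pytest.warns(UserWarning):
            assert select_reference_model(gene, []) == "Model 1"


class TestSummarize:
    def test_empty_input_all_zero(self):
        df = summarize_as([])
        assert (df["n"] == 0).all()

    def test_eix3_split(self):
        gene = make_gene("+")
        evs = [
            classify_event(jcall(620, 629), gene.models[0], gene),  # 9 nt
            classify_event(jcall(640, 650), gene.models[0], gene),  # 10 nt
        ]
        df = summarize_as(evs)
        assert df.loc["EI", "n"] == 2
        assert df.loc["EI", "frame_preserving"] == 1
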