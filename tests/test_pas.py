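import numpy as np
import pytest

from race3seq.pas import (
    AdaptorSpec,
    PASCall,
    cluster_pacs,
    filter_internal_region,
    filter_utr3,
    find_polyA_reads,
    profile_downstream_A,
)
from race3seq.refmodel import GenomeSequence, Region, revcomp


def pas(pos, region=Region.UTR3, stretch=0, window=0, reads=None, strand="+", gene="g"):
    return PASCall(
        contig="ctg",
        strand=strand,
        cleavage_pos=pos,
        gene_id=gene,
        region=region,
        reads_by_experiment=reads if reads is not None else {"e1": 10, "e2": 10},
        a_stretch_len=stretch,
        a_count_10nt=window,
    )


class TestAdaptor:
    def test_defaults(self):
        a = AdaptorSpec()
        assert a.stem == "GCGAGCACAGAATTAATACGACTCACTATAGG"
        assert a.tail == "TTTTTTTTTTTTVN"
        assert a.rc_stem == revcomp(a.stem)

    def test_min_stem_match_bound(self):
        with pytest.raises(ValueError):
            AdaptorSpec(min_stem_match=99)


class TestFindPolyAReads:
    ADAPTOR = AdaptorSpec()

    def test_tailed_read_is_trimmed(self):
        gene_part = "ACGTGTCAGCTCAGG"
        read = gene_part + "A" * 10 + self.ADAPTOR.rc_stem
        [hit], rejected = find_polyA_reads([("r1", read)], self.ADAPTOR)
        assert hit.trimmed_seq == gene_part
        assert hit.tail_len == 10
        assert rejected == 0

    def test_antisense_read_is_flipped(self):
        read = revcomp("ACGTGTCAGCTCAGG" + "A" * 12 + self.ADAPTOR.rc_stem)
        [hit], _ = find_polyA_reads([("r1", read)], self.ADAPTOR)
        assert hit.flipped is True
        assert hit.tail_len == 12

    def test_adaptor_without_tail_rejected_and_counted(self):
        read = "ACGTGTCAGCTCAGG" + "AAA" + self.ADAPTOR.rc_stem
        hits, rejected = find_polyA_reads([("r1", read)], self.ADAPTOR, min_tail_A=8)
        assert hits == [] and rejected == 1

    def test_read_without_adaptor_ignored(self):
        hits, rejected = find_polyA_reads([("r1", "ACGT" * 30)], self.ADAPTOR)
        assert hits == [] and rejected == 0

    def test_simulated_polya_molecules_all_qualify(self, sim):
        # Fragments covering tail+adaptor qualify; fragment-internal ones never do.
        names, _ = find_polyA_reads(sim.reads["exp1"], self.ADAPTOR)
        got = {t.name for t in names}
        for name, frag in sim.reads["exp1"]:
            if name in got:
                assert self.ADAPTOR.rc_stem[:12] in frag


class TestProfileDownstream:
    @pytest.mark.parametrize(
        "downstream,stretch,count",
        [
            ("AATAAGCTAG", 2, 5),
            ("AAAAAGGGGG", 5, 5),
            ("GCGCGCGCGC", 0, 0),
        ],
    )
    def test_plus_strand_profiles(self, downstream, stretch, count):
        g = GenomeSequence("c", "CCCC" + "C" + downstream + "CCCC")
        p = pas(4)
        assert profile_downstream_A(p, g) == (stretch, count)
        assert p.internal_priming_suspect is (count >= 5)

    def test_minus_strand_reads_transcribed_downstream(self):
        # Transcribed downstream of a minus-strand site are the forward bases
        # to its left, complemented: forward TTTTTTTTTT -> ten A's.
        g = GenomeSequence("c", "CC" + "T" * 10 + "G" + "CCCC")
        p = pas(12, strand="-")
        stretch, count = profile_downstream_A(p, g)
        assert count == 10 and stretch >= 10

    def test_truncated_window_flagged(self):
        g = GenomeSequence("c", "CCCCCAGT")
        p = pas(4)
        profile_downstream_A(p, g)
        assert p.window_truncated is True


class TestCascades:
    def test_internal_marker_requires_all_four(self):
        good = pas(100, Region.INTRON, stretch=0, window=2)
        markers = filter_internal_region([good])
        assert markers == [good] and good.marker
        assert good.criteria_flags == {
            "stretch": True, "window": True, "neighborhood": True, "reproducible": True,
        }

    def test_window_of_four_rejected_internally(self):
        c = pas(100, Region.INTRON, stretch=0, window=4)
        assert filter_internal_region([c]) == []
        assert c.criteria_flags["window"] is False

    def test_failing_neighbor_within_5nt_rejects(self):
        good = pas(100, Region.INTRON, stretch=0, window=2)
        bad = pas(103, Region.INTRON, stretch=6, window=8)
        assert filter_internal_region([good, bad]) == []
        assert good.criteria_flags["neighborhood"] is False
        # Same candidate with the bad neighbor out of range passes.
        good2 = pas(100, Region.INTRON, stretch=0, window=2)
        far_bad = pas(106, Region.INTRON, stretch=6, window=8)
        assert filter_internal_region([good2, far_bad]) == [good2]

    def test_one_experiment_candidate_rejected(self):
        c = pas(100, Region.INTRON, reads={"e1": 20, "e2": 0})
        assert filter_internal_region([c]) == []
        assert c.criteria_flags["reproducible"] is False

    def test_utr3_cascade_is_lenient(self):
        c = pas(100, Region.UTR3, stretch=2, window=4)
        assert filter_utr3([c]) == [c]

    def test_utr3_window_of_five_rejected(self):
        c = pas(100, Region.UTR3, stretch=2, window=5)
        assert filter_utr3([c]) == []

    def test_same_profile_fails_stringent_cascade_in_intron(self):
        c = pas(100, Region.INTRON, stretch=2, window=4)
        assert filter_internal_region([c]) == []
        assert filter_utr3([c]) == []  # wrong region: untouched, not a marker

    def test_tightening_thresholds_never_grows_marker_set(self):
        rng = np.random.default_rng(2)
        cands = [
            pas(
                int(rng.integers(0, 2000)),
                Region.INTRON,
                stretch=int(s),
                window=int(w),
                reads={"e1": 10, "e2": int(rng.integers(0, 3))},
            )
            for s, w in zip(rng.integers(0, 6, 120), rng.integers(0, 11, 120))
            if s <= w
        ]
        prev = None
        for max_w in (5, 4, 3, 2, 1):
            got = {
                id(c)
                for c in filter_internal_region(
                    [c for c in cands], max_window_a=max_w
                )
            }
            if prev is not None:
                assert got <= prev
            prev = got

    def test_internal_markers_satisfy_utr3_cascade_too(self, pipe):
        # Stringent criteria are a strict subset of the lenient ones.
        for c in pipe.markers:
            if c.region != Region.UTR3:
                assert c.a_stretch_len <= 3 and c.a_count_10nt <= 4


def brute_force_clusters(positions, max_gap):
    """O(n^2) transitive closure of the within-gap relation."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(positions)
    for a in positions:
        for b in positions:
            if a != b and abs(a - b) <= max_gap:
                g.add_edge(a, b)
    return sorted(tuple(sorted(cc)) for cc in nx.connected_components(g))


class TestClusterPACs:
    @pytest.mark.parametrize(
        "positions,expected",
        [
            ([100, 130, 200], [(100, 130), (200,)]),
            ([500], [(500,)]),
            ([0, 50, 100], [(0, 50, 100)]),  # exact-gap boundary is inclusive
        ],
    )
    def test_chaining_examples(self, positions, expected):
        clusters = cluster_pacs([pas(p) for p in positions])
        got = sorted(tuple(m.cleavage_pos for m in c.member_sites) for c in clusters)
        assert got == expected

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(1, 25))
            positions = sorted(set(rng.integers(0, 600, size=n).tolist()))
            clusters = cluster_pacs([pas(p) for p in positions])
            got = sorted(
                tuple(m.cleavage_pos for m in c.member_sites) for c in clusters
            )
            assert got == brute_force_clusters(positions, 50)

    def test_genes_never_share_a_cluster(self):
        sites = [pas(100, gene="a"), pas(110, gene="b")]
        clusters = cluster_pacs(sites)
        assert len(clusters) == 2

    def test_cluster_properties(self):
        cl = cluster_pacs([pas(100, reads={"e1": 3, "e2": 4}), pas(120)])[0]
        assert cl.span == (100, 121)
        assert cl.total_reads == 27
        assert cl.representative.cleavage_pos == 120
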