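import numpy as np
import pytest

from race3seq.junctions import (
    AUTHENTIC,
    POOR,
    SUSPECT_ARTIFACT,
    WELL,
    CoverageInconsistencyError,
    JunctionCall,
    MalformedJunctionError,
    assess_reproducibility,
    classify_canonical,
    classify_coverage,
    drs_lengths,
    extract_junctions,
    junction_verdict,
    percentage_coverage,
)
from race3seq.refmodel import GenomeSequence

from conftest import make_header, spliced_read


def call(s, e, strand="+", reads=None, **kw):
    return JunctionCall(
        contig="ctg",
        strand=strand,
        intron_start=s,
        intron_end=e,
        gene_id="g",
        reads_by_experiment=reads or {},
        **kw,
    )


class TestPercentageCoverage:
    @pytest.mark.parametrize(
        "j,g,expected", [(0, 10000, 0.0), (466, 10000, 4.66), (0, 0, 0.0)]
    )
    def test_examples(self, j, g, expected):
        assert percentage_coverage(j, g) == pytest.approx(expected)

    def test_inconsistent_counts(self):
        with pytest.raises(CoverageInconsistencyError):
            percentage_coverage(5, 0)

    def test_algebraic_inverse(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            g = int(rng.integers(1, 10**6))
            j = int(rng.integers(0, g + 1))
            assert percentage_coverage(j, g) * g / 100 == pytest.approx(j)


class TestCoverageClass:
    @pytest.mark.parametrize("total,expected", [(3801, WELL), (3800, POOR), (10, POOR)])
    def test_strict_threshold(self, total, expected):
        c = call(0, 100, reads={"e1": total})
        assert classify_coverage(c) == expected

    def test_pooled_across_experiments(self):
        c = call(0, 100, reads={"e1": 2000, "e2": 1900})
        assert classify_coverage(c) == WELL


class TestCanonical:
    def test_plus_strand_gt_ag(self):
        g = GenomeSequence("c", "CCCC" + "GTAAGTTTCAG" + "CCCC")
        c = call(4, 15)
        assert classify_canonical(c, g) is True
        assert c.dinucleotides == ("GT", "AG")

    def test_gc_donor_is_non_canonical(self):
        g = GenomeSequence("c", "CCCC" + "GCAAGTTTCAG" + "CCCC")
        assert classify_canonical(call(4, 15), g) is False

    def test_minus_strand_ct_ac_is_canonical(self):
        # Forward CT...AC reads GT...AG after the strand flip.
        g = GenomeSequence("c", "CCCC" + "CTGAATTTTAC" + "CCCC")
        c = call(4, 15, strand="-")
        assert classify_canonical(c, g) is True
        assert c.dinucleotides == ("GT", "AG")

    def test_short_intron_rejected(self):
        g = GenomeSequence("c", "ACGTACGTACGT")
        with pytest.raises(MalformedJunctionError):
            JunctionCall("c", "+", 2, 5, "g")


def brute_force_drs(seq, s, e, max_scan=15):
    """Longest shared affixes at the two boundaries, tried from max_scan down."""
    up = next(
        (
            L
            for L in range(max_scan, 0, -1)
            if s - L >= 0 and seq[s - L : s] == seq[e - L : e]
        ),
        0,
    )
    down = next(
        (
            L
            for L in range(max_scan, 0, -1)
            if e + L <= len(seq) and seq[s : s + L] == seq[e : e + L]
        ),
        0,
    )
    return up, down


class TestDRS:
    def test_repeat_ending_at_both_boundaries(self):
        g = GenomeSequence("c", "AAGCTACGGTTTTACGCCGG")
        c = call(8, 16)
        assert drs_lengths(c, g) == (4, 0)  # "TACG" ends at both boundaries

    def test_no_shared_flanks(self):
        g = GenomeSequence("c", "AAAACCCCGGGGTTTTACGT")
        assert drs_lengths(call(4, 12), g) == (0, 0)

    def test_cap_at_max_scan(self):
        rep = "ACGTGATC" * 3  # 24-nt repeat copies
        g = GenomeSequence("c", rep + "TTTT" + rep + "GGGG")
        up, down = drs_lengths(call(24, 52), g, max_scan=15)
        assert up == 15

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            seq = "".join(bases[rng.integers(0, 4, size=80)])
            s = int(rng.integers(16, 40))
            e = int(rng.integers(s + 4, 64))
            g = GenomeSequence("c", seq)
            assert drs_lengths(call(s, e), g) == brute_force_drs(seq, s, e)


class TestReproducibility:
    def test_partition(self):
        calls = [
            call(0, 100, reads={"e1": 21, "e2": 15}),
            call(200, 300, reads={"e1": 12, "e2": 0}),
            call(400, 500, reads={"e1": 0, "e2": 30}),
        ]
        part = assess_reproducibility(calls)
        assert [c.reproducible for c in calls] == [True, False, False]
        assert part == {"first_only": 1, "all": 1, "rest_only": 1}

    def test_single_experiment_warns(self):
        calls = [call(0, 100, reads={"e1": 5})]
        with pytest.warns(UserWarning):
            assess_reproducibility(calls)
        assert calls[0].reproducible is None


class TestVerdict:
    @pytest.mark.parametrize(
        "canonical,drs,verdict,long_flag",
        [
            (True, 0, AUTHENTIC, False),
            (False, 8, SUSPECT_ARTIFACT, True),
            (True, 7, AUTHENTIC, True),  # long DRS is evidence, not the rule
        ],
    )
    def test_canonical_rule(self, canonical, drs, verdict, long_flag):
        c = call(0, 100, canonical=canonical, drs_up_len=drs)
        assert junction_verdict(c) == verdict
        assert c.long_drs is long_flag

    def test_requires_canonical_computed(self):
        with pytest.raises(ValueError):
            junction_verdict(call(0, 100))


class TestExtractJunctions:
    def _gene_setup(self, plus_gene):
        return make_header(), plus_gene

    def test_retained_if_threshold_met_in_one_experiment(self, plus_gene):
        header = make_header()
        e1 = [
            spliced_read(header, f"r{i}", 150, [(150, 200), (320, 370)])
            for i in range(12)
        ]
        e2 = [spliced_read(header, f"s{i}", 60, [(60, 180)]) for i in range(3)]
        calls = extract_junctions({"e1": e1, "e2": e2}, plus_gene)
        assert len(calls) == 1
        c = calls[0]
        assert (c.intron_start, c.intron_end) == (200, 320)
        assert c.reads_by_experiment == {"e1": 12, "e2": 0}
        assert c.pct_coverage_by_experiment["e1"] == pytest.approx(100.0)
        assess_reproducibility(calls)
        assert c.reproducible is False

    def test_dropped_when_no_experiment_reaches_threshold(self, plus_gene):
        header = make_header()
        aln = {
            exp: [
                spliced_read(header, f"{exp}{i}", 150, [(150, 200), (320, 370)])
                for i in range(9)
            ]
            for exp in ("e1", "e2")
        }
        assert extract_junctions(aln, plus_gene) == []

    def test_reads_with_mismatches_near_ss_not_counted(self, plus_gene):
        header = make_header()
        clean = [
            spliced_read(header, f"c{i}", 150, [(150, 200), (320, 370)], md="100", nm=0)
            for i in range(10)
        ]
        # Two substitutions within 10 nt of the donor boundary: excluded.
        dirty = [
            spliced_read(
                header, f"d{i}", 150, [(150, 200), (320, 370)], md="44A3C51", nm=2
            )
            for i in range(5)
        ]
        calls = extract_junctions({"e1": clean + dirty, "e2": []}, plus_gene)
        assert calls[0].reads_by_experiment["e1"] == 10

    def test_unknown_contig_skipped_with_warning(self, plus_gene):
        header = make_header(contig="other")
        aln = {"e1": [spliced_read(header, "r", 150, [(150, 200), (320, 370)])]}
        with pytest.warns(UserWarning, match="skipped"):
            assert extract_junctions(aln, plus_gene) == []

    def test_empty_input(self, plus_gene):
        assert extract_junctions({"e1": [], "e2": []}, plus_gene) == []

    def test_support_bounded_by_gene_spliced_reads(self, sim, pipe):
        # A read spanning k introns yields k support incidences, so compare
        # against the per-gene count of N CIGAR operations.
        for exp in ("exp1", "exp2"):
            spliced = {}
            for seg in sim.alignments[exp]:
                n_ops = sum(1 for op, _ in seg.cigartuples if op == 3)
                if n_ops:
                    gid = seg.query_name.split(".")[0]
                    spliced[gid] = spliced.get(gid, 0) + n_ops
            per_gene = {}
            for c in pipe.junction_calls:
                per_gene[c.gene_id] = per_gene.get(c.gene_id, 0) + c.reads_by_experiment[exp]
            for gid, n in per_gene.items():
                assert n <= spliced[gid]
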