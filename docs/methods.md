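# Methods

## Scope and model of the data

`race3seq` analyzes targeted 3′-RACE amplicon sequencing: for each target
gene, a gene-specific primer anchored near the initiation codon is extended
to an oligo(dT)-anchored adaptor, so the amplicon covers most of the gene
body and ends at the transcript's cleavage site. Deep sequencing of such
amplicons observes two site classes — splice junctions (as `N` operations in
spliced alignments) and cleavage/polyadenylation sites (as read 3′ ends
carrying a poly(A) run plus the adaptor) — against a background of three
protocol-specific artifact classes: stochastic (Monte Carlo) amplification
of low-copy templates, direct-repeat mega-primer chimeras, and
internal-priming truncations. The package's job is detection plus artifact
triage; it does not quantify isoform abundance, model cleavage
microheterogeneity beyond cluster chaining, or predict downstream
consequences such as NMD.

Coordinates are 0-based half-open on the genome forward strand throughout;
GFF3 input (1-based inclusive) is converted once at the parsing boundary.
Donor and acceptor are always defined on the transcribed strand, so all
classifications are mirror-invariant for minus-strand genes.

## Junction evidence chain

1. **Extraction.** One call per distinct intron interval overlapping a
   target gene, support counted per experiment (zeros recorded). Reads with
   more than `max_mismatch_near_ss` (default 1) substitution mismatches
   within `ss_window` (default ±10 nt) of either boundary are not counted;
   the window width is this implementation's choice, as only the filter
   itself, not its width, is standard. Mismatch positions come from MD/NM
   tags when present; alignments without them are trusted.
2. **Retention.** A junction is kept when support reaches `min_ss_reads`
   (default 10) in *at least one* experiment. Requiring the threshold in
   every experiment would contradict the observed single-experiment
   junctions that motivate the reproducibility analysis; the per-experiment
   partition (first-only / all / rest-only) is reported instead.
3. **Coverage class.** Well-covered above `well_min_reads` (default 3 800)
   total reads pooled over experiments, strict inequality. Whether the
   cutoff should be pooled or per experiment is genuinely open; pooled is
   the default and the threshold is config.
4. **Canonical status.** First and last two intron bases on the transcribed
   strand; `GT`/`AG` exactly. No extended motif scoring — the dinucleotide
   rule is the decision rule for authenticity because chimeric junctions
   have arbitrary boundaries.
5. **Direct repeats.** `drs_up_len` is the longest L with
   `g[s−L:s] = g[e−L:e]` (one repeat copy ending at each boundary — the
   mega-primer geometry); `drs_down_len` the symmetric downstream variant;
   both capped at `max_scan` (default 15) and computed on the forward strand
   since repeat identity is strand-symmetric. For a minus-strand gene the
   mega-primer geometry lands in `drs_down_len`; reports should consider the
   maximum of the two. Repeats ≥4 are reported, ≥6 flagged "long". These are
   evidence annotations, not part of the verdict.
6. **Verdict.** Authentic iff canonical. Reproducibility and DRS length
   contextualize the call but do not override the dinucleotide rule.

A junction overlapping two genes is assigned to the gene whose inner-primer
anchor lies upstream of it on the transcribed strand (the amplicon that can
contain it); remaining ties are reported to all candidates with an
ambiguity flag.

## AS event classification

Event typing compares each authentic junction to one reference model per
gene, selected as the model whose model-specific annotated introns carry the
greatest summed well-covered support (ties, including no support, default to
the primary "Model 1") — a gene's dominant alternative model can legitimately
outrank the annotated primary. Taxonomy, checked in this order: exact
reference intron → `ANNOTATED`; strictly inside one reference exon → `EI`
(exitron), `frame_preserving` iff length ≡ 0 mod 3; spans ≥1 complete
reference exon → `ES` with 1-based skipped-exon indices in transcription
order (boundaries not resting in reference introns or on reference
boundaries mark the call `complex`); shares a reference acceptor only →
`A5SS`; donor only → `A3SS`; overlaps exactly one reference intron sharing
neither boundary → `A5A3SS`; junctions straddling several reference introns
without complete exon containment are filed under `ES` with the `complex`
flag, a boundary case the taxonomy itself leaves open. Novelty is judged
against the introns of *all* annotated models of the gene, so an event can
be non-novel yet non-annotated relative to the selected reference. Event
counts are per junction, not per gene.

## PAS calling and filtering

**Tail detection.** A read qualifies when a run of ≥`min_tail_A` (default 8)
adenosines is immediately followed by ≥`min_stem_match` (default 12) exact
5′ bases of the reverse-complemented adaptor stem; both read orientations
are searched. Adaptor without a preceding A-run is counted and rejected.

**Site placement.** The cleavage site is the 3′-terminal aligned base after
trimming *all* trailing adenosines, genomically templated ones included,
placing the site at the 5′-most (leftmost on the transcribed strand)
consistent position. Tail adenosines and templated adenosines are
indistinguishable in the read, so any other convention would scatter one
molecule's ends across the A run; the choice can shift reported sites
upstream by up to the downstream A-stretch length and is stated here
prominently for comparability.

**Candidacy.** ≥`min_pas_reads` (default 5) reads at one position in at
least one experiment (the same one-experiment resolution as junctions — the
observed sub-100% reproducibility of candidates requires that
single-experiment candidates exist). Region labels come from the gene's
dominant model; when models disagree, the dominant model's label wins (so a
site in its 3′-UTR is filtered leniently even if intronic in another model).

**Cascades.** 5′-UTR/exon/intron candidates: (1) downstream A-stretch ≤1;
(2) ≤3 A in the downstream 10-nt window; (3) no candidate failing (1) or
(2) within ±5 nt (inclusive), judged against the *pre-filter* candidate set
— this removes primer-sliding satellites around A-tracts; (4) detected
(≥`min_detect`, default 1 read) in every experiment. 3′-UTR candidates:
stretch ≤3, window ≤4, reproducible. The stringent cascade is a strict
subset of the lenient one. "Downstream" is the transcribed strand; N bases
count as non-A (conservative toward excluding a site); a window truncated at
a contig edge is flagged and the thresholds apply to the available bases.
Any site with ≥5 window adenosines is additionally annotated as an
internal-priming suspect.

**Clustering.** Markers within `pac_gap` (default 50 nt, inclusive) of the
next marker chain into one PAC per gene and strand (single linkage);
singletons are one-member clusters. A PAC is reported by its span and its
maximum-support member, since no single representative convention is
standard.

## Simulator

The generator's defaults are the study conditions the test-suite measures
under. Toy genes (default 3, strands alternating `+`/`−`) have three exons
(180–260, 260–340, 340–420 nt) and canonical GT..AG introns (90–150 nt),
a 60-nt 5′-UTR and 220-nt 3′-UTR. Genes are laid out in transcript-oriented
coordinates and mirrored onto the genome for minus-strand genes, so every
planted feature is specified once: a 6-A internal-priming tract in exon 2,
an 8-nt direct-repeat pair (68-nt skip, boundary dinucleotides forced
non-canonical on both strands) in exon 2, alternative donors/acceptors
(±12 nt), a 60-nt exitron in the last exon, and cleavage sites whose
downstream 10-mers are adenosine-free by construction (so their marker
status reflects the pipeline, not sequence luck). The default isoform table
holds two isoforms per gene at 0.7/0.3 abundance, cycling the injected
variant (A5′SS with a tandem 3′-UTR site 30 nt from the primary one;
frame-preserving EI; intron-retained transcript ending at an intronic
site) — 3 genes × 2 isoforms = 6 isoforms.

The two experiments mirror the bench design: 2 000 vs 4 000 starting
template molecules and 35 vs 33 cycles per round × 2 rounds. PCR is a
per-species branching process, `N ← N + Binomial(N, eff)` with per-cycle
efficiency uniform on (0.55, 0.90), simulated exactly while `N ≤ 10⁶` and
continued at the expected growth rate beyond — the stochasticity that
matters lives entirely at low copy number. Internal-priming truncations
enter the pool with per-molecule probability `min(1, rate·A-count)`
(default rate 0.02/A). Chimeras are seeded during amplification: expected
seeds per cycle are `parent copies × drs_chimera_rate` (default 10⁻³,
Poisson-drawn at low intensity), each growing deterministically for the
remaining cycles — so chimera abundance ≈ rate × cycle count relative to
the parent, a few percent, matching their status as detectable-but-minor
species. Chimeras are generated only at the planted repeats so the truth
stays exact.

Reads: poly(A) tails are 7 + Geometric(mean 44) ≈ mean 51 nt (the
*Arabidopsis* native-tail average), amplicons are fragmented uniformly to
150–600 nt, and 20 000 fragments per experiment are drawn multinomially
from final species weights. Each fragment yields one truth-SAM record
covering its full span (tail and adaptor soft-clipped, `N` at every
junction) plus a 125-bp read pair in FASTQ. Tests consume the truth SAM;
the FASTQ exists for end-to-end runs with a real aligner. The truth SAM is
error-free (NM=0) — sequencing-error realism is out of scope, and the
near-boundary mismatch filter is exercised with constructed records — and
one record per fragment stands in for a properly paired alignment, which is
the main idealization: real pairs can fail to bridge a junction that their
fragment spans. Passing recovery tests therefore demonstrate the logic of
the method under its own assumptions, not mapping robustness, alignment
ambiguity, or realistic artifact rates (which are unmeasured; the defaults
are chosen for test coverage).

## Numerical and determinism notes

All randomness flows from one integer seed through named
`numpy.random.Generator` streams per stage; fixed seed ⇒ byte-identical
outputs. Pipeline outputs are coordinate-sorted so reruns diff cleanly. The
filter funnel is conserved at every stage (input = passed + rejected, with
per-criterion rejection counts). Degenerate inputs: empty alignment files
produce empty-but-valid outputs; a single experiment leaves reproducibility
unknown with a warning rather than failing; percentage coverage of 0/0 is
0, while junction reads without gene-covering reads raise an inconsistency
error.

Desk-scale problem sizes used by the test-suite and the acceptance script —
3 genes, 20 000 reads per experiment, 1 000-case oracle comparisons, 100
Monte Carlo amplification trials — are the package's chosen defaults and
complete in well under a minute each.
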