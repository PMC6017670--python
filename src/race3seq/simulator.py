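"""Truth-tagged simulator for 3'-RACE deep-sequencing experiments.

The simulator builds a toy genome with multi-exon genes, transcribes a
configurable isoform table (alternative donors/acceptors, exitrons, exon
skipping, intron-retained transcripts ending at intronic cleavage sites),
and then pushes the molecules through the steps that create the artifact
classes the pipeline is designed to defeat:

* **reverse transcription with internal priming** — every isoform whose
  transcript crosses a planted internal A-tract spawns truncated cDNAs with
  a probability that grows with the local adenosine count;
* **two independent PCR amplifications** — per-species branching processes
  with per-cycle binomial efficiency noise, so low-copy templates show the
  Monte Carlo dropout that makes single-experiment junctions suspect;
* **direct-repeat mega-primer chimeras** — incomplete extension products
  ending inside a planted repeat copy re-anneal at the other copy, creating
  deletion species whose apparent junction is recorded in the truth and
  whose boundary dinucleotides are deliberately non-canonical;
* **fragmentation and read emission** — sonication-sized fragments
  (150-600 nt) yield paired 125-nt reads plus a truth SAM of correct
  spliced alignments (N CIGAR at true and chimeric junctions, poly(A) tail
  and adaptor soft-clipped), so the pipeline is testable without an
  external aligner.

Every read name encodes the species it came from; :class:`SimTruth` is the
oracle the test-suite checks pipeline output against.

Design choices worth knowing: genes are laid out in transcript-oriented
coordinates and mirrored onto the genome for minus-strand genes, so every
planted feature (canonical GT..AG boundaries, A-tracts, repeats, A-poor
cleavage windows) is specified once and strand handling is confined to the
coordinate mapper. PCR is modeled per species, not per molecule: exact
binomial branching while the copy number is small (where the Monte Carlo
effect lives) and deterministic expected growth once it is large.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from race3seq.pas import AdaptorSpec
from race3seq.refmodel import GeneModelSet, GenomeSequence, TranscriptModel, revcomp

CONTIG = "chrSim"
_SPACER = 400
_FLANK = 300

#: 10-mers with no adenosine, written downstream of genuine cleavage sites so
#: that the internal-priming cascades cannot reject them by construction.
_APOOR_WINDOWS = ["GTCGGCTGCT", "GCTGTCGCGT", "GGTCTGCGTC", "GTGCCTGCTC"]


@dataclass
class SimConfig:
    """Study conditions for one simulated two-experiment 3'-RACE run.

    The two experiments mirror the bench design: experiment 2 starts from
    twice the template of experiment 1 but runs two fewer cycles per PCR
    round, with two rounds each. Artifact rates have no measured real-world
    values; the defaults are chosen so that every artifact class is present
    at callable abundance in a desk-scale run.
    """

    seed: int = 1
    n_genes: int = 3
    strands: str | None = None  # e.g. "+-+"; default alternates
    n_exons: int = 3
    exon_len_ranges: tuple[tuple[int, int], ...] = ((180, 260), (260, 340), (340, 420))
    intron_len_range: tuple[int, int] = (90, 150)
    utr5_len: int = 60
    utr3_len: int = 220
    isoform_plan: list[list[tuple[str, str, float]]] | None = None
    ei_length: int = 60
    ss_shift: int = 12  # donor/acceptor offset of A5SS / A3SS variants
    internal_priming_rate_per_A: float = 0.02
    drs_chimera_rate: float = 0.001  # per parent molecule per cycle
    repeat_len: int = 8
    pcr_cycles_exp1: int = 35
    pcr_cycles_exp2: int = 33
    pcr_rounds: int = 2
    template_molecules_exp1: int = 2000
    template_molecules_exp2: int = 4000
    pcr_efficiency: tuple[float, float] = (0.55, 0.90)
    reads_per_experiment: int = 20000
    read_length: int = 125
    paired: bool = True
    fragment_len_range: tuple[int, int] = (150, 600)
    polyA_mean: int = 51
    adaptor: AdaptorSpec = field(default_factory=AdaptorSpec)

    @property
    def experiments(self) -> list[str]:
        return ["exp1", "exp2"]

    def cycles(self, exp: str) -> int:
        per_round = self.pcr_cycles_exp1 if exp == "exp1" else self.pcr_cycles_exp2
        return per_round * self.pcr_rounds

    def templates(self, exp: str) -> int:
        return self.template_molecules_exp1 if exp == "exp1" else self.template_molecules_exp2


def default_isoform_plan(gene_index: int) -> list[tuple[str, str, float]]:
    """Built-in two-isoform plan, cycling the injected event class per gene."""
    variant = ["A5SS", "EI", "INTRON_RETENTION"][gene_index % 3]
    pas_key = {"A5SS": "utr3_b", "EI": "utr3_a", "INTRON_RETENTION": "intron"}[variant]
    return [("ANNOTATED", "utr3_a", 0.7), (variant, pas_key, 0.3)]


@dataclass
class SimGene:
    """One toy gene, laid out in transcript-oriented coordinates.

    ``premrna`` is the unspliced gene sequence read 5'->3' on the transcribed
    strand; transcript coordinate t maps to the genome through :meth:`t2g`.
    """

    gene_id: str
    strand: str
    gstart: int
    length: int
    premrna: str
    exons_t: list[tuple[int, int]]
    introns_t: list[tuple[int, int]]
    utr5_t: tuple[int, int]
    utr3_t: tuple[int, int]
    cds_t: tuple[int, int]
    a_tract_t: int
    a_tract_len: int
    repeat_t: tuple[int, int]  # start of each planted repeat copy
    repeat_len: int
    pas_t: dict[str, int]
    variant_introns_t: dict[str, tuple[int, int]] = field(default_factory=dict)

    def t2g(self, t: int) -> int:
        if self.strand == "+":
            return self.gstart + t
        return self.gstart + self.length - 1 - t

    def iv_t2g(self, iv: tuple[int, int]) -> tuple[int, int]:
        ts, te = iv
        if self.strand == "+":
            return (self.gstart + ts, self.gstart + te)
        return (self.gstart + self.length - te, self.gstart + self.length - ts)

    @property
    def apparent_chimera_intron_t(self) -> tuple[int, int]:
        r1, r2 = self.repeat_t
        return (r1 + self.repeat_len, r2 + self.repeat_len)


@dataclass
class Species:
    """One molecular species in the amplicon pool."""

    species_id: str
    gene_id: str
    kind: str  # isoform | internal_priming | chimera
    introns_t: tuple[tuple[int, int], ...]
    aligned_end_t: int  # last aligned transcribed base, inclusive
    cleavage_t: int  # apparent cleavage site (truth), transcript coords
    tail_mode: str  # polyA | fixed12
    pas_region: str | None = None
    event_label: str | None = None

    def mature_blocks(self) -> list[tuple[int, int]]:
        """Pre-mRNA intervals making up the mature molecule, transcript order."""
        blocks = []
        pos = 0
        for s, e in sorted(self.introns_t):
            if s > pos:
                blocks.append((pos, min(s, self.aligned_end_t + 1)))
            pos = e
            if pos > self.aligned_end_t:
                break
        if pos <= self.aligned_end_t:
            blocks.append((pos, self.aligned_end_t + 1))
        return blocks


@dataclass
class SimTruth:
    """Ground-truth registry for one simulation."""

    true_junctions: list[dict] = field(default_factory=list)
    chimera_junctions: list[dict] = field(default_factory=list)
    true_pas: list[dict] = field(default_factory=list)
    internal_priming_sites: list[dict] = field(default_factory=list)
    species: dict[str, Species] = field(default_factory=dict)
    molecules: dict[str, dict[str, int]] = field(default_factory=dict)
    weights: dict[str, dict[str, float]] = field(default_factory=dict)
    read_counts: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    contigs: dict[str, GenomeSequence]
    genes: dict[str, GeneModelSet]
    sim_genes: dict[str, SimGene]
    truth: SimTruth
    alignments: dict[str, list[pysam.AlignedSegment]]
    header: pysam.AlignmentHeader
    reads: dict[str, list[tuple[str, str]]]  # (name, sense sequence) per experiment
    paths: dict[str, Path] = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.integers(0, 4, size=n)])


def _edit(seq: list[str], pos: int, text: str) -> None:
    seq[pos : pos + len(text)] = list(text)


def _build_gene(cfg: SimConfig, rng: np.random.Generator, idx: int, gstart: int, strand: str) -> SimGene:
    exon_lens = [
        int(rng.integers(lo, hi + 1))
        for lo, hi in (cfg.exon_len_ranges * cfg.n_exons)[: cfg.n_exons]
    ]
    intron_lens = [
        int(rng.integers(*cfg.intron_len_range)) for _ in range(cfg.n_exons - 1)
    ]
    exons_t: list[tuple[int, int]] = []
    introns_t: list[tuple[int, int]] = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons_t.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            introns_t.append((pos, pos + intron_lens[i]))
            pos += intron_lens[i]
    length = pos
    seq = list(_rand_seq(rng, length))
    for s, e in introns_t:
        _edit(seq, s, "GT")
        _edit(seq, e - 2, "AG")

    e2s, _ = exons_t[1]
    e3s, e3e = exons_t[-1]
    # Internal-priming bait: A-tract inside the second exon, preceded by a C
    # so the apparent cleavage base survives templated-A trimming untouched.
    a_tract_t = e2s + 30
    _edit(seq, a_tract_t - 1, "C" + "A" * 6 + "G")
    # Direct-repeat pair in the same exon; junction boundary dinucleotides are
    # forced non-canonical on both strands (CC donor / TT acceptor forward).
    rlen = cfg.repeat_len
    repeat = _rand_seq(rng, rlen - 2) + "TT"
    r1 = e2s + 60
    r2 = r1 + 60 + rlen
    _edit(seq, r1, repeat)
    _edit(seq, r2, repeat)
    _edit(seq, r1 + rlen, "CC")

    utr5_t = (0, cfg.utr5_len)
    utr3_t = (length - cfg.utr3_len, length)
    cds_t = (cfg.utr5_len, length - cfg.utr3_len)
    pas_t = {
        "utr3_a": length - 150,
        "utr3_b": length - 120,
        "intron": introns_t[-1][0] + 40,
    }
    for k, p in pas_t.items():
        _edit(seq, p, "C")  # cleavage base itself must survive trailing-A trimming
        _edit(seq, p + 1, _APOOR_WINDOWS[(idx + len(k)) % len(_APOOR_WINDOWS)])

    variant_introns: dict[str, tuple[int, int]] = {}
    i1s, i1e = introns_t[0]
    shift = cfg.ss_shift
    variant_introns["A5SS"] = (i1s - shift, i1e)
    _edit(seq, i1s - shift, "GT")
    variant_introns["A3SS"] = (i1s, i1e + shift)
    _edit(seq, i1e + shift - 2, "AG")
    ei_s = e3s + 30
    variant_introns["EI"] = (ei_s, ei_s + cfg.ei_length)
    _edit(seq, ei_s, "GT")
    _edit(seq, ei_s + cfg.ei_length - 2, "AG")
    variant_introns["ES"] = (introns_t[0][0], introns_t[-1][1])

    return SimGene(
        gene_id=f"gene{idx}",
        strand=strand,
        gstart=gstart,
        length=length,
        premrna="".join(seq),
        exons_t=exons_t,
        introns_t=introns_t,
        utr5_t=utr5_t,
        utr3_t=utr3_t,
        cds_t=cds_t,
        a_tract_t=a_tract_t,
        a_tract_len=6,
        repeat_t=(r1, r2),
        repeat_len=rlen,
        pas_t=pas_t,
        variant_introns_t=variant_introns,
    )


def _gene_model_set(g: SimGene) -> GeneModelSet:
    exons = sorted(g.iv_t2g(iv) for iv in g.exons_t)
    model = TranscriptModel(
        model_id="Model 1",
        exons=exons,
        strand=g.strand,
        cds=tuple(sorted(g.iv_t2g(g.cds_t))),
        utr5=[g.iv_t2g(g.utr5_t)],
        utr3=[g.iv_t2g(g.utr3_t)],
    )
    return GeneModelSet(
        gene_id=g.gene_id, contig=CONTIG, strand=g.strand, models=[model]
    )


def build_toy_locus(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, GenomeSequence], dict[str, GeneModelSet], dict[str, SimGene], SimTruth]:
    """Deterministically build the toy genome, annotation and truth skeleton."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    strands = config.strands or "".join(
        "+-"[i % 2] for i in range(config.n_genes)
    )
    if len(strands) != config.n_genes:
        raise ValueError("strands must have one entry per gene")
    sim_genes: dict[str, SimGene] = {}
    pieces: list[str] = [_rand_seq(rng, _FLANK)]
    gstart = _FLANK
    for i in range(config.n_genes):
        g = _build_gene(config, rng, i, gstart, strands[i])
        body = g.premrna if g.strand == "+" else revcomp(g.premrna)
        pieces.append(body)
        sim_genes[g.gene_id] = g
        gstart += g.length
        pieces.append(_rand_seq(rng, _SPACER))
        gstart += _SPACER
    contig = GenomeSequence(CONTIG, "".join(pieces))
    genes = {gid: _gene_model_set(g) for gid, g in sim_genes.items()}
    truth = SimTruth()
    for g in sim_genes.values():
        for iv in g.introns_t:
            truth.true_junctions.append(
                {
                    "gene_id": g.gene_id,
                    "intron": g.iv_t2g(iv),
                    "event_type": "ANNOTATED",
                    "novel": False,
                }
            )
    return {CONTIG: contig}, genes, sim_genes, truth


def _plan_species(
    config: SimConfig, sim_genes: dict[str, SimGene], truth: SimTruth
) -> dict[str, list[tuple[Species, float]]]:
    """Expand the isoform plan into species with relative abundances, per gene."""
    out: dict[str, list[tuple[Species, float]]] = {}
    for i, g in enumerate(sim_genes.values()):
        plan = (
            config.isoform_plan[i]
            if config.isoform_plan is not None
            else default_isoform_plan(i)
        )
        species_list: list[tuple[Species, float]] = []
        used_pas: set[str] = set()
        for j, (variant, pas_key, abundance) in enumerate(plan):
            introns = list(g.introns_t)
            if variant == "A5SS":
                introns[0] = g.variant_introns_t["A5SS"]
            elif variant == "A3SS":
                introns[0] = g.variant_introns_t["A3SS"]
            elif variant == "EI":
                introns.append(g.variant_introns_t["EI"])
            elif variant == "ES":
                introns = [g.variant_introns_t["ES"]]
            elif variant == "INTRON_RETENTION":
                pass  # annotated introns upstream of the cleavage; rest retained
            elif variant != "ANNOTATED":
                raise ValueError(f"unknown isoform variant {variant!r}")
            cleavage = g.pas_t[pas_key]
            introns = [iv for iv in introns if iv[1] <= cleavage]
            sp = Species(
                species_id=f"{g.gene_id}.iso{j}",
                gene_id=g.gene_id,
                kind="isoform",
                introns_t=tuple(sorted(introns)),
                aligned_end_t=cleavage,
                cleavage_t=cleavage,
                tail_mode="polyA",
                pas_region="INTRON" if pas_key == "intron" else "UTR3",
                event_label=variant,
            )
            species_list.append((sp, abundance))
            truth.species[sp.species_id] = sp
            if variant not in ("ANNOTATED", "INTRON_RETENTION"):
                truth.true_junctions.append(
                    {
                        "gene_id": g.gene_id,
                        "intron": g.iv_t2g(g.variant_introns_t[variant]),
                        "event_type": variant,
                        "novel": True,
                    }
                )
            if pas_key not in used_pas:
                used_pas.add(pas_key)
                truth.true_pas.append(
                    {
                        "gene_id": g.gene_id,
                        "pos": g.t2g(cleavage),
                        "region": sp.pas_region,
                        "pas_key": pas_key,
                    }
                )
        out[g.gene_id] = species_list
    return out


def truncation_probability(rate_per_A: float, a_count: int) -> float:
    """Per-molecule chance that RT truncates at an A-rich site (monotone in A)."""
    return min(1.0, rate_per_A * a_count)


def transcribe_and_rt(
    config: SimConfig,
    sim_genes: dict[str, SimGene],
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, int]]:
    """Build per-experiment molecule pools: full-length cDNAs plus truncations.

    Full-length molecules carry a poly(A) tail (drawn around the configured
    mean at read emission); each isoform whose mature transcript crosses the
    planted internal A-tract additionally spawns a truncated species ending
    at the tract, with probability per molecule given by
    :func:`truncation_probability`.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    plan = _plan_species(config, sim_genes, truth)
    pools: dict[str, dict[str, int]] = {e: {} for e in config.experiments}
    ip_recorded: set[str] = set()
    for exp in config.experiments:
        total = config.templates(exp)
        per_gene = total / len(sim_genes)
        for g in sim_genes.values():
            for sp, abundance in plan[g.gene_id]:
                n = int(round(per_gene * abundance))
                pools[exp][sp.species_id] = pools[exp].get(sp.species_id, 0) + n
                # Internal priming off this isoform's transcripts.
                tract_in = (
                    g.a_tract_t + g.a_tract_len <= sp.aligned_end_t
                    and not any(
                        s <= g.a_tract_t < e for s, e in sp.introns_t
                    )
                )
                if tract_in and config.internal_priming_rate_per_A > 0 and n > 0:
                    p = truncation_probability(
                        config.internal_priming_rate_per_A, g.a_tract_len
                    )
                    n_tr = int(rng.binomial(n, p))
                    if n_tr == 0:
                        continue
                    ip_id = f"{sp.species_id}.ip"
                    if ip_id not in truth.species:
                        ip = Species(
                            species_id=ip_id,
                            gene_id=g.gene_id,
                            kind="internal_priming",
                            introns_t=tuple(
                                iv for iv in sp.introns_t if iv[1] <= g.a_tract_t
                            ),
                            aligned_end_t=g.a_tract_t + g.a_tract_len - 1,
                            cleavage_t=g.a_tract_t - 1,
                            tail_mode="fixed12",
                        )
                        truth.species[ip_id] = ip
                    pools[exp][ip_id] = pools[exp].get(ip_id, 0) + n_tr
                    if g.gene_id not in ip_recorded:
                        ip_recorded.add(g.gene_id)
                        truth.internal_priming_sites.append(
                            {
                                "gene_id": g.gene_id,
                                "pos": g.t2g(g.a_tract_t - 1),
                                "a_count_10nt": g.a_tract_len,
                            }
                        )
        truth.molecules[exp] = dict(pools[exp])
    return pools


def _amplify_species(
    n0: int, cycles: int, rng: np.random.Generator, eff: tuple[float, float],
    cap: int = 1_000_000,
) -> tuple[float, list[float]]:
    """Branching-process amplification; returns final weight and trajectory."""
    mean_growth = 1.0 + (eff[0] + eff[1]) / 2.0
    n = float(n0)
    traj: list[float] = []
    for _ in range(cycles):
        traj.append(n)
        if n <= 0:
            continue
        if n <= cap:
            e = rng.uniform(*eff)
            n = n + float(rng.binomial(int(n), e))
        else:
            n *= mean_growth
    return n, traj


def amplify(
    pool: dict[str, int],
    config: SimConfig,
    experiment_id: str,
    truth: SimTruth,
    sim_genes: dict[str, SimGene],
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Amplify one experiment's molecule pool; may spawn chimera species.

    Each species follows an independent branching process. At every cycle,
    each molecule of an eligible parent (an isoform whose mature transcript
    contains both planted repeat copies) seeds a direct-repeat chimera with
    probability ``drs_chimera_rate``; the seeds then grow at the expected
    rate for the remaining cycles. Early seeds therefore dominate, exactly
    the dynamics that make these artifacts sporadic between experiments.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 2, int(experiment_id[-1])])
    cycles = config.cycles(experiment_id)
    mean_growth = 1.0 + sum(config.pcr_efficiency) / 2.0
    weights: dict[str, float] = {}
    chimera_seed_weight: dict[str, float] = {}
    for sp_id, n0 in sorted(pool.items()):
        final, traj = _amplify_species(n0, cycles, rng, config.pcr_efficiency)
        weights[sp_id] = final
        sp = truth.species[sp_id]
        g = sim_genes[sp.gene_id]
        r1, r2 = g.repeat_t
        eligible = (
            sp.kind == "isoform"
            and config.drs_chimera_rate > 0
            and r2 + g.repeat_len <= sp.aligned_end_t
            and not any(s <= r1 < e or s <= r2 < e for s, e in sp.introns_t)
        )
        if not eligible:
            continue
        ch_id = f"{sp.gene_id}.chimera"
        if ch_id not in truth.species:
            ch_intron = g.apparent_chimera_intron_t
            ch = Species(
                species_id=ch_id,
                gene_id=sp.gene_id,
                kind="chimera",
                introns_t=tuple(sorted([*sp.introns_t, ch_intron])),
                aligned_end_t=sp.aligned_end_t,
                cleavage_t=sp.cleavage_t,
                tail_mode="polyA",
            )
            truth.species[ch_id] = ch
            truth.chimera_junctions.append(
                {
                    "gene_id": sp.gene_id,
                    "intron": g.iv_t2g(ch_intron),
                    "repeat_len": g.repeat_len,
                }
            )
        acc = 0.0
        for c, n_c in enumerate(traj):
            lam = n_c * config.drs_chimera_rate
            seeds = float(rng.poisson(lam)) if lam < 1000 else lam
            if seeds:
                acc += seeds * mean_growth ** (cycles - 1 - c)
        if acc:
            chimera_seed_weight[ch_id] = chimera_seed_weight.get(ch_id, 0.0) + acc
    for ch_id, w in chimera_seed_weight.items():
        weights[ch_id] = weights.get(ch_id, 0.0) + w
    truth.weights[experiment_id] = dict(weights)
    return weights


def monte_carlo_trial(
    seed: int,
    low_copies: int = 1,
    high_copies: int = 1000,
    n_reads: int = 2000,
    config: SimConfig | None = None,
) -> dict[str, dict[str, int]]:
    """Amplify a two-species pool in both experiments and sample read counts.

    Isolates the Monte Carlo effect: a low-copy and a high-copy template are
    co-amplified under each experiment's cycle count, then ``n_reads`` are
    drawn multinomially from the final weights. Returns per-experiment read
    counts for the "low" and "high" species; a species with zero reads in an
    experiment has dropped out.
    """
    cfg = config or SimConfig(seed=seed)
    out: dict[str, dict[str, int]] = {}
    for k, exp in enumerate(cfg.experiments):
        rng = np.random.default_rng([seed, 7, k])
        w = {}
        for name, n0 in (("low", low_copies), ("high", high_copies)):
            w[name], _ = _amplify_species(n0, cfg.cycles(exp), rng, cfg.pcr_efficiency)
        total = w["low"] + w["high"]
        counts = rng.multinomial(n_reads, [w["low"] / total, w["high"] / total])
        out[exp] = {"low": int(counts[0]), "high": int(counts[1])}
    return out


def _species_seq(sp: Species, g: SimGene) -> str:
    return "".join(g.premrna[a:b] for a, b in sp.mature_blocks())


def _mature_to_genomic_blocks(
    sp: Species, g: SimGene, ms: int, me: int
) -> list[tuple[int, int]]:
    """Map a mature-transcript interval [ms, me) to sorted genomic intervals."""
    out: list[tuple[int, int]] = []
    off = 0
    for ts, te in sp.mature_blocks():
        blen = te - ts
        lo, hi = max(ms - off, 0), min(me - off, blen)
        if lo < hi:
            out.append(g.iv_t2g((ts + lo, ts + hi)))
        off += blen
    return sorted(out)


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    g: SimGene,
    sp: Species,
    frag_seq: str,
    aligned_len: int,
    ms: int,
) -> pysam.AlignedSegment | None:
    """Build the truth alignment of one fragment (sense coords within the molecule)."""
    blocks = _mature_to_genomic_blocks(sp, g, ms, ms + aligned_len)
    if not blocks:
        return None
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    soft = len(frag_seq) - aligned_len
    cig: list[tuple[int, int]] = []
    if g.strand == "+":
        seq = frag_seq
        flag = 0
        for i, (a, b) in enumerate(blocks):
            if i:
                cig.append((3, a - blocks[i - 1][1]))
            cig.append((0, b - a))
        if soft:
            cig.append((4, soft))
    else:
        seq = revcomp(frag_seq)
        flag = 16
        if soft:
            cig.append((4, soft))
        for i, (a, b) in enumerate(blocks):
            if i:
                cig.append((3, a - blocks[i - 1][1]))
            cig.append((0, b - a))
    seg.flag = flag
    seg.reference_id = 0
    seg.reference_start = blocks[0][0]
    seg.mapping_quality = 60
    seg.cigartuples = cig
    seg.query_sequence = seq
    seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    seg.set_tag("NM", 0)
    return seg


def emit_reads(
    weights: dict[str, dict[str, float]],
    config: SimConfig,
    sim_genes: dict[str, SimGene],
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[pysam.AlignedSegment]], dict[str, list[tuple[str, str]]], pysam.AlignmentHeader]:
    """Fragment the amplicon pools and emit truth alignments plus raw reads.

    Returns per-experiment truth alignments (one single-end record per
    sonication fragment, spliced through every true or chimeric junction,
    with tail and adaptor soft-clipped), and the fragment-sense sequences
    used to cut paired FASTQ reads.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 3])
    contig_len = _FLANK + sum(g.length + _SPACER for g in sim_genes.values())
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": CONTIG, "LN": contig_len}],
        }
    )
    rc_stem = config.adaptor.rc_stem
    sams: dict[str, list[pysam.AlignedSegment]] = {}
    raw: dict[str, list[tuple[str, str]]] = {}
    tail_p = 1.0 / max(config.polyA_mean - 7, 1)
    for exp in config.experiments:
        w = weights[exp]
        ids = sorted(w)
        total = sum(w[i] for i in ids)
        probs = np.array([w[i] / total for i in ids])
        counts = rng.multinomial(config.reads_per_experiment, probs)
        truth.read_counts[exp] = {i: int(c) for i, c in zip(ids, counts)}
        segs: list[pysam.AlignedSegment] = []
        seqs: list[tuple[str, str]] = []
        for sp_id, n in zip(ids, counts):
            if n == 0:
                continue
            sp = truth.species[sp_id]
            g = sim_genes[sp.gene_id]
            mature = _species_seq(sp, g)
            for i in range(n):
                tail = 12 if sp.tail_mode == "fixed12" else 7 + int(rng.geometric(tail_p))
                amplicon = mature + "A" * tail + rc_stem
                alen = len(amplicon)
                flo, fhi = config.fragment_len_range
                flen = min(alen, int(rng.integers(flo, fhi + 1)))
                start = int(rng.integers(0, alen - flen + 1))
                frag = amplicon[start : start + flen]
                name = f"{sp_id}|{exp}|{i}"
                seqs.append((name, frag))
                aligned_len = min(start + flen, len(mature)) - start
                if aligned_len >= 20:
                    seg = _make_segment(header, name, g, sp, frag, aligned_len, start)
                    if seg is not None:
                        segs.append(seg)
        segs.sort(key=lambda s: (s.reference_start, s.query_name))
        sams[exp] = segs
        raw[exp] = seqs
    return sams, raw, header


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Run the full simulation; optionally write genome/annotation/SAM/FASTQ."""
    rng_locus = np.random.default_rng([config.seed, 0])
    contigs, genes, sim_genes, truth = build_toy_locus(config, rng_locus)
    rng_rt = np.random.default_rng([config.seed, 1])
    pools = transcribe_and_rt(config, sim_genes, truth, rng_rt)
    weights: dict[str, dict[str, float]] = {}
    for k, exp in enumerate(config.experiments):
        rng_amp = np.random.default_rng([config.seed, 2, k])
        weights[exp] = amplify(pools[exp], config, exp, truth, sim_genes, rng_amp)
    rng_emit = np.random.default_rng([config.seed, 3])
    sams, raw, header = emit_reads(weights, config, sim_genes, truth, rng_emit)
    result = SimResult(
        config=config,
        contigs=contigs,
        genes=genes,
        sim_genes=sim_genes,
        truth=truth,
        alignments=sams,
        header=header,
        reads=raw,
    )
    if outdir is not None:
        result.paths = write_outputs(result, Path(outdir))
    return result


def write_gff3(genes: dict[str, GeneModelSet], path: Path) -> None:
    lines = ["##gff-version 3"]
    for gid in sorted(genes):
        g = genes[gid]
        lines.append(
            f"{g.contig}\trace3seq-sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={gid}"
        )
        for m in g.models:
            mid = f"{gid}.{m.model_id.replace(' ', '')}"
            lines.append(
                f"{g.contig}\trace3seq-sim\tmRNA\t{m.start + 1}\t{m.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={gid}"
            )
            for kind, ivs in (
                ("exon", m.exons),
                ("five_prime_UTR", m.utr5),
                ("three_prime_UTR", m.utr3),
                ("CDS", [m.cds] if m.cds else []),
            ):
                for a, b in ivs:
                    lines.append(
                        f"{g.contig}\trace3seq-sim\t{kind}\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                        f"ID={mid}.{kind};Parent={mid}"
                    )
    path.write_text("\n".join(lines) + "\n")


def write_outputs(result: SimResult, outdir: Path) -> dict[str, Path]:
    """Write FASTA, GFF3, per-experiment truth SAM and paired FASTQ, truth JSON."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fa = outdir / "genome.fa"
    contig = result.contigs[CONTIG]
    with fa.open("w") as fh:
        fh.write(f">{CONTIG}\n")
        for i in range(0, len(contig.sequence), 80):
            fh.write(contig.sequence[i : i + 80] + "\n")
    paths["genome"] = fa
    gff = outdir / "annotation.gff3"
    write_gff3(result.genes, gff)
    paths["annotation"] = gff
    rl = result.config.read_length
    for exp, segs in result.alignments.items():
        sam_path = outdir / f"{exp}.truth.sam"
        with pysam.AlignmentFile(str(sam_path), "w", header=result.header) as out:
            for seg in segs:
                out.write(seg)
        paths[f"sam_{exp}"] = sam_path
        if result.config.paired:
            r1 = outdir / f"{exp}_R1.fastq.gz"
            r2 = outdir / f"{exp}_R2.fastq.gz"
            with gzip.open(r1, "wt") as f1, gzip.open(r2, "wt") as f2:
                for name, frag in result.reads[exp]:
                    a = frag[:rl]
                    b = revcomp(frag[-rl:])
                    f1.write(f"@{name}/1\n{a}\n+\n{'I' * len(a)}\n")
                    f2.write(f"@{name}/2\n{b}\n+\n{'I' * len(b)}\n")
            paths[f"fastq1_{exp}"] = r1
            paths[f"fastq2_{exp}"] = r2
    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "true_junctions": result.truth.true_junctions,
                "chimera_junctions": result.truth.chimera_junctions,
                "true_pas": result.truth.true_pas,
                "internal_priming_sites": result.truth.internal_priming_sites,
                "molecules": result.truth.molecules,
                "read_counts": result.truth.read_counts,
            },
            indent=1,
        )
    )
    paths["truth"] = truth_path
    return paths
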