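"""Synthetic paired-assembly generator with a ground-truth ledger.

The generator emulates the situation the analysis is built for: a
high-quality "truth" genome with multi-exon genes whose promoters and
first exons are GC-rich CpG islands for a configurable fraction of
genes, interspersed softmasked repeats, and a degraded "prior-like"
copy suffering GC-biased sequence dropout, repeat-driven fragmentation,
N gaps, base errors, heterozygous-site differences, and engineered
events of all eight false-gene-loss types.  Every change is recorded in
a :class:`TruthLedger` with coordinates on both assemblies, and exact
alignment chains are emitted from the edit script, so downstream calls
can be scored against a known answer.

Identifiability conventions (what the generator deliberately does not
mix): random GC-dropout tiles avoid exons and engineered-event loci,
repeats are intergenic, and stochastic base errors / het sites avoid
coding sequence and splice junctions — each gene-level defect therefore
has exactly one recorded cause.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assembly import Assembly, revcomp
from .chain import AlignmentChain, write_paf
from .genes import GeneModel, GeneSet, TranscriptModel, write_gff3
from .intervals import GenomicInterval, IntervalSet
from .variants import Pileup

__all__ = [
    "SimulationConfig",
    "TruthEvent",
    "TruthLedger",
    "TruthGenome",
    "SimulationBundle",
    "generate_truth",
    "degrade",
    "simulate_pileup",
    "simulate_bundle",
    "write_bundle",
]

EVENT_TYPES = (
    "completely_missing",
    "missing_exon",
    "fragmented",
    "translocation",
    "frameshift",
    "premature_stop",
    "cds_Ns",
    "splice_disruption",
)
STRUCTURAL_TYPES = EVENT_TYPES[:4]
SEQUENCE_TYPES = EVENT_TYPES[4:]
AUX_TYPES = ("dropout_region", "repeat_break", "het_site", "base_error")

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
NON_STOP_CODONS = [c for c in _CODONS if c not in STOP_CODONS]
# CpG-bearing, GC-rich codons for CGI first exons
GC_RICH_CODONS = ["GCG", "CGC", "CCG", "CGG", "GCC", "GGC", "CGT", "ACG", "TCG", "GCA"]
FRAMESHIFT_LENGTHS = (1, 2, 4, 5, 7, 8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic paired-assembly experiment.

    Defaults describe the standard desk-scale bundle: a 5-Mbp,
    4-sequence genome with 300 coding genes, 75% of which carry a
    GC-rich (70% GC) CpG-island promoter and first exon on a 42%-GC
    background, ~7% intergenic softmasked repeat, logistic GC-dependent
    dropout of 100-bp tiles, 40 engineered events of each of the eight
    false-gene-loss types, and 30x read pileups.
    """

    seed: int = 0
    # genome shape
    n_sequences: int = 4
    sequence_length: int = 1_250_000
    n_genes: int = 300
    n_noncoding_genes: int = 40
    fraction_with_upstream_cgi: float = 0.75
    fraction_multi_exon: float = 1.0
    background_gc: float = 0.42
    promoter_gc: float = 0.70
    promoter_length: int = 1000
    coding_exon_count: Tuple[int, int] = (4, 8)
    cds_exon_length: Tuple[int, int] = (120, 280)
    intron_length: Tuple[int, int] = (300, 800)
    utr5_length: int = 100
    utr3_length: int = 150
    min_intergenic: int = 3500
    # repeats
    n_repeat_families: int = 3
    repeat_unit_length: Tuple[int, int] = (400, 800)
    n_repeat_copies: int = 600
    repeat_copy_divergence: float = 0.01
    repeat_break_fraction: float = 0.25
    # degradation
    dropout_midpoint_gc: float = 0.60
    dropout_steepness: float = 12.0
    dropout_tile: int = 100
    n_gap_fraction: float = 0.5
    event_counts: Dict[str, int] = field(
        default_factory=lambda: {t: 40 for t in EVENT_TYPES}
    )
    # sequence-level noise
    het_site_count: int = 200
    n_base_errors: int = 200
    gc_biased_errors: bool = True
    # GC weighting of error placement; None reuses the dropout curve
    error_gc_midpoint: Optional[float] = None
    error_gc_steepness: Optional[float] = None
    # reads
    read_depth: float = 30.0
    read_length: int = 150
    read_error_rate: float = 0.002
    prior_read_coverage: float = 0.5  # depth of prior reads over missing regions

    def validate(self) -> None:
        for name in ("fraction_with_upstream_cgi", "fraction_multi_exon",
                     "background_gc", "promoter_gc", "n_gap_fraction",
                     "repeat_break_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0,1], got {v}")
        if self.sequence_length <= 0 or self.n_sequences <= 0:
            raise ValueError("sequence dimensions must be positive")
        if any(v < 0 for v in self.event_counts.values()):
            raise ValueError("event counts must be >= 0")
        unknown = set(self.event_counts) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event types {sorted(unknown)}")
        if self.read_depth <= 0:
            raise ValueError("read depth must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=list)


@dataclass
class TruthEvent:
    """One engineered change, with coordinates on both assemblies."""

    type: str
    gene_id: str
    ref_sequence: str
    ref_start: int
    ref_end: int
    prior_sequence: str = ""
    prior_start: int = -1
    prior_end: int = -1
    payload: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES + AUX_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


class TruthLedger:
    def __init__(self, events: Optional[List[TruthEvent]] = None):
        self.events: List[TruthEvent] = list(events or [])

    def add(self, event: TruthEvent) -> None:
        self.events.append(event)

    def of_type(self, *types: str) -> List[TruthEvent]:
        return [e for e in self.events if e.type in types]

    def gene_level(self) -> List[TruthEvent]:
        return self.of_type(*EVENT_TYPES)

    def missing_truth_regions(self) -> IntervalSet:
        """Reference intervals expected to be unalignable against the
        degraded assembly (deleted or N-replaced)."""
        rows = []
        for e in self.events:
            deleted = (
                e.type in ("completely_missing", "missing_exon", "repeat_break", "cds_Ns")
                or (e.type == "dropout_region")
                or (e.type == "frameshift" and e.payload.get("kind") == "deletion")
            )
            if deleted and e.ref_end > e.ref_start:
                rows.append((e.ref_sequence, e.ref_start, e.ref_end))
        return IntervalSet.from_intervals(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "type": e.type,
                    "gene_id": e.gene_id,
                    "ref_sequence": e.ref_sequence,
                    "ref_start": e.ref_start,
                    "ref_end": e.ref_end,
                    "prior_sequence": e.prior_sequence,
                    "prior_start": e.prior_start,
                    "prior_end": e.prior_end,
                    "payload": json.dumps(e.payload, sort_keys=True),
                }
                for e in self.events
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthLedger":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        events = [
            TruthEvent(
                type=r["type"],
                gene_id=str(r["gene_id"]),
                ref_sequence=r["ref_sequence"],
                ref_start=int(r["ref_start"]),
                ref_end=int(r["ref_end"]),
                prior_sequence=r["prior_sequence"],
                prior_start=int(r["prior_start"]),
                prior_end=int(r["prior_end"]),
                payload=json.loads(r["payload"]) if r["payload"] else {},
            )
            for _, r in df.iterrows()
        ]
        return cls(events)


@dataclass
class TruthGenome:
    assembly: Assembly
    genes: GeneSet
    softmask: IntervalSet
    cgi_truth: IntervalSet


@dataclass
class SimulationBundle:
    config: SimulationConfig
    truth: TruthGenome
    degraded: Assembly
    ledger: TruthLedger
    chains: List[AlignmentChain]
    reference_pileup: Pileup
    prior_pileup: Pileup
    prior_read_depth_on_ref: Dict[str, np.ndarray]


# ======================================================================
# truth genome
# ======================================================================
_B = np.frombuffer(b"ACGT", dtype=np.uint8)

# Vertebrate neutral sequence is strongly CpG-depleted (methylation and
# deamination); the observed/expected CpG ratio of bulk genome is ~0.2-0.3.
# Background sequence keeps only this fraction of chance CpG dinucleotides,
# which is what makes CpG islands a detectable signal at all.
CPG_KEEP_BACKGROUND = 0.25


def _random_seq(
    rng: np.random.Generator, n: int, gc: float, cpg_keep: float = CPG_KEEP_BACKGROUND
) -> str:
    if n <= 0:
        return ""
    # compensate for the G->H replacements so realised GC matches the target
    if cpg_keep < 1.0:
        g = gc
        for _ in range(3):
            p_c_given_repl = (g / 2) / (1 - g / 2)
            loss = (g / 2) ** 2 * (1 - cpg_keep) * (1 - p_c_given_repl)
            g = gc + loss
        gc_in = min(g, 0.98)
    else:
        gc_in = gc
    p = np.array([(1 - gc_in) / 2, gc_in / 2, gc_in / 2, (1 - gc_in) / 2])
    arr = rng.choice(_B, size=n, p=p)
    if cpg_keep < 1.0:
        repl_p = p.copy()
        repl_p[2] = 0.0  # never replace by G
        repl_p /= repl_p.sum()
        cg = np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]
        drop = cg[rng.random(len(cg)) >= cpg_keep]
        if len(drop):
            arr[drop + 1] = rng.choice(_B, size=len(drop), p=repl_p)
            # a replacement by C can create a fresh CpG one step right
            new = drop + 1
            new = new[new + 1 < n]
            new = new[(arr[new] == ord("C")) & (arr[new + 1] == ord("G"))]
            drop2 = new[rng.random(len(new)) >= cpg_keep]
            if len(drop2):
                arr[drop2 + 1] = rng.choice(_B, size=len(drop2), p=repl_p)
    return arr.tobytes().decode("ascii")


def _codon_weights(gc: float = 0.42, cpg_keep: float = CPG_KEEP_BACKGROUND) -> np.ndarray:
    """Background codon usage: base composition at the stated GC with
    codon-internal CpG suppressed, mirroring the depleted bulk genome."""
    pb = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    w = []
    for codon in NON_STOP_CODONS:
        x = pb[codon[0]] * pb[codon[1]] * pb[codon[2]]
        x *= cpg_keep ** codon.count("CG")
        w.append(x)
    w = np.array(w)
    return w / w.sum()


_BACKGROUND_CODON_P = _codon_weights()


def _random_codons(
    rng: np.random.Generator, n: int, pool: Sequence[str],
    p: Optional[np.ndarray] = None,
) -> str:
    if n <= 0:
        return ""
    idx = rng.choice(len(pool), size=n, p=p)
    return "".join(pool[i] for i in idx)


@dataclass
class _Cassette:
    gene_id: str
    biotype: str
    seq: str
    tss_offset: int
    exon_offsets: List[Tuple[int, int]]  # transcript orientation, cassette coords
    cds_offsets: List[Tuple[int, int]]
    with_cgi: bool
    cgi_span: Optional[Tuple[int, int]] = None  # cassette coords


def _build_coding_cassette(
    rng: np.random.Generator, cfg: SimulationConfig, gene_id: str, with_cgi: bool
) -> _Cassette:
    lo, hi = cfg.coding_exon_count
    multi = rng.random() < cfg.fraction_multi_exon
    n_exons = int(rng.integers(lo, hi + 1)) if multi else int(rng.integers(1, lo))
    cds_lens = [int(rng.integers(*cfg.cds_exon_length)) for _ in range(n_exons)]
    pad = (3 - sum(cds_lens) % 3) % 3
    cds_lens[-1] += pad
    n_codons = sum(cds_lens) // 3
    first_codons = cds_lens[0] // 3 + 1
    prom_gc = cfg.promoter_gc if with_cgi else cfg.background_gc
    first_pool = GC_RICH_CODONS if with_cgi else NON_STOP_CODONS
    first_p = None if with_cgi else _BACKGROUND_CODON_P
    cds = (
        "ATG"
        + _random_codons(rng, min(first_codons, n_codons - 2), first_pool, p=first_p)
        + _random_codons(rng, max(0, n_codons - 2 - first_codons), NON_STOP_CODONS, p=_BACKGROUND_CODON_P)
        + STOP_CODONS[rng.integers(0, 3)]
    )
    assert len(cds) == n_codons * 3

    keep = 1.0 if with_cgi else CPG_KEEP_BACKGROUND
    promoter = _random_seq(rng, cfg.promoter_length, prom_gc, cpg_keep=keep)
    utr5 = _random_seq(rng, cfg.utr5_length, prom_gc, cpg_keep=keep)
    utr3 = _random_seq(rng, cfg.utr3_length, cfg.background_gc)

    parts = [promoter]
    pos = len(promoter)
    exon_offsets, cds_offsets = [], []
    cds_cursor = 0
    for i, clen in enumerate(cds_lens):
        exon_start = pos
        if i == 0:
            parts.append(utr5)
            pos += len(utr5)
        cds_offsets.append((pos, pos + clen))
        parts.append(cds[cds_cursor : cds_cursor + clen])
        cds_cursor += clen
        pos += clen
        if i == n_exons - 1:
            parts.append(utr3)
            pos += len(utr3)
        exon_offsets.append((exon_start, pos))
        if i < n_exons - 1:
            ilen = int(rng.integers(*cfg.intron_length))
            parts.append("GT" + _random_seq(rng, ilen - 4, cfg.background_gc) + "AG")
            pos += ilen
    cgi_span = (0, exon_offsets[0][1]) if with_cgi else None
    return _Cassette(
        gene_id=gene_id,
        biotype="protein_coding",
        seq="".join(parts),
        tss_offset=len(promoter),
        exon_offsets=exon_offsets,
        cds_offsets=cds_offsets,
        with_cgi=with_cgi,
        cgi_span=cgi_span,
    )


def _build_noncoding_cassette(
    rng: np.random.Generator, cfg: SimulationConfig, gene_id: str
) -> _Cassette:
    e1 = int(rng.integers(200, 400))
    e2 = int(rng.integers(200, 400))
    ilen = int(rng.integers(*cfg.intron_length))
    seq = (
        _random_seq(rng, e1, cfg.background_gc)
        + "GT" + _random_seq(rng, ilen - 4, cfg.background_gc) + "AG"
        + _random_seq(rng, e2, cfg.background_gc)
    )
    return _Cassette(
        gene_id=gene_id,
        biotype="lncRNA",
        seq=seq,
        tss_offset=0,
        exon_offsets=[(0, e1), (e1 + ilen, e1 + ilen + e2)],
        cds_offsets=[],
        with_cgi=False,
    )


def _mirror(iv: Tuple[int, int], length: int) -> Tuple[int, int]:
    return length - iv[1], length - iv[0]


def generate_truth(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> TruthGenome:
    """Build the truth assembly, gene annotation, softmask and CGI truth.

    Output is byte-identical for equal seeds.  Raises when the requested
    genes and repeats cannot be packed into the stated sequence lengths.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])

    repeat_units = [
        _random_seq(rng, int(rng.integers(*cfg.repeat_unit_length)), cfg.background_gc)
        for _ in range(cfg.n_repeat_families)
    ]

    cassettes: List[_Cassette] = []
    for i in range(cfg.n_genes):
        with_cgi = rng.random() < cfg.fraction_with_upstream_cgi
        cassettes.append(_build_coding_cassette(rng, cfg, f"gene{i:04d}", with_cgi))
    for i in range(cfg.n_noncoding_genes):
        cassettes.append(_build_noncoding_cassette(rng, cfg, f"ncgene{i:04d}"))
    order = rng.permutation(len(cassettes))
    per_seq: List[List[_Cassette]] = [[] for _ in range(cfg.n_sequences)]
    for j, idx in enumerate(order):
        per_seq[j % cfg.n_sequences].append(cassettes[idx])

    copies_left = cfg.n_repeat_copies
    sequences: Dict[str, str] = {}
    genes: List[GeneModel] = []
    softmask_rows, cgi_rows = [], []
    margin = 100

    for si in range(cfg.n_sequences):
        name = f"chr{si + 1}"
        cas = per_seq[si]
        cassette_total = sum(len(c.seq) for c in cas)
        n_gaps = len(cas) + 1
        budget = cfg.sequence_length - cassette_total
        if budget < n_gaps * cfg.min_intergenic:
            need = cassette_total + n_gaps * cfg.min_intergenic
            raise ValueError(
                f"infeasible packing on {name}: require sequence_length >= {need}"
            )
        extra = rng.multinomial(budget - n_gaps * cfg.min_intergenic, [1 / n_gaps] * n_gaps)
        gap_lens = [cfg.min_intergenic + int(x) for x in extra]

        # distribute repeat copies over this sequence's gaps
        share = copies_left if si == cfg.n_sequences - 1 else round(cfg.n_repeat_copies / cfg.n_sequences)
        share = min(share, copies_left)
        copies_left -= share
        gap_copy_count = [0] * n_gaps
        capacity = [
            max(0, (g - 2 * margin) // (max(cfg.repeat_unit_length) + margin))
            for g in gap_lens
        ]
        for _ in range(share):
            open_gaps = [i for i in range(n_gaps) if gap_copy_count[i] < capacity[i]]
            if not open_gaps:
                break
            gi = open_gaps[rng.integers(0, len(open_gaps))]
            gap_copy_count[gi] += 1

        parts: List[str] = []
        pos = 0
        for gi in range(n_gaps):
            gap_seq, mask_local = _build_gap(
                rng, cfg, gap_lens[gi], gap_copy_count[gi], repeat_units, margin
            )
            for s, e in mask_local:
                softmask_rows.append((name, pos + s, pos + e))
            parts.append(gap_seq)
            pos += len(gap_seq)
            if gi < len(cas):
                c = cas[gi]
                strand = "+" if rng.random() < 0.5 else "-"
                clen = len(c.seq)
                if strand == "+":
                    parts.append(c.seq)
                    exons = [(pos + s, pos + e) for s, e in c.exon_offsets]
                    cds = [(pos + s, pos + e) for s, e in c.cds_offsets]
                    if c.cgi_span:
                        cgi_rows.append((name, pos + c.cgi_span[0], pos + c.cgi_span[1]))
                else:
                    parts.append(revcomp(c.seq))
                    exons = sorted(
                        tuple(pos + x for x in _mirror(iv, clen)) for iv in c.exon_offsets
                    )
                    cds = sorted(
                        tuple(pos + x for x in _mirror(iv, clen)) for iv in c.cds_offsets
                    )
                    if c.cgi_span:
                        ms, me = _mirror(c.cgi_span, clen)
                        cgi_rows.append((name, pos + ms, pos + me))
                tid = f"{c.gene_id}.t1"
                gene = GeneModel(
                    id=c.gene_id, sequence=name, strand=strand, biotype=c.biotype
                )
                gene.transcripts[tid] = TranscriptModel(
                    id=tid, gene_id=c.gene_id, sequence=name, strand=strand,
                    exons=exons, cds=cds,
                )
                genes.append(gene)
                pos += clen
        sequences[name] = "".join(parts)
        assert len(sequences[name]) == cfg.sequence_length

    asm = Assembly(name="truth", sequences=sequences)
    softmask = IntervalSet.from_intervals(softmask_rows)
    asm = asm.with_softmask(softmask)
    return TruthGenome(
        assembly=asm,
        genes=GeneSet(genes),
        softmask=softmask,
        cgi_truth=IntervalSet.from_intervals(cgi_rows),
    )


def _build_gap(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    length: int,
    n_copies: int,
    repeat_units: List[str],
    margin: int,
) -> Tuple[str, List[Tuple[int, int]]]:
    """One intergenic stretch with lowercase repeat copies embedded."""
    copies = []
    for _ in range(n_copies):
        unit = repeat_units[rng.integers(0, len(repeat_units))]
        arr = np.frombuffer(unit.encode(), dtype=np.uint8).copy()
        nmut = rng.binomial(len(arr), cfg.repeat_copy_divergence)
        if nmut:
            at = rng.choice(len(arr), size=nmut, replace=False)
            arr[at] = _B[rng.integers(0, 4, size=nmut)]
        copies.append(arr.tobytes().decode().lower())
    total_rep = sum(len(c) for c in copies)
    bg_total = length - total_rep
    if bg_total < (n_copies + 1) * 1:
        raise ValueError("repeat copies exceed gap capacity")
    split = rng.multinomial(bg_total - (n_copies + 1) * margin, [1 / (n_copies + 1)] * (n_copies + 1)) \
        if bg_total >= (n_copies + 1) * margin else None
    if split is None:
        bg_lens = [bg_total] + [0] * n_copies
    else:
        bg_lens = [margin + int(x) for x in split]
    parts, mask = [], []
    pos = 0
    for i in range(n_copies + 1):
        bg = _random_seq(rng, bg_lens[i], cfg.background_gc)
        parts.append(bg)
        pos += len(bg)
        if i < n_copies:
            mask.append((pos, pos + len(copies[i])))
            parts.append(copies[i])
            pos += len(copies[i])
    return "".join(parts), mask


# ======================================================================
# degradation
# ======================================================================
@dataclass
class _Edit:
    start: int
    end: int
    kind: str  # del | ngap | inv | ins | break
    payload: str = ""


def _logistic_dropout(gc: np.ndarray, g0: float, s: float) -> np.ndarray:
    """Tile deletion probability.  Steepness 0 disables dropout."""
    if s <= 0:
        return np.zeros_like(gc)
    return 1.0 / (1.0 + np.exp(-s * (gc - g0)))


def _transcript_cds_positions(t: TranscriptModel) -> np.ndarray:
    segs = t.cds_5to3()
    if t.strand == "+":
        return np.concatenate([np.arange(s, e) for s, e in segs]) if segs else np.empty(0, int)
    return np.concatenate([np.arange(e - 1, s - 1, -1) for s, e in segs]) if segs else np.empty(0, int)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class _EventPlanner:
    """Chooses event genes and loci, producing edits plus ledger stubs."""

    def __init__(self, truth: TruthGenome, cfg: SimulationConfig, rng: np.random.Generator):
        self.truth = truth
        self.cfg = cfg
        self.rng = rng
        self.edits: Dict[str, List[_Edit]] = {n: [] for n in truth.assembly.sequences}
        self.stubs: List[Tuple[TruthEvent, _Edit | None]] = []
        self.guards: List[Tuple[str, int, int]] = []  # extra protected intervals
        self.used_exons: Dict[str, set] = {}
        self.used_introns: Dict[str, set] = {}

    def plan(self) -> None:
        counts = {t: int(self.cfg.event_counts.get(t, 0)) for t in EVENT_TYPES}
        eligible = [
            g for g in self.truth.genes.coding()
            if len(g.representative().cds_5to3()) >= 4
        ]
        order = self.rng.permutation(len(eligible))
        pool = [eligible[i] for i in order]
        need_structural = sum(counts[t] for t in STRUCTURAL_TYPES)
        need_sequence = sum(counts[t] for t in SEQUENCE_TYPES)
        if need_structural + math.ceil(need_sequence / 2) > len(pool):
            raise ValueError(
                f"more events requested ({need_structural + need_sequence}) than "
                f"eligible genes can host ({len(pool)})"
            )
        for t in STRUCTURAL_TYPES:
            for _ in range(counts[t]):
                gene = pool.pop()
                getattr(self, "_plan_" + t)(gene)
        # sequence-level events: up to two compatible events per gene
        assignments: List[Tuple[GeneModel, str]] = []
        single: List[Tuple[GeneModel, str]] = []
        todo = [(t, counts[t]) for t in SEQUENCE_TYPES]
        for t, n in todo:
            for _ in range(n):
                if pool:
                    gene = pool.pop()
                    single.append((gene, t))
                    assignments.append((gene, t))
                else:
                    host = next(
                        (
                            (g, ht) for g, ht in single
                            if ht != t and {ht, t} != {"frameshift", "premature_stop"}
                        ),
                        None,
                    )
                    if host is None:
                        raise ValueError("more events requested than eligible genes")
                    single.remove(host)
                    assignments.append((host[0], t))
        for gene, t in assignments:
            getattr(self, "_plan_" + t)(gene)

    # -- helpers -------------------------------------------------------
    def _internal_exon(self, gene: GeneModel) -> Tuple[int, Tuple[int, int]]:
        t = gene.representative()
        exons = t.exons_5to3()
        used = self.used_exons.setdefault(gene.id, set())
        options = [i for i in range(1, len(exons) - 1) if i not in used]
        if not options:
            raise ValueError(f"no free internal exon on {gene.id}")
        i = options[self.rng.integers(0, len(options))]
        used.add(i)
        return i, exons[i]

    def _free_intron(self, gene: GeneModel) -> Tuple[int, Tuple[int, int]]:
        t = gene.representative()
        introns = t.introns_5to3()
        used = self.used_introns.setdefault(gene.id, set())
        options = [i for i in range(len(introns)) if i not in used]
        if not options:
            raise ValueError(f"no free intron on {gene.id}")
        i = options[self.rng.integers(0, len(options))]
        used.add(i)
        return i, introns[i]

    def _add(self, gene: GeneModel, etype: str, start: int, end: int, edit: _Edit | None, **payload) -> None:
        if edit is not None:
            self.edits[gene.sequence].append(edit)
        self.stubs.append(
            (
                TruthEvent(
                    type=etype, gene_id=gene.id, ref_sequence=gene.sequence,
                    ref_start=start, ref_end=end, payload=payload,
                ),
                edit,
            )
        )

    # -- structural ----------------------------------------------------
    def _plan_completely_missing(self, gene: GeneModel) -> None:
        s, e = gene.start, gene.end
        self._add(gene, "completely_missing", s, e, _Edit(s, e, "del"))

    def _plan_missing_exon(self, gene: GeneModel) -> None:
        idx, (s, e) = self._internal_exon(gene)
        self._add(gene, "missing_exon", s, e, _Edit(s, e, "del"), exon_index=idx)

    def _plan_fragmented(self, gene: GeneModel) -> None:
        t = gene.representative()
        introns = t.introns()
        mid_i = introns[len(introns) // 2]
        p = (mid_i[0] + mid_i[1]) // 2
        self._add(gene, "fragmented", p, p, _Edit(p, p, "break"))

    def _plan_translocation(self, gene: GeneModel) -> None:
        t = gene.representative()
        ex5 = t.exons_5to3()[:2]
        intron2 = t.introns_5to3()[1]
        mid = (intron2[0] + intron2[1]) // 2
        if t.strand == "+":
            s, e = ex5[0][0] - 50, mid
        else:
            s, e = mid, ex5[0][1] + 50
        self._add(gene, "translocation", s, e, _Edit(s, e, "inv"))

    # -- sequence-level ------------------------------------------------
    def _plan_frameshift(self, gene: GeneModel) -> None:
        _, (s, e) = self._internal_exon(gene)
        length = int(self.rng.choice(FRAMESHIFT_LENGTHS))
        kind = "insertion" if self.rng.random() < 0.5 else "deletion"
        pos = int(self.rng.integers(s + 10, e - 10 - length))
        if kind == "deletion":
            edit = _Edit(pos, pos + length, "del")
            self._add(gene, "frameshift", pos, pos + length, edit, kind=kind, length=length)
        else:
            ins = _random_seq(self.rng, length, 0.5)
            edit = _Edit(pos, pos, "ins", payload=ins)
            self._add(gene, "frameshift", pos, pos + 1, edit, kind=kind, length=length, inserted=ins)

    def _plan_premature_stop(self, gene: GeneModel) -> None:
        t = gene.representative()
        seq = self.truth.assembly.sequences[gene.sequence]
        positions = _transcript_cds_positions(t)
        exons = t.exons_5to3()
        used = self.used_exons.setdefault(gene.id, set())
        internal = [
            (i, exons[i]) for i in range(1, len(exons) - 1) if i not in used
        ]
        n_codons = len(positions) // 3
        candidates = []
        for ci in range(2, n_codons - 2):
            p3 = positions[3 * ci : 3 * ci + 3]
            host = next(
                (i for i, (s, e) in internal if p3.min() >= s + 6 and p3.max() < e - 6),
                None,
            )
            if host is None:
                continue
            codon = "".join(
                seq[p].upper() if t.strand == "+" else _COMP[seq[p].upper()]
                for p in p3
            )
            if codon in STOP_CODONS:
                continue
            for stop in STOP_CODONS:
                diffs = [j for j in range(3) if codon[j] != stop[j]]
                if len(diffs) == 1:
                    candidates.append((ci, p3, codon, stop, diffs[0], host))
        if not candidates:
            raise ValueError(f"no premature-stop site available on {gene.id}")
        ci, p3, codon, stop, j, host = candidates[self.rng.integers(0, len(candidates))]
        used.add(host)
        gpos = int(p3[j])
        new_tbase = stop[j]
        gbase = new_tbase if t.strand == "+" else _COMP[new_tbase]
        self._add(
            gene, "premature_stop", int(p3.min()), int(p3.max()) + 1,
            _Edit(gpos, gpos + 1, "sub", payload=gbase),
            codon_index=ci, from_codon=codon, to_codon=stop,
        )

    def _plan_cds_Ns(self, gene: GeneModel) -> None:
        _, (s, e) = self._internal_exon(gene)
        run = 15
        pos = int(self.rng.integers(s + 5, e - 5 - run))
        self._add(gene, "cds_Ns", pos, pos + run, _Edit(pos, pos + run, "ngap"), run=run)

    def _plan_splice_disruption(self, gene: GeneModel) -> None:
        t = gene.representative()
        idx, (s, e) = self._free_intron(gene)
        if t.strand == "+":
            gpos, newbase = s + 1, "G"  # donor GT -> GG
        else:
            gpos, newbase = e - 2, "C"
        self._add(
            gene, "splice_disruption", gpos, gpos + 1,
            _Edit(gpos, gpos + 1, "sub", payload=newbase),
            intron_index=idx, junction="GT-AG->GG-AG",
        )
        # both junctions of the disrupted intron must stay liftable
        self.guards.append((gene.sequence, s - 10, s + 10))
        self.guards.append((gene.sequence, e - 10, e + 10))


def degrade(
    truth: TruthGenome,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Assembly, TruthLedger, List[AlignmentChain]]:
    """Apply GC-biased dropout, repeat collapses, noise and engineered
    events to the truth genome.

    Returns the degraded assembly, the ledger, and the exact alignment
    chains implied by the edit script (reference as query, degraded as
    target)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[1])
    asm = truth.assembly
    planner = _EventPlanner(truth, cfg, rng)
    planner.plan()

    # substitutions are applied to the sequence directly; interval edits
    # go through the structural edit applier
    edits: Dict[str, List[_Edit]] = {
        n: [ed for ed in v if ed.kind != "sub"] for n, v in planner.edits.items()
    }
    ledger = TruthLedger()

    # Protection keeps each engineered defect uniquely attributable:
    # dropout must not delete exon bases or engineered loci, and random
    # substitutions must additionally stay clear of splice junctions.
    prot_dropout_rows = {name: [] for name in asm.sequences}
    prot_subs_rows = {name: [] for name in asm.sequences}
    for gene in truth.genes:
        for t in gene.transcripts.values():
            for s, e in t.exons:
                prot_dropout_rows[gene.sequence].append((s, e))
                prot_subs_rows[gene.sequence].append((s - 10, e + 10))
    for ev, edit in planner.stubs:
        if edit is not None:
            pad = cfg.dropout_tile + 10
            prot_dropout_rows[ev.ref_sequence].append((edit.start - pad, edit.end + pad))
            prot_subs_rows[ev.ref_sequence].append((edit.start - pad, edit.end + pad))
    for name, s, e in planner.guards:
        prot_dropout_rows[name].append((s, e))
        prot_subs_rows[name].append((s, e))

    def _mkset(rows, name):
        if not rows:
            return IntervalSet()
        arr = np.array(
            [
                (max(0, s), min(len(asm.sequences[name]), max(e, s + 1)))
                for s, e in rows
            ]
        )
        return IntervalSet({name: arr})

    prot_dropout = {n: _mkset(r, n) for n, r in prot_dropout_rows.items()}
    prot_subs = {n: _mkset(r, n) for n, r in prot_subs_rows.items()}

    # repeat collapses: delete a fraction of repeat copies and break there
    n_break = int(round(cfg.repeat_break_fraction * len(truth.softmask)))
    copies = list(truth.softmask)
    if n_break and copies:
        chosen = rng.choice(len(copies), size=min(n_break, len(copies)), replace=False)
        for i in sorted(int(x) for x in chosen):
            iv = copies[i]
            edits[iv.sequence].append(_Edit(iv.start, iv.end, "del"))
            edits[iv.sequence].append(_Edit(iv.start, iv.start, "break"))
            ledger.add(
                TruthEvent(
                    type="repeat_break", gene_id="", ref_sequence=iv.sequence,
                    ref_start=iv.start, ref_end=iv.end, payload={"mode": "collapse"},
                )
            )
            guard = IntervalSet({iv.sequence: np.array([[iv.start, iv.end]])})
            prot_dropout[iv.sequence] = prot_dropout[iv.sequence].union(guard)
            prot_subs[iv.sequence] = prot_subs[iv.sequence].union(guard)

    # GC-biased tile dropout on unprotected ground
    tile = cfg.dropout_tile
    tile_gc_by_seq = {}
    for name, seq in asm.sequences.items():
        view = asm.byte_view(name)
        n_tiles = len(view) // tile
        if n_tiles == 0:
            continue
        arr = view[: n_tiles * tile].reshape(n_tiles, tile)
        gc = ((arr == ord("G")) | (arr == ord("C"))).mean(axis=1)
        tile_gc_by_seq[name] = gc
        p = _logistic_dropout(gc, cfg.dropout_midpoint_gc, cfg.dropout_steepness)
        hit = rng.random(n_tiles) < p
        pmask = prot_dropout[name].mask(name, len(view))
        for ti in np.nonzero(hit)[0]:
            s, e = int(ti) * tile, (int(ti) + 1) * tile
            mode = "ngap" if rng.random() < cfg.n_gap_fraction else "delete"
            # trim the tile to its unprotected pieces so dropout can run
            # right up to (but never into) exons and engineered loci
            free = ~pmask[s:e]
            if not free.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate([[0], free.view(np.int8), [0]])))
            for ps, pe in zip(edges[::2], edges[1::2]):
                ps, pe = s + int(ps), s + int(pe)
                edits[name].append(_Edit(ps, pe, "ngap" if mode == "ngap" else "del"))
                ledger.add(
                    TruthEvent(
                        type="dropout_region", gene_id="", ref_sequence=name,
                        ref_start=ps, ref_end=pe, payload={"mode": mode, "gc": float(gc[ti])},
                    )
                )

    # heterozygous sites and stochastic base errors in neutral sequence
    edited = {
        name: IntervalSet.from_intervals(
            (name, ed.start, max(ed.end, ed.start + 1)) for ed in edits[name]
        )
        for name in asm.sequences
    }
    sub_sites: Dict[str, Dict[int, str]] = {name: {} for name in asm.sequences}

    def _sample_sites(n: int, weighted: bool) -> List[Tuple[str, int]]:
        names = sorted(asm.sequences)
        out: List[Tuple[str, int]] = []
        lengths = np.array([len(asm.sequences[n_]) for n_ in names], dtype=float)
        tries = 0
        while len(out) < n and tries < n * 60:
            tries += 1
            si = int(rng.choice(len(names), p=lengths / lengths.sum()))
            name = names[si]
            pos = int(rng.integers(0, len(asm.sequences[name])))
            if weighted:
                gc_arr = tile_gc_by_seq.get(name)
                if gc_arr is None:
                    continue
                ti = min(pos // tile, len(gc_arr) - 1)
                g0 = cfg.error_gc_midpoint if cfg.error_gc_midpoint is not None else cfg.dropout_midpoint_gc
                s_err = cfg.error_gc_steepness if cfg.error_gc_steepness is not None else cfg.dropout_steepness
                keep_p = _logistic_dropout(np.array([gc_arr[ti]]), g0, s_err)[0]
                if s_err > 0 and rng.random() > keep_p:
                    continue
            if prot_subs[name].contains_point(name, pos):
                continue
            if edited[name].overlap_length(GenomicInterval(name, max(0, pos - 5), pos + 6)):
                continue
            # keep substitution sites >= 6 bp apart so the 2-bp flank
            # exclusion of one site cannot swallow another
            if any(abs(pos - p) < 6 for p in sub_sites[name]):
                continue
            base = asm.sequences[name][pos].upper()
            if base == "N":
                continue
            alt = _BASES[int(rng.integers(0, 4))]
            while alt == base:
                alt = _BASES[int(rng.integers(0, 4))]
            out.append((name, pos))
            sub_sites[name][pos] = alt
        if len(out) < n:
            raise ValueError("could not place requested het/error sites")
        return out

    het_positions = _sample_sites(cfg.het_site_count, weighted=False)
    for name, pos in het_positions:
        ledger.add(
            TruthEvent(
                type="het_site", gene_id="", ref_sequence=name,
                ref_start=pos, ref_end=pos + 1,
                payload={"ref": asm.sequences[name][pos].upper(), "alt": sub_sites[name][pos]},
            )
        )
    err_positions = _sample_sites(cfg.n_base_errors, weighted=cfg.gc_biased_errors)
    for name, pos in err_positions:
        ledger.add(
            TruthEvent(
                type="base_error", gene_id="", ref_sequence=name,
                ref_start=pos, ref_end=pos + 1,
                payload={"ref": asm.sequences[name][pos].upper(), "alt": sub_sites[name][pos]},
            )
        )

    # engineered substitutions also enter sub_sites
    for ev, edit in planner.stubs:
        if edit is not None and edit.kind == "sub":
            sub_sites[ev.ref_sequence][edit.start] = edit.payload

    # ---- apply -------------------------------------------------------
    out_sequences: Dict[str, str] = {}
    chains: List[AlignmentChain] = []
    maps: Dict[str, "_CoordinateMap"] = {}
    for name in sorted(asm.sequences):
        mutated = _apply_subs(asm.sequences[name], sub_sites[name])
        scaffolds, segs = _apply_edits(name, mutated, edits[name])
        for sc_name, sc_seq in scaffolds:
            out_sequences[sc_name] = sc_seq
        maps[name] = _CoordinateMap(segs)
        chains.extend(_chains_from_segments(name, segs, asm, {k: len(v) for k, v in scaffolds}))
    degraded = Assembly(name="prior", sequences=out_sequences)

    # fill prior coordinates
    for ev, _ in planner.stubs:
        ledger.add(ev)
    for ev in ledger.events:
        sc, ps, pe = maps[ev.ref_sequence].map_interval(ev.ref_start, ev.ref_end)
        ev.prior_sequence, ev.prior_start, ev.prior_end = sc, ps, pe
    return degraded, ledger, chains


def _apply_subs(seq: str, subs: Dict[int, str]) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    for pos, base in subs.items():
        # preserve the softmask case of the original position
        b = base.lower() if chr(arr[pos]).islower() else base.upper()
        arr[pos] = ord(b)
    return arr


@dataclass
class _Segment:
    truth_start: int
    truth_end: int
    scaffold: str
    out_start: int
    kind: str  # match | ngap | inv | ins | del
    ins_length: int = 0


def _apply_edits(
    name: str, mutated: np.ndarray, edit_list: List[_Edit]
) -> Tuple[List[Tuple[str, str]], List[_Segment]]:
    ops = sorted(edit_list, key=lambda ed: (ed.start, 0 if ed.kind == "break" else 1, ed.end))
    # overlap check (points may touch interval boundaries)
    prev_end = -1
    for ed in ops:
        if ed.kind in ("del", "ngap", "inv") and ed.start < prev_end:
            raise ValueError(f"overlapping edits on {name} at {ed.start}")
        prev_end = max(prev_end, ed.end)
    n_breaks = sum(1 for ed in ops if ed.kind == "break")
    scaffolds: List[Tuple[str, str]] = []
    segs: List[_Segment] = []
    parts: List[np.ndarray] = []
    cur = 0
    out = 0
    sc_idx = 0

    def sc_name() -> str:
        return name if n_breaks == 0 else f"{name}_frag{sc_idx}"

    def flush_scaffold() -> None:
        nonlocal parts, out, sc_idx
        seq = np.concatenate(parts).tobytes().decode("ascii") if parts else ""
        scaffolds.append((sc_name(), seq))
        parts = []
        out = 0
        sc_idx += 1

    def emit_match(upto: int) -> None:
        nonlocal cur, out
        if upto > cur:
            parts.append(mutated[cur:upto])
            segs.append(_Segment(cur, upto, sc_name(), out, "match"))
            out += upto - cur
            cur = upto

    for ed in ops:
        emit_match(ed.start)
        if ed.kind == "break":
            flush_scaffold()
        elif ed.kind == "del":
            segs.append(_Segment(ed.start, ed.end, sc_name(), out, "del"))
            cur = ed.end
        elif ed.kind == "ngap":
            parts.append(np.full(ed.end - ed.start, ord("N"), dtype=np.uint8))
            segs.append(_Segment(ed.start, ed.end, sc_name(), out, "ngap"))
            out += ed.end - ed.start
            cur = ed.end
        elif ed.kind == "inv":
            sub = mutated[ed.start : ed.end].tobytes().decode("ascii")
            parts.append(np.frombuffer(revcomp(sub).encode("ascii"), dtype=np.uint8))
            segs.append(_Segment(ed.start, ed.end, sc_name(), out, "inv"))
            out += ed.end - ed.start
            cur = ed.end
        elif ed.kind == "ins":
            ins = np.frombuffer(ed.payload.encode("ascii"), dtype=np.uint8)
            parts.append(ins)
            segs.append(_Segment(ed.start, ed.start, sc_name(), out, "ins", ins_length=len(ins)))
            out += len(ins)
        else:
            raise ValueError(f"unknown edit kind {ed.kind!r}")
    emit_match(len(mutated))
    flush_scaffold()
    return scaffolds, segs


class _CoordinateMap:
    def __init__(self, segs: List[_Segment]):
        self.segs = segs
        self._starts = np.array([s.truth_start for s in segs], dtype=np.int64)

    def map_point(self, pos: int) -> Tuple[str, int, str]:
        i = int(np.searchsorted(self._starts, pos, side="right")) - 1
        while i >= 0:
            seg = self.segs[i]
            if seg.truth_start <= pos < seg.truth_end:
                off = pos - seg.truth_start
                if seg.kind in ("match", "ngap"):
                    return seg.scaffold, seg.out_start + off, seg.kind
                if seg.kind == "inv":
                    return seg.scaffold, seg.out_start + (seg.truth_end - 1 - pos), seg.kind
                return seg.scaffold, seg.out_start, "del"  # collapse to boundary
            if seg.truth_end <= pos:
                break
            i -= 1
        if self.segs:
            last = self.segs[-1]
            return last.scaffold, last.out_start + (last.truth_end - last.truth_start), "end"
        return "", 0, "end"

    def map_interval(self, start: int, end: int) -> Tuple[str, int, int]:
        if end <= start:
            sc, p, _ = self.map_point(start)
            return sc, p, p
        sc1, p1, k1 = self.map_point(start)
        sc2, p2, k2 = self.map_point(end - 1)
        if sc1 != sc2:
            return sc1, p1, p1
        if k1 == "del" and k2 == "del" and p1 == p2:
            return sc1, p1, p1  # the whole span was deleted
        lo, hi = min(p1, p2), max(p1, p2) + 1
        return sc1, lo, hi


def _chains_from_segments(
    name: str, segs: List[_Segment], asm: Assembly, scaffold_lengths: Dict[str, int]
) -> List[AlignmentChain]:
    qlen = len(asm.sequences[name])
    plus_blocks: Dict[str, List[Tuple[int, int, int, int]]] = {}
    chains: List[AlignmentChain] = []
    for seg in segs:
        if seg.kind == "match" and seg.truth_end > seg.truth_start:
            plus_blocks.setdefault(seg.scaffold, []).append(
                (seg.truth_start, seg.truth_end, seg.out_start,
                 seg.out_start + seg.truth_end - seg.truth_start)
            )
        elif seg.kind == "inv" and seg.truth_end > seg.truth_start:
            chains.append(
                AlignmentChain(
                    query=name, target=seg.scaffold, strand="-",
                    blocks=[(seg.truth_start, seg.truth_end, seg.out_start,
                             seg.out_start + seg.truth_end - seg.truth_start)],
                    query_length=qlen, target_length=scaffold_lengths[seg.scaffold],
                )
            )
    for scaffold, blocks in plus_blocks.items():
        chains.append(
            AlignmentChain(
                query=name, target=scaffold, strand="+", blocks=sorted(blocks),
                query_length=qlen, target_length=scaffold_lengths[scaffold],
            )
        )
    return chains


# ======================================================================
# reads
# ======================================================================
def simulate_pileup(
    asm: Assembly,
    depth: float,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
    het_sites: Optional[Dict[str, Sequence[int]]] = None,
    mismatch_sites: Optional[Dict[str, Sequence[int]]] = None,
    indel_sites: Optional[Dict[str, Sequence[Tuple[int, str]]]] = None,
    indel_flank: int = 2,
) -> Pileup:
    """Per-position read-support summary from a Poisson read-start process.

    ``het_sites`` get ~50% alternate support (the other haplotype);
    ``mismatch_sites`` are positions where the assembly base disagrees
    with the sequenced individual, so nearly every read mismatches;
    ``indel_sites`` are (position, 'ins'|'del') loci whose reads carry
    the indel over a +/-``indel_flank`` window.  Reads do not map onto
    N runs.  Deterministic for equal generator state.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    for length in asm.lengths.values():
        if read_length > length:
            raise ValueError("read length exceeds a sequence length")
    pu = Pileup(asm.lengths)
    lam = depth / read_length
    for name in sorted(asm.sequences):
        n = asm.lengths[name]
        starts = rng.poisson(lam, n)
        c = np.concatenate([[0], np.cumsum(starts)])
        lo = np.maximum(0, np.arange(n) - read_length + 1)
        d = (c[np.arange(n) + 1] - c[lo]).astype(np.int32)
        view = asm.byte_view(name)
        d[view == ord("N")] = 0
        mm = rng.binomial(d, error_rate).astype(np.int32)
        if het_sites and name in het_sites:
            idx = np.asarray(list(het_sites[name]), dtype=int)
            if len(idx):
                mm[idx] = rng.binomial(d[idx], 0.5)
        if mismatch_sites and name in mismatch_sites:
            idx = np.asarray(list(mismatch_sites[name]), dtype=int)
            if len(idx):
                mm[idx] = rng.binomial(d[idx], 1.0 - error_rate)
        ins = np.zeros(n, dtype=np.int32)
        dele = np.zeros(n, dtype=np.int32)
        if indel_sites and name in indel_sites:
            for pos, kind in indel_sites[name]:
                s, e = max(0, pos - indel_flank), min(n, pos + indel_flank + 1)
                vals = rng.binomial(d[s:e], 1.0 - error_rate).astype(np.int32)
                if kind == "ins":
                    ins[s:e] = np.maximum(ins[s:e], vals)
                else:
                    dele[s:e] = np.maximum(dele[s:e], vals)
        pu.depth[name] = d
        pu.mismatch[name] = mm
        pu.ins[name] = ins
        pu.dele[name] = dele
        pu.ref[name] = np.maximum(d - mm - ins - dele, 0).astype(np.int32)
    return pu


def _prior_read_depth_on_ref(
    truth: TruthGenome,
    ledger: TruthLedger,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Depth of the prior individual's reads mapped onto the reference:
    nominal coverage outside missing regions, sparse
    (``prior_read_coverage``x) inside them — the signature of regions
    that failed to assemble rather than true deletions."""
    missing = ledger.missing_truth_regions()
    out = {}
    for name, length in truth.assembly.lengths.items():
        d = np.full(length, max(1, int(round(cfg.read_depth / 3))), dtype=np.int16)
        for s, e in missing.array(name):
            span = int(e - s)
            lam = cfg.prior_read_coverage / cfg.read_length
            starts = rng.poisson(lam, span + cfg.read_length)
            cover = np.convolve(starts, np.ones(cfg.read_length, dtype=int))[
                cfg.read_length - 1 : cfg.read_length - 1 + span
            ]
            d[s:e] = np.minimum(cover, 4).astype(np.int16)
        out[name] = d
    return out


# ======================================================================
# orchestration
# ======================================================================
def simulate_bundle(cfg: SimulationConfig) -> SimulationBundle:
    """Full generation: truth genome, degraded copy, chains, ledger,
    and both pileups, from one master seed (independent RNG streams per
    sub-generator)."""
    streams = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_genome = np.random.default_rng(streams[0])
    rng_events = np.random.default_rng(streams[1])
    rng_reads = np.random.default_rng(streams[2])

    truth = generate_truth(cfg, rng_genome)
    degraded, ledger, chains = degrade(truth, cfg, rng_events)

    het_ref: Dict[str, List[int]] = {}
    het_prior: Dict[str, List[int]] = {}
    mism_prior: Dict[str, List[int]] = {}
    indel_prior: Dict[str, List[Tuple[int, str]]] = {}
    for ev in ledger.events:
        if ev.type == "het_site":
            het_ref.setdefault(ev.ref_sequence, []).append(ev.ref_start)
            if ev.prior_sequence:
                het_prior.setdefault(ev.prior_sequence, []).append(ev.prior_start)
        elif ev.type in ("base_error", "premature_stop", "splice_disruption"):
            if ev.prior_sequence:
                for p in range(ev.prior_start, max(ev.prior_start + 1, ev.prior_end)):
                    mism_prior.setdefault(ev.prior_sequence, []).append(p)
        elif ev.type == "frameshift" and ev.prior_sequence:
            kind = "ins" if ev.payload.get("kind") == "deletion" else "del"
            # reads carry the truth: a deletion in the prior assembly makes
            # reads look inserted relative to it, and vice versa; reads
            # spanning the indel support it along its whole extent
            length = int(ev.payload.get("length", 1))
            sites = indel_prior.setdefault(ev.prior_sequence, [])
            for off in range(-length, length + 1):
                sites.append((ev.prior_start + off, kind))

    reference_pileup = simulate_pileup(
        truth.assembly, cfg.read_depth, cfg.read_length, cfg.read_error_rate,
        rng_reads, het_sites=het_ref,
    )
    prior_pileup = simulate_pileup(
        degraded, cfg.read_depth, cfg.read_length, cfg.read_error_rate,
        rng_reads, het_sites=het_prior, mismatch_sites=mism_prior,
        indel_sites=indel_prior,
    )
    prior_read_depth = _prior_read_depth_on_ref(truth, ledger, cfg, rng_reads)
    return SimulationBundle(
        config=cfg,
        truth=truth,
        degraded=degraded,
        ledger=ledger,
        chains=chains,
        reference_pileup=reference_pileup,
        prior_pileup=prior_pileup,
        prior_read_depth_on_ref=prior_read_depth,
    )


def write_bundle(bundle: SimulationBundle, outdir: str | Path, pileups: bool = True) -> None:
    """Write the bundle as plain-text files under one directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.truth.assembly.write_fasta(out / "truth.fa")
    bundle.degraded.write_fasta(out / "degraded.fa")
    write_gff3(bundle.truth.genes, out / "genes.gff3")
    bundle.truth.softmask.write_bed(out / "softmask.bed")
    bundle.truth.cgi_truth.write_bed(out / "cgi_truth.bed")
    write_paf(bundle.chains, out / "chains_cigar.paf", cigar=True)
    write_paf(bundle.chains, out / "chains_blocks.paf", cigar=False)
    bundle.ledger.write_tsv(out / "ledger.tsv")
    if pileups:
        bundle.reference_pileup.write_tsv(out / "reference_pileup.tsv")
        bundle.prior_pileup.write_tsv(out / "prior_pileup.tsv")
    (out / "config.json").write_text(bundle.config.to_json() + "\n")
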