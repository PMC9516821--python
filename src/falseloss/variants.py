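"""False SNP / short-indel candidates and their pileup-based filtering.

Candidates are variants carried by the prior assembly but not the
alternate haplotype, shorter than 10 bp, and mapping to a single prior
locus.  Sites where the reference-side read pileup shows more than 10
reads with more than 20% alternate support (real heterozygosity or
reference base errors) are excluded together with 2 bp of flank; both
thresholds are strict, as printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assembly import Assembly, revcomp
from .chain import AlignmentChain
from .genes import GeneSet
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "VariantCall",
    "Pileup",
    "prior_specific_variants",
    "split_multi_nucleotide",
    "left_align",
    "pileup_exclusion_sites",
    "annotate_homopolymer",
    "variants_from_chains",
    "filter_false_variants",
    "variant_block_frequency",
]

MAX_INDEL = 10  # kept indels are strictly under this length
EXCLUSION_MIN_READS = 10  # strictly more than this many reads ...
EXCLUSION_ALT_FRACTION = 0.20  # ... with strictly more than this alt fraction
EXCLUSION_FLANK = 2
HOMOPOLYMER_MIN_RUN = 5


@dataclass(frozen=True)
class VariantCall:
    """A variant expressed against the reference assembly."""

    sequence: str
    position: int  # 0-based; for indels, the anchor base position
    ref: str
    alt: str
    carriers: frozenset = frozenset({"prior"})
    mapping_multiplicity: int = 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.sequence, self.position, self.position + len(self.ref))


class Pileup:
    """Per-base read-support summary over an assembly.

    Arrays per sequence: total depth, reads supporting the assembly
    base, and reads supporting a mismatch, insertion or deletion at the
    position.
    """

    COLUMNS = ("depth", "ref", "mismatch", "ins", "del")

    def __init__(self, lengths: Mapping[str, int]):
        self.lengths = dict(lengths)
        self.depth = {k: np.zeros(v, dtype=np.int32) for k, v in lengths.items()}
        self.ref = {k: np.zeros(v, dtype=np.int32) for k, v in lengths.items()}
        self.mismatch = {k: np.zeros(v, dtype=np.int32) for k, v in lengths.items()}
        self.ins = {k: np.zeros(v, dtype=np.int32) for k, v in lengths.items()}
        self.dele = {k: np.zeros(v, dtype=np.int32) for k, v in lengths.items()}

    def alt_fraction(self, sequence: str) -> np.ndarray:
        d = self.depth[sequence].astype(float)
        alt = self.mismatch[sequence] + self.ins[sequence] + self.dele[sequence]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(d > 0, alt / d, 0.0)

    def column(self, sequence: str, pos: int) -> Dict[str, int]:
        return {
            "depth": int(self.depth[sequence][pos]),
            "ref": int(self.ref[sequence][pos]),
            "mismatch": int(self.mismatch[sequence][pos]),
            "ins": int(self.ins[sequence][pos]),
            "del": int(self.dele[sequence][pos]),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in sorted(self.lengths):
            rows.append(
                pd.DataFrame(
                    {
                        "sequence": name,
                        "pos": np.arange(self.lengths[name]),
                        "depth": self.depth[name],
                        "ref": self.ref[name],
                        "mismatch": self.mismatch[name],
                        "ins": self.ins[name],
                        "del": self.dele[name],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["sequence", "pos", *self.COLUMNS]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pileup":
        df = pd.read_csv(path, sep="\t")
        lengths = {name: int(sub["pos"].max()) + 1 for name, sub in df.groupby("sequence")}
        pu = cls(lengths)
        for name, sub in df.groupby("sequence"):
            idx = sub["pos"].to_numpy()
            pu.depth[name][idx] = sub["depth"].to_numpy()
            pu.ref[name][idx] = sub["ref"].to_numpy()
            pu.mismatch[name][idx] = sub["mismatch"].to_numpy()
            pu.ins[name][idx] = sub["ins"].to_numpy()
            pu.dele[name][idx] = sub["del"].to_numpy()
        return pu


# ----------------------------------------------------------------------
# candidate selection
# ----------------------------------------------------------------------
def prior_specific_variants(
    variants: Iterable[VariantCall],
    prior: str = "prior",
    alternate: str = "alternate",
) -> List[VariantCall]:
    """Keep variants carried by the prior assembly and not by the
    alternate haplotype, with indel length strictly under 10 bp and a
    unique prior mapping."""
    out = []
    for v in variants:
        if not v.carriers:
            raise ValueError(f"variant at {v.sequence}:{v.position} lacks carrier information")
        if prior not in v.carriers or alternate in v.carriers:
            continue
        if not v.is_snp and v.indel_length >= MAX_INDEL:
            continue
        if v.mapping_multiplicity > 1:
            continue
        out.append(v)
    return out


def split_multi_nucleotide(v: VariantCall) -> List[VariantCall]:
    """One SNV per differing position of a length-preserving
    multi-nucleotide variant."""
    if len(v.ref) != len(v.alt):
        raise ValueError("length-changing variant: route to the indel path")
    return [
        replace(v, position=v.position + i, ref=r, alt=a)
        for i, (r, a) in enumerate(zip(v.ref, v.alt))
        if r != a
    ]


def left_align(v: VariantCall, seq: str) -> VariantCall:
    """Shift an anchored indel to its leftmost equivalent representation."""
    if v.is_snp or (len(v.ref) > 1 and len(v.alt) > 1):
        return v
    ref, alt, pos = v.ref.upper(), v.alt.upper(), v.position
    while pos > 0 and ref[-1] == alt[-1]:
        prev = seq[pos - 1].upper()
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return replace(v, position=pos, ref=ref, alt=alt)


def pileup_exclusion_sites(pileup: Pileup) -> IntervalSet:
    """Loci with more than 10 reads and more than 20% of reads
    supporting insertion, deletion or mismatch, each expanded by 2 bp."""
    rows = []
    for name in pileup.lengths:
        depth = pileup.depth[name]
        alt = pileup.mismatch[name] + pileup.ins[name] + pileup.dele[name]
        flag = (depth > EXCLUSION_MIN_READS) & (alt > EXCLUSION_ALT_FRACTION * depth)
        pos = np.nonzero(flag)[0]
        for p in pos:
            rows.append(
                (name, max(0, p - EXCLUSION_FLANK), min(pileup.lengths[name], p + EXCLUSION_FLANK + 1))
            )
    return IntervalSet.from_intervals(rows)


def annotate_homopolymer(seq: str, position: int) -> bool:
    """True iff the position sits in a run of >= 5 identical bases."""
    if not (0 <= position < len(seq)):
        raise ValueError("position outside sequence")
    s = seq.upper()
    base = s[position]
    i = position
    while i > 0 and s[i - 1] == base:
        i -= 1
    j = position
    while j + 1 < len(s) and s[j + 1] == base:
        j += 1
    return j - i + 1 >= HOMOPOLYMER_MIN_RUN


# ----------------------------------------------------------------------
# discovery from chains
# ----------------------------------------------------------------------
_COMP_TBL = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TBL[a] = b


def variants_from_chains(
    ref: Assembly,
    prior: Assembly,
    chains: Sequence[AlignmentChain],
    carrier: str = "prior",
) -> List[VariantCall]:
    """Extract SNVs and short indels from alignment chains.

    Mismatches inside aligned blocks become SNVs; clean one-sided gaps
    between consecutive blocks of a chain become anchored, left-aligned
    indels.  Positions aligned by more than one chain get mapping
    multiplicity > 1.
    """
    cover: Dict[str, np.ndarray] = {
        name: np.zeros(length, dtype=np.int16) for name, length in ref.lengths.items()
    }
    for chain in chains:
        for qs, qe, _, _ in chain.blocks:
            cover[chain.query][qs:qe] += 1

    out: List[VariantCall] = []
    for chain in chains:
        qview = ref.byte_view(chain.query)
        tview = prior.byte_view(chain.target)
        prev = None
        for qs, qe, ts, te in chain.blocks:
            qseq = qview[qs:qe]
            if chain.strand == "+":
                tseq = tview[ts:te]
            else:
                tseq = _COMP_TBL[tview[ts:te]][::-1]
            diff = (qseq != tseq) & (qseq != ord("N")) & (tseq != ord("N"))
            for off in np.nonzero(diff)[0]:
                p = qs + int(off)
                out.append(
                    VariantCall(
                        sequence=chain.query,
                        position=p,
                        ref=chr(qseq[off]),
                        alt=chr(tseq[off]),
                        carriers=frozenset({carrier}),
                        mapping_multiplicity=int(cover[chain.query][p]),
                    )
                )
            if prev is not None:
                out.extend(
                    _gap_variant(chain, prev, (qs, qe, ts, te), qview, tview, cover, carrier)
                )
            prev = (qs, qe, ts, te)
    out.sort(key=lambda v: (v.sequence, v.position, v.ref, v.alt))
    return out


def _gap_variant(
    chain: AlignmentChain,
    prev: Tuple[int, int, int, int],
    cur: Tuple[int, int, int, int],
    qview: np.ndarray,
    tview: np.ndarray,
    cover: Mapping[str, np.ndarray],
    carrier: str,
) -> List[VariantCall]:
    pqs, pqe, pts, pte = prev
    qs, qe, ts, te = cur
    qgap = qs - pqe
    tgap = (ts - pte) if chain.strand == "+" else (pts - te)
    if qgap > 0 and tgap > 0:
        return []  # substitution-like double gap: not a clean indel
    if qgap == 0 and tgap == 0:
        return []
    if max(qgap, tgap) >= MAX_INDEL:
        return []  # large structural difference, not a short-indel candidate
    anchor = pqe - 1
    if anchor < 0:
        return []
    # decode only the neighbourhood needed for alleles and left-alignment
    ctx_start = max(0, anchor - 64)
    ctx = qview[ctx_start : anchor + 1 + max(qgap, 0)].tobytes().decode("ascii")
    a = anchor - ctx_start
    if qgap > 0:
        # bases present in the reference, absent in the prior: deletion
        ref_allele = ctx[a : a + 1 + qgap]
        alt_allele = ctx[a]
    else:
        # bases present in the prior, absent in the reference: insertion
        if chain.strand == "+":
            ins = tview[pte : pte + tgap]
        else:
            ins = _COMP_TBL[tview[pts - tgap : pts]][::-1]
        ref_allele = ctx[a]
        alt_allele = ctx[a] + ins.tobytes().decode("ascii")
    v = VariantCall(
        sequence=chain.query,
        position=a,
        ref=ref_allele,
        alt=alt_allele,
        carriers=frozenset({carrier}),
        mapping_multiplicity=int(cover[chain.query][anchor]),
    )
    v = left_align(v, ctx)
    return [replace(v, position=v.position + ctx_start)]


# ----------------------------------------------------------------------
# full filter and profiling
# ----------------------------------------------------------------------
def filter_false_variants(
    variants: Iterable[VariantCall],
    reference_pileup: Optional[Pileup] = None,
    reference: Optional[Assembly] = None,
    prior: str = "prior",
    alternate: str = "alternate",
) -> Tuple[List[VariantCall], Dict[str, bool]]:
    """Prior-specificity selection followed by pileup exclusion.

    Returns the retained variants and a homopolymer annotation keyed by
    ``sequence:position`` (computed when the reference is supplied).
    The two filters commute, so ordering is immaterial.
    """
    kept = prior_specific_variants(variants, prior=prior, alternate=alternate)
    if reference_pileup is not None:
        excl = pileup_exclusion_sites(reference_pileup)
        kept = [v for v in kept if excl.overlap_length(v.span) == 0]
    homopolymer: Dict[str, bool] = {}
    if reference is not None:
        for v in kept:
            homopolymer[f"{v.sequence}:{v.position}"] = annotate_homopolymer(
                reference.sequences[v.sequence], v.position
            )
    return kept, homopolymer


def variant_block_frequency(
    genes: GeneSet,
    variants: Sequence[VariantCall],
    asm: Assembly,
    block: int = 100,
    flank: int = 3000,
    min_coding_exons: int = 4,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of genes carrying at least one false variant per
    metagene flank block and per gene-body category, paired with GC."""
    from .content import _gc_of_view
    from .genewise import _body_segments, _flank_blocks

    var_set = IntervalSet.from_intervals(
        (v.sequence, v.position, v.position + max(1, len(v.ref))) for v in variants
    )
    lengths = asm.lengths
    block_acc: Dict[int, List[Tuple[bool, float]]] = {}
    body_acc: Dict[str, List[Tuple[bool, float]]] = {}
    for gene in genes.coding():
        t = gene.representative()
        if len(t.cds_5to3()) < min_coding_exons:
            continue
        seqlen = lengths[gene.sequence]
        for pos, s, e in _flank_blocks(t, block, flank):
            s2, e2 = max(s, 0), min(e, seqlen)
            if s2 >= e2:
                continue
            iv = GenomicInterval(gene.sequence, s2, e2)
            has = var_set.overlap_length(iv) > 0
            gc = _gc_of_view(asm.byte_view(gene.sequence)[s2:e2])
            block_acc.setdefault(pos, []).append((has, gc))
        for cat, segs in _body_segments(t).items():
            segs = [seg for seg in segs if seg[1] > seg[0]]
            if not segs:
                continue
            has = any(
                var_set.overlap_length(GenomicInterval(gene.sequence, s, e)) > 0
                for s, e in segs
            )
            view = np.concatenate([asm.byte_view(gene.sequence)[s:e] for s, e in segs])
            body_acc.setdefault(cat, []).append((has, _gc_of_view(view)))
    blocks = pd.DataFrame(
        [
            {
                "position": pos,
                "n_genes": len(recs),
                "variant_frequency": float(np.mean([r[0] for r in recs])),
                "gc_mean": float(np.nanmean([r[1] for r in recs])),
            }
            for pos, recs in sorted(block_acc.items())
        ]
    )
    body = pd.DataFrame(
        [
            {
                "category": cat,
                "n_genes": len(recs),
                "variant_frequency": float(np.mean([r[0] for r in recs])),
                "gc_mean": float(np.nanmean([r[1] for r in recs])),
            }
            for cat, recs in sorted(body_acc.items())
        ]
    )
    return blocks, body
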