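"""Per-gene and per-exon missingness, metagene profiles, and
read/gap support of missing sites.

A gene or exon counts as completely missing only when whole-genome
alignment finds nothing for it *and* no local-similarity ("blast-like")
hit rescues it; rescue requires unique query coverage (each exon base
counted once across hits) above 90%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assembly import Assembly
from .chain import AlignmentChain
from .content import _gc_of_view
from .genes import GeneModel, GeneSet, TranscriptModel
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "ExonHit",
    "GeneMissingness",
    "exon_unique_coverage",
    "filter_hits",
    "exon_hits_from_chains",
    "classify_feature_missingness",
    "genomic_category_missing",
    "category_intervals",
    "metagene_profile",
    "nearest_upstream_cgi",
    "missing_support",
    "cumulative_missing_distribution",
]

MIN_HIT_IDENTITY = 0.90
MIN_HIT_COVERAGE = 0.50
MIN_EXON_LENGTH = 15  # exons must be over this length to have eligible hits
QCOVUS_RESCUE = 90.0  # unique coverage must exceed this to rescue


@dataclass(frozen=True)
class ExonHit:
    """One local-similarity hit of an exon against the prior assembly,
    in exon-local coordinates."""

    gene_id: str
    exon_index: int  # 5'->3' order within the representative transcript
    start: int
    end: int
    identity: float = 1.0
    target_sequence: str = ""
    target_start: int = 0
    target_end: int = 0


def exon_unique_coverage(exon_length: int, hits: Iterable[Tuple[int, int]]) -> float:
    """Percent of exon bases covered by the union of hit intervals
    (each base counted once — the qcovus convention)."""
    if exon_length <= 0:
        raise ValueError("exon length must be positive")
    covered = np.zeros(exon_length, dtype=bool)
    for s, e in hits:
        if not (0 <= s <= e <= exon_length):
            raise ValueError(f"hit ({s},{e}) outside exon of length {exon_length}")
        covered[s:e] = True
    return 100.0 * covered.mean()


def filter_hits(hits: Iterable[ExonHit], exon_lengths: Mapping[Tuple[str, int], int]) -> List[ExonHit]:
    """Keep hits with identity >= 90%, per-hit exon coverage >= 50%, on
    exons longer than 15 bp."""
    out = []
    for h in hits:
        length = exon_lengths[(h.gene_id, h.exon_index)]
        if length <= MIN_EXON_LENGTH:
            continue
        if h.identity < MIN_HIT_IDENTITY:
            continue
        if (h.end - h.start) / length < MIN_HIT_COVERAGE:
            continue
        out.append(h)
    return out


def exon_hits_from_chains(
    genes: GeneSet, chains: Sequence[AlignmentChain]
) -> List[ExonHit]:
    """Exon-local covered spans derived from alignment chains, serving
    as the hit source when no external local aligner output is given."""
    by_query: Dict[str, List[AlignmentChain]] = {}
    for c in chains:
        by_query.setdefault(c.query, []).append(c)
    hits: List[ExonHit] = []
    for gene in genes:
        t = gene.representative()
        for idx, (es, ee) in enumerate(t.exons_5to3()):
            for chain in by_query.get(gene.sequence, ()):
                for qs, qe, ts, te in chain.blocks:
                    a, b = max(es, qs), min(ee, qe)
                    if a < b:
                        if chain.strand == "+":
                            tgt = (ts + (a - qs), ts + (b - qs))
                        else:
                            tgt = (te - (b - qs), te - (a - qs))
                        hits.append(
                            ExonHit(
                                gene_id=gene.id,
                                exon_index=idx,
                                start=a - es,
                                end=b - es,
                                identity=1.0,
                                target_sequence=chain.target,
                                target_start=tgt[0],
                                target_end=tgt[1],
                            )
                        )
    return hits


# ----------------------------------------------------------------------
# per-gene classification
# ----------------------------------------------------------------------
@dataclass
class GeneMissingness:
    gene_id: str
    status: str  # completely_missing | partially_missing | present
    missing_percent: float
    exon_status: List[str] = field(default_factory=list)  # per 5'->3' exon
    exon_qcovus: List[float] = field(default_factory=list)


def classify_feature_missingness(
    gene: GeneModel,
    missing: IntervalSet,
    hits: Iterable[ExonHit] = (),
    prefiltered: bool = False,
    exon_only_percent: bool = False,
) -> GeneMissingness:
    """Classify a gene's representative transcript against the missing set.

    An exon is completely missing iff it lies fully inside the missing
    regions and its unique hit coverage does not exceed 90%; the gene is
    completely missing iff every exon is.  The per-gene missing percent
    covers the full transcript span including introns by default
    (``exon_only_percent`` switches to exon bases only).
    """
    t = gene.representative()
    exons = t.exons_5to3()
    exon_lengths = {(gene.id, i): e - s for i, (s, e) in enumerate(exons)}
    hits = [h for h in hits if h.gene_id == gene.id]
    if not prefiltered:
        hits = filter_hits(hits, exon_lengths)
    statuses, qcovs = [], []
    for i, (es, ee) in enumerate(exons):
        if ee > gene.end or es < gene.start:
            raise ValueError(f"exon outside gene bounds for {gene.id}")
        iv = GenomicInterval(gene.sequence, es, ee)
        fully_missing = missing.overlap_length(iv) == len(iv)
        qc = exon_unique_coverage(
            ee - es, [(h.start, h.end) for h in hits if h.exon_index == i]
        )
        qcovs.append(qc)
        statuses.append(
            "completely_missing" if fully_missing and qc <= QCOVUS_RESCUE else "present"
        )
    if all(s == "completely_missing" for s in statuses):
        status = "completely_missing"
        percent = 100.0
    else:
        if exon_only_percent:
            covered = sum(
                missing.overlap_length(GenomicInterval(gene.sequence, s, e))
                for s, e in exons
            )
            percent = 100.0 * covered / sum(e - s for s, e in exons)
        else:
            span = GenomicInterval(gene.sequence, t.start, t.end)
            percent = 100.0 * missing.coverage_fraction(span)
        status = "partially_missing" if percent > 0 else "present"
    return GeneMissingness(
        gene_id=gene.id,
        status=status,
        missing_percent=percent,
        exon_status=statuses,
        exon_qcovus=qcovs,
    )


# ----------------------------------------------------------------------
# genomic categories
# ----------------------------------------------------------------------
def category_intervals(genes: GeneSet, lengths: Mapping[str, int]) -> Dict[str, IntervalSet]:
    """Partition-style category tracks from representative transcripts.

    Overlaps resolve with exon priority over intron; intergenic is the
    complement of all gene spans (coding and non-coding).
    """
    coding_exons, introns, noncoding = [], [], []
    for gene in genes:
        t = gene.representative()
        if gene.is_coding:
            coding_exons += [(gene.sequence, s, e) for s, e in t.exons]
            introns += [(gene.sequence, s, e) for s, e in t.introns()]
        else:
            noncoding += [(gene.sequence, s, e) for s, e in t.exons]
    exon_set = IntervalSet.from_intervals(coding_exons)
    noncoding_set = IntervalSet.from_intervals(noncoding)
    intron_set = IntervalSet.from_intervals(introns).subtract(exon_set).subtract(noncoding_set)
    intergenic = genes.spans().complement(lengths)
    return {
        "coding_exon": exon_set,
        "intron": intron_set,
        "noncoding_gene": noncoding_set,
        "intergenic": intergenic,
    }


def genomic_category_missing(
    genes: GeneSet, missing: IntervalSet, lengths: Mapping[str, int]
) -> Dict[str, float]:
    """Missing rate of merged coding-exon, intron, non-coding-gene and
    intergenic bases."""
    out = {}
    for name, part in category_intervals(genes, lengths).items():
        total = part.total_length
        out[name] = (part.intersect(missing).total_length / total) if total else math.nan
    return out


# ----------------------------------------------------------------------
# metagene profile
# ----------------------------------------------------------------------
def nearest_upstream_cgi(
    gene: GeneModel | TranscriptModel, cgis: IntervalSet
) -> Optional[int]:
    """Distance (bp) from the TSS to the nearest strictly upstream CpG
    island; 0 when a CGI overlaps the TSS; None when none lies upstream.
    Downstream islands are ignored, strand-aware."""
    t = gene.representative() if isinstance(gene, GeneModel) else gene
    tss = t.tss
    arr = cgis.array(t.sequence)
    best: Optional[int] = None
    for s, e in arr:
        if s <= tss < e:
            return 0
        if t.strand == "+" and e <= tss:
            d = int(tss - e)
            best = d if best is None else min(best, d)
        elif t.strand == "-" and s > tss:
            d = int(s - tss - 1)
            best = d if best is None else min(best, d)
    return best


def _flank_blocks(
    t: TranscriptModel, block: int, flank: int
) -> List[Tuple[int, int, int]]:
    """(position, genomic_start, genomic_end) for upstream and
    downstream flank blocks, strand-oriented.  Negative positions are
    upstream of the TSS (-1 adjacent), positive downstream of the TTS."""
    n = flank // block
    out = []
    for j in range(n):
        pos = -(n - j)  # -n .. -1
        if t.strand == "+":
            s = t.start - (n - j) * block
            out.append((pos, s, s + block))
        else:
            s = t.end + (n - j - 1) * block
            out.append((pos, s, s + block))
    for j in range(n):
        pos = j + 1  # 1 .. n
        if t.strand == "+":
            s = t.end + j * block
            out.append((pos, s, s + block))
        else:
            s = t.start - (j + 1) * block
            out.append((pos, s, s + block))
    return out


BODY_CATEGORIES = ("utr5", "first_cds", "internal_cds", "last_cds", "utr3")


def _body_segments(t: TranscriptModel) -> Dict[str, List[Tuple[int, int]]]:
    """Five-way gene-body partition for a coding transcript with >= 4
    coding exons; exons carrying both UTR and CDS are split at the
    boundary."""
    cds = t.cds_5to3()
    return {
        "utr5": t.utr5(),
        "first_cds": [cds[0]],
        "internal_cds": list(cds[1:-1]),
        "last_cds": [cds[-1]],
        "utr3": t.utr3(),
    }


def metagene_profile(
    genes: GeneSet,
    missing: IntervalSet,
    asm: Assembly,
    cgis: IntervalSet | None = None,
    block: int = 100,
    flank: int = 3000,
    missing_block_threshold: float = 0.90,
    min_coding_exons: int = 4,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Metagene missing-ratio/GC profile around TSS and TTS.

    Returns ``(blocks, body)``: per flank-block position the fraction of
    genes whose block is missing (>= 90% of block bases missing) and the
    block GC mean/SD, stratified by upstream-CGI presence; and per
    gene-body category the mean missing fraction and GC.  Blocks
    truncated by a sequence edge keep their surviving part and reduce
    the denominator when fully lost.
    """
    lengths = asm.lengths
    strata: Dict[Tuple[int, str], List[Tuple[bool, float]]] = {}
    body_acc: Dict[Tuple[str, str], List[Tuple[float, float]]] = {}
    eligible = [
        g
        for g in genes.coding()
        if len(g.representative().cds_5to3()) >= min_coding_exons
    ]
    for gene in eligible:
        t = gene.representative()
        if cgis is not None:
            d = nearest_upstream_cgi(t, cgis)
            stratum = "cgi+" if (d is not None and d <= flank) else "cgi-"
        else:
            stratum = "cgi-"
        seqlen = lengths[gene.sequence]
        for pos, s, e in _flank_blocks(t, block, flank):
            s2, e2 = max(s, 0), min(e, seqlen)
            if s2 >= e2:
                continue  # fully off the sequence: dropped from denominator
            iv = GenomicInterval(gene.sequence, s2, e2)
            frac = missing.coverage_fraction(iv)
            gc = _gc_of_view(asm.byte_view(gene.sequence)[s2:e2])
            rec = (frac >= missing_block_threshold, gc)
            strata.setdefault((pos, stratum), []).append(rec)
            strata.setdefault((pos, "all"), []).append(rec)
        for cat, segs in _body_segments(t).items():
            segs = [seg for seg in segs if seg[1] > seg[0]]
            if not segs:
                continue
            total = sum(e - s for s, e in segs)
            miss = sum(
                missing.overlap_length(GenomicInterval(gene.sequence, s, e))
                for s, e in segs
            )
            gcs = np.concatenate(
                [asm.byte_view(gene.sequence)[s:e] for s, e in segs]
            )
            for key in (stratum, "all"):
                body_acc.setdefault((cat, key), []).append((miss / total, _gc_of_view(gcs)))
    block_rows = []
    for (pos, stratum), recs in sorted(strata.items()):
        flags = np.array([r[0] for r in recs])
        gcs = np.array([r[1] for r in recs], dtype=float)
        gcs = gcs[~np.isnan(gcs)]
        block_rows.append(
            {
                "position": pos,
                "stratum": stratum,
                "n_genes": len(recs),
                "missing_fraction": float(flags.mean()),
                "gc_mean": float(gcs.mean()) if len(gcs) else math.nan,
                "gc_sd": float(gcs.std()) if len(gcs) else math.nan,
            }
        )
    body_rows = []
    for (cat, stratum), recs in sorted(body_acc.items()):
        fr = np.array([r[0] for r in recs], dtype=float)
        gcs = np.array([r[1] for r in recs], dtype=float)
        gcs = gcs[~np.isnan(gcs)]
        body_rows.append(
            {
                "category": cat,
                "stratum": stratum,
                "n_genes": len(recs),
                "missing_fraction_mean": float(fr.mean()),
                "gc_mean": float(gcs.mean()) if len(gcs) else math.nan,
            }
        )
    return pd.DataFrame(block_rows), pd.DataFrame(body_rows)


# ----------------------------------------------------------------------
# read / gap support of missing regions
# ----------------------------------------------------------------------
def missing_support(
    missing: IntervalSet,
    prior_depth: Mapping[str, np.ndarray],
    prior_gaps: IntervalSet,
    chains: Sequence[AlignmentChain],
) -> Dict[str, float]:
    """Fractions of missing reference bases supported by prior reads
    (depth >= 1), by prior assembly gaps, or neither.

    Gap support is determined by interpolation: a missing interval is
    gap-supported when the prior-side span bracketed by its nearest
    aligned neighbours overlaps an N run of the prior assembly.
    """
    by_query: Dict[str, List[AlignmentChain]] = {}
    for c in chains:
        by_query.setdefault(c.query, []).append(c)
    total = read_sup = gap_sup = 0
    for iv in missing:
        n = len(iv)
        total += n
        depth = prior_depth.get(iv.sequence)
        covered = (
            int(np.sum(depth[iv.start : iv.end] >= 1)) if depth is not None else 0
        )
        read_sup += covered
        rest = n - covered
        if rest and _interpolates_into_gap(iv, by_query.get(iv.sequence, ()), prior_gaps):
            gap_sup += rest
    if total == 0:
        return {"read_supported": math.nan, "gap_supported": math.nan, "unsupported": math.nan, "n_bases": 0}
    return {
        "read_supported": read_sup / total,
        "gap_supported": gap_sup / total,
        "unsupported": (total - read_sup - gap_sup) / total,
        "n_bases": total,
    }


def _interpolates_into_gap(
    iv: GenomicInterval, chains: Sequence[AlignmentChain], prior_gaps: IntervalSet
) -> bool:
    for chain in chains:
        left = right = None
        for qs, qe, ts, te in chain.blocks:
            if qe <= iv.start:
                left = (qs, qe, ts, te)
            if qs >= iv.end and right is None:
                right = (qs, qe, ts, te)
        if left is None or right is None:
            continue
        if chain.strand == "+":
            span = (left[3], right[2])
        else:
            span = (right[3], left[2])
        if span[1] <= span[0]:
            continue
        probe = IntervalSet({chain.target: np.array([list(span)])})
        if probe.intersect(prior_gaps):
            return True
    return False


def cumulative_missing_distribution(
    missing_percents: Mapping[str, float] | Sequence[float],
    readout_percent: float = 10.0,
) -> Tuple[pd.DataFrame, float]:
    """ECDF of per-gene missing percent and the fraction of genes with
    less than ``readout_percent`` missing."""
    if isinstance(missing_percents, Mapping):
        values = np.array(list(missing_percents.values()), dtype=float)
    else:
        values = np.array(list(missing_percents), dtype=float)
    values.sort()
    ecdf = pd.DataFrame(
        {
            "missing_percent": values,
            "ecdf": np.arange(1, len(values) + 1) / max(len(values), 1),
        }
    )
    frac = float(np.mean(values < readout_percent)) if len(values) else math.nan
    return ecdf, frac
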