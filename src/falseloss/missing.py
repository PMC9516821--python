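"""Missing-region calling between two assemblies.

A region of the reference assembly counts as *missing* in the other
("prior") assembly only when it is unaligned under two independent
alignments — the conservative intersection.  Regions that are merely
falsely duplicated are excluded after merging nearby duplication
intervals (25 kbp by default).

A small minimizer anchor aligner is included so the whole analysis can
run self-contained; externally supplied PAF alignments always win over
it when both are given.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.ndimage import minimum_filter1d

from .assembly import Assembly
from .chain import AlignmentChain
from .intervals import IntervalSet

__all__ = [
    "unaligned_regions",
    "conservative_missing",
    "exclude_false_duplications",
    "anchor_align",
]

log = logging.getLogger(__name__)


def unaligned_regions(
    lengths: Mapping[str, int],
    chains: Sequence[AlignmentChain],
    side: str = "query",
) -> IntervalSet:
    """Per-sequence complement of the union of aligned block intervals."""
    if side not in ("query", "target"):
        raise ValueError("side must be 'query' or 'target'")
    rows = []
    for chain in chains:
        name = chain.query if side == "query" else chain.target
        if name not in lengths:
            raise ValueError(f"chain references unknown sequence {name!r}")
        for qs, qe, ts, te in chain.blocks:
            s, e = (qs, qe) if side == "query" else (min(ts, te), max(ts, te))
            if e > lengths[name]:
                raise ValueError(f"alignment block beyond end of {name}")
            rows.append((name, s, e))
    return IntervalSet.from_intervals(rows).complement(lengths)


def conservative_missing(unaligned_a: IntervalSet, unaligned_b: IntervalSet) -> IntervalSet:
    """Per-base intersection of two aligners' unaligned regions."""
    return unaligned_a.intersect(unaligned_b)


def exclude_false_duplications(
    missing: IntervalSet, duplications: IntervalSet, merge_gap: int = 25_000
) -> IntervalSet:
    """Remove falsely duplicated regions, merged at ``merge_gap``, from
    the missing-region set."""
    return missing.subtract(duplications.merge(merge_gap))


# ----------------------------------------------------------------------
# toy anchor aligner
# ----------------------------------------------------------------------
_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i

MAX_K = 28  # 2-bit packing into int64 with headroom


def _kmer_codes(view: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement 2-bit k-mer codes at every offset.

    Positions whose window contains a non-ACGT base get code -1.
    """
    codes = _CODE[view].astype(np.int64)
    valid = codes != 255
    codes[~valid] = 0
    n = len(view) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        fwd = (fwd << 2) | codes[i : n + i]
        rev |= (3 - codes[i : n + i]) << (2 * i)
        ok &= valid[i : n + i]
    fwd[~ok] = -1
    rev[~ok] = -1
    return fwd, rev


def _minimizers(view: np.ndarray, k: int, w: int) -> Dict[int, List[Tuple[int, int]]]:
    """Canonical (k,w)-minimizers: {code: [(pos, strand)]} with strand
    +1 when the forward k-mer is canonical, -1 otherwise."""
    fwd, rev = _kmer_codes(view, k)
    if len(fwd) == 0:
        return {}
    canon = np.minimum(fwd, rev)
    strand = np.where(fwd <= rev, 1, -1)
    bad = fwd < 0
    big = np.int64(1) << 62
    canon = np.where(bad, big, canon)
    wm = minimum_filter1d(canon, size=w, mode="nearest")
    is_min = (canon == wm) & ~bad
    out: Dict[int, List[Tuple[int, int]]] = {}
    for pos in np.nonzero(is_min)[0]:
        out.setdefault(int(canon[pos]), []).append((int(pos), int(strand[pos])))
    return out


def anchor_align(
    a: Assembly,
    b: Assembly,
    k: int = 15,
    w: int = 10,
    max_gap: int = 1000,
    min_anchors: int = 3,
    max_occurrences: int = 8,
    mask_repeats: bool = True,
) -> List[AlignmentChain]:
    """Minimizer anchor alignment of assembly ``a`` (query) onto ``b``.

    Shared canonical minimizers below the occurrence cap become anchors;
    anchors on a common diagonal band are chained colinearly with at most
    ``max_gap`` between consecutive anchors, echoing a stringent
    assembly-to-assembly preset.  With ``mask_repeats`` (default) no
    seeds are drawn from softmasked (lowercase) sequence — repeats are
    still spanned when the flanking anchors share a diagonal, but cannot
    cross-seed between copies.  Intended for desk-scale, high-identity
    comparisons, not a general aligner.
    """
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")
    if min(min(map(len, a.sequences.values()), default=k), min(map(len, b.sequences.values()), default=k)) < k:
        raise ValueError("k exceeds the shortest sequence length")

    def view(asm: Assembly, name: str) -> np.ndarray:
        if mask_repeats:
            # lowercase bases fall outside the seed alphabet, so masked
            # windows produce no minimizers
            return np.frombuffer(asm.sequences[name].encode("ascii"), dtype=np.uint8)
        return asm.byte_view(name)

    mins_b: Dict[str, Dict[int, List[Tuple[int, int]]]] = {
        name: _minimizers(view(b, name), k, w) for name in b.sequences
    }
    occ_b = Counter()
    for table in mins_b.values():
        for code, hits in table.items():
            occ_b[code] += len(hits)

    chains: List[AlignmentChain] = []
    for qname in sorted(a.sequences):
        mins_a = _minimizers(view(a, qname), k, w)
        anchors: Dict[Tuple[str, int], List[Tuple[int, int]]] = {}
        for code, qhits in mins_a.items():
            if len(qhits) > max_occurrences or occ_b.get(code, 0) > max_occurrences:
                continue
            for tname, table in mins_b.items():
                for tpos, tstrand in table.get(code, ()):
                    for qpos, qstrand in qhits:
                        rel = 1 if qstrand == tstrand else -1
                        anchors.setdefault((tname, rel), []).append((qpos, tpos))
        qview = a.byte_view(qname)  # N-splitting is case-insensitive
        for (tname, rel), pairs in sorted(anchors.items()):
            tview = b.byte_view(tname)
            for chain in _chain_anchors(
                pairs, k, max_gap, min_anchors, qname, tname, rel,
                len(a.sequences[qname]), len(b.sequences[tname]),
            ):
                refined = _split_blocks_on_n(chain.blocks, qview, tview, chain.strand)
                if refined:
                    chains.append(
                        AlignmentChain(
                            query=chain.query, target=chain.target,
                            strand=chain.strand, blocks=refined,
                            query_length=chain.query_length,
                            target_length=chain.target_length,
                        )
                    )
    chains.sort(key=lambda c: (c.query, c.query_span, c.target, c.strand))
    return chains


def _split_blocks_on_n(blocks, qview: np.ndarray, tview: np.ndarray, strand: str):
    """Remove N-covered columns from blocks: anchors on a shared diagonal
    may bridge an assembly gap, but an aligner reports no alignment
    through N runs."""
    out = []
    for qs, qe, ts, te in blocks:
        qn = qview[qs:qe] == ord("N")
        tn = tview[ts:te] == ord("N")
        if strand == "-":
            tn = tn[::-1]
        bad = qn | tn
        if not bad.any():
            out.append((qs, qe, ts, te))
            continue
        good = ~bad
        edges = np.flatnonzero(np.diff(np.concatenate([[0], good.view(np.int8), [0]])))
        for a_, b_ in zip(edges[::2], edges[1::2]):
            a_, b_ = int(a_), int(b_)
            if strand == "+":
                out.append((qs + a_, qs + b_, ts + a_, ts + b_))
            else:
                out.append((qs + a_, qs + b_, te - b_, te - a_))
    return out


def _chain_anchors(
    pairs: List[Tuple[int, int]],
    k: int,
    max_gap: int,
    min_anchors: int,
    qname: str,
    tname: str,
    rel: int,
    qlen: int,
    tlen: int,
) -> List[AlignmentChain]:
    """Greedy colinear chaining of (qpos, tpos) anchors of one orientation."""
    pairs = sorted(pairs)
    chains: List[AlignmentChain] = []
    run: List[Tuple[int, int]] = []

    def flush() -> None:
        if len(run) >= min_anchors:
            blocks = _anchors_to_blocks(run, k, rel)
            if blocks:
                chains.append(
                    AlignmentChain(
                        query=qname, target=tname,
                        strand="+" if rel == 1 else "-",
                        blocks=blocks, query_length=qlen, target_length=tlen,
                    )
                )
        run.clear()

    for qpos, tpos in pairs:
        if run:
            pq, pt = run[-1]
            qd = qpos - pq
            td = (tpos - pt) * rel
            colinear = 0 < qd <= max_gap and 0 < td <= max_gap
            if not colinear:
                if qd == 0 or td <= 0 or td > max_gap or qd > max_gap:
                    flush()
        run.append((qpos, tpos))
    flush()
    return chains


def _anchors_to_blocks(run: List[Tuple[int, int]], k: int, rel: int) -> List:
    """Merge same-diagonal consecutive anchors into maximal gapless blocks."""
    blocks = []
    cur_q0, cur_t0 = run[0]
    cur_q1 = cur_q0
    for qpos, tpos in run[1:]:
        same_diag = (tpos - cur_t0) * rel == qpos - cur_q0
        if same_diag and qpos > cur_q1:
            cur_q1 = qpos
        else:
            blocks.append(_emit_block(cur_q0, cur_q1, cur_t0, k, rel))
            cur_q0, cur_t0, cur_q1 = qpos, tpos, qpos
    blocks.append(_emit_block(cur_q0, cur_q1, cur_t0, k, rel))
    # trim overlaps introduced by off-diagonal anchor spacing
    trimmed = []
    for blk in blocks:
        if trimmed:
            prev = trimmed[-1]
            if blk[0] < prev[1]:
                cut = prev[1] - blk[0]
                if blk[1] - blk[0] <= cut:
                    continue
                if rel == 1:
                    blk = (blk[0] + cut, blk[1], blk[2] + cut, blk[3])
                else:
                    blk = (blk[0] + cut, blk[1], blk[2], blk[3] - cut)
            if rel == 1 and blk[2] < prev[3]:
                cut = prev[3] - blk[2]
                if blk[1] - blk[0] <= cut:
                    continue
                blk = (blk[0] + cut, blk[1], blk[2] + cut, blk[3])
            if rel == -1 and blk[3] > prev[2]:
                # target overlap on a descending chain: the high end of
                # the target pairs with the low end of the query
                cut = blk[3] - prev[2]
                if blk[1] - blk[0] <= cut:
                    continue
                blk = (blk[0] + cut, blk[1], blk[2], blk[3] - cut)
        trimmed.append(blk)
    return trimmed


def _emit_block(q0: int, q1: int, t0: int, k: int, rel: int):
    length = q1 - q0 + k
    if rel == 1:
        return (q0, q0 + length, t0, t0 + length)
    # minus strand: anchor at query q0 pairs with target k-mer whose
    # forward-strand interval is [t0, t0+k); later query anchors pair
    # with lower target coordinates.
    t_hi = t0 + k
    return (q0, q0 + length, t_hi - length, t_hi)
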