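"""Colinear alignment chains, PAF input/output, and coordinate lifting.

A chain maps intervals of a query assembly onto a target assembly
through ordered, equal-length, non-overlapping blocks.  On the minus
strand, blocks ascend in query coordinates while descending in target
coordinates (both expressed on the forward strand, as in PAF).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .assembly import Assembly
from .intervals import IntervalSet

__all__ = ["AlignmentChain", "lift", "lift_interval", "identity_chains", "read_paf", "write_paf"]

log = logging.getLogger(__name__)

Block = Tuple[int, int, int, int]  # qstart, qend, tstart, tend (half-open)


@dataclass
class AlignmentChain:
    query: str
    target: str
    strand: str
    blocks: List[Block]
    query_length: int = 0
    target_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        self.blocks = [tuple(int(x) for x in b) for b in self.blocks]
        prev = None
        for qs, qe, ts, te in self.blocks:
            if qe - qs != te - ts or qs >= qe:
                raise ValueError(f"malformed block {(qs, qe, ts, te)}")
            if prev is not None:
                pqs, pqe, pts, pte = prev
                if qs < pqe:
                    raise ValueError("blocks overlap on query")
                if self.strand == "+" and ts < pte:
                    raise ValueError("blocks overlap on target")
                if self.strand == "-" and te > pts:
                    raise ValueError("minus-strand blocks must descend on target")
            prev = (qs, qe, ts, te)

    @property
    def query_span(self) -> Tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def target_span(self) -> Tuple[int, int]:
        ts = min(b[2] for b in self.blocks)
        te = max(b[3] for b in self.blocks)
        return ts, te

    @property
    def aligned_length(self) -> int:
        return sum(qe - qs for qs, qe, _, _ in self.blocks)

    def swapped(self) -> "AlignmentChain":
        """The same chain viewed from the target side."""
        blocks = [(ts, te, qs, qe) for qs, qe, ts, te in self.blocks]
        blocks.sort()
        return AlignmentChain(
            query=self.target,
            target=self.query,
            strand=self.strand,
            blocks=blocks,
            query_length=self.target_length,
            target_length=self.query_length,
        )


# ----------------------------------------------------------------------
# lifting
# ----------------------------------------------------------------------
def _map_block(qs: int, qe: int, ts: int, te: int, strand: str, a: int, b: int) -> Tuple[int, int]:
    """Map sub-interval [a,b) of the query side of a block to the target side."""
    if strand == "+":
        return ts + (a - qs), ts + (b - qs)
    return te - (b - qs), te - (a - qs)


def lift_interval(
    sequence: str, start: int, end: int, chains: Sequence[AlignmentChain],
    direction: str = "query_to_target",
) -> List[Tuple[str, int, int, str]]:
    """Image of one interval through aligned blocks only.

    Returns ``(dest_sequence, start, end, strand)`` pieces; sub-spans in
    alignment gaps drop out.  ``direction`` is ``query_to_target`` or
    ``target_to_query``.
    """
    if direction not in ("query_to_target", "target_to_query"):
        raise ValueError(f"unknown direction {direction!r}")
    pieces = []
    for chain in chains:
        if direction == "target_to_query":
            chain = chain.swapped()
        if chain.query != sequence:
            continue
        for qs, qe, ts, te in chain.blocks:
            a, b = max(start, qs), min(end, qe)
            if a < b:
                x, y = _map_block(qs, qe, ts, te, chain.strand, a, b)
                pieces.append((chain.target, x, y, chain.strand))
    return pieces


def lift(
    intervals: IntervalSet, chains: Sequence[AlignmentChain],
    direction: str = "query_to_target",
) -> IntervalSet:
    """Lift an interval set through chains; output on the destination assembly."""
    source_names = {c.query if direction == "query_to_target" else c.target for c in chains}
    out = []
    for iv in intervals:
        if iv.sequence not in source_names:
            log.debug("lift: sequence %s absent from chains; empty image", iv.sequence)
            continue
        for name, s, e, _ in lift_interval(iv.sequence, iv.start, iv.end, chains, direction):
            out.append((name, s, e))
    return IntervalSet.from_intervals(out)


def identity_chains(asm: Assembly) -> List[AlignmentChain]:
    """Self-alignment of an assembly: one full-length chain per sequence."""
    return [
        AlignmentChain(
            query=name, target=name, strand="+",
            blocks=[(0, len(seq), 0, len(seq))],
            query_length=len(seq), target_length=len(seq),
        )
        for name, seq in asm.sequences.items()
    ]


# ----------------------------------------------------------------------
# PAF
# ----------------------------------------------------------------------
_CIGAR_RE = re.compile(r"(\d+)([MIDNSH=X])")


def read_paf(path: str | Path) -> List[AlignmentChain]:
    """Parse PAF into chains.

    With a ``cg:Z`` CIGAR, M/=/X runs become blocks (I consumes query,
    D/N consume target).  Without a CIGAR, a line whose query and target
    spans have equal length is treated as one gapless block; other
    CIGAR-free lines are skipped with a warning, since their internal
    structure is unknown.
    """
    chains: List[AlignmentChain] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            qname, qlen, qstart, qend = f[0], int(f[1]), int(f[2]), int(f[3])
            strand = f[4]
            tname, tlen, tstart, tend = f[5], int(f[6]), int(f[7]), int(f[8])
            cg = None
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
                    break
            if cg is None:
                if qend - qstart == tend - tstart:
                    blocks = [(qstart, qend, tstart, tend)]
                else:
                    log.warning("skipping CIGAR-free gapped PAF line %s -> %s", qname, tname)
                    continue
            else:
                blocks = _blocks_from_cigar(cg, qstart, qend, tstart, tend, strand)
            chains.append(
                AlignmentChain(
                    query=qname, target=tname, strand=strand, blocks=blocks,
                    query_length=qlen, target_length=tlen,
                )
            )
    return chains


def _blocks_from_cigar(
    cg: str, qstart: int, qend: int, tstart: int, tend: int, strand: str
) -> List[Block]:
    # On '+', the CIGAR walks the forward query against the forward
    # target.  On '-', it walks the reverse-complemented query against
    # the forward target (the minimap2 convention), so reading the op
    # list backwards walks the forward query while the target descends.
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cg)]
    if strand == "-":
        ops = ops[::-1]
    blocks: List[Block] = []
    q = qstart
    t = tend if strand == "-" else tstart
    for n, op in ops:
        if op in "M=X":
            if strand == "+":
                blocks.append((q, q + n, t, t + n))
                t += n
            else:
                blocks.append((q, q + n, t - n, t))
                t -= n
            q += n
        elif op == "I":
            q += n
        elif op in "DN":
            t = t + n if strand == "+" else t - n
    if q != qend:
        raise ValueError("CIGAR does not span the stated query range")
    return blocks


def write_paf(
    chains: Sequence[AlignmentChain], path: str | Path, cigar: bool = True
) -> None:
    """Write chains as PAF.

    ``cigar=True`` emits one line per chain with a ``cg:Z`` tag;
    ``cigar=False`` emits one gapless line per block (a block-resolved,
    CIGAR-free dialect).  Output order is deterministic.
    """
    lines = []
    ordered = sorted(chains, key=lambda c: (c.query, c.query_span, c.target))
    for chain in ordered:
        if cigar:
            lines.append(_paf_line_with_cigar(chain))
        else:
            for qs, qe, ts, te in chain.blocks:
                nmatch = qe - qs
                lines.append(
                    "\t".join(
                        map(str, [
                            chain.query, chain.query_length, qs, qe, chain.strand,
                            chain.target, chain.target_length, ts, te,
                            nmatch, nmatch, 60,
                        ])
                    )
                )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _paf_line_with_cigar(chain: AlignmentChain) -> str:
    qstart, qend = chain.query_span
    tstart, tend = chain.target_span
    ops = []
    prev = None
    for qs, qe, ts, te in chain.blocks:
        if prev is not None:
            pqs, pqe, pts, pte = prev
            qgap = qs - pqe
            tgap = ts - pte if chain.strand == "+" else pts - te
            if qgap:
                ops.append(f"{qgap}I")
            if tgap:
                ops.append(f"{tgap}D")
        ops.append(f"{qe - qs}M")
        prev = (qs, qe, ts, te)
    if chain.strand == "-":
        ops = ops[::-1]
    nmatch = chain.aligned_length
    alen = max(qend - qstart, tend - tstart)
    return "\t".join(
        map(str, [
            chain.query, chain.query_length, qstart, qend, chain.strand,
            chain.target, chain.target_length, tstart, tend,
            nmatch, alen, 60, "cg:Z:" + "".join(ops),
        ])
    )
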