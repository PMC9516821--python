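"""GC content, repeat content, CpG islands, and windowed summaries.

GC content follows the convention of counting G+C over non-N bases
only; an all-N interval has undefined GC and is excluded from averages.
CpG islands use the classic criteria (length >= 200 bp, GC > 50%,
observed/expected CpG > 0.6) evaluated over 100-bp windows shifted by
1 bp, as popularised by EMBOSS newcpgreport; both inequalities are
strict.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .assembly import Assembly
from .genes import GeneSet
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "gc_content",
    "gc_fraction_of_string",
    "repeat_content",
    "detect_cpg_islands",
    "detect_cpg_islands_assembly",
    "window_summary",
    "partition_missing_rates",
    "gene_density",
]


def gc_fraction_of_string(seq: str) -> float:
    """G+C over non-N bases; NaN when every base is N."""
    view = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _gc_of_view(view)


def _gc_of_view(view: np.ndarray) -> float:
    n_ambig = int(np.sum(view == ord("N")))
    denom = len(view) - n_ambig
    if denom == 0:
        return math.nan
    gc = int(np.sum((view == ord("G")) | (view == ord("C"))))
    return gc / denom


def gc_content(asm: Assembly, interval: GenomicInterval) -> float:
    return _gc_of_view(asm.byte_view(interval.sequence)[interval.start : interval.end])


def repeat_content(interval: GenomicInterval, softmask: IntervalSet) -> float:
    """Fraction of the interval covered by softmasked (repeat) bases."""
    return softmask.coverage_fraction(interval)


# ----------------------------------------------------------------------
# CpG islands
# ----------------------------------------------------------------------
def detect_cpg_islands(
    seq: str,
    window: int = 100,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    sequence_name: str = "seq",
) -> IntervalSet:
    """CpG islands of one sequence.

    Every ``window``-bp window (shift 1) qualifies iff GC > ``min_gc``
    and observed/expected CpG = (#CpG * len) / (#C * #G) > ``min_obs_exp``;
    windows containing N never qualify.  Overlapping qualifying windows
    are fused, and fused regions are kept when they are at least
    ``min_length`` long and themselves satisfy both criteria.
    """
    view = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = len(view)
    if n < window:
        return IntervalSet()
    is_c = view == ord("C")
    is_g = view == ord("G")
    is_n = view == ord("N")
    is_cpg = np.zeros(n, dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def sliding(x: np.ndarray, width: int) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x, dtype=np.int64)])
        return c[width:] - c[: n - width + 1]

    c_cnt = sliding(is_c, window)
    g_cnt = sliding(is_g, window)
    n_cnt = sliding(is_n, window)
    # a CpG belongs to a window only when both bases are inside it
    cpg_cnt = sliding(is_cpg, window)
    cpg_cnt = cpg_cnt - is_cpg[window - 1 : n]  # drop pair straddling the right edge
    gc_ok = (c_cnt + g_cnt) > min_gc * window
    denom = c_cnt * g_cnt
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_ok = (cpg_cnt * window) > (min_obs_exp * denom)
    oe_ok &= denom > 0
    qualifies = gc_ok & oe_ok & (n_cnt == 0)
    if not qualifies.any():
        return IntervalSet()
    covered = np.zeros(n, dtype=bool)
    starts = np.nonzero(qualifies)[0]
    # fuse via run ends rather than a per-window loop
    run_start = starts[np.concatenate([[True], np.diff(starts) > 1])]
    run_end = starts[np.concatenate([np.diff(starts) > 1, [True]])]
    for rs, re_ in zip(run_start, run_end):
        covered[rs : re_ + window] = True
    regions = IntervalSet.from_mask(sequence_name, covered)
    kept = []
    for iv in regions:
        if len(iv) < min_length:
            continue
        sub = view[iv.start : iv.end]
        gc = int(np.sum(sub == ord("C")) + np.sum(sub == ord("G")))
        c = int(np.sum(sub == ord("C")))
        g = int(np.sum(sub == ord("G")))
        cpg = int(np.sum((sub[:-1] == ord("C")) & (sub[1:] == ord("G"))))
        if gc > min_gc * len(iv) and c * g > 0 and cpg * len(iv) > min_obs_exp * c * g:
            kept.append((sequence_name, iv.start, iv.end))
    return IntervalSet.from_intervals(kept)


def detect_cpg_islands_assembly(asm: Assembly, **kwargs) -> IntervalSet:
    out = IntervalSet()
    for name, seq in asm.sequences.items():
        out = out.union(detect_cpg_islands(seq, sequence_name=name, **kwargs))
    return out


# ----------------------------------------------------------------------
# windowed summaries
# ----------------------------------------------------------------------
def _tile(length: int, window: int) -> List[Tuple[int, int]]:
    edges = list(range(0, length, window)) + [length]
    return [(s, e) for s, e in zip(edges[:-1], edges[1:]) if e > s]


def window_summary(
    asm: Assembly,
    missing: IntervalSet,
    softmask: IntervalSet,
    window: int = 10_000,
    missing_threshold: float = 0.5,
    mode: str = "window",
) -> Tuple[pd.DataFrame, Dict]:
    """GC/repeat/missing per 10-kbp window plus a missing-vs-present
    class comparison.

    ``mode='window'`` tiles each sequence and classes a window as
    missing when its missing coverage reaches ``missing_threshold``.
    ``mode='concat'`` instead pools all missing bases (and separately
    all present bases) genome-wide and re-tiles each pool into
    ``window``-bp blocks before computing GC and repeat content — the
    concatenation approach used for block-level comparisons of missing
    versus present sequence.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if mode == "window":
        rows = []
        for name in sorted(asm.sequences):
            view = asm.byte_view(name)
            mmask = missing.mask(name, len(view))
            rmask = softmask.mask(name, len(view))
            for s, e in _tile(len(view), window):
                iv = GenomicInterval(name, s, e)
                rows.append(
                    {
                        "sequence": name,
                        "start": s,
                        "end": e,
                        "gc": _gc_of_view(view[s:e]),
                        "repeat": float(rmask[s:e].mean()),
                        "missing_frac": float(mmask[s:e].mean()),
                        "short": e - s < window,
                    }
                )
        table = pd.DataFrame(rows)
        is_missing = table["missing_frac"] >= missing_threshold
    elif mode == "concat":
        table = _concat_blocks(asm, missing, softmask, window)
        is_missing = table["klass"] == "missing"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    stats: Dict = {"mode": mode, "n_missing": int(is_missing.sum()), "n_present": int((~is_missing).sum())}
    if stats["n_missing"] and stats["n_present"]:
        for col in ("gc", "repeat"):
            x = table.loc[is_missing, col].dropna()
            y = table.loc[~is_missing, col].dropna()
            stat, p = mannwhitneyu(x, y, alternative="greater")
            stats[col] = {
                "missing_mean": float(x.mean()),
                "present_mean": float(y.mean()),
                "statistic": float(stat),
                "p_value": float(p),
            }
    return table, stats


def _concat_blocks(
    asm: Assembly, missing: IntervalSet, softmask: IntervalSet, window: int
) -> pd.DataFrame:
    pools = {"missing": [], "present": []}
    rpools = {"missing": [], "present": []}
    for name in sorted(asm.sequences):
        view = asm.byte_view(name)
        mmask = missing.mask(name, len(view))
        rmask = softmask.mask(name, len(view))
        pools["missing"].append(view[mmask])
        pools["present"].append(view[~mmask])
        rpools["missing"].append(rmask[mmask])
        rpools["present"].append(rmask[~mmask])
    rows = []
    for klass in ("missing", "present"):
        cat = np.concatenate(pools[klass]) if pools[klass] else np.empty(0, dtype=np.uint8)
        rcat = np.concatenate(rpools[klass]) if rpools[klass] else np.empty(0, dtype=bool)
        for s, e in _tile(len(cat), window):
            rows.append(
                {
                    "sequence": f"concat_{klass}",
                    "start": s,
                    "end": e,
                    "gc": _gc_of_view(cat[s:e]),
                    "repeat": float(rcat[s:e].mean()),
                    "missing_frac": 1.0 if klass == "missing" else 0.0,
                    "klass": klass,
                    "short": e - s < window,
                }
            )
    return pd.DataFrame(rows)


def partition_missing_rates(
    missing: IntervalSet,
    cgi: IntervalSet,
    repeats: IntervalSet,
    lengths: Mapping[str, int],
) -> Dict[str, float]:
    """Missing coverage of CGI bases, repeat bases, and control bases
    (everything that is neither)."""
    control = IntervalSet.whole(lengths).subtract(cgi).subtract(repeats)
    out = {}
    for label, part in (("cgi_rate", cgi), ("repeat_rate", repeats), ("control_rate", control)):
        total = part.total_length
        out[label] = (part.intersect(missing).total_length / total) if total else math.nan
    return out


def gene_density(
    genes: GeneSet, lengths: Mapping[str, int], window: int = 200_000
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Genes intersecting each non-overlapping window (a gene spanning
    two windows counts in both), plus a per-sequence genes/Mb summary."""
    spans = [(g.sequence, g.start, g.end) for g in genes]
    rows = []
    for name in sorted(lengths):
        seq_spans = [(s, e) for sn, s, e in spans if sn == name]
        for ws, we in _tile(lengths[name], window):
            count = sum(1 for s, e in seq_spans if s < we and e > ws)
            rows.append(
                {
                    "sequence": name,
                    "start": ws,
                    "end": we,
                    "n_genes": count,
                    "genes_per_mb": count / ((we - ws) / 1e6),
                }
            )
    table = pd.DataFrame(rows)
    per_seq = []
    for name in sorted(lengths):
        n = sum(1 for sn, _, _ in spans if sn == name)
        per_seq.append(
            {"sequence": name, "n_genes": n, "genes_per_mb": n / (lengths[name] / 1e6)}
        )
    return table, pd.DataFrame(per_seq)
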