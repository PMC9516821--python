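"""Scoring of classifier output against the simulator's truth ledger."""

from __future__ import annotations

from typing import Dict, List, Sequence

from .classify import FalseLossRecord
from .simulate import EVENT_TYPES, STRUCTURAL_TYPES, TruthLedger

__all__ = ["match_records", "per_type_metrics"]


def _loci_close(r: FalseLossRecord, ev, tolerance: int) -> bool:
    if r.ref_sequence != ev.ref_sequence:
        return False
    return r.ref_start <= ev.ref_end + tolerance and ev.ref_start <= r.ref_end + tolerance


def match_records(
    records: Sequence[FalseLossRecord],
    ledger: TruthLedger,
    tolerance: int = 5,
) -> Dict[str, Dict[str, int]]:
    """Greedy one-to-one matching of records to ledger events.

    Structural events match on (type, gene); sequence-level events
    additionally require the reference loci to agree within
    ``tolerance`` bp."""
    out: Dict[str, Dict[str, int]] = {}
    for etype in EVENT_TYPES:
        events = [e for e in ledger.gene_level() if e.type == etype]
        recs = [r for r in records if r.type == etype]
        used = set()
        matched_events = 0
        for ev in events:
            hit = None
            for i, r in enumerate(recs):
                if i in used or r.gene_id != ev.gene_id:
                    continue
                if etype not in STRUCTURAL_TYPES and not _loci_close(r, ev, tolerance):
                    continue
                hit = i
                break
            if hit is not None:
                used.add(hit)
                matched_events += 1
        out[etype] = {
            "n_events": len(events),
            "n_records": len(recs),
            "matched": matched_events,
        }
    return out


def per_type_metrics(match: Dict[str, Dict[str, int]]) -> Dict[str, Dict[str, float]]:
    """Sensitivity (recall of ledger events) and precision (fraction of
    records explained by a ledger event) per type."""
    out = {}
    for etype, m in match.items():
        sens = m["matched"] / m["n_events"] if m["n_events"] else float("nan")
        prec = m["matched"] / m["n_records"] if m["n_records"] else float("nan")
        out[etype] = {"sensitivity": sens, "precision": prec, **m}
    return out
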