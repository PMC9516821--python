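"""Assembly container and FASTA input/output.

Sequences are stored as Python strings over ``ACGTN`` in either case;
lowercase carries the softmask (repeat) annotation, the common FASTA
dialect emitted by WindowMasker/RepeatMasker.  A separately supplied
softmask BED track takes precedence over case when given.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import IntervalSet

__all__ = ["Assembly", "revcomp"]

_ALPHABET = frozenset("ACGTNacgtn")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Assembly:
    """Named nucleotide sequences with per-base softmask carried as case."""

    name: str
    sequences: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for sname, seq in self.sequences.items():
            if sname in seen:
                raise ValueError(f"duplicate sequence name {sname!r}")
            seen.add(sname)
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {sname!r} contains non-ACGTN characters: {sorted(bad)[:5]}"
                )

    @property
    def lengths(self) -> Dict[str, int]:
        return {k: len(v) for k, v in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(v) for v in self.sequences.values())

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.sequences

    def fetch(self, sequence: str, start: int, end: int) -> str:
        seq = self.sequences[sequence]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"range {start}-{end} outside {sequence} (len {len(seq)})")
        return seq[start:end]

    def byte_view(self, sequence: str) -> np.ndarray:
        """Uppercased uint8 view of one sequence (A=65 C=67 G=71 T=84 N=78)."""
        return np.frombuffer(self.sequences[sequence].upper().encode("ascii"), dtype=np.uint8)

    # ------------------------------------------------------------------
    # derived tracks
    # ------------------------------------------------------------------
    def softmask(self) -> IntervalSet:
        """Lowercase (repeat-masked) runs as an interval set."""
        out = IntervalSet()
        for name, seq in self.sequences.items():
            raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            out = out.union(IntervalSet.from_mask(name, raw >= ord("a")))
        return out

    def gap_runs(self) -> IntervalSet:
        """Runs of N (assembly gaps)."""
        out = IntervalSet()
        for name in self.sequences:
            out = out.union(IntervalSet.from_mask(name, self.byte_view(name) == ord("N")))
        return out

    # ------------------------------------------------------------------
    # FASTA round trip
    # ------------------------------------------------------------------
    @classmethod
    def read_fasta(
        cls,
        path: str | Path,
        name: str | None = None,
        exclude: Iterable[str] = (),
        softmask_bed: str | Path | None = None,
    ) -> "Assembly":
        """Load a (optionally gzipped) FASTA.

        ``exclude`` drops sequences by name at load time (e.g. the
        mitochondrial genome, which would otherwise cross-align with
        nuclear copies).  ``softmask_bed`` overrides case-based masking.
        """
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        exclude = set(exclude)
        sequences: Dict[str, str] = {}
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                if rec.id in exclude:
                    continue
                sequences[rec.id] = str(rec.seq)
        asm = cls(name=name or path.stem, sequences=sequences)
        if softmask_bed is not None:
            asm = asm.with_softmask(IntervalSet.read_bed(softmask_bed))
        return asm

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        records = [
            SeqRecord(Seq(self.sequences[k]), id=k, description="")
            for k in sorted(self.sequences)
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)

    def with_softmask(self, mask: IntervalSet) -> "Assembly":
        """Return a copy whose case encodes exactly ``mask``."""
        sequences = {}
        for name, seq in self.sequences.items():
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
            m = mask.mask(name, len(seq))
            arr[m] += 32  # to lowercase
            sequences[name] = arr.tobytes().decode("ascii")
        return Assembly(name=self.name, sequences=sequences)
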