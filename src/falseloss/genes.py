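"""Gene/transcript models and GFF3 input/output.

Internal coordinates are 0-based half-open; the GFF3 1-based closed
convention is converted at the file boundary.  Gene-relative notions
(first exon, upstream, TSS) are strand-aware throughout: "upstream
3 kbp" of a minus-strand gene extends to higher coordinates.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils

from .assembly import Assembly, revcomp
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "GeneSet",
    "select_representative_transcript",
    "read_gff3",
    "write_gff3",
]

CODING = "protein_coding"
NONCODING_BIOTYPES = ("lncRNA", "rRNA", "snRNA", "snoRNA", "tRNA")


@dataclass
class TranscriptModel:
    id: str
    gene_id: str
    sequence: str
    strand: str
    exons: List[Tuple[int, int]]  # genomic ascending
    cds: List[Tuple[int, int]] = field(default_factory=list)  # genomic ascending

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {self.id}")
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.id} has no strand")

    # -- extents -------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def tss(self) -> int:
        """Transcription start site (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    # -- strand-ordered views -----------------------------------------
    def exons_5to3(self) -> List[Tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_5to3(self) -> List[Tuple[int, int]]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def introns(self) -> List[Tuple[int, int]]:
        """Genomic-ascending intron intervals."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def introns_5to3(self) -> List[Tuple[int, int]]:
        iv = self.introns()
        return iv if self.strand == "+" else list(reversed(iv))

    def cds_frames(self) -> List[int]:
        """GFF3 phase for each CDS segment, in genomic-ascending order."""
        phases: Dict[Tuple[int, int], int] = {}
        cum = 0
        for seg in self.cds_5to3():
            phases[seg] = (3 - cum % 3) % 3
            cum += seg[1] - seg[0]
        return [phases[seg] for seg in self.cds]

    # -- UTR/CDS partition --------------------------------------------
    def utr5(self) -> List[Tuple[int, int]]:
        return self._utr(five_prime=True)

    def utr3(self) -> List[Tuple[int, int]]:
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool) -> List[Tuple[int, int]]:
        if not self.cds:
            return []
        cs, ce = self.cds[0][0], self.cds[-1][1]
        before = five_prime if self.strand == "+" else not five_prime
        out = []
        for s, e in self.exons:
            if before:
                if e <= cs:
                    out.append((s, e))
                elif s < cs:
                    out.append((s, cs))
            else:
                if s >= ce:
                    out.append((s, e))
                elif e > ce:
                    out.append((ce, e))
        return out

    # -- sequence extraction ------------------------------------------
    def spliced(self, asm: Assembly, segments: Sequence[Tuple[int, int]]) -> str:
        """Concatenate genomic segments in 5'→3' transcript orientation."""
        segs = sorted(segments)
        raw = "".join(asm.fetch(self.sequence, s, e).upper() for s, e in segs)
        return raw if self.strand == "+" else revcomp(raw)

    def cds_sequence(self, asm: Assembly) -> str:
        return self.spliced(asm, self.cds)


@dataclass
class GeneModel:
    id: str
    sequence: str
    strand: str
    biotype: str = CODING
    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.sequence, self.start, self.end)

    @property
    def is_coding(self) -> bool:
        return self.biotype == CODING

    def representative(self) -> TranscriptModel:
        return select_representative_transcript(self)


def select_representative_transcript(gene: GeneModel) -> TranscriptModel:
    """Longest transcript by summed exon length; ties break to the
    lexicographically smallest transcript id."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.id} has no transcripts")
    return min(gene.transcripts.values(), key=lambda t: (-t.exon_length, t.id))


class GeneSet:
    """Ordered collection of genes with shared-coordinate convenience views."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._genes: Dict[str, GeneModel] = {}
        for g in genes:
            if g.id in self._genes:
                raise ValueError(f"duplicate gene id {g.id}")
            self._genes[g.id] = g

    def __iter__(self):
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def coding(self) -> List[GeneModel]:
        return [g for g in self if g.is_coding]

    def noncoding(self) -> List[GeneModel]:
        return [g for g in self if not g.is_coding]

    def subset(self, gene_ids) -> "GeneSet":
        ids = set(gene_ids)
        return GeneSet([g for g in self if g.id in ids])

    def exclude(self, gene_ids) -> "GeneSet":
        """Drop genes by id (e.g. a falsely-duplicated-gene blacklist)."""
        ids = set(gene_ids)
        return GeneSet([g for g in self if g.id not in ids])

    def spans(self) -> IntervalSet:
        return IntervalSet.from_intervals(g.span for g in self)


# ----------------------------------------------------------------------
# GFF3 I/O
# ----------------------------------------------------------------------
_TRANSCRIPT_TYPES = {"mRNA", "transcript", "lnc_RNA", "rRNA", "snRNA", "snoRNA", "tRNA"}


def read_gff3(path: str | Path) -> GeneSet:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        biotype = gf.attributes.get("biotype", [CODING])[0]
        gene = GeneModel(
            id=gf.id, sequence=gf.seqid, strand=gf.strand, biotype=biotype
        )
        for tf in db.children(gf, level=1):
            if tf.featuretype not in _TRANSCRIPT_TYPES:
                continue
            exons = [
                (f.start - 1, f.end) for f in db.children(tf, featuretype="exon")
            ]
            cds = [(f.start - 1, f.end) for f in db.children(tf, featuretype="CDS")]
            gene.transcripts[tf.id] = TranscriptModel(
                id=tf.id,
                gene_id=gene.id,
                sequence=gf.seqid,
                strand=gf.strand,
                exons=exons,
                cds=cds,
            )
        if gene.transcripts:
            genes.append(gene)
    return GeneSet(genes)


def read_gff3_string(text: str) -> GeneSet:
    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_gff3(name)
    finally:
        Path(name).unlink(missing_ok=True)


def write_gff3(genes: GeneSet, path: str | Path) -> None:
    """Deterministic writer: genes sorted by (sequence, start, id)."""
    lines = ["##gff-version 3"]
    for gene in sorted(genes, key=lambda g: (g.sequence, g.start, g.id)):
        lines.append(
            _row(gene.sequence, "gene", gene.start, gene.end, gene.strand, ".",
                 f"ID={gene.id};biotype={gene.biotype}")
        )
        for tid in sorted(gene.transcripts):
            t = gene.transcripts[tid]
            ttype = "mRNA" if t.cds else "transcript"
            lines.append(
                _row(t.sequence, ttype, t.start, t.end, t.strand, ".",
                     f"ID={t.id};Parent={gene.id}")
            )
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append(
                    _row(t.sequence, "exon", s, e, t.strand, ".",
                         f"ID={t.id}.exon{i};Parent={t.id}")
                )
            for (s, e), phase in zip(t.cds, t.cds_frames()):
                lines.append(
                    _row(t.sequence, "CDS", s, e, t.strand, str(phase),
                         f"ID={t.id}.cds;Parent={t.id}")
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _row(seqid: str, ftype: str, start: int, end: int, strand: str, phase: str, attrs: str) -> str:
    return "\t".join(
        [seqid, "falseloss", ftype, str(start + 1), str(end), ".", strand, phase, attrs]
    )
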