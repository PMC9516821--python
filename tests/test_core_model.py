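"""Assembly container, gene models, GFF3 round trip, chains and lifting."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from falseloss.assembly import Assembly, revcomp
from falseloss.chain import AlignmentChain, identity_chains, lift, read_paf, write_paf
from falseloss.genes import (
    GeneModel,
    TranscriptModel,
    read_gff3,
    select_representative_transcript,
    write_gff3,
)
from falseloss.intervals import IntervalSet


def make_gene(exon_sets, strand="+", gene_id="g1"):
    gene = GeneModel(id=gene_id, sequence="chr", strand=strand)
    for tid, exons in exon_sets.items():
        gene.transcripts[tid] = TranscriptModel(
            id=tid, gene_id=gene_id, sequence="chr", strand=strand, exons=exons
        )
    return gene


class TestAssembly:
    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            Assembly("a", {"x": "ACGTX"})

    def test_softmask_and_gaps_from_case(self):
        asm = Assembly("a", {"x": "ACGTacgtNNNNACGT"})
        assert list(asm.softmask()) and asm.softmask().array("x").tolist() == [[4, 8]]
        assert asm.gap_runs().array("x").tolist() == [[8, 12]]

    def test_fasta_round_trip(self, tmp_path):
        asm = Assembly("a", {"s1": "ACGTNacgt" * 30, "s2": "TTTTgggg"})
        asm.write_fasta(tmp_path / "x.fa")
        back = Assembly.read_fasta(tmp_path / "x.fa")
        assert back.sequences == asm.sequences

    def test_mitochondrial_exclusion_at_load(self, tmp_path):
        Assembly("a", {"chr1": "ACGT" * 10, "MT": "ACGT" * 5}).write_fasta(tmp_path / "x.fa")
        back = Assembly.read_fasta(tmp_path / "x.fa", exclude=["MT"])
        assert set(back.sequences) == {"chr1"}

    def test_softmask_bed_overrides_case(self, tmp_path):
        Assembly("a", {"x": "acgtACGT"}).write_fasta(tmp_path / "x.fa")
        (tmp_path / "m.bed").write_text("x\t6\t8\n")
        back = Assembly.read_fasta(tmp_path / "x.fa", softmask_bed=tmp_path / "m.bed")
        assert back.sequences["x"] == "ACGTACgt"


class TestRepresentativeTranscript:
    def test_longest_wins(self):
        g = make_gene({"t1": [(0, 500)], "t2": [(0, 400), (600, 1000)]})
        assert select_representative_transcript(g).id == "t2"

    def test_tie_breaks_lexicographically(self):
        g = make_gene({"tB": [(0, 800)], "tA": [(100, 900)]})
        assert select_representative_transcript(g).id == "tA"

    def test_single_transcript(self):
        g = make_gene({"only": [(0, 100)]})
        assert select_representative_transcript(g).id == "only"

    def test_no_transcripts_rejected(self):
        with pytest.raises(ValueError):
            select_representative_transcript(GeneModel(id="g", sequence="chr", strand="+"))


class TestTranscriptGeometry:
    def test_strand_aware_tss_and_order(self):
        t = TranscriptModel(
            id="t", gene_id="g", sequence="chr", strand="-",
            exons=[(100, 200), (300, 400)], cds=[(150, 200), (300, 350)],
        )
        assert t.tss == 399 and t.tts == 100
        assert t.exons_5to3()[0] == (300, 400)
        assert t.introns() == [(200, 300)]

    def test_utr_cds_partition_exact(self):
        t = TranscriptModel(
            id="t", gene_id="g", sequence="chr", strand="+",
            exons=[(0, 100), (200, 300), (400, 500)],
            cds=[(50, 100), (200, 300), (400, 430)],
        )
        utr = IntervalSet.from_intervals([("chr", s, e) for s, e in t.utr5() + t.utr3()])
        cds = IntervalSet.from_intervals([("chr", s, e) for s, e in t.cds])
        exons = IntervalSet.from_intervals([("chr", s, e) for s, e in t.exons])
        assert utr.union(cds) == exons and not utr.intersect(cds)

    def test_cds_frames_cumulative(self):
        t = TranscriptModel(
            id="t", gene_id="g", sequence="chr", strand="+",
            exons=[(0, 10), (20, 30)], cds=[(2, 10), (20, 27)],
        )
        assert t.cds_frames() == [0, (3 - 8 % 3) % 3]


class TestGFF3RoundTrip:
    def test_read_write_read_identical(self, tmp_path, small_bundle):
        genes = small_bundle.truth.genes
        write_gff3(genes, tmp_path / "a.gff3")
        once = read_gff3(tmp_path / "a.gff3")
        write_gff3(once, tmp_path / "b.gff3")
        assert (tmp_path / "a.gff3").read_text() == (tmp_path / "b.gff3").read_text()
        twice = read_gff3(tmp_path / "b.gff3")
        assert {g.id for g in once} == {g.id for g in twice}
        for g in once:
            h = twice[g.id]
            assert g.biotype == h.biotype and g.strand == h.strand
            for tid, t in g.transcripts.items():
                assert h.transcripts[tid].exons == t.exons
                assert h.transcripts[tid].cds == t.cds


class TestLift:
    def test_identity(self):
        asm = Assembly("a", {"x": "ACGT" * 25})
        chains = identity_chains(asm)
        s = IntervalSet({"x": np.array([[5, 10]])})
        assert lift(s, chains) == s

    def test_interval_in_gap_drops_out(self):
        chain = AlignmentChain("x", "y", "+", [(0, 10, 0, 10), (50, 60, 40, 50)], 100, 100)
        s = IntervalSet({"x": np.array([[20, 40]])})
        assert not lift(s, [chain])

    def test_multi_block_images(self):
        chain = AlignmentChain(
            "x", "y", "+", [(0, 10, 100, 110), (20, 30, 200, 210)], 100, 1000
        )
        s = IntervalSet({"x": np.array([[0, 30]])})
        assert lift(s, [chain]) == IntervalSet({"y": np.array([[100, 110], [200, 210]])})

    def test_minus_strand_mapping(self):
        chain = AlignmentChain("x", "y", "-", [(10, 20, 30, 40)], 100, 100)
        s = IntervalSet({"x": np.array([[10, 12]])})
        assert lift(s, [chain]) == IntervalSet({"y": np.array([[38, 40]])})

    def test_unknown_sequence_empty_image(self):
        chain = AlignmentChain("x", "y", "+", [(0, 10, 0, 10)], 10, 10)
        assert not lift(IntervalSet({"z": np.array([[0, 5]])}), [chain])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 90), st.integers(1, 10))
    def test_round_trip_containment(self, a, w):
        chain = AlignmentChain(
            "x", "y", "-", [(0, 30, 120, 150), (40, 80, 60, 100)], 100, 200
        )
        s = IntervalSet({"x": np.array([[a, min(a + w, 100)]])})
        fwd = lift(s, [chain], "query_to_target")
        back = lift(fwd, [chain], "target_to_query")
        assert not back.subtract(s)  # image of the image is contained


class TestPAF:
    def test_round_trip_both_dialects(self, tmp_path, small_bundle):
        chains = small_bundle.chains
        for cigar in (True, False):
            write_paf(chains, tmp_path / "c.paf", cigar=cigar)
            back = read_paf(tmp_path / "c.paf")
            orig = sorted(
                (c.query, c.target, c.strand, b) for c in chains for b in c.blocks
            )
            rt = sorted(
                (c.query, c.target, c.strand, b) for c in back for b in c.blocks
            )
            assert rt == orig

    def test_minimap2_output_parses(self, tmp_path, small_bundle):
        """Cross-check the PAF reader against a real aligner's output."""
        asm = small_bundle.truth.assembly
        name = sorted(asm.sequences)[0]
        sub = Assembly("sub", {name: asm.sequences[name][:60_000]})
        sub.write_fasta(tmp_path / "a.fa")
        proc = subprocess.run(
            ["minimap2", "-x", "asm5", "-c", str(tmp_path / "a.fa"), str(tmp_path / "a.fa")],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            pytest.skip("minimap2 unavailable")
        (tmp_path / "self.paf").write_text(proc.stdout)
        chains = read_paf(tmp_path / "self.paf")
        cov = sum(c.aligned_length for c in chains)
        assert cov >= 0.99 * 60_000


def test_revcomp_preserves_case_and_involution():
    s = "ACGTacgtNn"
    assert revcomp(revcomp(s)) == s
    assert revcomp("ACgt") == "acGT"
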