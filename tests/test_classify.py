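"""Eight-type classifier: detectors, thresholds, validation, null control."""

import numpy as np
import pytest

from falseloss.assembly import Assembly
from falseloss.chain import AlignmentChain, identity_chains
from falseloss.classify import (
    FalseLossRecord,
    classify_assembly,
    detect_frameshift,
    detect_premature_stop,
    detect_splice_disruption,
    project_gene,
    summarize,
    validate_with_reads,
)
from falseloss.evaluate import match_records, per_type_metrics
from falseloss.genes import GeneModel, GeneSet, TranscriptModel
from falseloss.variants import Pileup


def mk_gene(exons, cds, strand="+", seq="chr", gene_id="g"):
    g = GeneModel(id=gene_id, sequence=seq, strand=strand)
    g.transcripts["t"] = TranscriptModel(
        id=f"{gene_id}.t", gene_id=gene_id, sequence=seq, strand=strand,
        exons=exons, cds=cds,
    )
    return g


class TestProjectGene:
    def test_identity_projection_equals_annotation(self, small_bundle):
        truth = small_bundle.truth
        chains = identity_chains(truth.assembly)
        for gene in truth.genes.coding()[:5]:
            proj = project_gene(gene, chains, truth.assembly)
            t = gene.representative()
            assert proj.exon_lifted == [e - s for s, e in t.exons_5to3()]
            assert not proj.split
            assert proj.cds_chars == t.cds_sequence(truth.assembly)

    def test_exons_on_two_scaffolds_flag_split(self):
        gene = mk_gene([(0, 100), (200, 300)], [(0, 100), (200, 300)])
        chains = [
            AlignmentChain("chr", "s1", "+", [(0, 100, 0, 100)], 1000, 500),
            AlignmentChain("chr", "s2", "+", [(200, 300, 50, 150)], 1000, 500),
        ]
        prior = Assembly("p", {"s1": "A" * 500, "s2": "A" * 500})
        proj = project_gene(gene, chains, prior)
        assert proj.split and proj.discordance == "multi_scaffold"
        assert {sc for sc, _, _ in proj.split_locations} == {"s1", "s2"}

    def test_inverted_five_prime_exons_same_scaffold_discordant(self):
        gene = mk_gene([(0, 100), (200, 300)], [(0, 100), (200, 300)])
        chains = [
            AlignmentChain("chr", "s1", "-", [(0, 100, 400, 500)], 1000, 1000),
            AlignmentChain("chr", "s1", "+", [(200, 300, 600, 700)], 1000, 1000),
        ]
        prior = Assembly("p", {"s1": "A" * 1000})
        proj = project_gene(gene, chains, prior)
        assert proj.split and proj.discordance == "orientation"


class TestDetectFrameshift:
    REF = "ATG" + "GCT" * 40 + "TAA"

    def test_four_bp_insertion_is_frameshift(self):
        proj = self.REF[:50] + "TTTT" + self.REF[50:]
        events = detect_frameshift(self.REF, proj)
        assert [e["length"] for e in events] == [4]

    def test_three_bp_deletion_is_not(self):
        proj = self.REF[:50] + self.REF[53:]
        assert detect_frameshift(self.REF, proj) == []

    def test_ten_bp_insertion_is_not(self):
        proj = self.REF[:50] + "TTTTTTTTTT" + self.REF[50:]
        assert detect_frameshift(self.REF, proj) == []

    def test_empty_projection_no_call(self):
        assert detect_frameshift(self.REF, "") == []


class TestValidateWithReads:
    def _record(self, rtype, pos=50):
        return FalseLossRecord(
            gene_id="g", type=rtype, ref_sequence="chr", ref_start=pos, ref_end=pos + 1,
            prior_sequence="y", prior_start=pos, prior_end=pos + 1,
        )

    def _pileup(self, depth, mismatch=0, indel=0, pos=50):
        pu = Pileup({"y": 100})
        pu.depth["y"][:] = depth
        pu.mismatch["y"][pos] = mismatch
        pu.ins["y"][pos] = indel
        return pu

    def test_low_depth_confirms_stop(self):
        v = validate_with_reads(self._record("premature_stop"), self._pileup(9))
        assert v == "confirmed_assembly_error"

    def test_high_mismatch_confirms_stop(self):
        v = validate_with_reads(self._record("premature_stop"), self._pileup(20, mismatch=18))
        assert v == "confirmed_assembly_error"

    def test_low_indel_fraction_rejects_frameshift(self):
        v = validate_with_reads(self._record("frameshift"), self._pileup(20, indel=2))
        assert v == "rejected"

    def test_exactly_eighty_percent_confirms_frameshift(self):
        v = validate_with_reads(self._record("frameshift"), self._pileup(20, indel=16))
        assert v == "confirmed_assembly_error"

    def test_missing_pileup_unvalidated(self):
        assert validate_with_reads(self._record("frameshift"), None) == "unvalidated"

    def test_structural_types_not_validated(self):
        assert validate_with_reads(self._record("missing_exon"), self._pileup(5)) == "unvalidated"


class TestSpliceDisruption:
    def _setup(self, prior_intron_edit):
        # gene with one intron GTxx..xxAG on the plus strand
        exon1 = "ATGGCTGCTGCAGCA"  # 15 bp
        intron = "GT" + "C" * 30 + "AG"
        exon2 = "GCTGCTGCAGCATAA"
        ref_seq = "AAAA" + exon1 + intron + exon2 + "AAAA"
        prior_seq = ref_seq.replace(intron, prior_intron_edit, 1)
        ref = Assembly("r", {"chr": ref_seq})
        prior = Assembly("p", {"y": prior_seq})
        gene = mk_gene(
            exons=[(4, 19), (53, 68)], cds=[(4, 19), (53, 68)]
        )
        chains = [AlignmentChain("chr", "y", "+", [(0, len(ref_seq), 0, len(prior_seq))], len(ref_seq), len(prior_seq))]
        return gene, chains, ref, prior

    def test_gt_to_gg_disrupts(self):
        gene, chains, ref, prior = self._setup("GG" + "C" * 30 + "AG")
        events = [e for e in detect_splice_disruption(gene, chains, ref, prior) if not e.get("skipped")]
        assert len(events) == 1 and events[0]["prior_junction"] == "GG-AG"

    def test_gc_ag_still_canonical(self):
        gene, chains, ref, prior = self._setup("GC" + "C" * 30 + "AG")
        events = [e for e in detect_splice_disruption(gene, chains, ref, prior) if not e.get("skipped")]
        assert events == []

    def test_ambiguous_prior_junction_excluded(self):
        gene, chains, ref, prior = self._setup("GN" + "C" * 30 + "AG")
        events = detect_splice_disruption(gene, chains, ref, prior)
        assert len(events) == 1 and events[0]["skipped"]


class TestPrematureStop:
    def test_engineered_stop_detected_and_flank_mismatch_rejected(self, small_bundle):
        b = small_bundle
        evs = [e for e in b.ledger.gene_level() if e.type == "premature_stop"]
        assert evs
        ev = evs[0]
        gene = b.truth.genes[ev.gene_id]
        chains = [c for c in b.chains if c.query == gene.sequence]
        proj = project_gene(gene, chains, b.degraded)
        events = detect_premature_stop(gene, proj, b.truth.assembly, b.degraded)
        assert len(events) == 1
        got = events[0]
        assert abs(got["ref_interval"][0] - ev.ref_start) <= 5
        # now corrupt a flank base on the prior: the same site must be rejected
        scaffold = got["prior_sequence"]
        lo = got["prior_interval"][0]
        seq = b.degraded.sequences[scaffold]
        flank_pos = lo - 3
        base = seq[flank_pos].upper()
        swap = "A" if base != "A" else "C"
        corrupted = Assembly(
            "p2", {**b.degraded.sequences, scaffold: seq[:flank_pos] + swap + seq[flank_pos + 1 :]}
        )
        events2 = detect_premature_stop(gene, proj, b.truth.assembly, corrupted)
        assert events2 == []

    def test_identical_assemblies_no_stops(self, small_bundle):
        truth = small_bundle.truth
        chains = identity_chains(truth.assembly)
        for gene in truth.genes.coding()[:5]:
            proj = project_gene(gene, chains, truth.assembly)
            assert detect_premature_stop(gene, proj, truth.assembly, truth.assembly) == []


class TestNullControlAndRecovery:
    def test_identity_comparison_yields_zero_records(self, small_bundle):
        truth = small_bundle.truth
        chains = identity_chains(truth.assembly)
        pu = Pileup(truth.assembly.lengths)
        for name in pu.lengths:
            pu.depth[name][:] = 30
            pu.ref[name][:] = 30
        records = classify_assembly(
            truth.assembly, truth.assembly, truth.genes, chains, prior_pileup=pu
        )
        assert records == []
        report = summarize(records, truth.genes)
        assert report["fraction_genes_affected"] == 0.0
        assert all(v == 0 for v in report["per_type_counts"].values())

    def test_ledger_recovery_on_small_bundle(self, small_bundle):
        b = small_bundle
        records = classify_assembly(
            b.truth.assembly, b.degraded, b.truth.genes, b.chains,
            prior_pileup=b.prior_pileup,
        )
        metrics = per_type_metrics(match_records(records, b.ledger))
        for etype, m in metrics.items():
            assert m["sensitivity"] >= 0.95, (etype, m)
            assert m["precision"] >= 0.95, (etype, m)
        # completely missing genes emit no other record type
        cm = {r.gene_id for r in records if r.type == "completely_missing"}
        for r in records:
            if r.gene_id in cm:
                assert r.type == "completely_missing"
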