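"""Gene/exon missingness, categories, metagene profile, read support."""

import numpy as np
import pytest

from falseloss.chain import AlignmentChain
from falseloss.genes import GeneModel, GeneSet, TranscriptModel
from falseloss.genewise import (
    ExonHit,
    category_intervals,
    classify_feature_missingness,
    cumulative_missing_distribution,
    exon_unique_coverage,
    genomic_category_missing,
    metagene_profile,
    missing_support,
    nearest_upstream_cgi,
)
from falseloss.intervals import GenomicInterval, IntervalSet
from falseloss.missing import conservative_missing, unaligned_regions


def coding_gene(exons, cds, strand="+", gene_id="g1", seq="chr"):
    g = GeneModel(id=gene_id, sequence=seq, strand=strand)
    g.transcripts["t"] = TranscriptModel(
        id=f"{gene_id}.t", gene_id=gene_id, sequence=seq, strand=strand,
        exons=exons, cds=cds,
    )
    return g


class TestExonUniqueCoverage:
    def test_overlapping_hits_counted_once(self):
        assert exon_unique_coverage(100, [(0, 50), (25, 75)]) == pytest.approx(75.0)

    def test_no_hits(self):
        assert exon_unique_coverage(100, []) == 0.0

    def test_full_hit(self):
        assert exon_unique_coverage(100, [(0, 100)]) == 100.0

    def test_zero_length_exon_rejected(self):
        with pytest.raises(ValueError):
            exon_unique_coverage(0, [])


class TestClassifyFeatureMissingness:
    def setup_method(self):
        self.gene = coding_gene(
            exons=[(100, 200), (300, 400), (500, 600)],
            cds=[(150, 200), (300, 400), (500, 550)],
        )

    def test_all_exons_missing_no_hits(self):
        missing = IntervalSet({"chr": np.array([[0, 1000]])})
        got = classify_feature_missingness(self.gene, missing)
        assert got.status == "completely_missing" and got.missing_percent == 100.0

    def test_one_exon_aligned_partial(self):
        missing = IntervalSet({"chr": np.array([[250, 1000]])})
        got = classify_feature_missingness(self.gene, missing)
        assert got.status == "partially_missing"
        assert got.exon_status == ["present", "completely_missing", "completely_missing"]

    def test_high_unique_coverage_rescues(self):
        missing = IntervalSet({"chr": np.array([[0, 1000]])})
        hits = [ExonHit("g1", 0, 0, 95)]  # 95% of a 100-bp exon
        got = classify_feature_missingness(self.gene, missing, hits)
        assert got.exon_status[0] == "present"

    def test_qcovus_exactly_90_not_rescued(self):
        missing = IntervalSet({"chr": np.array([[0, 1000]])})
        hits = [ExonHit("g1", 0, 0, 90)]  # exactly 90% unique coverage
        got = classify_feature_missingness(self.gene, missing, hits)
        assert got.exon_status[0] == "completely_missing"

    def test_low_identity_hits_filtered(self):
        missing = IntervalSet({"chr": np.array([[0, 1000]])})
        hits = [ExonHit("g1", 0, 0, 100, identity=0.85)]
        got = classify_feature_missingness(self.gene, missing, hits)
        assert got.status == "completely_missing"

    def test_span_vs_exon_only_percent(self):
        missing = IntervalSet({"chr": np.array([[300, 400]])})  # exon 2 only
        full = classify_feature_missingness(self.gene, missing)
        exon_only = classify_feature_missingness(self.gene, missing, exon_only_percent=True)
        assert full.missing_percent == pytest.approx(100 * 100 / 500)
        assert exon_only.missing_percent == pytest.approx(100 * 100 / 300)


class TestGenomicCategories:
    def _genes(self):
        coding = coding_gene(
            exons=[(100, 200), (300, 400)], cds=[(150, 200), (300, 350)]
        )
        nc = GeneModel(id="nc1", sequence="chr", strand="+", biotype="lncRNA")
        nc.transcripts["t"] = TranscriptModel(
            id="nc1.t", gene_id="nc1", sequence="chr", strand="+",
            exons=[(600, 700), (800, 900)],
        )
        return GeneSet([coding, nc])

    def test_partition_covers_genome(self):
        genes = self._genes()
        lengths = {"chr": 2000}
        cats = category_intervals(genes, lengths)
        total = sum(s.total_length for s in cats.values())
        # exon/intron/noncoding/intergenic tile the genome; the coding
        # gene's intron and the noncoding intron overlap nothing here
        union = IntervalSet()
        for s in cats.values():
            assert not union.intersect(s)
            union = union.union(s)
        covered = union.total_length
        # the noncoding gene's intron (700..800) belongs to no category
        assert covered == 2000 - 100 and total == covered

    def test_rates_zero_without_missing(self):
        rates = genomic_category_missing(self._genes(), IntervalSet(), {"chr": 2000})
        assert all(v == 0 for v in rates.values())

    def test_missing_exactly_coding_exons(self):
        genes = self._genes()
        missing = IntervalSet({"chr": np.array([[100, 200], [300, 400]])})
        rates = genomic_category_missing(genes, missing, {"chr": 2000})
        assert rates["coding_exon"] == 1.0 and rates["intron"] == 0.0


class TestNearestUpstreamCGI:
    def test_plus_strand_distance(self):
        g = coding_gene([(10_000, 10_500)], [(10_000, 10_300)])
        cgis = IntervalSet({"chr": np.array([[9_000, 9_500]])})
        assert nearest_upstream_cgi(g, cgis) == 500

    def test_overlap_is_zero(self):
        g = coding_gene([(10_000, 10_500)], [(10_000, 10_300)])
        cgis = IntervalSet({"chr": np.array([[9_900, 10_100]])})
        assert nearest_upstream_cgi(g, cgis) == 0

    def test_downstream_only_is_none(self):
        g = coding_gene([(10_000, 10_500)], [(10_000, 10_300)])
        cgis = IntervalSet({"chr": np.array([[11_000, 11_400]])})
        assert nearest_upstream_cgi(g, cgis) is None

    def test_minus_strand_mirrors(self):
        g = coding_gene([(10_000, 10_500)], [(10_200, 10_500)], strand="-")
        cgis = IntervalSet({"chr": np.array([[11_000, 11_400]])})
        assert nearest_upstream_cgi(g, cgis) == 500


class TestMetageneProfile:
    def test_no_missing_all_zero(self, small_bundle):
        genes = small_bundle.truth.genes
        blocks, body = metagene_profile(
            genes, IntervalSet(), small_bundle.truth.assembly, small_bundle.truth.cgi_truth
        )
        assert (blocks.missing_fraction == 0).all()
        assert (body.missing_fraction_mean == 0).all()

    def test_block_at_ninety_percent_counts_missing(self):
        g = coding_gene(
            exons=[(5000, 5200), (5400, 5600), (5800, 6000), (6200, 6400)],
            cds=[(5100, 5200), (5400, 5600), (5800, 6000), (6200, 6300)],
        )
        genes = GeneSet([g])
        from falseloss.assembly import Assembly

        asm = Assembly("a", {"chr": "ACGT" * 5000})
        # 90 of the 100 bases of the TSS-adjacent upstream block
        missing = IntervalSet({"chr": np.array([[4900, 4990]])})
        blocks, _ = metagene_profile(genes, missing, asm)
        row = blocks[(blocks.position == -1) & (blocks.stratum == "all")]
        assert row.missing_fraction.iloc[0] == 1.0
        # 89 bases falls below the 90% rule
        blocks2, _ = metagene_profile(
            genes, IntervalSet({"chr": np.array([[4900, 4989]])}), asm
        )
        row2 = blocks2[(blocks2.position == -1) & (blocks2.stratum == "all")]
        assert row2.missing_fraction.iloc[0] == 0.0

    def test_strand_symmetry(self, small_bundle):
        """Reversing all strands and reverse-complementing the genome
        leaves the profile unchanged."""
        from falseloss.assembly import Assembly, revcomp

        truth = small_bundle.truth
        asm = truth.assembly
        name = "chr1"
        L = asm.lengths[name]
        flipped_asm = Assembly("flip", {name: revcomp(asm.sequences[name])})
        sub = [g for g in truth.genes.coding() if g.sequence == name][:10]

        def mirror_iv(s, e):
            return L - e, L - s

        flipped_genes = []
        for g in sub:
            t = g.representative()
            fg = GeneModel(id=g.id, sequence=name, strand="-" if g.strand == "+" else "+")
            fg.transcripts["t"] = TranscriptModel(
                id=f"{g.id}.t", gene_id=g.id, sequence=name, strand=fg.strand,
                exons=[mirror_iv(s, e) for s, e in t.exons],
                cds=[mirror_iv(s, e) for s, e in t.cds],
            )
            flipped_genes.append(fg)
        missing = IntervalSet({name: np.array([[0, 40_000]])})
        flipped_missing = IntervalSet({name: np.array([[L - 40_000, L]])})
        b1, _ = metagene_profile(GeneSet(sub), missing, asm)
        b2, _ = metagene_profile(GeneSet(flipped_genes), flipped_missing, flipped_asm)
        a1 = b1[b1.stratum == "all"].set_index("position")
        a2 = b2[b2.stratum == "all"].set_index("position")
        assert np.allclose(a1.missing_fraction, a2.missing_fraction)
        assert np.allclose(a1.gc_mean, a2.gc_mean, atol=1e-12)


class TestMissingSupport:
    def test_all_read_supported(self):
        missing = IntervalSet({"x": np.array([[10, 20]])})
        depth = {"x": np.ones(100, dtype=int)}
        got = missing_support(missing, depth, IntervalSet(), [])
        assert got["read_supported"] == 1.0

    def test_unsupported_without_depth_or_gaps(self):
        missing = IntervalSet({"x": np.array([[10, 20]])})
        depth = {"x": np.zeros(100, dtype=int)}
        got = missing_support(missing, depth, IntervalSet(), [])
        assert got["unsupported"] == 1.0

    def test_gap_supported_by_interpolation(self):
        missing = IntervalSet({"x": np.array([[40, 60]])})
        depth = {"x": np.zeros(100, dtype=int)}
        chain = AlignmentChain("x", "y", "+", [(0, 40, 0, 40), (60, 100, 60, 100)], 100, 100)
        gaps = IntervalSet({"y": np.array([[40, 60]])})
        got = missing_support(missing, depth, gaps, [chain])
        assert got["gap_supported"] == 1.0

    def test_simulated_low_depth_fraction_matches(self, small_bundle):
        b = small_bundle
        lengths = b.truth.assembly.lengths
        missing = conservative_missing(
            unaligned_regions(lengths, b.chains, side="query"),
            unaligned_regions(lengths, b.chains, side="query"),
        )
        got = missing_support(
            missing, b.prior_read_depth_on_ref, b.degraded.gap_runs(), b.chains
        )
        covered = 0
        for iv in missing:
            d = b.prior_read_depth_on_ref[iv.sequence][iv.start : iv.end]
            covered += int((d >= 1).sum())
        expect = covered / missing.total_length
        assert got["read_supported"] == pytest.approx(expect, abs=0.02)


class TestECDF:
    def test_all_zero(self):
        _, frac = cumulative_missing_distribution([0.0] * 5)
        assert frac == 1.0

    def test_all_hundred(self):
        _, frac = cumulative_missing_distribution([100.0] * 5)
        assert frac == 0.0

    def test_mixed(self):
        _, frac = cumulative_missing_distribution([0, 5, 20, 50])
        assert frac == 0.5
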