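"""GC/repeat content, CpG island detection, windows, and densities."""

import math

import numpy as np
import pytest

from falseloss.assembly import Assembly
from falseloss.content import (
    detect_cpg_islands,
    gc_content,
    gc_fraction_of_string,
    gene_density,
    partition_missing_rates,
    repeat_content,
    window_summary,
)
from falseloss.genes import GeneModel, GeneSet, TranscriptModel
from falseloss.intervals import GenomicInterval, IntervalSet


class TestGCContent:
    def test_all_gc(self):
        assert gc_fraction_of_string("GGCC") == 1.0

    def test_ambiguous_excluded_from_denominator(self):
        assert gc_fraction_of_string("ATGCNN") == pytest.approx(0.5)

    def test_all_n_undefined(self):
        assert math.isnan(gc_fraction_of_string("NNNN"))

    def test_interval_accessor(self):
        asm = Assembly("a", {"x": "AAAAGGCCAAAA"})
        assert gc_content(asm, GenomicInterval("x", 4, 8)) == 1.0


class TestRepeatContent:
    @pytest.mark.parametrize(
        "mask,expected",
        [
            ([(0, 100)], 1.0),
            ([], 0.0),
            ([(0, 25), (50, 75)], 0.5),
        ],
    )
    def test_coverage_semantics(self, mask, expected):
        soft = IntervalSet({"x": np.array(mask)}) if mask else IntervalSet()
        assert repeat_content(GenomicInterval("x", 0, 100), soft) == expected


def brute_force_cpg_islands(seq, window=100, min_length=200, min_gc=0.5, min_oe=0.6):
    """Naive re-implementation of the windowed island definition:
    every window scored from scratch by direct counting."""
    seq = seq.upper()
    n = len(seq)
    covered = np.zeros(n, dtype=bool)
    for i in range(n - window + 1):
        win = seq[i : i + window]
        if "N" in win:
            continue
        c, g = win.count("C"), win.count("G")
        if c + g <= min_gc * window:
            continue
        cpg = win.count("CG")
        if c * g == 0 or cpg * window <= min_oe * c * g:
            continue
        covered[i : i + window] = True
    out = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            sub = seq[i:j]
            c, g = sub.count("C"), sub.count("G")
            cpg = sub.count("CG")
            if (
                j - i >= min_length
                and c + g > min_gc * (j - i)
                and c * g > 0
                and cpg * (j - i) > min_oe * c * g
            ):
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


class TestCpGIslands:
    def test_cg_tandem_repeat_single_island(self):
        got = detect_cpg_islands("CG" * 150)
        assert [(iv.start, iv.end) for iv in got] == [(0, 300)]

    def test_below_minimum_length(self):
        seq = "AT" * 200 + "G" * 100 + "C" * 99 + "AT" * 200
        # a 199-bp all-G/C run in an AT background stays below the
        # 200-bp minimum (and its single G|C junction cannot carry O/E)
        assert not detect_cpg_islands(seq)
        assert detect_cpg_islands(seq) == IntervalSet()
        got = brute_force_cpg_islands(seq)
        assert got == []

    def test_poly_a_empty(self):
        assert not detect_cpg_islands("A" * 500)

    def test_gc_exactly_half_not_island(self):
        # strict inequality: a window at exactly 50% GC never qualifies
        seq = "CGAT" * 100  # GC exactly 0.5 everywhere, O/E high
        assert not detect_cpg_islands(seq)

    def test_window_with_n_never_qualifies(self):
        core = "CG" * 150
        seq = core[:140] + "N" + core[141:]
        got = detect_cpg_islands(seq)
        # the island may split or shrink, but no kept region contains N
        for iv in got:
            assert "N" not in seq[iv.start : iv.end]

    def test_matches_brute_force_on_mixed_sequences(self, small_bundle):
        rng = np.random.default_rng(77)
        asm = small_bundle.truth.assembly
        chrom = asm.sequences["chr1"]
        for _ in range(12):
            start = int(rng.integers(0, len(chrom) - 5000))
            seq = chrom[start : start + 5000]
            got = [(iv.start, iv.end) for iv in detect_cpg_islands(seq)]
            assert got == brute_force_cpg_islands(seq)


class TestWindowSummary:
    def test_tiling_with_final_short_window(self, small_bundle):
        asm = Assembly("a", {"x": "ACGT" * 6250 + "A" * 5000})  # 30 kbp
        table, _ = window_summary(asm, IntervalSet(), IntervalSet())
        assert list(zip(table.start, table.end)) == [(0, 10_000), (10_000, 20_000), (20_000, 25_000 + 5_000)]

    def test_no_missing_comparison_skipped(self):
        asm = Assembly("a", {"x": "ACGT" * 5000})
        table, stats = window_summary(asm, IntervalSet(), IntervalSet())
        assert (table.missing_frac == 0).all()
        assert "gc" not in stats

    def test_invariant_to_interval_fragmentation(self):
        asm = Assembly("a", {"x": "ACGT" * 10_000})
        merged = IntervalSet({"x": np.array([[1000, 5000]])})
        split = IntervalSet({"x": np.array([[1000, 2500], [2500, 5000]])})
        t1, _ = window_summary(asm, merged, IntervalSet())
        t2, _ = window_summary(asm, split, IntervalSet())
        assert np.allclose(t1.missing_frac, t2.missing_frac)

    def test_concat_mode_pools_bases(self):
        asm = Assembly("a", {"x": "G" * 15_000 + "A" * 25_000})
        missing = IntervalSet({"x": np.array([[0, 15_000]])})
        table, stats = window_summary(asm, missing, IntervalSet(), mode="concat")
        miss = table[table.klass == "missing"]
        assert miss.gc.mean() == 1.0
        assert stats["gc"]["missing_mean"] > stats["gc"]["present_mean"]


class TestPartitionRates:
    def test_everything_missing(self):
        lengths = {"x": 1000}
        cgi = IntervalSet({"x": np.array([[0, 100]])})
        rep = IntervalSet({"x": np.array([[200, 300]])})
        rates = partition_missing_rates(IntervalSet.whole(lengths), cgi, rep, lengths)
        assert rates == {"cgi_rate": 1.0, "repeat_rate": 1.0, "control_rate": 1.0}

    def test_missing_equals_cgi(self):
        lengths = {"x": 1000}
        cgi = IntervalSet({"x": np.array([[0, 100]])})
        rep = IntervalSet({"x": np.array([[200, 300]])})
        rates = partition_missing_rates(cgi, cgi, rep, lengths)
        assert rates["cgi_rate"] == 1.0 and rates["control_rate"] == 0.0


class TestGeneDensity:
    def _genes(self, spans):
        out = []
        for i, (s, e) in enumerate(spans):
            g = GeneModel(id=f"g{i}", sequence="x", strand="+")
            g.transcripts["t"] = TranscriptModel(
                id=f"g{i}.t", gene_id=g.id, sequence="x", strand="+", exons=[(s, e)]
            )
            out.append(g)
        return GeneSet(out)

    def test_density_per_mb(self):
        genes = self._genes([(0, 100), (5_000, 5_100), (100_000, 100_100)])
        table, _ = gene_density(genes, {"x": 200_000})
        assert table.n_genes.iloc[0] == 3
        assert table.genes_per_mb.iloc[0] == pytest.approx(15.0)

    def test_no_genes_zero(self):
        table, summary = gene_density(self._genes([]), {"x": 400_000})
        assert (table.n_genes == 0).all() and (summary.n_genes == 0).all()

    def test_spanning_gene_counted_in_both_windows(self):
        genes = self._genes([(199_900, 200_100)])
        table, _ = gene_density(genes, {"x": 400_000})
        assert table.n_genes.tolist() == [1, 1]
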