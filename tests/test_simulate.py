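"""Simulator invariants: determinism, conservation, dropout structure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from falseloss.content import gc_fraction_of_string
from falseloss.genewise import nearest_upstream_cgi
from falseloss.content import detect_cpg_islands_assembly
from falseloss.simulate import (
    EVENT_TYPES,
    SimulationConfig,
    TruthLedger,
    degrade,
    generate_truth,
    simulate_bundle,
    simulate_pileup,
)
from tests.conftest import small_config


class TestDeterminism:
    def test_same_seed_identical_truth(self):
        cfg = small_config(seed=21)
        a = generate_truth(cfg)
        b = generate_truth(cfg)
        assert a.assembly.sequences == b.assembly.sequences
        assert a.softmask == b.softmask and a.cgi_truth == b.cgi_truth

    def test_same_seed_identical_bundle(self):
        cfg = small_config(seed=22, sequence_length=200_000, n_genes=15,
                          n_noncoding_genes=2, n_repeat_copies=15,
                          het_site_count=10, n_base_errors=10, events_per_type=1)
        b1 = simulate_bundle(cfg)
        b2 = simulate_bundle(cfg)
        assert b1.degraded.sequences == b2.degraded.sequences
        assert b1.ledger.to_frame().equals(b2.ledger.to_frame())
        for name in b1.reference_pileup.lengths:
            assert np.array_equal(b1.reference_pileup.depth[name], b2.reference_pileup.depth[name])


class TestTruthStructure:
    def test_cgi_fraction_binomial(self):
        cfg = small_config(
            seed=31, n_sequences=4, sequence_length=1_000_000, n_genes=200,
            n_noncoding_genes=0, n_repeat_copies=60,
            fraction_with_upstream_cgi=0.8,
        )
        truth = generate_truth(cfg)
        cgis = detect_cpg_islands_assembly(truth.assembly)
        n = sum(
            1 for g in truth.genes.coding()
            if (d := nearest_upstream_cgi(g, cgis)) is not None and d <= 3000
        )
        assert abs(n - 160) <= 13  # binomial 2 sigma around 0.8 * 200

    def test_zero_cgi_fraction_none_upstream(self):
        cfg = small_config(seed=32, fraction_with_upstream_cgi=0.0, n_genes=25)
        truth = generate_truth(cfg)
        cgis = detect_cpg_islands_assembly(truth.assembly)
        n = sum(
            1 for g in truth.genes.coding()
            if (d := nearest_upstream_cgi(g, cgis)) is not None and d <= 3000
        )
        assert n <= 2  # allow rare chance islands in depleted background

    def test_infeasible_packing_reports_requirement(self):
        cfg = small_config(seed=33, sequence_length=50_000, n_genes=40)
        with pytest.raises(ValueError, match="sequence_length >="):
            generate_truth(cfg)

    def test_promoter_gc_exceeds_background(self):
        truth = generate_truth(small_config(seed=34))
        gc = np.mean([gc_fraction_of_string(s) for s in truth.assembly.sequences.values()])
        prom_gc = []
        for iv in truth.cgi_truth:
            prom_gc.append(gc_fraction_of_string(
                truth.assembly.fetch(iv.sequence, iv.start, iv.end)))
        assert np.mean(prom_gc) > gc + 0.2


class TestDegrade:
    def test_disabled_degradation_identity(self, null_config):
        truth = generate_truth(null_config)
        degraded, ledger, chains = degrade(truth, null_config)
        assert degraded.sequences == truth.assembly.sequences
        assert ledger.events == []
        for chain in chains:
            assert chain.aligned_length == truth.assembly.lengths[chain.query]

    def test_event_bookkeeping_exact_counts(self, small_bundle):
        counts = {t: 0 for t in EVENT_TYPES}
        for e in small_bundle.ledger.gene_level():
            counts[e.type] += 1
        assert counts == small_bundle.config.event_counts

    def test_deletion_conservation(self):
        cfg = small_config(
            seed=41, events_per_type=0, n_gap_fraction=0.0,
            repeat_break_fraction=0.0, het_site_count=0, n_base_errors=0,
        )
        truth = generate_truth(cfg)
        degraded, ledger, _ = degrade(truth, cfg)
        deleted = ledger.missing_truth_regions().total_length
        assert truth.assembly.total_length == degraded.total_length + deleted

    def test_dropout_correlates_with_tile_gc(self):
        cfg = small_config(seed=42, events_per_type=0, het_site_count=0,
                          n_base_errors=0, repeat_break_fraction=0.0,
                          n_sequences=4, sequence_length=1_250_000, n_genes=75)
        truth = generate_truth(cfg)
        _, ledger, _ = degrade(truth, cfg)
        dropped = ledger.missing_truth_regions()
        tile = cfg.dropout_tile
        gcs, flags = [], []
        for name, seq in truth.assembly.sequences.items():
            view = truth.assembly.byte_view(name)
            n_tiles = len(view) // tile
            arr = view[: n_tiles * tile].reshape(n_tiles, tile)
            gc = ((arr == ord("G")) | (arr == ord("C"))).mean(axis=1)
            mask = dropped.mask(name, len(view))
            hit = mask[: n_tiles * tile].reshape(n_tiles, tile).any(axis=1)
            gcs.append(gc)
            flags.append(hit)
        rho, p = spearmanr(np.concatenate(gcs), np.concatenate(flags))
        assert rho > 0 and p < 0.01

    def test_steeper_dropout_hits_cgi_harder_than_background(self):
        base = dict(events_per_type=0, het_site_count=0, n_base_errors=0,
                    repeat_break_fraction=0.0)
        lo = small_config(seed=43, dropout_steepness=6.0, **base)
        hi = small_config(seed=43, dropout_steepness=18.0, **base)
        truth = generate_truth(lo)

        def rates(cfg):
            _, ledger, _ = degrade(truth, cfg)
            miss = ledger.missing_truth_regions()
            cgi = truth.cgi_truth
            cgi_rate = cgi.intersect(miss).total_length / cgi.total_length
            lengths = truth.assembly.lengths
            from falseloss.intervals import IntervalSet

            bg = IntervalSet.whole(lengths).subtract(cgi)
            bg_rate = bg.intersect(miss).total_length / bg.total_length
            return cgi_rate, bg_rate

        cgi_lo, bg_lo = rates(lo)
        cgi_hi, bg_hi = rates(hi)
        assert cgi_hi - cgi_lo > bg_hi - bg_lo

    def test_every_event_locus_valid_on_both_assemblies(self, small_bundle):
        b = small_bundle
        for e in b.ledger.events:
            L = b.truth.assembly.lengths[e.ref_sequence]
            assert 0 <= e.ref_start <= e.ref_end <= L
            if e.prior_sequence:
                Lp = b.degraded.lengths[e.prior_sequence]
                assert 0 <= e.prior_start <= e.prior_end <= Lp


class TestPileups:
    def test_mean_depth_within_ten_percent(self, small_bundle):
        pu = small_bundle.reference_pileup
        depths = np.concatenate([pu.depth[n] for n in pu.lengths])
        assert 27 <= depths.mean() <= 33

    def test_error_free_reads_mismatch_only_at_het_sites(self):
        from falseloss.assembly import Assembly

        rng = np.random.default_rng(0)
        asm = Assembly("a", {"x": "ACGT" * 5000})
        pu = simulate_pileup(asm, 30, 150, 0.0, rng, het_sites={"x": [100, 200]})
        mm = pu.mismatch["x"].copy()
        assert mm[100] > 0 and mm[200] > 0
        mm[[100, 200]] = 0
        assert (mm == 0).all()

    def test_read_length_longer_than_sequence_rejected(self):
        from falseloss.assembly import Assembly

        asm = Assembly("a", {"x": "ACGT" * 10})
        with pytest.raises(ValueError):
            simulate_pileup(asm, 30, 100, 0.0, np.random.default_rng(0))

    def test_no_reads_on_gap_runs(self, small_bundle):
        pu = small_bundle.prior_pileup
        gaps = small_bundle.degraded.gap_runs()
        for iv in list(gaps)[:20]:
            assert (pu.depth[iv.sequence][iv.start : iv.end] == 0).all()


class TestLedgerIO:
    def test_tsv_round_trip(self, small_bundle, tmp_path):
        b = small_bundle
        b.ledger.write_tsv(tmp_path / "ledger.tsv")
        back = TruthLedger.read_tsv(tmp_path / "ledger.tsv")
        assert back.to_frame().equals(b.ledger.to_frame())
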