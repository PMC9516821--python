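"""End-to-end pipeline: simulate (or ingest) -> missing regions ->
content metrics -> gene missingness -> false variants -> false-gene-loss
classification -> report.

Every stage consumes only declared inputs or earlier stage outputs; a
run manifest records the seed, a config hash, and per-stage row counts
so that identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .chain import read_paf, write_paf
from .classify import classify_assembly, summarize
from .content import (
    detect_cpg_islands_assembly,
    gene_density,
    partition_missing_rates,
    window_summary,
)
from .evaluate import match_records, per_type_metrics
from .genewise import (
    classify_feature_missingness,
    cumulative_missing_distribution,
    exon_hits_from_chains,
    genomic_category_missing,
    metagene_profile,
    missing_support,
)
from .intervals import IntervalSet
from .missing import conservative_missing, exclude_false_duplications, unaligned_regions
from .simulate import SimulationBundle, SimulationConfig, simulate_bundle, write_bundle
from .variants import filter_false_variants, variant_block_frequency, variants_from_chains

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    bundle: SimulationBundle
    missing: IntervalSet
    window_table: pd.DataFrame
    window_stats: Dict
    concat_stats: Dict
    cgi_detected: IntervalSet
    partition_rates: Dict[str, float]
    gene_density_summary: pd.DataFrame
    gene_missingness: Dict[str, object]
    category_rates: Dict[str, float]
    profile_blocks: pd.DataFrame
    profile_body: pd.DataFrame
    ecdf: pd.DataFrame
    ecdf_lt10: float
    support: Dict[str, float]
    false_variants: List
    variant_blocks: pd.DataFrame
    variant_body: pd.DataFrame
    records: List
    report: Dict
    ledger_metrics: Optional[Dict]
    manifest: Dict = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig | Dict,
    outdir: Optional[str | Path] = None,
    duplications: Optional[IntervalSet] = None,
    exclude_genes: Optional[List[str]] = None,
    write_pileups: bool = False,
) -> PipelineResult:
    """Run every stage on a simulated bundle and, optionally, write all
    stage outputs plus a manifest under ``outdir``."""
    if isinstance(config, dict):
        cfg = SimulationConfig(**config)
    else:
        cfg = config
    timers: Dict[str, float] = {}
    counts: Dict[str, int] = {}

    t0 = time.time()
    bundle = simulate_bundle(cfg)
    timers["simulate"] = time.time() - t0
    truth = bundle.truth
    lengths = truth.assembly.lengths
    genes = truth.genes
    if exclude_genes:
        genes = genes.exclude(exclude_genes)

    # --- missing regions: two aligner dialects, conservative intersection
    t0 = time.time()
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_bundle(bundle, out / "bundle", pileups=write_pileups)
        chains_a = read_paf(out / "bundle" / "chains_cigar.paf")
        chains_b = read_paf(out / "bundle" / "chains_blocks.paf")
    else:
        chains_a = chains_b = bundle.chains
    una_a = unaligned_regions(lengths, chains_a, side="query")
    una_b = unaligned_regions(lengths, chains_b, side="query")
    missing = conservative_missing(una_a, una_b)
    if duplications is not None:
        missing = exclude_false_duplications(missing, duplications)
    timers["missing"] = time.time() - t0
    counts["missing_intervals"] = len(missing)

    # --- content metrics
    t0 = time.time()
    window_table, window_stats = window_summary(
        truth.assembly, missing, truth.softmask, mode="window"
    )
    _, concat_stats = window_summary(
        truth.assembly, missing, truth.softmask, mode="concat"
    )
    cgi_detected = detect_cpg_islands_assembly(truth.assembly)
    partition = partition_missing_rates(missing, cgi_detected, truth.softmask, lengths)
    _, density_summary = gene_density(genes, lengths)
    timers["content"] = time.time() - t0
    counts["cgi_detected"] = len(cgi_detected)

    # --- gene missingness
    t0 = time.time()
    hits = exon_hits_from_chains(genes, bundle.chains)
    per_gene = {
        g.id: classify_feature_missingness(g, missing, hits) for g in genes.coding()
    }
    category = genomic_category_missing(genes, missing, lengths)
    blocks, body = metagene_profile(genes, missing, truth.assembly, cgi_detected)
    ecdf, lt10 = cumulative_missing_distribution(
        {gid: gm.missing_percent for gid, gm in per_gene.items()}
    )
    support = missing_support(
        missing, bundle.prior_read_depth_on_ref, bundle.degraded.gap_runs(), bundle.chains
    )
    timers["genewise"] = time.time() - t0
    counts["genes_classified"] = len(per_gene)

    # --- false variants
    t0 = time.time()
    raw_variants = variants_from_chains(truth.assembly, bundle.degraded, bundle.chains)
    false_vars, _homopoly = filter_false_variants(
        raw_variants, reference_pileup=bundle.reference_pileup, reference=truth.assembly
    )
    var_blocks, var_body = variant_block_frequency(genes, false_vars, truth.assembly)
    timers["variants"] = time.time() - t0
    counts["false_variants"] = len(false_vars)

    # --- classification
    t0 = time.time()
    records = classify_assembly(
        truth.assembly, bundle.degraded, genes, bundle.chains,
        prior_pileup=bundle.prior_pileup, exon_hits=hits,
    )
    report = summarize(records, genes)
    metrics = per_type_metrics(match_records(records, bundle.ledger))
    timers["classify"] = time.time() - t0
    counts["false_loss_records"] = len(records)

    manifest = {
        "falseloss_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        "timers_s": {k: round(v, 3) for k, v in timers.items()},
        "row_counts": counts,
    }
    result = PipelineResult(
        bundle=bundle,
        missing=missing,
        window_table=window_table,
        window_stats=window_stats,
        concat_stats=concat_stats,
        cgi_detected=cgi_detected,
        partition_rates=partition,
        gene_density_summary=density_summary,
        gene_missingness=per_gene,
        category_rates=category,
        profile_blocks=blocks,
        profile_body=body,
        ecdf=ecdf,
        ecdf_lt10=lt10,
        support=support,
        false_variants=false_vars,
        variant_blocks=var_blocks,
        variant_body=var_body,
        records=records,
        report=report,
        ledger_metrics=metrics,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.missing.write_bed(out / "missing.bed")
    result.cgi_detected.write_bed(out / "cgi_detected.bed")
    result.window_table.to_csv(out / "windows.tsv", sep="\t", index=False)
    result.profile_blocks.to_csv(out / "metagene_blocks.tsv", sep="\t", index=False)
    result.profile_body.to_csv(out / "metagene_body.tsv", sep="\t", index=False)
    result.ecdf.to_csv(out / "gene_missing_ecdf.tsv", sep="\t", index=False)
    result.variant_blocks.to_csv(out / "variant_blocks.tsv", sep="\t", index=False)
    result.variant_body.to_csv(out / "variant_body.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "type": r.type,
                "ref_sequence": r.ref_sequence,
                "ref_start": r.ref_start,
                "ref_end": r.ref_end,
                "prior_sequence": r.prior_sequence,
                "prior_start": r.prior_start,
                "prior_end": r.prior_end,
                "verdict": r.verdict,
            }
            for r in result.records
        ]
    ).to_csv(out / "false_loss_records.tsv", sep="\t", index=False)
    per_gene_rows = [
        {
            "gene_id": gm.gene_id,
            "status": gm.status,
            "missing_percent": gm.missing_percent,
        }
        for gm in result.gene_missingness.values()
    ]
    pd.DataFrame(per_gene_rows).to_csv(out / "gene_missingness.tsv", sep="\t", index=False)
    stats = {
        "window_stats": result.window_stats,
        "concat_stats": result.concat_stats,
        "partition_rates": result.partition_rates,
        "category_rates": result.category_rates,
        "ecdf_fraction_lt10pct": result.ecdf_lt10,
        "missing_support": result.support,
        "report": result.report,
        "ledger_metrics": result.ledger_metrics,
    }
    (out / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True, default=float))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True)
    )
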