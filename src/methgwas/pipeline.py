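"""End-to-end pipeline: simulate -> segment (HMR/PMD) -> tile testing ->
GWAS / GO enrichment -> integration, with a checksum manifest.

Every stage communicates through the declared file formats in the output
directory, so any stage can be re-run or replaced from files. The run is
deterministic given the config seed; the manifest records a sha256 per
output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import hmr as hmr_mod
from . import pmd as pmd_mod
from .core import GenomeLayout, GenomicInterval, IntervalSet, ValidationError, merge_intervals
from .gwas_enrichment import enrichment_panel
from .integration import candidate_gene_table, global_methylation_test, overlap_fisher
from .io import (
    write_bed,
    write_cpg_calls,
    write_genes_bed,
    write_go_map,
    write_gwas_stats,
    write_layout,
)
from .set_enrichment import count_based_test, map_windows_to_terms
from .simulate import (
    PlantedDmrTile,
    PlantedPmd,
    PlantedRegion,
    SimulationDesign,
    default_layout,
    simulate_gene_annotation,
    simulate_gwas,
    simulate_methylomes,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Plain-data pipeline configuration (YAML-loadable)."""

    out_dir: Path
    seed: int = 0
    n_chroms: int = 2
    chrom_bp: int = 2_000_000
    n_samples_per_group: int = 3
    coverage_mean: float = 10.0
    n_hmrs: int = 8
    hmr_bp: int = 1_500
    n_pmds: int = 2
    pmd_bp: int = 100_000
    n_dmr_tiles: int = 40
    dmr_delta: float = 0.30
    n_variants: int = 20_000
    gwas_delta: float = 2.0
    n_genes: int = 120
    n_terms: int = 12
    genes_per_term: int = 12
    n_perm: int = 2_000
    q_cutoff: float = 0.01
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        if "out_dir" not in kwargs:
            raise ValidationError("config must set out_dir")
        kwargs["out_dir"] = Path(kwargs["out_dir"])
        return cls(**kwargs, extra=extra)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_design(cfg: PipelineConfig, layout: GenomeLayout) -> SimulationDesign:
    """Plant HMRs, PMDs and DMR tiles on a regular non-overlapping grid."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 901]))
    hmrs, pmds, dmrs = [], [], []
    chroms = layout.chrom_names
    # deterministic placement: features rotate over chromosomes, spaced out
    for i in range(cfg.n_hmrs):
        chrom = chroms[i % len(chroms)]
        start = 50_000 + (i // len(chroms)) * 120_000
        hmrs.append(PlantedRegion(GenomicInterval(chrom, start, start + cfg.hmr_bp), 0.05))
    sample_ids = None
    for i in range(cfg.n_pmds):
        chrom = chroms[i % len(chroms)]
        start = 1_200_000 + (i // len(chroms)) * 200_000
        pmds.append(PlantedPmd(GenomicInterval(chrom, start, start + cfg.pmd_bp), 0.40))
    base = 0.45
    for i in range(cfg.n_dmr_tiles):
        chrom = chroms[i % len(chroms)]
        start = 600_000 + (i // len(chroms)) * 2_000
        sign = 1 if (i % 2 == 0) else -1
        lv1 = base + (cfg.dmr_delta if sign > 0 else 0.0)
        lv2 = base + (0.0 if sign > 0 else cfg.dmr_delta)
        dmrs.append(
            PlantedDmrTile(GenomicInterval(chrom, start, start + 500), lv1, lv2)
        )
    return SimulationDesign(
        layout=layout,
        coverage_mean=cfg.coverage_mean,
        planted_hmrs=hmrs,
        planted_pmds=pmds,
        planted_dmr_tiles=dmrs,
        n_samples_per_group=cfg.n_samples_per_group,
        group_names=("aged", "young"),
        seed=int(np.random.SeedSequence([cfg.seed, 11]).generate_state(1)[0] % (2**31)),
    )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run the full synthetic pipeline; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": cfg.seed, "outputs": {}, "counts": {}}

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    layout = default_layout(cfg.n_chroms, cfg.chrom_bp)
    write_layout(layout, out / "layout.tsv")
    record("layout", out / "layout.tsv")

    # --- simulate ---
    design = _default_design(cfg, layout)
    samples, truth = simulate_methylomes(design)
    for s in samples:
        p = out / f"calls_{s.sample_id}.tsv"
        write_cpg_calls(s, p)
        record(f"calls_{s.sample_id}", p)
    manifest["counts"]["n_samples"] = len(samples)

    enriched = merge_intervals(
        (t.interval for t in truth.dmr_tiles), layout=layout
    )
    gwas_seed = int(np.random.SeedSequence([cfg.seed, 23]).generate_state(1)[0] % (2**31))
    gwas, _ = simulate_gwas(
        layout, cfg.n_variants, enriched, delta=cfg.gwas_delta, seed=gwas_seed,
        trait="fertility",
    )
    write_gwas_stats(gwas, out / "gwas.tsv")
    record("gwas", out / "gwas.tsv")

    ann_seed = int(np.random.SeedSequence([cfg.seed, 37]).generate_state(1)[0] % (2**31))
    genes, go_map = simulate_gene_annotation(
        layout, cfg.n_genes, cfg.n_terms, cfg.genes_per_term, seed=ann_seed
    )
    write_genes_bed(genes, out / "genes.bed")
    write_go_map(go_map, out / "go_map.tsv")
    record("genes", out / "genes.bed")
    record("go_map", out / "go_map.tsv")

    truth_payload = {
        "hmrs": [[iv.chrom, iv.start, iv.end] for iv in truth.hmr_intervals],
        "pmds": [[iv.chrom, iv.start, iv.end] for iv in truth.pmd_intervals],
        "dmr_tiles": [
            [t.interval.chrom, t.interval.start, t.interval.end, t.true_diff]
            for t in truth.dmr_tiles
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    record("truth", out / "truth.json")

    group1 = [s for s in samples if s.age_group == "aged"]
    group2 = [s for s in samples if s.age_group == "young"]

    # --- HMR per group ---
    hmr_counts = {}
    hmr_sets = {}
    for name, grp in (("aged", group1), ("young", group2)):
        pooled = hmr_mod.pool_group(grp)
        records = hmr_mod.detect_hmrs(pooled)
        ivs = [r.interval for r in records]
        p = out / f"hmr_{name}.bed"
        write_bed(
            merge_intervals(ivs, layout=layout),
            p,
            names=[f"HMR_{i}" for i in range(len(ivs))],
            scores=[1000 * r.mean_level for r in records],
        )
        record(f"hmr_{name}", p)
        hmr_counts[name] = len(records)
        hmr_sets[name] = merge_intervals(ivs, layout=layout)
    manifest["counts"]["hmrs"] = hmr_counts

    # --- PMD per sample + consensus ---
    per_sample_pmds = []
    for s in samples:
        ivs = pmd_mod.detect_sample_pmds(s)
        per_sample_pmds.append(ivs)
        p = out / f"pmd_{s.sample_id}.bed"
        write_bed(ivs, p)
        record(f"pmd_{s.sample_id}", p)
    consensus = pmd_mod.consensus_pmds(per_sample_pmds)
    write_bed(consensus, out / "pmd_consensus.bed")
    record("pmd_consensus", out / "pmd_consensus.bed")
    manifest["counts"]["consensus_pmds"] = len(consensus)

    # --- DMR testing (age contrast on the synthetic groups) ---
    table = dmr_mod.build_tiles(samples, layout)
    results = dmr_mod.test_tiles(
        table, [s.sample_id for s in group1], [s.sample_id for s in group2]
    )
    results.to_csv(out / "dmr_results.tsv", sep="\t", index=False)
    record("dmr_results", out / "dmr_results.tsv")
    calls = dmr_mod.call_dmrs(results, q_cutoff=cfg.q_cutoff)
    feature_sets = {}
    for kind, df in calls.items():
        ivs = merge_intervals(dmr_mod.results_to_intervals(df), layout=layout)
        p = out / f"dmr_{kind}.bed"
        write_bed(ivs, p)
        record(f"dmr_{kind}", p)
        if len(ivs):
            feature_sets[kind] = ivs
    manifest["counts"]["dmrs"] = {k: int(len(v)) for k, v in calls.items()}

    # --- GWAS enrichment panel ---
    perm_seed = int(np.random.SeedSequence([cfg.seed, 53]).generate_state(1)[0] % (2**31))
    panel = enrichment_panel(
        {"fertility": gwas}, feature_sets, n_perm=cfg.n_perm, seed=perm_seed
    )
    panel.to_csv(out / "gwas_enrichment.tsv", sep="\t", index=False)
    record("gwas_enrichment", out / "gwas_enrichment.tsv")

    # --- GO window-set enrichment ---
    term_windows = map_windows_to_terms(results, genes, go_map, layout=layout)
    go_res = count_based_test(results["p"], term_windows)
    go_res.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
    record("go_enrichment", out / "go_enrichment.tsv")

    # --- integration ---
    t_stat, t_p, mean_diff = global_methylation_test(group1, group2)
    fold_rows = []
    for name, ivs in hmr_sets.items():
        if len(ivs) == 0:
            continue
        from .integration import element_fold_enrichment

        fold_rows.append(
            {
                "feature": f"hmr_{name}",
                "element": "planted_hmrs",
                "fold": element_fold_enrichment(
                    ivs, truth.hmr_intervals, layout.total_bp
                ),
            }
        )
    pd.DataFrame(fold_rows).to_csv(out / "fold_enrichment.tsv", sep="\t", index=False)
    record("fold_enrichment", out / "fold_enrichment.tsv")

    summary = {
        "global_t": t_stat,
        "global_p": t_p,
        "global_mean_diff": mean_diff,
    }
    (out / "integration.json").write_text(json.dumps(summary, indent=1))
    record("integration", out / "integration.json")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d outputs", len(manifest["outputs"]))
    return manifest
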