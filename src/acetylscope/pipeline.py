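"""End-to-end orchestration: simulate -> quantify -> DE -> integrate.

A flat YAML config (key: value) drives the run; one global seed is fanned
out to per-stage streams by fixed offsets so every stage is individually
reproducible. The run emits TSV/BED/JSON artifacts under the output
directory and returns a machine-readable report.
"""
from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .expression import called_genes, differential_expression, global_normalize, zscore_expression
from .integration import (
    bin_genes,
    bin_regression,
    binding_fold_change,
    classify_concordance,
    concordance_counts,
    de_set_overlap,
    fixture_concordance,
)
from .models import GROUPS
from .simulate import EffectConfig, GenomeSpec, TagSimParams, simulate_annotation, simulate_expression, simulate_tag_library
from .tags import call_binding_sites, normalize_factor, normalized_counts, overlap_partition, sites_to_genes, tss_profile

logger = logging.getLogger("acetylscope")

# fixed per-stage seed offsets (all derived seeds stay below 2**31)
_STAGE_OFFSETS = {
    "annotation": 11,
    "expression": 23,
    "tags_SS": 101, "tags_SM": 103, "tags_MS": 107, "tags_MM": 109,
    "input_SS": 201, "input_SM": 203, "input_MS": 207, "input_MM": 209,
}


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All knobs of a simulated end-to-end run, with documented defaults."""

    # genome / annotation
    n_chroms: int = 4
    chrom_length: int = 2_500_000
    n_genes: int = 1000
    min_gene_spacing: int = 8000
    # expression design
    n_replicates: int = 5
    frac_up_sm: float = 0.06
    frac_down_sm: float = 0.026
    frac_up_mm: float = 0.018
    frac_down_mm: float = 0.053
    effect_fold: float = 4.0
    blunting_factor: float = 0.5
    noise_sd_log2: float = 0.25
    # tag simulation
    library_size: int = 100_000
    background_fraction: float = 0.2
    enrichment_sd: float = 300.0
    expression_coupling_slope: float = 1.0
    fragment_length: int = 450
    # quantification / calling thresholds
    promoter_halfwidth: int = 2000
    flank: int = 2000
    binwidth: int = 100
    window: int = 500
    step: int = 250
    alpha: float = 1e-5
    min_fold: float = 2.0
    site_max_distance: int = 10_000
    fc_cut: float = 1.7
    p_cut: float = 0.01
    bin_size: int = 100
    nc_threshold: float = 1.4
    pseudocount: float = 0.5
    # run control
    seed: int = 0
    outdir: str = "acetylscope_run"

    def __post_init__(self) -> None:
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")
        if not 0 < self.p_cut <= 1:
            raise ValueError("p_cut must lie in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.nc_threshold < 1:
            raise ValueError("nc_threshold must be >= 1")
        if self.window < self.step:
            raise ValueError("window must be >= step")
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be positive")
        if not 300 <= self.fragment_length <= 600:
            raise ValueError("fragment_length must lie in the sheared range 300-600 bp")

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded)."""
        fields_dict = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields_dict, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a flat YAML config, fill defaults, and reject unknown keys
    (suggesting the closest known key) or out-of-domain values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key: value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"{path}: unknown config key {key!r}{suffix}")
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> quantify -> DE -> integrate and return the report.

    Writes annotation (BED6), expression + group map (TSV), per-condition
    DE tables, bins, sites (BED6) and the JSON report under
    ``config.outdir``. Deterministic for a fixed config and seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("thresholds: fc_cut=%s p_cut=%s alpha=%s min_fold=%s window=%s step=%s "
                "bin_size=%s nc_threshold=%s promoter_halfwidth=%s",
                config.fc_cut, config.p_cut, config.alpha, config.min_fold,
                config.window, config.step, config.bin_size, config.nc_threshold,
                config.promoter_halfwidth)

    spec = GenomeSpec(n_chroms=config.n_chroms, chrom_length=config.chrom_length,
                      n_genes=config.n_genes, min_gene_spacing=config.min_gene_spacing,
                      seed=stage_seed(config.seed, "annotation"))
    annotation = simulate_annotation(spec)
    io.write_annotation_bed(annotation, out / "annotation.bed")
    logger.info("simulated %d genes on %d chromosomes", len(annotation), config.n_chroms)

    cfg = EffectConfig(
        n_replicates_per_group=config.n_replicates,
        frac_up_SM=config.frac_up_sm, frac_down_SM=config.frac_down_sm,
        frac_up_MM=config.frac_up_mm, frac_down_MM=config.frac_down_mm,
        effect_fold=config.effect_fold, blunting_factor=config.blunting_factor,
        noise_sd_log2=config.noise_sd_log2,
    )
    matrix, truth = simulate_expression(annotation, cfg, seed=stage_seed(config.seed, "expression"))
    matrix = global_normalize(matrix)
    io.write_expression(matrix, out / "expression.tsv", out / "groups.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")

    libraries: dict[str, dict[str, object]] = {}
    for group in GROUPS:
        mean_expr = matrix.group_mean(group)
        ip = simulate_tag_library(
            annotation, mean_expr,
            TagSimParams(library_size=config.library_size,
                         background_fraction=config.background_fraction,
                         enrichment_sd=config.enrichment_sd,
                         expression_coupling_slope=config.expression_coupling_slope,
                         fragment_length=config.fragment_length,
                         seed=stage_seed(config.seed, f"tags_{group}")),
            role="IP", spec=spec, sample_id=f"{group}_IP", condition=group)
        inp = simulate_tag_library(
            annotation, mean_expr,
            TagSimParams(library_size=config.library_size, background_fraction=1.0,
                         enrichment_sd=config.enrichment_sd,
                         fragment_length=config.fragment_length,
                         seed=stage_seed(config.seed, f"input_{group}")),
            role="input", spec=spec, sample_id=f"{group}_input", condition=group)
        libraries[group] = {"IP": ip, "input": inp}
        io.write_tags(ip, out / f"tags_{group}_IP.bed")
        io.write_tags(inp, out / f"tags_{group}_input.bed")

    report: dict = {
        "provenance": {"version": __version__, "seed": config.seed,
                       "config_hash": config.config_hash()},
        "conditions": {},
    }

    norm_by_group: dict[str, pd.Series] = {}
    site_genes: dict[str, set[str]] = {}
    for group in GROUPS:
        ip = libraries[group]["IP"]
        inp = libraries[group]["input"]
        norm = normalized_counts(ip, annotation)
        norm_by_group[group] = norm
        profile = tss_profile(ip, annotation, flank=config.flank, binwidth=config.binwidth)
        sites = call_binding_sites(ip, inp, window=config.window, step=config.step,
                                   alpha=config.alpha, min_fold=config.min_fold,
                                   pseudocount=config.pseudocount)
        genes, per_gene = sites_to_genes(sites, annotation, max_distance=config.site_max_distance)
        site_genes[group] = genes
        io.write_sites_bed(sites, out / f"sites_{group}.bed")
        z = zscore_expression(matrix.group_mean(group))
        bins = bin_genes(z, norm.reindex(z.index).fillna(0.0), bin_size=config.bin_size)
        n_full = sum(not b.partial for b in bins)
        reg = bin_regression(bins, include_partial=n_full < 3)
        pd.DataFrame([asdict(b) for b in bins]).to_csv(out / f"bins_{group}.tsv", sep="\t", index=False)
        report["conditions"][group] = {
            "n_sites": len(sites),
            "n_annotated_genes": len(genes),
            "normalize_factor": normalize_factor(ip),
            "profile_peak_bin_left": int(profile.bin_left[int(np.argmax(profile.density))]),
            "regression": {"slope": reg.slope, "intercept": reg.intercept,
                           "r_squared": reg.r_squared, "n_bins": reg.n_bins},
        }
        logger.info("%s: %d sites over %d genes; regression R^2=%.3f",
                    group, len(sites), len(genes), reg.r_squared)

    binding_venn, binding_pct = overlap_partition(site_genes, reference="SS")
    report["binding_gene_venn"] = binding_venn
    report["binding_pct_vs_SS"] = binding_pct

    contrasts = {"SM_vs_SS": ("SS", "SM"), "MM_vs_MS": ("MS", "MM")}
    de_tables: dict[str, pd.DataFrame] = {}
    report["differential_expression"] = {}
    for name, (a, b) in contrasts.items():
        de = differential_expression(matrix, a, b, fc_cut=config.fc_cut, p_cut=config.p_cut)
        de_tables[name] = de
        io.write_tsv(de, out / f"de_{name}.tsv", index_label="gene_id")
        report["differential_expression"][name] = {
            "n_up": int((de["call"] == "up").sum()),
            "n_down": int((de["call"] == "down").sum()),
        }
    de_venn, _ = de_set_overlap(de_tables)
    report["de_gene_venn"] = de_venn

    bfold = binding_fold_change(
        norm_by_group["SS"], _input_norm(libraries["SS"]["input"], annotation),
        norm_by_group["SM"], _input_norm(libraries["SM"]["input"], annotation),
        pseudocount=config.pseudocount,
    )
    de_sm = de_tables["SM_vs_SS"]
    detected = site_genes["SS"] | site_genes["SM"]
    records = classify_concordance(de_sm, bfold, detected, nc_threshold=config.nc_threshold)
    table, totals = concordance_counts(records)
    io.write_tsv(table, out / "concordance_SM_vs_SS.tsv", index_label="expr_direction")
    report["concordance_SM_vs_SS"] = {
        "table": {d: {s: int(table.loc[d, s]) for s in table.columns} for d in table.index},
        "both_platform_totals": totals,
    }

    t1_records, t1_table, t1_totals = fixture_concordance("table1", nc_threshold=config.nc_threshold)
    t2_records, t2_table, t2_totals = fixture_concordance("table2", nc_threshold=config.nc_threshold)
    report["fixture_tables"] = {
        "table1": {"up_increased": int(t1_table.loc["up", "increased"]),
                   "up_NC": int(t1_table.loc["up", "NC"]),
                   "down_decreased": int(t1_table.loc["down", "decreased"]),
                   "down_NC": int(t1_table.loc["down", "NC"]),
                   "both_platform": t1_totals},
        "table2": {"up_increased": int(t2_table.loc["up", "increased"]),
                   "up_NC": int(t2_table.loc["up", "NC"]),
                   "down_decreased": int(t2_table.loc["down", "decreased"]),
                   "down_NC": int(t2_table.loc["down", "NC"]),
                   "both_platform": t2_totals},
    }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _input_norm(inp, annotation) -> pd.Series:
    return normalized_counts(inp, annotation)
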