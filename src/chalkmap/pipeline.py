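"""End-to-end orchestration with one configuration and one seed.

Stages: simulate (optional) -> filter -> bin -> map -> scan -> de ->
colocate.  All randomness derives from the single global seed through
numpy SeedSequence spawning, so re-running an identical configuration
reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bin_genotyping, colocalization, differential_expression as de
from . import io as cio
from . import linkage_map, qtl_mapping, synthetic_data, variant_filtering
from .synthetic_data import ChromosomeSpec, ENVIRONMENTS, RNA_SAMPLES, \
    SimConfig

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    out_dir: str = "chalkmap_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "filter", "bin", "map", "scan", "de", "colocate"])
    # simulate
    sim: SimConfig = field(default_factory=SimConfig)
    n_genes: int = 2000
    # inputs when not simulating
    vcf: str | None = None
    phenotypes: str | None = None
    counts: str | None = None
    gff3: str | None = None
    parent1: str = "PYZX"
    parent2: str = "P02428"
    # stage settings
    filter: variant_filtering.FilterConfig = field(
        default_factory=variant_filtering.FilterConfig)
    window: bin_genotyping.WindowConfig = field(
        default_factory=bin_genotyping.WindowConfig)
    scan: qtl_mapping.ScanConfig = field(
        default_factory=qtl_mapping.ScanConfig)
    drop_distorted_bins: bool = True
    dispersion: float = de.DEFAULT_DISPERSION
    environments: list[str] = field(default_factory=lambda: list(ENVIRONMENTS))
    traits: list[str] | None = None
    de_contrasts: list[tuple[str, str]] = field(default_factory=lambda: [
        ("PYZX", "P02428"), ("H-Pool", "L-Pool")])
    coloc_flank_bp: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"]["chromosomes"] = [
            [c.name, c.length_bp, c.length_cm]
            for c in self.sim.chromosomes
        ]
        d["de_contrasts"] = [list(c) for c in self.de_contrasts]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("sim", {})
        chroms = [ChromosomeSpec(str(n), int(b), float(c))
                  for n, b, c in sim.pop("chromosomes", [])]
        cfg = cls(
            **{k: v for k, v in d.items()
               if k not in ("filter", "window", "scan", "de_contrasts")})
        cfg.sim = SimConfig(chromosomes=chroms or synthetic_data
                            .rice_chromosomes(), **sim)
        cfg.filter = variant_filtering.FilterConfig(**d.get("filter", {}))
        cfg.window = bin_genotyping.WindowConfig(**d.get("window", {}))
        cfg.scan = qtl_mapping.ScanConfig(**d.get("scan", {}))
        cfg.de_contrasts = [tuple(c) for c in d.get("de_contrasts",
                                                    cfg.de_contrasts)]
        return cfg


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Schema and cross-field checks; returns human-readable findings."""
    findings: list[str] = []
    if cfg.scan.p_in > cfg.scan.p_out:
        findings.append("stepwise thresholds inverted: p_in > p_out")
    if cfg.window.window_size < cfg.window.mask_max_snps:
        findings.append("warning: window_size < mask_max_snps")
    if not cfg.environments:
        findings.append("environment list is empty")
    if "simulate" not in cfg.stages:
        for stage, path in (("filter", cfg.vcf), ("scan", cfg.phenotypes),
                            ("de", cfg.counts), ("colocate", cfg.gff3)):
            if stage in cfg.stages and (path is None
                                        or not Path(path).exists()):
                findings.append(f"stage {stage}: required input missing "
                                f"({path})")
    try:
        cfg.sim.validate()
        cfg.filter.validate()
        cfg.window.validate()
        cfg.scan.validate()
    except ValueError as exc:
        findings.append(str(exc))
    return findings


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    findings = validate_config(cfg)
    hard = [f for f in findings if not f.startswith("warning")]
    if hard:
        raise ValueError("invalid configuration: " + "; ".join(hard))
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    rngs = {name: np.random.default_rng(s) for name, s in
            zip(("genomes", "gbs", "pheno", "counts", "genes", "misc"),
                seeds)}
    manifest: dict = {"seed": cfg.seed, "stages": {},
                      "schema_version": cfg.schema_version}

    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2), **counts}
        log.info("stage %s done (%.1fs) %s", stage,
                 time.time() - t0, counts)

    genomes = None
    chrom_lengths: dict[str, int] | None = None
    vm = None
    try:
        if "simulate" in cfg.stages:
            t0 = time.time()
            stage = "simulate"
            genomes = synthetic_data.simulate_ril_genomes(
                cfg.sim, rngs["genomes"])
            vm = synthetic_data.simulate_gbs_observations(
                genomes, cfg.sim, rngs["gbs"])
            names = {c.name for c in cfg.sim.chromosomes}
            qtls = [q for q in synthetic_data.example_qtl_specs()
                    if q.chrom in names]
            pheno = synthetic_data.simulate_phenotypes(
                genomes, qtls, cfg.environments, rngs["pheno"],
                trait_means=synthetic_data.trait_baselines())
            genes = synthetic_data.simulate_genes(cfg.sim, cfg.n_genes,
                                                  rngs["genes"])
            windows = [("Chr05", 11_000_000, 14_000_000),
                       ("Chr07", 19_000_000, 23_000_000),
                       ("Chr08", 1_500_000, 4_500_000)]
            windows = [w for w in windows
                       if w[0] in {c.name for c in cfg.sim.chromosomes}]
            degs = synthetic_data.plant_degs(genes, windows, rngs["counts"])
            counts = synthetic_data.simulate_counts(
                degs, list(RNA_SAMPLES), None, rngs["counts"])
            cio.write_vcf(vm, out / "variants.vcf", cfg.parent1, cfg.parent2)
            cio.write_phenotypes_tsv(pheno, out / "phenotypes.tsv")
            cio.write_counts_tsv(counts, out / "counts.tsv")
            cio.write_gff3(genes, out / "genes.gff3")
            synthetic_data.write_truth_json(out / "truth.json", genomes,
                                            qtls, degs)
            chrom_lengths = {c.name: c.length_bp
                             for c in cfg.sim.chromosomes}
            record(stage, t0, sites=vm.n_sites, lines=vm.n_lines)
        else:
            pheno = cio.read_phenotypes_tsv(cfg.phenotypes) \
                if cfg.phenotypes else None
            counts = cio.read_counts_tsv(cfg.counts) if cfg.counts else None
            genes = cio.read_gff3_genes(cfg.gff3) if cfg.gff3 else None

        if "filter" in cfg.stages:
            t0 = time.time()
            stage = "filter"
            if vm is None:
                vm = cio.read_vcf(cfg.vcf, cfg.parent1, cfg.parent2)
            vm = variant_filtering.classify_sites(vm)
            vm, report = variant_filtering.filter_calls(vm, cfg.filter)
            report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
            record(stage, t0, sites=vm.n_sites)

        if "bin" in cfg.stages:
            t0 = time.time()
            stage = "bin"
            bins, segs = bin_genotyping.bin_population(vm, cfg.window,
                                                       chrom_lengths)
            if cfg.drop_distorted_bins:
                bins, dist = variant_filtering.drop_distorted_markers(
                    bins, cfg.filter.distortion_alpha)
                # renumber ids after the drop so they stay genome-ordered
                bins.ids = [f"mk{i + 1}" for i in range(bins.n_markers)]
            bins.write_tsv(out / "bin_markers.tsv")
            cio.write_segments_bed(segs, out / "segments.bed")
            record(stage, t0, markers=bins.n_markers)

        if "map" in cfg.stages:
            t0 = time.time()
            stage = "map"
            gmap = linkage_map.build_map(bins)
            gmap.write_tsv(out / "genetic_map.tsv")
            gmap.summary().to_csv(out / "map_summary.tsv", sep="\t",
                                  index=False)
            record(stage, t0, length_cm=round(gmap.total_length_cm(), 2))

        records = []
        clusters = []
        if "scan" in cfg.stages:
            t0 = time.time()
            stage = "scan"
            if pheno is None:
                raise FileNotFoundError(
                    f"phenotype file not found: {cfg.phenotypes}")
            records, profiles = qtl_mapping.scan_all(
                pheno, bins, gmap, cfg.scan, cfg.traits, cfg.environments)
            records = qtl_mapping.classify_stable(records)
            clusters = qtl_mapping.cluster_qtls(records)
            qtl_mapping.records_to_frame(records).to_csv(
                out / "qtl_records.tsv", sep="\t", index=False)
            qtl_mapping.clusters_to_frame(clusters).to_csv(
                out / "qtl_clusters.tsv", sep="\t", index=False)
            profiles.to_csv(out / "lod_profiles.tsv", sep="\t", index=False)
            record(stage, t0, qtls=len(records), clusters=len(clusters))

        de_results = {}
        if "de" in cfg.stages:
            t0 = time.time()
            stage = "de"
            if counts is None:
                raise FileNotFoundError(f"count file not found: {cfg.counts}")
            for baseline, contrast in cfg.de_contrasts:
                tab = de.de_table(counts, baseline, contrast,
                                  cfg.dispersion)
                tab.to_csv(out / f"de_{contrast}_vs_{baseline}.tsv",
                           sep="\t")
                de_results[(baseline, contrast)] = tab
            record(stage, t0, contrasts=len(de_results))

        if "colocate" in cfg.stages:
            t0 = time.time()
            stage = "colocate"
            if genes is None:
                raise FileNotFoundError(f"annotation not found: {cfg.gff3}")
            intervals = {
                c.cluster_id: colocalization.qtl_physical_interval(c, bins)
                for c in clusters
            }
            key = cfg.de_contrasts[-1] if de_results else None
            coloc = colocalization.colocate(
                genes, intervals,
                de_results.get(key) if key else None,
                flank_bp=cfg.coloc_flank_bp)
            coloc.to_csv(out / "colocalization.tsv", sep="\t", index=False)
            record(stage, t0, records=len(coloc))
    except Exception as exc:  # tag partial outputs, then re-raise
        for f in out.glob("*.tsv"):
            f.rename(f.with_suffix(f.suffix + ".partial"))
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
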