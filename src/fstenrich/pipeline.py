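"""End-to-end orchestration: F_ST scan → regions → enrichment → targets → gene sets.

Each stage writes plain TSV/BED/JSON artifacts into the output directory, so
any stage can be re-run or swapped independently; a manifest records
parameters, row counts and sha256 checksums of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import load_annotation, read_chrom_sizes
from .enrichment import binned_enrichment, classify_variants
from .fst import (DEFAULT_BIN_EDGES, allele_counts_from_vcf, compute_fst,
                  hudson_ratio_of_averages, select_hd)
from .genesets import enrich_collection, jaccard_tree, read_gmt
from .regions import (RegionSet, build_enhancers, build_exons, build_promoters,
                      genome_fraction)
from .targets import (assign_enhancer_targets, build_regulatory_domains,
                      density_filter, promoter_hd_genes)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    vcf: str
    pop1_list: str
    pop2_list: str
    gff: str
    peak_beds: List[str]
    chrom_sizes: str
    out_dir: str
    gmt_files: List[str] = field(default_factory=list)
    estimator: str = "weir_cockerham"
    quantile: float = 0.01
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
    promoter_up: int = 1000
    promoter_down: int = 500
    min_density: float = 1.0 / 500.0
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000
    fdr_threshold: float = 0.01
    max_reported_terms: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> None:
        required = [self.vcf, self.pop1_list, self.pop2_list, self.gff,
                    self.chrom_sizes, *self.peak_beds, *self.gmt_files]
        missing = [p for p in required if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_samples(path) -> List[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute every stage and write the report bundle.

    Returns a dict with the in-memory stage results; files and a manifest are
    written under ``config.out_dir``.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, Path] = {}
    manifest: Dict[str, object] = {
        "tool": "fstenrich", "version": __version__,
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in asdict(config).items()},
    }

    # --- fst stage -----------------------------------------------------
    pop1 = _read_samples(config.pop1_list)
    pop2 = _read_samples(config.pop2_list)
    counts, count_stats = allele_counts_from_vcf(config.vcf, pop1, pop2)
    records, drop_stats = compute_fst(counts, estimator=config.estimator)
    hd = select_hd(records, config.quantile)
    records = records.reset_index(drop=True)
    from .fst import bin_fst
    records["bin"] = bin_fst(records["fst"].to_numpy(), config.bin_edges)
    outputs["fst_tsv"] = out / "fst.tsv"
    records.to_csv(outputs["fst_tsv"], sep="\t", index=False, float_format="%.8g")
    hd_records = records.iloc[hd.index].sort_values(["chrom", "pos"], kind="mergesort")
    outputs["hd_tsv"] = out / "hd_variants.tsv"
    hd_records.to_csv(outputs["hd_tsv"], sep="\t", index=False, float_format="%.8g")
    fst_summary = {
        "estimator": config.estimator, "n_samples_pop1": len(pop1),
        "n_samples_pop2": len(pop2), **count_stats, **drop_stats,
        "n_records": len(records), "quantile": config.quantile,
        "hd_threshold": hd.threshold, "n_hd_nominal": hd.n_nominal,
        "n_hd_selected": hd.n_selected, "hd_ties": hd.has_ties,
        "hudson_ratio_of_averages": hudson_ratio_of_averages(counts),
    }
    outputs["fst_summary"] = out / "fst_summary.json"
    outputs["fst_summary"].write_text(json.dumps(fst_summary, indent=2))

    # --- region stage --------------------------------------------------
    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    annotation = load_annotation(config.gff, chrom_sizes)
    promoters, promoter_windows = build_promoters(
        annotation, config.promoter_up, config.promoter_down)
    exons = build_exons(annotation)
    peak_sets = [RegionSet.from_bed(p, name=Path(p).stem) for p in config.peak_beds]
    enhancers = build_enhancers(peak_sets, promoters)
    region_sets = {"promoter": promoters, "enhancer": enhancers, "exon": exons}
    coverage = {
        name: {"n_intervals": rs.n_intervals(), "bases": rs.total_length(),
               "genome_fraction": genome_fraction(rs, chrom_sizes)}
        for name, rs in region_sets.items()
    }
    coverage["promoter"]["n_windows"] = len(promoter_windows)
    for name, rs in region_sets.items():
        outputs[f"{name}_bed"] = out / f"{name}s.bed"
        rs.to_bed(outputs[f"{name}_bed"])
    outputs["promoter_windows_bed"] = out / "promoter_windows.bed"
    promoter_windows[["chrom", "start", "end", "gene_id", "tss0", "strand"]].to_csv(
        outputs["promoter_windows_bed"], sep="\t", header=False, index=False)
    outputs["coverage_json"] = out / "region_coverage.json"
    outputs["coverage_json"].write_text(json.dumps(coverage, indent=2))

    # --- enrichment stage ----------------------------------------------
    enr = binned_enrichment(records, hd, region_sets, config.bin_edges, chrom_sizes)
    outputs["enrichment_tsv"] = out / "enrichment.tsv"
    enr.to_csv(outputs["enrichment_tsv"], sep="\t", index=False, float_format="%.6g")

    # --- target stage --------------------------------------------------
    dens = density_filter(enhancers, hd_records, config.min_density)
    outputs["filtered_enhancers_bed"] = out / "filtered_enhancers.bed"
    kept = dens[dens["kept"]]
    kept[["chrom", "start", "end", "hd_count"]].to_csv(
        outputs["filtered_enhancers_bed"], sep="\t", header=False, index=False)
    domains = build_regulatory_domains(annotation, config.basal_up,
                                       config.basal_down, config.max_extension)
    edges, enhancer_genes = assign_enhancer_targets(dens, domains)
    outputs["enhancer_gene_edges"] = out / "enhancer_gene_edges.tsv"
    edges.to_csv(outputs["enhancer_gene_edges"], sep="\t", index=False)
    prom_genes, n_hd_promoters = promoter_hd_genes(promoter_windows, hd_records)
    union_genes = sorted(set(enhancer_genes) | set(prom_genes))
    for name, lst in [("enhancer_genes", enhancer_genes),
                      ("promoter_genes", prom_genes),
                      ("target_genes_union", union_genes)]:
        outputs[name] = out / f"{name}.txt"
        outputs[name].write_text("".join(f"{g}\n" for g in lst))
    target_summary = {
        "n_enhancers": int(len(dens)), "n_enhancers_kept": int(dens["kept"].sum()),
        "n_enhancer_genes": len(enhancer_genes),
        "n_promoter_hd_genes": len(prom_genes),
        "n_hd_promoters": n_hd_promoters,
        "n_target_genes_union": len(union_genes),
    }
    outputs["target_summary"] = out / "target_summary.json"
    outputs["target_summary"].write_text(json.dumps(target_summary, indent=2))

    # --- gene-set stage -------------------------------------------------
    geneset_tables = {}
    if config.gmt_files:
        # universe: all annotated genes carrying >= 1 tested variant in any
        # analyzed region (the selection frame of the scan)
        membership = classify_variants(records, region_sets)
        any_region = membership.any(axis=1).to_numpy()
        region_variants = records[any_region]
        universe = set()
        gene_windows = promoter_windows
        pg_all, _ = promoter_hd_genes(gene_windows, region_variants)
        universe |= set(pg_all)
        d_all, _genes_all = assign_enhancer_targets(
            density_filter(enhancers, region_variants, min_density=1e-12), domains)
        universe |= set(_genes_all)
        if not universe:
            universe = set(annotation.transcripts["gene_id"])
        query = set(union_genes) & universe
        for gmt_path in config.gmt_files:
            name = Path(gmt_path).stem
            collection = read_gmt(gmt_path)
            table = enrich_collection(query, collection, universe)
            outputs[f"genesets_{name}"] = out / f"genesets_{name}.tsv"
            table.to_csv(outputs[f"genesets_{name}"], sep="\t", index=False,
                         float_format="%.6g")
            geneset_tables[name] = table
            sig = table[table["q"] <= config.fdr_threshold].head(config.max_reported_terms)
            member_sets = {r.term: set(r.members.split(",")) if r.members else set()
                           for r in sig.itertuples(index=False)}
            nwk = jaccard_tree(member_sets)
            if nwk:
                outputs[f"tree_{name}"] = out / f"genesets_{name}.nwk"
                outputs[f"tree_{name}"].write_text(nwk + "\n")

    manifest["outputs"] = {k: {"path": str(v), "sha256": _sha256(v)}
                           for k, v in outputs.items()}
    manifest["fst_summary"] = fst_summary
    manifest["region_coverage"] = coverage
    manifest["target_summary"] = target_summary
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {"records": records, "hd": hd, "region_sets": region_sets,
            "enrichment": enr, "density": dens, "edges": edges,
            "enhancer_genes": enhancer_genes, "promoter_genes": prom_genes,
            "union_genes": union_genes, "genesets": geneset_tables,
            "fst_summary": fst_summary, "coverage": coverage,
            "target_summary": target_summary, "manifest": manifest,
            "outputs": outputs}
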