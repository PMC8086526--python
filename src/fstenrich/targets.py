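"""Target-gene assignment for HD-dense enhancers and HD-carrying promoters.

Enhancers are first filtered by HD-variant density (default: at least one
variant per 500 bases, i.e. count / length >= 1/500; a strict sliding-window
mode is available).  Surviving enhancers are assigned to genes whose
*basal-plus-extension* regulatory domain they overlap: each gene owns a basal
window around its TSS (default 5 kb upstream / 1 kb downstream), extended on
both sides up to a cap (default 1 Mb) but truncated at the nearest other
gene's basal domain — the published default rule of the GREAT tool,
re-implemented geometrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from . import intervals as iv
from .annotation import GeneAnnotation
from .regions import RegionSet

log = logging.getLogger(__name__)

__all__ = [
    "density_filter",
    "build_regulatory_domains",
    "assign_enhancer_targets",
    "promoter_hd_genes",
]


def _hd_positions_by_chrom(hd_variants: pd.DataFrame) -> Dict[str, np.ndarray]:
    out = {}
    for chrom, grp in hd_variants.groupby("chrom", sort=True):
        out[str(chrom)] = np.sort(grp["pos"].to_numpy(dtype=np.int64) - 1)
    return out


def _count_in(pos_sorted: np.ndarray, start: int, end: int) -> int:
    return int(np.searchsorted(pos_sorted, end, side="left")
               - np.searchsorted(pos_sorted, start, side="left"))


def density_filter(
    enhancers: RegionSet,
    hd_variants: pd.DataFrame,
    min_density: float = 1.0 / 500.0,
    sliding_window: bool = False,
) -> pd.DataFrame:
    """Keep enhancers with >= min_density HD variants per base.

    ``hd_variants`` needs chrom and 1-based pos columns.  The default reading
    is a per-enhancer rate: count / length >= min_density, boundary equality
    kept; enhancers with zero HD variants are always dropped.  With
    ``sliding_window=True`` every window of ``1/min_density`` bases (and every
    shorter trailing stub) must contain a variant — the strict reading.

    Returns a frame (chrom, start, end, length, hd_count, density, kept).
    """
    pos_by_chrom = _hd_positions_by_chrom(hd_variants)
    window = 1.0 / min_density
    rows = []
    for chrom in enhancers.chroms():
        pos = pos_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        for start, end in enhancers.intervals[chrom]:
            start, end = int(start), int(end)
            n = _count_in(pos, start, end)
            length = end - start
            dens = n / length
            if n == 0:
                kept = False
            elif sliding_window:
                inside = pos[(pos >= start) & (pos < end)]
                gaps = np.diff(np.concatenate(([start - 1], inside, [end])))
                kept = bool(np.all(gaps <= window))
            else:
                kept = dens >= min_density
            rows.append((chrom, start, end, length, n, dens, kept))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                     "hd_count", "density", "kept"])
    log.info("density filter kept %d / %d enhancers", int(df["kept"].sum()), len(df))
    return df


@dataclass
class RegulatoryDomains:
    """Per-gene basal and extended regulatory intervals (one TSS per gene)."""

    table: pd.DataFrame  # gene_id, chrom, strand, tss0, basal_start, basal_end,
                         # ext_start, ext_end


def build_regulatory_domains(
    annotation: GeneAnnotation,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
) -> RegulatoryDomains:
    """Basal-plus-extension regulatory domains, one per gene.

    The basal window is strand-aware around the gene's canonical TSS (first
    transcript's).  Each side extends by ``max_extension`` from the basal edge
    but stops at the nearest other gene's basal boundary, and is clipped to
    the chromosome.  Basal domains that themselves overlap a neighbour's basal
    are left intact (the basal window is never shrunk).
    """
    tx = annotation.transcripts
    genes = (tx[tx["strand"].isin(["+", "-"])]
             .sort_values(["chrom", "tss0", "gene_id"], kind="mergesort")
             .drop_duplicates(subset="gene_id", keep="first"))
    rows = []
    for chrom, grp in genes.groupby("chrom", sort=True):
        size = annotation.chrom_sizes.get(chrom)
        basal = []
        for r in grp.itertuples(index=False):
            t = int(r.tss0)
            if r.strand == "+":
                b = (t - basal_up, t + basal_down)
            else:
                b = (t - basal_down + 1, t + basal_up + 1)
            lo = max(b[0], 0)
            hi = min(b[1], size) if size is not None else b[1]
            basal.append((r.gene_id, r.strand, t, lo, hi))
        starts = np.array([b[3] for b in basal])
        ends = np.array([b[4] for b in basal])
        for i, (gene_id, strand, tss0, bs, be) in enumerate(basal):
            left_limit = 0
            right_limit = size if size is not None else np.iinfo(np.int64).max
            # nearest foreign basal boundary on each side (ignore overlapping ones)
            others_end = ends[(np.arange(len(basal)) != i) & (ends <= bs)]
            if len(others_end):
                left_limit = int(others_end.max())
            others_start = starts[(np.arange(len(basal)) != i) & (starts >= be)]
            if len(others_start):
                right_limit = min(right_limit, int(others_start.min()))
            ext_s = max(bs - max_extension, left_limit)
            ext_e = min(be + max_extension, right_limit)
            rows.append((gene_id, chrom, strand, tss0, bs, be, ext_s, ext_e))
    table = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss0",
                                        "basal_start", "basal_end",
                                        "ext_start", "ext_end"])
    return RegulatoryDomains(table=table)


def assign_enhancer_targets(
    filtered_enhancers: pd.DataFrame,
    domains: RegulatoryDomains,
) -> tuple[pd.DataFrame, list]:
    """Enhancer → gene edges by >= 1 base overlap with extended domains.

    ``filtered_enhancers`` is the density_filter output (only rows with
    ``kept`` are assigned; pass a pre-filtered frame otherwise).  Returns the
    edge table (one row per enhancer x gene, unassigned enhancers flagged with
    a null gene) and the sorted deduplicated target-gene list.
    """
    enh = filtered_enhancers
    if "kept" in enh.columns:
        enh = enh[enh["kept"]]
    dom = domains.table
    edges = []
    genes: set = set()
    for chrom, grp in enh.groupby("chrom", sort=True):
        d = dom[dom["chrom"] == chrom]
        ds = d["ext_start"].to_numpy()
        de = d["ext_end"].to_numpy()
        ids = d["gene_id"].to_numpy()
        for r in grp.itertuples(index=False):
            hit = (ds < r.end) & (de > r.start)
            if hit.any():
                for g in ids[hit]:
                    edges.append((chrom, r.start, r.end, r.hd_count, g))
                    genes.add(g)
            else:
                edges.append((chrom, r.start, r.end, r.hd_count, None))
    edge_df = pd.DataFrame(edges, columns=["chrom", "start", "end", "hd_count", "gene_id"])
    n_unassigned = int(edge_df["gene_id"].isna().sum())
    if n_unassigned:
        log.info("%d enhancers overlapped no regulatory domain", n_unassigned)
    return edge_df, sorted(genes)


def promoter_hd_genes(promoter_windows: pd.DataFrame,
                      hd_variants: pd.DataFrame) -> tuple[list, int]:
    """Genes with >= 1 HD variant in >= 1 of their per-TSS promoter windows.

    Returns (sorted gene list, number of qualifying promoter windows) — a
    gene with several qualifying promoters counts once in the list but each
    window counts in the promoter tally.
    """
    pos_by_chrom = _hd_positions_by_chrom(hd_variants)
    genes: set = set()
    n_promoters = 0
    for r in promoter_windows.itertuples(index=False):
        pos = pos_by_chrom.get(r.chrom)
        if pos is None:
            continue
        if _count_in(pos, int(r.start), int(r.end)) > 0:
            n_promoters += 1
            genes.add(r.gene_id)
    return sorted(genes), n_promoters
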