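"""Fold-enrichment of highly differentiated variants in region classes.

The central statistic: within a stratum of variants (the top quantile, or one
F_ST bin of it), the fraction falling in a region class is compared with the
fraction of *all tested variants* in that class,

    fold = (n_hd_in / n_hd_total) / (n_all_in / n_all_total).

The baseline is deliberately the variant-count fraction rather than the
genomic base fraction: variant density differs systematically between region
classes (constrained sequence carries fewer SNPs), and the variant-count
baseline is the one that conditions on that.  The genomic base fraction is
reported alongside for context.

Significance is a one-sided upper-tail hypergeometric probability of drawing
at least ``n_hd_in`` in-class variants among ``n_hd_total`` draws from the
universe of ``n_all_total`` tested variants of which ``n_all_in`` are in
class, computed in log space so that tails like 1e-258 remain representable.
"""

from __future__ import annotations

import logging
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .fst import DEFAULT_BIN_EDGES, HdSelection, bin_fst, bin_labels
from .regions import RegionSet

log = logging.getLogger(__name__)

__all__ = [
    "classify_variants",
    "fold_enrichment",
    "enrichment_pvalue",
    "binned_enrichment",
    "format_percent",
]


def classify_variants(variants: pd.DataFrame, region_sets: Mapping[str, RegionSet]) -> pd.DataFrame:
    """Boolean class-membership columns for a variant table.

    ``variants`` needs ``chrom`` and 1-based ``pos``; positions are treated as
    0-based points ``pos - 1`` against half-open intervals.  Membership is
    non-exclusive (a variant may be both promoter and exon); enhancers exclude
    promoters by construction upstream.  Variants on chromosomes absent from a
    region set are simply non-members.
    """
    chrom = variants["chrom"].to_numpy()
    pos0 = variants["pos"].to_numpy(dtype=np.int64) - 1
    out = pd.DataFrame(index=variants.index)
    for name, rs in region_sets.items():
        out[name] = rs.contains(chrom, pos0)
    return out


def fold_enrichment(n_hd_in: int, n_hd_total: int, n_all_in: int, n_all_total: int) -> float:
    """Ratio of the HD in-class fraction to the all-variants in-class fraction.

    Returns NaN when undefined (zero baseline).
    """
    if n_hd_total <= 0:
        raise ValueError("n_hd_total must be positive")
    if not (n_hd_in <= n_hd_total and n_all_in <= n_all_total and n_hd_in <= n_all_in):
        raise ValueError("inconsistent contingency counts")
    if n_all_in == 0 or n_all_total == 0:
        return float("nan")
    return (n_hd_in / n_hd_total) / (n_all_in / n_all_total)


def enrichment_pvalue(n_hd_in: int, n_hd_total: int, n_all_in: int,
                      n_all_total: int) -> tuple[float, float]:
    """One-sided upper-tail hypergeometric p-value, as ``(p, log10_p)``.

    P(X >= n_hd_in) for X ~ Hypergeom(N=n_all_total, K=n_all_in, n=n_hd_total).
    ``p`` may underflow to 0.0 for extreme tails; ``log10_p`` does not.
    """
    if not (0 <= n_hd_in <= n_hd_total <= n_all_total and
            n_hd_in <= n_all_in <= n_all_total):
        raise ValueError("inconsistent contingency counts")
    if n_hd_in == 0:
        return 1.0, 0.0
    logp = hypergeom.logsf(n_hd_in - 1, n_all_total, n_all_in, n_hd_total)
    return float(np.exp(logp)), float(logp / np.log(10.0))


def format_percent(x: float) -> str:
    """Report-style percent: whole numbers at >= 10%, one decimal below."""
    return f"{x:.0f}%" if x >= 10 else f"{x:.1f}%"


def binned_enrichment(
    fst_records: pd.DataFrame,
    hd: HdSelection,
    region_sets: Mapping[str, RegionSet],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """One enrichment row per (stratum x region class).

    Strata are the configured F_ST bins *of the selected HD variants* plus the
    overall top-quantile stratum.  The universe (baseline) is always the full
    tested-variant table.  Empty strata yield rows with n = 0 and no fold.
    """
    membership = classify_variants(fst_records, region_sets)
    n_all_total = len(fst_records)
    hd_mask = np.zeros(n_all_total, dtype=bool)
    hd_mask[hd.index] = True
    labels = np.array(bin_fst(fst_records["fst"].to_numpy(), edges), dtype=object)

    strata = [("top_quantile", hd_mask)]
    for lab in bin_labels(edges):
        strata.append((lab, hd_mask & (labels == lab)))

    genome = sum(chrom_sizes.values()) if chrom_sizes else None
    rows = []
    for stratum, smask in strata:
        n_hd_total = int(smask.sum())
        for cls, rs in region_sets.items():
            inm = membership[cls].to_numpy()
            n_all_in = int(inm.sum())
            n_hd_in = int((smask & inm).sum())
            if n_hd_total == 0:
                fold, p, log10p, pct = float("nan"), float("nan"), float("nan"), float("nan")
                note = "empty stratum"
            else:
                fold = fold_enrichment(n_hd_in, n_hd_total, n_all_in, n_all_total)
                p, log10p = enrichment_pvalue(n_hd_in, n_hd_total, n_all_in, n_all_total)
                pct = 100.0 * n_hd_in / n_hd_total
                note = ""
            rows.append({
                "stratum": stratum, "region_class": cls,
                "n_hd_in": n_hd_in, "n_hd_total": n_hd_total,
                "n_all_in": n_all_in, "n_all_total": n_all_total,
                "hd_percent": pct,
                "hd_percent_printed": format_percent(pct) if n_hd_total else "",
                "fold": fold, "p_value": p, "log10_p": log10p,
                "class_variant_fraction": n_all_in / n_all_total if n_all_total else float("nan"),
                "class_genome_fraction": (rs.total_length() / genome) if genome else float("nan"),
                "notes": note,
            })
    return pd.DataFrame(rows)
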