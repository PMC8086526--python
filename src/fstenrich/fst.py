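"""Per-site F_ST between two populations, top-quantile selection and binning.

Two estimators are provided:

* ``weir_cockerham`` — the Weir & Cockerham (1984) two-population per-site
  variance components a, b, c, with F_ST = a / (a + b + c).  The substrate is
  per-population allele counts, so the within-individual heterozygosity term
  is taken at its Hardy–Weinberg expectation 2 p_i (1 - p_i).
* ``hudson`` — the Hudson estimator in the Bhatia et al. parameterization:
  N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
  D = p1(1-p2) + p2(1-p1), with n_i in chromosomes.

Negative per-site estimates are clamped to 0 (the raw ratio is retained in the
output); sites with fewer than 2 called chromosomes in either population, or a
non-positive denominator, are dropped with a logged reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ESTIMATORS = ("weir_cockerham", "hudson")

DEFAULT_BIN_EDGES = (0.0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
FIXED_BIN_LABEL = "=1"


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def _sample_indices(header_samples: Sequence[str], wanted: Sequence[str], pop: str) -> np.ndarray:
    index = {s: i for i, s in enumerate(header_samples)}
    missing = [s for s in wanted if s not in index]
    if missing:
        raise ValueError(f"samples for {pop} absent from VCF header: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    return np.array([index[s] for s in wanted], dtype=np.intp)


def allele_counts_from_vcf(
    vcf_path,
    pop1_samples: Sequence[str],
    pop2_samples: Sequence[str],
    exclude_chroms: Iterable[str] = ("chrX", "chrY", "chrM", "X", "Y", "MT"),
) -> tuple[pd.DataFrame, Dict[str, int]]:
    """Stream a VCF into per-site, per-population alternate-allele counts.

    Only biallelic SNPs are counted; other records increment a skip counter.
    Half-called genotypes are treated as fully missing.  Sites monomorphic
    across both populations combined are dropped (counted).  Sex chromosomes
    and the mitochondrion are excluded by default so that, as in typical
    two-population scans, only autosomal sites are analyzed; pass
    ``exclude_chroms=()`` to admit everything.

    Returns a frame (chrom, pos, alt1, called1, alt2, called2) with 1-based
    positions, plus a counter dict.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    idx1 = _sample_indices(vcf.samples, pop1_samples, "pop1")
    idx2 = _sample_indices(vcf.samples, pop2_samples, "pop2")
    excl = set(exclude_chroms)
    counters = {"n_records": 0, "skipped_non_biallelic_snp": 0,
                "skipped_excluded_chrom": 0, "dropped_monomorphic": 0, "kept": 0}
    rows = []
    for v in vcf:
        counters["n_records"] += 1
        if v.CHROM in excl:
            counters["skipped_excluded_chrom"] += 1
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            counters["skipped_non_biallelic_snp"] += 1
            log.debug("skipping non-biallelic/non-SNP record at %s:%d", v.CHROM, v.POS)
            continue
        gt = np.asarray(v.genotypes, dtype=np.int64)[:, :2]
        ok = np.all(gt >= 0, axis=1)  # half-calls count as fully missing
        alt = gt.sum(axis=1)
        a1 = int(alt[idx1][ok[idx1]].sum())
        c1 = int(2 * ok[idx1].sum())
        a2 = int(alt[idx2][ok[idx2]].sum())
        c2 = int(2 * ok[idx2].sum())
        if a1 + a2 == 0 or a1 + a2 == c1 + c2:
            counters["dropped_monomorphic"] += 1
            continue
        rows.append((v.CHROM, v.POS, a1, c1, a2, c2))
        counters["kept"] += 1
    df = pd.DataFrame(rows, columns=["chrom", "pos", "alt1", "called1", "alt2", "called2"])
    return df, counters


# ---------------------------------------------------------------------------
# estimators (vectorized over sites)
# ---------------------------------------------------------------------------

def weir_cockerham_components(alt1, called1, alt2, called2):
    """Weir–Cockerham a and b+c... returns (p1, p2, numerator a, denominator a+b+c).

    Sample sizes are diploid individuals n_i = called_i / 2.  Entries where a
    component is undefined (n_i < 1 or nbar <= 1 or nc <= 0) yield NaN.
    """
    alt1 = np.asarray(alt1, dtype=float)
    alt2 = np.asarray(alt2, dtype=float)
    called1 = np.asarray(called1, dtype=float)
    called2 = np.asarray(called2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / called1
        p2 = alt2 / called2
        n1 = called1 / 2.0
        n2 = called2 / 2.0
        nsum = n1 + n2
        nbar = nsum / 2.0
        nc = nsum - (n1 ** 2 + n2 ** 2) / nsum          # (r*nbar - sum n_i^2/(r*nbar)) / (r-1), r=2
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # /(r-1), r=2
        h1 = 2.0 * p1 * (1.0 - p1)                       # HWE expectation of het frequency
        h2 = 2.0 * p2 * (1.0 - p2)
        hbar = (n1 * h1 + n2 * h2) / nsum
        pq = pbar * (1.0 - pbar)
        a = nbar / nc * (s2 - (pq - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (pq - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        num = a
        den = a + b + c
    bad = ~np.isfinite(num) | ~np.isfinite(den)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return p1, p2, num, den


def hudson_components(alt1, called1, alt2, called2):
    """Hudson/Bhatia per-site numerator N and denominator D."""
    alt1 = np.asarray(alt1, dtype=float)
    alt2 = np.asarray(alt2, dtype=float)
    n1 = np.asarray(called1, dtype=float)
    n2 = np.asarray(called2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / n1
        p2 = alt2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = ~np.isfinite(num) | ~np.isfinite(den)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return p1, p2, num, den


def compute_fst(
    counts: pd.DataFrame,
    estimator: str = "weir_cockerham",
    min_called: int = 2,
) -> tuple[pd.DataFrame, Dict[str, int]]:
    """Per-site F_ST records from an allele-counts frame.

    Returns (records, drop_counters).  Records carry the raw component ratio
    (``fst_raw``) and the [0, 1]-clamped value (``fst``).  Sites failing the
    called-chromosome minimum in either population, or with non-positive
    denominator, are dropped.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    fn = weir_cockerham_components if estimator == "weir_cockerham" else hudson_components
    p1, p2, num, den = fn(counts["alt1"], counts["called1"], counts["alt2"], counts["called2"])
    undercalled = (counts["called1"].to_numpy() < min_called) | \
                  (counts["called2"].to_numpy() < min_called)
    bad_den = ~undercalled & (~np.isfinite(den) | (den <= 0))
    keep = ~undercalled & ~bad_den
    drops = {"dropped_insufficient_called": int(undercalled.sum()),
             "dropped_nonpositive_denominator": int(bad_den.sum())}
    if drops["dropped_insufficient_called"]:
        log.info("dropped %d sites with < %d called chromosomes in a population",
                 drops["dropped_insufficient_called"], min_called)
    if drops["dropped_nonpositive_denominator"]:
        log.info("dropped %d sites with non-positive denominator",
                 drops["dropped_nonpositive_denominator"])
    raw = num[keep] / den[keep]
    out = pd.DataFrame({
        "chrom": counts.loc[keep, "chrom"].to_numpy(),
        "pos": counts.loc[keep, "pos"].to_numpy(),
        "p1": p1[keep],
        "p2": p2[keep],
        "numerator": num[keep],
        "denominator": den[keep],
        "fst_raw": raw,
        "fst": np.clip(raw, 0.0, 1.0),
    })
    out.attrs["estimator"] = estimator
    return out, drops


def hudson_ratio_of_averages(counts: pd.DataFrame) -> float:
    """Genome-wide Hudson F_ST as sum(N)/sum(D) — the recommended multi-site
    combination, far less biased than averaging per-site ratios."""
    _, _, num, den = hudson_components(counts["alt1"], counts["called1"],
                                       counts["alt2"], counts["called2"])
    ok = np.isfinite(num) & np.isfinite(den)
    return float(num[ok].sum() / den[ok].sum())


# ---------------------------------------------------------------------------
# selection & binning
# ---------------------------------------------------------------------------

@dataclass
class HdSelection:
    """The highly differentiated (HD) top-quantile selection."""

    quantile: float
    threshold: float
    index: np.ndarray          # positional indices into the records frame
    n_nominal: int
    n_selected: int
    has_ties: bool
    bin_edges: tuple = DEFAULT_BIN_EDGES

    @property
    def mask(self):
        return self.index


def select_hd(records: pd.DataFrame, quantile: float = 0.01) -> HdSelection:
    """Select the ceil(quantile * N) highest-F_ST records, ties included.

    All records tied with the threshold value enter the selection, so the
    realized set may exceed the nominal count (logged when it does).
    """
    n = len(records)
    if n == 0:
        raise ValueError("cannot select from an empty record set")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if n < 1 / quantile:
        log.warning("only %d records for quantile %g; selection degenerates", n, quantile)
    values = records["fst"].to_numpy()
    k = math.ceil(quantile * n)
    order = np.argsort(values, kind="stable")[::-1]
    threshold = float(values[order[k - 1]])
    selected = np.flatnonzero(values >= threshold)
    has_ties = len(selected) > k
    if has_ties:
        log.info("tie at threshold %.6g: selected %d records for nominal %d",
                 threshold, len(selected), k)
    return HdSelection(quantile=quantile, threshold=threshold, index=selected,
                       n_nominal=k, n_selected=len(selected), has_ties=has_ties)


def bin_fst(values, edges: Sequence[float] = DEFAULT_BIN_EDGES) -> np.ndarray:
    """Label each clamped F_ST value with its stratum.

    Bins are left-closed, right-open on the given edges, except that the exact
    value 1.0 forms its own singleton stratum ``"=1"`` — fixed differences are
    a qualitatively distinct class.
    """
    edges = list(edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("edges must be strictly increasing")
    if edges[0] > 0 or edges[-1] < 1:
        raise ValueError("edges must span (0, 1]")
    values = np.asarray(values, dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise AssertionError("clamped F_ST outside [0, 1]")
    labels = np.array([f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)],
                      dtype=object)
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(labels) - 1)
    out = labels[idx]
    out[values == 1.0] = FIXED_BIN_LABEL
    return out


def bin_labels(edges: Sequence[float] = DEFAULT_BIN_EDGES) -> list:
    """Ordered stratum labels for a set of edges (lowest bin first, '=1' last)."""
    edges = list(edges)
    return [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)] + [FIXED_BIN_LABEL]
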