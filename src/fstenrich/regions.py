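"""Construction of comparable genomic region classes: promoters, enhancers, exons.

Promoters are fixed windows around protein-coding TSSs (default 1,000 bases
upstream and 500 bases downstream including the TSS base, 1,500 bp total).
Enhancers are the union of the supplied peak sets (open chromatin and/or
H3K27Ac — the inclusive "and/or" reading, i.e. set union) minus promoters, so
the two classes are disjoint by construction.  Exons are the merged union of
coding (CDS) segments.  Exons are deliberately *not* subtracted from promoters
or enhancers; only the promoter/enhancer pair is mutually exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .annotation import GeneAnnotation, read_bed

log = logging.getLogger(__name__)

__all__ = [
    "RegionSet",
    "build_promoters",
    "build_exons",
    "build_enhancers",
    "genome_fraction",
]


@dataclass
class RegionSet:
    """A named class of merged, sorted, disjoint genomic intervals."""

    name: str
    intervals: Dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame, provenance: dict | None = None) -> "RegionSet":
        """Build (and merge) from a chrom/start/end frame."""
        out: Dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            out[str(chrom)] = iv.merge(grp[["start", "end"]].to_numpy())
        return cls(name=name, intervals=out, provenance=provenance or {})

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "RegionSet":
        df = read_bed(path)
        return cls.from_frame(name or str(path), df, provenance={"source": str(path)})

    def chroms(self) -> list:
        return sorted(self.intervals)

    def total_length(self) -> int:
        return sum(iv.total_length(a) for a in self.intervals.values())

    def n_intervals(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def contains(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Membership of 0-based positions; vectorized over a variant table."""
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.zeros(len(pos0), dtype=bool)
        for c, arr in self.intervals.items():
            m = chrom == c
            if m.any():
                out[m] = iv.contains_points(arr, pos0[m])
        return out

    def union(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        out: Dict[str, np.ndarray] = {}
        for c in set(self.intervals) | set(other.intervals):
            parts = [a for a in (self.intervals.get(c), other.intervals.get(c)) if a is not None and len(a)]
            merged = iv.merge(np.vstack(parts)) if parts else np.empty((0, 2), dtype=np.int64)
            if len(merged):
                out[c] = merged
        return RegionSet(name or f"{self.name}|{other.name}", out,
                         {"union_of": [self.name, other.name]})

    def subtract(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        out: Dict[str, np.ndarray] = {}
        for c, arr in self.intervals.items():
            res = iv.subtract(arr, other.intervals.get(c, np.empty((0, 2), dtype=np.int64)))
            if len(res):
                out[c] = res
        return RegionSet(name or self.name, out,
                         {"subtract": other.name, "from": self.name})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms():
            arr = self.intervals[c]
            rows.append(pd.DataFrame({"chrom": c, "start": arr[:, 0], "end": arr[:, 1]}))
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(rows, ignore_index=True)

    def to_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def genome_fraction(rs: RegionSet, chrom_sizes: Mapping[str, int]) -> float:
    """Fraction of the genome covered by a region set.

    Raises if the set has intervals on a chromosome absent from (or extending
    beyond) the declared sizes.
    """
    genome = sum(chrom_sizes.values())
    if genome <= 0:
        raise ValueError("empty chrom sizes")
    for c, arr in rs.intervals.items():
        if c not in chrom_sizes:
            raise ValueError(f"region set {rs.name!r} has intervals on undeclared chromosome {c!r}")
        if len(arr) and arr[-1, 1] > chrom_sizes[c]:
            raise ValueError(f"interval beyond declared length of {c!r}")
    return rs.total_length() / genome


def promoter_window(tss0: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Strand-aware promoter window around a 0-based TSS, half-open.

    The downstream stretch includes the TSS base itself, so the window length
    is always upstream + downstream.
    """
    if strand == "+":
        return tss0 - upstream, tss0 + downstream
    if strand == "-":
        return tss0 - downstream + 1, tss0 + upstream + 1
    raise ValueError(f"strand must be + or -, got {strand!r}")


def build_promoters(
    annotation: GeneAnnotation,
    upstream: int = 1000,
    downstream: int = 500,
    coding_only: bool = True,
) -> tuple[RegionSet, pd.DataFrame]:
    """Per-TSS promoter windows and their merged region set.

    Returns ``(merged_set, windows)``.  ``windows`` keeps one row per distinct
    (chrom, strand, TSS) of an eligible transcript — the per-promoter view used
    for promoter counting and per-gene variant lookup — while the merged set is
    the view used in overlap arithmetic.  Windows are clipped to chromosome
    bounds when sizes are known.
    """
    tx = annotation.transcripts
    if coding_only:
        tx = tx[tx["coding"]]
    stranded = tx[tx["strand"].isin(["+", "-"])]
    n_skipped = len(tx) - len(stranded)
    if n_skipped:
        log.warning("skipped %d strandless transcripts", n_skipped)
    rows = []
    for r in stranded.itertuples(index=False):
        s, e = promoter_window(int(r.tss0), r.strand, upstream, downstream)
        s = max(s, 0)
        size = annotation.chrom_sizes.get(r.chrom)
        if size is not None:
            e = min(e, size)
        if s < e:
            rows.append((r.chrom, s, e, r.strand, int(r.tss0), r.gene_id, r.tx_id))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "tss0",
                                          "gene_id", "tx_id"])
    # duplicate TSSs (several transcripts sharing a start) collapse to one window
    windows = windows.drop_duplicates(subset=["chrom", "strand", "tss0", "gene_id"])
    windows = windows.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    merged = RegionSet.from_frame(
        "promoter", windows,
        provenance={"upstream": upstream, "downstream": downstream,
                    "coding_only": coding_only, "n_windows": len(windows)},
    )
    return merged, windows


def build_exons(annotation: GeneAnnotation, coding_only: bool = True) -> RegionSet:
    """Merged union of exonic intervals (CDS segments when coding_only)."""
    cds = annotation.cds
    if len(cds) == 0:
        return RegionSet("exon", {}, {"coding_only": coding_only})
    return RegionSet.from_frame("exon", cds, provenance={"coding_only": coding_only})


def build_enhancers(peak_sets: Sequence[RegionSet], promoters: RegionSet) -> RegionSet:
    """Non-promoter regions covered by any of the peak sets.

    Union across peak sets, then promoter subtraction; all resulting
    fragments are retained regardless of length.
    """
    if not peak_sets:
        raise ValueError("at least one peak set is required")
    u = peak_sets[0]
    for other in peak_sets[1:]:
        u = u.union(other)
    enh = u.subtract(promoters, name="enhancer")
    enh.provenance = {"peak_sets": [p.name for p in peak_sets],
                      "subtracted": promoters.name}
    return enh
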