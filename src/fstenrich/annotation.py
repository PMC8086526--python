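"""Gene-annotation container and loaders for GFF3/GTF, BED and chrom-sizes files.

Internally everything is 0-based half-open.  GFF (1-based inclusive) is
converted at the boundary; BED passes through natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRANSCRIPT_COLUMNS = ["gene_id", "tx_id", "chrom", "strand", "start", "end", "tss0", "coding"]
CDS_COLUMNS = ["tx_id", "gene_id", "chrom", "start", "end"]


@dataclass
class GeneAnnotation:
    """Transcript and CDS tables plus chromosome sizes.

    ``transcripts`` columns: gene_id, tx_id, chrom, strand (+/-/.), start, end
    (0-based half-open gene-body span), tss0 (0-based position of the first
    transcribed base) and coding (has >= 1 CDS segment).
    ``cds`` columns: tx_id, gene_id, chrom, start, end (0-based half-open).
    """

    transcripts: pd.DataFrame
    cds: pd.DataFrame
    chrom_sizes: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(TRANSCRIPT_COLUMNS) - set(self.transcripts.columns)
        if missing:
            raise ValueError(f"transcripts table missing columns: {sorted(missing)}")
        missing = set(CDS_COLUMNS) - set(self.cds.columns)
        if missing:
            raise ValueError(f"cds table missing columns: {sorted(missing)}")

    @property
    def n_genes(self) -> int:
        return self.transcripts["gene_id"].nunique()


def tss_from_span(start: int, end: int, strand: str) -> int:
    """0-based TSS of a transcript spanning [start, end) on the given strand."""
    if strand == "+":
        return start
    if strand == "-":
        return end - 1
    raise ValueError(f"cannot derive TSS for strand {strand!r}")


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a two-column chrom<TAB>length file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64}, comment="#")
    return dict(zip(df["chrom"], df["length"]))


def load_annotation(gff_path, chrom_sizes: Dict[str, int] | None = None) -> GeneAnnotation:
    """Load gene/transcript/CDS structure from a GFF3 or GTF file.

    Dialect is auto-detected by gffutils.  Transcripts without a usable strand
    are skipped with a warning.  A transcript is *coding* iff it has at least
    one CDS child.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    tx_rows = []
    cds_rows = []
    transcript_types = {"mRNA", "transcript"}
    for tx in db.all_features():
        if tx.featuretype not in transcript_types:
            continue
        parents = [p.id for p in db.parents(tx, featuretype="gene")]
        gene_id = parents[0] if parents else tx.id
        if tx.strand not in ("+", "-"):
            log.warning("skipping strandless transcript %s", tx.id)
            continue
        start0, end0 = tx.start - 1, tx.end  # GFF is 1-based inclusive
        cds_children = list(db.children(tx, featuretype="CDS"))
        for c in cds_children:
            cds_rows.append((tx.id, gene_id, tx.seqid, c.start - 1, c.end))
        tx_rows.append((
            gene_id, tx.id, tx.seqid, tx.strand, start0, end0,
            tss_from_span(start0, end0, tx.strand), bool(cds_children),
        ))
    transcripts = pd.DataFrame(tx_rows, columns=TRANSCRIPT_COLUMNS)
    cds = pd.DataFrame(cds_rows, columns=CDS_COLUMNS)
    return GeneAnnotation(transcripts=transcripts, cds=cds,
                          chrom_sizes=dict(chrom_sizes or {}))


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a chrom/start/end frame (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str, 1: np.int64, 2: np.int64})
    return df
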