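"""Synthetic two-population genomes with planted allele-frequency differentiation.

The generator emits everything the analysis pipeline consumes — a gene
annotation (GFF3), peak sets (BED), chromosome sizes, a multi-sample VCF with
two population sample lists — together with a planted-truth table, so every
downstream stage can be checked against known ground truth.

Divergence model
----------------
Population allele frequencies follow the Balding–Nichols model: given an
ancestral frequency ``p`` and a divergence parameter ``F`` in (0, 1), each
population's frequency is an independent draw from
``Beta(p (1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
``p (1-p) F``.  The expected Hudson F_ST between two such populations is
approximately ``F``, which is what makes parameter recovery testable.  A site
falling in a planted region class (promoter / enhancer / exon) uses that
class's ``F`` from ``f_by_class``; all other sites use ``f_background``.

Genes are written with a 5' UTR of at least ~600 bases between the TSS and the
first coding base, so promoter windows (downstream 500) and coding exons are
disjoint by construction and a planted promoter effect cannot leak into the
exon stratum.

Diploid genotypes are binomial draws from the population frequency
(Hardy–Weinberg within populations); there is no linkage disequilibrium, no
sequencing-error model and no indels — only biallelic SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .annotation import GeneAnnotation, CDS_COLUMNS, TRANSCRIPT_COLUMNS
from .regions import RegionSet, build_enhancers, build_exons, build_promoters

log = logging.getLogger(__name__)

CLASS_PRECEDENCE = ("promoter", "exon", "enhancer")
_STAGE_ANNOTATION, _STAGE_FREQ, _STAGE_GENO, _STAGE_GMT = 11, 22, 33, 44


class InfeasibleConfigError(ValueError):
    """Raised when the requested structure cannot be placed in the genome."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults emulate the proportions of a mammalian two-population
    differentiation scan at desk scale: peaks covering ~5.4% of the genome,
    promoters ~1.8%, coding exons ~1.4%, and population samples of 38 and 41
    diploid individuals.
    """

    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 120
    promoter_up: int = 1000
    promoter_down: int = 500
    peak_density: float = 18.0                      # peaks per Mb, both marks pooled
    peak_length_range: Tuple[int, int] = (1000, 5000)
    n_sites: int = 50_000
    n_samples_pop1: int = 38
    n_samples_pop2: int = 41
    f_background: float = 0.2
    f_by_class: Mapping[str, float] = field(default_factory=dict)
    site_density_by_class: Mapping[str, float] = field(default_factory=dict)
    ancestral_freq_range: Tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_chromosomes=self.n_chromosomes, chrom_length=self.chrom_length,
                      n_genes=self.n_genes, n_sites=self.n_sites,
                      n_samples_pop1=self.n_samples_pop1, n_samples_pop2=self.n_samples_pop2,
                      promoter_up=self.promoter_up, promoter_down=self.promoter_down)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not 0 < self.f_background < 1:
            raise ValueError("f_background must be in (0, 1)")
        for cls, f in self.f_by_class.items():
            if not 0 < f < 1:
                raise ValueError(f"f_by_class[{cls!r}] must be in (0, 1)")
            if cls not in CLASS_PRECEDENCE:
                raise ValueError(f"unknown region class {cls!r}")
        lo, hi = self.ancestral_freq_range
        if not 0 < lo < hi < 1:
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.peak_length_range[0] <= 0 or self.peak_length_range[0] > self.peak_length_range[1]:
            raise ValueError("invalid peak_length_range")
        for cls, m in self.site_density_by_class.items():
            if m <= 0:
                raise ValueError(f"site_density_by_class[{cls!r}] must be > 0")


@dataclass
class PlantedTruth:
    """Ground truth of the simulation: one row per emitted site.

    ``sites`` columns: chrom, pos0, class_label, p_anc, f, p1, p2, n_redraws.
    ``region_sets`` are the planted classes exactly as labelled.
    """

    sites: pd.DataFrame
    region_sets: Dict[str, RegionSet]
    config: SyntheticConfig


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _place_nonoverlapping(rng, chrom_length: int, lengths: np.ndarray, margin: int = 0) -> np.ndarray:
    """Place blocks of the given lengths without overlap, uniformly spread.

    Free space is split into random gaps (Dirichlet) around the blocks.
    Returns start coordinates in left-to-right order.
    """
    total = int(lengths.sum())
    free = chrom_length - total - 2 * margin
    if free < 0:
        raise InfeasibleConfigError(
            f"cannot place {len(lengths)} blocks totalling {total} bp "
            f"in a {chrom_length} bp chromosome")
    gaps = np.floor(rng.dirichlet(np.ones(len(lengths) + 1)) * free).astype(np.int64)
    starts = margin + np.cumsum(np.concatenate(([0], lengths[:-1]))) + np.cumsum(gaps[:-1])
    return starts


def _split_counts(total: int, k: int) -> np.ndarray:
    base = total // k
    out = np.full(k, base, dtype=np.int64)
    out[: total - base * k] += 1
    return out


def simulate_annotation(config: SyntheticConfig) -> tuple[GeneAnnotation, Dict[str, RegionSet]]:
    """Generate a gene annotation and two peak sets (open chromatin, H3K27Ac).

    Gene bodies are non-overlapping, stranded, each with 1–3 coding exons and
    a 5' UTR keeping the CDS clear of the promoter's downstream window.  Peaks
    are placed without overlap so the union coverage tracks
    ``peak_density * mean(peak_length)`` closely, and each peak is assigned to
    one or both marks.
    """
    config.validate()
    rng = _rng(config, _STAGE_ANNOTATION)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_sizes = {c: int(config.chrom_length) for c in chroms}

    tx_rows, cds_rows = [], []
    genes_per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    gi = 0
    for c, ngene in zip(chroms, genes_per_chrom):
        if ngene == 0:
            continue
        lengths = rng.integers(3000, 12001, ngene)
        starts = _place_nonoverlapping(rng, config.chrom_length, lengths, margin=2000)
        strands = rng.choice(["+", "-"], size=ngene)
        for s0, L, strand in zip(starts, lengths, strands):
            gi += 1
            gene_id, tx_id = f"G{gi:05d}", f"T{gi:05d}"
            end0 = int(s0 + L)
            s0 = int(s0)
            tss0 = s0 if strand == "+" else end0 - 1
            # CDS layout in transcript coordinates (from the TSS)
            utr5 = int(rng.integers(600, 1501))
            cds_total = int(rng.integers(600, 1801))
            n_ex = int(rng.integers(1, 4))
            ex_len = _split_counts(cds_total, n_ex)
            coding_span = L - utr5 - 200           # keep a 3' UTR of 200 bp
            intron_space = coding_span - cds_total
            if intron_space < 0:
                n_ex, ex_len, cds_total = 1, np.array([max(coding_span, 300)]), max(coding_span, 300)
                intron_space = coding_span - cds_total
            introns = np.floor(rng.dirichlet(np.ones(max(n_ex - 1, 1))) *
                               max(intron_space, 0)).astype(np.int64)
            offs = utr5
            tx_cds = []
            for k in range(n_ex):
                tx_cds.append((offs, offs + int(ex_len[k])))
                offs += int(ex_len[k])
                if k < n_ex - 1:
                    offs += int(introns[k])
            for a, b in tx_cds:
                if strand == "+":
                    cds_rows.append((tx_id, gene_id, c, s0 + a, s0 + b))
                else:
                    cds_rows.append((tx_id, gene_id, c, end0 - b, end0 - a))
            tx_rows.append((gene_id, tx_id, c, strand, s0, end0, tss0, True))

    annotation = GeneAnnotation(
        transcripts=pd.DataFrame(tx_rows, columns=TRANSCRIPT_COLUMNS),
        cds=pd.DataFrame(cds_rows, columns=CDS_COLUMNS).sort_values(
            ["chrom", "start"], kind="mergesort").reset_index(drop=True),
        chrom_sizes=chrom_sizes,
    )

    # peaks: one non-overlapping pool, marks assigned per peak
    genome_mb = config.n_chromosomes * config.chrom_length / 1e6
    n_peaks = max(int(round(config.peak_density * genome_mb)), 1)
    peaks_per_chrom = _split_counts(n_peaks, config.n_chromosomes)
    lo, hi = config.peak_length_range
    atac_rows, k27_rows = [], []
    for c, npk in zip(chroms, peaks_per_chrom):
        if npk == 0:
            continue
        plens = rng.integers(lo, hi + 1, npk)
        pstarts = _place_nonoverlapping(rng, config.chrom_length, plens)
        marks = rng.choice(["atac", "h3k27ac", "both"], size=npk, p=[0.45, 0.45, 0.10])
        for s0, L, m in zip(pstarts, plens, marks):
            row = (c, int(s0), int(s0 + L))
            if m in ("atac", "both"):
                atac_rows.append(row)
            if m in ("h3k27ac", "both"):
                k27_rows.append(row)
    peak_sets = {
        "atac": RegionSet.from_frame("atac", pd.DataFrame(atac_rows, columns=["chrom", "start", "end"]),
                                     provenance={"simulated": True}),
        "h3k27ac": RegionSet.from_frame("h3k27ac", pd.DataFrame(k27_rows, columns=["chrom", "start", "end"]),
                                        provenance={"simulated": True}),
    }
    return annotation, peak_sets


def planted_region_sets(config: SyntheticConfig, annotation: GeneAnnotation,
                        peak_sets: Dict[str, RegionSet]) -> Dict[str, RegionSet]:
    """The region classes as planted: promoters, exons, enhancers."""
    promoters, _ = build_promoters(annotation, config.promoter_up, config.promoter_down)
    exons = build_exons(annotation)
    enhancers = build_enhancers(list(peak_sets.values()), promoters)
    return {"promoter": promoters, "exon": exons, "enhancer": enhancers}


def _classify(region_sets: Dict[str, RegionSet], chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
    labels = np.full(len(pos0), "background", dtype=object)
    for cls in reversed(CLASS_PRECEDENCE):   # apply lowest precedence first
        member = region_sets[cls].contains(chrom, pos0)
        labels[member] = cls
    return labels


def _draw_balding_nichols(rng, p_anc: np.ndarray, f: np.ndarray) -> np.ndarray:
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    return rng.beta(a, b)


def simulate_site_frequencies(
    config: SyntheticConfig,
    annotation: GeneAnnotation,
    peak_sets: Dict[str, RegionSet],
) -> PlantedTruth:
    """Place sites along the genome and draw per-population frequencies.

    Sites are uniform along the genome (optionally re-weighted per class via
    ``site_density_by_class``), deduplicated per position.  Each site records
    its class label, ancestral frequency, divergence parameter and the two
    Balding–Nichols population frequencies.
    """
    config.validate()
    rng = _rng(config, _STAGE_FREQ)
    region_sets = planted_region_sets(config, annotation, peak_sets)
    chroms = sorted(annotation.chrom_sizes)
    sizes = np.array([annotation.chrom_sizes[c] for c in chroms], dtype=np.int64)
    probs = sizes / sizes.sum()
    dens = config.site_density_by_class
    max_mult = max([1.0, *dens.values()]) if dens else 1.0

    chosen_chrom: list = []
    chosen_pos: list = []
    chosen_label: list = []
    seen = {c: set() for c in chroms}
    need = config.n_sites
    while need > 0:
        draw = max(int(need * 1.3) + 16, 64)
        ci = rng.choice(len(chroms), size=draw, p=probs)
        pos = rng.integers(0, sizes[ci])
        carr = np.array([chroms[i] for i in ci], dtype=object)
        labels = _classify(region_sets, carr, pos)
        if dens:
            mult = np.array([dens.get(l, 1.0) for l in labels]) / max_mult
            keep = rng.random(draw) < mult
        else:
            keep = np.ones(draw, dtype=bool)
        for c, p, l, k in zip(carr, pos, labels, keep):
            if not k or need == 0:
                continue
            if int(p) in seen[c]:
                continue
            seen[c].add(int(p))
            chosen_chrom.append(c)
            chosen_pos.append(int(p))
            chosen_label.append(l)
            need -= 1

    sites = pd.DataFrame({"chrom": chosen_chrom, "pos0": np.array(chosen_pos, dtype=np.int64),
                          "class_label": chosen_label})
    sites = sites.sort_values(["chrom", "pos0"], kind="mergesort").reset_index(drop=True)
    lo, hi = config.ancestral_freq_range
    sites["p_anc"] = rng.uniform(lo, hi, len(sites))
    sites["f"] = np.array([config.f_by_class.get(l, config.f_background)
                           for l in sites["class_label"]])
    f = sites["f"].to_numpy()
    p_anc = sites["p_anc"].to_numpy()
    sites["p1"] = _draw_balding_nichols(rng, p_anc, f)
    sites["p2"] = _draw_balding_nichols(rng, p_anc, f)
    sites["n_redraws"] = 0
    return PlantedTruth(sites=sites, region_sets=region_sets, config=config)


def simulate_genotypes(
    truth: PlantedTruth,
    config: SyntheticConfig,
    max_redraws: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw diploid genotype matrices for both populations.

    Returns ``(G1, G2)`` of shapes (n_sites, n_samples_pop*) with values in
    {0, 1, 2} (alternate-allele dosage) or -1 for missing.  Sites where the
    combined sample is monomorphic have their population frequencies and
    genotypes re-drawn (up to ``max_redraws`` times, recorded per site in
    ``truth.sites['n_redraws']``), since F_ST is undefined there.  Missingness
    is applied after the monomorphism check.
    """
    config.validate()
    rng = _rng(config, _STAGE_GENO)
    s = truth.sites
    n = len(s)
    n1, n2 = config.n_samples_pop1, config.n_samples_pop2
    p1 = s["p1"].to_numpy().copy()
    p2 = s["p2"].to_numpy().copy()
    G1 = rng.binomial(2, p1[:, None], size=(n, n1))
    G2 = rng.binomial(2, p2[:, None], size=(n, n2))
    redraws = np.zeros(n, dtype=np.int64)
    for _ in range(max_redraws):
        tot = G1.sum(axis=1) + G2.sum(axis=1)
        mono = (tot == 0) | (tot == 2 * (n1 + n2))
        if not mono.any():
            break
        idx = np.flatnonzero(mono)
        redraws[idx] += 1
        f = s["f"].to_numpy()[idx]
        pa = s["p_anc"].to_numpy()[idx]
        p1[idx] = _draw_balding_nichols(rng, pa, f)
        p2[idx] = _draw_balding_nichols(rng, pa, f)
        G1[idx] = rng.binomial(2, p1[idx, None], size=(len(idx), n1))
        G2[idx] = rng.binomial(2, p2[idx, None], size=(len(idx), n2))
    truth.sites["p1"] = p1
    truth.sites["p2"] = p2
    truth.sites["n_redraws"] = redraws
    if config.missing_rate > 0:
        G1[rng.random(G1.shape) < config.missing_rate] = -1
        G2[rng.random(G2.shape) < config.missing_rate] = -1
    return G1.astype(np.int8), G2.astype(np.int8)


def allele_counts_from_matrices(G1: np.ndarray, G2: np.ndarray,
                                sites: pd.DataFrame) -> pd.DataFrame:
    """In-memory equivalent of the VCF → allele-counts step (for simulations).

    Monomorphic combined sites are dropped, mirroring the VCF reader.
    """
    ok1, ok2 = G1 >= 0, G2 >= 0
    alt1 = np.where(ok1, G1, 0).sum(axis=1)
    alt2 = np.where(ok2, G2, 0).sum(axis=1)
    called1 = 2 * ok1.sum(axis=1)
    called2 = 2 * ok2.sum(axis=1)
    df = pd.DataFrame({"chrom": sites["chrom"].to_numpy(),
                       "pos": sites["pos0"].to_numpy() + 1,
                       "alt1": alt1, "called1": called1,
                       "alt2": alt2, "called2": called2})
    tot = df["alt1"] + df["alt2"]
    keep = (tot > 0) & (tot < df["called1"] + df["called2"])
    return df[keep.to_numpy()].reset_index(drop=True)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, truth: PlantedTruth, G1: np.ndarray, G2: np.ndarray,
              sample_names1, sample_names2) -> None:
    """Write a minimal VCF v4.2 (GT-only, biallelic SNPs, coordinate-sorted)."""
    s = truth.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fstenrich-synthetic\n")
        chroms = sorted(s["chrom"].unique())
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(sample_names1) + list(sample_names2)) + "\n")
        order = np.lexsort((s["pos0"].to_numpy(), s["chrom"].to_numpy()))
        for i in order:
            gts = [_GT_STR[int(g)] for g in G1[i]] + [_GT_STR[int(g)] for g in G2[i]]
            fh.write(f"{s['chrom'].iat[i]}\t{int(s['pos0'].iat[i]) + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_gff3(path, annotation: GeneAnnotation) -> None:
    """Write gene/mRNA/CDS records (1-based inclusive, per the GFF3 standard)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {c} 1 {annotation.chrom_sizes[c]}\n")
        cds_by_tx = dict(tuple(annotation.cds.groupby("tx_id", sort=False)))
        tx = annotation.transcripts.sort_values(["chrom", "start"], kind="mergesort")
        for r in tx.itertuples(index=False):
            g, t = r.gene_id, r.tx_id
            fh.write(f"{r.chrom}\tfstenrich\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t"
                     f"ID=gene:{g};biotype=protein_coding\n")
            fh.write(f"{r.chrom}\tfstenrich\tmRNA\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t"
                     f"ID={t};Parent=gene:{g}\n")
            for cr in cds_by_tx.get(t, pd.DataFrame(columns=CDS_COLUMNS)).itertuples(index=False):
                fh.write(f"{cr.chrom}\tfstenrich\tCDS\t{cr.start + 1}\t{cr.end}\t.\t{r.strand}\t0\t"
                         f"ID=cds:{t};Parent={t}\n")


def write_bundle(config: SyntheticConfig, out_dir) -> Dict[str, object]:
    """Run the full generator and write every artifact to ``out_dir``.

    Emits: annotation.gff3, peaks_atac.bed, peaks_h3k27ac.bed, chrom.sizes,
    genotypes.vcf, pop1.samples, pop2.samples, truth.tsv.  Returns a dict of
    paths plus the in-memory objects.  Byte-identical across runs with the
    same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation, peak_sets = simulate_annotation(config)
    truth = simulate_site_frequencies(config, annotation, peak_sets)
    G1, G2 = simulate_genotypes(truth, config)
    names1 = [f"P1_{i + 1:03d}" for i in range(config.n_samples_pop1)]
    names2 = [f"P2_{i + 1:03d}" for i in range(config.n_samples_pop2)]

    paths = {
        "gff3": out / "annotation.gff3",
        "atac_bed": out / "peaks_atac.bed",
        "h3k27ac_bed": out / "peaks_h3k27ac.bed",
        "chrom_sizes": out / "chrom.sizes",
        "vcf": out / "genotypes.vcf",
        "pop1": out / "pop1.samples",
        "pop2": out / "pop2.samples",
        "truth": out / "truth.tsv",
    }
    write_gff3(paths["gff3"], annotation)
    peak_sets["atac"].to_bed(paths["atac_bed"])
    peak_sets["h3k27ac"].to_bed(paths["h3k27ac_bed"])
    with open(paths["chrom_sizes"], "w") as fh:
        for c in sorted(annotation.chrom_sizes):
            fh.write(f"{c}\t{annotation.chrom_sizes[c]}\n")
    write_vcf(paths["vcf"], truth, G1, G2, names1, names2)
    Path(paths["pop1"]).write_text("".join(f"{n}\n" for n in names1))
    Path(paths["pop2"]).write_text("".join(f"{n}\n" for n in names2))
    cols = ["chrom", "pos0", "class_label", "p_anc", "f", "p1", "p2", "n_redraws"]
    truth.sites[cols].to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return {"paths": {k: str(v) for k, v in paths.items()},
            "annotation": annotation, "peak_sets": peak_sets, "truth": truth,
            "G1": G1, "G2": G2, "samples1": names1, "samples2": names2}


def simulate_gene_sets(annotation: GeneAnnotation, n_sets: int = 30,
                       set_size_range: Tuple[int, int] = (10, 40),
                       seed: int = 0) -> Dict[str, Tuple[str, set]]:
    """Random gene sets over the annotation's genes (a GMT-shaped collection)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_GMT]))
    genes = sorted(annotation.transcripts["gene_id"].unique())
    lo, hi = set_size_range
    out = {}
    for i in range(n_sets):
        k = int(rng.integers(lo, min(hi, len(genes)) + 1))
        members = set(rng.choice(genes, size=k, replace=False))
        out[f"SET_{i + 1:03d}"] = (f"synthetic gene set {i + 1}", members)
    return out


def write_gmt(path, collection: Mapping[str, Tuple[str, set]]) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            desc, members = collection[name]
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
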