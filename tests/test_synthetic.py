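"""Synthetic generator: determinism, Balding–Nichols moments, planted truth."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from fstenrich.regions import genome_fraction
from fstenrich.synthetic import (InfeasibleConfigError, SyntheticConfig,
                                 allele_counts_from_matrices,
                                 planted_region_sets, simulate_annotation,
                                 simulate_genotypes, simulate_site_frequencies,
                                 write_bundle)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(n_genes=0).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(f_background=1.5).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(f_by_class={"promoter": 0.0}).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(ancestral_freq_range=(0.0, 0.9)).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(missing_rate=1.0).validate()


def test_annotation_bounds_and_strands():
    cfg = SyntheticConfig(n_chromosomes=1, chrom_length=1_000_000, n_genes=10, seed=7)
    ann, peaks = simulate_annotation(cfg)
    tx = ann.transcripts
    assert len(tx) == 10
    assert (tx["start"] >= 0).all() and (tx["end"] <= 1_000_000).all()
    assert set(tx["strand"]) <= {"+", "-"}
    # gene bodies do not overlap
    s = tx.sort_values("start")
    assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
    # every gene coding, with CDS inside the gene body
    assert tx["coding"].all()
    merged = ann.cds.merge(tx[["tx_id", "start", "end"]], on="tx_id",
                           suffixes=("", "_gene"))
    assert (merged["start"] >= merged["start_gene"]).all()
    assert (merged["end"] <= merged["end_gene"]).all()
    for rs in peaks.values():
        for c, arr in rs.intervals.items():
            assert arr[:, 0].min() >= 0 and arr[:, 1].max() <= 1_000_000


def test_peak_coverage_tracks_configured_density():
    """density * mean peak length tuned for 5.4% of a 10 Mb genome."""
    cfg = SyntheticConfig(n_chromosomes=2, chrom_length=5_000_000, seed=5,
                          peak_density=18.0, peak_length_range=(1000, 5000))
    ann, peaks = simulate_annotation(cfg)
    union = peaks["atac"].union(peaks["h3k27ac"])
    frac = genome_fraction(union, ann.chrom_sizes)
    assert abs(frac - 0.054) < 0.005


def test_annotation_infeasible_config_raises():
    with pytest.raises(InfeasibleConfigError):
        simulate_annotation(SyntheticConfig(n_chromosomes=1, chrom_length=20_000,
                                            n_genes=50))


def test_bundle_byte_identical_under_seed(demo_config, tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    pa = write_bundle(demo_config, a)["paths"]
    pb = write_bundle(demo_config, b)["paths"]
    for key in pa:
        assert filecmp.cmp(pa[key], pb[key], shallow=False), key


def test_balding_nichols_moments():
    """Population frequencies have mean p and variance p(1-p)F.

    Closed form: Beta(pc, (1-p)c) with c=(1-F)/F has mean p and variance
    p(1-p)/(c+1) = p(1-p)F.
    """
    cfg = SyntheticConfig(n_chromosomes=1, chrom_length=2_000_000, n_genes=10,
                          n_sites=20_000, f_background=0.5,
                          ancestral_freq_range=(0.499999, 0.500001), seed=3)
    ann, peaks = simulate_annotation(cfg)
    truth = simulate_site_frequencies(cfg, ann, peaks)
    p = np.concatenate([truth.sites["p1"], truth.sites["p2"]])
    n = len(p)
    target_var = 0.5 * 0.5 * 0.5
    se_mean = np.sqrt(target_var / n)
    assert abs(p.mean() - 0.5) < 3 * se_mean
    # SE of the sample variance of Beta(.5,.5): use moment-based bound
    m4 = np.mean((p - p.mean()) ** 4)
    se_var = np.sqrt((m4 - target_var ** 2) / n)
    assert abs(p.var() - target_var) < 3 * se_var


def test_low_divergence_limit():
    cfg = SyntheticConfig(n_chromosomes=1, chrom_length=1_000_000, n_genes=5,
                          n_sites=2_000, f_background=1e-4, seed=1)
    ann, peaks = simulate_annotation(cfg)
    truth = simulate_site_frequencies(cfg, ann, peaks)
    dev = np.abs(truth.sites["p1"] - truth.sites["p_anc"])
    assert dev.mean() < 0.02


def test_planted_class_bookkeeping(demo_config, demo_bundle):
    truth = demo_bundle["truth"]
    s = truth.sites
    # recorded divergence parameter follows the class map
    assert (s.loc[s["class_label"] == "promoter", "f"] == 0.6).all()
    assert (s.loc[s["class_label"] != "promoter", "f"] == 0.2).all()
    # labels consistent with the emitted region sets
    for cls in ("promoter", "exon", "enhancer"):
        member = truth.region_sets[cls].contains(s["chrom"].to_numpy(),
                                                 s["pos0"].to_numpy())
        labelled = (s["class_label"] == cls).to_numpy()
        # a labelled site must be inside its class (precedence may relabel
        # a member of a lower class, never the reverse)
        assert (member | ~labelled).all()


def test_exons_disjoint_from_promoters():
    """The UTR offset keeps coding exons out of promoter windows."""
    cfg = SyntheticConfig(seed=2)
    ann, peaks = simulate_annotation(cfg)
    rs = planted_region_sets(cfg, ann, peaks)
    from fstenrich import intervals as iv
    for c in rs["exon"].intervals:
        inter = iv.intersect(rs["exon"].intervals[c],
                             rs["promoter"].intervals.get(c, np.empty((0, 2), int)))
        assert len(inter) == 0


def test_genotypes_match_fixed_frequencies():
    cfg = SyntheticConfig(n_chromosomes=1, chrom_length=500_000, n_genes=5,
                          n_sites=200, n_samples_pop1=4, n_samples_pop2=3,
                          missing_rate=0.0, seed=9)
    ann, peaks = simulate_annotation(cfg)
    truth = simulate_site_frequencies(cfg, ann, peaks)
    truth.sites["p1"] = 1.0
    truth.sites["p2"] = 0.0
    G1, G2 = simulate_genotypes(truth, cfg, max_redraws=0)
    assert (G1 == 2).all() and (G2 == 0).all()
    assert G1.shape == (200, 4) and G2.shape == (200, 3)


def test_no_missing_when_rate_zero(demo_config):
    cfg = SyntheticConfig(seed=4, n_chromosomes=1, chrom_length=500_000,
                          n_genes=5, n_sites=500, missing_rate=0.0)
    ann, peaks = simulate_annotation(cfg)
    truth = simulate_site_frequencies(cfg, ann, peaks)
    G1, G2 = simulate_genotypes(truth, cfg)
    assert (G1 >= 0).all() and (G2 >= 0).all()
    # monomorphic combined draws were re-drawn away
    tot = G1.sum(axis=1) + G2.sum(axis=1)
    assert (tot > 0).all() and (tot < 2 * (G1.shape[1] + G2.shape[1])).all()


def test_vcf_round_trip_frequencies(demo_bundle):
    """Sample frequencies from the written VCF converge to planted ones."""
    from fstenrich.fst import allele_counts_from_vcf

    counts, stats = allele_counts_from_vcf(demo_bundle["paths"]["vcf"],
                                           demo_bundle["samples1"],
                                           demo_bundle["samples2"])
    assert stats["kept"] == len(counts)
    truth = demo_bundle["truth"].sites
    merged = counts.merge(truth.assign(pos=truth["pos0"] + 1),
                          on=["chrom", "pos"], how="left")
    assert merged["p1"].notna().all()
    emp1 = merged["alt1"] / merged["called1"]
    # binomial sampling noise with ~76 chromosomes
    resid = emp1 - merged["p1"]
    assert abs(resid.mean()) < 0.01
    assert resid.std() < 0.08


def test_vcf_sample_columns(demo_bundle, demo_config):
    header = None
    with open(demo_bundle["paths"]["vcf"]) as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                header = line.rstrip("\n").split("\t")
                break
    n_samples = len(header) - 9
    assert n_samples == demo_config.n_samples_pop1 + demo_config.n_samples_pop2 == 79
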