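"""F_ST estimators, top-quantile selection and binning."""

from fractions import Fraction as Fr

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fstenrich.fst import (DEFAULT_BIN_EDGES, bin_fst, compute_fst,
                           hudson_components, hudson_ratio_of_averages,
                           select_hd, weir_cockerham_components)

# ---------------------------------------------------------------------------
# independent scalar transcriptions of both estimators (exact rationals)
# ---------------------------------------------------------------------------

def wc_oracle(alt1, c1, alt2, c2):
    p1, p2 = Fr(alt1, c1), Fr(alt2, c2)
    n1, n2 = Fr(c1, 2), Fr(c2, 2)
    ns = n1 + n2
    nbar = ns / 2
    nc = ns - (n1 ** 2 + n2 ** 2) / ns
    pbar = (n1 * p1 + n2 * p2) / ns
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * 2 * p1 * (1 - p1) + n2 * 2 * p2 * (1 - p2)) / ns
    pq = pbar * (1 - pbar)
    a = nbar / nc * (s2 - (pq - s2 / 2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pq - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, a + b + c


def hudson_oracle(alt1, c1, alt2, c2):
    p1, p2 = Fr(alt1, c1), Fr(alt2, c2)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (c1 - 1) - p2 * (1 - p2) / (c2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def counts_frame(alt1, c1, alt2, c2):
    return pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, len(np.atleast_1d(alt1)) + 1),
                         "alt1": alt1, "called1": c1, "alt2": alt2, "called2": c2})


# ---------------------------------------------------------------------------

def test_opposite_fixation_gives_one():
    for est in ("weir_cockerham", "hudson"):
        rec, _ = compute_fst(counts_frame([76], [76], [0], [82]), estimator=est)
        assert rec["fst"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_equal_frequencies_clamp_to_zero():
    for est in ("weir_cockerham", "hudson"):
        rec, _ = compute_fst(counts_frame([10], [20], [21], [42]), estimator=est)
        assert rec["fst"].iloc[0] == 0.0
        assert rec["fst_raw"].iloc[0] <= 0.0


def test_weir_cockerham_regression_constant():
    """Frozen from the exact rational transcription of the a/b/c components."""
    rec, _ = compute_fst(counts_frame([16], [20], [4], [20]))
    assert rec["fst"].iloc[0] == pytest.approx(0.503267973856209, rel=1e-12)
    a, den = wc_oracle(16, 20, 4, 20)
    assert (a, den) == (Fr(77, 450), Fr(17, 50))


def test_hudson_regression_constant():
    """N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) = 163/475, D = 17/25."""
    rec, _ = compute_fst(counts_frame([16], [20], [4], [20]), estimator="hudson")
    assert rec["numerator"].iloc[0] == pytest.approx(163 / 475, rel=1e-12)
    assert rec["denominator"].iloc[0] == pytest.approx(17 / 25, rel=1e-12)
    assert rec["fst"].iloc[0] == pytest.approx(0.504643962848297, rel=1e-12)


def test_estimators_match_oracles_on_random_counts(rng):
    """Both vectorized estimators agree with the exact transcriptions."""
    n = 1000
    c1 = 2 * rng.integers(1, 60, n)
    c2 = 2 * rng.integers(1, 60, n)
    alt1 = rng.integers(0, c1 + 1)
    alt2 = rng.integers(0, c2 + 1)
    poly = (alt1 + alt2 > 0) & (alt1 + alt2 < c1 + c2)
    # WC is undefined when both populations hold a single diploid (nbar = 1)
    poly &= ~((c1 == 2) & (c2 == 2))
    c1, c2, alt1, alt2 = c1[poly], c2[poly], alt1[poly], alt2[poly]
    _, _, wnum, wden = weir_cockerham_components(alt1, c1, alt2, c2)
    _, _, hnum, hden = hudson_components(alt1, c1, alt2, c2)
    for i in range(len(c1)):
        a, den = wc_oracle(int(alt1[i]), int(c1[i]), int(alt2[i]), int(c2[i]))
        assert wnum[i] == pytest.approx(float(a), rel=1e-12, abs=1e-15)
        assert wden[i] == pytest.approx(float(den), rel=1e-12, abs=1e-15)
        hn, hd = hudson_oracle(int(alt1[i]), int(c1[i]), int(alt2[i]), int(c2[i]))
        assert hnum[i] == pytest.approx(float(hn), rel=1e-12, abs=1e-15)
        assert hden[i] == pytest.approx(float(hd), rel=1e-12, abs=1e-15)


def test_clamp_bounds_and_exact_ratio(rng):
    c1 = 2 * rng.integers(1, 40, 500)
    c2 = 2 * rng.integers(1, 40, 500)
    alt1 = rng.integers(0, c1 + 1)
    alt2 = rng.integers(0, c2 + 1)
    df = counts_frame(alt1, c1, alt2, c2)
    tot = df["alt1"] + df["alt2"]
    df = df[(tot > 0) & (tot < df["called1"] + df["called2"])]
    for est in ("weir_cockerham", "hudson"):
        rec, _ = compute_fst(df.reset_index(drop=True), estimator=est)
        assert ((rec["fst"] >= 0) & (rec["fst"] <= 1)).all()
        np.testing.assert_allclose(rec["fst_raw"],
                                   rec["numerator"] / rec["denominator"], rtol=0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(2, 50), st.integers(2, 50), st.integers(0, 100))
def test_monotone_in_frequency_gap(n1d, n2d, a2_pct):
    """With p2 fixed, F_ST is non-decreasing in p1 moving away from p2."""
    c1, c2 = 2 * n1d, 2 * n2d
    alt2 = round(a2_pct / 100 * c2)
    p2 = alt2 / c2
    alts = np.arange(0, c1 + 1)
    keep = (alts + alt2 > 0) & (alts + alt2 < c1 + c2)
    alts = alts[keep]
    _, _, num, den = hudson_components(alts, np.full_like(alts, c1),
                                       np.full_like(alts, alt2), np.full_like(alts, c2))
    fst = np.clip(num / den, 0, 1)
    p1 = alts / c1
    above = p1 >= p2
    assert np.all(np.diff(fst[above]) >= -1e-12)
    assert np.all(np.diff(fst[~above][::-1]) >= -1e-12)


def test_insufficient_called_dropped():
    df = counts_frame([1, 5], [0, 20], [1, 3], [4, 20])
    rec, drops = compute_fst(df)
    assert drops["dropped_insufficient_called"] == 1
    assert len(rec) == 1 and rec["pos"].iloc[0] == 2


def test_select_hd_basic(rng):
    values = rng.permutation(np.linspace(0.001, 1.0, 1000))
    df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1000) + 1, "fst": values})
    hd = select_hd(df, 0.01)
    assert hd.n_selected == 10
    assert hd.threshold == pytest.approx(np.sort(values)[-10])
    assert not hd.has_ties
    assert set(df["fst"].iloc[hd.index]) == set(np.sort(values)[-10:])


def test_select_hd_all_tied():
    df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(100) + 1, "fst": 1.0})
    hd = select_hd(df, 0.01)
    assert hd.n_selected == 100 and hd.has_ties


def test_select_hd_empty_errors():
    with pytest.raises(ValueError):
        select_hd(pd.DataFrame({"fst": []}), 0.01)


def test_bin_boundaries():
    labels = bin_fst([1.0, 0.95, 0.9, 0.89999, 0.5, 0.0])
    assert labels[0] == "=1"
    assert labels[1] == "[0.9,1)"
    assert labels[2] == "[0.9,1)"       # left-closed
    assert labels[3] == "[0.8,0.9)"
    assert labels[4] == "[0.5,0.6)"
    assert labels[5] == "[0,0.5)"


def test_bin_bad_edges():
    with pytest.raises(ValueError):
        bin_fst([0.5], edges=[0.0, 0.5, 0.5, 1.0])
    with pytest.raises(ValueError):
        bin_fst([0.5], edges=[0.1, 0.5, 1.0])


def test_hudson_ratio_of_averages_recovers_planted_divergence():
    """Mean Hudson F_ST over background sites ~= the planted F (Balding–Nichols)."""
    from fstenrich.synthetic import (SyntheticConfig, allele_counts_from_matrices,
                                     simulate_annotation, simulate_genotypes,
                                     simulate_site_frequencies)

    cfg = SyntheticConfig(n_chromosomes=1, chrom_length=4_000_000, n_genes=10,
                          n_sites=15_000, f_background=0.25, seed=21)
    ann, peaks = simulate_annotation(cfg)
    truth = simulate_site_frequencies(cfg, ann, peaks)
    G1, G2 = simulate_genotypes(truth, cfg)
    counts = allele_counts_from_matrices(G1, G2, truth.sites)
    est = hudson_ratio_of_averages(counts)
    # 3 SEs of the per-site ratio spread, conservative for the pooled ratio
    assert est == pytest.approx(0.25, abs=0.015)
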