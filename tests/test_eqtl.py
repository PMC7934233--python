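"""cis pairing, OLS association, BH FDR, top-eSNP rules, model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sceqtl as sq
from sceqtl.eqtl import bh_fdr, top_esnps
from conftest import bh_bruteforce, ols_oracle


# ---------------------------------------------------------------------------
# cis pair enumeration
# ---------------------------------------------------------------------------

def test_cis_window_boundaries_and_maf_threshold():
    genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["1"],
                          "start": [2_000_000], "end": [2_010_000]})
    snps = pd.DataFrame({
        "snp_id": ["at_edge", "outside", "low_maf", "wrong_chrom", "at_maf"],
        "chrom": ["1", "1", "1", "2", "1"],
        "pos": [1_000_000, 999_999, 2_000_000, 2_000_000, 2_005_000],
        "maf": [0.3, 0.3, 0.04, 0.3, 0.05],
    })
    pairs = sq.enumerate_cis_pairs(genes, snps)
    got = set(pairs["snp_id"])
    assert got == {"at_edge"}   # inclusive window edge; strict MAF (> 0.05)


# ---------------------------------------------------------------------------
# single-pair OLS
# ---------------------------------------------------------------------------

def test_fit_eqtl_perfect_fit():
    g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], dtype=float)
    y = (g - g.mean()) / g.std(ddof=1)
    fit = sq.fit_eqtl(y, g)
    assert fit.beta > 0
    assert fit.pvalue < 1e-12


def test_fit_eqtl_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(8, 60)
        k = rng.integers(0, 3)
        g = rng.binomial(2, rng.uniform(0.1, 0.5), size=n).astype(float)
        if np.ptp(g) == 0:
            continue
        C = rng.normal(size=(n, k))
        y = rng.normal(size=n) + 0.4 * g
        fit = sq.fit_eqtl(y, g, C if k else None)
        X = np.column_stack([np.ones(n), g, C])
        beta, se, t, p = ols_oracle(y, X)
        assert fit.beta == pytest.approx(beta, abs=1e-10)
        assert fit.se == pytest.approx(se, abs=1e-10)
        assert fit.tstat == pytest.approx(t, abs=1e-8)
        assert fit.pvalue == pytest.approx(p, abs=1e-10)


def test_fit_eqtl_rejects_constant_genotype():
    with pytest.raises(ValueError, match="constant genotype"):
        sq.fit_eqtl(np.arange(5.0), np.ones(5))


def test_batch_mapper_equals_single_pair_fits(small_dataset, mito_ribo):
    mito, ribo = mito_ribo
    d = small_dataset
    kept, _ = sq.apply_qc(d["cells"], mito, ribo)
    pb = {ct: sq.normalize_chain(m) for ct, m in sq.aggregate_mean(kept).items()}
    fac = {ct: sq.fit_latent_factor(m) for ct, m in pb.items()}
    snps = d["snps"].drop(columns=["maf"]).merge(
        sq.compute_maf(d["geno"]), left_on="snp_id", right_index=True)
    pairs = sq.enumerate_cis_pairs(d["ann"], snps).head(200)
    rec, _ = sq.map_celltype_eqtls(pb, d["geno"], pairs, fac)
    sub = rec.sample(30, random_state=0)
    for row in sub.itertuples(index=False):
        m = pb[row.cell_type]
        y = m.values[row.gene_id].to_numpy()
        g = d["geno"].loc[m.donors, row.snp_id].to_numpy(float)
        C = fac[row.cell_type].values.loc[m.donors].to_numpy()
        fit = sq.fit_eqtl(y, g, C)
        assert row.beta == pytest.approx(fit.beta, abs=1e-10)
        assert row.pvalue == pytest.approx(fit.pvalue, abs=1e-10)


def test_null_pvalues_uniform_at_small_n():
    rng = np.random.default_rng(1)
    from scipy import stats
    ps = []
    for _ in range(10_000):
        g = rng.binomial(2, 0.3, size=100).astype(float)
        if np.ptp(g) == 0:
            continue
        y = rng.normal(size=100)
        ps.append(sq.fit_eqtl(y, g).pvalue)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def test_bh_hand_example_and_edge_cases():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
    np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_bh_matches_bruteforce_and_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(2)
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 40))
        q = bh_fdr(p)
        np.testing.assert_array_equal(q, bh_bruteforce(p))
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], rtol=0, atol=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.floats(0, 1))
def test_bh_qvalue_properties(plist, extra):
    p = np.asarray(plist + [extra])
    q = bh_fdr(p)
    assert ((q >= p - 1e-15) & (q <= 1.0)).all()  # q >= p, capped at 1
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-15).all()    # monotone in p-rank


# ---------------------------------------------------------------------------
# top eSNP selection and degenerate mapping outputs
# ---------------------------------------------------------------------------

def test_top_esnp_tie_breaking():
    rec = pd.DataFrame({
        "cell_type": ["A"] * 3, "gene_id": ["g"] * 3,
        "snp_id": ["s1", "s2", "s3"], "n_donors": 10,
        "beta": [0.5, -0.9, 0.9], "se": 1.0, "tstat": 1.0,
        "pvalue": [0.01, 0.001, 0.001], "fdr": 0.05, "significant": True,
    })
    snps = pd.DataFrame({"snp_id": ["s1", "s2", "s3"], "pos": [300, 200, 100]})
    top = top_esnps(rec, snps)
    # lowest p first (s2, s3 tie), |beta| ties too -> smallest position wins
    assert top["snp_id"].iloc[0] == "s3"


def test_mapping_with_zero_significant_pairs_is_valid(small_dataset, mito_ribo):
    mito, ribo = mito_ribo
    d = small_dataset
    kept, _ = sq.apply_qc(d["cells"], mito, ribo)
    pb = {ct: sq.normalize_chain(m) for ct, m in sq.aggregate_mean(kept).items()}
    snps = d["snps"].drop(columns=["maf"]).merge(
        sq.compute_maf(d["geno"]), left_on="snp_id", right_index=True)
    pairs = sq.enumerate_cis_pairs(d["ann"], snps).head(20)
    rec, eg = sq.map_celltype_eqtls(pb, d["geno"], pairs, None,
                                    fdr_threshold=1e-12)
    assert not rec["significant"].any()
    assert eg.empty
    assert (rec["fdr"] >= rec["pvalue"] - 1e-15).all()


# ---------------------------------------------------------------------------
# five-way model comparison
# ---------------------------------------------------------------------------

def test_compare_models_detects_planted_effect_and_mixed_is_calibrated():
    """Pseudobulk models detect the planted eQTL; under strong donor
    confounding the random-intercept cell-level models stay calibrated while
    naive cell-level OLS is inflated."""
    panel = sq.SnpPanelSpec(n_snps=12, spacing=200_000, maf_range=(0.2, 0.4))
    geno, snps = sq.simulate_genotypes(panel, 25, seed=2)
    cfg = sq.SimulationConfig(n_donors=25, cell_types=["A"],
                              cells_per_donor_per_type=30, n_genes=40,
                              donor_sd=0.8, seed=2)
    genes = sq.gene_ids_for(cfg)
    ann = sq.make_annotation(genes["gene_id"], snps)
    eff = [sq.EffectSpec("G0001", ann["anchor_snp"].iloc[0], ["A"], 1.2)]
    cells = sq.simulate_cells(geno, eff, cfg)

    null_snps = [s for s in snps["snp_id"] if s != ann["anchor_snp"].iloc[0]]
    pairs = pd.DataFrame(
        {"gene_id": ["G0001"] + [f"G{i + 2:04d}" for i in range(10)],
         "snp_id": [ann["anchor_snp"].iloc[0]] + list(null_snps[:10])})
    table = sq.compare_models(cells, geno, pairs)
    assert set(table["model"]) == {"pseudobulk_0f", "pseudobulk_1f",
                                   "pseudobulk_10f", "cells_qnz_ranef",
                                   "cells_raw_ranef"}
    records = table.attrs["records"]
    planted = records["pseudobulk_1f"]
    hit = planted[(planted.gene_id == "G0001")]
    assert hit["significant"].any()

    # calibration contrast under donor confounding: cell-level random
    # intercept vs naive cell-level OLS on null (gene, SNP) combinations
    from sceqtl.eqtl import _mixed_model_p
    X = np.asarray(cells.X.todense(), float)
    donors = cells.obs["donor"].to_numpy()
    rng = np.random.default_rng(9)
    mixed_p, ols_p = [], []
    while len(mixed_p) < 40:
        gene = rng.integers(1, 40)   # skip the planted gene at index 0
        snp = null_snps[rng.integers(len(null_snps))]
        y = X[:, gene]
        g_cell = geno.loc[donors, snp].to_numpy(float)
        if np.ptp(g_cell) == 0 or y.std() == 0:
            continue
        mixed_p.append(_mixed_model_p(y, g_cell, donors)[1])
        ols_p.append(sq.fit_eqtl(y, g_cell).pvalue)
    mixed_p, ols_p = np.array(mixed_p), np.array(ols_p)
    assert (ols_p < 0.05).mean() > (mixed_p < 0.05).mean()  # OLS inflated
    assert (ols_p < 0.05).mean() > 0.15
    assert np.median(mixed_p) > 0.2                         # mixed calibrated


def test_compare_models_skips_ten_factors_when_too_few_donors():
    panel = sq.SnpPanelSpec(n_snps=6, spacing=200_000, maf_range=(0.3, 0.4))
    geno, snps = sq.simulate_genotypes(panel, 8, seed=3)
    cfg = sq.SimulationConfig(n_donors=8, cell_types=["A"],
                              cells_per_donor_per_type=10, n_genes=20, seed=3)
    cells = sq.simulate_cells(geno, [], cfg)
    pairs = pd.DataFrame({"gene_id": ["G0001"], "snp_id": [snps["snp_id"].iloc[0]]})
    table = sq.compare_models(cells, geno, pairs)
    assert "pseudobulk_10f" not in set(table["model"])
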