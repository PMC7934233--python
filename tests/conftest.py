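import numpy as np
import pandas as pd
import pytest

import sceqtl as sq


@pytest.fixture(scope="session")
def small_panel():
    """40-SNP panel with two LD blocks, 30 donors."""
    panel = sq.SnpPanelSpec(
        n_snps=40, spacing=100_000, maf_range=(0.2, 0.4),
        ld_blocks=[{"block_size": 4, "copy_prob": 0.9}] * 2)
    geno, snps = sq.simulate_genotypes(panel, 30, seed=11)
    return geno, snps


@pytest.fixture(scope="session")
def small_dataset(small_panel):
    """30 donors x 2 cell types x 30 cells, 80 genes, one planted effect."""
    geno, snps = small_panel
    cfg = sq.SimulationConfig(
        n_donors=30, cell_types=["A", "B"], cells_per_donor_per_type=30,
        n_genes=80, n_outlier_cells=4, seed=11)
    genes = sq.gene_ids_for(cfg)
    ann = sq.make_annotation(genes["gene_id"], snps)
    effects = [sq.EffectSpec("G0001", ann["anchor_snp"].iloc[0], ["A"], 1.0,
                             "specific")]
    cells = sq.simulate_cells(geno, effects, cfg)
    return {"geno": geno, "snps": snps, "ann": ann, "cells": cells,
            "cfg": cfg, "effect_snp": ann["anchor_snp"].iloc[0]}


@pytest.fixture()
def mito_ribo(small_dataset):
    cells = small_dataset["cells"]
    return (set(cells.var_names[cells.var["is_mito"]]),
            set(cells.var_names[cells.var["is_ribo"]]))


@pytest.fixture(scope="session")
def hand_vcf(tmp_path_factory):
    """Hand-coded 3-donor, 2-SNP VCF with known reference-dosage table."""
    text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\n"
    )
    path = tmp_path_factory.mktemp("vcf") / "hand.vcf"
    path.write_text(text)
    # reference-allele dosages: 0/0 -> 2, 0/1 -> 1, 1/1 -> 0
    expected = pd.DataFrame([[2, 1], [1, 1], [0, 2]],
                            index=["S1", "S2", "S3"], columns=["rs1", "rs2"])
    return path, expected


def ols_oracle(y, X):
    """Normal-equations OLS: beta, se, t, two-sided p for column 1."""
    from scipy import stats
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return beta[1], se, t, p


def bh_bruteforce(p):
    """Literal BH step-up: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_idx in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_idx, m)]
        q[order[rank_idx]] = min(min(candidates), 1.0)
    return q
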