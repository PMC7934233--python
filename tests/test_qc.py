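"""Cell and gene QC filters: hand arithmetic, boundaries, degenerate guards."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import sceqtl as sq
from sceqtl.qc import (compute_qc_metrics, gene_prevalence_filter,
                       mad_outlier_filter, threshold_filter)


def _adata(counts, gene_ids, cell_ids=None):
    counts = np.asarray(counts)
    cell_ids = cell_ids or [f"c{i}" for i in range(counts.shape[0])]
    a = ad.AnnData(X=sp.csr_matrix(counts),
                   obs=pd.DataFrame(index=cell_ids),
                   var=pd.DataFrame(index=gene_ids))
    return a


def test_metrics_hand_arithmetic():
    # three cells with listed counts over genes [mt, rp, g1, g2]
    a = _adata([[10, 0, 90, 0],
                [0, 0, 0, 0],
                [5, 45, 25, 25]], ["mt1", "rp1", "g1", "g2"])
    m = compute_qc_metrics(a, {"mt1"}, {"rp1"})
    assert m.loc["c0", "library_size"] == 100
    assert m.loc["c0", "pct_mito"] == pytest.approx(10.0)
    assert m.loc["c0", "n_genes_detected"] == 2
    # all-zero cell: percentages are 0 by convention
    assert m.loc["c1", "library_size"] == 0
    assert m.loc["c1", "pct_mito"] == 0.0
    assert m.loc["c2", "pct_ribo"] == pytest.approx(45.0)
    with pytest.raises(ValueError, match="unknown gene"):
        compute_qc_metrics(a, {"absent"}, set())


def test_mad_filter_degenerate_and_extreme():
    # identical metric values: MAD = 0 -> guard removes nobody
    m = pd.DataFrame({"library_size": [100.0] * 5, "n_genes_detected": [10] * 5,
                      "pct_mito": [1.0] * 5, "pct_ribo": [2.0] * 5})
    assert not mad_outlier_filter(m).any().any()
    # one 100x library cell among jittered normals fails
    libs = [99, 100, 101, 100, 99, 101, 100, 99, 101, 100, 10000]
    m = pd.DataFrame({"library_size": libs, "n_genes_detected": [5] * 11,
                      "pct_mito": [1.0] * 11, "pct_ribo": [1.0] * 11})
    fails = mad_outlier_filter(m)["mad_library_size"]
    assert fails.iloc[-1] and fails.iloc[:-1].sum() == 0
    # k = inf removes nobody
    assert not mad_outlier_filter(m, k=np.inf).any().any()
    with pytest.raises(ValueError, match=">= 3 cells"):
        mad_outlier_filter(m.iloc[:2])


def test_threshold_filter_strict_boundaries():
    m = pd.DataFrame({"pct_mito": [25.0, 20.0, 5.0], "pct_ribo": [10.0, 10.0, 51.0]})
    f = threshold_filter(m)
    assert f["pct_mito_above_max"].tolist() == [True, False, False]
    assert f["pct_ribo_above_max"].tolist() == [False, False, True]


def test_gene_prevalence_boundaries():
    # 200 cells: a gene in exactly 2 cells (1%) is retained, 1 cell removed
    X = np.zeros((200, 3), dtype=int)
    X[:2, 0] = 1      # exactly 1% -> keep (strict "<")
    X[0, 1] = 1       # 0.5% -> remove
    a = _adata(X, ["g_at_1pct", "g_rare", "g_absent"])
    low = gene_prevalence_filter(a, min_frac=0.01)
    assert low.tolist() == [False, True, True]


def test_threshold_rule_is_cellwise_independent():
    # removing any cell leaves other cells' threshold pass/fail unchanged
    rng = np.random.default_rng(0)
    m = pd.DataFrame({"pct_mito": rng.uniform(0, 40, 30),
                      "pct_ribo": rng.uniform(0, 60, 30)})
    full = threshold_filter(m)
    drop = m.drop(index=7)
    again = threshold_filter(drop)
    pd.testing.assert_frame_equal(full.drop(index=7), again)


def test_full_qc_is_near_fixed_point(small_dataset, mito_ribo):
    """Re-applying the full QC to its own output changes (almost) nothing:
    threshold and prevalence rules are exactly idempotent, and only the
    re-estimated MAD bounds on the filtered distribution may trim a residual
    sliver of cells (< 1%). Each filter is evaluated once per application —
    there is no iterative re-filtering inside apply_qc."""
    mito, ribo = mito_ribo
    once, _ = sq.apply_qc(small_dataset["cells"], mito, ribo)
    twice, rep2 = sq.apply_qc(once, set(), set())
    assert twice.n_vars == once.n_vars
    assert twice.n_obs >= 0.99 * once.n_obs
    removed = rep2.summary["cells_removed_per_rule"]
    assert removed["pct_mito_above_max"] == 0
    assert removed["pct_ribo_above_max"] == 0


def test_planted_outliers_removed_and_retention(small_dataset, mito_ribo):
    mito, ribo = mito_ribo
    cells = small_dataset["cells"]
    kept, report = sq.apply_qc(cells, mito, ribo)
    outlier = cells.obs["is_outlier"].to_numpy()
    removed = ~report.cells["pass"].to_numpy()
    assert removed[outlier].all()
    assert (1 - removed[~outlier].mean()) > 0.95
    # report bookkeeping: a cell fails iff >= 1 rule names it
    rule_cols = [c for c in report.cells.columns if c != "pass"]
    assert (report.cells[rule_cols].any(axis=1) == ~report.cells["pass"]).all()
    assert report.summary["n_cells_kept"] == kept.n_obs


def test_qc_report_written_as_tsv_and_json(tmp_path, small_dataset, mito_ribo):
    mito, ribo = mito_ribo
    _, report = sq.apply_qc(small_dataset["cells"], mito, ribo)
    report.write(tmp_path)
    cells = pd.read_csv(tmp_path / "qc_cells.tsv", sep="\t")
    assert {"cell_id", "pass", "failed_rules"} <= set(cells.columns)
    import json
    summary = json.loads((tmp_path / "qc_summary.json").read_text())
    assert summary["n_cells_in"] == small_dataset["cells"].n_obs
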