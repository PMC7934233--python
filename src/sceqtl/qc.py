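"""Cell- and gene-level quality control for raw single-cell count matrices.

Cells are summarized by four metrics (library size, genes detected, percent
mitochondrial, percent ribosomal). A cell is removed if any metric deviates
from the metric's median by more than ``k`` scaled median absolute deviations
(two-sided, MAD scaled by 1.4826 for normal consistency), or if percent
mitochondrial exceeds 20 or percent ribosomal exceeds 50 (strict
inequalities). After cell filtering the provided mitochondrial/ribosomal gene
sets are dropped, then genes detected in fewer than 1% of the retained cells
are removed (strict). Each filter is evaluated once on its full input — there
is no iterative re-filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import atomic_write, write_tsv

MAD_SCALE = 1.4826

METRICS = ("library_size", "n_genes_detected", "pct_mito", "pct_ribo")


def _col_sums(X, mask):
    """Row-wise sum over a gene mask for sparse or dense X."""
    import scipy.sparse as sp
    sub = X[:, mask]
    s = sub.sum(axis=1)
    return np.asarray(s).ravel() if sp.issparse(sub) else np.asarray(s).ravel()


def compute_qc_metrics(adata, mito_gene_ids, ribo_gene_ids) -> pd.DataFrame:
    """Per-cell QC metric table (cell_id index, one column per metric).

    Percentages are 100 * (counts in the gene set / library size); all-zero
    cells get 0 by convention.
    """
    import scipy.sparse as sp

    genes = pd.Index(adata.var_names)
    for gid in set(mito_gene_ids) | set(ribo_gene_ids):
        if gid not in genes:
            raise ValueError(f"unknown gene id in mito/ribo sets: {gid}")
    X = adata.X
    lib = np.asarray(X.sum(axis=1)).ravel()
    if sp.issparse(X):
        n_det = X.getnnz(axis=1)
    else:
        n_det = (np.asarray(X) > 0).sum(axis=1)
    mito = _col_sums(X, genes.isin(set(mito_gene_ids)))
    ribo = _col_sums(X, genes.isin(set(ribo_gene_ids)))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(lib > 0, 100.0 * mito / np.maximum(lib, 1), 0.0)
        pct_ribo = np.where(lib > 0, 100.0 * ribo / np.maximum(lib, 1), 0.0)
    return pd.DataFrame({
        "library_size": lib,
        "n_genes_detected": n_det,
        "pct_mito": pct_mito,
        "pct_ribo": pct_ribo,
    }, index=adata.obs_names)


# metrics whose MAD cut is taken on log scale: library size and detected-gene
# counts are strongly right-skewed, and the R-ecosystem convention (scater's
# isOutlier) log-transforms them before the deviation test
LOG_SCALE_METRICS = ("library_size", "n_genes_detected")


def mad_outlier_filter(metrics: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Flag cells deviating > k scaled MADs from the median on any metric.

    Returns a boolean frame, one column per metric (True = fails). A metric
    with MAD == 0 removes no cell (degenerate-spread guard).
    """
    if len(metrics) < 3:
        raise ValueError("MAD filtering needs >= 3 cells")
    fails = {}
    for col in METRICS:
        x = metrics[col].to_numpy(dtype=float)
        if col in LOG_SCALE_METRICS:
            x = np.log1p(x)
        med = np.median(x)
        mad = MAD_SCALE * np.median(np.abs(x - med))
        if mad == 0 or not np.isfinite(k):
            fails[f"mad_{col}"] = np.zeros(len(x), dtype=bool)
        else:
            fails[f"mad_{col}"] = np.abs(x - med) > k * mad
    return pd.DataFrame(fails, index=metrics.index)


def threshold_filter(metrics: pd.DataFrame, mito_max: float = 20.0,
                     ribo_max: float = 50.0) -> pd.DataFrame:
    """Flag cells with pct_mito > mito_max or pct_ribo > ribo_max (strict)."""
    return pd.DataFrame({
        "pct_mito_above_max": metrics["pct_mito"].to_numpy() > mito_max,
        "pct_ribo_above_max": metrics["pct_ribo"].to_numpy() > ribo_max,
    }, index=metrics.index)


def gene_prevalence_filter(adata, min_frac: float = 0.01) -> pd.Series:
    """True where the gene is detected in < min_frac of cells (to remove)."""
    import scipy.sparse as sp
    X = adata.X
    n_cells_with = (X.getnnz(axis=0) if sp.issparse(X)
                    else (np.asarray(X) > 0).sum(axis=0))
    return pd.Series(n_cells_with < min_frac * adata.n_obs,
                     index=adata.var_names, name="low_prevalence")


@dataclass
class QcReport:
    """Per-cell and per-gene pass/fail tables plus rule-level counts."""

    cells: pd.DataFrame   # columns: pass + one bool column per rule
    genes: pd.DataFrame   # columns: pass, failed_rule
    summary: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        cells = self.cells.copy()
        rule_cols = [c for c in cells.columns if c != "pass"]
        cells["failed_rules"] = [
            ";".join(c for c in rule_cols if row[c]) for _, row in cells.iterrows()]
        write_tsv(cells.reset_index(names="cell_id")[["cell_id", "pass", "failed_rules"]],
                  outdir / "qc_cells.tsv")
        write_tsv(self.genes.reset_index(names="gene_id"), outdir / "qc_genes.tsv")
        with atomic_write(outdir / "qc_summary.json") as fh:
            json.dump(self.summary, fh, indent=2)


def apply_qc(adata, mito_gene_ids, ribo_gene_ids, mad_k: float = 3.0,
             mito_max: float = 20.0, ribo_max: float = 50.0,
             gene_min_frac: float = 0.01):
    """Full QC chain: MAD + threshold cell filters, then gene filters.

    Order: cell filters are evaluated on the raw input; the abundant
    mitochondrial/ribosomal gene sets are then discarded (so they cannot
    dominate normalization) and gene prevalence is computed on the retained
    cells. Returns ``(filtered AnnData, QcReport)``.
    """
    metrics = compute_qc_metrics(adata, mito_gene_ids, ribo_gene_ids)
    mad_fail = mad_outlier_filter(metrics, k=mad_k)
    thr_fail = threshold_filter(metrics, mito_max=mito_max, ribo_max=ribo_max)
    cell_rules = pd.concat([mad_fail, thr_fail], axis=1)
    cell_pass = ~cell_rules.any(axis=1)

    kept = adata[cell_pass.to_numpy()]
    drop_sets = kept.var_names.isin(set(mito_gene_ids) | set(ribo_gene_ids))
    kept = kept[:, ~drop_sets]
    low_prev = gene_prevalence_filter(kept, min_frac=gene_min_frac)
    kept = kept[:, ~low_prev.to_numpy()].copy()

    genes = pd.DataFrame(index=adata.var_names)
    genes["failed_rule"] = ""
    genes.loc[adata.var_names.isin(set(mito_gene_ids) | set(ribo_gene_ids)),
              "failed_rule"] = "mito_ribo_set"
    failed_prev = low_prev.index[low_prev.to_numpy()]
    genes.loc[genes.index.isin(failed_prev), "failed_rule"] = "low_prevalence"
    genes["pass"] = genes["failed_rule"] == ""

    cells = cell_rules.copy()
    cells.insert(0, "pass", cell_pass)
    summary = {
        "n_cells_in": int(adata.n_obs),
        "n_cells_kept": int(kept.n_obs),
        "n_genes_in": int(adata.n_vars),
        "n_genes_kept": int(kept.n_vars),
        "cells_removed_per_rule": {c: int(cell_rules[c].sum())
                                   for c in cell_rules.columns},
        "genes_removed_per_rule": {
            "mito_ribo_set": int((genes["failed_rule"] == "mito_ribo_set").sum()),
            "low_prevalence": int((genes["failed_rule"] == "low_prevalence").sum()),
        },
    }
    return kept, QcReport(cells=cells, genes=genes, summary=summary)
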