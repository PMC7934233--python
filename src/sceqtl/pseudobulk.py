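"""Pseudobulk aggregation and normalization of the eQTL response.

For each cell type, QC-passed cells are collapsed to the per-donor mean count
of each gene; donor rows are then quantile normalized to a common reference
distribution (the across-donor mean order statistics) and each gene is
z-transformed across donors (mean 0, sample SD 1). The top latent factor of
the normalized matrix — a probabilistic-PCA style stand-in for a one-factor
PEER fit — is the hidden-confounder covariate used by the association models.
The whole chain is deterministic: no RNG is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("sceqtl")

STAGES = ("mean", "quantile_normalized", "z_transformed")


@dataclass
class PseudobulkMatrix:
    """Donors x genes expression for one cell type at a named stage."""

    cell_type: str
    values: pd.DataFrame  # index = donors, columns = genes
    stage: str = "mean"
    constant_genes: list | None = None  # flagged zero-variance genes (z stage)

    @property
    def donors(self):
        return list(self.values.index)

    @property
    def genes(self):
        return list(self.values.columns)


@dataclass
class LatentFactors:
    """Standardized latent covariates (donors x k) for one cell type."""

    cell_type: str
    values: pd.DataFrame  # index = donors, columns = factor_1..factor_k


def aggregate_mean(adata) -> dict[str, PseudobulkMatrix]:
    """Per cell type, mean count of each gene over each donor's cells.

    Donors with zero cells of a type are absent from that type's matrix;
    a cell type with no cells at all is omitted with a warning.
    """
    out = {}
    for ct, idx in adata.obs.groupby("cell_type", observed=True).groups.items():
        sub = adata[idx]
        if sub.n_obs == 0:
            logger.warning("aggregate_mean: no cells for cell type %s", ct)
            continue
        donors = sub.obs["donor"].to_numpy()
        uniq, inv = np.unique(donors, return_inverse=True)
        M = np.zeros((len(uniq), adata.n_vars))
        np.add.at(M, inv, np.asarray(sub.X.todense())
                  if hasattr(sub.X, "todense") else np.asarray(sub.X))
        counts = np.bincount(inv, minlength=len(uniq))
        M /= counts[:, None]
        out[ct] = PseudobulkMatrix(
            cell_type=ct,
            values=pd.DataFrame(M, index=uniq, columns=adata.var_names),
            stage="mean")
    return out


def quantile_normalize(m: PseudobulkMatrix) -> PseudobulkMatrix:
    """Map each donor row to the across-donor mean order statistics.

    Every row becomes a permutation of one reference distribution (the mean
    of the row-wise sorted values); ties within a row receive the mean of the
    tied reference values.
    """
    if m.stage != "mean":
        raise ValueError(f"expected stage 'mean', got {m.stage!r}")
    X = m.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("quantile normalization needs >= 2 donors")
    ref = np.sort(X, axis=1).mean(axis=0)  # reference order statistics

    out = np.empty_like(X)
    for i in range(X.shape[0]):
        row = X[i]
        order = np.argsort(row, kind="mergesort")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # tied values all receive the mean of the reference values they span
        _, inv, cnt = np.unique(row, return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=assigned)
        out[i] = (sums / cnt)[inv]
    return PseudobulkMatrix(
        cell_type=m.cell_type,
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        stage="quantile_normalized")


def z_transform(m: PseudobulkMatrix) -> PseudobulkMatrix:
    """Center and scale each gene across donors (sample SD, n-1).

    Genes with zero variance are set to all-zero and flagged in
    ``constant_genes``.
    """
    if m.stage != "quantile_normalized":
        raise ValueError(f"expected stage 'quantile_normalized', got {m.stage!r}")
    X = m.values.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, const] = 0.0
    return PseudobulkMatrix(
        cell_type=m.cell_type,
        values=pd.DataFrame(Z, index=m.values.index, columns=m.values.columns),
        stage="z_transformed",
        constant_genes=list(np.asarray(m.values.columns)[const]))


def normalize_chain(m: PseudobulkMatrix) -> PseudobulkMatrix:
    """mean -> quantile_normalized -> z_transformed."""
    return z_transform(quantile_normalize(m))


def fit_latent_factor(m: PseudobulkMatrix, k: int = 1) -> LatentFactors:
    """Top-k left singular vectors of the normalized matrix, standardized.

    Each factor is scaled to mean 0 / SD 1; the sign is fixed so that the
    gene loading with the largest magnitude is positive, making the output
    deterministic.
    """
    if m.stage != "z_transformed":
        raise ValueError("latent factors are fit on the z_transformed stage")
    X = m.values.to_numpy(dtype=float)
    n = X.shape[0]
    if n < k + 2:
        raise ValueError(f"need >= k+2 donors to fit {k} factors (have {n})")
    if not np.any(X):
        raise ValueError("degenerate (all-zero) matrix")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    cols = {}
    for j in range(k):
        u, v = U[:, j], Vt[j]
        if v[np.argmax(np.abs(v))] < 0:
            u, v = -u, -v
        u = (u - u.mean()) / u.std(ddof=1)
        cols[f"factor_{j + 1}"] = u
    return LatentFactors(
        cell_type=m.cell_type,
        values=pd.DataFrame(cols, index=m.values.index))
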