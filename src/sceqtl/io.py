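"""Readers and writers for the standard formats used across the pipeline.

Conventions
-----------
* Genomic coordinates are 1-based inclusive everywhere (VCF/GFF convention).
* Genotype dosage counts copies of the REFERENCE allele (0, 1 or 2), which is
  the opposite of the common ALT-dosage convention. ``GT 0/0`` maps to 2.
* All file writes are atomic: content goes to a temporary file in the target
  directory which is renamed into place only on success, so partial outputs
  are never left behind.
"""

from __future__ import annotations

import logging
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("sceqtl")


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Context manager yielding a file handle; renames into place on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(genotypes: pd.DataFrame, snps: pd.DataFrame, path) -> None:
    """Write a minimal VCF 4.2 with unphased diploid GT fields.

    ``genotypes`` is donors x SNPs with values in {0,1,2} counting reference
    alleles; the GT string therefore uses allele index 0 for each counted
    reference copy (dosage 2 -> "0/0", 1 -> "0/1", 0 -> "1/1").
    """
    donors = list(genotypes.index)
    gt_for = {2: "0/0", 1: "0/1", 0: "1/1"}
    with atomic_write(path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(donors) + "\n")
        for rec in snps.itertuples(index=False):
            dosages = genotypes[rec.snp_id].to_numpy()
            gts = "\t".join(gt_for[int(d)] for d in dosages)
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.ref}\t{rec.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_genotypes(path):
    """Read a VCF into a reference-allele dosage matrix.

    Returns ``(genotypes, snps)`` where ``genotypes`` is a donors x SNPs
    DataFrame of {0,1,2} reference-allele counts and ``snps`` is a DataFrame
    with columns snp_id, chrom, pos, ref, alt, maf. Multi-allelic records and
    records with any missing genotype are dropped (counts logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    cols, rows = [], []
    n_multi = n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        g = np.asarray([gt[:2] for gt in var.genotypes], dtype=int)
        if (g < 0).any():
            n_missing += 1
            continue
        dos = (g == 0).sum(axis=1)  # reference-allele copies
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        f_ref = dos.mean() / 2.0
        rows.append((snp_id, str(var.CHROM), int(var.POS), var.REF, var.ALT[0],
                     float(min(f_ref, 1.0 - f_ref))))
        cols.append(dos)
    if n_multi or n_missing:
        logger.info("read_vcf_genotypes: dropped %d multi-allelic and %d "
                    "missing-GT records", n_multi, n_missing)
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "maf"])
    geno = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((len(donors), 0), dtype=int),
        index=donors, columns=snps["snp_id"].tolist(),
    )
    return geno, snps


# ---------------------------------------------------------------------------
# Counts (MatrixMarket triplet + features/barcodes + cell metadata)
# ---------------------------------------------------------------------------

def read_counts_mtx(mtx_path, features_path, barcodes_path, metadata_path):
    """Assemble a cells x genes AnnData from a 10x-style MTX triplet.

    The matrix on disk is features x barcodes (10x convention). Per-cell
    metadata must provide ``cell_id``, ``donor`` and ``cell_type`` columns;
    cells without metadata are rejected with a logged count.
    """
    import anndata as ad
    import scipy.io
    import scipy.sparse as sp

    mat = scipy.io.mmread(str(mtx_path)).tocsr()
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix is {mat.shape} but features/barcodes give "
            f"({len(features)}, {len(barcodes)})")
    if barcodes.duplicated().any():
        dupes = barcodes[barcodes.duplicated()].tolist()
        raise ValueError(f"duplicate cell barcodes: {dupes[:5]}")
    if features.duplicated().any():
        raise ValueError("duplicate feature ids")

    meta = pd.read_csv(metadata_path, sep="\t").set_index("cell_id")
    known = barcodes.isin(meta.index)
    if not known.all():
        logger.warning("read_counts_mtx: rejecting %d cells without metadata",
                       int((~known).sum()))
    keep_idx = np.flatnonzero(known.to_numpy())
    X = sp.csr_matrix(mat.T)[keep_idx]
    obs = meta.loc[barcodes[known.to_numpy()]].copy()
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=features))
    adata.obs_names = barcodes[known.to_numpy()].tolist()
    return adata


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV with columns gene_id, chrom, start, end."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if (ann["start"] > ann["end"]).any():
        raise ValueError("annotation has start > end")
    return ann
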