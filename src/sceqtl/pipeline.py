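"""End-to-end pipeline: QC -> pseudobulk -> cis-eQTL mapping -> specificity.

``run_pipeline`` wires the stage functions together, writes every stage's
outputs as TSV (atomically), and records a run manifest with the config
snapshot, input checksums, package versions, the seed, and per-stage row
counts. Reruns with the same inputs and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import atomic_write, read_counts_mtx, read_gene_annotation, \
    read_vcf_genotypes, write_tsv
from .qc import apply_qc
from .pseudobulk import aggregate_mean, fit_latent_factor, normalize_chain
from .eqtl import compute_maf, enumerate_cis_pairs, map_celltype_eqtls, top_esnps
from . import specificity as spec_mod

logger = logging.getLogger("sceqtl")


@dataclass
class PipelineConfig:
    # input paths
    genotypes: str = ""
    counts_mtx: str = ""
    features: str = ""
    barcodes: str = ""
    cell_metadata: str = ""
    annotation: str = ""
    outdir: str = "results"
    # QC
    mad_k: float = 3.0
    mito_max: float = 20.0
    ribo_max: float = 50.0
    gene_min_frac: float = 0.01
    # eQTL
    window_bp: int = 1_000_000
    maf_min: float = 0.05
    fdr: float = 0.10
    n_factors: int = 1
    # specificity
    r2_link: float = 0.2
    independence_alpha: float = 0.05
    interaction_fdr: float = 0.05
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gene_min_frac < 1 and 0 < self.maf_min < 0.5):
            raise ValueError("thresholds out of documented range")
        if not (0 < self.fdr < 1 and 0 < self.interaction_fdr < 1):
            raise ValueError("FDR thresholds must lie in (0, 1)")
        if self.mad_k <= 0 or self.window_bp <= 0 or self.n_perm < 1:
            raise ValueError("thresholds out of documented range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with atomic_write(path) as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _mito_ribo_sets(var: pd.DataFrame):
    """Mito/ribo gene sets from var flags or gene-symbol prefixes."""
    if {"is_mito", "is_ribo"}.issubset(var.columns):
        return (set(var.index[var["is_mito"]]), set(var.index[var["is_ribo"]]))
    idx = var.index.str.upper()
    return (set(var.index[idx.str.startswith("MT-")]),
            set(var.index[idx.str.startswith(("RPL", "RPS"))]))


def run_pipeline(config: PipelineConfig, adata=None, genotypes=None,
                 snps=None, annotation=None) -> dict:
    """Execute the full pipeline and write outputs + manifest to outdir.

    Inputs may be passed in-memory (adata/genotypes/snps/annotation) or read
    from the paths in the config. Returns the manifest dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    stage = "load"
    try:
        if genotypes is None:
            checksums["genotypes"] = _sha256(config.genotypes)
            genotypes, snps = read_vcf_genotypes(config.genotypes)
        if adata is None:
            for key in ("counts_mtx", "features", "barcodes", "cell_metadata"):
                checksums[key] = _sha256(getattr(config, key))
            adata = read_counts_mtx(config.counts_mtx, config.features,
                                    config.barcodes, config.cell_metadata)
        if annotation is None:
            checksums["annotation"] = _sha256(config.annotation)
            annotation = read_gene_annotation(config.annotation)

        stage = "qc"
        mito, ribo = _mito_ribo_sets(adata.var)
        adata_qc, qc_report = apply_qc(
            adata, mito, ribo, mad_k=config.mad_k, mito_max=config.mito_max,
            ribo_max=config.ribo_max, gene_min_frac=config.gene_min_frac)
        qc_report.write(outdir)

        stage = "pseudobulk"
        pb = {ct: normalize_chain(m) for ct, m in aggregate_mean(adata_qc).items()}
        factors = None
        if config.n_factors > 0:
            factors = {ct: fit_latent_factor(m, k=config.n_factors)
                       for ct, m in pb.items()}
        for ct, m in pb.items():
            write_tsv(m.values.reset_index(names="donor"),
                      outdir / f"pseudobulk_{ct}_z_transformed.tsv")
            if factors:
                write_tsv(factors[ct].values.reset_index(names="donor"),
                          outdir / f"factors_{ct}.tsv")

        stage = "map"
        analysis_donors = sorted({d for m in pb.values() for d in m.donors})
        snps = snps.drop(columns=["maf"], errors="ignore").merge(
            compute_maf(genotypes, analysis_donors).rename("maf"),
            left_on="snp_id", right_index=True)
        ann = annotation[annotation["gene_id"].isin(adata_qc.var_names)]
        pairs = enumerate_cis_pairs(ann, snps, config.window_bp, config.maf_min)
        records, egenes = map_celltype_eqtls(pb, genotypes, pairs, factors,
                                             config.fdr)
        egenes = top_esnps(records, snps)
        write_tsv(records, outdir / "eqtl_records.tsv")
        write_tsv(egenes, outdir / "egenes.tsv")

        stage = "specificity"
        sharing = spec_mod.classify_sharing(records, egenes, genotypes,
                                            n_cell_types=len(pb),
                                            r2_link=config.r2_link)
        indep = spec_mod.run_independence(egenes, pb, factors, genotypes,
                                          alpha=config.independence_alpha)
        inter = spec_mod.run_interactions(records, pb, factors, genotypes,
                                          fdr_threshold=config.interaction_fdr)
        expr_corr = spec_mod.egene_expression_correlation(pb, sharing)
        t_corr = spec_mod.tstat_correlation(records)
        enrich = spec_mod.run_enrichment(records, egenes, n_perm=config.n_perm,
                                         seed=config.seed)
        scen = spec_mod.assign_scenarios(sharing, indep, inter)
        write_tsv(sharing.per_gene, outdir / "sharing_per_gene.tsv")
        write_tsv(sharing.counts, outdir / "sharing_counts.tsv")
        write_tsv(indep, outdir / "independence.tsv")
        inter_out = inter.copy()
        if len(inter_out):
            inter_out["cell_type_pair"] = inter_out["cell_type_pair"].map(
                lambda t: ",".join(t))
        write_tsv(inter_out, outdir / "interactions.tsv")
        write_tsv(expr_corr, outdir / "egene_expression_correlation.tsv")
        write_tsv(t_corr, outdir / "tstat_correlation.tsv")
        write_tsv(enrich, outdir / "enrichment.tsv")
        write_tsv(scen.rename_axis("gene_id").reset_index(),
                  outdir / "scenarios.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "input_checksums": checksums,
        "versions": {"sceqtl": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "seed": config.seed,
        "stage_counts": {
            "cells_in": int(adata.n_obs),
            "cells_after_qc": int(adata_qc.n_obs),
            "genes_after_qc": int(adata_qc.n_vars),
            "cell_types": len(pb),
            "cis_pairs": int(len(pairs)),
            "eqtl_tests": int(len(records)),
            "significant_records": int(records["significant"].sum()) if len(records) else 0,
            "egenes": int(egenes["gene_id"].nunique()) if len(egenes) else 0,
            "independence_tests": int(len(indep)),
            "interaction_tests": int(len(inter)),
        },
    }
    with atomic_write(outdir / "manifest.json") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
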