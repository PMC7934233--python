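"""Synthetic multi-donor, multi-cell-type scRNA-seq and genotype generator.

Every downstream stage of the pipeline (QC, pseudobulk, cis-eQTL mapping,
specificity tests) is testable against data generated here with known planted
effects, so no external download is needed.

The generative model
--------------------
Genotypes: each SNP has a reference-allele frequency drawn from ``maf_range``;
per donor, two haplotypes are drawn as independent Bernoulli variables and the
dosage is their sum (0/1/2 reference copies, matching the dosage coding used
by the eQTL models). Linkage disequilibrium is produced by haplotype copying:
within an LD block each SNP copies the previous SNP's haplotype with
probability ``copy_prob`` per haplotype and redraws from its own allele
frequency otherwise, giving adjacent-SNP correlation r = copy_prob.

Counts: cell i, gene g is NegativeBinomial with mean
``s_i * exp(b_g + u_donor + beta_log * dosage)`` and dispersion theta
(variance mu + mu^2/theta), where s_i is a log-normal cell scaling factor,
b_g a gene base log-mean, and u_donor ~ Normal(0, donor_sd^2) a random
intercept shared across all of a donor's cells in every cell type.
Designated mitochondrial/ribosomal gene subsets receive mean boosts so
per-cell QC percentages are non-trivial, and ``n_outlier_cells`` cells get
their scaling factor inflated >= 10x the typical median to plant QC outliers.

Planted effect sizes
--------------------
``EffectSpec.beta`` is expressed on the scale the eQTL model actually fits:
quantile-normalized, z-transformed pseudobulk expression, per reference-allele
copy. Internally the effect is planted additively on the log-mean scale; the
log-scale coefficient is obtained by solving, over the realized genotype
vector, for the value whose implied regression slope on the z scale equals the
requested beta. The solve accounts for the exponential mean function evaluated
at the three dosage values, the residual noise left after averaging negative
binomial counts over cells, and the fact that quantile normalization across
donors removes the global donor intercept (a donor-wide multiplicative shift
does not change within-donor ranks). This keeps "planted beta" and "fitted
beta" on the same scale, which is what makes parameter-recovery checks
meaningful.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawns, one stream per operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import atomic_write, write_tsv, write_vcf

__all__ = [
    "SnpPanelSpec", "EffectSpec", "SimulationConfig",
    "simulate_genotypes", "simulate_cells", "write_fixture_bundle",
    "gene_ids_for", "make_annotation", "plan_scenario_effects",
    "base_log_means", "expressed_genes",
]

SCENARIOS = ("specific", "shared", "independent_loci", "interaction")


@dataclass
class SnpPanelSpec:
    """Layout of a simulated SNP panel on one chromosome."""

    n_snps: int
    chrom: str = "1"
    positions: np.ndarray | None = None  # 1-based bp, strictly increasing
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_blocks: list[dict] = field(default_factory=list)  # {block_size, copy_prob}
    spacing: int = 5_000  # used when positions is None

    def __post_init__(self):
        if self.positions is None:
            self.positions = 1 + self.spacing * np.arange(self.n_snps)
        self.positions = np.asarray(self.positions)
        if len(self.positions) != self.n_snps:
            raise ValueError("positions length must equal n_snps")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for blk in self.ld_blocks:
            if not (0 <= blk["copy_prob"] <= 1):
                raise ValueError("copy_prob must be in [0, 1]")
            if blk["block_size"] < 1:
                raise ValueError("block_size must be >= 1")


@dataclass
class EffectSpec:
    """One planted genotype effect on one gene.

    ``beta`` is in z-transformed-expression units per reference-allele copy.
    Scenarios: ``specific`` (one cell type), ``shared`` (same SNP and beta in
    several cell types), ``independent_loci`` (distinct unlinked SNPs drive the
    gene in different cell types; give ``snp_by_celltype``), ``interaction``
    (same SNP, cell type-dependent beta; give ``beta_by_celltype``).
    """

    gene_id: str
    snp_id: str | None
    cell_types: list[str]
    beta: float
    scenario: str = "specific"
    beta_by_celltype: dict[str, float] | None = None
    snp_by_celltype: dict[str, str] | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "independent_loci":
            if not self.snp_by_celltype or len(set(self.snp_by_celltype.values())) < 2:
                raise ValueError("independent_loci needs >=2 distinct (snp, cell_type) pairings")
        if self.scenario == "interaction":
            if not self.beta_by_celltype or len(set(self.beta_by_celltype.values())) < 2:
                raise ValueError("interaction needs >=2 distinct betas")

    def expand(self):
        """Yield (cell_type, snp_id, beta_z) triples."""
        if self.scenario == "independent_loci":
            for ct, snp in self.snp_by_celltype.items():
                yield ct, snp, self.beta
        elif self.scenario == "interaction":
            for ct, b in self.beta_by_celltype.items():
                yield ct, self.snp_id, b
        else:
            for ct in self.cell_types:
                yield ct, self.snp_id, self.beta


@dataclass
class SimulationConfig:
    n_donors: int = 80
    cell_types: list[str] = field(default_factory=lambda: ["A", "B", "C"])
    cells_per_donor_per_type: int = 50
    n_genes: int = 200
    nb_dispersion: float = 1.0
    donor_sd: float = 0.3
    library_size_lognormal: tuple[float, float] = (0.0, 0.35)
    frac_mito_genes: float = 0.03
    frac_ribo_genes: float = 0.05
    n_outlier_cells: int = 0
    outlier_factor: float = 12.0
    base_log_mean: tuple[float, float] = (-0.7, 1.0)  # Normal(mu, sd) for b_g
    mito_expr_share: float = 0.06  # expected fraction of counts from mito genes
    ribo_expr_share: float = 0.18
    seed: int = 0

    def __post_init__(self):
        if self.n_donors < 2 or self.n_genes < 1 or self.cells_per_donor_per_type < 1:
            raise ValueError("counts must be positive (n_donors >= 2)")
        if self.nb_dispersion <= 0 or self.donor_sd < 0:
            raise ValueError("dispersion must be > 0 and donor_sd >= 0")
        for f in (self.frac_mito_genes, self.frac_ribo_genes):
            if not (0 <= f < 1):
                raise ValueError("gene fractions must be in [0, 1)")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(spec: SnpPanelSpec, n_donors: int, seed: int):
    """Draw a donors x SNPs reference-dosage matrix with LD-block structure.

    Returns ``(genotypes, snps)``: a DataFrame of {0,1,2} dosages and a SNP
    table (snp_id, chrom, pos, ref, alt, maf, block) with realized MAF.
    """
    if n_donors < 2:
        raise ValueError("n_donors must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    af = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=spec.n_snps)

    # assign SNPs to LD blocks sequentially; leftover SNPs are singletons
    block_id = np.full(spec.n_snps, -1)
    copy_prob = np.zeros(spec.n_snps)
    i = 0
    for b, blk in enumerate(spec.ld_blocks):
        size = min(blk["block_size"], spec.n_snps - i)
        if size <= 0:
            break
        block_id[i:i + size] = b
        copy_prob[i:i + size] = blk["copy_prob"]
        i += size

    H = np.empty((2 * n_donors, spec.n_snps), dtype=np.int8)
    H[:, 0] = rng.random(2 * n_donors) < af[0]
    for j in range(1, spec.n_snps):
        fresh = (rng.random(2 * n_donors) < af[j]).astype(np.int8)
        same_block = block_id[j] >= 0 and block_id[j] == block_id[j - 1]
        if same_block and copy_prob[j] > 0:
            copy = rng.random(2 * n_donors) < copy_prob[j]
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
        else:
            H[:, j] = fresh
    dosage = H[0::2] + H[1::2]

    donors = [f"D{i + 1:03d}" for i in range(n_donors)]
    snp_ids = [f"snp{j + 1:05d}" for j in range(spec.n_snps)]
    f_ref = dosage.mean(axis=0) / 2.0
    snps = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": spec.chrom,
        "pos": spec.positions.astype(int),
        "ref": "A",
        "alt": "G",
        "maf": np.minimum(f_ref, 1 - f_ref),
        "block": block_id,
    })
    geno = pd.DataFrame(dosage.astype(np.int64), index=donors, columns=snp_ids)
    return geno, snps


# ---------------------------------------------------------------------------
# Planted-beta calibration (z scale -> log-mean scale)
# ---------------------------------------------------------------------------

def _zslope_given_log_beta(bl, g, base_mean, n_cells, theta, donor_sd, s_mu, s_sigma):
    """Implied z-scale regression slope for log-scale coefficient ``bl``.

    Donor-level pseudobulk for dosage g is C*exp(bl*g)*(1+eps) after quantile
    normalization strips the global donor intercept; eps collects the relative
    noise from averaging NB counts over ``n_cells`` cells with log-normal cell
    scaling factors. Moments are taken over the realized genotype vector.
    """
    Es = np.exp(s_mu + s_sigma ** 2 / 2)
    Es2_rel = np.exp(s_sigma ** 2)            # E[s^2]/E[s]^2
    cv2 = Es2_rel - 1.0
    kappa = np.exp(donor_sd ** 2 / 2)
    w = np.exp(bl * g)
    mu_cell = base_mean * Es * kappa * w.mean()
    v_n = (1.0 / n_cells) * (1.0 / mu_cell + Es2_rel / theta + cv2)
    m1 = w.mean()
    m2 = (w * w).mean()
    cov = (g * w).mean() - g.mean() * m1
    var_y = m2 * (1.0 + v_n) - m1 * m1
    vg = g.var()
    return cov / (vg * np.sqrt(var_y))


def _log_beta_for_z_target(beta_z, g, base_mean, n_cells, theta, donor_sd, s_mu, s_sigma):
    if beta_z == 0:
        return 0.0
    if g.var() == 0:
        raise ValueError("effect SNP is monomorphic in the donor panel")
    args = (g, base_mean, n_cells, theta, donor_sd, s_mu, s_sigma)
    f = lambda bl: _zslope_given_log_beta(bl, *args) - beta_z

    lo, hi = (0.0, 1e-3) if beta_z > 0 else (-1e-3, 0.0)
    while hi - lo < 40.0:  # the slope saturates well before |bl| = 20
        if beta_z > 0 and f(hi) > 0:
            return brentq(f, lo, hi, xtol=1e-10)
        if beta_z < 0 and f(lo) < 0:
            return brentq(f, lo, hi, xtol=1e-10)
        lo, hi = (hi, hi * 2) if beta_z > 0 else (lo * 2, lo)
    raise ValueError(
        f"requested beta={beta_z} is not reachable for this SNP "
        "(z-scale slope saturates below the target)")


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

def gene_ids_for(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene id table (gene_id, is_mito, is_ribo) for a config."""
    n_mito = int(round(config.frac_mito_genes * config.n_genes))
    n_ribo = int(round(config.frac_ribo_genes * config.n_genes))
    n_reg = config.n_genes - n_mito - n_ribo
    ids = ([f"G{i + 1:04d}" for i in range(n_reg)]
           + [f"MT-G{i + 1}" for i in range(n_mito)]
           + [f"RPL-G{i + 1}" for i in range(n_ribo)])
    return pd.DataFrame({
        "gene_id": ids,
        "is_mito": [False] * n_reg + [True] * n_mito + [False] * n_ribo,
        "is_ribo": [False] * (n_reg + n_mito) + [True] * n_ribo,
    })


def base_log_means(config: SimulationConfig) -> pd.Series:
    """Deterministic per-gene base log-mean b_g for a config (same stream the
    simulator uses), including the mito/ribo share rescale.

    Planners use this to place effects on adequately expressed genes — the
    same restriction real studies make by mapping eQTLs only for detected
    genes; for a very lowly expressed gene the pseudobulk noise floor can make
    a large standardized effect unreachable.
    """
    genes = gene_ids_for(config)
    r_gene = np.random.default_rng(np.random.SeedSequence([config.seed, 202]).spawn(5)[0])
    mu_b, sd_b = config.base_log_mean
    b_g = r_gene.normal(mu_b, sd_b, size=config.n_genes)
    is_m = genes["is_mito"].to_numpy()
    is_r = genes["is_ribo"].to_numpy()
    reg_sum = np.exp(b_g[~is_m & ~is_r]).sum()
    other = 1.0 - config.mito_expr_share - config.ribo_expr_share
    for mask, share in ((is_m, config.mito_expr_share),
                        (is_r, config.ribo_expr_share)):
        if mask.any() and share > 0:
            target = share / other * reg_sum
            b_g[mask] += np.log(target / np.exp(b_g[mask]).sum())
    return pd.Series(b_g, index=genes["gene_id"], name="base_log_mean")


def expressed_genes(config: SimulationConfig, low_q: float = 0.4,
                    high_q: float = 0.9) -> list[str]:
    """Regular (non-mito/ribo) gene ids with base expression between the two
    quantiles; the natural target set for planted effects.

    Very lowly expressed genes are excluded because the pseudobulk noise
    floor makes large standardized effects unreachable; the most extreme
    highly expressed genes are excluded because they pin the top within-donor
    ranks, where quantile normalization is locally degenerate and flattens
    across-donor variation.
    """
    genes = gene_ids_for(config)
    b = base_log_means(config)
    regular = genes.loc[~genes["is_mito"] & ~genes["is_ribo"], "gene_id"]
    b_reg = b.loc[regular]
    lo, hi = b_reg.quantile(low_q), b_reg.quantile(high_q)
    return list(b_reg[(b_reg >= lo) & (b_reg <= hi)].index)


def simulate_cells(genotypes: pd.DataFrame, effects: list[EffectSpec],
                   config: SimulationConfig):
    """Generate a cells x genes AnnData with planted eQTL effects.

    ``obs`` carries donor, cell_type and the planted outlier flag; ``var``
    carries mito/ribo flags; ``uns['truth']`` records each planted
    (gene, cell_type, snp) with the z-scale target beta and the log-scale
    coefficient actually planted.
    """
    import anndata as ad
    import scipy.sparse as sp

    genes = gene_ids_for(config)
    gene_index = {g: i for i, g in enumerate(genes["gene_id"])}
    ct_index = {c: i for i, c in enumerate(config.cell_types)}
    donors = list(genotypes.index)
    if config.n_donors != len(donors):
        raise ValueError("config.n_donors must match the genotype matrix")

    for eff in effects:
        for ct, snp, _ in eff.expand():
            if eff.gene_id not in gene_index:
                raise ValueError(f"unknown gene id in effects: {eff.gene_id}")
            if snp not in genotypes.columns:
                raise ValueError(f"unknown snp id in effects: {snp}")
            if ct not in ct_index:
                raise ValueError(f"unknown cell type in effects: {ct}")

    ss = np.random.SeedSequence([config.seed, 202])
    _, r_donor, r_cell, r_counts, r_out = (
        np.random.default_rng(s) for s in ss.spawn(5))

    b_g = base_log_means(config).to_numpy()
    u_d = r_donor.normal(0.0, config.donor_sd, size=len(donors))

    s_mu, s_sigma = config.library_size_lognormal
    theta = config.nb_dispersion
    n_cells_per = config.cells_per_donor_per_type

    # per (gene, cell type): planted log-scale coefficient and its SNP column
    beta_log = np.zeros((config.n_genes, len(config.cell_types)))
    eff_snp = np.full((config.n_genes, len(config.cell_types)), -1, dtype=int)
    snp_cols = {s: i for i, s in enumerate(genotypes.columns)}
    G = genotypes.to_numpy(dtype=float)
    truth_rows = []
    for eff in effects:
        gi = gene_index[eff.gene_id]
        for ct, snp, bz in eff.expand():
            g_vec = G[:, snp_cols[snp]]
            bl = _log_beta_for_z_target(
                bz, g_vec, float(np.exp(b_g[gi])), n_cells_per, theta,
                config.donor_sd, s_mu, s_sigma)
            ci = ct_index[ct]
            beta_log[gi, ci] = bl
            eff_snp[gi, ci] = snp_cols[snp]
            truth_rows.append((eff.gene_id, ct, snp, eff.scenario, bz, bl))

    n_types = len(config.cell_types)
    n_cells = len(donors) * n_types * n_cells_per
    donor_idx = np.repeat(np.arange(len(donors)), n_types * n_cells_per)
    type_idx = np.tile(np.repeat(np.arange(n_types), n_cells_per), len(donors))
    s_cell = r_cell.lognormal(s_mu, s_sigma, size=n_cells)

    is_outlier = np.zeros(n_cells, dtype=bool)
    if config.n_outlier_cells:
        out = r_out.choice(n_cells, size=config.n_outlier_cells, replace=False)
        is_outlier[out] = True
        s_cell[out] *= config.outlier_factor

    # cell x gene log-mean: base + donor intercept + genotype effect
    log_mu = np.tile(b_g, (n_cells, 1))
    log_mu += u_d[donor_idx][:, None]
    for gi, ci in zip(*np.nonzero(eff_snp >= 0)):
        mask = type_idx == ci
        log_mu[mask, gi] += beta_log[gi, ci] * G[donor_idx[mask], eff_snp[gi, ci]]

    mu = s_cell[:, None] * np.exp(log_mu)
    lam = r_counts.gamma(theta, mu / theta)
    counts = r_counts.poisson(lam).astype(np.int64)

    cell_types = np.asarray(config.cell_types, dtype=object)
    obs = pd.DataFrame({
        "donor": np.asarray(donors, dtype=object)[donor_idx],
        "cell_type": cell_types[type_idx],
        "is_outlier": is_outlier,
    })
    obs.index = [f"{d}_{c}_{i}" for i, (d, c) in
                 enumerate(zip(obs["donor"], obs["cell_type"]))]
    var = genes.set_index("gene_id")[["is_mito", "is_ribo"]]
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.uns["truth"] = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "cell_type", "snp_id", "scenario", "beta_z", "beta_log"])
    adata.uns["seed"] = config.seed
    return adata


# ---------------------------------------------------------------------------
# Annotation + scenario planning
# ---------------------------------------------------------------------------

def make_annotation(gene_ids, snps: pd.DataFrame, width: int = 1000) -> pd.DataFrame:
    """Anchor each gene to a SNP position, round-robin across the panel.

    Gene i starts at the position of SNP ``(i * stride) % n_snps`` so every
    gene has cis SNPs and effect SNPs can be chosen at the gene's anchor.
    """
    pos = snps["pos"].to_numpy()
    n = len(pos)
    stride = max(1, n // max(1, len(gene_ids)))
    anchors = [(i * stride) % n for i in range(len(gene_ids))]
    return pd.DataFrame({
        "gene_id": list(gene_ids),
        "chrom": snps["chrom"].iloc[0],
        "start": pos[anchors],
        "end": pos[anchors] + width - 1,
        "anchor_snp": snps["snp_id"].to_numpy()[anchors],
    })


def plan_scenario_effects(annotation: pd.DataFrame, snps: pd.DataFrame,
                          cell_types, n_per_scenario: int = 20,
                          beta: float = 1.0, window: int = 1_000_000):
    """Assign genes round-robin to the four planted scenarios.

    Uses each gene's anchor SNP as the causal SNP; for ``independent_loci``
    the second cell type gets the farthest cis SNP in a different LD block
    (r^2 ~ 0 to the anchor). Interaction plants opposite-sign betas so the
    gene is detectable in both cell types and the slopes differ maximally.
    Returns (effects, truth) where truth maps gene_id -> scenario.
    """
    if len(cell_types) < 2:
        raise ValueError("need >=2 cell types")
    ct_a, ct_b = cell_types[0], cell_types[1]
    snp_block = snps.set_index("snp_id")["block"] if "block" in snps else None
    pos_of = snps.set_index("snp_id")["pos"]

    effects, truth = [], {}
    rows = annotation.itertuples(index=False)
    scen_cycle = [s for s in SCENARIOS for _ in range(n_per_scenario)]
    for row, scen in zip(rows, scen_cycle):
        anchor = row.anchor_snp
        if scen == "specific":
            effects.append(EffectSpec(row.gene_id, anchor, [ct_a], beta, "specific"))
        elif scen == "shared":
            effects.append(EffectSpec(row.gene_id, anchor, [ct_a, ct_b], beta, "shared"))
        elif scen == "independent_loci":
            apos = pos_of[anchor]
            cis = snps[(snps["pos"] >= row.start - window)
                       & (snps["pos"] <= row.end + window)]
            if snp_block is not None:
                ablock = snp_block[anchor]
                cis = cis[(cis["block"] != ablock) | (cis["block"] < 0)]
            cis = cis[cis["snp_id"] != anchor]
            if cis.empty:
                raise ValueError(f"no unlinked cis SNP for {row.gene_id}")
            other = cis.iloc[(cis["pos"] - apos).abs().argmax()]["snp_id"]
            effects.append(EffectSpec(
                row.gene_id, None, [ct_a, ct_b], beta, "independent_loci",
                snp_by_celltype={ct_a: anchor, ct_b: other}))
        else:  # interaction
            effects.append(EffectSpec(
                row.gene_id, anchor, [ct_a, ct_b], beta, "interaction",
                beta_by_celltype={ct_a: beta, ct_b: -beta}))
        truth[row.gene_id] = scen
    return effects, truth


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(genotypes, snps, annotation, cells, outdir) -> dict:
    """Write VCF + MTX triplet + metadata/annotation/truth TSVs + manifest."""
    import scipy.io
    import scipy.sparse as sp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_vcf(genotypes, snps, outdir / "genotypes.vcf")
    X = sp.coo_matrix(cells.X.T)  # features x barcodes on disk (10x convention)
    with atomic_write(outdir / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, X, field="integer")
    with atomic_write(outdir / "features.tsv") as fh:
        fh.write("\n".join(cells.var_names) + "\n")
    with atomic_write(outdir / "barcodes.tsv") as fh:
        fh.write("\n".join(cells.obs_names) + "\n")
    meta = cells.obs.reset_index(names="cell_id")
    write_tsv(meta, outdir / "cell_metadata.tsv")
    write_tsv(annotation, outdir / "gene_annotation.tsv")
    truth = cells.uns.get("truth", pd.DataFrame())
    write_tsv(truth, outdir / "truth_effects.tsv")

    manifest = {
        "files": ["genotypes.vcf", "matrix.mtx", "features.tsv", "barcodes.tsv",
                  "cell_metadata.tsv", "gene_annotation.tsv", "truth_effects.tsv"],
        "seed": int(cells.uns.get("seed", -1)),
        "n_donors": int(genotypes.shape[0]),
        "n_snps": int(genotypes.shape[1]),
        "n_cells": int(cells.n_obs),
        "n_genes": int(cells.n_vars),
    }
    with atomic_write(outdir / "manifest.json") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
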