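"""Reusable simulation benchmarks exercising the full pipeline.

Each function sets up a synthetic study at desk scale (tens of donors, a few
hundred genes/SNPs), runs the relevant pipeline stages end to end, and
returns the measured quantities. They define the package's reference study
conditions for calibration, parameter-recovery and scenario-recovery checks,
and are shared between the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic as syn
from .eqtl import compute_maf, enumerate_cis_pairs, map_celltype_eqtls, top_esnps
from .pseudobulk import aggregate_mean, fit_latent_factor, normalize_chain
from .qc import apply_qc
from . import specificity as spec


def _mito_ribo(cells):
    return (set(cells.var_names[cells.var["is_mito"]]),
            set(cells.var_names[cells.var["is_ribo"]]))


def run_study(geno, snps, ann, cells, n_factors: int = 1,
              fdr_threshold: float = 0.10):
    """QC -> pseudobulk -> factors -> cis mapping. Returns a result dict."""
    mito, ribo = _mito_ribo(cells)
    kept, qc_report = apply_qc(cells, mito, ribo)
    pb = {ct: normalize_chain(m) for ct, m in aggregate_mean(kept).items()}
    factors = ({ct: fit_latent_factor(m, k=n_factors) for ct, m in pb.items()}
               if n_factors else None)
    snps = snps.drop(columns=["maf"], errors="ignore").merge(
        compute_maf(geno), left_on="snp_id", right_index=True)
    ann_kept = ann[ann["gene_id"].isin(kept.var_names)]
    pairs = enumerate_cis_pairs(ann_kept, snps)
    records, _ = map_celltype_eqtls(pb, geno, pairs, factors, fdr_threshold)
    egenes = top_esnps(records, snps)
    return {"cells_qc": kept, "qc_report": qc_report, "pseudobulk": pb,
            "factors": factors, "snps": snps, "pairs": pairs,
            "records": records, "egenes": egenes, "genotypes": geno}


# ---------------------------------------------------------------------------
# All-null calibration study: 80 donors, 6 cell types, 200 genes, 2000 SNPs
# ---------------------------------------------------------------------------

def null_study(seed: int, n_donors: int = 80, n_cell_types: int = 6,
               n_genes: int = 200, n_snps: int = 2000,
               cells_per_donor_per_type: int = 50):
    panel = syn.SnpPanelSpec(n_snps=n_snps, spacing=25_000)
    geno, snps = syn.simulate_genotypes(panel, n_donors, seed)
    cfg = syn.SimulationConfig(
        n_donors=n_donors,
        cell_types=[f"ct{i}" for i in range(n_cell_types)],
        cells_per_donor_per_type=cells_per_donor_per_type,
        n_genes=n_genes, seed=seed)
    genes = syn.gene_ids_for(cfg)
    ann = syn.make_annotation(genes["gene_id"], snps)
    cells = syn.simulate_cells(geno, [], cfg)
    return run_study(geno, snps, ann, cells)


def null_interaction_pvalues(study: dict, n_tests: int, seed: int) -> np.ndarray:
    """Interaction-test p-values for random null (gene, SNP, type-pair) picks."""
    rng = np.random.default_rng(seed)
    pb, factors = study["pseudobulk"], study["factors"]
    cts = list(pb)
    genes = list(pb[cts[0]].values.columns)
    common = study["snps"].loc[study["snps"]["maf"] > 0.05, "snp_id"].to_numpy()
    geno = study["genotypes"]
    ps = []
    while len(ps) < n_tests:
        gene = rng.choice(genes)
        a, b = rng.choice(cts, size=2, replace=False)
        snp = rng.choice(common)
        try:
            res = spec.interaction_test(
                {a: pb[a].values[gene], b: pb[b].values[gene]}, geno[snp],
                {a: factors[a].values.iloc[:, 0], b: factors[b].values.iloc[:, 0]})
        except ValueError:
            continue
        ps.append(res.p_anova)
    return np.asarray(ps)


def thinned_null_pvalues(records: pd.DataFrame, seed: int) -> np.ndarray:
    """One cis p-value per (cell type, gene): near-independent subsample for
    a distribution test (cis pairs of one gene share its expression vector)."""
    sub = records.groupby(["cell_type", "gene_id"]).sample(n=1, random_state=seed)
    return sub["pvalue"].to_numpy()


# ---------------------------------------------------------------------------
# Parameter recovery: one planted cell type-specific effect, n = 80 donors
# ---------------------------------------------------------------------------

def recovery_replicate(seed: int, beta: float = 1.0, n_donors: int = 80,
                       cells_per_donor_per_type: int = 100,
                       n_genes: int = 400):
    """Returns (fitted beta in the planted cell type, significant flag,
    median p of the same pair in the other cell type)."""
    panel = syn.SnpPanelSpec(n_snps=40, spacing=600_000, maf_range=(0.2, 0.4))
    geno, snps = syn.simulate_genotypes(panel, n_donors, seed)
    cfg = syn.SimulationConfig(
        n_donors=n_donors, cell_types=["A", "B"],
        cells_per_donor_per_type=cells_per_donor_per_type,
        n_genes=n_genes, seed=seed)
    genes = syn.gene_ids_for(cfg)
    ann = syn.make_annotation(genes["gene_id"], snps)
    gene = syn.base_log_means(cfg).loc[syn.expressed_genes(cfg)].idxmax()
    snp = ann.loc[ann["gene_id"] == gene, "anchor_snp"].iloc[0]
    effects = [syn.EffectSpec(gene, snp, ["A"], beta, "specific")]
    cells = syn.simulate_cells(geno, effects, cfg)
    st = run_study(geno, snps, ann, cells)
    rec = st["records"]
    hit = rec[(rec.gene_id == gene) & (rec.snp_id == snp)]
    a = hit[hit.cell_type == "A"].iloc[0]
    other_p = hit.loc[hit.cell_type == "B", "pvalue"]
    return float(a.beta), bool(a.significant), float(other_p.iloc[0]) if len(other_p) else np.nan


# ---------------------------------------------------------------------------
# Scenario panel: specific / shared / independent_loci / interaction
# ---------------------------------------------------------------------------

def scenario_panel_study(seed: int, n_per_scenario: int = 20,
                         n_donors: int = 80, n_genes: int = 200,
                         cells_per_donor_per_type: int = 100,
                         beta: float = 1.0):
    """Simulate the 4-scenario panel and run the full specificity battery.

    Returns (predicted labels Series, truth dict, study dict).
    """
    n_snps = max(360, 2 * n_genes)
    panel = syn.SnpPanelSpec(
        n_snps=n_snps, spacing=50_000, maf_range=(0.2, 0.4),
        ld_blocks=[{"block_size": 3, "copy_prob": 0.7}] * (n_snps // 3))
    geno, snps = syn.simulate_genotypes(panel, n_donors, seed)
    cfg = syn.SimulationConfig(
        n_donors=n_donors, cell_types=["A", "B", "C"],
        cells_per_donor_per_type=cells_per_donor_per_type,
        n_genes=n_genes, seed=seed)
    genes = syn.gene_ids_for(cfg)
    ann = syn.make_annotation(genes["gene_id"], snps)
    eligible = ann[ann["gene_id"].isin(syn.expressed_genes(cfg))]
    effects, truth = syn.plan_scenario_effects(
        eligible, snps, cfg.cell_types, n_per_scenario=n_per_scenario, beta=beta)
    cells = syn.simulate_cells(geno, effects, cfg)
    st = run_study(geno, snps, ann, cells)

    pb, factors, records, egenes = (st["pseudobulk"], st["factors"],
                                    st["records"], st["egenes"])
    sharing = spec.classify_sharing(records, egenes, geno,
                                    n_cell_types=len(pb))
    indep = spec.run_independence(egenes, pb, factors, geno)
    inter = spec.run_interactions(records, pb, factors, geno)
    labels = spec.assign_scenarios(sharing, indep, inter)
    st.update(sharing=sharing, independence=indep, interactions=inter)
    return labels, truth, st


def scenario_accuracy(labels: pd.Series, truth: dict) -> float:
    """Fraction of planted genes assigned their true scenario label.

    A planted gene whose signal was not detected at all (absent from labels)
    counts as missed.
    """
    hits = sum(1 for g, scen in truth.items() if labels.get(g) == scen)
    return hits / len(truth)


# ---------------------------------------------------------------------------
# Conditional-independence operating characteristics
# ---------------------------------------------------------------------------

def independence_replicate(seed: int, kind: str, beta: float = 1.0,
                           n_donors: int = 80,
                           cells_per_donor_per_type: int = 100,
                           n_genes: int = 150) -> bool:
    """One replicate of the conditional-independence test on planted truth.

    ``kind='independent'``: the gene is driven by two unlinked loci (one per
    cell type); the tested pair is the two causal SNPs; expected independent.
    ``kind='proxy'``: one shared causal SNP; the tested pair is two LD proxies
    flanking it (r^2 ~ 0.9 with each other); expected not independent.
    Returns the pair-level call (independent in both directions).
    """
    panel = syn.SnpPanelSpec(
        n_snps=60, spacing=20_000, maf_range=(0.2, 0.4),
        ld_blocks=[{"block_size": 3, "copy_prob": 0.974}] * 20)
    geno, snps = syn.simulate_genotypes(panel, n_donors, seed)
    cfg = syn.SimulationConfig(
        n_donors=n_donors, cell_types=["A", "B"],
        cells_per_donor_per_type=cells_per_donor_per_type,
        n_genes=n_genes, seed=seed)
    genes = syn.gene_ids_for(cfg)
    ann = syn.make_annotation(genes["gene_id"], snps)
    gene = syn.base_log_means(cfg).loc[syn.expressed_genes(cfg)].idxmax()
    ids = snps["snp_id"].tolist()
    if kind == "independent":
        snp_a, snp_b = ids[1], ids[31]       # different blocks, unlinked
        effects = [syn.EffectSpec(gene, None, ["A", "B"], beta,
                                  "independent_loci",
                                  snp_by_celltype={"A": snp_a, "B": snp_b})]
    elif kind == "proxy":
        causal, snp_a, snp_b = ids[1], ids[0], ids[2]  # proxies flank causal
        effects = [syn.EffectSpec(gene, causal, ["A", "B"], beta, "shared")]
    else:
        raise ValueError(kind)
    cells = syn.simulate_cells(geno, effects, cfg)
    mito, ribo = _mito_ribo(cells)
    kept, _ = apply_qc(cells, mito, ribo)
    pb = {ct: normalize_chain(m) for ct, m in aggregate_mean(kept).items()}
    factors = {ct: fit_latent_factor(m) for ct, m in pb.items()}
    calls = []
    for x, s1, s2 in (("A", snp_a, snp_b), ("B", snp_b, snp_a)):
        m = pb[x]
        res = spec.conditional_independence_test(
            m.values[gene].to_numpy(),
            geno.loc[m.donors, s1].to_numpy(),
            geno.loc[m.donors, s2].to_numpy(),
            factors[x].values.loc[m.donors].to_numpy())
        calls.append(res.independent)
    return all(calls)
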