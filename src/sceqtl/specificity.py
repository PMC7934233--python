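"""Cross-cell-type eQTL specificity battery.

Given per-cell-type association results, this module decides how each eGene's
genetic signal is distributed across cell types:

* sharing classification — unique / shared with the same eSNP (or eSNPs in
  LD, r^2 >= 0.2) / shared with different eSNPs / ubiquitous (all cell types);
* conditional independence — for an eGene significant in two cell types with
  different top eSNPs, the expression in cell type a is regressed on both top
  eSNPs (plus the latent factor); the eSNPs are deemed independent if S_a
  stays significant after adjusting for S_b, in both directions;
* interaction — for an eGene significant in >= 2 cell types, the eSNP with
  the largest between-cell-type slope difference is tested by comparing
  nested stacked models (with/without the SNP x cell-type term) by F-test
  (anova), BH-adjusted across eGenes at FDR 0.05;
* correlation analyses — donor-level expression correlation of unique eGenes
  across cell types, and correlation of full t-statistics for significant
  pairs between cell types;
* permutation enrichment — mean rank of a source cell type's eGenes in a
  target cell type's per-gene best p-values, against 10,000 random gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import bh_fdr

logger = logging.getLogger("sceqtl")

R2_LINK = 0.2
INDEPENDENCE_ALPHA = 0.05
INTERACTION_FDR = 0.05
N_PERMUTATIONS = 10_000


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def compute_r2(g1, g2) -> float:
    """Squared Pearson correlation of dosages (composite LD). NaN if either
    vector is constant."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) != len(g2):
        raise ValueError("genotype vectors must align on donors")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        return float("nan")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Sharing classification
# ---------------------------------------------------------------------------

@dataclass
class SharingSummary:
    per_gene: pd.DataFrame   # gene_id, cell_types, n_cell_types, category
    counts: pd.DataFrame     # category, n, pct


def classify_sharing(records: pd.DataFrame, egenes: pd.DataFrame,
                     genotypes: pd.DataFrame, n_cell_types: int,
                     r2_link: float = R2_LINK) -> SharingSummary:
    """Partition eGenes into unique / shared_same_eSNP / shared_different_eSNP
    / ubiquitous.

    A gene significant in >= 2 (but not all) cell types is shared_same_eSNP
    when some significant eSNP is shared between two of its cell types, or
    when the top eSNPs of two cell types are in LD (r^2 >= r2_link);
    otherwise shared_different_eSNP.
    """
    sig = records[records["significant"]]
    rows = []
    for gene, sub in sig.groupby("gene_id"):
        cts = sorted(sub["cell_type"].unique())
        if len(cts) == 1:
            cat = "unique"
        elif len(cts) == n_cell_types:
            cat = "ubiquitous"
        else:
            cat = "shared_different_eSNP"
            shared_snp = any(
                len(set(sub.loc[sub["cell_type"] == a, "snp_id"])
                    & set(sub.loc[sub["cell_type"] == b, "snp_id"])) > 0
                for i, a in enumerate(cts) for b in cts[i + 1:])
            if shared_snp:
                cat = "shared_same_eSNP"
            else:
                tops = egenes[egenes["gene_id"] == gene].set_index("cell_type")["snp_id"]
                for i, a in enumerate(cts):
                    for b in cts[i + 1:]:
                        if a in tops.index and b in tops.index:
                            r2 = compute_r2(genotypes[tops[a]], genotypes[tops[b]])
                            if np.isfinite(r2) and r2 >= r2_link:
                                cat = "shared_same_eSNP"
        rows.append((gene, ",".join(cts), len(cts), cat))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "cell_types",
                                           "n_cell_types", "category"])
    cats = ["unique", "shared_same_eSNP", "shared_different_eSNP", "ubiquitous"]
    n = per_gene["category"].value_counts().reindex(cats, fill_value=0)
    counts = pd.DataFrame({
        "category": cats,
        "n": n.to_numpy(),
        "pct": 100.0 * n.to_numpy() / max(1, len(per_gene)),
    })
    return SharingSummary(per_gene=per_gene, counts=counts)


# ---------------------------------------------------------------------------
# Conditional independence
# ---------------------------------------------------------------------------

@dataclass
class IndependenceResult:
    gene_id: str
    cell_type_a: str
    cell_type_b: str
    snp_a: str
    snp_b: str
    r2: float
    p_conditional: float
    independent: bool
    testable: bool = True


def conditional_independence_test(G_a, S_a, S_b, peer=None,
                                  alpha: float = INDEPENDENCE_ALPHA,
                                  gene_id: str = "", cell_type_a: str = "",
                                  cell_type_b: str = "", snp_a: str = "",
                                  snp_b: str = "") -> IndependenceResult:
    """OLS of expression in cell type a on [1, S_a, S_b, factor]; the pair is
    independent when S_a's slope stays significant after adjusting S_b.

    Collinear eSNPs (r^2 == 1) are flagged not testable.
    """
    G_a = np.asarray(G_a, dtype=float)
    S_a = np.asarray(S_a, dtype=float)
    S_b = np.asarray(S_b, dtype=float)
    r2 = compute_r2(S_a, S_b)
    if not np.isfinite(r2) or r2 > 1 - 1e-12:
        return IndependenceResult(gene_id, cell_type_a, cell_type_b, snp_a,
                                  snp_b, r2, float("nan"), False, testable=False)
    n = len(G_a)
    C = (np.empty((n, 0)) if peer is None
         else np.asarray(peer, dtype=float).reshape(n, -1))
    X = np.column_stack([np.ones(n), S_a, S_b, C])
    coef, _, _, _ = np.linalg.lstsq(X, G_a, rcond=None)
    resid = G_a - X @ coef
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = coef[1] / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    return IndependenceResult(gene_id, cell_type_a, cell_type_b, snp_a, snp_b,
                              r2, p, bool(p < alpha))


def run_independence(egenes: pd.DataFrame, pseudobulk: dict,
                     factors: dict | None, genotypes: pd.DataFrame,
                     alpha: float = INDEPENDENCE_ALPHA) -> pd.DataFrame:
    """Both-direction conditional tests for every eGene significant in >= 2
    cell types with distinct top eSNPs."""
    rows = []
    for gene, sub in egenes.groupby("gene_id"):
        cts = sorted(sub["cell_type"].unique())
        tops = sub.set_index("cell_type")["snp_id"]
        for i, a in enumerate(cts):
            for b in cts[i + 1:]:
                sa, sb = tops[a], tops[b]
                if sa == sb:
                    continue
                for (x, y, s1, s2) in ((a, b, sa, sb), (b, a, sb, sa)):
                    pb = pseudobulk[x]
                    donors = pb.donors
                    peer = (factors[x].values.loc[donors].to_numpy()
                            if factors and x in factors else None)
                    res = conditional_independence_test(
                        pb.values.loc[donors, gene].to_numpy(),
                        genotypes.loc[donors, s1].to_numpy(),
                        genotypes.loc[donors, s2].to_numpy(),
                        peer, alpha, gene, x, y, s1, s2)
                    rows.append(res.__dict__)
    return pd.DataFrame(rows, columns=[
        "gene_id", "cell_type_a", "cell_type_b", "snp_a", "snp_b", "r2",
        "p_conditional", "independent", "testable"])


# ---------------------------------------------------------------------------
# Interaction
# ---------------------------------------------------------------------------

def select_interaction_pair(records_gene: pd.DataFrame):
    """eSNP and cell-type pair with the largest |beta| difference.

    Candidates are eSNPs from significant eSNP-eGene pairs shared across cell
    types, i.e. the eSNP must be significant in both cell types of the pair;
    ties are broken by the smaller of the two p-values, then by snp_id.
    """
    sig = records_gene[records_gene["significant"]]
    best = None
    for snp in sorted(set(sig["snp_id"])):
        sub = sig[sig["snp_id"] == snp]
        cts = sub["cell_type"].tolist()
        if len(cts) < 2:
            continue
        betas = sub.set_index("cell_type")["beta"]
        ps = sub.set_index("cell_type")["pvalue"]
        for i, a in enumerate(cts):
            for b in cts[i + 1:]:
                diff = abs(betas[a] - betas[b])
                key = (-diff, min(ps[a], ps[b]), snp)
                if best is None or key < best[0]:
                    best = (key, snp, (a, b))
    if best is None:
        logger.info("select_interaction_pair: no shared tested eSNP")
        return None
    return best[1], best[2]


@dataclass
class InteractionResult:
    gene_id: str
    snp_id: str
    cell_type_pair: tuple
    beta_snp: float
    beta_celltype: float
    beta_interaction: float
    p_anova: float
    fdr: float = float("nan")


def interaction_test(expr_by_ct: dict[str, pd.Series], genotype: pd.Series,
                     peer_by_ct: dict[str, pd.Series] | None,
                     gene_id: str = "", snp_id: str = "") -> InteractionResult:
    """Nested-model F-test for a SNP x cell-type interaction.

    ``expr_by_ct`` maps each of exactly two cell types to a donor-indexed
    expression vector; rows are stacked (one row per donor x cell type, each
    row carrying its own cell type's latent-factor value) and the models
    G ~ S + C + factor and G ~ S + C + S:C + factor are compared by the
    F-statistic on the single extra parameter.
    """
    cts = sorted(expr_by_ct)
    if len(cts) != 2:
        raise ValueError("interaction test requires exactly 2 cell types")
    ys, gs, cs, ps = [], [], [], []
    for ci, ct in enumerate(cts):
        e = expr_by_ct[ct]
        donors = e.index
        if len(donors) < 2:
            raise ValueError(f"<2 donors in cell type {ct}")
        ys.append(e.to_numpy(dtype=float))
        gs.append(genotype.loc[donors].to_numpy(dtype=float))
        cs.append(np.full(len(donors), ci, dtype=float))
        if peer_by_ct is not None:
            ps.append(peer_by_ct[ct].loc[donors].to_numpy(dtype=float))
    y = np.concatenate(ys)
    S = np.concatenate(gs)
    Cind = np.concatenate(cs)
    if np.ptp(S) == 0:
        raise ValueError("constant genotype")
    cols0 = [np.ones_like(y), S, Cind]
    if ps:
        cols0.append(np.concatenate(ps))
    X0 = np.column_stack(cols0)
    X1 = np.column_stack(cols0[:3] + [S * Cind] + cols0[3:])

    def rss(X):
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return coef, r @ r

    coef0, rss0 = rss(X0)
    coef1, rss1 = rss(X1)
    df1 = len(y) - X1.shape[1]
    F = (rss0 - rss1) / (rss1 / df1)
    p = float(stats.f.sf(F, 1, df1))
    return InteractionResult(
        gene_id=gene_id, snp_id=snp_id, cell_type_pair=tuple(cts),
        beta_snp=float(coef1[1]), beta_celltype=float(coef1[2]),
        beta_interaction=float(coef1[3]), p_anova=p)


def run_interactions(records: pd.DataFrame, pseudobulk: dict,
                     factors: dict | None, genotypes: pd.DataFrame,
                     fdr_threshold: float = INTERACTION_FDR) -> pd.DataFrame:
    """Interaction tests for all eGenes significant in >= 2 cell types,
    BH-adjusted across the tested eGenes."""
    sig = records[records["significant"]]
    multi = sig.groupby("gene_id")["cell_type"].nunique()
    rows = []
    for gene in multi[multi >= 2].index:
        sub = records[records["gene_id"] == gene]
        picked = select_interaction_pair(sub)
        if picked is None:
            continue
        snp, (a, b) = picked
        expr, peer = {}, ({} if factors else None)
        ok = True
        for ct in (a, b):
            pb = pseudobulk.get(ct)
            if pb is None or gene not in pb.values.columns:
                ok = False
                break
            expr[ct] = pb.values[gene]
            if factors:
                peer[ct] = factors[ct].values.iloc[:, 0]
        if not ok:
            continue
        try:
            res = interaction_test(expr, genotypes[snp], peer, gene, snp)
        except ValueError:
            continue
        rows.append(res.__dict__)
    out = pd.DataFrame(rows, columns=[
        "gene_id", "snp_id", "cell_type_pair", "beta_snp", "beta_celltype",
        "beta_interaction", "p_anova", "fdr"])
    if len(out):
        out["fdr"] = bh_fdr(out["p_anova"].to_numpy())
        out["significant"] = out["fdr"] < fdr_threshold
    else:
        out["significant"] = []
    return out


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def egene_expression_correlation(pseudobulk: dict, sharing: SharingSummary
                                 ) -> pd.DataFrame:
    """Pearson correlation of each unique eGene's donor-level expression
    between its own cell type and every other cell type (shared donors)."""
    uniq = sharing.per_gene[sharing.per_gene["category"] == "unique"]
    rows = []
    for row in uniq.itertuples(index=False):
        src = row.cell_types  # single cell type for unique genes
        pb_src = pseudobulk.get(src)
        if pb_src is None or row.gene_id not in pb_src.values.columns:
            continue
        for ct, pb in pseudobulk.items():
            if ct == src or row.gene_id not in pb.values.columns:
                continue
            shared = pb_src.values.index.intersection(pb.values.index)
            if len(shared) < 3:
                logger.info("egene correlation: <3 shared donors for %s (%s vs %s)",
                            row.gene_id, src, ct)
                continue
            x = pb_src.values.loc[shared, row.gene_id]
            y = pb.values.loc[shared, row.gene_id]
            if x.std() == 0 or y.std() == 0:
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((row.gene_id, src, ct, len(shared), r, p))
    return pd.DataFrame(rows, columns=["gene_id", "source_cell_type",
                                       "target_cell_type", "n_donors", "r", "p"])


def tstat_correlation(records: pd.DataFrame) -> pd.DataFrame:
    """For each cell type's significant pairs, Pearson r of their t-statistics
    against the same (gene, SNP) pairs' t-statistics in every other cell type."""
    cts = sorted(records["cell_type"].unique())
    rows = []
    for a in cts:
        sig_a = records[(records["cell_type"] == a) & records["significant"]]
        if sig_a.empty:
            continue
        key_a = sig_a.set_index(["gene_id", "snp_id"])["tstat"]
        for b in cts:
            if b == a:
                continue
            all_b = records[records["cell_type"] == b].set_index(
                ["gene_id", "snp_id"])["tstat"]
            common = key_a.index.intersection(all_b.index)
            n_missing = len(key_a) - len(common)
            if n_missing:
                logger.info("tstat_correlation: %d pairs of %s untested in %s",
                            n_missing, a, b)
            if len(common) < 3:
                continue
            r, p = stats.pearsonr(key_a.loc[common], all_b.loc[common])
            rows.append((a, b, len(common), r, p))
    return pd.DataFrame(rows, columns=["source_cell_type", "target_cell_type",
                                       "n_pairs", "r", "p"])


# ---------------------------------------------------------------------------
# Permutation enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    source_cell_type: str
    target_cell_type: str
    observed_mean_rank: float
    null_mean: float
    null_sd: float
    n_permutations: int
    p: float


def enrichment_test(gene_min_p: pd.Series, egenes_source,
                    n_perm: int = N_PERMUTATIONS, seed: int = 0,
                    source_cell_type: str = "", target_cell_type: str = ""
                    ) -> EnrichmentResult:
    """Mean-rank enrichment of a source eGene set in a target cell type.

    Genes are ranked ascending by their best (minimum) p-value in the target
    cell type; the observed statistic is the mean rank of the source set and
    the null is the mean rank of ``n_perm`` random same-size gene sets. The
    p-value is one-sided toward enrichment (low mean rank):
    p = P(T <= (obs - null_mean)/null_sd) under a t reference with
    n_perm - 1 degrees of freedom.
    """
    genes = list(gene_min_p.index)
    source = [g for g in egenes_source]
    if len(source) > len(genes):
        raise ValueError("source set larger than the gene universe")
    missing = set(source) - set(genes)
    if missing:
        raise ValueError(f"source genes missing from universe: {sorted(missing)[:5]}")
    ranks = pd.Series(stats.rankdata(gene_min_p.to_numpy()), index=genes)
    obs = float(ranks.loc[source].mean())

    rng = np.random.default_rng(seed)
    k = len(source)
    rank_arr = ranks.to_numpy()
    # vectorized sampling without replacement: k smallest of G random keys
    keys = rng.random((n_perm, len(genes)))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null = rank_arr[idx].mean(axis=1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (obs - null_mean) / null_sd if null_sd > 0 else -np.inf
    p = float(stats.t.cdf(z, df=n_perm - 1))
    return EnrichmentResult(source_cell_type, target_cell_type, obs,
                            null_mean, null_sd, n_perm, p)


def run_enrichment(records: pd.DataFrame, egenes: pd.DataFrame,
                   n_perm: int = N_PERMUTATIONS, seed: int = 0) -> pd.DataFrame:
    """All source -> target cell-type enrichment tests."""
    cts = sorted(records["cell_type"].unique())
    rows = []
    for i, src in enumerate(cts):
        source_genes = egenes.loc[egenes["cell_type"] == src, "gene_id"].tolist()
        if not source_genes:
            continue
        for tgt in cts:
            if tgt == src:
                continue
            tgt_p = records[records["cell_type"] == tgt].groupby("gene_id")["pvalue"].min()
            source_here = [g for g in source_genes if g in tgt_p.index]
            if not source_here:
                continue
            res = enrichment_test(tgt_p, source_here, n_perm,
                                  seed=seed + 7919 * i, source_cell_type=src,
                                  target_cell_type=tgt)
            rows.append(res.__dict__)
    return pd.DataFrame(rows, columns=[
        "source_cell_type", "target_cell_type", "observed_mean_rank",
        "null_mean", "null_sd", "n_permutations", "p"])


# ---------------------------------------------------------------------------
# Scenario assignment (end-to-end label for each eGene)
# ---------------------------------------------------------------------------

def assign_scenarios(sharing: SharingSummary, independence: pd.DataFrame,
                     interactions: pd.DataFrame) -> pd.Series:
    """Combine the battery into one label per eGene.

    Precedence: unique -> 'specific'; shared with different, conditionally
    independent top eSNPs (both directions) -> 'independent_loci'; a
    significant SNP x cell-type interaction -> 'interaction'; anything else
    significant in >= 2 cell types -> 'shared'. Independence is checked
    before the interaction test because a gene driven by distinct loci in
    different cell types also produces a genuine interaction signal.
    """
    indep_genes = set()
    if len(independence):
        testable = independence[independence["testable"]]
        both = testable.groupby("gene_id")["independent"].all()
        ndir = testable.groupby("gene_id").size()
        indep_genes = set(both[(both) & (ndir >= 2)].index)
    inter_genes = set()
    if len(interactions) and "significant" in interactions:
        inter_genes = set(interactions.loc[interactions["significant"], "gene_id"])

    labels = {}
    for row in sharing.per_gene.itertuples(index=False):
        if row.category == "unique":
            labels[row.gene_id] = "specific"
        elif row.category == "shared_different_eSNP" and row.gene_id in indep_genes:
            labels[row.gene_id] = "independent_loci"
        elif row.gene_id in inter_genes:
            labels[row.gene_id] = "interaction"
        else:
            labels[row.gene_id] = "shared"
    return pd.Series(labels, name="scenario")
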