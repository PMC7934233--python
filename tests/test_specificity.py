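"""Sharing classification, conditional independence, interaction, correlation
and enrichment operations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sceqtl as sq
from sceqtl.pseudobulk import PseudobulkMatrix
from sceqtl.specificity import select_interaction_pair


def _records(rows):
    return pd.DataFrame(rows, columns=["cell_type", "gene_id", "snp_id",
                                       "beta", "pvalue", "significant"])


def test_r2_identity_independence_and_hand_value():
    g = np.array([0, 1, 2, 1, 0, 2], dtype=float)
    assert sq.compute_r2(g, g) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    a = rng.binomial(2, 0.3, 5000)
    b = rng.binomial(2, 0.3, 5000)
    assert sq.compute_r2(a, b) < 0.01
    g2 = np.array([1, 1, 2, 0, 0, 2], dtype=float)
    hand = np.corrcoef(g, g2)[0, 1] ** 2
    assert sq.compute_r2(g, g2) == pytest.approx(hand)
    assert np.isnan(sq.compute_r2(g, np.ones(6)))


def test_classify_sharing_categories_partition():
    rec = _records([
        ("A", "g_unique", "s1", 1.0, 1e-8, True),
        ("A", "g_same", "s2", 1.0, 1e-8, True),
        ("B", "g_same", "s2", 1.0, 1e-8, True),
        ("A", "g_diff", "s3", 1.0, 1e-8, True),
        ("B", "g_diff", "s4", 1.0, 1e-8, True),
        ("A", "g_ubiq", "s5", 1.0, 1e-8, True),
        ("B", "g_ubiq", "s5", 1.0, 1e-8, True),
        ("C", "g_ubiq", "s5", 1.0, 1e-8, True),
    ])
    eg = rec.copy()
    rng = np.random.default_rng(1)
    geno = pd.DataFrame(rng.binomial(2, 0.4, size=(200, 5)),
                        columns=["s1", "s2", "s3", "s4", "s5"])
    sharing = sq.classify_sharing(rec, eg, geno, n_cell_types=3)
    cat = sharing.per_gene.set_index("gene_id")["category"]
    assert cat["g_unique"] == "unique"
    assert cat["g_same"] == "shared_same_eSNP"
    assert cat["g_diff"] == "shared_different_eSNP"
    assert cat["g_ubiq"] == "ubiquitous"
    assert sharing.counts["pct"].sum() == pytest.approx(100.0)
    assert sharing.counts["n"].sum() == 4


def test_classify_sharing_uses_ld_link():
    rec = _records([
        ("A", "g", "s1", 1.0, 1e-8, True),
        ("B", "g", "s2", 1.0, 1e-8, True),
    ])
    rng = np.random.default_rng(2)
    s1 = rng.binomial(2, 0.4, 300)
    geno = pd.DataFrame({"s1": s1, "s2": s1})   # perfect LD
    sharing = sq.classify_sharing(rec, rec, geno, n_cell_types=3)
    assert sharing.per_gene["category"].iloc[0] == "shared_same_eSNP"


def test_conditional_independence_reduces_to_marginal_when_orthogonal():
    """With S_b orthogonal to S_a the S_a coefficient equals the marginal
    eQTL fit's coefficient."""
    rng = np.random.default_rng(3)
    S_a = np.tile([0., 1, 2, 1], 10)
    S_b = np.tile([1., 1, 1, 1], 10) + np.tile([0., 0, 0, 0], 10)
    S_b = rng.permutation(np.repeat([0., 2], 20))
    S_b = S_b - np.polyval(np.polyfit(S_a, S_b, 1), S_a)  # orthogonalize
    y = 0.7 * S_a + rng.normal(size=40)
    res = sq.conditional_independence_test(y, S_a, S_b)
    marginal = sq.fit_eqtl(y, S_a)
    # coefficient agreement on the constructed orthogonal fixture
    X = np.column_stack([np.ones(40), S_a, S_b])
    beta_joint = np.linalg.lstsq(X, y, rcond=None)[0][1]
    assert beta_joint == pytest.approx(marginal.beta, abs=1e-8)
    assert res.independent


def test_conditional_independence_flags_collinear_pair():
    g = np.tile([0., 1, 2], 10)
    res = sq.conditional_independence_test(np.random.default_rng(0).normal(size=30),
                                           g, g.copy())
    assert not res.testable


def test_select_interaction_pair_matches_bruteforce_scan():
    rec = _records([
        ("A", "g", "s1", 0.5, 1e-8, True), ("B", "g", "s1", 0.1, 1e-6, True),
        ("C", "g", "s1", 0.45, 1e-7, True),
        ("A", "g", "s2", 0.2, 1e-5, True), ("B", "g", "s2", 0.15, 1e-4, True),
        ("A", "g", "s3", 2.0, 1e-9, True),   # only one cell type: not eligible
    ])
    snp, pair = select_interaction_pair(rec)
    assert snp == "s1" and set(pair) == {"A", "B"}
    # exhaustive scan agrees
    best = None
    sig = rec[rec.significant]
    for s in sig.snp_id.unique():
        sub = sig[sig.snp_id == s]
        for i, a in enumerate(sub.cell_type):
            for b in sub.cell_type.iloc[i + 1:]:
                d = abs(sub.set_index("cell_type").beta[a]
                        - sub.set_index("cell_type").beta[b])
                if best is None or d > best[0]:
                    best = (d, s, {a, b})
    assert best[1] == snp and best[2] == set(pair)


def test_interaction_f_equals_wald_t_squared_and_degenerate_errors():
    rng = np.random.default_rng(4)
    donors = [f"d{i}" for i in range(40)]
    g = pd.Series(rng.binomial(2, 0.3, 40).astype(float), index=donors)
    ya = pd.Series(0.8 * g + rng.normal(size=40), index=donors)
    yb = pd.Series(-0.2 * g + rng.normal(size=40), index=donors)
    res = sq.interaction_test({"A": ya, "B": yb}, g, None)

    # Wald t^2 on the interaction coefficient in the full model
    y = np.concatenate([ya, yb])
    S = np.concatenate([g, g])
    C = np.repeat([0.0, 1.0], 40)
    X = np.column_stack([np.ones(80), S, C, S * C])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = 80 - 4
    cov = np.linalg.inv(X.T @ X) * (resid @ resid / df)
    t2 = coef[3] ** 2 / cov[3, 3]
    F = stats.f.sf(t2, 1, df)
    assert res.p_anova == pytest.approx(F, abs=1e-8)
    assert res.beta_interaction == pytest.approx(coef[3], abs=1e-10)

    with pytest.raises(ValueError, match="constant genotype"):
        sq.interaction_test({"A": ya, "B": yb},
                            pd.Series(np.ones(40), index=donors), None)
    with pytest.raises(ValueError, match="exactly 2"):
        sq.interaction_test({"A": ya}, g, None)


def test_egene_expression_correlation_hand_values():
    donors = [f"d{i}" for i in range(5)]
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 5])
    pba = PseudobulkMatrix("A", pd.DataFrame({"g": x}, index=donors), "z_transformed")
    pbb = PseudobulkMatrix("B", pd.DataFrame({"g": y}, index=donors), "z_transformed")
    sharing = sq.SharingSummary(
        per_gene=pd.DataFrame({"gene_id": ["g"], "cell_types": ["A"],
                               "n_cell_types": [1], "category": ["unique"]}),
        counts=pd.DataFrame())
    out = sq.egene_expression_correlation({"A": pba, "B": pbb}, sharing)
    r_hand, p_hand = stats.pearsonr(x, y)
    assert out["r"].iloc[0] == pytest.approx(r_hand)
    assert out["p"].iloc[0] == pytest.approx(p_hand)
    # identical vectors give r = 1
    out2 = sq.egene_expression_correlation({"A": pba, "B": PseudobulkMatrix(
        "B", pd.DataFrame({"g": x}, index=donors), "z_transformed")}, sharing)
    assert out2["r"].iloc[0] == pytest.approx(1.0)


def test_tstat_correlation_identity_and_exclusions():
    rec = pd.DataFrame({
        "cell_type": ["A"] * 4 + ["B"] * 3,
        "gene_id": ["g1", "g2", "g3", "g4", "g1", "g2", "g3"],
        "snp_id": ["s"] * 7,
        "tstat": [3.0, 4.0, 5.0, 6.0, 2.9, 4.2, 4.8],
        "significant": [True, True, True, True, False, False, False],
    })
    out = sq.tstat_correlation(rec)
    row = out[(out.source_cell_type == "A") & (out.target_cell_type == "B")]
    assert row["n_pairs"].iloc[0] == 3    # g4 untested in B is excluded
    hand = stats.pearsonr([3, 4, 5], [2.9, 4.2, 4.8])[0]
    assert row["r"].iloc[0] == pytest.approx(hand)


def test_enrichment_extremes_and_null_mean():
    rng = np.random.default_rng(5)
    G = 200
    pmin = pd.Series(rng.uniform(size=G), index=[f"g{i}" for i in range(G)])
    lowest = list(pmin.nsmallest(20).index)
    res = sq.enrichment_test(pmin, lowest, n_perm=2000, seed=0)
    assert res.p < 1e-6
    assert res.null_mean == pytest.approx((G + 1) / 2, rel=0.05)
    with pytest.raises(ValueError, match="larger than"):
        sq.enrichment_test(pmin.head(5), list(pmin.index[:6]))


def test_assign_scenarios_precedence():
    sharing = sq.SharingSummary(per_gene=pd.DataFrame({
        "gene_id": ["g_u", "g_ind", "g_int", "g_sh"],
        "cell_types": ["A", "A,B", "A,B", "A,B"],
        "n_cell_types": [1, 2, 2, 2],
        "category": ["unique", "shared_different_eSNP", "shared_same_eSNP",
                     "shared_same_eSNP"],
    }), counts=pd.DataFrame())
    indep = pd.DataFrame({
        "gene_id": ["g_ind", "g_ind"], "independent": [True, True],
        "testable": [True, True]})
    inter = pd.DataFrame({"gene_id": ["g_int", "g_ind"],
                          "significant": [True, True]})
    labels = sq.assign_scenarios(sharing, indep, inter)
    assert labels["g_u"] == "specific"
    # independence wins over an (expected) interaction signal
    assert labels["g_ind"] == "independent_loci"
    assert labels["g_int"] == "interaction"
    assert labels["g_sh"] == "shared"
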