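"""Association model, permutation calibration, FDR and LD semantics."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from regfire import (
    EqtlSimSpec,
    bh_qvalues,
    conditional_scan,
    fit_snp_gene,
    inverse_normal_transform,
    ld_r2,
    map_cis_eqtl,
    map_trans_eqtl,
    permutation_fwer_threshold,
    simulate_eqtl_dataset,
)
from regfire.eqtl_mapping import _population_design, _scan, _residualize

from oracles import bh_oracle


# ----------------------------------------------------- inverse normal

def test_inverse_normal_transform_quantiles():
    out = inverse_normal_transform(np.array([3.0, 1.0, 2.0]))
    expected = stats.norm.ppf([5 / 6, 1 / 6, 3 / 6])
    np.testing.assert_allclose(out, expected, atol=1e-12)
    np.testing.assert_allclose(out, [0.9674, -0.9674, 0.0], atol=1e-4)


def test_inverse_normal_transform_average_ranks_for_ties():
    out = inverse_normal_transform(np.array([5.0, 5.0, 1.0]))
    # hand-ranked: ranks (2.5, 2.5, 1) -> quantiles ((2.5-.5)/3, ., (0.5)/3)
    expected = stats.norm.ppf([2 / 3, 2 / 3, 1 / 6])
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_inverse_normal_transform_idempotent_on_ranks(rng):
    x = rng.normal(size=57)
    once = inverse_normal_transform(x)
    twice = inverse_normal_transform(once)
    np.testing.assert_allclose(once, twice, atol=1e-12)


def test_inverse_normal_transform_rejects_constant():
    with pytest.raises(ValueError, match="constant"):
        inverse_normal_transform(np.ones(5))


# ----------------------------------------------------- single fit

@pytest.mark.parametrize("seed", range(8))
def test_fit_matches_statsmodels_ols(seed):
    rng = np.random.default_rng(seed)
    n = 40
    g = rng.integers(0, 3, n).astype(float)
    cov = rng.integers(0, 2, n).astype(float)
    y = 0.3 * g + 0.5 * cov + rng.normal(size=n)
    r = fit_snp_gene(g, y, cov)
    f = sm.OLS(y, sm.add_constant(np.column_stack([cov, g]))).fit()
    assert r.beta == pytest.approx(f.params[-1], abs=1e-10)
    assert r.se == pytest.approx(f.bse[-1], abs=1e-10)
    assert r.p_value == pytest.approx(f.pvalues[-1], abs=1e-10)
    # p consistent with the t survival function at the reported statistic
    t = r.beta / r.se
    assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t), n - 3), abs=1e-12)


def test_exact_linear_relation_gives_zero_p():
    g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], float)
    r = fit_snp_gene(g, 2.0 * g + 1.0)
    assert r.p_value < 1e-300
    assert r.r2 == pytest.approx(1.0)


def test_monomorphic_genotype_flagged_p_one():
    r = fit_snp_gene(np.zeros(12), np.arange(12.0))
    assert r.monomorphic and r.p_value == 1.0 and np.isnan(r.beta)


def test_missing_dosage_mean_imputed():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, 30).astype(float)
    y = 0.5 * g + rng.normal(size=30)
    g_miss = g.copy()
    g_miss[3] = -1  # missing sentinel
    g_imp = g.copy()
    g_imp[3] = np.delete(g, 3).mean()
    r1 = fit_snp_gene(g_miss, y)
    r2 = fit_snp_gene(g_imp, y)
    assert r1.beta == pytest.approx(r2.beta, abs=1e-12)


def test_vectorized_scan_equals_per_snp_fits(eqtl_panel):
    gmat, expr, truth = eqtl_panel
    gi = expr.gene_index(truth.target_gene)
    cond = expr.conditions[0]
    mask = expr.condition == cond
    y = inverse_normal_transform(expr.values[gi, mask])
    C = _population_design(gmat.population)
    D = gmat.dosages.astype(float)
    beta, se, p, r2 = _scan(D, y, C)
    pop = (gmat.population == "EUB").astype(float)
    for j in range(gmat.n_variants):
        ref = fit_snp_gene(D[j], y, pop)
        assert beta[j] == pytest.approx(ref.beta, abs=1e-10)
        assert se[j] == pytest.approx(ref.se, abs=1e-10)
        assert p[j] == pytest.approx(ref.p_value, abs=1e-10)
        assert r2[j] == pytest.approx(ref.r2, abs=1e-10)


# ----------------------------------------------------- cis scan

def test_window_excluding_causal_returns_nothing_significant(eqtl_panel):
    gmat, expr, truth = eqtl_panel
    causal_pos = gmat.variants[gmat.snp_index(truth.causal_snp)].pos
    far = causal_pos + 10_000_000
    res = map_cis_eqtl(gmat, expr, truth.target_gene, window=1000, gene_pos=far)
    assert res == []


def test_duplicate_snp_columns_give_identical_results(eqtl_panel):
    gmat, expr, truth = eqtl_panel
    idx = gmat.snp_index(truth.causal_snp)
    dup = gmat.subset_variants([idx, idx])
    res = map_cis_eqtl(dup, expr, truth.target_gene)
    by_cond = {}
    for r in res:
        by_cond.setdefault(r.condition, []).append(r)
    for rs in by_cond.values():
        assert rs[0].beta == rs[1].beta and rs[0].p_value == rs[1].p_value


# ----------------------------------------------------- permutation FWER

def test_threshold_is_smallest_minimum_at_quantile_edge(eqtl_panel):
    gmat, expr, truth = eqtl_panel
    cal = permutation_fwer_threshold(
        gmat, expr, truth.target_gene, n_permutations=100, target_fwer=0.01, seed=3
    )
    assert cal.threshold == cal.min_p_distribution.min()
    assert len(cal.min_p_distribution) == 100


def test_threshold_rejects_unsupported_quantile(eqtl_panel):
    gmat, expr, truth = eqtl_panel
    with pytest.raises(ValueError, match="quantile"):
        permutation_fwer_threshold(
            gmat, expr, truth.target_gene, n_permutations=100,
            target_fwer=0.001, seed=3,
        )


def test_threshold_approaches_sidak_for_independent_snps():
    """With independent SNPs and one condition the permutation threshold
    approximates the Sidak bound 1 - (1 - alpha)^(1/m)."""
    spec = EqtlSimSpec(
        n_individuals=100, n_snps=150, ld_decay=0.0, beta_cis=0.0,
        n_conditions=1, seed=21,
    )
    gmat, expr, truth = simulate_eqtl_dataset(spec)
    cal = permutation_fwer_threshold(
        gmat, expr, truth.target_gene, n_permutations=2000, target_fwer=0.01,
        seed=4,
    )
    sidak = 1 - (1 - 0.01) ** (1 / 150)
    assert 0.4 * sidak < cal.threshold < 2.2 * sidak  # Monte-Carlo slack


def test_threshold_monotone_in_number_of_snps():
    """Scanning more SNPs gives a (weakly) stricter threshold when the
    permutation draws are shared."""
    spec = EqtlSimSpec(n_individuals=60, n_snps=60, beta_cis=0.0, seed=13)
    gmat, expr, truth = simulate_eqtl_dataset(spec)
    thresholds = []
    for m in (10, 30, 60):
        sub = gmat.subset_variants(np.arange(m))
        cal = permutation_fwer_threshold(
            sub, expr, truth.target_gene, n_permutations=200, seed=99
        )
        thresholds.append(cal.threshold)
    assert thresholds[0] >= thresholds[1] >= thresholds[2]


# ----------------------------------------------------- conditional scan

def _panel_with_perfect_proxy(seed=31):
    gmat, expr, truth = simulate_eqtl_dataset(
        EqtlSimSpec(n_snps=12, beta_cis=0.6, seed=seed)
    )
    idx = gmat.snp_index(truth.causal_snp)
    # append a perfect-LD copy of the causal SNP
    order = list(range(gmat.n_variants)) + [idx]
    dup = gmat.subset_variants(order)
    proxy = dup.variants[-1]
    dup.variants[-1] = type(proxy)(
        proxy.chrom, proxy.pos + 500, "proxy", proxy.ref_allele,
        proxy.alt_allele, proxy.ancestral_allele,
    )
    return dup, expr, truth


def test_conditioning_on_causal_removes_perfect_proxy():
    gmat, expr, truth = _panel_with_perfect_proxy()
    assert ld_r2(
        gmat.dosages[gmat.snp_index(truth.causal_snp)],
        gmat.dosages[gmat.snp_index("proxy")],
    ) == pytest.approx(1.0)
    res = conditional_scan(gmat, expr, truth.target_gene, truth.causal_snp)
    ids = {r.snp for r in res}
    assert truth.causal_snp not in ids  # excluded from output
    proxy_p = min(r.p_value for r in res if r.snp == "proxy")
    assert proxy_p > 0.01  # association fully absorbed


def test_conditioning_on_independent_snp_keeps_causal_signal():
    gmat, expr, truth = simulate_eqtl_dataset(
        EqtlSimSpec(n_snps=40, beta_cis=0.6, ld_decay=0.0, seed=37)
    )
    other = gmat.variants[0].id
    res = conditional_scan(gmat, expr, truth.target_gene, other)
    causal_p = min(r.p_value for r in res if r.snp == truth.causal_snp)
    assert causal_p < 1e-6


def test_conditioning_on_only_snp_returns_empty():
    gmat, expr, truth = simulate_eqtl_dataset(EqtlSimSpec(n_snps=2, seed=5))
    sub = gmat.subset_variants([gmat.snp_index(truth.causal_snp)])
    res = conditional_scan(sub, expr, truth.target_gene, truth.causal_snp)
    assert res == []


def test_conditioning_on_monomorphic_snp_rejected(eqtl_panel):
    gmat, expr, truth = eqtl_panel
    mono = gmat.subset_variants(np.arange(gmat.n_variants))
    mono.dosages[0, :] = 0
    with pytest.raises(ValueError, match="monomorphic"):
        conditional_scan(mono, expr, truth.target_gene, mono.variants[0].id)


# ----------------------------------------------------- BH / trans

@pytest.mark.parametrize("seed", range(6))
def test_bh_equals_stepup_oracle(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=rng.integers(5, 60))
    np.testing.assert_allclose(bh_qvalues(p), bh_oracle(p), atol=1e-12)
    # cross-check against statsmodels' independent implementation
    from statsmodels.stats.multitest import multipletests

    np.testing.assert_allclose(
        bh_qvalues(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
    )


def test_trans_scan_effect_size_filter():
    """A planted |beta| below the 0.2 floor is excluded regardless of p."""
    gmat, expr, truth = simulate_eqtl_dataset(
        EqtlSimSpec(
            n_individuals=800, n_snps=4, n_genes=30, n_trans_genes=5,
            beta_cis=0.0, beta_trans=0.12, maf_range=(0.25, 0.45), seed=77,
        )
    )
    res = map_trans_eqtl(
        gmat, truth.causal_snp, expr, "LPS", fdr=0.05, min_abs_beta=0.2
    )
    assert all(r.gene not in truth.trans_genes for r in res)
    res2 = map_trans_eqtl(
        gmat, truth.causal_snp, expr, "LPS", fdr=0.05, min_abs_beta=0.05
    )
    assert len([r for r in res2 if r.gene in truth.trans_genes]) >= 3


def test_trans_scan_null_is_empty():
    gmat, expr, truth = simulate_eqtl_dataset(
        EqtlSimSpec(n_snps=4, n_genes=200, beta_cis=0.0, seed=55)
    )
    res = map_trans_eqtl(gmat, truth.causal_snp, expr, "LPS", fdr=0.01)
    assert res == []


def test_trans_direction_labels():
    gmat, expr, truth = simulate_eqtl_dataset(
        EqtlSimSpec(n_snps=4, n_genes=5, n_trans_genes=3, beta_trans=-0.6, seed=6)
    )
    res = map_trans_eqtl(gmat, truth.causal_snp, expr, "LPS", fdr=0.05)
    planted = [r for r in res if r.gene in truth.trans_genes]
    assert planted and all(r.direction == "down" for r in planted)


# ----------------------------------------------------- LD

def test_ld_r2_self_is_one(rng):
    a = rng.integers(0, 3, 50)
    assert ld_r2(a, a) == pytest.approx(1.0)


def test_ld_r2_independent_snps_near_zero(rng):
    a = rng.integers(0, 3, 10_000)
    b = rng.integers(0, 3, 10_000)
    assert ld_r2(a, b) < 0.01


def test_ld_r2_missing_excluded_pairwise(rng):
    a = rng.integers(0, 3, 200)
    b = a.copy()
    b[:5] = -1  # missing in b; remaining pairs still identical
    assert ld_r2(a, b) == pytest.approx(1.0)


def test_ld_r2_monomorphic_rejected():
    with pytest.raises(ValueError, match="monomorphic"):
        ld_r2(np.zeros(10), np.arange(10) % 3)
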