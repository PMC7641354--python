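"""cis/trans eQTL mapping with permutation-based FWER calibration.

The model is ordinary least squares of rank-inverse-normal-transformed
expression on allele dosage with population of origin as a covariate,
fitted separately per stimulation condition.  Family-wise significance is
calibrated by permuting the transformed phenotype within population strata
and recording, per permutation, the minimum p-value over all SNPs *and*
conditions.  The trans scan tests one SNP against all expressed genes with
Benjamini-Hochberg FDR control plus a minimum effect-size filter.

Scans are vectorized with the Frisch-Waugh device: genotype and phenotype
are residualized on the covariates once, after which the dosage t-statistic
of the full OLS fit is a plain correlation.  ``fit_snp_gene`` is the
single-pair reference implementation and the tests pin the vectorized path
to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import MISSING, ExpressionMatrix, GenotypeMatrix


@dataclass
class EqtlResult:
    snp: str
    gene: str
    condition: str
    beta: float
    se: float
    p_value: float
    r2: float  # partial variance explained by genotype, after covariates
    q_value: float | None = None
    monomorphic: bool = False

    @property
    def direction(self) -> str:
        return "up" if self.beta > 0 else "down"


@dataclass
class FwerCalibration:
    n_permutations: int
    min_p_distribution: np.ndarray
    threshold: float
    target_fwer: float
    seed: int


# ---------------------------------------------------------------------------
# transforms and single fits
# ---------------------------------------------------------------------------

def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-inverse-normal transform: Phi^-1((rank - 0.5)/n), average ranks
    for ties."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("need a 1-D vector of at least 3 values")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if np.ptp(values) == 0:
        raise ValueError("rank transform undefined for a constant vector")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(values))


def _covariate_design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus covariate columns (population indicator etc.)."""
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


def fit_snp_gene(
    dosage: np.ndarray,
    expression: np.ndarray,
    covariates: np.ndarray | None = None,
    snp: str = "snp",
    gene: str = "gene",
    condition: str = "",
) -> EqtlResult:
    """OLS of (already transformed) expression on dosage + covariates.

    Missing dosages are mean-imputed.  A monomorphic genotype yields a
    flagged result with p = 1 by convention.
    """
    g = np.asarray(dosage, dtype=float).copy()
    y = np.asarray(expression, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples")
    miss = g == MISSING
    if miss.any():
        g[miss] = g[~miss].mean()
    if np.ptp(g) == 0:
        return EqtlResult(snp, gene, condition, np.nan, np.nan, 1.0, 0.0,
                          monomorphic=True)
    X = np.column_stack([_covariate_design(covariates, n), g])
    k = X.shape[1]
    beta_hat, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    df = n - k
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    b = float(beta_hat[-1])
    if se == 0.0 or rss <= 1e-20 * max(tss, 1e-300):
        # numerically perfect fit: p reported as exactly zero
        return EqtlResult(snp, gene, condition, b, 0.0, 0.0, 1.0)
    t = b / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    r2 = float(t * t / (t * t + df))  # partial R^2 of the dosage term
    return EqtlResult(snp, gene, condition, b, se, p, r2)


# ---------------------------------------------------------------------------
# vectorized scan machinery
# ---------------------------------------------------------------------------

def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residualize the columns of M on the column space of C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def _scan(
    G: np.ndarray, y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-SNP OLS via Frisch-Waugh.

    G: (m, n) imputed dosages; y: (n,); C: (n, k) covariate design with
    intercept.  Returns beta, se, p, r2 arrays of length m (NaN/p=1 for
    monomorphic SNPs).
    """
    n, k = C.shape
    df = n - k - 1
    Gr = _residualize(G.T, C).T  # (m, n)
    yr = _residualize(y[:, None], C)[:, 0]
    gss = (Gr * Gr).sum(axis=1)
    yss = float(yr @ yr)
    mono = gss <= 1e-12
    gss_safe = np.where(mono, 1.0, gss)
    beta = (Gr @ yr) / gss_safe
    rss = yss - beta**2 * gss_safe
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 0.0)
    r2 = np.where(np.isfinite(t), t * t / (t * t + df), 1.0)
    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)
    p = np.where(mono, 1.0, p)
    r2 = np.where(mono, 0.0, r2)
    return beta, se, p, r2


def _imputed_dosages(genotypes: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with per-variant, per-population mean imputation."""
    D = genotypes.dosages.astype(float)
    miss = genotypes.dosages == MISSING
    if miss.any():
        for pop in np.unique(genotypes.population):
            cols = genotypes.population == pop
            block = D[:, cols]
            mblock = miss[:, cols]
            with np.errstate(invalid="ignore"):
                means = np.where(mblock, np.nan, block)
                mu = np.nanmean(means, axis=1)
            mu = np.where(np.isnan(mu), 0.0, mu)
            block[mblock] = np.broadcast_to(mu[:, None], block.shape)[mblock]
            D[:, cols] = block
    return D


def _population_design(pop_labels: np.ndarray) -> np.ndarray:
    """Intercept + k-1 population indicator columns."""
    pops = sorted(set(pop_labels))
    cols = [np.ones(len(pop_labels))]
    for p in pops[1:]:
        cols.append((pop_labels == p).astype(float))
    return np.column_stack(cols)


def _condition_slices(
    genotypes: GenotypeMatrix, expression: ExpressionMatrix
) -> dict[str, np.ndarray]:
    """Per condition: index array mapping genotype individuals onto samples."""
    if expression.individual is None:
        raise ValueError("expression matrix lacks individual ids")
    out = {}
    for cond in expression.conditions:
        mask = expression.condition == cond
        ind_to_sample = {
            ind: i for i, ind in zip(np.nonzero(mask)[0], expression.individual[mask])
        }
        try:
            out[cond] = np.array(
                [ind_to_sample[ind] for ind in genotypes.individuals]
            )
        except KeyError as exc:
            raise ValueError(
                f"individual {exc} missing from condition {cond}"
            ) from None
    return out


# ---------------------------------------------------------------------------
# cis scan, permutation FWER, conditional scan
# ---------------------------------------------------------------------------

def map_cis_eqtl(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    target_gene: str,
    window: int | None = None,
    gene_pos: int | None = None,
    extra_covariate: np.ndarray | None = None,
    exclude_snps: set[str] = frozenset(),
) -> list[EqtlResult]:
    """Scan all SNPs (within ``window`` bp of ``gene_pos`` when given)
    against one gene, per condition, with population as covariate."""
    if window is not None and gene_pos is not None:
        keep = [
            i
            for i, v in enumerate(genotypes.variants)
            if abs(v.pos - gene_pos) <= window
        ]
        if not keep:
            return []
        genotypes = genotypes.subset_variants(keep)
    gi = expression.gene_index(target_gene)
    D = _imputed_dosages(genotypes)
    slices = _condition_slices(genotypes, expression)
    C0 = _population_design(genotypes.population)
    C = (
        C0
        if extra_covariate is None
        else np.column_stack([C0, np.asarray(extra_covariate, float)])
    )
    results: list[EqtlResult] = []
    for cond, sample_idx in slices.items():
        y = inverse_normal_transform(expression.values[gi, sample_idx])
        beta, se, p, r2 = _scan(D, y, C)
        for j, v in enumerate(genotypes.variants):
            if v.id in exclude_snps:
                continue
            results.append(
                EqtlResult(
                    v.id, target_gene, cond,
                    float(beta[j]), float(se[j]), float(p[j]), float(r2[j]),
                    monomorphic=bool(np.isnan(beta[j])),
                )
            )
    return results


def _strata_permutation(
    rng: np.random.Generator, pop_labels: np.ndarray, n_perm: int
) -> np.ndarray:
    """(n_perm, n) index matrix permuting within population strata."""
    n = len(pop_labels)
    out = np.tile(np.arange(n), (n_perm, 1))
    for pop in np.unique(pop_labels):
        idx = np.nonzero(pop_labels == pop)[0]
        for r in range(n_perm):
            out[r, idx] = rng.permutation(idx)
    return out


def permutation_fwer_threshold(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    target_gene: str,
    n_permutations: int = 1000,
    target_fwer: float = 0.01,
    seed: int = 0,
) -> FwerCalibration:
    """Permutation calibration of the family-wise significance threshold.

    Per permutation the transformed phenotype is shuffled within population
    strata (identically across SNPs), the whole scan re-run, and the minimum
    p over all SNPs and conditions recorded; the threshold is the
    ``target_fwer`` empirical quantile (k-th smallest, k = floor(alpha * B))
    of those minima, so that p < threshold occurs in fewer than
    ``target_fwer`` of permutations.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    k = int(np.floor(target_fwer * n_permutations))
    if k < 1:
        raise ValueError("target_fwer x n_permutations < 1: quantile unsupported")
    rng = np.random.default_rng(seed)
    gi = expression.gene_index(target_gene)
    D = _imputed_dosages(genotypes)
    C = _population_design(genotypes.population)
    slices = _condition_slices(genotypes, expression)

    n = genotypes.n_individuals
    df = n - C.shape[1] - 1
    Gr = _residualize(D.T, C).T
    gnorm = np.sqrt((Gr * Gr).sum(axis=1))
    mono = gnorm <= 1e-9
    Gn = Gr / np.where(mono, 1.0, gnorm)[:, None]
    Gn[mono] = 0.0

    perm_idx = _strata_permutation(rng, genotypes.population, n_permutations)
    min_p = np.full(n_permutations, np.inf)
    for cond, sample_idx in slices.items():
        y = inverse_normal_transform(expression.values[gi, sample_idx])
        Y = y[perm_idx.T]  # (n, n_perm)
        Yr = _residualize(Y, C)
        ynorm = np.sqrt((Yr * Yr).sum(axis=0))
        Yn = Yr / ynorm[None, :]
        R = Gn @ Yn  # (m, n_perm) partial correlations
        R = np.clip(R, -1 + 1e-15, 1 - 1e-15)
        T = R * np.sqrt(df / (1 - R * R))
        P = 2.0 * stats.t.sf(np.abs(T), df)
        P[mono] = 1.0
        min_p = np.minimum(min_p, P.min(axis=0))
    threshold = float(np.sort(min_p)[k - 1])
    return FwerCalibration(
        n_permutations=n_permutations,
        min_p_distribution=min_p,
        threshold=threshold,
        target_fwer=target_fwer,
        seed=seed,
    )


def conditional_scan(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    target_gene: str,
    condition_on: str,
    window: int | None = None,
    gene_pos: int | None = None,
) -> list[EqtlResult]:
    """cis scan with the conditioned SNP's dosage as an extra covariate;
    the conditioned SNP itself is excluded from the output."""
    ci = genotypes.snp_index(condition_on)
    cond_dosage = _imputed_dosages(genotypes)[ci]
    if np.ptp(cond_dosage) == 0:
        raise ValueError(f"cannot condition on monomorphic SNP {condition_on}")
    return map_cis_eqtl(
        genotypes,
        expression,
        target_gene,
        window=window,
        gene_pos=gene_pos,
        extra_covariate=cond_dosage,
        exclude_snps={condition_on},
    )


# ---------------------------------------------------------------------------
# trans scan with BH FDR
# ---------------------------------------------------------------------------

def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def map_trans_eqtl(
    genotypes: GenotypeMatrix,
    snp: str,
    expression: ExpressionMatrix,
    condition: str,
    fdr: float = 0.01,
    min_abs_beta: float = 0.2,
) -> list[EqtlResult]:
    """Test one SNP against every gene in one condition; return associations
    with BH q <= fdr and |beta| >= min_abs_beta."""
    if len(expression.genes) < 2:
        raise ValueError("need at least 2 genes for a trans scan")
    si = genotypes.snp_index(snp)
    g = _imputed_dosages(genotypes)[si]
    slices = _condition_slices(genotypes, expression)
    if condition not in slices:
        raise KeyError(condition)
    sample_idx = slices[condition]
    C = _population_design(genotypes.population)
    Y = np.vstack(
        [
            inverse_normal_transform(expression.values[k, sample_idx])
            for k in range(len(expression.genes))
        ]
    )  # (n_genes, n)
    beta, se, p, r2 = _scan_genes(g, Y, C)
    q = bh_qvalues(p)
    out = []
    for k, gene in enumerate(expression.genes):
        if q[k] <= fdr and abs(beta[k]) >= min_abs_beta:
            out.append(
                EqtlResult(
                    snp, gene, condition,
                    float(beta[k]), float(se[k]), float(p[k]), float(r2[k]),
                    q_value=float(q[k]),
                )
            )
    out.sort(key=lambda r: r.p_value)
    return out


def _scan_genes(
    g: np.ndarray, Y: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One SNP against many phenotypes: same algebra as _scan, transposed."""
    n, k = C.shape
    df = n - k - 1
    gr = _residualize(g[:, None].astype(float), C)[:, 0]
    Yr = _residualize(Y.T, C).T  # (n_genes, n)
    gss = float(gr @ gr)
    if gss <= 1e-12:
        m = Y.shape[0]
        return (np.full(m, np.nan), np.full(m, np.nan), np.ones(m), np.zeros(m))
    beta = Yr @ gr / gss
    rss = (Yr * Yr).sum(axis=1) - beta**2 * gss
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / df / gss)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), 0.0)
    r2 = np.where(np.isfinite(t), t * t / (t * t + df), 1.0)
    return beta, se, p, r2


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of dosage vectors, missing excluded
    pairwise.  Monomorphic input raises."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must cover the same individuals")
    valid = (a != MISSING) & (b != MISSING)
    a, b = a[valid], b[valid]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("r^2 undefined for a monomorphic site")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
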