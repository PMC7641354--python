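"""Population-genetic statistics around a focal SNP.

* Tajima's D over a physical window, from pairwise diversity pi and the
  Watterson estimator S/a1 with the standard variance normalisation.
* EHH decay curves and the integrated haplotype score iHS, with the
  log-ratio uiHS = ln(iHH_ancestral / iHH_derived) standardized within 40
  equal-width bins of derived allele frequency over [0.05, 0.95]; a sweep
  on the derived allele produces strongly negative values.
* Weir-Cockerham variance-components F_ST across populations (diploid
  dosages or haploid haplotypes), negative estimates retained.
* Empirical p-values by rank against a chromosome-wide reference
  distribution with the add-one rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import MISSING, GenotypeMatrix, HaplotypeSet


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass
class TajimaComponents:
    n: int
    S: int
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(
    haps: HaplotypeSet, window: tuple[int, int] | None = None
) -> TajimaComponents:
    """Tajima's D over sites with window[0] <= pos < window[1].

    pi is the mean pairwise difference over all haplotype pairs; D is NaN
    when the window holds no segregating site.
    """
    n = haps.n_haplotypes
    if n < 4:
        raise ValueError("need at least 4 haplotypes")
    sub = haps if window is None else haps.window(*window)
    H = sub.haplotypes.astype(np.int64)
    counts = H.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    counts = counts[seg]
    S = int(seg.sum())
    # mean pairwise difference: per site 2*k*(n-k) ordered pairs / C(n,2)
    pairs = n * (n - 1) / 2.0
    pi = float((counts * (n - counts)).sum() / pairs)
    c = _tajima_constants(n)
    if S == 0:
        D = math.nan
    else:
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        D = (pi - S / c["a1"]) / math.sqrt(var)
    return TajimaComponents(n=n, S=S, pi=pi, D=D, **c)


# ---------------------------------------------------------------------------
# EHH and iHS
# ---------------------------------------------------------------------------

def ehh(
    haps: HaplotypeSet,
    core_site: int,
    core_allele: int,
    direction: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Extended haplotype homozygosity decay from a core site.

    Returns (distances_bp, ehh_values), starting at distance 0 with EHH 1.
    EHH at each successive site outward is sum_k C(n_k, 2) / C(n_core, 2)
    over identical extended-haplotype classes k among core-allele carriers.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    H = haps.haplotypes
    carriers = np.nonzero(H[:, core_site] == core_allele)[0]
    n_core = len(carriers)
    if n_core < 2:
        raise ValueError("need at least 2 carriers of the core allele")
    denom = n_core * (n_core - 1) / 2.0
    core_pos = haps.positions[core_site]

    sites = (
        range(core_site - 1, -1, -1)
        if direction == "left"
        else range(core_site + 1, haps.n_sites)
    )
    dists = [0.0]
    values = [1.0]
    # incremental haplotype classes: group ids refined site by site
    groups = np.zeros(n_core, dtype=np.int64)
    sub = H[carriers]
    for s in sites:
        groups = groups * 2 + sub[:, s]
        _, counts = np.unique(groups, return_counts=True)
        # re-label to keep ids small
        _, groups = np.unique(groups, return_inverse=True)
        hom = float((counts * (counts - 1) / 2.0).sum() / denom)
        dists.append(abs(int(haps.positions[s]) - int(core_pos)))
        values.append(hom)
    return np.asarray(dists, float), np.asarray(values, float)


@dataclass
class IhsResult:
    position: int
    daf: float
    ihh_ancestral: float
    ihh_derived: float
    uihs: float
    ihs: float | None = None
    bin_index: int | None = None
    truncated: bool = False
    flagged: bool = False


def _ihh_one_side(
    dists: np.ndarray,
    values: np.ndarray,
    truncation_ehh: float,
    max_extension: float,
) -> tuple[float, bool]:
    """Trapezoidal integral of the EHH curve over physical distance, stopped
    at the first point below ``truncation_ehh`` or at ``max_extension``.
    Returns (area_bp, reached_truncation)."""
    area = 0.0
    for i in range(1, len(dists)):
        d0, d1 = dists[i - 1], min(dists[i], max_extension)
        v0, v1 = values[i - 1], values[i]
        if dists[i] > max_extension:
            if d1 > d0:
                # linear interpolation at the window edge
                frac = (max_extension - dists[i - 1]) / (dists[i] - dists[i - 1])
                v1 = v0 + frac * (v1 - v0)
                area += 0.5 * (v0 + v1) * (d1 - d0)
            return area, False
        area += 0.5 * (v0 + v1) * (d1 - d0)
        if v1 < truncation_ehh:
            return area, True
    return area, False


def ihs_unstandardized(
    haps: HaplotypeSet,
    core_site: int,
    truncation_ehh: float = 0.05,
    max_extension: float = 100_000.0,
) -> IhsResult:
    """uiHS = ln(iHH_ancestral / iHH_derived) at a polarized core site.

    iHH per allele is the trapezoidal integral of its EHH curve over both
    directions; a curve that never falls below ``truncation_ehh`` within
    ``max_extension`` (per side) leaves the result flagged as truncated.
    """
    daf = float(haps.haplotypes[:, core_site].mean())
    ihh = {}
    truncated = False
    for allele in (0, 1):
        total = 0.0
        for direction in ("left", "right"):
            d, v = ehh(haps, core_site, allele, direction)
            area, reached = _ihh_one_side(d, v, truncation_ehh, max_extension)
            total += area
            truncated |= not reached
        ihh[allele] = total
    if ihh[0] <= 0 or ihh[1] <= 0:
        raise ValueError("degenerate EHH integral (no flanking sites?)")
    uihs = math.log(ihh[0] / ihh[1])
    return IhsResult(
        position=int(haps.positions[core_site]),
        daf=daf,
        ihh_ancestral=ihh[0],
        ihh_derived=ihh[1],
        uihs=uihs,
        truncated=truncated,
    )


def ihs_scan(
    haps: HaplotypeSet,
    daf_range: tuple[float, float] = (0.05, 0.95),
    min_carriers: int = 2,
    truncation_ehh: float = 0.05,
    max_extension: float = 100_000.0,
) -> list[IhsResult]:
    """uiHS at every site whose DAF lies within ``daf_range`` and whose two
    alleles both have >= min_carriers carriers."""
    out = []
    daf = haps.daf
    n = haps.n_haplotypes
    for s in range(haps.n_sites):
        if not (daf_range[0] <= daf[s] <= daf_range[1]):
            continue
        k = int(round(daf[s] * n))
        if k < min_carriers or n - k < min_carriers:
            continue
        try:
            out.append(
                ihs_unstandardized(haps, s, truncation_ehh, max_extension)
            )
        except ValueError:
            continue
    return out


def ihs_standardize(
    results: list[IhsResult],
    n_bins: int = 40,
    daf_range: tuple[float, float] = (0.05, 0.95),
    min_bin_size: int = 2,
    bin_stats: list[tuple[float, float]] | None = None,
) -> list[IhsResult]:
    """Standardize uiHS within equal-width DAF bins: ihs = (uihs - bin mean)
    / bin sd.  Sites outside ``daf_range`` are dropped; bins with fewer than
    ``min_bin_size`` sites (or zero variance) are flagged, not standardized.

    ``bin_stats`` (per-bin mean/sd, e.g. from a neutral reference) overrides
    the within-data moments — used to standardize candidate sites against a
    neutral distribution.
    """
    lo, hi = daf_range
    width = (hi - lo) / n_bins
    kept = [r for r in results if lo <= r.daf <= hi]
    if not kept:
        return []
    bins = [min(int((r.daf - lo) / width), n_bins - 1) for r in kept]
    out: list[IhsResult] = []
    if bin_stats is None:
        bin_stats_arr: list[tuple[float, float] | None] = [None] * n_bins
        for b in range(n_bins):
            vals = np.array([r.uihs for r, bi in zip(kept, bins) if bi == b])
            if len(vals) >= min_bin_size and vals.std() > 0:
                bin_stats_arr[b] = (float(vals.mean()), float(vals.std()))
        if all(
            st is None for st in bin_stats_arr
        ) and len({b for b in bins}) == 1:
            raise ValueError("all sites in one bin with zero variance")
    else:
        bin_stats_arr = list(bin_stats)
    for r, b in zip(kept, bins):
        st = bin_stats_arr[b] if b < len(bin_stats_arr) else None
        if st is None:
            out.append(
                IhsResult(
                    r.position, r.daf, r.ihh_ancestral, r.ihh_derived, r.uihs,
                    ihs=None, bin_index=b, truncated=r.truncated, flagged=True,
                )
            )
        else:
            mu, sd = st
            out.append(
                IhsResult(
                    r.position, r.daf, r.ihh_ancestral, r.ihh_derived, r.uihs,
                    ihs=(r.uihs - mu) / sd, bin_index=b, truncated=r.truncated,
                )
            )
    return out


def ihs_bin_stats(
    results: list[IhsResult],
    n_bins: int = 40,
    daf_range: tuple[float, float] = (0.05, 0.95),
    min_bin_size: int = 2,
) -> list[tuple[float, float] | None]:
    """Per-DAF-bin (mean, sd) of uiHS, for standardizing other datasets."""
    lo, hi = daf_range
    width = (hi - lo) / n_bins
    stats: list[tuple[float, float] | None] = [None] * n_bins
    for b in range(n_bins):
        vals = np.array(
            [
                r.uihs
                for r in results
                if lo <= r.daf <= hi
                and min(int((r.daf - lo) / width), n_bins - 1) == b
            ]
        )
        if len(vals) >= min_bin_size and vals.std() > 0:
            stats[b] = (float(vals.mean()), float(vals.std()))
    return stats


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    fst_per_site: np.ndarray  # NaN where undefined (monomorphic overall)
    a: np.ndarray  # among-population variance component per site
    bc: np.ndarray  # within components (b + c) per site
    fst_global: float
    populations: list[str] = field(default_factory=list)


def _wc_components(
    p: np.ndarray, n: np.ndarray, h: np.ndarray
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one site.

    p: per-population ALT frequency; n: per-population sample size (diploid
    individuals, or haplotypes with h = 0 for haploid data); h: observed
    heterozygote frequency per population.
    """
    r = len(p)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    inner = pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0
    a = (nbar / nc) * (s2 - inner / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def fst_amova(
    data: GenotypeMatrix | HaplotypeSet,
    sites: np.ndarray | None = None,
) -> FstResult:
    """Weir-Cockerham multi-population F_ST per site and globally.

    The global value is the ratio of summed variance components over sites
    (the standard multi-locus combination).  Diploid dosage input uses the
    full a/b/c decomposition (heterozygotes from dosage == 1); haplotype
    input is treated as haploid samples (h = 0).  Sites monomorphic across
    all populations get NaN, flagged by omission from the global sums.
    """
    if isinstance(data, GenotypeMatrix):
        pops = sorted(set(data.population))
        if len(pops) < 2:
            raise ValueError("need at least 2 populations")
        D = data.dosages
        site_idx = np.arange(D.shape[0]) if sites is None else np.asarray(sites)
        a_arr = np.full(len(site_idx), np.nan)
        bc_arr = np.full(len(site_idx), np.nan)
        for out_i, s in enumerate(site_idx):
            p, nvec, hvec = [], [], []
            for pop in pops:
                d = D[s, data.population == pop]
                d = d[d != MISSING]
                if len(d) < 2:
                    raise ValueError(f"population {pop} has < 2 individuals at site {s}")
                nvec.append(len(d))
                p.append(d.sum() / (2.0 * len(d)))
                hvec.append((d == 1).mean())
            p, nvec, hvec = map(np.asarray, (p, nvec, hvec))
            pbar_all = (nvec * p).sum() / nvec.sum()
            if pbar_all in (0.0, 1.0):
                continue  # monomorphic overall: undefined
            a, b, c = _wc_components(p.astype(float), nvec.astype(float), hvec)
            a_arr[out_i], bc_arr[out_i] = a, b + c
    else:
        pops = sorted(set(data.population))
        if len(pops) < 2:
            raise ValueError("need at least 2 populations")
        H = data.haplotypes
        site_idx = np.arange(H.shape[1]) if sites is None else np.asarray(sites)
        a_arr = np.full(len(site_idx), np.nan)
        bc_arr = np.full(len(site_idx), np.nan)
        for out_i, s in enumerate(site_idx):
            p, nvec = [], []
            for pop in pops:
                col = H[data.population == pop, s]
                if len(col) < 2:
                    raise ValueError(f"population {pop} has < 2 haplotypes")
                nvec.append(len(col))
                p.append(col.mean())
            p, nvec = np.asarray(p, float), np.asarray(nvec, float)
            if (nvec * p).sum() / nvec.sum() in (0.0, 1.0):
                continue
            a, b, c = _wc_components(p, nvec, np.zeros_like(p))
            a_arr[out_i], bc_arr[out_i] = a, b + c

    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = a_arr / (a_arr + bc_arr)
    ok = ~np.isnan(a_arr)
    denom = (a_arr[ok] + bc_arr[ok]).sum()
    fst_global = float(a_arr[ok].sum() / denom) if ok.any() and denom != 0 else math.nan
    return FstResult(
        fst_per_site=per_site, a=a_arr, bc=bc_arr,
        fst_global=fst_global, populations=pops,
    )


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalP:
    observed: float
    n_reference: int
    rank: int  # number of reference values >= observed
    p_emp: float


def empirical_pvalue(
    observed: float, reference: np.ndarray, tail: str = "upper"
) -> EmpiricalP:
    """p_emp = (#{reference >= observed} + 1) / (N + 1); tail='abs' compares
    absolute values (used for iHS)."""
    reference = np.asarray(reference, dtype=float)
    reference = reference[~np.isnan(reference)]
    N = len(reference)
    if N < 20:
        raise ValueError("reference distribution too small (need >= 20 values)")
    if tail == "abs":
        observed = abs(observed)
        reference = np.abs(reference)
    elif tail != "upper":
        raise ValueError("tail must be 'upper' or 'abs'")
    rank = int((reference >= observed).sum())
    return EmpiricalP(
        observed=observed, n_reference=N, rank=rank, p_emp=(rank + 1) / (N + 1)
    )
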