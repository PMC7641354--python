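"""Independent brute-force reference implementations used to pin the
package's statistics.  Everything here is written directly from the
textbook definitions, scalar-looped, and deliberately shares no code with
the package."""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- Tajima's D --------------------------------------------------------------

def tajimas_d_oracle(hap_matrix: np.ndarray) -> tuple[int, float, float]:
    """(S, pi, D) from the definition: pi as the average number of
    differences over all C(n,2) haplotype pairs, Watterson from S."""
    H = np.asarray(hap_matrix)
    n = H.shape[0]
    seg_cols = [
        j for j in range(H.shape[1]) if 0 < H[:, j].sum() < n
    ]
    S = len(seg_cols)
    diffs = []
    for i, j in itertools.combinations(range(n), 2):
        diffs.append(sum(H[i, c] != H[j, c] for c in seg_cols))
    pi = sum(diffs) / len(diffs)
    if S == 0:
        return S, pi, math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return S, pi, D


# -- EHH ---------------------------------------------------------------------

def ehh_oracle(
    hap_matrix: np.ndarray,
    positions: np.ndarray,
    core_site: int,
    core_allele: int,
    direction: str,
) -> tuple[list[float], list[float]]:
    """EHH by direct pairwise comparison: the fraction of carrier pairs
    identical over every site from the core out to each successive site."""
    H = np.asarray(hap_matrix)
    carriers = [i for i in range(H.shape[0]) if H[i, core_site] == core_allele]
    n = len(carriers)
    pairs = list(itertools.combinations(carriers, 2))
    sites = (
        list(range(core_site - 1, -1, -1))
        if direction == "left"
        else list(range(core_site + 1, H.shape[1]))
    )
    dists, values = [0.0], [1.0]
    for stop_idx in range(len(sites)):
        span = sites[: stop_idx + 1]
        ident = 0
        for i, j in pairs:
            if all(H[i, s] == H[j, s] for s in span):
                ident += 1
        dists.append(abs(int(positions[sites[stop_idx]]) - int(positions[core_site])))
        values.append(ident / len(pairs))
    return dists, values


def trapezoid_oracle(dists, values, truncation, max_ext) -> float:
    """Integral by explicit trapezoid sums with the same stopping rule."""
    area = 0.0
    for i in range(1, len(dists)):
        if dists[i] > max_ext:
            frac = (max_ext - dists[i - 1]) / (dists[i] - dists[i - 1])
            v_edge = values[i - 1] + frac * (values[i] - values[i - 1])
            area += 0.5 * (values[i - 1] + v_edge) * (max_ext - dists[i - 1])
            return area
        area += 0.5 * (values[i - 1] + values[i]) * (dists[i] - dists[i - 1])
        if values[i] < truncation:
            return area
    return area


# -- Weir-Cockerham F_ST -----------------------------------------------------

def wc_fst_oracle(dosages: np.ndarray, pops: np.ndarray) -> tuple[float, float]:
    """Per-site (a, a+b+c) from the 1984 variance-components paper,
    transcribed term by term for diploid two-allele data."""
    labels = sorted(set(pops))
    r = len(labels)
    n_i, p_i, h_i = [], [], []
    for lab in labels:
        d = [x for x, p in zip(dosages, pops) if p == lab and x >= 0]
        n_i.append(len(d))
        p_i.append(sum(d) / (2.0 * len(d)))
        h_i.append(sum(1 for x in d if x == 1) / len(d))
    nbar = sum(n_i) / r
    sum_n = sum(n_i)
    nc = (sum_n - sum(n * n for n in n_i) / sum_n) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / sum_n
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / sum_n
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def wc_fst_haploid_oracle(alleles: np.ndarray, pops: np.ndarray) -> tuple[float, float]:
    """Haploid variant: same components with no heterozygote term."""
    labels = sorted(set(pops))
    r = len(labels)
    n_i, p_i = [], []
    for lab in labels:
        col = [x for x, p in zip(alleles, pops) if p == lab]
        n_i.append(len(col))
        p_i.append(sum(col) / len(col))
    nbar = sum(n_i) / r
    sum_n = sum(n_i)
    nc = (sum_n - sum(n * n for n in n_i) / sum_n) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / sum_n
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    )
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    return a, a + b


# -- Benjamini-Hochberg ------------------------------------------------------

def bh_oracle(pvalues) -> np.ndarray:
    """Adjusted p-values by the definition q_(i) = min_{j >= i} m p_(j) / j."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)), 1.0
        )
    return np.array(q)


# -- PWM scanning ------------------------------------------------------------

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def pwm_scan_oracle(
    weights: np.ndarray, sequence: str, focal: int, threshold: float | None
) -> list[tuple[int, str, float]]:
    """All (start, strand, relative_score) whose window covers ``focal`` and
    passes the min-max relative threshold, by explicit enumeration."""
    L = weights.shape[1]
    max_s = sum(max(weights[:, j]) for j in range(L))
    min_s = sum(min(weights[:, j]) for j in range(L))
    out = []
    for start in range(len(sequence) - L + 1):
        if not (start <= focal < start + L):
            continue
        window = sequence[start : start + L]
        for strand in "+-":
            w = window if strand == "+" else "".join(
                _COMP[b] for b in reversed(window)
            )
            if any(b not in _IDX for b in w):
                continue
            raw = sum(weights[_IDX[b], j] for j, b in enumerate(w))
            rel = (raw - min_s) / (max_s - min_s)
            if threshold is None or rel >= threshold:
                out.append((start, strand, rel))
    return out


# -- rank / empirical --------------------------------------------------------

def empirical_p_oracle(observed: float, reference, absolute: bool) -> float:
    ref = [abs(x) for x in reference] if absolute else list(reference)
    obs = abs(observed) if absolute else observed
    ge = sum(1 for x in ref if x >= obs)
    return (ge + 1) / (len(ref) + 1)
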