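"""Oracle equivalence and behavioral checks for the selection statistics."""

import math

import numpy as np
import pytest

from regfire import (
    HaplotypeSet,
    ehh,
    empirical_pvalue,
    fst_amova,
    ihs_scan,
    ihs_standardize,
    ihs_unstandardized,
    tajimas_d,
)
from regfire.selection_scan import _ihh_one_side

from conftest import random_haplotype_set, toy_genotypes
from oracles import (
    ehh_oracle,
    empirical_p_oracle,
    tajimas_d_oracle,
    trapezoid_oracle,
    wc_fst_haploid_oracle,
    wc_fst_oracle,
)


def hapset(matrix, positions=None):
    H = np.asarray(matrix, dtype=np.uint8)
    if positions is None:
        positions = np.arange(H.shape[1]) * 100 + 100
    return HaplotypeSet(
        haplotypes=H,
        positions=np.asarray(positions),
        population=np.array(["p"] * H.shape[0], dtype=object),
    )


# ----------------------------------------------------- Tajima's D

def test_tajima_four_haplotype_fixture():
    hs = hapset([[0, 0, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 1, 1]])
    res = tajimas_d(hs)
    S, pi, D = tajimas_d_oracle(hs.haplotypes)
    assert res.S == S == 4
    assert res.pi == pytest.approx(pi, abs=1e-12)
    assert res.D == pytest.approx(D, abs=1e-12)
    assert res.a1 == pytest.approx(1 + 1 / 2 + 1 / 3, abs=1e-12)


def test_tajima_no_segregating_sites_is_nan():
    hs = hapset(np.zeros((5, 0), dtype=np.uint8), positions=[])
    assert math.isnan(tajimas_d(hs).D)
    assert tajimas_d(hs).S == 0


@pytest.mark.parametrize("seed", range(25))
def test_tajima_matches_oracle_on_random_fixtures(seed, rng=None):
    rng = np.random.default_rng(seed)
    hs = random_haplotype_set(rng, n=int(rng.integers(4, 11)), s=int(rng.integers(4, 20)))
    res = tajimas_d(hs)
    S, pi, D = tajimas_d_oracle(hs.haplotypes)
    assert res.S == S
    assert res.pi == pytest.approx(pi, abs=1e-10)
    assert res.D == pytest.approx(D, abs=1e-10)


def test_tajima_windowing(neutral_haps):
    full = tajimas_d(neutral_haps)
    half = tajimas_d(neutral_haps, window=(0, 50_000))
    assert half.S < full.S
    lo = neutral_haps.positions < 50_000
    assert half.S == int(
        (
            (neutral_haps.haplotypes[:, lo].sum(axis=0) > 0)
            & (neutral_haps.haplotypes[:, lo].sum(axis=0) < neutral_haps.n_haplotypes)
        ).sum()
    )


# ----------------------------------------------------- EHH / iHS

def test_ehh_starts_at_one_and_is_monotone():
    rng = np.random.default_rng(5)
    hs = random_haplotype_set(rng, n=10, s=15)
    core = hs.n_sites // 2
    for allele in (0, 1):
        if (hs.haplotypes[:, core] == allele).sum() < 2:
            continue
        for direction in ("left", "right"):
            d, v = ehh(hs, core, allele, direction)
            assert v[0] == 1.0
            assert all(a >= b - 1e-12 for a, b in zip(v, v[1:]))


def test_ehh_identical_carriers_stay_at_one():
    H = np.vstack([np.tile([1, 0, 1, 1, 0], (3, 1)), np.zeros((3, 5), int)])
    H[3:, 2] = 0
    H[:3, 2] = 1  # core site: carriers are the three identical rows
    hs = hapset(H)
    d, v = ehh(hs, 2, 1, "right")
    np.testing.assert_allclose(v, 1.0)


@pytest.mark.parametrize("seed", range(15))
def test_ehh_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    hs = random_haplotype_set(rng, n=8, s=12)
    core = hs.n_sites // 2
    for allele in (0, 1):
        if (hs.haplotypes[:, core] == allele).sum() < 2:
            continue
        for direction in ("left", "right"):
            d, v = ehh(hs, core, allele, direction)
            d2, v2 = ehh_oracle(hs.haplotypes, hs.positions, core, allele, direction)
            np.testing.assert_allclose(d, d2, atol=1e-12)
            np.testing.assert_allclose(v, v2, atol=1e-12)


def test_ehh_requires_two_carriers():
    hs = hapset([[1, 0], [0, 0], [0, 0], [0, 1]])
    with pytest.raises(ValueError, match="carriers"):
        ehh(hs, 0, 1, "right")


def test_uihs_zero_under_mirror_symmetry():
    """Ancestral and derived carrier sets with mirror-image structure give
    log-ratio exactly zero."""
    block = np.array(
        [[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=np.uint8
    )
    core = np.array([0, 0, 1, 1], dtype=np.uint8)
    H = np.column_stack([block[:, :1], core, block[:, 1:]])
    # carriers of 0: rows 0,1 ; carriers of 1: rows 2,3 — same internal pattern
    H[2:, [0, 2, 3]] = H[:2, [0, 2, 3]]
    hs = hapset(H)
    res = ihs_unstandardized(hs, 1)
    assert res.uihs == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_ihh_matches_trapezoid_oracle(seed):
    rng = np.random.default_rng(300 + seed)
    hs = random_haplotype_set(rng, n=8, s=10, length=5000)
    core = hs.n_sites // 2
    counts = hs.haplotypes[:, core].sum()
    if counts < 2 or hs.n_haplotypes - counts < 2:
        return
    res = ihs_unstandardized(hs, core, truncation_ehh=0.05, max_extension=2000)
    for allele, got in ((0, res.ihh_ancestral), (1, res.ihh_derived)):
        exp = 0.0
        for direction in ("left", "right"):
            d, v = ehh_oracle(hs.haplotypes, hs.positions, core, allele, direction)
            exp += trapezoid_oracle(d, v, 0.05, 2000)
        assert got == pytest.approx(exp, abs=1e-6)
        assert math.log(res.ihh_ancestral / res.ihh_derived) == pytest.approx(
            res.uihs, abs=1e-12
        )


def test_hand_trapezoid_fixture():
    """8 haplotypes, 5 sites: iHH checked against explicit hand arithmetic."""
    H = np.array(
        [
            [1, 1, 1, 0, 0],
            [1, 1, 1, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 1, 1, 1, 0],
            [1, 0, 0, 0, 1],
            [0, 1, 0, 0, 1],
            [1, 1, 0, 1, 1],
            [0, 0, 0, 1, 1],
        ],
        dtype=np.uint8,
    )
    hs = hapset(H, positions=[0, 100, 200, 300, 400])
    # derived carriers at site 2 (col 2): rows 0,1,2,3
    # right: site 3 -> classes {0,0,1,1}: pairs (C(2,2 choices)) = 1+1 of 6 -> 1/3
    #        site 4 -> all carry 0 at col 4 -> classes {00,00,10,10} -> still 1/3
    # EHH right: [1, 1/3, 1/3]; area = 0.5*(1+1/3)*100 + 0.5*(1/3+1/3)*100
    d, v = ehh(hs, 2, 1, "right")
    np.testing.assert_allclose(v, [1.0, 1 / 3, 1 / 3])
    area, reached = _ihh_one_side(d, v, 0.05, 400)
    assert area == pytest.approx(0.5 * (1 + 1 / 3) * 100 + (1 / 3) * 100, abs=1e-9)
    assert not reached  # EHH never fell below 0.05


def test_truncation_flag_set_when_ehh_stays_high():
    H = np.tile(np.array([[1], [1], [0], [0]], dtype=np.uint8), (1, 3))
    hs = hapset(H)
    res = ihs_unstandardized(hs, 1, truncation_ehh=0.05, max_extension=10_000)
    assert res.truncated


# ----------------------------------------------------- iHS standardization

def _fake_results(rng, n=400):
    from regfire.selection_scan import IhsResult

    daf = rng.uniform(0.05, 0.95, n)
    uihs = rng.normal(0.3 * daf, 1.0)
    return [
        IhsResult(position=i, daf=float(daf[i]), ihh_ancestral=1.0,
                  ihh_derived=1.0, uihs=float(uihs[i]))
        for i in range(n)
    ]


def test_standardized_bins_have_zero_mean_unit_sd(rng):
    out = ihs_standardize(_fake_results(rng, 2000), n_bins=10)
    by_bin = {}
    for r in out:
        if r.ihs is not None:
            by_bin.setdefault(r.bin_index, []).append(r.ihs)
    for vals in by_bin.values():
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-9)
        assert np.std(vals) == pytest.approx(1.0, abs=1e-9)


def test_out_of_range_daf_dropped(rng):
    from regfire.selection_scan import IhsResult

    res = _fake_results(rng, 50) + [
        IhsResult(position=999, daf=0.96, ihh_ancestral=1, ihh_derived=1, uihs=0.0)
    ]
    out = ihs_standardize(res, n_bins=5)
    assert all(r.daf <= 0.95 for r in out)
    assert not any(r.position == 999 for r in out)


def test_two_bin_hand_arithmetic():
    from regfire.selection_scan import IhsResult

    mk = lambda daf, u: IhsResult(0, daf, 1, 1, u)
    res = [mk(0.1, 1.0), mk(0.12, 3.0), mk(0.8, -2.0), mk(0.82, 0.0)]
    out = ihs_standardize(res, n_bins=2, daf_range=(0.05, 0.95))
    # bin 0: mean 2, sd 1 -> (-1, 1); bin 1: mean -1, sd 1 -> (-1, 1)
    assert [round(r.ihs, 9) for r in out] == [-1.0, 1.0, -1.0, 1.0]


def test_standardization_affine_invariant_up_to_sign(rng):
    res = _fake_results(rng, 300)
    base = ihs_standardize(res, n_bins=6)
    from regfire.selection_scan import IhsResult

    scaled = [
        IhsResult(r.position, r.daf, r.ihh_ancestral, r.ihh_derived,
                  2.5 * r.uihs - 1.0)
        for r in res
    ]
    out = ihs_standardize(scaled, n_bins=6)
    for a, b in zip(base, out):
        if a.ihs is not None:
            assert b.ihs == pytest.approx(a.ihs, abs=1e-9)


def test_sparse_bin_flagged_not_standardized():
    from regfire.selection_scan import IhsResult

    res = [IhsResult(0, 0.1, 1, 1, 1.0), IhsResult(1, 0.9, 1, 1, 2.0),
           IhsResult(2, 0.9, 1, 1, 3.0)]
    out = ihs_standardize(res, n_bins=2)
    lone = [r for r in out if r.daf == 0.1][0]
    assert lone.flagged and lone.ihs is None


# ----------------------------------------------------- F_ST

def test_fst_opposite_fixation_near_one():
    dos = np.array([[2] * 50 + [0] * 50])
    pops = ["A"] * 50 + ["B"] * 50
    g = toy_genotypes(dos, pops)
    res = fst_amova(g)
    a, abc = wc_fst_oracle(dos[0], np.array(pops))
    assert res.fst_per_site[0] == pytest.approx(a / abc, abs=1e-12)
    assert res.fst_per_site[0] >= 0.97


def test_fst_identical_frequencies_near_zero(rng):
    m, n = 200, 200
    dos = rng.binomial(2, 0.3, size=(m, n)).astype(np.int8)
    pops = ["A"] * 100 + ["B"] * 100
    g = toy_genotypes(dos, pops)
    res = fst_amova(g)
    assert abs(res.fst_global) <= 0.02


def test_fst_three_population_toy_vs_oracle():
    dos = np.array([[0, 1, 2, 2, 1, 0], [2, 2, 1, 0, 0, 1]], dtype=np.int8)
    pops = np.array(["A", "A", "B", "B", "C", "C"])
    g = toy_genotypes(dos, pops)
    res = fst_amova(g)
    for s in range(2):
        a, abc = wc_fst_oracle(dos[s], pops)
        assert res.fst_per_site[s] == pytest.approx(a / abc, abs=1e-10)
    # global: ratio of summed components
    nums, dens = zip(*(wc_fst_oracle(dos[s], pops) for s in range(2)))
    assert res.fst_global == pytest.approx(sum(nums) / sum(dens), abs=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_fst_random_fixtures_vs_oracle(seed):
    rng = np.random.default_rng(400 + seed)
    n_pops = int(rng.integers(2, 4))
    sizes = rng.integers(3, 8, n_pops)
    pops = np.repeat([f"P{i}" for i in range(n_pops)], sizes)
    while True:
        dos = rng.integers(0, 3, size=(4, sizes.sum())).astype(np.int8)
        if all(0 < dos[s].sum() < 2 * len(pops) for s in range(4)):
            break
    g = toy_genotypes(dos, pops)
    res = fst_amova(g)
    for s in range(4):
        a, abc = wc_fst_oracle(dos[s], pops)
        assert res.fst_per_site[s] == pytest.approx(a / abc, abs=1e-10)


def test_fst_haploid_path_vs_oracle(rng):
    n = 40
    H = rng.integers(0, 2, size=(n, 6)).astype(np.uint8)
    H[0, H.sum(axis=0) == 0] = 1  # ensure polymorphic
    pops = np.array(["X"] * 20 + ["Y"] * 20, dtype=object)
    hs = HaplotypeSet(H, np.arange(6) * 10, pops)
    res = fst_amova(hs)
    for s in range(6):
        a, ab = wc_fst_haploid_oracle(H[:, s], pops)
        assert res.fst_per_site[s] == pytest.approx(a / ab, abs=1e-10)


def test_fst_invariant_to_population_label_permutation():
    rng = np.random.default_rng(9)
    dos = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
    pops = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
    g1 = fst_amova(toy_genotypes(dos, pops)).fst_global
    relabel = {"A": "C", "B": "A", "C": "B"}
    g2 = fst_amova(toy_genotypes(dos, [relabel[p] for p in pops])).fst_global
    assert g1 == pytest.approx(g2, abs=1e-12)


def test_fst_monomorphic_site_is_nan():
    dos = np.array([[0, 0, 0, 0], [0, 1, 2, 1]], dtype=np.int8)
    g = toy_genotypes(dos, ["A", "A", "B", "B"])
    res = fst_amova(g)
    assert math.isnan(res.fst_per_site[0])
    assert not math.isnan(res.fst_per_site[1])


# ----------------------------------------------------- empirical p

def test_empirical_p_add_one_rule():
    ref = np.arange(999, dtype=float)
    res = empirical_pvalue(10_000.0, ref)
    assert res.p_emp == pytest.approx(1 / 1000)
    mid = empirical_pvalue(499.0, ref)
    assert mid.p_emp == pytest.approx(0.5, abs=0.01)


@pytest.mark.parametrize("tail", ["upper", "abs"])
def test_empirical_p_matches_sort_count_oracle(tail, rng):
    ref = rng.normal(size=100)
    for obs in (-1.5, 0.0, 0.7, 2.5):
        got = empirical_pvalue(obs, ref, tail=tail).p_emp
        exp = empirical_p_oracle(obs, ref, absolute=(tail == "abs"))
        assert got == pytest.approx(exp, abs=1e-12)


def test_empirical_p_small_reference_rejected():
    with pytest.raises(ValueError, match="reference"):
        empirical_pvalue(1.0, np.arange(10))
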