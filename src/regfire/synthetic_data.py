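"""Synthetic genotype/expression panels, haplotypes and ortholog alignments.

Every generator is a pure function of its spec (including the seed), so all
downstream stages are testable against known ground truth without any
external download.

What these emulate, and what they do not:

* ``simulate_eqtl_dataset`` builds a two-population monocyte-style panel
  (default 100 + 100 individuals) with LD-correlated SNPs and one planted
  cis effect on a target gene across two stimulation conditions.  LD comes
  from a first-order Markov allele-copy process, not population history.
* ``simulate_haplotypes`` is a forward Wright–Fisher simulator (haploid
  reproduction with recombination and infinite-sites mutation) with an
  optional partial selective sweep; it stands in for phased reference-panel
  haplotypes.  No demography beyond a single constant-size population.
* ``simulate_ortholog_alignment`` mutates a root sequence independently per
  species and plants a motif consensus into a controllable number of
  species around a focal column; it stands in for multiz-style vertebrate
  alignment blocks (no indel process).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_io import (
    AlignmentBlock,
    ExpressionMatrix,
    GenotypeMatrix,
    HaplotypeSet,
    VariantRecord,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# eQTL panel
# ---------------------------------------------------------------------------

@dataclass
class EqtlSimSpec:
    """Study-design parameters for a two-population eQTL panel.

    ``beta_cis`` is the planted effect per ALT allele copy on the
    (approximately unit-variance, hence rank-normal) expression scale.  When
    ``noise_sd`` is None it is chosen per gene so the phenotype has unit
    marginal variance, which is what keeps ``beta_cis`` on the transformed
    scale that the eQTL fit estimates.
    """

    n_individuals: int = 100  # per population (2 populations)
    n_snps: int = 500
    n_genes: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_cis: float = 0.5
    pop_shift: float = 0.3  # mean expression offset between populations
    n_conditions: int = 2
    noise_sd: Optional[float] = None  # None -> auto (unit phenotype variance)
    ld_decay: float = 0.7  # per-adjacent-SNP allele-copy probability
    n_trans_genes: int = 0
    beta_trans: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_snps < 2:
            raise ValueError("need at least 2 SNPs")


@dataclass
class EqtlTruth:
    causal_snp: str
    target_gene: str
    beta_cis: float
    trans_genes: dict[str, float] = field(default_factory=dict)


_CONDITIONS = ("NS", "LPS", "Pam3CSK4", "R848")
_POPS = ("AFB", "EUB")


def _markov_haplotypes(
    rng: np.random.Generator, n_haps: int, freqs: np.ndarray, ld_decay: float
) -> np.ndarray:
    """First-order Markov copy process along SNPs.

    Allele at SNP j+1 copies the allele at SNP j with probability
    ``ld_decay``, otherwise it is a fresh Bernoulli(freq_{j+1}) draw.  The
    marginal frequency of each SNP is a convex combination of upstream
    frequencies, so it stays inside the frequency range of the draws.
    """
    m = len(freqs)
    haps = np.empty((n_haps, m), dtype=np.uint8)
    haps[:, 0] = rng.random(n_haps) < freqs[0]
    for j in range(1, m):
        fresh = (rng.random(n_haps) < freqs[j]).astype(np.uint8)
        copy = rng.random(n_haps) < ld_decay
        haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    return haps


def _auto_noise_sd(beta: float, g_var: float, pop_shift: float, pop_var: float) -> float:
    resid = 1.0 - beta**2 * g_var - pop_shift**2 * pop_var
    if resid <= 0:
        raise ValueError(
            "beta_cis/pop_shift too large for unit phenotype variance; "
            "pass an explicit noise_sd"
        )
    return float(np.sqrt(resid))


def simulate_eqtl_dataset(
    spec: EqtlSimSpec,
) -> tuple[GenotypeMatrix, ExpressionMatrix, EqtlTruth]:
    """Generate a genotype panel and matched expression with one planted
    cis effect (and optionally planted trans effects of the same SNP)."""
    rng = np.random.default_rng(spec.seed)
    n_per_pop, m = spec.n_individuals, spec.n_snps
    n_ind = 2 * n_per_pop

    freqs = rng.uniform(*spec.maf_range, size=m)
    haps = np.vstack(
        [
            _markov_haplotypes(rng, 2 * n_per_pop, freqs, spec.ld_decay)
            for _ in range(2)
        ]
    )
    dosages = (haps[0::2] + haps[1::2]).T.astype(np.int8)  # variants x individuals

    causal_idx = m // 2
    chrom, locus_start, spacing = "chr9", 20_500_000, 2_000
    variants = [
        VariantRecord(
            chrom=chrom,
            pos=locus_start + j * spacing,
            id=f"snp{j:05d}",
            ref_allele="A",
            alt_allele="G",
            ancestral_allele="A",
        )
        for j in range(m)
    ]
    individuals = [
        f"{_POPS[k]}{i:04d}" for k in range(2) for i in range(n_per_pop)
    ]
    population = np.array(
        [_POPS[0]] * n_per_pop + [_POPS[1]] * n_per_pop, dtype=object
    )
    gmat = GenotypeMatrix(variants, dosages, individuals, population)

    # expression: samples = individuals x conditions
    conds = _CONDITIONS[: spec.n_conditions]
    samples = [f"{ind}:{c}" for c in conds for ind in individuals]
    sample_cond = np.array([c for c in conds for _ in individuals], dtype=object)
    sample_pop = np.tile(population, spec.n_conditions)
    sample_ind = np.array([ind for _ in conds for ind in individuals], dtype=object)

    g = dosages[causal_idx].astype(float)
    g_c = g - g.mean()  # centered, NOT standardized: beta is per allele copy
    g_var = float(g_c.var())
    pop_ind = (population == _POPS[1]).astype(float)
    pop_c = pop_ind - pop_ind.mean()
    pop_var = float(pop_c.var())

    n_genes = spec.n_genes + spec.n_trans_genes
    genes = [f"gene{k:05d}" for k in range(n_genes)]
    target = genes[0]
    trans_ids = genes[spec.n_genes :]

    values = np.empty((n_genes, len(samples)))
    for k, gene in enumerate(genes):
        beta = (
            spec.beta_cis
            if gene == target
            else (spec.beta_trans if gene in trans_ids else 0.0)
        )
        sd = (
            spec.noise_sd
            if spec.noise_sd is not None
            else _auto_noise_sd(beta, g_var, spec.pop_shift, pop_var)
        )
        for ci in range(spec.n_conditions):
            eps = rng.normal(0.0, sd, size=n_ind)
            y = beta * g_c + spec.pop_shift * pop_c + eps
            values[k, ci * n_ind : (ci + 1) * n_ind] = y

    expr = ExpressionMatrix(
        genes=genes,
        values=values,
        samples=samples,
        condition=sample_cond,
        population=sample_pop,
        individual=sample_ind,
    )
    truth = EqtlTruth(
        causal_snp=variants[causal_idx].id,
        target_gene=target,
        beta_cis=spec.beta_cis,
        trans_genes={gid: spec.beta_trans for gid in trans_ids},
    )
    return gmat, expr, truth


# ---------------------------------------------------------------------------
# Forward Wright-Fisher haplotype simulator
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    position: int
    selection_coefficient: float
    final_frequency: float

    def __post_init__(self) -> None:
        if not (0 < self.final_frequency < 1):
            raise ValueError("final_frequency must be in (0, 1)")
        if self.selection_coefficient < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass
class HapSimSpec:
    """Forward Wright-Fisher run over a single panmictic population.

    Rates are per bp per haplotype per generation.  ``pop_size`` counts
    haplotypes.  Defaults give theta_W ~= 50 per 100 kb for a sample of 200,
    i.e. a few hundred segregating sites — enough site density for EHH/iHS
    at desk scale.
    """

    n_haplotypes: int = 200
    region_length: int = 100_000
    mutation_density: float = 1.25e-6
    recomb_prob: float = 1.0e-6
    pop_size: int = 200
    n_generations: int = 2_500
    sweep: Optional[SweepSpec] = None
    max_restarts: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_density < 0 or self.recomb_prob < 0:
            raise ValueError("rates must be >= 0")
        if self.n_haplotypes > self.pop_size:
            raise ValueError("cannot sample more haplotypes than the population holds")


class SweepLostError(RuntimeError):
    def __init__(self, restarts: int):
        super().__init__(
            f"sweep allele lost before reaching its target frequency in "
            f"{restarts} restarts"
        )
        self.restarts = restarts


class _WFState:
    """Population haplotype matrix with position-sorted columns."""

    __slots__ = ("haps", "positions")

    def __init__(self, haps: np.ndarray, positions: np.ndarray):
        self.haps = haps  # (N, S) uint8
        self.positions = positions  # (S,) int64 sorted

    def copy(self) -> "_WFState":
        return _WFState(self.haps.copy(), self.positions.copy())


def _wf_generation(
    state: _WFState,
    rng: np.random.Generator,
    spec: HapSimSpec,
    fitness: np.ndarray | None,
) -> _WFState:
    N, L = spec.pop_size, spec.region_length
    if fitness is None:
        parent1 = rng.integers(0, N, size=N)
    else:
        p = fitness / fitness.sum()
        parent1 = rng.choice(N, size=N, p=p)
    haps = state.haps[parent1]

    # recombination: Poisson crossovers per offspring, alternating segments
    mean_xo = spec.recomb_prob * L
    if mean_xo > 0 and state.haps.shape[1] > 0:
        n_xo = rng.poisson(mean_xo, size=N)
        for i in np.nonzero(n_xo)[0]:
            if fitness is None:
                p2 = int(rng.integers(0, N))
            else:
                p2 = int(rng.choice(N, p=p))
            bps = np.sort(rng.integers(0, L, size=n_xo[i]))
            cuts = np.searchsorted(state.positions, bps)
            row_a, row_b = haps[i].copy(), state.haps[p2]
            take_b = np.zeros(len(state.positions), dtype=bool)
            for k, c in enumerate(cuts):
                if k % 2 == 0:
                    take_b[c:] = True
                else:
                    take_b[c:] = False
            row_a[take_b] = row_b[take_b]
            haps[i] = row_a

    # infinite-sites mutation: new singleton columns
    n_mut = rng.poisson(spec.mutation_density * L * N)
    if n_mut > 0:
        mpos = rng.integers(0, L, size=n_mut)
        mpos = np.setdiff1d(mpos, state.positions)  # infinite sites: unique
        if len(mpos):
            rows = rng.integers(0, N, size=len(mpos))
            new_cols = np.zeros((N, len(mpos)), dtype=np.uint8)
            new_cols[rows, np.arange(len(mpos))] = 1
            positions = np.concatenate([state.positions, mpos])
            order = np.argsort(positions, kind="stable")
            haps = np.concatenate([haps, new_cols], axis=1)[:, order]
            positions = positions[order]
            return _prune(_WFState(haps, positions), N)
    return _prune(_WFState(haps, state.positions), N)


def _prune(state: _WFState, N: int, keep_pos: int | None = None) -> _WFState:
    counts = state.haps.sum(axis=0)
    keep = (counts > 0) & (counts < N)
    if keep_pos is not None:
        keep |= state.positions == keep_pos
    if keep.all():
        return state
    return _WFState(state.haps[:, keep], state.positions[keep])


def simulate_haplotypes(spec: HapSimSpec) -> HaplotypeSet:
    """Run the forward Wright-Fisher model and sample ``n_haplotypes``.

    Under a sweep, a derived allele is introduced on one haplotype after the
    neutral burn-in and evolved with multiplicative fitness 1 + s until it
    reaches ``final_frequency``; runs in which it is lost restart from the
    saved neutral state (an error is raised after ``max_restarts``).
    """
    if spec.sweep is not None and not (
        0 <= spec.sweep.position < spec.region_length
    ):
        raise ValueError("sweep position outside the simulated region")
    rng = np.random.default_rng(spec.seed)
    state = _WFState(
        np.zeros((spec.pop_size, 0), dtype=np.uint8), np.array([], dtype=np.int64)
    )
    for _ in range(spec.n_generations):
        state = _wf_generation(state, rng, spec, fitness=None)

    if spec.sweep is not None:
        state = _run_sweep(state, rng, spec)

    idx = rng.choice(spec.pop_size, size=spec.n_haplotypes, replace=False)
    haps = state.haps[idx]
    positions = state.positions
    # drop sites monomorphic in the sample (focal sweep site is retained by
    # construction: final_frequency is interior and the sample is large)
    counts = haps.sum(axis=0)
    seg = (counts > 0) & (counts < spec.n_haplotypes)
    if spec.sweep is not None:
        seg |= positions == spec.sweep.position
    return HaplotypeSet(
        haplotypes=haps[:, seg],
        positions=positions[seg],
        population=np.array(["pop"] * spec.n_haplotypes, dtype=object),
    )


def _run_sweep(
    neutral: _WFState, rng: np.random.Generator, spec: HapSimSpec
) -> _WFState:
    sweep = spec.sweep
    assert sweep is not None
    for restart in range(spec.max_restarts):
        state = neutral.copy()
        # introduce the derived allele on one haplotype
        col = np.zeros((spec.pop_size, 1), dtype=np.uint8)
        col[rng.integers(0, spec.pop_size), 0] = 1
        positions = np.concatenate([state.positions, [sweep.position]])
        order = np.argsort(positions, kind="stable")
        haps = np.concatenate([state.haps, col], axis=1)[:, order]
        state = _WFState(haps, positions[order])
        focal_col = int(np.searchsorted(state.positions, sweep.position))
        for _ in range(100 * spec.pop_size):  # generous cap; sweeps are fast
            fitness = 1.0 + sweep.selection_coefficient * state.haps[:, focal_col]
            state = _wf_generation(state, rng, spec, fitness=fitness)
            hits = np.nonzero(state.positions == sweep.position)[0]
            if len(hits) == 0:
                break  # lost
            focal_col = int(hits[0])
            freq = state.haps[:, focal_col].mean()
            if freq >= sweep.final_frequency:
                return state
        # lost (or fixed then pruned): restart
    raise SweepLostError(spec.max_restarts)


# ---------------------------------------------------------------------------
# Ortholog alignment blocks
# ---------------------------------------------------------------------------

@dataclass
class AlnSimSpec:
    """Star-phylogeny ortholog alignment with a planted motif.

    Each species' sequence is the root mutated independently at
    ``substitution_prob`` per base; the motif consensus is then written into
    exactly ``n_species_with_motif`` species (reference first) at
    ``motif_offset`` relative to the focal column (offset 1-L..0 keeps the
    motif overlapping the focal column).
    """

    n_species: int = 46
    seq_length: int = 101
    substitution_prob: float = 0.1
    motif: str = "TTTGTCAAC"
    n_species_with_motif: int = 46
    motif_offset: int = -4
    ref_start: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species > 46:
            raise ValueError("at most 46 species")
        if self.n_species_with_motif > self.n_species:
            raise ValueError("n_species_with_motif exceeds n_species")
        if set(self.motif) - set("ACGT"):
            raise ValueError("motif must be over ACGT")
        if len(self.motif) > self.seq_length:
            raise ValueError("motif longer than the sequence")

    @property
    def focal_column(self) -> int:
        return self.seq_length // 2

    @property
    def focal_ref_pos(self) -> int:
        return self.ref_start + self.focal_column


def simulate_ortholog_alignment(spec: AlnSimSpec) -> AlignmentBlock:
    rng = np.random.default_rng(spec.seed)
    L, n = spec.seq_length, spec.n_species
    motif_start = spec.focal_column + spec.motif_offset
    if not (0 <= motif_start and motif_start + len(spec.motif) <= L):
        raise ValueError("motif_offset places the motif outside the sequence")

    root = rng.integers(0, 4, size=L)
    species = ["hg19"] + [f"sp{i:02d}" for i in range(1, n)]
    rows = []
    motif_idx = np.array([("ACGT").index(b) for b in spec.motif])
    for s in range(n):
        seq = root.copy()
        mut = rng.random(L) < spec.substitution_prob
        shift = rng.integers(1, 4, size=L)
        seq[mut] = (seq[mut] + shift[mut]) % 4
        if s < spec.n_species_with_motif:
            seq[motif_start : motif_start + len(motif_idx)] = motif_idx
        rows.append("".join(_BASES[seq]))
    return AlignmentBlock(
        species=species,
        rows=rows,
        ref_species="hg19",
        ref_start=spec.ref_start,
        present=np.ones((n, L), dtype=bool),
        chrom="chr9",
    )
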