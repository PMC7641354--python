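"""Readers, writers and the shared data model.

All internal coordinates are 0-based, half-open.  External formats
(VCF, MAF, the CLI's ``chrom:start-end``) are converted at the boundary:
VCF POS is 1-based, MAF block starts are 0-based already, BED is 0-based
half-open.

Containers are deliberately thin dataclasses over numpy/pandas objects;
every analysis stage consumes these and nothing else.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, motifs as bio_motifs
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

MISSING = -1  # missing dosage sentinel
_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """A biallelic SNP.  ``pos`` is 0-based (VCF POS - 1)."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"{self.id}: alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if self.ancestral_allele is not None and self.ancestral_allele not in (
            self.ref_allele,
            self.alt_allele,
        ):
            raise ValueError(
                f"{self.id}: ancestral allele {self.ancestral_allele!r} matches "
                "neither ref nor alt"
            )

    @property
    def derived_allele(self) -> str | None:
        if self.ancestral_allele is None:
            return None
        return (
            self.alt_allele
            if self.ancestral_allele == self.ref_allele
            else self.ref_allele
        )


@dataclass
class GenotypeMatrix:
    """Dosage-coded variants x individuals with population labels.

    dosages counts ALT allele copies, in {0,1,2} with ``MISSING`` (-1) for
    missing calls.
    """

    variants: list[VariantRecord]
    dosages: np.ndarray  # (n_variants, n_individuals) int8
    individuals: list[str]
    population: np.ndarray  # (n_individuals,) of str labels

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.population = np.asarray(self.population, dtype=object)
        if self.dosages.shape != (len(self.variants), len(self.individuals)):
            raise ValueError("dosage matrix shape does not match variants x individuals")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        if len(self.population) != len(self.individuals):
            raise ValueError("one population label per individual required")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def snp_index(self, snp_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == snp_id:
                return i
        raise KeyError(snp_id)

    def alt_frequency(self, pop: str | None = None) -> np.ndarray:
        """Per-variant ALT allele frequency, missing excluded pairwise."""
        d = self.dosages
        if pop is not None:
            d = d[:, self.population == pop]
        valid = d != MISSING
        n_alleles = 2 * valid.sum(axis=1)
        alt = np.where(valid, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def maf(self, pop: str | None = None) -> np.ndarray:
        f = self.alt_frequency(pop)
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in index],
            dosages=self.dosages[index],
            individuals=list(self.individuals),
            population=self.population.copy(),
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes, 0 = ancestral / 1 = derived allele."""

    haplotypes: np.ndarray  # (2n, S) uint8
    positions: np.ndarray  # (S,) int, strictly increasing, 0-based bp
    population: np.ndarray  # (2n,) labels
    variants: list[VariantRecord] | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.population = np.asarray(self.population, dtype=object)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("one position per site required")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 (ancestral) or 1 (derived)")
        if len(self.population) != self.haplotypes.shape[0]:
            raise ValueError("one population label per haplotype required")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def daf(self) -> np.ndarray:
        """Per-site derived allele frequency (column mean)."""
        return self.haplotypes.mean(axis=0)

    def site_at(self, position: int) -> int:
        hits = np.nonzero(self.positions == position)[0]
        if len(hits) == 0:
            raise KeyError(f"no site at position {position}")
        return int(hits[0])

    def window(self, start: int, end: int) -> "HaplotypeSet":
        """Sites with start <= pos < end."""
        mask = (self.positions >= start) & (self.positions < end)
        return HaplotypeSet(
            haplotypes=self.haplotypes[:, mask],
            positions=self.positions[mask],
            population=self.population.copy(),
            variants=(
                [v for v, m in zip(self.variants, mask) if m]
                if self.variants is not None
                else None
            ),
        )


@dataclass
class ExpressionMatrix:
    """genes x samples log2 FPKM with per-sample condition/population labels."""

    genes: list[str]
    values: np.ndarray  # (n_genes, n_samples) float
    samples: list[str]
    condition: np.ndarray  # (n_samples,)
    population: np.ndarray  # (n_samples,)
    individual: np.ndarray | None = None  # maps sample -> individual id
    fpkm_raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("value matrix shape does not match genes x samples")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if self.individual is not None:
            self.individual = np.asarray(self.individual, dtype=object)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(c, None)
        return list(seen)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(gene) from None

    def mean_fpkm(self, gene: str, condition: str | None = None) -> float:
        """Mean raw (untransformed) FPKM; falls back to 2**log2 values."""
        i = self.gene_index(gene)
        raw = self.fpkm_raw if self.fpkm_raw is not None else 2.0 ** self.values
        mask = (
            np.ones(len(self.samples), bool)
            if condition is None
            else self.condition == condition
        )
        return float(raw[i, mask].mean())


@dataclass
class AlignmentBlock:
    """A stitched multiple-alignment block anchored to a reference species.

    ``column_of`` maps reference 0-based positions onto alignment columns;
    ``present`` flags, per species and column, whether that species actually
    aligns there (False for species absent from a constituent MAF block, as
    opposed to a genuine deletion gap).
    """

    species: list[str]
    rows: list[str]  # gapped sequences over ACGTN-
    ref_species: str
    ref_start: int  # 0-based reference coordinate of the first ref base
    present: np.ndarray  # (n_species, n_columns) bool
    chrom: str = "chr"

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        if self.ref_species not in self.species:
            raise ValueError(f"reference species {self.ref_species!r} absent")
        self.present = np.asarray(self.present, dtype=bool)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def ref_row(self) -> str:
        return self.rows[self.species.index(self.ref_species)]

    @property
    def column_of(self) -> dict[int, int]:
        """Map from reference 0-based position to alignment column."""
        out: dict[int, int] = {}
        pos = self.ref_start
        for col, base in enumerate(self.ref_row):
            if base != "-":
                out[pos] = col
                pos += 1
        return out

    @property
    def position_of(self) -> dict[int, int]:
        """Inverse of column_of on ungapped reference columns."""
        return {c: p for p, c in self.column_of.items()}


@dataclass
class PositionFrequencyMatrix:
    """JASPAR-style nucleotide count matrix, rows ordered A, C, G, T."""

    tf_name: str
    counts: np.ndarray  # (4, L) float, non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.tf_name}: counts must be a 4 x L matrix")
        if (self.counts < 0).any():
            raise ValueError(f"{self.tf_name}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.tf_name}: zero column totals")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def information_content(self) -> float:
        """Total IC in bits against a uniform background."""
        p = self.counts / self.counts.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return float((2.0 + plogp.sum(axis=0)).sum())


@dataclass
class AnnotationTrack:
    """Sorted genomic intervals with optional per-base scores.

    Intervals are half-open 0-based; ``source`` labels the provenance
    (ensembl_regulatory, encode_tfbs, ortholog_region, or a score table).
    """

    intervals: list[tuple[str, int, int, str]]
    source: str
    scores: dict[tuple[str, int], float] | None = None
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, start, end, _label in self.intervals:
            if start >= end:
                raise ValueError(f"interval {chrom}:{start}-{end} has start >= end")
        self.intervals = sorted(self.intervals)
        self._trees = {}
        for chrom, start, end, label in self.intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def overlaps(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos])

    def labels_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[pos])

    def score_at(self, chrom: str, pos: int) -> float | None:
        if self.scores is None:
            return None
        return self.scores.get((chrom, pos))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _polarize(
    rec: VariantRecord, dos_row: np.ndarray, hap_cols: np.ndarray
) -> np.ndarray | None:
    """Return derived-coded haplotype columns, or None if unpolarizable."""
    if rec.ancestral_allele is None:
        return None
    if rec.ancestral_allele == rec.ref_allele:
        return hap_cols
    return 1 - hap_cols


def read_vcf(
    path: str,
    region: tuple[str, int, int] | None = None,
    min_maf: float = 0.0,
    populations: Mapping[str, str] | None = None,
    ancestral: Mapping[str, str] | None = None,
) -> tuple[GenotypeMatrix, HaplotypeSet | None, int]:
    """Read biallelic SNPs from a VCF into the internal containers.

    Parameters
    ----------
    region : (chrom, start, end), 0-based half-open, optional
    min_maf : keep sites with MAF >= min_maf in at least one population
    populations : sample id -> population label (default: one pool "pop")
    ancestral : variant id -> ancestral base, overriding/augmenting the AA
        INFO tag

    Returns
    -------
    (GenotypeMatrix, HaplotypeSet or None, n_unpolarized_dropped)
        The HaplotypeSet is produced only when every genotype is phased and
        non-missing; sites without a usable ancestral allele are dropped
        from it (their count is returned).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    pop_labels = np.array(
        [populations.get(s, "pop") if populations else "pop" for s in samples],
        dtype=object,
    )

    variants: list[VariantRecord] = []
    dosage_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    all_phased = True
    for i, v in enumerate(vcf, start=1):
        try:
            if len(v.ALT) != 1:
                continue  # multi-allelic: out of scope
            ref, alt = v.REF, v.ALT[0]
            if ref not in _BASES or alt not in _BASES:
                continue  # indel or symbolic allele
            chrom, pos0 = v.CHROM, v.POS - 1
            if region is not None:
                rchrom, rstart, rend = region
                if chrom != rchrom or not (rstart <= pos0 < rend):
                    continue
            vid = v.ID or f"{chrom}:{v.POS}"
            aa = None
            if ancestral is not None and vid in ancestral:
                aa = ancestral[vid].upper()
            else:
                tag = v.INFO.get("AA")
                if tag:
                    aa = str(tag).split("|")[0].upper()
            if aa not in (ref, alt):
                aa = None
            rec = VariantRecord(chrom, pos0, vid, ref, alt, aa)

            gts = v.genotypes  # [[a0, a1, phased], ...]
            dos = np.empty(len(samples), dtype=np.int8)
            haps = np.empty(2 * len(samples), dtype=np.int8)
            for j, g in enumerate(gts):
                a = [x for x in g[:-1]]
                if len(a) != 2 or any(x < 0 for x in a):
                    dos[j] = MISSING
                    haps[2 * j] = haps[2 * j + 1] = -1
                    all_phased = False
                    continue
                dos[j] = a[0] + a[1]
                haps[2 * j], haps[2 * j + 1] = a[0], a[1]
                if not g[-1] and a[0] != a[1]:
                    all_phased = False
        except VcfParseError:
            raise
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record #{i} in {path}: {exc}") from exc
        variants.append(rec)
        dosage_rows.append(dos)
        hap_rows.append(haps)
    n_sites = len(variants)
    dosages = (
        np.vstack(dosage_rows) if n_sites else np.zeros((0, len(samples)), np.int8)
    )
    gmat = GenotypeMatrix(variants, dosages, samples, pop_labels)

    # MAF filter: retain sites common in at least one population
    if min_maf > 0 and n_sites:
        pops = sorted(set(pop_labels))
        mafs = np.vstack([gmat.maf(p) for p in pops] + [gmat.maf()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            keep = np.nanmax(mafs, axis=0) >= min_maf
        gmat = gmat.subset_variants(np.nonzero(keep)[0])
        hap_rows = [h for h, k in zip(hap_rows, keep) if k]

    haps: HaplotypeSet | None = None
    n_unpolarized = 0
    if all_phased and gmat.n_variants >= 0:
        cols, positions, kept_variants = [], [], []
        hap_pop = np.repeat(gmat.population, 2)
        for rec, hap in zip(gmat.variants, hap_rows):
            col = _polarize(rec, None, hap.astype(np.uint8))
            if col is None:
                n_unpolarized += 1
                continue
            cols.append(col)
            positions.append(rec.pos)
            kept_variants.append(rec)
        mat = (
            np.column_stack(cols)
            if cols
            else np.zeros((2 * gmat.n_individuals, 0), np.uint8)
        )
        order = np.argsort(positions) if positions else np.array([], int)
        haps = HaplotypeSet(
            haplotypes=mat[:, order] if len(order) else mat,
            positions=np.asarray(positions)[order] if len(order) else [],
            population=hap_pop,
            variants=[kept_variants[i] for i in order],
        )
    return gmat, haps, n_unpolarized


def write_vcf(
    path: str,
    genotypes: GenotypeMatrix,
    haplotypes: HaplotypeSet | None = None,
    phased: bool | None = None,
) -> None:
    """Write a minimal VCF 4.2.  Phased output requires a HaplotypeSet whose
    rows are ordered two-per-individual matching the GenotypeMatrix."""
    if phased is None:
        phased = haplotypes is not None
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individuals)
            + "\n"
        )
        for i, rec in enumerate(genotypes.variants):
            info = f"AA={rec.ancestral_allele}" if rec.ancestral_allele else "."
            gt_fields = []
            for j in range(genotypes.n_individuals):
                if phased and haplotypes is not None:
                    # recover ref/alt coding from derived coding
                    a0 = int(haplotypes.haplotypes[2 * j, i])
                    a1 = int(haplotypes.haplotypes[2 * j + 1, i])
                    if rec.ancestral_allele == rec.alt_allele:
                        a0, a1 = 1 - a0, 1 - a1
                    gt_fields.append(f"{a0}{sep}{a1}")
                else:
                    d = int(genotypes.dosages[i, j])
                    gt = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}.get(
                        d, f".{sep}."
                    )
                    gt_fields.append(gt)
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.id}\t{rec.ref_allele}\t"
                f"{rec.alt_allele}\t.\tPASS\t{info}\tGT\t" + "\t".join(gt_fields) + "\n"
            )


# ---------------------------------------------------------------------------
# MAF (multiple alignment format)
# ---------------------------------------------------------------------------

def _species_of(src: str) -> str:
    return src.split(".", 1)[0]


def read_maf(
    path: str, ref_species: str, ref_interval: tuple[int, int] | None = None
) -> AlignmentBlock:
    """Read and stitch MAF blocks intersecting ``ref_interval``.

    Blocks are concatenated in reference order; a species missing from a
    block contributes gap characters there with ``present`` False.
    """
    blocks = []
    for aln in AlignIO.parse(path, "maf"):
        per_species = {}
        for rec in aln:
            per_species[_species_of(rec.id)] = rec
        if ref_species not in per_species:
            warnings.warn(f"MAF block without reference species {ref_species}; skipped")
            continue
        ref_rec = per_species[ref_species]
        start = int(ref_rec.annotations["start"])
        size = int(ref_rec.annotations["size"])
        if ref_interval is not None:
            lo, hi = ref_interval
            if start + size <= lo or start >= hi:
                continue
        blocks.append((start, per_species, aln.get_alignment_length()))
    if not blocks:
        return AlignmentBlock([ref_species], [""], ref_species, 0, np.zeros((1, 0), bool))
    blocks.sort(key=lambda b: b[0])

    species: list[str] = []
    for _, per_species, _ in blocks:
        for sp in per_species:
            if sp not in species:
                species.append(sp)
    rows = {sp: [] for sp in species}
    present_cols = {sp: [] for sp in species}
    for _, per_species, ncol in blocks:
        for sp in species:
            if sp in per_species:
                seq = str(per_species[sp].seq).upper()
                rows[sp].append(seq)
                present_cols[sp].append(np.ones(ncol, bool))
            else:
                rows[sp].append("-" * ncol)
                present_cols[sp].append(np.zeros(ncol, bool))
    ref_start = blocks[0][0]
    chrom = blocks[0][1][ref_species].id
    chrom = chrom.split(".", 1)[1] if "." in chrom else "chr"
    return AlignmentBlock(
        species=species,
        rows=["".join(rows[sp]) for sp in species],
        ref_species=ref_species,
        ref_start=ref_start,
        present=np.vstack([np.concatenate(present_cols[sp]) for sp in species]),
        chrom=chrom,
    )


def write_maf(path: str, block: AlignmentBlock) -> None:
    """Write a single-block MAF via Biopython."""
    records = []
    for sp, row in zip(block.species, block.rows):
        start = block.ref_start if sp == block.ref_species else 0
        size = len(row.replace("-", ""))
        rec = SeqRecord(Seq(row), id=f"{sp}.{block.chrom}")
        rec.annotations.update(
            {"start": start, "size": size, "strand": 1, "srcSize": start + size + 10000}
        )
        records.append(rec)
    aln = MultipleSeqAlignment(records)
    with open(path, "w") as fh:
        AlignIO.write([aln], fh, "maf")


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path: str) -> list[PositionFrequencyMatrix]:
    """Read JASPAR text PFMs; keep one matrix per TF (highest total IC)."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return []
    try:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:
        raise ValueError(f"cannot parse JASPAR file {path}: {exc}") from exc
    best: dict[str, PositionFrequencyMatrix] = {}
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        name = m.name or m.base_id
        pfm = PositionFrequencyMatrix(tf_name=name, counts=counts)
        if name not in best or pfm.information_content > best[name].information_content:
            best[name] = pfm
    return list(best.values())


# ---------------------------------------------------------------------------
# BED and score tables
# ---------------------------------------------------------------------------

def read_bed(path: str, source: str) -> AnnotationTrack:
    """Read BED3/BED4 into a sorted, query-able annotation track."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            intervals.append((chrom, start, end, label))
    return AnnotationTrack(intervals=intervals, source=source)


def read_score_table(path: str, chrom: str | None = None) -> AnnotationTrack:
    """Read a per-base score table (pos<TAB>score, or chrom<TAB>pos<TAB>score).

    Positions are 0-based in the file (internal convention).
    """
    scores: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                if chrom is None:
                    raise ValueError(
                        f"{path}:{lineno}: 2-column table requires a chrom argument"
                    )
                c, pos, sc = chrom, int(parts[0]), float(parts[1])
            elif len(parts) >= 3:
                c, pos, sc = parts[0], int(parts[1]), float(parts[2])
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            scores[(c, pos)] = sc
    intervals = [(c, p, p + 1, f"{sc:g}") for (c, p), sc in sorted(scores.items())]
    return AnnotationTrack(intervals=intervals, source="score_table", scores=scores)


# ---------------------------------------------------------------------------
# Expression matrix TSV (2-line header: condition row, population row)
# ---------------------------------------------------------------------------

def read_expression(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cond_row = fh.readline().rstrip("\n").split("\t")
        pop_row = fh.readline().rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    samples = header[1:]
    if cond_row[0] != "#condition" or pop_row[0] != "#population":
        raise ValueError(f"{path}: expected #condition and #population header rows")
    individual = np.array([s.rsplit(":", 1)[0] for s in samples], dtype=object)
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        values=df.to_numpy(dtype=float),
        samples=samples,
        condition=np.array(cond_row[1:], dtype=object),
        population=np.array(pop_row[1:], dtype=object),
        individual=individual,
    )


def write_expression(path: str, expr: ExpressionMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(expr.samples) + "\n")
        fh.write("#condition\t" + "\t".join(map(str, expr.condition)) + "\n")
        fh.write("#population\t" + "\t".join(map(str, expr.population)) + "\n")
        for g, row in zip(expr.genes, expr.values):
            fh.write(g + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse a CLI region 'chrom:start-end' (1-based inclusive) to 0-based
    half-open."""
    chrom, span = text.split(":")
    start, end = span.replace(",", "").split("-")
    start1, end1 = int(start), int(end)
    if start1 < 1 or end1 < start1:
        raise ValueError(f"bad region {text!r}")
    return chrom, start1 - 1, end1
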