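"""PWM scanning, cross-species TFBS conservation, and allele-impact scoring.

Position frequency matrices are converted to log2-odds position weight
matrices with a background-distributed pseudocount (default 0.8, split 0.2
per base), the convention of the TFBS-scanning tools this pipeline mirrors.
Windows are scored on both strands; a hit requires a min-max relative score
(raw - min)/(max - min) of at least the threshold (default 0.85) and must
overlap the focal position.  A motif is called conserved when detected in
strictly more than ``species_threshold`` species (default 20), and an
allele is called disruptive when the best overlapping score drops by more
than 10% relative to the ancestral allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AlignmentBlock, ExpressionMatrix, PositionFrequencyMatrix

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PositionWeightMatrix:
    tf_name: str
    weights: np.ndarray  # (4, L) log2-odds
    pseudocount: float = 0.8
    background: float = 0.25

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValueError("weights must be a 4 x L matrix")

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            tf_name=self.tf_name,
            weights=self.weights[::-1, ::-1],
            pseudocount=self.pseudocount,
            background=self.background,
        )


@dataclass
class MotifHit:
    tf_name: str
    species: str
    start: int  # 0-based, in the scanned (degapped) sequence
    strand: str  # '+' or '-'
    raw_score: float
    relative_score: float
    overlaps_focal: bool


@dataclass
class ConservationCall:
    tf_name: str
    n_species_detected: int
    species_threshold: int
    best_hits: dict[str, MotifHit] = field(default_factory=dict)

    @property
    def conserved(self) -> bool:
        return self.n_species_detected > self.species_threshold


@dataclass
class AlleleImpact:
    tf_name: str
    score_ancestral: float
    score_derived: float

    @property
    def delta_fraction(self) -> float:
        if self.score_ancestral == 0:
            return 0.0
        return (self.score_ancestral - self.score_derived) / self.score_ancestral

    @property
    def decreased(self) -> bool:
        return self.delta_fraction > 0.10


# ---------------------------------------------------------------------------
# PFM -> PWM
# ---------------------------------------------------------------------------

def pfm_to_pwm(
    pfm: PositionFrequencyMatrix, pseudocount: float = 0.8
) -> PositionWeightMatrix:
    """Log probability ratio conversion with background-distributed
    pseudocount: p = (count + c*0.25) / (total + c); weight = log2(p/0.25)."""
    if pseudocount <= 0:
        raise ValueError(
            "pseudocount must be > 0 (zero counts would give -inf weights)"
        )
    counts = pfm.counts
    totals = counts.sum(axis=0, keepdims=True)
    p = (counts + pseudocount * 0.25) / (totals + pseudocount)
    weights = np.log2(p / 0.25)
    return PositionWeightMatrix(pfm.tf_name, weights, pseudocount)


# ---------------------------------------------------------------------------
# window scanning
# ---------------------------------------------------------------------------

def _score_window(pwm: PositionWeightMatrix, seq: str, start: int) -> float | None:
    """Raw score of seq[start:start+L]; None if the window has non-ACGT."""
    total = 0.0
    for j in range(pwm.length):
        b = _BASE_INDEX.get(seq[start + j])
        if b is None:
            return None
        total += pwm.weights[b, j]
    return total


def scan_window(
    pwm: PositionWeightMatrix,
    sequence: str,
    focal_offset: int,
    rel_threshold: float | None = 0.85,
    both_strands: bool = True,
    literal_max_fraction: bool = False,
    tf_name: str | None = None,
    species: str = "",
) -> list[MotifHit]:
    """Score every window of ``sequence``; keep hits that overlap
    ``focal_offset`` and pass the relative-score threshold.

    ``rel_threshold=None`` disables the score filter (used for allele-impact
    scoring, where the best overlapping score is needed regardless).  With
    ``literal_max_fraction`` the threshold is applied to raw >= t * max_score
    instead of the min-max relative score.
    """
    sequence = sequence.upper()
    L = pwm.length
    if len(sequence) < L:
        return []
    if not (0 <= focal_offset < len(sequence)):
        raise ValueError("focal_offset outside the sequence")
    name = tf_name or pwm.tf_name
    span = pwm.max_score - pwm.min_score
    rc = pwm.reverse_complement() if both_strands else None
    hits: list[MotifHit] = []
    for start in range(len(sequence) - L + 1):
        overlaps = start <= focal_offset < start + L
        if not overlaps:
            continue
        for strand, mat in (("+", pwm),) + ((("-", rc),) if rc else ()):
            raw = _score_window(mat, sequence, start)
            if raw is None:
                continue
            rel = (raw - pwm.min_score) / span if span > 0 else 0.0
            if rel_threshold is not None:
                if literal_max_fraction:
                    if raw < rel_threshold * pwm.max_score:
                        continue
                elif rel < rel_threshold:
                    continue
            hits.append(MotifHit(name, species, start, strand, raw, rel, True))
    return hits


# ---------------------------------------------------------------------------
# cross-species conservation
# ---------------------------------------------------------------------------

def _degapped_focal_index(row: str, focal_col: int) -> int | None:
    """Index of the focal column in the degapped row; if the focal column is
    a gap, the nearest aligned position to the left (permissive overlap
    convention).  None when the row has no aligned base in the window."""
    n_before = sum(1 for c in row[:focal_col] if c != "-")
    if focal_col < len(row) and row[focal_col] != "-":
        return n_before
    return max(n_before - 1, 0) if n_before > 0 or row.strip("-") else None


def cross_species_conservation(
    pwm: PositionWeightMatrix,
    block: AlignmentBlock,
    focal_ref_pos: int,
    window: int = 21,
    species_threshold: int = 20,
    rel_threshold: float = 0.85,
) -> ConservationCall:
    """Count species carrying a motif hit overlapping the focal position in
    a ``window``-bp alignment window; conserved iff strictly more than
    ``species_threshold`` species."""
    col_map = block.column_of
    if focal_ref_pos not in col_map:
        raise ValueError(
            f"focal position {focal_ref_pos} does not map to an alignment column"
        )
    focal_col = col_map[focal_ref_pos]
    half = window // 2
    lo = max(0, focal_col - half)
    hi = min(block.n_columns, focal_col + half + 1)
    best_hits: dict[str, MotifHit] = {}
    for si, sp in enumerate(block.species):
        sub = block.rows[si][lo:hi]
        present = block.present[si, lo:hi]
        # treat not-present columns as absent sequence
        sub = "".join(c if ok else "-" for c, ok in zip(sub, present))
        degapped = sub.replace("-", "")
        if not degapped:
            continue
        focal_idx = _degapped_focal_index(sub, focal_col - lo)
        if focal_idx is None or focal_idx >= len(degapped):
            continue
        hits = scan_window(
            pwm, degapped, focal_idx, rel_threshold=rel_threshold, species=sp
        )
        if hits:
            best_hits[sp] = max(hits, key=lambda h: h.relative_score)
    return ConservationCall(
        tf_name=pwm.tf_name,
        n_species_detected=len(best_hits),
        species_threshold=species_threshold,
        best_hits=best_hits,
    )


# ---------------------------------------------------------------------------
# allele impact
# ---------------------------------------------------------------------------

def allele_impact(
    pwm: PositionWeightMatrix,
    sequence_window: str,
    focal_offset: int,
    ancestral_base: str,
    derived_base: str,
) -> AlleleImpact:
    """Best overlapping relative score for each allele substituted at the
    focal offset; no score threshold is applied, so the delta is always
    defined."""
    for b in (ancestral_base, derived_base):
        if b not in _BASE_INDEX:
            raise ValueError(f"allele {b!r} is not one of A, C, G, T")
    seq = sequence_window.upper()
    if not (0 <= focal_offset < len(seq)):
        raise ValueError("focal_offset outside the window")

    def best(base: str) -> float:
        s = seq[:focal_offset] + base + seq[focal_offset + 1 :]
        hits = scan_window(pwm, s, focal_offset, rel_threshold=None)
        if not hits:
            return 0.0
        return max(h.relative_score for h in hits)

    return AlleleImpact(
        tf_name=pwm.tf_name,
        score_ancestral=best(ancestral_base),
        score_derived=best(derived_base),
    )


def expression_filter(
    impacts: list[AlleleImpact],
    expression: ExpressionMatrix,
    tf_to_gene: dict[str, str],
    min_fpkm: float = 1.0,
    condition: str | None = None,
) -> list[AlleleImpact]:
    """Keep impacts whose TF gene has mean raw FPKM >= min_fpkm in the given
    condition, ranked by expression (highest first).  TFs without a gene
    mapping are dropped with a warning."""
    import warnings

    kept: list[tuple[float, AlleleImpact]] = []
    for imp in impacts:
        gene = tf_to_gene.get(imp.tf_name)
        if gene is None:
            warnings.warn(f"no gene mapping for TF {imp.tf_name}; excluded")
            continue
        try:
            fpkm = expression.mean_fpkm(gene, condition)
        except KeyError:
            warnings.warn(f"gene {gene} for TF {imp.tf_name} not in matrix; excluded")
            continue
        if fpkm >= min_fpkm:
            kept.append((fpkm, imp))
    kept.sort(key=lambda t: -t[0])
    return [imp for _, imp in kept]
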