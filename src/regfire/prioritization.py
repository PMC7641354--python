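"""Multi-criterion regulatory-variant prioritization and allelic-imbalance
quantification, plus the end-to-end pipeline driver.

A candidate variant is scored on five boolean criteria: (1) it falls in a
region orthologous to a validated enhancer, (2) it overlaps a predicted
regulatory element, (3) it overlaps an experimentally defined clustered
TFBS, (4) its base is conserved across mammals (GERP rejected-substitution
score > 2), and (5) it overlaps at least one cross-species-conserved TF
motif.  Candidates are ranked by the number of criteria satisfied, ties
broken by cis-eQTL p-value; a missing annotation track leaves its criterion
unknown and excluded from the count rather than false.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import AnnotationTrack, VariantRecord
from .motif_conservation import ConservationCall

GERP_CONSERVED_MIN = 2.0


@dataclass
class CriteriaLedger:
    variant_id: str
    criteria: dict[str, bool | None] = field(default_factory=dict)
    eqtl_p: float = math.nan
    ld_with_peak: float = math.nan

    CRITERIA_KEYS = (
        "c1_ortholog_enhancer",
        "c2_regulatory_element",
        "c3_encode_tfbs",
        "c4_gerp_conserved",
        "c5_conserved_tfbs",
    )

    @property
    def n_criteria(self) -> int:
        return sum(1 for k in self.CRITERIA_KEYS if self.criteria.get(k) is True)

    @property
    def n_known(self) -> int:
        return sum(1 for k in self.CRITERIA_KEYS if self.criteria.get(k) is not None)

    @property
    def complete(self) -> bool:
        """All five criteria known and satisfied."""
        return all(self.criteria.get(k) is True for k in self.CRITERIA_KEYS)

    def as_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            **{k: self.criteria.get(k) for k in self.CRITERIA_KEYS},
            "n_criteria": self.n_criteria,
            "eqtl_p": self.eqtl_p,
            "ld_with_peak": self.ld_with_peak,
        }


def prioritize_variants(
    candidates: Sequence[VariantRecord],
    tracks: Mapping[str, AnnotationTrack | None],
    conservation: Mapping[str, Sequence[ConservationCall]] | None = None,
    eqtl_p: Mapping[str, float] | None = None,
    ld_with_peak: Mapping[str, float] | None = None,
    ld_threshold: float = 0.5,
) -> list[CriteriaLedger]:
    """Score and rank candidate variants on the five criteria.

    ``tracks`` maps {"ortholog_region", "ensembl_regulatory", "encode_tfbs",
    "gerp"} to annotation tracks (None or absent -> criterion unknown);
    ``conservation`` maps variant id to its conservation calls.  Candidates
    whose LD with the peak variant is below ``ld_threshold`` are dropped
    when LD information is supplied.  Ranking: n_criteria descending, then
    eQTL p ascending.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    ledgers: list[CriteriaLedger] = []
    for v in candidates:
        if ld_with_peak is not None:
            r2 = ld_with_peak.get(v.id, math.nan)
            if not math.isnan(r2) and r2 < ld_threshold:
                continue
        led = CriteriaLedger(variant_id=v.id)
        led.eqtl_p = eqtl_p.get(v.id, math.nan) if eqtl_p else math.nan
        led.ld_with_peak = (
            ld_with_peak.get(v.id, math.nan) if ld_with_peak else math.nan
        )

        def overlap(key: str) -> bool | None:
            track = tracks.get(key)
            if track is None:
                warnings.warn(f"track {key!r} missing: criterion marked unknown")
                return None
            return track.overlaps(v.chrom, v.pos)

        led.criteria["c1_ortholog_enhancer"] = overlap("ortholog_region")
        led.criteria["c2_regulatory_element"] = overlap("ensembl_regulatory")
        led.criteria["c3_encode_tfbs"] = overlap("encode_tfbs")

        gerp = tracks.get("gerp")
        if gerp is None:
            warnings.warn("track 'gerp' missing: criterion marked unknown")
            led.criteria["c4_gerp_conserved"] = None
        else:
            score = gerp.score_at(v.chrom, v.pos)
            led.criteria["c4_gerp_conserved"] = (
                score is not None and score > GERP_CONSERVED_MIN
            )

        if conservation is None:
            led.criteria["c5_conserved_tfbs"] = None
        else:
            calls = conservation.get(v.id, ())
            led.criteria["c5_conserved_tfbs"] = any(c.conserved for c in calls)
        ledgers.append(led)

    ledgers.sort(
        key=lambda l: (
            -l.n_criteria,
            l.eqtl_p if not math.isnan(l.eqtl_p) else math.inf,
            l.variant_id,
        )
    )
    return ledgers


# ---------------------------------------------------------------------------
# allelic imbalance (ChIP vs input)
# ---------------------------------------------------------------------------

@dataclass
class AllelicRatioResult:
    input_ratios: np.ndarray
    chip_ratios: np.ndarray
    enrichment: np.ndarray  # chip/input per donor
    mean_input: float
    sem_input: float
    mean_chip: float
    sem_chip: float
    p_value: float
    test: str
    n_donors: int
    n_excluded: int


def allelic_imbalance(
    donors: Sequence[tuple[float, float, float, float]],
) -> AllelicRatioResult:
    """Allele-specific enrichment after immunoprecipitation.

    Each donor supplies (input_A, input_B, chip_A, chip_B) signals; the
    per-donor allelic ratio is A/B before and after ChIP, and enrichment is
    their quotient.  The paired comparison of chip vs input ratios is a
    two-sided paired t-test on log ratios (Wilcoxon signed-rank for fewer
    than 6 usable donors); summaries are mean +/- sem on the natural scale.
    Donors with non-positive signal are excluded with a warning.
    """
    usable = []
    n_excluded = 0
    for d in donors:
        if any(x <= 0 for x in d):
            warnings.warn(f"donor with non-positive signal excluded: {d}")
            n_excluded += 1
            continue
        usable.append(d)
    if len(usable) < 3:
        raise ValueError("need at least 3 usable donors")
    arr = np.asarray(usable, dtype=float)
    input_r = arr[:, 0] / arr[:, 1]
    chip_r = arr[:, 2] / arr[:, 3]
    diffs = np.log(chip_r) - np.log(input_r)
    n = len(diffs)
    if np.allclose(diffs, 0.0):
        p, test = 1.0, "degenerate (no difference)"
    elif n < 6:
        p = float(stats.wilcoxon(diffs).pvalue)
        test = "wilcoxon signed-rank on log ratios"
    else:
        p = float(stats.ttest_rel(np.log(chip_r), np.log(input_r)).pvalue)
        test = "paired t on log ratios"
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(len(x)))
    return AllelicRatioResult(
        input_ratios=input_r,
        chip_ratios=chip_r,
        enrichment=chip_r / input_r,
        mean_input=float(input_r.mean()),
        sem_input=sem(input_r),
        mean_chip=float(chip_r.mean()),
        sem_chip=sem(chip_r),
        p_value=p,
        test=test,
        n_donors=n,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Inputs for a fully synthetic end-to-end run.

    The pipeline simulates a two-population eQTL panel with a planted causal
    cis variant (plus planted trans effects), haplotypes, and an ortholog
    alignment carrying a planted motif at the causal position; it then runs
    the cis scan with permutation FWER, the conditional scan, the trans
    scan, motif conservation, the selection scan, and prioritization.
    """

    seed: int = 0
    n_individuals: int = 100
    n_snps: int = 200
    n_genes: int = 60
    n_trans_genes: int = 10
    beta_cis: float = 0.6
    beta_trans: float = -0.5
    n_permutations: int = 1000
    target_fwer: float = 0.01
    fdr: float = 0.01
    min_abs_beta: float = 0.2
    n_motif_species: int = 30
    run_selection: bool = True
    with_pfm: bool = True


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Execute the full synthetic analysis; returns (and optionally writes)
    a JSON-serializable report bundle.  Each stage failure is re-raised with
    the stage name; earlier stages' results are preserved in the bundle."""
    from . import synthetic_data as sd
    from . import eqtl_mapping as eq
    from . import motif_conservation as mc
    from . import selection_scan as ss
    from .data_io import PositionFrequencyMatrix

    report: dict = {"config": {k: getattr(config, k) for k in vars(config)}}
    stage = "simulate"
    try:
        spec = sd.EqtlSimSpec(
            n_individuals=config.n_individuals,
            n_snps=config.n_snps,
            n_genes=config.n_genes,
            n_trans_genes=config.n_trans_genes,
            beta_cis=config.beta_cis,
            beta_trans=config.beta_trans,
            seed=config.seed,
        )
        gmat, expr, truth = sd.simulate_eqtl_dataset(spec)
        report["truth"] = {
            "causal_snp": truth.causal_snp,
            "target_gene": truth.target_gene,
            "beta_cis": truth.beta_cis,
        }

        stage = "eqtl-cis"
        cis = eq.map_cis_eqtl(gmat, expr, truth.target_gene)
        cal = eq.permutation_fwer_threshold(
            gmat, expr, truth.target_gene,
            n_permutations=config.n_permutations,
            target_fwer=config.target_fwer,
            seed=config.seed + 1,
        )
        significant = [r for r in cis if r.p_value < cal.threshold]
        peak = min(cis, key=lambda r: r.p_value)
        report["cis"] = {
            "threshold": cal.threshold,
            "n_significant": len(significant),
            "peak_snp": peak.snp,
            "peak_p": peak.p_value,
            "peak_beta": peak.beta,
            "peak_r2": peak.r2,
        }

        stage = "eqtl-conditional"
        cond = eq.conditional_scan(gmat, expr, truth.target_gene, peak.snp)
        report["conditional"] = {
            "n_significant": sum(1 for r in cond if r.p_value < cal.threshold)
        }

        stage = "eqtl-trans"
        cond_label = expr.conditions[-1]
        trans = eq.map_trans_eqtl(
            gmat, peak.snp, expr, cond_label,
            fdr=config.fdr, min_abs_beta=config.min_abs_beta,
        )
        trans = [r for r in trans if r.gene != truth.target_gene]
        n_down = sum(1 for r in trans if r.beta < 0)
        report["trans"] = {
            "n_genes": len(trans),
            "fraction_down": n_down / len(trans) if trans else math.nan,
        }

        stage = "motif-conserve"
        calls: dict[str, list[ConservationCall]] = {}
        if config.with_pfm:
            pfm = PositionFrequencyMatrix(
                tf_name="CEBPB",
                counts=_cebp_like_counts(),
            )
            pwm = mc.pfm_to_pwm(pfm)
            aln = sd.simulate_ortholog_alignment(
                sd.AlnSimSpec(
                    n_species_with_motif=config.n_motif_species,
                    seed=config.seed + 2,
                )
            )
            focal = sd.AlnSimSpec(seed=config.seed + 2).focal_ref_pos
            call = mc.cross_species_conservation(pwm, aln, focal)
            calls[truth.causal_snp] = [call]
            report["conservation"] = {
                "tf": call.tf_name,
                "n_species": call.n_species_detected,
                "conserved": call.conserved,
            }
        else:
            report["conservation"] = None

        stage = "selscan"
        if config.run_selection:
            haps = sd.simulate_haplotypes(sd.HapSimSpec(seed=config.seed + 3))
            taj = ss.tajimas_d(haps)
            report["selection"] = {"tajimas_d": taj.D, "S": taj.S}
        else:
            report["selection"] = None

        stage = "prioritize"
        causal = gmat.variants[gmat.snp_index(truth.causal_snp)]
        chrom, pos = causal.chrom, causal.pos
        tracks = {
            "ortholog_region": AnnotationTrack(
                [(chrom, pos - 500, pos + 500, "enhancer")], "ortholog_region"
            ),
            "ensembl_regulatory": AnnotationTrack(
                [(chrom, pos - 200, pos + 200, "reg")], "ensembl_regulatory"
            ),
            "encode_tfbs": AnnotationTrack(
                [(chrom, pos - 100, pos + 100, "tfbs")], "encode_tfbs"
            ),
            "gerp": AnnotationTrack(
                [(chrom, pos, pos + 1, "3.1")], "score_table",
                scores={(chrom, pos): 3.1},
            ),
        }
        peak_dosage = gmat.dosages[gmat.snp_index(peak.snp)]
        ld = {}
        for v in gmat.variants:
            try:
                ld[v.id] = eq.ld_r2(gmat.dosages[gmat.snp_index(v.id)], peak_dosage)
            except ValueError:
                ld[v.id] = math.nan
        pmap = {r.snp: r.p_value for r in cis if r.condition == cond_label}
        ranked = prioritize_variants(
            gmat.variants, tracks, conservation=calls or None,
            eqtl_p=pmap, ld_with_peak=ld,
        )
        report["prioritization"] = {
            "top_variant": ranked[0].variant_id,
            "top_n_criteria": ranked[0].n_criteria,
            "uniquely_complete": sum(1 for l in ranked if l.complete) == 1,
            "n_candidates": len(ranked),
        }
    except Exception as exc:
        err = RuntimeError(f"pipeline stage {stage!r} failed: {exc}")
        err.partial_report = report  # completed stages preserved
        raise err from exc

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(os.path.join(out_dir, "prioritization.tsv"), "w") as fh:
            fh.write(
                "variant\tn_criteria\t" + "\t".join(CriteriaLedger.CRITERIA_KEYS)
                + "\teqtl_p\n"
            )
            for l in ranked:
                fh.write(
                    f"{l.variant_id}\t{l.n_criteria}\t"
                    + "\t".join(str(l.criteria.get(k)) for k in l.CRITERIA_KEYS)
                    + f"\t{l.eqtl_p:.4g}\n"
                )
    return report


def _cebp_like_counts() -> np.ndarray:
    """A C/EBP-family-like 9-column count matrix (consensus TTTGCAAC-like
    half sites; synthetic stand-in for a database matrix)."""
    consensus = "TTTGTCAAC"
    counts = np.full((4, len(consensus)), 2.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 94.0
    return counts
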