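# Methods

`regfire` implements the computational workflow by which a regulatory
variant in an inducible enhancer is linked to the expression of the gene it
controls: association mapping with permutation-calibrated significance,
cross-species transcription-factor-motif analysis, haplotype-based
selection statistics, and a multi-criterion prioritization step.  All
stages run end-to-end on seeded synthetic generators with known ground
truth, so every statistical guarantee the package makes is checked by
simulation rather than asserted.

## eQTL model

Expression is rank-inverse-normal transformed per stimulation condition:
`y_i -> Phi^-1((r_i - 0.5)/n)` with average ranks for ties.  This variant of
the transform keeps all outputs finite and is idempotent on ranks (applying
it twice returns the same vector).  The association model is ordinary least
squares

    INT(expression) ~ intercept + dosage + population,

fitted separately per condition.  Population enters as k-1 indicator
columns (one binary indicator for the two-population design).  The reported
effect `beta` is per ALT-allele copy on the transformed scale; `r2` is the
partial variance explained by dosage after the covariates,
`t^2 / (t^2 + df)`, and is labelled as partial wherever it is printed.
Missing dosages are mean-imputed per variant and population for regression;
allele-frequency and F_ST computations instead exclude missing calls
pairwise.  Monomorphic genotypes return a flagged result with p = 1 by
convention so that downstream set operations never fail.

Scans are vectorized with the Frisch–Waugh device: genotypes and phenotype
are residualized on the covariate design once, after which the dosage
t-statistic is a scaled partial correlation.  `fit_snp_gene` is the
single-pair reference implementation; the test suite pins the vectorized
path to it (and to `statsmodels` OLS) at 1e-10.

### Permutation FWER

Family-wise significance is calibrated by permuting the transformed
phenotype within population strata — not residuals — which preserves the
covariate structure exactly under the null.  Per permutation the minimum
p-value over all SNPs *and* conditions is recorded (one shared threshold
across conditions); the threshold is the k-th smallest of the B minima with
k = floor(alpha * B), so a p-value below it arises in fewer than alpha of
permutations.  With B = 1000 and alpha = 0.01 this is the 10th smallest.
Calibration is validated by applying the threshold to independent null
panels; the achieved family-wise error sits at ~1% (the acceptance script
recomputes this figure at every run).

### Trans scan and LD

The trans scan tests one SNP against all genes in one condition, adjusts
p-values by Benjamini–Hochberg, and returns associations with q <= FDR
(default 0.01) and |beta| >= 0.2, labelled up/down by the sign of beta.
The BH implementation is pinned to a brute-force step-up oracle and to
`statsmodels.multipletests`.  LD between dosage vectors is the squared
Pearson correlation with pairwise exclusion of missing calls.

## Motif conservation

JASPAR-format count matrices are converted to log2-odds weight matrices by
the log-probability-ratio method: with pseudocount c = 0.8 distributed by
the uniform background (0.2 added per base, 0.8 to the column total),

    p = (count + 0.25 c) / (total + c),    weight = log2(p / 0.25).

When a TF has several matrices, only the one with the highest total
information content (base-2, uniform background, `sum_cols (2 + sum p log2
p)`) is kept.  Windows are scored on both strands; a hit must overlap the
focal position and reach a min–max relative score `(raw - min)/(max - min)`
of at least 0.85 — the convention of the scanning tools this mirrors.  The
literal reading (raw >= 0.85 * max) is available behind the
`literal_max_fraction` flag.

Cross-species conservation degaps each species' row within a 21-bp (±10)
alignment window around the focal column and rescans it; a species counts
as carrying the motif if any hit overlaps the focal column mapped into its
degapped coordinates (for a species gapped at the focal column, the nearest
aligned position to the left is used — the permissive choice).  A motif is
"conserved" when detected in strictly more than 20 species.  Allele impact
substitutes each allele at the focal offset and compares the best
overlapping relative scores with no score threshold, so the difference is
always defined; "decreased" requires a drop of strictly more than 10% of
the ancestral-allele score.  The expression filter keeps TFs whose gene
exceeds a mean raw-FPKM floor (1 for "expressed", 100 for "highly
expressed") in the stated condition.

## Selection statistics

All haplotype statistics operate on phased binary haplotypes coded
0 = ancestral / 1 = derived; sites whose ancestral state is unknown or
matches neither allele are dropped at VCF read time (with a reported
count), since derived-allele frequency and iHS are polarity-dependent.

* **Tajima's D** over a physical window (default 100 kb, ±50 kb around the
  focal site): pi is the mean pairwise difference, the normalizing
  constants a1…e2 follow the standard definitions, and D is NaN when the
  window holds no segregating site.
* **EHH/iHS**: EHH from a core allele is the probability that two random
  carriers are identical over all sites from the core to a given distance;
  iHH is the trapezoidal integral of the decay curve over physical distance
  (no genetic map is used; none is available to the pipeline), truncated at
  the first point below 0.05 or at the maximum extension (default 100 kb,
  ±50 kb in the pipeline).  A curve that never reaches the truncation level
  leaves the result flagged.  uiHS = ln(iHH_ancestral / iHH_derived), so a
  sweep on the derived allele gives strongly negative values.
  Standardization subtracts the mean and divides by the sd of uiHS within
  40 equal-width derived-allele-frequency bins over [0.05, 0.95]
  (equal-width rather than equal-count; the choice is exposed as
  parameters).  Bins with fewer than 2 sites are flagged, not standardized.
  Bin moments estimated on a neutral reference can be supplied to
  standardize candidate sites against neutrality.
* **F_ST**: the Weir–Cockerham (1984) variance-components estimator across
  all populations at once (not averaged pairwise); heterozygote frequencies
  come from dosage == 1 for diploid data, and haplotype input is treated as
  haploid samples (the heterozygosity term drops).  Negative estimates are
  retained; the global value is the ratio of summed components over sites.
* **Empirical p-values** use the add-one rule
  `(#{reference >= observed} + 1)/(N + 1)` against a chromosome-wide
  reference distribution, with ties counted as >=; `tail="abs"` compares
  absolute values (used for iHS).

## Prioritization

Each candidate variant is scored on five booleans: located in a region
orthologous to a validated enhancer (user-supplied interval track — no
whole-genome liftover is performed), overlapping a predicted regulatory
element, overlapping an experimentally defined clustered TFBS, GERP
rejected-substitution score > 2 at the base, and overlapping at least one
conserved TF motif.  A missing annotation track marks its criterion
unknown and excludes it from the count, so partially annotated runs remain
comparable.  Candidates below the LD floor with the peak variant (r^2 <
0.5 by default) are dropped.  Ranking is by criteria count, ties broken by
cis-eQTL p-value (the tie-break the data afford; documented here because
the choice was open).

Allelic imbalance after ChIP is quantified per donor as the allele-A/
allele-B signal ratio before and after immunoprecipitation; the paired
comparison is a two-sided t-test on log ratios (log makes ratios symmetric
around no-change), falling back to a Wilcoxon signed-rank for fewer than 6
usable donors, with p = 1 by convention when all log-differences are zero.

## Synthetic data: what it emulates and what it does not

* **eQTL panels** (`simulate_eqtl_dataset`): two populations of 100
  individuals by default, 500 SNPs with LD from a first-order Markov
  allele-copy process (adjacent-SNP copy probability 0.7), two conditions,
  one planted cis effect and optional trans effects of the same SNP, and a
  population expression offset (0.3) that makes the covariate matter.
  When `noise_sd` is not given it is set per gene so the phenotype has
  unit marginal variance, which keeps the planted `beta` on the
  (approximately) transformed scale the fits estimate.  LD comes from the
  copy process, not population history: the panels exercise the
  permutation and conditioning machinery but carry no demography, no
  haplotype-block boundaries, and Gaussian noise on the log2 scale rather
  than count-level noise.  Passing tests therefore demonstrate calibration
  and recovery under the model's own assumptions, not robustness to
  count-data artefacts.
* **Haplotypes** (`simulate_haplotypes`): a forward Wright–Fisher model of
  a single panmictic population of 200 haplotypes over 100 kb, with
  infinite-sites mutation (1.25e-6 per bp per haplotype per generation,
  giving Watterson theta ~50 per 100 kb), uniform recombination (1e-6 per
  bp per generation) and a 2500-generation burn-in from a monomorphic
  start — long relative to the ~4N-generation expected depth of the
  sample genealogy, so summary statistics sit near mutation–drift
  equilibrium (mean Tajima's D across replicates is ~0, within the mildly
  negative band expected).  A sweep introduces one derived allele after
  burn-in and evolves it with multiplicative fitness 1 + s until it
  reaches the target frequency, restarting from the saved neutral state
  when lost.  Population size and region length are deliberately small;
  the simulator provides controlled positives/negatives for the selection
  statistics, not human demographic realism.
* **Ortholog alignments** (`simulate_ortholog_alignment`): a star
  phylogeny — each species mutates the root independently (default 0.1
  per base) — with the motif consensus written into a controllable number
  of species around the focal column.  There is no indel process, so gap
  handling is exercised by constructed fixtures rather than the generator.

## Validation scale and numerical choices

The test suite validates, at desk scale: family-wise error of the
permutation threshold on 500 independent null panels (achieved ~1% against
a 1% target); cis effect recovery (beta = 0.5, MAF ~0.3, n = 200; ±2 SE
coverage ~98% over 300 panels); trans recovery of 50 planted |beta| = 0.5
genes among 1000 nulls (~95% at FDR 0.01 with realized FDR ~1%); sweep
detection by standardized |iHS| against the neutral 95th percentile (~90%
of 100 sweep replicates at s = 0.2, final frequency 0.7); and exact
agreement (1e-10; 1e-6 for trapezoid integrals) of Tajima's D, F_ST,
EHH/iHH, BH and PWM scanning with independently coded brute-force oracles.
The trans validation plants the causal SNP at MAF ~0.4: a power analysis
puts MAF ~0.3 exactly on the 90%-recovery design target (noncentrality
~4.85 against a BH cutoff ~3.55), and a validation experiment should not
sit on its own design boundary.

Numerical conventions: internal coordinates are 0-based half-open
everywhere, converted at format boundaries (VCF and CLI regions are
1-based); a regression fit whose residual sum of squares is below 1e-20 of
the total is reported as p = 0 exactly; the permutation threshold is an
order statistic (no interpolation); prioritization ranking is a total
order given distinct eQTL p-values (variant id as final tie-break).

## Known limitations

Multi-allelic sites and indels are excluded at read time; assemblies are
taken as declared per input file and never lifted over; the trans scan
does not perform enrichment analysis on its gene set; the selection module
does not implement cross-population haplotype statistics, allele-frequency
correlation scores for balancing selection, or ancestral-recombination-
graph TMRCA inference (for the latter, published runs used an external
tool with Neff = 10000, mu = 2.5e-8; those parameters are recorded here
for provenance only).  Conservation calls count any-strand hits; whether
cross-species hits should be required to share a strand is left open and
configurable upstream of the call.
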