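# Methods

## Model and procedure

`mirdosage` tests whether miRNAs in a recurrently gained chromosomal
region are (1) dosage-driven — their expression follows their local DNA
copy number — and (2) functional — their expression propagates to their
predicted target transcripts. Both questions are covariate-set association
tests with the miRNA's expression as the response. The direction matters
and is fixed throughout: copy number and target expression are always the
covariates, never the response.

### Score test

For response y (length n) and covariates X (n × m), the statistic is

    S = ỹᵀ X Xᵀ ỹ / (m σ̂²),   ỹ = y − ȳ,   σ̂² = ỹᵀỹ / n,

with X column-centred and, by default, column-scaled to unit variance
(`scale_covariates=True`) so that every covariate in a window contributes
comparably regardless of its dynamic range. Constant columns are zeroed
(they carry no signal) but still count in m. S is invariant to adding a
constant to y, to covariate order, and to jointly permuting the rows of
(y, X). Because σ̂² and ỹᵀỹ are permutation-invariant, the normalisation
affects only the scale of S, never the permutation p-value.

Inference permutes y. When n! ≤ `exact_cap` (5040, i.e. n ≤ 7) all n!
permutations are enumerated and p = #{S_perm ≥ S_obs}/n!; otherwise B
Monte-Carlo permutations (default 9999) give
p = (1 + #{S_perm ≥ S_obs})/(B + 1), which is never 0 and has floor
1/(B + 1). The "≥ observed" comparison uses a relative tolerance of 1e-9
so that algebraically tied statistics count as ties. An asymptotic option
fits a Satterthwaite scaled χ² to the eigenvalues of XXᵀ/m (inflated by
n/(n−1) for the plug-in variance); it exists for speed and the permutation
null remains the reference everywhere, including all tests.

Within one association stage, a single drawn permutation-index matrix is
shared by all features. The null is identical for every feature, results
become deterministic per feature (a duplicated response row yields an
identical p), and the draw is amortised.

### Grid resampling

Segmented copy-number profiles are evaluated on a genome-wide grid of
`grid_points` (default 30,000) equally spaced positions: points are laid
at midpoints of equal bins along the concatenated genome, which makes
spacing exactly uniform (to 1 bp rounding) and allocates points to
chromosomes in proportion to length. A grid point inside a segment takes
the segment's value; an uncovered point on a segmented chromosome takes
the nearest segment's value (segmentation should tile a chromosome — gaps
are platform artifacts; ties break to the left neighbour); a chromosome
absent from a sample's segmentation is missing (NaN) for that sample, and
such samples are dropped per miRNA at test time.

A miRNA's covariate window is [start − w/2, start + w/2) with
`window_bp` = 2,000,000 total, clipped at chromosome bounds. The literal
reading "a 2 Mb window around the start" is ±1 Mb; users who intend ±2 Mb
can set `window_bp=4_000_000`. Clustered miRNAs with equal (chrom, start)
share identical covariate sets by construction.

Arm-level gain calls (the in-silico stand-in for an MLPA assay) are the
mean log2 ratio over the region, called "gain" iff mean ≥ `gain_threshold`
(default 0.2, a common segmentation-calling heuristic; the boundary is
inclusive).

### Consensus targets, FDR and selection

A consensus target set holds genes predicted by ≥ `consensus_min_tools`
(default 3) of the 4 catalogs. Each level's p-values receive
Benjamini–Hochberg step-up adjustment (via statsmodels, cross-checked in
the tests against a literal min-over-tail implementation of the
definition). A miRNA with an empty consensus set (or none of its genes in
the mRNA matrix) is *not determined* at level 2: it is excluded from that
level's BH denominator and can never be selected. Selection requires
FDR < `fdr_alpha` (0.05) at both levels. Individual targets of selected
miRNAs are kept at raw p < `target_p_cut` (0.01), strict inequality, and
signed by the Pearson correlation (exactly zero correlation reports
"positive", logged). For filtering *already-printed* summary tables the
helper `filter_printed_targets` treats a p equal to the cut at the table's
printed precision as passing, since such a value is consistent with a raw
p below the cut before rounding; the pipeline itself always uses the
strict raw-p rule.

### Relative quantification and contrasts

ΔCt = Ct(assay) − Ct(reference assay) per sample; technical replicates are
averaged on the Ct scale beforehand (conventional choice). ΔΔCt subtracts
the mean (optionally median) ΔCt of a calibrator sample group — the
adenoma group by default for tumour panels, which fixes the adenoma
geometric-mean fold at 1; the calibrator choice shifts all folds by a
constant factor and does not affect group contrasts. Folds are 2^(−ΔΔCt).
Contrasts use the two-sided Mann–Whitney U test: exact when
nA + nB ≤ 12 with untied data, otherwise the tie-corrected normal
approximation with continuity correction (scipy). Unknown-status samples
are excluded and counted.

## Synthetic cohorts

The generator draws cohorts with the statistical structure the analysis
assumes, for testing without any data download. Defaults state the
emulated world: n = 125 samples; a 13q-arm gain (chr13:17.9–115.17 Mb on
GRCh37 autosome lengths, the q-arm from the approximate cytoband boundary)
in half the samples at log2 ~ N(0.4, 0.05); per-sample per-chromosome
baseline log2 ~ N(0, 0.05); 14 region miRNAs reusing the published
name/position table for chromosome 13q, of which 3 (mir-15a, mir-17,
mir-20a by preference) are planted with expression
base + 1.0·(local log2 CN) + N(0, 0.5); 2000 genes with 20 predicted
targets per miRNA, 25% of a planted miRNA's targets repressed at slope
−0.7 (5% positively coupled at +0.7); four catalogs including each true
target with probability 0.8 per tool plus 30 decoy pairs per miRNA per
tool drawn from non-target genes; qPCR Ct = offset − expression +
N(0, 0.1) with per-assay offsets ~ U(28, 34) and the non-planted region
miRNA hsa-mir-16-1 as reference assay; histology with carcinoma odds 0.6
in no-gain samples, multiplied by 4 under gain (≈ 37% vs 71% carcinoma),
mirroring a progression narrative without claiming estimates. Expression
is generated on a log-like additive scale so dosage and repression
couplings are exactly linear — matching the linear score test.

What a green planted-recovery test establishes: the pipeline detects
dosage and repression effects of the stated magnitude at the stated n with
the stated error control. What it does not establish: performance under
platform-specific noise, non-linear couplings, subclonal or focal copy
number, or correlated gene-gene structure — none of which the generator
attempts.

The realized dosage separation in a cohort is ~N(0.4, 0.09); about 4% of
planted miRNAs per run draw a separation too weak to clear the joint FDR
filter at n = 125, so the 20-seed recovery criterion (all three planted
miRNAs in ≥ 90% of runs) sits near its boundary by construction — this is
a property of the stated effect size, not of the test, whose null
calibration is verified independently.

## Numerical conventions and edge cases

- Coordinates are 0-based half-open throughout (BED convention).
- Constant response → error ("degenerate response"); all-constant
  covariates → S = 0, p = 1, with a warning.
- Permutation p-values are lattice-valued with floor 1/(B+1); exact
  enumeration includes the identity permutation, so its floor is 1/n!.
- Missing grid values are per sample × chromosome; association tests drop
  incomplete samples per miRNA and report the n used.
- BH adjustment maps back to input order; NaN p-values are excluded from
  the denominator at level 2 (not determined), never clipped.
- All randomness in a run flows from `AnalysisConfig.seed` /
  `ScenarioConfig.seed`; manifests record the seed and SHA-256 digests of
  outputs, and same-seed runs are byte-identical.

## Known limitations

- The score test assumes an exchangeable null under permutation; covariate
  adjustment (age, stage, purity) is out of scope.
- No segmentation, platform normalisation, or genome-build liftover is
  performed; inputs are taken as already segmented/normalised, and the
  genome description (chromosome lengths) is caller-supplied.
- The asymptotic p-value is an approximation that degrades for small n or
  highly collinear covariates; use permutation (the default) for
  reported results.
- qPCR quantification assumes perfect amplification efficiency (no
  standard-curve correction).
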