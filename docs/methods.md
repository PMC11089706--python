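# Methods

This note records the models, parameter choices and numerical decisions
behind `uroev`, and what the synthetic-data tests do and do not show.

## Coordinates and containers

All coordinates are 0-based half-open internally and in BED I/O; GTF
input (1-based inclusive) is converted on read (via pyranges). Region
identifiers serialize as `contig:start-end`. Strand is carried but never
affects counting — the library-prep protocols this pipeline targets do
not give reliable strand information at the region level.

## Region quantification

The genome is partitioned per contig into contiguous windows of `w` nt
(default 100). The final window of a contig keeps its natural shorter
length so the windows form an exact partition; its true length is used
in TPM. Total regions = Σ_contig ⌈len/w⌉. The bundled GRCh37 index
yields 30,956,785 regions over chromosomes 1–22, X and Y at w = 100;
the mitochondrial contig is kept out of that count because small-RNA
workflows of this kind screen out mitochondrial reads before alignment.

Two counting modes exist. `overlap` (default): a read increments every
region it overlaps by ≥ 1 bp, matching interval-intersection counting
with bedtools-style semantics; a boundary-crossing read is counted in
each region it touches, so column sums can exceed the read count.
`start`: a read increments only the region holding its 5′-most base —
counts are conserved exactly, which the simulation round-trip tests
exploit. Reads on contigs absent from the grid are skipped with a
warning (decoy-contig reads are expected in practice), not an error.

TPM_ij = (c_ij/L_i) / Σ_k (c_kj/L_k) × 10⁶. The expression-evidence
filter keeps a region iff at least ⌈min_fraction·n⌉ samples have ≥
min_reads reads (defaults 0.20 and 5); the ceiling is the strictest
integer reading of "at least 20 %".

## Coverage-variance QC

Tile value = summed per-base depth over the tile (a read contributes its
overlap length), tiles of 1 Mb at genome scale. Per contig with ≥ 2
*complete* tiles, the sample SD (n−1) and mean of tile values are taken;
CV = median(SDs)/median(means). Ragged final tiles are excluded from the
summaries — they would act as a systematic low outlier — and contigs
with fewer than two complete tiles (e.g. MT at 1 Mb) are excluded
because an SD of one value is undefined. CV is invariant to uniform
scaling of coverage and to contig order. Exclusion rule: DNA/RNA ratio
> 0 AND CV < 0.5 (strict), a conjunction — low CV alone never excludes.
On miniature simulated genomes the tile size scales as contig_length/50,
keeping ~50 tiles per contig as at genome scale.

## Differential region expression

Counts are modelled per region as NB with mean s_j·q_ij, variance
μ + αμ². Size factors are the median-of-ratios estimator restricted to
regions nonzero in all samples, rescaled to geometric mean 1. The design
is (intercept, status case = 1, gender male = 1, age mean-centered);
control/female reference levels make a negative status coefficient mean
"lower in cases". Centering the age stabilizes the intercept.

Dispersion is estimated in two steps: per region a method-of-moments
value α̂ = max(0, (var − ξ·μ̄)/μ̄²) on size-factor-normalized counts, with
design-explained variation removed by OLS projection (residual variance
with n − p denominator) and ξ = mean(1/s_j) correcting for the
normalization; then a trend α(μ) = a₀ + a₁/μ is fitted across regions by
Huber robust regression and each region's final dispersion is the
geometric mean of its (floored) raw estimate and the trend value, floor
10⁻⁸. With fewer than 10 regions the trend is refused and raw values
used with a warning. This is deliberately simpler than full
shrinkage-estimator machinery (no Cox–Reid adjustment, outlier
refitting, independent filtering or fold-change shrinkage); its contract
is calibration, verified by simulation: null type-I error at nominal
0.05 stays within [0.03, 0.08] at n = 63, and with planted |log2FC| ≥
2.3 at α = 0.4 marker recall exceeds 80 % with observed FDP ≤ 0.10.

GLM fitting is batched IRLS across regions sharing the design: working
response z = η + (y−μ)/μ, weights W = μ/(1+αμ), per-region normal
equations solved in a single einsum/solve; initialization from OLS on
log(y+0.5) − log s; convergence on relative deviance change < 10⁻⁸, max
100 iterations, linear predictor clipped to ±30, a 10⁻¹⁰ ridge guards
singular systems. Non-converged regions get missing p-values and are
excluded from the BH denominator. Standard errors use the expected
Fisher information XᵀWX at the optimum (the standard GLM/IRLS choice).
Wald z = β̂/SE, two-sided normal p, status coefficient reported in log2.
In the α → 0 limit the fits agree with a Poisson GLM to < 10⁻⁴
(tested). BH correction is the statsmodels step-up.

A note on an algebraic subtlety: multiplying one sample's counts by a
constant is absorbed *exactly* by its size factor, so fold-change
estimates are stable; Wald z values shift slightly (≲ 0.03 at ×4)
because a sample's information content depends on its absolute count
scale — true of any count GLM, and tested as such.

"Cohort structure" uses log2(TPM+1): PCA with samples as observations,
column-centered, no scaling, component signs fixed by the
largest-absolute-loading-positive convention; clustering is scipy
complete linkage on Euclidean sample distances. The count-based test
never runs on TPM; the log-TPM transform feeds only PCA/clustering.

## Reference-region screen

Candidates are maximal runs of ≥ k grid-adjacent regions (same contig,
end = next start) whose mean TPM each exceeds the q-th percentile of all
region means; score = max over the run of SD/mean (sample SD), sorted
ascending. Defaults k = 2 and q = 90 are package choices — the procedure
itself, not specific constants, is the method — and max-aggregation is
the conservative option. Runs never span contig boundaries; results are
invariant to sample order. On synthetic data with a planted constant
high-expression 3-region gene, that gene ranks first in ≥ 19/20 seeds.

## qPCR quantification

Replicate CTs are averaged per sample × assay; pairs differing by more
than 1 cycle are flagged "discordant", lone replicates "single
replicate". CT at the 45-cycle limit means no amplification and is
treated as missing rather than censored; affected samples drop out of
the models with a logged count. Relative level = 2^−ΔCT with
ΔCT = CT_target − CT_reference from the assay's matched reference gene.
No inter-run calibrator is modelled, so levels are defined up to a
constant per assay; the logistic model's intercept absorbs it. Predictors
are natural-log levels (= −ΔCT·ln 2); the log base is irrelevant — AUC
and p-values are invariant and OR_IQR is base-invariant because β and
the IQR rescale inversely (tested).

## Diagnostic models

Binomial GLM, logit link, case = 1, fitted by IRLS (statsmodels);
complete cases only, dropped with a log line. Perfect separation is
reported as a non-converged fit, not an exception, and such fits are
excluded (and counted) wherever aggregated. AUC is the Mann–Whitney
statistic with half-credit ties; ROC points at every distinct threshold,
anchored at (0,0) and (1,1). Classification metrics use p ≥ 0.5 by
default; a Youden-optimal threshold is available (`threshold="youden"`)
because published operating points are often threshold-optimized.
OR_IQR = exp(β̂·IQR) with linear-interpolation quartiles over the
modelled samples; zero IQR gives OR = 1 with a warning. The deviance
test compares the fitted model to the *intercept-only* null on the same
samples (one-tailed χ², df = parameter difference), so it measures the
joint contribution of genes and covariates; a covariates-only null can
be passed explicitly.

Cross-validation: per repeat, cases and controls are shuffled separately
and dealt round-robin into k bins, so per-class fold sizes differ by at
most one and every test fold contains both classes (54/24 at k = 5 gives
case folds {11,11,11,11,10} and control folds {5,5,5,5,4}, satisfying
the ≥ 10/≥ 4 minima). Metrics are pooled over all repeat × fold
evaluations for the mean/SD summary — pooling choice stated because
per-repeat averaging is an equally defensible alternative. Default 1000
repeats; tests and the acceptance script use 20–100 to keep runtimes in
seconds, which leaves the means essentially unchanged (SDs are slightly
noisier).

## Synthetic-data generator

The generator is a pure function of its config (every stage draws from
an independent seed-derived stream): equal configs give bit-identical
output. Defaults emulate the study shape the pipeline is designed for:

- cohort 54 cases / 24 controls; male probability 0.77 (cases) and 0.94
  (controls); ages uniform 40–80; obesity prevalence 0.30/0.17,
  hypertension 0.61/0.58 per group; 7 + 8 designated DNA-contaminated
  samples (DNA/RNA ratio > 0), so the exclusion rule leaves 47/16.
- miniature genome: 2 contigs × 100 kb, one lincRNA host gene per contig
  whose introns contain snoRNA genes, each snoRNA aligned to exactly one
  100-nt region (the planted markers), plus one protein-coding reference
  gene spanning 3 consecutive regions.
- counts: log2 baseline intensity ~ N(2.0, 2.5), truncated at 9 so no
  background locus dominates the library over the planted reference —
  heavy-tailed, as small-RNA profiles are; markers at baseline
  N(6, 0.5) with planted log2 fold changes −1.6…−3.5 (lower in cases)
  and a per-sample biological deviation (SD 1.5 log2) shared with the
  qPCR latent level; a +2 log2 male/female effect on 100 background
  regions, which makes PC1 track gender while status stays invisible in
  the leading components, as in real urine-EV cohorts; NB dispersion
  α = 0.4; log-normal library sizes (σ = 0.3). Reference regions are
  held at constant latent level 2¹⁰ with Poisson noise — a deliberately
  stable transcript for the screen to find.
- reads: single-end 50 nt. Clean samples place each region's exact count
  uniformly within the region (start-mode counting recovers the matrix
  bit-exactly); contaminated samples place the same read total uniformly
  over the genome. At tile = contig_length/50 this puts DNA-like CV near
  0.03–0.06 and RNA-like CV around 0.8–1.4, inside the 0.2–1.6 band
  observed in real cohorts, so the 0.5 rule separates them cleanly.
- qPCR: CT = intercept − slope·log2(latent) + N(0, 0.25), duplicate
  reactions, clipped to [1, 45]; slope 1, intercept 30 put marker CTs in
  the low-20s. With zero noise the ΔΔCT chain returns latent ratios
  exactly (tested).

The biological deviation on markers deserves a word: without it, latent
marker levels would be identical within group and qPCR classifiers
would be perfect, which no real cohort shows. SD 1.5 log2 yields
in-sample AUCs around 0.88–0.99 — still stronger than typical published
biomarkers, but with enough overlap that logistic fits converge and the
cross-validation optimism pattern is visible.

### What the simulations do not show

The generator omits mapping artifacts (soft-clipping, multi-mapping,
contaminant species), sequencing error, GC/mappability bias, batch
effects, correlated region blocks beyond the planted gender set, qPCR
efficiency differences and inter-run drift. Passing tests therefore
demonstrate that the *statistical machinery* is correct and calibrated
under its stated model — not that effect sizes or accuracies of this
magnitude would be attained on real urine-EV cohorts, where unmodelled
variation will reduce them.

## Problem sizes

Tests and the acceptance script run miniature configurations chosen to
exercise every code path at comfortable desk scale: genomes of 1–2
contigs × 20–100 kb (500–2000 regions, ~600–1200 expressed), cohorts of
6–78 samples, 10–20 simulation seeds per calibration claim, 10–100 CV
repeats. The full-genome tiling check uses the bundled GRCh37 contig
table directly (the grid is arithmetic, so no per-region materialization
is needed).

## Known limitations

- The dispersion trend `a₀ + a₁/μ` can misfit when expressed-region
  means span a narrow range; the geometric-mean shrinkage then pulls
  mildly toward the trend. Calibration tests bound the practical effect.
- `deviance_test` assumes nested fits on identical samples; it checks
  sample counts and non-negativity of the deviance difference but cannot
  verify nesting structurally.
- The screen reports gene labels by overlap; when a run overlaps several
  genes all are listed, and picking the assayable one is the analyst's
  call.
- `PipelineConfig` validates field names and shallow types, not deep
  value ranges; stage functions own their own validation.
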