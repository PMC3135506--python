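# Methods

## Study design and the per-locus model

The package targets the paired design: each case contributes one tumor
and one adjacent-normal sample, both processed on the same chip, with all
samples in a single batch. The per-locus response is the β-value
`M / (M + U)`; entries with zero total signal are missing (no offset
constant is added to the denominator — the missing-value path covers the
degenerate case).

The mixed model per locus is

    Y = μ + tissue + sex + location + case + ε,

tissue/sex/location fixed, case random, errors i.i.d. normal. Because sex
and location are constant within a case they are nested in the case
factor; the only coherent error strata on this design are:

* tissue (and case) against the residual — in the balanced paired layout
  the residual is exactly the tissue×case stratum, which makes the tissue
  F equal to the squared paired-t statistic (asserted to 1e-8 relative in
  the tests, observed ~1e-12);
* sex and location against the between-case mean square.

Sums of squares are sequential (type I) in the fixed order tissue, sex,
location, case, computed by block-orthogonalizing the dummy design via
SVD and projecting all loci at once (`Y @ Q` per block), so a genome-wide
fit is a few matrix products. The synthetic design is balanced, where
order is immaterial; on unbalanced real data the order above attributes
shared variation to the earlier factor — a documented convention, not an
inference claim. Variance *fractions* are SS/total-SS (they sum to 1 by
construction); variance *components* for the case effect and the residual
use method-of-moments, `σ²_case = max(0, (MS_case − MS_res)/2)`, with
negative estimates truncated at zero. Constant rows are reported as
F = 0, p = 1 with the whole variance assigned to error; loci with missing
values are refit on complete samples and skipped below three complete
pairs.

The univariate DiffScore uses an unpaired Welch t and the transform
`10·sign(Δβ)·(−log10 p)`; the ±30 threshold is then exactly the p = 0.001
cutoff. FDR control is Benjamini–Hochberg throughout (via statsmodels).

## Normalization routes and consensus

Background correction subtracts the per-sample mean of the
negative-control signals from both channels, flooring at zero (whether to
floor is an open choice; flooring keeps intensities interpretable).
Quantile normalization maps each sample onto the mean-of-order-statistics
reference; ties receive the average of their span of reference values.
With ties present (saturated β values), a second pass can move entries by
about the tie-averaging resolution (~1e-3 observed); on tie-free data the
transform is exactly idempotent, which is what the test suite asserts at
1e-12. The DML consensus is the direction-respecting intersection of the
calls from the four routes. The four routes' effect sizes are *similar*,
not identical: background subtraction at the emulated negative-control
level (1/20 of total signal) shifts β by ≈ (2β−1)/19 and rank
normalization adds a comparable wobble, so per-locus Δβ agrees across
routes to ~0.1 while directions coincide; the consensus absorbs exactly
this kind of route disagreement.

## Sex screen

Sex-differential loci are detected from the sex factor of the same mixed
model at FDR 0.01. Regardless of the screen's outcome, all X/Y loci are
removed before tumor/normal calling — in a mixed-sex cohort,
X-inactivation (female X loci drifting toward hemimethylation) otherwise
contaminates the tissue contrast.

## Gene sets

* GO enrichment: per set, a 2×2 chi-square (no continuity correction) of
  significant-vs-chip gene proportions; ES = −log10 p; sets with an
  expected cell < 1 are flagged, not dropped; no GO-hierarchy
  propagation — sets are taken as given in the GMT.
* Preranked GSEA: the ranking statistic is signed significance,
  `−log10(p_tissue)·sign(Δβ)`, collapsed to genes by the locus of largest
  magnitude. The ES is the weighted KS running-sum extreme (hit weight
  |stat|^w, default w = 1; miss 1/(N−|S|)); magnitude ties between the
  positive and negative extreme resolve to the positive one (tolerance
  1e-12 so the decision is stable under floating-point reordering). The
  null is gene-label permutation — phenotype permutation would break the
  tumor/normal pairing that produced the ranking statistic — with
  NES = ES / mean|ES*| over same-sign permutations and
  p = (1 + #{|ES*| ≥ |ES|}) / (1 + #same-sign), hence p ≥ 1/(n_perm+1).
* GO-ANOVA: one model per set on the stacked β of every member locus,
  fixed tissue + gene + patient, random sample-within-tissue×patient;
  the tissue F is tested against the sample stratum, so the category
  effect is judged against sample-to-sample, not locus-level, noise.
  Single-locus sets fall back to the locus model, flagged.
* Reported sets must pass all four filters (GSEA p ≤ 0.01, |NES| ≥ 1.5,
  GO-ANOVA FDR ≤ 0.01, category mean |Δβ| ≥ 0.1), sorted by NES
  descending.

## Nested cross-validation

Outer folds partition whole cases (6 folds × 4 cases = 8 samples held
out): splitting per sample would place a subject's paired sample in
training and leak subject identity. The 40 training samples run an inner
10-fold (2 cases = 4 samples per fold), giving 60 inner iterations.
Feature selection — 2-way tissue+case ANOVA ranking by tissue p, forced
loci first — is recomputed inside every training split; the fold audit
records the selected sets so leakage is assertable, and a deliberately
leaky selector (ranking on all 48 samples) is detected by differing
selections. The inner loop scores every (classifier, size) by normalized
correct rate (balanced accuracy); ties prefer the smaller model, then
menu order (knn1, knn3, centroid, lda). The classifiers are deliberately
minimal and deterministic: Euclidean KNN with stable neighbor order,
nearest centroid with midpoint ties to the first (alphabetical) class,
and pooled-covariance LDA with equal priors and a 1e-6 ridge fallback for
singular covariance. β enters unscaled (already bounded). Per-size report
rows refit the size's best classifier on the 40 and score the held-out 8;
confusion counts are pooled over outer folds (pooling vs averaging is an
open convention; pooled counts keep the metrics recomputable).

## Copy number, expression, integration

Segmentation is recursive binary splitting: the candidate breakpoint with
the smallest two-sample-t p between flanks is accepted if p < 0.001 and
both flanks keep ≥ 10 markers, then both sides recurse. The split test
uses the *pooled-variance* t rather than Welch: off the true breakpoint
one flank mixes both levels, and Welch's per-flank variances reward that
asymmetry — empirically it mislocalized ~4% of breakpoints beyond ±2
markers (step 0.5, noise sd 0.1) where the pooled t mislocalized none.
Segments are called amplification (mean ≥ 2.5), deletion (≤ 1.5) or
neutral; per-sample calls are tested against phenotype with Pearson
chi-square. Differential expression reuses the mixed ANOVA on log2
expression with a 1.3-fold gate at FDR 0.05 (the FDR is a config
parameter: descriptions of the threshold vary between 0.05 and 0.01, so
it is not hard-coded). Cis correlation is Spearman between a locus's β
and the expression of genes whose TSS (locus position minus annotated TSS
distance) lies within 2 kb; coordinates are 0-based, strand ignored.

## qPCR quantification

The digest quadruple (mock Mo, methyl-sensitive Ms, methyl-dependent Md,
double Msd) yields survival fractions `2^−(Ct_digest − Ct_mock)`:
survival of Ms estimates the hypermethylated fraction, survival of Md the
unmethylated fraction, the double digest the refractory background; the
intermediate fraction is the remainder after subtracting the background,
and the triple is clipped to [0,1] and renormalized to sum to one. A Ct
at the maximum cycle (40) means no amplification, i.e. a fraction of
exactly zero — this convention is what makes the generator/quantifier
round-trip exact (≤ 1e-9) at zero noise. Records where the two single
digests account for > 110% of template are flagged assay-inconsistent.
Only Ct differences enter, so the result is invariant to a constant shift
of all four Ct values.

## The synthetic-data generator

The generator emulates the study conditions end to end: 24 cases × 2
tissues (17M/7F, proximal/distal at random, 12 samples per chip, paired
samples sharing a chip), ~1.9 loci per gene with TSS distances uniform on
[0, 1499] bp, and X/Y locus counts matching the emulated chip
(1085 + 7 of 27,578 at chip scale). Latent β per locus and sample is

    clip(baseline + Δβ·[tumor] + sexshift·[X ∧ female] + subject + noise, 0, 1)

with subject effects N(0, 0.02) shared within a case, observation noise
N(0, 0.03), the X-inactivation shift 0.2 toward 0.5 on female X loci, and
planted tumor effects |Δβ| = 0.35 on a minority of loci. Channel
intensities are `M = round(T·β)`, `U = T − M` with T lognormal around
5,000 and negative controls lognormal at 1/20 of that — scales are
conventions (no public intensity distributions exist for the emulated
chemistry); only relative magnitudes matter for detection and background
correction. All draws come from one seeded generator in a fixed order, so
studies are bit-reproducible.

Design choices worth noting:

* The baseline is uniform on [0.05, 0.95]. Real promoter arrays are
  strongly bimodal; a flat baseline was chosen because it keeps every
  quantile populated (rank normalization then behaves comparably across
  routes) and keeps additive noise almost never clipped, which preserves
  null p-uniformity. Consequently, passing tests demonstrate correct
  statistical behavior of the machinery, not robustness to the extreme
  bimodality, probe-chemistry artifacts or batch effects of real chips
  (the emulated design has no batch structure by construction).
* Hypermethylation is planted on low-baseline loci and hypomethylation on
  high-baseline loci (the baseline is clamped so the shifted level stays
  inside [0.05, 0.95]). This mirrors the biology (promoter
  hypermethylation starts from unmethylated islands) and prevents
  boundary clipping from silently halving planted effects. If a plan
  still clips > 1% of draws, a warning is recorded in the truth metadata.
* The pipeline's simulate stage concentrates part of the hyper set in a
  couple of GO terms (coordinated-pathway hypermethylation) so gene-set
  analyses have a planted signal; annotation terms average ~25 genes.
* Expression for cis-coupled genes uses a Gaussian copula against the
  gene's promoter β targeting Spearman −0.8; CN regions add log2(CN/2)
  dosage terms for tumor samples; qPCR fractions derived from β use the
  split (β², β(1−β), 1−β) so the methylated total equals β exactly.

## Problem sizes

The test suite and the acceptance script run the genome-scale checks at
20,000 loci / 10,500 genes / 24 cases (with 500 planted DML for
recovery), chosen as the smallest sizes at which the chip-scale behaviors
(FDR calibration, consensus specificity, fold geometry) are exercised
without changing any threshold; manifest arithmetic is checked at the
full 27,578/14,495 scale. Known limitations: no IDAT/bead-level
emulation, no batch effects, no dye bias or BMIQ/SWAN-style corrections,
no GO-hierarchy propagation, no allele-specific copy number, and
quantile idempotency is exact only up to tie-averaging on saturated
values.
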