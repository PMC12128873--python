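# Methods

## Burden scoring model

A tumor sample is summarized by the genomic material it has gained minus
lost. The raw substrate is a segment table (sample, chromosome, 1-based
inclusive start/end, log2 copy ratio), optionally with a tumor-cell purity
per sample.

**Purity correction.** The observed copy ratio of a segment is modelled as a
linear mixture of tumor and contaminating normal DNA,
`R_obs = p·R_tumor + (1 − p)`, so the tumor component is recovered as
`R_tumor = (R_obs − (1 − p)) / p` before taking log2. Mixing on the linear
scale matches physical DNA mixing; the same algebra is used in reverse by the
segment simulator, so correction inverts simulation exactly. Segments whose
implied tumor ratio is nonpositive cannot be de-mixed; they are excluded with
a warning rather than clamped, since they indicate either very low purity or
a homozygous deletion the single-copy model does not cover.

**Arm calls.** An arm is called gained when segments with corrected log2
ratio strictly above +0.32 cover at least 50% of the arm's length, lost when
segments below −0.41 do; if both directions qualify the larger affected span
wins and an exact tie is neutral. The asymmetric cutoffs reflect that a
single-copy loss (log2 1/2 = −1) moves the ratio further than a single-copy
gain (log2 3/2 ≈ +0.58) at equal purity.

**Score.** `net = gain Mb − loss Mb` with megabases counted as
`(end − start + 1)/1e6`. The default weighting sums the megabases actually
affected on called arms; an alternative counts each called arm's full length.
The affected-megabase convention is the default because the score is defined
as material affected, not arms crossed; both are exposed because the stricter
arm-length convention is common in arm-level aneuploidy scores and the choice
is not settled by the score's definition alone. Gene-level matrices (log2 of
copy ratio + 1, diploid neutral at exactly 1.0) use cutoffs 1.16 / 0.8 and
count genes by default — gene-level input carries no unique megabase mapping,
so gene count is the honest default and megabase weighting is available when
gene lengths are supplied.

**Expression-inferred CNA.** Tumor expression is divided by the mean of a
normal reference panel per gene, smoothed along each chromosome with a
centered moving average (default 101 genes, forced odd, shrunk with a warning
on short chromosomes), and re-centered so each sample's genome-wide median is
1. Values above 1.02 / below 0.98 are called gained / lost. This is a
deliberately small reimplementation of the reference-normalize–smooth–recenter
idea behind expression-based CNA callers, not a replication of any particular
package's internals.

## Screen analysis

Guide abundance at PD0 (post-selection) and PD6 (six population doublings) is
library-size normalized per column and reduced to
`lfc = log2((c6 + 0.5)/N6) − log2((c0 + 0.5)/N0)`, median-centered per
column. Guides with PD0 count below 30 are excluded from testing for that
column: their fold changes are dominated by sampling noise.

**Copy-number bias correction.** Dropout and enrichment show a positional
bias on copy-number-altered arms that is unrelated to gene function. For each
clone and each arm its karyotype marks as gained or lost, the correction
subtracts (arm median guide LFC − background median guide LFC) from that
arm's guides. The background is the median over guides on copy-neutral arms
rather than the genome-wide median: when a large arm carries the bias, the
genome-wide median is itself contaminated and part of the shift would
survive. Arms with fewer than 20 guides are skipped — a median over fewer
guides is noisier than the bias it would remove.

**Gene-level test.** The gene score is the mean of its guides' LFCs. The
null for a gene with k guides is the score of pseudo-genes assembled from k
guides drawn at random (with replacement) from the whole library; the
two-sided p-value uses the (b + 1)/(n_perm + 1) correction and BH adjustment
across genes. Default n_perm = 10,000; the null is shared across genes of
equal guide count, so cost is independent of gene number. Essential-gene
calls default to FDR < 0.05 and LFC < −2. A count-model fit (the
limma-voom/edgeR route) is intentionally replaced by this permutation
framework: it is self-contained, seedable, and exactly testable against
enumeration on small instances.

**Epistasis.** The profile is per-gene mean aneuploid gene score minus mean
diploid gene score (negative = more essential in aneuploid clones); labels
swap antisymmetrically. With ≥2 clones per group significance comes from
permuting clone labels, otherwise from permuting guide-level values between
the groups within each gene.

**Preranked GSEA.** ES is the maximum deviation of the weighted KS running
sum (hit increments ∝ |score|^p with p = 1, miss decrements 1/(N − Nh));
p-values and NES come from gene-label permutation, compared within the
observed ES's sign against the same-sign side of the null, NES = ES divided
by the mean same-sign null ES. Sets are filtered to overlaps in [5, 500] by
default; a set covering the whole ranking is degenerate (the running sum
never decrements) and is skipped.

## Feature association and normalization

Association is per-feature ordinary least squares of feature on burden with
the two-sided t-test p-value and BH FDR across the matrix — deliberately
plain linear regression, no robust variants, so coefficients are directly
rankable for GSEA. Abundances can be normalized per cell (divide by cell
count) or per total chromosomal content (divide by chromosome_count/46, the
diploid human baseline). Ratio metrics (labeled::unlabeled, GSH::GSSG,
ATP::AMP) return NaN on a nonpositive denominator rather than a substitute
value. The mitochondrial copy estimate is
`nuclear_ploidy × mt coverage / autosomal coverage` (default ploidy 2). An
optional symmetric clamp on reported coefficients exists purely as a display
convention; p-values are always computed on the unclamped fit.

## Bioenergetics metrics

Phase means (by default the mean of the last 3 measurement cycles per phase,
the usual instrument convention) feed fixed arithmetic: for the
mitochondrial stress test, nonmito = post-rot/AA OCR, ATP-linked = basal −
post-oligomycin, maximal = post-FCCP − nonmito, spare = maximal − (basal −
nonmito); for the glycolytic rate test, compensatory = post-rot/AA PER −
post-2-DG PER. Everything is divided by a per-well protein factor. Negative
derived metrics are reported with a QC flag and never clipped — a negative
ATP-linked rate is a sign of a failed injection, and hiding it would hide the
failure. Differences in cell seeding across ploidies are assumed to be
absorbed by the protein normalization.

## Survival analysis

Chemotherapy patients are identified by keyword search over lowercased drug
strings: platin, dox, uracil, rubicin, mycin, phosphamid, citabine, cytoxan,
trexate, ac, capecetabine, 5-fu, metotreksat, mitoxantrone, cytoxen, gemzar,
tc, tch, xeloda. The short codes (ac, tc, tch, 5-fu) match whole tokens only
— as raw substrings "ac" fires inside "paclitaxel", which is not a
DNA-damaging chemotherapy; a pure-substring mode is available to replicate
the raw search-string behaviour. An empty drug list is non-chemo with an
"untreated" annotation.

Kaplan–Meier curves use the product-limit estimator with right censoring and
Greenwood variance, evaluated by the right-continuous step convention. Cox
fits are two-group maximum partial likelihood with Efron tie handling (via
lifelines); a monotone likelihood — one group with zero events — is reported
as a divergence, not a number. The stratified analysis truncates follow-up
at 5 years (administrative censoring) before fitting and reports, within the
chemo-treated and the non-chemo-treated patients separately, the hazard ratio
of net-loss vs net-gain. Truncating before fitting (not just for plotting)
is a design choice: the 5-year horizon defines the clinical question, and
the estimate should not be driven by late follow-up.

## Synthetic data: what it emulates, what it does not

The generators plant exactly the structure the analyses assume and record it
in a truth object (same seed ⇒ byte-identical output):

- **Segments**: whole-arm single-copy events, purity-mixed on the linear
  scale, Gaussian log2 noise (default arms split into 2 segments; event
  coverage fraction configurable). Real data's focal events, multi-copy
  amplifications, subclonality, and segmentation error are not emulated.
- **Screens**: genes laid out in contiguous arm blocks, per-guide lognormal
  abundance (σ = 0.25), negative-binomial counts with Var = μ + φμ²
  (default dispersion φ = 0.1, Poisson at φ = 0; mean depth 500 reads/guide,
  matching 500× representation), essential genes shifted by a configurable
  LFC (default −2, a 4-fold depletion), and an additive LFC shift on chosen
  arms as the positional bias. Guide-efficacy variation, off-target effects
  and passenger fitness effects are not modelled, so recovery rates here are
  upper bounds on real screens.
- **Features**: linear in burden plus Gaussian noise — no heteroscedasticity
  or batch structure.
- **Expression**: lognormal baselines scaled by a dosage factor on gained
  arms (losses scaled by 2 − dosage, single-copy symmetry around diploid).
- **Cohorts**: exponential event times with the baseline hazard calibrated
  from a stated 5-year survival (λ = −ln S(5)/5), a proportional hazard for
  the second group, administrative censoring at the horizon and optional
  uniform random censoring. Real cohorts violate proportional hazards and
  have informative censoring; passing recovery tests here demonstrates the
  estimators, not the clinical result.

## Problem sizes and numerical choices

The recovery analyses use 20 replicate cohorts of 2,000 subjects (Cox) and
500 subjects (KM), and the screen recovery suite runs at 2,000 genes × 5
guides with 1,000 permutations — sizes at which the estimators' sampling
error is well inside the tolerances being checked while the whole suite runs
in about a minute. Permutation p-values are never 0 by construction
((b + 1)/(n_perm + 1)); BH is applied per result table; RNG is NumPy's
default (PCG64) seeded explicitly everywhere, with child seeds drawn from a
single parent stream in the pipeline so stages are independently
reproducible.

## Known limitations

- Arm calls assume the single-copy mixture model; whole-genome doubling and
  allele-specific copy number are out of scope.
- The positional-bias correction is a median-shift scheme; it removes an
  additive arm-wide bias but not dose-dependent or sub-arm structure.
- The Cox interface is the two-group comparison the stratified design needs;
  multivariable adjustment and competing risks are out of scope.
- `infer_cna_from_expression` orders chromosomes lexically between
  chromosomes; only within-chromosome order affects the smoothing, but
  output row order follows that convention.
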