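# Methods

This note documents the statistical procedures, the synthetic-cohort model
behind the tests, the numerical choices, and the known limitations of
`gbmpipe`.

## Transcript deconvolution

Exon-array intensities of gene *i* are modeled as **e**ᵢ = **A**ᵢ**t**ᵢ + ε,
with **A**ᵢ the m×n binary exon–transcript incidence matrix built from the
annotation and **t**ᵢ the unknown transcript intensities.  Each sample is
solved independently by least squares through a complete orthogonal
decomposition (LAPACK `gelsy`), which is numerically stable on the
rank-deficient systems that arise when transcripts share all measured
exons; those systems get the minimum-norm solution and a flag rather than
an error.  Solved values are unconstrained — negative estimates are
permitted and flagged, not clipped, so the estimator stays linear and its
oracle (the normal equations (AᵀA)⁻¹Aᵀe on full-rank systems) is exact.
Incidence rows are restricted to measured exons; measured exons absent from
the annotation are dropped with a logged count.  Coordinates are 0-based
half-open internally; GTF input is converted at the boundary.  An exon id
recurring within a gene at different coordinates is ambiguous and rejected.

## Differential expression and DET selection

Fold change is the ratio of group means on the intensity scale; a
non-positive control mean makes it undefined (missing, flagged).  The test
is Welch's two-sample t (unequal variances) — the one t-test convention
used throughout the package — with Benjamini–Hochberg step-up adjustment
across all tested features.  Intensities are tested on the provided scale
by default; a `log_transform` toggle tests log2 intensities instead.
Features with zero variance in both groups get missing P and are excluded
from the adjustment.  The DET gate is symmetric on the ratio scale
(FC > 2 or FC < 0.5, both strict) with adjusted P < 0.05, matching the
±2-fold discretization used by the survival screen.

## Survival analysis

Kaplan–Meier estimation and its Greenwood-based 95% confidence intervals
come from `lifelines`.  The log-rank statistic is computed internally
(observed-minus-expected death counts with the multivariate hypergeometric
covariance at each distinct event time, tied events handled by the same
formula; χ² on k−1 df, two-sided upper-tail P) because the screens test
thousands of features/markers and the implementation is cross-checked
against `lifelines` in the tests.

The expression screen discretizes per-sample fold changes at 0.5 and 2,
drops classes with fewer than 20 patients, and skips features left with
fewer than two classes.  The SNP screen applies, in order: sample SNR ≥ 5,
call probability ≥ 0.95 (failing calls become missing), MAF ≥ 0.1 computed
by allele counting over called genotypes only, administrative censoring of
events and follow-up at the 36-month study horizon, and merging of the
rare-homozygote group into the heterozygote group when its count < 15 or
its fraction of called patients < 0.1.  All remaining genotype groups enter
one log-rank test (df = groups − 1).  The reporting limit is uncorrected
P < 10⁻⁴ — at that limit a 5 000-marker null screen is expected to pass
about 0.5 markers, a property the tests check with a Poisson bound.

## Copy-number segmentation and calling

Segmentation is a recursive circular-binary search implemented here (no
maintained Python implementation exists in the dependency set): within the
current stretch the candidate split is the arc (i, j) maximizing
|mean_in − mean_out| / (σ·√(1/k + 1/(n−k))), with σ the stretch's sample
SD and both sides at least `min_width` = 3 probes.  The split is accepted
when the permutation P of that maximum (add-one estimator over
`n_permutations` = 1000 shuffles, evaluated in vectorized blocks with early
rejection once significance is impossible) is below α = 0.01, and the
search recurses into the pieces.  Segment means are plain member-probe
means, so the probe-weighted mean of segments reproduces the chromosome
mean to machine precision.

Calling thresholds default to ±0.632 and are otherwise estimated as
mean ± 2·SD of pooled control-array probe log-ratios (sample SD); a
per-array SD option exists.  Degenerate controls (SD = 0, too few values)
fall back to the defaults with a warning.  Calls use strict inequalities
("over" the threshold).  Per-gene frequencies use any-base-pair overlap; a
gene overlapping both a gained and a lost segment in one sample is recorded
ambiguous and excluded from both numerators, and a gene with no covering
segment in a sample (possible in the inter-probe gap at a segment boundary)
counts neutral, logged.

## Amplification–expression integration

w = (μ_amp − μ_non)/(σ_amp + σ_non) with sample SDs; groups of fewer than
two samples, or two zero SDs, skip the gene.  Significance is one-sided
toward overexpression-with-amplification (a two-sided flag exists, since
"comparing the permuted weight to the original" is directionally
ambiguous): exhaustive enumeration of all C(n,k) label assignments when
that count is ≤ 10 000 (P = fraction of assignments reaching the observed
w), otherwise 10 000 random assignments with the add-one estimator so
P ≥ 1/(B+1) and a constant-expression feature yields P = 1.  The mirrored
statistic (loss mask, sign-flipped expression) screens deletion-driven
underexpression.  Candidate selection: P < 0.01 and gain frequency > 5%.

## Methylation and miRNA

Beta = M/(M+U) (missing when M+U = 0, scale-invariant by construction);
promoter probes combine to one beta per gene by the median over non-missing
probes.  Betas are reported descriptively — no hypo/hyper-methylation call
threshold is imposed.  miRNA differential expression is literally the
expression-module procedure applied to the miRNA matrix; the target-site
annotation is filtered at P < 10⁻⁵.  A synthetic miRNA→gene target table
(log-uniform P in 10⁻⁸…10⁻²) stands in for a curated target database.

## siRNA screen scoring

Plate background is a robust locally-weighted quadratic surface over well
coordinates: span 0.35 (neighborhood = that fraction of wells, tricube
distance weights), degree 2, and two bisquare reweighting passes so hit
wells do not drag the surface; the fit is subtracted.  Because the surface
model and the simulated plate backgrounds are both low-order polynomials,
removal is exact up to noise — which is also why the idempotence guarantee
(a second pass changes nothing) holds exactly on polynomial backgrounds and
only approximately on noisy plates.  Robust z = (x − median)/(1.4826·MAD),
the normal-consistent scaling.  Per-siRNA significance is Welch's
two-tailed t against negative-control wells, tiered at < 0.05 (*), < 0.01
(**), < 0.001 (***).  The qualitative notion of a "consistent" phenotype is
quantified as: ≥ 2 distinct siRNAs reaching |z| ≥ 2 in the effect
direction in every tested cell line (all three knobs configurable); the
two-siRNA floor guards against off-target effects of a single construct.

## Report

The fused table has one row per gene: gene/exon-platform fold changes,
min/max transcript fold change, best transcript and gene survival P, best
SNP P, gain/loss frequencies, combined beta, integration P.  Fusion is an
outer join on canonicalized (upper-case) gene ids; conflicting duplicates
are an error, missing values render blank (never 0), and per-field
provenance is kept in `table.attrs`.  The site is static and
self-contained: client-side column sorting, a two-color log-ratio ramp
saturating at |log2 FC| = 3, P cells shaded at the 0.05/0.01/0.001 cuts,
external databases linked via URL templates only, and Kaplan–Meier SVGs
embedded only for features with survival P < 0.01.  Rendering reads the
fused table verbatim and recomputes nothing.

## Synthetic cohort model

The generator emulates the platform roster above with one configuration
object and a single seed (identical configs are byte-identical on disk).

* **Expression.**  Per gene, 1–3 transcripts with private + shared exons
  (the private exons make every incidence matrix full column rank);
  baseline transcript intensities uniform in 50–150; exon intensities
  **A t** plus additive Gaussian noise (default SD 10 on the ~100-scale
  intensities — additive noise on the linear scale keeps the least-squares
  model exact).  Controls share the baseline; planted expression effects
  multiply carrier tumors (default 40% of tumors) by 4.
* **Survival.**  Exponential proportional hazards: baseline 0.05/month
  (≈ 14-month median, typical of GBM), hazard multiplied by the planted
  hazard ratios of a patient's carrier/genotype groups; independent
  censoring with probability 0.2 at a uniform fraction of the event time,
  plus administrative censoring at the 60-month horizon.  The exponential
  choice gives closed-form checks (median = ln 2 / h).
* **Copy number.**  A probe grid over one synthetic chromosome (2 probes
  per gene slot plus flanks), Gaussian probe noise SD 0.25; a planted CN
  effect writes a constant-mean segment spanning the gene ± 2 probes in the
  same carrier samples as the gene's expression effect, coupling
  amplification to overexpression.  Ten blood-like control arrays are pure
  noise.
* **Genotypes.**  Hardy–Weinberg proportions at MAFs drawn from the
  configured range; 2% of calls get probability 0.8 (failing QC); sample
  SNR ~ N(10, 2).  A planted SNP effect multiplies the hazard of
  minor-allele carriers of its marker.
* **Methylation / miRNA.**  Per-gene beta ~ Beta(2,2) with small probe
  noise on M/U channels of realistic total intensity; miRNA matrix null
  except two planted 4-fold species.
* **Plates.**  16×24 wells, negative-control and cell-death-control
  columns, 3 replicate wells × 4 siRNAs per screened gene, a low-order
  polynomial spatial background (by construction removable by the degree-2
  surface fit), Gaussian well noise, and strong spikes on two siRNAs of one
  hit gene in both assays.

What the generator does **not** emulate: probe-level normalization and raw
CEL/IDAT processing, batch effects, population structure (cohorts are
homogeneous by construction), correlated biological variation between
samples, and realistic linkage between markers.  Passing tests therefore
demonstrate correctness of the estimators and decision rules under the
stated noise models, not robustness to the full messiness of real arrays.

## Problem sizes in tests and the acceptance script

The validation harness chooses sizes where each property is sharply
testable: 200 random systems for the solver oracle; 2 000 null replicates
(100 patients/arm) for log-rank calibration; 1 000 null features × 999
permutations for integration uniformity; 20 profiles × 150 probes with
four planted breakpoints each for segmentation recovery; a 2 100-feature
matrix (100 four-fold signals, 50 tumor/10 control) for FDR/sensitivity;
and 10–20 independent cohorts of 200 tumors × 30 genes for end-to-end
planted-gene recovery.

## Known limitations and open choices

* The control-sample noise structure of real normal-tissue arrays is not
  specified anywhere; synthetic controls reuse the tumor noise model with
  baseline means.
* Whether the ±0.632-type thresholds should use pooled or per-array
  control SD is undetermined; pooled is the default, per-array an option.
* Exons present in the annotation but absent from the array are simply not
  rows of the incidence matrix; no attempt is made to impute them.
* The SNP screen uses however many genotype groups survive merging
  (df = groups − 1) rather than forcing a two-group comparison.
* Cox modeling, GISTIC-style recurrence significance, moderated-variance
  (empirical-Bayes) testing and methylation survival analysis are out of
  scope by design.
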