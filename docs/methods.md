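# Methods

## The analysis model

The core question is whether a treatment (here: forced AID expression in
primary CLL B cells) shifts DNA methylation at individual CpGs when each
patient serves as their own control. The data are Infinium EPIC beta
values β ∈ [0, 1] (fraction methylated signal per probe), observed for a
small number of patients (default 4) in matched control/treatment pairs.

### Paired moderated testing

For probe *i*, let d_i = (β_treated − β_control) over the n_i patients
with both samples observed. We test H₀: E[d_i] = 0 with an
empirical-Bayes moderated paired t-test. The per-probe sample variance
s_i² is assumed exchangeable across probes, drawn from a scaled inverse
chi-square prior with hyper-parameters (d₀, s₀²). The hyper-parameters
are estimated by matching the first two moments of log s² to the implied
scaled-F distribution: with e_i = log s_i² − ψ(df_i/2) + log(df_i/2),
the excess of var(e) over the mean sampling term ψ′(df/2) equals
ψ′(d₀/2), inverted by Newton iteration on the trigamma function; when
the observed dispersion does not exceed the sampling term, d₀ = ∞. The
posterior variance s̃_i² = (d₀s₀² + (n_i−1)s_i²)/(d₀ + n_i − 1) gives

    t_i = mean(d_i) / sqrt(s̃_i² / n_i),  referred to t(d₀ + n_i − 1)

(standard normal when d₀ = ∞). Two-sided p-values are thresholded on the
raw scale to call methylation variable positions (MVPs); BH-adjusted
p-values are always reported alongside, because with 4 pairs and
hundreds of thousands of probes the raw-p MVP list is primarily a
ranking device, not an inference.

Testing runs on the beta scale by default. Beta values are bounded and
heteroskedastic (variance shrinks toward 0 and 1), which the moderation
only partially absorbs; an M-value mode (log2 β/(1−β) differences,
beta-scale effect sizes still reported) is available via `scale="mvalue"`.

Probes with fewer than 2 complete pairs are excluded. Probes whose
replicate differences are numerically identical get their variance
snapped to exactly zero (rounding noise below 1e-28 is not variance);
with d₀ > 0 they receive a finite moderated t, with d₀ = 0 their p is
missing and they are excluded from the BH adjustment.

### BMIQ normalization

The two Infinium probe chemistries report on different dynamic ranges:
Type II betas are compressed toward 0.5. Per sample, a three-state beta
mixture (unmethylated / hemimethylated / methylated) is fitted separately
to Type I and Type II probes by EM. The M-step maximises the weighted
beta log-likelihood exactly (L-BFGS on log-shape parameters with analytic
gradients), so the log-likelihood trace is non-decreasing.
Initialisation is deterministic, by fixed thresholds (β < 0.25 → U,
β > 0.75 → M, else H); states are relabelled by increasing mean.
Convergence: relative log-likelihood change < 1e-4 (default), max 200
iterations. Betas at exactly 0 or 1 are nudged inward by ε = 1e-6.

Type II probes are then mapped per max-posterior state: U probes by
matching lower-tail beta-CDF quantiles of the Type II U component onto
the Type I U component, M probes via upper-tail quantiles, and H probes
by a monotone affine dilation of the observed H range onto the gap
between the transformed U maximum and the transformed M minimum. Type I
values pass through bit-identically; outputs are clipped to [0, 1].

The dilation step is affine rather than quantile-matching, so exact
idempotence is not a property of the transform: renormalizing an already
normalized sample still moves Type II values by a small amount (median
~2e-3 at realistic array sizes, an order of magnitude below the first
pass). The test suite asserts the contraction, not exact idempotence.
The no-op property — when Type II and Type I share one empirical
distribution, the transform is the identity — is exact for U/M probes
and is what the identity test checks.

### DMRs and the candidate cascade

An MVP cluster rule ("≥3 MVPs within 1 kb, all p < 0.05") is formalised
as: every inclusive 1000-bp window containing ≥3 MVPs is a qualifying
window; maximal unions of overlapping qualifying windows, trimmed to
their outermost member MVPs, are the DMRs. This is the least arbitrary
closure of the printed rule and is testable against exhaustive window
enumeration. A consequence worth noting: chained overlaps can produce
merged regions longer than a single window — the 1 kb constraint binds
per window, not per merged region. Window width and the MVP count are
parameters.

Candidate genes: every gene touched by a DMR is kept iff it is not
flagged as a pseudogene on the manifest and is supported by ≥2
hypomethylated member MVPs in a regulatory/transcribed feature. The
feature set {TSS1500, TSS200, 5'UTR, 1stExon, Body, 3'UTR} includes
TSS200 and the first exon because the selection criterion is positional
(within 1.5 kb upstream of the TSS, or inside the transcript) even
though the manifest categories are disjoint; the set is configurable. A
gene supported by several DMRs pools its hypomethylated regulatory MVPs
across them. Every excluded gene carries a reason (pseudogene /
feature_mismatch / insufficient_hypo).

### qPCR quantification

ΔCt = Ct(gene) − Ct(reference) per sample, after averaging technical
replicates on the Ct scale; relative expression 2^−ΔCt. Undetermined Ct
targets are reported at the sentinel 10⁻¹¹ with a detection flag — for
screening output only. Fold changes are 2^−ΔΔCt against a calibrator
condition; undetected genes are dropped from fold changes, not imputed.
The reference gene is a required parameter (the screening assays and the
microfluidic cards used different references — 18S vs GAPDH — so no
default constant is safe). Samples are non-AID-expressors iff their
AICDA Ct is undetermined or strictly above 32 cycles; a Ct of exactly 32
counts as an expressor (the rule is "above 32"), and the threshold is
configurable. The mutator statistic is the per-clone ratio of
rifampicin-resistant to total clones with mean ± sample SD.

### Cohort reanalysis

A marker gene (AICDA) with bimodal log2 expression splits a cohort at
the antimode: the deepest minimum of a Gaussian KDE (Silverman
bandwidth, 1024-point grid) between the two outermost density modes.
Cohorts where the marker is unimodal raise a typed error and fall back
to the correlation screen (per-gene squared Pearson R² against the
marker). Group differential expression reuses the same variance
moderation in pooled two-sample form, with BH FDR across the tested gene
subset only. When a marker is measured by several probes the
highest-variance probe is the intended representative (callers pass the
row; the convention is documented rather than enforced).

## The synthetic-data generator

The generator produces what the pipeline consumes with the structure the
analysis assumes; its defaults are the study conditions:

* 4 patient pairs; 84% Type II probes (the EPIC chemistry mix);
* three-state beta mixture with weights (0.35, 0.15, 0.50) and shapes
  ((2,18), (10,10), (18,2)), i.e. state means ≈ 0.1/0.5/0.9 — a
  bimodal methylome with a hemimethylated shoulder;
* Type II compression 0.25 toward 0.5 (an affine squash, emulating the
  reduced Type II dynamic range);
* per-sample noise applied on the logit(β) scale (default sd 0.25,
  chosen to reproduce paired-replicate scatter of a few percent beta at
  mid-range without leaving the unit interval; noise is back-transformed,
  so no clamping of noise is ever needed — only planted mean shifts are
  clamped);
* planted effects bounded at |Δβ| ≤ 0.20, matching the effect-size
  regime the analysis targets; planted DMRs are ≥3 probes within ≤1 kb
  with an assigned gene and feature;
* probe baselines are drawn once per probe and shared across patients,
  so with zero noise and no planted effects control and treatment
  columns are identical (the null pipeline yields no calls);
* expression cohorts: one marker gene from a two-component Gaussian
  mixture on the log2 scale (defaults 4.0/8.0, 30% high — a 130-sample
  cohort then splits near 91/39), other genes Gaussian, optional planted
  log2 effects in the marker-high group;
* Ct tables realise configured true fold changes exactly at zero noise.

What it does **not** emulate: dye bias, batch/chip effects, detection
p-values, probe cross-reactivity, cell-composition heterogeneity,
correlated neighbouring probes, and IDAT-level signal. Passing tests
therefore demonstrate the statistical machinery under the assumed
generative structure, not robustness to real-array artefacts.

Chromosome coordinates are 1-based point positions (the CpG site);
windows are inclusive of both endpoints; BED export converts to 0-based
half-open.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale arrays: 10⁴ probes for the
type-I-error null (the binomial band [0.04, 0.06] at nominal 0.05), 200
planted probes at logit noise 0.1 for power, 10⁴ simulated variances for
prior recovery (d₀ within ±20%, s₀² within ±10%), 50 random 200-probe
instances for the DMR oracle, 8000 probes for BMIQ mode alignment
(±0.05), and a 130-sample cohort for the split and FDR checks. These
sizes keep every check comfortably reproducible on one CPU while leaving
the statistics sharp enough to be meaningful.

Tie-breaks and degenerate inputs: BH ties resolve through the standard
running-minimum formulation; DMR member ordering breaks position ties by
effect size for determinism; mixture states with fewer than
`min_state_count` (default 5) Type II members abort normalization with
advice to supply a larger input; degenerate (constant) inputs to the
mixture fit, the prior estimator and the mutator statistic raise typed
errors.

## Known limitations

* With 4 pairs, power at |Δβ| ≤ 0.2 exists only because the moderated
  variance borrows strength across probes; single-probe inferences at
  this sample size should be read as rankings.
* The union-of-windows DMR rule can chain beyond 1 kb; analyses that
  need hard span bounds should post-filter on `DMR.span`.
* BMIQ here is per-sample; no cross-sample quantile step is included, so
  residual between-sample distributional differences persist (they are
  what the paired design absorbs).
* The per-sample BMIQ transforms add small sample-specific distortions;
  on very small synthetic arrays this mildly inflates the raw-p MVP
  count relative to testing unnormalized betas. At realistic array sizes
  the effect shrinks with the mixture-fit error.
* The antimode split assumes the marker's two modes dominate the KDE at
  Silverman bandwidth; heavily skewed or >2-modal markers may need a
  fixed threshold.
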