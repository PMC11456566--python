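# Methods

This note documents the models, conventions and numerical choices behind
`azasig`, and what the synthetic benchmarks do and do not demonstrate.

## Variant dynamics

Variants are handled on the percent VAF scale [0, 100], as clinical panels
report them. The panel filter keeps a call when its VAF is at or above the
cutoff (default 5%, boundary inclusive). With the paired rescue on
(default), a sub-threshold call is also kept when the same mutation — same
patient, gene, protein change and compartment — clears the cutoff at the
other timepoint. The rescue is symmetric: a high pre-treatment VAF rescues
a collapsing post-treatment observation (a clone driven near extinction by
therapy) and a high post-treatment VAF rescues a small pre-treatment clone
(incipient clonal expansion). Rescue is keyed within a compartment, so a
bulk-BMMC observation never rescues a CD34+ call; the two compartments are
analyzed as separate paired series. Filtering is idempotent.

Dynamics classification takes absence (no call, i.e. below detection) as
the defining state for ACQUIRED (absent → present) and LOST (present →
absent); a mutation present at both timepoints is STABLE when the relative
VAF change |post − pre| / pre is below `rel_change_min`, and INCREASED or
DECREASED by sign otherwise. `rel_change_min` defaults to 0.25: published
mutation-dynamics figures distinguish "no change" from gains and losses
without quantifying the band, and a 25% relative band is wide enough to
absorb sampling noise of targeted-panel VAFs at typical depth while
narrow enough that therapy-scale changes (halving, doubling) are never
called stable. The band boundary is exclusive (a change of exactly 25% is
called directional). ACQUIRED/LOST require true absence, not merely a VAF
below the 5% cutoff — this is what the rescue rule preserves: a rescued
3.98% post-treatment observation is a *decreased* clone, not a lost one.

The substitution spectrum is computed over the pre-treatment mutation set
(the headline transition/transversion proportions describe the diagnostic
clone); SNVs split into transitions (purine↔purine, pyrimidine↔pyrimidine)
and transversions, non-SNVs count as "other". The "unchanged" fraction per
substitution class is the fraction with dynamics STABLE. The CD34-vs-BMMC
comparison is a plain Pearson correlation of matched VAF pairs. Per-patient
burden summaries take a patient roster so that patients with zero mutations
enter the median and range; the "any VAF reduction" fraction is reported
over patients with at least one mutation.

## Differential expression

Counts are normalized with median-of-ratios size factors: over genes with
non-zero counts in every sample, each sample's factor is the median of
count / per-gene geometric mean. Rescaling one library by c multiplies its
factor by c relative to the others; because the geometric-mean reference
itself moves by c^(1/n), normalized values are invariant only up to a
single global constant, which cancels in every between-sample contrast.

The per-gene test is Welch's two-sample t on log2(normalized + 1), or a
paired t across patient-matched samples (both modes are provided because a
paired pre/post design supports either contrast). The pseudocount of 1
handles zeros; genes with zero variance in both groups get p = 1. DEGs are
called at |log2FC| ≥ 1 (boundary inclusive) and unadjusted p < 0.01
(boundary exclusive) — the thresholds are deliberately on the unadjusted p,
matching the convention the pipeline reproduces; a Benjamini–Hochberg
column is emitted for transparency but does not enter the call. A
full negative-binomial GLM with dispersion shrinkage is intentionally out
of scope; at the simulated group sizes the Welch test on log counts holds
its nominal type-I error (measured ≈ 0.01 at p < 0.01) with ample power
against two-fold-squared shifts.

Group-mean tables average normalized (or published mean) expression per
gene per named group. Directional contrasts average the left and right
column sets with *equal weight per column* — not weighted by group sizes —
and call a gene only on a strict inequality; ties are never called. Equal
weighting is the convention under which the bundled 56-gene B-cell panel
reproduces its published directional counts (43/56 down pre-treatment vs
control; 30 up post vs pre) exactly.

## Signature scoring and classification

The two DEG sets (R vs control, NR vs control, up- and down-regulated
pooled) are reduced to *unique* signatures by removing their intersection:
genes perturbed in both arms carry no response information. Signature
membership is unsigned — the derivation direction is implicit in the arm
contrast — and a direction-aware variant was deliberately not guessed,
since the scoring convention being reproduced is defined on gene lists.

A sample's score against a signature is the mean, over the signature's
genes present in the matrix, of the gene's cohort z-score (sample sd,
ddof = 1; zero-sd genes contribute 0). This makes scores invariant to
per-gene affine rescaling, so raw, normalized and log-scale matrices give
identical labels, and it makes a sample's score monotone in its own
expression of the signature's genes. Gene symbols are matched
case-insensitively after trimming (configurable); at least half of a
signature's genes must be present (`min_gene_coverage`, default 0.5) or
scoring fails with the missing genes listed.

Classification is a median split of Δ(NR−R) = NR-score − R-score: samples
with Δ at or above the cohort median are NR-like. The ≥ tie rule matches
the published convention and makes the degenerate all-equal cohort all
NR-like. Stratification splits each labeled class at the within-class
median of the class's own signature score (NR-score for NR-like), ≥ →
"high". When signatures transfer to an independent cohort, standardization
and both medians are recomputed entirely within the target cohort; only
gene lists cross cohorts.

## Survival

Kaplan–Meier, the log-rank test and Yates-corrected chi-square are
implemented from the standard formulas so that the pipeline is
self-contained and testable against hand-worked instances (lifelines and
scipy serve as independent cross-checks in the test suite, never as the
implementation). Events tied at one time are aggregated into a single d_i.
The k-group log-rank statistic is the quadratic form of the summed
observed-minus-expected vector against its hypergeometric covariance with
the last group dropped; for two groups this reduces to the familiar
(O−E)²/V form. Median survival is the first event time with S(t) ≤ 0.5,
reported as undefined when never reached. Survival times are treated as
unitless.

## Synthetic cohorts

The expression generator draws per-gene baselines log-normally
(`baseline_log_mean` 4.0, `baseline_log_sd` 1.0 on the natural-log scale,
i.e. typical means of tens to hundreds of counts) and counts from a
negative binomial with variance μ + φμ², φ constant across genes (default
0.1, a moderate bulk-RNA-seq dispersion; φ = 0 degrades to Poisson). The
default cohort mirrors a fourteen-patient study arm: 5 blast responders, 7
non-responders, 2 undetermined, plus 6 age-matched controls, each patient
contributing a paired pre and post sample that shares a per-patient
log-normal offset (`patient_log2_sd` 0.2). Responder-specific genes are
shifted by ±`planted_log2fc` (default 2) in responder patients only,
non-responder genes in non-responders only, and a disjoint treatment gene
set is shifted in every post sample — the magnitude of the real
AZA-induced shift is unknown, so the treatment effect is a free simulation
parameter (default 1 log2 unit), not an estimate.

The variant generator plants a dynamics category per mutation
(default mix: 8% acquired, 12% increased, 30% stable, 35% decreased, 15%
lost, reflecting the predominance of declining clones under therapy) and
realizes VAFs with a margin around the 25% stability band so the
classifier recovers the planted category exactly. SNV ref/alt pairs are
drawn so that, combined with the default 83.3% SNV fraction, the overall
pre-treatment spectrum targets ≈48% transitions / ≈35% transversions /
≈17% other, with C>T the modal transition. Mutations per patient are
uniform on 0–9. BMMC VAFs are the CD34+ VAFs perturbed by additive
Gaussian noise on the logit scale (keeping VAFs in range) plus a small
positive offset (bulk samples tend to run slightly higher); the noise sd
is solved by bisection against a Monte-Carlo estimate of the induced
correlation so the sample BMMC–CD34+ correlation targets
`compartment_rho` (default 0.73). Additive noise can only induce positive
correlation, so generation rejects non-positive targets.

The validation generator gives each sample a latent standard-normal NR
burden b, up-shifts the NR-signature genes by `burden_log2fc`·b (R genes
behave as background), and draws event times exponentially with hazard
`baseline_rate`·exp(`hazard_beta`·b) under independent exponential
censoring. Defaults (n = 180, baseline rate 0.02, censor rate 0.01,
hazard_beta 1) emulate a classifier-transfer experiment on a ~180-patient
diagnostic cohort.

### What the synthetic benchmarks show — and what they do not

The generators reproduce the *statistical structure* the pipeline assumes:
NB counts with a common dispersion, clean planted fold changes, a
single latent burden axis, exponential hazards. Real cohorts have
gene-specific dispersions, correlated gene modules, batch and composition
effects, partially overlapping response programs, and non-proportional
hazards; none of these are modeled. Passing the recovery benchmarks
therefore demonstrates that the implementation is correct and well
calibrated under its stated assumptions — not that the classifier will
achieve comparable accuracy on real diagnostic samples.

## Problem sizes and reproducibility

Recovery benchmarks use 2,000 genes with 100 planted genes per arm and 20
samples per group; calibration and power studies use 10–100 seeded
replicates (50 for log-rank power, 100 for the null false-positive rate,
1,000 simulated tables for the Yates-conservativeness check). All
randomness flows through numpy Generators seeded from the config or the
acceptance script's `--seed`; identical configs and seeds reproduce
byte-identical outputs, and every written table carries the version, seed
and config hash in a header comment.

## Known limitations

* The DE stage is a t-test on transformed counts, not an NB GLM; at very
  small group sizes (n < 5 per group, as in the default fourteen-patient
  cohort itself) its power is limited and the end-to-end demo uses
  recovery-scale cohorts instead.
* Unsigned signature scoring treats up- and down-regulated signature genes
  identically; a directional score could sharpen transfer when derivation
  directions are trusted.
* The 25% stability band and the detection-limit semantics of
  ACQUIRED/LOST are conventions; with deep sequencing a statistical test
  on read counts would be preferable.
* Minimal VCF ingestion reads CHROM/POS/REF/ALT and an AF field only; it
  does not parse genotypes, multi-sample columns, or symbolic alleles.
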