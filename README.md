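# azasig

Analysis toolkit for paired pre-/post-azacytidine (AZA) studies of
myelodysplastic syndrome (MDS). 5-azacytidine is a hypomethylating agent and
the standard of care for high-risk MDS, yet only a minority of patients
respond, and no routine assay predicts who will. `azasig` implements, as a
tested pipeline with fully synthetic benchmark cohorts, the analyses such a
study runs on CD34+ hematopoietic stem/progenitor cells sampled before and
during therapy:

* **Clonal mutation dynamics** — variant-allele-frequency (VAF) filtering at
  a 5% cutoff with a paired rescue rule, pre/post pairing, five-way dynamics
  classification (acquired / increased / stable / decreased / lost),
  transition–transversion spectrum, CD34+-vs-bone-marrow-mononuclear-cell
  VAF correlation, and per-patient mutational-burden summaries.
* **Differential expression** — median-of-ratios size-factor normalization
  and a per-gene Welch (or paired) t-test on log2(normalized + 1), with
  differentially expressed genes (DEGs) called at |log2FC| ≥ 1 and p < 0.01.
* **Response signatures and the Δ(NR−R) classifier** — genes significantly
  and *uniquely* differentially expressed in blast responders (R) versus
  controls form the R signature, those unique to non-responders (NR) the NR
  signature. Each sample is scored by the mean cohort z-score over each
  signature's genes, and the difference Δ(NR−R) = NR-score − R-score is
  median-split: samples with Δ ≥ median are NR-like, the rest R-like.
  NR-like and R-like groups can be further stratified high/low at the
  within-class median of their own signature score. Signatures transfer to
  an independent cohort with all standardization and medians recomputed in
  the target cohort.
* **Survival evaluation** — Kaplan–Meier curves, the k-group log-rank test
  and Pearson's chi-square with Yates' continuity correction, implemented
  from the standard formulas, to test whether NR-like patients have worse
  overall survival.
* **Synthetic cohorts with ground truth** — negative-binomial expression
  cohorts (variance μ + φμ²) with planted R-/NR-specific fold changes,
  paired variant tables with planted dynamics and a calibrated
  compartment-VAF correlation, and validation cohorts whose exponential
  hazard depends on a latent NR expression burden. Every generator is
  seeded, and the truth records let every downstream stage be scored by
  parameter recovery.

A 56-gene B-cell development panel of published group-mean expression values
(healthy controls; blast responders and non-responders, pre and post AZA)
ships with the package for the directional contrasts: B-lymphopoiesis genes
are broadly repressed in MDS at diagnosis and partially re-induced by AZA.

## Worked example

Run the full synthetic pipeline — simulate a cohort, derive DEGs and unique
signatures, classify an independent 180-sample validation cohort, and test
survival separation:

```sh
$ azasig run-all --seed 7 --out-dir demo
log-rank NR_like|R_like: chi2=77.033 p=1.681e-18
run complete -> demo
```

The derived signatures held 95 R-unique and 99 NR-unique genes; the median
split labeled 90 of 180 validation samples NR-like. In the survival report
(`demo/survival_report.json`) the NR-like arm reaches median survival at
t ≈ 13.2 versus t ≈ 88.7 in the R-like arm, and the log-rank test above
rejects equal survival decisively — the planted hazard on the NR burden is
recovered by the transcriptional classifier alone.

The bundled panel reproduces its published directional counts:

```sh
$ azasig panel
43 of 56 genes down-regulated pre-treatment vs control
30 of 56 genes up-regulated post- vs pre-treatment
```

Each stage is also available as its own subcommand (`simulate`, `variants`,
`de`, `signature`, `score`, `classify`, `survival`) reading and writing
plain TSV/CSV/GMT/JSON, with every output carrying a header comment
recording the package version, seed and config hash, and `run-all` writing
a reproducible run manifest. The same functionality is importable from
`azasig` as a library.

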