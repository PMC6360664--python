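# stemsig

Tools for deriving cancer stem-cell expression signatures from
marker-sorted cell-line experiments and for evaluating those signatures in
bulk tumor cohorts — where tumor purity and stromal content confound what a
"stemness score" means for patient survival.

The package is aimed at computational biologists who work with a design
like: a cell-surface stem-cell marker (e.g. CD133/PROM1) is used to sort
several cell lines into marker-positive and marker-negative fractions, each
fraction is expression-profiled, and the resulting up/down gene signature is
then scored across tumor cohorts with clinical annotation and survival
follow-up.

## What it computes

**Signature derivation.** For each gene the signal-to-noise ratio between
the sorted fractions,

    SNR(g) = (μ⁺ − μ⁻) / (σ⁺ + σ⁻),

with sample standard deviations floored at `max(0.2·|μ|, 1e-8)` (the
convention of the desktop GSEA tool). A gene joins the *up* signature when
its pooled SNR exceeds a threshold (default 1.0) **and** its mean difference
is positive within every cell line; the *down* signature is symmetric at
−1.0. A reduced "core" signature keeps genes recurring in at least
`min_count` of several stemness-related gene lists.

**Per-sample scoring (ssGSEA).** Each sample's genes are ranked by
expression; the enrichment score is the summed difference between the
rank-weighted (`rank^α`, α = 0.25) in-set cumulative distribution and the
unweighted out-of-set one. Scores depend only on within-sample ranks.

**Enrichment map.** One-sided Fisher exact (hypergeometric upper-tail)
tests of a gene list against a GMT collection (default P < 0.01), then the
same test on every pair of enriched sets; pairs overlapping at P < 1e-10
become edges of an exportable (SIF + attribute TSVs) functional network.

**Cohort statistics.** Pairwise signature-score correlation with
hierarchical clustering, score-vs-clinical-feature association tests
(Welch t / ANOVA / Pearson, dispatched by feature type), gene-list overlap
accounting, and kNN leave-one-out label prediction.

**Survival.** Kaplan–Meier curves with log-rank tests for median-split
scores, and multivariate Cox proportional-hazards fits (Efron ties, per-SD
hazard ratios) — in particular the two-covariate stemness + stromal model
that exposes how purity-driven anticorrelation between the two scores can
flip the apparent prognostic direction of a stemness signature between
univariate and adjusted analyses.

**Synthetic data.** Generators for (i) multi-cell-line sorted experiments
with planted up/down genes and (ii) tumor cohorts built as purity-weighted
mixtures of a tumor component (carrying latent stemness activity) and a
stromal component, with proportional-hazards survival times. All ground
truth is returned alongside the data, so every stage above is testable
without external downloads.

## Worked example

```
$ stemsig simulate sorted --seed 3 --n-genes 2000 --out sim
wrote 2000 genes x 12 samples to sim
$ stemsig derive --expr sim/expression.tsv --annotations sim/annotations.tsv \
      --name CD133 --out cd133.gmt
29 up, 29 down -> cd133.gmt
```

The simulated experiment plants 30 up and 30 down genes at a 3-sd effect;
the derivation recovers 29 of each here (one planted gene per direction
fell below the SNR threshold by sampling noise — see `docs/methods.md` for
the expected recovery rate at these settings).

```
$ stemsig simulate cohort --seed 5 --n-samples 300 --out cohort
$ stemsig score --expr cohort/expression.tsv --sets cohort/truth_sets.gmt \
      --out scores.tsv
$ stemsig survival --scores scores.tsv --clinical cohort/clinical.tsv \
      --covariates stemness,stromal --out survival.tsv
$ cat survival.tsv
signature  analysis          statistic  p_value     cutoff
stemness   km_logrank        33.77      6.2e-09     363.69
stromal    km_logrank        135.41     2.7e-31     668.43
stemness   multivariate_cox  0.565      1.2e-06
stromal    multivariate_cox  1.909      2.4e-33
```

Both signature levels split survival strongly (log-rank chi-squares 33.8
and 135.4), and the adjusted Cox model attributes a positive per-SD
log-hazard to each (0.57 and 1.91) — the generating model's construction,
recovered end to end from expression.

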