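# plasmarna

Differential-expression screening and nested cross-validated classification of
circulating small non-coding RNA (ncRNA) counts, built around the design of a
first-trimester preeclampsia (PE) case-control study: 35 women who later
developed early-onset PE versus 40 uncomplicated pregnancies, profiled by
plasma small-RNA sequencing in two processing batches, with a paired
second-trimester subset of 20 + 20 women.

It is aimed at computational biologists who want a transparent, fully seeded
re-implementation of this analysis style — abundance filtering, negative
binomial Wald screening with batch correction, empirical-Bayes batch
adjustment, exhaustive best-subset logistic models ranked by AIC inside a
nested cross-validation — together with a synthetic-cohort generator that
makes every stage testable without access to patient data.

## The model

Counts K_ij for transcript *i* in sample *j* are modeled as negative binomial,

    K_ij ~ NB(mu_ij, alpha_i),    Var = mu + alpha mu^2,
    log mu_ij = log s_j + beta_0i + beta_batch,i x_batch(j) + beta_i 1[PE_j]

with median-of-ratios size factors s_j, per-transcript method-of-moments
dispersions alpha_i, and a Wald test on the condition coefficient
(FC = exp(beta_i), FC > 1 means higher in PE).  P-values are adjusted by the
Benjamini–Hochberg step-up over an explicit family size m.  A likelihood-ratio
test of `~ condition + trimester + condition:trimester` against the reduced
model probes PE-specific change across trimesters.

Classification follows a repeated nested cross-validation: each of 100 outer
iterations draws a stratified train/blind-test split; a 5-fold inner CV on the
training set performs, per fold, in-fold feature selection (top-100 abundance
→ DE screen at FDR 0.05 → collapsing of transcripts with |Pearson r| > 0.7),
a frozen ComBat-style batch adjustment, and an exhaustive AIC-ranked logistic
search over models of at most six transcripts; the fold nominee with the
lowest held-out error is refit on the whole training set and scored on the
blind test (AUC, accuracy, sensitivity, specificity, MCC, F1, likelihood
ratios, sensitivity at fixed false positive rates).  Permutation runs repeat
the whole procedure on shuffled condition labels.

## Worked example

```bash
plasmarna simulate --seed 3 --plant-signature --out-prefix demo
plasmarna de demo_counts.tsv demo_samples.tsv --out de.tsv
# -> 25 significant (q<0.05): 15 up, 10 down
plasmarna classify demo_counts.tsv demo_samples.tsv \
    --iterations 2 --max-model-size 2 --seed 4 --out report.json
# -> mean AUC 0.946 (SE 0.054)
plasmarna permute demo_counts.tsv demo_samples.tsv --iterations 2 \
    --max-model-size 2 --n-permutations 2 --inner-iterations 1 --seed 4 --out perm.json
# -> null mean AUC 0.518 (SD 0.152)
plasmarna clinical-stats demo_samples.tsv --out clinical.tsv
```

`simulate --plant-signature` draws a synthetic 35 vs 40 cohort whose first 25
foreground transcripts carry the published signature fold changes.  The `de`
step recovers essentially that signature (25 transcripts at q < 0.05, here 15
up- and 10 down-regulated — sampling noise around the planted 16/9 split).
The `classify` report shows that a two-transcript logistic model separates
blind-test samples almost perfectly on this strongly planted cohort, while
`permute` confirms the same pipeline collapses to chance (AUC ≈ 0.5) once the
labels are shuffled.  The same computations are available as library calls
(`plasmarna.simulate_dataset`, `nb_wald_test`, `run_classification`,
`run_permutation`, ...).

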