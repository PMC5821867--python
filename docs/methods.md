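# Methods

## Differential-expression screen

Normalization is the classic median-of-ratios: per transcript, the log
geometric mean over samples is the reference; a sample's size factor is the
median of its count/reference ratios over transcripts positive in every
sample.  Inside cross-validation the reference is learned on training samples
only and frozen, so held-out samples can be normalized without touching them
during selection.

The screen fits, per transcript, an NB2 GLM (log link) with intercept, batch
dummies and a PE indicator, with log size factors as offsets.  Dispersions
are per-transcript method of moments on normalized counts pooled within
condition groups, alpha = sum n_g (s²_g − m_g) / sum n_g m²_g, floored at
1e-8.  The GLM is solved by iteratively reweighted least squares, vectorized
across transcripts (they share the design matrix), stopping when the deviance
changes by less than 1e-8 or after 50 iterations; non-converged transcripts
get NA p-values and leave the FDR family.  Standard errors come from the
expected information; the Wald z is referred to the standard normal.  This is
a deliberately transparent simplification of the reference RNA-seq tools: no
dispersion shrinkage toward a trend, no count-outlier replacement, no
independent filtering.  Its guarantees are therefore calibration properties
(type-I error of the Wald and interaction-LRT tests sits in [0.03, 0.07] at
nominal 0.05 in the test suite) and reproduction of the published
worked-example table, not numeric identity with any external tool.

The Benjamini–Hochberg family size m is an explicit parameter because the
published adjusted column is only reproduced with m = 95 — consistent with 5
of the 100 most abundant transcripts being dropped by the original tool's
filtering before adjustment.  The package verifies this as a worked example:
step-up with m = 95 regenerates all 25 printed adjusted values to three
significant figures.

The trimester analysis fits the full model `~ condition + trimester +
condition:trimester` and the reduced model without the interaction, using the
same method-of-moments dispersions (estimated on the full
condition × trimester grouping) in both fits; the LRT statistic is referred to
chi-square(1).

PCA QC runs on log2(normalized + 1) with transcripts centered.  A sample is
flagged when its PC1–PC2 robust z-norm (per-axis median/MAD scaling) exceeds
3.  This rule is an invented convention — the source analysis removed two
outliers without stating a criterion — and at a cohort of 75 it flags roughly
one sample by chance; it is a triage aid, not a test.  Note that an outlier
that differs only in sequencing depth is *invisible* here by construction,
because median-of-ratios normalization removes pure depth: the QC flags
composition changes, not depth changes.  The batch-association score is the
between-batch variance fraction (eta squared) of PC1.

## Batch adjustment

The ComBat-style model standardizes each transcript by its grand mean and
pooled residual variance, estimates naive per-batch locations/scales on the
standardized data, fits a normal prior (locations) and an inverse-gamma prior
(scales) across transcripts by moment matching, and iterates the standard EB
fixed point to tolerance 1e-6.  Two deliberate choices:

- **Batch-only design by default.**  Condition is not protected during
  standardization, so the fitted model is a label-free transform that can be
  applied to blind-test samples with no leakage.  This diverges from common
  usage where condition is protected; passing `condition=` to `combat_fit`
  restores the classic joint mode (usable only outside frozen train/apply
  settings).
- **Parametric priors only**; a single-batch fit degenerates to the identity
  transform, and a single-transcript fit keeps the naive estimates (the
  priors have nothing to borrow from).

Properties verified in the suite: planted batch shifts are removed (≥90% of
the batch-mean gap, per transcript, for genuine heterogeneous effects),
applying a train-fitted model to held-out samples shrinks their batch gap,
and at large per-batch n the transform converges to plain per-batch
location/scale standardization.  Exact idempotence is *not* a property of the
EB estimator: shrinkage deliberately retains part of each transcript's
sampling deviation (about half of it when batch effects are null), so
re-adjusting already-adjusted data moves entries by a small amount of order
1/sqrt(n_batch) standard deviations; the suite bounds this rather than
asserting identity.

## Feature selection and model search

Per selection set: top-k (default 100) transcripts by mean normalized count
(ties by id), NB Wald screen, BH at FDR 0.05; if nothing passes, the five
lowest-q transcripts are used and flagged.  Survivors are collapsed on
log2-normalized expression: features joined when |Pearson r| > 0.7, connected
components form groups, the highest-mean member represents each group.
Absolute correlation is used (anti-correlated duplicates carry the same
information); `signed_correlation` restores the literal one-sided reading.

Model features are z-scored, batch-adjusted log2-normalized values; the
standardization and the batch model are learned on the selecting data only
and stored with the model.  The exhaustive search fits every non-empty subset
up to `max_model_size` (default 6) plus the intercept-only baseline by
Newton/IRLS (deviance tolerance 1e-8, 50 iterations, |beta| > 15 flags
separation, a 1e-10 ridge keeps separated fits solvable) and ranks by
AIC = −2 loglik + 2(|subset| + 1); ties break toward smaller subsets, then
lexicographic ids.  When the subset count would exceed
`exhaustive_model_budget`, candidates are truncated to the best by DE q-value
first — a deterministic, testable stand-in for heuristic search alternatives.

## Cross-validation engine

Outer splits are stratified by condition (test fraction 0.2 by default — the
source describes random partitions without stating a proportion, so the value
is exposed in config and echoed in every report) and fully determined by
(seed, iteration).  Inner 5-fold assignment deals samples round-robin,
continuing the cycle across classes, so fold sizes differ by at most one
globally and per class.  Per fold, the nominee is the best-AIC model of that
fold's search; nominees are compared by held-out-fold misclassification at
threshold 0.5; the minimum wins, with ties resolved by lower AIC, smaller
subset, lexicographic ids (the tie-break trail is recorded).  The winner is
refit on the full training set and scored on the blind test.  Metric means
are arithmetic means over iterations; SEs are SD/sqrt(N).  Sensitivity at
fixed FPR levels uses a separate stratified 5-fold CV over all samples with
pooled out-of-fold probabilities and the conservative step-function ROC
convention (max TPR among operating points with FPR ≤ level).

Because outer splits are label-stratified, flipping a test sample's label
changes the partition itself; the leakage guarantee is therefore stated
per fixed partition: within a plan, test-sample counts and labels never
influence feature selection or the selected model (verified end to end).

Permutation validation shuffles the condition labels once per permutation
(class counts preserved) and reruns the whole procedure with a reduced outer
iteration count.  A single shuffle retains chance correlations with the
transcriptome — its mean AUC scatters around 0.5 with SD ≈ 0.07 at this
cohort size — so null summaries should always average several permutations,
as the permutation report does.

## Synthetic cohorts

The generator emulates the study design: 35 PE / 40 control first-trimester
samples, 100 foreground transcripts with baselines log-uniform on
[100, 30 000] normalized counts (the published table's scale) plus 150
low-abundance background transcripts, log-normal library sizes (log-SD 0.25),
two processing batches with per-transcript log-normal batch factors (log-SD
0.2), NB dispersion 0.2, optional planted fold changes (the 25 published
values are available via `signature_fold_changes`), and a paired 20 + 20
second-trimester subset redrawn from the same per-woman latent means with
configurable trimester/interaction multipliers.

Counts are drawn as an explicit Gamma–Poisson mixture: the Gamma component
(mean mu, CV² = alpha) is the woman's realized biological expression and the
Poisson layer is sequencing sampling given library size and batch factor —
marginally exact NB, and the simulated qPCR measures the same Gamma draw, so
sequencing/qPCR concordance arises mechanistically.  qPCR reports
Ct = c0 − log2(expression × input) plus Normal noise (SD 0.25 cycles, a
realistic probe-assay repeatability) with cDNA concentration proportional to
input; 2^−Ct normalized by cDNA then tracks normalized counts.

Clinical covariates are log-normal fits to the published per-group
median/IQR values and empirical category proportions (including structural
zeros such as chronic hypertension among controls).  One designated
transcript's latent log-mean is coupled to MAP and UT PI: the coupling
component is built from the realized cohort z-scores of the features, scaled
so the latent-vs-feature Pearson r equals the target (default 0.4) regardless
of the group structure of the features; tau = 0.8 sets how much log-variance
the coupling adds.  Count-level correlation estimates are attenuated by the
Gamma and Poisson layers, as they would be in real data.

What the generator does **not** emulate: isomiR/read-level structure,
sequencing error, correlated transcript modules beyond the planted
duplicates, longitudinal within-woman correlation (second-trimester draws
are conditionally independent given the latent mean), missing clinical data,
and cohort heterogeneity beyond the printed marginals.  Passing tests
demonstrate the machinery is correct and calibrated under the NB model; they
do not certify performance on real plasma RNA-seq, where dispersion trends,
compositional effects and batch-condition confounding can all be harsher.

## Problem sizes and determinism

The suite and the acceptance script run scaled-down: calibration uses 2,000
null transcripts, pipeline recovery uses 20 outer iterations with models of
at most three transcripts on ten planted signature-scale fold changes, and
the permutation null averages 10 shuffles × 2 iterations — sizes chosen so a
laptop reproduces everything in minutes while keeping Monte-Carlo bands
meaningful.  Every random quantity derives from an explicit integer seed;
reports are byte-identical across reruns with the same config.
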