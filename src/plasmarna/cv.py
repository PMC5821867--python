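"""Repeated random-partition evaluation of the small-ncRNA classifier.

Each outer iteration draws a stratified train/blind-test split, runs a 5-fold
inner cross-validation on the training set — every fold performs its own
feature selection (abundance, DE screen, correlation collapse), a frozen
batch adjustment, and an exhaustive AIC-ranked logistic model search — picks
the fold nominee with the lowest held-out error, refits it on the full
training set and scores the blind test set.  Permutation runs repeat the
whole procedure on shuffled condition labels to obtain the chance
distribution of every metric.
"""

from __future__ import annotations

import dataclasses as _dc
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import de as _de
from .batch import BatchModel, combat_apply, combat_fit
from .io import AnalysisConfig, CountMatrix, SampleTable
from .metrics import MetricSet, confusion_metrics, roc_auc, sensitivity_at_fpr as _sens_at
from .model_select import (FeatureSet, LogisticModel, exhaustive_search,
                           fit_logistic, predict_prob, select_features)

log = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "mcc", "f1",
                "lr_pos", "lr_neg", "auc")


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    iteration: int
    train_ids: list[str]
    test_ids: list[str]
    folds: list[list[str]]
    seed: int

    def to_dict(self) -> dict:
        return {"iteration": self.iteration, "train_ids": self.train_ids,
                "test_ids": self.test_ids, "folds": self.folds, "seed": self.seed}


def make_split_plan(
    metadata: SampleTable, config: AnalysisConfig, iteration: int,
    seed: int | None = None,
) -> SplitPlan:
    """Stratified outer split plus stratified inner-fold assignment, fully
    determined by (seed, iteration).  Fold sizes differ by at most one."""
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng([seed, iteration])
    df = metadata.frame
    train_ids: list[str] = []
    test_ids: list[str] = []
    per_class_train: list[list[str]] = []
    for cond in ("PE", "control"):
        ids = sorted(df.loc[df["condition"] == cond, "sample_id"])
        if not ids:
            raise ValueError(f"no samples with condition {cond!r}")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n_test = max(1, int(round(config.test_fraction * len(ids))))
        test_ids += ids[:n_test]
        cls_train = ids[n_test:]
        if len(cls_train) < config.inner_folds:
            raise ValueError(
                f"class {cond!r} has {len(cls_train)} training samples, fewer "
                f"than {config.inner_folds} inner folds"
            )
        train_ids += cls_train
        per_class_train.append(cls_train)

    folds: list[list[str]] = [[] for _ in range(config.inner_folds)]
    pos = 0
    for cls_train in per_class_train:   # continue the round-robin across classes
        for sid in cls_train:
            folds[pos % config.inner_folds].append(sid)
            pos += 1
    return SplitPlan(iteration, train_ids, test_ids, folds, seed)


# ---------------------------------------------------------------------------
# Frozen feature transform (normalization + batch adjustment)
# ---------------------------------------------------------------------------

@dataclass
class FeatureTransform:
    """Train-fitted transform: size-factor reference, batch model, transcripts."""

    transcript_ids: list[str]
    reference_log_geomeans: np.ndarray     # over the training count matrix's rows
    all_transcript_ids: list[str]
    batch_model: BatchModel


def fit_feature_transform(
    train_cm: CountMatrix, train_meta: SampleTable, transcript_ids: Sequence[str]
) -> FeatureTransform:
    reference = _de.log_geometric_means(train_cm.counts)
    s = _de.size_factors(train_cm, reference=reference)
    sub = train_cm.select_transcripts(transcript_ids)
    logx = _de.log2_normalized(sub, s)
    bm = combat_fit(logx, train_meta.select(train_cm.sample_ids).batch)
    return FeatureTransform(list(transcript_ids), reference,
                            list(train_cm.transcript_ids), bm)


def apply_feature_transform(
    ft: FeatureTransform, cm: CountMatrix, meta: SampleTable
) -> pd.DataFrame:
    """Samples x transcripts adjusted log expression for arbitrary samples,
    using only train-fitted parameters."""
    cm = cm.select_transcripts(ft.all_transcript_ids)
    s = _de.size_factors(cm, reference=ft.reference_log_geomeans)
    sub = cm.select_transcripts(ft.transcript_ids)
    logx = _de.log2_normalized(sub, s)
    adj = combat_apply(ft.batch_model, logx, meta.select(cm.sample_ids).batch)
    return pd.DataFrame(adj.T, index=cm.sample_ids, columns=ft.transcript_ids)


# ---------------------------------------------------------------------------
# Inner cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldOutcome:
    fold_index: int
    feature_set: FeatureSet
    model: LogisticModel
    heldout_error: float
    n_heldout: int


@dataclass
class InnerCVRecord:
    folds: list[FoldOutcome]
    selected_index: int
    tie_break: list[str] = field(default_factory=list)

    @property
    def selected(self) -> FoldOutcome:
        return self.folds[self.selected_index]


def run_inner_cv(
    train_cm: CountMatrix, train_meta: SampleTable, plan: SplitPlan,
    config: AnalysisConfig,
) -> InnerCVRecord:
    """Per fold: feature selection and exhaustive AIC search on the other
    folds, misclassification error on the held-out fold; the fold nominee with
    the lowest held-out error wins (ties: lower AIC, then smaller subset, then
    lexicographic feature ids)."""
    outcomes: list[FoldOutcome] = []
    for f, heldout in enumerate(plan.folds):
        sel_ids = [sid for g, fold in enumerate(plan.folds) if g != f for sid in fold]
        sel_cm = train_cm.select_samples(sel_ids)
        sel_meta = train_meta.select(sel_ids)
        fs = select_features(sel_cm, sel_meta, config)
        transform = fit_feature_transform(sel_cm, sel_meta, fs.candidates)
        X_sel = apply_feature_transform(transform, sel_cm, sel_meta)
        y_sel = sel_meta.is_pe()
        models = exhaustive_search(fs, X_sel, y_sel, config.max_model_size,
                                   budget=config.exhaustive_model_budget)
        best = models[0]
        ho_cm = train_cm.select_samples(heldout)
        ho_meta = train_meta.select(heldout)
        X_ho = apply_feature_transform(transform, ho_cm, ho_meta)
        probs = predict_prob(best, X_ho.loc[:, list(best.feature_ids)]
                             if best.feature_ids else X_ho.iloc[:, :0])
        pred = (probs >= config.classification_threshold).astype(int)
        err = float((pred != ho_meta.is_pe()).mean())
        outcomes.append(FoldOutcome(f, fs, best, err, len(heldout)))

    trail: list[str] = []
    pool = list(range(len(outcomes)))
    best_err = min(outcomes[i].heldout_error for i in pool)
    pool = [i for i in pool if outcomes[i].heldout_error == best_err]
    trail.append(f"error={best_err:.4f}:{len(pool)} fold(s)")
    if len(pool) > 1:
        best_aic = min(outcomes[i].model.aic for i in pool)
        pool = [i for i in pool if outcomes[i].model.aic == best_aic]
        trail.append(f"aic={best_aic:.4f}:{len(pool)} fold(s)")
    if len(pool) > 1:
        best_size = min(len(outcomes[i].model.feature_ids) for i in pool)
        pool = [i for i in pool if len(outcomes[i].model.feature_ids) == best_size]
        trail.append(f"size={best_size}:{len(pool)} fold(s)")
    if len(pool) > 1:
        pool.sort(key=lambda i: outcomes[i].model.feature_ids)
        trail.append("lexicographic")
    return InnerCVRecord(outcomes, pool[0], trail)


# ---------------------------------------------------------------------------
# Outer loop
# ---------------------------------------------------------------------------

@dataclass
class IterationResult:
    plan: SplitPlan
    selected_model: LogisticModel
    inner_tie_break: list[str]
    test_probs: np.ndarray
    test_labels: np.ndarray
    metrics: MetricSet

    def to_dict(self) -> dict:
        return {
            "plan": self.plan.to_dict(),
            "selected_model": self.selected_model.to_dict(),
            "inner_tie_break": self.inner_tie_break,
            "test_probs": list(map(float, self.test_probs)),
            "test_labels": list(map(int, self.test_labels)),
            "metrics": self.metrics.to_dict(),
        }


@dataclass
class ClassifierReport:
    config: dict
    seed: int
    iterations: list[IterationResult]
    metric_means: dict[str, float]
    metric_ses: dict[str, float]
    sens_at_fpr: dict[str, dict]
    se_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "n_iterations": len(self.iterations),
            "metric_means": self.metric_means,
            "metric_ses": self.metric_ses,
            "sensitivity_at_fpr": self.sens_at_fpr,
            "se_undefined": self.se_undefined,
            "iterations": [it.to_dict() for it in self.iterations],
        }


def _iterate_once(
    cm: CountMatrix, metadata: SampleTable, config: AnalysisConfig, iteration: int,
) -> IterationResult:
    plan = make_split_plan(metadata, config, iteration)
    train_cm = cm.select_samples(plan.train_ids)
    train_meta = metadata.select(plan.train_ids)
    record = run_inner_cv(train_cm, train_meta, plan, config)
    subset = record.selected.model.feature_ids

    y_train = train_meta.is_pe()
    test_cm = cm.select_samples(plan.test_ids)
    test_meta = metadata.select(plan.test_ids)
    if subset:
        transform = fit_feature_transform(train_cm, train_meta, list(subset))
        X_train = apply_feature_transform(transform, train_cm, train_meta)
        final = fit_logistic(X_train.loc[:, list(subset)].to_numpy(), y_train, subset)
        X_test = apply_feature_transform(transform, test_cm, test_meta)
        probs = predict_prob(final, X_test.loc[:, list(subset)])
    else:                                   # degenerate: intercept-only nominee
        final = fit_logistic(np.empty((len(y_train), 0)), y_train, ())
        probs = predict_prob(final, np.empty((len(plan.test_ids), 0)))
    y_test = test_meta.is_pe()
    _, ms = confusion_metrics(y_test, probs, config.classification_threshold)
    try:
        ms.auc = roc_auc(y_test, probs)
    except ValueError:
        ms.auc = float("nan")
    return IterationResult(plan, final, record.tie_break, probs, y_test, ms)


def run_classification(
    cm: CountMatrix, metadata: SampleTable, config: AnalysisConfig,
) -> ClassifierReport:
    """Full repeated-partition evaluation; see the module docstring.

    Metric means are arithmetic means over iterations; SEs are SD/sqrt(N).
    Sensitivity at the configured FPR levels is computed by the all-sample
    5-fold procedure when ``config.fpr_levels`` is non-empty.
    """
    iterations = []
    for i in range(config.n_outer_iterations):
        iterations.append(_iterate_once(cm, metadata, config, i))
        log.info("iteration %d/%d: AUC=%.3f model=%s", i + 1,
                 config.n_outer_iterations, iterations[-1].metrics.auc,
                 list(iterations[-1].selected_model.feature_ids))

    means, ses = {}, {}
    se_undef = len(iterations) < 2
    for name in METRIC_NAMES:
        vals = np.array([getattr(it.metrics, name) for it in iterations], dtype=float)
        finite = vals[np.isfinite(vals)]
        means[name] = float(finite.mean()) if len(finite) else float("nan")
        ses[name] = (float(finite.std(ddof=1) / np.sqrt(len(finite)))
                     if len(finite) > 1 else 0.0)

    sens = {}
    if config.fpr_levels:
        sens = sensitivity_at_fpr_cv(cm, metadata, config, config.fpr_levels)

    return ClassifierReport(config.to_dict(), config.rng_seed, iterations,
                            means, ses, sens, se_undefined=se_undef)


# ---------------------------------------------------------------------------
# Sensitivity at fixed false positive rates (all-sample 5-fold CV)
# ---------------------------------------------------------------------------

def sensitivity_at_fpr_cv(
    cm: CountMatrix, metadata: SampleTable, config: AnalysisConfig,
    levels: Sequence[float], n_iterations: int | None = None,
) -> dict[str, dict]:
    """Per iteration: stratified 5-fold CV over all samples with in-fold
    selection, pooled out-of-fold probabilities, empirical ROC; sensitivity at
    each level is the max TPR among operating points with FPR <= level.
    Returns per-level mean, SE and per-iteration values."""
    for lv in levels:
        if not (0 < lv < 1):
            raise ValueError("FPR levels must be in (0, 1)")
    if n_iterations is None:
        n_iterations = config.n_outer_iterations
    per_level: dict[float, list[float]] = {lv: [] for lv in levels}
    df = metadata.frame
    for it in range(n_iterations):
        rng = np.random.default_rng([config.rng_seed, 104729, it])
        folds: list[list[str]] = [[] for _ in range(config.inner_folds)]
        pos = 0
        for cond in ("PE", "control"):
            ids = sorted(df.loc[df["condition"] == cond, "sample_id"])
            ids = [ids[i] for i in rng.permutation(len(ids))]
            for sid in ids:
                folds[pos % config.inner_folds].append(sid)
                pos += 1
        probs = {}
        for f, heldout in enumerate(folds):
            train_ids = [sid for g, fold in enumerate(folds) if g != f for sid in fold]
            tr_cm = cm.select_samples(train_ids)
            tr_meta = metadata.select(train_ids)
            fs = select_features(tr_cm, tr_meta, config)
            transform = fit_feature_transform(tr_cm, tr_meta, fs.candidates)
            X_tr = apply_feature_transform(transform, tr_cm, tr_meta)
            models = exhaustive_search(fs, X_tr, tr_meta.is_pe(),
                                       config.max_model_size,
                                       budget=config.exhaustive_model_budget)
            best = models[0]
            ho_cm = cm.select_samples(heldout)
            X_ho = apply_feature_transform(transform, ho_cm, metadata.select(heldout))
            p = predict_prob(best, X_ho.loc[:, list(best.feature_ids)]
                             if best.feature_ids else X_ho.iloc[:, :0])
            for sid, pv in zip(heldout, p):
                probs[sid] = pv
        ids = list(probs)
        y = metadata.select(ids).is_pe()
        pv = np.array([probs[s] for s in ids])
        for lv in levels:
            per_level[lv].append(_sens_at(y, pv, lv))

    out = {}
    for lv in levels:
        vals = np.array(per_level[lv])
        out[str(lv)] = {
            "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
            "per_iteration": list(map(float, vals)),
        }
    return out


# ---------------------------------------------------------------------------
# Permutation validation
# ---------------------------------------------------------------------------

@dataclass
class PermutationReport:
    config: dict
    n_permutations: int
    inner_iterations: int
    per_permutation: list[dict[str, float]]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    normality_p: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "n_permutations": self.n_permutations,
            "inner_iterations": self.inner_iterations,
            "per_permutation": self.per_permutation,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "normality_p": self.normality_p,
        }


def permute_labels(metadata: SampleTable, rng: np.random.Generator) -> SampleTable:
    """Shuffle the condition column (class counts preserved)."""
    df = metadata.frame.copy()
    cond = df["condition"].to_numpy()
    df["condition"] = cond[rng.permutation(len(cond))]
    return SampleTable(df)


def run_permutation(
    cm: CountMatrix, metadata: SampleTable, config: AnalysisConfig,
    n_permutations: int | None = None, inner_iterations: int = 10,
) -> PermutationReport:
    """Repeat the whole classification procedure on label-shuffled data.

    Each permutation shuffles the condition labels once and runs the outer
    loop with ``inner_iterations`` random partitions (a reduced count keeps
    the null affordable); the per-permutation metric means form the null
    distribution, summarized by mean, SD and a Shapiro-Wilk normality p."""
    if n_permutations is None:
        n_permutations = config.n_permutations
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    per_perm: list[dict[str, float]] = []
    for p in range(n_permutations):
        rng = np.random.default_rng([config.rng_seed, 15485863, p])
        shuffled = permute_labels(metadata, rng)
        sub_cfg = _dc.replace(config, n_outer_iterations=inner_iterations,
                              fpr_levels=(), rng_seed=int(rng.integers(2 ** 31)))
        rep = run_classification(cm, shuffled, sub_cfg)
        per_perm.append(dict(rep.metric_means))
        log.info("permutation %d/%d: mean AUC=%.3f", p + 1, n_permutations,
                 rep.metric_means["auc"])

    null_mean, null_sd, norm_p = {}, {}, {}
    for name in METRIC_NAMES:
        vals = np.array([d[name] for d in per_perm], dtype=float)
        finite = vals[np.isfinite(vals)]
        null_mean[name] = float(finite.mean()) if len(finite) else float("nan")
        null_sd[name] = float(finite.std(ddof=1)) if len(finite) > 1 else float("nan")
        if len(finite) >= 3 and np.ptp(finite) > 0:
            norm_p[name] = float(_sps.shapiro(finite).pvalue)
        else:
            norm_p[name] = float("nan")
    return PermutationReport(config.to_dict(), n_permutations, inner_iterations,
                             per_perm, null_mean, null_sd, norm_p)
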