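"""In-fold feature selection and exhaustive AIC-ranked logistic best-subset search.

Candidate transcripts are chosen on training data only: abundance filter,
NB Wald differential-expression screen with FDR control, then collapsing of
highly correlated transcripts into single representatives.  Every subset of
the candidates up to a maximum model size is fitted by maximum-likelihood
logistic regression and ranked by AIC.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import de as _de
from .io import AnalysisConfig, CountMatrix, SampleTable

log = logging.getLogger(__name__)

LOGISTIC_TOL = 1e-8
LOGISTIC_MAX_ITER = 50
SEPARATION_BETA = 15.0


# ---------------------------------------------------------------------------
# Correlation collapsing
# ---------------------------------------------------------------------------

def collapse_correlated(
    expr: np.ndarray,
    feature_ids: Sequence[str],
    threshold: float = 0.7,
    signed: bool = False,
) -> dict[str, list[str]]:
    """Group features whose pairwise Pearson correlation exceeds ``threshold``.

    ``expr`` is samples x features.  Features are nodes; edges join pairs with
    |r| > threshold (or r > threshold when ``signed``); connected components
    form groups.  The representative of each group is the member with the
    highest mean expression (ties broken by id).  Zero-variance features get
    their own singleton group (their correlations are treated as 0).

    Returns ``{representative: [members...]}`` with members sorted.
    """
    x = np.asarray(expr, dtype=float)
    ids = list(feature_ids)
    n = len(ids)
    if x.shape[1] != n:
        raise ValueError("one column per feature required")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to correlate")
    if n == 1:
        return {ids[0]: [ids[0]]}
    sd = x.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        log.info("collapse: %d zero-variance feature(s) kept as singletons",
                 int(zero_var.sum()))
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    conn = (r if signed else np.abs(r)) > threshold
    conn[zero_var, :] = False
    conn[:, zero_var] = False

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if conn[i, j]:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    means = x.mean(axis=0)
    out: dict[str, list[str]] = {}
    for members in groups.values():
        rep = min(members, key=lambda i: (-means[i], ids[i]))
        out[ids[rep]] = sorted(ids[i] for i in members)
    return out


# ---------------------------------------------------------------------------
# Feature selection pipeline
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    candidates: list[str]                      # representative transcript ids
    collapse_map: dict[str, list[str]]         # representative -> members
    qvalues: dict[str, float]                  # BH q per candidate (selection data)
    fallback: bool = False                     # DE screen empty, lowest-q fallback used
    provenance: dict = field(default_factory=dict)


def select_features(
    train_counts: CountMatrix,
    train_meta: SampleTable,
    config: AnalysisConfig,
) -> FeatureSet:
    """Training-data-only candidate selection.

    Abundance top-k -> NB Wald + BH (q < ``fdr_alpha``) -> correlation
    collapse on log2-normalized expression.  If no transcript passes the DE
    screen the lowest-q min(5, available) transcripts are used and the
    ``fallback`` flag is set.
    """
    s = _de.size_factors(train_counts)
    k = min(config.abundance_top_k, train_counts.n_transcripts)
    top_ids = _de.top_abundant(train_counts, k, s)
    sub = train_counts.select_transcripts(top_ids)
    results = _de.nb_wald_test(sub, train_meta, s=s)
    tested = [r for r in results if np.isfinite(r.adjusted_p_value)]
    hits = [r for r in tested if r.adjusted_p_value < config.fdr_alpha]
    fallback = False
    if not hits:
        fallback = True
        tested.sort(key=lambda r: (r.adjusted_p_value, r.transcript_id))
        hits = tested[: min(5, len(tested))]
        log.info("select_features: DE screen empty, falling back to %d lowest-q "
                 "transcripts", len(hits))
    if not hits:
        raise ValueError("no testable transcripts for feature selection")

    hit_ids = [r.transcript_id for r in hits]
    expr = _de.log2_normalized(sub.select_transcripts(hit_ids), s).T  # samples x feats
    collapse = collapse_correlated(
        expr, hit_ids, threshold=config.correlation_threshold,
        signed=config.signed_correlation,
    )
    qmap = {r.transcript_id: r.adjusted_p_value for r in hits}
    candidates = sorted(collapse, key=lambda t: (qmap[t], t))
    return FeatureSet(
        candidates=candidates,
        collapse_map=collapse,
        qvalues={t: qmap[t] for t in candidates},
        fallback=fallback,
        provenance={"n_tested": len(tested), "n_de": 0 if fallback else len(hits)},
    )


# ---------------------------------------------------------------------------
# Logistic regression (Newton/IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """An ML-fitted logistic model on a transcript subset.

    Coefficients are on the standardized-feature scale; the training
    per-feature means/SDs are stored so the model can be applied to new data.
    AIC = -2 loglik + 2 (|subset| + 1).
    """

    feature_ids: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    loglik: float
    aic: float
    converged: bool
    separation: bool
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "intercept": self.intercept,
            "coef": list(map(float, self.coef)),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "separation": self.separation,
            "feature_means": list(map(float, self.feature_means)),
            "feature_sds": list(map(float, self.feature_sds)),
        }


def fit_logistic(
    X: np.ndarray, y: np.ndarray, feature_ids: Sequence[str] = ()
) -> LogisticModel:
    """Maximum-likelihood logistic fit by Newton/IRLS.

    ``X`` is samples x features (possibly zero columns for the intercept-only
    baseline); features are z-scored internally and the standardization is
    stored on the model.  Stops when the deviance changes by < 1e-8 or after
    50 iterations; complete separation is flagged when any |beta| > 15 (the
    model is kept).
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = np.asarray(X, dtype=float).reshape(len(y), -1)
    k = X.shape[1]
    feature_ids = tuple(feature_ids) if feature_ids else tuple(f"x{i}" for i in range(k))
    if len(feature_ids) != k:
        raise ValueError("one feature id per column required")

    means = X.mean(axis=0) if k else np.array([])
    sds = X.std(axis=0, ddof=0) if k else np.array([])
    sds = np.where(sds == 0, 1.0, sds)
    Z = np.column_stack([np.ones(len(y))] + ([(X - means) / sds] if k else []))

    beta = np.zeros(k + 1)
    dev = np.inf
    converged = False
    for _ in range(LOGISTIC_MAX_ITER):
        eta = np.clip(Z @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        z_work = eta + (y - p) / w
        A = Z.T @ (w[:, None] * Z) + 1e-10 * np.eye(k + 1)
        beta = np.linalg.solve(A, Z.T @ (w * z_work))
        ll = _bernoulli_loglik(y, np.clip(Z @ beta, -30, 30))
        new_dev = -2.0 * ll
        if abs(new_dev - dev) < LOGISTIC_TOL:
            converged = True
            dev = new_dev
            break
        dev = new_dev

    ll = -dev / 2.0
    return LogisticModel(
        feature_ids=feature_ids,
        intercept=float(beta[0]),
        coef=beta[1:].copy(),
        loglik=float(ll),
        aic=float(-2 * ll + 2 * (k + 1)),
        converged=converged,
        separation=bool(np.abs(beta).max() > SEPARATION_BETA),
        feature_means=np.asarray(means, dtype=float),
        feature_sds=np.asarray(sds, dtype=float),
    )


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def predict_prob(model: LogisticModel, X_new) -> np.ndarray:
    """Predicted PE probability per sample.

    ``X_new`` is a DataFrame containing the model's feature columns (or an
    array in the model's feature order).  Features are standardized with the
    training means/SDs stored on the model.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in model.feature_ids if f not in X_new.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        X = X_new.loc[:, list(model.feature_ids)].to_numpy(dtype=float)
    else:
        X = np.asarray(X_new, dtype=float)
        if X.ndim != 2:
            X = X.reshape(-1, max(len(model.feature_ids), 1))
    if len(model.feature_ids):
        Xz = (X - model.feature_means) / model.feature_sds
        eta = model.intercept + Xz @ model.coef
    else:
        eta = np.full(X.shape[0], model.intercept)
    eta = np.clip(eta, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# Exhaustive best-subset search
# ---------------------------------------------------------------------------

def _n_subsets(n: int, max_size: int) -> int:
    return sum(math.comb(n, k) for k in range(1, min(n, max_size) + 1))


def exhaustive_search(
    candidates: Sequence[str] | FeatureSet,
    X: pd.DataFrame,
    y: np.ndarray,
    max_size: int,
    budget: int | None = None,
    qvalues: Mapping[str, float] | None = None,
) -> list[LogisticModel]:
    """Fit every non-empty candidate subset of size <= ``max_size`` (plus the
    intercept-only baseline) and rank by AIC.

    Ties break toward smaller subsets, then lexicographic feature ids.  When
    the subset count exceeds ``budget``, candidates are first truncated to the
    best by DE q-value (then id) so the budget holds.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if isinstance(candidates, FeatureSet):
        if qvalues is None:
            qvalues = candidates.qvalues
        candidates = candidates.candidates
    cand = list(candidates)
    if not cand:
        raise ValueError("at least one candidate feature required")
    if budget is not None and _n_subsets(len(cand), max_size) > budget:
        key = (lambda t: (qvalues.get(t, np.inf), t)) if qvalues else (lambda t: t)
        ranked = sorted(cand, key=key)
        n_keep = len(ranked)
        while n_keep > 1 and _n_subsets(n_keep, max_size) > budget:
            n_keep -= 1
        log.info("exhaustive_search: truncating %d candidates to %d to honor "
                 "model budget %d", len(cand), n_keep, budget)
        cand = sorted(ranked[:n_keep])

    y = np.asarray(y, dtype=float)
    models = [fit_logistic(np.empty((len(y), 0)), y, ())]   # baseline
    for size in range(1, min(len(cand), max_size) + 1):
        for subset in itertools.combinations(sorted(cand), size):
            Xs = X.loc[:, list(subset)].to_numpy(dtype=float)
            models.append(fit_logistic(Xs, y, subset))
    models.sort(key=lambda m: (m.aic, len(m.feature_ids), m.feature_ids))
    return models
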