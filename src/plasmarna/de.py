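"""Normalization, QC and differential-expression screening of plasma small-ncRNA counts.

The screen models counts with a negative-binomial GLM (log link, per-sample
size-factor offsets, batch covariate) and tests the condition coefficient with
a Wald test; a likelihood-ratio test against a reduced model probes
condition x trimester interactions in the paired second-trimester subset.
This is a deliberately transparent re-implementation of the standard
RNA-seq workflow: dispersions are method-of-moments per transcript (no
shrinkage toward a trend, no count-outlier handling), so its guarantees are
calibration properties rather than numeric identity with any reference tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import CountMatrix, SampleTable

DISPERSION_FLOOR = 1e-8
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def log_geometric_means(counts: np.ndarray) -> np.ndarray:
    """Per-transcript log geometric mean; -inf where any count is zero."""
    k = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    return np.where((k > 0).all(axis=1), logk.mean(axis=1), -np.inf)


def size_factors(
    counts: CountMatrix | np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Median-of-ratios size factors.

    ``reference`` — per-transcript log geometric means learned on other data
    (for example the training split of a cross-validation cycle); defaults to
    the geometric means of ``counts`` itself.  Only transcripts with a finite
    reference (positive in every sample used to build it) enter the median.
    """
    k = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    k = k.astype(float)
    if reference is None:
        reference = log_geometric_means(k)
    usable = np.isfinite(reference)
    if not usable.any():
        raise ValueError(
            "no transcript has positive counts in every sample; "
            "filter to higher-abundance transcripts before normalizing"
        )
    ratios = k[usable, :] / np.exp(reference[usable])[:, None]
    s = np.median(ratios, axis=0)
    if not (np.isfinite(s).all() and (s > 0).all()):
        raise ValueError("degenerate size factor; filter low-count samples")
    return s


def normalized_counts(cm: CountMatrix, s: np.ndarray | None = None) -> np.ndarray:
    if s is None:
        s = size_factors(cm)
    return cm.counts / s[None, :]


def log2_normalized(cm: CountMatrix, s: np.ndarray | None = None) -> np.ndarray:
    """log2(normalized count + 1), the expression scale used by batch
    adjustment and the classifier."""
    return np.log2(normalized_counts(cm, s) + 1.0)


def top_abundant(
    cm: CountMatrix, k: int, s: np.ndarray | None = None
) -> list[str]:
    """Ids of the ``k`` transcripts with highest mean normalized count.

    Ties broken deterministically by transcript id (ascending).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > cm.n_transcripts:
        raise ValueError(f"k={k} exceeds {cm.n_transcripts} transcripts")
    means = normalized_counts(cm, s).mean(axis=1)
    order = sorted(range(cm.n_transcripts), key=lambda i: (-means[i], cm.transcript_ids[i]))
    return [cm.transcript_ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# PCA QC
# ---------------------------------------------------------------------------

@dataclass
class PCAQCResult:
    table: pd.DataFrame          # sample_id, pc1, pc2, outlier
    batch_association: float     # between-batch variance fraction of PC1
    explained_variance_ratio: tuple[float, float]


def pca_qc(cm: CountMatrix, metadata: SampleTable) -> PCAQCResult:
    """PC1/PC2 of log2-normalized expression with robust outlier flags.

    A sample is flagged when its PC1-PC2 distance from the coordinate-wise
    median exceeds 3 robust SDs (each axis scaled by 1.4826 x MAD).  The batch
    association score is the between-batch variance fraction (eta squared) of
    PC1 — near 0 when batches overlap, near 1 when PC1 is the batch axis.
    """
    if cm.n_samples < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    x = log2_normalized(cm)
    xc = x - x.mean(axis=1, keepdims=True)          # center each transcript
    u, sv, _ = np.linalg.svd(xc.T, full_matrices=False)
    pcs = u[:, :2] * sv[:2]
    total = (sv ** 2).sum()
    evr = (float(sv[0] ** 2 / total), float(sv[1] ** 2 / total)) if total > 0 else (0.0, 0.0)

    med = np.median(pcs, axis=0)
    mad = np.median(np.abs(pcs - med), axis=0)
    scale = 1.4826 * mad
    scale[scale == 0] = np.finfo(float).eps
    rz = (pcs - med) / scale
    outlier = np.sqrt((rz ** 2).sum(axis=1)) > 3.0

    pc1 = pcs[:, 0]
    batches = metadata.select(cm.sample_ids).batch
    grand = pc1.mean()
    ss_between = sum(
        (pc1[batches == b].mean() - grand) ** 2 * (batches == b).sum()
        for b in np.unique(batches)
    )
    ss_total = ((pc1 - grand) ** 2).sum()
    assoc = float(ss_between / ss_total) if ss_total > 0 else 0.0

    table = pd.DataFrame(
        {"sample_id": cm.sample_ids, "pc1": pcs[:, 0], "pc2": pcs[:, 1], "outlier": outlier}
    )
    return PCAQCResult(table, assoc, evr)


# ---------------------------------------------------------------------------
# Negative-binomial GLM (log link, IRLS), vectorized across transcripts
# ---------------------------------------------------------------------------

def moment_dispersions(
    norm: np.ndarray, groups: np.ndarray, floor: float = DISPERSION_FLOOR
) -> np.ndarray:
    """Per-transcript NB dispersion (Var = mu + alpha mu^2) by method of
    moments on normalized counts, pooled across the given groups."""
    norm = np.asarray(norm, dtype=float)
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        n = sub.shape[1]
        if n < 2:
            continue
        mu = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += n * (v - mu)
        den += n * mu ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, floor)


@dataclass
class NBGLMFit:
    beta: np.ndarray         # (T, p)
    cov: np.ndarray          # (T, p, p)
    deviance: np.ndarray     # (T,)
    loglik: np.ndarray       # (T,)
    converged: np.ndarray    # (T,) bool


def nb_glm_fit(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray
) -> NBGLMFit:
    """Fit an NB2 log-link GLM per transcript by IRLS (shared design matrix).

    ``y`` is transcripts x samples, ``X`` samples x p, ``offset`` the log size
    factors, ``alpha`` the per-transcript dispersion.  Stops when the deviance
    changes by less than 1e-8 or after 50 iterations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    T, S = y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (T,))

    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    dev = _nb_deviance(y, mu, alpha)
    beta = np.zeros((T, p))
    active = np.ones(T, dtype=bool)
    converged = np.zeros(T, dtype=bool)

    for _ in range(IRLS_MAX_ITER):
        if not active.any():
            break
        a = alpha[active, None]
        mu_a = mu[active]
        w = mu_a / (1.0 + a * mu_a)                       # IRLS weights, log link
        z = (eta[active] - offset[None, :]) + (y[active] - mu_a) / mu_a
        xtwx = np.einsum("sp,ts,sq->tpq", X, w, X)
        xtwz = np.einsum("sp,ts,ts->tp", X, w, z)
        # tiny ridge keeps near-separated fits solvable
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        eta_new = np.clip(beta_new @ X.T + offset[None, :], -30.0, 30.0)
        mu_new = np.exp(eta_new)
        dev_new = _nb_deviance(y[active], mu_new, alpha[active])

        beta[active] = beta_new
        eta[active] = eta_new
        mu[active] = mu_new
        done = np.abs(dev_new - dev[active]) < IRLS_TOL
        dev[active] = dev_new
        idx = np.where(active)[0]
        converged[idx[done]] = True
        active[idx[done]] = False

    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("sp,ts,sq->tpq", X, w, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(xtwx)
    llf = _nb_loglik(y, mu, alpha)
    return NBGLMFit(beta, cov, dev, llf, converged)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    a = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    term2 = (y + 1.0 / a) * (np.log1p(a * y) - np.log1p(a * mu))
    return 2.0 * (term1 - term2).sum(axis=1)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    a = alpha[:, None]
    inv = 1.0 / a
    ll = (
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1.0)
        + y * (np.log(a) + np.log(mu) - np.log1p(a * mu))
        - inv * np.log1p(a * mu)
    )
    return ll.sum(axis=1)


def _design(metadata: SampleTable, include_batch: bool = True) -> tuple[np.ndarray, int]:
    """Intercept + batch dummies (first level dropped) + condition indicator.

    Returns the design matrix and the column index of the condition term.
    """
    cond = metadata.is_pe().astype(float)
    if len(np.unique(cond)) < 2:
        raise ValueError("condition must have both PE and control samples")
    cols = [np.ones(len(cond))]
    if include_batch:
        levels = sorted(set(metadata.batch))
        for b in levels[1:]:
            cols.append((metadata.batch == b).astype(float))
    cols.append(cond)
    X = np.column_stack(cols)
    return X, X.shape[1] - 1


# ---------------------------------------------------------------------------
# Wald test and BH adjustment
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    transcript_id: str
    biotype: str
    mean_counts: float       # mean normalized count
    fold_change: float       # PE / control, linear scale
    log2_fold_change: float
    wald_stat: float
    p_value: float           # NaN when the fit did not converge
    adjusted_p_value: float
    dispersion: float


def nb_wald_test(
    cm: CountMatrix,
    metadata: SampleTable,
    s: np.ndarray | None = None,
    include_batch: bool = True,
    bh_family_size: int | None = None,
) -> list[DEResult]:
    """Per-transcript NB Wald test of PE vs control, batch in the design.

    FC > 1 means higher in PE.  Transcripts whose IRLS fit does not converge
    get NaN p-values and are excluded from the BH family.
    """
    meta = metadata.select(cm.sample_ids)
    if s is None:
        s = size_factors(cm)
    X, cond_col = _design(meta, include_batch=include_batch)
    norm = cm.counts / s[None, :]
    alpha = moment_dispersions(norm, meta.condition)
    fit = nb_glm_fit(cm.counts, X, np.log(s), alpha)

    beta_c = fit.beta[:, cond_col]
    se = np.sqrt(fit.cov[:, cond_col, cond_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta_c / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(fit.converged, pvals, np.nan)

    finite = np.isfinite(pvals)
    m = bh_family_size if bh_family_size is not None else int(finite.sum())
    qvals = np.full_like(pvals, np.nan)
    if finite.any():
        qvals[finite] = bh_adjust(pvals[finite], m=m)

    mean_norm = norm.mean(axis=1)
    out = []
    for i, tid in enumerate(cm.transcript_ids):
        out.append(
            DEResult(
                transcript_id=tid,
                biotype=cm.biotypes[i],
                mean_counts=float(mean_norm[i]),
                fold_change=float(np.exp(beta_c[i])),
                log2_fold_change=float(beta_c[i] / np.log(2)),
                wald_stat=float(z[i]),
                p_value=float(pvals[i]),
                adjusted_p_value=float(qvals[i]),
                dispersion=float(alpha[i]),
            )
        )
    return out


def bh_adjust(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the family size; it may exceed the vector length when some family
    members were tested elsewhere (or filtered out before adjustment).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"family size m={m} smaller than vector length {n}")
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Condition x trimester interaction LRT
# ---------------------------------------------------------------------------

def interaction_lrt(
    cm: CountMatrix, metadata: SampleTable, s: np.ndarray | None = None
) -> pd.DataFrame:
    """Likelihood-ratio test for a condition-specific change across trimesters.

    Fits the full NB GLM ``~ condition + trimester + condition:trimester`` and
    a reduced model without the interaction; the same method-of-moments
    dispersions (from the full condition x trimester grouping) are used in
    both fits, and the LRT statistic is referred to chi-square(1).
    """
    meta = metadata.select(cm.sample_ids)
    if "trimester" not in meta.frame.columns:
        raise ValueError("metadata must carry a 'trimester' column")
    cond = meta.is_pe().astype(float)
    trim = (meta.frame["trimester"].to_numpy().astype(int) == 2).astype(float)
    for c in (0, 1):
        for t in (0, 1):
            if not ((cond == c) & (trim == t)).any():
                raise ValueError(
                    f"empty design cell: condition={'PE' if c else 'control'}, "
                    f"trimester={'2' if t else '1'}"
                )
    if s is None:
        s = size_factors(cm)
    ones = np.ones(len(cond))
    X_full = np.column_stack([ones, cond, trim, cond * trim])
    X_red = X_full[:, :3]

    norm = cm.counts / s[None, :]
    cells = np.char.add(cond.astype(int).astype(str), trim.astype(int).astype(str))
    alpha = moment_dispersions(norm, cells)

    full = nb_glm_fit(cm.counts, X_full, np.log(s), alpha)
    red = nb_glm_fit(cm.counts, X_red, np.log(s), alpha)
    lrt = np.maximum(2.0 * (full.loglik - red.loglik), 0.0)
    pvals = stats.chi2.sf(lrt, df=1)
    ok = full.converged & red.converged
    pvals = np.where(ok, pvals, np.nan)
    finite = np.isfinite(pvals)
    qvals = np.full_like(pvals, np.nan)
    if finite.any():
        qvals[finite] = bh_adjust(pvals[finite])
    return pd.DataFrame(
        {
            "transcript_id": cm.transcript_ids,
            "lrt_stat": lrt,
            "p_value": pvals,
            "adjusted_p_value": qvals,
            "interaction_log2fc": full.beta[:, 3] / np.log(2),
        }
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class DESummary:
    n_significant: int
    n_up: int
    n_down: int
    by_biotype: dict[str, int] = field(default_factory=dict)


def summarize_de(results: Sequence[DEResult], alpha: float = 0.05) -> DESummary:
    """Count significant transcripts (q < alpha), split by direction and biotype."""
    sig = [r for r in results if np.isfinite(r.adjusted_p_value) and r.adjusted_p_value < alpha]
    up = sum(r.fold_change > 1 for r in sig)
    by_bio: dict[str, int] = {}
    for r in sig:
        by_bio[r.biotype] = by_bio.get(r.biotype, 0) + 1
    return DESummary(len(sig), up, len(sig) - up, by_bio)


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    """DE results as a DataFrame mirroring the published table's columns."""
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "biotype": [r.biotype for r in results],
            "mean_counts": [r.mean_counts for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p_value": [r.adjusted_p_value for r in results],
            "dispersion": [r.dispersion for r in results],
        }
    )
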