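"""Classifier metrics and clinical/validation statistics.

Confusion-matrix metrics, rank-based ROC AUC, sensitivity at a fixed false
positive rate, the exact conditional Fisher test for r x c contingency tables,
the Mann-Whitney U test (normal approximation with tie/continuity correction,
exact for tiny samples), transcript-clinical Pearson correlations with FDR
control, and sequencing-vs-qPCR concordance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import SampleTable

_TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# Confusion metrics and AUC
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    f1: float
    lr_pos: float      # sensitivity / (1 - specificity); inf at specificity 1
    lr_neg: float      # (1 - sensitivity) / specificity
    auc: float = float("nan")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sensitivity", "specificity", "accuracy", "mcc", "f1",
                 "lr_pos", "lr_neg", "auc")}


def confusion_metrics(
    labels: np.ndarray, probs: np.ndarray, threshold: float = 0.5
) -> tuple[ConfusionCounts, MetricSet]:
    """Threshold predicted probabilities (ties classified positive) and compute
    sensitivity, specificity, accuracy, MCC, F1 and the likelihood ratios."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    cc = ConfusionCounts(tp, fp, tn, fn)

    pos, neg = tp + fn, tn + fp
    sens = tp / pos if pos else float("nan")
    spec = tn / neg if neg else float("nan")
    acc = (tp + tn) / len(y) if len(y) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    prec_den = tp + fp
    f1_den = 2 * tp + fp + fn
    f1 = 2 * tp / f1_den if f1_den else float("nan")
    if np.isnan(spec):
        lrp = lrn = float("nan")
    else:
        lrp = sens / (1 - spec) if spec < 1 else float("inf")
        lrn = (1 - sens) / spec if spec > 0 else float("inf")
    return cc, MetricSet(sens, spec, acc, mcc, f1, lrp, lrn)


def roc_auc(labels: np.ndarray, probs: np.ndarray) -> float:
    """ROC AUC by the rank/pair formulation: P(score_pos > score_neg) plus
    half the tie probability — identical to trapezoidal integration of the
    empirical ROC."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sensitivity_at_fpr(labels: np.ndarray, probs: np.ndarray, level: float) -> float:
    """Max TPR among empirical-ROC operating points with FPR <= ``level``
    (conservative step-function convention)."""
    if not (0 < level < 1):
        raise ValueError("FPR level must be in (0, 1)")
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-p, kind="mergesort")
    y_sorted = y[order]
    p_sorted = p[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score block (valid operating points)
    last = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tpr = tp[last] / n_pos
    fpr = fp[last] / n_neg
    ok = fpr <= level + 1e-12
    return float(tpr[ok].max()) if ok.any() else 0.0


# ---------------------------------------------------------------------------
# Fisher exact test for r x c tables
# ---------------------------------------------------------------------------

def _table_logprob(cells: np.ndarray, lg: np.ndarray, const: float) -> float:
    return const - lg[cells].sum()


def fisher_exact_rxc(
    table, max_tables: int = 2_000_000, n_monte_carlo: int | None = None,
    seed: int = 0,
) -> float:
    """Two-sided exact conditional test for an r x c contingency table.

    Enumerates all tables with the observed margins and sums the multivariate
    hypergeometric probabilities of tables no more probable than the observed
    one (relative tie tolerance 1e-12).  Enumeration beyond ``max_tables``
    raises unless ``n_monte_carlo`` is given, in which case a seeded
    permutation Monte-Carlo estimate is returned.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if (t < 0).any():
        raise ValueError("cell counts must be nonnegative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    lg = np.array([math.lgamma(i + 1) for i in range(n + 1)])
    const = lg[row].sum() + lg[col].sum() - lg[n]
    logp_obs = _table_logprob(t, lg, const)

    if n_monte_carlo is not None:
        return _fisher_monte_carlo(row, col, lg, const, logp_obs, n_monte_carlo, seed)

    r, c = t.shape
    total = 0.0
    count = 0

    def rec(i: int, col_left: np.ndarray, acc: float) -> None:
        nonlocal total, count
        if i == r - 1:
            count += 1
            if count > max_tables:
                raise ValueError(
                    "table too large for exact enumeration; "
                    "pass n_monte_carlo for a seeded Monte-Carlo p-value"
                )
            logp = acc + const - lg[col_left].sum()
            if logp <= logp_obs + _TIE_TOL:
                total += math.exp(logp)
            return
        for comp in _compositions(int(row[i]), col_left):
            rec(i + 1, col_left - comp, acc - lg[comp].sum())

    rec(0, col.copy(), 0.0)
    return min(total, 1.0)


def _compositions(s: int, bounds: np.ndarray):
    """All vectors 0 <= v <= bounds with sum(v) == s."""
    c = len(bounds)

    def go(j: int, left: int, prefix: tuple):
        if j == c - 1:
            if left <= bounds[j]:
                yield np.array(prefix + (left,), dtype=int)
            return
        lo = max(0, left - int(bounds[j + 1:].sum()))
        hi = min(int(bounds[j]), left)
        for v in range(lo, hi + 1):
            yield from go(j + 1, left - v, prefix + (v,))

    yield from go(0, s, ())


def _fisher_monte_carlo(row, col, lg, const, logp_obs, n_draws, seed) -> float:
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(row)), row)
    col_labels = np.repeat(np.arange(len(col)), col)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(row_labels)
        tab = np.zeros((len(row), len(col)), dtype=int)
        np.add.at(tab, (perm, col_labels), 1)
        if _table_logprob(tab, lg, const) <= logp_obs + _TIE_TOL:
            hits += 1
    return (hits + 1) / (n_draws + 1)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Mann-Whitney U (midranks for ties) with a two-sided p-value.

    Exact p by full enumeration of group assignments when
    n_x + n_y <= ``exact_max_n``; otherwise the normal approximation with tie
    correction and continuity correction.
    Returns ``(U, p)`` with U the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mu = nx * ny / 2.0

    n = nx + ny
    if n <= exact_max_n:
        dist_dev = []
        obs_dev = abs(u - mu)
        for comb in itertools.combinations(range(n), nx):
            ux = ranks[list(comb)].sum() - nx * (nx + 1) / 2
            dist_dev.append(abs(ux - mu))
        dist_dev = np.asarray(dist_dev)
        p = float((dist_dev >= obs_dev - 1e-12).mean())
        return u, min(p, 1.0)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    sigma_sq = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma_sq <= 0:
        return u, 1.0
    dev = u - mu
    cc = 0.5 * np.sign(dev)
    z = (dev - cc) / math.sqrt(sigma_sq)
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Clinical correlations and qPCR concordance
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    transcript_id: str
    feature: str
    r: float
    p_value: float
    adjusted_p_value: float
    n: int
    skipped: bool = False


def transcript_clinical_correlation(
    expr: pd.DataFrame, clinical: pd.DataFrame
) -> list[CorrelationResult]:
    """Pearson correlation of each transcript (columns of ``expr``, rows
    samples) with each clinical feature, pairwise-complete, BH-adjusted across
    all transcript x feature pairs tested.  Pairs with fewer than 3 complete
    observations are skipped and flagged."""
    common = expr.index.intersection(clinical.index)
    expr = expr.loc[common]
    clinical = clinical.loc[common]
    results: list[CorrelationResult] = []
    pvals: list[float] = []
    for tid in expr.columns:
        for feat in clinical.columns:
            pair = pd.concat([expr[tid], pd.to_numeric(clinical[feat], errors="coerce")],
                             axis=1).dropna()
            if len(pair) < 3:
                results.append(CorrelationResult(tid, feat, float("nan"),
                                                 float("nan"), float("nan"),
                                                 len(pair), skipped=True))
                continue
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            results.append(CorrelationResult(tid, feat, float(r), float(p),
                                             float("nan"), len(pair)))
            pvals.append(float(p))
    if pvals:
        q = bh_adjust(np.array(pvals))
        it = iter(q)
        for res in results:
            if not res.skipped:
                res.adjusted_p_value = float(next(it))
    return results


def qpcr_concordance(
    seq_norm: pd.DataFrame,
    qpcr: pd.DataFrame,
    exclude_samples: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-transcript Pearson correlation between sequencing normalized counts
    and qPCR relative expression.

    ``seq_norm`` — samples (rows, indexed by sample id) x transcripts.
    ``qpcr`` — long table with columns sample_id, transcript_id, ct,
    cdna_concentration.  The qPCR quantity is 2^-Ct normalized by the cDNA
    concentration.  ``exclude_samples`` are removed before correlating.
    """
    q = qpcr[~qpcr["sample_id"].isin(exclude_samples)].copy()
    q["qpcr_value"] = np.exp2(-q["ct"].astype(float)) / q["cdna_concentration"].astype(float)
    rows = []
    for tid, grp in q.groupby("transcript_id"):
        grp = grp[grp["sample_id"].isin(seq_norm.index)]
        if tid not in seq_norm.columns:
            raise KeyError(f"transcript {tid!r} not in sequencing matrix")
        if len(grp) < 3:
            raise ValueError(f"fewer than 3 matched samples for {tid!r}")
        seq_vals = seq_norm.loc[grp["sample_id"], tid].to_numpy(dtype=float)
        r, p = stats.pearsonr(seq_vals, grp["qpcr_value"].to_numpy())
        rows.append({"transcript_id": tid, "r": float(r), "p_value": float(p),
                     "n": len(grp)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical group-comparison table
# ---------------------------------------------------------------------------

def clinical_group_stats(metadata: SampleTable) -> pd.DataFrame:
    """Per-covariate PE vs control comparison: Fisher exact for categorical
    variables, Mann-Whitney U for continuous ones."""
    df = metadata.frame
    is_pe = metadata.is_pe().astype(bool)
    rows = []
    for col in metadata.clinical_columns():
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.notna().all() and numeric.nunique() > 5:
            u, p = mann_whitney_u(numeric[is_pe].dropna(), numeric[~is_pe].dropna())
            rows.append({"variable": col, "test": "mann_whitney_u",
                         "statistic": u, "p_value": p})
        else:
            tab = pd.crosstab(df["condition"], series.astype(str))
            if min(tab.shape) < 2:
                continue
            p = fisher_exact_rxc(tab.to_numpy())
            rows.append({"variable": col, "test": "fisher_exact",
                         "statistic": float("nan"), "p_value": p})
    return pd.DataFrame(rows)
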