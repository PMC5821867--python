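"""Metric computations, exact tests and concordance statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import plasmarna as pr
from plasmarna.metrics import (confusion_metrics, fisher_exact_rxc,
                               mann_whitney_u, qpcr_concordance, roc_auc,
                               sensitivity_at_fpr,
                               transcript_clinical_correlation)

#: published per-group contingency tables (control row first) and the
#: p-values printed alongside them
PUBLISHED_TABLES = {
    "fetal_gender": ([[22, 18], [17, 18]], 0.65, 2),
    "ethnicity": ([[15, 1, 24], [19, 1, 15]], 0.2848, 4),
    "smoking": ([[34, 6], [34, 1]], 0.11, 2),
    "family_history": ([[2, 38], [4, 31]], 0.41, 2),
    "parity": ([[15, 0, 25], [6, 8, 21]], 0.0018, 4),
    "chronic_hypertension": ([[0, 40], [8, 27]], 0.001, 3),
}


# ---------------------------------------------------------------------------
# confusion metrics and AUC
# ---------------------------------------------------------------------------

def test_perfect_predictions():
    y = np.array([1, 1, 0, 0])
    cc, ms = confusion_metrics(y, np.array([0.9, 0.8, 0.1, 0.2]))
    assert (cc.tp, cc.tn, cc.fp, cc.fn) == (2, 2, 0, 0)
    for name in ("sensitivity", "specificity", "accuracy", "f1", "mcc"):
        assert getattr(ms, name) == 1.0
    assert roc_auc(y, np.array([0.9, 0.8, 0.1, 0.2])) == 1.0
    assert roc_auc(y, np.full(4, 0.5)) == 0.5


def test_likelihood_ratio_formulas():
    # sensitivity 0.8, specificity 0.9 on a constructed sample
    y = np.array([1] * 10 + [0] * 10)
    p = np.array([0.9] * 8 + [0.1] * 2 + [0.1] * 9 + [0.9] * 1)
    _, ms = confusion_metrics(y, p)
    assert ms.sensitivity == pytest.approx(0.8)
    assert ms.specificity == pytest.approx(0.9)
    assert ms.lr_pos == pytest.approx(8.0)
    assert ms.lr_neg == pytest.approx(0.2222, abs=1e-4)


def test_confusion_matches_direct_count_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.integers(0, 2, 200)
        p = rng.random(200)
        cc, ms = confusion_metrics(y, p, threshold=0.5)
        pred = (p >= 0.5).astype(int)
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        assert (cc.tp, cc.fp) == (tp, fp)
        assert ms.accuracy == pytest.approx(np.mean(pred == y))
        num = cc.tp * cc.tn - cc.fp * cc.fn
        den = math.sqrt((cc.tp + cc.fp) * (cc.tp + cc.fn)
                        * (cc.tn + cc.fp) * (cc.tn + cc.fn))
        assert ms.mcc == pytest.approx(num / den if den else 0.0)


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        y = rng.integers(0, 2, 40)
        if y.min() == y.max():
            continue
        p = np.round(rng.random(40), 2)          # force ties
        pos, neg = p[y == 1], p[y == 0]
        pairs = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        assert roc_auc(y, p) == pytest.approx(pairs / (len(pos) * len(neg)),
                                              abs=1e-12)
    with pytest.raises(ValueError):
        roc_auc(np.ones(5), rng.random(5))


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=4,
                max_size=60))
def test_auc_complement_symmetry(pairs):
    y = np.array([a for a, _ in pairs])
    p = np.array([b for _, b in pairs])
    if y.min() == y.max():
        return
    assert roc_auc(y, p) + roc_auc(y, -p) == pytest.approx(1.0, abs=1e-12)


def test_sensitivity_at_fpr_gaussian_oracle():
    """pos~N(1,1), neg~N(0,1): sensitivity at FPR 0.10 -> 1-Phi(z0.9 - 1)."""
    rng = np.random.default_rng(2)
    n = 2000
    scores = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
    y = np.r_[np.ones(n), np.zeros(n)]
    target = 1 - stats.norm.cdf(stats.norm.ppf(0.9) - 1)   # 0.389
    assert sensitivity_at_fpr(y, scores, 0.10) == pytest.approx(target, abs=0.04)
    # chance scores: sensitivity at level f is ~f
    shuffled = rng.permutation(scores)
    assert sensitivity_at_fpr(y, shuffled, 0.10) == pytest.approx(0.10, abs=0.03)
    # perfect separation
    assert sensitivity_at_fpr(np.array([1, 1, 0, 0]),
                              np.array([0.9, 0.8, 0.2, 0.1]), 0.05) == 1.0
    with pytest.raises(ValueError):
        sensitivity_at_fpr(y, scores, 1.5)


# ---------------------------------------------------------------------------
# Fisher exact r x c
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", sorted(PUBLISHED_TABLES))
def test_fisher_reproduces_published_pvalues(name):
    table, printed, digits = PUBLISHED_TABLES[name]
    p = fisher_exact_rxc(np.array(table))
    assert round(p, digits) == pytest.approx(printed, abs=10 ** -digits / 2)


def test_fisher_proportional_rows_p_one():
    assert fisher_exact_rxc([[10, 20, 30], [20, 40, 60]]) == pytest.approx(1.0)


def test_fisher_2x2_matches_hypergeometric_closed_form():
    rng = np.random.default_rng(3)
    for _ in range(30):
        t = rng.integers(0, 12, (2, 2))
        if t.sum() == 0 or (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            continue
        mine = fisher_exact_rxc(t)
        # closed form: sum hypergeometric pmf over tables no more probable
        n = t.sum(); r1 = t[0].sum(); c1 = t[:, 0].sum()
        rv = stats.hypergeom(n, r1, c1)
        p_obs = rv.pmf(t[0, 0])
        support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
        closed = rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-9)].sum()
        assert mine == pytest.approx(closed, abs=1e-10)
        assert mine == pytest.approx(stats.fisher_exact(t)[1], abs=1e-9)


def test_fisher_monte_carlo_agrees_with_exact():
    t = np.array([[8, 3, 1], [2, 6, 5]])
    exact = fisher_exact_rxc(t)
    mc = fisher_exact_rxc(t, n_monte_carlo=40000, seed=1)
    assert mc == pytest.approx(exact, abs=0.01)
    with pytest.raises(ValueError):
        fisher_exact_rxc(np.array([[40, 2, 1], [2, 40, 1], [1, 2, 40]]) * 9,
                         max_tables=100)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_mann_whitney_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    u, p = mann_whitney_u(x, list(x))
    assert u == pytest.approx(len(x) ** 2 / 2)
    assert p == pytest.approx(1.0)


def test_mann_whitney_complete_separation_exact():
    u, p = mann_whitney_u([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
    assert u == 0.0
    assert p == pytest.approx(2 / 252, abs=1e-12)


def test_mann_whitney_exact_matches_enumeration_with_ties():
    x = [1.0, 2.0, 2.0, 5.0]
    y = [2.0, 3.0, 4.0]
    u_obs, p_mine = mann_whitney_u(x, y)
    pooled = np.array(x + y)
    ranks = stats.rankdata(pooled)
    mu = len(x) * len(y) / 2
    devs = [abs(ranks[list(c)].sum() - len(x) * (len(x) + 1) / 2 - mu)
            for c in itertools.combinations(range(7), len(x))]
    p_oracle = np.mean(np.array(devs) >= abs(u_obs - mu) - 1e-12)
    assert p_mine == pytest.approx(p_oracle, abs=1e-12)


def test_mann_whitney_exact_matches_scipy_untied():
    rng = np.random.default_rng(4)
    for _ in range(10):
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 6)
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_mann_whitney_normal_approx_close_to_scipy():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.6, 1, 35)
    _, p = mann_whitney_u(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert p == pytest.approx(ref.pvalue, rel=0.01)
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# clinical correlations and qPCR concordance
# ---------------------------------------------------------------------------

def test_self_correlation_is_one():
    rng = np.random.default_rng(6)
    v = rng.normal(0, 1, 30)
    expr = pd.DataFrame({"t1": v}, index=[f"S{i}" for i in range(30)])
    clin = pd.DataFrame({"f": v}, index=expr.index)
    res = transcript_clinical_correlation(expr, clin)
    assert res[0].r == pytest.approx(1.0)


def test_planted_coupling_recovered_within_fisher_band():
    """Count-level estimate of a planted r=0.44 coupling lies inside the
    Fisher-z 95% band [0.24, 0.61]."""
    rs = []
    for seed in range(5):
        cfg = pr.SimulationConfig(rng_seed=seed, second_trimester=(0, 0),
                                  coupling=pr.CouplingSpec(r=0.44))
        ds = pr.simulate_dataset(cfg)
        cm, meta = ds.first_trimester()
        logx = pr.log2_normalized(cm, pr.size_factors(cm))
        ci = ds.truth["config"]["coupling"]["transcript_index"]
        expr = pd.DataFrame({"coupled": logx[ci]}, index=cm.sample_ids)
        clin = meta.frame.set_index("sample_id")[["MAP"]]
        res = transcript_clinical_correlation(expr, clin)
        rs.append(res[0].r)
    assert 0.24 <= np.mean(rs) <= 0.61


def test_correlation_family_calibration():
    rng = np.random.default_rng(7)
    idx = [f"S{i}" for i in range(75)]
    expr = pd.DataFrame(rng.normal(0, 1, (75, 10)),
                        columns=[f"t{i}" for i in range(10)], index=idx)
    clin = pd.DataFrame(rng.normal(0, 1, (75, 5)),
                        columns=[f"f{i}" for i in range(5)], index=idx)
    res = transcript_clinical_correlation(expr, clin)
    assert len(res) == 50
    sig = sum(r.adjusted_p_value < 0.05 for r in res if not r.skipped)
    assert sig <= 3
    # short pairs are skipped with a flag
    clin2 = clin.copy()
    clin2.loc[idx[2:], "f0"] = np.nan
    res2 = transcript_clinical_correlation(expr[["t0"]], clin2[["f0"]])
    assert res2[0].skipped and res2[0].n == 2


def test_qpcr_concordance_and_outlier_exclusion():
    ds = pr.simulate_dataset(pr.SimulationConfig(rng_seed=3, second_trimester=(0, 0)))
    samples = ds.counts.sample_ids[:6] + ds.counts.sample_ids[35:43]
    tids = ["FG0001", "FG0002"]
    q = pr.simulate_qpcr(ds, tids, samples, noise_sd=0.0, rng_seed=0)
    sub = ds.counts.select_samples(samples)
    norm = pr.normalized_counts(sub, pr.size_factors(sub))
    idx = [ds.counts.transcript_ids.index(t) for t in tids]
    seq = pd.DataFrame(norm[idx, :].T, index=samples, columns=tids)
    base = qpcr_concordance(seq, q)
    assert (base["r"] > 0.9).all()

    # a corrupted sample drags r down; excluding it recovers
    q_bad = q.copy()
    q_bad.loc[q_bad["sample_id"] == samples[0], "ct"] += 11.0
    worse = qpcr_concordance(seq, q_bad)
    fixed = qpcr_concordance(seq, q_bad, exclude_samples=(samples[0],))
    assert (fixed["r"] > worse["r"]).all()
    with pytest.raises(ValueError):
        qpcr_concordance(seq.iloc[:2], q)


def test_clinical_group_stats_runs_on_synthetic(null_dataset):
    _, _, meta = null_dataset
    out = pr.clinical_group_stats(meta)
    assert {"variable", "test", "statistic", "p_value"} <= set(out.columns)
    assert out["p_value"].between(0, 1).all()
    tests = dict(zip(out["variable"], out["test"]))
    assert tests["MAP"] == "mann_whitney_u"
    assert tests["ethnicity"] == "fisher_exact"
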