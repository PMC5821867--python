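"""Normalization, DE screen and FDR adjustment against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import plasmarna as pr
from plasmarna.de import log_geometric_means
from plasmarna.io import CountMatrix

from conftest import make_counts, make_metadata


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_identical_columns_are_one():
    col = np.array([10, 200, 3000, 44, 5])
    cm = make_counts(np.tile(col[:, None], (1, 6)))
    assert pr.size_factors(cm) == pytest.approx(np.ones(6))


def test_size_factors_scale_equivariance():
    rng = np.random.default_rng(0)
    k = rng.negative_binomial(5, 0.1, (50, 10)) + 1
    cm = make_counts(k)
    s = pr.size_factors(cm)
    # appending a doubled copy of a column: its factor is exactly 2x the
    # partner's within the same matrix
    k_dup = np.column_stack([k, 2 * k[:, 3]])
    s_dup = pr.size_factors(make_counts(k_dup))
    assert s_dup[10] == pytest.approx(2 * s_dup[3])
    # against a frozen reference, scaling a sample scales only its factor and
    # leaves every normalized count unchanged
    ref = log_geometric_means(k)
    k2 = k.copy()
    k2[:, 3] *= 2
    s2 = pr.size_factors(make_counts(k2), reference=ref)
    assert s2[3] == pytest.approx(2 * s[3])
    others = [j for j in range(10) if j != 3]
    assert s2[others] == pytest.approx(s[others])
    assert k2 / s2[None, :] == pytest.approx(k / s[None, :])


def test_size_factors_match_brute_force_median_of_ratios():
    rng = np.random.default_rng(1)
    k = rng.negative_binomial(5, 0.05, (50, 10)) + 1
    cm = make_counts(k)
    s = pr.size_factors(cm)
    geo = np.exp(np.log(k).mean(axis=1))
    expected = [np.median(k[:, j] / geo) for j in range(10)]
    assert s == pytest.approx(expected)


def test_size_factors_error_without_allpositive_transcript():
    k = np.array([[0, 5], [3, 0]])
    with pytest.raises(ValueError, match="filter"):
        pr.size_factors(make_counts(k))


# ---------------------------------------------------------------------------
# abundance filter
# ---------------------------------------------------------------------------

def test_top_abundant_matches_full_sort_oracle(null_dataset):
    _, cm, _ = null_dataset
    s = pr.size_factors(cm)
    top = pr.top_abundant(cm, 100, s)
    means = (cm.counts / s[None, :]).mean(axis=1)
    oracle = sorted(range(cm.n_transcripts),
                    key=lambda i: (-means[i], cm.transcript_ids[i]))[:100]
    assert top == [cm.transcript_ids[i] for i in oracle]
    assert pr.top_abundant(cm, cm.n_transcripts, s) == sorted(
        cm.transcript_ids, key=lambda t: (-means[cm.transcript_ids.index(t)], t))
    with pytest.raises(ValueError):
        pr.top_abundant(cm, 0)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def _bh_oracle(p, m):
    """Brute-force step-up: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    order = np.argsort(p)
    n = len(p)
    q = np.empty(n)
    for pos, idx in enumerate(order):
        q[idx] = min(1.0, min(p[order[j]] * m / (j + 1) for j in range(pos, n)))
    return q


def test_bh_matches_bruteforce_and_statsmodels():
    rng = np.random.default_rng(2)
    for _ in range(50):
        p = rng.random(rng.integers(1, 30))
        q = pr.bh_adjust(p)
        assert q == pytest.approx(_bh_oracle(p, len(p)))
        assert q == pytest.approx(
            sm.stats.multipletests(p, method="fdr_bh")[1])
    with pytest.raises(ValueError):
        pr.bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        pr.bh_adjust([0.5, 0.1], m=1)
    assert pr.bh_adjust([0.3], m=1) == pytest.approx([0.3])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
       st.integers(0, 60))
def test_bh_monotone_and_permutation_invariant(pvals, extra):
    p = np.array(pvals)
    m = len(p) + extra
    q = pr.bh_adjust(p, m=m)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)     # monotone in ranked p
    assert np.all(q >= p - 1e-12) and np.all(q <= 1)
    perm = np.random.default_rng(0).permutation(len(p))
    assert pr.bh_adjust(p[perm], m=m) == pytest.approx(q[perm])


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def test_nb_wald_matches_statsmodels_glm():
    rng = np.random.default_rng(3)
    n = 40
    cond = np.array(["PE"] * 20 + ["control"] * 20)
    batch = np.array(["B1", "B2"] * 20)
    meta = make_metadata(cond, batch)
    mu = 300 * np.exp(0.7 * (cond == "PE") + 0.3 * (batch == "B2"))
    r = 1 / 0.1
    k = rng.negative_binomial(r, r / (r + mu), (6, n))
    cm = make_counts(k)
    s = np.ones(n)
    res = pr.nb_wald_test(cm, meta, s=s)
    X = np.column_stack([np.ones(n), (batch == "B2").astype(float),
                         (cond == "PE").astype(float)])
    for i, row in enumerate(res):
        fit = sm.GLM(k[i], X,
                     family=sm.families.NegativeBinomial(alpha=row.dispersion)).fit()
        assert np.log(row.fold_change) == pytest.approx(fit.params[-1], abs=1e-5)
        z = fit.params[-1] / fit.bse[-1]
        assert row.wald_stat == pytest.approx(z, abs=1e-4)


def test_nb_wald_reference_relabel_symmetry(planted_dataset):
    """Swapping which condition is 'reference' inverts FC and keeps p-values."""
    _, cm, meta = planted_dataset
    sub = cm.select_transcripts([f"FG{i:04d}" for i in range(1, 11)])
    s = pr.size_factors(cm)
    res = pr.nb_wald_test(sub, meta, s=s)
    flipped = meta.frame.copy()
    flipped["condition"] = np.where(flipped["condition"] == "PE", "control", "PE")
    res_flip = pr.nb_wald_test(sub, pr.SampleTable(flipped), s=s)
    for a, b in zip(res, res_flip):
        assert a.fold_change == pytest.approx(1 / b.fold_change, rel=1e-6)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


def test_nb_wald_planted_fc_recovery(planted_dataset):
    """FC 0.50 planted at published scale is estimated inside the
    Monte-Carlo oracle band [0.42, 0.62] on average."""
    ests = []
    for seed in range(5):
        cfg = pr.SimulationConfig(rng_seed=seed, n_foreground=20, n_background=0,
                                  fold_changes=np.array([0.5]), dispersion=0.05,
                                  n_batches=1, coupling=None,
                                  second_trimester=(0, 0))
        ds = pr.simulate_dataset(cfg)
        cm, meta = ds.first_trimester()
        res = pr.nb_wald_test(cm, meta, include_batch=False)
        ests.append(res[0].fold_change)
    assert 0.42 <= np.mean(ests) <= 0.62


def test_nb_wald_constant_condition_errors(null_dataset):
    _, cm, meta = null_dataset
    df = meta.frame.copy()
    df["condition"] = "PE"
    with pytest.raises(ValueError, match="both"):
        pr.nb_wald_test(cm, pr.SampleTable(df))


# ---------------------------------------------------------------------------
# interaction LRT
# ---------------------------------------------------------------------------

def _paired_design(rng, T, inter_mult, alpha=0.05, npg=20):
    base = np.exp(rng.uniform(np.log(200), np.log(5000), T))
    cond = np.array([1] * npg + [0] * npg + [1] * npg + [0] * npg)
    trim = np.array([1] * 2 * npg + [2] * 2 * npg)
    inter = np.where((cond == 1) & (trim == 2), inter_mult, 1.0)
    r = 1 / alpha
    mu = base[:, None] * inter[None, :]
    k = rng.negative_binomial(r, r / (r + mu))
    cm = make_counts(k)
    meta = make_metadata(np.where(cond == 1, "PE", "control"),
                         trimester=trim)
    return cm, meta


def test_interaction_lrt_power_and_null():
    rng = np.random.default_rng(4)
    cm, meta = _paired_design(rng, 300, 2.0)
    res = pr.interaction_lrt(cm, meta, s=np.ones(80))
    assert np.nanmean(res["p_value"] < 0.05) > 0.5
    cm0, meta0 = _paired_design(rng, 300, 1.0)
    res0 = pr.interaction_lrt(cm0, meta0, s=np.ones(80))
    frac = np.nanmean(res0["p_value"] < 0.05)
    assert 0.02 <= frac <= 0.09


def test_interaction_lrt_empty_cell_errors():
    rng = np.random.default_rng(5)
    cm, meta = _paired_design(rng, 5, 1.0)
    df = meta.frame.copy()
    df = df[~((df["condition"] == "PE") & (df["trimester"] == 2))]
    with pytest.raises(ValueError, match="empty"):
        pr.interaction_lrt(cm.select_samples(df["sample_id"].tolist()),
                           pr.SampleTable(df))


# ---------------------------------------------------------------------------
# PCA QC
# ---------------------------------------------------------------------------

def test_pca_flags_composition_outlier(null_dataset):
    _, cm, meta = null_dataset
    k = cm.counts.copy()
    k[: cm.n_transcripts // 2, 10] *= 100        # distorts composition
    cm2 = CountMatrix(cm.transcript_ids, cm.biotypes, cm.sample_ids, k)
    qc = pr.pca_qc(cm2, meta)
    assert bool(qc.table.loc[10, "outlier"])


def test_pca_batch_association_orders_with_batch_effect():
    scores = []
    for sd in (0.0, 0.6):
        cfg = pr.SimulationConfig(rng_seed=9, batch_log_sd=sd, coupling=None,
                                  second_trimester=(0, 0))
        cm, meta = pr.simulate_dataset(cfg).first_trimester()
        scores.append(pr.pca_qc(cm, meta).batch_association)
    assert scores[1] > scores[0]
    with pytest.raises(ValueError):
        pr.pca_qc(cm.select_samples(cm.sample_ids[:2]), meta)


def test_pca_few_false_flags_on_clean_data(null_dataset):
    _, cm, meta = null_dataset
    assert int(pr.pca_qc(cm, meta).table["outlier"].sum()) <= 3


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summarize_de_matches_filter_and_count_oracle():
    rng = np.random.default_rng(6)
    results = []
    for i in range(60):
        q = rng.random() * 0.2
        results.append(pr.DEResult(f"T{i}", rng.choice(["miRNA", "lincRNA"]),
                                   100.0, float(np.exp(rng.normal(0, 1))), 0.0,
                                   0.0, q / 2, q, 0.1))
    summ = pr.summarize_de(results, alpha=0.05)
    sig = [r for r in results if r.adjusted_p_value < 0.05]
    assert summ.n_significant == len(sig)
    assert summ.n_up == sum(r.fold_change > 1 for r in sig)
    assert summ.n_up + summ.n_down == summ.n_significant
    assert sum(summ.by_biotype.values()) == summ.n_significant
    empty = pr.summarize_de([], alpha=0.05)
    assert (empty.n_significant, empty.n_up, empty.n_down) == (0, 0, 0)
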