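"""Parametric empirical-Bayes batch adjustment of log-expression (ComBat-style).

The model is fit on training samples only and stored, so it can be applied as
a frozen transform to held-out samples from the same batches inside a
cross-validation cycle without touching their labels.  By default the fit uses
a batch-only design (condition is NOT protected), which is what makes the
frozen train/apply split leak-free; a ``condition`` argument restores the
classic joint mode where the biological covariate is preserved during
standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

EB_TOL = 1e-6
EB_MAX_ITER = 500
VARIANCE_FLOOR = 1e-12


@dataclass
class BatchModel:
    """Fitted per-transcript batch location/scale model.

    ``grand_mean``/``pooled_var`` standardize expression; ``gamma_star`` and
    ``delta_sq_star`` are the EB-shrunk per-batch location and scale (in
    standardized units), indexed by ``batch_levels``.
    """

    batch_levels: list[str]
    grand_mean: np.ndarray            # (T,)
    pooled_var: np.ndarray            # (T,)
    gamma_star: np.ndarray            # (B, T)
    delta_sq_star: np.ndarray         # (B, T)
    hyper: dict = field(default_factory=dict)
    condition_beta: np.ndarray | None = None   # set only in protected mode

    def to_json(self) -> str:
        d = {
            "batch_levels": self.batch_levels,
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_sq_star": self.delta_sq_star.tolist(),
            "hyper": self.hyper,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "BatchModel":
        d = json.loads(s)
        return cls(
            batch_levels=d["batch_levels"],
            grand_mean=np.asarray(d["grand_mean"]),
            pooled_var=np.asarray(d["pooled_var"]),
            gamma_star=np.asarray(d["gamma_star"]),
            delta_sq_star=np.asarray(d["delta_sq_star"]),
            hyper=d["hyper"],
        )


def _batch_index(batches: np.ndarray, levels: list[str]) -> np.ndarray:
    lookup = {b: i for i, b in enumerate(levels)}
    try:
        return np.array([lookup[str(b)] for b in batches])
    except KeyError as e:
        raise KeyError(f"batch label {e.args[0]!r} not seen at fit time") from None


def combat_fit(
    logexpr: np.ndarray, batches, condition: np.ndarray | None = None
) -> BatchModel:
    """Fit the EB batch model on transcripts x samples log-expression.

    Per transcript: standardize by the grand mean and pooled variance,
    estimate naive per-batch location/scale on the standardized data, fit
    normal / inverse-gamma priors across transcripts by moment matching, and
    solve the EB fixed point for the shrunk estimates.

    With ``condition`` given (binary vector), the condition effect is
    estimated jointly and protected during standardization — the classic
    joint mode, usable only when labels for all samples are available.
    """
    x = np.asarray(logexpr, dtype=float)
    batches = np.asarray([str(b) for b in np.asarray(batches)])
    if x.shape[1] != len(batches):
        raise ValueError("one batch label required per sample")
    levels = sorted(set(batches))
    for b in levels:
        if (batches == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
    T, S = x.shape
    B = len(levels)
    idx = _batch_index(batches, levels)
    n_b = np.array([(idx == i).sum() for i in range(B)], dtype=float)

    cond_beta = None
    x_work = x
    if condition is not None:
        cond = np.asarray(condition, dtype=float)
        condc = cond - cond.mean()
        denom = (condc ** 2).sum()
        if denom <= 0:
            raise ValueError("condition has a single level")
        cond_beta = (x * condc[None, :]).sum(axis=1) / denom
        x_work = x - cond_beta[:, None] * condc[None, :]

    # grand mean = weighted average of batch means; pooled variance of residuals
    batch_means = np.stack([x_work[:, idx == i].mean(axis=1) for i in range(B)])
    grand = (n_b[:, None] * batch_means).sum(axis=0) / S
    resid = x_work - batch_means[idx, :].T
    pooled = (resid ** 2).sum(axis=1) / S
    pooled = np.maximum(pooled, VARIANCE_FLOOR)
    sd = np.sqrt(pooled)

    z = (x_work - grand[:, None]) / sd[:, None]

    if B == 1:
        # degenerate single-batch model: identity transform
        return BatchModel(levels, grand, pooled, np.zeros((1, T)), np.ones((1, T)),
                          hyper={"degenerate": True}, condition_beta=cond_beta)

    gamma_hat = np.stack([z[:, idx == i].mean(axis=1) for i in range(B)])
    delta_hat = np.stack(
        [np.maximum(z[:, idx == i].var(axis=1, ddof=1), VARIANCE_FLOOR) for i in range(B)]
    )

    if T < 2:
        # a single transcript gives the priors nothing to borrow from:
        # keep the naive per-batch estimates
        return BatchModel(levels, grand, pooled, gamma_hat, delta_hat,
                          hyper={"degenerate": True}, condition_beta=cond_beta)

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    v_bar = delta_hat.mean(axis=1)
    s_sq = delta_hat.var(axis=1, ddof=1)
    # inverse-gamma prior by moment matching (classic aprior/bprior)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = np.where(s_sq > 0, (2 * s_sq + v_bar ** 2) / s_sq, np.inf)
        b_prior = np.where(s_sq > 0, (v_bar * s_sq + v_bar ** 3) / s_sq, v_bar)

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for i in range(B):
        g, d = gamma_hat[i], delta_hat[i]
        n = n_b[i]
        ssq = np.array([(z[t, idx == i] ** 2).sum() for t in range(T)])
        sum_z = np.array([z[t, idx == i].sum() for t in range(T)])
        g_new, d_new = g.copy(), d.copy()
        if not np.isfinite(tau_sq[i]) or tau_sq[i] <= 0:
            gamma_star[i] = np.full(T, gamma_bar[i])
            delta_star[i] = d
            continue
        for _ in range(EB_MAX_ITER):
            g_old, d_old = g_new.copy(), d_new.copy()
            g_new = (n * tau_sq[i] * g + d_new * gamma_bar[i]) / (n * tau_sq[i] + d_new)
            sse = ssq - 2 * g_new * sum_z + n * g_new ** 2
            if np.isfinite(a_prior[i]) and n / 2 + a_prior[i] - 1 > 0:
                d_new = (b_prior[i] + 0.5 * sse) / (n / 2 + a_prior[i] - 1)
            else:
                d_new = sse / n
            d_new = np.maximum(d_new, VARIANCE_FLOOR)
            if max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max()) < EB_TOL:
                break
        gamma_star[i] = g_new
        delta_star[i] = d_new

    hyper = {
        "gamma_bar": gamma_bar.tolist(),
        "tau_sq": tau_sq.tolist(),
        "a_prior": np.asarray(a_prior, dtype=float).tolist(),
        "b_prior": np.asarray(b_prior, dtype=float).tolist(),
        "n_per_batch": n_b.tolist(),
    }
    return BatchModel(levels, grand, pooled, gamma_star, delta_star,
                      hyper=hyper, condition_beta=cond_beta)


def combat_apply(
    model: BatchModel, logexpr: np.ndarray, batches, condition: np.ndarray | None = None
) -> np.ndarray:
    """Apply a fitted batch model to (training or held-out) log-expression.

    ``X* = sd/delta* (Z - gamma*) + grand_mean`` with ``Z`` the model's
    standardization of ``X``.  Deterministic; raises KeyError for batch labels
    unseen at fit.  ``condition`` is required exactly when the model was fit
    in protected mode (the protected effect is removed before and restored
    after adjustment).
    """
    x = np.asarray(logexpr, dtype=float)
    batches = np.asarray([str(b) for b in np.asarray(batches)])
    idx = _batch_index(batches, model.batch_levels)
    sd = np.sqrt(model.pooled_var)

    cond_term = 0.0
    if model.condition_beta is not None:
        if condition is None:
            raise ValueError("model was fit with a protected condition; labels required")
        cond = np.asarray(condition, dtype=float)
        cond_term = model.condition_beta[:, None] * (cond - cond.mean())[None, :]

    z = (x - cond_term - model.grand_mean[:, None]) / sd[:, None]
    gamma = model.gamma_star[idx, :].T
    delta = np.sqrt(model.delta_sq_star[idx, :].T)
    out = sd[:, None] * (z - gamma) / delta + model.grand_mean[:, None]
    return out + cond_term


def combat_fit_transform(logexpr: np.ndarray, batches, condition=None) -> np.ndarray:
    """Convenience: fit on the data and adjust it (classic joint usage)."""
    model = combat_fit(logexpr, batches, condition=condition)
    return combat_apply(model, logexpr, batches, condition=condition)
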