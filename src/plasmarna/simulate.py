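"""Synthetic plasma small-ncRNA cohorts with the statistical structure the
analysis assumes.

Counts are negative-binomial (Var = mu + alpha mu^2) over library-size-scaled
per-transcript baselines, with multiplicative per-batch factors (emulating
processing-date batches), planted condition fold changes (optionally the 25
published signature values), a transcript whose latent abundance is coupled to
clinical risk markers (MAP, UT PI), and a paired second-trimester subset.
Clinical covariates are drawn to match the published cohort's per-group
medians/IQRs (log-normal fits) and category counts.  Everything is
reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable, load_pe_signature

_Z75 = 0.6744897501960817   # 75th percentile of the standard normal

#: per-group (median, Q1, Q3) of the continuous clinical covariates
CLINICAL_CONTINUOUS: dict[str, dict[str, tuple[float, float, float]]] = {
    "maternal_age": {"control": (31.3, 25.9, 34.6), "PE": (29.9, 28.1, 34.5)},
    "BMI": {"control": (24.1, 22.6, 28.7), "PE": (28.4, 24.4, 31.7)},
    "gestational_age": {"control": (12.8, 12.3, 13.2), "PE": (12.7, 12.2, 13.1)},
    "crown_rump_length": {"control": (63.9, 57.5, 70.2), "PE": (62.9, 56.2, 67.9)},
    "MAP": {"control": (83.2, 79.4, 87.7), "PE": (97.1, 90.1, 108.7)},
    "UT_PI": {"control": (1.5, 1.3, 1.7), "PE": (2.5, 2.0, 2.8)},
    "gestational_age_delivery": {"control": (39.8, 39.4, 40.7), "PE": (31.4, 29.4, 33.2)},
    "birth_weight": {"control": (3420, 3198, 3578), "PE": (1222, 951, 1565)},
}

#: per-group category counts of the categorical clinical covariates
CLINICAL_CATEGORICAL: dict[str, dict[str, dict[str, int]]] = {
    "fetal_gender": {
        "control": {"female": 22, "male": 18},
        "PE": {"female": 17, "male": 18},
    },
    "ethnicity": {
        "control": {"Afro-Caribbean": 15, "South Asian": 1, "Caucasian": 24},
        "PE": {"Afro-Caribbean": 19, "South Asian": 1, "Caucasian": 15},
    },
    "smoking": {
        "control": {"no": 34, "yes": 6},
        "PE": {"no": 34, "yes": 1},
    },
    "family_history": {
        "control": {"yes": 2, "no": 38},
        "PE": {"yes": 4, "no": 31},
    },
    "parity": {
        "control": {"multiparous_no_pe": 15, "multiparous_previous_pe": 0,
                    "nulliparous": 25},
        "PE": {"multiparous_no_pe": 6, "multiparous_previous_pe": 8,
               "nulliparous": 21},
    },
    "chronic_hypertension": {
        "control": {"yes": 0, "no": 40},
        "PE": {"yes": 8, "no": 27},
    },
}


def signature_fold_changes() -> tuple[list[str], np.ndarray]:
    """The 25 published signature transcripts and their printed fold changes."""
    sig = load_pe_signature()
    return sig["transcript_id"].tolist(), sig["fold_change"].to_numpy(dtype=float)


@dataclass
class CouplingSpec:
    """Planted latent coupling between one transcript and clinical features.

    The transcript's latent log-mean gains a component built from the
    cohort-level z-scores of the target features, scaled so that its Pearson
    correlation with each feature equals ``r`` (the coupled features
    themselves share a within-group factor at correlation ``feature_corr``,
    as clinical risk markers do).  ``tau`` is the log-scale SD the coupling
    contributes to that transcript's abundance.
    """

    transcript_index: int = 7            # the miR-4433b-like foreground slot
    features: tuple[str, ...] = ("MAP", "UT_PI")
    r: float = 0.4
    tau: float = 0.8                     # latent log-sd carried by the coupling
    feature_corr: float = 0.3

    def __post_init__(self) -> None:
        if not (abs(self.r) < 1):
            raise ValueError("coupling r must satisfy |r| < 1")
        if not (0 <= self.feature_corr < 1):
            raise ValueError("feature_corr must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Generative truth for a synthetic cohort (defaults mirror the study
    design: 35 PE vs 40 control first-trimester samples, two processing
    batches, top-100 foreground transcripts, NB dispersion 0.2, a 20+20
    paired second-trimester subset)."""

    n_pe: int = 35
    n_control: int = 40
    n_foreground: int = 100
    n_background: int = 150
    library_size_median: float = 1.0
    library_size_log_sd: float = 0.25
    baseline_range: tuple[float, float] = (100.0, 30_000.0)
    background_range: tuple[float, float] = (1.0, 50.0)
    fold_changes: np.ndarray | None = None      # per foreground transcript; default 1
    dispersion: float | np.ndarray = 0.2
    n_batches: int = 2
    batch_log_sd: float = 0.2                   # per-transcript log batch-factor SD
    coupling: CouplingSpec | None = field(default_factory=CouplingSpec)
    second_trimester: tuple[int, int] = (20, 20)   # (PE, control) paired subset
    trimester_effect: float | np.ndarray = 1.0
    interaction_effect: float | np.ndarray = 1.0
    qpcr_noise_sd: float = 0.25
    qpcr_c0: float = 30.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pe < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        if self.fold_changes is not None:
            fc = np.asarray(self.fold_changes, dtype=float)
            if (fc <= 0).any():
                raise ValueError("fold changes must be positive")
            if len(fc) > self.n_foreground:
                raise ValueError("more fold changes than foreground transcripts")
            self.fold_changes = fc
        disp = np.asarray(self.dispersion, dtype=float)
        if (disp < 0).any():
            raise ValueError("dispersion must be >= 0")
        if self.second_trimester[0] > self.n_pe or self.second_trimester[1] > self.n_control:
            raise ValueError("second-trimester subset larger than the cohort")
        if (self.coupling is not None
                and self.coupling.transcript_index >= self.n_foreground):
            raise ValueError("coupling transcript_index outside the foreground set")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


@dataclass
class SyntheticDataset:
    counts: CountMatrix          # all samples (both trimesters)
    metadata: SampleTable
    truth: dict                  # realized latent means, factors, config echo

    def first_trimester(self) -> tuple[CountMatrix, SampleTable]:
        ids = self.metadata.frame.loc[
            self.metadata.frame["trimester"] == 1, "sample_id"
        ].tolist()
        return self.counts.select_samples(ids), self.metadata.select(ids)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic cohort from ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.rng_seed)
    n1 = config.n_pe + config.n_control
    T = config.n_foreground + config.n_background

    sample_ids = [f"PE{i + 1:03d}" for i in range(config.n_pe)] + \
                 [f"CT{i + 1:03d}" for i in range(config.n_control)]
    is_pe = np.array([1] * config.n_pe + [0] * config.n_control)

    # balanced random batch assignment within each condition group
    batch = np.empty(n1, dtype=object)
    for grp in (np.where(is_pe == 1)[0], np.where(is_pe == 0)[0]):
        order = rng.permutation(grp)
        for j, idx in enumerate(order):
            batch[idx] = f"B{j % config.n_batches + 1}"

    # clinical covariates, then the coupled latent component derived from the
    # realized cohort z-scores of the target features
    clinical = _draw_clinical(rng, is_pe, config.coupling)
    coupling_score = _coupling_score(rng, clinical, config.coupling)

    # per-transcript baselines, fold changes, dispersions, batch factors
    lo, hi = config.baseline_range
    blo, bhi = config.background_range
    baseline = np.concatenate([
        np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_foreground)),
        np.exp(rng.uniform(np.log(blo), np.log(bhi), config.n_background)),
    ])
    fc = np.ones(T)
    if config.fold_changes is not None:
        fc[: len(config.fold_changes)] = config.fold_changes
    alpha = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (T,)).copy()
    batch_levels = [f"B{k + 1}" for k in range(config.n_batches)]
    batch_log_factors = np.zeros((config.n_batches, T))
    if config.n_batches > 1:
        batch_log_factors[1:] = rng.normal(0.0, config.batch_log_sd,
                                           (config.n_batches - 1, T))

    lib1 = np.exp(rng.normal(np.log(config.library_size_median),
                             config.library_size_log_sd, n1))

    trim_eff = np.broadcast_to(np.asarray(config.trimester_effect, dtype=float), (T,))
    inter_eff = np.broadcast_to(np.asarray(config.interaction_effect, dtype=float), (T,))

    def latent_log_mu(sample_idx: np.ndarray, trimester2: bool) -> np.ndarray:
        """T x n latent log expression (library-size free) for given women."""
        pe = is_pe[sample_idx].astype(float)
        lm = np.log(baseline)[:, None] + np.log(fc)[:, None] * pe[None, :]
        if trimester2:
            lm += np.log(trim_eff)[:, None]
            lm += np.log(inter_eff)[:, None] * pe[None, :]
        if config.coupling is not None:
            c = config.coupling
            lm[c.transcript_index, :] += c.tau * coupling_score[sample_idx]
        return lm

    # counts are Gamma-Poisson: the Gamma component is the woman's realized
    # biological expression (shared with qPCR), the Poisson layer is the
    # sequencing sampling given library size and batch factor; marginally the
    # counts are NB with Var = mu + alpha mu^2
    bidx1 = np.array([batch_levels.index(b) for b in batch])
    log_mu1 = latent_log_mu(np.arange(n1), False)
    bio1 = _biological_expression(rng, np.exp(log_mu1), alpha)
    counts1 = rng.poisson(bio1 * np.exp(batch_log_factors[bidx1, :].T) * lib1[None, :])

    meta1 = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": np.where(is_pe == 1, "PE", "control"),
        "batch": batch,
        "trimester": 1,
        "pair_id": "",
        **clinical,
    })

    # paired second-trimester subset: random women per group, new draws from
    # the same per-woman latent means (no extra within-woman correlation)
    n2_pe, n2_ct = config.second_trimester
    pe_pick = rng.choice(np.where(is_pe == 1)[0], n2_pe, replace=False)
    ct_pick = rng.choice(np.where(is_pe == 0)[0], n2_ct, replace=False)
    pick = np.sort(np.concatenate([pe_pick, ct_pick]).astype(int))

    frames = [meta1]
    all_counts = [counts1]
    all_ids = list(sample_ids)
    log_mu2 = bio2 = None
    if len(pick):
        lib2 = np.exp(rng.normal(np.log(config.library_size_median),
                                 config.library_size_log_sd, len(pick)))
        batch2 = np.array([f"B{j % config.n_batches + 1}" for j in range(len(pick))],
                          dtype=object)
        bidx2 = np.array([batch_levels.index(b) for b in batch2])
        log_mu2 = latent_log_mu(pick, True)
        bio2 = _biological_expression(rng, np.exp(log_mu2), alpha)
        counts2 = rng.poisson(bio2 * np.exp(batch_log_factors[bidx2, :].T)
                              * lib2[None, :])
        ids2 = [f"{sample_ids[i]}-T2" for i in pick]
        meta2 = meta1.iloc[pick].copy()
        meta2["sample_id"] = ids2
        meta2["pair_id"] = [sample_ids[i] for i in pick]
        meta2["trimester"] = 2
        meta2["batch"] = batch2
        frames.append(meta2)
        all_counts.append(counts2)
        all_ids += ids2

    transcript_ids = [f"FG{i + 1:04d}" for i in range(config.n_foreground)] + \
                     [f"BG{i + 1:04d}" for i in range(config.n_background)]
    biotypes = _default_biotypes(config.n_foreground, config.n_background)
    cm = CountMatrix(transcript_ids, biotypes,
                     all_ids, np.concatenate(all_counts, axis=1))
    metadata = SampleTable(pd.concat(frames, ignore_index=True))

    truth = {
        "config": config.to_dict(),
        "transcript_ids": transcript_ids,
        "baseline": baseline,
        "fold_changes": fc,
        "dispersion": alpha,
        "batch_levels": batch_levels,
        "batch_log_factors": batch_log_factors,
        "library_sizes": np.concatenate([lib1, lib2]) if len(pick) else lib1,
        "latent_log_mu": np.concatenate([log_mu1, log_mu2], axis=1)
        if log_mu2 is not None else log_mu1,
        "biological_expression": np.concatenate([bio1, bio2], axis=1)
        if bio2 is not None else bio1,
        "coupling_score": coupling_score,
    }
    return SyntheticDataset(cm, metadata, truth)


def _biological_expression(
    rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Per-woman realized expression: Gamma with mean mu and CV^2 = alpha
    (the NB mixing component); degenerate at mu when alpha ~ 0."""
    out = mu.astype(float).copy()
    mix = alpha >= 1e-8
    if mix.any():
        shape = 1.0 / alpha[mix]
        out[mix] = rng.gamma(shape[:, None], alpha[mix][:, None] * mu[mix])
    return out


def _draw_clinical(
    rng: np.random.Generator,
    is_pe: np.ndarray,
    coupling: CouplingSpec | None,
) -> dict[str, np.ndarray]:
    """Clinical covariates per woman: log-normal fits to the published
    per-group median/IQR for continuous variables, empirical category
    proportions for categorical ones.  Coupled features share a within-group
    factor at the configured feature_corr."""
    n = len(is_pe)
    out: dict[str, np.ndarray] = {}
    coupled = set(coupling.features) if coupling is not None else set()
    shared = rng.standard_normal(n)
    lam = np.sqrt(coupling.feature_corr) if coupling is not None else 0.0
    for name, groups in CLINICAL_CONTINUOUS.items():
        vals = np.empty(n)
        if name in coupled:
            score = lam * shared + np.sqrt(1 - lam ** 2) * rng.standard_normal(n)
        else:
            score = rng.standard_normal(n)
        for label, mask in (("PE", is_pe == 1), ("control", is_pe == 0)):
            med, q1, q3 = groups[label]
            sigma = (np.log(q3) - np.log(q1)) / (2 * _Z75)
            vals[mask] = np.exp(np.log(med) + sigma * score[mask])
        out[name] = np.round(vals, 3)
    for name, groups in CLINICAL_CATEGORICAL.items():
        vals = np.empty(n, dtype=object)
        for label, mask in (("PE", is_pe == 1), ("control", is_pe == 0)):
            cats = list(groups[label])
            p = np.array([groups[label][c] for c in cats], dtype=float)
            vals[mask] = rng.choice(cats, mask.sum(), p=p / p.sum())
        out[name] = vals
    return out


def _coupling_score(
    rng: np.random.Generator,
    clinical: dict[str, np.ndarray],
    coupling: CouplingSpec | None,
) -> np.ndarray:
    """Unit-variance score correlating at ``r`` with each coupled feature.

    Built from the realized cohort z-scores of the target features: with K
    equicorrelated features at average correlation rho, the loading on their
    mean z is c = r K / (1 + (K-1) rho); the residual weight keeps unit
    variance.  Raises if the requested r is infeasible for the realized rho.
    """
    if coupling is None:
        return np.zeros(len(next(iter(clinical.values()))))
    z = []
    for f in coupling.features:
        v = np.asarray(clinical[f], dtype=float)
        z.append((v - v.mean()) / v.std())
    z = np.stack(z)
    K = z.shape[0]
    rho = 0.0
    if K > 1:
        pairs = [np.corrcoef(z[i], z[j])[0, 1]
                 for i in range(K) for j in range(i + 1, K)]
        rho = float(np.mean(pairs))
    denom = 1 + (K - 1) * rho
    c = coupling.r * K / denom
    var_zbar = denom / K
    resid = 1.0 - c ** 2 * var_zbar
    if resid < 0:
        raise ValueError(
            f"coupling r={coupling.r} infeasible for {K} features with "
            f"realized inter-feature correlation {rho:.3f}"
        )
    score = c * z.mean(axis=0) + np.sqrt(resid) * rng.standard_normal(z.shape[1])
    return score


def _default_biotypes(n_fg: int, n_bg: int) -> list[str]:
    """Foreground biotypes cycle through the classes seen in plasma small-RNA
    data; background transcripts are generic low-abundance ncRNA."""
    classes = ["miRNA", "Mitochondrial tRNA", "lincRNA", "snoRNA", "snRNA", "rRNA"]
    fg = [classes[i % len(classes)] for i in range(n_fg)]
    return fg + ["misc_ncRNA"] * n_bg


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    dataset: SyntheticDataset,
    transcripts: Sequence[str],
    sample_ids: Sequence[str] | None = None,
    noise_sd: float | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulated RT-qPCR of the given transcripts.

    Ct = c0 - log2(latent expression) + Normal(0, noise SD), and the cDNA
    concentration is proportional to the library size with mild noise, so
    2^-Ct normalized by cDNA concentration tracks the transcript's normalized
    counts.  Returns a long table: sample_id, transcript_id, ct,
    cdna_concentration.
    """
    cfg = dataset.truth["config"]
    if noise_sd is None:
        noise_sd = cfg["qpcr_noise_sd"]
    c0 = cfg["qpcr_c0"]
    rng = np.random.default_rng(rng_seed)
    all_ids = dataset.counts.sample_ids
    if sample_ids is None:
        sample_ids = all_ids
    tindex = {t: i for i, t in enumerate(dataset.truth["transcript_ids"])}
    for t in transcripts:
        if t not in tindex:
            raise KeyError(f"unknown transcript id {t!r}")
    sindex = {s: j for j, s in enumerate(all_ids)}
    for s in sample_ids:
        if s not in sindex:
            raise KeyError(f"unknown sample id {s!r}")

    bio = dataset.truth["biological_expression"]
    libs = dataset.truth["library_sizes"]
    rows = []
    cdna = {}
    for s in sample_ids:
        j = sindex[s]
        cdna[s] = libs[j] * np.exp(rng.normal(0.0, 0.1))
    for t in transcripts:
        i = tindex[t]
        for s in sample_ids:
            j = sindex[s]
            # the measured quantity is the woman's realized expression times
            # the RNA input amount (the library-size analog); cDNA
            # normalization divides the input amount back out
            ct = c0 - np.log2(bio[i, j] * libs[j]) + rng.normal(0.0, noise_sd)
            rows.append({"sample_id": s, "transcript_id": t, "ct": ct,
                         "cdna_concentration": cdna[s]})
    return pd.DataFrame(rows)
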