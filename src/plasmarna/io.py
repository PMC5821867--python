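"""Data model and file formats for plasma small-ncRNA count analysis.

The pipeline's universal input is a transcripts x samples matrix of integer
read counts (with a biotype annotation per transcript) plus a sample metadata
table carrying the condition label (``PE`` vs ``control``), a processing-batch
label, the trimester of sampling, and clinical covariates.  Both are stored as
plain tab-separated files; classifier reports are JSON.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CONDITIONS = ("control", "PE")

#: metadata columns that are required, in canonical order
REQUIRED_SAMPLE_COLUMNS = ("sample_id", "condition", "batch")


class FormatError(ValueError):
    """A file violates the expected on-disk layout (duplicate keys, bad header)."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer read counts, transcripts x samples, with biotype annotations.

    Invariants: transcript and sample ids unique, counts nonnegative integers,
    dimensions consistent.  Validated on construction.
    """

    transcript_ids: list[str]
    biotypes: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.transcript_ids = list(self.transcript_ids)
        self.biotypes = list(self.biotypes)
        self.sample_ids = list(self.sample_ids)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ValueError(
                    f"non-integer count at transcript "
                    f"{self.transcript_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at transcript {self.transcript_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.counts.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.transcript_ids)} transcripts x {len(self.sample_ids)} samples"
            )
        if len(self.biotypes) != len(self.transcript_ids):
            raise ValueError("one biotype required per transcript")
        _check_unique(self.transcript_ids, "transcript id")
        _check_unique(self.sample_ids, "sample id")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def biotype_of(self, transcript_id: str) -> str:
        return self.biotypes[self.transcript_ids.index(transcript_id)]

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            self.transcript_ids, self.biotypes, list(sample_ids), self.counts[:, idx]
        )

    def select_transcripts(self, transcript_ids: Sequence[str]) -> "CountMatrix":
        pos = {t: i for i, t in enumerate(self.transcript_ids)}
        idx = [pos[t] for t in transcript_ids]
        return CountMatrix(
            list(transcript_ids),
            [self.biotypes[i] for i in idx],
            self.sample_ids,
            self.counts[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "biotype", self.biotypes)
        df.insert(0, "transcript_id", self.transcript_ids)
        return df


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


def read_count_matrix(path) -> CountMatrix:
    """Read a counts TSV: header of sample ids, first two columns
    ``transcript_id`` and ``biotype``.  Row order is preserved."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3 or tuple(df.columns[:2]) != ("transcript_id", "biotype"):
        raise FormatError(
            "counts file must start with columns 'transcript_id' and 'biotype' "
            "followed by one column per sample"
        )
    counts = df.iloc[:, 2:]
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"non-numeric count for transcript {df.iloc[row, 0]!r} in sample {col!r}"
            )
    return CountMatrix(
        df.iloc[:, 0].tolist(),
        df.iloc[:, 1].tolist(),
        [str(c) for c in counts.columns],
        counts.to_numpy(),
    )


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample metadata: condition, batch, trimester and clinical covariates.

    Backed by a pandas DataFrame with one row per sample.  Condition must be
    ``PE`` or ``control`` and batch non-missing for every sample; every other
    column is carried along as a clinical covariate.  Second-trimester rows
    reference the first-trimester sample of the same woman via ``pair_id``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"sample table missing required column {col!r}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample id")
        bad = ~df["condition"].isin(CONDITIONS)
        if bad.any():
            off = df.loc[bad].iloc[0]
            raise ValueError(
                f"sample {off['sample_id']!r}: condition {off['condition']!r} "
                f"not in {set(CONDITIONS)}"
            )
        if df["batch"].isna().any():
            off = df.loc[df["batch"].isna(), "sample_id"].iloc[0]
            raise ValueError(f"sample {off!r}: missing batch label")
        df["batch"] = df["batch"].astype(str)
        if "pair_id" in df.columns:
            df["pair_id"] = df["pair_id"].fillna("").astype(str)
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def condition(self) -> np.ndarray:
        return self.frame["condition"].to_numpy()

    @property
    def batch(self) -> np.ndarray:
        return self.frame["batch"].to_numpy()

    def is_pe(self) -> np.ndarray:
        """Binary labels, 1 = PE."""
        return (self.frame["condition"].to_numpy() == "PE").astype(int)

    def select(self, sample_ids: Sequence[str]) -> "SampleTable":
        sub = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(sub)

    def clinical_columns(self) -> list[str]:
        skip = set(REQUIRED_SAMPLE_COLUMNS) | {"trimester", "pair_id"}
        return [c for c in self.frame.columns if c not in skip]


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t"))


def write_sample_table(table: SampleTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters of the DE + classification pipeline.

    Defaults mirror the published analysis where a value is printed (100 outer
    iterations, 5 inner folds, models of at most six transcripts, correlation
    collapse threshold 0.7, top-100 abundance filter, FDR 0.05); the outer
    test fraction (0.2) and classification threshold (0.5) are gap-filling
    defaults, reported in every output.
    """

    n_outer_iterations: int = 100
    inner_folds: int = 5
    max_model_size: int = 6
    correlation_threshold: float = 0.7
    abundance_top_k: int = 100
    fdr_alpha: float = 0.05
    classification_threshold: float = 0.5
    test_fraction: float = 0.2
    fpr_levels: tuple[float, ...] = (0.10, 0.05)
    n_permutations: int = 20
    rng_seed: int = 0
    exhaustive_model_budget: int = 100_000
    signed_correlation: bool = False
    protect_condition: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 0.5):
            raise ValueError("test_fraction must be in (0, 0.5)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.max_model_size < 1:
            raise ValueError("max_model_size must be >= 1")
        for name in ("correlation_threshold", "fdr_alpha", "classification_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        self.fpr_levels = tuple(self.fpr_levels)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["fpr_levels"] = list(self.fpr_levels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(report, path) -> None:
    """Serialize a report object (ClassifierReport, PermutationReport, ...) to JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else _jsonify(report)
    with open(path, "w") as fh:
        json.dump(_jsonify(payload), fh, indent=2)
        fh.write("\n")


def read_report(path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Published signature table
# ---------------------------------------------------------------------------

def load_pe_signature() -> pd.DataFrame:
    """Published 25-transcript differential-expression signature of first-trimester
    plasma small ncRNA in early-onset preeclampsia vs control.

    Columns: transcript, transcript_id, biotype, mean_counts, fold_change
    (PE over control, linear scale), p_value, adjusted_p_value.
    """
    ref = importlib.resources.files("plasmarna").joinpath("data/pe_signature.tsv")
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
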