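"""Assembling (sample, drug) feature tables and response cleaning.

A feature row is the concatenation of the sample's pathway-score column
(P values) and the drug's descriptor vector (E values), so the table is
F = P + E columns wide; the response is LN IC50 (regression) or a binary
responder label (classification).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pathway_scoring import PathwayScoreMatrix

logger = logging.getLogger(__name__)

TASKS = ("regression", "classification")


@dataclass
class ResponseTable:
    """(sample_id, drug_id, response) records plus the task they encode."""

    records: pd.DataFrame
    task: str = "regression"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        need = {"sample_id", "drug_id", "response"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValueError(f"response table missing columns: {sorted(missing)}")
        if self.task == "classification":
            labels = set(pd.unique(self.records["response"]))
            if not labels <= {0, 1, 0.0, 1.0}:
                raise ValueError(f"classification labels must be 0/1, got {labels}")

    def __len__(self) -> int:
        return len(self.records)


def read_response_table(path: str | Path, task: str = "regression") -> ResponseTable:
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    df["drug_id"] = df["drug_id"].astype(str)
    df["response"] = pd.to_numeric(df["response"])
    return ResponseTable(df, task=task)


def average_duplicate_responses(r: ResponseTable) -> ResponseTable:
    """One record per (sample, drug); duplicate LN IC50 values are averaged.

    For classification, duplicates must agree — conflicting 0/1 labels for
    the same pair are an error.
    """
    grouped = r.records.groupby(["sample_id", "drug_id"], sort=False)["response"]
    if r.task == "classification":
        nuniq = grouped.nunique()
        conflicts = nuniq[nuniq > 1]
        if len(conflicts):
            raise ValueError(
                f"conflicting binary labels for pairs: {list(conflicts.index)[:5]}")
    out = grouped.mean().reset_index()
    n_dup = len(r.records) - len(out)
    if n_dup:
        logger.info("average_duplicate_responses: merged %d duplicate records", n_dup)
    return ResponseTable(out, task=r.task)


def iqr_filter(values) -> tuple[np.ndarray, list[int]]:
    """Tukey fences: retain v iff Q1 - 1.5*IQR <= v <= Q3 + 1.5*IQR.

    Quartiles use the linear-interpolation (type-7) convention.  Returns
    (retained values, indices of dropped values).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("IQR filter needs a flat list of >= 4 values")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (v >= lo) & (v <= hi)
    dropped = [int(i) for i in np.where(~keep)[0]]
    return v[keep], dropped


@dataclass
class FeatureTable:
    """Rows = (sample, drug) pairs; X = pathway block ++ drug block; y = response."""

    keys: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray
    pathway_names: list[str]
    drug_dims: list[str]
    task: str = "regression"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.keys), self.F):
            raise ValueError(
                f"X shape {self.X.shape} != ({len(self.keys)}, {self.F})")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate (sample, drug) row keys")
        if np.isnan(self.X).any():
            raise ValueError("feature table contains missing values; impute first")

    @property
    def P(self) -> int:
        return len(self.pathway_names)

    @property
    def E(self) -> int:
        return len(self.drug_dims)

    @property
    def F(self) -> int:
        return self.P + self.E

    @property
    def column_names(self) -> list[str]:
        return [*self.pathway_names, *self.drug_dims]

    @property
    def samples(self) -> list[str]:
        return [s for s, _ in self.keys]

    @property
    def drugs(self) -> list[str]:
        return [d for _, d in self.keys]

    def __len__(self) -> int:
        return len(self.keys)

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            keys=[self.keys[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
            pathway_names=self.pathway_names,
            drug_dims=self.drug_dims,
            task=self.task,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "sample_id", self.samples)
        df.insert(1, "drug_id", self.drugs)
        df["response"] = self.y
        df.to_csv(path, sep="\t", index=False)

    def schema(self) -> dict:
        return {
            "F": self.F,
            "P": self.P,
            "E": self.E,
            "task": self.task,
            "columns": self.column_names,
        }

    def write_schema(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.schema(), indent=1))


def read_feature_table(path: str | Path, schema_path: str | Path) -> FeatureTable:
    schema = json.loads(Path(schema_path).read_text())
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "drug_id": str})
    P, E = schema["P"], schema["E"]
    cols = schema["columns"]
    return FeatureTable(
        keys=list(zip(df["sample_id"], df["drug_id"])),
        X=df[cols].to_numpy(dtype=float),
        y=df["response"].to_numpy(dtype=float),
        pathway_names=cols[:P],
        drug_dims=cols[P:],
        task=schema["task"],
    )


def assemble_feature_table(
    scores: PathwayScoreMatrix,
    drug_vectors: pd.DataFrame,
    responses: ResponseTable,
    strict: bool = False,
) -> FeatureTable:
    """Join pathway scores and drug descriptors on the response records.

    Records whose sample or drug has no features are dropped with a logged
    count (``strict=True`` raises instead); zero assemblable rows is always
    an error.
    """
    sample_cols = {s: i for i, s in enumerate(scores.samples)}
    drug_rows = {d: i for i, d in enumerate(drug_vectors.index)}
    S = scores.data.to_numpy(dtype=float)
    D = drug_vectors.to_numpy(dtype=float)
    keys, rows, ys = [], [], []
    n_dropped = 0
    for rec in responses.records.itertuples(index=False):
        s, d = str(rec.sample_id), str(rec.drug_id)
        if s not in sample_cols or d not in drug_rows:
            n_dropped += 1
            if strict:
                raise ValueError(f"record ({s}, {d}) has no features (strict mode)")
            continue
        keys.append((s, d))
        rows.append(np.concatenate([S[:, sample_cols[s]], D[drug_rows[d]]]))
        ys.append(rec.response)
    if n_dropped:
        logger.info("assemble_feature_table: dropped %d unmatched records", n_dropped)
    if not keys:
        raise ValueError("no assemblable rows: responses match no sample/drug features")
    return FeatureTable(
        keys=keys,
        X=np.vstack(rows),
        y=np.asarray(ys, dtype=float),
        pathway_names=scores.pathways,
        drug_dims=list(drug_vectors.columns),
        task=responses.task,
    )


def zscore_by_drug(pred: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Z-score a (sample_id, drug_id, value) table per drug across samples.

    Uses the sample standard deviation; a drug with zero spread maps to all
    zeros (logged).
    """
    out = pred.copy()
    for drug, grp in out.groupby("drug_id", sort=False):
        v = grp[value_col].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"drug {drug!r} has <2 samples; cannot z-score")
        sd = v.std(ddof=1)
        if sd == 0:
            logger.info("zscore_by_drug: drug %s has zero spread; zeros emitted", drug)
            z = np.zeros_like(v)
        else:
            z = (v - v.mean()) / sd
        out.loc[grp.index, value_col] = z
    return out
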