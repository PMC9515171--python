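"""Reading and normalizing gene expression matrices.

Everything downstream of this module consumes log2(TPM + 1) values with
genes in rows and samples in columns.  Readers accept either orientation;
all other units (raw counts, UMI counts, RPKM, RSEM scaled estimates) are
converted to TPM first and log-transformed afterwards.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized expression units.
UNITS = ("counts", "umi", "tpm", "rpkm", "scaled_estimate", "log2tpm1")

#: Units on a linear (non-log) scale.
LINEAR_UNITS = ("counts", "umi", "tpm", "rpkm", "scaled_estimate")

TPM_TOTAL = 1e6
TPM_RTOL = 1e-6


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with a declared unit.

    ``data`` carries gene identifiers in the index and sample IDs in the
    columns.  Gene identifiers may be duplicated immediately after reading
    (e.g. multiple Ensembl IDs per symbol); :func:`collapse_gene_ids`
    resolves that.
    """

    data: pd.DataFrame
    unit: str = "tpm"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if self.unit == "log2tpm1" and (self.data.to_numpy() < 0).any():
            raise ValueError("log2tpm1 matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def has_duplicate_genes(self) -> bool:
        return bool(self.data.index.duplicated().any())

    def check_tpm(self) -> None:
        """Assert that every column sums to 1e6 within relative tolerance."""
        sums = self.data.sum(axis=0).to_numpy()
        if not np.allclose(sums, TPM_TOTAL, rtol=TPM_RTOL, atol=0):
            bad = self.data.columns[~np.isclose(sums, TPM_TOTAL, rtol=TPM_RTOL, atol=0)]
            raise ValueError(f"TPM columns do not sum to 1e6: {list(bad)[:5]}")


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | Path,
    unit: str,
    orientation: str = "genes-in-rows",
) -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV/CSV, gzip-transparent).

    The file must have one header row of sample IDs and a leading column of
    gene identifiers (or the transpose, with ``orientation="samples-in-rows"``).
    Any cell that does not parse as a number (including "NA") raises a
    ``ValueError`` naming the offending row and column.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"bad orientation {orientation!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.empty:
        raise ValueError(f"{path}: empty expression file")
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        mask = values.isna()
        j = int(np.argmax(mask.any(axis=0).to_numpy()))
        i = int(np.argmax(mask.iloc[:, j].to_numpy()))
        raise ValueError(
            f"{path}: non-numeric cell {raw.iloc[i, j]!r} at row "
            f"{raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    if orientation == "samples-in-rows":
        values = values.T
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    m = ExpressionMatrix(values, unit=unit)
    if m.has_duplicate_genes():
        n = int(values.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene rows (collapse before scoring)", path, n)
    return m


def collapse_gene_ids(
    m: ExpressionMatrix, mapping: Mapping[str, str] | pd.DataFrame
) -> ExpressionMatrix:
    """Average all source rows that map to the same gene symbol.

    ``mapping`` is id -> symbol (dict, or a 2-column DataFrame).  Must be
    applied on a linear unit; averaging log-space values would not match
    averaging expression.  Unmapped genes are dropped with a logged count.
    """
    if m.unit not in LINEAR_UNITS:
        raise ValueError(f"collapse requires a linear unit, got {m.unit!r}")
    if isinstance(mapping, pd.DataFrame):
        mapping = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    symbols = m.data.index.map(lambda g: mapping.get(str(g)))
    covered = symbols.notna()
    if not covered.any():
        raise ValueError("gene-ID mapping covers zero input genes")
    dropped = int((~covered).sum())
    if dropped:
        logger.info("collapse_gene_ids: dropped %d unmapped genes", dropped)
    sub = m.data.loc[covered]
    sub = sub.groupby(symbols[covered].to_numpy(), sort=False).mean()
    sub.index = sub.index.astype(str)
    return ExpressionMatrix(sub, unit=m.unit)


def to_log2_tpm(
    m: ExpressionMatrix,
    gene_lengths: Mapping[str, float] | pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Convert any supported linear unit to log2(TPM + 1).

    counts are divided by gene length first (genes without a length are
    dropped, logged); UMI counts, RPKM and scaled estimates are rescaled
    column-wise so each column sums to 1e6; an input already in TPM only
    receives the log transform.
    """
    if m.unit == "log2tpm1":
        return m
    if m.unit not in LINEAR_UNITS:
        raise ValueError(f"cannot convert unit {m.unit!r}")
    values = m.data
    if m.unit == "counts":
        if gene_lengths is None:
            raise ValueError("unit='counts' requires gene_lengths")
        if isinstance(gene_lengths, pd.DataFrame):
            gene_lengths = dict(
                zip(gene_lengths.iloc[:, 0].astype(str),
                    pd.to_numeric(gene_lengths.iloc[:, 1])))
        lens = pd.Series([gene_lengths.get(str(g)) for g in values.index],
                         index=values.index, dtype=float)
        have = lens.notna()
        if not have.any():
            raise ValueError("no gene has a length; cannot convert counts")
        n_dropped = int((~have).sum())
        if n_dropped:
            logger.info("to_log2_tpm: dropped %d genes lacking a length", n_dropped)
        values = values.loc[have].div(lens[have], axis=0)
    if m.unit == "tpm":
        tpm = values
    else:
        sums = values.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero):
            raise ValueError(f"column sums to zero for sample(s): {list(zero.index)}")
        tpm = values.div(sums, axis=1) * TPM_TOTAL
        ExpressionMatrix(tpm, unit="tpm").check_tpm()
    return ExpressionMatrix(np.log2(tpm + 1.0), unit="log2tpm1")


def filter_expressed_genes(
    m: ExpressionMatrix, min_tpm: float = 1.0, min_frac: float = 0.10
) -> ExpressionMatrix:
    """Keep genes with TPM >= min_tpm in at least ceil(min_frac * n) samples."""
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError(f"min_frac must be in [0, 1], got {min_frac}")
    if m.unit != "tpm":
        raise ValueError("expressed-gene filter applies to TPM (before log transform)")
    n = m.shape[1]
    need = math.ceil(min_frac * n)
    keep = (m.data >= min_tpm).sum(axis=1) >= need
    return ExpressionMatrix(m.data.loc[keep], unit=m.unit)


def select_hv_genes(m: ExpressionMatrix, n: int = 500) -> list[str]:
    """Top-n genes by squared coefficient of variation, CV2 = var / mean^2.

    Sample variance (n-1 denominator).  Genes with mean 0 get CV2 = 0 and
    rank last; ties keep input order.  n larger than the gene count returns
    every gene (logged).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m.unit != "log2tpm1":
        raise ValueError("highly-variable selection expects log2tpm1 values")
    x = m.data.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(x.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean == 0, 0.0, var / mean**2)
    if n > len(cv2):
        logger.info("select_hv_genes: n=%d > %d genes; returning all", n, len(cv2))
        n = len(cv2)
    order = np.argsort(-cv2, kind="stable")
    return [m.genes[i] for i in order[:n]]


def average_replicates(m, grouping: Mapping[str, str] | pd.DataFrame):
    """Average replicate columns into one column per group.

    Accepts an :class:`ExpressionMatrix` or any sets/genes x samples
    DataFrame (e.g. pathway scores); returns the same type.  Group order
    follows first appearance in the sample list.
    """
    if isinstance(grouping, pd.DataFrame):
        grouping = dict(zip(grouping.iloc[:, 0].astype(str), grouping.iloc[:, 1].astype(str)))
    frame = m.data if isinstance(m, ExpressionMatrix) else m
    missing = [s for s in frame.columns if str(s) not in grouping]
    if missing:
        raise ValueError(f"samples missing from grouping: {missing[:5]}")
    groups = [grouping[str(s)] for s in frame.columns]
    order = list(dict.fromkeys(groups))
    out = frame.T.groupby(np.asarray(groups), sort=False).mean().T
    out = out[order]
    if isinstance(m, ExpressionMatrix):
        return ExpressionMatrix(out, unit=m.unit)
    return out
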