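"""Shared fixtures and the independent straight-line scoring oracle.

The oracle deliberately uses plain Python loops, ``math.erf`` and explicit
sorting — no code shared with the package — so tests comparing the two are
a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pathdrp import ExpressionMatrix, FeatureTable
from pathdrp.genesets import GeneSet, GeneSetCollection


# ---------------------------------------------------------------------------
# brute-force enrichment-score oracle

def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def oracle_kernel_cdf(x: list[list[float]]) -> tuple[list[list[float]], list[int]]:
    """zhat by direct double loop; returns (zhat rows, kept gene indices)."""
    kept = []
    zhat = []
    n = len(x[0])
    for i, row in enumerate(x):
        mean = sum(row) / n
        var = sum((v - mean) ** 2 for v in row) / (n - 1)
        if var == 0:
            continue
        h = math.sqrt(var) / 4.0
        kept.append(i)
        zhat.append([sum(_phi((row[j] - row[k]) / h) for k in range(n)) / n
                     for j in range(n)])
    return zhat, kept


def oracle_walk(rt_in_order: list[float], member_in_order: list[bool],
                tau: float = 1.0) -> list[float]:
    p = len(rt_in_order)
    m = sum(member_in_order)
    denom_in = sum(rt_in_order[i] ** tau for i in range(p) if member_in_order[i])
    nu = []
    cum_in = 0.0
    cum_out = 0.0
    for i in range(p):
        if member_in_order[i]:
            cum_in += rt_in_order[i] ** tau
        else:
            cum_out += 1.0
        nu.append(cum_in / denom_in - cum_out / (p - m))
    return nu


def oracle_gsva(
    x: list[list[float]],
    genes: list[str],
    sets: dict[str, set[str]],
    variant: str = "diff",
    tau: float = 1.0,
    min_size: int = 1,
) -> dict[str, list[float]]:
    """Full straight-line re-implementation: set name -> per-sample scores."""
    zhat, kept = oracle_kernel_cdf(x)
    kept_genes = [genes[i] for i in kept]
    p = len(kept_genes)
    n = len(x[0])
    out: dict[str, list[float]] = {}
    orders = []
    rts = []
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-zhat[i][j], i))
        rank = [0] * p
        for pos, gi in enumerate(order):
            rank[gi] = pos + 1
        rt = [abs(p / 2.0 - rank[i]) for i in range(p)]
        orders.append(order)
        rts.append(rt)
    for name, members in sets.items():
        inter = set(members) & set(kept_genes)
        if not (min_size <= len(inter) < p):
            continue
        scores = []
        for j in range(n):
            order = orders[j]
            rt_o = [rts[j][gi] for gi in order]
            mem_o = [kept_genes[gi] in inter for gi in order]
            nu = oracle_walk(rt_o, mem_o, tau)
            if variant == "maxdev":
                # larger-magnitude extreme; near-ties resolve positive
                vmax, vmin = max(nu), min(nu)
                scores.append(vmax if vmax >= -vmin - 1e-12 else vmin)
            else:
                scores.append(max(0.0, max(nu)) - max(0.0, -min(nu)))
        out[name] = scores
    return out


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_log_matrix(rng) -> ExpressionMatrix:
    """10 genes x 4 samples of log2(TPM+1)-scale values."""
    x = rng.uniform(0.0, 10.0, (10, 4))
    return ExpressionMatrix(
        pd.DataFrame(x, index=[f"G{i}" for i in range(10)],
                     columns=[f"S{j}" for j in range(4)]),
        unit="log2tpm1",
    )


@pytest.fixture
def small_sets(small_log_matrix, rng) -> GeneSetCollection:
    genes = small_log_matrix.genes
    sets = []
    for k in range(3):
        members = rng.choice(len(genes), size=5, replace=False)
        sets.append(GeneSet(f"SET{k}", "", tuple(genes[i] for i in members)))
    return GeneSetCollection(sets)


def make_feature_table(n_samples=12, n_drugs=4, P=6, E=5, seed=0,
                       task="regression") -> FeatureTable:
    """Random small feature table with (sample, drug) cross-product rows."""
    rng = np.random.default_rng(seed)
    keys = [(f"S{i}", f"D{j}") for i in range(n_samples) for j in range(n_drugs)]
    X = rng.standard_normal((len(keys), P + E))
    if task == "classification":
        y = rng.integers(0, 2, len(keys)).astype(float)
    else:
        y = rng.standard_normal(len(keys))
    return FeatureTable(
        keys=keys, X=X, y=y,
        pathway_names=[f"P{i}" for i in range(P)],
        drug_dims=[f"d{i}" for i in range(E)],
        task=task,
    )


@pytest.fixture
def feature_table() -> FeatureTable:
    return make_feature_table()
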