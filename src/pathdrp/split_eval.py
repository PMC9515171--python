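"""Sample-group-disjoint train/validation/test splitting and metrics.

Random row-level splitting of (sample, drug) pairs leaks expression
profiles: a cell line seen with one drug in training makes its other drugs
easy.  All splits here therefore operate on sample groups (cell lines /
patients) so that no group contributes rows to more than one of
{train, validation fold, test}.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .dataset import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    groups: dict[str, str]              # sample_id -> group_id
    test_groups: set[str]
    train_groups: list[str]
    seed: int
    train_frac: float = 0.9
    k: int = 5
    cv_folds: list[tuple[list[str], list[str]]] = field(default_factory=list)

    def train_rows(self, table: FeatureTable) -> np.ndarray:
        tg = set(self.train_groups)
        return np.array([i for i, (s, _) in enumerate(table.keys)
                         if self.groups[s] in tg], dtype=int)

    def test_rows(self, table: FeatureTable) -> np.ndarray:
        return np.array([i for i, (s, _) in enumerate(table.keys)
                         if self.groups[s] in self.test_groups], dtype=int)

    def rows_for_groups(self, table: FeatureTable, groups) -> np.ndarray:
        gset = set(groups)
        return np.array([i for i, (s, _) in enumerate(table.keys)
                         if self.groups[s] in gset], dtype=int)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "seed": self.seed,
            "train_frac": self.train_frac,
            "k": self.k,
            "groups": self.groups,
            "test_groups": sorted(self.test_groups),
            "train_groups": self.train_groups,
            "cv_folds": [[sorted(tr), sorted(va)] for tr, va in self.cv_folds],
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            groups=d["groups"],
            test_groups=set(d["test_groups"]),
            train_groups=d["train_groups"],
            seed=d["seed"],
            train_frac=d["train_frac"],
            k=d["k"],
            cv_folds=[(tr, va) for tr, va in d["cv_folds"]],
        )


def group_holdout_split(
    table: FeatureTable, frac: float = 0.9, seed: int = 0
) -> SplitPlan:
    """Hold out whole sample groups until test rows reach (1-frac) of total.

    Groups are the sample IDs themselves (one cell line = one group).
    Groups are shuffled with the seed and assigned to the test side until
    the test row count first reaches the target; a group is never split.
    The assignment targets the row fraction because groups carry unequal
    numbers of drug records.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    groups = {s: s for s in dict.fromkeys(table.samples)}
    counts = Counter(groups[s] for s, _ in table.keys)
    names = list(dict.fromkeys(groups.values()))
    if len(names) < 2:
        raise ValueError("need >= 2 distinct sample groups to split")
    rng = np.random.default_rng(seed)
    shuffled = [names[i] for i in rng.permutation(len(names))]
    target = (1.0 - frac) * len(table)
    test: list[str] = []
    rows = 0
    for g in shuffled:
        if rows >= target or len(test) == len(names) - 1:
            break
        test.append(g)
        rows += counts[g]
    if not test:
        test.append(shuffled[0])
    train = [g for g in names if g not in set(test)]
    return SplitPlan(groups=groups, test_groups=set(test), train_groups=train,
                     seed=seed, train_frac=frac)


def group_kfold(plan: SplitPlan, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition training groups into k validation folds.

    Groups are shuffled with the seed and dealt round-robin into the folds,
    so fold sizes differ by at most one group.  Every training group lands
    in exactly one validation fold.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(plan.train_groups) < k:
        raise ValueError(f"only {len(plan.train_groups)} training groups for k={k}")
    rng = np.random.default_rng(seed)
    order = [plan.train_groups[i] for i in rng.permutation(len(plan.train_groups))]
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, g in enumerate(order):
        folds[i % k].append(g)
    cv_folds = []
    for f in folds:
        val = set(f)
        tr = [g for g in plan.train_groups if g not in val]
        cv_folds.append((tr, list(f)))
    plan.cv_folds = cv_folds
    plan.k = k
    return plan


def _align(pred, obs):
    """Align prediction/observation inputs keyed by (sample, drug)."""
    if isinstance(pred, pd.DataFrame):
        pred = pred.set_index(["sample_id", "drug_id"])["value"]
    if isinstance(obs, pd.DataFrame):
        obs = obs.set_index(["sample_id", "drug_id"])["value"]
    if isinstance(pred, pd.Series) and isinstance(obs, pd.Series):
        joined = pd.concat([pred.rename("pred"), obs.rename("obs")], axis=1).dropna()
        return joined
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred/obs length mismatch")
    return pd.DataFrame({"pred": pred, "obs": obs})


def per_drug_pearson(
    pred: pd.DataFrame, obs: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Sample Pearson rho per drug over aligned (sample, drug) records.

    ``pred``/``obs`` are DataFrames with sample_id, drug_id, value columns.
    Drugs with fewer than min_pairs pairs or zero variance on either side
    are reported with rho = NaN and a reason.  No qualifying drug at all is
    an error.
    """
    p = pred.set_index(["sample_id", "drug_id"])["value"]
    o = obs.set_index(["sample_id", "drug_id"])["value"]
    joined = pd.concat([p.rename("pred"), o.rename("obs")], axis=1).dropna()
    out = []
    for drug, grp in joined.groupby(level="drug_id", sort=False):
        n = len(grp)
        if n < min_pairs:
            out.append((drug, np.nan, n, "too_few_pairs"))
            continue
        if grp["pred"].std(ddof=1) == 0 or grp["obs"].std(ddof=1) == 0:
            out.append((drug, np.nan, n, "zero_variance"))
            continue
        rho = pearsonr(grp["pred"], grp["obs"]).statistic
        out.append((drug, float(rho), n, ""))
    df = pd.DataFrame(out, columns=["drug_id", "pearson", "n_pairs", "reason"])
    if df["pearson"].notna().sum() == 0:
        raise ValueError("no drug qualifies for per-drug correlation")
    return df


def pooled_metrics(pred, obs) -> dict[str, float]:
    """Pooled Pearson rho, R^2 = rho^2, MSE, RMSE over all aligned pairs.

    R^2 is reported as the squared Pearson correlation — the convention of
    the regression tooling this field's sensitivity studies report with —
    not as 1 - SS_res/SS_tot.
    """
    joined = _align(pred, obs)
    if len(joined) < 3:
        raise ValueError("pooled metrics need >= 3 aligned pairs")
    p = joined["pred"].to_numpy()
    o = joined["obs"].to_numpy()
    if p.std(ddof=1) == 0 or o.std(ddof=1) == 0:
        raise ValueError("zero variance in predictions or observations")
    rho = float(pearsonr(p, o).statistic)
    mse = float(np.mean((p - o) ** 2))
    return {
        "pearson": rho,
        "r2": rho ** 2,
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "n": int(len(joined)),
    }


def classification_metrics(
    prob, labels, threshold: float = 0.5
) -> dict[str, float]:
    """AUC (rank statistic, tie-corrected), AUC-PR (step integration), F1."""
    from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels)
    classes = set(np.unique(labels).tolist())
    if classes != {0, 1} and classes != {0.0, 1.0}:
        raise ValueError(f"need both classes present, got labels {classes}")
    return {
        "auc": float(roc_auc_score(labels, prob)),
        "auc_pr": float(average_precision_score(labels, prob)),
        "f1": float(f1_score(labels, (prob >= threshold).astype(int))),
        "n": int(len(labels)),
    }


def check_no_leakage(plan: SplitPlan, table: FeatureTable) -> None:
    """Raise if any sample group reaches more than one partition."""
    seen: dict[str, str] = {}
    partitions = [("test", plan.test_groups)]
    partitions += [(f"val{j}", set(va)) for j, (_, va) in enumerate(plan.cv_folds)]
    for name, gset in partitions:
        for g in gset:
            if g in seen:
                raise ValueError(f"group {g} in both {seen[g]} and {name}")
            seen[g] = name
    test_idx = set(plan.test_rows(table).tolist())
    train_idx = set(plan.train_rows(table).tolist())
    if test_idx & train_idx:
        raise ValueError("row appears on both sides of the holdout split")
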