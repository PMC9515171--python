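"""The core learner: a feed-forward network over pathway + drug features.

Architecture (regression): input F -> dense 512 (ReLU) -> L tunable hidden
layers of a shared width W (ReLU, dropout after each hidden layer) ->
1 linear output.  The classification variant swaps the output for a
sigmoid and the loss for binary cross-entropy.  The first two layers
(input and the 512 layer) are fixed; L, W, the dropout rate and the Adam
learning rate are tuned per cross-validation fold from the grids below,
after which one model per fold is retrained on the full training data and
the five models form an ensemble (member predictions are exposed
individually; the default aggregate is their mean).

The network, Adam optimizer and inverted dropout are implemented directly
in numpy; training is mini-batch SGD with a fixed epoch budget (no early
stopping) and is reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import FeatureTable
from .split_eval import SplitPlan

logger = logging.getLogger(__name__)

# Tuning grids.
LAYER_GRID = tuple(range(2, 7))                 # tunable hidden layers after the 512 layer
WIDTH_GRID = tuple(range(128, 257, 4))          # shared width, step 4
DROPOUT_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)
LR_GRID = (1e-3, 1e-4, 1e-5)

EPOCHS_TUNE = 30
EPOCHS_FINAL = 50
BATCH_SIZE = 128
FIXED_WIDTH = 512


@dataclass(frozen=True)
class HyperParams:
    n_hidden_extra: int
    width: int
    dropout: float
    lr: float
    epochs_tune: int = EPOCHS_TUNE
    epochs_final: int = EPOCHS_FINAL
    batch: int = BATCH_SIZE

    def __post_init__(self) -> None:
        if self.n_hidden_extra not in LAYER_GRID:
            raise ValueError(f"n_hidden_extra {self.n_hidden_extra} outside {LAYER_GRID}")
        if self.width not in WIDTH_GRID:
            raise ValueError(f"width {self.width} outside the 128..256 step-4 grid")
        if self.dropout not in DROPOUT_GRID:
            raise ValueError(f"dropout {self.dropout} outside {DROPOUT_GRID}")
        if self.lr not in LR_GRID:
            raise ValueError(f"lr {self.lr} outside {LR_GRID}")


def sample_hyperparams(rng: np.random.Generator, lr: float | None = None) -> HyperParams:
    return HyperParams(
        n_hidden_extra=int(rng.choice(LAYER_GRID)),
        width=int(rng.choice(WIDTH_GRID)),
        dropout=float(rng.choice(DROPOUT_GRID)),
        lr=float(rng.choice(LR_GRID)) if lr is None else lr,
    )


def sample_candidates(rng: np.random.Generator, budget: int) -> list[HyperParams]:
    """Budgeted draw from the grids, stratified over the learning rate.

    The learning rate dominates whether the net trains at all, so candidate
    i cycles through the lr grid while the architecture dimensions are
    sampled uniformly; a small budget therefore never consists solely of
    near-frozen (lr=1e-5) configurations.
    """
    return [sample_hyperparams(rng, lr=LR_GRID[i % len(LR_GRID)])
            for i in range(budget)]


class _MLP:
    """Dense ReLU network with inverted dropout and an Adam optimizer."""

    def __init__(self, n_features: int, hp: HyperParams, task: str, seed: int):
        self.hp = hp
        self.task = task
        self.n_features = n_features
        rng = np.random.default_rng(seed)
        sizes = [n_features, FIXED_WIDTH] + [hp.width] * hp.n_hidden_extra + [1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        # float32 throughout: halves the training cost at no practical
        # accuracy cost for SGD-trained nets
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
            self.W.append((rng.standard_normal((fan_in, fan_out)) * scale
                           ).astype(np.float32))
            self.b.append(np.zeros(fan_out, dtype=np.float32))
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def _forward(self, X, train: bool = False, rng: np.random.Generator | None = None):
        """Return (output, cache).  Dropout is active only when train=True."""
        a = X
        acts = [a]
        masks = []
        keep = 1.0 - self.hp.dropout
        n_layers = len(self.W)
        for li in range(n_layers - 1):
            z = a @ self.W[li] + self.b[li]
            a = np.maximum(z, 0.0)
            if train:
                mask = (rng.random(a.shape, dtype=np.float32) < keep
                        ).astype(np.float32) / np.float32(keep)
                a = a * mask
                masks.append(mask)
            acts.append(a)
        out = a @ self.W[-1] + self.b[-1]
        if self.task == "classification":
            out = 1.0 / (1.0 + np.exp(-out))
        return out[:, 0], (acts, masks)

    def _backward(self, y_hat, y, cache):
        """Gradients of mean loss (MSE or BCE); both reduce to (y_hat-y)/n at the output."""
        acts, masks = cache
        n = len(y)
        if self.task == "regression":
            delta = (2.0 / n) * (y_hat - y)
        else:
            delta = (y_hat - y) / n  # BCE through the sigmoid
        delta = delta[:, None]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for li in range(len(self.W) - 1, -1, -1):
            a_prev = acts[li]
            gW[li] = a_prev.T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.W[li].T
                if masks:
                    delta = delta * masks[li - 1]
                delta = delta * (acts[li] > 0)
        return gW, gb

    def _adam_step(self, gW, gb, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        grads = gW + gb
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = beta1 * self._adam_m[i] + (1 - beta1) * g
            self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g * g
            mhat = self._adam_m[i] / (1 - beta1**t)
            vhat = self._adam_v[i] / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def _loss(self, y_hat, y):
        if self.task == "regression":
            return float(np.mean((y_hat - y) ** 2))
        eps = 1e-7  # float32-safe: 1 - 1e-12 would round to 1
        yh = np.clip(y_hat.astype(np.float64), eps, 1 - eps)
        return float(-np.mean(y * np.log(yh) + (1 - y) * np.log(1 - yh)))

    # -- public -------------------------------------------------------------

    def fit(self, X, y, epochs: int, seed: int) -> list[float]:
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        n = len(y)
        batch = self.hp.batch
        if n < batch:
            batch = max(1, n)
            logger.info("fit: %d rows < batch %d; batch reduced to %d",
                        n, self.hp.batch, batch)
        rng = np.random.default_rng(seed)
        curve = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                y_hat, cache = self._forward(X[idx], train=True, rng=rng)
                gW, gb = self._backward(y_hat, y[idx], cache)
                self._adam_step(gW, gb, self.hp.lr)
            y_hat, _ = self._forward(X)
            loss = self._loss(y_hat, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch + 1} "
                    f"(lr={self.hp.lr}, width={self.hp.width}); training aborted")
            curve.append(loss)
        return curve

    def predict(self, X) -> np.ndarray:
        out, _ = self._forward(np.asarray(X, dtype=np.float32))
        return out.astype(float)

    def weight_shapes(self) -> list[tuple[int, int]]:
        return [w.shape for w in self.W]


@dataclass
class TrainedModel:
    net: _MLP
    hp: HyperParams
    seed: int
    task: str
    loss_curve: list[float]
    feature_names: list[str]

    def predict(self, X, columns: Sequence[str] | None = None) -> np.ndarray:
        X = _align_columns(np.asarray(X, dtype=float), columns, self.feature_names)
        return self.net.predict(X)


def _align_columns(X, columns, feature_names):
    """Reorder X's columns by name to the training schema; mismatch is an error."""
    if columns is None:
        if X.shape[1] != len(feature_names):
            raise ValueError(
                f"feature width {X.shape[1]} != model width {len(feature_names)}")
        return X
    columns = list(columns)
    missing = [c for c in feature_names if c not in columns]
    extra = [c for c in columns if c not in feature_names]
    if missing or extra:
        raise ValueError(f"feature mismatch; missing={missing[:5]} extra={extra[:5]}")
    pos = {c: i for i, c in enumerate(columns)}
    return X[:, [pos[c] for c in feature_names]]


def train_regressor(
    table: FeatureTable, hp: HyperParams, seed: int,
    rows: np.ndarray | None = None, epochs: int | None = None,
) -> TrainedModel:
    """Train the regression network on (a row subset of) a feature table."""
    if table.task != "regression":
        raise ValueError("train_regressor needs a regression feature table")
    sub = table if rows is None else table.subset(rows)
    net = _MLP(sub.F, hp, "regression", seed)
    curve = net.fit(sub.X, sub.y, epochs or hp.epochs_final, seed)
    return TrainedModel(net, hp, seed, "regression", curve, sub.column_names)


def train_classifier(
    table: FeatureTable, hp: HyperParams, seed: int,
    rows: np.ndarray | None = None, epochs: int | None = None,
) -> TrainedModel:
    """Train the sigmoid/BCE classifier variant; outputs are probabilities."""
    sub = table if rows is None else table.subset(rows)
    if len(np.unique(sub.y)) < 2:
        raise ValueError("classifier training needs both classes present")
    net = _MLP(sub.F, hp, "classification", seed)
    curve = net.fit(sub.X, sub.y, epochs or hp.epochs_final, seed)
    return TrainedModel(net, hp, seed, "classification", curve, sub.column_names)


def _val_loss(table, hp, train_rows, val_rows, seed, epochs, task) -> float:
    trainer = train_classifier if task == "classification" else train_regressor
    m = trainer(table, hp, seed, rows=train_rows, epochs=epochs)
    val = table.subset(val_rows)
    return m.net._loss(m.net.predict(val.X), val.y)


def tune_hyperparameters(
    plan: SplitPlan,
    table: FeatureTable,
    budget: int = 10,
    seed: int = 0,
    strategy: str = "random",
) -> list[HyperParams]:
    """Per cross-validation fold, pick the grid configuration with the
    lowest validation loss within the candidate budget.

    ``random`` draws ``budget`` configurations from the grids and trains
    each for the tuning epoch budget; ``halving`` draws the same candidates
    but spends a third of the epochs on all of them and the full tuning
    epochs only on the top half (successive-halving style).  Deterministic
    for a fixed seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not plan.cv_folds:
        raise ValueError("plan has no cv folds; run group_kfold first")
    if strategy not in ("random", "halving"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    candidates = sample_candidates(rng, budget)
    chosen: list[HyperParams] = []
    for fi, (tr_groups, va_groups) in enumerate(plan.cv_folds):
        tr_rows = plan.rows_for_groups(table, tr_groups)
        va_rows = plan.rows_for_groups(table, va_groups)
        fold_seed = seed * 1009 + fi
        pool = list(candidates)
        if strategy == "halving" and len(pool) > 1:
            short = max(1, EPOCHS_TUNE // 3)
            losses = [_val_loss(table, hp, tr_rows, va_rows, fold_seed, short, table.task)
                      for hp in pool]
            keep = int(np.ceil(len(pool) / 2))
            pool = [pool[i] for i in np.argsort(losses, kind="stable")[:keep]]
        losses = [_val_loss(table, hp, tr_rows, va_rows, fold_seed,
                            hp.epochs_tune, table.task) for hp in pool]
        best = pool[int(np.argmin(losses))]
        logger.info("fold %d: chose %s (val loss %.4f)", fi, best, min(losses))
        chosen.append(best)
    return chosen


@dataclass
class Ensemble:
    members: list[TrainedModel]
    member_hyperparams: list[HyperParams]
    task: str = "regression"

    def __post_init__(self) -> None:
        widths = {len(m.feature_names) for m in self.members}
        if len(widths) != 1:
            raise ValueError("ensemble members disagree on feature width")


def train_ensemble(
    table: FeatureTable,
    per_fold_hp: Sequence[HyperParams],
    seed: int = 0,
    rows: np.ndarray | None = None,
) -> Ensemble:
    """Train one model per tuned hyperparameter set on the full training rows."""
    if not per_fold_hp:
        raise ValueError("need at least one hyperparameter set")
    trainer = train_classifier if table.task == "classification" else train_regressor
    seeds = np.random.SeedSequence(seed).generate_state(len(per_fold_hp)) % (2**31)
    members = [trainer(table, hp, int(s), rows=rows)
               for hp, s in zip(per_fold_hp, seeds)]
    return Ensemble(members=members, member_hyperparams=list(per_fold_hp),
                    task=table.task)


def predict(
    e: Ensemble, X, columns: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(member predictions, K x n) and their mean (n,)."""
    member = np.vstack([m.predict(X, columns=columns) for m in e.members])
    return member, member.mean(axis=0)


# -- classical baselines ----------------------------------------------------

RF_MTRY_GRID = tuple(range(1, 11))
RF_TREE_GRID = tuple(range(100, 1001, 100))
ENET_ALPHA_GRID = (0.001, 0.01, 0.1, 1.0)
ENET_L1_GRID = (0.1, 0.5, 0.9)
ENET_N_BOOT = 25


def train_baseline(
    kind: str,
    table: FeatureTable,
    plan: SplitPlan,
    seed: int = 0,
    rf_mtry_grid: Sequence[int] = RF_MTRY_GRID,
    rf_tree_grid: Sequence[int] = RF_TREE_GRID,
    n_boot: int = ENET_N_BOOT,
):
    """Random-forest or elastic-net baselines with per-fold selection.

    rf: grid search mtry x n_trees per fold by validation MSE; elasticnet:
    per fold, ``n_boot`` bootstrap resamples score an (alpha, l1_ratio)
    grid by RMSE.  The per-fold winners are then refit on the full
    training rows, mirroring the ensemble protocol.  Returns
    (fitted models, chosen parameter dicts).
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import ElasticNet

    if kind not in ("rf", "elasticnet"):
        raise ValueError(f"unknown baseline kind {kind!r}")
    if not plan.cv_folds:
        raise ValueError("plan has no cv folds; run group_kfold first")
    train_rows = plan.train_rows(table)
    chosen: list[dict] = []
    for fi, (tr_groups, va_groups) in enumerate(plan.cv_folds):
        tr = table.subset(plan.rows_for_groups(table, tr_groups))
        va = table.subset(plan.rows_for_groups(table, va_groups))
        if kind == "rf":
            best, best_mse = None, np.inf
            for mtry in rf_mtry_grid:
                for n_trees in rf_tree_grid:
                    rf = RandomForestRegressor(
                        n_estimators=n_trees, max_features=min(mtry, table.F),
                        random_state=seed * 1009 + fi, n_jobs=1)
                    rf.fit(tr.X, tr.y)
                    mse = float(np.mean((rf.predict(va.X) - va.y) ** 2))
                    if mse < best_mse:
                        best, best_mse = {"mtry": mtry, "n_trees": n_trees}, mse
            chosen.append(best)
        else:
            rng = np.random.default_rng(seed * 1009 + fi)
            scores: dict[tuple[float, float], list[float]] = {}
            for _ in range(n_boot):
                idx = rng.integers(0, len(tr), len(tr))
                oob = np.setdiff1d(np.arange(len(tr)), idx)
                if len(oob) == 0:
                    continue
                for alpha in ENET_ALPHA_GRID:
                    for l1 in ENET_L1_GRID:
                        en = ElasticNet(alpha=alpha, l1_ratio=l1, max_iter=5000)
                        en.fit(tr.X[idx], tr.y[idx])
                        rmse = float(np.sqrt(np.mean((en.predict(tr.X[oob]) - tr.y[oob]) ** 2)))
                        scores.setdefault((alpha, l1), []).append(rmse)
            best = min(scores, key=lambda key: np.mean(scores[key]))
            chosen.append({"alpha": best[0], "l1_ratio": best[1]})
    full = table.subset(train_rows)
    models = []
    for fi, params in enumerate(chosen):
        if kind == "rf":
            m = RandomForestRegressor(
                n_estimators=params["n_trees"],
                max_features=min(params["mtry"], table.F),
                random_state=seed * 2003 + fi, n_jobs=1)
        else:
            m = ElasticNet(alpha=params["alpha"], l1_ratio=params["l1_ratio"],
                           max_iter=5000)
        m.fit(full.X, full.y)
        models.append(m)
    return models, chosen


# -- persistence -------------------------------------------------------------

def save_ensemble(e: Ensemble, outdir: str | Path) -> None:
    """Write weights (npz) plus a JSON schema (F, columns, hp, seeds)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"task": e.task, "members": []}
    for i, m in enumerate(e.members):
        arrays = {}
        for li, (w, b) in enumerate(zip(m.net.W, m.net.b)):
            arrays[f"W{li}"] = w
            arrays[f"b{li}"] = b
        np.savez(outdir / f"member{i}.npz", **arrays)
        meta["members"].append({"hp": asdict(m.hp), "seed": m.seed,
                                "loss_curve": m.loss_curve})
        with open(outdir / f"member{i}_loss.tsv", "w") as fh:
            fh.write("epoch\tloss\n")
            for ep, loss in enumerate(m.loss_curve, 1):
                fh.write(f"{ep}\t{loss:.10g}\n")
    meta["feature_names"] = e.members[0].feature_names
    meta["F"] = len(e.members[0].feature_names)
    (outdir / "schema.json").write_text(json.dumps(meta, indent=1))


def load_ensemble(outdir: str | Path) -> Ensemble:
    outdir = Path(outdir)
    meta = json.loads((outdir / "schema.json").read_text())
    members = []
    for i, mm in enumerate(meta["members"]):
        hp = HyperParams(**mm["hp"])
        net = _MLP(meta["F"], hp, meta["task"], mm["seed"])
        data = np.load(outdir / f"member{i}.npz")
        for li in range(len(net.W)):
            net.W[li] = data[f"W{li}"]
            net.b[li] = data[f"b{li}"]
        members.append(TrainedModel(net, hp, mm["seed"], meta["task"],
                                    mm["loss_curve"], meta["feature_names"]))
    return Ensemble(members=members,
                    member_hyperparams=[m.hp for m in members],
                    task=meta["task"])
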