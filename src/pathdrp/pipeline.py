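"""End-to-end orchestration: expression -> scores -> features -> model -> report.

Every random decision is keyed off one master seed, expanded
deterministically per stage, so re-running an identical config reproduces
the run manifest's metric values.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression_io import read_expression_matrix, to_log2_tpm
from .genesets import read_gmt
from .pathway_scoring import gsva_scores
from .drug_featurizer import build_embedding, featurize_drugs, read_drug_table
from .dataset import (assemble_feature_table, average_duplicate_responses,
                      read_response_table)
from .split_eval import (classification_metrics, group_holdout_split,
                         group_kfold, per_drug_pearson, pooled_metrics,
                         check_no_leakage)
from . import model as model_mod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expr: str
    gmt: str
    drugs: str
    responses: str
    out: str
    unit: str = "log2tpm1"
    task: str = "regression"
    variant: str = "diff"
    min_size: int = 5
    embed_mode: str = "hashed"
    embed_dim: int = 100
    kmer: int = 8
    train_frac: float = 0.9
    k_folds: int = 5
    budget: int = 6
    tune_strategy: str = "halving"
    n_models: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def validate(self) -> None:
        for name in ("expr", "gmt", "drugs", "responses"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValueError(f"config path {name}={p!r} does not exist")


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; write the seven run artifacts; return the manifest."""
    cfg.validate()
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        logger.info("pipeline stage: %s", name)

    try:
        stage("expression_io")
        expr = read_expression_matrix(cfg.expr, unit=cfg.unit)
        expr = to_log2_tpm(expr)

        stage("pathway_scoring")
        sets = read_gmt(cfg.gmt)
        scores = gsva_scores(expr, sets, variant=cfg.variant, min_size=cfg.min_size)
        scores.data.to_csv(out / "scores.tsv", sep="\t")

        stage("drug_featurizer")
        drugs = read_drug_table(cfg.drugs)
        table_emb = build_embedding(dim=cfg.embed_dim, k=cfg.kmer,
                                    mode=cfg.embed_mode,
                                    seed=_stage_seed(cfg.seed, 1))
        dvec = featurize_drugs(drugs, table_emb)
        dvec.to_csv(out / "drug_vectors.tsv", sep="\t")

        stage("dataset")
        responses = read_response_table(cfg.responses, task=cfg.task)
        responses = average_duplicate_responses(responses)
        table = assemble_feature_table(scores, dvec, responses)
        table.to_tsv(out / "features.tsv")
        table.write_schema(out / "features.schema.json")

        stage("split_eval")
        plan = group_holdout_split(table, frac=cfg.train_frac,
                                   seed=_stage_seed(cfg.seed, 2))
        plan = group_kfold(plan, k=cfg.k_folds, seed=_stage_seed(cfg.seed, 3))
        check_no_leakage(plan, table)
        plan.to_json(out / "split.json")

        stage("model")
        per_fold_hp = model_mod.tune_hyperparameters(
            plan, table, budget=cfg.budget, seed=_stage_seed(cfg.seed, 4),
            strategy=cfg.tune_strategy)
        ensemble = model_mod.train_ensemble(
            table, per_fold_hp[:cfg.n_models], seed=_stage_seed(cfg.seed, 5),
            rows=plan.train_rows(table))
        model_mod.save_ensemble(ensemble, out / "model")

        stage("evaluation")
        test = table.subset(plan.test_rows(table))
        member, mean_pred = model_mod.predict(ensemble, test.X)
        pred_df = pd.DataFrame({"sample_id": test.samples, "drug_id": test.drugs,
                                "value": mean_pred})
        obs_df = pd.DataFrame({"sample_id": test.samples, "drug_id": test.drugs,
                               "value": test.y})
        pred_df.to_csv(out / "predictions.tsv", sep="\t", index=False)
        if cfg.task == "classification":
            report = {"classification": classification_metrics(mean_pred, test.y)}
        else:
            report = {"pooled": pooled_metrics(mean_pred, test.y)}
            per_drug = per_drug_pearson(pred_df, obs_df)
            per_drug.to_csv(out / "per_drug.tsv", sep="\t", index=False)
            report["per_drug_median_pearson"] = float(per_drug["pearson"].median())
    except Exception as exc:  # halt with the failing stage's name and context
        raise type(exc)(f"pipeline stage {current['stage']!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "input_sha256": {name: _sha256(getattr(cfg, name))
                         for name in ("expr", "gmt", "drugs", "responses")},
        "n_rows": len(table),
        "F": table.F,
        "P": table.P,
        "E": table.E,
        "report": report,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "evaluation.json").write_text(json.dumps(report, indent=1))
    return manifest


# -- synthetic benchmark ------------------------------------------------------

def run_synthetic_benchmark(
    sim_cfg=None,
    seed: int = 0,
    budget: int = 6,
    strategy: str = "halving",
    embed_dim: int = 100,
    holdout_drugs: int = 0,
    ablate_drug_features: bool = False,
):
    """Score -> featurize -> split -> tune -> ensemble on a simulated screen.

    Returns a dict with the pooled held-out metrics.  With
    ``holdout_drugs`` > 0, that many whole drugs (chosen so their drug
    family stays represented in training) are additionally removed from
    training and reported under ``unseen_drug``; with
    ``ablate_drug_features`` the drug descriptor block is zeroed
    everywhere, the no-structure control for the unseen-drug comparison.
    """
    from .synthetic_data import SimConfig, simulate

    if sim_cfg is None:
        sim_cfg = SimConfig(seed=seed)
    expr, sets, drugs, responses, truth = simulate(sim_cfg)
    scores = gsva_scores(expr, sets, variant="diff", min_size=5)
    emb = build_embedding(dim=embed_dim, mode="hashed", seed=_stage_seed(seed, 11))
    dvec = featurize_drugs(drugs, emb)
    if ablate_drug_features:
        dvec.loc[:, :] = 0.0
    table = assemble_feature_table(scores, dvec,
                                   average_duplicate_responses(responses))

    unseen_ids: list[str] = []
    if holdout_drugs > 0:
        # hold out the last drug of each family so every family keeps
        # training representation
        by_family: dict[int, list[str]] = {}
        for d, fam in truth.families.items():
            by_family.setdefault(fam, []).append(d)
        for fam in sorted(by_family):
            if len(unseen_ids) >= holdout_drugs:
                break
            if len(by_family[fam]) > 1:
                unseen_ids.append(by_family[fam][-1])
        if len(unseen_ids) < holdout_drugs:
            raise ValueError("not enough multi-drug families to hold drugs out")

    plan = group_holdout_split(table, frac=0.9, seed=_stage_seed(seed, 12))
    plan = group_kfold(plan, k=5, seed=_stage_seed(seed, 13))
    check_no_leakage(plan, table)
    train_rows = plan.train_rows(table)
    if unseen_ids:
        keep = np.array([i for i in train_rows
                         if table.keys[i][1] not in set(unseen_ids)], dtype=int)
    else:
        keep = train_rows
    # tuning sees only the kept training rows (fold row lookup scans keys,
    # so it works on the subset table directly)
    per_fold_hp = model_mod.tune_hyperparameters(
        plan, table.subset(keep), budget=budget, seed=_stage_seed(seed, 14),
        strategy=strategy)
    ensemble = model_mod.train_ensemble(table, per_fold_hp, rows=keep,
                                        seed=_stage_seed(seed, 15))
    test_rows = plan.test_rows(table)
    test = table.subset(test_rows)
    _, mean_pred = model_mod.predict(ensemble, test.X)
    out = {"pooled": pooled_metrics(mean_pred, test.y), "n_train": int(len(keep))}
    if unseen_ids:
        un_rows = np.array([i for i in test_rows
                            if table.keys[i][1] in set(unseen_ids)], dtype=int)
        un = table.subset(un_rows)
        _, un_pred = model_mod.predict(ensemble, un.X)
        out["unseen_drug"] = pooled_metrics(un_pred, un.y)
        out["unseen_drug_ids"] = unseen_ids
    return out
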