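"""Synthetic expression / gene-set / drug / response generator.

Emulates the structure of a pharmacogenomic screen with known ground
truth: each sample carries a latent activity per pathway, member genes of
a pathway shift with that activity, each drug targets a few pathways, and
the response is a linear function of the targeted activities plus
Gaussian noise::

    y(sample, drug) = mu + sum_k w_dk * a_sk + eps,   eps ~ N(0, sigma^2)

with w_dk = beta on the drug's target pathways and 0 elsewhere.  Drugs
sharing a target set ("families") also share SMILES substrings, so the
k-mer descriptor carries signal about the targets and unseen drugs of a
known family remain predictable.  Synthetic SMILES are strings over a
SMILES-like alphabet and are not required to be chemically valid; they
exercise the k-mer featurizer's contract.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .genesets import GeneSet, GeneSetCollection
from .dataset import ResponseTable

logger = logging.getLogger(__name__)

SMILES_ALPHABET = list("CNOPSFIcno123456789()=#[]+-")


@dataclass
class SimConfig:
    """Study conditions for the synthetic screen.

    Defaults are the benchmark conditions used throughout the test suite:
    600 genes x 120 samples, 40 pathways of 10 genes, 25 drugs with 3
    target pathways each, effect size beta = 1.5 LN IC50 units per unit
    activity, response noise sigma = 0.5, baseline LN IC50 mu = 2.5 (a
    GDSC-like scale).  Expression signal: member genes shift by
    delta = 2.0 log2 units per unit activity over per-gene noise sd 0.4
    (a 5x signal-to-noise ratio, comfortably detectable by the scoring
    step).
    """

    n_genes: int = 600
    n_samples: int = 120
    n_sets: int = 40
    set_size_min: int = 10
    set_size_max: int = 10
    n_drugs: int = 25
    n_targets_per_drug: int = 3
    n_families: int = 8
    beta: float = 1.5
    sigma: float = 0.5
    mu: float = 2.5
    expr_delta: float = 2.0
    expr_noise_sd: float = 0.4
    expr_baseline_lo: float = 2.0
    expr_baseline_hi: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_sets", "set_size_min",
                     "set_size_max", "n_drugs", "n_targets_per_drug", "n_families"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.set_size_max > self.n_genes:
            raise ValueError("set size exceeds the gene universe")
        if self.set_size_min > self.set_size_max:
            raise ValueError("set_size_min > set_size_max")


@dataclass
class SimTruth:
    """Ground truth retained by the generator."""

    activities: pd.DataFrame | None = None     # sets x samples, a_sk
    weights: pd.DataFrame | None = None        # drugs x sets, w_dk
    mu: float = 0.0
    families: dict[str, int] = field(default_factory=dict)  # drug -> family

    def expected_response(self, sample: str, drug: str) -> float:
        w = self.weights.loc[drug].to_numpy()
        a = self.activities[sample].to_numpy()
        return float(self.mu + w @ a)


def simulate_gene_sets(cfg: SimConfig) -> GeneSetCollection:
    """Sample gene sets uniformly from the universe (sizes in the configured range)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    sets = []
    for k in range(cfg.n_sets):
        size = int(rng.integers(cfg.set_size_min, cfg.set_size_max + 1))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        sets.append(GeneSet(f"SET{k:03d}", "simulated", tuple(genes[i] for i in sorted(members))))
    return GeneSetCollection(sets)


def simulate_expression(
    cfg: SimConfig, sets: GeneSetCollection
) -> tuple[ExpressionMatrix, SimTruth]:
    """Expression with pathway-structured signal; activities kept as truth.

    Member genes of pathway k in sample s are shifted by
    ``expr_delta * a_sk`` over a per-gene baseline plus N(0, expr_noise_sd)
    noise; values are clipped at 0 to stay on the log2(TPM+1) scale.  A
    gene in several sets receives the summed shift of its sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    samples = [f"S{j:03d}" for j in range(cfg.n_samples)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    activities = rng.standard_normal((len(sets), cfg.n_samples))
    baseline = rng.uniform(cfg.expr_baseline_lo, cfg.expr_baseline_hi, cfg.n_genes)
    x = baseline[:, None] + rng.normal(0.0, cfg.expr_noise_sd,
                                       (cfg.n_genes, cfg.n_samples))
    for k, s in enumerate(sets):
        idx = [gene_pos[g] for g in s.genes]
        x[idx, :] += cfg.expr_delta * activities[k][None, :]
    x = np.clip(x, 0.0, None)
    truth = SimTruth(
        activities=pd.DataFrame(activities, index=sets.names(), columns=samples),
        mu=cfg.mu,
    )
    m = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples),
                         unit="log2tpm1")
    return m, truth


def _family_motif(rng: np.random.Generator, length: int = 12) -> str:
    return "".join(rng.choice(SMILES_ALPHABET, size=length))


def simulate_drugs_and_responses(
    cfg: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, ResponseTable, SimTruth]:
    """Synthetic drugs (id + SMILES) and the response table.

    Drugs are grouped into families; a family shares a target-pathway set
    and a set of SMILES motif substrings, so descriptors correlate within
    a family.  Responses follow the linear generating function with
    N(0, sigma^2) noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    set_names = list(truth.activities.index)
    n_sets = len(set_names)
    n_fam = min(cfg.n_families, cfg.n_drugs)
    fam_targets = []
    fam_motifs = []
    for f in range(n_fam):
        targets = rng.choice(n_sets, size=min(cfg.n_targets_per_drug, n_sets),
                             replace=False)
        fam_targets.append(targets)
        fam_motifs.append([_family_motif(rng) for _ in range(3)])
    drug_ids = [f"D{d:03d}" for d in range(cfg.n_drugs)]
    families = {d: i % n_fam for i, d in enumerate(drug_ids)}
    weights = np.zeros((cfg.n_drugs, n_sets))
    smiles_list = []
    for i, d in enumerate(drug_ids):
        fam = families[d]
        weights[i, fam_targets[fam]] = cfg.beta
        parts = list(fam_motifs[fam])
        parts.append("".join(rng.choice(SMILES_ALPHABET, size=10)))  # private tail
        order = rng.permutation(len(parts) - 1)
        smiles = "".join([parts[j] for j in order] + [parts[-1]])
        smiles_list.append(smiles)
    drugs = pd.DataFrame({"drug_id": drug_ids, "smiles": smiles_list})
    A = truth.activities.to_numpy()  # sets x samples
    samples = list(truth.activities.columns)
    Y = truth.mu + weights @ A + rng.normal(0.0, cfg.sigma,
                                            (cfg.n_drugs, len(samples)))
    records = pd.DataFrame({
        "sample_id": np.repeat(samples, cfg.n_drugs),
        "drug_id": drug_ids * len(samples),
        "response": Y.T.reshape(-1),
    })
    truth.weights = pd.DataFrame(weights, index=drug_ids, columns=set_names)
    truth.families = families
    return drugs, ResponseTable(records, task="regression"), truth


def simulate(cfg: SimConfig, outdir: str | Path | None = None):
    """Run the full generator; optionally write the five artifact files."""
    sets = simulate_gene_sets(cfg)
    expr, truth = simulate_expression(cfg, sets)
    drugs, responses, truth = simulate_drugs_and_responses(cfg, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        expr.data.to_csv(outdir / "expr.tsv", sep="\t")
        from .genesets import write_gmt
        write_gmt(sets, outdir / "sets.gmt")
        drugs.to_csv(outdir / "drugs.tsv", sep="\t", index=False)
        responses.records.to_csv(outdir / "responses.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(json.dumps({
            "config": asdict(cfg),
            "mu": truth.mu,
            "families": truth.families,
            "weights": truth.weights.to_dict(),
            "activities": truth.activities.round(10).to_dict(),
        }, indent=1))
    return expr, sets, drugs, responses, truth
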