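"""Fixed-length drug descriptors from SMILES character k-mers.

A SMILES string is decomposed into overlapping length-k substrings
(k = 8 by default) and the descriptor is the arithmetic mean of the
k-mers' embedding vectors (default dimension 100).  Three embedding
sources are supported:

* ``hashed`` — each k-mer is mapped through a seeded cryptographic hash to
  a unit-variance pseudo-random Gaussian vector.  Fully deterministic from
  (seed, k, dim), needs no corpus or download, and distinct k-mers are
  near-orthogonal at dim=100, so drugs sharing substructure strings get
  correlated descriptors.
* ``trained`` — a co-occurrence embedding fitted on a SMILES corpus:
  windowed k-mer co-occurrence counts -> positive PMI -> truncated SVD
  (the implicit factorization behind skip-gram word vectors).
* ``loaded`` — a k-mer -> vector table read from TSV.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_K = 8
DEFAULT_DIM = 100
MODES = ("hashed", "trained", "loaded")


def smiles_kmers(smiles: str, k: int = DEFAULT_K) -> list[str]:
    """All overlapping length-k substrings, in order.

    Strings shorter than k yield themselves as the single "k-mer"; an empty
    (post-strip) string is an error.
    """
    s = smiles.strip()
    if not s:
        raise ValueError("empty SMILES string")
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(s) < k:
        return [s]
    return [s[i:i + k] for i in range(len(s) - k + 1)]


@dataclass
class EmbeddingTable:
    k: int
    dim: int
    mode: str
    seed: int | None = None
    entries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown embedding mode {self.mode!r}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.mode == "hashed" and self.seed is None:
            raise ValueError("hashed mode requires an explicit seed")

    def _hash_vector(self, kmer: str) -> np.ndarray:
        key = f"{self.seed}|{self.k}|{self.dim}|{kmer}".encode()
        digest = hashlib.blake2b(key, digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big"))
        return rng.standard_normal(self.dim)

    def vector(self, kmer: str) -> np.ndarray | None:
        """Vector for a k-mer, or None when out-of-vocabulary (loaded/trained)."""
        if kmer in self.entries:
            return self.entries[kmer]
        if self.mode == "hashed":
            v = self._hash_vector(kmer)
            self.entries[kmer] = v
            return v
        return None

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            header = "\t".join(["kmer", *[f"e{i}" for i in range(self.dim)]])
            fh.write(header + "\n")
            for kmer in sorted(self.entries):
                vals = "\t".join(format(v, ".17g") for v in self.entries[kmer])
                fh.write(f"{kmer}\t{vals}\n")


def load_embedding(path: str | Path, k: int = DEFAULT_K) -> EmbeddingTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dim = df.shape[1]
    entries = {str(kmer): row.to_numpy(dtype=float) for kmer, row in df.iterrows()}
    return EmbeddingTable(k=k, dim=dim, mode="loaded", entries=entries)


def _train_cooccurrence(
    corpus: Sequence[str], dim: int, k: int, seed: int, window: int = 5
) -> dict[str, np.ndarray]:
    """PPMI + truncated-SVD embedding of k-mer co-occurrence in the corpus."""
    from sklearn.decomposition import TruncatedSVD

    docs = [smiles_kmers(s, k) for s in corpus]
    vocab = sorted({km for doc in docs for km in doc})
    idx = {km: i for i, km in enumerate(vocab)}
    V = len(vocab)
    counts = np.zeros((V, V))
    for doc in docs:
        ids = [idx[km] for km in doc]
        for pos, a in enumerate(ids):
            for b in ids[max(0, pos - window):pos]:
                counts[a, b] += 1
                counts[b, a] += 1
    total = counts.sum()
    if total == 0:  # single-kmer documents only: no context pairs
        counts += np.eye(V)
        total = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / (row @ row.T))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    ncomp = min(dim, V - 1) if V > 1 else 1
    svd = TruncatedSVD(n_components=ncomp, random_state=seed)
    emb = svd.fit_transform(ppmi)
    if emb.shape[1] < dim:  # small vocabularies: zero-pad to the contracted width
        emb = np.hstack([emb, np.zeros((V, dim - emb.shape[1]))])
    return {km: emb[i].copy() for km, i in idx.items()}


def build_embedding(
    corpus: Sequence[str] | None = None,
    dim: int = DEFAULT_DIM,
    k: int = DEFAULT_K,
    mode: str = "hashed",
    seed: int = 0,
) -> EmbeddingTable:
    """Construct an embedding table in hashed or trained mode."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if mode == "hashed":
        return EmbeddingTable(k=k, dim=dim, mode="hashed", seed=seed)
    if mode == "trained":
        if corpus is None or len(corpus) < 10:
            raise ValueError("trained mode requires a corpus of >= 10 SMILES")
        entries = _train_cooccurrence(corpus, dim, k, seed)
        return EmbeddingTable(k=k, dim=dim, mode="trained", seed=seed, entries=entries)
    raise ValueError(f"build_embedding: unsupported mode {mode!r}")


@dataclass
class DrugVector:
    drug_id: str
    smiles: str
    vector: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.isfinite(self.vector).all():
            raise ValueError(f"{self.drug_id}: non-finite descriptor entries")


def embed_smiles(smiles: str, table: EmbeddingTable, drug_id: str = "") -> DrugVector:
    """Descriptor = mean of the embedding vectors of all k-mers.

    In loaded/trained mode, out-of-vocabulary k-mers are skipped (logged);
    if every k-mer is out of vocabulary the drug cannot be embedded and an
    error names it.  Hashed mode never misses.
    """
    kmers = smiles_kmers(smiles, table.k)
    vectors = []
    misses = 0
    for km in kmers:
        v = table.vector(km)
        if v is None:
            misses += 1
        else:
            vectors.append(v)
    if misses:
        logger.info("embed_smiles(%s): %d/%d k-mers out of vocabulary",
                    drug_id or smiles, misses, len(kmers))
    if not vectors:
        raise ValueError(f"drug {drug_id or smiles!r}: all k-mers out of vocabulary")
    return DrugVector(
        drug_id=drug_id or smiles,
        smiles=smiles,
        vector=np.mean(vectors, axis=0),
        source=table.mode,
    )


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Drug table TSV with columns drug_id, smiles."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"{path}: drug table missing column {col!r}")
    if df["drug_id"].duplicated().any():
        dupes = df.loc[df["drug_id"].duplicated(), "drug_id"].tolist()
        raise ValueError(f"{path}: duplicate drug_id values: {dupes}")
    return df[["drug_id", "smiles"]]


def featurize_drugs(drugs: pd.DataFrame, table: EmbeddingTable) -> pd.DataFrame:
    """Embed every drug in a (drug_id, smiles) table -> drugs x dim DataFrame."""
    rows = {}
    for _, rec in drugs.iterrows():
        dv = embed_smiles(rec["smiles"], table, drug_id=rec["drug_id"])
        rows[dv.drug_id] = dv.vector
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"d{i}" for i in range(table.dim)])
    out.index.name = "drug_id"
    return out
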