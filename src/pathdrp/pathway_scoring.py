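"""Per-sample pathway enrichment scoring (GSVA) and kNN feature imputation.

The scoring statistic follows the gene set variation analysis recipe for
continuous (log-scale) expression:

1. **Kernel CDF.**  For gene *i* with values ``x_i1..x_in`` across *n*
   samples, a Gaussian-kernel estimate of the expression CDF is evaluated
   at each sample::

       zhat_ij = (1/n) * sum_k Phi((x_ij - x_ik) / h_i),   h_i = s_i / 4

   where ``Phi`` is the standard normal CDF and ``s_i`` the per-gene sample
   standard deviation.  Genes with zero variance carry no ranking
   information and would have bandwidth 0; they are dropped (logged).

2. **Symmetric rank statistic.**  Within each sample, genes are ranked by
   decreasing ``zhat`` (rank 1 = largest; ties broken by input gene order)
   and converted to ``rtilde_ij = |p/2 - rank_ij|``, which upweights both
   extremes of the expression spectrum.

3. **Weighted KS-like walk.**  For gene set γ, walking down the sample's
   decreasing-zhat ordering::

       nu(l) = sum_{i<=l, g(i) in γ} rtilde^tau / sum_{i<=p, g(i) in γ} rtilde^tau
             - sum_{i<=l, g(i) not in γ} 1 / (p - |γ|)

   The enrichment score is either the maximum deviation
   (``nu`` at ``argmax_l |nu(l)|``, "maxdev") or the difference of the
   positive and negative extremes, ``max(0, max nu) - max(0, -min nu)``
   ("diff", the default).  Scores live strictly inside (-1, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr  # standard normal CDF, vectorized

from .expression_io import ExpressionMatrix
from .genesets import GeneSetCollection, filter_by_size

logger = logging.getLogger(__name__)

VARIANTS = ("maxdev", "diff")

_KERNEL_BLOCK = 256  # genes per block when forming the pairwise-delta cube


@dataclass
class KernelCDFMatrix:
    """Kernel-CDF values zhat (genes x samples, each in (0,1)) + bandwidths."""

    values: pd.DataFrame
    bandwidths: pd.Series

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not ((v > 0) & (v < 1)).all():
            raise ValueError("kernel CDF values must lie strictly in (0, 1)")
        if not (self.bandwidths.to_numpy() > 0).all():
            raise ValueError("bandwidths must be positive")


@dataclass
class RankStatMatrix:
    """Per-sample gene orderings and the symmetric rank statistic.

    ``orderings[l, j]`` is the index (into ``genes``) of the gene at walk
    position l+1 in sample j; ``rtilde`` is genes x samples.
    """

    genes: list[str]
    samples: list[str]
    orderings: np.ndarray  # (p, n) int
    rtilde: np.ndarray     # (p, n) float, |p/2 - rank|


@dataclass
class WalkResult:
    nu: np.ndarray
    es_maxdev: float
    es_diff: float
    tau: float


@dataclass
class PathwayScoreMatrix:
    """Gene sets x samples enrichment scores, all strictly in (-1, 1)."""

    data: pd.DataFrame
    score_variant: str = "diff"

    def __post_init__(self) -> None:
        if self.score_variant not in VARIANTS:
            raise ValueError(f"unknown score variant {self.score_variant!r}")
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise ValueError("pathway score labels must be unique")

    @property
    def pathways(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def kernel_cdf(m: ExpressionMatrix) -> KernelCDFMatrix:
    """Gaussian-kernel expression CDF per gene, bandwidth s_i / 4."""
    if m.unit != "log2tpm1":
        raise ValueError(f"kernel_cdf expects log2tpm1 input, got {m.unit!r}")
    x = m.data.to_numpy(dtype=float)
    p, n = x.shape
    if n < 2:
        raise ValueError("kernel CDF needs at least 2 samples")
    s = x.std(axis=1, ddof=1)
    keep = s > 0
    if not keep.all():
        logger.info("kernel_cdf: dropped %d zero-variance genes", int((~keep).sum()))
    if not keep.any():
        raise ValueError("all genes have zero variance")
    x = x[keep]
    h = s[keep] / 4.0
    out = np.empty_like(x)
    for start in range(0, x.shape[0], _KERNEL_BLOCK):
        blk = slice(start, start + _KERNEL_BLOCK)
        delta = (x[blk, :, None] - x[blk, None, :]) / h[blk, None, None]
        out[blk] = ndtr(delta).mean(axis=2)
    genes = [g for g, k in zip(m.genes, keep) if k]
    return KernelCDFMatrix(
        values=pd.DataFrame(out, index=genes, columns=m.samples),
        bandwidths=pd.Series(h, index=genes),
    )


def rank_statistic(k: KernelCDFMatrix) -> RankStatMatrix:
    """Rank genes by decreasing zhat per sample; rtilde = |p/2 - rank|."""
    z = k.values.to_numpy()
    p, n = z.shape
    orderings = np.argsort(-z, axis=0, kind="stable")
    ranks = np.empty_like(orderings)
    pos = np.arange(1, p + 1)[:, None]
    np.put_along_axis(ranks, orderings, np.broadcast_to(pos, (p, n)), axis=0)
    rtilde = np.abs(p / 2.0 - ranks)
    return RankStatMatrix(
        genes=list(k.values.index),
        samples=list(k.values.columns),
        orderings=orderings,
        rtilde=rtilde,
    )


def _walk(rs_order: np.ndarray, member_order: np.ndarray) -> np.ndarray:
    """nu(l) for one (sample, set): rs/member indicator already in walk order."""
    p = rs_order.shape[0]
    m = int(member_order.sum())
    member_mass = float(rs_order[member_order].sum())
    if member_mass > 0:
        inc = np.where(member_order, rs_order, 0.0) / member_mass
    else:
        # all member statistics are exactly 0 (only possible for a single
        # mid-rank gene); fall back to uniform member weights
        logger.warning("enrichment walk: zero member mass; uniform member weights used")
        inc = member_order.astype(float) / m
    dec = (~member_order).astype(float) / (p - m)
    return np.cumsum(inc - dec)


_MAXDEV_TIE_TOL = 1e-12


def _scores_from_nu(nu: np.ndarray) -> tuple[float, float]:
    vmax = float(nu.max())
    vmin = float(nu.min())
    # maxdev is the extreme of larger magnitude; a near-tie (within
    # _MAXDEV_TIE_TOL) resolves to the positive extreme so the choice is
    # robust to summation-order rounding
    es_maxdev = vmax if vmax >= -vmin - _MAXDEV_TIE_TOL else vmin
    es_diff = float(max(0.0, vmax) - max(0.0, -vmin))
    return es_maxdev, es_diff


def enrichment_walk(
    r: RankStatMatrix,
    sample: str,
    members,
    tau: float = 1.0,
    variant: str = "diff",
) -> WalkResult:
    """Run the weighted KS-like walk for one sample and one gene set."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    j = r.samples.index(sample)
    member_set = set(members) & set(r.genes)
    p = len(r.genes)
    if not 0 < len(member_set) < p:
        raise ValueError("gene set must be a proper non-empty subset of the genes")
    member_bool = np.fromiter((g in member_set for g in r.genes), bool, count=p)
    order = r.orderings[:, j]
    rs_order = np.abs(r.rtilde[order, j]) ** tau
    nu = _walk(rs_order, member_bool[order])
    es_maxdev, es_diff = _scores_from_nu(nu)
    return WalkResult(nu=nu, es_maxdev=es_maxdev, es_diff=es_diff, tau=tau)


def gsva_scores(
    m: ExpressionMatrix,
    c: GeneSetCollection,
    variant: str = "diff",
    tau: float = 1.0,
    min_size: int = 5,
) -> PathwayScoreMatrix:
    """kernel_cdf -> rank_statistic -> enrichment_walk for every (set, sample)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    k = kernel_cdf(m)
    universe = list(k.values.index)
    filtered = filter_by_size(c, universe, min_size=min_size)
    r = rank_statistic(k)
    p, n = r.rtilde.shape
    gene_pos = {g: i for i, g in enumerate(r.genes)}
    member_masks = np.zeros((len(filtered), p), dtype=bool)
    for si, s in enumerate(filtered):
        member_masks[si, [gene_pos[g] for g in s.genes]] = True
    scores = np.empty((len(filtered), n))
    for j in range(n):
        order = r.orderings[:, j]
        rs_order = r.rtilde[order, j] ** tau
        masks_order = member_masks[:, order]
        for si in range(len(filtered)):
            nu = _walk(rs_order, masks_order[si])
            es_maxdev, es_diff = _scores_from_nu(nu)
            scores[si, j] = es_maxdev if variant == "maxdev" else es_diff
    return PathwayScoreMatrix(
        data=pd.DataFrame(scores, index=filtered.names(), columns=r.samples),
        score_variant=variant,
    )


def knn_impute_pathways(scores: PathwayScoreMatrix, k: int = 10) -> PathwayScoreMatrix:
    """Fill missing entries from the k nearest pathways (rows).

    Distance between rows is Euclidean over mutually observed columns
    (scaled to the full column count, which leaves neighbor order
    unchanged).  A missing entry becomes the mean of that column over the k
    nearest rows observed there; if no usable neighbor exists the row's own
    observed mean is used (logged).  A fully missing row is an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from sklearn.metrics.pairwise import nan_euclidean_distances

    X = scores.data.to_numpy(dtype=float).copy()
    obs = ~np.isnan(X)
    if (~obs).sum() == 0:
        return PathwayScoreMatrix(scores.data.copy(), scores.score_variant)
    if not obs.any(axis=1).all():
        bad = scores.data.index[~obs.any(axis=1)].tolist()
        raise ValueError(f"rows fully missing, cannot impute: {bad}")
    D = nan_euclidean_distances(X, X)
    np.fill_diagonal(D, np.inf)
    out = X.copy()
    for i, j in zip(*np.where(~obs)):
        cand = np.where(obs[:, j] & np.isfinite(D[:, i]))[0]
        cand = cand[cand != i]
        if len(cand) == 0:
            out[i, j] = X[i, obs[i]].mean()
            logger.info("knn_impute: row %s has no usable neighbor at column %s; row mean used",
                        scores.data.index[i], scores.data.columns[j])
            continue
        nearest = cand[np.argsort(D[cand, i], kind="stable")[:k]]
        out[i, j] = X[nearest, j].mean()
    return PathwayScoreMatrix(
        pd.DataFrame(out, index=scores.data.index, columns=scores.data.columns),
        scores.score_variant,
    )
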