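"""Resampling-based consensus clustering of samples.

The inner clusterer is unsupervised hierarchical clustering with
1 - Spearman correlation as the sample-sample distance and unweighted
average linkage (UPGMA).  Stability is assessed by repeatedly clustering a
random subsample of the cohort (without replacement) and recording, for
every sample pair, how often the two samples land in the same cluster among
the resamples that drew both.  The resulting consensus matrix is itself
hierarchically clustered to produce the final labels, and the per-k change
in the area under the consensus CDF drives an advisory choice of k.

Because the gene list is fixed (no gene resampling), the sample-sample
distance matrix is computed once and subsampling reduces to selecting a
submatrix, which makes hundreds of resamples cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .types import DegenerateInputError, ExpressionMatrix

__all__ = [
    "spearman_distance_matrix",
    "average_linkage_cluster",
    "consensus_cluster",
    "select_k",
    "ConsensusResult",
]

log = logging.getLogger("icpipe")


def spearman_distance_matrix(
    expr: ExpressionMatrix, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise sample distance d(i,j) = 1 - Spearman rho of the two
    expression profiles, over the given gene list (default: all genes).

    Distances lie in [0, 2]; the diagonal is exactly 0.  A sample whose
    profile is constant over the gene list has no rank correlation and is
    reported by name as an error.
    """
    values = expr.values
    if genes is not None:
        keep = values.index.intersection(pd.Index(genes))
        values = values.loc[keep]
    if values.shape[0] < 3:
        raise DegenerateInputError(
            f"need >= 3 genes for rank correlation, got {values.shape[0]}"
        )
    arr = values.to_numpy()
    constant = np.all(arr == arr[0, :], axis=0)
    if constant.any():
        name = values.columns[np.argmax(constant)]
        raise DegenerateInputError(f"constant expression profile for sample {name!r}")
    rho = stats.spearmanr(arr).statistic  # columns = samples
    if values.shape[1] == 2:  # spearmanr returns a scalar for 2 variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - np.asarray(rho, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def average_linkage_cluster(dist: pd.DataFrame | np.ndarray, k: int) -> np.ndarray:
    """UPGMA clustering of a square distance matrix, cut to exactly k groups.

    Returns integer labels 1..k in the row order of ``dist``.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == n:
        return np.arange(1, n + 1)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return hierarchy.fcluster(z, t=k, criterion="maxclust")


@dataclass
class ConsensusResult:
    """Output of :func:`consensus_cluster`.

    consensus
        per-k samples x samples matrix: co-cluster count / co-sample count.
    cosample_counts
        samples x samples counts of resamples drawing both samples.
    labels
        per-k final labels (1..k) from average-linkage clustering of
        1 - consensus.
    per_k_stats
        per-k DataFrame row: area under the consensus CDF and relative
        change versus the previous k (the advisory k-selection statistic).
    k_selected
        advisory k from :func:`select_k`.
    """

    consensus: dict[int, pd.DataFrame]
    cosample_counts: pd.DataFrame
    labels: dict[int, pd.Series]
    per_k_stats: pd.DataFrame
    k_selected: int


def _consensus_cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus entries.

    For values in [0, 1] this equals 1 - mean(entries): a larger area means
    more pairs with low co-clustering (less of the matrix saturated at 1).
    """
    iu = np.triu_indices_from(consensus, k=1)
    return float(1.0 - consensus[iu].mean())


def consensus_cluster(
    expr: ExpressionMatrix,
    genes: Sequence[str] | None,
    k_range: Sequence[int],
    config: PipelineConfig,
    center_genes: bool = True,
) -> ConsensusResult:
    """Consensus clustering over a range of candidate k.

    For each of ``config.consensus_n_resamples`` resamples,
    ``ceil(fraction * n)`` samples are drawn without replacement and the
    subsample is clustered at every k; co-clustering and co-sampling counts
    accumulate into the consensus matrices.  Deterministic given
    ``config.rng_seed``.

    ``center_genes`` subtracts each gene's median across samples before
    computing distances (standard practice for correlation-based sample
    clustering): without it the shared per-gene baseline dominates every
    sample-sample rank correlation and even structureless cohorts cluster
    deceptively stably.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if len(k_range) < 1:
        raise ValueError("k_range must contain at least one k")
    if center_genes:
        values = expr.values
        if genes is not None:
            values = values.loc[values.index.intersection(pd.Index(genes))]
        expr = ExpressionMatrix(values.sub(values.median(axis=1), axis=0))
        genes = None
    dist = spearman_distance_matrix(expr, genes)
    samples = dist.index
    n = len(samples)
    if max(k_range) > n:
        raise ValueError(f"max k {max(k_range)} exceeds n={n}")
    m = int(np.ceil(config.consensus_subsample_fraction * n))
    m = max(m, max(k_range))
    rng = np.random.default_rng(config.rng_seed)
    d = dist.to_numpy()

    cosample = np.zeros((n, n), dtype=np.int64)
    cocluster = {k: np.zeros((n, n), dtype=np.int64) for k in k_range}
    for _ in range(config.consensus_n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        cosample[np.ix_(idx, idx)] += 1
        sub = d[np.ix_(idx, idx)]
        z = hierarchy.linkage(squareform(sub, checks=False), method="average")
        for k in k_range:
            lab = (
                hierarchy.fcluster(z, t=k, criterion="maxclust")
                if k < m
                else np.arange(1, m + 1)
            )
            same = lab[:, None] == lab[None, :]
            cocluster[k][np.ix_(idx, idx)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {
            k: np.where(cosample > 0, cocluster[k] / np.maximum(cosample, 1), 0.0)
            for k in k_range
        }

    labels: dict[int, pd.Series] = {}
    areas: list[float] = []
    for k in k_range:
        lab = average_linkage_cluster(1.0 - consensus[k], k)
        labels[k] = pd.Series(lab, index=samples, name="cluster")
        areas.append(_consensus_cdf_area(consensus[k]))
    per_k = pd.DataFrame({"k": k_range, "cdf_area": areas})
    deltas = [areas[0]]
    for i in range(1, len(areas)):
        prev = areas[i - 1]
        deltas.append((areas[i] - prev) / prev if prev > 0 else 0.0)
    per_k["delta_area"] = deltas
    k_sel = select_k(per_k)
    log.info("consensus_cluster: n=%d, k candidates %s, advisory k=%d", n, k_range, k_sel)
    return ConsensusResult(
        consensus={k: pd.DataFrame(consensus[k], index=samples, columns=samples) for k in k_range},
        cosample_counts=pd.DataFrame(cosample, index=samples, columns=samples),
        labels=labels,
        per_k_stats=per_k,
        k_selected=k_sel,
    )


def select_k(per_k_stats: pd.DataFrame) -> int:
    """Advisory number of clusters from consensus-CDF areas.

    ``delta_area`` is the relative gain in area under the consensus CDF
    when moving to each k from the previous one (for the smallest candidate
    k it is the area itself).  The chosen k is the one after which the gain
    curve flattens most sharply — argmax over k of
    ``delta_area(k) / delta_area(k_next)`` — i.e. the largest k that adds
    substantial partition structure while the next k adds little.  This
    elbow form is used rather than a fixed cut-off on ``delta_area``
    because the residual gains beyond the true k fluctuate around any
    fixed threshold, while the flattening ratio at the true k is an order
    of magnitude larger than elsewhere.

    Ties go to the smallest k.  The largest candidate k carries no
    flattening evidence and cannot be chosen; extend the candidate range
    one k beyond the largest value of interest (as any elbow criterion
    requires).  The full statistics are reported so the choice can be
    overridden by eye, which is how the cluster count is usually fixed in
    practice.
    """
    ks = per_k_stats["k"].to_list()
    deltas = per_k_stats["delta_area"].to_list()
    if len(ks) < 2:
        return int(ks[0])
    ratios = [deltas[i] / max(deltas[i + 1], 1e-12) for i in range(len(ks) - 1)]
    return int(ks[int(np.argmax(ratios))])


def name_clusters(
    labels: Mapping[str, int] | pd.Series,
    enrichment: pd.DataFrame | None = None,
    reference_sets: Sequence[str] | None = None,
) -> dict[int, str]:
    """Map raw cluster numbers to semantic names IC1/IC2/...

    If an enrichment matrix (gene sets x samples) and reference set names
    (e.g. mitochondrial / oxidative-phosphorylation sets) are given, IC1 is
    the cluster with the highest mean reference enrichment, then descending.
    Otherwise clusters are anchored lexicographically: the cluster holding
    the alphabetically first sample becomes IC1.
    """
    labels = pd.Series(labels)
    clusters = sorted(labels.unique())
    if enrichment is not None and reference_sets:
        ref = [s for s in reference_sets if s in enrichment.index]
        if ref:
            means = {
                c: float(enrichment.loc[ref, labels.index[labels == c]].mean().mean())
                for c in clusters
            }
            order = sorted(clusters, key=lambda c: (-means[c], c))
            return {int(c): f"IC{i + 1}" for i, c in enumerate(order)}
    anchor = {c: min(labels.index[labels == c]) for c in clusters}
    order = sorted(clusters, key=lambda c: anchor[c])
    log.info("name_clusters: lexicographic anchor used (%s)", anchor)
    return {int(c): f"IC{i + 1}" for i, c in enumerate(order)}
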