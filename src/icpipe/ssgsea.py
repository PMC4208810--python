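"""Single-sample gene-set enrichment (ssGSEA) scoring and subtype pathways.

For one sample, genes are ordered by decreasing expression (ties broken by
gene ID) and assigned descending-rank weights r (top gene gets r = N).  The
enrichment score of a set S is the summed difference of two running
distributions over the ordered gene list:

    P_in(i)  = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha
    P_out(i) = #{j<=i, j not in S} / (N - |S|)
    ES       = sum_i ( P_in(i) - P_out(i) )

This is the sum variant used in single-sample enrichment work, not the
max-deviation statistic of classical two-group GSEA; it depends only on
expression ranks, so it is invariant to any strictly monotone transform of
the profile.  Scores across a cohort are rank-normalised to [0, 1] by a
global min-max map before downstream comparison, and subtype-specific
pathways are called by SAM on the normalised score matrix together with a
fold-change filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .sam import sam_analyze
from .types import DegenerateInputError, ExpressionMatrix, GeneSetCollection

__all__ = [
    "ssgsea_score",
    "enrichment_matrix",
    "rank_normalize",
    "subtype_pathways",
    "EnrichmentMatrix",
]

log = logging.getLogger("icpipe")


@dataclass
class EnrichmentMatrix:
    """Gene sets x samples enrichment scores with scoring metadata."""

    scores: pd.DataFrame
    alpha: float
    normalized: bool = False
    variant: str = "sum-of-differences"


def _ordered_ranks(profile: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Gene order (descending expression, ties by gene ID) and descending
    ranks r (top = N) for one expression profile."""
    by_id = np.argsort(profile.index.to_numpy().astype(str), kind="mergesort")
    vals = profile.to_numpy()[by_id]
    idx = by_id[np.argsort(-vals, kind="mergesort")]
    n = len(profile)
    ranks = np.arange(n, 0, -1, dtype=float)  # r at ordered position i is N-i
    return idx, ranks


def _es_from_order(
    in_set_ordered: np.ndarray, ranks: np.ndarray, alpha: float
) -> float:
    n = in_set_ordered.size
    n_in = int(in_set_ordered.sum())
    if n_in == 0:
        raise DegenerateInputError("gene set does not intersect the profile")
    if n_in == n:
        raise DegenerateInputError("gene set covers every profile gene")
    w = np.where(in_set_ordered, ranks**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_set_ordered) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_score(profile: pd.Series, gene_set: Sequence[str], alpha: float = 0.25) -> float:
    """Enrichment score of one gene set in one sample's expression profile."""
    order, ranks = _ordered_ranks(profile)
    members = set(gene_set)
    in_set = profile.index.to_numpy()[order]
    in_set = np.fromiter((g in members for g in in_set), dtype=bool, count=len(in_set))
    return _es_from_order(in_set, ranks, alpha)


def enrichment_matrix(
    expr: ExpressionMatrix, gene_sets: GeneSetCollection, alpha: float = 0.25
) -> EnrichmentMatrix:
    """ssGSEA scores for every (gene set, sample) pair (unnormalised)."""
    genes = expr.values.index.to_numpy()
    set_masks = {}
    for name in gene_sets.names():
        members = set(gene_sets.members(name))
        mask = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
        set_masks[name] = mask
        if not mask.any():
            raise DegenerateInputError(f"gene set {name!r} does not intersect the matrix")
        if mask.all():
            raise DegenerateInputError(f"gene set {name!r} covers every gene")
    out = np.empty((len(set_masks), len(expr.samples)))
    for j, sample in enumerate(expr.samples):
        profile = expr.values.iloc[:, j]
        order, ranks = _ordered_ranks(profile)
        for i, name in enumerate(gene_sets.names()):
            out[i, j] = _es_from_order(set_masks[name][order], ranks, alpha)
    scores = pd.DataFrame(out, index=gene_sets.names(), columns=expr.samples)
    return EnrichmentMatrix(scores=scores, alpha=alpha, normalized=False)


def rank_normalize(es: EnrichmentMatrix) -> EnrichmentMatrix:
    """Linear rescale of the whole score matrix to [0, 1] (global min-max).

    Order-preserving; the global minimum maps to exactly 0 and the maximum
    to exactly 1.  A constant matrix is degenerate.
    """
    arr = es.scores.to_numpy()
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateInputError("constant enrichment matrix cannot be normalised")
    scaled = (es.scores - lo) / (hi - lo)
    return EnrichmentMatrix(scores=scaled, alpha=es.alpha, normalized=True,
                            variant=es.variant)


def subtype_pathways(
    es: EnrichmentMatrix,
    labels: Sequence,
    config: PipelineConfig,
    classes: Sequence | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Subtype-specific pathway calls from a normalised enrichment matrix.

    SAM runs on the pathway x sample score matrix; the fold change is
    mean(class1) / mean(class2) with the denominator floored at 1e-6.
    A pathway is called UP (in class1) when q < pathway_q_threshold and
    fc > pathway_fc_up, DOWN when q < threshold and fc < pathway_fc_down,
    otherwise NONE.
    """
    if not es.normalized:
        raise ValueError("subtype_pathways expects a rank-normalised matrix")
    sam = sam_analyze(
        es.scores,
        labels,
        n_permutations=config.sam_n_permutations,
        seed=config.rng_seed if seed is None else seed,
        s0_percentiles=config.sam_s0_percentiles,
        classes=classes,
    )
    c1, c2 = sam.classes
    labels_arr = np.asarray(labels)
    mean1 = es.scores.loc[:, labels_arr == c1].mean(axis=1)
    mean2 = es.scores.loc[:, labels_arr == c2].mean(axis=1)
    fc = mean1 / np.maximum(mean2, 1e-6)
    tab = sam.table.set_index("feature")
    call = np.where(
        (tab["q"] < config.pathway_q_threshold) & (fc > config.pathway_fc_up),
        "UP",
        np.where(
            (tab["q"] < config.pathway_q_threshold) & (fc < config.pathway_fc_down),
            "DOWN",
            "NONE",
        ),
    )
    out = pd.DataFrame(
        {
            "pathway": tab.index,
            "d": tab["d"].to_numpy(),
            "q": tab["q"].to_numpy(),
            "fold_change": fc.to_numpy(),
            "call": call,
        }
    ).reset_index(drop=True)
    n_up, n_down = int((out["call"] == "UP").sum()), int((out["call"] == "DOWN").sum())
    log.info("subtype_pathways: %d UP, %d DOWN of %d pathways", n_up, n_down, len(out))
    return out
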