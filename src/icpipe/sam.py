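"""Significance Analysis of Microarrays (SAM), two-class unpaired design.

For each feature the statistic is a moderated t:

    d_i = (mean_1i - mean_2i) / (s_i + s0)

with the pooled scatter

    s_i = sqrt( (1/n1 + 1/n2) * (SS_1i + SS_2i) / (n1 + n2 - 2) )

and a fudge constant s0 chosen to make |d| comparable across the range of
s (features with tiny scatter would otherwise dominate).  False-discovery
q-values come from permuting the class labels: for each threshold t equal
to an observed |d|, the estimated FDR is the median, across permutations,
of the number of permuted |d*| exceeding t, divided by the observed count;
a feature's q is the smallest FDR at any threshold it clears.

The module also derives a subtype signature (features below a q cut-off,
tagged with the class they are up-regulated in) and assigns new samples to
a class by nearest centroid under Spearman correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DegenerateInputError

__all__ = [
    "sam_statistic",
    "estimate_s0",
    "sam_qvalues",
    "sam_analyze",
    "select_signature",
    "class_centroids",
    "classify_sample",
    "SamResult",
]

log = logging.getLogger("icpipe")


def _two_class_masks(labels: Sequence, classes: Sequence | None = None):
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    m1 = labels == classes[0]
    m2 = labels == classes[1]
    if not (m1 | m2).all():
        raise ValueError("labels contain values outside the two classes")
    return np.asarray(classes), m1, m2


def sam_statistic(
    values: pd.DataFrame | np.ndarray,
    labels: Sequence,
    s0: float,
    classes: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature SAM d and pooled scatter s.

    ``values`` is features x samples; ``labels`` assigns each sample
    (column) to one of two classes.  The sign convention is
    class1 - class2 with classes in sorted order unless ``classes`` is
    given explicitly.  Both classes need >= 2 samples.
    """
    arr = np.asarray(values, dtype=float)
    _, m1, m2 = _two_class_masks(labels, classes)
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError(f"each class needs >= 2 samples (got {n1}, {n2})")
    x1, x2 = arr[:, m1], arr[:, m2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mean1 - mean2) / (s + s0)
    d = np.nan_to_num(d, nan=0.0, posinf=np.inf, neginf=-np.inf)
    return d, s


def estimate_s0(
    values: pd.DataFrame | np.ndarray,
    labels: Sequence,
    percentiles: Sequence[int] = tuple(range(0, 101, 5)),
    n_windows: int = 10,
    classes: Sequence | None = None,
) -> float:
    """Fudge factor s0 stabilising |d| across the scatter range.

    Candidate s0 values are percentiles of the per-feature scatter s; the
    chosen candidate minimises the coefficient of variation of the median
    |d| computed within s-quantile windows.  Deterministic; returns 0 when
    every feature has the same scatter.
    """
    arr = np.asarray(values, dtype=float)
    _, s = sam_statistic(arr, labels, 0.0, classes)
    if np.allclose(s, s[0]):
        return 0.0
    candidates = np.percentile(s, sorted(set(int(p) for p in percentiles)))
    if candidates.size == 1:
        return float(candidates[0])
    # s0 = 0 (no moderation) always competes, as in the original procedure
    candidates = np.unique(np.append(candidates, 0.0))
    # s-quantile windows (equal feature counts)
    order = np.argsort(s, kind="mergesort")
    windows = np.array_split(order, min(n_windows, len(s)))
    numer = arr  # d numerator recomputed per candidate via sam_statistic
    best_s0, best_cv = 0.0, math.inf
    d0_num, _ = sam_statistic(arr, labels, 0.0, classes)
    numerator = d0_num * s  # = mean difference, independent of s0
    for cand in candidates:
        d = numerator / (s + cand)
        med = np.array([np.median(np.abs(d[w])) for w in windows if len(w)])
        mean = med.mean()
        if mean == 0:
            continue
        cv = med.std(ddof=1) / mean if len(med) > 1 else 0.0
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


def _distinct_label_permutations(
    m1: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean matrix (n_perm x n_samples): membership of class 1 per permutation.

    All C(n, n1) distinct assignments are enumerated when there are at most
    ``n_permutations`` of them; otherwise that many distinct assignments are
    sampled uniformly without replacement (the observed assignment is always
    part of an enumeration but not forced into a sample).
    """
    n = m1.size
    n1 = int(m1.sum())
    total = math.comb(n, n1)
    if total <= n_permutations:
        out = np.zeros((total, n), dtype=bool)
        for r, pos in enumerate(combinations(range(n), n1)):
            out[r, list(pos)] = True
        return out
    seen: set[tuple[int, ...]] = set()
    rows: list[np.ndarray] = []
    while len(rows) < n_permutations:
        pos = tuple(sorted(map(int, rng.choice(n, size=n1, replace=False))))
        if pos in seen:
            continue
        seen.add(pos)
        row = np.zeros(n, dtype=bool)
        row[list(pos)] = True
        rows.append(row)
    return np.vstack(rows)


def _perm_d_matrix(arr: np.ndarray, perm_m1: np.ndarray, s0: float) -> np.ndarray:
    """d statistics for every permutation: features x permutations."""
    n = arr.shape[1]
    n1 = int(perm_m1[0].sum())
    n2 = n - n1
    ind1 = perm_m1.T.astype(float)  # samples x perms
    ind2 = 1.0 - ind1
    sum1 = arr @ ind1
    sum2 = arr @ ind2
    sq = arr**2
    sumsq1 = sq @ ind1
    sumsq2 = sq @ ind2
    mean1, mean2 = sum1 / n1, sum2 / n2
    ss = (sumsq1 - n1 * mean1**2) + (sumsq2 - n2 * mean2**2)
    ss = np.maximum(ss, 0.0)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mean1 - mean2) / (s + s0)
    # zero scatter with equal means is a no-signal feature, not a NaN
    return np.nan_to_num(d, nan=0.0, posinf=np.inf, neginf=-np.inf)


def sam_qvalues(
    values: pd.DataFrame | np.ndarray,
    labels: Sequence,
    s0: float,
    n_permutations: int = 1000,
    seed: int = 0,
    classes: Sequence | None = None,
) -> np.ndarray:
    """Permutation q-values for the SAM statistic.

    Thresholds are the observed |d| values; FDR(t) = median over
    permutations of #{|d*| >= t} divided by #{|d| >= t}; a feature's q is
    the minimum FDR over thresholds at or below its own |d|, capped at 1
    (which also makes q non-increasing in |d|).  With an exhaustive
    enumeration of label permutations the result is seed-independent.
    """
    arr = np.asarray(values, dtype=float)
    _, m1, m2 = _two_class_masks(labels, classes)
    if m1.sum() < 2 or m2.sum() < 2:
        raise DegenerateInputError("each class needs >= 2 samples")
    d_obs, _ = sam_statistic(arr, labels, s0, classes)
    rng = np.random.default_rng(seed)
    perm_m1 = _distinct_label_permutations(m1, n_permutations, rng)
    d_perm = np.abs(_perm_d_matrix(arr, perm_m1, s0))  # features x perms
    d_perm_sorted = np.sort(d_perm, axis=0)  # ascending per permutation

    abs_obs = np.abs(d_obs)
    order = np.argsort(abs_obs, kind="mergesort")  # ascending
    thresholds = abs_obs[order]
    n_feat = len(abs_obs)
    # observed counts >= threshold, for thresholds in ascending order
    obs_counts = n_feat - np.arange(n_feat)
    # permutation counts >= each threshold: per permutation via searchsorted
    perm_counts = np.empty((d_perm_sorted.shape[1], n_feat), dtype=np.int64)
    for p in range(d_perm_sorted.shape[1]):
        perm_counts[p] = n_feat - np.searchsorted(d_perm_sorted[:, p], thresholds, side="left")
    med_counts = np.median(perm_counts, axis=0)
    fdr = np.minimum(med_counts / obs_counts, 1.0)
    # q of a feature = min FDR over thresholds at or below its |d|
    # -> running minimum over ascending thresholds
    q_sorted = np.minimum.accumulate(fdr)
    q = np.empty(n_feat)
    q[order] = q_sorted
    return q


@dataclass
class SamResult:
    """SAM analysis of one two-class comparison.

    ``table`` has one row per feature: ``feature, mean_diff, s, d, q``;
    ``classes`` records the (class1, class2) sign convention.
    """

    table: pd.DataFrame
    s0: float
    n_permutations: int
    classes: tuple

    def signature(self, q_threshold: float) -> pd.DataFrame:
        return select_signature(self, q_threshold)


def sam_analyze(
    values: pd.DataFrame,
    labels: Sequence,
    n_permutations: int = 1000,
    seed: int = 0,
    s0: float | None = None,
    s0_percentiles: Sequence[int] = tuple(range(0, 101, 5)),
    classes: Sequence | None = None,
) -> SamResult:
    """Full SAM run: s0 estimation (unless given), d, s and q per feature."""
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(np.asarray(values, dtype=float))
    cls, m1, m2 = _two_class_masks(labels, classes)
    if s0 is None:
        s0 = estimate_s0(values, labels, s0_percentiles, classes=cls)
    d, s = sam_statistic(values, labels, s0, classes=cls)
    q = sam_qvalues(values, labels, s0, n_permutations, seed, classes=cls)
    mean_diff = d * (s + s0)
    table = pd.DataFrame(
        {"feature": values.index, "mean_diff": mean_diff, "s": s, "d": d, "q": q}
    ).reset_index(drop=True)
    n_perm_used = min(n_permutations, math.comb(len(m1), int(m1.sum())))
    return SamResult(table=table, s0=float(s0), n_permutations=n_perm_used,
                     classes=tuple(cls.tolist()))


def select_signature(sam: SamResult, q_threshold: float) -> pd.DataFrame:
    """Features with q below the threshold, tagged with the class they are
    up-regulated in (sign of d); an empty signature is allowed and logged."""
    tab = sam.table
    sel = tab.loc[tab["q"] < q_threshold].copy()
    c1, c2 = sam.classes
    sel["up_in"] = np.where(sel["d"] > 0, c1, c2)
    if sel.empty:
        log.info("select_signature: empty signature at q<%g", q_threshold)
    return sel.reset_index(drop=True)


def class_centroids(
    values: pd.DataFrame, labels: Sequence, signature_features: Sequence[str],
    classes: Sequence | None = None,
) -> pd.DataFrame:
    """Per-class mean expression over signature features (training centroids)."""
    cls, m1, m2 = _two_class_masks(np.asarray(labels), classes)
    feats = values.index.intersection(pd.Index(signature_features))
    if len(feats) == 0:
        raise DegenerateInputError("no signature features present in the matrix")
    sub = values.loc[feats]
    return pd.DataFrame(
        {cls[0]: sub.loc[:, np.asarray(m1)].mean(axis=1),
         cls[1]: sub.loc[:, np.asarray(m2)].mean(axis=1)}
    )


def classify_sample(
    profile: pd.Series, centroids: pd.DataFrame
) -> tuple[object, dict[object, float]]:
    """Nearest-centroid class assignment under Spearman correlation.

    ``profile`` must cover at least half of the centroid (signature)
    features; returns the winning class and the correlation with every
    centroid.  Ties go to the first class in centroid column order.
    """
    shared = centroids.index.intersection(profile.index)
    if len(shared) < 0.5 * len(centroids.index):
        raise DegenerateInputError(
            f"profile covers {len(shared)}/{len(centroids.index)} signature features (<50%)"
        )
    scores: dict[object, float] = {}
    for cls in centroids.columns:
        scores[cls] = float(
            stats.spearmanr(profile.loc[shared], centroids.loc[shared, cls]).statistic
        )
    best = max(centroids.columns, key=lambda c: scores[c])
    return best, scores
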