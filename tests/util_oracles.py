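"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (explicit
loops, full enumeration) and shares no code with the package internals.
"""

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb


def mw_enumeration_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating every assignment of the
    pooled tie-free values to the two groups."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    m = n1 * len(y)

    def u_min(group1):
        group2 = [v for v in pooled if v not in group1]
        u = sum(1 for a in group1 for b in group2 if a > b)
        return min(u, m - u)

    observed = u_min(x)
    hits = 0
    total = 0
    for pos in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in pos]
        total += 1
        if u_min(g1) <= observed:
            hits += 1
    return observed, hits / total


def ssgsea_brute_force(profile: pd.Series, gene_set, alpha: float) -> float:
    """Running-sum enrichment score computed step by step."""
    ordered = sorted(profile.index, key=lambda g: (-profile[g], g))
    n = len(ordered)
    members = set(gene_set) & set(profile.index)
    n_in = len(members)
    assert 0 < n_in < n
    rank_of = {g: n - i for i, g in enumerate(ordered)}  # top gene -> N
    denom_in = sum(rank_of[g] ** alpha for g in members)
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for g in ordered:
        if g in members:
            p_in += rank_of[g] ** alpha / denom_in
        else:
            p_out += 1.0 / (n - n_in)
        es += p_in - p_out
    return es


def adjusted_rand_index(a, b) -> float:
    """ARI from the contingency table (label-permutation invariant)."""
    ct = pd.crosstab(pd.Series(np.asarray(a)), pd.Series(np.asarray(b))).to_numpy()
    s = comb(ct, 2).sum()
    r = comb(ct.sum(axis=1), 2).sum()
    c = comb(ct.sum(axis=0), 2).sum()
    n = comb(ct.sum(), 2)
    expected = r * c / n
    denom = (r + c) / 2 - expected
    return 1.0 if denom == 0 else float((s - expected) / denom)


def upgma_4point():
    """Hand-computed UPGMA merge schedule for a fixed 4-point metric.

    Points a,b,c,d with d(a,b)=2, d(c,d)=3, d(a,c)=8, d(a,d)=9, d(b,c)=9,
    d(b,d)=10: merges (a,b)@2, (c,d)@3, then the two pairs at the
    unweighted average (8+9+9+10)/4 = 9.
    """
    dist = np.array(
        [
            [0.0, 2.0, 8.0, 9.0],
            [2.0, 0.0, 9.0, 10.0],
            [8.0, 9.0, 0.0, 3.0],
            [9.0, 10.0, 3.0, 0.0],
        ]
    )
    heights = [2.0, 3.0, 9.0]
    return dist, heights
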