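"""Selection of putative CNV-driven genes.

A gene is called a driver when its expression differs between samples
carrying its dominant copy-number aberration and copy-neutral samples
(two-sided Mann-Whitney U test) *and* its expression tracks the numeric
copy dose (LOSS=-1, NEUTRAL=0, GAIN=+1) monotonically (Spearman rho above a
threshold).  Both filters must pass jointly; no multiple-testing correction
is applied at this stage — the rho filter, not the p-value alone, carries
the specificity.

The rho is always computed between dose and expression, so concordance has
the same sign for gain-driven (more copies, more transcript) and
loss-driven (fewer copies, less transcript) genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .types import (
    GAIN,
    LOSS,
    NEUTRAL,
    CopyNumberCalls,
    DegenerateInputError,
    ExpressionMatrix,
)

__all__ = ["mann_whitney_u", "spearman_rho", "select_drivers", "DriverGeneRecord"]

log = logging.getLogger("icpipe")

#: largest combined sample size for which the exact permutation null of the
#: Mann-Whitney U statistic is enumerated (tie-free data only)
EXACT_MW_LIMIT = 20


@dataclass
class DriverGeneRecord:
    gene: str
    direction: str  # "GAIN" or "LOSS"
    u_statistic: float
    p_value: float
    rho: float
    selected: bool
    reason: str  # "ok" or why the gene was untestable


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(u_min, p)`` where ``u_min = min(U_x, U_y)`` with half credit
    for ties.  The p-value is exact (full enumeration of the permutation
    null) when ``len(x) + len(y) <= 20`` and the data are tie-free,
    otherwise the normal approximation with tie and continuity correction
    is used.  p is capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("Mann-Whitney groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u_x = float(res.statistic)
    u_min = min(u_x, x.size * y.size - u_x)
    return u_min, float(min(res.pvalue, 1.0))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks under ties).

    Requires equal lengths >= 3; a constant vector has no defined rank
    correlation and raises :class:`DegenerateInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateInputError("Spearman rho needs at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input: Spearman rho undefined")
    return float(stats.spearmanr(x, y).statistic)


def _align(calls: CopyNumberCalls, expr: ExpressionMatrix):
    shared_samples = [s for s in calls.samples if s in set(expr.samples)]
    if not shared_samples:
        raise DegenerateInputError("no shared samples between calls and expression")
    shared_genes = calls.state.index.intersection(expr.values.index)
    n_drop = (len(calls.genes) - len(shared_genes)) + (len(expr.genes) - len(shared_genes))
    if n_drop:
        log.info("select_drivers: dropped %d genes absent from one matrix", n_drop)
    log.info(
        "select_drivers: %d genes x %d shared samples", len(shared_genes), len(shared_samples)
    )
    state = calls.state.loc[shared_genes, shared_samples]
    values = expr.values.loc[shared_genes, shared_samples]
    return state, values


def select_drivers(
    calls: CopyNumberCalls, expr: ExpressionMatrix, config: PipelineConfig
) -> pd.DataFrame:
    """Test every shared gene for a copy-number-driven expression pattern.

    Returns one row per shared gene with columns ``gene, direction,
    u_statistic, p_value, rho, selected, reason``.  Untestable genes
    (too few aberrant or neutral samples, constant dose or expression) are
    reported with ``selected=False`` and a reason code rather than dropped,
    so the output is a complete audit of the input gene space.
    """
    state, values = _align(calls, expr)
    m = config.min_group_size
    rows: list[DriverGeneRecord] = []
    st_arr = state.to_numpy()
    ex_arr = values.to_numpy()
    for i, gene in enumerate(state.index):
        st = st_arr[i]
        ex = ex_arr[i]
        n_gain = int((st == GAIN).sum())
        n_loss = int((st == LOSS).sum())
        direction = "GAIN" if n_gain >= n_loss else "LOSS"
        if n_gain == n_loss and n_gain > 0:
            log.debug("gene %s: GAIN/LOSS tie (%d each); direction set to GAIN", gene, n_gain)
        dir_state = GAIN if direction == "GAIN" else LOSS
        aberrant = st == dir_state
        neutral = st == NEUTRAL
        rec = DriverGeneRecord(gene, direction, np.nan, np.nan, np.nan, False, "ok")
        if aberrant.sum() < m:
            rec.reason = "too_few_aberrant"
        elif neutral.sum() < m:
            rec.reason = "too_few_neutral"
        elif np.all(ex == ex[0]):
            rec.reason = "constant_expression"
        else:
            rec.u_statistic, rec.p_value = mann_whitney_u(ex[aberrant], ex[neutral])
            rec.rho = spearman_rho(st.astype(float), ex)
            rec.selected = bool(
                rec.p_value < config.driver_p_threshold
                and rec.rho > config.driver_rho_threshold
            )
        rows.append(rec)
    out = pd.DataFrame([r.__dict__ for r in rows])
    n_sel = int(out["selected"].sum())
    log.info("select_drivers: %d/%d genes selected", n_sel, len(out))
    return out
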