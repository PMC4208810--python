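"""Dose-response summarisation and differential chemosensitivity.

Viability curves from serial-dilution assays are refit with the standard
four-parameter logistic

    v(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

on log concentration; an IC50 at or beyond the top tested dose (or a curve
that never reaches half-inhibition in the tested range) is reported capped
at the top dose with a ``censored`` flag rather than dropped, since
discarding non-responders would bias a cohort toward apparent sensitivity.

Per-drug comparison between integrative clusters uses the two-sided
Mann-Whitney U test on log10 IC50 (the rank statistic is identical on the
raw scale), the per-cluster medians, and their ratio as the fold
difference with the more-sensitive (lower-median) cluster named.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .drivers import mann_whitney_u
from .types import DegenerateInputError, Ic50Table

__all__ = [
    "dilution_series",
    "DoseResponse",
    "Ic50Fit",
    "fit_ic50",
    "compare_clusters",
    "compare_all_drugs",
    "DrugComparison",
]

log = logging.getLogger("icpipe")


def dilution_series(
    start_uM: float, ratio: float = 4.0, n_points: int = 9, assay_dilution: float = 0.5
) -> np.ndarray:
    """Final assay concentrations of a serial dilution, descending (µM).

    ``start_uM`` is the top stock concentration, diluted by ``ratio`` at
    each step; ``assay_dilution`` accounts for adding compound to an equal
    volume of cells (0.5 for a 1:1 addition).
    """
    if start_uM <= 0 or ratio <= 1 or n_points < 1 or assay_dilution <= 0:
        raise ValueError("need start>0, ratio>1, n_points>=1, assay_dilution>0")
    return start_uM * ratio ** -np.arange(n_points, dtype=float) * assay_dilution


@dataclass
class DoseResponse:
    """Replicate-averaged viability fractions at descending concentrations."""

    drug: str
    sample: str
    concentrations_uM: np.ndarray
    viabilities: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_uM, dtype=float)
        v = np.asarray(self.viabilities, dtype=float)
        if c.shape != v.shape:
            raise ValueError("concentrations and viabilities must have equal length")
        if (c <= 0).any() or (np.diff(c) >= 0).any():
            raise ValueError("concentrations must be positive and strictly decreasing")
        self.concentrations_uM, self.viabilities = c, v


@dataclass
class Ic50Fit:
    ic50_uM: float | None
    hill: float | None
    top: float | None
    bottom: float | None
    converged: bool
    censored: bool


def _four_pl(log10_c: np.ndarray, log10_ic50: float, hill: float, top: float,
             bottom: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log10_c - log10_ic50)))


def fit_ic50(dr: DoseResponse) -> Ic50Fit:
    """Least-squares 4PL refit of one dose-response curve.

    Multi-start initialisation over candidate IC50s spanning the tested
    range; non-convergence from every start is flagged rather than guessed.
    ``censored=True`` when the fitted IC50 exceeds the top tested dose or
    the fitted curve never drops to half of its top plateau within the
    tested range; the reported IC50 is then the top tested concentration.
    """
    c = dr.concentrations_uM
    v = dr.viabilities
    if c.size < 4:
        raise ValueError("need >= 4 concentration points for a 4PL fit")
    logc = np.log10(c)
    lo, hi = logc.min(), logc.max()
    bounds = ([lo - 3.0, 0.1, 0.2, -0.5], [hi + 3.0, 10.0, 1.5, 0.6])
    best = None
    best_sse = np.inf
    for ic_start in np.linspace(lo, hi, 5):
        for hill_start in (0.5, 1.0, 2.0):
            p0 = [ic_start, hill_start, float(np.clip(v.max(), 0.3, 1.4)),
                  float(np.clip(v.min(), -0.4, 0.5))]
            try:
                popt, _ = curve_fit(_four_pl, logc, v, p0=p0, bounds=bounds,
                                    maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((_four_pl(logc, *popt) - v) ** 2))
            if sse < best_sse:
                best_sse, best = sse, popt
    if best is None:
        return Ic50Fit(None, None, None, None, converged=False, censored=False)
    log10_ic50, hill, top, bottom = (float(x) for x in best)
    ic50 = 10.0**log10_ic50
    top_dose = float(c.max())
    half = bottom + (top - bottom) / 2.0
    v_at_top_dose = float(_four_pl(np.array([hi]), *best)[0])
    censored = ic50 > top_dose or v_at_top_dose > 0.5 or abs(top - bottom) < 0.1
    if censored:
        ic50 = top_dose
    return Ic50Fit(ic50, hill, top, bottom, converged=True, censored=censored)


@dataclass
class DrugComparison:
    drug: str
    median_by_cluster: dict
    fold_difference: float
    u_statistic: float
    p_value: float
    n_by_cluster: dict
    sensitive_cluster: object


def compare_clusters(
    ic50: Ic50Table,
    labels: Mapping[str, object] | pd.Series,
    drug: str,
    min_group_size: int = 3,
) -> DrugComparison:
    """Two-sided Mann-Whitney comparison of one drug's IC50s between two clusters.

    Censored records participate at their capped value (ties handled by the
    rank test's midrank/tie correction).  The fold difference is the ratio
    of the larger to the smaller cluster median, and the cluster with the
    smaller median IC50 is named the sensitive one.
    """
    labels = pd.Series(labels)
    rec = ic50.for_drug(drug)
    if rec.empty:
        raise DegenerateInputError(f"no IC50 records for drug {drug!r}")
    rec = rec.loc[rec["sample"].isin(labels.index)]
    clusters = sorted(pd.unique(labels.loc[rec["sample"]]))
    if len(clusters) != 2:
        raise DegenerateInputError(
            f"drug {drug!r}: need samples from exactly 2 clusters, got {clusters}"
        )
    groups = {
        c: rec.loc[labels.loc[rec["sample"]].to_numpy() == c, "ic50_uM"].to_numpy()
        for c in clusters
    }
    for c, vals in groups.items():
        if vals.size < min_group_size:
            raise DegenerateInputError(
                f"drug {drug!r}: cluster {c!r} has {vals.size} IC50s "
                f"(min_group_size={min_group_size})"
            )
    u, p = mann_whitney_u(np.log10(groups[clusters[0]]), np.log10(groups[clusters[1]]))
    med = {c: float(np.median(groups[c])) for c in clusters}
    m_sorted = sorted(med.items(), key=lambda kv: kv[1])
    fold = m_sorted[-1][1] / m_sorted[0][1]
    return DrugComparison(
        drug=drug,
        median_by_cluster=med,
        fold_difference=float(fold),
        u_statistic=float(u),
        p_value=float(p),
        n_by_cluster={c: int(groups[c].size) for c in clusters},
        sensitive_cluster=m_sorted[0][0],
    )


def compare_all_drugs(
    ic50: Ic50Table,
    labels: Mapping[str, object] | pd.Series,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Per-drug cluster comparison table, sorted by ascending p-value.

    Drugs that cannot be compared (too few samples in a cluster) are
    reported with NaN statistics and a reason instead of being dropped.
    """
    rows = []
    for drug in ic50.drugs:
        try:
            c = compare_clusters(ic50, labels, drug, min_group_size)
        except DegenerateInputError as exc:
            rows.append({"drug": drug, "p_value": np.nan, "fold_difference": np.nan,
                         "u_statistic": np.nan, "sensitive_cluster": None,
                         "reason": str(exc)})
            continue
        clusters = sorted(c.median_by_cluster)
        rows.append(
            {
                "drug": drug,
                "p_value": c.p_value,
                "fold_difference": c.fold_difference,
                "u_statistic": c.u_statistic,
                "sensitive_cluster": c.sensitive_cluster,
                "median_1": c.median_by_cluster[clusters[0]],
                "median_2": c.median_by_cluster[clusters[1]],
                "n_1": c.n_by_cluster[clusters[0]],
                "n_2": c.n_by_cluster[clusters[1]],
                "reason": "ok",
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["p_value", "drug"], kind="mergesort", na_position="last")
        .reset_index(drop=True)
    )
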