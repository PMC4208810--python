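"""Aberration-burden profiling of gene-level copy-number calls.

Three summaries:

* per-sample burden (gain / loss / LOH counts and their sum) over the whole
  call matrix or a gene list such as the human kinome;
* per-gene recurrence of a given aberration type across the cohort, ranked
  and reported as a rounded percent frequency;
* per-pathway aberration counts (sum over member genes and samples).

Gain and loss are mutually exclusive states, but LOH is an independent flag,
so a gene with loss plus LOH contributes to both the loss and the LOH count;
this is what makes the burden total the exact sum of its three components.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import GAIN, LOSS, CopyNumberCalls, GeneSetCollection

__all__ = [
    "ABERRATION_TYPES",
    "count_aberrations",
    "recurrence_table",
    "pathway_aberration_counts",
]

ABERRATION_TYPES = ("GAIN", "LOSS", "LOH")


def _flag_matrix(calls: CopyNumberCalls, aberration_type: str) -> pd.DataFrame:
    """Boolean genes x samples indicator of one aberration type."""
    if aberration_type == "GAIN":
        return calls.state == GAIN
    if aberration_type == "LOSS":
        return calls.state == LOSS
    if aberration_type == "LOH":
        return calls.loh
    raise ValueError(
        f"unknown aberration type {aberration_type!r}; expected one of {ABERRATION_TYPES}"
    )


def count_aberrations(
    calls: CopyNumberCalls, gene_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-sample aberration burden.

    Returns a DataFrame indexed by sample with integer columns
    ``gain, loss, loh, total`` where ``total = gain + loss + loh``.
    ``gene_subset`` (e.g. a kinome list) is intersected with the call
    matrix; an empty intersection is an error.
    """
    if gene_subset is not None:
        calls = calls.restrict(gene_subset)
    out = pd.DataFrame(
        {
            "gain": (calls.state == GAIN).sum(axis=0),
            "loss": (calls.state == LOSS).sum(axis=0),
            "loh": calls.loh.sum(axis=0),
        },
        index=calls.state.columns,
    ).astype(int)
    out["total"] = out["gain"] + out["loss"] + out["loh"]
    out.index.name = "sample"
    return out


def recurrence_table(
    calls: CopyNumberCalls, aberration_type: str, top_n: int
) -> pd.DataFrame:
    """Most recurrently aberrant genes for one aberration type.

    Genes are ranked by the number of samples carrying the aberration
    (descending), ties broken lexicographically by gene ID; ``frequency`` is
    the percent of cohort samples, rounded to the nearest integer.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    flags = _flag_matrix(calls, aberration_type)
    n = flags.sum(axis=1).astype(int)
    if len(n) == 0 or calls.n_samples == 0:
        return pd.DataFrame(columns=["gene", "n_samples", "frequency"]).astype(
            {"n_samples": int, "frequency": int}
        )
    tab = (
        pd.DataFrame({"gene": n.index, "n_samples": n.to_numpy()})
        .sort_values(["n_samples", "gene"], ascending=[False, True], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
    # round-half-up matches conventional percent reporting (13/18 -> 72)
    tab["frequency"] = np.floor(100.0 * tab["n_samples"] / calls.n_samples + 0.5).astype(int)
    return tab


def pathway_aberration_counts(
    calls: CopyNumberCalls,
    pathways: GeneSetCollection,
    top_n: int = 10,
    per_sample: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Aberration counts aggregated over pathway member genes.

    A pathway's count for a type is the number of (sample, member gene)
    cells carrying that aberration; members absent from the call matrix
    contribute zero.  Returns a table with columns ``pathway, gain, loss,
    loh, total, rank_gain, rank_loss, rank_loh`` where ``rank_<type>`` is
    the 1-based rank of the pathway for that type (<= top_n pathways are the
    reported "top" set).  With ``per_sample=True`` also returns, per type, a
    pathway x sample count matrix.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    names = pathways.names()
    gene_index = calls.state.index
    flag = {t: _flag_matrix(calls, t).to_numpy() for t in ABERRATION_TYPES}
    counts = {t: [] for t in ABERRATION_TYPES}
    sample_counts: dict[str, list[np.ndarray]] = {t: [] for t in ABERRATION_TYPES}
    for name in names:
        members = gene_index.get_indexer_for(
            gene_index.intersection(pd.Index(pathways.members(name)))
        )
        for t in ABERRATION_TYPES:
            if len(members) == 0:
                per = np.zeros(calls.n_samples, dtype=int)
            else:
                per = flag[t][members].sum(axis=0)
            counts[t].append(int(per.sum()))
            sample_counts[t].append(per)
    tab = pd.DataFrame(
        {
            "pathway": names,
            "gain": counts["GAIN"],
            "loss": counts["LOSS"],
            "loh": counts["LOH"],
        }
    )
    tab["total"] = tab["gain"] + tab["loss"] + tab["loh"]
    for t, col in (("GAIN", "gain"), ("LOSS", "loss"), ("LOH", "loh")):
        order = tab.sort_values(
            [col, "pathway"], ascending=[False, True], kind="mergesort"
        ).index
        ranks = pd.Series(np.arange(1, len(tab) + 1), index=order)
        tab[f"rank_{col}"] = ranks.reindex(tab.index).to_numpy()
    tab = tab.sort_values(
        ["total", "pathway"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if not per_sample:
        return tab
    mats = {
        t: pd.DataFrame(
            np.vstack(sample_counts[t]) if names else np.zeros((0, calls.n_samples)),
            index=names,
            columns=calls.samples,
            dtype=int,
        )
        for t in ABERRATION_TYPES
    }
    return tab, mats
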