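"""Core in-memory containers for the integrative-clustering pipeline.

All matrices are pandas DataFrames with gene identifiers on the rows and
sample names on the columns.  Copy-number states are stored as small signed
integers (``LOSS=-1, NEUTRAL=0, GAIN=+1``) so that the same matrix doubles
as the per-gene "copy dose" used by the driver-selection stage; loss of
heterozygosity (LOH) is an independent boolean flag that may co-occur with
any state (copy-neutral LOH is common in tumour genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOSS",
    "NEUTRAL",
    "GAIN",
    "STATE_NAMES",
    "FormatError",
    "DegenerateInputError",
    "CopyNumberCalls",
    "ExpressionMatrix",
    "GeneSetCollection",
    "Ic50Table",
]

LOSS: int = -1
NEUTRAL: int = 0
GAIN: int = 1

STATE_NAMES: dict[int, str] = {LOSS: "LOSS", NEUTRAL: "NEUTRAL", GAIN: "GAIN"}
STATE_CODES: dict[str, int] = {v: k for k, v in STATE_NAMES.items()}


class FormatError(ValueError):
    """Malformed input file or matrix (bad token, duplicate ID, ragged row...)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but statistically degenerate (constant
    vector, empty group, all-identical scatter...)."""


def _check_unique(values: Sequence, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CopyNumberCalls:
    """Gene-level copy-number calls for a cohort.

    Parameters
    ----------
    state
        genes x samples integer matrix with entries in ``{LOSS, NEUTRAL, GAIN}``.
    loh
        genes x samples boolean matrix, same index/columns; ``True`` marks a
        loss-of-heterozygosity call for that gene in that sample.
    """

    state: pd.DataFrame
    loh: pd.DataFrame

    def __post_init__(self) -> None:
        if self.state.shape != self.loh.shape:
            raise FormatError(
                f"state {self.state.shape} and loh {self.loh.shape} shapes differ"
            )
        if not self.state.index.equals(self.loh.index) or not self.state.columns.equals(
            self.loh.columns
        ):
            raise FormatError("state and loh matrices must share genes and samples")
        _check_unique(self.state.index, "gene IDs")
        _check_unique(self.state.columns, "sample names")
        bad = ~np.isin(self.state.to_numpy(), (LOSS, NEUTRAL, GAIN))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid state {self.state.iat[i, j]!r} at gene "
                f"{self.state.index[i]!r}, sample {self.state.columns[j]!r}"
            )
        self.state = self.state.astype(np.int8)
        self.loh = self.loh.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.state.index)

    @property
    def samples(self) -> list[str]:
        return list(self.state.columns)

    @property
    def n_samples(self) -> int:
        return self.state.shape[1]

    def dose(self) -> pd.DataFrame:
        """Numeric copy dose: LOSS=-1, NEUTRAL=0, GAIN=+1 (LOH carries no dose)."""
        return self.state.astype(float)

    def restrict(self, genes: Sequence[str]) -> "CopyNumberCalls":
        """Subset to the given genes (intersection, original row order)."""
        keep = self.state.index.intersection(pd.Index(genes))
        if len(keep) == 0:
            raise DegenerateInputError("gene subset does not intersect the call matrix")
        return CopyNumberCalls(self.state.loc[keep], self.loh.loc[keep])


@dataclass
class ExpressionMatrix:
    """Normalised log2 expression, one row per gene (probe sets already
    collapsed upstream), one column per sample."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample names")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite expression at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        self.values = self.values.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Ordered mapping of gene-set name -> (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            # de-duplicate, preserving first occurrence
            self.sets[name] = (self.sets[name][0], list(dict.fromkeys(members)))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class Ic50Table:
    """Long-format half-maximal inhibitory concentrations.

    ``records`` has columns ``drug, sample, ic50_uM, censored``; ``censored``
    means the IC50 was at or above the top tested dose and is reported capped
    at that dose.
    """

    records: pd.DataFrame

    REQUIRED = ("drug", "sample", "ic50_uM", "censored")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise FormatError(f"IC50 table missing columns: {missing}")
        rec = self.records.loc[:, list(self.REQUIRED)].copy()
        rec["ic50_uM"] = rec["ic50_uM"].astype(float)
        rec["censored"] = rec["censored"].astype(bool)
        if (rec["ic50_uM"] <= 0).any():
            bad = rec.loc[rec["ic50_uM"] <= 0].iloc[0]
            raise FormatError(
                f"non-positive IC50 for drug {bad['drug']!r}, sample {bad['sample']!r}"
            )
        if rec.duplicated(subset=["drug", "sample"]).any():
            bad = rec.loc[rec.duplicated(subset=["drug", "sample"])].iloc[0]
            raise FormatError(
                f"duplicate (drug, sample) record: ({bad['drug']!r}, {bad['sample']!r})"
            )
        self.records = rec.reset_index(drop=True)

    @property
    def drugs(self) -> list[str]:
        return list(pd.unique(self.records["drug"]))

    def for_drug(self, drug: str) -> pd.DataFrame:
        return self.records.loc[self.records["drug"] == drug]
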