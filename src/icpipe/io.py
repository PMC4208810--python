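"""Readers and writers for the pipeline's tab-delimited exchange formats.

Formats
-------
* copy-number calls: TSV, header row of sample names, first column ``gene``,
  cells drawn from ``NEUTRAL, GAIN, LOSS, LOH, GAIN+LOH, LOSS+LOH``;
* expression: numeric TSV with gene-ID first column;
* gene sets: standard GMT (name, description, members, tab-separated);
* IC50: long-format TSV with columns ``drug  sample  ic50_uM  censored``.

Missing values are rejected rather than imputed: the pipeline consumes
complete post-call / post-normalisation matrices.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GAIN,
    LOSS,
    NEUTRAL,
    STATE_NAMES,
    CopyNumberCalls,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    Ic50Table,
)

__all__ = [
    "read_cn_calls",
    "write_cn_calls",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_ic50",
    "write_ic50",
]

_TOKEN_TO_CALL: dict[str, tuple[int, bool]] = {
    "NEUTRAL": (NEUTRAL, False),
    "GAIN": (GAIN, False),
    "LOSS": (LOSS, False),
    "LOH": (NEUTRAL, True),
    "GAIN+LOH": (GAIN, True),
    "LOSS+LOH": (LOSS, True),
}


def _call_to_token(state: int, loh: bool) -> str:
    if state == NEUTRAL:
        return "LOH" if loh else "NEUTRAL"
    name = STATE_NAMES[state]
    return f"{name}+LOH" if loh else name


def read_cn_calls(path: str | Path) -> CopyNumberCalls:
    """Read a gene-level copy-number call matrix.

    Raises :class:`FormatError` naming the offending row/column for unknown
    tokens, ragged rows or duplicate gene IDs.
    """
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        samples = header[1:]
        if not samples:
            raise FormatError(f"{path}: header has no sample names")
        genes: list[str] = []
        state_rows: list[list[int]] = []
        loh_rows: list[list[bool]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            gene, cells = row[0], row[1:]
            if len(cells) != len(samples):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(samples)} cells, got {len(cells)}"
                )
            st, lo = [], []
            for j, tok in enumerate(cells):
                try:
                    s, l = _TOKEN_TO_CALL[tok.strip().upper()]
                except KeyError:
                    raise FormatError(
                        f"{path}:{lineno}: unknown call token {tok!r} "
                        f"(gene {gene!r}, sample {samples[j]!r})"
                    ) from None
                st.append(s)
                lo.append(l)
            genes.append(gene)
            state_rows.append(st)
            loh_rows.append(lo)
    state = pd.DataFrame(state_rows, index=genes, columns=samples, dtype=np.int8)
    loh = pd.DataFrame(loh_rows, index=genes, columns=samples, dtype=bool)
    return CopyNumberCalls(state, loh)


def write_cn_calls(calls: CopyNumberCalls, path: str | Path) -> None:
    path = Path(path)
    st, lo = calls.state.to_numpy(), calls.loh.to_numpy()
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", *calls.samples])
        for i, g in enumerate(calls.genes):
            w.writerow([g, *(_call_to_token(int(s), bool(l)) for s, l in zip(st[i], lo[i]))])


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a numeric gene x sample TSV matrix; any non-numeric cell is an error."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=[])
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene IDs {dups[:5]}")
    try:
        # numpy's parser is correctly rounded, keeping round-trips bit-exact
        numeric = df.to_numpy(dtype=str).astype(float)
    except ValueError:
        for i, j in np.ndindex(df.shape):
            try:
                float(df.iat[i, j])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {df.iat[i, j]!r} at gene "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                ) from None
        raise
    bad = ~np.isfinite(numeric)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-finite cell {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(pd.DataFrame(numeric, index=df.index, columns=df.columns))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    # repr-based formatting keeps the round-trip bit-exact
    df.to_csv(path, sep="\t", float_format=lambda x: repr(float(x)))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (one set per line: name, description, members)."""
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in collection.names():
            fh.write(
                "\t".join([name, collection.description(name), *collection.members(name)])
                + "\n"
            )


def read_ic50(path: str | Path) -> Ic50Table:
    """Read a long-format IC50 table (drug, sample, ic50_uM, censored 0/1)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"drug": str, "sample": str},
                     float_precision="round_trip")
    missing = [c for c in Ic50Table.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    ic = pd.to_numeric(df["ic50_uM"], errors="coerce")
    if ic.isna().any():
        row = df.loc[ic.isna()].iloc[0]
        raise FormatError(
            f"{path}: non-numeric IC50 {row['ic50_uM']!r} "
            f"(drug {row['drug']!r}, sample {row['sample']!r})"
        )
    cen = df["censored"]
    if not set(pd.unique(cen)) <= {0, 1, True, False}:
        raise FormatError(f"{path}: censored column must be 0/1")
    df = df.assign(ic50_uM=ic.astype(float), censored=cen.astype(bool))
    return Ic50Table(df)


def write_ic50(table: Ic50Table, path: str | Path) -> None:
    df = table.records.copy()
    df["censored"] = df["censored"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))
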