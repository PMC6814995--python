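"""Delimited-text formats for every pipeline artifact.

Everything is tab-separated UTF-8 text with a leading ``#`` comment line
carrying the tool version and a configuration hash, so each output file
records what produced it. Absent entries are empty fields or ``NA``.
Replicate tables carry two header rows (treatment, replicate); trait
matrices carry a trait-kind row tagged ``__kind__``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import ReplicateIntensityTable
from .traits import TraitMatrix

__all__ = [
    "config_hash",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_replicate_table",
    "read_replicate_table",
    "write_trait_matrix",
    "read_trait_matrix",
]

_NA_STRINGS = {"", "NA", "NaN", "nan"}


def config_hash(payload: str | bytes) -> str:
    """Short stable hash of a resolved configuration dump."""
    if isinstance(payload, str):
        payload = payload.encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_comment(cfg_hash: str | None) -> str:
    return f"# nmomics v{__version__} config={cfg_hash or 'none'}\n"


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, (float, np.floating)):
        return repr(float(x))  # shortest representation that round-trips exactly
    return str(x)


def write_matrix_tsv(
    frame: pd.DataFrame, path, *, cfg_hash: str | None = None, index_name: str = "id"
) -> None:
    """Write a single-header matrix with the standard comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_comment(cfg_hash))
        fh.write("\t".join([frame.index.name or index_name] + [str(c) for c in frame.columns]) + "\n")
        for idx, row in frame.iterrows():
            fh.write("\t".join([str(idx)] + [_fmt(v) for v in row]) + "\n")


def _parse_cell(token: str, path, line_no: int, col: str):
    token = token.strip()
    if token in _NA_STRINGS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"{path}:{line_no}: non-numeric value {token!r} in column {col!r}"
        ) from None


def _read_rows(path) -> list[tuple[int, list[str]]]:
    rows = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip("\r\n"):
                continue
            rows.append((line_no, line.rstrip("\r\n").split("\t")))
    if not rows:
        raise ValueError(f"{path}: no data found")
    return rows


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a single-header numeric matrix; first column is the identifier.

    Empty fields and ``NA`` become absent entries; ragged rows, duplicate
    identifiers and non-numeric cells raise errors naming the line.
    """
    rows = _read_rows(path)
    _, header = rows[0]
    columns = header[1:]
    ids, data = [], []
    for line_no, fields in rows[1:]:
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{line_no}: expected {len(header)} fields, found {len(fields)}"
            )
        ids.append(fields[0])
        data.append([_parse_cell(tok, path, line_no, col) for tok, col in zip(fields[1:], columns)])
    index = pd.Index(ids, name=header[0])
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate identifiers {dupes[:5]}")
    return pd.DataFrame(data, index=index, columns=columns)


def write_replicate_table(
    table: ReplicateIntensityTable, path, *, cfg_hash: str | None = None
) -> None:
    """Write an analyte x (treatment, replicate) table with two header rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = table.values.columns
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_comment(cfg_hash))
        fh.write(f"# layer={table.layer_name} control={table.control_label} log2={table.is_log2}\n")
        fh.write("\t".join(["treatment"] + [str(t) for t in cols.get_level_values(0)]) + "\n")
        fh.write("\t".join(["analyte"] + [str(r) for r in cols.get_level_values(1)]) + "\n")
        for idx, row in table.values.iterrows():
            fh.write("\t".join([str(idx)] + [_fmt(v) for v in row]) + "\n")


def read_replicate_table(
    path, *, layer_name: str | None = None, control_label: str | None = None
) -> ReplicateIntensityTable:
    """Read a two-header-row replicate table written by
    :func:`write_replicate_table` (metadata recovered from the ``# layer=``
    comment unless overridden)."""
    meta: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# layer="):
                for tok in line[2:].split():
                    k, _, v = tok.partition("=")
                    meta[k] = v
    rows = _read_rows(path)
    if len(rows) < 3:
        raise ValueError(f"{path}: replicate tables need two header rows plus data")
    _, treat_row = rows[0]
    _, rep_row = rows[1]
    if len(treat_row) != len(rep_row):
        raise ValueError(f"{path}: header rows disagree in length")
    columns = pd.MultiIndex.from_arrays(
        [treat_row[1:], [int(float(r)) for r in rep_row[1:]]], names=["treatment", "replicate"]
    )
    ids, data = [], []
    for line_no, fields in rows[2:]:
        if len(fields) != len(treat_row):
            raise ValueError(
                f"{path}:{line_no}: expected {len(treat_row)} fields, found {len(fields)}"
            )
        ids.append(fields[0])
        data.append([_parse_cell(tok, path, line_no, str(col)) for tok, col in zip(fields[1:], columns)])
    index = pd.Index(ids, name="analyte")
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate identifiers {dupes[:5]}")
    values = pd.DataFrame(data, index=index, columns=columns)
    return ReplicateIntensityTable(
        layer_name=layer_name or meta.get("layer", Path(path).stem),
        values=values,
        control_label=control_label or meta.get("control", "control"),
        is_log2=meta.get("log2", "False") == "True",
    )


def write_trait_matrix(traits: TraitMatrix, path, *, cfg_hash: str | None = None) -> None:
    """Write a sample x trait matrix with a ``__kind__`` trait-kind row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_comment(cfg_hash))
        fh.write("\t".join(["sample"] + [str(c) for c in traits.values.columns]) + "\n")
        fh.write("\t".join(["__kind__"] + [str(traits.trait_kind[c]) for c in traits.values.columns]) + "\n")
        for idx, row in traits.values.iterrows():
            fh.write("\t".join([str(idx)] + [_fmt(v) for v in row]) + "\n")


def read_trait_matrix(path) -> TraitMatrix:
    rows = _read_rows(path)
    _, header = rows[0]
    columns = header[1:]
    kind = None
    ids, data = [], []
    for line_no, fields in rows[1:]:
        if len(fields) != len(header):
            raise ValueError(f"{path}:{line_no}: expected {len(header)} fields, found {len(fields)}")
        if fields[0] == "__kind__":
            kind = pd.Series(fields[1:], index=columns)
            continue
        ids.append(fields[0])
        data.append([_parse_cell(tok, path, line_no, col) for tok, col in zip(fields[1:], columns)])
    values = pd.DataFrame(data, index=pd.Index(ids, name="sample"), columns=columns)
    return TraitMatrix(values=values, trait_kind=kind)
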