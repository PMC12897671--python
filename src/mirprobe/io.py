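"""Reading and writing the pipeline's delimited-text formats.

Canonical on-disk format is TSV; CSV is auto-detected by sniffing the header
line, since qPCR instrument exports vary.  Missing-value tokens cover the
common dialects: empty cell, ``NA``, and ``Undetermined``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigurationError, CpMatrix, ExpressionMatrix

MISSING_TOKENS = {"", "NA", "NaN", "nan", "Undetermined"}


def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_numeric_table(path: Path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, header=None)
    header = [str(v) for v in raw.iloc[0, 1:]]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ConfigurationError(f"duplicate sample columns in {path.name}: {dupes}")
    index = [str(v) for v in raw.iloc[1:, 0]]
    if len(set(index)) != len(index):
        dupes = sorted({i for i in index if index.count(i) > 1})
        raise ConfigurationError(f"duplicate {index_name} ids in {path.name}: {dupes}")

    body = raw.iloc[1:, 1:].copy()
    values = np.full(body.shape, np.nan)
    for r in range(body.shape[0]):
        for c in range(body.shape[1]):
            cell = body.iat[r, c]
            token = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if token in MISSING_TOKENS:
                continue
            try:
                values[r, c] = float(token)
            except ValueError:
                raise ConfigurationError(
                    f"non-numeric cell {token!r} at row {index[r]!r}, column {header[c]!r} "
                    f"in {path.name}"
                ) from None
    return pd.DataFrame(values, index=pd.Index(index, name=index_name), columns=header)


def read_metadata(path: str | Path) -> pd.Series:
    """Sample metadata TSV/CSV with columns ``sample_id`` and ``group``."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ConfigurationError(f"metadata {path.name} missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ConfigurationError(f"duplicate sample ids in metadata {path.name}")
    groups = pd.Series(meta["group"].to_numpy(), index=meta["sample_id"], name="group")
    return groups


def read_cp_table(path: str | Path, metadata_path: str | Path | None = None,
                  groups: pd.Series | None = None) -> CpMatrix:
    """Cp matrix from delimited text: first column assay ids, header samples.

    Blank/``NA``/``Undetermined`` cells become missing; duplicate assay or
    sample ids and non-numeric cells are rejected with coordinates.
    """
    values = _parse_numeric_table(Path(path), "assay_id")
    if groups is None:
        if metadata_path is None:
            raise ConfigurationError("provide metadata_path or groups")
        groups = read_metadata(metadata_path)
    return CpMatrix(values=values, groups=groups)


def write_cp_table(matrix: CpMatrix, path: str | Path, metadata_path: str | Path | None = None) -> None:
    out = matrix.values.copy()
    out.index.name = "assay_id"
    out.to_csv(path, sep="\t")
    if metadata_path is not None:
        write_metadata(matrix.groups, metadata_path)


def write_metadata(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path: str | Path, metadata_path: str | Path,
                    control_group: str) -> ExpressionMatrix:
    values = _parse_numeric_table(Path(path), "mirna")
    groups = read_metadata(metadata_path)
    return ExpressionMatrix(values=values, groups=groups, control_group=control_group)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "mirna"
    out.to_csv(path, sep="\t")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
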