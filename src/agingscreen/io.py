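"""Readers and writers for the package's on-disk interfaces.

Supported formats:

* expression — TSV (first column gene id, header row of sample ids) and
  GCT 1.2 as produced by GTEx-style exports;
* sample metadata — TSV with columns sample_id, age, sex, tissue,
  condition, activity, cohort;
* gene sets — standard GMT (set name, description, members, tab-delimited).

All writers emit deterministic text: fixed float formatting, no timestamps,
so byte-identical inputs yield byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, validate_sample_table
from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

# repr-faithful: floats survive a write/read round trip bit-exactly
FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path, format: str | None = None, scale: str = "raw") -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT 1.2.

    ``format`` is inferred from the suffix when omitted. Duplicate gene rows
    are rejected rather than silently collapsed.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        df = _read_gct(path)
    else:
        raise FormatError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale=scale)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: first line must be '#1.2', got {version!r}")
        dims = fh.readline().strip().split("\t")
        if len(dims) != 2:
            raise FormatError(f"{path}: second line must hold row and column counts")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer dimension line {dims!r}") from exc
        df = pd.read_csv(fh, sep="\t")
    if df.columns[0].lower() not in ("name", "id"):
        raise FormatError(f"{path}: third line must start with a Name/id column")
    df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]], errors="ignore")
    # GCT column 2 is Description; drop it by position to be safe
    if df.shape[1] == n_cols + 1:
        df = df.iloc[:, 1:]
    if df.shape[0] != n_rows or df.shape[1] != n_cols:
        raise IntegrityError(
            f"{path}: declared {n_rows}x{n_cols} but found {df.shape[0]}x{df.shape[1]}"
        )
    return df


def write_expression(expr: ExpressionMatrix, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    df = expr.values
    if format == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format=FLOAT_FMT)
    else:
        raise FormatError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_table(path) -> pd.DataFrame:
    """Read tab-delimited sample metadata.

    Rows whose age fails numeric parsing are dropped with a logged count —
    never silently.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    if "age" in df.columns:
        parsed = pd.to_numeric(df["age"], errors="coerce")
        bad = parsed.isna() & df["age"].notna()
        if bad.any():
            logger.warning("%s: dropped %d rows with unparseable age", path, int(bad.sum()))
            df = df[~bad]
        df = df.assign(age=parsed[~bad] if bad.any() else parsed)
    return validate_sample_table(df)


def write_sample_table(samples: pd.DataFrame, path) -> None:
    validate_sample_table(samples).to_csv(
        Path(path), sep="\t", index=False, float_format=FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise IntegrityError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [f for f in fields[2:] if f]
            sets[name] = frozenset(members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(Path(path), "w") as fh:
        for name in collection.names():
            members = sorted(collection[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False, index_label=None) -> None:
    """Deterministic TSV export for result tables."""
    df.to_csv(Path(path), sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
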