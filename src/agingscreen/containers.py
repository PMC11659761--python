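"""In-memory data model.

The substrate of every stage is :class:`ExpressionMatrix`, a genes x samples
numeric table with an explicit expression scale (``raw`` counts/intensities
or ``log2``) and an optional missingness mask. Sample metadata travels as a
plain :class:`pandas.DataFrame` with a fixed column contract, validated by
:func:`validate_sample_table`; gene sets as :class:`GeneSetCollection`.

All downstream statistics operate on the log2 scale; :meth:`ExpressionMatrix.to_log2`
applies ``log2(x + 1)`` to raw matrices and is a no-op on matrices already
flagged log2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError, IntegrityError

logger = logging.getLogger(__name__)

#: Columns a sample table must provide (activity/cohort may be NA).
SAMPLE_COLUMNS = ("sample_id", "age", "sex", "tissue", "condition", "activity", "cohort")

VALID_SEX = frozenset({"male", "female", "unknown"})
VALID_CONDITION = frozenset({"healthy", "case", "control"})


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. All stored
        entries must be finite; missing measurements are declared through
        ``mask``, never as silent NaN.
    scale
        ``"raw"`` for count/intensity data, ``"log2"`` for log2-transformed.
    mask
        Optional boolean DataFrame of the same shape; ``True`` marks a
        missing entry. The corresponding value is ignored by all statistics.
    """

    values: pd.DataFrame
    scale: str = "raw"
    mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ConfigError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate sample identifiers: {dups[:5]}")
        self.values = self.values.astype(np.float64)
        if self.mask is not None:
            if self.mask.shape != self.values.shape:
                raise IntegrityError("mask shape does not match values shape")
            self.mask = pd.DataFrame(
                np.asarray(self.mask, dtype=bool),
                index=self.values.index,
                columns=self.values.columns,
            )
        observed = self.values.to_numpy()
        if self.mask is not None:
            observed = observed[~self.mask.to_numpy()]
        if not np.all(np.isfinite(observed)):
            raise IntegrityError(
                "non-finite expression values outside the mask; declare missing "
                "entries explicitly via the mask"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- transforms ----------------------------------------------------------
    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale view: ``log2(x + 1)`` for raw data, identity
        for matrices already on the log2 scale. The pseudocount of 1 makes
        the transform total on non-negative input."""
        if self.scale == "log2":
            return self
        vals = self.values.to_numpy()
        if np.any(vals < 0) and (self.mask is None or np.any(vals[~self.mask.to_numpy()] < 0)):
            raise IntegrityError("raw-scale matrix contains negative values")
        return ExpressionMatrix(
            np.log2(self.values + 1.0), scale="log2", mask=self.mask
        )

    def masked_values(self) -> np.ndarray:
        """Values with masked entries replaced by NaN (for pairwise-complete
        statistics)."""
        out = self.values.to_numpy(copy=True)
        if self.mask is not None:
            out[self.mask.to_numpy()] = np.nan
        return out

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise IntegrityError(f"unknown sample ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.values[sample_ids],
            scale=self.scale,
            mask=None if self.mask is None else self.mask[sample_ids],
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise IntegrityError(f"unknown gene ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.values.loc[gene_ids],
            scale=self.scale,
            mask=None if self.mask is None else self.mask.loc[gene_ids],
        )


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a sample table.

    Requires ``sample_id`` and ``age``; fills the remaining standard columns
    with defaults. Ages must be positive where present. Returns a copy with
    ``sample_id`` as a plain column (unique) and canonical dtypes.
    """
    if "sample_id" not in df.columns:
        raise IntegrityError("sample table lacks a sample_id column")
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique().tolist()
        raise IntegrityError(f"duplicate sample_ids: {dups[:5]}")
    defaults = {
        "age": np.nan,
        "sex": "unknown",
        "tissue": "unknown",
        "condition": "healthy",
        "activity": np.nan,
        "cohort": "default",
    }
    for col, default in defaults.items():
        if col not in df.columns:
            df[col] = default
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if (df["age"].dropna() <= 0).any():
        raise IntegrityError("ages must be positive where present")
    df["activity"] = pd.to_numeric(df["activity"], errors="coerce")
    if (df["activity"].dropna() < 0).any():
        raise IntegrityError("activity must be non-negative")
    bad_sex = set(df["sex"].dropna()) - VALID_SEX
    if bad_sex:
        raise IntegrityError(f"invalid sex labels: {sorted(bad_sex)}")
    bad_cond = set(df["condition"].dropna()) - VALID_CONDITION
    if bad_cond:
        raise IntegrityError(f"invalid condition labels: {sorted(bad_cond)}")
    return df[list(SAMPLE_COLUMNS)].reset_index(drop=True)


def join_expression_samples(
    expr: ExpressionMatrix, samples: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame, int]:
    """Align an expression matrix with a sample table on their shared
    sample ids, preserving the matrix' column order.

    Returns the aligned pair and the number of samples discarded from the
    union of the two id sets; the count is also logged, so silent sample
    loss at a join can always be traced.
    """
    samples = validate_sample_table(samples)
    meta_ids = set(samples["sample_id"])
    common = [s for s in expr.sample_ids if s in meta_ids]
    dropped = len(set(expr.sample_ids) | meta_ids) - len(common)
    if dropped:
        logger.info("join discarded %d samples outside the id intersection", dropped)
    sub = expr.subset_samples(common)
    meta = samples.set_index("sample_id").loc[common].reset_index()
    return sub, meta, dropped


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            members = frozenset(str(m) for m in members)
            if not members:
                raise IntegrityError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean
        if self.universe is not None:
            self.universe = frozenset(str(m) for m in self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def upper_ids(ids) -> list[str]:
    """Canonical gene-identifier form: exact string match after upper-casing.

    No alias resolution is attempted; cross-dataset joins rely on inputs
    sharing an identifier namespace.
    """
    return [str(g).upper() for g in ids]
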