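"""Signature-based bulk deconvolution (digital cytometry).

A marker-gene signature matrix is built from labeled single-cell profiles:
for each cell type, the genes whose mean expression most exceeds the best
competing type's mean are selected, and signature entries are per-type
means over cells. Cell-type fractions of a bulk sample are then estimated
by non-negative least squares on the marker genes,

    min_f  || S f - b ||_2   s.t.  f >= 0,

followed by renormalization to the probability simplex. NNLS is a
transparent, fully specified estimator for the fraction task; it makes no
attempt to reproduce the numerical output of support-vector-regression
based cytometry tools, and no batch correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .containers import ExpressionMatrix
from .errors import ConfigError, DegenerateDataError

MIN_CELLS_PER_TYPE = 20


def build_signature(
    sc_expr: ExpressionMatrix,
    cell_labels: pd.Series | dict,
    markers_per_type: int = 50,
) -> pd.DataFrame:
    """Build a marker x cell-type signature matrix from single-cell data.

    ``cell_labels`` maps each single-cell sample id to a cell-type label;
    every type needs at least 20 cells. For each type the
    ``markers_per_type`` genes with the largest margin
    ``mean(type) - max(mean(other types))`` are selected; a type with no
    positive-margin gene is rejected by name. Signature entries are
    per-type mean log2 expression over cells.
    """
    labels = pd.Series(dict(cell_labels) if not isinstance(cell_labels, pd.Series)
                       else cell_labels)
    missing = set(sc_expr.sample_ids) - set(labels.index)
    if missing:
        raise ConfigError(f"cells without label: {sorted(missing)[:5]}")
    labels = labels.loc[sc_expr.sample_ids]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ConfigError("need >= 2 cell types")
    counts = labels.value_counts()
    small = counts[counts < MIN_CELLS_PER_TYPE]
    if not small.empty:
        raise ConfigError(
            f"cell types below {MIN_CELLS_PER_TYPE} cells: {dict(small)}"
        )
    if markers_per_type < 1:
        raise ConfigError("markers_per_type must be >= 1")

    log_expr = sc_expr.to_log2()
    vals = log_expr.values
    means = pd.DataFrame(
        {t: vals.loc[:, labels[labels == t].index].mean(axis=1) for t in types}
    )
    markers: list[str] = []
    for t in types:
        others = means.drop(columns=t).max(axis=1)
        margin = means[t] - others
        if (margin <= 0).all():
            raise DegenerateDataError(
                f"cell type {t!r} has no gene with a positive margin over "
                "the other types"
            )
        top = margin.nlargest(min(markers_per_type, int((margin > 0).sum())))
        markers.extend(top.index)
    marker_idx = pd.Index(pd.unique(pd.Series(markers)))
    sig = means.loc[marker_idx]
    for a_i in range(len(types)):
        for b_i in range(a_i + 1, len(types)):
            if np.allclose(sig.iloc[:, a_i], sig.iloc[:, b_i]):
                raise DegenerateDataError(
                    f"signature columns {types[a_i]!r} and {types[b_i]!r} are "
                    "identical; the types are indistinguishable"
                )
    sig.index.name = "gene"
    return sig


def estimate_fractions(
    bulk: ExpressionMatrix,
    signature: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Estimate per-sample cell-type fractions by NNLS on marker genes.

    The bulk matrix is restricted to the signature's marker genes (at least
    as many shared markers as cell types are required). Each sample's
    non-negative solution is renormalized to sum to one, which also makes
    the estimate invariant to positive rescaling of the bulk profile.
    Returns (fractions, residual norm per sample).
    """
    shared = signature.index.intersection(bulk.values.index)
    if len(shared) < signature.shape[1]:
        raise DegenerateDataError(
            f"{len(shared)} marker genes shared with the bulk matrix; need at "
            f"least {signature.shape[1]} (one per cell type)"
        )
    S = signature.loc[shared].to_numpy()
    B = bulk.values.loc[shared].to_numpy()
    fracs = np.zeros((B.shape[1], S.shape[1]))
    residuals = np.zeros(B.shape[1])
    for j, sid in enumerate(bulk.sample_ids):
        b = B[:, j]
        if not np.any(b):
            raise DegenerateDataError(
                f"bulk sample {sid!r} is all zero on the marker genes; "
                "fractions undefined"
            )
        f, res = nnls(S, b)
        total = f.sum()
        if total == 0:
            raise DegenerateDataError(
                f"NNLS returned the zero vector for sample {sid!r}"
            )
        fracs[j] = f / total
        residuals[j] = res
    fractions = pd.DataFrame(fracs, index=bulk.sample_ids,
                             columns=list(signature.columns))
    return fractions, pd.Series(residuals, index=bulk.sample_ids, name="residual")


def compare_fractions(
    fractions: pd.DataFrame,
    group_labels: pd.Series | dict,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Compare estimated fractions between two sample groups.

    ``group_labels`` maps sample id to one of exactly two group labels.
    Returns one row per cell type with group means, their difference
    (first group minus second, groups ordered lexicographically) and a
    two-sided Welch t p-value.
    """
    labels = pd.Series(dict(group_labels) if not isinstance(group_labels, pd.Series)
                       else group_labels)
    labels = labels.loc[labels.index.intersection(fractions.index)]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ConfigError(f"need exactly two groups, got {groups}")
    ids_a = labels.index[labels == groups[0]]
    ids_b = labels.index[labels == groups[1]]
    if len(ids_a) < min_group_size or len(ids_b) < min_group_size:
        raise ConfigError(
            f"groups below the minimum size {min_group_size}: "
            f"{groups[0]}={len(ids_a)}, {groups[1]}={len(ids_b)}"
        )
    rows = []
    for ctype in fractions.columns:
        a = fractions.loc[ids_a, ctype].to_numpy()
        b = fractions.loc[ids_b, ctype].to_numpy()
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append({
            "cell_type": ctype,
            f"mean_{groups[0]}": float(np.mean(a)),
            f"mean_{groups[1]}": float(np.mean(b)),
            "difference": float(np.mean(a) - np.mean(b)),
            "p": p,
        })
    return pd.DataFrame(rows)


def age_bins(samples: pd.DataFrame, split: float = 60.0) -> pd.Series:
    """Binary age grouping for fraction comparisons (default split at 60
    years: 'le60' vs 'gt60'); samples without age are dropped."""
    ages = pd.to_numeric(samples["age"], errors="coerce")
    keep = np.isfinite(ages)
    return pd.Series(
        np.where(ages[keep] > split, f"gt{split:g}", f"le{split:g}"),
        index=samples.loc[keep, "sample_id"].to_numpy(),
        name="age_bin",
    )
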