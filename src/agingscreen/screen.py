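"""Age-correlation screening and tissue-signature grouping.

Per tissue, every gene's expression is correlated with donor age (Pearson);
genes with ``r > 0`` and ``p < alpha_up`` are called upregulated aging
genes and genes with ``r < 0`` and ``p < alpha_down`` downregulated aging
genes — the down threshold is stricter by default (0.01 vs 0.05) because
brain cohorts carry a large excess of negatively trending genes. Tissues
are then compared by correlating their per-gene r-vectors ("aging
signatures"), grouped by average-linkage hierarchical clustering on the
``1 - r`` distance, and per-group aging-gene sets are formed by
intersection. A validation step retains genes that replicate, with the same
sign, in independent cohorts screened against log-transformed age.

p-values come from the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` against a t distribution with
``n - 2`` degrees of freedom, two-sided; no multiple-testing correction is
applied in the screen itself (raw p thresholds are the calling convention;
an optional BH switch is available for sensitivity analyses).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, join_expression_samples
from .errors import ConfigError, DegenerateDataError

logger = logging.getLogger(__name__)

MIN_SAMPLES = 10  # minimum unmasked samples for a usable correlation
MIN_COMMON_GENES = 100  # minimum shared genes for signature comparison


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with a two-sided t-transform p-value.

    NaN entries in either vector are removed pairwise. Raises
    :class:`DegenerateDataError` for n < 3 or a constant vector — a
    correlation of 0 is never reported silently for undefined input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"need >= 3 paired observations, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Pearson r, two-sided p and n of a genes x samples matrix
    against one covariate. NaNs in X are handled pairwise per row."""
    finite = np.isfinite(X)
    n = finite.sum(axis=1)
    Xz = np.where(finite, X, 0.0)
    y_mat = np.where(finite, y[None, :], 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        sx = Xz.sum(axis=1)
        sy = y_mat.sum(axis=1)
        sxx = (Xz ** 2).sum(axis=1)
        syy = (y_mat ** 2).sum(axis=1)
        sxy = (Xz * y_mat).sum(axis=1)
        cov = sxy - sx * sy / n
        varx = sxx - sx ** 2 / n
        vary = syy - sy ** 2 / n
        r = cov / np.sqrt(varx * vary)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isclose(np.abs(r), 1.0)] = np.finfo(float).tiny
    usable = (n >= 3) & (varx > 0) & (vary > 0)
    r[~usable] = np.nan
    p[~usable] = np.nan
    return r, p, n


def screen_tissue(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    alpha_up: float = 0.05,
    alpha_down: float = 0.01,
    log_age: bool = False,
    age_window: tuple[float, float] | None = (40.0, 69.0),
    min_samples: int = MIN_SAMPLES,
    bh_adjust: bool = False,
    tissue: str | None = None,
) -> pd.DataFrame:
    """Screen one tissue for aging genes.

    Returns a call table indexed by gene with columns ``r``, ``p``, ``n``
    and ``call`` in {up, down, none}; genes with an undefined correlation
    (constant expression, too few samples) are excluded and counted in
    ``result.attrs["n_skipped"]``. ``log_age`` correlates against
    log-transformed age (the validation-cohort convention); ``age_window``
    restricts donors to an age interval before screening (``None`` keeps
    all). With ``bh_adjust`` the thresholds are applied to BH-adjusted
    p-values instead of raw ones.
    """
    if not (0 < alpha_up <= 1 and 0 < alpha_down <= 1):
        raise ConfigError("alpha thresholds must lie in (0, 1]")
    expr, meta, n_dropped = join_expression_samples(expr, samples)
    meta = meta[np.isfinite(meta["age"])]
    if age_window is not None:
        lo, hi = age_window
        meta = meta[(meta["age"] >= lo) & (meta["age"] <= hi)]
    if len(meta) < max(min_samples, 3):
        raise DegenerateDataError(
            f"only {len(meta)} samples with usable age after join/window; "
            f"need >= {max(min_samples, 3)}"
        )
    expr = expr.subset_samples(meta["sample_id"])
    ages = meta["age"].to_numpy(dtype=float)
    if log_age:
        ages = np.log(ages)

    X = expr.to_log2().masked_values()
    r, p, n = _pearson_rows(X, ages)
    usable = np.isfinite(r) & (n >= min_samples)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("screen: skipped %d genes with undefined correlation "
                    "or < %d usable samples", n_skipped, min_samples)

    table = pd.DataFrame(
        {"r": r[usable], "p": p[usable], "n": n[usable]},
        index=pd.Index(np.asarray(expr.gene_ids)[usable], name="gene"),
    )
    p_eff = table["p"].to_numpy()
    if bh_adjust:
        p_eff = multipletests(p_eff, method="fdr_bh")[1]
    call = np.where((table["r"] > 0) & (p_eff < alpha_up), "up",
                    np.where((table["r"] < 0) & (p_eff < alpha_down), "down", "none"))
    table["call"] = call
    table.attrs.update({
        "tissue": tissue or "unknown",
        "alpha_up": alpha_up,
        "alpha_down": alpha_down,
        "log_age": log_age,
        "n_samples_dropped": n_dropped,
        "n_skipped": n_skipped,
    })
    return table


def called_genes(table: pd.DataFrame, direction: str) -> frozenset[str]:
    """Gene ids carrying a given call in an aging-call table."""
    if direction not in ("up", "down"):
        raise ConfigError("direction must be 'up' or 'down'")
    return frozenset(table.index[table["call"] == direction])


# ---------------------------------------------------------------------------
# tissue signatures
# ---------------------------------------------------------------------------

@dataclass
class TissueSimilarity:
    """Tissue x tissue correlation of aging signatures with a grouping.

    ``similarity`` is symmetric with unit diagonal; ``groups`` maps each
    tissue to a group label partitioning the tissue set; ``linkage`` is the
    scipy average-linkage tree on the ``1 - r`` distance.
    """

    similarity: pd.DataFrame
    groups: pd.Series
    linkage: np.ndarray | None = None

    def group_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for tissue, grp in self.groups.items():
            out.setdefault(str(grp), []).append(tissue)
        return out


def tissue_signature_similarity(
    tables: dict[str, pd.DataFrame],
    n_groups: int | None = None,
    fixed_groups: dict[str, str] | None = None,
) -> TissueSimilarity:
    """Correlate per-tissue aging signatures and group tissues.

    The signature of a tissue is its vector of per-gene r-values; tissues
    are compared by Pearson correlation of these vectors over the genes
    usable in every tissue. Grouping is by average-linkage hierarchical
    clustering on the ``1 - r`` distance cut into ``n_groups`` clusters,
    or taken verbatim from ``fixed_groups`` so downstream stages do not
    depend on clustering reproducibility.
    """
    if len(tables) < 2:
        raise ConfigError("need at least two tissues to compare signatures")
    common: pd.Index | None = None
    for table in tables.values():
        idx = table.index[np.isfinite(table["r"])]
        common = idx if common is None else common.intersection(idx)
    if common is None or len(common) < MIN_COMMON_GENES:
        raise DegenerateDataError(
            f"only {0 if common is None else len(common)} genes shared across "
            f"tissues; need >= {MIN_COMMON_GENES} for a meaningful signature "
            "correlation"
        )
    common = common.sort_values()
    tissues = list(tables)
    R = np.column_stack([tables[t].loc[common, "r"].to_numpy() for t in tissues])
    sim = np.corrcoef(R, rowvar=False)
    sim_df = pd.DataFrame(sim, index=tissues, columns=tissues)

    condensed = squareform(1.0 - sim, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    if fixed_groups is not None:
        missing = set(tissues) - set(fixed_groups)
        if missing:
            raise ConfigError(f"fixed grouping lacks tissues: {sorted(missing)}")
        groups = pd.Series({t: str(fixed_groups[t]) for t in tissues})
    else:
        if n_groups is None:
            raise ConfigError("specify n_groups or a fixed grouping")
        if not 1 <= n_groups <= len(tissues):
            raise ConfigError("n_groups must lie in [1, number of tissues]")
        labels = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
        groups = pd.Series({t: str(lab) for t, lab in zip(tissues, labels)})
    return TissueSimilarity(similarity=sim_df, groups=groups, linkage=Z)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Export a scipy linkage tree as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# group intersections and validation
# ---------------------------------------------------------------------------

@dataclass
class GroupAgingGenes:
    """Intersection of same-direction calls across a tissue group."""

    group: str
    direction: str
    tissues: list[str]
    genes: frozenset[str]
    venn_counts: dict[tuple[str, ...], int]


def group_intersection(
    tables: dict[str, pd.DataFrame],
    group_tissues: list[str],
    direction: str,
    group: str = "",
) -> GroupAgingGenes:
    """Intersect the ``direction`` calls of every tissue in a group.

    ``venn_counts`` reports, for every non-empty subset of member tissues,
    the number of genes called in exactly that subset.
    """
    if not group_tissues:
        raise ConfigError("empty tissue group")
    missing = [t for t in group_tissues if t not in tables]
    if missing:
        raise ConfigError(f"no call table for tissues: {missing}")
    sets = {t: called_genes(tables[t], direction) for t in group_tissues}
    inter = frozenset.intersection(*sets.values())

    venn: dict[tuple[str, ...], int] = {}
    union = frozenset.union(*sets.values())
    membership = {g: tuple(t for t in group_tissues if g in sets[t]) for g in union}
    for k in range(1, len(group_tissues) + 1):
        for combo in itertools.combinations(group_tissues, k):
            venn[combo] = sum(1 for pat in membership.values() if pat == combo)
    return GroupAgingGenes(
        group=group, direction=direction, tissues=list(group_tissues),
        genes=inter, venn_counts=venn,
    )


def cross_validate(
    discovery_tables: dict[str, pd.DataFrame],
    validation_tables: list[pd.DataFrame],
    k_min: int,
    direction: str,
) -> frozenset[str]:
    """Validated aging genes across cohorts.

    Returns genes called ``direction`` in at least ``k_min`` discovery
    tissues that also carry a same-direction call in at least one
    validation table (validation screens conventionally correlate against
    log age). Separate ``k_min`` values for up and down are plain
    parameters.
    """
    if k_min < 1 or k_min > len(discovery_tables):
        raise ConfigError(
            f"k_min must lie in [1, {len(discovery_tables)}], got {k_min}"
        )
    if not validation_tables:
        raise ConfigError("at least one validation table is required")
    counts: dict[str, int] = {}
    for table in discovery_tables.values():
        for g in called_genes(table, direction):
            counts[g] = counts.get(g, 0) + 1
    candidates = {g for g, c in counts.items() if c >= k_min}
    validated = frozenset().union(
        *(called_genes(t, direction) for t in validation_tables)
    )
    return frozenset(candidates & validated)
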