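"""Two-group contrasts, syntropy and rescue scoring.

The contrast statistic is deliberately simple and fully specified: on log2
values, ``log2FC = mean(group A) - mean(group B)`` with a two-sided
unequal-variance (Welch) t-test per gene. Syntropy asks what proportion of
a tissue's aging genes is *further* shifted in the same direction in an
age-matched case/control contrast; rescue asks what proportion is
significantly shifted in the *opposite* direction under an intervention
contrast (e.g. high vs low physical activity). Genes absent from the
contrast dataset are excluded from the denominator in both scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import ConfigError, DegenerateDataError

logger = logging.getLogger(__name__)

#: Actigraphy arm cut-offs, in units of ``ACTIVITY_SCALE`` counts/day.
HIGH_ACTIVITY_CUT = 2.1
MODERATE_ACTIVITY_CUT = 1.0
ACTIVITY_SCALE = 1e5


def normalize_to_control_mean(
    expr: ExpressionMatrix,
    control_ids,
    strata: pd.Series | dict | None = None,
) -> ExpressionMatrix:
    """Normalize each stratum to its own control-sample mean.

    Within each stratum (e.g. brain area), every gene is divided by the
    stratum's control mean on the raw scale, or shifted by it on the log2
    scale, so control-arm stratum means become 1 (raw) or 0 (log2). With
    ``strata=None`` all samples form one stratum. Every stratum must
    contain at least two control samples.
    """
    control_ids = set(control_ids)
    if strata is None:
        strata = pd.Series("all", index=expr.sample_ids)
    else:
        strata = pd.Series(dict(strata) if not isinstance(strata, pd.Series) else strata)
        missing = set(expr.sample_ids) - set(strata.index)
        if missing:
            raise ConfigError(f"samples without stratum label: {sorted(missing)[:5]}")
    vals = expr.values.copy()
    for stratum in sorted(strata.unique()):
        members = [s for s in expr.sample_ids if strata[s] == stratum]
        controls = [s for s in members if s in control_ids]
        if len(controls) < 2:
            raise DegenerateDataError(
                f"stratum {stratum!r} has {len(controls)} control samples; need >= 2"
            )
        ctl_mean = vals[controls].mean(axis=1)
        if expr.scale == "log2":
            vals[members] = vals[members].sub(ctl_mean, axis=0)
        else:
            if (ctl_mean == 0).any():
                raise DegenerateDataError(
                    f"stratum {stratum!r} has genes with zero control mean on "
                    "the raw scale"
                )
            vals[members] = vals[members].div(ctl_mean, axis=0)
    return ExpressionMatrix(vals, scale=expr.scale, mask=expr.mask)


def two_group_diff(
    expr: ExpressionMatrix,
    group_a_ids,
    group_b_ids,
) -> pd.DataFrame:
    """Per-gene A-vs-B contrast on log2 values.

    Returns a table indexed by gene with ``log2fc`` (mean A minus mean B),
    two-sided Welch ``p``, group sizes, and a ``degenerate`` flag for genes
    with zero within-group variance in both groups (their p is undefined
    and set to NaN; downstream scores ignore them).
    """
    if expr.scale != "log2":
        raise ConfigError("two_group_diff requires a log2-scale matrix; "
                          "call .to_log2() first")
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ConfigError("each group needs >= 3 samples")
    if set(a_ids) & set(b_ids):
        raise ConfigError("groups overlap")
    A = expr.subset_samples(a_ids).masked_values()
    B = expr.subset_samples(b_ids).masked_values()
    log2fc = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant genes trip scipy's precision warning; they are
        # flagged as degenerate below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    var_a = np.nanvar(A, axis=1)
    var_b = np.nanvar(B, axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    p[degenerate] = np.nan
    if degenerate.any():
        logger.info("two_group_diff: %d genes with zero variance in both "
                    "groups flagged as degenerate", int(degenerate.sum()))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "n_a": len(a_ids),
            "n_b": len(b_ids),
            "degenerate": degenerate,
        },
        index=pd.Index(expr.gene_ids, name="gene"),
    )


@dataclass
class SyntropyReport:
    """Proportion of aging genes further deregulated in the same direction."""

    tissue: str
    direction: str
    n_aging_detected: int
    n_syntropic: int
    syntropic_genes: frozenset[str]

    @property
    def proportion(self) -> float:
        return self.n_syntropic / self.n_aging_detected


@dataclass
class RescueReport:
    """Proportion of aging genes significantly reversed under a contrast."""

    contrast: str
    direction: str
    n_aging_detected: int
    n_rescued: int
    rescued_genes: frozenset[str]

    @property
    def proportion(self) -> float:
        return self.n_rescued / self.n_aging_detected


def _aging_genes_in_diff(
    aging_calls: pd.DataFrame, diff: pd.DataFrame, direction: str
) -> pd.Index:
    if direction not in ("up", "down"):
        raise ConfigError("direction must be 'up' or 'down'")
    aging = aging_calls.index[aging_calls["call"] == direction]
    usable = diff.index[~diff["degenerate"] & np.isfinite(diff["p"])]
    return aging.intersection(usable)


def syntropy(
    aging_calls: pd.DataFrame,
    diff: pd.DataFrame,
    direction: str,
    alpha: float = 0.05,
    tissue: str = "unknown",
) -> SyntropyReport:
    """Score syntropic deregulation of aging genes in a disease contrast.

    The denominator is the aging genes of ``direction`` present (and
    testable) in the disease dataset; the numerator counts those with a
    same-signed log2 fold change significant at ``alpha`` in the
    case-vs-control contrast. Because the controls are age-matched, the
    contrast measures deregulation beyond the shared aging trend.
    """
    detected = _aging_genes_in_diff(aging_calls, diff, direction)
    if len(detected) == 0:
        raise DegenerateDataError(
            "no aging genes of the requested direction detected in the "
            "disease dataset; proportion undefined"
        )
    sub = diff.loc[detected]
    sign_ok = sub["log2fc"] > 0 if direction == "up" else sub["log2fc"] < 0
    hits = sub.index[sign_ok & (sub["p"] < alpha)]
    return SyntropyReport(
        tissue=tissue, direction=direction,
        n_aging_detected=len(detected), n_syntropic=len(hits),
        syntropic_genes=frozenset(hits),
    )


def stratify_activity(
    samples: pd.DataFrame,
    high_cut: float = HIGH_ACTIVITY_CUT,
    moderate_cut: float = MODERATE_ACTIVITY_CUT,
    scale: float = ACTIVITY_SCALE,
) -> pd.Series:
    """Assign physical-activity arms from the actigraphy covariate.

    ``high`` for activity strictly above ``high_cut * scale`` counts/day,
    ``moderate`` for the half-open interval
    ``(moderate_cut * scale, high_cut * scale]`` — the boundary value
    belongs to the moderate arm — and ``low`` otherwise. Samples without an
    activity measurement are excluded with a logged count.
    """
    if "activity" not in samples.columns:
        raise ConfigError("sample table lacks an activity column")
    act = pd.to_numeric(samples["activity"], errors="coerce")
    keep = np.isfinite(act)
    n_missing = int((~keep).sum())
    if n_missing:
        logger.info("stratify_activity: excluded %d samples without activity",
                    n_missing)
    act = act[keep]
    arms = pd.Series(
        np.where(act > high_cut * scale, "high",
                 np.where(act > moderate_cut * scale, "moderate", "low")),
        index=samples.loc[keep, "sample_id"].to_numpy(),
        name="arm",
    )
    return arms


def rescue(
    aging_calls: pd.DataFrame,
    diff: pd.DataFrame,
    direction: str,
    alpha: float = 0.05,
    fold_min: float = 1.0,
    contrast: str = "high_vs_low",
) -> RescueReport:
    """Score reversal of aging genes under an intervention contrast.

    For ``direction="down"`` the numerator counts aging genes with
    ``log2fc > log2(fold_min)`` and ``p < alpha`` in the (e.g.) high- vs
    low-activity contrast; symmetric for up genes. ``fold_min = 1.0`` means
    any significant opposite-direction change counts; a stricter fold
    threshold (1.1 is the convention for cell-resolved contrasts) shrinks
    the numerator monotonically. Aging genes not detected in the
    intervention dataset are excluded from the denominator.
    """
    if fold_min <= 0:
        raise ConfigError("fold_min must be positive")
    detected = _aging_genes_in_diff(aging_calls, diff, direction)
    if len(detected) == 0:
        raise DegenerateDataError(
            "no aging genes of the requested direction detected in the "
            "intervention dataset; proportion undefined"
        )
    sub = diff.loc[detected]
    thr = np.log2(fold_min)
    if direction == "down":
        reversed_ok = sub["log2fc"] > thr
    else:
        reversed_ok = sub["log2fc"] < -thr
    hits = sub.index[reversed_ok & (sub["p"] < alpha)]
    return RescueReport(
        contrast=contrast, direction=direction,
        n_aging_detected=len(detected), n_rescued=len(hits),
        rescued_genes=frozenset(hits),
    )
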