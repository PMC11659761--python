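"""Synthetic cohorts with planted, machine-readable ground truth.

Four generators mirror the data types the analysis consumes:

* :func:`simulate_aging_cohort` — multi-tissue cohorts in which a planted
  fraction of genes trends linearly with donor age on the log2 scale, with
  the direction map shared by all tissues of the same signature group;
* :func:`simulate_disease_cohort` — an age-matched case/control cohort in
  which a stated fraction of the planted aging genes is shifted further in
  its aging direction in the case arm (syntropic deregulation);
* :func:`simulate_intervention_cohort` — an activity-stratified cohort in
  which a stated fraction of the planted down-aging genes is lifted in the
  high-activity arm only (rescue);
* :func:`simulate_mixture` — bulk profiles as noisy linear combinations of
  cell-type signature profiles with known mixing fractions.

Every generator takes an explicit seed and draws from one private
:class:`numpy.random.Generator`; identical seeds give bit-identical output.
The planted truth travels in :class:`SyntheticTruth` so recovery of effects
by the downstream screen/syntropy/rescue/deconvolution stages can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ConfigError

#: Default 12-region discovery panel: four signature groups of three tissues.
DEFAULT_TISSUES: dict[str, str] = {
    "hippocampus": "i",
    "amygdala": "i",
    "anterior_cingulate": "i",
    "frontal_cortex": "ii",
    "cortex": "ii",
    "hypothalamus": "ii",
    "cerebellum": "iii",
    "cerebellar_hemisphere": "iii",
    "caudate": "iii",
    "putamen": "iv",
    "nucleus_accumbens": "iv",
    "substantia_nigra": "iv",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the aging-cohort generator.

    Slopes are log2 units per year of age; ``noise_sd`` is the residual
    standard deviation in log2 units. Defaults plant a 40–69-year cohort
    with 10% down- and 5% up-trending genes per signature group.
    """

    n_genes: int = 2000
    n_samples_per_tissue: int = 60
    tissues: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    age_range: tuple[float, float] = (40.0, 69.0)
    frac_down: float = 0.10
    frac_up: float = 0.05
    slope_down: float = -0.04
    slope_up: float = 0.03
    noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_samples_per_tissue < 10:
            raise ConfigError(
                "n_samples_per_tissue must be >= 10; smaller cohorts make the "
                "downstream correlation screen unusable"
            )
        if not self.tissues:
            raise ConfigError("at least one tissue is required")
        if not (0 <= self.frac_down <= 1 and 0 <= self.frac_up <= 1):
            raise ConfigError("planted fractions must lie in [0, 1]")
        if self.frac_down + self.frac_up > 1:
            raise ConfigError("frac_down + frac_up must not exceed 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range must satisfy min < max")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulation lineage.

    ``aging`` holds one row per gene x signature group with the planted
    direction (up/down/null) and slope; ``baselines`` the per-gene log2
    baseline shared by all derived cohorts. Disease, rescue and mixture
    truths are attached by the respective generators.
    """

    config: SimulationConfig
    aging: pd.DataFrame
    baselines: pd.Series
    disease: pd.DataFrame | None = None
    rescue: pd.DataFrame | None = None
    mixture_fractions: pd.DataFrame | None = None

    def planted_genes(self, group: str, direction: str) -> list[str]:
        sub = self.aging[(self.aging["group"] == group)
                         & (self.aging["direction"] == direction)]
        return sub["gene"].tolist()

    def groups(self) -> list[str]:
        return sorted(self.aging["group"].unique())


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _mid_age(age_range: tuple[float, float]) -> float:
    return 0.5 * (age_range[0] + age_range[1])


def simulate_aging_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame, SyntheticTruth]:
    """Simulate a multi-tissue aging cohort.

    For gene *g* in sample *s* of a tissue in group *G*::

        log2 value = baseline_g + slope_{g,G} * (age_s - mid_age) + eps,
        eps ~ Normal(0, noise_sd^2)

    Ages are uniform on ``age_range``. Tissues of the same group share the
    planted direction map; null genes have slope zero.

    Returns per-tissue log2 expression matrices, one combined sample table,
    and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baselines = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes),
        index=genes, name="baseline",
    )

    n_down = round(config.frac_down * config.n_genes)
    n_up = round(config.frac_up * config.n_genes)
    groups = sorted(set(config.tissues.values()))
    truth_rows = []
    slopes: dict[str, np.ndarray] = {}
    for group in groups:
        order = rng.permutation(config.n_genes)
        slope = np.zeros(config.n_genes)
        direction = np.array(["null"] * config.n_genes, dtype=object)
        slope[order[:n_down]] = config.slope_down
        direction[order[:n_down]] = "down"
        slope[order[n_down:n_down + n_up]] = config.slope_up
        direction[order[n_down:n_down + n_up]] = "up"
        slopes[group] = slope
        truth_rows.append(pd.DataFrame({
            "gene": genes, "group": group, "direction": direction, "slope": slope,
        }))

    mid = _mid_age(config.age_range)
    matrices: dict[str, ExpressionMatrix] = {}
    sample_rows = []
    base = baselines.to_numpy()[:, None]
    for tissue in config.tissues:  # insertion order: deterministic
        group = config.tissues[tissue]
        n = config.n_samples_per_tissue
        ages = rng.uniform(*config.age_range, size=n)
        sids = [f"{tissue}_s{i:03d}" for i in range(1, n + 1)]
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
        vals = base + slopes[group][:, None] * (ages[None, :] - mid) + noise
        matrices[tissue] = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=sids), scale="log2"
        )
        sample_rows.append(pd.DataFrame({
            "sample_id": sids, "age": ages, "sex": "unknown", "tissue": tissue,
            "condition": "healthy", "activity": np.nan, "cohort": "discovery",
        }))

    samples = pd.concat(sample_rows, ignore_index=True)
    truth = SyntheticTruth(
        config=config,
        aging=pd.concat(truth_rows, ignore_index=True),
        baselines=baselines,
    )
    return matrices, samples, truth


def simulate_disease_cohort(
    truth: SyntheticTruth,
    group: str = "i",
    shift: float = 1.0,
    frac_syntropic: float = 0.4,
    n_per_arm: int = 50,
    seed: int = 0,
    noise_sd: float | None = None,
    tissue: str = "disease_tissue",
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate an age-matched case/control cohort on a prior truth.

    A fraction ``frac_syntropic`` of the group's planted aging genes gains a
    case-arm shift of magnitude ``shift`` with the same sign as its aging
    direction. Case and control arms use identical age vectors, so the
    case/control contrast is net of the shared aging trend.
    """
    if not 0 <= frac_syntropic <= 1:
        raise ConfigError("frac_syntropic must lie in [0, 1]")
    if n_per_arm < 3:
        raise ConfigError("n_per_arm must be >= 3")
    cfg = truth.config
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    genes = list(truth.baselines.index)

    sub = truth.aging[truth.aging["group"] == group].set_index("gene")
    if sub.empty:
        raise ConfigError(f"unknown signature group {group!r}")
    aging_genes = sub.index[sub["direction"] != "null"].to_numpy()
    n_syn = round(frac_syntropic * len(aging_genes))
    syn_genes = rng.choice(aging_genes, size=n_syn, replace=False) if n_syn else []
    sign = sub["direction"].map({"up": 1.0, "down": -1.0, "null": 0.0})
    shift_vec = pd.Series(0.0, index=genes)
    shift_vec.loc[list(syn_genes)] = shift * sign.loc[list(syn_genes)]

    mid = _mid_age(cfg.age_range)
    ages = rng.uniform(*cfg.age_range, size=n_per_arm)
    slope = sub["slope"].reindex(genes).fillna(0.0).to_numpy()[:, None]
    base = truth.baselines.to_numpy()[:, None]

    def arm(label: str, extra: np.ndarray | float) -> tuple[np.ndarray, list[str]]:
        noise = rng.normal(0.0, noise_sd, size=(len(genes), n_per_arm))
        vals = base + slope * (ages[None, :] - mid) + extra + noise
        sids = [f"{tissue}_{label}_s{i:03d}" for i in range(1, n_per_arm + 1)]
        return vals, sids

    ctl_vals, ctl_ids = arm("control", 0.0)
    case_vals, case_ids = arm("case", shift_vec.to_numpy()[:, None])

    expr = ExpressionMatrix(
        pd.DataFrame(
            np.hstack([case_vals, ctl_vals]), index=genes, columns=case_ids + ctl_ids
        ),
        scale="log2",
    )
    samples = pd.DataFrame({
        "sample_id": case_ids + ctl_ids,
        "age": np.concatenate([ages, ages]),
        "sex": "unknown",
        "tissue": tissue,
        "condition": ["case"] * n_per_arm + ["control"] * n_per_arm,
        "activity": np.nan,
        "cohort": "disease",
    })
    disease = pd.DataFrame({
        "gene": genes,
        "shift": shift_vec.to_numpy(),
        "syntropic": [g in set(syn_genes) for g in genes],
        "group": group,
    })
    return expr, samples, replace(truth, disease=disease)


def simulate_intervention_cohort(
    truth: SyntheticTruth,
    group: str = "i",
    rescue_frac: float = 0.4,
    offset: float = 1.0,
    n_per_arm: int = 50,
    seed: int = 0,
    noise_sd: float | None = None,
    high_cut: float = 2.1,
    moderate_cut: float = 1.0,
    activity_scale: float = 1e5,
    activity_max: float = 3.5,
    tissue: str = "hippocampus",
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate an activity-stratified intervention cohort.

    Samples fall in three arms (high / moderate / low) of ``n_per_arm``
    each, with the actigraphy covariate drawn uniformly inside the arm's
    interval (cut-offs ``moderate_cut`` and ``high_cut`` in units of
    ``activity_scale`` counts/day). A fraction ``rescue_frac`` of the
    group's planted down-aging genes gains a positive offset of ``offset``
    log2 units in the high-activity arm only.

    Arms are age-matched (one shared age vector), emulating the matched
    cohort designs the contrast assumes; otherwise the shared aging trend
    would confound the high-vs-low contrast coherently across genes.
    """
    if not 0 <= rescue_frac <= 1:
        raise ConfigError("rescue_frac must lie in [0, 1]")
    if n_per_arm < 3:
        raise ConfigError("n_per_arm must be >= 3")
    cfg = truth.config
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    genes = list(truth.baselines.index)

    sub = truth.aging[truth.aging["group"] == group].set_index("gene")
    if sub.empty:
        raise ConfigError(f"unknown signature group {group!r}")
    down_genes = sub.index[sub["direction"] == "down"].to_numpy()
    n_res = round(rescue_frac * len(down_genes))
    res_genes = set(rng.choice(down_genes, size=n_res, replace=False)) if n_res else set()
    offset_vec = pd.Series(0.0, index=genes)
    offset_vec.loc[sorted(res_genes)] = offset

    mid = _mid_age(cfg.age_range)
    slope = sub["slope"].reindex(genes).fillna(0.0).to_numpy()[:, None]
    base = truth.baselines.to_numpy()[:, None]

    arm_bounds = {
        "low": (0.1, moderate_cut),
        "moderate": (moderate_cut, high_cut),
        "high": (high_cut, activity_max),
    }
    ages = rng.uniform(*cfg.age_range, size=n_per_arm)  # shared: age-matched
    blocks, sids_all, rows = [], [], []
    for label, (lo, hi) in arm_bounds.items():
        activity = rng.uniform(lo, hi, size=n_per_arm) * activity_scale
        noise = rng.normal(0.0, noise_sd, size=(len(genes), n_per_arm))
        extra = offset_vec.to_numpy()[:, None] if label == "high" else 0.0
        vals = base + slope * (ages[None, :] - mid) + extra + noise
        sids = [f"{tissue}_{label}_s{i:03d}" for i in range(1, n_per_arm + 1)]
        blocks.append(vals)
        sids_all.extend(sids)
        rows.append(pd.DataFrame({
            "sample_id": sids, "age": ages, "sex": "unknown", "tissue": tissue,
            "condition": "healthy", "activity": activity, "cohort": "intervention",
        }))

    expr = ExpressionMatrix(
        pd.DataFrame(np.hstack(blocks), index=genes, columns=sids_all), scale="log2"
    )
    samples = pd.concat(rows, ignore_index=True)
    rescue = pd.DataFrame({
        "gene": genes,
        "offset": offset_vec.to_numpy(),
        "rescued": [g in res_genes for g in genes],
        "group": group,
    })
    return expr, samples, replace(truth, rescue=rescue)


def simulate_validation_cohort(
    truth: SyntheticTruth,
    group: str = "i",
    n_samples: int = 100,
    seed: int = 0,
    noise_sd: float | None = None,
    age_range: tuple[float, float] | None = None,
    tissue: str = "validation_cohort",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate an independent healthy cohort sharing a group's planted
    slopes, for replication screening (conventionally against log age)."""
    if n_samples < 10:
        raise ConfigError("n_samples must be >= 10")
    cfg = truth.config
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    age_range = cfg.age_range if age_range is None else age_range
    rng = np.random.default_rng(seed)
    genes = list(truth.baselines.index)
    sub = truth.aging[truth.aging["group"] == group].set_index("gene")
    if sub.empty:
        raise ConfigError(f"unknown signature group {group!r}")
    slope = sub["slope"].reindex(genes).fillna(0.0).to_numpy()[:, None]
    base = truth.baselines.to_numpy()[:, None]
    mid = _mid_age(age_range)
    ages = rng.uniform(*age_range, size=n_samples)
    noise = rng.normal(0.0, noise_sd, size=(len(genes), n_samples))
    vals = base + slope * (ages[None, :] - mid) + noise
    sids = [f"{tissue}_s{i:03d}" for i in range(1, n_samples + 1)]
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=sids), scale="log2"
    )
    samples = pd.DataFrame({
        "sample_id": sids, "age": ages, "sex": "unknown", "tissue": tissue,
        "condition": "healthy", "activity": np.nan, "cohort": "validation",
    })
    return expr, samples


# ---------------------------------------------------------------------------
# cell mixtures
# ---------------------------------------------------------------------------

DEFAULT_CELL_TYPES = ("neuron", "oligodendrocyte", "astrocyte",
                      "microglia", "vascular", "opc")


def make_separated_signatures(
    cell_types=DEFAULT_CELL_TYPES,
    markers_per_type: int = 30,
    n_background: int = 120,
    marker_level: float = 200.0,
    background_level: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear-scale signature profiles with disjoint marker blocks.

    Each cell type expresses its own block of ``markers_per_type`` genes at
    ``marker_level`` (with mild lognormal variation) on top of a shared
    background; blocks are disjoint, so columns are well separated.
    """
    rng = np.random.default_rng(seed)
    n_genes = markers_per_type * len(cell_types) + n_background
    genes = [f"M{i:05d}" for i in range(1, n_genes + 1)]
    sig = rng.lognormal(mean=np.log(background_level), sigma=0.3,
                        size=(n_genes, len(cell_types)))
    for j, _ in enumerate(cell_types):
        block = slice(j * markers_per_type, (j + 1) * markers_per_type)
        sig[block, j] = rng.lognormal(np.log(marker_level), 0.2, markers_per_type)
    return pd.DataFrame(sig, index=genes, columns=list(cell_types))


def simulate_single_cell(
    signatures: pd.DataFrame,
    cells_per_type: int = 30,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Labeled single-cell log2 profiles around per-type signature means."""
    rng = np.random.default_rng(seed)
    log_sig = np.log2(signatures.to_numpy() + 1.0)
    blocks, sids, rows = [], [], []
    for j, ctype in enumerate(signatures.columns):
        noise = rng.normal(0.0, noise_sd, size=(signatures.shape[0], cells_per_type))
        blocks.append(log_sig[:, [j]] + noise)
        ids = [f"{ctype}_c{i:03d}" for i in range(1, cells_per_type + 1)]
        sids.extend(ids)
        rows.append(pd.DataFrame({
            "sample_id": ids, "age": np.nan, "sex": "unknown", "tissue": "brain",
            "condition": "healthy", "activity": np.nan, "cohort": "single_cell",
            "cell_type": ctype,
        }))
    expr = ExpressionMatrix(
        pd.DataFrame(np.hstack(blocks), index=signatures.index, columns=sids),
        scale="log2",
    )
    return expr, pd.concat(rows, ignore_index=True)


def random_fractions(n_samples: int, cell_types, seed: int = 0) -> pd.DataFrame:
    """Dirichlet(1) fraction vectors, one per sample."""
    rng = np.random.default_rng(seed)
    frac = rng.dirichlet(np.ones(len(cell_types)), size=n_samples)
    return pd.DataFrame(frac, columns=list(cell_types),
                        index=[f"mix_s{i:03d}" for i in range(1, n_samples + 1)])


def simulate_mixture(
    signatures: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk profiles as linear mixtures of signature columns.

    ``bulk[g, s] = sum_type fractions[s, type] * signatures[g, type]`` with
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``
    (clipped at zero). With ``noise_cv = 0`` the simulation is the exact
    matrix product.
    """
    if (fractions.to_numpy() < 0).any():
        raise ConfigError("fractions must be non-negative")
    sums = fractions.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = fractions.index[~np.isclose(sums, 1.0, atol=1e-6)].tolist()
        raise ConfigError(f"fraction vectors must sum to 1: {bad[:5]}")
    if list(fractions.columns) != list(signatures.columns):
        raise ConfigError("fraction columns must match signature cell types")
    rng = np.random.default_rng(seed)
    bulk = signatures.to_numpy() @ fractions.to_numpy().T
    if noise_cv > 0:
        factor = 1.0 + noise_cv * rng.standard_normal(bulk.shape)
        bulk = bulk * np.clip(factor, 0.0, None)
    expr = ExpressionMatrix(
        pd.DataFrame(bulk, index=signatures.index, columns=fractions.index),
        scale="raw",
    )
    return expr, fractions.copy()
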