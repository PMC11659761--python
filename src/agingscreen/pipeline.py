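"""End-to-end synthetic pipeline: simulate → screen → group → validate →
syntropy → rescue → deconvolve → enrich.

The pipeline runs on synthetic cohorts with planted truth (individual CLI
subcommands operate on user-supplied files instead). Every stage writes its
tables through the package's deterministic TSV writers, and the run
manifest records the config hash, seed, per-file SHA-256 checksums and row
counts plus a planted-truth recovery summary — so a rerun with an identical
config is byte-identical and verifiably so.

All thresholds the analysis convention fixes (alpha 0.05 up / 0.01 down,
actigraphy cut-offs 1 and 2.1 x 1e5 counts/day, fold 1.1 for
cell-resolved contrasts, age-bin split at 60 years, replication minima of
3 tissues for up and 6 for down genes) are explicit config keys with those
values as defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrasts, deconv, enrich, io, screen, simulate
from .containers import GeneSetCollection
from .errors import ConfigError, DependencyError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "group", "validate", "syntropy", "rescue",
          "deconvolve", "enrich")

#: upstream requirements of each stage
STAGE_DEPS = {
    "screen": ("simulate",),
    "group": ("screen",),
    "validate": ("screen",),
    "syntropy": ("screen",),
    "rescue": ("screen",),
    "deconvolve": (),
    "enrich": ("group",),
}


@dataclass
class PipelineConfig:
    """Full configuration of a synthetic end-to-end run."""

    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})

    # cohort simulation
    n_genes: int = 2000
    n_samples_per_tissue: int = 60
    tissues: dict[str, str] = field(
        default_factory=lambda: dict(simulate.DEFAULT_TISSUES))
    age_range: tuple[float, float] = (40.0, 69.0)
    frac_down: float = 0.10
    frac_up: float = 0.05
    slope_down: float = -0.04
    slope_up: float = 0.03
    noise_sd: float = 1.0

    # screening
    alpha_up: float = 0.05
    alpha_down: float = 0.01
    age_window: tuple[float, float] | None = (40.0, 69.0)
    n_groups: int = 4
    grouping_file: str | None = None

    # validation
    n_validation_cohorts: int = 2
    n_validation_samples: int = 100
    k_min_up: int = 3
    k_min_down: int = 6
    validation_group: str = "i"

    # disease / intervention contrasts
    alpha_diff: float = 0.05
    fold_min: float = 1.0
    disease_shift: float = 1.0
    frac_syntropic: float = 0.40
    disease_n_per_arm: int = 50
    rescue_offset: float = 1.0
    rescue_frac: float = 0.40
    intervention_n_per_arm: int = 50
    high_activity_cut: float = contrasts.HIGH_ACTIVITY_CUT
    moderate_activity_cut: float = contrasts.MODERATE_ACTIVITY_CUT
    activity_scale: float = contrasts.ACTIVITY_SCALE
    contrast_group: str = "i"

    # deconvolution
    markers_per_type: int = 50
    n_mixture_samples: int = 50
    mixture_noise_cv: float = 0.10
    age_split: float = 60.0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for stage, deps in STAGE_DEPS.items():
            if self.stages.get(stage, False):
                for dep in deps:
                    if not self.stages.get(dep, False):
                        raise DependencyError(
                            f"stage {stage!r} requires stage {dep!r}"
                        )
        if self.grouping_file is not None and not Path(self.grouping_file).exists():
            raise ConfigError(f"grouping file not found: {self.grouping_file}")
        self.simulation_config()  # validates simulation parameters

    def simulation_config(self) -> simulate.SimulationConfig:
        cfg = simulate.SimulationConfig(
            n_genes=self.n_genes,
            n_samples_per_tissue=self.n_samples_per_tissue,
            tissues=dict(self.tissues),
            age_range=tuple(self.age_range),
            frac_down=self.frac_down,
            frac_up=self.frac_up,
            slope_down=self.slope_down,
            slope_up=self.slope_up,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["age_range"] = list(self.age_range)
        if self.age_window is not None:
            out["age_window"] = list(self.age_window)
        return out

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)  # minus header


class _Run:
    """Mutable state of one pipeline execution."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.files: dict[str, Path] = {}
        self.summary: dict[str, object] = {}
        # seeds for the derived cohorts, decoupled from the cohort seed
        ss = np.random.SeedSequence(config.seed)
        self.subseeds = [int(s.generate_state(1)[0] % (2 ** 31))
                         for s in ss.spawn(8)]

    def write(self, key: str, df: pd.DataFrame, name: str, **kw) -> None:
        path = self.outdir / name
        io.write_table(df, path, **kw)
        self.files[key] = path


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order and return the run
    manifest (also written to ``manifest.json`` in ``outdir``)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, outdir)
    on = lambda stage: config.stages.get(stage, False)

    matrices = samples = truth = None
    call_tables: dict[str, pd.DataFrame] = {}
    similarity = None

    if on("simulate"):
        matrices, samples, truth = simulate.simulate_aging_cohort(
            config.simulation_config())
        run.write("truth_aging", truth.aging, "truth_aging.tsv")
        io.write_sample_table(samples, outdir / "samples.tsv")
        run.files["samples"] = outdir / "samples.tsv"
        for tissue, expr in matrices.items():
            path = outdir / f"expr_{tissue}.tsv"
            io.write_expression(expr, path)
            run.files[f"expr_{tissue}"] = path
        run.summary["n_genes"] = config.n_genes
        run.summary["n_tissues"] = len(matrices)

    if on("screen"):
        for tissue, expr in matrices.items():
            table = screen.screen_tissue(
                expr, samples[samples["tissue"] == tissue],
                alpha_up=config.alpha_up, alpha_down=config.alpha_down,
                age_window=config.age_window, tissue=tissue,
            )
            call_tables[tissue] = table
            run.write(f"calls_{tissue}", table.reset_index(),
                      f"calls_{tissue}.tsv")
        run.summary["screen"] = {
            t: {"n_up": int((tab["call"] == "up").sum()),
                "n_down": int((tab["call"] == "down").sum())}
            for t, tab in call_tables.items()
        }

    if on("group"):
        fixed = None
        if config.grouping_file is not None:
            gdf = io.read_table(config.grouping_file)
            fixed = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1].astype(str)))
        similarity = screen.tissue_signature_similarity(
            call_tables, n_groups=config.n_groups, fixed_groups=fixed)
        run.write("similarity", similarity.similarity.reset_index(names="tissue"),
                  "tissue_similarity.tsv")
        groups_df = similarity.groups.rename("group").rename_axis("tissue").reset_index()
        run.write("groups", groups_df, "tissue_groups.tsv")
        (outdir / "tissue_linkage.nwk").write_text(
            screen.linkage_to_newick(similarity.linkage,
                                     list(similarity.similarity.index)) + "\n")
        run.files["linkage"] = outdir / "tissue_linkage.nwk"

        inter_rows = []
        for grp, members in sorted(similarity.group_members().items()):
            for direction in ("down", "up"):
                gi = screen.group_intersection(call_tables, members, direction,
                                               group=grp)
                for gene in sorted(gi.genes):
                    inter_rows.append({"group": grp, "direction": direction,
                                       "gene": gene})
        run.write("group_genes",
                  pd.DataFrame(inter_rows, columns=["group", "direction", "gene"]),
                  "group_aging_genes.tsv")
        planted = _partition_from_truth(truth)
        recovered = {frozenset(m) for m in similarity.group_members().values()}
        run.summary["grouping_matches_planted"] = recovered == planted
        run.summary["n_group_down_genes"] = {
            grp: sum(1 for r in inter_rows
                     if r["group"] == grp and r["direction"] == "down")
            for grp in sorted(similarity.group_members())
        }

    if on("validate"):
        val_tables = []
        for i in range(config.n_validation_cohorts):
            vexpr, vsamples = simulate.simulate_validation_cohort(
                truth, group=config.validation_group,
                n_samples=config.n_validation_samples,
                seed=run.subseeds[0] + i, tissue=f"validation{i}",
            )
            val_tables.append(screen.screen_tissue(
                vexpr, vsamples, alpha_up=config.alpha_up,
                alpha_down=config.alpha_down, log_age=True, age_window=None,
                tissue=f"validation{i}",
            ))
        validated = {}
        for direction, k_min in (("up", config.k_min_up),
                                 ("down", config.k_min_down)):
            validated[direction] = screen.cross_validate(
                call_tables, val_tables, k_min=k_min, direction=direction)
        rows = [{"direction": d, "gene": g}
                for d in ("down", "up") for g in sorted(validated[d])]
        run.write("validated", pd.DataFrame(rows, columns=["direction", "gene"]),
                  "validated_genes.tsv")
        run.summary["n_validated"] = {d: len(validated[d]) for d in validated}

    if on("syntropy"):
        dexpr, dsamples, truth = simulate.simulate_disease_cohort(
            truth, group=config.contrast_group, shift=config.disease_shift,
            frac_syntropic=config.frac_syntropic,
            n_per_arm=config.disease_n_per_arm, seed=run.subseeds[1],
        )
        case_ids = dsamples.loc[dsamples["condition"] == "case", "sample_id"]
        ctl_ids = dsamples.loc[dsamples["condition"] == "control", "sample_id"]
        norm = contrasts.normalize_to_control_mean(dexpr, ctl_ids)
        diff = contrasts.two_group_diff(norm, case_ids, ctl_ids)
        run.write("disease_diff", diff.reset_index(), "disease_diff.tsv")
        calls = call_tables[_group_tissue(config, truth)]
        reports = []
        for direction in ("down", "up"):
            rep = contrasts.syntropy(calls, diff, direction,
                                     alpha=config.alpha_diff,
                                     tissue="disease_tissue")
            reports.append({"tissue": rep.tissue, "direction": rep.direction,
                            "n_aging_detected": rep.n_aging_detected,
                            "n_syntropic": rep.n_syntropic,
                            "proportion": rep.proportion})
        run.write("syntropy", pd.DataFrame(reports), "syntropy.tsv")
        run.summary["syntropy_down_proportion"] = reports[0]["proportion"]
        run.summary["planted_syntropic_fraction"] = config.frac_syntropic

    if on("rescue"):
        iexpr, isamples, truth = simulate.simulate_intervention_cohort(
            truth, group=config.contrast_group, rescue_frac=config.rescue_frac,
            offset=config.rescue_offset,
            n_per_arm=config.intervention_n_per_arm, seed=run.subseeds[2],
            high_cut=config.high_activity_cut,
            moderate_cut=config.moderate_activity_cut,
            activity_scale=config.activity_scale,
        )
        arms = contrasts.stratify_activity(
            isamples, high_cut=config.high_activity_cut,
            moderate_cut=config.moderate_activity_cut,
            scale=config.activity_scale)
        high_ids = arms.index[arms == "high"]
        low_ids = arms.index[arms == "low"]
        diff = contrasts.two_group_diff(iexpr, high_ids, low_ids)
        run.write("intervention_diff", diff.reset_index(),
                  "intervention_diff.tsv")
        calls = call_tables[_group_tissue(config, truth)]
        reports = []
        for direction in ("down", "up"):
            rep = contrasts.rescue(calls, diff, direction,
                                   alpha=config.alpha_diff,
                                   fold_min=config.fold_min)
            reports.append({"contrast": rep.contrast, "direction": rep.direction,
                            "n_aging_detected": rep.n_aging_detected,
                            "n_rescued": rep.n_rescued,
                            "proportion": rep.proportion})
        run.write("rescue", pd.DataFrame(reports), "rescue.tsv")
        run.summary["rescue_down_proportion"] = reports[0]["proportion"]
        run.summary["planted_rescue_fraction"] = config.rescue_frac

    if on("deconvolve"):
        _run_deconvolve(run)

    if on("enrich"):
        _run_enrich(run, truth, call_tables, outdir)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": [s for s in STAGES if on(s)],
        "files": {
            key: {"path": path.name, "sha256": _sha256(path),
                  "n_rows": _count_rows(path)}
            for key, path in sorted(run.files.items())
        },
        "summary": run.summary,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest


def _partition_from_truth(truth) -> set[frozenset[str]]:
    groups: dict[str, set[str]] = {}
    for tissue, grp in truth.config.tissues.items():
        groups.setdefault(grp, set()).add(tissue)
    return {frozenset(m) for m in groups.values()}


def _group_tissue(config: PipelineConfig, truth) -> str:
    """First tissue of the contrast group — its call table is the aging
    reference for syntropy/rescue scoring."""
    for tissue, grp in config.tissues.items():
        if grp == config.contrast_group:
            return tissue
    raise ConfigError(f"no tissue in contrast group {config.contrast_group!r}")


def _run_deconvolve(run: _Run) -> None:
    config = run.config
    signatures = simulate.make_separated_signatures(seed=run.subseeds[3])
    sc_expr, sc_samples = simulate.simulate_single_cell(
        signatures, seed=run.subseeds[4])
    built = deconv.build_signature(
        sc_expr, pd.Series(sc_samples["cell_type"].to_numpy(),
                           index=sc_samples["sample_id"]),
        markers_per_type=config.markers_per_type)
    run.write("signature", built.reset_index(), "cell_signature.tsv")

    # two mixture groups: neuron-rich "young" vs neuron-poor "old"
    rng = np.random.default_rng(run.subseeds[5])
    half = config.n_mixture_samples // 2
    n_types = signatures.shape[1]
    alpha_young = np.ones(n_types)
    alpha_young[0] = 6.0  # neuron-dominated
    alpha_old = np.ones(n_types)
    alpha_old[0] = 3.0
    frac = np.vstack([rng.dirichlet(alpha_young, size=half),
                      rng.dirichlet(alpha_old, size=config.n_mixture_samples - half)])
    fractions = pd.DataFrame(
        frac, columns=list(signatures.columns),
        index=[f"mix_s{i:03d}" for i in range(1, config.n_mixture_samples + 1)])
    bulk, true_frac = simulate.simulate_mixture(
        signatures, fractions, noise_cv=config.mixture_noise_cv,
        seed=run.subseeds[6])
    run.write("true_fractions", true_frac.reset_index(names="sample_id"),
              "true_fractions.tsv")

    linear_sig = np.exp2(built) - 1.0
    est, residuals = deconv.estimate_fractions(bulk, linear_sig)
    run.write("fractions", est.reset_index(names="sample_id"), "fractions.tsv")
    l1 = np.abs(est - true_frac).sum(axis=1).mean()
    run.summary["deconv_mean_l1_error"] = float(l1)

    ages = np.array([50.0] * half
                    + [65.0] * (config.n_mixture_samples - half))
    mix_samples = pd.DataFrame({
        "sample_id": fractions.index, "age": ages, "sex": "unknown",
        "tissue": "hippocampus", "condition": "healthy",
        "activity": np.nan, "cohort": "mixtures",
    })
    comparison = deconv.compare_fractions(
        est, deconv.age_bins(mix_samples, split=config.age_split))
    run.write("fraction_comparison", comparison, "fraction_comparison.tsv")
    neuron = comparison[comparison["cell_type"] == signatures.columns[0]]
    run.summary["neuron_fraction_p"] = float(neuron["p"].iloc[0])


def _run_enrich(run: _Run, truth, call_tables, outdir: Path) -> None:
    config = run.config
    # gene-set collection derived from the planted truth plus random decoys
    rng = np.random.default_rng(run.subseeds[7])
    genes = list(truth.baselines.index)
    sets: dict[str, frozenset] = {}
    for grp in truth.groups():
        for direction in ("down", "up"):
            members = truth.planted_genes(grp, direction)
            if members:
                sets[f"planted_{direction}_group_{grp}"] = frozenset(members)
    for i in range(5):
        sets[f"random_set_{i}"] = frozenset(
            rng.choice(genes, size=50, replace=False))
    collection = GeneSetCollection(sets=sets)
    io.write_gmt(collection, outdir / "genesets.gmt")
    run.files["genesets"] = outdir / "genesets.gmt"

    ref_tissue = _group_tissue(config, truth)
    calls = call_tables[ref_tissue]
    universe = frozenset(calls.index)
    query = frozenset(calls.index[calls["call"] == "down"])
    table = enrich.hypergeom_enrich(query, collection, universe)
    run.write("enrichment", table, "enrichment.tsv")
    if not table.empty:
        run.summary["top_enriched_set"] = str(table.iloc[0]["set"])
        run.summary["top_enrichment_q"] = float(table.iloc[0]["q"])
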