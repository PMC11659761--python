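# Methods

## Aging-gene screen

The screen models expression as linear in age on the log2 scale and tests
each gene's Pearson correlation *r* against donor age with the exact
*t* transform, t = r·√((n−2)/(1−r²)), two-sided against t(n−2). Raw
matrices are transformed as log2(x+1); the fixed pseudocount makes the
transform total on counts and intensities. Calling is asymmetric by
convention: up requires r > 0 and p < α_up (default 0.05), down requires
r < 0 and p < α_down (default 0.01). No multiple-testing correction is
applied inside the screen — the raw-p thresholds *are* the calling rule —
but a BH switch (`bh_adjust`) exists for sensitivity analyses. Under the
null, the two-sided p combined with the sign constraint yields expected
call rates of α_up/2 and α_down/2; the test suite asserts this calibration
on 10,000 null genes.

Donors are restricted to a configurable age window, default 40–69 years, a
plain mid-to-late-life discovery window; validation screens instead use
all ages and correlate against log-transformed age, matching the
convention for cohorts with wide age spans where expression trends flatten
at high age. Genes are usable in a tissue only with ≥ 10 unmasked samples;
genes constant within a tissue are excluded from that tissue's calls and
signature (a correlation of 0 is never silently reported for an undefined
statistic). Missing values are explicit boolean masks — accidental NaN is
rejected at construction.

## Tissue signatures and groups

A tissue's aging signature is its vector of per-gene *r*-values. Tissues
are compared by the Pearson correlation of signatures over the genes
usable in every tissue (minimum 100 shared genes), and grouped by
average-linkage hierarchical clustering on the 1−r distance, cut at a
user-chosen group count. Average linkage on correlation distance is the
default behavior of the standard clustered-heatmap tools this mirrors, and
is stated here so the grouping is deterministic. Because a data-driven
grouping is a fragile foundation for downstream set intersections, an
explicit tissue→group file can override clustering. Group aging genes are
the genes called in the same direction in *every* member tissue;
Venn-region counts over all tissue subsets are reported alongside.
Cross-cohort validation retains genes called in ≥ k_min discovery tissues
(defaults: 3 for up, 6 for down — plain parameters) that replicate with
the same sign in ≥ 1 validation screen.

## Disease and intervention contrasts

The two-group contrast is deliberately simple and fully specified:
log2FC = mean(A) − mean(B) on log2 values with a two-sided Welch *t* per
gene. Genes with zero variance in both groups are flagged degenerate and
excluded from downstream denominators. Count-model machinery
(negative-binomial dispersion estimation, TMM/size-factor normalization)
is intentionally out of scope: with a fully specified contrast the
syntropy/rescue estimators can be validated exactly against planted truth,
which is this package's acceptance surface; absolute gene lists from
count-model pipelines will differ.

Syntropy: among aging genes of a direction detected in the disease
dataset, the proportion with same-signed log2FC at p < α (default 0.05)
in the case-vs-control contrast. Controls are assumed age-matched, so the
contrast is net of the shared aging trend. Optionally, expression is first
normalized per stratum (brain area) to the control-sample mean — a shift
on the log2 scale, a division on the raw scale — which centers control
strata at 0/1; this changes no Welch statistic within a stratum but makes
cross-stratum tables comparable.

Rescue: among aging genes of a direction detected in the intervention
dataset, the proportion significantly shifted the *opposite* way —
for down genes, log2FC > log2(fold_min) and p < α in the high-vs-low
contrast. fold_min defaults to 1.0 (any significant reversal); 1.1 is the
convention for cell-resolved contrasts. Counts are monotone in both
thresholds. Activity arms follow the actigraphy convention: high strictly
above 2.1×10⁵ counts/day, moderate in (1×10⁵, 2.1×10⁵] — the boundary
value is moderate, encoding the half-open interval exactly — low
otherwise; samples without an actigraphy value are excluded with a logged
count.

## Deconvolution

The signature matrix is built from labeled single-cell log2 profiles
(≥ 20 cells per type): for each cell type, the `markers_per_type`
(default 50) genes with the largest margin mean(type) − max(mean(other
types)) are selected, and entries are per-type means. A type with no
positive-margin gene, or two indistinguishable types, is rejected by name.
Fractions are estimated per bulk sample by non-negative least squares
min‖Sf − b‖₂, f ≥ 0, then renormalized to the simplex; renormalization
makes estimates invariant to positive rescaling of the bulk profile, and
the residual norm is reported per sample. NNLS is a transparent, testable
estimator for the fraction task; it does not attempt to reproduce
ν-SVR-based digital-cytometry tools, and no batch correction is applied
(none is algorithmically specified for those tools). Group comparisons of
fractions use Welch's *t* per cell type, with a default age split at 60
years for aging contrasts.

## Over-representation

For a query of size n from a universe of size N and a set covering K
universe genes with overlap k, p = P[X ≥ k] under
Hypergeometric(N, K, n); k = 0 gives p = 1 exactly. The universe defaults
to the genes detectable in the experiment that produced the query, not
the genome — conditioning on detectability avoids inflating enrichment of
well-expressed pathways. BH step-up q-values are computed across all
tested sets; depletion is not tested. The implementation agrees with
exhaustive rational enumeration for every configuration with N ≤ 25
(asserted in the suite).

## Synthetic cohorts

The generators are the matched generative model of the analysis, not a
facsimile of real data:

* **Aging cohort** — per gene, tissue group and sample:
  log2 value = baseline_g + slope_{g,group}·(age − mid-age) + ε,
  ε ~ N(0, noise_sd²), ages uniform on the age range. Tissues of a group
  share the planted direction map; maps are drawn independently per group.
  Defaults: 2000 genes, 60 samples/tissue, twelve brain regions in four
  groups, ages 40–69, 10% down at −0.04 log2/yr, 5% up at +0.03, noise sd
  1.0 log2 units, baselines N(5, 2²) — a mid-expressed transcriptome with
  age effects of realistic magnitude (|r| ≈ 0.3 at n = 150). For
  recovery experiments at |r| ≈ 0.4 the slope 0.052 is used; the closed
  form r = s·sd(age)/√(s²·var(age) + σ²) ties slopes to target
  correlations and is asserted empirically in the suite.
* **Disease cohort** — case and control arms share one age vector
  (age-matched by construction); a stated fraction of the group's planted
  aging genes gains a case-arm shift with the sign of its aging direction.
* **Intervention cohort** — three activity arms with actigraphy drawn
  uniformly inside each arm's interval; a stated fraction of planted
  down genes gains a positive offset in the high arm only. Arms share one
  age vector: without age matching the shared aging trend confounds the
  high-vs-low contrast coherently across genes, which is exactly what the
  matched designs this emulates rule out.
* **Mixtures** — bulk = Σ fraction × signature with multiplicative
  Gaussian noise of stated CV (clipped at 0); zero noise is an exact
  matrix product. Companion helpers generate well-separated linear-scale
  signatures (disjoint marker blocks) and labeled single-cell log2
  profiles around them.

Every generator draws from one private `numpy.random.Generator` seeded
explicitly; identical seeds give bit-identical cohorts. What the
generators do **not** emulate: library-size and batch artifacts, GTEx-like
marginal expression distributions, count overdispersion, correlated gene
modules, or nonlinear age trajectories. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data complications.

## Pipeline and determinism

`run_pipeline` executes the enabled stages in dependency order on
synthetic cohorts, writing every intermediate table through deterministic
writers (fixed `%.17g` float format, no timestamps) plus a manifest with
the config hash, seed, per-file SHA-256 and row counts. Derived cohorts
use seeds spawned from the master seed via `SeedSequence`, so stage
toggles do not shift one another's streams. Problem sizes in the default
config (2000 genes × 12 tissues × 60 samples; 50 samples/arm; 50
mixtures) keep a full run in seconds while leaving all recovery
comparisons well-powered.

## Numerical conventions

* Pearson r clipped to [−1, 1]; |r| = 1 maps to the smallest positive
  float rather than p = 0 (p is defined on (0, 1]).
* Round-trip fidelity: TSV/GCT writers use repr-faithful floats, so
  write→read reproduces values to < 1e-9 (asserted).
* Gene identifiers are matched by exact string equality after
  upper-casing; no alias resolution is attempted.
* The permutation check of the Pearson p-value is aggregate (mean bias
  over vector pairs within 3 standard errors): at n = 8 the conditional
  permutation law differs from the unconditional t law per dataset by far
  more than Monte-Carlo error, so a per-vector comparison would reject a
  provably correct implementation. The aggregate form still detects a
  wrong degrees-of-freedom or one-sided-tail implementation at |z| > 13.

## Known limitations

* The Welch-t contrast and NNLS deconvolution are stand-ins chosen for
  specifiability; studies using count models or ν-SVR cytometry will
  produce different gene lists and fraction estimates.
* The screen assumes linear-in-age trends; nonlinear trajectories
  attenuate r and reduce sensitivity.
* Cross-dataset joins require a shared identifier namespace.
* The clustering-based grouping depends on the signal-to-noise of the
  signatures; the fixed-grouping override exists for exactly that reason.
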