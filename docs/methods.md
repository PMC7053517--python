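# Methods

`tilquant` quantifies the functional state of tumour-infiltrating
lymphocytes (TILs) from multiplexed-immunofluorescence single-cell
tables. This note describes the statistical model behind each stage, the
parameters that matter, what the synthetic cohorts do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Input model

The pipeline starts from a quantified single-cell table: one row per
segmented cell carrying identifiers (`cell_id`, `core_id`, `patient_id`),
the centroid in pixels, and one mean-fluorescence-intensity (MFI) column
per marker of a 39-marker panel. Everything upstream — registration,
autofluorescence subtraction, segmentation — is out of scope; everything
downstream of the table is implemented here.

## QC and normalization (`tilquant.qc`)

Cells expressing fewer than 3 markers are removed, then markers expressed
in fewer than 1% of cells are dropped (the boundary is inclusive:
exactly 1% is retained). "Expressed" means raw MFI strictly above a
configurable threshold, default 0 — the data are assumed
background-subtracted upstream, and no positivity gate is imposed beyond
that. Filters run cells-first, then markers.

Each surviving marker is converted to a z-score over all retained cells
(sample sd, n−1 denominator) and trimmed to [−5, +5] so single outliers
cannot dominate the PCA or the clustering. Trimming counts are logged;
the transform is idempotent only when nothing was clipped. A per-core
z-scoring mode exists behind a flag for sensitivity analysis; the default
is global, and all downstream defaults assume it.

## Activation scoring (`tilquant.activation`)

Two activation markers (CD69, OX40) and two exhaustion markers (TIM3,
LAG3) are measured on CD8+ cells. PCA of the n×4 z-score matrix typically
produces a first component on which all four markers load with one sign —
a common-mode "overall staining" axis driven by cell-to-cell brightness
variation — so the functional contrast lives in the PC2–PC3 plane. If PC1
is *not* common-mode the model falls back, with a warning, to the
component pair that maximises the CD69–TIM3 angle.

In the retained plane, the CD69 loading direction is the activation
anchor (score +1) and the TIM3 loading direction the exhaustion anchor
(score −1). The loading direction is exactly the plane direction along
which the reconstructed marker value grows fastest, i.e. "the point where
the projected value of the marker is maximal" per unit distance. LAG3 and
OX40 shape the fit but do not define anchors: LAG3's loading is not
aligned with TIM3's and few cells express it, so it contributes little to
the exhaustion end.

A cell's score depends only on the *direction* of its centred projection
(centroid of the training projections = origin; a cell exactly there
scores 0). With φ_a and φ_e the angles between the cell direction and the
two anchors, and Δ the anchor separation angle, the score is

    score = (φ_e − φ_a) / Δ .

Along the shorter arc this is linear in angle (+1 at the activation
anchor, −1 at the exhaustion anchor, 0 on the bisector), and by the
triangle inequality for angles it is bounded in [−1, 1] everywhere, so no
discontinuous clamping occurs; a cell "beyond" an anchor saturates at
±1 smoothly. An alternative `projection` strategy (signed projection on
the anchor-difference axis) is available as a switch. Angles are computed
with atan2 rather than arccos: arccos loses half the floating-point
digits near 0 and π, exactly where the anchors sit.

Sign indeterminacy of the PCA is resolved by flipping the first retained
component so CD69 loads positively and the second so TIM3 loads
non-negatively; scores are invariant to this convention, it only makes
refits byte-reproducible.

## Status classification (`tilquant.status`)

A unit (core, or patient with all cores pooled) is compared against the
background distribution of all scored cells — the unit's own cells
included — with two one-tailed two-sample t-tests (Welch by default;
pooled-variance behind a flag): unit mean greater (Active side) and
smaller (Exhausted side). Raw p-values are collected across all units and
adjusted with Benjamini–Hochberg FDR, separately per side by default
(a joint-family mode exists; the per-side default reflects that the two
one-sided families answer different questions). A unit is Active if its
adjusted Active-side p < α (default 0.001), Exhausted if the other side
is, Transition otherwise. The two sides cannot both be significant for
one-tailed tests on the same mean, but the case is guarded (Transition
with a warning). Units with fewer than 2 cells are excluded and logged.

Robustness resampling reclassifies a patient from subsamples drawn
without replacement (sizes 10…1000 step 10, 100 replicates each, capped
at the patient's cell count) against the full background, and reports the
smallest size reaching 95% agreement with the full-data label
(`min_n_95`).

For survival, each patient is summarised by the mean activation of its
cells and dichotomized: Active if the mean is strictly positive,
Exhausted otherwise (a mean of exactly 0 is Exhausted). Kaplan–Meier
curves and the log-rank test come from `lifelines`.

## Consensus phenotyping (`tilquant.phenotyping`)

Three independent clusterings over the phenotypic-marker z-scores:

* **K-means** — K fixed, or chosen by silhouette over a range (default
  10–30 for cohort-scale data).
* **PhenoGraph-style graph communities** — kNN graph (default k = 30),
  Jaccard edge weights from shared-neighbour overlap, Leiden modularity
  optimisation (`python-igraph` + `leidenalg`). For small datasets k must
  be on the order of the smallest subpopulation, else modularity
  over-splits; the tests use k ≈ cluster size on 100-point blobs.
* **ClusterX-style density peaks** — local density (Gaussian kernel at
  the 2% pairwise-distance quantile) and distance-to-nearest-denser-point,
  with automatic centre selection by γ = ρ·δ outliers and assignment by
  descending-density inheritance. As in common cytometry practice the
  density clustering runs on a 2-D UMAP embedding by default (density is
  not meaningful in raw 25-dimensional marker space); a raw-space mode
  exists.

Each method's clusters are summarised by their per-marker mean z and
annotated through an explicit, ordered marker rulebook (shipped as YAML:
Tcy = CD3+CD8+, Treg = CD3+CD4+FOXP3+, Melanoma = S100AB/MelanA, …). A
rule fires when its "high" markers exceed +0.5 mean z and its "low"
markers fall below −0.1. Two deliberate refinements to the thresholds:
markers whose positive population is small (FOXP3; the functional markers
CD69/OX40/LAG3/TIM3) have z ≈ 0, not negative, in cells that do not
express them — the global z-scale is compressed by low prevalence — so
"low/absent" requirements on such markers use per-rule overrides
(0.2–0.3, meaning "not elevated"). Clusters matching no rule are
`unassigned`.

A cell keeps a phenotype only when at least two of the three methods
agree on its annotated label (`unassigned` never wins); otherwise it is
`discarded`. The inclusion fraction is reported. Functional subpopulations
are then found per phenotype by the graph clustering over the functional
markers (Tcy cells use a personalised CD8/CD69/OX40/LAG3/TIM3/PD-1/Ki-67
panel), annotated by a functional rulebook (active / transition /
exhausted / proliferating / anergic, where anergic means no functional
marker elevated).

## Neighborhood analysis (`tilquant.neighborhood`)

Within an image, two cells are neighbours when their centroids are at
most 30 px apart (inclusive; kd-tree construction, verified against the
all-pairs oracle). For an ordered pair (i, j) the statistic is the mean
number of type-j neighbours per type-i cell (a total-count variant is a
flag). The null shuffles the phenotype labels over the fixed positions
(1000 permutations), preserving the point pattern and the composition;
one-sided empirical p-values use the add-one estimator (r+1)/(n+1), so
with α = 0.001 a call requires the observed statistic to beat every
permutation. Calls are +1 (proximity), −1 (avoidance) or 0. Pairs
involving a phenotype absent from an image are not evaluable there and
are excluded from integration for that image. The statistic is
directional; both orderings are computed.

Across images, calls are combined as P_ij = Σ_k c_ijk·N_ijk / Σ_k N_ijk
with N_ijk the geometric mean of the two phenotypes' counts in image k,
and |P| categorized with strict upper bounds: strong > 0.75, moderate
> 0.5, weak > 0.25, else non-significant (|P| = 0.75 exactly is
moderate).

Melanoma grows in packed nests that violate the label-shuffle null, so a
separate descriptive profile counts, per non-melanoma subpopulation, the
number of its cells adjacent to at least one melanoma cell, summed over
the cores where the subpopulation occurs, divided by the geometric mean
of the melanoma and subpopulation totals over those cores. (When one
subpopulation cell touches several melanoma cells it is counted once;
the alternative edge-count reading is within a cell constant on typical
data and the chosen reading matches "number of cells … in their
neighborhood".)

## Cohort statistics (`tilquant.cohort_stats`)

Each core is represented by the mean activation of its CD8+ cells (sd =
intra-core heterogeneity). Two-level histopathological factors use a
two-sample pooled-sd t-test; multi-level factors use all pairwise
pooled-sd t-tests with Holm adjustment; continuous covariates (Breslow,
lymphocyte counts) use the linear-model slope test. Composition
differences across core groups use Wilcoxon rank-sum (2 groups) or
Kruskal–Wallis (≥3), flagged at p < 0.05; constant compositions return
p = 1 with a warning.

The qPCR rule for micro-dissected TIL samples: `active` iff
log(IFNg/CD45) > 0; `exhausted` iff LAG3 and/or TIM3 are expressed while
IFNg and CD40L are not (expression floor configurable, default 0; the
CD45 ratio is computed exactly as stated, with no extra reference-gene
normalization, since none is specified for the ratio).

## RNA deconvolution utilities (`tilquant.deconvolution`)

Single cells are assigned to immune types by Spearman correlation against
signature profiles (LM22 layout) over the shared genes; each cell takes
its best-correlating type unless the maximum correlation is below 0.25,
in which case it is unassigned. Spearman works on ranks, so the
assignment is provably invariant to monotone transforms of a cell's
expression (asserted by test). CD8 cells can then be scored with the
activation model applied to the transcripts of the four markers (the
six-gene default list, with OX40 = TNFRSF4 and TIM3 = HAVCR2 plus their
ligand transcripts, is an explicitly non-authoritative best guess — pass
your own), split at score 0 (0 itself is Exhausted), and averaged into
`T.cells.CD8.Active` / `T.cells.CD8.Exhausted` profiles for bulk
deconvolution by an external tool. Patient labels from deconvolved
fractions: Active iff the Active fraction ≥ the Exhausted fraction.
Support-vector deconvolution itself (Cibersort) is not reimplemented.

## Synthetic cohorts (`tilquant.synthetic`)

The generator emulates exactly the structure the pipeline assumes:

* **Marker intensities.** Every marker has baseline intensity 1.0;
  lineage-defining markers sit at 8.0; values carry multiplicative
  log-normal noise (σ = 0.4) — MFIs are non-negative and right-skewed —
  and each cell multiplies *all* its markers by a common log-normal
  staining/size factor. The factor's default σ = 0.8 is set so that the
  default cohort reproduces the common-mode PC1 of real MFI data on the
  four scored markers; it is also the main realism knob, because strong
  brightness variation smears cluster mean z-scores exactly as it does in
  tissue. "Well-separated" fixtures use σ ≈ 0.15–0.25.
* **Planted activation.** Tcy cells get a functional class per core
  according to the core's planted status mix (Active cores: 70% active
  cells; Exhausted cores: 70% exhausted; Transition: 55% transition),
  with class-specific CD69/OX40/LAG3/TIM3 means (active = high CD69/OX40,
  exhausted = high TIM3 with moderate LAG3, transition intermediate,
  anergic all baseline).
* **Space.** Uniform (CSR) placement, with planted pairwise attraction
  (satellite placement within a radius) or avoidance (bounded rejection
  sampling), giving closed-form CSR oracles for the neighborhood module.
* **Clinical.** Exponential overall-survival times whose scale depends on
  the planted patient status, censored at a fixed horizon.

Default scale mirrors a TMA study (29 patients, 1–4 cores each,
3000–5000 cells/core); tests and the acceptance script use reduced
profiles (10–60 cores, ≤1200 cells/core) to stay at desk scale. Not
emulated: segmentation errors, spatial marker gradients within a core,
spillover between channels, batch effects across staining rounds — so
passing tests demonstrate correctness of the statistical machinery on
data satisfying its assumptions, not robustness to those artefacts.

## Numerical and design notes

* All randomness flows through `numpy.random.Generator` seeds or
  `SeedSequence.spawn`; fixed seeds give byte-identical outputs.
* Zero-variance markers fail loudly by name rather than producing NaN
  z-scores; duplicate coordinates in an image warn but are allowed.
* BH/Holm adjustments come from `statsmodels`; survival from
  `lifelines`; all rank tests from `scipy.stats` — each is checked
  against hand-computed textbook values on tiny fixtures.
* The acceptance script (`scripts/acceptance.py`) reruns the whole
  pipeline at the reduced profiles above; on one CPU it takes ~1.5 min.

## Known limitations

* The activation gradient's exact interpolation in the original method is
  not published in detail; the linear-in-angle map is the package's own
  choice (with the projection alternative switchable) and reproduces the
  stated anchor/centroid geometry.
* Cluster annotation is threshold-based; on cohorts with strong brightness
  confounding (default σ = 0.8) a substantial fraction of cells is
  honestly discarded by the consensus, as happens on real tissue.
* The melanoma contact profile is descriptive, not a significance test.
* Patient-level "planted status" for mixed-core patients is defined by
  core majority (ties → Transition); other conventions are defensible.
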