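# Methods

## Scope and data model

The package analyses segmented, cell-resolution spatial omics cohorts:
per-cell centroids in microns, a categorical cell-type label, image and
patient keys, and a cell × marker intensity matrix. Coordinates live in a
per-image Cartesian frame with arbitrary origin; only intra-image
distances are ever computed, so no cross-image registration is attempted.
Expression is consumed exactly as the upstream quantification provides it
— no internal normalisation — because the regression model below is
defined on the raw intensity scale. An optional arcsinh transform is
exposed (`CellDataset.transformed`) but off by default.

## Proximity metrics

Two per-cell measures quantify proximity to each cell type B within an
image:

* abundance `n_iB(r)`: the count of B cells whose centroid lies within
  `r` µm of cell i (default r = 200);
* distance `d_iB(r)`: the Euclidean centroid distance to the nearest B
  cell, ceiling-capped at `cap` µm (default 200) to limit the leverage of
  isolated cells.

A cell is never its own neighbour (otherwise every self-pair would
trivially report d = 0, n ≥ 1). A cell with no B neighbour within the
search radius is assigned the cap rather than dropped, which keeps it in
the regression; when an image contains no other B cell at all, the
distance is undefined and the entry is masked invalid (abundance is
simply 0). Both metrics are computed per image with a k-d tree and are
checked entrywise against quadratic-time all-pairs oracles in the test
suite. No edge correction is applied; with a capped nearest-neighbour
metric, boundary effects only compress the upper range of the metric.

## Per-image regression and cohort testing

For each (image, A, B, marker) combination, marker expression over the
type-A cells is regressed on the metric by OLS. Because every marker of a
given (image, A, B) triple shares the same design matrix, the solve is
vectorised across markers (pseudo-inverse of the normal equations; the
test suite verifies agreement with an independent OLS implementation to
1e-8). Conventions and edge cases:

* fits with fewer than 100 valid type-A cells are excluded (the
  `min_cells` gate, configurable);
* a metric that is constant — exactly, or to within a relative tolerance
  of 1e-9, which catches nearest-neighbour distances that are equal up to
  floating-point rounding — marks the fit *degenerate*: the slope is not
  estimable and 0 would be a fabricated estimate, so the fit is recorded
  with beta = NaN and skipped by aggregation;
* with the distance metric, a marker that **rises** near B has a
  **negative** slope; the result tables record the metric kind so signs
  stay interpretable.

Image-level slopes are averaged per patient (unweighted; an
n-cells-weighted mean is available behind a flag) and each relationship
is tested with a two-sided one-sample t-test of the patient means against
zero. Testing patient means rather than pooled image slopes respects the
cohort's unit of independence; an image-level mode exists behind a flag.
Relationships observed in fewer than two patients, or with zero variance
across patients, are reported with p = NA and flagged rather than
silently dropped. The Bonferroni denominator is the number of
relationships actually tested (recorded as `n_tests`), not the
theoretical grid.

## Purity scores and spillover correction

Lateral spillover — marker signal from one cell mis-assigned to an
adjacent cell by imperfect segmentation — manufactures artefactual
proximity–expression associations. The correction estimates, for every
cell, the probability of belonging to each cell type from its marker
profile, using a random forest trained on all cells pooled across images
(default 500 trees, fixed seed, recorded in the score metadata). The
forest uses a minimum leaf size of 10, the probability-forest convention:
fully grown trees assign saturated 0/1 probabilities to training cells,
and a saturated score carries no contamination signal. Predictions are
in-sample by default; out-of-bag votes are available and are the less
optimistic choice when scoring the training cohort itself.

The corrected model adds the purity columns as covariates. Since the
probabilities sum to one, the block is collinear with the intercept; the
focal type A's own column is dropped before fitting, which restores full
rank with no change to the fitted subspace. When the purity columns are
constant the corrected slope equals the uncorrected slope exactly (tested).

Evaluation uses cell-type-specific markers as internal negative controls:
a B-specific marker surfacing as a CCM inside a different type A is
labelled a false positive, cell-state-marker relationships count as
(potential) true positives, and a relationship of a type marker within
its own owner type is excluded from false-positive counting because the
marker is legitimately expressed there. Walking the p-value-ranked list
(ties broken by |t| descending, then lexicographically, so curves are
deterministic) until a fixed number of false positives accrues yields the
partial ROC summary `tp_at_fp_cutoff`.

## Survival analysis

Per-relationship, per-image slope t-statistics are summarised per patient
by their mean (the raw-coefficient variant is available behind a flag).
Image contributions with fewer than 20 cells are dropped first;
relationships missing in more than 5% of patients are removed; residual
missingness is column-mean imputed and flagged. Each retained column is
screened with a univariate Cox proportional-hazards fit
(partial likelihood via lifelines); non-convergent columns (monotone
separation) and constant columns are flagged with p = NA. Bonferroni
correction runs over the columns actually tested.

Survival random forests (log-rank splitting, 500 trees by default,
minimum leaf 3) are evaluated by repeated k-fold cross-validation
(default 20 repeats × 3 folds). Inside each training fold the candidate
columns are ranked by the univariate Cox **score test** — the score
statistic at beta = 0 needs only risk-set means and variances, so all
columns are screened with a few cumulative sums while preserving the
significance ordering of per-column partial-likelihood fits — and the top
k (default 10) feed the forest. Feature selection never sees the held-out
patients; a deliberately leaky mode (`_select_on_all`) exists only to
demonstrate selection bias in the tests. Held-out predictions are scored
with Harrell's concordance index: the fraction of comparable pairs
(shorter observed survival is an event) in which the shorter-lived
patient carries the higher predicted risk, ties in risk counting 1/2.
Each (repeat, fold) forest seed derives deterministically from the master
seed.

## Synthetic cohorts

The generator emulates a multi-patient multiplexed-imaging cohort. Cells
are uniform over a square field; types are multinomial; expression is a
type baseline plus Gaussian noise, clipped at zero to respect intensity
semantics. Three mechanisms switch on independently so each pipeline
stage has an isolating fixture.

**Default study conditions.** Four cell types (tumour 40%, macrophage
25%, T cell 20%, stroma 15%); a panel of three defining markers per type
(baseline 5.0 in the owner type, 1.0 background) plus six shared state
markers (baselines 3.5–6.5, varying by type); noise sd 1.5; 800 cells per
1500 × 1500 µm image. Two aspects of this geometry matter and were chosen
deliberately:

* *Panel width.* Contamination moves all of a donor type's defining
  markers coherently, which is what lets a classifier recognise it; a
  one-marker-per-type panel confounds contamination with single-marker
  noise.
* *Field density vs. metric range.* The field is sparse enough that the
  nearest-neighbour distance metric spans tens to hundreds of microns
  while spillover (exponential kernel, e-folding length 12 µm, leak
  fraction 0.8 at zero distance, pairs beyond 8 decay lengths skipped)
  acts only at cell-contact range. This mirrors real cohorts, where
  images span millimetres but segmentation errors act at the cell scale.
  In this regime the purity covariates can absorb the contact-driven
  component of a distance slope. When the whole metric range is
  contact-scale (a dense field), distance itself is as good a
  contamination proxy as purity, and correction cannot separate the two —
  a regime the package's own simulations document (see Limitations).

Planted effects add `beta_true` times the **capped** metric to one
marker in one cell type, so truth and estimator share a scale. The
recovery studies plant CD163 in macrophages rising at 0.05 per µm of
distance from tumour cells — the marker falls as macrophages approach
tumours, and the estimated slope is positive against distance.

Survival times are exponential with hazard `exp(log_hazard · z_i) /
baseline_scale` for a latent standard-normal patient risk `z_i`
(baseline scale 365 days). Censoring is independent uniform; the upper
bound of the censoring distribution is solved numerically per patient so
the expected censoring fraction matches the configuration exactly.
Planted slope sizes can be coupled to `z_i` so that a relationship's
statistics genuinely carry prognostic signal.

**What the generator does not emulate:** tissue architecture (glands,
niches, spatial clustering of types), patient-level heterogeneity in
staining or segmentation quality, cell-shape or boundary geometry,
count-like or zero-inflated intensity distributions beyond the clip at
zero, and correlated marker noise. Passing tests therefore demonstrate
the statistical machinery under a controlled data-generating process, not
performance on any particular real dataset.

## Simulation studies and problem sizes

The reproduction script and acceptance tests run these studies:

* effect recovery — 10 patients × 3 images × 800 cells, planted slope
  0.05; the estimate is compared with truth across seeds and the planted
  triple must out-rank all state-marker relationships;
* global null — 50 cohorts of 6 patients × 2 images × 600 cells; the
  pooled fraction of Bonferroni-significant relationships and the
  family-wise any-discovery rate are reported (the latter judged by
  binomial consistency with the nominal 5% level, since 50 cohorts give
  a noisy point estimate);
* spillover contamination — 6 patients × 2 images × 800 cells, spillover
  only; corrected vs uncorrected models are compared on significant
  false-positive counts and `tp_at_fp_cutoff` at a cutoff of 30 (scaled
  to this grid of 288 relationships; simulation forests use 150 trees);
* survival — 100 patients with a hazard-linked feature among 14 noise
  columns for Cox screening; 60 patients for cross-validated forests and
  their permuted-survival null.

## Limitations

* OLS on raw intensities inherits the usual caveats: zero-inflation and
  heteroscedasticity make per-cell p-values approximate; the cohort-level
  inference rests on the cross-patient t-test, not the per-image fits.
* Purity correction is partial. The forest's probabilities are a
  nonlinear, imperfect proxy for contamination, and because they are
  row-stochastic they encode neighbourhood *composition* but not total
  contaminated *amount*. In dense fields, or for relationships between a
  type and a third bystander type, correction can leave — and
  occasionally slightly amplify — residual artefactual associations.
  Cell-type markers should stay in every panel as internal controls.
* The cross-patient t-test is extremely powerful for effects that are
  consistent across patients; with realistic cohort sizes nearly any
  systematic artefact reaches significance. Effect sizes (mean
  coefficients) should always be read alongside p-values.
* Survival feature screening is univariate; correlated relationships are
  ranked, not jointly modelled.
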