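# spatialccm

Detection of **cell–cell–marker (CCM) relationships** in segmented,
cell-resolution spatial omics data (CODEX, MIBI-TOF, Xenium and similar
platforms): changes in a cell type's marker expression that are associated
with its spatial proximity to another cell type. The package is aimed at
analysts of multiplexed imaging cohorts who want to ask, across many images
and patients, *"does marker m on cell type A change when A is near cell
type B — and does that relationship matter for patient outcome?"*

## The model

For each image, each ordered cell-type pair (A, B) and each marker m, an
ordinary-least-squares model is fitted over the type-A cells i:

```
E_im = mu_mA + beta_mAB * d_iB(r) + eps_imB        (distance metric)
E_im = mu_mA + beta_mAB * n_iB(r) + eps_imB        (abundance metric)
```

where `d_iB(r)` is the Euclidean distance from cell i to the nearest
type-B cell, ceiling-capped at 200 µm, and `n_iB(r)` is the number of
type-B cells within an `r` = 200 µm radius. Fits with fewer than 100
type-A cells are excluded. Image-level slopes are averaged per patient and
each (A, B, m) relationship is tested with a two-sided one-sample t-test
of the patient means against zero, Bonferroni-corrected.

Two downstream layers build on these fits:

* **Lateral-spillover correction.** Imperfect segmentation leaks marker
  signal between adjacent cells and manufactures artefactual CCMs (a
  B-specific marker "appearing" in A cells near B). A random forest
  trained to predict each cell's type from its marker profile yields
  per-cell purity scores `p_it`; adding them as covariates absorbs
  contamination-driven expression variance. Cell-type-specific markers act
  as internal negative controls, and a partial ROC (cell-state
  relationships accumulated before a fixed number of cell-type-marker
  false positives) quantifies the benefit.
* **Survival modelling.** Per-relationship slope t-statistics are
  summarised per patient (dropping per-image contributions under 20 cells
  and relationships missing in more than 5% of patients), then screened
  with univariate Cox proportional-hazards models, `h_i(t) = h_0(t)
  exp(beta x_i)`, and fed to survival random forests evaluated by repeated
  3-fold cross-validation with Harrell's concordance index.

A fully parameterised synthetic-cohort generator (known planted effects,
controllable spillover, survival linked to a latent patient risk) makes
every stage testable without any external download.

## Worked example

```python
import spatialccm as sc

cfg = sc.SyntheticConfig(
    n_patients=6, images_per_patient=2, cells_per_image=800,
    planted_ccms=[sc.PlantedCCM("macrophage", "tumour", "CD163", 0.05)],
    seed=42)
dataset, truth = sc.generate_cohort(cfg)

prox = sc.compute_proximity(dataset, "distance", r=200, cap=200)
fits = sc.fit_all(dataset, prox, min_cells=100)
results = sc.aggregate_and_test(fits)
print(results.sort_values("p_adjusted").head(3)[
    ["cell_type_A", "cell_type_B", "marker", "mean_coef",
     "t_stat", "p_adjusted", "n_patients"]].to_string(index=False))
```

```
cell_type_A cell_type_B    marker  mean_coef    t_stat  p_adjusted  n_patients
 macrophage      tumour     CD163   0.050011 31.893791    0.000164           6
     tumour      tumour GranzymeB   0.000788  0.961788    1.000000           6
     tumour      tumour     HLADR   0.000991  1.227068    1.000000           6
```

The cohort was generated with one genuine relationship — CD163 on
macrophages rising by 0.05 intensity units per micron of distance from the
nearest tumour cell (i.e. CD163 is *suppressed* near tumours). The top row
recovers that slope (`mean_coef` 0.0500), it is the only relationship that
survives Bonferroni correction, and every other entry is flat noise. With
the distance metric, a positive slope means the marker falls as the cells
get closer.

The same chain is available from the shell:

```sh
spatialccm simulate --out-dir demo --planted-beta 0.05 --seed 42
spatialccm ccm --cells demo/cells.csv --expression demo/expression.csv \
    --out demo/results.csv --no-correct
spatialccm run-all --out-dir demo_run --seed 42   # full pipeline + manifest
```

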