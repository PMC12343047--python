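"""Per-image linear models of marker expression against spatial proximity.

For every (image, cell type A, cell type B, marker m) combination an
ordinary-least-squares model is fitted over the type-A cells i of that
image:

    E_im = mu_mA + beta_mAB * d_iB(r) + eps          (distance metric)
    E_im = mu_mA + beta_mAB * n_iB(r) + eps          (abundance metric)

where d/n is the capped nearest-distance or abundance metric. The slope
beta_mAB measures how marker m changes in A cells as proximity to B
changes; with the distance metric a marker that *rises* near B has a
*negative* slope. When purity scores are supplied the model gains the
cell-type probability covariates p_{i,t}, which absorb expression variance
attributable to lateral spillover rather than genuine state change. The
purity columns sum to one and would be collinear with the intercept, so
the focal type A's own column is dropped before fitting.

Fits with fewer than ``min_cells`` type-A cells (default 100) are excluded,
as are degenerate fits whose metric has zero variance. Image-level slopes
are averaged per patient, and each (A, B, marker) relationship is tested
with a two-sided one-sample t-test of the patient means against zero,
Bonferroni-corrected over the number of relationships actually tested.

All markers of a given (image, A, B) fit share the same design matrix, so
the least-squares solve is vectorised across markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import PurityScores
from .io_data import CellDataset
from .spatial_metrics import ProximityMatrix

DEFAULT_MIN_CELLS = 100

FIT_COLUMNS = [
    "image_id",
    "patient_id",
    "cell_type_A",
    "cell_type_B",
    "marker",
    "metric",
    "beta",
    "intercept",
    "t_stat",
    "n_cells",
    "corrected",
    "degenerate",
]


@dataclass
class CCMFit:
    """A single per-image fit for one (A, B, marker) combination."""

    image_id: str
    patient_id: str
    cell_type_A: str
    cell_type_B: str
    marker: str
    metric: str
    beta: float
    intercept: float
    t_stat: float
    n_cells: int
    corrected: bool
    degenerate: bool = False


def _is_degenerate(x: np.ndarray) -> bool:
    """Metric carries no usable variation (exactly or numerically constant)."""
    return bool(np.ptp(x) <= 1e-9 * max(1.0, float(np.abs(x).max())))


def _design_matrix(
    x: np.ndarray,
    purity_block: np.ndarray | None,
) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if purity_block is not None:
        cols.extend(purity_block.T)
    return np.column_stack(cols)


def _ols_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each column of Y on the shared design X.

    Returns (coef matrix p x m, slope standard errors, slope t statistics).
    Uses the pseudo-inverse so near-collinear purity blocks (e.g. a type
    absent from one image giving an all-zero column) stay solvable.
    """
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    coef = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coef
    dof = max(n - p, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    var_slope = sigma2 * XtX_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_slope)
        t = np.where(se > 0, coef[1] / se, np.nan)
    return coef, se, t


def _purity_block(
    purity: PurityScores | None, cell_ids: np.ndarray, focal_type: str
) -> np.ndarray | None:
    if purity is None:
        return None
    cols = [c for c in purity.cell_types if c != focal_type]
    return purity.probabilities.loc[cell_ids, cols].to_numpy()


def fit_image_ccm(
    image_cells: pd.DataFrame,
    image_expression: pd.DataFrame,
    cell_type_A: str,
    cell_type_B: str,
    marker: str,
    proximity: ProximityMatrix,
    purity: PurityScores | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> CCMFit | None:
    """Fit one (A, B, marker) model in one image; None when excluded.

    The regression sample is the set of type-A cells with a valid metric
    entry for B; below ``min_cells`` the fit is excluded. A zero-variance
    metric yields a degenerate fit (beta undefined) that aggregation skips.
    """
    a_mask = (image_cells["cell_type"] == cell_type_A).to_numpy()
    ids = image_cells.loc[a_mask, "cell_id"].to_numpy()
    x = proximity.values.loc[ids, cell_type_B].to_numpy()
    ok = proximity.valid.loc[ids, cell_type_B].to_numpy()
    ids, x = ids[ok], x[ok]
    if len(ids) < min_cells:
        return None
    y = image_expression.loc[a_mask].loc[ok, marker].to_numpy()
    common = dict(
        image_id=str(image_cells["image_id"].iloc[0]),
        patient_id=str(image_cells["patient_id"].iloc[0]),
        cell_type_A=cell_type_A,
        cell_type_B=cell_type_B,
        marker=marker,
        metric=proximity.metric_kind,
        n_cells=len(ids),
        corrected=purity is not None,
    )
    if _is_degenerate(x):
        return CCMFit(beta=np.nan, intercept=np.nan, t_stat=np.nan,
                      degenerate=True, **common)
    X = _design_matrix(x, _purity_block(purity, ids, cell_type_A))
    coef, _, t = _ols_multi(X, y[:, None])
    return CCMFit(beta=float(coef[1, 0]), intercept=float(coef[0, 0]),
                  t_stat=float(t[0]), **common)


def fit_all(
    dataset: CellDataset,
    proximity: ProximityMatrix,
    purity: PurityScores | None = None,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Fit every (image, A, B, marker) model and return the fit table.

    A = B pairs are fitted too, using the self-excluded metric. Markers are
    solved jointly per (image, A, B) since they share the design matrix.
    """
    types = dataset.cell_types
    markers = dataset.markers
    rows: list[dict] = []
    for image_id in dataset.image_ids:
        cells_img, expr_img = dataset.image_view(image_id)
        patient_id = str(cells_img["patient_id"].iloc[0])
        for a in types:
            a_mask = (cells_img["cell_type"] == a).to_numpy()
            if not a_mask.any():
                continue
            ids_a = cells_img.loc[a_mask, "cell_id"].to_numpy()
            Y_full = expr_img.loc[a_mask].to_numpy()
            for b in types:
                x = proximity.values.loc[ids_a, b].to_numpy()
                ok = proximity.valid.loc[ids_a, b].to_numpy()
                n = int(ok.sum())
                if n < min_cells:
                    continue
                xb, ids = x[ok], ids_a[ok]
                common = dict(
                    image_id=image_id,
                    patient_id=patient_id,
                    cell_type_A=a,
                    cell_type_B=b,
                    metric=proximity.metric_kind,
                    n_cells=n,
                    corrected=purity is not None,
                )
                if _is_degenerate(xb):
                    for m in markers:
                        rows.append(dict(marker=m, beta=np.nan, intercept=np.nan,
                                         t_stat=np.nan, degenerate=True, **common))
                    continue
                X = _design_matrix(xb, _purity_block(purity, ids, a))
                coef, _, t = _ols_multi(X, Y_full[ok])
                for k, m in enumerate(markers):
                    rows.append(dict(marker=m, beta=float(coef[1, k]),
                                     intercept=float(coef[0, k]),
                                     t_stat=float(t[k]), degenerate=False,
                                     **common))
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def aggregate_and_test(
    fits: pd.DataFrame,
    patient_weighting: str = "unweighted",
    test_level: str = "patient",
) -> pd.DataFrame:
    """Aggregate image-level slopes and test each relationship cohort-wide.

    Image slopes are averaged per patient (unweighted by default; set
    ``patient_weighting='n_cells'`` for a cell-count-weighted mean). Each
    (A, B, marker, metric) relationship with at least two contributing
    patients gets a two-sided one-sample t-test of the patient-mean slopes
    against zero; p-values are Bonferroni-adjusted over the number of
    relationships actually tested (recorded in ``attrs['n_tests']``).
    Relationships with fewer than two patients or zero variance across
    patients are reported with p = NA and flagged.

    ``test_level='image'`` runs the t-test over image-level slopes instead
    of patient means (not the default aggregation).
    """
    if patient_weighting not in ("unweighted", "n_cells"):
        raise ValueError(f"unknown patient_weighting {patient_weighting!r}")
    if test_level not in ("patient", "image"):
        raise ValueError(f"unknown test_level {test_level!r}")
    usable = fits.loc[~fits["degenerate"] & np.isfinite(fits["beta"])]
    out = []
    for (a, b, m, metric), grp in usable.groupby(
        ["cell_type_A", "cell_type_B", "marker", "metric"], sort=True
    ):
        if test_level == "patient":
            if patient_weighting == "n_cells":
                samples = grp.groupby("patient_id").apply(
                    lambda g: np.average(g["beta"], weights=g["n_cells"]),
                    include_groups=False,
                ).to_numpy()
            else:
                samples = grp.groupby("patient_id")["beta"].mean().to_numpy()
        else:
            samples = grp["beta"].to_numpy()
        n_pat = grp["patient_id"].nunique()
        mean_coef = float(np.mean(samples))
        flag = ""
        if len(samples) < 2 or n_pat < 2:
            t_val, p_val, flag = np.nan, np.nan, "single_patient"
        elif np.ptp(samples) == 0:
            t_val, p_val, flag = np.nan, np.nan, "zero_variance"
        else:
            t_val, p_val = stats.ttest_1samp(samples, 0.0)
        out.append(dict(
            cell_type_A=a, cell_type_B=b, marker=m, metric=metric,
            mean_coef=mean_coef, t_stat=t_val, p_value=p_val,
            n_patients=int(n_pat), flag=flag,
        ))
    results = pd.DataFrame(out)
    if len(results):
        tested = results["p_value"].notna()
        n_tests = int(tested.sum())
        results["p_adjusted"] = np.minimum(results["p_value"] * n_tests, 1.0)
    else:
        n_tests = 0
        results["p_adjusted"] = pd.Series(dtype=float)
    results.attrs["n_tests"] = n_tests
    cols = ["cell_type_A", "cell_type_B", "marker", "metric", "mean_coef",
            "t_stat", "p_value", "p_adjusted", "n_patients", "flag"]
    return results[cols] if len(results) else pd.DataFrame(columns=cols)
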