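import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from spatialccm import synthetic_data as synth
from spatialccm.ccm_regression import aggregate_and_test, fit_all, fit_image_ccm
from spatialccm.deconvolution import PurityScores
from spatialccm.spatial_metrics import compute_proximity

from conftest import make_dataset


def _line_dataset(n, slope=2.0, intercept=1.0, noise=0.0, seed=0):
    """n A cells on a line with one B cell at the origin."""
    rng = np.random.default_rng(seed)
    xs = np.linspace(5, 150, n)
    coords = [[0.0, 0.0]] + [[x, 0.0] for x in xs]
    types = ["B"] + ["A"] * n
    e = intercept + slope * xs + rng.normal(0, noise, n)
    expr = np.concatenate([[0.0], e])[:, None]
    return make_dataset(coords, types, expr, markers=["mk"])


class TestFitImageCCM:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        ds = _line_dataset(150)
        prox = compute_proximity(ds, "distance", r=200, cap=200)
        fit = fit_image_ccm(ds.cells, ds.expression, "A", "B", "mk",
                            prox, min_cells=100)
        assert fit.beta == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_below_min_cells_excluded(self):
        ds = _line_dataset(99)
        prox = compute_proximity(ds, "distance", r=200, cap=200)
        assert fit_image_ccm(ds.cells, ds.expression, "A", "B", "mk",
                             prox, min_cells=100) is None

    def test_zero_metric_variance_marked_degenerate(self):
        # all A cells far beyond the search radius -> every distance == cap
        coords = [[0, 0]] + [[500 + i, 800] for i in range(120)]
        types = ["B"] + ["A"] * 120
        ds = make_dataset(coords, types, np.ones((121, 1)), markers=["mk"])
        prox = compute_proximity(ds, "distance", r=200, cap=200)
        fit = fit_image_ccm(ds.cells, ds.expression, "A", "B", "mk",
                            prox, min_cells=100)
        assert fit.degenerate and np.isnan(fit.beta)

    def test_matches_statsmodels_ols(self):
        ds = _line_dataset(500, slope=0.05, noise=1.0, seed=3)
        prox = compute_proximity(ds, "distance", r=200, cap=200)
        fit = fit_image_ccm(ds.cells, ds.expression, "A", "B", "mk",
                            prox, min_cells=100)
        a_mask = ds.cells["cell_type"] == "A"
        x = prox.values.loc[ds.cells.loc[a_mask, "cell_id"], "B"].to_numpy()
        y = ds.expression.loc[a_mask.to_numpy(), "mk"].to_numpy()
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.beta == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.t_stat == pytest.approx(ref.tvalues[1], abs=1e-8)


class TestFitAll:
    def test_fit_count_bookkeeping(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 300, size=(240, 2))
        types = ["A"] * 120 + ["B"] * 120
        expr = rng.gamma(2, 1, size=(240, 2))
        ds = make_dataset(coords, types, expr, markers=["mk1", "mk2"])
        prox = compute_proximity(ds, "distance", r=200, cap=200)
        fits = fit_all(ds, prox, min_cells=100)
        assert len(fits) == 8  # 2 types x 2 types x 2 markers

    def test_purity_constant_columns_leave_beta_unchanged(self):
        ds = _line_dataset(200, slope=0.1, noise=0.5, seed=5)
        prox = compute_proximity(ds, "distance", r=200, cap=200)
        plain = fit_all(ds, prox, min_cells=100)
        const = PurityScores(
            pd.DataFrame(0.5, index=ds.expression.index, columns=["A", "B"]),
            model_meta={})
        corrected = fit_all(ds, prox, purity=const, min_cells=100)
        np.testing.assert_allclose(
            corrected["beta"].to_numpy(), plain["beta"].to_numpy(), atol=1e-10)

    def test_every_fit_matches_normal_equations(self, small_cohort):
        dataset, _, _ = small_cohort
        prox = compute_proximity(dataset, "distance", r=200, cap=200)
        fits = fit_all(dataset, prox, min_cells=50)
        assert len(fits) > 0
        for _, row in fits.sample(30, random_state=1).iterrows():
            cells_img, expr_img = dataset.image_view(row.image_id)
            a = cells_img["cell_type"] == row.cell_type_A
            ids = cells_img.loc[a, "cell_id"]
            x = prox.values.loc[ids, row.cell_type_B].to_numpy()
            ok = prox.valid.loc[ids, row.cell_type_B].to_numpy()
            X = np.column_stack([np.ones(ok.sum()), x[ok]])
            y = expr_img.loc[a.to_numpy(), row.marker].to_numpy()[ok]
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert row.beta == pytest.approx(beta[1], abs=1e-8)


class TestAggregateAndTest:
    @staticmethod
    def _fits_from_betas(betas_by_patient):
        rows = []
        for pat, betas in betas_by_patient.items():
            for k, b in enumerate(betas):
                rows.append(dict(
                    image_id=f"{pat}_i{k}", patient_id=pat, cell_type_A="A",
                    cell_type_B="B", marker="mk", metric="distance", beta=b,
                    intercept=0.0, t_stat=1.0, n_cells=150, corrected=False,
                    degenerate=False))
        return pd.DataFrame(rows)

    def test_zero_variance_across_patients_flagged_na(self):
        fits = self._fits_from_betas({f"p{i}": [1.0] for i in range(4)})
        res = aggregate_and_test(fits)
        assert res["flag"].iloc[0] == "zero_variance"
        assert np.isnan(res["p_value"].iloc[0])

    def test_single_patient_flagged_na(self):
        fits = self._fits_from_betas({"p0": [0.5, 0.7]})
        res = aggregate_and_test(fits)
        assert res["flag"].iloc[0] == "single_patient"

    def test_matches_one_sample_t_oracle(self):
        betas = {"p0": [0.5], "p1": [-0.5], "p2": [0.3], "p3": [-0.3]}
        res = aggregate_and_test(self._fits_from_betas(betas))
        vals = np.array([0.5, -0.5, 0.3, -0.3])
        # textbook one-sample t: mean / (sd / sqrt(n))
        t_ref = vals.mean() / (vals.std(ddof=1) / np.sqrt(4))
        p_ref = 2 * stats.t.sf(abs(t_ref), df=3)
        assert res["t_stat"].iloc[0] == pytest.approx(t_ref)
        assert res["p_value"].iloc[0] == pytest.approx(p_ref)
        assert res["p_adjusted"].iloc[0] == pytest.approx(min(1, p_ref * 1))

    def test_patient_averaging_precedes_test(self):
        # patient means all equal 0.5 -> zero variance despite image spread
        fits = self._fits_from_betas(
            {"p0": [0.4, 0.6], "p1": [0.3, 0.7], "p2": [0.5, 0.5]})
        res = aggregate_and_test(fits)
        assert res["flag"].iloc[0] == "zero_variance"
        assert res["mean_coef"].iloc[0] == pytest.approx(0.5)

    def test_image_level_mode_uses_all_fits(self):
        fits = self._fits_from_betas(
            {"p0": [0.4, 0.6], "p1": [0.3, 0.7], "p2": [0.5, 0.5]})
        res = aggregate_and_test(fits, test_level="image")
        assert np.isfinite(res["p_value"].iloc[0])

    def test_bonferroni_uses_emitted_test_count(self):
        rng = np.random.default_rng(9)
        rows = []
        for m in ("mk1", "mk2", "mk3"):
            for pat in ("p0", "p1", "p2", "p3"):
                rows.append(dict(
                    image_id=f"{pat}_i", patient_id=pat, cell_type_A="A",
                    cell_type_B="B", marker=m, metric="distance",
                    beta=rng.normal(), intercept=0.0, t_stat=0.0, n_cells=150,
                    corrected=False, degenerate=False))
        res = aggregate_and_test(pd.DataFrame(rows))
        assert res.attrs["n_tests"] == 3
        np.testing.assert_allclose(
            res["p_adjusted"], np.minimum(res["p_value"] * 3, 1.0))


class TestSignConvention:
    def test_marker_decreasing_near_target_gives_positive_distance_slope(self):
        # expression rises with distance from B <=> falls with proximity
        ds = _line_dataset(150, slope=0.05, noise=0.2, seed=2)
        prox = compute_proximity(ds, "distance", r=200, cap=200)
        fit = fit_image_ccm(ds.cells, ds.expression, "A", "B", "mk",
                            prox, min_cells=100)
        assert fit.beta > 0
        assert fit.metric == "distance"


class TestParameterRecovery:
    def test_planted_beta_recovered_within_two_se(self):
        cfg = synth.SyntheticConfig(
            n_patients=6, images_per_patient=2, cells_per_image=600,
            planted_ccms=[synth.PlantedCCM(
                "macrophage", "tumour", "CD163", 0.05)],
            seed=21)
        ds, _ = synth.generate_cohort(cfg)
        prox = compute_proximity(ds, "distance", r=200, cap=200)
        fits = fit_all(ds, prox, min_cells=100)
        sel = fits[(fits.cell_type_A == "macrophage")
                   & (fits.cell_type_B == "tumour")
                   & (fits.marker == "CD163")]
        means = sel.groupby("patient_id")["beta"].mean()
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.05) < 2 * se + 1e-12
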