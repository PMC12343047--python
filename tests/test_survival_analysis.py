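import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.utils import concordance_index as lifelines_cindex

from spatialccm import experiments as ex
from spatialccm.io_data import ClinicalTable
from spatialccm.survival_analysis import (
    SurvivalFeatureMatrix,
    build_feature_matrix,
    concordance_index,
    cv_survival_forest,
    univariate_cox,
)


def _fit_rows(patient, image, rel_marker, t_stat, n_cells):
    return dict(image_id=image, patient_id=patient, cell_type_A="A",
                cell_type_B="B", marker=rel_marker, metric="distance",
                beta=0.0, intercept=0.0, t_stat=t_stat, n_cells=n_cells,
                corrected=False, degenerate=False)


class TestBuildFeatureMatrix:
    def test_complete_column_retained_without_imputation(self):
        fits = pd.DataFrame([
            _fit_rows(f"p{i}", f"p{i}_img", "mk", float(i), 50)
            for i in range(5)])
        fm = build_feature_matrix(fits, min_cells_image=20, max_missing=0.05)
        assert fm.features.shape == (5, 1)
        assert not fm.imputed.any().any()

    def test_small_image_contribution_dropped_from_patient_mean(self):
        fits = pd.DataFrame([
            _fit_rows("p0", "i1", "mk", 1.0, 50),
            _fit_rows("p0", "i2", "mk", 99.0, 19),  # below the 20-cell gate
            _fit_rows("p1", "i3", "mk", 3.0, 50),
        ])
        fm = build_feature_matrix(fits)
        assert fm.features.iloc[0, 0] == pytest.approx(1.0)

    def test_column_exceeding_missingness_threshold_dropped(self):
        rows = []
        for i in range(100):
            rows.append(_fit_rows(f"p{i:03d}", f"i{i}", "kept", 1.0, 50))
            if i >= 6:  # absent for 6 patients -> 6% missing
                rows.append(_fit_rows(f"p{i:03d}", f"i{i}", "gappy", 2.0, 50))
        fm = build_feature_matrix(pd.DataFrame(rows), max_missing=0.05)
        assert fm.features.shape[1] == 1
        assert fm.features.columns[0].startswith("kept")
        assert fm.dropped_columns  # the gappy relationship was removed

    def test_residual_missingness_mean_imputed_and_flagged(self):
        rows = []
        for i in range(50):
            rows.append(_fit_rows(f"p{i:03d}", f"i{i}", "kept", float(i), 50))
            if i >= 1:  # 2% missing: below threshold, must be imputed
                rows.append(_fit_rows(f"p{i:03d}", f"i{i}", "nearly", 5.0, 50))
        fm = build_feature_matrix(pd.DataFrame(rows), max_missing=0.05)
        assert fm.features.shape[1] == 2
        assert fm.imputed.to_numpy().sum() == 1

    def test_no_surviving_fits_is_an_error(self):
        fits = pd.DataFrame([_fit_rows("p0", "i0", "mk", 1.0, 5)])
        with pytest.raises(ValueError, match="cell filter"):
            build_feature_matrix(fits)


class TestConcordanceIndex:
    def test_risk_inverse_to_time_scores_one(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(-time, time, np.ones(4)) == 1.0

    def test_constant_risk_scores_half(self):
        time = np.array([1.0, 2.0, 3.0])
        assert concordance_index(np.zeros(3), time, np.ones(3)) == 0.5

    def test_matches_exhaustive_enumeration_with_censoring(self):
        risk = np.array([2.0, 0.5, 1.5, 0.1, 3.0, 1.0])
        time = np.array([10.0, 40.0, 20.0, 50.0, 5.0, 30.0])
        event = np.array([1, 0, 1, 0, 1, 1])
        num = den = 0.0
        for i, j in itertools.permutations(range(6), 2):
            if time[i] > time[j] and event[j] == 1:
                den += 1
                if risk[i] < risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
        assert concordance_index(risk, time, event) == pytest.approx(num / den)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        risk = rng.normal(size=n)
        time = rng.exponential(100, size=n)
        event = rng.integers(0, 2, size=n)
        if event.sum() == 0:
            event[0] = 1
        ours = concordance_index(risk, time, event)
        # lifelines scores "predicted survival time"; negate risk to match
        ref = lifelines_cindex(time, -risk, event)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_flip_symmetry_without_ties(self):
        rng = np.random.default_rng(3)
        risk = rng.normal(size=30)
        time = rng.exponential(10, size=30)
        event = rng.integers(0, 2, size=30)
        event[:5] = 1
        c = concordance_index(risk, time, event)
        assert concordance_index(-risk, time, event) == pytest.approx(1 - c)

    def test_no_comparable_pairs_is_nan(self):
        assert np.isnan(concordance_index(
            np.array([1.0, 2.0]), np.array([5.0, 6.0]), np.array([0, 0])))


def _clinical(times, events):
    return ClinicalTable(pd.DataFrame({
        "patient_id": [f"p{i:03d}" for i in range(len(times))],
        "time": times, "event": events}))


class TestUnivariateCox:
    def test_constant_feature_flagged(self):
        rng = np.random.default_rng(0)
        n = 20
        fm = SurvivalFeatureMatrix(
            features=pd.DataFrame(
                {"flat": np.ones(n), "noise": rng.normal(size=n)},
                index=[f"p{i:03d}" for i in range(n)]),
            imputed=pd.DataFrame(False, index=[f"p{i:03d}" for i in range(n)],
                                 columns=["flat", "noise"]))
        clin = _clinical(rng.exponential(50, n) + 1, np.ones(n, dtype=int))
        res = univariate_cox(fm, clin).set_index("relationship")
        assert res.loc["flat", "flag"] == "constant"
        assert np.isnan(res.loc["flat", "p_value"])

    def test_constructed_separation_ranks_first_with_hr_above_one(self):
        rng = np.random.default_rng(4)
        n = 20
        idx = [f"p{i:03d}" for i in range(n)]
        feature = np.array([1.0] * 10 + [0.0] * 10)
        data = {"risky": feature}
        for j in range(5):
            data[f"noise_{j}"] = rng.normal(size=n)
        fm = SurvivalFeatureMatrix(
            features=pd.DataFrame(data, index=idx),
            imputed=pd.DataFrame(False, index=idx, columns=list(data)))
        # high-feature patients die early (overlapping ranges keep the
        # partial-likelihood maximum finite)
        times = np.concatenate([np.linspace(5, 60, 10),
                                np.linspace(40, 200, 10)])
        clin = _clinical(times, np.ones(n, dtype=int))
        res = univariate_cox(fm, clin)
        best = res.sort_values("p_value").iloc[0]
        assert best["relationship"] == "risky"
        assert best["hazard_ratio"] > 1

    def test_planted_hazard_column_recovered(self):
        hits = [ex.survival_recovery_experiment(s)["planted_is_top"]
                for s in range(3)]
        assert all(hits)


class TestCVSurvivalForest:
    def test_fold_bookkeeping(self):
        rng = np.random.default_rng(1)
        idx = [f"p{i:03d}" for i in range(9)]
        fm = SurvivalFeatureMatrix(
            features=pd.DataFrame({"f": rng.normal(size=9)}, index=idx),
            imputed=pd.DataFrame(False, index=idx, columns=["f"]))
        clin = _clinical(rng.exponential(10, 9) + 1, np.ones(9, dtype=int))
        cv = cv_survival_forest(fm, clin, repeats=1, folds=3, top_k=1,
                                seed=0, n_trees=20)
        assert len(cv.scores) == 3

    def test_oracle_feature_gives_high_concordance(self):
        # steep hazard link: survival order is then mostly determined by
        # the risk score, so a faithful model must score far above chance
        features, clinical, planted = ex.survival_feature_table(
            5, n_patients=60, feature_noise_sd=0.01, log_hazard=4.0,
            censoring_fraction=0.0)
        cv = cv_survival_forest(features, clinical, repeats=2, folds=3,
                                top_k=3, seed=0, n_trees=100)
        assert cv.mean_concordance > 0.8
        assert all(planted in sel for sel in cv.selected)

    def test_selection_leakage_inflates_null_concordance(self):
        # permuted survival: honest CV must hover at 0.5, leaky selection
        # (ranking on the full cohort) must look optimistically better
        rng = np.random.default_rng(2)
        idx = [f"p{i:03d}" for i in range(45)]
        data = {f"n{j:02d}": rng.normal(size=45) for j in range(40)}
        fm = SurvivalFeatureMatrix(
            features=pd.DataFrame(data, index=idx),
            imputed=pd.DataFrame(False, index=idx, columns=list(data)))
        clin = _clinical(rng.exponential(100, 45) + 1,
                         np.ones(45, dtype=int))
        honest = []
        leaky = []
        for seed in range(3):
            honest.append(cv_survival_forest(
                fm, clin, repeats=2, folds=3, top_k=5, seed=seed,
                n_trees=50).mean_concordance)
            leaky.append(cv_survival_forest(
                fm, clin, repeats=2, folds=3, top_k=5, seed=seed,
                n_trees=50, _select_on_all=True).mean_concordance)
        assert np.mean(leaky) > np.mean(honest)
        assert np.mean(honest) == pytest.approx(0.5, abs=0.1)


class TestConcordanceProperties:

    @staticmethod
    def _tables(draw):
        import hypothesis.strategies as st
        n = draw(st.integers(min_value=3, max_value=25))
        risk = draw(st.lists(st.floats(-5, 5, allow_nan=False), min_size=n,
                             max_size=n))
        time = draw(st.lists(st.floats(0.1, 1e3, allow_nan=False), min_size=n,
                             max_size=n))
        event = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        return np.array(risk), np.array(time), np.array(event)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_flip_symmetric(self, data):
        risk, time, event = self._tables(data.draw)
        c = concordance_index(risk, time, event)
        if np.isnan(c):
            return  # no comparable pair
        assert 0.0 <= c <= 1.0
        # flipping the risk ordering mirrors the score around 1/2 whenever
        # no two risk values tie
        if len(np.unique(risk)) == len(risk):
            assert concordance_index(-risk, time, event) == pytest.approx(1 - c)

    @given(st.floats(0.5, 100), st.floats(-1e3, 1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_affine_risk_rescaling(self, scale, shift):
        rng = np.random.default_rng(0)
        risk = rng.normal(size=20)
        time = rng.exponential(50, size=20)
        event = rng.integers(0, 2, size=20)
        event[0] = 1
        c1 = concordance_index(risk, time, event)
        c2 = concordance_index(scale * risk + shift, time, event)
        assert c1 == pytest.approx(c2)
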