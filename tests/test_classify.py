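import numpy as np
import pandas as pd
import pytest

from uripept.classify import (
    ClassifierModel,
    fit_linear_model,
    fit_margin_model,
    log_floor_transform,
    loo_cv,
    time_course_scores,
)
from uripept.core import DataError
from uripept.diffstats import auc


class TestLogFloor:
    def test_zero_maps_to_zero(self):
        assert log_floor_transform(0.0) == 0.0

    def test_below_one_floored(self):
        assert log_floor_transform(0.5) == 0.0

    def test_natural_log_convention(self):
        assert log_floor_transform(np.e) == pytest.approx(1.0)

    def test_negative_raises(self):
        with pytest.raises(DataError):
            log_floor_transform(-1.0)

    def test_vectorized(self):
        np.testing.assert_allclose(
            log_floor_transform([0.0, 1.0, np.e**2]), [0.0, 0.0, 2.0]
        )


def _matrix(case_logmeans, ctrl_logmeans, n_case=10, n_ctrl=10, noise=0.0, seed=0):
    """Panel x samples matrix with exact or noisy per-group log-means."""
    rng = np.random.default_rng(seed)
    k = len(case_logmeans)
    cols = {}
    for j in range(n_ctrl):
        cols[f"ctrl{j}"] = np.exp(ctrl_logmeans + rng.normal(0, noise, k))
    for j in range(n_case):
        cols[f"case{j}"] = np.exp(case_logmeans + rng.normal(0, noise, k))
    idx = pd.RangeIndex(k, name="peptide_id")
    return pd.DataFrame(cols, index=idx)


class TestLinearModel:
    def test_center_and_scale_formula(self):
        matrix = _matrix(np.array([5.0]), np.array([3.0]))
        model = fit_linear_model([0], matrix, [f"case{j}" for j in range(10)],
                                 [f"ctrl{j}" for j in range(10)])
        assert model.params["center"][0] == pytest.approx(4.0)
        assert model.params["scale"][0] == pytest.approx(1.0)

    def test_down_marker_sign_flip(self):
        matrix = _matrix(np.array([3.0]), np.array([5.0]))
        model = fit_linear_model([0], matrix, [f"case{j}" for j in range(10)],
                                 [f"ctrl{j}" for j in range(10)])
        assert model.params["scale"][0] == pytest.approx(-1.0)

    def test_scaled_group_distance_exactly_two(self):
        rng = np.random.default_rng(5)
        k = 12
        matrix = _matrix(rng.uniform(2, 8, k), rng.uniform(2, 8, k),
                         noise=1.0, seed=5)
        case = [f"case{j}" for j in range(10)]
        ctrl = [f"ctrl{j}" for j in range(10)]
        model = fit_linear_model(list(range(k)), matrix, case, ctrl)
        x = log_floor_transform(matrix.loc[model.panel].to_numpy().T)
        w = np.asarray(model.params["scale"])
        m = np.asarray(model.params["center"])
        scaled = (x - m) * w
        dist = scaled[10:].mean(axis=0) - scaled[:10].mean(axis=0)
        np.testing.assert_allclose(dist, 2.0, atol=1e-12)

    def test_control_training_mean_scores_minus_one(self):
        matrix = _matrix(np.array([6.0]), np.array([4.0]), noise=0.5, seed=1)
        case = [f"case{j}" for j in range(10)]
        ctrl = [f"ctrl{j}" for j in range(10)]
        model = fit_linear_model([0], matrix, case, ctrl)
        scores = model.score(matrix)
        assert scores[ctrl].mean() == pytest.approx(-1.0, abs=1e-12)
        assert scores[case].mean() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_marker_dropped_with_warning(self):
        matrix = _matrix(np.array([5.0, 4.0]), np.array([3.0, 4.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_linear_model([0, 1], matrix,
                                     [f"case{j}" for j in range(10)],
                                     [f"ctrl{j}" for j in range(10)])
        assert model.panel == [0]

    def test_all_degenerate_raises(self):
        matrix = _matrix(np.array([4.0]), np.array([4.0]))
        with pytest.warns(UserWarning):
            with pytest.raises(DataError):
                fit_linear_model([0], matrix, [f"case{j}" for j in range(10)],
                                 [f"ctrl{j}" for j in range(10)])

    def test_markerwise_rescaling_invariance(self):
        # consistent per-marker rescaling of raw intensities (keeping
        # values above the floor) shifts log-means but not scores
        rng = np.random.default_rng(9)
        k = 5
        matrix = _matrix(rng.uniform(4, 8, k), rng.uniform(4, 8, k),
                         noise=0.5, seed=9)
        case = [f"case{j}" for j in range(10)]
        ctrl = [f"ctrl{j}" for j in range(10)]
        factors = rng.uniform(1.5, 4.0, k)
        scaled = matrix.mul(factors, axis=0)
        s1 = fit_linear_model(list(range(k)), matrix, case, ctrl).score(matrix)
        s2 = fit_linear_model(list(range(k)), scaled, case, ctrl).score(scaled)
        np.testing.assert_allclose(s1, s2, atol=1e-10)


class TestMarginModel:
    def test_separable_training_auc_one(self):
        matrix = _matrix(np.full(6, 7.0), np.full(6, 3.0), noise=0.3, seed=2)
        case = [f"case{j}" for j in range(10)]
        ctrl = [f"ctrl{j}" for j in range(10)]
        model = fit_margin_model(list(range(6)), matrix, case, ctrl)
        scores = model.score(matrix)
        assert auc(scores[case], scores[ctrl]) == 1.0

    def test_save_load_identical_scores(self, tmp_path):
        matrix = _matrix(np.full(4, 6.0), np.full(4, 4.0), noise=0.5, seed=3)
        case = [f"case{j}" for j in range(10)]
        ctrl = [f"ctrl{j}" for j in range(10)]
        for fit in (fit_margin_model, fit_linear_model):
            model = fit(list(range(4)), matrix, case, ctrl)
            path = tmp_path / f"{model.kind}.json"
            model.to_json(path)
            reloaded = ClassifierModel.from_json(path)
            np.testing.assert_allclose(
                model.score(matrix), reloaded.score(matrix), atol=1e-12
            )

    def test_permuted_labels_loo_auc_near_half(self):
        rng = np.random.default_rng(11)
        aucs = []
        for rep in range(5):
            matrix = _matrix(np.full(6, 5.0), np.full(6, 5.0), noise=1.0,
                             seed=100 + rep)
            ids = [f"ctrl{j}" for j in range(10)] + [f"case{j}" for j in range(10)]
            perm = rng.permutation(ids)
            cv_auc, _ = loo_cv(fit_margin_model, list(range(6)), matrix,
                               list(perm[:10]), list(perm[10:]))
            aucs.append(cv_auc)
        assert 0.3 < np.mean(aucs) < 0.7


class TestLooCv:
    def test_strong_separation_gives_auc_one(self):
        matrix = _matrix(np.full(8, 8.0), np.full(8, 4.0), noise=1.0, seed=4)
        case = [f"case{j}" for j in range(10)]
        ctrl = [f"ctrl{j}" for j in range(10)]
        for fit in (fit_linear_model, fit_margin_model):
            cv_auc, scores = loo_cv(fit, list(range(8)), matrix, case, ctrl)
            assert cv_auc == 1.0
            assert len(scores) == 20

    def test_no_leakage_constants_differ_across_folds(self):
        matrix = _matrix(np.full(3, 7.0), np.full(3, 4.0), noise=1.0, seed=6)
        case = [f"case{j}" for j in range(10)]
        ctrl = [f"ctrl{j}" for j in range(10)]
        m_full = fit_linear_model(list(range(3)), matrix, case, ctrl)
        m_fold = fit_linear_model(list(range(3)), matrix, case[1:], ctrl)
        assert not np.allclose(m_full.params["center"], m_fold.params["center"])

    def test_single_member_class_raises(self):
        matrix = _matrix(np.full(3, 7.0), np.full(3, 4.0), n_case=1)
        with pytest.raises(DataError):
            loo_cv(fit_linear_model, list(range(3)), matrix, ["case0"],
                   [f"ctrl{j}" for j in range(10)])


class TestTimeCourse:
    def test_mean_per_cell_and_ordering(self):
        days = [1.0, 3.0, 44.0]
        doses = [0.0, 150.0, 300.0]
        rng = np.random.default_rng(13)
        rows, cols = [], {}
        for dose in doses:
            for day in days:
                for a in range(3):
                    sid = f"d{dose:g}_{day:g}_{a}"
                    rows.append({"sample_id": sid, "dose_mg_kg": dose, "day": day})
                    eff = (dose / 300.0) * (4.0 if day == 3.0 else 0.0)
                    cols[sid] = np.exp(4.0 + eff + rng.normal(0, 0.2, 4))
        matrix = pd.DataFrame(cols, index=pd.RangeIndex(4, name="peptide_id"))
        design = pd.DataFrame(rows)
        case = [s for s in cols if s.startswith("d300_3")]
        ctrl = [s for s in cols if s.startswith("d0_")]
        model = fit_linear_model(list(range(4)), matrix, case, ctrl)
        tc = time_course_scores(model, matrix, design)
        assert list(tc.index) == days
        peak = tc.loc[3.0]
        assert peak[300.0] >= peak[150.0] >= peak[0.0]
        assert abs(tc.loc[44.0, 300.0] - tc.loc[44.0, 0.0]) < 0.8

    def test_sample_missing_from_design_raises(self):
        matrix = pd.DataFrame({"s1": [1.0]}, index=pd.RangeIndex(1, name="peptide_id"))
        design = pd.DataFrame({"sample_id": ["other"], "dose_mg_kg": [0], "day": [1]})
        model = ClassifierModel("linear", [0], {"center": [0.0], "scale": [1.0]})
        with pytest.raises(DataError):
            time_course_scores(model, matrix, design)
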