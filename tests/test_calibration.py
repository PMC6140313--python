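"""Design building, OLS fitting, grid evaluation and optimum selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import fast_sim
from thermolimit.calibration import (
    FitResult,
    GridCell,
    GridSpec,
    ModelSpec,
    build_design,
    evaluate_grid_point,
    grid_search,
    ols_fit,
    select_optimum,
    surface_frame,
)
from thermolimit.simulate import simulate_experiment


def _meta_frame(treatments, sizes):
    return pd.DataFrame({"treatment": treatments, "body_size_mm": sizes})


class TestBuildDesign:
    def test_additive_two_levels(self):
        meta = _meta_frame(["17", "22", "17", "22"], [2.0, 2.1, 1.9, 2.2])
        X, terms = build_design(meta, ModelSpec())
        assert terms == ["intercept", "treatment[22]", "body_size_mm"]
        np.testing.assert_array_equal(X["treatment[22]"], [0, 1, 0, 1])

    def test_interactive_two_levels_has_four_columns(self):
        meta = _meta_frame(["17", "22", "17", "22", "17"], [2.0, 2.1, 1.9, 2.2, 2.3])
        X, terms = build_design(meta, ModelSpec(form="interactive"))
        assert len(terms) == 4
        assert terms[-1] == "treatment[22]:body_size_mm"
        np.testing.assert_allclose(
            X["treatment[22]:body_size_mm"], X["treatment[22]"] * X["body_size_mm"]
        )

    def test_single_level_design_has_no_dummies(self):
        meta = _meta_frame(["17"] * 4, [2.0, 2.1, 1.9, 2.2])
        X, terms = build_design(meta, ModelSpec())
        assert terms == ["intercept", "body_size_mm"]

    def test_reference_level_override(self):
        meta = _meta_frame(["17", "22", "17", "22"], [2.0, 2.1, 1.9, 2.2])
        X, terms = build_design(meta, ModelSpec(reference_level="22"))
        assert "treatment[17]" in terms

    def test_sparse_level_warns(self):
        meta = _meta_frame(["17", "17", "17", "22"], [2.0, 2.1, 1.9, 2.2])
        with pytest.warns(UserWarning, match="'22'"):
            build_design(meta, ModelSpec())

    def test_fewer_rows_than_columns_rejected(self):
        meta = _meta_frame(["17", "22"], [2.0, 2.1])
        with pytest.raises(ValueError, match="fewer rows"):
            build_design(meta, ModelSpec(form="interactive"))

    def test_missing_size_rejected(self):
        meta = _meta_frame(["17", "22", "17"], [2.0, np.nan, 1.9])
        with pytest.raises(ValueError, match="body_size_mm"):
            build_design(meta, ModelSpec())


class TestOlsFit:
    def test_exact_linear_response_gives_r2_one(self):
        meta = _meta_frame(["a", "b"] * 4, np.arange(8, dtype=float) / 4 + 1.5)
        X, _ = build_design(meta, ModelSpec())
        y = 3.0 * X["intercept"] + 2.0 * X["treatment[b]"] - 1.0 * X["body_size_mm"]
        fit = ols_fit(y, X)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_response_gives_r2_zero(self):
        X = pd.DataFrame({"intercept": np.ones(6), "x": [1, -1, 1, -1, 1, -1.0]})
        y = np.array([1, 1, -1, -1, 0, 0.0])  # orthogonal to intercept and x
        fit = ols_fit(y, X)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        # two groups of three with sizes 1,2,3 each; response built from
        # known coefficients plus fixed residuals
        meta = _meta_frame(["a", "a", "a", "b", "b", "b"], [1.0, 2, 3, 1, 2, 3])
        X, _ = build_design(meta, ModelSpec())
        beta_true = np.array([10.0, 5.0, -2.0])
        resid = np.array([0.3, -0.1, -0.2, 0.1, 0.2, -0.3])
        y = X.to_numpy() @ beta_true + resid
        fit = ols_fit(y, X)
        # independent computation straight from the normal equations
        A = X.to_numpy()
        xtx_inv = np.linalg.inv(A.T @ A)
        beta = xtx_inv @ A.T @ y
        e = y - A @ beta
        s2 = e @ e / (6 - 3)
        se = np.sqrt(np.diag(s2 * xtx_inv))
        np.testing.assert_allclose(fit.coefficients["estimate"], beta, rtol=1e-10)
        np.testing.assert_allclose(fit.coefficients["se"], se, rtol=1e-10)
        np.testing.assert_allclose(fit.coefficients["t"], beta / se, rtol=1e-10)
        sst = np.sum((y - y.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1 - e @ e / sst, rel=1e-12)

    def test_constant_response_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(5), "x": np.arange(5.0)})
        with pytest.raises(ValueError, match="degenerate response"):
            ols_fit(np.full(5, 7.0), X)

    def test_collinear_design_rejected_with_term_names(self):
        X = pd.DataFrame(
            {"intercept": np.ones(6), "x": np.arange(6.0), "x_copy": np.arange(6.0)}
        )
        with pytest.raises(ValueError, match="x_copy"):
            ols_fit(np.random.default_rng(0).random(6), X)

    def test_r_squared_equals_one_minus_sse_over_sst(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 30))
            X = pd.DataFrame(
                {"intercept": np.ones(n), "a": rng.random(n), "b": rng.random(n)}
            )
            y = rng.random(n) * 10
            fit = ols_fit(y, X)
            beta = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
            sse = np.sum((y - X.to_numpy() @ beta) ** 2)
            sst = np.sum((y - y.mean()) ** 2)
            assert fit.r_squared == pytest.approx(1 - sse / sst, rel=1e-10)


@pytest.fixture(scope="module")
def sim_dataset():
    return simulate_experiment(fast_sim(seed=3, n_per_treatment=12))


class TestEvaluateGridPoint:
    def test_sensible_cell_beats_absurd_cell(self, sim_dataset):
        dataset, _ = sim_dataset
        good = evaluate_grid_point(dataset, 0.03, 280)
        bad = evaluate_grid_point(dataset, 0.9, 20)
        assert good.valid and bad.valid
        assert good.fit.r_squared > bad.fit.r_squared

    def test_threshold_above_all_velocities_degenerates(self):
        dataset, _ = simulate_experiment(
            fast_sim(seed=4, n_per_treatment=4, intro_spacing_s=0.0)
        )
        cell = evaluate_grid_point(dataset, 500.0, 20)
        assert not cell.valid
        assert "degenerate" in cell.reason

    def test_window_exceeding_series_marks_invalid(self, sim_dataset):
        dataset, _ = sim_dataset
        n = dataset.tracks[0].n_samples
        cell = evaluate_grid_point(dataset, 0.03, n + 10)
        assert not cell.valid and cell.reason == "window exceeds series"

    def test_exclude_policy_drops_censored(self, sim_dataset):
        dataset, _ = sim_dataset
        # below the jitter floor of most subjects: many censored
        cell_ex = evaluate_grid_point(dataset, 0.005, 280, censor_policy="exclude")
        cell_eor = evaluate_grid_point(dataset, 0.005, 280, censor_policy="end_of_record")
        assert cell_ex.n_censored == cell_eor.n_censored
        if cell_ex.valid:
            assert cell_ex.n_used == cell_ex.n_subjects - cell_ex.n_censored
        if cell_eor.valid:
            assert cell_eor.n_used == cell_eor.n_subjects


class TestGridSearch:
    def test_default_grid_cell_count(self):
        assert len(GridSpec.default()) == 5400
        assert len(GridSpec.default().v_thresh_values) == 100
        assert len(GridSpec.default().w_values) == 54

    def test_single_cell_grid_equals_point_evaluation(self, sim_dataset):
        dataset, _ = sim_dataset
        grid = GridSpec(v_thresh_values=(0.05,), w_values=(60,))
        (cell,) = grid_search(dataset, grid)
        direct = evaluate_grid_point(dataset, 0.05, 60)
        assert (cell.v_thresh, cell.w, cell.n_used, cell.n_censored) == (
            direct.v_thresh, direct.w, direct.n_used, direct.n_censored,
        )
        assert cell.fit.r_squared == direct.fit.r_squared
        pd.testing.assert_frame_equal(cell.fit.coefficients, direct.fit.coefficients)

    def test_maximum_matches_bruteforce_reevaluation(self, sim_dataset):
        dataset, _ = sim_dataset
        grid = GridSpec(v_thresh_values=(0.03, 0.1, 0.4), w_values=(40, 160))
        cells = grid_search(dataset, grid)
        assert len(cells) == 6
        v, w, best = select_optimum(cells, max_censored_frac=1.0)
        direct = [
            evaluate_grid_point(dataset, vv, ww)
            for vv in grid.v_thresh_values
            for ww in grid.w_values
        ]
        best_direct = max(
            (c for c in direct if c.valid), key=lambda c: (c.fit.r_squared, -c.w, -c.v_thresh)
        )
        assert (v, w) == (best_direct.v_thresh, best_direct.w)
        assert best.fit.r_squared == best_direct.fit.r_squared

    def test_parallel_equals_sequential(self, sim_dataset):
        dataset, _ = sim_dataset
        grid = GridSpec(v_thresh_values=(0.03, 0.2), w_values=(40, 160))
        seq = surface_frame(grid_search(dataset, grid, n_jobs=1))
        par = surface_frame(grid_search(dataset, grid, n_jobs=2))
        pd.testing.assert_frame_equal(seq, par)

    def test_grid_spec_validation(self):
        with pytest.raises(ValueError):
            GridSpec(v_thresh_values=(0.2, 0.1), w_values=(20,))
        with pytest.raises(ValueError):
            GridSpec(v_thresh_values=(0.1,), w_values=(1,))


def _cell(v, w, r2, n_censored=0, n=20):
    fit = FitResult(r_squared=r2, coefficients=pd.DataFrame(), n_used=n, dof_resid=n - 3)
    return GridCell(
        v_thresh=v, w=w, fit=fit, r2_partial_treatment=r2, n_subjects=n,
        n_used=n, n_censored=n_censored, n_excluded_size=0,
        censor_policy="end_of_record", valid=True,
    )


class TestSelectOptimum:
    def test_unique_maximum_selected(self):
        cells = [_cell(0.1, 20, 0.3), _cell(0.2, 40, 0.6), _cell(0.3, 60, 0.5)]
        v, w, _ = select_optimum(cells)
        assert (v, w) == (0.2, 40)

    def test_exact_tie_prefers_smaller_w_then_v(self):
        cells = [_cell(0.2, 40, 0.6), _cell(0.1, 20, 0.6), _cell(0.3, 20, 0.6)]
        v, w, _ = select_optimum(cells)
        assert (v, w) == (0.1, 20)

    def test_censoring_bound_is_binding(self):
        cells = [_cell(0.1, 20, 0.9, n_censored=10), _cell(0.2, 40, 0.4, n_censored=0)]
        v, w, _ = select_optimum(cells, max_censored_frac=0.1)
        assert (v, w) == (0.2, 40)
        with pytest.raises(ValueError, match="max_censored_frac"):
            select_optimum([_cell(0.1, 20, 0.9, n_censored=10)], max_censored_frac=0.1)

    def test_selected_r2_dominates_admissible_cells(self, sim_dataset):
        dataset, _ = sim_dataset
        grid = GridSpec(v_thresh_values=(0.02, 0.05, 0.2), w_values=(40, 280))
        cells = grid_search(dataset, grid)
        _, _, best = select_optimum(cells, max_censored_frac=0.2)
        for c in cells:
            if c.valid and c.censored_frac <= 0.2:
                assert best.fit.r_squared >= c.fit.r_squared
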