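"""Calibration machinery on cheap analytic surrogates of the circuit."""

import numpy as np
import pytest

from psyqsp.calibration import (
    CalibrationResult,
    ClinicalDataset,
    ClinicalPoint,
    coarse_grid_search,
    load_clinical_csv,
    objective_r2,
    prediction_interval,
    sensitivity_analysis,
    steepest_descent_refine,
    weighted_average_outcome,
)
from psyqsp.msn_circuit import CouplingParams


def make_dataset(outcomes):
    return ClinicalDataset(
        points=[
            ClinicalPoint(drug="x", dose=float(i), concentration=1.0,
                          outcome=float(o), n=100)
            for i, o in enumerate(outcomes)
        ]
    )


def quadratic_evaluator(center):
    """Analytic stand-in: output_i = i * value, value peaks at ``center``.

    Correlation with outcomes [0, 1, ..., n-1] is maximal where the
    quadratic distortion vanishes, i.e. at the center.
    """
    center = np.asarray(center)

    def ev(coupling: CouplingParams) -> np.ndarray:
        x = coupling.as_array()
        d2 = float(np.sum((x - center) ** 2))
        i = np.arange(8, dtype=float)
        return i + d2 * (i - i.mean()) ** 2
    return ev


ZERO_BOUNDS = {n: (0.0, 0.0) for n in CouplingParams.NAMES}


class TestWeightedAverage:
    def test_single_arm_identity(self):
        assert weighted_average_outcome([(7.5, 42)]) == 7.5

    def test_equal_weights(self):
        assert weighted_average_outcome([(10.0, 100), (20.0, 100)]) == 15.0

    def test_hand_computed(self):
        assert weighted_average_outcome([(6.4, 99), (18.0, 99)]) == pytest.approx(12.2)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            weighted_average_outcome([])
        with pytest.raises(ValueError):
            weighted_average_outcome([(1.0, 0)])


class TestObjectiveR2:
    def test_exact_linear_relation(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert objective_r2([10, 20, 30, 40], y) == pytest.approx(1.0)

    def test_sign_blind(self):
        y = [1.0, 2.0, 3.0, 4.0]
        assert objective_r2([40, 30, 20, 10], y) == pytest.approx(1.0)

    def test_five_point_textbook_value(self):
        # direct evaluation of r = S_xy / sqrt(S_xx S_yy) on this fixture
        x = [1.0, 2.0, 4.0, 5.0, 7.0]
        y = [2.0, 3.0, 5.0, 4.0, 8.0]
        sx = np.array(x) - np.mean(x)
        sy = np.array(y) - np.mean(y)
        expected = (np.dot(sx, sy) ** 2) / (np.dot(sx, sx) * np.dot(sy, sy))
        assert objective_r2(x, y) == pytest.approx(expected, rel=1e-12)
        assert objective_r2(x, y) == pytest.approx(0.860973, abs=1e-5)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            objective_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            objective_r2([1.0, 2.0], [1.0, 2.0])


class TestCoarseGrid:
    def test_one_dimensional_quadratic_argmax_within_one_step(self):
        center = np.zeros(10)
        center[2] = 0.7   # free dimension d2_gk
        bounds = dict(ZERO_BOUNDS)
        bounds["d2_gk"] = (0.0, 2.0)
        ds = make_dataset(np.arange(8.0))
        best, r2 = coarse_grid_search(
            ds, quadratic_evaluator(center), bounds, grid_points_per_dim=9
        )
        step = 2.0 / 8
        assert abs(best.d2_gk - 0.7) <= step
        assert r2 <= 1.0

    def test_latin_hypercube_reproducible_per_seed(self):
        center = np.full(10, 0.3)
        bounds = {n: (-1.0, 1.0) for n in CouplingParams.NAMES}
        ds = make_dataset(np.arange(8.0))
        ev = quadratic_evaluator(center)
        a, _ = coarse_grid_search(ds, ev, bounds, n_samples=64, seed=7)
        b, _ = coarse_grid_search(ds, ev, bounds, n_samples=64, seed=7)
        assert np.allclose(a.as_array(), b.as_array())

    def test_recovers_known_center_within_grid_resolution(self):
        center = np.zeros(10)
        center[2], center[4] = 0.5, -0.25
        bounds = dict(ZERO_BOUNDS)
        bounds["d2_gk"] = (0.0, 1.0)
        bounds["m1_leak"] = (-1.0, 1.0)
        ds = make_dataset(np.arange(8.0))
        best, _ = coarse_grid_search(
            ds, quadratic_evaluator(center), bounds, grid_points_per_dim=5
        )
        assert abs(best.d2_gk - 0.5) <= 0.25 + 1e-12
        assert abs(best.m1_leak + 0.25) <= 0.5 + 1e-12


class TestSteepestDescent:
    def test_start_at_optimum_converges_immediately(self):
        center = np.full(10, 0.2)
        bounds = {n: (-1.0, 1.0) for n in CouplingParams.NAMES}
        ds = make_dataset(np.arange(8.0))
        res = steepest_descent_refine(
            CouplingParams.from_array(center), ds, quadratic_evaluator(center), bounds
        )
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.converged

    def test_r2_trace_monotone_non_decreasing(self):
        center = np.full(10, 0.4)
        bounds = {n: (-1.0, 1.0) for n in CouplingParams.NAMES}
        ds = make_dataset(np.arange(8.0))
        start = CouplingParams.from_array(np.full(10, -0.5))
        res = steepest_descent_refine(start, ds, quadratic_evaluator(center), bounds)
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))

    def test_descent_never_worse_than_grid(self):
        center = np.full(10, 0.35)
        bounds = {n: (-1.0, 1.0) for n in CouplingParams.NAMES}
        ds = make_dataset(np.arange(8.0))
        ev = quadratic_evaluator(center)
        best, grid_r2 = coarse_grid_search(ds, ev, bounds, n_samples=32, seed=1)
        res = steepest_descent_refine(best, ds, ev, bounds)
        assert res.r2 >= grid_r2 - 1e-12

    def test_order_invariance_of_objective(self):
        center = np.full(10, 0.1)
        ev = quadratic_evaluator(center)
        ds = make_dataset(np.arange(8.0))
        perm = [3, 1, 7, 0, 5, 2, 6, 4]
        ds_perm = make_dataset(np.arange(8.0)[perm])
        x = CouplingParams.from_array(np.full(10, 0.3))

        def ev_perm(c):
            return ev(c)[perm]
        assert objective_r2(ev(x), ds.outcomes) == pytest.approx(
            objective_r2(ev_perm(x), ds_perm.outcomes), rel=1e-12
        )


class TestSensitivityAndIntervals:
    def test_inert_parameter_has_zero_influence(self):
        def ev(coupling):
            return np.arange(5.0) * (1.0 + coupling.d2_gk)
        sens = sensitivity_analysis(
            CouplingParams(d2_gk=0.5, m1_leak=0.4), ev, outcome_link=lambda f: f
        )
        assert sens["m1_leak"]["influence"] == 0.0
        assert sens["d2_gk"]["influence"] > 0.0
        assert list(sens)[0] == "d2_gk"

    def test_near_linear_response_antisymmetric(self):
        def ev(coupling):
            return np.arange(5.0) * (1.0 + 0.1 * coupling.d2_gk)
        sens = sensitivity_analysis(
            CouplingParams(d2_gk=0.5), ev, outcome_link=lambda f: f, perturbation=0.05
        )
        up, down = sens["d2_gk"]["up_mean"], sens["d2_gk"]["down_mean"]
        assert up == pytest.approx(-down, rel=0.5)

    def test_prediction_interval_formula(self):
        res = CalibrationResult(
            coupling=CouplingParams(), r2=0.9, residual_sd=2.0,
            scale_slope=1.0, scale_intercept=0.0,
        )
        lo, hi = prediction_interval(res, 10.0)
        assert lo == pytest.approx(10 - 1.96 * 2, abs=0.01)
        assert hi == pytest.approx(10 + 1.96 * 2, abs=0.01)
        res0 = CalibrationResult(
            coupling=CouplingParams(), r2=0.9, residual_sd=0.0,
            scale_slope=1.0, scale_intercept=0.0,
        )
        assert prediction_interval(res0, 5.0) == (5.0, 5.0)


class TestClinicalCsv:
    def test_round_trip_with_weighted_aggregation(self, tmp_path):
        p = tmp_path / "clin.csv"
        p.write_text(
            "drug,dose_mg,concentration_nM,outcome,scale,n\n"
            "a,1,10,6.4,PANSS-total,99\n"
            "a,1,10,18,PANSS-total,99\n"
            "b,2,20,5,PANSS-total,50\n"
        )
        ds = load_clinical_csv(p)
        assert len(ds) == 2
        point_a = next(pt for pt in ds.points if pt.drug == "a")
        assert point_a.outcome == pytest.approx(12.2)
        assert point_a.n == 198

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            ClinicalDataset(points=[
                ClinicalPoint("a", 1.0, 1.0, 1.0, 10),
                ClinicalPoint("a", 1.0, 2.0, 2.0, 10),
            ])
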