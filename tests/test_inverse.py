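"""Inverse estimation: bounds, stage-1 lumped fits against independent
ODE oracles, objective self-consistency, and the goal-attainment contract."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from seedwave import props, tables
from seedwave.inverse import (
    Bounds,
    CoefficientVector,
    GoalAttainmentProblem,
    MicrowaveDryingModel,
    default_bounds,
    estimate_treatment,
)
from seedwave.lensgeom import LensGeometry, characteristic_length
from seedwave.obs import DryingRecord
from seedwave.props import LossFactorModel, MicrowaveSource

L = characteristic_length(LensGeometry())
EST = dict(target_h=2.5e-4, dt=1.0)


class TestBounds:
    def test_unit_cube_roundtrip(self):
        b = default_bounds()
        rng = np.random.default_rng(0)
        for _ in range(10):
            u = rng.random(len(b.lb))
            x = b.from_unit(u)
            assert np.all(x >= b.lb - 1e-12) and np.all(x <= b.ub + 1e-12)
            assert np.allclose(b.to_unit(x), u, atol=1e-9)

    def test_published_rows_inside_default_bounds(self):
        b = default_bounds()
        for tid in tables.TREATMENTS:
            lm = tables.loss_factor_model(tid)
            dm = tables.diffusivity_model(tid)
            vec = CoefficientVector.from_models(lm, dm, *tables.biot_numbers(tid))
            assert np.all(vec.values >= b.lb) and np.all(vec.values <= b.ub)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Bounds(lb=np.array([1.0]), ub=np.array([0.0]), log=np.array([False]))
        with pytest.raises(ValueError):
            Bounds(lb=np.array([-1.0]), ub=np.array([1.0]), log=np.array([True]))


class TestCoefficientVector:
    def test_named_access_and_model_construction(self):
        lm = tables.loss_factor_model("0.70kW-50")
        dm = tables.diffusivity_model("0.70kW-50")
        vec = CoefficientVector.from_models(lm, dm, 0.038, 0.016)
        assert vec["Ea"] == pytest.approx(29.026)
        assert vec.bi_heat == 0.038
        assert vec.loss_model().g == lm.g
        assert vec.diff_model()(350.0, 0.2) == pytest.approx(float(dm(350.0, 0.2)))

    def test_length_checked(self):
        with pytest.raises(ValueError):
            CoefficientVector(np.zeros(3))


def _lumped_moisture_record(diff, bi_mass, seed_T=None):
    """Independent oracle: solve_ivp of the lumped moisture balance under a
    prescribed smooth temperature history."""
    t = np.arange(0.0, 361.0, 15.0)
    T_of = lambda s: 277.15 + 60.0 * (1.0 - np.exp(-s / 150.0))

    def rhs(s, y):
        return [-bi_mass * float(diff(T_of(s), max(y[0], 0.0))) / L**2 * y[0]]

    sol = solve_ivp(rhs, (0, t[-1]), [0.5], t_eval=t, rtol=1e-10, atol=1e-12)
    return DryingRecord(
        treatment_id="lumped-m",
        times=t,
        moisture_db=sol.y[0],
        surface_T_C=T_of(t) - 273.15,
        meta={"pav_watts": 616.0, "s11": 0.421},
    )


def _lumped_heat_record(loss, bi_heat, source):
    """Independent oracle: solve_ivp of the lumped energy balance at
    constant moisture (a tempered seed before appreciable drying).  The
    constant moisture history is exactly representable by the Fourier
    smoother, so the only reconstruction error is the integrator's."""
    t = np.arange(0.0, 151.0, 10.0)
    M0 = 0.35
    E = props.field_strength(source)
    q_fac = 2 * np.pi * source.f * source.eps0 * E**2

    def rhs(s, y):
        T = y[0]
        rho = props.density(M0)
        cp = props.specific_heat(T, M0)
        k = props.thermal_conductivity(T, M0)
        q = q_fac * float(loss(T, M0))
        return [(q - bi_heat * k / L**2 * (T - 296.15)) / (rho * cp)]

    sol = solve_ivp(rhs, (0, t[-1]), [277.15], t_eval=t, rtol=1e-10, atol=1e-10)
    return DryingRecord(
        treatment_id="lumped-h",
        times=t,
        moisture_db=np.full_like(t, M0),
        surface_T_C=sol.y[0] - 273.15,
        meta={"pav_watts": source.Pav, "s11": source.S11},
    )


class TestStage1Diffusivity:
    def test_recovers_diffusivity_trajectory_with_known_biot(self):
        true_d = tables.diffusivity_model("0.70kW-50")
        bi = 0.016
        rec = _lumped_moisture_record(true_d, bi)
        model = MicrowaveDryingModel(rec, optimize_biot=False, bi_known=(0.04, bi), **EST)
        res = model.stage1_diffusivity()
        est = CoefficientVector(np.concatenate([np.zeros(8), res.params[:4], [0.04, bi]])).diff_model()
        T = rec.surface_T_C + 273.15
        M = np.maximum(rec.moisture_db, 1e-3)
        rel = np.abs(est(T, M) / true_d(T, M) - 1)
        assert rel.mean() < 0.05
        # residual reflects only the Fourier reconstruction of the driving
        # temperature, far below the record's signal scale
        assert res.sse < 1e-3

    def test_free_biot_identifies_the_transfer_product(self):
        """With Bi_mass free only the product Bi * D is identified; the
        recovered product tracks the true one along the trajectory."""
        true_d = tables.diffusivity_model("0.70kW-50")
        bi = 0.016
        rec = _lumped_moisture_record(true_d, bi)
        model = MicrowaveDryingModel(rec, optimize_biot=True, **EST)
        res = model.stage1_diffusivity()
        est = CoefficientVector(
            np.concatenate([np.zeros(8), res.params[:4], [0.04, res.params[4]]])
        ).diff_model()
        T = rec.surface_T_C + 273.15
        M = np.maximum(rec.moisture_db, 1e-3)
        rel = np.abs(res.params[4] * est(T, M) / (bi * true_d(T, M)) - 1)
        assert rel.mean() < 0.05

    def test_degenerate_record_flagged_not_crashed(self):
        t = np.arange(0.0, 361.0, 15.0)
        rec = DryingRecord("flat", t, np.full_like(t, 0.3), 20.0 + 0.1 * t,
                           meta={"pav_watts": 616.0, "s11": 0.421})
        model = MicrowaveDryingModel(rec, optimize_biot=True, **EST)
        res = model.stage1_diffusivity(maxiter=50)
        assert "degenerate_moisture_record" in res.flags


class TestStage1LossFactor:
    def test_recovers_loss_trajectory_with_known_biot(self):
        true_l = tables.loss_factor_model("average", ash_db=2.6)
        bi = 0.043
        source = MicrowaveSource(Pav=308.0, S11=0.694)
        rec = _lumped_heat_record(true_l, bi, source)
        model = MicrowaveDryingModel(rec, optimize_biot=False, bi_known=(bi, 0.015), **EST)
        res = model.stage1_lossfactor()
        est = LossFactorModel(g=tuple(res.params[:8]), ash_db=2.6)
        T = rec.surface_T_C + 273.15
        M = rec.moisture_db
        rel = np.abs(est(T, M) / true_l(T, M) - 1)
        assert rel.mean() < 0.10

    def test_isothermal_record_reported_unidentifiable(self):
        t = np.arange(0.0, 361.0, 15.0)
        rec = DryingRecord("iso", t, 0.4 * np.exp(-t / 500.0),
                           np.full_like(t, 23.0),
                           meta={"pav_watts": 616.0, "s11": 0.421})
        model = MicrowaveDryingModel(rec, optimize_biot=True, **EST)
        res = model.stage1_lossfactor()
        assert "unidentifiable_temperature_record" in res.flags


class TestObjectivePair:
    def test_self_consistency_at_generating_coefficients(self, scenario_50, record_50):
        model = MicrowaveDryingModel(record_50, optimize_biot=False,
                                     bi_known=scenario_50.true_bi, **EST)
        truth = CoefficientVector.from_models(
            scenario_50.true_loss_model, scenario_50.true_diff_model, *scenario_50.true_bi
        )
        sse_T, sse_M = model.objective_pair(truth)
        assert sse_T < 1e-4 and sse_M < 1e-4

    def test_perturbing_diffusivity_increases_moisture_error(self, scenario_50, record_50):
        model = MicrowaveDryingModel(record_50, optimize_biot=False,
                                     bi_known=scenario_50.true_bi, **EST)
        truth = CoefficientVector.from_models(
            scenario_50.true_loss_model, scenario_50.true_diff_model, *scenario_50.true_bi
        )
        bumped = truth.values.copy()
        bumped[8] *= 1.5  # D0
        sse_M0 = model.objective_pair(truth)[1]
        sse_M1 = model.objective_pair(CoefficientVector(bumped))[1]
        assert sse_M1 > sse_M0 + 1e-6

    def test_invariant_to_measurement_order(self, scenario_50, record_50):
        perm = np.random.default_rng(0).permutation(record_50.n)
        shuffled = DryingRecord(
            record_50.treatment_id,
            record_50.times[perm],
            record_50.moisture_db[perm],
            record_50.surface_T_C[perm],
            meta=record_50.meta,
        )
        m1 = MicrowaveDryingModel(record_50, optimize_biot=False,
                                  bi_known=scenario_50.true_bi, **EST)
        m2 = MicrowaveDryingModel(shuffled, optimize_biot=False,
                                  bi_known=scenario_50.true_bi, **EST)
        truth = CoefficientVector.from_models(
            scenario_50.true_loss_model, scenario_50.true_diff_model, *scenario_50.true_bi
        )
        assert m1.objective_pair(truth) == m2.objective_pair(truth)


class TestGoalAttainment:
    def test_truth_start_is_immediately_feasible(self, scenario_50, record_50):
        """Starting at the generating coefficients the attainment level is
        already <= 0 and the refinement terminates quickly."""
        model = MicrowaveDryingModel(record_50, optimize_biot=False,
                                     bi_known=scenario_50.true_bi, **EST)
        truth = CoefficientVector.from_models(
            scenario_50.true_loss_model, scenario_50.true_diff_model, *scenario_50.true_bi
        )
        res = model.goal_attainment(truth, GoalAttainmentProblem(bounds=model.bounds, maxiter=3))
        assert res.gamma <= 1e-9
        assert res.sse_T < 1e-3 and res.sse_M < 1e-6

    def test_reported_stats_reproducible_from_coefficients(self, scenario_50, record_50):
        model = MicrowaveDryingModel(record_50, optimize_biot=False,
                                     bi_known=scenario_50.true_bi, **EST)
        truth = CoefficientVector.from_models(
            scenario_50.true_loss_model, scenario_50.true_diff_model, *scenario_50.true_bi
        )
        res = model.goal_attainment(truth, GoalAttainmentProblem(bounds=model.bounds, maxiter=2))
        sse_T, sse_M = model.objective_pair(res.params)
        assert res.sse_T == pytest.approx(sse_T, rel=1e-12)
        assert res.sse_M == pytest.approx(sse_M, rel=1e-12)
        assert res.stats_T.sse == pytest.approx(sse_T, rel=1e-9, abs=1e-12)

    def test_final_loss_factor_positive_on_trajectory(self, scenario_50, record_50):
        model = MicrowaveDryingModel(record_50, optimize_biot=False,
                                     bi_known=scenario_50.true_bi, **EST)
        truth = CoefficientVector.from_models(
            scenario_50.true_loss_model, scenario_50.true_diff_model, *scenario_50.true_bi
        )
        res = model.goal_attainment(truth, GoalAttainmentProblem(bounds=model.bounds, maxiter=2))
        assert model.min_loss_factor(res.params) > 0


@pytest.fixture(scope="module")
def tiny_record():
    """13-point record from the 0.35 kW / 35 % preset, the smallest the
    Fourier smoother accepts (the moisture stays above the truncation
    threshold over the window)."""
    from dataclasses import replace

    from seedwave.synth import generate_record, make_paper_like_scenarios

    sc = next(s for s in make_paper_like_scenarios(noise=(0.0, 0.0))
              if s.treatment_id == "0.35kW-35")
    sc = replace(sc, schedule=np.arange(0.0, 241.0, 20.0))
    return sc, generate_record(sc, target_h=3.5e-4, dt=2.0)


class TestEstimateTreatment:
    def test_pipeline_emits_consistent_result(self, tiny_record):
        sc, rec = tiny_record
        res = estimate_treatment(rec, maxiter=4, optimize_biot=False,
                                 bi_known=sc.true_bi, target_h=3.5e-4, dt=2.0)
        d = res.to_dict()
        assert set(d["coefficients"]) == set(
            ("g0", "g1", "g2", "g3", "g4", "g5", "g6", "g7",
             "D0", "Ea", "a0", "a1", "Bi_heat", "Bi_mass")
        )
        assert d["stats_T"]["r2"] <= 1.0 and d["stats_M"]["r2"] <= 1.0
        assert "loss factor" in res.summary()
        assert np.all(np.diff(res.accepted_trace["gamma"]) <= 0)

    def test_rerun_is_bit_identical(self, tiny_record):
        sc, rec = tiny_record
        kwargs = dict(maxiter=2, optimize_biot=False, bi_known=sc.true_bi,
                      target_h=3.5e-4, dt=2.0)
        r1 = estimate_treatment(rec, **kwargs)
        r2 = estimate_treatment(rec, **kwargs)
        assert np.array_equal(r1.params.values, r2.params.values)
        assert r1.gamma == r2.gamma

    def test_missing_temperature_column_is_hard_error(self, tmp_path):
        import pandas as pd

        path = tmp_path / "x.csv"
        pd.DataFrame({"time_s": [0, 1], "moisture_db": [0.4, 0.39]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="surface_T_C"):
            MicrowaveDryingModel.from_csv(path)
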