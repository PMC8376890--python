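import dataclasses

import numpy as np
import pytest
import sympy as sp

import odeident as oi
from odeident.ic_search import resolve_pattern
from odeident.model_core import promote_initial_conditions
from odeident.sensitivity import (ExperimentConfig, IntegrationError,
                                  assemble_sensitivity_system,
                                  build_sensitivity_matrix,
                                  integrate_sensitivities)


def _scalar_decay():
    x, th, x0 = sp.symbols("x theta x0")
    model = oi.OdeModel(name="decay", states=(x,), params=(th,),
                        drift=(-th * x,), outputs=(x,),
                        initial_conditions=(x0,))
    return promote_initial_conditions(model, {"x"})


class TestClosedFormOracle:
    """dx/dt = -theta x, y = x has dy/dtheta = -t x0 exp(-theta t) and
    dy/dx0 = exp(-theta t) in closed form."""

    def test_sensitivities_match_closed_form(self):
        model = _scalar_decay()
        system = assemble_sensitivity_system(model)
        cfg = ExperimentConfig(t_end=5.0, n_points=51)
        th, x0 = 0.7, 2.3
        nominal = oi.NominalAssignment.from_dict(
            dict(zip(model.unknowns, [th, x0])))
        traj = integrate_sensitivities(system, cfg, nominal)
        t = traj.times
        expected_dth = -t * x0 * np.exp(-th * t)
        expected_dx0 = np.exp(-th * t)
        np.testing.assert_allclose(traj.output_sensitivities[:, 0, 0],
                                   expected_dth, atol=1e-8)
        np.testing.assert_allclose(traj.output_sensitivities[:, 0, 1],
                                   expected_dx0, atol=1e-8)

    def test_initial_sensitivities(self):
        # at t0: zero for the rate parameter, one for the own initial value
        model = _scalar_decay()
        system = assemble_sensitivity_system(model)
        traj = integrate_sensitivities(
            system, ExperimentConfig(), oi.NominalAssignment.from_dict(
                dict(zip(model.unknowns, [1.0, 1.0]))))
        np.testing.assert_allclose(traj.output_sensitivities[0, 0, :], [0.0, 1.0],
                                   atol=1e-14)


@pytest.mark.parametrize("fid,seed", [("m1", 0), ("m2", 1), ("m3_epo", 2)])
def test_finite_difference_cross_check(models, systems, fid, seed):
    """Brute-force oracle for the whole module: central finite differences of
    re-integrated output trajectories reproduce the variational
    sensitivities."""
    from odeident.fixtures import default_config, default_scenario

    model = models[fid]
    system = systems(fid)
    cfg = default_config(fid, n_points=21)
    _, pattern, _ = default_scenario(fid, seed=seed)
    rng = np.random.default_rng(seed)
    ic_exprs, values = resolve_pattern(model, pattern, rng)
    nominal = oi.NominalAssignment.from_dict(values)
    traj = integrate_sensitivities(system, cfg, nominal, ic_exprs)

    cfg_fd = dataclasses.replace(cfg, adapt_horizon=False,
                                 t_end=float(traj.times[-1]))
    for j, sym in enumerate(model.unknowns):
        v = values[sym]
        h = 1e-5 * max(abs(v), 1e-2)
        ys = []
        for delta in (+h, -h):
            pert = dict(values)
            pert[sym] = v + delta
            tr = integrate_sensitivities(system, cfg_fd,
                                         oi.NominalAssignment.from_dict(pert),
                                         ic_exprs)
            ys.append(tr.outputs)
        fd = (ys[0] - ys[1]) / (2 * h)
        scale = np.max(np.abs(traj.output_sensitivities[:, :, j])) + 1.0
        np.testing.assert_allclose(traj.output_sensitivities[:, :, j], fd,
                                   atol=2e-4 * scale,
                                   err_msg=f"{fid}: column {sym}")


def test_matrix_shape_and_labels(models, systems):
    from odeident.fixtures import default_scenario

    model = models["m3_epo"]
    cfg = ExperimentConfig(n_points=51)
    _, pattern, _ = default_scenario("m3_epo")
    rng = np.random.default_rng(0)
    ic_exprs, values = resolve_pattern(model, pattern, rng)
    nominal = oi.NominalAssignment.from_dict(values)
    traj = integrate_sensitivities(systems("m3_epo"), cfg, nominal, ic_exprs)
    S = build_sensitivity_matrix(traj, model, cfg, nominal)
    assert S.shape == (2 * 51, 10)  # m*(N+1) rows, one column per unknown
    assert S.labels == tuple(map(str, model.unknowns))


def test_m2_parameter_tied_initial_condition_chain_rule(models, systems):
    """x2(0) = p1/p3 contributes chain-rule terms to the initial state
    sensitivities: dx2(0)/dp1 = 1/p3 and dx2(0)/dp3 = -p1/p3^2."""
    model = models["m2"]
    p = dict(zip(map(str, model.params), [1.5, 2.0, 0.8, 1.2]))
    values = {s: p[str(s)] for s in model.params}
    values[sp.Symbol("x10")] = 1.0
    cfg = ExperimentConfig(n_points=11)
    traj = integrate_sensitivities(systems("m2"), cfg,
                                   oi.NominalAssignment.from_dict(values))
    # at t0 the output y = x1 only sees x1's initial row (all zeros); at the
    # first interior point the x2(0) dependence must already be visible with
    # the chain-rule sign pattern: dy/dp1 < 0 mirrors -p3*x2(0) coupling
    s1 = traj.output_sensitivities[1, 0, :]
    assert s1[1] < 0  # p1 enters only through x2(0) = p1/p3 and -p3*x2 in f
    assert s1[3] != 0


def test_column_scaling_preserves_zero_columns_and_rank(models, systems):
    from odeident.fixtures import default_scenario

    model = models["m5_pk"]
    _, pattern, _ = default_scenario("m5_pk")
    rng = np.random.default_rng(3)
    ic_exprs, values = resolve_pattern(model, pattern, rng)
    nominal = oi.NominalAssignment.from_dict(values)

    mats = {}
    for mode in ("none", "nominal", "norm"):
        cfg = ExperimentConfig(column_scaling=mode)
        traj = integrate_sensitivities(systems("m5_pk"), cfg, nominal, ic_exprs)
        mats[mode] = build_sensitivity_matrix(traj, model, cfg, nominal)

    def zero_cols(S):
        return tuple(np.linalg.norm(S.values, axis=0) < 1e-10)

    def numrank(S):
        sv = np.linalg.svd(S.values, compute_uv=False)
        return int(np.sum(sv > 1e-9 * sv[0]))

    assert zero_cols(mats["none"]) == zero_cols(mats["nominal"]) == zero_cols(mats["norm"])
    assert numrank(mats["none"]) == numrank(mats["nominal"]) == numrank(mats["norm"])


def test_m1_p2_p3_columns_are_collinear(models, systems):
    """With x2(0) = 0 the p2 and p3 sensitivity columns are numerically
    collinear — the geometric origin of that model's unidentifiability."""
    model = models["m1"]
    values = {sp.Symbol("p1"): 0.5, sp.Symbol("p2"): 1.1, sp.Symbol("p3"): 0.9,
              sp.Symbol("x10"): 1.3}
    cfg = ExperimentConfig(column_scaling="none")
    ics = (sp.Symbol("x10"), sp.S.Zero)
    traj = integrate_sensitivities(systems("m1"), cfg,
                                   oi.NominalAssignment.from_dict(values), ics)
    S = build_sensitivity_matrix(traj, model, cfg)
    c2, c3 = S.values[:, 1], S.values[:, 2]
    cosang = abs(c2 @ c3) / (np.linalg.norm(c2) * np.linalg.norm(c3))
    assert np.arccos(min(cosang, 1.0)) < 1e-6


@pytest.mark.parametrize("kw,msg", [
    (dict(t_end=0.0), "t_end"),
    (dict(n_points=1), "grid points"),
    (dict(rtol=0.0), "tolerances"),
    (dict(column_scaling="bogus"), "column_scaling"),
])
def test_config_validation(kw, msg):
    with pytest.raises(ValueError, match=msg):
        ExperimentConfig(**kw)


def test_blowup_without_horizon_adaptation_raises():
    x, th = sp.symbols("x theta")
    model = promote_initial_conditions(
        oi.OdeModel(name="explode", states=(x,), params=(th,),
                    drift=(th * x**2,), outputs=(x,),
                    initial_conditions=(sp.Symbol("x_ic"),)), set())
    system = assemble_sensitivity_system(model)
    cfg = ExperimentConfig(t_end=5.0, adapt_horizon=False)
    nominal = oi.NominalAssignment.from_dict(
        {th: 2.0, sp.Symbol("x_ic"): 1.0})
    with pytest.raises(IntegrationError):
        integrate_sensitivities(system, cfg, nominal)


def test_horizon_adaptation_recovers_blowup_model():
    x, th = sp.symbols("x theta")
    model = promote_initial_conditions(
        oi.OdeModel(name="explode", states=(x,), params=(th,),
                    drift=(th * x**2,), outputs=(x,),
                    initial_conditions=(sp.Symbol("x_ic"),)), set())
    system = assemble_sensitivity_system(model)
    cfg = ExperimentConfig(t_end=5.0)  # escape time is 1/(theta*x0) = 0.5
    nominal = oi.NominalAssignment.from_dict({th: 2.0, sp.Symbol("x_ic"): 1.0})
    traj = integrate_sensitivities(system, cfg, nominal)
    assert traj.times[-1] < 0.5
    assert np.all(np.isfinite(traj.output_sensitivities))
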