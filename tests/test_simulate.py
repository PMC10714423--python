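"""Coupled simulation of the study arms: determinism, accuracy, phenomenology."""

import numpy as np
import pytest

import hemopkpd as hp
from hemopkpd.hematopoiesis import state_index
from hemopkpd.simulate import Trajectory


def _max_rel_diff(a, b):
    return float(np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12)))


def test_tumor_control_is_flat_at_baselines(table1, nominal_pk):
    spec = hp.SimulationSpec(hp.build_study_arm("tumor_control"), nominal_pk, table1)
    for mode in ("coupled", "fast"):
        traj = hp.simulate(spec, mode=mode)
        np.testing.assert_allclose(traj.rbc, 6.343, rtol=1e-6)
        np.testing.assert_allclose(traj.plt, 1.009, rtol=1e-6)
        np.testing.assert_allclose(traj.hgb, 21.75 * 6.343 / 10.0, rtol=1e-6)


def test_initial_observables_equal_baselines(arm_trajectories, table1):
    for traj in arm_trajectories.values():
        assert traj.rbc[0] == pytest.approx(table1.rbc0, rel=1e-12)
        assert traj.plt[0] == pytest.approx(table1.plt0, rel=1e-12)


def test_simulation_is_deterministic(table1, nominal_pk):
    spec = hp.SimulationSpec(hp.build_study_arm("combo_450"), nominal_pk, table1)
    a = hp.simulate(spec, mode="fast")
    b = hp.simulate(spec, mode="fast")
    assert np.array_equal(a.rbc, b.rbc) and np.array_equal(a.plt, b.plt)
    c = hp.simulate(spec, mode="coupled")
    d = hp.simulate(spec, mode="coupled")
    assert np.array_equal(c.rbc, d.rbc) and np.array_equal(c.plt, d.plt)


def test_fast_and_coupled_modes_agree(arm_trajectories, coupled_trajectories):
    for arm in hp.STUDY_ARMS:
        f, c = arm_trajectories[arm], coupled_trajectories[arm]
        for obs in ("rbc", "hgb", "plt"):
            assert _max_rel_diff(getattr(f, obs), getattr(c, obs)) < 1e-4, (arm, obs)


def test_coupled_solver_cross_check(table1, nominal_pk):
    """Two independent implicit/explicit schemes agree on a treated arm."""
    spec_l = hp.SimulationSpec(hp.build_study_arm("combo_1350"), nominal_pk, table1, method="LSODA")
    spec_r = hp.SimulationSpec(hp.build_study_arm("combo_1350"), nominal_pk, table1, method="Radau")
    a = hp.simulate(spec_l, mode="coupled")
    b = hp.simulate(spec_r, mode="coupled")
    for obs in ("rbc", "hgb", "plt"):
        assert _max_rel_diff(getattr(a, obs), getattr(b, obs)) < 1e-5


def test_fast_mode_step_refinement(table1, nominal_pk):
    reg = hp.build_study_arm("combo_450")
    a = hp.simulate(hp.SimulationSpec(reg, nominal_pk, table1, dt_fast=0.25), mode="fast")
    b = hp.simulate(hp.SimulationSpec(reg, nominal_pk, table1, dt_fast=0.125), mode="fast")
    for obs in ("rbc", "hgb", "plt"):
        assert _max_rel_diff(getattr(a, obs), getattr(b, obs)) < 1e-6


def test_all_states_nonnegative_and_inhibition_in_range(table1, nominal_pk):
    """No state goes negative on any arm and the linear-inhibition clamp
    never engages at the packaged parameter values."""
    for arm in hp.STUDY_ARMS:
        spec = hp.SimulationSpec(hp.build_study_arm(arm), nominal_pk, table1)
        traj = hp.simulate(spec, mode="fast")
        for name, arr in traj.latents.items():
            assert np.all(arr >= -1e-12), (arm, name)
        assert np.all(traj.rbc >= 0) and np.all(traj.plt >= 0)
        assert table1.kill * traj.latents["C_eff"].max() < 1.0, arm


def test_carboplatin_platelet_nadir_then_rebound(arm_trajectories, table1):
    s = hp.summarize(arm_trajectories["carboplatin_control"])
    assert s["nadir_value"] < table1.plt0 * 0.9
    assert s["peak_value"] > table1.plt0 * 1.1  # rebound overshoots baseline
    assert s["nadir_time_h"] < s["peak_time_h"]


def test_epo_monotherapy_secondary_thrombocytopenia(arm_trajectories):
    """High-dose rHuEPO drives a post-rebound platelet dip below baseline,
    deeper with dose (progenitor competition)."""
    depths = [
        hp.summarize(arm_trajectories[a])["pct_below_baseline_at_second_nadir"]
        for a in ("epo_100", "epo_450", "epo_1350")
    ]
    assert all(d > 0 for d in depths)
    assert depths[0] < depths[1] < depths[2]


def test_romiplostim_peak_exceeds_carboplatin_rebound(arm_trajectories):
    s_romi = hp.summarize(arm_trajectories["romi_30"])
    s_car = hp.summarize(arm_trajectories["carboplatin_control"])
    assert s_romi["peak_value"] > s_car["peak_value"]


def test_hgb_recovery_monotone_in_epo_dose(arm_trajectories):
    aucs = [
        hp.summarize(arm_trajectories[a], "HGB")["deficit_auc"]
        for a in ("carboplatin_control", "epo_100", "epo_450", "epo_1350")
    ]
    assert aucs[0] > aucs[1] > aucs[2] > aucs[3]


def test_zero_kill_reduces_to_tumor_control(table1, nominal_pk):
    params = table1.with_updates(kill=0.0)
    spec = hp.SimulationSpec(hp.build_study_arm("carboplatin_control"), nominal_pk, params)
    traj = hp.simulate(spec, mode="fast")
    np.testing.assert_allclose(traj.rbc, table1.rbc0, rtol=1e-9)
    np.testing.assert_allclose(traj.plt, table1.plt0, rtol=1e-9)


def _synthetic_traj(times, plt):
    z = np.full_like(plt, np.nan)
    return Trajectory("synthetic", times, z, z, plt, {})


def test_summarize_flat_trajectory():
    t = np.arange(0.0, 961.0)
    s = hp.summarize(_synthetic_traj(t, np.full(t.size, 1.009)))
    assert s["pct_below_baseline_at_nadir"] == 0.0
    assert s["time_to_baseline_recovery_h"] == 0.0
    assert s["deficit_auc"] == 0.0


def test_summarize_v_shape():
    t = np.arange(0.0, 961.0)
    plt0 = 1.009
    v = np.maximum(np.abs(t - 480.0) / 480.0, 0.5) * plt0
    s = hp.summarize(_synthetic_traj(t, v), baseline=plt0)
    assert s["pct_below_baseline_at_nadir"] == pytest.approx(50.0, abs=0.2)
    assert s["nadir_time_h"] == pytest.approx(480.0, abs=241.0)


def test_mk_chain_transit_time_statistics(table1):
    """The impulse response of the 10-stage aging chain has mean T_MP and
    coefficient of variation 1/sqrt(10)."""
    from scipy.integrate import solve_ivp

    n, k = table1.n_mk, table1.n_mk / table1.t_mp

    def rhs(t, y):
        d = np.empty(n)
        d[0] = -k * y[0]
        for j in range(1, n):
            d[j] = k * (y[j - 1] - y[j])
        return d

    y0 = np.zeros(n)
    y0[0] = 1.0
    t = np.linspace(0, 12 * table1.t_mp, 6001)
    sol = solve_ivp(rhs, (0, t[-1]), y0, t_eval=t, rtol=1e-10, atol=1e-13)
    outflow = k * sol.y[-1]  # exit-time density
    m0 = np.trapezoid(outflow, t)
    mean = np.trapezoid(t * outflow, t) / m0
    var = np.trapezoid((t - mean) ** 2 * outflow, t) / m0
    assert m0 == pytest.approx(1.0, rel=1e-6)
    assert mean == pytest.approx(table1.t_mp, rel=1e-4)
    assert np.sqrt(var) / mean == pytest.approx(1 / np.sqrt(10), rel=1e-3)


def test_mk_impulse_platelet_yield_equals_cf(table1):
    y = hp.mk_impulse_platelet_yield(table1)
    assert y == pytest.approx(4000.0, rel=1e-3)


def test_trajectory_frame_tidy(arm_trajectories):
    frame = arm_trajectories["epo_450"].to_frame(include_latents=True)
    assert set(frame.columns) == {"arm", "time_h", "observable", "value", "unit"}
    assert {"RBC", "HGB", "PLT", "HSPC", "MK1", "BFUE"} <= set(frame["observable"])


def test_grid_validation(table1, nominal_pk):
    reg = hp.build_study_arm("tumor_control")
    with pytest.raises(ValueError, match="within"):
        hp.SimulationSpec(reg, nominal_pk, table1, grid=np.array([0.0, 2000.0])).output_grid()
    with pytest.raises(ValueError, match="increasing"):
        hp.SimulationSpec(reg, nominal_pk, table1, grid=np.array([10.0, 5.0])).output_grid()
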