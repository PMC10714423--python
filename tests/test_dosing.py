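"""Dose-schedule construction and linear PK against closed-form oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

import hemopkpd as hp
from hemopkpd.dosing import (
    CarboplatinPK,
    EpoPK,
    HOURS_PER_DAY,
    PKParameters,
    RomiplostimPK,
    impulse_response_coeffs,
)


@pytest.mark.parametrize(
    "arm, n_carbo, n_epo, n_romi",
    [
        ("tumor_control", 0, 0, 0),
        ("carboplatin_control", 1, 0, 0),
        ("epo_450", 1, 6, 0),
        ("romi_30", 1, 0, 2),
        ("combo_450", 1, 6, 2),
    ],
)
def test_study_arm_event_counts(arm, n_carbo, n_epo, n_romi):
    reg = hp.build_study_arm(arm)
    counts = {d: len(reg.doses_for(d)[0]) for d in hp.Drug}
    assert counts[hp.Drug.CARBOPLATIN] == n_carbo
    assert counts[hp.Drug.RHUEPO] == n_epo
    assert counts[hp.Drug.ROMIPLOSTIM] == n_romi
    times = [e.time_h for e in reg.events]
    assert times == sorted(times)
    assert reg.horizon_h >= (max(times) if times else 0)


def test_carboplatin_dose_amount_and_day():
    reg = hp.build_study_arm("carboplatin_control", body_weight_kg=0.180)
    (t,), (a,) = reg.doses_for(hp.Drug.CARBOPLATIN)
    assert a == pytest.approx(60.0 * 0.180)  # 10.8 mg absolute
    assert t == 4 * HOURS_PER_DAY


def test_treatment_calendar():
    reg = hp.build_study_arm("combo_1350")
    t_epo, a_epo = reg.doses_for(hp.Drug.RHUEPO)
    assert list(t_epo / HOURS_PER_DAY) == [8, 10, 12, 15, 17, 19]
    assert np.allclose(a_epo, 1350.0 * 0.180)
    t_romi, a_romi = reg.doses_for(hp.Drug.ROMIPLOSTIM)
    assert list(t_romi / HOURS_PER_DAY) == [8, 15]
    assert np.allclose(a_romi, 30.0 * 0.180)


def test_dose_and_arm_validation():
    with pytest.raises(ValueError, match="unknown arm"):
        hp.build_study_arm("no_such_arm")
    with pytest.raises(ValueError, match="positive"):
        hp.build_study_arm("custom", epo_dose_iu_kg=-5, carboplatin=False)
    with pytest.raises(ValueError, match="amount"):
        hp.DoseEvent(hp.Drug.CARBOPLATIN, 0.0, -1.0, hp.Route.IV_BOLUS)
    with pytest.raises(ValueError, match="iv_bolus"):
        hp.DoseEvent(hp.Drug.CARBOPLATIN, 0.0, 1.0, hp.Route.SUBCUTANEOUS)
    with pytest.raises(ValueError, match="subcutaneous"):
        hp.DoseEvent(hp.Drug.ROMIPLOSTIM, 0.0, 1.0, hp.Route.IV_BOLUS)
    with pytest.raises(ValueError, match="named study arm"):
        hp.build_study_arm("epo_100", epo_dose_iu_kg=100)


def test_pk_rhs_zero_state_is_fixed_point(nominal_pk):
    assert np.all(hp.pk_rhs(np.zeros(7), 0.0, nominal_pk) == 0.0)


def test_epo_rate_constants_satisfy_flow_identity(nominal_pk):
    e = nominal_pk.epo
    assert e.k_cp * e.v4 == pytest.approx(e.q, rel=1e-14)
    assert e.k_pc * e.v5 == pytest.approx(e.q, rel=1e-14)


def test_concentration_identities(nominal_pk):
    state = np.zeros(7)
    assert hp.concentrations(state, nominal_pk) == (0.0, 0.0, 0.0)
    state[3] = nominal_pk.epo.v4  # A4 = V4 => C_EPO = 1 mIU/mL
    assert hp.concentrations(state, nominal_pk)[1] == pytest.approx(1.0)


def test_monoexponential_central_decay():
    """With negligible distribution, the central amount is A0*exp(-kel*t)."""
    tiny = 1e-12
    pk = PKParameters(
        CarboplatinPK(0.3, tiny, tiny, tiny, tiny, 0.09),
        EpoPK(0.4, 0.009, 0.006, 0.0015),
        RomiplostimPK(0.08, 0.01, 0.15),
    )
    reg = hp.Regimen("bolus", (hp.DoseEvent(hp.Drug.CARBOPLATIN, 0.0, 10.8, hp.Route.IV_BOLUS),), 48.0)
    grid = np.linspace(0, 48, 25)
    frame = hp.solve_pk(reg, pk, grid, atol=1e-16)
    conc = frame[frame.drug == "carboplatin"]["conc"].to_numpy()
    expected = 10.8 / 0.09 * np.exp(-0.3 * grid)
    np.testing.assert_allclose(conc, expected, rtol=1e-8)


def _matrix_exponential_conc(regimen, pk, grid):
    """Independent oracle: per-dose matrix-exponential superposition."""
    out = {}
    systems = {
        hp.Drug.CARBOPLATIN: (pk.carboplatin.rate_matrix(), 0, 0, pk.carboplatin.v_central),
        hp.Drug.RHUEPO: (pk.epo.rate_matrix(), 0, 0, pk.epo.v4),
        hp.Drug.ROMIPLOSTIM: (pk.romiplostim.rate_matrix(), 0, 1, pk.romiplostim.v7),
    }
    for drug, (A, i_dose, i_obs, vol) in systems.items():
        c = np.zeros(len(grid))
        times, amounts = regimen.doses_for(drug)
        for td, da in zip(times, amounts):
            for k, t in enumerate(grid):
                if t >= td:
                    e = np.zeros(A.shape[0])
                    e[i_dose] = da
                    c[k] += (expm(A * (t - td)) @ e)[i_obs] / vol
        out[drug] = c
    return out


@pytest.mark.parametrize("arm", ["carboplatin_control", "combo_450"])
def test_solve_pk_matches_matrix_exponential(arm, nominal_pk):
    reg = hp.build_study_arm(arm)
    grid = np.arange(0.0, 960.5, 24.0)
    frame = hp.solve_pk(reg, nominal_pk, grid)
    oracle = _matrix_exponential_conc(reg, nominal_pk, grid)
    for drug in hp.Drug:
        conc = frame[frame.drug == drug.value]["conc"].to_numpy()
        np.testing.assert_allclose(conc, oracle[drug], rtol=1e-6, atol=1e-9)


def test_analytic_impulse_matches_matrix_exponential(nominal_pk):
    reg = hp.build_study_arm("combo_100")
    apk = hp.AnalyticPK.build(reg, nominal_pk)
    grid = np.linspace(0, 960, 97)
    oracle = _matrix_exponential_conc(reg, nominal_pk, grid)
    np.testing.assert_allclose(apk.conc_carboplatin(grid), oracle[hp.Drug.CARBOPLATIN], rtol=1e-9, atol=1e-13)
    np.testing.assert_allclose(apk.conc_epo(grid), oracle[hp.Drug.RHUEPO], rtol=1e-9, atol=1e-13)
    np.testing.assert_allclose(apk.conc_romiplostim(grid), oracle[hp.Drug.ROMIPLOSTIM], rtol=1e-9, atol=1e-13)


def test_superposition_of_boluses(nominal_pk):
    """Linear PK: response to two boluses is the sum of single-bolus responses."""
    grid = np.arange(0.0, 400.0, 8.0)

    def conc(times):
        events = tuple(hp.DoseEvent(hp.Drug.RHUEPO, t, 81.0, hp.Route.IV_BOLUS) for t in times)
        reg = hp.Regimen("sup", events, 400.0)
        frame = hp.solve_pk(reg, nominal_pk, grid)
        return frame[frame.drug == "rHuEPO"]["conc"].to_numpy()

    np.testing.assert_allclose(conc([0.0, 48.0]), conc([0.0]) + conc([48.0]), rtol=1e-7, atol=1e-8)


def test_dose_proportionality(nominal_pk):
    grid = np.arange(0.0, 960.5, 24.0)
    reg1 = hp.build_study_arm("custom_low", epo_dose_iu_kg=100, carboplatin=False)
    reg2 = hp.build_study_arm("custom_high", epo_dose_iu_kg=1350, carboplatin=False)
    c1 = hp.solve_pk(reg1, nominal_pk, grid)
    c2 = hp.solve_pk(reg2, nominal_pk, grid)
    e1 = c1[c1.drug == "rHuEPO"]["conc"].to_numpy()
    e2 = c2[c2.drug == "rHuEPO"]["conc"].to_numpy()
    mask = e1 > 1e-6 * e1.max()  # exclude pre-dose zeros and deep tail
    np.testing.assert_allclose(e2[mask] / e1[mask], 13.5, rtol=1e-8)


def test_mass_balance_without_elimination():
    tiny = 1e-14
    pk = PKParameters(
        CarboplatinPK(tiny, 0.3, 0.15, 0.05, 0.05, 0.09),
        EpoPK(tiny, 0.009, 0.006, 0.0015),
        RomiplostimPK(0.08, tiny * 0.15, 0.15),
    )
    events = (
        hp.DoseEvent(hp.Drug.CARBOPLATIN, 0.0, 10.8, hp.Route.IV_BOLUS),
        hp.DoseEvent(hp.Drug.RHUEPO, 0.0, 81.0, hp.Route.IV_BOLUS),
        hp.DoseEvent(hp.Drug.ROMIPLOSTIM, 0.0, 5.4, hp.Route.SUBCUTANEOUS),
    )
    reg = hp.Regimen("conserve", events, 960.0)
    grid = np.array([0.0, 100.0, 500.0, 960.0])
    from scipy.integrate import solve_ivp
    from hemopkpd.dosing import pk_rhs

    y0 = np.zeros(7)
    y0[0], y0[3], y0[5] = 10.8, 81.0, 5.4
    sol = solve_ivp(lambda t, s: pk_rhs(s, t, pk), (0, 960), y0, t_eval=grid, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(sol.y[:3].sum(axis=0), 10.8, rtol=1e-8)
    np.testing.assert_allclose(sol.y[3:5].sum(axis=0), 81.0, rtol=1e-8)
    np.testing.assert_allclose(sol.y[5:7].sum(axis=0), 5.4, rtol=1e-8)


def test_stiff_and_nonstiff_integrators_agree(nominal_pk):
    reg = hp.build_study_arm("carboplatin_control")
    grid = np.arange(0.0, 960.5, 24.0)
    a = hp.solve_pk(reg, nominal_pk, grid, method="LSODA")
    b = hp.solve_pk(reg, nominal_pk, grid, method="Radau")
    np.testing.assert_allclose(a["conc"], b["conc"], rtol=1e-6, atol=1e-8)


def test_nonnegative_amounts_on_all_arms(arm_trajectories):
    for arm, traj in arm_trajectories.items():
        for key in ("C_CAR", "C_EPO", "C_ROM"):
            assert np.all(traj.latents[key] >= 0), f"{key} negative on {arm}"


def test_defective_romiplostim_kinetics_rejected():
    with pytest.raises(ValueError, match="coincide"):
        RomiplostimPK(ka=0.08, cl=0.012, v7=0.15)


def test_impulse_response_coeffs_reject_complex():
    rot = np.array([[0.0, -1.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match="complex"):
        impulse_response_coeffs(rot)
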