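"""Numba kernel for the fast PD integration path.

The disposition of all three drugs is linear, so their central
concentrations are evaluated in closed form (dose-superposed sums of
exponentials) inside the integrator instead of carrying PK states.  The PD
system is advanced with a fixed-step classical Runge-Kutta scheme between
dose times (the only discontinuities of the forcing); the per-segment active
dose counts are precomputed so a dose contributes exactly from its own time
onward and never leaks into the preceding step.

State layout (must match ``hematopoiesis.state_index``):
``[HSPC, BFUE, CFUE, EP*n_ep, RET, MRBC, MK*n_mk, PLT*n_plt, C_eff]``.

Parameter vector layout (see ``pack_params`` in ``simulate``):
``[kill, KE, KM, Kin1, T_EP, T_RET, T_RBC, T_MP, T_PLT, Smax_ROM1,
Smax_ROM2, Smax_PLT1, Smax_PLT2, Smax_EPO, SC50_EPO, Ke0, PLT0, CF,
2**MCFU, 2**MNOR]``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rk4_simulate"]


@njit(cache=False)
def _conc(t, lam, alpha, dose_t, dose_a, n_active):
    c = 0.0
    for i in range(n_active):
        dt = t - dose_t[i]
        s = 0.0
        for j in range(lam.size):
            s += alpha[j] * np.exp(lam[j] * dt)
        c += dose_a[i] * s
    return c


@njit(cache=False)
def _pd_rhs(y, dy, p, n_ep, n_mk, n_plt, c_car, c_epo, c_rom):
    kill = p[0]
    ke = p[1]
    km = p[2]
    kin1 = p[3]
    t_ep = p[4]
    t_ret = p[5]
    t_rbc = p[6]
    t_mp = p[7]
    t_plt = p[8]
    s_r1 = p[9]
    s_r2 = p[10]
    s_p1 = p[11]
    s_p2 = p[12]
    smax_e = p[13]
    sc50 = p[14]
    ke0 = p[15]
    plt0 = p[16]
    cf = p[17]
    amp_cfu = p[18]
    amp_nor = p[19]

    i_ret = 3 + n_ep
    i_mrbc = i_ret + 1
    i_mk = i_mrbc + 1
    i_plt = i_mk + n_mk
    i_ceff = i_plt + n_plt

    c_eff = y[i_ceff]
    plt_sum = 0.0
    for j in range(n_plt):
        plt_sum += y[i_plt + j]
    dplt = plt0 - plt_sum

    surv = 1.0 - kill * c_eff
    if surv < 0.0:
        surv = 0.0
    dp = dplt if dplt > 0.0 else 0.0
    fb1 = 1.0 + s_p1 * dp
    fb2 = 1.0 + s_p2 * dp
    epo_st = 1.0 + smax_e * c_epo / (sc50 + c_epo)
    rom1 = 1.0 + s_r1 * c_rom
    rom2 = 1.0 + s_r2 * c_rom

    hspc = y[0]
    to_ery = ke * epo_st * surv * hspc
    to_mk = km * rom2 * fb2 * surv * hspc
    dy[0] = kin1 * rom1 * fb1 * surv - to_ery - to_mk
    dy[1] = to_ery - y[1] / t_ep
    dy[2] = amp_cfu * y[1] / t_ep - y[2] / t_ep
    k_ep = n_ep / t_ep
    dy[3] = amp_nor * y[2] / t_ep - k_ep * y[3]
    for j in range(1, n_ep):
        dy[3 + j] = k_ep * (y[3 + j - 1] - y[3 + j])
    dy[i_ret] = k_ep * y[3 + n_ep - 1] - y[i_ret] / t_ret
    dy[i_mrbc] = y[i_ret] / t_ret - y[i_mrbc] / t_rbc

    k_mk = n_mk / t_mp
    apop = kill * c_eff / t_mp
    dy[i_mk] = to_mk - (k_mk + apop) * y[i_mk]
    for j in range(1, n_mk):
        dy[i_mk + j] = k_mk * y[i_mk + j - 1] - (k_mk + apop) * y[i_mk + j]
    k_p = n_plt / t_plt
    dy[i_plt] = cf * k_mk * y[i_mk + n_mk - 1] - k_p * y[i_plt]
    for j in range(1, n_plt):
        dy[i_plt + j] = k_p * (y[i_plt + j - 1] - y[i_plt + j])
    dy[i_ceff] = ke0 * (c_car - c_eff)


@njit(cache=False)
def rk4_simulate(
    bounds,
    out_slot,
    dt_max,
    y0,
    p,
    n_ep,
    n_mk,
    n_plt,
    lam_c, al_c, t_c, a_c, nact_c,
    lam_e, al_e, t_e, a_e, nact_e,
    lam_r, al_r, t_r, a_r, nact_r,
):
    """Advance the PD state across ``bounds`` and collect output states.

    ``bounds`` is the sorted union of dose times and requested output times;
    ``out_slot[i]`` is the output row for ``bounds[i]`` or -1.  ``nact_*[s]``
    is the number of doses active throughout segment ``s``.
    """
    nstate = y0.size
    n_out = 0
    for i in range(out_slot.size):
        if out_slot[i] >= 0:
            n_out += 1
    out = np.zeros((n_out, nstate))
    y = y0.copy()
    k1 = np.empty(nstate)
    k2 = np.empty(nstate)
    k3 = np.empty(nstate)
    k4 = np.empty(nstate)
    yt = np.empty(nstate)

    if out_slot[0] >= 0:
        out[out_slot[0], :] = y

    for s in range(bounds.size - 1):
        t0 = bounds[s]
        t1 = bounds[s + 1]
        span = t1 - t0
        if span > 0.0:
            n = int(np.ceil(span / dt_max))
            if n < 1:
                n = 1
            h = span / n
            for m in range(n):
                ta = t0 + m * h
                tm = ta + 0.5 * h
                tb = ta + h
                cc = _conc(ta, lam_c, al_c, t_c, a_c, nact_c[s])
                ce = _conc(ta, lam_e, al_e, t_e, a_e, nact_e[s])
                cr = _conc(ta, lam_r, al_r, t_r, a_r, nact_r[s])
                _pd_rhs(y, k1, p, n_ep, n_mk, n_plt, cc, ce, cr)
                cc = _conc(tm, lam_c, al_c, t_c, a_c, nact_c[s])
                ce = _conc(tm, lam_e, al_e, t_e, a_e, nact_e[s])
                cr = _conc(tm, lam_r, al_r, t_r, a_r, nact_r[s])
                for i in range(nstate):
                    yt[i] = y[i] + 0.5 * h * k1[i]
                _pd_rhs(yt, k2, p, n_ep, n_mk, n_plt, cc, ce, cr)
                for i in range(nstate):
                    yt[i] = y[i] + 0.5 * h * k2[i]
                _pd_rhs(yt, k3, p, n_ep, n_mk, n_plt, cc, ce, cr)
                cc = _conc(tb, lam_c, al_c, t_c, a_c, nact_c[s])
                ce = _conc(tb, lam_e, al_e, t_e, a_e, nact_e[s])
                cr = _conc(tb, lam_r, al_r, t_r, a_r, nact_r[s])
                for i in range(nstate):
                    yt[i] = y[i] + h * k3[i]
                _pd_rhs(yt, k4, p, n_ep, n_mk, n_plt, cc, ce, cr)
                for i in range(nstate):
                    y[i] = y[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        if out_slot[s + 1] >= 0:
            out[out_slot[s + 1], :] = y
    return out
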