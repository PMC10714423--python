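"""Catenary lifespan model of erythropoiesis and thrombopoiesis.

The latent system is a shared hematopoietic stem/progenitor (HSPC) pool
feeding two lineages:

* erythroid: HSPC -> BFU-E -> CFU-E -> precursors (normoblasts) -> RET ->
  mature RBC, with mitotic amplification ``2**MCFU`` at BFU-E -> CFU-E and
  ``2**MNOR`` at CFU-E -> precursor, and lifespan-based transit (mean
  residence times T_EP, T_RET, T_RBC);
* megakaryocytic: HSPC -> MK1..MK10 aging chain (mean lifespan T_MP) ->
  platelet chain PLT1..PLT10 (mean lifespan T_PLT), with CF platelets shed
  per megakaryocyte.

Drug effects:

* carboplatin acts through an effect compartment (equilibration rate Ke0);
  the survival factor ``1 - kill*C_eff`` multiplies HSPC production and both
  differentiation branches, and ``kill*C_eff`` additionally scales an
  apoptotic loss on the MK chain;
* rHuEPO stimulates HSPC -> BFU-E differentiation with an Emax function
  (Smax_EPO, SC50_EPO);
* romiplostim linearly stimulates HSPC production (Smax_ROM1) and
  HSPC -> MK differentiation (Smax_ROM2);
* endogenous thrombopoietin feedback is represented by the platelet deficit
  dPLT = PLT0 - PLT(t) acting linearly on HSPC production (Smax_PLT1) and on
  HSPC -> MK differentiation (Smax_PLT2); the stimulus is one-sided (active
  only while platelets are below baseline), which keeps the drug-free
  steady state stable at the reported feedback slopes.

Observables are derived, never stored: RBC = RET + MRBC (analyzers count
reticulocytes within RBC), HGB = MCH * RBC / 10 (the 10 converts pg/cell x
10^12 cells/L to g/dL), PLT = sum of the platelet chain.

Zero-order HSPC production (Kin1), the HSPC -> MK rate constant (KM) and all
latent baselines are secondary parameters fixed by the steady state of the
drug-free system given the observable baselines (RBC0, PLT0) — see
:func:`solve_baselines`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np

N_MK = 10
N_PLT = 10
CONVERSION_FACTOR = 4000.0  # platelets produced per megakaryocyte


@dataclass(frozen=True)
class PDParameters:
    """Structural and residual-error parameters of the PD system.

    Units: lifespans in h, rate constants in 1/h, ``kill`` in mL/µg,
    ``sc50_epo`` in mIU/mL, ``smax_rom*`` per (ng/mL), ``smax_plt*`` per
    (10^12 cells/L), ``mch`` in pg/cell, cell counts in 10^12 cells/L.
    """

    kill: float
    rbc0: float
    t_ret: float
    t_rbc: float
    plt0: float
    t_mp: float
    t_plt: float
    ke: float
    mch: float
    smax_rom1: float
    smax_rom2: float
    smax_plt1: float
    smax_plt2: float
    smax_epo: float
    sc50_epo: float
    ke0: float
    # residual error model (per observable): Y = Yhat*(1+eps1) + eps2
    sigma_plt1: float = 0.0
    sigma_plt2: float = 0.0
    sigma_rbc: float = 0.0
    sigma_hgb: float = 0.0
    # fixed structural constants
    mcfu: float = 5.0  # BFU-E -> CFU-E amplification exponent
    mnor: float = 4.0  # CFU-E -> normoblast amplification exponent
    cf: float = CONVERSION_FACTOR
    t_ep: float | None = None  # defaults to t_ret (tied)
    n_ep: int = 1  # transit sub-compartments representing the precursor stage
    n_mk: int = N_MK
    n_plt: int = N_PLT

    def __post_init__(self) -> None:
        for name in ("t_ret", "t_rbc", "t_mp", "t_plt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"lifespan {name} must be > 0")
        if self.ke <= 0:
            raise ValueError("KE must be > 0: no erythroid flux can sustain RBC0 > 0")
        if self.sc50_epo <= 0:
            raise ValueError("SC50_EPO must be > 0")
        if self.rbc0 <= 0 or self.plt0 <= 0:
            raise ValueError("baselines RBC0, PLT0 must be > 0")
        if self.kill < 0 or self.ke0 <= 0:
            raise ValueError("kill must be >= 0 and Ke0 > 0")
        for name in ("sigma_plt1", "sigma_plt2", "sigma_rbc", "sigma_hgb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_ep < 1 or self.n_mk < 1 or self.n_plt < 1:
            raise ValueError("chain lengths must be >= 1")

    @property
    def t_ep_effective(self) -> float:
        return self.t_ret if self.t_ep is None else self.t_ep

    @property
    def amplification(self) -> float:
        return 2.0 ** (self.mcfu + self.mnor)

    def with_updates(self, **kwargs: float) -> "PDParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PDDerived:
    """Secondary parameters and the drug-free steady state."""

    kin1: float          # zero-order HSPC production (10^12 cells/L/h)
    km: float            # HSPC -> MK differentiation rate (1/h)
    hspc0: float
    bfue0: float
    cfue0: float
    ep0: np.ndarray      # precursor (normoblast) sub-compartments
    ret0: float
    mrbc0: float
    mk0: np.ndarray
    plt_i0: np.ndarray
    hgb0: float

    def baseline_state(self, params: PDParameters) -> np.ndarray:
        """Full latent state vector at baseline (effect compartment at 0)."""
        return np.concatenate(
            [
                [self.hspc0, self.bfue0, self.cfue0],
                self.ep0,
                [self.ret0, self.mrbc0],
                self.mk0,
                self.plt_i0,
                [0.0],  # C_eff
            ]
        )


def state_size(params: PDParameters) -> int:
    return 5 + params.n_ep + params.n_mk + params.n_plt + 1


def state_index(params: PDParameters) -> dict[str, int | slice]:
    n_ep, n_mk, n_plt = params.n_ep, params.n_mk, params.n_plt
    i = 3 + n_ep
    return {
        "hspc": 0,
        "bfue": 1,
        "cfue": 2,
        "ep": slice(3, 3 + n_ep),
        "ret": i,
        "mrbc": i + 1,
        "mk": slice(i + 2, i + 2 + n_mk),
        "plt": slice(i + 2 + n_mk, i + 2 + n_mk + n_plt),
        "c_eff": i + 2 + n_mk + n_plt,
    }


def solve_baselines(params: PDParameters) -> PDDerived:
    """Secondary parameters from steady state of the drug-free system.

    The observable baselines anchor the fluxes: the erythroid production
    flux is ``RBC0/(T_RET + T_RBC)`` (reticulocytes are counted within RBC),
    and the platelet production flux is ``PLT0/T_PLT``; dividing the latter
    by CF gives the megakaryocyte flux.  Walking both chains upstream yields
    every latent baseline, HSPC0, KM and Kin1.  The returned baselines make
    the drug-free right-hand side identically zero.
    """
    t_ep = params.t_ep_effective
    flux_rbc = params.rbc0 / (params.t_ret + params.t_rbc)  # cells/h into RET
    ret0 = flux_rbc * params.t_ret
    mrbc0 = flux_rbc * params.t_rbc
    hspc0 = flux_rbc / (params.ke * params.amplification)
    bfue0 = params.ke * hspc0 * t_ep
    cfue0 = (2.0 ** params.mcfu) * params.ke * hspc0 * t_ep
    ep0 = np.full(params.n_ep, flux_rbc * t_ep / params.n_ep)

    flux_plt = params.plt0 / params.t_plt
    flux_mk = flux_plt / params.cf
    km = flux_mk / hspc0
    mk0 = np.full(params.n_mk, flux_mk * params.t_mp / params.n_mk)
    plt_i0 = np.full(params.n_plt, params.plt0 / params.n_plt)
    kin1 = (params.ke + km) * hspc0
    if km <= 0 or not np.isfinite(km):
        raise ValueError(f"infeasible parameters: implied KM = {km}")
    return PDDerived(
        kin1=kin1, km=km, hspc0=hspc0, bfue0=bfue0, cfue0=cfue0, ep0=ep0,
        ret0=ret0, mrbc0=mrbc0, mk0=mk0, plt_i0=plt_i0,
        hgb0=params.mch * params.rbc0 / 10.0,
    )


# ---------------------------------------------------------------------------
# Drug-effect factors (each behind a named function so the wiring of any one
# factor is a one-line change)
# ---------------------------------------------------------------------------


def carboplatin_survival(c_eff: float, kill: float) -> float:
    """Linear inhibition ``1 - kill*C_eff``, floored at 0 (no negative rates)."""
    return max(0.0, 1.0 - kill * c_eff)


def epo_stimulus(c_epo: float, smax_epo: float, sc50_epo: float) -> float:
    """Emax stimulation of HSPC -> BFU-E differentiation by rHuEPO."""
    return 1.0 + smax_epo * c_epo / (sc50_epo + c_epo)


def rom_stimulus(c_rom: float, smax: float) -> float:
    """Linear stimulation by romiplostim serum concentration."""
    return 1.0 + smax * c_rom


def plt_feedback(delta_plt: float, smax: float) -> float:
    """Linear stimulation by the platelet deficit dPLT = PLT0 - PLT.

    One-sided: the thrombopoietin-like stimulus acts only while platelets
    are below baseline (surplus platelets do not actively suppress
    hematopoiesis beyond the loss of the deficit stimulus).
    """
    return 1.0 + smax * max(0.0, delta_plt)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------


def effect_compartment_rhs(c_eff: float, c_car: float, ke0: float) -> float:
    """First-order equilibration of the carboplatin effect site with plasma."""
    return ke0 * (c_car - c_eff)


def hspc_rhs(
    hspc: float,
    c_rom: float,
    c_epo: float,
    c_eff: float,
    delta_plt: float,
    params: PDParameters,
    derived: PDDerived,
) -> float:
    surv = carboplatin_survival(c_eff, params.kill)
    production = (
        derived.kin1
        * rom_stimulus(c_rom, params.smax_rom1)
        * plt_feedback(delta_plt, params.smax_plt1)
        * surv
    )
    to_erythroid = params.ke * epo_stimulus(c_epo, params.smax_epo, params.sc50_epo) * surv * hspc
    to_mk = (
        derived.km
        * rom_stimulus(c_rom, params.smax_rom2)
        * plt_feedback(delta_plt, params.smax_plt2)
        * surv
        * hspc
    )
    return production - to_erythroid - to_mk


def erythroid_chain_rhs(
    bfue: float,
    cfue: float,
    ep: np.ndarray,
    ret: float,
    mrbc: float,
    hspc: float,
    c_epo: float,
    c_eff: float,
    params: PDParameters,
) -> tuple[float, float, np.ndarray, float, float]:
    """Derivatives of the erythroid chain given the upstream HSPC state."""
    t_ep = params.t_ep_effective
    surv = carboplatin_survival(c_eff, params.kill)
    inflow = params.ke * epo_stimulus(c_epo, params.smax_epo, params.sc50_epo) * surv * hspc
    d_bfue = inflow - bfue / t_ep
    d_cfue = (2.0 ** params.mcfu) * bfue / t_ep - cfue / t_ep
    k_ep = params.n_ep / t_ep
    d_ep = np.empty_like(ep)
    d_ep[0] = (2.0 ** params.mnor) * cfue / t_ep - k_ep * ep[0]
    for j in range(1, params.n_ep):
        d_ep[j] = k_ep * (ep[j - 1] - ep[j])
    d_ret = k_ep * ep[-1] - ret / params.t_ret
    d_mrbc = ret / params.t_ret - mrbc / params.t_rbc
    return d_bfue, d_cfue, d_ep, d_ret, d_mrbc


def mk_platelet_rhs(
    mk: np.ndarray,
    plt: np.ndarray,
    hspc: float,
    c_rom: float,
    c_eff: float,
    delta_plt: float,
    params: PDParameters,
    derived: PDDerived,
) -> tuple[np.ndarray, np.ndarray]:
    """Derivatives of the megakaryocyte aging chain and platelet chain.

    Carboplatin-stimulated apoptosis removes MK cells at the extra
    first-order rate ``kill * C_eff / T_MP`` in every aging compartment (the
    dimensionless drug effect scales the pool turnover rate 1/T_MP); the
    apoptotic flux is lost, not transferred downstream.
    """
    surv = carboplatin_survival(c_eff, params.kill)
    k_mk = params.n_mk / params.t_mp
    k_plt = params.n_plt / params.t_plt
    apop = params.kill * c_eff / params.t_mp
    inflow = (
        derived.km
        * rom_stimulus(c_rom, params.smax_rom2)
        * plt_feedback(delta_plt, params.smax_plt2)
        * surv
        * hspc
    )
    d_mk = np.empty_like(mk)
    d_mk[0] = inflow - (k_mk + apop) * mk[0]
    for j in range(1, params.n_mk):
        d_mk[j] = k_mk * mk[j - 1] - (k_mk + apop) * mk[j]
    d_plt = np.empty_like(plt)
    d_plt[0] = params.cf * k_mk * mk[-1] - k_plt * plt[0]
    for j in range(1, params.n_plt):
        d_plt[j] = k_plt * (plt[j - 1] - plt[j])
    return d_mk, d_plt


def full_rhs(
    t: float,
    state: np.ndarray,
    c_car: float,
    c_epo: float,
    c_rom: float,
    params: PDParameters,
    derived: PDDerived,
) -> np.ndarray:
    """Assembled PD right-hand side (pure function of states and inputs)."""
    idx = state_index(params)
    hspc = state[idx["hspc"]]
    bfue = state[idx["bfue"]]
    cfue = state[idx["cfue"]]
    ep = state[idx["ep"]]
    ret = state[idx["ret"]]
    mrbc = state[idx["mrbc"]]
    mk = state[idx["mk"]]
    plt = state[idx["plt"]]
    c_eff = state[idx["c_eff"]]
    delta_plt = params.plt0 - float(np.sum(plt))

    d = np.empty_like(state)
    d[idx["hspc"]] = hspc_rhs(hspc, c_rom, c_epo, c_eff, delta_plt, params, derived)
    d_bfue, d_cfue, d_ep, d_ret, d_mrbc = erythroid_chain_rhs(
        bfue, cfue, ep, ret, mrbc, hspc, c_epo, c_eff, params
    )
    d[idx["bfue"]] = d_bfue
    d[idx["cfue"]] = d_cfue
    d[idx["ep"]] = d_ep
    d[idx["ret"]] = d_ret
    d[idx["mrbc"]] = d_mrbc
    d_mk, d_plt = mk_platelet_rhs(mk, plt, hspc, c_rom, c_eff, delta_plt, params, derived)
    d[idx["mk"]] = d_mk
    d[idx["plt"]] = d_plt
    d[idx["c_eff"]] = effect_compartment_rhs(c_eff, c_car, params.ke0)
    return d


def observables_from_state(state: np.ndarray, params: PDParameters) -> tuple[float, float, float]:
    """(RBC, HGB, PLT) derived from one latent state vector."""
    idx = state_index(params)
    rbc = state[idx["ret"]] + state[idx["mrbc"]]
    hgb = params.mch * rbc / 10.0
    plt = float(np.sum(state[idx["plt"]]))
    return float(rbc), float(hgb), plt


def steady_state_residual(params: PDParameters, derived: PDDerived | None = None) -> float:
    """Max relative drug-free RHS magnitude at the solved baselines."""
    if derived is None:
        derived = solve_baselines(params)
    y0 = derived.baseline_state(params)
    rhs = full_rhs(0.0, y0, 0.0, 0.0, 0.0, params, derived)
    scale = np.where(np.abs(y0) > 0, np.abs(y0), 1.0)
    # normalize by state magnitude over its slowest turnover time
    tmax = max(params.t_rbc, params.t_plt, params.t_mp, params.t_ep_effective)
    return float(np.max(np.abs(rhs) * tmax / scale))
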