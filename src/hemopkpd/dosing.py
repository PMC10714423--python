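"""Dosing regimens and drug disposition (pharmacokinetics).

Three drugs drive the hematopoiesis model:

* carboplatin — single i.v. bolus, three-compartment mammillary disposition;
* rHuEPO — repeated i.v. boluses, two-compartment disposition parameterized
  by clearance/volumes (``K_CP = Q/V4``, ``K_PC = Q/V5``);
* romiplostim — subcutaneous doses, one-compartment disposition with
  first-order absorption from a depot; bioavailability is absorbed into the
  apparent clearance ``CL_R`` and volume ``V7``.

All disposition is linear, so concentration-time profiles are superpositions
of per-dose impulse responses, each a sum of exponentials obtained from the
eigendecomposition of the (small) rate matrix.  Both that closed form and a
plain ODE right-hand side (for the coupled PK-PD integrator) are provided.

Unit conventions (amounts are absolute, volumes in litres):

=============  ============  ============  ===================
drug           dose unit     amount unit   concentration unit
=============  ============  ============  ===================
carboplatin    mg/kg         mg            mg/L  = µg/mL
rHuEPO         IU/kg         IU            IU/L  = mIU/mL
romiplostim    µg/kg         µg            µg/L  = ng/mL
=============  ============  ============  ===================

Time is in hours; t = 0 is pharmacodynamic sampling day 0 (tumor
inoculation), carboplatin is given on day 4 and the supportive drugs start
on day 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

HOURS_PER_DAY = 24.0

#: study calendar (hours): carboplatin on day 4, supportive therapy from day 8
CARBOPLATIN_DAY = 4
TREATMENT_START_DAY = 8
#: thrice-weekly grid (days after first treatment dose), Mon/Wed/Fri x 2 weeks
TIW_OFFSET_DAYS = (0, 2, 4, 7, 9, 11)
#: once-weekly grid (days after first treatment dose)
QW_OFFSET_DAYS = (0, 7)

STUDY_HORIZON_H = 40 * HOURS_PER_DAY

DEFAULT_BODY_WEIGHT_KG = 0.180  # midpoint of the 160-200 g rats used

CARBOPLATIN_DOSE_MG_PER_KG = 60.0
ROMIPLOSTIM_DOSE_UG_PER_KG = 30.0
EPO_DOSE_LEVELS_IU_PER_KG = (100.0, 450.0, 1350.0)


class Drug(str, Enum):
    CARBOPLATIN = "carboplatin"
    RHUEPO = "rHuEPO"
    ROMIPLOSTIM = "romiplostim"


class Route(str, Enum):
    IV_BOLUS = "iv_bolus"
    SUBCUTANEOUS = "subcutaneous"


_ALLOWED_ROUTE = {
    Drug.CARBOPLATIN: Route.IV_BOLUS,
    Drug.RHUEPO: Route.IV_BOLUS,
    Drug.ROMIPLOSTIM: Route.SUBCUTANEOUS,
}


@dataclass(frozen=True)
class DoseEvent:
    """A single timed administration.

    ``amount`` is the absolute amount (dose in drug-native units per kg,
    multiplied by body weight), see the module-level unit table.
    """

    drug: Drug
    time_h: float
    amount: float
    route: Route

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time_h}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if _ALLOWED_ROUTE[self.drug] is not self.route:
            raise ValueError(
                f"{self.drug.value} must be given {_ALLOWED_ROUTE[self.drug].value}, "
                f"got {self.route.value}"
            )


@dataclass(frozen=True)
class Regimen:
    """An ordered dose schedule for one treatment arm."""

    arm_name: str
    events: tuple[DoseEvent, ...]
    horizon_h: float = STUDY_HORIZON_H

    def __post_init__(self) -> None:
        times = [e.time_h for e in self.events]
        if times != sorted(times):
            object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.time_h)))
        if self.events and self.horizon_h < max(e.time_h for e in self.events):
            raise ValueError("horizon must cover the last dose event")

    def doses_for(self, drug: Drug) -> tuple[np.ndarray, np.ndarray]:
        """(times, amounts) arrays for one drug, sorted by time."""
        ev = [e for e in self.events if e.drug is drug]
        t = np.array([e.time_h for e in ev], dtype=float)
        a = np.array([e.amount for e in ev], dtype=float)
        return t, a


# The 9 study arms: tumor control, carboplatin control, three rHuEPO dose
# levels, romiplostim, and the three combinations.  All treated arms receive
# the single carboplatin dose.
STUDY_ARMS = (
    "tumor_control",
    "carboplatin_control",
    "epo_100",
    "epo_450",
    "epo_1350",
    "romi_30",
    "combo_100",
    "combo_450",
    "combo_1350",
)

_ARM_SPECS: dict[str, tuple[float | None, float | None, bool]] = {
    "tumor_control": (None, None, False),
    "carboplatin_control": (None, None, True),
    "epo_100": (100.0, None, True),
    "epo_450": (450.0, None, True),
    "epo_1350": (1350.0, None, True),
    "romi_30": (None, ROMIPLOSTIM_DOSE_UG_PER_KG, True),
    "combo_100": (100.0, ROMIPLOSTIM_DOSE_UG_PER_KG, True),
    "combo_450": (450.0, ROMIPLOSTIM_DOSE_UG_PER_KG, True),
    "combo_1350": (1350.0, ROMIPLOSTIM_DOSE_UG_PER_KG, True),
}


def build_study_arm(
    arm_name: str,
    epo_dose_iu_kg: float | None = None,
    romi_dose_ug_kg: float | None = None,
    carboplatin: bool | None = None,
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG,
    horizon_h: float = STUDY_HORIZON_H,
) -> Regimen:
    """Construct the dose schedule of a named study arm (or a custom one).

    For the nine named arms the drug assignment is looked up and the explicit
    dose arguments must be omitted; for a custom ``arm_name`` they are taken
    as given.  Doses are per kg and scaled by ``body_weight_kg``.
    """
    if not 0.05 <= body_weight_kg <= 1.0:
        raise ValueError(f"implausible rat body weight {body_weight_kg} kg")
    if arm_name in _ARM_SPECS:
        if epo_dose_iu_kg is not None or romi_dose_ug_kg is not None or carboplatin is not None:
            raise ValueError(f"{arm_name!r} is a named study arm; do not pass custom doses")
        epo_dose_iu_kg, romi_dose_ug_kg, carboplatin = _ARM_SPECS[arm_name]
    elif carboplatin is None:
        raise ValueError(f"unknown arm {arm_name!r}; known arms: {', '.join(STUDY_ARMS)}")
    for d in (epo_dose_iu_kg, romi_dose_ug_kg):
        if d is not None and d <= 0:
            raise ValueError(f"dose must be positive, got {d}")

    events: list[DoseEvent] = []
    if carboplatin:
        events.append(
            DoseEvent(
                Drug.CARBOPLATIN,
                CARBOPLATIN_DAY * HOURS_PER_DAY,
                CARBOPLATIN_DOSE_MG_PER_KG * body_weight_kg,
                Route.IV_BOLUS,
            )
        )
    start = TREATMENT_START_DAY * HOURS_PER_DAY
    if epo_dose_iu_kg is not None:
        amount_iu = epo_dose_iu_kg * body_weight_kg  # IU (C comes out in mIU/mL)
        for off in TIW_OFFSET_DAYS:
            events.append(DoseEvent(Drug.RHUEPO, start + off * HOURS_PER_DAY, amount_iu, Route.IV_BOLUS))
    if romi_dose_ug_kg is not None:
        amount_ug = romi_dose_ug_kg * body_weight_kg
        for off in QW_OFFSET_DAYS:
            events.append(
                DoseEvent(Drug.ROMIPLOSTIM, start + off * HOURS_PER_DAY, amount_ug, Route.SUBCUTANEOUS)
            )
    return Regimen(arm_name, tuple(sorted(events, key=lambda e: e.time_h)), horizon_h)


# ---------------------------------------------------------------------------
# PK parameter sets
# ---------------------------------------------------------------------------


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class CarboplatinPK:
    """Three-compartment i.v. disposition (rate-constant parameterization)."""

    k_el: float  # 1/h
    k_cp1: float
    k_pc1: float
    k_cp2: float
    k_pc2: float
    v_central: float  # L

    def __post_init__(self) -> None:
        _require_positive(
            k_el=self.k_el, k_cp1=self.k_cp1, k_pc1=self.k_pc1,
            k_cp2=self.k_cp2, k_pc2=self.k_pc2, v_central=self.v_central,
        )

    def rate_matrix(self) -> np.ndarray:
        return np.array(
            [
                [-(self.k_el + self.k_cp1 + self.k_cp2), self.k_pc1, self.k_pc2],
                [self.k_cp1, -self.k_pc1, 0.0],
                [self.k_cp2, 0.0, -self.k_pc2],
            ]
        )


@dataclass(frozen=True)
class EpoPK:
    """Two-compartment i.v. disposition, clearance/volume parameterization."""

    k_el: float  # 1/h, elimination from the central compartment
    v4: float    # L, central volume
    v5: float    # L, peripheral volume
    q: float     # L/h, intercompartmental flow

    def __post_init__(self) -> None:
        _require_positive(k_el=self.k_el, v4=self.v4, v5=self.v5, q=self.q)

    @property
    def k_cp(self) -> float:
        return self.q / self.v4

    @property
    def k_pc(self) -> float:
        return self.q / self.v5

    def rate_matrix(self) -> np.ndarray:
        return np.array(
            [
                [-(self.k_el + self.k_cp), self.k_pc],
                [self.k_cp, -self.k_pc],
            ]
        )


@dataclass(frozen=True)
class RomiplostimPK:
    """One-compartment disposition with first-order absorption (apparent)."""

    ka: float  # 1/h
    cl: float  # L/h, apparent clearance CL/F
    v7: float  # L, apparent central volume V/F

    def __post_init__(self) -> None:
        _require_positive(ka=self.ka, cl=self.cl, v7=self.v7)
        if abs(self.ka - self.k_el) < 1e-9:
            raise ValueError("ka and CL/V7 coincide (defective kinetics); perturb one")

    @property
    def k_el(self) -> float:
        return self.cl / self.v7

    def rate_matrix(self) -> np.ndarray:
        # state = (depot A6, central A7)
        return np.array([[-self.ka, 0.0], [self.ka, -self.k_el]])


@dataclass(frozen=True)
class PKParameters:
    carboplatin: CarboplatinPK
    epo: EpoPK
    romiplostim: RomiplostimPK


# PK state layout: A1..A3 carboplatin, A4..A5 rHuEPO, A6 depot / A7 central
# romiplostim.  Initial A2 = A3 = A7 = 0 (and everything else 0 pre-dose).
N_PK_STATES = 7


def pk_rhs(state: np.ndarray, t: float, params: PKParameters) -> np.ndarray:
    """Time-derivative of the 7 PK amounts (pure function; doses are jumps)."""
    a1, a2, a3, a4, a5, a6, a7 = state
    c = params.carboplatin
    e = params.epo
    r = params.romiplostim
    return np.array(
        [
            -(c.k_el + c.k_cp1 + c.k_cp2) * a1 + c.k_pc1 * a2 + c.k_pc2 * a3,
            c.k_cp1 * a1 - c.k_pc1 * a2,
            c.k_cp2 * a1 - c.k_pc2 * a3,
            -(e.k_el + e.k_cp) * a4 + e.k_pc * a5,
            e.k_cp * a4 - e.k_pc * a5,
            -r.ka * a6,
            r.ka * a6 - r.k_el * a7,
        ]
    )


def concentrations(state: np.ndarray, params: PKParameters) -> tuple[float, float, float]:
    """Central-compartment concentrations (C_CAR µg/mL, C_EPO mIU/mL, C_ROM ng/mL)."""
    return (
        state[0] / params.carboplatin.v_central,
        state[3] / params.epo.v4,
        state[6] / params.romiplostim.v7,
    )


# ---------------------------------------------------------------------------
# Closed-form impulse responses (linear disposition => sums of exponentials)
# ---------------------------------------------------------------------------


def impulse_response_coeffs(
    matrix: np.ndarray, dose_idx: int = 0, obs_idx: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Exponents and weights of the unit-bolus response of a linear system.

    Returns ``(lam, alpha)`` such that the observed compartment's amount after
    a unit bolus into ``dose_idx`` is ``sum_j alpha_j * exp(lam_j * t)``.
    Mammillary/absorption rate matrices have real, distinct eigenvalues in
    the parameter ranges used here; near-defective matrices are rejected.
    """
    lam, vecs = np.linalg.eig(matrix)
    if np.max(np.abs(lam.imag)) > 1e-10 * (1 + np.max(np.abs(lam.real))):
        raise ValueError("complex eigenvalues: not a valid disposition matrix")
    cond = np.linalg.cond(vecs)
    if cond > 1e10:
        raise ValueError("near-defective rate matrix (repeated eigenvalues)")
    e = np.zeros(matrix.shape[0])
    e[dose_idx] = 1.0
    w = np.linalg.solve(vecs, e)
    alpha = (vecs[obs_idx, :] * w).real
    return lam.real.astype(float), alpha.astype(float)


@dataclass(frozen=True)
class AnalyticPK:
    """Per-drug exponential impulse responses for one regimen.

    ``conc_*`` give central concentrations by dose superposition; a dose at
    time ``t_d`` contributes for ``t >= t_d`` (right-continuous profiles).
    """

    lam_car: np.ndarray
    alpha_car: np.ndarray  # concentration per unit amount
    t_car: np.ndarray
    a_car: np.ndarray
    lam_epo: np.ndarray
    alpha_epo: np.ndarray
    t_epo: np.ndarray
    a_epo: np.ndarray
    lam_rom: np.ndarray
    alpha_rom: np.ndarray
    t_rom: np.ndarray
    a_rom: np.ndarray

    @classmethod
    def build(cls, regimen: Regimen, params: PKParameters) -> "AnalyticPK":
        lam_c, al_c = impulse_response_coeffs(params.carboplatin.rate_matrix())
        lam_e, al_e = impulse_response_coeffs(params.epo.rate_matrix())
        lam_r, al_r = impulse_response_coeffs(params.romiplostim.rate_matrix(), dose_idx=0, obs_idx=1)
        tc, ac = regimen.doses_for(Drug.CARBOPLATIN)
        te, ae = regimen.doses_for(Drug.RHUEPO)
        tr, ar = regimen.doses_for(Drug.ROMIPLOSTIM)
        return cls(
            lam_c, al_c / params.carboplatin.v_central, tc, ac,
            lam_e, al_e / params.epo.v4, te, ae,
            lam_r, al_r / params.romiplostim.v7, tr, ar,
        )

    @staticmethod
    def _superpose(t, lam, alpha, dose_t, dose_a):
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        for td, da in zip(dose_t, dose_a):
            mask = t >= td
            if np.any(mask):
                dt = t[mask, None] - td
                out[mask] += da * np.sum(alpha * np.exp(lam * dt), axis=-1)
        return out

    def conc_carboplatin(self, t):
        return self._superpose(t, self.lam_car, self.alpha_car, self.t_car, self.a_car)

    def conc_epo(self, t):
        return self._superpose(t, self.lam_epo, self.alpha_epo, self.t_epo, self.a_epo)

    def conc_romiplostim(self, t):
        return self._superpose(t, self.lam_rom, self.alpha_rom, self.t_rom, self.a_rom)


def _event_times(regimen: Regimen) -> np.ndarray:
    return np.unique([e.time_h for e in regimen.events])


def solve_pk(
    regimen: Regimen,
    params: PKParameters,
    grid: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> pd.DataFrame:
    """Integrate the PK amounts over ``grid`` and return tidy concentrations.

    Boluses are state jumps at event times (integration restarts), so the
    profiles are right-continuous at dose times.  Columns: ``arm, time_h,
    drug, conc, unit``.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted")
    if grid.size and grid[-1] > regimen.horizon_h:
        raise ValueError("grid extends beyond the regimen horizon")

    jump = {Drug.CARBOPLATIN: 0, Drug.RHUEPO: 3, Drug.ROMIPLOSTIM: 5}
    y = np.zeros(N_PK_STATES)
    t0 = grid[0] if grid.size else 0.0
    # apply any events at or before the grid start
    out = np.zeros((grid.size, N_PK_STATES))
    seg_bounds = np.unique(np.concatenate([[t0], _event_times(regimen), [grid[-1]]]))
    seg_bounds = seg_bounds[(seg_bounds >= t0) & (seg_bounds <= grid[-1])]
    for e in regimen.events:
        if e.time_h <= t0:
            y[jump[e.drug]] += e.amount
    filled = np.zeros(grid.size, dtype=bool)
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        sel = (grid >= a) & (grid < b) & ~filled
        t_eval = grid[sel]
        if b == seg_bounds[-1]:
            sel_end = (grid == b) & ~filled
        else:
            sel_end = np.zeros_like(filled)
        try:
            sol = solve_ivp(
                lambda t, s: pk_rhs(s, t, params),
                (a, b),
                y,
                method=method,
                t_eval=np.unique(np.concatenate([t_eval, [b]])),
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise RuntimeError(sol.message)
        except Exception as exc:  # pragma: no cover - context propagation
            raise RuntimeError(
                f"PK integration failed on arm {regimen.arm_name!r} in [{a}, {b}] h: {exc}"
            ) from exc
        lookup = {t: i for i, t in enumerate(sol.t)}
        for i in np.flatnonzero(sel):
            out[i] = sol.y[:, lookup[grid[i]]]
            filled[i] = True
        y = sol.y[:, -1].copy()
        for e in regimen.events:
            if e.time_h == b:
                y[jump[e.drug]] += e.amount
        for i in np.flatnonzero(sel_end):
            out[i] = y
            filled[i] = True
    frames = []
    c_car = out[:, 0] / params.carboplatin.v_central
    c_epo = out[:, 3] / params.epo.v4
    c_rom = out[:, 6] / params.romiplostim.v7
    for drug, conc, unit in (
        (Drug.CARBOPLATIN, c_car, "ug/mL"),
        (Drug.RHUEPO, c_epo, "mIU/mL"),
        (Drug.ROMIPLOSTIM, c_rom, "ng/mL"),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "arm": regimen.arm_name,
                    "time_h": grid,
                    "drug": drug.value,
                    "conc": conc,
                    "unit": unit,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
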