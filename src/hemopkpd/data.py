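"""Synthetic observation datasets with the study's sampling design.

The generator reproduces the statistical structure of the rat study: nine
treatment arms, six animals per arm, hematology sampling on days 0-40, and a
per-observable residual-error model

    Y = Yhat * (1 + eps1) + eps2,   eps1 ~ N(0, sigma1^2), eps2 ~ N(0, sigma2^2)

with a combined (proportional + additive) error for platelets and purely
additive errors for RBC and hemoglobin.  Negative draws are floored at zero
(hematology analyzers report non-negative values) and flagged so they can be
excluded downstream.  Subject identifiers are generated for realism but the
naive-pooled fitter ignores them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dosing import HOURS_PER_DAY, PKParameters, STUDY_ARMS, build_study_arm
from .hematopoiesis import PDParameters
from .simulate import OBSERVABLE_UNITS, SimulationSpec, simulate

#: hematology sampling days of the study design
SAMPLING_DAYS = (0, 4, 8, 10, 12, 15, 17, 19, 22, 24, 26, 29, 31, 33, 36, 38, 40)

OBSERVABLES = ("RBC", "HGB", "PLT")

TABLE_COLUMNS = ("arm", "subject_id", "time_h", "observable", "value", "unit", "floored")


@dataclass(frozen=True)
class ErrorModel:
    """Proportional and additive residual SDs for one observable."""

    sigma_prop: float
    sigma_add: float

    def __post_init__(self) -> None:
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual SDs must be >= 0")

    def marginal_sd(self, yhat: float) -> float:
        return float(np.sqrt(self.sigma_prop**2 * yhat**2 + self.sigma_add**2))

    def sample(self, yhat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        yhat = np.asarray(yhat, dtype=float)
        eps1 = rng.normal(0.0, self.sigma_prop, size=yhat.shape) if self.sigma_prop > 0 else 0.0
        eps2 = rng.normal(0.0, self.sigma_add, size=yhat.shape) if self.sigma_add > 0 else 0.0
        return yhat * (1.0 + eps1) + eps2


def error_models(params: PDParameters) -> dict[str, ErrorModel]:
    """Residual-error assignment per observable (combined for PLT only)."""
    return {
        "PLT": ErrorModel(params.sigma_plt1, params.sigma_plt2),
        "RBC": ErrorModel(0.0, params.sigma_rbc),
        "HGB": ErrorModel(0.0, params.sigma_hgb),
    }


def generate_dataset(
    true_params: PDParameters,
    pk_params: PKParameters,
    arms: Sequence[str] | None = None,
    n_per_arm: int = 6,
    seed: int = 0,
    sampling_days: Sequence[int] = SAMPLING_DAYS,
    body_weight_kg: float | None = None,
    mode: str = "fast",
) -> pd.DataFrame:
    """Simulate each arm, sample at the design days, add residual noise.

    Returns a long-format table with columns ``arm, subject_id, time_h,
    observable, value, unit, floored`` plus generator metadata in
    ``DataFrame.attrs``.  Fully reproducible from ``seed``.
    """
    if arms is None:
        arms = STUDY_ARMS
    unknown = [a for a in arms if a not in STUDY_ARMS]
    if unknown:
        raise ValueError(f"unknown arm(s): {', '.join(unknown)}")
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.asarray(sorted(set(sampling_days)), dtype=float) * HOURS_PER_DAY
    models = error_models(true_params)
    kw = {} if body_weight_kg is None else {"body_weight_kg": body_weight_kg}
    rows = []
    for arm in arms:
        regimen = build_study_arm(arm, **kw)
        traj = simulate(
            SimulationSpec(regimen, pk_params, true_params, grid=times), mode=mode
        )
        for obs in OBSERVABLES:
            yhat = traj.observable(obs)
            em = models[obs]
            for subject in range(1, n_per_arm + 1):
                y = em.sample(yhat, rng)
                floored = y < 0
                y = np.where(floored, 0.0, y)
                rows.append(
                    pd.DataFrame(
                        {
                            "arm": arm,
                            "subject_id": f"{arm}_{subject:02d}",
                            "time_h": times,
                            "observable": obs,
                            "value": y,
                            "unit": OBSERVABLE_UNITS[obs],
                            "floored": floored,
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TABLE_COLUMNS)
    table.attrs["meta"] = {
        "seed": int(seed),
        "generator": f"hemopkpd {__version__}",
        "n_per_arm": int(n_per_arm),
        "arms": ",".join(arms),
    }
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table as CSV (comma, dot-decimal, header row).

    Generator metadata is stored in leading ``# key: value`` comment lines.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for key, value in table.attrs.get("meta", {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an observation table written by :func:`write_table`."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                lines.append(line)
    table = pd.read_csv(io.StringIO("".join(lines)))
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    bad_obs = set(table["observable"]) - set(OBSERVABLES)
    if bad_obs:
        raise ValueError(f"{path}: unknown observable(s): {', '.join(sorted(bad_obs))}")
    for i, (obs, unit) in enumerate(zip(table["observable"], table["unit"])):
        if OBSERVABLE_UNITS[obs] != unit:
            raise ValueError(
                f"{path}: line {i + 2 + len(meta)}: column 'unit' is {unit!r} "
                f"but observable {obs} requires {OBSERVABLE_UNITS[obs]!r}"
            )
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        bad = int(np.flatnonzero(~np.isfinite(table["value"].to_numpy(dtype=float)))[0])
        raise ValueError(f"{path}: line {bad + 2 + len(meta)}: non-finite value")
    table["floored"] = table["floored"].astype(bool)
    table.attrs["meta"] = meta
    return table
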