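"""YAML parameter/config files, schema validation, packaged fixtures."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dosing import CarboplatinPK, EpoPK, PKParameters, RomiplostimPK
from .hematopoiesis import PDParameters

log = logging.getLogger("hemopkpd")

#: YAML key -> PDParameters field
_PD_KEYS = {
    "kill": "kill",
    "RBC0": "rbc0",
    "T_RET": "t_ret",
    "T_RBC": "t_rbc",
    "PLT0": "plt0",
    "T_MP": "t_mp",
    "T_PLT": "t_plt",
    "KE": "ke",
    "MCH": "mch",
    "Smax_RM1": "smax_rom1",
    "Smax_RM2": "smax_rom2",
    "Smax_PLT1": "smax_plt1",
    "Smax_PLT2": "smax_plt2",
    "Smax_EPO": "smax_epo",
    "SC50_E": "sc50_epo",
    "Ke0": "ke0",
    "sigma_PLT1": "sigma_plt1",
    "sigma_PLT2": "sigma_plt2",
    "sigma_RBC": "sigma_rbc",
    "sigma_HGB": "sigma_hgb",
    "CF": "cf",
    "MCFU": "mcfu",
    "MNOR": "mnor",
    "T_EP": "t_ep",
    "N_EP": "n_ep",
    "N_MK": "n_mk",
    "N_PLT": "n_plt",
}
_PD_REQUIRED = (
    "kill", "RBC0", "T_RET", "T_RBC", "PLT0", "T_MP", "T_PLT", "KE", "MCH",
    "Smax_RM1", "Smax_RM2", "Smax_PLT1", "Smax_PLT2", "Smax_EPO", "SC50_E", "Ke0",
)


def _load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return doc


def pd_params_from_mapping(doc: Mapping[str, Any], source: str = "<mapping>") -> PDParameters:
    missing = [k for k in _PD_REQUIRED if k not in doc]
    if missing:
        raise ValueError(f"{source}: missing required PD parameters: {', '.join(missing)}")
    unknown = [k for k in doc if k not in _PD_KEYS]
    if unknown:
        raise ValueError(f"{source}: unknown PD parameter keys: {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in doc.items():
        f = _PD_KEYS[key]
        if f in ("n_ep", "n_mk", "n_plt"):
            kwargs[f] = int(value)
        elif value is None and f == "t_ep":
            kwargs[f] = None
        else:
            kwargs[f] = float(value)
    return PDParameters(**kwargs)


def pd_params_to_mapping(params: PDParameters) -> dict[str, Any]:
    inv = {v: k for k, v in _PD_KEYS.items()}
    out: dict[str, Any] = {}
    for f, key in inv.items():
        out[key] = getattr(params, f)
    return out


def load_pd_params(path: str | Path) -> PDParameters:
    return pd_params_from_mapping(_load_yaml(path), source=str(path))


def pk_params_from_mapping(doc: Mapping[str, Any], source: str = "<mapping>") -> PKParameters:
    for section, fields in (
        ("carboplatin", ("k_el", "k_cp1", "k_pc1", "k_cp2", "k_pc2", "v_central")),
        ("epo", ("k_el", "v4", "v5", "q")),
        ("romiplostim", ("ka", "cl", "v7")),
    ):
        if section not in doc:
            raise ValueError(f"{source}: missing PK section {section!r}")
        missing = [f for f in fields if f not in doc[section]]
        if missing:
            raise ValueError(f"{source}: section {section!r} missing: {', '.join(missing)}")
    return PKParameters(
        carboplatin=CarboplatinPK(**{k: float(v) for k, v in doc["carboplatin"].items()}),
        epo=EpoPK(**{k: float(v) for k, v in doc["epo"].items()}),
        romiplostim=RomiplostimPK(**{k: float(v) for k, v in doc["romiplostim"].items()}),
    )


def load_pk_params(path: str | Path) -> PKParameters:
    return pk_params_from_mapping(_load_yaml(path), source=str(path))


def _packaged(name: str) -> Path:
    return Path(resources.files("hemopkpd.params") / name)


def table1_pd_params() -> PDParameters:
    """The packaged PD parameter estimates of the published model fit."""
    return load_pd_params(_packaged("table1.yaml"))


def nominal_pk_params() -> PKParameters:
    """Packaged synthetic nominal PK set (plausible values, not study estimates)."""
    return load_pk_params(_packaged("nominal_pk.yaml"))


def packaged_param_path(name: str) -> Path:
    """Path of a packaged parameter file (``table1.yaml``, ``nominal_pk.yaml``)."""
    p = _packaged(name)
    if not p.exists():
        raise FileNotFoundError(f"no packaged parameter file {name!r}")
    return p


@dataclass(frozen=True)
class ProjectConfig:
    """End-to-end pipeline configuration (``report`` command)."""

    out_dir: Path
    pd_params: Path | None = None   # default: packaged table1.yaml
    pk_params: Path | None = None   # default: packaged nominal_pk.yaml
    arms: tuple[str, ...] = ()      # empty = all 9 study arms
    preset: str = "core8"
    n_replicates: int = 2
    seed: int = 1
    n_per_arm: int = 6
    dt_fast: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectConfig":
        doc = _load_yaml(path)
        known = {
            "out_dir", "pd_params", "pk_params", "arms", "preset",
            "n_replicates", "seed", "n_per_arm", "dt_fast",
        }
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {', '.join(sorted(unknown))}")
        if "out_dir" not in doc:
            raise ValueError(f"{path}: 'out_dir' is required")
        for key in ("pd_params", "pk_params"):
            if doc.get(key) is not None and not Path(doc[key]).exists():
                raise ValueError(f"{path}: {key} file does not exist: {doc[key]}")
        return cls(
            out_dir=Path(doc["out_dir"]),
            pd_params=Path(doc["pd_params"]) if doc.get("pd_params") else None,
            pk_params=Path(doc["pk_params"]) if doc.get("pk_params") else None,
            arms=tuple(doc.get("arms") or ()),
            preset=str(doc.get("preset", "core8")),
            n_replicates=int(doc.get("n_replicates", 2)),
            seed=int(doc.get("seed", 1)),
            n_per_arm=int(doc.get("n_per_arm", 6)),
            dt_fast=float(doc.get("dt_fast", 0.25)),
        )
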