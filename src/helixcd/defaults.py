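"""Default calibration for alanine-rich (AAKAA)n-GY peptides.

Dichroic-model global-fit values per peptide unit at 0 °C: the CD baseline
block ([θ]H∞, ∂[θ]H∞/∂T, k, [θ]C, ∂[θ]C/∂T) and the helix–coil block
(ΔG, ΔH, ΔCp of propagation, nucleation constant v).  These serve as the
shipped parameter-file defaults and as the center of the uniform prior box
in global fitting; override them for other peptide systems.
"""

from __future__ import annotations

import json
from pathlib import Path

from .helix_coil import ThermoParams
from .spectro import SpectroParams

__all__ = ["DEFAULT_CALIBRATION", "default_spectro", "default_thermo", "load_params", "save_params"]

DEFAULT_CALIBRATION: dict[str, float] = {
    "theta_H_inf": -41_000.0,  # deg cm^2 dmol^-1
    "dtheta_H_inf_dT": 100.0,  # deg cm^2 dmol^-1 degC^-1
    "k": 3.4,
    "theta_C": 2_100.0,  # deg cm^2 dmol^-1
    "dtheta_C_dT": -45.0,  # deg cm^2 dmol^-1 degC^-1
    "dG0": -0.22,  # kcal mol^-1 at 0 degC
    "dH0": -1.3,  # kcal mol^-1
    "dCp": 0.006,  # kcal mol^-1 K^-1
    "v": 0.07,
}


def default_spectro() -> SpectroParams:
    c = DEFAULT_CALIBRATION
    return SpectroParams(
        theta_H_inf=c["theta_H_inf"],
        dtheta_H_inf_dT=c["dtheta_H_inf_dT"],
        k=c["k"],
        theta_C=c["theta_C"],
        dtheta_C_dT=c["dtheta_C_dT"],
    )


def default_thermo() -> ThermoParams:
    c = DEFAULT_CALIBRATION
    return ThermoParams(v=c["v"], dG0=c["dG0"], dH0=c["dH0"], dCp=c["dCp"])


def load_params(path: str | Path | None = None) -> tuple[SpectroParams, ThermoParams]:
    """Load a JSON parameter file; with no path, return the defaults."""
    if path is None:
        return default_spectro(), default_thermo()
    with open(path) as fh:
        data = json.load(fh)
    merged = dict(DEFAULT_CALIBRATION)
    unknown = set(data) - set(merged)
    if unknown:
        raise ValueError(f"unknown parameter names in {path}: {sorted(unknown)}")
    merged.update(data)
    spectro = SpectroParams(
        theta_H_inf=merged["theta_H_inf"],
        dtheta_H_inf_dT=merged["dtheta_H_inf_dT"],
        k=merged["k"],
        theta_C=merged["theta_C"],
        dtheta_C_dT=merged["dtheta_C_dT"],
    )
    thermo = ThermoParams(
        v=merged["v"], dG0=merged["dG0"], dH0=merged["dH0"], dCp=merged["dCp"]
    )
    return spectro, thermo


def save_params(path: str | Path, spectro: SpectroParams, thermo: ThermoParams) -> None:
    data = {
        "theta_H_inf": spectro.theta_H_inf,
        "dtheta_H_inf_dT": spectro.dtheta_H_inf_dT,
        "k": spectro.k,
        "theta_C": spectro.theta_C,
        "dtheta_C_dT": spectro.dtheta_C_dT,
        "dG0": thermo.dG0,
        "dH0": thermo.dH0,
        "dCp": thermo.dCp,
        "v": thermo.v,
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
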