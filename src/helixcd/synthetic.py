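"""Synthetic CD datasets with the statistical structure of alanine-peptide melts.

The default suite emulates the experimental design the global fit expects:
thermal melts of blocked (AAKAA)n-GY peptides (n = 1, 3, 4, 5, 6, i.e.
n_res = 7, 17, 22, 27, 32) sampled every 1 °C from 0 to 95 °C with i.i.d.
Gaussian noise on [θ]222, plus a fully-helical reference series
([θ]H versus N_pep at 0 °C) and a pre-transition slope series
(∂[θ]H/∂T versus N_pep).  Everything is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .defaults import default_spectro, default_thermo
from .helix_coil import ChainSpec, ThermoParams
from .inference import MeltCurve, ReferenceSeries, predict_melt
from .io import read_melt_csv, write_melt_csv
from .spectro import SpectroParams, helix_per_unit_empirical

__all__ = [
    "SimulationConfig",
    "simulate_melt_suite",
    "simulate_fully_helical_series",
    "simulate_pretransition_slopes",
    "write_read_roundtrip",
]

#: Residue counts of the (AAKAA)n-GY series for n = 1, 3, 4, 5, 6.
AAKAA_N_RES = (7, 17, 22, 27, 32)


@dataclass
class SimulationConfig:
    """Generating parameters for the synthetic suite.

    ``sigma_222`` (default 300 deg cm² dmol⁻¹) is the Gaussian noise scale
    of the melt points, the order of the visible scatter in measured melts.
    The reference series emulate literature compilations for fully helical
    peptides, whose scatter is far larger than instrument noise
    (heterogeneous systems, digitization): defaults are 1,500 deg cm² dmol⁻¹
    for [θ]H values and 15 deg cm² dmol⁻¹ °C⁻¹ for pre-transition slopes.
    """

    spectro: SpectroParams = field(default_factory=default_spectro)
    thermo: ThermoParams = field(default_factory=default_thermo)
    n_res_list: Sequence[int] = AAKAA_N_RES
    T_grid: np.ndarray = field(default_factory=lambda: np.arange(0.0, 95.0 + 0.5, 1.0))
    sigma_222: float = 300.0
    sigma_ref_theta: float = 1500.0
    sigma_ref_slope: float = 15.0
    n_pep_reference: Sequence[int] = tuple(range(7, 61))
    seed: int = 0
    blocked: bool = True

    def __post_init__(self) -> None:
        if self.sigma_222 < 0 or self.sigma_ref_theta < 0 or self.sigma_ref_slope < 0:
            raise ValueError("noise scales must be nonnegative")
        T = np.asarray(self.T_grid, dtype=float)
        if T.min() < -10.0 or T.max() > 110.0:
            raise ValueError("temperature grid must lie within [-10, 110] degC")


def simulate_melt_suite(config: SimulationConfig) -> list[MeltCurve]:
    """Noiseless forward melts plus i.i.d. Gaussian noise of scale sigma_222."""
    rng = np.random.default_rng(config.seed)
    curves = []
    for n_res in config.n_res_list:
        chain = ChainSpec(n_res, blocked=config.blocked)
        clean = predict_melt(config.spectro, config.thermo, chain, config.T_grid)
        noise = rng.normal(0.0, config.sigma_222, size=len(clean.temperatures))
        curves.append(
            MeltCurve(
                chain=chain,
                temperatures=clean.temperatures,
                theta_222=clean.theta_222 + noise,
                sigma_222=config.sigma_222 if config.sigma_222 > 0 else None,
                label=f"synthetic-n_res{n_res}",
            )
        )
    return curves


def simulate_fully_helical_series(
    spectro: SpectroParams,
    n_pep_list: Sequence[int],
    T: float = 0.0,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ReferenceSeries:
    """[θ]H(N_pep, T) for fully helical peptides, ``[θ]H∞(T)·(1 − k/N_pep)``."""
    n_pep = np.asarray(n_pep_list, dtype=float)
    if np.any(n_pep < 7):
        raise ValueError("fully-helical reference peptides need N_pep >= 7")
    values = np.asarray(helix_per_unit_empirical(n_pep, spectro, T), dtype=float)
    if sigma > 0:
        rng = rng if rng is not None else np.random.default_rng()
        values = values + rng.normal(0.0, sigma, size=n_pep.shape)
    return ReferenceSeries(
        kind="theta_H", n_pep=n_pep, values=values, sigma=sigma or None, T=T
    )


def simulate_pretransition_slopes(
    spectro: SpectroParams,
    n_pep_list: Sequence[int],
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ReferenceSeries:
    """Pre-transition slopes ``∂[θ]H(N_pep)/∂T = (∂[θ]H∞/∂T)·(1 − k/N_pep)``
    under temperature-independent k."""
    n_pep = np.asarray(n_pep_list, dtype=float)
    values = spectro.dtheta_H_inf_dT * (1.0 - spectro.k / n_pep)
    if sigma > 0:
        rng = rng if rng is not None else np.random.default_rng()
        values = values + rng.normal(0.0, sigma, size=n_pep.shape)
    return ReferenceSeries(kind="slope", n_pep=n_pep, values=values, sigma=sigma or None)


def simulate_suite(config: SimulationConfig):
    """Melts plus both reference series, all from one seeded RNG stream."""
    rng = np.random.default_rng(config.seed + 1)
    melts = simulate_melt_suite(config)
    helical = simulate_fully_helical_series(
        config.spectro, config.n_pep_reference, T=0.0, sigma=config.sigma_ref_theta, rng=rng
    )
    slopes = simulate_pretransition_slopes(
        config.spectro, config.n_pep_reference, sigma=config.sigma_ref_slope, rng=rng
    )
    return melts, helical, slopes


def write_read_roundtrip(curves: Sequence[MeltCurve], directory: str | Path) -> list[MeltCurve]:
    """Serialize curves to CSV and parse them back (values to full precision)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, curve in enumerate(curves):
        path = directory / f"melt_{curve.label or i}.csv"
        write_melt_csv(curve, path)
        out.append(read_melt_csv(path))
    return out
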