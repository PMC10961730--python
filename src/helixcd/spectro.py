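"""Spectroscopic models mapping helix–coil ensembles to [θ]222.

Three helix-length corrections are implemented for the mean molar
ellipticity at 222 nm (deg cm² dmol⁻¹ per peptide unit):

``linear``
    Every helical unit contributes the per-unit ellipticity of the
    maximal-length helix, ``[θ]H(N_pep)``, regardless of how the helical
    units are distributed over segments.  This is the common approximation
    used for direct helicity read-out, and the one whose bias the ensemble
    models quantify.
``empirical``
    Each segment of ``n_H`` units contributes ``n_H·[θ]H∞(T)·(1 − k/n_H)``
    — the classic end-effect correction applied per segment.
``dichroic``
    Each segment assigns ``[θ]H1`` to its six singly hydrogen-bonded end
    units (three per end) and ``[θ]H∞`` to the doubly bonded interior
    units; with ``[θ]H1 = [θ]H∞(1 − k/6)`` the dichroic and empirical
    per-unit values coincide for ``n_H > 6`` and diverge only for short
    segments.

Coil units contribute the temperature-dependent coil baseline.  All
temperatures at this layer are in °C with parameters referenced to 0 °C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .helix_coil import ChainSpec, EnsembleDistribution

__all__ = [
    "SpectroParams",
    "RawCDRecord",
    "theta_H_inf_at_T",
    "theta_H1",
    "helix_per_unit_empirical",
    "helix_total_dichroic",
    "helix_total_linear",
    "coil_baseline",
    "ensemble_signal",
    "raw_to_molar",
    "MODELS",
]

#: Singly hydrogen-bonded units per helical segment (three at each end).
SINGLE_BONDED_UNITS = 6

MODELS = ("linear", "empirical", "dichroic")


@dataclass(frozen=True)
class SpectroParams:
    """CD baseline parameters, per peptide unit, referenced to 0 °C.

    Parameters
    ----------
    theta_H_inf : float
        Molar ellipticity of a unit in an infinitely long helix,
        deg cm² dmol⁻¹ (negative).
    dtheta_H_inf_dT : float
        Temperature slope of ``theta_H_inf``, deg cm² dmol⁻¹ °C⁻¹.
    k : float
        Dimensionless end-effect parameter (temperature independent).
    theta_C : float
        Coil ellipticity at 0 °C, deg cm² dmol⁻¹.
    dtheta_C_dT : float
        Temperature slope of the coil baseline.
    """

    theta_H_inf: float
    dtheta_H_inf_dT: float = 0.0
    k: float = 0.0
    theta_C: float = 0.0
    dtheta_C_dT: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(
            [self.theta_H_inf, self.dtheta_H_inf_dT, self.k, self.theta_C, self.dtheta_C_dT]
        ).all():
            raise ValueError("all spectroscopic parameters must be finite")
        if self.theta_H_inf >= 0:
            raise ValueError(f"theta_H_inf must be negative, got {self.theta_H_inf}")
        if self.k < 0:
            raise ValueError(f"end-effect parameter k must be nonnegative, got {self.k}")
        if self.k >= SINGLE_BONDED_UNITS:
            warnings.warn(
                f"k = {self.k} >= 6 makes theta_H1 nonnegative; the dichroic "
                "end contribution loses its helical sign",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RawCDRecord:
    """A raw ellipticity measurement to be converted to molar units."""

    theta_mdeg: float
    path_cm: float
    conc_M: float
    chain: ChainSpec

    def __post_init__(self) -> None:
        if self.path_cm <= 0:
            raise ValueError(f"optical path length must be positive, got {self.path_cm}")
        if self.conc_M <= 0:
            raise ValueError(f"molar concentration must be positive, got {self.conc_M}")


def theta_H_inf_at_T(params: SpectroParams, T: float):
    """Infinite-helix unit ellipticity at temperature ``T`` (°C)."""
    return params.theta_H_inf + params.dtheta_H_inf_dT * np.asarray(T, dtype=float)


def theta_H1(params: SpectroParams, T: float):
    """Ellipticity of a singly hydrogen-bonded helix-end unit.

    The constant-``k`` relation ``[θ]H1(T) = [θ]H∞(T)·(1 − k/6)`` makes the
    dichroic per-unit ellipticity of a segment with ``n_H > 6`` equal the
    empirical form ``[θ]H∞(1 − k/n_H)`` exactly, and ties the temperature
    dependence of the end units to that of the helix interior.
    """
    return theta_H_inf_at_T(params, T) * (1.0 - params.k / SINGLE_BONDED_UNITS)


def helix_per_unit_empirical(n_H: float, params: SpectroParams, T: float = 0.0):
    """Per-unit helix ellipticity with the empirical length correction,
    ``[θ]H∞(T)·(1 − k/n_H)`` for a segment of ``n_H`` units."""
    n_H = np.asarray(n_H, dtype=float)
    if np.any(n_H < 1):
        raise ValueError("segment length n_H must be >= 1")
    return theta_H_inf_at_T(params, T) * (1.0 - params.k / n_H)


def helix_total_dichroic(
    segment_lengths: Iterable[int], params: SpectroParams, T: float = 0.0
) -> float:
    """Summed helical ellipticity of a conformer under the dichroic model.

    Each segment of ``n_H`` units contributes ``n_H·[θ]H1`` when ``n_H <= 6``
    (all units singly bonded) and ``6·[θ]H1 + (n_H − 6)·[θ]H∞`` otherwise.
    """
    th1 = float(theta_H1(params, T))
    thinf = float(theta_H_inf_at_T(params, T))
    total = 0.0
    for n_H in segment_lengths:
        if n_H < 4:
            raise ValueError(f"helical segments span >= 4 peptide units, got {n_H}")
        n_ends = min(n_H, SINGLE_BONDED_UNITS)
        total += n_ends * th1 + (n_H - n_ends) * thinf
    return total


def helix_total_linear(
    n_H_total: float, chain: ChainSpec, params: SpectroParams, T: float = 0.0
) -> float:
    """Summed helical ellipticity under the linear approximation.

    All ``n_H_total`` helical units contribute the per-unit value of the
    maximal-length helix, ``[θ]H(N_pep, T)``, regardless of segmentation —
    including multi-segment conformers, which is precisely the
    approximation the ensemble models correct.
    """
    if n_H_total < 0 or n_H_total > chain.n_pep:
        raise ValueError(f"n_H_total must lie in [0, {chain.n_pep}], got {n_H_total}")
    return float(n_H_total * helix_per_unit_empirical(chain.n_pep, params, T))


def coil_baseline(params: SpectroParams, T: float):
    """Coil unit ellipticity ``[θ]C + (∂[θ]C/∂T)·T`` at ``T`` in °C."""
    return params.theta_C + params.dtheta_C_dT * np.asarray(T, dtype=float)


def _segment_end_units(dist: EnsembleDistribution) -> np.ndarray:
    return np.array(
        [
            sum(min(s, SINGLE_BONDED_UNITS) for s in c.segment_lengths)
            for c in dist.compositions
        ]
    )


def ensemble_signal(
    dist: EnsembleDistribution,
    params: SpectroParams,
    T: float = 0.0,
    model: str = "dichroic",
) -> float:
    """Ensemble-averaged [θ]222 per peptide unit.

    Sums the probability-weighted helical and coil contributions of every
    composition class: ``Σ_i p_i·(θ_helix(i, T) + n_C,i·θ_C(T)) / N_pep``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    n_pep = dist.chain.n_pep
    p = dist.probabilities
    n_h = dist.n_helical_units
    coil = float(coil_baseline(params, T)) * (n_pep - n_h)
    if model == "linear":
        helix = n_h * helix_per_unit_empirical(n_pep, params, T)
    elif model == "empirical":
        thinf = float(theta_H_inf_at_T(params, T))
        helix = np.array(
            [
                sum(s * thinf * (1.0 - params.k / s) for s in c.segment_lengths)
                for c in dist.compositions
            ]
        )
    else:  # dichroic
        th1 = float(theta_H1(params, T))
        thinf = float(theta_H_inf_at_T(params, T))
        n_ends = _segment_end_units(dist)
        helix = n_ends * th1 + (n_h - n_ends) * thinf
    return float(p @ (helix + coil)) / n_pep


def raw_to_molar(rec: RawCDRecord) -> float:
    """Mean molar ellipticity per peptide unit from a raw CD signal,
    ``θ(mdeg) / (10 · l · c · N_pep)`` in deg cm² dmol⁻¹."""
    return rec.theta_mdeg / (10.0 * rec.path_cm * rec.conc_M * rec.chain.n_pep)
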