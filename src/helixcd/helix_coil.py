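"""Lifson–Roig helix–coil statistics resolved by helical-segment composition.

Each residue of a peptide backbone is either helical (h) or coil (c).
A run of ``m >= 3`` consecutive helical residues forms a helical segment
spanning ``m + 1`` peptide units (the amide chromophores flanking the run);
shorter h-runs are spectroscopic coil but still pay their nucleation
penalty.  Terminal residues are held in the coil state, the classic
Lifson–Roig end treatment.  A run of ``m`` helical residues carries the
statistical weight ``v**2 * w**(m - 2)`` for ``m >= 2`` and ``v`` for
``m = 1``; coil residues carry 1.

The ensemble is enumerated exactly, resolved by the multiset of helical
run lengths, so per-conformer spectroscopic corrections (which depend on
the length of every helical segment) can be applied without the two-segment
truncation used by transfer-matrix shortcuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "R_KCAL",
    "CELSIUS_OFFSET",
    "ThermoParams",
    "ChainSpec",
    "SegmentComposition",
    "EnsembleDistribution",
    "gibbs_helmholtz",
    "propagation_at_T",
    "enumerate_bruteforce",
    "composition_weights",
    "conformer_class_probability",
    "mean_helicity",
    "mean_helical_units",
    "segment_count_distribution",
    "helical_conformer_fraction",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

#: Offset between Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15

#: Minimum length (in residues) of an h-run that counts as a helical segment.
MIN_HELICAL_RUN = 3

#: Brute-force enumeration guard: 2^(n_res) states beyond this are refused.
BRUTEFORCE_MAX_RES = 22


@dataclass(frozen=True)
class ThermoParams:
    """Helix–coil thermodynamic parameters.

    Parameters
    ----------
    v : float
        Dimensionless nucleation constant (temperature independent).
    dG0 : float
        Per-residue helix propagation free energy at ``T0``, kcal/mol.
    dH0 : float
        Propagation enthalpy at ``T0``, kcal/mol.
    dCp : float
        Propagation heat capacity change, kcal/mol/K (assumed constant).
    T0 : float
        Reference temperature in kelvin; defaults to 273.15 K (0 degC).
    """

    v: float
    dG0: float
    dH0: float = 0.0
    dCp: float = 0.0
    T0: float = CELSIUS_OFFSET

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError(f"nucleation constant v must be positive, got {self.v}")
        if not self.T0 > 0:
            raise ValueError(f"reference temperature T0 must be positive, got {self.T0}")


def gibbs_helmholtz(thermo: ThermoParams, T: float) -> float:
    """Propagation free energy dG(T) in kcal/mol at absolute temperature ``T``.

    Uses the three-parameter Gibbs–Helmholtz form with (dG0, dH0, dCp) given
    at the reference temperature ``T0``::

        dG(T) = dH0 + dCp*(T - T0) - T*[(dH0 - dG0)/T0 + dCp*ln(T/T0)]

    which reduces to the van 't Hoff two-parameter form for ``dCp = 0``.
    """
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    dS0 = (thermo.dH0 - thermo.dG0) / thermo.T0
    return (
        thermo.dH0
        + thermo.dCp * (T - thermo.T0)
        - T * (dS0 + thermo.dCp * math.log(T / thermo.T0))
    )


def propagation_at_T(thermo: ThermoParams, T: float) -> float:
    """Propagation constant ``w(T) = exp(-dG(T) / (R*T))`` at ``T`` in kelvin."""
    return math.exp(-gibbs_helmholtz(thermo, T) / (R_KCAL * T))


@dataclass(frozen=True)
class ChainSpec:
    """A homopolymer peptide chain.

    ``blocked`` chains (N-terminal acetyl, C-terminal amide) have one more
    peptide unit than residues: ``n_pep = n_res + 1``.
    """

    n_res: int
    blocked: bool = True

    def __post_init__(self) -> None:
        if self.n_res < 1:
            raise ValueError(f"n_res must be >= 1, got {self.n_res}")

    @property
    def n_pep(self) -> int:
        return self.n_res + 1 if self.blocked else self.n_res

    @property
    def n_interior(self) -> int:
        """Residues free to adopt the helical state (terminal residues are coil)."""
        return max(self.n_res - 2, 0)


def _run_to_segment_units(run_length: int) -> int:
    """Peptide units spanned by a helical run of ``run_length`` residues."""
    return run_length + 1


@dataclass(frozen=True)
class SegmentComposition:
    """A class of conformers sharing the same multiset of helical-run lengths.

    ``run_lengths`` lists every maximal h-run in residues (descending).
    Runs of >= 3 residues are helical segments of ``run + 1`` peptide units
    (``segment_lengths``); shorter runs contribute to the coil signal.
    The statistical weight of the class is ``degeneracy * v**n_v * w**n_w``.
    """

    run_lengths: tuple[int, ...]
    n_pep: int
    degeneracy: int
    n_v: int = field(init=False)
    n_w: int = field(init=False)
    segment_lengths: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        n_v = sum(1 if r == 1 else 2 for r in self.run_lengths)
        n_w = sum(max(r - 2, 0) for r in self.run_lengths)
        segs = tuple(
            sorted(
                (_run_to_segment_units(r) for r in self.run_lengths if r >= MIN_HELICAL_RUN),
                reverse=True,
            )
        )
        object.__setattr__(self, "n_v", n_v)
        object.__setattr__(self, "n_w", n_w)
        object.__setattr__(self, "segment_lengths", segs)

    @property
    def n_helical_units(self) -> int:
        """Units inside helical segments (>= 4 units each)."""
        return sum(self.segment_lengths)

    @property
    def n_helical_residues(self) -> int:
        """Residues in helical runs of >= 3 (one fewer than units per segment)."""
        return sum(r for r in self.run_lengths if r >= MIN_HELICAL_RUN)

    @property
    def n_coil_units(self) -> int:
        return self.n_pep - self.n_helical_units

    @property
    def n_segments(self) -> int:
        return len(self.segment_lengths)

    def weight(self, v: float, w: float) -> float:
        return self.degeneracy * v**self.n_v * w**self.n_w


def _partitions(total: int, max_part: int | None = None) -> Iterator[tuple[int, ...]]:
    """Integer partitions of ``total`` as descending tuples."""
    if total == 0:
        yield ()
        return
    if max_part is None or max_part > total:
        max_part = total
    for first in range(max_part, 0, -1):
        for rest in _partitions(total - first, first):
            yield (first, *rest)


def _arrangements(partition: Sequence[int], n_interior: int) -> int:
    """Number of h/c strings of length ``n_interior`` whose maximal h-runs
    realize ``partition``: distinct orderings of the run multiset times the
    stars-and-bars count of coil-separated placements."""
    r = len(partition)
    m = sum(partition)
    orderings = math.factorial(r)
    run = 1
    for i in range(1, r):
        if partition[i] == partition[i - 1]:
            run += 1
        else:
            orderings //= math.factorial(run)
            run = 1
    orderings //= math.factorial(run)
    return orderings * math.comb(n_interior - m + 1, r)


@lru_cache(maxsize=None)
def _composition_table(n_interior: int, n_pep: int) -> tuple[SegmentComposition, ...]:
    """All run-length compositions of a chain, with exact degeneracies."""
    comps: list[SegmentComposition] = []
    for m in range(n_interior + 1):
        for part in _partitions(m):
            r = len(part)
            if m + r - 1 > n_interior:
                continue  # runs cannot be separated by coil residues
            comps.append(
                SegmentComposition(
                    run_lengths=part,
                    n_pep=n_pep,
                    degeneracy=_arrangements(part, n_interior),
                )
            )
    return tuple(comps)


class EnsembleDistribution:
    """Normalized distribution over segment compositions of one chain.

    Attributes
    ----------
    chain : ChainSpec
    v, w : float
        Effective nucleation and propagation constants at the working
        temperature.
    compositions : tuple of SegmentComposition
    weights, probabilities : ndarray
        Per-composition statistical weights and normalized probabilities.
    Q : float
        Partition function (sum of all weights; the all-coil class has
        weight 1).
    """

    def __init__(
        self,
        chain: ChainSpec,
        v: float,
        w: float,
        compositions: Sequence[SegmentComposition],
        weights: np.ndarray,
    ) -> None:
        self.chain = chain
        self.v = v
        self.w = w
        self.compositions = tuple(compositions)
        self.weights = np.asarray(weights, dtype=float)
        self.Q = float(self.weights.sum())
        self.probabilities = self.weights / self.Q
        self._index = {c.run_lengths: i for i, c in enumerate(self.compositions)}
        # cached per-composition statistics for vectorized reductions
        self.n_helical_units = np.array([c.n_helical_units for c in self.compositions])
        self.n_helical_residues = np.array([c.n_helical_residues for c in self.compositions])
        self.n_segments = np.array([c.n_segments for c in self.compositions])

    def probability_of(self, composition: SegmentComposition | Sequence[int]) -> float:
        """Probability of one composition class (``weight / Q``)."""
        key = (
            composition.run_lengths
            if isinstance(composition, SegmentComposition)
            else tuple(sorted(composition, reverse=True))
        )
        try:
            return float(self.probabilities[self._index[key]])
        except KeyError:
            raise KeyError(f"composition with run lengths {key} not in ensemble") from None


def composition_weights(chain: ChainSpec, v: float, w: float) -> EnsembleDistribution:
    """Exact composition-resolved ensemble by run-length combinatorics.

    Enumerates every multiset of helical-run lengths compatible with the
    interior of the chain and computes its degeneracy in closed form, so
    the cost grows with the number of integer partitions rather than
    ``2**n_res``.  All segment counts are treated exactly.
    """
    if v < 0 or w < 0:
        raise ValueError("v and w must be nonnegative")
    comps = _composition_table(chain.n_interior, chain.n_pep)
    n_v = np.array([c.n_v for c in comps])
    n_w = np.array([c.n_w for c in comps])
    deg = np.array([c.degeneracy for c in comps], dtype=float)
    weights = deg * np.power(float(v), n_v) * np.power(float(w), n_w)
    return EnsembleDistribution(chain, v, w, comps, weights)


def enumerate_bruteforce(chain: ChainSpec, v: float, w: float) -> EnsembleDistribution:
    """Reference enumerator over all helix/coil strings of the chain interior.

    Walks every one of the ``2**n_interior`` residue-state strings (terminal
    residues fixed coil), applies the Lifson–Roig run weights, and groups
    states by their run-length multiset.  Intended as the oracle for
    :func:`composition_weights`; refuses chains beyond ``n_res = 22``.
    """
    if chain.n_res > BRUTEFORCE_MAX_RES:
        raise ValueError(
            f"n_res = {chain.n_res} exceeds the brute-force guard "
            f"({BRUTEFORCE_MAX_RES}); use composition_weights instead"
        )
    n_int = chain.n_interior
    grouped: dict[tuple[int, ...], int] = {}
    for state in range(2**n_int):
        runs: list[int] = []
        run = 0
        for pos in range(n_int):
            if (state >> pos) & 1:
                run += 1
            else:
                if run:
                    runs.append(run)
                run = 0
        if run:
            runs.append(run)
        key = tuple(sorted(runs, reverse=True))
        grouped[key] = grouped.get(key, 0) + 1
    comps = [
        SegmentComposition(run_lengths=key, n_pep=chain.n_pep, degeneracy=count)
        for key, count in sorted(grouped.items())
    ]
    weights = np.array([c.weight(v, w) for c in comps])
    return EnsembleDistribution(chain, v, w, comps, weights)


def conformer_class_probability(
    dist: EnsembleDistribution, composition: SegmentComposition | Sequence[int]
) -> float:
    """Probability of a conformer class: its weight divided by Q."""
    return dist.probability_of(composition)


def mean_helicity(dist: EnsembleDistribution) -> float:
    """Mean fractional helicity: helical residues over total residues.

    A residue is helical when it belongs to a run of >= 3 consecutive h
    residues; shorter runs are spectroscopic coil.  This is the standard
    helix-coil fractional helicity; the per-unit bookkeeping used for CD
    signals is exposed by :func:`mean_helical_units`.
    """
    n_h = float(dist.probabilities @ dist.n_helical_residues)
    return n_h / dist.chain.n_res


def mean_helical_units(dist: EnsembleDistribution) -> float:
    """Mean number of peptide units inside helical segments."""
    return float(dist.probabilities @ dist.n_helical_units)


def segment_count_distribution(dist: EnsembleDistribution) -> np.ndarray:
    """Probabilities of conformers with 0, 1, 2 and >= 3 helical segments."""
    out = np.zeros(4)
    bins = np.minimum(dist.n_segments, 3)
    np.add.at(out, bins, dist.probabilities)
    return out


def helical_conformer_fraction(dist: EnsembleDistribution) -> float:
    """Probability that a conformer contains at least one helical segment."""
    return float(dist.probabilities[dist.n_segments >= 1].sum())
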