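"""Helicity estimation and global fitting of CD thermal melts.

Two directions through the forward model:

* **Inversion** — given a measured [θ]222 at one temperature, solve for the
  propagation constant ``w`` whose ensemble reproduces the signal
  (:func:`helicity_from_signal_ensemble`), or apply the closed-form linear
  read-out ``([θ]obs − [θ]C)/([θ]H(N_pep) − [θ]C)``
  (:func:`helicity_from_signal_linear`).

* **Global fitting** — :class:`CDGlobalFit` estimates the five spectroscopic
  baseline parameters and four helix–coil thermodynamic parameters jointly
  from a collection of thermal melts plus fully-helical reference series,
  under a Gaussian noise model.  The deterministic backend is weighted
  multi-start maximum likelihood (scipy ``least_squares``); the ``mcmc``
  backend samples the same posterior under uniform box priors with emcee's
  affine-invariant ensemble sampler.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .helix_coil import (
    CELSIUS_OFFSET,
    R_KCAL,
    ChainSpec,
    ThermoParams,
    _composition_table,
    composition_weights,
    helical_conformer_fraction,
    mean_helicity,
    propagation_at_T,
)
from .spectro import (
    MODELS,
    SINGLE_BONDED_UNITS,
    SpectroParams,
    coil_baseline,
    helix_per_unit_empirical,
    theta_H1,
    theta_H_inf_at_T,
)

__all__ = [
    "MeltCurve",
    "ReferenceSeries",
    "FitResult",
    "CDGlobalFit",
    "SignalOutOfRangeError",
    "helicity_from_signal_ensemble",
    "helicity_from_signal_linear",
    "predict_melt",
    "global_fit",
    "PARAM_NAMES",
]

#: Canonical order of the nine globally fitted parameters.
PARAM_NAMES = (
    "theta_H_inf",
    "dtheta_H_inf_dT",
    "k",
    "theta_C",
    "dtheta_C_dT",
    "dG0",
    "dH0",
    "dCp",
    "v",
)

TEMP_MIN_C, TEMP_MAX_C = -10.0, 110.0


@dataclass
class MeltCurve:
    """A CD thermal melt: [θ]222 per peptide unit versus temperature."""

    chain: ChainSpec
    temperatures: np.ndarray
    theta_222: np.ndarray
    sigma_222: float | np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.theta_222 = np.asarray(self.theta_222, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.shape != self.theta_222.shape:
            raise ValueError("temperatures and theta_222 must be 1-D arrays of equal length")
        if len(self.temperatures) < 2:
            raise ValueError("a melt curve needs at least two points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temperatures.min() < TEMP_MIN_C or self.temperatures.max() > TEMP_MAX_C:
            raise ValueError(
                f"temperatures must lie within [{TEMP_MIN_C}, {TEMP_MAX_C}] degC"
            )


@dataclass
class ReferenceSeries:
    """Fully-helical reference observations versus peptide-unit count.

    ``kind = "theta_H"``: [θ]H(N_pep) at temperature ``T`` (°C);
    ``kind = "slope"``: pre-transition slope ∂[θ]H(N_pep)/∂T.
    """

    kind: str
    n_pep: np.ndarray
    values: np.ndarray
    sigma: float | np.ndarray | None = None
    T: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("theta_H", "slope"):
            raise ValueError(f"kind must be 'theta_H' or 'slope', got {self.kind!r}")
        self.n_pep = np.asarray(self.n_pep, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.n_pep.shape != self.values.shape:
            raise ValueError("n_pep and values must have equal length")


class SignalOutOfRangeError(ValueError):
    """Observed ellipticity falls outside the attainable model interval."""

    def __init__(self, theta_obs: float, attainable: tuple[float, float]):
        lo, hi = sorted(attainable)
        super().__init__(
            f"theta_obs = {theta_obs:.1f} outside the attainable interval "
            f"[{lo:.1f}, {hi:.1f}] deg cm^2 dmol^-1"
        )
        self.attainable = (lo, hi)


# ---------------------------------------------------------------------------
# fast vectorized forward model


@lru_cache(maxsize=None)
def _chain_arrays(n_interior: int, n_pep: int):
    """Per-composition integer statistics as numpy arrays (cached per chain)."""
    comps = _composition_table(n_interior, n_pep)
    return (
        np.array([c.n_v for c in comps]),
        np.array([c.n_w for c in comps]),
        np.array([c.degeneracy for c in comps], dtype=float),
        np.array([c.n_helical_units for c in comps], dtype=float),
        np.array(
            [sum(min(s, SINGLE_BONDED_UNITS) for s in c.segment_lengths) for c in comps],
            dtype=float,
        ),
        np.array([c.n_segments for c in comps], dtype=float),
    )


def _ensemble_moments(chain: ChainSpec, v: float, w_arr: np.ndarray):
    """⟨n_H⟩, ⟨n_ends⟩ and an empirical-correction moment for each w.

    Weights are evaluated in log space, ``deg · exp(n_v·ln v + n_w·ln w)``,
    with the all-coil class fixed at weight 1, so long chains at large w do
    not overflow.
    """
    n_v, n_w, deg, n_h, n_ends, _ = _chain_arrays(chain.n_interior, chain.n_pep)
    w_arr = np.atleast_1d(np.asarray(w_arr, dtype=float))
    logv = np.log(v)
    logw = np.log(np.maximum(w_arr, 1e-300))
    expo = n_v * logv + np.outer(logw, n_w)  # (nT, ncomp)
    expo -= expo.max(axis=1, keepdims=True)
    wt = deg * np.exp(expo)
    Q = wt.sum(axis=1)
    return wt, Q, n_h, n_ends


def _signal_grid(
    chain: ChainSpec,
    spectro: SpectroParams,
    v: float,
    w_arr: np.ndarray,
    T_arr: np.ndarray,
    model: str,
) -> np.ndarray:
    """[θ]222 per unit for matched arrays of (w, T) pairs."""
    wt, Q, n_h, n_ends = _ensemble_moments(chain, v, w_arr)
    mean_nh = (wt @ n_h) / Q
    T_arr = np.atleast_1d(np.asarray(T_arr, dtype=float))
    thinf = theta_H_inf_at_T(spectro, T_arr)
    coil = coil_baseline(spectro, T_arr)
    n_pep = chain.n_pep
    if model == "linear":
        helix = mean_nh * thinf * (1.0 - spectro.k / n_pep)
    elif model == "dichroic":
        mean_ends = (wt @ n_ends) / Q
        th1 = theta_H1(spectro, T_arr)
        helix = mean_ends * th1 + (mean_nh - mean_ends) * thinf
    elif model == "empirical":
        # per segment: s*thinf*(1 - k/s) = (s - k)*thinf, so only ⟨n_seg⟩ is needed
        n_seg = _chain_arrays(chain.n_interior, chain.n_pep)[5]
        mean_seg = (wt @ n_seg) / Q
        helix = (mean_nh - spectro.k * mean_seg) * thinf
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return (helix + (n_pep - mean_nh) * coil) / n_pep


def predict_melt(
    spectro: SpectroParams,
    thermo: ThermoParams,
    chain: ChainSpec,
    T_grid: Sequence[float],
    model: str = "dichroic",
) -> MeltCurve:
    """Noiseless forward model of a thermal melt.

    Propagation follows the Gibbs–Helmholtz relation, the ensemble is the
    exact composition-resolved distribution, and the signal is the
    probability-weighted conformer sum under the chosen spectroscopic model.
    """
    T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
    w_arr = np.array([propagation_at_T(thermo, t + CELSIUS_OFFSET) for t in T_grid])
    theta = _signal_grid(chain, spectro, thermo.v, w_arr, T_grid, model)
    if T_grid.size >= 2:
        return MeltCurve(chain, T_grid, theta)
    # single-point evaluation: bypass the >= 2 point curve contract
    mc = MeltCurve.__new__(MeltCurve)
    mc.chain, mc.temperatures, mc.theta_222, mc.sigma_222, mc.label = (
        chain,
        T_grid,
        theta,
        None,
        "",
    )
    return mc


# ---------------------------------------------------------------------------
# inversion

W_SOLVE_BOUNDS = (1e-8, 50.0)


def helicity_from_signal_ensemble(
    theta_obs: float,
    T: float,
    chain: ChainSpec,
    spectro: SpectroParams,
    v: float,
) -> dict:
    """Invert the dichroic ensemble signal for the propagation constant.

    Solves ``ensemble_signal(w) = theta_obs`` by Brent's method (the signal
    is strictly monotone in ``w``) and reports the mean helicity and the
    probability of at least one helical segment at the solution.
    """
    if v <= 0:
        raise ValueError("nucleation constant v must be positive")
    w_lo, w_hi = W_SOLVE_BOUNDS

    def f(w: float) -> float:
        return float(_signal_grid(chain, spectro, v, np.array([w]), np.array([T]), "dichroic")[0])

    s_lo, s_hi = f(w_lo), f(w_hi)
    lo, hi = sorted((s_lo, s_hi))
    tol = 1e-9 * (hi - lo) + 1e-9  # the coil baseline sits exactly on the boundary
    if not lo - tol <= theta_obs <= hi + tol:
        raise SignalOutOfRangeError(theta_obs, (s_lo, s_hi))
    theta_obs = float(np.clip(theta_obs, lo, hi))
    w_hat = optimize.brentq(lambda w: f(w) - theta_obs, w_lo, w_hi, xtol=1e-10, rtol=1e-12)
    dist = composition_weights(chain, v, w_hat)
    return {
        "w_hat": float(w_hat),
        "mean_helicity": mean_helicity(dist),
        "helical_conformer_fraction": helical_conformer_fraction(dist),
    }


def helicity_from_signal_linear(
    theta_obs: float, T: float, chain: ChainSpec, spectro: SpectroParams
) -> float:
    """Closed-form linear-model helicity,
    ``([θ]obs − [θ]C(T)) / ([θ]H(N_pep, T) − [θ]C(T))``, clipped to [0, 1]."""
    theta_h = float(helix_per_unit_empirical(chain.n_pep, spectro, T))
    theta_c = float(coil_baseline(spectro, T))
    denom = theta_h - theta_c
    if denom == 0:
        raise ZeroDivisionError("degenerate baselines: theta_H(N_pep, T) equals theta_C(T)")
    f = (theta_obs - theta_c) / denom
    if f < 0 or f > 1:
        warnings.warn(
            f"linear helicity {f:.3f} outside [0, 1]; clipping", stacklevel=2
        )
    return float(np.clip(f, 0.0, 1.0))


# ---------------------------------------------------------------------------
# global fitting


@dataclass
class FitResult:
    """Point estimates, 2σ uncertainties and diagnostics of a global fit."""

    params: dict[str, float]
    uncertainties_2sigma: dict[str, float]
    correlation: np.ndarray
    param_names: tuple[str, ...]
    cost: float
    n_data: int
    model: str
    backend: str
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def spectro(self) -> SpectroParams:
        p = self.params
        return SpectroParams(
            theta_H_inf=p["theta_H_inf"],
            dtheta_H_inf_dT=p["dtheta_H_inf_dT"],
            k=p["k"],
            theta_C=p["theta_C"],
            dtheta_C_dT=p["dtheta_C_dT"],
        )

    @property
    def thermo(self) -> ThermoParams:
        p = self.params
        return ThermoParams(v=p["v"], dG0=p["dG0"], dH0=p["dH0"], dCp=p["dCp"])

    def mean_abs_correlation(self) -> float:
        """Mean absolute off-diagonal parameter correlation."""
        c = np.asarray(self.correlation)
        off = c[~np.eye(len(c), dtype=bool)]
        return float(np.abs(off).mean())

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "uncertainties_2sigma": self.uncertainties_2sigma,
            "correlation": np.asarray(self.correlation).tolist(),
            "param_names": list(self.param_names),
            "cost": self.cost,
            "n_data": self.n_data,
            "model": self.model,
            "backend": self.backend,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _unpack(x: np.ndarray) -> tuple[SpectroParams, ThermoParams]:
    p = dict(zip(PARAM_NAMES, x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # optimizer may probe k >= 6
        return _unpack_quiet(p)


def _unpack_quiet(p: dict) -> tuple[SpectroParams, ThermoParams]:
    spectro = SpectroParams(
        theta_H_inf=p["theta_H_inf"],
        dtheta_H_inf_dT=p["dtheta_H_inf_dT"],
        k=p["k"],
        theta_C=p["theta_C"],
        dtheta_C_dT=p["dtheta_C_dT"],
    )
    thermo = ThermoParams(v=p["v"], dG0=p["dG0"], dH0=p["dH0"], dCp=p["dCp"])
    return spectro, thermo


class CDGlobalFit(BaseEstimator):
    """Global fit of CD melt and reference data, scikit-learn style.

    Parameters
    ----------
    model : {"dichroic", "linear", "empirical"}
        Spectroscopic model used for the melt forward calculation.
    backend : {"mle", "mcmc"}
        "mle": multi-start weighted least squares (deterministic given
        ``seed``); "mcmc": affine-invariant ensemble sampling of the same
        Gaussian likelihood under the uniform box prior.
    center : dict or None
        Reference parameter values defining the prior box and start points;
        defaults to the package's alanine-peptide calibration.
    box_factor : float
        Uniform priors span ``center/box_factor .. center*box_factor``
        (sign-preserving) for each parameter.
    n_starts : int
        Number of seeded optimizer starts (best objective wins).
    fixed : dict or None
        Parameters held at fixed values (e.g. ``{"dCp": 0.0}``).
    sigma_default : float
        Noise scale applied to observations that carry none.
    n_walkers, n_steps, n_burn : int
        emcee sampler configuration (mcmc backend only).

    Attributes
    ----------
    result_ : FitResult
    spectro_ : SpectroParams
    thermo_ : ThermoParams
    """

    def __init__(
        self,
        model: str = "dichroic",
        backend: str = "mle",
        center: dict | None = None,
        box_factor: float = 5.0,
        n_starts: int = 5,
        fixed: dict | None = None,
        sigma_default: float = 300.0,
        seed: int = 0,
        n_walkers: int = 32,
        n_steps: int = 3000,
        n_burn: int = 1000,
    ):
        self.model = model
        self.backend = backend
        self.center = center
        self.box_factor = box_factor
        self.n_starts = n_starts
        self.fixed = fixed
        self.sigma_default = sigma_default
        self.seed = seed
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn

    # -- likelihood plumbing ------------------------------------------------

    def _center_vector(self) -> np.ndarray:
        from .defaults import DEFAULT_CALIBRATION

        center = dict(DEFAULT_CALIBRATION)
        if self.center:
            center.update(self.center)
        return np.array([center[name] for name in PARAM_NAMES], dtype=float)

    def _bounds(self, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = np.empty_like(center), np.empty_like(center)
        for i, c in enumerate(center):
            if c == 0:
                lo[i], hi[i] = -1.0, 1.0
            else:
                a, b = c / self.box_factor, c * self.box_factor
                lo[i], hi[i] = min(a, b), max(a, b)
        # physical constraints override the box
        names = list(PARAM_NAMES)
        lo[names.index("v")] = max(lo[names.index("v")], 1e-4)
        lo[names.index("k")] = 0.0
        hi[names.index("theta_H_inf")] = min(hi[names.index("theta_H_inf")], -1.0)
        return lo, hi

    def _residuals(self, x_free, melts, refs, free_idx, template):
        x = template.copy()
        x[free_idx] = x_free
        spectro, thermo = _unpack(x)
        out = []
        for m in melts:
            w_arr = np.exp(-_gibbs_vec(thermo, m.temperatures + CELSIUS_OFFSET))
            pred = _signal_grid(m.chain, spectro, thermo.v, w_arr, m.temperatures, self.model)
            sigma = m.sigma_222 if m.sigma_222 is not None else self.sigma_default
            out.append((pred - m.theta_222) / sigma)
        for r in refs:
            if r.kind == "theta_H":
                pred = helix_per_unit_empirical(r.n_pep, spectro, r.T)
            else:
                pred = spectro.dtheta_H_inf_dT * (1.0 - spectro.k / r.n_pep)
            sigma = r.sigma if r.sigma is not None else self.sigma_default
            out.append((pred - r.values) / sigma)
        return np.concatenate(out)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        melts: Sequence[MeltCurve],
        helical_series: ReferenceSeries | None = None,
        slope_series: ReferenceSeries | None = None,
    ) -> "CDGlobalFit":
        """Fit all parameters to the supplied datasets jointly."""
        melts = list(melts)
        if not melts and helical_series is None and slope_series is None:
            raise ValueError("at least one dataset is required")
        refs = [r for r in (helical_series, slope_series) if r is not None]
        if melts and len({m.chain.blocked for m in melts}) > 1:
            raise ValueError("melt curves mix blocked and unblocked chains")

        center = self._center_vector()
        lo, hi = self._bounds(center)
        fixed = dict(self.fixed or {})
        free_idx = np.array([i for i, n in enumerate(PARAM_NAMES) if n not in fixed])
        template = center.copy()
        for name, value in fixed.items():
            template[list(PARAM_NAMES).index(name)] = value

        n_data = sum(len(m.temperatures) for m in melts) + sum(len(r.values) for r in refs)
        if n_data < len(free_idx):
            raise ValueError(
                f"non-identifiable configuration: {n_data} observations cannot "
                f"constrain {len(free_idx)} free parameters "
                f"({', '.join(PARAM_NAMES[i] for i in free_idx)})"
            )

        if self.backend == "mle":
            result = self._fit_mle(melts, refs, center, lo, hi, free_idx, template)
        elif self.backend == "mcmc":
            result = self._fit_mcmc(melts, refs, center, lo, hi, free_idx, template)
        else:
            raise ValueError(f"unknown backend {self.backend!r}")
        result.n_data = n_data
        self.result_ = result
        self.spectro_ = result.spectro
        self.thermo_ = result.thermo
        return self

    def _starts(self, center, lo, hi, free_idx):
        rng = np.random.default_rng(self.seed)
        starts = [center[free_idx]]
        for _ in range(self.n_starts - 1):
            jitter = rng.uniform(0.6, 1.4, size=len(free_idx))
            cand = np.clip(center[free_idx] * jitter, lo[free_idx], hi[free_idx])
            cand[center[free_idx] == 0] = rng.uniform(-0.1, 0.1)
            starts.append(cand)
        return starts

    def _fit_mle(self, melts, refs, center, lo, hi, free_idx, template) -> FitResult:
        scale = np.maximum(np.abs(center[free_idx]), 1e-3)
        best = None
        for x0 in self._starts(center, lo, hi, free_idx):
            sol = optimize.least_squares(
                self._residuals,
                x0,
                args=(melts, refs, free_idx, template),
                bounds=(lo[free_idx], hi[free_idx]),
                x_scale=scale,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        x = template.copy()
        x[free_idx] = best.x
        # linearized covariance of the weighted least-squares problem
        J = best.jac
        try:
            cov_free = np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov_free = np.full((len(free_idx), len(free_idx)), np.nan)
        sd = np.sqrt(np.clip(np.diag(cov_free), 0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr_free = cov_free / np.outer(sd, sd)
        n = len(PARAM_NAMES)
        corr = np.eye(n)
        unc = np.zeros(n)
        for a, ia in enumerate(free_idx):
            unc[ia] = 2.0 * sd[a]
            for b, ib in enumerate(free_idx):
                corr[ia, ib] = corr_free[a, b]
        np.fill_diagonal(corr, 1.0)
        return FitResult(
            params=dict(zip(PARAM_NAMES, map(float, x))),
            uncertainties_2sigma=dict(zip(PARAM_NAMES, map(float, unc))),
            correlation=corr,
            param_names=PARAM_NAMES,
            cost=float(best.cost),
            n_data=0,
            model=self.model,
            backend="mle",
            seed=self.seed,
            diagnostics={"optimizer_status": int(best.status), "n_starts": self.n_starts},
        )

    def _fit_mcmc(self, melts, refs, center, lo, hi, free_idx, template) -> FitResult:
        import emcee

        ndim = len(free_idx)

        def log_prob(x_free):
            if np.any(x_free < lo[free_idx]) or np.any(x_free > hi[free_idx]):
                return -np.inf
            r = self._residuals(x_free, melts, refs, free_idx, template)
            return -0.5 * float(r @ r)

        rng = np.random.default_rng(self.seed)
        # initialize walkers in a tight ball around the MLE for fast burn-in
        mle = self._fit_mle(melts, refs, center, lo, hi, free_idx, template)
        x0 = np.array([mle.params[PARAM_NAMES[i]] for i in free_idx])
        scale = np.maximum(np.abs(x0), 1e-3) * 1e-3
        p0 = np.clip(
            x0 + scale * rng.standard_normal((self.n_walkers, ndim)),
            lo[free_idx],
            hi[free_idx],
        )
        sampler = emcee.EnsembleSampler(self.n_walkers, ndim, log_prob)
        state = emcee.State(p0, random_state=np.random.RandomState(self.seed))
        sampler.run_mcmc(state, self.n_steps, progress=False)
        chain = sampler.get_chain(discard=self.n_burn, flat=True)
        mean = chain.mean(axis=0)
        sd = chain.std(axis=0, ddof=1)
        if ndim == 1:
            rho = np.array([[1.0]])
        elif ndim == 2:
            r = float(stats.spearmanr(chain).statistic)
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = np.asarray(stats.spearmanr(chain).statistic)
        x = template.copy()
        x[free_idx] = mean
        n = len(PARAM_NAMES)
        corr = np.eye(n)
        unc = np.zeros(n)
        for a, ia in enumerate(free_idx):
            unc[ia] = 2.0 * sd[a]
            for b, ib in enumerate(free_idx):
                corr[ia, ib] = rho[a, b] if ndim > 1 else 1.0
        np.fill_diagonal(corr, 1.0)
        try:
            ess = float(
                chain.shape[0] / np.nanmax(emcee.autocorr.integrated_time(
                    sampler.get_chain(discard=self.n_burn), quiet=True
                ))
            )
        except Exception:
            ess = float("nan")
        return FitResult(
            params=dict(zip(PARAM_NAMES, map(float, x))),
            uncertainties_2sigma=dict(zip(PARAM_NAMES, map(float, unc))),
            correlation=corr,
            param_names=PARAM_NAMES,
            cost=float(-sampler.get_log_prob(discard=self.n_burn, flat=True).max()),
            n_data=0,
            model=self.model,
            backend="mcmc",
            seed=self.seed,
            diagnostics={
                "mean_acceptance_fraction": float(sampler.acceptance_fraction.mean()),
                "effective_sample_size": ess,
                "n_steps": self.n_steps,
                "n_burn": self.n_burn,
            },
        )

    def predict(self, chain: ChainSpec, T_grid: Sequence[float]) -> np.ndarray:
        """Model [θ]222 on ``T_grid`` for ``chain`` at the fitted parameters."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the estimator before calling predict")
        return predict_melt(self.spectro_, self.thermo_, chain, T_grid, self.model).theta_222


def _gibbs_vec(thermo: ThermoParams, T_kelvin: np.ndarray) -> np.ndarray:
    """Vectorized -ln w(T): Gibbs–Helmholtz free energy over R*T."""
    T = np.asarray(T_kelvin, dtype=float)
    dS0 = (thermo.dH0 - thermo.dG0) / thermo.T0
    dG = (
        thermo.dH0
        + thermo.dCp * (T - thermo.T0)
        - T * (dS0 + thermo.dCp * np.log(T / thermo.T0))
    )
    return dG / (R_KCAL * T)


def global_fit(
    melts: Sequence[MeltCurve],
    helical_series: ReferenceSeries | None = None,
    slope_series: ReferenceSeries | None = None,
    **kwargs,
) -> FitResult:
    """Functional wrapper around :class:`CDGlobalFit`."""
    est = CDGlobalFit(**kwargs)
    est.fit(melts, helical_series=helical_series, slope_series=slope_series)
    return est.result_
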