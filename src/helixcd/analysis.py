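"""Ensemble-level model comparisons and parameter-range scans."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .helix_coil import ChainSpec
from .inference import _chain_arrays, _signal_grid
from .spectro import SpectroParams

__all__ = ["model_difference_scan", "max_multi_segment_probability"]


def model_difference_scan(
    chain: ChainSpec,
    v: float,
    w_grid: Sequence[float],
    spectro: SpectroParams,
    T: float = 0.0,
) -> pd.DataFrame:
    """[θ]222 per model over a propagation-constant scan.

    Returns a frame with columns ``w``, ``theta_linear``, ``theta_empirical``,
    ``theta_dichroic``, ``abs_diff`` (|linear − dichroic|) and
    ``rel_diff_pct`` (100·|linear − dichroic|/|dichroic|).
    """
    w_grid = np.asarray(w_grid, dtype=float)
    T_arr = np.full_like(w_grid, T)
    out = {"w": w_grid}
    for model in ("linear", "empirical", "dichroic"):
        out[f"theta_{model}"] = _signal_grid(chain, spectro, v, w_grid, T_arr, model)
    df = pd.DataFrame(out)
    df["abs_diff"] = np.abs(df["theta_linear"] - df["theta_dichroic"])
    with np.errstate(divide="ignore", invalid="ignore"):
        df["rel_diff_pct"] = 100.0 * df["abs_diff"] / np.abs(df["theta_dichroic"])
    return df


def max_multi_segment_probability(
    n_res_values: Sequence[int],
    v_grid: Sequence[float],
    w_grid: Sequence[float],
    min_segments: int = 3,
) -> tuple[float, dict]:
    """Exact maximum of P(≥ ``min_segments`` helical segments) over a grid.

    Evaluates every (chain, v, w) combination by the composition-resolved
    partition function; returns the maximum probability and its location.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    w_grid = np.asarray(w_grid, dtype=float)
    logw = np.log(w_grid)
    best = 0.0
    where: dict = {}
    for n_res in n_res_values:
        chain = ChainSpec(int(n_res))
        n_v, n_w, deg, _, _, n_seg = _chain_arrays(chain.n_interior, chain.n_pep)
        mask = n_seg >= min_segments
        if not mask.any():
            continue
        w_pow = np.exp(np.outer(logw, n_w))  # (n_w_grid, ncomp)
        for v in v_grid:
            wt = deg * np.power(v, n_v) * w_pow
            p = wt[:, mask].sum(axis=1) / wt.sum(axis=1)
            i = int(np.argmax(p))
            if p[i] > best:
                best = float(p[i])
                where = {"n_res": int(n_res), "v": float(v), "w": float(w_grid[i])}
    return best, where
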