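"""Plain-text serialization of melt curves and reference series.

Melt-curve CSV layout: ``# key=value`` metadata header lines followed by a
``temperature_C,theta_222`` table.  Required metadata: ``n_res``; optional:
``blocked`` (default true), ``conc_M``, ``path_cm``, ``sigma_222``,
``label``.  Decimal commas are rejected — files must use the C locale.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .helix_coil import ChainSpec
from .inference import MeltCurve

__all__ = ["write_melt_csv", "read_melt_csv", "write_series_csv", "read_series_csv"]

_DECIMAL_COMMA = re.compile(r"\d,\d")


class MeltParseError(ValueError):
    """Malformed melt-curve CSV."""


def write_melt_csv(curve: MeltCurve, path: str | Path) -> None:
    lines = [f"# n_res={curve.chain.n_res}", f"# blocked={str(curve.chain.blocked).lower()}"]
    if curve.sigma_222 is not None and np.isscalar(curve.sigma_222):
        lines.append(f"# sigma_222={float(curve.sigma_222)!r}")
    if curve.label:
        lines.append(f"# label={curve.label}")
    lines.append("temperature_C,theta_222")
    for t, th in zip(curve.temperatures, curve.theta_222):
        lines.append(f"{float(t)!r},{float(th)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_melt_csv(path: str | Path) -> MeltCurve:
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "=" not in stripped:
                raise MeltParseError(f"{path}:{lineno}: metadata line without '=': {line!r}")
            key, _, value = stripped.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
        else:
            if _DECIMAL_COMMA.search(stripped) and stripped.count(",") > 1:
                raise MeltParseError(
                    f"{path}:{lineno}: decimal commas are not supported; "
                    "use '.' as the decimal separator"
                )
            body_lines.append(line)
    if "n_res" not in meta:
        raise MeltParseError(f"{path}: missing required metadata header '# n_res=...'")
    if not body_lines:
        raise MeltParseError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    if list(df.columns) != ["temperature_C", "theta_222"]:
        raise MeltParseError(
            f"{path}: expected columns temperature_C,theta_222; got {list(df.columns)}"
        )
    chain = ChainSpec(
        n_res=int(meta["n_res"]),
        blocked=meta.get("blocked", "true").lower() in ("true", "1", "yes"),
    )
    sigma = float(meta["sigma_222"]) if "sigma_222" in meta else None
    return MeltCurve(
        chain=chain,
        temperatures=df["temperature_C"].to_numpy(float),
        theta_222=df["theta_222"].to_numpy(float),
        sigma_222=sigma,
        label=meta.get("label", ""),
    )


def write_series_csv(n_pep: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"n_pep": np.asarray(n_pep), "value": np.asarray(values)}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_series_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["n_pep", "value"]:
        raise MeltParseError(f"{path}: expected columns n_pep,value; got {list(df.columns)}")
    return df["n_pep"].to_numpy(float), df["value"].to_numpy(float)
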