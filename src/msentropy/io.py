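"""Plain-text readers and writers for series, curves and result tables.

Series files are one value per line (or a single-column CSV, header
auto-detected); lines starting with '#' are comments.  Curve files are CSV
with the run parameters recorded in '#' header comments so every result file
is self-describing and the numeric payload round-trips at full precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import EntropyConfig
from .multiscale import MultiscaleCurve

__all__ = [
    "read_series",
    "write_series",
    "write_curve",
    "read_curve",
    "write_error_surface",
    "write_exponent_table",
    "write_exponent_model",
]


def read_series(path) -> np.ndarray:
    """Read a series from one-value-per-line text or single-column CSV.

    '#' comment lines and blank lines are skipped; a single non-numeric
    leading row is treated as a header.  Non-finite or non-numeric values
    raise with the offending line number.
    """
    path = Path(path)
    values: list[float] = []
    header_allowed = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.split(",") if f.strip() != ""]
            if len(fields) > 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected a single column, "
                    f"got {len(fields)} fields"
                )
            token = fields[0].strip()
            try:
                value = float(token)
            except ValueError:
                if header_allowed and not values:
                    header_allowed = False
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value {token!r}"
                ) from None
            if not np.isfinite(value):
                raise ValueError(
                    f"{path}: line {lineno}: non-finite value {token!r}"
                )
            values.append(value)
            header_allowed = False
    if not values:
        raise ValueError(f"{path}: no numeric samples found")
    return np.asarray(values, dtype=np.float64)


def write_series(path, values, header: dict | None = None) -> None:
    """Write a series one value per line, with '#' header comments."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        for v in np.asarray(values, dtype=np.float64):
            fh.write(f"{float(v)!r}\n")


def _curve_metadata(curve: MultiscaleCurve) -> dict:
    cfg = curve.config
    meta = {
        "variant": curve.variant,
        "estimator": curve.estimator,
        "scheme": curve.scheme,
        "m": cfg.m,
        "r": repr(cfg.r),
        "n": cfg.n,
        "similarity": cfg.similarity,
        "min_separation": cfg.min_separation,
        "tau_max": int(curve.scales.max()),
    }
    for key, val in curve.r_basis.items():
        meta[f"r_basis_{key}"] = val
    return meta


def write_curve(curve: MultiscaleCurve, path) -> None:
    """Write scale,value,defined CSV with the run parameters as '#' comments."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in _curve_metadata(curve).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("scale,value,defined\n")
        for tau, val in zip(curve.scales, curve.values):
            if np.isnan(val):
                fh.write(f"{tau},,false\n")
            else:
                fh.write(f"{tau},{float(val)!r},true\n")


def read_curve(path) -> MultiscaleCurve:
    """Read a curve written by :func:`write_curve` (full-precision roundtrip)."""
    path = Path(path)
    meta: dict[str, str] = {}
    scales: list[int] = []
    values: list[float] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("scale,"):
                continue
            tau, val, defined = line.split(",")
            scales.append(int(tau))
            values.append(float(val) if defined == "true" else np.nan)
    cfg = EntropyConfig(
        m=int(meta.get("m", 2)),
        r=float(meta["r"]) if meta.get("r", "None") != "None" else None,
        n=float(meta.get("n", 1.0)),
        similarity=meta.get("similarity", "hard"),
        min_separation=int(meta.get("min_separation", 1)),
    )
    r_basis = {
        k[len("r_basis_"):]: v for k, v in meta.items() if k.startswith("r_basis_")
    }
    return MultiscaleCurve(
        variant=meta.get("variant", "MSE"),
        scales=np.asarray(scales),
        values=np.asarray(values),
        config=cfg,
        r_basis=r_basis,
    )


def write_error_surface(surface, path) -> None:
    """Tidy CSV: variant, estimator, length, exponent, error."""
    surface.to_frame().to_csv(Path(path), index=False)


def write_exponent_table(n_star: dict[int, float], path, variant: str = "") -> None:
    """Tidy CSV of optimal exponents: variant, length, n_star."""
    df = pd.DataFrame(
        {
            "variant": variant,
            "length": list(n_star.keys()),
            "n_star": list(n_star.values()),
        }
    )
    df.to_csv(Path(path), index=False)


def write_exponent_model(model, path, label: str = "") -> None:
    """Key-value text block for a fitted n*(x) = a + b exp(c x) model."""
    path = Path(path)
    with path.open("w") as fh:
        if label:
            fh.write(f"# {label}\n")
        fh.write("# n_star(x) = a + b*exp(c*x), x in samples\n")
        fh.write(f"a: {model.a!r}\n")
        fh.write(f"b: {model.b!r}\n")
        fh.write(f"c: {model.c!r}\n")
        fh.write(f"residual_rms: {model.residual!r}\n")
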