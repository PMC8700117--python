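"""Multiscale entropy curves: the eight estimator/coarse-graining variants.

Every variant is the composition of a coarse-graining scheme with a
single-scale estimator, evaluated for scale factors tau = 1..tau_max:

    MSE  / MFE    standard graining, SampEn / FuzzyEn, delay 1
    CMSE / CMFE   composite: average the entropy over the tau graining offsets
    RCMSE/ RCMFE  refined composite: average the match statistics over the
                  offsets first, then take -ln of the ratio of the averages
    MMSE / MMFE   modified: overlapping moving average, estimator delay tau

The tolerance r is fixed once from the raw (scale-1) series as
r_factor x SD (population SD) and reused at every scale and offset -- the
canonical multiscale convention; pass an absolute ``r`` to override.

Undefined sample-entropy values (zero match counts on short coarse series)
propagate as NaN; the refined-composite variants are defined whenever any
offset has matches, which is the point of that variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .coarse import composite_coarse_grain, coarse_grain, overlapping_coarse_grain
from .entropy import (
    EntropyConfig,
    _fuzzy_phi,
    _hard_statistics,
    _require_length,
    _as_series,
)

__all__ = [
    "MultiscaleCurve",
    "multiscale_curve",
    "mse_curve",
    "composite_curve",
    "refined_composite_curve",
    "modified_curve",
    "mse",
    "mfe",
    "cmse",
    "cmfe",
    "rcmse",
    "rcmfe",
    "mmse",
    "mmfe",
    "VARIANTS",
    "eval_counter",
]

logger = logging.getLogger(__name__)

#: variant name -> (coarse-graining scheme, estimator)
VARIANTS: dict[str, tuple[str, str]] = {
    "MSE": ("standard", "sample"),
    "MFE": ("standard", "fuzzy"),
    "CMSE": ("composite", "sample"),
    "CMFE": ("composite", "fuzzy"),
    "RCMSE": ("refined_composite", "sample"),
    "RCMFE": ("refined_composite", "fuzzy"),
    "MMSE": ("overlapping", "sample"),
    "MMFE": ("overlapping", "fuzzy"),
}

Estimator = Literal["sample", "fuzzy"]


class _EvalCounter:
    """Counts single-scale estimator evaluations (one per coarse series per
    scale), exposing the structural work ordering of the variants."""

    def __init__(self) -> None:
        self.count = 0

    def reset(self) -> None:
        self.count = 0

    def add(self, k: int = 1) -> None:
        self.count += k


eval_counter = _EvalCounter()


@dataclass(frozen=True)
class MultiscaleCurve:
    variant: str
    scales: np.ndarray
    values: np.ndarray  # NaN marks an undefined scale
    config: EntropyConfig  # with r resolved to absolute units
    r_basis: dict

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def scheme(self) -> str:
        return VARIANTS[self.variant][0]

    @property
    def estimator(self) -> str:
        return VARIANTS[self.variant][1]

    def __len__(self) -> int:
        return self.scales.size


def _max_feasible_scale(n: int, m: int, scheme: str) -> int:
    if scheme in ("standard",):
        return n // (m + 2)
    if scheme in ("composite", "refined_composite"):
        return (n + 1) // (m + 3)
    # overlapping: (N - tau + 1) - m*tau >= 2
    return (n - 1) // (m + 1)


def _check_feasible(n: int, m: int, scheme: str, tau_max: int) -> None:
    if tau_max < 1:
        raise ValueError(f"tau_max must be >= 1, got {tau_max}")
    feasible = _max_feasible_scale(n, m, scheme)
    if tau_max > feasible:
        raise ValueError(
            f"tau_max={tau_max} too large for a series of {n} samples with "
            f"m={m} under the {scheme} scheme; maximum feasible scale is "
            f"{feasible}"
        )


def _hard_value(series: np.ndarray, m: int, r: float, delta: int, min_sep: int) -> float:
    stats = _hard_statistics(series, m, delta, r, min_sep)
    eval_counter.add()
    return stats.entropy()


def _hard_phis(series: np.ndarray, m: int, r: float, delta: int, min_sep: int):
    stats = _hard_statistics(series, m, delta, r, min_sep)
    eval_counter.add()
    return stats.phi_m, stats.phi_m1


def _fuzzy_phis_grid(
    series: np.ndarray,
    m: int,
    r: float,
    n_grid: np.ndarray,
    delta: int,
    kind: str,
    min_sep: int,
    precision: str,
):
    count = _require_length(series.size, m, delta)
    phi_m, _ = _fuzzy_phi(series, m, delta, count, r, n_grid, kind, min_sep, precision)
    phi_m1, _ = _fuzzy_phi(
        series, m + 1, delta, count, r, n_grid, kind, min_sep, precision
    )
    eval_counter.add()
    return phi_m, phi_m1


def _values_grid(
    u: np.ndarray,
    scheme: str,
    estimator: str,
    cfg: EntropyConfig,
    n_grid: np.ndarray,
    tau_max: int,
    precision: str = "double",
    undefined_offsets: str = "propagate",
) -> np.ndarray:
    """Curve values, shape (tau_max, len(n_grid)); hard estimators use a
    single column.  Shared by the public curves (single exponent, double
    precision) and the evaluation module's exponent surveys."""
    m, r, kind, min_sep = (cfg.m, cfg.r, cfg.similarity, cfg.min_separation)
    hard = estimator == "sample"
    width = 1 if hard else len(n_grid)
    out = np.full((tau_max, width), np.nan)
    for ti, tau in enumerate(range(1, tau_max + 1)):
        if scheme == "standard":
            g = coarse_grain(u, tau).values
            if hard:
                out[ti, 0] = _hard_value(g, m, r, 1, min_sep)
            else:
                pm, pm1 = _fuzzy_phis_grid(g, m, r, n_grid, 1, kind, min_sep, precision)
                out[ti] = -np.log(pm1 / pm)
        elif scheme in ("composite", "refined_composite"):
            phis_m = np.zeros(width)
            phis_m1 = np.zeros(width)
            vals = np.zeros((tau, width))
            for k in range(1, tau + 1):
                g = composite_coarse_grain(u, tau, k).values
                if hard:
                    pm, pm1 = _hard_phis(g, m, r, 1, min_sep)
                    pm = np.array([pm])
                    pm1 = np.array([pm1])
                else:
                    pm, pm1 = _fuzzy_phis_grid(
                        g, m, r, n_grid, 1, kind, min_sep, precision
                    )
                phis_m += pm
                phis_m1 += pm1
                with np.errstate(divide="ignore", invalid="ignore"):
                    vals[k - 1] = np.where(
                        (pm1 > 0) & (pm > 0), -np.log(pm1 / pm), np.nan
                    )
            if scheme == "composite":
                if undefined_offsets == "skip" and np.isnan(vals).any():
                    n_bad = int(np.isnan(vals[:, 0]).sum())
                    logger.warning(
                        "scale %d: skipping %d undefined offset entropies", tau, n_bad
                    )
                    ok = ~np.isnan(vals)
                    n_ok = ok.sum(axis=0)
                    sums = np.where(ok, vals, 0.0).sum(axis=0)
                    out[ti] = np.where(n_ok > 0, sums / np.maximum(n_ok, 1), np.nan)
                else:
                    out[ti] = vals.mean(axis=0)  # NaN offsets propagate
            else:
                pm_bar = phis_m / tau
                pm1_bar = phis_m1 / tau
                with np.errstate(divide="ignore", invalid="ignore"):
                    out[ti] = np.where(
                        (pm1_bar > 0) & (pm_bar > 0),
                        -np.log(pm1_bar / pm_bar),
                        np.nan,
                    )
        elif scheme == "overlapping":
            g = overlapping_coarse_grain(u, tau).values
            if hard:
                out[ti, 0] = _hard_value(g, m, r, tau, min_sep)
            else:
                pm, pm1 = _fuzzy_phis_grid(
                    g, m, r, n_grid, tau, kind, min_sep, precision
                )
                out[ti] = -np.log(pm1 / pm)
        else:
            raise ValueError(f"unknown coarse-graining scheme {scheme!r}")
    return out


def _resolve(u, cfg: EntropyConfig, estimator: str) -> tuple[np.ndarray, EntropyConfig, dict]:
    arr = _as_series(u)
    sd = float(np.std(arr))
    if cfg.r is None:
        r = cfg.r_factor * sd if sd > 0 else 1.0
        basis = {"sd": sd, "r_factor": cfg.r_factor, "r": r, "policy": "r_factor*sd"}
    else:
        r = cfg.r
        basis = {"sd": sd, "r_factor": None, "r": r, "policy": "absolute"}
    sim = cfg.similarity
    if estimator == "sample":
        sim = "hard"
    elif sim == "hard":
        sim = "fuzzy_v1"
    return arr, replace(cfg, r=r, similarity=sim), basis


def _curve(
    u,
    variant: str,
    scheme: str,
    estimator: str,
    cfg: EntropyConfig,
    tau_max: int,
    undefined_offsets: str,
) -> MultiscaleCurve:
    if estimator not in ("sample", "fuzzy"):
        raise ValueError(f"estimator must be 'sample' or 'fuzzy', got {estimator!r}")
    arr, rcfg, basis = _resolve(u, cfg, estimator)
    _check_feasible(arr.size, rcfg.m, scheme, tau_max)
    grid = np.asarray([rcfg.n], dtype=np.float64)
    values = _values_grid(
        arr, scheme, estimator, rcfg, grid, tau_max,
        precision="double", undefined_offsets=undefined_offsets,
    )[:, 0]
    return MultiscaleCurve(
        variant=variant,
        scales=np.arange(1, tau_max + 1),
        values=values,
        config=rcfg,
        r_basis=basis,
    )


def mse_curve(
    u, cfg: EntropyConfig | None = None, tau_max: int = 20,
    estimator: Estimator = "sample", undefined_offsets: str = "propagate",
) -> MultiscaleCurve:
    """Standard-graining multiscale entropy (MSE for sample, MFE for fuzzy)."""
    cfg = cfg or EntropyConfig()
    name = "MSE" if estimator == "sample" else "MFE"
    return _curve(u, name, "standard", estimator, cfg, tau_max, undefined_offsets)


def composite_curve(
    u, cfg: EntropyConfig | None = None, tau_max: int = 20,
    estimator: Estimator = "sample", undefined_offsets: str = "propagate",
) -> MultiscaleCurve:
    """Composite variant: mean entropy over the tau graining offsets."""
    cfg = cfg or EntropyConfig()
    name = "CMSE" if estimator == "sample" else "CMFE"
    return _curve(u, name, "composite", estimator, cfg, tau_max, undefined_offsets)


def refined_composite_curve(
    u, cfg: EntropyConfig | None = None, tau_max: int = 20,
    estimator: Estimator = "sample", undefined_offsets: str = "propagate",
) -> MultiscaleCurve:
    """Refined composite variant: offset-averaged match statistics, then -ln."""
    cfg = cfg or EntropyConfig()
    name = "RCMSE" if estimator == "sample" else "RCMFE"
    return _curve(
        u, name, "refined_composite", estimator, cfg, tau_max, undefined_offsets
    )


def modified_curve(
    u, cfg: EntropyConfig | None = None, tau_max: int = 20,
    estimator: Estimator = "sample", undefined_offsets: str = "propagate",
) -> MultiscaleCurve:
    """Modified variant: overlapping moving average with estimator delay tau."""
    cfg = cfg or EntropyConfig()
    name = "MMSE" if estimator == "sample" else "MMFE"
    return _curve(u, name, "overlapping", estimator, cfg, tau_max, undefined_offsets)


def multiscale_curve(
    u,
    variant: str = "MSE",
    *,
    m: int = 2,
    r: float | None = None,
    r_factor: float = 0.15,
    n: float = 1.0,
    fuzzy_kind: str = "fuzzy_v1",
    tau_max: int = 20,
    min_separation: int = 1,
    undefined_offsets: str = "propagate",
) -> MultiscaleCurve:
    """Compute any of the eight variants by name (MSE, MFE, CMSE, CMFE,
    RCMSE, RCMFE, MMSE, MMFE)."""
    key = variant.upper()
    if key not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}"
        )
    scheme, estimator = VARIANTS[key]
    sim = "hard" if estimator == "sample" else fuzzy_kind
    cfg = EntropyConfig(
        m=m, r=r, r_factor=r_factor, n=n, similarity=sim,
        min_separation=min_separation,
    )
    return _curve(u, key, scheme, estimator, cfg, tau_max, undefined_offsets)


def _alias(name: str):
    def f(u, **kwargs) -> MultiscaleCurve:
        return multiscale_curve(u, name, **kwargs)

    f.__name__ = name.lower()
    f.__qualname__ = name.lower()
    f.__doc__ = (
        f"{name} curve; see :func:`multiscale_curve` for keyword arguments."
    )
    return f


mse = _alias("MSE")
mfe = _alias("MFE")
cmse = _alias("CMSE")
cmfe = _alias("CMFE")
rcmse = _alias("RCMSE")
rcmfe = _alias("RCMFE")
mmse = _alias("MMSE")
mmfe = _alias("MMFE")
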