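"""Short-segment accuracy of multiscale entropy variants.

The question this module answers: how well does a multiscale entropy variant,
computed on short overlapping segments of a long series and averaged per
scale, reproduce the sample-entropy MSE curve of the *full-length* series?

Procedure, for one series and one variant:

1. cut the series into windows of length L with fractional overlap
   (default 90%, step = round(0.1 L));
2. compute the variant's curve on every window and take the arithmetic mean
   across windows at each scale (undefined window values are excluded from
   that scale's mean);
3. score the averaged curve by its mean squared difference from the reference
   curve -- always the hard-counting, standard-graining MSE of the full
   series -- over scales 1..tau_max.

Sweeping the fuzzy exponent n over a grid and the segment length L over a
list gives an :class:`ErrorSurface`; the per-length argmin over n is the
optimal exponent n*(L), and n*(L) is well described by a three-parameter
exponential a + b exp(c L), fitted here by nonlinear least squares.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .entropy import EntropyConfig
from .multiscale import VARIANTS, MultiscaleCurve, _check_feasible, _values_grid

__all__ = [
    "SegmentationScheme",
    "ErrorSurface",
    "ExponentModel",
    "segment_series",
    "averaged_curve",
    "curve_error",
    "error_surface",
    "optimal_exponents",
    "fit_exponent_curve",
    "predict_exponent",
    "DEFAULT_EXPONENTS_V1",
    "DEFAULT_EXPONENTS_V2",
]

logger = logging.getLogger(__name__)

#: Default fuzzy-exponent grids per membership function: 0.80..1.50 step 0.01
#: for exp(-d^n/r) and 1.30..5.50 step 0.05 for exp(-0.6931 (d/r)^n).
DEFAULT_EXPONENTS_V1 = np.round(np.arange(0.80, 1.50 + 1e-9, 0.01), 2)
DEFAULT_EXPONENTS_V2 = np.round(np.arange(1.30, 5.50 + 1e-9, 0.05), 2)


@dataclass(frozen=True)
class SegmentationScheme:
    """Sliding-window segmentation: length L, fractional overlap in [0, 1)."""

    length: int
    overlap: float = 0.9

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.step < 1:
            raise ValueError(
                f"overlap {self.overlap} with length {self.length} gives a "
                "zero step; use a smaller overlap"
            )

    @property
    def step(self) -> int:
        return int(round(self.length * (1.0 - self.overlap)))

    def n_windows(self, n: int) -> int:
        if self.length > n:
            raise ValueError(
                f"segment length {self.length} exceeds series length {n}"
            )
        return (n - self.length) // self.step + 1


def segment_series(u, scheme: SegmentationScheme | int, overlap: float = 0.9):
    """Fully-contained windows starting at 0, step, 2 step, ...

    ``scheme`` may be a :class:`SegmentationScheme` or a plain length (then
    ``overlap`` applies).  Returns a list of views into the input array.
    """
    if not isinstance(scheme, SegmentationScheme):
        scheme = SegmentationScheme(length=int(scheme), overlap=overlap)
    arr = np.ascontiguousarray(u, dtype=np.float64)
    count = scheme.n_windows(arr.size)
    step, length = scheme.step, scheme.length
    return [arr[i * step : i * step + length] for i in range(count)]


def _window_grid_mean(
    windows,
    scheme_name: str,
    estimator: str,
    cfg: EntropyConfig,
    n_grid: np.ndarray,
    tau_max: int,
    r_policy: str,
    precision: str,
) -> np.ndarray:
    """Per-scale mean of the variant's values across windows, for every
    exponent in the grid; NaN window values are excluded per scale."""
    width = 1 if estimator == "sample" else len(n_grid)
    total = np.zeros((tau_max, width))
    counts = np.zeros((tau_max, width), dtype=np.int64)
    for w in windows:
        if r_policy == "window":
            sd = float(np.std(w))
            r = cfg.r_factor * sd if sd > 0 else 1.0
        else:
            if cfg.r is None:
                raise ValueError("r_policy='full' requires an absolute r in cfg")
            r = cfg.r
        wcfg = EntropyConfig(
            m=cfg.m, r=r, n=cfg.n, similarity=cfg.similarity,
            min_separation=cfg.min_separation,
        )
        vals = _values_grid(
            np.ascontiguousarray(w), scheme_name, estimator, wcfg, n_grid,
            tau_max, precision=precision,
        )
        ok = np.isfinite(vals)
        total[ok] += vals[ok]
        counts += ok
    if (counts == 0).any():
        logger.warning(
            "some (scale, exponent) cells undefined in every window; "
            "their averaged values are NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    excluded = counts.size * len(windows) - counts.sum()
    if excluded:
        logger.info("excluded %d undefined window values from scale means", excluded)
    return mean


def averaged_curve(
    u,
    variant: str,
    L: int,
    *,
    m: int = 2,
    r: float | None = None,
    r_factor: float = 0.15,
    n: float = 1.0,
    fuzzy_kind: str = "fuzzy_v1",
    tau_max: int = 20,
    overlap: float = 0.9,
    r_policy: str = "window",
) -> MultiscaleCurve:
    """Window the series into length-L segments and average the variant's
    curve across windows at each scale.

    ``r_policy='window'`` recomputes r from each window's own SD (the default
    reading of "r = 0.15 x SD of the series" when the analysed series is the
    window); ``'full'`` inherits r from the full series instead.
    """
    key = variant.upper()
    scheme_name, estimator = VARIANTS[key]
    arr = np.ascontiguousarray(u, dtype=np.float64)
    windows = segment_series(arr, L, overlap)
    _check_feasible(L, m, scheme_name, tau_max)
    sim = "hard" if estimator == "sample" else fuzzy_kind
    full_sd = float(np.std(arr))
    r_abs = r if r is not None else (r_factor * full_sd if full_sd > 0 else 1.0)
    cfg = EntropyConfig(
        m=m, r=r_abs if r_policy == "full" else None, r_factor=r_factor,
        n=n, similarity=sim,
    )
    grid = np.asarray([n], dtype=np.float64)
    mean = _window_grid_mean(
        windows, scheme_name, estimator, cfg, grid, tau_max, r_policy, "double"
    )[:, 0]
    return MultiscaleCurve(
        variant=key,
        scales=np.arange(1, tau_max + 1),
        values=mean,
        config=EntropyConfig(m=m, r=r_abs, r_factor=r_factor, n=n, similarity=sim),
        r_basis={
            "sd": full_sd, "r_factor": r_factor, "policy": f"per-{r_policy}",
            "segment_length": L, "overlap": overlap, "n_windows": len(windows),
        },
    )


def curve_error(curve: MultiscaleCurve, reference: MultiscaleCurve) -> float:
    """Mean over scales of the squared difference to the reference curve.

    Scales where ``curve`` is undefined propagate: the result is NaN (with a
    warning) rather than silently dropping scales.  The reference must be
    fully defined.
    """
    if curve.scales.size != reference.scales.size or np.any(
        curve.scales != reference.scales
    ):
        raise ValueError("curve and reference cover different scale ranges")
    if not reference.defined.all():
        raise ValueError("reference curve has undefined scales")
    diff = curve.values - reference.values
    if np.isnan(diff).any():
        logger.warning(
            "curve undefined at %d scale(s); error is NaN",
            int(np.isnan(curve.values).sum()),
        )
        return math.nan
    return float(np.mean(diff * diff))


@dataclass(frozen=True)
class ErrorSurface:
    """Mean squared error vs the full-length MSE reference, indexed by
    (segment length, fuzzy exponent), averaged over series."""

    variant: str
    estimator: str
    lengths: np.ndarray
    exponents: np.ndarray  # [nan] sentinel for hard (sample) estimators
    errors: np.ndarray  # shape (len(lengths), len(exponents))
    tau_max: int
    n_series: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, length in enumerate(self.lengths):
            for j, n in enumerate(self.exponents):
                rows.append(
                    {
                        "variant": self.variant,
                        "estimator": self.estimator,
                        "length": int(length),
                        "exponent": float(n),
                        "error": float(self.errors[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def min_errors(self) -> np.ndarray:
        """Per-length minimum over the exponent grid (NaN if no cell defined)."""
        out = np.full(self.errors.shape[0], np.nan)
        for i, row in enumerate(self.errors):
            finite = row[np.isfinite(row)]
            if finite.size:
                out[i] = finite.min()
        return out


def error_surface(
    series_set,
    variant: str,
    lengths,
    exponents=None,
    *,
    m: int = 2,
    r_factor: float = 0.15,
    tau_max: int = 20,
    overlap: float = 0.9,
    fuzzy_kind: str = "fuzzy_v1",
    r_policy: str = "window",
    aggregate: str = "mean",
    precision: str = "single",
) -> ErrorSurface:
    """Mean squared error of the window-averaged variant curve against each
    series' own full-length MSE reference, for every (length, exponent).

    ``series_set`` is a list of 1-D arrays.  For fuzzy variants ``exponents``
    defaults to the conventional grid for the membership function; sample
    (hard) variants ignore it.  Per-series errors are combined across series
    with equal weight (``aggregate``: 'mean' or 'median').
    """
    key = variant.upper()
    scheme_name, estimator = VARIANTS[key]
    if estimator == "sample":
        grid = np.asarray([np.nan])
        eval_grid = np.asarray([1.0])
    else:
        if exponents is None:
            exponents = (
                DEFAULT_EXPONENTS_V2 if fuzzy_kind == "fuzzy_v2"
                else DEFAULT_EXPONENTS_V1
            )
        grid = np.asarray(exponents, dtype=np.float64)
        if grid.size == 0:
            raise ValueError("exponent grid is empty")
        eval_grid = grid
    lengths = np.asarray([int(x) for x in np.atleast_1d(lengths)])
    series_list = [np.ascontiguousarray(s, dtype=np.float64) for s in series_set]
    if not series_list:
        raise ValueError("series_set is empty")
    for s in series_list:
        if s.size < lengths.max():
            raise ValueError(
                f"series of {s.size} samples shorter than the largest "
                f"segment length {lengths.max()}"
            )
    sim = "hard" if estimator == "sample" else fuzzy_kind
    per_series = np.empty((len(series_list), len(lengths), len(eval_grid)))
    for si, s in enumerate(series_list):
        sd = float(np.std(s))
        ref_cfg = EntropyConfig(m=m, r=(r_factor * sd if sd > 0 else 1.0))
        _check_feasible(s.size, m, "standard", tau_max)
        ref = _values_grid(
            s, "standard", "sample", ref_cfg, np.asarray([1.0]), tau_max
        )[:, 0]
        if np.isnan(ref).any():
            raise ValueError(
                f"full-length MSE reference undefined at some scale for "
                f"series {si}; cannot score against it"
            )
        for li, L in enumerate(lengths):
            _check_feasible(int(L), m, scheme_name, tau_max)
            windows = segment_series(s, int(L), overlap)
            cfg = EntropyConfig(
                m=m,
                r=(r_factor * sd if sd > 0 else 1.0) if r_policy == "full" else None,
                r_factor=r_factor,
                similarity=sim,
            )
            mean = _window_grid_mean(
                windows, scheme_name, estimator, cfg, eval_grid, tau_max,
                r_policy, precision,
            )
            diff = mean - ref[:, None]
            per_series[si, li] = np.mean(diff * diff, axis=0)
    if aggregate == "median":
        errors = np.median(per_series, axis=0)
    else:
        errors = per_series.mean(axis=0)
    return ErrorSurface(
        variant=key,
        estimator=estimator,
        lengths=lengths,
        exponents=grid,
        errors=errors,
        tau_max=tau_max,
        n_series=len(series_list),
    )


def optimal_exponents(surface: ErrorSurface) -> dict[int, float]:
    """Per segment length, the grid exponent minimising the error; ties break
    toward the smallest exponent."""
    if surface.exponents.size == 0 or np.isnan(surface.exponents).all():
        raise ValueError("surface has no fuzzy exponent grid")
    order = np.argsort(surface.exponents, kind="stable")
    out: dict[int, float] = {}
    for i, length in enumerate(surface.lengths):
        row = surface.errors[i, order]
        best = order[int(np.nanargmin(row))]  # argmin returns first == smallest n
        out[int(length)] = float(surface.exponents[best])
    return out


@dataclass(frozen=True)
class ExponentModel:
    """Fitted n*(x) = a + b exp(c x): asymptote a, amplitude b, rate c
    (per sample), plus the RMS of the fit residuals."""

    a: float
    b: float
    c: float
    residual: float

    def predict(self, x) -> float | np.ndarray:
        return predict_exponent(self, x)


class FitConvergenceError(RuntimeError):
    """Exponential fit failed; carries the initial guess and data summary."""

    def __init__(self, message: str, p0: tuple[float, float, float]):
        super().__init__(f"{message} (initial guess a={p0[0]:.4g}, "
                         f"b={p0[1]:.4g}, c={p0[2]:.4g})")
        self.p0 = p0


def _exp_model(x, a, b, c):
    return a + b * np.exp(c * x)


def fit_exponent_curve(lengths, n_star) -> ExponentModel:
    """Nonlinear least-squares fit of n*(x) = a + b exp(c x).

    Initialisation: a from the mean of the last two points (the large-x
    asymptote), b from first minus last, |c| = 3e-4 per sample with the sign
    chosen so the exponential term decays toward the asymptote.
    """
    x = np.asarray(lengths, dtype=np.float64)
    y = np.asarray(n_star, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("lengths and n_star differ in size")
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a + b*exp(c*x)")
    order = np.argsort(x)
    x, y = x[order], y[order]
    a0 = float(np.mean(y[-2:]))
    b0 = float(y[0] - y[-1])
    c0 = -3e-4
    # If the points move away from the asymptote with x, a decaying term
    # cannot follow them; start with a growing exponential instead.
    if abs(y[-1] - a0) > abs(y[0] - a0):
        c0 = 3e-4
    p0 = (a0, b0 if b0 != 0 else 1e-6, c0)
    try:
        with warnings.catch_warnings():
            # degenerate data (e.g. constant n*) fits fine but has a singular
            # covariance, which we do not use
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_exp_model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(str(exc), p0) from exc
    resid = y - _exp_model(x, *popt)
    return ExponentModel(
        a=float(popt[0]),
        b=float(popt[1]),
        c=float(popt[2]),
        residual=float(np.sqrt(np.mean(resid**2))),
    )


def predict_exponent(model, x):
    """Evaluate a + b exp(c x); ``model`` is an ExponentModel or (a, b, c)."""
    if isinstance(model, ExponentModel):
        a, b, c = model.a, model.b, model.c
    else:
        a, b, c = model
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("segment length x must be positive")
    out = a + b * np.exp(c * x)
    return float(out) if out.ndim == 0 else out
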