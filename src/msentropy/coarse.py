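"""Coarse-graining: the three scale-reduction procedures.

A multiscale entropy curve looks at a series through block averages of
increasing length tau (the scale factor).  Three schemes are in use:

standard     non-overlapping block means, length floor(N/tau);
composite    the tau offset versions of the standard scheme (offsets
             k = 1..tau), whose entropies or match statistics are averaged by
             the composite / refined-composite variants;
overlapping  a moving average of length tau, keeping N - tau + 1 samples, used
             by the "modified" variants together with an entropy delay of tau.

Only fully-populated windows are emitted; there is no padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoarseSeries",
    "coarse_grain",
    "composite_coarse_grain",
    "overlapping_coarse_grain",
]


@dataclass(frozen=True)
class CoarseSeries:
    values: np.ndarray
    tau: int
    offset: int  # k in [1, tau]; 1 for the non-composite schemes
    scheme: str  # standard | composite | overlapping

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _check(u, tau: int) -> np.ndarray:
    arr = np.ascontiguousarray(u, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {arr.shape}")
    if tau < 1:
        raise ValueError(f"scale factor tau must be >= 1, got {tau}")
    if tau > arr.size:
        raise ValueError(
            f"scale factor tau={tau} exceeds series length N={arr.size}"
        )
    return arr


def coarse_grain(u, tau: int) -> CoarseSeries:
    """Non-overlapping block means; element j averages u((j-1)tau+1 .. j tau)."""
    arr = _check(u, tau)
    if tau == 1:
        return CoarseSeries(arr.copy(), tau=1, offset=1, scheme="standard")
    n_blocks = arr.size // tau
    vals = arr[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)
    return CoarseSeries(vals, tau=tau, offset=1, scheme="standard")


def composite_coarse_grain(u, tau: int, k: int) -> CoarseSeries:
    """Offset-k block means; element j averages u((j-1)tau+k .. j tau+k-1).

    Only fully-populated blocks are kept, so the length is
    floor((N - k + 1)/tau); k=1 reproduces :func:`coarse_grain`.
    """
    arr = _check(u, tau)
    if not 1 <= k <= tau:
        raise ValueError(f"offset k={k} outside [1, tau={tau}]")
    n_blocks = (arr.size - k + 1) // tau
    if n_blocks < 1:
        raise ValueError(
            f"no full block of length tau={tau} at offset k={k} in "
            f"a series of {arr.size} samples"
        )
    start = k - 1
    vals = arr[start : start + n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)
    return CoarseSeries(vals, tau=tau, offset=k, scheme="composite")


def overlapping_coarse_grain(u, tau: int) -> CoarseSeries:
    """Moving average of length tau; element i averages u(i .. i+tau-1).

    Length is N - tau + 1, far longer than floor(N/tau) at large scales, which
    is what makes the modified multiscale variants usable on short series.
    """
    arr = _check(u, tau)
    if tau == 1:
        return CoarseSeries(arr.copy(), tau=1, offset=1, scheme="overlapping")
    windows = np.lib.stride_tricks.sliding_window_view(arr, tau)
    vals = windows.mean(axis=1)
    return CoarseSeries(vals, tau=tau, offset=1, scheme="overlapping")
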