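"""Seeded synthetic series with the statistical structure the toolkit assumes.

Long stationary recordings (heart-rate-variability RR series are the
motivating case) are emulated by four generators:

white    iid Gaussian noise -- the analytic benchmark for sample entropy;
pink     1/f noise by spectral synthesis -- long-range correlated, the classic
         "complex" reference whose multiscale entropy curve stays flat;
ar1      a first-order autoregression with stationary initialisation;
rr_like  a positive baseline level with slow and oscillatory sinusoidal
         modulation plus AR(1) noise -- a statistical stand-in for an RR
         series (defaults sized so SD/mean is about 0.05, typical of resting
         sinus-rhythm variability), not a physiological model.

Every generator is a pure function of its arguments: the same spec always
yields the same samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalSpec",
    "gen_white_noise",
    "gen_pink_noise",
    "gen_ar1",
    "gen_rr_like",
    "generate",
]


def gen_white_noise(n: int, seed: int, sd: float = 1.0) -> np.ndarray:
    """iid Gaussian samples, mean 0, standard deviation ``sd``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, sd, size=n)


def gen_pink_noise(n: int, seed: int) -> np.ndarray:
    """1/f noise by spectral synthesis, standardised to mean 0, SD 1.

    Fourier amplitudes are drawn Gaussian and shaped proportional to
    f^(-1/2), so the power spectrum falls off as 1/f; the inverse real FFT
    gives a Gaussian series with the matching long-range autocorrelation.
    """
    if n < 16:
        raise ValueError("n must be >= 16 for a meaningful spectrum")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    spectrum = np.zeros(freqs.size, dtype=complex)
    shape = freqs[1:] ** -0.5
    re = rng.standard_normal(freqs.size - 1)
    im = rng.standard_normal(freqs.size - 1)
    spectrum[1:] = shape * (re + 1j * im)
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real  # Nyquist bin must be real
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    x /= x.std()
    return x


def gen_ar1(n: int, phi: float, seed: int, sd: float = 1.0) -> np.ndarray:
    """AR(1) process x(t) = phi x(t-1) + eps, innovation SD ``sd``.

    x(1) is drawn from the stationary distribution, so the whole series is
    stationary (no burn-in transient).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(phi) >= 1:
        raise ValueError(f"AR(1) requires |phi| < 1 for stationarity, got {phi}")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def gen_rr_like(
    n: int,
    seed: int,
    level: float = 800.0,
    lf_amplitude: float = 25.0,
    lf_period: float = 60.0,
    hf_amplitude: float = 15.0,
    hf_period: float = 4.0,
    noise_sd: float = 34.0,
    ar_phi: float = 0.8,
) -> np.ndarray:
    """RR-interval-like series (ms): baseline level + low-frequency and
    respiratory-like sinusoidal modulation + AR(1) noise.

    Defaults give mean ~800 ms and SD/mean ~0.05.  ``noise_sd`` is the
    stationary SD of the AR(1) component; periods are in beats.  Raises if the
    parameters can produce non-positive intervals.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    if level <= 0:
        raise ValueError("mean RR level must be positive")
    if lf_amplitude < 0 or hf_amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitudes and noise SD must be non-negative")
    t = np.arange(n, dtype=np.float64)
    x = level + lf_amplitude * np.sin(2 * np.pi * t / lf_period)
    x += hf_amplitude * np.sin(2 * np.pi * t / hf_period)
    if noise_sd > 0:
        innov_sd = noise_sd * np.sqrt(1.0 - ar_phi * ar_phi)
        x += gen_ar1(n, ar_phi, seed, sd=innov_sd)
    if np.any(x <= 0):
        raise ValueError(
            "parameters produced non-positive RR intervals; reduce the "
            "modulation amplitudes or noise SD relative to the mean level"
        )
    return x


_GENERATORS = {
    "white": gen_white_noise,
    "pink": gen_pink_noise,
    "ar1": gen_ar1,
    "rr_like": gen_rr_like,
}


@dataclass(frozen=True)
class SignalSpec:
    """Declarative description of a synthetic series (kind, length, seed,
    kind-specific params); the unit of reproducibility for files and configs."""

    kind: str
    n: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _GENERATORS:
            raise ValueError(
                f"unknown signal kind {self.kind!r}; expected one of "
                f"{sorted(_GENERATORS)}"
            )

    def generate(self) -> np.ndarray:
        return _GENERATORS[self.kind](self.n, seed=self.seed, **self.params)


def generate(spec: SignalSpec) -> np.ndarray:
    """Generate the series described by ``spec``."""
    return spec.generate()
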