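"""Single-scale entropy estimators: sample entropy and fuzzy entropy.

Both estimators quantify the (ir)regularity of a univariate series u(1..N) by
asking how often patterns of m consecutive (delay-spaced) samples that are
similar within a tolerance r remain similar when extended by one sample:

    SampEn(u, m, r, delta)    = -ln( C^{m+1}(r) / C^m(r) )
    FuzzyEn(u, m, n, r, delta) = -ln( phi^{m+1}(n, r) / phi^m(n, r) )

Sample entropy counts pairs with Chebyshev distance <= r (a hard threshold,
self-matches excluded).  Fuzzy entropy replaces the threshold with a smooth
membership function of the distance, evaluated on baseline-removed templates
(each template has its own mean subtracted), which keeps the estimator defined
and smooth even on very short series.

Conventions
-----------
* Exactly N - m*delta templates are used at BOTH dimensions m and m+1, so the
  conditional probability compares like with like (the standard
  Richman-Moorman convention).
* phi is the double average over ordered pairs i != j; by symmetry it is
  computed from unordered pairs.
* ``min_separation`` generalises the pair-exclusion rule: pairs with
  |i - j| < min_separation are skipped.  The default 1 excludes only
  self-matches (the canonical definition); ``delta + 1`` gives the stricter
  Theiler-style exclusion j > i + delta that some formulations state.
* r is an absolute tolerance here.  Callers that want the conventional
  r = 0.15 x SD derive it from the series first (see msentropy.multiscale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from ._kernels import chebyshev_condensed_block, hard_match_counts

__all__ = [
    "EntropyConfig",
    "MatchStatistics",
    "TemplateSet",
    "InsufficientLengthError",
    "build_templates",
    "chebyshev_distance",
    "fuzzy_similarity",
    "sampen",
    "fuzzyen",
    "entropy",
    "match_statistics",
]

#: Decay constant of the alternative membership function exp(-0.6931 (d/r)^n).
#: The conventional printed truncation of ln 2, kept literally so that the
#: membership at d = r is exp(-0.6931) for every exponent n.
FUZZY_V2_DECAY = 0.6931

SimilarityKind = Literal["hard", "fuzzy_v1", "fuzzy_v2"]

# Largest number of condensed distances held in memory at once in the fuzzy
# accumulation loop (~128 MB of float64).
_BLOCK_PAIRS = 16_000_000


class InsufficientLengthError(ValueError):
    """Raised when a series is too short for the requested embedding."""


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters of a single-scale entropy estimate.

    r is the absolute tolerance; if None, callers that know the series derive
    it as r_factor x SD.  n is the fuzzy exponent (ignored by the hard
    estimator).  delta is the delay between samples within a template.
    """

    m: int = 2
    r: float | None = None
    r_factor: float = 0.15
    n: float = 1.0
    delta: int = 1
    similarity: SimilarityKind = "hard"
    min_separation: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.r is not None and self.r <= 0:
            raise ValueError(f"tolerance r must be positive, got {self.r}")
        if self.n <= 0:
            raise ValueError(f"fuzzy exponent n must be positive, got {self.n}")
        if self.delta < 1:
            raise ValueError(f"delay delta must be >= 1, got {self.delta}")
        if self.similarity not in ("hard", "fuzzy_v1", "fuzzy_v2"):
            raise ValueError(f"unknown similarity kind {self.similarity!r}")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")

    def resolve_r(self, u: np.ndarray) -> "EntropyConfig":
        """Return a copy with r fixed to r_factor x SD(u) if not already set."""
        if self.r is not None:
            return self
        sd = float(np.std(u))
        if sd == 0.0:
            # Constant series: every distance is 0, any positive r works.
            return replace(self, r=1.0)
        return replace(self, r=self.r_factor * sd)


@dataclass(frozen=True)
class TemplateSet:
    """Delay-embedded template vectors x_m(i), optionally baseline-removed."""

    templates: np.ndarray  # (count, m)
    baseline: np.ndarray  # per-template mean subtracted (zeros if not removed)
    m: int
    delta: int

    @property
    def count(self) -> int:
        return self.templates.shape[0]


@dataclass(frozen=True)
class MatchStatistics:
    """Mean pattern-similarity at dimensions m and m+1, before the logarithm.

    For hard counting phi_* are match fractions; for fuzzy estimators they are
    mean memberships in (0, 1].  valid is False when a hard count is zero, in
    which case the entropy is undefined (NaN), never an exception.
    """

    phi_m: float
    phi_m1: float
    n_templates: int
    n_pairs: int
    valid: bool = True

    def entropy(self) -> float:
        if not self.valid or self.phi_m1 <= 0.0 or self.phi_m <= 0.0:
            return math.nan
        return -math.log(self.phi_m1 / self.phi_m)


def _as_series(u) -> np.ndarray:
    arr = np.ascontiguousarray(u, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {arr.shape}")
    if arr.size < 1:
        raise ValueError("series is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return arr


def _require_length(n: int, m: int, delta: int) -> int:
    count = n - m * delta
    if count < 2:
        raise InsufficientLengthError(
            f"insufficient length: series of {n} samples supports no pair of "
            f"dimension-{m} delay-{delta} templates; at least {m * delta + 2} "
            "samples are required"
        )
    return count


def _embed(
    arr: np.ndarray, dim: int, delta: int, count: int, remove_baseline: bool
) -> TemplateSet:
    idx = np.arange(count)[:, None] + np.arange(dim)[None, :] * delta
    templates = arr[idx]
    if remove_baseline:
        baseline = templates.mean(axis=1)
        templates = templates - baseline[:, None]
    else:
        baseline = np.zeros(count)
    return TemplateSet(templates=templates, baseline=baseline, m=dim, delta=delta)


def build_templates(
    u, m: int, delta: int = 1, remove_baseline: bool = False
) -> TemplateSet:
    """Build the N - m*delta delay-embedded template vectors.

    The count N - m*delta (rather than the maximal N - (m-1)*delta) is the
    shared-template convention: the same template starts serve the dimension-m
    and dimension-(m+1) comparisons, so conditional probabilities compare like
    with like.  With ``remove_baseline`` each template has its own mean
    subtracted, the construction fuzzy entropy applies before measuring
    distances.
    """
    arr = _as_series(u)
    count = _require_length(arr.size, m, delta)
    return _embed(arr, m, delta, count, remove_baseline)


def chebyshev_distance(a, b) -> float:
    """Maximum absolute coordinate difference between two equal-length vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.max(np.abs(a - b))) if a.size else 0.0


def fuzzy_similarity(d, r: float, n: float, kind: str = "fuzzy_v1"):
    """Membership of a distance d under tolerance r and fuzzy exponent n.

    fuzzy_v1: exp(-d^n / r)            (d and r not raised to the same power)
    fuzzy_v2: exp(-0.6931 (d/r)^n)     (half-membership at d = r for every n)
    """
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if n <= 0:
        raise ValueError("fuzzy exponent n must be positive")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    with np.errstate(over="ignore"):
        if kind == "fuzzy_v1":
            out = np.exp(-(d**n) / r)
        elif kind == "fuzzy_v2":
            out = np.exp(-FUZZY_V2_DECAY * (d / r) ** n)
        else:
            raise ValueError(f"unknown fuzzy similarity kind {kind!r}")
    return out if out.ndim else float(out)


def _iter_condensed(templates: np.ndarray, min_sep: int):
    """Yield condensed Chebyshev-distance blocks of bounded size."""
    count = templates.shape[0]
    if count < 2:
        return
    per_row = count  # upper bound on distances produced by one row
    rows_per_block = max(1, _BLOCK_PAIRS // per_row)
    buf = np.empty(rows_per_block * per_row)
    start = 0
    while start < count:
        stop = min(start + rows_per_block, count)
        written = chebyshev_condensed_block(templates, start, stop, min_sep, buf)
        if written:
            yield buf[:written]
        start = stop


def _fuzzy_phi(
    u: np.ndarray,
    dim: int,
    delta: int,
    count: int,
    r: float,
    n_values: np.ndarray,
    kind: str,
    min_sep: int,
    precision: str = "double",
) -> tuple[np.ndarray, int]:
    """Mean membership phi for ``count`` dimension-``dim`` baseline-removed
    templates, for each fuzzy exponent in ``n_values``.

    ``precision="single"`` evaluates the membership function in float32 with
    float64 accumulation -- used by the exponent-grid survey code where the
    downstream quantities are stochastic; the default double-precision path is
    the reference estimator.
    """
    ts = _embed(u, dim, delta, count, remove_baseline=True)
    sums = np.zeros(len(n_values))
    pairs = 0
    if kind == "fuzzy_v2":
        scale, decay = r, FUZZY_V2_DECAY
    else:
        scale, decay = 1.0, 1.0 / r
    for block in _iter_condensed(ts.templates, min_sep):
        pairs += block.size
        d = block / scale if scale != 1.0 else block
        if precision == "single":
            d = d.astype(np.float32)
        with np.errstate(over="ignore", under="ignore"):
            if _is_uniform_grid(n_values):
                t = d ** n_values[0]
                step = d ** (n_values[1] - n_values[0]) if len(n_values) > 1 else None
                for j in range(len(n_values)):
                    sums[j] += np.exp(-decay * t).sum(dtype=np.float64)
                    if step is not None and j + 1 < len(n_values):
                        t = t * step
            else:
                for j, n in enumerate(n_values):
                    sums[j] += np.exp(-decay * d**n).sum(dtype=np.float64)
    if pairs == 0:
        raise InsufficientLengthError("no template pairs to compare")
    return sums / pairs, pairs


def _is_uniform_grid(n_values: np.ndarray) -> bool:
    if len(n_values) < 3:
        return len(n_values) == 2
    diffs = np.diff(n_values)
    return bool(np.allclose(diffs, diffs[0], rtol=1e-12, atol=0))


def _hard_statistics(u: np.ndarray, m: int, delta: int, r: float, min_sep: int) -> MatchStatistics:
    count = _require_length(u.size, m, delta)
    b, a, pairs = hard_match_counts(u, m, delta, r, min_sep)
    if pairs == 0:
        raise InsufficientLengthError("no template pairs to compare")
    return MatchStatistics(
        phi_m=b / pairs,
        phi_m1=a / pairs,
        n_templates=count,
        n_pairs=pairs,
        valid=(b > 0 and a > 0),
    )


def _fuzzy_statistics(
    u: np.ndarray, m: int, delta: int, r: float, n: float, kind: str, min_sep: int,
    precision: str = "double",
) -> MatchStatistics:
    count = _require_length(u.size, m, delta)
    grid = np.asarray([n], dtype=np.float64)
    phi_m, pairs = _fuzzy_phi(u, m, delta, count, r, grid, kind, min_sep, precision)
    phi_m1, _ = _fuzzy_phi(u, m + 1, delta, count, r, grid, kind, min_sep, precision)
    return MatchStatistics(
        phi_m=float(phi_m[0]),
        phi_m1=float(phi_m1[0]),
        n_templates=count,
        n_pairs=pairs,
        valid=True,
    )


def match_statistics(u, cfg: EntropyConfig) -> MatchStatistics:
    """Similarity statistics phi^m, phi^{m+1} before the logarithm.

    Refined-composite multiscale variants average these across coarse-graining
    offsets before forming -ln(phi^{m+1}/phi^m).
    """
    arr = _as_series(u)
    cfg = cfg.resolve_r(arr)
    if cfg.similarity == "hard":
        return _hard_statistics(arr, cfg.m, cfg.delta, cfg.r, cfg.min_separation)
    return _fuzzy_statistics(
        arr, cfg.m, cfg.delta, cfg.r, cfg.n, cfg.similarity, cfg.min_separation
    )


def entropy(u, cfg: EntropyConfig) -> float:
    """Single-scale entropy under ``cfg`` (NaN when undefined)."""
    return match_statistics(u, cfg).entropy()


def sampen(
    u,
    r: float,
    m: int = 2,
    delta: int = 1,
    min_separation: int = 1,
) -> float:
    """Sample entropy -ln(C^{m+1}(r)/C^m(r)) with hard threshold matching.

    Returns NaN (an undefined marker, not an exception) when either match
    count is zero; use :func:`match_statistics` for the diagnostic counts.
    """
    cfg = EntropyConfig(
        m=m, r=r, delta=delta, similarity="hard", min_separation=min_separation
    )
    return entropy(u, cfg)


def fuzzyen(
    u,
    r: float,
    n: float = 1.0,
    m: int = 2,
    delta: int = 1,
    kind: str = "fuzzy_v1",
    min_separation: int = 1,
) -> float:
    """Fuzzy entropy -ln(phi^{m+1}/phi^m) on baseline-removed templates."""
    cfg = EntropyConfig(
        m=m, r=r, n=n, delta=delta, similarity=kind, min_separation=min_separation
    )
    return entropy(u, cfg)
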