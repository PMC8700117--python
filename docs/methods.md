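# Methods

## Estimators

Both single-scale estimators compare delay-embedded template vectors
x_m(i) = {u(i+kδ) : 0 ≤ k ≤ m−1} under the Chebyshev (maximum-coordinate)
distance.

**Sample entropy.** Exactly N − mδ templates are used at *both* dimensions
m and m+1 — the Richman–Moorman shared-template convention: the dimension-m
template list is truncated to the starts that can also be extended to
dimension m+1, so the conditional probability C^{m+1}/C^m compares like with
like and SampEn ≥ 0 whenever defined. Matching is the exact comparison
d ≤ r (no tolerance fudging); self-matches are excluded; ordered pairs are
normalised by (N−mδ)(N−mδ−1). When either match count is zero the result is
the value-level marker NaN, never an exception, so window averages can skip
undefined cells; `match_statistics` exposes the counts for diagnosis.

**Fuzzy entropy.** Templates additionally have their per-template mean
(baseline) removed before distances are taken. The similarity of a pair is a
smooth membership of its distance; φ^m is the double average of the
similarities over ordered pairs i ≠ j, and FuzzyEn = −ln(φ^{m+1}/φ^m).
Because every similarity is strictly positive, FuzzyEn is defined on any
admissible series — the property that motivates the fuzzy multiscale
variants on short segments.

Two membership functions are implemented. `fuzzy_v1`, exp(−d^n/r), is the
historical form; note d and r are not raised to the same power, so the
estimate is *not* invariant under jointly rescaling the series and r
(except n = 1). `fuzzy_v2`, exp(−0.6931·(d/r)^n), is scale-invariant and
crosses ½ exactly at d = r for every exponent; the decay constant is kept
as the conventional printed truncation 0.6931 (not ln 2 to machine
precision) so that membership at the tolerance is exp(−0.6931) ≈ 0.50002
reproducibly. As n → ∞, `fuzzy_v2` converges to hard-threshold counting on
the baseline-removed templates.

**Pair exclusion.** The default counts all ordered pairs i ≠ j, matching
the canonical SampEn/FuzzyEn definitions and reference implementations. A
stricter Theiler-style exclusion (|i − j| ≥ δ + 1, sometimes written
"j > i + δ") is available via `min_separation=delta + 1`; it is not the
default because published values are overwhelmingly computed without it.

Ambiguity resolved: in the printed fuzzy formulation the B statistics are
built from dimension-m distances and the A statistics from dimension-(m+1)
distances (superscript placement in the sources is inconsistent); φ is the
double average over pairs even where a single sum is printed.

## Coarse-graining and the eight variants

Three grainings: non-overlapping block means (length ⌊N/τ⌋), the composite
family of all τ block offsets (offset k keeps only fully-populated blocks,
length ⌊(N−k+1)/τ⌋ — the printed index bound 1 ≤ j ≤ N/τ would overrun the
array for k > 1, so trailing partial blocks are dropped), and the
overlapping moving average (length N−τ+1). No padding anywhere.

The composite variants average the τ offset entropies; if any offset is
undefined under hard counting the scale is undefined (the mean of a set
containing an undefined value is undefined) — an explicit
`undefined_offsets="skip"` averages the defined offsets instead, with a
logged count, since silent skipping would bias comparisons between
variants. The refined-composite variants average the match *fractions*
φ across offsets before taking −ln; offsets may differ by one in length
when τ ∤ N, and averaging fractions (not raw counts) keeps every offset
equally weighted. Refined-composite is therefore defined whenever any
offset has matches — strictly more often than the composite variant.

The modified variants pair the overlapping graining with an estimator delay
δ = τ, which keeps the embedded templates sampling the series at the scale
of interest while preserving series length.

**Tolerance policy.** r = r_factor × SD of the raw scale-1 series
(population SD, ddof = 0), fixed once and reused at every scale and offset —
the canonical multiscale convention; the entropy falls with scale for white
noise precisely because the coarse SD shrinks while r stays fixed. Default
r_factor = 0.15, m = 2, τ_max = 20. An absolute `r` can be given instead.

## Short-segment evaluation

Windows of length L start every `round(L·(1−overlap))` samples (default
overlap 0.9 → step L/10); only fully-contained windows are used, giving
⌊(N−L)/step⌋ + 1 windows. (For N = 15,892 and L = 400 this formula yields
388 windows; a count of 385 sometimes quoted for those dimensions is not
reproduced by any rounding of the stated rule and would correspond to an
effective length of 15,760 — both counts are noted here rather than
guessed at.)

Per window, the variant's curve is computed with r from the window's own SD
(default; the natural reading of "r = 0.15 × SD of the series" when the
analysed series is the window). `r_policy="full"` inherits the full-series
tolerance instead; the two readings are one flag apart because the original
procedure is ambiguous. Undefined window values are excluded from that
scale's mean (logged); a scale is undefined only if all windows are.

The error of a curve is the mean over scales 1..τ_max of the squared
difference from the reference — always hard-counting, standard-graining MSE
of the full series, even when scoring fuzzy variants, because the question
is how well each variant *estimates MSE*. Undefined scales propagate to a
NaN error rather than silently shrinking the average. Per-series errors are
combined across series with equal weights (median optional).

The default exponent grids are 0.80–1.50 step 0.01 for `fuzzy_v1` and
1.30–5.50 step 0.05 for `fuzzy_v2`, covering the ranges where optimal
exponents for RR data have been reported; ties in the per-length argmin
break toward the smallest exponent (deterministic).

**Exponent model.** n*(x) = a + b·exp(c·x) is fitted with
`scipy.optimize.curve_fit`, initialised from the data: a₀ = mean of the last
two points, b₀ = first − last, |c₀| = 3×10⁻⁴ per sample with the sign
chosen so the exponential decays toward the asymptote. Non-convergence
raises an error carrying the initial guess. The reported `residual` is the
RMS of the fit residuals. With 39 points (x = 400..15,600 step 400) and
additive noise of SD 0.01 on n*, the mean of 50 replicate fits recovers
generating parameters to ~1%; *per-replicate* 5% recovery holds only when
the amplitude |b| is large against the noise (e.g. b ≈ −0.75), not for
b ≈ −0.10, where the noise is 10% of the signal amplitude — a statistical
limit, not a fitting defect.

## Synthetic signals

White noise is the analytic anchor: for iid Gaussian data SampEn(m=2, r) →
−ln(2Φ(r/(σ√2)) − 1), ≈ 2.471 at r = 0.15σ, and ≈ 1.784 at scale 4 where
the coarse SD is σ/2. Pink (1/f) noise is generated by spectral synthesis —
Gaussian Fourier amplitudes shaped ∝ f^(−1/2), inverse real FFT,
standardised — chosen over cascaded filters because its log-log periodogram
slope (≈ −1 ± 0.15 at N = 16,384) is directly checkable. AR(1) uses a
stationary initial draw. The RR-like generator is a statistical stand-in
for a resting RR series, not a physiological model: a positive baseline
(default 800 ms) plus low-frequency (period 60 beats) and respiratory-like
(period 4 beats) sinusoids plus AR(1) noise, with default amplitudes
(25, 15, 34 ms) sized so SD/mean ≈ 0.05; it is validated to stay positive.
All generators are pure functions of (kind, N, seed, params).

What these synthetics do *not* capture: the non-Gaussian, nonstationary
structure of empirical RR series. This matters for one documented finding:
on Gaussian 1/f noise, fuzzy entropy (v1, baseline-removed) sits ~0.5 below
sample entropy at every scale for all exponents near 1, so windowed fuzzy
variants cannot approach the SampEn-based MSE reference the way they do on
empirical RR data, where the optimal exponent lies inside 0.8–1.5 and the
fuzzy variants dominate at short lengths. The fuzzy advantage re-emerges
even on Gaussian noise when the study is pushed to the regime that breaks
hard counting (scales up to 20 on 400-sample windows: composite hard
entropies become undefined and modified hard errors blow up). Passing tests
on synthetic data therefore validate the estimators, the graining algebra
and the evaluation machinery — not the empirical superiority ordering,
which is data-class dependent.

## Numerical choices

* Hard match counting and condensed Chebyshev distances are compiled
  (numba) pairwise loops, so long series (N ~ 2×10⁴, ~2×10⁸ pairs) never
  materialise a distance matrix; fuzzy membership sums stream over condensed
  distance blocks of ≤ 1.6×10⁷ pairs (~128 MB).
* Public estimators accumulate in double precision end to end and agree
  with naive all-pairs enumeration to 1e−12. The exponent-*grid* survey
  path (error surfaces) evaluates the membership function in float32 with
  float64 accumulation — a ~10⁻⁷ relative perturbation on φ, negligible
  against the stochastic quantities it feeds, and an order of magnitude
  faster on hosts without SIMD double-precision `exp`. `precision="double"`
  restores the reference path.
* Uniform exponent grids are evaluated with one power and repeated
  multiplication (d^{n₀+kΔ} = d^{n₀}·(d^Δ)^k) instead of a power per
  exponent.
* Degenerate inputs: constant series give entropy 0 (every template
  matches); a zero SD makes the relative tolerance fall back to r = 1 so
  the 0/0 is avoided; overflow in (d/r)^n for sharp exponents saturates to
  membership 0 deliberately.
* Study sizes in the shipped tests and acceptance script (series of
  2,000–20,000 samples, scales ≤ 10, ≤ 5 series) are chosen so the full
  suite completes in minutes on one CPU while every qualitative regime
  (short-window bias, undefined hard counts, analytic limits) is exercised.

## Known limitations

Univariate series only; no cross-entropy, permutation or dispersion
estimators; no wavelet or variance-based grainings; no ECG/beat-detection
or artifact handling (inputs are assumed to be clean RR or generic series);
no statistical testing between variants' error curves. Timing comparisons
between variants are structural (evaluation counts, series lengths), not
wall-clock benchmarks.
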