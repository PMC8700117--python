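"""Naive all-pairs reference implementations used as oracles.

Deliberately written from the definitions (explicit template lists, ordered
double loops, per-row sums) and independent of the package's optimised
kernels, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import math

import numpy as np

LN2_TRUNCATED = 0.6931


def embed_naive(u, dim, delta, count, remove_baseline):
    """Dimension-`dim` delay templates for starts 0..count-1 as a list."""
    out = []
    for i in range(count):
        t = np.array([u[i + k * delta] for k in range(dim)], dtype=float)
        if remove_baseline:
            t = t - t.mean()
        out.append(t)
    return out


def _similarity(d, r, n, kind):
    if kind == "hard":
        return 1.0 if d <= r else 0.0
    if kind == "fuzzy_v1":
        return math.exp(-(d**n) / r)
    if kind == "fuzzy_v2":
        return math.exp(-LN2_TRUNCATED * (d / r) ** n)
    raise ValueError(kind)


def phi_naive(u, dim, delta, count, r, n, kind, min_sep=1, remove_baseline=None):
    """Double average over ordered pairs |i-j| >= min_sep of the similarity.

    Row-by-row over the full ordered pair matrix (the optimised code walks a
    condensed upper triangle in compiled blocks, so the enumeration order and
    arithmetic differ).
    """
    if remove_baseline is None:
        remove_baseline = kind != "hard"
    templates = np.stack(
        embed_naive(u, dim, delta, count, remove_baseline=remove_baseline)
    )
    total = 0.0
    pairs = 0
    for i in range(count):
        d = np.max(np.abs(templates - templates[i]), axis=1)
        keep = np.abs(np.arange(count) - i) >= min_sep
        if kind == "hard":
            sims = (d[keep] <= r).astype(float)
        elif kind == "fuzzy_v1":
            sims = np.exp(-(d[keep] ** n) / r)
        else:
            sims = np.exp(-LN2_TRUNCATED * (d[keep] / r) ** n)
        total += float(sims.sum())
        pairs += int(keep.sum())
    if pairs == 0:
        raise ValueError("no pairs")
    return total / pairs


def match_counts_naive(u, m, r, delta=1, min_sep=1):
    """Ordered match counts (B, A) at dimensions m and m+1, shared count."""
    count = len(u) - m * delta
    tm = np.stack(embed_naive(u, m, delta, count, remove_baseline=False))
    tm1 = np.stack(embed_naive(u, m + 1, delta, count, remove_baseline=False))
    b = a = 0
    for i in range(count):
        keep = np.abs(np.arange(count) - i) >= min_sep
        b += int((np.max(np.abs(tm - tm[i]), axis=1)[keep] <= r).sum())
        a += int((np.max(np.abs(tm1 - tm1[i]), axis=1)[keep] <= r).sum())
    return b, a


def sampen_naive(u, m, r, delta=1, min_sep=1):
    b, a = match_counts_naive(u, m, r, delta, min_sep)
    if b == 0 or a == 0:
        return math.nan
    return -math.log(a / b)


def fuzzyen_naive(u, m, r, n, delta=1, kind="fuzzy_v1", min_sep=1):
    count = len(u) - m * delta
    phi_m = phi_naive(u, m, delta, count, r, n, kind, min_sep)
    phi_m1 = phi_naive(u, m + 1, delta, count, r, n, kind, min_sep)
    return -math.log(phi_m1 / phi_m)


def entropy_naive(u, estimator, m, r, n, kind="fuzzy_v1", delta=1):
    if estimator == "sample":
        return sampen_naive(u, m, r, delta)
    return fuzzyen_naive(u, m, r, n, delta, kind)


def coarse_naive(u, tau):
    return [
        sum(u[(j * tau) : (j * tau + tau)]) / tau for j in range(len(u) // tau)
    ]


def composite_naive(u, tau, k):
    n_blocks = (len(u) - k + 1) // tau
    start = k - 1
    return [
        sum(u[start + j * tau : start + j * tau + tau]) / tau
        for j in range(n_blocks)
    ]


def overlapping_naive(u, tau):
    return [sum(u[i : i + tau]) / tau for i in range(len(u) - tau + 1)]


def hard_phis_naive(u, m, r, delta=1):
    """(phi_m, phi_m1) hard match fractions over ordered pairs."""
    count = len(u) - m * delta
    pairs = count * (count - 1)
    b, a = match_counts_naive(u, m, r, delta)
    return b / pairs, a / pairs


def curve_naive(u, variant, m, r, n, tau_max, kind="fuzzy_v1"):
    """Any of the eight multiscale curves from naive components; NaN marks
    undefined scales."""
    u = np.asarray(u, dtype=float)
    estimator = "sample" if variant in ("MSE", "CMSE", "RCMSE", "MMSE") else "fuzzy"
    values = []
    for tau in range(1, tau_max + 1):
        if variant in ("MSE", "MFE"):
            g = coarse_naive(u, tau)
            values.append(entropy_naive(g, estimator, m, r, n, kind, delta=1))
        elif variant in ("CMSE", "CMFE"):
            vals = [
                entropy_naive(
                    composite_naive(u, tau, k), estimator, m, r, n, kind, delta=1
                )
                for k in range(1, tau + 1)
            ]
            values.append(sum(vals) / tau)  # nan propagates
        elif variant in ("RCMSE", "RCMFE"):
            pm_list, pm1_list = [], []
            for k in range(1, tau + 1):
                g = composite_naive(u, tau, k)
                if estimator == "sample":
                    pm, pm1 = hard_phis_naive(g, m, r)
                else:
                    count = len(g) - m
                    pm = phi_naive(g, m, 1, count, r, n, kind)
                    pm1 = phi_naive(g, m + 1, 1, count, r, n, kind)
                pm_list.append(pm)
                pm1_list.append(pm1)
            pm_bar = sum(pm_list) / tau
            pm1_bar = sum(pm1_list) / tau
            values.append(
                -math.log(pm1_bar / pm_bar) if pm_bar > 0 and pm1_bar > 0 else math.nan
            )
        elif variant in ("MMSE", "MMFE"):
            g = overlapping_naive(u, tau)
            values.append(entropy_naive(g, estimator, m, r, n, kind, delta=tau))
        else:
            raise ValueError(variant)
    return np.array(values)
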