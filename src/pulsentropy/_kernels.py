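"""Compiled pairwise template-matching kernels.

Sample/fuzzy entropy needs all O(N^2) pairwise Chebyshev distances between
delay-embedded templates; these loops are the runtime bottleneck of the
whole pipeline, so they are JIT-compiled with numba.  All kernels count
ordered pairs (i != j) over templates i = 0..N-m-1, with the length-(m+1)
distance obtained by extending the length-m running maximum.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["crisp_counts", "fuzzy_sums", "combined_counts"]


@njit(cache=True)
def crisp_counts(y: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """Ordered-pair match counts ``(a, b)`` at lengths m+1 and m, d <= r."""
    n_t = y.size - m
    a = 0
    b = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            d = 0.0
            for k in range(m):
                diff = abs(y[i + k] - y[j + k])
                if diff > d:
                    d = diff
                    if d > r:
                        break
            if d > r:
                continue
            b += 1
            diff = abs(y[i + m] - y[j + m])
            if diff <= r and d <= r:
                a += 1
    return 2.0 * a, 2.0 * b


@njit(cache=True)
def fuzzy_sums(
    y: np.ndarray, m: int, r: float, n_power: float
) -> tuple[float, float]:
    """Ordered-pair membership sums ``(a, b)``: exp(-(d/r)^n) over i != j."""
    n_t = y.size - m
    a = 0.0
    b = 0.0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            d = 0.0
            for k in range(m):
                diff = abs(y[i + k] - y[j + k])
                if diff > d:
                    d = diff
            b += math.exp(-((d / r) ** n_power))
            diff = abs(y[i + m] - y[j + m])
            if diff > d:
                d = diff
            a += math.exp(-((d / r) ** n_power))
    return 2.0 * a, 2.0 * b


@njit(cache=True)
def combined_counts(
    y: np.ndarray, m: int, r: float, n_power: float
) -> tuple[float, float, float, float]:
    """Crisp counts and fuzzy sums from one pass over the pair distances.

    Returns ``(a_crisp, b_crisp, a_fuzzy, b_fuzzy)``.
    """
    n_t = y.size - m
    a_c = 0.0
    b_c = 0.0
    a_f = 0.0
    b_f = 0.0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            d = 0.0
            for k in range(m):
                diff = abs(y[i + k] - y[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                b_c += 1.0
            b_f += math.exp(-((d / r) ** n_power))
            diff = abs(y[i + m] - y[j + m])
            if diff > d:
                d = diff
            if d <= r:
                a_c += 1.0
            a_f += math.exp(-((d / r) ** n_power))
    return 2.0 * a_c, 2.0 * b_c, 2.0 * a_f, 2.0 * b_f
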