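"""Single-scale entropy estimators: sample, fuzzy, permutation, dispersion.

All four quantify the irregularity of a one-dimensional series but probe
different aspects of it:

* sample entropy (SaEn) — the negative log of the conditional probability
  that template vectors close at length m (Chebyshev distance within a
  tolerance r, self-matches excluded) remain close at length m+1;
* fuzzy entropy (FuEn) — SaEn with the hard match threshold replaced by a
  graded membership exp(-(d/r)^n), continuous in r and always finite;
* permutation entropy (PeEn) — Shannon entropy of the ordinal (rank-order)
  pattern distribution, normalized by ln(m!) to [0, 1];
* dispersion entropy (DiEn) — Shannon entropy of patterns of amplitude
  classes obtained by pushing samples through the normal CDF into c
  classes, normalized by ln(c^m).

Conventions used throughout: natural logarithms; 0 ln 0 = 0; ordinal ties
broken by original index order (stable sort); tolerance r defaults to
``r_factor`` times the series SD.  An undefined sample entropy (zero crisp
matches at either length) is returned as ``nan`` rather than raised — the
refined composite multiscale framework exists precisely to reduce its
incidence on short coarse-grained series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from ._kernels import crisp_counts, fuzzy_sums

__all__ = [
    "EntropyParams",
    "chebyshev_distance",
    "sample_entropy",
    "fuzzy_entropy",
    "sample_match_counts",
    "fuzzy_match_counts",
    "ordinal_pattern",
    "ordinal_pattern_distribution",
    "permutation_entropy",
    "dispersion_map",
    "dispersion_pattern_distribution",
    "dispersion_entropy",
]


@dataclass(frozen=True)
class EntropyParams:
    """Estimator configuration shared by all four measures.

    Defaults follow common practice for short physiological records:
    embedding dimension ``m = 3``; tolerance ``r = 0.15 sigma``; fuzzy
    membership exponent ``n = 2``; ``c = 6`` amplitude classes for
    dispersion patterns; unit delay; scales 1..10 for the multiscale
    profiles.
    """

    m: int = 3
    r_factor: float = 0.15
    n: float = 2.0
    c: int = 6
    delay: int = 1
    tau_max: int = 10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("tolerance factor r_factor must be positive")
        if self.n <= 0:
            raise ValueError("fuzzy power n must be positive")
        if self.c < 2:
            raise ValueError("number of classes c must be >= 2")
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")


def chebyshev_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Maximum absolute componentwise difference (the infinity norm)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v)))


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    """Delay-embedding matrix with rows (x_i, x_{i+d}, ..., x_{i+(m-1)d})."""
    n_win = x.size - (m - 1) * delay
    if n_win < 1:
        raise ValueError(
            f"series of length {x.size} too short for m={m}, delay={delay}"
        )
    idx = np.arange(n_win)[:, None] + delay * np.arange(m)[None, :]
    return x[idx]


def _resolve_r(x: np.ndarray, params: EntropyParams, r: float | None) -> float:
    if r is None:
        sd = float(np.std(x))
        if sd == 0:
            raise ValueError(
                "constant series: tolerance r = r_factor * SD is zero; "
                "supply an absolute r instead"
            )
        r = params.r_factor * sd
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    return float(r)


def _pairwise_chebyshev(X: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Chebyshev distances at template lengths ``m`` and ``m + 1``.

    ``X`` has ``m + 1`` columns; the length-m distance uses the first m and
    the length-(m+1) distance is its running maximum with the last column.
    """
    d_m = np.abs(X[:, 0][:, None] - X[:, 0][None, :])
    for k in range(1, m):
        np.maximum(d_m, np.abs(X[:, k][:, None] - X[:, k][None, :]), out=d_m)
    d_m1 = np.maximum(d_m, np.abs(X[:, m][:, None] - X[:, m][None, :]))
    return d_m, d_m1


def sample_match_counts(
    x: np.ndarray, m: int, r: float
) -> tuple[float, float]:
    """Pooled crisp template-match counts ``(a, b)`` at lengths m+1 and m.

    Both template sets run over i = 1..N-m so the pair sets are comparable;
    matches are ordered pairs with d <= r and i != j.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.size < m + 2:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    return crisp_counts(x, m, r)


def fuzzy_match_counts(
    x: np.ndarray, m: int, r: float, n_power: float = 2.0
) -> tuple[float, float]:
    """Pooled fuzzy membership sums ``(a, b)`` at lengths m+1 and m.

    Each crisp match is replaced by the graded membership
    ``exp(-(d/r)^n)``, summed over ordered pairs i != j.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.size < m + 2:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    return fuzzy_sums(x, m, r, n_power)


def sample_entropy(
    x: np.ndarray,
    params: EntropyParams | None = None,
    r: float | None = None,
    method: str = "pooled",
) -> float:
    """Sample entropy of a series; ``nan`` when undefined.

    ``r`` defaults to ``params.r_factor * SD(x)``; pass an absolute ``r``
    for series whose SD is zero or fixed externally.  ``method="pooled"``
    (the default) returns ``-ln(A/B)`` over pooled pair counts; the
    ``"averaged"`` variant instead averages per-template log-probabilities
    (the approximate-entropy style estimate) and is provided for
    comparison only.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    if x.size < params.m + 2:
        raise ValueError(f"series of length {x.size} too short for m={params.m}")
    r = _resolve_r(x, params, r)
    if method == "pooled":
        a, b = sample_match_counts(x, params.m, r)
        if a <= 0 or b <= 0:
            return math.nan
        return -math.log(a / b)
    if method == "averaged":
        return _sample_entropy_averaged(x, params.m, r)
    raise ValueError(f"unknown method {method!r}")


def _sample_entropy_averaged(x: np.ndarray, m: int, r: float) -> float:
    """Per-template averaged-log variant (approximate-entropy style)."""
    X = _embed(x, m + 1)
    d_m, d_m1 = _pairwise_chebyshev(X, m)
    n_t = X.shape[0]
    denom = n_t - 1
    c_m = (np.count_nonzero(d_m <= r, axis=1) - 1) / denom
    c_m1 = (np.count_nonzero(d_m1 <= r, axis=1) - 1) / denom
    if np.any(c_m == 0) or np.any(c_m1 == 0):
        return math.nan
    return float(np.mean(np.log(c_m)) - np.mean(np.log(c_m1)))


def fuzzy_entropy(
    x: np.ndarray,
    params: EntropyParams | None = None,
    r: float | None = None,
    center: bool = False,
) -> float:
    """Fuzzy entropy of a series; finite for any series of length >= m + 2.

    With ``center=True`` each template has its own mean removed before the
    distance computation (a common variant that measures only local shape);
    the default compares raw templates.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    if x.size < params.m + 2:
        raise ValueError(f"series of length {x.size} too short for m={params.m}")
    r = _resolve_r(x, params, r)
    m = params.m
    if not center:
        a, b = fuzzy_match_counts(x, m, r, params.n)
        return -math.log(a / b)
    # centered variant needs separate embeddings per template length
    total = []
    for mm in (m, m + 1):
        X = _embed(x, mm)
        X = X - X.mean(axis=1, keepdims=True)
        d = np.abs(X[:, 0][:, None] - X[:, 0][None, :])
        for k in range(1, mm):
            np.maximum(d, np.abs(X[:, k][:, None] - X[:, k][None, :]), out=d)
        n_full = x.size - m  # keep both template sets the same size
        d = d[:n_full, :n_full]
        e = np.exp(-((d / r) ** params.n))
        np.fill_diagonal(e, 0.0)
        total.append(float(np.sum(e)))
    b, a = total
    return -math.log(a / b)


# ---------------------------------------------------------------------------
# ordinal (permutation) patterns
# ---------------------------------------------------------------------------

def ordinal_pattern(window: np.ndarray) -> tuple[int, ...]:
    """Permutation of indices sorting the window ascending, ties by index.

    The stable sort makes tied amplitudes resolve in original order, so the
    mapping is deterministic.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1:
        raise ValueError("window must be 1-D")
    return tuple(int(i) for i in np.argsort(w, kind="stable"))


def _pattern_codes(X: np.ndarray) -> np.ndarray:
    """Encode each row's ordinal pattern as an integer (mixed-radix)."""
    m = X.shape[1]
    perms = np.argsort(X, axis=1, kind="stable")
    codes = np.zeros(X.shape[0], dtype=np.int64)
    for k in range(m):
        codes = codes * m + perms[:, k]
    return codes


def ordinal_pattern_distribution(
    x: np.ndarray, m: int, delay: int = 1
) -> dict[int, float]:
    """Relative frequency of each observed ordinal pattern (coded as int)."""
    x = np.asarray(x, dtype=float)
    X = _embed(x, m, delay)
    codes, counts = np.unique(_pattern_codes(X), return_counts=True)
    total = counts.sum()
    return {int(c): float(k) / total for c, k in zip(codes, counts)}


def shannon_entropy(probabilities: np.ndarray) -> float:
    """Shannon entropy in nats with the 0 ln 0 = 0 convention."""
    p = np.asarray(probabilities, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def permutation_entropy(
    x: np.ndarray, params: EntropyParams | None = None
) -> float:
    """Normalized permutation entropy in [0, 1].

    0 for a monotone (single-pattern) series, 1 when all m! ordinal
    patterns are equally frequent.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    if x.size - (params.m - 1) * params.delay < 2:
        raise ValueError(
            f"series of length {x.size} too short for m={params.m}, "
            f"delay={params.delay}"
        )
    dist = ordinal_pattern_distribution(x, params.m, params.delay)
    h = shannon_entropy(np.array(list(dist.values())))
    return h / math.log(math.factorial(params.m))


# ---------------------------------------------------------------------------
# dispersion patterns
# ---------------------------------------------------------------------------

def dispersion_map(
    x: np.ndarray,
    c: int = 6,
    mu: float | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Map amplitudes to integer classes 1..c through the normal CDF.

    ``y = Phi((x - mu)/sigma)`` followed by ``z = round(c*y + 0.5)`` (half
    rounds up) clipped to [1, c].  ``mu``/``sigma`` default to the sample
    mean and SD of ``x`` itself; the multiscale framework passes the
    full-resolution moments so classes stay comparable across scales.
    """
    x = np.asarray(x, dtype=float)
    mu = float(np.mean(x)) if mu is None else mu
    sigma = float(np.std(x)) if sigma is None else sigma
    if sigma <= 0:
        raise ValueError("constant series: cannot build the class mapping")
    y = ndtr((x - mu) / sigma)
    z = np.floor(c * y + 1.0).astype(np.int64)  # round-half-up of c*y + 0.5
    return np.clip(z, 1, c)


def dispersion_pattern_distribution(
    z: np.ndarray, m: int, c: int, delay: int = 1
) -> dict[int, float]:
    """Relative frequency of dispersion patterns of the class series ``z``."""
    Z = _embed(np.asarray(z, dtype=np.int64), m, delay)
    codes = np.zeros(Z.shape[0], dtype=np.int64)
    for k in range(m):
        codes = codes * c + (Z[:, k] - 1)
    vals, counts = np.unique(codes, return_counts=True)
    total = counts.sum()
    return {int(v): float(k) / total for v, k in zip(vals, counts)}


def dispersion_entropy(
    x: np.ndarray,
    params: EntropyParams | None = None,
    mu: float | None = None,
    sigma: float | None = None,
) -> float:
    """Normalized dispersion entropy in [0, 1]."""
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    if x.size - (params.m - 1) * params.delay < 2:
        raise ValueError(
            f"series of length {x.size} too short for m={params.m}, "
            f"delay={params.delay}"
        )
    z = dispersion_map(x, params.c, mu=mu, sigma=sigma)
    dist = dispersion_pattern_distribution(z, params.m, params.c, params.delay)
    h = shannon_entropy(np.array(list(dist.values())))
    return h / (params.m * math.log(params.c))
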