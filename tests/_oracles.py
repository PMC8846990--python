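"""Independent brute-force reference implementations.

Everything here is written as literal double loops / full enumerations,
deliberately sharing no code with the package, so the fast vectorized
estimators can be checked against them on small inputs.
"""

from __future__ import annotations

import math
from collections import Counter


def chebyshev_brute(u, v):
    assert len(u) == len(v)
    return max(abs(a - b) for a, b in zip(u, v))


def _templates(x, m):
    """Template vectors of length m for i = 0..N-m-1 (both lengths use this range)."""
    n = len(x)
    return [tuple(x[i + k] for k in range(m)) for i in range(n - m)]


def sample_entropy_brute(x, m, r):
    """Pooled-pair sample entropy by explicit double loop; nan if undefined."""
    a = b = 0
    temps_m = _templates(x, m)
    temps_m1 = _templates_m1(x, m)
    for i in range(len(temps_m)):
        for j in range(len(temps_m)):
            if i == j:
                continue
            if chebyshev_brute(temps_m[i], temps_m[j]) <= r:
                b += 1
            if chebyshev_brute(temps_m1[i], temps_m1[j]) <= r:
                a += 1
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def _templates_m1(x, m):
    """Length-(m+1) templates over the same i range as the length-m ones."""
    n = len(x)
    return [tuple(x[i + k] for k in range(m + 1)) for i in range(n - m)]


def fuzzy_entropy_brute(x, m, r, n_power=2.0):
    total = {}
    for key, temps in (("b", _templates(x, m)), ("a", _templates_m1(x, m))):
        s = 0.0
        for i in range(len(temps)):
            for j in range(len(temps)):
                if i == j:
                    continue
                d = chebyshev_brute(temps[i], temps[j])
                s += math.exp(-((d / r) ** n_power))
        total[key] = s
    return -math.log(total["a"] / total["b"])


def ordinal_pattern_brute(window):
    """Stable argsort by (value, index) pairs."""
    return tuple(i for _, i in sorted((v, i) for i, v in enumerate(window)))


def permutation_entropy_brute(x, m, delay=1):
    n_win = len(x) - (m - 1) * delay
    patterns = Counter(
        ordinal_pattern_brute([x[i + k * delay] for k in range(m)])
        for i in range(n_win)
    )
    h = 0.0
    for count in patterns.values():
        p = count / n_win
        h -= p * math.log(p)
    return h / math.log(math.factorial(m))


def _phi(z):
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def dispersion_map_brute(x, c, mu=None, sigma=None):
    if mu is None:
        mu = sum(x) / len(x)
    if sigma is None:
        sigma = (sum((v - mu) ** 2 for v in x) / len(x)) ** 0.5
    z = []
    for v in x:
        y = _phi((v - mu) / sigma)
        cls = math.floor(c * y + 1.0)  # round-half-up of c*y + 0.5
        z.append(min(max(cls, 1), c))
    return z


def dispersion_entropy_brute(x, m, c, delay=1, mu=None, sigma=None):
    z = dispersion_map_brute(x, c, mu, sigma)
    n_win = len(z) - (m - 1) * delay
    patterns = Counter(
        tuple(z[i + k * delay] for k in range(m)) for i in range(n_win)
    )
    h = 0.0
    for count in patterns.values():
        p = count / n_win
        h -= p * math.log(p)
    return h / math.log(c**m)


def coarse_grain_brute(x, tau, k):
    """Literal evaluation of the windowed-mean definition (1-based k)."""
    n = len(x)
    out = []
    j = 1
    while (j - 1) * tau + k - 1 + tau <= n:
        start = (j - 1) * tau + k - 1
        out.append(sum(x[start : start + tau]) / tau)
        j += 1
    return out


def rc_sample_entropy_brute(x, tau, m, r):
    """Pool crisp counts over every offset series built explicitly."""
    a = b = 0
    for k in range(1, tau + 1):
        y = coarse_grain_brute(x, tau, k)
        temps_m = _templates(y, m)
        temps_m1 = _templates_m1(y, m)
        for i in range(len(temps_m)):
            for j in range(len(temps_m)):
                if i == j:
                    continue
                if chebyshev_brute(temps_m[i], temps_m[j]) <= r:
                    b += 1
                if chebyshev_brute(temps_m1[i], temps_m1[j]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def rc_fuzzy_entropy_brute(x, tau, m, r, n_power=2.0):
    a = b = 0.0
    for k in range(1, tau + 1):
        y = coarse_grain_brute(x, tau, k)
        temps_m = _templates(y, m)
        temps_m1 = _templates_m1(y, m)
        for i in range(len(temps_m)):
            for j in range(len(temps_m)):
                if i == j:
                    continue
                d_m = chebyshev_brute(temps_m[i], temps_m[j])
                d_m1 = chebyshev_brute(temps_m1[i], temps_m1[j])
                b += math.exp(-((d_m / r) ** n_power))
                a += math.exp(-((d_m1 / r) ** n_power))
    return -math.log(a / b)


def rc_permutation_entropy_brute(x, tau, m, delay=1):
    """Average ordinal-pattern distributions over explicit offset series."""
    avg = Counter()
    for k in range(1, tau + 1):
        y = coarse_grain_brute(x, tau, k)
        n_win = len(y) - (m - 1) * delay
        counts = Counter(
            ordinal_pattern_brute([y[i + kk * delay] for kk in range(m)])
            for i in range(n_win)
        )
        for pat, cnt in counts.items():
            avg[pat] += cnt / n_win / tau
    h = -sum(p * math.log(p) for p in avg.values() if p > 0)
    return h / math.log(math.factorial(m))


def rc_dispersion_entropy_brute(x, tau, m, c, delay=1):
    """As above for dispersion patterns; class map frozen at full-series moments."""
    mu = sum(x) / len(x)
    sigma = (sum((v - mu) ** 2 for v in x) / len(x)) ** 0.5
    avg = Counter()
    for k in range(1, tau + 1):
        y = coarse_grain_brute(x, tau, k)
        z = dispersion_map_brute(y, c, mu, sigma)
        n_win = len(z) - (m - 1) * delay
        counts = Counter(
            tuple(z[i + kk * delay] for kk in range(m)) for i in range(n_win)
        )
        for pat, cnt in counts.items():
            avg[pat] += cnt / n_win / tau
    h = -sum(p * math.log(p) for p in avg.values() if p > 0)
    return h / math.log(c**m)
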