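"""Independent brute-force references used to check the vectorized code.

Everything here is written as plain loops over explicit formulas so it
shares no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_mean_std_cov(samples) -> tuple[float, float, float]:
    """Two-pass mean / sample std (N-1) / CoV of a 1D sample sequence."""
    xs = [float(x) for x in samples]
    n = len(xs)
    mean = sum(xs) / n
    var = sum((x - mean) ** 2 for x in xs) / (n - 1)
    std = math.sqrt(var)
    cov = 0.0 if mean == 0 or std == 0 else std / mean
    return mean, std, cov


def naive_cov_stack(stack: np.ndarray) -> np.ndarray:
    """Element-wise CoV of a (N, ...) stack by explicit per-element loops."""
    n = stack.shape[0]
    flat = stack.reshape(n, -1)
    out = np.empty(flat.shape[1])
    for j in range(flat.shape[1]):
        _, _, cov = naive_mean_std_cov(flat[:, j])
        out[j] = cov
    return out.reshape(stack.shape[1:])


def naive_lognormal_pdf(v: float, mu: float, sigma: float) -> float:
    if v <= 0:
        return 0.0
    return math.exp(-((math.log(v) - mu) ** 2) / (2 * sigma**2)) / (
        v * sigma * math.sqrt(2 * math.pi)
    )


def grid_intersection(lam, mu, sigma, n=200_001) -> float:
    """Dense-grid argmin of |weighted density difference| between the modes."""
    modes = sorted(math.exp(m - s**2) for m, s in zip(mu, sigma))
    vs = np.linspace(modes[0], modes[1], n)
    diffs = [
        abs(
            lam[0] * naive_lognormal_pdf(v, mu[0], sigma[0])
            - lam[1] * naive_lognormal_pdf(v, mu[1], sigma[1])
        )
        for v in vs
    ]
    return float(vs[int(np.argmin(diffs))])
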