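"""Small statistical primitives shared by the samplers and estimate tables."""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import gaussian_kde

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def truncnorm_logpdf(x, loc, scale, lower, upper):
    """Log density of N(loc, scale) truncated to [lower, upper].

    ``loc``/``scale`` are the pre-truncation mean and standard deviation (the
    conventional reading of a truncated ``N(M, s)``).  Stable for bounds far
    in the tails via log-CDF differencing.
    """
    x = np.asarray(x, dtype=float)
    loc = np.asarray(loc, dtype=float)
    scale = np.asarray(scale, dtype=float)
    z = (x - loc) / scale
    beta = (upper - loc) / scale
    alpha = (lower - loc) / scale
    # log(Phi(beta) - Phi(alpha)) without cancellation
    la, lb = log_ndtr(alpha), log_ndtr(beta)
    log_z = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-16)))
    out = -0.5 * z * z - np.log(scale) - _LOG_SQRT_2PI - log_z
    return np.where((x >= lower) & (x <= upper), out, -np.inf)


def truncnorm_mean(loc, scale, lower, upper):
    """Analytic mean of a truncated normal (used as a prior-sampling oracle)."""
    a = (lower - loc) / scale
    b = (upper - loc) / scale
    phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)
    z = ndtr(b) - ndtr(a)
    return loc + scale * (phi(a) - phi(b)) / z


def hpd_interval(samples, prob: float = 0.95):
    """Shortest contiguous interval containing ``prob`` posterior mass.

    Assumes a unimodal marginal; computed by sliding a window over the sorted
    samples.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 4:
        return float(x[0]), float(x[-1])
    k = max(int(np.ceil(prob * n)), 2)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def kde_map(samples, grid_size: int = 512):
    """Sample-based MAP: mode of a Gaussian-KDE fit on a 512-point grid."""
    x = np.asarray(samples, dtype=float).ravel()
    if np.ptp(x) == 0:
        return float(x[0])
    grid = np.linspace(x.min(), x.max(), grid_size)
    density = gaussian_kde(x)(grid)
    return float(grid[int(np.argmax(density))])
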