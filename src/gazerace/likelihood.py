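"""Closed-form GLAM race likelihood.

The gaze-weighted linear accumulator model (GLAM) turns trial-level gaze and
value data into one constant drift rate per item and treats the decision as a
race of independent linear diffusion accumulators toward a common boundary
``b = 1``:

1. Average absolute signal per item:  ``A_i = g_i r_i + (1 - g_i) * gamma * r_i``,
   where ``g_i`` is the fraction of trial time spent looking at item ``i`` and
   ``gamma <= 1`` is the gaze-bias weight (``gamma = 1``: no gaze influence,
   ``gamma < 0``: evidence is actively lost while unattended).
2. Relative signal: ``R_i = logistic(tau * (A_i - max_{j != i} A_j))``.
3. Drift of accumulator ``i``: ``v * R_i``.

The first-passage time of one accumulator is inverse-Gaussian (Wald); the
winning item's density is corrected by the survival probabilities of its
competitors.  A fixed-rate uniform contaminant accounts for lapses.

All densities are evaluated in log space; survival probabilities are floored
at 1e-300 before taking logs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import expit, log_ndtr, ndtr

__all__ = [
    "BOUNDARY",
    "ParameterSet",
    "ContaminantModel",
    "TrialLikelihood",
    "gaze_weighted_signal",
    "relative_signals",
    "ig_fpt_logpdf",
    "ig_fpt_pdf",
    "ig_fpt_cdf",
    "ig_fpt_logsf",
    "race_log_density",
    "race_density",
    "trial_likelihood",
    "table_log_likelihood",
]

#: Decision boundary; fixed to 1 to make the model identifiable.
BOUNDARY = 1.0

_LOG_TINY = np.log(1e-300)


@dataclass(frozen=True)
class ParameterSet:
    """One subject/condition's GLAM parameters.

    Parameters
    ----------
    v : float
        Drift scaling (> 0).  Smaller values produce longer response times.
    gamma : float
        Gaze-bias weight (<= 1; may be negative).
    sigma : float
        Accumulation noise standard deviation (> 0).
    tau : float
        Logistic sensitivity of the relative signal transform (>= 0).
    b : float
        Decision boundary, fixed at 1.
    """

    v: float
    gamma: float
    sigma: float
    tau: float
    b: float = BOUNDARY

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError(f"v must be > 0, got {self.v}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.tau >= 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if not self.gamma <= 1:
            raise ValueError(f"gamma must be <= 1, got {self.gamma}")
        if self.b != BOUNDARY:
            raise ValueError("the boundary b is fixed at 1")


@dataclass(frozen=True)
class ContaminantModel:
    """Uniform lapse model: a random item at a random time.

    ``epsilon`` is the fixed error rate (default 5%, never estimated);
    ``rt_min``/``rt_max`` are the subject's empirical response-time bounds in
    seconds, so the contaminant density is
    ``u(t) = 1 / (n_items * (rt_max - rt_min))`` on its support.
    """

    n_items: int
    rt_min: float
    rt_max: float
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")
        if not self.rt_max > self.rt_min:
            raise ValueError(
                f"rt_max ({self.rt_max}) must exceed rt_min ({self.rt_min})"
            )
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")

    @property
    def log_u(self) -> float:
        """Log of the constant uniform density over items x RT support."""
        return -np.log(self.n_items * (self.rt_max - self.rt_min))


class TrialLikelihood(NamedTuple):
    likelihood: float
    log_likelihood: float


def gaze_weighted_signal(values, gazes, gamma):
    """Average absolute decision signal ``A_i = g_i r_i + (1-g_i) gamma r_i``.

    Computed as ``r * (gamma + g * (1 - gamma))`` — algebraically identical,
    but exact (bitwise ``A = r``) at ``gamma = 1``, so gaze allocation then has
    provably no influence.
    """
    values = np.asarray(values, dtype=float)
    gazes = np.asarray(gazes, dtype=float)
    if values.shape != gazes.shape:
        raise ValueError(
            f"values shape {values.shape} != gazes shape {gazes.shape}"
        )
    if values.shape[-1] < 2:
        raise ValueError("need at least two items")
    return values * (gamma + gazes * (1.0 - gamma))


def _max_of_others(a: np.ndarray) -> np.ndarray:
    """For each entry along the last axis, the maximum of the *other* entries."""
    part = np.partition(a, a.shape[-1] - 2, axis=-1)
    top1 = part[..., -1]
    top2 = part[..., -2]
    out = np.broadcast_to(top1[..., None], a.shape).copy()
    # an entry equal to a unique maximum sees the runner-up instead
    unique_max = np.count_nonzero(a == top1[..., None], axis=-1) == 1
    mask = (a == top1[..., None]) & unique_max[..., None]
    out[mask] = np.broadcast_to(top2[..., None], a.shape)[mask]
    return out


def relative_signals(a_bar, tau):
    """Scaled relative signals ``R_i = logistic(tau * (A_i - max_{j!=i} A_j))``.

    ``tau = 0`` collapses every ``R_i`` to 0.5 (no sensitivity to signal
    differences); an exact tie of the top two signals likewise gives 0.5.
    """
    a_bar = np.asarray(a_bar, dtype=float)
    if a_bar.shape[-1] < 2:
        raise ValueError("need at least two items")
    if np.any(np.asarray(tau) < 0):
        raise ValueError("tau must be >= 0")
    r_star = a_bar - _max_of_others(a_bar)
    return expit(tau * r_star)


def _mu_lambda(drift, sigma, b):
    mu = b / np.asarray(drift, dtype=float)
    lam = (b / np.asarray(sigma, dtype=float)) ** 2
    return mu, lam


def ig_fpt_logpdf(t, drift, sigma, b=BOUNDARY):
    """Log first-passage density of one linear accumulator (inverse Gaussian).

    Mean ``mu = b / drift`` and shape ``lambda = b^2 / sigma^2``; ``t <= 0``
    maps to ``-inf`` (density 0), not an error.
    """
    t = np.asarray(t, dtype=float)
    mu, lam = _mu_lambda(drift, sigma, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpos = np.where(t > 0, t, 1.0)
        logf = 0.5 * (np.log(lam) - np.log(2.0 * np.pi) - 3.0 * np.log(tpos)) \
            - lam * (tpos - mu) ** 2 / (2.0 * mu**2 * tpos)
    return np.where(t > 0, logf, -np.inf)


def ig_fpt_pdf(t, drift, sigma, b=BOUNDARY):
    """First-passage density; see :func:`ig_fpt_logpdf`."""
    return np.exp(ig_fpt_logpdf(t, drift, sigma, b))


def ig_fpt_cdf(t, drift, sigma, b=BOUNDARY):
    """Inverse-Gaussian first-passage CDF.

    ``F(t) = Phi(sqrt(lam/t)(t/mu - 1)) + exp(2 lam/mu) Phi(-sqrt(lam/t)(t/mu + 1))``,
    with the second term evaluated as ``exp(2 lam/mu + logPhi(.))`` to avoid
    overflow when ``lam/mu`` is large.
    """
    t = np.asarray(t, dtype=float)
    mu, lam = _mu_lambda(drift, sigma, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpos = np.where(t > 0, t, 1.0)
        srt = np.sqrt(lam / tpos)
        a = srt * (tpos / mu - 1.0)
        c = -srt * (tpos / mu + 1.0)
        f = ndtr(a) + np.exp(2.0 * lam / mu + log_ndtr(c))
    return np.where(t > 0, np.clip(f, 0.0, 1.0), 0.0)


def ig_fpt_logsf(t, drift, sigma, b=BOUNDARY):
    """Log survival function ``log(1 - F(t))``, floored at log(1e-300).

    Evaluated as ``logPhi(-a) + log1p(-exp(2 lam/mu + logPhi(c) - logPhi(-a)))``
    which is stable far into the upper tail.
    """
    t = np.asarray(t, dtype=float)
    mu, lam = _mu_lambda(drift, sigma, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpos = np.where(t > 0, t, 1.0)
        srt = np.sqrt(lam / tpos)
        a = srt * (tpos / mu - 1.0)
        c = -srt * (tpos / mu + 1.0)
        log_phi_ma = log_ndtr(-a)
        d = 2.0 * lam / mu + log_ndtr(c) - log_phi_ma
        d = np.minimum(d, -1e-16)
        logsf = log_phi_ma + np.log1p(-np.exp(d))
    logsf = np.where(t > 0, logsf, 0.0)
    return np.maximum(logsf, _LOG_TINY)


def race_log_density(t, i, drifts, sigma, b=BOUNDARY):
    """Log joint density that accumulator ``i`` wins the race exactly at ``t``.

    ``log p_i(t) = log f_i(t) + sum_{j != i} log(1 - F_j(t))``: the winner's
    first-passage density corrected by every competitor's survival.
    """
    drifts = np.asarray(drifts, dtype=float)
    if drifts.ndim != 1 or drifts.size < 2:
        raise ValueError("drifts must be a 1-d array of length >= 2")
    if not np.all(np.isfinite(drifts)):
        raise ValueError("drifts must be finite")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t1 = np.atleast_1d(t)
    logf = ig_fpt_logpdf(t1, drifts[i], sigma, b)
    logsf = ig_fpt_logsf(t1[..., None], drifts[None, :], sigma, b)
    out = logf + logsf.sum(axis=-1) - logsf[..., i]
    return out[0] if scalar else out


def race_density(t, i, drifts, sigma, b=BOUNDARY):
    """Joint win density ``p_i(t) = f_i(t) prod_{j != i} (1 - F_j(t))``."""
    return np.exp(race_log_density(t, i, drifts, sigma, b))


def _trial_arrays(trial, n_items):
    values = np.array([trial[f"item_value_{i}"] for i in range(n_items)], float)
    gazes = np.array([trial[f"gaze_{i}"] for i in range(n_items)], float)
    return values, gazes


def trial_likelihood(trial, params: ParameterSet, contaminant: ContaminantModel):
    """Likelihood of one observed (choice, rt) pair under the GLAM.

    ``l_i(t) = (1 - eps) p_i(t) + eps u(t)`` where ``p_i`` is the race density
    built from this trial's values and gazes and ``u`` the uniform contaminant.
    Returns a :class:`TrialLikelihood` with both the likelihood and its log.
    """
    values, gazes = _trial_arrays(trial, contaminant.n_items)
    choice = int(trial["choice"])
    rt = float(trial["rt"])
    a_bar = gaze_weighted_signal(values, gazes, params.gamma)
    r = relative_signals(a_bar, params.tau)
    drifts = params.v * r
    log_race = race_log_density(np.asarray(rt), choice, drifts, params.sigma, params.b)
    eps = contaminant.epsilon
    in_support = contaminant.rt_min <= rt <= contaminant.rt_max
    log_u = contaminant.log_u if in_support else -np.inf
    if eps == 0.0:
        loglik = float(log_race)
    elif eps == 1.0:
        loglik = log_u
    else:
        loglik = float(
            np.logaddexp(np.log1p(-eps) + log_race, np.log(eps) + log_u)
        )
    if np.isnan(loglik):
        raise FloatingPointError(
            f"non-finite likelihood for trial {trial.get('trial', '?')} "
            f"(subject {trial.get('subject', '?')}) at parameters {params}"
        )
    return TrialLikelihood(float(np.exp(loglik)), loglik)


def table_log_likelihood(values, gazes, choice, rt, v, gamma, sigma, tau,
                         epsilon, log_u, b=BOUNDARY):
    """Vectorized per-trial log-likelihood over a whole trial table.

    ``values``/``gazes`` are ``(n, N)``; ``choice``/``rt`` and the four
    parameter vectors are ``(n,)`` (parameters may vary per trial, e.g. under
    condition dependencies); ``log_u`` is the per-trial log contaminant
    density.  Returns the ``(n,)`` vector of trial log-likelihoods.
    """
    values = np.asarray(values, float)
    gazes = np.asarray(gazes, float)
    gamma = np.asarray(gamma, float)
    v = np.asarray(v, float)
    sigma = np.asarray(sigma, float)
    tau = np.asarray(tau, float)
    n = values.shape[0]
    idx = np.arange(n)

    a_bar = values * (gamma[:, None] + gazes * (1.0 - gamma[:, None]))
    r = expit(tau[:, None] * (a_bar - _max_of_others(a_bar)))
    drifts = v[:, None] * r

    log_f = ig_fpt_logpdf(rt, drifts[idx, choice], sigma, b)
    log_sf = ig_fpt_logsf(rt[:, None], drifts, sigma[:, None], b)
    log_race = log_f + log_sf.sum(axis=1) - log_sf[idx, choice]

    if epsilon == 0.0:
        return log_race
    if epsilon == 1.0:
        return np.broadcast_to(np.asarray(log_u, float), (n,)).copy()
    return np.logaddexp(np.log1p(-epsilon) + log_race,
                        np.log(epsilon) + np.asarray(log_u, float))
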