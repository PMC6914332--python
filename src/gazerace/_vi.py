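"""Mean-field variational approximation for GLAM models.

Every free scalar (subject-level parameter instance, and group means/SDs for
hierarchical models) lives on a bounded interval and is mapped to the real
line by a scaled-logit transform.  A diagonal Gaussian is fitted in the
transformed space by stochastic gradient ascent (Adam) on the reparameterized
evidence lower bound; likelihood gradients are obtained by column-wise
central finite differences (subjects are conditionally independent, so one
perturbed table evaluation yields every subject's partial derivative at
once), while the truncated-normal prior and hyperprior gradients are
analytic.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

from ._stats import truncnorm_logpdf


def _phi(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def _truncnorm_dlogpdf_dx(x, loc, scale):
    # truncation constant does not depend on x
    return -(x - loc) / scale**2


def _truncnorm_dlogpdf_dmu(x, mu, sd, lo, hi):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    z = ndtr(b) - ndtr(a)
    return (x - mu) / sd**2 + (_phi(b) - _phi(a)) / (z * sd)


def _truncnorm_dlogpdf_dsd(x, mu, sd, lo, hi):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    z = ndtr(b) - ndtr(a)
    return (-1.0 + ((x - mu) / sd) ** 2 + (_phi(b) * b - _phi(a) * a) / z) / sd


class _Coords:
    """Flat coordinate bookkeeping: subject coords first, then group coords."""

    def __init__(self, model):
        self.model = model
        self.sub = np.argwhere(model.used)            # rows (u, k)
        self.n_sub = len(self.sub)
        self.hier = model.spec.kind == "hierarchical"
        if self.hier:
            K = model.n_instances
            self.grp = [(k, j) for k in range(K) for j in (0, 1)]
        else:
            self.grp = []
        self.n = self.n_sub + len(self.grp)
        lo = np.empty(self.n)
        hi = np.empty(self.n)
        lo[:self.n_sub] = model.bounds_lo[self.sub[:, 1]]
        hi[:self.n_sub] = model.bounds_hi[self.sub[:, 1]]
        for i, (k, j) in enumerate(self.grp):
            hyper = model.hyper_mu[k] if j == 0 else model.hyper_sd[k]
            lo[self.n_sub + i] = hyper.lower
            hi[self.n_sub + i] = hyper.upper
        # keep strictly inside the support (sd of exactly 0 is degenerate)
        self.lo = lo
        self.hi = hi

    def unpack(self, x):
        model = self.model
        theta = np.full((model.n_units, model.n_instances),
                        0.5 * (model.bounds_lo + model.bounds_hi))
        theta[self.sub[:, 0], self.sub[:, 1]] = x[:self.n_sub]
        group = None
        if self.hier:
            group = np.empty((model.n_instances, 2))
            for i, (k, j) in enumerate(self.grp):
                group[k, j] = x[self.n_sub + i]
        return theta, group


def _logp_and_grad(model, coords, x):
    """Total log-density and its gradient at constrained point ``x``."""
    theta, group = coords.unpack(x)
    pt = model.loglik_pointwise(theta)
    ull = model.unit_loglik(pt)
    logp = float(ull.sum())
    grad = np.zeros(coords.n)

    # likelihood gradient for subject coords: column-wise central differences
    for k in range(model.n_instances):
        in_col = coords.sub[:, 1] == k
        if not in_col.any():
            continue
        h = 1e-5 * (model.bounds_hi[k] - model.bounds_lo[k])
        diff = np.zeros(model.n_units)
        for sign in (1.0, -1.0):
            pert = theta.copy()
            pert[:, k] = theta[:, k] + sign * h
            diff += sign * model.unit_loglik(model.loglik_pointwise(pert))
        dcol = diff / (2.0 * h)
        grad[:coords.n_sub][in_col] = dcol[coords.sub[in_col, 0]]

    if coords.hier:
        lo_k, hi_k = model.bounds_lo, model.bounds_hi
        for i, (k, j) in enumerate(coords.grp):
            members = theta[model.used[:, k], k]
            mu, sd = group[k]
            hyper = model.hyper_mu[k] if j == 0 else model.hyper_sd[k]
            val = group[k, j]
            if j == 0:
                g = _truncnorm_dlogpdf_dmu(members, mu, sd, lo_k[k], hi_k[k]).sum()
            else:
                g = _truncnorm_dlogpdf_dsd(members, mu, sd, lo_k[k], hi_k[k]).sum()
            g += _truncnorm_dlogpdf_dx(val, hyper.loc, hyper.scale)
            grad[coords.n_sub + i] = g
            logp += float(truncnorm_logpdf(val, hyper.loc, hyper.scale,
                                           hyper.lower, hyper.upper))
        # subject-prior terms: contribute to logp and to subject-coord grads
        for k in range(model.n_instances):
            members_mask = model.used[:, k]
            members = theta[members_mask, k]
            lp = truncnorm_logpdf(members, group[k, 0], group[k, 1],
                                  model.bounds_lo[k], model.bounds_hi[k])
            logp += float(lp.sum())
            dx = _truncnorm_dlogpdf_dx(members, group[k, 0], group[k, 1])
            in_col = coords.sub[:, 1] == k
            grad[:coords.n_sub][in_col] += dx
    return logp, grad


def run_vi(model, iterations, n_draws, learning_rate, seed):
    """Optimize the mean-field ELBO; returns draws shaped like MCMC output."""
    rng = np.random.default_rng(seed)
    coords = _Coords(model)
    span = coords.hi - coords.lo

    m = np.zeros(coords.n)          # transformed-space means (midpoints)
    log_s = np.full(coords.n, np.log(0.3))
    mm = np.zeros((2, coords.n))    # Adam first moments
    vv = np.zeros((2, coords.n))    # Adam second moments
    b1, b2, eps = 0.9, 0.999, 1e-8
    trace = []

    for it in range(1, iterations + 1):
        s = np.exp(log_s)
        z = m + s * rng.standard_normal(coords.n)
        sig = expit(z)
        x = coords.lo + span * sig
        logp, grad_x = _logp_and_grad(model, coords, x)
        if not np.isfinite(logp):
            raise RuntimeError(
                f"variational optimizer diverged at iteration {it}; "
                f"recent ELBO trace: {trace[-10:]}"
            )
        dxdz = span * sig * (1.0 - sig)
        # d/dz [log p(x(z)) + log |dx/dz|]
        gz = grad_x * dxdz + (1.0 - 2.0 * sig)
        g_m = gz
        g_ls = gz * (z - m) + 1.0   # + entropy gradient
        if it % 50 == 0:
            elbo = logp + float(np.sum(np.log(dxdz))) + float(np.sum(log_s))
            trace.append(elbo)

        for idx, g in enumerate((g_m, g_ls)):
            mm[idx] = b1 * mm[idx] + (1 - b1) * g
            vv[idx] = b2 * vv[idx] + (1 - b2) * g * g
            mhat = mm[idx] / (1 - b1**it)
            vhat = vv[idx] / (1 - b2**it)
            stepv = learning_rate * mhat / (np.sqrt(vhat) + eps)
            if idx == 0:
                m += stepv
            else:
                log_s += stepv
        np.clip(log_s, -10.0, 2.0, out=log_s)

    # draw from the fitted family, shaped (chains=2, n_draws//2)
    half = n_draws // 2
    z = m + np.exp(log_s) * rng.standard_normal((2 * half, coords.n))
    x = coords.lo + span * expit(z)

    units, K = model.n_units, model.n_instances
    theta = np.full((2, half, units, K),
                    0.5 * (model.bounds_lo + model.bounds_hi))
    flat = x[:, :coords.n_sub].reshape(2, half, coords.n_sub)
    theta[:, :, coords.sub[:, 0], coords.sub[:, 1]] = flat
    group = None
    if coords.hier:
        group = np.empty((2, half, K, 2))
        for i, (k, j) in enumerate(coords.grp):
            group[:, :, k, j] = x[:, coords.n_sub + i].reshape(2, half)

    pointwise = np.empty((2, half, model.n_trials), dtype=np.float32)
    for c in range(2):
        for d in range(half):
            pointwise[c, d] = model.loglik_pointwise(theta[c, d])
    return theta, group, pointwise, trace
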