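"""Adaptive Metropolis-within-Gibbs sampler for GLAM models.

Subjects are conditionally independent given the group-level parameters, so
one sweep proposes, for every free-parameter instance (column), a new value
for *all* units at once and accepts or rejects per unit — the per-trial
likelihood is evaluated vectorized over the whole table.  Hierarchical group
means and standard deviations are updated by scalar Metropolis steps against
their cheap truncated-normal conditionals.

Proposal scales adapt per (unit, column) toward a 0.44 acceptance rate during
the tuning phase only; they are frozen afterwards so the retained draws
target the exact posterior.
"""

from __future__ import annotations

import numpy as np

from ._stats import truncnorm_logpdf

_ADAPT_WINDOW = 25
_TARGET_RATE = 0.44


def _init_state(model, rng):
    units, K = model.n_units, model.n_instances
    lo, hi = model.bounds_lo, model.bounds_hi
    theta = np.empty((units, K))
    group = None
    if model.kind == "hierarchical":
        group = np.empty((K, 2))
        for k in range(K):
            hm, hs = model.hyper_mu[k], model.hyper_sd[k]
            mu0 = np.clip(hm.loc + 0.05 * (hm.upper - hm.lower) * rng.standard_normal(),
                          hm.lower + 1e-6 * (hm.upper - hm.lower), hm.upper)
            sd0 = np.clip(hs.loc * (1.0 + 0.1 * rng.standard_normal()),
                          max(hs.lower, 1e-3), hs.upper)
            group[k] = (mu0, sd0)
            eps = 1e-6 * (hi[k] - lo[k])
            theta[:, k] = np.clip(mu0 + 0.5 * sd0 * rng.standard_normal(units),
                                  lo[k] + eps, hi[k] - eps)
        return theta, group

    for attempt in range(200):
        bad = None
        if attempt == 0:
            theta[:] = lo + (hi - lo) * rng.random((units, K))
        ull = model.unit_loglik(model.loglik_pointwise(theta))
        bad = ~np.isfinite(ull)
        if not bad.any():
            return theta, None
        theta[bad] = lo + (hi - lo) * rng.random((int(bad.sum()), K))
    raise RuntimeError(
        f"could not find a finite initial log-density; last point {theta[bad][:3]}"
    )


def _subject_prior_col(model, group, col_values, k):
    """Per-unit log prior of one column (0 for uniform priors)."""
    if model.kind != "hierarchical":
        return np.zeros_like(col_values)
    return truncnorm_logpdf(col_values, group[k, 0], group[k, 1],
                            model.bounds_lo[k], model.bounds_hi[k])


def _group_conditional(model, theta, group, k, j, value):
    """Log conditional of group mean (j=0) or sd (j=1) for instance k."""
    hyper = model.hyper_mu[k] if j == 0 else model.hyper_sd[k]
    if not (hyper.lower < value < hyper.upper) or (j == 1 and value <= 0):
        return -np.inf
    mu, sd = (value, group[k, 1]) if j == 0 else (group[k, 0], value)
    members = theta[model.used[:, k], k]
    lp = truncnorm_logpdf(members, mu, sd, model.bounds_lo[k],
                          model.bounds_hi[k]).sum()
    lp += truncnorm_logpdf(value, hyper.loc, hyper.scale, hyper.lower, hyper.upper)
    return float(lp)


def _grad_col(model, theta, group, unit_ll, k, h):
    """Finite-difference gradient of each unit's conditional log-density
    with respect to column k (used by the MALA step)."""
    g = np.zeros(model.n_units)
    for sign in (1.0, -1.0):
        pert = theta.copy()
        pert[:, k] = theta[:, k] + sign * h
        ull = model.unit_loglik(model.loglik_pointwise(pert))
        ull = ull + _subject_prior_col(model, group, pert[:, k], k)
        g += sign * ull
    return g / (2.0 * h)


def sample_chain(model, draws, tune, rng, step="metropolis"):
    """Run one chain; returns (theta_draws, group_draws, pointwise_draws)."""
    units, K, n = model.n_units, model.n_instances, model.n_trials
    lo, hi = model.bounds_lo, model.bounds_hi
    used = model.used
    hierarchical = model.kind == "hierarchical"
    mala = step == "mala"

    theta, group = _init_state(model, rng)
    pt = model.loglik_pointwise(theta)
    unit_ll = model.unit_loglik(pt)

    log_scale = np.log(np.broadcast_to(0.1 * (hi - lo), (units, K)).copy())
    acc = np.zeros((units, K))
    if hierarchical:
        g_log_scale = np.empty((K, 2))
        for k in range(K):
            g_log_scale[k, 0] = np.log(max(0.1 * model.hyper_mu[k].scale, 1e-3))
            g_log_scale[k, 1] = np.log(max(0.1 * model.hyper_sd[k].scale, 1e-3))
        g_acc = np.zeros((K, 2))

    theta_draws = np.empty((draws, units, K))
    group_draws = np.empty((draws, K, 2)) if hierarchical else None
    pt_draws = np.empty((draws, n), dtype=np.float32)

    window = 0
    for it in range(tune + draws):
        adapting = it < tune
        for k in range(K):
            scale = np.exp(log_scale[:, k])
            if mala:
                h = 1e-4 * (hi[k] - lo[k])
                grad = _grad_col(model, theta, group, unit_ll, k, h)
                drift_fwd = 0.5 * scale**2 * grad
                prop = theta[:, k] + drift_fwd + scale * rng.standard_normal(units)
            else:
                prop = theta[:, k] + scale * rng.standard_normal(units)
            inside = used[:, k] & (prop > lo[k]) & (prop < hi[k])
            theta_prop = theta.copy()
            theta_prop[:, k] = np.where(inside, prop, theta[:, k])
            pt_prop = model.loglik_pointwise(theta_prop)
            ull_prop = model.unit_loglik(pt_prop)
            dlp = ull_prop - unit_ll
            if hierarchical:
                dlp = dlp + _subject_prior_col(model, group, theta_prop[:, k], k) \
                    - _subject_prior_col(model, group, theta[:, k], k)
            if mala:
                grad_rev = _grad_col(model, theta_prop, group, ull_prop, k, h)
                drift_rev = 0.5 * scale**2 * grad_rev
                fwd = -((prop - theta[:, k] - drift_fwd) ** 2) / (2 * scale**2)
                rev = -((theta[:, k] - prop - drift_rev) ** 2) / (2 * scale**2)
                dlp = dlp + rev - fwd
            accept = inside & (np.log(rng.random(units)) < dlp)
            if accept.any():
                theta[accept, k] = theta_prop[accept, k]
                unit_ll[accept] = ull_prop[accept]
                tmask = accept[model.unit_of_trial]
                pt[tmask] = pt_prop[tmask]
            acc[:, k] += accept

        if hierarchical:
            for k in range(K):
                for j in (0, 1):
                    cur = group[k, j]
                    lp_cur = _group_conditional(model, theta, group, k, j, cur)
                    prop = cur + np.exp(g_log_scale[k, j]) * rng.standard_normal()
                    lp_prop = _group_conditional(model, theta, group, k, j, prop)
                    if np.log(rng.random()) < lp_prop - lp_cur:
                        group[k, j] = prop
                        g_acc[k, j] += 1
                        # group parameters entered the subject priors only;
                        # cached likelihoods are unaffected

        if adapting and (it + 1) % _ADAPT_WINDOW == 0:
            window += 1
            delta = min(0.5, 2.0 / np.sqrt(window))
            log_scale += delta * (acc / _ADAPT_WINDOW - _TARGET_RATE)
            np.clip(log_scale, np.log(1e-7 * (hi - lo)), np.log(5.0 * (hi - lo)),
                    out=log_scale)
            acc[:] = 0
            if hierarchical:
                g_log_scale += delta * (g_acc / _ADAPT_WINDOW - _TARGET_RATE)
                g_acc[:] = 0

        if not adapting:
            d = it - tune
            theta_draws[d] = theta
            if hierarchical:
                group_draws[d] = group
            pt_draws[d] = pt

    return theta_draws, group_draws, pt_draws


def run_mcmc(model, draws, tune, chains, seed=None, step="metropolis"):
    """Run ``chains`` independent chains; returns stacked raw draws."""
    if step not in ("metropolis", "mala"):
        raise ValueError("step must be 'metropolis' or 'mala'")
    seqs = np.random.SeedSequence(seed).spawn(chains)
    theta_all, group_all, pt_all = [], [], []
    for c in range(chains):
        rng = np.random.default_rng(seqs[c])
        th, gr, pt = sample_chain(model, draws, tune, rng, step)
        theta_all.append(th)
        group_all.append(gr)
        pt_all.append(pt)
    theta = np.stack(theta_all)              # (chains, draws, units, K)
    group = np.stack(group_all) if group_all[0] is not None else None
    pointwise = np.stack(pt_all)             # (chains, draws, n)
    return theta, group, pointwise
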