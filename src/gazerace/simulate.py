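"""Exact forward simulation of GLAM behaviour.

Because the racers are independent given the trial's drifts, a trial can be
simulated exactly: draw one inverse-Gaussian (Wald) first-passage time per
accumulator and keep the argmin — no time discretization is involved.  With
probability ``epsilon`` a trial is replaced by a contaminant response
(uniform item, uniform RT over the contaminant support).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import data as _data
from .likelihood import (BOUNDARY, ContaminantModel, ParameterSet,
                         gaze_weighted_signal, relative_signals)
from .priors import PARAMETERS, canonical_parameter

__all__ = ["GroupSpec", "SimulationResult", "simulate_trial", "simulate_group",
           "predict"]

# Per-subject heterogeneity of the default generator: truncated normals
# centred on the across-dataset group-level locations with the across-dataset
# spread as SD, truncated to the uniform prior support.
_INDIVIDUAL_DEFAULTS = {
    "v": (0.63, 0.26), "gamma": (0.12, 0.35),
    "sigma": (0.27, 0.05), "tau": (1.03, 0.62),
}
# Within-group SDs for hierarchical generation (group means supplied by the
# user; groups in the motivating designs are clearly separated).
_HIERARCHICAL_SD_DEFAULTS = {"v": 0.2, "gamma": 0.2, "sigma": 0.05, "tau": 0.3}
_SUPPORT = {"v": (0.0, 4.0), "gamma": (-2.0, 1.0),
            "sigma": (0.0, 4.0), "tau": (0.0, 10.0)}


def _truncated_normal(rng, loc, scale, lower, upper, size):
    out = np.empty(size, float)
    todo = np.arange(size)
    for _ in range(1000):
        draw = rng.normal(loc, scale, todo.size)
        ok = (draw >= lower) & (draw <= upper)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise RuntimeError("truncated-normal rejection sampling did not terminate")


@dataclass
class GroupSpec:
    """Study design for :func:`simulate_group`.

    ``kind='individual'`` takes per-subject parameters (dict of arrays, one
    entry per subject; missing parameters are drawn from the package's default
    truncated-normal population).  ``kind='hierarchical'`` takes group-level
    means and SDs per parameter (``{'gamma': {'mu': 0.1, 'sd': 0.2}, ...}``;
    ``mu`` may be a dict keyed by group label when ``group_labels`` is set)
    and draws each subject's parameters from the corresponding truncated
    normal.  Values are i.i.d. uniform integers on [value_low, value_high]
    (the recommended 1-10 rating scale); gaze vectors are symmetric
    Dirichlet(concentration) draws, independent of the values.
    """

    kind: str = "individual"
    n_individuals: int = 30
    n_trials: int = 300
    n_items: int = 3
    parameters: dict | None = None
    group_labels: list | None = None
    no_bias_subjects: list = field(default_factory=list)
    value_low: int = 1
    value_high: int = 10
    gaze_concentration: float = 1.0
    error_weight: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("individual", "hierarchical"):
            raise ValueError("kind must be 'individual' or 'hierarchical'")
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")
        if self.n_individuals < 1 or self.n_trials < 1:
            raise ValueError("n_individuals and n_trials must be positive")
        if self.group_labels is not None and len(self.group_labels) != self.n_individuals:
            raise ValueError("group_labels must have one entry per subject")


@dataclass
class SimulationResult:
    """Simulated trial table plus the generating per-subject parameters."""

    data: pd.DataFrame
    parameters: pd.DataFrame


def simulate_trial(values, gazes, params: ParameterSet,
                   contaminant: ContaminantModel, rng) -> tuple:
    """Simulate one (choice, rt) pair.

    With probability ``epsilon``: a uniform item and a uniform RT on the
    contaminant support.  Otherwise each accumulator's first-passage time is
    drawn from its inverse Gaussian (mean ``b / (v R_i)``, shape
    ``b^2 / sigma^2``) and the fastest accumulator wins.
    """
    if rng.random() < contaminant.epsilon:
        choice = int(rng.integers(contaminant.n_items))
        rt = float(rng.uniform(contaminant.rt_min, contaminant.rt_max))
        return choice, rt
    r = relative_signals(gaze_weighted_signal(values, gazes, params.gamma),
                         params.tau)
    drifts = params.v * r
    fpt = rng.wald(params.b / drifts, (params.b / params.sigma) ** 2)
    return int(np.argmin(fpt)), float(np.min(fpt))


def _race_rts(values, gazes, v, gamma, sigma, tau, rng):
    """Vectorized exact race over many trials; per-trial parameter vectors."""
    a_bar = values * (gamma[:, None] + gazes * (1.0 - gamma[:, None]))
    from .likelihood import _max_of_others
    from scipy.special import expit

    r = expit(tau[:, None] * (a_bar - _max_of_others(a_bar)))
    drifts = v[:, None] * r
    fpt = rng.wald(BOUNDARY / drifts, (BOUNDARY / sigma[:, None]) ** 2)
    return fpt.argmin(axis=1), fpt.min(axis=1)


def _resolve_parameters(spec: GroupSpec, rng) -> pd.DataFrame:
    S = spec.n_individuals
    params = {}
    supplied = {canonical_parameter(k): np.asarray(val, float)
                for k, val in (spec.parameters or {}).items()} \
        if spec.kind == "individual" else {}
    if spec.kind == "individual":
        for p in PARAMETERS:
            if p in supplied:
                arr = supplied[p]
                if arr.shape != (S,):
                    raise ValueError(
                        f"parameters[{p!r}] must have length n_individuals={S}"
                    )
                params[p] = arr.copy()
            else:
                loc, scale = _INDIVIDUAL_DEFAULTS[p]
                lo, hi = _SUPPORT[p]
                params[p] = _truncated_normal(rng, loc, scale, lo, hi, S)
    else:
        spec_params = {canonical_parameter(k): v
                       for k, v in (spec.parameters or {}).items()}
        labels = (np.asarray(spec.group_labels)
                  if spec.group_labels is not None else np.zeros(S, int))
        for p in PARAMETERS:
            conf = spec_params.get(p, {})
            if conf and "mu" in conf and "sd" not in conf:
                raise ValueError(f"hierarchical spec for {p!r} is missing the group s.d.")
            mu = conf.get("mu", _INDIVIDUAL_DEFAULTS[p][0])
            sd = conf.get("sd", _HIERARCHICAL_SD_DEFAULTS[p])
            lo, hi = _SUPPORT[p]
            draws = np.empty(S, float)
            for lab in np.unique(labels):
                mask = labels == lab
                mu_g = mu[lab] if isinstance(mu, dict) else mu
                sd_g = sd[lab] if isinstance(sd, dict) else sd
                draws[mask] = _truncated_normal(rng, mu_g, sd_g, lo, hi,
                                                int(mask.sum()))
            params[p] = draws
    if spec.no_bias_subjects:
        params["gamma"] = params["gamma"].copy()
        params["gamma"][np.asarray(spec.no_bias_subjects, int)] = 1.0
    out = pd.DataFrame({"subject": np.arange(S), **params})
    return out


def simulate_group(spec: GroupSpec) -> SimulationResult:
    """Simulate a full cohort; returns trials and generating parameters.

    The contaminant RT support of each simulated subject is the 1st-99th
    percentile range of that subject's race-component RTs (no empirical RTs
    exist yet, so the race itself defines a self-consistent support).
    """
    rng = np.random.default_rng(spec.seed)
    pars = _resolve_parameters(spec, rng)
    S, T, N = spec.n_individuals, spec.n_trials, spec.n_items
    n = S * T
    subject = np.repeat(np.arange(S), T)

    values = rng.integers(spec.value_low, spec.value_high + 1, (n, N)).astype(float)
    gazes = rng.dirichlet(np.full(N, spec.gaze_concentration), n)

    v = pars["v"].to_numpy()[subject]
    gamma = pars["gamma"].to_numpy()[subject]
    sigma = pars["sigma"].to_numpy()[subject]
    tau = pars["tau"].to_numpy()[subject]
    choice, rt = _race_rts(values, gazes, v, gamma, sigma, tau, rng)

    if spec.error_weight > 0:
        lapse = rng.random(n) < spec.error_weight
        lo = np.empty(S)
        hi = np.empty(S)
        for s in range(S):
            lo[s], hi[s] = np.percentile(rt[subject == s], [1.0, 99.0])
        choice = np.where(lapse, rng.integers(0, N, n), choice)
        rt = np.where(lapse, rng.uniform(lo[subject], hi[subject]), rt)

    table = pd.DataFrame({
        "subject": subject,
        "trial": np.tile(np.arange(T), S),
        "choice": choice.astype(int),
        "rt": rt,
    })
    for i in range(N):
        table[f"item_value_{i}"] = values[:, i]
    for i in range(N):
        table[f"gaze_{i}"] = gazes[:, i]
    if spec.group_labels is not None:
        table["group"] = np.asarray(spec.group_labels)[subject]
        pars = pars.assign(group=np.asarray(spec.group_labels))
    return SimulationResult(table, pars)


def predict(data: pd.DataFrame, estimates: pd.DataFrame, n_repeats: int = 1,
            error_weight: float = 0.05, seed: int | None = None) -> pd.DataFrame:
    """Posterior-predictive simulation of every observed trial.

    Each trial is replicated ``n_repeats`` times through the exact sampler
    using the subject's (per-condition) point estimates and the trial's
    observed values and gazes.  The contaminant support is the subject's
    empirical RT range in ``data``.  Output rows keep their provenance
    columns plus a ``repeat`` index.
    """
    n_items = _data.validate_trial_table(data)
    rng = np.random.default_rng(seed)
    estimates = estimates.rename(columns={"s": "sigma"})
    for p in PARAMETERS:
        if p not in estimates.columns:
            raise ValueError(f"estimates table lacks a {p!r} column")

    missing = set(data["subject"].unique()) - set(estimates["subject"].unique())
    if missing:
        raise ValueError(
            f"no estimates for subjects {sorted(int(s) for s in missing)}")

    merge_on = ["subject"] + [c for c in _data.factor_columns(data, n_items)
                              if c in estimates.columns]
    merged = data.merge(estimates[merge_on + list(PARAMETERS)], on=merge_on,
                        how="left", validate="many_to_one")
    if merged[list(PARAMETERS)].isna().any().any():
        raise ValueError("estimates do not cover every subject/condition in data")

    rep = pd.concat([merged.assign(repeat=k) for k in range(n_repeats)],
                    ignore_index=True)
    vcols, gcols = _data.item_columns(n_items)
    values = rep[vcols].to_numpy(float)
    gazes = rep[gcols].to_numpy(float)
    choice, rt = _race_rts(values, gazes, rep["v"].to_numpy(),
                           rep["gamma"].to_numpy(), rep["sigma"].to_numpy(),
                           rep["tau"].to_numpy(), rng)
    if error_weight > 0:
        bounds = data.groupby("subject")["rt"].agg(["min", "max"])
        lo = bounds["min"].reindex(rep["subject"]).to_numpy()
        hi = bounds["max"].reindex(rep["subject"]).to_numpy()
        degenerate = ~(hi > lo)
        if degenerate.any():
            warnings.warn("degenerate contaminant support (single observed RT); "
                          "lapse trials resample the observed RT")
            hi = np.where(degenerate, lo + 1e-9, hi)
        lapse = rng.random(len(rep)) < error_weight
        choice = np.where(lapse, rng.integers(0, n_items, len(rep)), choice)
        rt = np.where(lapse, rng.uniform(lo, hi), rt)

    out = rep.drop(columns=list(PARAMETERS))
    out["choice"] = choice.astype(int)
    out["rt"] = rt
    return out
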